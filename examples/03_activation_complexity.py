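"""Activation Complexity of an intact vs a partially isolated population.

Two local field potentials are simulated from the same rhythmic spiking
population — one intact, one with 40% of scheduled spikes suppressed
(emulating hypoxia-induced neuronal isolation).  AC is the sample
entropy of the inter-peak-interval sequence of the rhythm band's
intensity envelope: regular waxing-waning gives low AC, disrupted surge
timing gives high AC.
"""

import warnings

from eegac import FilterBank, SpikePopulation, activation_complexity, decompose, gen_lfp, published_bank
from eegac.experiments import rhythm_matched_filter

warnings.filterwarnings("ignore")

fs = 256.0
bank = published_bank()
fi = rhythm_matched_filter(bank, 10.0)
sub = FilterBank(specs=[bank.specs[fi]])

for label, iso in [("intact (isolation 0.0)", 0.0), ("isolated (isolation 0.4)", 0.4)]:
    pop = SpikePopulation(isolation_frac=iso, duration=600.0)
    sig = gen_lfp(pop, fs=fs, seed=42)
    stack = decompose(sig.samples, sub, fs)
    cell = activation_complexity(stack).cells[0]
    print(f"{label}: AC = {cell.ac:.3f} from {cell.n_peaks} intensity peaks "
          f"in filter {fi + 1} ({bank.specs[fi].band})")

print("\nHigher AC for the isolated population = more irregular surge timing,")
print("the signature this feature is designed to detect.")
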