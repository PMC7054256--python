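import numpy as np
import pytest

from eegac.bank import published_bank
from eegac.intensity import decompose
from eegac.synthetic import reference_composite


@pytest.fixture(scope="session")
def bank():
    return published_bank()


@pytest.fixture(scope="session")
def composite():
    return reference_composite(fs=256.0)


@pytest.fixture(scope="session")
def composite_stack(bank, composite):
    return decompose(composite.samples, bank, composite.fs)


def sampen_bruteforce(x, m, tol):
    """Independent double-loop oracle for the sample-entropy match counts.

    Counts unordered pairs (i < j) of m- and (m+1)-length templates
    within Chebyshev distance tol, using only templates that admit an
    (m+1)-length extension.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    n_t = n - m
    b = 0
    a = 0
    for i in range(n_t):
        for j in range(i + 1, n_t):
            db = 0.0
            for k in range(m):
                db = max(db, abs(x[i + k] - x[j + k]))
            if db <= tol:
                b += 1
            da = max(db, abs(x[i + m] - x[j + m]))
            if da <= tol:
                a += 1
    return a, b
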