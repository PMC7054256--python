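"""Design and inspection of the EEG-band-constrained flattened-Gaussian filter bank.

Each filter is a frequency-domain "flattened Gaussian"

    psi(f) = exp(-a (f - fc)^2 - b (f - fc)^4) * H(f),

parameterized by its center frequency ``fc`` (Hz), a quadratic shape
parameter ``a`` (Hz^-2) and a quartic shape parameter ``b`` (Hz^-4); the
Heaviside factor ``H`` zeroes negative frequencies so the filter is
analytic (one-sided).  The quartic term flattens the passband top and
steepens the skirts relative to an ordinary Gaussian.

A bank is a set of K such filters whose centers are pinned to the
classical EEG rhythm bands (delta ... gamma) and whose summed response is
optimized to be flat ("plateau") between the first and last center
frequency.  Flatness is quantified by the *plateau value*: the standard
deviation of the summed gain sampled on a fine grid — near zero means the
bank partitions the spectrum with no band dominating.

Design runs in two steps:

1. center-frequency seeding — place the K centers inside admissible
   windows derived from the band boundary table so that adjacent spacings
   are as equal as possible;
2. sliding triplet optimization — minimize the normalized excess arc
   length of the summed response of three consecutive filters at a time,
   subject to cutoff-window, parameter-bound and neighbor-leakage
   constraints, fixing the last filter of each round before the next.

``published_bank`` returns the 12-filter reference parameterization used
throughout the validation suite.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "BandDefinition",
    "CenterWindow",
    "FilterSpec",
    "FilterBank",
    "BankDesignError",
    "basis_eval",
    "cutoffs",
    "band_windows",
    "cutoff_windows",
    "optimize_spacing",
    "arc_length_objective",
    "optimize_triplet",
    "build_bank",
    "plateau",
    "published_bank",
    "default_bands",
    "load_bands",
]

#: neighbor-leakage design bound: gain of a filter evaluated at an adjacent
#: filter's center frequency may not exceed this.
EPSILON = 5e-4

#: default bounds for the shape parameters; bracket the published values
#: with margin.
A_BOUNDS = (0.0005, 0.5)
B_BOUNDS = (0.01, 0.5)

#: default plateau evaluation grid spacing in Hz.
PLATEAU_GRID = 0.01


class BankDesignError(ValueError):
    """Raised for infeasible or inconsistent bank configurations."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BandDefinition:
    """One EEG rhythm band with fuzzy edges.

    The band's lower edge lies somewhere in ``[start_lo, start_hi]`` and
    its upper edge in ``[end_lo, end_hi]`` (both Hz); the literature does
    not agree on exact boundaries, and this admissible range is what the
    center/cutoff windows are built from.  ``n_filters`` filters share
    the band.
    """

    name: str
    start_lo: float
    start_hi: float
    end_lo: float
    end_hi: float
    n_filters: int = 1

    def __post_init__(self) -> None:
        if not (self.start_lo <= self.start_hi < self.end_lo <= self.end_hi):
            raise BankDesignError(
                f"band {self.name!r}: edge ranges must satisfy "
                "start_lo <= start_hi < end_lo <= end_hi, got "
                f"({self.start_lo}, {self.start_hi}, {self.end_lo}, {self.end_hi})"
            )
        if self.n_filters < 1:
            raise BankDesignError(f"band {self.name!r}: n_filters must be >= 1")


@dataclass(frozen=True)
class CenterWindow:
    """Admissible range for one filter's center frequency.

    ``hard`` windows are forced by adjacent bands (midpoints of the
    band-edge ranges); ``soft`` windows arise when several filters share
    a band and the interior boundaries are artificial.
    """

    lb: float
    ub: float
    kind: str = "hard"  # "hard" | "soft"
    band: str = ""

    def __post_init__(self) -> None:
        if not self.lb < self.ub:
            raise BankDesignError(
                f"degenerate center window [{self.lb}, {self.ub}] for band "
                f"{self.band!r}: lower bound must be strictly below upper bound"
            )


@dataclass(frozen=True)
class FilterSpec:
    """One flattened-Gaussian filter.

    ``fco_lo``/``fco_hi`` are the derived 1/e cutoffs; ``annotated_lo``/
    ``annotated_hi`` carry printed reference cutoffs where available
    (informational only — they may differ from the derived values by
    rounding).
    """

    fc: float
    a: float
    b: float
    band: str = ""
    annotated_lo: float | None = None
    annotated_hi: float | None = None

    def __post_init__(self) -> None:
        if self.fc <= 0:
            raise BankDesignError(f"center frequency must be positive, got {self.fc}")
        if self.b <= 0:
            raise BankDesignError(f"quartic shape parameter b must be > 0, got {self.b}")
        if self.a < 0:
            raise BankDesignError(f"quadratic shape parameter a must be >= 0, got {self.a}")

    @property
    def fco_lo(self) -> float:
        return cutoffs(self)[0]

    @property
    def fco_hi(self) -> float:
        return cutoffs(self)[1]


@dataclass
class FilterBank:
    """Ordered collection of filters plus plateau diagnostics."""

    specs: list[FilterSpec]
    epsilon: float = EPSILON
    plateau_grid: float = PLATEAU_GRID
    plateau_vector: np.ndarray | None = field(default=None, repr=False)
    plateau_value: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.specs) < 1:
            raise BankDesignError("a bank needs at least one filter")
        fcs = [s.fc for s in self.specs]
        if any(f2 <= f1 for f1, f2 in zip(fcs, fcs[1:])):
            raise BankDesignError("center frequencies must be strictly increasing")

    def __len__(self) -> int:
        return len(self.specs)

    def __iter__(self):
        return iter(self.specs)

    @property
    def center_frequencies(self) -> np.ndarray:
        return np.array([s.fc for s in self.specs])

    def with_plateau(self, grid: float | None = None) -> "FilterBank":
        """Return a copy with plateau diagnostics computed over [fc_1, fc_K]."""
        g = self.plateau_grid if grid is None else grid
        pv, p_v = plateau(self, g, self.specs[0].fc, self.specs[-1].fc)
        return replace(self, plateau_grid=g, plateau_vector=pv, plateau_value=p_v)

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "name": self.name,
            "epsilon": self.epsilon,
            "grid": self.plateau_grid,
            "plateau_value": self.plateau_value,
            "filters": [
                {
                    "band": s.band,
                    "fc": s.fc,
                    "a": s.a,
                    "b": s.b,
                    "fco_lo": s.fco_lo,
                    "fco_hi": s.fco_hi,
                    "annotated_lo": s.annotated_lo,
                    "annotated_hi": s.annotated_hi,
                }
                for s in self.specs
            ],
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "FilterBank":
        p = Path(source)
        doc = json.loads(p.read_text()) if p.exists() else json.loads(str(source))
        specs = [
            FilterSpec(
                fc=d["fc"],
                a=d["a"],
                b=d["b"],
                band=d.get("band", ""),
                annotated_lo=d.get("annotated_lo"),
                annotated_hi=d.get("annotated_hi"),
            )
            for d in doc["filters"]
        ]
        bank = cls(
            specs=specs,
            epsilon=doc.get("epsilon", EPSILON),
            plateau_grid=doc.get("grid", PLATEAU_GRID),
            name=doc.get("name", ""),
        )
        if doc.get("plateau_value") is not None:
            bank = bank.with_plateau()
        return bank


# ---------------------------------------------------------------------------
# basis function and cutoffs
# ---------------------------------------------------------------------------


def basis_eval(f, spec: FilterSpec):
    """Gain of one filter at frequency ``f`` (Hz); 0 for negative frequencies.

    Vectorized over ``f``; the result lies in [0, 1] and attains 1 only
    at the center frequency.
    """
    farr = np.asarray(f, dtype=float)
    d = farr - spec.fc
    gain = np.exp(-spec.a * d**2 - spec.b * d**4)
    out = np.where(farr >= 0.0, gain, 0.0)
    return float(out) if np.isscalar(f) else out


def cutoffs(spec: FilterSpec) -> tuple[float, float]:
    """1/e cutoff frequencies, symmetric about the center.

    The half-width solves a w^2 + b w^4 = 1, giving
    w = sqrt((sqrt(a^2 + 4b) - a) / (2b)).
    """
    if spec.b <= 0:
        raise BankDesignError("cutoffs undefined for b <= 0")
    w = math.sqrt((math.sqrt(spec.a**2 + 4.0 * spec.b) - spec.a) / (2.0 * spec.b))
    return spec.fc - w, spec.fc + w


# ---------------------------------------------------------------------------
# band table -> center / cutoff windows
# ---------------------------------------------------------------------------


def default_bands() -> list[BandDefinition]:
    """Default seven-band table with a (1,1,2,1,1,3,3) filter allocation.

    Delta/theta/alpha edge ranges follow the classical literature span;
    where adjacent band boundaries are quoted as a single number the
    admissible range is taken as +-0.5 Hz around it.  Gamma is truncated
    near 38 Hz: twelve filters cover delta through low gamma.
    """
    return [
        BandDefinition("delta", 0.5, 1.0, 3.0, 4.0, 1),
        BandDefinition("theta", 3.0, 4.0, 7.0, 8.0, 1),
        BandDefinition("alpha", 7.0, 8.0, 12.0, 13.0, 2),
        BandDefinition("low_beta", 12.0, 13.0, 14.5, 15.5, 1),
        BandDefinition("mid_beta", 14.5, 15.5, 17.5, 18.5, 1),
        BandDefinition("high_beta", 17.5, 18.5, 27.5, 28.5, 3),
        BandDefinition("gamma", 27.5, 28.5, 37.5, 38.5, 3),
    ]


def _check_band_order(bands: Sequence[BandDefinition]) -> None:
    for b1, b2 in zip(bands, bands[1:]):
        if b2.start_lo < b1.end_lo or b2.start_hi < b1.end_lo:
            raise BankDesignError(
                f"bands {b1.name!r} and {b2.name!r} overlap or are out of order"
            )


def band_windows(bands: Sequence[BandDefinition]) -> list[CenterWindow]:
    """Admissible center-frequency window for every filter slot.

    A band holding a single filter gets a *hard* window: the center must
    lie between the midpoint of (lower-edge-low, upper-edge-low) and the
    midpoint of (lower-edge-high, upper-edge-high).  A band holding n > 1
    filters gets n *soft* windows partitioning the admissible center span
    [mid(start range), mid(end range)] evenly.
    """
    _check_band_order(bands)
    windows: list[CenterWindow] = []
    for band in bands:
        if band.n_filters == 1:
            lb = 0.5 * (band.start_lo + band.end_lo)
            ub = 0.5 * (band.start_hi + band.end_hi)
            windows.append(CenterWindow(lb, ub, "hard", band.name))
        else:
            span_lo = 0.5 * (band.start_lo + band.start_hi)
            span_hi = 0.5 * (band.end_lo + band.end_hi)
            if not span_lo < span_hi:
                raise BankDesignError(
                    f"band {band.name!r}: admissible center span collapsed"
                )
            edges = np.linspace(span_lo, span_hi, band.n_filters + 1)
            for lo, hi in zip(edges[:-1], edges[1:]):
                windows.append(CenterWindow(float(lo), float(hi), "soft", band.name))
    return windows


def cutoff_windows(
    bands: Sequence[BandDefinition], interior_halfwidth: float = 1.5
) -> list[tuple[tuple[float, float], tuple[float, float]]]:
    """Per-slot admissible ranges for the lower and upper 1/e cutoffs.

    Band-edge cutoffs must fall inside the band's fuzzy edge range;
    artificial interior boundaries of a shared band get a window of
    +-``interior_halfwidth`` Hz around the even partition point.
    """
    _check_band_order(bands)
    out = []
    for band in bands:
        span_lo = 0.5 * (band.start_lo + band.start_hi)
        span_hi = 0.5 * (band.end_lo + band.end_hi)
        interior = np.linspace(span_lo, span_hi, band.n_filters + 1)[1:-1]
        boundaries = (
            [(band.start_lo, band.start_hi)]
            + [(float(x - interior_halfwidth), float(x + interior_halfwidth)) for x in interior]
            + [(band.end_lo, band.end_hi)]
        )
        for k in range(band.n_filters):
            out.append((boundaries[k], boundaries[k + 1]))
    return out


# ---------------------------------------------------------------------------
# step 1: center spacing
# ---------------------------------------------------------------------------


def optimize_spacing(windows: Sequence[CenterWindow]) -> tuple[np.ndarray, float]:
    """Seed center frequencies by equalizing adjacent spacings.

    Minimizes sum_i ((fc_{i+1}-fc_i) - (fc_{i+2}-fc_{i+1}))^2 subject to
    each center lying in its window.  Returns ``(fc, objective)``.
    """
    K = len(windows)
    if K < 3:
        raise BankDesignError("spacing optimization needs at least 3 windows")
    lb = np.array([w.lb for w in windows])
    ub = np.array([w.ub for w in windows])
    if np.any(ub < lb):
        raise BankDesignError("infeasible window (ub < lb)")

    def objective(fc: np.ndarray) -> float:
        return float(np.sum(np.diff(fc, n=2) ** 2))

    def gradient(fc: np.ndarray) -> np.ndarray:
        d2 = np.diff(fc, n=2)
        g = np.zeros_like(fc)
        # d/dfc_j of sum d2_i^2 where d2_i = fc_{i+2} - 2 fc_{i+1} + fc_i
        g[:-2] += 2.0 * d2
        g[1:-1] += -4.0 * d2
        g[2:] += 2.0 * d2
        return g

    x0 = 0.5 * (lb + ub)
    res = minimize(
        objective,
        x0,
        jac=gradient,
        bounds=list(zip(lb, ub)),
        method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-12},
    )
    return res.x, float(res.fun)


# ---------------------------------------------------------------------------
# step 2: triplet arc-length optimization
# ---------------------------------------------------------------------------


def _sum_response_and_derivative(f: np.ndarray, specs: Iterable[FilterSpec]):
    s = np.zeros_like(f)
    ds = np.zeros_like(f)
    for spec in specs:
        d = f - spec.fc
        psi = np.exp(-spec.a * d**2 - spec.b * d**4)
        s += psi
        ds += psi * (-2.0 * spec.a * d - 4.0 * spec.b * d**3)
    return s, ds


def arc_length_objective(specs: Sequence[FilterSpec], grid: float = 0.01) -> float:
    """Normalized excess arc length of the summed response of a filter triple.

    Integrates sqrt(1 + S'(f)^2) over [fc_first, fc_last] with the
    composite trapezoid rule, subtracts the chord length and normalizes
    by it.  Zero iff the summed response is constant over the interval.
    """
    fcs = [s.fc for s in specs]
    if any(f2 <= f1 for f1, f2 in zip(fcs, fcs[1:])):
        raise BankDesignError("triplet centers must be strictly increasing")
    f_lo, f_hi = fcs[0], fcs[-1]
    n = max(int(round((f_hi - f_lo) / grid)), 8)
    f = np.linspace(f_lo, f_hi, n + 1)
    _, ds = _sum_response_and_derivative(f, specs)
    integrand = np.sqrt(1.0 + ds**2)
    length = float(np.trapezoid(integrand, f))
    chord = f_hi - f_lo
    return (length - chord) / chord


def _unpack(x: np.ndarray, fixed: FilterSpec | None, bands_of: list[str]) -> list[FilterSpec]:
    specs = [] if fixed is None else [fixed]
    n_free = len(x) // 3
    for j in range(n_free):
        fc, a, b = x[3 * j : 3 * j + 3]
        specs.append(FilterSpec(fc=fc, a=a, b=b, band=bands_of[j]))
    return specs


def optimize_triplet(
    prev_fixed: FilterSpec | None,
    seeds: Sequence[FilterSpec],
    windows: Sequence[CenterWindow],
    cut_windows: Sequence[tuple[tuple[float, float], tuple[float, float]]],
    *,
    a_bounds: tuple[float, float] = A_BOUNDS,
    b_bounds: tuple[float, float] = B_BOUNDS,
    epsilon: float = EPSILON,
    grid: float = 0.01,
    n_starts: int = 5,
    seed: int = 0,
) -> tuple[list[FilterSpec], dict]:
    """Optimize the free filters of one sliding round.

    ``seeds`` are the free filters (2 or 3 of them); ``prev_fixed`` is the
    last filter of the previous round (participates in the objective and
    leakage constraints but is not varied).  Constraints: centers in
    their windows, shape parameters within bounds, 1/e cutoffs inside
    their cutoff windows, and gain at both neighboring centers at most
    ``epsilon``.  Multi-start local optimization; returns the best
    feasible iterate and a diagnostics dict (objective, constraint
    violation, convergence flag).
    """
    n_free = len(seeds)
    if n_free not in (1, 2, 3):
        raise BankDesignError("a round optimizes 1-3 free filters")
    bands_of = [s.band for s in seeds]

    lo = np.empty(3 * n_free)
    hi = np.empty(3 * n_free)
    for j, w in enumerate(windows):
        lo[3 * j], hi[3 * j] = w.lb, w.ub
        lo[3 * j + 1], hi[3 * j + 1] = a_bounds
        lo[3 * j + 2], hi[3 * j + 2] = b_bounds

    def all_specs(x: np.ndarray) -> list[FilterSpec]:
        return _unpack(x, prev_fixed, bands_of)

    def objective(x: np.ndarray) -> float:
        return arc_length_objective(all_specs(x), grid=grid)

    def constraint_values(x: np.ndarray) -> np.ndarray:
        """All inequality constraints as g(x) >= 0."""
        specs = all_specs(x)
        free = specs[1:] if prev_fixed is not None else specs
        vals: list[float] = []
        for j, spec in enumerate(free):
            (llo, lhi), (ulo, uhi) = cut_windows[j]
            clo, chi = cutoffs(spec)
            vals += [clo - llo, lhi - clo, chi - ulo, uhi - chi]
        # centers ascending with margin
        fcs = [s.fc for s in specs]
        vals += [f2 - f1 - 0.25 for f1, f2 in zip(fcs, fcs[1:])]
        # leakage at adjacent centers (each filter's gain at its neighbors)
        for k, spec in enumerate(specs):
            for kn in (k - 1, k + 1):
                if 0 <= kn < len(specs):
                    vals.append(epsilon - basis_eval(fcs[kn], spec))
        return np.asarray(vals)

    rng = np.random.default_rng(seed)
    x0_base = np.empty(3 * n_free)
    for j, s in enumerate(seeds):
        x0_base[3 * j : 3 * j + 3] = (s.fc, s.a, s.b)
    x0_base = np.clip(x0_base, lo, hi)

    best = None
    for trial in range(max(1, n_starts)):
        if trial == 0:
            x0 = x0_base
        else:
            jitter = rng.uniform(-0.15, 0.15, size=x0_base.shape) * (hi - lo)
            x0 = np.clip(x0_base + jitter, lo, hi)
        res = minimize(
            objective,
            x0,
            method="SLSQP",
            bounds=list(zip(lo, hi)),
            constraints=[{"type": "ineq", "fun": constraint_values}],
            options={"maxiter": 300, "ftol": 1e-10},
        )
        viol = float(np.clip(-constraint_values(res.x), 0, None).max(initial=0.0))
        cand = (viol > 1e-6, res.fun, viol, res)
        if best is None or cand[:2] < best[:2]:
            best = cand
    infeasible, fval, viol, res = best
    diagnostics = {
        "objective": float(fval),
        "max_violation": viol,
        "converged": bool(res.success) and not infeasible,
        "message": res.message,
    }
    return all_specs(res.x)[1:] if prev_fixed is not None else all_specs(res.x), diagnostics


def build_bank(
    bands: Sequence[BandDefinition] | None = None,
    *,
    a_bounds: tuple[float, float] = A_BOUNDS,
    b_bounds: tuple[float, float] = B_BOUNDS,
    epsilon: float = EPSILON,
    grid: float = 0.01,
    n_starts: int = 5,
    seed: int = 0,
    name: str = "designed",
) -> FilterBank:
    """Run the full two-step design: spacing seed, then sliding triplets.

    The first round fits three filters; each later round fixes the
    previous round's last filter and fits the next two (a final round
    may fit a single remaining filter).  Raises with the round index on
    optimizer failure; plateau diagnostics are attached to the result.
    """
    bands = list(default_bands() if bands is None else bands)
    windows = band_windows(bands)
    cuts = cutoff_windows(bands)
    K = len(windows)
    if K < 3:
        raise BankDesignError("bank design needs at least 3 filter slots")

    fc_seed, _ = optimize_spacing(windows)
    seeds = [
        FilterSpec(fc=float(fc), a=0.05, b=0.1, band=w.band)
        for fc, w in zip(fc_seed, windows)
    ]

    specs: list[FilterSpec] = []
    start = 0
    round_idx = 0
    prev: FilterSpec | None = None
    while start < K:
        n_free = 3 if round_idx == 0 else min(2, K - start)
        # a trailing singleton has too little freedom on its own: fold it
        # into the final round so three filters are fitted together
        if round_idx > 0 and K - start == 3:
            n_free = 3
        sl = slice(start, start + n_free)
        free, diag = optimize_triplet(
            prev,
            seeds[sl],
            windows[sl],
            cuts[sl],
            a_bounds=a_bounds,
            b_bounds=b_bounds,
            epsilon=epsilon,
            grid=grid,
            n_starts=n_starts,
            seed=seed + round_idx,
        )
        if not diag["converged"] and diag["max_violation"] > 1e-3:
            raise BankDesignError(
                f"round {round_idx}: optimizer failed "
                f"(violation {diag['max_violation']:.2e}, {diag['message']})"
            )
        specs.extend(free)
        prev = specs[-1]
        start += n_free
        round_idx += 1

    return FilterBank(specs=specs, epsilon=epsilon, name=name).with_plateau(grid)


def polish_bank(
    bank: FilterBank,
    bands: Sequence[BandDefinition] | None = None,
    *,
    a_bounds: tuple[float, float] = A_BOUNDS,
    b_bounds: tuple[float, float] = B_BOUNDS,
    grid: float = 0.05,
) -> FilterBank:
    """Optional final pass: minimize the plateau value over a, b directly.

    Center frequencies stay frozen; shape parameters move within their
    bounds subject to the cutoff-window and neighbor-leakage
    constraints.  This replaces manual trimming of the shape parameters
    after the sliding rounds; it optimizes flatness globally, which the
    three-filter horizon cannot.
    """
    bands = list(default_bands() if bands is None else bands)
    cuts = cutoff_windows(bands)
    K = len(bank)
    if len(cuts) != K:
        raise BankDesignError("band table does not match bank size")
    fcs = bank.center_frequencies
    f_grid = np.arange(fcs[0], fcs[-1] + grid * 0.5, grid)

    def specs_of(x: np.ndarray) -> list[FilterSpec]:
        return [
            replace(bank.specs[i], a=float(x[2 * i]), b=float(x[2 * i + 1]))
            for i in range(K)
        ]

    def objective(x: np.ndarray) -> float:
        pv = np.zeros_like(f_grid)
        for s in specs_of(x):
            pv += basis_eval(f_grid, s)
        return float(np.std(pv))

    def constraint_values(x: np.ndarray) -> np.ndarray:
        specs = specs_of(x)
        vals: list[float] = []
        for j, spec in enumerate(specs):
            (llo, lhi), (ulo, uhi) = cuts[j]
            clo, chi = cutoffs(spec)
            vals += [clo - llo, lhi - clo, chi - ulo, uhi - chi]
            for kn in (j - 1, j + 1):
                if 0 <= kn < K:
                    vals.append(bank.epsilon - basis_eval(fcs[kn], spec))
        return np.asarray(vals)

    x0 = np.empty(2 * K)
    for i, s in enumerate(bank.specs):
        x0[2 * i], x0[2 * i + 1] = s.a, s.b
    bounds = [a_bounds if i % 2 == 0 else b_bounds for i in range(2 * K)]
    res = minimize(
        objective,
        x0,
        method="SLSQP",
        bounds=bounds,
        constraints=[{"type": "ineq", "fun": constraint_values}],
        options={"maxiter": 400, "ftol": 1e-12},
    )
    x = res.x if res.fun <= objective(x0) else x0
    return replace(bank, specs=specs_of(x), name=bank.name + "+polish").with_plateau(
        bank.plateau_grid
    )


# ---------------------------------------------------------------------------
# plateau diagnostics and the published parameterization
# ---------------------------------------------------------------------------


def plateau(
    bank: FilterBank, grid: float = PLATEAU_GRID, f_lo: float | None = None, f_hi: float | None = None
) -> tuple[np.ndarray, float]:
    """Summed gain on a frequency grid and its standard deviation.

    Defaults to the designed plateau span [fc_1, fc_K]; pass explicit
    bounds (e.g. up to the Nyquist frequency) for the full-range variant.
    """
    if grid <= 0:
        raise BankDesignError("grid spacing must be positive")
    f_lo = bank.specs[0].fc if f_lo is None else f_lo
    f_hi = bank.specs[-1].fc if f_hi is None else f_hi
    if not f_lo < f_hi:
        if f_lo == f_hi:
            f = np.array([f_lo])
        else:
            raise BankDesignError("f_lo must not exceed f_hi")
    else:
        f = np.arange(f_lo, f_hi + grid * 0.5, grid)
    pv = np.zeros_like(f)
    for spec in bank.specs:
        pv += basis_eval(f, spec)
    return pv, float(np.std(pv))


_PUBLISHED = [
    # (fc, a, b, annotated_lo, annotated_hi, band)
    (2.349, 0.072, 0.095, 0.6, 4.0, "delta"),
    (5.605, 0.001, 0.077, 3.8, 7.6, "theta"),
    (8.759, 0.101, 0.119, 7.2, 10.4, "alpha"),
    (11.400, 0.219, 0.161, 10.0, 12.8, "alpha"),
    (13.859, 0.170, 0.180, 12.4, 15.2, "low_beta"),
    (16.608, 0.007, 0.135, 15.0, 18.2, "mid_beta"),
    (19.627, 0.001, 0.127, 18.0, 21.4, "high_beta"),
    (22.792, 0.001, 0.095, 21.0, 24.6, "high_beta"),
    (26.094, 0.001, 0.090, 24.2, 28.0, "high_beta"),
    (29.432, 0.001, 0.088, 27.6, 31.2, "gamma"),
    (32.820, 0.003, 0.078, 31.0, 34.8, "gamma"),
    (36.307, 0.001, 0.070, 34.4, 38.2, "gamma"),
]


def published_bank(with_diagnostics: bool = True) -> FilterBank:
    """The 12-filter reference bank (printed parameters, exact)."""
    specs = [
        FilterSpec(fc=fc, a=a, b=b, band=band, annotated_lo=lo, annotated_hi=hi)
        for fc, a, b, lo, hi, band in _PUBLISHED
    ]
    bank = FilterBank(specs=specs, name="published-12")
    return bank.with_plateau() if with_diagnostics else bank


# ---------------------------------------------------------------------------
# band table I/O
# ---------------------------------------------------------------------------


def load_bands(path: str | Path) -> list[BandDefinition]:
    """Read a band table from JSON or CSV.

    CSV columns: name, start_lo, start_hi, end_lo, end_hi, n_filters.
    JSON: a list of objects with the same keys.
    """
    p = Path(path)
    if p.suffix.lower() == ".json":
        rows = json.loads(p.read_text())
    else:
        import pandas as pd

        rows = pd.read_csv(p).to_dict("records")
    return [
        BandDefinition(
            name=str(r["name"]),
            start_lo=float(r["start_lo"]),
            start_hi=float(r["start_hi"]),
            end_lo=float(r["end_lo"]),
            end_hi=float(r["end_hi"]),
            n_filters=int(r.get("n_filters", 1)),
        )
        for r in rows
    ]
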