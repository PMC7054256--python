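"""Activation Complexity: sample entropy of intensity inter-peak intervals.

The statistic asks how *predictable* the timing of intensity surges in a
band is.  Strict local maxima of the smoothed intensity are detected,
their times first-differenced into an inter-peak-interval sequence, and
sample entropy (template length m, Chebyshev tolerance r) of that
sequence is the Activation Complexity (AC) of the band.  Regular surge
timing (a steady rhythm waxing and waning periodically) gives low AC;
erratic surge timing — the signature of a partially desynchronized,
"isolated" neural population — gives high AC.

Sample entropy is -ln(A/B) where B counts ordered template pairs of
length m within tolerance and A the corresponding pairs of length m+1,
self-matches excluded.  When either count is zero the statistic is
undefined and is propagated as such (never substituted with 0 or inf).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .intensity import IntensitySeries, IntensityStack

__all__ = [
    "PeakTrain",
    "IntervalSeries",
    "SampleEntropyResult",
    "ACCell",
    "ACMatrix",
    "UndefinedEntropyWarning",
    "detect_peaks",
    "intervals",
    "peak_count",
    "sample_entropy",
    "activation_complexity",
    "normalize_ac",
]

#: hard floor on interval count for a defined AC cell.
MIN_INTERVALS = 10
#: sample-size guidance; below this a warning is emitted.
RECOMMENDED_SAMPLES = 100


class UndefinedEntropyWarning(UserWarning):
    pass


@dataclass(frozen=True)
class PeakTrain:
    """Sample indices of strict local maxima of one intensity series."""

    indices: np.ndarray
    fs: float

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def times(self) -> np.ndarray:
        return self.indices / self.fs


@dataclass(frozen=True)
class IntervalSeries:
    """First differences of peak indices, in samples."""

    intervals: np.ndarray
    fs: float

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def seconds(self) -> np.ndarray:
        return self.intervals / self.fs


@dataclass(frozen=True)
class SampleEntropyResult:
    """Sample entropy with its raw match counts.

    ``value`` is None when undefined (A or B zero, or too few points).
    A and B are the unordered template-pair match counts at lengths m+1
    and m respectively.
    """

    value: float | None
    a_count: int
    b_count: int
    m: int
    r: float
    r_mode: str
    n: int

    @property
    def defined(self) -> bool:
        return self.value is not None


def detect_peaks(series: IntensitySeries | np.ndarray, fs: float | None = None) -> PeakTrain:
    """Strict local maxima, restricted to the series' valid span.

    A peak sample is strictly greater than both neighbors; endpoints are
    never peaks and flat runs contribute none (matching the common
    reference peak-finder semantics).
    """
    if isinstance(series, IntensitySeries):
        lo, hi = series.valid_span
        v = series.values
        fs = series.fs
    else:
        v = np.asarray(series, dtype=float)
        lo, hi = 0, len(v)
        if fs is None:
            fs = 1.0
    if len(v) < 3:
        raise ValueError("series must have at least 3 samples")
    idx = np.flatnonzero((v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])) + 1
    idx = idx[(idx >= lo) & (idx < hi)]
    return PeakTrain(indices=idx, fs=float(fs))


def peak_count(peaks: PeakTrain) -> int:
    return len(peaks)


def intervals(peaks: PeakTrain) -> IntervalSeries:
    """First differences of the peak positions; requires >= 2 peaks."""
    if len(peaks) < 2:
        raise ValueError("need at least 2 peaks to form intervals")
    return IntervalSeries(intervals=np.diff(peaks.indices), fs=peaks.fs)


def _match_counts(x: np.ndarray, m: int, tol: float) -> tuple[int, int]:
    """Unordered template-pair counts (B at length m, A at length m+1).

    Pairs are counted once (i < j); a pair matches when the Chebyshev
    distance between the templates is <= tol.  Only templates that also
    admit an (m+1)-length extension participate, the standard convention
    that keeps A <= B.
    """
    n = len(x)
    n_templates = n - m  # number of m-templates with an (m+1) extension
    tm = np.lib.stride_tricks.sliding_window_view(x, m)[:n_templates]
    tm1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)
    db = np.abs(tm[:, None, :] - tm[None, :, :]).max(axis=2)
    da = np.abs(tm1[:, None, :] - tm1[None, :, :]).max(axis=2)
    iu = np.triu_indices(n_templates, k=1)
    b = int(np.count_nonzero(db[iu] <= tol))
    a = int(np.count_nonzero(da[iu] <= tol))
    return a, b


def sample_entropy(
    x: np.ndarray | IntervalSeries,
    m: int = 2,
    r: float = 0.25,
    r_mode: str = "sd_scaled",
) -> SampleEntropyResult:
    """Sample entropy -ln(A/B) of a sequence.

    ``r_mode='sd_scaled'`` (default) scales the tolerance by the sample
    standard deviation of ``x``, making the statistic invariant under
    affine rescaling; ``'absolute'`` uses ``r`` as-is in the units of
    ``x``.  Sequences shorter than the recommended 100 points trigger a
    warning; fewer than m+2 points, or zero match counts, give an
    undefined result.
    """
    if isinstance(x, IntervalSeries):
        x = x.intervals
    x = np.asarray(x, dtype=float)
    if r <= 0:
        raise ValueError("tolerance r must be positive")
    if r_mode not in ("sd_scaled", "absolute"):
        raise ValueError(f"unknown r_mode {r_mode!r}")
    n = len(x)
    if n < m + 2:
        return SampleEntropyResult(None, 0, 0, m, r, r_mode, n)
    if n < RECOMMENDED_SAMPLES:
        warnings.warn(
            f"sample entropy on {n} points; at least {RECOMMENDED_SAMPLES} recommended",
            UndefinedEntropyWarning,
            stacklevel=2,
        )
    scale = float(np.std(x)) if r_mode == "sd_scaled" else 1.0
    tol = r * scale
    a, b = _match_counts(x, m, tol)
    if a == 0 or b == 0:
        return SampleEntropyResult(None, a, b, m, r, r_mode, n)
    return SampleEntropyResult(float(-np.log(a / b)), a, b, m, r, r_mode, n)


@dataclass(frozen=True)
class ACCell:
    """One (lead, filter) Activation Complexity result."""

    lead: str
    band_index: int
    band: str
    ac: float | None
    n_peaks: int
    n_intervals: int
    entropy: SampleEntropyResult | None

    @property
    def defined(self) -> bool:
        return self.ac is not None


@dataclass
class ACMatrix:
    """Activation Complexity per (lead, filter) with detection metadata."""

    cells: list[ACCell]
    m: int
    r: float
    r_mode: str

    def value_array(self, leads: list[str] | None = None) -> np.ndarray:
        """(n_leads, n_filters) array with NaN for undefined cells."""
        leads = sorted({c.lead for c in self.cells}) if leads is None else leads
        nf = max(c.band_index for c in self.cells) + 1
        out = np.full((len(leads), nf), np.nan)
        pos = {lead: i for i, lead in enumerate(leads)}
        for c in self.cells:
            out[pos[c.lead], c.band_index] = np.nan if c.ac is None else c.ac
        return out

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "lead": c.lead,
                    "filter": c.band_index + 1,
                    "band_label": c.band,
                    "ac": np.nan if c.ac is None else c.ac,
                    "n_peaks": c.n_peaks,
                    "n_intervals": c.n_intervals,
                    "m": self.m,
                    "r": self.r,
                    "r_mode": self.r_mode,
                }
                for c in self.cells
            ]
        )


def activation_complexity(
    stack: IntensityStack,
    m: int = 2,
    r: float = 0.25,
    r_mode: str = "sd_scaled",
    min_intervals: int = MIN_INTERVALS,
) -> ACMatrix:
    """AC of every band of one lead: peaks -> intervals -> sample entropy.

    Cells with fewer than ``min_intervals`` intervals, or with no
    template matches, are flagged undefined rather than zeroed.
    """
    cells = []
    for s in stack.series:
        peaks = detect_peaks(s)
        npk = len(peaks)
        if npk < 2 or npk - 1 < min_intervals:
            cells.append(
                ACCell(stack.lead, s.band_index, s.band, None, npk, max(npk - 1, 0), None)
            )
            continue
        iv = intervals(peaks)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UndefinedEntropyWarning)
            ent = sample_entropy(iv, m=m, r=r, r_mode=r_mode)
        cells.append(
            ACCell(stack.lead, s.band_index, s.band, ent.value, npk, len(iv), ent)
        )
    return ACMatrix(cells=cells, m=m, r=r, r_mode=r_mode)


def normalize_ac(values: np.ndarray) -> np.ndarray:
    """Min-max scale each filter's AC map to [0, 1] across leads/cohorts.

    Operates column-wise on an (observations, filters) array; NaN
    (undefined) cells stay NaN.  An all-equal column maps to 0.5 by
    convention (flagged via warning).  A visualization aid only — raw
    values should be kept for statistics.
    """
    v = np.asarray(values, dtype=float)
    out = np.full_like(v, np.nan)
    cols = np.atleast_2d(v.T)
    res = []
    for col in cols:
        finite = np.isfinite(col)
        if finite.sum() < 2:
            res.append(col.copy())
            continue
        lo, hi = np.nanmin(col), np.nanmax(col)
        scaled = np.full_like(col, np.nan)
        if hi == lo:
            warnings.warn("all-equal AC column normalized to 0.5", UserWarning, stacklevel=2)
            scaled[finite] = 0.5
        else:
            scaled[finite] = (col[finite] - lo) / (hi - lo)
        res.append(scaled)
    out = np.vstack(res).T
    return out.reshape(v.shape)
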