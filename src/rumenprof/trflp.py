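"""Terminal restriction fragment (T-RF) profile processing.

The chain implemented here turns raw electropherogram peak tables
(fragment size in bp, peak height in RFU) into a standardized
bins x samples community profile:

1. size filtering to the calibrated read window,
2. iterative true-peak calling against a zero-mean background,
3. cross-sample fragment-length binning,
4. within-sample standardization to relative abundances.

The true-peak rule treats background peak heights as draws whose true
mean is zero, so the background scale is estimated as the root mean
square of the heights (divisor ``n``, not ``n - 1``).  Peaks exceeding
``k_sd`` times that scale are declared true, removed, and the scale is
re-estimated over the remainder until no further peak exceeds the
threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PeakTable",
    "TruePeakSet",
    "BinnedMatrix",
    "filter_by_size",
    "detect_true_peaks",
    "bin_fragments",
    "standardize",
]


@dataclass(frozen=True)
class PeakTable:
    """One sample's electropherogram as parallel size/height arrays.

    Sizes are fragment lengths in base pairs; heights are in relative
    fluorescence units (RFU).  Row order is meaningful and preserved.
    """

    sample_id: str
    sizes: np.ndarray
    heights: np.ndarray

    def __post_init__(self) -> None:
        sizes = np.asarray(self.sizes, dtype=float)
        heights = np.asarray(self.heights, dtype=float)
        object.__setattr__(self, "sizes", sizes)
        object.__setattr__(self, "heights", heights)
        if sizes.shape != heights.shape or sizes.ndim != 1:
            raise ValueError("sizes and heights must be 1-D arrays of equal length")
        if len(sizes) and (np.any(sizes <= 0) or np.any(heights <= 0)):
            raise ValueError("fragment sizes and peak heights must be positive")

    def __len__(self) -> int:
        return len(self.sizes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_id, "size_bp": self.sizes, "height_rfu": self.heights}
        )


@dataclass(frozen=True)
class TruePeakSet:
    """Result of iterative true-peak calling on one sample.

    ``true_mask`` aligns with the input table's rows; ``n_iterations``
    counts detection rounds that declared at least one peak (plus the
    terminating round), and ``final_sd`` is the background RMS height at
    termination.
    """

    sample_id: str
    sizes: np.ndarray
    heights: np.ndarray
    true_mask: np.ndarray
    n_iterations: int
    final_sd: float
    converged: bool = True

    @property
    def true_sizes(self) -> np.ndarray:
        return self.sizes[self.true_mask]

    @property
    def true_heights(self) -> np.ndarray:
        return self.heights[self.true_mask]

    @property
    def n_true(self) -> int:
        return int(self.true_mask.sum())


@dataclass
class BinnedMatrix:
    """Bins x samples matrix of (optionally standardized) peak heights.

    ``representatives`` holds each bin's representative fragment length,
    the arithmetic mean of the member lengths pooled across samples.
    """

    representatives: np.ndarray
    sample_ids: list[str]
    values: np.ndarray  # shape (n_bins, n_samples)
    member_lengths: list[list[float]]
    standardized: bool = False
    zero_samples: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.sample_ids)
        frame.insert(0, "bin_bp", np.round(self.representatives, 2))
        return frame

    def column(self, sample_id: str) -> np.ndarray:
        return self.values[:, self.sample_ids.index(sample_id)]


def filter_by_size(peaks: PeakTable, min_bp: float = 27.0, max_bp: float = 520.0) -> PeakTable:
    """Discard T-RFs outside the calibrated size window.

    Bounds are inclusive: only fragments strictly shorter than ``min_bp``
    or strictly longer than ``max_bp`` are dropped.
    """
    if not min_bp < max_bp:
        raise ValueError(f"min_bp ({min_bp}) must be < max_bp ({max_bp})")
    keep = (peaks.sizes >= min_bp) & (peaks.sizes <= max_bp)
    return PeakTable(peaks.sample_id, peaks.sizes[keep], peaks.heights[keep])


def detect_true_peaks(peaks: PeakTable, k_sd: float = 3.0, max_iter: int = 100) -> TruePeakSet:
    """Iteratively call true peaks against a zero-mean background.

    Each round estimates the background scale as ``sqrt(mean(h^2))``
    over all peaks not yet declared true and declares true every
    remaining peak with height strictly greater than ``k_sd`` times
    that scale.  Rounds repeat until one declares nothing (or
    ``max_iter`` is hit, in which case ``converged`` is False).

    Parameters
    ----------
    peaks:
        A size-filtered :class:`PeakTable`.
    k_sd:
        Threshold multiplier on the zero-mean standard deviation.
    max_iter:
        Safety cap on detection rounds.
    """
    n = len(peaks)
    if n == 0:
        return TruePeakSet(
            peaks.sample_id,
            peaks.sizes,
            peaks.heights,
            np.zeros(0, dtype=bool),
            n_iterations=0,
            final_sd=float("nan"),
        )

    heights = peaks.heights
    true_mask = np.zeros(n, dtype=bool)
    sd = float("nan")
    converged = False
    iterations = 0
    for _ in range(max_iter):
        remaining = heights[~true_mask]
        if remaining.size == 0:
            # every peak declared true; background scale undefined
            sd = 0.0
            converged = True
            break
        sd = math.sqrt(float(np.mean(remaining**2)))
        newly = (~true_mask) & (heights > k_sd * sd)
        iterations += 1
        if not newly.any():
            converged = True
            break
        true_mask |= newly

    return TruePeakSet(
        peaks.sample_id,
        peaks.sizes,
        peaks.heights,
        true_mask,
        n_iterations=iterations,
        final_sd=sd,
        converged=converged,
    )


def bin_fragments(
    true_peak_sets: list[TruePeakSet], tolerance_bp: float = 0.5
) -> BinnedMatrix:
    """Bin true-peak fragment lengths pooled across samples.

    Pooled lengths are sorted and chained in a single pass: a new length
    joins the current bin while its gap to the previous pooled length is
    at most ``tolerance_bp``.  The bin representative is the arithmetic
    mean of member lengths; heights of a sample's peaks falling in one
    bin are summed.
    """
    if tolerance_bp < 0:
        raise ValueError("tolerance_bp must be non-negative")

    sample_ids = [tps.sample_id for tps in true_peak_sets]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids in true-peak sets")

    pooled: list[tuple[float, float, int]] = []  # (length, height, sample index)
    for j, tps in enumerate(true_peak_sets):
        for size, height in zip(tps.true_sizes, tps.true_heights):
            pooled.append((float(size), float(height), j))
    pooled.sort(key=lambda rec: rec[0])

    n_samples = len(sample_ids)
    if not pooled:
        return BinnedMatrix(
            np.zeros(0), sample_ids, np.zeros((0, n_samples)), member_lengths=[]
        )

    bins: list[list[tuple[float, float, int]]] = [[pooled[0]]]
    for rec in pooled[1:]:
        if rec[0] - bins[-1][-1][0] <= tolerance_bp:
            bins[-1].append(rec)
        else:
            bins.append([rec])

    representatives = np.array([np.mean([r[0] for r in members]) for members in bins])
    values = np.zeros((len(bins), n_samples))
    member_lengths: list[list[float]] = []
    for i, members in enumerate(bins):
        member_lengths.append(sorted({r[0] for r in members}))
        for _, height, j in members:
            values[i, j] += height

    return BinnedMatrix(representatives, sample_ids, values, member_lengths)


def standardize(matrix: BinnedMatrix) -> BinnedMatrix:
    """Convert each sample column to relative abundances (sum = 1).

    Columns with zero total height (samples without true peaks) are left
    all-zero and recorded in ``zero_samples``.
    """
    if matrix.standardized:
        raise ValueError("matrix is already standardized")
    totals = matrix.values.sum(axis=0)
    values = matrix.values.copy()
    zero_samples = [sid for sid, tot in zip(matrix.sample_ids, totals) if tot == 0]
    nonzero = totals > 0
    values[:, nonzero] = values[:, nonzero] / totals[nonzero]
    return BinnedMatrix(
        matrix.representatives.copy(),
        list(matrix.sample_ids),
        values,
        [list(m) for m in matrix.member_lengths],
        standardized=True,
        zero_samples=zero_samples,
    )
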