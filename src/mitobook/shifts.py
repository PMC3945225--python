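"""Peak-position shift analysis between cell-cycle states.

For every peak in one condition, the distance to the closest peak of the
other condition (center-to-center, same chromosome) is computed; distances
are binned every 50 bp. Paired common peaks whose centers differ by a
distance inside a configurable window (default 50–250 bp: above center-call
jitter, within the empirically observed shift range) are flagged as shifted
occupancy sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, MitobookError
from .differential import CommonPeak, PeakSetComparison
from .peaks import Peak, PeakSet


@dataclass
class ShiftHistogram:
    bin_width: int
    counts: np.ndarray  # counts for [0,bw), [bw,2bw), ...
    total: int
    overflow: int  # distances beyond max_distance, reported separately
    max_distance: int

    def validate(self) -> None:
        if self.bin_width <= 0:
            raise ConfigError("bin width must be positive")
        if int(self.counts.sum()) + self.overflow != self.total:
            raise MitobookError("histogram mass not conserved")

    def bin_edges(self) -> np.ndarray:
        return np.arange(len(self.counts) + 1) * self.bin_width

    def modal_bin(self) -> tuple[int, int]:
        """(start, end) of the fullest bin; ties break toward the smallest
        distance."""
        i = int(np.argmax(self.counts))
        return i * self.bin_width, (i + 1) * self.bin_width


def nearest_peak_distances(
    a: PeakSet, b: PeakSet
) -> list[tuple[Peak, int | None]]:
    """For each peak of A, min |centerA - centerB| over same-chromosome peaks
    of B; None when B has no peak on that chromosome."""
    b_centers: dict[str, np.ndarray] = {}
    for chrom, centers in b.centers_by_chrom().items():
        b_centers[chrom] = np.sort(np.asarray(centers, dtype=np.int64))
    out: list[tuple[Peak, int | None]] = []
    for peak in a.peaks:
        centers = b_centers.get(peak.chrom)
        if centers is None or len(centers) == 0:
            out.append((peak, None))
            continue
        i = int(np.searchsorted(centers, peak.center))
        best = min(
            abs(peak.center - int(centers[j]))
            for j in (i - 1, i)
            if 0 <= j < len(centers)
        )
        out.append((peak, best))
    return out


def shift_histogram(
    distances: list[int | float],
    bin_width: int = 50,
    max_distance: int = 10_000,
) -> ShiftHistogram:
    """Count distances per half-open 50-bp bin; distances beyond
    ``max_distance`` land in the overflow bucket."""
    if bin_width <= 0:
        raise ConfigError("bin width must be positive")
    arr = np.asarray([d for d in distances if d is not None], dtype=float)
    if len(arr) and (arr < 0).any():
        raise ConfigError("distances must be non-negative")
    n_bins = max_distance // bin_width
    in_range = arr[arr < n_bins * bin_width]
    counts = np.bincount((in_range // bin_width).astype(int), minlength=n_bins)
    hist = ShiftHistogram(
        bin_width=bin_width,
        counts=counts,
        total=len(arr),
        overflow=int(len(arr) - len(in_range)),
        max_distance=n_bins * bin_width,
    )
    hist.validate()
    return hist


def flag_shifted_common(
    comparison: PeakSetComparison,
    min_shift: int = 50,
    max_shift: int = 250,
) -> list[tuple[CommonPeak, int]]:
    """Paired common peaks whose centers differ by d, min_shift <= d <= max_shift."""
    if min_shift > max_shift:
        raise ConfigError("min_shift must not exceed max_shift")
    out = []
    for entry in comparison.common:
        d = entry.shift_distance
        if d is not None and min_shift <= d <= max_shift:
            out.append((entry, d))
    return out


def paired_shift_distances(comparison: PeakSetComparison) -> list[int]:
    return [c.shift_distance for c in comparison.common if c.shift_distance is not None]
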