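"""Poisson-window peak calling against a matched input library.

The caller scans fixed-width windows (default 200 bp) at half-window stride,
tests each window's ChIP tag count against a local Poisson expectation
lambda = max(depth-scaled input count, genome-wide expectation, floor),
resolves overlapping candidates greedily by ascending p-value, controls a
target empirical FDR, and finally applies a reads-per-million height floor.

The FDR estimate at a p threshold t is

    max(#swapped peaks with p <= t, n_windows * t) / #forward peaks with p <= t

i.e. the larger of the sample-swap estimate (input called against ChIP) and
the Poisson expected false-positive count; the threshold is tightened until
the estimate meets the target. The defaults (p < 1e-4, FDR 0.001, 1 RPM)
follow standard transcription-factor ChIP-seq practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ConfigError, MitobookError
from .tags import TagCollection


@dataclass
class PeakCallParams:
    width: int = 200
    p_cutoff: float = 1e-4
    fdr: float = 0.001
    min_rpm: float = 1.0
    input_pseudocount: float = 0.0
    lambda_floor: float = 0.5
    center_mode: str = "tag_mean"  # or 'window_midpoint'
    genome_lambda_only: bool = False
    min_distance: int | None = None  # default 2*width, suppresses satellites
    center_window: int | None = None  # default 2.5*width, for tag_mean centers

    def validate(self) -> None:
        if self.min_distance is not None and self.min_distance < self.width:
            raise ConfigError("min_distance must be at least the window width")
        if self.center_window is not None and self.center_window < self.width:
            raise ConfigError("center_window must be at least the window width")
        if not (0 < self.p_cutoff < 1 and 0 < self.fdr < 1):
            raise ConfigError("p cutoff and FDR must lie in (0, 1)")
        if self.width <= 0 or self.width % 2:
            raise ConfigError("window width must be a positive even integer")
        if self.min_rpm < 0 or self.input_pseudocount < 0 or self.lambda_floor < 0:
            raise ConfigError("floors and pseudocounts must be >= 0")
        if self.center_mode not in ("tag_mean", "window_midpoint"):
            raise ConfigError("center_mode must be 'tag_mean' or 'window_midpoint'")


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    center: int
    count: int
    height_rpm: float
    pvalue: float
    condition: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise MitobookError("peak start must precede end")
        if not self.start <= self.center < self.end:
            raise MitobookError("peak center must lie inside [start, end)")
        if not (0.0 <= self.pvalue <= 1.0) or self.height_rpm < 0:
            raise MitobookError("invalid peak statistics")


@dataclass
class PeakSet:
    condition: str
    peaks: list[Peak] = field(default_factory=list)
    total_tags: int = 0

    def __post_init__(self) -> None:
        self.peaks.sort(key=lambda p: (p.chrom, p.start))
        prev: Peak | None = None
        for p in self.peaks:
            if prev is not None and p.chrom == prev.chrom and p.start < prev.end:
                raise MitobookError("peaks must be non-overlapping")
            prev = p

    def __len__(self) -> int:
        return len(self.peaks)

    def centers_by_chrom(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for p in self.peaks:
            out.setdefault(p.chrom, []).append(p.center)
        return out


def rpm(count: float, total: int) -> float:
    """Reads-per-million normalization: count * 1e6 / total."""
    if total <= 0:
        raise ConfigError("total depth must be positive")
    return count * 1e6 / total


def poisson_upper_tail(k: int, lam: float) -> float:
    """Exact upper tail P(X >= k) for X ~ Poisson(lam).

    Stable for lam well beyond 1e4 (delegates to the regularized incomplete
    gamma function). k = 0 returns 1 for any rate; a zero rate puts no mass
    above zero.
    """
    if k < 0 or lam < 0:
        raise ConfigError("k and lambda must be non-negative")
    k = int(k)
    if k == 0:
        return 1.0
    if lam == 0:
        return 0.0
    return float(stats.poisson.sf(k - 1, lam))


def _poisson_sf_vec(k: np.ndarray, lam: np.ndarray) -> np.ndarray:
    p = stats.poisson.sf(k - 1, lam)
    return np.where(k <= 0, 1.0, p)


def _candidate_windows(
    fg: TagCollection,
    bg: TagCollection | None,
    params: PeakCallParams,
) -> tuple[list[tuple[float, str, int, int]], int]:
    """All stride-w/2 windows with p < cutoff, plus total windows scanned.

    Candidates are (pvalue, chrom, start, count).
    """
    w = params.width
    stride = w // 2
    genome_len = fg.genome_length
    genome_expected = fg.total_tags * w / genome_len
    ratio = fg.total_tags / bg.total_tags if bg is not None and bg.total_tags else 0.0

    candidates: list[tuple[float, str, int, int]] = []
    n_windows = 0
    for chrom in sorted(fg.chrom_lengths):
        L = fg.chrom_lengths[chrom]
        if L < w:
            continue
        starts = np.arange(0, L - w + 1, stride, dtype=np.int64)
        n_windows += len(starts)
        counts = fg.counts_in_windows(chrom, starts, w)
        lam = np.full(len(starts), max(genome_expected, params.lambda_floor))
        if bg is not None and bg.total_tags:
            ctrl = bg.counts_in_windows(chrom, starts, w)
            lam = np.maximum(lam, (ctrl + params.input_pseudocount) * ratio)
        pvals = _poisson_sf_vec(counts, lam)
        for i in np.nonzero(pvals < params.p_cutoff)[0]:
            candidates.append(
                (float(pvals[i]), chrom, int(starts[i]), int(counts[i]))
            )
    return candidates, n_windows


def _resolve_overlaps(
    candidates: list[tuple[float, str, int, int]], min_distance: int
) -> list[tuple[float, str, int, int]]:
    """Greedy resolution: ascending p, then leftmost start, then chromosome
    name; an accepted window excludes any later window whose start lies
    within ``min_distance`` (default 2x width — one binding event spreads
    tags over about twice the window, so nearer secondary windows are tails
    of the same event, not separate sites)."""
    accepted: list[tuple[float, str, int, int]] = []
    taken: dict[str, list[int]] = {}
    for cand in sorted(candidates, key=lambda c: (c[0], c[2], c[1])):
        _, chrom, start, _ = cand
        if any(abs(start - s) < min_distance for s in taken.get(chrom, ())):
            continue
        taken.setdefault(chrom, []).append(start)
        accepted.append(cand)
    return accepted


def _fdr_threshold(
    forward_p: np.ndarray, swapped_p: np.ndarray, n_windows: int, fdr: float
) -> float | None:
    """Largest threshold t (among forward p-values) whose estimated FDR is
    within target; None if no threshold qualifies."""
    fp = np.sort(forward_p)
    sp = np.sort(swapped_p)
    for t in np.unique(fp)[::-1]:
        n_fwd = int(np.searchsorted(fp, t, "right"))
        n_sw = int(np.searchsorted(sp, t, "right"))
        expected_null = n_windows * t
        if max(n_sw, expected_null) / n_fwd <= fdr:
            return float(t)
    return None


def _refine_center(
    chip: TagCollection, chrom: str, start: int, width: int,
    center_window: int, max_iterations: int = 50, tol: float = 0.5,
) -> int:
    """Mean-shift center estimate: iterate the mean of the tags inside a
    ``center_window``-wide window re-centered on the current estimate, to
    convergence.

    A window-midpoint center is quantized to the stride grid; the local mean
    converges onto the underlying tag mode and supports shift distances finer
    than the stride. The refinement window is wider than the peak window so
    that it covers the full fragment-offset spread of one binding event —
    truncating the tag cloud both biases the mean and amplifies its sampling
    noise. The result is clipped into the fixed peak interval.
    """
    c = start + width / 2.0
    half = center_window // 2
    for _ in range(max_iterations):
        lo = int(round(c)) - half
        pos = chip.positions_in(chrom, lo, lo + 2 * half)
        if len(pos) == 0:
            break
        new = float(pos.mean())
        done = abs(new - c) < tol
        c = new
        if done:
            break
    return int(min(max(round(c), start), start + width - 1))


def call_peaks(
    chip: TagCollection,
    control: TagCollection | None,
    params: PeakCallParams | None = None,
    condition: str = "chip",
) -> PeakSet:
    """Call enriched windows in ``chip`` against the matched ``control``.

    Every emitted peak satisfies all three criteria: Poisson p below the
    (FDR-tightened) cutoff, non-overlap with a better peak, and tag total of
    at least ``min_rpm`` reads per million.
    """
    params = params or PeakCallParams()
    params.validate()
    if chip.total_tags == 0:
        raise MitobookError("ChIP tag collection is empty")
    no_control = control is None or control.total_tags == 0
    if no_control and not params.genome_lambda_only:
        raise MitobookError(
            "control collection is empty; pass genome_lambda_only=True to call "
            "against the genome-wide expectation alone"
        )
    if not no_control and set(chip.chrom_lengths) != set(control.chrom_lengths):
        raise MitobookError("chip and control use different chromosome namespaces")
    bg = None if no_control else control

    min_distance = params.min_distance or 2 * params.width
    forward, n_windows = _candidate_windows(chip, bg, params)
    forward = _resolve_overlaps(forward, min_distance)
    if bg is not None:
        swapped, _ = _candidate_windows(bg, chip, params)
        swapped = _resolve_overlaps(swapped, min_distance)
        swapped_p = np.array([c[0] for c in swapped])
    else:
        swapped_p = np.empty(0)

    if not forward:
        return PeakSet(condition, [], chip.total_tags)
    threshold = _fdr_threshold(
        np.array([c[0] for c in forward]), swapped_p, n_windows, params.fdr
    )
    if threshold is None:
        return PeakSet(condition, [], chip.total_tags)

    peaks = []
    for p, chrom, start, count in forward:
        if p > threshold:
            continue
        height = rpm(count, chip.total_tags)
        if height < params.min_rpm:
            continue
        if params.center_mode == "tag_mean":
            center_window = params.center_window or (2 * params.width + params.width // 2)
            center = _refine_center(chip, chrom, start, params.width, center_window)
        else:
            center = start + params.width // 2
        peaks.append(
            Peak(chrom, start, start + params.width, center, count, height, p, condition)
        )
    out = PeakSet(condition, peaks, chip.total_tags)
    _check_emitted(out, params)
    return out


def _check_emitted(peak_set: PeakSet, params: PeakCallParams) -> None:
    for p in peak_set.peaks:
        assert p.pvalue < params.p_cutoff
        assert p.height_rpm >= params.min_rpm


def score_bed(pvalue: float) -> int:
    """-10*log10(p), capped at 1000, for BED score columns."""
    if pvalue <= 0:
        return 1000
    return min(1000, int(round(-10 * math.log10(pvalue))))
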