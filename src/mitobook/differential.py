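"""Condition-specific vs common peak classification.

A peak is *specific* to its own cell population when the tag enrichment in a
200-bp region around its center is more than 4-fold (strict) above the other
population after depth normalization AND a Poisson test of the observed count
against the depth-scaled other-population count gives p < 1e-4, each
population tested against the other as background. All remaining peaks are
*common*; common peaks from the two calls whose centers lie within the
pairing distance are merged into one entry referenced to the asynchronous
center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigError, MitobookError
from .peaks import Peak, PeakSet, poisson_upper_tail
from .tags import TagCollection


@dataclass
class ClassificationParams:
    width: int = 200
    fold: float = 4.0  # strict: specific requires ratio > fold
    p_threshold: float = 1e-4
    pairing_distance: int = 200
    pseudocount: float = 0.5  # tags, added to the background side

    def validate(self) -> None:
        if self.width <= 0:
            raise ConfigError("comparison width must be positive")
        if self.fold <= 1:
            raise ConfigError("fold threshold must exceed 1")
        if not 0 < self.p_threshold < 1:
            raise ConfigError("p threshold must lie in (0, 1)")
        if self.pairing_distance < 0 or self.pseudocount < 0:
            raise ConfigError("pairing distance and pseudocount must be >= 0")


@dataclass
class CommonPeak:
    """One common site: the asynchronous peak, its paired mitotic peak when
    one exists within pairing distance, and the reference center (the
    asynchronous center when available)."""

    async_peak: Peak | None
    mitotic_peak: Peak | None
    reference_center: int
    chrom: str

    @property
    def shift_distance(self) -> int | None:
        if self.async_peak is None or self.mitotic_peak is None:
            return None
        return abs(self.async_peak.center - self.mitotic_peak.center)


@dataclass
class PeakSetComparison:
    async_specific: list[Peak] = field(default_factory=list)
    mitotic_specific: list[Peak] = field(default_factory=list)
    common: list[CommonPeak] = field(default_factory=list)
    centering: str = "asynchronous"

    @property
    def n_common_paired(self) -> int:
        return sum(1 for c in self.common if c.async_peak and c.mitotic_peak)

    def counts(self) -> dict[str, int]:
        return {
            "async_specific": len(self.async_specific),
            "mitotic_specific": len(self.mitotic_specific),
            "common": len(self.common),
            "common_paired": self.n_common_paired,
        }

    def validate(self, n_async_input: int, n_mitotic_input: int) -> None:
        n_async = len(self.async_specific) + sum(
            1 for c in self.common if c.async_peak is not None
        )
        n_mitotic = len(self.mitotic_specific) + sum(
            1 for c in self.common if c.mitotic_peak is not None
        )
        if n_async != n_async_input or n_mitotic != n_mitotic_input:
            raise MitobookError("classification does not partition the input peaks")


def region_count(tags: TagCollection, chrom: str, center: int, width: int) -> int:
    """Tags in the half-open region [center - width//2, center + width//2)."""
    if width <= 0:
        raise ConfigError("width must be positive")
    half = width // 2
    return tags.count_in(chrom, center - half, center + half)


def _is_specific(
    own_count: int,
    other_count: int,
    own_total: int,
    other_total: int,
    params: ClassificationParams,
) -> bool:
    # fold on depth-normalized counts, pseudocount on the background side;
    # cross-multiplied so the strict ">" is exact at the fold boundary
    lhs = own_count * other_total
    rhs = params.fold * (other_count + params.pseudocount) * own_total
    if not lhs > rhs:
        return False
    lam = (other_count + params.pseudocount) * own_total / other_total
    return poisson_upper_tail(own_count, lam) < params.p_threshold


def classify_peaks(
    async_peaks: PeakSet,
    mitotic_peaks: PeakSet,
    async_tags: TagCollection,
    mitotic_tags: TagCollection,
    params: ClassificationParams | None = None,
) -> PeakSetComparison:
    params = params or ClassificationParams()
    params.validate()
    if async_peaks.total_tags <= 0 or mitotic_peaks.total_tags <= 0:
        raise MitobookError("peak sets must record the calling depth")
    Na, Nm = async_tags.total_tags, mitotic_tags.total_tags
    if Na == 0 or Nm == 0:
        raise MitobookError("tag collections must be non-empty")

    comparison = PeakSetComparison()
    async_common: list[Peak] = []
    mitotic_common: list[Peak] = []

    for peak in async_peaks.peaks:
        ka = region_count(async_tags, peak.chrom, peak.center, params.width)
        km = region_count(mitotic_tags, peak.chrom, peak.center, params.width)
        if _is_specific(ka, km, Na, Nm, params):
            comparison.async_specific.append(peak)
        else:
            async_common.append(peak)
    for peak in mitotic_peaks.peaks:
        km = region_count(mitotic_tags, peak.chrom, peak.center, params.width)
        ka = region_count(async_tags, peak.chrom, peak.center, params.width)
        if _is_specific(km, ka, Nm, Na, params):
            comparison.mitotic_specific.append(peak)
        else:
            mitotic_common.append(peak)

    comparison.common = _pair_common(async_common, mitotic_common, params.pairing_distance)
    comparison.validate(len(async_peaks.peaks), len(mitotic_peaks.peaks))
    return comparison


def _pair_common(
    async_common: list[Peak], mitotic_common: list[Peak], pairing_distance: int
) -> list[CommonPeak]:
    """One-to-one pairing of non-specific peaks across conditions, nearest
    centers first; leftovers become unpaired common entries."""
    pairs: list[tuple[int, int, int]] = []  # (distance, ai, mi)
    by_chrom: dict[str, list[int]] = {}
    for mi, m in enumerate(mitotic_common):
        by_chrom.setdefault(m.chrom, []).append(mi)
    for ai, a in enumerate(async_common):
        for mi in by_chrom.get(a.chrom, ()):
            d = abs(a.center - mitotic_common[mi].center)
            if d <= pairing_distance:
                pairs.append((d, ai, mi))
    pairs.sort()
    used_a: set[int] = set()
    used_m: set[int] = set()
    out: list[CommonPeak] = []
    for d, ai, mi in pairs:
        if ai in used_a or mi in used_m:
            continue
        used_a.add(ai)
        used_m.add(mi)
        a, m = async_common[ai], mitotic_common[mi]
        out.append(CommonPeak(a, m, a.center, a.chrom))
    for ai, a in enumerate(async_common):
        if ai not in used_a:
            out.append(CommonPeak(a, None, a.center, a.chrom))
    for mi, m in enumerate(mitotic_common):
        if mi not in used_m:
            out.append(CommonPeak(None, m, m.center, m.chrom))
    out.sort(key=lambda c: (c.chrom, c.reference_center))
    return out


def summarize_comparison(
    n_async_specific: int, n_mitotic_specific: int, n_common: int
) -> dict[str, float]:
    """Class fractions as percentages.

    ``common_of_async`` is the retained fraction: of all sites occupied in
    asynchronous (cycling) cells, the percentage also occupied on mitotic
    chromatin. ``async_unique`` is its complement; the two mitotic-side
    fractions are defined analogously. A side with no peaks at all yields
    NaN for its fractions.
    """
    if min(n_async_specific, n_mitotic_specific, n_common) < 0:
        raise ConfigError("counts must be >= 0")
    if n_async_specific == n_mitotic_specific == n_common == 0:
        raise ConfigError("fractions undefined for all-zero counts")
    na = n_common + n_async_specific
    nm = n_common + n_mitotic_specific
    nan = float("nan")
    return {
        "common_of_async": 100.0 * n_common / na if na else nan,
        "async_unique": 100.0 * n_async_specific / na if na else nan,
        "common_of_mitotic": 100.0 * n_common / nm if nm else nan,
        "mitotic_unique": 100.0 * n_mitotic_specific / nm if nm else nan,
    }
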