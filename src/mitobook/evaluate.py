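"""Scoring pipeline output against planted ground truth.

Used by the synthetic-data validation run: matches called/classified peaks
back to planted sites by proximity and reports per-class recovery, plus
recovery of planted shift distances.
"""

from __future__ import annotations

from dataclasses import dataclass

from .differential import PeakSetComparison
from .peaks import Peak
from .simulate import PlantedSiteSet


@dataclass
class RecoveryReport:
    per_class: dict[str, tuple[int, int]]  # class -> (recovered, planted)
    overall_fraction: float

    def fraction(self, site_class: str) -> float:
        rec, tot = self.per_class[site_class]
        return rec / tot if tot else float("nan")


def _nearest(centers: list[tuple[str, int]], chrom: str, pos: int, tol: int) -> bool:
    return any(c == chrom and abs(p - pos) <= tol for c, p in centers)


def score_class_recovery(
    sites: PlantedSiteSet,
    comparison: PeakSetComparison,
    tol: int = 100,
) -> RecoveryReport:
    """Fraction of planted sites whose pipeline classification matches their
    planted class.

    A common or shifted site counts as recovered when a *paired* common entry
    sits within ``tol`` bp of its asynchronous center; a condition-specific
    site when a peak of the matching specific list does.
    """
    def centers(peaks: list[Peak]) -> list[tuple[str, int]]:
        return [(p.chrom, p.center) for p in peaks]

    async_spec = centers(comparison.async_specific)
    mitotic_spec = centers(comparison.mitotic_specific)
    common_paired = [
        (c.chrom, c.reference_center)
        for c in comparison.common
        if c.async_peak is not None and c.mitotic_peak is not None
    ]

    per_class: dict[str, list[int]] = {}
    for site in sites.sites:
        if site.site_class == "async_specific":
            ok = _nearest(async_spec, site.chrom, site.position, tol)
        elif site.site_class == "mitotic_specific":
            ok = _nearest(mitotic_spec, site.chrom, site.position, tol)
        else:  # common and shifted sites must both land in the paired commons
            ok = _nearest(common_paired, site.chrom, site.position, tol)
        acc = per_class.setdefault(site.site_class, [0, 0])
        acc[0] += int(ok)
        acc[1] += 1

    totals = {k: (v[0], v[1]) for k, v in per_class.items()}
    recovered = sum(v[0] for v in totals.values())
    planted = sum(v[1] for v in totals.values())
    return RecoveryReport(totals, recovered / planted if planted else float("nan"))


def score_shift_flags(
    sites: PlantedSiteSet,
    flagged: list,  # list of (CommonPeak, distance) from flag_shifted_common
    tol: int = 100,
) -> float:
    """Fraction of planted *shifted* sites appearing among the flagged common
    peaks (matched by asynchronous center within tol)."""
    flagged_centers = [(entry.chrom, entry.reference_center) for entry, _ in flagged]
    shifted = sites.by_class("shifted")
    if not shifted:
        return float("nan")
    hit = sum(
        _nearest(flagged_centers, s.chrom, s.position, tol) for s in shifted
    )
    return hit / len(shifted)


def recovered_shift_distances(
    sites: PlantedSiteSet,
    comparison: PeakSetComparison,
    tol: int = 100,
) -> list[int]:
    """Center-to-center distances of paired common peaks that match planted
    shifted sites."""
    out = []
    for s in sites.by_class("shifted"):
        for c in comparison.common:
            if (
                c.chrom == s.chrom
                and c.shift_distance is not None
                and abs(c.reference_center - s.position) <= tol
            ):
                out.append(c.shift_distance)
                break
    return out
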