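"""Priority-based genomic annotation of peak centers.

Each peak is assigned to exactly one of six categories, tested in order:

1. promoter  — TSS -1000 to +100 (strand-relative)
2. TTS       — transcription termination site -100 to +1000
3. exon
4. intron    — inside the gene span but not in an exon
5. dTSS      — distal promoter, TSS -10000 to +1000
6. intergenic (fallback)

The first matching category wins; ties among genes within a category break
by nearest TSS, then gene id. Peaks are annotated by their center point.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigError, MitobookError
from .simulate import Gene, GenomeModel

CATEGORIES = ("promoter", "TTS", "exon", "intron", "dTSS", "intergenic")


@dataclass
class AnnotationScheme:
    promoter_up: int = 1000
    promoter_down: int = 100
    tts_up: int = 100
    tts_down: int = 1000
    dtss_up: int = 10_000
    dtss_down: int = 1000

    def validate(self) -> None:
        if min(self.promoter_up, self.promoter_down, self.tts_up,
               self.tts_down, self.dtss_up, self.dtss_down) < 0:
            raise ConfigError("annotation windows must be non-negative")


@dataclass(frozen=True)
class AnnotationResult:
    category: str
    gene_id: str | None  # None for intergenic
    distance: int | None  # strand-relative offset to the anchoring feature


def _offset(center: int, anchor: int, strand: str) -> int:
    """Strand-relative offset; positive = downstream of transcription."""
    return center - anchor if strand == "+" else anchor - center


def _category_match(
    center: int, gene: Gene, category: str, scheme: AnnotationScheme
) -> int | None:
    """Strand-relative anchor offset if the center falls in the category's
    window for this gene, else None. Windows are inclusive on both ends."""
    if category == "promoter":
        off = _offset(center, gene.tss, gene.strand)
        return off if -scheme.promoter_up <= off <= scheme.promoter_down else None
    if category == "TTS":
        off = _offset(center, gene.tts, gene.strand)
        return off if -scheme.tts_up <= off <= scheme.tts_down else None
    if category == "exon":
        if any(s <= center < e for s, e in gene.exons):
            return _offset(center, gene.tss, gene.strand)
        return None
    if category == "intron":
        inside = gene.start <= center < gene.end
        in_exon = any(s <= center < e for s, e in gene.exons)
        return _offset(center, gene.tss, gene.strand) if inside and not in_exon else None
    if category == "dTSS":
        off = _offset(center, gene.tss, gene.strand)
        return off if -scheme.dtss_up <= off <= scheme.dtss_down else None
    raise ConfigError(f"unknown category {category!r}")


def annotate_peak(
    chrom: str,
    center: int,
    genome: GenomeModel,
    scheme: AnnotationScheme | None = None,
) -> AnnotationResult:
    scheme = scheme or AnnotationScheme()
    scheme.validate()
    if chrom not in genome.chrom_lengths:
        raise MitobookError(f"unknown chromosome {chrom!r}")
    genes = [g for g in genome.genes if g.chrom == chrom]
    for category in CATEGORIES[:-1]:
        hits: list[tuple[int, str, int]] = []  # (|tss distance|, gene_id, offset)
        for gene in genes:
            off = _category_match(center, gene, category, scheme)
            if off is not None:
                hits.append((abs(center - gene.tss), gene.gene_id, off))
        if hits:
            hits.sort()
            _, gene_id, off = hits[0]
            return AnnotationResult(category, gene_id, off)
    return AnnotationResult("intergenic", None, None)


def annotation_summary(
    centers_by_chrom: dict[str, list[int]],
    genome: GenomeModel,
    scheme: AnnotationScheme | None = None,
) -> dict:
    """Per-category counts and fractions over a set of peak centers."""
    counts = {c: 0 for c in CATEGORIES}
    n = 0
    for chrom, centers in centers_by_chrom.items():
        for center in centers:
            counts[annotate_peak(chrom, int(center), genome, scheme).category] += 1
            n += 1
    if n == 0:
        raise MitobookError("no peaks to annotate")
    fractions = {c: counts[c] / n for c in CATEGORIES}
    assert abs(sum(fractions.values()) - 1.0) < 1e-12
    return {"n_peaks": n, "counts": counts, "fractions": fractions}
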