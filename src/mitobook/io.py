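"""Readers and writers for the pipeline's on-disk formats.

Conventions: all BED files are 0-based half-open; human-readable tables and
reports are 1-based inclusive. The conversion happens exactly once, here at
the file boundary. Tag files are 6-column BED with 1-bp intervals (the tag's
5' position) and the strand in column 6.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, MitobookError
from .peaks import Peak, PeakSet, score_bed
from .simulate import Gene, GenomeModel, PlantedSite, PlantedSiteSet, SyntheticImage
from .tags import TagCollection

_STRAND_CODE = {"+": 1, "-": -1}
_STRAND_CHAR = {1: "+", -1: "-"}


# ---------------------------------------------------------------------------
# tags


def write_tag_bed(tags: TagCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(tags.chrom_lengths):
            pos = tags.positions[chrom]
            strand = tags.strands[chrom]
            for p, s in zip(pos, strand):
                fh.write(f"{chrom}\t{p}\t{p + 1}\ttag\t0\t{_STRAND_CHAR[int(s)]}\n")


def read_tag_bed(
    path: str | Path, chrom_lengths: dict[str, int] | None = None
) -> TagCollection:
    """Read a 6-column tag BED. Chromosome lengths are taken from
    ``chrom_lengths`` when given, otherwise inferred as max(position)+1."""
    positions: dict[str, list[int]] = {}
    strands: dict[str, list[int]] = {}
    path = str(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError("expected 6 tab-separated columns", path, lineno)
            chrom, start_s, end_s, _name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError("non-integer coordinates", path, lineno) from None
            if end - start != 1:
                raise FormatError(
                    f"tag interval must be exactly 1 bp (got {end - start})",
                    path, lineno,
                )
            if strand not in _STRAND_CODE:
                raise FormatError(f"unknown strand {strand!r}", path, lineno)
            if start < 0:
                raise FormatError("negative coordinate", path, lineno)
            positions.setdefault(chrom, []).append(start)
            strands.setdefault(chrom, []).append(_STRAND_CODE[strand])
    if chrom_lengths is None:
        chrom_lengths = {
            c: (max(p) + 1 if p else 1) for c, p in positions.items()
        }
    return TagCollection(
        chrom_lengths=dict(chrom_lengths),
        positions={c: np.array(p, dtype=np.int64) for c, p in positions.items()},
        strands={c: np.array(s, dtype=np.int8) for c, s in strands.items()},
    )


def read_tag_sam(path: str | Path, chrom_lengths: dict[str, int] | None = None) -> TagCollection:
    """Thin importer reducing mapped SAM records to 5' tag positions."""
    import pysam

    positions: dict[str, list[int]] = {}
    strands: dict[str, list[int]] = {}
    lengths: dict[str, int] = {}
    with pysam.AlignmentFile(str(path), "r") as sam:
        for name, length in zip(sam.references, sam.lengths):
            lengths[name] = length
        for rec in sam:
            if rec.is_unmapped:
                continue
            chrom = rec.reference_name
            if rec.is_reverse:
                positions.setdefault(chrom, []).append(rec.reference_end - 1)
                strands.setdefault(chrom, []).append(-1)
            else:
                positions.setdefault(chrom, []).append(rec.reference_start)
                strands.setdefault(chrom, []).append(1)
    return TagCollection(
        chrom_lengths=chrom_lengths or lengths,
        positions={c: np.array(p, dtype=np.int64) for c, p in positions.items()},
        strands={c: np.array(s, dtype=np.int8) for c, s in strands.items()},
    )


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"duplicate sequence name {rec.id!r}", str(path))
        out[rec.id] = str(rec.seq).upper()
    return out


# ---------------------------------------------------------------------------
# gene models (TSV is 1-based inclusive; BED12 is 0-based half-open)


def write_gene_table(genome: GenomeModel, path: str | Path) -> None:
    rows = []
    for g in genome.genes:
        exons = ",".join(f"{s + 1}-{e}" for s, e in g.exons)
        rows.append(
            dict(gene_id=g.gene_id, chrom=g.chrom, strand=g.strand,
                 tss=g.tss + 1, tts=g.tts + 1, exons=exons)
        )
    header = "\t".join(["gene_id", "chrom", "strand", "tss", "tts", "exons"])
    with open(path, "w") as fh:
        fh.write("#" + json.dumps({"chrom_lengths": genome.chrom_lengths}) + "\n")
        fh.write(header + "\n")
        for r in rows:
            fh.write("\t".join(str(r[k]) for k in
                               ("gene_id", "chrom", "strand", "tss", "tts", "exons")) + "\n")


def read_gene_table(path: str | Path) -> GenomeModel:
    path = str(path)
    chrom_lengths: dict[str, int] = {}
    genes: list[Gene] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    body: list[tuple[int, str]] = []
    for lineno, line in enumerate(lines, start=1):
        if line.startswith("#"):
            try:
                chrom_lengths = json.loads(line[1:]).get("chrom_lengths", {})
            except json.JSONDecodeError:
                pass
            continue
        if line.strip():
            body.append((lineno, line))
    if not body:
        raise FormatError("empty gene table", path)
    header = body[0][1].split("\t")
    if header[:6] != ["gene_id", "chrom", "strand", "tss", "tts", "exons"]:
        raise FormatError("unexpected gene table header", path, body[0][0])
    for lineno, line in body[1:]:
        f = line.split("\t")
        if len(f) < 6:
            raise FormatError("expected 6 columns", path, lineno)
        exons = []
        for part in f[5].split(","):
            if not part:
                continue
            s, e = part.split("-")
            exons.append((int(s) - 1, int(e)))
        genes.append(Gene(f[0], f[1], f[2], int(f[3]) - 1, int(f[4]) - 1, tuple(exons)))
    if not chrom_lengths:
        # fall back to the gene extents when no header metadata is present
        for g in genes:
            chrom_lengths[g.chrom] = max(chrom_lengths.get(g.chrom, 0), g.end)
    model = GenomeModel(sorted(chrom_lengths.items()), genes)
    model.validate()
    return model


def write_gene_bed12(genome: GenomeModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genome.genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            offsets = ",".join(str(s - g.start) for s, e in g.exons)
            fh.write(
                "\t".join(map(str, [
                    g.chrom, g.start, g.end, g.gene_id, 0, g.strand,
                    g.start, g.end, "0,0,0", len(g.exons), sizes, offsets,
                ])) + "\n"
            )


def read_gene_bed12(path: str | Path, chrom_lengths: dict[str, int]) -> GenomeModel:
    path = str(path)
    genes: list[Gene] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError("expected 12 BED12 columns", path, lineno)
            chrom, start, end, name, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            if start >= end:
                raise FormatError("start must precede end", path, lineno)
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
            tss, tts = (start, end - 1) if strand == "+" else (end - 1, start)
            genes.append(Gene(name, chrom, strand, tss, tts, exons))
    model = GenomeModel(sorted(chrom_lengths.items()), genes)
    model.validate()
    return model


# ---------------------------------------------------------------------------
# peaks


def write_peaks_bed(peak_set: PeakSet, path: str | Path) -> None:
    """BED6+ peaks: name=condition, score=-10*log10(p) capped at 1000, then
    height (RPM), raw count, p-value and center as extra columns."""
    with open(path, "w") as fh:
        fh.write(f"#condition={peak_set.condition}\ttotal_tags={peak_set.total_tags}\n")
        for p in peak_set.peaks:
            fh.write(
                "\t".join(map(str, [
                    p.chrom, p.start, p.end, p.condition or peak_set.condition,
                    score_bed(p.pvalue), ".",
                    f"{p.height_rpm:.6g}", p.count, f"{p.pvalue:.6e}", p.center,
                ])) + "\n"
            )


def read_peaks_bed(
    path: str | Path, chrom_lengths: dict[str, int] | None = None
) -> PeakSet:
    path = str(path)
    condition = "peaks"
    total = 0
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("#"):
                for part in line[1:].split("\t"):
                    if part.startswith("condition="):
                        condition = part.split("=", 1)[1]
                    elif part.startswith("total_tags="):
                        total = int(part.split("=", 1)[1])
                continue
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise FormatError("expected 10 columns in peaks BED", path, lineno)
            start, end = int(f[1]), int(f[2])
            if start >= end:
                raise FormatError("peak start must precede end", path, lineno)
            if chrom_lengths is not None:
                if f[0] not in chrom_lengths:
                    raise FormatError(f"unknown chromosome {f[0]!r}", path, lineno)
                if end > chrom_lengths[f[0]]:
                    raise FormatError("peak exceeds chromosome length", path, lineno)
            peaks.append(
                Peak(f[0], start, end, int(f[9]), int(f[7]), float(f[6]),
                     float(f[8]), f[3])
            )
    return PeakSet(condition, peaks, total)


# ---------------------------------------------------------------------------
# planted sites


def write_sites_bed(sites: PlantedSiteSet, path: str | Path, half_width: int = 100) -> None:
    """Ground-truth sites as BED6: name carries class and embedded motifs,
    score carries the planted shift distance."""
    with open(path, "w") as fh:
        for s in sites.sites:
            motifs = "+".join(sorted(s.motifs)) or "none"
            fh.write(
                "\t".join(map(str, [
                    s.chrom, s.position - half_width, s.position + half_width,
                    f"{s.site_class};{motifs}", s.shift_distance, ".",
                ])) + "\n"
            )


def read_sites_bed(path: str | Path) -> PlantedSiteSet:
    path = str(path)
    sites: list[PlantedSite] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise FormatError("expected 6 columns", path, lineno)
            start, end = int(f[1]), int(f[2])
            cls, motifs_s = (f[3].split(";") + ["none"])[:2]
            motifs = frozenset(m for m in motifs_s.split("+") if m and m != "none")
            sites.append(
                PlantedSite(f[0], (start + end) // 2, cls, int(f[4]), motifs)
            )
    return PlantedSiteSet(sites)


# ---------------------------------------------------------------------------
# generic tables, JSON, images


def write_table(rows: list[dict], path: str | Path) -> None:
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def write_image(image: SyntheticImage, stem: str | Path) -> list[Path]:
    """Write pixels as TIFF and the three compartment masks as PNGs."""
    import imageio.v3 as iio
    import tifffile

    stem = Path(stem)
    paths = [stem.with_suffix(".tif")]
    tifffile.imwrite(paths[0], image.pixels.astype(np.float32))
    for name, mask in (
        ("chromatin", image.chromatin_mask),
        ("nucleocytoplasm", image.nucleocytoplasm_mask),
        ("background", image.background_mask),
    ):
        p = stem.parent / f"{stem.name}.{name}.png"
        iio.imwrite(p, (mask.astype(np.uint8) * 255))
        paths.append(p)
    return paths


def read_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return np.asarray(tifffile.imread(path), dtype=float)
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path), dtype=float)
    if arr.ndim == 3:  # collapse RGB(A) to one channel
        arr = arr[..., :3].mean(axis=-1)
    return arr


def read_mask(path: str | Path) -> np.ndarray:
    return read_image(path) > 0


def require(path: str | Path, what: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise MitobookError(f"missing {what}: {p}")
    return p
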