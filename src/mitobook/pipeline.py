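"""End-to-end orchestration: simulate (or ingest) -> call peaks in both
conditions -> classify -> shift analysis -> motif content -> annotation
[-> image quantification], writing every stage artifact plus a JSON manifest
under one run directory. Re-running with the same config and seed reproduces
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import io as mio
from .annotate import AnnotationScheme, annotation_summary
from .differential import (ClassificationParams, PeakSetComparison,
                           classify_peaks, summarize_comparison)
from .errors import MitobookError, StageError
from .evaluate import (RecoveryReport, recovered_shift_distances,
                       score_class_recovery, score_shift_flags)
from .imaging import group_summary, measure_image, retention_ratio
from .motifs import (CTCF_LIKE_CONSENSUS, MotifModel, RBPJ_CONSENSUS,
                     motif_enrichment, peak_motif_content)
from .peaks import PeakCallParams, call_peaks
from .shifts import flag_shifted_common, nearest_peak_distances, shift_histogram
from .simulate import (ImageConfig, SimConfig, make_genome, plant_sites,
                       simulate_tags)

log = logging.getLogger("mitobook")

#: Retention-ratio groups emulated by default: wild type plus the three
#: DNA-contact mutant combinations, at their reported mean ratios.
DEFAULT_IMAGE_GROUPS = {
    "RBPJ": 3.6,
    "K153A_S182A": 1.6,
    "R179A_R181A": 1.3,
    "R52A_K153A_S182A": 1.1,
}


@dataclass
class RunConfig:
    outdir: str = "run"
    seed: int = 0
    sim: SimConfig | None = field(default_factory=SimConfig)
    peak_params: PeakCallParams = field(default_factory=PeakCallParams)
    class_params: ClassificationParams = field(default_factory=ClassificationParams)
    scheme: AnnotationScheme = field(default_factory=AnnotationScheme)
    histogram_bin: int = 50
    shift_flag_min: int = 50
    shift_flag_max: int = 250
    motif_half_width: int = 100
    enrichment_resamples: int = 200
    common_centering: str = "asynchronous"  # or 'mitotic'
    include_images: bool = True
    image: ImageConfig = field(default_factory=ImageConfig)
    image_groups: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_IMAGE_GROUPS)
    )
    n_cells_per_group: int = 12
    cell_cv: float = 0.10  # cell-to-cell coefficient of variation of the true ratio
    write_images: bool = False  # dump the first cell of each group as TIFF+PNG masks
    # ingest paths, used when sim is None
    genome_fasta: str | None = None
    gene_table: str | None = None
    tags_async: str | None = None
    tags_mitotic: str | None = None
    tags_input: str | None = None

    def __post_init__(self) -> None:
        if self.sim is not None:
            self.sim.seed = self.seed

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        for key, klass in (("sim", SimConfig), ("peak_params", PeakCallParams),
                           ("class_params", ClassificationParams),
                           ("scheme", AnnotationScheme), ("image", ImageConfig)):
            if isinstance(raw.get(key), dict):
                sub = raw[key]
                if "chrom_lengths" in sub:
                    sub["chrom_lengths"] = {k: int(v) for k, v in sub["chrom_lengths"].items()}
                raw[key] = klass(**sub)
        if raw.get("sim") is None and "sim" in raw:
            raw["sim"] = None
        return cls(**raw)

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)

        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=enc)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kw):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kw)
            except Exception as exc:  # noqa: BLE001 - wrapped with stage context
                raise StageError(name, exc) from exc
            log.info("stage %s: done in %.1fs", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


def common_centers(comparison: PeakSetComparison, centering: str) -> dict[str, list[int]]:
    """Reference centers of common peaks under the chosen centering."""
    out: dict[str, list[int]] = {}
    for c in comparison.common:
        if centering == "mitotic":
            peak = c.mitotic_peak or c.async_peak
        else:
            peak = c.async_peak or c.mitotic_peak
        out.setdefault(c.chrom, []).append(peak.center)
    return out


@dataclass
class RunResult:
    outdir: Path
    manifest: dict
    comparison: PeakSetComparison | None = None
    recovery: RecoveryReport | None = None


def run_pipeline(cfg: RunConfig) -> RunResult:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    manifest: dict = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "artifacts": artifacts,
        "stages": [],
    }

    def record(key: str, path: Path) -> Path:
        artifacts[key] = str(path.relative_to(outdir))
        return path

    # ----------------------------------------------------------- simulate
    @_stage("simulate")
    def stage_simulate():
        if cfg.sim is None:
            if cfg.gene_table is None or cfg.genome_fasta is None:
                raise MitobookError("ingest mode needs genome_fasta and gene_table")
            genome = mio.read_gene_table(mio.require(cfg.gene_table, "gene table"))
            sequences = mio.read_fasta(mio.require(cfg.genome_fasta, "genome FASTA"))
            return genome, sequences, None
        genome, sequences = make_genome(cfg.sim)
        sites, sequences = plant_sites(genome, sequences, cfg.sim)
        mio.write_fasta(sequences, record("genome_fasta", outdir / "genome.fa"))
        mio.write_gene_table(genome, record("gene_table", outdir / "genes.tsv"))
        mio.write_gene_bed12(genome, record("gene_bed12", outdir / "genes.bed12"))
        mio.write_sites_bed(sites, record("sites_bed", outdir / "sites.bed"))
        for cond in ("asynchronous", "mitotic", "input"):
            tags = simulate_tags(genome, sites, cond, cfg.sim)
            mio.write_tag_bed(tags, record(f"tags_{cond}", outdir / f"tags_{cond}.bed"))
        return genome, sequences, sites

    genome, sequences, sites = stage_simulate()
    manifest["stages"].append("simulate")

    # --------------------------------------------------------- call-peaks
    @_stage("call-peaks")
    def stage_call():
        lengths = genome.chrom_lengths
        if cfg.sim is not None:
            paths = {c: outdir / f"tags_{c}.bed" for c in ("asynchronous", "mitotic", "input")}
        else:
            paths = {"asynchronous": cfg.tags_async, "mitotic": cfg.tags_mitotic,
                     "input": cfg.tags_input}
        tag_sets = {
            cond: mio.read_tag_bed(mio.require(p, f"{cond} tag BED"), lengths)
            for cond, p in paths.items()
        }
        peak_sets = {}
        for cond in ("asynchronous", "mitotic"):
            ps = call_peaks(tag_sets[cond], tag_sets["input"], cfg.peak_params,
                            condition=cond)
            mio.write_peaks_bed(ps, record(f"peaks_{cond}", outdir / f"peaks_{cond}.bed"))
            peak_sets[cond] = ps
        report = {
            "params": dataclasses.asdict(cfg.peak_params),
            "depth": {c: t.total_tags for c, t in tag_sets.items()},
            "n_peaks": {c: len(p) for c, p in peak_sets.items()},
        }
        mio.write_json(report, record("call_report", outdir / "call_report.json"))
        return tag_sets, peak_sets

    tag_sets, peak_sets = stage_call()
    manifest["stages"].append("call-peaks")

    # ----------------------------------------------------------- classify
    @_stage("classify")
    def stage_classify():
        comparison = classify_peaks(
            peak_sets["asynchronous"], peak_sets["mitotic"],
            tag_sets["asynchronous"], tag_sets["mitotic"], cfg.class_params,
        )
        counts = comparison.counts()
        summary = summarize_comparison(
            counts["async_specific"], counts["mitotic_specific"], counts["common"]
        )
        mio.write_json({"counts": counts, "percent": summary},
                       record("class_summary", outdir / "class_summary.json"))
        half = cfg.class_params.width // 2
        for label, rows in (
            ("async_specific", [(p.chrom, p.center) for p in comparison.async_specific]),
            ("mitotic_specific", [(p.chrom, p.center) for p in comparison.mitotic_specific]),
            ("common", [(c, x) for c, xs in
                        common_centers(comparison, cfg.common_centering).items()
                        for x in xs]),
        ):
            path = record(f"bed_{label}", outdir / f"{label}.bed")
            with open(path, "w") as fh:
                for chrom, center in sorted(rows):
                    fh.write(f"{chrom}\t{center - half}\t{center + half}\t{label}\t0\t.\n")
        return comparison

    comparison = stage_classify()
    manifest["stages"].append("classify")

    # -------------------------------------------------------------- shift
    @_stage("shift")
    def stage_shift():
        dists = [d for _, d in
                 nearest_peak_distances(peak_sets["asynchronous"], peak_sets["mitotic"])
                 if d is not None]
        hist = shift_histogram(dists, cfg.histogram_bin)
        rows = [
            {"bin_start": int(i * hist.bin_width),
             "bin_end": int((i + 1) * hist.bin_width),
             "count": int(c)}
            for i, c in enumerate(hist.counts)
        ]
        mio.write_table(rows, record("shift_histogram", outdir / "shift_histogram.tsv"))
        flagged = flag_shifted_common(comparison, cfg.shift_flag_min, cfg.shift_flag_max)
        path = record("shifted_common", outdir / "shifted_common.bed")
        half = cfg.class_params.width // 2
        with open(path, "w") as fh:
            for entry, d in sorted(flagged, key=lambda t: (t[0].chrom, t[0].reference_center)):
                fh.write(
                    f"{entry.chrom}\t{entry.reference_center - half}\t"
                    f"{entry.reference_center + half}\tshifted_common\t{d}\t.\n"
                )
        mio.write_json(
            {"overflow": hist.overflow, "total": hist.total,
             "n_flagged": len(flagged)},
            record("shift_summary", outdir / "shift_summary.json"),
        )
        return hist, flagged

    hist, flagged = stage_shift()
    manifest["stages"].append("shift")

    # -------------------------------------------------------------- motif
    @_stage("motif")
    def stage_motif():
        rbpj = MotifModel(name="RBPJ", consensus=RBPJ_CONSENSUS)
        ctcf = MotifModel(name="CTCF-like", consensus=CTCF_LIKE_CONSENSUS)
        groups = {
            "async_specific": {
                c: [p.center for p in comparison.async_specific if p.chrom == c]
                for c in genome.chrom_lengths},
            "mitotic_specific": {
                c: [p.center for p in comparison.mitotic_specific if p.chrom == c]
                for c in genome.chrom_lengths},
            "common": common_centers(comparison, cfg.common_centering),
        }
        rows = []
        for label, centers in groups.items():
            if not any(centers.values()):
                continue
            table = peak_motif_content(
                centers, sequences, rbpj, ctcf,
                half_width=cfg.motif_half_width, label=label,
                centering=cfg.common_centering if label == "common" else "own",
            )
            rows.append(table.as_dict())
        mio.write_table(rows, record("motif_table", outdir / "motif_content.tsv"))
        enrich = {}
        common = groups["common"]
        if any(common.values()):
            for model in (rbpj, ctcf):
                enrich[model.name] = motif_enrichment(
                    common, sequences, model,
                    n_resamples=cfg.enrichment_resamples,
                    seed=cfg.seed + 101,
                    half_width=cfg.motif_half_width,
                )
        mio.write_json(enrich, record("motif_enrichment", outdir / "motif_enrichment.json"))
        return rows, enrich

    motif_rows, enrich = stage_motif()
    manifest["stages"].append("motif")

    # ----------------------------------------------------------- annotate
    @_stage("annotate")
    def stage_annotate():
        out = {}
        groups = {
            "async_specific": [(p.chrom, p.center) for p in comparison.async_specific],
            "mitotic_specific": [(p.chrom, p.center) for p in comparison.mitotic_specific],
            "common": [(c, x) for c, xs in
                       common_centers(comparison, cfg.common_centering).items()
                       for x in xs],
        }
        for label, pairs in groups.items():
            if not pairs:
                continue
            centers: dict[str, list[int]] = {}
            for chrom, x in pairs:
                centers.setdefault(chrom, []).append(x)
            out[label] = annotation_summary(centers, genome, cfg.scheme)
        mio.write_json(out, record("annotation", outdir / "annotation_summary.json"))
        return out

    annotation = stage_annotate()
    manifest["stages"].append("annotate")

    # ----------------------------------------------------- quantify-images
    recovery = None
    if cfg.include_images:
        @_stage("quantify-images")
        def stage_images():
            import numpy as np

            from .simulate import make_cell_image

            rows = []
            summaries = []
            for gi, (label, ratio) in enumerate(sorted(cfg.image_groups.items())):
                base_seed = cfg.seed + 1000 * (gi + 1)
                cell_rng = np.random.default_rng([base_seed, 71])
                ratios = []
                for ci in range(cfg.n_cells_per_group):
                    # biological scatter: each cell has its own true ratio
                    cell_ratio = max(
                        0.1, ratio * (1 + cfg.cell_cv * cell_rng.standard_normal())
                    )
                    icfg = dataclasses.replace(
                        cfg.image, true_ratio=cell_ratio, seed=base_seed + ci
                    )
                    img = make_cell_image(icfg)
                    if cfg.write_images and ci == 0:
                        mio.write_image(img, outdir / f"cell_{label}_{ci:03d}")
                    m = measure_image(img, cell_id=f"{label}_{ci:03d}",
                                      seed=base_seed + ci)
                    r = retention_ratio(m)
                    ratios.append(r)
                    rows.append({"group": label, "cell": m.cell_id,
                                 "ratio": round(r, 6)})
                s = group_summary(label, ratios)
                summaries.append({"group": label, "n": s.n,
                                  "mean": round(s.mean, 6), "sem": round(s.sem, 6)})
            mio.write_table(rows, record("cell_ratios", outdir / "cell_ratios.tsv"))
            mio.write_table(summaries, record("retention_summary",
                                              outdir / "retention_summary.tsv"))
            return summaries

        manifest["image_groups"] = stage_images()
        manifest["stages"].append("quantify-images")

    # ------------------------------------------------- ground-truth scoring
    if sites is not None:
        recovery = score_class_recovery(sites, comparison)
        shift_flag_frac = score_shift_flags(sites, flagged)
        rec = {
            "per_class": {k: {"recovered": v[0], "planted": v[1]}
                          for k, v in recovery.per_class.items()},
            "overall_fraction": recovery.overall_fraction,
            "shifted_flag_fraction": shift_flag_frac,
            "recovered_shift_distances": recovered_shift_distances(sites, comparison),
        }
        mio.write_json(rec, record("recovery", outdir / "recovery.json"))
        manifest["recovery"] = rec

    mio.write_json(manifest, outdir / "manifest.json")
    return RunResult(outdir, manifest, comparison, recovery)
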