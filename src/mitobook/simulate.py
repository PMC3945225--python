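"""Synthetic-data generator with known ground truth.

Emulates a paired-condition ChIP-seq experiment on a mitotic-bookmarking
factor: a random genome with gene models, planted binding sites that are
common to both cell populations, specific to one, or *shifted* (occupied in
both but displaced in mitosis), tag collections for asynchronous-ChIP,
mitotic-ChIP and input libraries, the three 147-bp nucleosome fragment
designs used for in-vitro binding work, and two-channel-style cell images
with a planted chromatin/nucleocytoplasm retention ratio.

Everything is byte-reproducible under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, PlacementError, SizingError
from .motifs import CTCF_LIKE_CONSENSUS, MotifModel, RBPJ_CONSENSUS, scan_iupac
from .tags import TagCollection

CONDITIONS = ("asynchronous", "mitotic", "input")
SITE_CLASSES = ("common", "async_specific", "mitotic_specific", "shifted")

#: The 8-bp RBPJ binding motif embedded at planted sites (consensus with the
#: degenerate final position resolved to A; ``plant_sites`` may resolve to G).
RBPJ_SITE_MOTIF = "TTCCCACA"

_COND_CODE = {c: i for i, c in enumerate(CONDITIONS, start=1)}


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SimConfig:
    """Study conditions for one synthetic run.

    Defaults give, per planted site, an expected
    ``enrichment_fold * bg_rate * 2 * fragment_half_width`` = 160 ChIP tags
    on top of a 0.04 tags/bp background — a strongly bound factor at desk
    scale (~2x10^5 tags total instead of the ~35M of a real library), deep
    enough that peak centers localize to ~15-20 bp, the precision needed to
    resolve sub-window occupancy shifts.
    """

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_500_000, "chr2": 1_500_000}
    )
    n_genes: int = 60
    gene_length_range: tuple[int, int] = (2_000, 10_000)
    n_common: int = 200
    n_async_specific: int = 100
    n_mitotic_specific: int = 50
    n_shifted: int = 50
    enrichment_fold: float = 10.0
    bg_rate: float = 0.04  # background tags per bp per library
    fragment_half_width: int = 200  # tag offsets are truncated at +/- this
    min_spacing: int = 2_000
    shift_distance: int = 150
    rbpj_motif_prob: float = 0.20
    ctcf_motif_prob: float = 0.16
    motif_r_rule: str = "random"  # 'random' | 'A' | 'G' for the consensus R

    def validate(self) -> None:
        counts = (self.n_genes, self.n_common, self.n_async_specific,
                  self.n_mitotic_specific, self.n_shifted)
        if any(c < 0 for c in counts):
            raise ConfigError("counts must be >= 0")
        if self.enrichment_fold < 1:
            raise ConfigError("enrichment fold must be >= 1")
        if self.bg_rate <= 0 or self.fragment_half_width <= 0 or self.min_spacing <= 0:
            raise ConfigError("rates, widths and spacing must be positive")
        if self.shift_distance < 0:
            raise ConfigError("shift distance must be >= 0")
        if self.n_shifted > 0 and self.shift_distance == 0:
            raise ConfigError("shifted sites require shift_distance > 0")
        if self.motif_r_rule not in ("random", "A", "G"):
            raise ConfigError("motif_r_rule must be 'random', 'A' or 'G'")
        if not (0 <= self.rbpj_motif_prob <= 1 and 0 <= self.ctcf_motif_prob <= 1):
            raise ConfigError("motif probabilities must lie in [0, 1]")

    @property
    def n_sites(self) -> int:
        return self.n_common + self.n_async_specific + self.n_mitotic_specific + self.n_shifted

    @property
    def expected_site_tags(self) -> float:
        """Expected total tag count in a site's own window: background plus
        (fold - 1) x background of site-specific tags, i.e. fold x background.
        At fold = 1 a site is indistinguishable from background."""
        return self.enrichment_fold * self.bg_rate * 2 * self.fragment_half_width


# ---------------------------------------------------------------------------
# genome and gene models


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    tss: int  # 0-based position
    tts: int  # 0-based position
    exons: tuple[tuple[int, int], ...]  # sorted, non-overlapping, half-open

    @property
    def start(self) -> int:
        return min(self.tss, self.tts)

    @property
    def end(self) -> int:  # half-open
        return max(self.tss, self.tts) + 1


@dataclass
class GenomeModel:
    chromosomes: list[tuple[str, int]]
    genes: list[Gene]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def validate(self) -> None:
        lengths = self.chrom_lengths
        for g in self.genes:
            L = lengths[g.chrom]
            if not (0 <= g.start and g.end <= L):
                raise ConfigError(f"{g.gene_id} outside chromosome bounds")
            if g.strand == "+" and not g.tss < g.tts:
                raise ConfigError(f"{g.gene_id}: + strand requires TSS < TTS")
            if g.strand == "-" and not g.tss > g.tts:
                raise ConfigError(f"{g.gene_id}: - strand requires TSS > TTS")
            prev_end = None
            for s, e in g.exons:
                if not (g.start <= s < e <= g.end):
                    raise ConfigError(f"{g.gene_id}: exon outside gene span")
                if prev_end is not None and s < prev_end:
                    raise ConfigError(f"{g.gene_id}: exons overlap or unsorted")
                prev_end = e
            if not g.exons:
                raise ConfigError(f"{g.gene_id}: gene without exons")


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def make_genome(cfg: SimConfig) -> tuple[GenomeModel, dict[str, str]]:
    """Random genome sequence (uniform base composition) plus non-overlapping
    gene models, each with 1–3 exons."""
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 11])
    sequences = {
        chrom: _BASES[rng.integers(0, 4, size=L)].tobytes().decode()
        for chrom, L in cfg.chrom_lengths.items()
    }

    chroms = list(cfg.chrom_lengths)
    total = sum(cfg.chrom_lengths.values())
    # apportion genes to chromosomes by length (largest remainder)
    quotas = {c: cfg.n_genes * cfg.chrom_lengths[c] / total for c in chroms}
    n_per = {c: int(q) for c, q in quotas.items()}
    leftover = cfg.n_genes - sum(n_per.values())
    for c in sorted(chroms, key=lambda c: quotas[c] - n_per[c], reverse=True)[:leftover]:
        n_per[c] += 1

    genes: list[Gene] = []
    gid = 0
    for chrom in chroms:
        n = n_per[chrom]
        if n == 0:
            continue
        L = cfg.chrom_lengths[chrom]
        lengths = rng.integers(cfg.gene_length_range[0], cfg.gene_length_range[1] + 1, n)
        slack = L - int(lengths.sum())
        if slack < n + 1:
            raise SizingError(
                f"chromosome {chrom} ({L} bp) too short for {n} genes"
            )
        gaps = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
        pos = 0
        for i in range(n):
            pos += int(gaps[i])
            start, glen = pos, int(lengths[i])
            end = start + glen
            pos = end
            strand = "+" if rng.random() < 0.5 else "-"
            k = int(rng.integers(1, 4))
            cuts = np.sort(rng.choice(np.arange(glen + 1), size=2 * k, replace=False))
            exons = tuple(
                (start + int(cuts[2 * j]), start + int(cuts[2 * j + 1]))
                for j in range(k)
            )
            tss, tts = (start, end - 1) if strand == "+" else (end - 1, start)
            genes.append(Gene(f"gene{gid:04d}", chrom, strand, tss, tts, exons))
            gid += 1

    model = GenomeModel([(c, cfg.chrom_lengths[c]) for c in chroms], genes)
    model.validate()
    return model, sequences


# ---------------------------------------------------------------------------
# planted binding sites


@dataclass(frozen=True)
class PlantedSite:
    chrom: str
    position: int  # asynchronous (interphase) enrichment center
    site_class: str
    shift_distance: int = 0  # >0 only for 'shifted'
    motifs: frozenset[str] = frozenset()

    def center(self, condition: str) -> int:
        if condition == "mitotic" and self.site_class == "shifted":
            return self.position + self.shift_distance
        return self.position


@dataclass
class PlantedSiteSet:
    sites: list[PlantedSite]

    def by_class(self, site_class: str) -> list[PlantedSite]:
        return [s for s in self.sites if s.site_class == site_class]

    def active_centers(self, condition: str) -> list[tuple[str, int]]:
        """Enrichment centers active in the given condition."""
        if condition == "input":
            return []
        out = []
        for s in self.sites:
            if s.site_class == "common" or s.site_class == "shifted":
                out.append((s.chrom, s.center(condition)))
            elif s.site_class == "async_specific" and condition == "asynchronous":
                out.append((s.chrom, s.position))
            elif s.site_class == "mitotic_specific" and condition == "mitotic":
                out.append((s.chrom, s.position))
        return out

    def validate(self, chrom_lengths: dict[str, int], min_spacing: int) -> None:
        per_chrom: dict[str, list[int]] = {}
        for s in self.sites:
            L = chrom_lengths[s.chrom]
            if not (0 <= s.position < L and 0 <= s.position + s.shift_distance < L):
                raise ConfigError("site outside chromosome bounds")
            if s.site_class == "shifted" and s.shift_distance <= 0:
                raise ConfigError("shifted site without positive shift distance")
            per_chrom.setdefault(s.chrom, []).append(s.position)
        for positions in per_chrom.values():
            positions.sort()
            gaps = np.diff(positions)
            if len(gaps) and gaps.min() < min_spacing:
                raise PlacementError("planted sites closer than minimum spacing")


def _resolve_r(rule: str, rng: np.random.Generator) -> str:
    if rule == "random":
        return "A" if rng.random() < 0.5 else "G"
    return rule


def plant_sites(
    genome: GenomeModel,
    sequences: dict[str, str],
    cfg: SimConfig,
) -> tuple[PlantedSiteSet, dict[str, str]]:
    """Place sites at >= min_spacing pairwise distance and embed motifs.

    The RBPJ 8-mer is written at the asynchronous center (degenerate final
    position resolved per ``cfg.motif_r_rule``); the CTCF-like 12-mer, when
    planted, sits 15 bp right of the center so both fit in one 200-bp window.
    A shifted site is one underlying element whose enrichment center moves by
    ``shift_distance`` in mitosis while the motif stays at the asynchronous
    center.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 23])
    lengths = genome.chrom_lengths
    margin = cfg.min_spacing + cfg.shift_distance

    # lattice at 2*min_spacing steps, jittered by < min_spacing/2, keeps all
    # pairwise distances >= min_spacing while randomizing placement
    candidates: list[tuple[str, int]] = []
    for chrom, L in lengths.items():
        span = L - 2 * margin
        if span <= 0:
            continue
        grid = np.arange(margin, L - margin, 2 * cfg.min_spacing)
        jitter = rng.integers(-(cfg.min_spacing // 2 - 1), cfg.min_spacing // 2,
                              size=len(grid))
        for p in grid + jitter:
            candidates.append((chrom, int(p)))
    if len(candidates) < cfg.n_sites:
        raise PlacementError(
            f"cannot place {cfg.n_sites} sites at spacing {cfg.min_spacing}: "
            f"only {len(candidates)} slots available"
        )
    order = rng.permutation(len(candidates))
    chosen = [candidates[i] for i in order[: cfg.n_sites]]

    labels = (
        ["common"] * cfg.n_common
        + ["async_specific"] * cfg.n_async_specific
        + ["mitotic_specific"] * cfg.n_mitotic_specific
        + ["shifted"] * cfg.n_shifted
    )

    mutable = {c: bytearray(s, "ascii") for c, s in sequences.items()}
    sites: list[PlantedSite] = []
    for (chrom, pos), label in zip(chosen, labels):
        motifs = set()
        if rng.random() < cfg.rbpj_motif_prob:
            motifs.add("RBPJ")
        if rng.random() < cfg.ctcf_motif_prob:
            motifs.add("CTCF")
        if "RBPJ" in motifs:
            eight = RBPJ_SITE_MOTIF[:7] + _resolve_r(cfg.motif_r_rule, rng)
            start = pos - len(eight) // 2
            mutable[chrom][start:start + len(eight)] = eight.encode()
        if "CTCF" in motifs:
            start = pos + 15
            mutable[chrom][start:start + len(CTCF_LIKE_CONSENSUS)] = (
                CTCF_LIKE_CONSENSUS.encode()
            )
        shift = cfg.shift_distance if label == "shifted" else 0
        sites.append(PlantedSite(chrom, pos, label, shift, frozenset(motifs)))

    sites.sort(key=lambda s: (s.chrom, s.position))
    site_set = PlantedSiteSet(sites)
    site_set.validate(lengths, cfg.min_spacing)
    return site_set, {c: b.decode() for c, b in mutable.items()}


# ---------------------------------------------------------------------------
# tag simulation


def simulate_tags(
    genome: GenomeModel,
    sites: PlantedSiteSet,
    condition: str,
    cfg: SimConfig,
) -> TagCollection:
    """One sequencing library for the given condition.

    Background tags fall uniformly at rate ``bg_rate`` per bp. Each site
    active in the condition adds Poisson((fold - 1) * bg_rate * 2 * half_width)
    site-specific tags — so the site window's total expectation is fold times
    background, and fold = 1 reduces exactly to the null — with offsets from
    the condition-specific center following a normal with sd = half_width/2,
    clipped at +/- half_width. The input library receives background only.
    """
    if condition not in CONDITIONS:
        raise ConfigError(f"condition must be one of {CONDITIONS}")
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, _COND_CODE[condition], 37])
    lengths = genome.chrom_lengths
    hw = cfg.fragment_half_width

    positions: dict[str, list[np.ndarray]] = {c: [] for c in lengths}
    strands: dict[str, list[np.ndarray]] = {c: [] for c in lengths}
    for chrom, L in lengths.items():
        n_bg = rng.poisson(cfg.bg_rate * L)
        positions[chrom].append(rng.integers(0, L, size=n_bg, dtype=np.int64))
        strands[chrom].append(
            rng.choice(np.array([1, -1], dtype=np.int8), size=n_bg)
        )

    mean_extra_tags = (cfg.enrichment_fold - 1) * cfg.bg_rate * 2 * hw
    for chrom, center in sites.active_centers(condition):
        n = rng.poisson(mean_extra_tags)
        offsets = np.clip(
            np.rint(rng.normal(0.0, hw / 2.0, size=n)).astype(np.int64), -hw, hw - 1
        )
        pos = np.clip(center + offsets, 0, lengths[chrom] - 1)
        positions[chrom].append(pos)
        strands[chrom].append(rng.choice(np.array([1, -1], dtype=np.int8), size=n))

    return TagCollection(
        chrom_lengths=dict(lengths),
        positions={c: np.concatenate(v) for c, v in positions.items()},
        strands={c: np.concatenate(v) for c, v in strands.items()},
    )


# ---------------------------------------------------------------------------
# nucleosome fragment designs


@dataclass(frozen=True)
class FragmentDesign:
    """One 147-bp nucleosome-assembly fragment.

    ``motif_interval`` is 1-based inclusive, matching how fragment
    coordinates are quoted in bench work (e.g. an end-proximal motif at
    127–134 leaves exactly 13 nt distal to it on a 147-bp fragment).
    """

    name: str
    length: int = 147
    phasing_interval: tuple[int, int] = (1, 40)
    motif: str | None = None
    motif_interval: tuple[int, int] | None = None

    def validate(self) -> None:
        if self.length != 147:
            raise ConfigError("nucleosomal fragment must be 147 bp")
        if self.phasing_interval != (1, 40):
            raise ConfigError("phasing sequences occupy positions 1–40")
        if (self.motif is None) != (self.motif_interval is None):
            raise ConfigError("motif and motif_interval must come together")
        if self.motif_interval is not None:
            s, e = self.motif_interval
            if e - s + 1 != len(self.motif) or len(self.motif) != 8:
                raise ConfigError("motif interval must span the 8-bp motif")
            if not (41 <= s and e <= self.length):
                raise ConfigError("motif must lie outside the phasing region")


_RBPJ_MODEL = MotifModel(name="RBPJ", consensus=RBPJ_CONSENSUS)

#: Two 20-bp GT-repeat phasing sequences occupying fragment positions 1–40.
PHASING_SEQUENCE = "GT" * 20


def _filler(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def build_nucleosome_fragments(
    dyad_motif_start: int = 67,
) -> list[tuple[FragmentDesign, str]]:
    """The three 147-bp fragment designs: motif-free (RBPJ-minus),
    end-proximal motif at 127–134 (RBPJ-end), and near-dyad motif
    (RBPJ-dyad, default start 67; pass 57 for the alternative placement).

    Construction is deterministic; each sequence is verified at build time to
    contain exactly the intended number of consensus matches on either strand.
    """
    end_start = 127
    designs = {
        "RBPJ-minus": None,
        "RBPJ-end": (end_start, end_start + 7),
        "RBPJ-dyad": (dyad_motif_start, dyad_motif_start + 7),
    }
    out: list[tuple[FragmentDesign, str]] = []
    for name, interval in designs.items():
        for attempt in range(1000):
            name_code = int.from_bytes(name.encode(), "little") % (2**31)
            rng = np.random.default_rng([147, attempt, name_code])
            seq = PHASING_SEQUENCE + _filler(rng, 147 - len(PHASING_SEQUENCE))
            expected_starts: list[int] = []
            if interval is not None:
                s0 = interval[0] - 1  # to 0-based
                seq = seq[:s0] + RBPJ_SITE_MOTIF + seq[s0 + 8:]
                expected_starts = [s0]
            matches = scan_iupac(seq, _RBPJ_MODEL, both_strands=True)
            if [m.start for m in matches] == expected_starts:
                break
        else:  # pragma: no cover - astronomically unlikely
            raise ConfigError(f"could not construct clean fragment {name}")
        design = FragmentDesign(
            name=name,
            motif=RBPJ_SITE_MOTIF if interval else None,
            motif_interval=interval,
        )
        design.validate()
        assert len(seq) == 147
        out.append((design, seq))
    return out


# ---------------------------------------------------------------------------
# synthetic cell images


@dataclass
class ImageConfig:
    shape: tuple[int, int] = (128, 128)
    background_level: float = 100.0
    cyto_signal: float = 200.0
    true_ratio: float = 3.6
    noise_sigma: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.background_level, self.cyto_signal, self.true_ratio) < 0:
            raise ConfigError("image levels must be non-negative")
        if self.noise_sigma < 0:
            raise ConfigError("noise sigma must be non-negative")
        if min(self.shape) < 64:
            raise ConfigError("image too small for the three-compartment layout")


@dataclass
class SyntheticImage:
    """Single-channel (eGFP-like) mitotic cell image with known truth.

    The chromatin disk sits at the image center, surrounded by a
    nucleocytoplasm annulus; the extracellular background occupies the far
    corners. Masks are pairwise disjoint. Pixel means inside the masks before
    noise are background_level, background_level + cyto_signal, and
    background_level + true_ratio * cyto_signal respectively.
    """

    pixels: np.ndarray
    chromatin_mask: np.ndarray
    nucleocytoplasm_mask: np.ndarray
    background_mask: np.ndarray
    true_ratio: float
    noise_sigma: float

    def validate(self) -> None:
        overlap = (
            (self.chromatin_mask & self.nucleocytoplasm_mask)
            | (self.chromatin_mask & self.background_mask)
            | (self.nucleocytoplasm_mask & self.background_mask)
        )
        if overlap.any():
            raise ConfigError("compartment masks must be disjoint")
        if (self.pixels < 0).any():
            raise ConfigError("pixel values must be non-negative")


def make_cell_image(icfg: ImageConfig) -> SyntheticImage:
    icfg.validate()
    rng = np.random.default_rng([icfg.seed, 53])
    h, w = icfg.shape
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(yy - h / 2.0, xx - w / 2.0)
    scale = min(h, w) / 128.0
    chrom = r <= 14 * scale
    cyto = (r > 20 * scale) & (r <= 38 * scale)
    bg = r > 52 * scale

    img = np.full((h, w), icfg.background_level, dtype=float)
    img[cyto] += icfg.cyto_signal
    img[chrom] += icfg.true_ratio * icfg.cyto_signal
    if icfg.noise_sigma > 0:
        img += rng.normal(0.0, icfg.noise_sigma, size=img.shape)
    np.clip(img, 0.0, None, out=img)

    out = SyntheticImage(img, chrom, cyto, bg, icfg.true_ratio, icfg.noise_sigma)
    out.validate()
    return out


def image_battery(icfg: ImageConfig, n_images: int) -> list[SyntheticImage]:
    """n images differing only in their noise seed."""
    return [make_cell_image(replace(icfg, seed=icfg.seed + i)) for i in range(n_images)]
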