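"""Synthetic-data generator: determinism, invariants, planted ground truth."""

import dataclasses

import numpy as np
import pytest

from mitobook import (ImageConfig, MotifModel, SimConfig,
                      build_nucleosome_fragments, make_cell_image, make_genome,
                      plant_sites, scan_iupac, simulate_tags)
from mitobook.errors import ConfigError, PlacementError, SizingError
from mitobook.motifs import RBPJ_CONSENSUS
from mitobook.simulate import PHASING_SEQUENCE, RBPJ_SITE_MOTIF

RBPJ = MotifModel(name="RBPJ", consensus=RBPJ_CONSENSUS)


class TestMakeGenome:
    def test_zero_genes(self):
        cfg = SimConfig(seed=1, chrom_lengths={"c": 10_000}, n_genes=0)
        genome, seqs = make_genome(cfg)
        assert genome.genes == []
        assert len(seqs["c"]) == 10_000

    def test_deterministic(self):
        cfg = SimConfig(seed=5, chrom_lengths={"c": 50_000}, n_genes=4)
        g1, s1 = make_genome(cfg)
        g2, s2 = make_genome(cfg)
        assert s1 == s2
        assert g1.genes == g2.genes

    def test_gene_invariants_exhaustive(self):
        cfg = SimConfig(seed=3, chrom_lengths={"c": 1_000_000}, n_genes=20)
        genome, _ = make_genome(cfg)
        assert len(genome.genes) == 20
        spans = []
        for g in genome.genes:
            lo, hi = min(g.tss, g.tts), max(g.tss, g.tts)
            assert 0 <= lo < hi <= 1_000_000
            if g.strand == "+":
                assert g.tss < g.tts
            else:
                assert g.tss > g.tts
            prev_end = None
            assert g.exons
            for s, e in g.exons:
                assert lo <= s < e <= hi + 1
                if prev_end is not None:
                    assert s >= prev_end
                prev_end = e
            spans.append((lo, hi))
        spans.sort()
        for (_, e1), (s2, _) in zip(spans, spans[1:]):
            assert s2 > e1  # genes do not overlap

    def test_sizing_error(self):
        cfg = SimConfig(seed=1, chrom_lengths={"c": 15_000}, n_genes=10)
        with pytest.raises(SizingError):
            make_genome(cfg)


class TestPlantSites:
    def test_empty(self):
        cfg = SimConfig(seed=1, chrom_lengths={"c": 100_000}, n_genes=0,
                        n_common=0, n_async_specific=0, n_mitotic_specific=0,
                        n_shifted=0)
        genome, seqs = make_genome(cfg)
        sites, out = plant_sites(genome, seqs, cfg)
        assert sites.sites == []
        assert out == seqs

    def test_rbpj_motif_planted(self):
        cfg = SimConfig(seed=2, chrom_lengths={"c": 300_000}, n_genes=0,
                        n_common=10, n_async_specific=5, n_mitotic_specific=0,
                        n_shifted=0, rbpj_motif_prob=1.0, ctcf_motif_prob=0.0,
                        motif_r_rule="A")
        genome, seqs = make_genome(cfg)
        sites, out = plant_sites(genome, seqs, cfg)
        for s in sites.sites:
            assert "RBPJ" in s.motifs
            window = out[s.chrom][s.position - 100: s.position + 100]
            assert RBPJ_SITE_MOTIF in window
            assert scan_iupac(window, RBPJ)  # recoverable by the scanner

    def test_min_spacing_all_pairs(self):
        cfg = SimConfig(seed=4, chrom_lengths={"c": 300_000}, n_genes=0,
                        n_common=10, n_async_specific=5, n_mitotic_specific=0,
                        n_shifted=0, min_spacing=2000)
        genome, seqs = make_genome(cfg)
        sites, _ = plant_sites(genome, seqs, cfg)
        pos = [s.position for s in sites.sites]
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                assert abs(pos[i] - pos[j]) >= 2000

    def test_placement_error(self):
        cfg = SimConfig(seed=1, chrom_lengths={"c": 30_000}, n_genes=0,
                        n_common=50, n_async_specific=0, n_mitotic_specific=0,
                        n_shifted=0, min_spacing=2000)
        genome, seqs = make_genome(cfg)
        with pytest.raises(PlacementError):
            plant_sites(genome, seqs, cfg)

    def test_shifted_sites_record_shift(self):
        cfg = SimConfig(seed=6, chrom_lengths={"c": 300_000}, n_genes=0,
                        n_common=0, n_async_specific=0, n_mitotic_specific=0,
                        n_shifted=8, shift_distance=150)
        genome, seqs = make_genome(cfg)
        sites, _ = plant_sites(genome, seqs, cfg)
        assert all(s.shift_distance == 150 for s in sites.sites)
        assert all(s.center("mitotic") - s.center("asynchronous") == 150
                   for s in sites.sites)


def _site_window_counts(cfg, condition, n_seeds):
    """Mean tag count over all site windows across seeded replicates."""
    counts = []
    for seed in range(n_seeds):
        c = dataclasses.replace(cfg, seed=seed)
        genome, seqs = make_genome(c)
        sites, _ = plant_sites(genome, seqs, c)
        tags = simulate_tags(genome, sites, condition, c)
        hw = c.fragment_half_width
        for s in sites.sites:
            counts.append(tags.count_in(s.chrom, s.position - hw, s.position + hw))
    return np.array(counts, dtype=float)


class TestSimulateTags:
    BASE = dict(chrom_lengths={"c": 60_000}, n_genes=0, n_common=4,
                n_async_specific=0, n_mitotic_specific=0, n_shifted=0,
                min_spacing=2000)

    def test_fold_one_is_null(self):
        # at fold 1 the site windows match the background expectation
        cfg = SimConfig(enrichment_fold=1.0, **self.BASE)
        counts = _site_window_counts(cfg, "asynchronous", n_seeds=50)
        expected = cfg.bg_rate * 2 * cfg.fragment_half_width
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - expected) < 3 * se + 1e-9

    def test_input_receives_no_enrichment(self):
        cfg = SimConfig(enrichment_fold=10.0, **self.BASE)
        counts = _site_window_counts(cfg, "input", n_seeds=50)
        expected = cfg.bg_rate * 2 * cfg.fragment_half_width
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - expected) < 3 * se + 1e-9

    def test_expected_site_tags(self):
        # fold 10, rate and window chosen so the site-window total is 50
        cfg = SimConfig(enrichment_fold=10.0, bg_rate=0.0125,
                        fragment_half_width=200, **self.BASE)
        assert cfg.expected_site_tags == pytest.approx(50.0)
        counts = _site_window_counts(cfg, "asynchronous", n_seeds=50)
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - 50.0) < 3 * se

    def test_total_tags_consistent(self, sim_run):
        for tags in sim_run["tags"].values():
            assert tags.total_tags == sum(len(p) for p in tags.positions.values())

    def test_deterministic(self, small_cfg):
        genome, seqs = make_genome(small_cfg)
        sites, _ = plant_sites(genome, seqs, small_cfg)
        t1 = simulate_tags(genome, sites, "mitotic", small_cfg)
        t2 = simulate_tags(genome, sites, "mitotic", small_cfg)
        assert t1 == t2

    def test_bad_condition(self, small_cfg):
        genome, seqs = make_genome(small_cfg)
        sites, _ = plant_sites(genome, seqs, small_cfg)
        with pytest.raises(ConfigError):
            simulate_tags(genome, sites, "interphase", small_cfg)


class TestNucleosomeFragments:
    def test_designs(self):
        frags = dict((d.name, (d, s)) for d, s in build_nucleosome_fragments())
        assert set(frags) == {"RBPJ-minus", "RBPJ-end", "RBPJ-dyad"}
        for _, (design, seq) in frags.items():
            assert len(seq) == 147
            assert design.length == 147
            assert seq[:40] == PHASING_SEQUENCE

    def test_end_motif_coordinates(self):
        # end-proximal placement: 1-based 127-134, leaving 13 nt distal
        _, seq = [x for x in build_nucleosome_fragments() if x[0].name == "RBPJ-end"][0]
        assert seq[126:134] == RBPJ_SITE_MOTIF
        assert 147 - 134 == 13
        matches = scan_iupac(seq, RBPJ)
        assert [m.start for m in matches] == [126]

    def test_dyad_motif_default_and_alternative(self):
        for start in (67, 57):
            _, seq = [x for x in build_nucleosome_fragments(dyad_motif_start=start)
                      if x[0].name == "RBPJ-dyad"][0]
            assert seq[start - 1: start + 7] == RBPJ_SITE_MOTIF
            assert [m.start for m in scan_iupac(seq, RBPJ)] == [start - 1]

    def test_minus_fragment_has_no_match(self):
        _, seq = [x for x in build_nucleosome_fragments() if x[0].name == "RBPJ-minus"][0]
        assert scan_iupac(seq, RBPJ, both_strands=True) == []

    def test_deterministic(self):
        a = build_nucleosome_fragments()
        b = build_nucleosome_fragments()
        assert [(d.name, s) for d, s in a] == [(d.name, s) for d, s in b]


class TestCellImage:
    def test_noise_free_levels(self):
        icfg = ImageConfig(background_level=10, cyto_signal=10, true_ratio=3,
                           noise_sigma=0)
        img = make_cell_image(icfg)
        assert img.pixels[img.background_mask].mean() == 10
        assert img.pixels[img.nucleocytoplasm_mask].mean() == 20
        assert img.pixels[img.chromatin_mask].mean() == 40

    def test_ratio_one_equalizes_compartments(self):
        icfg = ImageConfig(true_ratio=1.0, noise_sigma=0)
        img = make_cell_image(icfg)
        assert (img.pixels[img.chromatin_mask].mean()
                == img.pixels[img.nucleocytoplasm_mask].mean())

    def test_masks_disjoint_and_nonnegative(self):
        img = make_cell_image(ImageConfig(seed=9))
        img.validate()  # raises on overlap or negative pixels

    def test_negative_level_rejected(self):
        with pytest.raises(ConfigError):
            make_cell_image(ImageConfig(background_level=-1))
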