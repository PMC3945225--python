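"""IUPAC/PWM scanning, contingency tables, enrichment resampling, offsets."""

import numpy as np
import pytest

from mitobook import (MotifModel, motif_center_offset, motif_enrichment,
                      peak_motif_content, scan_iupac, scan_pwm)
from mitobook.errors import ConfigError, MitobookError
from mitobook.motifs import (IUPAC, genome_match_starts, read_jaspar_matrix,
                             reverse_complement)

RBPJ = MotifModel(name="RBPJ", consensus="TTCCCACR")


class TestScanIupac:
    def test_exact_site_plus_strand(self):
        m = scan_iupac("TTCCCACA", RBPJ)
        assert len(m) == 1 and m[0].start == 0 and m[0].strand == "+"

    def test_degenerate_position_matches_g(self):
        assert scan_iupac("TTCCCACG", RBPJ)[0].strand == "+"

    def test_minus_strand_in_plus_coordinates(self):
        # TGTGGGAA is the reverse complement of TTCCCACA
        m = scan_iupac("TGTGGGAA", RBPJ, both_strands=True)
        assert len(m) == 1 and m[0].strand == "-" and m[0].start == 0

    def test_poly_a_matches_nothing(self):
        assert scan_iupac("A" * 500, RBPJ) == []

    def test_n_never_matches(self):
        assert scan_iupac("TTCCCACN", RBPJ) == []

    def test_invalid_code_rejected(self):
        with pytest.raises(ConfigError):
            MotifModel(name="bad", consensus="TTQX")

    def test_overlapping_matches_reported(self):
        m = scan_iupac("TTCCCACATTCCCACA", RBPJ, both_strands=False)
        assert [x.start for x in m] == [0, 8]

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        classes = {c: set(IUPAC[c]) for c in IUPAC}
        consensus = "TTCCCACR"
        rc = reverse_complement(consensus)
        n_hits = 0
        for _ in range(500):
            seq = "".join(rng.choice(list("ACGT"), 500))
            # plant one instance to guarantee some positives
            i = int(rng.integers(0, 492))
            seq = seq[:i] + "TTCCCAC" + ("A" if rng.random() < 0.5 else "G") + seq[i + 8:]
            got = {(m.start, m.strand) for m in scan_iupac(seq, RBPJ)}
            naive = set()
            for pat, strand in ((consensus, "+"), (rc, "-")):
                for j in range(len(seq) - 7):
                    if all(seq[j + k] in classes[pat[k]] for k in range(8)):
                        naive.add((j, strand))
            assert got == naive
            n_hits += len(naive)
        assert n_hits >= 500  # planted instances were found

    def test_strand_symmetry(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), 300))
            fwd = {(m.start, m.strand) for m in scan_iupac(seq, RBPJ)}
            L = len(seq)
            flipped = {
                (L - 8 - s, {"+": "-", "-": "+"}[st])
                for m in scan_iupac(reverse_complement(seq), RBPJ)
                for s, st in [(m.start, m.strand)]
            }
            assert fwd == flipped


class TestScanPwm:
    def _pwm_for(self, word):
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        mat = np.full((4, len(word)), 0.0)
        for j, c in enumerate(word):
            mat[idx[c], j] = 1.0
        return MotifModel(name="p", pwm=mat)

    def test_finds_exact_word(self):
        m = self._pwm_for("ACGTAC")
        hits = scan_pwm("TTACGTACTT", m, both_strands=False)
        assert [h.start for h in hits] == [2]

    def test_minus_strand_hit(self):
        m = self._pwm_for("ACGGGT")
        hits = scan_pwm("TT" + "ACCCGT" + "TT", m)  # revcomp of ACGGGT
        assert len(hits) == 1 and hits[0].strand == "-"

    def test_threshold_excludes_mismatches(self):
        m = self._pwm_for("AAAAAAAA")
        assert scan_pwm("AAAATAAA", m, both_strands=False) == []

    def test_jaspar_round_trip(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(">CTCFlike\nA [ 1 9 0 ]\nC [ 8 0 1 ]\nG [ 1 1 9 ]\nT [ 0 0 0 ]\n")
        m = read_jaspar_matrix(p)
        assert m.name == "CTCFlike" and m.length == 3
        assert np.allclose(m.pwm.sum(axis=0), 1.0)


class TestPeakMotifContent:
    def test_empty(self):
        ctcf = MotifModel(name="CTCF-like", consensus="CCACTAGGGGGC")
        t = peak_motif_content({}, {"c": "A" * 1000}, RBPJ, ctcf)
        assert t.n_peaks == 0 and t.with_either == 0

    def test_constructed_counts(self):
        ctcf = MotifModel(name="CTCF-like", consensus="CCACTAGGGGGC")
        seq = ["A"] * 12_000
        centers = [500 + 1000 * i for i in range(10)]
        # 4 RBPJ only, 3 CTCF only, 1 both, 2 neither
        def put(center, word, off):
            start = center + off
            seq[start:start + len(word)] = list(word)
        for c in centers[:4]:
            put(c, "TTCCCACA", -4)
        for c in centers[4:7]:
            put(c, "CCACTAGGGGGC", 10)
        put(centers[7], "TTCCCACA", -40)
        put(centers[7], "CCACTAGGGGGC", 20)
        t = peak_motif_content({"c": centers}, {"c": "".join(seq)}, RBPJ, ctcf)
        assert (t.with_first, t.with_second, t.with_either, t.with_both) == (5, 4, 8, 1)

    def test_inclusion_exclusion_identity(self, sim_run):
        ctcf = MotifModel(name="CTCF-like", consensus="CCACTAGGGGGC")
        centers = sim_run["peaks"]["asynchronous"].centers_by_chrom()
        t = peak_motif_content(centers, sim_run["sequences"], RBPJ, ctcf)
        assert t.with_either == t.with_first + t.with_second - t.with_both
        t.validate()


class TestMotifEnrichment:
    def _flat_genome(self, n=200_000, seed=0):
        rng = np.random.default_rng(seed)
        return {"c": "".join(rng.choice(list("ACGT"), n))}

    def test_planted_everywhere_hits_resolution_floor(self):
        seqs = self._flat_genome()
        seq = list(seqs["c"])
        centers = [1000 + 1500 * i for i in range(30)]
        for c in centers:
            seq[c - 4: c + 4] = list("TTCCCACA")
        seqs = {"c": "".join(seq)}
        out = motif_enrichment({"c": centers}, seqs, RBPJ, n_resamples=199, seed=1)
        assert out["p_value"] == pytest.approx(1 / 200)
        assert out["observed_fraction"] == 1.0
        if out["null_mean_fraction"] > 0:
            assert out["fold"] >= 1 / out["null_mean_fraction"] * out["observed_fraction"] * 0.999

    def test_too_few_resamples_rejected(self):
        with pytest.raises(ConfigError):
            motif_enrichment({"c": [500]}, self._flat_genome(), RBPJ, n_resamples=10)

    def test_no_peaks_rejected(self):
        with pytest.raises(MitobookError):
            motif_enrichment({}, self._flat_genome(), RBPJ, n_resamples=100)

    def test_genome_match_index_agrees_with_scan(self):
        seqs = self._flat_genome(20_000, seed=2)
        starts = genome_match_starts(seqs, RBPJ)["c"]
        direct = sorted({m.start for m in scan_iupac(seqs["c"], RBPJ)})
        assert starts.tolist() == direct


class TestMotifCenterOffset:
    def test_match_at_center(self):
        m = scan_iupac("TTCCCACA", RBPJ)
        assert motif_center_offset(4.0, m) == 0.0

    def test_left_of_center(self):
        seq = "TTCCCACA" + "G" * 72
        m = scan_iupac(seq, RBPJ)
        assert motif_center_offset(44.0, m) == -40.0

    def test_no_match_is_none(self):
        assert motif_center_offset(100.0, []) is None

    def test_shifted_sites_show_motif_displacement(self):
        """On planted shifted sites the motif stays at the asynchronous
        center, so its offset from the mitotic center is larger by about the
        planted shift."""
        from mitobook import (SimConfig, call_peaks, make_genome, plant_sites,
                              simulate_tags)
        cfg = SimConfig(seed=21, chrom_lengths={"c": 400_000}, n_genes=0,
                        n_common=0, n_async_specific=0, n_mitotic_specific=0,
                        n_shifted=20, rbpj_motif_prob=1.0, ctcf_motif_prob=0.0,
                        shift_distance=150)
        genome, seqs = make_genome(cfg)
        sites, seqs = plant_sites(genome, seqs, cfg)
        ta = simulate_tags(genome, sites, "asynchronous", cfg)
        tm = simulate_tags(genome, sites, "mitotic", cfg)
        ti = simulate_tags(genome, sites, "input", cfg)
        pa = call_peaks(ta, ti, condition="asynchronous")
        pm = call_peaks(tm, ti, condition="mitotic")
        ok = 0
        for s in sites.sites:
            pa_c = min((p for p in pa.peaks if p.chrom == s.chrom),
                       key=lambda p: abs(p.center - s.position), default=None)
            pm_c = min((p for p in pm.peaks if p.chrom == s.chrom),
                       key=lambda p: abs(p.center - s.position - 150), default=None)
            if pa_c is None or pm_c is None:
                continue
            win = seqs[s.chrom][s.position - 300: s.position + 300]
            matches = scan_iupac(win, RBPJ, offset=s.position - 300,
                                 sequence_id=s.chrom)
            off_a = motif_center_offset(pa_c.center, matches)
            off_m = motif_center_offset(pm_c.center, matches)
            if off_a is None or off_m is None:
                continue
            if abs(abs(off_m) - abs(off_a) - 150) <= 25:
                ok += 1
        assert ok >= 0.8 * len(sites.sites)
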