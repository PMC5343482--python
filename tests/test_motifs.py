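"""PWM construction, scanning, sensitivity classes and GC-corrected enrichment."""

import numpy as np
import pandas as pd
import pytest

from enhancerscape.motifs import (
    PWMotif,
    classify_enhancer_sensitivity,
    gc_corrected_enrichment,
    match_count_threshold,
    motif_similarity,
    pwm_from_sites,
    read_meme,
    scan_genome,
    write_meme,
)
from enhancerscape.synthetic import (
    SyntheticGenomeSpec,
    generate_motif_landscape,
    plant_sites,
)


def _random_pwm(rng, length=8, motif_id="m"):
    mat = rng.dirichlet([0.4] * 4, size=length)
    return PWMotif(id=motif_id, matrix=mat)


class TestPwmFromSites:
    def test_hand_counted_frequencies(self):
        pwm = pwm_from_sites(["AC", "AC", "AT", "AG"])
        # column 2: C twice, T once, G once; with 0.5 pseudo per cell
        assert pwm.matrix[1, 1] == pytest.approx((2 + 0.5) / 6)
        assert pwm.matrix[1, 2] == pytest.approx((1 + 0.5) / 6)
        assert pwm.matrix[1, 3] == pytest.approx((1 + 0.5) / 6)
        assert pwm.matrix[0, 0] == pytest.approx((4 + 0.5) / 6)

    def test_gc_content_of_pure_gc_sites(self):
        pwm = pwm_from_sites(["GG", "GG"])
        # pseudo-frequency keeps gc below 1: P(G)=(2+.5)/(2+2), P(C)=.5/4
        assert pwm.gc_content == pytest.approx((2.5 + 0.5) / 4, abs=1e-9)
        assert pwm.consensus() == "GG"

    def test_uniform_sites_gc_half(self):
        rng = np.random.default_rng(0)
        sites = ["".join(rng.choice(list("ACGT"), 10)) for _ in range(2000)]
        assert pwm_from_sites(sites).gc_content == pytest.approx(0.5,
                                                                 abs=0.02)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pwm_from_sites(["AC", "ACG"])

    def test_rows_must_sum_to_one(self):
        with pytest.raises(ValueError):
            PWMotif(id="bad", matrix=np.array([[0.5, 0.5, 0.5, 0.5]]))


class TestScanGenome:
    def test_planted_consensus_recovered(self):
        rng = np.random.default_rng(1)
        pwm = pwm_from_sites(["ACGTACGTAC"] * 20, motif_id="planted")
        seq = list(rng.choice(list("ACGT"), 5000))
        planted_at = np.arange(10) * 450 + 100
        for p in planted_at:
            seq[p:p + 10] = list("ACGTACGTAC")
        matches = scan_genome(pwm, {"chr1": "".join(seq)},
                              pvalue_threshold=1e-4)
        plus = set(matches[matches["strand"] == 1]["pos"])
        assert set(planted_at) <= plus
        assert len(matches) >= 10

    def test_reverse_complement_genome_same_match_count(self):
        rng = np.random.default_rng(2)
        pwm = _random_pwm(rng)
        seq = "".join(rng.choice(list("ACGT"), 3000))
        rc = seq[::-1].translate(str.maketrans("ACGT", "TGCA"))
        bg = np.full(4, 0.25)
        m1 = scan_genome(pwm, {"chr1": seq}, 1e-3, background=bg)
        m2 = scan_genome(pwm, {"chr1": rc}, 1e-3, background=bg)
        assert len(m1) == len(m2)

    def test_consensus_pvalue_closed_form(self):
        # all-G PWM of length k: P(consensus score) = 0.25^k under uniform bg
        for k in (4, 6):
            mat = np.tile([0.0, 0.0, 1.0, 0.0], (k, 1))
            pwm = PWMotif(id="g", matrix=mat)
            matches = scan_genome(pwm, {"chr1": "G" * (k + 5)},
                                  pvalue_threshold=1.0,
                                  background=np.full(4, 0.25))
            top = matches[matches["strand"] == 1].sort_values("p").iloc[0]
            assert top["p"] == pytest.approx(0.25 ** k, rel=1e-9)

    def test_pvalues_super_uniform_under_background(self):
        rng = np.random.default_rng(3)
        pwm = _random_pwm(rng, length=6)
        seq = "".join(rng.choice(list("ACGT"), 20_000))
        matches = scan_genome(pwm, {"chr1": seq}, pvalue_threshold=1.0,
                              background=np.full(4, 0.25))
        ps = matches[matches["strand"] == 1]["p"].to_numpy()
        n = len(ps)
        for alpha in (0.01, 0.05, 0.2):
            frac = (ps <= alpha).mean()
            # super-uniform: P(p <= a) <= a, up to binomial noise
            assert frac <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / n)

    def test_pwm_longer_than_sequence_empty(self):
        rng = np.random.default_rng(4)
        pwm = _random_pwm(rng, length=8)
        assert len(scan_genome(pwm, {"chr1": "ACGT"}, 1.0)) == 0


class TestMatchCountThreshold:
    def _cands(self, ps):
        return pd.DataFrame({"chrom": "chr1", "pos": range(len(ps)),
                             "strand": 1, "score": 0.0, "p": ps})

    def test_top_n_kept(self):
        out = match_count_threshold(
            self._cands([0.5, 0.1, 0.3, 0.2, 0.9, 0.4, 0.6, 0.7, 0.8, 0.05]),
            target_n=3)
        assert sorted(out["p"]) == [0.05, 0.1, 0.2]

    def test_target_exceeding_size_keeps_all(self):
        cands = self._cands([0.1, 0.2])
        assert len(match_count_threshold(cands, 10)) == 2

    def test_ties_at_cutoff_all_dropped(self):
        out = match_count_threshold(
            self._cands([0.1, 0.2, 0.3, 0.3, 0.3]), target_n=3)
        assert sorted(out["p"]) == [0.1, 0.2]

    def test_zero_target_empty(self):
        assert len(match_count_threshold(self._cands([0.1]), 0)) == 0


class TestSensitivityClasses:
    @pytest.mark.parametrize("fcs,expected", [
        ((0.4, 0.2), "neither"),    # mean reduction ~3.54x < 4x
        ((0.2, 0.2), "sensitive"),  # each >2x, mean 5x
        ((0.8, 1.2), "insensitive"),
        ((0.4, 0.6), "neither"),
        ((3.0, 3.0), "neither"),
    ])
    def test_mef_rules(self, fcs, expected):
        assert classify_enhancer_sensitivity(fcs, mode="mef") == expected

    @pytest.mark.parametrize("fc,expected", [
        (1.2, "insensitive"), (0.3, "sensitive"), (0.55, "neither"),
    ])
    def test_human_rules(self, fc, expected):
        assert classify_enhancer_sensitivity([fc], mode="human") == expected

    def test_human_gain_direction(self):
        assert classify_enhancer_sensitivity([3.0], mode="human",
                                             direction="gain") == "sensitive"

    def test_classes_mutually_exclusive_property(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            fcs = np.exp(rng.normal(0, 1, size=2))
            label = classify_enhancer_sensitivity(fcs, mode="mef")
            assert label in {"sensitive", "insensitive", "neither"}
        with pytest.raises(ValueError):
            classify_enhancer_sensitivity((0.5, -1.0), mode="mef")


def _landscape(seed, strength, plant=None, n_pwms=30):
    rng = np.random.default_rng(seed)
    pwms = {}
    for i in range(n_pwms):
        gc = 0.2 + 0.6 * i / (n_pwms - 1)
        p_gc, p_at = gc / 2, (1 - gc) / 2
        mat = np.tile([p_at, p_gc, p_gc, p_at], (8, 1))
        mat += rng.uniform(0, 0.01, size=mat.shape)
        mat /= mat.sum(axis=1, keepdims=True)
        pwms[f"m{i:02d}"] = PWMotif(id=f"m{i:02d}", matrix=mat)
    spec = SyntheticGenomeSpec(n_chroms=2, chrom_length=2_000_000,
                               n_promoter_sites=20, n_distal_sites=300,
                               fraction_sensitive=0.5, seed=seed)
    gt = plant_sites(spec)
    gc_track, maps = generate_motif_landscape(
        gt, pwms, gc_confound_strength=strength, base_rate=3.0,
        plant=plant, seed=seed + 1)
    sens = gc_track[gc_track["sensitive"]][["chrom", "start", "end"]]
    insens = gc_track[~gc_track["sensitive"]][["chrom", "start", "end"]]
    return pwms, maps, sens, insens


class TestGcCorrectedEnrichment:
    def test_confounded_null_corrected_to_unity(self):
        pwms, maps, sens, insens = _landscape(seed=0, strength=1.0)
        out = gc_corrected_enrichment(maps, pwms, sens, insens)
        assert np.median(out["enrichment"]) == pytest.approx(1.0, abs=0.15)
        # without correction the extreme-GC motifs would deviate widely
        raw = (out["observed_sensitive"] + 1) / (out["observed_insensitive"]
                                                 + 1)
        assert raw.max() / raw.min() > out["enrichment"].max() / \
            out["enrichment"].min()

    def test_planted_motif_recovered_as_top(self):
        pwms, maps, sens, insens = _landscape(seed=1, strength=1.0,
                                              plant={"m15": 3.0})
        out = gc_corrected_enrichment(maps, pwms, sens, insens)
        top = out.sort_values("enrichment", ascending=False).iloc[0]
        assert top["motif"] == "m15"
        assert top["enrichment"] == pytest.approx(3.0, rel=0.35)

    def test_scale_invariance_in_zero_pseudocount_limit(self):
        pwms, maps, sens, insens = _landscape(seed=2, strength=0.5)
        out1 = gc_corrected_enrichment(maps, pwms, sens, insens,
                                       pseudocount=0.0)
        doubled = {m: pd.concat([df, df], ignore_index=True)
                   for m, df in maps.items()}
        out2 = gc_corrected_enrichment(doubled, pwms, sens, insens,
                                       pseudocount=0.0)
        np.testing.assert_allclose(out1["enrichment"], out2["enrichment"],
                                   rtol=1e-9)

    def test_order_invariance(self):
        pwms, maps, sens, insens = _landscape(seed=3, strength=0.5)
        out1 = gc_corrected_enrichment(maps, pwms, sens, insens)
        shuffled = dict(reversed(list(maps.items())))
        out2 = gc_corrected_enrichment(shuffled, pwms, sens, insens)
        pd.testing.assert_frame_equal(out1, out2)

    def test_all_zero_counts_rejected(self):
        pwms, maps, sens, insens = _landscape(seed=4, strength=0.0)
        empty = {m: df.iloc[0:0] for m, df in maps.items()}
        with pytest.raises(ValueError):
            gc_corrected_enrichment(empty, pwms, sens, insens)


class TestMotifSimilarity:
    def test_identical_pwms(self):
        rng = np.random.default_rng(6)
        pwm = _random_pwm(rng, length=10)
        assert motif_similarity(pwm, pwm) == pytest.approx(1.0)

    def test_reverse_complement_found_by_orientation_search(self):
        rng = np.random.default_rng(7)
        pwm = _random_pwm(rng, length=10)
        assert motif_similarity(pwm, pwm.reverse_complement()) == \
            pytest.approx(1.0)

    def test_column_shuffle_breaks_similarity(self):
        rng = np.random.default_rng(8)
        pwm = _random_pwm(rng, length=10)
        below = 0
        for _ in range(100):
            perm = rng.permutation(10)
            while (perm == np.arange(10)).all():
                perm = rng.permutation(10)
            shuffled = PWMotif(id="s", matrix=pwm.matrix[perm])
            below += motif_similarity(pwm, shuffled) < 0.85
        assert below >= 95


def test_meme_roundtrip(tmp_path):
    rng = np.random.default_rng(9)
    pwms = {f"m{i}": _random_pwm(rng, length=6, motif_id=f"m{i}")
            for i in range(3)}
    path = tmp_path / "motifs.meme"
    write_meme(pwms, path)
    back = read_meme(path)
    assert set(back) == set(pwms)
    for name in pwms:
        np.testing.assert_allclose(back[name].matrix, pwms[name].matrix,
                                   atol=1e-5)
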