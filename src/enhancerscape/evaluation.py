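"""Property-based evaluation experiments for the pipeline.

Each function runs a self-contained experiment on synthetic data and returns
plain metrics: normalization-factor recovery, classification and stitching
agreement with brute-force oracles, sensitivity-rule checks, motif-enrichment
null calibration and plant/recover, segmentation recovery, GO-oracle
agreement, and the end-to-end demonstration.  All randomness flows from the
``seed`` argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from enhancerscape import synthetic
from enhancerscape.catalog import (
    call_super_enhancers,
    classify_elements,
    segment_transcription,
    stitch_enhancers,
)
from enhancerscape.intervals import interval_distance
from enhancerscape.linkage import go_enrichment, select_sensitive_enhancers
from enhancerscape.motifs import (
    PWMotif,
    classify_enhancer_sensitivity,
    gc_corrected_enrichment,
)
from enhancerscape.pipeline import run_synthetic_demo
from enhancerscape.signal import RegionSignalMatrix, _log2_mode, fit_ip_efficiency
from enhancerscape.taglib import TagLibrary


def _sub_seed(seed: int, offset: int) -> int:
    return (int(seed) * 9973 + offset) % (2 ** 31)


# ---------------------------------------------------------------------------
# 1. IP-efficiency recovery
# ---------------------------------------------------------------------------

def ip_efficiency_recovery(seed: int, n_promoters: int = 2000,
                           n_distal: int = 4000,
                           fraction_sensitive: float = 0.3,
                           sensitive_fold: float = 0.25) -> dict:
    """Six-sample design; fit promoter-mode factors; compare to model targets.

    Per-sample IP efficiencies are drawn uniformly from [0.6, 1.4]; the
    truth-implied target per sample is the factor that zeroes the mode of
    the model distribution of promoter log2 fold-changes (computed by exact
    Monte-Carlo from the generator's Poisson rate model).
    """
    spec = synthetic.SyntheticGenomeSpec(
        n_chroms=4, chrom_length=15_500_000, n_promoter_sites=n_promoters,
        n_distal_sites=n_distal, fraction_sensitive=fraction_sensitive,
        sensitive_fold_change=sensitive_fold, seed=_sub_seed(seed, 1))
    gt = synthetic.plant_sites(spec)
    rng = np.random.default_rng(_sub_seed(seed, 2))
    design = [(c, r) for c in spec.conditions for r in ("I", "II")]
    effs = {f"{c}_{r}": float(rng.uniform(0.6, 1.4)) for c, r in design}
    libs = {}
    for c, r in design:
        sid = f"{c}_{r}"
        libs[sid] = synthetic.generate_tag_library(
            spec, c, "IP", ground_truth=gt, ip_efficiency=effs[sid],
            seed=_sub_seed(seed, 10 + design.index((c, r))))
    regions = gt.sites[["chrom", "start", "end"]]
    matrix = RegionSignalMatrix.from_libraries(libs, regions)
    promoter_rows = regions.index[gt.sites["site_class"] == "promoter"]
    reference = "WT_I"
    fitted = fit_ip_efficiency(matrix, promoter_rows, reference=reference)
    errors = {}
    post_modes = {}
    for sid in libs:
        if sid == reference:
            continue
        cond = sid.rsplit("_", 1)[0]
        target = synthetic.mode_normalization_target(
            spec, gt, cond, eff_ref=effs[reference], eff_sample=effs[sid],
            seed=_sub_seed(seed, 99))
        errors[sid] = fitted.factors[sid] / target - 1.0
        corrected = np.log2(fitted.factors[sid]
                            * matrix.values.loc[promoter_rows, sid]
                            / matrix.values.loc[promoter_rows, reference])
        post_modes[sid] = _log2_mode(corrected.to_numpy())
    return {
        "max_factor_error_pct": 100.0 * max(abs(e) for e in errors.values()),
        "max_post_correction_mode": max(abs(m) for m in post_modes.values()),
        "factor_errors": errors,
        "fitted": fitted.factors,
        "true_efficiencies": effs,
        "n_promoters": n_promoters,
    }


# ---------------------------------------------------------------------------
# 2. Classification oracle
# ---------------------------------------------------------------------------

def _brute_force_classify(region, me3_list, tss_list) -> str:
    """Direct application of the distance rules to one region."""
    overlaps_me3 = any(region[0] < e and s < region[1] for s, e in me3_list)
    overlaps_tss = any(region[0] <= p < region[1] for p in tss_list)
    d_me3 = min((interval_distance(region[0], region[1], s, e)
                 for s, e in me3_list), default=np.inf)
    d_tss = min((interval_distance(region[0], region[1], p, p + 1)
                 for p in tss_list), default=np.inf)
    if overlaps_tss and overlaps_me3:
        return "promoter"
    if d_me3 > 1000 and d_tss > 2000:
        return "enhancer"
    return "ambiguous"


def classification_agreement(seed: int, n_layouts: int = 1000) -> dict:
    """Random region/TSS/RoE layouts; fraction agreeing with brute force."""
    rng = np.random.default_rng(_sub_seed(seed, 3))
    agree = 0
    total = 0
    for _ in range(n_layouts):
        genome = 100_000
        n_reg = rng.integers(1, 8)
        n_me3 = rng.integers(0, 6)
        n_tss = rng.integers(0, 6)
        regions = pd.DataFrame({
            "chrom": "chr1",
            "start": rng.integers(0, genome - 3000, n_reg)})
        regions["end"] = regions["start"] + rng.integers(200, 3000, n_reg)
        me3 = pd.DataFrame({
            "chrom": "chr1", "start": rng.integers(0, genome - 2000, n_me3)})
        me3["end"] = me3["start"] + rng.integers(200, 2000, n_me3)
        tss_pos = rng.integers(0, genome, n_tss)
        tss = pd.DataFrame({"chrom": "chr1", "pos": tss_pos, "strand": "+",
                            "gene_id": [f"g{i}" for i in range(n_tss)]})
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            out = classify_elements(regions, me3, tss)
        me3_list = list(zip(me3["start"], me3["end"]))
        tss_list = list(tss_pos)
        for i, row in out.iterrows():
            expected = _brute_force_classify((row["start"], row["end"]),
                                             me3_list, tss_list)
            agree += row["cre_class"] == expected
            total += 1
    return {"agreement": agree / total, "n_regions": total}


# ---------------------------------------------------------------------------
# 3. Stitching / super-enhancer oracle
# ---------------------------------------------------------------------------

def stitching_agreement(seed: int, n_sets: int = 500) -> dict:
    """stitch_enhancers vs union-find single linkage on random RoE sets."""
    rng = np.random.default_rng(_sub_seed(seed, 4))
    matches = 0
    empty = pd.DataFrame(columns=["chrom", "start", "end"])
    for _ in range(n_sets):
        n = int(rng.integers(2, 30))
        starts = np.sort(rng.integers(0, 400_000, n))
        roes = pd.DataFrame({"chrom": "chr1", "start": starts,
                             "end": starts + rng.integers(100, 3000, n)})
        got = sorted((r.start, r.end)
                     for r in stitch_enhancers(roes, empty))
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        s_arr, e_arr = roes["start"].to_numpy(), roes["end"].to_numpy()
        for i in range(n):
            for j in range(i + 1, n):
                if interval_distance(s_arr[i], e_arr[i],
                                     s_arr[j], e_arr[j]) <= 12_500:
                    parent[find(i)] = find(j)
        clusters: dict[int, list[int]] = {}
        for i in range(n):
            clusters.setdefault(find(i), []).append(i)
        expected = sorted((int(s_arr[c].min()), int(e_arr[c].max()))
                          for c in clusters.values())
        matches += got == expected
    toy = _super_enhancer_toy(seed)
    return {"agreement": matches / n_sets, **toy}


def _super_enhancer_toy(seed: int) -> dict:
    """99 regions at signal ~1 plus one at ~1000: exactly one super."""
    width = 1000
    tags, inp = [], []
    signals = [10] * 99 + [10_000]
    for i, n in enumerate(signals):
        start = i * 20_000
        for p in np.linspace(start, start + width - 1, n).astype(int):
            tags.append(("chr1", int(p), 1))
        inp.append(("chr1", start + width // 2, 1))
    lens = {"chr1": 20_000 * 100 + width}
    ip_lib = TagLibrary.from_arrays(
        np.array([t[0] for t in tags]), [t[1] for t in tags],
        [t[2] for t in tags], chrom_lengths=lens)
    in_lib = TagLibrary.from_arrays(
        np.array([t[0] for t in inp]), [t[1] for t in inp],
        [t[2] for t in inp], chrom_lengths=lens)
    roes = pd.DataFrame({"chrom": "chr1",
                         "start": [i * 20_000 for i in range(100)]})
    roes["end"] = roes["start"] + width
    stitched = stitch_enhancers(roes,
                                pd.DataFrame(columns=["chrom", "start", "end"]))
    out = call_super_enhancers(stitched, ip_lib, in_lib)
    supers = [r for r in out if r.is_super]
    return {"toy_n_super": len(supers),
            "toy_super_is_outlier": len(supers) == 1
            and supers[0].start == 99 * 20_000}


# ---------------------------------------------------------------------------
# 4. Sensitivity rules
# ---------------------------------------------------------------------------

def sensitivity_rule_checks() -> dict:
    """Hand-computed labels for the worked replicate pairs."""
    checks = [
        select_sensitive_enhancers(0.6, 0.7) is False,
        select_sensitive_enhancers(0.4, 0.5) is True,
        classify_enhancer_sensitivity((0.4, 0.2), mode="mef") == "neither",
        classify_enhancer_sensitivity((0.2, 0.2), mode="mef") == "sensitive",
        classify_enhancer_sensitivity([1.2], mode="human") == "insensitive",
    ]
    return {"n_correct": sum(checks), "n_checks": len(checks)}


# ---------------------------------------------------------------------------
# 5. GC-lowess motif null and recovery
# ---------------------------------------------------------------------------

def _gc_graded_pwms(rng, n_pwms: int = 40) -> dict[str, PWMotif]:
    pwms = {}
    for i in range(n_pwms):
        gc = 0.2 + 0.6 * i / (n_pwms - 1)
        p_gc, p_at = gc / 2, (1 - gc) / 2
        mat = np.tile([p_at, p_gc, p_gc, p_at], (8, 1))
        mat += rng.uniform(0, 0.01, size=mat.shape)
        mat /= mat.sum(axis=1, keepdims=True)
        pwms[f"m{i:02d}"] = PWMotif(id=f"m{i:02d}", matrix=mat)
    return pwms


def _landscape_run(seed: int, plant: dict | None, n_pwms: int = 40):
    rng = np.random.default_rng(seed)
    pwms = _gc_graded_pwms(rng, n_pwms=n_pwms)
    spec = synthetic.SyntheticGenomeSpec(
        n_chroms=2, chrom_length=2_000_000, n_promoter_sites=20,
        n_distal_sites=300, fraction_sensitive=0.5, seed=seed)
    gt = synthetic.plant_sites(spec)
    gc_track, maps = synthetic.generate_motif_landscape(
        gt, pwms, gc_confound_strength=1.0, base_rate=3.0, plant=plant,
        seed=seed + 1)
    sens = gc_track[gc_track["sensitive"]][["chrom", "start", "end"]]
    insens = gc_track[~gc_track["sensitive"]][["chrom", "start", "end"]]
    return gc_corrected_enrichment(maps, pwms, sens, insens)


def motif_null_calibration(seed: int) -> dict:
    """GC-confounded null: fraction of motifs inside the Poisson envelope.

    Both counts are Poisson, so the envelope for the ratio conditions on the
    total: given n = observed_sensitive + observed_insensitive, the sensitive
    count is Binomial(n, p) with p = expected / (expected + insensitive)
    under the GC-corrected null; a motif is inside the envelope when its
    sensitive count falls in that central 95% interval.
    """
    out = _landscape_run(_sub_seed(seed, 5), plant=None, n_pwms=80)
    n = (out["observed_sensitive"] + out["observed_insensitive"]).to_numpy()
    p = (out["expected_sensitive"]
         / (out["expected_sensitive"] + out["observed_insensitive"])).to_numpy()
    lo = stats.binom.ppf(0.025, n, p)
    hi = stats.binom.ppf(0.975, n, p)
    obs = out["observed_sensitive"].to_numpy()
    inside = ((obs >= lo) & (obs <= hi)).mean()
    return {"fraction_in_envelope": float(inside), "n_motifs": len(out)}


def motif_plant_recovery(seed: int, n_runs: int = 100) -> dict:
    """A motif planted 3x denser in sensitive regions must rank first."""
    top_hits = 0
    for r in range(n_runs):
        out = _landscape_run(_sub_seed(seed, 1000 + r), plant={"m20": 3.0})
        top = out.sort_values("enrichment", ascending=False).iloc[0]
        top_hits += top["motif"] == "m20"
    return {"top_rank_rate": top_hits / n_runs, "n_runs": n_runs}


# ---------------------------------------------------------------------------
# 6. Hypergeometric / BH oracle
# ---------------------------------------------------------------------------

def go_oracle_agreement(seed: int, n_instances: int = 50,
                        n_draws: int = 4000) -> dict:
    """Exact enumeration example plus Monte-Carlo agreement within 3 SE."""
    universe = [f"g{i}" for i in range(10)]
    go_map = pd.DataFrame({"term": "T", "gene": universe[:5]})
    example = go_enrichment(universe[:3] + [universe[9]], universe, go_map)
    example_ok = abs(example["p"].iloc[0] - 55 / 210) < 1e-12

    rng = np.random.default_rng(_sub_seed(seed, 6))
    within = 0
    for _ in range(n_instances):
        N = int(rng.integers(8, 30))
        K = int(rng.integers(1, N))
        n = int(rng.integers(1, N))
        uni = [f"g{i}" for i in range(N)]
        gmap = pd.DataFrame({"term": "T", "gene": uni[:K]})
        selected = list(rng.choice(uni, size=n, replace=False))
        k = len(set(selected) & set(uni[:K]))
        p = go_enrichment(selected, uni, gmap)["p"].iloc[0]
        draws = rng.hypergeometric(K, N - K, n, size=n_draws)
        mc = (draws >= k).mean()
        se = np.sqrt(max(mc * (1 - mc), 1e-9) / n_draws)
        within += abs(p - mc) <= 3 * se + 1e-9
    from statsmodels.stats.multitest import multipletests
    bh_ok = np.allclose(multipletests([0.01, 0.02, 0.03, 0.04],
                                      method="fdr_bh")[1], 0.04)
    return {"example_exact": bool(example_ok),
            "mc_agreement": within / n_instances,
            "bh_arithmetic_ok": bool(bh_ok)}


# ---------------------------------------------------------------------------
# 7. Segmentation recovery
# ---------------------------------------------------------------------------

def segmentation_recovery(seed: int, n_seeds: int = 100) -> dict:
    """Homogeneous-signal and step-signal recovery rates over seeds."""
    ones = 0
    hits = 0
    for r in range(n_seeds):
        rng = np.random.default_rng(_sub_seed(seed, 2000 + r))
        ones += len(segment_transcription(rng.poisson(5, 1000),
                                          rng.poisson(5, 1000))) == 1
        rng = np.random.default_rng(_sub_seed(seed, 3000 + r))
        case = np.concatenate([rng.poisson(5, 500), rng.poisson(50, 500)])
        segs = segment_transcription(case, rng.poisson(5, 1000))
        hits += any(abs(s.start_bin - 500) <= 3 for s in segs[1:])
    return {"homogeneous_single_segment_rate": ones / n_seeds,
            "step_breakpoint_rate": hits / n_seeds, "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# 8. End-to-end synthetic run
# ---------------------------------------------------------------------------

def end_to_end_metrics(seed: int) -> dict:
    """Default demo genome; precision/recall of sensitive-enhancer calls."""
    out = run_synthetic_demo(seed=seed)
    s = out["summary"]
    return {"precision": s["precision"], "recall": s["recall"],
            "n_promoters": s["n_promoters"], "n_enhancers": s["n_enhancers"],
            "n_called_sensitive": s["n_called_sensitive"],
            "n_planted_sensitive": s["n_planted_sensitive"]}
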