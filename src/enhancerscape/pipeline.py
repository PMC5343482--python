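"""End-to-end pipeline: preprocessing through catalogue, normalization,
sensitivity calls, motifs, expression linkage and GO.

The stage order follows the analysis design: prep -> RoE calling ->
reproducible unions -> element classification -> signal quantification ->
IP-efficiency normalization -> super-enhancers / transcribed regions ->
sensitive-enhancer selection -> motif enrichment -> gene linkage -> GO.
Stage outputs are pure functions of (config, manifest, input files); every
run serializes its configuration for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from enhancerscape import synthetic
from enhancerscape.catalog import (
    active_tss,
    call_super_enhancers,
    classify_elements,
    segment_transcription,
    stitch_enhancers,
    stitched_to_frame,
    transcribed_to_frame,
)
from enhancerscape.enrichment import call_roe, reproducible_roe_union
from enhancerscape.linkage import (
    expression_change,
    go_enrichment,
    link_enhancers,
    select_downregulated_genes,
    select_sensitive_enhancers,
)
from enhancerscape.preprocess import build_blacklist, merge_blacklists, preprocess_library
from enhancerscape.signal import RegionSignalMatrix, fit_ip_efficiency, fold_change
from enhancerscape.taglib import TagLibrary, read_tags_tsv

logger = logging.getLogger("enhancerscape")


@dataclass
class PipelineConfig:
    """All numeric pipeline constants, with their standard defaults."""

    bin_size: int = 1000
    k_sd: float = 3.0
    window: int = 500
    z_thr: float = 4.0
    min_samples: int = 2
    promoter_h3k4me3_max_dist: int = 1000
    enhancer_tss_min_dist: int = 2000
    stitch_gap: int = 12500
    segment_lambda: float = 1.0
    transcribed_min_log2: float = 0.1
    smoothing_sigma: float = 100.0
    signal_pseudocount: float = 1.0
    expression_pseudocount: float = 5.0
    link_min_dist: int = 5000
    link_max_dist: int = 100000
    peak_match_dist: int = 90
    idr_threshold: float = 0.01
    complexity_threshold: float = 0.90
    sensitivity_each_fold: float = 2.0
    sensitivity_mean_fold: float = 4.0
    insensitive_mean_fold: float = 1.5
    go_fdr: float = 0.05
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class Sample:
    """One manifest entry; ``library`` may be preloaded or read from path."""

    id: str
    mark: str
    condition: str
    replicate: str
    path: str | None = None
    fragment_size: int = 160
    library: TagLibrary | None = None

    def load(self) -> TagLibrary:
        if self.library is None:
            if self.path is None:
                raise ValueError(f"sample {self.id}: no library or path")
            self.library = read_tags_tsv(self.path,
                                         fragment_size=self.fragment_size)
        return self.library


@dataclass
class SampleManifest:
    samples: list[Sample]

    def validate(self) -> None:
        """Every IP sample must have a matching input (condition, replicate)."""
        inputs = {(s.condition, s.replicate) for s in self.samples
                  if s.mark == "input"}
        for s in self.samples:
            if s.mark != "input" and (s.condition, s.replicate) not in inputs:
                raise ValueError(
                    f"IP sample {s.id!r} ({s.mark}, {s.condition}, "
                    f"rep {s.replicate}) has no matching input sample")

    def by_mark(self, mark: str) -> list[Sample]:
        return [s for s in self.samples if s.mark == mark]

    def matched_input(self, sample: Sample) -> Sample:
        for s in self.samples:
            if s.mark == "input" and s.condition == sample.condition \
                    and s.replicate == sample.replicate:
                return s
        raise KeyError(f"no input for {sample.id}")


@dataclass
class PipelineResult:
    config: PipelineConfig
    blacklist_bp: int
    roe_by_sample: dict
    h3k27ac_union: pd.DataFrame
    elements: pd.DataFrame
    signal_matrix: RegionSignalMatrix
    factors: object
    sensitive_calls: dict
    stitched: pd.DataFrame
    transcribed: pd.DataFrame
    links: pd.DataFrame | None = None
    go_results: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig, manifest: SampleManifest,
                 tss_table: pd.DataFrame,
                 expression_table: pd.DataFrame | None = None,
                 go_map: pd.DataFrame | None = None,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Execute all stages on the samples in ``manifest``.

    H3K27ac samples drive the element catalogue; H3K4me3 samples define
    active TSSs.  If an expression table (cuffdiff-shaped) and a GO map are
    supplied, the expression-linkage and GO stages run as well.
    """
    manifest.validate()
    logger.info("config %s", config.config_hash())

    # --- prep: blacklist from inputs, shift+mask all samples --------------
    input_samples = manifest.by_mark("input")
    blacklists = [build_blacklist(s.load(), bin_size=config.bin_size,
                                  k_sd=config.k_sd, source_sample=s.id)
                  for s in input_samples]
    blacklist = merge_blacklists(blacklists)
    logger.info("blacklist: %d bp", blacklist.total_bp())
    prepped: dict[str, TagLibrary] = {}
    for s in manifest.samples:
        res = preprocess_library(
            s.load(), blacklist,
            complexity_threshold=config.complexity_threshold)
        prepped[s.id] = res.library
        logger.info("prep %s: complexity %.3f dedup=%s", s.id,
                    res.complexity, res.deduplicated)

    # --- RoE calling ------------------------------------------------------
    roe_by_sample: dict[str, pd.DataFrame] = {}
    for mark in ("H3K27ac", "H3K4me3"):
        for s in manifest.by_mark(mark):
            inp = manifest.matched_input(s)
            roe_by_sample[s.id] = call_roe(
                prepped[s.id], prepped[inp.id],
                window=config.window, z_thr=config.z_thr)
            logger.info("RoE %s: %d regions", s.id, len(roe_by_sample[s.id]))

    k27_samples = manifest.by_mark("H3K27ac")
    k27_union = reproducible_roe_union(
        [roe_by_sample[s.id] for s in k27_samples],
        min_samples=min(config.min_samples, len(k27_samples)))

    # H3K4me3 calls from single samples carry the window z-test's residual
    # false positives; requiring support from >= 2 samples (as for H3K27ac)
    # removes them while keeping every consistently marked promoter
    me3_sets = [roe_by_sample[s.id] for s in manifest.by_mark("H3K4me3")]
    me3_union = reproducible_roe_union(
        me3_sets, min_samples=min(config.min_samples, len(me3_sets))) \
        if me3_sets else pd.DataFrame(columns=["chrom", "start", "end"])

    # --- catalogue --------------------------------------------------------
    act_tss = active_tss(tss_table, me3_union) if me3_sets else tss_table.iloc[0:0]
    elements = classify_elements(
        k27_union, me3_union, act_tss,
        h3k4me3_max_dist=config.promoter_h3k4me3_max_dist,
        tss_min_dist=config.enhancer_tss_min_dist)
    logger.info("elements: %s", elements["cre_class"].value_counts().to_dict())

    # --- signal + normalization ------------------------------------------
    k27_libs = {s.id: prepped[s.id] for s in k27_samples}
    matrix = RegionSignalMatrix.from_libraries(
        k27_libs, elements, pseudocount=config.signal_pseudocount)
    promoter_rows = elements.index[elements["cre_class"] == "promoter"]
    reference = _pick_reference(k27_samples)
    factors = fit_ip_efficiency(matrix, promoter_rows, reference=reference)
    logger.info("factors: %s", {k: round(v, 3)
                                for k, v in factors.factors.items()})

    # --- sensitive enhancers per mutant ----------------------------------
    enh_rows = elements.index[elements["cre_class"] == "enhancer"]
    sensitive_calls: dict[str, np.ndarray] = {}
    conditions = sorted({s.condition for s in k27_samples})
    wt_by_rep = {s.replicate: s for s in k27_samples if s.condition == "WT"}
    fold_changes: dict[tuple, np.ndarray] = {}
    for cond in conditions:
        if cond == "WT":
            continue
        reps = sorted(s.replicate for s in k27_samples if s.condition == cond)
        per_rep = []
        for rep in reps:
            mut = next(s for s in k27_samples
                       if s.condition == cond and s.replicate == rep)
            wt = wt_by_rep[rep]
            fc = fold_change(matrix.values.loc[enh_rows, mut.id],
                             matrix.values.loc[enh_rows, wt.id],
                             factors.pair(mut.id, wt.id))
            fold_changes[(cond, rep)] = fc
            per_rep.append(fc)
        if len(per_rep) >= 2:
            sensitive_calls[cond] = select_sensitive_enhancers(per_rep[0],
                                                               per_rep[1])

    # --- super-enhancers and transcribed regions -------------------------
    wt_rep = sorted(wt_by_rep)[0]
    wt_sample = wt_by_rep[wt_rep]
    wt_input = manifest.matched_input(wt_sample)
    stitched = stitch_enhancers(k27_union, me3_union, gap=config.stitch_gap)
    stitched = call_super_enhancers(stitched, prepped[wt_sample.id],
                                    prepped[wt_input.id])
    stitched_df = stitched_to_frame(stitched)

    pol2 = manifest.by_mark("PolII")
    tx_source = pol2[0] if pol2 else wt_sample
    tx_input = manifest.matched_input(tx_source)
    tx_frames = []
    for chrom in prepped[tx_source.id].chrom_names():
        case = prepped[tx_source.id].bin_counts(chrom, 100)
        ctrl = prepped[tx_input.id].bin_counts(chrom, 100)
        n = min(len(case), len(ctrl))
        segs = segment_transcription(case[:n], ctrl[:n],
                                     lam=config.segment_lambda,
                                     min_log2=config.transcribed_min_log2)
        tx_frames.append(transcribed_to_frame(segs, chrom=chrom))
    transcribed_df = pd.concat(tx_frames, ignore_index=True) if tx_frames \
        else pd.DataFrame()

    # --- expression linkage and GO ---------------------------------------
    links = None
    go_results = None
    extras: dict = {}
    if len(act_tss):
        enh_frame = elements.loc[enh_rows]
        links = link_enhancers(enh_frame, act_tss,
                               max_dist=config.link_max_dist,
                               min_dist_expr=config.link_min_dist)
    if expression_table is not None and links is not None:
        expr = expression_table.set_index("gene_id")
        expr_lfc = pd.Series(
            expression_change(expr["value_2"], expr["value_1"],
                              config.expression_pseudocount),
            index=expr.index)
        extras["expression_log2fc"] = expr_lfc
        down = select_downregulated_genes(expression_table, fdr=config.go_fdr)
        extras["downregulated_genes"] = down
        if go_map is not None:
            universe = [g for g in expression_table.loc[
                expression_table["status"] == "OK", "gene_id"]]
            go_results = go_enrichment(
                [g for g in down if g in set(universe)], universe, go_map)

    result = PipelineResult(
        config=config, blacklist_bp=blacklist.total_bp(),
        roe_by_sample=roe_by_sample, h3k27ac_union=k27_union,
        elements=elements, signal_matrix=matrix, factors=factors,
        sensitive_calls=sensitive_calls, stitched=stitched_df,
        transcribed=transcribed_df, links=links, go_results=go_results,
        extras=extras)
    result.extras["fold_changes"] = fold_changes
    result.extras["enhancer_rows"] = enh_rows
    result.extras["active_tss"] = act_tss
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _pick_reference(k27_samples: list[Sample]) -> str:
    wt = sorted((s.replicate, s.id) for s in k27_samples if s.condition == "WT")
    if not wt:
        raise ValueError("no wild-type H3K27ac sample in manifest")
    return wt[0][1]


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    els = result.elements
    bed = els[["chrom", "start", "end"]].copy()
    bed["name"] = els["cre_class"]
    bed.to_csv(out_dir / "elements.bed", sep="\t", header=False, index=False)
    els.to_csv(out_dir / "elements.tsv", sep="\t", index=False)
    result.signal_matrix.values.to_csv(out_dir / "signal_matrix.tsv", sep="\t")
    pd.Series(result.factors.factors).rename("factor") \
        .to_csv(out_dir / "normalization_factors.tsv", sep="\t")
    result.stitched.to_csv(out_dir / "stitched_enhancers.tsv", sep="\t",
                           index=False)
    result.transcribed.to_csv(out_dir / "transcribed_segments.tsv", sep="\t",
                              index=False)
    if result.links is not None:
        result.links.to_csv(out_dir / "enhancer_gene_links.tsv", sep="\t",
                            index=False)
    if result.go_results is not None:
        result.go_results.to_csv(out_dir / "go_enrichment.tsv", sep="\t",
                                 index=False)
    with open(out_dir / "run_config.json", "w") as fh:
        json.dump({"config": result.config.to_dict(),
                   "config_hash": result.config.config_hash(),
                   "python": sys.version.split()[0]}, fh, indent=2)


# ---------------------------------------------------------------------------
# Synthetic demonstration run
# ---------------------------------------------------------------------------

def simulate_manifest(spec: synthetic.SyntheticGenomeSpec,
                      ground_truth: synthetic.GroundTruth | None = None,
                      efficiencies: dict[str, float] | None = None,
                      seed: int | None = None
                      ) -> tuple[SampleManifest, synthetic.GroundTruth]:
    """Generate the standard 2-replicate x 3-condition design in memory.

    Produces H3K27ac IP + input for every (condition, replicate) pair and an
    H3K4me3 IP per condition (replicate I).  ``efficiencies`` maps H3K27ac
    sample ids (e.g. ``"H3K27ac_WT_I"``) to IP-efficiency multipliers; when
    absent they are drawn uniformly from [0.6, 1.4].
    """
    if ground_truth is None:
        ground_truth = synthetic.plant_sites(spec)
    base_seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(synthetic._derive_seed(base_seed, "manifest"))
    samples = []
    eff_used: dict[str, float] = {}
    for cond in spec.conditions:
        for rep in ("I", "II"):
            sid = f"H3K27ac_{cond}_{rep}"
            eff = (efficiencies or {}).get(sid)
            if eff is None:
                eff = float(rng.uniform(0.6, 1.4))
            eff_used[sid] = eff
            lib = synthetic.generate_tag_library(
                spec, cond, "IP", mark="H3K27ac", ground_truth=ground_truth,
                ip_efficiency=eff,
                seed=synthetic._derive_seed(base_seed, "tags", cond, "IP",
                                            "H3K27ac", rep))
            samples.append(Sample(id=sid, mark="H3K27ac", condition=cond,
                                  replicate=rep, library=lib,
                                  fragment_size=spec.fragment_size))
            inp = synthetic.generate_tag_library(
                spec, cond, "input", ground_truth=ground_truth,
                seed=synthetic._derive_seed(base_seed, "tags", cond, "input",
                                            "any", rep))
            samples.append(Sample(id=f"input_{cond}_{rep}", mark="input",
                                  condition=cond, replicate=rep, library=inp,
                                  fragment_size=spec.fragment_size))
        me3 = synthetic.generate_tag_library(
            spec, cond, "IP", mark="H3K4me3", ground_truth=ground_truth,
            seed=synthetic._derive_seed(base_seed, "tags", cond, "IP",
                                        "H3K4me3", "I"))
        samples.append(Sample(id=f"H3K4me3_{cond}_I", mark="H3K4me3",
                              condition=cond, replicate="I", library=me3,
                              fragment_size=spec.fragment_size))
    ground_truth.ip_efficiency = eff_used
    return SampleManifest(samples=samples), ground_truth


def run_synthetic_demo(spec: synthetic.SyntheticGenomeSpec | None = None,
                       seed: int = 0, out_dir=None,
                       coupling: float = 1.0) -> dict:
    """End-to-end demonstration on a planted genome; returns a summary dict
    including precision/recall of the sensitive-enhancer calls against the
    planted truth."""
    if spec is None:
        spec = synthetic.SyntheticGenomeSpec(
            n_chroms=2, chrom_length=3_000_000, n_promoter_sites=200,
            n_distal_sites=400, seed=seed)
    gt = synthetic.plant_sites(spec)
    manifest, gt = simulate_manifest(spec, gt, seed=seed)
    expr = synthetic.generate_expression_table(
        gt, coupling=coupling, seed=synthetic._derive_seed(seed, "expr"))
    config = PipelineConfig(seed=seed)
    result = run_pipeline(config, manifest, gt.tss,
                          expression_table=expr, out_dir=out_dir)
    summary = {"config_hash": config.config_hash(),
               "n_elements": len(result.elements),
               "n_promoters": int((result.elements["cre_class"]
                                   == "promoter").sum()),
               "n_enhancers": int((result.elements["cre_class"]
                                   == "enhancer").sum())}
    prf = sensitive_call_metrics(result, gt)
    summary.update(prf)
    summary["factors"] = result.factors.factors
    summary["true_efficiencies"] = gt.ip_efficiency
    return {"summary": summary, "result": result, "ground_truth": gt}


def sensitive_call_metrics(result: PipelineResult,
                           gt: synthetic.GroundTruth) -> dict:
    """Precision/recall of called sensitive enhancers vs planted sites.

    A called enhancer counts as a true positive iff it overlaps a planted
    sensitive distal site; a planted sensitive site is recovered iff some
    called-sensitive enhancer overlaps it.  Calls from all mutant conditions
    are pooled.
    """
    from enhancerscape.intervals import overlap_pairs

    enh_rows = result.extras["enhancer_rows"]
    enh = result.elements.loc[enh_rows].reset_index(drop=True)
    called = np.zeros(len(enh), dtype=bool)
    for flags in result.sensitive_calls.values():
        called |= np.asarray(flags, dtype=bool)
    sens_sites = gt.sites[(gt.sites["site_class"] == "distal")
                          & gt.sites["sensitive"]].reset_index(drop=True)
    called_regions = enh[called].reset_index(drop=True)
    ia, ib = overlap_pairs(called_regions, sens_sites)
    tp_calls = len(np.unique(ia))
    recovered = len(np.unique(ib))
    precision = tp_calls / max(len(called_regions), 1)
    recall = recovered / max(len(sens_sites), 1)
    return {"n_called_sensitive": int(len(called_regions)),
            "n_planted_sensitive": int(len(sens_sites)),
            "precision": float(precision), "recall": float(recall)}
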