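"""Synthetic genomes, tag libraries, motif landscapes and expression tables.

The generator emulates the statistical structure the analysis pipeline
assumes, mirroring a two-replicate, three-condition histone-mark ChIP-seq
design:

* background tag coverage is Poisson along each chromosome;
* enriched sites come in two classes — TSS-proximal sites carrying both
  H3K27ac and H3K4me3 (promoters), and TSS-distal sites carrying H3K27ac
  only (enhancers);
* a configurable fraction of distal sites is *sensitive*: their H3K27ac
  signal drops by a planted fold-change in mutant conditions;
* each IP library suffers a per-sample multiplicative immunoprecipitation-
  efficiency distortion, modelled as scaling of the enriched (pulled-down)
  fragments against a constant background admixture;
* motif occurrences are planted with a density that can be confounded with
  region GC content;
* gene expression counts are coupled to the fold-change of the nearest
  planted enhancer.

All generators are deterministic under their seed; no global random state
is used.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from enhancerscape.taglib import TagLibrary
from enhancerscape.motifs import PWMotif

SITE_WIDTH = 1000  # bp
DEFAULT_FRAGMENT_SIZE = 160  # bp, midpoint of typical 140-180 bp fragments
GC_MOTIF_COUPLING = 20.0  # rate-model coupling between motif GC and region GC


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Parameters of a toy genome with planted regulatory sites.

    ``background_rate`` is the Poisson tag rate per bp of the input (and the
    IP background); ``enrichment_fold`` the IP tag-rate multiplier at
    enriched sites; ``ip_efficiency`` the default per-sample scaling of
    enriched fragments; ``fraction_sensitive`` the proportion of distal
    sites whose signal drops to ``sensitive_fold_change`` in mutants.
    """

    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_promoter_sites: int = 50
    n_distal_sites: int = 100
    fraction_sensitive: float = 0.3
    background_rate: float = 0.02
    enrichment_fold: float = 8.0
    ip_efficiency: float = 1.0
    fragment_size: int = DEFAULT_FRAGMENT_SIZE
    seed: int = 0
    site_width: int = SITE_WIDTH
    sensitive_fold_change: float = 0.25
    site_strength_sd: float = 0.0  # log-normal sd of per-site strength
    conditions: tuple = ("WT", "mutantA", "mutantB")

    def __post_init__(self):
        for name in ("n_chroms", "chrom_length", "n_promoter_sites",
                     "n_distal_sites"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.fraction_sensitive <= 1:
            raise ValueError("fraction_sensitive must be in [0, 1]")
        if self.background_rate <= 0:
            raise ValueError("background_rate must be > 0")
        if self.ip_efficiency <= 0:
            raise ValueError("ip_efficiency must be > 0")
        n_sites = self.n_promoter_sites + self.n_distal_sites
        if n_sites and self.n_chroms * self.chrom_length < \
                10 * n_sites * self.site_width:
            raise ValueError(
                "genome too small: need chrom space >= 10x total site width")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names}


@dataclass
class GroundTruth:
    """Planted truth: site table, TSS annotation, per-sample efficiencies."""

    sites: pd.DataFrame  # chrom,start,end,site_class,sensitive,gene_id,fold_change_mutant
    tss: pd.DataFrame  # chrom,pos,strand,gene_id
    ip_efficiency: dict[str, float] = field(default_factory=dict)
    spec: SyntheticGenomeSpec | None = None


def _derive_seed(seed: int, *labels) -> int:
    """Stable sub-seed from a base seed and string labels (crc32-based)."""
    h = zlib.crc32("|".join(str(x) for x in labels).encode())
    return (int(seed) * 1_000_003 + h) % (2 ** 31)


def plant_sites(spec: SyntheticGenomeSpec) -> GroundTruth:
    """Place promoter/distal sites on an even grid (jittered), assign genes.

    Sites are laid out with spacing that keeps any two sites several site
    widths apart, so distance-rule classification has unambiguous truth.
    Every promoter site carries a TSS at its centre; each distal site is
    assigned the gene of its nearest TSS.
    """
    rng = np.random.default_rng(_derive_seed(spec.seed, "sites"))
    n_sites = spec.n_promoter_sites + spec.n_distal_sites
    rows = []
    if n_sites:
        per_chrom = np.full(spec.n_chroms, n_sites // spec.n_chroms)
        per_chrom[:n_sites % spec.n_chroms] += 1
        classes = np.array(["promoter"] * spec.n_promoter_sites
                           + ["distal"] * spec.n_distal_sites)
        rng.shuffle(classes)
        idx = 0
        for ci, chrom in enumerate(spec.chrom_names):
            k = per_chrom[ci]
            if k == 0:
                continue
            spacing = spec.chrom_length // (k + 1)
            # keep site edges >= ~7 site widths apart so that called-region
            # and H3K4me3-region margins cannot defeat the distance rules
            jitter_max = max((spacing - 8 * spec.site_width) // 2, 1)
            jitter = rng.integers(-jitter_max, jitter_max + 1, size=k)
            for j in range(k):
                centre = (j + 1) * spacing + int(jitter[j])
                start = centre - spec.site_width // 2
                rows.append((chrom, start, start + spec.site_width,
                             classes[idx]))
                idx += 1
    sites = pd.DataFrame(rows, columns=["chrom", "start", "end", "site_class"])
    sites["sensitive"] = False
    distal_idx = sites.index[sites["site_class"] == "distal"].to_numpy()
    n_sens = int(round(spec.fraction_sensitive * len(distal_idx)))
    sens_pick = rng.choice(distal_idx, size=n_sens, replace=False) \
        if n_sens else np.array([], dtype=int)
    sites.loc[sens_pick, "sensitive"] = True
    sites["fold_change_mutant"] = np.where(sites["sensitive"],
                                           spec.sensitive_fold_change, 1.0)
    # optional per-site strength variation (multiplies the enriched rate);
    # the default of 1.0 everywhere keeps promoter signals exchangeable
    if spec.site_strength_sd > 0:
        sites["strength"] = rng.lognormal(0.0, spec.site_strength_sd,
                                          size=len(sites))
    else:
        sites["strength"] = 1.0

    prom = sites[sites["site_class"] == "promoter"]
    tss = pd.DataFrame({
        "chrom": prom["chrom"].to_numpy(),
        "pos": ((prom["start"] + prom["end"]) // 2).to_numpy(),
        "strand": np.where(np.arange(len(prom)) % 2 == 0, "+", "-"),
        "gene_id": [f"gene{i:05d}" for i in range(len(prom))],
    })
    gene_ids = []
    for row in sites.itertuples(index=False):
        if row.site_class == "promoter":
            centre = (row.start + row.end) // 2
            match = tss[(tss["chrom"] == row.chrom) & (tss["pos"] == centre)]
            gene_ids.append(match["gene_id"].iloc[0])
        else:
            sub = tss[tss["chrom"] == row.chrom]
            if len(sub) == 0:
                gene_ids.append(None)
                continue
            centre = (row.start + row.end) // 2
            j = (sub["pos"] - centre).abs().idxmin()
            gene_ids.append(sub.loc[j, "gene_id"])
    sites["gene_id"] = gene_ids
    return GroundTruth(sites=sites, tss=tss, spec=spec)


def _site_fold_change(site_class: str, fold_change_mutant: float,
                      condition: str, mark: str) -> float:
    if condition == "WT" or mark == "H3K4me3":
        return 1.0
    if site_class == "distal":
        return fold_change_mutant
    return 1.0  # promoters are unaffected by the perturbation


def generate_tag_library(spec: SyntheticGenomeSpec, condition: str,
                         sample_role: str, mark: str = "H3K27ac",
                         ground_truth: GroundTruth | None = None,
                         ip_efficiency: float | None = None,
                         seed: int | None = None) -> TagLibrary:
    """Draw one sample's tag library.

    Background fragment centres arrive as Poisson(background_rate) per bp
    genome-wide.  For IP samples, enriched sites add fragments at rate
    ``background_rate * (enrichment_fold * fold_change - 1)``, scaled by the
    sample's IP efficiency; input samples ignore enrichment.  Each fragment
    yields one tag: a uniformly random strand with the 5' position offset
    by -strand * fragment_size // 2 from the fragment centre.
    """
    if sample_role not in ("IP", "input"):
        raise ValueError("sample_role must be 'IP' or 'input'")
    if condition not in spec.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    if ground_truth is None:
        ground_truth = plant_sites(spec)
    eff = spec.ip_efficiency if ip_efficiency is None else ip_efficiency
    if eff <= 0:
        raise ValueError("ip_efficiency must be > 0")
    if seed is None:
        seed = _derive_seed(spec.seed, "tags", condition, sample_role, mark)
    rng = np.random.default_rng(seed)
    half = spec.fragment_size // 2

    chrom_arr, pos_arr, strand_arr = [], [], []

    def add_fragments(chrom: str, centres: np.ndarray):
        if len(centres) == 0:
            return
        strands = rng.choice(np.array([1, -1], dtype=np.int8), size=len(centres))
        pos = centres - strands.astype(np.int64) * half
        pos = np.clip(pos, 0, spec.chrom_length - 1)
        chrom_arr.append(np.full(len(centres), chrom))
        pos_arr.append(pos)
        strand_arr.append(strands)

    for chrom in spec.chrom_names:
        n_bg = rng.poisson(spec.background_rate * spec.chrom_length)
        add_fragments(chrom, rng.integers(0, spec.chrom_length, size=n_bg))

    if sample_role == "IP":
        enriched = ground_truth.sites if mark == "H3K27ac" else \
            ground_truth.sites[ground_truth.sites["site_class"] == "promoter"]
        for row in enriched.itertuples(index=False):
            fc = _site_fold_change(row.site_class, row.fold_change_mutant,
                                   condition, mark)
            extra_rate = spec.background_rate * \
                (spec.enrichment_fold * fc - 1.0) * eff * row.strength
            if extra_rate <= 0:
                continue
            n_extra = rng.poisson(extra_rate * (row.end - row.start))
            add_fragments(row.chrom,
                          rng.integers(row.start, row.end, size=n_extra))

    if not chrom_arr:
        return TagLibrary(chroms={}, chrom_lengths=spec.chrom_lengths,
                          fragment_size=spec.fragment_size)
    return TagLibrary.from_arrays(
        np.concatenate(chrom_arr), np.concatenate(pos_arr),
        np.concatenate(strand_arr),
        chrom_lengths=spec.chrom_lengths, fragment_size=spec.fragment_size)


def expected_site_tag_count(spec: SyntheticGenomeSpec, fold_change: float,
                            ip_efficiency: float) -> float:
    """Expected IP tag count falling inside a site interval.

    Background contributes ``background_rate * site_width`` (the strand
    offset does not change a uniform rate).  Enriched fragments contribute
    with an effective width of ``site_width - fragment_size // 2``: a tag's
    5' offset moves it outside the site when its fragment centre lies within
    half a fragment of the matching edge.
    """
    eff_width = spec.site_width - spec.fragment_size // 2
    return spec.background_rate * (
        spec.site_width
        + (spec.enrichment_fold * fold_change - 1.0) * ip_efficiency
        * eff_width)


def expected_total_tags(spec: SyntheticGenomeSpec, sites: pd.DataFrame,
                        condition: str, ip_efficiency: float,
                        mark: str = "H3K27ac") -> float:
    """Expected total mapped tags of an IP library under the rate model."""
    total = spec.background_rate * spec.n_chroms * spec.chrom_length
    enriched = sites if mark == "H3K27ac" else \
        sites[sites["site_class"] == "promoter"]
    for row in enriched.itertuples(index=False):
        fc = _site_fold_change(row.site_class, row.fold_change_mutant,
                               condition, mark)
        total += spec.background_rate * \
            (spec.enrichment_fold * fc - 1.0) * ip_efficiency * \
            (row.end - row.start)
    return total


def mode_normalization_target(spec: SyntheticGenomeSpec, gt: GroundTruth,
                              condition: str, eff_ref: float,
                              eff_sample: float, n_mc: int = 200_000,
                              seed: int = 0,
                              pseudocount: float = 1.0) -> float:
    """Truth-implied promoter-mode normalization factor for one sample.

    Simulates promoter tag counts directly from the generator's Poisson rate
    model (no tag libraries involved) for the sample and the reference,
    forms the log2 fold-change of RPM+pseudocount signals, and returns
    ``2 ** (-mode)`` of that model distribution — the factor a perfect
    promoter-mode fit should recover.  Monte-Carlo at large ``n_mc`` makes
    the sampling error of the target negligible next to a fit on thousands
    of promoters.
    """
    from enhancerscape.signal import _log2_mode

    rng = np.random.default_rng(seed)
    lam_ref = expected_site_tag_count(spec, 1.0, eff_ref)
    lam_s = expected_site_tag_count(spec, 1.0, eff_sample)
    t_ref = expected_total_tags(spec, gt.sites, "WT", eff_ref)
    t_s = expected_total_tags(spec, gt.sites, condition, eff_sample)
    c_ref = rng.poisson(lam_ref, n_mc)
    c_s = rng.poisson(lam_s, n_mc)
    sig_ref = c_ref / (t_ref / 1e6) + pseudocount
    sig_s = c_s / (t_s / 1e6) + pseudocount
    mode = _log2_mode(np.log2(sig_s / sig_ref))
    return float(2.0 ** (-mode))


# ---------------------------------------------------------------------------
# Motif landscape
# ---------------------------------------------------------------------------

def generate_motif_landscape(ground_truth: GroundTruth,
                             pwm_set: dict[str, PWMotif],
                             gc_confound_strength: float = 0.0,
                             base_rate: float = 2.0,
                             plant: dict[str, float] | None = None,
                             seed: int | None = None
                             ) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Plant motif occurrences in distal sites with a GC-dependent rate.

    Each distal site receives a GC content (sensitive sites are drawn
    GC-richer than insensitive ones, creating a composition difference
    between the classes).  For motif m in region r the occurrence count is
    Poisson with rate::

        base_rate * exp(strength * K * (gc_m - 1/2) * (gc_r - 1/2)) * plant_m

    where ``plant_m`` multiplies the rate in sensitive regions only.  With
    ``gc_confound_strength = 0`` placement is uniform regardless of GC.
    Returns (region GC table, {motif_id: match positions}).
    """
    if not pwm_set:
        raise ValueError("pwm_set must be non-empty")
    spec = ground_truth.spec
    if seed is None:
        seed = _derive_seed(spec.seed if spec else 0, "motifs")
    rng = np.random.default_rng(seed)
    plant = plant or {}
    distal = ground_truth.sites[
        ground_truth.sites["site_class"] == "distal"].reset_index(drop=True)
    gc = np.where(distal["sensitive"],
                  rng.normal(0.55, 0.08, size=len(distal)),
                  rng.normal(0.45, 0.08, size=len(distal)))
    gc = np.clip(gc, 0.2, 0.8)
    gc_track = distal[["chrom", "start", "end", "sensitive"]].copy()
    gc_track["gc"] = gc

    maps: dict[str, pd.DataFrame] = {}
    for motif_id in sorted(pwm_set):
        gc_m = pwm_set[motif_id].gc_content
        rate = base_rate * np.exp(
            gc_confound_strength * GC_MOTIF_COUPLING
            * (gc_m - 0.5) * (gc - 0.5))
        factor = plant.get(motif_id, 1.0)
        rate = np.where(distal["sensitive"], rate * factor, rate)
        counts = rng.poisson(rate)
        rows = []
        for (row, k) in zip(distal.itertuples(index=False), counts):
            if k == 0:
                continue
            pos = rng.integers(row.start, row.end, size=k)
            for p in pos:
                rows.append((row.chrom, int(p)))
        maps[motif_id] = pd.DataFrame(rows, columns=["chrom", "pos"])
    return gc_track, maps


# ---------------------------------------------------------------------------
# Expression table
# ---------------------------------------------------------------------------

def generate_expression_table(ground_truth: GroundTruth, coupling: float = 0.5,
                              dispersion: float = 0.05, seed: int = 0,
                              base_mean: float = 200.0) -> pd.DataFrame:
    """Gene-level two-condition counts coupled to nearby-enhancer change.

    Per gene, the mutant/WT expected log2 ratio is ``coupling`` times the
    planted log2 fold-change of the nearest distal site assigned to the gene
    (0 for genes without one).  Counts are negative-binomial
    (Var = mu + dispersion * mu^2); with ``dispersion = 0`` counts equal
    their means exactly.  Output is a cuffdiff-shaped table with columns
    (gene_id, status, value_1 (WT), value_2 (mutant), log2_fold, fdr).
    """
    rng = np.random.default_rng(seed)
    tss = ground_truth.tss
    distal = ground_truth.sites[ground_truth.sites["site_class"] == "distal"]
    enh_lfc = distal.groupby("gene_id")["fold_change_mutant"] \
        .apply(lambda v: float(np.log2(v.min())))
    genes = tss["gene_id"].tolist()
    mu_wt = np.exp(rng.normal(np.log(base_mean), 0.6, size=len(genes)))
    lfc_true = np.array([coupling * enh_lfc.get(g, 0.0) for g in genes])
    mu_mut = mu_wt * 2.0 ** lfc_true

    def draw(mu):
        if dispersion == 0:
            return mu
        shape = 1.0 / dispersion
        lam = rng.gamma(shape, mu / shape)
        return rng.poisson(lam).astype(float)

    v1 = draw(mu_wt)
    v2 = draw(mu_mut)
    # a simple two-sided binomial test per gene stands in for cuffdiff's
    # significance call on this synthetic table
    pvals = np.array([
        stats.binomtest(int(round(a)), int(round(a + b)), 0.5).pvalue
        if (a + b) > 0 else 1.0
        for a, b in zip(v2, v1)])
    from statsmodels.stats.multitest import multipletests

    fdr = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else pvals
    return pd.DataFrame({
        "gene_id": genes,
        "status": "OK",
        "value_1": v1,
        "value_2": v2,
        "log2_fold": np.log2((v2 + 1e-300) / (v1 + 1e-300)),
        "fdr": fdr,
    })


# ---------------------------------------------------------------------------
# Convenience writers (tag TSV / BED / TSS tables)
# ---------------------------------------------------------------------------

def write_ground_truth(gt: GroundTruth, sites_path, tss_path) -> None:
    gt.sites.to_csv(sites_path, sep="\t", index=False)
    gt.tss.to_csv(tss_path, sep="\t", index=False)


def read_tss_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom", "pos", "strand", "gene_id"],
                       dtype={"chrom": str})
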