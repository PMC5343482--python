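"""Enhancer-gene linkage, expression change, and GO enrichment.

Each enhancer is associated to its closest active TSS within 100 kb;
expression analyses keep links whose TSS is 5-100 kb away so that the gene's
own promoter signal does not contaminate the enhancer categories.  Gene set
enrichment uses the hypergeometric upper tail with Benjamini-Hochberg
correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

MAX_LINK_DIST = 100_000
MIN_EXPR_LINK_DIST = 5_000
EXPRESSION_PSEUDOCOUNT = 5.0

# mutant/WT fold-change categories (thresholds exclusive on "more than";
# boundary values fall into the milder category)
CATEGORY_LABELS = ["loss>3x", "loss1.5-3x", "stable<1.5x", "gain>1.5x"]


def link_enhancers(enhancers: pd.DataFrame, active_tss: pd.DataFrame,
                   max_dist: int = MAX_LINK_DIST,
                   min_dist_expr: int = MIN_EXPR_LINK_DIST) -> pd.DataFrame:
    """Associate each enhancer to its closest active TSS within ``max_dist``.

    Distance is from the enhancer edge to the TSS position (0 if the TSS
    falls inside the enhancer).  Returns one row per linked enhancer with
    columns (enhancer_id, gene_id, distance, usable_for_expression); the
    expression flag marks links with distance in [min_dist_expr, max_dist].
    """
    rows = []
    tss_by_chrom = {
        chrom: sub.reset_index(drop=True)
        for chrom, sub in active_tss.groupby("chrom", sort=False)
    }
    enh = enhancers.reset_index(drop=False).rename(columns={"index": "enhancer_id"})
    for row in enh.itertuples(index=False):
        sub = tss_by_chrom.get(row.chrom)
        if sub is None or len(sub) == 0:
            continue
        pos = sub["pos"].to_numpy()
        d = np.maximum(np.maximum(row.start - pos, pos - (row.end - 1)), 0)
        j = int(np.argmin(d))
        if d[j] > max_dist:
            continue
        rows.append((row.enhancer_id, sub["gene_id"].iloc[j], int(d[j]),
                     min_dist_expr <= int(d[j]) <= max_dist))
    return pd.DataFrame(rows, columns=["enhancer_id", "gene_id", "distance",
                                       "usable_for_expression"])


def expression_change(count_mut, count_wt,
                      pseudocount: float = EXPRESSION_PSEUDOCOUNT):
    """log2((count_mut + pc) / (count_wt + pc)); default pc = 5."""
    return np.log2((np.asarray(count_mut, dtype=float) + pseudocount)
                   / (np.asarray(count_wt, dtype=float) + pseudocount))


def categorize_fold_change(fc: float) -> str:
    """Map an enhancer mutant/WT signal ratio to its change category."""
    if fc < 1 / 3:
        return "loss>3x"
    if fc < 1 / 1.5:
        return "loss1.5-3x"
    if fc <= 1.5:
        return "stable<1.5x"
    return "gain>1.5x"


def categorize_and_compare(links: pd.DataFrame,
                           enhancer_fold_changes: pd.Series,
                           expression_changes: pd.Series) -> dict:
    """Group expression changes by enhancer fold-change category.

    ``links`` must carry enhancer_id/gene_id (rows flagged
    usable_for_expression are used); ``enhancer_fold_changes`` is indexed by
    enhancer_id and ``expression_changes`` by gene_id.  Returns a dict with
    per-category values, boxplot summary statistics (quartiles and 1.5 x IQR
    whiskers) and Welch two-sided t-test p-values between category pairs.
    """
    usable = links[links["usable_for_expression"]] \
        if "usable_for_expression" in links.columns else links
    groups: dict[str, list[float]] = {c: [] for c in CATEGORY_LABELS}
    for row in usable.itertuples(index=False):
        if row.enhancer_id not in enhancer_fold_changes.index:
            continue
        if row.gene_id not in expression_changes.index:
            continue
        cat = categorize_fold_change(float(enhancer_fold_changes[row.enhancer_id]))
        groups[cat].append(float(expression_changes[row.gene_id]))
    summary = {}
    for cat, vals in groups.items():
        if not vals:
            summary[cat] = None
            continue
        arr = np.array(vals)
        q1, med, q3 = np.percentile(arr, [25, 50, 75])
        iqr = q3 - q1
        summary[cat] = {
            "n": len(arr), "median": float(med), "q1": float(q1),
            "q3": float(q3),
            "whisker_low": float(arr[arr >= q1 - 1.5 * iqr].min()),
            "whisker_high": float(arr[arr <= q3 + 1.5 * iqr].max()),
        }
    pvalues = {}
    for a, b in combinations(CATEGORY_LABELS, 2):
        if len(groups[a]) < 2 or len(groups[b]) < 2:
            pvalues[(a, b)] = None
            continue
        res = stats.ttest_ind(groups[a], groups[b], equal_var=False)
        pvalues[(a, b)] = float(res.pvalue)
    return {"groups": {c: np.array(v) for c, v in groups.items()},
            "summary": summary, "pvalues": pvalues}


def select_sensitive_enhancers(fold_change_rep1, fold_change_rep2) -> np.ndarray:
    """Sensitive iff both replicate ratios < 1 and their geometric mean < 1/2."""
    fc1 = np.atleast_1d(np.asarray(fold_change_rep1, dtype=float))
    fc2 = np.atleast_1d(np.asarray(fold_change_rep2, dtype=float))
    if np.any(fc1 <= 0) or np.any(fc2 <= 0):
        raise ValueError("fold-changes must be positive")
    gm = np.sqrt(fc1 * fc2)
    out = (fc1 < 1) & (fc2 < 1) & (gm < 0.5)
    return out if out.size > 1 else bool(out[0])


def select_downregulated_genes(diff_table: pd.DataFrame, fdr: float = 0.05,
                               min_fold: float = 2.0) -> list[str]:
    """Genes with status OK, FDR < threshold and > min_fold expression drop.

    ``diff_table`` is cuffdiff-shaped with columns gene_id, status, value_1
    (WT), value_2 (mutant), fdr (q_value accepted as an alias).
    """
    required = {"gene_id", "status"}
    cols = set(diff_table.columns)
    if not required <= cols:
        raise ValueError(f"missing columns: {sorted(required - cols)}")
    fdr_col = "fdr" if "fdr" in cols else "q_value"
    if fdr_col not in cols or not {"value_1", "value_2"} <= cols:
        raise ValueError("diff table needs value_1, value_2 and fdr columns")
    ok = diff_table[diff_table["status"] == "OK"]
    ratio = (ok["value_2"].to_numpy() + 1e-300) / (ok["value_1"].to_numpy()
                                                   + 1e-300)
    keep = (ok[fdr_col].to_numpy() < fdr) & (ratio < 1.0 / min_fold)
    return ok["gene_id"][keep].tolist()


@dataclass
class GoResult:
    term: str
    k_selected: int
    K_annotated: int
    n_selected: int
    N_universe: int
    p: float
    q: float


def go_enrichment(selected_genes, universe_genes,
                  go_map: pd.DataFrame) -> pd.DataFrame:
    """Hypergeometric GO-term enrichment with Benjamini-Hochberg q-values.

    ``go_map`` is a two-column frame (term, gene).  For each term with K
    annotated genes in the universe of N, the p-value is the upper-tail
    probability of >= k annotated among the n selected genes.  Terms with no
    annotated universe genes are skipped.
    """
    selected = set(selected_genes)
    universe = set(universe_genes)
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    n = len(selected)
    N = len(universe)
    rows = []
    for term, sub in go_map.groupby("term", sort=True):
        annotated = set(sub["gene"]) & universe
        K = len(annotated)
        if K == 0:
            continue
        k = len(annotated & selected)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, n, N, p))
    if not rows:
        return pd.DataFrame(columns=["term", "k_selected", "K_annotated",
                                     "n_selected", "N_universe", "p", "q"])
    out = pd.DataFrame(rows, columns=["term", "k_selected", "K_annotated",
                                      "n_selected", "N_universe", "p"])
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out.sort_values("p").reset_index(drop=True)
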