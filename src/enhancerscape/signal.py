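"""Region signal, enrichment, fold-change and IP-efficiency normalization.

ChIP-seq signal at a region is reads-per-million in the region plus a
pseudocount of 1.  Enrichment is IP signal over input signal; fold-change
between conditions uses IP signals only (input cancels poorly and inflates
variance when ratios of ratios are taken).

Library-size normalization does not make IP samples comparable when the
immunoprecipitation efficiency — the ratio of pulled-down to background
fragments — differs between experiments: every region's signal is then off
by a constant factor.  Because the bulk of promoters is unaffected by the
perturbations studied here, that factor is identifiable as the mode of the
promoter log-fold-change distribution, and each sample receives a
multiplicative correction placing that mode at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from enhancerscape.taglib import TagLibrary

MODE_GRID_STEP = 0.01  # log2 units
MODE_GRID_SPAN = 3.0


def region_signal(lib: TagLibrary, regions: pd.DataFrame,
                  pseudocount: float = 1.0) -> np.ndarray:
    """Reads in region per million mapped reads + pseudocount."""
    total = lib.total_mapped
    if total <= 0:
        raise ValueError("library has no mapped tags")
    for row in regions.itertuples(index=False):
        length = lib.chrom_lengths.get(row.chrom)
        if length is not None and (row.start < 0 or row.end > length):
            raise ValueError(
                f"region {row.chrom}:{row.start}-{row.end} outside chromosome")
    counts = lib.count_in_regions(regions)
    return counts / (total / 1e6) + pseudocount


def enrichment(ip_signal: np.ndarray, input_signal: np.ndarray) -> np.ndarray:
    """Elementwise IP signal / input signal; > 1 means enriched."""
    return np.asarray(ip_signal, dtype=float) / np.asarray(input_signal, dtype=float)


def fold_change(signal_a: np.ndarray, signal_b: np.ndarray,
                factors: "NormalizationFactors | tuple | None" = None
                ) -> np.ndarray:
    """Elementwise (factor_a * signal_a) / (factor_b * signal_b).

    ``factors`` may be None (library-size normalization only), a pair of
    scalars, or a :class:`NormalizationFactors` plus sample names via
    :meth:`NormalizationFactors.pair`.
    """
    fa = fb = 1.0
    if factors is not None:
        fa, fb = factors
    return (fa * np.asarray(signal_a, dtype=float)) / \
        (fb * np.asarray(signal_b, dtype=float))


@dataclass
class RegionSignalMatrix:
    """Signals (RPM + pseudocount) for regions (rows) x samples (columns)."""

    values: pd.DataFrame  # index: region ids, columns: sample ids
    total_mapped: dict[str, int] = field(default_factory=dict)
    pseudocount: float = 1.0

    @classmethod
    def from_libraries(cls, libraries: dict[str, TagLibrary],
                       regions: pd.DataFrame,
                       pseudocount: float = 1.0) -> "RegionSignalMatrix":
        values = pd.DataFrame(
            {name: region_signal(lib, regions, pseudocount)
             for name, lib in libraries.items()},
            index=regions.index)
        totals = {name: lib.total_mapped for name, lib in libraries.items()}
        return cls(values=values, total_mapped=totals, pseudocount=pseudocount)


@dataclass
class NormalizationFactors:
    """Per-sample multiplicative IP-efficiency corrections.

    Factors are parameterized so that, after multiplying each sample's
    signals by its factor, the mode of the promoter log2 fold-change of any
    sample against the reference is zero.  The reference sample has factor 1.
    """

    factors: dict[str, float]
    reference: str
    diagnostics: dict = field(default_factory=dict)

    def pair(self, sample_a: str, sample_b: str) -> tuple[float, float]:
        return self.factors[sample_a], self.factors[sample_b]


def _log2_mode(values: np.ndarray, grid_step: float = MODE_GRID_STEP,
               grid_span: float = MODE_GRID_SPAN) -> float:
    """Mode of a sample of log2 ratios: KDE argmax on a fixed grid.

    Gaussian KDE with Silverman bandwidth; the grid spans [-span, span] in
    ``grid_step`` increments, so the mode resolution is grid_step/2.
    """
    values = np.asarray(values, dtype=float)
    if np.allclose(values, values[0]):
        return float(values[0])
    kde = stats.gaussian_kde(values, bw_method="silverman")
    grid = np.arange(-grid_span, grid_span + grid_step / 2, grid_step)
    dens = kde(grid)
    return float(grid[np.argmax(dens)])


def fit_ip_efficiency(signal_matrix: RegionSignalMatrix,
                      promoter_rows, reference: str,
                      min_promoters: int = 50) -> NormalizationFactors:
    """Fit per-sample factors zeroing the promoter log2 fold-change mode.

    For each non-reference sample s the mode m_s of
    ``log2(signal_s / signal_ref)`` over promoter regions is estimated by
    Gaussian-KDE argmax, and the factor is ``2 ** (-m_s)``; the reference
    factor is 1.  Promoters dominate the mode because most of them are
    unaffected, while sensitive enhancers form an asymmetric tail that would
    bias a median.
    """
    sub = signal_matrix.values.loc[promoter_rows]
    if len(sub) < min_promoters:
        raise ValueError(
            f"need >= {min_promoters} promoter rows, got {len(sub)}")
    if reference not in sub.columns:
        raise KeyError(f"reference sample {reference!r} not in matrix")
    ref = sub[reference].to_numpy()
    factors = {}
    modes = {}
    for sample in sub.columns:
        if sample == reference:
            factors[sample] = 1.0
            modes[sample] = 0.0
            continue
        lfc = np.log2(sub[sample].to_numpy() / ref)
        m = _log2_mode(lfc)
        modes[sample] = m
        factors[sample] = float(2.0 ** (-m))
    return NormalizationFactors(
        factors=factors, reference=reference,
        diagnostics={"promoter_mode_log2": modes,
                     "n_promoters": len(sub),
                     "mode_grid_step": MODE_GRID_STEP})


def smooth_profile(lib: TagLibrary, sigma: float = 100.0,
                   step: int = 10) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome Gaussian-smoothed, library-size-normalized profiles.

    Each tag contributes a Gaussian kernel (sd ``sigma`` bp, truncated at
    4 sigma); the profile is tags-per-bp density scaled to per million mapped
    reads, evaluated every ``step`` bp.  Returns
    ``{chrom: (grid_positions, values)}``.
    """
    if step > sigma:
        raise ValueError("step must be <= sigma")
    from scipy.ndimage import gaussian_filter1d

    total = lib.total_mapped
    scale = 1e6 / total if total > 0 else 0.0
    out = {}
    for chrom in lib.chrom_names():
        t = lib.chroms[chrom]
        length = lib.chrom_lengths[chrom]
        n = int(np.ceil(length / step))
        hist = np.zeros(n)
        if len(t.pos):
            idx = np.clip(t.pos // step, 0, n - 1)
            np.add.at(hist, idx, t.count)
        # binned kernel density: per-bp rate = smoothed bin counts / step
        vals = gaussian_filter1d(hist, sigma / step, mode="constant",
                                 truncate=4.0) / step
        grid = np.arange(n) * step + step // 2
        out[chrom] = (grid, vals * scale)
    return out


def write_bedgraph(profile: dict, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(profile):
            grid, vals = profile[chrom]
            step = int(grid[1] - grid[0]) if len(grid) > 1 else 1
            for g, v in zip(grid, vals):
                if v != 0:
                    start = int(g) - step // 2
                    fh.write(f"{chrom}\t{start}\t{start + step}\t{v:.6g}\n")


def write_wig(profile: dict, path) -> None:
    """Fixed-step wiggle output of a smoothed profile."""
    with open(path, "w") as fh:
        for chrom in sorted(profile):
            grid, vals = profile[chrom]
            step = int(grid[1] - grid[0]) if len(grid) > 1 else 1
            start = int(grid[0]) - step // 2 + 1  # wig is 1-based
            fh.write(f"fixedStep chrom={chrom} start={max(start, 1)} "
                     f"step={step} span={step}\n")
            for v in vals:
                fh.write(f"{v:.6g}\n")
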