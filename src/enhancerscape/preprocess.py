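"""Aligned-tag preprocessing: blacklist, complexity, deduplication, shift.

Input samples occasionally show extreme pileups at collapsed repeats and
copy-number artefacts; bins whose input coverage exceeds mean + k*SD over all
genome bins are blacklisted and excluded from every downstream analysis.
Reads are reduced to single-bp tags at half the typical fragment size from
the 5' end, and libraries from low-complexity batches are deduplicated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from enhancerscape.intervals import merge_intervals
from enhancerscape.taglib import ChromTags, TagLibrary

COMPLEXITY_DEDUP_THRESHOLD = 0.90


@dataclass
class Blacklist:
    """High-signal genome bins to exclude; unions of whole 1 kb bins."""

    intervals: pd.DataFrame  # chrom, start, end; merged & sorted
    bin_size: int = 1000
    source_sample: str = ""

    def total_bp(self) -> int:
        if len(self.intervals) == 0:
            return 0
        return int((self.intervals["end"] - self.intervals["start"]).sum())

    def merge_with(self, other: "Blacklist") -> "Blacklist":
        combined = pd.concat([self.intervals, other.intervals], ignore_index=True)
        return Blacklist(
            intervals=merge_intervals(combined),
            bin_size=self.bin_size,
            source_sample=f"{self.source_sample}+{other.source_sample}",
        )


def merge_blacklists(blacklists: list[Blacklist]) -> Blacklist:
    """Union of several per-sample blacklists (no duplicate bins)."""
    if not blacklists:
        return Blacklist(intervals=pd.DataFrame(columns=["chrom", "start", "end"]))
    out = blacklists[0]
    for b in blacklists[1:]:
        out = out.merge_with(b)
    return out


def build_blacklist(input_library: TagLibrary, bin_size: int = 1000,
                    k_sd: float = 3.0, source_sample: str = "") -> Blacklist:
    """Bins with input tag count > mean + k_sd * SD over ALL genome bins.

    Mean and (population) SD are computed over every bin of every chromosome
    in the library, zero-coverage bins included.
    """
    all_counts = []
    per_chrom = {}
    for chrom in input_library.chrom_names():
        counts = input_library.bin_counts(chrom, bin_size)
        per_chrom[chrom] = counts
        all_counts.append(counts)
    if not all_counts or sum(len(c) for c in all_counts) == 0:
        warnings.warn("empty input library: returning empty blacklist")
        return Blacklist(
            intervals=pd.DataFrame(columns=["chrom", "start", "end"]),
            bin_size=bin_size, source_sample=source_sample)
    flat = np.concatenate(all_counts)
    threshold = flat.mean() + k_sd * flat.std()  # population SD
    rows = []
    for chrom in sorted(per_chrom):
        counts = per_chrom[chrom]
        hot = np.nonzero(counts > threshold)[0]
        for i in hot:
            rows.append((chrom, int(i) * bin_size, (int(i) + 1) * bin_size))
    intervals = merge_intervals(pd.DataFrame(rows, columns=["chrom", "start", "end"])) \
        if rows else pd.DataFrame(columns=["chrom", "start", "end"])
    return Blacklist(intervals=intervals, bin_size=bin_size,
                     source_sample=source_sample)


def library_complexity(lib: TagLibrary) -> float:
    """Unique (position, strand) pairs divided by total mapped reads."""
    total = lib.total_mapped
    if total == 0:
        raise ValueError("library_complexity undefined for an empty library")
    return lib.n_records / total


def deduplicate(lib: TagLibrary) -> TagLibrary:
    """Keep at most one read per (position, strand)."""
    chroms = {
        c: ChromTags(t.pos.copy(), t.strand.copy(),
                     np.ones(len(t.count), dtype=np.int64))
        for c, t in lib.chroms.items()
    }
    return TagLibrary(chroms=chroms, chrom_lengths=dict(lib.chrom_lengths),
                      fragment_size=lib.fragment_size)


def maybe_deduplicate(lib: TagLibrary,
                      threshold: float = COMPLEXITY_DEDUP_THRESHOLD) -> TagLibrary:
    """Deduplicate only when batch complexity falls below ``threshold``."""
    if library_complexity(lib) < threshold:
        return deduplicate(lib)
    return lib


def shift_and_mask(lib: TagLibrary, blacklist: Blacklist | None = None) -> TagLibrary:
    """Move tags half a fragment toward the fragment centre; drop blacklisted.

    + strand tags move +fragment_size//2, - strand tags move
    -fragment_size//2 (integer division: half-fragments round toward zero).
    Tags shifted past chromosome ends are clamped to the ends; tags landing
    inside a blacklisted bin are removed.
    """
    half = lib.fragment_size // 2
    chroms: dict[str, ChromTags] = {}
    bl_by_chrom = {}
    if blacklist is not None and len(blacklist.intervals) > 0:
        bl_by_chrom = {
            chrom: (sub["start"].to_numpy(), sub["end"].to_numpy())
            for chrom, sub in blacklist.intervals.groupby("chrom", sort=False)
        }
    for chrom, t in lib.chroms.items():
        new_pos = t.pos + half * t.strand.astype(np.int64)
        length = lib.chrom_lengths.get(chrom)
        if length is not None:
            new_pos = np.clip(new_pos, 0, length - 1)
        keep = np.ones(len(new_pos), dtype=bool)
        if chrom in bl_by_chrom:
            starts, ends = bl_by_chrom[chrom]
            # a tag is masked iff some blacklist interval contains it
            idx = np.searchsorted(starts, new_pos, side="right") - 1
            valid = idx >= 0
            keep[valid] = new_pos[valid] >= ends[idx[valid]]
        pos, strand, count = new_pos[keep], t.strand[keep], t.count[keep]
        order = np.lexsort((strand, pos))
        chroms[chrom] = ChromTags(pos[order], strand[order], count[order])
    return TagLibrary(chroms=chroms, chrom_lengths=dict(lib.chrom_lengths),
                      fragment_size=lib.fragment_size)


@dataclass
class PreprocessResult:
    library: TagLibrary
    complexity: float
    deduplicated: bool
    blacklist: Blacklist | None = None


def preprocess_library(lib: TagLibrary, blacklist: Blacklist | None = None,
                       chrom_whitelist=None,
                       complexity_threshold: float = COMPLEXITY_DEDUP_THRESHOLD
                       ) -> PreprocessResult:
    """Whitelist chromosomes, dedup if low-complexity, shift and mask."""
    if chrom_whitelist is not None:
        lib = lib.subset_chroms(chrom_whitelist)
    cx = library_complexity(lib)
    dedup = cx < complexity_threshold
    if dedup:
        lib = deduplicate(lib)
    shifted = shift_and_mask(lib, blacklist)
    return PreprocessResult(library=shifted, complexity=cx, deduplicated=dedup,
                            blacklist=blacklist)
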