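"""Strand-aware tag libraries: the in-memory form of an aligned ChIP-seq sample.

A *tag* is the single-bp position assigned to an aligned read: its 5' end,
later shifted by half the typical fragment size toward the fragment centre.
Libraries store per-chromosome arrays of (position, strand, multiplicity),
kept sorted by (position, strand); multiplicity counts reads mapped to the
same position and strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ChromTags:
    """Tags on one chromosome. Arrays are parallel and sorted by (pos, strand)."""

    pos: np.ndarray  # int64, 5'-end (or shifted signal) position
    strand: np.ndarray  # int8, +1 / -1
    count: np.ndarray  # int64, multiplicity >= 1

    def total(self) -> int:
        return int(self.count.sum())


def _normalize(pos, strand, count):
    pos = np.asarray(pos, dtype=np.int64)
    strand = np.asarray(strand, dtype=np.int8)
    count = np.asarray(count, dtype=np.int64)
    order = np.lexsort((strand, pos))
    pos, strand, count = pos[order], strand[order], count[order]
    if len(pos) > 1:
        # collapse duplicate (pos, strand) entries by summing multiplicities
        same = (np.diff(pos) == 0) & (np.diff(strand) == 0)
        if same.any():
            group = np.concatenate([[0], np.cumsum(~same)])
            n_groups = group[-1] + 1
            agg = np.zeros(n_groups, dtype=np.int64)
            np.add.at(agg, group, count)
            keep = np.concatenate([[True], ~same])
            pos, strand, count = pos[keep], strand[keep], agg
    return pos, strand, count


@dataclass
class TagLibrary:
    """One sample's tags across chromosomes.

    Parameters
    ----------
    chroms
        Mapping chromosome name -> :class:`ChromTags`.
    chrom_lengths
        Mapping chromosome name -> length in bp.
    fragment_size
        Typical sequenced-fragment size in bp (used by the fragment shift).
    """

    chroms: dict[str, ChromTags] = field(default_factory=dict)
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    fragment_size: int = 160

    @classmethod
    def from_arrays(cls, chrom, pos, strand, count=None, chrom_lengths=None,
                    fragment_size=160) -> "TagLibrary":
        """Build from parallel arrays (one entry per tag record)."""
        chrom = np.asarray(chrom)
        pos = np.asarray(pos, dtype=np.int64)
        strand_arr = np.asarray(
            [1 if s in (1, "+") else -1 for s in strand], dtype=np.int8
        )
        if count is None:
            count = np.ones(len(pos), dtype=np.int64)
        count = np.asarray(count, dtype=np.int64)
        chroms: dict[str, ChromTags] = {}
        for c in pd.unique(chrom):
            m = chrom == c
            p, s, n = _normalize(pos[m], strand_arr[m], count[m])
            chroms[str(c)] = ChromTags(p, s, n)
        if chrom_lengths is None:
            chrom_lengths = {
                c: int(t.pos.max()) + 1 if len(t.pos) else 0
                for c, t in chroms.items()
            }
        return cls(chroms=chroms, chrom_lengths=dict(chrom_lengths),
                   fragment_size=fragment_size)

    @property
    def total_mapped(self) -> int:
        return sum(t.total() for t in self.chroms.values())

    @property
    def n_records(self) -> int:
        return sum(len(t.pos) for t in self.chroms.values())

    def chrom_names(self) -> list[str]:
        return sorted(self.chroms)

    def to_frame(self) -> pd.DataFrame:
        """Flatten to a (chrom, pos, strand, count) frame; strand as '+'/'-'."""
        parts = []
        for c in self.chrom_names():
            t = self.chroms[c]
            parts.append(pd.DataFrame({
                "chrom": c,
                "pos": t.pos,
                "strand": np.where(t.strand > 0, "+", "-"),
                "count": t.count,
            }))
        if not parts:
            return pd.DataFrame(columns=["chrom", "pos", "strand", "count"])
        return pd.concat(parts, ignore_index=True)

    def subset_chroms(self, whitelist) -> "TagLibrary":
        keep = [c for c in self.chrom_names() if c in set(whitelist)]
        return TagLibrary(
            chroms={c: self.chroms[c] for c in keep},
            chrom_lengths={c: self.chrom_lengths[c] for c in keep
                           if c in self.chrom_lengths},
            fragment_size=self.fragment_size,
        )

    # ---- counting -------------------------------------------------------

    def count_in_regions(self, regions: pd.DataFrame) -> np.ndarray:
        """Tag multiplicity sum inside each (chrom, start, end) region."""
        out = np.zeros(len(regions), dtype=np.int64)
        cum_by_chrom = {}
        for c, t in self.chroms.items():
            csum = np.concatenate([[0], np.cumsum(t.count)])
            cum_by_chrom[c] = (t.pos, csum)
        for i, row in enumerate(regions.itertuples(index=False)):
            entry = cum_by_chrom.get(row.chrom)
            if entry is None:
                continue
            pos, csum = entry
            lo = np.searchsorted(pos, row.start, side="left")
            hi = np.searchsorted(pos, row.end, side="left")
            out[i] = csum[hi] - csum[lo]
        return out

    def bin_counts(self, chrom: str, bin_size: int) -> np.ndarray:
        """Tag counts in consecutive [i*bin, (i+1)*bin) bins covering the chrom."""
        length = self.chrom_lengths[chrom]
        n_bins = int(np.ceil(length / bin_size))
        t = self.chroms.get(chrom)
        if t is None or len(t.pos) == 0:
            return np.zeros(n_bins, dtype=np.int64)
        idx = np.clip(t.pos // bin_size, 0, n_bins - 1)
        out = np.zeros(n_bins, dtype=np.int64)
        np.add.at(out, idx, t.count)
        return out


def read_tags_tsv(path, chrom_lengths=None, fragment_size=160) -> TagLibrary:
    """Read a 4-column tag TSV (chrom, pos5prime, strand, count)."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "pos", "strand", "count"],
                     dtype={"chrom": str})
    return TagLibrary.from_arrays(
        df["chrom"].to_numpy(), df["pos"].to_numpy(), df["strand"].to_numpy(),
        df["count"].to_numpy(), chrom_lengths=chrom_lengths,
        fragment_size=fragment_size)


def write_tags_tsv(lib: TagLibrary, path) -> None:
    lib.to_frame().to_csv(path, sep="\t", header=False, index=False)
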