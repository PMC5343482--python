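"""PWM motif scanning and GC-corrected motif enrichment.

Motif occurrence counts in sensitive vs insensitive enhancers are confounded
by base composition: GC-rich motifs match more often in GC-rich regions, and
the two enhancer classes need not have the same GC distribution.  The
correction fits a lowess curve of the per-motif log count ratio
(sensitive/insensitive) against the GC content of the motif PWM across the
whole motif collection, and uses the curve to compute an expected sensitive
count per motif; enrichment is observed/expected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

LOWESS_FRAC = 0.3
LOWESS_IT = 3


@dataclass
class PWMotif:
    """Position weight matrix over {A, C, G, T} with derived GC content."""

    id: str
    matrix: np.ndarray  # (length, 4) probabilities, rows sum to 1
    is_shuffled_control: bool = False

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.id}: rows must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def gc_content(self) -> float:
        """Mean over positions of P(C) + P(G)."""
        return float(self.matrix[:, [1, 2]].sum(axis=1).mean())

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "PWMotif":
        return PWMotif(id=self.id, matrix=self.matrix[::-1, ::-1],
                       is_shuffled_control=self.is_shuffled_control)


def pwm_from_sites(site_sequences, motif_id: str = "motif",
                   pseudo: float = 0.5) -> PWMotif:
    """Build a PWM from aligned site sequences.

    Column probabilities are (count + pseudo) / (n + 4 * pseudo): a small
    pseudo-frequency avoids log-odds infinities for bases unseen at a
    position.
    """
    seqs = [s.upper() for s in site_sequences]
    if not seqs:
        raise ValueError("no site sequences provided")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("site sequences must have equal length")
    counts = np.zeros((length, 4))
    for s in seqs:
        for i, base in enumerate(s):
            counts[i, _BASE_INDEX[base]] += 1
    matrix = (counts + pseudo) / (len(seqs) + 4 * pseudo)
    return PWMotif(id=motif_id, matrix=matrix)


def encode_sequence(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_INDEX[b] for b in seq.upper()), dtype=np.int8,
                       count=len(seq))


SCORE_GRANULARITY = 0.05  # bits; log-odds discretization for exact p-values


def _discretize_log_odds(matrix: np.ndarray, background: np.ndarray,
                         granularity: float = SCORE_GRANULARITY) -> np.ndarray:
    """Integer log-odds (units of ``granularity`` bits) with zero-prob guard."""
    log_odds = np.log2(np.clip(matrix, 1e-9, None) / background)
    return np.round(log_odds / granularity).astype(np.int64)


def _score_pvalue_table(q: np.ndarray,
                        background: np.ndarray) -> tuple[int, np.ndarray]:
    """Exact upper-tail distribution of the integer match score.

    Builds P(total score) by dynamic programming over positions under the
    background model.  Returns (base, tail) where ``tail[s - base]`` is
    P(score >= s) for integer scores s.
    """
    dist = np.array([1.0])
    base = 0
    for row in q:
        new_lo = base + row.min()
        new_hi = base + len(dist) - 1 + row.max()
        new = np.zeros(new_hi - new_lo + 1)
        for k in range(4):
            shift = base + row[k] - new_lo
            new[shift:shift + len(dist)] += background[k] * dist
        dist = new
        base = new_lo
    tail = np.cumsum(dist[::-1])[::-1]
    return base, tail


def scan_genome(pwm: PWMotif, genome_sequences: dict[str, str],
                pvalue_threshold: float = 1e-4,
                background: np.ndarray | None = None) -> pd.DataFrame:
    """Log-odds scan of both strands against a mononucleotide background.

    ``background`` defaults to the genome's mononucleotide frequencies.
    Scores are discretized to 0.05-bit units and p-values are exact for the
    discretized score under the background model.  Returns
    (chrom, pos, strand, score, p) sorted by position; ``pos`` is the
    0-based start of the match on the + strand.
    """
    if not genome_sequences:
        raise ValueError("empty genome")
    if background is None:
        counts = np.zeros(4)
        for seq in genome_sequences.values():
            enc = encode_sequence(seq)
            counts += np.bincount(enc, minlength=4)
        background = counts / counts.sum()
    background = np.asarray(background, dtype=float)
    q_fwd = _discretize_log_odds(pwm.matrix, background)
    q_rev = _discretize_log_odds(pwm.reverse_complement().matrix, background)
    tables = {1: _score_pvalue_table(q_fwd, background),
              -1: _score_pvalue_table(q_rev, background)}

    def pvalue(int_scores, strand):
        base, tail = tables[strand]
        idx = np.clip(int_scores - base, 0, len(tail) - 1)
        out = tail[idx]
        out[int_scores - base >= len(tail)] = 0.0
        out[int_scores < base] = 1.0
        return out

    rows = []
    L = pwm.length
    for chrom, seq in genome_sequences.items():
        enc = encode_sequence(seq)
        if len(enc) < L:
            continue
        n_windows = len(enc) - L + 1
        for strand, q in ((1, q_fwd), (-1, q_rev)):
            scores = np.zeros(n_windows, dtype=np.int64)
            for j in range(L):
                scores += q[j, enc[j:j + n_windows]]
            ps = pvalue(scores, strand)
            hits = np.nonzero(ps <= pvalue_threshold)[0]
            for h in hits:
                rows.append((chrom, int(h), strand,
                             float(scores[h] * SCORE_GRANULARITY),
                             float(ps[h])))
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "score", "p"]) \
        .sort_values(["chrom", "pos"]).reset_index(drop=True)


def match_count_threshold(candidates: pd.DataFrame,
                          target_n: int) -> pd.DataFrame:
    """Keep the best matches up to the largest p cutoff with <= target_n kept.

    All matches tied at a p-value that would push the count past ``target_n``
    are dropped together.
    """
    if target_n <= 0 or len(candidates) == 0:
        return candidates.iloc[0:0]
    ps = np.sort(candidates["p"].to_numpy())
    cutoff = None
    for p in np.unique(ps):
        if (ps <= p).sum() <= target_n:
            cutoff = p
        else:
            break
    if cutoff is None:
        return candidates.iloc[0:0]
    return candidates[candidates["p"] <= cutoff].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Enhancer sensitivity classes
# ---------------------------------------------------------------------------

def classify_enhancer_sensitivity(fold_changes, mode: str = "mef",
                                  direction: str = "loss") -> str:
    """Label an enhancer sensitive / insensitive / neither from fold-changes.

    mef mode (two replicate fold-changes, mutant/WT):
      sensitive  — > 2x reduction in each replicate and > 4x reduction on
                   average (geometric mean);
      insensitive — < 2x change in each replicate and < 1.5 fold-change on
                   average.
    human mode (single fold-change): sensitive when the change in the
    ``direction`` of interest exceeds 2x; insensitive when the fold-change
    lies within (1/1.5, 1.5).
    """
    fc = np.asarray(fold_changes, dtype=float)
    if np.any(fc <= 0):
        raise ValueError("fold-changes must be positive")
    if mode == "human":
        if fc.size != 1:
            raise ValueError("human mode expects a single fold-change")
        v = float(fc[0])
        effect = v if direction == "gain" else 1.0 / v
        if effect > 2:
            return "sensitive"
        if 1 / 1.5 < v < 1.5:
            return "insensitive"
        return "neither"
    if mode == "mef":
        if fc.size != 2:
            raise ValueError("mef mode expects two replicate fold-changes")
        if direction == "gain":
            fc = 1.0 / fc
        gm = float(np.sqrt(fc[0] * fc[1]))
        if np.all(fc < 0.5) and gm < 0.25:
            return "sensitive"
        if np.all((fc > 0.5) & (fc < 2.0)) and (1 / 1.5 < gm < 1.5):
            return "insensitive"
        return "neither"
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# GC-corrected enrichment
# ---------------------------------------------------------------------------

def count_matches_in_regions(matches: pd.DataFrame,
                             regions: pd.DataFrame) -> int:
    """Number of motif match positions falling inside any of the regions."""
    total = 0
    by_chrom = {c: (sub["start"].to_numpy(), sub["end"].to_numpy())
                for c, sub in
                regions.sort_values(["chrom", "start"]).groupby("chrom",
                                                                sort=False)}
    for chrom, sub in matches.groupby("chrom", sort=False):
        feats = by_chrom.get(chrom)
        if feats is None:
            continue
        starts, ends = feats
        pos = sub["pos"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        valid = idx >= 0
        total += int((pos[valid] < ends[idx[valid]]).sum())
    return total


def gc_corrected_enrichment(motif_maps: dict[str, pd.DataFrame],
                            pwms: dict[str, PWMotif],
                            sensitive_regions: pd.DataFrame,
                            insensitive_regions: pd.DataFrame,
                            pseudocount: float = 1.0,
                            min_motifs: int = 20,
                            frac: float = LOWESS_FRAC,
                            it: int = LOWESS_IT) -> pd.DataFrame:
    """GC-corrected motif enrichment in sensitive vs insensitive enhancers.

    Per motif, occurrences are counted in each region class; a lowess curve
    of log((sensitive + pc) / (insensitive + pc)) against PWM GC content is
    fitted across motifs; the expected sensitive count at a motif's GC is
    (insensitive + pc) * exp(curve), and enrichment is
    (observed + pc) / expected.  In the pc -> 0 limit the enrichment is
    exactly invariant to uniform count rescaling.

    Returns a frame (motif, gc_content, observed_sensitive,
    observed_insensitive, expected_sensitive, enrichment).
    """
    ids = sorted(motif_maps)
    if len(ids) == 0:
        raise ValueError("no motif maps supplied")
    obs_s = np.array([count_matches_in_regions(motif_maps[m], sensitive_regions)
                      for m in ids], dtype=float)
    obs_i = np.array([count_matches_in_regions(motif_maps[m],
                                               insensitive_regions)
                      for m in ids], dtype=float)
    if obs_s.sum() == 0 and obs_i.sum() == 0:
        raise ValueError("all motif counts are zero in both region classes")
    usable = obs_i > 0
    if usable.sum() < min_motifs:
        raise ValueError(
            f"need >= {min_motifs} motifs with non-zero insensitive counts")
    gc = np.array([pwms[m].gc_content for m in ids])
    log_ratio = np.log((obs_s + pseudocount) / (obs_i + pseudocount))
    # lowess is fitted over all motifs ordered by GC; the fit at each motif's
    # own GC is the curve value used for its expectation
    fitted = lowess(log_ratio, gc, frac=frac, it=it, return_sorted=False)
    expected = (obs_i + pseudocount) * np.exp(fitted)
    enrich = (obs_s + pseudocount) / expected
    return pd.DataFrame({
        "motif": ids,
        "gc_content": gc,
        "observed_sensitive": obs_s.astype(int),
        "observed_insensitive": obs_i.astype(int),
        "expected_sensitive": expected,
        "enrichment": enrich,
    })


# ---------------------------------------------------------------------------
# PWM similarity
# ---------------------------------------------------------------------------

def motif_similarity(pwm_a: PWMotif, pwm_b: PWMotif,
                     max_offset: int = 3) -> float:
    """Pearson correlation between PWMs over the best ungapped alignment.

    Offsets up to ``max_offset`` columns and both orientations of the second
    motif are searched; unmatched columns are padded with the uniform
    background 0.25.
    """
    best = -1.0
    for b in (pwm_b, pwm_b.reverse_complement()):
        for offset in range(-max_offset, max_offset + 1):
            la, lb = pwm_a.length, b.length
            lo = min(0, offset)
            hi = max(la, offset + lb)
            span = hi - lo
            mat_a = np.full((span, 4), 0.25)
            mat_b = np.full((span, 4), 0.25)
            mat_a[-lo:-lo + la] = pwm_a.matrix
            mat_b[offset - lo:offset - lo + lb] = b.matrix
            va, vb = mat_a.ravel(), mat_b.ravel()
            if va.std() == 0 or vb.std() == 0:
                continue
            r = float(np.corrcoef(va, vb)[0, 1])
            best = max(best, r)
    return best


# ---------------------------------------------------------------------------
# MEME minimal motif format I/O
# ---------------------------------------------------------------------------

def read_meme(path) -> dict[str, PWMotif]:
    """Read PWMs from a MEME minimal motif format file."""
    pwms: dict[str, PWMotif] = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            name = line.split()[1]
            rows = []
            i += 1
            while i < len(lines) and not lines[i].strip().startswith(
                    "letter-probability"):
                i += 1
            i += 1
            while i < len(lines):
                parts = lines[i].split()
                if len(parts) != 4:
                    break
                try:
                    rows.append([float(x) for x in parts])
                except ValueError:
                    break
                i += 1
            if rows:
                mat = np.array(rows)
                mat = mat / mat.sum(axis=1, keepdims=True)
                pwms[name] = PWMotif(id=name, matrix=mat)
        else:
            i += 1
    return pwms


def write_meme(pwms: dict[str, PWMotif], path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("strands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for name in sorted(pwms):
            pwm = pwms[name]
            fh.write(f"MOTIF {name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {pwm.length}\n")
            for row in pwm.matrix:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")
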