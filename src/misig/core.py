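"""Pairwise ANI and AF between gene sets via bidirectional best hits.

ANI between two genomes is the (length-weighted) mean nucleotide identity of
orthologous genes, with orthologs operationalised as bidirectional best hits
(BBHs): gene pairs that are each other's best local-alignment hit and show at
least 70% identity over at least 70% of the shorter gene.  AF in the 1->2
direction is the summed length of genome 1's BBH genes divided by genome 1's
total protein-coding length.  Structural RNA genes must be filtered out
upstream (``misig.io.filter_structural_rnas``) so they cannot inflate either
index.

Alignment model
---------------
Local alignment with affine gaps (Smith-Waterman/Gotoh), default scoring
match +1, mismatch -1, gap open -5, gap extend -2 (the first gap column is
charged the open penalty).  Because several alignments can share the optimal
score while differing in identity, the aligner optimises a lexicographic
objective -- maximal score, then maximal matches, then fewest alignment
columns -- packed into a single integer DP so the reported identity is
canonical and deterministic.  Both orientations of the target gene are tried
(gene callers emit either strand) and the better-scoring one is used.
IUPAC ambiguity codes never match anything, including themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from numba import njit

from .errors import MisigError
from .io import FeatureClass, Gene, GeneSet, PairwiseScore

__all__ = [
    "MisiConfig",
    "AlignmentHit",
    "BBHPair",
    "align_genes",
    "best_hits",
    "bidirectional_best_hits",
    "compute_pairwise_score",
]


@dataclass(frozen=True, slots=True)
class MisiConfig:
    """Thresholds and scoring for ANI/AF computation.

    ``identity_threshold`` / ``coverage_threshold`` implement the 70%/70% hit
    qualification rule.  ``min_bbh`` guards against reporting an ANI averaged
    over a handful of genes: below it the ANI fields are undefined while AF is
    still reported.  ``prescreen_k`` (off by default) skips gene pairs sharing
    no k-mer in the tested orientation; results are identical to the exhaustive
    path whenever every qualifying hit shares a k-mer, which holds with
    overwhelming probability at the 70% identity floor for k=12.
    """

    identity_threshold: float = 0.70
    coverage_threshold: float = 0.70
    min_bbh: int = 5
    ani_weighting: Literal["length_weighted", "unweighted"] = "length_weighted"
    match: int = 1
    mismatch: int = 1
    gap_open: int = 5
    gap_extend: int = 2
    prescreen_k: int | None = None

    def __post_init__(self) -> None:
        for name in ("identity_threshold", "coverage_threshold"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise MisigError(f"invalid config: {name}={v} not in (0, 1]")
        if self.min_bbh < 1:
            raise MisigError(f"invalid config: min_bbh={self.min_bbh} < 1")
        if self.ani_weighting not in ("length_weighted", "unweighted"):
            raise MisigError(f"invalid config: ani_weighting={self.ani_weighting!r}")
        if min(self.match, self.mismatch, self.gap_open, self.gap_extend) < 0:
            raise MisigError("invalid config: scoring parameters must be non-negative")


@dataclass(frozen=True, slots=True)
class AlignmentHit:
    query_gene_id: str
    target_gene_id: str
    identity: float           # matches / alignment columns
    aligned_fraction_shorter: float
    alignment_length: int     # alignment columns
    score: int                # classic alignment score
    matches: int
    reverse_complement: bool


@dataclass(frozen=True, slots=True)
class BBHPair:
    gene_id_a: str
    gene_id_b: str
    identity: float
    length_a: int
    length_b: int
    alignment_length: int


# ---------------------------------------------------------------------------
# Sequence encoding
# ---------------------------------------------------------------------------

_CODE = {c: i for i, c in enumerate("ACGTRYSWKMBDHVN")}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE[c] for c in seq], dtype=np.int8)


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Canonical local Gotoh alignment (packed lexicographic objective)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _gotoh_canonical(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    """Local affine alignment maximising (score, matches, -columns).

    The three criteria are packed into one int64 weight
    ``W = K1*score + K2*matches - columns`` with ``K2`` larger than any column
    count and ``K1`` larger than any ``K2*matches - columns`` range, so integer
    comparison of W orders alignments lexicographically.  Returns
    (matches, mismatches, gap_columns, gap_opens, columns,
     a_start, a_end, b_start, b_end) of the canonical alignment; all zeros if
    the best local alignment is empty.
    """
    n = a.shape[0]
    m = b.shape[0]
    K2 = np.int64(n + m + 1)
    K1 = K2 * np.int64(min(n, m) * match + 2)

    w_match = K1 * match + K2 - 1
    w_mismatch = -K1 * mismatch - 1
    w_open = K1 * gap_open + 1     # subtracted
    w_ext = K1 * gap_extend + 1    # subtracted

    NEG = np.int64(-(1 << 60))
    H = np.full((n + 1, m + 1), np.int64(0))
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)

    best = np.int64(0)
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            e = max(H[i, j - 1] - w_open, E[i, j - 1] - w_ext)
            f = max(H[i - 1, j] - w_open, F[i - 1, j] - w_ext)
            E[i, j] = e
            F[i, j] = f
            if ai == b[j - 1] and ai < 4:
                sub = w_match
            else:
                sub = w_mismatch
            h = H[i - 1, j - 1] + sub
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = np.int64(0)
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    if best <= 0:
        return 0, 0, 0, 0, 0, 0, 0, 0, 0

    # Traceback (prefer diagonal, then horizontal gap, then vertical gap;
    # ties here have identical packed objectives).
    matches = 0
    mismatches = 0
    gap_cols = 0
    opens = 0
    i = bi
    j = bj
    a_end = bi
    b_end = bj
    state = 0  # 0=H, 1=E (gap in a, consumes b), 2=F (gap in b, consumes a)
    while True:
        if state == 0:
            if H[i, j] == 0:
                break
            if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                sub = w_match
                is_match = True
            else:
                sub = w_mismatch
                is_match = False
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + sub:
                if is_match:
                    matches += 1
                else:
                    mismatches += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            gap_cols += 1
            if E[i, j] == H[i, j - 1] - w_open:
                opens += 1
                state = 0
            j -= 1
        else:
            gap_cols += 1
            if F[i, j] == H[i - 1, j] - w_open:
                opens += 1
                state = 0
            i -= 1
    cols = matches + mismatches + gap_cols
    return matches, mismatches, gap_cols, opens, cols, i, a_end, j, b_end


def _warmup() -> None:
    """Trigger numba compilation once at import-cost-sensitive call sites."""
    _gotoh_canonical(
        np.array([0, 1, 2, 3], dtype=np.int8),
        np.array([0, 1, 2, 3], dtype=np.int8),
        1, 1, 5, 2,
    )


def _align_encoded(
    qa: np.ndarray, qb: np.ndarray, cfg: MisiConfig
) -> tuple[int, int, int, int, int, int, int, int, int]:
    return _gotoh_canonical(qa, qb, cfg.match, cfg.mismatch, cfg.gap_open, cfg.gap_extend)


def _packed_weight(matches: int, mismatches: int, gap_cols: int, opens: int,
                   cols: int, n: int, m: int, cfg: MisiConfig) -> int:
    """Recompute the packed objective of an alignment (for orientation choice)."""
    if cols == 0:
        return 0
    K2 = n + m + 1
    K1 = K2 * (min(n, m) * cfg.match + 2)
    score = (
        cfg.match * matches
        - cfg.mismatch * mismatches
        - cfg.gap_open * opens
        - cfg.gap_extend * (gap_cols - opens)
    )
    return K1 * score + K2 * matches - cols


def align_genes(
    a: Gene,
    b: Gene,
    cfg: MisiConfig | None = None,
    _orientations: tuple[bool, bool] = (True, True),
) -> AlignmentHit | None:
    """Best qualifying local alignment of two genes, or None.

    Returns None when the best alignment falls below the identity or
    shorter-gene coverage threshold (a valid outcome, not an error).
    """
    cfg = cfg or MisiConfig()
    ea = _encode(a.sequence)
    eb_f = _encode(b.sequence)
    candidates = []
    if _orientations[0]:
        candidates.append((False, _align_encoded(ea, eb_f, cfg)))
    if _orientations[1]:
        eb_r = _encode(_revcomp(b.sequence))
        candidates.append((True, _align_encoded(ea, eb_r, cfg)))
    if not candidates:
        return None

    best_rc, best_res = candidates[0]
    best_w = _packed_weight(best_res[0], best_res[1], best_res[2], best_res[3],
                            best_res[4], len(ea), len(eb_f), cfg)
    for rc, res in candidates[1:]:
        w = _packed_weight(res[0], res[1], res[2], res[3], res[4],
                           len(ea), len(eb_f), cfg)
        if w > best_w:
            best_rc, best_res, best_w = rc, res, w

    matches, mismatches, gap_cols, opens, cols, a0, a1, b0, b1 = best_res
    if cols == 0:
        return None
    identity = matches / cols
    if a.length <= b.length:
        span = a1 - a0
        shorter_len = a.length
    else:
        span = b1 - b0
        shorter_len = b.length
    afs = span / shorter_len
    if identity < cfg.identity_threshold or afs < cfg.coverage_threshold:
        return None
    score = (
        cfg.match * matches
        - cfg.mismatch * mismatches
        - cfg.gap_open * opens
        - cfg.gap_extend * (gap_cols - opens)
    )
    return AlignmentHit(
        query_gene_id=a.gene_id,
        target_gene_id=b.gene_id,
        identity=identity,
        aligned_fraction_shorter=afs,
        alignment_length=cols,
        score=score,
        matches=matches,
        reverse_complement=best_rc,
    )


# ---------------------------------------------------------------------------
# Best hits and BBHs
# ---------------------------------------------------------------------------

def _coding(gs: GeneSet) -> list[Gene]:
    genes = [g for g in gs.genes if g.feature_class is FeatureClass.protein_coding]
    if not genes:
        raise MisigError(f"no protein-coding genes in genome {gs.genome_id!r}")
    return genes


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _better(new: AlignmentHit, cur: AlignmentHit) -> bool:
    """Best-hit ordering: score, then identity, then alignment length, then
    lexicographically smaller target gene id."""
    a = (new.score, new.identity, new.alignment_length)
    b = (cur.score, cur.identity, cur.alignment_length)
    if a != b:
        return a > b
    return new.target_gene_id < cur.target_gene_id


def best_hits(query: GeneSet, target: GeneSet, cfg: MisiConfig | None = None) -> dict[str, AlignmentHit]:
    """Map each query gene id to its best qualifying hit in ``target``."""
    cfg = cfg or MisiConfig()
    q_genes = _coding(query)
    t_genes = _coding(target)

    use_prescreen = cfg.prescreen_k is not None
    if use_prescreen:
        k = cfg.prescreen_k
        t_kmers = [_kmer_set(g.sequence, k) for g in t_genes]
        q_kmers_f = [_kmer_set(g.sequence, k) for g in q_genes]
        q_kmers_r = [_kmer_set(_revcomp(g.sequence), k) for g in q_genes]

    hits: dict[str, AlignmentHit] = {}
    for qi, qg in enumerate(q_genes):
        best: AlignmentHit | None = None
        for ti, tg in enumerate(t_genes):
            if use_prescreen:
                fwd_ok = not q_kmers_f[qi].isdisjoint(t_kmers[ti])
                rev_ok = not q_kmers_r[qi].isdisjoint(t_kmers[ti])
                if not (fwd_ok or rev_ok):
                    continue
                orientations = (fwd_ok, rev_ok)
            else:
                orientations = (True, True)
            hit = align_genes(qg, tg, cfg, _orientations=orientations)
            if hit is not None and (best is None or _better(hit, best)):
                best = hit
        if best is not None:
            hits[qg.gene_id] = best
    return hits


def bidirectional_best_hits(
    a: GeneSet, b: GeneSet, cfg: MisiConfig | None = None
) -> list[BBHPair]:
    """Gene pairs that are reciprocally each other's best qualifying hit."""
    cfg = cfg or MisiConfig()
    fwd = best_hits(a, b, cfg)
    rev = best_hits(b, a, cfg)
    lengths_a = {g.gene_id: g.length for g in a.genes}
    lengths_b = {g.gene_id: g.length for g in b.genes}
    pairs: list[BBHPair] = []
    for ga, hit in fwd.items():
        back = rev.get(hit.target_gene_id)
        if back is not None and back.target_gene_id == ga:
            pairs.append(
                BBHPair(
                    gene_id_a=ga,
                    gene_id_b=hit.target_gene_id,
                    identity=hit.identity,
                    length_a=lengths_a[ga],
                    length_b=lengths_b[hit.target_gene_id],
                    alignment_length=hit.alignment_length,
                )
            )
    pairs.sort(key=lambda p: p.gene_id_a)
    return pairs


def compute_pairwise_score(
    a: GeneSet, b: GeneSet, cfg: MisiConfig | None = None
) -> PairwiseScore:
    """Directional and averaged ANI/AF between two genomes.

    ANI is averaged over BBH identities (length-weighted by alignment columns
    by default); AF in each direction divides the summed length of that
    genome's BBH genes by its total protein-coding length.  With fewer than
    ``cfg.min_bbh`` BBHs the ANI fields are undefined (None) while AF is still
    reported.
    """
    cfg = cfg or MisiConfig()
    coding_a = _coding(a)
    coding_b = _coding(b)
    pairs = bidirectional_best_hits(a, b, cfg)
    n_bbh = len(pairs)
    total_a = sum(g.length for g in coding_a)
    total_b = sum(g.length for g in coding_b)
    af_12 = sum(p.length_a for p in pairs) / total_a
    af_21 = sum(p.length_b for p in pairs) / total_b
    defined = n_bbh >= cfg.min_bbh
    if defined:
        if cfg.ani_weighting == "length_weighted":
            wsum = sum(p.alignment_length for p in pairs)
            ani = 100.0 * sum(p.identity * p.alignment_length for p in pairs) / wsum
        else:
            ani = 100.0 * sum(p.identity for p in pairs) / n_bbh
        ani_12 = ani_21 = ani
    else:
        ani_12 = ani_21 = None
    return PairwiseScore(
        genome_a=a.genome_id,
        genome_b=b.genome_id,
        ani_12=ani_12,
        ani_21=ani_21,
        af_12=af_12,
        af_21=af_21,
        n_bbh=n_bbh,
        defined=defined,
    )
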