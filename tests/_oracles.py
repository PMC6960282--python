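"""Independent brute-force oracles used only by the test suite.

Deliberately written without numpy/numba and without reusing any code from
the package: a plain tuple-based dynamic program for local affine-gap
alignment under the same lexicographic objective (score, matches, fewest
columns), an all-pairs BBH/ANI/AF scorer built on it, and a full-enumeration
Mann-Whitney permutation test.
"""

from __future__ import annotations

from itertools import combinations

_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
_ACGT = set("ACGT")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def oracle_align_oriented(a: str, b: str, match=1, mismatch=1, gap_open=5, gap_extend=2):
    """Local Gotoh DP maximising (score, matches, -columns) tuples.

    Returns None for an empty optimum, else a dict with matches, mismatches,
    gap columns, opens, columns, score and the aligned spans on a and b.
    Cell records are tuples (score, matches, -cols, mismatches, gapcols,
    opens, i0, j0); only the first three participate in the objective, the
    rest ride along for reporting.
    """
    n, m = len(a), len(b)
    NEG = (-10**9, 0, 0, 0, 0, 0, 0, 0)

    def add_col(rec, ds, dm, dx, dg, do):
        s, mt, nc, x, g, o, i0, j0 = rec
        return (s + ds, mt + dm, nc - 1, x + dx, g + dg, o + do, i0, j0)

    H = [[NEG] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = None
    best_pos = None
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(
                add_col(H[i][j - 1], -gap_open, 0, 0, 1, 1),
                add_col(E[i][j - 1], -gap_extend, 0, 0, 1, 0),
                key=lambda r: r[:3],
            )
            F[i][j] = max(
                add_col(H[i - 1][j], -gap_open, 0, 0, 1, 1),
                add_col(F[i - 1][j], -gap_extend, 0, 0, 1, 0),
                key=lambda r: r[:3],
            )
            ca, cb = a[i - 1], b[j - 1]
            if ca == cb and ca in _ACGT:
                ds, dm, dx = match, 1, 0
            else:
                ds, dm, dx = -mismatch, 0, 1
            fresh = (0, 0, 0, 0, 0, 0, i - 1, j - 1)
            diag = max(H[i - 1][j - 1], fresh, key=lambda r: r[:3])
            cand = [add_col(diag, ds, dm, dx, 0, 0), E[i][j], F[i][j]]
            H[i][j] = max(cand, key=lambda r: r[:3])
            if H[i][j][0] > 0 and (best is None or H[i][j][:3] > best[:3]):
                best = H[i][j]
                best_pos = (i, j)
    if best is None:
        return None
    s, mt, nc, x, g, o, i0, j0 = best
    i, j = best_pos
    return {
        "score": s,
        "matches": mt,
        "mismatches": x,
        "gap_cols": g,
        "opens": o,
        "columns": -nc,
        "a_span": i - i0,
        "b_span": j - j0,
    }


def oracle_align(a: str, b: str, identity_threshold=0.70, coverage_threshold=0.70,
                 match=1, mismatch=1, gap_open=5, gap_extend=2):
    """Both orientations, qualification thresholds applied; None if no hit."""
    fw = oracle_align_oriented(a, b, match, mismatch, gap_open, gap_extend)
    rv = oracle_align_oriented(a, _revcomp(b), match, mismatch, gap_open, gap_extend)

    def key(r):
        return (-10**9, 0, 0) if r is None else (r["score"], r["matches"], -r["columns"])

    res = fw if key(fw) >= key(rv) else rv
    if res is None:
        return None
    identity = res["matches"] / res["columns"]
    span = res["a_span"] if len(a) <= len(b) else res["b_span"]
    afs = span / min(len(a), len(b))
    if identity < identity_threshold or afs < coverage_threshold:
        return None
    return {**res, "identity": identity, "aligned_fraction_shorter": afs}


def oracle_pairwise(genes_a, genes_b, identity_threshold=0.70, coverage_threshold=0.70,
                    min_bbh=1, length_weighted=True):
    """All-vs-all BBH ANI/AF on {gene_id: sequence} dicts.

    Returns (ani or None, af_12, af_21, n_bbh).
    """
    def hits(src, dst):
        out = {}
        for qid, qseq in src.items():
            best_key = None
            best_tid = None
            best_res = None
            for tid, tseq in dst.items():
                r = oracle_align(qseq, tseq, identity_threshold, coverage_threshold)
                if r is None:
                    continue
                k = (r["score"], r["identity"], r["columns"])
                if best_key is None or k > best_key or (k == best_key and tid < best_tid):
                    best_key, best_tid, best_res = k, tid, r
            if best_tid is not None:
                out[qid] = (best_tid, best_res)
        return out

    fwd = hits(genes_a, genes_b)
    rev = hits(genes_b, genes_a)
    bbh = []
    for ga, (gb, res) in fwd.items():
        if gb in rev and rev[gb][0] == ga:
            bbh.append((ga, gb, res))
    n = len(bbh)
    af_12 = sum(len(genes_a[ga]) for ga, _, _ in bbh) / sum(map(len, genes_a.values()))
    af_21 = sum(len(genes_b[gb]) for _, gb, _ in bbh) / sum(map(len, genes_b.values()))
    if n >= min_bbh and n > 0:
        if length_weighted:
            w = sum(r["columns"] for _, _, r in bbh)
            ani = 100.0 * sum(r["identity"] * r["columns"] for _, _, r in bbh) / w
        else:
            ani = 100.0 * sum(r["identity"] for _, _, r in bbh) / n
    else:
        ani = None
    return ani, af_12, af_21, n


def permutation_mannwhitney_p(x, y):
    """Two-sided exact p by enumerating every group assignment.

    U counts pairs (xi > yj) with half-credit for ties; the p-value is the
    null fraction of assignments at least as far from n1*n2/2 as observed.
    """
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_of(idx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        return sum(
            1.0 if xv > yv else (0.5 if xv == yv else 0.0) for xv in xs for yv in ys
        )

    u_obs = u_of(set(range(n1)))
    mu = n1 * (len(pooled) - n1) / 2.0
    dev = abs(u_obs - mu)
    total = 0
    extreme = 0
    for idx in combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_of(set(idx)) - mu) >= dev - 1e-9:
            extreme += 1
    return extreme / total
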