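"""Independent brute-force oracles used to validate the implementation.

These re-derive every definition from first principles — a pure-Python
affine-gap Smith-Waterman with traceback, a literal reciprocal-best-hit
enumeration, and an exhaustive synteny-interval enumeration — and share no
code with the package's computational paths.
"""

from __future__ import annotations

import math

NEG = float("-inf")


def sw_affine_score(a: str, b: str, score, gap_open: float, gap_extend: float) -> float:
    """Optimal local alignment score, affine gaps (open+k*extend for length k)."""
    n, m = len(a), len(b)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = score(a[i - 1], b[j - 1])
            M[i][j] = max(0.0, M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - gap_open - gap_extend, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - gap_open - gap_extend, Y[i][j - 1] - gap_extend)
            best = max(best, M[i][j])
    return best


def sw_affine_align(a: str, b: str, score, gap_open: float, gap_extend: float):
    """Score plus one optimal alignment's matched index pairs (0-based).

    Returns (score, pairs); pairs is empty when no positive-scoring local
    alignment exists.
    """
    n, m = len(a), len(b)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    ptr_m = [[None] * (m + 1) for _ in range(n + 1)]  # origin of M cell
    ptr_x = [[None] * (m + 1) for _ in range(n + 1)]
    ptr_y = [[None] * (m + 1) for _ in range(n + 1)]
    best, best_cell = 0.0, None
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = score(a[i - 1], b[j - 1])
            options = [
                (0.0, "start"),
                (M[i - 1][j - 1], "M"),
                (X[i - 1][j - 1], "X"),
                (Y[i - 1][j - 1], "Y"),
            ]
            base, origin = max(options, key=lambda t: t[0])
            M[i][j] = base + s
            ptr_m[i][j] = origin
            xo = [
                (M[i - 1][j] - gap_open - gap_extend, "M"),
                (X[i - 1][j] - gap_extend, "X"),
            ]
            X[i][j], ptr_x[i][j] = max(xo, key=lambda t: t[0])
            yo = [
                (M[i][j - 1] - gap_open - gap_extend, "M"),
                (Y[i][j - 1] - gap_extend, "Y"),
            ]
            Y[i][j], ptr_y[i][j] = max(yo, key=lambda t: t[0])
            if M[i][j] > best:
                best, best_cell = M[i][j], (i, j)
    if best <= 0 or best_cell is None:
        return 0.0, []
    pairs = []
    i, j = best_cell
    state = "M"
    while True:
        if state == "M":
            pairs.append((i - 1, j - 1))
            origin = ptr_m[i][j]
            i, j = i - 1, j - 1
            if origin == "start":
                break
            state = origin
        elif state == "X":
            origin = ptr_x[i][j]
            i = i - 1
            state = origin
        else:
            origin = ptr_y[i][j]
            j = j - 1
            state = origin
    pairs.reverse()
    return best, pairs


def evalue(raw_score: float, m: int, n: int, lam: float, K: float) -> float:
    return K * m * n * math.exp(-lam * raw_score)


def bit_score(raw_score: float, lam: float, K: float) -> float:
    return (lam * raw_score - math.log(K)) / math.log(2)


def rbh_oracle(proteome_a, proteome_b, policy, matrix, gap_open=11, gap_extend=1):
    """Literal reciprocal-best-hit enumeration.

    Scores every cross pair with the oracle DP, applies the E-value and
    either-sequence coverage filters per direction, takes tied best-hit
    sets, and intersects reciprocally. Returns {query_gene: set(subjects)}.
    """

    def score(x, y):
        return float(matrix[x, y])

    db_a = sum(len(p.sequence) for p in proteome_a)
    db_b = sum(len(p.sequence) for p in proteome_b)
    info = {}
    for pa in proteome_a:
        for pb in proteome_b:
            s, pairs = sw_affine_align(pa.sequence, pb.sequence, score, gap_open, gap_extend)
            if not pairs:
                info[(pa.gene_id, pb.gene_id)] = None
                continue
            qspan = pairs[-1][0] - pairs[0][0] + 1
            sspan = pairs[-1][1] - pairs[0][1] + 1
            info[(pa.gene_id, pb.gene_id)] = {
                "raw": s,
                "bit": bit_score(s, 0.267, 0.041),
                "cov_a": qspan / len(pa.sequence),
                "cov_b": sspan / len(pb.sequence),
            }

    def surviving(query, targets, db_len, side):
        out = {}
        for t in targets:
            key = (query, t) if side == "a" else (t, query)
            rec = info[key]
            if rec is None:
                continue
            qlen = next(
                len(p.sequence)
                for p in (proteome_a if side == "a" else proteome_b)
                if p.gene_id == query
            )
            ev = evalue(rec["raw"], qlen, db_len, 0.267, 0.041)
            if ev > policy.max_evalue:
                continue
            if max(rec["cov_a"], rec["cov_b"]) < policy.min_coverage:
                continue
            out[t] = rec["bit"]
        return out

    def best_set(scores, tol):
        if not scores:
            return set()
        top = max(scores.values())
        return {g for g, s in scores.items() if s >= top * (1 - tol)}

    tol = policy.effective_tie_tolerance
    a_ids = [p.gene_id for p in proteome_a]
    b_ids = [p.gene_id for p in proteome_b]
    best_fwd = {qa: best_set(surviving(qa, b_ids, db_b, "a"), tol) for qa in a_ids}
    best_bwd = {qb: best_set(surviving(qb, a_ids, db_a, "b"), tol) for qb in b_ids}
    return {
        qa: {g for g in best_fwd[qa] if qa in best_bwd[g]}
        for qa in a_ids
        if any(qa in best_bwd[g] for g in best_fwd[qa])
    }


def synteny_oracle(gene_candidates, n_genes, max_gap):
    """All maximal feasible (start, end, chromosome) synteny intervals.

    ``gene_candidates``: list (per conserved gene, in human order) of dicts
    chromosome -> list of ordinals. Feasibility of an interval on one
    chromosome is checked by exhaustive search over copy choices.
    """

    def feasible(s, e, chrom):
        layers = [gene_candidates[i].get(chrom) for i in range(s, e + 1)]
        if any(not layer for layer in layers):
            return False

        def extend(idx, prev):
            if idx == len(layers):
                return True
            for rank in layers[idx]:
                if abs(rank - prev) - 1 <= max_gap and extend(idx + 1, rank):
                    return True
            return False

        return any(extend(1, r0) for r0 in layers[0])

    chroms = sorted({c for cand in gene_candidates for c in cand})
    found = []
    for chrom in chroms:
        feas = [
            (s, e)
            for s in range(n_genes)
            for e in range(s + 1, n_genes)
            if feasible(s, e, chrom)
        ]
        for s, e in feas:
            if not any(
                (s2 <= s and e <= e2) and (s2, e2) != (s, e) for s2, e2 in feas
            ):
                found.append((s, e, chrom))
    return sorted(found)
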