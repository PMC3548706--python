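"""Independent brute-force oracles the implementation is checked against.

These deliberately re-derive results from first principles (full dynamic-
programming matrix fill, naive O(n^3) linkage recomputation, exhaustive
score tables) and share no code with the package internals.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def blosum62(a: str, b: str) -> float:
    return float(_B62[a, b])


def sw_score(query: str, subject: str, gap_open: float = 11.0,
             gap_extend: float = 1.0) -> float:
    """Smith-Waterman optimal local score, Gotoh affine gaps.

    Gap of length k costs gap_open + k * gap_extend (BLAST convention).
    Plain O(mn) matrix fill.
    """
    m, n = len(query), len(subject)
    NEG = -1e9
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), NEG)  # gap in query (move along subject)
    F = np.full((m + 1, n + 1), NEG)  # gap in subject
    first = gap_open + gap_extend
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i, j] = max(H[i, j - 1] - first, E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - first, F[i - 1, j] - gap_extend)
            H[i, j] = max(
                0.0,
                H[i - 1, j - 1] + blosum62(query[i - 1], subject[j - 1]),
                E[i, j],
                F[i, j],
            )
            if H[i, j] > best:
                best = H[i, j]
    return best


def best_hit_table(queries: dict[str, str], targets: dict[str, str]) -> dict:
    """Exhaustive all-vs-all raw-score table."""
    return {
        (qn, tn): sw_score(q, t)
        for qn, q in queries.items()
        for tn, t in targets.items()
    }


def karlin_altschul_evalue(score, m, n, lam=0.267, K=0.041):
    return K * m * n * np.exp(-lam * score)


def brute_bbh(seeds: dict[str, str], target: dict[str, str],
              max_evalue: float = 1e-3) -> dict[str, str | None]:
    """BBH calls from exhaustive score tables (no coverage filter).

    Forward database = target proteome residues, reverse = seed residues;
    ties break to the lexicographically smallest id, as the package
    documents.
    """
    n_t = sum(len(s) for s in target.values())
    n_s = sum(len(s) for s in seeds.values())
    fwd = best_hit_table(seeds, target)
    rev = best_hit_table(target, seeds)
    calls: dict[str, str | None] = {}
    for sn, sseq in seeds.items():
        cands = sorted(target, key=lambda t: (-fwd[(sn, t)], t))
        hit = None
        for t in cands:
            sc = fwd[(sn, t)]
            if sc > 0 and karlin_altschul_evalue(sc, len(sseq), n_t) <= max_evalue:
                hit = t
            break
        if hit is None:
            calls[sn] = None
            continue
        rcands = sorted(seeds, key=lambda s: (-rev[(hit, s)], s))
        rhit = None
        for s in rcands:
            sc = rev[(hit, s)]
            if sc > 0 and karlin_altschul_evalue(sc, len(target[hit]), n_s) <= max_evalue:
                rhit = s
            break
        calls[sn] = hit if rhit == sn else None
    return calls


def naive_average_linkage(labels: list[str], dist: np.ndarray):
    """O(n^3) average-linkage merges recomputed from leaf distances.

    At every step the average distance between each cluster pair is
    recomputed as the mean over all cross leaf pairs; ties break toward
    the lexicographically smallest pair of cluster representatives.
    Returns [(sorted_members_a, sorted_members_b, height), ...].
    """
    idx = {lab: i for i, lab in enumerate(labels)}
    clusters = [[lab] for lab in labels]
    merges = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                pairs = [
                    dist[idx[x], idx[y]] for x in clusters[a] for y in clusters[b]
                ]
                d = float(np.mean(pairs))
                key = tuple(sorted((min(clusters[a]), min(clusters[b]))))
                if best is None or (d, key) < (best[0], best[1]):
                    best = (d, key, a, b)
        d, _, a, b = best
        ca, cb = clusters[a], clusters[b]
        merges.append((tuple(sorted(ca)), tuple(sorted(cb)), d))
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(sorted(ca + cb))
    return merges
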