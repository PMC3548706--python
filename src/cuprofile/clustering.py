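"""Profile clustering: Pearson distance, average-linkage trees, CAST.

Two clustering surfaces are exposed.  Pairwise *protein* co-occurrence in
the whole genome ensemble uses Pearson correlation of the binary
species-level columns (for binary vectors this is the phi coefficient).
Profile *optimization* operates on the genus-level interval matrix: columns
(proteins) and/or rows (genera) are ordered by average-linkage hierarchical
clustering under Pearson distance d = 1 - r, and discrete clusters are
defined with the Clustering Affinity Search Technique (CAST) keeping every
member's mean affinity to its cluster above the threshold t.  By default
the affinity is the Pearson correlation itself with t = 0.5; an
alternative [0, 1]-scaled surface a = (r + 1) / 2 is available.

In the *single* (phylogeny-subordinated) optimization the genus order is
fixed by a reference genus tree and only proteins are clustered; the
*double* optimization additionally reorders genera by their profiles,
exposing clades of genomes sharing a protein repertoire.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles import GenusProfile

__all__ = [
    "ZeroVarianceWarning",
    "DistanceMatrix",
    "Dendrogram",
    "ClusterSet",
    "OptimizedProfile",
    "pearson_correlation",
    "correlation_matrix",
    "raw_affinity",
    "scaled_affinity",
    "distance_matrix",
    "hac_average_linkage",
    "cast_clusters",
    "single_optimization",
    "double_optimization",
    "pair_correlation_report",
]


class ZeroVarianceWarning(UserWarning):
    """A correlation involved a constant vector; the sentinel r = 0 was used."""


def pearson_correlation(x, y) -> float:
    """Product-moment correlation with defined behaviour on constant input.

    Identical vectors always give r = 1 (even when constant); otherwise a
    constant vector on either side yields the sentinel r = 0 together with
    a ZeroVarianceWarning, so that structureless items (e.g. genera lacking
    every ortholog) remain comparable instead of raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be one-dimensional and of equal length")
    if x.size < 2:
        raise ValueError("need at least two observations")
    if np.array_equal(x, y):
        return 1.0
    sx = x.std()
    sy = y.std()
    if sx == 0.0 or sy == 0.0:
        warnings.warn(
            "zero-variance vector in correlation; returning r = 0",
            ZeroVarianceWarning,
            stacklevel=2,
        )
        return 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def correlation_matrix(vectors: pd.DataFrame) -> pd.DataFrame:
    """All pairwise correlations between the *columns* of ``vectors``.

    Applies the same constant-vector conventions as
    :func:`pearson_correlation` but warns at most once per call.
    """
    labels = list(vectors.columns)
    arr = vectors.to_numpy(dtype=float)
    n = len(labels)
    out = np.eye(n)
    stds = arr.std(axis=0)
    if (stds == 0.0).any():
        warnings.warn(
            "zero-variance vector(s) in correlation matrix; sentinel r = 0 used",
            ZeroVarianceWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        cc = np.corrcoef(arr, rowvar=False)
    for i in range(n):
        for j in range(i + 1, n):
            if np.array_equal(arr[:, i], arr[:, j]):
                r = 1.0
            elif stds[i] == 0.0 or stds[j] == 0.0:
                r = 0.0
            else:
                r = float(np.clip(cc[i, j], -1.0, 1.0))
            out[i, j] = out[j, i] = r
    return pd.DataFrame(out, index=labels, columns=labels)


@dataclass
class DistanceMatrix:
    """Pairwise Pearson distances d = 1 - r over labelled items."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        if v.min() < -1e-9 or v.max() > 2.0 + 1e-9:
            raise ValueError("Pearson distances must lie in [0, 2]")
        self.values = v

    def get(self, a: str, b: str) -> float:
        return float(
            self.values[self.labels.index(a), self.labels.index(b)]
        )


def distance_matrix(
    profile: GenusProfile | pd.DataFrame,
    axis: str = "proteins",
    use: str = "intervals",
) -> DistanceMatrix:
    """Pearson distance matrix over one axis of a genus profile.

    ``axis='proteins'`` compares seed-protein columns (their vectors across
    genera); ``axis='taxa'`` compares genus rows.  ``use`` selects the
    discretised interval levels (default, what the profile heatmap shows)
    or the raw fractions.
    """
    if isinstance(profile, GenusProfile):
        data = profile.intervals if use == "intervals" else profile.fractions
    else:
        data = profile
    if axis == "proteins":
        vectors = data
    elif axis == "taxa":
        vectors = data.T
    else:
        raise ValueError("axis must be 'proteins' or 'taxa'")
    if vectors.shape[1] < 2:
        raise ValueError(f"need at least two items on axis {axis!r}")
    corr = correlation_matrix(vectors)
    vals = 1.0 - corr.to_numpy()
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(labels=list(vectors.columns), values=vals)


@dataclass
class Dendrogram:
    """Average-linkage merge history plus a deterministic leaf order.

    ``merges`` lists, oldest first, tuples ``(left_leaves, right_leaves,
    height)`` where the leaf tuples are sorted label tuples of the two
    clusters joined at that height.
    """

    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]]
    leaf_order: list[str]
    newick: str


def hac_average_linkage(dist: DistanceMatrix) -> Dendrogram:
    """Agglomerative clustering with unweighted average linkage (UPGMA).

    Deterministic by construction: equal-height merge candidates resolve
    toward the lexicographically smallest pair of cluster representatives,
    and at every merge each subtree is oriented so that the cross-junction
    leaf pair with the smallest original distance sits adjacent (ties again
    lexicographic), which fixes the heatmap leaf order.
    """
    labels = dist.labels
    n = len(labels)
    if n == 1:
        return Dendrogram(merges=[], leaf_order=list(labels), newick=f"{labels[0]};")
    leaf_index = {lab: i for i, lab in enumerate(labels)}
    base = dist.values

    clusters: dict[int, dict] = {
        i: {"leaves": [lab], "members": (lab,), "size": 1, "height": 0.0,
            "rep": lab, "nwk": lab}
        for i, lab in enumerate(labels)
    }
    d: dict[tuple[int, int], float] = {
        (i, j): float(base[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    merges = []
    next_id = n
    while len(clusters) > 1:
        # pick the closest pair; ties -> smallest (rep_a, rep_b) sorted pair
        best = None
        for (i, j), dij in d.items():
            key = tuple(sorted((clusters[i]["rep"], clusters[j]["rep"])))
            cand = (dij, key, (i, j))
            if best is None or cand[:2] < best[:2]:
                best = cand
        h, _, (i, j) = best
        a, b = clusters.pop(i), clusters.pop(j)
        left, right = (a, b) if a["rep"] <= b["rep"] else (b, a)
        la, lb = _orient(left["leaves"], right["leaves"], base, leaf_index)
        bl_l = h / 2 - left["height"] / 2
        bl_r = h / 2 - right["height"] / 2
        merged = {
            "leaves": la + lb,
            "members": tuple(sorted(left["members"] + right["members"])),
            "size": a["size"] + b["size"],
            "height": h,
            "rep": min(a["rep"], b["rep"]),
            "nwk": f"({left['nwk']}:{bl_l:.6g},{right['nwk']}:{bl_r:.6g})",
        }
        merges.append((left["members"], right["members"], float(h)))
        # unweighted average linkage update
        newd = {}
        for (p, q), dpq in d.items():
            if i in (p, q) or j in (p, q):
                continue
            newd[(p, q)] = dpq
        for k in clusters:
            dik = d[(min(i, k), max(i, k))]
            djk = d[(min(j, k), max(j, k))]
            newd[(min(k, next_id), max(k, next_id))] = (
                a["size"] * dik + b["size"] * djk
            ) / (a["size"] + b["size"])
        clusters[next_id] = merged
        d = newd
        next_id += 1
    root = clusters.popitem()[1]
    return Dendrogram(
        merges=merges, leaf_order=root["leaves"], newick=root["nwk"] + ";"
    )


def _orient(left: list[str], right: list[str], base: np.ndarray, idx) -> tuple:
    """Flip subtrees so the closest cross-junction leaves are adjacent."""
    pairs = sorted(
        ((float(base[idx[a], idx[b]]), a, b) for a in left for b in right),
        key=lambda t: (t[0], t[1], t[2]),
    )
    _, a, b = pairs[0]
    ia, ib = left.index(a), right.index(b)
    if ia < len(left) - 1 - ia:
        left = left[::-1]
    if ib > len(right) - 1 - ib:
        right = right[::-1]
    return left, right


@dataclass
class ClusterSet:
    """Disjoint CAST clusters over labelled items."""

    clusters: list[list[str]]
    affinity_threshold: float
    mean_affinity: dict[str, float] = field(default_factory=dict)

    @property
    def labels(self) -> list[str]:
        return [lab for c in self.clusters for lab in c]

    def assignment(self) -> dict[str, int]:
        return {lab: k for k, c in enumerate(self.clusters) for lab in c}


def raw_affinity(corr: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations used directly as affinities (unit diagonal).

    With the conventional threshold t = 0.5, CAST then keeps clusters whose
    members correlate above 0.5 with the cluster on average — the regime in
    which co-presence correlations in the 0.75-0.9 confidence band group
    together while weakly correlated items stay apart.
    """
    aff = corr.copy()
    np.fill_diagonal(aff.values, 1.0)
    return aff


def scaled_affinity(corr: pd.DataFrame) -> pd.DataFrame:
    """Map correlations in [-1, 1] onto affinities in [0, 1], unit diagonal.

    Alternative affinity surface; note that t = 0.5 on this scale admits
    any positive correlation.
    """
    aff = (corr + 1.0) / 2.0
    np.fill_diagonal(aff.values, 1.0)
    return aff


def _affinity(corr: pd.DataFrame, scale: str) -> pd.DataFrame:
    if scale == "pearson":
        return raw_affinity(corr)
    if scale == "scaled":
        return scaled_affinity(corr)
    raise ValueError("affinity scale must be 'pearson' or 'scaled'")


def cast_clusters(affinity: pd.DataFrame, t: float = 0.5) -> ClusterSet:
    """Clustering Affinity Search Technique over a pairwise affinity matrix.

    Clusters open with the unassigned element of maximal total affinity and
    grow by alternating phases: ADD the outside element whose mean affinity
    to the cluster is highest, while that mean exceeds ``t``; REMOVE the
    member whose mean affinity (self included) is lowest, while that mean
    falls below ``t``.  The cluster closes when a full pass changes
    nothing.
    """
    if affinity.shape[0] == 0:
        return ClusterSet(clusters=[], affinity_threshold=t)
    arr = affinity.to_numpy(dtype=float)
    if affinity.shape[0] != affinity.shape[1] or not np.allclose(arr, arr.T):
        raise ValueError("affinity matrix must be square and symmetric")
    if not 0.0 <= t <= 1.0:
        raise ValueError("threshold t must lie in [0, 1]")
    labels = list(affinity.columns)
    unassigned = set(labels)
    clusters: list[list[str]] = []
    mean_aff: dict[str, float] = {}

    def mean_to(x: str, members: list[str]) -> float:
        return float(np.mean([affinity.loc[x, y] for y in members]))

    while unassigned:
        # open with the maximal-total-affinity element; ties lexicographic
        opener = min(
            sorted(unassigned),
            key=lambda u: (-sum(affinity.loc[u, v] for v in unassigned), u),
        )
        members = [opener]
        unassigned.discard(opener)
        seen_states: set[frozenset] = {frozenset(members)}
        while True:
            changed = False
            # ADD phase
            while unassigned:
                cand = min(
                    sorted(unassigned), key=lambda u: (-mean_to(u, members), u)
                )
                if mean_to(cand, members) >= t:
                    members.append(cand)
                    unassigned.discard(cand)
                    changed = True
                else:
                    break
            # REMOVE phase
            while len(members) > 1:
                worst = min(sorted(members), key=lambda m: (mean_to(m, members), m))
                if mean_to(worst, members) < t:
                    members.remove(worst)
                    unassigned.add(worst)
                    changed = True
                else:
                    break
            state = frozenset(members)
            if not changed or state in seen_states:
                break
            seen_states.add(state)
        for m in members:
            mean_aff[m] = mean_to(m, members)
        clusters.append(sorted(members))
    return ClusterSet(clusters=clusters, affinity_threshold=t, mean_affinity=mean_aff)


@dataclass
class OptimizedProfile:
    """A genus profile with optimized row/column orders and cluster calls."""

    profile: GenusProfile
    row_order: list[str]
    col_order: list[str]
    protein_clusters: ClusterSet
    protein_dendrogram: Dendrogram
    taxa_clusters: ClusterSet | None = None
    taxa_dendrogram: Dendrogram | None = None
    mode: str = "single"

    def ordered_intervals(self) -> pd.DataFrame:
        return self.profile.intervals.loc[self.row_order, self.col_order]

    def clade_assignment(self) -> dict[str, int]:
        """Genus -> repertoire clade id, numbered along the optimized row order."""
        if self.taxa_clusters is None:
            raise ValueError("no taxa clustering attached (run double_optimization)")
        raw = self.taxa_clusters.assignment()
        first_pos = {}
        for k, members in enumerate(self.taxa_clusters.clusters):
            first_pos[k] = min(self.row_order.index(m) for m in members)
        renumber = {
            old: new for new, old in enumerate(sorted(first_pos, key=first_pos.get))
        }
        return {g: renumber[raw[g]] for g in raw}

    def clade_table(self) -> pd.DataFrame:
        """Per-clade genus count and mean per-seed fractional abundance."""
        assign = self.clade_assignment()
        rows = []
        for clade in sorted(set(assign.values())):
            genera = [g for g in self.row_order if assign[g] == clade]
            mean_abund = self.profile.fractions.loc[genera].mean(axis=0)
            row = {"clade": clade, "n_genera": len(genera),
                   "genera": ",".join(genera)}
            row.update({s: round(float(mean_abund[s]), 4) for s in self.col_order})
            rows.append(row)
        return pd.DataFrame(rows)


def _protein_axis(profile: GenusProfile, t: float, use: str, scale: str):
    dist = distance_matrix(profile, axis="proteins", use=use)
    dendro = hac_average_linkage(dist)
    data = profile.intervals if use == "intervals" else profile.fractions
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ZeroVarianceWarning)
        corr = correlation_matrix(data)
    clusters = cast_clusters(_affinity(corr, scale), t)
    return dendro, clusters


def single_optimization(
    profile: GenusProfile,
    tree_newick: str,
    t: float = 0.5,
    use: str = "intervals",
    affinity_scale: str = "pearson",
) -> OptimizedProfile:
    """Phylogeny-subordinated optimization: genus order fixed by the tree.

    Rows follow the leaf order of the reference genus tree; columns are
    ordered by the protein dendrogram, with protein clusters called by CAST
    at threshold ``t``.
    """
    import dendropy

    tree = dendropy.Tree.get(data=tree_newick, schema="newick")
    leaf_order = [lf.taxon.label for lf in tree.leaf_node_iter()]
    missing = [g for g in profile.genera if g not in leaf_order]
    if missing:
        raise KeyError(f"genera missing from the reference tree: {missing}")
    row_order = [g for g in leaf_order if g in set(profile.genera)]
    dendro, clusters = _protein_axis(profile, t, use, affinity_scale)
    return OptimizedProfile(
        profile=profile,
        row_order=row_order,
        col_order=list(dendro.leaf_order),
        protein_clusters=clusters,
        protein_dendrogram=dendro,
        mode="single",
    )


def double_optimization(
    profile: GenusProfile,
    t: float = 0.5,
    use: str = "intervals",
    affinity_scale: str = "pearson",
) -> OptimizedProfile:
    """Two-dimensional optimization exposing repertoire clades.

    The protein (column) order is computed first exactly as in the single
    optimization and preserved; genera (rows) are then reordered by their
    own average-linkage dendrogram and partitioned into repertoire clades
    by CAST at threshold ``t`` on the chosen affinity scale.
    """
    if len(profile.genera) < 2 or len(profile.seeds) < 2:
        raise ValueError("double optimization needs >= 2 genera and >= 2 proteins")
    col_dendro, protein_clusters = _protein_axis(profile, t, use, affinity_scale)
    taxa_dist = distance_matrix(profile, axis="taxa", use=use)
    taxa_dendro = hac_average_linkage(taxa_dist)
    data = profile.intervals if use == "intervals" else profile.fractions
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ZeroVarianceWarning)
        corr = correlation_matrix(data.T)
    taxa_clusters = cast_clusters(_affinity(corr, affinity_scale), t)
    return OptimizedProfile(
        profile=profile,
        row_order=list(taxa_dendro.leaf_order),
        col_order=list(col_dendro.leaf_order),
        protein_clusters=protein_clusters,
        protein_dendrogram=col_dendro,
        taxa_clusters=taxa_clusters,
        taxa_dendrogram=taxa_dendro,
        mode="double",
    )


def pair_correlation_report(matrix: pd.DataFrame) -> pd.DataFrame:
    """All protein-pair correlations on the binary species-level matrix.

    For binary columns Pearson r is the phi coefficient of the 2x2
    co-presence table.  ``confident`` flags pairs in the 0.75-0.9 band and
    above, a range conventionally taken as reliable evidence of
    co-occurrence; ``high_affinity`` flags r >= 0.5, the CAST operating
    regime.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two proteins")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ZeroVarianceWarning)
        corr = correlation_matrix(matrix.astype(float))
    rows = []
    seeds = list(matrix.columns)
    for i in range(len(seeds)):
        for j in range(i + 1, len(seeds)):
            r = float(corr.iloc[i, j])
            rows.append(
                {
                    "seed_a": seeds[i],
                    "seed_b": seeds[j],
                    "r": round(r, 4),
                    "confident": r >= 0.75,
                    "high_affinity": r >= 0.5,
                }
            )
    out = pd.DataFrame(rows).sort_values(
        by=["r", "seed_a", "seed_b"], ascending=[False, True, True]
    )
    return out.reset_index(drop=True)
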