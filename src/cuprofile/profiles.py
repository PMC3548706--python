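"""Phylogenetic profile construction at species and genus level.

The species-level profile is a binary genomes x seeds matrix (1 = BBH
ortholog found).  To remove the over-representation of heavily sequenced
species, the matrix is consolidated per genus into *fractional abundances*
(fraction of the genus's genomes carrying the ortholog), which are then
discretised into 11 levels: 0 reserved for complete absence, 10 for
presence in every genome, interior fractions rounded to the nearest tenth
and clamped to 1..9 so that any non-zero presence stays distinguishable
from absence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Taxonomy",
    "GenusProfile",
    "build_presence_matrix",
    "aggregate_by_genus",
    "discretize",
    "ensemble_abundance",
]


@dataclass
class Taxonomy:
    """genome_id -> (genus, family, order) lookup."""

    table: pd.DataFrame  # columns: genome_id, genus, family, order

    def __post_init__(self) -> None:
        required = {"genome_id", "genus", "family", "order"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"taxonomy table missing columns: {sorted(missing)}")
        if self.table["genome_id"].duplicated().any():
            raise ValueError("duplicate genome_id in taxonomy table")

    def genus_of(self, genome_id: str) -> str:
        hit = self.table.loc[self.table["genome_id"] == genome_id, "genus"]
        if hit.empty:
            raise KeyError(f"genome {genome_id!r} has no taxonomy entry")
        return str(hit.iloc[0])

    @classmethod
    def from_tsv(cls, path) -> "Taxonomy":
        return cls(pd.read_csv(path, sep="\t", dtype=str))


@dataclass
class GenusProfile:
    """Genus-level fractional-abundance profile and its discretisation."""

    fractions: pd.DataFrame  # genera x seeds, values in [0, 1]
    intervals: pd.DataFrame  # genera x seeds, integer levels 0..10
    genus_sizes: pd.Series  # genomes per genus

    @property
    def genera(self) -> list[str]:
        return list(self.fractions.index)

    @property
    def seeds(self) -> list[str]:
        return list(self.fractions.columns)


def build_presence_matrix(calls, genomes, seeds) -> pd.DataFrame:
    """Binary genomes x seeds presence matrix from BBH calls.

    Cell (g, s) is 1 iff an ``is_bbh`` call exists for seed s in genome g.
    Conflicting duplicate calls (same seed and genome, different gene) are
    an integrity error.
    """
    genomes = list(genomes)
    seeds = list(seeds)
    mat = pd.DataFrame(0, index=genomes, columns=seeds, dtype=int)
    seen: dict[tuple[str, str], str | None] = {}
    for c in calls:
        if c.genome_id not in mat.index:
            raise ValueError(f"call references unknown genome {c.genome_id!r}")
        if c.seed not in mat.columns:
            raise ValueError(f"call references unknown seed {c.seed!r}")
        key = (c.genome_id, c.seed)
        if key in seen and seen[key] != c.gene_id:
            raise ValueError(f"conflicting duplicate calls for {key}")
        seen[key] = c.gene_id
        if c.is_bbh:
            mat.loc[c.genome_id, c.seed] = 1
    return mat


def aggregate_by_genus(matrix: pd.DataFrame, taxonomy: Taxonomy) -> GenusProfile:
    """Consolidate a species-level binary matrix into genus fractions.

    Genus order follows first appearance in the matrix rows; single-genome
    genera are retained (their fractions are necessarily 0 or 1).
    """
    tax = taxonomy.table.set_index("genome_id")["genus"]
    missing = [g for g in matrix.index if g not in tax.index]
    if missing:
        raise KeyError(f"no taxonomy entry for genome(s): {missing}")
    genus_per_row = pd.Series([tax[g] for g in matrix.index], index=matrix.index)
    order = list(dict.fromkeys(genus_per_row))
    grouped = matrix.groupby(genus_per_row, sort=False)
    fractions = grouped.mean().loc[order]
    sizes = grouped.size().loc[order]
    intervals = fractions.map(discretize).astype(int)
    return GenusProfile(fractions=fractions, intervals=intervals, genus_sizes=sizes)


def discretize(fraction: float) -> int:
    """Map a fractional abundance in [0, 1] to one of 11 discrete levels.

    0 means absence within the genus and 10 presence in 100% of its
    genomes; interior fractions round to the nearest tenth, clamped into
    1..9 so they never collide with the reserved endpoints.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction {fraction} outside [0, 1]")
    if fraction == 0.0:
        return 0
    if fraction == 1.0:
        return 10
    return int(min(9, max(1, round(fraction * 10))))


def ensemble_abundance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-seed ortholog abundance over the whole genome ensemble.

    Returns exact fractions alongside integer percentages (the form in
    which such surveys are usually quoted).
    """
    if matrix.shape[0] == 0:
        raise ValueError("presence matrix has no genomes")
    frac = matrix.mean(axis=0)
    return pd.DataFrame(
        {
            "n_present": matrix.sum(axis=0).astype(int),
            "n_genomes": matrix.shape[0],
            "fraction": frac,
            "percent": (100 * frac).round().astype(int),
        }
    )


def genus_profile_table(profile: GenusProfile) -> pd.DataFrame:
    """Long-form TSV layout: genus, n_genomes, then fraction/interval per seed."""
    out = pd.DataFrame({"genus": profile.genera})
    out["n_genomes"] = [int(profile.genus_sizes[g]) for g in profile.genera]
    for seed in profile.seeds:
        out[f"{seed}_fraction"] = np.round(profile.fractions[seed].to_numpy(), 4)
        out[f"{seed}_interval"] = profile.intervals[seed].to_numpy()
    return out
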