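"""Readers for the pipeline's plain-text input formats (FASTA, TSV, Newick)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .orthology import Proteome, SeedProtein

__all__ = ["read_seeds", "read_proteomes_manifest", "read_proteome_fasta"]


def read_seeds(path) -> list[SeedProtein]:
    """Seed proteins from FASTA; ``accession=`` in the description if present."""
    seeds = []
    for rec in SeqIO.parse(str(path), "fasta"):
        accession = rec.id
        for token in rec.description.split()[1:]:
            if token.startswith("accession="):
                accession = token.split("=", 1)[1]
        seeds.append(SeedProtein(name=rec.id, accession=accession, sequence=str(rec.seq)))
    if not seeds:
        raise ValueError(f"no sequences found in {path}")
    names = [s.name for s in seeds]
    if len(names) != len(set(names)):
        raise ValueError("seed names must be unique")
    return seeds


def read_proteome_fasta(path, genome_id: str | None = None) -> list[Proteome]:
    """One or more proteomes from FASTA.

    With ``genome_id`` given, the whole file is one proteome; otherwise each
    record's ``genome_id=<id>`` description token assigns it to a genome.
    """
    if genome_id is not None:
        proteins = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
        return [Proteome(genome_id=genome_id, proteins=proteins)]
    grouped: dict[str, list[tuple[str, str]]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        gid = None
        for token in rec.description.split()[1:]:
            if token.startswith("genome_id="):
                gid = token.split("=", 1)[1]
        if gid is None:
            raise ValueError(
                f"record {rec.id!r} lacks a genome_id= token; "
                "use a manifest or pass genome_id explicitly"
            )
        grouped.setdefault(gid, []).append((rec.id, str(rec.seq)))
    return [Proteome(genome_id=g, proteins=p) for g, p in grouped.items()]


def read_proteomes_manifest(manifest_path) -> list[Proteome]:
    """Per-genome FASTA files listed in a TSV manifest (genome_id, path)."""
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path, sep="\t", dtype=str)
    if not {"genome_id", "path"} <= set(table.columns):
        raise ValueError("manifest needs 'genome_id' and 'path' columns")
    proteomes = []
    for row in table.itertuples():
        fasta = manifest_path.parent / row.path
        proteomes.extend(read_proteome_fasta(fasta, genome_id=row.genome_id))
    return proteomes
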