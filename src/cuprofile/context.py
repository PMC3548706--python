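"""Gene-neighborhood analysis of ortholog loci.

Works from an annotation table assigning every gene an ordinal rank on its
replicon (chromosome or plasmid).  Contiguity is defined on ranks, not
nucleotide distance, and ignores strand: a set of ortholog genes is
contiguous when they all lie on one replicon and, after sorting by rank,
consecutive genes are separated by at most ``max_gap`` intervening genes.
Circular replicons wrap (the first and last ranks are adjacent).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd

__all__ = [
    "GeneLocus",
    "ContiguityCall",
    "Annotation",
    "contiguous",
    "operon_runs",
    "location_summary",
]

ANNOTATION_COLUMNS = [
    "genome_id",
    "replicon_id",
    "replicon_type",
    "circular",
    "gene_id",
    "rank",
    "start",
    "end",
    "strand",
]


@dataclass(frozen=True)
class GeneLocus:
    genome_id: str
    replicon_id: str
    replicon_type: str  # chromosome | plasmid
    gene_id: str
    rank: int
    start: int
    end: int
    strand: str
    circular: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"locus {self.gene_id!r}: start must be < end")
        if self.replicon_type not in ("chromosome", "plasmid"):
            raise ValueError(f"unknown replicon type {self.replicon_type!r}")


@dataclass(frozen=True)
class ContiguityCall:
    genome_id: str
    gene_ids: tuple[str, ...]
    replicon_id: str
    replicon_type: str
    max_rank_gap: int  # largest number of intervening genes observed


class Annotation:
    """Per-genome gene annotation with ordinal ranks per replicon."""

    def __init__(self, table: pd.DataFrame):
        missing = set(ANNOTATION_COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"annotation table missing columns: {sorted(missing)}")
        self.table = table.copy()
        self.table["rank"] = self.table["rank"].astype(int)
        self.table["start"] = self.table["start"].astype(int)
        self.table["end"] = self.table["end"].astype(int)
        if isinstance(self.table["circular"].iloc[0], str):
            self.table["circular"] = self.table["circular"].str.lower().isin(
                ("1", "true", "yes")
            )
        dup = self.table.duplicated(subset=["genome_id", "replicon_id", "rank"])
        if dup.any():
            raise ValueError("duplicate rank within a replicon")
        self._index = {
            (r.genome_id, r.gene_id): GeneLocus(
                genome_id=r.genome_id,
                replicon_id=r.replicon_id,
                replicon_type=r.replicon_type,
                gene_id=r.gene_id,
                rank=int(r.rank),
                start=int(r.start),
                end=int(r.end),
                strand=r.strand,
                circular=bool(r.circular),
            )
            for r in self.table.itertuples()
        }
        self._replicon_sizes = (
            self.table.groupby(["genome_id", "replicon_id"])["rank"].count().to_dict()
        )

    @classmethod
    def from_tsv(cls, path) -> "Annotation":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    @classmethod
    def from_gff3(cls, path, genome_id: str) -> "Annotation":
        """Derive ranks from gene features of a GFF3 file, sorted by start."""
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 9 or parts[2] != "gene":
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
                )
                rows.append(
                    {
                        "genome_id": genome_id,
                        "replicon_id": parts[0],
                        "replicon_type": attrs.get("replicon_type", "chromosome"),
                        "circular": attrs.get("circular", "false"),
                        "gene_id": attrs.get("ID", f"{parts[0]}:{parts[3]}"),
                        "start": int(parts[3]) - 1,
                        "end": int(parts[4]),
                        "strand": parts[6],
                    }
                )
        df = pd.DataFrame(rows).sort_values(["replicon_id", "start"])
        df["rank"] = df.groupby("replicon_id").cumcount()
        return cls(df[ANNOTATION_COLUMNS])

    def locus(self, genome_id: str, gene_id: str) -> GeneLocus:
        try:
            return self._index[(genome_id, gene_id)]
        except KeyError:
            raise KeyError(
                f"gene {gene_id!r} of genome {genome_id!r} not in annotation"
            ) from None

    def replicon_size(self, genome_id: str, replicon_id: str) -> int:
        return int(self._replicon_sizes[(genome_id, replicon_id)])


def _rank_gaps(ranks: list[int], n_replicon: int, circular: bool) -> list[int]:
    """Intervening-gene counts between consecutive sorted ranks.

    On a circular replicon the smallest wrap-around arrangement is used:
    the largest inter-gene gap is dropped from the cycle of gaps.
    """
    ranks = sorted(ranks)
    if len(ranks) < 2:
        return []
    gaps = [b - a - 1 for a, b in zip(ranks, ranks[1:])]
    if circular and n_replicon:
        wrap = (ranks[0] + n_replicon) - ranks[-1] - 1
        cycle = gaps + [wrap]
        cycle.remove(max(cycle))
        return cycle
    return gaps


def contiguous(
    loci: list[GeneLocus],
    max_gap: int = 0,
    annotation: Annotation | None = None,
) -> ContiguityCall | None:
    """Test whether a set of ortholog loci forms one contiguous block.

    Returns a ContiguityCall iff all loci share a replicon and every pair
    of rank-consecutive genes has at most ``max_gap`` genes between them;
    otherwise None.  The input order of ``loci`` is irrelevant.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if not loci:
        return None
    if len({(l.genome_id, l.replicon_id) for l in loci}) > 1:
        return None
    first = loci[0]
    n_repl = (
        annotation.replicon_size(first.genome_id, first.replicon_id)
        if annotation is not None
        else 0
    )
    gaps = _rank_gaps([l.rank for l in loci], n_repl, first.circular)
    if any(g > max_gap for g in gaps):
        return None
    return ContiguityCall(
        genome_id=first.genome_id,
        gene_ids=tuple(sorted(l.gene_id for l in loci)),
        replicon_id=first.replicon_id,
        replicon_type=first.replicon_type,
        max_rank_gap=max(gaps) if gaps else 0,
    )


def operon_runs(
    annotation: Annotation,
    genome_id: str,
    gene_seeds: dict[str, str],
    max_gap: int = 0,
) -> list[dict]:
    """Partition a genome's ortholog loci into maximal contiguity runs.

    ``gene_seeds`` maps each ortholog gene_id to its seed label.  Each run
    is reported with its replicon, ordered gene ids and the corresponding
    seed labels joined as e.g. ``"PcoA-PcoB-PcoC"``.  Every locus lands in
    exactly one run; isolated genes form runs of size one.
    """
    loci = [annotation.locus(genome_id, g) for g in gene_seeds]
    runs: list[dict] = []
    by_replicon: dict[str, list[GeneLocus]] = {}
    for l in loci:
        by_replicon.setdefault(l.replicon_id, []).append(l)
    for replicon_id in sorted(by_replicon):
        group = sorted(by_replicon[replicon_id], key=lambda l: l.rank)
        n_repl = annotation.replicon_size(genome_id, replicon_id)
        segments: list[list[GeneLocus]] = [[group[0]]]
        for prev, cur in zip(group, group[1:]):
            if cur.rank - prev.rank - 1 <= max_gap:
                segments[-1].append(cur)
            else:
                segments.append([cur])
        # circular wrap: first and last segments may join across the origin
        if (
            group[0].circular
            and len(segments) > 1
            and (group[0].rank + n_repl) - group[-1].rank - 1 <= max_gap
        ):
            segments[-1].extend(segments[0])
            segments = segments[1:]
        for seg in segments:
            runs.append(
                {
                    "genome_id": genome_id,
                    "replicon_id": replicon_id,
                    "replicon_type": seg[0].replicon_type,
                    "gene_ids": [l.gene_id for l in seg],
                    "seeds": "-".join(gene_seeds[l.gene_id] for l in seg),
                    "size": len(seg),
                }
            )
    return runs


def location_summary(
    calls,
    annotation: Annotation,
    max_gap: int = 0,
) -> pd.DataFrame:
    """Per seed-pair co-presence, contiguity and replicon-type breakdown.

    For every pair of seeds: in how many genomes both have a BBH call, how
    often the two called genes are contiguous when co-present, and whether
    those contiguous pairs sit on chromosomes or plasmids.
    """
    by_genome: dict[str, dict[str, str]] = {}
    for c in calls:
        if c.is_bbh and c.gene_id is not None:
            by_genome.setdefault(c.genome_id, {})[c.seed] = c.gene_id
    seeds = sorted({c.seed for c in calls})
    rows = []
    for sa, sb in combinations(seeds, 2):
        n_co = n_contig = n_chrom = n_plasmid = 0
        for genome_id, genes in sorted(by_genome.items()):
            if sa not in genes or sb not in genes:
                continue
            n_co += 1
            loci = [
                annotation.locus(genome_id, genes[sa]),
                annotation.locus(genome_id, genes[sb]),
            ]
            call = contiguous(loci, max_gap=max_gap, annotation=annotation)
            if call is not None:
                n_contig += 1
                if call.replicon_type == "chromosome":
                    n_chrom += 1
                else:
                    n_plasmid += 1
        rows.append(
            {
                "seed_a": sa,
                "seed_b": sb,
                "n_copresent": n_co,
                "n_contiguous": n_contig,
                "frac_contiguous": round(n_contig / n_co, 4) if n_co else float("nan"),
                "n_chromosome": n_chrom,
                "n_plasmid": n_plasmid,
            }
        )
    return pd.DataFrame(rows)
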