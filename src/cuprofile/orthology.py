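"""Bidirectional-best-hit ortholog detection and fusion-gene flagging.

A seed protein's *best hit* in a target proteome is the protein with the
highest bit score among those passing the E-value and coverage thresholds.
The hit is *bidirectional* (a BBH, the operational ortholog call used
throughout this package) when the target gene's own best hit back in the
seed proteome is the original seed.  Default thresholds are E <= 1e-3 and
alignment coverage >= 50% of the query and/or the subject.

A gene called as the forward best hit of two or more seeds whose subject
spans are (almost) disjoint is flagged as a candidate fusion gene.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field

import pandas as pd

from .alignment import (
    AlignmentResult,
    ScoringScheme,
    align_local,
    evalue as _evalue,
    sanitize_sequence,
)

__all__ = [
    "SeedProtein",
    "Proteome",
    "Thresholds",
    "OrthologCall",
    "FusionCall",
    "best_hit",
    "bidirectional_best_hit",
    "call_orthologs",
    "detect_fusions",
    "calls_to_table",
    "fusions_to_table",
]


@dataclass(frozen=True)
class SeedProtein:
    """A named query protein used to seed ortholog searches."""

    name: str
    accession: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"seed {self.name!r} has an empty sequence")
        object.__setattr__(self, "sequence", sanitize_sequence(self.sequence))


@dataclass
class Proteome:
    """All annotated proteins of one genome: ``(gene_id, sequence)`` pairs."""

    genome_id: str
    proteins: list[tuple[str, str]]

    def __post_init__(self) -> None:
        ids = [g for g, _ in self.proteins]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate gene_ids in proteome {self.genome_id!r}")

    @property
    def size(self) -> int:
        return len(self.proteins)

    @property
    def total_residues(self) -> int:
        return sum(len(s) for _, s in self.proteins)

    def sequence_of(self, gene_id: str) -> str:
        for g, s in self.proteins:
            if g == gene_id:
                return s
        raise KeyError(gene_id)


@dataclass(frozen=True)
class Thresholds:
    """BBH acceptance thresholds.

    ``coverage_mode='any'`` passes an alignment covering >= ``min_coverage``
    of the query *or* the subject; ``'both'`` requires both.
    """

    max_evalue: float = 1e-3
    min_coverage: float = 0.5
    coverage_mode: str = "any"

    def __post_init__(self) -> None:
        if self.coverage_mode not in ("any", "both"):
            raise ValueError("coverage_mode must be 'any' or 'both'")

    def covers(self, aln: AlignmentResult) -> bool:
        if self.coverage_mode == "any":
            return (
                aln.query_coverage >= self.min_coverage
                or aln.subject_coverage >= self.min_coverage
            )
        return (
            aln.query_coverage >= self.min_coverage
            and aln.subject_coverage >= self.min_coverage
        )


@dataclass(frozen=True)
class OrthologCall:
    """Outcome of a BBH test for one (seed, genome) pair."""

    seed: str
    genome_id: str
    gene_id: str | None
    forward: AlignmentResult | None
    reverse: AlignmentResult | None
    is_bbh: bool


@dataclass(frozen=True)
class FusionCall:
    """A gene hit by two seeds over (nearly) non-overlapping subject spans."""

    gene_id: str
    genome_id: str
    seed_a: str
    seed_b: str
    span_a: tuple[int, int]
    span_b: tuple[int, int]


def best_hit(
    query: str,
    target: Proteome,
    thresholds: Thresholds | None = None,
    scoring: ScoringScheme | None = None,
) -> tuple[str, AlignmentResult] | None:
    """Highest-bit-score protein in ``target`` passing the thresholds.

    The E-value search space is the total residue count of the target
    proteome, matching a per-genome database search.  Ties on score break
    toward the lexicographically smallest gene_id.  Returns None when no
    protein passes (an empty proteome trivially yields None).
    """
    thresholds = thresholds or Thresholds()
    scoring = scoring or ScoringScheme()
    if not query:
        raise ValueError("empty query sequence")
    q = sanitize_sequence(query)
    db_len = target.total_residues
    if db_len == 0:
        return None
    aligner = scoring.aligner()
    scored = sorted(
        ((aligner.score(q, sanitize_sequence(s)), g, s) for g, s in target.proteins),
        key=lambda t: (-t[0], t[1]),
    )
    for score, gene_id, seq in scored:
        if score <= 0:
            break
        if _evalue(score, len(q), db_len, scoring.lam, scoring.K) > thresholds.max_evalue:
            break  # scores only decrease from here on
        aln = align_local(q, seq, scoring, db_len=db_len)
        if aln is not None and thresholds.covers(aln):
            return gene_id, aln
    return None


def bidirectional_best_hit(
    seed: SeedProtein,
    seed_proteome: Proteome,
    target: Proteome,
    thresholds: Thresholds | None = None,
    scoring: ScoringScheme | None = None,
) -> OrthologCall:
    """Run the BBH test for one seed against one target proteome.

    ``is_bbh`` is True iff the forward best hit ``g`` exists and the best
    hit of ``g`` back in the seed proteome is the seed itself.
    """
    seed_ids = {g for g, _ in seed_proteome.proteins}
    if seed.name not in seed_ids:
        raise ValueError(f"seed {seed.name!r} is not a member of the seed proteome")
    fwd = best_hit(seed.sequence, target, thresholds, scoring)
    if fwd is None:
        return OrthologCall(seed.name, target.genome_id, None, None, None, False)
    gene_id, fwd_aln = fwd
    rev = best_hit(target.sequence_of(gene_id), seed_proteome, thresholds, scoring)
    rev_gene, rev_aln = rev if rev is not None else (None, None)
    return OrthologCall(
        seed=seed.name,
        genome_id=target.genome_id,
        gene_id=gene_id,
        forward=fwd_aln,
        reverse=rev_aln,
        is_bbh=rev_gene == seed.name,
    )


def call_orthologs(
    seeds: list[SeedProtein],
    proteomes: list[Proteome],
    thresholds: Thresholds | None = None,
    scoring: ScoringScheme | None = None,
    seed_proteome: Proteome | None = None,
    progress: bool = False,
) -> list[OrthologCall]:
    """BBH calls for every (seed, genome) combination.

    The seed proteome (reverse-search database) defaults to the seeds
    themselves, mirroring a search seeded from curated reference proteins.
    """
    names = [s.name for s in seeds]
    if len(names) != len(set(names)):
        raise ValueError("seed names must be unique")
    if seed_proteome is None:
        seed_proteome = Proteome("seeds", [(s.name, s.sequence) for s in seeds])
    calls: list[OrthologCall] = []
    for i, target in enumerate(proteomes):
        for seed in seeds:
            calls.append(
                bidirectional_best_hit(seed, seed_proteome, target, thresholds, scoring)
            )
        if progress:
            print(f"  orthology: {i + 1}/{len(proteomes)} proteomes", file=sys.stderr)
    return calls


def detect_fusions(
    calls: list[OrthologCall], overlap_tolerance: int = 10
) -> list[FusionCall]:
    """Flag genes that are the forward hit of >=2 seeds on disjoint spans.

    Two seeds hitting the same gene over essentially the same span (overlap
    greater than ``overlap_tolerance`` residues) indicate a shared domain,
    not a fusion, and are not reported.
    """
    by_gene: dict[tuple[str, str], list[OrthologCall]] = {}
    for c in calls:
        if c.gene_id is not None and c.forward is not None:
            by_gene.setdefault((c.genome_id, c.gene_id), []).append(c)
    fusions: list[FusionCall] = []
    for (genome_id, gene_id), hits in sorted(by_gene.items()):
        if len(hits) < 2:
            continue
        hits = sorted(hits, key=lambda c: c.seed)
        for i in range(len(hits)):
            for j in range(i + 1, len(hits)):
                a, b = hits[i].forward.subject_span, hits[j].forward.subject_span
                overlap = min(a[1], b[1]) - max(a[0], b[0])
                if overlap <= overlap_tolerance:
                    fusions.append(
                        FusionCall(gene_id, genome_id, hits[i].seed, hits[j].seed, a, b)
                    )
    return fusions


def calls_to_table(calls: list[OrthologCall]) -> pd.DataFrame:
    """Flatten calls into the ortholog TSV layout."""
    rows = []
    for c in calls:
        f = c.forward
        rows.append(
            {
                "seed": c.seed,
                "genome_id": c.genome_id,
                "gene_id": c.gene_id if c.gene_id is not None else "",
                "bit_score": round(f.bit_score, 2) if f else float("nan"),
                "evalue": f.evalue if f else float("nan"),
                "q_cov": round(f.query_coverage, 4) if f else float("nan"),
                "s_cov": round(f.subject_coverage, 4) if f else float("nan"),
                "identity": round(f.identity, 4) if f else float("nan"),
                "is_bbh": int(c.is_bbh),
            }
        )
    return pd.DataFrame(rows)


def fusions_to_table(fusions: list[FusionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "genome_id": f.genome_id,
                "gene_id": f.gene_id,
                "seed_a": f.seed_a,
                "seed_b": f.seed_b,
                "span_a_start": f.span_a[0],
                "span_a_end": f.span_a[1],
                "span_b_start": f.span_b[0],
                "span_b_end": f.span_b[1],
            }
            for f in fusions
        ],
        columns=[
            "genome_id",
            "gene_id",
            "seed_a",
            "seed_b",
            "span_a_start",
            "span_a_end",
            "span_b_start",
            "span_b_end",
        ],
    )
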