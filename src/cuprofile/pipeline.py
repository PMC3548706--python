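"""End-to-end orchestration: orthologs -> profiles -> clustering -> context.

A run is fully specified by a :class:`RunConfig` (serialisable to YAML).
Every stage writes its table to the output directory and is a pure
function of the inputs plus the config, so re-running a config reproduces
identical files; a manifest records the config hash alongside per-file
checksums for auditability.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .clustering import double_optimization, pair_correlation_report, single_optimization
from .context import Annotation, location_summary, operon_runs
from .io import read_proteomes_manifest, read_seeds
from .orthology import (
    Thresholds,
    call_orthologs,
    calls_to_table,
    detect_fusions,
    fusions_to_table,
)
from .profiles import (
    Taxonomy,
    aggregate_by_genus,
    build_presence_matrix,
    ensemble_abundance,
    genus_profile_table,
)

__all__ = ["RunConfig", "run_pipeline", "summarize", "PipelineError"]

CONFIG_VERSION = 1


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Paths and parameters of one reproducible pipeline run.

    Defaults are the standard operating point of this kind of survey:
    E-value cutoff 1e-3, >= 50% query-and/or-subject coverage, 11
    discretisation intervals and CAST affinity threshold 0.5.
    """

    seeds: str = "seeds.faa"
    proteome_manifest: str = "manifest.tsv"
    taxonomy: str = "taxonomy.tsv"
    tree: str = "genera.nwk"
    annotation: str = "annotation.tsv"
    out_dir: str = "results"
    max_evalue: float = 1e-3
    min_coverage: float = 0.5
    coverage_mode: str = "any"
    affinity_threshold: float = 0.5
    profile_values: str = "intervals"  # or "fractions"
    max_gap: int = 0
    fusion_overlap_tolerance: int = 10
    rng_seed: int = 0
    config_version: int = CONFIG_VERSION

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        version = data.get("config_version", CONFIG_VERSION)
        if version != CONFIG_VERSION:
            raise PipelineError(f"unsupported config_version {version}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig, base_dir=".", verbose: bool = False) -> dict:
    """Execute every stage and write the full report bundle.

    Returns a dict of the in-memory stage results keyed by stage name.
    Any stage failure is re-raised as :class:`PipelineError` naming the
    stage.
    """
    base = Path(base_dir)
    out = base / config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    results: dict = {}

    def log(stage: str, msg: str) -> None:
        if verbose:
            print(f"[{stage}] {msg}", file=sys.stderr)

    def write(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=index)
        written.append(path)

    def stage(name):
        def deco(fn):
            try:
                results[name] = fn()
                log(name, "done")
            except Exception as exc:  # noqa: BLE001 - surfaced with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return results[name]

        return deco

    @stage("inputs")
    def _inputs():
        return {
            "seeds": read_seeds(base / config.seeds),
            "proteomes": read_proteomes_manifest(base / config.proteome_manifest),
            "taxonomy": Taxonomy.from_tsv(base / config.taxonomy),
            "annotation": Annotation.from_tsv(base / config.annotation),
            "tree": (base / config.tree).read_text().strip(),
        }

    inputs = results["inputs"]
    thresholds = Thresholds(
        max_evalue=config.max_evalue,
        min_coverage=config.min_coverage,
        coverage_mode=config.coverage_mode,
    )

    @stage("orthologs")
    def _orthologs():
        calls = call_orthologs(
            inputs["seeds"], inputs["proteomes"], thresholds, progress=verbose
        )
        write(calls_to_table(calls), "orthologs.tsv")
        fusions = detect_fusions(calls, config.fusion_overlap_tolerance)
        write(fusions_to_table(fusions), "fusions.tsv")
        return {"calls": calls, "fusions": fusions}

    calls = results["orthologs"]["calls"]

    @stage("profile")
    def _profile():
        genomes = [p.genome_id for p in inputs["proteomes"]]
        seeds = [s.name for s in inputs["seeds"]]
        presence = build_presence_matrix(calls, genomes, seeds)
        write(presence.rename_axis("genome_id"), "presence_matrix.tsv", index=True)
        profile = aggregate_by_genus(presence, inputs["taxonomy"])
        write(genus_profile_table(profile), "genus_profile.tsv")
        abundance = ensemble_abundance(presence)
        write(abundance.rename_axis("seed"), "abundance.tsv", index=True)
        return {"presence": presence, "profile": profile, "abundance": abundance}

    presence = results["profile"]["presence"]
    profile = results["profile"]["profile"]

    @stage("cluster")
    def _cluster():
        single = single_optimization(
            profile,
            inputs["tree"],
            t=config.affinity_threshold,
            use=config.profile_values,
        )
        double = double_optimization(
            profile, t=config.affinity_threshold, use=config.profile_values
        )
        (out / "protein_dendrogram.nwk").write_text(
            double.protein_dendrogram.newick + "\n"
        )
        (out / "taxa_dendrogram.nwk").write_text(double.taxa_dendrogram.newick + "\n")
        written.extend([out / "protein_dendrogram.nwk", out / "taxa_dendrogram.nwk"])
        pclust = double.protein_clusters
        write(
            pd.DataFrame(
                [
                    {
                        "item": lab,
                        "cluster_id": k,
                        "mean_affinity": round(pclust.mean_affinity[lab], 4),
                    }
                    for k, c in enumerate(pclust.clusters)
                    for lab in c
                ]
            ),
            "protein_clusters.tsv",
        )
        assign = double.clade_assignment()
        write(
            pd.DataFrame(
                [
                    {
                        "genus": g,
                        "clade": assign[g],
                        "mean_affinity": round(
                            double.taxa_clusters.mean_affinity[g], 4
                        ),
                    }
                    for g in double.row_order
                ]
            ),
            "repertoire_clades.tsv",
        )
        write(double.clade_table(), "clade_summary.tsv")
        write(
            double.ordered_intervals().rename_axis("genus"),
            "optimized_profile.tsv",
            index=True,
        )
        write(pair_correlation_report(presence), "pair_correlations.tsv")
        return {"single": single, "double": double}

    @stage("context")
    def _context():
        runs = []
        for p in inputs["proteomes"]:
            gene_seeds = {
                c.gene_id: c.seed
                for c in calls
                if c.genome_id == p.genome_id and c.is_bbh and c.gene_id
            }
            if gene_seeds:
                runs.extend(
                    operon_runs(
                        inputs["annotation"], p.genome_id, gene_seeds, config.max_gap
                    )
                )
        runs_df = pd.DataFrame(
            [
                {**r, "gene_ids": ",".join(r["gene_ids"])}
                for r in runs
            ],
            columns=[
                "genome_id",
                "replicon_id",
                "replicon_type",
                "gene_ids",
                "seeds",
                "size",
            ],
        )
        write(runs_df, "operon_runs.tsv")
        summary = location_summary(calls, inputs["annotation"], config.max_gap)
        write(summary, "location_summary.tsv")
        return {"runs": runs, "location_summary": summary}

    @stage("manifest")
    def _manifest():
        config.to_yaml(out / "config.yaml")
        written.append(out / "config.yaml")
        manifest = {
            "config_sha256": config.digest(),
            "cuprofile_version": __version__,
            "rng_seed": config.rng_seed,
            "files": {p.name: _sha256(p) for p in sorted(set(written))},
        }
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        return manifest

    return results


def summarize(out_dir) -> str:
    """Human-readable digest of a completed report bundle."""
    out = Path(out_dir)
    needed = [
        "abundance.tsv",
        "protein_clusters.tsv",
        "repertoire_clades.tsv",
        "clade_summary.tsv",
    ]
    missing = [n for n in needed if not (out / n).exists()]
    if missing:
        raise PipelineError(f"incomplete report bundle; missing: {missing}")
    abundance = pd.read_csv(out / "abundance.tsv", sep="\t")
    clusters = pd.read_csv(out / "protein_clusters.tsv", sep="\t")
    clades = pd.read_csv(out / "clade_summary.tsv", sep="\t")
    lines = ["Per-seed ensemble abundance:"]
    for row in abundance.sort_values("percent", ascending=False).itertuples():
        lines.append(f"  {row.seed:6s} {row.percent:3d}%  ({row.n_present}/{row.n_genomes})")
    lines.append("Protein clusters (CAST):")
    for cid, grp in clusters.groupby("cluster_id"):
        lines.append(f"  cluster {cid}: " + "-".join(grp["item"]))
    lines.append("Repertoire clades:")
    for row in clades.itertuples():
        lines.append(f"  clade {row.clade}: {row.n_genera} genera ({row.genera})")
    return "\n".join(lines) + "\n"
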