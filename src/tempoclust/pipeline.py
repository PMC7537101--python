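"""File-contract pipeline driver: simulate/DE -> cluster -> gene sets.

Stages compose through plain TSV/GMT files rather than only in memory so
that any stage can be swapped for externally produced tables (most usefully
a differential-expression table from a dedicated count-model package). A
run writes, into the output directory: ``de_table.tsv``, ``clusters.tsv``,
``centroids.tsv``, ``enrichment.tsv``, ``intersections.tsv``,
``pathway_aggregates.tsv`` and ``run_manifest.json``; a failed stage leaves
a ``FAILED`` marker naming the stage, with earlier outputs retained.
Re-running with the same config (seed included) reproduces byte-identical
tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .containers import CountMatrix, read_de_table, write_de_table
from .dge import de_all_timepoints, size_factors_median_of_ratios, vst_like
from .genesets import (
    GeneSetCollection,
    aggregate_pathway,
    enrich,
    read_gmt,
    upset_counts,
    write_gmt,
)
from .simdata import (
    SimulationConfig,
    feasible_set_size,
    simulate_counts,
    simulate_gene_sets,
)
from .timecluster import ClusterParams, cluster_profiles, recurrent_gene_report

logger = logging.getLogger("tempoclust")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineParams:
    """Everything needed to reproduce a run.

    Exactly one entry point must be supplied: a counts+metadata TSV pair, a
    precomputed DE table, or a ``simulate`` block for a fully self-contained
    run on synthetic data.
    """

    outdir: Path
    counts: Path | None = None
    metadata: Path | None = None
    de_table: Path | None = None
    gmt: Path | None = None
    cluster: ClusterParams = field(default_factory=ClusterParams)
    alpha: float = 0.05
    pseudocount: float = 1.0
    simulate: SimulationConfig | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        entry_points = [
            self.counts is not None and self.metadata is not None,
            self.de_table is not None,
            self.simulate is not None,
        ]
        if sum(entry_points) != 1:
            raise ValueError(
                "exactly one entry point required: counts+metadata, de_table, "
                "or a simulate block"
            )
        self.outdir = Path(self.outdir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineParams":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "cluster" in kwargs and isinstance(kwargs["cluster"], dict):
            kwargs["cluster"] = ClusterParams(**kwargs["cluster"])
        if "simulate" in kwargs and isinstance(kwargs["simulate"], dict):
            sim = dict(kwargs["simulate"])
            if "timepoints" in sim:
                sim["timepoints"] = tuple(sim["timepoints"])
            kwargs["simulate"] = SimulationConfig(**sim)
        for key in ("outdir", "counts", "metadata", "de_table", "gmt"):
            if kwargs.get(key) is not None:
                kwargs[key] = Path(kwargs[key])
        return cls(**kwargs)

    def manifest(self) -> dict:
        def ser(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: ser(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, Path):
                return str(obj)
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        import numpy, pandas, scipy  # noqa: PLC0415

        return {
            "config": {f.name: ser(getattr(self, f.name)) for f in dataclasses.fields(self)},
            "versions": {
                "tempoclust": __version__,
                "numpy": numpy.__version__,
                "pandas": pandas.__version__,
                "scipy": scipy.__version__,
            },
            "seed": self.seed,
        }


def _updown_lists(de: pd.DataFrame, adjp_threshold: float) -> dict[str, list[str]]:
    lists: dict[str, list[str]] = {}
    for tp in dict.fromkeys(de["timepoint"]):
        sub = de[(de["timepoint"] == tp) & (de["adjp"] < adjp_threshold)]
        up = sorted(sub.loc[sub["log2fc"] > 0, "gene_id"])
        down = sorted(sub.loc[sub["log2fc"] < 0, "gene_id"])
        if up:
            lists[f"{tp}_up"] = up
        if down:
            lists[f"{tp}_down"] = down
    return lists


def run(params: PipelineParams) -> Path:
    """Execute the pipeline described by ``params``; returns the outdir."""
    outdir = params.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    stage = "setup"
    try:
        cm: CountMatrix | None = None
        vst = None

        if params.simulate is not None:
            stage = "simulate"
            logger.info("[simulate] generating synthetic counts")
            cm, truth = simulate_counts(params.simulate)
            cm.to_tsv(outdir / "counts.tsv", outdir / "metadata.tsv")
            truth.to_tsv(outdir / "ground_truth.tsv")
            if params.gmt is None and truth.nonnull_genes:
                sim_gmt = simulate_gene_sets(
                    truth,
                    set_size=feasible_set_size(truth),
                    seed=params.simulate.seed,
                )
                write_gmt(sim_gmt, outdir / "simulated_sets.gmt")
                gmt_path: Path | None = outdir / "simulated_sets.gmt"
            else:
                gmt_path = params.gmt
        elif params.counts is not None:
            stage = "load_counts"
            cm = CountMatrix.from_tsv(params.counts, params.metadata)
            gmt_path = params.gmt
        else:
            gmt_path = params.gmt

        if cm is not None:
            stage = "de"
            logger.info("[de] normalizing and testing %d genes", len(cm.gene_ids))
            sf = size_factors_median_of_ratios(cm)
            vst = vst_like(cm, sf, pseudocount=params.pseudocount)
            de = de_all_timepoints(cm, pseudocount=params.pseudocount)
            timepoints: tuple[str, ...] | None = cm.timepoints
        else:
            stage = "load_de"
            de = read_de_table(params.de_table)
            timepoints = None
        write_de_table(de, outdir / "de_table.tsv")

        stage = "cluster"
        logger.info("[cluster] clustering temporal profiles")
        assignment, std_profiles, _ = cluster_profiles(de, params.cluster, timepoints)
        assignment.to_tsv(outdir / "clusters.tsv")
        assignment.centroids_to_tsv(outdir / "centroids.tsv")

        stage = "enrich"
        enrichment = pd.DataFrame()
        if gmt_path is not None:
            logger.info("[enrich] testing cluster gene sets against %s", gmt_path)
            gmt = read_gmt(gmt_path)
            universe = sorted(de["gene_id"].unique())
            queries = {
                f"cluster_{cid}": genes for cid, genes in assignment.final_members().items()
            }
            enrichment = enrich(queries, gmt, universe=universe, alpha=params.alpha)
            enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        else:
            logger.info("[enrich] no GMT supplied; writing empty enrichment table")
            pd.DataFrame(
                columns=[
                    "query_name", "set_name", "overlap_k", "set_size_K",
                    "query_size_n", "universe_N", "pvalue", "adjp",
                    "significant", "overlap_genes",
                ]
            ).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)

        stage = "intersections"
        lists = _updown_lists(de, params.cluster.adjp_threshold)
        if lists:
            upset_counts(lists).to_csv(outdir / "intersections.tsv", sep="\t", index=False)
        else:
            pd.DataFrame(columns=["combination", "degree", "exclusive_count"]).to_csv(
                outdir / "intersections.tsv", sep="\t", index=False
            )

        stage = "aggregate"
        agg_cols = ["pathway", "genotype", "timepoint", "replicate", "sample_id", "mean_vst"]
        if vst is not None and not enrichment.empty and enrichment["significant"].any():
            sig = enrichment[enrichment["significant"]]
            pathways = {
                f"{r.query_name}:{r.set_name}": r.overlap_genes.split(",")
                for r in sig.itertuples()
                if r.overlap_genes
            }
            if pathways:
                agg = aggregate_pathway(vst, cm.design, pathways)
                agg.to_csv(outdir / "pathway_aggregates.tsv", sep="\t", index=False)
            else:
                pd.DataFrame(columns=agg_cols).to_csv(
                    outdir / "pathway_aggregates.tsv", sep="\t", index=False
                )
        else:
            logger.info("[aggregate] no expression matrix or no significant pathways")
            pd.DataFrame(columns=agg_cols).to_csv(
                outdir / "pathway_aggregates.tsv", sep="\t", index=False
            )

        stage = "recurrence"
        report = recurrent_gene_report(de, params.cluster)
        with open(outdir / "recurrent_genes.json", "w", encoding="utf-8") as fh:
            json.dump({str(k): v for k, v in report.items()}, fh, indent=1)

        stage = "manifest"
        with open(outdir / "run_manifest.json", "w", encoding="utf-8") as fh:
            json.dump(params.manifest(), fh, indent=1, sort_keys=True)
    except Exception as exc:
        failed_marker.write_text(f"stage: {stage}\nerror: {exc}\n", encoding="utf-8")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return outdir
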