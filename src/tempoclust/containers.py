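"""Core data containers shared across the pipeline stages.

The pipeline's on-disk contracts are plain TSV files (tab-separated, UTF-8,
'.' decimal, mandatory header, no quoting) so that any stage can be replaced
by externally produced tables — in particular, a differential-expression
table produced by a dedicated count-model package can be fed straight into
the clustering stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GENOTYPES = ("WT", "MUT")

#: Default ordered ages of the two-genotype cortical time course being emulated.
DEFAULT_TIMEPOINTS = ("E14.5", "1mo", "6mo", "12mo")

DESIGN_COLUMNS = ("genotype", "timepoint", "replicate", "batch")


class ValidationError(ValueError):
    """Raised when an input table violates its documented contract."""


@dataclass
class CountMatrix:
    """Gene x sample matrix of nonnegative integer counts plus the sample design.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id with one column per sample id.
    design
        DataFrame indexed by sample id with columns ``genotype`` (WT/MUT),
        ``timepoint``, ``replicate`` and ``batch``.
    timepoints
        The ordered timepoint labels. Order matters: it defines the x-axis of
        every temporal profile downstream.
    """

    counts: pd.DataFrame
    design: pd.DataFrame
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS

    def __post_init__(self) -> None:
        self.timepoints = tuple(self.timepoints)
        self.validate()

    def validate(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValidationError("duplicate gene ids in count matrix")
        if self.counts.columns.duplicated().any():
            raise ValidationError("duplicate sample ids in count matrix")
        missing = [c for c in DESIGN_COLUMNS if c not in self.design.columns]
        if missing:
            raise ValidationError(f"design table missing columns: {missing}")
        if set(self.counts.columns) != set(self.design.index):
            raise ValidationError("count matrix samples and design samples differ")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValidationError("counts must be integers")
        if (vals < 0).any():
            raise ValidationError("counts must be nonnegative")
        bad_geno = set(self.design["genotype"]) - set(GENOTYPES)
        if bad_geno:
            raise ValidationError(f"unknown genotype labels: {sorted(bad_geno)}")
        bad_tp = set(self.design["timepoint"]) - set(self.timepoints)
        if bad_tp:
            raise ValidationError(f"timepoints not in declared order set: {sorted(bad_tp)}")
        if len(set(self.timepoints)) != len(self.timepoints):
            raise ValidationError("timepoint labels must be distinct")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_at(self, timepoint: str) -> pd.DataFrame:
        """Design rows for one timepoint, both genotypes."""
        return self.design[self.design["timepoint"] == timepoint]

    # ---- TSV round trip -------------------------------------------------
    def to_tsv(self, counts_path: str | Path, design_path: str | Path) -> None:
        counts = self.counts.copy()
        counts.index.name = "gene_id"
        counts.to_csv(counts_path, sep="\t")
        design = self.design.copy()
        design.index.name = "sample_id"
        design.loc[:, DESIGN_COLUMNS].to_csv(design_path, sep="\t")

    @classmethod
    def from_tsv(
        cls,
        counts_path: str | Path,
        design_path: str | Path,
        timepoints: tuple[str, ...] | None = None,
    ) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        design = pd.read_csv(design_path, sep="\t", index_col=0, dtype={"batch": str})
        design["batch"] = design["batch"].astype(str)
        if timepoints is None:
            # preserve first-appearance order of the design file
            timepoints = tuple(dict.fromkeys(design["timepoint"]))
        return cls(counts=counts, design=design, timepoints=tuple(timepoints))


DE_TABLE_COLUMNS = ["gene_id", "timepoint", "log2fc", "pvalue", "adjp", "mean_expr"]


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a per-(gene, timepoint) differential-expression table.

    Expected columns: gene_id, timepoint, log2fc, pvalue, adjp, mean_expr.
    This is both the output format of the bundled DE stage and the accepted
    input format for externally computed results.
    """
    # round_trip: the writer emits shortest round-trippable decimals, and the
    # default fast parser can be one ulp off, breaking byte-identical reruns
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in DE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"DE table {path} missing columns: {missing}")
    return df[DE_TABLE_COLUMNS]


def write_de_table(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, DE_TABLE_COLUMNS].to_csv(path, sep="\t", index=False)


@dataclass
class GroundTruth:
    """Planted per-gene truth emitted alongside a simulated count matrix.

    ``table`` has one row per gene: the template name (or ``"null"``) and the
    planted log2 fold-change at every timepoint. ``true_size_factors`` records
    the library-size multipliers applied per sample, so normalization can be
    checked against truth.
    """

    table: pd.DataFrame  # index gene_id; columns: template, log2fc_<tp>...
    true_size_factors: pd.Series = field(default=None)  # type: ignore[assignment]

    @property
    def nonnull_genes(self) -> list[str]:
        return list(self.table.index[self.table["template"] != "null"])

    def planted_log2fc(self) -> pd.DataFrame:
        cols = [c for c in self.table.columns if c.startswith("log2fc_")]
        out = self.table[cols].copy()
        out.columns = [c[len("log2fc_"):] for c in cols]
        return out

    def to_tsv(self, path: str | Path) -> None:
        t = self.table.copy()
        t.index.name = "gene_id"
        t.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GroundTruth":
        return cls(table=pd.read_csv(path, sep="\t", index_col=0))
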