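"""Core containers and tab-separated readers/writers.

The pipeline works on RPKM expression matrices (genes x samples) from
FACS-sorted pharyngeal-arch cell populations, together with a sample design
table that records, for every sample, which sorted population it came from
(GFP/DsRed double-positive arch NCCs, or the GFP-only / DsRed-only
contaminating fractions), the developmental stage (20, 28 or 36 hours
post-fertilization) and the genetic/pharmacological condition.

All files are plain TSV with UTF-8 encoding and "." decimals, so that a
write -> read round trip is bit-exact.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "POPULATIONS",
    "STAGES",
    "CONTRAST_CONDITIONS",
    "FormatError",
    "ConfigurationError",
    "ExpressionMatrix",
    "SampleDesign",
    "ContrastSpec",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_design",
    "write_sample_design",
    "compute_rpkm",
    "resolve_contrasts",
]

POPULATIONS = ("double_positive", "gfp_only", "dsred_only", "double_negative")
STAGES = (20, 28, 36)

#: condition labels expected for each named perturbation-vs-control contrast.
#: The Edn1 and NICD overexpression arms share the heat-shock driver-only
#: control; the DBZ arm is compared to its vehicle (DMSO) control.
CONTRAST_CONDITIONS: Mapping[str, tuple[str, str]] = {
    "edn1_mut": ("edn1_mut", "edn1_ctrl"),
    "jag1b_mut": ("jag1b_mut", "jag1b_ctrl"),
    "edn1_oe": ("edn1_oe", "hs_ctrl"),
    "nicd_oe": ("nicd_oe", "hs_ctrl"),
    "dbz": ("dbz", "vehicle_ctrl"),
}


class FormatError(ValueError):
    """A file violates the TSV contract (duplicates, bad cells, ...)."""


class ConfigurationError(ValueError):
    """The sample design cannot support a requested operation."""


class ExpressionMatrix:
    """Non-negative gene x sample RPKM matrix with unique identifiers.

    Thin validated wrapper around a :class:`pandas.DataFrame` whose index
    holds gene ids and whose columns hold sample ids.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.name is None:
            data = data.rename_axis("gene_id")
        dup = data.index[data.index.duplicated()]
        if len(dup):
            raise FormatError(f"duplicate gene id: {dup[0]!r}")
        dup = data.columns[data.columns.duplicated()]
        if len(dup):
            raise FormatError(f"duplicate sample id: {dup[0]!r}")
        values = data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("expression values must be numeric")
        if np.isnan(values).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise FormatError(
                f"missing value at gene {data.index[r]!r}, sample {data.columns[c]!r}"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative value at gene {data.index[r]!r}, sample {data.columns[c]!r}"
            )
        self.data = data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def value(self, gene: str, sample: str) -> float:
        return float(self.data.at[gene, sample])

    def column(self, sample: str) -> pd.Series:
        if sample not in self.data.columns:
            raise KeyError(f"unknown sample: {sample!r}")
        return self.data[sample]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.data.equals(other.data)

    def __repr__(self) -> str:
        return f"ExpressionMatrix({len(self.data)} genes x {self.data.shape[1]} samples)"


@dataclasses.dataclass(frozen=True)
class ContrastSpec:
    """A named perturbed-vs-control sample pair (double-positive cells)."""

    name: str
    perturbed_sample: str
    control_sample: str

    def __post_init__(self):
        if self.perturbed_sample == self.control_sample:
            raise ConfigurationError(
                f"contrast {self.name!r}: perturbed and control sample coincide"
            )


class SampleDesign:
    """Maps each sample to its sorted population, stage and condition."""

    REQUIRED_COLUMNS = ("sample_id", "population", "stage_hpf", "condition")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED_COLUMNS if c not in table.columns]
        if missing:
            raise FormatError(f"sample design missing columns: {missing}")
        table = table.loc[:, list(self.REQUIRED_COLUMNS)].copy()
        table["sample_id"] = table["sample_id"].astype(str)
        table["population"] = table["population"].astype(str)
        table["stage_hpf"] = table["stage_hpf"].astype(int)
        table["condition"] = table["condition"].astype(str)
        dup = table["sample_id"][table["sample_id"].duplicated()]
        if len(dup):
            raise FormatError(f"duplicate sample id: {dup.iloc[0]!r}")
        bad = set(table["population"]) - set(POPULATIONS)
        if bad:
            raise FormatError(f"unknown population label(s): {sorted(bad)}")
        bad_stage = set(table["stage_hpf"]) - set(STAGES)
        if bad_stage:
            raise FormatError(f"unknown stage(s): {sorted(bad_stage)} (expected {STAGES})")
        self.table = table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def find(
        self,
        population: str | None = None,
        stage_hpf: int | None = None,
        condition: str | None = None,
    ) -> list[str]:
        """Sample ids matching every given field, in table order."""
        mask = pd.Series(True, index=self.table.index)
        if population is not None:
            mask &= self.table["population"] == population
        if stage_hpf is not None:
            mask &= self.table["stage_hpf"] == int(stage_hpf)
        if condition is not None:
            mask &= self.table["condition"] == condition
        return list(self.table.loc[mask, "sample_id"])

    def one(
        self,
        population: str | None = None,
        stage_hpf: int | None = None,
        condition: str | None = None,
    ) -> str:
        """The unique matching sample id, or a configuration error."""
        hits = self.find(population, stage_hpf, condition)
        what = f"population={population}, stage={stage_hpf}, condition={condition}"
        if not hits:
            raise ConfigurationError(f"no sample with {what}")
        if len(hits) > 1:
            raise ConfigurationError(f"multiple samples with {what}: {hits}")
        return hits[0]

    def check_against(self, matrix: ExpressionMatrix) -> None:
        missing = set(self.sample_ids) - set(matrix.sample_ids)
        if missing:
            raise ConfigurationError(
                f"design references samples absent from the matrix: {sorted(missing)}"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SampleDesign):
            return NotImplemented
        return self.table.equals(other.table)


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a `gene_id<TAB>sample...` RPKM matrix, preserving row/col order."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    seen: set[str] = set()
    for s in samples:
        if s in seen:
            raise FormatError(f"duplicate sample id: {s!r}")
        seen.add(s)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, encoding="utf-8")
    raw.columns = samples  # undo pandas' mangling of any duplicate headers
    try:
        data = raw.apply(pd.to_numeric)
    except (ValueError, TypeError):
        for sample in raw.columns:
            col = pd.to_numeric(raw[sample], errors="coerce")
            bad = col.index[col.isna() & raw[sample].notna()]
            if len(bad):
                raise FormatError(
                    f"non-numeric value at gene {bad[0]!r}, sample {sample!r}"
                ) from None
        raise
    return ExpressionMatrix(data)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", encoding="utf-8")


def read_sample_design(path: str | Path) -> SampleDesign:
    table = pd.read_csv(path, sep="\t", encoding="utf-8")
    return SampleDesign(table)


def write_sample_design(design: SampleDesign, path: str | Path) -> None:
    design.table.to_csv(path, sep="\t", index=False, encoding="utf-8")


def compute_rpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    totals: pd.Series,
) -> ExpressionMatrix:
    """Reads per kilobase per million mapped reads from raw counts.

    RPKM(g, s) = 1e9 * count(g, s) / (length_bp(g) * total_mapped(s)).

    This is the standard definition; pipelines that already provide RPKM
    matrices (however quantified) can skip this step entirely.
    """
    lengths = lengths.reindex(counts.index)
    totals = totals.reindex(counts.columns)
    if lengths.isna().any():
        raise ValueError("gene length missing for some genes in the count matrix")
    if totals.isna().any():
        raise ValueError("library size missing for some samples in the count matrix")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if (totals <= 0).any():
        raise ValueError("library sizes must be positive")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    values = 1e9 * counts.div(lengths, axis=0).div(totals, axis=1)
    return ExpressionMatrix(values)


def resolve_contrasts(
    design: SampleDesign, requested: Iterable[str]
) -> list[ContrastSpec]:
    """Resolve contrast names to double-positive 36 hpf sample pairs.

    Deterministic given the design (and independent of its row order, since
    each lookup must be unique).
    """
    specs: list[ContrastSpec] = []
    for name in requested:
        if name not in CONTRAST_CONDITIONS:
            raise ConfigurationError(
                f"unknown contrast {name!r}; expected one of {sorted(CONTRAST_CONDITIONS)}"
            )
        perturbed_cond, control_cond = CONTRAST_CONDITIONS[name]
        try:
            perturbed = design.one("double_positive", 36, perturbed_cond)
            control = design.one("double_positive", 36, control_cond)
        except ConfigurationError as exc:
            raise ConfigurationError(f"contrast {name!r}: {exc}") from None
        specs.append(ContrastSpec(name, perturbed, control))
    return specs
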