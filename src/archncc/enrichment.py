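"""Arch NCC enrichment filtering.

Two-step filter defining the per-stage "arch-enriched" gene sets:

1. Minimum expression: genes with RPKM <= ``min_rpkm`` (default 3) in the
   wild-type double-positive 36 hpf reference sample are discarded.
2. Double-positive enrichment: a gene is retained at a stage only if its
   double-positive RPKM is at least ``enrichment_ratio`` (default 1.5,
   inclusive) times its RPKM in *both* single-positive fractions at that
   stage.  This removes erythroid/macrophage/ear transcripts carried over
   from the GFP-only and DsRed-only contaminating populations.

Zero denominators are replaced by ``zero_replacement`` (default 0.01, the
smallest positive RPKM observed in the original dataset) so every ratio is
defined.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import ConfigurationError, ExpressionMatrix, SampleDesign, STAGES

__all__ = [
    "EnrichmentThresholds",
    "filter_min_expression",
    "filter_arch_enriched",
    "arch_enriched_sets",
]


@dataclasses.dataclass(frozen=True)
class EnrichmentThresholds:
    min_rpkm: float = 3.0          # genes with value <= min_rpkm are excluded
    enrichment_ratio: float = 1.5  # inclusive: DP/SP >= ratio retains
    zero_replacement: float = 0.01

    def __post_init__(self):
        if self.min_rpkm < 0:
            raise ValueError("min_rpkm must be >= 0")
        if self.enrichment_ratio <= 0:
            raise ValueError("enrichment_ratio must be > 0")
        if self.zero_replacement <= 0:
            raise ValueError("zero_replacement must be > 0")


def filter_min_expression(
    matrix: ExpressionMatrix,
    reference_sample: str,
    thresholds: EnrichmentThresholds = EnrichmentThresholds(),
) -> set[str]:
    """Genes with RPKM strictly above ``min_rpkm`` in the reference sample."""
    col = matrix.column(reference_sample)
    return set(col.index[col > thresholds.min_rpkm])


def _replaced(col: pd.Series, zero_replacement: float) -> pd.Series:
    return col.where(col > 0, zero_replacement)


def filter_arch_enriched(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    stage_hpf: int,
    thresholds: EnrichmentThresholds = EnrichmentThresholds(),
    genes: Iterable[str] | None = None,
    single_positive_stage: int | None = None,
    condition: str = "wt",
) -> set[str]:
    """Genes enriched in double-positive over both single-positive fractions.

    ``genes`` restricts the candidate set (normally the output of
    :func:`filter_min_expression`); by default all genes are candidates.
    ``single_positive_stage`` allows the single-positive reference fractions
    to be taken from a different stage than the double-positive sample
    (default: stage-matched).
    """
    sp_stage = stage_hpf if single_positive_stage is None else single_positive_stage
    dp = matrix.column(design.one("double_positive", stage_hpf, condition))
    gfp = matrix.column(design.one("gfp_only", sp_stage, condition))
    dsred = matrix.column(design.one("dsred_only", sp_stage, condition))
    if genes is not None:
        keep = dp.index.intersection(list(genes))
        dp, gfp, dsred = dp.loc[keep], gfp.loc[keep], dsred.loc[keep]
    z = thresholds.zero_replacement
    r = thresholds.enrichment_ratio
    ok = (dp / _replaced(gfp, z) >= r) & (dp / _replaced(dsred, z) >= r)
    return set(dp.index[ok])


def arch_enriched_sets(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    thresholds: EnrichmentThresholds = EnrichmentThresholds(),
    stages: Iterable[int] = STAGES,
    single_positive_stage: int | None = None,
    condition: str = "wt",
) -> dict[int, set[str]]:
    """Per-stage arch-enriched gene sets (min filter at 36 hpf, then ratios).

    The 36 hpf set is the "total" arch gene list used as the classification
    universe downstream.
    """
    reference = design.one("double_positive", 36, condition)
    expressed = filter_min_expression(matrix, reference, thresholds)
    return {
        int(stage): filter_arch_enriched(
            matrix,
            design,
            int(stage),
            thresholds,
            genes=expressed,
            single_positive_stage=single_positive_stage,
            condition=condition,
        )
        for stage in stages
    }
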