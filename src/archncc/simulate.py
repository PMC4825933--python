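"""Synthetic RPKM datasets with planted, labelled gene classes.

The generator emulates the full FACS/RNA-seq experimental design: wild-type
double-positive (arch NCC) samples at 20, 28 and 36 hpf with matching
GFP-only and DsRed-only contaminating fractions, plus perturbed/control
double-positive pairs at 36 hpf for the five contrasts (edn1 mutant, jag1b
mutant, Edn1 overexpression, NICD overexpression, DBZ treatment).  Every
gene carries exactly one planted class label, so the enrichment filter, the
pathway classifier and the temporal statistics can all be verified by
recovering the labels.

Expression model (one sample per condition, no replicates, as in the
underlying design):

    value = baseline × population multiplier × stage multiplier
            × perturbation-response multiplier × exp(N(0, noise_sd))

Baselines are log-normal with a floor, arch genes are attenuated in the
single-positive fractions, contaminants are elevated there, and planted
responders move by ``effect_multiplier`` in the appropriate direction in
each perturbation arm.  A configurable subset of the Notch-inhibited class
is additionally strongly induced between 20 and 28 hpf, reproducing the
temporal signature of genes repressed by Notch at the onset of
skeletogenesis.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, SampleDesign

__all__ = [
    "CLASSES",
    "UNREGULATED",
    "SimulationParams",
    "generate_dataset",
    "plant_worked_example",
]

#: the ten planted classes; genes left over after the fractions are filled
#: carry the UNREGULATED label (broadly expressed, not arch-enriched).
CLASSES = (
    "arch_enriched",
    "contaminant_erythroid",
    "contaminant_macrophage",
    "contaminant_ear",
    "notch_inhibited",
    "notch_activated",
    "edn1_inhibited",
    "edn1_activated",
    "co_regulated_positive",
    "co_regulated_negative",
)
UNREGULATED = "unregulated"

#: perturbation response direction per class: +1 responds like a gene the
#: pathway inhibits in that arm's loss direction, etc.  Encoded directly as
#: the exponent applied to effect_multiplier per condition.
_RESPONSE_EXPONENTS: Mapping[str, Mapping[str, int]] = {
    "notch_inhibited": {"jag1b_mut": +1, "dbz": +1, "nicd_oe": -1},
    "notch_activated": {"jag1b_mut": -1, "dbz": -1, "nicd_oe": +1},
    "edn1_inhibited": {"edn1_mut": +1, "edn1_oe": -1},
    "edn1_activated": {"edn1_mut": -1, "edn1_oe": +1},
    "co_regulated_positive": {
        "nicd_oe": +1,
        "edn1_oe": +1,
        "jag1b_mut": -1,
        "dbz": -1,
        "edn1_mut": -1,
    },
    "co_regulated_negative": {
        "nicd_oe": -1,
        "edn1_oe": -1,
        "jag1b_mut": +1,
        "dbz": +1,
        "edn1_mut": +1,
    },
}

#: contamination source fraction per contaminant class.  Hemoglobin-like
#: erythroid transcripts behave as ambient RNA and run high in both sorted
#: single-positive fractions; macrophage transcripts ride along with the
#: GFP-only (fli1a) fraction and otic transcripts with the DsRed-only
#: (sox10) fraction.
_CONTAMINANT_SOURCE = {
    "contaminant_erythroid": "both",
    "contaminant_macrophage": "gfp_only",
    "contaminant_ear": "dsred_only",
}

_DEFAULT_FRACTIONS: Mapping[str, float] = {
    "arch_enriched": 0.05,
    "contaminant_erythroid": 0.02,
    "contaminant_macrophage": 0.02,
    "contaminant_ear": 0.02,
    "notch_inhibited": 0.06,
    "notch_activated": 0.06,
    "edn1_inhibited": 0.06,
    "edn1_activated": 0.06,
    "co_regulated_positive": 0.01,
    "co_regulated_negative": 0.01,
}


@dataclasses.dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic experiment.

    ``class_fractions`` maps each planted class to its share of the
    ``n_genes`` genes; the remainder is broadly expressed, non-enriched
    background.  ``effect_multiplier`` is the fold-response of a planted
    responder in each perturbation arm; ``induction_multiplier_20_28``/
    ``_28_36`` replace the baseline stage multipliers for the strongly
    induced subset of the Notch-inhibited class.  Noise is multiplicative
    log-normal per matrix cell, with ``noise_sd`` on the natural-log scale.
    """

    n_genes: int = 5000
    class_fractions: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(_DEFAULT_FRACTIONS)
    )
    baseline_log_mean: float = float(np.log(50.0))
    baseline_log_sd: float = 1.0
    baseline_floor: float = 10.0
    effect_multiplier: float = 4.0
    stage_multiplier_20_28: float = 1.46
    stage_multiplier_28_36: float = 1.18
    induction_multiplier_20_28: float = 12.0
    induction_multiplier_28_36: float = 1.5
    induced_fraction_within_notch_inhibited: float = 0.5
    sp_attenuation: float = 0.25
    contaminant_enrichment: float = 4.0
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self):
        unknown = set(self.class_fractions) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown class(es) in fractions: {sorted(unknown)}")
        if any(f < 0 for f in self.class_fractions.values()):
            raise ValueError("class fractions must be non-negative")
        if sum(self.class_fractions.values()) > 1 + 1e-9:
            raise ValueError("class fractions must sum to at most 1")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.effect_multiplier <= 1:
            raise ValueError("effect_multiplier must be > 1")
        for name in (
            "stage_multiplier_20_28",
            "stage_multiplier_28_36",
            "induction_multiplier_20_28",
            "induction_multiplier_28_36",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 <= self.induced_fraction_within_notch_inhibited <= 1:
            raise ValueError(
                "induced_fraction_within_notch_inhibited must lie in [0, 1]"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _sample_table() -> pd.DataFrame:
    rows = []
    for stage in (20, 28, 36):
        rows.append((f"wt_dp_{stage}", "double_positive", stage, "wt"))
        rows.append((f"wt_gfp_{stage}", "gfp_only", stage, "wt"))
        rows.append((f"wt_dsred_{stage}", "dsred_only", stage, "wt"))
    for cond in (
        "edn1_mut",
        "edn1_ctrl",
        "jag1b_mut",
        "jag1b_ctrl",
        "edn1_oe",
        "nicd_oe",
        "hs_ctrl",
        "dbz",
        "vehicle_ctrl",
    ):
        rows.append((f"{cond}_dp_36", "double_positive", 36, cond))
    return pd.DataFrame(
        rows, columns=["sample_id", "population", "stage_hpf", "condition"]
    )


def _class_labels(params: SimulationParams) -> np.ndarray:
    counts = {c: int(round(params.class_fractions.get(c, 0.0) * params.n_genes))
              for c in CLASSES}
    total = sum(counts.values())
    if total > params.n_genes:  # rounding pushed past n_genes; trim background
        counts["arch_enriched"] -= total - params.n_genes
        if counts["arch_enriched"] < 0:
            raise ValueError("class fractions leave no room after rounding")
    labels = np.array(
        [c for c in CLASSES for _ in range(counts[c])]
        + [UNREGULATED] * (params.n_genes - sum(counts.values())),
        dtype=object,
    )
    return labels


def generate_dataset(
    params: SimulationParams = SimulationParams(),
) -> tuple[ExpressionMatrix, SampleDesign, pd.DataFrame]:
    """Simulate the full design; returns (matrix, design, truth).

    The truth table has one row per gene with its planted ``class``, the
    contamination ``source`` fraction (or ``none``) and whether the gene
    belongs to the strongly ``induced`` temporal subset.  Identical params
    (including seed) give byte-identical output.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_genes
    labels = _class_labels(params)
    width = max(4, len(str(n - 1)))
    gene_ids = np.array([f"g{i:0{width}d}" for i in range(n)], dtype=object)

    baseline = np.exp(
        rng.normal(params.baseline_log_mean, params.baseline_log_sd, size=n)
    )
    baseline = np.maximum(baseline, params.baseline_floor)

    is_contaminant = np.isin(labels, list(_CONTAMINANT_SOURCE))
    is_unregulated = labels == UNREGULATED
    is_arch = ~is_contaminant & ~is_unregulated

    induced = np.zeros(n, dtype=bool)
    ni = labels == "notch_inhibited"
    induced[ni] = (
        rng.random(int(ni.sum())) < params.induced_fraction_within_notch_inhibited
    )

    m28 = np.where(induced, params.induction_multiplier_20_28,
                   params.stage_multiplier_20_28)
    m36 = np.where(induced, params.induction_multiplier_28_36,
                   params.stage_multiplier_28_36)
    dp = {20: baseline, 28: baseline * m28, 36: baseline * m28 * m36}

    gfp_mult = np.ones(n)
    dsred_mult = np.ones(n)
    gfp_mult[is_arch] = params.sp_attenuation
    dsred_mult[is_arch] = params.sp_attenuation
    for cls, source in _CONTAMINANT_SOURCE.items():
        mask = labels == cls
        if source in ("gfp_only", "both"):
            gfp_mult[mask] = params.contaminant_enrichment
        else:
            gfp_mult[mask] = params.sp_attenuation
        if source in ("dsred_only", "both"):
            dsred_mult[mask] = params.contaminant_enrichment
        else:
            dsred_mult[mask] = params.sp_attenuation

    response: dict[str, np.ndarray] = {}
    for cond in ("edn1_mut", "jag1b_mut", "edn1_oe", "nicd_oe", "dbz"):
        mult = np.ones(n)
        for cls, exponents in _RESPONSE_EXPONENTS.items():
            if cond in exponents:
                mult[labels == cls] = params.effect_multiplier ** exponents[cond]
        response[cond] = mult

    design = SampleDesign(_sample_table())
    columns: dict[str, np.ndarray] = {}
    for stage in (20, 28, 36):
        columns[f"wt_dp_{stage}"] = dp[stage]
        columns[f"wt_gfp_{stage}"] = dp[stage] * gfp_mult
        columns[f"wt_dsred_{stage}"] = dp[stage] * dsred_mult
    for cond in ("edn1_ctrl", "jag1b_ctrl", "hs_ctrl", "vehicle_ctrl"):
        columns[f"{cond}_dp_36"] = dp[36].copy()
    for cond, mult in response.items():
        columns[f"{cond}_dp_36"] = dp[36] * mult

    values = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
    values = values.loc[:, design.sample_ids]  # column order = design order
    if params.noise_sd > 0:
        noise = rng.normal(0.0, params.noise_sd, size=values.shape)
        values = values * np.exp(noise)

    truth = pd.DataFrame(
        {
            "class": labels,
            "source": [
                _CONTAMINANT_SOURCE.get(c, "none") for c in labels
            ],
            "induced": induced,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return ExpressionMatrix(values), design, truth


# ---------------------------------------------------------------------------
# hand-built worked example sitting exactly on every threshold boundary

_WE_SAMPLES = (
    "wt_dp_20",
    "wt_dp_28",
    "wt_dp_36",
    "wt_gfp_36",
    "wt_dsred_36",
    "edn1_mut_dp_36",
    "edn1_ctrl_dp_36",
    "jag1b_mut_dp_36",
    "jag1b_ctrl_dp_36",
    "edn1_oe_dp_36",
    "nicd_oe_dp_36",
    "hs_ctrl_dp_36",
    "dbz_dp_36",
    "vehicle_ctrl_dp_36",
)

# name -> (base value v, overrides, planted class)
# defaults per gene: dp20 = v/2, dp28 = v, dp36 = v, gfp36 = dsred36 = v/4,
# every perturbation/control sample = v (fold-change 1)
_WE_GENES: tuple[tuple[str, float, dict[str, float], str], ...] = (
    ("boundary_rpkm", 3.0, {}, UNREGULATED),
    ("above_min", 3.01, {}, "arch_enriched"),
    ("boundary_enrich", 6.0, {"wt_gfp_36": 4.0, "wt_dsred_36": 1.0},
     "arch_enriched"),
    ("below_enrich", 6.0, {"wt_gfp_36": 4.1, "wt_dsred_36": 1.0}, UNREGULATED),
    ("zero_denominator", 4.0, {"wt_gfp_36": 0.0, "wt_dsred_36": 0.0},
     "arch_enriched"),
    ("boundary_act", 6.0,
     {"hs_ctrl_dp_36": 6.0, "nicd_oe_dp_36": 18.0,
      "jag1b_ctrl_dp_36": 6.0, "jag1b_mut_dp_36": 12.0,
      "vehicle_ctrl_dp_36": 6.0, "dbz_dp_36": 12.0},
     "notch_activated"),
    ("boundary_dbz_up", 6.0,
     {"hs_ctrl_dp_36": 6.0, "nicd_oe_dp_36": 15.0,
      "vehicle_ctrl_dp_36": 6.0, "dbz_dp_36": 12.0},
     "notch_activated"),
    ("removed_dbz_up", 6.0,
     {"hs_ctrl_dp_36": 6.0, "nicd_oe_dp_36": 18.0,
      "jag1b_ctrl_dp_36": 6.0, "jag1b_mut_dp_36": 12.0,
      "vehicle_ctrl_dp_36": 6.0, "dbz_dp_36": 15.0},
     "arch_enriched"),
    ("boundary_inh", 6.0,
     {"hs_ctrl_dp_36": 1.0, "nicd_oe_dp_36": 0.667, "edn1_oe_dp_36": 1.0},
     "notch_inhibited"),
    ("boundary_dbz", 6.0,
     {"hs_ctrl_dp_36": 5.0, "nicd_oe_dp_36": 2.0, "edn1_oe_dp_36": 5.0,
      "vehicle_ctrl_dp_36": 4.0, "dbz_dp_36": 2.0},
     "notch_inhibited"),
    ("removed_dbz_down", 6.0,
     {"hs_ctrl_dp_36": 4.0, "nicd_oe_dp_36": 2.0, "edn1_oe_dp_36": 4.0,
      "vehicle_ctrl_dp_36": 4.0, "dbz_dp_36": 2.0},
     "arch_enriched"),
    ("between_thresholds", 6.0,
     {"hs_ctrl_dp_36": 5.0, "nicd_oe_dp_36": 6.0, "edn1_oe_dp_36": 5.0},
     "arch_enriched"),
    ("guard_blocks_activation", 6.0,
     {"hs_ctrl_dp_36": 5.0, "nicd_oe_dp_36": 4.0, "edn1_oe_dp_36": 5.0,
      "jag1b_ctrl_dp_36": 5.0, "jag1b_mut_dp_36": 2.0},
     "arch_enriched"),
    ("edn1_activated_gene", 6.0,
     {"hs_ctrl_dp_36": 2.0, "edn1_oe_dp_36": 6.0, "nicd_oe_dp_36": 2.0},
     "edn1_activated"),
    ("edn1_inhibited_gene", 6.0,
     {"hs_ctrl_dp_36": 4.0, "edn1_oe_dp_36": 2.0, "nicd_oe_dp_36": 4.0,
      "edn1_ctrl_dp_36": 4.0, "edn1_mut_dp_36": 6.0},
     "edn1_inhibited"),
    ("co_pos_gene", 6.0,
     {"hs_ctrl_dp_36": 2.0, "nicd_oe_dp_36": 6.0, "edn1_oe_dp_36": 6.0,
      "vehicle_ctrl_dp_36": 3.0, "dbz_dp_36": 6.0},
     "co_regulated_positive"),
    ("co_neg_gene", 6.0,
     {"hs_ctrl_dp_36": 4.0, "nicd_oe_dp_36": 2.0, "edn1_oe_dp_36": 2.0},
     "co_regulated_negative"),
    ("erythroid_like", 8.0, {"wt_gfp_36": 32.0, "wt_dsred_36": 32.0},
     "contaminant_erythroid"),
    ("macrophage_like", 8.0, {"wt_gfp_36": 32.0, "wt_dsred_36": 2.0},
     "contaminant_macrophage"),
    ("ear_like", 8.0, {"wt_gfp_36": 2.0, "wt_dsred_36": 32.0},
     "contaminant_ear"),
    ("ubiquitous", 10.0, {"wt_gfp_36": 10.0, "wt_dsred_36": 10.0}, UNREGULATED),
)


def plant_worked_example() -> tuple[ExpressionMatrix, SampleDesign, pd.DataFrame]:
    """Fixed noise-free ≤21-gene dataset hitting every threshold boundary.

    Contains at least one gene of every planted class plus hand-chosen
    boundary genes: RPKM exactly 3 (excluded by the minimum-expression
    filter), enrichment ratio exactly 1.5 (retained), classifier ratios
    exactly 1.5 / 0.667 (retained on the activated / inhibited lists) and
    NICD-vs-DBZ fold-change ratios exactly 1.25 / 0.8 (retained by the DBZ
    refinement).
    """
    rows = []
    names = []
    classes = []
    for name, v, overrides, cls in _WE_GENES:
        cells = {
            "wt_dp_20": v / 2,
            "wt_dp_28": v,
            "wt_dp_36": v,
            "wt_gfp_36": v / 4,
            "wt_dsred_36": v / 4,
        }
        for s in _WE_SAMPLES[5:]:
            cells[s] = v
        cells.update(overrides)
        rows.append([cells[s] for s in _WE_SAMPLES])
        names.append(name)
        classes.append(cls)
    values = pd.DataFrame(
        rows, index=pd.Index(names, name="gene_id"), columns=list(_WE_SAMPLES)
    )
    design_rows = [
        ("wt_dp_20", "double_positive", 20, "wt"),
        ("wt_dp_28", "double_positive", 28, "wt"),
        ("wt_dp_36", "double_positive", 36, "wt"),
        ("wt_gfp_36", "gfp_only", 36, "wt"),
        ("wt_dsred_36", "dsred_only", 36, "wt"),
    ] + [
        (f"{cond}_dp_36", "double_positive", 36, cond)
        for cond in (
            "edn1_mut",
            "edn1_ctrl",
            "jag1b_mut",
            "jag1b_ctrl",
            "edn1_oe",
            "nicd_oe",
            "hs_ctrl",
            "dbz",
            "vehicle_ctrl",
        )
    ]
    design = SampleDesign(
        pd.DataFrame(
            design_rows,
            columns=["sample_id", "population", "stage_hpf", "condition"],
        )
    )
    truth = pd.DataFrame(
        {
            "class": classes,
            "source": [_CONTAMINANT_SOURCE.get(c, "none") for c in classes],
            "induced": [False] * len(classes),
        },
        index=pd.Index(names, name="gene_id"),
    )
    return ExpressionMatrix(values), design, truth
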