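"""Fold-change computation and pathway activated/inhibited classification.

For each perturbation contrast the fold-change of a gene is the RPKM ratio
perturbed/control (zeros replaced before division).  A gene is called

* *activated* by a pathway when its overexpression fold-change divided by
  its mutant fold-change is >= ``activation_ratio`` (default 1.5) and the
  overexpression fold-change itself is >= 1 (the gene really went up when
  the pathway was forced on);
* *inhibited* when that ratio is <= ``inhibition_ratio`` (default 0.667)
  and the mutant fold-change is >= 1 (the gene really went up when the
  pathway was removed).

For the Notch pathway the overexpression arm is NICD (nicd_oe) and the
loss arm the jag1b mutant; for Edn1 they are edn1_oe and the edn1 mutant.
The Notch lists are further refined against the orthogonal DBZ
(gamma-secretase inhibitor) loss-of-function contrast: activated genes must
also be elevated in NICD relative to DBZ (fold-change ratio >= 1.25) and
inhibited genes decreased (<= 0.8).  All comparisons are inclusive.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ConfigurationError, ContrastSpec, ExpressionMatrix

__all__ = [
    "PATHWAY_CONTRASTS",
    "ClassifierThresholds",
    "DbzRefinement",
    "GeneClassification",
    "compute_fold_changes",
    "classify_pathway",
    "refine_notch_with_dbz",
    "classify_all",
    "intersect_lists",
    "top_k_regulated",
]

#: (overexpression contrast, loss-of-function contrast) per pathway
PATHWAY_CONTRASTS: Mapping[str, tuple[str, str]] = {
    "notch": ("nicd_oe", "jag1b_mut"),
    "edn1": ("edn1_oe", "edn1_mut"),
}


@dataclasses.dataclass(frozen=True)
class ClassifierThresholds:
    activation_ratio: float = 1.5     # inclusive >=
    inhibition_ratio: float = 0.667   # inclusive <=
    oe_over_control_min: float = 1.0  # inclusive >=
    mut_over_control_min: float = 1.0  # inclusive >=
    dbz_up_min: float = 1.25          # inclusive >=
    dbz_down_max: float = 0.8         # inclusive <=
    zero_replacement: float = 0.01

    def __post_init__(self):
        if not (self.activation_ratio > 1 > self.inhibition_ratio > 0):
            raise ValueError(
                "require activation_ratio > 1 > inhibition_ratio > 0"
            )
        if not (self.dbz_up_min > 1 > self.dbz_down_max > 0):
            raise ValueError("require dbz_up_min > 1 > dbz_down_max > 0")
        if self.zero_replacement <= 0:
            raise ValueError("zero_replacement must be > 0")


@dataclasses.dataclass
class DbzRefinement:
    activated: set[str]
    inhibited: set[str]
    removed_activated: set[str]
    removed_inhibited: set[str]


@dataclasses.dataclass
class GeneClassification:
    """Per-pathway activated/inhibited gene sets over a common universe."""

    universe: set[str]
    notch_activated: set[str]
    notch_inhibited: set[str]
    edn1_activated: set[str]
    edn1_inhibited: set[str]
    dbz_refinement: DbzRefinement | None = None

    def sets(self) -> dict[str, set[str]]:
        return {
            "notch_activated": self.notch_activated,
            "notch_inhibited": self.notch_inhibited,
            "edn1_activated": self.edn1_activated,
            "edn1_inhibited": self.edn1_inhibited,
        }


def compute_fold_changes(
    matrix: ExpressionMatrix,
    contrasts: Sequence[ContrastSpec],
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> pd.DataFrame:
    """Gene x contrast fold-change table (zeros replaced before division)."""
    z = thresholds.zero_replacement
    cols = {}
    for spec in contrasts:
        num = matrix.column(spec.perturbed_sample)
        den = matrix.column(spec.control_sample)
        num = num.where(num > 0, z)
        den = den.where(den > 0, z)
        cols[spec.name] = num / den
    return pd.DataFrame(cols)


def _require_contrasts(fc: pd.DataFrame, names: Iterable[str]) -> None:
    missing = [n for n in names if n not in fc.columns]
    if missing:
        raise ConfigurationError(
            f"fold-change table lacks contrast(s) {missing}; have {list(fc.columns)}"
        )


def classify_pathway(
    fc: pd.DataFrame,
    pathway: Literal["notch", "edn1"],
    thresholds: ClassifierThresholds = ClassifierThresholds(),
    universe: Iterable[str] | None = None,
) -> tuple[set[str], set[str]]:
    """(activated, inhibited) gene sets for one pathway.

    The RPKM guard ratios (overexpression/control and mutant/control) are
    exactly the per-contrast fold-changes, so the classification reads off
    the fold-change table alone.
    """
    if pathway not in PATHWAY_CONTRASTS:
        raise ValueError(f"unknown pathway {pathway!r}")
    oe_name, mut_name = PATHWAY_CONTRASTS[pathway]
    _require_contrasts(fc, (oe_name, mut_name))
    sub = fc if universe is None else fc.loc[fc.index.intersection(list(universe))]
    ratio = sub[oe_name] / sub[mut_name]
    activated = (ratio >= thresholds.activation_ratio) & (
        sub[oe_name] >= thresholds.oe_over_control_min
    )
    inhibited = (ratio <= thresholds.inhibition_ratio) & (
        sub[mut_name] >= thresholds.mut_over_control_min
    )
    return set(sub.index[activated]), set(sub.index[inhibited])


def refine_notch_with_dbz(
    activated: set[str],
    inhibited: set[str],
    fc: pd.DataFrame,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
    mode: Literal["fc_ratio", "sample_ratio"] = "fc_ratio",
    matrix: ExpressionMatrix | None = None,
    nicd_sample: str | None = None,
    dbz_sample: str | None = None,
) -> DbzRefinement:
    """Contract the Notch lists using the orthogonal DBZ contrast.

    ``fc_ratio`` (default) compares the two control-normalized fold-changes,
    fc_nicd / fc_dbz, since the NICD and DBZ arms have different controls.
    ``sample_ratio`` instead uses the direct RPKM ratio NICD/DBZ and needs
    the expression matrix plus the two sample ids.
    """
    if mode == "fc_ratio":
        _require_contrasts(fc, ("nicd_oe", "dbz"))
        stat = fc["nicd_oe"] / fc["dbz"]
    elif mode == "sample_ratio":
        if matrix is None or nicd_sample is None or dbz_sample is None:
            raise ValueError(
                "sample_ratio mode needs matrix, nicd_sample and dbz_sample"
            )
        z = thresholds.zero_replacement
        num = matrix.column(nicd_sample)
        den = matrix.column(dbz_sample)
        stat = num.where(num > 0, z) / den.where(den > 0, z)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    up = set(stat.index[stat >= thresholds.dbz_up_min])
    down = set(stat.index[stat <= thresholds.dbz_down_max])
    act = set(activated) & up
    inh = set(inhibited) & down
    return DbzRefinement(
        activated=act,
        inhibited=inh,
        removed_activated=set(activated) - act,
        removed_inhibited=set(inhibited) - inh,
    )


def classify_all(
    fc: pd.DataFrame,
    universe: Iterable[str],
    thresholds: ClassifierThresholds = ClassifierThresholds(),
    refine_dbz: bool = True,
) -> GeneClassification:
    """Classify both pathways over a universe, with DBZ refinement of Notch."""
    universe = set(universe)
    n_act, n_inh = classify_pathway(fc, "notch", thresholds, universe)
    e_act, e_inh = classify_pathway(fc, "edn1", thresholds, universe)
    refinement = None
    if refine_dbz:
        refinement = refine_notch_with_dbz(n_act, n_inh, fc, thresholds)
        n_act, n_inh = refinement.activated, refinement.inhibited
    return GeneClassification(
        universe=universe,
        notch_activated=n_act,
        notch_inhibited=n_inh,
        edn1_activated=e_act,
        edn1_inhibited=e_inh,
        dbz_refinement=refinement,
    )


#: the four cross-pathway pairings reported in the Venn summary
VENN_PAIRS = (
    ("notch_inhibited", "edn1_activated"),
    ("notch_activated", "edn1_inhibited"),
    ("notch_activated", "edn1_activated"),
    ("notch_inhibited", "edn1_inhibited"),
)


def intersect_lists(classification: GeneClassification) -> dict[str, dict[str, int]]:
    """Venn summary of the cross-pathway list pairings."""
    sets = classification.sets()
    out: dict[str, dict[str, int]] = {}
    for a_name, b_name in VENN_PAIRS:
        a, b = sets[a_name], sets[b_name]
        out[f"{a_name}__{b_name}"] = {
            "A": len(a),
            "B": len(b),
            "A_and_B": len(a & b),
            "A_not_B": len(a - b),
            "B_not_A": len(b - a),
        }
    return out


def top_k_regulated(
    fc: pd.DataFrame,
    contrast: str,
    k: int,
    direction: Literal["up", "down"],
) -> list[str]:
    """Top-k genes by fold-change for one contrast, over the full gene set.

    Ties are broken lexicographically by gene id (plain string ordering) so
    the ranking is deterministic across runs and platforms.
    """
    if k <= 0:
        raise ValueError("k must be a positive integer")
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    _require_contrasts(fc, (contrast,))
    col = fc[contrast]
    order = sorted(
        col.index, key=lambda g: (-col[g] if direction == "up" else col[g], g)
    )
    return order[: min(k, len(order))]
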