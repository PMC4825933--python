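"""Configuration-driven orchestration: simulate → filter → classify → temporal.

A :class:`RunConfig` (YAML-loadable) points at an RPKM matrix + design table
— or asks for a simulated dataset — and carries every threshold.  The run
writes all stage outputs as TSV/JSON plus a manifest with per-stage gene
counts and SHA-256 checksums, so identical config + inputs give a
byte-identical output tree.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .classify import ClassifierThresholds, top_k_regulated
from .enrichment import EnrichmentThresholds
from .io import (
    CONTRAST_CONDITIONS,
    ConfigurationError,
    ExpressionMatrix,
    SampleDesign,
    read_expression_matrix,
    read_sample_design,
    write_expression_matrix,
    write_sample_design,
)
from .recovery import derive_gene_lists, predict_labels, score_recovery
from .simulate import SimulationParams, generate_dataset
from .stats import compare_lists, temporal_fold_changes
from .classify import intersect_lists

__all__ = ["RunConfig", "validate_config", "run_pipeline"]


@dataclasses.dataclass
class RunConfig:
    out_dir: str = "archncc_run"
    matrix_path: str | None = None
    design_path: str | None = None
    simulation: SimulationParams | None = None
    enrichment: EnrichmentThresholds = dataclasses.field(
        default_factory=EnrichmentThresholds
    )
    classifier: ClassifierThresholds = dataclasses.field(
        default_factory=ClassifierThresholds
    )
    stages: tuple[int, ...] = (20, 28, 36)
    contrasts: tuple[str, ...] = tuple(CONTRAST_CONDITIONS)
    single_positive_stage: int | None = None
    refine_dbz: bool = True
    alpha: float = 0.05
    induction_threshold: float = 10.0
    top_k: int = 20

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw: Mapping[str, Any] = yaml.safe_load(fh) or {}
        kwargs: dict[str, Any] = {}
        for key in (
            "out_dir",
            "matrix_path",
            "design_path",
            "single_positive_stage",
            "refine_dbz",
            "alpha",
            "induction_threshold",
            "top_k",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "stages" in raw:
            kwargs["stages"] = tuple(int(s) for s in raw["stages"])
        if "contrasts" in raw:
            kwargs["contrasts"] = tuple(raw["contrasts"])
        if "simulation" in raw and raw["simulation"] is not None:
            kwargs["simulation"] = SimulationParams(**raw["simulation"])
        if "enrichment" in raw:
            kwargs["enrichment"] = EnrichmentThresholds(**raw["enrichment"])
        if "classifier" in raw:
            kwargs["classifier"] = ClassifierThresholds(**raw["classifier"])
        return cls(**kwargs)

    def echo(self) -> dict[str, Any]:
        """JSON-serializable copy of the configuration for the manifest."""

        def conv(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {
                    f.name: conv(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)
                }
            if isinstance(obj, Mapping):
                return {k: conv(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return [conv(v) for v in obj]
            return obj

        return conv(self)


def validate_config(config: RunConfig) -> list[str]:
    """Findings (empty = valid).  Never raises for content problems."""
    findings: list[str] = []
    if config.simulation is None:
        if not config.matrix_path or not config.design_path:
            findings.append(
                "either simulation parameters or matrix_path + design_path required"
            )
        else:
            for label, p in (
                ("matrix_path", config.matrix_path),
                ("design_path", config.design_path),
            ):
                if not Path(p).is_file():
                    findings.append(f"{label}: file not found: {p}")
    for block, factory in (
        ("enrichment", config.enrichment),
        ("classifier", config.classifier),
    ):
        try:
            dataclasses.replace(factory)
        except ValueError as exc:
            findings.append(f"{block}: {exc}")
    if config.classifier.activation_ratio <= config.classifier.inhibition_ratio:
        findings.append("classifier: activation_ratio must exceed inhibition_ratio")
    unknown = set(config.contrasts) - set(CONTRAST_CONDITIONS)
    if unknown:
        findings.append(f"unknown contrast name(s): {sorted(unknown)}")
    if config.refine_dbz and "dbz" not in config.contrasts:
        findings.append("DBZ refinement enabled but 'dbz' contrast not requested")
    bad_stages = set(config.stages) - {20, 28, 36}
    if bad_stages:
        findings.append(f"unknown stage(s): {sorted(bad_stages)}")
    if not (0 < config.alpha < 1):
        findings.append("alpha must lie in (0, 1)")
    if config.top_k <= 0:
        findings.append("top_k must be positive")
    return findings


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(payload: Any, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _gene_list_frame(genes: set[str], fc: pd.DataFrame) -> pd.DataFrame:
    frame = fc.loc[sorted(genes)].copy()
    frame.insert(0, "gene_id", frame.index)
    return frame


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute all stages; returns the manifest (also written to disk)."""
    findings = validate_config(config)
    if findings:
        raise ConfigurationError("invalid configuration: " + "; ".join(findings))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    truth = None
    if config.simulation is not None:
        matrix, design, truth = generate_dataset(config.simulation)
        write_expression_matrix(matrix, out / "matrix.tsv")
        write_sample_design(design, out / "design.tsv")
        truth.to_csv(out / "truth.tsv", sep="\t")
    else:
        matrix = read_expression_matrix(config.matrix_path)
        design = read_sample_design(config.design_path)

    derived = derive_gene_lists(
        matrix,
        design,
        config.enrichment,
        config.classifier,
        stages=config.stages,
        single_positive_stage=config.single_positive_stage,
        refine_dbz=config.refine_dbz,
    )
    for stage, genes in derived.arch_sets.items():
        pd.Series(sorted(genes), name="gene_id").to_csv(
            out / f"arch_genes_{stage}hpf.tsv", sep="\t", index=False
        )
    fc_out = derived.fold_changes.copy()
    fc_out.insert(0, "gene_id", fc_out.index)
    fc_out.to_csv(out / "fold_changes.tsv", sep="\t", index=False)

    cls = derived.classification
    for name, genes in cls.sets().items():
        _gene_list_frame(genes, derived.fold_changes).to_csv(
            out / f"{name}.tsv", sep="\t", index=False
        )
    venn = intersect_lists(cls)
    _write_json(venn, out / "venn.json")
    if cls.dbz_refinement is not None:
        removed = sorted(cls.dbz_refinement.removed_activated) + sorted(
            cls.dbz_refinement.removed_inhibited
        )
        pd.DataFrame(
            {
                "gene_id": removed,
                "removed_from": ["notch_activated"]
                * len(cls.dbz_refinement.removed_activated)
                + ["notch_inhibited"] * len(cls.dbz_refinement.removed_inhibited),
            }
        ).to_csv(out / "removed_by_dbz.tsv", sep="\t", index=False)

    for contrast in config.contrasts:
        for direction in ("up", "down"):
            top = top_k_regulated(
                derived.fold_changes, contrast, config.top_k, direction
            )
            pd.DataFrame(
                {
                    "gene_id": top,
                    "fold_change": derived.fold_changes.loc[top, contrast].to_numpy(),
                }
            ).to_csv(
                out / f"top{config.top_k}_{contrast}_{direction}.tsv",
                sep="\t",
                index=False,
            )

    universe = derived.arch_sets[36]
    temporal = temporal_fold_changes(
        matrix, design, universe, config.classifier.zero_replacement
    )
    temporal_out = temporal.copy()
    temporal_out.insert(0, "gene_id", temporal_out.index)
    temporal_out.to_csv(out / "temporal_fold_changes.tsv", sep="\t", index=False)
    lists = {"total": universe, **cls.sets()}
    reports = {}
    for interval in ("20_28", "28_36"):
        report = compare_lists(
            temporal,
            lists,
            interval,
            alpha=config.alpha,
            threshold=config.induction_threshold,
        )
        reports[interval] = {
            "kruskal_h": report.kruskal_h,
            "kruskal_wallis_p": report.kruskal_wallis_p,
            "n_pairwise": report.n_pairwise,
            "total": dataclasses.asdict(report.total),
            "lists": {
                name: {
                    "summary": dataclasses.asdict(comp.summary)
                    if comp.summary
                    else None,
                    "u_statistic": comp.u_statistic,
                    "p_raw": comp.p_raw,
                    "p_adjusted": comp.p_adjusted,
                    "significant": comp.significant,
                }
                for name, comp in report.lists.items()
            },
        }
    _write_json(reports, out / "temporal_report.json")

    recovery_summary = None
    if truth is not None:
        predicted = predict_labels(
            matrix,
            design,
            config.enrichment,
            config.classifier,
            single_positive_stage=config.single_positive_stage,
            derived=derived,
        )
        scores = score_recovery(truth["class"], predicted)
        scores.to_csv(out / "recovery.tsv", sep="\t")
        recovery_summary = {
            "macro_f1": float(scores["f1"].mean()),
            "per_class_f1": {c: float(v) for c, v in scores["f1"].items()},
        }

    counts = {
        "genes": len(matrix.gene_ids),
        "samples": len(matrix.sample_ids),
        "expressed_min_filter": len(derived.expressed),
        "arch_enriched": {
            str(stage): len(genes) for stage, genes in derived.arch_sets.items()
        },
        "lists": {name: len(genes) for name, genes in cls.sets().items()},
    }
    outputs = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "version": __version__,
        "config": config.echo(),
        "counts": counts,
        "venn": venn,
        "recovery": recovery_summary,
        "checksums": {name: _sha256(out / name) for name in outputs},
    }
    _write_json(manifest, out / "manifest.json")
    return manifest
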