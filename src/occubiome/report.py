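"""Cohort summaries and the end-to-end pipeline runner.

``cohort_summary`` reproduces the usual participants table: per-group
counts with percentages for categorical attributes and mean (sd) for
numeric ones.  ``run_pipeline`` chains prevalence filtering, relative
abundance, alpha/beta diversity, ANOSIM, per-feature tests, the LDA
effect-size screen and the RFE classifier over one study, writing every
stage's table plus a machine-readable JSON report whose layout is
validated against a schema shipped with the package.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alpha import compare_alpha_across_groups, comparison_frame, shannon_per_sample
from .beta import anosim, pairwise_distances, pcoa
from .classifier import BmParams, fit_occupation_model, save_model
from .diffabund import (
    feature_test_frame,
    lefse_frame,
    lefse_two_class,
    per_feature_tests,
)
from .tables import (
    FeatureTable,
    TableError,
    drop_undetermined,
    load_feature_table,
    prevalence_filter,
    relative_abundance,
)

log = logging.getLogger(__name__)


def cohort_summary(
    metadata: pd.DataFrame, attributes: list[str], group_by: str = "occupation"
) -> pd.DataFrame:
    """Tidy per-group summary of cohort attributes.

    Categorical attributes yield one row per (attribute, level, group)
    with ``n`` and ``percent`` (100 * n / group size); numeric
    attributes yield ``mean`` and ``sd``.  Unknown attributes raise
    ``TableError``.
    """
    if metadata.empty:
        raise TableError("metadata is empty")
    unknown = [a for a in attributes if a not in metadata.columns]
    if unknown:
        raise TableError(f"unknown attributes: {unknown}")
    if group_by not in metadata.columns:
        raise TableError(f"unknown grouping column {group_by!r}")
    rows = []
    for group, sub in metadata.groupby(group_by, sort=True):
        size = len(sub)
        for attr in attributes:
            col = sub[attr]
            if pd.api.types.is_numeric_dtype(col):
                rows.append(
                    {
                        "attribute": attr,
                        "level": "",
                        "group": group,
                        "group_size": size,
                        "n": size,
                        "percent": 100.0,
                        "mean": float(col.mean()),
                        "sd": float(col.std(ddof=1)) if size > 1 else 0.0,
                    }
                )
            else:
                levels = sorted(metadata[attr].dropna().unique())
                counts = col.value_counts()
                for level in levels:
                    n = int(counts.get(level, 0))
                    rows.append(
                        {
                            "attribute": attr,
                            "level": level,
                            "group": group,
                            "group_size": size,
                            "n": n,
                            "percent": 100.0 * n / size,
                            "mean": np.nan,
                            "sd": np.nan,
                        }
                    )
    return pd.DataFrame(rows)


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; the seed is mandatory because
    ANOSIM, the LDA screen and the forests are stochastic."""

    table_path: str
    metadata_path: str
    out_dir: str
    seed: int
    feature_kind: str = "species"
    sample_type: str | None = None      # restrict to one sample type if set
    min_prevalence: int = 10
    gate_alpha: float = 0.05
    lda_threshold: float = 4.0
    n_permutations: int = 999
    n_forests: int = 100
    trees_per_forest: int = 50
    test_size: int = 12
    bm_prior: str = "SQ"
    run_classifier: bool = True

    def validate(self) -> None:
        if self.seed is None:
            raise TableError("config must set a seed")
        if not 0 < self.gate_alpha < 1:
            raise TableError("gate_alpha must be in (0, 1)")
        if self.min_prevalence < 0:
            raise TableError("min_prevalence must be >= 0")
        if self.n_permutations < 99:
            raise TableError("n_permutations must be >= 99")
        if self.n_forests < 1 or self.trees_per_forest < 1:
            raise TableError("forest counts must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


#: minimal structural schema for the pipeline report (shipped as
#: report_schema.json next to this module)
_SCHEMA_PATH = Path(__file__).with_name("report_schema.json")


def validate_report(report: dict) -> None:
    """Validate the report layout against the shipped JSON schema
    (required keys and primitive types only)."""
    schema = json.loads(_SCHEMA_PATH.read_text())
    _check_schema(report, schema, "report")


def _check_schema(obj, schema: dict, where: str) -> None:
    t = schema.get("type")
    types = {"object": dict, "array": list, "string": str, "number": (int, float),
             "integer": int, "boolean": bool}
    if t and not isinstance(obj, types[t]):
        raise TableError(f"{where}: expected {t}, got {type(obj).__name__}")
    if t == "object":
        for key in schema.get("required", []):
            if key not in obj:
                raise TableError(f"{where}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in obj:
                _check_schema(obj[key], sub, f"{where}.{key}")
    elif t == "array" and "items" in schema:
        for i, item in enumerate(obj):
            _check_schema(item, schema["items"], f"{where}[{i}]")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every analysis stage on one study and write the report bundle.

    Stage failures abort with the stage name and cause.  Reruns with the
    same config produce an identical report.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config": asdict(config),
        "stages": {},
    }

    stage = "load"
    try:
        table, metadata = load_feature_table(
            config.table_path, config.metadata_path, config.feature_kind
        )
        if config.sample_type is not None:
            keep = metadata.index[metadata["sample_type"] == config.sample_type]
            table = table.select_samples(list(keep))
            metadata = metadata.loc[keep]
        table = drop_undetermined(table)
        report["stages"][stage] = {
            "n_features": len(table.feature_ids),
            "n_samples": len(table.sample_ids),
        }

        stage = "filter"
        filtered = prevalence_filter(table, config.min_prevalence)
        filtered.to_tsv(out / "filtered_counts.tsv")
        report["stages"][stage] = {"n_features": len(filtered.feature_ids)}

        stage = "relative_abundance"
        comp = relative_abundance(table)
        comp.to_tsv(out / "relative_abundance.tsv")
        report["stages"][stage] = {"n_features": len(comp.feature_ids)}

        stage = "alpha_diversity"
        shannon = shannon_per_sample(comp)
        shannon.rename_axis("sample_id").to_csv(out / "shannon.tsv", sep="\t")
        alpha_results = compare_alpha_across_groups(comp, metadata, config.gate_alpha)
        comparison_frame(alpha_results).to_csv(out / "alpha_comparisons.tsv", sep="\t", index=False)
        report["stages"][stage] = {
            "n_comparisons": len(alpha_results),
            "significant": int(sum(r.adjusted_p < 0.05 for r in alpha_results)),
        }

        stage = "beta_diversity"
        dm = pairwise_distances(comp)
        pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(
            out / "hellinger.tsv", sep="\t"
        )
        ord_res = pcoa(dm, n_axes=min(3, len(dm.ids) - 1))
        ord_res.coordinates.rename_axis("sample_id").to_csv(out / "pcoa.tsv", sep="\t")
        occ = metadata.loc[list(dm.ids), "occupation"].to_numpy()
        ano = anosim(dm, occ, config.n_permutations, seed=config.seed)
        report["stages"][stage] = {
            "anosim_r": ano.r,
            "anosim_p": ano.p_value,
            "anosim_method": ano.method,
            "pcoa_proportions": ord_res.proportion_explained.tolist(),
        }

        stage = "differential_abundance"
        occ_all = metadata.loc[comp.sample_ids, "occupation"].to_numpy()
        tests = per_feature_tests(comp, occ_all, config.gate_alpha)
        feature_test_frame(tests).to_csv(out / "feature_tests.tsv", sep="\t")
        lefse = lefse_two_class(
            comp,
            occ_all,
            alpha=config.gate_alpha,
            lda_threshold=config.lda_threshold,
            seed=config.seed,
        )
        lefse_frame(lefse).to_csv(out / "lefse.tsv", sep="\t")
        report["stages"][stage] = {
            "n_tested": len(tests),
            "significant_after_bonferroni": int(sum(t.adjusted_p < 0.05 for t in tests)),
            "lefse_flagged": int(sum(f.passed for f in lefse)),
        }

        if config.run_classifier:
            stage = "classifier"
            model, trace, provenance = fit_occupation_model(
                table,
                metadata,
                min_prevalence=config.min_prevalence,
                bm=BmParams(config.bm_prior),
                n_forests=config.n_forests,
                trees_per_forest=config.trees_per_forest,
                test_size=config.test_size,
                seed=config.seed,
            )
            trace.frame().to_csv(out / "rfe_trace.tsv", sep="\t", index=False)
            save_model(model, out / "model")
            report["stages"][stage] = {
                "n_features_selected": len(model.features),
                "selected_features": list(model.features),
                "train_accuracy": model.train_accuracy,
                "test_accuracy": model.test_accuracy,
            }
    except Exception as exc:
        raise TableError(f"pipeline stage {stage!r} failed: {exc}") from exc

    validate_report(report)
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    log.info("pipeline finished: %s", out / "report.json")
    return report
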