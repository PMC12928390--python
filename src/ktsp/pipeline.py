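"""End-to-end study orchestration: train on cohort A, test on cohort B.

The pipeline mirrors the temporal-split study design: per drug, label
samples from drug response (AUC threshold or pooled sDSS percentile),
keep drugs with enough samples per class in both cohorts, fit one kTSP
model and optional comparator learners on the training cohort only, and
evaluate everything on the held-out cohort.  Training is completed — k,
hyperparameters and standardization constants frozen — before any test
expression is touched.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as kio
from .benchmark import ComparatorSpec, TrainedComparator, majority_class_predictor, tune_and_train
from .core import KTSPResults, fit_ktsp
from .dose_response import label_by_auc
from .evaluation import (
    auroc,
    confusion_metrics,
    drug_inclusion_filter,
    gene_recurrence,
    rule_compliance_profile,
)
from .simulate import SyntheticConfig, SyntheticCohort, generate_train_test_cohorts

__all__ = ["RunConfig", "DrugDataset", "PipelineError", "run_train_test", "plot_cohort_pca"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a run cannot produce any evaluable drug."""


@dataclass
class RunConfig:
    """Configuration of one train/test study run."""

    synthetic: SyntheticConfig | None = None
    n_drugs: int = 1
    train_expression: str | None = None
    test_expression: str | None = None
    train_response: str | None = None
    test_response: str | None = None
    thresholds: tuple[int, int, int, int] = (20, 20, 10, 10)
    k_range: tuple[int, int] = (1, 15)
    comparators: tuple[str, ...] = ()
    comparator_draws: int = 20
    balanced: str = "both"  # both | on | off
    sdss_percentile: float = 95.0
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.balanced not in ("both", "on", "off"):
            raise ValueError(f"balanced must be both/on/off, got {self.balanced!r}")
        if any(t <= 0 for t in self.thresholds):
            raise ValueError("inclusion thresholds must be positive")
        if not (1 <= self.k_range[0] <= self.k_range[1] <= 15):
            raise ValueError("k_range must lie within [1, 15]")
        if self.synthetic is None and not (
            self.train_expression and self.test_expression
            and self.train_response and self.test_response
        ):
            raise ValueError("provide either a synthetic config or all four input paths")

    def config_hash(self) -> str:
        payload = asdict(self)
        if self.synthetic is not None:
            payload["synthetic"] = asdict(self.synthetic)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class DrugDataset:
    """Per-drug training and test data, expression as genes × samples."""

    drug: str
    train_expr: pd.DataFrame
    train_labels: pd.Series
    test_expr: pd.DataFrame
    test_labels: pd.Series


def _labels_from_response(response: pd.DataFrame) -> pd.DataFrame:
    """sample_id/drug_id/label table from a long response table with AUC."""
    if "label" in response.columns:
        out = response[["sample_id", "drug_id", "label"]].copy()
    else:
        out = response[["sample_id", "drug_id"]].copy()
        out["label"] = [label_by_auc(a) for a in response["auc"]]
    return out


def _datasets_from_files(config: RunConfig) -> tuple[list[DrugDataset], dict]:
    train_m = kio.read_expression_matrix(config.train_expression, "log2tpm")
    test_m = kio.read_expression_matrix(config.test_expression, "log2tpm")
    shared = [g for g in train_m.gene_ids if g in set(test_m.gene_ids)]
    if not shared:
        raise PipelineError("train and test cohorts share no genes")
    frac = 1 - len(shared) / max(len(train_m.gene_ids), len(test_m.gene_ids))
    logger.info("gene intersection: %d genes (%.1f%% dropped)", len(shared), 100 * frac)
    train_df = train_m.values.loc[shared]
    test_df = test_m.values.loc[shared]
    train_resp = _labels_from_response(pd.read_csv(config.train_response))
    test_resp = _labels_from_response(pd.read_csv(config.test_response))
    datasets = []
    for drug in sorted(set(train_resp["drug_id"]) & set(test_resp["drug_id"])):
        tr = train_resp[train_resp["drug_id"] == drug].set_index("sample_id")["label"]
        te = test_resp[test_resp["drug_id"] == drug].set_index("sample_id")["label"]
        tr = tr[tr.index.isin(train_df.columns)]
        te = te[te.index.isin(test_df.columns)]
        if tr.empty or te.empty:
            continue
        datasets.append(DrugDataset(str(drug), train_df[tr.index], tr,
                                    test_df[te.index], te))
    meta = {"n_shared_genes": len(shared), "dropped_gene_fraction": frac}
    return datasets, meta


def _datasets_synthetic(config: RunConfig) -> tuple[list[DrugDataset], dict]:
    datasets = []
    base = config.synthetic
    for d in range(config.n_drugs):
        cfg = SyntheticConfig(**{**asdict(base), "seed": base.seed + 7919 * d})
        train, test = generate_train_test_cohorts(cfg)
        datasets.append(
            DrugDataset(f"DRUG{d + 1:02d}", train.expression.values, train.labels,
                        test.expression.values, test.labels)
        )
    return datasets, {"n_shared_genes": base.n_genes, "dropped_gene_fraction": 0.0}


def _class_counts(labels: pd.Series) -> tuple[int, int]:
    sens = int((labels == "sensitive").sum())
    return sens, len(labels) - sens


def _evaluate(truth: pd.Series, predicted, scores) -> dict:
    report = confusion_metrics(truth, predicted)
    d = report.as_dict()
    try:
        d["auroc"] = auroc(truth, scores)
    except ValueError:
        d["auroc"] = float("nan")
    return d


def run_train_test(config: RunConfig) -> dict:
    """Execute the full study; returns the run report (and writes artifacts).

    Report structure: ``{"drugs": {drug: {model_name: metrics...}},
    "included": [...], "excluded": [...], "config_hash": ..., "seed": ...}``.
    """
    if config.synthetic is not None:
        datasets, meta = _datasets_synthetic(config)
    else:
        datasets, meta = _datasets_from_files(config)

    counts = {
        ds.drug: (*_class_counts(ds.train_labels), *_class_counts(ds.test_labels))
        for ds in datasets
    }
    included = set(drug_inclusion_filter(counts, config.thresholds))
    excluded = sorted(set(counts) - included)
    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "included": sorted(included),
        "excluded": excluded,
        "counts": {d: list(c) for d, c in counts.items()},
        "meta": meta,
        "drugs": {},
    }
    if not included:
        report["error"] = "no drugs pass the inclusion filter"
        _write_artifacts(config, report, {}, [])
        raise PipelineError("no drugs pass the inclusion filter")

    balance_variants = {"both": (False, True), "on": (True,), "off": (False,)}[config.balanced]
    ktsp_models: dict[str, KTSPResults] = {}
    metric_rows: list[dict] = []

    for ds in datasets:
        if ds.drug not in included:
            continue
        logger.info("drug %s: fitting kTSP (train n=%d)", ds.drug, ds.train_expr.shape[1])
        drug_report: dict = {}

        # --- training stage: everything fitted from the training cohort only
        model = fit_ktsp(ds.train_expr, ds.train_labels, k_range=config.k_range)
        ktsp_models[ds.drug] = model
        comparators: list[tuple[str, bool, TrainedComparator]] = []
        X_train = ds.train_expr.to_numpy(dtype=float).T
        for kind in config.comparators:
            for balanced in balance_variants:
                spec = ComparatorSpec(
                    kind=kind, n_random_draws=config.comparator_draws,
                    seed=config.seed, balance="smote" if balanced else "none",
                )
                comparators.append(
                    (kind, balanced, tune_and_train(spec, X_train, ds.train_labels))
                )
        baseline = majority_class_predictor(ds.train_labels)

        # --- evaluation stage: test data enters only now
        drug_report["ktsp"] = {
            "k": model.k,
            **_evaluate(ds.test_labels, model.predict(ds.test_expr),
                        model.decision_scores(ds.test_expr)),
        }
        X_test = ds.test_expr.to_numpy(dtype=float).T
        for kind, balanced, trained in comparators:
            name = f"{kind}_{'balanced' if balanced else 'not_balanced'}"
            drug_report[name] = _evaluate(
                ds.test_labels, trained.predict(X_test), trained.decision_scores(X_test)
            )
        drug_report["majority_baseline"] = _evaluate(
            ds.test_labels, baseline.predict(X_test), baseline.decision_scores(X_test)
        )
        report["drugs"][ds.drug] = drug_report

        for model_name, metrics in drug_report.items():
            if not isinstance(metrics, dict):
                continue
            for metric in ("sensitivity", "specificity", "balanced_accuracy", "auroc"):
                if metric in metrics:
                    metric_rows.append(
                        {"drug": ds.drug, "model": model_name, "metric": metric,
                         "value": metrics[metric]}
                    )

    _write_artifacts(config, report, ktsp_models, metric_rows, datasets)
    return report


def _write_artifacts(config: RunConfig, report: dict,
                     models: Mapping[str, KTSPResults],
                     metric_rows: Sequence[dict],
                     datasets: Sequence[DrugDataset] = ()) -> None:
    if config.out_dir is None:
        return
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    if metric_rows:
        pd.DataFrame(metric_rows).to_csv(out / "metrics.csv", index=False)
    if models:
        kio.write_rules_table(kio.rules_table_from_models(models), out / "rules.csv")
        recurrence, frac_unique = gene_recurrence(models)
        recurrence.to_csv(out / "gene_recurrence.csv")
        (out / "gene_recurrence.json").write_text(
            json.dumps({"fraction_unique": frac_unique})
        )
        by_drug = {ds.drug: ds for ds in datasets}
        compliance_rows = []
        for drug, model in models.items():
            ds = by_drug.get(drug)
            if ds is None:
                continue
            combined = pd.concat([ds.train_expr, ds.test_expr], axis=1)
            groups = {s: "train" for s in ds.train_expr.columns}
            groups.update({s: "test" for s in ds.test_expr.columns})
            profile = rule_compliance_profile(model, combined, groups,
                                              seed=config.seed)
            for sample, vs in profile.vote_sums.items():
                compliance_rows.append(
                    {"drug": drug, "sample_id": sample,
                     "group": profile.groups[sample], "vote_sum": int(vs)}
                )
        if compliance_rows:
            pd.DataFrame(compliance_rows).to_csv(out / "compliance.csv", index=False)


def plot_cohort_pca(matrices: Mapping[str, pd.DataFrame], out_path: str | None = None):
    """Convenience ordination: first two PCs of pooled samples, colored by cohort."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.decomposition import PCA

    shared = None
    for df in matrices.values():
        shared = df.index if shared is None else shared.intersection(df.index)
    pooled = pd.concat([df.loc[shared] for df in matrices.values()], axis=1)
    tags = np.concatenate([[name] * df.shape[1] for name, df in matrices.items()])
    coords = PCA(n_components=2).fit_transform(pooled.to_numpy(dtype=float).T)
    fig, ax = plt.subplots(figsize=(6, 5))
    for name in matrices:
        mask = tags == name
        ax.scatter(coords[mask, 0], coords[mask, 1], label=name, alpha=0.7, s=18)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend()
    fig.tight_layout()
    if out_path:
        fig.savefig(out_path, dpi=120)
    return fig
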