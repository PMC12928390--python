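"""Evaluation metrics and secondary analyses.

Covers the metrics used to judge drug-response classifiers under class
imbalance (sensitivity, specificity, balanced accuracy, AUROC), the
sample-count filter deciding which drugs are evaluable, the one-sided
Wilcoxon + Benjamini–Hochberg group test of sDSS against predicted
labels, rule-compliance (vote-sum) profiles across sample subgroups, and
gene recurrence across per-drug classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import KTSPResults, _as_frame, _sensitive_mask

__all__ = [
    "EvaluationReport",
    "ComplianceProfile",
    "confusion_metrics",
    "auroc",
    "drug_inclusion_filter",
    "sdss_group_test",
    "rule_compliance_profile",
    "gene_recurrence",
]

SENSITIVE = "sensitive"


@dataclass
class EvaluationReport:
    """Confusion-matrix metrics with 'sensitive' as the positive class.

    Undefined quantities (an absent class in the truth vector) are NaN,
    never silently 0.  balanced_accuracy is exactly
    (sensitivity + specificity) / 2.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    auroc: float | None = None

    def __post_init__(self) -> None:
        if np.isfinite(self.sensitivity) and np.isfinite(self.specificity):
            assert self.balanced_accuracy == (self.sensitivity + self.specificity) / 2.0

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "balanced_accuracy": self.balanced_accuracy,
            "auroc": self.auroc,
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
        }


def confusion_metrics(truth: Sequence, predicted: Sequence) -> EvaluationReport:
    """Sensitivity, specificity and balanced accuracy of binary calls."""
    t = _sensitive_mask(truth)
    p = _sensitive_mask(predicted)
    if t.shape != p.shape:
        raise ValueError("truth and predicted must have equal length")
    tp = int(np.sum(t & p))
    fn = int(np.sum(t & ~p))
    tn = int(np.sum(~t & ~p))
    fp = int(np.sum(~t & p))
    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    specificity = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    return EvaluationReport(tp, fp, tn, fn, sensitivity, specificity,
                            (sensitivity + specificity) / 2.0)


def auroc(truth: Sequence, scores: Sequence[float]) -> float:
    """Mann–Whitney AUROC: P(score_sens > score_res) + ½·P(equal).

    Computed from midranks, which is algebraically identical to averaging
    the indicator (with ties counting 1/2) over all cross-class pairs.
    """
    t = _sensitive_mask(truth)
    s = np.asarray(scores, dtype=float)
    if t.shape != s.shape:
        raise ValueError("truth and scores must have equal length")
    n_pos, n_neg = int(t.sum()), int((~t).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: both classes must be present")
    ranks = stats.rankdata(s)
    u = ranks[t].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def drug_inclusion_filter(
    counts: Mapping[str, tuple[int, int, int, int]],
    thresholds: tuple[int, int, int, int] = (20, 20, 10, 10),
) -> list[str]:
    """Drugs with enough samples per class in both cohorts.

    ``counts`` maps drug → (train_sensitive, train_resistant,
    test_sensitive, test_resistant); a drug is included iff every count
    meets its threshold (default 20/20 train, 10/10 test).
    """
    included = []
    for drug, c in counts.items():
        if len(c) != 4 or any(v < 0 for v in c):
            raise ValueError(f"drug {drug!r}: need 4 non-negative counts, got {c}")
        if all(v >= t for v, t in zip(c, thresholds)):
            included.append(drug)
    return included


def sdss_group_test(per_drug: Mapping[str, tuple[Sequence[float], Sequence]],
                    alpha: float = 0.05) -> pd.DataFrame:
    """One-sided Wilcoxon rank-sum of sDSS by predicted label, BH-corrected.

    ``per_drug`` maps drug → (sdss values, predicted labels).  Per drug the
    alternative is: predicted-sensitive sDSS stochastically greater than
    predicted-resistant sDSS (exact null when both groups are small and
    tie-free, normal approximation with tie/continuity correction
    otherwise).  Drugs with an empty predicted group are reported with
    ``tested = False`` and NaN p-values, not p = 1.
    """
    rows = []
    for drug, (values, labels) in per_drug.items():
        v = np.asarray(values, dtype=float)
        m = _sensitive_mask(labels)
        if v.shape != m.shape:
            raise ValueError(f"drug {drug!r}: values and labels differ in length")
        if m.sum() == 0 or (~m).sum() == 0:
            rows.append({"drug": drug, "tested": False, "p_value": np.nan})
            continue
        res = stats.mannwhitneyu(v[m], v[~m], alternative="greater", method="auto")
        rows.append({"drug": drug, "tested": True, "p_value": float(res.pvalue)})
    df = pd.DataFrame(rows)
    tested = df["tested"].to_numpy()
    if tested.sum() < 1:
        raise ValueError("no drug has both predicted groups non-empty; nothing to test")
    adjusted = np.full(len(df), np.nan)
    reject = np.zeros(len(df), dtype=bool)
    rej, p_adj, _, _ = multipletests(df.loc[tested, "p_value"], alpha=alpha,
                                     method="fdr_bh")
    adjusted[tested] = p_adj
    reject[tested] = rej
    df["p_adjusted"] = adjusted
    df["significant"] = reject
    return df.set_index("drug")


@dataclass
class ComplianceProfile:
    """Per-sample vote sums with subgroup tags and per-group summaries."""

    vote_sums: pd.Series  # index sample_id, values in [-k, k]
    groups: pd.Series  # index sample_id, subgroup tag
    summary: pd.DataFrame  # per-tag mean/sd/n
    mean_difference: float | None  # group A mean - group B mean (2 groups)
    ci_low: float | None
    ci_high: float | None


def rule_compliance_profile(model: KTSPResults, m, groups: Mapping[str, str],
                            n_boot: int = 1000, seed: int = 0) -> ComplianceProfile:
    """Vote-sum consistency of a rule set across sample subgroups.

    Every sample's vote sum (in [−k, k]) is tagged with its subgroup; per
    group the mean and sd are reported.  With exactly two groups the
    difference of group means gets a seeded bootstrap percentile CI
    (``n_boot`` resamples) quantifying whether rule compliance differs
    between the groups.
    """
    df = _as_frame(m)
    unknown = sorted(set(df.columns) - set(groups))
    if unknown:
        raise ValueError(f"samples without a group tag: {unknown}")
    vs = model.vote_sums(df)
    tags = pd.Series({s: groups[s] for s in df.columns})
    summary = (
        pd.DataFrame({"vote_sum": vs, "group": tags})
        .groupby("group")["vote_sum"]
        .agg(["mean", "std", "count"])
    )
    mean_diff = ci_low = ci_high = None
    tag_names = sorted(summary.index)
    if len(tag_names) == 2:
        rng = np.random.default_rng(seed)
        a = vs[tags == tag_names[0]].to_numpy(dtype=float)
        b = vs[tags == tag_names[1]].to_numpy(dtype=float)
        mean_diff = float(a.mean() - b.mean())
        boots = np.empty(n_boot)
        for i in range(n_boot):
            boots[i] = (
                rng.choice(a, size=a.size, replace=True).mean()
                - rng.choice(b, size=b.size, replace=True).mean()
            )
        ci_low, ci_high = (float(q) for q in np.percentile(boots, [2.5, 97.5]))
    return ComplianceProfile(vs, tags, summary, mean_diff, ci_low, ci_high)


def gene_recurrence(models: Mapping[str, KTSPResults]) -> tuple[pd.DataFrame, float]:
    """How often each gene recurs across per-drug classifiers.

    Returns a table (gene, n_classifiers, orientation per drug) and the
    fraction of distinct genes appearing in exactly one classifier.  The
    orientation records whether the gene sits on the over-expressed
    ('up_in_sensitive', gene_a side) or under-expressed side of its rule.
    """
    if not models:
        raise ValueError("need at least one fitted model")
    rows: dict[str, dict] = {}
    for drug, model in models.items():
        for rule in model.rules:
            for gene, orient in ((rule.gene_a, "up_in_sensitive"),
                                 (rule.gene_b, "down_in_sensitive")):
                entry = rows.setdefault(gene, {"n_classifiers": 0, "orientation": {}})
                entry["n_classifiers"] += 1
                entry["orientation"][drug] = orient
    table = pd.DataFrame(
        {
            "gene": list(rows),
            "n_classifiers": [r["n_classifiers"] for r in rows.values()],
            "orientation": [
                ";".join(f"{d}:{o}" for d, o in sorted(r["orientation"].items()))
                for r in rows.values()
            ],
        }
    ).sort_values(["n_classifiers", "gene"], ascending=[False, True]).set_index("gene")
    fraction_unique = float((table["n_classifiers"] == 1).mean())
    return table, fraction_unique
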