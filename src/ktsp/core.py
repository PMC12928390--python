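"""k-Top Scoring Pairs (kTSP) classification.

A TSP rule is an ordered gene pair (geneA, geneB): within a sample,
observing geneA > geneB casts a +1 vote for the *sensitive* class and a
−1 vote otherwise.  A kTSP classifier is an ordered, gene-disjoint list
of k such rules (k ≤ 15 here) and predicts by unweighted majority vote.
Because rules compare expression values *within* one sample, predictions
are invariant to any strictly monotone per-sample transformation — the
property that makes the classifier robust to batch effects and usable on
single samples without normalization against a reference cohort.

Pair scoring follows the classic TSP construction: the primary score
Δ = |P̂(A>B | sensitive) − P̂(A>B | resistant)| (ties A = B count 1/2),
with a secondary rank-difference score γ as tie-break.  k is chosen on
the training data by a variance-standardized separation of the vote sums
(a Welch-type analysis-of-variance criterion), favouring the smallest k
on ties.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import ExpressionMatrix, RULE_DIRECTION, read_rules_table, write_rules_table

__all__ = [
    "TSPRule",
    "KTSP",
    "KTSPResults",
    "pair_score",
    "rank_disjoint_pairs",
    "select_k",
    "fit_ktsp",
    "vote_sum",
    "predict",
    "decision_score",
    "check_rank_invariance",
]

logger = logging.getLogger(__name__)

SENSITIVE = "sensitive"
RESISTANT = "resistant"
DEFAULT_K_MAX = 15
DEFAULT_GENE_CAP = 5000


@dataclass(frozen=True)
class TSPRule:
    """Oriented gene pair: gene_a > gene_b votes 'sensitive'."""

    gene_a: str
    gene_b: str
    delta: float
    gamma: float

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"rule genes must differ, got {self.gene_a!r} twice")
        if not 0.0 <= self.delta <= 1.0 + 1e-12:
            raise ValueError(f"delta must be in [0,1], got {self.delta}")


def _sensitive_mask(labels: Sequence) -> np.ndarray:
    """Boolean mask (True = sensitive) from str or bool labels."""
    arr = np.asarray(labels)
    if arr.dtype == bool:
        return arr
    mask = np.zeros(arr.shape, dtype=bool)
    for i, v in enumerate(arr):
        if v == SENSITIVE or v is True:
            mask[i] = True
        elif v == RESISTANT or v is False:
            mask[i] = False
        else:
            raise ValueError(f"unknown label {v!r}; expected sensitive/resistant")
    return mask


def _as_frame(m) -> pd.DataFrame:
    if isinstance(m, ExpressionMatrix):
        return m.values
    if isinstance(m, pd.DataFrame):
        return m
    raise TypeError("expected ExpressionMatrix or genes×samples DataFrame")


def pair_score(a_values, b_values, labels,
               rank_a=None, rank_b=None) -> tuple[float, float]:
    """Primary and secondary TSP scores for one gene pair.

    delta = |P̂(a > b | sensitive) − P̂(a > b | resistant)| with ties a = b
    contributing 1/2 to each empirical fraction.  gamma compares the mean
    within-sample rank difference rank_a − rank_b between classes; when
    full-profile ranks are not supplied the ranks within the pair itself
    are used.
    """
    a = np.asarray(a_values, dtype=float)
    b = np.asarray(b_values, dtype=float)
    sens = _sensitive_mask(labels)
    if a.shape != b.shape or a.shape != sens.shape:
        raise ValueError("a_values, b_values and labels must have equal length")
    n_s, n_r = int(sens.sum()), int((~sens).sum())
    if n_s == 0 or n_r == 0:
        raise ValueError("both classes must be non-empty")
    gt = (a > b).astype(float) + 0.5 * (a == b)
    delta = abs(gt[sens].mean() - gt[~sens].mean())
    if rank_a is None or rank_b is None:
        # ranks within the two-gene profile: {1, 2}, ties 1.5
        pair = np.vstack([a, b])
        ranks = np.apply_along_axis(rankdata, 0, pair)
        rank_a, rank_b = ranks[0], ranks[1]
    rd = np.asarray(rank_a, dtype=float) - np.asarray(rank_b, dtype=float)
    gamma = abs(rd[sens].mean() - rd[~sens].mean())
    return float(delta), float(gamma)


def _class_order_prob(X: np.ndarray, chunk: int = 16) -> np.ndarray:
    """P[i, j] = empirical P(gene_i > gene_j) over samples, ties 1/2."""
    G, n = X.shape
    P = np.zeros((G, G))
    for start in range(0, n, chunk):
        xs = X[:, start:start + chunk]
        gt = xs[:, None, :] > xs[None, :, :]
        eq = xs[:, None, :] == xs[None, :, :]
        P += gt.sum(axis=2) + 0.5 * eq.sum(axis=2)
    return P / n


def rank_disjoint_pairs(m, labels, max_pairs: int = DEFAULT_K_MAX,
                        gene_cap: int | None = DEFAULT_GENE_CAP) -> list[TSPRule]:
    """Score all gene pairs and greedily accept gene-disjoint top scorers.

    Pairs are oriented so P̂(a>b | sensitive) ≥ P̂(a>b | resistant) and
    accepted in (delta desc, gamma desc, lexicographic) order, skipping
    any pair that shares a gene with an already-accepted pair, until
    ``max_pairs`` rules are collected or candidates are exhausted.
    Deterministic for fixed input.
    """
    df = _as_frame(m)
    sens = _sensitive_mask(labels)
    if df.shape[1] != sens.shape[0]:
        raise ValueError("label length must match the number of samples")
    if df.shape[0] < 2:
        raise ValueError("need at least 2 genes to form a pair")
    if sens.sum() == 0 or (~sens).sum() == 0:
        raise ValueError("both classes must be non-empty")

    if gene_cap is not None and df.shape[0] > gene_cap:
        logger.warning(
            "gene count %d exceeds cap %d: keeping the %d most variable genes",
            df.shape[0], gene_cap, gene_cap,
        )
        variances = df.var(axis=1)
        keep = variances.sort_values(ascending=False, kind="stable").index[:gene_cap]
        df = df.loc[df.index.isin(set(keep))]

    genes = np.asarray(df.index, dtype=object)
    X = df.to_numpy(dtype=float)

    ps = _class_order_prob(X[:, sens])
    pr = _class_order_prob(X[:, ~sens])

    # gamma from within-sample full-profile ranks, per-gene class mean difference
    ranks = rankdata(X, axis=0)
    mdiff = ranks[:, sens].mean(axis=1) - ranks[:, ~sens].mean(axis=1)

    iu, ju = np.triu_indices(len(genes), k=1)
    d_fwd = ps[iu, ju] - pr[iu, ju]
    delta = np.abs(d_fwd)
    gamma = np.abs(mdiff[iu] - mdiff[ju])
    # orient: forward (i, j) when P(i>j|S) >= P(i>j|R), else reversed
    fwd = d_fwd >= 0
    ga = np.where(fwd, genes[iu], genes[ju])
    gb = np.where(fwd, genes[ju], genes[iu])

    order = np.lexsort((gb.astype(str), ga.astype(str), -gamma, -delta))

    rules: list[TSPRule] = []
    used: set[str] = set()
    for idx in order:
        a, b = str(ga[idx]), str(gb[idx])
        if a in used or b in used:
            continue
        rules.append(TSPRule(a, b, float(delta[idx]), float(gamma[idx])))
        used.update((a, b))
        if len(rules) >= max_pairs:
            break
    return rules


def _vote_matrix(df: pd.DataFrame, rules: Sequence[TSPRule]) -> np.ndarray:
    """±1 votes, shape (n_rules, n_samples); expression ties vote −1."""
    missing = sorted(
        {g for r in rules for g in (r.gene_a, r.gene_b)} - set(df.index)
    )
    if missing:
        raise KeyError(f"expression matrix is missing model genes: {missing}")
    a = df.loc[[r.gene_a for r in rules]].to_numpy(dtype=float)
    b = df.loc[[r.gene_b for r in rules]].to_numpy(dtype=float)
    return np.where(a > b, 1, -1)


def select_k(m, labels, candidates: Sequence[TSPRule],
             k_range: tuple[int, int] = (1, DEFAULT_K_MAX)) -> int:
    """Pick k by the variance criterion on training vote sums.

    For each k the vote sums under the first k rules are compared between
    classes with a Welch-type standardized mean difference
    |m_s − m_r| / sqrt(v_s/n_s + v_r/n_r); the maximizing k wins, the
    smallest k on ties, and zero-variance separations score +inf.
    """
    if not candidates:
        raise ValueError("no candidate rules to select k from")
    k_min, k_max = k_range
    if not (1 <= k_min <= k_max):
        raise ValueError(f"invalid k_range {k_range}")
    df = _as_frame(m)
    sens = _sensitive_mask(labels)
    votes = _vote_matrix(df, candidates)
    cum = np.cumsum(votes, axis=0)  # row k-1 = vote sums under first k rules
    k_hi = min(k_max, len(candidates))
    best_k, best_score = k_min, -np.inf
    n_s, n_r = int(sens.sum()), int((~sens).sum())
    for k in range(k_min, k_hi + 1):
        vs = cum[k - 1]
        s, r = vs[sens], vs[~sens]
        mean_gap = abs(s.mean() - r.mean())
        var_s = s.var(ddof=1) if n_s > 1 else 0.0
        var_r = r.var(ddof=1) if n_r > 1 else 0.0
        se = np.sqrt(var_s / n_s + var_r / n_r)
        if se == 0.0:
            score = np.inf if mean_gap > 0 else 0.0
        else:
            score = mean_gap / se
        if score > best_score:
            best_k, best_score = k, score
    return best_k


class KTSP:
    """kTSP classifier model: expression matrix + binary sensitivity labels.

    Parameters
    ----------
    expression : ExpressionMatrix or DataFrame
        Genes × samples training expression (log2 TPM by convention,
        though only within-sample orderings matter).
    labels : sequence
        Per-sample labels, ``"sensitive"``/``"resistant"`` or booleans
        (True = sensitive), aligned with the sample columns.
    k_range : (int, int)
        Inclusive search range for the number of rules (default (1, 15)).
    tie_policy : str
        Class called when the vote sum is exactly 0 (default "resistant").
    gene_cap : int or None
        All-pairs scoring is O(G²·n); above this many genes only the most
        variable ``gene_cap`` genes enter the search (None disables).
    """

    def __init__(self, expression, labels,
                 k_range: tuple[int, int] = (1, DEFAULT_K_MAX),
                 tie_policy: str = RESISTANT,
                 gene_cap: int | None = DEFAULT_GENE_CAP):
        self.expression = _as_frame(expression)
        self.labels = labels
        self.sens_mask = _sensitive_mask(labels)
        if self.expression.shape[1] != self.sens_mask.shape[0]:
            raise ValueError("label length must match sample count")
        if tie_policy not in (SENSITIVE, RESISTANT):
            raise ValueError(f"tie_policy must be sensitive/resistant, got {tie_policy!r}")
        self.k_range = (int(k_range[0]), int(k_range[1]))
        if not (1 <= self.k_range[0] <= self.k_range[1] <= DEFAULT_K_MAX):
            raise ValueError(f"k_range must lie within [1, {DEFAULT_K_MAX}]")
        self.tie_policy = tie_policy
        self.gene_cap = gene_cap

    def fit(self) -> "KTSPResults":
        n_s = int(self.sens_mask.sum())
        n_r = int((~self.sens_mask).sum())
        if n_s < 2 or n_r < 2:
            raise ValueError(
                f"need >= 2 samples per class, got {n_s} sensitive / {n_r} resistant"
            )
        candidates = rank_disjoint_pairs(
            self.expression, self.sens_mask,
            max_pairs=self.k_range[1], gene_cap=self.gene_cap,
        )
        k = select_k(self.expression, self.sens_mask, candidates, self.k_range)
        meta = {
            "n_sensitive": n_s,
            "n_resistant": n_r,
            "k_max": self.k_range[1],
            "n_genes_searched": int(
                min(self.expression.shape[0],
                    self.gene_cap if self.gene_cap else self.expression.shape[0])
            ),
        }
        res = KTSPResults(candidates[:k], tie_policy=self.tie_policy,
                          training_meta=meta, model=self)
        res.candidate_rules = candidates  # full accepted disjoint list (k_max)
        return res


class KTSPResults:
    """A fitted kTSP rule set: ordered gene-disjoint rules plus voting logic."""

    def __init__(self, rules: Sequence[TSPRule], tie_policy: str = RESISTANT,
                 training_meta: dict | None = None, model: KTSP | None = None):
        rules = list(rules)
        if not rules:
            raise ValueError("a kTSP model needs at least one rule")
        genes = [g for r in rules for g in (r.gene_a, r.gene_b)]
        if len(set(genes)) != len(genes):
            raise ValueError("rules must be gene-disjoint")
        self.rules = rules
        self.k = len(rules)
        self.candidate_rules: list[TSPRule] = rules
        self.tie_policy = tie_policy
        self.training_meta = training_meta or {}
        self.model = model
        self.class_labels = (SENSITIVE, RESISTANT)

    # -- voting ------------------------------------------------------------
    def _sample_frame(self, sample) -> pd.DataFrame:
        if isinstance(sample, ExpressionMatrix):
            return sample.values
        if isinstance(sample, pd.DataFrame):
            return sample
        if isinstance(sample, pd.Series):
            return sample.to_frame()
        if isinstance(sample, Mapping):
            return pd.Series(sample, dtype=float).to_frame()
        raise TypeError("sample must be a mapping, Series, DataFrame or ExpressionMatrix")

    def vote_sums(self, samples) -> pd.Series:
        """Vote sum per sample: Σ rules (+1 if gene_a > gene_b else −1) ∈ [−k, k]."""
        df = self._sample_frame(samples)
        votes = _vote_matrix(df, self.rules)
        return pd.Series(votes.sum(axis=0), index=df.columns, dtype=int)

    def vote_sum(self, sample) -> int:
        return int(self.vote_sums(sample).iloc[0])

    def decision_scores(self, samples) -> pd.Series:
        """(vote_sum + k) / 2k, a continuous score in [0, 1] for AUROC."""
        return (self.vote_sums(samples) + self.k) / (2.0 * self.k)

    def decision_score(self, sample) -> float:
        return float(self.decision_scores(sample).iloc[0])

    def predict(self, samples) -> pd.Series:
        """Majority vote: sensitive iff vote_sum > 0; 0 resolves by tie_policy."""
        vs = self.vote_sums(samples)
        out = np.where(vs > 0, SENSITIVE,
                       np.where(vs < 0, RESISTANT, self.tie_policy))
        return pd.Series(out, index=vs.index)

    def predict_one(self, sample) -> str:
        return str(self.predict(sample).iloc[0])

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        meta = self.training_meta
        lines = [
            "kTSP classification rules",
            "=" * 58,
            f"k = {self.k}   tie policy: {self.tie_policy}   "
            f"trained on {meta.get('n_sensitive', '?')} sensitive / "
            f"{meta.get('n_resistant', '?')} resistant",
            "-" * 58,
            f"{'rank':>4}  {'gene_a':<14} > {'gene_b':<14} {'delta':>8} {'gamma':>8}",
        ]
        for i, r in enumerate(self.rules, 1):
            lines.append(
                f"{i:>4}  {r.gene_a:<14} > {r.gene_b:<14} {r.delta:8.4f} {r.gamma:8.4f}"
            )
        lines.append("-" * 58)
        lines.append("gene_a > gene_b votes +1 (sensitive); majority vote decides")
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------
    def save(self, rules_path: str | Path, drug: str = "drug") -> None:
        """Write the rules CSV plus a JSON sidecar with k/tie policy/meta."""
        rows = pd.DataFrame(
            {
                "drug": drug,
                "rank": range(1, self.k + 1),
                "gene_a": [r.gene_a for r in self.rules],
                "gene_b": [r.gene_b for r in self.rules],
                "direction": RULE_DIRECTION,
            }
        )
        write_rules_table(rows, rules_path)
        sidecar = Path(str(rules_path) + ".json")
        sidecar.write_text(json.dumps(
            {
                "k": self.k,
                "tie_policy": self.tie_policy,
                "training_meta": self.training_meta,
                "delta": [r.delta for r in self.rules],
                "gamma": [r.gamma for r in self.rules],
            },
            indent=2,
        ))

    @classmethod
    def load(cls, rules_path: str | Path) -> "KTSPResults":
        table = read_rules_table(rules_path)
        sidecar = Path(str(rules_path) + ".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        table = table.sort_values("rank")
        deltas = meta.get("delta", [0.0] * len(table))
        gammas = meta.get("gamma", [0.0] * len(table))
        rules = [
            TSPRule(str(a), str(b), float(d), float(g))
            for a, b, d, g in zip(table["gene_a"], table["gene_b"], deltas, gammas)
        ]
        return cls(rules, tie_policy=meta.get("tie_policy", RESISTANT),
                   training_meta=meta.get("training_meta", {}))


# -- functional wrappers ----------------------------------------------------

def fit_ktsp(m, labels, k_range: tuple[int, int] = (1, DEFAULT_K_MAX),
             tie_policy: str = RESISTANT,
             gene_cap: int | None = DEFAULT_GENE_CAP) -> KTSPResults:
    """Fit a kTSP classifier (rank pairs → select k → truncate)."""
    return KTSP(m, labels, k_range=k_range, tie_policy=tie_policy,
                gene_cap=gene_cap).fit()


def vote_sum(model: KTSPResults, sample) -> int:
    return model.vote_sum(sample)


def predict(model: KTSPResults, sample) -> str:
    return model.predict_one(sample)


def decision_score(model: KTSPResults, sample) -> float:
    return model.decision_score(sample)


def check_rank_invariance(model: KTSPResults, m,
                          transform: Callable[[np.ndarray], np.ndarray]
                          | Sequence[Callable[[np.ndarray], np.ndarray]]) -> bool:
    """True iff predictions are unchanged by the strictly increasing transform.

    ``transform`` is either one callable applied to every sample column or
    a sequence of callables, one per sample.
    """
    df = _as_frame(m)
    transformed = df.copy()
    if callable(transform):
        transforms = [transform] * df.shape[1]
    else:
        transforms = list(transform)
        if len(transforms) != df.shape[1]:
            raise ValueError("need one transform per sample")
    for j, fn in enumerate(transforms):
        col = df.iloc[:, j].to_numpy(dtype=float)
        new = np.asarray(fn(col), dtype=float)
        order = np.argsort(col, kind="stable")
        if np.any(np.diff(new[order]) < 0) or np.any(
            (np.diff(col[order]) > 0) & (np.diff(new[order]) <= 0)
        ):
            raise ValueError(f"transform for sample {df.columns[j]!r} is not strictly increasing")
        transformed.iloc[:, j] = new
    before = model.predict(df)
    after = model.predict(transformed)
    return bool((before == after).all())
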