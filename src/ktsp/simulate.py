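"""Synthetic AML-like cohort generation with known ground truth.

The generator produces exactly the statistical structure the kTSP
analysis assumes, so every pipeline stage can be exercised end to end
with a known answer:

* log2-scale background expression: every gene gets its own baseline
  level (Normal(8, baseline_sd) across genes) plus iid within-sample
  noise Normal(0, noise_sd) — different genes sit at different absolute
  expression levels, as in real RNA-seq;
* a minority of *truth pairs* — gene-disjoint pairs (a, b) sharing one
  baseline (informative pairs are comparably expressed) whose
  within-sample ordering is class-dependent: with probability θ
  (pair fidelity) a sensitive sample has a boosted by the effect size δ,
  otherwise b; mirrored for resistant samples.  The two genes of a pair
  are additionally co-expressed: they share a per-sample level
  (Normal(0, pair_level_sd)) on top of the baseline.  Co-expression is
  what makes the true pairing identifiable: it cancels exactly in the
  within-pair comparison but adds large independent variation to any
  cross-pairing of genes from two different truth pairs, diluting the
  cross-pair class signal;
* configurable sensitive/resistant imbalance (default 30/150, mimicking
  the minority status of sensitive samples for most single drugs);
* class-conditional drug AUC draws (sensitive Uniform(60, 95),
  resistant Uniform(100, 150)) so thresholding AUC at 100 reproduces the
  intended labels exactly;
* per-batch strictly increasing distortions x → α(x−c)³ + βx + γ that
  shift distributions between batches while preserving every
  within-sample gene ordering — a stylized batch effect;
* seven-point probit dose–response curves with additive viability noise.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .dose_response import DoseResponseCurve, SEVEN_POINT_SERIES_UM, label_by_auc
from .io import ExpressionMatrix

__all__ = [
    "SyntheticConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_train_test_cohorts",
    "apply_monotone_batch",
    "generate_dose_response",
]


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic cohort."""

    n_genes: int = 1000
    n_sensitive: int = 30
    n_resistant: int = 150
    n_truth_pairs: int = 10
    pair_fidelity: float = 0.9  # θ: P(the class-favoured gene of a pair is boosted)
    effect_size: float = 1.5  # δ on the log2 scale
    noise_sd: float = 1.0
    background_mean: float = 8.0
    baseline_sd: float = 2.0  # spread of per-gene baseline levels (log2)
    pair_level_sd: float = 3.0  # within-pair co-expression level spread (log2)
    auc_sensitive: tuple[float, float] = (60.0, 95.0)
    auc_resistant: tuple[float, float] = (100.0, 150.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if 2 * self.n_truth_pairs > self.n_genes:
            raise ValueError("need n_genes >= 2 * n_truth_pairs")
        if not 0.5 <= self.pair_fidelity <= 1.0:
            # θ = 0.5 is the signal-free null used for calibration checks
            raise ValueError(f"pair_fidelity must be in [0.5, 1], got {self.pair_fidelity}")
        if self.n_sensitive < 2 or self.n_resistant < 2:
            raise ValueError("class sizes must be >= 2")
        if not self.effect_size > 0:
            raise ValueError("effect_size must be > 0")


@dataclass
class SyntheticCohort:
    """Generated expression, labels, truth pairs and per-sample drug AUC."""

    expression: ExpressionMatrix
    labels: pd.Series  # sample_id -> sensitive/resistant
    truth_pairs: list[tuple[str, str]]  # oriented: a > b indicates sensitive
    auc: pd.Series  # sample_id -> drug AUC
    config: SyntheticConfig

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expression.sample_ids)


def _draw_truth_pairs(rng: np.random.Generator, n_genes: int,
                      n_pairs: int) -> list[tuple[int, int]]:
    gene_idx = rng.choice(n_genes, size=2 * n_pairs, replace=False)
    return [(int(gene_idx[2 * i]), int(gene_idx[2 * i + 1])) for i in range(n_pairs)]


def _draw_baselines(rng: np.random.Generator, config: SyntheticConfig,
                    truth_pairs: Sequence[tuple[int, int]]) -> np.ndarray:
    base = rng.normal(config.background_mean, config.baseline_sd, size=config.n_genes)
    for ia, ib in truth_pairs:
        base[ib] = base[ia]  # informative pairs are comparably expressed
    return base


def generate_cohort(config: SyntheticConfig,
                    truth_pairs: Sequence[tuple[int, int]] | None = None,
                    baselines: np.ndarray | None = None,
                    sample_prefix: str = "S") -> SyntheticCohort:
    """Draw one cohort under the given study conditions.

    ``truth_pairs`` (gene index pairs, a-side first) and ``baselines``
    (per-gene baseline levels) can be passed to reuse the discriminative
    structure of another cohort — e.g. to draw an independent test
    cohort that shares the training cohort's truth.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_sensitive + config.n_resistant
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    samples = [f"{sample_prefix}{j:03d}" for j in range(n)]
    sens = np.zeros(n, dtype=bool)
    sens[: config.n_sensitive] = True

    if truth_pairs is None:
        truth_pairs = _draw_truth_pairs(rng, config.n_genes, config.n_truth_pairs)
    if baselines is None:
        baselines = _draw_baselines(rng, config, truth_pairs)
    X = baselines[:, None] + rng.normal(0.0, config.noise_sd,
                                        size=(config.n_genes, n))
    for (ia, ib) in truth_pairs:
        # co-expression: one shared per-sample level for both pair genes
        level = rng.normal(0.0, config.pair_level_sd, size=n)
        X[ia] += level
        X[ib] += level
        # sensitive samples boost gene a with probability θ, else gene b;
        # resistant samples mirror this, favouring gene b.
        favour_a = np.where(sens,
                            rng.uniform(size=n) < config.pair_fidelity,
                            rng.uniform(size=n) >= config.pair_fidelity)
        X[ia, favour_a] += config.effect_size
        X[ib, ~favour_a] += config.effect_size

    auc = np.where(
        sens,
        rng.uniform(*config.auc_sensitive, size=n),
        rng.uniform(*config.auc_resistant, size=n),
    )
    labels = pd.Series(
        [label_by_auc(a) for a in auc], index=samples, name="label"
    )
    intended = pd.Series(np.where(sens, "sensitive", "resistant"), index=samples)
    assert (labels == intended).all(), "AUC ranges must reproduce the intended labels"

    expr = ExpressionMatrix(pd.DataFrame(X, index=genes, columns=samples), "log2tpm")
    named_pairs = [(genes[ia], genes[ib]) for ia, ib in truth_pairs]
    return SyntheticCohort(expr, labels, named_pairs,
                           pd.Series(auc, index=samples, name="auc"), config)


def generate_train_test_cohorts(config: SyntheticConfig,
                                test_config: SyntheticConfig | None = None
                                ) -> tuple[SyntheticCohort, SyntheticCohort]:
    """Two independent cohorts sharing truth pairs and gene baselines."""
    rng = np.random.default_rng(config.seed)
    pairs = _draw_truth_pairs(rng, config.n_genes, config.n_truth_pairs)
    base = _draw_baselines(rng, config, pairs)
    if test_config is None:
        test_config = SyntheticConfig(**{**asdict(config), "seed": config.seed + 1_000_003})
    if test_config.n_genes != config.n_genes:
        raise ValueError("train and test cohorts must share the gene universe")
    train = generate_cohort(config, truth_pairs=pairs, baselines=base, sample_prefix="TR")
    test = generate_cohort(test_config, truth_pairs=pairs, baselines=base, sample_prefix="TE")
    return train, test


def _monotone_transform(rng: np.random.Generator) -> Callable[[np.ndarray], np.ndarray]:
    """A random strictly increasing map x → α(x−c)³ + βx + γ, α ≥ 0, β > 0."""
    alpha = float(rng.uniform(0.0, 0.5))
    beta = float(rng.uniform(0.2, 3.0))
    c = float(rng.uniform(4.0, 12.0))
    gamma = float(rng.uniform(-5.0, 5.0))
    if alpha < 0 or beta <= 0:
        raise RuntimeError("non-increasing transform drawn; impossible by construction")
    return lambda x: alpha * (np.asarray(x) - c) ** 3 + beta * np.asarray(x) + gamma


def apply_monotone_batch(m: ExpressionMatrix,
                         batch_spec: Sequence[tuple[Sequence[str], str]],
                         seed: int = 0) -> ExpressionMatrix:
    """Apply per-batch strictly increasing distortions to sample subsets.

    ``batch_spec`` is a list of (sample ids, transform id); samples in the
    same batch share one transform drawn deterministically from
    (seed, transform id).  ``"identity"`` leaves a batch untouched.
    Within-sample gene orderings are provably unchanged.
    """
    df = m.values.copy()
    seen: set[str] = set()
    for sample_ids, transform_id in batch_spec:
        dup = seen.intersection(sample_ids)
        if dup:
            raise ValueError(f"samples assigned to more than one batch: {sorted(dup)}")
        seen.update(sample_ids)
        missing = sorted(set(sample_ids) - set(df.columns))
        if missing:
            raise ValueError(f"unknown samples in batch spec: {missing}")
        if transform_id == "identity":
            continue
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, zlib.crc32(str(transform_id).encode())])
        )
        fn = _monotone_transform(rng)
        cols = list(sample_ids)
        df[cols] = fn(df[cols].to_numpy(dtype=float))
    # distorted values can be negative; keep the log2-like tag
    return ExpressionMatrix(df, "log2tpm")


def generate_dose_response(probit_params: Sequence[tuple[float, float]],
                           noise_sd: float = 0.0, seed: int = 0,
                           concentrations: Sequence[float] = SEVEN_POINT_SERIES_UM,
                           drug_id: str = "drug") -> list[DoseResponseCurve]:
    """Seven-point dose–response curves from per-sample probit parameters.

    viability = 100·Φ(intercept + slope·log10 c) + Normal(0, noise_sd),
    clipped to [0, 300].  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    conc = np.asarray(concentrations, dtype=float)
    x = np.log10(conc)
    curves = []
    for i, (intercept, slope) in enumerate(probit_params):
        v = 100.0 * norm.cdf(intercept + slope * x)
        if noise_sd > 0:
            v = v + rng.normal(0.0, noise_sd, size=v.shape)
        v = np.clip(v, 0.0, 300.0)
        curves.append(DoseResponseCurve(conc, v, sample_id=f"S{i:03d}", drug_id=drug_id))
    return curves
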