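"""Probit dose–response modelling and drug-sensitivity scoring.

Ex vivo drug screens measure cell viability (percent of control) over a
seven-point concentration series.  A probit regression curve
``v(x) = 100·Φ(β0 + β1·x)`` is fitted to viability against
``x = log10(concentration)`` by maximum likelihood under homoscedastic
Gaussian errors (equivalently, least squares).  From the fitted curve we
derive:

* **AUC** — the mean fitted viability over the screened log10 range,
  normalized so a non-responsive profile scores exactly 100
  (theoretical range 0–300; AUC < 100 calls the sample *Sensitive*).
* **DSS1/2/3** — drug sensitivity scores: normalized areas of the
  inhibition curve ``r(x) = 100 − v(x)`` above an activity threshold
  ``Amin`` over the dose window where the drug is active.
* **sDSS** — selective DSS, the patient DSS minus the mean DSS of
  healthy-control samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize
from scipy.stats import norm

__all__ = [
    "DoseResponseCurve",
    "ProbitFit",
    "ProbitDoseResponse",
    "DrugResponseRecord",
    "DSSInputs",
    "fit_probit_curve",
    "probit_auc",
    "label_by_auc",
    "compute_dss",
    "dss_from_fit",
    "sdss",
    "label_by_sdss_percentile",
]

SEVEN_POINT_SERIES_UM = (10.0, 10 / 3, 10 / 9, 10 / 27, 10 / 81, 10 / 243, 10 / 729)
AUC_MAX = 300.0
SENSITIVE = "sensitive"
RESISTANT = "resistant"

_N_GRID = 4096  # composite-trapezoid resolution on the log10 axis


@dataclass
class DoseResponseCurve:
    """A single sample × drug concentration–viability series.

    concentrations are in µM (strictly monotone, all positive); viability
    is in percent of control and may exceed 100 when the drug enhanced
    growth (capped at 300 downstream).
    """

    concentrations: np.ndarray
    viability: np.ndarray
    sample_id: str = ""
    drug_id: str = ""

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if self.concentrations.shape != self.viability.shape:
            raise ValueError("concentrations and viability must have equal length")
        if (self.concentrations <= 0).any():
            raise ValueError("concentrations must be positive")
        d = np.diff(self.concentrations)
        if not ((d > 0).all() or (d < 0).all()):
            raise ValueError("concentrations must be strictly monotone")
        if not np.all(np.isfinite(self.viability)) or (self.viability < 0).any():
            raise ValueError("viability must be finite and non-negative")

    @property
    def log10_conc(self) -> np.ndarray:
        return np.log10(self.concentrations)

    @property
    def x_bounds(self) -> tuple[float, float]:
        x = self.log10_conc
        return float(x.min()), float(x.max())


@dataclass
class ProbitFit:
    """Fitted probit parameters: viability/100 = Φ(intercept + slope·x).

    ``flat_level`` is set instead of a Φ-model when all viabilities are
    identical (the degenerate closed form); it carries the observed mean
    viability in percent, clipped to [0, 300] at integration time.
    """

    intercept: float
    slope: float
    converged: bool
    x_grid: tuple[float, float]
    flat_level: float | None = None

    def viability(self, x: np.ndarray | float) -> np.ndarray | float:
        """Model viability (percent) at log10-concentration x, capped at 100."""
        if self.flat_level is not None:
            return np.broadcast_to(
                np.clip(self.flat_level, 0.0, AUC_MAX), np.shape(x)
            ).astype(float) if np.ndim(x) else float(np.clip(self.flat_level, 0, AUC_MAX))
        return 100.0 * norm.cdf(self.intercept + self.slope * np.asarray(x, dtype=float))

    def inhibition(self, x: np.ndarray | float) -> np.ndarray | float:
        """Inhibition r(x) = 100 − v(x), floored at 0."""
        return np.clip(100.0 - np.asarray(self.viability(x)), 0.0, None)


def fit_probit_curve(curve: DoseResponseCurve) -> ProbitFit:
    """Least-squares (Gaussian-MLE) probit fit of viability/100 vs log10 dose.

    Requires at least 4 distinct concentrations.  All-identical
    viabilities short-circuit to the flat-curve closed form: slope 0 and,
    when 0 < v̄ < 100, intercept Φ⁻¹(v̄/100); otherwise the observed level
    is carried directly (``flat_level``).  Non-convergence is reported via
    ``converged=False``, never silently defaulted.
    """
    x = curve.log10_conc
    if len(np.unique(curve.concentrations)) < 4:
        raise ValueError("probit fit requires at least 4 distinct concentrations")
    y = curve.viability / 100.0
    bounds = curve.x_bounds

    if np.ptp(curve.viability) == 0.0:
        v_mean = float(curve.viability[0])
        if 0.0 < v_mean < 100.0:
            return ProbitFit(float(norm.ppf(v_mean / 100.0)), 0.0, True, bounds,
                             flat_level=v_mean)
        return ProbitFit(np.nan, 0.0, True, bounds, flat_level=v_mean)

    def residuals(params: np.ndarray) -> np.ndarray:
        return norm.cdf(params[0] + params[1] * x) - y

    # moment-based start: linearize through the probit link on clipped y
    y_clip = np.clip(y, 1e-4, 1 - 1e-4)
    z = norm.ppf(y_clip)
    slope0, icept0 = np.polyfit(x, z, 1)
    best = None
    for start in ((icept0, slope0), (0.0, -1.0), (0.0, 1.0)):
        sol = optimize.least_squares(residuals, x0=np.asarray(start, dtype=float),
                                     method="lm", max_nfev=2000)
        if best is None or sol.cost < best.cost:
            best = sol
    converged = bool(best.success and np.all(np.isfinite(best.x)))
    return ProbitFit(float(best.x[0]), float(best.x[1]), converged, bounds)


def probit_auc(fit: ProbitFit, curve: DoseResponseCurve | None = None) -> float:
    """Normalized AUC: mean fitted viability (percent) over the screened log10 range.

    Flat 100 % viability gives exactly 100 (non-responsive); results are
    clipped to the theoretical range [0, 300].
    """
    if fit.flat_level is not None:
        return float(np.clip(fit.flat_level, 0.0, AUC_MAX))
    if not fit.converged:
        raise ValueError("probit fit did not converge; AUC undefined")
    x_lo, x_hi = fit.x_grid
    if x_hi == x_lo:
        return float(np.clip(fit.viability(x_lo), 0.0, AUC_MAX))
    grid = np.linspace(x_lo, x_hi, _N_GRID)
    mean_v = np.trapezoid(fit.viability(grid), grid) / (x_hi - x_lo)
    return float(np.clip(mean_v, 0.0, AUC_MAX))


def label_by_auc(auc: float) -> str:
    """Sensitivity call from normalized AUC: < 100 → sensitive, otherwise resistant."""
    if not (0.0 <= auc <= AUC_MAX):
        raise ValueError(f"AUC must be in [0, {AUC_MAX}], got {auc}")
    return SENSITIVE if auc < 100.0 else RESISTANT


@dataclass
class DSSInputs:
    """Geometry of the inhibition curve needed by the DSS formulas.

    All of c_min, c_max, x1, x2 live on the log10-concentration axis so
    the DSS ratios are dimensionless.  ``auc_resp`` is the area under the
    inhibition (response) curve over [x1, x2]; ``r_max`` the top asymptote
    of the response in percent; ``a_min`` the minimum activity threshold.
    """

    a_min: float
    c_min: float
    c_max: float
    x1: float
    x2: float
    r_max: float
    auc_resp: float

    def __post_init__(self) -> None:
        if not self.c_min < self.c_max:
            raise ValueError("require c_min < c_max")
        if not (self.c_min <= self.x1 <= self.x2 <= self.c_max):
            raise ValueError("require c_min <= x1 <= x2 <= c_max")


def compute_dss(inputs: DSSInputs, version: int = 2) -> float:
    """Drug sensitivity score from inhibition-curve geometry.

    DSS1 = (AUC_r − Amin·(x2−x1)) / ((100−Amin)·(Cmax−Cmin));
    DSS2 = DSS1 / log10(Rmax); DSS3 = DSS2 · (x2−x1)/(Cmax−Cmin).
    A response never exceeding Amin (x1 = x2) scores 0 in every version.
    """
    if version not in (1, 2, 3):
        raise ValueError(f"DSS version must be 1, 2 or 3, got {version}")
    i = inputs
    if i.x1 == i.x2:
        return 0.0
    dss1 = (i.auc_resp - i.a_min * (i.x2 - i.x1)) / (
        (100.0 - i.a_min) * (i.c_max - i.c_min)
    )
    if version == 1:
        return float(dss1)
    if not i.r_max > 1.0:
        raise ValueError(
            f"DSS{version} requires r_max > 1 (log10 positive), got {i.r_max}"
        )
    dss2 = dss1 / np.log10(i.r_max)
    if version == 2:
        return float(dss2)
    return float(dss2 * (i.x2 - i.x1) / (i.c_max - i.c_min))


def _crossings(fit: ProbitFit, a_min: float, c_min: float, c_max: float,
               tol: float = 1e-8) -> tuple[float, float] | None:
    """x1 (first up-crossing) and x2 (last down-crossing or c_max) of r(x) = a_min.

    Bisection on each sign-change interval of a dense scan; returns None
    when the inhibition never exceeds a_min.
    """
    grid = np.linspace(c_min, c_max, _N_GRID)
    f = np.asarray(fit.inhibition(grid)) - a_min
    above = f > 0
    if not above.any():
        return None

    def bisect(lo: float, hi: float) -> float:
        g = lambda x: float(fit.inhibition(x)) - a_min
        return float(optimize.bisect(g, lo, hi, xtol=tol))

    sign_change = np.nonzero(np.diff(above))[0]
    if above[0]:
        x1 = c_min
    else:
        k = sign_change[0]
        x1 = bisect(grid[k], grid[k + 1])
    if above[-1]:
        x2 = c_max
    else:
        k = sign_change[-1]
        x2 = bisect(grid[k], grid[k + 1])
    return x1, x2


def dss_from_fit(fit: ProbitFit, curve: DoseResponseCurve, a_min: float = 10.0,
                 version: int = 2) -> float:
    """DSS of a fitted curve: find the active window, integrate, normalize."""
    c_min, c_max = curve.x_bounds
    grid = np.linspace(c_min, c_max, _N_GRID)
    r = np.asarray(fit.inhibition(grid))
    r_max = float(r.max())
    xs = _crossings(fit, a_min, c_min, c_max)
    if xs is None:
        return 0.0
    x1, x2 = xs
    if x1 == x2:
        return 0.0
    window = np.linspace(x1, x2, _N_GRID)
    auc_resp = float(np.trapezoid(np.asarray(fit.inhibition(window)), window))
    return compute_dss(
        DSSInputs(a_min=a_min, c_min=c_min, c_max=c_max, x1=x1, x2=x2,
                  r_max=r_max, auc_resp=auc_resp),
        version=version,
    )


def sdss(dss_patient: float, dss_controls: Sequence[float]) -> float:
    """Selective DSS: patient DSS minus the mean of the control DSSs."""
    controls = np.asarray(dss_controls, dtype=float)
    if controls.size == 0:
        raise ValueError("sDSS requires at least one control DSS value")
    return float(dss_patient - controls.mean())


@dataclass
class DrugResponseRecord:
    """One (sample, drug) response: AUC and/or sDSS plus the sensitivity call."""

    sample_id: str
    drug_id: str
    auc: float | None = None
    sdss: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.auc is None and self.sdss is None:
            raise ValueError("record needs at least one of auc/sdss")
        if self.auc is not None and not (0.0 <= self.auc <= AUC_MAX):
            raise ValueError(f"AUC must be in [0, {AUC_MAX}], got {self.auc}")


def label_by_sdss_percentile(records: Sequence[DrugResponseRecord],
                             percentile: float = 95.0) -> list[DrugResponseRecord]:
    """Label records sensitive iff sDSS strictly exceeds the pooled percentile.

    The threshold is the given linear-interpolation percentile of the sDSS
    values pooled across ALL drugs and samples; records are returned with
    labels filled in.
    """
    if not records:
        raise ValueError("no records to label")
    if not 0.0 <= percentile < 100.0:
        raise ValueError(f"percentile must be in [0, 100), got {percentile}")
    values = [r.sdss for r in records]
    if any(v is None for v in values):
        raise ValueError("every record must carry an sDSS value")
    threshold = float(np.percentile(np.asarray(values, dtype=float), percentile))
    return [
        DrugResponseRecord(
            r.sample_id, r.drug_id, auc=r.auc, sdss=r.sdss,
            label=SENSITIVE if r.sdss > threshold else RESISTANT,
        )
        for r in records
    ]


class ProbitDoseResponse:
    """Probit dose–response model for one concentration–viability series.

    Examples
    --------
    >>> curve = DoseResponseCurve(SEVEN_POINT_SERIES_UM,
    ...                           100 * norm.cdf(1.0 - 1.2 * np.log10(SEVEN_POINT_SERIES_UM)))
    >>> res = ProbitDoseResponse(curve).fit()
    >>> 0 <= res.auc <= 300
    True
    """

    def __init__(self, curve: DoseResponseCurve):
        self.curve = curve

    def fit(self) -> "ProbitResults":
        return ProbitResults(self, fit_probit_curve(self.curve))


class ProbitResults:
    """Results of a probit dose–response fit: parameters, AUC, DSS, label."""

    def __init__(self, model: ProbitDoseResponse, fit: ProbitFit):
        self.model = model
        self.probit_fit = fit
        self.intercept = fit.intercept
        self.slope = fit.slope
        self.converged = fit.converged

    @property
    def auc(self) -> float:
        return probit_auc(self.probit_fit, self.model.curve)

    @property
    def label(self) -> str:
        return label_by_auc(self.auc)

    def dss(self, a_min: float = 10.0, version: int = 2) -> float:
        return dss_from_fit(self.probit_fit, self.model.curve,
                            a_min=a_min, version=version)

    def predict(self, concentrations: Iterable[float]) -> np.ndarray:
        x = np.log10(np.asarray(list(concentrations), dtype=float))
        return np.asarray(self.probit_fit.viability(x))

    def summary(self) -> str:
        c = self.model.curve
        lines = [
            "Probit dose-response fit",
            "=" * 40,
            f"sample: {c.sample_id or '-'}   drug: {c.drug_id or '-'}",
            f"intercept: {self.intercept:10.4f}",
            f"slope:     {self.slope:10.4f}",
            f"converged: {self.converged}",
            f"AUC:       {self.auc:10.2f}   ({self.label})",
            f"DSS2:      {self.dss():10.4f}",
        ]
        return "\n".join(lines)
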