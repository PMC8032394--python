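"""Weibull psychometric model and detection-threshold fitting.

Detection performance as a function of odor concentration x is modeled with a
Weibull psychometric function

    SR(x) = A − (A − g) · exp(−c · (x / T)^b),   c = −ln((A − criterion)/(A − g))

where A is asymptotic performance, g the floor (false-alarm rate: 0 % for the
dishabituation assay, 50 % chance level for Go/No-Go), b the steepness, and T
the threshold concentration — the concentration at which the curve attains the
``criterion`` performance level.  With the default half-range criterion
(A + g)/2, c = ln 2 and T is the half-maximum point.  The curve rises
monotonically from g at x = 0 toward A.

Thresholds are estimated by nonlinear least squares on mean responses per
concentration, with the concentration axis handled on log10 scale internally
(thresholds span orders of magnitude, e.g. 10⁻⁸–10⁻⁴ v/v) and a multi-start
grid over initial thresholds, since Weibull fits are initialization-sensitive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "PsychometricModel",
    "FitResult",
    "weibull_sr",
    "fit_weibull",
    "threshold_from_fit",
]


@dataclass(frozen=True)
class PsychometricModel:
    """Weibull performance-curve parameters.

    ``criterion`` defaults to the half-range point (A + g)/2; pass it
    explicitly to define the threshold at another performance level.
    """

    A: float
    g: float
    b: float
    T: float
    criterion: float | None = None

    def __post_init__(self) -> None:
        if not self.A > self.g:
            raise ValueError("need A > g")
        if not self.b > 0:
            raise ValueError("need b > 0")
        if not self.T > 0:
            raise ValueError("need T > 0")
        crit = self.criterion if self.criterion is not None else 0.5 * (self.A + self.g)
        if not (self.g < crit < self.A):
            raise ValueError("criterion must lie strictly between g and A")
        object.__setattr__(self, "criterion", float(crit))

    @property
    def c(self) -> float:
        """Shape constant making SR(T) = criterion exactly."""
        return -np.log((self.A - self.criterion) / (self.A - self.g))


def weibull_sr(x, model: PsychometricModel):
    """Forward Weibull curve; accepts scalar or array concentrations ≥ 0."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("concentrations must be non-negative")
    out = model.A - (model.A - model.g) * np.exp(-model.c * (x / model.T) ** model.b)
    return float(out) if out.ndim == 0 else out


def threshold_from_fit(model: PsychometricModel) -> float:
    """The fitted detection threshold: the concentration where the curve
    reaches the criterion performance level."""
    return model.T


@dataclass
class FitResult:
    """Outcome of a Weibull fit.

    ``success`` is False when the data carry no usable dynamic range (the
    fitted amplitude is indistinguishable from the floor) or the optimizer
    failed from every start; then ``model`` / ``threshold`` are None and
    ``message`` explains why, rather than returning a silently wrong curve.
    """

    model: PsychometricModel | None
    success: bool
    message: str
    sse: float
    n_starts: int
    threshold: float | None = None
    threshold_ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.model is not None and self.threshold is None:
            self.threshold = self.model.T


def _mean_responses(data: pd.DataFrame, variant: str) -> tuple[np.ndarray, np.ndarray]:
    if variant == "binary":
        if "n_trials" in data.columns:
            agg = data.groupby("concentration").apply(
                lambda d: 100.0 * d["n_success"].sum() / d["n_trials"].sum(),
                include_groups=False,
            )
            return agg.index.to_numpy(float), agg.to_numpy(float)
        # per-trial 0/1 outcomes in `response`
        agg = data.groupby("concentration")["response"].mean() * 100.0
        return agg.index.to_numpy(float), agg.to_numpy(float)
    agg = data.groupby("concentration")["response"].mean()
    return agg.index.to_numpy(float), agg.to_numpy(float)


def _fit_means(conc: np.ndarray, resp: np.ndarray, fixed_g: float,
               criterion_frac: float = 0.5) -> tuple[np.ndarray, float] | None:
    """Least-squares fit of (A, b, log10 T) at fixed g; multi-start over log10 T.

    ``criterion_frac`` places the criterion at g + frac·(A − g); 0.5 gives the
    half-range convention (c = ln 2).
    """
    u = np.log10(conc)
    c_const = -np.log(1.0 - criterion_frac)

    def residuals(theta):
        A, b, uT = theta
        pred = A - (A - fixed_g) * np.exp(-c_const * 10.0 ** (b * (u - uT)))
        return pred - resp

    a0 = max(resp.max(), fixed_g + 1e-3)
    lo = [fixed_g + 1e-9, 1e-3, u.min() - 4.0]
    hi = [max(2.0 * a0, fixed_g + 1.0), 50.0, u.max() + 4.0]
    best = None
    for uT0 in np.linspace(u.min() - 1.0, u.max() + 1.0, 7):
        for b0 in (0.5, 1.0, 2.0):
            try:
                sol = least_squares(residuals, x0=[a0, b0, uT0], bounds=(lo, hi))
            except ValueError:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        return None
    return best.x, float(2.0 * best.cost)  # cost is 0.5·SSE


def fit_weibull(data: pd.DataFrame, fixed_g: float, variant: str = "continuous",
                criterion_frac: float = 0.5, n_bootstrap: int = 0,
                seed: int | None = None) -> FitResult:
    """Fit the Weibull psychometric curve to a concentration–response table.

    ``data`` is tidy with columns ``subject_id``, ``concentration`` and
    ``response`` (ΔNPI percent for the dishabituation variant, success percent
    or 0/1 outcomes — optionally ``n_success``/``n_trials`` — for Go/No-Go).
    The floor g is fixed (0 for dishabituation, 50 for Go/No-Go) and A, b, T
    are estimated on the per-concentration mean responses.  ``n_bootstrap`` > 0
    adds a percentile confidence interval for T from resampling subjects.
    """
    if variant not in ("continuous", "binary"):
        raise ValueError(f"unknown variant {variant!r}")
    conc, resp = _mean_responses(data, variant)
    if len(conc) < 3:
        raise ValueError("need at least three distinct concentrations")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")

    n_starts = 21
    fit = _fit_means(conc, resp, fixed_g, criterion_frac)
    if fit is None:
        return FitResult(model=None, success=False, sse=float("nan"),
                         message="optimizer failed from every start", n_starts=n_starts)
    (A, b, uT), sse = fit
    rmse = np.sqrt(sse / len(conc))
    # no usable dynamic range: amplitude indistinguishable from the floor
    if (A - fixed_g) <= max(2.0 * rmse, 1e-8):
        return FitResult(model=None, success=False, sse=sse, n_starts=n_starts,
                         message="flat response: fitted amplitude indistinguishable "
                                 "from the floor; no threshold reported")
    model = PsychometricModel(A=float(A), g=float(fixed_g), b=float(b), T=float(10.0 ** uT),
                              criterion=float(fixed_g + criterion_frac * (A - fixed_g)))
    ci = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        subjects = data["subject_id"].unique()
        draws = []
        for _ in range(n_bootstrap):
            pick = rng.choice(subjects, size=len(subjects), replace=True)
            boot = pd.concat([data[data["subject_id"] == s] for s in pick])
            bc, br = _mean_responses(boot, variant)
            if len(bc) < 3:
                continue
            bfit = _fit_means(bc, br, fixed_g, criterion_frac)
            if bfit is not None:
                draws.append(10.0 ** bfit[0][2])
        if draws:
            ci = tuple(float(q) for q in np.percentile(draws, [2.5, 97.5]))
    return FitResult(model=model, success=True, sse=sse, n_starts=n_starts,
                     message="converged", threshold_ci=ci)
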