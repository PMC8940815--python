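"""Parameter estimation on simulated plasma data.

Two estimators live in this package: the naive pooled least-squares fit used
for the structural-identifiability screen (this module) and the nonlinear
mixed-effects FOCE estimator for population trials (:mod:`pulmodeconv.nlme`).

Both work in a transformed, unconstrained parameter space: rate constants
and dispositional volumes/clearances on the log scale, bounded fractions
(``f_pul``, process fractions, proportionality factors) on the logit scale,
and the three-way fraction simplex of the parallel-absorption models through
two log-ratio coordinates.  Estimates are mapped back and canonicalised
(fast > med > slow), which removes label-switching between equivalent
orderings of the parallel processes.

Identifiability is judged from the Fisher information matrix of the
residual model at the optimum: a parameter vector is declared identifiable
when the FIM is numerically non-singular (condition number below a
threshold, default 1e10) and all implied standard errors are finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .models import (
    AbsorptionVariant,
    ConfigurationError,
    ParameterSet,
    Route,
    VariantName,
    solve_profiles,
)

__all__ = [
    "ParameterTransform",
    "FitResult",
    "IdentifiabilityVerdict",
    "fit_naive",
    "fisher_information",
    "aic",
    "PULMONARY_THETA",
    "DISPOSITION_THETA",
]

LOGIT_BOUND = 15.0
LOG_RATE_BOUNDS = (math.log(1e-5), math.log(1e4))
FIM_CONDITION_LIMIT = 1e10
CORRELATION_FLAG = 0.99

#: free pulmonary parameters per estimation variant
PULMONARY_THETA: dict[VariantName, tuple[str, ...]] = {
    VariantName.I: ("f_pul", "k_fast"),
    VariantName.II: ("f_pul", "f_fast", "k_fast", "k_slow"),
    VariantName.IIIA: ("f_pul", "f_fast", "f_med", "k_fast", "k_med", "k_slow"),
    VariantName.IIIB: ("f_pul", "f_fast", "f_med", "k_fast", "pf1", "pf2"),
    VariantName.TRANSIT: ("f_pul", "k_trans"),
    VariantName.NAL: ("f_pul", "k_fast", "k_nal"),
}

DISPOSITION_THETA = ("cl", "v1", "q2", "v2", "q3", "v3", "q4", "v4")

_LOGIT_PARAMS = {"f_pul", "pf1", "pf2"}

#: neutral starting values used when no initial guess is supplied
DEFAULT_INITIALS = {
    "f_pul": 0.5,
    "f_fast": 0.5,
    "f_med": 1.0 / 3.0,
    "f_slow": 0.5,
    "k_fast": 1.0,
    "k_med": 0.1,
    "k_slow": 0.01,
    "k_trans": 0.5,
    "k_nal": 1.0,
    "pf1": 0.1,
    "pf2": 0.1,
}


def _logit(p: float) -> float:
    p = min(max(p, 1e-12), 1.0 - 1e-12)
    return math.log(p / (1.0 - p))


def _expit(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


class ParameterTransform:
    """Bijection between a named parameter subset and an unconstrained vector.

    ``names`` lists the model parameters to free.  When both ``f_fast`` and
    ``f_med`` appear (three parallel processes), the simplex
    ``f_fast + f_med + f_slow = 1`` is parameterised by the two log-ratios
    ``log(f_fast/f_slow)`` and ``log(f_med/f_slow)``; a lone ``f_fast``
    (two processes) uses a logit with ``f_slow = 1 - f_fast``.
    """

    def __init__(self, names: Sequence[str]):
        self.names = tuple(names)
        self._simplex3 = "f_fast" in self.names and "f_med" in self.names
        self._pair = "f_fast" in self.names and not self._simplex3
        self.labels: list[str] = []
        for name in self.names:
            if name == "f_fast" and self._simplex3:
                self.labels.append("log(f_fast/f_slow)")
            elif name == "f_med" and self._simplex3:
                self.labels.append("log(f_med/f_slow)")
            elif name == "f_fast":
                self.labels.append("logit(f_fast)")
            elif name in _LOGIT_PARAMS:
                self.labels.append(f"logit({name})")
            else:
                self.labels.append(f"log({name})")

    @property
    def size(self) -> int:
        return len(self.names)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = [], []
        for name in self.names:
            if name in _LOGIT_PARAMS or name.startswith("f_"):
                lo.append(-LOGIT_BOUND)
                hi.append(LOGIT_BOUND)
            else:
                lo.append(LOG_RATE_BOUNDS[0])
                hi.append(LOG_RATE_BOUNDS[1])
        return np.asarray(lo), np.asarray(hi)

    def encode(self, values: Mapping[str, float]) -> np.ndarray:
        z = np.empty(self.size)
        for i, name in enumerate(self.names):
            v = values[name]
            if self._simplex3 and name in ("f_fast", "f_med"):
                f_slow = 1.0 - values["f_fast"] - values["f_med"]
                f_slow = max(f_slow, 1e-12)
                z[i] = math.log(max(v, 1e-12) / f_slow)
            elif name == "f_fast":
                z[i] = _logit(v)
            elif name in _LOGIT_PARAMS:
                z[i] = _logit(v)
            else:
                z[i] = math.log(v)
        return z

    def decode(self, z: np.ndarray) -> dict[str, float]:
        out: dict[str, float] = {}
        for i, name in enumerate(self.names):
            if self._simplex3 and name in ("f_fast", "f_med"):
                continue  # handled jointly below
            elif name == "f_fast":
                f_fast = _expit(z[i])
                out["f_fast"] = f_fast
                out["f_slow"] = 1.0 - f_fast
            elif name in _LOGIT_PARAMS:
                out[name] = _expit(z[i])
            else:
                out[name] = math.exp(z[i])
        if self._simplex3:
            i_fast = self.names.index("f_fast")
            i_med = self.names.index("f_med")
            a = math.exp(min(z[i_fast], 500.0))
            b = math.exp(min(z[i_med], 500.0))
            denom = 1.0 + a + b
            out["f_fast"] = a / denom
            out["f_med"] = b / denom
            out["f_slow"] = 1.0 / denom
        # keep fractions strictly inside (0, 1) so ParameterSet accepts them
        for key in ("f_pul", "f_fast", "f_med", "f_slow", "pf1", "pf2"):
            if key in out:
                out[key] = min(max(out[key], 1e-12), 1.0 - 1e-12 if key != "f_pul" else 1.0)
        return out

    def apply(self, base: ParameterSet, z: np.ndarray) -> ParameterSet:
        return replace(base, **self.decode(z))


@dataclass
class IdentifiabilityVerdict:
    """FIM-based structural-identifiability verdict at a fitted optimum."""

    identifiable: bool
    fim_condition_number: float
    correlated_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    cause: str = ""


@dataclass
class FitResult:
    """Outcome of a fit: canonical estimates plus optimisation metadata."""

    variant: AbsorptionVariant
    strategy: str
    params: ParameterSet
    objective: float
    converged: bool
    n_retries_used: int
    param_labels: tuple[str, ...]
    z: np.ndarray
    n_estimated: int
    se: dict[str, float] | None = None
    omega: dict[str, float] | None = None
    sigma: float | None = None
    ebes: object | None = None  # pandas DataFrame of empirical Bayes estimates
    verdict: IdentifiabilityVerdict | None = None
    extra: dict = field(default_factory=dict)


def _clean_observations(times: np.ndarray, obs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    obs = np.asarray(obs, dtype=float)
    mask = (obs > 0) & (times > 0)
    return times[mask], obs[mask]


def fit_naive(
    times: np.ndarray,
    obs_plasma: np.ndarray,
    estimation_variant: AbsorptionVariant,
    fixed_disposition: ParameterSet,
    dose: float,
    n_retries: int = 10,
    seed: int = 0,
    initials: Mapping[str, float] | None = None,
) -> FitResult:
    """Least-squares fit of one absorption model to a rich plasma profile.

    Only the pulmonary parameters are estimated; the systemic disposition
    (and ``v_lung``) is fixed to ``fixed_disposition``.  The loss is the sum
    of squared log-concentration residuals — the noiseless analogue of a
    proportional error model.  The best of ``1 + n_retries`` starts is kept;
    retries perturb the initial values log-uniformly within a 10-fold range.
    If every start fails, a non-converged result is returned (not raised).
    """
    transform = ParameterTransform(PULMONARY_THETA[estimation_variant.name])
    t_obs, y_obs = _clean_observations(times, obs_plasma)
    if t_obs.size < transform.size:
        raise ConfigurationError("fewer usable observations than free parameters")
    log_y = np.log(y_obs)
    lo, hi = transform.bounds()

    init_values = dict(DEFAULT_INITIALS)
    if initials:
        init_values.update(initials)
    z0 = np.clip(transform.encode(init_values), lo, hi)

    def residuals(z: np.ndarray) -> np.ndarray:
        try:
            p = transform.apply(fixed_disposition, z)
            profile = solve_profiles(estimation_variant, p, dose, Route.INHALED, t_obs)
        except (ConfigurationError, FloatingPointError):
            return np.full_like(log_y, 1e6)
        pred = np.clip(profile.c_plasma, 1e-300, None)
        r = np.log(pred) - log_y
        return np.where(np.isfinite(r), r, 1e6)

    rng = np.random.default_rng(seed)
    best = None
    retries_used = 0
    for attempt in range(1 + n_retries):
        if attempt == 0:
            start = z0
        else:
            start = np.clip(z0 + rng.uniform(-math.log(10.0), math.log(10.0), transform.size), lo, hi)
        try:
            res = least_squares(residuals, start, bounds=(lo, hi), method="trf",
                                xtol=1e-12, ftol=1e-12, gtol=1e-12,
                                max_nfev=2000)
        except Exception:
            continue
        if not np.isfinite(res.cost):
            continue
        if best is None or res.cost < best.cost:
            best = res
            retries_used = attempt
    if best is None:
        return FitResult(
            variant=estimation_variant, strategy="naive",
            params=fixed_disposition, objective=math.inf, converged=False,
            n_retries_used=n_retries, param_labels=tuple(transform.labels),
            z=z0, n_estimated=transform.size,
        )
    params_hat = transform.apply(fixed_disposition, best.x).canonical(estimation_variant)
    return FitResult(
        variant=estimation_variant,
        strategy="naive",
        params=params_hat,
        objective=float(2.0 * best.cost),  # sum of squared residuals
        converged=bool(best.success),
        n_retries_used=retries_used,
        param_labels=tuple(transform.labels),
        z=best.x.copy(),
        n_estimated=transform.size,
        extra={
            "transform": transform,
            "dose": dose,
            "obs_times": t_obs,
            "obs_values": y_obs,
            "fixed_disposition": fixed_disposition,
        },
    )


def _residual_jacobian(fit: FitResult, rel_step: float = 1e-6) -> np.ndarray:
    """Central-difference Jacobian of the log-residuals at the optimum."""
    transform: ParameterTransform = fit.extra["transform"]
    t_obs = fit.extra["obs_times"]
    base = fit.extra["fixed_disposition"]
    dose = fit.extra["dose"]

    def predict_log(z: np.ndarray) -> np.ndarray:
        p = transform.apply(base, z)
        prof = solve_profiles(fit.variant, p, dose, Route.INHALED, t_obs)
        return np.log(np.clip(prof.c_plasma, 1e-300, None))

    z = fit.z
    J = np.empty((t_obs.size, transform.size))
    for j in range(transform.size):
        h = rel_step * max(1.0, abs(z[j]))
        zp, zm = z.copy(), z.copy()
        zp[j] += h
        zm[j] -= h
        J[:, j] = (predict_log(zp) - predict_log(zm)) / (2.0 * h)
    return J


def fisher_information(
    fit: FitResult,
    condition_limit: float = FIM_CONDITION_LIMIT,
    correlation_flag: float = CORRELATION_FLAG,
) -> IdentifiabilityVerdict:
    """Identifiability verdict from the FIM ``J^T J`` of a naive fit.

    ``J`` holds the sensitivities of the log-scale predictions with respect
    to the transformed parameters.  The verdict is *unidentifiable* when the
    FIM condition number exceeds ``condition_limit``, inversion fails, or a
    standard error is non-finite; parameter pairs whose estimated
    correlation exceeds ``correlation_flag`` in magnitude are reported
    (e.g. the structural ``f_pul``/``k_nal`` coupling of the NaL model).
    """
    if not fit.converged:
        return IdentifiabilityVerdict(False, math.inf, cause="fit did not converge")
    try:
        J = _residual_jacobian(fit)
    except Exception as exc:  # non-finite sensitivities
        return IdentifiabilityVerdict(False, math.inf, cause=f"Jacobian failure: {exc}")
    if not np.all(np.isfinite(J)):
        return IdentifiabilityVerdict(False, math.inf, cause="non-finite Jacobian")
    fim = J.T @ J
    cond = float(np.linalg.cond(fim))
    labels = fit.param_labels
    if not np.isfinite(cond) or cond > condition_limit:
        pairs = _correlated_pairs(fim, labels, correlation_flag)
        return IdentifiabilityVerdict(False, cond, pairs, cause="singular FIM")
    try:
        cov = np.linalg.inv(fim)
    except np.linalg.LinAlgError:
        return IdentifiabilityVerdict(False, cond, cause="FIM not invertible")
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    if not np.all(np.isfinite(se)) or np.any(np.diag(cov) < 0):
        return IdentifiabilityVerdict(False, cond, cause="non-finite standard errors")
    fit.se = {label: float(s) for label, s in zip(labels, se)}
    pairs = _correlated_pairs(fim, labels, correlation_flag)
    return IdentifiabilityVerdict(True, cond, pairs)


def _correlated_pairs(fim: np.ndarray, labels: Sequence[str], flag: float):
    # a tiny ridge keeps the near-null direction visible: for a structurally
    # degenerate pair the stabilised covariance shows |r| -> 1, which a
    # plain pseudo-inverse (nulling that direction) would hide
    pairs: list[tuple[str, str, float]] = []
    lam = 1e-10 * float(np.mean(np.diag(fim)) + 1e-300)
    try:
        cov = np.linalg.inv(fim + lam * np.eye(fim.shape[0]))
    except np.linalg.LinAlgError:  # pragma: no cover
        return pairs
    d = np.sqrt(np.clip(np.diag(cov), 1e-300, None))
    corr = cov / np.outer(d, d)
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            if abs(corr[i, j]) > flag:
                pairs.append((labels[i], labels[j], float(corr[i, j])))
    return pairs


def aic(fit: FitResult) -> float:
    """Akaike information criterion: -2 log-likelihood + 2 #parameters.

    For mixed-effects fits the objective already is the (approximate)
    -2 log-likelihood and the parameter count includes the estimated
    variance components.  Undefined for non-converged fits.
    """
    if not fit.converged:
        raise ValueError("AIC is undefined for a non-converged fit")
    return float(fit.objective + 2.0 * fit.n_estimated)
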