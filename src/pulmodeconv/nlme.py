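"""Nonlinear mixed-effects estimation (FOCE with interaction).

The population model is the standard pharmacometric one: individual
parameters are ``theta * exp(eta)`` with ``eta ~ N(0, Omega)`` (diagonal
Omega), inter-occasion variability adds per-occasion ``exp(kappa)`` factors,
and observations follow ``y = f(t) * (1 + eps)`` (proportional error; an
additive component is also supported).

The marginal likelihood is approximated by a Laplace expansion at the
per-subject conditional mode ``eta_hat`` with a Gauss-Newton Hessian whose
weights include the dependence of the residual variance on ``eta`` — the
"with interaction" term.  For a model linear in ``eta`` with additive error
the approximation is exact, which the test-suite exploits as an analytic
check.  Exact NONMEM numerics are not replicated; what is compared across
strategies are the recovered parameters and exposure metrics.

Three ways of combining i.v. and inhalation data are provided:

* ``PPP`` — sequential: population disposition parameters *and* their IIV
  variances are fixed to an i.v.-stage fit; individual disposition
  parameters may still vary within that fixed variability (their etas stay
  in the model).  Applicable whenever both datasets exist.
* ``IPP`` — sequential: each subject's disposition parameters are fixed to
  their i.v.-stage empirical Bayes estimates; requires i.v. and inhalation
  data from the same subjects (cross-over).
* ``ALL`` — simultaneous estimation of everything on the pooled dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .estimate import (
    DISPOSITION_THETA,
    PULMONARY_THETA,
    FitResult,
    IdentifiabilityVerdict,
    ParameterTransform,
)
from .models import (
    AbsorptionVariant,
    ConfigurationError,
    ParameterSet,
    Route,
    build_disposition_matrix,
    build_rate_matrix,
    solve_amounts,
)
from .simulate import PKDataset

__all__ = ["NlmeConfig", "fit_nlme", "fit_iv_stage", "Strategy"]

LOG2PI = math.log(2.0 * math.pi)
_VAR_FLOOR = 1e-30
_PRED_FLOOR = 1e-12


class Strategy:
    PPP = "PPP"
    IPP = "IPP"
    ALL = "ALL"


# --------------------------------------------------------------------------
# data marshalling


@dataclass
class _Occasion:
    route: Route
    occ: int
    doses: list[tuple[float, float]]
    times: np.ndarray
    y: np.ndarray


@dataclass
class _Subject:
    sid: int
    occasions: list[_Occasion]

    @property
    def n_obs(self) -> int:
        return sum(len(o.y) for o in self.occasions)


def _marshal(dataset: PKDataset) -> list[_Subject]:
    subjects = []
    for sid, sgrp in dataset.frame.groupby("ID", sort=True):
        occs = []
        for (route, occ), grp in sgrp.groupby(["ROUTE", "OCC"], sort=True):
            doses = [
                (float(r.TIME), float(r.AMT))
                for r in grp[grp["EVID"] == 1].itertuples()
            ]
            obs = grp[grp["EVID"] == 0]
            times = obs["TIME"].to_numpy(dtype=float)
            y = obs["DV"].to_numpy(dtype=float)
            if len(y):
                occs.append(_Occasion(Route(route), int(occ), doses, times, y))
        if occs:
            subjects.append(_Subject(int(sid), occs))
    return subjects


# --------------------------------------------------------------------------
# configuration


@dataclass
class NlmeConfig:
    """What to estimate and what to hold fixed in one NLME fit.

    ``theta`` lists the estimated population parameters; everything else
    stays at its value in ``base``.  ``eta``/``iov`` list the parameters
    carrying inter-individual / inter-occasion random effects; their
    variances are estimated unless listed in ``omega_fixed``.
    ``individual_overrides`` (IPP) pins named parameters per subject.
    """

    variant: AbsorptionVariant | None
    base: ParameterSet
    theta: tuple[str, ...]
    eta: tuple[str, ...] = ()
    iov: tuple[str, ...] = ()
    omega_init: Mapping[str, float] = field(default_factory=dict)
    omega_fixed: Mapping[str, float] = field(default_factory=dict)
    sigma_init: float = 0.15
    fix_sigma: bool = False
    error_model: str = "proportional"  # or "additive"
    individual_overrides: Mapping[int, Mapping[str, float]] | None = None
    strategy: str = "ALL"

    def __post_init__(self) -> None:
        if self.error_model not in ("proportional", "additive"):
            raise ConfigurationError(f"unknown error model {self.error_model!r}")
        overlap = set(self.eta) & set(self.iov)
        if overlap:
            raise ConfigurationError(f"parameters cannot carry both IIV and IOV here: {overlap}")
        for name in self.free_omega_names():
            if self.omega_init.get(name, 0.1) < 0:
                raise ConfigurationError(f"omega init for {name} must be >= 0")
        if self.sigma_init < 0:
            raise ConfigurationError("sigma must be >= 0")

    def free_omega_names(self) -> list[str]:
        return [n for n in (*self.eta, *self.iov) if n not in self.omega_fixed]

    @property
    def n_estimated(self) -> int:
        return len(self.theta) + len(self.free_omega_names()) + (0 if self.fix_sigma else 1)


_PULMONARY_PARAMS = {"f_pul", "f_slow", "f_med", "f_fast", "k_slow", "k_med",
                     "k_fast", "k_trans", "k_nal", "pf1", "pf2"}


# --------------------------------------------------------------------------
# the FOCE engine


class _FoceProblem:
    def __init__(self, cfg: NlmeConfig, subjects: list[_Subject]):
        self.cfg = cfg
        self.subjects = subjects
        self.transform = ParameterTransform(cfg.theta)
        self._warm: dict[int, np.ndarray] = {}
        #: inner Gauss-Newton budget; raised temporarily for the FD Hessian,
        #: whose curvature estimates need tighter conditional modes
        self.inner_max_iter = 15
        # per subject: random-effect layout [(name, occ_index or None), ...]
        self.layout: dict[int, list[tuple[str, int | None]]] = {}
        for s in subjects:
            entries: list[tuple[str, int | None]] = [(n, None) for n in cfg.eta]
            for n in cfg.iov:
                pulmonary = n in _PULMONARY_PARAMS
                for idx, occ in enumerate(s.occasions):
                    if pulmonary and occ.route is not Route.INHALED:
                        continue
                    entries.append((n, idx))
            self.layout[s.sid] = entries

    # -- parameter handling ------------------------------------------------

    def theta_params(self, z: np.ndarray) -> ParameterSet:
        return self.transform.apply(self.cfg.base, z)

    def subject_base(self, pop: ParameterSet, sid: int) -> ParameterSet:
        over = (self.cfg.individual_overrides or {}).get(sid)
        if over:
            return replace(pop, **dict(over))
        return pop

    def occasion_params(
        self, base: ParameterSet, subj: _Subject, re_vec: np.ndarray
    ) -> list[ParameterSet]:
        entries = self.layout[subj.sid]
        out = []
        for idx, occ in enumerate(subj.occasions):
            updates: dict[str, float] = {}
            for (name, occ_idx), value in zip(entries, re_vec):
                if occ_idx is not None and occ_idx != idx:
                    continue
                factor = math.exp(value)
                updates[name] = updates.get(name, getattr(base, name)) * factor
            if "f_pul" in updates:
                updates["f_pul"] = min(updates["f_pul"], 1.0)
            out.append(replace(base, **updates) if updates else base)
        return out

    def omega_matrix(self, subj: _Subject, omegas: Mapping[str, float]) -> np.ndarray:
        entries = self.layout[subj.sid]
        return np.diag([max(omegas[name], 1e-6) ** 2 for name, _ in entries])

    # -- model evaluation --------------------------------------------------

    def predict(self, subj: _Subject, params_per_occ: Sequence[ParameterSet]) -> np.ndarray:
        preds = []
        for occ, p in zip(subj.occasions, params_per_occ):
            if occ.route is Route.IV:
                system = build_disposition_matrix(p)
            else:
                system = build_rate_matrix(self.cfg.variant, p, Route.INHALED)
            amounts = solve_amounts(system, occ.doses, occ.times)
            preds.append(amounts[system.central_index] / p.v1)
        return np.concatenate(preds) if preds else np.empty(0)

    # -- inner problem -----------------------------------------------------

    def _inner_terms(self, f, y, sp2, sa2):
        f = np.clip(f, _PRED_FLOOR, None)
        V = np.clip(sp2 * f * f + sa2, _VAR_FLOOR, None)
        r = y - f
        return f, V, r

    def conditional_mode(
        self,
        subj: _Subject,
        base: ParameterSet,
        omega: np.ndarray,
        sp2: float,
        sa2: float,
        eta0: np.ndarray,
        max_iter: int = 15,
        max_step: float = 0.5,
    ) -> tuple[np.ndarray, float, np.ndarray]:
        """Gauss-Newton search for the conditional mode of one subject.

        Returns (eta_hat, G(eta_hat), H) where ``G`` is -2 log of the joint
        density and ``H`` the interaction-weighted Gauss-Newton Hessian of
        G/2 at the mode.
        """
        y = np.concatenate([o.y for o in subj.occasions])
        q = omega.shape[0]
        if q == 0:
            f = self.predict(subj, self.occasion_params(base, subj, np.empty(0)))
            f, V, r = self._inner_terms(f, y, sp2, sa2)
            G = float(np.sum(np.log(2 * np.pi * V) + r * r / V))
            return np.empty(0), G, np.empty((0, 0))

        omega_inv = np.linalg.inv(omega)
        sign, logdet_omega = np.linalg.slogdet(omega)

        def G_of(eta: np.ndarray) -> tuple[float, np.ndarray]:
            f = self.predict(subj, self.occasion_params(base, subj, eta))
            f, V, r = self._inner_terms(f, y, sp2, sa2)
            G = float(
                np.sum(np.log(2 * np.pi * V) + r * r / V)
                + q * LOG2PI + logdet_omega + eta @ omega_inv @ eta
            )
            return G, f

        eta = eta0.copy()
        G, f = G_of(eta)
        H = omega_inv.copy()
        step_h = 1e-4
        for it in range(max_iter):
            J = np.empty((len(y), q))
            for j in range(q):
                e = eta.copy()
                e[j] += step_h
                fj = self.predict(subj, self.occasion_params(base, subj, e))
                J[:, j] = (np.clip(fj, _PRED_FLOOR, None) - f) / step_h
            V = np.clip(sp2 * f * f + sa2, _VAR_FLOOR, None)
            r = y - f
            dV = 2.0 * sp2 * f
            gf = dV / V - r * r * dV / (V * V) - 2.0 * r / V
            grad = 0.5 * (J.T @ gf) + omega_inv @ eta
            W = 1.0 / V + 0.5 * (dV / V) ** 2
            H = (J * W[:, None]).T @ J + omega_inv
            try:
                delta = np.linalg.solve(H, -grad)
            except np.linalg.LinAlgError:
                delta = -grad
            if not np.all(np.isfinite(delta)):
                break
            # trust region: far from the mode the GN model overshoots badly
            # on these strongly nonlinear (exponential-in-eta) predictions
            biggest = np.max(np.abs(delta))
            if biggest > max_step:
                delta = delta * (max_step / biggest)
            alpha = 1.0
            improved = False
            for _ls in range(8):
                G_new, f_new = G_of(eta + alpha * delta)
                if G_new < G - 1e-12:
                    gain = G - G_new
                    eta = eta + alpha * delta
                    G, f = G_new, f_new
                    improved = True
                    break
                alpha *= 0.5
            if not improved:
                break
            if np.max(np.abs(alpha * delta)) < 1e-6 or gain < 1e-10:
                break
        # rebuild the curvature at the final mode with a fresh Jacobian so
        # the Laplace log-det term does not depend on the iteration history
        J = np.empty((len(y), q))
        for j in range(q):
            e = eta.copy()
            e[j] += step_h
            fj = self.predict(subj, self.occasion_params(base, subj, e))
            J[:, j] = (np.clip(fj, _PRED_FLOOR, None) - f) / step_h
        V = np.clip(sp2 * f * f + sa2, _VAR_FLOOR, None)
        dV = 2.0 * sp2 * f
        W = 1.0 / V + 0.5 * (dV / V) ** 2
        H = (J * W[:, None]).T @ J + omega_inv
        return eta, G, H

    # -- outer objective ---------------------------------------------------

    def unpack(self, x: np.ndarray):
        nt = self.transform.size
        z = x[:nt]
        free_omega = self.cfg.free_omega_names()
        omegas = dict(self.cfg.omega_fixed)
        for i, name in enumerate(free_omega):
            omegas[name] = math.exp(x[nt + i])
        if self.cfg.fix_sigma:
            sigma = self.cfg.sigma_init
        else:
            sigma = math.exp(x[nt + len(free_omega)])
        return z, omegas, sigma

    def pack_initial(self) -> np.ndarray:
        cfg = self.cfg
        z0 = self.transform.encode({n: getattr(cfg.base, n) for n in cfg.theta})
        parts = [z0]
        for name in cfg.free_omega_names():
            parts.append([math.log(max(cfg.omega_init.get(name, 0.2), 1e-3))])
        if not cfg.fix_sigma:
            parts.append([math.log(max(cfg.sigma_init, 1e-3))])
        return np.concatenate([np.atleast_1d(p) for p in parts])

    def per_subject_neg2ll(self, x: np.ndarray) -> np.ndarray:
        z, omegas, sigma = self.unpack(x)
        try:
            pop = self.theta_params(z)
        except ConfigurationError:
            return np.full(len(self.subjects), 1e10)
        if self.cfg.error_model == "proportional":
            sp2, sa2 = sigma * sigma, 0.0
        else:
            sp2, sa2 = 0.0, sigma * sigma
        out = np.empty(len(self.subjects))
        for i, subj in enumerate(self.subjects):
            base = self.subject_base(pop, subj.sid)
            omega = self.omega_matrix(subj, omegas)
            q = omega.shape[0]
            eta0 = self._warm.get(subj.sid, np.zeros(q))
            if eta0.shape[0] != q:  # layout changed
                eta0 = np.zeros(q)
            try:
                eta_hat, G, H = self.conditional_mode(
                    subj, base, omega, sp2, sa2, eta0,
                    max_iter=self.inner_max_iter,
                )
            except Exception:
                out[i] = 1e10
                continue
            self._warm[subj.sid] = eta_hat
            if q:
                sign, logdetH = np.linalg.slogdet(H)
                if sign <= 0:
                    out[i] = 1e10
                    continue
                out[i] = G - q * LOG2PI + logdetH
            else:
                out[i] = G
            if not np.isfinite(out[i]):
                out[i] = 1e10
        return out

    def _bounds_penalty(self, x: np.ndarray) -> float:
        """Soft box penalty on the packed outer vector.

        The likelihood is flat in directions like log-omega -> -inf (a
        variance component collapsing to zero), where an unpenalised
        simplex search crawls without ever meeting its tolerance.  A
        quadratic pull back into the plausible box leaves converged fits
        untouched and terminates the flat-direction wander.
        """
        lo_t, hi_t = self.transform.bounds()
        lo = list(lo_t)
        hi = list(hi_t)
        for _ in self.cfg.free_omega_names():
            lo.append(math.log(5e-3))
            hi.append(math.log(3.0))
        if not self.cfg.fix_sigma:
            lo.append(math.log(1e-3))
            hi.append(math.log(2.0))
        lo_a = np.asarray(lo)
        hi_a = np.asarray(hi)
        excess = np.maximum(lo_a - x, 0.0) + np.maximum(x - hi_a, 0.0)
        return 100.0 * float(excess @ excess)

    def objective(self, x: np.ndarray) -> float:
        return float(np.sum(self.per_subject_neg2ll(x))) + self._bounds_penalty(x)

    def ebes(self, x: np.ndarray) -> pd.DataFrame:
        z, omegas, sigma = self.unpack(x)
        pop = self.theta_params(z)
        sp2 = sigma * sigma if self.cfg.error_model == "proportional" else 0.0
        sa2 = sigma * sigma if self.cfg.error_model == "additive" else 0.0
        rows = []
        for subj in self.subjects:
            base = self.subject_base(pop, subj.sid)
            omega = self.omega_matrix(subj, omegas)
            eta_hat, _, _ = self.conditional_mode(
                subj, base, omega, sp2, sa2,
                self._warm.get(subj.sid, np.zeros(omega.shape[0])),
            )
            row: dict[str, float] = {"ID": subj.sid}
            for (name, occ_idx), value in zip(self.layout[subj.sid], eta_hat):
                key = f"eta_{name}" if occ_idx is None else f"kappa_{name}_occ{occ_idx + 1}"
                row[key] = value
            # individual parameter values (IIV only, occasion effects excluded)
            for name in self.cfg.eta:
                row[name] = getattr(base, name) * math.exp(row[f"eta_{name}"])
            rows.append(row)
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# public fitting API


def _hessian_se(problem: _FoceProblem, x: np.ndarray) -> tuple[dict[str, float] | None, float]:
    """Standard errors from a finite-difference Hessian of the -2LL.

    cov = 2 * H^{-1}; a non-positive-definite or ill-conditioned Hessian
    yields no standard errors, which downstream counts as an unsuccessful
    estimation (mirroring the non-estimable-covariance failure mode of
    standard NLME software).
    """
    p = len(x)
    h = np.array([0.02 * max(1.0, abs(v)) for v in x])
    problem.inner_max_iter = 40
    f0 = problem.objective(x)
    f_i = np.empty(p)
    for i in range(p):
        xi = x.copy()
        xi[i] += h[i]
        f_i[i] = problem.objective(xi)
    H = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            xij = x.copy()
            xij[i] += h[i]
            xij[j] += h[j]
            fij = problem.objective(xij)
            H[i, j] = H[j, i] = (fij - f_i[i] - f_i[j] + f0) / (h[i] * h[j])
    problem.inner_max_iter = 15
    if not np.all(np.isfinite(H)):
        return None, math.inf
    w, V = np.linalg.eigh(0.5 * (H + H.T))
    cond = float(abs(w).max() / max(abs(w).min(), 1e-300))
    if w.min() <= 1e-10 * max(abs(w).max(), 1e-300) or cond > 1e10:
        return None, cond
    cov = 2.0 * (V / w) @ V.T
    d = np.diag(cov)
    if np.any(d < 0) or not np.all(np.isfinite(d)):
        return None, cond
    labels = _outer_labels(problem)
    return {lab: float(s) for lab, s in zip(labels, np.sqrt(d))}, cond


def _outer_labels(problem: _FoceProblem) -> list[str]:
    labels = list(problem.transform.labels)
    labels += [f"log(omega_{n})" for n in problem.cfg.free_omega_names()]
    if not problem.cfg.fix_sigma:
        labels.append("log(sigma)")
    return labels


def fit_nlme_config(
    dataset: PKDataset,
    cfg: NlmeConfig,
    max_retries: int = 2,
    seed: int = 0,
    maxfev: int | None = None,
    compute_se: bool = True,
) -> FitResult:
    """Fit one NLME configuration by FOCE-I; retries perturb the initials.

    The outer optimisation is a Nelder-Mead search over the transformed
    population parameters, log-omegas and log-sigma; each evaluation solves
    every subject's conditional-mode problem (warm-started).  On failure,
    up to ``max_retries`` restarts draw multiplicative log-uniform [0.1, 10]
    perturbations of the initial values.
    """
    subjects = _marshal(dataset)
    if not subjects:
        raise ConfigurationError("dataset contains no usable observations")
    problem = _FoceProblem(cfg, subjects)
    x0 = problem.pack_initial()
    if maxfev is None:
        maxfev = max(400, 180 * len(x0))
    rng = np.random.default_rng(seed)

    nm_options = dict(xatol=5e-3, fatol=0.05, adaptive=True)

    def attempt_fit(start: np.ndarray, budget: int):
        """One Nelder-Mead attempt with a restart-stability convergence test.

        On flat likelihood surfaces (12-dimensional disposition stages with
        weakly identified deep compartments) the simplex keeps polishing the
        optimum without ever meeting its own tolerance; a short restart with
        a fresh simplex that fails to improve the objective by more than 1.0
        (-2LL units) is accepted as convergence.
        """
        res = minimize(problem.objective, start, method="Nelder-Mead",
                       options=dict(maxfev=budget, **nm_options))
        ok = bool(res.success) and np.isfinite(res.fun) and res.fun < 1e9
        if not ok and np.isfinite(res.fun) and res.fun < 1e9:
            res2 = minimize(problem.objective, res.x, method="Nelder-Mead",
                            options=dict(maxfev=max(250, budget // 8), **nm_options))
            res2.nfev += res.nfev
            if res2.fun <= res.fun and res.fun - res2.fun < 1.0:
                return res2, True
            if res2.fun < res.fun:
                return res2, bool(res2.success)
        return res, ok

    best = None
    best_ok = False
    retries_used = 0
    for attempt in range(1 + max_retries):
        start = x0 if attempt == 0 else x0 + rng.uniform(
            -math.log(10.0), math.log(10.0), len(x0)
        )
        problem._warm.clear()
        res, ok = attempt_fit(start, maxfev if attempt == 0 else max(400, maxfev // 2))
        if ok:
            best = res
            best_ok = True
            retries_used = attempt
            break
        if best is None or (np.isfinite(res.fun) and res.fun < best.fun):
            best = res
            retries_used = attempt

    converged = best_ok and np.isfinite(best.fun) and best.fun < 1e9
    z_hat, omegas, sigma = problem.unpack(best.x)
    params_hat = problem.theta_params(z_hat)
    if cfg.variant is not None:
        try:
            params_hat = params_hat.canonical(cfg.variant)
        except ConfigurationError:
            pass

    se = None
    verdict = None
    if converged and compute_se:
        se, cond = _hessian_se(problem, best.x)
        verdict = IdentifiabilityVerdict(
            identifiable=se is not None, fim_condition_number=cond,
            cause="" if se is not None else "non-finite standard errors",
        )
    ebes = problem.ebes(best.x) if converged else None

    return FitResult(
        variant=cfg.variant if cfg.variant is not None
        else AbsorptionVariant.from_name("I"),
        strategy=cfg.strategy,
        params=params_hat,
        objective=float(best.fun),
        converged=converged,
        n_retries_used=retries_used,
        param_labels=tuple(_outer_labels(problem)),
        z=best.x.copy(),
        n_estimated=cfg.n_estimated,
        se=se,
        omega={k: float(v) for k, v in omegas.items()},
        sigma=float(sigma),
        ebes=ebes,
        verdict=verdict,
        extra={"config": cfg, "n_subjects": len(subjects),
               "nfev": int(best.nfev)},
    )


def _disposition_names(params: ParameterSet) -> tuple[str, ...]:
    return tuple(n for n in DISPOSITION_THETA if getattr(params, n) is not None)


def fit_iv_stage(
    dataset: PKDataset,
    base_params: ParameterSet,
    iiv: Sequence[str],
    sigma_init: float = 0.15,
    max_retries: int = 2,
    seed: int = 0,
    omega_init: Mapping[str, float] | None = None,
    maxfev: int | None = None,
) -> FitResult:
    """Stage-1 fit of the systemic disposition model to i.v. data alone."""
    iv_data = dataset.subset(Route.IV.value)
    disp_iiv = tuple(n for n in iiv if n not in _PULMONARY_PARAMS)
    cfg = NlmeConfig(
        variant=None,
        base=base_params,
        theta=_disposition_names(base_params),
        eta=disp_iiv,
        omega_init=dict(omega_init or {n: 0.2 for n in disp_iiv}),
        sigma_init=sigma_init,
        strategy="iv-stage",
    )
    return fit_nlme_config(iv_data, cfg, max_retries=max_retries, seed=seed,
                           maxfev=maxfev)


def fit_nlme(
    dataset: PKDataset,
    estimation_variant: AbsorptionVariant,
    base_params: ParameterSet,
    strategy: str,
    iiv: Sequence[str],
    iov: Sequence[str] = (),
    prior: FitResult | None = None,
    sigma_init: float = 0.15,
    max_retries: int = 2,
    seed: int = 0,
    omega_init: Mapping[str, float] | None = None,
    maxfev: int | None = None,
) -> FitResult:
    """Fit a pulmonary absorption model to a population trial dataset.

    ``strategy`` is one of ``PPP``, ``IPP`` or ``ALL`` (see module
    docstring).  ``iiv``/``iov`` name the parameters carrying random
    effects; ``base_params`` provides the structural initial values (and
    the fixed disposition for the sequential strategies, via ``prior``).
    """
    strategy = strategy.upper()
    pulm_theta = PULMONARY_THETA[estimation_variant.name]
    omega_init = dict(omega_init or {})
    disp_iiv = tuple(n for n in iiv if n not in _PULMONARY_PARAMS)
    pulm_iiv = tuple(n for n in iiv if n in _PULMONARY_PARAMS)

    if strategy in (Strategy.PPP, Strategy.IPP):
        if prior is None or not prior.converged:
            raise ConfigurationError(
                f"{strategy} requires a converged i.v.-stage prior fit"
            )
        inh = dataset.subset(Route.INHALED.value)
        disp_updates = {
            n: getattr(prior.params, n) for n in _disposition_names(prior.params)
        }
        base = replace(base_params, **disp_updates)
        if strategy == Strategy.PPP:
            omega_fixed = {n: prior.omega.get(n, 0.0) for n in disp_iiv}
            cfg = NlmeConfig(
                variant=estimation_variant, base=base, theta=pulm_theta,
                eta=(*disp_iiv, *pulm_iiv), iov=tuple(iov),
                omega_init={**{n: 0.2 for n in (*pulm_iiv, *iov)}, **omega_init},
                omega_fixed=omega_fixed, sigma_init=sigma_init,
                strategy=Strategy.PPP,
            )
        else:  # IPP
            if prior.ebes is None:
                raise ConfigurationError("IPP requires EBEs from the i.v. stage")
            inh_ids = set(inh.subject_ids())
            ebe_ids = set(int(i) for i in prior.ebes["ID"])
            if not inh_ids <= ebe_ids:
                raise ConfigurationError(
                    "IPP is only applicable if i.v. and inhalation PK have been "
                    "measured in the same subjects (cross-over design); "
                    f"subjects without i.v. estimates: {sorted(inh_ids - ebe_ids)}"
                )
            disp_cols = [c for c in prior.ebes.columns if c in DISPOSITION_THETA]
            overrides = {
                int(r.ID): {c: float(getattr(r, c)) for c in disp_cols}
                for r in prior.ebes.itertuples()
            }
            cfg = NlmeConfig(
                variant=estimation_variant, base=base, theta=pulm_theta,
                eta=pulm_iiv, iov=tuple(iov),
                omega_init={**{n: 0.2 for n in (*pulm_iiv, *iov)}, **omega_init},
                sigma_init=sigma_init, individual_overrides=overrides,
                strategy=Strategy.IPP,
            )
        return fit_nlme_config(inh, cfg, max_retries=max_retries, seed=seed,
                               maxfev=maxfev)

    if strategy == Strategy.ALL:
        cfg = NlmeConfig(
            variant=estimation_variant, base=base_params,
            theta=(*_disposition_names(base_params), *pulm_theta),
            eta=(*disp_iiv, *pulm_iiv), iov=tuple(iov),
            omega_init={**{n: 0.2 for n in (*disp_iiv, *pulm_iiv, *iov)},
                        **omega_init},
            sigma_init=sigma_init, strategy=Strategy.ALL,
        )
        return fit_nlme_config(dataset, cfg, max_retries=max_retries, seed=seed,
                               maxfev=maxfev)

    raise ConfigurationError(f"unknown strategy {strategy!r}")
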