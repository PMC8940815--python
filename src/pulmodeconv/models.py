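"""Linear compartmental models for pulmonary absorption after oral inhalation.

The lung is represented by one or more well-stirred depot compartments from
which drug transfers into the central compartment of a mammillary systemic
disposition model (1-4 compartments).  Six absorption structures are
supported:

* ``I``       - a single first-order absorption process,
* ``II``      - two parallel first-order processes (fractions ``f_slow``/``f_fast``),
* ``IIIa``    - three parallel first-order processes,
* ``IIIb``    - the same three-process structure parameterised by the fastest
  rate and two proportionality factors (``k_med = PF1*k_fast``,
  ``k_slow = PF2*k_med``),
* ``Transit`` - a chain of transit compartments traversed at ``k_trans``,
* ``NaL``     - a single absorption process with a parallel non-absorptive
  first-order loss (mucociliary clearance / pulmonary metabolism) that never
  reaches plasma,

plus a simulation-only ``SemiMechanistic`` variant that adds back-flow from
the central compartment into the lung (drug re-distribution), used to probe
the one-directional-absorption assumption of the empirical models.

All systems are linear with constant coefficients, so profiles are obtained
from the matrix exponential (via eigendecomposition where well conditioned);
an adaptive ODE integrator is only used as an independent cross-check in the
test-suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import scipy.linalg

__all__ = [
    "ConfigurationError",
    "SolverError",
    "VariantName",
    "AbsorptionVariant",
    "ParameterSet",
    "LinearSystem",
    "ProfilePair",
    "build_rate_matrix",
    "solve_profiles",
    "solve_amounts",
    "analytic_auc",
    "slowest_half_life",
]

SIMPLEX_TOL = 1e-9


class ConfigurationError(ValueError):
    """A model/parameter combination that cannot be built."""


class SolverError(RuntimeError):
    """Numerical failure while solving a linear system."""


class VariantName(str, Enum):
    I = "I"
    II = "II"
    IIIA = "IIIa"
    IIIB = "IIIb"
    TRANSIT = "Transit"
    NAL = "NaL"
    SEMIMECH = "SemiMechanistic"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class AbsorptionVariant:
    """Structural description of one pulmonary absorption model."""

    name: VariantName
    n_lung_compartments: int
    has_nonabsorptive_loss: bool = False
    has_backflow: bool = False

    def __post_init__(self) -> None:
        if self.n_lung_compartments < 1:
            raise ConfigurationError("n_lung_compartments must be >= 1")
        if self.has_backflow and self.name is not VariantName.SEMIMECH:
            raise ConfigurationError(
                "only the SemiMechanistic variant permits back-flow"
            )
        expected = _EXPECTED_LUNG_CMTS.get(self.name)
        if expected is not None and self.n_lung_compartments != expected:
            raise ConfigurationError(
                f"variant {self.name} requires {expected} lung compartment(s), "
                f"got {self.n_lung_compartments}"
            )
        if self.name is VariantName.TRANSIT and self.n_lung_compartments < 2:
            raise ConfigurationError("Transit requires a chain of >= 2 compartments")

    @classmethod
    def from_name(cls, name: str | VariantName, n_transit: int = 3) -> "AbsorptionVariant":
        """Canonical structure for a variant name.

        ``n_transit`` sets the Transit chain length (default 3).
        """
        name = VariantName(name)
        if name is VariantName.TRANSIT:
            return cls(name, n_transit)
        if name is VariantName.NAL:
            return cls(name, 1, has_nonabsorptive_loss=True)
        if name is VariantName.SEMIMECH:
            return cls(name, 1, has_backflow=True)
        return cls(name, _EXPECTED_LUNG_CMTS[name])


_EXPECTED_LUNG_CMTS = {
    VariantName.I: 1,
    VariantName.II: 2,
    VariantName.IIIA: 3,
    VariantName.IIIB: 3,
    VariantName.NAL: 1,
    VariantName.SEMIMECH: 1,
}

#: absorption-process parameter names per variant, ordered fast -> slow
_PROCESS_PARAMS = {
    VariantName.I: [("k_fast", None)],
    VariantName.II: [("k_fast", "f_fast"), ("k_slow", "f_slow")],
    VariantName.IIIA: [("k_fast", "f_fast"), ("k_med", "f_med"), ("k_slow", "f_slow")],
}


@dataclass
class ParameterSet:
    """Numeric values for one model: disposition, lung and dose-fraction terms.

    Rates are in 1/h, volumes in L, clearances in L/h.  ``f_pul`` is the
    pulmonary bioavailability (designated lung dose as a fraction of the
    inhaled dose); the absorbed-fraction terms ``f_slow``/``f_med``/``f_fast``
    partition the lung dose across parallel processes and must sum to one.
    ``v_lung`` (default 0.84 L) converts unabsorbed pulmonary amounts to a
    lung concentration.
    """

    cl: float
    v1: float
    q2: float | None = None
    v2: float | None = None
    q3: float | None = None
    v3: float | None = None
    q4: float | None = None
    v4: float | None = None
    f_pul: float = 1.0
    f_slow: float | None = None
    f_med: float | None = None
    f_fast: float | None = None
    k_slow: float | None = None
    k_med: float | None = None
    k_fast: float | None = None
    k_trans: float | None = None
    k_nal: float | None = None
    k_back: float | None = None
    pf1: float | None = None
    pf2: float | None = None
    v_lung: float = 0.84

    def __post_init__(self) -> None:
        for name in ("cl", "v1", "v_lung"):
            value = getattr(self, name)
            if not (value > 0):
                raise ConfigurationError(f"{name} must be strictly positive, got {value}")
        for name in ("q2", "v2", "q3", "v3", "q4", "v4", "k_slow", "k_med",
                     "k_fast", "k_trans", "k_nal", "k_back", "pf1", "pf2"):
            value = getattr(self, name)
            if value is not None and not (value > 0):
                raise ConfigurationError(f"{name} must be strictly positive, got {value}")
        if not (0.0 < self.f_pul <= 1.0):
            raise ConfigurationError(f"f_pul must lie in (0, 1], got {self.f_pul}")
        for name in ("f_slow", "f_med", "f_fast"):
            value = getattr(self, name)
            if value is not None and not (0.0 <= value <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1], got {value}")
        for qname, vname in (("q2", "v2"), ("q3", "v3"), ("q4", "v4")):
            if (getattr(self, qname) is None) != (getattr(self, vname) is None):
                raise ConfigurationError(f"{qname} and {vname} must be given together")
        if self.q3 is not None and self.q2 is None:
            raise ConfigurationError("q3/v3 require q2/v2")
        if self.q4 is not None and self.q3 is None:
            raise ConfigurationError("q4/v4 require q3/v3")

    # -- structure queries -------------------------------------------------

    @property
    def n_disposition_compartments(self) -> int:
        return 1 + sum(getattr(self, q) is not None for q in ("q2", "q3", "q4"))

    def peripheral(self) -> list[tuple[float, float]]:
        """(Q, V) pairs of the peripheral disposition compartments."""
        out = []
        for qname, vname in (("q2", "v2"), ("q3", "v3"), ("q4", "v4")):
            q = getattr(self, qname)
            if q is not None:
                out.append((q, getattr(self, vname)))
        return out

    # -- canonical form ----------------------------------------------------

    def resolved_processes(self, variant: AbsorptionVariant) -> list[tuple[float, float]]:
        """Parallel-process (rate, fraction) pairs for this variant.

        Model I and NaL carry a single process with implicit fraction 1;
        IIIb rates are expanded from (k_fast, PF1, PF2).  The returned list
        is sorted fastest-first.
        """
        name = variant.name
        if name in (VariantName.I, VariantName.NAL, VariantName.SEMIMECH):
            self._require(name, "k_fast")
            return [(self.k_fast, 1.0)]
        if name is VariantName.TRANSIT:
            raise ConfigurationError("Transit has no parallel processes")
        if name is VariantName.IIIB:
            for p in ("k_fast", "pf1", "pf2", "f_slow", "f_med", "f_fast"):
                self._require(name, p)
            k_med = self.pf1 * self.k_fast
            k_slow = self.pf2 * k_med
            pairs = [(self.k_fast, self.f_fast), (k_med, self.f_med), (k_slow, self.f_slow)]
        else:
            pairs = []
            for kname, fname in _PROCESS_PARAMS[name]:
                self._require(name, kname)
                self._require(name, fname)
                pairs.append((getattr(self, kname), getattr(self, fname)))
        total = sum(f for _, f in pairs)
        if abs(total - 1.0) > SIMPLEX_TOL:
            raise ConfigurationError(
                f"absorbed fractions must sum to 1 (got {total!r}) for variant {name}"
            )
        return sorted(pairs, key=lambda kf: -kf[0])

    def canonical(self, variant: AbsorptionVariant) -> "ParameterSet":
        """Return a copy with (rate, fraction) pairs in fast > med > slow order.

        Any permutation of the parallel-process labels maps to the same
        canonical set, removing label-switching ambiguity; IIIb sets are
        expanded to explicit rate constants.
        """
        name = variant.name
        if name in (VariantName.TRANSIT,):
            self._require(name, "k_trans")
            return replace(self)
        pairs = self.resolved_processes(variant)
        updates: dict[str, float | None] = {"pf1": None, "pf2": None}
        slots = [("k_fast", "f_fast"), ("k_med", "f_med"), ("k_slow", "f_slow")]
        if len(pairs) == 1:
            updates.update(k_fast=pairs[0][0], k_med=None, k_slow=None,
                           f_fast=None, f_med=None, f_slow=None)
        elif len(pairs) == 2:
            updates.update(k_fast=pairs[0][0], f_fast=pairs[0][1],
                           k_slow=pairs[1][0], f_slow=pairs[1][1],
                           k_med=None, f_med=None)
        else:
            for (kname, fname), (k, f) in zip(slots, pairs):
                updates[kname] = k
                updates[fname] = f
        if name is VariantName.NAL:
            self._require(name, "k_nal")
        return replace(self, **updates)

    def _require(self, variant_name: VariantName, param: str) -> None:
        if getattr(self, param) is None:
            raise ConfigurationError(
                f"parameter '{param}' is required for variant {variant_name} but missing"
            )

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)
                if getattr(self, f.name) is not None}


class Route(str, Enum):
    IV = "iv"
    INHALED = "inhaled"


@dataclass(frozen=True)
class LinearSystem:
    """A built first-order system: x'(t) = A x(t), dose enters along ``dose_in``.

    Sink states (systemic elimination, non-absorptive loss) are carried
    explicitly so that the total state sums to the administered dose at all
    times (mass balance).  ``dose_in`` already accounts for the discarded
    ``1 - f_pul`` fraction of an inhaled dose, so its entries may sum to < 1.
    """

    matrix: np.ndarray
    dose_in: np.ndarray
    labels: tuple[str, ...]
    lung_indices: tuple[int, ...]
    central_index: int
    sink_indices: tuple[int, ...]
    v1: float
    v_lung: float

    @property
    def n_states(self) -> int:
        return self.matrix.shape[0]


@dataclass
class ProfilePair:
    """Matched plasma and lung concentration-time profiles."""

    times: np.ndarray
    c_plasma: np.ndarray
    c_lung: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.c_plasma = np.asarray(self.c_plasma, dtype=float)
        self.c_lung = np.asarray(self.c_lung, dtype=float)
        if not (self.times.shape == self.c_plasma.shape == self.c_lung.shape):
            raise ValueError("times, c_plasma and c_lung must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_h": self.times, "c_plasma": self.c_plasma, "c_lung": self.c_lung}
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_rate_matrix(
    variant: AbsorptionVariant,
    params: ParameterSet,
    route: Route | str,
) -> LinearSystem:
    """Assemble the rate matrix and unit-dose entry vector for one model.

    State ordering: lung compartments, central, peripheral disposition
    compartments, elimination sink, and (NaL only) the non-absorptive loss
    sink.  Off-diagonal entries are non-negative first-order rate constants;
    each column sums to zero, so total mass (including sinks) is conserved.
    """
    route = Route(route)
    if variant.name is VariantName.TRANSIT:
        params._require(variant.name, "k_trans")
    else:
        params.resolved_processes(variant)  # validates presence + simplex
    if variant.has_nonabsorptive_loss:
        params._require(variant.name, "k_nal")
    if variant.has_backflow:
        params._require(variant.name, "k_back")

    m = variant.n_lung_compartments
    periph = params.peripheral()
    n_disp = 1 + len(periph)
    n_sinks = 2 if variant.has_nonabsorptive_loss else 1
    n = m + n_disp + n_sinks

    labels = [f"lung_{i + 1}" for i in range(m)] + ["central"]
    labels += [f"periph_{j + 2}" for j in range(len(periph))]
    labels += ["eliminated"]
    if variant.has_nonabsorptive_loss:
        labels += ["lost"]

    central = m
    elim = m + n_disp
    loss = elim + 1 if variant.has_nonabsorptive_loss else None

    A = np.zeros((n, n))

    def flow(src: int, dst: int, rate: float) -> None:
        A[dst, src] += rate
        A[src, src] -= rate

    # systemic disposition
    flow(central, elim, params.cl / params.v1)
    for j, (q, v) in enumerate(periph):
        p = central + 1 + j
        flow(central, p, q / params.v1)
        flow(p, central, q / v)

    # pulmonary absorption
    dose_in = np.zeros(n)
    if variant.name is VariantName.TRANSIT:
        for i in range(m - 1):
            flow(i, i + 1, params.k_trans)
        flow(m - 1, central, params.k_trans)
        if route is Route.INHALED:
            dose_in[0] = params.f_pul
    else:
        pairs = params.resolved_processes(variant)
        if len(pairs) != m:
            raise ConfigurationError(
                f"variant {variant.name} defines {m} lung compartment(s) but "
                f"{len(pairs)} absorption process(es) were resolved"
            )
        for i, (k, f) in enumerate(pairs):
            flow(i, central, k)
            if variant.has_nonabsorptive_loss:
                flow(i, loss, params.k_nal)
            if route is Route.INHALED:
                dose_in[i] = params.f_pul * f
        if variant.has_backflow:
            flow(central, 0, params.k_back)

    if route is Route.IV:
        dose_in[central] = 1.0

    sinks = (elim,) if loss is None else (elim, loss)
    return LinearSystem(
        matrix=A,
        dose_in=dose_in,
        labels=tuple(labels),
        lung_indices=tuple(range(m)),
        central_index=central,
        sink_indices=sinks,
        v1=params.v1,
        v_lung=params.v_lung,
    )


def build_disposition_matrix(params: ParameterSet) -> LinearSystem:
    """Systemic disposition only (i.v. dosing): no lung states.

    Used when fitting i.v. data, where the absorption model is irrelevant.
    """
    periph = params.peripheral()
    n = 1 + len(periph) + 1  # central + peripherals + elimination sink
    A = np.zeros((n, n))
    elim = n - 1
    A[elim, 0] += params.cl / params.v1
    A[0, 0] -= params.cl / params.v1
    for j, (q, v) in enumerate(periph):
        p = 1 + j
        A[p, 0] += q / params.v1
        A[0, 0] -= q / params.v1
        A[0, p] += q / v
        A[p, p] -= q / v
    dose_in = np.zeros(n)
    dose_in[0] = 1.0
    labels = ["central"] + [f"periph_{j + 2}" for j in range(len(periph))] + ["eliminated"]
    return LinearSystem(
        matrix=A, dose_in=dose_in, labels=tuple(labels), lung_indices=(),
        central_index=0, sink_indices=(elim,), v1=params.v1, v_lung=params.v_lung,
    )


# --------------------------------------------------------------------------
# propagation


def _propagator(A: np.ndarray):
    """Return amounts(t) = exp(A t) x0 evaluated at many times.

    Uses the eigendecomposition when it is well conditioned (the generic
    case: distinct eigenvalues), falling back to per-interval matrix
    exponentials for defective matrices (e.g. exactly tied rate constants).
    """
    n = A.shape[0]
    ok = False
    try:
        w, V = np.linalg.eig(A)
        Vinv = np.linalg.inv(V)
        # cheap accuracy check: a defective/near-defective matrix fails to
        # reconstruct (Transit chains have tied eigenvalues, for instance)
        err = np.max(np.abs((V * w) @ Vinv - A).real)
        ok = np.isfinite(err) and err <= 1e-8 * (1.0 + np.max(np.abs(A)))
    except np.linalg.LinAlgError:  # pragma: no cover - eig rarely fails
        ok = False
    if ok:

        def run(x0: np.ndarray, times: np.ndarray) -> np.ndarray:
            c = Vinv @ x0
            modes = c[:, None] * np.exp(np.outer(w, times))
            out = (V @ modes).real
            return out

        return run

    def run_expm(x0: np.ndarray, times: np.ndarray) -> np.ndarray:
        out = np.empty((n, len(times)))
        x = x0
        t_prev = 0.0
        cache: dict[float, np.ndarray] = {}
        for i, t in enumerate(times):
            dt = t - t_prev
            if dt != 0.0:
                P = cache.get(dt)
                if P is None:
                    P = scipy.linalg.expm(A * dt)
                    cache[dt] = P
                x = P @ x
            out[:, i] = x
            t_prev = t
        return out

    return run_expm


def solve_amounts(
    system: LinearSystem,
    doses: Sequence[tuple[float, float]],
    times: np.ndarray,
) -> np.ndarray:
    """Amounts in every state at ``times`` for doses (time, amount).

    Supports multiple (super-posed) doses through the system's linearity:
    the state is propagated piecewise between dose events.  ``times`` must be
    non-negative and non-decreasing.
    """
    times = np.asarray(times, dtype=float)
    if times.size and (times[0] < 0 or np.any(np.diff(times) < 0)):
        raise ValueError("times must be non-negative and non-decreasing")
    run = _propagator(system.matrix)
    out = np.zeros((system.n_states, times.size))
    for t_dose, amount in doses:
        if amount < 0:
            raise ConfigurationError("dose amounts must be non-negative")
        mask = times >= t_dose
        if not mask.any():
            continue
        x0 = amount * system.dose_in
        contrib = run(x0, times[mask] - t_dose)
        out[:, mask] += contrib
    if not np.all(np.isfinite(out)):
        raise SolverError("non-finite amounts encountered during propagation")
    return out


def amounts_to_profile(system: LinearSystem, times: np.ndarray, amounts: np.ndarray) -> ProfilePair:
    c_plasma = amounts[system.central_index] / system.v1
    c_lung = amounts[list(system.lung_indices)].sum(axis=0) / system.v_lung
    # clip tiny negative round-off from the eigen route
    return ProfilePair(times, np.clip(c_plasma, 0.0, None), np.clip(c_lung, 0.0, None))


def solve_profiles(
    variant: AbsorptionVariant,
    params: ParameterSet,
    dose: float,
    route: Route | str,
    times: Iterable[float],
) -> ProfilePair:
    """Plasma and lung concentration-time profiles for a single bolus dose.

    The lung concentration is the total unabsorbed amount across all
    pulmonary compartments (the loss sink excluded) divided by ``v_lung``;
    plasma is the central amount divided by ``v1``.
    """
    times = np.asarray(list(times), dtype=float)
    system = build_rate_matrix(variant, params, route)
    amounts = solve_amounts(system, [(0.0, dose)], times)
    return amounts_to_profile(system, times, amounts)


# --------------------------------------------------------------------------
# exposure


def analytic_auc(
    variant: AbsorptionVariant,
    params: ParameterSet,
    dose: float,
    route: Route | str,
    target: str = "plasma",
) -> float:
    """Closed-form AUC(0-inf) for plasma or lung.

    Plasma: ``dose * F / CL`` with ``F = f_pul`` after inhalation and 1 after
    i.v. dosing.  Lung (inhaled, one-directional absorption only): each
    parallel depot contributes ``f_i / (k_i + k_nal)`` and each transit
    compartment ``1 / k_trans``, scaled by ``dose * f_pul / v_lung``.
    """
    route = Route(route)
    if target == "plasma":
        if variant.has_backflow and route is Route.INHALED:
            # back-flow returns drug to the lung but it is eventually
            # re-absorbed; total systemic exposure is unchanged for a system
            # whose only exit is systemic elimination.
            pass
        f_sys = params.f_pul if route is Route.INHALED else 1.0
        if variant.has_nonabsorptive_loss and route is Route.INHALED:
            pairs = params.resolved_processes(variant)
            reaching = sum(f * k / (k + params.k_nal) for k, f in pairs)
            f_sys = params.f_pul * reaching
        return dose * f_sys / params.cl
    if target != "lung":
        raise ValueError(f"unknown AUC target {target!r}")
    if variant.has_backflow:
        raise ConfigurationError(
            "analytic lung AUC is unsupported for back-flow models; integrate numerically"
        )
    if route is Route.IV:
        return 0.0
    if variant.name is VariantName.TRANSIT:
        params._require(variant.name, "k_trans")
        residence = variant.n_lung_compartments / params.k_trans
        return dose * params.f_pul * residence / params.v_lung
    pairs = params.resolved_processes(variant)
    loss = params.k_nal if variant.has_nonabsorptive_loss else 0.0
    if variant.has_nonabsorptive_loss:
        params._require(variant.name, "k_nal")
    residence = sum(f / (k + loss) for k, f in pairs)
    return dose * params.f_pul * residence / params.v_lung


def slowest_half_life(variant: AbsorptionVariant, params: ParameterSet) -> float:
    """Half-life of the slowest kinetic mode (absorption and disposition).

    Computed from the non-zero eigenvalues of the transient part of the rate
    matrix; used to pick integration horizons and the search window for
    retention metrics.
    """
    system = build_rate_matrix(variant, params, Route.INHALED)
    keep = [i for i in range(system.n_states) if i not in system.sink_indices]
    sub = system.matrix[np.ix_(keep, keep)]
    w = np.linalg.eigvals(sub)
    rates = -w.real
    rates = rates[rates > 1e-12]
    if rates.size == 0:
        raise SolverError("system has no decaying mode")
    return math.log(2.0) / rates.min()
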