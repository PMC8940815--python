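"""Synthetic study generation: rich noiseless profiles and population trials.

Two kinds of input are produced for the simulation-estimation experiments:

* *rich* profiles — noiseless plasma and lung concentrations sampled every
  0.01 h over 48 h, used for the structural-identifiability screen;
* *trial* datasets — sparse, per-subject observations with log-normal
  inter-individual (IIV) and inter-occasion (IOV) variability on selected
  parameters and proportional residual error, emulating published inhaled /
  i.v. study designs, written in a NONMEM-style rectangular CSV layout.

Occasions are treated as pharmacokinetically independent (complete washout;
the within-occasion clock restarts at zero); multiple doses within one
occasion superpose through the linearity of the models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .models import (
    AbsorptionVariant,
    ConfigurationError,
    ParameterSet,
    ProfilePair,
    Route,
    amounts_to_profile,
    build_disposition_matrix,
    build_rate_matrix,
    solve_amounts,
    solve_profiles,
)

__all__ = [
    "Occasion",
    "StudyArm",
    "TrialDesign",
    "VariabilityModel",
    "PKDataset",
    "DEFAULT_SAMPLING",
    "single_dose_occasion",
    "simulate_rich",
    "simulate_trial",
    "write_dataset",
    "read_dataset",
]

DATASET_COLUMNS = ["ID", "TIME", "AMT", "DV", "EVID", "CMT", "OCC", "ROUTE"]

#: CMT coding in datasets: 1 = dosing entry (lung depot(s) after inhalation,
#: central vein after i.v.), 2 = plasma observation.
CMT_DOSE = 1
CMT_PLASMA_OBS = 2

MAX_RANDOM_EFFECT_TERMS = 4


@dataclass(frozen=True)
class Occasion:
    """One dosing occasion: dose events and a sampling schedule (hours)."""

    doses: tuple[tuple[float, float], ...]  # (time, amount)
    sampling_times: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.doses:
            raise ConfigurationError("an occasion needs at least one dose event")
        for t, amt in self.doses:
            if t < 0 or amt <= 0:
                raise ConfigurationError(f"invalid dose event ({t}, {amt})")
        times = np.asarray(self.sampling_times, dtype=float)
        if times.size == 0:
            raise ConfigurationError("an occasion needs at least one sampling time")
        if np.any(np.diff(times) <= 0) or times[0] < 0:
            raise ConfigurationError("sampling times must be non-negative and increasing")
        first_dose = min(t for t, _ in self.doses)
        if times[0] < first_dose:
            raise ConfigurationError("samples before the first dose are not supported")


#: default rich-yet-plausible clinical sampling schedule (hours post dose)
DEFAULT_SAMPLING = (0.083, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0, 36.0, 48.0)


def single_dose_occasion(amount: float, sampling: Sequence[float] = DEFAULT_SAMPLING) -> Occasion:
    return Occasion(doses=((0.0, amount),), sampling_times=tuple(sampling))


@dataclass(frozen=True)
class StudyArm:
    """One treatment arm: route, per-occasion dosing/sampling, subject count."""

    route: Route
    n_subjects: int
    occasions: tuple[Occasion, ...]

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if not self.occasions:
            raise ConfigurationError("an arm needs at least one occasion")

    @property
    def n_occasions(self) -> int:
        return len(self.occasions)


@dataclass(frozen=True)
class TrialDesign:
    """A complete trial: one or more arms, optionally cross-over.

    With ``crossover=True`` every arm must enrol the same number of subjects
    and the same individuals (identical IDs, shared random effects) receive
    every arm — the classic i.v./inhalation cross-over.  Otherwise arms
    enrol disjoint subjects.
    """

    arms: tuple[StudyArm, ...]
    crossover: bool = False

    def __post_init__(self) -> None:
        if not self.arms:
            raise ConfigurationError("a design needs at least one arm")
        if self.crossover:
            counts = {arm.n_subjects for arm in self.arms}
            if len(counts) != 1:
                raise ConfigurationError(
                    "crossover designs require equal n_subjects in every arm"
                )

    @property
    def n_subjects_total(self) -> int:
        if self.crossover:
            return self.arms[0].n_subjects
        return sum(arm.n_subjects for arm in self.arms)


@dataclass(frozen=True)
class VariabilityModel:
    """Stochastic model: log-normal IIV/IOV and proportional residual error.

    ``iiv`` and ``iov`` map parameter names to log-normal standard
    deviations (omega).  At most four IIV and/or IOV terms are allowed in
    total — the deliberately simplified stochastic model used throughout the
    simulation studies.  The residual model is proportional with standard
    deviation ``residual_proportional_sd``.
    """

    iiv: Mapping[str, float] = field(default_factory=dict)
    iov: Mapping[str, float] = field(default_factory=dict)
    residual_proportional_sd: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "iiv", dict(self.iiv))
        object.__setattr__(self, "iov", dict(self.iov))
        for name, sd in list(self.iiv.items()) + list(self.iov.items()):
            if sd < 0:
                raise ConfigurationError(f"omega for {name!r} must be >= 0, got {sd}")
        if self.residual_proportional_sd < 0:
            raise ConfigurationError("residual_proportional_sd must be >= 0")
        n_terms = len(self.iiv) + len(self.iov)
        if n_terms > MAX_RANDOM_EFFECT_TERMS:
            raise ConfigurationError(
                f"at most {MAX_RANDOM_EFFECT_TERMS} IIV/IOV terms are supported, got {n_terms}"
            )

    @staticmethod
    def none() -> "VariabilityModel":
        return VariabilityModel()


class PKDataset:
    """Long-format dose/observation records for one simulated study.

    Thin wrapper around a pandas DataFrame with the NONMEM-style columns
    ID, TIME, AMT, DV, EVID, CMT, OCC, ROUTE.  Observation rows (EVID=0)
    carry a positive DV; dose rows (EVID=1) carry AMT and no DV.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in DATASET_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"dataset missing columns: {missing}")
        self.frame = frame.reset_index(drop=True)[DATASET_COLUMNS]
        self._validate()

    def _validate(self) -> None:
        df = self.frame
        obs = df[df["EVID"] == 0]
        if (obs["DV"] <= 0).any():
            raise ValueError("observations must be strictly positive (no BLQ handling)")
        for (sid, route, occ), grp in df.groupby(["ID", "ROUTE", "OCC"], sort=False):
            t = grp["TIME"].to_numpy(dtype=float)
            if np.any(np.diff(t) < 0):
                raise ValueError(
                    f"TIME not monotone within ID={sid} ROUTE={route} OCC={occ}"
                )
            first_obs = grp[grp["EVID"] == 0]["TIME"].min()
            first_dose = grp[grp["EVID"] == 1]["TIME"].min()
            if pd.notna(first_obs) and (pd.isna(first_dose) or first_dose > first_obs):
                raise ValueError(
                    f"observation precedes any dose for ID={sid} ROUTE={route} OCC={occ}"
                )

    # -- convenience views -------------------------------------------------

    def observations(self) -> pd.DataFrame:
        return self.frame[self.frame["EVID"] == 0]

    def doses(self) -> pd.DataFrame:
        return self.frame[self.frame["EVID"] == 1]

    def subject_ids(self, route: str | None = None) -> list[int]:
        df = self.frame if route is None else self.frame[self.frame["ROUTE"] == route]
        return sorted(df["ID"].unique().tolist())

    def subset(self, route: str) -> "PKDataset":
        return PKDataset(self.frame[self.frame["ROUTE"] == route].copy())

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PKDataset):
            return NotImplemented
        return self.frame.equals(other.frame)


# --------------------------------------------------------------------------
# simulation


def simulate_rich(
    variant: AbsorptionVariant,
    params: ParameterSet,
    dose: float,
    route: Route | str = Route.INHALED,
    horizon_h: float = 48.0,
    dt_h: float = 0.01,
) -> ProfilePair:
    """Noiseless plasma/lung profiles on a dense uniform grid.

    Defaults give 4801 points over 48 h (observations every 0.01 h), the
    rich design that removes sampling-sparsity effects from the structural
    identifiability screen.  Fully deterministic.
    """
    n_steps = horizon_h / dt_h
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ConfigurationError("dt_h must divide horizon_h")
    times = np.linspace(0.0, horizon_h, int(round(n_steps)) + 1)
    return solve_profiles(variant, params, dose, route, times)


def _individual_params(
    base: ParameterSet,
    eta: Mapping[str, float],
    kappa: Mapping[str, float],
) -> ParameterSet:
    updates: dict[str, float] = {}
    for name, e in eta.items():
        updates[name] = getattr(base, name) * math.exp(e)
    for name, k in kappa.items():
        updates[name] = updates.get(name, getattr(base, name)) * math.exp(k)
    if "f_pul" in updates:
        updates["f_pul"] = min(updates["f_pul"], 1.0)
    from dataclasses import replace

    return replace(base, **updates)


def simulate_trial(
    variant: AbsorptionVariant,
    params: ParameterSet,
    design: TrialDesign,
    variability: VariabilityModel,
    seed: int,
    first_subject_id: int = 1,
) -> tuple[PKDataset, pd.DataFrame]:
    """Simulate a population trial; returns the dataset and the truth table.

    Per subject, parameters are drawn as ``theta * exp(eta)`` with
    ``eta ~ N(0, omega^2)``; IOV parameters get an additional per-occasion
    ``exp(kappa)`` factor.  Observations are ``f(t) * (1 + eps)`` with
    proportional ``eps``; draws that would produce non-positive
    concentrations are redrawn.  Sampling times at which the model predicts
    a zero concentration (e.g. plasma at t=0 after inhalation) are dropped.

    The truth table lists each subject's realised parameters per occasion —
    the reference for recovery checks.  Reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    records: list[dict] = []
    truth_rows: list[dict] = []

    if design.crossover:
        n = design.arms[0].n_subjects
        subject_sets = [[first_subject_id + i for i in range(n)]] * len(design.arms)
        eta_per_subject = {
            sid: {p: rng.normal(0.0, w) for p, w in variability.iiv.items()}
            for sid in subject_sets[0]
        }
    else:
        subject_sets = []
        next_id = first_subject_id
        eta_per_subject = {}
        for arm in design.arms:
            ids = [next_id + i for i in range(arm.n_subjects)]
            next_id += arm.n_subjects
            subject_sets.append(ids)
            for sid in ids:
                eta_per_subject[sid] = {
                    p: rng.normal(0.0, w) for p, w in variability.iiv.items()
                }

    sigma = variability.residual_proportional_sd
    for arm, ids in zip(design.arms, subject_sets):
        for sid in ids:
            eta = eta_per_subject[sid]
            for occ_idx, occasion in enumerate(arm.occasions, start=1):
                kappa = {p: rng.normal(0.0, w) for p, w in variability.iov.items()}
                p_ind = _individual_params(params, eta, kappa)
                if arm.route is Route.IV and not variant.has_backflow:
                    # i.v. dosing never reaches the lung in one-directional
                    # models; the absorption parameters need not be present
                    system = build_disposition_matrix(p_ind)
                else:
                    system = build_rate_matrix(variant, p_ind, arm.route)
                times = np.asarray(occasion.sampling_times, dtype=float)
                amounts = solve_amounts(system, occasion.doses, times)
                profile = amounts_to_profile(system, times, amounts)
                truth_rows.append(
                    {"ID": sid, "ROUTE": arm.route.value, "OCC": occ_idx,
                     **{k: getattr(p_ind, k) for k in p_ind.to_dict()}}
                )
                for t_dose, amt in occasion.doses:
                    records.append(
                        {"ID": sid, "TIME": t_dose, "AMT": amt, "DV": np.nan,
                         "EVID": 1, "CMT": CMT_DOSE, "OCC": occ_idx,
                         "ROUTE": arm.route.value}
                    )
                for t, f in zip(times, profile.c_plasma):
                    if f <= 0.0:
                        continue
                    if sigma > 0:
                        dv = -1.0
                        while dv <= 0.0:
                            dv = f * (1.0 + rng.normal(0.0, sigma))
                    else:
                        dv = f
                    records.append(
                        {"ID": sid, "TIME": t, "AMT": np.nan, "DV": dv,
                         "EVID": 0, "CMT": CMT_PLASMA_OBS, "OCC": occ_idx,
                         "ROUTE": arm.route.value}
                    )

    frame = pd.DataFrame.from_records(records)
    frame = frame.sort_values(
        ["ID", "ROUTE", "OCC", "TIME", "EVID"],
        ascending=[True, True, True, True, False],
        kind="stable",
    ).reset_index(drop=True)
    return PKDataset(frame), pd.DataFrame(truth_rows)


# --------------------------------------------------------------------------
# persistence


def write_dataset(dataset: PKDataset, path) -> None:
    """Write the NONMEM-style CSV; missing DV on dose rows is encoded as '.'."""
    df = dataset.frame.copy()
    df["DV"] = df["DV"].map(lambda v: "." if pd.isna(v) else repr(float(v)))
    df["AMT"] = df["AMT"].map(lambda v: "." if pd.isna(v) else repr(float(v)))
    df.to_csv(path, index=False)


def read_dataset(path) -> PKDataset:
    """Read a NONMEM-style CSV written by :func:`write_dataset`.

    Raises a parse error naming the offending line for malformed rows or
    invariant violations (non-monotone TIME, non-positive observations).
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in DATASET_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")

    def parse_number(value: str, column: str, line: int, allow_dot: bool):
        if value == "." and allow_dot:
            return np.nan
        try:
            return float(value)
        except ValueError:
            raise ValueError(
                f"{path}, line {line}: cannot parse {column}={value!r}"
            ) from None

    rows = []
    for i, row in raw.iterrows():
        line = i + 2  # header is line 1
        rows.append(
            {
                "ID": int(parse_number(row["ID"], "ID", line, False)),
                "TIME": parse_number(row["TIME"], "TIME", line, False),
                "AMT": parse_number(row["AMT"], "AMT", line, True),
                "DV": parse_number(row["DV"], "DV", line, True),
                "EVID": int(parse_number(row["EVID"], "EVID", line, False)),
                "CMT": int(parse_number(row["CMT"], "CMT", line, False)),
                "OCC": int(parse_number(row["OCC"], "OCC", line, False)),
                "ROUTE": row["ROUTE"],
            }
        )
    frame = pd.DataFrame(rows, columns=DATASET_COLUMNS)
    try:
        return PKDataset(frame)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None
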