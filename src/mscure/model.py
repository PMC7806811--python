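"""Mathematical core of the multi-state cure model.

The model joins a logistic *incidence* submodel for the latent not-cured
status,

    logit P(NotCured = 1 | x) = alpha + gamma' x,

to four proportional-hazards *transition* submodels between the states
1 = apparently cured, 2 = not cured (event-free), 3 = recurrence,
4 = death:

    lambda_jk(t | x) = lambda0_jk(t) exp(beta_jk' x)

for the transitions 1->4, 2->4, 2->3 on the study clock and 3->4 on the
gap-time clock (time since entry into the recurrence state; clock reset,
semi-Markov).  Baseline hazards are unrestricted, realised as
right-continuous step cumulative hazards with jumps at observed event
times (Breslow convention).  The transient-state survival functions are

    S1(t|x) = exp(-e^{b14'x} L14(t))
    S2(t|x) = exp(-e^{b23'x} L23(t) - e^{b24'x} L24(t))
    S3(g|x) = exp(-e^{b34'x} L34(g)),   g = t - t_rec,

with L the baseline cumulative hazards.  A cumulative hazard evaluated at
a jump time includes the jump; left limits are written L(t-).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "TRANSITIONS",
    "StepCumHaz",
    "IncidenceModel",
    "TransitionModel",
    "FittedMSCure",
    "not_cured_probability",
    "transition_survival",
    "hazard_ratio",
    "wald_ci",
    "complete_data_loglik",
    "observed_data_loglik",
]

#: transition labels, in the fixed order used everywhere
TRANSITIONS = ("1->4", "2->4", "2->3", "3->4")


# ----------------------------------------------------------------------
# baseline cumulative hazard

@dataclass(frozen=True)
class StepCumHaz:
    """Nondecreasing right-continuous step function with Lambda(0-) = 0.

    ``times`` are strictly increasing jump locations (>= 0) and
    ``increments`` the nonnegative jump sizes.
    """

    times: np.ndarray
    increments: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        dz = np.asarray(self.increments, dtype=float)
        if t.shape != dz.shape:
            raise ValueError("times and increments must have equal length")
        if len(t) and (np.any(np.diff(t) <= 0) or np.any(t < 0)):
            raise ValueError("jump times must be nonnegative and strictly increasing")
        if np.any(dz < 0):
            raise ValueError("increments must be nonnegative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "increments", dz)
        object.__setattr__(self, "_csum", np.concatenate(([0.0], np.cumsum(dz))))

    @classmethod
    def zero(cls) -> "StepCumHaz":
        return cls(np.empty(0), np.empty(0))

    def cumhaz(self, t) -> np.ndarray:
        """Lambda(t) = sum of increments with jump time <= t (jump included)."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        return self._csum[idx]

    def cumhaz_left(self, t) -> np.ndarray:
        """Left limit Lambda(t-): jumps strictly before t."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="left")
        return self._csum[idx]

    def jump_at(self, t) -> np.ndarray:
        """Jump mass dLambda(t); zero where t is not a jump time."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="left")
        out = np.zeros(t.shape)
        if len(self.times):
            ok = idx < len(self.times)
            hit = np.zeros(t.shape, dtype=bool)
            hit[ok] = self.times[idx[ok]] == t[ok]
            out[hit] = self.increments[idx[hit]]
        return out

    def smoothed_rate(self, t, bandwidth: float) -> np.ndarray:
        """Kernel-smoothed hazard rate at ``t``: the increment mass in the
        window [t-h, t+h] divided by the window length (left-truncated at
        0).  A stable density surrogate for Bayes ratios of event
        attribution, where raw per-atom jump masses are degenerate.
        """
        if bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        t = np.asarray(t, dtype=float)
        lo = np.maximum(t - bandwidth, 0.0)
        hi = t + bandwidth
        mass = self.cumhaz(hi) - self.cumhaz_left(lo)
        return mass / (hi - lo)

    @property
    def total(self) -> float:
        return float(self._csum[-1])

    def scaled(self, c: float) -> "StepCumHaz":
        return StepCumHaz(self.times.copy(), self.increments * c)


# ----------------------------------------------------------------------
# submodels

@dataclass(frozen=True)
class IncidenceModel:
    """Logistic submodel for the probability of *not* being cured."""

    alpha: float
    gamma: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self):
        g = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        if not np.all(np.isfinite(g)) or not np.isfinite(self.alpha):
            raise ValueError("incidence coefficients must be finite")
        if len(g) != len(self.names):
            raise ValueError("gamma and names length mismatch")
        object.__setattr__(self, "gamma", g)
        object.__setattr__(self, "names", tuple(self.names))


@dataclass(frozen=True)
class TransitionModel:
    """One proportional-hazards transition with a step baseline."""

    label: str
    beta: np.ndarray
    names: tuple[str, ...]
    baseline: StepCumHaz
    clock: str = "study"  # "gap" for 3->4

    def __post_init__(self):
        if self.label not in TRANSITIONS:
            raise ValueError(f"unknown transition label {self.label!r}")
        b = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if len(b) != len(self.names):
            raise ValueError("beta and names length mismatch")
        expected_clock = "gap" if self.label == "3->4" else "study"
        if self.clock != expected_clock:
            raise ValueError(f"transition {self.label} must use the {expected_clock} clock")
        object.__setattr__(self, "beta", b)
        object.__setattr__(self, "names", tuple(self.names))

    def linear_predictor(self, x) -> np.ndarray:
        X = _as_matrix(x, self.names)
        return X @ self.beta


def _as_matrix(x, names: Sequence[str]) -> np.ndarray:
    """Coerce a covariate mapping / Series / DataFrame / array to (n, p)."""
    if isinstance(x, pd.DataFrame):
        return x.loc[:, list(names)].to_numpy(dtype=float)
    if isinstance(x, (Mapping, pd.Series)):
        return np.array([[float(x[n]) for n in names]])
    arr = np.atleast_2d(np.asarray(x, dtype=float))
    if arr.shape[1] != len(names):
        raise ValueError(f"covariate vector has {arr.shape[1]} entries, expected {len(names)}")
    return arr


# ----------------------------------------------------------------------
# elementary evaluations

def not_cured_probability(inc: IncidenceModel, x) -> np.ndarray | float:
    """P(NotCured = 1 | x) = expit(alpha + gamma' x)."""
    X = _as_matrix(x, inc.names)
    p = expit(inc.alpha + X @ inc.gamma)
    return float(p[0]) if p.shape == (1,) else p


def transition_survival(model: TransitionModel, t, x,
                        companion: TransitionModel | None = None):
    """Survival in a transient state at time ``t`` on the model's clock.

    For state 2 pass the 2->3 model with the 2->4 model as ``companion``
    (or vice versa): the state-2 survival uses the *sum* of both
    covariate-scaled cumulative hazards.  For 3->4 pass the gap time.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    a = np.exp(model.linear_predictor(x)) * model.baseline.cumhaz(t)
    if companion is not None:
        a = a + np.exp(companion.linear_predictor(x)) * companion.baseline.cumhaz(t)
    s = np.exp(-a)
    return float(s[0]) if s.shape == (1,) else s


def hazard_ratio(beta_entry: float) -> float:
    """exp(B): odds ratio (incidence) or hazard ratio (transitions)."""
    if not np.isfinite(beta_entry):
        raise ValueError("coefficient must be finite")
    return float(np.exp(beta_entry))


def wald_ci(b: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Symmetric normal-theory confidence interval B +/- z * SE."""
    from scipy.stats import norm
    z = norm.ppf(0.5 + level / 2)
    return (b - z * se, b + z * se)


# ----------------------------------------------------------------------
# fitted model container

@dataclass
class FittedMSCure:
    """A fitted multi-state cure model.

    ``weights`` holds the per-subject posterior not-cured probability at
    convergence; ``trace`` the observed-data log-likelihood after each EM
    iteration (nondecreasing up to numerical tolerance); ``dropped`` any
    covariates removed from a transition because they were constant within
    the weighted risk set.
    """

    incidence: IncidenceModel
    transitions: dict[str, TransitionModel]
    weights: pd.Series
    trace: list[float] = field(default_factory=list)
    converged: bool = True
    n_iter: int = 0
    ci_table: pd.DataFrame | None = None
    age_center: float | None = None
    dropped: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if np.any((w < 0) | (w > 1)):
            raise ValueError("posterior weights must lie in [0, 1]")

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "incidence": {
                "alpha": self.incidence.alpha,
                "gamma": self.incidence.gamma.tolist(),
                "names": list(self.incidence.names),
            },
            "transitions": {
                lab: {
                    "beta": tm.beta.tolist(),
                    "names": list(tm.names),
                    "clock": tm.clock,
                    "baseline_times": tm.baseline.times.tolist(),
                    "baseline_increments": tm.baseline.increments.tolist(),
                }
                for lab, tm in self.transitions.items()
            },
            "weights": {"id": self.weights.index.tolist(),
                        "w": self.weights.tolist()},
            "trace": list(self.trace),
            "converged": self.converged,
            "n_iter": self.n_iter,
            "age_center": self.age_center,
            "dropped": {k: list(v) for k, v in self.dropped.items()},
            "ci_table": None if self.ci_table is None
            else self.ci_table.to_dict(orient="list"),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "FittedMSCure":
        inc = IncidenceModel(d["incidence"]["alpha"],
                             np.asarray(d["incidence"]["gamma"], dtype=float),
                             tuple(d["incidence"]["names"]))
        trans = {
            lab: TransitionModel(
                lab,
                np.asarray(td["beta"], dtype=float),
                tuple(td["names"]),
                StepCumHaz(np.asarray(td["baseline_times"], dtype=float),
                           np.asarray(td["baseline_increments"], dtype=float)),
                clock=td["clock"],
            )
            for lab, td in d["transitions"].items()
        }
        w = pd.Series(d["weights"]["w"], index=d["weights"]["id"], dtype=float)
        ci = None if d.get("ci_table") is None else pd.DataFrame(d["ci_table"])
        return cls(inc, trans, w, trace=list(d.get("trace", [])),
                   converged=d.get("converged", True), n_iter=d.get("n_iter", 0),
                   ci_table=ci, age_center=d.get("age_center"),
                   dropped={k: list(v) for k, v in d.get("dropped", {}).items()})

    @classmethod
    def from_json(cls, path: str | Path) -> "FittedMSCure":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ----------------------------------------------------------------------
# likelihoods

def _design_pieces(fit: FittedMSCure, design: pd.DataFrame):
    """Linear predictors and outcome arrays shared by both likelihoods."""
    t_rec = design["t_rec"].to_numpy(dtype=float)
    d_rec = design["d_rec"].to_numpy() == 1
    t_death = design["t_death"].to_numpy(dtype=float)
    d_death = design["d_death"].to_numpy() == 1

    p = expit(fit.incidence.alpha
              + _as_matrix(design, fit.incidence.names) @ fit.incidence.gamma)

    eta = {}
    for lab in TRANSITIONS:
        tm = fit.transitions[lab]
        names = tm.names
        if lab == "3->4" and "t_rec" in names:
            cols = [design[n].to_numpy(dtype=float) if n != "t_rec" else t_rec
                    for n in names]
            X = np.column_stack(cols) if cols else np.empty((len(design), 0))
        else:
            X = _as_matrix(design, names)
        eta[lab] = X @ tm.beta
    return p, eta, t_rec, d_rec, t_death, d_death


def _path_logliks(fit: FittedMSCure, design: pd.DataFrame):
    """Per-subject log-likelihood of the observed history under each latent
    class (cured path, not-cured path), *excluding* the logistic prior.

    Event contributions use Breslow jump masses d Lambda0(t) e^{eta}; the
    survivor term at a subject's own time includes the jump at that time.
    Impossible paths get -inf.
    """
    p, eta, t_rec, d_rec, t_death, d_death = _design_pieces(fit, design)
    tm = fit.transitions
    with np.errstate(divide="ignore"):
        # cured path: at risk for 1->4 over the whole follow-up, no recurrence
        L14 = tm["1->4"].baseline.cumhaz(t_death)
        dL14 = tm["1->4"].baseline.jump_at(t_death)
        ll_cured = -np.exp(eta["1->4"]) * L14
        ll_cured += np.where(d_death, np.log(dL14) + eta["1->4"], 0.0)
        ll_cured[d_rec] = -np.inf  # cured subjects cannot recur

        # not-cured path: state 2 until t_rec (exit by recurrence, death or
        # censoring), then 3->4 on the gap clock for observed recurrences
        L23 = tm["2->3"].baseline.cumhaz(t_rec)
        L24 = tm["2->4"].baseline.cumhaz(t_rec)
        ll_nc = -(np.exp(eta["2->3"]) * L23 + np.exp(eta["2->4"]) * L24)
        dL23 = tm["2->3"].baseline.jump_at(t_rec)
        ll_nc += np.where(d_rec, np.log(dL23) + eta["2->3"], 0.0)
        death_norec = d_death & ~d_rec
        dL24 = tm["2->4"].baseline.jump_at(t_rec)
        ll_nc += np.where(death_norec, np.log(dL24) + eta["2->4"], 0.0)

        gap = np.where(d_rec, t_death - t_rec, 0.0)
        L34 = tm["3->4"].baseline.cumhaz(gap)
        dL34 = tm["3->4"].baseline.jump_at(gap)
        ll_34 = -np.exp(eta["3->4"]) * L34
        ll_34 += np.where(d_death, np.log(dL34) + eta["3->4"], 0.0)
        ll_nc += np.where(d_rec, ll_34, 0.0)
    return p, ll_cured, ll_nc, d_rec


def complete_data_loglik(fit: FittedMSCure, cohort, status) -> float:
    """Expected complete-data log-likelihood at weights ``status``.

    ``status`` is a per-subject not-cured probability (0, 1 or fractional).
    The value is the weighted sum of the logistic log-likelihood of the
    latent status and the status-weighted transition contributions.
    """
    design = cohort.design(center_age=fit.age_center)
    w = np.asarray(status, dtype=float)
    if np.any((w < 0) | (w > 1)):
        raise ValueError("status weights must lie in [0, 1]")
    p, ll_cured, ll_nc, d_rec = _path_logliks(fit, design)
    if np.any((1.0 - w > 0) & d_rec):
        bad = design["id"].to_numpy()[(1.0 - w > 0) & d_rec]
        raise ValueError(
            f"cured weight assigned to subjects with observed recurrence: {list(bad)}")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (w * np.log(p) + (1 - w) * np.log1p(-p)
                 + np.where(w > 0, w * ll_nc, 0.0)
                 + np.where(w < 1, (1 - w) * ll_cured, 0.0))
    return float(np.sum(terms))


def observed_data_loglik(fit: FittedMSCure, cohort, known_cured=None) -> float:
    """Observed-data (incomplete) log-likelihood of the mixture model.

    Subjects with observed recurrence contribute the not-cured path only;
    subjects in ``known_cured`` (boolean per-subject array, e.g. event-free
    beyond the cure threshold) contribute the cured path only; everyone
    else contributes the two-component mixture.
    """
    design = cohort.design(center_age=fit.age_center)
    p, ll_cured, ll_nc, d_rec = _path_logliks(fit, design)
    kc = (np.zeros(len(design), dtype=bool) if known_cured is None
          else np.asarray(known_cured, dtype=bool))
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        a = np.log(p) + ll_nc        # not-cured component
        b = np.log1p(-p) + ll_cured  # cured component
        a = np.where(kc, -np.inf, a)
        b = np.where(d_rec, -np.inf, b)
        m = np.maximum(a, b)
        mix = m + np.log(np.exp(a - m) + np.exp(b - m))
        mix = np.where(np.isneginf(m), -np.inf, mix)
    return float(np.sum(mix))
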