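"""State-occupancy, survival and cumulative-hazard prediction.

For a covariate profile x with not-cured probability p, the occupancy
probabilities are

    p1(t) = (1 - p) S1(t | x)                     (apparently cured, alive)
    p2(t) = p S2(t | x)                           (not cured, event-free)
    p3(t) = p sum_{u <= t} P(exit state 2 at u, cause 2->3 | x) S34(t-u | x)
    p4(t) = 1 - p1 - p2 - p3                      (dead)

where the sum runs over the jump times u of the fitted 2->3 baseline — a
discrete semi-Markov convolution over the recurrence time.  The exit
probability at an atom is the exact discrete S2(u-)(1 - e^{-dA2(u)}) with
the cause split proportional to the covariate-scaled atom masses (to
first order, the familiar dL23(u|x) S2(u-)); the left limit S2(u-) means
a subject cannot occupy two states at the jump instant, and the exact
form keeps the death-state probability nondecreasing for any atom sizes.
Overall survival is ``os = p1 + p2 + p3`` and event-free survival
``efs = p1 + p2``.

By default the time-to-recurrence covariate on the 3->4 transition is
*not* applied (its coefficient is zeroed): marginal curves for a profile
do not fix a recurrence time.  ``recurrence_time_covariate="convolution"``
instead plugs the running recurrence time u of each convolution term into
the 3->4 linear predictor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import FittedMSCure, TRANSITIONS, not_cured_probability

__all__ = [
    "OccupancyCurves",
    "default_grid",
    "mean_profile",
    "state_occupancy",
    "overall_survival",
    "event_free_survival",
    "cumulative_hazard_curves",
]


@dataclass
class OccupancyCurves:
    """Occupancy probabilities and derived curves on a time grid."""

    grid: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    p3: np.ndarray
    p4: np.ndarray
    cumhaz: dict[str, np.ndarray]

    @property
    def os(self) -> np.ndarray:
        """Overall survival: probability of being alive, 1 - p4."""
        return self.p1 + self.p2 + self.p3

    @property
    def efs(self) -> np.ndarray:
        """Event-free survival: neither recurrence nor death yet."""
        return self.p1 + self.p2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.grid, "p1": self.p1, "p2": self.p2, "p3": self.p3,
            "p4": self.p4, "os": self.os, "efs": self.efs,
            "H14": self.cumhaz["1->4"], "H24": self.cumhaz["2->4"],
            "H23": self.cumhaz["2->3"], "H34": self.cumhaz["3->4"],
        })


def default_grid(fit: FittedMSCure, max_months: float = 180.0) -> np.ndarray:
    """Union of all baseline jump times and monthly points up to
    ``max_months`` (study clock)."""
    pts = [np.arange(0.0, max_months + 1.0)]
    for lab in TRANSITIONS:
        t = fit.transitions[lab].baseline.times
        pts.append(t[t <= max_months])
    return np.unique(np.concatenate(pts))


def mean_profile(cohort, center_age: float | None = None) -> pd.Series:
    """Mean-covariate profile: continuous covariates at the sample mean,
    binary dummies at their sample proportion (fractional values)."""
    design = cohort.design(center_age=center_age)
    from .cohort import COVARIATES
    return design[list(COVARIATES)].mean()


def _profile_eta(fit: FittedMSCure, x, label: str, zero_t_rec: bool) -> float:
    tm = fit.transitions[label]
    eta = 0.0
    for name, b in zip(tm.names, tm.beta):
        if name == "t_rec":
            if zero_t_rec:
                continue
            eta += b * float(x["t_rec"]) if "t_rec" in x else 0.0
        else:
            eta += b * float(x[name])
    return float(eta)


def state_occupancy(fit: FittedMSCure, x, grid=None,
                    recurrence_time_covariate: str = "exclude") -> OccupancyCurves:
    """Occupancy curves for covariate profile ``x`` (mapping of design
    covariate names to values; fractional dummies allowed).

    ``recurrence_time_covariate``: ``"exclude"`` (default) zeroes the
    sojourn-time coefficient on 3->4; ``"convolution"`` applies it at the
    running recurrence time of each convolution term.
    """
    if recurrence_time_covariate not in ("exclude", "convolution"):
        raise ValueError("recurrence_time_covariate must be 'exclude' or 'convolution'")
    grid = default_grid(fit) if grid is None else np.asarray(grid, dtype=float)
    if np.any(grid < 0):
        raise ValueError("grid times must be nonnegative")

    p = not_cured_probability(
        fit.incidence, {n: float(x[n]) for n in fit.incidence.names})

    last_jump = max((fit.transitions[lab].baseline.times[-1]
                     for lab in ("1->4", "2->4", "2->3")
                     if len(fit.transitions[lab].baseline.times)), default=np.inf)
    if np.isfinite(last_jump) and grid.max() > last_jump:
        warnings.warn("grid extends beyond the last baseline jump; "
                      "curves are extended flat")

    tm14 = fit.transitions["1->4"]
    tm23 = fit.transitions["2->3"]
    tm24 = fit.transitions["2->4"]
    tm34 = fit.transitions["3->4"]

    e14 = np.exp(_profile_eta(fit, x, "1->4", zero_t_rec=True))
    e23 = np.exp(_profile_eta(fit, x, "2->3", zero_t_rec=True))
    e24 = np.exp(_profile_eta(fit, x, "2->4", zero_t_rec=True))

    S1 = np.exp(-e14 * tm14.baseline.cumhaz(grid))
    A2 = e23 * tm23.baseline.cumhaz(grid) + e24 * tm24.baseline.cumhaz(grid)
    S2 = np.exp(-A2)

    # convolution over the 2->3 baseline jump times.  The entry probability
    # at an atom u uses the exact discrete form S2(u-)(1 - e^{-dA2(u)})
    # with the cause split proportional to the atom masses; the naive
    # first-order mass dL23(u) S2(u-) would overshoot by O(dL^2) at large
    # atoms and make the death-state probability non-monotone.
    u = tm23.baseline.times
    dL23 = tm23.baseline.increments * e23
    dA2 = dL23 + e24 * tm24.baseline.jump_at(u)
    S2_left = np.exp(-(e23 * tm23.baseline.cumhaz_left(u)
                       + e24 * tm24.baseline.cumhaz_left(u)))
    with np.errstate(invalid="ignore", divide="ignore"):
        frac23 = np.where(dA2 > 0, dL23 / dA2, 0.0)
    entry_mass = S2_left * -np.expm1(-dA2) * frac23  # P(enter state 3 at u)/p

    beta34 = dict(zip(tm34.names, tm34.beta))
    eta34_base = sum(b * float(x[nm]) for nm, b in beta34.items() if nm != "t_rec")
    if recurrence_time_covariate == "convolution" and "t_rec" in beta34:
        e34_u = np.exp(eta34_base + beta34["t_rec"] * u)
    else:
        e34_u = np.full(len(u), np.exp(eta34_base))

    # S34(t - u | x) for each grid point t and jump u <= t
    gap = grid[:, None] - u[None, :]                 # (m, k)
    valid = gap >= 0
    L34 = tm34.baseline.cumhaz(np.where(valid, gap, 0.0))
    S34 = np.exp(-e34_u[None, :] * L34)
    p3 = p * np.sum(np.where(valid, entry_mass[None, :] * S34, 0.0), axis=1)

    p1 = (1 - p) * S1
    p2 = p * S2
    p4 = 1.0 - p1 - p2 - p3

    e34 = np.exp(eta34_base)  # gap-time axis; sojourn covariate not applicable
    cumhaz = {
        "1->4": e14 * tm14.baseline.cumhaz(grid),
        "2->4": e24 * tm24.baseline.cumhaz(grid),
        "2->3": e23 * tm23.baseline.cumhaz(grid),
        "3->4": e34 * tm34.baseline.cumhaz(grid),
    }
    return OccupancyCurves(grid=grid, p1=p1, p2=p2, p3=p3, p4=p4, cumhaz=cumhaz)


def overall_survival(curves: OccupancyCurves) -> np.ndarray:
    """P(alive at t) = 1 - p4(t) = p1 + p2 + p3."""
    return curves.os


def event_free_survival(curves: OccupancyCurves) -> np.ndarray:
    """P(no recurrence and no death by t) = p1 + p2."""
    return curves.efs


def cumulative_hazard_curves(fit: FittedMSCure, x, grid) -> dict[str, np.ndarray]:
    """Covariate-scaled cumulative hazards ``exp(beta'x) L0(t)`` for the
    four transitions; the 3->4 curve is on the gap-time axis."""
    grid = np.asarray(grid, dtype=float)
    out = {}
    for lab in TRANSITIONS:
        tm = fit.transitions[lab]
        eta = _profile_eta(fit, x, lab, zero_t_rec=True)
        out[lab] = np.exp(eta) * tm.baseline.cumhaz(grid)
    return out
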