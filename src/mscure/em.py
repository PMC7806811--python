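"""EM estimation of the multi-state cure model.

Latent not-cured status is handled by EM:

* **Known statuses.** Subjects with an observed recurrence are known not
  cured; subjects still event-free (alive, no recurrence) beyond the cure
  threshold (default 50 months) are labelled apparently cured; everyone
  else has unknown status.
* **E-step.** Unknown subjects get the posterior not-cured probability
  from Bayes' rule on the two candidate paths.  Censored alive at t:
  ``w = p S2(t) / [p S2(t) + (1-p) S1(t)]``.  Dead without recurrence at
  t: the same ratio with each survival multiplied by that path's Breslow
  jump mass at t (the standard nonparametric density surrogate).
* **M-steps.** A weighted logistic Newton fit for the incidence submodel
  and four weighted Cox partial-likelihood fits (Breslow ties, Breslow
  baseline) for the transitions: 1->4 with weight 1-w, 2->3 and 2->4 with
  weight w, 3->4 with weight 1 among observed recurrences on the gap
  clock.

The observed-data log-likelihood is recorded each iteration and is
nondecreasing (EM ascent).  Standard errors are nonparametric-bootstrap;
confidence intervals and p-values are Wald.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .cohort import COVARIATES, Cohort
from .model import (
    TRANSITIONS,
    FittedMSCure,
    IncidenceModel,
    StepCumHaz,
    TransitionModel,
    observed_data_loglik,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FitConfig",
    "DegenerateWeightError",
    "SeparationError",
    "assign_known_status",
    "e_step",
    "m_step_incidence",
    "m_step_transition",
    "fit",
    "bootstrap_ci",
    "univariate_screen",
]

#: default covariate map mirroring the published model structure
#: (chemotherapy cannot enter 2->4; 3->4 is restricted to the clinically
#: designated covariates plus the realised time to recurrence)
DEFAULT_COVARIATE_MAP: dict[str, tuple[str, ...]] = {
    "incidence": COVARIATES,
    "1->4": COVARIATES,
    "2->4": ("age", "sex_male", "stage_III", "stage_IV", "metastasis"),
    "2->3": COVARIATES,
    "3->4": ("stage_III", "stage_IV", "metastasis", "t_rec"),
}


class DegenerateWeightError(RuntimeError):
    """Both latent paths have zero likelihood for a subject."""


class SeparationError(RuntimeError):
    """The weighted logistic fit diverged (complete separation)."""


@dataclass(frozen=True)
class FitConfig:
    """Settings for :func:`fit`.

    ``cure_threshold`` is the months of event-free follow-up after which a
    subject is labelled apparently cured.  ``center_age`` is ``None`` (raw
    years), a float (center at that constant) or ``"mean"`` (center at the
    sample mean); centering changes only the incidence intercept and the
    baselines, never the other coefficients' ORs/HRs.
    """

    cure_threshold: float = 50.0
    covariates: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_MAP))
    max_iter: int = 500
    tol: float = 1e-6
    n_boot: int = 50
    seed: int = 0
    center_age: float | str | None = None
    init_weight: float = 0.5
    #: half-width (months) of the uniform kernel used to smooth the two
    #: death-route hazards in the E-step attribution ratio for subjects
    #: dead without recurrence.  Raw Breslow atoms are degenerate there: at
    #: an isolated death time the subject's own weight dominates both jump
    #: masses, the posterior odds multiply across iterations, and every
    #: such subject ratchets to a hard 0/1 attribution (an overfitted,
    #: biased fixed point).  Smoothing restores the continuous-time hazard
    #: ratio that Bayes' rule actually requires.  Set to 0 to use raw jump
    #: masses.  With time grouping on (the default), atoms are shared by
    #: all subjects with events in the same interval and the raw masses
    #: are already non-degenerate, so 0 is the default.
    e_step_bandwidth: float = 0.0
    #: event times are grouped onto a grid of this width (months) before
    #: fitting; ``None`` disables.  The study records follow-up in whole
    #: months, and shared monthly baseline atoms both reflect that
    #: resolution and keep the nonparametric mixture E-step well behaved
    #: (every atom is shared by all subjects with events that month).
    time_grouping: float | None = 1.0
    #: apply Firth's bias-reducing penalty (0.5 log det of the partial-
    #: likelihood information) in the transition M-steps.  The latent
    #: mixture can starve a covariate level of weighted events (monotone
    #: partial likelihood), sending hazard ratios to infinity; Firth's
    #: penalty keeps them finite with second-order bias reduction.
    firth: bool = True

    def __post_init__(self):
        if self.cure_threshold <= 0:
            raise ValueError("cure_threshold must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


# ----------------------------------------------------------------------
# known-status rule

def assign_known_status(cohort: Cohort, threshold: float = 50.0) -> pd.Series:
    """Baseline cure-status labels.

    Observed recurrence -> ``not_cured``.  Subjects still at risk for
    recurrence beyond ``threshold`` -- i.e. recurrence-free with follow-up
    past the threshold, whether subsequently censored alive or dead --
    -> ``cured``.  Everyone else (recurrence-free with short follow-up,
    including early deaths without recurrence) -> ``unknown``.

    Labelling late recurrence-free deaths as cured is what identifies the
    two death routes: it bounds the not-cured death baseline's support to
    [0, threshold], the cure-model analogue of the zero-tail constraint.
    Without it the two unrestricted death baselines can trade mass
    arbitrarily.
    """
    df = cohort.frame
    status = np.full(len(df), "unknown", dtype=object)
    rec_free = df["d_rec"].to_numpy() == 0
    status[rec_free & (df["t_death"].to_numpy() > threshold)] = "cured"
    status[df["d_rec"].to_numpy() == 1] = "not_cured"
    return pd.Series(status, index=df.index, name="status")


# ----------------------------------------------------------------------
# M-step: weighted logistic regression (Newton)

def m_step_incidence(X: np.ndarray, w: np.ndarray,
                     names: tuple[str, ...] = (),
                     beta0: np.ndarray | None = None,
                     tol: float = 1e-10, max_iter: int = 100) -> IncidenceModel:
    """Maximise the weighted Bernoulli log-likelihood
    ``sum_i [w_i log p_i + (1-w_i) log(1-p_i)]`` with
    ``p_i = expit(alpha + gamma' x_i)``.

    ``X`` is (n, p) *without* an intercept column; fractional targets
    ``w`` in [0, 1] are allowed.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(len(X), -1)
    w = np.asarray(w, dtype=float)
    n, p = X.shape
    if n and (w.min() >= 1.0 - 1e-12 or w.max() <= 1e-12):
        # cure fraction forced off (or on): pin the intercept at the
        # saturation bound instead of letting Newton diverge
        return IncidenceModel(alpha=38.0 if w.min() >= 1.0 - 1e-12 else -38.0,
                              gamma=np.zeros(p), names=tuple(names))
    Z = np.column_stack([np.ones(n), X])
    theta = np.zeros(p + 1) if beta0 is None else np.asarray(beta0, dtype=float).copy()

    def negll(th):
        eta = Z @ th
        # -sum w*log(p) + (1-w)*log(1-p) in a stable form
        return float(np.sum(np.logaddexp(0.0, eta) - w * eta))

    f = negll(theta)
    for _ in range(max_iter):
        prob = expit(Z @ theta)
        g = Z.T @ (w - prob)
        if np.max(np.abs(g)) < tol:
            break
        W = prob * (1 - prob)
        H = (Z * W[:, None]).T @ Z
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            raise SeparationError(
                "singular Hessian in weighted logistic fit; consider removing "
                "a degenerate covariate") from None
        # step halving on the (negative) log-likelihood
        s = 1.0
        for _ in range(40):
            cand = theta + s * step
            fc = negll(cand)
            if fc <= f + 1e-12:
                theta, f = cand, fc
                break
            s *= 0.5
        else:
            break
        if np.max(np.abs(theta)) > 30:
            raise SeparationError(
                "weighted logistic fit diverged (complete separation); "
                "consider removing a covariate")
    return IncidenceModel(alpha=float(theta[0]), gamma=theta[1:], names=tuple(names))


# ----------------------------------------------------------------------
# M-step: weighted Cox partial likelihood with Breslow baseline

def weighted_partial_loglik(beta, times, events, X, w) -> float:
    """Breslow-tie weighted Cox partial log-likelihood (reference form).

    Risk set at an event time tau is ``{j : t_j >= tau}``.
    """
    times = np.asarray(times, float)
    events = np.asarray(events).astype(bool)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X.reshape(len(X), -1)
    w = np.asarray(w, float)
    eta = X @ np.atleast_1d(np.asarray(beta, float))
    ll = 0.0
    for tau in np.unique(times[events & (w > 0)]):
        d = events & (times == tau) & (w > 0)
        risk = times >= tau
        W = w[d].sum()
        ll += float(np.sum(w[d] * eta[d]) - W * np.log(np.sum(w[risk] * np.exp(eta[risk]))))
    return ll


def m_step_transition(label: str, times, events, X, w,
                      names: tuple[str, ...] = (),
                      beta0: np.ndarray | None = None,
                      tol: float = 1e-9, max_iter: int = 60,
                      drop_degenerate: bool = True,
                      firth: bool = False) -> tuple[TransitionModel, list[str]]:
    """Weighted Cox fit (Breslow ties) plus Breslow baseline for one
    transition.  Returns ``(model, dropped_covariates)``.

    Covariates that are constant within the weighted sample (weight > 0)
    are dropped with a logged warning — e.g. a treatment received by every
    not-cured subject cannot have its effect estimated on their
    transitions.  Subjects with zero weight contribute nothing.

    ``firth=True`` adds Firth's bias-reducing penalty
    ``0.5 log det I(beta)`` to the partial likelihood, which keeps the
    estimate finite under monotone likelihood (a covariate level with
    exposure but no weighted events).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(len(X), -1)
    w = np.asarray(w, dtype=float)
    names = tuple(names)

    active = w > 1e-12
    times, events, X, w = times[active], events[active], X[active], w[active]
    n = len(times)

    dropped: list[str] = []
    keep = list(range(X.shape[1]))
    if drop_degenerate and n:
        for j, nm in enumerate(names):
            col = X[:, j]
            mean = np.average(col, weights=w) if w.sum() > 0 else 0.0
            var = np.average((col - mean) ** 2, weights=w) if w.sum() > 0 else 0.0
            if var < 1e-12:
                dropped.append(nm)
        if dropped:
            logger.warning("transition %s: dropping constant covariate(s) %s",
                           label, dropped)
            keep = [j for j, nm in enumerate(names) if nm not in dropped]
            X = X[:, keep]
    kept_names = tuple(nm for nm in names if nm not in dropped)
    p = X.shape[1]

    clock = "gap" if label == "3->4" else "study"
    total_event_w = float(w[events].sum()) if n else 0.0
    if n == 0 or total_event_w <= 0:
        warnings.warn(f"transition {label}: no weighted events; returning empty submodel")
        return (TransitionModel(label, np.zeros(p), kept_names,
                                StepCumHaz.zero(), clock=clock), dropped)

    order = np.argsort(times, kind="stable")
    t_s = times[order]
    e_s = events[order]
    w_s = w[order]
    X_s = X[order]

    # distinct event times and per-time weighted event sums
    ev_mask = e_s
    ev_times = t_s[ev_mask]
    uniq, inv = np.unique(ev_times, return_inverse=True)
    W_tau = np.bincount(inv, weights=w_s[ev_mask])
    Wx_tau = np.zeros((len(uniq), p))
    for j in range(p):
        Wx_tau[:, j] = np.bincount(inv, weights=w_s[ev_mask] * X_s[ev_mask, j])
    # index of first at-risk subject for each distinct event time
    first = np.searchsorted(t_s, uniq, side="left")

    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float)[keep].copy()

    def suffix(arr):
        return np.cumsum(arr[::-1], axis=0)[::-1]

    def loglik_grad_hess(b):
        eta = X_s @ b
        shift = eta.max() if len(eta) else 0.0
        r = w_s * np.exp(eta - shift)
        s0 = suffix(r)[first]                      # (k,)
        rX = X_s * r[:, None]
        s1 = suffix(rX)[first]                     # (k, p)
        ll = float(np.sum(Wx_tau @ b) - np.sum(W_tau * (np.log(s0) + shift)))
        grad = Wx_tau.sum(axis=0) - (W_tau[:, None] * (s1 / s0[:, None])).sum(axis=0)
        rXX = np.einsum("ij,ik->ijk", X_s, rX)     # (n, p, p)
        s2 = suffix(rXX)[first]                    # (k, p, p)
        m1 = s1 / s0[:, None]                      # (k, p)
        m2 = s2 / s0[:, None, None]                # (k, p, p)
        info = (np.einsum("k,kjl->jl", W_tau, m2)
                - np.einsum("k,kj,kl->jl", W_tau, m1, m1))
        if not firth:
            return ll, grad, -info, s0
        # Firth: l* = l + 0.5 log det I;  U*_c = U_c + 0.5 tr(I^-1 dI/dbc)
        rXXX = np.einsum("ijk,il->ijkl", rXX, X_s)  # (n, p, p, p)
        m3 = suffix(rXXX)[first] / s0[:, None, None, None]
        dI = (np.einsum("k,kabc->abc", W_tau, m3)
              - np.einsum("k,kab,kc->abc", W_tau, m2, m1)
              - np.einsum("k,kb,kac->abc", W_tau, m1, m2)
              - np.einsum("k,ka,kbc->abc", W_tau, m1, m2)
              + 2.0 * np.einsum("k,ka,kb,kc->abc", W_tau, m1, m1, m1))
        sign, logdet = np.linalg.slogdet(info)
        if sign <= 0:
            return ll, grad, -info, s0  # fall back to plain ML this step
        Iinv = np.linalg.inv(info)
        pen_grad = 0.5 * np.einsum("ab,abc->c", Iinv, dI)
        return ll + 0.5 * logdet, grad + pen_grad, -info, s0

    if p:
        ll, grad, hess, s0 = loglik_grad_hess(beta)
        for _ in range(max_iter):
            if np.max(np.abs(grad)) < tol:
                break
            try:
                step = np.linalg.solve(-hess, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(-hess, grad, rcond=None)[0]
            s = 1.0
            for _ in range(40):
                cand = beta + s * step
                ll_c, g_c, h_c, s0_c = loglik_grad_hess(cand)
                if ll_c >= ll - 1e-12:
                    beta, ll, grad, hess, s0 = cand, ll_c, g_c, h_c, s0_c
                    break
                s *= 0.5
            else:
                break
    else:
        s0 = suffix(w_s)[first]

    # Breslow baseline: dL0(tau) = sum(weighted events at tau) / S0(tau)
    if p:
        eta = X_s @ beta
        shift = eta.max()
        r = w_s * np.exp(eta - shift)
        s0_final = suffix(r)[first] * np.exp(shift)
    else:
        s0_final = s0
    increments = W_tau / s0_final
    baseline = StepCumHaz(uniq, increments)
    return (TransitionModel(label, beta, kept_names, baseline, clock=clock), dropped)


# ----------------------------------------------------------------------
# E-step

def e_step(cohort: Cohort, current: FittedMSCure, status: pd.Series,
           bandwidth: float = 6.0) -> np.ndarray:
    """Posterior not-cured probabilities given the current parameters.

    Known statuses are pinned to 0/1; unknown subjects get the Bayes
    ratio of the two path likelihoods.  Censored alive at t:
    ``w = p S2 / (p S2 + (1-p) S1)``.  Dead without recurrence at t: each
    survival is additionally multiplied by that route's hazard at t —
    kernel-smoothed over ``bandwidth`` months (see
    :class:`FitConfig.e_step_bandwidth`; ``bandwidth=0`` uses the raw
    Breslow jump masses instead).
    """
    design = cohort.design(center_age=current.age_center)
    from .model import _design_pieces  # shared linear-predictor machinery
    p, eta, t_rec, d_rec, t_death, d_death = _design_pieces(current, design)
    tm = current.transitions

    w = np.empty(len(design))
    st = np.asarray(status, dtype=object)
    w[st == "not_cured"] = 1.0
    w[st == "cured"] = 0.0

    unknown = st == "unknown"
    if unknown.any():
        S1 = np.exp(-np.exp(eta["1->4"]) * tm["1->4"].baseline.cumhaz(t_death))
        A2 = (np.exp(eta["2->3"]) * tm["2->3"].baseline.cumhaz(t_rec)
              + np.exp(eta["2->4"]) * tm["2->4"].baseline.cumhaz(t_rec))
        S2 = np.exp(-A2)
        num = p * S2
        den_extra = (1 - p) * S1
        dead = unknown & d_death & ~d_rec
        if dead.any():
            if bandwidth > 0:
                h24 = tm["2->4"].baseline.smoothed_rate(t_rec, bandwidth)
                h14 = tm["1->4"].baseline.smoothed_rate(t_death, bandwidth)
            else:
                h24 = tm["2->4"].baseline.jump_at(t_rec)
                h14 = tm["1->4"].baseline.jump_at(t_death)
            num = np.where(dead, num * h24 * np.exp(eta["2->4"]), num)
            den_extra = np.where(dead, den_extra * h14 * np.exp(eta["1->4"]), den_extra)
        den = num + den_extra
        bad = unknown & (den <= 0)
        if bad.any():
            bad_ids = design["id"].to_numpy()[bad]
            raise DegenerateWeightError(
                f"zero posterior denominator for subject(s) {list(bad_ids[:5])}"
                f"{'...' if bad.sum() > 5 else ''}")
        w[unknown] = (num / den)[unknown]
    return np.clip(w, 0.0, 1.0)


# ----------------------------------------------------------------------
# transition data extraction

def _transition_arrays(design: pd.DataFrame, cfg_cov: dict[str, tuple[str, ...]]):
    """Per-transition (times, events, X, weight-source) arrays.

    Weight source: '1-w' for 1->4, 'w' for 2->3 / 2->4, 'one' (observed
    recurrences only) for 3->4.
    """
    t_rec = design["t_rec"].to_numpy(dtype=float)
    d_rec = design["d_rec"].to_numpy() == 1
    t_death = design["t_death"].to_numpy(dtype=float)
    d_death = design["d_death"].to_numpy() == 1

    def mat(names, subset=None):
        cols = []
        for n in names:
            v = t_rec if n == "t_rec" else design[n].to_numpy(dtype=float)
            cols.append(v if subset is None else v[subset])
        size = len(design) if subset is None else int(np.sum(subset))
        return np.column_stack(cols) if cols else np.empty((size, 0))

    out = {}
    out["1->4"] = dict(times=t_death, events=d_death & ~d_rec, X=mat(cfg_cov["1->4"]),
                       subset=None, wsrc="cured")
    out["2->4"] = dict(times=t_rec, events=d_death & ~d_rec, X=mat(cfg_cov["2->4"]),
                       subset=None, wsrc="not_cured")
    out["2->3"] = dict(times=t_rec, events=d_rec, X=mat(cfg_cov["2->3"]),
                       subset=None, wsrc="not_cured")
    rec = d_rec
    out["3->4"] = dict(times=(t_death - t_rec)[rec], events=d_death[rec],
                       X=mat(cfg_cov["3->4"], subset=rec), subset=rec, wsrc="one")
    return out


def _m_steps(design, tdata, cfg, w, warm=None):
    names_inc = tuple(cfg.covariates["incidence"])
    X_inc = design[list(names_inc)].to_numpy(dtype=float)
    warm = warm or {}
    inc = m_step_incidence(X_inc, w, names=names_inc,
                           beta0=warm.get("incidence"))
    transitions = {}
    dropped = {}
    for lab in TRANSITIONS:
        td = tdata[lab]
        if td["wsrc"] == "cured":
            wt = 1.0 - w
        elif td["wsrc"] == "not_cured":
            wt = w
        else:
            wt = np.ones(len(td["times"]))
        tm, drp = m_step_transition(lab, td["times"], td["events"], td["X"], wt,
                                    names=tuple(cfg.covariates[lab]),
                                    beta0=warm.get(lab), firth=cfg.firth)
        transitions[lab] = tm
        if drp:
            dropped[lab] = drp
    return inc, transitions, dropped


def _theta_vector(inc: IncidenceModel, transitions: dict[str, TransitionModel]):
    parts = [np.concatenate(([inc.alpha], inc.gamma))]
    for lab in TRANSITIONS:
        parts.append(transitions[lab].beta)
    return np.concatenate(parts)


def _resolve_center(cohort: Cohort, center_age) -> float | None:
    if center_age is None or center_age is False:
        return None
    if center_age == "mean" or center_age is True:
        return float(cohort.frame["age"].mean())
    return float(center_age)


# ----------------------------------------------------------------------
# main fit

def fit(cohort: Cohort, config: FitConfig | None = None,
        known_status: pd.Series | None = None) -> FittedMSCure:
    """Fit the multi-state cure model by EM.

    Event times are grouped onto a monthly grid during the EM (see
    :class:`FitConfig.time_grouping`): shared baseline atoms keep the
    latent death-route attribution well behaved.  The reported
    coefficients and baselines come from a final M-step at the original
    time resolution, evaluated at the converged posterior weights, so the
    estimates carry no tie-coarsening attenuation.

    The recorded ``trace`` is the observed-data log-likelihood of the
    (grouped) EM after each iteration; iterations stop early, reverting
    to the previous iterate, if the log-likelihood ever decreases beyond
    numerical tolerance (an ascent guard: with Firth-penalised M-steps
    the exact observed-data ascent is no longer a theorem, though in
    practice the trace is monotone).

    ``known_status`` overrides the threshold rule with explicit labels in
    {"cured", "not_cured", "unknown"} (e.g. fully labelled synthetic
    data, under which EM is a one-pass fixed point).  Non-convergence at
    ``max_iter`` flags the result; it is not an exception.
    """
    config = config or FitConfig()
    center = _resolve_center(cohort, config.center_age)
    original = cohort
    if config.time_grouping:
        g = float(config.time_grouping)
        frame = cohort.frame.copy()
        frame["t_rec"] = np.ceil(frame["t_rec"].to_numpy() / g) * g
        frame["t_death"] = np.ceil(frame["t_death"].to_numpy() / g) * g
        # grouping can only merge an observed recurrence with a subsequent
        # censoring time; skip revalidation of that edge case
        cohort = Cohort(frame, spec=cohort.spec, validate=False)
    design = cohort.design(center_age=center)
    status = (known_status if known_status is not None
              else assign_known_status(cohort, config.cure_threshold))
    st = np.asarray(status, dtype=object)

    w = np.full(len(design), config.init_weight)
    w[st == "not_cured"] = 1.0
    w[st == "cured"] = 0.0

    tdata = _transition_arrays(design, config.covariates)
    inc, transitions, dropped = _m_steps(design, tdata, config, w)
    theta = _theta_vector(inc, transitions)
    trace: list[float] = []
    converged = False
    n_iter = 0
    current = FittedMSCure(inc, transitions, pd.Series(w, index=design["id"]),
                           age_center=center, dropped=dropped)
    kc = st == "cured"
    trace.append(observed_data_loglik(current, cohort, known_cured=kc))

    def warm_start():
        warm = {"incidence": np.concatenate(([inc.alpha], inc.gamma))}
        for lab in TRANSITIONS:
            full = np.zeros(len(config.covariates[lab]))
            tm = transitions[lab]
            for j, nm in enumerate(config.covariates[lab]):
                if nm in tm.names:
                    full[j] = tm.beta[list(tm.names).index(nm)]
            warm[lab] = full
        return warm

    for n_iter in range(1, config.max_iter + 1):
        w_new = e_step(cohort, current, pd.Series(st),
                       bandwidth=config.e_step_bandwidth)
        inc_new, trans_new, dropped_new = _m_steps(design, tdata, config, w_new,
                                                   warm=warm_start())
        cand = FittedMSCure(inc_new, trans_new,
                            pd.Series(w_new, index=design["id"]),
                            age_center=center, dropped=dropped_new)
        ll = observed_data_loglik(cand, cohort, known_cured=kc)
        if ll < trace[-1] - 1e-10:
            logger.info("EM iter %d: ascent stalled (delta loglik %.3g); "
                        "stopping at previous iterate", n_iter, ll - trace[-1])
            converged = True
            n_iter -= 1
            break
        w, inc, transitions, dropped, current = w_new, inc_new, trans_new, dropped_new, cand
        trace.append(ll)
        theta_new = _theta_vector(inc, transitions)
        delta = (np.max(np.abs(theta_new - theta) / np.maximum(np.abs(theta), 1.0))
                 if len(theta_new) == len(theta) else np.inf)
        logger.info("EM iter %d: loglik=%.6f max-rel-delta=%.3g",
                    n_iter, trace[-1], delta)
        theta = theta_new
        if delta < config.tol:
            converged = True
            break
    if not converged:
        logger.warning("EM did not converge in %d iterations", config.max_iter)

    if config.time_grouping:
        # final M-step at the original time resolution (no tie coarsening)
        design_orig = original.design(center_age=center)
        tdata_orig = _transition_arrays(design_orig, config.covariates)
        inc, transitions, dropped = _m_steps(design_orig, tdata_orig, config, w,
                                             warm=warm_start())

    return FittedMSCure(inc, transitions, pd.Series(w, index=design["id"]),
                        trace=trace, converged=converged, n_iter=n_iter,
                        age_center=center, dropped=dropped)


# ----------------------------------------------------------------------
# bootstrap confidence intervals

def _coef_series(f: FittedMSCure) -> pd.Series:
    idx = [("incidence", "intercept")] + [("incidence", n) for n in f.incidence.names]
    vals = [f.incidence.alpha] + list(f.incidence.gamma)
    for lab in TRANSITIONS:
        tm = f.transitions[lab]
        idx += [(lab, n) for n in tm.names]
        vals += list(tm.beta)
    return pd.Series(vals, index=pd.MultiIndex.from_tuples(idx, names=["submodel", "variable"]))


def bootstrap_ci(cohort: Cohort, config: FitConfig | None = None,
                 base_fit: FittedMSCure | None = None) -> pd.DataFrame:
    """Nonparametric bootstrap SEs with Wald CIs and p-values.

    Resamples subjects with replacement, refits per replicate; SE is the
    replicate standard deviation, CI is ``B +/- 1.96 SE`` and p the
    two-sided normal tail.  With ``n_boot == 0`` the table carries the
    point estimates only.  Non-converged replicates are dropped (with a
    warning if more than 10% are lost).
    """
    config = config or FitConfig()
    if base_fit is None:
        base_fit = fit(cohort, config)
    est = _coef_series(base_fit)

    table = pd.DataFrame({
        "submodel": [i[0] for i in est.index],
        "variable": [i[1] for i in est.index],
        "B": est.to_numpy(),
    })
    order = ["submodel", "variable", "B", "SE", "exp_B", "ci_low", "ci_high", "p"]
    table["exp_B"] = np.exp(table["B"])
    if config.n_boot < 1:
        for col in ("SE", "ci_low", "ci_high", "p"):
            table[col] = np.nan
        return table[order]

    rng = np.random.default_rng(config.seed)
    reps = []
    dropped_reps = 0
    boot_cfg = replace(config, n_boot=0)
    n = len(cohort)
    for _ in range(config.n_boot):
        take = rng.integers(0, n, size=n)
        bf = cohort.frame.iloc[take].reset_index(drop=True).copy()
        bf["id"] = [f"b{i}" for i in range(n)]  # keep ids unique
        bco = Cohort(bf, spec=cohort.spec)
        try:
            rfit = fit(bco, boot_cfg)
        except (DegenerateWeightError, SeparationError):
            dropped_reps += 1
            continue
        if not rfit.converged:
            dropped_reps += 1
            continue
        reps.append(_coef_series(rfit))
    if dropped_reps > 0.10 * config.n_boot:
        warnings.warn(f"{dropped_reps}/{config.n_boot} bootstrap replicates dropped")
    rep_df = pd.DataFrame(reps)
    se = rep_df.std(ddof=1).reindex(est.index)
    z = norm.ppf(0.975)
    table["SE"] = se.to_numpy()
    table["ci_low"] = table["B"] - z * table["SE"]
    table["ci_high"] = table["B"] + z * table["SE"]
    with np.errstate(divide="ignore", invalid="ignore"):
        table["p"] = 2 * norm.sf(np.abs(table["B"] / table["SE"]))
    return table[order]


# ----------------------------------------------------------------------
# univariate screening

#: covariates clinically designated for the data-poor recurrence->death
#: transition (the full candidate set cannot be supported there)
TRANSITION_34_CANDIDATES = ("stage_III", "stage_IV", "metastasis")

#: grouping of design columns into screenable "variables"
VARIABLE_GROUPS = {
    "age": ("age",),
    "sex": ("sex_male",),
    "stage": ("stage_III", "stage_IV"),
    "chemotherapy": ("chemotherapy",),
    "metastasis": ("metastasis",),
}


def univariate_screen(cohort: Cohort, candidates: list[str], alpha: float = 0.05,
                      config: FitConfig | None = None) -> dict[str, bool]:
    """Single-covariate multi-state cure model per candidate; a candidate
    is retained when any of its coefficients is significant at ``alpha``
    on the incidence submodel or any transition.

    Candidates are variable names from :data:`VARIABLE_GROUPS` (or raw
    design column names).  On the recurrence->death transition only the
    clinically designated covariates are screened.  Duplicated candidates
    are flagged with a warning and screened once each.
    """
    config = config or FitConfig()
    if len(set(candidates)) < len(candidates):
        warnings.warn("duplicate candidates supplied; screening each once")
    design = cohort.design()
    seen_cols: dict[tuple, list[str]] = {}
    results: dict[str, bool] = {}
    for cand in candidates:
        cols = VARIABLE_GROUPS.get(cand, (cand,))
        key = design[list(cols)].to_numpy(dtype=float).tobytes()
        if key in seen_cols:
            warnings.warn(f"candidate {cand!r} duplicates {seen_cols[key][0]!r}")
        seen_cols.setdefault(key, []).append(cand)
        if alpha >= 1.0:
            results[cand] = True
            continue
        cov34 = tuple(c for c in cols if c in TRANSITION_34_CANDIDATES) + ("t_rec",)
        cov_map = {"incidence": cols, "1->4": cols, "2->4": cols, "2->3": cols,
                   "3->4": cov34}
        cfg = replace(config, covariates=cov_map)
        table = bootstrap_ci(cohort, cfg)
        rows = table[(table["variable"].isin(cols))]
        results[cand] = bool((rows["p"] < alpha).any())
    return results
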