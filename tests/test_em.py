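import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

import mscure
from mscure import (FitConfig, FittedMSCure, IncidenceModel, StepCumHaz,
                    TransitionModel, assign_known_status, default_truth,
                    e_step, fit, generate_cohort, m_step_incidence,
                    m_step_transition)
from mscure.em import weighted_partial_loglik
from tests.conftest import make_cohort


# ----------------------------------------------------------------------
# known-status rule

class TestAssignKnownStatus:
    def rows(self):
        return [
            ("rec12", 60.0, "female", "II", "no", "no", None, 12.0, 1, 40.0, 1),
            ("cens60", 60.0, "female", "II", "no", "no", None, 60.0, 0, 60.0, 0),
            ("dead20", 60.0, "female", "II", "no", "no", None, 20.0, 0, 20.0, 1),
            ("dead70", 60.0, "female", "II", "no", "no", None, 70.0, 0, 70.0, 1),
            ("cens30", 60.0, "female", "II", "no", "no", None, 30.0, 0, 30.0, 0),
        ]

    def test_rule(self):
        st = assign_known_status(make_cohort(self.rows()), 50.0)
        assert list(st) == ["not_cured", "cured", "unknown", "cured", "unknown"]


# ----------------------------------------------------------------------
# E-step patterns

def _manual_fit(p, S1, S2, t, j14=None, j24=None):
    """Build a FittedMSCure whose survivals at time t equal S1/S2 and
    whose death baselines have the given jump masses at t."""
    alpha = np.log(p / (1 - p)) if 0 < p < 1 else (50.0 if p >= 1 else -50.0)
    L1 = -np.log(S1)
    L2 = -np.log(S2)
    b14 = StepCumHaz(np.array([t]), np.array([L1])) if j14 is None else \
        StepCumHaz(np.array([t - 1.0, t]), np.array([L1 - j14, j14]))
    b2 = StepCumHaz(np.array([t]), np.array([L2])) if j24 is None else \
        StepCumHaz(np.array([t - 1.0, t]), np.array([L2 - j24, j24]))
    trans = {
        "1->4": TransitionModel("1->4", np.array([]), (), b14),
        "2->4": TransitionModel("2->4", np.array([]), (), b2),
        "2->3": TransitionModel("2->3", np.array([]), (), StepCumHaz.zero()),
        "3->4": TransitionModel("3->4", np.array([]), (), StepCumHaz.zero(),
                                clock="gap"),
    }
    return FittedMSCure(IncidenceModel(alpha, np.array([]), ()), trans,
                        pd.Series(dtype=float))


def test_e_step_censored_alive_bayes_ratio():
    # p=0.5, S1=0.9, S2=0.6 -> w = 0.3/0.75 = 0.4
    c = make_cohort([("a", 60.0, "female", "II", "no", "no", None, 10.0, 0, 10.0, 0)])
    cur = _manual_fit(0.5, 0.9, 0.6, 10.0)
    w = e_step(c, cur, pd.Series(["unknown"]))
    assert w[0] == pytest.approx(0.4, abs=1e-12)


def test_e_step_degenerate_prior():
    c = make_cohort([("a", 60.0, "female", "II", "no", "no", None, 10.0, 0, 10.0, 0)])
    cur = _manual_fit(1.0 - 1e-22, 0.9, 0.6, 10.0)
    w = e_step(c, cur, pd.Series(["unknown"]))
    assert w[0] == pytest.approx(1.0, abs=1e-9)


def test_e_step_dead_symmetric_is_half():
    # identical survivals and identical jump masses at the death time
    c = make_cohort([("a", 60.0, "female", "II", "no", "no", None, 10.0, 0, 10.0, 1)])
    cur = _manual_fit(0.5, 0.7, 0.7, 10.0, j14=0.2, j24=0.2)
    w = e_step(c, cur, pd.Series(["unknown"]), bandwidth=0.0)
    assert w[0] == pytest.approx(0.5, abs=1e-12)
    # the kernel-smoothed ratio preserves the symmetry
    w_s = e_step(c, cur, pd.Series(["unknown"]), bandwidth=6.0)
    assert w_s[0] == pytest.approx(0.5, abs=1e-12)


def test_e_step_zero_denominator_raises():
    from mscure.em import DegenerateWeightError
    c = make_cohort([("a", 60.0, "female", "II", "no", "no", None, 10.0, 0, 10.0, 1)])
    cur = _manual_fit(0.5, 0.7, 0.7, 10.0)  # no jump mass at t for either route
    # place jumps elsewhere so jump_at(10)=0 on both routes
    cur.transitions["1->4"].baseline.times[:] = [3.0]
    cur.transitions["2->4"].baseline.times[:] = [3.0]
    with pytest.raises(DegenerateWeightError):
        e_step(c, cur, pd.Series(["unknown"]), bandwidth=0.0)


# ----------------------------------------------------------------------
# weighted logistic M-step

class TestMStepIncidence:
    def test_intercept_only_balanced(self):
        m = m_step_incidence(np.empty((4, 0)), np.array([1.0, 1, 0, 0]))
        assert m.alpha == pytest.approx(0.0, abs=1e-9)

    def test_intercept_only_fractional(self):
        # sum w = 3, sum(1-w) = 1 -> alpha = log 3
        m = m_step_incidence(np.empty((4, 0)), np.array([1.0, 1, 0.5, 0.5]))
        assert m.alpha == pytest.approx(np.log(3.0), abs=1e-9)

    def test_binary_covariate_matches_2x2_table(self):
        # x=1: 6 of 10 "events"; x=0: 2 of 10 -> log OR = log(6*8/(4*2))
        x = np.array([1.0] * 10 + [0.0] * 10).reshape(-1, 1)
        w = np.array([1.0] * 6 + [0.0] * 4 + [1.0] * 2 + [0.0] * 8)
        m = m_step_incidence(x, w, names=("x",))
        assert m.gamma[0] == pytest.approx(np.log(6 * 8 / (4 * 2)), abs=1e-8)
        assert m.alpha == pytest.approx(np.log(2 / 8), abs=1e-8)

    def test_complete_separation_raises(self):
        from mscure.em import SeparationError
        x = np.array([0.0] * 5 + [1.0] * 5).reshape(-1, 1)
        w = np.array([0.0] * 5 + [1.0] * 5)
        with pytest.raises(SeparationError):
            m_step_incidence(x, w, names=("x",))


# ----------------------------------------------------------------------
# weighted Cox M-step

class TestMStepTransition:
    def test_breslow_increment_with_fractional_weights(self):
        # weights (1, .5, .5), one event at t=1, all at risk -> dL = 1/2
        tm, _ = m_step_transition("2->3", np.array([1.0, 2.0, 3.0]),
                                  np.array([1, 0, 0]), np.empty((3, 0)),
                                  np.array([1.0, 0.5, 0.5]))
        assert tm.baseline.times[0] == 1.0
        assert tm.baseline.increments[0] == pytest.approx(0.5)

    def test_reduces_to_nelson_aalen(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10, 40).round(1) + 0.1
        e = rng.random(40) < 0.7
        tm, _ = m_step_transition("2->3", t, e, np.empty((40, 0)), np.ones(40))
        # hand Nelson-Aalen with Breslow tie handling: d(tau)/n(tau)
        for tau, inc in zip(tm.baseline.times, tm.baseline.increments):
            d = np.sum((t == tau) & e)
            n = np.sum(t >= tau)
            assert inc == pytest.approx(d / n, rel=1e-12)

    def test_beta_matches_brute_force_maximizer(self):
        """n=20 toy with one binary covariate and fractional weights: the
        Newton estimate agrees with a scalar brute-force maximizer of the
        identical weighted partial likelihood."""
        rng = np.random.default_rng(42)
        t = rng.exponential(5, 20)
        e = rng.random(20) < 0.8
        x = (rng.random(20) < 0.5).astype(float)
        w = rng.uniform(0.2, 1.0, 20)
        tm, _ = m_step_transition("2->3", t, e, x.reshape(-1, 1), w, names=("x",))
        res = minimize_scalar(
            lambda b: -weighted_partial_loglik(np.array([b]), t, e,
                                               x.reshape(-1, 1), w),
            bounds=(-4, 4), method="bounded",
            options={"xatol": 1e-10})
        assert tm.beta[0] == pytest.approx(res.x, abs=1e-3)

    def test_constant_covariate_dropped(self):
        tm, dropped = m_step_transition(
            "2->4", np.array([1.0, 2, 3, 4]), np.array([1, 1, 0, 0]),
            np.column_stack([np.ones(4), [0, 1, 0, 1.0]]),
            np.ones(4), names=("const", "z"))
        assert dropped == ["const"]
        assert tm.names == ("z",)

    def test_zero_weight_subjects_ignored(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 1, 0, 1])
        x = np.array([[0.0], [1.0], [0.0], [1.0]])
        w_full = np.array([1.0, 1.0, 1.0, 0.0])
        tm1, _ = m_step_transition("2->3", t, e, x, w_full, names=("x",))
        tm2, _ = m_step_transition("2->3", t[:3], e[:3], x[:3], np.ones(3),
                                   names=("x",))
        assert tm1.beta[0] == pytest.approx(tm2.beta[0], abs=1e-10)

    def test_firth_shrinks_separated_fit(self):
        # all events in one group: plain ML diverges, Firth stays finite
        t = np.concatenate([np.random.default_rng(3).exponential(2, 15),
                            np.full(15, 30.0)])
        e = np.array([1] * 15 + [0] * 15)
        x = np.array([1.0] * 15 + [0.0] * 15).reshape(-1, 1)
        tm_f, _ = m_step_transition("2->3", t, e, x, np.ones(30), names=("x",),
                                    firth=True)
        assert np.isfinite(tm_f.beta[0]) and abs(tm_f.beta[0]) < 8


# ----------------------------------------------------------------------
# full EM fit

@pytest.fixture(scope="module")
def cohort500():
    return generate_cohort(500, default_truth(), seed=21)


def test_fully_labeled_em_is_one_pass_fixed_point(cohort500):
    cohort, lat = cohort500
    ks = pd.Series(np.where(lat["not_cured"], "not_cured", "cured"))
    cfg = FitConfig(n_boot=0, center_age=55.58)
    f1 = fit(cohort, FitConfig(n_boot=0, center_age=55.58, max_iter=1), known_status=ks)
    f2 = fit(cohort, cfg, known_status=ks)
    assert np.allclose(f1.incidence.gamma, f2.incidence.gamma, atol=1e-10)
    assert f1.incidence.alpha == pytest.approx(f2.incidence.alpha, abs=1e-10)
    for lab in mscure.TRANSITIONS:
        assert np.allclose(f1.transitions[lab].beta,
                           f2.transitions[lab].beta, atol=1e-10)


def test_known_status_weights_pinned(cohort500):
    cohort, _ = cohort500
    f = fit(cohort, FitConfig(n_boot=0, center_age=55.58))
    st = assign_known_status(cohort, 50.0)
    w = f.weights.to_numpy()
    assert np.all(w[(st == "not_cured").to_numpy()] == 1.0)
    assert np.all(w[(st == "cured").to_numpy()] == 0.0)


def test_loglik_trace_nondecreasing_over_random_cohorts():
    for seed in (31, 32, 33):
        cohort, _ = generate_cohort(350, default_truth(), seed=seed)
        f = fit(cohort, FitConfig(n_boot=0, center_age=55.58))
        tr = np.asarray(f.trace)
        assert len(tr) >= 2
        assert np.all(np.diff(tr) >= -1e-8), f"trace dipped for seed {seed}"


def test_age_centering_leaves_other_coefficients_unchanged(cohort500):
    cohort, _ = cohort500
    f_raw = fit(cohort, FitConfig(n_boot=0, center_age=None))
    f_cen = fit(cohort, FitConfig(n_boot=0, center_age=55.58))
    assert np.allclose(f_raw.incidence.gamma, f_cen.incidence.gamma, atol=1e-4)
    for lab in mscure.TRANSITIONS:
        assert np.allclose(f_raw.transitions[lab].beta,
                           f_cen.transitions[lab].beta, atol=1e-4)
    # intercepts differ by gamma_age * center
    g_age = f_cen.incidence.gamma[list(f_cen.incidence.names).index("age")]
    assert f_raw.incidence.alpha == pytest.approx(
        f_cen.incidence.alpha - g_age * 55.58, abs=1e-3)


def test_init_weight_sensitivity():
    """Starting the unknowns at 0.2 or 0.8 instead of 0.5 converges to
    essentially the same solution once the cohort is informative enough
    for stable latent attribution."""
    cohort, _ = generate_cohort(1500, default_truth(), seed=21)
    fits = [fit(cohort, FitConfig(n_boot=0, center_age=55.58, init_weight=iw))
            for iw in (0.2, 0.5, 0.8)]
    for f in fits[1:]:
        assert np.allclose(f.incidence.gamma, fits[0].incidence.gamma, atol=0.05)
        assert f.trace[-1] == pytest.approx(fits[0].trace[-1], abs=1.0)


def test_cure_forced_off_reduces_to_plain_cox(cohort500):
    """With every subject labelled not cured, the 2->3 submodel is an
    ordinary unweighted PH fit; cross-check against lifelines."""
    lifelines = pytest.importorskip("lifelines")
    cohort, _ = cohort500
    ks = pd.Series(["not_cured"] * len(cohort))
    cfg = FitConfig(n_boot=0, center_age=55.58, firth=False, time_grouping=None)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f = fit(cohort, cfg, known_status=ks)
    design = cohort.design(center_age=55.58)
    cols = list(cfg.covariates["2->3"])
    df = design[cols + ["t_rec", "d_rec"]]
    cph = lifelines.CoxPHFitter()
    cph.fit(df, duration_col="t_rec", event_col="d_rec")
    ours = f.transitions["2->3"].beta
    theirs = cph.params_[cols].to_numpy()
    assert np.allclose(ours, theirs, atol=1e-3)


def test_fitted_model_json_roundtrip(tmp_path, cohort500):
    cohort, _ = cohort500
    f = fit(cohort, FitConfig(n_boot=0, center_age=55.58))
    path = tmp_path / "fit.json"
    f.to_json(path)
    back = FittedMSCure.from_json(path)
    assert back.incidence.alpha == f.incidence.alpha
    assert np.array_equal(back.incidence.gamma, f.incidence.gamma)
    for lab in mscure.TRANSITIONS:
        assert np.array_equal(back.transitions[lab].beta,
                              f.transitions[lab].beta)
        assert np.array_equal(back.transitions[lab].baseline.times,
                              f.transitions[lab].baseline.times)
        assert np.array_equal(back.transitions[lab].baseline.increments,
                              f.transitions[lab].baseline.increments)
    assert np.array_equal(back.weights.to_numpy(), f.weights.to_numpy())
    assert back.age_center == f.age_center


def test_complete_data_loglik_maximised_at_fit(cohort500):
    """Given the converged weights, the reported parameters (near-)
    maximise the complete-data log-likelihood: perturbing any submodel's
    coefficients lowers it."""
    from mscure import complete_data_loglik
    import dataclasses
    cohort, _ = cohort500
    f = fit(cohort, FitConfig(n_boot=0, center_age=55.58))
    w = f.weights.to_numpy()
    base = complete_data_loglik(f, cohort, w)
    rng = np.random.default_rng(0)
    for _ in range(4):
        pert = {lab: dataclasses.replace(
            tm, beta=tm.beta + rng.normal(0, 0.3, len(tm.beta)))
            for lab, tm in f.transitions.items()}
        inc_p = dataclasses.replace(
            f.incidence, gamma=f.incidence.gamma + rng.normal(0, 0.3, 6))
        fp = FittedMSCure(inc_p, pert, f.weights, age_center=f.age_center)
        assert complete_data_loglik(fp, cohort, w) < base


def test_empty_transition_yields_empty_submodel():
    rows = [(f"s{i}", 60.0, "female", "II", "no", "no", None, 10.0 + i, 0,
             10.0 + i, 0) for i in range(8)]
    cohort = make_cohort(rows)
    with pytest.warns(UserWarning, match="no weighted events"):
        f = fit(cohort, FitConfig(n_boot=0, max_iter=2,
                                  covariates={k: () for k in
                                              ("incidence", "1->4", "2->4",
                                               "2->3", "3->4")}))
    assert len(f.transitions["3->4"].baseline.times) == 0
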