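"""Descriptive estimators and the end-to-end pipeline.

Kaplan–Meier and Aalen–Johansen estimators are implemented directly (the
test suite cross-checks them against an independent survival library);
``run_pipeline`` ties simulate -> fit -> predict -> report together and
writes CSV/JSON artifacts plus a MANIFEST.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import Cohort, read_cohort, write_cohort
from .em import FitConfig, bootstrap_ci, fit
from .model import FittedMSCure
from .predict import mean_profile, state_occupancy
from .simulate import TruthParams, default_truth, generate_cohort, truth_from_yaml

__all__ = [
    "StepCurve",
    "kaplan_meier",
    "cumulative_incidence",
    "follow_up_summary",
    "check_equal_censoring",
    "run_pipeline",
]


@dataclass
class StepCurve:
    """A right-continuous survival / incidence step curve.

    ``values[k]`` is the curve just after ``times[k]``; ``n_at_risk[k]``
    counts subjects with follow-up >= times[k].
    """

    times: np.ndarray
    values: np.ndarray
    n_at_risk: np.ndarray
    plateau: bool = False
    kind: str = "survival"  # "survival" falls from 1, "incidence" rises from 0

    def at(self, t) -> np.ndarray:
        """Right-continuous evaluation (value before the first jump is 1
        for survival curves, 0 for incidence curves)."""
        start = 0.0 if self.kind == "incidence" else 1.0
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        padded = np.concatenate(([start], self.values))
        return padded[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.times, "value": self.values,
                             "n_at_risk": self.n_at_risk})


def kaplan_meier(times, events, plateau_level: float = 0.2,
                 min_trailing_censored: int = 5) -> StepCurve:
    """Product-limit estimator.

    The plateau flag is a descriptive cure-model diagnostic: it is set
    when the final survival level exceeds ``plateau_level`` and at least
    ``min_trailing_censored`` subjects are censored beyond the last event.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    if len(times) == 0:
        raise ValueError("empty input")
    if np.any(times < 0) or not set(np.unique(events)) <= {0, 1}:
        raise ValueError("times must be >= 0 and events in {0, 1}")

    uniq = np.unique(times[events == 1])
    surv = []
    at_risk = []
    s = 1.0
    for tau in uniq:
        n = int(np.sum(times >= tau))
        d = int(np.sum((times == tau) & (events == 1)))
        s *= 1.0 - d / n
        surv.append(s)
        at_risk.append(n)
    last_event = uniq[-1] if len(uniq) else -np.inf
    trailing = int(np.sum((events == 0) & (times > last_event)))
    final = surv[-1] if surv else 1.0
    plateau = final > plateau_level and trailing >= min_trailing_censored
    return StepCurve(np.asarray(uniq, dtype=float), np.asarray(surv),
                     np.asarray(at_risk), plateau=plateau)


def cumulative_incidence(times, causes) -> dict[int, StepCurve]:
    """Aalen–Johansen cumulative incidence under competing risks.

    ``causes``: 0 = censored, positive integers = event types.  Returns
    one nondecreasing CIF per cause:
    ``CIF_k(t) = sum_{u <= t} S(u-) d_k(u) / n(u)`` with S the all-cause
    Kaplan–Meier estimator.
    """
    times = np.asarray(times, dtype=float)
    causes = np.asarray(causes).astype(int)
    if len(times) == 0:
        raise ValueError("empty input")
    if np.any(causes < 0):
        raise ValueError(f"unknown cause code(s): {sorted(set(causes[causes < 0]))}")
    cause_set = sorted(set(causes) - {0})

    uniq = np.unique(times[causes > 0])
    out = {k: ([], [], []) for k in cause_set}
    s_left = 1.0
    for tau in uniq:
        n = int(np.sum(times >= tau))
        d_all = int(np.sum((times == tau) & (causes > 0)))
        for k in cause_set:
            d_k = int(np.sum((times == tau) & (causes == k)))
            prev = out[k][1][-1] if out[k][1] else 0.0
            out[k][0].append(tau)
            out[k][1].append(prev + s_left * d_k / n)
            out[k][2].append(n)
        s_left *= 1.0 - d_all / n
    return {k: StepCurve(np.asarray(out[k][0]), np.asarray(out[k][1]),
                         np.asarray(out[k][2]), kind="incidence")
            for k in cause_set}


# ----------------------------------------------------------------------
# follow-up diagnostics

def follow_up_summary(cohort: Cohort) -> pd.DataFrame:
    """Per-subject follow-up lengths with the four marker categories:
    recurrence event, censored-for-recurrence, death event,
    censored-for-death (each subject shows one recurrence marker and one
    death marker)."""
    df = cohort.frame
    return pd.DataFrame({
        "id": df["id"],
        "follow_up": df["t_death"],
        "recurrence_event": df["d_rec"] == 1,
        "recurrence_censored": df["d_rec"] == 0,
        "recurrence_marker_time": df["t_rec"],
        "death_event": df["d_death"] == 1,
        "death_censored": df["d_death"] == 0,
        "death_marker_time": df["t_death"],
    })


def check_equal_censoring(cohort: Cohort) -> tuple[bool, list[str]]:
    """Verify the shared-censoring convention: subjects censored for
    recurrence must carry the death/censoring time as their recurrence
    censoring time.  Returns ``(ok, offending_ids)``."""
    df = cohort.frame
    bad = (df["d_rec"] == 0) & (df["t_rec"] != df["t_death"])
    return (not bad.any()), df.loc[bad, "id"].tolist()


# ----------------------------------------------------------------------
# optional plots (headless CSV outputs are canonical; plots are
# conveniences and need matplotlib)

def plot_descriptives(cohort: Cohort, path: str | Path) -> None:
    """Two-panel figure: KM curves for recurrence and death, and
    per-subject follow-up segments with event markers."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = cohort.frame
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    for label, times, events in (("recurrence", df["t_rec"], df["d_rec"]),
                                 ("death", df["t_death"], df["d_death"])):
        km = kaplan_meier(times, events)
        ax1.step(np.concatenate(([0], km.times)),
                 np.concatenate(([1.0], km.values)),
                 where="post", label=label)
    ax1.set_xlabel("months since resection")
    ax1.set_ylabel("survival probability")
    ax1.set_ylim(0, 1.02)
    ax1.legend()

    order = np.argsort(df["t_death"].to_numpy())
    y = np.arange(len(df))
    ax2.hlines(y, 0, df["t_death"].to_numpy()[order], lw=0.3, color="grey")
    rec = df["d_rec"].to_numpy()[order] == 1
    dead = df["d_death"].to_numpy()[order] == 1
    ax2.plot(df["t_rec"].to_numpy()[order][rec], y[rec], ".", ms=3,
             color="tab:blue", label="recurrence")
    ax2.plot(df["t_death"].to_numpy()[order][dead], y[dead], ".", ms=3,
             color="tab:red", label="death")
    ax2.set_xlabel("months since resection")
    ax2.set_ylabel("subject (sorted by follow-up)")
    ax2.legend(markerscale=3)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_occupancy(curves, path: str | Path) -> None:
    """Stacked state-occupancy probabilities plus OS/EFS curves."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    ax1.stackplot(curves.grid, curves.p4, curves.p3, curves.p2, curves.p1,
                  labels=["death", "recurrence", "not cured", "cured"],
                  alpha=0.8)
    ax1.set_xlabel("months since resection")
    ax1.set_ylabel("state occupancy probability")
    ax1.legend(loc="center right", fontsize=8)
    ax2.plot(curves.grid, curves.os, label="overall survival")
    ax2.plot(curves.grid, curves.efs, "--", label="event-free survival")
    ax2.set_xlabel("months since resection")
    ax2.set_ylim(0, 1.02)
    ax2.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ----------------------------------------------------------------------
# pipeline

def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run simulate/load -> fit -> predict -> describe and write artifacts.

    ``config`` keys:

    - ``simulate``: {n, seed, truth (optional YAML path)} or ``cohort``: CSV path
    - ``fit``: kwargs for :class:`FitConfig` (optional)
    - ``profile``: "mean" (default) or a mapping of covariate values
    - ``max_months``: prediction horizon (default 180)

    Writes cohort.csv, summary.json, km_recurrence.csv, km_death.csv,
    cif.csv, coefficients.csv, fit.json, curves.csv and MANIFEST.json.
    On failure, partial outputs are retained and the MANIFEST notes the
    failure point.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"package": "mscure", "version": __version__,
                      "python": platform.python_version(),
                      "artifacts": [], "status": "ok", "failed_stage": None}

    def save_manifest():
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=1))

    stage = "input"
    try:
        if "simulate" in config:
            sim = config["simulate"]
            truth = (truth_from_yaml(sim["truth"]) if sim.get("truth")
                     else default_truth())
            cohort, latent = generate_cohort(int(sim.get("n", 283)), truth,
                                             seed=int(sim.get("seed", 0)))
            latent.to_csv(out / "latent.csv", index=False)
            manifest["artifacts"].append("latent.csv")
            manifest["seed"] = int(sim.get("seed", 0))
        else:
            cohort = read_cohort(config["cohort"])
        write_cohort(cohort, out / "cohort.csv")
        manifest["artifacts"].append("cohort.csv")

        stage = "describe"
        df = cohort.frame
        km_rec = kaplan_meier(df["t_rec"], df["d_rec"])
        km_death = kaplan_meier(df["t_death"], df["d_death"])
        km_rec.to_frame().to_csv(out / "km_recurrence.csv", index=False)
        km_death.to_frame().to_csv(out / "km_death.csv", index=False)
        cause = np.where(df["d_rec"] == 1, 1, np.where(df["d_death"] == 1, 2, 0))
        t_first = np.where(df["d_rec"] == 1, df["t_rec"], df["t_death"])
        cifs = cumulative_incidence(t_first, cause)
        cif_frames = []
        for k, curve in cifs.items():
            fr = curve.to_frame()
            fr.insert(0, "cause", {1: "recurrence", 2: "death"}.get(k, str(k)))
            cif_frames.append(fr)
        (pd.concat(cif_frames) if cif_frames else pd.DataFrame(
            columns=["cause", "t", "value", "n_at_risk"])).to_csv(
                out / "cif.csv", index=False)
        ok, bad_ids = check_equal_censoring(cohort)
        summary = {
            "n": len(cohort),
            "n_recurrence": int(df["d_rec"].sum()),
            "n_death": int(df["d_death"].sum()),
            "recurrence_pct": round(100.0 * df["d_rec"].mean(), 4),
            "km_recurrence_plateau": bool(km_rec.plateau),
            "equal_censoring": ok,
            "equal_censoring_violations": bad_ids,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=1))
        manifest["artifacts"] += ["km_recurrence.csv", "km_death.csv",
                                  "cif.csv", "summary.json"]

        stage = "fit"
        fit_cfg = FitConfig(**config.get("fit", {}))
        fitted = fit(cohort, fit_cfg)
        table = bootstrap_ci(cohort, fit_cfg, base_fit=fitted)
        table.to_csv(out / "coefficients.csv", index=False)
        fitted.ci_table = table
        fitted.to_json(out / "fit.json")
        manifest["artifacts"] += ["coefficients.csv", "fit.json"]
        manifest["converged"] = bool(fitted.converged)
        manifest["em_iterations"] = int(fitted.n_iter)

        stage = "predict"
        profile_cfg = config.get("profile", "mean")
        profile = (mean_profile(cohort, center_age=fitted.age_center)
                   if profile_cfg == "mean" else pd.Series(profile_cfg, dtype=float))
        curves = state_occupancy(fitted, profile)
        horizon = float(config.get("max_months", 180.0))
        frame = curves.to_frame()
        frame[frame["t"] <= horizon].to_csv(out / "curves.csv", index=False)
        manifest["artifacts"].append("curves.csv")
    except Exception as exc:  # partial outputs retained
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        save_manifest()
        raise
    save_manifest()
    manifest["artifacts"].append("MANIFEST.json")
    return manifest
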