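"""Prospective validation of fixed-horizon risk predictions.

Discrimination uses a horizon-truncated Harrell concordance: usable pairs
are (case with event time <= horizon, comparator still event-free at that
time); follow-up is truncated at the horizon so the standard Harrell
estimator on the truncated data counts exactly those pairs.  Calibration
compares mean predicted risks per predicted-risk decile with Kaplan-Meier
observed risks (Greenwood/log-log intervals).  Recalibration rescales every
subject's cumulative hazard by a common factor so the overall expected
number of events matches the observed, leaving the risk ranking unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.utils import concordance_index
from scipy.optimize import brentq


class ValidationError(ValueError):
    pass


def _truncate(time, event, horizon):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if horizon <= 0:
        raise ValidationError("horizon must be > 0")
    t = np.minimum(time, horizon)
    e = np.where(time <= horizon, event, 0)
    return t, e


def concordance(time, event, risk, horizon, n_boot=0, seed=0, alpha=0.05):
    """Horizon-truncated C-index, optionally with a bootstrap CI.

    Ties in predicted risk count one half.  Returns ``(c, (lo, hi))``; the
    interval is ``(nan, nan)`` when ``n_boot == 0``.
    """
    t, e = _truncate(time, event, horizon)
    risk = np.asarray(risk, dtype=float)
    if e.sum() == 0:
        raise ValidationError("no usable pairs: no events within the horizon")
    c = concordance_index(t, -risk, e)
    lo = hi = np.nan
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = len(t)
        stats = []
        for _ in range(n_boot):
            i = rng.integers(0, n, size=n)
            if e[i].sum() == 0:
                continue
            stats.append(concordance_index(t[i], -risk[i], e[i]))
        lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return float(c), (float(lo), float(hi))


def _group_index(risk, n_groups):
    """Equal-count groups by predicted risk (0 = lowest)."""
    order = np.argsort(np.asarray(risk), kind="mergesort")
    g = np.empty(len(risk), dtype=int)
    g[order] = (np.arange(len(risk)) * n_groups) // len(risk)
    return g


def km_observed(time, event, horizon, alpha=0.05):
    """Kaplan-Meier failure probability at ``horizon`` with Greenwood
    (log-log) confidence interval."""
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(time, event)
    s = float(kmf.predict(horizon))
    ci = kmf.confidence_interval_
    idx = ci.index.to_numpy()
    row = ci.iloc[np.searchsorted(idx, horizon, side="right") - 1]
    return 1.0 - s, (1.0 - float(row.iloc[1]), 1.0 - float(row.iloc[0]))


def calibration(time, event, risk, horizon, n_groups=10):
    """Per-group calibration table: mean predicted vs KM observed risk."""
    if n_groups < 2:
        raise ValidationError("n_groups must be >= 2")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    risk = np.asarray(risk, dtype=float)
    if len(risk) < n_groups:
        raise ValidationError("fewer subjects than groups")
    g = _group_index(risk, n_groups)
    rows = []
    for k in range(n_groups):
        sel = g == k
        if not sel.any():
            raise ValidationError(f"group {k} has zero subjects")
        t, e = _truncate(time[sel], event[sel], horizon)
        obs, (lo, hi) = km_observed(t, e, horizon)
        pred = risk[sel].mean()
        rows.append({"group": k + 1, "n": int(sel.sum()),
                     "events": int(e.sum()), "mean_predicted": pred,
                     "km_observed": obs, "obs_ci_lo": lo, "obs_ci_hi": hi,
                     "o_over_e": obs / pred if pred > 0 else np.nan})
    return pd.DataFrame(rows)


def overall_o_over_e(time, event, risk, horizon):
    """Cohort-level observed (KM) over expected (mean predicted) risk."""
    t, e = _truncate(time, event, horizon)
    obs, _ = km_observed(t, e, horizon)
    exp = float(np.mean(risk))
    if exp <= 0:
        raise ValidationError("expected events are zero")
    return obs / exp


def recalibrate(time, event, risk, horizon):
    """Rescale risks on the cumulative-hazard scale to the observed level.

    Each risk is mapped ``r -> 1 - (1 - r)**c`` with a common exponent ``c``
    solved so that the mean recalibrated risk equals the KM-observed risk
    (``c`` equals the overall O/E ratio when risks are homogeneous; the
    root-solve makes the post-recalibration overall O/E exactly 1).
    Returns ``(adjusted_risks, info_dict)``.
    """
    risk = np.asarray(risk, dtype=float)
    t, e = _truncate(time, event, horizon)
    obs, _ = km_observed(t, e, horizon)
    exp = float(np.mean(risk))
    if exp <= 0:
        raise ValidationError("expected events are zero")
    oe = obs / exp
    if abs(oe - 1.0) < 1e-12:
        return risk.copy(), {"o_over_e": 1.0, "exponent": 1.0, "observed": obs,
                             "expected": exp}

    def gap(c):
        return float(np.mean(1.0 - (1.0 - risk) ** c)) - obs

    c = brentq(gap, 1e-6, 1e3, xtol=1e-12, rtol=1e-14)
    adj = 1.0 - (1.0 - risk) ** c
    return adj, {"o_over_e": oe, "exponent": float(c), "observed": obs,
                 "expected": exp}


def risk_classification(time, event, risk, horizon, quantiles=(0.01, 0.10, 0.50)):
    """Case capture, sensitivity and specificity at top risk quantiles."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    risk = np.asarray(risk, dtype=float)
    cases = (event == 1) & (time <= horizon)
    n = len(risk)
    n_cases = int(cases.sum())
    order = np.argsort(-risk, kind="mergesort")
    in_top = np.zeros(n, dtype=bool)
    rows = []
    for q in quantiles:
        if not (0 < q <= 1):
            raise ValidationError("quantiles must lie in (0, 1]")
        k = int(np.ceil(q * n))
        in_top[:] = False
        in_top[order[:k]] = True
        tp = int((cases & in_top).sum())
        fp = int((~cases & in_top).sum())
        sens = tp / n_cases if n_cases else np.nan
        spec = 1.0 - fp / max(1, n - n_cases)
        rows.append({"quantile": q, "n_top": k, "cases_captured": tp,
                     "capture_fraction": sens, "sensitivity": sens,
                     "specificity": spec})
    return pd.DataFrame(rows)


def impute_relative_dx_ages(records: pd.DataFrame, father_offset=28,
                            brother_offset=0, min_dx_age=40, max_dx_age=89):
    """Deterministically fill missing diagnosis ages of affected relatives.

    A relative's assumed current age is the consultand's baseline age plus a
    generational offset; the imputed diagnosis age is that age clamped to
    ``[min_dx_age, max_dx_age]`` (and to the relative's censoring age when
    known).  Stated ages are never changed and unaffected relatives are never
    invented.
    """
    out = records.copy()
    if "father_affected" in out and "father_dx_age" in out:
        need = (out["father_affected"] == 1) & out["father_dx_age"].isna()
        if need.any():
            age_now = out.loc[need, "baseline_age"] + father_offset
            out.loc[need, "father_dx_age"] = age_now.clip(min_dx_age, max_dx_age)
    if "brother_dx_ages" in out:
        def fix(row):
            v = row["brother_dx_ages"]
            if not isinstance(v, str) or "?" not in v:
                return v
            rep = int(np.clip(row["baseline_age"] + brother_offset,
                              min_dx_age, max_dx_age))
            return ";".join(str(rep) if x == "?" else x for x in v.split(";"))

        out["brother_dx_ages"] = out.apply(fix, axis=1)
    return out


def plot_calibration(table, ax=None, title=None):
    """Calibration panel: mean predicted vs KM observed risk per group,
    with the observed intervals and the identity line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = 100 * table["mean_predicted"].to_numpy()
    y = 100 * table["km_observed"].to_numpy()
    ylo = 100 * table["obs_ci_lo"].to_numpy()
    yhi = 100 * table["obs_ci_hi"].to_numpy()
    ax.errorbar(x, y, yerr=[y - ylo, yhi - y], fmt="o", capsize=3)
    lim = max(x.max(), yhi.max()) * 1.05
    ax.plot([0, lim], [0, lim], color="grey", lw=1)
    ax.set_xlabel("mean predicted risk (%)")
    ax.set_ylabel("observed risk, Kaplan-Meier (%)")
    if title:
        ax.set_title(title)
    return ax


@dataclass
class ValidationReport:
    """Collected validation metrics for one cohort."""

    horizons: tuple
    n_subjects: int
    n_events: dict
    c_index: dict = field(default_factory=dict)          # (level, horizon) -> (c, ci)
    calibration_tables: dict = field(default_factory=dict)
    recalibrated_tables: dict = field(default_factory=dict)
    o_over_e: dict = field(default_factory=dict)
    recalibration: dict = field(default_factory=dict)
    capture_tables: dict = field(default_factory=dict)

    def to_dict(self):
        return {
            "horizons": list(self.horizons),
            "n_subjects": self.n_subjects,
            "n_events": {str(k): v for k, v in self.n_events.items()},
            "c_index": {f"{lvl}_{h}y": {"c": c, "ci": list(ci)}
                        for (lvl, h), (c, ci) in self.c_index.items()},
            "o_over_e": {f"{h}y": v for h, v in self.o_over_e.items()},
            "recalibration": {f"{h}y": v for h, v in self.recalibration.items()},
            "calibration": {f"{h}y": t.to_dict(orient="records")
                            for h, t in self.calibration_tables.items()},
            "calibration_recalibrated": {f"{h}y": t.to_dict(orient="records")
                                         for h, t in self.recalibrated_tables.items()},
            "risk_classification": {f"{h}y": t.to_dict(orient="records")
                                    for h, t in self.capture_tables.items()},
        }

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def validate_cohort(records: pd.DataFrame, predictions: dict, horizons=(5, 10),
                    n_groups=10, quantiles=(0.01, 0.10, 0.50), n_boot=0,
                    seed=0) -> ValidationReport:
    """Full validation battery.

    ``predictions`` maps information level (e.g. 'age', 'full') to a
    DataFrame with ``risk_{h}`` columns as produced by
    :func:`canpros.predict.predict_cohort`; discrimination is reported for
    every level, calibration/recalibration/classification for 'full' (or the
    only level given).
    """
    time = records["time"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=int)
    main = "full" if "full" in predictions else next(iter(predictions))
    rep = ValidationReport(
        horizons=tuple(horizons), n_subjects=len(records),
        n_events={h: int(((event == 1) & (time <= h)).sum()) for h in horizons})
    for lvl, df in predictions.items():
        for h in horizons:
            risk = df[f"risk_{h}"].to_numpy(dtype=float)
            rep.c_index[(lvl, h)] = concordance(time, event, risk, h,
                                                n_boot=n_boot if lvl == main else 0,
                                                seed=seed)
    for h in horizons:
        risk = predictions[main][f"risk_{h}"].to_numpy(dtype=float)
        rep.calibration_tables[h] = calibration(time, event, risk, h, n_groups)
        rep.o_over_e[h] = overall_o_over_e(time, event, risk, h)
        adj, info = recalibrate(time, event, risk, h)
        rep.recalibration[h] = info
        rep.recalibrated_tables[h] = calibration(time, event, adj, h, n_groups)
        rep.capture_tables[h] = risk_classification(time, event, risk, h, quantiles)
    return rep
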