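"""Per-circuit survival association of signaling activity.

Builds censored overall-survival records from clinical metadata (time = max
of days-to-death and days-to-last-follow-up, event = vital status), fits one
univariate Cox proportional-hazards model per circuit (Efron tie handling),
tests the PH assumption on scaled Schoenfeld residuals against Kaplan-Meier
transformed time, adjusts Wald p-values with Benjamini-Hochberg, and groups
samples into high/low activity at +/-0.5 activity z-score for Kaplan-Meier
curves with a log-rank test.
"""

from __future__ import annotations

import logging
import warnings
from typing import NamedTuple

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test, proportional_hazard_test

from .differential import bh_adjust
from .propagation import ActivityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalReport",
    "build_survival",
    "cox_per_circuit",
    "zph_test",
    "km_groups",
    "km_estimate",
]

_DEAD_TOKENS = {"dead", "deceased"}
_ALIVE_TOKENS = {"alive", "living"}


class SurvivalReport(NamedTuple):
    records: pd.DataFrame  # sample_id, time, event
    n_dropped: int


def _parse_days(x) -> float:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return np.nan
    s = str(x).strip()
    if s == "" or s.lower() in {"na", "nan", "none"}:
        return np.nan
    return float(s)


def build_survival(clinical: pd.DataFrame) -> SurvivalReport:
    """Censored survival records from a clinical table.

    Expects columns ``sample_id``, ``days_to_death``,
    ``days_to_last_follow_up`` and ``vital_status``; either day field may be
    missing per row.  time = max of the available day fields; rows with no
    usable positive time are dropped (count reported).
    """
    required = {"sample_id", "days_to_death", "days_to_last_follow_up", "vital_status"}
    missing = required - set(clinical.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    rows, dropped = [], 0
    for _, row in clinical.iterrows():
        status = str(row["vital_status"]).strip().lower()
        if status in _DEAD_TOKENS:
            event = True
        elif status in _ALIVE_TOKENS:
            event = False
        else:
            raise ValueError(f"unparseable vital_status token {row['vital_status']!r}")
        days = [
            _parse_days(row["days_to_death"]),
            _parse_days(row["days_to_last_follow_up"]),
        ]
        time = np.nanmax(days) if not all(np.isnan(d) for d in days) else np.nan
        if np.isnan(time) or time <= 0:
            dropped += 1
            continue
        rows.append({"sample_id": row["sample_id"], "time": float(time), "event": event})
    if dropped:
        logger.info("build_survival: dropped %d rows without usable time", dropped)
    records = pd.DataFrame(rows, columns=["sample_id", "time", "event"])
    return SurvivalReport(records=records, n_dropped=dropped)


def _fit_frame(activity: np.ndarray, records: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time": records["time"].to_numpy(dtype=float),
            "event": records["event"].to_numpy(dtype=bool),
            "activity": activity,
        }
    )


def zph_test(fit: CoxPHFitter, df: pd.DataFrame) -> float:
    """PH-assumption p-value: score test for zero slope of scaled Schoenfeld
    residuals against Kaplan-Meier transformed time."""
    if int(df["event"].sum()) < 3:
        raise ValueError("PH diagnostic needs at least 3 events")
    res = proportional_hazard_test(fit, df, time_transform="km")
    return float(np.asarray(res.p_value).ravel()[0])


def cox_per_circuit(
    activity: ActivityMatrix | pd.DataFrame,
    records: pd.DataFrame,
    standardize: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Univariate Cox fit per circuit with BH correction across circuits.

    Returns a table with hazard ratio, 95% CI, Harrell's concordance, Wald p,
    BH FDR and the PH-diagnostic p.  Constant-activity (or non-converging)
    circuits are kept with hr=NaN and p=1 so BH denominators stay
    reproducible.  ``standardize`` fits on activity z-scores.
    """
    values = activity.values if isinstance(activity, ActivityMatrix) else activity
    common = [s for s in values.columns if s in set(records["sample_id"])]
    if len(common) < 3:
        raise ValueError("fewer than 3 samples shared between activity and survival")
    rec = records.set_index("sample_id").loc[common]
    if int(rec["event"].sum()) < 2:
        raise ValueError("need at least 2 observed events")
    rows = []
    for cid in values.index:
        x = values.loc[cid, common].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            rows.append(
                {"circuit_id": cid, "hr": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                 "concordance": np.nan, "p": 1.0, "p_zph": np.nan, "flag": "constant"}
            )
            continue
        if standardize:
            x = (x - x.mean()) / sd
        df = _fit_frame(x, rec.reset_index())
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph = CoxPHFitter()
                cph.fit(df, duration_col="time", event_col="event")
            summ = cph.summary.loc["activity"]
            try:
                p_zph = zph_test(cph, df)
            except Exception:
                p_zph = np.nan
            with np.errstate(over="ignore"):  # extreme HRs on unstandardized scales
                hr, lo, hi = np.exp(
                    [summ["coef"], summ["coef lower 95%"], summ["coef upper 95%"]]
                )
            rows.append(
                {
                    "circuit_id": cid,
                    "hr": float(hr),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                    "concordance": float(cph.concordance_index_),
                    "p": float(summ["p"]),
                    "p_zph": p_zph,
                    "flag": "",
                }
            )
        except (ConvergenceError, np.linalg.LinAlgError) as exc:
            logger.warning("Cox fit failed for %s: %s", cid, exc)
            rows.append(
                {"circuit_id": cid, "hr": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                 "concordance": np.nan, "p": 1.0, "p_zph": np.nan, "flag": "no_convergence"}
            )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["fdr"] < alpha
    cols = ["circuit_id", "hr", "ci_low", "ci_high", "concordance", "p", "fdr", "p_zph", "flag", "significant"]
    return out[cols]


def km_groups(activity_row: pd.Series, cutoff_z: float = 0.5) -> pd.Series:
    """Label samples high / low / excluded by activity z-score at +/-cutoff_z."""
    x = activity_row.to_numpy(dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zero-variance activity; groups undefined")
    z = (x - x.mean()) / sd
    labels = np.where(z > cutoff_z, "high", np.where(z < -cutoff_z, "low", "excluded"))
    out = pd.Series(labels, index=activity_row.index, name="km_group")
    if (out == "excluded").all():
        logger.warning("all samples fall inside (-%.2g, +%.2g); no KM groups", cutoff_z, cutoff_z)
    return out


def km_estimate(
    groups: pd.Series,
    records: pd.DataFrame,
) -> tuple[dict[str, pd.DataFrame], float]:
    """Product-limit survival curve per group and the high-vs-low log-rank p.

    Each curve is a table (time, at_risk, survival).  An empty group's curve
    is omitted and the log-rank p is NaN; p is also NaN without any event.
    """
    rec = records.set_index("sample_id")
    curves: dict[str, pd.DataFrame] = {}
    parts: dict[str, pd.DataFrame] = {}
    for label in ("high", "low"):
        samples = [s for s in groups.index[groups == label] if s in rec.index]
        if not samples:
            continue
        sub = rec.loc[samples]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"], label=label)
        table = kmf.event_table
        surv = kmf.survival_function_[label]
        curves[label] = pd.DataFrame(
            {
                "time": table.index.to_numpy(dtype=float),
                "at_risk": table["at_risk"].to_numpy(dtype=float),
                "survival": surv.reindex(table.index).to_numpy(dtype=float),
            }
        )
        parts[label] = sub
    if len(parts) < 2:
        return curves, float("nan")
    pooled_events = sum(int(p["event"].sum()) for p in parts.values())
    if pooled_events < 1:
        return curves, float("nan")
    res = logrank_test(
        parts["high"]["time"], parts["low"]["time"],
        event_observed_A=parts["high"]["event"], event_observed_B=parts["low"]["event"],
    )
    return curves, float(res.p_value)
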