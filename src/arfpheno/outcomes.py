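"""28-day outcome analysis: Kaplan-Meier survival, log-rank, VFD.

Survival is measured from the index intubation time and administratively
censored at 28 days. Encounters discharged alive before day 28 are censored
at discharge by default (conservative); set ``assume_alive_post_discharge``
to treat them as alive through day 28. Ventilator-free days use the
critical-care convention: 0 for anyone dead by day 28, otherwise 28 minus
days ventilated, requiring a sustained (>= 48 h) extubation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

HORIZON_DAYS = 28.0


def survival_records(cohort: pd.DataFrame, stream, truth: pd.DataFrame | None = None,
                     assume_alive_post_discharge: bool = False) -> pd.DataFrame:
    """Per-encounter (duration, event) records from index time.

    Returns a frame indexed by encounter_id with duration_days, event,
    plus ventilation bookkeeping columns.
    """
    meta = stream.metadata.set_index("encounter_id")
    rows = {}
    eps = stream.episodes.groupby("encounter_id")
    for enc, idx_t in cohort["index_time"].items():
        death = meta.at[enc, "death_time"]
        disc = meta.at[enc, "discharge_time"]
        if pd.notna(death):
            t = (death - idx_t) / 24.0
            if t < 0:
                raise ValueError(f"negative time-to-event for {enc}")
            event, dur = (1, min(t, HORIZON_DAYS)) if t <= HORIZON_DAYS else (0, HORIZON_DAYS)
        elif pd.notna(disc) and not assume_alive_post_discharge:
            t = max((disc - idx_t) / 24.0, 0.0)
            event, dur = 0, min(t, HORIZON_DAYS)
        else:
            event, dur = 0, HORIZON_DAYS
        vent_days = 0.0
        if enc in eps.groups:
            iv = eps.get_group(enc)[["start_hours", "stop_hours"]].to_numpy()
            lo = idx_t
            hi = idx_t + HORIZON_DAYS * 24.0
            clipped = np.clip(iv, lo, hi)
            vent_days = float(np.sum(np.maximum(clipped[:, 1] - clipped[:, 0], 0)) / 24.0)
        rows[enc] = {"duration_days": dur, "event": event, "vent_days": vent_days,
                     "index_time": idx_t}
    return pd.DataFrame(rows).T.rename_axis("encounter_id")


def km_estimate(durations, events, alpha: float = 0.05) -> pd.DataFrame:
    """Product-limit survival estimate with Greenwood confidence bands.

    Returns a frame with time, survival, ci_lower, ci_upper.
    """
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events)
    if durations.size == 0:
        raise ValueError("km_estimate requires >= 1 record")
    if (durations < 0).any():
        raise ValueError("negative durations")
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(durations, events)
    sf = kmf.survival_function_
    ci = kmf.confidence_interval_
    out = pd.DataFrame(
        {
            "time": sf.index.to_numpy(),
            "survival": sf.iloc[:, 0].to_numpy(),
            "ci_lower": ci.iloc[:, 0].to_numpy(),
            "ci_upper": ci.iloc[:, 1].to_numpy(),
        }
    )
    return out


def survival_at(km: pd.DataFrame, t: float) -> float:
    """Step-function evaluation of a km_estimate frame at time t."""
    below = km[km["time"] <= t]
    return float(below["survival"].iloc[-1]) if len(below) else 1.0


def logrank(durations, events, groups) -> tuple[float, float]:
    """k-group log-rank statistic and p (chi-squared, k-1 df)."""
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise ValueError("log-rank requires >= 2 groups")
    res = multivariate_logrank_test(
        np.asarray(durations, dtype=float), groups, np.asarray(events)
    )
    return float(res.test_statistic), float(res.p_value)


def vfd28(records: pd.DataFrame) -> pd.Series:
    """Ventilator-free days in the first 28 days, per encounter.

    0 if dead by day 28; otherwise 28 - days ventilated, but 0 when the
    final extubation is not sustained >= 48 h before the horizon.
    """
    out = {}
    for enc, r in records.iterrows():
        if r["event"] == 1:
            out[enc] = 0.0
            continue
        vent = float(r["vent_days"])
        free = max(HORIZON_DAYS - vent, 0.0)
        # sustained-extubation requirement: at least 48 h free of the vent
        out[enc] = free if free >= 2.0 else 0.0
    return pd.Series(out, name="vfd28").rename_axis("encounter_id")


def vfd_by_group(records: pd.DataFrame, groups: pd.Series) -> pd.Series:
    """Mean VFD per phenotype."""
    v = vfd28(records)
    return v.groupby(groups.loc[v.index]).mean()


def outcome_summary(records: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-phenotype 28-day mortality, mean VFD and KM S(28)."""
    rows = {}
    for g, idx in groups.loc[records.index].groupby(groups).groups.items():
        rec = records.loc[idx]
        km = km_estimate(rec["duration_days"], rec["event"])
        rows[g] = {
            "n": len(rec),
            "mortality_28d": float(rec["event"].mean()),
            "mean_vfd": float(vfd28(rec).mean()),
            "km_s28": survival_at(km, HORIZON_DAYS),
        }
    return pd.DataFrame(rows).T
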