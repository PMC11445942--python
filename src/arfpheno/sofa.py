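"""SOFA scoring and EMR sepsis-3 onset detection.

Four steps: (a) six organ-system SOFA subscores from a bundled rubric table,
(b) infection-suspicion time from paired antibiotic/blood-culture events,
(c) acute total-SOFA increase of >= 2 over a pre-window baseline, and
(d) onset assignment inside a window around the suspicion time.

Components with no available inputs score 0 (no presumed pre-existing organ
dysfunction); inputs are carried forward on the scoring grid within a bounded
staleness horizon (default 24 h labs, 8 h vitals).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import sofa_rubric

COMPONENTS = ("respiration", "coagulation", "hepatic", "cardiovascular", "cns", "renal")

#: carry-forward staleness horizon per SOFA input variable, hours
DEFAULT_STALENESS = {
    "pf_ratio": 24.0,
    "platelets": 24.0,
    "bilirubin_total": 24.0,
    "creatinine": 24.0,
    "map": 8.0,
    "gcs_total": 24.0,
    "norepinephrine": 8.0,
    "epinephrine": 8.0,
    "dopamine": 8.0,
    "dobutamine": 8.0,
}

_NONNEG = {"pf_ratio", "platelets", "bilirubin_total", "creatinine", "map",
           "norepinephrine", "epinephrine", "dopamine", "dobutamine"}


@dataclass(frozen=True)
class SofaComponents:
    time: float
    respiration: int
    coagulation: int
    hepatic: int
    cardiovascular: int
    cns: int
    renal: int

    @property
    def total(self) -> int:
        return (self.respiration + self.coagulation + self.hepatic
                + self.cardiovascular + self.cns + self.renal)


@dataclass(frozen=True)
class SuspicionEvent:
    time: float
    trigger: str  # "abx_then_culture" or "culture_then_abx"


@dataclass(frozen=True)
class SepsisOnset:
    onset_time: float | None
    suspicion: SuspicionEvent | None
    delta_sofa: int


class _Rubric:
    def __init__(self, table: pd.DataFrame | None = None):
        self.table = sofa_rubric() if table is None else table

    def score(self, component: str, obs: dict[str, float], ventilated: bool) -> int:
        best = 0
        rows = self.table[self.table["component"] == component]
        for r in rows.itertuples():
            if r.requires_ventilation and not ventilated:
                continue
            v = obs.get(r.variable)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                continue
            hit = {"lt": v < r.threshold, "le": v <= r.threshold,
                   "gt": v > r.threshold, "ge": v >= r.threshold}[r.op]
            if hit:
                best = max(best, int(r.score))
        return best


_DEFAULT_RUBRIC = None


def _rubric() -> _Rubric:
    global _DEFAULT_RUBRIC
    if _DEFAULT_RUBRIC is None:
        _DEFAULT_RUBRIC = _Rubric()
    return _DEFAULT_RUBRIC


def score_sofa(observations: dict[str, float], ventilated: bool = False,
               time: float = 0.0, rubric: pd.DataFrame | None = None) -> SofaComponents:
    """Score the six SOFA components from a snapshot of observations.

    ``observations`` maps variable name -> value; vasopressor doses are in
    ug/kg/min. Missing inputs score 0 for their component.
    """
    for k, v in observations.items():
        if k in _NONNEG and v is not None and not np.isnan(v) and v < 0:
            raise ValueError(f"negative value for {k}: {v}")
    rb = _rubric() if rubric is None else _Rubric(rubric)
    scores = {c: rb.score(c, observations, ventilated) for c in COMPONENTS}
    return SofaComponents(time=time, **scores)


def sofa_track_frame(events: pd.DataFrame, episodes: pd.DataFrame,
                     resolution: float = 1.0,
                     staleness: dict[str, float] | None = None) -> pd.DataFrame:
    """Vectorized per-hour SOFA for every encounter in an event table.

    Returns a frame with encounter_id, time_hours, the six components and
    ``total``. Inputs are last-observation-carried-forward on the grid within
    the per-variable staleness horizon.
    """
    stale = DEFAULT_STALENESS if staleness is None else staleness
    sofa_vars = list(stale)
    ev = events[events["variable"].isin(sofa_vars)]
    if ev.empty:
        return pd.DataFrame(
            columns=["encounter_id", "time_hours", *COMPONENTS, "total"]
        )
    ev = ev.copy()
    ev["grid_t"] = np.ceil(ev["time_hours"] / resolution) * resolution

    spans = ev.groupby("encounter_id")["grid_t"].agg(["min", "max"])
    grids = []
    for enc, (lo, hi) in spans.iterrows():
        t = np.arange(lo, hi + resolution / 2, resolution)
        grids.append(pd.DataFrame({"encounter_id": enc, "time_hours": t}))
    grid = pd.concat(grids, ignore_index=True)

    # last value per (enc, grid step, variable), then carry forward with limit
    last = (
        ev.sort_values(["encounter_id", "variable", "time_hours"], kind="mergesort")
        .groupby(["encounter_id", "grid_t", "variable"], sort=True)["value"]
        .last()
        .unstack("variable")
    )
    last.index = last.index.set_names(["encounter_id", "time_hours"])
    wide = grid.set_index(["encounter_id", "time_hours"]).join(last)
    wide = wide.sort_index()
    filled = {}
    for var in wide.columns:
        limit = max(int(round(stale.get(var, 24.0) / resolution)), 0)
        filled[var] = wide[var].groupby(level="encounter_id").ffill(limit=limit)
    w = pd.DataFrame(filled, index=wide.index)

    # ventilation status per grid point (join on encounter, check intervals)
    vent = np.zeros(len(w), dtype=bool)
    if episodes is not None and len(episodes):
        idxf = w.index.to_frame(index=False)
        idxf["_row"] = np.arange(len(idxf))
        m = idxf.merge(episodes, on="encounter_id", how="left")
        on = (m["time_hours"] >= m["start_hours"]) & (m["time_hours"] < m["stop_hours"])
        hit = m.loc[on.fillna(False), "_row"].unique()
        vent[hit] = True

    comp = pd.DataFrame(index=w.index)
    get = lambda v: w[v].to_numpy() if v in w.columns else np.full(len(w), np.nan)
    pf, plt_, bili = get("pf_ratio"), get("platelets"), get("bilirubin_total")
    mapv, gcs, cre = get("map"), get("gcs_total"), get("creatinine")
    nor, epi, dop, dob = (get("norepinephrine"), get("epinephrine"),
                          get("dopamine"), get("dobutamine"))

    resp = np.select(
        [pf < 100, pf < 200, pf < 300, pf < 400],
        [np.where(vent, 4, 2), np.where(vent, 3, 2), 2, 1], default=0,
    )
    resp = np.where(np.isnan(pf), 0, resp)
    coag = np.select([plt_ < 20, plt_ < 50, plt_ < 100, plt_ < 150], [4, 3, 2, 1], 0)
    coag = np.where(np.isnan(plt_), 0, coag)
    hep = np.select([bili >= 12, bili >= 6, bili >= 2, bili >= 1.2], [4, 3, 2, 1], 0)
    hep = np.where(np.isnan(bili), 0, hep)
    high_p = (np.nan_to_num(dop) > 15) | (np.nan_to_num(nor) > 0.1) | (np.nan_to_num(epi) > 0.1)
    mid_p = (np.nan_to_num(dop) > 5) | (np.nan_to_num(nor) > 0) | (np.nan_to_num(epi) > 0)
    low_p = (np.nan_to_num(dop) > 0) | (np.nan_to_num(dob) > 0)
    cardio = np.select([high_p, mid_p, low_p, mapv < 70], [4, 3, 2, 1], 0)
    cns = np.select([gcs < 6, gcs <= 9, gcs <= 12, gcs <= 14], [4, 3, 2, 1], 0)
    cns = np.where(np.isnan(gcs), 0, cns)
    ren = np.select([cre >= 5, cre >= 3.5, cre >= 2, cre >= 1.2], [4, 3, 2, 1], 0)
    ren = np.where(np.isnan(cre), 0, ren)

    comp["respiration"], comp["coagulation"], comp["hepatic"] = resp, coag, hep
    comp["cardiovascular"], comp["cns"], comp["renal"] = cardio, cns, ren
    comp["total"] = resp + coag + hep + cardio + cns + ren
    return comp.astype(int).reset_index()


def sofa_track(stream, encounter_id: str, resolution: float = 1.0,
               staleness: dict[str, float] | None = None) -> list[SofaComponents]:
    """Hourly SOFA series for one encounter (empty input -> empty track)."""
    ev = stream.events[stream.events["encounter_id"] == encounter_id]
    ep = stream.episodes[stream.episodes["encounter_id"] == encounter_id]
    frame = sofa_track_frame(ev, ep, resolution=resolution, staleness=staleness)
    return [
        SofaComponents(
            time=float(r.time_hours), respiration=int(r.respiration),
            coagulation=int(r.coagulation), hepatic=int(r.hepatic),
            cardiovascular=int(r.cardiovascular), cns=int(r.cns), renal=int(r.renal),
        )
        for r in frame.itertuples()
    ]


def windowed_max(track: list[SofaComponents], start: float, stop: float) -> dict[str, int]:
    """Per-component maximum over [start, stop] (the track aggregation rule)."""
    agg = {c: 0 for c in COMPONENTS}
    for s in track:
        if start <= s.time <= stop:
            for c in COMPONENTS:
                agg[c] = max(agg[c], getattr(s, c))
    agg["total"] = sum(agg[c] for c in COMPONENTS)
    return agg


def find_suspicion(abx_times, culture_times,
                   abx_to_culture_h: float = 24.0,
                   culture_to_abx_h: float = 72.0) -> SuspicionEvent | None:
    """Earliest qualifying antibiotic/blood-culture pair.

    A pair qualifies when the culture follows antibiotics within
    ``abx_to_culture_h`` or antibiotics follow the culture within
    ``culture_to_abx_h``; suspicion time is the earlier member.
    """
    best: SuspicionEvent | None = None
    for a in abx_times:
        for c in culture_times:
            if a <= c <= a + abx_to_culture_h:
                cand = SuspicionEvent(time=float(a), trigger="abx_then_culture")
            elif c <= a <= c + culture_to_abx_h:
                cand = SuspicionEvent(time=float(c), trigger="culture_then_abx")
            else:
                continue
            if best is None or cand.time < best.time:
                best = cand
    return best


def detect_sepsis3(track, suspicion: SuspicionEvent | None,
                   window_before_h: float = 48.0,
                   window_after_h: float = 24.0,
                   baseline_h: float = 24.0) -> SepsisOnset:
    """Earliest time in the suspicion window with total SOFA >= baseline + 2.

    Baseline is the minimum total over the ``baseline_h`` hours preceding the
    search window, or 0 when no prior data exist (no presumed pre-existing
    dysfunction). ``track`` may be a list of SofaComponents or a frame with
    time_hours/total columns.
    """
    if suspicion is None:
        return SepsisOnset(onset_time=None, suspicion=None, delta_sofa=0)
    if isinstance(track, pd.DataFrame):
        times = track["time_hours"].to_numpy(dtype=float)
        totals = track["total"].to_numpy(dtype=float)
    else:
        times = np.array([s.time for s in track], dtype=float)
        totals = np.array([s.total for s in track], dtype=float)
    if np.any(np.diff(times) < 0):
        raise ValueError("track must be time-ordered")
    lo = suspicion.time - window_before_h
    hi = suspicion.time + window_after_h
    pre = (times >= lo - baseline_h) & (times < lo)
    baseline = float(totals[pre].min()) if pre.any() else 0.0
    inwin = (times >= lo) & (times <= hi)
    if not inwin.any():
        return SepsisOnset(onset_time=None, suspicion=suspicion, delta_sofa=0)
    delta = totals[inwin] - baseline
    hits = np.where(delta >= 2)[0]
    if hits.size == 0:
        return SepsisOnset(onset_time=None, suspicion=suspicion,
                           delta_sofa=int(delta.max()))
    t_in = times[inwin]
    return SepsisOnset(onset_time=float(t_in[hits[0]]), suspicion=suspicion,
                       delta_sofa=int(delta[hits[0]]))


def detect_cohort_sepsis(stream, resolution: float = 1.0) -> pd.DataFrame:
    """Sepsis-3 onsets for every encounter in a stream.

    Returns a frame indexed by encounter_id with suspicion_time, onset_time
    and delta_sofa (NaN onset when criteria not met).
    """
    tracks = sofa_track_frame(stream.events, stream.episodes, resolution=resolution)
    micro = stream.micro
    rows = []
    grouped = dict(tuple(tracks.groupby("encounter_id"))) if len(tracks) else {}
    for enc in stream.metadata["encounter_id"]:
        m = micro[micro["encounter_id"] == enc]
        susp = find_suspicion(
            m.loc[m["kind"] == "antibiotic", "time_hours"].to_numpy(),
            m.loc[m["kind"] == "blood_culture", "time_hours"].to_numpy(),
        )
        trk = grouped.get(enc)
        if trk is None or susp is None:
            onset = SepsisOnset(None, susp, 0)
        else:
            onset = detect_sepsis3(trk.sort_values("time_hours"), susp)
        rows.append(
            {
                "encounter_id": enc,
                "suspicion_time": susp.time if susp else np.nan,
                "onset_time": onset.onset_time if onset.onset_time is not None else np.nan,
                "delta_sofa": onset.delta_sofa,
            }
        )
    return pd.DataFrame(rows).set_index("encounter_id")
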