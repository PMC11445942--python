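"""Study cohort construction: index IMV time, inclusion rules, 24-h window.

The index event is the first recorded ventilation parameter (PEEP, tidal
volume or plateau pressure); for surgical ICU encounters it is the first
such record at or after 48 h past surgery completion. Inclusion rules are
applied in a documented order and the first failing rule is recorded as the
exclusion reason. The pre-intubation observation window is the half-open
interval (index - 24 h, index].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

VENT_PARAM_VARS = ("peep", "tidal_volume", "plateau_pressure")

#: rule order; the first failure becomes the exclusion reason
RULE_ORDER = (
    "age",
    "sepsis3",
    "icu_type",
    "index_time",
    "imv_duration",
    "pre_index_data",
    "ed_initiated",
)

WINDOW_HOURS = 24.0


@dataclass(frozen=True)
class IndexedEncounter:
    encounter_id: str
    index_time: float | None
    icu_type: str
    included: bool
    exclusion_reason: str | None

    @property
    def window(self) -> tuple[float, float] | None:
        """Half-open (index - 24, index]."""
        if self.index_time is None:
            return None
        return (self.index_time - WINDOW_HOURS, self.index_time)


def find_index_time(meta_row: pd.Series, vent_param_times: np.ndarray) -> float | None:
    """Index IMV time for one encounter, or None if no qualifying record."""
    t = np.sort(np.asarray(vent_param_times, dtype=float))
    if t.size == 0:
        return None
    if meta_row["icu_type"] == "SICU":
        surg = meta_row.get("surgery_end_time")
        if surg is None or (isinstance(surg, float) and np.isnan(surg)):
            raise ValueError(
                f"SICU encounter {meta_row['encounter_id']} lacks surgery_end_time"
            )
        t = t[t >= surg + 48.0]
        return float(t[0]) if t.size else None
    return float(t[0])


def apply_inclusion(
    stream,
    sepsis_onsets: pd.DataFrame,
    allowed_icu_types: tuple[str, ...] = ("MICU", "SICU"),
    min_imv_hours: float = 24.0,
    min_age: float = 18.0,
) -> pd.DataFrame:
    """Tag every encounter included/excluded with the first failing rule.

    Returns a frame indexed by encounter_id with index_time, included and
    exclusion_reason columns. Rules, in order: age >= 18; sepsis-3 onset
    present; ICU type allowed; index time exists; >= ``min_imv_hours`` of IMV
    from index; pre-index observations present; IMV not initiated before ICU
    arrival (field/ED intubation).
    """
    ev = stream.events
    vent_param = ev[ev["variable"].isin(VENT_PARAM_VARS)]
    vp_times = {enc: grp["time_hours"].to_numpy()
                for enc, grp in vent_param.groupby("encounter_id")}
    obs = ev[~ev["variable"].isin(VENT_PARAM_VARS)]
    obs_times = {enc: grp["time_hours"].to_numpy()
                 for enc, grp in obs.groupby("encounter_id")}
    episodes = {enc: grp[["start_hours", "stop_hours"]].to_numpy()
                for enc, grp in stream.episodes.groupby("encounter_id")}

    rows = []
    for meta in stream.metadata.itertuples():
        enc = meta.encounter_id
        reason = None
        index_time = None
        if meta.age < min_age:
            reason = "age"
        if reason is None:
            onset = sepsis_onsets["onset_time"].get(enc, np.nan)
            if pd.isna(onset):
                reason = "sepsis3"
        if reason is None and meta.icu_type not in allowed_icu_types:
            reason = "icu_type"
        try:
            index_time = find_index_time(
                pd.Series(meta._asdict()), vp_times.get(enc, np.array([]))
            )
        except ValueError:
            index_time = None
            if reason is None:
                reason = "index_time"
        if reason is None and index_time is None:
            reason = "index_time"
        if reason is None:
            # duration from index to the end of the containing episode
            eps = episodes.get(enc, np.empty((0, 2)))
            containing = eps[(eps[:, 0] <= index_time) & (eps[:, 1] > index_time)]
            dur = float(containing[:, 1].max() - index_time) if len(containing) else 0.0
            if dur < min_imv_hours:
                reason = "imv_duration"
        if reason is None:
            t = obs_times.get(enc, np.array([]))
            in_win = (t > index_time - WINDOW_HOURS) & (t <= index_time)
            if not in_win.any():
                reason = "pre_index_data"
        if reason is None:
            eps = episodes.get(enc, np.empty((0, 2)))
            if len(eps) and float(eps[:, 0].min()) < meta.icu_admission_time - 1e-9:
                reason = "ed_initiated"

        rows.append(
            {
                "encounter_id": enc,
                "index_time": np.nan if index_time is None else index_time,
                "included": reason is None,
                "exclusion_reason": reason,
            }
        )
    out = pd.DataFrame(rows).set_index("encounter_id")
    return out


def extract_window(stream, cohort: pd.DataFrame) -> pd.DataFrame:
    """Pre-intubation observations for included encounters.

    Keeps physiologic records with index - 24 < t <= index. Raises if called
    with any excluded encounter in ``cohort``.
    """
    if (~cohort["included"]).any():
        bad = cohort.index[~cohort["included"]][:3].tolist()
        raise ValueError(f"extract_window called on excluded encounters: {bad}")
    ev = stream.events
    ev = ev[~ev["variable"].isin(VENT_PARAM_VARS)]
    idx = cohort["index_time"]
    joined = ev.merge(idx.rename("index_time"), left_on="encounter_id", right_index=True)
    keep = (joined["time_hours"] > joined["index_time"] - WINDOW_HOURS) & (
        joined["time_hours"] <= joined["index_time"]
    )
    return joined.loc[keep, ["encounter_id", "patient_id", "time_hours", "variable", "value"]
                      ].reset_index(drop=True)


def build_cohort(stream, sepsis_onsets: pd.DataFrame, **kwargs) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inclusion table plus windowed observations for the included subset."""
    cohort = apply_inclusion(stream, sepsis_onsets, **kwargs)
    included = cohort[cohort["included"]]
    window = extract_window(stream, included)
    return cohort, window
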