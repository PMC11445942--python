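"""Synthetic multi-hospital EHR cohort with four latent ARF phenotypes.

Each encounter is drawn from exactly one latent phenotype (A-D). Per-feature
marginals are calibrated from median/IQR parameters: log-normal for strictly
positive labs, truncated normal otherwise, tied together by a Gaussian copula
with modest organ-system block correlation so downstream correlation pruning
has something to prune. Missingness acts at the encounter-feature level,
outliers are multiplicative unit-entry mistakes, 28-day survival and high-PEEP
assignment are phenotype-dependent and confounded by severity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .features import PHENOTYPE_LABELS, load_feature_table, phenotype_quartiles

_Z75 = 0.6744897501960817  # standard-normal 75th percentile

# copula pairs tightened beyond their block baseline (near-duplicate measurements)
_COPULA_PAIRS = {
    ("hemoglobin", "hematocrit"): 0.95,
    ("ast", "alt"): 0.90,
    ("map", "sbp"): 0.85,
    ("bicarbonate", "base_excess"): 0.90,
    ("pf_ratio", "sf_ratio"): 0.60,
}
_BLOCK_RHO = 0.45

# fraction of encounters on a vasopressor pre-intubation, by phenotype
_PRESSOR_FRACTION = {"A": 0.35, "B": 0.25, "C": 0.10, "D": 0.45}

# survivor ventilation duration medians (days), log-normal sigma 0.5
_VENT_MEDIAN_DAYS = {"A": 9.0, "B": 11.0, "C": 7.0, "D": 10.0}

_AGE_MEAN = {"A": 64.8, "B": 62.0, "C": 61.7, "D": 60.8}

_DX_POOL = {
    "A": ["428", "585", "250.4", "410", "403"],
    "B": ["486", "518.81", "493", "507.0", "480"],
    "C": ["486", "599.0", "038.9", "276.51", "493"],
    "D": ["571.2", "572.2", "038.9", "286.6", "155"],
}


@dataclass(frozen=True)
class PhenotypeSpec:
    """Generative parameters for one latent phenotype.

    ``feature_params`` maps feature name -> (median, q1, q3) on original
    units. ``mortality_28d`` is the untreated 28-day mortality;
    ``treatment_risk_difference`` the additive change under high PEEP.
    If ``mortality_28d`` is None it is derived from ``hazard_rate`` as
    1 - exp(-28 * hazard).
    """

    label: str
    prevalence: float
    feature_params: dict[str, tuple[float, float, float]]
    mortality_28d: float | None = None
    hazard_rate: float = 0.02
    high_peep_propensity_coefs: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PROPENSITY_COEFS)
    )
    treated_fraction: float = 0.2
    treatment_risk_difference: float = 0.0
    mortality_risk_coefs: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_RISK_COEFS)
    )

    @property
    def mortality(self) -> float:
        if self.mortality_28d is not None:
            return self.mortality_28d
        return 1.0 - float(np.exp(-28.0 * self.hazard_rate))

    def validate(self) -> None:
        if self.label not in PHENOTYPE_LABELS:
            raise ValueError(f"unknown phenotype label {self.label!r}")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must be in [0, 1]")
        m = self.mortality
        if not 0.0 <= m <= 1.0:
            raise ValueError("mortality_28d must be in [0, 1]")
        if not 0.0 <= m + self.treatment_risk_difference <= 1.0:
            raise ValueError("treated mortality out of [0, 1]")
        for name, (med, q1, q3) in self.feature_params.items():
            if not (q1 <= med <= q3):
                raise ValueError(f"{name}: quartiles must satisfy q1 <= median <= q3")
            if q3 - q1 < 0:
                raise ValueError(f"{name}: negative IQR")


_DEFAULT_PROPENSITY_COEFS = {
    "pf_ratio": -0.5,
    "lactate": 0.25,
    "creatinine": 0.15,
    "age": 0.1,
}
_DEFAULT_RISK_COEFS = {
    "pf_ratio": -0.6,
    "lactate": 0.6,
    "creatinine": 0.4,
    "age": 0.4,
}

# paper-anchored defaults for the four phenotypes
_DEFAULT_PREVALENCE = {"A": 0.252, "B": 0.207, "C": 0.297, "D": 0.244}
_DEFAULT_MORTALITY = {"A": 0.409, "B": 0.512, "C": 0.214, "D": 0.496}
_DEFAULT_TREATED_FRACTION = {"A": 0.167, "B": 0.496, "C": 0.24, "D": 0.162}
_DEFAULT_RISK_DIFFERENCE = {"A": 0.04, "B": -0.04, "C": 0.07, "D": -0.03}


def default_specs(feature_table: pd.DataFrame | None = None) -> list[PhenotypeSpec]:
    """The four phenotype specs parameterized from the packaged dictionary."""
    tab = load_feature_table() if feature_table is None else feature_table
    quart = phenotype_quartiles(tab)
    specs = []
    for lab in PHENOTYPE_LABELS:
        q = quart[lab]
        params = {f: (q.at[f, "median"], q.at[f, "q1"], q.at[f, "q3"]) for f in q.index}
        mort = _DEFAULT_MORTALITY[lab]
        specs.append(
            PhenotypeSpec(
                label=lab,
                prevalence=_DEFAULT_PREVALENCE[lab],
                feature_params=params,
                mortality_28d=mort,
                hazard_rate=-np.log(1.0 - mort) / 28.0,
                treated_fraction=_DEFAULT_TREATED_FRACTION[lab],
                treatment_risk_difference=_DEFAULT_RISK_DIFFERENCE[lab],
            )
        )
    # renormalize prevalences to sum exactly to 1
    total = sum(s.prevalence for s in specs)
    return [replace(s, prevalence=s.prevalence / total) for s in specs]


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level knobs: size, seed, noise and sampling cadence."""

    n_encounters: int = 500
    seed: int = 0
    outlier_rate: float = 0.005
    hospital_id: str = "hospital-1"
    icu_type: str = "MICU"
    sampling_resolution_hours: float = 1.0
    lab_resolution_hours: float = 6.0
    missingness: dict[str, float] | None = None  # overrides dictionary defaults
    ed_intubation_rate: float = 0.02
    sparse_vitals_rate: float = 0.01
    repeat_patient_rate: float = 0.03

    def validate(self) -> None:
        if self.n_encounters < 4:
            raise ValueError("n_encounters must be >= 4")
        if not 0.0 <= self.outlier_rate < 0.1:
            raise ValueError("outlier_rate must be in [0, 0.1)")
        if self.icu_type not in ("MICU", "SICU"):
            raise ValueError("icu_type must be MICU or SICU")
        if self.sampling_resolution_hours <= 0:
            raise ValueError("sampling resolution must be positive")


@dataclass
class EventStream:
    """Long-format timestamped clinical observations plus encounter metadata.

    ``events``: encounter_id, patient_id, time_hours, variable, value.
    ``metadata``: one row per encounter (demographics, times, dx codes).
    ``episodes``: ventilation intervals [start_hours, stop_hours).
    ``micro``: antibiotic / blood-culture administration times.
    """

    events: pd.DataFrame
    metadata: pd.DataFrame
    episodes: pd.DataFrame
    micro: pd.DataFrame

    def validate(self) -> None:
        if (self.events["time_hours"] < 0).any():
            raise ValueError("negative observation timestamps")
        for enc, grp in self.episodes.groupby("encounter_id"):
            iv = grp.sort_values("start_hours")[["start_hours", "stop_hours"]].to_numpy()
            if (iv[1:, 0] < iv[:-1, 1]).any():
                raise ValueError(f"overlapping ventilation intervals for {enc}")
        meta = self.metadata.set_index("encounter_id")
        last_obs = self.events.groupby("encounter_id")["time_hours"].max()
        dead = meta["death_time"].dropna()
        common = dead.index.intersection(last_obs.index)
        if (dead.loc[common] < last_obs.loc[common] - 1e-9).any():
            raise ValueError("death_time precedes last observation")

    def for_encounters(self, encounter_ids) -> "EventStream":
        ids = pd.Index(encounter_ids)
        return EventStream(
            events=self.events[self.events["encounter_id"].isin(ids)].reset_index(drop=True),
            metadata=self.metadata[self.metadata["encounter_id"].isin(ids)].reset_index(drop=True),
            episodes=self.episodes[self.episodes["encounter_id"].isin(ids)].reset_index(drop=True),
            micro=self.micro[self.micro["encounter_id"].isin(ids)].reset_index(drop=True),
        )


def _lognormal_params(med: float, q1: float, q3: float) -> tuple[float, float]:
    if med <= 0 or q1 <= 0:
        raise ValueError("lognormal features require strictly positive quartiles")
    mu = np.log(med)
    sigma = (np.log(q3) - np.log(q1)) / (2 * _Z75) if q3 > q1 else 1e-6
    return mu, max(sigma, 1e-6)


def _truncnorm_loc(target_med: float, scale: float, lo: float, hi: float) -> float:
    """Solve for the location that puts the truncated-normal median on target."""

    def med_of(loc: float) -> float:
        a, b = (lo - loc) / scale, (hi - loc) / scale
        return float(stats.truncnorm.ppf(0.5, a, b, loc=loc, scale=scale))

    left, right = lo - 8 * scale, hi + 8 * scale
    if med_of(right) < target_med:
        return right
    if med_of(left) > target_med:
        return left
    return float(optimize.brentq(lambda c: med_of(c) - target_med, left, right, xtol=1e-9))


def _marginal_from_z(z: np.ndarray, family: str, med: float, q1: float, q3: float,
                     lo: float, hi: float) -> np.ndarray:
    if family == "lognormal":
        mu, sigma = _lognormal_params(med, q1, q3)
        return np.clip(np.exp(mu + sigma * z), lo, hi)
    scale = max((q3 - q1) / (2 * _Z75), 1e-6 * max(abs(med), 1.0), 1e-9)
    loc = _truncnorm_loc(med, scale, lo, hi)
    a, b = (lo - loc) / scale, (hi - loc) / scale
    u = stats.norm.cdf(z)
    return stats.truncnorm.ppf(np.clip(u, 1e-12, 1 - 1e-12), a, b, loc=loc, scale=scale)


def _copula_cholesky(features: list[str], blocks: pd.Series) -> np.ndarray:
    p = len(features)
    corr = np.eye(p)
    idx = {f: i for i, f in enumerate(features)}
    for i in range(p):
        for j in range(i + 1, p):
            if blocks.iloc[i] == blocks.iloc[j]:
                corr[i, j] = corr[j, i] = _BLOCK_RHO
    for (f1, f2), rho in _COPULA_PAIRS.items():
        if f1 in idx and f2 in idx:
            corr[idx[f1], idx[f2]] = corr[idx[f2], idx[f1]] = rho
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(corr)
        corr = (v * np.maximum(w, 1e-6)) @ v.T
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
        return np.linalg.cholesky(corr)


def _validate_specs(specs: list[PhenotypeSpec], feature_names: list[str]) -> None:
    if abs(sum(s.prevalence for s in specs) - 1.0) > 1e-9:
        raise ValueError("phenotype prevalences must sum to 1")
    for s in specs:
        s.validate()
        unknown = set(s.feature_params) - set(feature_names)
        if unknown:
            raise ValueError(f"unknown features in spec {s.label}: {sorted(unknown)}")
        missing = set(feature_names) - set(s.feature_params)
        if missing:
            raise ValueError(
                f"spec {s.label} lacks parameters for dictionary features: {sorted(missing)}"
            )


def generate_cohort(
    specs: list[PhenotypeSpec],
    config: CohortConfig,
    feature_table: pd.DataFrame | None = None,
) -> tuple[EventStream, pd.Series, pd.DataFrame]:
    """Draw a cohort; returns (stream, latent labels, per-encounter true levels).

    The third element holds each encounter's latent per-feature level (plus
    age), before measurement noise, missingness or outliers — ground truth
    for recovery tests and for confounded outcome assignment.
    """
    config.validate()
    tab = load_feature_table() if feature_table is None else feature_table
    feature_names = list(tab["feature"])
    _validate_specs(specs, feature_names)
    rng = np.random.default_rng(config.seed)

    n = config.n_encounters
    prev = np.array([s.prevalence for s in specs])
    label_idx = rng.choice(len(specs), size=n, p=prev)
    enc_ids = np.array([f"{config.hospital_id}-e{i:05d}" for i in range(n)])

    # a few patients contribute two encounters
    pat_ids = np.array([f"{config.hospital_id}-p{i:05d}" for i in range(n)])
    n_rep = int(round(config.repeat_patient_rate * n))
    if n_rep and n >= 2 * n_rep:
        src = rng.choice(n, size=2 * n_rep, replace=False)
        pat_ids[src[n_rep:]] = pat_ids[src[:n_rep]]

    chol = _copula_cholesky(feature_names, tab["block"])
    levels = np.empty((n, len(feature_names)))
    ages = np.empty(n)
    for k, spec in enumerate(specs):
        rows = np.where(label_idx == k)[0]
        if rows.size == 0:
            continue
        z = rng.standard_normal((rows.size, len(feature_names))) @ chol.T
        for j, f in enumerate(feature_names):
            med, q1, q3 = spec.feature_params[f]
            frow = tab.loc[f]
            levels[rows, j] = _marginal_from_z(
                z[:, j], frow["family"], med, q1, q3, float(frow["lo"]), float(frow["hi"])
            )
        mu_age = _AGE_MEAN.get(spec.label, 62.0)
        a, b = (18 - mu_age) / 15.0, (95 - mu_age) / 15.0
        ages[rows] = stats.truncnorm.rvs(a, b, loc=mu_age, scale=15.0,
                                         size=rows.size, random_state=rng)

    labels = pd.Series([specs[k].label for k in label_idx], index=enc_ids, name="phenotype")

    # timeline: admission 0, ICU arrival shortly after, index IMV ~26-54 h
    icu_adm = rng.uniform(0.0, 4.0, size=n)
    if config.icu_type == "SICU":
        surgery_end = rng.uniform(0.0, 5.0, size=n)
        index_time = surgery_end + 48.0 + rng.uniform(2.0, 30.0, size=n)
    else:
        surgery_end = np.full(n, np.nan)
        index_time = icu_adm + rng.uniform(26.0, 50.0, size=n)
    ed_mask = rng.random(n) < config.ed_intubation_rate
    sparse_mask = rng.random(n) < config.sparse_vitals_rate

    abx_time = rng.uniform(2.0, 10.0, size=n)
    culture_time = abx_time + rng.uniform(0.0, 12.0, size=n)

    # encounter-level missingness: feature entirely unmeasured with prob m_f
    miss = tab["missingness"].to_dict()
    if config.missingness:
        miss.update(config.missingness)
    measured = np.empty((n, len(feature_names)), dtype=bool)
    for j, f in enumerate(feature_names):
        measured[:, j] = rng.random(n) >= float(miss.get(f, 0.0))

    frames: list[pd.DataFrame] = []
    vit_res = config.sampling_resolution_hours
    lab_res = config.lab_resolution_hours
    is_vital = (tab["kind"] == "vital").to_numpy()
    noise_sd = np.where(is_vital, 0.05, 0.03)

    max_t = float(np.max(index_time))
    vit_grid = np.arange(0.0, max_t + vit_res, vit_res)
    lab_grid = np.arange(1.0, max_t + lab_res, lab_res)
    for j, f in enumerate(feature_names):
        grid = vit_grid if is_vital[j] else lab_grid
        # per-encounter counts of in-window samples
        n_obs = np.searchsorted(grid, index_time, side="right")
        keep = measured[:, j] & (n_obs > 0)
        if sparse_mask.any() and is_vital[j]:
            keep &= ~sparse_mask
        rows = np.where(keep)[0]
        if rows.size == 0:
            continue
        counts = n_obs[rows]
        ridx = np.repeat(rows, counts)
        t = np.concatenate([grid[:c] for c in counts])
        vals = levels[ridx, j] * np.exp(
            noise_sd[j] * rng.standard_normal(ridx.size)
        ) if tab.iloc[j]["family"] == "lognormal" else (
            levels[ridx, j]
            + noise_sd[j] * np.maximum(np.abs(levels[ridx, j]), 1.0)
            * rng.standard_normal(ridx.size)
        )
        lo, hi = float(tab.iloc[j]["lo"]), float(tab.iloc[j]["hi"])
        vals = np.clip(vals, lo, hi)
        if f == "gcs_total":
            vals = np.round(vals)
        frames.append(
            pd.DataFrame(
                {
                    "encounter_id": enc_ids[ridx],
                    "patient_id": pat_ids[ridx],
                    "time_hours": t,
                    "variable": f,
                    "value": vals,
                }
            )
        )

    # vasopressor infusions for a phenotype-dependent fraction
    for k, spec in enumerate(specs):
        rows = np.where(label_idx == k)[0]
        on = rows[rng.random(rows.size) < _PRESSOR_FRACTION.get(spec.label, 0.2)]
        if on.size == 0:
            continue
        dose = rng.uniform(0.02, 0.4, size=on.size)
        start = rng.uniform(4.0, 20.0, size=on.size)
        recs = []
        for i, r in enumerate(on):
            ts = np.arange(start[i], index_time[r], 2.0)
            recs.append(
                pd.DataFrame(
                    {
                        "encounter_id": enc_ids[r],
                        "patient_id": pat_ids[r],
                        "time_hours": ts,
                        "variable": "norepinephrine",
                        "value": dose[i],
                    }
                )
            )
        if recs:
            frames.append(pd.concat(recs, ignore_index=True))

    events = pd.concat(frames, ignore_index=True)

    # implausible outliers: multiplicative unit-entry mistakes
    n_out = int(round(config.outlier_rate * len(events)))
    if n_out:
        phys = events["variable"].isin(feature_names).to_numpy()
        cand = np.where(phys)[0]
        pick = rng.choice(cand, size=min(n_out, cand.size), replace=False)
        factor = np.where(rng.random(pick.size) < 0.5, 100.0, 0.01)
        events.loc[pick, "value"] = events.loc[pick, "value"] * factor

    events = events.sort_values(
        ["encounter_id", "time_hours", "variable"], kind="mergesort"
    ).reset_index(drop=True)

    sex = rng.choice(["male", "female"], size=n, p=[0.542, 0.458])
    race = rng.choice(
        ["black", "white", "other"], size=n, p=[0.485, 0.431, 0.084]
    )
    ethnicity = rng.choice(["hispanic", "non-hispanic"], size=n, p=[0.043, 0.957])
    dx = []
    for i in range(n):
        pool = _DX_POOL[specs[label_idx[i]].label]
        k_codes = rng.poisson(1.5)
        dx.append(";".join(rng.choice(pool, size=min(k_codes, len(pool)), replace=False)))

    metadata = pd.DataFrame(
        {
            "encounter_id": enc_ids,
            "patient_id": pat_ids,
            "hospital_id": config.hospital_id,
            "icu_type": config.icu_type,
            "icu_admission_time": icu_adm,
            "surgery_end_time": surgery_end,
            "age": ages,
            "sex": sex,
            "race": race,
            "ethnicity": ethnicity,
            "diagnosis_codes": dx,
            "death_time": np.nan,
            "discharge_time": np.nan,
        }
    )

    # vent-parameter records at/after index define the index; ED-initiated
    # encounters have a ventilation episode starting before ICU arrival
    vent_start = np.where(ed_mask, np.maximum(icu_adm - rng.uniform(1.0, 3.0, n), 0.0),
                          index_time)
    episodes = pd.DataFrame(
        {
            "encounter_id": enc_ids,
            "start_hours": vent_start,
            "stop_hours": vent_start + 48.0,  # placeholder; generate_outcomes sets the stop
        }
    )
    vent_param_rows = pd.DataFrame(
        {
            "encounter_id": enc_ids,
            "patient_id": pat_ids,
            "time_hours": vent_start,
            "variable": "peep",
            "value": 5.0,
        }
    )
    events = pd.concat([events, vent_param_rows], ignore_index=True)
    events = events.sort_values(
        ["encounter_id", "time_hours", "variable"], kind="mergesort"
    ).reset_index(drop=True)

    micro = pd.concat(
        [
            pd.DataFrame({"encounter_id": enc_ids, "kind": "antibiotic", "time_hours": abx_time}),
            pd.DataFrame({"encounter_id": enc_ids, "kind": "blood_culture", "time_hours": culture_time}),
        ],
        ignore_index=True,
    )

    truth = pd.DataFrame(levels, index=enc_ids, columns=feature_names)
    truth["age"] = ages
    truth["index_time"] = vent_start
    stream = EventStream(events=events, metadata=metadata, episodes=episodes, micro=micro)
    return stream, labels, truth


def _calibrate_intercept(lin: np.ndarray, target: float) -> float:
    """Intercept such that mean sigmoid(a + lin) equals target on this sample."""
    if target <= 0.0:
        return -np.inf
    if target >= 1.0:
        return np.inf

    def mean_p(a: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(a + lin)))))

    return float(optimize.brentq(lambda a: mean_p(a) - target, -30.0, 30.0, xtol=1e-10))


def generate_outcomes(
    stream: EventStream,
    latent_labels: pd.Series,
    specs: list[PhenotypeSpec],
    truth: pd.DataFrame,
    seed: int = 0,
) -> tuple[EventStream, pd.DataFrame]:
    """Assign confounded high-PEEP treatment and 28-day survival.

    Treatment probability follows a logistic model of the spec's confounders
    (computed on within-phenotype z-scored latent levels, intercept calibrated
    to the spec's treated fraction). Untreated individual risk averages the
    spec's 28-day mortality; treatment adds the spec's risk difference. Death
    times are truncated-exponential with the spec hazard; death implies no
    extubation-alive record.
    """
    rng = np.random.default_rng(seed)
    meta = stream.metadata.set_index("encounter_id")
    missing = latent_labels.index.difference(meta.index)
    if len(missing):
        raise ValueError(f"labels for unknown encounters: {list(missing)[:3]}")
    if meta.index.difference(latent_labels.index).size:
        raise ValueError("every encounter needs a latent label")

    enc_ids = meta.index.to_numpy()
    labels = latent_labels.loc[enc_ids]
    by_label = {s.label: s for s in specs}

    treated = pd.Series(False, index=enc_ids)
    died = pd.Series(False, index=enc_ids)
    death_day = pd.Series(np.nan, index=enc_ids)
    propensity = pd.Series(np.nan, index=enc_ids)

    for lab, spec in by_label.items():
        rows = enc_ids[labels.to_numpy() == lab]
        if rows.size == 0:
            continue
        conf = list(spec.high_peep_propensity_coefs)
        x = truth.loc[rows, conf].to_numpy(dtype=float)
        xz = (x - x.mean(axis=0)) / np.where(x.std(axis=0) > 0, x.std(axis=0), 1.0)
        lin_t = xz @ np.array([spec.high_peep_propensity_coefs[c] for c in conf])
        a_t = _calibrate_intercept(lin_t, spec.treated_fraction)
        p_t = 1.0 / (1.0 + np.exp(-(a_t + lin_t)))
        trt = rng.random(rows.size) < p_t

        risk_conf = list(spec.mortality_risk_coefs)
        xr = truth.loc[rows, risk_conf].to_numpy(dtype=float)
        xrz = (xr - xr.mean(axis=0)) / np.where(xr.std(axis=0) > 0, xr.std(axis=0), 1.0)
        lin_r = xrz @ np.array([spec.mortality_risk_coefs[c] for c in risk_conf])
        a_r = _calibrate_intercept(lin_r, spec.mortality)
        base_risk = 1.0 / (1.0 + np.exp(-(a_r + lin_r))) if np.isfinite(a_r) else (
            np.full(rows.size, float(spec.mortality))
        )
        risk = np.clip(base_risk + trt * spec.treatment_risk_difference, 0.0, 1.0)
        d = rng.random(rows.size) < risk
        # death day: exponential truncated to (0, 28]
        u = rng.random(rows.size)
        lam = max(spec.hazard_rate, 1e-9)
        tday = -np.log(1.0 - u * (1.0 - np.exp(-lam * 28.0))) / lam
        treated.loc[rows] = trt
        died.loc[rows] = d
        death_day.loc[rows] = np.where(d, np.maximum(tday, 0.05), np.nan)
        propensity.loc[rows] = p_t

    index_time = truth.loc[enc_ids, "index_time"]
    vent_days = pd.Series(index=enc_ids, dtype=float)
    for lab, spec in by_label.items():
        rows = enc_ids[labels.to_numpy() == lab]
        med = _VENT_MEDIAN_DAYS.get(lab, 9.0)
        vent_days.loc[rows] = np.clip(
            np.exp(np.log(med) + 0.5 * rng.standard_normal(rows.size)), 1.5, 27.0
        )

    death_time = index_time + death_day * 24.0
    vent_stop = np.where(
        died.loc[enc_ids],
        death_time.loc[enc_ids],
        index_time + np.minimum(vent_days.loc[enc_ids], 27.0) * 24.0,
    )
    # keep the episode non-degenerate even for very early deaths
    vent_stop = np.maximum(vent_stop, index_time + 1.0)
    discharge = np.where(
        died.loc[enc_ids],
        death_time.loc[enc_ids],
        vent_stop + rng.uniform(24.0, 240.0, size=enc_ids.size),
    )

    meta2 = stream.metadata.copy()
    meta2["death_time"] = meta2["encounter_id"].map(pd.Series(death_time.values, index=enc_ids))
    meta2["discharge_time"] = meta2["encounter_id"].map(pd.Series(discharge, index=enc_ids))

    ep = stream.episodes.copy().set_index("encounter_id")
    ep.loc[enc_ids, "stop_hours"] = vent_stop
    ep = ep.reset_index()

    # PEEP settings every 6 h over the first 24 h of ventilation
    pat = stream.metadata.set_index("encounter_id")["patient_id"]
    offsets = np.arange(0.0, 24.1, 6.0)
    trt_arr = treated.loc[enc_ids].to_numpy()
    peep_levels = np.where(
        trt_arr[:, None],
        rng.integers(10, 17, size=(enc_ids.size, offsets.size)),
        rng.integers(5, 9, size=(enc_ids.size, offsets.size)),
    ).astype(float)
    t_mat = index_time.to_numpy()[:, None] + offsets[None, :]
    stop_mat = np.asarray(vent_stop)[:, None]
    valid = t_mat <= stop_mat
    ridx, cidx = np.where(valid)
    peep_df = pd.DataFrame(
        {
            "encounter_id": enc_ids[ridx],
            "patient_id": pat.loc[enc_ids[ridx]].to_numpy(),
            "time_hours": t_mat[ridx, cidx],
            "variable": "peep",
            "value": peep_levels[ridx, cidx],
        }
    )
    events = pd.concat([stream.events, peep_df], ignore_index=True)
    events = events.sort_values(
        ["encounter_id", "time_hours", "variable"], kind="mergesort"
    ).reset_index(drop=True)
    # drop observations recorded after death
    dt = events["encounter_id"].map(pd.Series(death_time.values, index=enc_ids))
    events = events[(dt.isna()) | (events["time_hours"] <= dt)].reset_index(drop=True)

    out_stream = EventStream(events=events, metadata=meta2, episodes=ep, micro=stream.micro)
    truth_out = pd.DataFrame(
        {
            "phenotype": labels.to_numpy(),
            "treated": treated.loc[enc_ids].to_numpy(),
            "died_28d": died.loc[enc_ids].to_numpy(),
            "death_day": death_day.loc[enc_ids].to_numpy(),
            "propensity": propensity.loc[enc_ids].to_numpy(),
            "true_risk_difference": [by_label[l].treatment_risk_difference for l in labels],
            "index_time": index_time.loc[enc_ids].to_numpy(),
        },
        index=pd.Index(enc_ids, name="encounter_id"),
    )
    return out_stream, truth_out


def generate_study(
    specs: list[PhenotypeSpec] | None = None,
    config: CohortConfig | None = None,
    feature_table: pd.DataFrame | None = None,
) -> tuple[EventStream, pd.Series, pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: cohort plus outcomes in one call."""
    specs = default_specs(feature_table) if specs is None else specs
    config = CohortConfig() if config is None else config
    stream, labels, levels = generate_cohort(specs, config, feature_table)
    out_stream, truth = generate_outcomes(
        stream, labels, specs, levels, seed=config.seed + 1
    )
    return out_stream, labels, levels, truth
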