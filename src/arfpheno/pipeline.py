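"""Pipeline orchestration and schema-validated IO.

Runs the stages in order — sepsis-3 detection, cohort construction,
preprocessing, phenotype derivation, characterization, outcomes, high-PEEP
ATE — persisting every intermediate as flat CSV/JSON plus a manifest of
seeds, parameters and artifact hashes for bit-for-bit reproducibility.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import characterize, cohort as cohort_mod, outcomes as outcomes_mod
from . import psm as psm_mod, sofa as sofa_mod, transfer as transfer_mod
from .phenotype import PhenotypeModel
from .preprocess import Preprocessor
from .synth import CohortConfig, EventStream, default_specs, generate_study

EVENT_COLUMNS = ["encounter_id", "patient_id", "time_hours", "variable", "value"]

DEFAULT_CONFOUNDERS = ["age", "creatinine", "lactate", "pf_ratio", "platelets"]


@dataclass
class PipelineConfig:
    """Stage parameters for a full run (all seeds derive from ``seed``)."""

    seed: int = 0
    n_encounters: int = 200
    methods: tuple = ("umap",)
    dimensions: tuple = (2,)
    ks: tuple = (2, 3, 4, 5, 6)
    n_init: int = 10
    mice_iterations: int = 10
    missing_threshold: float = 0.85
    r_threshold: float = 0.75
    n_boot: int = 2000
    caliper_sd: float = 0.2
    confounders: tuple = tuple(DEFAULT_CONFOUNDERS)
    mse_subsample: int = 200

    def validate(self) -> None:
        if not 0 < self.missing_threshold <= 1:
            raise ValueError("missing_threshold out of (0, 1]")
        if not 0 < self.r_threshold <= 1:
            raise ValueError("r_threshold out of (0, 1]")
        if int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        for key in ("methods", "dimensions", "ks", "confounders"):
            if key in known and isinstance(known[key], list):
                known[key] = tuple(known[key])
        return cls(**known)


def read_events(path: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a long-format events CSV; malformed rows go to a rejects frame."""
    df = pd.read_csv(path, dtype={"encounter_id": str, "patient_id": str})
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"events file missing mandatory columns: {missing}")
    vals = pd.to_numeric(df["value"], errors="coerce")
    times = pd.to_numeric(df["time_hours"], errors="coerce")
    bad = vals.isna() | times.isna()
    rejects = df[bad].copy()
    good = df[~bad].copy()
    good["value"] = vals[~bad]
    good["time_hours"] = times[~bad]
    return good.reset_index(drop=True), rejects.reset_index(drop=True)


def read_stream(events_path: str, metadata_path: str, episodes_path: str,
                micro_path: str) -> tuple[EventStream, pd.DataFrame]:
    events, rejects = read_events(events_path)
    metadata = pd.read_csv(metadata_path, dtype={"encounter_id": str, "patient_id": str})
    episodes = pd.read_csv(episodes_path, dtype={"encounter_id": str})
    micro = pd.read_csv(micro_path, dtype={"encounter_id": str})
    return EventStream(events, metadata, episodes, micro), rejects


def write_stream(stream: EventStream, outdir: Path) -> dict[str, str]:
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (
        ("events", stream.events), ("metadata", stream.metadata),
        ("episodes", stream.episodes), ("micro", stream.micro),
    ):
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = str(p)
    return paths


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path,
                 stream: EventStream | None = None,
                 latent_labels: pd.Series | None = None) -> dict:
    """Execute all stages; returns the manifest (also written to disk).

    When ``stream`` is None a synthetic cohort of ``config.n_encounters``
    encounters is generated first.
    """
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                                 for k, v in asdict(config).items()},
                      "artifacts": {}}

    if stream is None:
        cfg = CohortConfig(n_encounters=config.n_encounters, seed=config.seed)
        stream, latent_labels, _, truth = generate_study(config=cfg)
        write_stream(stream, out / "synthetic")
        truth.to_csv(out / "synthetic" / "truth.csv")
        latent_labels.to_csv(out / "synthetic" / "latent_labels.csv")

    # stage: sepsis-3
    onsets = sofa_mod.detect_cohort_sepsis(stream)
    onsets.to_csv(out / "sepsis_onsets.csv")

    # stage: cohort
    cohort_tab, window = cohort_mod.build_cohort(stream, onsets)
    cohort_tab.to_csv(out / "cohort.csv")
    included = cohort_tab[cohort_tab["included"]]

    # stage: preprocess
    prep = Preprocessor(
        missing_threshold=config.missing_threshold, r_threshold=config.r_threshold,
        mice_iterations=config.mice_iterations, seed=config.seed,
    )
    scaled = prep.fit_transform(window)
    scaled.to_csv(out / "features_scaled.csv")
    (out / "preprocess_report.json").write_text(
        json.dumps(asdict(prep.report_), indent=2, default=str)
    )

    # stage: phenotype
    res = PhenotypeModel(
        scaled, methods=config.methods, dimensions=config.dimensions,
        ks=config.ks, seed=config.seed, n_init=config.n_init,
        mse_subsample=config.mse_subsample,
    ).fit()
    res.score_table.to_csv(out / "model_selection.csv", index=False)
    res.coordinates.to_csv(out / "embedding.csv")
    res.assignments.to_csv(out / "assignments.csv")

    # stage: characterize
    unscaled = prep.unscaled_
    medians = characterize.cluster_medians(unscaled, res.assignments)
    label_map = characterize.canonical_label(medians)
    labels = res.assignments.map(
        {int(k) if isinstance(k, (int, np.integer)) else k: v
         for k, v in label_map["labels"].items()}
    ).rename("phenotype")
    labels.to_csv(out / "phenotypes.csv")
    (out / "labeling.json").write_text(json.dumps(
        {k: (v if not isinstance(v, dict)
             else {str(kk): vv for kk, vv in v.items()}) for k, v in label_map.items()},
        indent=2, default=str))
    summary_tab = characterize.summarize(unscaled, labels)
    summary_tab.to_csv(out / "phenotype_profiles.csv")
    importances, residual = characterize.feature_importance(
        scaled, res.assignments, seed=config.seed
    )
    importances.to_csv(out / "feature_importance.csv")
    charl = characterize.charlson_by_group(stream.metadata, labels)
    charl.to_csv(out / "charlson.csv")

    # stage: transfer
    tm = transfer_mod.train_transfer(scaled, labels, seed=config.seed)
    (out / "transfer_metrics.json").write_text(json.dumps(
        {"accuracy": tm.accuracy, "baselines": tm.baseline_accuracy}, indent=2))

    # stage: outcomes
    records = outcomes_mod.survival_records(included, stream)
    records.to_csv(out / "survival_records.csv")
    osum = outcomes_mod.outcome_summary(records, labels)
    osum.to_csv(out / "outcome_summary.csv")
    stat, p = outcomes_mod.logrank(
        records["duration_days"], records["event"], labels.loc[records.index]
    )
    (out / "logrank.json").write_text(json.dumps({"statistic": stat, "p_value": p}))

    # stage: high-PEEP ATE per phenotype
    treated = _median_peep_treated(stream, included)
    conf_cols = [c for c in config.confounders if c in unscaled.columns]
    conf = unscaled[conf_cols].copy()
    meta_age = stream.metadata.set_index("encounter_id")["age"]
    if "age" in config.confounders and "age" not in conf.columns:
        conf["age"] = meta_age.loc[conf.index]
    ate_rows = {}
    for lab in sorted(labels.unique()):
        ids = labels.index[labels == lab]
        tr = treated.loc[ids]
        if tr.nunique() < 2 or min(tr.sum(), (~tr).sum()) < 5:
            continue
        eff = psm_mod.HighPeepEffect(
            conf.loc[ids], tr, records.loc[ids, "event"].astype(float),
            phenotype=str(lab), caliper_sd=config.caliper_sd,
            n_boot=config.n_boot, seed=config.seed,
        ).fit()
        ate_rows[str(lab)] = {
            "n_matched": eff.n_matched, "ate": eff.ate,
            "ci_lower": eff.ci_lower, "ci_upper": eff.ci_upper,
            "naive": eff.naive_difference,
            "max_abs_smd_after": float(eff.smd_after.abs().max()),
        }
    (out / "ate.json").write_text(json.dumps(ate_rows, indent=2))

    for p_ in sorted(out.rglob("*")):
        if p_.is_file() and p_.name != "manifest.json":
            manifest["artifacts"][str(p_.relative_to(out))] = _sha256(p_)
    manifest["selection"] = res.selection
    manifest["attribution_additivity_residual"] = residual
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _median_peep_treated(stream: EventStream, included: pd.DataFrame,
                         window_h: float = 24.0, threshold: float = 10.0) -> pd.Series:
    """Treatment flag: median PEEP >= threshold over the first ``window_h``
    hours of index ventilation."""
    ev = stream.events
    peep = ev[ev["variable"] == "peep"].merge(
        included["index_time"].rename("index_time"),
        left_on="encounter_id", right_index=True,
    )
    inwin = peep[(peep["time_hours"] >= peep["index_time"])
                 & (peep["time_hours"] <= peep["index_time"] + window_h)]
    med = inwin.groupby("encounter_id")["value"].median()
    return med.reindex(included.index).fillna(0.0) >= threshold
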