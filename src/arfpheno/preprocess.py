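"""Windowed events -> model-ready feature matrix.

Stages: per-encounter median aggregation over the 24-h pre-intubation window,
physiologic-outlier screening to missing, drop of features missing in > 85%
of encounters, chained-equation (MICE) imputation, greedy |r| > 0.75
correlation pruning, and z-score scaling. The fitted pipeline is frozen and
reapplied verbatim to external validation cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer
from sklearn.preprocessing import StandardScaler

from .features import plausibility_bounds


def aggregate_median(window: pd.DataFrame, feature_names=None) -> pd.DataFrame:
    """Per-cell median of in-window values; NaN when a feature is unobserved.

    ``window`` is long-format (encounter_id, variable, value). Non-numeric
    values raise with the offending record identified.
    """
    vals = pd.to_numeric(window["value"], errors="coerce")
    bad = vals.isna() & window["value"].notna()
    if bad.any():
        rec = window[bad].iloc[0]
        raise ValueError(
            f"non-numeric value {rec['value']!r} for {rec['variable']} "
            f"in encounter {rec['encounter_id']}"
        )
    w = window.assign(value=vals)
    mat = w.pivot_table(index="encounter_id", columns="variable", values="value",
                        aggfunc="median")
    if feature_names is not None:
        mat = mat.reindex(columns=list(feature_names))
    mat.columns.name = None
    return mat


def outliers_to_missing(matrix: pd.DataFrame,
                        bounds: dict[str, tuple[float, float]] | None = None
                        ) -> tuple[pd.DataFrame, pd.Series]:
    """Blank values outside closed physiologic [lo, hi] bounds.

    Returns (matrix, per-feature conversion counts). Every feature must be
    covered by the bounds table.
    """
    bnd = plausibility_bounds() if bounds is None else bounds
    missing = [c for c in matrix.columns if c not in bnd]
    if missing:
        raise KeyError(f"features absent from plausibility table: {missing}")
    out = matrix.copy()
    counts = {}
    for c in out.columns:
        lo, hi = bnd[c]
        mask = out[c].notna() & ((out[c] < lo) | (out[c] > hi))
        counts[c] = int(mask.sum())
        out.loc[mask, c] = np.nan
    return out, pd.Series(counts, name="outliers_converted")


def drop_high_missingness(matrix: pd.DataFrame, threshold: float = 0.85
                          ) -> tuple[pd.DataFrame, list[str]]:
    """Drop features missing in strictly more than ``threshold`` of rows."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    frac = matrix.isna().mean()
    dropped = list(frac.index[frac > threshold])
    return matrix.drop(columns=dropped), dropped


def impute_chained(matrix: pd.DataFrame, n_iterations: int = 10, seed: int = 0,
                   imputer: IterativeImputer | None = None
                   ) -> tuple[pd.DataFrame, IterativeImputer]:
    """MICE-style chained-equation imputation; observed cells untouched.

    Pass a fitted ``imputer`` to apply a frozen derivation-fit model to
    validation data.
    """
    if imputer is None:
        if matrix.isna().all().any():
            bad = list(matrix.columns[matrix.isna().all()])
            raise ValueError(f"all-missing features reached imputation: {bad}")
        imputer = IterativeImputer(
            max_iter=n_iterations, random_state=seed, sample_posterior=False,
            keep_empty_features=True,
        )
        filled = imputer.fit_transform(matrix.to_numpy(dtype=float))
    else:
        filled = imputer.transform(matrix.to_numpy(dtype=float))
    out = pd.DataFrame(filled, index=matrix.index, columns=matrix.columns)
    out = out.where(matrix.isna(), matrix)  # guarantee observed cells exact
    return out, imputer


def correlation_prune(matrix: pd.DataFrame, r_threshold: float = 0.75,
                      original_missingness: pd.Series | None = None
                      ) -> tuple[pd.DataFrame, list[str]]:
    """Greedy pruning of feature pairs with |Pearson r| > threshold.

    Features are visited sorted by (original missingness, name); for each
    offending pair the member with the higher original missingness is
    dropped, ties broken against the lexicographically later name.
    """
    miss = (
        original_missingness.reindex(matrix.columns).fillna(0.0)
        if original_missingness is not None
        else pd.Series(0.0, index=matrix.columns)
    )
    order = sorted(matrix.columns, key=lambda c: (miss[c], c))
    corr = matrix[order].corr().abs()
    kept = list(order)
    dropped: list[str] = []
    for i, fi in enumerate(order):
        if fi in dropped:
            continue
        for fj in order[i + 1:]:
            if fj in dropped:
                continue
            r = corr.at[fi, fj]
            if pd.notna(r) and r > r_threshold:
                mi, mj = miss[fi], miss[fj]
                victim = fj if (mj > mi or (mj == mi)) else fi
                # tie or higher missingness on fj -> drop fj (later in order)
                if victim == fi:
                    dropped.append(fi)
                    break
                dropped.append(fj)
    kept = [c for c in matrix.columns if c not in dropped]
    return matrix[kept], dropped


def scale_features(matrix: pd.DataFrame, scaler: StandardScaler | None = None
                   ) -> tuple[pd.DataFrame, StandardScaler]:
    """Z-score per feature; zero-variance features dropped with a warning.

    Pass a fitted ``scaler`` to reuse derivation means/variances on external
    cohorts (the frozen-transfer contract).
    """
    import warnings

    if scaler is None:
        variances = matrix.var(axis=0, ddof=0)
        degenerate = list(variances.index[variances <= 1e-12])
        if degenerate:
            warnings.warn(f"dropping zero-variance features: {degenerate}")
            matrix = matrix.drop(columns=degenerate)
        scaler = StandardScaler()
        vals = scaler.fit_transform(matrix.to_numpy(dtype=float))
        scaler.feature_names_ = list(matrix.columns)
    else:
        matrix = matrix[list(scaler.feature_names_)]
        vals = scaler.transform(matrix.to_numpy(dtype=float))
    return pd.DataFrame(vals, index=matrix.index, columns=matrix.columns), scaler


@dataclass
class PreprocessReport:
    outlier_counts: dict = field(default_factory=dict)
    dropped_missingness: list = field(default_factory=list)
    dropped_correlated: list = field(default_factory=list)
    dropped_zero_variance: list = field(default_factory=list)
    original_missingness: dict = field(default_factory=dict)
    n_features_final: int = 0


class Preprocessor:
    """The full fitted preprocessing pipeline (fit on derivation, frozen)."""

    def __init__(self, missing_threshold: float = 0.85, r_threshold: float = 0.75,
                 mice_iterations: int = 10, seed: int = 0,
                 bounds: dict[str, tuple[float, float]] | None = None):
        self.missing_threshold = missing_threshold
        self.r_threshold = r_threshold
        self.mice_iterations = mice_iterations
        self.seed = seed
        self.bounds = bounds
        self.imputer_: IterativeImputer | None = None
        self.scaler_: StandardScaler | None = None
        self.impute_columns_: list[str] | None = None
        self.report_ = PreprocessReport()

    def _dictionary_features(self, mat: pd.DataFrame) -> pd.DataFrame:
        # clustering features are the dictionary's; support flags (vasopressor
        # doses, vent parameters) are not aggregated into the matrix
        bnd = plausibility_bounds() if self.bounds is None else self.bounds
        return mat[[c for c in mat.columns if c in bnd]]

    def fit_transform(self, window: pd.DataFrame) -> pd.DataFrame:
        mat = self._dictionary_features(aggregate_median(window))
        mat, counts = outliers_to_missing(mat, self.bounds)
        self.report_.outlier_counts = counts.to_dict()
        self.report_.original_missingness = mat.isna().mean().to_dict()
        mat, dropped = drop_high_missingness(mat, self.missing_threshold)
        self.report_.dropped_missingness = dropped
        miss = mat.isna().mean()
        mat, self.imputer_ = impute_chained(mat, self.mice_iterations, self.seed)
        self.impute_columns_ = list(mat.columns)
        mat, pruned = correlation_prune(mat, self.r_threshold, miss)
        self.report_.dropped_correlated = pruned
        before = set(mat.columns)
        scaled, self.scaler_ = scale_features(mat)
        self.report_.dropped_zero_variance = sorted(before - set(scaled.columns))
        self.report_.n_features_final = scaled.shape[1]
        self.unscaled_ = mat[list(scaled.columns)]
        return scaled

    def transform(self, window: pd.DataFrame) -> pd.DataFrame:
        """Apply the frozen pipeline to an external cohort's window."""
        if self.imputer_ is None or self.scaler_ is None:
            raise RuntimeError("Preprocessor not fitted")
        mat = self._dictionary_features(aggregate_median(window))
        mat, _ = outliers_to_missing(mat, self.bounds)
        mat = mat.reindex(columns=self.impute_columns_)
        mat, _ = impute_chained(mat, imputer=self.imputer_)
        scaled, _ = scale_features(mat, scaler=self.scaler_)
        return scaled
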