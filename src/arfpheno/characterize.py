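"""Cluster characterization: summary tables, attributions, comorbidity, names.

Turns anonymous cluster indices into the canonical A-D phenotypes:

* per-phenotype median/IQR tables with Kruskal-Wallis (continuous) and
  Chi-squared (categorical) significance tests, patient-level mortality;
* additive feature attributions from a gradient-boosted cluster-vs-rest
  surrogate (exact tree-path attributions, additivity checked);
* age-adjusted Charlson comorbidity index from ICD-9 codes;
* the labelling rubric: B has the lowest median P/F ratio, A the highest
  creatinine among the rest, D the highest total bilirubin of the remainder
  (platelet minimum as tie check), C is the residual cluster.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .features import charlson_map

LABEL_ORDER = ("A", "B", "C", "D")


def summarize(matrix: pd.DataFrame, assignments: pd.Series,
              outcomes: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-group median [IQR] for every feature plus a Kruskal-Wallis p.

    ``matrix`` is the unscaled feature matrix. Returns a feature x group
    frame of strings plus 'p_value' column; groups with < 2 members skip
    the test with a warning.
    """
    groups = sorted(assignments.unique())
    small = [g for g in groups if (assignments == g).sum() < 2]
    if small:
        warnings.warn(f"groups with < 2 members, tests skipped: {small}")
    rows = {}
    pvals = {}
    for feat in matrix.columns:
        cells = {}
        samples = []
        for g in groups:
            vals = matrix.loc[assignments[assignments == g].index, feat].dropna()
            if len(vals):
                med, q1, q3 = (vals.median(), vals.quantile(0.25), vals.quantile(0.75))
                cells[g] = f"{med:.1f} [{q1:.1f}, {q3:.1f}]"
            else:
                cells[g] = "-"
            if len(vals) >= 2:
                samples.append(vals.to_numpy())
        if len(samples) >= 2 and not small:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stat, p = stats.kruskal(*samples)
            pvals[feat] = p
        else:
            pvals[feat] = np.nan
        rows[feat] = cells
    out = pd.DataFrame(rows).T
    out["p_value"] = pd.Series(pvals)
    if outcomes is not None:
        out.attrs["mortality"] = patient_level_mortality(outcomes, assignments)
    return out


def patient_level_mortality(outcomes: pd.DataFrame, assignments: pd.Series) -> pd.Series:
    """28-day mortality by group, counted over patients: a patient is dead if
    any of their encounters ends in death within 28 days of its index."""
    df = outcomes.loc[assignments.index].copy()
    df["group"] = assignments
    dead = df.groupby("patient_id")["died_28d"].any()
    grp = df.groupby("patient_id")["group"].first()
    tab = pd.DataFrame({"dead": dead, "group": grp})
    return tab.groupby("group")["dead"].mean()


def categorical_tests(categorical: pd.DataFrame, assignments: pd.Series) -> pd.Series:
    """Chi-squared p per categorical column across groups."""
    out = {}
    for col in categorical.columns:
        tab = pd.crosstab(categorical.loc[assignments.index, col], assignments)
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            out[col] = np.nan
            continue
        chi2, p, _, _ = stats.chi2_contingency(tab)
        out[col] = p
    return pd.Series(out, name="chi2_p")


def feature_importance(scaled: pd.DataFrame, assignments: pd.Series,
                       seed: int = 0, n_estimators: int = 100
                       ) -> tuple[pd.DataFrame, float]:
    """Per-phenotype ranked additive attributions from a surrogate classifier.

    Fits one gradient-boosted cluster-vs-rest model per cluster and computes
    exact per-sample additive attributions (tree-path contributions). The
    per-phenotype importance is the mean |attribution| among that cluster's
    members. Returns (feature x cluster importances, max additivity residual).
    """
    import xgboost as xgb

    clusters = sorted(assignments.unique())
    if len(clusters) < 2:
        raise ValueError("attribution requires >= 2 phenotypes")
    x = scaled.to_numpy(dtype=float)
    cols = list(scaled.columns)
    imp = {}
    worst_residual = 0.0
    for g in clusters:
        y = (assignments.loc[scaled.index] == g).astype(int).to_numpy()
        model = xgb.XGBClassifier(
            n_estimators=n_estimators, max_depth=3, learning_rate=0.3,
            random_state=seed, n_jobs=1, base_score=0.5,
            objective="binary:logistic", verbosity=0,
        )
        model.fit(x, y)
        booster = model.get_booster()
        dm = xgb.DMatrix(x, feature_names=[str(c) for c in cols])
        contrib = booster.predict(dm, pred_contribs=True)  # (n, p + 1), last = bias
        margin = booster.predict(dm, output_margin=True)
        worst_residual = max(
            worst_residual, float(np.max(np.abs(contrib.sum(axis=1) - margin)))
        )
        members = (assignments.loc[scaled.index] == g).to_numpy()
        imp[g] = np.abs(contrib[members, :-1]).mean(axis=0)
    table = pd.DataFrame(imp, index=cols)
    table.columns.name = "cluster"
    return table, worst_residual


def top_features(importances: pd.DataFrame, n: int = 10) -> dict:
    return {g: list(importances[g].sort_values(ascending=False).index[:n])
            for g in importances.columns}


_AGE_BANDS = ((50, 1), (60, 2), (70, 3), (80, 4))


def charlson_age_adjusted(diagnosis_codes, age: float,
                          mapping: pd.DataFrame | None = None) -> float:
    """Age-adjusted Charlson comorbidity index.

    Sums the 17-category weights (each category once, hierarchical pairs
    collapsed to the more severe member) plus one age point per decade from
    50-59 upward, capped at 4. Malformed codes are skipped with a warning.
    """
    cmap = charlson_map() if mapping is None else mapping
    hit: set[str] = set()
    for code in diagnosis_codes:
        code = str(code).strip()
        if not code:
            continue
        if not any(ch.isdigit() for ch in code):
            warnings.warn(f"malformed diagnosis code skipped: {code!r}")
            continue
        for row in cmap.itertuples():
            prefixes = str(row.prefixes).split(";")
            if any(code.startswith(p) for p in prefixes):
                hit.add(row.category)
    # hierarchy: keep only the more severe member of each supersedes pair
    for row in cmap.itertuples():
        sup = row.supersedes
        if isinstance(sup, str) and sup and row.category in hit:
            hit.discard(sup)
    weights = cmap.set_index("category")["weight"]
    score = float(sum(weights[c] for c in hit))
    age_points = 0
    for band, pts in _AGE_BANDS:
        if age >= band:
            age_points = pts
    return score + min(age_points, 4)


def charlson_by_group(metadata: pd.DataFrame, assignments: pd.Series) -> pd.DataFrame:
    """Mean age-adjusted Charlson index with normal-theory 95% CI per group."""
    meta = metadata.set_index("encounter_id").loc[assignments.index]
    scores = meta.apply(
        lambda r: charlson_age_adjusted(
            str(r["diagnosis_codes"]).split(";") if pd.notna(r["diagnosis_codes"]) else [],
            r["age"],
        ),
        axis=1,
    )
    rows = {}
    for g, vals in scores.groupby(assignments):
        m = vals.mean()
        se = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
        rows[g] = {"mean": m, "ci_lo": m - 1.96 * se, "ci_hi": m + 1.96 * se,
                   "n": len(vals)}
    return pd.DataFrame(rows).T


def canonical_label(profiles: pd.DataFrame) -> dict:
    """Map cluster index -> canonical phenotype letter from anchor medians.

    ``profiles``: cluster x feature frame of medians; must contain pf_ratio,
    creatinine, bilirubin_total (platelets used as tie check). Returns a
    bijection, or numeric labels with reason when the rubric cannot apply.
    """
    # each rubric anchor has clinical fallbacks in case the primary feature
    # was dropped upstream (e.g. P/F pruned for correlation with S/F)
    candidates = {
        "hypoxemia": ("pf_ratio", "sf_ratio"),
        "renal": ("creatinine", "bun"),
        "hepatic": ("bilirubin_total", "ast"),
    }
    anchors = {}
    for role, opts in candidates.items():
        pick = next((o for o in opts if o in profiles.columns), None)
        if pick is None:
            return {"labels": {c: str(c) for c in profiles.index},
                    "applied": False, "reason": f"anchors missing: {role} ({opts})"}
        anchors[role] = pick
    if len(profiles) != 4:
        return {"labels": {c: str(c) for c in profiles.index},
                "applied": False, "reason": f"rubric requires 4 clusters, got {len(profiles)}"}
    acols = list(anchors.values())
    # degenerate: all anchor profiles identical
    if (profiles[acols].nunique() <= 1).all():
        return {"labels": {c: str(c) for c in profiles.index},
                "applied": False, "reason": "ambiguous: identical anchor profiles"}

    remaining = list(profiles.index)
    labels: dict = {}
    b = profiles.loc[remaining, anchors["hypoxemia"]].idxmin()
    labels[b] = "B"
    remaining.remove(b)
    a = profiles.loc[remaining, anchors["renal"]].idxmax()
    labels[a] = "A"
    remaining.remove(a)
    d = profiles.loc[remaining, anchors["hepatic"]].idxmax()
    if "platelets" in profiles.columns:
        d_check = profiles.loc[remaining, "platelets"].idxmin()
        if d_check != d:
            warnings.warn(
                "bilirubin and platelet anchors disagree on phenotype D; "
                "using bilirubin"
            )
    labels[d] = "D"
    remaining.remove(d)
    labels[remaining[0]] = "C"
    anchor_log = {
        f"B_{anchors['hypoxemia']}": float(profiles.at[b, anchors["hypoxemia"]]),
        f"A_{anchors['renal']}": float(profiles.at[a, anchors["renal"]]),
        f"D_{anchors['hepatic']}": float(profiles.at[d, anchors["hepatic"]]),
    }
    return {"labels": labels, "applied": True, "anchors": anchor_log}


def cluster_medians(matrix: pd.DataFrame, assignments: pd.Series) -> pd.DataFrame:
    """Cluster x feature medians on original units (rubric input)."""
    return matrix.groupby(assignments.loc[matrix.index]).median()
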