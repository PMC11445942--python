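"""Packaged clinical feature dictionary.

The dictionary drives the synthetic cohort generator (per-phenotype
median/IQR parameters), the outlier screen (physiologic plausibility
bounds) and the SOFA scorer (variable naming). It is a configurable
resource: callers may load their own CSV with the same columns.

The per-phenotype parameter rows beyond the published derivation-cohort
summary variables are synthetic stand-ins (see the resource file header).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources

import pandas as pd

PHENOTYPE_LABELS = ("A", "B", "C", "D")

#: features used as anchors by the canonical labelling rubric
LABEL_ANCHORS = ("pf_ratio", "creatinine", "bilirubin_total", "platelets")


@dataclass(frozen=True)
class FeatureDef:
    """One clinical feature: marginal family, bounds and sampling cadence."""

    name: str
    unit: str
    kind: str  # "vital" (hourly) or "lab" (6-hourly)
    family: str  # "lognormal" or "truncnorm"
    lo: float
    hi: float
    missingness: float
    block: str  # organ-system block for the copula correlation


def _read_resource(name: str) -> pd.DataFrame:
    text = resources.files("arfpheno.resources").joinpath(name).read_text()
    return pd.read_csv(io.StringIO(text), comment="#")


def load_feature_table(path: str | None = None) -> pd.DataFrame:
    """Load the feature dictionary (packaged default or a user CSV)."""
    if path is None:
        tab = _read_resource("synthetic_phenotype_params.csv")
    else:
        tab = pd.read_csv(path, comment="#")
    required = {"feature", "family", "lo", "hi", "missingness", "block", "kind"}
    missing = required - set(tab.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    if tab["feature"].duplicated().any():
        raise ValueError("duplicate feature names in dictionary")
    return tab.set_index("feature", drop=False)


def feature_defs(table: pd.DataFrame | None = None) -> dict[str, FeatureDef]:
    tab = load_feature_table() if table is None else table
    return {
        row.feature: FeatureDef(
            name=row.feature,
            unit=row.unit,
            kind=row.kind,
            family=row.family,
            lo=float(row.lo),
            hi=float(row.hi),
            missingness=float(row.missingness),
            block=row.block,
        )
        for row in tab.itertuples()
    }


def plausibility_bounds(table: pd.DataFrame | None = None) -> dict[str, tuple[float, float]]:
    """Per-feature closed [lo, hi] physiologic plausibility interval."""
    tab = load_feature_table() if table is None else table
    return {r.feature: (float(r.lo), float(r.hi)) for r in tab.itertuples()}


def phenotype_quartiles(table: pd.DataFrame | None = None) -> dict[str, pd.DataFrame]:
    """Per-phenotype frame of (median, q1, q3) indexed by feature."""
    tab = load_feature_table() if table is None else table
    out = {}
    for lab in PHENOTYPE_LABELS:
        p = lab.lower()
        out[lab] = pd.DataFrame(
            {
                "median": tab[f"{p}_med"].astype(float),
                "q1": tab[f"{p}_q1"].astype(float),
                "q3": tab[f"{p}_q3"].astype(float),
            }
        )
    return out


def sofa_rubric() -> pd.DataFrame:
    """The bundled SOFA rubric table (versioned CSV resource)."""
    return _read_resource("sofa_rubric.csv")


def charlson_map() -> pd.DataFrame:
    """Bundled 17-category ICD-9 comorbidity mapping with weights."""
    return _read_resource("charlson_icd9.csv")
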