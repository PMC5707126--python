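"""Bundled three-group brain-specimen cohort table and its summaries.

The packaged TSV lists the study design: specimen ids, post-mortem
interval, age, sex, collection year and high-quality read yield (millions)
for the demyelination, normal-control and OND groups. Summary helpers
recompute the demographic and sequencing-yield statistics used in the
group comparisons.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .group_stats import anova_oneway, chi_square_yates

__all__ = [
    "load_cohort",
    "group_mean",
    "female_fraction",
    "summarize",
]


def load_cohort() -> pd.DataFrame:
    with resources.files("hervex.data").joinpath("cohort.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", na_values=["NA"])
    return df


def group_mean(df: pd.DataFrame, group: str, column: str) -> float:
    vals = df.loc[df["group"] == group, column].dropna()
    return float(vals.mean())


def female_fraction(df: pd.DataFrame, group: str) -> float:
    """Fraction of F among specimens of the group with recorded sex."""
    sexes = df.loc[df["group"] == group, "sex"].dropna()
    if sexes.empty:
        return float("nan")
    return float((sexes == "F").mean())


def summarize(df: pd.DataFrame | None = None) -> dict:
    """Group sizes, HQ-read means, ages, sex composition, and group tests."""
    if df is None:
        df = load_cohort()
    out: dict = {"groups": {}}
    for group, sub in df.groupby("group"):
        out["groups"][group] = {
            "n": int(len(sub)),
            "mean_hq_reads_millions": round(float(sub["hq_reads_millions"].mean()), 1),
            "mean_age": float(sub["age"].dropna().mean()) if sub["age"].notna().any() else None,
            "female_fraction": female_fraction(df, group),
            "pmi_range": [float(sub["pmi_hours"].min()), float(sub["pmi_hours"].max())]
            if sub["pmi_hours"].notna().any() else None,
        }
    dem_age = df.loc[df["group"] == "demyelination", "age"].dropna()
    ctl_age = df.loc[df["group"] == "control", "age"].dropna()
    out["age_anova_dem_vs_control"] = anova_oneway(dem_age, ctl_age).p_value

    dem_sex = df.loc[df["group"] == "demyelination", "sex"].dropna()
    ctl_sex = df.loc[df["group"] == "control", "sex"].dropna()
    table = [[int((dem_sex == "F").sum()), int((dem_sex == "M").sum())],
             [int((ctl_sex == "F").sum()), int((ctl_sex == "M").sum())]]
    out["sex_chi2_dem_vs_control"] = chi_square_yates(table).p_value

    hq = [df.loc[df["group"] == g, "hq_reads_millions"].dropna()
          for g in ("demyelination", "control", "OND")]
    out["hq_reads_anova"] = anova_oneway(*hq).p_value
    return out
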