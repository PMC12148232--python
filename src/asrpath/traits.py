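"""Build the analysis trait table: sex-bias metrics, standardization,
complete-case subsetting, and outlier flagging.

The table is a plain pandas DataFrame with one row per species and columns

======  ====================================================================
column  meaning
======  ====================================================================
species tip label matching the phylogeny
gsd     sex-determination system, ``"XY"`` or ``"ZW"`` (may be missing)
asr     adult sex ratio, proportion of males among adults, in [0, 1]
bsr     birth sex ratio, proportion of males at birth/hatching, in [0, 1]
jmb     juvenile mortality bias, log10(male / female annual mortality)
amb     adult mortality bias, log10(male / female annual mortality)
mat     maturation bias, log10(male / female age at maturity)
======  ====================================================================

Positive bias values mean males die more / mature later than females.
Standardized (z-score) copies carry a ``_z`` suffix.  Sample SD (n-1
denominator) is used throughout.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .phylo import Phylogeny

CONTINUOUS_VARS = ("asr", "bsr", "jmb", "amb", "mat")

#: raw input columns recognised by :func:`compute_bias_metrics`
RAW_COLUMNS = {
    "asr": ("adult_males", "adult_females"),
    "bsr": ("birth_males", "birth_females"),
    "jmb": ("male_juv_mortality", "female_juv_mortality"),
    "amb": ("male_adult_mortality", "female_adult_mortality"),
    "mat": ("male_maturation_age", "female_maturation_age"),
}


class TraitError(ValueError):
    pass


def _ratio_metric(male: pd.Series, female: pd.Series, name: str) -> pd.Series:
    male = pd.to_numeric(male, errors="coerce")
    female = pd.to_numeric(female, errors="coerce")
    if (male.dropna() < 0).any() or (female.dropna() < 0).any():
        raise TraitError(f"negative input for {name}")
    zero = female == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} records with female rate 0 for {name}; "
            "metric set to missing",
            stacklevel=3,
        )
    out = np.log10(male.where(male > 0) / female.where(female > 0))
    return out


def _proportion(males: pd.Series, females: pd.Series, name: str) -> pd.Series:
    males = pd.to_numeric(males, errors="coerce")
    females = pd.to_numeric(females, errors="coerce")
    if (males.dropna() < 0).any() or (females.dropna() < 0).any():
        raise TraitError(f"negative count for {name}")
    total = males + females
    return males / total.where(total > 0)


def compute_bias_metrics(raw: pd.DataFrame) -> pd.DataFrame:
    """Per-species trait table from raw sex-specific records.

    ``raw`` has one row per population record with a ``species`` column, an
    optional ``gsd`` column, and any of the sex-specific columns listed in
    :data:`RAW_COLUMNS`; ready-made metric columns (``asr`` ... ``mat``) are
    passed through.  Species with multiple records get the arithmetic mean of
    each metric.
    """
    if "species" not in raw.columns:
        raise TraitError("raw table needs a 'species' column")
    rec = pd.DataFrame({"species": raw["species"].astype(str)})
    for metric, (mcol, fcol) in RAW_COLUMNS.items():
        if mcol in raw.columns and fcol in raw.columns:
            if metric in ("asr", "bsr"):
                rec[metric] = _proportion(raw[mcol], raw[fcol], metric)
            else:
                rec[metric] = _ratio_metric(raw[mcol], raw[fcol], metric)
        elif metric in raw.columns:
            rec[metric] = pd.to_numeric(raw[metric], errors="coerce")
    present = [c for c in CONTINUOUS_VARS if c in rec.columns]
    table = rec.groupby("species", sort=True)[present].mean().reset_index()
    if "gsd" in raw.columns:
        gsd = (
            raw[["species", "gsd"]]
            .dropna()
            .drop_duplicates("species")
            .set_index("species")["gsd"]
            .astype(str)
        )
        bad = set(gsd.unique()) - {"XY", "ZW"}
        if bad:
            raise TraitError(f"unknown GSD labels: {sorted(bad)}")
        table["gsd"] = table["species"].map(gsd)
    for col in ("asr", "bsr"):
        if col in table.columns:
            vals = table[col].dropna()
            if ((vals < 0) | (vals > 1)).any():
                raise TraitError(f"{col} outside [0, 1]")
    return table


def standardize(values: pd.Series) -> pd.Series:
    """z-scores over the non-missing entries (sample SD); missing preserved."""
    vals = pd.to_numeric(values, errors="coerce")
    nonmiss = vals.dropna()
    if len(nonmiss) < 2:
        raise TraitError(f"cannot standardize '{values.name}': <2 values")
    sd = nonmiss.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise TraitError(f"cannot standardize constant column '{values.name}'")
    return (vals - nonmiss.mean()) / sd


def standardize_table(
    table: pd.DataFrame, columns: Sequence[str] | None = None
) -> pd.DataFrame:
    """Append ``_z`` columns for each continuous variable present."""
    out = table.copy()
    cols = columns if columns is not None else [
        c for c in CONTINUOUS_VARS if c in table.columns
    ]
    for col in cols:
        out[col + "_z"] = standardize(table[col])
    return out


def gsd_indicator(gsd: pd.Series, reference: str = "XY") -> pd.Series:
    """Numeric coding of the GSD factor: reference level 0, the other 1."""
    other = "ZW" if reference == "XY" else "XY"
    mapping = {reference: 0.0, other: 1.0}
    return gsd.map(mapping)


def flag_outliers(values: pd.Series, groups: pd.Series, z: float = 3.0) -> pd.Series:
    """High-leverage flags: more than ``z`` group SDs from the group mean,
    with groups assessed separately.  Groups with fewer than 3 members get no
    flags (with a warning)."""
    vals = pd.to_numeric(values, errors="coerce")
    flags = pd.Series(False, index=values.index)
    for label, idx in groups.dropna().groupby(groups).groups.items():
        sub = vals.loc[idx].dropna()
        if len(sub) < 3:
            warnings.warn(
                f"group {label!r} has <3 members; no outlier flags", stacklevel=2
            )
            continue
        mu, sd = sub.mean(), sub.std(ddof=1)
        if sd == 0:
            continue
        flags.loc[sub.index] = (sub - mu).abs() / sd > z
    return flags


def model_subset(
    table: pd.DataFrame,
    variables: Iterable[str],
    tree: Phylogeny | None = None,
    standardize_scope: str = "subset",
) -> tuple[pd.DataFrame, Phylogeny | None]:
    """Complete cases for the named variables, matched against the tree.

    ``standardize_scope`` controls where z-scores are computed: ``"subset"``
    (default; z-scores refer to exactly the species entering the model, so
    group coefficients read directly as Cohen's d) or ``"full"`` (z-scores
    inherited from the full table before subsetting).
    """
    variables = list(variables)
    missing_cols = [v for v in variables if v not in table.columns]
    if missing_cols:
        raise TraitError(f"unknown variables: {missing_cols}")
    work = table
    if standardize_scope == "full":
        cont = [v for v in variables if v in CONTINUOUS_VARS]
        work = standardize_table(work, cont)
    sub = work.dropna(subset=variables).copy()
    if tree is not None:
        labels = [s for s in sub["species"] if s in set(tree.tip_labels)]
        sub = sub[sub["species"].isin(labels)]
    if sub.empty:
        raise TraitError("no complete cases for requested variables")
    if standardize_scope == "subset":
        cont = [v for v in variables if v in CONTINUOUS_VARS]
        sub = standardize_table(sub, cont)
    pruned = tree.prune(list(sub["species"])) if tree is not None else None
    if pruned is not None:
        order = {lab: i for i, lab in enumerate(pruned.tip_labels)}
        sub = sub.sort_values("species", key=lambda s: s.map(order))
    return sub.reset_index(drop=True), pruned


def read_trait_csv(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a species trait CSV, optionally renaming columns via
    ``column_map`` ({file column -> canonical name})."""
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    if "species" not in df.columns:
        raise TraitError("trait CSV needs a 'species' column (use column_map)")
    df["species"] = df["species"].astype(str).str.replace(" ", "_")
    if df["species"].duplicated().any():
        dups = df.loc[df["species"].duplicated(), "species"].tolist()
        raise TraitError(f"duplicate species rows: {dups[:5]}")
    return df
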