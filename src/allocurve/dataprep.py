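"""Validation and transformation of species- and individual-level tables.

Species-level tables hold one row per species with log10 brain and body
masses in grams plus class/subclade labels; individual-level tables hold
one row per measured specimen with sex and measurement-method labels.
All operations work on pandas DataFrames and preserve column order.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "SPECIES_COLUMNS",
    "INDIVIDUAL_COLUMNS",
    "read_species_table",
    "read_individual_table",
    "volume_to_mass",
    "center_sex_method",
    "filter_min_individuals",
    "filter_subclades",
    "within_group_center",
]

SPECIES_COLUMNS = ["species", "log10_body_g", "log10_brain_g", "class"]
INDIVIDUAL_COLUMNS = ["species", "log10_body_g", "log10_brain_g", "sex", "method"]
SEX_LEVELS = {"male", "female", "unreported"}
METHOD_LEVELS = {"mass", "volume"}


class SchemaError(ValueError):
    pass


def _check_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")


def _check_finite(df: pd.DataFrame, cols, path) -> None:
    for c in cols:
        bad = df.index[~np.isfinite(df[c].astype(float))].tolist()
        if bad:
            raise SchemaError(
                f"{path}: non-finite values in column '{c}' at rows "
                f"{[i + 2 for i in bad[:5]]} (1-based, incl. header)"
            )


def read_species_table(path, sep: str = "\t") -> pd.DataFrame:
    """Read and validate a species-level TSV/CSV table.

    Required columns: species, log10_body_g, log10_brain_g, class; an
    optional subclade column is preserved. Duplicate species are an error
    (duplicates must be resolved upstream during curation).
    """
    df = pd.read_csv(path, sep=sep)
    _check_columns(df, SPECIES_COLUMNS, path)
    _check_finite(df, ["log10_body_g", "log10_brain_g"], path)
    dup = df.species[df.species.duplicated()].unique().tolist()
    if dup:
        raise SchemaError(f"{path}: duplicate species rows: {dup[:5]}")
    if df["class"].isna().any() or (df["class"].astype(str) == "").any():
        raise SchemaError(f"{path}: empty class labels")
    return df


def read_individual_table(path, sep: str = "\t") -> pd.DataFrame:
    """Read and validate an individual-level table (one row per specimen)."""
    df = pd.read_csv(path, sep=sep)
    _check_columns(df, INDIVIDUAL_COLUMNS, path)
    _check_finite(df, ["log10_body_g", "log10_brain_g"], path)
    bad_sex = set(df.sex.unique()) - SEX_LEVELS
    if bad_sex:
        raise SchemaError(f"{path}: invalid sex labels {sorted(bad_sex)}")
    bad_m = set(df.method.unique()) - METHOD_LEVELS
    if bad_m:
        raise SchemaError(f"{path}: invalid method labels {sorted(bad_m)}")
    return df


def volume_to_mass(volume):
    """Endocranial volume (cm^3) to brain mass (g) at unit density.

    The conventional 1 g = 1 cm^3 conversion used across major brain-size
    compilations: numerically the identity.
    """
    v = np.asarray(volume, dtype=float)
    if np.any(v < 0):
        raise ValueError("volume must be nonnegative")
    return v if v.shape else float(v)


def center_sex_method(records: pd.DataFrame) -> pd.DataFrame:
    """Remove sex- and method-group offsets within each species.

    Within each species, each (sex x method) group's mean log10 brain and
    body values are shifted onto the species grand mean, so dimorphism and
    measurement-method offsets do not inflate within-species variance.
    Species grand means are unchanged up to float rounding.
    """
    out = records.copy()
    for col in ("log10_body_g", "log10_brain_g"):
        grand = out.groupby("species")[col].transform("mean")
        group = out.groupby(["species", "sex", "method"])[col].transform("mean")
        out[col] = out[col] - group + grand
    return out


def filter_min_individuals(records: pd.DataFrame, min_n: int = 10) -> pd.DataFrame:
    """Drop species represented by fewer than ``min_n`` individuals."""
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    counts = records.groupby("species")["species"].transform("size")
    kept = records[counts >= min_n].reset_index(drop=True)
    if kept.empty and not records.empty:
        warnings.warn(f"no species has >= {min_n} individuals", stacklevel=2)
    return kept


def filter_subclades(
    species: pd.DataFrame, min_n: int = 20, exceptions=()
) -> pd.DataFrame:
    """Retain subclades with at least ``min_n`` species, plus exceptions.

    Species without a subclade assignment are dropped (they cannot enter
    subclade-level models). ``exceptions`` lists subclades retained
    regardless of size (e.g. a small group kept to enable a planned
    comparison).
    """
    if "subclade" not in species.columns:
        raise SchemaError("species table has no 'subclade' column")
    df = species[species.subclade.notna() & (species.subclade.astype(str) != "")]
    sizes = df.groupby("subclade")["species"].size()
    keep = set(sizes.index[sizes >= min_n]) | (set(exceptions) & set(sizes.index))
    return df[df.subclade.isin(keep)].reset_index(drop=True)


def within_group_center(records: pd.DataFrame) -> pd.DataFrame:
    """Within-group centring: split each individual's body size into the
    species mean (across-species component) and the deviation from it.

    Returns the input plus columns:

    - ``across_body``: species mean of log10 body mass,
    - ``within_body``: individual deviation from that mean (sums to zero
      within every species),
    - ``within_body_sq_centred``: log10 body mass squared minus its
      species mean (the species-centred quadratic term),
    - ``n_individuals``: species sample size.
    """
    out = records.copy()
    g = out.groupby("species")["log10_body_g"]
    out["across_body"] = g.transform("mean")
    out["within_body"] = out["log10_body_g"] - out["across_body"]
    sq = out["log10_body_g"] ** 2
    out["within_body_sq_centred"] = sq - sq.groupby(out["species"]).transform("mean")
    out["n_individuals"] = g.transform("size")
    return out
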