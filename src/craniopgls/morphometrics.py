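"""Linear cranial morphometrics: size, log-shape ratios, species means.

Ten linear cranial measurements per specimen (mm) are reduced to a
geometric-mean size and ten Mosimann log-shape ratios

    size_i = (prod_j x_ij)^(1/p),      z_ij = log(x_ij / size_i),

so each specimen's z row sums to zero and is invariant to uniform
rescaling of the raw measurements: size carries scale, z carries shape.
Species means of shape ratios and of the facial-tilt angle feed the
phylogenetic analyses; per-group summaries of the facial-tilt angle are
computed at the specimen level.
"""

from __future__ import annotations

import importlib.resources
import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Table-2 measurement abbreviations, in canonical column order.
MEASUREMENT_COLUMNS = [
    "BLD",  # bulla diameter
    "BOL",  # basioccipital length
    "DIL",  # diastema length
    "IOW",  # interorbital width
    "NL",   # nasal length
    "NW",   # nasal width
    "PAL",  # parietal length
    "SCF",  # splenius capitis fossa length
    "SLD",  # skull length, dorsal
    "SW",   # skull width
]

LOCOMOTION_LEVELS = ("cursorial", "generalized", "saltatorial")


# ---------------------------------------------------------------------
# table ingestion
# ---------------------------------------------------------------------

def read_measurements(path_or_buf, drop_incomplete: bool = True,
                      adult_column: str | None = None) -> pd.DataFrame:
    """Read a specimen measurement CSV (specimen_id, species, 10 variables).

    Rows with missing or non-positive measurements are dropped with a
    warning by default; ``drop_incomplete=False`` raises instead.  If
    ``adult_column`` names a boolean column, rows flagged False
    (juveniles, e.g. unfused occipital sutures) are dropped with a
    logged count.
    """
    df = pd.read_csv(path_or_buf)
    return validate_measurements(df, drop_incomplete=drop_incomplete,
                                 adult_column=adult_column)


def validate_measurements(df: pd.DataFrame, drop_incomplete: bool = True,
                          adult_column: str | None = None) -> pd.DataFrame:
    required = ["specimen_id", "species", *MEASUREMENT_COLUMNS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"measurement table missing columns: {missing}")
    df = df.copy()
    if adult_column is not None:
        juv = ~df[adult_column].astype(bool)
        if juv.any():
            logger.info("dropping %d juvenile specimens", int(juv.sum()))
            df = df.loc[~juv]
    vals = df[MEASUREMENT_COLUMNS].apply(pd.to_numeric, errors="coerce")
    bad = vals.isna().any(axis=1) | (vals <= 0).any(axis=1)
    if bad.any():
        offenders = df.loc[bad, "specimen_id"].tolist()
        if not drop_incomplete:
            raise ValueError(
                f"missing or non-positive measurements for specimens {offenders}"
            )
        warnings.warn(
            f"dropping {int(bad.sum())} specimens with missing/non-positive "
            f"measurements: {offenders}",
            stacklevel=2,
        )
        df = df.loc[~bad]
    if df["specimen_id"].duplicated().any():
        dup = df.loc[df["specimen_id"].duplicated(), "specimen_id"].tolist()
        raise ValueError(f"duplicate specimen_id values: {dup}")
    if len(df) == 0:
        raise ValueError("no valid specimens remain")
    df["species"] = df["species"].str.strip()
    df[MEASUREMENT_COLUMNS] = vals.loc[df.index]
    return df.reset_index(drop=True)


def read_facial_tilt(path_or_buf) -> pd.DataFrame:
    """Read a facial-tilt CSV (specimen_id, species, FT in degrees)."""
    df = pd.read_csv(path_or_buf)
    for col in ("specimen_id", "species", "FT"):
        if col not in df.columns:
            raise ValueError(f"facial-tilt table missing column: {col}")
    df = df.copy()
    df["species"] = df["species"].str.strip()
    df["FT"] = pd.to_numeric(df["FT"])
    if not np.isfinite(df["FT"]).all():
        raise ValueError("non-finite FT values")
    if df["specimen_id"].duplicated().any():
        raise ValueError("duplicate specimen_id values in facial-tilt table")
    return df


def read_ecology(path_or_buf) -> pd.DataFrame:
    """Read a species-level ecology CSV (species, locomotion, burrowing)."""
    df = pd.read_csv(path_or_buf)
    return validate_ecology(df)


def validate_ecology(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("species", "locomotion", "burrowing"):
        if col not in df.columns:
            raise ValueError(f"ecology table missing column: {col}")
    df = df.copy()
    df["species"] = df["species"].str.strip()
    if df["species"].duplicated().any():
        raise ValueError("ecology table must have one row per species")
    df["locomotion"] = df["locomotion"].str.strip().str.lower()
    bad = sorted(set(df["locomotion"]) - set(LOCOMOTION_LEVELS))
    if bad:
        raise ValueError(
            f"unknown locomotion levels {bad}; expected {LOCOMOTION_LEVELS}"
        )
    if df["burrowing"].dtype == object:
        df["burrowing"] = (
            df["burrowing"].str.strip().str.lower().map({"yes": True, "no": False,
                                                         "true": True, "false": False})
        )
    if df["burrowing"].isna().any():
        raise ValueError("burrowing must be yes/no")
    df["burrowing"] = df["burrowing"].astype(bool)
    return df.reset_index(drop=True)


def load_leporid_ecology() -> pd.DataFrame:
    """Packaged 16-species leporid ecology fixture (locomotion, burrowing, n)."""
    ref = importlib.resources.files("craniopgls") / "data" / "leporid_ecology.csv"
    with ref.open("r", encoding="utf-8") as fh:
        return validate_ecology(pd.read_csv(fh))


# ---------------------------------------------------------------------
# size and shape
# ---------------------------------------------------------------------

def geometric_mean_size(x) -> float:
    """Geometric mean of a vector of positive measurements."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("expected a 1-D vector of measurements")
    if not np.all(np.isfinite(x)) or np.any(x <= 0):
        raise ValueError("all measurements must be finite and > 0")
    return float(np.exp(np.mean(np.log(x))))


def log_shape_ratios(measurements: pd.DataFrame,
                     columns: list[str] | None = None) -> pd.DataFrame:
    """Per-specimen geometric-mean size and log-shape ratios.

    Returns a frame with specimen_id, species, size, and one ``z_<var>``
    column per measurement.  Rows of z sum to zero by construction.
    """
    cols = MEASUREMENT_COLUMNS if columns is None else list(columns)
    missing = [c for c in cols if c not in measurements.columns]
    if missing:
        raise ValueError(f"missing measurement columns: {missing}")
    X = measurements[cols].to_numpy(dtype=float)
    if np.any(~np.isfinite(X)) or np.any(X <= 0):
        i, j = np.argwhere(~(np.isfinite(X) & (X > 0)))[0]
        raise ValueError(
            f"non-positive/missing measurement {cols[j]} for specimen "
            f"{measurements['specimen_id'].iloc[i]}"
        )
    logX = np.log(X)
    log_size = logX.mean(axis=1, keepdims=True)
    Z = logX - log_size
    out = measurements[["specimen_id", "species"]].copy()
    out["size"] = np.exp(log_size[:, 0])
    for k, c in enumerate(cols):
        out[f"z_{c}"] = Z[:, k]
    return out


def shape_columns(shape_table: pd.DataFrame) -> list[str]:
    return [c for c in shape_table.columns if c.startswith("z_")]


def species_means(values: pd.DataFrame, taxa_order: list[str],
                  columns: list[str] | None = None) -> pd.DataFrame:
    """Arithmetic per-species means, rows re-indexed to ``taxa_order``.

    ``values`` is any per-specimen table with a ``species`` column;
    ``columns`` defaults to all numeric columns except ``size``.
    """
    if columns is None:
        columns = [c for c in values.columns
                   if c not in ("specimen_id", "species", "size")
                   and pd.api.types.is_numeric_dtype(values[c])]
    have = set(values["species"])
    empty = [t for t in taxa_order if t not in have]
    if empty:
        raise ValueError(f"taxa with no specimens: {empty}")
    means = values.groupby("species")[columns].mean()
    return means.reindex(taxa_order)


def summarize_ft_by_group(ft: pd.DataFrame, ecology: pd.DataFrame) -> pd.DataFrame:
    """Specimen-level FT mean/SD (ddof=1) per locomotor group and burrowing level.

    Returns a tidy frame with columns factor, level, n, mean, sd.
    """
    ecology = validate_ecology(ecology)
    missing = sorted(set(ft["species"]) - set(ecology["species"]))
    if missing:
        raise ValueError(f"species missing from ecology table: {missing}")
    merged = ft.merge(ecology, on="species", how="left")
    rows = []
    for factor in ("locomotion", "burrowing"):
        for level, grp in merged.groupby(factor, sort=True):
            rows.append({
                "factor": factor,
                "level": str(level),
                "n": int(len(grp)),
                "mean": float(grp["FT"].mean()),
                "sd": float(grp["FT"].std(ddof=1)) if len(grp) > 1 else 0.0,
            })
    return pd.DataFrame(rows)
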