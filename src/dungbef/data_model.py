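"""Typed containers, CSV schemas and validation for the study tables.

A *study bundle* holds the five tables the pipeline consumes:

``sites``
    one row per pasture (site-regime); pastures come in low/high-intensity
    pairs sharing a ``landscape_id`` and a biogeographical ``region``.
``covariates``
    per-pasture management covariates (cattle density, anthelmintic use,
    land history) plus 13 bioclimatic columns (any names prefixed ``bio``).
``dungpats``
    per-dung-pat wet/dry weights for experimental and control units.
``occurrences``
    per-pasture species abundances with food-relocation guild labels.
``traits``
    per-individual morphological measurements (nine linear traits, in mm)
    and dry biomass (g).

All tables are plain :class:`pandas.DataFrame` objects; validation is
performed eagerly by :func:`read_tables` and :func:`validate_bundle`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GUILDS",
    "GUILD_ALIASES",
    "TRAIT_COLUMNS",
    "BODY_LENGTH_PARTS",
    "SchemaError",
    "ValidationError",
    "StudyBundle",
    "read_tables",
    "write_tables",
    "validate_bundle",
    "normalize_guilds",
]


class SchemaError(ValueError):
    """A required column is missing or a table cannot be parsed."""


class ValidationError(ValueError):
    """A table parses but violates a content invariant."""


#: The four food-relocation guilds (canonical vocabulary).
GUILDS = ("paracoprid", "telecoprid", "endocoprid", "kleptocoprid")

#: Behavioral synonyms accepted on input and normalized to the canonical
#: guild names: tunnelers, rollers, dwellers and kleptoparasites.
GUILD_ALIASES = {
    "tunneler": "paracoprid",
    "roller": "telecoprid",
    "dweller": "endocoprid",
    "kleptoparasite": "kleptocoprid",
}

#: The nine linear morphological traits (mm), in canonical column order.
TRAIT_COLUMNS = (
    "head_length",
    "head_width",
    "pronotum_length",
    "pronotum_width",
    "pronotum_height",
    "elytra_length",
    "protibia_length",
    "protibia_width",
    "metatibia_length",
)

#: Components summed to obtain body length.
BODY_LENGTH_PARTS = ("head_length", "pronotum_length", "elytra_length")

REGIMES = ("low", "high")
REGIME_CODES = {"low": 0, "high": 1}
PAT_ROLES = ("experimental", "control")

# Required (non-bioclim) columns per table.
SCHEMAS = {
    "sites": ["site_id", "landscape_id", "region", "regime", "latitude", "longitude"],
    "covariates": ["site_id", "cattle_density", "anthelmintic_use", "land_history"],
    "dungpats": ["site_id", "regime", "unit_id", "role", "iw_wet", "fw_wet", "fw_dry", "exposure_h"],
    "occurrences": ["site_id", "regime", "species_id", "guild", "abundance"],
    "traits": ["species_id", "individual_id", *TRAIT_COLUMNS, "biomass"],
}

TABLE_FILES = {name: f"{name}.csv" for name in SCHEMAS}

# canonical numeric dtypes enforced on read (CSV round-trips otherwise
# demote e.g. 300.0 to an integer column)
FLOAT_COLUMNS = {
    "sites": ["latitude", "longitude"],
    "covariates": ["cattle_density"],
    "dungpats": ["iw_wet", "fw_wet", "fw_dry", "exposure_h"],
    "traits": [*TRAIT_COLUMNS, "biomass"],
}
INT_COLUMNS = {
    "covariates": ["anthelmintic_use", "land_history"],
    "occurrences": ["abundance"],
}

#: Expected replication of the field design (soft checks emit warnings).
N_EXPERIMENTAL_PATS = 10
N_CONTROL_PATS = 5
N_BIOCLIM = 13


@dataclass
class StudyBundle:
    """The five validated study tables plus convenience accessors."""

    sites: pd.DataFrame
    covariates: pd.DataFrame
    dungpats: pd.DataFrame
    occurrences: pd.DataFrame
    traits: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "sites": self.sites,
            "covariates": self.covariates,
            "dungpats": self.dungpats,
            "occurrences": self.occurrences,
            "traits": self.traits,
        }

    @property
    def bioclim_columns(self) -> list[str]:
        return [c for c in self.covariates.columns if c.startswith("bio")]

    @property
    def landscape_ids(self) -> list[str]:
        return sorted(self.sites["landscape_id"].unique())

    def site_pair(self, landscape_id: str) -> dict[str, str]:
        """Map regime -> site_id for one landscape."""
        rows = self.sites[self.sites["landscape_id"] == landscape_id]
        return dict(zip(rows["regime"], rows["site_id"]))

    def equals(self, other: "StudyBundle") -> bool:
        mine, theirs = self.tables(), other.tables()
        return all(mine[k].equals(theirs[k]) for k in mine)


def normalize_guilds(guilds: pd.Series, aliases: bool = True) -> pd.Series:
    """Lower-case guild labels and optionally map behavioral synonyms."""
    out = guilds.astype(str).str.strip().str.lower()
    if aliases:
        out = out.replace(GUILD_ALIASES)
    return out


def _require_columns(df: pd.DataFrame, table: str) -> None:
    missing = [c for c in SCHEMAS[table] if c not in df.columns]
    if missing:
        raise SchemaError(f"table '{table}' is missing required column(s): {', '.join(missing)}")


def _check_range(ok: pd.Series, table: str, id_col: pd.Series, message: str) -> None:
    if not ok.all():
        bad = id_col[~ok].iloc[0]
        raise ValidationError(f"{table}: {message} (first offending row id: {bad!r})")


def validate_bundle(bundle: StudyBundle, strict: bool = False) -> StudyBundle:
    """Check every content invariant; raise :class:`ValidationError` on the
    first violation, warn on soft deviations from the field design.

    With ``strict=True`` the cattle-density regime thresholds (< 2 for low,
    > 4 animals/ha for high) are enforced as errors instead of warnings.
    """
    sites, cov = bundle.sites, bundle.covariates
    pats, occ, traits = bundle.dungpats, bundle.occurrences, bundle.traits
    for name, df in bundle.tables().items():
        _require_columns(df, name)

    # --- sites ----------------------------------------------------------
    _check_range(sites["latitude"].between(-90, 90), "sites", sites["site_id"],
                 "latitude outside [-90, 90]")
    _check_range(sites["longitude"].between(-180, 180), "sites", sites["site_id"],
                 "longitude outside [-180, 180]")
    bad_regime = ~sites["regime"].isin(REGIMES)
    _check_range(~bad_regime, "sites", sites["site_id"], "regime not in {low, high}")
    if sites["site_id"].duplicated().any():
        dup = sites.loc[sites["site_id"].duplicated(), "site_id"].iloc[0]
        raise ValidationError(f"sites: duplicated site_id {dup!r}")
    pair_shape = sites.groupby("landscape_id")["regime"].agg(["count", "nunique"])
    bad_pairs = pair_shape[(pair_shape["count"] != 2) | (pair_shape["nunique"] != 2)]
    if len(bad_pairs):
        raise ValidationError(
            "sites: every landscape needs exactly one low- and one high-intensity "
            f"pasture (first offending landscape: {bad_pairs.index[0]!r})")

    # --- covariates -----------------------------------------------------
    known_sites = set(sites["site_id"])
    _check_range(cov["site_id"].isin(known_sites), "covariates", cov["site_id"],
                 "site_id not present in sites table")
    _check_range(cov["cattle_density"] > 0, "covariates", cov["site_id"],
                 "cattle_density must be > 0")
    _check_range(cov["anthelmintic_use"].isin([0, 1, 2, 3, 4]), "covariates",
                 cov["site_id"], "anthelmintic_use must be an integer in 0..4")
    _check_range(cov["land_history"] >= 0, "covariates", cov["site_id"],
                 "land_history must be >= 0")
    bio_cols = bundle.bioclim_columns
    if len(bio_cols) != N_BIOCLIM:
        warnings.warn(
            f"covariates: expected {N_BIOCLIM} bioclimatic columns (prefix 'bio'), "
            f"found {len(bio_cols)}", stacklevel=2)
    regime_of = sites.set_index("site_id")["regime"]
    dens = cov.set_index("site_id")["cattle_density"]
    low_bad = dens[regime_of.reindex(dens.index) == "low"] >= 2
    high_bad = dens[regime_of.reindex(dens.index) == "high"] <= 4
    if low_bad.any() or high_bad.any():
        msg = ("covariates: cattle density outside the regime definition "
               "(< 2 animals/ha for low, > 4 for high)")
        if strict:
            raise ValidationError(msg)
        warnings.warn(msg, stacklevel=2)

    # --- dung pats ------------------------------------------------------
    _check_range(pats["site_id"].isin(known_sites), "dungpats", pats["unit_id"],
                 "site_id not present in sites table")
    _check_range(pats["role"].isin(PAT_ROLES), "dungpats", pats["unit_id"],
                 "role must be experimental or control")
    _check_range(pats["iw_wet"] > 0, "dungpats", pats["unit_id"],
                 "initial wet weight must be > 0")
    for col in ("fw_wet", "fw_dry"):
        _check_range(pats[col] >= 0, "dungpats", pats["unit_id"],
                     f"{col} must be >= 0")
    _check_range(pats["fw_dry"] <= pats["fw_wet"], "dungpats", pats["unit_id"],
                 "final dry weight exceeds final wet weight")
    design = pats.pivot_table(index="site_id", columns="role", values="unit_id",
                              aggfunc="count", fill_value=0)
    n_exp = design.get("experimental", pd.Series(0, index=design.index))
    n_ctl = design.get("control", pd.Series(0, index=design.index))
    off = (n_exp != N_EXPERIMENTAL_PATS) | (n_ctl != N_CONTROL_PATS)
    if off.any():
        warnings.warn(
            f"dungpats: {int(off.sum())} site(s) deviate from the "
            f"{N_EXPERIMENTAL_PATS} experimental + {N_CONTROL_PATS} control design",
            stacklevel=2)

    # --- occurrences ----------------------------------------------------
    _check_range(occ["site_id"].isin(known_sites), "occurrences", occ["species_id"],
                 "site_id not present in sites table")
    unknown = ~occ["guild"].isin(GUILDS)
    if unknown.any():
        bad = occ.loc[unknown, "guild"].iloc[0]
        raise ValidationError(
            f"occurrences: unknown guild label {bad!r}; canonical labels are "
            f"{GUILDS} (aliases {tuple(GUILD_ALIASES)} are normalized on read)")
    _check_range(occ["abundance"] >= 0, "occurrences", occ["species_id"],
                 "abundance must be >= 0")
    if not (occ["abundance"] == occ["abundance"].round()).all():
        raise ValidationError("occurrences: abundance must be integer counts")

    # --- traits ---------------------------------------------------------
    if len(traits):
        trait_vals = traits[list(TRAIT_COLUMNS) + ["biomass"]]
        bad_mask = ((trait_vals <= 0) & trait_vals.notna()).any(axis=1)
        if bad_mask.any():
            bad = traits.loc[bad_mask, "individual_id"].iloc[0]
            raise ValidationError(
                f"traits: non-positive trait value (first offending individual: {bad!r})")
        measured = occ.loc[occ["abundance"] > 0, "species_id"].unique()
        missing = set(measured) - set(traits["species_id"])
        if missing:
            warnings.warn(
                f"traits: {len(missing)} species occur but have no measured "
                "individuals; their functional contribution cannot be computed",
                stacklevel=2)
    return bundle


def read_tables(directory: str | Path, aliases: bool = True,
                strict: bool = False) -> StudyBundle:
    """Read the five study CSVs from ``directory`` and validate them.

    Parameters
    ----------
    directory
        Folder containing ``sites.csv``, ``covariates.csv``, ``dungpats.csv``,
        ``occurrences.csv`` and ``traits.csv``.
    aliases
        Normalize behavioral guild synonyms ("tunneler", "roller", "dweller",
        "kleptoparasite") to the canonical guild vocabulary.
    strict
        Enforce regime cattle-density thresholds as errors.
    """
    directory = Path(directory)
    frames: dict[str, pd.DataFrame] = {}
    for name, fname in TABLE_FILES.items():
        path = directory / fname
        if not path.exists():
            raise SchemaError(f"missing input table: {path}")
        df = pd.read_csv(path)
        _require_columns(df, name)
        for col in FLOAT_COLUMNS.get(name, []):
            df[col] = df[col].astype(float)
        for col in INT_COLUMNS.get(name, []):
            df[col] = df[col].astype("int64")
        frames[name] = df
    frames["occurrences"]["guild"] = normalize_guilds(frames["occurrences"]["guild"],
                                                      aliases=aliases)
    bundle = StudyBundle(**frames)
    return validate_bundle(bundle, strict=strict)


def write_tables(bundle: StudyBundle, directory: str | Path,
                 validate: bool = True) -> dict[str, Path]:
    """Write the bundle as CSVs with deterministic column order and float
    formatting; the output is re-readable by :func:`read_tables`."""
    if validate:
        validate_bundle(bundle)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, df in bundle.tables().items():
        required = SCHEMAS[name]
        extra = [c for c in df.columns if c not in required]
        ordered = df[required + sorted(extra)]
        path = directory / TABLE_FILES[name]
        ordered.to_csv(path, index=False, float_format="%.10g")
        written[name] = path
    return written
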