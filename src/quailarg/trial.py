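"""Raw trial records and derived nutritional response variables.

A laying trial observes, per bird and collection period: feed intake, egg
production rate, egg weight, and body weight at the start and end of the
period. From these and a body/egg composition table the module derives the
arginine flows that drive the response analysis: dietary arginine intake,
arginine deposited in egg output, and arginine mobilized from (or accreted
to) the body, each in mg/bird·d, plus their standardization to metabolic
body-weight units (mg/kg BW^0.67·d).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import DomainError, ParseError, SchemaError

__all__ = [
    "Composition",
    "TrialRecord",
    "read_trial",
    "write_trial",
    "arg_intake",
    "egg_mass",
    "egg_arg_deposition",
    "arg_mobilization",
    "metabolic_weight",
    "standardize_metabolic",
    "derive_birds",
    "summarize_treatments",
]

#: default allometric exponent for metabolic body weight
METABOLIC_EXPONENT = 0.67


@dataclass(frozen=True)
class Composition:
    """Protein/arginine composition constants used to convert egg mass and
    body-weight change into arginine flows.

    Parameters
    ----------
    egg_protein
        Crude protein content of whole egg, g CP per kg egg.
    egg_arg_per_cp
        Arginine content of egg protein, g arginine per 100 g CP.
    body_arg
        Arginine content of quail body tissue, mg arginine per g body weight.
    collection_days
        Length of the collection window over which body-weight change was
        measured, days.
    egg_arg_coeff
        Optional direct override of the egg arginine coefficient
        (mg arginine per g egg). When ``None`` the coefficient is the product
        ``egg_protein × egg_arg_per_cp / 100``.
    """

    egg_protein: float = 129.9
    egg_arg_per_cp: float = 5.14
    body_arg: float = 9.40
    collection_days: int = 28
    egg_arg_coeff: float | None = None

    def __post_init__(self):
        for name in ("egg_protein", "egg_arg_per_cp", "body_arg"):
            if getattr(self, name) <= 0:
                raise DomainError(f"composition field {name} must be positive")
        if int(self.collection_days) < 1:
            raise DomainError("collection_days must be an integer >= 1")

    @property
    def egg_arg_mg_per_g(self) -> float:
        """Arginine per g of whole egg, mg/g."""
        if self.egg_arg_coeff is not None:
            return float(self.egg_arg_coeff)
        # g CP/kg egg x (g Arg/100 g CP) -> g Arg/kg egg == mg Arg/g egg
        return self.egg_protein * self.egg_arg_per_cp / 100.0

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "Composition":
        known = {k: mapping[k] for k in (
            "egg_protein", "egg_arg_per_cp", "body_arg",
            "collection_days", "egg_arg_coeff") if k in mapping}
        return cls(**known)

    @classmethod
    def from_yaml(cls, path) -> "Composition":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_mapping(data)

    def with_coefficient(self, coeff: float) -> "Composition":
        return replace(self, egg_arg_coeff=coeff)


@dataclass(frozen=True)
class TrialRecord:
    """One bird-period observation of raw measured variables."""

    bird_id: str
    treatment: str
    arg_level: float          # dietary arginine, g/kg
    feed_intake: float        # g/bird·d
    egg_production: float     # fraction of days with an egg, 0-1
    egg_weight: float         # g
    bw_initial: float         # g
    bw_final: float           # g

    def __post_init__(self):
        if self.feed_intake < 0:
            raise DomainError(f"{self.bird_id}: negative feed intake")
        if not 0 <= self.egg_production <= 1:
            raise DomainError(f"{self.bird_id}: egg production outside [0, 1]")
        if self.egg_production > 0 and self.egg_weight < 0:
            raise DomainError(f"{self.bird_id}: negative egg weight")
        if self.bw_initial <= 0 or self.bw_final <= 0:
            raise DomainError(f"{self.bird_id}: nonpositive body weight")


# canonical column -> accepted header aliases (headers are normalized to
# lowercase with underscores before lookup)
_ALIASES = {
    "observation": {"observation", "obs"},
    "cage": {"cage"},
    "treatment": {"treatment", "diet", "trt"},
    "replicate": {"replicate", "rep"},
    "arg_level": {"arg_level", "level_of_arginine", "arginine_level", "level"},
    "feed_intake": {"feed_intake", "fi"},
    "egg_production": {"egg_production", "ep"},
    "egg_weight": {"egg_weight", "ew"},
    "bw_initial": {"bw_initial", "initial_body_weight", "initial_bw"},
    "bw_final": {"bw_final", "final_body_weight", "final_bw"},
}
_REQUIRED = ("treatment", "arg_level", "feed_intake", "egg_production",
             "egg_weight", "bw_initial", "bw_final")
_NUMERIC = ("arg_level", "feed_intake", "egg_production", "egg_weight",
            "bw_initial", "bw_final")


def _normalize_header(name: str) -> str:
    return str(name).strip().lower().replace(" ", "_").replace("-", "_")


def read_trial(path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a per-bird trial table (CSV/TSV) into canonical columns.

    The header is matched case-insensitively against known aliases (e.g.
    ``"level of arginine"`` maps to ``arg_level``). Egg production values
    greater than 1 are treated as percentages and normalized to fractions
    with a warning. Returns a DataFrame with one row per bird and a
    ``bird_id`` column built from cage, or treatment and replicate, when no
    explicit identifier is present.

    Raises
    ------
    SchemaError
        If a required column is absent.
    ParseError
        If a numeric cell cannot be parsed (the row index is reported).
    """
    raw = pd.read_csv(path, sep=delimiter, engine="python", dtype=str)
    colmap: dict[str, str] = {}
    for col in raw.columns:
        norm = _normalize_header(col)
        for canonical, aliases in _ALIASES.items():
            if norm in aliases:
                colmap[canonical] = col
                break
    for required in _REQUIRED:
        if required not in colmap:
            raise SchemaError(required)

    out = pd.DataFrame(index=raw.index)
    for canonical, source in colmap.items():
        out[canonical] = raw[source]
    for col in _NUMERIC:
        parsed = pd.to_numeric(out[col], errors="coerce")
        bad = parsed.isna() & out[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(row, col, out[col].iloc[row])
        out[col] = parsed.astype(float)

    percent = out["egg_production"] > 1
    if percent.any():
        warnings.warn(
            f"egg_production: {int(percent.sum())} value(s) > 1 interpreted "
            "as percentages and divided by 100",
            stacklevel=2,
        )
        out.loc[percent, "egg_production"] /= 100.0

    if "cage" in out.columns:
        out["bird_id"] = out["cage"].astype(str)
    elif {"treatment", "replicate"} <= set(out.columns):
        out["bird_id"] = (
            out["treatment"].astype(str) + "-" + out["replicate"].astype(str)
        )
    else:
        out["bird_id"] = out.index.astype(str)
    out["treatment"] = out["treatment"].astype(str)

    # validate invariants record by record
    for i, row in out.iterrows():
        TrialRecord(
            bird_id=row["bird_id"], treatment=row["treatment"],
            arg_level=row["arg_level"], feed_intake=row["feed_intake"],
            egg_production=row["egg_production"], egg_weight=row["egg_weight"],
            bw_initial=row["bw_initial"], bw_final=row["bw_final"],
        )
    keep = ["bird_id", "treatment"] + [c for c in out.columns
                                       if c not in ("bird_id", "treatment")]
    return out[keep]


def write_trial(records: pd.DataFrame, path) -> None:
    """Write a trial table readable by :func:`read_trial` (lossless round trip)."""
    records.to_csv(path, index=False)


def as_records(frame: pd.DataFrame) -> list[TrialRecord]:
    """Convert a canonical trial DataFrame to a list of :class:`TrialRecord`."""
    fields = ("bird_id", "treatment", "arg_level", "feed_intake",
              "egg_production", "egg_weight", "bw_initial", "bw_final")
    return [TrialRecord(**{f: row[f] for f in fields})
            for _, row in frame.iterrows()]


# ---------------------------------------------------------------------------
# derived variables (all vectorized over numpy arrays / pandas Series)

def arg_intake(feed_intake, arg_level):
    """Daily arginine intake, mg/bird·d = feed intake (g/d) × dietary level (g/kg)."""
    feed_intake = np.asarray(feed_intake, dtype=float)
    arg_level = np.asarray(arg_level, dtype=float)
    if np.any(feed_intake < 0) or np.any(arg_level < 0):
        raise DomainError("feed intake and arginine level must be nonnegative")
    return feed_intake * arg_level


def egg_mass(egg_production, egg_weight):
    """Egg mass output, g/bird·d = production rate (fraction) × egg weight (g)."""
    return np.asarray(egg_production, dtype=float) * np.asarray(egg_weight, dtype=float)


def egg_arg_deposition(egg_mass_g, comp: Composition):
    """Arginine deposited in egg output, mg/bird·d."""
    return np.asarray(egg_mass_g, dtype=float) * comp.egg_arg_mg_per_g


def arg_mobilization(bw_change, comp: Composition):
    """Net arginine flow from body-weight change over the collection window,
    mg/bird·d. Negative values indicate mobilization of body arginine."""
    return (np.asarray(bw_change, dtype=float) * comp.body_arg
            / float(comp.collection_days))


def metabolic_weight(body_weight_g, exponent: float = METABOLIC_EXPONENT):
    """Metabolic body size (kg^exponent) from body weight in grams."""
    bw = np.asarray(body_weight_g, dtype=float)
    if np.any(bw <= 0):
        raise DomainError("body weight must be positive")
    return (bw / 1000.0) ** exponent


def standardize_metabolic(value, body_weight_g, exponent: float = METABOLIC_EXPONENT):
    """Express a per-bird daily flow per kg of metabolic body weight."""
    return np.asarray(value, dtype=float) / metabolic_weight(body_weight_g, exponent)


def derive_birds(records: pd.DataFrame, comp: Composition | None = None,
                 exponent: float = METABOLIC_EXPONENT) -> pd.DataFrame:
    """Compute every derived response variable per bird.

    Adds to a copy of ``records``: mean body weight (the per-bird mean of
    initial and final weight), body-weight change, egg mass, feed efficiency,
    arginine intake/deposition/mobilization (mg/bird·d) and the standardized
    intake ``X`` and deposition ``Y`` (mg/kg BW^exponent·d) used by the
    response models, plus standardized mobilization ``mob_std``.
    """
    comp = comp or Composition()
    d = records.copy()
    d["body_weight"] = (d["bw_initial"] + d["bw_final"]) / 2.0
    d["bw_change"] = d["bw_final"] - d["bw_initial"]
    d["arg_intake"] = arg_intake(d["feed_intake"], d["arg_level"])
    d["egg_mass"] = egg_mass(d["egg_production"], d["egg_weight"])
    with np.errstate(divide="ignore", invalid="ignore"):
        fe = np.where(d["feed_intake"] > 0, d["egg_mass"] / d["feed_intake"], np.nan)
    d["feed_efficiency"] = fe
    d["arg_deposition"] = egg_arg_deposition(d["egg_mass"], comp)
    d["arg_mobilization"] = arg_mobilization(d["bw_change"], comp)
    mbw = metabolic_weight(d["body_weight"], exponent)
    d["X"] = d["arg_intake"] / mbw
    d["Y"] = d["arg_deposition"] / mbw
    d["mob_std"] = d["arg_mobilization"] / mbw
    return d


def summarize_treatments(derived: pd.DataFrame) -> pd.DataFrame:
    """Treatment-mean table of the derived variables, ordered by arginine level.

    ``egg_production`` is reported as a percentage here, matching how laying
    trials conventionally tabulate it; all other columns keep their per-bird
    units.
    """
    cols = ["arg_level", "feed_intake", "arg_intake", "egg_production",
            "egg_weight", "egg_mass", "feed_efficiency", "arg_deposition",
            "body_weight", "bw_change", "arg_mobilization", "X", "Y"]
    cols = [c for c in cols if c in derived.columns]
    g = derived.groupby("treatment", sort=False)[cols].mean()
    g = g.sort_values("arg_level")
    g["egg_production"] = g["egg_production"] * 100.0
    g.insert(0, "n_birds", derived.groupby("treatment", sort=False).size())
    return g.reset_index()
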