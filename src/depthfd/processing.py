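"""From raw per-individual observations to transect x species density matrices.

The processing chain is: stereo-video length correction on calibration-flagged
transects -> missing-length fill from conspecific means -> length-weight
biomass conversion (W = a * L^b) -> surrogate constants for taxa not resolved
to species -> densities standardized per 100 m^2.

Observation tables are plain pandas DataFrames with columns
``transect_id, taxon, id_level, length_cm`` (and optionally ``group_label``
tagging the genus/order of unresolved taxa).  Transect metadata carry
``transect_id, atoll, depth_band_m, length_m, width_m, calibration_flag``.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

OBS_COLUMNS = ["transect_id", "taxon", "id_level", "length_cm"]
META_COLUMNS = [
    "transect_id", "atoll", "depth_band_m", "length_m", "width_m", "calibration_flag",
]


@dataclass
class CommunityMatrix:
    """Transect x taxon density matrix (per 100 m^2).

    ``species_columns`` lists the columns resolved to species level; the
    remaining columns are unresolved taxa that count toward density totals
    but never toward richness or composition.
    """

    data: pd.DataFrame
    kind: str
    species_columns: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("abundance", "biomass"):
            raise ValueError(f"kind must be abundance|biomass, got {self.kind!r}")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("community matrix values must be >= 0")
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValueError("community matrix labels must be unique")
        unknown = set(self.species_columns) - set(self.data.columns)
        if unknown:
            raise ValueError(f"species_columns not in matrix: {sorted(unknown)}")

    @property
    def species_data(self) -> pd.DataFrame:
        """Only the species-level columns (for richness/composition)."""
        return self.data[self.species_columns]

    @property
    def transects(self) -> list:
        return list(self.data.index)


def correction_factor(underestimation: float, round_to: int | None = 2) -> float:
    """Length-correction multiplier 1 / (1 - underestimation).

    The reported multiplier is rounded to 2 decimals by default — a 46%
    underestimation gives 1.85, the factor applied to affected transects.
    """
    if not 0.0 <= underestimation < 1.0:
        raise ValueError(f"underestimation must be in [0, 1), got {underestimation}")
    factor = 1.0 / (1.0 - underestimation)
    return round(factor, round_to) if round_to is not None else factor


def apply_length_correction(
    obs: pd.DataFrame, meta: pd.DataFrame, factor: float
) -> pd.DataFrame:
    """Multiply lengths on calibration-flagged transects by *factor*.

    Adds a ``length_corrected`` provenance column; all other lengths are
    untouched.
    """
    if factor < 1.0:
        raise ValueError(f"correction factor must be >= 1, got {factor}")
    flagged = set(meta.loc[meta["calibration_flag"].astype(bool), "transect_id"])
    out = obs.copy()
    mask = out["transect_id"].isin(flagged) & out["length_cm"].notna()
    out.loc[mask, "length_cm"] = out.loc[mask, "length_cm"] * factor
    out["length_corrected"] = mask
    return out


def fill_missing_lengths(obs: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Fill missing lengths from conspecific means.

    Order of preference: mean of measured conspecifics on the same transect;
    then the species mean within the same atoll (logged fallback); an
    individual with no measured conspecific anywhere is kept for abundance
    but excluded from biomass (``length_source = 'unfilled'``, logged).
    """
    out = obs.copy()
    atoll_of = meta.set_index("transect_id")["atoll"]
    out["_atoll"] = out["transect_id"].map(atoll_of)
    measured = out["length_cm"].notna()
    out["length_source"] = np.where(measured, "measured", "unfilled")

    transect_mean = (
        out[measured].groupby(["transect_id", "taxon"])["length_cm"].mean()
    )
    atoll_mean = out[measured].groupby(["_atoll", "taxon"])["length_cm"].mean()

    missing_idx = out.index[~measured]
    for i in missing_idx:
        key_t = (out.at[i, "transect_id"], out.at[i, "taxon"])
        key_a = (out.at[i, "_atoll"], out.at[i, "taxon"])
        if key_t in transect_mean.index:
            out.at[i, "length_cm"] = transect_mean[key_t]
            out.at[i, "length_source"] = "transect_mean"
        elif key_a in atoll_mean.index:
            out.at[i, "length_cm"] = atoll_mean[key_a]
            out.at[i, "length_source"] = "atoll_mean"
            logger.info(
                "length for %s on %s filled from atoll-level mean",
                out.at[i, "taxon"], out.at[i, "transect_id"],
            )
    n_unfilled = int((out["length_source"] == "unfilled").sum())
    if n_unfilled:
        logger.warning(
            "%d individuals have no measured conspecific anywhere; "
            "retained in abundance, excluded from biomass", n_unfilled,
        )
    return out.drop(columns="_atoll")


def biomass(length_cm: float, a: float, b: float) -> float:
    """Length-weight conversion W = a * L^b (L in cm, W in grams)."""
    if a <= 0 or b <= 0:
        raise ValueError("length-weight constants must be positive")
    if length_cm < 0:
        raise ValueError("length must be >= 0")
    return a * length_cm**b


def assign_surrogate_constants(
    obs: pd.DataFrame,
    constants: pd.DataFrame,
    meta: pd.DataFrame,
) -> pd.DataFrame:
    """Attach length-weight constants to every observation.

    Species-level taxa take their own constants (missing constants are an
    error naming the taxon).  Unresolved taxa (id_level != species) inherit
    the constants of the most abundant resolved species sharing their
    ``group_label`` in the same transect, falling back to the same location
    (atoll x depth band).  Ties break by greater study-wide abundance, then
    lexicographic taxon label.  Output columns: ``lw_a, lw_b,
    surrogate_source``.
    """
    const = constants.set_index("taxon")
    out = obs.copy()
    if "group_label" not in out.columns:
        out["group_label"] = pd.NA
    minfo = meta.set_index("transect_id")
    out["_atoll"] = out["transect_id"].map(minfo["atoll"])
    out["_band"] = out["transect_id"].map(minfo["depth_band_m"])

    resolved = out[out["id_level"] == "species"]
    missing_const = sorted(set(resolved["taxon"]) - set(const.index))
    if missing_const:
        raise KeyError(f"no length-weight constants for taxa: {missing_const}")

    study_counts = resolved.groupby("taxon").size()

    def best(candidates: pd.Series) -> str | None:
        """Most abundant taxon among candidate counts, deterministic ties."""
        if candidates.empty:
            return None
        ranked = sorted(
            candidates.items(),
            key=lambda kv: (-kv[1], -study_counts.get(kv[0], 0), kv[0]),
        )
        return ranked[0][0]

    transect_counts = resolved.groupby(["transect_id", "group_label", "taxon"]).size()
    location_counts = resolved.groupby(["_atoll", "_band", "group_label", "taxon"]).size()

    out["lw_a"] = out["taxon"].map(const["a"])
    out["lw_b"] = out["taxon"].map(const["b"])
    out["surrogate_source"] = np.where(out["id_level"] == "species", "own", "")

    orphans = []
    unresolved_idx = out.index[out["id_level"] != "species"]
    for i in unresolved_idx:
        grp = out.at[i, "group_label"]
        if pd.isna(grp):
            orphans.append(out.at[i, "taxon"])
            continue
        tkey = (out.at[i, "transect_id"], grp)
        lkey = (out.at[i, "_atoll"], out.at[i, "_band"], grp)
        donor = None
        if tkey in transect_counts.index:
            donor = best(transect_counts.loc[tkey])
            source = "transect"
        if donor is None and lkey in location_counts.index:
            donor = best(location_counts.loc[lkey])
            source = "location"
        if donor is None:
            sw = study_counts[
                resolved.loc[resolved["group_label"] == grp, "taxon"].unique()
            ] if (resolved["group_label"] == grp).any() else pd.Series(dtype=int)
            donor = best(sw)
            source = "study"
        if donor is None:
            orphans.append(out.at[i, "taxon"])
            continue
        out.at[i, "lw_a"] = const.at[donor, "a"]
        out.at[i, "lw_b"] = const.at[donor, "b"]
        out.at[i, "surrogate_source"] = f"{source}:{donor}"
    if orphans:
        raise KeyError(
            "no resolved group member anywhere for unresolved taxa: "
            f"{sorted(set(orphans))}"
        )
    return out.drop(columns=["_atoll", "_band"])


def aggregate_matrix(
    obs: pd.DataFrame, meta: pd.DataFrame, kind: str = "abundance"
) -> CommunityMatrix:
    """Transect x taxon matrix of densities per 100 m^2.

    cell(t, s) = count (or summed grams) of s in t * 100 / (length * width).
    Unresolved taxa keep their own columns, excluded from species-level use.
    Individuals without a usable length contribute nothing to biomass but
    still count toward abundance.
    """
    unknown = set(obs["transect_id"]) - set(meta["transect_id"])
    if unknown:
        raise KeyError(f"observations reference unknown transects: {sorted(unknown)}")
    minfo = meta.set_index("transect_id")
    area_scale = 100.0 / (minfo["length_m"] * minfo["width_m"])

    work = obs.copy()
    if kind == "abundance":
        work["_value"] = 1.0
    elif kind == "biomass":
        if "lw_a" not in work.columns:
            raise ValueError("biomass aggregation requires assigned constants")
        usable = work["length_cm"].notna()
        if "length_source" in work.columns:
            usable &= work["length_source"] != "unfilled"
        work["_value"] = 0.0
        lu = work.loc[usable]
        work.loc[usable, "_value"] = lu["lw_a"] * lu["length_cm"] ** lu["lw_b"]
    else:
        raise ValueError(f"kind must be abundance|biomass, got {kind!r}")

    table = (
        work.pivot_table(
            index="transect_id", columns="taxon", values="_value",
            aggfunc="sum", fill_value=0.0,
        )
        .reindex(minfo.index, fill_value=0.0)
        .mul(area_scale, axis=0)
    )
    table.columns.name = None
    species_cols = sorted(
        obs.loc[obs["id_level"] == "species", "taxon"].unique()
    )
    species_cols = [c for c in species_cols if c in table.columns]
    return CommunityMatrix(data=table.sort_index(axis=1), kind=kind,
                           species_columns=species_cols)


def group_species(obs: pd.DataFrame, synonymy: dict) -> pd.DataFrame:
    """Collapse hard-to-separate species complexes under one group label.

    *synonymy* maps group label -> list of member taxa.  Member observations
    are relabeled to the group label (id_level stays 'species': the complex
    is analyzed as one species-level unit).  Idempotent; a taxon claimed by
    two groups is a configuration error.
    """
    seen: dict[str, str] = {}
    for grp, members in synonymy.items():
        for m in members:
            if m in seen and seen[m] != grp:
                raise ValueError(f"taxon {m!r} mapped to two groups: "
                                 f"{seen[m]!r} and {grp!r}")
            seen[m] = grp
    # make grouping idempotent: a group label maps to itself
    for grp in synonymy:
        seen.setdefault(grp, grp)
    out = obs.copy()
    out["taxon"] = out["taxon"].map(lambda t: seen.get(t, t))
    return out


DEFAULT_SPECIES_GROUPS = {
    # species that cannot be separated consistently on stereo-video footage
    "Ctenochaetus binotatus complex": [
        "Ctenochaetus binotatus", "Ctenochaetus striatus", "Acanthurus nigrofuscus",
    ],
    "Forcipiger flavissimus complex": [
        "Forcipiger flavissimus", "Forcipiger longirostris",
    ],
    "Chromis nigrura complex": ["Chromis nigrura", "Chromis ternatensis"],
    "Chromis xutha complex": ["Chromis xutha", "Pycnochromis agilis"],
    "Pomacentrus nagasakiensis complex": [
        "Pomacentrus nagasakiensis", "Pomacentrus indicus",
    ],
}
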