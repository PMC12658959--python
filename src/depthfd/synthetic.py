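"""Synthetic demersal-fish survey generator.

Emulates the statistical structure of a stereo-video transect survey across
a 2-500 m depth gradient in an atoll system: a ~300-species pool with
depth-band affinities and habitat-filtered life-history traits, transect
observations with log-normal individual lengths and negative-binomial
counts, per-band species richness peaking at 10 m and bottoming out at
250 m, calibration-biased lengths on a subset of deep transects, taxa only
resolvable to genus, and missing trait cells.

The generator is seeded once; every transect and species derives its own
RNG sub-stream by hashing its identifier, so adding transects never
perturbs earlier draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._utils import substream
from .traits import TraitScheme, default_trait_scheme

DEPTH_BANDS = (4, 10, 30, 60, 120, 250, 500)  # 4 stands for the 2-5 m band
ATOLLS = ("VAA", "LAA", "HUV", "ADD", "MAL")

#: expected per-transect species richness by band: peak at 10 m, minimum at
#: 250 m, comparable low values from 120 to 500 m
DEFAULT_RICHNESS = {4: 22, 10: 32, 30: 26, 60: 16, 120: 9, 250: 6, 500: 7}

#: expected individuals per present species by band (abundance also peaks
#: shallow and thins with depth)
DEFAULT_COUNT_MEAN = {4: 7.0, 10: 10.0, 30: 7.0, 60: 5.0, 120: 3.0,
                      250: 2.0, 500: 2.5}


@dataclass
class SurveyDesign:
    """Sampling design and noise levels of a simulated survey."""

    depth_bands: tuple = DEPTH_BANDS
    atolls: tuple = ATOLLS
    replicates_per_cell: int = 3
    transect_length: float = 250.0
    transect_width: float = 5.0
    richness_decay: dict = field(default_factory=lambda: dict(DEFAULT_RICHNESS))
    count_mean: dict = field(default_factory=lambda: dict(DEFAULT_COUNT_MEAN))
    abundance_dispersion: float = 0.8  # negative-binomial size parameter
    length_missing_rate: float = 0.05
    trait_missing_rate: float = 0.03
    calibration_bias: float = 0.46  # measured = (1 - u) * true on flagged
    calibration_fraction: float = 0.4  # of submersible (>= 60 m) transects
    seed: int = 0


# ---------------------------------------------------------------------------
# species pool


def _band_window(trait, band_index: int, n_bands: int, strength: float,
                 direction: int):
    """Allowed modality subset for a trait at a given depth band.

    Habitat filtering: the window narrows linearly with depth down to a
    fraction (1 - strength) of the modalities at the deepest band, anchored
    at one end of the (ordered or declared) modality list.
    """
    k = len(trait.modalities)
    frac = 1.0 - strength * band_index / max(n_bands - 1, 1)
    w = max(1, int(round(k * frac)))
    if direction > 0:
        return trait.modalities[k - w:]
    return trait.modalities[:w]


def generate_species_pool(
    n_species: int = 300,
    scheme: TraitScheme | None = None,
    depth_bands: tuple = DEPTH_BANDS,
    seed: int = 0,
    filtering_strength: float = 0.55,
    archetype_ratio: tuple = (0.40, 0.35, 0.35, 0.5, 0.7, 0.9, 0.9),
    dd_ne_rate: float = 0.15,
) -> pd.DataFrame:
    """Generate a species pool with depth affinities and filtered traits.

    Each species has a centre depth band and spans 1-3 adjacent bands.
    Trait vectors derive from per-band archetypes drawn from band-restricted
    modality windows, so deep-band specialists share a narrower region of
    trait space and the count of distinct trait combinations shrinks with
    depth; archetype reuse within a band creates the trait redundancy that
    shallow assemblages show.  Generation time and population doubling time
    track age at first maturity (rank +/- 1) so the correlation screen has
    something to find.  IUCN threat probability rises with body size.
    """
    if n_species < 0:
        raise ValueError("n_species must be >= 0")
    scheme = scheme or default_trait_scheme()
    if not scheme.traits:
        raise ValueError("trait scheme is empty")
    for t in scheme.traits.values():
        if len(t.modalities) < 2:
            raise ValueError(f"trait {t.name!r} needs >= 2 modalities")
    bands = tuple(depth_bands)
    n_bands = len(bands)
    cols = [
        "species", "genus", "depth_bands", "center_band", "typical_length",
        "length_sd", "lw_a", "lw_b", "iucn", "commercial_value", "resolvable",
    ] + scheme.names
    if n_species == 0:
        return pd.DataFrame(columns=cols).set_index("species")

    rng = substream(seed, "pool")
    # deterministic filter direction per trait: deep communities anchor at
    # the slow/large/narrow end for ordered traits, alternating otherwise
    directions = {name: (1 if i % 2 == 0 else -1)
                  for i, name in enumerate(scheme.names)}
    derived = {"generation_time", "pop_doubling"}

    def draw_archetype(band_idx: int, arng: np.random.Generator) -> dict:
        vec = {}
        for name, trait in scheme.traits.items():
            if name in derived and name in scheme.traits and "age_maturity" in scheme.traits:
                continue
            window = _band_window(trait, band_idx, n_bands,
                                  filtering_strength, directions[name])
            vec[name] = window[arng.integers(len(window))]
        # correlated life-history trio: generation time and doubling time
        # follow the age-at-maturity rank with +/-1 jitter
        if "age_maturity" in vec:
            base = scheme.traits["age_maturity"].rank(vec["age_maturity"])
            rel = base / max(len(scheme.traits["age_maturity"].modalities) - 1, 1)
            for name in derived & set(scheme.names):
                trait = scheme.traits[name]
                k = len(trait.modalities)
                r = int(round(rel * (k - 1)))
                if arng.random() < 0.15:
                    r += int(arng.integers(0, 2)) * 2 - 1
                vec[name] = trait.modalities[int(np.clip(r, 0, k - 1))]
        return vec

    # per-band archetype libraries sized to the expected specialist counts;
    # shallow bands get fewer archetypes per species (more redundancy)
    band_share = np.array([DEFAULT_RICHNESS.get(b, 10) for b in bands], float)
    band_share /= band_share.sum()
    specialists = np.maximum(1, np.round(band_share * n_species).astype(int))
    archetypes = []
    for bi in range(n_bands):
        ratio = archetype_ratio[bi % len(archetype_ratio)]
        n_arch = max(2, int(round(specialists[bi] * ratio)))
        arng = substream(seed, "archetypes", bands[bi])
        # archetypes are distinct combos where the filtered modality space
        # allows it, so redundancy comes from archetype sharing, not from
        # accidental collisions inside the library
        lib, seen = [], set()
        attempts = 0
        while len(lib) < n_arch and attempts < 50 * n_arch:
            attempts += 1
            vec = draw_archetype(bi, arng)
            key = tuple(vec[n] for n in scheme.names)
            if key not in seen:
                seen.add(key)
                lib.append(vec)
        archetypes.append(lib)

    rows = []
    for i in range(n_species):
        srng = substream(seed, "species", i)
        center = int(srng.choice(n_bands, p=band_share))
        # vertical home range: 1-3 adjacent bands
        span = int(srng.integers(1, 4))
        lo = max(0, center - (span - 1) // 2)
        hi = min(n_bands, lo + span)
        affinity = tuple(bands[lo:hi])
        vec = dict(archetypes[center][srng.integers(len(archetypes[center]))])
        if srng.random() < 0.15:  # rare one-trait mutation off the archetype
            name = scheme.names[srng.integers(len(scheme.names))]
            window = _band_window(scheme.traits[name], center, n_bands,
                                  filtering_strength, directions[name])
            vec[name] = window[srng.integers(len(window))]
        # body size from the max-length modality; typical length ~60% of a
        # nominal bin midpoint
        ml_trait = scheme.traits.get("max_length")
        if ml_trait is not None:
            r = ml_trait.rank(vec["max_length"])
            midpoints = np.geomspace(10, 200, len(ml_trait.modalities))
            typical = 0.6 * midpoints[r]
            size_rel = r / max(len(ml_trait.modalities) - 1, 1)
        else:
            typical, size_rel = 15.0, 0.3
        iucn = _draw_iucn(srng, size_rel, dd_ne_rate)
        rows.append({
            "species": f"S{i:04d}",
            "genus": f"G{i % max(1, n_species // 3):03d}",
            "depth_bands": affinity,
            "center_band": bands[center],
            "typical_length": float(typical),
            "length_sd": 0.25,
            "lw_a": float(np.exp(srng.normal(np.log(0.012), 0.3))),
            "lw_b": float(np.clip(srng.normal(3.0, 0.12), 2.5, 3.5)),
            "iucn": iucn,
            "commercial_value": int(srng.choice(6, p=[0.55, 0.18, 0.1, 0.08,
                                                      0.05, 0.04])),
            "resolvable": True,
            **vec,
        })
    pool = pd.DataFrame(rows).set_index("species")
    _mark_unresolvable(pool, seed)
    return pool


def _draw_iucn(rng: np.random.Generator, size_rel: float, dd_ne_rate: float) -> str:
    """Threat rises with body size; a fraction stays unevaluated (DD/NE)."""
    if rng.random() < dd_ne_rate:
        return "DD" if rng.random() < 0.6 else "NE"
    p_threat = 0.04 + 0.45 * size_rel**2
    if rng.random() >= p_threat:
        return "LC"
    return str(rng.choice(["NT", "VU", "EN", "CR"], p=[0.35, 0.35, 0.2, 0.1]))


def _mark_unresolvable(pool: pd.DataFrame, seed: int,
                       rate: float = 0.03) -> None:
    """Mark ~rate of species as identifiable only to genus, ensuring each
    shares its genus with at least one resolvable species (so surrogate
    length-weight constants exist)."""
    rng = substream(seed, "unresolvable")
    genus_counts = pool.groupby("genus").size()
    candidates = [s for s in pool.index
                  if genus_counts[pool.at[s, "genus"]] >= 2]
    n_pick = int(round(rate * len(pool)))
    if not candidates or n_pick == 0:
        return
    picked = rng.choice(candidates, size=min(n_pick, len(candidates)),
                        replace=False)
    for s in picked:
        g = pool.at[s, "genus"]
        others = pool.index[(pool["genus"] == g) & (pool.index != s)
                            & pool["resolvable"]]
        if len(others):
            pool.at[s, "resolvable"] = False


# ---------------------------------------------------------------------------
# transect simulation


def simulate_transects(pool: pd.DataFrame, design: SurveyDesign):
    """Simulate per-individual observations over the survey design.

    Returns ``(observations, metadata)``.  Observation columns:
    transect_id, taxon, id_level, length_cm, group_label, species_true,
    length_true_cm.  The ``*_true`` columns carry the latent truth for
    validation and are dropped by the pipeline's CSV writer.
    """
    if design.replicates_per_cell < 0:
        raise ValueError("replicates_per_cell must be >= 0")
    if len(pool) == 0 and design.replicates_per_cell > 0:
        raise ValueError("species pool is empty")
    covered = set()
    for bands in pool["depth_bands"]:
        covered.update(bands)
    for band in design.depth_bands:
        if len(pool) and band not in covered:
            raise ValueError(f"no species has affinity for depth band {band} m")

    band_pools = {
        band: pool.index[[band in b for b in pool["depth_bands"]]]
        for band in design.depth_bands
    }
    meta_rows, obs_rows = [], []
    for band in design.depth_bands:
        members = band_pools[band]
        r_target = design.richness_decay.get(band, 10)
        p_present = min(1.0, r_target / max(len(members), 1))
        mu = design.count_mean.get(band, 3.0)
        size = design.abundance_dispersion
        for atoll in design.atolls:
            for rep in range(1, design.replicates_per_cell + 1):
                tid = f"{atoll}-{band:03d}m-r{rep}"
                trng = substream(design.seed, "transect", tid)
                flagged = bool(
                    band >= 60 and trng.random() < design.calibration_fraction
                )
                meta_rows.append({
                    "transect_id": tid, "atoll": atoll, "depth_band_m": band,
                    "length_m": design.transect_length,
                    "width_m": design.transect_width,
                    "calibration_flag": flagged,
                })
                present = members[trng.random(len(members)) < p_present]
                for sp in present:
                    # NB count via gamma-Poisson mixture, at least 1
                    lam = trng.gamma(size, mu / size)
                    count = 1 + int(trng.poisson(lam))
                    typ = pool.at[sp, "typical_length"]
                    sd = pool.at[sp, "length_sd"]
                    lengths = np.exp(
                        trng.normal(math.log(typ), sd, size=count)
                    )
                    resolvable = bool(pool.at[sp, "resolvable"])
                    genus = pool.at[sp, "genus"]
                    taxon = sp if resolvable else f"{genus} spp."
                    for length in lengths:
                        missing = trng.random() < design.length_missing_rate
                        measured = length * (1.0 - design.calibration_bias) \
                            if flagged else length
                        obs_rows.append({
                            "transect_id": tid,
                            "taxon": taxon,
                            "id_level": "species" if resolvable else "genus",
                            "length_cm": (np.nan if missing
                                          else float(measured)),
                            "group_label": genus,
                            "species_true": sp,
                            "length_true_cm": float(length),
                        })
    obs = pd.DataFrame(
        obs_rows,
        columns=["transect_id", "taxon", "id_level", "length_cm",
                 "group_label", "species_true", "length_true_cm"],
    )
    meta = pd.DataFrame(
        meta_rows,
        columns=["transect_id", "atoll", "depth_band_m", "length_m",
                 "width_m", "calibration_flag"],
    )
    return obs, meta


def lw_constants(pool: pd.DataFrame) -> pd.DataFrame:
    """Length-weight constants table (taxon, a, b) for resolvable species."""
    res = pool[pool["resolvable"]]
    return pd.DataFrame({"taxon": res.index, "a": res["lw_a"].to_numpy(),
                         "b": res["lw_b"].to_numpy()}).reset_index(drop=True)


def trait_table(pool: pd.DataFrame, scheme: TraitScheme | None = None) -> pd.DataFrame:
    """Species x trait table (plus genus, iucn, commercial_value)."""
    scheme = scheme or default_trait_scheme()
    cols = ["genus"] + scheme.names + ["iucn", "commercial_value"]
    return pool[cols].copy()


# ---------------------------------------------------------------------------
# trait masking


def mask_traits(
    table: pd.DataFrame,
    rate: float,
    seed: int = 0,
    columns: list | None = None,
):
    """Blank exactly ``round(rate * cells)`` observed cells uniformly.

    *cells* counts all entries of the imputable columns; masked positions
    are drawn only from currently observed cells, so they are disjoint from
    original missingness.  Returns (masked table, boolean mask frame).
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"rate must be in [0, 1), got {rate}")
    cols = columns if columns is not None else list(table.columns)
    n_cells = len(table) * len(cols)
    n_mask = int(round(rate * n_cells))
    mask = pd.DataFrame(False, index=table.index, columns=cols)
    out = table.copy()
    if n_mask == 0:
        return out, mask
    observed = [
        (i, c) for c in cols for i in table.index if pd.notna(table.at[i, c])
    ]
    if n_mask > len(observed):
        raise ValueError("not enough observed cells to mask at this rate")
    rng = substream(seed, "mask")
    picks = rng.choice(len(observed), size=n_mask, replace=False)
    for k in picks:
        i, c = observed[k]
        out.at[i, c] = np.nan
        mask.at[i, c] = True
    return out, mask
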