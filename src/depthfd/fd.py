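"""Functional entities, distance-based functional diversity, and FUSE.

Functional entities (FEs) are unique combinations of categorical trait
modalities; species sharing every modality share an FE.  On top of the FE
partition sit the redundancy metrics (FRed, FOR, FVul); in the PCoA trait
space sit the distance-based metrics (FRic, FDis, FEve, FSpe, FUn).  FUSE
combines uniqueness, specialization and IUCN threat rank to flag threatened
species whose trait combinations have no backup in the pool:

    FUSE = ln(1 + FUn * GE) + ln(1 + FSpe * GE)

with GE the threat rank (LC=0, NT=1, VU=2, EN=3, CR=4), so a least-concern
species scores 0 regardless of its trait position.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .processing import CommunityMatrix
from .stats import kendall_tau
from .traits import GE_MAP, TraitScheme, TraitSpace

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# functional entities


def assign_functional_entities(table: pd.DataFrame,
                               scheme: TraitScheme) -> pd.DataFrame:
    """Partition species into functional entities (unique trait combos).

    Returns a frame indexed by species with columns ``fe_id`` and
    ``combination``; FE ids are deterministic (sorted by combination).
    """
    cols = [c for c in scheme.names if c in table.columns]
    if table[cols].isna().any().any():
        raise ValueError("trait table has missing cells; impute first")
    combos = table[cols].apply(tuple, axis=1)
    unique = sorted(combos.unique())
    width = max(3, len(str(len(unique))))
    fe_of = {combo: f"FE{i+1:0{width}d}" for i, combo in enumerate(unique)}
    return pd.DataFrame(
        {"fe_id": combos.map(fe_of), "combination": combos}, index=table.index
    )


@dataclass
class FEMetrics:
    """FE-based redundancy metrics for one assemblage."""

    n_species: int
    n_entities: int
    fred: float  # mean species per FE
    fover: float  # % of species in excess of FRed in crowded FEs
    fvul: float  # % of FEs with a single species


def fe_metrics(fe_assign: pd.DataFrame, community=None) -> FEMetrics:
    """Redundancy metrics over a community (or, by default, the whole pool).

    FRed = S / K; FVul = 100 * |{FEs with one species}| / K;
    FOR = 100 * sum_k max(0, n_k - FRed) / S (species-in-excess convention).
    """
    members = fe_assign if community is None else fe_assign.loc[list(community)]
    if len(members) == 0:
        raise ValueError("community is empty")
    sizes = members.groupby("fe_id").size().to_numpy()
    s, k = int(sizes.sum()), sizes.size
    fred = s / k
    fvul = 100.0 * (sizes == 1).sum() / k
    fover = 100.0 * np.maximum(sizes - fred, 0.0).sum() / s
    return FEMetrics(s, k, fred, float(fover), float(fvul))


# ---------------------------------------------------------------------------
# distance-based metrics


def hull_volume(points: np.ndarray) -> float:
    """Convex-hull volume; NaN for degenerate (affinely dependent) sets."""
    points = np.asarray(points, dtype=float)
    if points.shape[0] <= points.shape[1]:
        return float("nan")
    try:
        return float(ConvexHull(points).volume)
    except QhullError:
        return float("nan")


def fric(space: TraitSpace, community, pool_volume: float | None = None) -> float:
    """Convex-hull volume of the community, as a fraction of the pool hull.

    Undefined (NaN) when the community has no more species than axes or its
    points are affinely dependent.
    """
    if pool_volume is None:
        pool_volume = hull_volume(space.points())
    vol = hull_volume(space.points(community))
    if math.isnan(vol):
        return float("nan")
    return vol / pool_volume


def fdis(space: TraitSpace, weights: pd.Series) -> float:
    """Abundance-weighted mean distance to the community centroid."""
    w = weights[weights > 0]
    if len(w) == 0:
        raise ValueError("all abundances are zero")
    x = space.points(w.index)
    wv = w.to_numpy(dtype=float)
    centroid = (x * wv[:, None]).sum(axis=0) / wv.sum()
    return float((np.linalg.norm(x - centroid, axis=1) * wv).sum() / wv.sum())


def _mst_edges(points: np.ndarray, labels: list) -> list:
    """Prim's minimum spanning tree with lexicographic tie-breaks.

    Candidate edges (tree node i, outside node j) are compared by
    (distance, label_i, label_j), so the tree is unique even with ties.
    """
    n = points.shape[0]
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(axis=2))
    order = sorted(range(n), key=lambda i: labels[i])
    in_tree = {order[0]}
    edges = []
    while len(in_tree) < n:
        best = None
        for i in sorted(in_tree, key=lambda i: labels[i]):
            for j in order:
                if j in in_tree:
                    continue
                cand = (d[i, j], labels[i], labels[j], i, j)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        edges.append((best[3], best[4], best[0]))
        in_tree.add(best[4])
    return edges


def feve(space: TraitSpace, weights: pd.Series) -> float:
    """Functional evenness: regularity of abundance along the MST.

    Branch weight EW = length / (w_i + w_j) with relative abundances;
    FEve = (sum min(PEW, 1/(S-1)) - 1/(S-1)) / (1 - 1/(S-1)).  Undefined
    (NaN) below 3 species; invariant to rescaling all abundances.
    """
    w = weights[weights > 0]
    s = len(w)
    if s < 3:
        return float("nan")
    rel = w / w.sum()
    labels = list(w.index)
    x = space.points(labels)
    edges = _mst_edges(x, labels)
    ew = np.array(
        [length / (rel.iloc[i] + rel.iloc[j]) for i, j, length in edges]
    )
    if ew.sum() == 0:
        return float("nan")
    pew = ew / ew.sum()
    thr = 1.0 / (s - 1)
    return float((np.minimum(pew, thr).sum() - thr) / (1.0 - thr))


def fspe(space: TraitSpace) -> pd.Series:
    """Per-species functional specialization, scaled so the maximum is 1.

    Distance to the unweighted pool centroid, divided by the pool maximum.
    """
    x = space.points()
    centroid = x.mean(axis=0)
    d = np.linalg.norm(x - centroid, axis=1)
    dmax = d.max()
    if dmax == 0:
        return pd.Series(0.0, index=space.species, name="FSpe")
    return pd.Series(d / dmax, index=space.species, name="FSpe")


def community_fspe(species_fspe: pd.Series, weights: pd.Series) -> float:
    """Abundance-weighted mean of member FSpe values."""
    w = weights[weights > 0]
    return float((species_fspe[w.index] * w).sum() / w.sum())


def fun(space: TraitSpace, k_neighbors: int = 5) -> pd.Series:
    """Per-species functional uniqueness, scaled so the maximum is 1.

    Mean Euclidean distance to the k nearest pool neighbours (k=5 by
    default), divided by the pool maximum of that quantity.  A pool of at
    most k species reduces k to pool size - 1 with a warning.
    """
    x = space.points()
    n = x.shape[0]
    if n <= k_neighbors:
        logger.warning("pool size %d <= k=%d; using k=%d", n, k_neighbors, n - 1)
        k_neighbors = n - 1
    if k_neighbors < 1:
        raise ValueError("pool too small for uniqueness")
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
    np.fill_diagonal(d, np.inf)
    nearest = np.sort(d, axis=1)[:, :k_neighbors]
    iso = nearest.mean(axis=1)
    imax = iso.max()
    if imax == 0:
        return pd.Series(0.0, index=space.species, name="FUn")
    return pd.Series(iso / imax, index=space.species, name="FUn")


# ---------------------------------------------------------------------------
# FUSE


def ge_from_iucn(category: str) -> int:
    """IUCN category -> threat rank GE (LC=0 ... CR=4).

    DD/NE have no rank; they must be imputed to an evaluated category first.
    """
    if category not in GE_MAP:
        raise ValueError(
            f"IUCN category {category!r} has no threat rank; "
            "impute DD/NE before computing FUSE"
        )
    return GE_MAP[category]


def fuse(fun_value, fspe_value, ge):
    """FUSE = ln(1 + FUn * GE) + ln(1 + FSpe * GE); vectorized.

    Inputs must satisfy FUn, FSpe in [0, 1] and GE in {0..4}.
    """
    fu = np.asarray(fun_value, dtype=float)
    fs = np.asarray(fspe_value, dtype=float)
    g = np.asarray(ge, dtype=float)
    if ((fu < 0) | (fu > 1)).any() or ((fs < 0) | (fs > 1)).any():
        raise ValueError("FUn and FSpe must lie in [0, 1]")
    if ((g < 0) | (g > 4) | (g != np.round(g))).any():
        raise ValueError("GE must be an integer in 0..4")
    out = np.log1p(fu * g) + np.log1p(fs * g)
    return float(out) if out.ndim == 0 else out


def classify_habitat(depth_m: float) -> str:
    """Shallow (<30 m), mesophotic (30-150 m) or deep (>150 m)."""
    if depth_m < 30:
        return "shallow"
    if depth_m <= 150:
        return "MCE"
    return "deep"


def fuse_ranking(
    species_fun: pd.Series,
    species_fspe: pd.Series,
    iucn: pd.Series,
    commercial: pd.Series | None = None,
    abundance: CommunityMatrix | None = None,
    meta: pd.DataFrame | None = None,
    reference_area_m2: float = 1250.0,
) -> pd.DataFrame:
    """FUSE scores for every pool species, highest first.

    Ties break by FUn then species label.  When a community matrix and
    transect metadata are given, each species also gets its habitat class
    (from the shallowest band of occurrence), atoll occurrence count, and
    mean density per ``reference_area_m2`` (1250 m^2, one 250 x 5 m
    transect) over occupied transects.  An all-least-concern pool makes the
    ranking degenerate (all scores 0); flagged with a warning.
    """
    species = list(species_fun.index)
    ge = iucn.loc[species].map(ge_from_iucn)
    scores = fuse(species_fun.loc[species], species_fspe.loc[species],
                  ge.to_numpy())
    out = pd.DataFrame(
        {
            "FUSE": scores,
            "FUn": species_fun.loc[species],
            "FSpe": species_fspe.loc[species],
            "IUCN": iucn.loc[species],
            "GE": ge,
        },
        index=pd.Index(species, name="species"),
    )
    if commercial is not None:
        out["commercial_value"] = commercial.loc[species]
    if abundance is not None and meta is not None:
        minfo = meta.set_index("transect_id")
        dens = abundance.data  # per 100 m^2
        habitat, occ, mean_dens = {}, {}, {}
        for sp in species:
            if sp not in dens.columns:
                habitat[sp], occ[sp], mean_dens[sp] = pd.NA, 0, float("nan")
                continue
            present = dens.index[dens[sp] > 0]
            if len(present) == 0:
                habitat[sp], occ[sp], mean_dens[sp] = pd.NA, 0, float("nan")
                continue
            bands = minfo.loc[present, "depth_band_m"]
            habitat[sp] = classify_habitat(float(bands.min()))
            occ[sp] = int(minfo.loc[present, "atoll"].nunique())
            mean_dens[sp] = float(
                dens.loc[present, sp].mean() * reference_area_m2 / 100.0
            )
        out["habitat"] = pd.Series(habitat)
        out["occurrence_atolls"] = pd.Series(occ)
        out["density_per_1250m2"] = pd.Series(mean_dens)
    if (out["FUSE"] == 0).all():
        logger.warning("all FUSE scores are 0 (no threatened species); "
                       "ranking is degenerate")
    return (
        out.assign(_lbl=out.index)
        .sort_values(["FUSE", "FUn", "_lbl"], ascending=[False, False, True],
                     kind="stable")
        .drop(columns="_lbl")
    )


# ---------------------------------------------------------------------------
# transect-level assembly


def alpha_fd_filter(matrix: CommunityMatrix, min_species: int = 5):
    """Exclude transects with fewer than *min_species* species from the
    alpha metrics (FRic/FDis/FEve) only; report removals per depth band.

    Returns (kept transect labels, report DataFrame) — the matrix itself is
    never mutated.
    """
    richness = (matrix.species_data > 0).sum(axis=1)
    removed = richness.index[richness < min_species]
    kept = richness.index[richness >= min_species]
    report = pd.DataFrame({"transect_id": removed,
                           "richness": richness.loc[removed].to_numpy()})
    return list(kept), report


def community_fd(
    matrix: CommunityMatrix,
    space: TraitSpace,
    fe_assign: pd.DataFrame,
    min_species: int = 5,
) -> pd.DataFrame:
    """Per-transect functional diversity table.

    Species absent from the trait space are ignored with a warning.  FRic,
    FDis and FEve are computed only for transects passing the ``<
    min_species`` filter; FE metrics and FSpe for every non-empty transect.
    """
    in_space = [s for s in matrix.species_columns if s in space.species]
    dropped = set(matrix.species_columns) - set(in_space)
    if dropped:
        logger.warning("%d species lack trait coordinates; ignored", len(dropped))
    pool_volume = hull_volume(space.points())
    sp_fspe = fspe(space)
    kept, _ = alpha_fd_filter(matrix, min_species=min_species)
    kept = set(kept)
    rows = []
    for t in matrix.transects:
        dens = matrix.data.loc[t, in_space]
        present = dens[dens > 0]
        row = {"transect_id": t, "species_count": int(len(present))}
        if len(present) == 0:
            rows.append(row)
            continue
        fem = fe_metrics(fe_assign, community=present.index)
        row.update(
            n_fe=fem.n_entities, FRed=fem.fred, FOR=fem.fover, FVul=fem.fvul,
            FSpe_community=community_fspe(sp_fspe, present),
        )
        if t in kept:
            row["FRic"] = fric(space, present.index, pool_volume)
            row["FDis"] = fdis(space, present)
            row["FEve"] = feve(space, present)
        rows.append(row)
    return pd.DataFrame(rows).set_index("transect_id")


def metric_correlation_summary(metrics: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Kendall tau-b matrix over transect-level metric columns.

    Constant columns give undefined (NaN) correlations.
    """
    if len(metrics) < 3:
        raise ValueError("need at least 3 transects")
    cols = list(metrics.columns)
    out = pd.DataFrame(np.nan, index=cols, columns=cols)
    for a in cols:
        for b in cols:
            ok = metrics[a].notna() & metrics[b].notna()
            if ok.sum() < 2:
                continue
            out.loc[a, b] = kendall_tau(metrics.loc[ok, a],
                                        metrics.loc[ok, b]).statistic
    return out
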