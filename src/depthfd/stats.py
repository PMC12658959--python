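"""Rank-based univariate tests and permutational multivariate statistics.

Everything here is computed from first principles on top of numpy:
midrank Kruskal-Wallis with tie correction, exact/approximate two-sided
Mann-Whitney, Benjamini-Hochberg step-up, Kendall's tau-b, Bray-Curtis
dissimilarity, principal coordinates analysis (PCoA), one-way PERMANOVA
and PERMDISP with seeded label permutations.

Permutation p-values always use the (b + 1) / (m + 1) estimator and are
therefore never exactly zero.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2
from scipy.stats import norm as _norm

from ._utils import check_square, substream

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "PCoAResult",
    "bh_adjust",
    "kruskal_wallis",
    "mann_whitney",
    "pairwise_mann_whitney",
    "kendall_tau",
    "bray_curtis",
    "pcoa",
    "permanova",
    "pairwise_permanova",
    "permdisp",
    "transect_metrics",
]


@dataclass
class TestResult:
    """Outcome of a single hypothesis test."""

    name: str
    statistic: float
    p_value: float
    p_adjusted: float | None = None
    n_permutations: int | None = None
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


# ---------------------------------------------------------------------------
# multiple testing


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# rank helpers


def _midranks(x: np.ndarray) -> np.ndarray:
    """Midranks (average rank for ties), 1-based."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(x.size)
    sx = x[order]
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _tie_sizes(x: np.ndarray) -> np.ndarray:
    _, counts = np.unique(np.asarray(x, dtype=float), return_counts=True)
    return counts


# ---------------------------------------------------------------------------
# Kruskal-Wallis


def kruskal_wallis(values, groups) -> TestResult:
    """Kruskal-Wallis H with tie correction; chi-square p with g-1 df.

    Degenerate all-equal data return H = 0, p = 1.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    labels = pd.unique(g)
    if labels.size < 2:
        raise ValueError("Kruskal-Wallis requires at least 2 groups")
    n = v.size
    ranks = _midranks(v)
    h = 12.0 / (n * (n + 1)) * sum(
        ranks[g == lab].sum() ** 2 / (g == lab).sum() for lab in labels
    ) - 3.0 * (n + 1)
    ties = _tie_sizes(v)
    correction = 1.0 - (ties**3 - ties).sum() / (n**3 - n)
    if correction == 0.0:  # all values identical
        return TestResult("kruskal-wallis", 0.0, 1.0, extra={"df": labels.size - 1})
    h /= correction
    p = float(_chi2.sf(h, labels.size - 1))
    return TestResult("kruskal-wallis", float(h), p, extra={"df": labels.size - 1})


# ---------------------------------------------------------------------------
# Mann-Whitney


def _mw_u(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic of sample x (number of (x, y) pairs with x > y, ties 0.5)."""
    diff = x[:, None] - y[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def mann_whitney(x, y, exact_max_n: int = 8) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration over rank arrangements when both samples have at most
    *exact_max_n* observations and there are no ties; otherwise a normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("Mann-Whitney requires non-empty samples")
    pooled = np.concatenate([x, y])
    u = _mw_u(x, y)
    mid = n1 * n2 / 2.0
    has_ties = np.unique(pooled).size < pooled.size
    if n1 <= exact_max_n and n2 <= exact_max_n and not has_ties:
        # enumerate which positions of the sorted pooled sample belong to x
        spooled = np.sort(pooled)
        total = 0
        extreme = 0
        for idx in itertools.combinations(range(n1 + n2), n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(idx)] = True
            u_perm = _mw_u(spooled[mask], spooled[~mask])
            total += 1
            if abs(u_perm - mid) >= abs(u - mid) - 1e-12:
                extreme += 1
        p = extreme / total
        method = "exact"
    else:
        var = n1 * n2 / 12.0 * (
            (n1 + n2 + 1)
            - (_tie_sizes(pooled) ** 3 - _tie_sizes(pooled)).sum()
            / ((n1 + n2) * (n1 + n2 - 1))
        )
        if var == 0:
            return TestResult("mann-whitney", u, 1.0, extra={"method": "degenerate"})
        # continuity correction toward the mean
        z = (u - mid - 0.5 * np.sign(u - mid)) / math.sqrt(var)
        p = min(1.0, 2.0 * float(_norm.sf(abs(z))))
        method = "normal"
    return TestResult("mann-whitney", u, p, extra={"method": method})


def pairwise_mann_whitney(values, groups, alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise two-sided U tests with BH adjustment across the family."""
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    labels = list(pd.unique(g))
    rows = []
    for a, b in itertools.combinations(labels, 2):
        res = mann_whitney(v[g == a], v[g == b])
        rows.append({"group_a": a, "group_b": b, "U": res.statistic, "p": res.p_value})
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adjusted"] = bh_adjust(table["p"].to_numpy())
        table["significant"] = table["p_adjusted"] < alpha
    return table


# ---------------------------------------------------------------------------
# Kendall tau-b


def kendall_tau(x, y) -> TestResult:
    """Kendall's tau-b with tie correction (O(n^2) pair count).

    A constant input vector makes tau undefined; reported as NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("kendall_tau requires two equal-length vectors, n >= 2")
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(x.size, k=1)
    sx, sy = dx[iu], dy[iu]
    nc = int(((sx * sy) > 0).sum())
    nd = int(((sx * sy) < 0).sum())
    n0 = sx.size
    tx = int((sx == 0).sum())
    ty = int((sy == 0).sum())
    denom = math.sqrt((n0 - tx) * (n0 - ty))
    if denom == 0:
        return TestResult("kendall-tau", float("nan"), float("nan"),
                          extra={"undefined": True})
    tau = (nc - nd) / denom
    # normal approximation for the p-value (no-tie variance)
    n = x.size
    var = 2.0 * (2 * n + 5) / (9.0 * n * (n - 1))
    p = min(1.0, 2.0 * float(_norm.sf(abs(tau) / math.sqrt(var))))
    return TestResult("kendall-tau", float(tau), p)


# ---------------------------------------------------------------------------
# Bray-Curtis


def bray_curtis(matrix: pd.DataFrame, transform: str = "sqrt") -> pd.DataFrame:
    """Bray-Curtis dissimilarity between rows of a community matrix.

    ``transform='sqrt'`` square-root-transforms abundances first.  Two
    all-zero rows get distance 0 by convention (logged).
    """
    x = np.asarray(matrix, dtype=float)
    if (x < 0).any():
        raise ValueError("community matrix must be non-negative")
    if transform == "sqrt":
        x = np.sqrt(x)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    sums = x.sum(axis=1)
    if (sums == 0).any():
        logger.warning(
            "%d all-zero rows in Bray-Curtis input; mutual distance set to 0",
            int((sums == 0).sum()),
        )
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    den = sums[:, None] + sums[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    np.fill_diagonal(d, 0.0)
    labels = list(matrix.index) if isinstance(matrix, pd.DataFrame) else None
    return pd.DataFrame(d, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# PCoA


@dataclass
class PCoAResult:
    """Principal coordinates of a distance matrix.

    ``coordinates`` holds the axes with positive eigenvalues (descending);
    ``imaginary`` the axes of negative eigenvalues scaled by sqrt(-lambda),
    kept for Anderson-style corrected distances in PERMDISP.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    imaginary: pd.DataFrame
    negative_magnitude: float

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


def pcoa(dist, eps: float = 1e-9) -> PCoAResult:
    """Gower double-centering + eigendecomposition of a distance matrix."""
    if isinstance(dist, pd.DataFrame):
        labels = list(dist.index)
        d = check_square(dist.to_numpy())
    else:
        d = check_square(np.asarray(dist, dtype=float))
        labels = list(range(d.shape[0]))
    n = d.shape[0]
    if n < 2:
        raise ValueError("PCoA requires at least 2 objects")
    a = -0.5 * d**2
    row_means = a.mean(axis=1, keepdims=True)
    b = a - row_means - row_means.T + a.mean()
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    scale = np.abs(vals).max() if vals.size else 1.0
    tol = eps * max(scale, 1.0)
    pos = vals > tol
    neg = vals < -tol
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    imag = vecs[:, neg] * np.sqrt(-vals[neg])
    return PCoAResult(
        coordinates=pd.DataFrame(
            coords, index=labels, columns=[f"PCo{i+1}" for i in range(coords.shape[1])]
        ),
        eigenvalues=vals,
        imaginary=pd.DataFrame(
            imag, index=labels, columns=[f"NEG{i+1}" for i in range(imag.shape[1])]
        ),
        negative_magnitude=float(-vals[neg].sum()),
    )


# ---------------------------------------------------------------------------
# PERMANOVA


def _permanova_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """One-way pseudo-F from squared distances and integer group codes."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(n_groups):
        members = codes == g
        ng = int(members.sum())
        if ng > 1:
            ss_within += d2[np.ix_(members, members)].sum() / (2.0 * ng)
    df_between = n_groups - 1
    df_within = n - n_groups
    ss_between = ss_total - ss_within
    if ss_within <= 0 or df_within <= 0:
        return math.inf if ss_between > 0 else 0.0
    return (ss_between / df_between) / (ss_within / df_within)


def permanova(
    dist,
    groups,
    n_perm: int = 9999,
    seed: int = 0,
    permutations: str = "random",
) -> TestResult:
    """One-way PERMANOVA on a distance matrix.

    Pseudo-F from total and within-group sums of squared distances; the
    p-value permutes group labels, ``(b + 1) / (m + 1)``.  With a single
    factor, type-III partial sums of squares reduce to this one-way form.
    ``permutations='exact'`` enumerates every distinct label arrangement
    (only sensible for tiny designs) and reports the exact fraction.
    All points identical (SS_total = 0) returns F = 0, p = 1 by convention.
    """
    if isinstance(dist, pd.DataFrame):
        d = check_square(dist.to_numpy())
    else:
        d = check_square(np.asarray(dist, dtype=float))
    g = np.asarray(groups)
    if g.size != d.shape[0]:
        raise ValueError("groups length must match distance matrix size")
    labels, codes = np.unique(g, return_inverse=True)
    if labels.size < 2:
        raise ValueError("PERMANOVA requires at least 2 groups")
    counts = np.bincount(codes)
    if (counts < 2).any():
        raise ValueError("every group needs n >= 2 for PERMANOVA")
    d2 = d**2
    if d2.sum() == 0.0:
        return TestResult("permanova", 0.0, 1.0, n_permutations=0, seed=seed)
    f_obs = _permanova_f(d2, codes, labels.size)
    if permutations == "exact":
        perms = set(itertools.permutations(codes.tolist()))
        hits = sum(
            1
            for perm in perms
            if _permanova_f(d2, np.array(perm), labels.size) >= f_obs - 1e-12
        )
        p = hits / len(perms)
        return TestResult(
            "permanova", f_obs, p, n_permutations=len(perms), seed=seed,
            extra={"exact": True},
        )
    rng = substream(seed, "permanova")
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _permanova_f(d2, perm, labels.size) >= f_obs - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return TestResult("permanova", f_obs, p, n_permutations=n_perm, seed=seed)


def pairwise_permanova(
    dist: pd.DataFrame, groups, n_perm: int = 9999, seed: int = 0
) -> pd.DataFrame:
    """PERMANOVA on every two-group submatrix, BH-adjusted across pairs."""
    g = np.asarray(groups)
    labels = list(pd.unique(g))
    rows = []
    for a, b in itertools.combinations(labels, 2):
        mask = (g == a) | (g == b)
        sub = dist.loc[mask, mask] if isinstance(dist, pd.DataFrame) else dist[np.ix_(mask, mask)]
        if (g == a).sum() < 2 or (g == b).sum() < 2:
            raise ValueError(f"group of size < 2 in pair ({a}, {b})")
        res = permanova(sub, g[mask], n_perm=n_perm, seed=seed)
        rows.append(
            {"group_a": a, "group_b": b, "pseudo_F": res.statistic, "p": res.p_value}
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adjusted"] = bh_adjust(table["p"].to_numpy())
    return table


# ---------------------------------------------------------------------------
# PERMDISP


def _anova_f(values: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = values.size
    grand = values.mean()
    ssb = 0.0
    ssw = 0.0
    for g in range(n_groups):
        v = values[codes == g]
        ssb += v.size * (v.mean() - grand) ** 2
        ssw += ((v - v.mean()) ** 2).sum()
    df_b, df_w = n_groups - 1, n - n_groups
    if ssw <= 0 or df_w <= 0:
        return math.inf if ssb > 0 else 0.0
    return (ssb / df_b) / (ssw / df_w)


def centroid_distances(dist, groups) -> pd.Series:
    """Anderson-corrected distance of each sample to its group centroid.

    The distance matrix is embedded by PCoA keeping real and imaginary
    axes; squared distance to the centroid is the real-part squared
    distance minus the imaginary-part squared distance (clipped at zero).
    """
    res = pcoa(dist)
    real = res.coordinates.to_numpy()
    imag = res.imaginary.to_numpy()
    g = np.asarray(groups)
    z = np.empty(g.size)
    for lab in pd.unique(g):
        members = g == lab
        cr = real[members].mean(axis=0)
        ci = imag[members].mean(axis=0) if imag.size else np.zeros(0)
        dr2 = ((real[members] - cr) ** 2).sum(axis=1)
        di2 = ((imag[members] - ci) ** 2).sum(axis=1) if imag.size else 0.0
        z[members] = np.sqrt(np.clip(dr2 - di2, 0.0, None))
    index = list(dist.index) if isinstance(dist, pd.DataFrame) else None
    return pd.Series(z, index=index, name="dist_to_centroid")


def permdisp(dist, groups, n_perm: int = 9999, seed: int = 0) -> TestResult:
    """Homogeneity of multivariate dispersions (distance to group centroid).

    One-way ANOVA F on the centroid distances; the p-value permutes group
    labels of those distances.
    """
    g = np.asarray(groups)
    labels, codes = np.unique(g, return_inverse=True)
    if labels.size < 2:
        raise ValueError("PERMDISP requires at least 2 groups")
    if (np.bincount(codes) < 2).any():
        raise ValueError("every group needs n >= 2 for PERMDISP")
    z = centroid_distances(dist, g).to_numpy()
    f_obs = _anova_f(z, codes, labels.size)
    rng = substream(seed, "permdisp")
    hits = 0
    for _ in range(n_perm):
        if _anova_f(z, rng.permutation(codes), labels.size) >= f_obs - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return TestResult(
        "permdisp", f_obs, p, n_permutations=n_perm, seed=seed,
        extra={"centroid_distances": z},
    )


def pairwise_permdisp(
    dist: pd.DataFrame, groups, n_perm: int = 9999, seed: int = 0
) -> pd.DataFrame:
    """PERMDISP on every two-group submatrix, BH-adjusted across pairs.

    Groups of a single sample are excluded with a warning (their distance
    to their own centroid is identically zero).
    """
    g = np.asarray(groups)
    labels = [lab for lab in pd.unique(g)]
    usable = []
    for lab in labels:
        if (g == lab).sum() < 2:
            logger.warning("PERMDISP pairwise: group %r has n < 2; excluded", lab)
        else:
            usable.append(lab)
    rows = []
    for a, b in itertools.combinations(usable, 2):
        mask = (g == a) | (g == b)
        sub = dist.loc[mask, mask] if isinstance(dist, pd.DataFrame) else dist[np.ix_(mask, mask)]
        res = permdisp(sub, g[mask], n_perm=n_perm, seed=seed)
        rows.append({"group_a": a, "group_b": b, "F": res.statistic, "p": res.p_value})
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adjusted"] = bh_adjust(table["p"].to_numpy())
    return table


# ---------------------------------------------------------------------------
# per-transect taxonomic metrics


def transect_metrics(abundance, biomass=None) -> pd.DataFrame:
    """Per-transect species richness and standardized densities.

    Richness counts species-level columns with positive density; the
    density totals include unresolved-taxon columns.
    """
    rows = abundance.species_data
    richness = (rows > 0).sum(axis=1)
    out = pd.DataFrame(
        {
            "richness": richness,
            "abundance_density": abundance.data.sum(axis=1),
        }
    )
    if biomass is not None:
        out["biomass_density"] = biomass.data.sum(axis=1)
    out.index.name = "transect_id"
    return out
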