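"""Categorical life-history trait tables and the Gower/PCoA trait space.

Eight categorical traits describe each species' life-history strategy:
age at first maturity, generation time, maximum length, minimum population
doubling time (a resilience proxy), fishing vulnerability, position in the
water column, preferred temperature range, and vertical home range.  Traits
are screened for redundancy (Kendall tau-b > 0.8 between ordered traits),
missing entries are imputed with an iterative random-forest scheme, and the
species are embedded by PCoA of Gower distances.  The mean absolute
deviation (mAD) between embedded and Gower distances scores candidate
dimensionalities.

The three stages that transform a trait table are sklearn-style estimators
(`CorrelationPruner`, `MissForestImputer`, `GowerPCoA`) and compose with
sklearn pipelines; thin module-level functions wrap them.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import RandomForestClassifier

from . import stats as _stats
from ._utils import substream

logger = logging.getLogger(__name__)

IUCN_CATEGORIES = ("LC", "NT", "VU", "EN", "CR", "DD", "NE")
#: IUCN threat rank used by the FUSE index: LC=0 ... CR=4 (DD/NE imputed first)
GE_MAP = {"LC": 0, "NT": 1, "VU": 2, "EN": 3, "CR": 4}


@dataclass(frozen=True)
class Trait:
    name: str
    modalities: tuple
    ordered: bool

    def rank(self, modality) -> int:
        return self.modalities.index(modality)


@dataclass
class TraitScheme:
    """Declared modality sets and order flags for each trait column."""

    traits: dict = field(default_factory=dict)

    @property
    def names(self) -> list:
        return list(self.traits)

    @property
    def ordered_names(self) -> list:
        return [n for n, t in self.traits.items() if t.ordered]

    def validate(self, table: pd.DataFrame) -> None:
        for name, trait in self.traits.items():
            if name not in table.columns:
                raise ValueError(f"trait column {name!r} missing from table")
            bad = set(table[name].dropna()) - set(trait.modalities)
            if bad:
                raise ValueError(f"unknown modalities in {name!r}: {sorted(bad)}")


def default_trait_scheme() -> TraitScheme:
    """The default 8-trait scheme.

    Continuous life-history values are binned into ordered categories
    (maximum length bins at 15/30/50/80/150 cm); binning thresholds are
    configuration, and every analysis downstream is bin-agnostic.
    """
    spec = [
        ("age_maturity", ("<1y", "1-2y", "2-5y", "5-10y", ">10y"), True),
        ("generation_time", ("<2y", "2-4y", "4-8y", "8-15y", ">15y"), True),
        ("max_length", ("<15", "15-30", "30-50", "50-80", "80-150", ">150"), True),
        ("pop_doubling", ("<15mo", "15mo-4.5y", "4.5-14y", ">14y"), True),
        ("fishing_vulnerability", ("low", "moderate", "high", "very_high"), True),
        ("water_column", ("benthic", "demersal", "benthopelagic", "pelagic"), False),
        ("temp_range", ("narrow", "intermediate", "broad"), True),
        ("vertical_range", ("narrow", "intermediate", "broad"), True),
    ]
    return TraitScheme({n: Trait(n, m, o) for n, m, o in spec})


# ---------------------------------------------------------------------------
# Gower distance


def gower_distance(table: pd.DataFrame, scheme: TraitScheme) -> pd.DataFrame:
    """Gower distance between species over categorical traits.

    Unordered trait contribution: 0 if equal else 1.  Ordered trait:
    |rank_i - rank_j| / (n_modalities - 1) with evenly spaced ranks.  The
    distance is the unweighted mean contribution, in [0, 1].
    """
    cols = [c for c in scheme.names if c in table.columns]
    if table[cols].isna().any().any():
        raise ValueError("trait table has missing cells; run imputation first")
    n = len(table)
    total = np.zeros((n, n))
    for name in cols:
        trait = scheme.traits[name]
        if trait.ordered:
            ranks = table[name].map(trait.rank).to_numpy(dtype=float)
            span = max(len(trait.modalities) - 1, 1)
            contrib = np.abs(ranks[:, None] - ranks[None, :]) / span
        else:
            vals = table[name].to_numpy()
            contrib = (vals[:, None] != vals[None, :]).astype(float)
        total += contrib
    d = total / len(cols)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=table.index, columns=table.index)


# ---------------------------------------------------------------------------
# correlation pruning


class CorrelationPruner(BaseEstimator, TransformerMixin):
    """Drop one trait of every highly rank-correlated ordered-trait pair.

    Kendall's tau-b is computed on rank encodings over pairwise-complete
    species; while any pair exceeds ``threshold`` in |tau|, the member with
    more missing cells is dropped (tie: the one later in the scheme's
    declared trait order).  Unordered traits are never screened — tau is
    undefined for unordered modalities.
    """

    def __init__(self, scheme: TraitScheme | None = None, threshold: float = 0.8):
        self.scheme = scheme
        self.threshold = threshold

    def fit(self, X: pd.DataFrame, y=None):
        scheme = self.scheme or default_trait_scheme()
        keep = [c for c in scheme.ordered_names if c in X.columns]
        order = {c: i for i, c in enumerate(scheme.names)}
        report = []
        while True:
            worst = None
            for a, b in itertools.combinations(keep, 2):
                ra = X[a].map(scheme.traits[a].rank, na_action="ignore")
                rb = X[b].map(scheme.traits[b].rank, na_action="ignore")
                ok = ra.notna() & rb.notna()
                if ok.sum() < 2:
                    continue
                tau = _stats.kendall_tau(ra[ok], rb[ok]).statistic
                if np.isnan(tau) or abs(tau) <= self.threshold:
                    continue
                if worst is None or abs(tau) > abs(worst[2]):
                    worst = (a, b, tau)
            if worst is None:
                break
            a, b, tau = worst
            na, nb = X[a].isna().sum(), X[b].isna().sum()
            if na > nb or (na == nb and order[a] > order[b]):
                drop, kept = a, b
            else:
                drop, kept = b, a
            report.append({"dropped": drop, "kept": kept, "tau": tau,
                           "missing_dropped": int(X[drop].isna().sum()),
                           "missing_kept": int(X[kept].isna().sum())})
            keep.remove(drop)
        self.dropped_ = [r["dropped"] for r in report]
        self.report_ = pd.DataFrame(
            report, columns=["dropped", "kept", "tau",
                             "missing_dropped", "missing_kept"]
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X.drop(columns=[c for c in self.dropped_ if c in X.columns])

    def pruned_scheme(self) -> TraitScheme:
        scheme = self.scheme or default_trait_scheme()
        return TraitScheme(
            {n: t for n, t in scheme.traits.items() if n not in self.dropped_}
        )


def prune_correlated(table: pd.DataFrame, scheme: TraitScheme,
                     threshold: float = 0.8):
    """Functional wrapper around :class:`CorrelationPruner`."""
    pruner = CorrelationPruner(scheme=scheme, threshold=threshold).fit(table)
    return pruner.transform(table), pruner.report_


# ---------------------------------------------------------------------------
# missForest-style imputation


class MissForestImputer(BaseEstimator, TransformerMixin):
    """Iterative random-forest imputation of categorical columns.

    Missing cells start at their column modes; columns are then revisited in
    order of increasing missingness, each fitted by a random forest on all
    other columns (one-hot encoded) and its missing cells re-predicted.  The
    loop stops when the proportion of changed categorical imputations rises
    relative to the previous sweep, returning the previous iterate.

    Parameters
    ----------
    n_trees : trees per forest (100 by default).
    columns : columns to impute; defaults to every column with a missing
        value.  Other columns act as predictors only (e.g. genus, giving the
        imputation access to taxonomic signal for IUCN categories).
    missing_tokens : cell values treated as missing in addition to NaN
        (IUCN "DD"/"NE" are imputed alongside the traits).

    Attributes
    ----------
    pfc_ : out-of-bag proportion of falsely classified cells, averaged over
        imputed categorical columns.
    nrmse_ : 0.0 for all-categorical tables (reserved for continuous
        auxiliary columns).
    n_iter_ : completed sweeps.
    """

    def __init__(self, n_trees: int = 100, max_iter: int = 10,
                 columns: list | None = None,
                 missing_tokens: tuple = ("DD", "NE"),
                 random_state: int = 0):
        self.n_trees = n_trees
        self.max_iter = max_iter
        self.columns = columns
        self.missing_tokens = missing_tokens
        self.random_state = random_state

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        work = X.copy()
        for tok in self.missing_tokens:
            work = work.mask(work == tok)
        cols = self.columns
        if cols is None:
            cols = [c for c in work.columns if work[c].isna().any()]
        fully_missing = [c for c in cols if work[c].isna().all()]
        if fully_missing:
            raise ValueError(f"columns entirely missing: {fully_missing}")
        mask = {c: work[c].isna() for c in cols}
        n_missing_total = sum(int(m.sum()) for m in mask.values())
        if n_missing_total == 0:
            self.n_iter_ = 0
            self.pfc_ = 0.0
            self.nrmse_ = 0.0
            self.oob_by_column_ = pd.Series(dtype=float)
            return X.copy()

        # initialize with column modes
        current = work.copy()
        for c in cols:
            mode = work[c].mode(dropna=True).iloc[0]
            current.loc[mask[c], c] = mode
        # visit columns in order of increasing missingness
        visit = sorted(cols, key=lambda c: (int(mask[c].sum()), c))
        rng = np.random.default_rng(self.random_state)

        prev = current.copy()
        prev_change = np.inf
        prev_oob: dict[str, float] = {}
        oob: dict[str, float] = {}
        it = 0
        while it < self.max_iter:
            it += 1
            for c in visit:
                predictors = pd.get_dummies(current.drop(columns=[c]))
                obs_rows = ~mask[c]
                yc = work.loc[obs_rows, c].astype(str)
                if yc.nunique() < 2:
                    oob[c] = 0.0
                    current.loc[mask[c], c] = yc.iloc[0]
                    continue
                forest = RandomForestClassifier(
                    n_estimators=self.n_trees,
                    oob_score=True,
                    bootstrap=True,
                    random_state=int(rng.integers(2**31 - 1)),
                )
                forest.fit(predictors[obs_rows], yc)
                oob[c] = 1.0 - float(forest.oob_score_)
                current.loc[mask[c], c] = forest.predict(predictors[mask[c]])
            changed = sum(
                int((current.loc[mask[c], c] != prev.loc[mask[c], c]).sum())
                for c in cols
            )
            change = changed / n_missing_total
            if change >= prev_change:
                current = prev  # divergence: keep the previous iterate
                oob = prev_oob
                it -= 1
                break
            if change == 0.0:
                break
            prev = current.copy()
            prev_change = change
            prev_oob = dict(oob)

        self.n_iter_ = it
        self.oob_by_column_ = pd.Series(oob, dtype=float)
        self.pfc_ = float(self.oob_by_column_.mean()) if len(oob) else 0.0
        self.nrmse_ = 0.0
        out = X.copy()
        for c in cols:
            out.loc[mask[c], c] = current.loc[mask[c], c]
        return out

    def fit(self, X: pd.DataFrame, y=None):
        self.fit_transform(X)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return self.fit_transform(X)


def impute_missforest(table: pd.DataFrame, n_trees: int = 100, seed: int = 0,
                      columns: list | None = None):
    """Impute *table*; returns (imputed table, error report dict)."""
    imp = MissForestImputer(n_trees=n_trees, columns=columns, random_state=seed)
    imputed = imp.fit_transform(table)
    report = {"NRMSE": imp.nrmse_, "PFC": imp.pfc_, "n_iter": imp.n_iter_,
              "oob_by_column": imp.oob_by_column_}
    return imputed, report


def mode_impute(table: pd.DataFrame, columns: list | None = None) -> pd.DataFrame:
    """Column-mode imputation — the baseline the forest must beat."""
    out = table.copy()
    cols = columns if columns is not None else [c for c in out.columns
                                                if out[c].isna().any()]
    for c in cols:
        if out[c].isna().any():
            out.loc[out[c].isna(), c] = out[c].mode(dropna=True).iloc[0]
    return out


# ---------------------------------------------------------------------------
# trait space


@dataclass
class TraitSpace:
    """Species coordinates on PCoA axes of the Gower distance matrix."""

    coordinates: pd.DataFrame  # species x m_selected axes
    eigenvalues: np.ndarray
    m_selected: int
    mad: dict = field(default_factory=dict)  # dimensionality -> mAD

    @property
    def species(self) -> list:
        return list(self.coordinates.index)

    def points(self, species=None) -> np.ndarray:
        if species is None:
            return self.coordinates.to_numpy()
        return self.coordinates.loc[list(species)].to_numpy()


class GowerPCoA(BaseEstimator, TransformerMixin):
    """Gower-distance PCoA embedding of a categorical trait table.

    ``fit`` computes the distance matrix and its principal coordinates;
    ``transform`` returns the coordinates restricted to ``m_axes`` positive
    axes (4 by default, the dimensionality used for all functional metrics).
    """

    def __init__(self, scheme: TraitScheme | None = None, m_axes: int = 4):
        self.scheme = scheme
        self.m_axes = m_axes

    def fit(self, X: pd.DataFrame, y=None):
        scheme = self.scheme or default_trait_scheme()
        self.distance_ = gower_distance(X, scheme)
        res = _stats.pcoa(self.distance_)
        self.eigenvalues_ = res.eigenvalues
        self.coordinates_ = res.coordinates
        n_pos = res.coordinates.shape[1]
        if self.m_axes > n_pos:
            raise ValueError(
                f"m_axes={self.m_axes} exceeds the {n_pos} positive-eigenvalue axes"
            )
        return self

    def transform(self, X=None) -> pd.DataFrame:
        return self.coordinates_.iloc[:, : self.m_axes]

    def trait_space(self, dims: list | None = None) -> TraitSpace:
        mad = quality_mad(self.distance_, self.coordinates_, dims=dims)
        return TraitSpace(
            coordinates=self.transform(None),
            eigenvalues=self.eigenvalues_,
            m_selected=self.m_axes,
            mad=mad,
        )


def build_trait_space(dist: pd.DataFrame, m: int = 4,
                      dims: list | None = None) -> TraitSpace:
    """PCoA embedding of a precomputed distance matrix, first *m* axes."""
    res = _stats.pcoa(dist)
    n_pos = res.coordinates.shape[1]
    if m > n_pos:
        raise ValueError(f"m={m} exceeds the {n_pos} positive-eigenvalue axes")
    mad = quality_mad(dist, res.coordinates, dims=dims)
    return TraitSpace(
        coordinates=res.coordinates.iloc[:, :m],
        eigenvalues=res.eigenvalues,
        m_selected=m,
        mad=mad,
    )


def quality_mad(dist: pd.DataFrame, coordinates: pd.DataFrame,
                dims: list | None = None) -> dict:
    """Embedding quality per candidate dimensionality.

    For each m, Euclidean distances on the first m axes are rescaled so
    their maximum equals the maximum input distance, and mAD is the mean
    absolute deviation over species pairs.  Lower is better; ties between
    dimensionalities resolve to the smaller m via :func:`best_dimensionality`.
    """
    d = dist.to_numpy() if isinstance(dist, pd.DataFrame) else np.asarray(dist)
    coords = coordinates.to_numpy()
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    gd = d[iu]
    if dims is None:
        dims = list(range(1, coords.shape[1] + 1))
    out = {}
    for m in dims:
        if m > coords.shape[1]:
            raise ValueError(f"dimensionality {m} exceeds available axes")
        x = coords[:, :m]
        ed = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))[iu]
        if ed.max() > 0:
            ed = ed * (gd.max() / ed.max())
        out[m] = float(np.abs(ed - gd).mean())
    return out


def best_dimensionality(mad: dict) -> int:
    """argmin of mAD; ties go to the smaller dimensionality."""
    return min(sorted(mad), key=lambda m: (mad[m], m))
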