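"""Multi-population comparison of mtDNA haplotype and haplogroup data.

Implements the comparative layer of the pipeline: shared-haplotype
census against a reference database, pairwise FST from haplotype
identity via a two-group AMOVA with permutation significance and
Benjamini-Hochberg correction, PCA of pooled haplogroup frequencies with
Ward minimum-variance clustering and v-test cluster characterisation,
and inverse-distance-weighted geographic affinity surfaces.

FST here is the "haplotype frequency" flavour: the inter-individual
distance is 0 for identical variant sets over the comparison window and
1 otherwise, so the among/within variance components reduce to functions
of haplotype counts.  Negative estimates are reported as computed.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import norm, ttest_1samp

from .core import COMPLETE_WINDOW, Haplotype, Window, trim_to_window

logger = logging.getLogger(__name__)


# --- database ---------------------------------------------------------------


@dataclass(frozen=True)
class DBRecord:
    individual_id: str
    population_id: str
    haplotype: Haplotype
    haplogroup: str


@dataclass(frozen=True)
class PopulationMeta:
    region: str = ""
    latitude: float | None = None
    longitude: float | None = None
    geographic_ok: bool = True


@dataclass
class HaplotypeDatabase:
    """Individual HVS1 records plus per-population metadata."""

    records: list[DBRecord] = field(default_factory=list)
    metadata: dict[str, PopulationMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for population, meta in self.metadata.items():
            if meta.geographic_ok and (meta.latitude is None or meta.longitude is None):
                raise ValueError(
                    f"population {population!r} flagged geographic but lacks coordinates"
                )

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.population_id, None)
        return list(seen)

    def population(self, population_id: str) -> list[DBRecord]:
        return [r for r in self.records if r.population_id == population_id]

    def __len__(self) -> int:
        return len(self.records)


# --- shared haplotypes ------------------------------------------------------


@dataclass
class SharedHaplotypeResult:
    population_id: str
    n_query_haplotypes: int
    n_shared_haplotypes: int
    pct_shared_haplotypes: float
    n_individuals: int
    n_carriers: int
    pct_carriers: float


def _labels_agree(a: str, b: str) -> bool:
    """Haplogroup labels agree when equal, or when one names a sub-clade
    of the other (K matches K1a); a paragroup label (U*) matches only
    itself, not named sub-clades."""
    a, b = a.strip(), b.strip()
    if not a or not b:
        return True
    if a == b:
        return True
    if a.endswith("*") or b.endswith("*"):
        return False
    return a.startswith(b) or b.startswith(a)


def shared_haplotypes(
    query: Sequence[tuple[Haplotype, str]],
    db: HaplotypeDatabase,
    win: Window | tuple[int, int] = COMPLETE_WINDOW,
    require_haplogroup: bool = True,
    complete_only: bool = True,
) -> list[SharedHaplotypeResult]:
    """Census of query haplotypes across database populations.

    A database individual *carries* a query haplotype when their variant
    sets over ``win`` are identical and, if ``require_haplogroup``, the
    haplogroup labels agree (a label matches its own sub-clades).
    Reports, per population, both directions: how many of the distinct
    query haplotypes occur there, and how many individuals carry any of
    them.
    """
    if isinstance(win, tuple):
        win = Window(*win)
    usable = [
        (trim_to_window(h, win), label)
        for h, label in query
        if not complete_only or h.is_complete
    ]
    if not usable:
        raise ValueError("empty query after window/completeness filtering")
    distinct: dict[frozenset, str] = {}
    for h, label in usable:
        distinct.setdefault(h.variants, label)

    results = []
    for population_id in db.populations():
        members = db.population(population_id)
        found: set[frozenset] = set()
        carriers = 0
        for record in members:
            key = trim_to_window(record.haplotype, win).variants
            label = distinct.get(key)
            if label is None:
                continue
            if require_haplogroup and not _labels_agree(label, record.haplogroup):
                continue
            found.add(key)
            carriers += 1
        results.append(
            SharedHaplotypeResult(
                population_id=population_id,
                n_query_haplotypes=len(distinct),
                n_shared_haplotypes=len(found),
                pct_shared_haplotypes=100.0 * len(found) / len(distinct),
                n_individuals=len(members),
                n_carriers=carriers,
                pct_carriers=100.0 * carriers / len(members) if members else 0.0,
            )
        )
    return results


# --- FST --------------------------------------------------------------------


def _sum_identical_pairs(counts: Iterable[int]) -> float:
    return sum(c * (c - 1) / 2.0 for c in counts)


def pairwise_fst(a: Sequence[Hashable], b: Sequence[Hashable]) -> float:
    """Two-population FST from haplotype identity (AMOVA variance ratio).

    ``a`` and ``b`` are sequences of hashable haplotype keys (e.g.
    ``Haplotype.variants``).  With identity distance the sums of squared
    differences depend only on haplotype counts.  May be negative; when
    every individual in both samples is identical the value is defined
    as 0.
    """
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least 2 individuals")
    N = n1 + n2
    ca, cb = Counter(a), Counter(b)
    total = ca + cb
    diff_pairs_total = N * (N - 1) / 2.0 - _sum_identical_pairs(total.values())
    ssd_total = diff_pairs_total / N
    ssd_within = (
        (n1 * (n1 - 1) / 2.0 - _sum_identical_pairs(ca.values())) / n1
        + (n2 * (n2 - 1) / 2.0 - _sum_identical_pairs(cb.values())) / n2
    )
    ssd_among = ssd_total - ssd_within
    sigma_w = ssd_within / (N - 2)
    n_prime = N - (n1 * n1 + n2 * n2) / N  # divided by (P-1) = 1
    sigma_a = (ssd_among - sigma_w) / n_prime
    denom = sigma_a + sigma_w
    if denom == 0.0:
        return 0.0
    return sigma_a / denom


@dataclass
class FstResult:
    pop_a: str
    pop_b: str
    fst: float
    p_raw: float | None = None
    p_adjusted: float | None = None
    n_permutations: int = 0
    seed: int | None = None


def fst_permutation_test(
    a: Sequence[Hashable],
    b: Sequence[Hashable],
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Permutation p-value for FST by reshuffling individuals between pops.

    Returns (observed FST, p) with the add-one estimator
    ``p = (1 + #{FST_perm >= FST_obs}) / (1 + n_perm)``; ties count as
    exceedances, so p is never 0.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if seed is None:
        raise ValueError("a seed is required for reproducibility")
    observed = pairwise_fst(a, b)
    pool = np.array(list(a) + list(b), dtype=object)
    n1 = len(a)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        rng.shuffle(pool)
        if pairwise_fst(pool[:n1], pool[n1:]) >= observed:
            exceed += 1
    return observed, (1 + exceed) / (1 + n_perm)


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (input order kept)."""
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1)) or np.any(np.isnan(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return list(multipletests(arr, method="fdr_bh")[1])


def fst_scan(
    query_key: str,
    samples: Mapping[str, Sequence[Hashable]],
    n_perm: int = 10_000,
    seed: int | None = None,
) -> list[FstResult]:
    """FST of one query population against every other, BH-corrected as
    a single family of tests."""
    if seed is None:
        raise ValueError("a seed is required for reproducibility")
    query = samples[query_key]
    others = [k for k in samples if k != query_key]
    results = []
    rng = np.random.default_rng(seed)
    for other in others:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        fst, p = fst_permutation_test(query, samples[other], n_perm, seed=sub_seed)
        results.append(
            FstResult(query_key, other, fst, p, None, n_perm, sub_seed)
        )
    adjusted = bh_adjust([r.p_raw for r in results])
    for r, p_adj in zip(results, adjusted):
        r.p_adjusted = float(p_adj)
    return results


def pool_populations(
    db: HaplotypeDatabase,
    region_map: Mapping[str, str],
    exclude: Iterable[str] = (),
) -> dict[str, list[DBRecord]]:
    """Concatenate populations into regional pools.

    Every population must be mapped or explicitly excluded — silent
    dropping would bias regional comparisons.
    """
    excluded = set(exclude)
    pooled: dict[str, list[DBRecord]] = {}
    for population_id in db.populations():
        if population_id in excluded:
            continue
        if population_id not in region_map:
            raise KeyError(
                f"population {population_id!r} neither mapped to a region nor excluded"
            )
        pooled.setdefault(region_map[population_id], []).extend(
            db.population(population_id)
        )
    return pooled


# --- PCA / Ward / v-tests ---------------------------------------------------


@dataclass
class PCAResult:
    variables: list[str]
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    scores: pd.DataFrame          # populations x components
    loadings: pd.DataFrame        # variables x components
    standardized: bool
    dropped: list[str] = field(default_factory=list)


def pca_haplogroups(freq: pd.DataFrame, standardize: bool = True) -> PCAResult:
    """PCA of a populations x categories percentage table.

    Centred and, by default, scaled to unit variance (correlation-style
    PCA).  Component signs follow a deterministic convention: the
    largest-magnitude loading of each component is positive.
    Zero-variance variables cannot be standardized and are dropped with
    a warning.
    """
    if freq.isna().any().any():
        raise ValueError("frequency table has missing cells")
    if len(freq) < 3:
        raise ValueError("PCA needs at least 3 populations")
    X = freq.astype(float).copy()
    dropped: list[str] = []
    if standardize:
        sd = X.std(axis=0, ddof=1)
        dead = sd[sd == 0.0].index.tolist()
        if dead:
            warnings.warn(f"dropping zero-variance variables: {dead}", stacklevel=2)
            dropped = dead
            X = X.drop(columns=dead)
            sd = sd.drop(index=dead)
        X = (X - X.mean(axis=0)) / sd
    else:
        X = X - X.mean(axis=0)

    values = X.to_numpy()
    n = values.shape[0]
    U, s, Vt = np.linalg.svd(values, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    # deterministic sign: largest-|loading| positive per component
    for j in range(Vt.shape[0]):
        pivot = np.argmax(np.abs(Vt[j]))
        if Vt[j, pivot] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    scores = U * s
    total = eigenvalues.sum()
    percent = 100.0 * eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
    comp_names = [f"PC{i + 1}" for i in range(len(eigenvalues))]
    return PCAResult(
        variables=list(X.columns),
        eigenvalues=eigenvalues,
        percent_variance=percent,
        scores=pd.DataFrame(scores, index=freq.index, columns=comp_names),
        loadings=pd.DataFrame(Vt.T, index=X.columns, columns=comp_names),
        standardized=standardize,
        dropped=dropped,
    )


@dataclass
class ClusterPartition:
    merge_tree: np.ndarray
    k: int
    labels: pd.Series                 # population -> cluster id (1..k)
    inertia_between: float
    inertia_within: float
    inertia_total: float
    coordinates: pd.DataFrame         # the score coordinates clustered

    @property
    def inertia_ratio(self) -> float:
        return self.inertia_between / self.inertia_total if self.inertia_total else 1.0


def _inertia_decomposition(X: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    grand = X.mean(axis=0)
    total = float(((X - grand) ** 2).sum())
    within = 0.0
    between = 0.0
    for cluster in np.unique(labels):
        members = X[labels == cluster]
        centroid = members.mean(axis=0)
        within += float(((members - centroid) ** 2).sum())
        between += len(members) * float(((centroid - grand) ** 2).sum())
    return between, within, total


def ward_partition(pca: PCAResult, k: int, n_components: int = 6) -> ClusterPartition:
    """Ward minimum-variance clustering of populations in PC space.

    Agglomerates on the first ``n_components`` principal-component
    scores with Euclidean distances; cutting the tree at ``k`` clusters
    yields the labels and the between/within inertia decomposition.
    """
    n_components = min(n_components, pca.scores.shape[1])
    coords = pca.scores.iloc[:, :n_components]
    n = len(coords)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    X = coords.to_numpy()
    Z = linkage(X, method="ward")
    labels = fcluster(Z, t=k, criterion="maxclust")
    between, within, total = _inertia_decomposition(X, labels)
    return ClusterPartition(
        merge_tree=Z,
        k=k,
        labels=pd.Series(labels, index=coords.index, name="cluster"),
        inertia_between=between,
        inertia_within=within,
        inertia_total=total,
        coordinates=coords,
    )


def inertia_ratio_profile(pca: PCAResult, k_max: int, n_components: int = 6) -> pd.Series:
    """Between/total inertia ratio for every cut 1..k_max."""
    ratios = {}
    for k in range(1, k_max + 1):
        ratios[k] = ward_partition(pca, k=k, n_components=n_components).inertia_ratio
    return pd.Series(ratios, name="inertia_ratio")


def test_values(
    partition: ClusterPartition,
    freq: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Characterise clusters by variable: v-tests and t-test marks.

    The v-test compares a cluster's mean of a variable with the overall
    mean, standardized with the finite-population (sampling without
    replacement) correction::

        v = (mean_cluster - mean_overall)
            / sqrt(((N - n) / (N - 1)) * var_overall / n)

    with a two-sided normal p-value; a cluster containing all N rows has
    v = 0 by convention.  Separately, each (cluster, variable) cell is
    marked ``higher``/``lower`` when a one-sample t-test of the
    cluster's values against the overall mean is significant at
    ``alpha``.

    Returns (long DataFrame of v and p, cluster x variable marks).
    """
    labels = partition.labels
    if not labels.index.equals(freq.index):
        freq = freq.loc[labels.index]
    N = len(freq)
    rows = []
    marks = pd.DataFrame(
        "", index=sorted(labels.unique()), columns=freq.columns, dtype=object
    )
    for cluster in sorted(labels.unique()):
        members = freq[labels == cluster]
        n = len(members)
        if n == 0:
            raise ValueError(f"cluster {cluster} is empty")
        for variable in freq.columns:
            overall = freq[variable].to_numpy(dtype=float)
            values = members[variable].to_numpy(dtype=float)
            mean_gap = values.mean() - overall.mean()
            var_overall = overall.var()  # population variance (1/N)
            if n == N or var_overall == 0.0:
                v = 0.0
            else:
                se = np.sqrt(((N - n) / (N - 1)) * var_overall / n)
                v = mean_gap / se
            p = 2.0 * norm.sf(abs(v))
            rows.append(
                {"cluster": cluster, "variable": variable, "n": n,
                 "cluster_mean": values.mean(), "overall_mean": overall.mean(),
                 "v": v, "p": p}
            )
            if n >= 2 and np.std(values) > 0:
                t_res = ttest_1samp(values, popmean=overall.mean())
                if t_res.pvalue <= alpha:
                    marks.loc[cluster, variable] = (
                        "higher" if mean_gap > 0 else "lower"
                    )
    return pd.DataFrame(rows), marks


# --- IDW surface ------------------------------------------------------------


def idw_surface(
    points: Sequence[tuple[float, float, float]],
    bounds: tuple[float, float, float, float] | None = None,
    resolution: int = 50,
    power: float = 2.0,
) -> pd.DataFrame:
    """Inverse-distance-weighted interpolation on a lon/lat grid.

    ``points`` are (latitude, longitude, value) triples — populations
    without a clear geographic location should be excluded upstream.
    ``bounds`` is (lat_min, lat_max, lon_min, lon_max); default is the
    data bounding box.  Grid nodes coinciding with a data point take the
    point's value exactly; coincident input points with different values
    are averaged with a warning.  Returns a long DataFrame with columns
    lon, lat, value.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 geographic points")
    collapsed: dict[tuple[float, float], list[float]] = {}
    for lat, lon, value in points:
        collapsed.setdefault((float(lat), float(lon)), []).append(float(value))
    for coord, values in collapsed.items():
        if len(values) > 1 and len(set(values)) > 1:
            warnings.warn(
                f"coincident points at {coord} with different values: averaging",
                stacklevel=2,
            )
    lats = np.array([c[0] for c in collapsed])
    lons = np.array([c[1] for c in collapsed])
    vals = np.array([float(np.mean(v)) for v in collapsed.values()])

    if bounds is None:
        bounds = (lats.min(), lats.max(), lons.min(), lons.max())
    lat_axis = np.linspace(bounds[0], bounds[1], resolution)
    lon_axis = np.linspace(bounds[2], bounds[3], resolution)
    grid_lat, grid_lon = np.meshgrid(lat_axis, lon_axis, indexing="ij")

    d2 = (grid_lat[..., None] - lats) ** 2 + (grid_lon[..., None] - lons) ** 2
    dist = np.sqrt(d2)
    out = np.empty(grid_lat.shape)
    exact = dist.min(axis=-1) < 1e-12
    with np.errstate(divide="ignore"):
        weights = dist ** (-power)
    weights[~np.isfinite(weights)] = 0.0
    numer = (weights * vals).sum(axis=-1)
    denom = weights.sum(axis=-1)
    safe = denom > 0
    out[safe] = numer[safe] / denom[safe]
    nearest = dist.argmin(axis=-1)
    out[exact] = vals[nearest[exact]]

    return pd.DataFrame(
        {
            "lat": grid_lat.ravel(),
            "lon": grid_lon.ravel(),
            "value": out.ravel(),
        }
    )
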