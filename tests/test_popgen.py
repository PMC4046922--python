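"""FST + permutation test, BH, shared haplotypes, PCA/Ward/v-tests, IDW."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from paleomt.core import parse_motif
from paleomt.popgen import (
    DBRecord,
    HaplotypeDatabase,
    PopulationMeta,
    bh_adjust,
    fst_permutation_test,
    fst_scan,
    idw_surface,
    inertia_ratio_profile,
    pairwise_fst,
    pca_haplogroups,
    pool_populations,
    shared_haplotypes,
    ward_partition,
)
from paleomt.popgen import test_values as compute_test_values


# --- brute-force AMOVA oracle -------------------------------------------------


def amova_fst_oracle(a, b):
    """Independent AMOVA implementation: explicit distance double loops."""
    pops = [list(a), list(b)]
    everyone = pops[0] + pops[1]
    N = len(everyone)

    def d(x, y):
        return 0.0 if x == y else 1.0

    ssd_total = sum(
        d(everyone[i], everyone[j]) for i in range(N) for j in range(N)
    ) / (2.0 * N)
    ssd_within = 0.0
    for pop in pops:
        n = len(pop)
        ssd_within += sum(
            d(pop[i], pop[j]) for i in range(n) for j in range(n)
        ) / (2.0 * n)
    ssd_among = ssd_total - ssd_within
    sigma_w = ssd_within / (N - 2)
    n_prime = N - (len(pops[0]) ** 2 + len(pops[1]) ** 2) / N
    sigma_a = (ssd_among / 1.0 - sigma_w) / n_prime
    if sigma_a + sigma_w == 0.0:
        return 0.0
    return sigma_a / (sigma_a + sigma_w)


def random_samples(rng, max_n=12, n_types=5):
    n1 = int(rng.integers(2, max_n + 1))
    n2 = int(rng.integers(2, max_n + 1))
    a = [int(x) for x in rng.integers(0, n_types, n1)]
    b = [int(x) for x in rng.integers(0, n_types, n2)]
    return a, b


def test_fst_matches_bruteforce_oracle_on_random_instances():
    rng = np.random.default_rng(123)
    for _ in range(200):
        a, b = random_samples(rng)
        assert pairwise_fst(a, b) == pytest.approx(amova_fst_oracle(a, b), abs=1e-12)


def test_fst_edge_cases():
    # identical composition: no between-group differentiation.  The AMOVA
    # estimator is unbiased around 0, so the realized value is slightly
    # negative (never positive) and vanishes with sample size.
    small = pairwise_fst([1, 2, 3, 1], [1, 2, 3, 1])
    assert small == pytest.approx(amova_fst_oracle([1, 2, 3, 1], [1, 2, 3, 1]), abs=1e-12)
    assert small <= 1e-12
    rng = np.random.default_rng(1)
    big = [int(x) for x in rng.integers(0, 6, 500)]
    assert abs(pairwise_fst(big, list(big))) < 0.01
    assert pairwise_fst(["X"] * 4, ["Y"] * 4) == 1.0
    assert pairwise_fst(["X"] * 5, ["X"] * 7) == 0.0  # defined as 0
    with pytest.raises(ValueError):
        pairwise_fst(["X"], ["Y", "Y"])


def test_fst_is_symmetric():
    rng = np.random.default_rng(5)
    for _ in range(50):
        a, b = random_samples(rng)
        assert pairwise_fst(a, b) == pytest.approx(pairwise_fst(b, a), abs=1e-15)


# --- permutation test -----------------------------------------------------------


def test_permutation_p_bound_attained_for_disjoint_fixed_pops():
    fst, p = fst_permutation_test(["X"] * 6, ["Y"] * 6, n_perm=999, seed=3)
    assert fst == 1.0
    # only permutations reproducing the exact split tie the observed value
    assert p <= 0.01


def test_permutation_reproducible_and_validated():
    a = [0, 0, 1, 2, 2]
    b = [0, 1, 1, 2, 3]
    r1 = fst_permutation_test(a, b, n_perm=200, seed=9)
    r2 = fst_permutation_test(a, b, n_perm=200, seed=9)
    assert r1 == r2
    with pytest.raises(ValueError):
        fst_permutation_test(a, b, n_perm=50, seed=9)
    with pytest.raises(ValueError):
        fst_permutation_test(a, b, n_perm=200, seed=None)


def test_permutation_null_p_is_uniform():
    """Under the null (one population split at random) the permutation p-value
    is uniform: KS test over 300 null replicates not rejected at alpha=0.01.

    The population uses 12 haplotype classes over 30+30 individuals so the
    FST statistic takes enough distinct values for the discrete permutation
    p to be effectively continuous.
    """
    rng = np.random.default_rng(77)
    pvals = []
    for i in range(300):
        pool = rng.integers(0, 12, size=60)
        a, b = [int(x) for x in pool[:30]], [int(x) for x in pool[30:]]
        _, p = fst_permutation_test(a, b, n_perm=199, seed=1000 + i)
        pvals.append(p)
    assert kstest(pvals, "uniform").pvalue > 0.01


# --- BH ---------------------------------------------------------------------------


def test_bh_step_up_enumerated_cases():
    assert bh_adjust([0.2]) == [pytest.approx(0.2)]
    assert bh_adjust([0.01, 0.02, 0.03]) == [pytest.approx(0.03)] * 3
    # hand-computed step-up: sorted (0.01, 0.03, 0.04) -> raw*m/rank =
    # (0.03, 0.045, 0.04); enforcing monotonicity from the top caps the
    # middle one at 0.04
    assert bh_adjust([0.01, 0.04, 0.03]) == [
        pytest.approx(0.03),
        pytest.approx(0.04),
        pytest.approx(0.04),
    ]


def test_bh_properties():
    rng = np.random.default_rng(4)
    p = rng.uniform(size=40)
    adj = np.array(bh_adjust(p))
    assert np.all(adj >= p - 1e-15)
    assert np.all(adj <= 1.0)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)  # monotone in sorted raw p
    assert np.allclose(bh_adjust(adj), adj)  # idempotent
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


def test_fst_scan_applies_bh_family():
    samples = {
        "q": [0] * 6 + [1] * 2,
        "x": [0] * 5 + [2] * 3,
        "y": [3] * 8,
        "z": [0] * 4 + [1] * 4,
    }
    results = fst_scan("q", samples, n_perm=199, seed=11)
    assert [r.pop_b for r in results] == ["x", "y", "z"]
    assert bh_adjust([r.p_raw for r in results]) == [r.p_adjusted for r in results]


# --- shared haplotypes ------------------------------------------------------------


def small_db():
    k = parse_motif("16224C 16311C")
    other = parse_motif("16256T")
    third = parse_motif("16293C")
    records = (
        [DBRecord(f"a{i}", "popA", k, "K") for i in range(3)]
        + [DBRecord("a3", "popA", other, "H")]
        + [DBRecord(f"b{i}", "popB", third, "R0") for i in range(2)]
        + [DBRecord("b2", "popB", k, "U5")]
    )
    return HaplotypeDatabase(records)


def test_shared_haplotypes_counts_match_scan_oracle():
    db = small_db()
    query = [(parse_motif("16224C 16311C"), "K"), (parse_motif("16293C"), "R0")]
    results = {r.population_id: r for r in shared_haplotypes(query, db)}
    # popA: K haplotype carried by 3 of 4; the b2 K-motif carrier is U5 so
    # haplogroup agreement excludes it in popB
    assert results["popA"].n_shared_haplotypes == 1
    assert results["popA"].n_carriers == 3
    assert results["popA"].pct_carriers == pytest.approx(75.0)
    assert results["popB"].n_shared_haplotypes == 1  # 16293C/R0
    assert results["popB"].n_carriers == 2
    no_hg = {r.population_id: r for r in shared_haplotypes(query, db, require_haplogroup=False)}
    assert no_hg["popB"].n_carriers == 3


def test_population_shares_everything_with_itself():
    db = small_db()
    query = [
        (r.haplotype, r.haplogroup) for r in db.population("popA")
    ]
    result = {r.population_id: r for r in shared_haplotypes(query, db)}["popA"]
    assert result.pct_shared_haplotypes == 100.0
    assert result.pct_carriers == 100.0


def test_shared_empty_query_errors():
    with pytest.raises(ValueError):
        shared_haplotypes([], small_db())


def test_pool_populations_sizes_and_errors():
    db = small_db()
    pooled = pool_populations(db, {"popA": "west", "popB": "west"})
    assert len(pooled["west"]) == 7
    with pytest.raises(KeyError):
        pool_populations(db, {"popA": "west"})
    pooled2 = pool_populations(db, {"popA": "west"}, exclude=["popB"])
    assert len(pooled2["west"]) == 4


# --- PCA ---------------------------------------------------------------------------


def random_freq_table(rng, n_pops=12, n_vars=6):
    X = rng.dirichlet(np.ones(n_vars), size=n_pops) * 100.0
    return pd.DataFrame(
        X,
        index=[f"pop{i}" for i in range(n_pops)],
        columns=[f"v{j}" for j in range(n_vars)],
    )


def test_pca_eigenvalue_sum_equals_variable_count():
    rng = np.random.default_rng(8)
    freq = random_freq_table(rng)
    pca = pca_haplogroups(freq)
    assert pca.eigenvalues.sum() == pytest.approx(len(pca.variables))
    assert pca.percent_variance.sum() == pytest.approx(100.0)
    assert np.all(np.diff(pca.eigenvalues) <= 1e-12)
    assert np.all(pca.eigenvalues >= -1e-12)


def test_pca_two_correlated_variables_closed_form():
    """For two standardized variables with correlation r the eigenvalues are
    1 +/- r; at r = 1 they are (2, 0)."""
    rng = np.random.default_rng(10)
    x = rng.normal(size=30)
    freq = pd.DataFrame({"a": x, "b": 2.0 * x + 1.0}, index=range(30))
    pca = pca_haplogroups(freq)
    assert pca.eigenvalues[0] == pytest.approx(2.0)
    assert pca.eigenvalues[1] == pytest.approx(0.0, abs=1e-12)
    y = 0.5 * x + rng.normal(size=30)
    freq2 = pd.DataFrame({"a": x, "b": y}, index=range(30))
    r = np.corrcoef(x, y)[0, 1]
    pca2 = pca_haplogroups(freq2)
    assert pca2.eigenvalues[0] == pytest.approx(1 + abs(r))
    assert pca2.eigenvalues[1] == pytest.approx(1 - abs(r))


def test_pca_scores_reconstruct_data():
    rng = np.random.default_rng(12)
    freq = random_freq_table(rng)
    pca = pca_haplogroups(freq, standardize=False)
    centered = freq - freq.mean(axis=0)
    reconstructed = pca.scores.to_numpy() @ pca.loadings.to_numpy().T
    assert np.allclose(reconstructed, centered.to_numpy(), atol=1e-9)


def test_pca_zero_variance_column_dropped():
    rng = np.random.default_rng(13)
    freq = random_freq_table(rng)
    freq["dead"] = 5.0
    with pytest.warns(UserWarning, match="zero-variance"):
        pca = pca_haplogroups(freq)
    assert "dead" in pca.dropped and "dead" not in pca.variables


def test_pca_sign_convention_deterministic():
    rng = np.random.default_rng(14)
    freq = random_freq_table(rng)
    p1 = pca_haplogroups(freq)
    p2 = pca_haplogroups(freq.iloc[::-1])  # row order must not matter
    assert np.allclose(
        p1.loadings.to_numpy(), p2.loadings.to_numpy(), atol=1e-9
    )
    for j in range(p1.loadings.shape[1]):
        col = p1.loadings.iloc[:, j].to_numpy()
        assert col[np.argmax(np.abs(col))] > 0


# --- Ward / inertia / v-tests --------------------------------------------------------


def test_ward_k_equals_n_gives_ratio_one():
    rng = np.random.default_rng(20)
    freq = random_freq_table(rng, n_pops=8)
    pca = pca_haplogroups(freq)
    part = ward_partition(pca, k=8)
    assert part.inertia_within == pytest.approx(0.0, abs=1e-9)
    assert part.inertia_ratio == pytest.approx(1.0)


def test_ward_recovers_two_planted_blobs():
    rng = np.random.default_rng(21)
    blob1 = rng.normal(0.0, 1.0, size=(10, 4))
    blob2 = rng.normal(12.0, 1.0, size=(10, 4))
    freq = pd.DataFrame(
        np.vstack([blob1, blob2]),
        index=[f"p{i}" for i in range(20)],
        columns=list("abcd"),
    )
    pca = pca_haplogroups(freq, standardize=False)
    part = ward_partition(pca, k=2, n_components=4)
    labels = part.labels.to_numpy()
    assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
    assert labels[0] != labels[10]
    assert part.inertia_ratio > 0.9


def test_inertia_decomposition_sums_for_every_k():
    rng = np.random.default_rng(22)
    freq = random_freq_table(rng, n_pops=10)
    pca = pca_haplogroups(freq)
    for k in range(1, 11):
        part = ward_partition(pca, k=k)
        assert part.inertia_between + part.inertia_within == pytest.approx(
            part.inertia_total, rel=1e-9
        )
    profile = inertia_ratio_profile(pca, k_max=10)
    assert profile.is_monotonic_increasing
    with pytest.raises(ValueError):
        ward_partition(pca, k=0)
    with pytest.raises(ValueError):
        ward_partition(pca, k=11)


def test_v_test_hand_computed_toy():
    """N=6, cluster n=2, overall variance 1, mean gap 2:
    v = 2 / sqrt((4/5) / 2) = 3.162."""
    values = np.array([2.0, 2.0, 0.0, 0.0, -1.0, -3.0])
    # shift so overall mean 0, variance exactly 1 (population variance)
    values = (values - values.mean()) / values.std()
    freq = pd.DataFrame({"x": values + 0.0}, index=[f"p{i}" for i in range(6)])
    # craft a partition object directly
    from paleomt.popgen import ClusterPartition

    labels = pd.Series([1, 1, 2, 2, 2, 2], index=freq.index)
    part = ClusterPartition(
        merge_tree=np.empty((0, 4)), k=2, labels=labels,
        inertia_between=0, inertia_within=0, inertia_total=0,
        coordinates=freq,
    )
    table, _ = compute_test_values(part, freq)
    row = table[(table.cluster == 1) & (table.variable == "x")].iloc[0]
    gap = row.cluster_mean - row.overall_mean
    expected = gap / np.sqrt((4 / 5) * 1.0 / 2)
    assert row.v == pytest.approx(expected)
    # and with the gap forced to exactly 2:
    assert abs(2.0 / np.sqrt((4 / 5) / 2)) == pytest.approx(3.1623, abs=1e-4)


def test_v_test_zero_for_whole_data_cluster():
    freq = pd.DataFrame({"x": [1.0, 2.0, 3.0]}, index=list("abc"))
    from paleomt.popgen import ClusterPartition

    labels = pd.Series([1, 1, 1], index=freq.index)
    part = ClusterPartition(np.empty((0, 4)), 1, labels, 0, 0, 0, freq)
    table, marks = compute_test_values(part, freq)
    assert (table.v == 0).all()
    assert (marks == "").all().all()


def test_v_test_marks_direction():
    rng = np.random.default_rng(30)
    low = rng.normal(0, 0.5, size=(8, 1))
    high = rng.normal(10, 0.5, size=(8, 1))
    freq = pd.DataFrame(np.vstack([low, high]), columns=["x"],
                        index=[f"p{i}" for i in range(16)])
    pca = pca_haplogroups(freq, standardize=False)
    part = ward_partition(pca, k=2, n_components=1)
    table, marks = compute_test_values(part, freq)
    high_cluster = part.labels.iloc[-1]
    assert marks.loc[high_cluster, "x"] == "higher"
    assert marks.loc[3 - high_cluster, "x"] == "lower"
    v_high = table[(table.cluster == high_cluster)].iloc[0].v
    assert v_high > 3


# --- IDW ---------------------------------------------------------------------------


def test_idw_flat_field():
    points = [(0.0, 0.0, 5.0), (1.0, 1.0, 5.0), (0.0, 1.0, 5.0)]
    grid = idw_surface(points, resolution=10)
    assert np.allclose(grid["value"], 5.0)


def test_idw_exact_at_data_points_and_bounded():
    points = [(0.0, 0.0, 1.0), (1.0, 1.0, 3.0), (0.0, 1.0, 2.0)]
    grid = idw_surface(points, bounds=(0.0, 1.0, 0.0, 1.0), resolution=11)
    for lat, lon, value in points:
        node = grid[(np.isclose(grid.lat, lat)) & (np.isclose(grid.lon, lon))]
        assert node.value.iloc[0] == pytest.approx(value)
    assert grid.value.min() >= 1.0 - 1e-12 and grid.value.max() <= 3.0 + 1e-12


def test_idw_approximates_linear_field():
    """A linear field sampled on an 11x11 grid is reproduced in the interior
    to within 2 units on a field spanning 18 (IDW flattens gradients between
    points; it is an interpolant, not a linear model)."""
    import itertools

    axis = np.linspace(0, 10, 11)
    pts = [
        (float(a), float(b), float(2 * a + b))
        for a, b in itertools.product(axis, repeat=2)
    ]
    grid = idw_surface(pts, bounds=(2.0, 8.0, 2.0, 8.0), resolution=12, power=2.0)
    truth = 2 * grid.lat + grid.lon
    assert np.max(np.abs(grid.value - truth)) < 2.0


def test_idw_coincident_points_averaged():
    points = [(0.0, 0.0, 1.0), (0.0, 0.0, 3.0), (1.0, 1.0, 2.0), (0.0, 1.0, 2.0)]
    with pytest.warns(UserWarning, match="coincident"):
        grid = idw_surface(points, bounds=(0.0, 1.0, 0.0, 1.0), resolution=3)
    node = grid[(grid.lat == 0.0) & (grid.lon == 0.0)]
    assert node.value.iloc[0] == pytest.approx(2.0)


def test_idw_requires_three_points():
    with pytest.raises(ValueError):
        idw_surface([(0, 0, 1), (1, 1, 2)])
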