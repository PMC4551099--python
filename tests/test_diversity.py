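"""Coverage, Chao1, Shannon and Coleman rarefaction."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from clonelib.diversity import (
    CloneLibrary,
    chao1,
    coleman_rarefaction,
    diversity_table,
    good_coverage,
    shannon,
)

abundance_vectors = st.lists(st.integers(1, 12), min_size=1, max_size=12)


def test_clone_library_validation():
    with pytest.raises(ValueError):
        CloneLibrary(())
    with pytest.raises(ValueError):
        CloneLibrary((0, 3))
    lib = CloneLibrary((5, 2, 1))
    assert (lib.n_otus, lib.n_clones) == (3, 8)
    assert lib.count_of_count(1) == 1


# --- coverage -------------------------------------------------------------


@pytest.mark.parametrize(
    "n,N,expected", [(3, 96, 0.97), (15, 71, 0.79), (2, 32, 0.94)]
)
def test_coverage_otu_count_variant(n, N, expected):
    # n OTUs: one big OTU plus n-1 singletons summing to N clones
    lib = CloneLibrary((N - n + 1,) + (1,) * (n - 1))
    assert round(good_coverage(lib, "otu_count"), 2) == expected


def test_coverage_every_clone_own_otu():
    assert good_coverage(CloneLibrary((1,) * 7), "otu_count") == 0.0


def test_coverage_singleton_variant_is_classic_good():
    lib = CloneLibrary((5, 2, 1, 1))  # F1=2, N=9
    assert good_coverage(lib, "singleton") == pytest.approx(1 - 2 / 9)
    # without singletons classic coverage is complete
    assert good_coverage(CloneLibrary((4, 3)), "singleton") == 1.0


# --- Chao1 ----------------------------------------------------------------


def test_chao1_single_otu_29_clones_degenerate():
    est = chao1(CloneLibrary((29,)))
    assert (est.estimate, est.lo, est.hi) == (1.0, 1.0, 1.0)


def test_chao1_no_singletons_equals_observed():
    assert chao1(CloneLibrary((2, 2, 3))).estimate == 3.0


def test_chao1_hand_evaluated_formula():
    # S=5, F1=3, F2=1: 5 + 3*2/(2*2) = 6.5
    assert chao1(CloneLibrary((5, 2, 1, 1, 1))).estimate == pytest.approx(6.5)


@given(abundance_vectors)
def test_chao1_at_least_observed_richness(a):
    lib = CloneLibrary(tuple(a))
    est = chao1(lib)
    f1 = lib.count_of_count(1)
    assert est.estimate >= lib.n_otus
    if f1 <= 1:
        assert est.estimate == lib.n_otus
    else:
        assert est.estimate > lib.n_otus
    assert est.lo <= est.estimate <= est.hi


def test_chao1_parameter_recovery_multinomial():
    """Median Chao1 over 200 replicates within 15% of true richness
    once the library is 10x deeper than the richness."""
    rng = np.random.default_rng(7)
    s_true = 10
    n_clones = 100
    p = np.full(s_true, 1.0 / s_true)
    estimates = []
    for _ in range(200):
        counts = rng.multinomial(n_clones, p)
        counts = counts[counts > 0]
        estimates.append(chao1(CloneLibrary(tuple(int(c) for c in counts))).estimate)
    assert abs(np.median(estimates) - s_true) <= 0.15 * s_true


# --- Shannon --------------------------------------------------------------


def test_shannon_single_otu_zero():
    est = shannon(CloneLibrary((29,)))
    assert est.estimate == 0.0


def test_shannon_equal_abundances_max_entropy():
    assert shannon(CloneLibrary((5, 5, 5, 5))).estimate == pytest.approx(math.log(4))


def test_shannon_two_otus_hand_value():
    assert shannon(CloneLibrary((21, 11))).estimate == pytest.approx(0.6435, abs=5e-5)
    assert round(shannon(CloneLibrary((21, 11))).estimate, 2) == 0.64


@given(abundance_vectors)
def test_shannon_zero_iff_single_otu(a):
    est = shannon(CloneLibrary(tuple(a)))
    if len(a) == 1:
        assert est.estimate == 0.0
    else:
        assert est.estimate > 0.0
    assert est.lo <= est.estimate <= est.hi


@given(st.integers(2, 8), st.integers(0, 1000))
def test_shannon_maximized_at_equal_abundances(k, seed):
    rng = np.random.default_rng(seed)
    equal = CloneLibrary((6,) * k)
    perturbed = np.full(k, 6)
    i, j = rng.choice(k, size=2, replace=False)
    perturbed[i] += 3
    perturbed[j] -= 3
    assert shannon(CloneLibrary(tuple(perturbed))).estimate \
        <= shannon(equal).estimate + 1e-12


# --- Coleman rarefaction --------------------------------------------------


def test_coleman_depth_one():
    # E[S|1] = S - sum(1 - 1/N)^a; for [1,1]: 2 - 2*0.5 = 1 (also exact)
    assert coleman_rarefaction(CloneLibrary((1, 1)), [1])[0] == pytest.approx(1.0)


def test_coleman_single_otu_approaches_one():
    vals = coleman_rarefaction(CloneLibrary((30,)), [1, 10, 30])
    assert np.all(vals <= 1.0) and vals[-1] == pytest.approx(1.0, abs=1e-10)


def test_coleman_vs_exact_hypergeometric_small_case():
    """Documents the approximation gap: Coleman 1.5 vs exact 5/3 on
    [2,2] at depth 2 (exhaustive subset enumeration)."""
    val = coleman_rarefaction(CloneLibrary((2, 2)), [2])[0]
    assert val == pytest.approx(1.5)
    clones = ["a", "a", "b", "b"]
    richness = [len(set(sub)) for sub in itertools.combinations(clones, 2)]
    exact = sum(richness) / len(richness)
    assert exact == pytest.approx(5 / 3)
    assert val != pytest.approx(exact)


def test_coleman_monotone_and_range_checked():
    lib = CloneLibrary((8, 4, 2, 1))
    curve = coleman_rarefaction(lib, list(range(1, 16)))
    assert np.all(np.diff(curve) >= -1e-12)
    with pytest.raises(ValueError):
        coleman_rarefaction(lib, [0])
    with pytest.raises(ValueError):
        coleman_rarefaction(lib, [16])


@pytest.mark.parametrize("seed", range(3))
def test_coleman_matches_monte_carlo_inclusion_oracle(seed):
    """The curve is the exact mean richness under independent clone
    inclusion at rate m/N; a 10^4-draw Monte-Carlo oracle of that scheme
    must agree within 3 standard errors at every depth."""
    rng = np.random.default_rng(seed)
    a = rng.integers(1, 10, size=rng.integers(2, 8))
    a = a[: max(2, len(a))]
    lib = CloneLibrary(tuple(int(x) for x in a))
    n_total = lib.n_clones
    depths = sorted({1, n_total // 2, n_total})
    curve = coleman_rarefaction(lib, depths)
    n_draws = 10_000
    for depth, expected in zip(depths, curve):
        keep = rng.random((n_draws, n_total)) < depth / n_total
        otu_of_clone = np.repeat(np.arange(lib.n_otus), lib.abundances)
        seen = np.zeros((n_draws, lib.n_otus), dtype=bool)
        for j in range(lib.n_otus):
            seen[:, j] = keep[:, otu_of_clone == j].any(axis=1)
        richness = seen.sum(axis=1)
        se = richness.std(ddof=1) / math.sqrt(n_draws)
        assert abs(richness.mean() - expected) <= 3 * max(se, 1e-9)


# --- report table ---------------------------------------------------------


def test_diversity_table_layout():
    lib = CloneLibrary((94, 1, 1), sample_id="ST09", year=2005, marker="16S-archaea")
    df = diversity_table([lib])
    row = df.iloc[0]
    assert row["OTUs"] == 3 and row["clones"] == 96
    assert row["coverage"] == 0.97
    assert row["chao1"] >= row["OTUs"]
    assert list(df.columns[:5]) == ["sample", "year", "marker", "OTUs", "clones"]
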