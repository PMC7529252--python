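"""Exact enumeration, Monte Carlo agreement, and the 0/RG predictions."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from meioconjsim import (
    ChromosomeSpec,
    ConfigurationError,
    MeiosisScenario,
    ScenarioSizeError,
    UndefinedRatioError,
    ValidationError,
    conjunction_null_scenario,
    dna_content_distribution,
    enumerate_meioses,
    fish_class_probabilities,
    normal_to_abnormal_ratio,
    pattern_distribution,
    simulate_meioses,
    wild_type_scenario,
    xy_univalent_scenario,
)
from meioconjsim.scenario import autosome_univalent_scenario

from conftest import brute_force_patterns, brute_force_xy_classes


# ---------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------


def test_wild_type_enumerates_to_single_certain_outcome(wt_scenario):
    dist = enumerate_meioses(wt_scenario)
    dist.validate()
    assert len(dist.support) == 1
    outcome, p = dist.support[0]
    assert p == 1
    # every spermatid holds exactly one chromatid of one homolog per pair
    for entry in outcome:
        for spermatid in entry:
            assert sorted(spermatid) == [0, 1]


def test_xy_univalent_regular_sisters_has_four_equiprobable_outcomes(xy_regular):
    dist = enumerate_meioses(xy_regular)
    dist.validate()
    assert len(dist.support) == 4
    assert all(p == Fraction(1, 4) for _, p in dist.support)


@pytest.mark.parametrize("rule", ["regular_sisters", "random_chromatids"])
def test_class_probabilities_match_brute_force(rule):
    """The factorized enumerator agrees with explicit elementary enumeration."""
    summary = fish_class_probabilities(xy_univalent_scenario(rule))
    expected = brute_force_xy_classes(rule)
    assert summary.p_none == expected["none"]
    assert summary.p_red_only == expected["red_only"]
    assert summary.p_green_only == expected["green_only"]
    assert summary.p_both == expected["both"]


def test_xy_univalent_random_chromatid_classes_exact(xy_random):
    summary = fish_class_probabilities(xy_random)
    assert summary.p_none == Fraction(25, 64)
    assert summary.p_red_only == Fraction(15, 64)
    assert summary.p_green_only == Fraction(15, 64)
    assert summary.p_both == Fraction(9, 64)


def test_wild_type_classes(wt_scenario):
    summary = fish_class_probabilities(wt_scenario)
    assert summary.p_red_only == summary.p_green_only == Fraction(1, 2)
    assert summary.p_none == summary.p_both == 0


def test_missing_probe_is_configuration_error():
    s = MeiosisScenario(
        chromosomes=(ChromosomeSpec.pair("2", "bivalent"),), name="unprobed"
    )
    with pytest.raises(ConfigurationError):
        fish_class_probabilities(s)


def test_oversized_enumeration_raises_size_error():
    entries = tuple(
        ChromosomeSpec.pair(str(i), "univalent_pair") for i in range(6)
    )
    s = MeiosisScenario(chromosomes=entries, mII_rule="random_chromatids")
    with pytest.raises(ScenarioSizeError):
        enumerate_meioses(s)


def test_more_than_eight_entries_rejected():
    entries = tuple(ChromosomeSpec.pair(str(i), "bivalent") for i in range(9))
    with pytest.raises(ConfigurationError):
        MeiosisScenario(chromosomes=entries)


# ---------------------------------------------------------------------
# ratios
# ---------------------------------------------------------------------


def test_zero_to_rg_regular_sisters_is_one(xy_regular):
    assert fish_class_probabilities(xy_regular).zero_to_rg == 1


def test_zero_to_rg_random_chromatids_is_25_ninths(xy_random):
    ratio = fish_class_probabilities(xy_random).zero_to_rg
    assert ratio == Fraction(25, 9)
    # two-decimal truncation gives the printed prediction
    assert math.floor(float(ratio) * 100) / 100 == 2.77


def test_normal_to_abnormal_ratios(xy_regular, xy_random):
    assert normal_to_abnormal_ratio(xy_regular) == 1
    assert normal_to_abnormal_ratio(xy_random) == Fraction(15, 17)


def test_ratios_undefined_for_wild_type(wt_scenario):
    summary = fish_class_probabilities(wt_scenario)
    with pytest.raises(UndefinedRatioError):
        summary.zero_to_rg
    with pytest.raises(UndefinedRatioError):
        summary.normal_to_abnormal


# ---------------------------------------------------------------------
# meiosis I patterns
# ---------------------------------------------------------------------


def test_all_bivalent_pattern_is_certain_four_four(wt_scenario):
    patterns = pattern_distribution(wt_scenario)
    assert patterns.patterns["4:4"] == 1
    assert sum(patterns.patterns.values()) == 1


def test_eight_free_units_pattern_matches_brute_force():
    got = pattern_distribution(conjunction_null_scenario()).patterns
    expected = brute_force_patterns(n_bivalents=0, n_univalent_pairs=4)
    assert got["4:4"] == Fraction(70, 256)
    assert got["5:3"] == Fraction(112, 256)
    assert got["6:2"] == Fraction(56, 256)
    assert got["7:1"] == Fraction(16, 256)
    assert got["8:0"] == Fraction(2, 256)
    for key, p in expected.items():
        assert got[key] == p


def test_single_univalent_pair_pattern():
    got = pattern_distribution(autosome_univalent_scenario()).patterns
    expected = brute_force_patterns(n_bivalents=3, n_univalent_pairs=1)
    assert got["4:4"] == expected["4:4"] == Fraction(1, 2)
    assert got["5:3"] == expected["5:3"] == Fraction(1, 2)


@pytest.mark.parametrize("n_pairs", [1, 2, 3, 4])
def test_pattern_distribution_is_folded_binomial(n_pairs):
    """n free units split as Binomial(n, 1/2) folded at n/2."""
    entries = tuple(
        ChromosomeSpec.pair(str(i), "univalent_pair") for i in range(n_pairs)
    )
    got = pattern_distribution(MeiosisScenario(chromosomes=entries)).patterns
    n = 2 * n_pairs
    assert len(got) == n // 2 + 1
    for key, p in got.items():
        a, b = map(int, key.split(":"))
        assert a + b == n and a >= b
        expected = Fraction(math.comb(n, a), 2**n)
        if a != b:
            expected *= 2  # either pole can be the majority pole
        assert p == expected


# ---------------------------------------------------------------------
# properties on random scenarios
# ---------------------------------------------------------------------


@st.composite
def scenarios(draw):
    n = draw(st.integers(1, 3))
    entries = tuple(
        ChromosomeSpec.pair(
            f"c{i}",
            conjunction=draw(st.sampled_from(["bivalent", "univalent_pair"])),
            dna_content=draw(
                st.floats(0.2, 5, allow_nan=False, allow_infinity=False)
            ),
        )
        for i in range(n)
    )
    rule = draw(st.sampled_from(["regular_sisters", "random_chromatids"]))
    return MeiosisScenario(chromosomes=entries, mII_rule=rule)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(scenarios())
def test_enumeration_sums_to_one_and_conserves_chromatids(scenario):
    dist = enumerate_meioses(scenario)
    dist.validate()  # asserts sum == 1 and 4 chromatids per pair


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    st.sampled_from(["bivalent", "univalent_pair"]),
    st.sampled_from(["regular_sisters", "random_chromatids"]),
)
def test_red_green_symmetry_for_symmetric_homologs(conjunction, rule):
    """Relabeling poles swaps X and Y, so symmetric specs give equal fractions."""
    s = MeiosisScenario(
        chromosomes=(
            ChromosomeSpec.pair(
                "XY", conjunction=conjunction, probes=("red", "green")
            ),
        ),
        mII_rule=rule,
    )
    summary = fish_class_probabilities(s)
    assert summary.p_red_only == summary.p_green_only


# ---------------------------------------------------------------------
# Monte Carlo twin
# ---------------------------------------------------------------------


def test_wild_type_sampling_always_yields_the_unique_outcome(wt_scenario):
    sample = simulate_meioses(wt_scenario, 200, seed=11)
    assert np.unique(sample.counts, axis=0).shape[0] == 1


def test_same_seed_reproduces_sample(xy_random):
    a = simulate_meioses(xy_random, 1000, seed=42)
    b = simulate_meioses(xy_random, 1000, seed=42)
    assert np.array_equal(a.counts, b.counts)


def test_different_seeds_differ(xy_random):
    a = simulate_meioses(xy_random, 1000, seed=1)
    b = simulate_meioses(xy_random, 1000, seed=2)
    assert not np.array_equal(a.counts, b.counts)


@pytest.mark.parametrize("rule", ["regular_sisters", "random_chromatids"])
def test_empirical_class_frequencies_converge_to_enumeration(rule):
    scenario = xy_univalent_scenario(rule)
    n = 100_000
    sample = simulate_meioses(scenario, n, seed=7)
    freqs = sample.fish_class_frequencies()
    exact = fish_class_probabilities(scenario).as_floats()
    for cls, p in exact.items():
        se = math.sqrt(p * (1 - p) / (4 * n))
        assert abs(freqs[cls] - p) < 4 * se + 1e-12, cls


def test_empirical_patterns_converge_to_enumeration():
    scenario = conjunction_null_scenario()
    n = 100_000
    counts = simulate_meioses(scenario, n, seed=13).mi_pattern_counts()
    exact = pattern_distribution(scenario).as_floats()
    for pat, p in exact.items():
        se = math.sqrt(p * (1 - p) / n)
        assert abs(counts.get(pat, 0) / n - p) < 4 * se, pat


def test_invalid_n_meioses(xy_random):
    with pytest.raises(ValidationError):
        simulate_meioses(xy_random, 0, seed=1)


# ---------------------------------------------------------------------
# DNA-content variability
# ---------------------------------------------------------------------


def test_all_bivalent_equal_contents_give_zero_variability():
    sds = dna_content_distribution(
        wild_type_scenario(unit_contents=True), 64, n_cysts=5, seed=3
    )
    assert np.allclose(sds, 0)


def test_eight_univalent_unit_content_sd_approaches_closed_form(
    null_unit_regular,
):
    """Spermatid content ~ Binomial(8, 1/2): normalized s.d. -> sqrt(2)/4."""
    sds = dna_content_distribution(null_unit_regular, 64, n_cysts=200, seed=5)
    assert abs(sds.mean() - math.sqrt(2) / 4) < 0.01


def test_dna_content_distribution_is_seed_reproducible(null_unit_regular):
    a = dna_content_distribution(null_unit_regular, 64, 20, seed=9)
    b = dna_content_distribution(null_unit_regular, 64, 20, seed=9)
    assert np.array_equal(a, b)


def test_cyst_size_must_be_multiple_of_four(null_unit_regular):
    with pytest.raises(ValidationError):
        dna_content_distribution(null_unit_regular, 30, 5, seed=1)
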