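"""Shared fixtures and independent brute-force oracles.

The oracles enumerate the elementary sample space of a meiosis directly
(explicit chromatids, explicit pole/spermatid tosses) without going
through the package's factorized enumerator, so they can vouch for it.
"""

from collections import Counter
from fractions import Fraction
from itertools import product

import pytest

from meioconjsim import (
    conjunction_null_scenario,
    wild_type_scenario,
    xy_univalent_scenario,
)


@pytest.fixture
def wt_scenario():
    return wild_type_scenario()


@pytest.fixture
def xy_regular():
    return xy_univalent_scenario("regular_sisters")


@pytest.fixture
def xy_random():
    return xy_univalent_scenario("random_chromatids")


@pytest.fixture
def null_unit_regular():
    return conjunction_null_scenario("regular_sisters", unit_contents=True)


def brute_force_xy_classes(mII_rule: str) -> dict[str, Fraction]:
    """Per-spermatid FISH class probabilities for X/Y univalents.

    Enumerates every elementary assignment explicitly: the X univalent
    and the Y univalent each toss a meiosis I pole; at meiosis II each
    of the four chromatids (x1, x2, y1, y2) goes to a spermatid of its
    pole — both spermatids for ``random_chromatids``, one each for
    ``regular_sisters``.  Spermatids 0,1 descend from pole 0; 2,3 from
    pole 1.
    """
    counts: Counter = Counter()
    n_assignments = 0
    for px, py in product((0, 1), repeat=2):
        if mII_rule == "random_chromatids":
            mii_space = product((0, 1), repeat=4)
        else:  # one chromatid to each spermatid of the pole
            mii_space = [(0, 1, 0, 1)]
        for bx1, bx2, by1, by2 in mii_space:
            x_spermatids = {2 * px + bx1, 2 * px + bx2}
            y_spermatids = {2 * py + by1, 2 * py + by2}
            n_assignments += 1
            for s in range(4):
                red, green = s in x_spermatids, s in y_spermatids
                if red and green:
                    counts["both"] += 1
                elif red:
                    counts["red_only"] += 1
                elif green:
                    counts["green_only"] += 1
                else:
                    counts["none"] += 1
    total = 4 * n_assignments
    return {
        c: Fraction(counts[c], total)
        for c in ("none", "red_only", "green_only", "both")
    }


def brute_force_patterns(n_bivalents: int, n_univalent_pairs: int):
    """Unordered meiosis I split distribution by explicit enumeration.

    Every bivalent sends one centromere unit to each pole; every
    univalent homolog tosses a fair coin.
    """
    n_units = 2 * (n_bivalents + n_univalent_pairs)
    n_free = 2 * n_univalent_pairs
    counts: Counter = Counter()
    for tosses in product((0, 1), repeat=n_free):
        c0 = n_bivalents + sum(1 for t in tosses if t == 0)
        a, b = max(c0, n_units - c0), min(c0, n_units - c0)
        counts[f"{a}:{b}"] += 1
    total = 2**n_free
    return {k: Fraction(v, total) for k, v in counts.items()}
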