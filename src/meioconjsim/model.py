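"""Exact enumeration and Monte Carlo simulation of meiotic transmission.

The sample space of one meiosis is factorized per homolog pair: a
bivalent splits 1:1 at meiosis I with a conventional orientation (pole
labels are arbitrary, so which homolog faces which pole is not a random
degree of freedom), a univalent pair takes one of 4 equiprobable pole
assignments (each homolog tossed independently); at meiosis II each chromosome at a pole
either splits its two sister chromatids 1:1 between the pole's two
spermatids (``regular_sisters``) or sends each chromatid independently to
either spermatid (``random_chromatids``).  Pairs are independent, so the
tetrad distribution is the product of small per-pair distributions.

All enumeration is exact over :class:`fractions.Fraction`, so printed
predictions such as the 0/RG ratio 25/9 are rational numbers, not
floating-point approximations.  :func:`simulate_meioses` is the seeded
stochastic twin of the enumerator and must converge to it.

Tetrad geometry: spermatids 0 and 1 descend from meiosis I pole 0,
spermatids 2 and 3 from pole 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DegenerateInputError,
    ScenarioSizeError,
    UndefinedRatioError,
    ValidationError,
)
from .scenario import MeiosisScenario

#: chromatid counts per (spermatid, homolog) for one pair:
#: tuple over 4 spermatids of (count_homolog_a, count_homolog_b)
EntryOutcome = tuple[tuple[int, int], ...]
#: one tetrad outcome: tuple over chromosome entries of EntryOutcome
TetradOutcome = tuple[EntryOutcome, ...]

FISH_CLASSES = ("none", "red_only", "green_only", "both")

_MAX_SUPPORT = 2_000_000  # guard for the cross-entry product enumeration

HALF = Fraction(1, 2)


def _mii_splits(mII_rule: str) -> list[tuple[tuple[int, int], Fraction]]:
    """Distribution of a chromosome's 2 chromatids over its pole's 2 spermatids."""
    if mII_rule == "regular_sisters":
        return [((1, 1), Fraction(1))]
    # independent coin per chromatid: 2:0, 1:1, 0:2
    return [
        ((2, 0), Fraction(1, 4)),
        ((1, 1), Fraction(1, 2)),
        ((0, 2), Fraction(1, 4)),
    ]


def _entry_distribution(chrom, mII_rule: str) -> dict[EntryOutcome, Fraction]:
    """Exact tetrad distribution of a single homolog pair."""
    if chrom.conjunction == "bivalent":
        # pole labels are arbitrary, so the 1:1 bivalent split is fixed by
        # convention (homolog a -> pole 0); no random choice exists
        mi_options = [((0, 1), Fraction(1))]
    else:  # univalent_pair: each homolog independently to either pole
        mi_options = [
            ((pa, pb), Fraction(1, 4))
            for pa, pb in itertools.product((0, 1), repeat=2)
        ]
    splits = _mii_splits(mII_rule)
    dist: dict[EntryOutcome, Fraction] = {}
    for (pole_a, pole_b), p_mi in mi_options:
        for (sa, p_a), (sb, p_b) in itertools.product(splits, repeat=2):
            counts = [[0, 0], [0, 0], [0, 0], [0, 0]]
            counts[2 * pole_a][0] += sa[0]
            counts[2 * pole_a + 1][0] += sa[1]
            counts[2 * pole_b][1] += sb[0]
            counts[2 * pole_b + 1][1] += sb[1]
            outcome: EntryOutcome = tuple(tuple(c) for c in counts)
            dist[outcome] = dist.get(outcome, Fraction(0)) + p_mi * p_a * p_b
    return dist


@dataclass
class OutcomeDistribution:
    """Exact probability law over the four spermatids of one meiosis."""

    scenario: MeiosisScenario
    support: list[tuple[TetradOutcome, Fraction]]

    def total_probability(self) -> Fraction:
        return sum((p for _, p in self.support), Fraction(0))

    def validate(self) -> None:
        if self.total_probability() != 1:
            raise ValidationError("outcome probabilities do not sum to 1")
        n_entries = len(self.scenario.chromosomes)
        for outcome, p in self.support:
            if p < 0:
                raise ValidationError("negative probability in support")
            for e in range(n_entries):
                total = sum(sum(sp) for sp in outcome[e])
                if total != 4:
                    raise ValidationError(
                        "chromatid conservation violated: homolog pair "
                        f"{self.scenario.chromosomes[e].name!r} has {total} "
                        "chromatids across the tetrad (expected 4)"
                    )

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy table: one row per (outcome, spermatid, chromosome)."""
        rows = []
        for i, (outcome, p) in enumerate(self.support):
            for e, chrom in enumerate(self.scenario.chromosomes):
                for s in range(4):
                    rows.append(
                        {
                            "outcome": i,
                            "probability": float(p),
                            "spermatid": s,
                            "chromosome": chrom.name,
                            chrom.homologs[0].label: outcome[e][s][0],
                            chrom.homologs[1].label: outcome[e][s][1],
                        }
                    )
        return pd.DataFrame(rows)


def enumerate_meioses(scenario: MeiosisScenario) -> OutcomeDistribution:
    """Exhaustively enumerate the tetrad distribution of a scenario.

    Deterministic and exact; every independent binary choice (meiosis I
    pole tosses, meiosis II chromatid tosses) carries equal probability.

    Raises
    ------
    ScenarioSizeError
        If the joint support would exceed the enumeration guard.
    """
    scenario.validate()
    per_entry = [
        _entry_distribution(c, scenario.mII_rule) for c in scenario.chromosomes
    ]
    size = 1
    for d in per_entry:
        size *= len(d)
        if size > _MAX_SUPPORT:
            raise ScenarioSizeError(
                f"joint outcome space exceeds {_MAX_SUPPORT} states; "
                "use simulate_meioses or marginal operations instead"
            )
    support: list[tuple[TetradOutcome, Fraction]] = []
    for combo in itertools.product(*(d.items() for d in per_entry)):
        outcome = tuple(o for o, _ in combo)
        p = Fraction(1)
        for _, pe in combo:
            p *= pe
        support.append((outcome, p))
    return OutcomeDistribution(scenario=scenario, support=support)


# ---------------------------------------------------------------------
# FISH class probabilities
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class FishClassSummary:
    """Exact per-spermatid FISH class probabilities of a scenario."""

    p_none: Fraction
    p_red_only: Fraction
    p_green_only: Fraction
    p_both: Fraction

    def as_floats(self) -> dict[str, float]:
        return {
            "none": float(self.p_none),
            "red_only": float(self.p_red_only),
            "green_only": float(self.p_green_only),
            "both": float(self.p_both),
        }

    @property
    def zero_to_rg(self) -> Fraction:
        """0/RG: P(no signal) / P(both red and green)."""
        if self.p_both == 0:
            raise UndefinedRatioError(
                "0/RG undefined: probability of a both-signal nucleus is 0"
            )
        return self.p_none / self.p_both

    @property
    def normal_to_abnormal(self) -> Fraction:
        """(P(red only) + P(green only)) / (P(none) + P(both))."""
        denom = self.p_none + self.p_both
        if denom == 0:
            raise UndefinedRatioError(
                "normal:abnormal undefined: no abnormal class has "
                "positive probability"
            )
        return (self.p_red_only + self.p_green_only) / denom


def fish_class_probabilities(scenario: MeiosisScenario) -> FishClassSummary:
    """Exact FISH class probabilities marginalized over the four spermatids.

    A spermatid's class records presence (>= 1 chromatid) of the
    red-probed and the green-probed chromosome; two chromatids of the
    same chromosome still give a single presence call, matching how FISH
    spots of the same color are scored.
    """
    probes = scenario.probe_positions()
    if "red" not in probes or "green" not in probes:
        raise ConfigurationError(
            "scenario needs exactly one red-probed and one green-probed "
            f"chromosome; found probes {sorted(probes)}"
        )
    # only entries carrying a probe matter for the marginal
    entries = sorted({probes["red"][0], probes["green"][0]})
    per_entry = [
        _entry_distribution(scenario.chromosomes[e], scenario.mII_rule)
        for e in entries
    ]
    pos = {
        color: (entries.index(e), h) for color, (e, h) in probes.items()
    }
    acc = {c: Fraction(0) for c in FISH_CLASSES}
    for combo in itertools.product(*(d.items() for d in per_entry)):
        p = Fraction(1)
        for _, pe in combo:
            p *= pe
        for s in range(4):
            red = combo[pos["red"][0]][0][s][pos["red"][1]] >= 1
            green = combo[pos["green"][0]][0][s][pos["green"][1]] >= 1
            if red and green:
                cls = "both"
            elif red:
                cls = "red_only"
            elif green:
                cls = "green_only"
            else:
                cls = "none"
            acc[cls] += p * Fraction(1, 4)
    return FishClassSummary(
        p_none=acc["none"],
        p_red_only=acc["red_only"],
        p_green_only=acc["green_only"],
        p_both=acc["both"],
    )


def zero_to_rg_ratio(scenario: MeiosisScenario) -> Fraction:
    """Predicted 0/RG ratio of a scenario (exact rational number)."""
    return fish_class_probabilities(scenario).zero_to_rg


def normal_to_abnormal_ratio(scenario: MeiosisScenario) -> Fraction:
    """Predicted ratio of normal-signal to abnormal-signal nuclei."""
    return fish_class_probabilities(scenario).normal_to_abnormal


# ---------------------------------------------------------------------
# Meiosis I centromere segregation patterns
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class PatternDistribution:
    """Unordered meiosis I pole-split distribution over centromere units."""

    n_units: int
    patterns: dict[str, Fraction]

    def as_floats(self) -> dict[str, float]:
        return {k: float(v) for k, v in self.patterns.items()}


def pattern_distribution(scenario: MeiosisScenario) -> PatternDistribution:
    """Exact distribution of unordered meiosis I centromere splits.

    Each bivalent contributes two centromere-bearing units forced to
    opposite poles; each univalent pair contributes two units that choose
    a pole independently.  With four univalent pairs this reproduces the
    classic 4:4 / 5:3 / 6:2 / 7:1 / 8:0 spectrum of random segregation of
    eight centromeres.
    """
    scenario.validate()
    n_biv = sum(1 for c in scenario.chromosomes if c.conjunction == "bivalent")
    n_uni_units = 2 * (len(scenario.chromosomes) - n_biv)
    n = 2 * len(scenario.chromosomes)
    patterns = {
        f"{n - b}:{b}": Fraction(0) for b in range(n // 2, -1, -1)
    }
    denom = 2**n_uni_units
    for k in range(n_uni_units + 1):  # k univalent units to pole 0
        c0 = n_biv + k
        a, b = max(c0, n - c0), min(c0, n - c0)
        patterns[f"{a}:{b}"] += Fraction(comb(n_uni_units, k), denom)
    return PatternDistribution(n_units=n, patterns=patterns)


# ---------------------------------------------------------------------
# Monte Carlo twin
# ---------------------------------------------------------------------


@dataclass
class TetradSample:
    """Sampled tetrads: chromatid counts per (meiosis, entry, homolog, spermatid)."""

    scenario: MeiosisScenario
    counts: np.ndarray  # shape (n, n_entries, 2, 4), integer
    seed: int

    @property
    def n_meioses(self) -> int:
        return self.counts.shape[0]

    def probe_presence(self) -> tuple[np.ndarray, np.ndarray]:
        """Boolean (n, 4) arrays: red / green chromatid present per spermatid."""
        probes = self.scenario.probe_positions()
        if "red" not in probes or "green" not in probes:
            raise ConfigurationError("scenario carries no red/green probe pair")
        (er, hr), (eg, hg) = probes["red"], probes["green"]
        return self.counts[:, er, hr, :] >= 1, self.counts[:, eg, hg, :] >= 1

    def fish_class_frequencies(self) -> dict[str, float]:
        """Empirical per-spermatid class frequencies over all tetrads."""
        red, green = self.probe_presence()
        n = red.size
        return {
            "none": float((~red & ~green).sum()) / n,
            "red_only": float((red & ~green).sum()) / n,
            "green_only": float((~red & green).sum()) / n,
            "both": float((red & green).sum()) / n,
        }

    def dna_contents(self) -> np.ndarray:
        """Per-spermatid DNA content, shape (n, 4): sum of chromatid contents."""
        contents = np.array(
            [[h.dna_content for h in c.homologs] for c in self.scenario.chromosomes]
        )  # (n_entries, 2)
        return np.einsum("nehs,eh->ns", self.counts, contents)

    def mi_pattern_counts(self) -> dict[str, int]:
        """Empirical unordered meiosis I centromere split counts."""
        # a homolog's pole is where its chromatids went (pole 0 = spermatids 0,1)
        at_pole0 = self.counts[:, :, :, :2].sum(axis=3) > 0  # (n, entries, 2)
        c0 = at_pole0.sum(axis=(1, 2))
        n = 2 * len(self.scenario.chromosomes)
        a = np.maximum(c0, n - c0)
        out: dict[str, int] = {}
        for split in range(n // 2, n + 1):
            k = int((a == split).sum())
            if k:
                out[f"{split}:{n - split}"] = k
        return out


def simulate_meioses(
    scenario: MeiosisScenario, n_meioses: int, seed: int
) -> TetradSample:
    """Sample complete meioses; the stochastic twin of :func:`enumerate_meioses`.

    Reproducible for a fixed seed; empirical frequencies converge to the
    exact enumeration as ``n_meioses`` grows.
    """
    scenario.validate()
    if n_meioses < 1:
        raise ValidationError(f"n_meioses must be >= 1, got {n_meioses}")
    rng = np.random.default_rng(seed)
    n_entries = len(scenario.chromosomes)
    counts = np.zeros((n_meioses, n_entries, 2, 4), dtype=np.int8)
    idx = np.arange(n_meioses)
    for e, chrom in enumerate(scenario.chromosomes):
        if chrom.conjunction == "bivalent":
            # fixed orientation, matching the enumerator's convention
            poles = np.tile([0, 1], (n_meioses, 1))
        else:
            poles = rng.integers(0, 2, size=(n_meioses, 2))
        for h in range(2):
            pole = poles[:, h]
            if scenario.mII_rule == "regular_sisters":
                first = np.ones(n_meioses, dtype=np.int8)
            else:
                first = rng.binomial(2, 0.5, size=n_meioses).astype(np.int8)
            counts[idx, e, h, 2 * pole] = first
            counts[idx, e, h, 2 * pole + 1] = 2 - first
    return TetradSample(scenario=scenario, counts=counts, seed=seed)


# ---------------------------------------------------------------------
# DNA-content variability
# ---------------------------------------------------------------------


def dna_content_distribution(
    scenario: MeiosisScenario,
    spermatids_per_cyst: int = 64,
    n_cysts: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Per-cyst s.d. of mean-normalized spermatid DNA contents.

    Each cyst pools ``spermatids_per_cyst / 4`` complete meioses (all four
    spermatids of each tetrad stay together, as in a real cyst).  Every
    nucleus content is divided by its cyst mean before the s.d. is taken,
    mirroring how imaging intensities are normalized cyst by cyst.

    Returns an array of length ``n_cysts`` of sample (n-1) standard
    deviations of the normalized contents.
    """
    if spermatids_per_cyst < 4 or spermatids_per_cyst % 4:
        raise ValidationError(
            "spermatids_per_cyst must be a positive multiple of 4, "
            f"got {spermatids_per_cyst}"
        )
    if n_cysts < 1:
        raise ValidationError(f"n_cysts must be >= 1, got {n_cysts}")
    meioses_per_cyst = spermatids_per_cyst // 4
    sample = simulate_meioses(scenario, meioses_per_cyst * n_cysts, seed)
    contents = sample.dna_contents().reshape(n_cysts, spermatids_per_cyst)
    means = contents.mean(axis=1)
    if np.any(means == 0):
        raise DegenerateInputError("cyst mean DNA content is 0")
    normalized = contents / means[:, None]
    return normalized.std(axis=1, ddof=1)
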