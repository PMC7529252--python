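"""Parameterization of meiosis segregation scenarios.

A scenario lists the homolog pairs of a spermatocyte after pre-meiotic S
phase.  Each :class:`ChromosomeSpec` entry holds the two homologs of one
pair (four chromatids in total).  A pair is either a *bivalent* — the
homologs are conjoined and split 1:1 at anaphase I — or a
*univalent_pair* — conjunction is lost and each homolog segregates to a
meiosis I pole independently, as an intact two-chromatid unit.  Meiosis II
either splits each chromosome's two sister chromatids 1:1 between the two
daughter spermatids (``regular_sisters``) or sends every chromatid
independently to either spermatid with probability 1/2
(``random_chromatids``).

In *Drosophila* males the X and Y are heteromorphic homologs of one pair;
FISH probes are therefore carried by individual homologs (red on X, green
on Y), which is why probes live on :class:`Homolog` rather than on the
pair entry.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

from .errors import ConfigurationError

CONJUNCTIONS = ("bivalent", "univalent_pair")
MII_RULES = ("regular_sisters", "random_chromatids")
PROBES = ("none", "red", "green")

#: Approximate chromosome sizes in Mb, used as relative per-chromatid DNA
#: contents for the default D. melanogaster male karyotype.
DMEL_MB = {"X": 42.0, "Y": 40.0, "2": 48.0, "3": 52.0, "4": 4.3}


@dataclass(frozen=True)
class Homolog:
    """One homologous chromosome (two sister chromatids after S phase)."""

    label: str
    dna_content: float = 1.0
    probe: str = "none"

    def validate(self) -> None:
        if self.dna_content <= 0:
            raise ConfigurationError(
                f"homolog {self.label!r}: dna_content must be > 0, "
                f"got {self.dna_content}"
            )
        if self.probe not in PROBES:
            raise ConfigurationError(
                f"homolog {self.label!r}: unknown probe {self.probe!r}; "
                f"expected one of {PROBES}"
            )


@dataclass(frozen=True)
class ChromosomeSpec:
    """One homolog pair and its conjunction state at meiosis I."""

    name: str
    conjunction: str
    homologs: tuple[Homolog, Homolog]

    @classmethod
    def pair(
        cls,
        name: str,
        conjunction: str = "bivalent",
        dna_content: float = 1.0,
        probes: tuple[str, str] = ("none", "none"),
        dna_contents: tuple[float, float] | None = None,
        labels: tuple[str, str] | None = None,
    ) -> "ChromosomeSpec":
        """Build a pair from shorthand per-pair values."""
        if labels is None:
            labels = (f"{name}a", f"{name}b")
        if dna_contents is None:
            dna_contents = (dna_content, dna_content)
        homologs = (
            Homolog(labels[0], dna_contents[0], probes[0]),
            Homolog(labels[1], dna_contents[1], probes[1]),
        )
        return cls(name=name, conjunction=conjunction, homologs=homologs)

    def validate(self) -> None:
        if self.conjunction not in CONJUNCTIONS:
            raise ConfigurationError(
                f"chromosome {self.name!r}: unknown conjunction "
                f"{self.conjunction!r}; expected one of {CONJUNCTIONS}"
            )
        if len(self.homologs) != 2:
            raise ConfigurationError(
                f"chromosome {self.name!r}: a pair needs exactly 2 homologs"
            )
        for h in self.homologs:
            h.validate()


@dataclass(frozen=True)
class MeiosisScenario:
    """Complete parameterization of one meiotic segregation model."""

    chromosomes: tuple[ChromosomeSpec, ...]
    mII_rule: str = "regular_sisters"
    name: str = "scenario"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 1 <= len(self.chromosomes) <= 8:
            raise ConfigurationError(
                f"scenario must have 1-8 chromosome entries, "
                f"got {len(self.chromosomes)}"
            )
        if self.mII_rule not in MII_RULES:
            raise ConfigurationError(
                f"unknown mII_rule {self.mII_rule!r}; expected one of {MII_RULES}"
            )
        seen: dict[str, str] = {}
        for chrom in self.chromosomes:
            chrom.validate()
            for h in chrom.homologs:
                if h.probe == "none":
                    continue
                if h.probe in seen:
                    raise ConfigurationError(
                        f"probe {h.probe!r} assigned to both {seen[h.probe]!r} "
                        f"and {h.label!r}; at most one chromosome may carry "
                        f"each probe color"
                    )
                seen[h.probe] = h.label

    # -- probe lookup -------------------------------------------------

    def probe_positions(self) -> dict[str, tuple[int, int]]:
        """Map probe color -> (entry index, homolog index)."""
        out: dict[str, tuple[int, int]] = {}
        for e, chrom in enumerate(self.chromosomes):
            for h, hom in enumerate(chrom.homologs):
                if hom.probe != "none":
                    out[hom.probe] = (e, h)
        return out

    # -- serialization -----------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "mII_rule": self.mII_rule,
            "chromosomes": [
                {
                    "name": c.name,
                    "conjunction": c.conjunction,
                    "homologs": [
                        {
                            "label": h.label,
                            "dna_content": h.dna_content,
                            "probe": h.probe,
                        }
                        for h in c.homologs
                    ],
                }
                for c in self.chromosomes
            ],
        }

    def hash(self) -> str:
        """Short content hash used to stamp output tables."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------
# Canonical scenarios
# ---------------------------------------------------------------------


def _xy_entry(conjunction: str, x_content: float, y_content: float) -> ChromosomeSpec:
    return ChromosomeSpec.pair(
        "XY",
        conjunction=conjunction,
        probes=("red", "green"),
        dna_contents=(x_content, y_content),
        labels=("X", "Y"),
    )


def xy_univalent_scenario(
    mII_rule: str = "regular_sisters",
    x_content: float = 1.0,
    y_content: float = 1.0,
) -> MeiosisScenario:
    """X and Y univalents segregating randomly and intact at meiosis I.

    This is the scenario behind the 0/RG diagnostic: the red probe marks
    the X, the green probe the Y, and the meiosis II rule selects between
    the two competing models of sister segregation.
    """
    return MeiosisScenario(
        chromosomes=(_xy_entry("univalent_pair", x_content, y_content),),
        mII_rule=mII_rule,
        name=f"xy_univalent_{mII_rule}",
    )


def wild_type_scenario(unit_contents: bool = False) -> MeiosisScenario:
    """Full male karyotype, all pairs bivalent, regular sister segregation."""
    c = (lambda _k: 1.0) if unit_contents else DMEL_MB.__getitem__
    return MeiosisScenario(
        chromosomes=(
            _xy_entry("bivalent", c("X"), c("Y")),
            ChromosomeSpec.pair("2", "bivalent", c("2")),
            ChromosomeSpec.pair("3", "bivalent", c("3")),
            ChromosomeSpec.pair("4", "bivalent", c("4")),
        ),
        mII_rule="regular_sisters",
        name="wild_type",
    )


def conjunction_null_scenario(
    mII_rule: str = "regular_sisters", unit_contents: bool = False
) -> MeiosisScenario:
    """All four pairs univalent — loss of homolog conjunction genome-wide.

    Eight centromere-bearing units segregate independently at meiosis I,
    the condition behind the 4:4 / 5:3 / 6:2 / 7:1 / 8:0 pattern spectrum.
    """
    c = (lambda _k: 1.0) if unit_contents else DMEL_MB.__getitem__
    return MeiosisScenario(
        chromosomes=(
            _xy_entry("univalent_pair", c("X"), c("Y")),
            ChromosomeSpec.pair("2", "univalent_pair", c("2")),
            ChromosomeSpec.pair("3", "univalent_pair", c("3")),
            ChromosomeSpec.pair("4", "univalent_pair", c("4")),
        ),
        mII_rule=mII_rule,
        name=f"conjunction_null_{mII_rule}",
    )


def autosome_univalent_scenario() -> MeiosisScenario:
    """Three bivalents plus one univalent autosome pair.

    Models a genotype that loses conjunction of a single large autosome
    while the other pairs stay conjoined.
    """
    return MeiosisScenario(
        chromosomes=(
            _xy_entry("bivalent", DMEL_MB["X"], DMEL_MB["Y"]),
            ChromosomeSpec.pair("2", "univalent_pair", DMEL_MB["2"]),
            ChromosomeSpec.pair("3", "bivalent", DMEL_MB["3"]),
            ChromosomeSpec.pair("4", "bivalent", DMEL_MB["4"]),
        ),
        mII_rule="regular_sisters",
        name="autosome_univalent",
    )


BUILTIN_SCENARIOS = {
    "wild_type": wild_type_scenario,
    "xy_univalent_regular": lambda: xy_univalent_scenario("regular_sisters"),
    "xy_univalent_random": lambda: xy_univalent_scenario("random_chromatids"),
    "conjunction_null": conjunction_null_scenario,
    "autosome_univalent": autosome_univalent_scenario,
}
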