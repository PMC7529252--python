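"""Classification and aggregation of per-nucleus FISH signal counts.

Input is a table with one row per spermatid nucleus giving the number of
red (chr X probe) and green (chr Y probe) spots.  Nuclei are classified
into four scored classes — ``none``, ``red_only``, ``green_only``,
``both`` — plus an ``unscored_multisignal`` bin for nuclei with two or
more spots of one color and none of the other, which cannot be scored
reliably (two same-color spots are often not resolved) and are excluded
from all fractions.

The per-cyst 0/RG ratio (zero-signal nuclei over both-signal nuclei) is
the diagnostic statistic: it separates regular from random sister
segregation at meiosis II once meiosis I is random.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedRatioError, ValidationError

SCORED_CLASSES = ("none", "red_only", "green_only", "both")
UNSCORED = "unscored_multisignal"

FISH_COLUMNS = ("cyst_id", "nucleus_id", "red_count", "green_count")


@dataclass(frozen=True)
class NucleusRecord:
    """FISH spot counts of a single spermatid nucleus."""

    cyst_id: str
    nucleus_id: str
    red_count: int
    green_count: int


def classify_nucleus(record) -> str:
    """Assign a FISH class to one nucleus.

    Accepts a :class:`NucleusRecord` or any object with ``red_count`` and
    ``green_count`` attributes.  Nuclei with >= 2 spots of one color and
    none of the other are ``unscored_multisignal``; a nucleus with at
    least one spot of each color is ``both`` regardless of multiplicity
    (presence-based scoring).
    """
    r, g = int(record.red_count), int(record.green_count)
    if r < 0 or g < 0:
        raise ValidationError(f"negative signal counts ({r}, {g})")
    if r >= 1 and g >= 1:
        return "both"
    if (r >= 2 and g == 0) or (g >= 2 and r == 0):
        return UNSCORED
    if r == 1:
        return "red_only"
    if g == 1:
        return "green_only"
    return "none"


def classify_table(table: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`classify_nucleus` over a FISH count table."""
    missing = [c for c in FISH_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"FISH table is missing columns {missing}")
    r = table["red_count"].to_numpy()
    g = table["green_count"].to_numpy()
    if (r < 0).any() or (g < 0).any():
        raise ValidationError("negative signal counts in FISH table")
    cls = np.select(
        [
            (r >= 1) & (g >= 1),
            ((r >= 2) & (g == 0)) | ((g >= 2) & (r == 0)),
            (r == 1) & (g == 0),
            (g == 1) & (r == 0),
        ],
        ["both", UNSCORED, "red_only", "green_only"],
        default="none",
    )
    out = table.copy()
    out["fish_class"] = cls
    return out


@dataclass(frozen=True)
class CystFishSummary:
    """Class fractions and the 0/RG ratio of one spermatid cyst."""

    cyst_id: str
    n_scored: int
    n_unscored_multisignal: int
    fractions: dict[str, float]  # over scored nuclei, keys SCORED_CLASSES
    counts: dict[str, int]

    @property
    def zero_to_rg(self) -> float:
        if self.counts["both"] == 0:
            raise UndefinedRatioError(
                f"cyst {self.cyst_id!r}: 0/RG undefined (no both-signal nuclei)"
            )
        return self.counts["none"] / self.counts["both"]

    @property
    def zero_to_rg_defined(self) -> bool:
        return self.counts["both"] > 0

    @property
    def abnormal_fraction(self) -> float:
        """Fraction of scored nuclei with abnormal signals (none or both)."""
        return self.fractions["none"] + self.fractions["both"]


def summarize_cyst(records: pd.DataFrame) -> CystFishSummary:
    """Summarize all nuclei of one cyst into class fractions and 0/RG."""
    if len(records) == 0:
        raise ValidationError("empty cyst: no nuclei to summarize")
    cyst_ids = records["cyst_id"].unique()
    if len(cyst_ids) != 1:
        raise ValidationError(
            f"summarize_cyst expects a single cyst, got {list(cyst_ids)}"
        )
    classified = classify_table(records)
    counts = {c: int((classified["fish_class"] == c).sum()) for c in SCORED_CLASSES}
    n_unscored = int((classified["fish_class"] == UNSCORED).sum())
    n_scored = sum(counts.values())
    if n_scored == 0:
        raise ValidationError(
            f"cyst {cyst_ids[0]!r}: no scorable nuclei "
            f"({n_unscored} unscored multi-signal)"
        )
    fractions = {c: counts[c] / n_scored for c in SCORED_CLASSES}
    return CystFishSummary(
        cyst_id=str(cyst_ids[0]),
        n_scored=n_scored,
        n_unscored_multisignal=n_unscored,
        fractions=fractions,
        counts=counts,
    )


def summarize_by_cyst(table: pd.DataFrame) -> list[CystFishSummary]:
    """Summaries for every cyst in a FISH count table, in order of appearance."""
    return [
        summarize_cyst(group)
        for _, group in table.groupby("cyst_id", sort=False)
    ]


def summaries_to_frame(summaries: list[CystFishSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {
            "cyst_id": s.cyst_id,
            "n_scored": s.n_scored,
            "n_unscored_multisignal": s.n_unscored_multisignal,
            **{f"frac_{c}": s.fractions[c] for c in SCORED_CLASSES},
            "abnormal_fraction": s.abnormal_fraction,
            "zero_to_rg": s.zero_to_rg if s.zero_to_rg_defined else math.nan,
            "zero_to_rg_defined": s.zero_to_rg_defined,
        }
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GenotypeFishSummary:
    """Cross-cyst mean +/- s.d. of the FISH statistics of one genotype."""

    n_cysts: int
    abnormal_mean: float
    abnormal_sd: float
    zero_to_rg_mean: float
    zero_to_rg_sd: float
    n_cysts_rg_defined: int
    n_cysts_rg_undefined: int


def aggregate_genotype(summaries: list[CystFishSummary]) -> GenotypeFishSummary:
    """Average per-cyst statistics across the cysts of one genotype.

    Sample (n-1) standard deviations are used throughout, appropriate
    for the small cyst numbers typical of these experiments (10-15 per
    genotype).  Cysts whose 0/RG is undefined (no both-signal nuclei)
    are excluded from the ratio aggregate and counted separately, never
    imputed.
    """
    if len(summaries) < 2:
        raise ValidationError(
            f"need >= 2 cysts to aggregate, got {len(summaries)}"
        )
    abnormal = np.array([s.abnormal_fraction for s in summaries])
    rg = np.array([s.zero_to_rg for s in summaries if s.zero_to_rg_defined])
    n_undef = sum(1 for s in summaries if not s.zero_to_rg_defined)
    if rg.size == 0:
        raise UndefinedRatioError(
            "0/RG undefined in every cyst; cannot aggregate the ratio"
        )
    return GenotypeFishSummary(
        n_cysts=len(summaries),
        abnormal_mean=float(abnormal.mean()),
        abnormal_sd=float(abnormal.std(ddof=1)),
        zero_to_rg_mean=float(rg.mean()),
        zero_to_rg_sd=float(rg.std(ddof=1)) if rg.size > 1 else math.nan,
        n_cysts_rg_defined=int(rg.size),
        n_cysts_rg_undefined=n_undef,
    )
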