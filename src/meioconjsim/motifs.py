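"""Separase cleavage-site and docking-motif scanning in protein sequences.

Separase cleaves its substrates after the arginine of an [E/D]XXR
consensus (X = any residue); a separate docking motif, [L/V/I/M]PE,
enhances cleavage of some substrates.  This module finds all matches of
either motif, applies the in-silico "non-cleavable" mutation (both anchor
residues of a cleavage site to alanine, the E130A/R133A design), and
scores per-column conservation of a hit across a multiple alignment —
the signature of a functional site inside an otherwise divergent linker.

Coordinates are 1-based in all reports, matching the E130/R133 residue
numbering convention.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
WILDCARD = "X"
GAP_CHARS = {"-", "."}

#: motif name -> tuple of allowed residue sets per position (None = any)
MOTIF_PATTERNS: dict[str, tuple[frozenset | None, ...]] = {
    "cleavage_ExxR": (frozenset("ED"), None, None, frozenset("R")),
    "docking_LVIMPE": (frozenset("LVIM"), frozenset("P"), frozenset("E")),
}


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence; gaps are allowed only in aligned records."""

    id: str
    sequence: str

    def ungapped(self) -> "ProteinRecord":
        seq = "".join(c for c in self.sequence if c not in GAP_CHARS)
        return ProteinRecord(id=self.id, sequence=seq)


@dataclass(frozen=True)
class MotifHit:
    """One motif match: 1-based start, matched residues, scissile position."""

    motif_name: str
    start: int
    matched_text: str
    cleavage_position: int | None = None  # position after the R, cleavage only


def _validate_sequence(seq: str, allow_gaps: bool = False) -> str:
    seq = seq.upper()
    allowed = AMINO_ACIDS | {WILDCARD} | (GAP_CHARS if allow_gaps else set())
    bad = sorted(set(seq) - allowed)
    if bad:
        raise ValidationError(f"invalid residues in sequence: {bad}")
    return seq


def scan_motif(record: ProteinRecord, motif_name: str) -> list[MotifHit]:
    """All (overlapping) matches of a motif, left to right, 1-based.

    The anchor positions of a motif must match literally; an ``X``
    wildcard residue in the sequence satisfies only the "any residue"
    positions, never an anchor.  An empty sequence yields no hits.
    """
    if motif_name not in MOTIF_PATTERNS:
        raise ValidationError(
            f"unknown motif {motif_name!r}; expected one of "
            f"{sorted(MOTIF_PATTERNS)}"
        )
    seq = _validate_sequence(record.sequence)
    pattern = MOTIF_PATTERNS[motif_name]
    width = len(pattern)
    hits: list[MotifHit] = []
    for i in range(len(seq) - width + 1):
        window = seq[i : i + width]
        if all(
            allowed is None or window[j] in allowed
            for j, allowed in enumerate(pattern)
        ):
            hits.append(
                MotifHit(
                    motif_name=motif_name,
                    start=i + 1,
                    matched_text=window,
                    cleavage_position=(
                        i + width + 1 if motif_name == "cleavage_ExxR" else None
                    ),
                )
            )
    return hits


def scan_all_motifs(record: ProteinRecord) -> list[MotifHit]:
    """Cleavage and docking hits of one sequence, cleavage first."""
    return [
        hit for name in MOTIF_PATTERNS for hit in scan_motif(record, name)
    ]


def apply_site_mutation(record: ProteinRecord, hit: MotifHit) -> ProteinRecord:
    """Mutate both anchors of a cleavage site to alanine (non-cleavable).

    The acidic residue at ``hit.start`` and the arginine at
    ``hit.start + 3`` become A, abolishing the consensus match at that
    position while leaving the rest of the sequence untouched.  The
    operation is idempotent on an already-mutated site.
    """
    if hit.motif_name != "cleavage_ExxR":
        raise ValidationError(
            f"site mutation applies to cleavage hits, not {hit.motif_name!r}"
        )
    seq = list(_validate_sequence(record.sequence))
    i = hit.start - 1
    if i < 0 or i + 3 >= len(seq):
        raise ValidationError(
            f"hit at position {hit.start} is out of range for a "
            f"{len(seq)}-residue sequence"
        )
    seq[i] = "A"
    seq[i + 3] = "A"
    return ProteinRecord(id=record.id, sequence="".join(seq))


def map_to_alignment_columns(aligned_seq: str, positions: list[int]) -> list[int]:
    """Map 1-based ungapped residue positions to 0-based alignment columns."""
    cols = [i for i, c in enumerate(aligned_seq) if c not in GAP_CHARS]
    out = []
    for p in positions:
        if not 1 <= p <= len(cols):
            raise ValidationError(
                f"residue position {p} outside the ungapped sequence "
                f"({len(cols)} residues)"
            )
        out.append(cols[p - 1])
    return out


def column_conservation(
    alignment: list[ProteinRecord], reference_id: str, hit: MotifHit
) -> list[float]:
    """Per-column identity of a motif hit across an alignment.

    ``hit`` is given in ungapped coordinates of the reference sequence;
    its positions are mapped through the reference's gaps to alignment
    columns.  For each motif column the returned fraction is the share
    of non-gap rows (reference included) carrying the reference residue.
    """
    by_id = {r.id: r for r in alignment}
    if reference_id not in by_id:
        raise ValidationError(f"reference {reference_id!r} not in alignment")
    lengths = {len(r.sequence) for r in alignment}
    if len(lengths) != 1:
        raise ValidationError("alignment rows have unequal lengths")
    ref = _validate_sequence(by_id[reference_id].sequence, allow_gaps=True)
    width = len(hit.matched_text)
    cols = map_to_alignment_columns(ref, list(range(hit.start, hit.start + width)))
    fractions = []
    for k, col in enumerate(cols):
        ref_res = ref[col]
        assert ref_res not in GAP_CHARS, "hit mapped into a reference gap"
        assert ref_res == hit.matched_text[k], (
            "hit text does not match the reference sequence"
        )
        residues = [
            _validate_sequence(r.sequence, allow_gaps=True)[col]
            for r in alignment
        ]
        non_gap = [c for c in residues if c not in GAP_CHARS]
        fractions.append(
            sum(1 for c in non_gap if c == ref_res) / len(non_gap)
        )
    return fractions


def conserved_cleavage_hits(
    alignment: list[ProteinRecord],
    reference_id: str,
    min_conservation: float = 0.9,
) -> list[tuple[MotifHit, list[float]]]:
    """Cleavage hits in the reference whose columns are all well conserved.

    Scans the ungapped reference, scores each hit across the alignment,
    and keeps those with every motif column at or above
    ``min_conservation`` — the criterion that singles out a functional
    site within a divergent linker.
    """
    by_id = {r.id: r for r in alignment}
    if reference_id not in by_id:
        raise ValidationError(f"reference {reference_id!r} not in alignment")
    ref = by_id[reference_id].ungapped()
    out = []
    for hit in scan_motif(ref, "cleavage_ExxR"):
        cons = column_conservation(alignment, reference_id, hit)
        if min(cons) >= min_conservation:
            out.append((hit, cons))
    return out
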