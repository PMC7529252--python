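"""Seeded synthetic-data generators standing in for fly work and microscopy.

Every generator is deterministic given (parameters, seed) and records its
ground truth, so each downstream operator can be tested for exact
recovery at zero noise and for statistical convergence with noise:

* :func:`gen_fish_table` — per-nucleus FISH spot counts whose class
  frequencies follow a segregation scenario (13 cysts of 64 spermatids
  by default, the scale of the real FISH experiments);
* :func:`gen_cyst_image` — a cyst of round nuclei rendered as uniform
  disks whose pixel sums equal the scenario's DNA contents, with
  optional touching pairs, blur and background;
* :func:`gen_protein_set` — protein families with conserved terminal
  blocks, a divergent central linker, and a separase cleavage site
  planted in the linker of every member;
* :func:`gen_intensity_trace` — a plateau-then-linear-decay dot
  intensity time course.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk
from skimage.filters import gaussian

from .errors import LayoutError, ValidationError
from .imagequant import CystImage, IntensityTrace
from .model import simulate_meioses
from .motifs import MOTIF_PATTERNS, ProteinRecord, scan_motif
from .scenario import MeiosisScenario

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class GeneratorSpec:
    """Shared knobs of the scenario-driven generators.

    ``intensity_sigma`` is the s.d. of the per-nucleus multiplicative
    lognormal intensity noise (lognormal keeps intensities positive);
    ``detection_dropout`` is the probability that a true FISH signal is
    missed.  Defaults mirror the real experiments: 13 cysts of 64
    spermatids, noise-free detection.
    """

    scenario: MeiosisScenario
    n_cysts: int = 13
    nuclei_per_cyst: int = 64
    intensity_sigma: float = 0.05
    background: float = 0.0
    detection_dropout: float = 0.0
    chromatid_resolved: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.detection_dropout <= 1:
            raise ValidationError("detection_dropout must be in [0, 1]")
        if self.intensity_sigma < 0:
            raise ValidationError("intensity_sigma must be >= 0")
        if self.nuclei_per_cyst < 4 or self.nuclei_per_cyst % 4:
            raise ValidationError(
                "nuclei_per_cyst must be a positive multiple of 4 "
                "(nuclei are pooled tetrads)"
            )
        if self.n_cysts < 1:
            raise ValidationError("n_cysts must be >= 1")


# ---------------------------------------------------------------------
# FISH count tables
# ---------------------------------------------------------------------


def gen_fish_table(spec: GeneratorSpec) -> pd.DataFrame:
    """Synthetic per-nucleus FISH count table for a scenario.

    Signals are presence-based by default (one spot per present probed
    chromosome, as scored in practice); with ``chromatid_resolved=True``
    each chromatid yields its own spot, exercising the
    unscored-multisignal path.  Dropout thins every spot independently.
    """
    rng = np.random.default_rng(spec.seed)
    probes = spec.scenario.probe_positions()
    if "red" not in probes or "green" not in probes:
        raise ValidationError("scenario must carry red and green probes")
    n_meioses = spec.n_cysts * spec.nuclei_per_cyst // 4
    sample = simulate_meioses(
        spec.scenario, n_meioses, int(rng.integers(0, 2**31))
    )
    (er, hr), (eg, hg) = probes["red"], probes["green"]
    red = sample.counts[:, er, hr, :].astype(int)  # (n, 4) chromatid counts
    green = sample.counts[:, eg, hg, :].astype(int)
    if not spec.chromatid_resolved:
        red = (red >= 1).astype(int)
        green = (green >= 1).astype(int)
    if spec.detection_dropout > 0:
        red = rng.binomial(red, 1 - spec.detection_dropout)
        green = rng.binomial(green, 1 - spec.detection_dropout)
    red = red.reshape(spec.n_cysts, spec.nuclei_per_cyst)
    green = green.reshape(spec.n_cysts, spec.nuclei_per_cyst)
    rows = []
    for c in range(spec.n_cysts):
        for i in range(spec.nuclei_per_cyst):
            rows.append(
                {
                    "cyst_id": f"cyst{c + 1:03d}",
                    "nucleus_id": f"n{i + 1:03d}",
                    "red_count": int(red[c, i]),
                    "green_count": int(green[c, i]),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# Cyst images
# ---------------------------------------------------------------------


@dataclass
class SyntheticCyst:
    """A rendered cyst image plus its ground truth."""

    image: CystImage
    labels: np.ndarray  # true label map, one label per nucleus
    truth: pd.DataFrame  # per-nucleus centers, contents, planted intensity sums


def gen_cyst_image(
    spec: GeneratorSpec,
    radius_um: float = 1.8,
    min_separation_um: float = 1.5,
    touching_fraction: float = 0.0,
    pixel_size_um: float = 0.16,
    intensity_scale: float = 1000.0,
    blur_sigma_px: float = 0.0,
    image_size: int | None = None,
    contents: np.ndarray | None = None,
    cyst_index: int = 0,
) -> SyntheticCyst:
    """Render one cyst of round nuclei as uniform disks.

    Nuclei are laid out on a jittered grid so that non-touching nuclei
    keep at least ``min_separation_um`` edge distance; a
    ``touching_fraction`` of nuclei is placed as tangent pairs to
    exercise the watershed.  Each nucleus's pixel sum equals its
    (noise-perturbed) DNA content times ``intensity_scale`` exactly, so
    integrated intensities are recoverable to machine precision at zero
    noise, blur and background.

    DNA contents come from complete simulated meioses of the scenario
    unless ``contents`` overrides them.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, cyst_index]))
    n = spec.nuclei_per_cyst
    if contents is None:
        sample = simulate_meioses(
            spec.scenario, n // 4, int(rng.integers(0, 2**31))
        )
        contents = sample.dna_contents().reshape(-1)
    contents = np.asarray(contents, float)
    if contents.size != n:
        raise ValidationError(
            f"contents has {contents.size} entries, expected {n}"
        )

    r_px = radius_um / pixel_size_um
    sep_px = min_separation_um / pixel_size_um
    n_pairs = int(round(touching_fraction * n / 2))
    n_units = n - n_pairs  # a tangent pair occupies one layout unit

    # one grid cell per unit; pairs extend ~4 radii along x
    pitch = int(math.ceil(4 * r_px + sep_px))
    grid = int(math.ceil(math.sqrt(n_units)))
    margin = int(math.ceil(2 * r_px + sep_px))
    needed = grid * pitch + 2 * margin
    if image_size is None:
        image_size = needed
    elif image_size < needed:
        raise LayoutError(
            f"cannot pack {n} nuclei of radius {radius_um} um into a "
            f"{image_size}-px field (need >= {needed} px)"
        )

    jitter = max(0.0, (pitch - 2 * r_px - sep_px) / 2 - 1)
    centers: list[tuple[float, float]] = []
    cells = [(gy, gx) for gy in range(grid) for gx in range(grid)][:n_units]
    unit_of: list[int] = []  # layout unit index per nucleus
    for u, (gy, gx) in enumerate(cells):
        cy = margin + gy * pitch + pitch / 2 + rng.uniform(-jitter, jitter)
        cx = margin + gx * pitch + pitch / 2 + rng.uniform(-jitter, jitter)
        if u < n_pairs:
            # tangent pair: centers 2 r apart so the disks touch
            centers.append((cy, cx - r_px))
            centers.append((cy, cx + r_px))
            unit_of += [u, u]
        else:
            centers.append((cy, cx))
            unit_of.append(u)

    noisy = contents * (
        rng.lognormal(0.0, spec.intensity_sigma, size=n)
        if spec.intensity_sigma > 0
        else 1.0
    )
    image = np.zeros((image_size, image_size), float)
    labels = np.zeros((image_size, image_size), np.int32)
    rows = []
    for i, (cy, cx) in enumerate(centers):
        rr, cc = draw_disk((cy, cx), r_px, shape=image.shape)
        total = noisy[i] * intensity_scale
        image[rr, cc] += total / rr.size
        labels[rr, cc] = i + 1
        rows.append(
            {
                "nucleus_id": i + 1,
                "center_y": cy,
                "center_x": cx,
                "radius_px": r_px,
                "area_um2": rr.size * pixel_size_um**2,
                "content": contents[i],
                "integrated_intensity": total,
                "layout_unit": unit_of[i],
                "touching": unit_of[i] < n_pairs,
            }
        )
    if blur_sigma_px > 0:
        image = gaussian(image, sigma=blur_sigma_px, preserve_range=True)
    if spec.background != 0:
        image = image + spec.background
    return SyntheticCyst(
        image=CystImage(pixels=image, pixel_size_um=pixel_size_um),
        labels=labels,
        truth=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------
# Protein families with planted motifs
# ---------------------------------------------------------------------


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def _block_without_motifs(rng: np.random.Generator, length: int) -> str:
    """A random peptide containing no cleavage or docking match."""
    for _ in range(200):
        block = _random_peptide(rng, length)
        rec = ProteinRecord("tmp", block)
        if not any(scan_motif(rec, m) for m in MOTIF_PATTERNS):
            return block
    raise RuntimeError("could not sample a motif-free block")  # pragma: no cover


def gen_protein_set(
    n_sequences: int = 8,
    linker_divergence: float = 0.5,
    seed: int = 0,
    block_len: int = 40,
    linker_len: int = 60,
    plant_docking: bool = False,
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """A protein family with a cleavage site planted in a divergent linker.

    Emulates the architecture of the conjunction proteins: N- and
    C-terminal blocks conserved across all members, a central linker
    diverged at ``linker_divergence`` per position, and an [E/D]XXR site
    written into the linker of every member at the same (alignment)
    position.  Because the family is generated without indels the
    records double as their own multiple alignment.

    Returns the records and a truth table of planted motif positions.
    """
    if n_sequences < 1:
        raise ValidationError("n_sequences must be >= 1")
    if not 0 <= linker_divergence <= 1:
        raise ValidationError("linker_divergence must be in [0, 1]")
    min_linker = 4 + (3 if plant_docking else 0) + 2
    if linker_len < min_linker:
        raise ValidationError(f"linker_len must be >= {min_linker}")
    rng = np.random.default_rng(seed)
    n_block = _block_without_motifs(rng, block_len)
    c_block = _block_without_motifs(rng, block_len)
    linker_ref = list(_random_peptide(rng, linker_len))

    cleavage_pos = 1  # 0-based within linker
    motif = "E" + _random_peptide(rng, 2) + "R"
    docking_pos = cleavage_pos + 6
    docking = str(rng.choice(list("LVIM"))) + "PE"

    records, rows = [], []
    for s in range(n_sequences):
        linker = list(linker_ref)
        for j in range(linker_len):
            if rng.random() < linker_divergence:
                choices = [a for a in AA20 if a != linker_ref[j]]
                linker[j] = str(rng.choice(choices))
        linker[cleavage_pos : cleavage_pos + 4] = motif
        if plant_docking:
            linker[docking_pos : docking_pos + 3] = docking
        seq = n_block + "".join(linker) + c_block
        rec = ProteinRecord(id=f"seq{s + 1:02d}", sequence=seq)
        records.append(rec)
        rows.append(
            {
                "id": rec.id,
                "motif_name": "cleavage_ExxR",
                "start": block_len + cleavage_pos + 1,
                "matched_text": motif,
            }
        )
        if plant_docking:
            rows.append(
                {
                    "id": rec.id,
                    "motif_name": "docking_LVIMPE",
                    "start": block_len + docking_pos + 1,
                    "matched_text": docking,
                }
            )
    return records, pd.DataFrame(rows)


# ---------------------------------------------------------------------
# Dot-intensity time courses
# ---------------------------------------------------------------------


def gen_intensity_trace(
    plateau: float = 50.0,
    decay_start_min: float = 2.0,
    decay_duration_min: float = 9.0,
    background: float = 2.0,
    t_start_min: float = -12.0,
    t_end_min: float = 20.0,
    dt_min: float = 0.75,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[IntensityTrace, dict]:
    """Plateau-then-linear-decay dot intensity trace.

    Defaults emulate the anaphase I disappearance of a conjunction
    protein dot: a stable plateau, then decay to background over about
    nine minutes, sampled at the 45-s frame interval of the time-lapse
    recordings.  Additive Gaussian noise with s.d.
    ``noise_sigma * plateau`` is applied when requested.
    """
    if plateau <= background:
        raise ValidationError("plateau must exceed background")
    t_decay_end = decay_start_min + decay_duration_min
    if decay_start_min < t_start_min or t_decay_end > t_end_min:
        raise ValidationError("decay interval must lie within the trace span")
    rng = np.random.default_rng(seed)
    times = np.arange(t_start_min, t_end_min + dt_min / 2, dt_min)
    values = np.where(
        times <= decay_start_min,
        plateau,
        np.where(
            times >= t_decay_end,
            background,
            plateau
            + (background - plateau) * (times - decay_start_min) / decay_duration_min,
        ),
    ).astype(float)
    if noise_sigma > 0:
        values = values + rng.normal(0, noise_sigma * plateau, size=values.size)
    truth = {
        "plateau": plateau,
        "decay_start_min": decay_start_min,
        "decay_duration_min": decay_duration_min,
        "background": background,
    }
    return IntensityTrace(times_min=times, intensities=values), truth
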