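"""Spermatid DNA-content quantification from cyst images.

Re-implements, as composable operators, the measurement chain used to
quantify DNA staining in round-spermatid cysts:

1. maximum-intensity projection of the stack;
2. min-max rescale of the intensities within the region of interest
   (the effect of resetting the display histogram before thresholding);
3. local-mean auto threshold (circular neighborhood, default radius
   15 px, optional constant offset);
4. watershed on the distance transform to split touching nuclei;
5. particle filter on area (default 1-25 um^2) and circularity
   (default 0.70-1.00, circularity = 4*pi*area/perimeter^2);
6. per-image QC: if more than 10% of the expected nuclei were missed
   the image is discarded;
7. integrated DNA-stain intensity per retained nucleus, normalized by
   the cyst mean; the s.d. of the normalized values is the per-cyst
   DNA-content variability statistic.

Also contains the time-lapse dot-intensity normalization (mean of the
ten brightest time points set to 100 a.u.).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from scipy.signal import fftconvolve
from skimage.measure import label as sk_label, regionprops
from skimage.morphology import disk, h_maxima
from skimage.segmentation import watershed

from .errors import DegenerateInputError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class CystImage:
    """A calibrated cyst image (single plane or z-stack).

    ``roi`` restricts analysis to the manually outlined cyst;
    ``exclusion_mask`` marks regions (e.g. cyst-cell nuclei) whose
    objects must be dropped, replacing interactive deletion.
    """

    pixels: np.ndarray
    pixel_size_um: float
    roi: np.ndarray | None = None
    exclusion_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValidationError(
                f"pixel_size_um must be > 0, got {self.pixel_size_um}"
            )
        if self.pixels.ndim not in (2, 3):
            raise ValidationError(
                f"expected a 2-D image or 3-D stack, got ndim={self.pixels.ndim}"
            )
        plane_shape = self.pixels.shape[-2:]
        for name in ("roi", "exclusion_mask"):
            m = getattr(self, name)
            if m is not None and m.shape != plane_shape:
                raise ValidationError(
                    f"{name} shape {m.shape} does not match plane {plane_shape}"
                )

    def projected(self) -> np.ndarray:
        """Maximum-intensity projection (identity for a single plane)."""
        if self.pixels.ndim == 3:
            return self.pixels.max(axis=0)
        return self.pixels


@dataclass
class QuantConfig:
    """Parameters of the segmentation and filtering chain.

    Defaults follow the published analysis settings; the local-threshold
    offset and the watershed seed parameters are not specified there and
    are exposed with documented defaults.
    """

    local_radius_px: int = 15
    local_offset: float = 0.0
    min_area_um2: float = 1.0
    max_area_um2: float = 25.0
    min_circularity: float = 0.70
    max_circularity: float = 1.00
    qc_missed_fraction: float = 0.10
    pixel_size_um: float = 0.16
    watershed_min_separation_px: float = 2.0
    watershed_h: float = 1.0  # depth below which distance maxima are merged

    def __post_init__(self) -> None:
        if not 0 < self.min_area_um2 < self.max_area_um2:
            raise ValidationError("need 0 < min_area_um2 < max_area_um2")
        if not (0 <= self.min_circularity <= self.max_circularity <= 1):
            raise ValidationError("circularity bounds must satisfy 0 <= lo <= hi <= 1")


@dataclass(frozen=True)
class NucleusMeasurement:
    """Shape and intensity measurements of one segmented nucleus."""

    label_id: int
    area_um2: float
    circularity: float
    integrated_intensity: float
    centroid: tuple[float, float] = (0.0, 0.0)


#: tolerance added to the local-mean comparison; absorbs the ~1e-16
#: numerical noise of the FFT convolution on a [0, 1]-rescaled image
_THRESHOLD_EPS = 1e-9


def _local_mean(image: np.ndarray, radius: int) -> np.ndarray:
    """Mean over a circular neighborhood, zero-padded at the borders."""
    kernel = disk(radius).astype(float)
    kernel /= kernel.sum()
    return fftconvolve(image, kernel, mode="same")


def _watershed_markers(distance: np.ndarray, config: QuantConfig) -> np.ndarray:
    """Seed labels from regional maxima of the distance transform.

    Regional maxima shallower than ``watershed_h`` are suppressed (this
    makes plateaus of the discrete distance transform yield a single
    seed), then seeds whose centroids are closer than
    ``watershed_min_separation_px`` are merged.
    """
    peaks = h_maxima(distance, config.watershed_h)
    markers = sk_label(peaks)
    n = markers.max()
    if n > 1 and config.watershed_min_separation_px > 0:
        centroids = np.array(ndi.center_of_mass(peaks, markers, range(1, n + 1)))
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if (
                    np.hypot(*(centroids[i] - centroids[j]))
                    < config.watershed_min_separation_px
                ):
                    parent[find(j)] = find(i)
        remap = np.zeros(n + 1, dtype=np.int32)
        roots = {}
        for i in range(n):
            r = find(i)
            roots.setdefault(r, len(roots) + 1)
            remap[i + 1] = roots[r]
        markers = remap[markers]
    return markers


def _measure(
    labels: np.ndarray, intensity: np.ndarray, pixel_size_um: float
) -> list[NucleusMeasurement]:
    out = []
    for prop in regionprops(labels, intensity_image=intensity):
        area = prop.area * pixel_size_um**2
        perim = prop.perimeter
        circ = 4 * np.pi * prop.area / perim**2 if perim > 0 else 0.0
        circ = min(circ, 1.0)  # discretization can push a disk above 1
        out.append(
            NucleusMeasurement(
                label_id=prop.label,
                area_um2=float(area),
                circularity=float(circ),
                integrated_intensity=float(
                    intensity[prop.slice][prop.image].sum()
                ),
                centroid=tuple(float(c) for c in prop.centroid),
            )
        )
    return out


def segment_nuclei(
    image: CystImage,
    config: QuantConfig | None = None,
    apply_filter: bool = True,
) -> tuple[np.ndarray, list[NucleusMeasurement]]:
    """Segment round spermatid nuclei and measure them.

    Returns the label map and the measurements of the retained labels.
    With ``apply_filter=True`` (default) the area/circularity particle
    filter is applied and rejected objects are removed from the label
    map; pass ``False`` to obtain all raw objects.

    A zero-dynamic-range image yields an empty result with a logged
    warning rather than an error; an empty ROI is a validation error.
    """
    if config is None:
        config = QuantConfig()
    plane = image.projected().astype(float)
    roi = image.roi if image.roi is not None else np.ones(plane.shape, bool)
    roi = roi.astype(bool)
    if not roi.any():
        raise ValidationError("ROI is empty")

    vmin = plane[roi].min()
    vmax = plane[roi].max()
    if vmax == vmin:
        logger.warning("zero dynamic range within ROI; no nuclei segmented")
        return np.zeros(plane.shape, dtype=np.int32), []
    rescaled = np.clip((plane - vmin) / (vmax - vmin), 0.0, 1.0)
    rescaled[~roi] = 0.0

    local_mean = _local_mean(rescaled, config.local_radius_px)
    foreground = (
        rescaled > local_mean - config.local_offset + _THRESHOLD_EPS
    ) & roi
    if image.exclusion_mask is not None:
        foreground &= ~image.exclusion_mask.astype(bool)

    distance = ndi.distance_transform_edt(foreground)
    markers = _watershed_markers(distance, config)
    labels = watershed(-distance, markers, mask=foreground).astype(np.int32)

    measurements = _measure(labels, plane, image.pixel_size_um)
    if apply_filter:
        measurements = particle_filter(measurements, config)
        keep = np.zeros(labels.max() + 1, dtype=bool)
        for m in measurements:
            keep[m.label_id] = True
        labels = np.where(keep[labels], labels, 0)
    return labels, measurements


def particle_filter(
    measurements: list[NucleusMeasurement], config: QuantConfig
) -> list[NucleusMeasurement]:
    """Retain objects inside the area and circularity bounds (inclusive)."""
    return [
        m
        for m in measurements
        if config.min_area_um2 <= m.area_um2 <= config.max_area_um2
        and config.min_circularity <= m.circularity <= config.max_circularity
    ]


def qc_check(n_expected: int, n_detected: int, config: QuantConfig) -> bool:
    """Image-level quality control on the detection rate.

    Returns ``True`` (keep) unless more than ``qc_missed_fraction`` of
    the expected nuclei were missed, in which case the image should be
    discarded (``False``).  Extra detections do not count as misses.
    """
    if n_expected <= 0:
        raise ValidationError(f"expected nucleus count must be > 0, got {n_expected}")
    if n_detected < 0:
        raise ValidationError("detected nucleus count must be >= 0")
    missed = max(0, n_expected - n_detected) / n_expected
    return missed <= config.qc_missed_fraction


@dataclass(frozen=True)
class CystVariability:
    """DNA-content variability of one cyst."""

    n_nuclei: int
    normalized_contents: np.ndarray
    sd_normalized: float


def cyst_variability(intensities) -> CystVariability:
    """Per-cyst DNA-content variability statistic.

    Each integrated intensity is divided by the cyst mean and the sample
    (n-1) standard deviation of the normalized values is returned.  The
    statistic is invariant to any global intensity rescaling, so cysts
    imaged at different exposures remain comparable.
    """
    values = np.asarray(
        [
            m.integrated_intensity if isinstance(m, NucleusMeasurement) else m
            for m in intensities
        ],
        dtype=float,
    )
    if values.size < 2:
        raise ValidationError(
            f"need >= 2 nuclei for a variability estimate, got {values.size}"
        )
    mean = values.mean()
    if mean == 0:
        raise DegenerateInputError("cyst mean intensity is 0")
    normalized = values / mean
    return CystVariability(
        n_nuclei=int(values.size),
        normalized_contents=normalized,
        sd_normalized=float(normalized.std(ddof=1)),
    )


# ---------------------------------------------------------------------
# Time-lapse dot intensity traces
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class IntensityTrace:
    """A fluorescence intensity time course (minutes, arbitrary units)."""

    times_min: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, float)
        v = np.asarray(self.intensities, float)
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "intensities", v)
        if t.shape != v.shape or t.ndim != 1:
            raise ValidationError("times and intensities must be equal-length 1-D")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValidationError("time points must be strictly increasing")


def normalize_trace(
    trace: IntensityTrace, nebd_index: int | None = None
) -> IntensityTrace:
    """Scale a dot-intensity trace so its ten brightest points average 100 a.u.

    If ``nebd_index`` is given, times are shifted so that t = 0 at that
    point (by convention the last frame before nuclear envelope
    breakdown).  The output is invariant to any positive rescaling of
    the input intensities.
    """
    n = trace.intensities.size
    if n < 10:
        raise ValidationError(f"need >= 10 time points, got {n}")
    top10 = np.sort(trace.intensities)[-10:]
    scale_base = top10.mean()
    if scale_base <= 0:
        raise DegenerateInputError(
            "top-10 mean intensity is not positive; cannot normalize"
        )
    times = trace.times_min
    if nebd_index is not None:
        if not -n <= nebd_index < n:
            raise ValidationError(
                f"nebd_index {nebd_index} out of range for {n} points"
            )
        times = times - times[nebd_index]
    return IntensityTrace(
        times_min=times,
        intensities=trace.intensities * (100.0 / scale_base),
    )
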