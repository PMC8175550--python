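"""Axial biometry from spectral-domain OCT B-scans.

OCT measures *optical* path length: geometric distance times the refractive
index of the traversed tissue.  To report physical compartment dimensions the
optical extent of each compartment (boundary gap in pixels times the axial
pixel depth) is divided by a tissue-specific scalar refractive index.  Axial
length is defined anatomically as the distance from the apical corneal
epithelium to the anterior border of the retinal pigmented epithelium (RPE),
i.e. the sum of the five compartments cornea, anterior chamber, lens,
vitreous chamber and neural retina.  The RPE itself appears as the brightest
(melanin-rich, hyperreflective) band of the A-scan and its sharp anterior
edge is the posterior landmark for the axial length.

Boundary convention: a boundary pixel belongs to the posterior compartment
(half-open pixel intervals), so compartment extents sum exactly to the
apex-to-RPE pixel gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "COMPARTMENTS",
    "DEFAULT_REFRACTIVE_INDICES",
    "BScan",
    "AxialSegmentation",
    "BiometryResult",
    "SegmentationError",
    "segment_axial_boundaries",
    "segmentation_from_boundaries",
    "optical_to_physical",
    "compute_biometry",
    "percent_change",
]

#: Anterior-to-posterior order of the ocular compartments spanning the axial length.
COMPARTMENTS = ("cornea", "anterior_chamber", "lens", "vitreous", "retina")

#: Scalar tissue refractive indices used to convert optical to physical path.
#: The lens value is the single equivalent index of the gradient-index
#: spherical fish lens.
DEFAULT_REFRACTIVE_INDICES: dict[str, float] = {
    "cornea": 1.33,
    "anterior_chamber": 1.34,
    "lens": 1.40,
    "vitreous": 1.34,
    "retina": 1.38,
}


class SegmentationError(RuntimeError):
    """Raised when axial boundaries cannot be located or are non-monotonic."""


@dataclass
class BScan:
    """A 2-D axial intensity image; rows run along the optical (Z) axis."""

    image: np.ndarray
    pixel_depth_um: float = 2.0

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2:
            raise ValueError("BScan image must be 2-D (depth x lateral)")
        if self.pixel_depth_um <= 0:
            raise ValueError("pixel depth must be positive")


@dataclass
class AxialSegmentation:
    """Six ordered axial boundaries (pixels): corneal apex, cornea/AC, AC/lens,
    lens/vitreous, vitreous/retina, anterior RPE."""

    boundaries_px: Sequence[float]
    pixel_depth_um: float = 2.0

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries_px, dtype=float)
        if b.size != 6:
            raise ValueError("exactly 6 boundaries required")
        if np.any(np.diff(b) <= 0):
            raise SegmentationError("boundaries must be strictly increasing")
        self.boundaries_px = b


@dataclass
class BiometryResult:
    """Per-compartment physical dimensions and total axial length (µm)."""

    physical_um: Mapping[str, float]
    optical_um: Mapping[str, float]
    axial_length_um: float = field(init=False)

    def __post_init__(self) -> None:
        self.axial_length_um = float(sum(self.physical_um[c] for c in COMPARTMENTS))


def segmentation_from_boundaries(
    boundaries_px: Sequence[float], pixel_depth_um: float = 2.0
) -> AxialSegmentation:
    """Wrap manually marked boundaries unchanged (the manual-marking path)."""
    return AxialSegmentation(boundaries_px, pixel_depth_um)


def _rpe_rising_edge(ascan: np.ndarray, start: int) -> int:
    """Anterior RPE boundary: rising edge of the brightest band after ``start``.

    The edge is the largest intensity step between ``start`` (posterior to the
    vitreous/retina boundary) and the band's peak, so a speckle-shifted peak
    position within the hyperreflective band cannot displace the edge.
    """
    peak = start + int(np.argmax(ascan[start:]))
    if peak <= start:
        return peak
    d = np.diff(ascan[start : peak + 1])
    return start + int(np.argmax(d)) + 1


def segment_axial_boundaries(
    bscan: BScan,
    column: int | None = None,
    prior: Sequence[float] | None = None,
    signs: Sequence[int] | None = None,
    smooth_sigma: float = 1.0,
    window: int = 10,
) -> AxialSegmentation:
    """Locate the six axial boundaries on a (possibly averaged) A-scan.

    Parameters
    ----------
    bscan
        Input B-scan; intensities are averaged over all lateral columns unless
        ``column`` selects a single central A-scan.
    prior
        Optional approximate boundary layout (pixels).  When given, each of
        the first five boundaries is refined to the strongest intensity-step
        extremum within ``window`` pixels of its prior.  Without a prior the
        six most prominent steps are used.
    signs
        Optional expected step polarity per boundary (+1 rising, -1 falling);
        restricting the search to the expected polarity disambiguates closely
        spaced boundaries (the anterior chamber can be only a few pixels deep).

    The sixth boundary (anterior RPE) is always the rising edge of the
    brightest band, the sharp-cut hyperreflective landmark.
    """
    img = bscan.image
    ascan = img[:, column] if column is not None else img.mean(axis=1)
    smoothed = gaussian_filter1d(ascan, smooth_sigma)
    d = np.gradient(smoothed)

    if prior is not None:
        prior = np.asarray(prior, dtype=float)
        if prior.size != 6:
            raise ValueError("prior must supply 6 approximate boundaries")
        bounds: list[int] = []
        for k, p in enumerate(prior[:5]):
            lo = max(1, int(round(p)) - window)
            hi = min(len(d) - 1, int(round(p)) + window + 1)
            if hi <= lo:
                raise SegmentationError(f"prior boundary {k} outside the scan")
            seg = d[lo:hi]
            if signs is not None and signs[k] != 0:
                seg = seg * np.sign(signs[k])
                bounds.append(lo + int(np.argmax(seg)))
            else:
                bounds.append(lo + int(np.argmax(np.abs(seg))))
        rpe_search_start = bounds[-1] + 1
        bounds.append(_rpe_rising_edge(smoothed, rpe_search_start))
    else:
        from scipy.signal import find_peaks

        # only edges up to the brightest-band (RPE) peak are anatomical
        # boundaries; the band's posterior falling edge must not compete
        band_peak = int(np.argmax(smoothed))
        mag = np.abs(d[: band_peak + 1])
        floor = 0.05 * mag.max()
        peaks, props = find_peaks(mag, height=floor, distance=2)
        if peaks.size < 6:
            raise SegmentationError(
                f"only {peaks.size} intensity transitions found; 6 required"
            )
        strongest = peaks[np.argsort(props["peak_heights"])[-6:]]
        bounds = sorted(int(p) for p in strongest)
        bounds[-1] = _rpe_rising_edge(smoothed, bounds[-2] + 1)

    if np.any(np.diff(bounds) <= 0):
        raise SegmentationError(f"non-monotonic boundary sequence: {bounds}")
    return AxialSegmentation(bounds, bscan.pixel_depth_um)


def optical_to_physical(optical_length_um: float, n: float) -> float:
    """Convert an optical path length to physical length: ``optical / n``."""
    if n < 1:
        raise ValueError(f"refractive index must be >= 1, got {n}")
    if optical_length_um < 0:
        raise ValueError("optical length must be non-negative")
    return optical_length_um / n


def compute_biometry(
    seg: AxialSegmentation,
    indices: Mapping[str, float] | None = None,
) -> BiometryResult:
    """Convert boundary gaps to physical compartment dimensions and axial length."""
    if indices is None:
        indices = DEFAULT_REFRACTIVE_INDICES
    missing = set(COMPARTMENTS) - set(indices)
    if missing:
        raise ValueError(f"missing refractive indices for: {sorted(missing)}")
    b = np.asarray(seg.boundaries_px, dtype=float)
    optical = {
        c: float((b[i + 1] - b[i]) * seg.pixel_depth_um)
        for i, c in enumerate(COMPARTMENTS)
    }
    physical = {c: optical_to_physical(optical[c], indices[c]) for c in COMPARTMENTS}
    return BiometryResult(physical_um=physical, optical_um=optical)


def percent_change(mutant_mean: float, wt_mean: float) -> float:
    """Relative group difference, ``100 * (mutant - wt) / wt``, in percent."""
    if wt_mean == 0:
        raise ZeroDivisionError("wild-type mean is zero; percent change undefined")
    return 100.0 * (mutant_mean - wt_mean) / wt_mean
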