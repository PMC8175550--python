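"""Eccentric-photorefraction analysis.

In eccentric infrared photorefraction the defocus of the eye maps onto a
linear brightness gradient across the pupil.  The slope of that gradient,
multiplied by a device-specific conversion factor calibrated with trial
lenses of known power, gives the refractive error (RE) in diopters.  The
zebrafish application adds two twists handled here: replicate averaging
(one hundred slope measurements per eye) and qualitative profile phenotypes —
a normal single gradient (monofocal), two opposite-signed half-gradients
(bifocal, the signature of a lens with two focal regions), and the absent
gradient of severely elongated eyes.  Because small eyes carry a hyperopic
retinoscopic offset, group comparisons use RE relative to the wild-type
baseline rather than absolute RE.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "PupilProfile",
    "CalibrationCurve",
    "RefractionResult",
    "estimate_slope",
    "average_refraction",
    "calibrate",
    "relative_refraction",
    "classify_profile",
    "extract_pupil_profile",
]

ProfileClass = Literal["monofocal", "bifocal", "absent"]


@dataclass
class PupilProfile:
    """Brightness-vs-position samples across a pupil meridian."""

    position: np.ndarray
    brightness: np.ndarray
    replicate: int | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.brightness = np.asarray(self.brightness, dtype=float)
        if self.position.size != self.brightness.size:
            raise ValueError("position and brightness must have equal length")
        if self.position.size < 3:
            raise ValueError("a profile needs at least 3 samples")
        if np.any(np.diff(self.position) <= 0):
            raise ValueError("positions must be strictly increasing")


@dataclass
class CalibrationCurve:
    lens_powers_d: np.ndarray
    mean_slopes: np.ndarray
    conversion_factor: float  # diopters per slope unit
    r_squared: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("R^2 must lie in [0, 1]")


@dataclass
class RefractionResult:
    mean_refraction_d: float
    n_replicates: int
    classification: ProfileClass
    relative_refraction_d: float | None = None


def estimate_slope(profile: PupilProfile) -> tuple[float, float]:
    """Ordinary least-squares slope of brightness on position, with fit R²."""
    if np.ptp(profile.brightness) == 0:
        return 0.0, 1.0  # flat profile: slope 0, trivially perfect fit
    res = _sps.linregress(profile.position, profile.brightness)
    return float(res.slope), float(res.rvalue**2)


def average_refraction(slopes: Sequence[float], factor: float) -> float:
    """Mean slope over replicates converted to diopters via the factor."""
    slopes = np.asarray(slopes, dtype=float)
    if slopes.size == 0:
        raise ValueError("at least one slope measurement required")
    if factor == 0:
        raise ValueError("conversion factor must be nonzero")
    return float(slopes.mean() * factor)


def calibrate(
    lens_powers_d: Sequence[float], slopes_per_lens: Sequence[Sequence[float]]
) -> CalibrationCurve:
    """Trial-lens calibration: regress lens power on mean measured slope.

    The regression slope is the conversion factor (D per slope unit) used to
    turn brightness-gradient slopes into refractive errors.
    """
    powers = np.asarray(lens_powers_d, dtype=float)
    if np.unique(powers).size < 2:
        raise ValueError("need at least 2 distinct lens powers")
    if len(slopes_per_lens) != powers.size:
        raise ValueError("one slope list required per lens power")
    mean_slopes = np.array([np.mean(s) for s in slopes_per_lens], dtype=float)
    if np.ptp(mean_slopes) == 0:
        raise ValueError("all mean slopes identical; conversion factor undefined")
    res = _sps.linregress(mean_slopes, powers)
    return CalibrationCurve(
        lens_powers_d=powers,
        mean_slopes=mean_slopes,
        conversion_factor=float(res.slope),
        r_squared=float(res.rvalue**2),
    )


def relative_refraction(
    mutant_re_d: Sequence[float], wt_re_d: Sequence[float]
) -> np.ndarray:
    """Mutant REs minus the wild-type group baseline (mean) RE.

    Positive values are hyperopic shifts, negative myopic, relative to the
    assumed-emmetropic wild-type group; this cancels the shared small-eye
    retinoscopic offset.
    """
    wt = np.asarray(wt_re_d, dtype=float)
    if wt.size == 0:
        raise ValueError("wild-type RE list must be non-empty")
    return np.asarray(mutant_re_d, dtype=float) - wt.mean()


def extract_pupil_profile(image: np.ndarray) -> PupilProfile:
    """Extract the vertical brightness profile across the pupil of an image.

    The pupil is located as the largest connected region darker than the
    automatic (Otsu) threshold — in infrared photorefraction images the
    pupil is darker than the illuminated iris/surround — and the profile is
    the brightness along the vertical meridian through the pupil centroid,
    with positions normalized to the pupil extent [0, 1].  This raw-image
    path is optional; CSV profiles are the primary input, since meridian
    geometry depends on rig eccentricity and working distance.
    """
    from skimage.filters import threshold_otsu
    from skimage.measure import label, regionprops

    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("pupil image must be 2-D grayscale")
    lab = label(image < threshold_otsu(image))
    props = regionprops(lab)
    if not props:
        raise ValueError("no dark pupil region found")
    pupil = max(props, key=lambda p: p.area)
    mask = lab == pupil.label
    cy, cx = pupil.centroid
    col = int(round(cx))
    rows = np.flatnonzero(mask[:, col])
    if rows.size < 3:
        raise ValueError("pupil meridian spans fewer than 3 pixels")
    position = (rows - rows[0]) / (rows[-1] - rows[0])
    return PupilProfile(position=position, brightness=image[rows, col])


def _normalize(profile: PupilProfile) -> tuple[np.ndarray, np.ndarray]:
    """Map positions to [0, 1] and brightness to unit range (affine-invariant)."""
    x = profile.position
    x = (x - x[0]) / (x[-1] - x[0])
    b = profile.brightness
    rng = np.ptp(b)
    b = (b - b.min()) / rng if rng > 0 else np.zeros_like(b)
    return x, b


def _line_rss(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and residual sum of squares of y on x."""
    A = np.column_stack([x, np.ones_like(x)])
    coef, rss, *_ = np.linalg.lstsq(A, y, rcond=None)
    if rss.size == 0:  # perfectly collinear
        rss = np.array([0.0])
    return float(coef[0]), float(rss[0])


def classify_profile(
    profile: PupilProfile,
    slope_threshold: float = 0.05,
    split_gain_threshold: float = 0.5,
    r2_threshold: float = 0.2,
) -> ProfileClass:
    """Classify a pupil profile as monofocal, bifocal or gradient-absent.

    Works on the normalized profile (positions in [0,1], brightness in unit
    range) so thresholds are unit-free and the call is invariant to affine
    brightness transforms.  A global line and the best two-segment piecewise
    line (breakpoint scanned over interior samples) are fitted; the profile is
    *bifocal* when the two segment slopes have opposite signs, both exceed the
    slope threshold, and splitting removes at least ``split_gain_threshold``
    of the global residual sum of squares; *absent* when no reliable gradient
    exists — the global slope is below threshold or the line explains less
    than ``r2_threshold`` of the brightness variance (a min-max normalized
    pure-noise profile always spans the unit range, so the slope magnitude
    alone cannot separate noise from gradient); otherwise *monofocal*.
    """

    def _r2(rss: float, y: np.ndarray) -> float:
        tss = float(np.sum((y - y.mean()) ** 2))
        return 1.0 - rss / tss if tss > 0 else 1.0

    if profile.position.size < 6:
        # too few samples for a meaningful piecewise fit: monofocal/absent only
        x, b = _normalize(profile)
        slope, rss = _line_rss(x, b)
        good = abs(slope) >= slope_threshold and _r2(rss, b) >= r2_threshold
        return "monofocal" if good else "absent"

    x, b = _normalize(profile)
    g_slope, g_rss = _line_rss(x, b)

    best = None  # (rss2, slope_left, slope_right)
    n = x.size
    for k in range(3, n - 2):  # at least 3 samples per segment
        sl, rl = _line_rss(x[:k], b[:k])
        sr, rr = _line_rss(x[k:], b[k:])
        if best is None or rl + rr < best[0]:
            best = (rl + rr, sl, sr)

    if best is not None and g_rss > 1e-12:
        rss2, sl, sr = best
        opposite = sl * sr < 0
        strong = min(abs(sl), abs(sr)) >= slope_threshold
        gain = 1.0 - rss2 / g_rss
        if opposite and strong and gain >= split_gain_threshold:
            return "bifocal"

    good = abs(g_slope) >= slope_threshold and _r2(g_rss, b) >= r2_threshold
    return "monofocal" if good else "absent"
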