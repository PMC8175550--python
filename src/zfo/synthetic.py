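"""Synthetic ground-truth generators for every pipeline input.

Each generator is a pure function of its spec (including the seed) and
returns both the rendered data and the designed ground truth, so every
analysis stage can be validated as a parameter-recovery experiment:

* ``generate_bscan`` — layered-eye OCT phantom in optical-path coordinates
  (compartment extent = physical thickness x refractive index), RPE rendered
  as the brightest band, multiplicative speckle noise;
* ``generate_pupil_profile`` — linear pupil brightness gradient with slope
  refraction / conversion factor, plus bifocal and gradient-absent variants;
* ``generate_okr_trace`` — sawtooth nystagmus: slow phases at gain x drum
  velocity interrupted by instantaneous resets at a fixed rate;
* ``generate_erg_trace`` — biphasic difference-of-gamma ERG template whose
  noiseless baseline-corrected maximum equals the designed B-wave amplitude;
* ``generate_lens_image`` — lens disk with concentric opaque nuclear rings;
  ring widths can be solved on the pixel grid to hit a target opaque
  fraction, and the ground-truth fraction is reported from the rendered mask;
* ``generate_cohort`` — two-eyed fish with genotype effect, per-fish random
  intercept and per-eye residual, feeding the mixed model.

Designed quantities (slopes, gain, amplitudes, opaque fractions, effect
sizes) are carried in the returned ground truth and never re-derived from
the rendered data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .erg import ERGTrace
from .oct import BScan, COMPARTMENTS, DEFAULT_REFRACTIVE_INDICES
from .okr import Direction, EyeTrace, _DIR_SIGN, _opposite
from .photorefraction import PupilProfile

__all__ = [
    "EyePhantomSpec",
    "OkrTraceSpec",
    "ErgTraceSpec",
    "LensImageSpec",
    "CohortSpec",
    "DegeneratePhantomError",
    "generate_bscan",
    "generate_pupil_profile",
    "generate_okr_trace",
    "generate_erg_trace",
    "generate_lens_image",
    "generate_cohort",
]

#: Default compartment reflectivities (arbitrary units).  The instrument's
#: per-tissue intensity response is a free parameter; these values are chosen
#: only to give every boundary a clear step and the RPE the brightest band.
DEFAULT_REFLECTIVITIES: dict[str, float] = {
    "cornea": 0.50,
    "anterior_chamber": 0.20,
    "lens": 0.35,
    "vitreous": 0.12,
    "retina": 0.55,
}

#: Wild-type-like compartment thicknesses (µm) of an adult zebrafish eye.
WT_THICKNESSES_UM: dict[str, float] = {
    "cornea": 22.0,
    "anterior_chamber": 5.0,
    "lens": 500.0,
    "vitreous": 300.0,
    "retina": 180.0,
}


class DegeneratePhantomError(ValueError):
    """A compartment's optical extent fell below one pixel."""


# ---------------------------------------------------------------------------
# OCT phantom


@dataclass
class EyePhantomSpec:
    thicknesses_um: Mapping[str, float] = field(
        default_factory=lambda: dict(WT_THICKNESSES_UM)
    )
    indices: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REFRACTIVE_INDICES)
    )
    reflectivities: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REFLECTIVITIES)
    )
    speckle: float = 0.0  # multiplicative noise SD as fraction of mean intensity
    pixel_depth_um: float = 2.0
    width_px: int = 32
    margin_px: int = 20  # background rows before the corneal apex
    rpe_thickness_um: float = 30.0
    rpe_reflectivity: float = 1.0
    background_reflectivity: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for c in COMPARTMENTS:
            if self.thicknesses_um.get(c, 0) <= 0:
                raise ValueError(f"thickness of {c!r} must be positive")
            if self.indices.get(c, 0) < 1:
                raise ValueError(f"refractive index of {c!r} must be >= 1")
        if self.speckle < 0:
            raise ValueError("speckle level must be >= 0")
        if self.pixel_depth_um <= 0:
            raise ValueError("pixel depth must be positive")


def generate_bscan(spec: EyePhantomSpec) -> tuple[BScan, pd.DataFrame]:
    """Render an axial phantom and its ground-truth biometry table.

    Each compartment occupies ``round(thickness * n / pixel_depth)`` pixels of
    optical path; the returned table lists, per compartment, the designed
    physical thickness, the exact optical extent (thickness x n) and the
    rendered pixel boundaries.  The RPE band behind the retina is the
    brightest structure, giving the posterior axial-length landmark.
    """
    rng = np.random.default_rng(spec.seed)
    boundaries = [spec.margin_px]
    optical_cum = 0.0
    rows = []
    for c in COMPARTMENTS:
        t = float(spec.thicknesses_um[c])
        n = float(spec.indices[c])
        optical_cum += t * n
        b_next = spec.margin_px + int(round(optical_cum / spec.pixel_depth_um))
        extent_px = b_next - boundaries[-1]
        if extent_px < 1:
            raise DegeneratePhantomError(
                f"{c}: optical extent {t * n:.2f} µm is below one pixel "
                f"({spec.pixel_depth_um} µm)"
            )
        rows.append(
            {
                "compartment": c,
                "physical_um": t,
                "optical_um": t * n,
                "start_px": boundaries[-1],
                "end_px": b_next,
                "extent_px": extent_px,
                "refractive_index": n,
            }
        )
        boundaries.append(b_next)

    rpe_px = max(1, int(round(spec.rpe_thickness_um * spec.indices["retina"]
                              / spec.pixel_depth_um)))
    depth = boundaries[-1] + rpe_px + spec.margin_px
    img = np.full((depth, spec.width_px), spec.background_reflectivity)
    for row in rows:
        img[row["start_px"] : row["end_px"], :] = spec.reflectivities[
            row["compartment"]
        ]
    img[boundaries[-1] : boundaries[-1] + rpe_px, :] = spec.rpe_reflectivity
    if spec.speckle > 0:
        img = img * (1.0 + spec.speckle * rng.standard_normal(img.shape))
        np.clip(img, 0.0, None, out=img)

    truth = pd.DataFrame(rows)
    truth.attrs["boundaries_px"] = boundaries + [boundaries[-1] + rpe_px]
    truth.attrs["axial_length_um"] = float(
        sum(spec.thicknesses_um[c] for c in COMPARTMENTS)
    )
    truth.attrs["optical_total_um"] = float(optical_cum)
    return BScan(image=img, pixel_depth_um=spec.pixel_depth_um), truth


# ---------------------------------------------------------------------------
# Pupil brightness profiles


def generate_pupil_profile(
    refraction_d: float,
    conversion_factor: float,
    n_points: int = 50,
    noise_sd: float = 0.0,
    seed: int = 0,
    kind: Literal["monofocal", "bifocal", "absent"] = "monofocal",
    baseline: float = 0.5,
) -> PupilProfile:
    """Brightness profile across a pupil with the designed gradient slope.

    Positions are the normalized pupil coordinate in [0, 1]; the designed
    slope is ``refraction / conversion_factor`` per pupil width.  The bifocal
    variant concatenates two half-profiles with opposite-signed slopes (a
    tent shape); the absent variant is flat, relying on ``noise_sd`` for the
    realistic high-noise floor.
    """
    if conversion_factor == 0:
        raise ValueError("conversion factor must be nonzero")
    if n_points < 3:
        raise ValueError("cannot fit a slope to fewer than 3 points")
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, 1.0, n_points)
    slope = refraction_d / conversion_factor
    if kind == "monofocal":
        b = baseline + slope * (x - 0.5)
    elif kind == "bifocal":
        b = baseline + slope * (np.minimum(x, 1.0 - x) - 0.25)
    elif kind == "absent":
        b = np.full_like(x, baseline)
    else:
        raise ValueError(f"unknown profile kind {kind!r}")
    if noise_sd > 0:
        b = b + noise_sd * rng.standard_normal(n_points)
    return PupilProfile(position=x, brightness=b)


# ---------------------------------------------------------------------------
# OKR sawtooth traces


@dataclass
class OkrTraceSpec:
    gain: float = 0.8
    drum_velocity_deg_s: float = 20.0
    frame_rate: float = 96.0
    duration_s: float = 30.0
    saccade_amplitude_deg: float = 10.0
    saccade_rate_hz: float = 0.8
    noise_sd_deg: float = 0.0
    direction: Direction = "nasal"
    spatial_frequency_cpd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame rate must be positive")
        if self.gain < 0:
            raise ValueError("gain must be >= 0")
        if self.drum_velocity_deg_s == 0:
            raise ValueError("drum velocity must be nonzero")
        if self.noise_sd_deg < 0 or self.saccade_amplitude_deg < 0:
            raise ValueError("noise and saccade amplitude must be >= 0")


def generate_okr_trace(spec: OkrTraceSpec) -> EyeTrace:
    """Sawtooth nystagmus: linear slow phases with instantaneous resets.

    Slow-phase velocity is ``gain * drum_velocity`` in the stimulus
    direction; resets of the designed amplitude occur at the designed rate in
    the opposite direction, falling exactly between two frames so every slow
    segment stays exactly linear.  Designed reset times and directions are
    recorded in the trace metadata.
    """
    n = int(round(spec.duration_s * spec.frame_rate))
    if n < 2:
        raise ValueError("trace too short")
    sign = _DIR_SIGN[spec.direction]
    t = np.arange(n) / spec.frame_rate
    slow_v = spec.gain * abs(spec.drum_velocity_deg_s) * sign
    angle = slow_v * t

    reset_times: list[float] = []
    if spec.gain > 0 and spec.saccade_rate_hz > 0:
        spacing_frames = spec.frame_rate / spec.saccade_rate_hz
        if spacing_frames < 4:
            raise ValueError(
                "saccade rate too high: no slow phase would span >= 2 frames"
            )
        interval = 1.0 / spec.saccade_rate_hz
        k = 1
        while k * interval < spec.duration_s - 1.0 / spec.frame_rate:
            idx = int(round(k * interval * spec.frame_rate))
            if idx < n:
                angle[idx:] -= spec.saccade_amplitude_deg * sign
                reset_times.append(float(t[idx]))
            k += 1

    if spec.noise_sd_deg > 0:
        rng = np.random.default_rng(spec.seed)
        angle = angle + spec.noise_sd_deg * rng.standard_normal(n)

    return EyeTrace(
        time_s=t,
        angle_deg=angle,
        drum_velocity_deg_s=abs(spec.drum_velocity_deg_s) * sign,
        spatial_frequency_cpd=spec.spatial_frequency_cpd,
        direction=spec.direction,
        meta={
            "designed_gain": spec.gain,
            "designed_slow_velocity_deg_s": slow_v,
            "reset_times_s": reset_times,
            "reset_direction": _opposite(spec.direction),
        },
    )


# ---------------------------------------------------------------------------
# ERG traces


@dataclass
class ErgTraceSpec:
    sampling_rate_hz: float = 1000.0
    pre_stimulus_ms: float = 200.0
    n_stimuli: int = 2
    inter_stimulus_ms: float = 8000.0
    stimulus_duration_ms: float = 100.0
    a_amplitude_uv: float = 80.0  # magnitude of the negative lobe
    b_amplitude_uv: float = 200.0  # designed post-correction maximum
    tau_a_ms: float = 30.0  # negative-lobe peak time
    tau_b_ms: float = 120.0  # positive-lobe peak time
    template_support_ms: float = 1000.0
    baseline_offset_uv: float = 0.0
    noise_sd_uv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pre_stimulus_ms < 50.0:
            raise ValueError("need >= 50 ms of pre-stimulus baseline")
        if self.b_amplitude_uv < 0 or self.a_amplitude_uv < 0:
            raise ValueError("lobe amplitudes must be >= 0")
        if self.n_stimuli < 1:
            raise ValueError("need at least one stimulus")
        if self.n_stimuli > 1 and self.inter_stimulus_ms < self.template_support_ms:
            raise ValueError(
                "inter-stimulus interval shorter than the response template; "
                "responses would overlap"
            )


def _gamma_lobe(t_ms: np.ndarray, tp_ms: float, shape: float = 2.0) -> np.ndarray:
    """Gamma-shaped kernel peaking at ``tp_ms`` with unit peak amplitude."""
    x = np.clip(t_ms, 0.0, None) / tp_ms
    return x**shape * np.exp(shape * (1.0 - x))


def erg_template(spec: ErgTraceSpec, t_ms: np.ndarray) -> np.ndarray:
    """Difference-of-gamma biphasic response (negative A lobe, positive B lobe).

    The positive-lobe coefficient is solved so the template maximum equals
    the designed B-wave amplitude exactly in the noiseless case.
    """
    ga = _gamma_lobe(t_ms, spec.tau_a_ms)
    gb = _gamma_lobe(t_ms, spec.tau_b_ms)
    if spec.b_amplitude_uv == 0 and spec.a_amplitude_uv == 0:
        return np.zeros_like(t_ms)
    if spec.b_amplitude_uv == 0:
        return -spec.a_amplitude_uv * ga  # max is 0 at onset: amplitude 0
    a = spec.a_amplitude_uv

    def overshoot(s: float) -> float:
        return float(np.max(-a * ga + s * gb)) - spec.b_amplitude_uv

    s = brentq(overshoot, 0.0, spec.b_amplitude_uv + a + 1.0, xtol=1e-12)
    return -a * ga + s * gb


def generate_erg_trace(spec: ErgTraceSpec) -> ERGTrace:
    """Render the stimulus train with baseline offset and additive noise."""
    dt = 1000.0 / spec.sampling_rate_hz
    total_ms = (
        spec.pre_stimulus_ms
        + (spec.n_stimuli - 1) * spec.inter_stimulus_ms
        + spec.template_support_ms
        + 100.0
    )
    t = np.arange(0.0, total_ms, dt)
    v = np.full_like(t, spec.baseline_offset_uv)
    onsets = [
        spec.pre_stimulus_ms + k * spec.inter_stimulus_ms
        for k in range(spec.n_stimuli)
    ]
    for onset in onsets:
        rel = t - onset
        mask = (rel >= 0) & (rel <= spec.template_support_ms)
        v[mask] += erg_template(spec, rel[mask])
    if spec.noise_sd_uv > 0:
        rng = np.random.default_rng(spec.seed)
        v = v + spec.noise_sd_uv * rng.standard_normal(t.size)
    return ERGTrace(
        time_ms=t,
        voltage_uv=v,
        onsets_ms=onsets,
        stimulus_duration_ms=spec.stimulus_duration_ms,
    )


# ---------------------------------------------------------------------------
# Lens images


@dataclass
class LensImageSpec:
    image_size_px: int = 128
    lens_radius_px: float = 50.0
    background: float = 0.10
    cortical: float = 1.0
    # each ring: (radius fraction of lens radius, full width px, contrast above cortex)
    rings: Sequence[tuple[float, float, float]] = ()
    target_opaque_fraction: float | None = None
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.lens_radius_px < self.image_size_px / 2:
            raise ValueError("lens radius must lie in (0, image half-size)")
        for f, w, c in self.rings:
            if not 0 < f < 1:
                raise ValueError("ring radius fractions must lie in (0, 1)")
            if c < 0 or w <= 0:
                raise ValueError("ring contrast must be >= 0 and width positive")
        if self.target_opaque_fraction is not None and not (
            0 <= self.target_opaque_fraction < 1
        ):
            raise ValueError("target opaque fraction must lie in [0, 1)")


def generate_lens_image(spec: LensImageSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render a coronal lens section and its ground-truth opaque mask.

    When ``target_opaque_fraction`` is set, the common ring width is solved
    on the actual pixel grid (monotone search over the annulus half-width)
    so the rendered mask covers the target fraction of the lens disk up to
    ring quantization; the ground truth is always the rendered mask itself.
    """
    n = spec.image_size_px
    yy, xx = np.mgrid[0:n, 0:n]
    c = (n - 1) / 2.0
    rho = np.hypot(yy - c, xx - c)
    disk = rho <= spec.lens_radius_px
    img = np.full((n, n), spec.background, dtype=float)
    img[disk] = spec.cortical

    rings = list(spec.rings)
    if spec.target_opaque_fraction is not None:
        if not rings:
            rings = [(0.4, 1.0, 0.3)]
        disk_px = int(disk.sum())
        target_px = spec.target_opaque_fraction * disk_px

        def mask_for(hw: float) -> np.ndarray:
            # a ring stops growing once it would reach the center or the rim
            m = np.zeros_like(disk)
            for f, _, _ in rings:
                cap = min(f, 1.0 - f) * spec.lens_radius_px
                m |= (np.abs(rho - f * spec.lens_radius_px) <= min(hw, cap)) & disk
            return m

        max_hw = max(min(f, 1.0 - f) for f, _, _ in rings) * spec.lens_radius_px
        if mask_for(max_hw).sum() < target_px:
            raise ValueError("target opaque fraction exceeds ring capacity")
        hws = np.arange(0.0, max_hw + 0.25, 0.25)
        counts = np.array([mask_for(h).sum() for h in hws])
        best = hws[int(np.argmin(np.abs(counts - target_px)))]
        rings = [(f, 2.0 * best, cc) for f, _, cc in rings]

    opaque = np.zeros_like(disk)
    for f, w, contrast in rings:
        ring = (np.abs(rho - f * spec.lens_radius_px) <= w / 2.0) & disk
        img[ring] = spec.cortical * (1.0 + contrast)
        opaque |= ring

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + spec.noise_sd * rng.standard_normal(img.shape)
    return img, opaque


# ---------------------------------------------------------------------------
# Cohorts


@dataclass
class CohortSpec:
    n_fish_per_group: int = 20
    eyes_per_fish: int = 2
    genotype_effect: float = -47.0  # mutant minus WT, in outcome units
    grand_mean: float = 1000.0
    between_fish_sd: float = 15.0  # random-intercept SD
    residual_sd: float = 10.0  # within-fish (per-eye) SD
    body_length_mean_mm: float = 20.0
    body_length_sd_mm: float = 1.0
    age: str = "1.5 mpf"
    outcome: str = "axial_length_um"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eyes_per_fish != 2:
            raise ValueError("the paired-eye design has exactly 2 eyes per fish")
        if min(self.between_fish_sd, self.residual_sd, self.body_length_sd_mm) < 0:
            raise ValueError("SDs must be >= 0")
        if self.n_fish_per_group < 1:
            raise ValueError("need at least one fish per group")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Two rows (eyes) per fish: grand mean + genotype effect + random
    intercept + per-eye residual, plus a per-fish body length."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for genotype in ("WT", "mutant"):
        effect = spec.genotype_effect if genotype == "mutant" else 0.0
        for i in range(spec.n_fish_per_group):
            fish_id = f"{genotype}_{i:03d}"
            u = spec.between_fish_sd * rng.standard_normal()
            length = spec.body_length_mean_mm + spec.body_length_sd_mm * (
                rng.standard_normal()
            )
            for eye in ("left", "right"):
                eps = spec.residual_sd * rng.standard_normal()
                rows.append(
                    {
                        "fish_id": fish_id,
                        "genotype": genotype,
                        "eye": eye,
                        "age": spec.age,
                        "body_length_mm": length,
                        "outcome": spec.outcome,
                        "value": spec.grand_mean + effect + u + eps,
                    }
                )
    df = pd.DataFrame(rows)
    df.attrs["designed_effect"] = spec.genotype_effect
    return df
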