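"""Canned recovery-experiment designs built from the synthetic generators.

These helpers wire generator output into the matching analysis stage for the
standard group designs (ringed/ringless lens sets, opacity-fraction pairs,
phantom cohorts at a scaled axial length) so that scripted experiments and
tests drive one shared implementation.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from . import lens as lens_mod
from . import synthetic as syn
from .lens import CataractCall, OpacityResult
from .oct import compute_biometry, segment_axial_boundaries

#: Step polarity of the default phantom's six boundaries (see
#: ``synthetic.DEFAULT_REFLECTIVITIES``): bright cornea, dark anterior
#: chamber, mid lens, dark vitreous, bright retina, brightest RPE.
PHANTOM_EDGE_SIGNS = (1, -1, 1, -1, 1, 1)


def ring_calls(
    n_ringed: int, n_total: int, contrast: float, seed0: int,
    radius_fraction: float = 0.4, width_px: float = 3.0,
) -> list[CataractCall]:
    """Nuclear-ring detection over a lens set with ``n_ringed`` ringed lenses."""
    calls = []
    for i in range(n_total):
        rings = [(radius_fraction, width_px, contrast)] if i < n_ringed else []
        img, _ = syn.generate_lens_image(
            syn.LensImageSpec(rings=rings, seed=seed0 + i)
        )
        mask = lens_mod.auto_lens_mask(img)
        calls.append(lens_mod.detect_nuclear_ring(img, mask))
    return calls


def lens_image_set(
    fraction: float, n: int, seed0: int
) -> list[OpacityResult]:
    """Opacity ratios of ``n`` lenses rendered at a target opaque fraction."""
    results = []
    for i in range(n):
        spec = syn.LensImageSpec(target_opaque_fraction=fraction, seed=seed0 + i)
        img, _ = syn.generate_lens_image(spec)
        mask = lens_mod.auto_lens_mask(img)
        results.append(lens_mod.opacity_ratio(img, mask))
    return results


def phantom_cohort_axial_mean(
    scale: float,
    seeds: Iterable[int],
    baseline_axial_um: float = 1000.0,
    speckle: float = 0.05,
) -> float:
    """Mean recovered axial length over a phantom group.

    The wild-type compartment proportions are rescaled so the designed axial
    length equals ``baseline_axial_um``; ``scale`` multiplies every
    compartment (a uniformly scaled eye).  Each phantom is segmented with the
    nominal design as prior and converted to physical biometry.
    """
    total = sum(syn.WT_THICKNESSES_UM.values())
    thick = {
        k: v * scale * baseline_axial_um / total
        for k, v in syn.WT_THICKNESSES_UM.items()
    }
    values = []
    for seed in seeds:
        spec = syn.EyePhantomSpec(
            thicknesses_um=thick, speckle=speckle, seed=int(seed)
        )
        bscan, truth = syn.generate_bscan(spec)
        seg = segment_axial_boundaries(
            bscan,
            prior=truth.attrs["boundaries_px"][:6],
            signs=PHANTOM_EDGE_SIGNS,
        )
        values.append(compute_biometry(seg, spec.indices).axial_length_um)
    return float(np.mean(values))
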