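# zfo — zebrafish ocular phenotyping

`zfo` is a Python toolkit for the quantitative ocular phenotyping of
zebrafish: it turns raw instrument output — OCT B-scans, eccentric
photorefraction pupil profiles, optokinetic eye-angle traces, ERG voltage
recordings, and coronal lens sections — into the biometric, refractive,
behavioral and electrophysiological endpoints used in fish models of
refractive error and cataract, and ties them together with the paired-eye
statistics such studies require.

It is written for vision researchers who need a scripted, reproducible
version of measurements that are often done with ad-hoc lab software, plus a
synthetic-data module that renders phantoms, traces and cohorts with known
ground truth so every stage can be validated as a parameter-recovery
experiment.

## What it computes

**OCT biometry** (`zfo.oct`). OCT measures optical path length
`OPL = n · d`. Given six axial boundaries (corneal apex → anterior RPE, the
hyperreflective melanin band), each compartment's physical thickness is
`d = Δpx · pixel_depth / n` with tissue indices
`n_cornea = 1.33, n_chambers = 1.34, n_lens = 1.40 (equivalent gradient
index), n_retina = 1.38`, and axial length is the sum over the five
compartments. Boundaries can be marked manually or detected automatically
(prior-guided step detection on the averaged A-scan; the anterior RPE is the
rising edge of the brightest band).

**Eccentric photorefraction** (`zfo.photorefraction`). Defocus produces a
linear brightness gradient across the pupil; refractive error is
`RE = k · slope` with the conversion factor `k` (D per slope unit)
calibrated by regressing trial-lens power on measured slope. Replicate
slopes are averaged (the protocol uses 100 per eye), group comparisons use
RE relative to the wild-type baseline, and profiles are classified
monofocal / bifocal / gradient-absent by a piecewise-line fit.

**Lens opacity and cataract** (`zfo.lens`). Opacity ratio = fraction of
lens-mask pixels above an Otsu threshold computed within the mask; nuclear
cataract is called from the radial intensity profile (concentric ring
elevation over a median-filtered baseline); prevalences are integer
percents and group contrasts are percentage-point differences. Percent
transmission loss is `100·(1 − T/I)` at 365 nm, 940 nm or 380–760 nm.

**Optokinetic response** (`zfo.okr`). Nystagmus traces (96 frames/s, 20 °/s
drum) are segmented into fast and slow phases by a velocity criterion; gain
= slow-phase eye velocity / drum velocity; eye-tracking movements (ETMs)
are counted per 10-s interval by direction; spatial acuity follows the
ascending staircase from 0.15 cpd in 0.05 cpd steps with a ≥3-consecutive-
cycles-in-both-directions positivity rule and a verification repeat.

**ERG** (`zfo.erg`). Baseline correction over the 50 ms before the first
stimulus, point-wise averaging of the (two) onset-aligned epochs, maximal
B-wave amplitude in a post-onset window, optional normalization per mm body
length.

**Statistics** (`zfo.stats`). Because both eyes of a fish are measured, the
model of record is the random-intercept linear mixed model

```
y_ij = β0 + β1·I(mutant_i) + u_i + ε_ij,   u_i ~ N(0, σ_u²),  ε_ij ~ N(0, σ²)
```

fitted by REML (genotype fixed, fish random); wild-type controls are first
size-matched to within 10% of the mean mutant body length, ages are
analyzed cross-sectionally, and heteroscedastic multi-group outcomes use
Welch's ANOVA.

**Synthetic data** (`zfo.synthetic`). Deterministic, seeded generators for
layered-eye OCT phantoms (optical-path geometry, speckle), pupil gradients
(including bifocal/absent variants), sawtooth nystagmus traces, biphasic
difference-of-gamma ERG templates, lens disks with concentric nuclear
rings (optionally solved to a target opaque fraction), and two-eyed cohorts
with genotype effects and random intercepts.

## Worked example

```python
from zfo import synthetic as syn, stats
from zfo.oct import compute_biometry, segment_axial_boundaries
from zfo.designs import PHANTOM_EDGE_SIGNS

# OCT: segment a speckled phantom and recover its biometry
bscan, truth = syn.generate_bscan(syn.EyePhantomSpec(speckle=0.05, seed=1))
seg = segment_axial_boundaries(bscan, prior=truth.attrs["boundaries_px"][:6],
                               signs=PHANTOM_EDGE_SIGNS)
biom = compute_biometry(seg)
print(f"axial length: {biom.axial_length_um:.1f} um "
      f"(designed {truth.attrs['axial_length_um']:.0f} um)")

# stats: recover a -47 um genotype effect from a 20-fish-per-group cohort
cohort = syn.generate_cohort(syn.CohortSpec(genotype_effect=-47.0, seed=1))
fit = stats.fit_random_intercept_lmm(stats.size_match_controls(cohort))
print(f"genotype effect: {fit.beta1:.1f} um (SE {fit.se:.1f}, p={fit.p_value:.2e})")
```

prints

```
axial length: 1006.7 um (designed 1007 um)
genotype effect: -44.3 um (SE 4.7, p=4.47e-21)
```

The recovered axial length is within one pixel-equivalent of the designed
1007 µm (cornea 22 + anterior chamber 5 + lens 500 + vitreous 300 + retina
180), and the fitted fixed effect sits within one standard error of the
designed −47 µm for this single simulated cohort.

A command-line interface mirrors the library
(`zfo synth|oct|refract|lens|okr|erg|stats|run`, each with
`--config <yaml> --seed <int> --out <dir>`); every output directory gets a
manifest with parameters, seed and versions.

## Limitations

Phantoms and traces are idealizations (piecewise-constant reflectivity,
instantaneous saccades, single-template ERG); passing recovery tests shows
the analysis is correct for data matching its assumptions, not that it is
robust to every instrument artifact. See `docs/methods.md` for the full
model descriptions, parameter defaults and design decisions.
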