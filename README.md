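# tpm — tissue phase mapping for the rodent heart

Post-processing for velocity-encoded (phase-contrast) cine CMR of the left
ventricle at high spatiotemporal resolution: from multi-coil nine-point
encoded complex images to per-pixel myocardial velocities, closed material
trajectories, segmental circumferential Lagrangian strain and regional
dyssynchrony indices, across 32 circumferential segments. It targets the
rat mid-ventricular short axis (128×128 over 50×50 mm, 3.2 ms frames,
venc 13.9 cm/s) and is intended for small-animal CMR groups building
regional-function analyses from tissue-phase-mapping acquisitions.

The core quantities: the coil-combined encoded phase
`φ_e = (π/venc)·M_e·v` is decoded to velocity by least squares; pixels are
tracked through the cycle by forward–backward integration blended for
exact closure; and strain in segment *s* follows the chord between the
adjacent segments' mean positions,

    Sc_s(t) = |x_{s−1}(t) − x_{s+1}(t)| / |x_{s−1}(t_ED) − x_{s+1}(t_ED)| − 1,

so that Sc_s(t_ED) = 0 identically for closed paths. Radial velocity is
reported **contraction-positive**. Two acquisitions of the same slice with
the FOV rotated in-plane are processed independently and segment-wise
averaged after temporal normalization, attenuating phase-encode-direction
artifacts. A deforming-annulus phantom with closed-form velocity, contour
and strain ground truth generates all test data. See `docs/methods.md` for
the model, conventions, and accuracy floors.

## Worked example

Simulate the default dual-rotation phantom study, run the full chain, and
summarize:

```python
from tpm.phantom import PhantomSpec, simulate
from tpm.pipeline import process_acquisition, combine_runs
from tpm.metrics import compute_indices

bundle = simulate(PhantomSpec())          # two rotated, encoded acquisitions
runs = [process_acquisition(acq, ann)
        for acq, ann in zip(bundle.acquisitions, bundle.annotations)]
waveforms, strain, key, alignment = combine_runs(runs[0], runs[1])
indices = compute_indices(waveforms["radial"], strain, key)
for name, value in indices.as_dict().items():
    print(f"{name:35s} {value: .4f}")
```

prints

```
peak_global_radial_max_cm_s          2.5007
peak_global_radial_min_cm_s         -2.5007
peak_global_Sc_percent              -19.1549
dispersion_peak_motion_cm_s          0.0505
dispersion_peak_strain_percent       0.4327
coherence_motion                     0.9999
dispersion_motion_waveforms          0.0001
dyssynchrony_index_ms                0.0000
```

Read: the phantom contracts at up to 2.5 cm/s and reaches a peak global
circumferential strain of −19.2%, close to the analytic mid-wall −20%
(the residual is the documented rasterization/tracking floor at ~8 pixels
per segment). Because this phantom has no regional heterogeneity, the
dispersions are near zero, every segment's waveform correlates with the
global one (coherence ≈ 1), and the dyssynchrony index is ≈ 0 ms. The
hypokinetic preset (`tpm.phantom.mi_like_spec()`) flips every one of these
the way an infarcted heart does.

The same pipeline runs from the shell:

```
tpm phantom --config phantom.yaml --out study/
tpm run --config pipeline.yaml --out results/
tpm compare results_a/ results_b/ --out loa.csv
```

`tpm run` writes `waveforms.csv`, `strain.csv`, `indices.csv` and a
`run.log` with stage decisions and timings.

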