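# nirsync

Dyadic fNIRS hyperscanning analysis: from raw two-wavelength optical
recordings of interacting pairs to inter-brain synchrony statistics.

When two people interact — here, playing variations of Rock-Paper-Scissors —
the slow hemodynamic signals over their prefrontal and temporo-parietal
cortices can become weakly coupled.  `nirsync` implements the full analysis
chain used to quantify that coupling:

1. **Preprocessing** of raw intensities: heart-band channel QC, optical
   density, MARA-style spline motion correction (p = 0.99), zero-phase
   0.01–0.50 Hz Butterworth filtering, and modified Beer–Lambert conversion
   to HbO/HbR concentration changes.
2. **Wavelet-transform coherence (WTC)** between the paired subjects'
   channels — a Morlet continuous wavelet transform (omega0 = 6, 12
   sub-octaves per octave) with Gaussian-in-time / 0.6-octave-in-scale
   smoothing:

       R²(s,t) = |S(W_xy/s)|² / ( S(|W_x|²/s) · S(|W_y|²/s) )

   band-averaged over 0.05–0.16 Hz (Fourier periods 6.25–20 s) outside the
   cone of influence, per condition block and resting phase, yielding
   5 condition-level values × 16 channels per dyad.
3. **Pseudo-dyad permutation null**: each Subject 1 is re-paired with
   random Subject 2 partners from other dyads (1000 draws in the full
   profile) and the pseudo-pair coherence averaged — the "random pair"
   comparison level.
4. **Beta mixed-effects regression** on the coherence values:
   `WTC ~ pairing * condition * region + (1 + … | dyad)` with a
   logit-link beta likelihood (Laplace approximation, random-slope
   reduction on non-convergence), likelihood-ratio effect tests, and
   Tukey-adjusted contrasts of estimated marginal means.

Because raw hyperscanning data of this kind are not publicly deposited, the
package includes a forward **simulator** that generates complete dyadic
sessions — montage, schedule, physiological noise, motion artifacts, and a
controllable condition- and ROI-dependent shared hemodynamic component — so
the whole pipeline is testable end to end with known ground truth.

## Worked example

Simulate six dyads at desk scale, run the permutation null, and fit the
control analysis:

```python
from nirsync import (build_montage, build_schedule, simulate_dyad,
                     make_pairing_plan, null_coherence)
from nirsync.preprocess import preprocess_recording
from nirsync.inference import control_spec, fit_beta_glmm, lr_effect, emmeans_contrasts

montage = build_montage("mini-8")                      # 8 channels, 2 per ROI
schedule = build_schedule(1, trials_per_block=6, rest_s=30.0)

hb = {}
for i in range(6):
    raw1, raw2 = simulate_dyad(montage, schedule, seed=100 + i)
    hb[f"d{i:02d}"] = (preprocess_recording(raw1), preprocess_recording(raw2))

plan = make_pairing_plan(list(hb), n_permutations=50, seed=0)
table = null_coherence(hb, plan, schedule, min_part_s=40)
print(table.groupby(["condition", "pairing"])["wtc_value"].mean().unstack().round(3))

table = table.rename(columns={"roi": "region"})
spec = control_spec()
fit = fit_beta_glmm(table, spec)
test = lr_effect(table, spec, "pairing:condition", full_fit=fit)
print(f"pairing x condition: chi2({test['df']}) = {test['chi2']:.2f}, p = {test['p']:.2g}")
print(emmeans_contrasts(fit, "pairing", by="condition")[["by", "estimate", "t", "p_adj"]].round(3))
```

Output:

```
pairing              original  random
condition
Control                 0.447   0.434
FreePlay                0.679   0.455
PredictionDifferent     0.515   0.396
PredictionSame          0.512   0.397
Rest                    0.559   0.522
pairing x condition: chi2(16) = 148.34, p = 1.7e-23
                 by  estimate      t  p_adj
            Control     0.046  0.772  0.441
           FreePlay     0.972 15.914  0.000
PredictionDifferent     0.475  8.034  0.000
     PredictionSame     0.459  7.761  0.000
               Rest     0.151  2.566  0.011
```

Reading this: mean coherence of true pairs exceeds that of random pairs in
every interactive condition (largest during Free Play, where the simulated
coupling is strongest), while the Control condition — in which players act
alone and the simulator couples nothing — shows no original-vs-random
difference (p = 0.44), and the resting phases show only weak residual
coupling.  The pairing × condition likelihood-ratio test picks
up exactly this pattern.  Note that raw coherence differs across conditions
partly because record length biases WTC; that is why all inference is
against pseudo-dyads with the identical segment structure.

The same pipeline is scriptable from a shell:

```sh
nirsync show-config --profile full      # all defaults (full study design)
nirsync simulate  --profile test --seed 1 --out run/   # SNIRF files + truth sidecar
nirsync preprocess --out run/
nirsync coherence  --out run/
nirsync permute    --out run/
nirsync fit        --out run/
nirsync report     --out run/           # box plots by condition and pairing
```

or in one go: `nirsync run --profile test --seed 1 --out run/`.

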