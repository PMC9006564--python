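# rfrad — RF-ultrasound radiomics analysis

`rfrad` implements a radiomics pipeline that works directly on raw
radiofrequency (RF) ultrasound echoes instead of display images.  It is
aimed at quantitative-ultrasound researchers who want to test whether
RF-derived parameter maps carry diagnostic information that is destroyed
by B-mode processing — e.g. predicting an immunohistochemical marker of
a liver lesion from a pre-operative scan.

Because no patient RF data are publicly available, the package ships a
first-class synthetic phantom generator, so every stage of the pipeline
is exercised and tested end-to-end with known ground truth.

## The method

From the RF samples of a lesion ROI (axial samples × A-lines, 32 MHz
sampling, c = 1540 m/s assumed), three parameter maps are computed with
sliding gated windows:

* **DEA** (direct energy attenuation, dB/m) — two 64-sample gated
  windows separated by a 16-sample interval; with average spectral
  energies E₀ (upper) and E₁ (lower),

      DEA = 10·log₁₀(E₀/E₁) / (D·c/fs/2),    D = 64

  the denominator being the depth spanned by one window (1.54 mm).
* **SSD** (skewness of spectrum difference, dimensionless) — the third
  standardised moment, S = m₃/m₂^{3/2} with population moments, of the
  elementwise difference between the magnitude spectra of two 64-sample
  windows separated by a 40-sample interval.
* **NRD** (Rician noncentrality, amplitude units) — the
  maximum-likelihood noncentrality parameter s of the Rician density
  p(x) = (x/σ²)·exp(−(x²+s²)/2σ²)·I₀(xs/σ²) fitted to the envelope in a
  sliding 37 × 8 block; s ≈ 0 under fully developed speckle and grows
  with coherent scattering.

Each map (and each of its four single-level wavelet subbands) yields 69
texture features — 16 histogram, 13 GLCM/Haralick, 22 GLRLM, 13 GLSZM,
5 NGTDM — i.e. 345 features per map and 1035 for the three-map model.
Features are ranked by their sparse-representation coefficients (SRC):
the label vector is approximated as a sparse combination s = Φβ of the
standardized feature atoms via orthogonal matching pursuit, and |β|
orders the features (off-support features follow, ordered by absolute
correlation).  An RBF-kernel SVM (C = 0.8, γ = 1) is trained on the top
k features for k = 1…K and evaluated by leave-one-out cross-validation
(ROC/AUC with bootstrap CI, ACC/SENS/SPEC, precision-recall with
break-even point, ANOVA on the per-patient scores).  Four model
variants are compared: GM (grayscale B-mode ROI), DM (DEA), DSM
(DEA+SSD) and DSNM (DEA+SSD+NRD).

## Worked example

```python
import numpy as np
from rfrad import (PhantomSpec, simulate_rf, crop_roi,
                   compute_dea_map, compute_nrd_map)

# a tall phantom with 0.7 dB/(cm·MHz) attenuation: DEA recovery
spec = PhantomSpec(shape=(2000, 48), lesion_shape=(1900, 44),
                   attenuation=70.0, seed=0)
frame, roi = simulate_rf(spec)
rf, mask = crop_roi(frame.samples, roi)
dea = compute_dea_map(rf, mask, c=frame.c, fs=frame.fs)
print(f"DEA median: {np.median(dea.values[dea.valid]):.0f} dB/m")

# a lesion with a coherent component of twice the diffuse RMS: NRD recovery
spec = PhantomSpec(attenuation=0.0, coherent_amp=2.0, seed=0)
frame, roi = simulate_rf(spec)
rf, mask = crop_roi(frame.samples, roi)
nrd = compute_nrd_map(rf, mask)
print(f"NRD median: {np.median(nrd.values[nrd.valid]):.2f}")
```

prints

```
DEA median: 286 dB/m
NRD median: 2.16
```

The DEA median sits near the value the estimator assigns to a 70
dB/(m·MHz) decay at 3.5 MHz: the energy log-ratio spans the 80-sample
window separation while the normalising depth is one 64-sample window,
so the estimate is (80/64)·α·f₀ = 306 dB/m.  The NRD median recovers
the planted coherent amplitude 2.0 within ~8% on a single phantom
(~3% pooled over seeds).

The full pipeline over a synthetic 40-patient cohort:

```bash
rfrad run --out results/
```

produces `summary.csv` with one row per variant (AUC/ACC/SENS/SPEC in
percent, chosen feature count, bootstrap CI), per-variant feature
tables (345/345/690/1035 columns), SRC rankings and ROC/PRC curves.
At the default study conditions the RF-map variants improve with map
count, with DSNM highest — mirroring the qualitative trend expected
when each map carries complementary information.

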