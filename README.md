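# aslpower

**Voxel-wise white-matter PCASL power analysis: how long until a WM voxel's
perfusion signal is significant?**

Arterial spin labeling (ASL) measures perfusion by magnetically labeling
arterial blood and subtracting labeled from control images. In cerebral
white matter (WM) the per-pair difference signal sits near the noise floor:
WM perfusion is 2–4× below gray matter and arterial transit times are
longer, so the label decays (T1 of blood ≈ 1.65 s at 3T) before it arrives.
Detection is therefore a question of *averaging*: with N label/control
pairs the paired t-statistic for a voxel with mean difference u and
difference s.d. σ grows as

    T = u · √N / σ,

so each voxel crosses a significance threshold at some number of signal
averages (NSA) — or never. This package implements that analysis as a
tested, reusable pipeline for background-suppressed PCASL:

- **`synthetic` generator** (`phantom`, `simulate`): a layered digital head
  phantom (GM shell, WM core, ventricle-like CSF, mixed-tissue interface
  voxels) driven by the single-compartment PCASL kinetic model, with
  per-volume Gaussian noise, slice-dependent residual static signal, a
  configurable fraction of non-responding WM voxels, and a matched
  single-inversion-recovery (SIR) volume for segmentation. Everything is
  deterministic given one seed.
- **`prep`**: label/control splitting and control − label subtraction;
  scan-time bookkeeping (NSA ↔ minutes).
- **`significance`**: one-tailed paired t-tests on every cumulative prefix
  of the difference series (running-sums engine, linear cost per voxel),
  significant-fraction curves at α = 0.05 / 0.01, uncorrected or
  Bonferroni-corrected over the WM mask, per-voxel time-to-significance
  maps, and non-responder detection (t < 0 at every NSA).
- **`masking`**: WM segmentation from the SIR volume by intensity banding,
  and the three-way split into periventricular (one-voxel expansion of the
  ventricles), peripheral (WM bordering GM) and deep WM.
- **`models`**: normalized t-histograms on the fixed range [−10, +50] as a
  function of NSA, sample skewness, competitive fits of
  percent-significant-vs-NSA to y = a(1 − e^(−bx)), y = a·ln x and the
  fractional (Michaelis–Menten) form y = ax/(b + x) with 95% CIs, and the
  through-origin √NSA fit of mean WM t.
- **`pipeline` / CLI**: end-to-end orchestration with CSV/NIfTI/JSON
  outputs and a provenance record (config, seed, versions, SHA-256 of
  every output).

Four built-in acquisition presets `exp1`–`exp4` cover labeling-duration /
post-labeling-delay combinations of 1650/1500, 1650/2000, 2150/1500 and
2150/1000 ms (TR 3500 or 4000 ms, 400 pairs; 46.6 or 53.3 min per run).

## Worked example

```python
import numpy as np
from aslpower import *

tmap = sample_tissue_map(seed=1)                  # 32×32×8 phantom
proto = get_protocol("exp3")                      # LD/PLD 2150/1500, TR 4000
series, sir = simulate_series(tmap, proto, seed=1)
diff = split_and_subtract(series)                 # control − label
masks = build_masks(sir)
print(masks.counts())

grid = np.concatenate([[2], np.arange(20, 401, 20)])
tc = t_curves(diff, grid)
sc = significant_fraction(tc, masks.full_wm, alpha=0.05)
for nsa, f in zip(sc.nsa_grid[:5], sc.fraction[:5]):
    print(f"NSA {nsa:3d}  {nsa_to_minutes(int(nsa), proto):5.2f} min  {100*f:.1f}%")

best, cands = fit_response_curve(sc.nsa_grid, 100 * sc.fraction)
print(best.model, best.params)
```

prints

```
{'full': 2538, 'periventricular': 238, 'peripheral': 470, 'deep': 1830}
NSA   2   0.27 min  8.5%
NSA  20   2.67 min  48.2%
NSA  40   5.33 min  70.8%
NSA  60   8.00 min  82.9%
NSA  80  10.67 min  87.7%
exp_recovery {'a': 93.87186219251478, 'b': 0.03547389830820241}
```

Reading: of the 2538 segmented WM voxels, 71% show a significant ASL
signal after about 5 minutes of averaging and 94.2% after the full 53-min
run; the fitted response curve is asymptotic with a plateau just below
94% — the phantom was generated with 6% of WM voxels not responding at
any NSA, and the fitted asymptote recovers that ceiling. Which of the
three asymptotic models wins is data-dependent; on noiseless
fractional-model data the fractional fit is recovered exactly
(a, b to 10⁻⁶).

The same analysis from the shell:

```bash
aslpower simulate --protocol exp3 --seed 1 --out-prefix sim
aslpower prep --input sim_series.nii.gz --out diff.nii.gz
aslpower masks --sir sim_sir.nii.gz --out-prefix masks_
aslpower significance --diff diff.nii.gz --mask masks_full.nii.gz \
    --alpha 0.05 --grid 20 --out curves.csv --map tts.nii.gz
aslpower respmodel --curves curves.csv --out fit.json
aslpower run --config run.yaml          # everything, with provenance
```

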