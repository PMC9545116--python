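# qsmme — multi-echo combination strategies for QSM

Quantitative susceptibility mapping (QSM) recovers the tissue magnetic
susceptibility χ (in ppm) from the phase of multi-echo gradient-recalled
echo (GRE) MRI. The phase at echo time TE follows

    φ(r, TE) = γ · ΔB_tot(r) · TE + φ0(r),

with γ the proton gyromagnetic ratio, ΔB_tot the χ-induced field
perturbation and φ0 a TE-independent offset. Turning φ into χ requires
phase unwrapping, background-field removal (here SHARP, via the discrete
Laplacian with truncated inversion), and an ill-posed dipole deconvolution
(here closed-form Tikhonov regularization, D(k)/(D(k)² + α), with the
L-curve choice of α and a calibrated correction for regularization
shrinkage). An open practical question is **when** the echoes should be
combined. This package implements and compares the four standard answers
on synthetic head phantoms with known ground truth:

| pipeline    | combination stage |
|-------------|-------------------|
| `nlfit`     | nonlinear complex fit of ΔB_tot and φ0 over TEs, *before* any Laplacian processing |
| `te-wavg`   | per-echo Laplacian unwrapping, then TE-weighted phase averaging (w_i ∝ TE_i) |
| `snr-wavg`  | per-echo SHARP, then SNR-weighted averaging (w_i ∝ TE_i e^(−TE_i R2\*)) |
| `susc-wavg` | per-echo SHARP + inversion, then magnitude-weighted χ averaging (w_i ∝ M_i² TE_i²) |

It also implements the matching analytic noise theory — per-echo phase
noise σ(φ) = σ(M)/M, closed-form noise of each combined field, and
propagation through the inversion to σ(χ) maps — together with a
Monte-Carlo driver that validates every analytic map by rerunning entire
pipelines on independent noise realizations, and the evaluation layer
(RMSE, regional statistics, line profiles, Bland–Altman bias with a
|0.01| ppm negligibility threshold, Shapiro–Wilk-gated sign/t tests,
subject pooling).

Intended users: researchers developing or validating QSM processing
pipelines who need a controlled, fully synthetic test bed with exact
ground truth for fields, χ, and noise levels.

## Worked example

```python
import numpy as np
from qsmme import (default_head_phantom, build_phantom, attach_fields,
                   simulate_gre, run_pipeline, PipelineConfig,
                   rmse_percent)

spec = default_head_phantom((96, 96, 96), noise_sd=0.07, seed=42)
lv, gt = build_phantom(spec)          # labels + chi/M0/T2* ground truth
gt = attach_fields(gt, spec, lv)      # dipole fields (total/bg/local)
gre = simulate_gre(gt, spec, n_repeats=1)[0]

for name in ("nlfit", "te-wavg", "snr-wavg", "susc-wavg"):
    r = run_pipeline(gre, lv.brain_mask, PipelineConfig(pipeline=name))
    rmse = rmse_percent(r.chi.chi, gt.chi_true, r.eroded_mask, demean=True)
    vein = np.isin(lv.labels, [13]) & r.eroded_mask
    print(f"{name:9s} alpha={r.alpha:.3f} corr={r.correction_factor:.2f} "
          f"RMSE={rmse:.1f}%  vein chi={r.chi.chi[vein].mean():.3f} ppm")
```

prints (true venous χ ≈ 0.45 ppm):

```
nlfit     alpha=0.149 corr=3.39 RMSE=102.9%  vein chi=0.369 ppm
te-wavg   alpha=0.108 corr=2.86 RMSE=83.5%  vein chi=0.204 ppm
snr-wavg  alpha=0.108 corr=2.86 RMSE=83.7%  vein chi=0.219 ppm
susc-wavg alpha=0.079 corr=2.45 RMSE=81.6%  vein chi=0.210 ppm
```

Read: the nonlinear-fit pipeline carries the *noisier but unfiltered*
field into the inversion — its whole-brain RMSE is highest, yet its
venous mean is by far the closest to truth, because every
Laplacian-processed-then-averaged pipeline high-pass filters away part of
the high-χ vein signal before inversion. All pipelines underestimate χ to
some degree, as expected for regularized ill-posed inversion.

A command-line interface mirrors the library
(`qsmme simulate|run|preproc|invert|evaluate`); see `qsmme --help`.

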