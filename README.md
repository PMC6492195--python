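# cardiomoco

Respiratory- and cardiac-motion-corrected reconstruction for
simultaneously acquired **dual-phase coronary MR angiography (CMRA)**
and **cardiac PET**, driven end-to-end by a synthetic dynamic
heart/torso phantom.

Free-breathing cardiac PET-MR suffers from two motion sources:
respiration displaces the heart by ~10 mm (non-rigidly), and the
cardiac cycle contracts it. This package implements, and makes fully
testable without scanner data, a framework in which one ECG-triggered
MR acquisition per heartbeat samples a golden-step Cartesian spiral
interleaf in both mid-systole and mid-diastole, beat-to-beat 2D image
navigators (iNAVs) track the respiratory motion of the heart, and the
derived motion models correct **both** modalities:

* **MR** — iNAV template tracking → equal-count respiratory binning
  with 2-SD deep-breath rejection → translational k-space
  pre-correction → soft-gated iterative SENSE per bin
  (`argmin_I ||W_b(E I − K_b)||²`) → non-rigid bin-to-bin registration
  → motion-compensated reconstruction per cardiac phase by solving the
  generalized-matrix model `K_c = Σ_b S_bc E U_bc I_c` with a
  conjugate-direction solver using exact adjoints.
* **PET** — list-mode events dual-gated by cardiac phase (R-R/3 window
  around maximum contraction → systole) and the same respiratory
  windows → per-gate OSEM
  (`ρ ← ρ/(PᵀAᵀNᵀ1) · PᵀAᵀNᵀ[y/(NAPρ+r+s)]`) with the attenuation map
  warped to each gate → inverse-warped and summed
  (post-reconstruction registration) into one motion-compensated image.

A `phantom` module generates the study conditions: dual-phase anatomy,
FDG-like emission and attenuation maps, analytic ground-truth
deformations, a pseudo-periodic breathing trace with occasional deep
breaths, and the ECG trigger stream. Every stage is validated against
this ground truth. See `docs/methods.md` for the models, parameter
choices and limitations.

## Worked example

```python
from cardiomoco import PipelineConfig, run_pipeline

res = run_pipeline(PipelineConfig(seed=1))

r = res.cmra_rmse
print(f"CMRA RMSE ratio MC/NMC (heart ROI): "
      f"systole {r['mc_gt_systole']/r['nmc_systole']:.2f}, "
      f"diastole {r['mc_gt_diastole']/r['nmc_diastole']:.2f}")
print(f"PET sharpness  MC {res.sharpness['mc']:.1f} > "
      f"RespMC {res.sharpness['respmc']:.1f} > NMC {res.sharpness['nmc']:.1f}")
print(f"EF measured {res.lv_measured.ef_percent:.1f}% "
      f"(truth {res.lv_truth.ef_percent:.1f}%)")
```

prints (default phantom, seed 1):

```
CMRA RMSE ratio MC/NMC (heart ROI): systole 0.36, diastole 0.45
PET sharpness  MC 10.2 > RespMC 7.5 > NMC 4.3
EF measured 58.3% (truth 58.0%)
```

The motion-corrected CMRA reaches less than half the uncorrected
reconstruction error around the heart; PET myocardial sharpness
(wall-peak to blood-pool ratio along the motion axis) strictly improves
from no correction through respiratory-only to full dual correction;
and the ejection fraction measured from the corrected images matches
the phantom's programmed contraction.

The same pipeline is available from the shell:

```bash
cardiomoco run-all --seed 1 --out-dir out/
```

which writes NIfTI volumes (corrected/uncorrected CMRA and PET), CSV
tables (traces, bins, gate counts) and a JSON summary.

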