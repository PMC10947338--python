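# dosepred3d

Deep-learning 3D dose prediction and plan-quality assurance for female-pelvis
VMAT radiotherapy plans with a single 45 Gy / 25-fraction target level.

Knowledge-based planning uses models of prior treatment plans to predict the
dose distribution achievable for a new patient. The predicted volume then
drives plan quality assurance: if a clinically approved plan delivers
markedly more dose to an organ at risk (OAR) than the prediction says is
achievable, the plan is flagged and optimization objectives are extracted
from the prediction to guide replanning. `dosepred3d` implements that whole
workflow as a reproducible pipeline:

1. **Synthetic phantom cohort** (`dosepred3d.phantom`) — seeded ellipsoidal
   pelvis anatomies (PTV, bladder, bowel bag, rectum, femoral heads, kidneys,
   liver, spinal cord, L4/L5, pelvic bone, sacrum) with an analytic VMAT-like
   reference dose: homogeneous in-target with a bounded hotspot, exponential
   falloff `Rx·exp(−d/τ)` outside, and directional OAR sparing.
2. **Preprocessing** (`dosepred3d.pipeline`) — the 16-channel model input:
   CT clipped to [−1000, 1000] HU and rescaled to [0, 1], a target array
   carrying the prescription dose on PTV voxels, and 14 binary structure
   masks, all resampled to the dose grid (3 mm default).
3. **Model** (`dosepred3d.nn`, `dosepred3d.model`) — a 3D dense dilated
   U-Net trained on random cubic patches with the combined loss

   ```
   L = MSE(D_ref, D_pred) + 0.25·(|ΔD1%| + |ΔD95%| + |ΔD98%|)
   ```

   where `D_V%` is the minimum dose to the hottest V% of the PTV. Adam
   starts at lr 0.001 and halves after every 55 epochs without validation
   improvement (early stopping, ≤ 1000 epochs). At inference, overlapping
   patches (stride 16) from each of the three ensemble members are averaged
   voxel-wise, and the result is rescaled so its PTV D95% matches the
   reference plan (`D_norm = D_pred · D95_ref / D95_pred`).
4. **Plan evaluation** (`dosepred3d.metrics`) — DVHs, conformity index
   `CI = TV_RI / V_RI` at the 42.75 Gy reference isodose (95% of the
   prescription), homogeneity index `HI = D5%/D95%`, PTV percentage deltas
   `ΔD_V%(%) = (D_V%_pred − D_V%_ref)/D_V%_ref·100`, OAR `ΔDmean`/`ΔDmax`
   in Gy, voxel-wise mean difference in the body, and a paired two one-sided
   t-test (TOST) of mean-dose equivalence within a 1 Gy bound.
5. **Flagging and objective extraction** — plans whose prediction indicates
   achievable OAR sparing beyond configurable thresholds are flagged;
   max-dose and max-DVH point objectives are emitted at the predicted
   values, and dose-falloff planning structures are built by subtracting
   predicted isodose volumes from the body contour.

The network and its training loop are a compact pure-numpy implementation
(hand-written backpropagation, Adam), sized for CPU-scale experiments.

## Worked example

```python
import dosepred3d as dp
from dosepred3d.experiments import ScaledStudyConfig, run_scaled_study

result = run_scaled_study(seed=1, cfg=ScaledStudyConfig(n_models=1, max_epochs=20))
print(f"split sizes      : {result['split_sizes']}")
print(f"held-out MAE     : {result['holdout_mae_Gy']:.2f} Gy "
      f"({result['holdout_mae_pct_rx']:.1f}% of Rx)")
print(f"CI  pred / ref   : {result['ci_pred_mean']:.3f} / {result['ci_ref_mean']:.3f}")
print(f"HI  pred / ref   : {result['hi_pred_mean']:.3f} / {result['hi_ref_mean']:.3f}")
print(f"TOST p-value     : {result['tost_p_value']:.2e} "
      f"(equivalent={result['tost_equivalent']})")
```

prints (numbers from this exact invocation):

```
split sizes      : (32, 11, 11)
held-out MAE     : 1.05 Gy (2.3% of Rx)
CI  pred / ref   : 1.000 / 1.000
HI  pred / ref   : 1.100 / 1.027
TOST p-value     : 9.36e-09 (equivalent=True)
```

The split sizes are the largest-remainder 3:1:1 allocation of the 54-plan
cohort. The held-out mean absolute voxel error is computed inside the body
mask of the 11 test plans after D95 renormalization; CI/HI compare the
predicted and reference dose distributions on the PTV; the TOST p-value
tests whether predicted and reference body mean doses are equivalent within
1 Gy.

The same pipeline is available from the shell:

```bash
dosepred3d simulate --n-plans 54 --seed 1 --out runs/data --grid 48
dosepred3d train    --data runs/data --out runs/models --models 3
dosepred3d predict  --data runs/data --checkpoints runs/models --out runs/pred --patch-size 24
dosepred3d evaluate --data runs/data --pred runs/pred --out runs/report
dosepred3d flag     --data runs/data --pred runs/pred --out runs/report
# or everything from one config:
dosepred3d run-all  --config examples/run.yaml
```

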