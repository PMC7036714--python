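# canaliflow

Zonated bile-canaliculi mechanics and YAP mechano-transduction in the
regenerating liver lobule.

After a partial hepatectomy the remnant liver must transport the body's
essentially conserved bile-salt pool through a reduced canalicular
network. `canaliflow` implements the quantitative chain from that
observation to switch-like YAP activation, for computational biologists
studying liver regeneration and mechano-signalling:

1. **Zonal image quantification** — bile-canaliculi (BC) diameter and
   nuclear/apical marker intensities measured from 3D confocal-style
   stacks and binned into zones along the central-vein -> portal-vein
   (CV-PV) axis (18 zones for diameters with the boundary cell layer
   excluded, 10 zones for intensities).
2. **Biophysics** — a distributed-inflow Hagen-Poiseuille model of the
   canalicular network: isotonic water inflow `q_z = J_z / c_osm` per
   zone, serial drainage toward the PV outlet, pressure
   `dP = (128 mu / (pi d^4 N)) Q dx`, Laplace cortical tension
   `T_z = P_z d_z / 2` and membrane strain `eps_z = d_z/d_z0 - 1`.
   Secretion per remnant mass scales as `1/(1-f)` for resection
   fraction `f` under pool conservation.
3. **YAP model** — a 16-parameter mass-action/Michaelis-Menten scheme
   (synthesis, degradation, sensor-mediated (in)activation, cytoplasmic
   sequestration, nuclear-cytoplasmic shuttling; 7 species, 2
   conservation laws). Its quasi-steady state has a closed form; the
   normalized nuclear-YAP stimulus-response curve is sigmoidal with a
   tangent-at-inflection activation threshold.
4. **Fitting** — multi-start weighted least squares of the nine free
   parameters against long-format nuclear/total-YAP tables, with
   parameter-recovery experiments and honest reporting of
   non-identifiable rates.
5. **Synthetic data** — lobule phantoms (tube network + nuclei + apical
   shell, PSF blur, shot/read noise) and forward-simulated noisy
   measurement tables, so the whole pipeline is testable without any
   external data.

## Worked example

```python
import numpy as np
from canaliflow import biophysics as bp, hippo

# tension prediction for the regenerating liver (68% resection)
fold, mean, profile = bp.regeneration_tension_fold(resection_fraction=0.68)
print(f"mean apical tension fold-change (1.5 d post-PH): {mean:.3f}")

net = bp.CanalicularNetworkModel.baseline()
print(f"baseline CV:PV pressure ratio: {bp.solve_pressure(net).cv_pv_ratio:.1f}")

# stimulus-response curve of the YAP model at the reference parameters
params = hippo.HippoParams.reference()
curve = hippo.stimulus_response(params)
thr = hippo.activation_threshold(curve)
print(f"activation threshold (tangent method): {thr.value:.2f}-fold")
print(f"effective Hill coefficient: {curve.hill:.2f}")
```

prints

```
mean apical tension fold-change (1.5 d post-PH): 1.947
baseline CV:PV pressure ratio: 30.0
activation threshold (tangent method): 1.75-fold
effective Hill coefficient: 4.12
```

Reading: with the measured zonal diameters (untreated 1.96-2.27 um,
dilated to 2.40-2.61 um at 1.5 days) and the bile-salt load per remnant
tripled by a 68% resection, the model predicts apical cortical tension
roughly doubling across the whole CV-PV axis. Feeding that relative
stimulus into the YAP model, nuclear YAP stays at baseline until the
stimulus exceeds about 1.75-fold and then rises steeply (effective Hill
coefficient ~4): moderate fluctuations of bile-acid load are tolerated,
severe ones flip the switch.

The same chain is available from the shell:

```sh
canaliflow run --out runs/demo --seed 0      # simulate -> quantify ->
                                             # biophysics -> fit -> predict
canaliflow report runs/demo
```

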