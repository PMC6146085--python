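# chestwall

Chest-wall volumes, breathing pattern and ribcage-shape indices from
optoelectronic plethysmography (OEP) marker trajectories.

## The problem

In infants and children with ribcage-muscle weakness — spinal muscular
atrophy (SMA) being the archetype — the diaphragm is relatively spared while
the intercostal and accessory muscles fail. Two consequences are visible at
the body surface during quiet breathing:

* the **pulmonary ribcage** (the part of the ribcage apposed to the lungs)
  contributes little to the tidal volume, and in severe cases moves *inward*
  during inspiration (**paradoxical breathing**);
* over time the upper chest fails to grow, producing a **bell-shaped chest**
  — narrow at the apex, wide at the base.

Both can be quantified non-invasively and without any cooperation from the
child, from the 3D trajectories of passive markers placed on the anterior
trunk surface of the supine subject. This package implements that analysis
for clinicians and respiratory physiologists working with marker-based
acquisitions, together with a synthetic torso/breathing simulator that
provides exact ground truth for validation.

## What it computes

**Compartment volumes.** The anterior marker grid (36 markers from clavicles
to pubis by default) is triangulated and closed onto the bed plane; the
enclosed volume follows from the divergence (Gauss) theorem,
`V = (1/6) Σ_faces v0 · (v1 × v2)`. Transverse marker rows at the
xiphisternum and the lower costal margin split the chest wall into pulmonary
ribcage (RC,p), abdominal ribcage (RC,a) and abdomen (AB); the three
compartment volumes sum to the chest-wall volume exactly at every frame.

**Breathing pattern.** Within a stable quiet-breathing window (≥ 40 s,
chosen to minimise the variability of breath duration), the chest-wall trace
is segmented into breaths between end-expiratory troughs. Per subject:
respiratory rate `RR = 60 / mean(T_tot)`, tidal volume `V_T`, minute
ventilation `V_E = RR·V_T`, rapid and shallow breathing index
`RSBi = RR / V_T`, and the mean percentage contributions
`ΔV_RC,p (%V_T)`, `ΔV_RC,a (%V_T)`, `ΔV_AB (%V_T)` (they sum to 100%).
A negative mean pulmonary-ribcage contribution flags paradoxical breathing.

**Bell-shaped chest index.** The ratio of two frontal-view distances:
anterior axillary line to anterior axillary line at the sternal angle (of
Louis), over right to left 10th costal cartilage. Index well below 1 → bell
shape; near 1 → rectangular; well above 1 → inverted triangle (default class
bounds 0.85 / 1.15, configurable). A tape-measure mode accepts the two
distances directly, and the radiographic upper-to-lower ribcage ratio
(2nd-rib over 9th-rib transverse diameter) is provided as plain ratio
arithmetic.

## Worked example

Simulate a severe bell-chested subject with paradoxical breathing
(programmed bell index 0.75, pulmonary-ribcage contribution −5%), then run
the full analysis:

```python
import chestwall as cw

torso = cw.TorsoSpec(upper_width=0.135, lower_width=0.18)   # bell index 0.75
spec = cw.BreathSpec(rr=35.0, v_t=0.12, split=(-0.05, 0.10, 0.95),
                     rate_cv=0.04, noise_sigma=2e-4, seed=7)
traj, truth = cw.simulate_breathing(torso, spec)

report = cw.analyze_subject(traj, cw.default_layout(), subject_id="demo")
print(report.to_json())
```

prints (abridged):

```json
{
  "paradox": true,
  "pattern": {
    "RR_per_min": 35.597,
    "RSBi_per_min_per_L": 297.44,
    "V_E_L_per_min": 4.2603,
    "V_T_L": 0.11968,
    "dV_AB_pct_VT": 94.877,
    "dV_RCa_pct_VT": 9.8858,
    "dV_RCp_pct_VT": -4.7631,
    "n_breaths": 23
  },
  "shape": {
    "bell_index": 0.74957,
    "shape_class": "bell",
    "d_upper_m": 0.13493,
    "d_lower_m": 0.18002
  }
}
```

The programmed quantities are recovered through the whole pipeline: RR
35.6/min vs 35 programmed (the draw has 4% period variability), V_T 0.1197 L
vs 0.12, pulmonary-ribcage contribution −4.8% vs −5 with 0.2 mm marker
noise, bell index 0.7496 vs 0.75 — and the subject is correctly flagged as
paradoxical with a bell-shaped chest.

The same pipeline is available from the shell:

```sh
chestwall simulate cohort/ --n-per-group 10 --seed 1   # synthetic cohort
chestwall analyze cohort/SMA1_00.csv                   # one subject report
chestwall summarize cohort/ --out summary.csv          # group medians/IQR + Spearman
chestwall index 0.219 0.300                            # tape-measure mode
```

Trajectory files are plain CSV (one row per frame, `<marker>_x,_y,_z`
columns, a `# sample_rate_hz:` comment line); convert C3D acquisitions to
this dialect upstream.

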