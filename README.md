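# ivpglab

Intraventricular pressure gradients (IVPG) and diastolic echo indices from
color-M-mode velocity maps, with a synthetic rat-cohort generator.

## The problem

During early diastole the left ventricle (LV) generates a base-to-apex
suction gradient that pulls blood from the atrium. Color-M-mode
echocardiography (CMME) records the inflow velocity field v(s, t) along a
scanline from the mitral annulus toward the apex, and the relative pressure
field can be recovered from it non-invasively through the one-dimensional
Euler equation

```
∂P/∂s = −ρ (∂v/∂t + v ∂v/∂s),        ρ = 1060 kg/m³
```

Integrating along the scanline gives the intraventricular pressure
difference IVPD(t) = P(0, t) − P(L, t); normalising by the LV long-axis
length L gives the IVPG in mmHg/cm, split into a **basal** segment (first
third from the mitral valve, tracking left-atrial pressure) and a
**mid-to-apical** segment (remaining two-thirds, tracking active
relaxation), both normalised by the full length so that
`total = basal + mid_apical` exactly.

In small animals the heart rate is high, diastasis is short, and the early
(E) and atrial (A) inflow waves merge: **EA-separation → EA-half-separation
→ EA-fusion** (coded 1/2/3 for correlation analyses). This package provides
the whole analysis chain needed to study how that merging, and heart rate
itself, affect IVPG, E/E' and the E/E'-derived pressure estimates

```
LVEDP      = 17.1 + 0.19 · E/E'      (mmHg)
Pre-A LVDP = 6.97 + 0.30 · E/E'      (mmHg)
```

in a two-group design (sham-operated vs. hypertensive-cardiomyopathy rats),
including a synthetic cohort generator that reproduces the study structure
(group sizes 7/7/19 and 15/25/26, heart-rate-driven wave merging, preload
acting more strongly on E' than on E) so every stage is testable without
animal data.

## Worked example

```python
from ivpglab import synthetic, engine, patterns, stats, indices

cfg = synthetic.SimConfig(seed=0)
table, maps, truths = synthetic.generate_cohort(cfg)

res = engine.compute_ivpg(maps[0])
print(f"total {res.total_ivpg:.2f}  basal {res.basal_ivpg:.2f}  "
      f"mid-apical {res.mid_apical_ivpg:.2f} mmHg/cm")
print("pattern:", patterns.classify_map(maps[0]).name)

for var in ("basal_ivpg_mmhg_cm", "mid_apical_ivpg_mmhg_cm", "e_over_eprime"):
    r, p, n = stats.pearson_with_coded_pattern(table, var)
    print(f"r(pattern, {var}) = {r:+.3f} (p = {p:.3g}, n = {n})")

print("LVEDP at E/E' = 13.21:", round(indices.lvedp(13.21), 2), "mmHg")
```

prints

```
total 2.63  basal 1.59  mid-apical 1.04 mmHg/cm
pattern: EA_FUSION
r(pattern, basal_ivpg_mmhg_cm) = +0.289 (p = 0.00371, n = 99)
r(pattern, mid_apical_ivpg_mmhg_cm) = +0.155 (p = 0.124, n = 99)
r(pattern, e_over_eprime) = -0.316 (p = 0.00143, n = 99)
LVEDP at E/E' = 13.21: 19.61 mmHg
```

The first animal of the default cohort has a fused inflow; its total
gradient decomposes exactly into the basal and mid-apical parts. Across the
99-animal cohort the basal gradient correlates significantly with the coded
inflow pattern while the mid-apical gradient does not, and E/E' falls as
the waves merge — the qualitative fingerprint of the heart-rate/inflow
analysis this package implements.

The same stages are available from a shell:

```
ivpglab pipeline --seed 4 --out out/          # simulate + analyze
ivpglab ivpg --map out/R0000.ivm.csv          # gradients for one map
ivpglab classify --map out/R0000.ivm.csv      # inflow pattern for one map
```

## Layout

| module              | contents                                                         |
| ------------------- | ---------------------------------------------------------------- |
| `ivpglab.io`        | `VelocityMap` / cohort-table containers, versioned file formats  |
| `ivpglab.engine`    | Euler pressure engine: `ivpd_trace`, `ivpg_from_trace`           |
| `ivpglab.patterns`  | E/A peak detection and the separation/half/fusion rule           |
| `ivpglab.indices`   | LV mass (cube formula), E/E', LVEDP, pre-A LVDP                  |
| `ivpglab.synthetic` | velocity-field and cohort simulator (`SimConfig`, `generate_*`)  |
| `ivpglab.stats`     | two-way ANOVA, Tukey compact letters, Pearson vs. pattern code   |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
numerical choices.
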