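# Methods

## Pressure engine

The engine treats the CMME scanline as a one-dimensional inviscid flow and
evaluates the Euler momentum balance ∂P/∂s = −ρ(∂v/∂t + v ∂v/∂s) with
constant blood density ρ = 1060 kg/m³. Derivatives are central finite
differences in the interior and second-order one-sided differences at the
boundaries; the pressure difference IVPD(t) = P(0) − P(L) is the
trapezoidal integral of ρ(∂v/∂t + v ∂v/∂s) over the scanline, converted
from Pa to mmHg (÷133.322). Velocities are in m/s; the spatial axis is
converted cm → m and the time axis ms → s before differentiation. No
smoothing is applied by default; a Gaussian pre-smoothing option
(`smooth_sigma`, in grid samples) exists for noisy maps but is off so the
default operator is deterministic and checkable against closed forms
(uniform acceleration and a travelling sine; observed convergence is
second order in the grid step).

**Scalar reduction.** IVPD(t) is reduced to a scalar by taking its peak
inside the diastolic filling window (by default the whole cycle, which is
equivalent for maps that are quiescent during systole). Both segmental
values are read at that same instant, and all three are divided by the
*full* LV length. This choice — same-instant evaluation with full-length
normalisation — is what makes the decomposition exactly additive
(total = basal + mid-apical) at the scalar level as well as for the
traces; per-segment peaks or per-segment-length normalisation would break
that contract. The basal/mid-apical split at L/3 is snapped to the nearest
grid node and the snapped coordinate is recorded in the result rather than
silently interpolated. Multi-cycle maps are reduced per cycle (using the
stored cycle boundaries) and averaged, mirroring the practice of averaging
several consecutive heart cycles.

## Inflow-pattern classifier

Wave detection runs on the mitral-annulus row of the map (where pulse-wave
Doppler samples the inflow), one cycle at a time. Local maxima below 10%
of the filling peak are discarded; if two remain, the earlier is E and the
later is A. The trichotomy is operationalised with one explicit threshold:

* single maximum → **EA-fusion** (code 3);
* two maxima with inter-peak minimum ≤ 5% of the smaller peak →
  **EA-separation** (code 1);
* otherwise → **EA-half-separation** (code 2).

The field's definitions of these patterns are qualitative; the 5% valley
threshold and the 10% prominence floor are this package's explicit
operational choices, are reported in the classifier's output provenance,
and are settable. The per-animal label is the modal label across cycles,
ties broken toward the higher (more merged) code. The rule is monotone in
wave overlap: for fixed wave shapes, raising heart rate never decreases
the code.

## Echo indices

* LV mass by the cube formula, `0.8·1.04·[(LVIDd+IVSd+LVFWd)³ − LVIDd³] + 0.6`
  with dimensions in cm and mass in g. Whether a species-specific
  correction was used upstream of the reference values is unknown; the
  standard cube reading is implemented and flagged here.
* `E/E'` converts E from m/s to cm/s and averages the septal and free-wall
  ratios — the printed magnitudes (≈13–18) are only consistent with
  same-unit division.
* `LVEDP = 17.1 + 0.19·E/E'` and `Pre-A LVDP = 6.97 + 0.3·E/E'` are exact
  affine maps; rounding happens only at presentation. One published LVEDP
  cell (hypertensive group, fused inflow) is inconsistent with its own
  E/E' mean under this regression (19.85 expected vs. 19.61 printed, a
  likely copy of the sham cell); it is documented here and excluded from
  the reproduction checks.
* When the inflow is merged (fusion *and* half-separation), A and E/A are
  recorded as absent rather than imputed, matching how such cells are
  reported.

## Synthetic cohort generator

The generator produces the *structure* the analysis assumes, not a
hemodynamic simulation. Per animal:

1. Heart rate is drawn from the group × pattern cell's normal distribution
   (defaults are the published cell means ± SD, truncated to the observed
   anesthetized range 219–421 bpm). Cycle length is 60000/HR ms.
2. The base inflow trace is the sum of two raised-cosine (Hann) pulses: an
   E wave starting at the end of the non-filling (systolic +
   isovolumic-relaxation) interval and an A wave ending at cycle end, so
   diastasis = cycle − systole − E duration − A duration. Compact support
   makes exact separation achievable and the merging sequence sharp.
3. Wave overlap (merge fraction m = overlap / A duration, clipped to
   [0, 1]) acts as the preload surrogate: latent E' gains 25% per unit m,
   latent E only 5% (the E' coefficient is required to be strictly larger
   — preload affects E' more than E, which is what drives E/E' *down* as
   waves merge). The merged atrial wave is attenuated (×(1 − 0.5 m)):
   atrial contraction pushing an already-moving column adds less velocity
   than a free contraction, so a merged peak is not a naive linear stack.
   Merging also shortens the E wave by 15% per unit m — merged filling
   under elevated atrial pressure accelerates faster — which is the
   mechanism that raises the (basal-dominated) pressure gradient in merged
   patterns without inflating the velocity peak.
4. Each wave propagates apically at its propagation velocity with
   exponential amplitude decay exp(−s/λ). λ varies between animals
   independently of pattern (a relaxation property), which is what leaves
   the mid-to-apical gradient largely uncorrelated with the inflow pattern
   while the basal gradient tracks it.
5. Pattern-cell counts are enforced by rejection sampling on the actual
   classifier output (bounded by `attempt_budget`, with a clear error when
   the HR distribution is inconsistent with the wave durations), keeping
   the HR → pattern link causal rather than assigned.

Measurements are then taken the way a sonographer would: E is the diastolic
peak of the base trace (merged or not), A only exists for separated inflow,
E' is the peak of a tissue-velocity pulse train with the same timing, read
at two annulus sites with a small random asymmetry, and the pressure
gradients come from running the actual engine on the generated map, with
additive segment-level measurement noise (total kept equal to the segment
sum). Group effects are additive shifts for the hypertensive group:
+70 mmHg systolic pressure and +0.08 cm per wall.

**Defaults that are assumptions, not measurements.** Wave durations
(E 35 ms, A 38 ms), the non-filling interval (97 ms), propagation
velocities (350 / 280 cm/s), decay lengths (0.65 / 0.59 cm) and LV length
(1.6 cm) are not published for rats; they were chosen once so that (i) the
merging sequence spans the observed heart-rate range (separation below
~360 bpm, fusion above ~410 bpm at mean parameters, with between-animal
variability blurring the boundary), and (ii) the resulting gradients have
the reported basal-dominant proportions at plausible magnitudes
(total ≈ 1.8–2.1 mmHg/cm at mean parameters). The M-mode dimension
defaults (LVIDd 0.62 cm, walls 0.020 cm sham / 0.10 cm hypertensive) are
calibrated so the cube mass formula reproduces the observed mass range
(≈0.64 vs. 0.86 g); they are not anatomical references, and the
between-animal mass spread is consequently narrower than in real animals.

**What passing tests do and do not show.** The generator reproduces the
design (cell counts, classifier-consistent labels), the merging mechanism,
and the qualitative correlation structure (positive HR–pattern and
pattern–basal-IVPG correlations, E' rising more than E, E/E' falling,
mid-apical gradient near-independent). It does not emulate speckle noise,
aliasing, respiratory motion, anesthesia-depth effects or any feature of
vendor color-Doppler acquisition, so passing tests validate the analysis
chain, not the hardware-facing preprocessing. Published correlation and p
values derive from unreleased per-animal data and are *not* reproduction
targets; only their sign/ordering structure is.

## Statistics

Outcomes are compared by two-way factorial ANOVA (group × pattern). The
design is unbalanced; Type-II sums of squares are the default (the
conventional choice without a strong interaction), with Type I/III behind
a flag. The post-hoc is Tukey HSD (Tukey–Kramer for unequal n) over the
six group × pattern cells — matching tables whose superscript letters
annotate cells, not marginal factors — summarised by an insert-and-absorb
compact letter display whose letters are guaranteed consistent with the
pairwise decisions. Pearson correlations use the 1/2/3 pattern coding;
with an ordinal regressor the r is a relative measure, which is how it is
interpreted. No multiplicity correction is applied across outcomes
(matching upstream practice); this is a known limitation, not an
oversight. Degenerate inputs (zero-variance variables, cells with fewer
than two observations, single-group tables) raise or drop with explicit
warnings rather than propagating NaNs.

## Problem sizes

The default cohort is 99 animals on a 0.05 cm × 1 ms grid (33 × ~300
samples per map, two cycles), generated in well under a second. The
correlation-sign recovery check uses 500 animals per cell (3000 total,
maps discarded on the fly), a size at which the sign and ordering
assertions are stable across seeds while the whole suite stays fast.
Engine convergence checks use 32×128 → 128×512 grids on closed-form
fields.

## Known limitations

* The velocity model is kinematic (superposed travelling pulses), not a
  solution of the flow equations; convective effects are therefore mild
  and the engine's convective term is exercised mainly by the closed-form
  oracle fields.
* Ejection fraction is not modelled (no published formula to anchor it).
* The classifier thresholds (5% valley, 10% prominence) are operational
  choices; real pulsed-Doppler tracings with noise floors may need the
  smoothing hook and threshold tuning.
* Doppler dealiasing is out of scope; maps are assumed alias-free.
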