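# Methods

## Flux conventions and the partition

Net photosynthesis P_n (μmol CO₂ m⁻² s⁻¹) is signed: negative means the
leaf is a net CO₂ source. All respiratory quantities — photorespiration
R_p, day respiration R_d, total light respiration R_L = R_p + R_d, and
dark respiration R_n — are positive magnitudes. The partition rests on
three relations:

1. R_p = P_n(2 % O₂) − P_n(21 % O₂) at matched C_a and PAR
   (differential-O₂ method; 2 % O₂ suppresses Rubisco oxygenation).
2. ratio_i = (R_p,max − R_p,i)/R_p,max, the recovery ratio below the
   C_a of peak photorespiration and the inhibition ratio above it.
   R_p,max is taken as the maximum of the measured series (ties broken
   toward the lowest C_a), not from a fitted curve.
3. R_d,i = R_n,i · (1 − ratio_i): mitochondrial CO₂ is assumed to be
   recycled by the chloroplast with the same efficiency as
   photorespiratory CO₂, since both are released in the same cells.

`build_respiration_series` applies 1–3 per replicate (each replicate's
ratio comes from its own R_p series) and then averages, reporting
sample SDs (ddof = 1, NaN for n = 1). Negative per-replicate R_p values
produced by noise are kept in the averages to avoid truncation bias and
listed in a QC field; only the ratio computation floors them at zero,
because ratios outside [0, 1] are meaningless. The dark series used in
relation 3 defaults to the 21 % O₂ one and is configurable; O₂ level
has no systematic effect on R_n, and with the default generator the
choice is exactly immaterial. Ratios are evaluated only at measured
C_a levels; no interpolation between grid points is attempted.

## Model forms

Empirical forms carry an additive intercept R_p, so their value at
C = 0 is exactly −R_p; fitted on a 21 % O₂ curve that intercept
estimates R_L, on a 2 % O₂ curve R_d:

* rectangular hyperbola  P_n = αP_max·C/(αC + P_max) − R_p
* Michaelis–Menten       P_n = P_max·C/(C + K) − R_p
  (identical to the former under K = P_max/α; kept as a separate
  surface because users know it by name)
* modified rectangular hyperbola  P_n = a(1 − bC)/(1 + cC)·C − R_p,
  the only form able to bend over and decline at high CO₂.

The biochemical form is P_n = min(w_c, w_j, w_p)·(1 − γ*/C) − R_d with
the standard limitation branches w_c = V_cmax·C/(C + K_c(1 + O/K_o)),
w_j = J·C/(4C + 8γ*), w_p = 3·TPU. The compensation factor is read as
(1 − γ*/C) — the conventional form; a literal product (1 − γ*·C) would
be meaningless at large C. Kinetic constants are fixed, not fitted
(defaults K_c = 270 μmol mol⁻¹, K_o = 165 mmol mol⁻¹, γ* = 37
μmol mol⁻¹, O = 210 mmol mol⁻¹ at 21 % O₂ and 20 at 2 %): on a single
12-point curve only V_cmax, J, TPU and R_d are identifiable. Fitting
the biochemical form against C_a simply substitutes C_a for C_i in the
same expression. No temperature response of the kinetic constants and
no mesophyll conductance are modelled.

Derived quantities (CO₂ compensation point, realized maximum) are
computed numerically — sign-change bracketing plus Brent refinement and
a dense grid scan with bounded local polish — rather than from
closed-form expressions, so they work identically for all four forms.

## Fitting

`fit_model` minimizes Σ(P_n,obs − model)² with
`scipy.optimize.least_squares` (trust-region reflective) under
non-negativity bounds on all rate parameters. Bounds rather than plain
Levenberg–Marquardt: 12-point curves routinely offer negative-rate
local minima that LM happily returns. Eight multi-start candidates are
generated by log-normal perturbation (scale 0.35) of a heuristic guess
— respiration read off the lowest-C point, the initial slope off the
two lowest points, the plateau off the maximum rate — seeded from a
CRC32 hash of the curve data so refits are bit-identical with no global
RNG involved. The best-SSR candidate is polished once at tolerance
1e-15. For the biochemical form the min-of-three sits inside the
residual (no pre-assignment of limitation states); the multi-start
handles its non-smoothness. Points with C ≤ 1 μmol mol⁻¹ are excluded
from biochemical fits, whose compensation factor diverges at zero.
r² is plain 1 − SSR/SStot about the observed mean. Replicates are
fitted separately and their fitted parameters averaged downstream,
never pooled into one fit. Fewer than 5 usable points is an input
error; if no start converges the fit is refused rather than returned
partially.

## Trend regression

`fit_trend` is OLS (statsmodels) on a Vandermonde basis, degree 2 by
default for R_p and R_d — the minimal unimodal polynomial — and
degree 1 for R_n. Replicate means per C_a level are regressed, not
pooled replicates. n ≥ degree + 2 is required (equality would be
interpolation) and rank-deficient designs are rejected. The smoothed
extremum is the derivative root inside the data range; `peak_ca`
additionally reports the grid argmax (ties toward the lowest C_a) and
flags series whose maximum sits at an endpoint as monotone.

## Synthetic data generator

The generator emulates the measurement design the partition assumes:
12 C_a levels (0, 50, 80, 100, 150, 200, 380, 400, 600, 800, 1000,
1200 μmol mol⁻¹), 21 % and 2 % O₂, PAR 2000 (light) and 0 (dark),
n = 5 replicates, two default species profiles — wheat: R_p from 4.923
at zero CO₂ to a 12.307 maximum at 600 μmol mol⁻¹, R_n 3.862 → 1.453;
bean: R_p 4.686 → 11.673 at 1000, R_n 4.040 → 1.210 (all
μmol CO₂ m⁻² s⁻¹).

Ground truth per species: R_p(C_a) is a quadratic with its vertex at
the peak, anchored at its zero-CO₂ value and truncated below at that
value so asymmetric peak positions cannot drive it negative (the
truncation never engages for the default profiles); R_n(C_a) is linear
between its endpoints, identical at both O₂ levels; and R_d(C_a) is
**derived** as R_n·(1 − ratio) with the ratio computed from the R_p
profile — the same relation the pipeline inverts. This self-consistency
is deliberate: it is what makes the noiseless round-trip exact
(recovered R_p, R_d, R_n equal truth to ≈1e-15) and it reproduces the
qualitative behaviour of interest, an emergent unimodal R_d peaking
below the R_p peak (near 400 μmol mol⁻¹ for the wheat profile, range
≈ 0.58–2.86). An independently parameterized R_d would be incompatible
with the recycling relation and could not round-trip.

Observed fluxes pre-noise: P_n(21 %, light) = G − R_p − R_d,
P_n(2 %, light) = G − R_d, P_n(dark) = −R_n, with gross assimilation G
from a respiration-free modified-rectangular-hyperbola shape (defaults
chosen to give light-saturated net rates of ~15–25 μmol m⁻² s⁻¹ at high
CO₂, ordinary for these crops; an FvCB-shaped gross is available for
cross-model robustness). C_i = 0.75·C_a, a fixed ratio in the typical
C₃ range — no stomatal model is attempted. Noise is independent
homoscedastic Gaussian, sd 0.3 μmol m⁻² s⁻¹ (the order of the replicate
SDs the design targets), with an optional proportional term for
heteroscedastic experiments. Everything is driven by one
`numpy.random.default_rng(seed)`; identical seeds give bit-identical
datasets.

What the generator does **not** emulate — and hence what passing tests
do not establish about field data: replicate-to-replicate correlation
(replicates are independent), stomatal dynamics (the fixed C_i/C_a
ratio makes A/C_i fits a pure rescaling of A/C_a fits for the empirical
forms, so axis-comparison deviations vanish on synthetic data; the
axis comparison is exercised instead through reference fitted values
whose inputs are fully known), instrument drift, and leaf-temperature
or humidity effects.

## Numerical and design notes

* Problem sizes: the estimator-sanity test uses 200 Monte-Carlo
  replicates at noise sd 0.3 (median fitted R_p of the modified
  hyperbola within 5 % of truth) with 2 multi-starts per fit; the
  coverage test uses 100 seeds of the full design. Both are seeded and
  deterministic.
* The recovery/inhibition phase boundary places the peak level itself
  in the recovery (prefix) phase; its ratio is 0 either way.
* CSV I/O writes floats with `repr` and reads with pandas'
  `round_trip` parser, so datasets survive a write/read cycle
  bit-exactly. O₂ columns given in percent are normalized to fractions
  with a warning; instrument-style headers are bridged by a
  `column_map` rather than a bespoke parser per vendor format.
* The pipeline summary JSON contains no timestamps, so identical
  seed + config runs are byte-identical — the determinism contract is
  checkable by file hash.
* Known limitations: no confidence intervals on fitted parameters, no
  model selection criteria, no ANOVA-style inference across species;
  the package quantifies fluxes and deviations, not their significance.
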