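# Methods

This note documents the models and estimators implemented in `beadpk`, the
defaults and why they were chosen, the numerical conventions, and the known
limitations — in particular what the synthetic study generator does and
does not emulate about real dual-route (hepatic drug-eluting bead vs IV)
irinotecan pharmacokinetics.

## Data model and time convention

A profile is one (subject, phase, analyte) concentration-time series with
explicit below-LOQ censoring flags. The study design has four phases per
subject: two embolization (bead) cycles and two IV cycles, dosed ~24 h
apart within a cycle.

**The time origin of every phase is the completion of administration** —
end of embolization for the bead route, end of infusion for the IV route.
This is the clock the blood-sampling schedule is anchored to (the first
sample is drawn "at completion", t = 0) and the only clock on which
sub-minute IV Tmax values make sense. Its analytical consequence is
discussed under *Limitations*: exposure during the infusion itself is
unobservable.

Times are stored in hours; minute-based input is converted on read
(division by 60, no rounding). The CSV dialect is documented in
`beadpk.profiles`; round-tripping is bit-exact.

## Non-compartmental analysis

* **AUC(0-t)** — linear trapezoid over the quantifiable span (linear
  up/linear down; no log-trapezoid variant). BLOQ handling: censored points
  before the first quantifiable sample enter as concentration 0; embedded
  and trailing censored points are excluded, with no imputation. This is
  the conservative choice for data whose assay LLOQ is not published.
* **Terminal slope** — ordinary least squares of log10(concentration) on
  time; `β = slope × (−2.303)` and `T½ = 0.693/β`, using the printed
  decimal constants rather than ln-based ones so the reported formulas are
  reproduced verbatim (the difference is a relative 1.8 × 10⁻⁴ on β).
* **Window selection (λz policy)** — among candidate windows formed by the
  last m quantifiable points strictly after Tmax (m = 3 … all), the window
  with the highest adjusted R² wins, preferring windows whose slope is
  *conforming*: negative and statistically established, |slope| ≥ t_min ·
  SE(slope) with t_min = 2 by default. A profile whose best window is
  non-conforming gets no half-life — the same behaviour as excluding
  profiles with "insufficient or non-conforming data". An explicit time
  range can override the search; `t_min = 0` disables the precision
  requirement.
* **Extension to infinity** — `AUC(0-∞) = AUC(0-t) + C_last/k` with the
  observed last quantifiable concentration. A tail fraction above 20 %
  raises a quality flag; above 50 % (the extrapolated tail exceeding the
  observed area) the extension, and everything derived from it (nAUC, CL),
  is withheld as non-conforming. Without this validity cap a noisy,
  shallow terminal slope can send `C_last/k` arbitrarily high: the
  estimator has a heavy right tail precisely when k̂ → 0, and a single such
  profile dominates a 7-animal mean. Both thresholds are configuration
  values, not constants.
* **Dose normalisation** — linear-PK rescaling of AUC(0-∞) to a 174 mg
  reference dose, making routes with different absolute doses comparable.
* **Bioavailability** — `F% = 100 × nAUC∞(bead)/nAUC∞(IV)` computed per
  subject per cycle and then averaged (mean of ratios). Because the mean of
  ratios differs from the ratio of group means whenever exposures vary
  between animals, both conventions are reported, the former labelled "as
  published" since that is the convention the reference tables follow.
* **Summaries** — arithmetic mean, sample SD (n−1), CV% = 100·SD/mean; an
  n = 1 group reports SD = 0. Report tables round AUC to 2 decimals, k to
  3, T½/Cmax/Tmax to 1; computation keeps full precision throughout
  (including the dose entering CL).

## BSA dosing

`dose = 0.0734 × weight^0.656 × intensity` (porcine allometric surface
area, m², times mg/m²). Only the reporting layer rounds (1 decimal). The
reference dosing table also lists dispensed volumes implying a ~20 mg/ml
concentrate; volume conversion is deliberately out of scope.

## Compartmental models

Disposition is a two-compartment mammillary model parameterised by
(CL, V1, Q, V2) — clearance is the quantity the analysis reasons about —
converted internally to micro-constants k10 = CL/V1, k12 = Q/V1,
k21 = Q/V2 and hybrid constants α > β.

* **IV route**: exact constant-rate infusion solution (superposition of the
  bolus response), duration drawn per administration from 0.5–1.5 h.
* **Bead route**: superposition of (i) an immediate bolus of
  `bolus_fraction × dose` — drug displaced from the beads into the contrast
  suspension, observed to be 5–15 % of load — and (ii) first-order release
  of the remainder at `k_release` (default 0.219 h⁻¹). The embolized
  liver's reduced clearance is a route multiplier on CL (default 0.5).
  When `k_release` ≪ β the terminal slope of the bead curve equals
  `k_release` (flip-flop kinetics): the curve then shows an initial
  decline, a plateau/bump while release roughly balances elimination, and
  a slow release-governed tail.

Mass balance (∫CL·C dt = dose) holds exactly for both inputs and is tested
by adaptive quadrature. The near-degenerate case k_release ≈ α or β is
evaluated by its analytic `t·e^(−λt)` limit.

**Fitting** (`fit_model`) minimises Σ(log10 Cobs − log10 Cpred)² by bounded
nonlinear least squares on log-scale parameters with a seeded multi-start.
Note a structural identifiability limit: from a single bead curve the
release rate and the fast hybrid constant are exchangeable — a mirrored
parameter set with the two exponents swapped (and compensating amplitudes)
reproduces the concentrations exactly. Identifying which exponent is
"release" requires outside information (e.g. the same subject's IV phase)
or a constrained/near-truth start; the tests document both the recovery
from a near-truth start and the exact equivalence of the mirrored set.
Fitting two-compartment structure to one-compartment data correctly
degenerates (Q or V2 collapses, flagged when on a bound).

## Synthetic study generator

`generate_study` emulates the reference design exactly in structure:
7 subjects (6 standard + 1 dose-escalated), 2 cycles × {bead, IV} phases,
the printed sampling schedules (0, 2, 5, 10, 15, 30, 60, 90 min, 2, 3, 4,
6, 9, 12, 16, 20 h after embolization; the same plus 24 and 48 h after
infusion), parent + metabolite analytes, and BSA-computed IV doses from
drawn body weights.

Defaults (all configurable, `StudyDesignConfig`):

| parameter | default | basis |
|---|---|---|
| bead dose (standard / escalated) | 100 / 200 mg (135 mg at the escalated animal's second cycle) | dose levels of the design; the escalated animal reached stasis early on cycle 2 |
| IV intensity (standard / escalated) | 250 / 350 mg/m² | design dose levels |
| weight at cycle 1 | U(30.0, 33.5) kg | observed initial weights |
| weight gain to cycle 2 | U(4, 13) kg | observed per-animal gains |
| infusion duration | U(0.5, 1.5) h | "over 30–90 min" |
| bolus_fraction | U(0.05, 0.15) per administration | displaced-dose range |
| k_release | 0.219 h⁻¹ | the bead-phase terminal rate it must reproduce under flip-flop |
| bead CL multiplier | 0.5 | reduced clearance under embolization; makes the true exposure ratio 200 % |
| disposition CL | 495 ml/min | reported IV clearance |
| disposition V1, Q, V2 | 110 L, 550 ml/min, 200 L | calibrated, see below |
| LLOQ parent / metabolite | 10 / 0.12 ng/ml | plausible assay floors; chosen so metabolite samples straddle the limit |
| metabolite exposure ratio / delay | 10⁻³ / 0.25 h | ~1000-fold lower metabolite exposure |
| residual error | lognormal, CV 15 % | typical bioanalytical + PK variability |
| between-subject variability | lognormal CV 25 % on CL and V1 | typical preclinical IIV |
| cycle-2 clearance effect | 1.0 (off) | no cycle difference was reported; an optional multiplier exists |

The metabolite is phenomenological — a delayed, scaled copy of the parent
achieving the configured exposure ratio — not a mechanistic
carboxylesterase conversion model, for which no parameters are available.
Its low level against its LLOQ reproduces the reported behaviour: many
metabolite profiles fail the terminal fit and are listed as exclusions.

**Calibration of V1/Q/V2.** The disposition volumes were set — once,
before freezing, by simulating the full pipeline — so that the *measured*
outputs of the default study are centred on their targets: the
mean-of-ratios bioavailability distributes around 200 % (median ≈ 199 %
over replicate studies) and NCA clearance recovers the true CL up to a
known systematic below ~10 % (worst case ~15 % at the longest infusions).
That systematic exists because the sampling clock starts when the infusion
ends: drug eliminated *during* a 0.5–1.5 h infusion never appears in the
observed AUC, so measured CL is biased high by exactly that fraction. A
much slower disposition would shrink it, but then terminal slopes become so
shallow relative to the 15 % residual noise that the `C_last/k` tail
estimate destabilises; the default is the calibrated compromise.

Determinism: a single seed drives every draw; identical seeds give
byte-identical output files.

## What the generator does *not* emulate

The reported study combines features that no shared linear two-compartment
disposition with a clearance-only route effect can produce at once: a
measured bioavailability of ~200 % (requiring negligible elimination
during the infusion, i.e. slow kinetics), a bead profile fully below the
LOQ by 20 h (requiring a sustained decline ≥ ~0.2 h⁻¹, i.e. fast kinetics),
and an IV terminal half-life of ~6 h quantifiable to 48 h. Within this
model class those are mutually exclusive; the defaults prioritise unbiased
exposure and bioavailability recovery. Consequently, in the default
simulated study:

* simulated peak concentrations are lower than those reported (the high
  reported Cmax values together with their AUCs imply substantial
  elimination during the infusion, which is incompatible with an unbiased
  200 % exposure ratio on the post-administration clock);
* the simulated bead terminal slope (~0.04–0.05 h⁻¹) is disposition-governed,
  slower than the reported 0.219 h⁻¹, which is release-governed
  (flip-flop). The flip-flop regime itself is implemented and verified
  with a fast-elimination disposition in the model tests — it is just not
  the default study condition;
* bead profiles remain quantifiable at 20 h, so the reported
  "no overlap between bead and IV plasma levels" censoring pattern is not
  reproduced at the default LLOQ.

Passing tests on generated data therefore demonstrate correctness of the
estimators and the pipeline under a coherent linear-PK world, not that the
generator reproduces every observed feature of the animal data — the raw
animal concentrations were never published, and the printed group tables
cannot be regenerated from any data this package can lawfully construct.

## Numerical conventions and degenerate inputs

* Printed-formula constants 0.693 and 2.303 are used verbatim (not ln 2 /
  ln 10).
* Cmax ties break to the earliest time; candidate λz windows tie-break to
  the longer window.
* A profile needs ≥ 2 usable points for AUC, ≥ 3 quantifiable points after
  Tmax for a terminal fit, and parameters + 2 points for a model fit;
  failures are per-parameter flags, never fatal to the rest of the profile
  ("derived where possible").
* All-BLOQ profiles yield a result object whose fields are absent with a
  single flag.
* Empty studies analyse to empty reports without error.

## Known limitations

* The infusion-period exposure bias on CL and F is inherent to the
  post-administration time origin; a dose-clock AUC (sampling during the
  infusion) would remove it but does not match the design being emulated.
* The bead model's release rate is not identifiable from bead data alone
  (exponent-swap ambiguity above).
* No lactone/carboxylate speciation, no urinary/biliary recovery, no
  enzyme saturation, and no inferential statistics comparing routes — the
  analysis is deliberately the standard descriptive NCA set.
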