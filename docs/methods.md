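# Methods

## The triage problem

A qHTS campaign against paired kidney cell models asks one question per
compound: does it suppress the viability of cystic (*Pkd1*-null mouse, or
patient-derived ADPKD human) epithelial cells more than that of their
matched normal counterparts? Because every compound is screened as a full
titration, the unit of analysis is the concentration–response curve (CRC)
in percent activity, and all decisions are made on curve-level summaries
(curve class, AUC) rather than single-point readouts.

## Normalization and plate quality

Percent activity is the affine map anchored on intra-plate controls:
DMSO (neutral) wells map to 0, full-kill (positive) wells to −100, so
viability loss is negative. Control centers use the **median** of the
control wells — robust to the occasional failed control well — and control
spread uses the standard deviation, which is what the Z′ factor

Z′ = 1 − 3(σ₊ + σ₋)/|µ₊ − µ₋|

is defined on. A plate whose control centers coincide cannot be
normalized: its Z′ is reported as −∞, the plate is flagged, and its well
activities are set missing rather than propagated.

## Hill fit

Each titration (median across replicates; replicate spread retained for
diagnostics) is fit by the four-parameter Hill equation

a(c) = a₀ + (a∞ − a₀) / (1 + (AC₅₀/c)^h)

by bounded least squares. Parameter bounds keep fits physical:
a₀ ∈ [−30, 30] (baselines near the DMSO anchor), a∞ ∈ [−130, 30],
h ∈ [0.3, 8], AC₅₀ within one decade of the tested range. Optimization is
seeded by a coarse grid over (AC₅₀, h) — for fixed shape parameters the
model is linear in (a₀, a∞), so each grid node is a 2×2 solve — followed
by a trust-region refinement with an analytic Jacobian. If the refinement
exhausts its iteration budget the best iterate is still used (this happens
for flat or saturated curves where AC₅₀ and h are weakly identified); only
invalid solutions fall back to the grid seed with `converged = False`, in
which case downstream AUC uses the empirical points.

## Curve classes

The signed taxonomy (negative = decreasing response) is assigned by a
decision table with three fixed thresholds taken from common qHTS
practice: a 25-point inactivity band, an 80-point high-efficacy split, and
r² ≥ 0.9 for "high-quality" fits.

1. |efficacy| < 25 → **4** (inactive);
2. activity ≥ 25 points from baseline at *only* the top concentration →
   **−3** (this check precedes the asymptote classes because a steep Hill
   fit through single-point activity can reach r² ≥ 0.9);
3. r² ≥ 0.9 with both asymptotes observed inside the tested range (the
   fitted curve comes within 10% of the efficacy span of each asymptote at
   ≥ 1 dose) → **−1.1** / **−1.2** by the 80-point split;
4. r² ≥ 0.9 with a single observed asymptote → **−2.1** / **−2.2**;
5. otherwise → **5** (active but poorly fit).

## AUC

AUC is the trapezoidal integral of the fitted curve evaluated at the assay
concentrations with **unit spacing per dilution step** — not raw
log-concentration — so 7-, 8- and 11-point libraries share one scale and
the fixed cutoffs (−10/−20/−60/−100) apply uniformly; constant −100%
activity over an 11-point curve integrates to −1000. A clean inactive
(class 4 with every dose inside the inactivity band) is assigned AUC = 0
exactly, so ΔAUC against an inactive partner reflects only the active
curve.

## Hit calling

* **Murine differential** (per pair × readout): the *Pkd1*-null curve must
  be class −1.x/−2.x and ΔAUC = AUC(null) − AUC(wt) must fall below −10
  (primary, single replicate) or −20 (validation, triplicate). The
  wild-type AUC is subtracted unconditionally, whatever its class.
* **Two-stage triage**: the campaign design screens everything once,
  then re-screens primary hits in triplicate; a differential finding is
  confirmed only if the *same* cell pair and readout passes again in
  validation. The two stages see independent noise, which is what gives
  the triage its specificity: a false positive must survive two
  independent screens.
* **3D cyst activity** (CTG-3D readout): active ⇔ curve class ≠ 4 and
  AUC < −100. The imaging readout is not used for activity cutoffs
  because its plate quality is far weaker than the ATP readout's.
* **Human pairs**: for each of the 30 ADPKD × NHK combinations and each
  readout, a hit needs an ADPKD class of −1.x/−2.x, ΔAUC < −60, and
  baseline agreement — the difference of the absolute fitted
  zero-activities below 10 points (read literally as
  | |a₀(ADPKD)| − |a₀(NHK)| |). A pair counts if either readout passes
  (the combination rule across readouts is not prescribed; OR is the
  default, AND available via the call's cutoff arguments). A compound is
  flagged panel-wide with ≥ 6 hit pairs spanning ≥ 2 ADPKD and ≥ 3 NHK
  isolates.
* Boundary conventions: all cutoffs are strict inequalities; a Wilcoxon
  p exactly at 0.05 counts as "similar"; enrichment significance is
  p_adj < 0.05 (the literal "more than 0.05" reading is available behind
  `significant_if="greater"`).

## Panel similarity

Each isolate is summarized by its per-compound AUC vector; every unordered
pair is compared with the paired Wilcoxon signed-rank test. Zero
differences are dropped before ranking (Wilcoxon convention; the Pratt
variant is available), ties get midranks, and the null distribution of W⁺
is computed **exactly** up to 25 nonzero differences by convolution on the
doubled-rank lattice — midranks are half-integers, so doubling makes the
lattice integral. Beyond 25 the normal approximation with continuity and
tie corrections is used; the two agree to within 0.02 at the crossover.
No multiple-testing correction is applied across the 55 pairs, matching
how the comparison matrix is reported. Isolates sharing fewer than 5
compounds with a partner are excluded from that pair.

## Target enrichment

Per gene, a one-sided Fisher's exact test (hypergeometric upper tail) on
the 2×2 table of gene-annotation × hit status over the annotated screened
compounds, followed by Benjamini–Hochberg correction across genes.
Unannotated compounds are excluded from the counts and reported;
multi-target compounds count once per target. Genes backed by fewer than
two hit compounds are suppressed from display output but retained in the
full table.

## Cyst imaging

The sharpest z-plane per well is the one maximizing the variance of the
Laplacian response — a standard autofocus metric chosen as a fully
specifiable surrogate for proprietary ridge-texture filters, with the same
intent (defocus blur suppresses high-frequency energy). Ties break to the
lowest index. Segmentation estimates background as the plane median,
detects pixels deviating by more than 10% of background, closes and
hole-fills the mask (so an annulus and its lumen are one region), and
accepts a region iff area ≥ 3500 µm² and SBR ≥ 0.4. SBR is computed as
the mean *absolute* deviation from background over the detected pixels,
normalized by background: identical to |mean − background|/background for
one-signed regions, but it does not self-cancel on the mixed bright-rim /
dark-lumen geometry of a swelled cyst. Size-based analysis cannot
distinguish a solid aggregate from a swelled cyst of equal area; a lumen
flag is reported when annulus geometry is evident (an interior hole, or a
mix of brighter- and darker-than-background pixels), and this flag is a
diagnostic only — no decision rule consumes it.

## Synthetic campaigns

The generators emulate the campaign designs: 1,536-well plates with one
positive- and one neutral-control column, 11-point 1:3 titrations from
57 µM (lowest dose ≈ 0.96 nM), GF-AFC and CTG readouts, two null/wt mouse
pairs ("embryonic" and "postnatal"); 384-well 3D plates with 8-point 1:2
dilutions from 100 µM and a CTG-3D readout; an 11-isolate human panel
(5 ADPKD + 6 NHK). Plates follow the qHTS **inter-plate dilution series**:
the library is arrayed at one concentration per plate, so a titration's
doses come from different plates and control-estimation error is
independent across doses rather than shifting whole curves. Replicates
are separate plate series. Noise is multiplicative log-normal per well
(plate readers show signal-proportional noise) plus a log-normal
whole-plate factor (default CV 5%) that plate-wise normalization removes.

Planted categories and their defaults, chosen once as a realistic mix for
a repurposing library: 15% differential (5% per pair plus 5% both-pairs),
10% pan-active, 5% cyst-swelling-only, 70% inactive. Active compounds get
AC₅₀ log-uniform in 0.05–5 µM (well inside the titration), Hill slope
uniform in 1–2, saturating efficacy uniform in −100..−65; wild-type-side
efficacy of differential compounds is −5..0, enforcing an efficacy gap of
at least 60 points. Differential compounds draw their primary target from
a small disease-associated gene set so enrichment has signal to find. The
3D generator gives DMSO wells 30 swelled cysts of 8000 µm² on average;
cyst-swelling-only compounds suppress the swelled count with their own
dose response (saturating at −60..−90%) while leaving the ATP signal at
the DMSO level.

What the generator does **not** model — and what passing tests therefore
do not establish about real data: plate edge effects and dispenser
artifacts, compound fluorescence/luminescence interference, biphasic or
cytostatic responses, correlated compound-stock errors between cell
lines, inter-patient covariance structure beyond per-isolate sensitivity
multipliers, and cell aggregates in rendered images beyond the
disc/annulus idealization.

## Verification battery and problem sizes

The acceptance script and test suite run the whole chain at sizes chosen
to give stable statistics on a single CPU: 500-compound campaigns (one
noise-free, three at 10% CV) through the two-stage triage; 200 noisy
titrations for AC₅₀ recovery; 64 control wells per group for the Z′
closed-form check at 3% CV; 100/50/20 random instances for the
Wilcoxon/Fisher/BH enumeration oracles plus the full 35-cell 3D-rule truth
table; ten planted disks above and three below the segmentation margins;
1000 random hit assignments for the enrichment null. Every oracle is an
independent re-derivation (full sign enumeration, `math.comb`
hypergeometric tails, hand-rolled step-up), never a second call into the
code under test.

## Known limitations

* Curve-class thresholds (25 / 80 / r² 0.9 / 10% plateau proximity) are
  conventions; the class boundaries for marginal curves are sensitive to
  them.
* The AUC scale is fixed by the unit-per-dilution-step convention; AUCs
  from titrations with different dilution ratios are comparable only in
  step units, not in log-molar units.
* The exact Wilcoxon null treats midranks as exact values; with heavy
  ties at n ≤ 25 this is the standard but not unique choice.
* The imaging channel quantifies total cyst area only; it cannot separate
  fewer-but-larger from more-but-smaller cyst populations, and the lumen
  flag is geometric, not biological.
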