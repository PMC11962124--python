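# Methods

## The mitotic-entry network

The model describes the G2/M transition as a bistable switch in
CDK1-cyclin B activity. Six state variables are integrated (all
concentrations in arbitrary units, time in hours):

| state      | meaning |
|------------|---------|
| `cdc25`    | unphosphorylated Cdc25 |
| `cdc25pp`  | bi-phosphorylated (active) Cdc25; the mono-phosphorylated pool follows from conservation |
| `cycbcdk1` | active CDK1-cyclin B (`V_Cdk1`) |
| `wee1`     | active Wee1/Myt1 |
| `pp2ab55`  | active PP2A-B55 |
| `subp`     | phosphorylated CDK1 substrate (NEBD reporter) |

The Cdc25 and substrate equations are the two printed in the README.
PLK1 enters only there, as a CDK1-independent Cdc25 kinase with activity
`f_Plk1 · [CycACdk2_Tot]`; `f_Plk1` interpolates between fully active
(1) and completely inhibited (0) PLK1.

The remaining regulation (Tyr15/Wee1 control of CDK1, and PP2A-B55) is
not uniquely determined by the published equations, so it is
reconstructed here with mass-action forms chosen for transparency and
testability:

    d[CycBCdk1]/dt = (k_Cdc25,Cdk1·[Cdc25pp] + k_PPX,T14)·([CycBCdk1_Tot] − [CycBCdk1])
                     − k_Wee1,Cdk1·[Wee1]·[CycBCdk1]
    d[Wee1]/dt     = k_B55,Wee1·[PP2AB55]·([Wee1_Tot] − [Wee1])
                     − (k_Cdk1,Wee1·V_Cdk1 + k_CycA,Wee1·[CycACdk2_Tot])·[Wee1]
    d[PP2AB55]/dt  = k_B55,act·([B55_Tot] − [PP2AB55]) − k_Cdk1,B55·V_Cdk1·[PP2AB55]

Three regulatory motifs matter:

1. CDK1 → Cdc25 → CDK1 (positive feedback; the two-step Cdc25
   phosphorylation supplies the ultrasensitivity that makes it bistable);
2. CDK1 ⊣ Wee1 ⊣ CDK1 (double-negative feedback);
3. CDK1 ⊣ PP2A-B55 (the Greatwall/ENSA branch collapsed into a single
   inhibitory step — one state instead of three, because only the net
   CDK1-dependent suppression of B55 activity shapes the switch).

CDK2-cyclin A drives entry through two routes: via PLK1 onto Cdc25
(blocked by inhibitor) and via inhibitory phosphorylation of Wee1
(inhibitor-independent). The weak constitutive Thr14/Tyr15 phosphatase
activity `k_PPX,T14` gives CDK1 a small Cdc25-independent activation
route; without it a fully inhibited cell could never leave the ground
state. This combination reproduces the defining observation: with PLK1
inhibited, Cdc25 activation is slow, so CDK1 activity creeps up for
hours until the feedback becomes self-sustaining.

### Reduced mode

`Clamp(v_cdk1=…, pp2ab55=…)` holds CDK1 and/or PP2A-B55 activity
constant. With both clamped, the Cdc25 three-state chain and the
substrate equation are linear; the tests exploit this for closed-form
oracles (matrix exponential; `Sub_Tot·(1 − e^(−k·v·t))`, which crosses
the 30% threshold at `ln(10/7) ≈ 0.357` time units).

### Parameters and calibration

No published rate-constant table accompanies the printed equations (the
original constants were rescaled by an unspecified factor), so the
defaults shipped in `data/default_params.json` were calibrated with the
package's own tools (`scratch`-level scans of NEBD timing and of the
bistable window) against the stated behavioural targets:

- uninhibited entry (f_Plk1 = 1, CycA = 4 a.u.): NEBD ≈ 1.5 h after G2
  entry (target ~0.5–2 h);
- full inhibition at the same activity: NEBD ≈ 11.4 h (delayed by
  several hours but within the 24-h imaging horizon);
- upper saddle-node threshold `SN_upper` ≈ 0.23 a.u. at f_Plk1 = 1
  rising to ≈ 2.26 a.u. at f_Plk1 = 0, so the reference activity of
  4 a.u. sits comfortably above threshold when PLK1 is active and close
  enough to it under inhibition that delays stretch into hours
  (saddle-node ghost slowing).

All totals are 1 a.u. except `cyca_cdk2_tot` (default 4). Time unit:
hours, with G2 entry (the step in CycA) at t = 0; residual S-phase after
release is neglected.

### Numerics

- Integrator: LSODA (stiff-capable), rtol 1e-8, atol 1e-10; the NEBD
  threshold crossing is located by the solver's event machinery and the
  trajectory is reported on a 0.01-h output grid (population sweeps use
  0.05 h and terminate at the event).
- Initial condition: `cdc25 = cdc25_tot`, `cdc25pp = subp = 0`;
  CDK1/Wee1/PP2A-B55 are relaxed to their pre-G2 (CycA = 0) steady state
  with those pools pinned, so the start is an exact rest point of the
  pre-entry system — computed, never hard-coded.
- `detect_nebd`: linear interpolation between the bracketing output
  samples; default threshold 0.30.

## Bifurcation analysis

Fixed points are found by multi-start hybrid-Powell root finding (three
structured corners plus 17 seeded random interior starts), filtered to
the physical simplex, de-duplicated at relative 1e-6, and classified by
the eigenvalues of a central-difference Jacobian (|Re λ| < 1e-9 is
reported as indeterminate). Saddle nodes are bracketed on a 33-point
parameter grid and refined by bisection on the count of stable fixed
points to 1e-3 of the bounds width. Brute force was chosen over
pseudo-arclength continuation deliberately: at six states and one
parameter it is robust, trivially testable (every stable point is
re-verified by forward integration in the tests), and fast (~0.2 s per
scan).

## Population simulation

Cell-to-cell variability enters through `cyca_cdk2_tot` only; all rate
constants are shared. The default family is a normal distribution
truncated at zero by redrawing (lognormal and uniform alternatives are
selectable). Each of the 400 cells (the default population size) keeps
its sampled activity across the dose series f_Plk1 ∈ {1.0, 0.5, 0.1,
0.0} (0/50/90/100% inhibition); NEBD times are censored at the 24-h
horizon, mirroring the imaging window.

Three presets (`data/scenarios.json`) reproduce the three qualitative
dose-response regimes; they differ only in mean/SD of the activity
distribution and were placed relative to the calibrated full-inhibition
saddle-node (≈2.26 a.u., with the 24-h entry boundary at ≈2.8 a.u.):

| preset           | mean | sd   | regime |
|------------------|------|------|--------|
| `narrow`         | 4.0  | 0.15 | near-step curves, shifted by dose |
| `broad`          | 4.0  | 0.8  | delays plus hours-wide broadening |
| `broad_low_mean` | 2.6  | 0.8  | majority of cells censored at full inhibition |

## Imaging metrics

Segmentation and tracking are inputs (integer label images aligned to
intensity frames), not computed. Conventions: population SD (divide by
N); frames 0-based internally and 1-based in exports; origin top-left.

- **Condensation score** = SD(nuclear pixels) / (mean(nuclear pixels) −
  background). Division by the background-corrected mean cancels
  multiplicative bleaching exactly (verified on generated movies with
  bleaching on/off). Undefined (error, not NaN) when the mean does not
  exceed background.
- **N/C ratio**: cytoplasm ring = (nucleus dilated by a disk of radius
  10 px) ∩ (the nucleus's generalised-Voronoi territory, computed by
  nearest-label distance transform) minus all nuclei; background-
  subtracted nuclear mean over ring mean. Companion helper normalises
  series to the mean of the first 5 frames.
- **FRET ratio**: background-corrected YFP/CFP per nucleus per frame.
- **Eccentricity course**: second-moments ellipse eccentricity per
  frame, normalised to the mean of the frames within 10 min after NEBD
  (2 frames at the 5-min default interval). A near-circular
  normalisation window returns the raw series with an explicit
  `unnormalized` status instead of dividing by noise.
- **z-centroid**: Σ z·(masked integrated density at z) / Σ (masked
  integrated density), in z-step units (acquisition analogue: 8 steps,
  1 µm); normalised to the first 5 frames.
- **Foci count**: connected local maxima with topographic prominence
  above threshold (default 100), 8-connected, restricted to the mask
  (h-maxima reconstruction).
- **Cumulative NEBD**: percentage of the nuclei counted on the first
  frame with an NEBD event at or before each frame.

## Phosphosite pipeline

Input: per-(site, multiplicity) log2 intensities over 4 groups × 3
replicates laid out in three TMT sixplex batches, each batch carrying
one replicate of every group plus two pooled reference channels. The
groups encode the factorial design: treatment (DMSO vs BI2536) ×
fraction (attached = pre-NEBD vs suspended = post-NEBD), i.e. G2,
Prometa, ProPro, Polo.

Steps, in order:

1. **Site filters**: drop contaminant and reverse hits; drop
   localization probability < 0.75 (exactly 0.75 is kept).
2. **Valid-value rule**: per labeling batch, a site with < 70% observed
   values among that batch's non-reference channels is "not quantified"
   there (all its values in the batch are blanked, reference channels
   included); sites quantified in no batch are dropped. Reference
   channels are excluded from the 70% count — a documented choice, since
   the rule's operational scope is not fixed by the design.
3. **MNAR imputation**: per channel column, missing values are drawn from
   Normal(mean_obs − 1.8·sd_obs, (0.3·sd_obs)²) — the Perseus convention
   with width and downshift in units of each column's observed SD.
   Seeded; columns with < 2 observed values are a hard error.
4. **Median-polish normalisation**, per batch: alternating row/column
   median sweeps to convergence (tol 1e-6, max 100 iterations,
   non-convergence is a warning status); the removed column effect is
   the within-batch column effect plus the centred per-batch overall.
   Folding in the centred overall is what aligns batches — a constant
   batch offset lands in the polish's overall term, not in its column
   effects, and would otherwise survive normalisation and inflate
   within-group variances (replicates of a group span batches). For a
   single batch this reduces to plain column-effect removal. Row (site)
   effects are retained: this is a normalisation, not a decomposition.
5. **Internal-reference scaling** (optional, off by default): subtract
   per batch and site the mean of the pooled reference channels. With
   only two reference channels per batch, the subtracted profile carries
   σ²/2 of noise that is shared across a batch's samples; it cancels in
   balanced contrasts but inflates residual variances ≈1.5× and makes
   the moderated t conservative (measured: spiked-site sensitivity falls
   from ≈0.58 to ≈0.18). Since step 4 already aligns batch offsets, the
   default pipeline leaves it off; it exists for data with genuine
   site×batch interactions.
6. **Factorial fit**: per site, least squares on the four cell means
   (equivalently the group means in this balanced full-rank design);
   residual variance s² with d = n − 4 degrees of freedom. Rank
   deficiency (a missing group) and < 2 replicates per group are errors
   naming the offending cells.
7. **Variance moderation**: the s² are modelled as scaled-F around a
   prior (s0², d0) estimated by digamma/trigamma moment matching on
   log s²; the posterior variance is s̃² = (d0·s0² + d·s²)/(d0 + d) and
   the moderated t uses d + d0 degrees of freedom. If log s² shows no
   excess spread beyond χ² sampling noise, the prior is degenerate:
   d0 = ∞ and every s̃² equals the pooled mean variance. The
   implementation is verified against Bioconductor limma (lmFit +
   eBayes) to 1e-6 on t and p in the test suite — limma is the
   independent oracle there, never the implementation.
8. **Contrasts**: the interaction
   (ProPro − Polo) − (G2 − Prometa) = [BI.attached − BI.suspended] −
   [DMSO.attached − DMSO.suspended] isolates prolonged-prophase-specific
   sites; the four pairwise edges of the square are also reported.
   Two-sided p-values; Benjamini-Hochberg step-up adjustment within each
   contrast separately.
9. **Classification**: significant at adjusted p < 0.05; volcano-style
   labels additionally require |log2FC| > 0.5, while the pairwise
   up/down counts use sign only.

### Operating characteristics (what the tests do and do not show)

On null synthetic data (no group effects, no dropout, 2000 sites) the
interaction p-values are uniform (KS) and essentially no site passes
BH at 0.05. With 5% of sites carrying a 1.0 log2 interaction at
within-group SD 0.25, the observed FDR stays below 0.10 but sensitivity
is ≈0.6, not higher — and cannot be higher: the contrast's standard
error is √(σ²·4/3) = 0.289, giving a noncentrality of 3.46, and any
procedure achieving 0.9 sensitivity at these settings would need a
threshold admitting ≈0.38 FDR. The corresponding acceptance test states
the stronger sensitivity bound and is left failing rather than weakening
the condition or enlarging the effect size. With MNAR dropout switched
on, imputation additionally inflates the variances of low-abundance
sites and thereby the variance prior, further reducing power — the
statistical-property tests therefore run the generator without dropout,
while the imputation's own moment behaviour is verified separately.

## Synthetic data generators

- **Phosphosite tables**: log2 intensity = site baseline (N(20, 1.5²)) +
  batch effect (SD 0.3) + channel effect (SD 0.1) + signed half-effect
  parameterisation of the factorial design (so the injected interaction
  effect equals the interaction contrast exactly) + noise (SD 0.25).
  Reference channels receive the group-average shift. Dropout is
  logistic in the true intensity with midpoint at the 15th percentile
  and slope 1.5 per log2 unit (slope 0 disables it); exactly
  round(fraction·n) sites are spiked. The generator emulates the
  additive structure and MNAR missingness the pipeline assumes; it does
  not simulate reporter-ion interference, co-isolation compression, or
  peptide-level correlation between multiplicity rows, so passing tests
  speak to the statistics, not to MS artefact handling.
- **Movies**: nuclei are non-overlapping disks with Gaussian interior
  texture whose SD follows a per-frame schedule (the condensation ramp),
  a global exponential bleaching factor, constant background and
  optional camera noise; labels are exact by construction and NEBD is
  label disappearance. No optics/PSF: the metrics under test are
  statistics of labelled regions, not detection.
- All generators are pure functions of (spec, seed).

## Problem sizes

The shipped tests run the population acceptance check at the full 400
cells × 4 doses × 3 scenarios (≈20 s), the statistical checks at 2000
sites, and the imputation moment check at 2×10⁵ observed values; the
whole suite completes in under a minute on one CPU.

## Known limitations

- The auxiliary Wee1/PP2A-B55 submodel is a reconstruction; its rate
  constants are calibrated to behavioural targets, not measured, so only
  the qualitative structure (thresholds, delays, dose ordering) carries
  meaning — not absolute parameter values.
- No spatial/compartmental cyclin B dynamics (nuclear import is known to
  matter for the real transition) and no stochastic kinetics.
- The entry delay near the saddle node is sensitive to the activity
  distribution's tail; censored fractions should be read as
  regime-level, not quantitative, predictions.
- Multiplicity rows are treated as independent quantification units.
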