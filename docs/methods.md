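# Methods

## The screening model

The pipeline treats a pH titration observed by ¹H-¹⁵N correlation
spectroscopy as a set of per-residue trajectories δ(pH) = (δH, δN). A
single-site protonation event with Hill coefficient n produces

    δ(pH) = δ_base + (δ_acid − δ_base) · θ(pH),
    θ(pH) = 1 / (1 + 10^{n (pH − pKa)})

for every nucleus that senses the event, so both channels of a residue share
one pKa and one n; only the endpoint shifts differ. All classification and
fitting in the package assumes this single-site form. Multi-site titrations,
ring-current effects from neighbouring groups and temperature drift are not
modelled; on real spectra the group labels remain meaningful (they only ask
*where* along the pH axis the change concentrates) but fitted pKa values of
residues sensing several sites will be effective values.

### Peak tracking

Assignments are anchored at the lowest pH (where spectra are best resolved
and triple-resonance assignment is done in practice). Walking up the series,
each residue's position is predicted by linear extrapolation of its last two
points (copy of the single point if only one exists), and the nearest
unclaimed peak within the elliptical gate (ΔH/0.10)² + (ΔN/1.0)² ≤ 1 is
claimed, greedily in ascending normalized distance, one claim per observed
peak. The gate semi-axes are twice the significance thresholds. This greedy
scheme is not a globally optimal assignment; it is adequate when adjacent-pH
steps are small compared with peak spacing, which is the regime the
extrapolation-based assignment strategy presumes anyway. Peaks that carry an
explicit assignment in a higher-pH list are honoured before geometric
matching, so partially assigned spectra anchor the tracking.

A residue with no in-gate peak at some pH gets that pH recorded in
`missing_phs`; residues with any missing pH are reported as candidates for
intermediate-timescale exchange broadening. The pipeline cannot flag a
residue it has never seen: a residue invisible at every pH (fully broadened
loops) never enters the series, so the synthetic screen keeps such residues
visible in the acidic spectra and removes them from pH 5 upward.

### Significance and grouping

Significance uses the per-nucleus OR rule — ΔδH > 0.05 ppm or ΔδN > 0.5 ppm
between the series endpoints — with strict inequalities. The combined metric
√(ΔδH² + (α ΔδN)²) with α = 0.1 (the ratio of the two thresholds) is used
*only* for trajectory path lengths and reporting, never for the significance
call, so the two rules cannot disagree with themselves.

"Change mainly below/above pH 5" is operationalized as the path-length
fraction f_low: the α-weighted length of the trajectory over segments with
pH ≤ 5, divided by the total length from pH 3 to 7, with segments straddling
pH 5 split linearly in pH. Path length handles non-monotonic trajectories;
an endpoints-only mode (`use_path_length=False`) is available for
comparison. f_low > 0.5 gives group A, otherwise group B; an exact tie goes
to group B (the functionally relevant window), implemented with a 1e-9 guard
so floating-point asymmetry cannot flip a symmetric trajectory. For a
noiseless single-site trajectory every channel is proportional to θ, so
f_low has the closed form Σ|Δθ| ratios used as the independent oracle in the
tests. If no observed point lies strictly between the endpoints the fraction
is undefined and the residue gets group "none".

### pKa fitting

Bounded least squares (scipy `least_squares`) with pKa ∈ [2, 9], n ∈
[0.5, 2], free per-channel endpoints, ¹⁵N residuals weighted by α so both
channels contribute on a common ppm scale. The pKa start value is the
midpoint of the steepest observed segment. Fewer than 4 observed points, a
constant trajectory, or optimizer failure return an absent fit with a
reason, never an exception. The standard error comes from the Gauss-Newton
covariance at the solution.

## Structure mapping

Distances are heavy-atom minimum distances (hydrogens dropped, altlocs
resolved to highest occupancy) — CSP proximity reasoning is about
through-space contact, not backbone geometry. Defaults: 8.0 Å for "near a
histidine" (His ring protonation perturbs amides well beyond van der Waals
contact; there is no community-standard number, so this convention is
deliberately prominent and configurable) and 5.0 Å for subunit-interface
membership. Implementation uses KD-trees; the test suite checks exact
agreement with exhaustive all-pairs scans and invariance under rigid-body
motion. Residue numbering is 1-based per subunit; author numbering in
structure files is mapped via an explicit offset, never guessed.

## Dose–response

The cell assay counts responding cells above baseline, normalized to a
reference agonist, so the Hill curve bottom is structurally zero and `top`
is free: R(c) = top·cʰ/(EC50ʰ + cʰ), h bounded to [0.3, 5]. Weights are
1/SE² when per-point standard errors exist, otherwise unweighted; the
functional form is recorded in the output metadata since EC50 values depend
mildly on it. Monotone-decreasing responses raise an error pointing to the
antagonist-mode analysis instead of silently fitting a negative slope.

The pH-dependency ratio is the ratio of predicted responses
(acidic/neutral) at a reference dose, by default the largest dose shared by
both tables (a plateau comparison); ratio ≈ 1 means pH-insensitive. The
antagonism index is 1 − R(agonist+test)/R(agonist alone), read at the
highest tested dose of the test protein against the mean agonist-alone
response.

Summary-table arrows are conventions, configurable in the report stage:
pH sensitivity ↓ when the ratio falls below 1.5; agonist potency ↑/↓ when
the EC50 fold-change vs wild type exceeds 1.4 (chosen so that a ~1.5-fold
affinity shift — the smallest change the assay resolves reliably — is
called, while fit jitter is not); antagonist ↑/↓ when the suppression index
differs from the wild type's by more than 1.3-fold. Variants whose pH
sensitivity is lost get no agonist arrow: their altered neutral-pH potency
is a facet of the same effect, not an affinity change.

## SAXS

Guinier fits are weighted straight-line fits of ln I on q² (σ_lnI = σ/I
when σ is present). The window is selected automatically: starting from the
five lowest usable points, the upper bound is set by the fixed point of
q_max·Rg ≤ 1.3 (the globular convention; configurable), then a curvature
guard shrinks the window while the best-fit q⁴ term deviates from the
straight line by more than max(10⁻⁴, 2×) the residual noise level. The
guard matters because real form factors bend downward beyond the strict
Guinier regime: on a noiseless sphere the uncorrected 1.3-window fit
overestimates Rg by ≈ 2%, while the guarded fit stays within 0.5% of
R√(3/5) across Rg 10–50 Å; on noisy data the curvature is buried in noise
and the full conventional window is kept. Points below a beamstop cutoff
(default 0.025 Å⁻¹ in the pipeline stage) are dropped before fitting.
Profile comparison reports |ΔRg| with propagated fit uncertainty and a
reduced χ² between least-squares-scaled Kratky curves on the common grid.
Zero-concentration extrapolation of a dilution series is out of scope.

## Synthetic study conditions

The generators define the study conditions and emit exact ground truth
alongside the data; all are deterministic given (scenario, seed), default
seed 20150811.

* **Titration screen fixture**: 113 + 114 residues on a well-separated
  (δH, δN) lattice (0.38 ppm × 2.2 ppm spacing), pH grid {3, 4, 5, 6, 7}.
  36 acidic-subunit and 33 basic-subunit residues are significant: group-A
  members titrate at pKa 4.0, group-B at pKa 6.0, with amplitudes
  alternating between ¹H-dominated (0.10–0.12 ppm) and ¹⁵N-dominated
  (1.0–1.2 ppm) so both arms of the OR rule are exercised; NBS residue 94
  titrates at pKa 4.8 (group A with a sizeable pH 5–7 tail). Twelve loop
  residues (NAS 29/52 and NBS 27–30, 47–49, 52–53, 72) are
  exchange-broadened: visible at pH 3–4, absent at pH 5–7. Non-significant
  residues are static or drift below threshold. Noise, when enabled, is
  Gaussian per nucleus (σH = 0.005, σN = 0.05 ppm in the recovery studies —
  sub-linewidth peak-position uncertainty at high field).
* **Toy structures**: residues are 3-atom clusters at stated coordinates;
  the study layout places an interface strip, a histidine patch with the
  activation-interface residues beside it, and the affinity patch ≈ 25 Å
  away, so all distance relations are known by construction. What the toy
  layout does not emulate: real side-chain packing and density — so
  distance *values* are illustrative, only their relations are asserted.
* **Cell assay**: nine variants with EC50 ladder
  {0.31, 0.84, 1.03, 1.20, 1.24, 2.12, 3.79, 6.90} μM, Hill slope 1.5,
  acidic/neutral plateau pairs encoding a strongly pH-dependent wild type
  (ratio 5), a fully pH-independent His-site variant (ratio 1.0) and
  partially desensitized variants (ratio ≈ 1.3–1.4); antagonist-mode
  strengths order the affinity variants around the wild type. Counting
  noise is binomial with n cells (n = 100 in the recovery studies), since
  the assay counts responding cells; fraction-space SEs √(p(1−p)/n)
  accompany the data. Dose grids are log-spaced, 8 points over
  0.01–20 μM (12 points in the estimator-calibration studies, a standard
  dilution-series design for EC50 estimation).
* **SAXS**: homogeneous-sphere form factor on q ∈ [0.006, 0.35] Å⁻¹
  (180 points) with multiplicative Gaussian noise and σ = noise·I.

Passing tests on these conditions demonstrate correctness of the
algorithms under the stated models — single-site titration, zero-bottom
Hill response, monodisperse spheres — not robustness to peak overlap,
multi-site coupling, aggregation or interparticle interference in real
data.

## Numerical choices and degenerate inputs

Strict `>` at significance thresholds; ties at the f_low cut to group B;
zero-path-length trajectories to group "none"; residues missing an endpoint
are "not evaluable" rather than errors; pKa/Guinier/Hill fit failures
return absent results with a reason. Greedy tracking claims each observed
peak once; unmatched residues accumulate missing pH values rather than
stealing peaks outside the gate. All stochastic tests fix seeds; Hypothesis
property tests run derandomized.

## Known limitations

Greedy (non-global) peak tracking; single-site titration model; no
relaxation-dispersion treatment of exchange; no structural pKa prediction;
no P(r)/3-D shape reconstruction; dose–response assumes the zero-bottom
Hill form the assay normalisation implies. The conditional check against an
external per-residue shift table is implemented as the screen-on-table path
(`titrascreen screen` on CSV input) but ships validated on synthetic truth
only, since no machine-readable per-pH shift table is bundled.
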