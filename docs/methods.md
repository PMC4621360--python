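# Methods

`fuzzfit` implements the quantitative NMR analyses used to characterize
disordered FG-repeat nucleoporins (Nsp1 fragments) and their fast, weak
interaction with nuclear transport factors (Kap95): secondary-chemical-shift
disorder profiling, relaxation-derived apparent correlation times, and
fast-exchange binding-constant estimation from ¹⁵N R₂ titrations. This note
records the models, their assumptions, the defaults, and the choices made
where the design was genuinely open.

## Construct registry

The eight constructs (FG-N, FSFG-K variants, and p53-tetramerization-domain
fusions) ship as packaged data, recorded verbatim as published — including
one typographical defect: the untagged FSFG-K row prints 124 residues
against a stated count of 125, and its stated mass exceeds the printed
sequence's mass by exactly one alanine residue. `validate_registry` flags
the row; nothing is silently "fixed". Masses are average (isotope-abundance
weighted) residue masses plus one water per chain; all other rows agree with
the published counts and masses to <0.5 Da. Coordinates are 1-based
inclusive; Nsp1 reference numbering is carried per region (`ref_start`
applied to the region's first residue), so tag and linker residues map to an
explicit non-reference label rather than a fabricated number.

## Secondary-shift disorder profiling

Per residue, Δδ = (δCα,obs − δCα,rc) − (δCβ,obs − δCβ,rc), with standard
error sqrt(SD²Cα + SD²Cβ) from the random-coil reference dispersions:
≈ +4 ppm in helix, ≈ −4 ppm in sheet, ≈ 0 for random coil. (One published
figure caption states the opposite pairing; the field convention for
ΔδCα − ΔδCβ, +4 helix / −4 sheet, is used.) Glycine has no Cβ and
contributes ΔδCα alone with SE = SDCα.

The packaged reference ("wishart1995") carries the standard random-coil
Cα/Cβ means with representative dispersions (0.30 ppm Cα, 0.40 ppm Cβ) and a
single dominant sequence correction, −1.85 ppm on Cα of a residue preceding
proline. The reference identity is configurable (any TSV with residue,
nucleus, mean_ppm, sd_ppm) and is recorded in output metadata; terminal
corrections are not applied unless a user table supplies them.

**Disorder call.** A chain is "disordered" iff there is no run of
`run_length` (default 3) consecutive residues whose |Δδ| exceeds its SE with
consistent sign. Ambiguous or missing residues break runs and are excluded
from run statistics. The default of 3 is a choice — short enough to catch a
single helical turn, long enough that isolated noise excursions (expected
under the null) never trigger it.

**Assignment extension.** Repeat proteins leave near-identical positions
unassigned. Each unassigned position inherits Cα/Cβ shifts from the assigned
position of the same residue type whose centered sequence window (default 9
residues, odd) has maximal positionwise identity; ties break by smallest
index distance, then lowest index. Extended entries are flagged `extended`
and never overwrite observations. The canonical example reproduced in tests:
the C-terminal proline of His-tagged FSFG-K (window ATSKPALEH) inherits from
the repeat proline with window ATSKPAFSF.

## Relaxation

R₁/R₂ come from mono-exponential fits I(t) = I₀·exp(−Rt)
(scipy `curve_fit`, log-linear start, SE from the covariance). No correction
is made for fast amide–water exchange: the sequence-dependent R₂ variation
analysed here (up to ~sixfold) dwarfs that effect. R₂/R₁ ratios carry
first-order propagated SEs.

The ¹⁵N[¹H] nOe ratio O = I_sat/I_ref depends on field and correlation time
only through x = f_H·τ_n (Hz·s):

    O(x) = 0.782804 − (0.010000683009 + 0.5132297763·x²)
                      / (0.002123332299 + 0.1102575629·x² + x⁴)

for the dipolar pair, ignoring CSA. O is strictly increasing in x (verified
on a dense grid), from ≈ −3.927 (extreme narrowing) to 0.782804 (slow
tumbling), so τ_n is recovered by monotone bracketing (brentq, relative
tolerance near machine precision). An independent inversion — the positive
root of the quadratic in u = x² — serves as a test oracle; the published
closed-form inverse is typographically corrupt and is not evaluated as
printed. Working through x normalizes across fields: the same motion
measured at 500 and 900 MHz inverts to the same τ_n. nOe values outside the
open physical interval are flagged, never clipped, and nOe uncertainties
propagate to τ_n through the local slope of the forward map. τ_n is the
apparent N–H bond-vector correlation time of a disordered chain, not a
global tumbling time; no Lipari–Szabo, spectral-density-mapping, or Rex
modelling is attempted.

## Titration (fast-exchange binding)

Observed rates are population averages, Robs = R₀(1−f) + R_b·f, with the
bound fraction from the ligand-depletion quadratic

    f = [(K_d+L+T_f) − sqrt((K_d+L+T_f)² − 4·L·T_f)] / (2L),

evaluated in the conjugate form 2T_f/(S + sqrt(S² − 4LT_f)) for numerical
stability (exact at K_d = 0 and T_f = 0). L is the observed FG protein,
T_f the transport factor, both μM end to end. The single-site-equivalent
model treats the six FSFG motifs as one effective site class; R_ex is
neglected (very-fast-exchange assumption), so the fitted K_d is a lower
bound on the gross constant, and the per-site constant is K_d × n_sites
exactly.

Fitting is two-stage: a χ² scan over log-spaced K_d ∈ [0.1, 10⁴] μM ×
linear R_b ∈ [R₀, 100·R₀] (200×200 default), then nonlinear least squares
from the grid minimum; σ-weights use supplied per-point SEs, falling back
to unweighted. Because R_b enters linearly, the surface is also profiled
over R_b in closed form; unimodality is asserted on that smooth 1-D profile
(the raw discrete grid scallops along its curved valley and shows spurious
strict 4-neighbor minima even for noiseless data). Tracks with no
T_f-dependent response (e.g. spacer residues) raise a non-identifiability
error with surface diagnostics rather than returning an arbitrary K_d.

Per-residue-type fits (the four FSFG positions) are independent (K_d, R_b)
fits by default — matching the narrow-but-distinct published range — with
the free-state R₀ taken per group from the T_f = 0 measurement.

Attenuation is a = 1 − I/I₀ (the published "(1 − I)/I₀" read as a
typesetting artifact, since attenuation must vanish at I = I₀). The
reversibility check compares per-residue attenuations from different mixing
paths at matched final concentrations; a fast-exchange equilibrium is
path-independent, a frozen (irreversible) complex is not.

## Synthetic data

The generators produce every input class at the study conditions, which are
fixed defaults, not dials: the seven-point titration design (Kap95 20 μM;
L = 12.5, 20, 80, 140, 220, 575, 1200 μM) with the published delay grids per
molar ratio; τ_n = 0.9 ns (buffer) and 1.17 ns (in cell); gross
K_d = 36.1 μM, R_b = 25.5 s⁻¹ over six FSFG sites; per-position K_d
31/55/44/17 μM; up to sixfold motif-centered R₂ elevation with a symmetric
triangular kernel of half-width 2 residues (the 2–4-residue interaction
shell around each FG). Values the source plots but does not print were
chosen once as field-realistic and documented here: free-state
R₂ = 4.0 s⁻¹ and R₁ = 1.4 s⁻¹ for a disordered chain at these fields.
Noise is Gaussian — 2% of I₀ on intensities, 0.3 s⁻¹ on R₂-class
observables, a configurable fraction (default 0.2) of the reference SD on
shifts — since no error model is published. One seeded generator drives
each run; identical config + seed gives byte-identical files, and ground
truth is written alongside the data but never read by any analysis.

What the generators deliberately do not emulate: spectral lineshapes and
overlap, exchange (R_ex) contributions, intermediate-exchange behavior,
scalar/CSA relaxation pathways, metabolite decoy peaks, and non-Gaussian
intensity errors. Passing closure tests therefore demonstrates correctness
of the estimators under the stated statistical model, not robustness to
every artifact of real spectra.

## Numerical and testing choices

- Fits are exact-recovery-tested on noiseless data (≤0.1% relative for the
  headline binding fit) and bias-tested on 1000 seeded decay replicates
  (<1% mean bias at 2% noise).
- The Wald 68% interval for K_d at σ = 5% of the dynamic range covers truth
  at 72% over 1000 replicates — slightly above nominal, as expected for a
  strongly nonlinear parameter with correlation to R_b; the calibration
  test asserts coverage within 68 ± 5 points using enough replicates that
  the binomial error (~1.5 points) is negligible.
- Per-group K_d recovery is asserted on the mean of 8 replicate fits (the
  single-fit SE is comparable to the published SEs, so a one-replicate
  check would fail for ~1/3 of seeds by construction).
- Problem sizes in the test suite (grid 60–200, 8–1000 replicates, 133-residue
  construct) were chosen to keep the full suite under a minute on one CPU
  while leaving every statistical assertion sharper than the band it tests.

## Known limitations

- The binding model is single-site-equivalent; competitive multi-site
  binding, R_ex estimation and lineshape analysis are out of scope, so K_d
  is a lower bound by design.
- The packaged random-coil dispersions are representative constants, not the
  residue-specific scatter of any one compilation; supply a measured table
  for production use.
- The NMR-STAR reader covers chemical-shift loops only; it is not a general
  STAR parser.
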