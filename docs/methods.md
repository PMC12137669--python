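# Methods

## Species model and chemistry

The unit of quantification is a base composition over {A, C, G, U} plus a
terminus. Ring-opening transphosphorylation (the 5′-OH of one nucleotide
attacking the cyclic phosphate of another) releases no water, so a
cyclic-terminated n-mer's elemental formula is exactly the sum of its
monomer formulas; hydrolysis of the terminal cyclic phosphate adds one H₂O.
Fully dephosphorylated species are not modelled — they are not part of the
quantified product tables this pipeline targets. 2′-5′ and 3′-5′
regioisomers are mass-identical; species identity is composition + terminus
only, and linkage regiochemistry enters the analysis only through the
³¹P-NMR integral ratio operation.

Atomic masses and isotopic abundances are an embedded IUPAC/CIAAW 2021
constants table, so envelopes are bit-reproducible and carry no dependence
on external data files. Charge-state arithmetic uses the proton mass
1.007276 Da. Envelopes are computed by exact pairwise convolution of
per-atom isotope distributions (binary exponentiation per element, floating
floor 1e-16), with two post-processing steps:

- fine structure closer than 0.01 Da (e.g. the ¹³C vs ¹⁵N splitting, about
  6 mDa) is centroided into abundance-weighted peaks, since no TOF-class
  instrument separates it;
- isotopologues below a relative abundance of 1e-6 (default, configurable in
  (0, 0.01]) are pruned and the envelope renormalised.

The first retained peak is always the monoisotopic one, and the test suite
checks the convolution against an independent exhaustive multinomial
enumeration for small formulas.

## Synthetic data: what it emulates, and what it does not

The generator produces ground-truth pools with the statistical structure of
dry-state cNMP oligomerisation experiments. Within a pool:

- total nucleotide mass in n-mers decays geometrically, q^(n−2), with
  q = 0.3 and maximum length 7 by default, giving the qualitative reach of
  observed product ladders (detectable products up to 7-mers);
- the converted fraction φ (default 0.10, the order of the amino-acid
  catalysed yields for the less reactive nucleotides) fixes the oligomer
  yield, and residual monomer is carried explicitly so that
  Σ conc × length = C₀ holds exactly;
- within a length, composition c receives the random-copolymerisation share
  M(c)·Π p_b^{n_b} (equal efficiencies by default); allocation is
  deterministic (expected values) so conservation and share identities are
  exact, with an optional multinomially sampled mode;
- each species is split θ : (1−θ) between cyclic and linear termini
  (θ = 0.33 by default, the observed cyclic-terminus fraction of diverse
  pools).

Spectra are negative-mode centroided peak lists: every species contributes
its envelope at [M − zH]ᶻ⁻ positions for z = 1..min(n, 3) with geometric
charge weights (ratio 0.5), scaled by concentration × per-length response.
The noise model has four components, all seeded: m/z jitter (5 ppm sigma),
multiplicative lognormal intensity noise (sigma 0.10), sparse uniform
baseline peaks, and finite resolving power (20 000): peaks closer than
m/z / R are reported as one abundance-weighted centroid, which is what makes
pseudo-isobars genuinely unresolvable. Exact mass coincidences (a 2-mer at
z = 1 and its double at z = 2 are identical by mass additivity) coalesce even
on the "perfect" instrument.

Not emulated: chromatographic separation and retention, adducts (Na/K/TEA),
profile-mode peak shapes, detector saturation, and any reaction mechanism —
the pool parameters are set, not simulated. Passing round-trip tests
therefore demonstrates correctness of the quantification given the assumed
instrument model (linear response, known charge-weight family), not
robustness to the full messiness of real LC-MS data.

## Envelope quantification

Candidates are enumerated from the experiment's alphabet up to a configured
maximum length with both termini — never learned from the data. The fit
builds a design matrix over observed peaks and solves non-negative least
squares (`scipy.optimize.nnls`); non-negativity is what prevents negative
concentrations in overlap regions. Uncertainties come from the linearised
covariance on the active set. The fitter assumes the same geometric
charge-weight model as the simulator; this is the package's explicit
instrument-response assumption, stated here because real charge-state
distributions would have to be calibrated per instrument.

Peak matching is nearest-within-tolerance, default 10 ppm (TOF-class mass
accuracy), with a floor of 30 ppm when matching against centroided data:
centroids of unresolved neighbours sit up to ~half the centroiding width
(0.5e6/R = 25 ppm at R = 20 000) from any single contributor, so matching
tighter than that systematically drops shared peaks. The plain
`match_peaks` function keeps pure ppm semantics.

Ambiguity detection compares predicted envelopes in neutral-mass space with
per-isotopologue tolerance max(0.05 Da, ppm × mass). The absolute floor
captures the A₅/G₃C₂ class of pseudo-isobars (Δ = 0.038 Da, indistinguishable
at any charge on this instrument); groups are maximal under the pairwise
relation. Grouped species share one design column (member-averaged
envelope), and the group concentration is split equally among members — a
reporting convention for unresolvable signal, not an inference; the table
carries the group id so downstream analyses can treat members jointly.
Equal-split members are exactly equal by construction; the group *total* is
recovered up to the small envelope-shape mismatch between members (≲1%).
Note the same floor admits cross-terminus pseudo-isobars (G + 2U vs
A + 2C + H₂O, Δ = 0.048 Da) in four-letter pools.

Calibration is a through-origin least-squares slope per length (the
simplest model consistent with calibration against standards of known
concentration; blank-subtracted instruments have no intercept). At least
three distinct concentration levels are required per length; lengths
without standards borrow the nearest calibrated length's slope and are
flagged. Charge states are summed before calibration — the response is per
length on total ion signal.

## Composition statistics

Yield excludes monomers (min_length = 2, configurable): the statistic is
"nucleotides in oligomer form", and product tables start at dimers. The
denominator is the nominal input concentration, not the recovered total, so
incomplete extraction shows up as missing yield rather than silently
renormalising. Both termini count toward yield — hydrolysed oligomers are
still oligomers. Fold changes are plain yield ratios; a zero-yield control
returns +inf rather than raising, since "increase from nothing" is a real
outcome at trace-level controls.

The null model is anchored per length to the measured totals T_n
(concentration, not nucleotide mass — the expectations then sum to T_n
exactly and the shares are scale-free), so it predicts composition structure
while taking overall conversion from the data. G-incorporation classes
enumerate the non-G positions over H = {A, C, U}; class averages over
partially detected classes use the detected members with a completeness
flag, because non-detections are routine in MS. Deviations from the null
are log₂(obs/exp) with observed zeros flagged missing (NaN, not −inf) and a
Σ(obs−exp)²/exp summary.

## Acid-base kinetics

The mechanism — free amine abstracts the 5′-OH proton while the ammonium
form protonates the leaving-group oxygen — requires both forms at once. The
package embodies this as the minimal bifunctional rate law r(pH) =
s·f_base·f_acid with Henderson–Hasselbalch fractions; it is an interpretive
model choice (no microscopic rate law is implied) but yields the observed
signatures: maximum exactly at pKaH, 1:1 speciation there, symmetry about
the optimum. Fitting uses bounded Levenberg–Marquardt (`curve_fit`) with
the peak-rate heuristic start; a fitted pKaH outside the observed pH range
is flagged extrapolated rather than rejected. Shipped pKa values (valine /
glycine 9.6, lysine side chain 10.5, basic sites of G and U ≈ 9.3) are an
editable table, used as condition labels; pH drift during drying is
deliberately not modelled — the initial pH labels the condition.

Initial rates are through-origin regressions over the early window (first
25% of the course or first 3 points, whichever is larger; t = 0 must be
included since yield(0) = 0). The standard error is
heteroscedasticity-consistent (HC3): yield noise is typically
multiplicative, so residual variance grows along the course and the naive
OLS error is anticonservative; the leverage correction keeps small-window
estimates honest. Even so, 2-SE coverage is only nominal in the linear
regime with a reasonably dense grid — the test suite checks it there.

## Problem sizes and numerical choices

The round-trip validations run an A/U pool to 7-mers at 40 mM (70 candidate
species, ~1200 peaks — the copolymerisation setting) under default noise,
and a four-letter pool to 4-mers at 10 mM noise-free; both complete in
seconds and are sized to exercise every code path (multi-charge overlap,
exact coincidences, ambiguity groups) rather than to stress throughput.
Bell-fit recovery uses 100 seeded profiles on six pH points spanning 7–12.
All stochastic operations take explicit seeds; there is no global random
state, and derived seeds come from `numpy.random.SeedSequence`.

Known limitations: no adduct or retention modelling; the equal-split rule
biases individual members of ambiguity groups (their sum is right, the
split is a convention); calibration transfer across lengths without
standards is nearest-neighbour with a flag, not a fitted response curve;
and the linear-response assumption is untested against saturating detectors.
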