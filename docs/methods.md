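# Methods

This note documents the models, rules and numerical choices behind
`kdacsel`, in the order the pipeline applies them.

## Interaction definitions

All geometry is computed in nanometres (input PDB coordinates in Å are
divided by 10 on load).  For each frame, each enzyme residue and each
substrate position (signed offset from the acetyllysine, Kac = 0):

| type | rule | default cutoff |
|---|---|---|
| contact | min distance over all atom pairs of the two residues | ≤ 0.30 nm |
| ionic | any cationic-group H to any anionic-group O | ≤ 0.25 nm |
| hbond_sidechain | D–A heavy-atom distance and H–D–A angle, side chain ↔ side chain, both donor directions | ≤ 0.35 nm, ≤ 30° |
| hbond_to_backbone | same geometry, enzyme side chain ↔ substrate backbone, both donor directions | ≤ 0.35 nm, ≤ 30° |

Boundary comparisons are inclusive (≤).  The hydrogen-bond angle is
measured at the donor heavy atom between the D→H and D→A vectors; 30° is
the convention of standard MD analysis tools and is configurable, as are
all cutoffs (`InteractionCriteria`).

Charged groups: Arg guanidinium, Lys ε-ammonium and (doubly protonated)
His imidazolium are cationic; Asp/Glu carboxylates are anionic.  The
peptides modelled here are N-acetylated and C-amidated, so termini carry no
charge by default.  Acetyllysine (residue `ALY`) is neutral; its side-chain
amide N–H is a donor and the acetyl carbonyl oxygen (atom `OH`) an
acceptor.  All classification tables live in `kdacsel.chemistry` and can be
overridden by a JSON sidecar.

## Catalytically relevant conformation

A frame counts as catalytically relevant while the Zn²⁺-to-acetyl-carbonyl
distance is at most 0.32 nm; the pose is lost only when the distance
*strictly exceeds* the cutoff, so exactly 0.32 nm still qualifies.  The
"carbonyl" reference atom is the acetyl *oxygen* (it is the atom that
coordinates the zinc in the accepted mechanism); the atom name is
configurable at load time for structures using different conventions.

## Frequency aggregation and exclusion

Percent time is computed over **all** frames of each replicate (catalytic
relevance is not used for re-normalization), then averaged over the
replicate simulations (default R = 5; default 2500 frames per replicate,
matching 5 ns sampled every 2 ps).  Exclusion order:

1. **Catalytic-pose exclusion** — a key whose occurrences never overlap a
   catalytically relevant frame in *any* replicate is removed outright
   (all-or-nothing; one overlapping frame in one replicate retains it).
2. **Truncation** — replicate means are floored to integer percent; keys
   flooring to 0 are dropped, which realises the 1% lower limit.
3. **Low-frequency filter** — across the peptide panel, a key is kept only
   if its mean truncated frequency over the peptides *capable* of the
   interaction is ≥ 1%.  Capability is judged per key: contact and
   backbone H-bonds need only a residue at the position; side-chain
   H-bonds need a side chain with a donor or acceptor; ionic needs
   opposite charges between the enzyme residue and the substrate residue.
   Incapable peptides are excluded from the mean's denominator, so a single
   capable peptide at ≥ 1% keeps its interaction.

The order (catalytic → truncation → panel filter) was an open choice; it is
fixed here because the panel-wide filter operates naturally on the same
integer percentages that are reported.

## Two-stage cluster statistics

Substrate clusters are all subsets of one or two residues from the alphabet
(default {A,E,R,W,Y}) at each analysed position (default +1, +2); 15 per
position.  Stage 1 compares members vs non-members per (enzyme residue,
interaction type) with a **pooled-variance** two-sample t-test (two-sided).
Pooled rather than Welch was chosen for consistency with the equal-variance
assumption used for the activity t-tests.  The Bonferroni family is *every
t-test run in the analysis invocation* (clusters × matching keys); the
family size is recorded in the report.  Significance: adjusted p ≤ 0.01.

Stage 2 tests each passing cluster for an activity difference with a
two-sided Mann–Whitney U at p ≤ 0.05 (a rank test limits the influence of
the residue at the other position).  The exact null distribution is used
when the smaller group has ≤ 8 observations and there are no ties;
otherwise the tie-corrected normal approximation.  Direction (enhanced /
inhibited) comes from the median difference.  An interaction is annotated
in the heat-map exports only when both stages pass.

Degenerate cases: zero pooled variance with equal means gives t = 0, p = 1;
with unequal means the p-value is reported at the smallest positive double
and logged.  Identical activity values across both groups give p = 1.

## Fisher exact tests

Both the frame-level co-occurrence test and the residue-preference
validation use the same two-sided convention: the sum of hypergeometric
probabilities no greater than the observed table's probability, with the
customary (1 + 1e-7) relative slack for ties.  The sum is computed from
log-probabilities with `logsumexp`, so associations over thousands of
frames report finite `log10_p` even when the p-value underflows a double
(≈ 1e-308); `p_value` itself is exact down to that underflow.

On the packaged panels, classifying peptides by detectable activity:
a mean at or above the limit of reliable detection (0.0013 s⁻¹ for the
KDAC6 panel, 0.0004 s⁻¹ for KDAC8) counts as deacetylated; "–" entries are
censored, not zero, and are excluded from normalization and correlation.
Phenylalanine is grouped with W/Y in the default aromatic predicates;
predicates are arbitrary callables over `PeptideSequence`.

## Activity panels

Normalized activity divides each mean specific activity by the reference
peptide's (FRKacWR ≡ 1 exactly); standard deviations propagate as for a
ratio, so the reference's own normalized sd is √2 × its relative sd.
Pairwise comparisons use two-tailed pooled t-tests with Bonferroni
m = number of unordered pairs and significance p ≤ 0.01; the direction
matrix is antisymmetric by construction.

## Michaelis–Menten kinetics

Initial rates are OLS slopes of product vs time (intercept fitted, ≥ 3
timepoints per concentration); a warning fires when a quadratic term
improves a timecourse fit by more than 10 AIC units (product-depletion
guard).  The rate model v₀ = k_cat·[E]·[S]/(K_M + [S]) is fitted by
weighted nonlinear least squares (K_M₀ = median [S], k_cat₀ = max v₀/[E],
parameters bounded positive).

Because assay noise is close to proportional to the measured product, the
per-rate uncertainties are derived from a **pooled** relative-noise
estimate over all timecourse residuals (Σ(nᵢ−2) degrees of freedom) with
exact OLS slope-variance propagation, and enter the fit as known absolute
sigmas.  This matters for honest uncertainties: re-estimating the error
scale from the 5 residual degrees of freedom of the rate-level fit, or
weighting by single-timecourse slope errors (2 dof each), produced ±1.96·SE
intervals covering the truth in only 70–88% of simulations; the pooled
scheme covers at 96–98% (500 simulations at 5% noise).  When rates are
supplied without timecourses, the fit falls back to magnitude (relative)
weighting with the scale estimated from its own residuals.

K_M is reported in μM, k_cat in s⁻¹, and efficiency k_cat/K_M in M⁻¹s⁻¹
(K_M converted to molar); the efficiency SE propagates the full 2×2
covariance including the k_cat–K_M term.  A fit is flagged unreliable when
the K_M relative SE exceeds 1 or K_M lands outside 0.1×–10× of the sampled
concentration range (e.g. only saturating [S] measured).

The published concentration text ("10 to 2500 nM") is inconsistent with
the μM-scale K_M values of the kinetics table; the synthetic generator
follows the μM scale, spanning 0.1×–10× K_M with seven log-spaced
concentrations and four timepoints (300–1200 s) by default.

## Synthetic data

The generators exist to make every stage testable without MD runs; their
defaults mirror the study conditions (five replicates × 2500 frames; the
16 FRKacXY derivative peptides; n = 4 replicate activities with log-normal
noise of sd 0.15 on the natural-log scale, matching the ~15% relative SDs
typical of the measured panels; baseline 0.02 s⁻¹).

*Trajectories.*  Enzyme residues sit on a 1.5 nm grid with a fixed Zn site;
substrate residues park on a distant row and each planted interaction moves
a probe atom between an "on" shell (inside the relevant cutoff: contact
0.20–0.29 nm; ionic H–O 0.18–0.24 nm; H-bond collinear D–H–A at
0.28–0.34 nm) and an "off" shell (contact 0.40–0.80 nm; ionic 0.30–0.60 nm;
H-bond bent to 45° at 0.30 nm), following a two-state Markov chain with
stationary occupancy p_on/(p_on+p_off).  The Markov structure (rather than
i.i.d. frames) reproduces the occurrence autocorrelation of real
trajectories; statistical tolerances use the effective sample size
n·(1−ρ)/(1+ρ) with ρ = 1 − p_on − p_off.  The acetyl carbonyl oxygen
follows its own chain relative to Zn (0.28–0.31 nm catalytic vs
0.33–0.50 nm otherwise; default stationary catalytic fraction 0.9).
Identical seeds reproduce trajectories — and written PDB files — byte for
byte.  At most one interaction can be planted per (position, type): a
second would need the same probe atom in two places, and raises a
`GeometryError`.

What the toy scaffold does **not** emulate: real side-chain geometry and
packing, solvent, correlated motions between interactions, or
conformational coupling between the catalytic pose and the planted
episodes.  Passing recovery tests therefore demonstrates correctness of the
detection/aggregation arithmetic under known ground truth, not fidelity of
any MD force field.

*Activity panels.*  log(activity) = log(baseline) + Σ log(cluster effects)
+ N(0, σ²) per replicate, i.i.d. under the seed.

## Determinism and report format

All pipeline randomness flows from a single config seed; reports are JSON
with a `schema_version` field and sorted keys, heat-map tables are TSV with
blank cells where an interaction was not observed or was excluded, and
rerunning with the same inputs reproduces every output byte for byte.

## Problem sizes used in the test suite

The acceptance-grade checks run at the study's own scale where that scale
is what is being claimed — five replicates × 2500 frames for occupancy
recovery, 200 null panels for the family-wise error bound, 500 simulated
fits for CI coverage — and at reduced frame counts (150–1000) for unit
tests where only the arithmetic is under test.

## Known limitations

- Multi-model PDB is the only trajectory format; other formats can be
  converted upstream (e.g. with MDAnalysis or mdtraj) or adapted by
  constructing `Trajectory` arrays directly.
- Substrate residue numbering is assumed sequential so that position
  offsets equal residue-number differences from the acetyllysine.
- His protonation is taken from the structure's hydrogens: the imidazolium
  is treated as cationic only if the relevant hydrogens are present.
- The low-frequency filter's capability rules are heuristic (letter-based);
  unusual chemistries need a custom capability callable.
- The linear activity–interaction correlation is intentionally simple; no
  multivariate modelling of activity is attempted.
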