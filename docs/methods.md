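# Methods

This note documents the models, conventions and design choices behind
`pepscreen`, and what the synthetic-data tests do and do not demonstrate.

## In silico digestion

Cleavage rules follow the simplified PeptideCutter grammar: the peptide
bond C-terminal to a P1 residue is cut unless the P1′ residue blocks it.
Two pepsin variants are built in — `pepsin_pH1.3` (P1 ∈ {F, L}) and
`pepsin_pH2` (P1 ∈ {F, L, W, Y}), both vetoed by proline in P1′. Full
P4–P2′ context tables are outside the rule grammar; users can load custom
P1/P1′ rules from YAML. The simplification is deliberate: it is
transparent, property-testable (fragment concatenation reconstructs the
parent; with `c` cut sites and `k` allowed missed cleavages the fragment
count is Σ_{j=0..min(k,c)} (c+1−j)), and overridable.

Missed cleavages default to 0. Coordinates are 0-based half-open
internally and 1-based inclusive in every emitted record. Deduplication is
global across proteins and keeps the first occurrence in input order, so
output order is deterministic. Unknown residues (`X`) are tolerated in
proteins, never act as cut sites, and any peptide containing `X` is
dropped (with a logged count) before property computation, where the
arithmetic would be undefined.

## Physicochemical descriptors

* **Net charge**: integer side-chain model at neutral pH — K, R = +1;
  D, E = −1; H = 0; termini ignored. This reproduces the qualitative
  cationic/anionic labels used in candidate triage. A Henderson–
  Hasselbalch fractional-charge mode (EMBOSS pKa set) is available but is
  not the classification default.
* **GRAVY**: mean Kyte–Doolittle hydropathy; a peptide is labelled
  hydrophobic iff GRAVY > 0. The scale is pluggable (Hopp–Woods,
  Eisenberg) because no single scale is canonical; the reported class
  always refers to the scale actually used. Note that reasonable scales
  disagree near zero — e.g. TTMICLTCAR is weakly hydrophobic by
  Kyte–Doolittle yet reads hydrophilic under other conventions; the
  package reports, it does not adjudicate.
* **Hydrophobic moment**: Eisenberg mean-vector magnitude at
  100°/residue (α-helical periodicity), Eisenberg consensus scale.
  A peptide is called amphipathic when μH ≥ 0.2, a conventional
  moderate-amphipathicity cut-off; the threshold is a parameter.

## Consensus screening

Thresholds are strict (">"): AntiCP-style SVM score > 1.00; iACP-style
probability > 0.5; MLACP positive only when *both* its RF and SVM
probabilities exceed 0.5. The consensus call is the conjunction of the
three predictors. Raising any score can therefore never turn a positive
verdict negative (tested as a monotonicity property), and the seven Venn
regions over the three predictors obey inclusion–exclusion exactly.

Mode-of-action stratification partitions consensus ACPs into
`toxic_only / cpp_only / both / none` from the binary toxicity and
cell-penetration flags; overlapping totals (toxic_total = toxic_only +
both, cpp_total = cpp_only + both) are reported alongside, since both
conventions appear in the literature. Ranking sorts by the SVM score
descending, breaking ties by the mean of the other three scores and then
lexicographically, which makes it a total order independent of input
order.

## Redesign search

The redesign operation is a greedy hill-climb: each round enumerates all
19·L single mutants in a fixed order (position-major, residue
alphabetical), takes the best-scoring one (first maximum wins, which
encodes the tie-break), and stops after `max_rounds` rounds (default 2,
matching the two-substitution redesigns such tools typically emit) or
when the gain drops to `min_gain`. An exhaustive ≤k-substitution search
with the same tie-break serves as the test oracle; at one round the two
must agree exactly. The package ships only a transparent additive
per-residue demo scorer — fabricating an ACP model would be worse than
having none — and accepts any callable as the real scorer.

## MTT dose–response

Viability is `100·(A_t − blank)/(A_c − blank)` per treated well, with the
per-timepoint mean blank and mean corrected control; the quantity is
invariant to rescaling all absorbances, and a non-positive corrected
control is a hard plate error.

The dose–response model is the four-parameter logistic
`V(d) = bottom + (top − bottom)/(1 + (d/IC50)^hill)`, defined at d = 0
(V(0) = top), so the zero dose is fitted rather than dropped. Fitting is
bounded trust-region least squares with a deterministic initializer
(top = max mean viability, bottom = min mean viability, IC50 = dose
nearest the half-way response, hill = 1; bounds top/bottom ∈ [0, 120],
hill ∈ [0.1, 10], IC50 within 10³× the tested dose range) and no random
restarts. Parameter standard errors come from the Jacobian curvature at
the optimum; the IC50 additionally carries a replicate-level bootstrap SD
(199 resamples, fixed seed).

**Complete-inhibition convention.** When the true lower plateau sits on
the 0% boundary, estimating it under a `bottom ≥ 0` constraint truncates
its sampling distribution; the positive-biased plateau drags the fitted
IC50 downward by roughly 3% at this package's default plate design. For
compounds expected to reach full inhibition, fits should therefore pin
the plateau (`fix_bottom=0.0`) — the familiar "Bottom = 0" constraint of
standard curve-fitting software — which simulation shows is
median-unbiased (within 0.1% over 100 plate sets) with roughly half the
spread of the free fit. The free four-parameter fit remains the default
for compounds whose floor is unknown.

Curves whose mean viability spans less than 20 percentage points are
flagged `no_inhibition` and given no IC50 instead of an unstable number;
a converged IC50 outside the tested dose range raises a flag rather than
an error.

Group comparisons use one-way ANOVA followed by Dunnett's many-to-one
test against the shared control (`scipy.stats.dunnett`, multivariate-t
with fixed rng; the method string is recorded in the result), with the
conventional `*` (p < 0.05) and `**` (p < 0.01) flags. Combination grids
are analysed per cell: each peptide × drug cell is compared against the
untreated control and both monotherapy margins with a many-to-one
adjustment, and the direction (lower/higher viability) is reported. No
formal synergy index is computed — the claim the analysis supports is
directional, not mechanistic.

## Synthetic data

The generators define the study conditions for every test:

* **Proteome**: i.i.d. residues from a fungal-like composition with the
  combined F+L frequency at 0.09 (and P at 0.05), so pepsin fragments
  average ~12 residues and the retained 5–50 aa peptidome splits roughly
  77/18/5% across the 5–20/21–35/36–50 bins — a short-peptide-dominated
  profile typical of a frequent cutter. Protein lengths are normal around
  450 residues (floored at 60).
* **Score model**: a latent ACP label with prevalence 0.05; each
  predictor column is Gaussian given the label (probability columns
  clipped to [0, 1], which cannot move mass across an interior
  threshold, so closed-form tail probabilities stay exact). Default
  separations put consensus recall near 0.75 with a vanishing
  false-positive rate — an idealisation: real predictor errors correlate,
  so real consensus precision is lower than the synthetic one. MoA flags
  are Bernoulli given the label, with ACP-conditional rates taken from
  the 14/242/5/55-of-316 stratification arithmetic of the motivating
  screen (toxic 19/316, cell-penetrating 247/316), drawn independently.
* **MTT plates**: absorbance = blank + control_OD·V(d)/100 + Gaussian
  noise equivalent to 5 viability points; control OD 1.0, blank OD 0.05,
  4 replicates, doses 0/25/50/100/200/400 µM at 72 h. The active-peptide
  scenario uses a true IC50 of 114.9 µM with hill 1.5; the inactive
  scenario is flat at 100%; the doxorubicin scenario uses 0.12 µM over
  two-fold dilutions from 0.25 µM. Hill slopes, noise level and optical
  densities are this package's design choices, declared in
  `synthetic.DEFAULTS`. Combination grids assume Bliss independence with
  an optional interaction factor.
* **Seeding**: one master seed expands into per-stage `SeedSequence`
  streams (proteome = 0, scores = 1, mtt = 2, combo = 3); all generators
  are byte-stable across runs and platforms for a fixed seed.

What passing tests show: the machinery is correct (digestion algebra,
threshold logic, fit recovery, error calibration) under a known
generative model. What they do not show: performance on a real proteome
or real predictor outputs, whose score distributions, correlations and
noise structure the generators do not attempt to emulate. Corpus-scale
counts from the motivating screen depend on an unversioned proteome build
and third-party trained servers and are covered by these properties, not
reproduced numerically.

## Problem sizes

Defaults keep everything desk-scale: 120 proteins (~3,200 unique
peptides) for the screening drivers, 10,000 peptides for the
recall/precision check, 1,000 random proteins for digestion properties,
20 plates for the IC50 stability check, 100 plates for estimator
calibration, and 1,000 replicates for the Dunnett null simulation. These
sizes give stable statistics while the whole suite runs in well under a
minute of compute per module.

## Known limitations

* Pepsin specificity is reduced to P1/P1′; genuine pepsin context
  dependence (P4–P2′) is not modelled.
* The integer charge model ignores histidine and the termini; peptides
  with His-dominated charge will classify as neutral.
* The additive demo scorer is a stand-in for a trained ACP model and has
  no biological validity; redesign results with it illustrate the search,
  not peptide biology.
* The no-inhibition flag is a 20-point heuristic on the observed range;
  very shallow true curves (hill « 0.5) could be misflagged at noisy,
  narrow dose ranges.
* Dunnett p-values come from randomized-QMC multivariate-t integration
  and are reproducible only for a fixed rng argument.
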