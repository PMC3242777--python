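# Methods

## The model

The package implements the standard reversible codon substitution process on
the 61 sense codons of the universal genetic code. Between codons *i* and
*j* differing at exactly one nucleotide position the instantaneous rate is

    q_ij ∝ π_j · κ^[transition] · ω^[nonsynonymous]

with rate 0 between codons differing at more than one position. Here π is
the equilibrium codon frequency vector (modes: equal, F1x4, F3x4 — the
default, built from positional nucleotide frequencies — or F61), κ > 0 the
transition/transversion rate ratio, and ω = dN/dS the selection parameter:
ω < 1 purifying selection, ω = 1 neutrality, ω > 1 positive selection. The
generator is scaled so branch lengths are expected substitutions per codon.

Heterogeneity in ω is a mixture of site classes, each with a background and
a foreground ω (the foreground being the branches flagged `#1` in the input
tree). The catalogue covers:

| model | free ω-structure parameters |
|---|---|
| M0 | ω |
| M1a | p0, ω0 (ω1 = 1) |
| M2a | p0, p1, ω0, ω2 ≥ 1 |
| M7 | beta p, q (10 equal-probability classes at their category means) |
| M8 | p, q, p0, ωs ≥ 1 |
| M8a | p, q, p0 (ωs = 1) |
| branch 0 / 1 | one ω / one ω per branch |
| branch 2 strict / relaxed | background ω ≤ 1 + foreground ω (relaxed: foreground ω = 1) |
| A1 / A2 | p0, p1, ω0 (+ ω2 ≥ 1 in A2), four classes 0/1/2a/2b |

In the branch-site structure, classes 2a/2b take their background ω from
classes 0/1 but ω2 on the foreground branch, with proportions
(1−p0−p1)·p0/(p0+p1) and (1−p0−p1)·p1/(p0+p1).

### Rate scaling across site classes

Site classes share a single generator scaling, so a class with larger ω
genuinely evolves faster; normalising each class separately would erase the
rate contrast between classes and with it most of the branch-site signal.
Two equivalent conventions are used. The simulator and the public
`log_likelihood` use the *mixture-average* convention: a branch length is
the expected number of substitutions per codon averaged over site classes on
that branch (foreground and background averaged separately). Optimisation
uses the *neutral-reference* convention (rates relative to an ω = 1 class),
which differs only by a per-branch-category rescaling — absorbed by the
freely estimated branch lengths or tree scale — and has the practical
advantage that the per-class likelihood caches do not depend on the mixture
proportions. Reported branch lengths therefore follow the convention of the
fit that produced them; likelihood values and tests are unaffected.

## Likelihood and optimisation

Likelihoods use Felsenstein pruning over pattern-compressed alignments with
per-node rescaling (log-scale accumulators) for numerical stability; gaps
and IUPAC ambiguities are marginalised (partial likelihood 1 over compatible
states). Trees are handled unrooted; the stored root is an arbitrary
internal node and, by reversibility, the likelihood is invariant to it
(checked to 1e-8 in the tests against re-rooted newicks). A brute-force
summation over internal-node states on quartets is the correctness oracle
(agreement to 1e-8).

`fit_model` maximises lnL over branch lengths, κ, and the model's mixture
parameters with L-BFGS-B on transformed parameters: log scale for rates,
branch lengths (bounds [1e-6, 50]), κ ([1e-3, 100]) and ω ([1e-6, 999]);
stick-breaking on [0, 1] for proportions, which are allowed to hit the
boundary exactly. The gradient is analytic for branch lengths (pre/postorder
edge partials) and finite-difference for the scalar block, with per-class
likelihood caching so that perturbations which do not change a class's ω are
nearly free. Three restarts from distinct starting points are the default;
all restart lnLs are reported and non-convergence is flagged, not silenced.
Negative LRT statistics within 1e-4 (optimiser noise) are clamped to zero
with a warning.

## Tests of selection

Nested pairs and their degrees of freedom: M1a⊂M2a (2), M7⊂M8 (2), M8a⊂M8
(1), branch0⊂branch1 (branches−1), branch0⊂branch2-strict (1),
branch2-relaxed⊂branch2-strict (1), A1⊂A2 (1). The statistic 2δ =
2[lnL(alt) − lnL(null)] is referred to the plain χ² with those df — no
50:50 boundary mixture correction — which for the boundary cases makes the
test conservative. `fit_nested_pair` warm-starts the alternative from the
null MLE embedded in the alternative's parameter space, guaranteeing 2δ ≥ 0
up to optimiser tolerance.

Bayes Empirical Bayes site identification integrates the branch-site class
posteriors over a discrete prior grid on (p0, p1, ω0, ω2), with κ and branch
lengths fixed at their MLEs: 10 categories per dimension (`BEB_GRID_SIZE`),
(p0, p1) uniform on the 2-simplex via the square-to-triangle map on midpoint
categories, ω0 uniform on (0, 1), ω2 uniform on (1, 11). Sites are reported
in the tiers P > 0.95 and P > 0.99 together with the posterior mean
foreground ω. A plain-loop grid-summation oracle on quartets agrees to
1e-6.

## Pairwise statistics

kS and kA use Nei–Gojobori (1986) counting: synonymous site counts per codon
with changes to stop codons counted as nonsynonymous, equal-weight averaging
over all minimal mutational pathways between codon pairs (pathways through
stops excluded), pairwise deletion of gap/ambiguous codon columns, and the
Jukes–Cantor correction −3/4·ln(1 − 4p/3). Pairs with p ≥ 3/4 are flagged
saturated (kS = NaN) rather than silently dropped; pairs with no comparable
sites are flagged undefined. Protein identity is identical residues over
aligned positions that are not gaps in both sequences.

## Synthetic data

The generator emulates a mosquito GSTE-like gene cluster so that the whole
pipeline runs without downloads:

- **Codon usage** (`default_codon_usage`): a frozen synthetic F3x4-structured
  table with GC3 ≈ 0.68, emulating the GC3-rich usage of *Anopheles* coding
  sequence. It is a synthetic stand-in, not a measured usage table.
- **Tree** (`gstall_like_tree`): a random resolved unrooted topology
  (sequential random edge attachment), exponential branch lengths, globally
  rescaled until the mean pairwise kS of data simulated under the null
  branch-site model matches the target (default 1.6 ± 0.15 in calibration,
  the paralog-level mean of the real cluster; the spread of the exponential
  draws reproduces a kS s.d. of roughly 0.7). Calibration is deterministic
  given the seed and raises with diagnostics if it cannot converge.
- **Foreground branch**: one internal branch set to 0.33 substitutions/codon
  and flagged. The real lineage of interest showed dN ≈ 0.11 (4th of 59
  branches) at a near-neutral ω, i.e. t = 3·dN ≈ 0.33 — moderately
  divergent but far from saturated. Selecting by length rank instead would,
  on a reduced-taxa tree, pick a saturated branch and misrepresent the
  study conditions.
- **Mixture defaults** (`DatasetTemplate`): p0 = 0.80, p1 = 0.15 (5% of
  sites in classes 2a/2b), ω0 = 0.10, κ = 2.0, 257 codons, 31 taxa. No
  published estimates of the branch-site mixture exist for this cluster, so
  these are explicit assumptions, chosen as typical of a strongly purifying
  insect detoxification gene family, and all overridable.

What the generator does *not* emulate: alignment error, indels/gaps,
recombination, among-site rate variation beyond the ω mixture, and codon
usage differences among lineages. Passing tests therefore demonstrate the
estimators' behaviour under the model's own assumptions at GSTE-like
divergence, not robustness to real-data misspecification.

## The power study

One condition = (generating model A1 or A2, foreground ω2, branch-length
scale factor). Per replicate: simulate → fit A1 and A2 → LRT at α = 0.05 →
on significant A2-generated replicates, BEB at thresholds 0.95/0.99 scored
against the simulated truth (true positives = sites in classes 2a/2b).
Site-level power, accuracy and false-positive rate are pooled over
replicates (micro-average; per-replicate means are reported alongside);
accuracy is undefined, and excluded, when nothing is detected. Replicates
whose fits fail are excluded and counted.

Fitting inside the study is two-stage for speed: branch lengths and κ are
estimated once under M0, then held fixed while each branch-site model
re-optimises κ, its mixture parameters, a global tree-scale factor, and a
separate scale factor on the foreground branch. The alternative is
warm-started from the null solution (so 2δ ≥ 0) plus a second start away
from the ω2 = 1 boundary. Probing against full joint re-optimisation (which
`fit_model` performs and the library defaults to) showed the two-stage LRT
statistic is slightly smaller on average, i.e. the study's test is somewhat
conservative; joint refitting costs 3–5× more per replicate.

Standard condition grid (`run_standard_study`): null at 1× and 2× branch
lengths; A2 with ω2 ∈ {4, 9, 999} at 1×; A2 with ω2 = 9 at 0.5×. Problem
sizes: the acceptance script uses 12 taxa × 257 codons × 50 replicates per
condition; the test suite uses 10 taxa at the same codon count and replicate
number; `full_profile` (31 taxa, 100 replicates) reproduces the full-size
study as a batch run. Power probes showed little sensitivity to taxon count
(12 vs 31 taxa at fixed calibrated divergence differed by a few points at
ω2 = 9), so the reduced profile preserves the study's qualitative behaviour;
absolute power levels remain sensitive to the assumed mixture proportions
and foreground branch length (see Known limitations).

## Numerical choices and edge cases

- Spectral decomposition of the symmetrised generator for P(t); tiny
  negative entries from round-off are clipped at 0.
- Pattern compression keyed on whole codon columns; identical columns share
  all computation and BEB posteriors.
- A terminal-column stop codon in an input alignment is converted to a
  missing state (it carries no information under a sense-codon model);
  internal stops are validation errors naming taxon and site.
- Proportion sticks may reach 0/1 exactly; ω2 and ωs start points include
  the boundary value 1, and fits at the boundary reproduce the nested null.
- χ² p-values use the stated df even when the null is on a boundary, the
  procedure as commonly applied in practice; this is conservative.

## Known limitations

- The two-stage study fits are mildly conservative relative to full joint
  optimisation (see above).
- Absolute LRT power depends strongly on the generating conditions — the
  share of sites in the selected classes, the foreground branch length, and
  ω0 — which for the emulated cluster are documented assumptions, no
  estimates being available. Error rates (LRT and BEB false positives) and
  BEB accuracy are robust to these choices; power levels should be read as
  properties of the stated defaults.
- With a correctly specified generating model and exact likelihoods, the
  branch-site false-positive rate does *not* inflate when branch lengths are
  doubled; the test stays conservative at high divergence. The inflation
  reported for the original software at doubled branch lengths is not
  reproduced by this implementation.
- Real-data reproduction (GenBank-derived alignments) is out of scope of the
  test suite; the pipeline accepts such alignments and trees as inputs.
- BEB uses the fixed default grid; posterior probabilities at boundary-fit
  parameters (ω2 = 999) are integrated only up to the grid's ω2 range (1–11),
  as in the cited default.
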