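# Methods

## The question and the model

`cladeshift` asks whether a set of higher taxa (units — e.g. insect orders)
behave as *evolutionarily significant units of selection*: whether a sizable
class of codons is under purifying selection within every unit while diverging
freely among units. The statistical vehicle is the comparison of site and
branch-site codon substitution models on a tree whose branches are labeled
*background* (within a unit) or *foreground* (connecting units).

All four models are mixtures over per-codon selective classes on top of a
Goldman–Yang style codon process over the 61 sense codons. For codons `i != j`
differing at exactly one nucleotide position,

    q_ij = pi_j            synonymous transversion
         = kappa * pi_j    synonymous transition
         = omega * pi_j    nonsynonymous transversion
         = omega * kappa * pi_j   nonsynonymous transition

with `q_ij = 0` for multi-step changes and diagonals set for zero row sums.
The chain is time-reversible with stationary distribution `pi`, so
`P(t) = exp(Qt)` is computed from the eigendecomposition of the symmetrized
form `diag(pi)^{1/2} Q diag(pi)^{-1/2}` (stable, and ~10x faster than general
expm at this size).

The four models, with free-parameter counts in parentheses:

| model | classes (proportion, omega background / foreground) |
|---|---|
| 1 site nearly-neutral (2) | `(p0, w0/w0)`, `(1-p0, 1/1)` |
| 2 site positive-selection (4) | adds `(1-p0-p1, w2/w2)`, `w2 >= 1` |
| 3 branch-site nearly-neutral (3) | `(p0, w0/w0)`, `(p1, 1/1)`, `(p2a, w0/1)`, `(p2b, 1/1)` |
| 4 branch-site positive-selection (4) | as 3 but the switching classes take `w2 >= 1` on foreground |

Branch-site proportions follow the constrained expansion
`p2a = (1-p0-p1) p0/(p0+p1)`, `p2b = (1-p0-p1) p1/(p0+p1)`, which is what
makes models 2 and 4 equally complex and forces AIC rather than nested LRTs
for the cross-family comparison.

Likelihoods use Felsenstein pruning with site-pattern compression and
per-node log rescaling. Per model, one shared scale factor normalizes the
background-mixture expected substitution rate to 1, so branch lengths are in
expected substitutions per codon (foreground branches then run slightly
"hot" for the switching classes, which is the intended biology). On trees of
up to 4 tips the pruning likelihood is verified against explicit
marginalization over all internal-state assignments, to 1e-8, for all four
models.

## Branch labeling and taxon structures

A branch is background iff the tips below it all belong to one unit and form
a proper subset of that unit's tips present in the tree; unit stems and all
deeper branches are foreground. The "present in the tree" clause is the
gene-tree relaxation: with paralogs or missing taxa a unit need not be
monophyletic, and labeling then operates on maximal same-unit subtrees. On
the 21-tip species tree (unit sizes 6+5+5+5) this gives 40 rooted branches,
34 background and 6 foreground — the rooted convention is chosen because the
branch-ratio ANOVA degrees of freedom (1, 38) imply 40 branch observations.

Alternative taxon structures are generated from the base partition by
(a) lumping the two most derived units, (b) lumping the three most derived
units (both read from the nesting of unit crowns; a ladder unit topology is
required and enforced), and (c) splitting every subset of units at their
basal nodes (`2^4 - 1 = 15` subsets), totalling 17 alternatives for four
units. All structure fits share the model id and hence parameter count, so
their AIC ranking reduces to log-likelihood ranking.

## Fitting

Parameters are optimized by L-BFGS-B in an unconstrained transform
(log kappa, logit omega0, log(omega2 - 1), softmax class proportions, log
branch-length scale), multi-start (two deterministic starts, further ones
seeded-random). Kappa and the branch-length scale are estimated once under
model 1 and then fixed for models 2-4, matching the accounting in which only
class parameters count toward model complexity; `reoptimize_nuisance=True`
re-estimates them per model. Because `omega2 >= 1` places the nearly-neutral
solution on a constraint boundary where the log transform converges slowly,
fits of models 2 and 4 end with an explicit boundary evaluation: if
`omega2 = 1` is not measurably worse (within 1e-4 log-units) it is accepted
as the MLE. The uninformative-parameter rule then excludes models 2/4 from
the AIC comparison when `|omega2_hat - 1| < 1e-3` (the published rule says
"estimated as 1.0"; a numeric tolerance is unavoidable).

Site posteriors are naive empirical Bayes at the MLEs,
`P(class k | site) = p_k L_k / sum_j p_j L_j` — not the Bayes Empirical Bayes
sampler of CODEML, which integrates parameter uncertainty. Only the
high-threshold (0.95) class-2a site set feeds downstream GC summaries, where
the two approaches agree closely away from the threshold.

dS-scaled branch lengths use Goldman–Yang mutational-opportunity site
counting: per branch, `dS = t * f_syn(label) / s1`, where `f_syn` is the
mixture synonymous flux fraction under the branch's label and `s1` the
proportion of synonymous sites from the `omega = 1` matrix.

## Codon positions and GC

The 2nd:3rd-position branch-length-ratio analysis refits GTR branch lengths
(empirical base frequencies, jointly estimated exchangeabilities, fixed
topology) to the positional splits of the alignment and compares the
per-branch ratio between foreground and background branches with a classical
one-way ANOVA (`F`, `R^2 = SSB/SST`, F-distribution p-values, no
multiple-testing correction). Ratio denominators are floored at 1e-6
substitutions/site and flagged, since near-zero 3rd-position branches
otherwise explode the ratio. GC content is reported per taxon and codon
position in percent, with gaps and ambiguity codes excluded from
denominators; raw ratios (not log-ratios) enter the ANOVA, consistent with
reported group means well above zero.

## The simulator and what it does (not) emulate

`simulate_units_tree` builds the study geometry directly — a ladder backbone
`(U1,(U2,(U3,U4)))` with four monophyletic units of 6+5+5+5 tips, unit stems
of 0.4, backbone edges of 0.25 and unit crowns of depth 0.4 expected
substitutions per codon, each length jittered lognormally (sd 0.25, unit
mean) — rather than sampling a birth-death process, because the analysis
needs the clade structure, not a realistic diversification history. With the
reference mixture this yields a maximum patristic dS of ~6-7 synonymous
substitutions per codon, the same depth regime as the real concatenated
alignment (8.03). Default position-specific nucleotide frequencies are
AT-rich with AT-richer third positions, the composition typical of
holometabolan coding sequence.

Alignments are evolved by exact endpoint sampling: per codon a mixture class
is drawn, the root codon comes from `pi`, and each branch applies the
class- and label-specific transition matrix. No Gillespie simulation is
needed because only endpoint states matter. Stop codons cannot arise; output
is gap-free and passes every filtering precondition.

Not emulated: indels (real alignments are cleaned to gap-free before
fitting, so tests say nothing about alignment error), among-site rate
variation beyond the omega mixture, codon-usage/GC-bias mutation models,
recombination, and orthology-inference error. Passing recovery tests
therefore demonstrate correctness of the inference machinery under the
model's own assumptions, not robustness to real-data misspecification.

## Reference experiment and problem sizes

The recovery experiment simulates 2,000 codons on the 21-tip tree under the
branch-site nearly-neutral model with the concatenated-alignment estimates
as truth (F3X4: `p0 = 0.730`, `p1 = 0.043`, `w0 = 0.040`; empirical-frequency
variant: `p0 = 0.708`, `p1 = 0.040`, `w0 = 0.035`; `kappa = 2.5`, a typical
insect nuclear value, since kappa is not among the published mixture
estimates) and refits models 1 and 3 with shared nuisance parameters. The
saturation/null experiment simulates under the site model (`p0 = 0.940`,
`w0 = 0.041`) with the tree rescaled so the maximum patristic dS is ~1
(shallow, far below saturation) and records how often AIC prefers the
branch-site model; 20 replicates of 500 codons keep the run in minutes.
Simulation-backed tests elsewhere use 8-tip trees and 300-600 codons — large
enough for stable signs of effects, small enough for a fast suite.

## Numerical choices and edge cases

- Codon order: lexicographic over A,C,G,T with stops removed; frequencies
  floored at 1e-10 and renormalized (logged) to keep Q irreducible.
- F3X4 renormalizes the positional product over sense codons after stop
  removal.
- Transition probabilities are clipped at 0 and row-renormalized to absorb
  eigendecomposition rounding.
- Optimizer: `ftol = 1e-10`, `gtol = 1e-6`, 500 iterations; a failed
  orthogroup fit is retried once with fresh starts before being skipped
  (never fatal to a batch).
- Polytomies are resolved deterministically (children sorted by smallest tip
  label) with zero-length branches; knuckles collapse by summing lengths.
- Filtering tie-breaks: "most nested" all-unit clade = fewest tips, then
  lexicographically smallest tip tuple; the top-5% divergence cut removes
  exactly `ceil(0.05 N)` groups ordered by (max branch length desc, id asc).
- Gap fraction is counted over nucleotide positions including terminal gaps,
  with a strict `> 0.66` removal rule; duplicate sequences are compared
  before gap stripping.
- Every stochastic routine takes an explicit seed and is a pure function of
  (inputs, seed).

## Known limitations

- Naive empirical Bayes (not BEB) for site classification, as above.
- The one-per-branch free-ratio model and per-branch dN/dS are out of scope.
- Lump enumeration requires a ladder unit topology; balanced unit trees
  raise an explicit error rather than guessing which units are "most
  derived".
- AIC weights between models 3 and 4 on small datasets reflect boundary
  noise in `omega2`; on short alignments model 4 may legitimately retain
  weight even when the truth is model 3 (its extra parameter absorbs
  sampling noise), which is why the exclusion rule matters.
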