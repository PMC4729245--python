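# Methods

`codonsel` tests whether two mating-system classes of closely related
species — permanently social, inbreeding species versus subsocial,
outcrossing congeners — differ in the effectiveness of selection, using
only a multi-species in-frame codon alignment, a fixed rooted topology,
and a species-to-class label map. Reduced effective population size (from
inbreeding, reproductive skew and female-biased sex ratios) weakens
selection relative to drift; the two genomic signatures examined are a
higher dN/dS ratio and weaker codon usage bias in the low-Ne class.

## Codon usage bias (ENC)

Codon usage bias is summarised per species by Wright's effective number
of codons,

    ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6,

where Fk is the mean codon "homozygosity" over amino-acid families of
synonymous degeneracy k. The degeneracy scheme is Wright's original:
Met and Trp excluded (the leading 2), Ile the sole 3-fold family, and
Leu/Ser/Arg treated as whole 6-fold families. ENC runs from 20 (one codon
per amino acid, extreme bias) to 61 (all synonymous codons equally used,
no bias).

Two F estimators are available:

* `wright` (default): the bias-corrected F = (n·Σp² − 1)/(n − 1), n the
  family codon count; families with n < 2 are skipped.
* `plain`: F = Σp², which realises the 20/61 endpoints analytically and
  is used wherever exact endpoint behaviour matters.

A degeneracy class with no usable family borrows the mean F of the
observed classes. The result is clamped to [20, 61]; values within 1e-9
of an endpoint are snapped onto it first, a pure floating-point guard so
that analytically exact endpoint inputs report exactly 20.0 or 61.0.

Group inference follows the resampling design of the underlying study:
1000 bootstrap replicates over codon columns give percentile 95% CIs for
the group-mean ENC, and a permutation test draws random 3-vs-7 splits of
the per-species ENC values, with statistic mean(small group) −
mean(large group). The p-value is one-sided in the direction "social mean
higher", the direction predicted by reduced selection effectiveness (the
source analysis does not state sidedness; the choice is recorded here).
When the number of distinct splits is at most the requested permutation
count — C(10,3) = 120 always is — the null is enumerated exhaustively and
the exact fraction reported; sampled mode applies the add-one correction
(1 + #{null ≥ obs})/(1 + n_perm).

Caveat: the percentile bootstrap is biased near the ENC boundaries
(resampling duplicates inflate homozygosity), so CIs computed on
near-endpoint data need not straddle the point estimate; mid-range ENC
values (like real data around 50) are unaffected to first order.

## Codon substitution models

The generator is Goldman–Yang-style over the 61 sense codons:
q_ij = π_j · κ^[transition] · ω^[nonsynonymous] for single-nucleotide
changes, zero otherwise, scaled to one expected substitution per codon
per unit branch length at stationarity. Codon frequencies default to
F3×4 (products of per-position nucleotide frequencies, floored at 1e-6
and renormalised); empirical F61 is available. Only the universal genetic
code is supported (spider nuclear loci).

Branch-class models share κ, frequencies and branch lengths and give each
branch class its own ω: A (one class), B (internal/external), C
(internal/external-social/external-subsocial), D (internal plus one ω per
external branch). Site models M7 and M8 let ω vary over columns instead:
M7 a Beta(p, q) on (0, 1) discretised into 10 equal-probability
categories (quantile midpoints), M8 adding one class with ω > 1 and
weight 1 − p0. The site mixture is normalised by the category-weighted
average rate, so high-ω site classes evolve faster in total, as they
should.

Likelihoods use Felsenstein pruning over compressed column patterns with
per-node rescaling; ambiguous codons are marginalised (summed over all 61
states). Transition matrices come from a symmetric eigendecomposition of
the reversible generator (falling back to scaling-and-squaring if the
reconstruction check fails); entries are floored at 1e-16 so that
eigen-reconstruction noise on near-zero multi-step probabilities cannot
zero out a site likelihood at short branch lengths.

Fitting alternates two bounded L-BFGS-B phases until the round-to-round
log-likelihood gain falls below 1e-6 (default cap 30 rounds): a global
phase over log κ and the log ω set (or the transformed site-model shape
parameters), and a branch-length phase over log lengths using an analytic
gradient obtained from one outside-likelihood (up-down) pass. Site-model
global phases carry one extra tree-length scale factor; without it the
mixture-average rate normalisation couples the shape parameters to the
fixed branch lengths and can trap M8 at the p0 = 1 boundary. Branch
lengths are initialised by non-negative least squares on rough
JC-corrected pairwise codon distances. Fits are single-start by default —
the surfaces encountered here are well behaved and the deterministic
initialisation reproduces multi-start optima — with jittered restarts
available via `FitConfig(n_starts=...)`. Convergence failures are
reported, never hidden.

Likelihood-ratio tests use −2ΔlnL (clamped at zero) against χ² with df
equal to the free-parameter difference: A-vs-B 1, A-vs-C 2, B-vs-C 1,
C-vs-D (#external branches − 2), M7-vs-M8 2. The M7/M8 comparison sits on
a parameter boundary; χ²(2) is the conventional, mildly conservative
choice and is what the pipeline reports. No multiple-testing correction
is applied; the report footer says so.

The regrouping robustness check refits the three-class model with a focal
tip's branch co-classed with chosen partner tips instead of its
mating-system group, comparing each refit to the single-ω model — the
standard way to ask whether one outlier branch drives a class effect.

## Synonymous distances and dating

Pairwise dS/dN use Nei–Gojobori (1986) counting: synonymous site
fractions per codon (changes creating stops count as nonsynonymous
sites), differences averaged with equal weight over all minimal
mutational pathways avoiding stop codons, pairwise deletion of codons
missing in either sequence, sites averaged over the two sequences, and
Jukes–Cantor correction of the proportions. pS ≥ 3/4 makes the correction
undefined; such distances are returned as flagged infinities and the
affected nodes reported undated. Only the NG86 flavour is implemented and
the method tag is recorded in every output.

Each internal node's synonymous depth is the mean dS over all tip pairs
whose MRCA is that node (the pair counts partition all C(n,2) pairs).
Ages assume a strict clock: age = dS/(2μ) generations, the 2 because both
diverging lineages accumulate μ substitutions per site per generation;
μ defaults to the Drosophila estimate 8.4e-8 and generation time to one
year (both configurable). Clock violations (a child node dated older than
its parent) are visible in the report, not hidden.

## The simulator and what passing tests mean

The simulator evolves root codons drawn from the stationary distribution
down the fixed tree, each branch using the transition matrix of its class
ω — exactly the estimators' model. The bundled 10-taxon fixture mirrors
the study design: 3 social tips on short terminal branches, each sister
to a subsocial tip, 7 subsocial tips, 13 loci totalling 1583 codons
(4749 coding bp), ω defaults 0.1674 (internal) / 0.2534 (social) / 0.1018
(subsocial), κ = 2, uniform codon frequencies. Terminal social branches
are a quarter the subsocial terminal length (0.04 vs 0.16 expected
substitutions per codon), echoing the relative youth of social lineages;
the ~0.4 subs/codon root-to-tip depth reflects the substantial synonymous
divergence of a multi-million-year radiation while staying clear of
saturation. The fixture topology is synthetic — it preserves the reported
social/subsocial sister pairings but is otherwise constructed — and any
user Newick can replace it.
`simulate_skewed_codon_usage` creates controlled ENC differences by
moving a group's synonymous codons toward a preferred codon without
touching the amino-acid sequence.

Because simulated data match the fitted model exactly (no indels, no
recombination, no within-species polymorphism, no among-locus rate
heterogeneity, uniform codon frequencies), passing recovery and
calibration tests demonstrate the correctness of the estimators and
their inference machinery — not robustness to the model violations real
spider data certainly contain.

## Problem sizes used by the test suite

Chosen as a balance between statistical resolution and a test suite that
runs in minutes: three-class ω recovery uses 20 replicates of the full
1583-codon, 10-taxon fixture; the null χ² calibration of the A-vs-C test
uses 200 replicates of 300 codons on a 6-taxon tree with both classes;
dating accuracy uses 10⁴ codons on a 6-taxon ultrametric tree; the
pipeline smoke tests run the fixture at 150–300 codons. The accession
data of the original study (GenBank KU232626–KU232779) are not bundled;
the pipeline accepts them as ordinary FASTA/Newick inputs for
benchmarking against the published estimates.
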