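# Methods

## Pipeline model and assumptions

The package treats mini-driver detection as four chained inferences.

**Co-expression networks.** Pearson correlation on RPKM-scale values, with
no log transform, is used as the similarity measure; the network is the
thresholded correlation graph. Only non-negative, finite expression values
are accepted, and duplicate gene rows are collapsed by summation on read
(exon-level aggregation artefacts). The low-expression filter is
rank-based: genes are ordered by summed expression over all samples and
the lowest `floor(p/100 · G)` are removed (default p = 40), with stable
ordering so that, among tied sums, earlier-listed genes are retained. The
cut is deliberately not interpolation-based — the intent is to drop a
fixed fraction of weakly expressed genes, and a rank cut makes the
retained count exact and order-stable. Edges default to *positive*
correlations only (`ρ ≥ threshold`); an absolute-value mode exists because
negatively co-regulated pairs are a defensible alternative. Genes left
without any edge are excluded from the node set: density, path length,
module membership and the enrichment background are all defined over
participating genes. Average path length is the mean over mutually
reachable ordered pairs; the thresholded networks are disconnected, and
excluding unreachable pairs keeps the statistic finite without arbitrary
penalties.

**Community structure.** Partitions come from seeded Louvain greedy
modularity optimisation (networkx's implementation) at resolution 1, on
the unweighted thresholded graph — thresholding is the edge-inclusion
decision, and topology is analysed afterwards. Modularity is the
Newman–Girvan score computed by direct edge/degree accounting. Because Q
grows mechanically with sparsity and size, cross-network comparisons use
the normalised score against a degree-preserving null: each of `n_null`
replicates (default 100) applies `10 · E` attempted double-edge swaps —
proposals creating self-loops or multi-edges are rejected, so the degree
multiset is preserved exactly — and is re-partitioned with Louvain. The
default normalisation is `(Q − Q̄_null) / (1 − Q̄_null)`, which maps "no
better than the degree-matched null" to 0 and a perfectly modular graph
to 1; the plain ratio `Q / Q̄_null` is available as a config alternative
since both forms appear in the normalisation literature. A null mean of 1
(shifted) or 0 (ratio) makes the score undefined; the report then carries
NaN and a `degenerate` flag rather than a silent value.

**Mutation projection and overrepresentation.** Non-synonymous status is a
closed whitelist of ten Variant_Classification values (Missense_Mutation,
Nonsense_Mutation, Frame_Shift_Del, Frame_Shift_Ins, In_Frame_Ins,
In_Frame_Del, Missense, Splice_Site, Translation_Start_Site,
Nonstop_Mutation); everything else — Silent, UTRs, introns, RNA — is
excluded. No driver-significance filtering is applied anywhere: the
weak-effect mutations are the object of study. Residue-level frequencies
use single-nucleotide variants only, pool different substitutions at the
same position, and count each patient once per residue. The
overrepresentation statistic is the hypergeometric upper tail
P(X ≥ k) — the one-tailed Fisher exact test — with the whole network as
background; mutated genes absent from the network are dropped before
testing. BH adjustment is per patient by default (each patient's profile
is one screen); a cohort-wide family is available via config since the
choice of family is genuinely open. Modules smaller than
`min_module_size = 5` are not tested by default (the test is degenerate on
tiny modules); setting 1 disables the guard. E status uses the strict
inequality q < 0.05. Untestable patients (no mutated gene in the network)
report p = q = 1 and E = False, flagged.

**Survival.** The event is disease-specific death: dead *and* "with
tumour". Patients dying tumour-free are censored at death — a
competing-risk-naïve choice, made because only the event is defined by the
study design, not the treatment of other deaths. Time is days-to-death
when available, else days-to-last-follow-up; all times are
administratively censored at the horizon (default 1826 days = 5 years, the
days-based reading of "5-year"). Cox fitting, Kaplan–Meier estimation and
the k-sample log-rank test are delegated to lifelines (Efron tie
handling, recorded in results). Categorical covariates are dummy-coded
against the first sorted level (Stage I / T1 / N0 style references);
unknown/X levels (NX, MX, TX, RX, Unknown) are treated as missing for that
covariate. The univariate model-level p is the partial
log-likelihood-ratio test — asymptotically equivalent to the score
(log-rank) test, and identical in spirit for the two-group case — because
lifelines does not expose the score statistic directly. Backward stepwise
selection starts from all covariates with univariate p < 0.2
(complete-case across the entering set), repeatedly removes the covariate
*block* (all dummies of a factor together) whose removal most lowers
`AIC = −2 log PL + 2k`, and stops when no removal lowers AIC; the AIC
trace is strictly decreasing by construction.

## Synthetic cohorts

The generator produces the three linked inputs with known ground truth.

* *Expression*: gene g in module j is `x = a_j·f_j + σ·ε` with factor and
  noise standard normal, so within-module Pearson correlation is exactly
  `a²/(a²+σ²)` — 0.9 at the defaults a = 3, σ = 1 — giving closed-form
  oracles. The tumour condition multiplies every loading by
  `1 − modularity_degradation` (default 0.5): a single-scalar attenuation
  that lowers within-module correlation below the ρ = 0.8 edge threshold
  and so reproduces the directional loss of community structure without
  modelling its mechanism. Non-negativity is enforced by exponentiating
  the standardized latent value at scale 0.5 (lognormal, monotone;
  within-module Pearson ≈ 0.89 for latent 0.9); a pure shift, which
  preserves Pearson exactly, is the config alternative used by the
  correlation oracle tests.
* *Mutations*: independent per-gene Bernoulli at background rate 0.02;
  the planted E+ subgroup (30% of 500 patients) uses rate × 8 (capped at
  1) inside one designated 150-gene module of a 3000-gene pool — expected
  in-module counts 24 vs 3.
* *Survival*: exponential event times with hazard
  `h₀·exp(β_E·E + β_N·N_level)` (defaults h₀ = 2.4·10⁻⁴/day, β_E = log 2,
  β_N = log 1.5, N stage sampled at 66/18/14/2%), independent exponential
  censoring whose rate is tuned to the target censored fraction (default
  0.30) via the cohort-average hazard — an approximation, accurate to a
  few points at these effect sizes. Two inert covariates (smoking, margin
  status) are included so selection procedures have noise to reject.

What the generator does **not** emulate: mutational signatures and
trinucleotide context, copy-number change, gene-length– or
position-dependent mutation rates, expression–mutation coupling within a
patient, correlated censoring, or cohort heterogeneity beyond the planted
subgroup. Passing tests therefore demonstrate that the statistics recover
the structure they model, under their own assumptions — not that real
cohorts satisfy those assumptions.

## Numerical choices and degenerate inputs

* Correlation on fewer than 3 samples is refused; zero-variance profiles
  have undefined correlation and yield no edges.
* Rewiring on graphs with no valid swap (triangles, stars, < 2 edges)
  returns an identical copy.
* Louvain, rewiring and all generators take explicit integer seeds; the
  null ensemble derives child seeds from a `SeedSequence`, and every
  report records its seed. Pipeline reruns with the same config are
  byte-identical.
* BH q-values are clamped to `max(q, p)`: dominance holds mathematically
  but `p·m/m` can round one ulp below `p`.
* Candidate-module ranking breaks ties by larger module, then lower id.
* Cox fits that fail to converge (separation, constant covariates) are
  skipped with a logged warning rather than aborting the screen.

## Problem sizes

The test suite and the acceptance script run the generators at reduced
sizes chosen to preserve the default per-module signal strength: network
and modularity checks use 120–600 genes with 4–5 planted modules and null
ensembles of 8–30 rewired replicates; enrichment calibration runs at the
full default 3000-gene / 500-patient condition (it needs no expression
matrix); survival calibration uses n = 500 with 100–200 replicates. These
are the package's standard verification sizes; the full-scale expression
default (3000 genes, 100 nulls) runs in minutes and is intended for
analysis use.

## Known limitations

* Competing risks are handled by censoring, not by a Fine–Gray model;
  proportionality is not formally tested (a violation surfaces only as a
  lifelines warning).
* The normalisation formula of the published normalised-modularity scheme
  exists in two variants; both are implemented, the shifted form is the
  default, and results should state which was used.
* The per-patient BH family makes E-status calls independent across
  patients but means the cohort-level fraction of enriched patients is
  not itself FDR-controlled.
* Weighted or signed community detection, partial-correlation networks,
  and consensus clustering across seeds are out of scope.
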