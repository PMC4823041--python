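# Methods

This note documents the models, statistics and design choices behind
`mircuits`, and what the synthetic test bed does and does not establish
about behaviour on real microarray cohorts.

## Data model

A cohort is a pair of log2-scale expression matrices (miRNA and gene,
features × samples) over one ordered sample list, with a binary class
label per sample (e.g. presence of the t(4;14) translocation) and at
least three samples per class for any correlation or test. Interaction
priors are typed directed edges — `miRNA_target`, `TF_gene`, `TF_miRNA`
— tagged `predicted` or `validated`; a feature counts as TF-capable
exactly when it appears as the regulator of a `TF_*` edge, since the TF
vocabulary comes from the prior source rather than from annotation.
Missing values are not supported: readers reject non-numeric cells,
matching the complete matrices that normalized arrays produce.

## Variance filtering

The coefficient of variation is computed on linear-scale intensities
`2**x` (sd/mean per feature) and the top `cv_keep_fraction` (default
0.75) of genes is kept — `ceil(f·n)` features, ranked descending with
exact ties broken lexicographically by feature ID for determinism.
Working on the linear scale keeps the CV positive and well defined; for
log-normally distributed intensities it is a monotone function of the
log-scale spread alone. Whether the original analyses filtered on log or
linear intensities is not documented, so results on real data may differ
marginally at the filter boundary; a `cv_filter_mirnas` switch extends
the filter to miRNAs (off by default — the published wording filters
genes only).

## Circuit inference

Pearson correlations are computed only along prior edges. Binary
miRNA/target relations keep `r ≤ −0.4` (repression is the modelled
mechanism); a switch admits `|r| ≥ 0.4` for exploratory use. Mixed
circuits require all three triangle edges in the prior and threshold the
two apex edges at `|r| ≥ 0.2` with topology-consistent signs (positive
for TF activation, negative for miRNA repression); the closing edge is
required in the prior but not sign-constrained, and its correlation is
recorded for network export. Correlation p-values (t-distribution) are
reported but never used for filtering — selection is on r, as in the
thresholds above. Output ordering is lexicographic in (topology, TF,
miRNA, gene), so results are pure functions of the inputs.

Cross-cohort consensus: circuit identity is the (topology, TF, miRNA,
gene) quadruple; relationship identity for node sharing is the (ordered
pair, sign) of an edge, so concordant relations with different
magnitudes count as shared. Where both cohorts supply an attribute the
configured reference cohort wins. The child network is the merged-network
induced subgraph on shared-relationship nodes plus first neighbours
(undirected neighbourhood).

## Pathway scoring

Pathway graphs are augmented by adding each expressed miRNA with at
least one prior target among the pathway's genes, with one repression
edge per such target; gene–gene topology is never modified. The directed
graph is then moralized, triangulated with a deterministic minimum-fill
heuristic (ties on fill-in size broken by node ID; already-chordal
graphs pass through unchanged) and decomposed into maximal cliques
joined by a maximum-|separator| spanning tree, which yields the running
intersection property for chordal graphs.

Each clique is scored with the Gaussian likelihood-ratio statistic

    T_C = n·log|Σ̂_0| − n₁·log|Σ̂_1| − n₂·log|Σ̂_2|

over the clique's variables, where the Σ̂ are maximum-likelihood
covariances of the pooled and per-class fits with a ridge
`λ = covariance_ridge × mean pooled variance` (default 1e-3) added to
the diagonal; the statistic is clipped at zero, which the ridge can
otherwise undershoot by a rounding margin. Pathway nodes without
expression rows are dropped from cliques before fitting (logged); a
pathway with fewer than two expression-backed nodes is skipped. The
pathway statistic is the clique sum, and significance comes from
permuting class labels jointly for both matrices (samples are shared),
with the positively biased estimator `p = (1 + #{T* ≥ T}) / (1 + N)`,
so p is never zero and the smallest attainable value is `1/(N+1)`.
N defaults to 10,000; the calibration and power analyses in the test
suite and acceptance script use N = 1,000, which bounds p from below at
~0.001 and keeps 200-replicate calibration runs in seconds.

### Portions

A portion is a simple path of cliques through the junction tree (every
pair of cliques in a tree is joined by exactly one path; single cliques
count, and paths are capped at 10 cliques). The path score is the
**permutation-standardized** path statistic: the summed clique
statistics along the path, centred and scaled by their permutation null.
A raw mean or sum cannot localize: the mean of a path never exceeds its
best single clique, and the raw sum always grows with path length.
Standardization makes a path of several jointly modulated cliques
outscore each clique alone while diluting paths that drag in null
cliques, which is what lets the top portion recover a multi-clique
signal. The raw mean clique statistic is kept on each portion for
reference, and each portion carries its own permutation p-value from the
same null. Portions at or above the upper `portion_percentile` (default
0.10) quantile of path scores are retained, per pathway by default (a
pooled-across-pathways variant is available).

The meta-pathway is the node-identified union of the selected portions'
subnetworks (induced subgraphs of their augmented pathways), with
pathway-of-origin provenance on edges; it is re-analysed with the same
machinery and the union of its own top portions' nodes is the cohort's
selection.

### Union network and the discrepancy rule

Candidate nodes are the union of the two cohorts' selections. Each needs
a log2ratio (positive-class mean minus negative-class mean of log2
expression) in both cohorts; nodes lacking one are dropped with a logged
reason. With discrepancy `d = |lr_A − lr_B|`, the default `sign` mode
discards sign-discordant nodes with `d > 0.1`, keeps smaller
discordances as display-neutral, and colours concordant nodes by the
reference cohort's log2ratio. The published description of the ±0.1
rule is ambiguous between this reading and a pure distance cut;
`discrepancy_mode="difference"` implements the latter. Edges are the
union of meta-pathway edges among surviving nodes.

Permutations are unstratified: no covariate structure is assumed within
classes.

## Synthetic study generator

`simulate_cohort` plants mixed circuits by sampling (TF, miRNA, gene)
triples from the exact trivariate Gaussian implied by the requested
pairwise correlations (Cholesky; a non-positive-definite target is
rejected before sampling). Default plants use apex-edge strengths of
0.6–0.8 with the closing edge at their product, which is always
realisable. Background features are independent Gaussians with log2-sd
drawn in 0.5–0.9 — below the planted spread of 1.0, so variance
filtering retains planted members, mirroring the empirical tendency of
regulated transcripts to be the variable ones. Baselines are uniform in
6–10 log2 units. Priors carry all planted relations plus 10× as many
decoy edges among background features, mimicking the low precision of
target predictions. Pathway cohorts are drawn from a multivariate
Gaussian whose precision matrix is a diagonally dominant M-matrix on
the pathway's moral graph (unit-variance after normalization); the
positive class receives the effect-size shift (SD units) on the signal
nodes. Candidate miRNAs are noisy negatives of their targets' mean
profile. The default study mirrors the motivating design: cohorts of 96
and 153 samples with 13 and 22 positives, 300 miRNA and 2,000 gene
features, six planted circuits shared by both cohorts with independent
noise, and one signal pathway (a 21-node chain of five 5-cliques, six
affected genes confined to two adjacent cliques, 1.5 SD effect) among
nine decoys.

What passing tests show — and do not. The generator produces clean
Gaussian data with exchangeable samples, complete matrices, exactly
realised planted correlations and disjoint pathway node sets. It does
not emulate probe-level noise, batch effects, cohort-specific platform
differences, correlated backgrounds, overlapping pathway membership, or
annotation mismatch between prior and expression vocabularies. Recovery
rates near 1.0 on this bed therefore demonstrate correctness of the
inference machinery at the published operating point, not expected
sensitivity on real arrays, where the published analyses found far
sparser consensus (a handful of shared circuits out of ~10² per
cohort).

## Numerical and engineering choices

* All randomness flows through `numpy.random.default_rng`; per-pathway
  permutation streams are keyed by (seed, CRC32 of pathway ID), so
  results are independent of pathway ordering and reruns are
  byte-identical (matrix IO uses `%.17g` with round-trip float parsing).
* Network edge deduplication keeps the largest |r|; merged networks
  resolve same-pair/same-sign conflicts in favour of the reference
  cohort.
* Fisher's exact test is the two-sided point-probability method;
  Wilcoxon rank-sum uses exact enumeration for tie-free groups of ≤ 10
  and the tie-corrected normal approximation otherwise;
  Benjamini–Hochberg is the standard step-up procedure. These wrap
  scipy/statsmodels implementations behind validated interfaces and are
  cross-checked against enumeration oracles in the tests.
* Degenerate inputs: zero-variance profiles are skipped in correlation
  (logged); degenerate contingency margins give p = 1 with a warning;
  constant pooled samples give Wilcoxon p = 1; an empty prior or empty
  portion list yields empty results, not errors.

## Known limitations

The clique statistic assumes within-class Gaussianity; heavy-tailed
expression would call for rank-based variants. The junction-tree
decomposition is a defined, testable variant of recursive clique-tree
pathway scoring, not a byte-level reproduction of any particular
published implementation. Portion enumeration is quadratic in clique
count and intended for pathway-scale graphs (tens of cliques), not
genome-scale networks. Survival association and functional enrichment
are out of scope; the child-network gene list is exported for external
enrichment tools.
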