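# Methods

## Scope and data model

The pipeline starts from an OTU count table (samples × taxa, integer
reads), optional 7-rank taxonomy, per-sample metadata (water chemistry,
nutrients, trace metals, reach and season labels) and a per-sub-basin
land-use area table in five classes (farmlands, forests, freshwaters,
urban, others). All interchange is plain TSV; networks are additionally
exported as GraphML for Cytoscape-style viewers. Writers are
deterministic (stable edge ordering, fixed line terminators), so a rerun
of the same configuration produces byte-identical output — this is
asserted, not assumed.

## Preprocessing and diversity

Samples are rarefied to a common depth by subsampling without replacement
(multivariate hypergeometric, one draw per seed); samples below the
target depth are dropped with a warning. Low-count OTUs are removed per
analysis group at a default threshold of 30 total reads, applied within
each reach × season group because that is the unit on which networks are
built. Alpha diversity reports observed richness, Chao1, Shannon and
Good's coverage. Chao1 defaults to the bias-corrected estimator
S_obs + F1(F1−1)/(2(F2+1)) — the common default of amplicon toolchains
and defined when F2 = 0 — with the classical F1²/(2F2) form available by
option. Shannon is reported in nats (base-e), base configurable. Chao1
and Shannon are computed by scikit-bio; Good's coverage is 1 − F1/N.

## Ensemble network inference

Association is scored on per-sample relative abundances with four
measures per unordered taxon pair: Spearman and Pearson correlation,
Bray–Curtis dissimilarity Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ), and symmetrized
Kullback–Leibler divergence on per-taxon probability profiles over
samples (pseudocount 1e−6 before normalization, configurable). Taxa with
zero variance are excluded from testing with a log entry.

Significance comes from a permutation null: each taxon's values are
shuffled independently across samples; for pair (i, j) the null statistic
is the measure between shuffled-i and observed-j, symmetrized over the
two roles. P-values use the add-one estimator (b+1)/(B+1), so the floor
at B = 1000 permutations is 1/1001 and no p is exactly zero.
Correlations are tested two-sided; the dissimilarities one-sided in both
directions, reporting the smaller tail with its direction (smaller than
null ⇒ co-presence, larger ⇒ exclusion). Before permuting, the matrix is
put into canonical (sorted-id) order, which makes the inferred network
exactly invariant to sample and taxon ordering.

Benjamini–Hochberg FDR is applied per measure across all tested pairs.
An edge is retained iff (a) |Spearman| or |Pearson| exceeds the strength
threshold (default 0.8), (b) at least `min_support` (default 2 of 4)
measures are significant at q ≤ 0.05 with direction concordant with the
edge sign, and (c) the sign — from Spearman, Pearson breaking ties of at
least equal magnitude — is well defined. Requiring all four measures is
brittle (the dissimilarities disagree with rank correlations on
compositional data); requiring one defeats the ensemble. Isolated nodes
are dropped.

**A numerical constraint worth knowing:** permutation FDR couples the
attainable q-value to the number of tested pairs. With B permutations
the smallest possible q for D discoveries among P pairs is
(P/D)·1/(B+1). At B = 1000 and ~90 true pairs, tables beyond ~90 taxa
(4000+ pairs) cannot produce q ≤ 0.05 no matter how strong the signal;
either raise B or pre-filter taxa. The synthetic defaults (60 taxa) and
the bundled pipeline fixture (30 taxa at B = 300) respect this.

**Limitations.** Measures are computed on relative abundances without a
compositionally corrected null (no ReBoot-style renormalized bootstrap);
on strongly compositional data spurious negative correlations are
possible. SparCC/SPIEC-EASI-style inference is out of scope.

## Topology indices

All metrics treat the graph as undirected and unweighted except NP
(= negative/positive links), which uses edge signs and is reported as
undefined (not infinite) when there are no positive links. avgCC is the
mean local clustering coefficient with degree-<2 nodes contributing 0;
APD is the mean shortest-path length over *connected* node pairs
(disconnected pairs excluded rather than infinite — common viewer
behavior); CD is Freeman centralization Σ(k_max−kᵢ)/((TN−1)(TN−2)); the
power-law R is the OLS R² of log₁₀ P(k) against log₁₀ k over unit-width
degree bins, k ≥ 1, zero-frequency degrees excluded. Reported values
carry 3 decimals.

`rivernet.topology` also bundles the published index values of the six
Yuan River reach × season networks as a worked consistency dataset. The
checker verifies avgK = 2·TL/TN, NP = NL/PL, GD = avgK/(TN−1) and
TL = NL + PL at printed rounding, and *flags* cells that fail (two
corrupted dry-season upper-reach cells) rather than correcting them.

## Modules and node roles

Partitions maximize Newman–Girvan modularity on the unsigned graph via
greedy agglomeration (deterministic, networkx CNM), with a seeded Louvain
option; module ids are renumbered by decreasing size with
lexicographic tie-breaks so output is stable. Signs are collapsed for
partitioning but retained for module edge-sign profiles; signed
modularity variants are out of scope.

Roles follow the within-module degree z-score / participation coefficient
scheme: zi is the z-score of a node's intra-module link count over its
module's members (zi = 0 when the spread is zero), pi = 1 − Σₛ(k_is/k_i)².
Thresholds: network hubs zi > 2.5 and pi > 0.62; module hubs zi > 2.5
only; connectors pi > 0.62 only; peripherals otherwise. The inequalities
are strict, so boundary values (zi = 2.5 or pi = 0.62 exactly) fall to
the lower category. Keystones = hubs ∪ connectors. Major modules hold
strictly more than 5% of the network's nodes. Shared-node (Venn)
percentages are 100·|A∩B|/|A∪B|, one decimal.

## Neutral community model

Sloan's model predicts a taxon's occurrence frequency across samples from
its mean relative abundance p, community size N_T (reads per sample after
rarefaction) and immigration rate m. The classical prediction is the
threshold form F(p) = 1 − I(d; N_T m p, N_T m (1−p)) with detection limit
d = 1/N_T (one read). This package defaults to a *binomial detection*
variant: the probability a taxon with Beta-distributed latent proportion
q is seen in N reads is 1 − E[(1−q)^N], the complement of the
beta-binomial zero-count probability, evaluated in log space. The
threshold form treats a taxon at one expected read as always detected,
when binomial sampling misses it ~37% of the time; on count data this
inflates the fitted m by roughly a quarter, while the binomial form
recovers simulated m to a few percent. The classical form stays available
(`detection="threshold"`, d configurable) for comparability with other
toolchains — note its m estimates run systematically higher.

m is fitted on (0, 1] by bounded least squares over all taxa with p > 0,
without abundance binning; R² = 1 − SS_res/SS_tot on occurrence
frequencies (may be negative; > 0 indicates partial neutrality). Samples
must share one depth; unequal depths raise an error instructing
rarefaction. No confidence interval is reported. Group comparisons
tabulate (R², m) per reach × season, sorted by R² descending with stable
ties.

## HAILS

HAILS = 100 × Σ(human-influenced class areas)/total area per sub-basin;
the human classes default to {farmlands, urban} ("residential land" maps
to the urban class of the five-class scheme; overridable). Reach classes
default to tertiles of the HAILS ranking (ties broken by table order,
i.e. upstream first; realized boundaries logged) because the source
survey does not print its cut-offs; fixed thresholds are available.
Degenerate gradients (all equal) label everything "low" with a warning.

## Environment statistics

Variables are screened per column with Shapiro–Wilk; p < 0.05 triggers
log(x + shift) with shift 0 when min > 0, else |min| + √ε. Correlations
are Pearson with pairwise deletion; cells with n < 3 are left empty. The
significance convention is p ≤ 0.05 with no FDR across correlation tables
(FDR is reserved for network edges). Keystone × chemistry networks use
|r| ≥ 0.8 and p ≤ 0.05 by default, both exposed as flags. Index ×
environment correlations use one network (reach × season group) as the
observation unit paired with group-mean environmental values — the unit
is explicit and n is unavoidably small, so these p-values are low-power
descriptive statistics. Group comparisons are one-way ANOVA with Fisher's
LSD post hoc tests on the pooled within-group variance, without
additional multiplicity correction (the LSD convention); for two groups
LSD reduces exactly to the pooled-variance t-test.

## Synthetic data

*Planted blocks*: taxa in a block share a standard-normal factor on the
log-abundance scale. The loading is √(2 sin(π c/6)) so the latent pairwise
**Spearman** correlation equals the requested c (the sine term converts
rank to Pearson correlation for a Gaussian copula). A requested fraction
of within-block pairs is made negative by flipping loadings on k of n
taxa, with k chosen so 2k(n−k)/(n(n−1)) is closest to the request.
Latents pass through a per-sample softmax and multinomial sampling, so
tables are compositional counts. Defaults: 60 samples, 60 taxa, two
blocks of 10 at c = 0.9, depth 57,068 reads (a realistic rarefied depth
for this kind of survey), baseline log-abundance spread 0.5. Ground truth
(membership, factors, signs, pre-softmax latents) rides along in `attrs`.

*Neutral communities*: per sample and taxon, latent proportions are drawn
from Beta(N_T m p, N_T m (1−p)) around a log-normal source pool
(σ = 1.5), renormalized, then multinomially sampled — matching the
fitted model's assumptions exactly, which is what parameter-recovery
tests require. Source taxa with p = 0 are never observed.

What the generators do **not** emulate: sequencing error, chimeras,
taxonomy-assignment noise, true ecological drift dynamics, or the
compositional biases of real amplicon libraries beyond closure itself.
Passing tests therefore demonstrate correctness of the estimators under
their own assumptions and calibrated false-positive control — not
robustness to real-data artifacts.

## Pipeline and reproducibility

A single YAML config drives load → rarefy → diversity → per-group
networks → topology → modules/roles → NCM → HAILS → correlations. Groups
with fewer than 4 samples are skipped with a logged reason. Every stage
seed derives deterministically from one master seed (CRC-based, recorded
in the manifest together with all thresholds and SHA-256 input hashes);
the manifest suffices to reproduce the run. The command-line entry point
(`rivernet`) wraps the library thinly; all thresholds are flags.

Test problem sizes are chosen to keep the full suite fast (~10 s): graph
oracles use ≤ 30-node random graphs against hand-rolled BFS/triangle
counting; recovery tests use the generator defaults above; NCM recovery
uses 200 samples × 500 taxa at depth 10,000; the end-to-end fixture uses
32 samples × 30 taxa at 300 permutations.
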