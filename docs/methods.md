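# Methods

This note records the statistical model behind each stage of `psmnet`,
the defaults and why they were chosen, the numerical conventions, and
what the synthetic-data tests do and do not demonstrate about real data.

## Spectral-count model and normalization

The pipeline's central object is a protein-by-subject matrix of summed
peptide-spectrum matches (PSMs), a semi-quantitative spectral-count
abundance measure.  Subjects are compared after *total-signal
normalization*: each column is scaled so every subject's total equals the
mean of the original column totals.  The target constant (mean rather
than, say, 1) preserves the magnitude of the counts; every downstream
ratio-style statistic (DAve in particular) is invariant to that choice.
A subject with an all-zero column has no defined scale factor and is
rejected with an error naming the subject.  Zeros are preserved exactly:
normalization rescales, it never imputes.

## DAP selection

Two complementary selection routes are combined, reflecting the two ways
a protein can carry group information in presence-prone spectral-count
data:

* **Identification frequency (IF).**  IF is the percentage of a group's
  subjects with a nonzero PSM, reported as an integer percent with
  halves rounded away from zero (so 4/7 → 57 %, 6/7 → 86 %), matching
  how such frequencies are conventionally printed.  The rule retains
  proteins with IF strictly above 50 % in one group and strictly below
  50 % in at least one other; the strict inequalities make the 50 %
  boundary itself non-selecting.  This route is sensitive to
  presence/absence structure that variance-based tests miss.
* **F-ratio ("LDA") selection.**  Group separation of normalized
  abundances is scored per protein by the one-way fixed-effects F ratio
  (between-group over within-group mean squares, df₁ = g − 1,
  df₂ = N − g) with selection at F ≥ 3.5 AND p ≤ 0.05.  This is the
  univariate F-to-enter criterion of stepwise linear discriminant
  analysis; a full multivariate stepwise LDA would be software- and
  path-dependent, whereas the per-feature F reproduces the stated
  decision rule exactly and is trivially auditable.  Proteins with zero
  total variance are assigned F = 0 (never selected); zero within-group
  variance with nonzero between-group variance yields F = ∞, p = 0.

Pairwise contrasts are annotated with the **DAve index**,
((A − B)/(A + B))/0.5 on group mean PSMs, bounded in [−2, 2].  A protein
with positive mean in exactly one condition receives ±2 by convention;
both means zero is undefined and reported as missing.  The retention
threshold is two-sided, |DAve| ≥ 0.4: the one-sided chain
"−0.4 ≥ DAve ≥ 0.4" sometimes seen in print is unsatisfiable as written
and is read as the magnitude rule.  The DAP table records, per protein,
the selection source (IF, LDA, or both), group means and IFs, all
pairwise DAve values, and the F statistics.

## Presence-based biomarker test

Tables of "detected in k of n subjects" are compared between two groups
with an exact test on the per-subject detection indicators
(1 if PSM > 0).  Because the indicators are binary and exchangeable
under the null, the permutation distribution of the group-A detected
count is hypergeometric, and the implementation evaluates it exactly;
the two-sided p doubles the smaller tail, capped at 1 — equivalent to an
exact two-sided rank-sum (Mann–Whitney) test on 0/1 data.  A perfectly
separated 5-present vs 11-absent split gives p = 2/C(16,5) ≈ 4.6×10⁻⁴.
Raw p-values drive selection at p ≤ 0.05 to mirror common practice in
this literature; Benjamini–Hochberg adjusted values are reported in an
adjacent column so the FDR-controlled view is always available.

## Clustering / PCA quality control

Subjects are clustered over the selected proteins with Euclidean
distance and Ward linkage, and projected by PCA with per-component
variance shares (which sum to one over all retained components).  These
are diagnostics: they verify that subjects group by their clinical label
and expose outliers; they play no role in selection.

## Network construction and topology

Interactions are a scored undirected edge list with independent
"databases" and "experiments" channel scores in [0, 1].  An edge is
retained when *either* channel passes its inclusive threshold (defaults
0.3 and 0.15) — an OR across evidence channels; duplicate pairs are
merged keeping the maximum per-channel score and self-loops are dropped.
DAP networks restrict nodes to the selected proteins (proteins without a
retained interaction remain as isolated nodes so the report covers the
whole selection).  Per-group networks admit the proteins detected in at
least ⌈n/2⌉ of the group's n subjects — 3-of-5, 2-of-4 and 4-of-7 for
the default cohort shape.

Centralities follow the Centiscape conventions.  With d(v,w) the
shortest-path distance, σ_st the number of shortest s–t paths and σ_st(v)
those through v, computed per connected component of size n_c:

* betweenness(v) = Σ_{s<t≠v} σ_st(v)/σ_st and
  stress(v) = Σ_{s<t≠v} σ_st(v); both are unnormalized counts over
  unordered pairs, so a star's center on k leaves scores C(k, 2);
* closeness(v) = 1/Σ_w d(v,w); eccentricity(v) = 1/max_w d(v,w)
  (reciprocal forms — larger is more central);
* radiality(v) = Σ_{w≠v} (Δ + 1 − d(v,w))/(n_c − 1) with Δ the
  component diameter;
* centroid(v) = min_{w≠v} (γ_v(w) − γ_w(v)), γ_v(w) counting nodes
  strictly closer to v than to w;
* bridging(v) = betweenness(v) × (1/deg v)/Σ_{i∈N(v)} 1/deg i;
* eigenvector centrality is the principal adjacency eigenvector per
  component (unit norm, nonnegative; values are comparable within, not
  across, components);
* edge betweenness per edge, and diameter / average distance / average
  degree reported for the largest component.

Distances and path counts come from breadth-first search per component;
betweenness/stress are assembled from the distance and path-count
matrices by the σ_sv·σ_vt composition rule, which the test suite checks
against an independent oracle that enumerates every shortest path
explicitly (exhaustively on all 995 connected graphs with ≤ 7 nodes, and
on 100 seeded random graphs with ≤ 30 nodes), and against the Brandes
implementation in networkx.  Isolated nodes keep degree 0 and missing
distance-based values.

**Hubs and bottlenecks.**  A node is a hub when its betweenness and
centroid both exceed the network means, a bottleneck when betweenness
and bridging do; means are taken over all non-singleton nodes and the
comparison is strict, so perfectly regular networks (complete graphs)
yield none.

**Random-model validation.**  Null ensembles are built by double-edge
swap rewiring — 10 successful swaps per edge per replica — which
preserves every node's degree exactly while randomizing the wiring; a
graph admitting no valid swap (e.g. a star) yields flagged replicas
equal to the input.  The comparison statistic is the per-replica mean
node betweenness; the real network's value is located in the ensemble by
its empirical quantile, (#replicas ≤ real)/n, with n = 1000 replicas by
default.  All replicas derive from one root seed via a seed sequence, so
ensembles are reproducible.

## Enrichment

Functional-module assignment uses the upper-tail hypergeometric test:
with a universe of M proteins, a term of K members and a selection of N,
p = P(X ≥ overlap).  Benjamini–Hochberg step-up adjustment is applied
across all tested terms and a term is called enriched at adjusted
p ≤ 0.01 by default.  The universe must be supplied explicitly and
defaults to the detected proteome (the union of annotation members when
reading GMT without one); enrichment against a whole-genome universe is
systematically more liberal, so the choice is the caller's and is
recorded in the output columns.  Differential enrichment across groups
reuses the one-way F kernel on a term-by-subject score matrix; when the
package builds that matrix itself it scores each subject's
detected-protein set against every term and uses −log10 raw p as the
score (the F rule is scale-dependent, so the scale is fixed and
documented here).  Live annotation retrieval is out of scope: annotation
sets are file inputs (GMT).

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
starting at the protein level (spectra, peptides and protein inference
are not modeled):

* **Baselines**: per-protein log-normal mean abundances
  (``baseline_log_mean`` = 3.0, ``baseline_log_sd`` = 1.0 on the natural
  log scale → median ≈ 20 PSMs, right-skewed like real spectral counts).
* **Counts**: present cells draw ``1 + NB(mean − 1, dispersion)`` — a
  shifted negative binomial with the exact target mean (default
  ``dispersion`` = 10, a moderately overdispersed regime).  The shift
  means a present protein is always observed with ≥ 1 count, so
  presence/absence is governed *only* by the dropout and exclusivity
  layers; this separation is what lets the IF-rule recovery tests make
  exact claims.
* **Dropout**: each cell is zeroed independently with probability
  1 − ``detection_prob`` (default 0.8, a typical detected-fraction for
  urine profiles), producing the missingness the IF filters target.
* **Planted signal**: per group, ``n_exclusive_per_group`` (default 20)
  proteins are zeroed outside their group; ``n_foldchange_daps``
  (default 30) proteins have their mean multiplied or divided by
  ``fold_change`` (default 3) in one affected group (for "down"
  proteins the baseline is floored at 1.5 × fold_change so the reduced
  mean stays above the count floor).
* **Cohort shape**: defaults of 5/4/7 subjects across three groups
  (HD/LRPCa/HRPCa) and 2490 proteins mirror a realistic small urine
  cohort; one column per subject (technical replicates are assumed
  already collapsed).
* **Interactome**: Barabási–Albert preferential attachment over a
  sample of the cohort's protein IDs (heavy-tailed degrees, as real
  interactomes show), uniform [0, 1] channel scores per edge, with the
  top-degree nodes recorded as hub-like truth.
* **Annotations**: random member sets per term; planted terms draw
  their members from the planted DAPs so a correct selection recovers
  them as top-ranked enrichments.

A single integer seed drives one root generator for all draws, so every
artifact is reproducible bit-for-bit.

What passing the recovery tests shows — and what it does not: the
generator produces independent cells with clean group structure, no
correlated proteins, no batch effects, no abundance-dependent dropout,
and planted effects of homogeneous size.  Recovery under these
conditions validates the *selection logic* (thresholds, rounding,
rule boundaries, test exactness); it does not certify sensitivity or
FDR on real cohorts, where correlation and structured missingness can
be adversarial.

## Numerical conventions and degenerate inputs

* IF percents and printed detection percentages round halves away from
  zero.
* Spearman correlations involving a constant profile are reported as
  missing (NaN), never coerced to 0; the matrix is symmetric with unit
  diagonal.
* DAve with both means zero is missing; the magnitude filter rejects
  missing values.
* Hypergeometric p-values are clamped to [0, 1] by construction; BH
  adjustment is monotone and bounded by 1.
* Empty networks are permitted at construction; centrality computation
  requires at least one node, randomization at least two edges.
* All tabular artifacts are TSV with headers; annotation sets are GMT;
  networks are edge-list TSV.

## Problem sizes used in the validation suites

The test suites run the centrality oracle exhaustively on all connected
graphs with up to 7 nodes plus 100 random graphs with up to 30 nodes,
validate degree preservation on 1000 rewired replicas of a 200-node
scale-free graph, and exercise recovery on the default 2490-protein
5/4/7 cohort; these sizes give exhaustive or near-exhaustive coverage of
the relevant combinatorics while keeping the full suite fast enough to
run routinely.

## Known limitations

* The F-ratio route is a univariate stand-in for multivariate stepwise
  discriminant analysis; proteins informative only jointly will be
  missed.
* The exact presence test conditions on the observed total number of
  detections; software using normal approximations or different
  two-sided conventions will print different p-values for the same
  table.
* Eigenvector centrality is computed per component and is not
  comparable across components of a disconnected network.
* The edge-channel OR filter treats the two evidence channels as
  interchangeable; no combined-score model is applied.
* Random-model validation randomizes wiring conditional on the degree
  sequence only; higher-order constraints (clustering, modularity) are
  not preserved.
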