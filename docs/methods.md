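# Methods

This note documents the statistical models, conventions and design
choices behind `guideomics`, in the order the pipeline runs them.

## Scope and data model

The package analyzes a cohort profiled across seven omics layers:
taxonomic profiles from metagenome, metatranscriptome and metaproteome
(taxMG, taxMT, taxMP), their functional counterparts at KEGG-ortholog
(KO) resolution (funMG, funMT, funMP), and the meta-metabolome (MM,
measured in three blocks: untargeted GC-MS, targeted short-chain fatty
acids, targeted bile acids). Every layer is a nonnegative feature x
sample matrix; per-sample metadata carries the diagnosis group (HC,
iRBD, PD) and the confounders sex, age, constipation and recruitment
site. A reaction universe (KO -> reactions -> reactant/product
compounds, with compound names and a ubiquitous-compound list) and a
genus x KO x sample expression tensor complete the inputs.

Normalization is total-sum scaling per sample. The three MM blocks are
sum-normalized independently and then concatenated, so a merged MM
column sums to 3; this keeps each analytical platform's internal
composition intact and is applied uniformly, including before
differential testing. Whether to re-normalize the merged matrix is an
open choice; we do not, and record the block of origin per feature so
either convention can be reconstructed.

## Guide-layer selection

Beta diversity uses the Bray-Curtis dissimilarity
d(x,y) = sum|x_i - y_i| / sum(x_i + y_i) on sum-normalized columns.
Group separation is tested with one-factor PERMANOVA: with squared
distances decomposed as SST = SSW + SSB (within-group sums computed as
(1/n_g) * sum of squared within-group distances), the statistic is

    pseudo-F = (SSB / (k-1)) / (SSW / (n-k)),    R^2 = SSB / SST.

The permutation p-value uses the add-one estimator
p = (1 + #{F_perm >= F_obs}) / (1 + n_perm) with free label
permutations (no strata; the two recruitment sites are not used as
blocks). p is therefore never 0 and is bounded below by 1/(n_perm+1).
When the number of distinct label assignments is small the test can
enumerate all of them exactly. Default n_perm = 1000.

A layer is an eligible guide when its group p < alpha (default 0.05)
and every confounder p >= alpha; eligible layers are ranked by group
R^2 and the top one drives the downstream analysis. Confounders are
tested marginally as single factors; continuous age is dichotomized at
the cohort median so the same machinery applies. No eligible layer is
a reported outcome, not an error. Note the collider caveat: when a
confounder is itself associated with diagnosis, a genuine diagnosis
effect leaks into the marginal confounder test, so strongly coupled
cohorts can reject a perfectly clean layer; the selection logic
implements the marginal convention regardless.

Alpha diversity is the Shannon index in nats, H = -sum p_i ln p_i
(natural log recorded in output metadata; the base is a convention).

## Metabolite differential analysis

Unidentified compounds are excluded before testing (they cannot be
linked to genes). Per compound: Kruskal-Wallis omnibus (tie-corrected)
across the three groups, followed by Dunn's post hoc z on the pooled
average ranks,

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j)),
    T = sum(t^3 - t) / (12(N-1)),

with two-sided normal p-values. Benjamini-Hochberg adjustment runs
across compounds separately within the omnibus family and within each
pairwise family, mirroring how comparison panels are usually reported.
Compounds constant across all samples get p = q = 1 with a flag.
Significant compounds are those with omnibus q < 0.05, annotated with
the pairwise contrasts that also pass.

Explained variance per compound and clinical factor is the one-way
ANOVA decomposition 1 - SSW/SST (clipped to [0,1]), computed after
dropping samples missing that factor; per-level variances are reported
alongside. This quantity is scale-invariant, which is what makes it
comparable across compounds.

## KO linkage

Significant compound names become case-insensitive, unanchored Python
regular expressions matched against the compound names of the reaction
universe. Every KO with at least one reaction whose reactant OR
product set intersects the matched compounds is retrieved (reaction
sides are treated symmetrically). Because the beta enantiomer of
glutamate has essentially a single reaction entry, any glutamate match
collapses to the family pattern and retrieves the KOs of L-, D- and
beta-glutamate together. A match log (pattern, compound, name) is kept
for auditability.

## Gene vs transcript differential analysis

For each linked KO the identical two-group Mann-Whitney test runs on
the sum-normalized gene-abundance layer (funMG) and transcript layer
(funMT), with BH within each (layer, pair) family. Effect size is
log2((mean_1 + eps)/(mean_2 + eps)) with eps set to half the smallest
positive value of the layer — scale-adaptive and finite even when a
group mean is 0; eps is recorded in the output. Rows are tagged by
layer so transcript-only dissociation (significant in funMT, null in
funMG) is a direct query.

Per-KO functional diversity is the Shannon index over the genus-level
expression vector of that KO, computed per sample (then compared across
groups with the same Kruskal-Wallis/Dunn machinery); a sample with zero
expression of the KO contributes a missing value rather than 0, since
the function is absent there, not evenly spread. Pathway panels (KO
lists supplied as configuration) combine the differential rows with the
log2 fold change of group-mean Shannon and a down/up/unchanged tally at
q < 0.05 that partitions the pathway.

Metabolite-feature association is Spearman's rho with average-rank
ties, two-sided p by the t approximation, BH across all (metabolite,
feature) pairs; constant vectors leave rho undefined and flagged.

## Genus-resolved expression

Transcripts-per-million scales each sample's genus x KO slice to a
total of 1e6. There is no gene-length term: synthetic features are
length-free, and real-data users should supply pre-length-normalized
counts. Group profiles are per-cell means; per-genus totals are also
reported with the display square-root transform kept as a separate
column set. Genera are clustered on their per-KO log2FC between two
groups (same eps convention) with Canberra distance — zero/zero terms
contribute 0 — and Ward linkage (the squared-update variant, i.e. what
R calls ward.D2 when fed unsquared dissimilarities). The cluster count
k is a user parameter, default 4; assignments and the dendrogram leaf
order are deterministic. The extracellular flagellum report tests each
(genus, gene) pair of the panel (default fliC, fliD, fliS, flgK, flgL,
mapped to KO ids in configuration) across the three groups.

## Community metabolic network

KOs present (nonzero) in at least 50% of samples (>= semantics: exactly
50% passes) are connected to the non-cofactor reactants and products of
their reactions, giving a bipartite KO-compound graph; cofactors
(water, energy carriers, ...) are removed so that paths reflect the
main compounds of each reaction, and compounds left without edges are
dropped. Each KO node carries an activity ratio
(mean normalized funMT + eps)/(mean normalized funMG + eps), the
transcription-per-gene-copy proxy.

Two unweighted one-mode projections are analyzed: KO nodes joined by
any shared compound, and the inverted view with compound nodes joined
by any shared KO; shared labels are retained as edge attributes, and
multiplicity is not used as a weight (single centralities are reported,
so the projections stay simple graphs; the label sets keep weighted
variants possible). Betweenness centrality on the unweighted projection
is reported both raw (unordered pair-count scale) and normalized (by
(n-1)(n-2)/2, so values lie in [0,1]); both scales are emitted because
subnetwork-vs-community comparisons are otherwise ambiguous.
Disconnected graphs are handled per component with global
normalization. A subnetwork summary compares the mean whole-graph
centrality over a node subset (not recomputed on the induced subgraph —
the comparison is against the whole community) with the community mean,
plus the induced edge count and connectedness.

The directed alternative for the KO projection (connecting only
product -> reactant chains) is deliberately not the default; reaction
sides are treated symmetrically throughout.

## Synthetic study generator

The generator produces a fully consistent study — reaction universe,
cohort, seven layers, tensor — with the planted truth serialized next
to the data. It emulates:

* **Counts.** Gamma-Poisson (negative-binomial) counts,
  Var = mu + 0.3 mu^2, with log-normal sample depths (sigma 0.3) and
  log-normal baseline compositions — the standard overdispersed model
  for sequencing-style microbiome counts. Default dimensions: 300 taxa,
  800 KOs, 150 compounds (12 cofactors), 200 MM features (180
  untargeted of which 30 unidentified, 8 SCFAs, 12 bile acids), 40
  genera x 120 KOs in the tensor, cohort 49 HC / 27 iRBD / 46 PD.
* **Reaction universe.** Random reactions with 1-3 reactants and
  products; cofactors attached to 85% of reactions; one hub compound
  (which carries the L-glutamate name, so name retrieval exercises it)
  joins a configurable fraction of reactions (0.15 default, 0.6 in the
  hub-demo preset).
* **Planted metabolite shifts.** 20 compounds across the blocks:
  beta-glutamate up in PD and iRBD, glycerol/thymine/glucuronate down,
  alanine/serine up, isovalerate/isobutyrate/valerate up, CDCA down in
  PD and iRBD, GCA down in PD, plus generic features with alternating
  directions. Fold 3.0 in PD (2.0 in iRBD where planted). Planted
  compounds sit in the upper-middle abundance range and the targeted
  panels use realistic profiles in which the shifted species are minor
  constituents — otherwise per-block sum normalization would drag every
  other feature the opposite way (compositional closure) and blow up
  the false-discovery proportion.
* **Transcript-only effects.** 30 glutamate-linked KOs get a 0.35 fold
  in PD in funMT only; funMG is untouched. The chemotaxis (26 KOs) and
  flagellar-assembly (46 KOs) pathways live among the tensor KOs with
  14 and 25 planted transcript decreases respectively, and one
  Lachnospiraceae-type genus has the extracellular flagellar panel
  additionally suppressed (fold 0.15) in PD; that genus is guaranteed a
  nonzero share of the panel KOs so the planted truth is recoverable.
* **Confounder leakage.** A sex effect (fold 2.5) is injected into
  taxMT and funMT only, so guide-layer selection must reject them.
  Cohort confounders couple to diagnosis with moderate contrasts (male
  probability 0.45/0.60/0.60, constipation 0.20/0.35/0.40 for
  HC/iRBD/PD). The coupling is kept moderate deliberately: because the
  eligibility rule tests confounders marginally, a strong
  diagnosis-confounder correlation would let the planted diagnosis
  effect masquerade as a confounder association and veto every
  informative layer.
* **Consistency.** Summing the tensor over genera reproduces the funMT
  rows of the tensor KOs exactly, by construction. All randomness
  derives from one master seed through named substreams, recorded in
  the planted truth.

What the generator does **not** emulate: phylogenetic correlation
between taxa, taxon-function coupling across layers beyond the tensor,
batch/site effects on abundances, compositional zero-inflation beyond
what gamma-Poisson produces, or measurement-specific noise (peak
integration, spectral counting). Passing tests therefore demonstrate
that the statistical machinery is correct and that planted structure of
realistic magnitude is recoverable — not that real-data effect sizes
will match.

## Numerical conventions

* Ties: average ranks everywhere.
* BH families: per layer and per comparison panel; q >= p is asserted.
* Permutation p-values: add-one estimator, seeded; exhaustive
  enumeration when requested.
* eps for fold changes and activity ratios: half the smallest positive
  value of the table(s) involved, recorded in output.
* Canberra 0/0 terms contribute 0; Bray-Curtis requires no all-zero
  sample pair.
* Degenerate inputs are flagged rows (constant features, missing KOs,
  zero-expression samples), not exceptions; contract violations
  (negative values, duplicate ids, all-zero columns, empty groups)
  raise with the offending cell or sample named.
* Betweenness is computed by igraph's exact Brandes implementation for
  speed, with networkx as fallback; tests pin both against a
  brute-force shortest-path enumeration oracle.
* Determinism: all iteration orders are sorted; GraphML is written with
  sorted node/edge order; TSVs use %.17g so write -> read round trips
  are bit-exact; re-running a pipeline with the same inputs and seed
  reproduces every output byte.

## Validation problem sizes

The validation suite scales its simulations to desk size: the
centrality oracle uses 200 random graphs of up to 12 nodes; the
PERMANOVA oracle enumerates all 20 assignments for n = 6 on 100 random
matrices, and calibrates type-I error over 500 null simulations
(99 permutations each); FDR control uses 100 null plus 100 planted
replicates at 3 x 20 samples with 200 compounds; guide-layer selection
runs 100 studies at 24/12/24 samples with a sex-balanced cohort (the
benchmark isolates the planted sex leakage from cohort-level
sex-diagnosis correlation) and 99 permutations; dissociation,
hub-recovery and determinism checks run at the full default dimensions.
Note that the type-I binomial-interval check and the >= 95/100
selection bar are themselves stochastic criteria with non-negligible
per-seed failure probability even for a perfectly calibrated
implementation; the add-one estimator is exact-or-conservative by
construction.

## Known limitations

* PERMANOVA is one-factor only; no interactions, no dispersion test,
  no stratified permutations.
* The confounder screen is marginal, hence subject to the collider
  leakage described above; a partial (covariate-adjusted) PERMANOVA is
  out of scope.
* TPM lacks a length term by design.
* Subnetwork centrality compares means of whole-graph betweenness; it
  does not recompute centrality within the induced subgraph.
* The KO projection connects KOs through any shared compound; the
  directed product->reactant chaining variant is not implemented as a
  default behavior.
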