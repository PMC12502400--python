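# guideomics

Guide-layer driven multi-omics analysis of gut-microbiome cohorts.

Integrated microbiome studies of Parkinson's disease and its prodrome
(iRBD) profile the same stool samples at up to seven omics layers:
taxonomic and functional views of the metagenome, metatranscriptome and
metaproteome (taxMG/taxMT/taxMP, funMG/funMT/funMP, with functions at
KEGG-ortholog = KO resolution) plus the meta-metabolome (MM).
`guideomics` implements the analytical chain such studies need once the
upstream feature tables exist, as a tested, reusable library and CLI:

1. **Guide-layer selection.** Bray–Curtis dissimilarity and one-factor
   PERMANOVA (pseudo-F = (SSB/(k−1))/(SSW/(n−k)), R² = SSB/SST,
   permutation p with the add-one rule, 1000 permutations by default)
   test every layer against diagnosis and against each confounder (sex,
   age, constipation). The layer that separates diagnosis groups while
   showing no confounder association becomes the *guide* for everything
   downstream.
2. **Metabolite differential analysis.** Kruskal–Wallis omnibus with
   Dunn post hoc z = (R̄ᵢ−R̄ⱼ)/√((N(N+1)/12 − T)(1/nᵢ+1/nⱼ)) on the
   identified compounds of the guide layer, Benjamini–Hochberg FDR per
   comparison family, plus a per-compound explained-variance
   decomposition (1 − SSW/SST) for each clinical factor.
3. **KO linkage.** Significant compound names become case-insensitive
   regular expressions against the compound names of a KO→reaction→
   compound universe; every KO touching a matched compound as reactant
   *or* product is retrieved (glutamate matches collapse to the L-/D-/β
   family).
4. **Gene vs transcript dissociation.** The same Mann–Whitney test runs
   per linked KO on gene abundances (funMG) and transcripts (funMT),
   BH-adjusted within each (layer, pair) family, with log₂ fold changes
   using a scale-adaptive pseudocount — so "expression changed, gene
   copies did not" is a direct query. Per-KO functional diversity
   (Shannon over the genera expressing the KO) and pathway panels with
   down/up tallies complete the picture.
5. **Genus-resolved expression.** Transcripts-per-million summaries per
   diagnosis group, clustering of genera on per-gene log₂FC (Canberra
   distance, Ward linkage), and a report for the extracellular flagellum
   genes (fliC, fliD, fliS, flgK, flgL).
6. **Community metabolic network.** A bipartite KO–compound graph from
   the reaction universe (KOs kept at ≥50% sample prevalence, ubiquitous
   cofactors removed), projected both ways — KOs joined by shared
   compounds, and the inverted view with compounds joined by shared
   KOs — with betweenness centrality (raw and normalized) ranking genes
   and metabolites by their importance to community-wide metabolism, and
   MT/MG activity ratios annotating each KO node.

A first-class synthetic-study generator produces all inputs with
recorded planted truth (metabolite shifts, transcript-only KO effects,
sex leakage confined to the metatranscriptomic layers, a hub compound,
suppressed flagellar genes), so the whole chain is testable end to end
without any data download. See `docs/methods.md` for the statistical
conventions and generator details.

## Worked example

Generate a synthetic study at the default dimensions (49/27/46 cohort,
seven layers, 800 KOs, 200 metabolites) and run the full chain:

```sh
guideomics generate --preset paper-like --seed 0 --out demo/study
guideomics run-all --input demo/study --out demo/results --seed 0
```

The run report (abridged) printed for seed 0:

```
"ecology":     {"winner": "MM", "eligible": ["MM"]}
"metabolites": {"n_tested": 170, "n_significant": 20, ...}
"link_kos":    {"n_compounds": 13, "n_kos": 509, ...}
"functional":  {"n_sig_funMT": 58, "n_sig_funMG": 0,
                "pathway_tallies": {
                  "chemotaxis":         {"down": 14, "up": 0, "size": 26},
                  "flagellar_assembly": {"down": 26, "up": 4, "size": 46}}}
"network":     {"n_ko_nodes": 794, "n_compound_nodes": 138,
                "top_compound_by_bc": "c0013", ...}
```

Reading it: the meta-metabolome separated the diagnosis groups without
confounder association and was selected as guide; 20 compounds were
significant at q < 0.05 (exactly the 20 the generator planted — check
`demo/study/planted_truth.json`); their names retrieved 509 linked KOs;
58 of those changed at the transcript level against 0 at the
gene-abundance level — the transcript-only dissociation the generator
planted; both pathways are tallied predominantly down in PD; and the
most-between compound in the inverted network, `c0013`, is the planted
hub (the compound carrying the L-glutamate name), whose linked-KO
subnetwork sits above the community mean betweenness
(0.00108 vs 0.00077 normalized). Stage outputs are plain TSV/GraphML
files under `demo/results/`.

Each stage is also a standalone subcommand (`ecology`, `metabolites`,
`link-kos`, `functional`, `taxa`, `network`) reading the same file
layout, so any step can be re-run or swapped in isolation.

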