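"""End-to-end orchestration of the guided multi-omics analysis chain.

Stages communicate only through files so partial re-runs stay
inspectable: generate (or load) -> ecology / guide-layer selection ->
metabolite differential -> KO linkage -> functional differential ->
taxon expression -> metabolic network -> machine-readable run report.
Each stage is also individually invokable from the CLI.
"""

from __future__ import annotations

import json
import logging
import re
import sys
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import ecology, functional, linkage, metabolites, network, taxa
from .tables import (
    CohortMetadata,
    OmicsTable,
    ReactionUniverse,
    TaxonFunctionTensor,
    load_metadata,
    load_omics_table,
    load_reaction_universe,
    load_tensor_long_tsv,
    merge_mm_blocks,
    sum_normalize,
)

log = logging.getLogger("guideomics")

LAYER_FILES = ["taxMG", "taxMT", "taxMP", "funMG", "funMT", "funMP"]
MM_BLOCK_FILES = {
    "untargeted": "mm_untargeted.tsv",
    "scfa": "mm_scfa.tsv",
    "bile_acids": "mm_bile_acids.tsv",
}


@dataclass
class RunConfig:
    """Parameters of a full pipeline run.

    Thresholds default to the study conventions: significance alpha
    0.05, discovery q 0.05, 1000 PERMANOVA permutations, 50% prevalence
    filter for network construction.
    """

    input_dir: str
    out_dir: str
    seed: int = 0
    alpha: float = 0.05
    q_threshold: float = 0.05
    n_perm: int = 1000
    prevalence: float = 0.5
    confounders: list[str] = field(default_factory=lambda: ["sex", "age", "constipation"])
    pair: tuple[str, str] = ("HC", "PD")
    cluster_k: int = 4
    top_correlation_features: int = 100
    patterns: list[str] | None = None  # override metabolite name patterns

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        if "pair" in doc:
            doc["pair"] = tuple(doc["pair"])
        return cls(**doc)


@dataclass
class StudyInputs:
    layers: dict[str, OmicsTable]
    mm_blocks: dict[str, OmicsTable]
    meta: CohortMetadata
    universe: ReactionUniverse
    tensor: TaxonFunctionTensor
    pathways: dict[str, list[str]]
    flagellar_genes: dict[str, str]


def write_study(study, out_dir: str | Path) -> None:
    """Serialize a generated study into the file layout run_all reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in LAYER_FILES:
        study.tables[name].to_tsv(out / f"{name}.tsv")
    for block, fname in MM_BLOCK_FILES.items():
        study.mm_blocks[block].to_tsv(out / fname)
    ann = pd.concat(
        [b.feature_annotations.assign(block=name)
         for name, b in study.mm_blocks.items()]
    )
    ann.index.name = "feature"
    ann.to_csv(out / "mm_annotations.tsv", sep="\t")
    study.meta.to_tsv(out / "metadata.tsv")
    study.universe.to_json(out / "universe.json")
    study.tensor.to_long_tsv(out / "tensor.tsv")
    study.truth.to_json(out / "planted_truth.json")
    config = {
        "pathways": study.truth.pathways,
        "flagellar_genes": study.truth.flagellar_gene_map,
    }
    (out / "pathways.json").write_text(json.dumps(config, indent=1, sort_keys=True))


def load_inputs(input_dir: str | Path) -> StudyInputs:
    d = Path(input_dir)
    layers = {name: load_omics_table(d / f"{name}.tsv", name) for name in LAYER_FILES}
    ann = pd.read_csv(d / "mm_annotations.tsv", sep="\t", index_col=0)
    blocks = {}
    for block, fname in MM_BLOCK_FILES.items():
        t = load_omics_table(d / fname, "MM")
        sub = ann[ann["block"] == block].drop(columns=["block"]).loc[t.features]
        t.feature_annotations = sub
        blocks[block] = t
    layers["MM"] = merge_mm_blocks(blocks["untargeted"], blocks["scfa"], blocks["bile_acids"])
    meta = load_metadata(d / "metadata.tsv")
    universe = load_reaction_universe(d / "universe.json")
    tensor = load_tensor_long_tsv(d / "tensor.tsv")
    pathways_doc = {}
    pw_path = d / "pathways.json"
    if pw_path.exists():
        pathways_doc = json.loads(pw_path.read_text())
    return StudyInputs(
        layers=layers, mm_blocks=blocks, meta=meta, universe=universe,
        tensor=tensor, pathways=pathways_doc.get("pathways", {}),
        flagellar_genes=pathways_doc.get("flagellar_genes", {}),
    )


def _patterns_from_compounds(names: list[str]) -> list[str]:
    """Metabolite names -> retrieval patterns.

    Any glutamate enantiomer collapses to the family pattern
    ``glutamate`` (the beta form alone has essentially no reaction
    entries, so the whole family is retrieved instead).
    """
    patterns = []
    for name in names:
        if "glutamate" in name.lower():
            patterns.append("glutamate")
        else:
            patterns.append(re.escape(name))
    return sorted(set(patterns))


def run_all(config: RunConfig) -> dict:
    """Execute every stage in order; returns (and writes) the run report.

    Any stage contract violation aborts with the stage name; outputs of
    completed stages are retained alongside a failure marker.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "parameters": {
            "seed": config.seed, "alpha": config.alpha,
            "q_threshold": config.q_threshold, "n_perm": config.n_perm,
            "prevalence": config.prevalence, "confounders": list(config.confounders),
            "pair": list(config.pair), "cluster_k": config.cluster_k,
        },
        "stages": {},
    }
    stage = "load"
    try:
        inputs = load_inputs(config.input_dir)

        # ---- stage: ecology / guide-layer selection ---------------------
        stage = "ecology"
        t0 = time.perf_counter()
        guide = ecology.select_guide_layer(
            inputs.layers, inputs.meta, confounders=config.confounders,
            alpha=config.alpha, n_perm=config.n_perm, seed=config.seed,
        )
        guide.results.to_csv(out / "guide_selection.tsv", sep="\t", index=False)
        report["stages"]["ecology"] = {
            "winner": guide.winner, "eligible": guide.eligible,
        }
        log.info("ecology stage: %.1fs", time.perf_counter() - t0)
        log.info("ecology: guide layer = %s", guide.winner)

        # ---- stage: metabolite differential -----------------------------
        stage = "metabolites"
        sig_names: list[str] = []
        if guide.winner is None:
            report["stages"]["metabolites"] = {"skipped": "no guide layer"}
        else:
            t0 = time.perf_counter()
            mm = inputs.layers["MM"]
            ann = mm.feature_annotations
            identified = ann.index[ann["identified"].astype(bool)].tolist()
            mm_tested = OmicsTable("MM", mm.data.loc[identified], normalized=False)
            diff = metabolites.kruskal_dunn(mm_tested, inputs.meta)
            diff.to_csv(out / "mm_differential.tsv", sep="\t", index=False)
            var_frames = [
                metabolites.variance_explained(mm_tested, inputs.meta, factor)
                for factor in ["group"] + list(config.confounders)
            ]
            pd.concat(var_frames).to_csv(out / "mm_variance.tsv", sep="\t", index=False)
            sig = metabolites.significant_compounds(diff, config.q_threshold)
            sig_df = pd.DataFrame(
                [dict(feature=c.feature, q=c.q, direction=c.direction,
                      significant_pairs="|".join(c.significant_pairs)) for c in sig]
            )
            sig_df.to_csv(out / "significant_compounds.tsv", sep="\t", index=False)
            sig_names = [c.feature for c in sig]
            report["stages"]["metabolites"] = {
                "n_tested": len(identified), "n_significant": len(sig_names),
                "significant": sig_names,
            }
            log.info("metabolites stage: %.1fs", time.perf_counter() - t0)
            log.info("metabolites: %d significant compounds", len(sig_names))

        # ---- stage: KO linkage ------------------------------------------
        stage = "link-kos"
        linked_kos: set[str] = set()
        if not sig_names:
            report["stages"]["link_kos"] = {"skipped": "no significant compounds"}
        else:
            patterns = config.patterns or _patterns_from_compounds(sig_names)
            mlog = linkage.MatchLog()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                compounds = linkage.find_compounds(inputs.universe, patterns, log=mlog)
                linked_kos = linkage.kos_for_compounds(inputs.universe, compounds)
            rows = []
            for pattern, cid, name in mlog.records:
                for ko in sorted(linkage.kos_for_compounds(inputs.universe, {cid})):
                    rows.append(dict(pattern=pattern, compound=cid, name=name, ko=ko))
            pd.DataFrame(rows, columns=["pattern", "compound", "name", "ko"]).to_csv(
                out / "ko_links.tsv", sep="\t", index=False
            )
            report["stages"]["link_kos"] = {
                "patterns": patterns, "n_compounds": len(compounds),
                "n_kos": len(linked_kos),
            }
            log.info("link-kos: %d compounds -> %d KOs", len(compounds), len(linked_kos))

        # ---- stage: functional differential -----------------------------
        stage = "functional"
        norm_mg = sum_normalize(inputs.layers["funMG"])
        norm_mt = sum_normalize(inputs.layers["funMT"])
        if not linked_kos:
            report["stages"]["functional"] = {"skipped": "no linked KOs"}
        else:
            t0 = time.perf_counter()
            fdiff = functional.differential_ko(
                norm_mg, norm_mt, inputs.meta, linked_kos, config.pair
            )
            fdiff.to_csv(out / "functional_differential.tsv", sep="\t", index=False)
            mt_sig = fdiff[(fdiff["layer"] == "funMT") & (fdiff["q"] < config.q_threshold)]
            mg_sig = fdiff[(fdiff["layer"] == "funMG") & (fdiff["q"] < config.q_threshold)]

            mm_norm = sum_normalize(inputs.layers["MM"])
            taxmt_norm = sum_normalize(inputs.layers["taxMT"])
            top = (
                taxmt_norm.data.mean(axis=1)
                .sort_values(ascending=False, kind="mergesort")
                .head(config.top_correlation_features)
                .index.tolist()
            )
            corr = functional.metabolite_feature_correlation(
                mm_norm, taxmt_norm, features=top, metabolites=sig_names
            )
            corr.to_csv(out / "mm_taxmt_correlations.tsv", sep="\t", index=False)

            tallies = {}
            for pw_name, pw_kos in sorted(inputs.pathways.items()):
                panel = functional.pathway_panel(
                    norm_mg, norm_mt, inputs.meta, pw_kos, config.pair,
                    tensor=taxa.tpm_normalize(inputs.tensor), pathway=pw_name,
                    q_threshold=config.q_threshold,
                )
                panel.table.to_csv(out / f"pathway_{pw_name}.tsv", sep="\t", index=False)
                panel.shannon_fc.to_csv(
                    out / f"pathway_{pw_name}_shannon.tsv", sep="\t", index=False
                )
                tallies[pw_name] = panel.tally
            report["stages"]["functional"] = {
                "n_kos_tested": len(linked_kos),
                "n_sig_funMT": int(len(mt_sig)), "n_sig_funMG": int(len(mg_sig)),
                "pathway_tallies": tallies,
            }
            log.info("functional stage: %.1fs", time.perf_counter() - t0)
            log.info(
                "functional: %d/%d KOs significant in funMT/funMG",
                len(mt_sig), len(mg_sig),
            )

        # ---- stage: taxon expression ------------------------------------
        stage = "taxa"
        t0 = time.perf_counter()
        tpm = taxa.tpm_normalize(inputs.tensor)
        profiles = taxa.genus_group_profiles(tpm, inputs.meta)
        profiles.genus_totals.round(6).to_csv(out / "genus_group_totals.tsv", sep="\t")
        clusters = taxa.cluster_genera(profiles, config.pair, k=config.cluster_k)
        cl = clusters.assignment.to_frame()
        cl["dendrogram_position"] = [clusters.order.index(g) for g in cl.index]
        cl.index.name = "genus"
        cl.to_csv(out / "genus_clusters.tsv", sep="\t")
        (out / "genus_dendrogram.nwk").write_text(clusters.to_newick() + "\n")
        if inputs.flagellar_genes:
            flag = taxa.extracellular_flagellar_report(
                tpm, inputs.meta, inputs.flagellar_genes, tpm.genera
            )
            flag.to_csv(out / "flagellar_report.tsv", sep="\t", index=False)
        report["stages"]["taxa"] = {
            "n_genera": len(tpm.genera), "k": config.cluster_k,
        }
        log.info("taxa stage: %.1fs", time.perf_counter() - t0)

        # ---- stage: metabolic network -----------------------------------
        stage = "network"
        t0 = time.perf_counter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net = network.build_network(
                inputs.universe, inputs.layers["funMG"], prevalence=config.prevalence
            )
            network.attach_activity(net, norm_mt, norm_mg)
        ko_graph = network.project_ko(net)
        cpd_graph = network.project_compound(net)
        ko_bc = network.betweenness(ko_graph)
        cpd_bc = network.betweenness(cpd_graph)
        ko_bc.table.round(10).to_csv(out / "centrality_ko.tsv", sep="\t")
        cpd_bc.table.round(10).to_csv(out / "centrality_compound.tsv", sep="\t")
        for n_, d_ in ko_graph.nodes(data=True):
            d_["bc_norm"] = float(ko_bc.table.loc[n_, "bc_norm"])
            act = net.graph.nodes[n_].get("activity")
            if act is not None:
                d_["activity"] = float(act)
        network.write_graphml(ko_graph, out / "network_ko.graphml")
        network.write_graphml(cpd_graph, out / "network_compound.graphml")

        sub_rows = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glut = linkage.glutamate_ko_set(inputs.universe) & set(ko_graph.nodes)
            if glut:
                sub_rows.append(
                    network.subnetwork_report(ko_graph, ko_bc, glut, "glutamate").to_dict()
                )
            if linked_kos:
                present = linked_kos & set(ko_graph.nodes)
                if present:
                    sub_rows.append(
                        network.subnetwork_report(
                            ko_graph, ko_bc, present, "significant-metabolite-linked"
                        ).to_dict()
                    )
        pd.DataFrame(sub_rows).to_csv(out / "subnetworks.tsv", sep="\t", index=False)
        ranked = cpd_bc.ranked()
        report["stages"]["network"] = {
            "n_ko_nodes": int(ko_graph.number_of_nodes()),
            "n_compound_nodes": int(cpd_graph.number_of_nodes()),
            "top_compound_by_bc": str(ranked.index[0]) if len(ranked) else None,
            "subnetworks": sub_rows,
        }
        log.info("network stage: %.1fs", time.perf_counter() - t0)
    except Exception as exc:
        report["failed_stage"] = stage
        report["error"] = str(exc)
        (out / "run_report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        (out / "FAILED").write_text(f"{stage}: {exc}\n")
        raise

    (out / "run_report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def setup_logging(verbose: bool = True) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if verbose else logging.WARNING,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
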