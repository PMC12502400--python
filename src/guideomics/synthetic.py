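"""Synthetic multi-omics study generator with recorded planted truth.

Emulates the statistical structure the analysis chain assumes: a
three-group cohort (healthy controls, prodromal iRBD, Parkinson's
disease) with sex/age/constipation confounders, compositional
overdispersed count matrices for seven omics layers, a reaction universe
with a designated hub compound and ubiquitous cofactors, planted
metabolite shifts in the meta-metabolome, transcript-only effects
(present in funMT, absent from funMG), sex leakage confined to the
metatranscriptomic layers, and a genus x KO x sample expression tensor
consistent with funMT by construction.

Counts are gamma-Poisson (negative-binomial-like) with log-normal
sample depths, the standard overdispersed model for sequencing-derived
microbiome counts; it keeps the rank-based tests downstream honest.
All randomness flows from one master seed through named substreams.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import (
    CohortMetadata,
    OmicsTable,
    ReactionUniverse,
    TaxonFunctionTensor,
    ValidationError,
    merge_mm_blocks,
)
from .linkage import glutamate_ko_set

__all__ = [
    "EffectConfig",
    "PlantedTruth",
    "SyntheticStudy",
    "make_universe",
    "make_cohort",
    "make_multiomics",
    "generate_study",
]

_COFACTOR_NAMES = [
    "water", "ATP", "ADP", "NAD+", "NADH", "NADP+", "NADPH", "coenzyme A",
    "phosphate", "diphosphate", "CO2", "H+",
]

#: Real-sounding fecal-metabolome names attached to designated compounds so
#: that name-pattern retrieval has something to match.
_NAMED_COMPOUNDS = [
    "L-glutamate", "D-glutamate", "beta-glutamate", "2-oxoglutarate",
    "glycerol", "L-alanine", "L-serine", "thymine", "D-glucuronate",
    "isovalerate", "isobutyrate", "valerate", "chenodeoxycholic acid",
    "glycocholic acid", "cholic acid", "butyrate", "propionate", "acetate",
]

_GENUS_POOL = [
    ("Roseburia", "Lachnospiraceae"), ("Blautia", "Lachnospiraceae"),
    ("Agathobacter", "Lachnospiraceae"), ("Eubacterium", "Eubacteriaceae"),
    ("Faecalibacterium", "Ruminococcaceae"), ("Ruminococcus", "Ruminococcaceae"),
    ("Methanobrevibacter", "Methanobacteriaceae"), ("Akkermansia", "Akkermansiaceae"),
    ("Escherichia", "Enterobacteriaceae"), ("Citrobacter", "Enterobacteriaceae"),
    ("Clostridium", "Clostridiaceae"), ("Cellulosilyticum", "Lachnospiraceae"),
    ("Flavonifractor", "Oscillospiraceae"), ("Eisenbergiella", "Lachnospiraceae"),
    ("Succinivibrio", "Succinivibrionaceae"), ("Prevotella", "Prevotellaceae"),
    ("Bacteroides", "Bacteroidaceae"), ("Alistipes", "Rikenellaceae"),
    ("Dysosmobacter", "Oscillospiraceae"), ("Enterocloster", "Lachnospiraceae"),
    ("Ruminiclostridium", "Oscillospiraceae"), ("Butyrivibrio", "Lachnospiraceae"),
    ("Fusicatenibacter", "Lachnospiraceae"), ("Oliverpabstia", "Lachnospiraceae"),
    ("Lawsonibacter", "Oscillospiraceae"), ("Choladocola", "Lachnospiraceae"),
    ("Lactobacillus", "Lactobacillaceae"), ("Bifidobacterium", "Bifidobacteriaceae"),
    ("Hungatella", "Lachnospiraceae"), ("Coprococcus", "Lachnospiraceae"),
    ("Dorea", "Lachnospiraceae"), ("Anaerostipes", "Lachnospiraceae"),
    ("Oscillibacter", "Oscillospiraceae"), ("Parabacteroides", "Tannerellaceae"),
    ("Phocaeicola", "Bacteroidaceae"), ("Streptococcus", "Streptococcaceae"),
    ("Veillonella", "Veillonellaceae"), ("Collinsella", "Coriobacteriaceae"),
    ("Holdemanella", "Erysipelotrichaceae"), ("Subdoligranulum", "Ruminococcaceae"),
]

_SCFA_FEATURES = [
    "acetate", "propionate", "butyrate", "formate",
    "valerate", "isovalerate", "isobutyrate", "caproate",
]

_BILE_FEATURES = [
    "cholic acid", "chenodeoxycholic acid", "glycocholic acid",
    "taurocholic acid", "deoxycholic acid", "lithocholic acid",
    "ursodeoxycholic acid", "glycochenodeoxycholic acid", "hyocholic acid",
    "taurodeoxycholic acid", "glycodeoxycholic acid", "hyodeoxycholic acid",
]


@dataclass
class EffectConfig:
    """Planted effect sizes; folds are multiplicative on group means.

    Defaults are the study conditions the generator emulates: moderate
    metabolite shifts on abundant compounds, a strong transcription-only
    decrease in PD, and sex leakage confined to the two
    metatranscriptomic layers.
    """

    mm_fold: float = 3.0            # planted metabolite fold in PD
    mm_fold_irbd: float = 2.0       # intermediate fold in iRBD where planted
    n_mm_generic_planted: int = 9   # generic planted untargeted features
    transcript_fold: float = 0.35   # funMT-only PD fold on planted KOs
    n_transcript_only: int = 30
    sex_fold: float = 2.5           # male/female fold on leaked features
    n_sex_taxa: int = 25            # taxMT features with sex leakage
    n_sex_kos: int = 50             # funMT features with sex leakage
    taxmt_group_fold: float = 1.8   # mild taxMT group shift (15 taxa)
    n_taxmt_group: int = 15
    funmp_group_fold: float = 1.6
    n_funmp_group: int = 20
    pathway_down_fold: float = 0.35  # PD fold for planted pathway transcripts
    flagellar_suppression_fold: float = 0.15
    dispersion: float = 0.3          # gamma-Poisson overdispersion

    @classmethod
    def null(cls) -> "EffectConfig":
        """Zero-effect configuration: all layers exchangeable across groups."""
        return cls(
            mm_fold=1.0, mm_fold_irbd=1.0, n_mm_generic_planted=0,
            transcript_fold=1.0, n_transcript_only=0, sex_fold=1.0,
            n_sex_taxa=0, n_sex_kos=0, taxmt_group_fold=1.0, n_taxmt_group=0,
            funmp_group_fold=1.0, n_funmp_group=0, pathway_down_fold=1.0,
            flagellar_suppression_fold=1.0,
        )


@dataclass
class PlantedTruth:
    """Ground truth recorded alongside the generated study."""

    mm_differential: list[dict] = field(default_factory=list)
    unidentified: list[str] = field(default_factory=list)
    transcript_only_kos: list[str] = field(default_factory=list)
    confounded_layers: list[str] = field(default_factory=list)
    hub_compound: str | None = None
    glutamate_compounds: list[str] = field(default_factory=list)
    pathways: dict[str, list[str]] = field(default_factory=dict)
    pathway_down: dict[str, list[str]] = field(default_factory=dict)
    flagellar_gene_map: dict[str, str] = field(default_factory=dict)
    suppressed_pairs: list[list[str]] = field(default_factory=list)
    suppressed_genus: str | None = None
    seeds: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        return cls(**json.loads(Path(path).read_text()))


def _substreams(seed: int | None, names: list[str]):
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    rngs = {n: np.random.default_rng(c) for n, c in zip(names, children)}
    seeds = {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}
    return rngs, seeds


# ---------------------------------------------------------------------------
# Reaction universe


def make_universe(
    n_ko: int = 800,
    n_compound: int = 150,
    n_cofactor: int = 12,
    hub_degree_fraction: float = 0.15,
    seed: int | None = None,
) -> tuple[ReactionUniverse, PlantedTruth]:
    """Random reaction universe with a planted hub compound.

    Reactions have 1-3 non-cofactor reactants and products; the hub
    compound (which doubles as the L-glutamate-named compound so the
    name-retrieval path exercises it) joins ``hub_degree_fraction`` of
    all reactions; cofactors are attached to most reactions, emulating
    water/ATP ubiquity.
    """
    if not (0 < n_cofactor < n_compound):
        raise ValidationError("need 0 < n_cofactor < n_compound")
    if not (0.0 < hub_degree_fraction < 1.0):
        raise ValidationError("hub_degree_fraction must be in (0, 1)")
    if n_compound < n_cofactor + len(_NAMED_COMPOUNDS) + 2:
        raise ValidationError(
            f"n_compound must be at least {n_cofactor + len(_NAMED_COMPOUNDS) + 2}"
        )
    rngs, seeds = _substreams(seed, ["reactions", "names"])
    rng = rngs["reactions"]

    compounds = [f"c{i + 1:04d}" for i in range(n_compound)]
    cofactors = compounds[:n_cofactor]
    main = compounds[n_cofactor:]
    hub = main[0]  # doubles as L-glutamate below

    names: dict[str, tuple[str, ...]] = {}
    for i, cid in enumerate(cofactors):
        names[cid] = (_COFACTOR_NAMES[i % len(_COFACTOR_NAMES)],)
    for i, cid in enumerate(main):
        if i < len(_NAMED_COMPOUNDS):
            names[cid] = (_NAMED_COMPOUNDS[i],)
        else:
            names[cid] = (f"compound-{cid}",)
    glutamate_compounds = [main[0], main[1], main[2]]  # L-, D-, beta-glutamate

    n_rxn = n_ko  # roughly one reaction per KO plus reuse
    reaction_sides: dict[str, tuple[frozenset, frozenset]] = {}
    hub_pool = np.array([c for c in main if c != hub])
    for r in range(n_rxn):
        rid = f"R{r + 1:05d}"
        n_lhs = rng.integers(1, 4)
        n_rhs = rng.integers(1, 4)
        chosen = rng.choice(hub_pool, size=n_lhs + n_rhs, replace=False)
        lhs = set(chosen[:n_lhs])
        rhs = set(chosen[n_lhs:])
        if rng.random() < hub_degree_fraction:
            (lhs if rng.random() < 0.5 else rhs).add(hub)
        # ubiquitous cofactors on most reactions
        if rng.random() < 0.85:
            lhs.add(str(rng.choice(cofactors)))
            rhs.add(str(rng.choice(cofactors)))
        reaction_sides[rid] = (frozenset(lhs), frozenset(rhs))

    rxn_ids = sorted(reaction_sides)
    ko_reactions: dict[str, frozenset] = {}
    for i in range(n_ko):
        ko = f"K{i + 1:05d}"
        k_rxn = rng.integers(1, 4)
        ko_reactions[ko] = frozenset(rng.choice(rxn_ids, size=k_rxn, replace=False))

    universe = ReactionUniverse(
        ko_reactions=ko_reactions,
        reaction_sides=reaction_sides,
        compound_names=names,
        cofactors=frozenset(cofactors),
    )
    truth = PlantedTruth(
        hub_compound=hub, glutamate_compounds=glutamate_compounds, seeds=seeds,
    )
    return universe, truth


# ---------------------------------------------------------------------------
# Cohort


def make_cohort(
    n_hc: int = 49,
    n_irbd: int = 27,
    n_pd: int = 46,
    seed: int | None = None,
    male_prob: tuple[float, float, float] = (0.45, 0.60, 0.60),
    constipation_prob: tuple[float, float, float] = (0.20, 0.35, 0.40),
) -> CohortMetadata:
    """Three-group cohort with male excess and higher constipation
    prevalence in the iRBD/PD groups (configurable), ages from a shared
    distribution, and two recruitment-site labels."""
    for n in (n_hc, n_irbd, n_pd):
        if n < 3:
            raise ValidationError("each group needs >= 3 samples")
    rngs, _ = _substreams(seed, ["cohort"])
    rng = rngs["cohort"]
    rows = []
    for group, n, pm, pc in zip(
        ("HC", "iRBD", "PD"), (n_hc, n_irbd, n_pd), male_prob, constipation_prob
    ):
        for i in range(n):
            rows.append(
                dict(
                    sample=f"{group}{i + 1:03d}",
                    group=group,
                    sex="M" if rng.random() < pm else "F",
                    age=float(np.clip(rng.normal(65, 8), 40, 88).round(1)),
                    constipation=bool(rng.random() < pc),
                    cohort="siteA" if rng.random() < 0.7 else "siteB",
                )
            )
    frame = pd.DataFrame(rows).set_index("sample")
    return CohortMetadata(frame)


# ---------------------------------------------------------------------------
# Count machinery


def _baseline(rng, n: int, sigma: float = 1.5) -> np.ndarray:
    w = np.exp(rng.normal(0.0, sigma, size=n))
    return w / w.sum()


def _gamma_poisson(rng, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Overdispersed counts: Poisson with gamma-mixed rate,
    Var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mu).astype(float)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam).astype(float)


def _counts_layer(
    rng,
    features: list[str],
    meta: CohortMetadata,
    base: np.ndarray,
    depth_mean: float,
    dispersion: float,
    group_mult: dict[str, dict[str, float]] | None = None,
    sex_mult: dict[str, float] | None = None,
) -> pd.DataFrame:
    """One feature x sample count matrix with per-feature multiplicative
    group and sex modulation."""
    samples = meta.samples
    depths = np.exp(rng.normal(np.log(depth_mean), 0.3, size=len(samples)))
    mult = np.ones((len(features), len(samples)))
    fidx = {f: i for i, f in enumerate(features)}
    if group_mult:
        grp = meta.frame["group"]
        for f, per_group in group_mult.items():
            for g, m in per_group.items():
                cols = [j for j, s in enumerate(samples) if grp[s] == g]
                mult[fidx[f], cols] *= m
    if sex_mult:
        sex = meta.frame["sex"]
        male_cols = [j for j, s in enumerate(samples) if sex[s] == "M"]
        for f, m in sex_mult.items():
            mult[fidx[f], male_cols] *= m
    mu = np.outer(base, depths) * mult
    counts = _gamma_poisson(rng, mu, dispersion)
    return pd.DataFrame(counts, index=features, columns=samples)


# ---------------------------------------------------------------------------
# Full study


@dataclass
class SyntheticStudy:
    universe: ReactionUniverse
    meta: CohortMetadata
    tables: dict[str, OmicsTable]
    mm_blocks: dict[str, OmicsTable]
    tensor: TaxonFunctionTensor
    truth: PlantedTruth


def make_multiomics(
    u: ReactionUniverse,
    meta: CohortMetadata,
    effects: EffectConfig | None = None,
    seed: int | None = None,
    truth: PlantedTruth | None = None,
    n_taxa: int = 300,
    n_mm_untargeted: int = 180,
    n_unidentified: int = 30,
    n_genera: int = 40,
    n_tensor_kos: int = 120,
) -> SyntheticStudy:
    """Generate all seven omics layers plus the genus x KO x sample
    tensor, consistent with the given reaction universe and cohort.

    Planted structure (recorded in the returned truth):

    * meta-metabolome shifts on 20 abundant compounds across the three
      blocks (beta-glutamate up in PD and iRBD, a primary bile acid
      down, three branched/straight SCFAs up, plus generic features);
    * a transcript-only KO set, shifted in funMT but untouched in funMG,
      drawn from the glutamate-linked KOs of the universe;
    * chemotaxis (26 KOs) and flagellar-assembly (46 KOs) pathways among
      the tensor KOs with planted transcript decreases in PD;
    * sex leakage confined to taxMT and funMT;
    * per-genus suppression of the extracellular flagellar panel in PD
      for one Lachnospiraceae-like genus.
    """
    effects = effects or EffectConfig()
    if truth is None:
        truth = PlantedTruth()
    rngs, seeds = _substreams(
        seed,
        ["taxMG", "taxMT", "taxMP", "funMG", "funMT", "funMP",
         "mm", "tensor", "choices"],
    )
    truth.seeds.update(seeds)
    choice_rng = rngs["choices"]
    phi = effects.dispersion
    kos = u.kos
    if len(kos) < n_tensor_kos:
        raise ValidationError("universe smaller than requested tensor KO count")

    # ----- designated KO sets -------------------------------------------
    glut_kos = sorted(glutamate_ko_set(u))
    tensor_kos = sorted(
        choice_rng.choice(kos, size=n_tensor_kos, replace=False)
    )
    non_tensor = sorted(set(kos) - set(tensor_kos))
    glut_non_tensor = [k for k in glut_kos if k in set(non_tensor)]
    n_to = min(effects.n_transcript_only, len(glut_non_tensor))
    transcript_only = sorted(
        choice_rng.choice(glut_non_tensor, size=n_to, replace=False)
    ) if n_to else []
    truth.transcript_only_kos = transcript_only

    if n_tensor_kos < 72:
        raise ValidationError(
            "need >= 72 tensor KOs to host the chemotaxis (26) and "
            "flagellar-assembly (46) pathway panels"
        )
    chemotaxis = tensor_kos[:26]
    flagellar = tensor_kos[26:72]
    truth.pathways = {"chemotaxis": chemotaxis, "flagellar_assembly": flagellar}
    down_chemo = sorted(choice_rng.choice(chemotaxis, size=14, replace=False))
    down_fa = sorted(choice_rng.choice(flagellar, size=25, replace=False))
    if effects.pathway_down_fold == 1.0:
        down_chemo, down_fa = [], []
    truth.pathway_down = {"chemotaxis": down_chemo, "flagellar_assembly": down_fa}
    flag_panel = {
        gene: ko
        for gene, ko in zip(("fliC", "fliD", "fliS", "flgK", "flgL"), flagellar[:5])
    }
    truth.flagellar_gene_map = flag_panel

    # ----- taxa layers ---------------------------------------------------
    taxa = [f"t{i + 1:04d}" for i in range(n_taxa)]
    base_tax = _baseline(rngs["taxMG"], n_taxa)
    taxMG = OmicsTable(
        "taxMG",
        _counts_layer(rngs["taxMG"], taxa, meta, base_tax, 5e4, phi),
    )

    sex_taxa = sorted(
        choice_rng.choice(taxa, size=min(effects.n_sex_taxa, n_taxa), replace=False)
    ) if effects.n_sex_taxa else []
    grp_pool = [t for t in taxa if t not in set(sex_taxa)]
    grp_taxa = sorted(
        choice_rng.choice(
            grp_pool, size=min(effects.n_taxmt_group, len(grp_pool)), replace=False,
        )
    ) if effects.n_taxmt_group else []
    taxMT = OmicsTable(
        "taxMT",
        _counts_layer(
            rngs["taxMT"], taxa, meta, base_tax, 5e4, phi,
            group_mult={
                t: {"PD": effects.taxmt_group_fold, "iRBD": np.sqrt(effects.taxmt_group_fold)}
                for t in grp_taxa
            },
            sex_mult={t: effects.sex_fold for t in sex_taxa},
        ),
    )
    taxMP = OmicsTable(
        "taxMP", _counts_layer(rngs["taxMP"], taxa, meta, base_tax, 4e3, phi)
    )

    # ----- functional layers --------------------------------------------
    base_fun = _baseline(rngs["funMG"], len(kos))
    funMG = OmicsTable(
        "funMG", _counts_layer(rngs["funMG"], kos, meta, base_fun, 1e5, phi)
    )

    # funMT: tensor KOs come from the genus-resolved tensor (collapsed);
    # the remaining KOs are generated directly.
    samples = meta.samples
    mt_rng = rngs["funMT"]
    depths_mt = np.exp(mt_rng.normal(np.log(1e5), 0.3, size=len(samples)))
    base_fun_series = pd.Series(base_fun, index=kos)

    sex_ko_pool = [k for k in non_tensor if k not in set(transcript_only)]
    sex_kos = sorted(
        choice_rng.choice(sex_ko_pool, size=min(effects.n_sex_kos, len(sex_ko_pool)),
                          replace=False)
    ) if effects.n_sex_kos else []

    grp = meta.frame["group"]
    sex = meta.frame["sex"]
    pd_cols = np.array([grp[s] == "PD" for s in samples])
    irbd_cols = np.array([grp[s] == "iRBD" for s in samples])
    male_cols = np.array([sex[s] == "M" for s in samples])

    # direct (non-tensor) funMT rows
    mult_direct = np.ones((len(non_tensor), len(samples)))
    nt_idx = {k: i for i, k in enumerate(non_tensor)}
    for k in transcript_only:
        mult_direct[nt_idx[k], pd_cols] *= effects.transcript_fold
        mult_direct[nt_idx[k], irbd_cols] *= np.sqrt(effects.transcript_fold)
    for k in sex_kos:
        mult_direct[nt_idx[k], male_cols] *= effects.sex_fold
    mu_direct = np.outer(base_fun_series[non_tensor].to_numpy(), depths_mt) * mult_direct
    direct_counts = _gamma_poisson(mt_rng, mu_direct, phi)

    # tensor: genus shares per KO, then counts at genus resolution
    tensor_rng = rngs["tensor"]
    genus_names = [g for g, _ in _GENUS_POOL[:n_genera]]
    genus_family = {g: f for g, f in _GENUS_POOL[:n_genera]}
    shares = np.zeros((n_genera, n_tensor_kos))
    for j in range(n_tensor_kos):
        n_expr = tensor_rng.integers(4, 9)
        who = tensor_rng.choice(n_genera, size=n_expr, replace=False)
        shares[who, j] = tensor_rng.dirichlet(np.ones(n_expr) * 1.5)

    t_idx = {k: i for i, k in enumerate(tensor_kos)}
    # the genus carrying the planted flagellar suppression must actually
    # express the panel, or the planted truth would be unrecoverable
    suppressed_genus = "Roseburia" if "Roseburia" in genus_names else genus_names[0]
    gi_panel = genus_names.index(suppressed_genus)
    for ko in flag_panel.values():
        j = t_idx[ko]
        if shares[gi_panel, j] < 0.2:
            shares[gi_panel, j] = 0.2 + 0.2 * tensor_rng.random()
            shares[:, j] /= shares[:, j].sum()
    mult_tensor = np.ones((n_genera, n_tensor_kos, len(samples)))
    for k in down_chemo + down_fa:
        mult_tensor[:, t_idx[k], pd_cols] *= effects.pathway_down_fold
    gi = gi_panel
    suppressed_pairs = []
    if effects.flagellar_suppression_fold != 1.0:
        for gene, ko in flag_panel.items():
            mult_tensor[gi, t_idx[ko], pd_cols] *= effects.flagellar_suppression_fold
            suppressed_pairs.append([suppressed_genus, ko])
    truth.suppressed_pairs = suppressed_pairs
    truth.suppressed_genus = suppressed_genus

    base_tensor = base_fun_series[tensor_kos].to_numpy()
    mu_tensor = (
        shares[:, :, None]
        * base_tensor[None, :, None]
        * depths_mt[None, None, :]
        * mult_tensor
    )
    tensor_counts = _gamma_poisson(tensor_rng, mu_tensor, phi)
    tensor = TaxonFunctionTensor(
        genus_names, tensor_kos, list(samples), tensor_counts,
        units="counts", genus_family=genus_family,
    )

    funmt_frame = pd.concat(
        [
            pd.DataFrame(direct_counts, index=non_tensor, columns=samples),
            tensor.collapse_genera(),
        ]
    ).loc[kos]
    funMT = OmicsTable("funMT", funmt_frame)

    funmp_grp = sorted(
        choice_rng.choice(kos, size=min(effects.n_funmp_group, len(kos)), replace=False)
    ) if effects.n_funmp_group else []
    funMP = OmicsTable(
        "funMP",
        _counts_layer(
            rngs["funMP"], kos, meta, base_fun, 4e3, phi,
            group_mult={
                k: {"PD": effects.funmp_group_fold, "iRBD": np.sqrt(effects.funmp_group_fold)}
                for k in funmp_grp
            },
        ),
    )

    # ----- meta-metabolome ----------------------------------------------
    mm_rng = rngs["mm"]
    planted: list[dict] = []

    def add_planted(feature, block, direction, fold_pd, fold_irbd):
        planted.append(
            dict(feature=feature, block=block, direction=direction,
                 fold_pd=fold_pd, fold_irbd=fold_irbd)
        )

    f = effects.mm_fold
    fi = effects.mm_fold_irbd
    named_plants = [
        ("beta-glutamate", +1, f, fi),
        ("glycerol", -1, 1 / f, 1.0),
        ("L-alanine", +1, f, 1.0),
        ("L-serine", +1, f, 1.0),
        ("thymine", -1, 1 / f, 1.0),
        ("D-glucuronate", -1, 1 / f, 1.0),
    ]
    generic = [f"met-unt-{i + 1:03d}" for i in range(
        n_mm_untargeted - len(named_plants) - n_unidentified)]
    unknown = [f"unknown-{i + 1:03d}" for i in range(n_unidentified)]
    unt_features = [n for n, *_ in named_plants] + generic + unknown
    for name, direction, fp, fir in named_plants:
        if f != 1.0:
            add_planted(name, "untargeted", direction, fp, fir)
    gen_planted = sorted(
        choice_rng.choice(generic, size=min(effects.n_mm_generic_planted, len(generic)),
                          replace=False)
    ) if effects.n_mm_generic_planted else []
    for i, name in enumerate(gen_planted):
        direction = 1 if i % 2 == 0 else -1
        add_planted(name, "untargeted", direction, f**direction, 1.0)

    scfa_plants = {"valerate": +1, "isovalerate": +1, "isobutyrate": +1}
    if f != 1.0:
        for name, direction in sorted(scfa_plants.items()):
            add_planted(name, "scfa", direction, f, fi)
    bile_plants = {"chenodeoxycholic acid": (-1, 1 / f, 1 / fi),
                   "glycocholic acid": (-1, 1 / f, 1.0)}
    if f != 1.0:
        for name, (direction, fp, fir) in sorted(bile_plants.items()):
            add_planted(name, "bile_acids", direction, fp, fir)
    truth.mm_differential = planted
    truth.unidentified = unknown
    truth.confounded_layers = (
        ["taxMT", "funMT"] if (effects.n_sex_taxa or effects.n_sex_kos) else []
    )

    planted_mult = {
        p["feature"]: {"PD": p["fold_pd"], "iRBD": p["fold_irbd"]} for p in planted
    }

    def mm_block(
        features: list[str], depth: float, boost: list[str],
        fixed_base: dict[str, float] | None = None,
    ) -> OmicsTable:
        if fixed_base is not None:
            # targeted panels have a characteristic abundance profile;
            # jitter it slightly between studies
            base = pd.Series(
                [fixed_base[f] * np.exp(mm_rng.normal(0, 0.2)) for f in features],
                index=features,
            )
        else:
            base = pd.Series(_baseline(mm_rng, len(features), sigma=1.2), index=features)
            # planted/named compounds sit in the upper-middle abundance
            # range: detectable, but not dominating the block total (which
            # would leak group structure into every feature through
            # sum-normalization closure)
            hi = np.quantile(base, 0.75)
            for name in boost:
                base[name] = hi * (0.7 + 0.6 * mm_rng.random())
        base = (base / base.sum()).to_numpy()
        gm = {name: m for name, m in planted_mult.items() if name in set(features)}
        return OmicsTable(
            "MM",
            _counts_layer(mm_rng, features, meta, base, depth, phi, group_mult=gm),
        )

    # major species dominate the targeted panels; the planted species
    # (branched/odd SCFAs, the two shifted bile acids) are minor, so their
    # fold changes barely perturb the per-block totals
    scfa_base = {
        "acetate": 0.50, "propionate": 0.20, "butyrate": 0.20, "formate": 0.03,
        "valerate": 0.02, "isovalerate": 0.015, "isobutyrate": 0.012, "caproate": 0.005,
    }
    bile_base = {
        "cholic acid": 0.24, "chenodeoxycholic acid": 0.08, "glycocholic acid": 0.05,
        "taurocholic acid": 0.05, "deoxycholic acid": 0.22, "lithocholic acid": 0.16,
        "ursodeoxycholic acid": 0.05, "glycochenodeoxycholic acid": 0.04,
        "hyocholic acid": 0.03, "taurodeoxycholic acid": 0.03,
        "glycodeoxycholic acid": 0.03, "hyodeoxycholic acid": 0.02,
    }
    unt = mm_block(unt_features, 1e5,
                   [n for n, *_ in named_plants] + list(gen_planted))
    scfa = mm_block(list(_SCFA_FEATURES), 5e4, [], fixed_base=scfa_base)
    bile = mm_block(list(_BILE_FEATURES), 5e4, [], fixed_base=bile_base)

    ann = pd.DataFrame(
        {"identified": [not f.startswith("unknown-") for f in unt_features]},
        index=pd.Index(unt_features),
    )
    unt.feature_annotations = ann
    scfa.feature_annotations = pd.DataFrame(
        {"identified": [True] * len(_SCFA_FEATURES)}, index=pd.Index(_SCFA_FEATURES)
    )
    bile.feature_annotations = pd.DataFrame(
        {"identified": [True] * len(_BILE_FEATURES)}, index=pd.Index(_BILE_FEATURES)
    )
    mm_blocks = {"untargeted": unt, "scfa": scfa, "bile_acids": bile}
    mm = merge_mm_blocks(unt, scfa, bile)

    tables = {
        "taxMG": taxMG, "taxMT": taxMT, "taxMP": taxMP,
        "funMG": funMG, "funMT": funMT, "funMP": funMP, "MM": mm,
    }
    return SyntheticStudy(
        universe=u, meta=meta, tables=tables, mm_blocks=mm_blocks,
        tensor=tensor, truth=truth,
    )


def generate_study(
    preset: str = "paper-like",
    seed: int | None = None,
    **overrides,
) -> SyntheticStudy:
    """Convenience wrapper: universe + cohort + multi-omics in one call.

    Presets: ``paper-like`` (default planted effects), ``null`` (no
    effects anywhere), ``hub-demo`` (small universe with a pronounced
    hub compound for network demonstrations).
    """
    rngs, _ = _substreams(seed, ["universe", "cohort", "omics"])
    del rngs
    ss = np.random.SeedSequence(seed).spawn(3)
    u_seed, c_seed, o_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss)

    if preset == "hub-demo":
        u, truth = make_universe(
            n_ko=overrides.pop("n_ko", 150),
            n_compound=overrides.pop("n_compound", 60),
            n_cofactor=overrides.pop("n_cofactor", 8),
            hub_degree_fraction=overrides.pop("hub_degree_fraction", 0.6),
            seed=u_seed,
        )
    else:
        u, truth = make_universe(
            n_ko=overrides.pop("n_ko", 800),
            n_compound=overrides.pop("n_compound", 150),
            n_cofactor=overrides.pop("n_cofactor", 12),
            hub_degree_fraction=overrides.pop("hub_degree_fraction", 0.15),
            seed=u_seed,
        )
    cohort_kwargs = {
        k: overrides.pop(k)
        for k in ("n_hc", "n_irbd", "n_pd", "male_prob", "constipation_prob")
        if k in overrides
    }
    meta = make_cohort(seed=c_seed, **cohort_kwargs)
    effects = overrides.pop("effects", None)
    if effects is None:
        effects = EffectConfig.null() if preset == "null" else EffectConfig()
    if preset == "hub-demo":
        overrides.setdefault("n_tensor_kos", min(100, len(u.kos)))
    return make_multiomics(u, meta, effects=effects, seed=o_seed, truth=truth, **overrides)
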