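"""Genus-resolved functional expression summaries and clustering.

TPM here carries no gene-length term: the synthetic features are
length-free, and real-data users are expected to supply pre-length-
normalized counts. Clustering of genera follows the fold-change
convention of the expression heatmap: log2FC between two diagnosis
groups per gene, Canberra distance, Ward linkage.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .metabolites import _dunn_pairwise, half_min_positive
from .tables import (
    CohortMetadata,
    TaxonFunctionTensor,
    ValidationError,
    make_difftable,
)

__all__ = [
    "tpm_normalize",
    "genus_group_profiles",
    "GroupProfiles",
    "cluster_genera",
    "ClusterResult",
    "extracellular_flagellar_report",
    "DEFAULT_FLAGELLAR_GENES",
]

#: Extracellular flagellum components: flagellin, filament cap, and
#: hook-filament junction genes.
DEFAULT_FLAGELLAR_GENES = ("fliC", "fliD", "fliS", "flgK", "flgL")


def tpm_normalize(counts: TaxonFunctionTensor) -> TaxonFunctionTensor:
    """Scale each sample slice so all (genus, KO) cells sum to 1e6."""
    totals = counts.values.sum(axis=(0, 1))
    zero = np.where(totals <= 0)[0]
    if len(zero):
        raise ValidationError(
            f"zero-total sample(s): {[counts.samples[i] for i in zero]}"
        )
    values = counts.values / totals[None, None, :] * 1e6
    return TaxonFunctionTensor(
        list(counts.genera), list(counts.kos), list(counts.samples), values,
        units="tpm", genus_family=counts.genus_family,
    )


@dataclass
class GroupProfiles:
    """Mean TPM per (genus, KO) per diagnosis group, plus per-genus
    per-group totals (with the display square-root transform kept as a
    separate column set)."""

    means: dict[str, pd.DataFrame]  # group -> genus x KO
    genus_totals: pd.DataFrame  # genus x group (raw sums)
    genus_totals_sqrt: pd.DataFrame


def genus_group_profiles(t: TaxonFunctionTensor, meta: CohortMetadata) -> GroupProfiles:
    meta.require_samples(t.samples)
    grp = meta.group_of(t.samples)
    means: dict[str, pd.DataFrame] = {}
    totals = {}
    for g in sorted(grp.unique()):
        cols = [i for i, s in enumerate(t.samples) if grp[s] == g]
        if not cols:
            raise ValidationError(f"group {g} has zero samples")
        m = t.values[:, :, cols].mean(axis=2)
        means[g] = pd.DataFrame(m, index=t.genera, columns=t.kos)
        totals[g] = means[g].sum(axis=1)
    genus_totals = pd.DataFrame(totals)
    return GroupProfiles(
        means=means, genus_totals=genus_totals, genus_totals_sqrt=np.sqrt(genus_totals)
    )


@dataclass
class ClusterResult:
    assignment: pd.Series  # genus -> cluster id (1..k)
    order: list[str]  # dendrogram leaf order
    linkage: np.ndarray
    log2fc: pd.DataFrame  # genus x KO matrix the clustering ran on

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)
        labels = list(self.log2fc.index)

        def rec(node) -> str:
            if node.is_leaf():
                return labels[node.id]
            return f"({rec(node.left)},{rec(node.right)}):{node.dist:.6g}"

        return rec(tree) + ";"


def cluster_genera(
    profiles: GroupProfiles, pair: tuple[str, str] = ("HC", "PD"), k: int = 4
) -> ClusterResult:
    """Agglomerative clustering of genera on their per-gene log2 fold
    change between two groups.

    Distance is Canberra, d(x, y) = sum |x_i - y_i| / (|x_i| + |y_i|)
    with zero-denominator terms contributing 0; linkage is Ward (the
    squared-distance update, i.e. R's ward.D2 on unsquared distances).
    Deterministic: identical input gives identical assignment and leaf
    order.
    """
    a, b = pair
    ma, mb = profiles.means[a], profiles.means[b]
    if len(ma) < 2:
        raise ValidationError("need >= 2 genera")
    if k > len(ma):
        raise ValidationError(f"k={k} exceeds number of genera ({len(ma)})")
    eps = half_min_positive(ma.to_numpy(), mb.to_numpy())
    fc = np.log2((ma.to_numpy() + eps) / (mb.to_numpy() + eps))
    fc_df = pd.DataFrame(fc, index=ma.index, columns=ma.columns)
    d = pdist(fc, metric="canberra")  # scipy: 0/0 terms contribute 0
    z = hierarchy.linkage(d, method="ward")
    labels = hierarchy.fcluster(z, t=k, criterion="maxclust")
    order = [ma.index[i] for i in hierarchy.leaves_list(z)]
    return ClusterResult(
        assignment=pd.Series(labels, index=ma.index, name="cluster"),
        order=order, linkage=z, log2fc=fc_df,
    )


def extracellular_flagellar_report(
    t: TaxonFunctionTensor,
    meta: CohortMetadata,
    genes: dict[str, str],
    genera: list[str],
    groups: tuple[str, ...] = ("HC", "iRBD", "PD"),
) -> pd.DataFrame:
    """Per (genus, gene) three-group comparison of TPM expression.

    ``genes`` maps gene symbols (default panel fliC, fliD, fliS, flgK,
    flgL) to KO ids. Each present (genus, gene) cell gets a
    Kruskal-Wallis omnibus row and Dunn pairwise rows; BH adjustment runs
    across (genus, gene) cells within each comparison family. Absent
    genes or genera yield flagged rows.
    """
    meta.require_samples(t.samples)
    grp = meta.group_of(t.samples)
    codes = grp.map({g: i for i, g in enumerate(groups)}).to_numpy()
    pair_labels = [f"{a}_vs_{b}" for a, b in itertools.combinations(groups, 2)]
    rows = []
    for genus in genera:
        for gene, ko in sorted(genes.items()):
            ident = f"{genus}:{gene}"
            if genus not in t.genera or ko not in t.kos:
                rows.append(dict(feature=ident, comparison="omnibus", test="kruskal-wallis",
                                 genus=genus, gene=gene, ko=ko, flag="missing"))
                continue
            v = t.values[t.genera.index(genus), t.kos.index(ko), :]
            if np.ptp(v) == 0:
                rows.append(dict(feature=ident, comparison="omnibus", test="kruskal-wallis",
                                 genus=genus, gene=gene, ko=ko, statistic=0.0, p=1.0,
                                 flag="constant"))
                continue
            by_group = [v[codes == i] for i in range(len(groups))]
            h, p = stats.kruskal(*by_group)
            rows.append(dict(feature=ident, comparison="omnibus", test="kruskal-wallis",
                             genus=genus, gene=gene, ko=ko, statistic=float(h), p=float(p)))
            dunn = _dunn_pairwise(v, codes, len(groups))
            for (i, j), lab in zip(itertools.combinations(range(len(groups)), 2), pair_labels):
                z, pz = dunn[(i, j)]
                rows.append(dict(feature=ident, comparison=lab, test="dunn",
                                 genus=genus, gene=gene, ko=ko, statistic=z, p=pz,
                                 direction=float(np.sign(z))))
    df = make_difftable(rows)
    df["q"] = np.nan
    for lab in ["omnibus"] + pair_labels:
        mask = (df["comparison"] == lab) & df["p"].notna()
        if mask.any():
            df.loc[mask, "q"] = multipletests(df.loc[mask, "p"], method="fdr_bh")[1]
    return df
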