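"""Gene-abundance vs transcript differential analysis over linked KO sets.

The central contrast of the pipeline: for each metabolite-linked KO, the
same two-group Mann-Whitney test is run on the gene-abundance layer
(funMG) and the transcript layer (funMT), with BH adjustment within each
(layer, pair) family, so transcript-only dissociation - expression
changes without gene-copy changes - is directly queryable. Per-KO
taxonomic Shannon diversity quantifies how many, and how evenly, genera
carry out a function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ecology import shannon
from .metabolites import half_min_positive, log2_fold_change
from .tables import (
    CohortMetadata,
    OmicsTable,
    TaxonFunctionTensor,
    ValidationError,
    make_difftable,
)

__all__ = [
    "differential_ko",
    "ko_taxon_shannon",
    "metabolite_feature_correlation",
    "pathway_panel",
    "PathwayPanel",
]


def differential_ko(
    funMG: OmicsTable,
    funMT: OmicsTable,
    meta: CohortMetadata,
    kos: set[str] | list[str],
    pair: tuple[str, str] = ("HC", "PD"),
) -> pd.DataFrame:
    """Paired gene vs transcript differential test for a KO set.

    One row per (KO, layer): two-sided Mann-Whitney p, BH q within the
    (layer, pair) family, and log2 fold change of group means with a
    per-layer pseudocount of half the smallest positive value. KOs
    missing from a layer produce a flagged row with missing statistics.
    """
    a, b = pair
    kos = sorted(kos)
    rows = []
    for layer_name, table in (("funMG", funMG), ("funMT", funMT)):
        if not table.normalized:
            raise ValidationError(f"{layer_name} must be sum-normalized first")
        meta.require_samples(table.samples)
        grp = meta.group_of(table.samples)
        ia = grp[grp == a].index
        ib = grp[grp == b].index
        if len(ia) < 2 or len(ib) < 2:
            raise ValidationError(f"pair {pair} needs >= 2 samples per group")
        eps = half_min_positive(table.data.to_numpy())
        present = [k for k in kos if k in table.data.index]
        for ko in kos:
            if ko not in table.data.index:
                rows.append(
                    dict(feature=ko, comparison=f"{a}_vs_{b}", test="mann-whitney",
                         layer=layer_name, flag="missing-from-layer")
                )
                continue
            va = table.data.loc[ko, ia].to_numpy(dtype=float)
            vb = table.data.loc[ko, ib].to_numpy(dtype=float)
            if np.ptp(np.concatenate([va, vb])) == 0:
                rows.append(
                    dict(feature=ko, comparison=f"{a}_vs_{b}", test="mann-whitney",
                         layer=layer_name, statistic=float(len(va) * len(vb) / 2),
                         p=1.0, direction=0.0, effect=0.0, flag="constant")
                )
                continue
            u, p = stats.mannwhitneyu(va, vb, alternative="two-sided")
            rows.append(
                dict(feature=ko, comparison=f"{a}_vs_{b}", test="mann-whitney",
                     layer=layer_name, statistic=float(u), p=float(p),
                     direction=float(np.sign(u - len(va) * len(vb) / 2.0)),
                     effect=log2_fold_change(va.mean(), vb.mean(), eps))
            )
        del present
    df = make_difftable(rows)
    df["q"] = np.nan
    for layer_name in ("funMG", "funMT"):
        mask = (df["layer"] == layer_name) & df["p"].notna()
        if mask.any():
            df.loc[mask, "q"] = multipletests(df.loc[mask, "p"], method="fdr_bh")[1]
    return df


def ko_taxon_shannon(tensor: TaxonFunctionTensor, ko: str) -> pd.Series:
    """Per-sample Shannon diversity (nats) over the genera expressing one
    KO. Samples with zero total expression of the KO yield NaN (the
    function is absent there, not evenly absent)."""
    if ko not in tensor.kos:
        raise ValidationError(f"KO {ko!r} not in tensor")
    mat = tensor.ko_slice(ko)  # genus x sample
    out = {}
    for s in tensor.samples:
        v = mat[s].to_numpy(dtype=float)
        out[s] = shannon(v) if v.sum() > 0 else np.nan
    return pd.Series(out, name=ko)


def metabolite_feature_correlation(
    mm: OmicsTable, other: OmicsTable, features: list[str] | None = None,
    metabolites: list[str] | None = None,
) -> pd.DataFrame:
    """Spearman correlation of every (metabolite, feature) pair across
    the shared sample set.

    Average-rank ties, two-sided p by the t approximation, BH across all
    pairs. Constant vectors leave rho undefined and the row flagged.
    """
    shared = [s for s in mm.samples if s in set(other.samples)]
    if len(shared) < 4:
        raise ValidationError("need >= 4 shared samples for correlation")
    mets = metabolites if metabolites is not None else mm.features
    feats = features if features is not None else other.features
    xm = mm.data.loc[mets, shared].to_numpy(dtype=float)
    xo = other.data.loc[feats, shared].to_numpy(dtype=float)
    n = len(shared)

    rm = np.apply_along_axis(stats.rankdata, 1, xm)
    ro = np.apply_along_axis(stats.rankdata, 1, xo)
    const_m = np.ptp(xm, axis=1) == 0
    const_o = np.ptp(xo, axis=1) == 0
    rm_c = rm - rm.mean(axis=1, keepdims=True)
    ro_c = ro - ro.mean(axis=1, keepdims=True)
    denom = np.outer(
        np.sqrt((rm_c**2).sum(axis=1)), np.sqrt((ro_c**2).sum(axis=1))
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (rm_c @ ro_c.T) / denom
    rho = np.clip(rho, -1.0, 1.0)
    rho[const_m, :] = np.nan
    rho[:, const_o] = np.nan

    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    p[np.isinf(tstat)] = 0.0

    rows = []
    for i, m in enumerate(mets):
        for j, f in enumerate(feats):
            rows.append(
                dict(feature=f, metabolite=m, comparison="correlation",
                     test="spearman", statistic=np.nan,
                     p=float(p[i, j]) if np.isfinite(rho[i, j]) else np.nan,
                     effect=float(rho[i, j]) if np.isfinite(rho[i, j]) else np.nan,
                     direction=float(np.sign(rho[i, j])) if np.isfinite(rho[i, j]) else np.nan,
                     flag=None if np.isfinite(rho[i, j]) else "constant-vector")
            )
    df = make_difftable(rows)
    mask = df["p"].notna()
    df["q"] = np.nan
    if mask.any():
        df.loc[mask, "q"] = multipletests(df.loc[mask, "p"], method="fdr_bh")[1]
    return df


@dataclass
class PathwayPanel:
    """Differential rows plus Shannon fold changes for one pathway's KOs.

    ``tally`` counts KOs down/up/unchanged in the transcript layer at
    q < 0.05, partitioning the pathway.
    """

    table: pd.DataFrame
    shannon_fc: pd.DataFrame
    tally: dict[str, int]
    pathway: str


def pathway_panel(
    funMG: OmicsTable,
    funMT: OmicsTable,
    meta: CohortMetadata,
    kos: list[str],
    pair: tuple[str, str] = ("HC", "PD"),
    tensor: TaxonFunctionTensor | None = None,
    pathway: str = "pathway",
    q_threshold: float = 0.05,
) -> PathwayPanel:
    """Pathway-level summary: per-KO gene/transcript differential rows,
    per-KO taxonomic-Shannon fold change between groups, and the
    down/up/unchanged tally over the pathway.

    Shannon is computed per sample and averaged within each group before
    the fold change (log2 of group means with a half-min-positive
    pseudocount over the per-KO means).
    """
    if not kos:
        raise ValidationError("empty pathway KO list")
    table = differential_ko(funMG, funMT, meta, kos, pair)

    sh_rows = []
    if tensor is not None:
        a, b = pair
        grp = meta.group_of(tensor.samples)
        means_a, means_b = {}, {}
        for ko in kos:
            if ko not in tensor.kos:
                sh_rows.append(dict(ko=ko, shannon_log2fc=np.nan, flag="missing-from-tensor"))
                continue
            h = ko_taxon_shannon(tensor, ko)
            ha = h[grp[grp == a].index].dropna()
            hb = h[grp[grp == b].index].dropna()
            means_a[ko] = ha.mean() if len(ha) else np.nan
            means_b[ko] = hb.mean() if len(hb) else np.nan
        eps = half_min_positive(
            np.array([v for v in means_a.values() if np.isfinite(v)]),
            np.array([v for v in means_b.values() if np.isfinite(v)]),
        )
        for ko in kos:
            if ko in means_a and np.isfinite(means_a[ko]) and np.isfinite(means_b[ko]):
                sh_rows.append(
                    dict(ko=ko, shannon_log2fc=log2_fold_change(means_a[ko], means_b[ko], eps),
                         flag=None)
                )
            elif ko in means_a:
                sh_rows.append(dict(ko=ko, shannon_log2fc=np.nan, flag="no-expression"))
    shannon_fc = pd.DataFrame(sh_rows, columns=["ko", "shannon_log2fc", "flag"])

    mt = table[(table["layer"] == "funMT") & table["q"].notna()]
    down = int(((mt["q"] < q_threshold) & (mt["direction"] > 0)).sum())
    up = int(((mt["q"] < q_threshold) & (mt["direction"] < 0)).sum())
    tally = {"down": down, "up": up, "unchanged": len(kos) - down - up, "size": len(kos)}
    return PathwayPanel(table=table, shannon_fc=shannon_fc, tally=tally, pathway=pathway)
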