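"""Differential abundance of guide-layer features across diagnosis groups.

Nonparametric throughout: Kruskal-Wallis omnibus with Dunn post hoc for
three groups, Mann-Whitney for pairs, Benjamini-Hochberg adjustment
across features within each comparison family, and a per-feature
explained-variance decomposition for confounder assessment. Ties take
average ranks everywhere.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import (
    CohortMetadata,
    OmicsTable,
    ValidationError,
    make_difftable,
)

__all__ = [
    "kruskal_dunn",
    "pairwise_mannwhitney",
    "variance_explained",
    "significant_compounds",
    "SignificantCompound",
    "log2_fold_change",
    "half_min_positive",
]


def half_min_positive(*arrays) -> float:
    """Scale-adaptive pseudocount: half the smallest positive value seen
    across the given arrays (1.0 if there is none)."""
    mins = []
    for a in arrays:
        a = np.asarray(a, dtype=float)
        pos = a[a > 0]
        if pos.size:
            mins.append(pos.min())
    return float(min(mins)) / 2.0 if mins else 1.0


def log2_fold_change(mean_a: float, mean_b: float, eps: float) -> float:
    return float(np.log2((mean_a + eps) / (mean_b + eps)))


def _dunn_pairwise(values: np.ndarray, codes: np.ndarray, k: int):
    """Dunn's post hoc z statistics on pooled average ranks with tie
    correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))
    with tie term T = sum(t^3 - t) / (12 (N - 1)).
    """
    n_tot = len(values)
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_tot - 1))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term
    out = {}
    for i, j in itertools.combinations(range(k), 2):
        ni, nj = (codes == i).sum(), (codes == j).sum()
        ri = ranks[codes == i].mean()
        rj = ranks[codes == j].mean()
        denom = np.sqrt(var_base * (1.0 / ni + 1.0 / nj))
        z = 0.0 if denom == 0 else (ri - rj) / denom
        p = 2.0 * stats.norm.sf(abs(z))
        out[(i, j)] = (float(z), float(min(p, 1.0)))
    return out


def kruskal_dunn(
    t: OmicsTable,
    meta: CohortMetadata,
    groups: tuple[str, ...] = ("HC", "iRBD", "PD"),
    eps: float | None = None,
) -> pd.DataFrame:
    """Per-feature Kruskal-Wallis omnibus plus Dunn pairwise post hoc.

    Returns a long differential table with one omnibus row and one row
    per group pair for every feature. BH adjustment is applied across
    features separately within the omnibus family and within each
    pairwise family. Features constant across all samples get p = 1 with
    a ``constant`` flag. ``direction`` is the sign of the mean-rank
    difference of the first pair member minus the second; ``effect`` is
    the log2 fold change of group means with a scale-adaptive
    pseudocount.
    """
    meta.require_samples(t.samples)
    grp = meta.group_of(t.samples)
    present = [g for g in groups if (grp == g).sum() > 0]
    if len(present) < 3:
        raise ValidationError(f"need all three groups present, found {present}")
    codes = grp.map({g: i for i, g in enumerate(groups)}).to_numpy()
    for i, g in enumerate(groups):
        if (codes == i).sum() < 2:
            raise ValidationError(f"group {g} has fewer than two samples")
    if eps is None:
        eps = half_min_positive(t.data.to_numpy())

    pair_labels = [f"{a}_vs_{b}" for a, b in itertools.combinations(groups, 2)]
    rows = []
    x = t.data.to_numpy()
    for fi, feature in enumerate(t.features):
        v = x[fi]
        if np.ptp(v) == 0:
            rows.append(
                dict(feature=feature, comparison="omnibus", test="kruskal-wallis",
                     statistic=0.0, p=1.0, flag="constant")
            )
            for lab in pair_labels:
                rows.append(
                    dict(feature=feature, comparison=lab, test="dunn",
                         statistic=0.0, p=1.0, direction=0.0, effect=0.0,
                         flag="constant")
                )
            continue
        samples_by_group = [v[codes == i] for i in range(len(groups))]
        h, p_omni = stats.kruskal(*samples_by_group)
        rows.append(
            dict(feature=feature, comparison="omnibus", test="kruskal-wallis",
                 statistic=float(h), p=float(p_omni))
        )
        dunn = _dunn_pairwise(v, codes, len(groups))
        means = [sg.mean() for sg in samples_by_group]
        for (i, j), lab in zip(itertools.combinations(range(len(groups)), 2), pair_labels):
            z, p = dunn[(i, j)]
            rows.append(
                dict(feature=feature, comparison=lab, test="dunn",
                     statistic=z, p=p, direction=float(np.sign(z)),
                     effect=log2_fold_change(means[i], means[j], eps))
            )
    df = make_difftable(rows)
    df["q"] = np.nan
    for lab in ["omnibus"] + pair_labels:
        mask = df["comparison"] == lab
        df.loc[mask, "q"] = multipletests(df.loc[mask, "p"], method="fdr_bh")[1]
    return df


def pairwise_mannwhitney(
    t: OmicsTable,
    meta: CohortMetadata,
    pair: tuple[str, str],
    eps: float | None = None,
) -> pd.DataFrame:
    """Two-sided Mann-Whitney per feature for one group pair, BH-adjusted
    across features.

    Uses the exact null distribution for small tie-free samples and the
    tie-corrected normal approximation otherwise (scipy's ``auto``
    policy).
    """
    a, b = pair
    meta.require_samples(t.samples)
    grp = meta.group_of(t.samples)
    ia = grp[grp == a].index
    ib = grp[grp == b].index
    if len(ia) == 0 or len(ib) == 0:
        raise ValidationError(f"empty group in pair {pair}")
    if eps is None:
        eps = half_min_positive(t.data.to_numpy())
    rows = []
    for feature in t.features:
        va = t.data.loc[feature, ia].to_numpy(dtype=float)
        vb = t.data.loc[feature, ib].to_numpy(dtype=float)
        if np.ptp(np.concatenate([va, vb])) == 0:
            rows.append(
                dict(feature=feature, comparison=f"{a}_vs_{b}", test="mann-whitney",
                     statistic=float(len(va) * len(vb) / 2.0), p=1.0,
                     direction=0.0, effect=0.0, flag="constant")
            )
            continue
        u, p = stats.mannwhitneyu(va, vb, alternative="two-sided")
        rows.append(
            dict(feature=feature, comparison=f"{a}_vs_{b}", test="mann-whitney",
                 statistic=float(u), p=float(p),
                 direction=float(np.sign(u - len(va) * len(vb) / 2.0)),
                 effect=log2_fold_change(va.mean(), vb.mean(), eps))
        )
    df = make_difftable(rows)
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


def variance_explained(
    t: OmicsTable, meta: CohortMetadata, factor: str
) -> pd.DataFrame:
    """Per-feature fraction of variance explained by a clinical factor.

    explained = 1 - SSW/SST, the one-way ANOVA decomposition (pooled
    within-level sum of squares over total sum of squares), clipped to
    [0, 1]. Samples with a missing value for the factor are dropped;
    features with zero total variance get explained = 0 with a flag.
    Per-level variances are reported alongside so alternative summaries
    can be reconstructed.
    """
    meta.require_samples(t.samples)
    lab = meta.frame.loc[t.samples, factor].dropna()
    if factor == "group":
        lab = lab.astype(str)
    levels = sorted(lab.unique(), key=str)
    if len(levels) < 2:
        raise ValidationError(f"factor {factor!r} has fewer than two levels after dropping NAs")
    cols = list(lab.index)
    x = t.data[cols].to_numpy(dtype=float)
    codes = lab.map({lv: i for i, lv in enumerate(levels)}).to_numpy()
    rows = []
    for fi, feature in enumerate(t.features):
        v = x[fi]
        sst = ((v - v.mean()) ** 2).sum()
        level_vars = {}
        ssw = 0.0
        for i, lv in enumerate(levels):
            vi = v[codes == i]
            ssw += ((vi - vi.mean()) ** 2).sum()
            level_vars[f"var_{lv}"] = float(vi.var(ddof=1)) if len(vi) > 1 else np.nan
        if sst <= 0:
            rows.append(dict(feature=feature, factor=factor, explained=0.0,
                             total_variance=0.0, flag="zero-variance", **level_vars))
            continue
        rows.append(
            dict(feature=feature, factor=factor,
                 explained=float(np.clip(1.0 - ssw / sst, 0.0, 1.0)),
                 total_variance=float(np.var(v, ddof=1)), flag=None, **level_vars)
        )
    return pd.DataFrame(rows)


@dataclass
class SignificantCompound:
    feature: str
    q: float
    direction: float
    significant_pairs: list[str] = field(default_factory=list)


def significant_compounds(
    diff: pd.DataFrame, q_threshold: float = 0.05
) -> list[SignificantCompound]:
    """Features whose omnibus q-value clears the threshold, annotated with
    the pairwise contrasts that also pass.

    Expects a :func:`kruskal_dunn` table from which unidentified
    compounds were excluded before testing (they cannot be linked to
    genes).
    """
    if len(diff) == 0:
        return []
    omni = diff[diff["comparison"] == "omnibus"]
    hits = omni[omni["q"] < q_threshold]
    out = []
    for _, row in hits.iterrows():
        pairs = diff[(diff["feature"] == row["feature"]) & (diff["comparison"] != "omnibus")]
        sig_pairs = pairs[pairs["q"] < q_threshold]
        # headline direction: sign of the strongest passing contrast
        if len(sig_pairs):
            best = sig_pairs.loc[sig_pairs["q"].idxmin()]
            direction = float(best["direction"])
        else:
            direction = 0.0
        out.append(
            SignificantCompound(
                feature=row["feature"], q=float(row["q"]), direction=direction,
                significant_pairs=sorted(sig_pairs["comparison"].tolist()),
            )
        )
    out.sort(key=lambda c: (c.q, c.feature))
    return out
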