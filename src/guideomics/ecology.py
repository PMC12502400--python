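"""Alpha/beta diversity and permutational multivariate ANOVA.

The guide-layer selection logic lives here: every omics layer is tested
against the diagnosis grouping and against each confounder with a
one-factor PERMANOVA on Bray-Curtis dissimilarities, and the layer that
separates diagnosis groups while showing no confounder association is
flagged as the guide for downstream differential analysis.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .tables import CohortMetadata, OmicsTable, ValidationError, sum_normalize

__all__ = [
    "DistanceMatrix",
    "PermanovaResult",
    "shannon",
    "bray_curtis",
    "permanova",
    "pairwise_permanova",
    "select_guide_layer",
    "GuideLayerReport",
]


def shannon(abundances) -> float:
    """Shannon diversity H = -sum p_i ln p_i in nats.

    The vector is normalized internally; zeros contribute nothing. An
    all-zero vector has no defined composition and raises.
    """
    x = np.asarray(abundances, dtype=float)
    if (x < 0).any():
        raise ValidationError("negative abundances")
    total = x.sum()
    if total <= 0:
        raise ValidationError("all-zero abundance vector")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample dissimilarity matrix with zero diagonal."""

    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.samples)
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix shape does not match sample list")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValidationError("distance matrix diagonal not zero")
        if (self.values < -1e-12).any():
            raise ValidationError("negative distances")

    def subset(self, samples: list[str]) -> "DistanceMatrix":
        idx = [self.samples.index(s) for s in samples]
        return DistanceMatrix(list(samples), self.values[np.ix_(idx, idx)])


def bray_curtis(t: OmicsTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between sample columns.

    d(x, y) = sum|x_i - y_i| / sum(x_i + y_i). Undefined (and rejected)
    when a pair of all-zero samples occurs.
    """
    if t.data.shape[1] < 2:
        raise ValidationError("need at least two samples")
    x = t.data.to_numpy().T  # samples x features
    zero = np.where(x.sum(axis=1) == 0)[0]
    if len(zero) >= 2:
        names = [t.samples[i] for i in zero]
        raise ValidationError(f"all-zero sample pair(s) make Bray-Curtis undefined: {names}")
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(list(t.samples), d)


@dataclass
class PermanovaResult:
    factor: str
    pseudo_F: float
    R2: float
    p: float
    n_perm: int
    comparison: str = "all"
    q: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.R2 <= 1.0 + 1e-12):
            raise ValidationError(f"R2 out of range: {self.R2}")


def _group_ss(d2: np.ndarray, codes: np.ndarray, k: int) -> float:
    """Within-group sum of squares from squared distances:
    SSW = sum_g (1/n_g) sum_{i<j in g} d_ij^2."""
    ssw = 0.0
    for g in range(k):
        idx = np.where(codes == g)[0]
        sub = d2[np.ix_(idx, idx)]
        ssw += sub.sum() / (2.0 * len(idx))
    return ssw


def _distinct_assignments(codes: np.ndarray):
    """Yield all distinct rearrangements of a label vector (multiset
    permutations), identity included."""
    n = len(codes)
    counts = np.bincount(codes)
    # recursive multiset permutation, lexicographic, no external deps
    def rec(prefix, remaining):
        if len(prefix) == n:
            yield np.array(prefix, dtype=int)
            return
        for g in range(len(remaining)):
            if remaining[g] > 0:
                remaining[g] -= 1
                yield from rec(prefix + [g], remaining)
                remaining[g] += 1

    yield from rec([], list(counts))


def permanova(
    d: DistanceMatrix,
    labels,
    n_perm: int = 1000,
    seed: int | None = None,
    factor: str = "group",
    exhaustive: bool = False,
) -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    pseudo-F = (SSB / (k - 1)) / (SSW / (n - k)) from the standard
    decomposition of the total sum of squared distances;
    R^2 = SSB / SST. The p-value uses the add-one permutation estimator
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm) with free label
    permutations, so p is never 0 and is bounded below by
    1 / (n_perm + 1). With ``exhaustive=True`` every distinct label
    assignment is enumerated instead and p = #{F >= F_obs} / #assignments
    (the identity assignment counts itself).
    """
    labels = pd.Series(list(labels), index=d.samples)
    levels = sorted(labels.unique())
    k = len(levels)
    n = len(labels)
    if k < 2:
        raise ValidationError("need at least two groups")
    codes = labels.map({lv: i for i, lv in enumerate(levels)}).to_numpy()
    counts = np.bincount(codes)
    if (counts < 2).any():
        small = [levels[i] for i in np.where(counts < 2)[0]]
        raise ValidationError(f"group(s) with fewer than two samples: {small}")
    if n_perm < 1 and not exhaustive:
        raise ValidationError("n_perm must be >= 1")

    d2 = d.values**2
    ss_total = d2.sum() / (2.0 * n)
    if ss_total <= 0:
        raise ValidationError("constant distance matrix: zero total sum of squares")

    def f_of(c: np.ndarray) -> float:
        ssw = _group_ss(d2, c, k)
        ssb = ss_total - ssw
        return (ssb / (k - 1)) / (ssw / (n - k))

    f_obs = f_of(codes)
    r2 = 1.0 - _group_ss(d2, codes, k) / ss_total

    if exhaustive:
        fs = np.array([f_of(c) for c in _distinct_assignments(codes)])
        p = float((fs >= f_obs - 1e-12).sum() / len(fs))
        n_perm_used = len(fs) - 1
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        perm = codes.copy()
        for _ in range(n_perm):
            rng.shuffle(perm)
            if f_of(perm) >= f_obs - 1e-12:
                hits += 1
        p = (1.0 + hits) / (1.0 + n_perm)
        n_perm_used = n_perm

    return PermanovaResult(
        factor=factor, pseudo_F=float(f_obs), R2=float(np.clip(r2, 0, 1)),
        p=p, n_perm=n_perm_used,
    )


def pairwise_permanova(
    d: DistanceMatrix, labels, n_perm: int = 1000, seed: int | None = None,
    factor: str = "group",
) -> list[PermanovaResult]:
    """PERMANOVA for every unordered group pair on the corresponding
    sub-matrix, Benjamini-Hochberg adjusted across the pairs."""
    labels = pd.Series(list(labels), index=d.samples)
    levels = sorted(labels.unique())
    seeds = np.random.SeedSequence(seed).spawn(len(list(itertools.combinations(levels, 2))))
    results: list[PermanovaResult] = []
    for (a, b), ss in zip(itertools.combinations(levels, 2), seeds):
        keep = labels.index[labels.isin([a, b])].tolist()
        sub = d.subset(keep)
        res = permanova(
            sub, labels.loc[keep], n_perm=n_perm,
            seed=int(ss.generate_state(1)[0] % (2**31)), factor=factor,
        )
        res.comparison = f"{a}_vs_{b}"
        results.append(res)
    qs = multipletests([r.p for r in results], method="fdr_bh")[1]
    for r, q in zip(results, qs):
        r.q = float(q)
    return results


# ---------------------------------------------------------------------------
# Guide-layer selection


@dataclass
class GuideLayerReport:
    """Outcome of guide-layer selection across omics layers.

    ``results`` holds one row per (layer, factor) PERMANOVA; ``eligible``
    lists layers with a significant group effect and no significant
    confounder association, ranked by group R^2 descending; ``winner`` is
    the top eligible layer or None.
    """

    results: pd.DataFrame
    eligible: list[str] = field(default_factory=list)
    winner: str | None = None
    alpha: float = 0.05

    @property
    def no_winner(self) -> bool:
        return self.winner is None


def _factor_labels(meta: CohortMetadata, factor: str, samples: list[str]) -> pd.Series:
    """Grouping labels for a metadata factor, dropping missing values.

    Continuous age is dichotomized at the cohort median so the one-factor
    permutation machinery applies uniformly.
    """
    col = meta.frame.loc[samples, factor] if factor != "group" else meta.group_of(samples)
    col = col.dropna()
    if factor == "age":
        med = col.median()
        col = col.map(lambda a: "age<=median" if a <= med else "age>median")
    elif factor == "constipation":
        col = col.map(lambda v: "constipated" if bool(v) else "regular")
    return col.astype(str)


def select_guide_layer(
    layers: dict[str, OmicsTable],
    meta: CohortMetadata,
    confounders: list[str] = ("sex", "age", "constipation"),
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
) -> GuideLayerReport:
    """Rank omics layers as candidate guides for differential analysis.

    A layer is eligible when its diagnosis-group PERMANOVA p < alpha and
    every confounder PERMANOVA p >= alpha; eligible layers are ranked by
    group R^2 and the best is flagged as winner. An empty eligible set
    yields a report with ``winner=None`` rather than an exception.
    """
    confounders = list(confounders)
    rows = []
    layer_names = sorted(layers)
    seeds = dict(zip(layer_names, np.random.SeedSequence(seed).spawn(len(layer_names))))
    for name in layer_names:
        t = layers[name]
        meta.require_samples(t.samples)
        norm = t if t.normalized else sum_normalize(t)
        d = bray_curtis(norm)
        factor_seeds = seeds[name].spawn(1 + len(confounders))
        for factor, fs in zip(["group"] + confounders, factor_seeds):
            lab = _factor_labels(meta, factor, norm.samples)
            sub = d.subset(list(lab.index)) if len(lab) < len(norm.samples) else d
            res = permanova(
                sub, lab, n_perm=n_perm,
                seed=int(fs.generate_state(1)[0] % (2**31)), factor=factor,
            )
            rows.append(
                {
                    "layer": name, "factor": factor, "pseudo_F": res.pseudo_F,
                    "R2": res.R2, "p": res.p, "n_perm": res.n_perm,
                }
            )
    results = pd.DataFrame(rows)
    eligible = []
    for name in layer_names:
        sub = results[results["layer"] == name].set_index("factor")
        ok_group = sub.loc["group", "p"] < alpha
        ok_conf = all(sub.loc[c, "p"] >= alpha for c in confounders)
        if ok_group and ok_conf:
            eligible.append((sub.loc["group", "R2"], name))
    eligible.sort(reverse=True)
    ranked = [name for _, name in eligible]
    return GuideLayerReport(
        results=results, eligible=ranked, winner=ranked[0] if ranked else None, alpha=alpha,
    )
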