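"""Shared domain types and tabular I/O.

Feature tables are plain TSV: header row of sample identifiers, first
column feature identifiers, numeric body (tab-separated, UTF-8, ``.``
decimal, no quoting). Reaction universes are JSON. Everything is kept in
pandas containers so downstream statistics can consume them directly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: The seven omics layers handled by the pipeline.  taxMG/taxMT/taxMP are
#: taxonomic profiles from metagenome, metatranscriptome and metaproteome;
#: funMG/funMT/funMP their functional (KEGG-ortholog level) counterparts;
#: MM is the meta-metabolome.
LAYERS = ("taxMG", "taxMT", "taxMP", "funMG", "funMT", "funMP", "MM")

GROUPS = ("HC", "iRBD", "PD")

_NORM_TOL = 1e-9


class ValidationError(ValueError):
    """An input violated a contract of one of the domain types."""


@dataclass
class OmicsTable:
    """One feature x sample abundance matrix tagged with its layer identity.

    Parameters
    ----------
    layer:
        One of :data:`LAYERS`.
    data:
        DataFrame with features as rows and samples as columns; all values
        nonnegative.
    normalized:
        True once every sample column has been divided by its sum.
    feature_annotations:
        Optional per-feature annotation frame indexed like ``data`` (used
        for the MM layer to carry block-of-origin and identification
        status).
    """

    layer: str
    data: pd.DataFrame
    normalized: bool = False
    feature_annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- contracts ---------------------------------------------------------

    def validate(self) -> None:
        if self.layer not in LAYERS:
            raise ValidationError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if not isinstance(self.data, pd.DataFrame):
            raise ValidationError("data must be a pandas DataFrame")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("non-numeric values in table body")
        if np.isnan(values).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise ValidationError(
                f"missing value at feature {self.data.index[r]!r}, sample {self.data.columns[c]!r}"
            )
        neg = values < 0
        if neg.any():
            r, c = np.argwhere(neg)[0]
            raise ValidationError(
                f"negative value {values[r, c]} at feature {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}"
            )
        if self.normalized:
            sums = values.sum(axis=0)
            bad = np.abs(sums - 1.0) > _NORM_TOL
            if bad.any():
                s = self.data.columns[np.argmax(bad)]
                raise ValidationError(f"normalized table but column {s!r} sums to {sums[np.argmax(bad)]}")
        if self.feature_annotations is not None:
            if not self.feature_annotations.index.equals(self.data.index):
                raise ValidationError("feature_annotations index must match feature ids")

    # -- convenience -------------------------------------------------------

    @property
    def features(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "feature"
        # %.17g keeps write -> read round trips bit-exact for doubles
        out.to_csv(path, sep="\t", float_format="%.17g")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"OmicsTable(layer={self.layer!r}, {self.data.shape[0]} features x "
            f"{self.data.shape[1]} samples, normalized={self.normalized})"
        )


def load_omics_table(path: str | Path, layer: str) -> OmicsTable:
    """Read a feature x sample TSV into a raw (unnormalized) OmicsTable.

    The first header cell is ignored; row and column order are preserved.
    Negative, missing, duplicate or non-numeric content is rejected with
    the offending cell named.
    """
    # round_trip parsing keeps write -> read exact to the bit
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    bad = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if bad:
        col = bad[0]
        cell = df[col][~df[col].astype(str).str.fullmatch(r"[-+0-9.eE]*")].head(1)
        where = f"feature {cell.index[0]!r}" if len(cell) else "unknown row"
        raise ValidationError(f"non-numeric cell in {path}, column {col!r}, {where}")
    return OmicsTable(layer=layer, data=df.astype(float), normalized=False)


def sum_normalize(t: OmicsTable) -> OmicsTable:
    """Divide every sample column by its sum (total-sum scaling).

    Idempotent; errors on all-zero sample columns, which have no defined
    relative composition.
    """
    sums = t.data.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValidationError(f"all-zero sample column(s): {list(zero.index)}")
    data = t.data.div(sums, axis=1)
    return replace(t, data=data, normalized=True)


def merge_mm_blocks(
    untargeted: OmicsTable, scfa: OmicsTable, bile_acids: OmicsTable
) -> OmicsTable:
    """Concatenate the three meta-metabolome blocks after per-block sum
    normalization.

    Each block (untargeted GC-MS, targeted short-chain fatty acids,
    targeted bile acids) is normalized independently before stacking, so
    merged sample columns sum to 3, not 1. Block of origin is recorded in
    ``feature_annotations``.
    """
    blocks = {"untargeted": untargeted, "scfa": scfa, "bile_acids": bile_acids}
    sample_sets = {name: set(b.samples) for name, b in blocks.items()}
    union = set.union(*sample_sets.values())
    inter = set.intersection(*sample_sets.values())
    if union != inter:
        missing = {name: sorted(union - s) for name, s in sample_sets.items() if union - s}
        raise ValidationError(f"sample-set mismatch between MM blocks: {missing}")
    order = untargeted.samples

    frames = []
    ann = []
    for name, block in blocks.items():
        norm = block if block.normalized else sum_normalize(block)
        frames.append(norm.data[order])
        base = (
            norm.feature_annotations.copy()
            if norm.feature_annotations is not None
            else pd.DataFrame(index=norm.data.index)
        )
        base["block"] = name
        ann.append(base)
    merged = pd.concat(frames, axis=0)
    if merged.index.has_duplicates:
        dups = merged.index[merged.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate feature ids across MM blocks: {dups}")
    annotations = pd.concat(ann, axis=0)
    out = OmicsTable(layer="MM", data=merged, normalized=False)
    out.feature_annotations = annotations
    return out


# ---------------------------------------------------------------------------
# Cohort metadata


@dataclass
class CohortMetadata:
    """Per-sample clinical metadata: diagnosis group plus confounders.

    ``frame`` is indexed by sample id with columns ``group`` (HC/iRBD/PD),
    ``sex`` (M/F), ``age`` (years), ``constipation`` (boolean) and
    ``cohort`` (free recruitment-site label). Group is never allowed to be
    missing; confounders may be, and analyses drop missing rows per
    factor.
    """

    frame: pd.DataFrame

    REQUIRED = ("group", "sex", "age", "constipation", "cohort")

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            raise ValidationError("duplicate sample ids in metadata")
        missing_cols = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing_cols:
            raise ValidationError(f"metadata missing columns: {missing_cols}")
        if self.frame["group"].isna().any():
            bad = self.frame.index[self.frame["group"].isna()].tolist()
            raise ValidationError(f"group missing for samples: {bad}")
        bad_groups = set(self.frame["group"]) - set(GROUPS)
        if bad_groups:
            raise ValidationError(f"group labels outside {GROUPS}: {sorted(bad_groups)}")

    @property
    def samples(self) -> list[str]:
        return list(self.frame.index)

    def group_of(self, samples: Sequence[str]) -> pd.Series:
        return self.frame.loc[list(samples), "group"]

    def require_samples(self, samples: Iterable[str]) -> None:
        missing = sorted(set(samples) - set(self.frame.index))
        if missing:
            raise ValidationError(f"samples without metadata: {missing}")

    def to_tsv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out.index.name = "sample"
        out.to_csv(path, sep="\t")


def load_metadata(path: str | Path) -> CohortMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if "constipation" in df.columns:
        df["constipation"] = df["constipation"].map(
            {True: True, False: False, "True": True, "False": False, 1: True, 0: False}
        )
    return CohortMetadata(df)


# ---------------------------------------------------------------------------
# Reaction universe


@dataclass(frozen=True)
class ReactionUniverse:
    """KO -> reaction -> compound mapping plus a ubiquitous-compound list.

    ``ko_reactions`` maps a KEGG-ortholog-style gene family id to its
    reaction ids; ``reaction_sides`` maps a reaction to its (reactants,
    products); ``compound_names`` gives each compound at least one
    human-readable name (the substrate of regex retrieval); ``cofactors``
    lists compounds treated as ubiquitous (water, energy carriers, ...)
    and excluded from network construction.
    """

    ko_reactions: Mapping[str, frozenset[str]]
    reaction_sides: Mapping[str, tuple[frozenset[str], frozenset[str]]]
    compound_names: Mapping[str, tuple[str, ...]]
    cofactors: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for ko, rxns in self.ko_reactions.items():
            if not rxns:
                raise ValidationError(f"KO {ko!r} maps to no reaction")
            unknown = set(rxns) - set(self.reaction_sides)
            if unknown:
                raise ValidationError(f"KO {ko!r} references unknown reactions {sorted(unknown)}")
        for rxn, (lhs, rhs) in self.reaction_sides.items():
            if not lhs and not rhs:
                raise ValidationError(f"reaction {rxn!r} has empty reactant and product sets")
            for cid in set(lhs) | set(rhs):
                if not self.compound_names.get(cid):
                    raise ValidationError(f"reaction {rxn!r} references unnamed compound {cid!r}")
        stray = self.cofactors - set(self.compound_names)
        if stray:
            warnings.warn(
                f"cofactor ids absent from compound space: {sorted(stray)}", stacklevel=2
            )

    @property
    def kos(self) -> list[str]:
        return sorted(self.ko_reactions)

    @property
    def compounds(self) -> list[str]:
        return sorted(self.compound_names)

    def reaction_compounds(self, rxn: str) -> frozenset[str]:
        lhs, rhs = self.reaction_sides[rxn]
        return lhs | rhs

    def ko_compounds(self, ko: str) -> frozenset[str]:
        out: set[str] = set()
        for rxn in self.ko_reactions[ko]:
            out |= self.reaction_compounds(rxn)
        return frozenset(out)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "ko_reactions": {k: sorted(v) for k, v in sorted(self.ko_reactions.items())},
            "reaction_sides": {
                r: {"reactants": sorted(lhs), "products": sorted(rhs)}
                for r, (lhs, rhs) in sorted(self.reaction_sides.items())
            },
            "compound_names": {c: sorted(n) for c, n in sorted(self.compound_names.items())},
            "cofactors": sorted(self.cofactors),
        }
        text = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def load_reaction_universe(path: str | Path) -> ReactionUniverse:
    doc = json.loads(Path(path).read_text())
    return ReactionUniverse(
        ko_reactions={k: frozenset(v) for k, v in doc["ko_reactions"].items()},
        reaction_sides={
            r: (frozenset(s["reactants"]), frozenset(s["products"]))
            for r, s in doc["reaction_sides"].items()
        },
        compound_names={c: tuple(sorted(n)) for c, n in doc["compound_names"].items()},
        cofactors=frozenset(doc.get("cofactors", [])),
    )


# ---------------------------------------------------------------------------
# Genus x KO x sample expression tensor


@dataclass
class TaxonFunctionTensor:
    """Genus-resolved functional expression: genus x KO x sample array.

    ``units`` distinguishes raw counts from transcripts-per-million;
    summing over genera reproduces (up to normalization) the funMT table
    restricted to the same KOs.
    """

    genera: list[str]
    kos: list[str]
    samples: list[str]
    values: np.ndarray
    units: str = "counts"
    genus_family: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.genera), len(self.kos), len(self.samples))
        if self.values.shape != expected:
            raise ValidationError(f"tensor shape {self.values.shape} != {expected}")
        if (self.values < 0).any():
            raise ValidationError("negative entries in expression tensor")
        for name, ids in (("genera", self.genera), ("kos", self.kos), ("samples", self.samples)):
            if len(set(ids)) != len(ids):
                raise ValidationError(f"duplicate {name} identifiers")

    def collapse_genera(self) -> pd.DataFrame:
        """Sum over genera -> KO x sample table."""
        return pd.DataFrame(self.values.sum(axis=0), index=self.kos, columns=self.samples)

    def ko_slice(self, ko: str) -> pd.DataFrame:
        """Genus x sample matrix for one KO."""
        i = self.kos.index(ko)
        return pd.DataFrame(self.values[:, i, :], index=self.genera, columns=self.samples)

    def to_long_tsv(self, path: str | Path) -> None:
        g, k, s = np.meshgrid(
            np.arange(len(self.genera)), np.arange(len(self.kos)), np.arange(len(self.samples)),
            indexing="ij",
        )
        df = pd.DataFrame(
            {
                "genus": np.asarray(self.genera)[g.ravel()],
                "ko": np.asarray(self.kos)[k.ravel()],
                "sample": np.asarray(self.samples)[s.ravel()],
                "value": self.values.ravel(),
            }
        )
        df.to_csv(path, sep="\t", index=False)


def load_tensor_long_tsv(path: str | Path, units: str = "counts") -> TaxonFunctionTensor:
    df = pd.read_csv(path, sep="\t", dtype={"genus": str, "ko": str, "sample": str})
    genera = list(dict.fromkeys(df["genus"]))
    kos = list(dict.fromkeys(df["ko"]))
    samples = list(dict.fromkeys(df["sample"]))
    arr = np.zeros((len(genera), len(kos), len(samples)))
    gi = {g: i for i, g in enumerate(genera)}
    ki = {k: i for i, k in enumerate(kos)}
    si = {s: i for i, s in enumerate(samples)}
    arr[
        df["genus"].map(gi).to_numpy(),
        df["ko"].map(ki).to_numpy(),
        df["sample"].map(si).to_numpy(),
    ] = df["value"].to_numpy()
    return TaxonFunctionTensor(genera, kos, samples, arr, units=units)


# ---------------------------------------------------------------------------
# Differential-result tables

DIFF_COLUMNS = [
    "feature",
    "comparison",
    "test",
    "statistic",
    "p",
    "q",
    "direction",
    "effect",
    "flag",
]


def make_difftable(rows: list[dict]) -> pd.DataFrame:
    """Assemble a long-format differential-result table with the standard
    column set (statistic, raw p, BH q, direction, effect size, flag)."""
    df = pd.DataFrame(rows)
    for col in DIFF_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    extra = [c for c in df.columns if c not in DIFF_COLUMNS]
    return df[DIFF_COLUMNS + extra]


def validate_difftable(df: pd.DataFrame, source_features: Iterable[str] | None = None) -> None:
    for col in ("feature", "comparison", "test", "p", "q"):
        if col not in df.columns:
            raise ValidationError(f"differential table missing column {col!r}")
    p = df["p"].dropna()
    q = df["q"].dropna()
    if ((p < 0) | (p > 1)).any() or ((q < 0) | (q > 1)).any():
        raise ValidationError("p/q outside [0, 1]")
    both = df.dropna(subset=["p", "q"])
    if (both["q"] < both["p"] - 1e-12).any():
        raise ValidationError("q < p: adjustment family violated")
    if source_features is not None:
        missing = sorted(set(df["feature"]) - set(source_features))
        if missing:
            raise ValidationError(f"differential rows for unknown features: {missing}")
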