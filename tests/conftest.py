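import warnings

import numpy as np
import pandas as pd
import pytest

from guideomics import synthetic
from guideomics.tables import CohortMetadata, OmicsTable, ReactionUniverse

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_universe():
    """KO1: A -> B, KO2: B -> C, KO3: D -> E; no cofactors."""
    return ReactionUniverse(
        ko_reactions={"KO1": frozenset({"R1"}), "KO2": frozenset({"R2"}),
                      "KO3": frozenset({"R3"})},
        reaction_sides={
            "R1": (frozenset({"A"}), frozenset({"B"})),
            "R2": (frozenset({"B"}), frozenset({"C"})),
            "R3": (frozenset({"D"}), frozenset({"E"})),
        },
        compound_names={c: (f"name-{c}",) for c in "ABCDE"},
    )


@pytest.fixture
def small_meta():
    """Balanced 4+4+4 cohort, handcrafted."""
    rows = []
    for g in ("HC", "iRBD", "PD"):
        for i in range(4):
            rows.append(dict(sample=f"{g}{i}", group=g, sex="M" if i % 2 else "F",
                             age=60.0 + i, constipation=bool(i == 3), cohort="siteA"))
    return CohortMetadata(pd.DataFrame(rows).set_index("sample"))


@pytest.fixture
def mktable():
    def _make(values, meta, layer="MM", features=None):
        values = np.asarray(values, dtype=float)
        features = features or [f"f{i}" for i in range(values.shape[0])]
        return OmicsTable(layer, pd.DataFrame(values, index=features, columns=meta.samples))

    return _make


@pytest.fixture(scope="session")
def paper_like_small():
    """Reduced paper-like study shared by the heavier tests."""
    return synthetic.generate_study(
        "paper-like", seed=11, n_ko=200, n_compound=70, n_cofactor=8,
        n_hc=22, n_irbd=14, n_pd=22, n_taxa=80, n_mm_untargeted=80,
        n_unidentified=12, n_genera=25, n_tensor_kos=90,
    )


@pytest.fixture(scope="session")
def null_small():
    return synthetic.generate_study(
        "null", seed=13, n_ko=150, n_compound=70, n_cofactor=8,
        n_hc=15, n_irbd=12, n_pd=15, n_taxa=60, n_mm_untargeted=60,
        n_unidentified=10, n_genera=20, n_tensor_kos=80,
    )
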