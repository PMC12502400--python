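import numpy as np
import pandas as pd
import pytest

from guideomics.functional import (
    differential_ko,
    ko_taxon_shannon,
    metabolite_feature_correlation,
    pathway_panel,
)
from guideomics.tables import (
    OmicsTable,
    TaxonFunctionTensor,
    ValidationError,
    sum_normalize,
)


def norm_table(values, meta, layer, features=None):
    features = features or [f"K{i}" for i in range(len(values))]
    t = OmicsTable(layer, pd.DataFrame(np.asarray(values, float),
                                       index=features, columns=meta.samples))
    return sum_normalize(t)


class TestDifferentialKo:
    def test_null_ko_q_near_one(self, small_meta, rng):
        vals = rng.gamma(5, 1, size=(10, 12))
        mg = norm_table(vals, small_meta, "funMG")
        mt = norm_table(vals + rng.normal(0, 0.01, vals.shape).clip(-0.5), small_meta, "funMT")
        df = differential_ko(mg, mt, small_meta, [f"K{i}" for i in range(10)], ("HC", "PD"))
        assert df["q"].dropna().min() > 0.2

    def test_requires_normalized_tables(self, small_meta, rng):
        raw = OmicsTable("funMG", pd.DataFrame(
            rng.gamma(5, 1, size=(3, 12)), index=["K0", "K1", "K2"],
            columns=small_meta.samples))
        with pytest.raises(ValidationError, match="sum-normalized"):
            differential_ko(raw, sum_normalize(raw), small_meta, ["K0"], ("HC", "PD"))

    def test_missing_ko_flagged(self, small_meta, rng):
        vals = rng.gamma(5, 1, size=(3, 12))
        mg = norm_table(vals, small_meta, "funMG")
        mt = norm_table(vals, small_meta, "funMT")
        df = differential_ko(mg, mt, small_meta, ["K0", "K999"], ("HC", "PD"))
        ghost = df[df["feature"] == "K999"]
        assert (ghost["flag"] == "missing-from-layer").all()
        assert ghost["p"].isna().all()

    def test_transcript_only_shift_detected_in_mt_only(self, rng):
        from guideomics.synthetic import make_cohort

        meta = make_cohort(n_hc=12, n_irbd=8, n_pd=12, seed=6)
        base = rng.gamma(20, 1, size=(20, 32)) + 5
        shifted = base.copy()
        pd_cols = (meta.frame["group"] == "PD").to_numpy()
        shifted[0, pd_cols] *= 0.05  # strong PD decrease on K0, transcripts only
        mg = norm_table(base, meta, "funMG")
        mt = norm_table(shifted, meta, "funMT")
        df = differential_ko(mg, mt, meta, [f"K{i}" for i in range(20)], ("HC", "PD"))
        k0 = df[df["feature"] == "K0"].set_index("layer")
        assert k0.loc["funMT", "q"] < 0.05 and k0.loc["funMT", "direction"] > 0
        assert k0.loc["funMG", "q"] > 0.2
        assert k0.loc["funMT", "effect"] > 1.0  # HC over PD fold

    def test_dissociation_specificity_on_identical_generators(self, null_small):
        """When funMG and funMT are generated identically (null study),
        almost no KO should be significant in exactly one layer."""
        s = null_small
        mg = sum_normalize(s.tables["funMG"])
        mt = sum_normalize(s.tables["funMT"])
        kos = s.tables["funMG"].features[:80]
        df = differential_ko(mg, mt, s.meta, kos, ("HC", "PD"))
        piv = df.pivot(index="feature", columns="layer", values="q")
        one_layer = ((piv < 0.05).sum(axis=1) == 1).mean()
        assert one_layer <= 0.1


class TestKoTaxonShannon:
    def _tensor(self, values):
        values = np.asarray(values, float)
        g, k, s = values.shape
        return TaxonFunctionTensor(
            [f"g{i}" for i in range(g)], [f"K{i}" for i in range(k)],
            [f"s{i}" for i in range(s)], values,
        )

    def test_single_genus_zero(self):
        vals = np.zeros((3, 1, 2))
        vals[1, 0, :] = 5.0
        h = ko_taxon_shannon(self._tensor(vals), "K0")
        assert (h == 0.0).all()

    def test_four_genera_uniform_ln4(self):
        vals = np.ones((4, 1, 3))
        h = ko_taxon_shannon(self._tensor(vals), "K0")
        assert np.allclose(h, np.log(4))

    def test_zero_expression_sample_is_missing(self):
        vals = np.ones((2, 1, 2))
        vals[:, 0, 1] = 0.0
        h = ko_taxon_shannon(self._tensor(vals), "K0")
        assert h["s0"] == pytest.approx(np.log(2)) and np.isnan(h["s1"])

    def test_zero_iff_single_expressing_genus(self, rng):
        vals = rng.poisson(3, size=(5, 1, 6)).astype(float)
        h = ko_taxon_shannon(self._tensor(vals), "K0")
        for j, s in enumerate([f"s{i}" for i in range(6)]):
            pos = (vals[:, 0, j] > 0).sum()
            if pos == 1:
                assert h[s] == 0.0
            elif pos > 1 and len(set(vals[vals[:, 0, j] > 0, 0, j])) > 0:
                assert h[s] > 0 or pos == 1


class TestCorrelation:
    def _tables(self, x, y, layer_other="taxMT"):
        samples = [f"s{i}" for i in range(len(x))]
        mm = OmicsTable("MM", pd.DataFrame([x], index=["m"], columns=samples))
        other = OmicsTable(layer_other, pd.DataFrame([y], index=["t"], columns=samples))
        return mm, other

    def test_monotone_identity(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        df = metabolite_feature_correlation(*self._tables(x, x))
        assert df.iloc[0]["effect"] == pytest.approx(1.0)

    def test_antitone(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        df = metabolite_feature_correlation(*self._tables(x, x[::-1]))
        assert df.iloc[0]["effect"] == pytest.approx(-1.0)

    def test_closed_form_n5(self, rng):
        x = rng.permutation(5).astype(float) + 1
        y = rng.permutation(5).astype(float) + 1
        from scipy.stats import rankdata

        d = rankdata(x) - rankdata(y)
        rho_hand = 1 - 6 * (d**2).sum() / (5 * (25 - 1))
        df = metabolite_feature_correlation(*self._tables(x, y))
        assert df.iloc[0]["effect"] == pytest.approx(rho_hand, rel=1e-12)

    def test_constant_vector_flagged(self):
        df = metabolite_feature_correlation(
            *self._tables([1.0, 2.0, 3.0, 4.0, 5.0], [2.0] * 5)
        )
        assert df.iloc[0]["flag"] == "constant-vector"
        assert np.isnan(df.iloc[0]["effect"])

    def test_sign_flips_under_negation_of_ranks(self, rng):
        x = rng.gamma(2, 1, 8)
        y = rng.gamma(2, 1, 8)
        a = metabolite_feature_correlation(*self._tables(x, y))
        b = metabolite_feature_correlation(*self._tables(x, y.max() + 1 - y))
        assert a.iloc[0]["effect"] == pytest.approx(-b.iloc[0]["effect"], rel=1e-10)

    def test_q_adjusted_across_all_pairs(self, small_meta, rng):
        mm = OmicsTable("MM", pd.DataFrame(rng.gamma(2, 1, (4, 12)),
                                           index=list("abcd"), columns=small_meta.samples))
        other = OmicsTable("taxMT", pd.DataFrame(rng.gamma(2, 1, (6, 12)),
                                                 index=[f"t{i}" for i in range(6)],
                                                 columns=small_meta.samples))
        df = metabolite_feature_correlation(mm, other)
        assert len(df) == 24
        ok = df.dropna(subset=["p", "q"])
        assert (ok["q"] >= ok["p"] - 1e-12).all()


class TestPathwayPanel:
    def test_empty_pathway_rejected(self, small_meta, rng):
        vals = rng.gamma(5, 1, size=(3, 12))
        mg = norm_table(vals, small_meta, "funMG")
        mt = norm_table(vals, small_meta, "funMT")
        with pytest.raises(ValidationError, match="empty"):
            pathway_panel(mg, mt, small_meta, [], ("HC", "PD"))

    def test_pathway_absent_rows_flagged(self, small_meta, rng):
        vals = rng.gamma(5, 1, size=(3, 12))
        mg = norm_table(vals, small_meta, "funMG")
        mt = norm_table(vals, small_meta, "funMT")
        panel = pathway_panel(mg, mt, small_meta, ["K77", "K88"], ("HC", "PD"))
        assert (panel.table["flag"] == "missing-from-layer").all()

    def test_tally_partitions_pathway(self, paper_like_small):
        from guideomics.tables import sum_normalize as sn

        s = paper_like_small
        mg, mt = sn(s.tables["funMG"]), sn(s.tables["funMT"])
        kos = s.truth.pathways["chemotaxis"]
        panel = pathway_panel(mg, mt, s.meta, kos, ("HC", "PD"), tensor=s.tensor,
                              pathway="chemotaxis")
        t = panel.tally
        assert t["down"] + t["up"] + t["unchanged"] == t["size"] == len(kos)

    def test_suppressed_pathway_tallied_down(self, paper_like_small):
        from guideomics.tables import sum_normalize as sn

        s = paper_like_small
        mg, mt = sn(s.tables["funMG"]), sn(s.tables["funMT"])
        planted_down = set(s.truth.pathway_down["flagellar_assembly"])
        panel = pathway_panel(mg, mt, s.meta, s.truth.pathways["flagellar_assembly"],
                              ("HC", "PD"), pathway="flagellar_assembly")
        mt_rows = panel.table[(panel.table["layer"] == "funMT")
                              & panel.table["feature"].isin(planted_down)]
        down_frac = ((mt_rows["q"] < 0.05) & (mt_rows["direction"] > 0)).mean()
        assert down_frac >= 0.8
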