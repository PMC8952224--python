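import numpy as np
import pandas as pd
import pytest

from cerna_switch.diffexpr import (
    TierThresholds,
    association,
    class_direction_association,
    classify,
    size_factors,
    test_de as run_de,
)
from cerna_switch.io_formats import ExpressionMatrix


def _matrix(values, conditions=("control", "control", "treated", "treated"),
            classes="mRNA", unit="counts"):
    df = pd.DataFrame(
        values, index=[f"g{i}" for i in range(len(values))],
        columns=[f"s{i}" for i in range(len(values[0]))],
    )
    cond = pd.Series(dict(zip(df.columns, conditions)))
    cls = pd.Series(classes, index=df.index)
    return ExpressionMatrix(df, cond, cls, unit=unit)


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        m = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5]})
        assert np.allclose(size_factors(m), 1.0)

    def test_doubled_sample_has_double_factor(self):
        m = pd.DataFrame({"a": [10, 20, 5], "b": [20, 40, 10]})
        f = size_factors(m)
        assert f["b"] == pytest.approx(2 * f["a"])

    def test_matches_hand_computed_median_of_ratios(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.integers(1, 200, size=(5, 3)), columns=list("abc"))
        # oracle: direct geometric means and medians
        vals = m.to_numpy(float)
        geo = np.exp(np.log(vals).mean(axis=1))
        expected = np.median(vals / geo[:, None], axis=0)
        assert np.allclose(size_factors(m), expected)

    def test_no_all_positive_gene_rejected(self):
        m = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
        with pytest.raises(ValueError, match="positive"):
            size_factors(m)


class TestWaldTest:
    def test_flat_gene_is_null(self):
        # both genes flat across samples: unit size factors, identical
        # normalized group means
        m = _matrix([[10, 10, 10, 10], [50, 50, 50, 50]])
        de = run_de(m, "control", "treated")
        assert de.loc["g0", "log2fc"] == pytest.approx(0.0)
        assert de.loc["g0", "p_value"] == pytest.approx(1.0)

    def test_requires_two_replicates(self):
        m = _matrix([[10, 10, 10]], conditions=("control", "treated", "treated"))
        with pytest.raises(ValueError, match="replicates"):
            run_de(m, "control", "treated")

    def test_scale_invariance_of_log2fc(self):
        rng = np.random.default_rng(8)
        vals = rng.integers(5, 500, size=(40, 6))
        cond = ("control",) * 3 + ("treated",) * 3
        m1 = _matrix(vals.tolist(), conditions=cond)
        scaled = vals.copy().astype(float)
        scaled[:, 0] *= 3
        m2 = _matrix(scaled.tolist(), conditions=cond)
        f1, f2 = size_factors(m1.values), size_factors(m2.values)
        # the scaled sample's factor grows 3x relative to every other
        # sample (the absolute factors carry the geometric-mean shift of
        # the per-gene reference, as in median-of-ratios normalization)
        assert f2["s0"] / f2["s1"] == pytest.approx(3 * f1["s0"] / f1["s1"])
        de1 = run_de(m1, "control", "treated")
        de2 = run_de(m2, "control", "treated")
        # log2FC estimates are unchanged up to the pseudocount's response
        # to the global rescaling of normalized counts
        assert np.allclose(de1["log2fc"], de2["log2fc"], atol=0.05)

    def test_power_at_large_planted_effect(self):
        # planted log2FC = 4 against moderate NB noise, 3 vs 3: nearly all
        # planted genes must clear the stringent tier
        rng = np.random.default_rng(12)
        n_null, n_de = 300, 60
        mu = rng.lognormal(5, 1, size=n_null + n_de)
        alpha = 0.1
        lfc = np.concatenate([np.zeros(n_null), np.full(n_de, 4.0)])
        mean = mu[:, None] * np.power(2.0, lfc[:, None] * np.array([0, 0, 0, 1, 1, 1]))
        r = 1 / alpha
        counts = rng.negative_binomial(r, r / (r + mean))
        cond = ("control",) * 3 + ("treated",) * 3
        cm = _matrix(counts.tolist(), conditions=cond)
        fpkm = ExpressionMatrix(
            cm.values.astype(float), cm.sample_condition, cm.gene_class, unit="FPKM"
        )
        cls = classify(
            run_de(cm, "control", "treated"), fpkm, "control", "treated"
        )
        planted = cls.iloc[n_null:]
        assert (planted["stringent"].mean()) >= 0.9

    def test_null_fdr_rate_controlled(self, null_stringent_fractions):
        # across 20 all-null simulated studies the BH-adjusted rejection
        # rate stays at the nominal level (plus Monte-Carlo error)
        frac = null_stringent_fractions["fdr05"]
        n = null_stringent_fractions["n"]
        mc = 2 * np.sqrt(0.05 * 0.95 / n)
        assert frac <= 0.05 + mc

    def test_bh_monotone_and_bounded(self, classified_de):
        de = classified_de.sort_values("p_value")
        assert (de["fdr"] >= de["p_value"] - 1e-12).all()
        # BH step-up: adjusted values are non-decreasing in p
        assert (np.diff(de["fdr"].to_numpy()) >= -1e-12).all()


class TestClassify:
    def _cls(self, log2fc, fdr, gene_class="mRNA", fpkm=10.0):
        de = pd.DataFrame(
            {
                "gene_class": [gene_class],
                "base_mean": [50.0],
                "log2fc": [log2fc],
                "dispersion": [0.1],
                "p_value": [fdr / 2],
                "fdr": [fdr],
            },
            index=pd.Index(["g0"], name="gene_id"),
        )
        f = pd.DataFrame(
            {"s0": [fpkm], "s1": [fpkm], "s2": [fpkm], "s3": [fpkm]},
            index=["g0"],
        )
        fm = ExpressionMatrix(
            f,
            pd.Series(
                {"s0": "control", "s1": "control", "s2": "treated", "s3": "treated"}
            ),
            pd.Series({"g0": gene_class}),
            unit="FPKM",
        )
        return classify(de, fm, "control", "treated").iloc[0]

    def test_screening_boundaries_inclusive(self):
        row = self._cls(log2fc=1.0, fdr=0.05)
        assert row["screening"] and not row["stringent"]
        assert row["fdr_at_screening_boundary"]

    def test_cerna_lnc_strict_boundary(self):
        assert self._cls(2.6, 0.005, "lncRNA")["cerna_lnc"]
        assert not self._cls(2.5, 0.005, "lncRNA")["cerna_lnc"]

    def test_fpkm_quantifiability_gates_stringent(self):
        row = self._cls(-3.0, 0.001, fpkm=0.5)
        assert not row["stringent"]
        assert row["direction"] == "down"  # still flagged via other tiers

    def test_missing_fpkm_gene_reported(self, classified_de, default_study):
        de = classified_de.copy()
        de.loc["ghost"] = de.iloc[0]
        with pytest.raises(ValueError, match="ghost"):
            classify(
                de, default_study.fpkm, "contractile", "stent"
            )

    def test_direction_partition(self, classified_de):
        flagged = classified_de[classified_de["screening"]]
        assert set(flagged["direction"]) <= {"up", "down"}
        up = (flagged["direction"] == "up").sum()
        down = (flagged["direction"] == "down").sum()
        assert up + down == len(flagged)


class TestAssociation:
    def test_equal_proportions_give_zero(self):
        t = pd.DataFrame({"down": [40, 80], "up": [10, 20]}, index=["a", "b"])
        assert class_direction_association(t).chi_square == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_2x2_matches_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = rng.integers(5, 500, 4)
        t = pd.DataFrame({"down": [a, c], "up": [b, d]}, index=["x", "y"])
        res = class_direction_association(t)
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d)
        )
        assert res.chi_square == pytest.approx(expected)
        assert res.dof == 1
        assert res.fisher_p is not None

    def test_tier_association_on_synthetic_study(self, classified_de):
        res = association(classified_de, "stringent")
        assert res.dof == (len(res.table) - 1) * 1
        assert (res.table["down"] + res.table["up"] == res.table["total"]).all()

    def test_empty_class_dropped_with_warning(self, classified_de):
        cls = classified_de.copy()
        cls.loc[cls["gene_class"] == "miRNA", "stringent"] = False
        with pytest.warns(UserWarning, match="miRNA"):
            res = association(cls, "stringent")
        assert "miRNA" not in res.table.index


class TestThresholdValidation:
    def test_negative_fdr_rejected(self):
        with pytest.raises(ValueError, match="screening_max_fdr"):
            TierThresholds(screening_max_fdr=-0.1).validate()
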