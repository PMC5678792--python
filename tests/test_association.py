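import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glutmet.association import (
    CondCoexprConfig,
    PROTEASOME_GENES,
    conditional_coexpression,
    correlate_change,
    merge_cohorts,
    pearson,
    ros_change,
)
from glutmet.errors import ValidationError

from conftest import make_matrix


class TestPearson:
    def test_perfect_positive_linearity(self):
        x = np.arange(10.0)
        res = pearson(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0, abs=1e-12)

    def test_perfect_negative(self):
        x = np.arange(8.0)
        assert pearson(x, -x).r == pytest.approx(-1.0, abs=1e-12)

    def test_closed_form_on_fixed_points(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 9.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 8.0])
        res = pearson(x, y)
        r_manual = (
            np.sum((x - x.mean()) * (y - y.mean()))
            / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        )
        assert res.r == pytest.approx(r_manual, abs=1e-12)
        from scipy import stats

        t = r_manual * np.sqrt((5 - 2) / (1 - r_manual**2))
        assert res.p_value == pytest.approx(2 * stats.t.sf(abs(t), 3), abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=(2, 25))
        assert pearson(x, y).r == pearson(y, x).r

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        a=st.floats(0.1, 10.0),
        b=st.floats(-5.0, 5.0),
    )
    def test_affine_invariance(self, seed, a, b):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=(2, 20))
        base = pearson(x, y).r
        assert pearson(a * x + b, y).r == pytest.approx(base, abs=1e-9)
        assert pearson(-a * x + b, y).r == pytest.approx(-base, abs=1e-9)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError):
            pearson(np.ones(5), np.arange(5.0))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            pearson(np.arange(2.0), np.arange(2.0))


class TestCorrelateChange:
    def test_merge_averages_named_cohorts(self):
        change = pd.Series(
            {"KICH": 1.0, "KIRC": 2.0, "KIRP": 3.0, "LUAD": 4.0, "BRCA": 5.0}
        )
        merged = merge_cohorts(change, {"KIDNEY": ["KICH", "KIRC", "KIRP"]})
        assert merged["KIDNEY"] == pytest.approx(2.0)
        assert set(merged.index) == {"KIDNEY", "LUAD", "BRCA"}

    def test_merge_missing_cohort_raises(self):
        with pytest.raises(ValidationError):
            merge_cohorts(pd.Series({"A": 1.0}), {"K": ["A", "B"]})

    def test_cohort_level_correlation(self):
        change = pd.Series({"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.5})
        external = pd.Series({"A": 0.9, "B": 0.7, "C": 0.5, "D": 0.2})
        res = correlate_change(change, external)
        assert res.r < -0.99
        assert res.n == 4

    def test_requires_three_shared_cohorts(self):
        with pytest.raises(ValidationError):
            correlate_change(pd.Series({"A": 1.0, "B": 2.0}),
                             pd.Series({"A": 1.0, "B": 2.0}))


class TestRosChange:
    def test_default_set_is_the_seven_proteasome_genes(self):
        assert PROTEASOME_GENES == {
            "PSMD1", "PSMD2", "PSMD11", "PSMD14", "PSME3", "PSME4", "PSMB5",
        }

    def test_null_fixture_change_near_zero_planted_shift_detected(self):
        rng = np.random.default_rng(8)
        genes = sorted(PROTEASOME_GENES)
        null_block = rng.normal(7, 1, (7, 60))
        groups = ["cancer"] * 30 + ["control"] * 30
        null = ros_change(make_matrix(null_block, groups, genes=genes))
        assert not null["significant"].any()

        shifted = null_block.copy()
        latent = rng.normal(0, 1, 60) + np.array([1.0] * 30 + [0.0] * 30)
        shifted = 0.3 * rng.normal(size=(7, 60)) + latent[None, :] + 7.0
        up = ros_change(make_matrix(shifted, groups, genes=genes))
        assert up["significant"].all()
        assert (up["change"] > 0).all()


class TestConditionalCoexpression:
    def test_full_band_equals_plain_correlations(self):
        rng = np.random.default_rng(12)
        genes = ["PPAT", "CAD", "PSMD1", "PSMD2"]
        block = rng.normal(7, 1, (4, 50))
        m = make_matrix(block, ["cancer"] * 25 + ["control"] * 25, genes=genes)
        config = CondCoexprConfig(band=(0.0, 1.0), target_genes=("PSMD1", "PSMD2"),
                                  p_threshold=1.0)
        out = conditional_coexpression(m, config)
        for i, anchor in enumerate(("PPAT", "CAD")):
            for j, target in enumerate(("PSMD1", "PSMD2")):
                plain = pearson(block[i], block[2 + j]).r
                assert out.loc[anchor, target] == pytest.approx(plain, abs=1e-12)

    def test_conditioning_attenuates_confounded_correlation(self):
        """Anchor-target correlation driven by a shared latent factor
        shrinks when samples are restricted to a narrow anchor band."""
        rng = np.random.default_rng(13)
        n = 600
        latent = rng.normal(0, 1, n)
        anchor1 = latent + 0.3 * rng.normal(size=n) + 7
        anchor2 = latent + 0.3 * rng.normal(size=n) + 7
        target = latent + 0.3 * rng.normal(size=n) + 7
        other = rng.normal(7, 1, n)
        block = np.vstack([anchor1, anchor2, target, other])
        m = make_matrix(block, ["cancer"] * (n // 2) + ["control"] * (n // 2),
                        genes=["PPAT", "CAD", "PSMD1", "G1"])
        full = conditional_coexpression(
            m, CondCoexprConfig(band=(0.0, 1.0), target_genes=("PSMD1",),
                                p_threshold=1.0)
        )
        banded = conditional_coexpression(
            m, CondCoexprConfig(band=(0.4, 0.6), target_genes=("PSMD1",),
                                p_threshold=1.0)
        )
        assert abs(banded.loc["PPAT", "PSMD1"]) < abs(full.loc["PPAT", "PSMD1"])

    def test_reported_cells_all_pass_significance(self):
        rng = np.random.default_rng(14)
        genes = ["PPAT", "CAD"] + sorted(PROTEASOME_GENES)
        block = rng.normal(7, 1, (len(genes), 80))
        m = make_matrix(block, ["cancer"] * 40 + ["control"] * 40, genes=genes)
        config = CondCoexprConfig(band=(0.1, 0.9))
        out = conditional_coexpression(m, config)
        composite_band = out.notna()
        # recompute every reported cell and confirm P <= 0.05
        from glutmet.pathway import score_process
        from glutmet.registry import ProcessGeneSet

        comp = score_process(
            m, ProcessGeneSet(id="a", name="a", genes=frozenset(("PPAT", "CAD")))
        ).scores
        lo, hi = comp.quantile([0.1, 0.9])
        keep = comp.index[(comp >= lo) & (comp <= hi)]
        for anchor in out.index:
            for target in out.columns:
                if composite_band.loc[anchor, target]:
                    res = pearson(m.values.loc[anchor, keep],
                                  m.values.loc[target, keep])
                    assert res.p_value <= 0.05

    def test_band_widening_monotonically_adds_samples(self):
        rng = np.random.default_rng(15)
        genes = ["PPAT", "CAD", "PSMD1"]
        m = make_matrix(rng.normal(7, 1, (3, 100)),
                        ["cancer"] * 50 + ["control"] * 50, genes=genes)
        from glutmet.pathway import score_process
        from glutmet.registry import ProcessGeneSet

        comp = score_process(
            m, ProcessGeneSet(id="a", name="a", genes=frozenset(("PPAT", "CAD")))
        ).scores
        counts = []
        for width in (0.1, 0.2, 0.3, 0.45):
            lo, hi = comp.quantile([0.5 - width, 0.5 + width])
            counts.append(int(((comp >= lo) & (comp <= hi)).sum()))
        assert counts == sorted(counts)

    def test_narrow_band_raises_helpful_error(self):
        rng = np.random.default_rng(16)
        genes = ["PPAT", "CAD", "PSMD1"]
        m = make_matrix(rng.normal(7, 1, (3, 20)),
                        ["cancer"] * 10 + ["control"] * 10, genes=genes)
        with pytest.raises(ValidationError, match="widen"):
            conditional_coexpression(m, CondCoexprConfig(band=(0.49, 0.51)))

    def test_missing_anchor_rejected(self):
        m = make_matrix(np.random.default_rng(17).normal(7, 1, (2, 12)),
                        ["cancer"] * 6 + ["control"] * 6, genes=["GA", "GB"])
        with pytest.raises(ValidationError, match="PPAT"):
            conditional_coexpression(m, CondCoexprConfig())

    def test_invalid_band_rejected(self):
        with pytest.raises(ValidationError):
            CondCoexprConfig(band=(0.7, 0.3))
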