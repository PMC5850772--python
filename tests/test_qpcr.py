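"""Relative quantification: standard curves, ratio model, error propagation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cladecall import (
    ConfigurationError,
    MissingDataError,
    build_matrix,
    fit_standard_curve,
    relative_expression,
)
from cladecall.errors import DegenerateDataError
from cladecall.signatures import DEFAULT_PANEL

from conftest import tiny_ct_table


def ratio_oracle(ct, clone, ancestor, gene, ref, eff):
    """Independent direct-ratio oracle: (1+E_ref)^dCt_ref / (1+E_g)^dCt_g,
    computed per biological replicate from technical means, then averaged
    on the log2 scale."""
    means = ct.groupby(["clone", "gene", "bio_rep"])["ct"].mean()
    ratios = []
    for b in sorted(ct.loc[ct["clone"] == clone, "bio_rep"].unique()):
        d_g = means[clone, gene, b] - means[ancestor, gene, b]
        d_r = means[clone, ref, b] - means[ancestor, ref, b]
        ratio = (1 + eff[ref]) ** d_r / (1 + eff[gene]) ** d_g
        ratios.append(math.log2(ratio))
    return float(np.mean(ratios))


class TestStandardCurve:
    def test_perfect_twofold_series_has_unit_efficiency(self):
        dil = [1.0, 0.5, 0.25, 0.125, 0.0625]
        ct = [20.0 + i for i in range(5)]  # +1 cycle per 2-fold dilution
        curve = fit_standard_curve(dil, ct, "HXT2")
        assert curve.valid
        assert curve.slope == pytest.approx(-1 / math.log10(2), abs=1e-9)
        assert curve.efficiency == pytest.approx(1.0, abs=1e-9)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_flat_cts_flag_invalid_curve(self):
        curve = fit_standard_curve([1.0, 0.1, 0.01], [20.0, 20.0, 20.0])
        assert not curve.valid
        assert "slope" in curve.message

    def test_noisy_series_matches_closed_form_ols(self):
        rng = np.random.default_rng(42)
        dil = np.array([1.0, 0.1, 0.01, 0.001, 0.0001])
        ct = 18.0 - 3.4 * np.log10(dil) + rng.normal(0, 0.2, 5)
        curve = fit_standard_curve(dil, ct)
        # closed-form least squares, written out independently
        x, y = np.log10(dil), ct
        sxx = ((x - x.mean()) ** 2).sum()
        slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
        intercept = y.mean() - slope * x.mean()
        assert curve.slope == pytest.approx(slope, abs=1e-9)
        assert curve.intercept == pytest.approx(intercept, abs=1e-9)

    def test_too_few_dilutions_rejected(self):
        with pytest.raises(DegenerateDataError):
            fit_standard_curve([1.0, 0.5, 0.5], [20, 21, 21.1])


def _simple_table(clone_gene, clone_ref, anc_gene, anc_ref):
    rows = []
    for b in (1, 2):
        rows += [("evo", "HXT3", b, 1, clone_gene), ("evo", "ACT1", b, 1, clone_ref)]
        rows += [("anc", "HXT3", b, 1, anc_gene), ("anc", "ACT1", b, 1, anc_ref)]
    return tiny_ct_table(rows)


class TestRelativeExpression:
    eff = {"HXT3": 1.0, "ACT1": 1.0}

    def test_identical_cts_give_zero_ratio(self):
        ct = _simple_table(22.0, 16.0, 22.0, 16.0)
        ratio, se = relative_expression(ct, "evo", "anc", "HXT3", "ACT1", self.eff)
        assert ratio == pytest.approx(0.0, abs=1e-12)
        assert se == 0.0

    def test_one_cycle_earlier_means_doubling(self):
        ct = _simple_table(21.0, 16.0, 22.0, 16.0)
        ratio, _ = relative_expression(ct, "evo", "anc", "HXT3", "ACT1", self.eff)
        assert ratio == pytest.approx(1.0, abs=1e-12)

    def test_matches_direct_ratio_oracle_with_efficiencies(self):
        eff = {"HXT3": 0.9, "ACT1": 1.0}
        rows = []
        vals = {  # (clone, gene, bio) -> list of tech Cts
            ("evo", "HXT3", 1): [20.1, 20.3, 20.2],
            ("evo", "HXT3", 2): [20.6, 20.4, 20.5],
            ("evo", "ACT1", 1): [15.9, 16.1, 16.0],
            ("evo", "ACT1", 2): [16.2, 16.1, 16.0],
            ("anc", "HXT3", 1): [22.0, 22.2, 22.1],
            ("anc", "HXT3", 2): [22.3, 22.2, 22.4],
            ("anc", "ACT1", 1): [16.0, 16.1, 15.9],
            ("anc", "ACT1", 2): [16.1, 16.0, 16.2],
        }
        for (clone, gene, b), cts in vals.items():
            rows += [(clone, gene, b, t + 1, c) for t, c in enumerate(cts)]
        ct = tiny_ct_table(rows)
        ratio, _ = relative_expression(ct, "evo", "anc", "HXT3", "ACT1", eff)
        assert ratio == pytest.approx(
            ratio_oracle(ct, "evo", "anc", "HXT3", "ACT1", eff), abs=1e-12
        )

    @given(
        d_gene=st.floats(-5, 5),
        d_ref=st.floats(-2, 2),
        e_gene=st.floats(0.5, 1.0),
        e_ref=st.floats(0.5, 1.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_antisymmetry_under_clone_ancestor_swap(
        self, d_gene, d_ref, e_gene, e_ref
    ):
        eff = {"HXT3": e_gene, "ACT1": e_ref}
        ct = _simple_table(22.0 + d_gene, 16.0 + d_ref, 22.0, 16.0)
        fwd, _ = relative_expression(ct, "evo", "anc", "HXT3", "ACT1", eff)
        rev, _ = relative_expression(ct, "anc", "evo", "HXT3", "ACT1", eff)
        assert fwd == pytest.approx(-rev, abs=1e-10)

    def test_higher_efficiency_amplifies_magnitude(self):
        ct = _simple_table(20.0, 16.0, 22.0, 16.0)  # dCt_gene = -2
        prev = 0.0
        for e in (0.6, 0.8, 1.0):
            ratio, _ = relative_expression(
                ct, "evo", "anc", "HXT3", "ACT1", {"HXT3": e, "ACT1": 1.0}
            )
            assert abs(ratio) > abs(prev)
            prev = ratio

    def test_bio_sem_and_quadrature_modes(self):
        rows = []
        for b, (g, r) in enumerate([(20.0, 16.0), (21.0, 16.0)], start=1):
            rows += [("evo", "HXT3", b, 1, g), ("evo", "ACT1", b, 1, r)]
            rows += [("anc", "HXT3", b, 1, 22.0), ("anc", "ACT1", b, 1, 16.0)]
        ct = tiny_ct_table(rows)
        ratio, se = relative_expression(ct, "evo", "anc", "HXT3", "ACT1", self.eff)
        # per-bio ratios are 2.0 and 1.0 -> mean 1.5, SEM = 0.5/sqrt(2)... sd=0.707
        assert ratio == pytest.approx(1.5)
        assert se == pytest.approx(np.std([2.0, 1.0], ddof=1) / math.sqrt(2))
        _, se_q = relative_expression(
            ct, "evo", "anc", "HXT3", "ACT1", self.eff, mode="quadrature"
        )
        assert se_q > 0

    def test_missing_measurement_names_clone_and_gene(self):
        ct = _simple_table(22.0, 16.0, 22.0, 16.0)
        with pytest.raises(MissingDataError, match="evo.*SUC2"):
            relative_expression(
                ct, "evo", "anc", "SUC2", "ACT1", {"SUC2": 1.0, "ACT1": 1.0}
            )

    def test_batch_column_pairs_clone_with_its_batch_ancestor(self):
        rows = []
        for batch, shift in (("b1", 0.0), ("b2", 3.0)):
            clone = f"evo_{batch}"
            for b in (1, 2):
                rows += [
                    (clone, "HXT3", b, 1, 21.0 + shift, batch),
                    (clone, "ACT1", b, 1, 16.0 + shift, batch),
                    ("anc", "HXT3", b, 1, 22.0 + shift, batch),
                    ("anc", "ACT1", b, 1, 16.0 + shift, batch),
                ]
        ct = pd.DataFrame(
            rows, columns=["clone", "gene", "bio_rep", "tech_rep", "ct", "batch"]
        )
        for clone in ("evo_b1", "evo_b2"):
            ratio, _ = relative_expression(
                ct, clone, "anc", "HXT3", "ACT1", self.eff
            )
            assert ratio == pytest.approx(1.0, abs=1e-12)


class TestBuildMatrix:
    def test_zero_noise_round_trip_recovers_signatures_exactly(
        self, zero_noise_cohort
    ):
        ct, truth, sigset = zero_noise_cohort
        matrix = build_matrix(ct, "ancestor")
        for clone, cls in zip(truth["clone"], truth["class"]):
            np.testing.assert_allclose(
                matrix.log2.loc[clone].to_numpy(),
                sigset[cls].mean_log2,
                atol=1e-9,
            )
        assert (matrix.se.to_numpy() < 1e-9).all()

    def test_matrix_matches_oracle_on_noisy_cohort(self, cohort, cohort_matrix):
        ct, truth = cohort
        from cladecall.simulate import DEFAULT_EFFICIENCIES

        rng = np.random.default_rng(0)
        clones = rng.choice(truth["clone"], 5, replace=False)
        for clone in clones:
            for gene in DEFAULT_PANEL:
                expected = ratio_oracle(
                    ct, clone, "ancestor", gene, "ACT1", DEFAULT_EFFICIENCIES
                )
                assert cohort_matrix.log2.loc[clone, gene] == pytest.approx(
                    expected, abs=1e-12
                )

    def test_missing_panel_gene_lists_every_gap(self):
        rows = []
        for clone in ("anc", "c1"):
            for gene in list(DEFAULT_PANEL) + ["ACT1"]:
                if clone == "c1" and gene in ("HXT2", "SUC2"):
                    continue
                rows.append((clone, gene, 1, 1, 20.0))
        ct = tiny_ct_table(rows)
        with pytest.raises(MissingDataError, match="c1:HXT2.*c1:SUC2"):
            build_matrix(ct, "anc")

    def test_missing_ancestor_is_an_error(self):
        ct = tiny_ct_table([("c1", g, 1, 1, 20.0) for g in DEFAULT_PANEL + ("ACT1",)])
        with pytest.raises(MissingDataError, match="ancestor"):
            build_matrix(ct, "anc")

    def test_row_and_column_order_are_deterministic(self, cohort, cohort_matrix):
        ct, _ = cohort
        first_seen = [c for c in pd.unique(ct["clone"]) if c != "ancestor"]
        assert list(cohort_matrix.log2.index) == first_seen
        assert list(cohort_matrix.log2.columns) == list(DEFAULT_PANEL)
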