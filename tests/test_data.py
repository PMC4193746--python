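"""Summary-data model, p-value/SE conversion, orientation, exclusions, I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import mvmr
from mvmr import (
    CorrelationSpec,
    SummaryDataset,
    apply_exclusions,
    orient_risk_increasing,
    pvalue_from_se,
    read_summary_table,
    se_from_pvalue,
    write_summary_table,
)
from mvmr.data import SummaryDataError, VariantRecord, attach_ld, clear_exclusions
from mvmr.fixtures import load_exclusion_list

from conftest import make_dataset


class TestSummaryDataset:
    def test_rejects_nonpositive_se(self):
        with pytest.raises(SummaryDataError, match="positive"):
            SummaryDataset(("a",), ("r",), [[0.1]], [[0.0]], [0.1], [0.1])

    def test_rejects_duplicate_ids(self):
        with pytest.raises(SummaryDataError, match="unique"):
            SummaryDataset(
                ("a", "a"), ("r",), [[0.1], [0.2]], [[0.1], [0.1]],
                [0.1, 0.2], [0.1, 0.1],
            )

    def test_rejects_asymmetric_ld(self):
        ld = np.array([[1.0, 0.2], [0.3, 1.0]])
        with pytest.raises(SummaryDataError, match="symmetric"):
            SummaryDataset(
                ("a", "b"), ("r",), [[0.1], [0.2]], [[0.1], [0.1]],
                [0.1, 0.2], [0.1, 0.1], ld=ld,
            )

    def test_rejects_dimension_mismatch(self):
        with pytest.raises(SummaryDataError, match="dimension"):
            SummaryDataset(("a", "b"), ("r",), [[0.1]], [[0.1]], [0.1], [0.1])


class TestCorrelationSpec:
    def test_lipid_default_entries(self):
        P = CorrelationSpec.lipid_default().P
        assert P[0, 1] == -0.1 and P[0, 2] == 0.2 and P[0, 3] == 0.1
        assert P[1, 2] == -0.1 and P[1, 3] == -0.1 and P[2, 3] == 0.1

    def test_rejects_non_psd(self):
        with pytest.raises(SummaryDataError, match="positive semi-definite"):
            CorrelationSpec.from_rhos([0.9, 0.9, -0.9], k=2)

    def test_scaled_zero_is_identity(self):
        assert np.array_equal(
            CorrelationSpec.lipid_default().scaled(0.0).P, np.eye(4)
        )


class TestSeFromPvalue:
    def test_inverts_normal_quantile(self):
        # hand inversion: Phi^-1(1 - 0.05/2) = 1.959964
        assert se_from_pvalue(0.10, 0.05) == pytest.approx(
            0.10 / 1.959964, rel=1e-6
        )

    def test_p_equal_one_uses_fallback_mean(self):
        assert se_from_pvalue(0.0, 1.0, fallback_ses=[0.02, 0.04]) == pytest.approx(0.03)

    def test_extreme_p_stays_finite(self):
        se = se_from_pvalue(1.0, 1e-310)
        assert np.isfinite(se) and se > 0
        # string input below the double-precision floor
        se2 = se_from_pvalue(1.0, "1e-400")
        assert np.isfinite(se2) and 0 < se2 < se

    @pytest.mark.parametrize(
        "beta,p,err",
        [(0.1, -0.5, "p-value"), (0.1, 0.0, "p-value"), (0.0, 0.5, "inconsistent"),
         (np.inf, 0.5, "finite"), (0.0, 1.0, "fallback")],
    )
    def test_domain_errors(self, beta, p, err):
        with pytest.raises(ValueError, match=err):
            se_from_pvalue(beta, p)

    @given(
        logp=st.floats(min_value=-300, max_value=np.log10(0.999)),
        beta=st.floats(min_value=0.001, max_value=10.0),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_roundtrip_through_pvalue(self, logp, beta):
        p = 10.0**logp
        se = se_from_pvalue(beta, p)
        assert pvalue_from_se(beta, se) == pytest.approx(p, rel=1e-6)


class TestVariantRecord:
    def test_warns_on_inconsistent_se_and_p(self):
        with pytest.warns(UserWarning, match="disagree"):
            VariantRecord("rs1", {"rf": 0.1}, {"rf": 0.1}, {"rf": 0.05})

    def test_consistent_inputs_silent(self, recwarn):
        VariantRecord("rs1", {"rf": 0.1}, {"rf": 0.10 / 1.959964}, {"rf": 0.05})
        assert not recwarn.list


class TestOrientation:
    def test_flips_negative_outcome_rows(self):
        ds = SummaryDataset(
            ("a",), ("r1", "r2", "r3"), [[0.2, -0.1, 0.0]],
            [[0.1, 0.1, 0.1]], [-0.05], [0.1],
        )
        out = orient_risk_increasing(ds)
        assert out.Y[0] == 0.05
        assert np.allclose(out.X[0], [-0.2, 0.1, 0.0])

    def test_identity_when_all_nonnegative(self, small_ds):
        out = orient_risk_increasing(small_ds)
        assert np.array_equal(out.Y, small_ds.Y)
        assert np.array_equal(out.X, small_ds.X)

    def test_idempotent_and_magnitude_preserving(self):
        rng = np.random.default_rng(3)
        ds = make_dataset(rng, J=6, K=2, with_ld=True)
        once = orient_risk_increasing(ds)
        twice = orient_risk_increasing(once)
        assert np.array_equal(once.X, twice.X)
        assert np.array_equal(once.Y, twice.Y)
        assert np.allclose(np.abs(once.X), np.abs(ds.X))
        assert np.array_equal(once.SE_X, ds.SE_X)
        assert np.array_equal(once.SE_Y, ds.SE_Y)
        assert np.allclose(np.abs(once.ld), np.abs(ds.ld))


class TestExclusions:
    def test_pleiotropy_fixture_reduces_185_to_162(self):
        fixture = load_exclusion_list("pleiotropy_bp_bmi")
        # embed the 23 listed variants among 185
        ids = tuple(fixture) + tuple(f"snp{j}" for j in range(185 - 23))
        ds = SummaryDataset(
            ids, ("r",), np.ones((185, 1)) * 0.1, np.ones((185, 1)) * 0.01,
            np.ones(185) * 0.05, np.ones(185) * 0.02,
        )
        out = apply_exclusions(ds, fixture, "pleiotropy with BP/BMI")
        assert len(fixture) == 23
        assert out.n_active == 162

    def test_empty_list_is_noop(self, small_ds):
        assert apply_exclusions(small_ds, []).excluded == {}

    def test_double_exclusion_counted_once(self, small_ds):
        out = apply_exclusions(small_ds, ["v1", "v1"], "dup")
        out = apply_exclusions(out, ["v1"], "again")
        assert out.n_active == 4
        assert out.excluded["v1"] == "dup"

    def test_unknown_ids_warn_not_fail(self, small_ds):
        with pytest.warns(UserWarning, match="not present"):
            out = apply_exclusions(small_ds, ["nope"], "x")
        assert out.n_active == 5

    def test_reversible(self, small_ds):
        out = clear_exclusions(apply_exclusions(small_ds, ["v1"], "x"))
        assert out.n_active == 5


class TestTableIO:
    def test_se_columns_pass_through(self, tmp_path):
        path = tmp_path / "t.tsv"
        pd.DataFrame(
            {
                "id": ["a", "b", "c"],
                "rf_beta": [0.1, 0.2, 0.3],
                "rf_se": [0.01, 0.02, 0.03],
                "outcome_beta": [0.05, 0.06, 0.07],
                "outcome_se": [0.02, 0.02, 0.02],
            }
        ).to_csv(path, sep="\t", index=False)
        ds = read_summary_table(path, ["rf"])
        assert ds.n_variants == 3
        assert np.allclose(ds.SE_X[:, 0], [0.01, 0.02, 0.03])

    def test_p_columns_reconstruct_ses(self, tmp_path):
        path = tmp_path / "t.tsv"
        betas = [0.1, 0.2, 0.3]
        ps = [0.05, 0.01, 0.001]
        pd.DataFrame(
            {
                "id": ["a", "b", "c"],
                "rf_beta": betas,
                "rf_p": ps,
                "outcome_beta": [0.05, 0.06, 0.07],
                "outcome_se": [0.02, 0.02, 0.02],
            }
        ).to_csv(path, sep="\t", index=False)
        ds = read_summary_table(path, ["rf"])
        expected = [abs(b) / stats.norm.isf(p / 2) for b, p in zip(betas, ps)]
        assert np.allclose(ds.SE_X[:, 0], expected, rtol=1e-12)

    def test_p_equal_one_row_uses_other_rows_mean(self, tmp_path):
        path = tmp_path / "t.tsv"
        pd.DataFrame(
            {
                "id": ["a", "b", "c"],
                "rf_beta": [0.1, 0.0, 0.3],
                "rf_p": [0.05, 1.0, 0.001],
                "outcome_beta": [0.05, 0.06, 0.07],
                "outcome_se": [0.02, 0.02, 0.02],
            }
        ).to_csv(path, sep="\t", index=False)
        ds = read_summary_table(path, ["rf"])
        assert ds.SE_X[1, 0] == pytest.approx((ds.SE_X[0, 0] + ds.SE_X[2, 0]) / 2)

    def test_missing_outcome_column_is_config_error(self, tmp_path):
        path = tmp_path / "t.tsv"
        pd.DataFrame({"id": ["a"], "rf_beta": [0.1], "rf_se": [0.01]}).to_csv(
            path, sep="\t", index=False
        )
        with pytest.raises(SummaryDataError, match="outcome_beta"):
            read_summary_table(path, ["rf"])

    def test_non_numeric_cell_names_row_and_column(self, tmp_path):
        path = tmp_path / "t.tsv"
        pd.DataFrame(
            {
                "id": ["a", "b"],
                "rf_beta": [0.1, "oops"],
                "rf_se": [0.01, 0.01],
                "outcome_beta": [0.05, 0.06],
                "outcome_se": [0.02, 0.02],
            }
        ).to_csv(path, sep="\t", index=False)
        with pytest.raises(SummaryDataError, match="rf_beta.*'b'"):
            read_summary_table(path, ["rf"])

    def test_roundtrip_full_precision(self, tmp_path):
        rng = np.random.default_rng(5)
        ds = make_dataset(rng, J=7, K=3)
        ds = apply_exclusions(ds, ["s2"], "why not")
        path = tmp_path / "rt.tsv"
        write_summary_table(ds, path)
        back = read_summary_table(path, ds.risk_factor_names)
        assert back.variant_ids == ds.variant_ids
        assert np.array_equal(back.X, ds.X)
        assert np.array_equal(back.SE_X, ds.SE_X)
        assert np.array_equal(back.Y, ds.Y)
        assert np.array_equal(back.SE_Y, ds.SE_Y)
        assert back.excluded == ds.excluded

    def test_ld_roundtrip_and_alignment(self, tmp_path):
        rng = np.random.default_rng(6)
        ds = make_dataset(rng, J=4, K=1, with_ld=True)
        path = tmp_path / "ld.tsv"
        mvmr.write_ld_matrix(ds.ld, ds.variant_ids, path)
        ld, ids = mvmr.read_ld_matrix(path)
        # attach in permuted order: alignment is by id
        perm = [2, 0, 3, 1]
        permuted = SummaryDataset(
            tuple(np.array(ds.variant_ids)[perm]), ds.risk_factor_names,
            ds.X[perm], ds.SE_X[perm], ds.Y[perm], ds.SE_Y[perm],
        )
        out = attach_ld(permuted, ld, ids)
        for a, va in enumerate(permuted.variant_ids):
            for b, vb in enumerate(permuted.variant_ids):
                ja = ds.variant_ids.index(va)
                jb = ds.variant_ids.index(vb)
                assert out.ld[a, b] == pytest.approx(ds.ld[ja, jb])


class TestFixtures:
    def test_shipped_list_sizes(self):
        assert len(load_exclusion_list("pleiotropy_bp_bmi")) == 23
        assert len(load_exclusion_list("pruned_98th")) == 24
        assert len(load_exclusion_list("pruned_95th")) == 31
        assert len(load_exclusion_list("pruned_90th")) == 42
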