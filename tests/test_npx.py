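"""NPX arithmetic and the LOD/missingness filter contracts."""

import numpy as np
import pandas as pd
import pytest

from evpanel.exceptions import ConfigurationError, DataIntegrityError
from evpanel.matrix import ExpressionMatrix
from evpanel.npx import (
    apply_filters,
    compute_npx,
    filter_lod,
    filter_missing,
    reverse_normalization,
)
from evpanel.synthetic import generate_ct_data


def _readout_row(sample="S1", analyte="A1", plate="PL1", ct=0.0, ext=0.0,
                 ipc=0.0, cf=0.0):
    return {
        "sample_id": sample, "analyte_id": analyte, "plate_id": plate,
        "ct_analyte": ct, "ct_extension_control": ext,
        "dct_interplate_control": ipc, "correction_factor": cf,
    }


def _simple_matrix(values, below=None):
    """samples x proteins DataFrame -> ExpressionMatrix (all HC)."""
    idx = values.index
    return ExpressionMatrix(
        values=values,
        sample_group=pd.Series("HC", index=idx),
        subject_id=pd.Series(idx, index=idx),
        below_lod=below,
    )


class TestComputeNpx:
    @pytest.mark.parametrize(
        "ct,ext,ipc,cf,expected",
        [
            (0, 0, 0, 0, 0.0),  # all-zero identity
            (25, 20, 3, 10, 8.0),  # dCt=5, ddCt=2, NPX=10-2
            (25, 25, 0, 5, 5.0),
        ],
    )
    def test_three_step_formula(self, ct, ext, ipc, cf, expected):
        m = compute_npx(pd.DataFrame([_readout_row(ct=ct, ext=ext, ipc=ipc, cf=cf)]))
        assert m.values.iloc[0, 0] == expected

    def test_affine_in_ct_with_slope_minus_one(self):
        base = compute_npx(pd.DataFrame([_readout_row(ct=25, ext=20, ipc=3, cf=10)]))
        for delta in (0.5, 1.0, 7.25):
            shifted = compute_npx(
                pd.DataFrame([_readout_row(ct=25 + delta, ext=20, ipc=3, cf=10)])
            )
            assert shifted.values.iloc[0, 0] == base.values.iloc[0, 0] - delta

    def test_roundtrip_matches_generated_truth(self):
        readouts, true_npx = generate_ct_data(12, 6, seed=9)
        m = compute_npx(readouts)
        assert np.array_equal(m.values.to_numpy(), true_npx.to_numpy())

    def test_interplate_difference_shifts_npx_exactly(self):
        rows = [
            _readout_row(sample="S1", plate="PL1", ct=24, ext=20, ipc=2.0, cf=10),
            _readout_row(sample="S2", plate="PL2", ct=24, ext=20, ipc=3.5, cf=10),
        ]
        m = compute_npx(pd.DataFrame(rows))
        # same analyte/extension Ct; NPX differs by exactly the dCt difference
        assert m.values.loc["S2", "A1"] - m.values.loc["S1", "A1"] == pytest.approx(1.5)

    def test_missing_control_names_pair(self):
        rows = pd.DataFrame([
            _readout_row(sample="S1", analyte="A9", plate="PL2", ipc=np.nan),
        ])
        with pytest.raises(DataIntegrityError, match="PL2.*A9"):
            compute_npx(rows)

    def test_inconsistent_correction_factor_rejected(self):
        rows = pd.DataFrame([
            _readout_row(sample="S1", cf=10),
            _readout_row(sample="S2", cf=11),
        ])
        with pytest.raises(DataIntegrityError, match="correction factor"):
            compute_npx(rows)

    def test_missing_ct_yields_missing_cell(self):
        rows = pd.DataFrame([
            _readout_row(sample="S1", ct=np.nan),
            _readout_row(sample="S2", ct=25),
        ])
        m = compute_npx(rows)
        assert m.values.loc["S1", "A1"] != m.values.loc["S1", "A1"]  # NaN


class TestFilters:
    def test_no_below_lod_is_identity(self):
        vals = pd.DataFrame(np.arange(12.0).reshape(4, 3),
                            index=list("abcd"), columns=["P1", "P2", "P3"])
        out, report = filter_lod(_simple_matrix(vals))
        pd.testing.assert_frame_equal(out.values, vals)
        assert report.removed_lod == {} and report.n_retained == 3

    def test_fully_censored_protein_removed(self):
        vals = pd.DataFrame(np.ones((4, 2)), index=list("abcd"), columns=["P1", "P2"])
        below = vals.astype(bool).copy()
        below["P2"] = False
        out, report = filter_lod(_simple_matrix(vals, below), max_below_lod_frac=0.5)
        assert list(out.protein_ids) == ["P2"]
        assert set(report.removed_lod) == {"P1"}

    def test_retained_below_lod_cells_become_missing(self):
        vals = pd.DataFrame(np.ones((4, 1)), index=list("abcd"), columns=["P1"])
        below = vals.astype(bool).copy()
        below.iloc[1:] = False  # 25% below LOD: protein retained
        out, _ = filter_lod(_simple_matrix(vals, below), max_below_lod_frac=0.5)
        assert out.values["P1"].isna().tolist() == [True, False, False, False]

    @pytest.mark.parametrize("n_missing,expected_kept", [(3, True), (4, False)])
    def test_missingness_boundary_is_strict(self, n_missing, expected_kept):
        # 10 samples: exactly 30% missing is retained, 40% is removed
        vals = pd.DataFrame(np.ones((10, 1)), index=[f"s{i}" for i in range(10)],
                            columns=["P1"])
        vals.iloc[:n_missing, 0] = np.nan
        out, _ = filter_missing(_simple_matrix(vals), max_missing_frac=0.30)
        assert ("P1" in out.protein_ids) == expected_kept

    @pytest.mark.parametrize("seed", range(4))
    def test_removal_matches_bruteforce_recount(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 30, 25
        vals = pd.DataFrame(rng.normal(size=(n, p)),
                            index=[f"s{i}" for i in range(n)],
                            columns=[f"P{j:02d}" for j in range(p)])
        below = pd.DataFrame(rng.random((n, p)) < 0.3, index=vals.index,
                             columns=vals.columns)
        vals = vals.mask(rng.random((n, p)) < 0.2)
        below = below & vals.notna()
        m = _simple_matrix(vals.copy(), below.copy())
        out, report = apply_filters(m, max_below_lod_frac=0.5, max_missing_frac=0.30)

        # independent per-column counting oracle
        expect_lod = set()
        for c in vals.columns:
            obs = vals[c].notna()
            if obs.sum() and (below[c] & obs).sum() / obs.sum() > 0.5:
                expect_lod.add(c)
        assert set(report.removed_lod) == expect_lod
        expect_missing = set()
        for c in vals.columns:
            if c in expect_lod:
                continue
            miss = vals[c].isna() | below[c]  # censored cells become missing
            if miss.mean() > 0.30:
                expect_missing.add(c)
        assert set(report.removed_missing) == expect_missing
        assert report.n_input - report.n_retained == len(expect_lod | expect_missing)
        assert list(out.protein_ids) == [c for c in vals.columns
                                         if c not in expect_lod | expect_missing]

    def test_retained_count_monotone_in_thresholds(self):
        rng = np.random.default_rng(1)
        vals = pd.DataFrame(rng.normal(size=(20, 15)),
                            index=[f"s{i}" for i in range(20)],
                            columns=[f"P{j}" for j in range(15)])
        below = pd.DataFrame(rng.random((20, 15)) < 0.4, index=vals.index,
                             columns=vals.columns)
        m = _simple_matrix(vals, below)
        kept = [apply_filters(m, max_below_lod_frac=t, max_missing_frac=0.3)[1].n_retained
                for t in (0.0, 0.2, 0.5, 0.8, 1.0)]
        assert kept == sorted(kept)

    def test_invalid_threshold(self):
        vals = pd.DataFrame(np.ones((3, 1)), index=list("abc"), columns=["P1"])
        with pytest.raises(ConfigurationError):
            filter_lod(_simple_matrix(vals), max_below_lod_frac=1.2)


class TestReverseNormalization:
    def _matrix(self):
        vals = pd.DataFrame(np.arange(6.0).reshape(3, 2),
                            index=list("abc"), columns=["P1", "P2"])
        return _simple_matrix(vals)

    def test_equal_concentration_is_identity(self):
        m = self._matrix()
        conc = pd.Series(0.5, index=m.sample_ids)
        out = reverse_normalization(m, conc, fixed_conc=0.5)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_doubled_concentration_adds_one(self):
        m = self._matrix()
        conc = pd.Series(1.0, index=m.sample_ids)
        out = reverse_normalization(m, conc, fixed_conc=0.5)
        assert np.allclose(out.values, m.values + 1.0)

    def test_roundtrip_inverse(self):
        m = self._matrix()
        rng = np.random.default_rng(0)
        conc = pd.Series(rng.uniform(0.1, 5.0, 3), index=m.sample_ids)
        out = reverse_normalization(m, conc, fixed_conc=0.5)
        back = reverse_normalization(out, pd.Series(0.5, index=m.sample_ids) ** 2 / conc,
                                     fixed_conc=0.5)
        assert np.allclose(back.values, m.values)

    def test_nonpositive_concentration_rejected(self):
        m = self._matrix()
        conc = pd.Series([1.0, 0.0, 1.0], index=m.sample_ids)
        with pytest.raises(DataIntegrityError):
            reverse_normalization(m, conc, fixed_conc=0.5)
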