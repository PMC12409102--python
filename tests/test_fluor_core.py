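"""Lake-model fluorescence algebra: identities, round trips, QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafquanta import fluor_core as fc
from leafquanta.fluor_core import (
    InvalidMeasurementError,
    PhotoState,
    compute_npqt,
    compute_phi_no,
    compute_phi_npq,
    compute_phi_psii,
    compute_ql,
    derive_vpd,
    forward_fluorescence,
    qc_filter,
)


class TestNpqt:
    @pytest.mark.parametrize("fm, fo, expected", [
        (5.88, 1.0, 0.0),            # dark-adapted reference ratio
        (2.22, 1.0, 3.0),            # 4.88/1.22 - 1
        (1.96, 0.74619289, 2.0),     # inverse-model state with npqt = 2
    ])
    def test_reference_values(self, fm, fo, expected):
        assert compute_npqt(fm, fo) == pytest.approx(expected, abs=1e-6)

    def test_monotone_decreasing_in_ratio(self):
        ratios = np.linspace(1.2, 8.0, 50)
        vals = compute_npqt(ratios, np.ones_like(ratios))
        assert np.all(np.diff(vals) < 0)

    def test_invalid_ratio_raises(self):
        with pytest.raises(InvalidMeasurementError):
            compute_npqt(1.0, 1.2)
        with pytest.raises(ValueError):
            compute_npqt(-1.0, 0.5)


class TestQl:
    def test_boundaries(self):
        assert compute_ql(0.7, 2.0, 0.7) == pytest.approx(1.0)  # all open
        assert compute_ql(2.0, 2.0, 0.7) == pytest.approx(0.0)  # all closed

    def test_inverse_model_state(self):
        assert compute_ql(1.08088235, 1.96, 0.74619289) == pytest.approx(0.5, abs=1e-6)

    def test_fo_above_fm_raises(self):
        with pytest.raises(InvalidMeasurementError):
            compute_ql(1.0, 0.5, 0.7)


class TestYields:
    @pytest.mark.parametrize("ql, npqt, expected", [
        (0.0, 0.0, 1.0),
        (1.0, 0.0, 1.0 / 5.88),
        (0.5, 2.0, 1.0 / 5.44),
    ])
    def test_phi_no(self, ql, npqt, expected):
        assert compute_phi_no(PhotoState(ql, npqt)) == pytest.approx(expected)

    def test_phi_no_monotone_in_both_args(self):
        grid = np.linspace(0.01, 1.0, 25)
        vals_ql = [compute_phi_no(PhotoState(q, 1.0)) for q in grid]
        vals_npqt = [compute_phi_no(PhotoState(0.5, n)) for n in grid * 10]
        assert np.all(np.diff(vals_ql) < 0)
        assert np.all(np.diff(vals_npqt) < 0)

    @pytest.mark.parametrize("fs, fm, expected", [
        (5.88, 5.88, 0.0),
        (1.0, 5.88, 4.88 / 5.88),
        (1.08088235, 1.96, 0.44852941),
    ])
    def test_phi_psii(self, fs, fm, expected):
        assert compute_phi_psii(fs, fm) == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("psii, no, expected", [
        (4.88 / 5.88, 1.0 / 5.88, 0.0),  # dark-adapted limit
        (0.44852941, 0.18382353, 0.36764706),
        (0.0, 1.0, 0.0),
    ])
    def test_phi_npq_remainder(self, psii, no, expected):
        assert compute_phi_npq(psii, no) == pytest.approx(expected, abs=1e-6)

    def test_partition_identity_exact(self):
        rng = np.random.default_rng(0)
        ql = rng.uniform(0.01, 1.0, 200)
        npqt = rng.uniform(0.0, 12.0, 200)
        fs, fm, fo = forward_fluorescence(PhotoState(ql, npqt))
        psii = compute_phi_psii(fs, fm)
        no = compute_phi_no(PhotoState(compute_ql(fs, fm, fo),
                                       compute_npqt(fm, fo)))
        npq = compute_phi_npq(psii, no)
        np.testing.assert_allclose(psii + no + npq, 1.0, rtol=0, atol=1e-15)


class TestForwardModel:
    def test_dark_adapted_state(self):
        fs, fm, fo = forward_fluorescence(PhotoState(1.0, 0.0))
        assert (fs, fm, fo) == pytest.approx((1.0, 5.88, 1.0))
        assert compute_phi_psii(fs, fm) == pytest.approx(4.88 / 5.88)

    def test_reference_state(self):
        fs, fm, fo = forward_fluorescence(PhotoState(0.5, 2.0))
        assert fm == pytest.approx(1.96)
        assert fo == pytest.approx(0.74619289, abs=1e-6)
        assert fs == pytest.approx(1.08088235, abs=1e-6)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(ql=st.floats(0.01, 1.0), npqt=st.floats(0.0, 15.0))
    def test_round_trip_recovers_state(self, ql, npqt):
        fs, fm, fo = forward_fluorescence(PhotoState(ql, npqt))
        assert compute_ql(fs, fm, fo) == pytest.approx(ql, abs=1e-10)
        assert compute_npqt(fm, fo) == pytest.approx(npqt, abs=1e-10)


class TestVpd:
    def test_saturated_air_gives_zero(self):
        assert derive_vpd(25.0, 100.0) == 0.0

    @pytest.mark.parametrize("t, rh", [(25.0, 50.0), (35.0, 60.0), (18.0, 85.0)])
    def test_tetens_closed_form(self, t, rh):
        es = 0.61078 * np.exp(17.27 * t / (t + 237.3))
        assert derive_vpd(t, rh) == pytest.approx(es * (1 - rh / 100.0))

    def test_out_of_range_rh_raises(self):
        with pytest.raises(ValueError):
            derive_vpd(25.0, 104.0)


class TestQcFilter:
    @staticmethod
    def _frame(triples):
        return pd.DataFrame(triples, columns=["phi_psii", "phi_no", "phi_npq"])

    def test_valid_triple_kept(self):
        kept, log = qc_filter(self._frame([(0.5, 0.2, 0.3)]))
        assert len(kept) == 1 and log["n_rejected"] == 0

    def test_negative_component_rejected(self):
        kept, log = qc_filter(self._frame([(0.7, 0.4, -0.1)]))
        assert len(kept) == 0
        assert log["nonpositive_phi_npq"] == 1

    def test_sum_violation_rejected_for_supplied_yields(self):
        kept, log = qc_filter(self._frame([(0.5, 0.2, 0.31)]))
        assert len(kept) == 0 and log["sum_not_unity"] == 1

    def test_injected_corruption_counts(self):
        rng = np.random.default_rng(42)
        n = 100
        psii = rng.uniform(0.1, 0.6, n)
        no = rng.uniform(0.1, 0.3, n)
        df = pd.DataFrame(dict(phi_psii=psii, phi_no=no, phi_npq=1 - psii - no))
        bad = rng.choice(n, 13, replace=False)
        df.loc[bad, "phi_npq"] = -0.05
        kept, log = qc_filter(df)
        assert len(kept) == 87
        assert log["nonpositive_phi_npq"] + log["sum_not_unity"] == 13 + 13
        assert set(kept.index) == set(df.index) - set(bad)


class TestAddYields:
    def test_recompute_matches_supplied(self, small_campaign):
        out = fc.add_yields(small_campaign)
        good = out[~small_campaign["corrupted"].to_numpy()]
        # forward model + small measurement noise: recomputed state near truth
        assert np.corrcoef(good["ql"], good["true_ql"])[0, 1] > 0.99
        assert np.corrcoef(good["npqt"], good["true_npqt"])[0, 1] > 0.99

    def test_discrepancy_warning_for_inconsistent_supplied_yields(self):
        df = pd.DataFrame(dict(
            fs=[1.0], fm_prime=[2.0], fo_prime=[0.8], par=[100.0],
            air_temp=[25.0], rh=[60.0], height_m=[10.0], species=["a"],
            season=["wet"], phi_psii=[0.9], phi_no=[0.05], phi_npq=[0.05]))
        with pytest.warns(UserWarning, match="differ from"):
            fc.add_yields(df)
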