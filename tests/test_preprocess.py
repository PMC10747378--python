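import numpy as np
import pandas as pd
import pytest

from aqualeaf import (
    SgConfig,
    SpectraSet,
    difference_spectra,
    msc_apply,
    msc_fit_transform,
    sg_derivative,
)


def _plain(wl, A):
    return SpectraSet(wl, A, pd.DataFrame({"spectrum_id":
                                           [f"s{i}" for i in range(len(A))]}))


class TestSgDerivative:
    def test_quadratic_second_derivative_is_exact(self):
        wl = np.arange(40.0)
        s = _plain(wl, (3.0 * wl**2)[None, :])
        d = sg_derivative(s, SgConfig(window=11, polyorder=2, deriv_order=2))
        np.testing.assert_allclose(d.absorbance, 6.0, atol=1e-8)
        assert d.n_bands == 40 - 10  # half-window dropped at each edge

    def test_linear_spectrum_gives_zero(self):
        wl = np.arange(30.0)
        s = _plain(wl, (2.0 + 0.5 * wl)[None, :])
        d = sg_derivative(s, SgConfig())
        np.testing.assert_allclose(d.absorbance, 0.0, atol=1e-10)

    def test_matches_per_point_polyfit_oracle(self, rng):
        wl = np.arange(50.0)
        y = rng.standard_normal(50)
        s = _plain(wl, y[None, :])
        cfg = SgConfig(window=7, polyorder=3, deriv_order=2)
        d = sg_derivative(s, cfg)
        half = 3
        for k, j in enumerate(range(half, 50 - half)):
            x_local = np.arange(-half, half + 1, dtype=float)
            coef = np.polynomial.polynomial.polyfit(
                x_local, y[j - half : j + half + 1], 3
            )
            assert d.absorbance[0, k] == pytest.approx(2.0 * coef[2], abs=1e-9)

    def test_linearity(self, rng):
        wl = np.arange(60.0)
        x, y = rng.standard_normal(60), rng.standard_normal(60)
        a, b = 2.7, -0.3
        cfg = SgConfig()
        dx = sg_derivative(_plain(wl, x[None, :]), cfg).absorbance
        dy = sg_derivative(_plain(wl, y[None, :]), cfg).absorbance
        dz = sg_derivative(_plain(wl, (a * x + b * y)[None, :]), cfg).absorbance
        np.testing.assert_allclose(dz, a * dx + b * dy, atol=1e-12)

    def test_per_nm_scaling(self, rng):
        wl = np.linspace(900.0, 1700.0, 60)  # step ~13.6 nm
        y = rng.standard_normal((2, 60))
        s = _plain(wl, y)
        di = sg_derivative(s, SgConfig(scale="per_index")).absorbance
        dn = sg_derivative(s, SgConfig(scale="per_nm")).absorbance
        step = np.median(np.diff(wl))
        np.testing.assert_allclose(dn, di / step**2, atol=1e-12)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            SgConfig(window=10)

    def test_window_exceeding_bands_rejected(self, rng):
        s = _plain(np.arange(9.0), rng.standard_normal((1, 9)))
        with pytest.raises(ValueError, match="window"):
            sg_derivative(s, SgConfig(window=11))


class TestMsc:
    def test_affine_distortions_collapse_to_reference(self, rng):
        wl = np.arange(40.0)
        ref = np.sin(wl / 5.0) + 2.0
        offs, slopes = rng.normal(0, 0.5, 5), rng.normal(1.0, 0.2, 5)
        A = offs[:, None] + slopes[:, None] * ref
        corrected, model = msc_fit_transform(_plain(wl, A))
        # every corrected spectrum equals the set reference (itself affine in ref)
        for row in corrected.absorbance:
            np.testing.assert_allclose(row, model.reference, atol=1e-9)

    def test_identical_spectra_unchanged(self):
        wl = np.arange(20.0)
        ref = np.cos(wl / 3.0)
        A = np.vstack([ref, ref, ref])
        corrected, _ = msc_fit_transform(_plain(wl, A))
        np.testing.assert_allclose(corrected.absorbance, A, atol=1e-12)

    def test_refit_against_reference_gives_identity_fit(self, rng):
        wl = np.arange(50.0)
        A = 0.5 + rng.random((8, 50))
        corrected, model = msc_fit_transform(_plain(wl, A))
        ref_c = model.reference - model.reference.mean()
        denom = ref_c @ ref_c
        for row in corrected.absorbance:
            b = (row - row.mean()) @ ref_c / denom
            a = row.mean() - b * model.reference.mean()
            assert b == pytest.approx(1.0, abs=1e-10)
            assert a == pytest.approx(0.0, abs=1e-10)

    def test_degenerate_spectrum_is_named(self, rng):
        wl = np.arange(30.0)
        A = np.vstack([np.sin(wl / 3), np.cos(wl / 4), np.full(30, 0.7)])
        s = SpectraSet(wl, A, pd.DataFrame({"spectrum_id": ["a", "b", "flat"]}))
        with pytest.raises(ValueError, match="flat"):
            msc_fit_transform(s)

    def test_apply_reproduces_fit_transform(self, rng):
        wl = np.arange(25.0)
        A = 1.0 + rng.random((6, 25))
        s = _plain(wl, A)
        corrected, model = msc_fit_transform(s)
        again = msc_apply(model, s)
        np.testing.assert_allclose(again.absorbance, corrected.absorbance,
                                   atol=1e-12)

    def test_apply_to_reference_is_identity(self, rng):
        wl = np.arange(25.0)
        A = 1.0 + rng.random((4, 25))
        _, model = msc_fit_transform(_plain(wl, A))
        out = msc_apply(model, _plain(wl, model.reference[None, :]))
        np.testing.assert_allclose(out.absorbance[0], model.reference,
                                   atol=1e-10)

    def test_grid_mismatch_raises(self, rng):
        wl = np.arange(25.0)
        A = 1.0 + rng.random((4, 25))
        _, model = msc_fit_transform(_plain(wl, A))
        with pytest.raises(ValueError, match="grid"):
            msc_apply(model, _plain(wl + 1.0, A))

    def test_needs_two_spectra(self, rng):
        s = _plain(np.arange(10.0), rng.random((1, 10)))
        with pytest.raises(ValueError):
            msc_fit_transform(s)


class TestDifferenceSpectra:
    def _daily_set(self, values_by_day):
        wl = np.arange(10.0)
        rows, meta = [], []
        for day, val in values_by_day.items():
            rows.append(np.full(10, val))
            meta.append({"spectrum_id": f"d{day}", "day": day})
        return SpectraSet(wl, np.vstack(rows), pd.DataFrame(meta))

    def test_baseline_row_is_excluded(self):
        s = self._daily_set({3: 1.0, 7: 2.0, 10: 3.0})
        d = difference_spectra(s, 3, field="day")
        assert d.n_spectra == 2
        assert 3 not in set(d.meta["day"])

    def test_equal_days_give_zero_difference(self):
        s = self._daily_set({3: 1.5, 7: 1.5})
        d = difference_spectra(s, 3, field="day")
        np.testing.assert_allclose(d.absorbance, 0.0, atol=1e-15)

    def test_constant_in_day_dataset_is_identically_zero(self, rng):
        wl = np.arange(12.0)
        spec = rng.random(12)
        rows = np.vstack([spec] * 6)
        meta = pd.DataFrame({"day": [3, 3, 7, 7, 10, 10],
                             "spectrum_id": list("abcdef")})
        d = difference_spectra(SpectraSet(wl, rows, meta), 3, field="day")
        np.testing.assert_allclose(d.absorbance, 0.0, atol=1e-12)

    def test_missing_baseline_raises(self):
        s = self._daily_set({7: 1.0, 10: 2.0})
        with pytest.raises(ValueError, match="baseline"):
            difference_spectra(s, 3, field="day")

    def test_within_groups_subtract_their_own_baseline(self):
        wl = np.arange(5.0)
        meta = pd.DataFrame(
            {"line_label": ["a", "a", "b", "b"], "day": [3, 7, 3, 7],
             "spectrum_id": list("wxyz")}
        )
        A = np.array([[0.0] * 5, [1.0] * 5, [10.0] * 5, [14.0] * 5])
        d = difference_spectra(SpectraSet(wl, A, meta), 3, field="day",
                               within=["line_label"])
        vals = {row["line_label"]: d.absorbance[i, 0]
                for i, row in d.meta.iterrows()}
        assert vals == {"a": 1.0, "b": 4.0}
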