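"""Referencing, baseline correction, binning, normalization, assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psymetab.preprocessing import (
    BinnedMatrix,
    PreprocessConfig,
    ReferencingError,
    assemble_matrix,
    bin_label,
    bin_spectrum,
    correct_baseline,
    default_bin_edges,
    normalize_and_scale,
    reference_to_lactate,
)
from psymetab.spectra import Spectrum
from psymetab.synthetic import generate_spectrum


def _grid(step=0.001):
    n = int(round(8.5 / step)) + 1
    return np.linspace(0.5, 9.0, n)


class TestBinEdges:
    def test_default_convention_retains_328_bins(self):
        edges = default_bin_edges()
        assert edges.shape[0] == 328

    def test_enumeration_oracle_for_default_convention(self):
        # direct enumeration: fixed grid anchored at 0.80, right edge <= 8.47,
        # drop any bin overlapping the open water interval (4.13, 5.22)
        kept = []
        k = 0
        while True:
            left = 0.80 + 0.02 * k
            right = left + 0.02
            if right > 8.47 + 1e-9:
                break
            if not (right > 4.13 + 1e-9 and left < 5.22 - 1e-9):
                kept.append((left, right))
            k += 1
        edges = default_bin_edges()
        assert len(kept) == len(edges) == 328
        assert np.allclose(edges, np.array(kept))

    def test_total_grid_has_383_bins_before_water_drop(self):
        edges = default_bin_edges(exclusion=None)
        assert edges.shape[0] == 383


class TestBinSpectrum:
    def test_constant_intensity_gives_width_per_bin(self):
        ppm = _grid()
        s = Spectrum(ppm, np.ones_like(ppm), "c")
        vals, edges = bin_spectrum(s)
        assert np.allclose(vals, 0.02, rtol=1e-9)

    def test_single_peak_in_one_bin_carries_whole_integral(self):
        ppm = _grid(0.00005)
        gamma = 0.00012  # sharp enough that the Lorentzian tails are negligible
        center = 3.21
        y = gamma**2 / ((ppm - center) ** 2 + gamma**2)
        s = Spectrum(ppm, y, "peak")
        vals, edges = bin_spectrum(s)
        total = np.trapezoid(y, ppm)
        j = np.argmax(vals)
        assert edges[j][0] <= center < edges[j][1]
        assert vals[j] == pytest.approx(total, rel=0.01)

    def test_coarse_axis_rejected(self):
        ppm = np.arange(0.5, 9.01, 0.01)  # coarser than width/4 = 0.005
        s = Spectrum(ppm, np.ones_like(ppm), "coarse")
        with pytest.raises(ValueError, match="resolution"):
            bin_spectrum(s)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(-2, 2), st.floats(-2, 2))
    def test_binning_is_linear(self, seed, a, b):
        ppm = _grid(0.004)
        r = np.random.default_rng(seed)
        y1, y2 = r.normal(size=ppm.size), r.normal(size=ppm.size)
        v1, _ = bin_spectrum(Spectrum(ppm, y1, "1"))
        v2, _ = bin_spectrum(Spectrum(ppm, y2, "2"))
        v12, _ = bin_spectrum(Spectrum(ppm, a * y1 + b * y2, "12"))
        assert np.allclose(v12, a * v1 + b * v2, atol=1e-10)

    def test_bin_sum_equals_integral_over_retained_regions(self, library):
        s = generate_spectrum({"glucose": 1.0, "lipid_ch2": 1.0}, library, noise_sd=0.01, seed=3)
        vals, edges = bin_spectrum(s)
        total = 0.0
        for left, right in edges:
            m = (s.ppm >= left) & (s.ppm <= right)
            xs = np.concatenate([[left], s.ppm[m], [right]])
            ys = np.interp(xs, s.ppm, s.intensity)
            total += np.trapezoid(ys, xs)
        assert np.sum(vals) == pytest.approx(total, rel=1e-9)


class TestReferencing:
    def test_centered_doublet_needs_no_shift(self, library):
        s = generate_spectrum({"lactate": 1.0}, library)
        _, shift = reference_to_lactate(s)
        assert abs(shift) <= 0.0011  # within one grid step

    def test_round_trip_recovers_imposed_displacement(self, library):
        # the search window must cover the displaced doublet
        s = generate_spectrum({"lactate": 1.0}, library)
        displaced = s.shifted(+0.05)
        _, shift = reference_to_lactate(displaced, search_halfwidth=0.08)
        assert shift == pytest.approx(-0.05, abs=0.0011)

    def test_flat_spectrum_raises_referencing_error(self):
        ppm = _grid()
        s = Spectrum(ppm, np.zeros_like(ppm), "flat-1")
        with pytest.raises(ReferencingError, match="flat-1"):
            reference_to_lactate(s)

    def test_window_outside_axis_rejected(self, library):
        ppm = np.linspace(2.0, 9.0, 8000)
        s = Spectrum(ppm, np.ones_like(ppm) + np.sin(ppm), "far")
        with pytest.raises(ValueError, match="window"):
            reference_to_lactate(s)

    def test_bins_invariant_under_recoverable_shift(self, library):
        # referencing invariance: a +delta-displaced copy re-bins to the same values
        s = generate_spectrum({"lactate": 1.0, "glucose": 0.8, "alanine": 0.5}, library)
        ref0, _ = reference_to_lactate(s)
        v0, _ = bin_spectrum(ref0)
        # one grid step's integration error: peak height x step
        tol = float(np.max(s.intensity)) * 0.001
        for delta in (-0.03, 0.02, 0.045):
            refd, _ = reference_to_lactate(s.shifted(delta), search_halfwidth=0.08)
            vd, _ = bin_spectrum(refd)
            assert np.allclose(vd, v0, atol=tol)


class TestBaseline:
    def test_pure_degree5_polynomial_removed(self):
        ppm = _grid()
        x = (ppm - 4.75) / 4.25
        base = 3.0 - 2.0 * x + 1.5 * x**2 - x**3 + 0.5 * x**4 + 0.2 * x**5
        s = Spectrum(ppm, base, "poly")
        out = correct_baseline(s)
        assert np.max(np.abs(out.intensity)) < 1e-6 * np.max(np.abs(base))

    def test_zero_spectrum_stays_zero(self):
        ppm = _grid()
        out = correct_baseline(Spectrum(ppm, np.zeros_like(ppm), "z"))
        assert np.allclose(out.intensity, 0.0, atol=1e-12)

    def test_peak_heights_preserved_after_baseline_removal(self, library):
        conc = {"lactate": 1.0, "choline": 0.8, "glucose": 0.9}
        clean = generate_spectrum(conc, library)
        with_base = generate_spectrum(conc, library, baseline_poly_sd=0.3, seed=9)
        out = correct_baseline(with_base)
        for name in conc:
            tpl = library[name]
            for center, height in tpl.multiplet:
                j = np.argmin(np.abs(clean.ppm - center))
                window = slice(max(j - 5, 0), j + 5)
                truth = clean.intensity[window].max()
                recovered = out.intensity[window].max()
                assert recovered == pytest.approx(truth, rel=0.02)

    def test_too_few_points_rejected(self):
        s = Spectrum(np.linspace(0, 1, 5), np.ones(5), "tiny")
        with pytest.raises(ValueError, match="degree"):
            correct_baseline(s, degree=5)


def _matrix(values, left0=0.80):
    n = values.shape[1]
    lefts = left0 + 0.02 * np.arange(n)
    edges = np.column_stack([lefts, lefts + 0.02])
    df = pd.DataFrame(values, index=[f"s{i}" for i in range(values.shape[0])],
                      columns=[bin_label(l, r) for l, r in edges])
    return BinnedMatrix(df, edges)


class TestNormalizeAndScale:
    def test_total_area_rows_sum_to_one(self, rng):
        m = _matrix(rng.uniform(0.1, 2.0, size=(8, 20)))
        out = normalize_and_scale(m, "total_area")
        assert np.allclose(out.values.sum(axis=1), 1.0, atol=1e-12)
        assert out.normalization_state == "total_area"

    def test_unit_variance_after_centering(self, rng):
        m = _matrix(rng.uniform(0.1, 2.0, size=(10, 6)))
        out = normalize_and_scale(m, "none", "unit_variance", center=True)
        X = out.values.to_numpy()
        assert np.allclose(X.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(X.var(axis=0, ddof=1), 1.0, atol=1e-9)

    def test_pqn_collapses_exact_dilutions(self, rng):
        base = rng.uniform(0.5, 2.0, size=12)
        dilutions = np.array([0.5, 0.8, 1.0, 1.3, 2.0, 4.0])
        m = _matrix(np.outer(dilutions, base))
        out = normalize_and_scale(m, "pqn")
        X = out.values.to_numpy()
        assert np.allclose(X, X[0], rtol=1e-10)

    def test_zero_row_sum_rejected_by_sample_name(self, rng):
        vals = rng.uniform(0.1, 1.0, size=(4, 5))
        vals[2] = 0.0
        with pytest.raises(ValueError, match="s2"):
            normalize_and_scale(_matrix(vals), "total_area")

    def test_double_normalization_rejected(self, rng):
        m = _matrix(rng.uniform(0.1, 2.0, size=(5, 5)))
        out = normalize_and_scale(m, "total_area")
        with pytest.raises(ValueError, match="already normalized"):
            normalize_and_scale(out, "total_area")
        scaled = normalize_and_scale(out, "none", "pareto", center=True)
        with pytest.raises(ValueError, match="already scaled"):
            normalize_and_scale(scaled, "none", "pareto", center=True)


class TestAssembleMatrix:
    def test_default_cohort_yields_143_by_328(self, default_cohort):
        spectra, meta, _ = default_cohort
        bm = assemble_matrix(spectra, meta)
        assert bm.values.shape == (143, 328)
        assert bm.sample_ids == list(meta["sample_id"])

    def test_multi_positive_samples_excluded_and_logged(self, default_cohort):
        spectra, meta, _ = default_cohort
        meta2 = meta.copy()
        flagged = [meta2.at[3, "sample_id"], meta2.at[80, "sample_id"]]
        meta2.loc[[3, 80], "multi_positive"] = True
        bm = assemble_matrix(spectra, meta2)
        assert bm.values.shape[0] == 141
        assert sorted(bm.provenance["excluded_multi_positive"]) == sorted(flagged)
        assert not set(flagged) & set(bm.sample_ids)

    def test_empty_spectrum_list_rejected(self, default_cohort):
        _, meta, _ = default_cohort
        with pytest.raises(ValueError, match="empty"):
            assemble_matrix([], meta)

    def test_id_mismatch_lists_orphans(self, default_cohort, library):
        spectra, meta, _ = default_cohort
        stray = generate_spectrum({"lactate": 1.0}, library, sample_id="stray_01")
        with pytest.raises(ValueError, match="stray_01"):
            assemble_matrix(list(spectra) + [stray], meta)
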