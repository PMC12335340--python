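"""Spin-system loading and density-matrix simulation."""

import numpy as np
import pytest

from mrsiglx.spin_sim import (
    LineShape,
    SequenceTiming,
    SpinSystem,
    SpinSystemError,
    UnknownMetaboliteError,
    available_metabolites,
    inphase_fraction,
    load_spin_system,
    make_basis_set,
    simulate_fid,
    spectrum_from_fid,
    te_separability_scan,
)

ALL_METS = ("NAA", "NAAG", "Cho", "GPC", "Cr", "Glu", "Gln", "mI", "Lac",
            "GABA", "GSH", "Gly", "Ala", "Glc", "Val", "2HG")


class TestSpinSystemLoading:
    def test_all_basis_metabolites_loadable(self):
        for name in ALL_METS:
            system = load_spin_system(name)
            assert system.n_protons >= 2
            assert np.allclose(system.j_matrix, system.j_matrix.T)

    def test_glu_is_five_coupled_protons_in_one_subsystem(self):
        glu = load_spin_system("Glu")
        assert glu.n_protons == 5
        assert len(glu.subsystem_indices()) == 1

    def test_cr_is_uncoupled_singlet_groups(self):
        cr = load_spin_system("Cr")
        assert cr.n_protons == 5
        assert np.all(cr.j_matrix == 0)
        assert set(cr.groups) == {"CH3", "CH2"}

    def test_unknown_metabolite_raises(self):
        with pytest.raises(UnknownMetaboliteError):
            load_spin_system("Xx")

    def test_asymmetric_j_rejected(self):
        with pytest.raises(SpinSystemError):
            SpinSystem("bad", (1.0, 2.0), ((0.0, 5.0), (3.0, 0.0)),
                       ("a", "b"), (1, 1))

    def test_cross_subsystem_coupling_rejected(self):
        with pytest.raises(SpinSystemError):
            SpinSystem("bad", (1.0, 2.0), ((0.0, 5.0), (5.0, 0.0)),
                       ("a", "b"), (1, 2))

    def test_available_metabolites_covers_default_basis(self):
        avail = set(available_metabolites())
        assert set(ALL_METS) <= avail


class TestSequenceTiming:
    def test_default_delays_sum_to_te_and_refocus(self):
        for scheme in ("vendor", "symmetric"):
            t = SequenceTiming(te=120.0, scheme=scheme)
            assert sum(t.delays) == pytest.approx(120.0)
            sign, acc = 1, 0.0
            for d in t.delays:
                acc += sign * d
                sign = -sign
            assert acc == pytest.approx(0.0, abs=1e-9)

    def test_non_refocusing_delays_rejected(self):
        with pytest.raises(ValueError):
            SequenceTiming(te=40.0, delays=(10.0, 10.0, 10.0, 5.0, 5.0))

    def test_negative_delay_rejected(self):
        with pytest.raises(ValueError):
            SequenceTiming(te=8.0, delays=(4.0, 8.0, 8.0, -8.0, -4.0))


class TestSimulateFid:
    def test_singlets_are_te_invariant(self, acq):
        cr = load_spin_system("Cr")
        ref = simulate_fid(cr, SequenceTiming(te=40.0), acq)
        for te in (80.0, 120.0, 144.0):
            s = simulate_fid(cr, SequenceTiming(te=te), acq)
            np.testing.assert_allclose(s.fid, ref.fid, atol=1e-12)

    def test_per_proton_normalization_at_short_te(self, acq):
        # at TE -> 0 the FID amplitude equals the proton count
        for name in ("Cr", "Gly", "Lac"):
            sys_ = load_spin_system(name)
            s = simulate_fid(sys_, SequenceTiming(
                te=0.06, scheme="symmetric"), acq)
            assert abs(s.fid[0]) == pytest.approx(sys_.n_protons, rel=1e-2)

    def test_singlet_fid_start_is_real(self, acq):
        for name in ("Cr", "Gly"):
            s = simulate_fid(load_spin_system(name), SequenceTiming(te=120.0), acq)
            assert abs(s.fid[0].imag) < 1e-10

    def test_weak_coupling_ax_follows_cos_pi_j_te(self, acq):
        # AX pair with shift difference >> J: in-phase amplitude modulates
        # as cos(pi J TE) regardless of the multi-pulse echo structure
        j = 10.0
        ax = SpinSystem("AX", (-6.0, 14.0), ((0.0, j), (j, 0.0)), ("A", "X"), (1, 1))
        for te in (40.0, 60.0, 90.0, 120.0, 144.0):
            s = simulate_fid(ax, SequenceTiming(te=te), acq)
            expected = 2 * np.cos(np.pi * j * te * 1e-3)
            assert s.fid[0].real == pytest.approx(expected, abs=2 * 0.02)

    def test_subsystem_size_cap_raises(self, acq):
        val = load_spin_system("Val")  # 8-spin coupled block
        with pytest.raises(ValueError, match="exceeds"):
            simulate_fid(val, SequenceTiming(te=120.0), acq, max_subsystem_spins=6)

    def test_spectrum_is_fft_of_fid(self, acq):
        s = simulate_fid(load_spin_system("Lac"), SequenceTiming(te=120.0), acq)
        np.testing.assert_allclose(
            s.spectrum, np.fft.fftshift(np.fft.fft(s.fid)), atol=1e-9)
        assert np.all(np.diff(s.ppm_axis) > 0)


class TestSpectrumFromFid:
    def test_zero_broadening_is_invertible(self, acq):
        rng = np.random.default_rng(0)
        fid = rng.standard_normal(acq.n_points) + 1j * rng.standard_normal(acq.n_points)
        spec = spectrum_from_fid(fid, acq)
        back = np.fft.ifft(np.fft.ifftshift(spec.spectrum))
        np.testing.assert_allclose(back, fid, atol=1e-10)

    def test_singlet_lands_on_its_shift(self, acq):
        s = simulate_fid(load_spin_system("Cr"), SequenceTiming(te=120.0), acq)
        spec = spectrum_from_fid(s.fid, acq, LineShape(lorentz_hz=3.0))
        peak_ppm = spec.ppm_axis[np.argmax(spec.spectrum.real)]
        bin_w = np.diff(spec.ppm_axis).mean()
        assert abs(peak_ppm - 3.027) <= bin_w

    def test_lorentzian_broadening_sets_fwhm(self, acq):
        gamma = 4.0
        s = simulate_fid(load_spin_system("Cr"), SequenceTiming(te=120.0), acq)
        spec = spectrum_from_fid(s.fid, acq, LineShape(lorentz_hz=gamma))
        # measure FWHM of the 3.03 ppm singlet with sub-bin interpolation
        ax = spec.ppm_axis
        sel = (ax > 2.8) & (ax < 3.25)
        x, y = ax[sel], spec.spectrum.real[sel]
        half = y.max() / 2
        above = np.flatnonzero(y >= half)
        i0, i1 = above[0], above[-1]
        left = np.interp(half, [y[i0 - 1], y[i0]], [x[i0 - 1], x[i0]])
        right = np.interp(half, [y[i1 + 1], y[i1]], [x[i1 + 1], x[i1]])
        assert right - left == pytest.approx(gamma / acq.larmor_freq, rel=0.10)

    def test_empty_fid_rejected(self, acq):
        with pytest.raises(ValueError):
            spectrum_from_fid(np.array([]), acq)


class TestBasisSet:
    def test_structure_and_determinism(self, basis_small, acq):
        assert set(basis_small.entries) == {"Glu", "Gln", "Cr"}
        again = make_basis_set(["Glu", "Gln", "Cr"], 120.0, acq)
        for m in basis_small.entries:
            np.testing.assert_array_equal(
                basis_small.entries[m].fid, again.entries[m].fid)

    def test_coupled_entries_differ_between_tes(self, basis_te40, basis_te120):
        for m in basis_te40.entries:
            a, b = basis_te40.entries[m].fid, basis_te120.entries[m].fid
            if np.all(load_spin_system(m).j_matrix == 0):
                np.testing.assert_allclose(a, b, atol=1e-10)
            else:
                assert not np.allclose(a, b)

    def test_total_spin_conservation_near_zero_te(self, acq):
        # integrated signal at TE -> 0+ matches proton count per metabolite
        timing = SequenceTiming(te=0.06, scheme="symmetric")
        for name in ("Glu", "Gln", "NAA", "mI"):
            sys_ = load_spin_system(name)
            s = simulate_fid(sys_, timing, acq)
            assert abs(s.fid[0]) == pytest.approx(sys_.n_protons, rel=0.01)


class TestSpectralDiagnostics:
    def test_pure_singlet_inphase_is_one(self, acq):
        s = simulate_fid(load_spin_system("Cr"), SequenceTiming(te=120.0), acq)
        spec = spectrum_from_fid(s.fid, acq, LineShape(lorentz_hz=2.0))
        assert inphase_fraction(spec, (2.9, 3.15)) == pytest.approx(1.0, abs=0.02)

    def test_antiphase_doublet_cancels(self, acq):
        # build a perfect anti-phase doublet directly in the time domain
        t = acq.time_axis()
        f = 100.0
        fid = np.exp(2j * np.pi * f * t) - np.exp(-2j * np.pi * f * t)
        spec = spectrum_from_fid(fid * np.exp(-np.pi * 2 * t), acq)
        lo = acq.ref_ppm - 2 * f / acq.larmor_freq
        hi = acq.ref_ppm + 2 * f / acq.larmor_freq
        assert inphase_fraction(spec, (lo, hi)) == pytest.approx(0.0, abs=1e-6)

    def test_glu_more_inphase_than_gln_at_te120(self, basis_te120, acq):
        ls = LineShape(1.5, 2.7)
        vals = {}
        for m in ("Glu", "Gln"):
            spec = spectrum_from_fid(basis_te120.entries[m].fid, acq, ls)
            vals[m] = inphase_fraction(spec, (2.0, 2.4))
        assert vals["Glu"] > vals["Gln"]

    def test_empty_band_rejected(self, basis_small, acq):
        spec = basis_small.entries["Cr"]
        with pytest.raises(ValueError):
            inphase_fraction(spec, (20.0, 21.0))

    def test_self_separability_is_one(self, acq):
        scan = te_separability_scan("Cr", "Cr", [120.0], acq)
        assert scan[120.0] == pytest.approx(1.0)

    def test_distant_singlets_separable(self, acq):
        scan = te_separability_scan("Cr", "Lac", [120.0], acq,
                                    LineShape(1.5, 2.7))
        # Cr 3.03/3.91 vs Lac 1.31/4.10: dominated by well-separated peaks
        assert scan[120.0] < 0.05

    def test_glu_gln_more_separable_at_120_than_40(self, acq):
        scan = te_separability_scan("Glu", "Gln", [40.0, 120.0], acq,
                                    LineShape(1.5, 2.7))
        assert scan[120.0] < scan[40.0]
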