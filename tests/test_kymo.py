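import numpy as np
import pytest

from nucleoforce import synth
from nucleoforce.kymo import (
    Kymograph,
    PsfModel,
    calibrate_psf,
    count_coverage,
    decompose_peaks,
    estimate_background,
    intensity_profile,
)


class TestIntensityProfile:
    def test_background_only_gives_zero_profile(self):
        km, _ = synth.simulate_kymograph([], background=4.0, n_lines=100, seed=0)
        _, prof = intensity_profile(km, window=6.0)
        assert prof.mean() == pytest.approx(0.0, abs=0.3)

    def test_single_monomer_area_matches_flux(self):
        km, _ = synth.simulate_kymograph(
            [(5000.0, 1)], photons_per_monomer_per_line=100.0, n_lines=100, seed=1
        )
        pos, prof = intensity_profile(km, window=6.0)
        near = np.abs(pos - 5000.0) <= 600.0  # +/- 4 sigma
        assert prof[near].sum() == pytest.approx(100.0, rel=0.10)

    def test_variance_shrinks_with_window(self):
        """Poisson averaging: longer windows give smoother profiles."""
        km, _ = synth.simulate_kymograph(
            [], background=20.0, n_lines=400, seed=2
        )
        devs = []
        for window in (1.0, 36.0):
            n = int(window / km.line_time)
            devs.append(np.var(km.photons[:n].mean(axis=0)))
        assert devs[1] < devs[0] / 10  # ~36x fewer per-pixel variance

    def test_empty_window_rejected(self):
        km, _ = synth.simulate_kymograph([], n_lines=10, seed=0)
        with pytest.raises(ValueError):
            intensity_profile(km, window=0.01)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            Kymograph(photons=np.array([[-1, 2]]))


class TestCalibratePsf:
    def test_recovers_known_sigma(self, monomer_psf_calibration):
        # generator PSF sigma is 150 nm
        assert monomer_psf_calibration.sigma == pytest.approx(150.0, rel=0.05)
        assert monomer_psf_calibration.unit_area == pytest.approx(100.0, rel=0.05)

    def test_noiseless_gaussian_exact(self):
        x = np.arange(0, 10800.0, 75.0)
        prof = 100.0 * 75.0 * np.exp(-0.5 * ((x - 5000) / 150.0) ** 2) / (
            150.0 * np.sqrt(2 * np.pi)
        )
        psf = calibrate_psf([(x, prof)] * 50, n_molecules=5)
        assert psf.sigma == pytest.approx(150.0, rel=1e-3)

    def test_too_few_profiles_rejected(self):
        x = np.arange(0, 750.0, 75.0)
        with pytest.raises(ValueError, match="insufficient"):
            calibrate_psf([(x, np.ones_like(x))] * 10, n_molecules=5)


class TestDecomposePeaks:
    def test_dimer_area_quantized_to_two(self, monomer_psf_calibration):
        km, _ = synth.simulate_kymograph(
            [(5000.0, 2)], photons_per_monomer_per_line=100.0, n_lines=100, seed=11
        )
        pos, prof = intensity_profile(km, window=6.0)
        (peak,) = decompose_peaks(pos, prof, monomer_psf_calibration)
        assert peak.apparent_oligomer == 2

    def test_resolved_monomers_positioned_within_half_pixel(
        self, monomer_psf_calibration
    ):
        # two monomers 3 sigma apart: resolvable, positions within ~pixel/2
        km, _ = synth.simulate_kymograph(
            [(4000.0, 1), (4450.0, 1)],
            photons_per_monomer_per_line=100.0,
            n_lines=100,
            seed=12,
        )
        pos, prof = intensity_profile(km, window=6.0)
        peaks = decompose_peaks(pos, prof, monomer_psf_calibration)
        assert [p.apparent_oligomer for p in peaks] == [1, 1]
        assert abs(peaks[0].position - 4000.0) <= 37.5 + 1e-9
        assert abs(peaks[1].position - 4450.0) <= 37.5 + 1e-9

    def test_fully_overlapping_monomers_appear_as_dimer(
        self, monomer_psf_calibration
    ):
        # diffraction limit: co-located monomers are one apparent dimer
        km, _ = synth.simulate_kymograph(
            [(5000.0, 1), (5000.0, 1)],
            photons_per_monomer_per_line=100.0,
            n_lines=100,
            seed=13,
        )
        pos, prof = intensity_profile(km, window=6.0)
        (peak,) = decompose_peaks(pos, prof, monomer_psf_calibration)
        assert peak.apparent_oligomer == 2

    def test_intensity_conservation(self, monomer_psf_calibration):
        km, _ = synth.simulate_kymograph(
            [(2000.0, 1), (5000.0, 3)],
            photons_per_monomer_per_line=100.0,
            n_lines=100,
            seed=14,
        )
        pos, prof = intensity_profile(km, window=6.0)
        peaks = decompose_peaks(pos, prof, monomer_psf_calibration)
        dx = pos[1] - pos[0]
        assert sum(p.area for p in peaks) == pytest.approx(
            prof.sum(), rel=0.15
        )


class TestCountCoverage:
    def test_empty(self):
        assert count_coverage([]) == (0, 0.0)

    def test_seven_bound_proteins_recovered(self, monomer_psf_calibration):
        """A low-coverage construct: 2+1+1+3 emitters counted as 7."""
        km, _ = synth.simulate_kymograph(
            [(1500.0, 2), (3000.0, 1), (4500.0, 1), (6000.0, 3)],
            photons_per_monomer_per_line=100.0,
            n_lines=100,
            seed=5,
        )
        pos, prof = intensity_profile(km, window=6.0)
        peaks = decompose_peaks(pos, prof, monomer_psf_calibration)
        count, _ = count_coverage(peaks)
        assert count == 7

    def test_doubling_emitters_doubles_coverage(self, monomer_psf_calibration):
        counts = []
        for mult, seed in [(1, 21), (2, 22)]:
            km, _ = synth.simulate_kymograph(
                [(2000.0, mult), (5000.0, 2 * mult)],
                photons_per_monomer_per_line=100.0,
                n_lines=100,
                seed=seed,
            )
            pos, prof = intensity_profile(km, window=6.0)
            counts.append(count_coverage(decompose_peaks(pos, prof,
                                                         monomer_psf_calibration))[0])
        assert counts[1] == 2 * counts[0]


def test_background_estimated_from_flanks():
    km, _ = synth.simulate_kymograph(
        [(5000.0, 3)], background=7.0, n_lines=200, seed=30
    )
    assert estimate_background(km) == pytest.approx(7.0, abs=1.0)
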