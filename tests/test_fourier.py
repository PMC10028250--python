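"""Fourier decomposition and affine superimposition (FCAS) tests.

Expected coefficient values are computed with an independent oracle:
direct numerical integration of the synthesis convention's projection
integral, rather than the FFT path under test.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaitscreen import fourier
from gaitscreen.fourier import (
    AMPLITUDE_EPS,
    ANALYSIS_JOINTS,
    DegenerateAmplitudeError,
    FourierRepresentation,
    align_cycles,
    amplitude_of,
    coordination_residual,
    decompose,
    extract_affine,
    phase_of,
    phase_preserving_average,
    reconstruct,
    shift_phase,
)

GRID = np.arange(100) / 100


def oracle_coefficient(x: np.ndarray, n: int) -> complex:
    """Projection integral c_n = (1/T) sum x(t) e^{-i 2 pi n t} dt on the grid."""
    t = np.arange(len(x)) / len(x)
    return complex(np.mean(x * np.exp(-2j * np.pi * n * t)))


def random_bandlimited(rng, n_harmonics=8, n_samples=100):
    c = np.zeros(n_harmonics + 1, dtype=complex)
    c[0] = rng.normal()
    c[1:] = rng.normal(size=n_harmonics) + 1j * rng.normal(size=n_harmonics)
    return reconstruct(c, n_samples), c


class TestDecompose:
    def test_constant_profile(self):
        c = decompose(np.full(100, 1.7))
        assert c[0] == pytest.approx(1.7)
        assert np.abs(c[1:]).max() < 1e-14

    def test_pure_cosine_matches_convention(self):
        c = decompose(np.cos(2 * np.pi * GRID))
        assert c[1] == pytest.approx(0.5 + 0j, abs=1e-12)
        assert np.abs(np.delete(c, 1)).max() < 1e-12

    def test_matches_numerical_integration_oracle(self, rng):
        x, _ = random_bandlimited(rng)
        c = decompose(x)
        for n in range(9):
            assert c[n] == pytest.approx(oracle_coefficient(x, n), abs=1e-10)

    def test_c0_is_temporal_mean(self, rng):
        x = rng.normal(size=100)
        assert decompose(x)[0].real == pytest.approx(x.mean())

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="samples"):
            decompose(np.zeros(16), n_harmonics=8)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_bandlimited_round_trip_and_parseval(self, seed):
        rng = np.random.default_rng(seed)
        x, _ = random_bandlimited(rng)
        c = decompose(x)
        assert np.abs(reconstruct(c, 100) - x).max() < 1e-10
        # Parseval under the one-sided convention: var(x) = 2 sum |c_n|^2
        assert x.var() == pytest.approx(2 * (np.abs(c[1:]) ** 2).sum(), abs=1e-10)


class TestReconstruct:
    def test_zero_coefficients(self):
        assert np.all(reconstruct(np.zeros(9, dtype=complex), 50) == 0)

    def test_constant_term_only(self):
        c = np.zeros(9, dtype=complex)
        c[0] = 1.0
        assert np.allclose(reconstruct(c, 50), 1.0)


class TestAffineExtraction:
    @pytest.mark.parametrize("a,b,phi", [(0.3, 1.0, 0.0), (-0.5, 0.4, 0.25), (1.2, 2.0, 0.7)])
    def test_shifted_cosine_components(self, a, b, phi):
        # x(t) = a + b cos(2 pi (t - phi)): mean a, energy amplitude b/2, phase phi
        x = a + b * np.cos(2 * np.pi * (GRID - phi))
        rep = FourierRepresentation.from_profiles({"forelimb_total": x, "shoulder": x})
        comps, norm = extract_affine(rep)
        assert comps.mean["shoulder"] == pytest.approx(a, abs=1e-10)
        assert comps.amplitude["shoulder"] == pytest.approx(b / 2, abs=1e-10)
        assert comps.phase == pytest.approx(phi % 1.0, abs=1e-10)
        # normalized: zero mean, unit amplitude, zero phase
        assert norm.coeffs["shoulder"][0] == 0
        assert amplitude_of(norm.coeffs["shoulder"]) == pytest.approx(1.0)
        wrapped = (phase_of(norm.coeffs["forelimb_total"]) + 0.5) % 1.0 - 0.5
        assert wrapped == pytest.approx(0.0, abs=1e-10)

    def test_already_normalized_is_identity(self):
        x = np.cos(2 * np.pi * GRID)
        rep = FourierRepresentation.from_profiles({"forelimb_total": x})
        _, norm1 = extract_affine(rep)
        _, norm2 = extract_affine(norm1)
        np.testing.assert_allclose(norm1.coeffs["forelimb_total"], norm2.coeffs["forelimb_total"], atol=1e-12)

    def test_time_shifted_copies_same_normalization(self, rng):
        x, c = random_bandlimited(rng)
        rep1 = FourierRepresentation(coeffs={"forelimb_total": c.copy()})
        rep2 = FourierRepresentation(coeffs={"forelimb_total": shift_phase(c, 0.3)})
        p1 = phase_of(rep1.coeffs["forelimb_total"])
        p2 = phase_of(rep2.coeffs["forelimb_total"])
        assert (p1 - p2) % 1.0 == pytest.approx(0.3, abs=1e-10)
        _, n1 = extract_affine(rep1)
        _, n2 = extract_affine(rep2)
        np.testing.assert_allclose(n1.coeffs["forelimb_total"], n2.coeffs["forelimb_total"], atol=1e-9)

    def test_degenerate_reference_raises(self):
        rep = FourierRepresentation.from_profiles({"forelimb_total": np.full(100, 0.2)})
        with pytest.raises(DegenerateAmplitudeError, match="phase"):
            extract_affine(rep)


def _stride_rep(rng, phase=0.0):
    """A stride with all seven angles as random band-limited profiles."""
    coeffs = {}
    for joint in ANALYSIS_JOINTS + ("forelimb_total",):
        _, c = random_bandlimited(rng)
        coeffs[joint] = shift_phase(c, -phase)
    return FourierRepresentation(coeffs=coeffs)


class TestAlignment:
    def test_destructive_interference_repair(self):
        # identical sines half a cycle apart: pointwise mean vanishes,
        # phase-aligned mean keeps the full amplitude
        x1 = np.sin(2 * np.pi * GRID)
        x2 = np.sin(2 * np.pi * (GRID - 0.5))
        assert np.abs((x1 + x2) / 2).max() < 1e-12
        avg = phase_preserving_average([x1, x2])
        assert (avg.max() - avg.min()) / 2 == pytest.approx(1.0, abs=1e-6)

    def test_single_stride_alignment_is_identity(self, rng):
        rep = _stride_rep(rng)
        aligned, phases = align_cycles([rep])
        for joint in rep.coeffs:
            np.testing.assert_allclose(aligned[0].coeffs[joint], rep.coeffs[joint], atol=1e-12)
        assert phases[0] == pytest.approx(phase_of(rep.coeffs["forelimb_total"]))

    def test_alignment_preserves_amplitude_spectra(self, rng):
        reps = [_stride_rep(rng, phase=p) for p in (0.0, 0.2, 0.8)]
        aligned, _ = align_cycles(reps)
        for before, after in zip(reps, aligned):
            for joint in before.coeffs:
                np.testing.assert_allclose(
                    np.abs(before.coeffs[joint]), np.abs(after.coeffs[joint]), atol=1e-12
                )

    def test_alignment_idempotent(self, rng):
        reps = [_stride_rep(rng, phase=p) for p in (0.1, 0.4, 0.9)]
        once, _ = align_cycles(reps)
        twice, _ = align_cycles(once)
        for a, b in zip(once, twice):
            for joint in a.coeffs:
                np.testing.assert_allclose(a.coeffs[joint], b.coeffs[joint], atol=1e-10)

    def test_degenerate_stride_excluded(self, rng):
        good = _stride_rep(rng)
        flat = FourierRepresentation.from_profiles(
            {j: np.full(100, 0.1) for j in ANALYSIS_JOINTS + ("forelimb_total",)}
        )
        aligned, phases = align_cycles([good, flat])
        assert len(aligned) == 1
        assert np.isnan(phases[1])


class TestCoordination:
    def test_vector_length_96(self, rng):
        vec = coordination_residual(_stride_rep(rng))
        assert vec.shape == (96,)

    def test_affine_invariance(self, rng):
        """Defining FCAS contract: per-joint offset and scale plus a global
        time shift leave the coordination vector unchanged."""
        rep = _stride_rep(rng)
        base = coordination_residual(rep)
        for _ in range(5):
            shift = rng.uniform(0, 1)
            transformed = {}
            for joint, c in rep.coeffs.items():
                cc = c.copy()
                cc[0] += rng.normal()  # mean offset
                cc[1:] *= rng.uniform(0.3, 3.0)  # amplitude scale
                transformed[joint] = shift_phase(cc, shift)  # whole-stride shift
            vec = coordination_residual(FourierRepresentation(coeffs=transformed))
            assert np.abs(vec - base).max() < 1e-8

    def test_in_phase_first_harmonics_have_zero_imaginary_part(self):
        coeffs = {}
        for joint in ANALYSIS_JOINTS + ("forelimb_total",):
            c = np.zeros(9, dtype=complex)
            c[1] = 0.4  # pure first harmonic, in phase with the reference
            coeffs[joint] = c
        vec = coordination_residual(FourierRepresentation(coeffs=coeffs))
        vec = vec.reshape(6, 16)  # per joint: 8 real then 8 imaginary
        assert np.abs(vec[:, 8]).max() < 1e-12  # Im of harmonic 1
        np.testing.assert_allclose(vec[:, 0], 1.0)  # Re of harmonic 1, unit amp

    def test_degenerate_joint_contributes_zeros(self, rng):
        rep = _stride_rep(rng)
        rep.coeffs["carpal"][1:] = 0.0
        vec = coordination_residual(rep).reshape(6, 16)
        assert np.all(vec[ANALYSIS_JOINTS.index("carpal")] == 0)


class TestPhasePreservingAverage:
    def test_identical_profiles_average_to_themselves(self, rng):
        x, _ = random_bandlimited(rng)
        np.testing.assert_allclose(phase_preserving_average([x, x, x]), x, atol=1e-10)

    def test_random_phase_copies_keep_amplitude(self, rng):
        base, c = random_bandlimited(rng)
        amp = amplitude_of(c)
        shifted = [reconstruct(shift_phase(c, rng.uniform(0, 1)), 100) for _ in range(8)]
        avg = phase_preserving_average(shifted)
        assert amplitude_of(decompose(avg)) == pytest.approx(amp, rel=1e-8)
        naive = np.mean(shifted, axis=0)
        assert amplitude_of(decompose(naive)) < 0.8 * amp  # attenuation it avoids

    def test_degenerate_falls_back_with_warning(self):
        flat = np.full(100, 0.3)
        with pytest.warns(UserWarning, match="degenerate"):
            avg = phase_preserving_average([flat, flat])
        np.testing.assert_allclose(avg, flat, atol=AMPLITUDE_EPS)
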