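"""Fourier Series decomposition and Fourier Coefficient Affine Superimposition.

A cyclic joint-angle profile x(t), t in [0, 1), is represented by one-sided
complex harmonic coefficients c_0..c_N (N = 8 by default)::

    x(t) = c_0 + sum_{n=1..N} 2 * Re(c_n * exp(i * 2*pi * n * t))

so that c_0 is the temporal mean and, for a single harmonic of peak
amplitude b, |c_1| = b / 2.  In the frequency domain the affine components
of a profile are directly accessible:

* mean      = c_0
* amplitude = sqrt(sum_{n>=1} |c_n|^2)   (harmonic energy norm; for a pure
  first harmonic of peak amplitude b this equals b/2)
* phase     = -arg(c_1) / 2*pi of a designated reference profile, as a
  cycle fraction in [0, 1)

Removing mean and amplitude per joint and rotating all harmonics by the
single reference phase (a whole-stride time shift) leaves the "coordination"
residual: the precise temporal succession of joint configurations, invariant
under affine transformation of the input profiles.  Averaging in the
frequency domain after phase alignment avoids the destructive-interference
artifact of naive pointwise averaging of phase-shifted cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Analysis joints in canonical order.
ANALYSIS_JOINTS: tuple[str, ...] = ("shoulder", "elbow", "carpal", "hip", "stifle", "tarsal")

#: Reference angle used for temporal alignment (it does not enter the analysis).
REFERENCE_JOINT = "forelimb_total"

DEFAULT_N_HARMONICS = 8

#: Amplitude below which a phase is considered undefined (radians).
AMPLITUDE_EPS = 1e-6


class DegenerateAmplitudeError(ValueError):
    """Reference amplitude too small: phase undefined."""


def decompose(profile: np.ndarray, n_harmonics: int = DEFAULT_N_HARMONICS) -> np.ndarray:
    """Fourier Series decomposition of one uniformly sampled cyclic profile.

    Returns the complex coefficient array ``c[0..n_harmonics]`` under the
    module's synthesis convention.  Requires ``len(profile) > 2*n_harmonics``.
    """
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1:
        raise ValueError("profile must be 1-D")
    n = x.size
    if n <= 2 * n_harmonics:
        raise ValueError(f"need more than {2 * n_harmonics} samples for {n_harmonics} harmonics, got {n}")
    c = np.fft.rfft(x) / n
    out = np.zeros(n_harmonics + 1, dtype=complex)
    k = min(n_harmonics + 1, c.size)
    out[:k] = c[:k]
    out[0] = out[0].real
    return out


def reconstruct(coeffs: np.ndarray, n_samples: int = 100) -> np.ndarray:
    """Evaluate the synthesis formula on a uniform grid of ``n_samples``."""
    c = np.asarray(coeffs, dtype=complex)
    t = np.arange(n_samples) / n_samples
    n = np.arange(1, c.size)
    x = np.full(n_samples, c[0].real)
    x += 2.0 * np.real(c[1:][None, :] * np.exp(2j * np.pi * n[None, :] * t[:, None])).sum(axis=1)
    return x


def amplitude_of(coeffs: np.ndarray) -> float:
    """Harmonic energy amplitude sqrt(sum_{n>=1} |c_n|^2)."""
    c = np.asarray(coeffs, dtype=complex)
    return float(np.sqrt((np.abs(c[1:]) ** 2).sum()))


def phase_of(coeffs: np.ndarray) -> float:
    """First-harmonic phase as a cycle fraction in [0, 1).

    For x(t) = cos(2*pi*(t - phi)) this returns phi (mod 1).
    """
    c = np.asarray(coeffs, dtype=complex)
    if amplitude_of(c) <= AMPLITUDE_EPS or abs(c[1]) == 0.0:
        raise DegenerateAmplitudeError("amplitude too small: phase undefined")
    return float((-np.angle(c[1]) / (2 * np.pi)) % 1.0)


def shift_phase(coeffs: np.ndarray, delta: float) -> np.ndarray:
    """Advance a profile by ``delta`` cycle fractions (time shift).

    ``shift_phase(decompose(x), d)`` equals ``decompose(x(t + d))``:
    c_n <- c_n * exp(+i * 2*pi * n * d).  Moduli |c_n| are unchanged.
    """
    c = np.asarray(coeffs, dtype=complex).copy()
    n = np.arange(c.size)
    return c * np.exp(2j * np.pi * n * delta)


@dataclass
class FourierRepresentation:
    """Per-joint harmonic coefficients of one stride cycle.

    ``coeffs`` maps joint name -> complex array c_0..c_N.  The reference
    angle (total forelimb, croup-withers-forehoof) is carried alongside the
    six analysis joints and is only used for temporal alignment.
    """

    coeffs: dict[str, np.ndarray]
    n_harmonics: int = DEFAULT_N_HARMONICS
    meta: dict = field(default_factory=dict)

    @classmethod
    def from_profiles(cls, profiles: dict[str, np.ndarray], n_harmonics: int = DEFAULT_N_HARMONICS, **meta) -> "FourierRepresentation":
        return cls(
            coeffs={name: decompose(p, n_harmonics) for name, p in profiles.items()},
            n_harmonics=n_harmonics,
            meta=dict(meta),
        )

    def copy(self) -> "FourierRepresentation":
        return FourierRepresentation(
            coeffs={k: v.copy() for k, v in self.coeffs.items()},
            n_harmonics=self.n_harmonics,
            meta=dict(self.meta),
        )

    def profiles(self, n_samples: int = 100) -> dict[str, np.ndarray]:
        return {name: reconstruct(c, n_samples) for name, c in self.coeffs.items()}


@dataclass
class AffineComponents:
    """Mean, amplitude and (reference) phase extracted from one stride."""

    mean: dict[str, float]
    amplitude: dict[str, float]
    phase: float  # reference phase, cycle fraction in [0, 1)


def extract_affine(
    rep: FourierRepresentation,
    reference_joint: str = REFERENCE_JOINT,
    eps: float = AMPLITUDE_EPS,
) -> tuple[AffineComponents, FourierRepresentation]:
    """Isolate affine components and return the normalized representation.

    The normalized representation has, per joint, zero mean (c_0 = 0) and
    unit energy amplitude, and all joints rotated by the single reference
    phase (a whole-stride time shift): c_n <- c_n * exp(+i*2*pi*n*phi_ref).
    Joints with amplitude <= eps are left at zero and recorded in
    ``meta['degenerate_joints']``.
    """
    if reference_joint not in rep.coeffs:
        raise KeyError(f"reference joint {reference_joint!r} not in representation")
    ref_c = rep.coeffs[reference_joint]
    if amplitude_of(ref_c) <= eps:
        raise DegenerateAmplitudeError(f"reference joint {reference_joint!r} amplitude <= {eps}: phase undefined")
    phi = phase_of(ref_c)

    means: dict[str, float] = {}
    amps: dict[str, float] = {}
    norm_coeffs: dict[str, np.ndarray] = {}
    degenerate: list[str] = []
    for name, c in rep.coeffs.items():
        means[name] = float(c[0].real)
        a = amplitude_of(c)
        amps[name] = a
        cc = shift_phase(c, phi)
        cc[0] = 0.0
        if a > eps:
            cc[1:] = cc[1:] / a
        else:
            cc[1:] = 0.0
            degenerate.append(name)
        norm_coeffs[name] = cc
    normalized = FourierRepresentation(
        coeffs=norm_coeffs,
        n_harmonics=rep.n_harmonics,
        meta={**rep.meta, "normalized": True, "reference_phase": phi, "degenerate_joints": degenerate},
    )
    return AffineComponents(mean=means, amplitude=amps, phase=phi), normalized


def circular_mean_phase(phases) -> float:
    """Circular mean of cycle-fraction phases, in [0, 1)."""
    ph = np.asarray(list(phases), dtype=float)
    z = np.exp(2j * np.pi * ph).mean()
    if abs(z) < 1e-12:
        return 0.0
    return float((np.angle(z) / (2 * np.pi)) % 1.0)


def align_cycles(
    reps: list[FourierRepresentation],
    reference_joint: str = REFERENCE_JOINT,
    eps: float = AMPLITUDE_EPS,
) -> tuple[list[FourierRepresentation], np.ndarray]:
    """Temporally align a set of strides on the reference angle's phase.

    Every stride is time-shifted (all joints rotated together) so that its
    reference phase equals the set's circular-mean phase.  Amplitude
    spectra are untouched (the rotation has unit modulus).  Strides with a
    degenerate reference are excluded; their phase entry is NaN.

    Returns (aligned representations, original phases).
    """
    phases = np.full(len(reps), np.nan)
    usable: list[int] = []
    for i, rep in enumerate(reps):
        try:
            phases[i] = phase_of(rep.coeffs[reference_joint])
            usable.append(i)
        except DegenerateAmplitudeError:
            continue
    if not usable:
        raise DegenerateAmplitudeError("no stride with a usable reference phase")
    target = circular_mean_phase(phases[usable])
    aligned: list[FourierRepresentation] = []
    for i in usable:
        rep = reps[i]
        delta = phases[i] - target  # advance by delta moves phase phi -> phi - delta
        out = rep.copy()
        for name in out.coeffs:
            out.coeffs[name] = shift_phase(out.coeffs[name], delta)
        out.meta = {**out.meta, "alignment_shift": float(delta), "aligned_phase": target}
        aligned.append(out)
    return aligned, phases


def coordination_residual(
    rep: FourierRepresentation,
    joints: tuple[str, ...] = ANALYSIS_JOINTS,
    reference_joint: str = REFERENCE_JOINT,
    eps: float = AMPLITUDE_EPS,
) -> np.ndarray:
    """The coordination vector of one stride: 96 real values.

    After mean removal, per-joint amplitude normalization and rotation by
    the reference phase (all done here if the representation is not already
    normalized), the real and imaginary parts of harmonics 1..N of the six
    analysis joints are concatenated joint by joint:
    ``[Re c_1..c_N, Im c_1..c_N]`` per joint.  With N = 8 harmonics the
    vector has 6 * 8 * 2 = 96 entries.  A joint with degenerate amplitude
    contributes zeros.
    """
    if not rep.meta.get("normalized"):
        _, rep = extract_affine(rep, reference_joint=reference_joint, eps=eps)
    parts: list[np.ndarray] = []
    for name in joints:
        if name not in rep.coeffs:
            raise KeyError(f"joint {name!r} missing from representation")
        c = rep.coeffs[name][1:]
        parts.append(np.concatenate([c.real, c.imag]))
    return np.concatenate(parts)


def coordination_labels(
    joints: tuple[str, ...] = ANALYSIS_JOINTS, n_harmonics: int = DEFAULT_N_HARMONICS
) -> list[str]:
    """Column labels matching :func:`coordination_residual` ordering."""
    labels = []
    for j in joints:
        labels += [f"{j}_re{n}" for n in range(1, n_harmonics + 1)]
        labels += [f"{j}_im{n}" for n in range(1, n_harmonics + 1)]
    return labels


def phase_preserving_average(
    profiles: list[np.ndarray],
    n_harmonics: int = DEFAULT_N_HARMONICS,
    n_samples: int | None = None,
    align: bool = True,
) -> np.ndarray:
    """Average cyclic profiles of one joint without amplitude loss.

    Naive pointwise averaging of phase-shifted cycles attenuates the
    common shape — two antiphase sines cancel exactly, as in destructive
    interference.  Here each profile is decomposed, shifted to the set's
    circular-mean phase, averaged coefficient-wise in the frequency domain
    and transformed back, so the shared amplitude is conserved while mean
    angle and phase are averaged.  With ``align=False`` this degrades to
    the naive frequency-domain (= pointwise) mean.

    Falls back to the arithmetic mean with a warning when the profiles have
    degenerate amplitude (no phase to align).
    """
    import warnings

    if len(profiles) == 0:
        raise ValueError("need at least one profile")
    if n_samples is None:
        n_samples = len(profiles[0])
    reps = [decompose(np.asarray(p, dtype=float), n_harmonics) for p in profiles]
    if align:
        try:
            phases = [phase_of(c) for c in reps]
        except DegenerateAmplitudeError:
            warnings.warn("degenerate amplitude: falling back to arithmetic mean", stacklevel=2)
            return np.mean([reconstruct(c, n_samples) for c in reps], axis=0)
        target = circular_mean_phase(phases)
        reps = [shift_phase(c, ph - target) for c, ph in zip(reps, phases)]
    mean_c = np.mean(reps, axis=0)
    mean_c[0] = np.mean([c[0].real for c in reps])  # mean angle: arithmetic mean of means
    return reconstruct(mean_c, n_samples)
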