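"""Fourier outline descriptors with full invariance normalization.

The closed outline signal ``z = <z_0 ... z_{N-1}>``, ``z_l = x_l + i*y_l``,
is mapped to the frequency domain by the (unnormalized) DFT

    Z_m = sum_l z_l exp(-i 2*pi*l*m / N),   m = -N/2 ... N/2 - 1,

written ``Z_m = R_m exp(i*theta_m)``.  The coefficients are then modified
so that the descriptor no longer depends on where the shape sits, how big
it is, how it is rotated, or where the boundary parameterization starts:

==============  =======================================================
translation     Zhat_0 = 0              (only Z_0 carries position)
scale           Rhat_m = R_m / R_1      (all moduli scale together)
rotation +      thetahat_m = theta_m - (theta_{-1} + theta_1)/2
start point                    + m * (theta_{-1} - theta_1)/2
==============  =======================================================

The combined phase rule cancels both a global rotation ``exp(i*theta_0)``
and a starting-point shift of ``l_0`` positions, whose joint effect on the
phases is ``theta'_m = theta_m + theta_0 - 2*pi*l_0*m/N``.

Phases are principal arguments in (-pi, pi].  Worked with principal
values, the phase rule leaves one residual half-turn ambiguity: the
normalized coefficient sets {Zhat_m} and {(-1)^(m+1) Zhat_m} (a flip of
the even-index coefficients, equivalent to rotating the shape by pi while
shifting the start by N/2) describe the same shape.  The package resolves
it with a fixed convention: if the real part of the strongest even-index
coefficient is negative, the even-index coefficients are negated, making
normalization a deterministic function of the shape.

Dimensionality reduction keeps only the ``M`` (``M << N``) coefficients
closest to frequency zero, with ``M`` chosen from the retained-energy
curve ``E(M)/E(N)`` where

    E(M) = sum_{m=-M/2, m != 0}^{M/2-1} |Z_m|^2 .

The inverse DFT of the truncated normalized coefficients yields the
canonical (normalized, smoothed) outline used for feature extraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SpectralCoefficients",
    "NormalizedDescriptor",
    "EnergySelection",
    "DegenerateShapeError",
    "dft",
    "normalize",
    "energy",
    "select_m",
    "truncate",
    "reconstruct",
]


class DegenerateShapeError(ValueError):
    """Normalization is undefined (the fundamental modulus R_1 is zero)."""


@dataclass
class SpectralCoefficients:
    """DFT coefficients of an outline signal.

    ``Z`` holds the complex coefficients in index order
    ``m = -N/2 ... N/2 - 1``; ``N`` is the signal period.
    """

    Z: np.ndarray
    N: int

    @property
    def m_values(self) -> np.ndarray:
        return np.arange(-self.N // 2, self.N // 2)

    def coeff(self, m: int) -> complex:
        """Coefficient ``Z_m`` for ``m`` in ``[-N/2, N/2 - 1]``."""
        if not -self.N // 2 <= m <= self.N // 2 - 1:
            raise IndexError(f"m={m} outside [-N/2, N/2-1]")
        return complex(self.Z[m + self.N // 2])

    @property
    def modules(self) -> np.ndarray:
        """Moduli ``R_m = |Z_m|``."""
        return np.abs(self.Z)

    @property
    def arguments(self) -> np.ndarray:
        """Principal arguments ``theta_m`` (``arg 0`` taken as 0)."""
        return np.angle(self.Z)


@dataclass
class NormalizedDescriptor:
    """Truncated invariance-normalized coefficients.

    ``Zhat`` holds ``m = -M/2 ... M/2 - 1``; ``retained_energy_fraction``
    is ``E(M)/E(N)`` of the source coefficients.
    """

    Zhat: np.ndarray
    M: int
    retained_energy_fraction: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "M": self.M,
                "retained_energy_fraction": self.retained_energy_fraction,
                "coefficients": [[c.real, c.imag] for c in self.Zhat],
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "NormalizedDescriptor":
        obj = json.loads(text)
        z = np.array([complex(re, im) for re, im in obj["coefficients"]])
        return cls(Zhat=z, M=int(obj["M"]),
                   retained_energy_fraction=float(obj["retained_energy_fraction"]))


def dft(signal: Sequence[complex]) -> SpectralCoefficients:
    """Forward DFT of an outline signal, indexed ``m = -N/2 ... N/2 - 1``.

    Unnormalized convention: ``Z_m = sum_l z_l exp(-i 2 pi l m / N)``.
    ``N`` must be even and at least 4.
    """
    z = np.asarray(signal, dtype=complex)
    n = len(z)
    if n < 4 or n % 2 != 0:
        raise ValueError("signal period must be even and >= 4")
    if not np.all(np.isfinite(z)):
        raise ValueError("signal contains non-finite values")
    # fftshift reorders the standard FFT output to -N/2 ... N/2-1.
    return SpectralCoefficients(Z=np.fft.fftshift(np.fft.fft(z)), N=n)


def normalize(coeffs: SpectralCoefficients) -> SpectralCoefficients:
    """Apply translation, scale, rotation and starting-point normalization.

    Returns coefficients over the full index range; raises
    :class:`DegenerateShapeError` when ``R_1 = 0``.
    """
    n = coeffs.N
    half = n // 2
    r1 = abs(coeffs.coeff(1))
    if r1 == 0.0:
        raise DegenerateShapeError("R_1 = 0: shape has no fundamental harmonic")
    theta = coeffs.arguments
    t_plus = float(np.angle(coeffs.coeff(1)))
    t_minus = float(np.angle(coeffs.coeff(-1)))
    m = coeffs.m_values
    theta_hat = theta - (t_minus + t_plus) / 2.0 + m * (t_minus - t_plus) / 2.0
    zhat = (coeffs.modules / r1) * np.exp(1j * theta_hat)
    zhat[half] = 0.0  # translation invariance: drop the DC term
    # Half-turn convention: resolve the residual (-1)^(m+1) ambiguity by
    # fixing the sign of the real part of the strongest even-index
    # coefficient.  Moduli are transform-invariant, so the anchor choice
    # is stable; anchoring on a fixed index would misfire whenever that
    # coefficient happens to vanish for a shape.
    even = (m % 2 == 0) & (m != 0)
    anchor = int(np.argmax(np.where(even, np.abs(zhat), -1.0)))
    if zhat[anchor].real < 0.0:
        zhat[m % 2 == 0] *= -1.0
    return SpectralCoefficients(Z=zhat, N=n)


def energy(coeffs: SpectralCoefficients, m_keep: int) -> float:
    """Energy retained by the ``m_keep`` lowest-frequency coefficients.

    ``E(M) = sum |Z_m|^2`` over ``m = -M/2 ... M/2 - 1`` excluding
    ``m = 0``; the window is asymmetric by construction (one more
    negative than positive index).
    """
    n = coeffs.N
    if m_keep % 2 != 0 or not 2 <= m_keep <= n:
        raise ValueError("M must be even with 2 <= M <= N")
    half = n // 2
    window = coeffs.Z[half - m_keep // 2: half + m_keep // 2].copy()
    window[m_keep // 2] = 0.0  # exclude m = 0
    return float(np.sum(np.abs(window) ** 2))


@dataclass
class EnergySelection:
    """Result of retained-energy dimensionality selection.

    ``M`` is the selected dimensionality (power of two); ``candidate_m``
    and ``mean_energy_fraction`` give the averaged ``E(M)/E(N)`` curve for
    plotting; ``target_reached`` is False when even ``M = N`` falls short
    of the requested fraction.
    """

    M: int
    candidate_m: np.ndarray
    mean_energy_fraction: np.ndarray
    target_reached: bool


def select_m(collection: Iterable[SpectralCoefficients],
             energy_fraction: float) -> EnergySelection:
    """Choose the descriptor dimensionality from a coefficient collection.

    Finds the smallest even ``M`` whose mean retained-energy fraction
    ``E(M)/E(N)`` over the collection reaches ``energy_fraction``, then
    rounds up to the next power of two (and never below the descriptor
    minimum of 4).  All members must share the same period ``N``.
    """
    if not 0.0 < energy_fraction < 1.0:
        raise ValueError("energy_fraction must be in (0, 1)")
    coeffs = list(collection)
    if not coeffs:
        raise ValueError("empty coefficient collection")
    n = coeffs[0].N
    if any(c.N != n for c in coeffs):
        raise ValueError("all coefficient sets must share the same period N")
    candidates = np.arange(2, n + 1, 2)
    fractions = np.zeros(len(candidates))
    for c in coeffs:
        total = energy(c, n)
        if total == 0.0:
            raise DegenerateShapeError("signal with zero non-DC energy")
        fractions += np.array([energy(c, int(m)) for m in candidates]) / total
    fractions /= len(coeffs)
    reached = fractions >= energy_fraction
    if reached.any():
        raw = int(candidates[int(np.argmax(reached))])
        target_reached = True
    else:
        raw = n
        target_reached = False
    raw = max(raw, 4)
    m_pow2 = 1 << (raw - 1).bit_length()  # next power of two >= raw
    m_final = min(m_pow2, n)
    return EnergySelection(M=m_final, candidate_m=candidates,
                           mean_energy_fraction=fractions,
                           target_reached=target_reached)


def truncate(coeffs: SpectralCoefficients, m_keep: int) -> NormalizedDescriptor:
    """Keep the ``m_keep`` lowest-frequency normalized coefficients.

    ``coeffs`` is expected to be normalized already (see :func:`normalize`);
    indices ``m = -M/2 ... M/2 - 1`` are retained and the retained energy
    fraction ``E(M)/E(N)`` recorded.
    """
    n = coeffs.N
    if m_keep % 2 != 0 or not 4 <= m_keep <= n:
        raise ValueError("M must be even with 4 <= M <= N")
    half = n // 2
    window = coeffs.Z[half - m_keep // 2: half + m_keep // 2].copy()
    total = energy(coeffs, n)
    fraction = 1.0 if total == 0.0 else energy(coeffs, m_keep) / total
    return NormalizedDescriptor(Zhat=window, M=m_keep,
                                retained_energy_fraction=float(fraction))


def reconstruct(descriptor: NormalizedDescriptor) -> np.ndarray:
    """Inverse DFT of the truncated descriptor.

    Returns the canonical outline ``zhat_l = (1/M) sum_m Zhat_m
    exp(i 2 pi l m / M)`` for ``l = 0 ... M-1`` (period ``M``).
    """
    return np.fft.ifft(np.fft.ifftshift(descriptor.Zhat))
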