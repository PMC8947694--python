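"""Forward signal model for mono-exponential T2 decay under Rician noise.

A spin-echo magnitude image voxel decays as ``|S(TE)| = S0 * exp(-TE/T2)``.
Thermal noise enters the complex signal as independent zero-mean Gaussians of
standard deviation ``sigma`` in the real and imaginary channels, so measured
magnitudes follow a Rician distribution.  The Rician mean exceeds the
noise-free magnitude — the "noise floor" — which is what biases naive
least-squares fits at low SNR and what the noise-corrected fitter models
explicitly.

All echo times are in milliseconds throughout the package; signal amplitudes
are in arbitrary scanner units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special

__all__ = [
    "EchoTrain",
    "DecayParams",
    "mono_exp_signal",
    "add_rician_noise",
    "rician_expected_magnitude",
    "snr_of",
]

#: Permitted echo-train lengths.
N_MIN, N_MAX = 5, 15


@dataclass(frozen=True)
class EchoTrain:
    """Echo times and measured magnitudes for a single voxel/sample.

    Parameters
    ----------
    te
        Echo times in ms, strictly increasing, length 5-15.
    magnitude
        Non-negative measured signal magnitudes, same length as ``te``.
    """

    te: np.ndarray
    magnitude: np.ndarray

    def __post_init__(self) -> None:
        te = np.asarray(self.te, dtype=float)
        mag = np.asarray(self.magnitude, dtype=float)
        if te.ndim != 1 or mag.ndim != 1 or len(te) != len(mag):
            raise ValueError("te and magnitude must be 1-D and equally long")
        if not (N_MIN <= len(te) <= N_MAX):
            raise ValueError(f"echo train length must be in [{N_MIN}, {N_MAX}], got {len(te)}")
        if np.any(np.diff(te) <= 0):
            raise ValueError("echo times must be strictly increasing")
        if np.any(mag < 0):
            raise ValueError("magnitudes must be non-negative")
        object.__setattr__(self, "te", te)
        object.__setattr__(self, "magnitude", mag)

    def __len__(self) -> int:
        return len(self.te)


@dataclass(frozen=True)
class DecayParams:
    """True or estimated parameters of one mono-exponential decay.

    Attributes
    ----------
    s0
        Apparent proton density (signal at TE = 0), arbitrary units, >= 0.
    t2
        Transverse relaxation time in ms, > 0.
    sigma
        Per-channel Gaussian noise standard deviation, same units as s0.
    offset
        Additive constant; only meaningful for the offset decay model.
    """

    s0: float
    t2: float
    sigma: float = 0.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.s0 < 0:
            raise ValueError("s0 must be non-negative")
        if self.t2 <= 0:
            raise ValueError("t2 must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


def mono_exp_signal(params: DecayParams | tuple[float, float], te):
    """Noise-free mono-exponential magnitude ``S0 * exp(-te / T2)``.

    ``params`` may be a :class:`DecayParams` or an ``(s0, t2)`` pair; ``te``
    may be a scalar or an array of echo times in ms.
    """
    if isinstance(params, DecayParams):
        s0, t2 = params.s0, params.t2
    else:
        s0, t2 = params
    if t2 <= 0:
        raise ValueError("t2 must be positive")
    te = np.asarray(te, dtype=float)
    out = s0 * np.exp(-te / t2)
    return float(out) if out.ndim == 0 else out


def add_rician_noise(signal, sigma: float, rng: np.random.Generator):
    """Corrupt noise-free magnitudes with complex Gaussian noise.

    The noise-free signal is placed on the real axis (zero phase) and
    independent ``N(0, sigma^2)`` noise is added to the real and imaginary
    channels; the returned magnitude ``sqrt((s + g1)^2 + g2^2)`` is Rician
    distributed.  ``sigma = 0`` returns ``signal`` exactly.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    signal = np.asarray(signal, dtype=float)
    if sigma == 0:
        return float(signal) if signal.ndim == 0 else signal.copy()
    g1 = rng.normal(0.0, sigma, size=signal.shape)
    g2 = rng.normal(0.0, sigma, size=signal.shape)
    out = np.hypot(signal + g1, g2)
    return float(out) if out.ndim == 0 else out


def rician_expected_magnitude(signal, sigma: float):
    """Mean of the Rician distribution with noise-free magnitude ``signal``.

    Computed as ``sigma * sqrt(pi/2) * e^-a * [(1 + 2a) I0(a) + 2a I1(a)]``
    with ``a = (signal / (2 sigma))^2``, using exponentially scaled Bessel
    functions so the expression stays finite at arbitrarily large ``a``
    (``a`` grows quadratically with SNR).  For ``sigma = 0`` the limit value
    ``signal`` is returned, keeping the model family continuous.

    The result is always >= ``signal`` and >= the Rayleigh floor
    ``sigma * sqrt(pi/2)``, and approaches ``signal`` from above as
    ``signal / sigma -> inf``.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    signal = np.asarray(signal, dtype=float)
    if sigma == 0:
        return float(signal) if signal.ndim == 0 else signal.copy()
    a = np.square(signal / (2.0 * sigma))
    # ive(n, a) == exp(-a) * iv(n, a); avoids overflow past a ~ 700 but loses
    # accuracy (NaN) beyond a ~ 1e9, where the high-SNR expansion
    # E = s + sigma^2/(2 s) - sigma^4/(8 s^3) is exact to ~1e-14 relative.
    small = a < 1e6
    a_safe = np.where(small, a, 0.0)
    bessel = sigma * math.sqrt(math.pi / 2.0) * (
        (1.0 + 2.0 * a_safe) * special.ive(0, a_safe)
        + 2.0 * a_safe * special.ive(1, a_safe)
    )
    s_safe = np.where(small, 1.0, signal)
    expansion = signal + sigma**2 / (2.0 * s_safe) - sigma**4 / (8.0 * s_safe**3)
    out = np.where(small, bessel, expansion)
    return float(out) if out.ndim == 0 else out


def snr_of(params: DecayParams) -> float:
    """Signal-to-noise ratio ``S0 / sigma`` (``inf`` for noise-free decays)."""
    if params.sigma == 0:
        return math.inf
    return params.s0 / params.sigma
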