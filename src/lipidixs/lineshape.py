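"""Forward spectral model for inelastic X-ray scattering (IXS) of lipid bilayers.

The measured dynamic structure factor S(Q, omega) at fixed momentum transfer Q
is modelled as

    S(omega) = bg + S(Q,0) * RF(omega)
               + sum_modes [ I * B(omega, T) * D(omega; Omega, Gamma) ] (*) RF

where

* ``RF`` is the instrument resolution function, a unit-area Pseudo-Voigt
  profile (Lorentzian/Gaussian mix with a common FWHM),
* ``D`` is the classical damped-harmonic-oscillator (DHO) kernel

      D(omega) = (1/pi) * Gamma * Omega^2 / [(omega^2 - Omega^2)^2 + (Gamma*omega)^2],

  an even, unit-area density that peaks near +/-Omega when the mode is
  underdamped (R = Omega/Gamma > 1),
* ``B(omega, T) = x / (1 - exp(-x))`` with ``x = hbar*omega / kB*T`` is the
  quantum detailed-balance weight making phonon creation (omega > 0) more
  intense than annihilation by exp(hbar*omega / kB*T),
* ``(*)`` denotes convolution in energy, and the elastic line -- a term
  proportional to delta(omega) -- convolved with the RF is the RF itself, so
  it enters with a free amplitude S(Q,0) and a fixed shape.

All energies are in meV; intensities are in detector counts; mode intensities
``I`` are integrated strengths in counts*meV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import fft as _fft

from .constants import KB_MEV_PER_K, celsius_to_kelvin
from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "ResolutionFunction",
    "DHOMode",
    "SpectralModelParams",
    "Spectrum",
    "validate_energy_grid",
    "pseudo_voigt",
    "detailed_balance_factor",
    "dho_kernel",
    "dho_profile",
    "ConvolutionEngine",
    "convolve_with_rf",
    "evaluate_model",
]

_TWO_SQRT_2LN2 = 2.0 * np.sqrt(2.0 * np.log(2.0))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResolutionFunction:
    """Instrument resolution: Pseudo-Voigt lineshape.

    Parameters
    ----------
    fwhm : float
        Full width at half maximum in meV (must be positive).
    eta : float
        Mixing parameter in [0, 1]: fraction of Lorentzian character
        (eta=1 pure Lorentzian, eta=0 pure Gaussian).
    """

    fwhm: float
    eta: float = 0.5

    def __post_init__(self) -> None:
        if not np.isfinite(self.fwhm) or self.fwhm <= 0:
            raise InvalidParameterError(f"fwhm must be positive, got {self.fwhm}")
        if not (0.0 <= self.eta <= 1.0):
            raise InvalidParameterError(f"eta must lie in [0, 1], got {self.eta}")

    @property
    def hwhm(self) -> float:
        return 0.5 * self.fwhm

    def __call__(self, omega) -> np.ndarray:
        return pseudo_voigt(omega, self)


@dataclass(frozen=True)
class DHOMode:
    """A single damped-harmonic-oscillator phonon mode.

    ``omega0`` is the excitation energy Omega(Q) in meV, ``gamma`` the damping
    width Gamma(Q) in meV and ``intensity`` the integrated strength I(Q) in
    counts*meV. ``branch_label`` records the acoustic-branch assignment.
    """

    omega0: float
    gamma: float
    intensity: float
    branch_label: str = "unassigned"

    _LABELS = ("longitudinal", "transverse", "unassigned")

    def __post_init__(self) -> None:
        if not np.isfinite(self.omega0) or self.omega0 < 0:
            raise InvalidParameterError(f"omega0 must be >= 0, got {self.omega0}")
        if not np.isfinite(self.gamma) or self.gamma <= 0:
            raise InvalidParameterError(f"gamma must be > 0, got {self.gamma}")
        if not np.isfinite(self.intensity) or self.intensity < 0:
            raise InvalidParameterError(f"intensity must be >= 0, got {self.intensity}")
        if self.branch_label not in self._LABELS:
            raise InvalidParameterError(f"unknown branch label {self.branch_label!r}")

    @property
    def damping_ratio(self) -> float:
        """R = Omega / Gamma; > 1 underdamped (propagating), < 1 overdamped."""
        return self.omega0 / self.gamma

    def relabel(self, label: str) -> "DHOMode":
        return replace(self, branch_label=label)


@dataclass(frozen=True)
class SpectralModelParams:
    """Full parameter set of the spectral model at one Q.

    ``elastic_amplitude`` is S(Q,0) (counts*meV; the elastic peak height is
    elastic_amplitude * RF(0)), ``background`` a flat level in counts,
    ``modes`` up to two DHO modes and ``temperature`` the sample temperature
    in kelvin entering the detailed-balance weight.
    """

    elastic_amplitude: float
    background: float
    modes: tuple[DHOMode, ...] = ()
    temperature: float = 293.15

    def __post_init__(self) -> None:
        if not np.isfinite(self.elastic_amplitude) or self.elastic_amplitude < 0:
            raise InvalidParameterError("elastic_amplitude must be >= 0")
        if not np.isfinite(self.background) or self.background < 0:
            raise InvalidParameterError("background must be >= 0")
        if self.temperature <= 0:
            raise InvalidParameterError("temperature must be positive (kelvin)")
        object.__setattr__(self, "modes", tuple(self.modes))
        if len(self.modes) > 2:
            raise InvalidParameterError("at most two DHO modes are supported")

    @property
    def n_free_params(self) -> int:
        """Free parameters of the corresponding fit: amplitude, background
        and (Omega, Gamma, I) per mode."""
        return 2 + 3 * len(self.modes)


def validate_energy_grid(grid, *, require_both_signs: bool = False) -> np.ndarray:
    """Validate an energy-transfer grid (meV) and return it as a float array.

    The grid must contain at least 3 strictly increasing finite values; grids
    used for fitting must span both signs of energy.
    """
    g = np.asarray(grid, dtype=float)
    if g.ndim != 1 or g.size < 3:
        raise InvalidInputError("energy grid must be 1-D with at least 3 points")
    if not np.all(np.isfinite(g)):
        raise InvalidInputError("energy grid contains non-finite values")
    if not np.all(np.diff(g) > 0):
        raise InvalidInputError("energy grid must be strictly increasing")
    if require_both_signs and not (g[0] < 0.0 < g[-1]):
        raise InvalidInputError("energy grid must span negative and positive energies")
    return g


@dataclass
class Spectrum:
    """One IXS scan at fixed momentum transfer.

    ``energy`` (meV), ``intensity`` and ``error`` (1 s.d., counts) are equal
    length arrays; ``q`` is the momentum transfer in nm^-1, ``temperature_c``
    the sample temperature in Celsius and ``rf`` the instrument resolution.
    """

    q: float
    energy: np.ndarray
    intensity: np.ndarray
    error: np.ndarray
    temperature_c: float
    rf: ResolutionFunction

    def __post_init__(self) -> None:
        self.energy = validate_energy_grid(self.energy, require_both_signs=True)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.error = np.asarray(self.error, dtype=float)
        if self.q <= 0:
            raise InvalidParameterError(f"q must be positive, got {self.q}")
        if self.intensity.shape != self.energy.shape or self.error.shape != self.energy.shape:
            raise InvalidInputError("energy, intensity and error must have equal lengths")
        if not np.all(np.isfinite(self.intensity)):
            raise InvalidInputError("intensity contains non-finite values")
        if not np.all(np.isfinite(self.error)) or np.any(self.error <= 0):
            raise InvalidInputError("errors must be positive and finite everywhere")
        celsius_to_kelvin(self.temperature_c)  # range check

    @property
    def temperature_k(self) -> float:
        return celsius_to_kelvin(self.temperature_c)

    def __len__(self) -> int:
        return self.energy.size


# ---------------------------------------------------------------------------
# elementary lineshapes
# ---------------------------------------------------------------------------

def pseudo_voigt(omega, rf: ResolutionFunction) -> np.ndarray:
    """Unit-area Pseudo-Voigt density eta*L + (1-eta)*G evaluated at omega (meV).

    Both the Lorentzian L and the Gaussian G are unit-area profiles sharing
    the same FWHM, so the mixture is symmetric about zero, has unit area on an
    infinite domain and reaches half of its peak exactly at +/- fwhm/2.
    """
    if not isinstance(rf, ResolutionFunction):
        rf = ResolutionFunction(*rf)
    w = np.asarray(omega, dtype=float)
    hw = 0.5 * rf.fwhm
    lor = hw / (np.pi * (w * w + hw * hw))
    sigma = rf.fwhm / _TWO_SQRT_2LN2
    gauss = np.exp(-0.5 * (w / sigma) ** 2) / (sigma * np.sqrt(2.0 * np.pi))
    out = rf.eta * lor + (1.0 - rf.eta) * gauss
    return out if out.ndim else float(out)


def detailed_balance_factor(omega, temperature: float) -> np.ndarray:
    """Quantum detailed-balance weight B(omega, T) = x / (1 - exp(-x)).

    Here x = hbar*omega / kB*T with omega in meV and T in kelvin.  The weight
    satisfies B(omega)/B(-omega) = exp(x) (Stokes/anti-Stokes asymmetry) and
    B(0) = 1 by continuous extension; for large positive omega it grows
    linearly as x.
    """
    if temperature <= 0:
        raise InvalidParameterError("temperature must be positive (kelvin)")
    x = np.asarray(omega, dtype=float) / (KB_MEV_PER_K * temperature)
    small = np.abs(x) < 1.0e-8
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        out = np.where(small, 1.0 + 0.5 * x, x / (-np.expm1(-np.where(small, 1.0, x))))
    return out if out.ndim else float(out)


def dho_kernel(omega, omega0: float, gamma: float) -> np.ndarray:
    """Classical DHO spectral kernel, even in omega and of unit area on R.

    D(omega) = (1/pi) * Gamma * Omega0^2 / [(omega^2 - Omega0^2)^2 + (Gamma*omega)^2].

    For an underdamped mode (Omega0 > Gamma/sqrt(2)) the kernel peaks at
    +/- sqrt(Omega0^2 - Gamma^2/2), close to +/-Omega0 when R = Omega0/Gamma >> 1.
    A mode with Omega0 = 0 carries no inelastic weight in this convention and
    evaluates to zero.  This function is the single place where the DHO
    lineshape convention lives; an alternative convention is a one-line change.
    """
    if gamma <= 0:
        raise InvalidParameterError("gamma must be positive")
    if omega0 < 0:
        raise InvalidParameterError("omega0 must be >= 0")
    w = np.asarray(omega, dtype=float)
    if omega0 == 0.0:
        out = np.zeros_like(w)
        return out if out.ndim else float(out)
    w2 = w * w
    out = (gamma * omega0 * omega0 / np.pi) / (
        (w2 - omega0 * omega0) ** 2 + (gamma * gamma) * w2
    )
    return out if out.ndim else float(out)


def dho_profile(omega, mode: DHOMode, temperature: float) -> np.ndarray:
    """One-mode inelastic density I * B(omega, T) * D(omega), counts*meV^-1."""
    if not isinstance(mode, DHOMode):
        raise InvalidParameterError("mode must be a DHOMode")
    return (
        mode.intensity
        * detailed_balance_factor(omega, temperature)
        * dho_kernel(omega, mode.omega0, mode.gamma)
    )


# ---------------------------------------------------------------------------
# resolution convolution
# ---------------------------------------------------------------------------

class ConvolutionEngine:
    """Discrete convolution of a model density with the resolution function.

    The density is sampled on an internal uniform fine grid with step
    min(grid spacing)/2 capped at fwhm/10, padded beyond both ends of the
    measurement grid by the kernel half-width so edge values are exact.  The
    kernel support is max(5, 159*eta) x fwhm, which keeps the truncated
    Lorentzian tail mass below 0.2%; the truncated kernel is renormalised to
    unit area so the zeroth moment of any well-contained density is preserved.
    The convolved density is interpolated back to the (possibly irregular)
    measurement grid.

    Instances cache the kernel FFT, so repeated convolutions during a fit are
    cheap.
    """

    def __init__(self, grid, rf: ResolutionFunction, step: float | None = None):
        self.grid = validate_energy_grid(grid)
        self.rf = rf
        if step is None:
            step = min(float(np.min(np.diff(self.grid))) / 2.0, rf.fwhm / 10.0)
        if step <= 0:
            raise InvalidParameterError("fine-grid step must be positive")
        self.step = float(step)

        half_width = rf.fwhm * max(5.0, 159.0 * rf.eta)
        self._n_half = int(np.ceil(half_width / self.step))
        pad = self._n_half * self.step
        n_fine = int(np.ceil((self.grid[-1] - self.grid[0] + 2.0 * pad) / self.step)) + 1
        self.fine_grid = (self.grid[0] - pad) + self.step * np.arange(n_fine)

        offsets = self.step * (np.arange(2 * self._n_half + 1) - self._n_half)
        kernel = pseudo_voigt(offsets, rf)
        kernel = kernel / (kernel.sum() * self.step)
        self._kernel = kernel

        n_k = kernel.size
        self._fft_len = _fft.next_fast_len(n_fine + n_k - 1)
        self._kernel_fft = _fft.rfft(kernel, self._fft_len)
        self._same_lo = (n_k - 1) // 2

    def convolve_fine(self, density_fine: np.ndarray) -> np.ndarray:
        """Convolve density values sampled on ``fine_grid``; returns values on
        the measurement grid."""
        d = np.asarray(density_fine, dtype=float)
        if d.shape != self.fine_grid.shape:
            raise InvalidInputError("density must be sampled on the engine's fine grid")
        full = _fft.irfft(_fft.rfft(d, self._fft_len) * self._kernel_fft, self._fft_len)
        same = full[self._same_lo : self._same_lo + d.size] * self.step
        return np.interp(self.grid, self.fine_grid, same)

    def convolve(self, density: Callable[[np.ndarray], np.ndarray]) -> np.ndarray:
        """Convolve a callable density (of omega in meV) with the RF."""
        return self.convolve_fine(np.asarray(density(self.fine_grid), dtype=float))


def convolve_with_rf(model_density: Callable[[np.ndarray], np.ndarray],
                     rf: ResolutionFunction, grid) -> np.ndarray:
    """Convolve ``model_density`` with the resolution function, sampled on ``grid``.

    See :class:`ConvolutionEngine` for the discretisation.  The density must be
    evaluable on the padded internal grid extending beyond both grid ends.
    """
    return ConvolutionEngine(grid, rf).convolve(model_density)


# ---------------------------------------------------------------------------
# total model
# ---------------------------------------------------------------------------

def evaluate_model(params: SpectralModelParams, grid, rf: ResolutionFunction,
                   engine: ConvolutionEngine | None = None) -> np.ndarray:
    """Evaluate the full spectral model on ``grid`` (counts per point).

    background + elastic_amplitude * RF(omega) + sum over modes of the
    resolution-convolved inelastic densities.  The elastic term uses the RF
    shape directly: a delta function convolved with the RF is the RF itself.
    """
    if engine is None:
        engine = ConvolutionEngine(grid, rf)
    g = engine.grid
    y = params.background + params.elastic_amplitude * pseudo_voigt(g, rf)
    if params.modes:
        balance = detailed_balance_factor(engine.fine_grid, params.temperature)
        density = np.zeros_like(engine.fine_grid)
        for mode in params.modes:
            density += mode.intensity * dho_kernel(engine.fine_grid, mode.omega0, mode.gamma)
        y = y + engine.convolve_fine(density * balance)
    return y
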