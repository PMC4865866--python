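"""Nonlinear least-squares fitting of IXS spectra and mode-count selection.

The free parameters of an n-mode fit are the elastic amplitude S(Q,0), the
flat background and (Omega, Gamma, I) per DHO mode -- 2 + 3n parameters, all
bound below by zero.  Fits minimise sum(((data - model)/error)^2) with a
bounded trust-region least-squares solver and a seeded multi-start strategy
(log-uniform x0.5-x2 perturbations of the initial Omega and Gamma); 1-sigma
parameter uncertainties come from the covariance of the linearised problem at
the optimum.

Whether a spectrum needs one or two phonon modes is decided the way an IXS
practitioner reads the fits: the two-mode model is accepted only if it
improves the reduced chi^2 materially AND its extra mode does not "vanish"
(intensity indistinguishable from zero within its uncertainty).  A symmetric
two-hump structure in the one-mode residuals -- excess intensity at +/-omega*
-- is recorded as supporting evidence for a missing excitation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .errors import InvalidInputError, UnderDeterminedError
from .lineshape import (
    ConvolutionEngine,
    DHOMode,
    ResolutionFunction,
    SpectralModelParams,
    Spectrum,
    detailed_balance_factor,
    dho_kernel,
    pseudo_voigt,
    validate_energy_grid,
)

__all__ = [
    "FitResult",
    "ModeSelection",
    "TwoHumpResult",
    "SpectrumFitter",
    "ModeCountSelector",
    "fit_spectrum",
    "reduced_chi_square",
    "two_hump_diagnostic",
    "select_mode_count",
]

logger = logging.getLogger(__name__)

_GAMMA_MIN = 1.0e-3  # meV; Gamma > 0 is a hard physical constraint


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Best fit of one spectrum.

    ``param_errors`` is aligned with the packed parameter vector
    [elastic_amplitude, background, (Omega, Gamma, I) per mode] after modes
    are sorted by increasing Omega (lower branch first).
    """

    params: SpectralModelParams
    param_errors: np.ndarray
    reduced_chi2: float
    residuals: np.ndarray
    n_free_params: int
    converged: bool
    q: float
    n_starts: int = 0

    @property
    def chi2(self) -> float:
        """Raw (unreduced) chi^2 = sum of squared normalised residuals."""
        return float(np.sum(self.residuals ** 2))

    def mode_uncertainties(self, i: int) -> tuple[float, float, float]:
        """(sigma_Omega, sigma_Gamma, sigma_I) of mode ``i``."""
        off = 2 + 3 * i
        return tuple(self.param_errors[off : off + 3])


@dataclass
class ModeSelection:
    """Outcome of the one-vs-two-mode comparison at one Q."""

    chosen_n_modes: int
    chi2_one: float
    chi2_two: float
    vanished: bool
    two_hump_flag: bool

    def __post_init__(self) -> None:
        if self.chosen_n_modes not in (1, 2):
            raise InvalidInputError("chosen_n_modes must be 1 or 2")


@dataclass
class TwoHumpResult:
    """Residual diagnostic: symmetric positive lobes about zero energy."""

    flag: bool
    positions: tuple[float, float] | None = None  # (negative side, positive side), meV
    amplitudes: tuple[float, float] | None = None  # smoothed residual peaks, sigma units

    def __bool__(self) -> bool:
        return self.flag


# ---------------------------------------------------------------------------
# chi^2 and residual diagnostics
# ---------------------------------------------------------------------------

def reduced_chi_square(spectrum: Spectrum, params: SpectralModelParams,
                       engine: ConvolutionEngine | None = None) -> float:
    """Reduced chi^2 = sum(((y - m)/sigma)^2) / (N - n_free).

    ``n_free`` is 2 + 3 * n_modes, the free-parameter count of the
    corresponding fit.
    """
    from .lineshape import evaluate_model

    n = len(spectrum)
    n_free = params.n_free_params
    if n <= n_free:
        raise UnderDeterminedError(f"{n} points cannot constrain {n_free} parameters")
    model = evaluate_model(params, spectrum.energy, spectrum.rf, engine=engine)
    r = (spectrum.intensity - model) / spectrum.error
    return float(np.sum(r * r) / (n - n_free))


def _boxcar(x: np.ndarray, width: int) -> np.ndarray:
    width = max(1, int(width))
    if width == 1:
        return x
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def two_hump_diagnostic(residuals, grid, window_mev: float = 1.5,
                        exclude_below_mev: float = 0.85,
                        amplitude_sigma: float = 1.5,
                        smooth_points: int = 5) -> TwoHumpResult:
    """Detect two positive residual lobes symmetric about zero energy.

    The normalised residuals are boxcar-smoothed; on each side of the elastic
    region (|omega| > ``exclude_below_mev``, the resolution HWHM by default)
    the largest smoothed residual is located.  The diagnostic fires when both
    peaks exceed ``amplitude_sigma`` (in sigma units) and their positions
    mirror each other within ``window_mev``.  Degenerate input returns a
    non-firing result rather than raising.
    """
    g = np.asarray(grid, dtype=float)
    r = np.asarray(residuals, dtype=float)
    if r.shape != g.shape or g.size < 5 or not np.all(np.isfinite(r)):
        return TwoHumpResult(False)
    smooth = _boxcar(r, smooth_points)
    pos_mask = g > exclude_below_mev
    neg_mask = g < -exclude_below_mev
    if not pos_mask.any() or not neg_mask.any():
        return TwoHumpResult(False)
    i_pos = np.argmax(np.where(pos_mask, smooth, -np.inf))
    i_neg = np.argmax(np.where(neg_mask, smooth, -np.inf))
    amp_pos, amp_neg = smooth[i_pos], smooth[i_neg]
    pos, neg = g[i_pos], g[i_neg]
    fired = (
        amp_pos >= amplitude_sigma
        and amp_neg >= amplitude_sigma
        and abs(pos + neg) <= window_mev
    )
    return TwoHumpResult(bool(fired), (float(neg), float(pos)),
                         (float(amp_neg), float(amp_pos)))


# ---------------------------------------------------------------------------
# parameter packing
# ---------------------------------------------------------------------------

def _pack(params: SpectralModelParams) -> np.ndarray:
    x = [params.elastic_amplitude, params.background]
    for m in params.modes:
        x.extend([m.omega0, m.gamma, m.intensity])
    return np.asarray(x, dtype=float)


def _unpack(x: np.ndarray, n_modes: int, temperature: float,
            labels: Sequence[str] | None = None) -> SpectralModelParams:
    modes = []
    for j in range(n_modes):
        omega0, gamma, intensity = x[2 + 3 * j : 5 + 3 * j]
        label = labels[j] if labels else "unassigned"
        modes.append(DHOMode(max(omega0, 0.0), max(gamma, _GAMMA_MIN),
                             max(intensity, 0.0), label))
    return SpectralModelParams(elastic_amplitude=max(x[0], 0.0),
                               background=max(x[1], 0.0),
                               modes=tuple(modes), temperature=temperature)


def _branch_labels(n_modes: int) -> list[str]:
    # Lower-Omega mode is the transverse candidate, higher the longitudinal.
    if n_modes == 1:
        return ["longitudinal"]
    if n_modes == 2:
        return ["transverse", "longitudinal"]
    return []


# ---------------------------------------------------------------------------
# the fitter
# ---------------------------------------------------------------------------

class SpectrumFitter(BaseEstimator):
    """Least-squares fit of one IXS spectrum with an n-mode DHO model.

    Parameters
    ----------
    n_modes : int
        Number of DHO modes (0, 1 or 2).
    n_restarts : int
        Number of seeded perturbed restarts added to each supplied or
        heuristic initialisation; the best chi^2 is kept.
    random_state : int or None
        Seed for the restart perturbations; identical spectrum and seed give
        a bit-identical result.
    init : SpectralModelParams, sequence of them, or None
        Optional initialisation(s).  When None an heuristic start is built
        from the data (elastic amplitude from the peak, background from the
        outer 10% of energy points, mode positions from the residual shoulder
        of an elastic-only model with a 8 meV fallback and a 2 meV transverse
        candidate).

    Fitted attributes: ``result_`` (:class:`FitResult`) plus the flattened
    ``params_``, ``param_errors_``, ``reduced_chi2_``, ``residuals_``,
    ``converged_``, ``n_free_params_``.
    """

    def __init__(self, n_modes: int = 1, n_restarts: int = 5,
                 random_state: int | None = None, init=None):
        self.n_modes = n_modes
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.init = init

    # -- initialisation heuristic ------------------------------------------

    def _heuristic_init(self, spectrum: Spectrum) -> SpectralModelParams:
        g, y = spectrum.energy, spectrum.intensity
        n_tail = max(int(round(0.05 * g.size)), 2)
        background = float(np.median(np.concatenate([y[:n_tail], y[-n_tail:]])))
        background = max(background, 0.0)
        rf0 = float(pseudo_voigt(0.0, spectrum.rf))
        amplitude = max(float(y.max()) - background, 1.0) / rf0

        if self.n_modes == 0:
            return SpectralModelParams(amplitude, background, (),
                                       spectrum.temperature_k)

        # residual shoulder of the elastic-only model locates the dominant
        # (longitudinal) excitation; fallback 8 meV
        elastic = background + amplitude * pseudo_voigt(g, spectrum.rf)
        resid = _boxcar((y - elastic) / spectrum.error, 5)
        shoulder_mask = np.abs(g) > spectrum.rf.fwhm
        omega_long = 8.0
        if shoulder_mask.any():
            i = np.argmax(np.where(shoulder_mask, resid, -np.inf))
            if resid[i] > 0:
                omega_long = float(np.clip(abs(g[i]), 1.0, 0.9 * abs(g).max()))

        # local excess intensity sets the strength scale
        dw = float(np.mean(np.diff(g)))
        excess = float(np.sum(np.clip(y - elastic, 0.0, None)) * dw)
        excess = max(excess, 10.0 * dw)

        if self.n_modes == 1:
            modes = (DHOMode(omega_long, 2.0, 0.8 * excess),)
        else:
            modes = (DHOMode(2.0, 2.0, 0.3 * excess),
                     DHOMode(omega_long, 2.0, 0.5 * excess))
        return SpectralModelParams(amplitude, background, modes,
                                   spectrum.temperature_k)

    # -- fitting ------------------------------------------------------------

    def fit(self, spectrum: Spectrum, y=None) -> "SpectrumFitter":
        if not isinstance(spectrum, Spectrum):
            raise InvalidInputError("SpectrumFitter.fit expects a Spectrum")
        if self.n_modes not in (0, 1, 2):
            raise InvalidInputError("n_modes must be 0, 1 or 2")
        n_free = 2 + 3 * self.n_modes
        if len(spectrum) <= n_free:
            raise UnderDeterminedError(
                f"{len(spectrum)} points cannot constrain {n_free} parameters")

        temperature = spectrum.temperature_k
        engine = ConvolutionEngine(spectrum.energy, spectrum.rf)
        pv_grid = pseudo_voigt(engine.grid, spectrum.rf)
        balance = detailed_balance_factor(engine.fine_grid, temperature)
        data, sigma = spectrum.intensity, spectrum.error
        fine = engine.fine_grid
        n_modes = self.n_modes

        def model_counts(x: np.ndarray) -> np.ndarray:
            y_model = x[1] + x[0] * pv_grid
            if n_modes:
                density = np.zeros_like(fine)
                for j in range(n_modes):
                    omega0, gamma, intensity = x[2 + 3 * j : 5 + 3 * j]
                    if intensity > 0.0 and omega0 > 0.0:
                        density += intensity * dho_kernel(fine, omega0, gamma)
                if density.any():
                    y_model = y_model + engine.convolve_fine(density * balance)
            return y_model

        def residual(x: np.ndarray) -> np.ndarray:
            return (model_counts(x) - data) / sigma

        # initial points
        if self.init is None:
            inits = [self._heuristic_init(spectrum)]
        elif isinstance(self.init, SpectralModelParams):
            inits = [self.init]
        else:
            inits = list(self.init)
        starts = [_pack(p) for p in inits]
        rng = np.random.default_rng(self.random_state)
        base = starts[0]
        for _ in range(int(self.n_restarts)):
            x0 = base.copy()
            for j in range(n_modes):
                factors = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=2))
                x0[2 + 3 * j] *= factors[0]
                x0[3 + 3 * j] *= factors[1]
            starts.append(x0)

        omega_max = 1.2 * float(np.abs(spectrum.energy).max())
        lower = [0.0, 0.0] + [0.0, _GAMMA_MIN, 0.0] * n_modes
        upper = [np.inf, np.inf] + [omega_max, 60.0, np.inf] * n_modes
        lower, upper = np.asarray(lower), np.asarray(upper)

        best = None
        n_converged = 0
        for x0 in starts:
            x0 = np.clip(x0, lower, upper)
            x_scale = np.maximum(np.abs(x0),
                                 [1.0, 1.0] + [0.5, 0.5, 1.0] * n_modes)
            sol = least_squares(residual, x0, bounds=(lower, upper),
                                method="trf", x_scale=x_scale, max_nfev=400)
            if sol.status > 0:
                n_converged += 1
            if best is None or sol.cost < best.cost - 1e-12:
                best = sol

        # 1-sigma uncertainties from the linearised covariance at the optimum
        jac = best.jac
        try:
            cov = np.linalg.pinv(jac.T @ jac)
            errors = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:  # pragma: no cover
            errors = np.full(best.x.size, np.inf)

        # sort modes by Omega (lower branch first) and label them
        x = best.x.copy()
        if n_modes == 2 and x[2] > x[5]:
            x[2:5], x[5:8] = best.x[5:8].copy(), best.x[2:5].copy()
            errors = errors.copy()
            errors[2:5], errors[5:8] = errors[5:8].copy(), errors[2:5].copy()

        params = _unpack(x, n_modes, temperature, _branch_labels(n_modes))
        resid = residual(x)
        self.result_ = FitResult(
            params=params,
            param_errors=errors,
            reduced_chi2=float(np.sum(resid ** 2) / (len(spectrum) - n_free)),
            residuals=resid,
            n_free_params=n_free,
            converged=n_converged > 0,
            q=spectrum.q,
            n_starts=len(starts),
        )
        self.params_ = params
        self.param_errors_ = errors
        self.reduced_chi2_ = self.result_.reduced_chi2
        self.residuals_ = resid
        self.converged_ = self.result_.converged
        self.n_free_params_ = n_free
        self._engine = engine
        self._model_counts = model_counts
        logger.info("fit q=%.3f n_modes=%d red_chi2=%.4f converged=%s starts=%d",
                    spectrum.q, n_modes, self.reduced_chi2_, self.converged_,
                    len(starts))
        return self

    def predict(self, grid=None) -> np.ndarray:
        """Model counts on ``grid`` (default: the fitted spectrum's grid)."""
        if not hasattr(self, "result_"):
            raise InvalidInputError("fit before predict")
        if grid is None:
            return self._model_counts(_pack(self.params_))
        from .lineshape import evaluate_model

        grid = validate_energy_grid(grid)
        return evaluate_model(self.params_, grid, self._engine.rf)


class ModeCountSelector(BaseEstimator):
    """Decide between the one- and two-mode spectral models at one Q.

    The spectrum is fitted with both models; two modes are chosen only when
    the reduced chi^2 improves by at least ``rel_improvement_threshold``
    (relative) and the extra mode has not vanished (every mode intensity must
    exceed ``vanish_sigma`` times its 1-sigma uncertainty).  The two-mode fit
    is additionally started from the one-mode optimum (with a zero- and a
    small-intensity second mode), which guarantees the nested-model property
    chi2_two <= chi2_one.

    Fitted attributes: ``selection_`` (:class:`ModeSelection`), ``fit_one_``,
    ``fit_two_`` (:class:`FitResult`), ``best_fit_`` and ``two_hump_``.
    """

    def __init__(self, rel_improvement_threshold: float = 0.15,
                 vanish_sigma: float = 2.0, n_restarts: int = 5,
                 random_state: int | None = None):
        self.rel_improvement_threshold = rel_improvement_threshold
        self.vanish_sigma = vanish_sigma
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, spectrum: Spectrum, y=None) -> "ModeCountSelector":
        one = SpectrumFitter(n_modes=1, n_restarts=self.n_restarts,
                             random_state=self.random_state).fit(spectrum)
        fit1 = one.result_

        hump = two_hump_diagnostic(fit1.residuals, spectrum.energy,
                                   exclude_below_mev=spectrum.rf.hwhm)

        # two-mode starts: heuristic + nested continuations of the 1-mode optimum
        heur = SpectrumFitter(n_modes=2)._heuristic_init(spectrum)
        long_mode = fit1.params.modes[0]
        omega_second = hump.positions[1] if hump.flag else 2.0
        omega_second = float(np.clip(abs(omega_second), 0.5, 0.9 * abs(spectrum.energy).max()))
        seeded = []
        for frac in (0.0, 0.15):
            seeded.append(SpectralModelParams(
                fit1.params.elastic_amplitude, fit1.params.background,
                (DHOMode(omega_second, 1.5, frac * long_mode.intensity),
                 long_mode.relabel("unassigned")),
                fit1.params.temperature))
        two = SpectrumFitter(n_modes=2, n_restarts=self.n_restarts,
                             random_state=self.random_state,
                             init=[heur] + seeded).fit(spectrum)
        fit2 = two.result_

        # a mode has "vanished" when it collapsed to zero: statistically
        # consistent with zero AND physically negligible next to its
        # companion.  The statistical check alone misfires for a real
        # resolution-buried mode, whose intensity is strongly covariant with
        # the elastic amplitude and so carries a huge linearised error.
        vanished = False
        intensities = [m.intensity for m in fit2.params.modes]
        for i in range(2):
            stat_zero = intensities[i] < self.vanish_sigma * fit2.mode_uncertainties(i)[2]
            negligible = intensities[i] <= 0.05 * intensities[1 - i]
            if stat_zero and negligible:
                vanished = True
        improvement = (fit1.reduced_chi2 - fit2.reduced_chi2) / max(fit1.reduced_chi2, 1e-12)
        choose_two = improvement >= self.rel_improvement_threshold and not vanished

        self.fit_one_ = fit1
        self.fit_two_ = fit2
        self.two_hump_ = hump
        self.selection_ = ModeSelection(
            chosen_n_modes=2 if choose_two else 1,
            chi2_one=fit1.reduced_chi2,
            chi2_two=fit2.reduced_chi2,
            vanished=bool(vanished),
            two_hump_flag=bool(hump.flag),
        )
        self.best_fit_ = fit2 if choose_two else fit1
        logger.info("select q=%.3f chi2_one=%.3f chi2_two=%.3f vanished=%s "
                    "two_hump=%s chosen=%d", spectrum.q, fit1.reduced_chi2,
                    fit2.reduced_chi2, vanished, hump.flag,
                    self.selection_.chosen_n_modes)
        return self


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def fit_spectrum(spectrum: Spectrum, n_modes: int, init=None,
                 seed: int | None = 0, n_restarts: int = 5) -> FitResult:
    """Fit one spectrum with an ``n_modes`` DHO model; see :class:`SpectrumFitter`."""
    return SpectrumFitter(n_modes=n_modes, n_restarts=n_restarts,
                          random_state=seed, init=init).fit(spectrum).result_


def select_mode_count(spectrum: Spectrum, seed: int | None = 0,
                      rel_improvement_threshold: float = 0.15,
                      vanish_sigma: float = 2.0,
                      n_restarts: int = 5) -> ModeSelection:
    """One- vs two-mode decision for one spectrum; see :class:`ModeCountSelector`."""
    return ModeCountSelector(
        rel_improvement_threshold=rel_improvement_threshold,
        vanish_sigma=vanish_sigma, n_restarts=n_restarts,
        random_state=seed).fit(spectrum).selection_
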