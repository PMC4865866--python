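"""Forward simulator of the IXS experiment on oriented DPPC multilayers.

Generates seeded, Poisson-noisy spectra from known dispersion relations for
the gel (L_beta', 20 degC) and fluid (L_alpha, 45 degC) phases so that the
fitting and dispersion stages can be exercised end to end without measured
data.  Each scenario carries one longitudinal and one transverse acoustic
branch; in the fluid scenario the transverse branch is suppressed below the
phononic gap edge (~5 nm^-1).

The acoustic branches use the sine parameterisation of a nearest-neighbour
chain,

    omega(q) = omega_max * |sin(pi * q / Q_min)|,   omega_max = s * Q_min / pi,

whose low-q slope s = v / C (C the meV*nm -> m/s conversion) matches the
branch sound speed and whose first minimum sits at the quasi-Brillouin-zone
boundary Q_min.  Damping grows linearly with q: Gamma(q) = gamma0 + gamma1*q.
These closed forms are simulator conventions -- the minimal shapes consistent
with a linear acoustic onset and a dispersion minimum -- not physical claims.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import MEV_NM_TO_M_PER_S, celsius_to_kelvin
from .errors import InvalidParameterError
from .lineshape import (
    ConvolutionEngine,
    DHOMode,
    ResolutionFunction,
    SpectralModelParams,
    Spectrum,
    evaluate_model,
)

__all__ = [
    "PhaseScenario",
    "gel_scenario",
    "fluid_scenario",
    "true_dispersion",
    "true_modes",
    "generate_spectrum",
    "simulate_from_params",
    "generate_dataset",
    "default_q_list",
]

_BRANCHES = ("longitudinal", "transverse")


def default_q_list(n: int = 18, q_min: float = 2.47, q_max: float = 27.29) -> np.ndarray:
    """The measured Q values: 18 points evenly spanning 2.47-27.29 nm^-1."""
    return np.linspace(q_min, q_max, n)


@dataclass(frozen=True)
class PhaseScenario:
    """Ground-truth description of one simulated experiment.

    Sound speeds are in m/s, the zone boundary (dispersion minimum) and gap
    edge in nm^-1, counts are expected detector counts.  ``damping`` maps each
    branch to (gamma0, gamma1) of Gamma(q) = gamma0 + gamma1*q (meV, meV*nm).
    ``intensity_frac`` maps each branch to the integrated mode strength as a
    fraction of ``peak_counts`` (in counts*meV).
    """

    name: str
    temperature_c: float
    v_long: float
    v_trans: float
    q_zone_boundary: float
    gap_edge: float | None = None
    peak_counts: float = 5000.0
    background_counts: float = 10.0
    rf: ResolutionFunction = field(default_factory=lambda: ResolutionFunction(1.7, 0.5))
    n_points: int = 97
    e_min: float = -15.0
    e_max: float = 15.0
    q_list: tuple[float, ...] = tuple(default_q_list())
    damping: dict = field(default_factory=dict)
    intensity_frac: dict = field(default_factory=lambda: {"longitudinal": 0.6, "transverse": 0.6})

    def __post_init__(self) -> None:
        if self.v_long <= 0 or self.v_trans <= 0:
            raise InvalidParameterError("sound speeds must be positive")
        if self.q_zone_boundary <= 0:
            raise InvalidParameterError("q_zone_boundary must be positive")
        if self.peak_counts <= 0 or self.background_counts < 0:
            raise InvalidParameterError("counts must be positive")
        celsius_to_kelvin(self.temperature_c)
        q = np.asarray(self.q_list, dtype=float)
        if q.size == 0 or not np.all(np.diff(q) > 0) or np.any(q <= 0):
            raise InvalidParameterError("q_list must be strictly increasing and positive")

    @property
    def temperature_k(self) -> float:
        return celsius_to_kelvin(self.temperature_c)

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(self.e_min, self.e_max, self.n_points)

    def speed(self, branch: str) -> float:
        return {"longitudinal": self.v_long, "transverse": self.v_trans}[branch]


def gel_scenario(**overrides) -> PhaseScenario:
    """L_beta' (gel) phase at 20 degC: stiffer branches, no transverse gap."""
    kw = dict(
        name="gel_20C",
        temperature_c=20.0,
        v_long=2532.0,
        v_trans=582.0,
        q_zone_boundary=15.4,
        gap_edge=None,
        damping={"longitudinal": (0.8, 0.25), "transverse": (0.25, 0.06)},
    )
    kw.update(overrides)
    return PhaseScenario(**kw)


def fluid_scenario(**overrides) -> PhaseScenario:
    """L_alpha (fluid) phase at 45 degC: softened branches, transverse branch
    suppressed below the 5 nm^-1 gap edge."""
    kw = dict(
        name="fluid_45C",
        temperature_c=45.0,
        v_long=2241.0,
        v_trans=582.0,
        q_zone_boundary=14.2,
        gap_edge=5.0,
        damping={"longitudinal": (1.0, 0.25), "transverse": (0.8, 0.15)},
    )
    kw.update(overrides)
    return PhaseScenario(**kw)


def true_dispersion(scenario: PhaseScenario, branch: str, q: float):
    """Ground-truth (omega, gamma) in meV for one branch at momentum q.

    Returns ``None`` for the transverse branch below the scenario's gap edge
    (the mode does not propagate there).
    """
    if branch not in _BRANCHES:
        raise InvalidParameterError(f"unknown branch {branch!r}")
    if q <= 0:
        raise InvalidParameterError("q must be positive")
    if branch == "transverse" and scenario.gap_edge is not None and q < scenario.gap_edge:
        return None
    slope = scenario.speed(branch) / MEV_NM_TO_M_PER_S  # meV * nm
    q_zb = scenario.q_zone_boundary
    omega = slope * q_zb / np.pi * abs(np.sin(np.pi * q / q_zb))
    gamma0, gamma1 = scenario.damping.get(branch, (0.5, 0.1))
    gamma = gamma0 + gamma1 * q
    return float(omega), float(gamma)


def true_modes(scenario: PhaseScenario, q: float) -> tuple[DHOMode, ...]:
    """Ground-truth DHO modes (with branch labels) at momentum q."""
    modes = []
    for branch in _BRANCHES:
        disp = true_dispersion(scenario, branch, q)
        if disp is None:
            continue
        omega, gamma = disp
        intensity = scenario.intensity_frac[branch] * scenario.peak_counts
        modes.append(DHOMode(omega, gamma, intensity, branch))
    return tuple(modes)


def true_params(scenario: PhaseScenario, q: float) -> SpectralModelParams:
    """Noise-free model parameters at momentum q.

    The elastic amplitude is set so the elastic component peaks at
    ``scenario.peak_counts`` counts.
    """
    rf0 = float(scenario.rf(0.0))
    return SpectralModelParams(
        elastic_amplitude=scenario.peak_counts / rf0,
        background=scenario.background_counts,
        modes=true_modes(scenario, q),
        temperature=scenario.temperature_k,
    )


def simulate_from_params(params: SpectralModelParams, grid, rf: ResolutionFunction,
                         q: float, temperature_c: float, seed) -> Spectrum:
    """Poisson-noisy spectrum from explicit model parameters.

    ``seed`` may be anything accepted by :func:`numpy.random.default_rng`
    (int or SeedSequence).  Errors are sqrt(counts) with a floor of 1.
    """
    expected = evaluate_model(params, grid, rf)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(np.clip(expected, 0.0, None)).astype(float)
    error = np.sqrt(np.clip(counts, 1.0, None))
    return Spectrum(q=q, energy=np.asarray(grid, dtype=float), intensity=counts,
                    error=error, temperature_c=temperature_c, rf=rf)


def generate_spectrum(scenario: PhaseScenario, q: float, seed) -> Spectrum:
    """Simulate one IXS scan of the scenario at momentum q (deterministic in seed)."""
    return simulate_from_params(true_params(scenario, q), scenario.grid, scenario.rf,
                                q, scenario.temperature_c, seed)


def generate_dataset(scenario: PhaseScenario, seed: int):
    """Simulate the full Q scan of a scenario.

    Returns ``(spectra, manifest)``: one spectrum per q in ``scenario.q_list``
    with per-Q sub-seeds derived as SeedSequence([seed, q_index]), and a
    manifest dict recording the scenario and the exact ground truth used at
    each q (for recovery tests; the truth is re-read from
    :func:`true_dispersion`, so generator and record cannot drift).
    """
    spectra = []
    truth = []
    for i, q in enumerate(scenario.q_list):
        sub = np.random.SeedSequence([int(seed), i])
        spectra.append(generate_spectrum(scenario, float(q), sub))
        entry = {"q_nm_inv": float(q)}
        for branch in _BRANCHES:
            disp = true_dispersion(scenario, branch, float(q))
            if disp is None:
                entry[branch] = None
            else:
                entry[branch] = {"omega_meV": disp[0], "gamma_meV": disp[1],
                                 "intensity": scenario.intensity_frac[branch] * scenario.peak_counts}
        truth.append(entry)
    manifest = {
        "scenario": {
            "name": scenario.name,
            "temperature_C": scenario.temperature_c,
            "v_long_m_per_s": scenario.v_long,
            "v_trans_m_per_s": scenario.v_trans,
            "q_zone_boundary_nm_inv": scenario.q_zone_boundary,
            "gap_edge_nm_inv": scenario.gap_edge,
            "peak_counts": scenario.peak_counts,
            "background_counts": scenario.background_counts,
            "rf_fwhm_meV": scenario.rf.fwhm,
            "rf_eta": scenario.rf.eta,
        },
        "seed": int(seed),
        "truth": truth,
    }
    return spectra, manifest
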