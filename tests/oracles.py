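"""Independent straightforward reference implementations used as test oracles.

Everything here is written directly from the model definitions with
scipy.integrate quadrature and makes no use of the package's convolution or
evaluation code paths, so it can certify them.
"""

import numpy as np
from scipy.integrate import quad

KB = 8.617333262e-2  # meV/K


def lorentzian(w, fwhm):
    hw = fwhm / 2.0
    return hw / (np.pi * (w * w + hw * hw))


def gaussian(w, fwhm):
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.exp(-0.5 * (w / sigma) ** 2) / (sigma * np.sqrt(2.0 * np.pi))


def pseudo_voigt(w, fwhm, eta):
    return eta * lorentzian(w, fwhm) + (1.0 - eta) * gaussian(w, fwhm)


def balance(w, t_k):
    x = w / (KB * t_k)
    if abs(x) < 1e-10:
        return 1.0
    return x / (1.0 - np.exp(-x))


def dho_density(w, omega0, gamma, intensity, t_k):
    kernel = (gamma * omega0**2 / np.pi) / ((w * w - omega0**2) ** 2 + (gamma * w) ** 2)
    return intensity * balance(w, t_k) * kernel


def model_point(w, amplitude, bg, modes, t_k, fwhm, eta, lim=400.0):
    """Elastic + background + quadrature convolution of each DHO with the RF."""
    y = bg + amplitude * pseudo_voigt(w, fwhm, eta)
    for omega0, gamma, intensity in modes:
        integrand = lambda u: dho_density(u, omega0, gamma, intensity, t_k) * \
            pseudo_voigt(w - u, fwhm, eta)
        val = 0.0
        # split at the sharp features of the integrand
        pts = sorted({-lim, -omega0, 0.0, omega0, w, lim})
        for a, b in zip(pts[:-1], pts[1:]):
            val += quad(integrand, a, b, limit=400)[0]
        y += val
    return y


def model_curve(grid, amplitude, bg, modes, t_k, fwhm, eta):
    return np.array([model_point(w, amplitude, bg, modes, t_k, fwhm, eta) for w in grid])
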