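"""Phonon dispersion assembly and derived membrane observables.

Per-Q fit results are collected into longitudinal and transverse acoustic
branches omega(Q), Gamma(Q).  From the branches the module computes the
observables a lipid-membrane IXS study reports:

* the high-frequency sound speed from the low-Q linear slope of a branch
  (origin-constrained weighted fit, since an acoustic branch has omega(0)=0);
* the position Q_min of the longitudinal dispersion minimum -- the
  quasi-Brillouin-zone boundary of the two-dimensional lipid lattice -- via a
  weighted parabola through the lowest points;
* the mean inter-chain distance d = 2*pi/Q_min and the area per lipid
  A_L = 2.64 * (9 d / 8)^2 (d in Angstrom);
* the damping ratio R(Q) = omega/Gamma with the over/critically/underdamped
  classification (R = 1 marks the crossover);
* the low-Q transverse phononic band gap: the Q below which the transverse
  branch does not propagate, and the implied dynamic cluster size
  d_gap = 2*pi/Q_gap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import MEV_NM_TO_M_PER_S, nm_inv_to_spacing_nm
from .errors import InsufficientDataError, InvalidInputError, InvalidParameterError
from .fitting import FitResult, ModeSelection

__all__ = [
    "DispersionBranch",
    "QMinResult",
    "GapResult",
    "DerivedQuantities",
    "assemble_branches",
    "sound_speed",
    "find_q_min",
    "area_per_lipid",
    "damping_ratio",
    "classify_damping",
    "detect_phonon_gap",
    "cluster_size",
    "derive_quantities",
    "branches_to_frame",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class DispersionBranch:
    """One acoustic branch sampled on the measured Q grid.

    ``present`` flags the Q values where the mode was detected; omega/gamma
    are NaN where it was not.
    """

    q: np.ndarray
    omega: np.ndarray
    omega_err: np.ndarray
    gamma: np.ndarray
    gamma_err: np.ndarray
    present: np.ndarray
    label: str

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        for name in ("omega", "omega_err", "gamma", "gamma_err"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.q.shape:
                raise InvalidInputError("branch arrays must share one length")
            setattr(self, name, arr)
        self.present = np.asarray(self.present, dtype=bool)
        if self.present.shape != self.q.shape:
            raise InvalidInputError("branch arrays must share one length")
        if self.q.size == 0:
            raise InvalidInputError("empty branch")
        if np.any(np.diff(self.q) <= 0):
            raise InvalidInputError("q must be strictly increasing")
        if self.label not in ("longitudinal", "transverse"):
            raise InvalidInputError(f"unknown branch label {self.label!r}")

    def __len__(self) -> int:
        return self.q.size


@dataclass
class QMinResult:
    """Dispersion-minimum estimate; ``edge_flag`` marks an untrustworthy vertex
    (minimum at the window edge or non-convex fit)."""

    q_min: float
    stderr: float
    edge_flag: bool


@dataclass
class GapResult:
    """Transverse band-gap edge: midpoint between the largest absent Q of the
    contiguous low-Q gap and the first present Q above it."""

    q_gap: float
    last_absent_q: float
    first_present_q: float


@dataclass
class DerivedQuantities:
    """All derived observables of one analysed dataset (errors are 1 s.d.)."""

    sound_speed_longitudinal: float | None = None
    sound_speed_longitudinal_err: float | None = None
    sound_speed_transverse: float | None = None
    sound_speed_transverse_err: float | None = None
    q_min: float | None = None
    q_min_err: float | None = None
    q_min_edge_flag: bool = False
    d_angstrom: float | None = None
    area_per_lipid: float | None = None
    area_per_lipid_err: float | None = None
    q_gap: float | None = None
    d_gap_nm: float | None = None
    d_gap_interval_nm: tuple[float, float] | None = None
    damping_ratio_longitudinal: list = field(default_factory=list)
    damping_ratio_transverse: list = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {}
        for key, val in self.__dict__.items():
            if isinstance(val, tuple):
                val = list(val)
            out[key] = val
        return out


# ---------------------------------------------------------------------------
# branch assembly
# ---------------------------------------------------------------------------

def assemble_branches(results: Sequence[tuple[FitResult, ModeSelection]]):
    """Collect per-Q (chosen) fits into the two acoustic branches.

    ``results`` pairs each chosen :class:`FitResult` with its
    :class:`ModeSelection`.  The longitudinal branch is populated wherever a
    longitudinal-labelled mode exists; the transverse branch only where the
    two-mode model was selected, so its ``present`` flags encode the phononic
    gap.  Duplicate Q values or an empty input raise.
    """
    results = list(results)
    if not results:
        raise InvalidInputError("no fit results to assemble")
    results = sorted(results, key=lambda pair: pair[0].q)
    qs = np.array([fit.q for fit, _ in results], dtype=float)
    if np.any(np.diff(qs) <= 0):
        raise InvalidInputError("duplicate Q values in fit results")

    n = qs.size
    data = {
        label: {k: np.full(n, np.nan) for k in ("omega", "omega_err", "gamma", "gamma_err")}
        | {"present": np.zeros(n, dtype=bool)}
        for label in ("longitudinal", "transverse")
    }
    for i, (fit, selection) in enumerate(results):
        for j, mode in enumerate(fit.params.modes):
            label = mode.branch_label
            if label not in data:
                continue
            if label == "transverse" and selection.chosen_n_modes < 2:
                continue
            err = fit.mode_uncertainties(j)
            d = data[label]
            d["omega"][i] = mode.omega0
            d["gamma"][i] = mode.gamma
            d["omega_err"][i] = err[0]
            d["gamma_err"][i] = err[1]
            d["present"][i] = True

    return tuple(
        DispersionBranch(q=qs, label=label, **data[label])
        for label in ("longitudinal", "transverse")
    )


# ---------------------------------------------------------------------------
# derived observables
# ---------------------------------------------------------------------------

def sound_speed(branch: DispersionBranch, q_linear_max: float) -> tuple[float, float]:
    """High-frequency sound speed from the low-Q linear slope, in m/s.

    Weighted least squares of omega = s * Q through the origin over the
    present points with Q <= ``q_linear_max``; the slope (meV*nm) is converted
    with C = 1519.27 m/s per meV*nm.  Returns (speed, 1-sigma error).
    """
    sel = branch.present & (branch.q <= q_linear_max) & np.isfinite(branch.omega)
    if np.count_nonzero(sel) < 2:
        raise InsufficientDataError(
            f"need >= 2 present points with q <= {q_linear_max}")
    q, w_val = branch.q[sel], branch.omega[sel]
    err = branch.omega_err[sel]
    have_errors = np.all(np.isfinite(err)) and np.all(err > 0)
    weights = 1.0 / err**2 if have_errors else np.ones_like(q)
    denom = float(np.sum(weights * q * q))
    slope = float(np.sum(weights * q * w_val)) / denom
    if have_errors:
        slope_var = 1.0 / denom
    else:
        resid = w_val - slope * q
        slope_var = float(np.sum(resid**2)) / max(q.size - 1, 1) / denom
    return slope * MEV_NM_TO_M_PER_S, float(np.sqrt(slope_var)) * MEV_NM_TO_M_PER_S


def find_q_min(branch: DispersionBranch,
               search_window: tuple[float, float],
               n_neighbors: int = 2) -> QMinResult:
    """Locate the dispersion minimum inside ``search_window`` (nm^-1).

    A weighted parabola is fitted through the lowest-omega present point and
    up to ``n_neighbors`` neighbours on each side; the vertex abscissa is the
    estimate.  A minimum sitting at the window edge, or a non-convex fit, is
    flagged rather than silently returned.  The 1-sigma error is propagated
    from the omega uncertainties through the vertex position.
    """
    lo, hi = search_window
    sel = np.flatnonzero(branch.present & (branch.q >= lo) & (branch.q <= hi)
                         & np.isfinite(branch.omega))
    if sel.size < 3:
        raise InsufficientDataError("need >= 3 present points inside the window")
    omega = branch.omega[sel]
    i_low = int(np.argmin(omega))
    edge = i_low == 0 or i_low == sel.size - 1

    i0, i1 = max(i_low - n_neighbors, 0), min(i_low + n_neighbors, sel.size - 1)
    idx = sel[i0 : i1 + 1]
    q, y = branch.q[idx], branch.omega[idx]
    err = branch.omega_err[idx]
    if not (np.all(np.isfinite(err)) and np.all(err > 0)):
        err = np.ones_like(y)

    def vertex_of(yv: np.ndarray) -> float:
        coeffs = np.polyfit(q, yv, 2, w=1.0 / err)
        a, b = coeffs[0], coeffs[1]
        if a <= 0:
            return np.nan
        return -b / (2.0 * a)

    vertex = vertex_of(y)
    if not np.isfinite(vertex) or not (lo <= vertex <= hi):
        edge = True

    # propagate omega uncertainties through the vertex by finite differences
    stderr = np.nan
    if np.isfinite(vertex):
        grads = np.zeros_like(y)
        for k in range(y.size):
            h = 1e-4 * max(err[k], 1e-6)
            y_hi = y.copy(); y_hi[k] += h
            y_lo = y.copy(); y_lo[k] -= h
            v_hi, v_lo = vertex_of(y_hi), vertex_of(y_lo)
            grads[k] = (v_hi - v_lo) / (2.0 * h) if np.isfinite(v_hi) and np.isfinite(v_lo) else 0.0
        stderr = float(np.sqrt(np.sum((grads * err) ** 2)))

    return QMinResult(q_min=float(vertex), stderr=stderr, edge_flag=bool(edge))


def area_per_lipid(q_min: float) -> float:
    """Area per lipid molecule in Angstrom^2 from the zone-boundary position.

    d = 2*pi/Q_min is the mean inter-chain distance; the simplified relation
    A_L = 2.64 * (9 d / 8)^2 (d in Angstrom) converts it to an in-plane area.
    """
    if q_min <= 0:
        raise InvalidParameterError("q_min must be positive")
    d_angstrom = 10.0 * nm_inv_to_spacing_nm(q_min)
    return 2.64 * (9.0 * d_angstrom / 8.0) ** 2


def damping_ratio(branch: DispersionBranch):
    """R(Q) = omega/Gamma with 1-sigma errors (NaN where the mode is absent)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        r = branch.omega / branch.gamma
        rel = np.sqrt((branch.omega_err / branch.omega) ** 2
                      + (branch.gamma_err / branch.gamma) ** 2)
        r_err = np.abs(r) * rel
    r = np.where(branch.present, r, np.nan)
    r_err = np.where(branch.present, r_err, np.nan)
    return r, r_err


def classify_damping(r: float, r_err: float = 0.0) -> str:
    """'overdamped' (R<1), 'critical' (R=1 within error) or 'underdamped' (R>1).

    Exactly one class applies to every finite R.
    """
    if not np.isfinite(r):
        raise InvalidParameterError("damping ratio must be finite")
    err = r_err if np.isfinite(r_err) else 0.0
    if abs(r - 1.0) <= err:
        return "critical"
    return "underdamped" if r > 1.0 else "overdamped"


def detect_phonon_gap(transverse: DispersionBranch) -> GapResult | None:
    """Low-Q phononic band gap of the transverse branch.

    The gap edge Q_gap is the midpoint between the largest Q of the contiguous
    low-Q run of absent points and the smallest present Q above it.  Returns
    ``None`` when the branch propagates at its lowest measured Q (no gap, the
    gel-phase case) or when no transverse mode was detected at all (with a
    warning).
    """
    present = transverse.present
    if present[0]:
        return None
    if not present.any():
        warnings.warn("no transverse branch detected at any Q; gap undefined",
                      stacklevel=2)
        return None
    first_present = int(np.argmax(present))
    last_absent = first_present - 1
    q_lo, q_hi = transverse.q[last_absent], transverse.q[first_present]
    return GapResult(q_gap=float(0.5 * (q_lo + q_hi)),
                     last_absent_q=float(q_lo), first_present_q=float(q_hi))


def cluster_size(q_gap: float) -> float:
    """Dynamic cluster size d_gap = 2*pi/Q_gap in nm."""
    return nm_inv_to_spacing_nm(q_gap)


# ---------------------------------------------------------------------------
# top-level derivation and tabulation
# ---------------------------------------------------------------------------

def derive_quantities(longitudinal: DispersionBranch,
                      transverse: DispersionBranch,
                      q_linear_max_longitudinal: float = 5.0,
                      q_linear_max_transverse: float = 5.0,
                      q_min_window: tuple[float, float] = (10.0, 20.0)) -> DerivedQuantities:
    """Compute every derived observable the analysis reports.

    Individual estimates that cannot be formed from the available points
    (e.g. a transverse speed when the branch is gapped at low Q) are left as
    None rather than raising.
    """
    out = DerivedQuantities()

    try:
        v, v_err = sound_speed(longitudinal, q_linear_max_longitudinal)
        out.sound_speed_longitudinal, out.sound_speed_longitudinal_err = v, v_err
    except InsufficientDataError:
        pass
    try:
        v, v_err = sound_speed(transverse, q_linear_max_transverse)
        out.sound_speed_transverse, out.sound_speed_transverse_err = v, v_err
    except InsufficientDataError:
        pass

    try:
        qmin = find_q_min(longitudinal, q_min_window)
        out.q_min, out.q_min_err = qmin.q_min, qmin.stderr
        out.q_min_edge_flag = qmin.edge_flag
        if np.isfinite(qmin.q_min) and qmin.q_min > 0:
            out.d_angstrom = 10.0 * nm_inv_to_spacing_nm(qmin.q_min)
            out.area_per_lipid = area_per_lipid(qmin.q_min)
            if np.isfinite(qmin.stderr):
                # A_L ~ q^-2  =>  sigma_A = 2 A sigma_q / q
                out.area_per_lipid_err = 2.0 * out.area_per_lipid * qmin.stderr / qmin.q_min
    except InsufficientDataError:
        pass

    gap = detect_phonon_gap(transverse)
    if gap is not None:
        out.q_gap = gap.q_gap
        out.d_gap_nm = cluster_size(gap.q_gap)
        out.d_gap_interval_nm = (cluster_size(gap.first_present_q),
                                 cluster_size(gap.last_absent_q))

    for branch, attr in ((longitudinal, "damping_ratio_longitudinal"),
                         (transverse, "damping_ratio_transverse")):
        r, r_err = damping_ratio(branch)
        rows = []
        for qi, ri, ei in zip(branch.q, r, r_err):
            if np.isfinite(ri):
                rows.append({"q_nm_inv": float(qi), "R": float(ri),
                             "R_err": float(ei) if np.isfinite(ei) else None,
                             "regime": classify_damping(ri, ei)})
        setattr(out, attr, rows)
    return out


def branches_to_frame(longitudinal: DispersionBranch,
                      transverse: DispersionBranch) -> pd.DataFrame:
    """Long-format dispersion table (one row per branch per Q)."""
    frames = []
    for branch in (longitudinal, transverse):
        r, r_err = damping_ratio(branch)
        frames.append(pd.DataFrame({
            "Q_nm_inv": branch.q,
            "branch": branch.label,
            "omega_meV": branch.omega,
            "omega_err": branch.omega_err,
            "gamma_meV": branch.gamma,
            "gamma_err": branch.gamma_err,
            "R": r,
            "present": branch.present,
        }))
    return pd.concat(frames, ignore_index=True)
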