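"""File formats, configuration and end-to-end orchestration.

Spectrum files are plain text: a ``#``-prefixed ``key: value`` header
(q_nm_inv, temperature_C, rf_fwhm_meV, rf_eta, units) followed by a CSV block
with columns energy_meV, intensity_counts, error_counts.  Floats are written
with ``repr`` so a write/read round trip is bit exact.

``run_pipeline`` orchestrates the full analysis -- simulate (or load) spectra,
select the mode count and fit at every Q, assemble dispersion branches and
derive the physical observables -- and serialises every intermediate so each
number in the summary traces to an artifact on disk.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .dispersion import assemble_branches, branches_to_frame, derive_quantities
from .errors import ConfigError, EmptyResultError, SpectrumParseError
from .fitting import FitResult, ModeCountSelector
from .lineshape import ResolutionFunction, Spectrum

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "write_dataset",
    "read_manifest_spectra",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

_MANDATORY_KEYS = ("q_nm_inv", "temperature_C", "rf_fwhm_meV", "rf_eta", "units")
_COLUMNS = "energy_meV,intensity_counts,error_counts"


# ---------------------------------------------------------------------------
# spectrum files
# ---------------------------------------------------------------------------

def write_spectrum(spectrum: Spectrum, path) -> Path:
    """Write one spectrum in the package's plain-text format."""
    path = Path(path)
    lines = [
        "# lipidixs spectrum v1",
        f"# q_nm_inv: {float(spectrum.q)!r}",
        f"# temperature_C: {float(spectrum.temperature_c)!r}",
        f"# rf_fwhm_meV: {float(spectrum.rf.fwhm)!r}",
        f"# rf_eta: {float(spectrum.rf.eta)!r}",
        f"# units: {_COLUMNS}",
        _COLUMNS,
    ]
    for e, y, s in zip(spectrum.energy, spectrum.intensity, spectrum.error):
        lines.append(f"{float(e)!r},{float(y)!r},{float(s)!r}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_spectrum(path) -> Spectrum:
    """Parse a spectrum file; malformed input raises :class:`SpectrumParseError`
    naming the offending line or key."""
    path = Path(path)
    header: dict[str, str] = {}
    rows = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    header[key.strip()] = value.strip()
                continue
            if line == _COLUMNS:
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise SpectrumParseError(
                    f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            try:
                rows.append(tuple(float(p) for p in parts))
            except ValueError as exc:
                raise SpectrumParseError(f"{path}:{lineno}: {exc}") from None

    for key in _MANDATORY_KEYS:
        if key not in header:
            raise SpectrumParseError(f"{path}: missing mandatory header key '{key}'")
    if not rows:
        raise SpectrumParseError(f"{path}: no data rows")

    data = np.asarray(rows, dtype=float)
    energy, intensity, error = data.T
    if np.any(~np.isfinite(error)) or np.any(error <= 0):
        raise SpectrumParseError(f"{path}: error column must be positive and finite")
    if np.any(np.diff(energy) <= 0):
        bad = int(np.flatnonzero(np.diff(energy) <= 0)[0])
        raise SpectrumParseError(
            f"{path}: energy grid not strictly increasing at row {bad + 2} "
            f"(energy {energy[bad + 1]!r} after {energy[bad]!r})")
    try:
        return Spectrum(
            q=float(header["q_nm_inv"]),
            energy=energy,
            intensity=intensity,
            error=error,
            temperature_c=float(header["temperature_C"]),
            rf=ResolutionFunction(float(header["rf_fwhm_meV"]), float(header["rf_eta"])),
        )
    except (ValueError, TypeError) as exc:
        raise SpectrumParseError(f"{path}: {exc}") from None


def write_dataset(spectra, manifest: dict, out_dir) -> Path:
    """Write a simulated dataset (one file per Q) plus its manifest.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for spectrum in spectra:
        name = f"spectrum_q{spectrum.q:06.2f}.csv"
        write_spectrum(spectrum, out_dir / name)
        files.append(name)
    manifest = dict(manifest, files=files)
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest_path


def read_manifest_spectra(manifest_path):
    """Load every spectrum listed in a dataset manifest.

    Returns ``(spectra, manifest_dict)``.
    """
    manifest_path = Path(manifest_path)
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        raise SpectrumParseError(f"{manifest_path}: invalid JSON ({exc})") from None
    if "files" not in manifest:
        raise SpectrumParseError(f"{manifest_path}: missing 'files' key")
    spectra = [read_spectrum(manifest_path.parent / name) for name in manifest["files"]]
    return spectra, manifest


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_SCENARIOS = {"gel_20C": synthetic.gel_scenario, "fluid_45C": synthetic.fluid_scenario,
              "gel": synthetic.gel_scenario, "fluid": synthetic.fluid_scenario}


@dataclass
class RunConfig:
    """Everything one pipeline run depends on.

    Exactly one of ``manifest`` (path to a dataset manifest.json) or
    ``scenario`` ('gel_20C' / 'fluid_45C') must be given.
    """

    output_dir: str = "lipidixs_run"
    manifest: str | None = None
    scenario: str | None = None
    seed: int = 0
    rel_improvement_threshold: float = 0.15
    vanish_sigma: float = 2.0
    n_restarts: int = 5
    q_linear_max_longitudinal: float = 5.0
    q_linear_max_transverse: float = 5.0
    q_min_window: tuple[float, float] = (10.0, 20.0)

    def __post_init__(self) -> None:
        if (self.manifest is None) == (self.scenario is None):
            raise ConfigError("exactly one of 'manifest' or 'scenario' must be set")
        if self.scenario is not None and self.scenario not in _SCENARIOS:
            raise ConfigError(f"unknown scenario {self.scenario!r}; "
                              f"expected one of {sorted(set(_SCENARIOS))}")
        for name in ("rel_improvement_threshold", "vanish_sigma", "n_restarts",
                     "q_linear_max_longitudinal", "q_linear_max_transverse"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        lo, hi = self.q_min_window
        if not (0 < lo < hi):
            raise ConfigError("q_min_window must be an increasing positive pair")
        self.q_min_window = (float(lo), float(hi))

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        """Load a YAML config; unknown keys are rejected, keyword overrides win."""
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "q_min_window" in raw:
            raw["q_min_window"] = tuple(raw["q_min_window"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _fit_result_to_dict(fit: FitResult) -> dict:
    return {
        "q_nm_inv": fit.q,
        "elastic_amplitude": fit.params.elastic_amplitude,
        "background": fit.params.background,
        "temperature_K": fit.params.temperature,
        "modes": [
            {
                "branch": m.branch_label,
                "omega_meV": m.omega0,
                "gamma_meV": m.gamma,
                "intensity": m.intensity,
                "omega_err": fit.mode_uncertainties(j)[0],
                "gamma_err": fit.mode_uncertainties(j)[1],
                "intensity_err": fit.mode_uncertainties(j)[2],
            }
            for j, m in enumerate(fit.params.modes)
        ],
        "param_errors": [float(e) for e in fit.param_errors],
        "reduced_chi2": fit.reduced_chi2,
        "n_free_params": fit.n_free_params,
        "converged": fit.converged,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write the report bundle to ``output_dir``.

    Artifacts: per-Q fits (fits.json), the mode-selection table
    (mode_selection.csv), the dispersion table (dispersion.csv), the derived
    observables (derived.json) and a human-readable summary.txt, plus a
    structured run.log recording seeds and thresholds.  Per-Q failures are
    logged and skipped; an empty surviving set raises
    :class:`EmptyResultError`.  Output is deterministic for identical config
    and seed (no timestamps are written).
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("lipidixs")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        logger.info("config: %s", {k: v for k, v in dataclasses.asdict(config).items()})

        if config.scenario is not None:
            scenario = _SCENARIOS[config.scenario]()
            spectra, manifest = synthetic.generate_dataset(scenario, config.seed)
            write_dataset(spectra, manifest, out_dir / "dataset")
        else:
            spectra, manifest = read_manifest_spectra(config.manifest)

        results = []
        selection_rows = []
        fit_dicts = []
        for i, spectrum in enumerate(spectra):
            try:
                selector = ModeCountSelector(
                    rel_improvement_threshold=config.rel_improvement_threshold,
                    vanish_sigma=config.vanish_sigma,
                    n_restarts=config.n_restarts,
                    random_state=int(np.random.SeedSequence([config.seed, i]).generate_state(1)[0] % (2**31)),
                ).fit(spectrum)
            except Exception:
                logger.exception("fit failed at q=%.3f; skipping", spectrum.q)
                continue
            sel = selector.selection_
            results.append((selector.best_fit_, sel))
            fit_dicts.append(_fit_result_to_dict(selector.best_fit_))
            selection_rows.append({
                "Q_nm_inv": spectrum.q,
                "chosen_n_modes": sel.chosen_n_modes,
                "red_chi2_one": sel.chi2_one,
                "red_chi2_two": sel.chi2_two,
                "vanished": sel.vanished,
                "two_hump_flag": sel.two_hump_flag,
            })
        if not results:
            raise EmptyResultError("every per-Q fit failed")

        longitudinal, transverse = assemble_branches(results)
        derived = derive_quantities(
            longitudinal, transverse,
            q_linear_max_longitudinal=config.q_linear_max_longitudinal,
            q_linear_max_transverse=config.q_linear_max_transverse,
            q_min_window=config.q_min_window,
        )

        (out_dir / "fits.json").write_text(json.dumps(fit_dicts, indent=2) + "\n")
        selection_df = pd.DataFrame(selection_rows)
        selection_df.to_csv(out_dir / "mode_selection.csv", index=False)
        dispersion_df = branches_to_frame(longitudinal, transverse)
        dispersion_df.to_csv(out_dir / "dispersion.csv", index=False)
        derived_dict = derived.to_dict()
        (out_dir / "derived.json").write_text(json.dumps(derived_dict, indent=2) + "\n")

        summary = _render_summary(config, selection_df, derived_dict)
        (out_dir / "summary.txt").write_text(summary)
        logger.info("pipeline complete: %d/%d Q values analysed",
                    len(results), len(spectra))
        return {
            "output_dir": str(out_dir),
            "n_analysed": len(results),
            "n_input": len(spectra),
            "derived": derived_dict,
            "selection": selection_rows,
        }
    finally:
        root.removeHandler(handler)
        handler.close()


def _render_summary(config: RunConfig, selection_df: pd.DataFrame,
                    derived: dict) -> str:
    lines = ["lipidixs pipeline summary", "=" * 25, ""]
    source = config.scenario if config.scenario else config.manifest
    lines.append(f"input: {source}   seed: {config.seed}")
    lines.append(f"thresholds: rel_improvement={config.rel_improvement_threshold} "
                 f"vanish_sigma={config.vanish_sigma}")
    lines.append("")
    lines.append("per-Q mode selection")
    lines.append(selection_df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    lines.append("")
    lines.append("derived quantities")

    def fmt(value, unit=""):
        if value is None:
            return "not determined"
        return f"{value:.4g}{unit}"

    v, e = derived["sound_speed_longitudinal"], derived["sound_speed_longitudinal_err"]
    lines.append(f"  longitudinal sound speed: {fmt(v)} +/- {fmt(e)} m/s")
    v, e = derived["sound_speed_transverse"], derived["sound_speed_transverse_err"]
    lines.append(f"  transverse sound speed:   {fmt(v)} +/- {fmt(e)} m/s")
    lines.append(f"  Q_min: {fmt(derived['q_min'])} +/- {fmt(derived['q_min_err'])} nm^-1"
                 + ("  [edge-flagged]" if derived["q_min_edge_flag"] else ""))
    lines.append(f"  inter-chain distance d: {fmt(derived['d_angstrom'])} Angstrom")
    lines.append(f"  area per lipid A_L: {fmt(derived['area_per_lipid'])} "
                 f"+/- {fmt(derived['area_per_lipid_err'])} Angstrom^2")
    if derived["q_gap"] is None:
        lines.append("  transverse phononic gap: none detected")
    else:
        lo, hi = derived["d_gap_interval_nm"]
        lines.append(f"  transverse phononic gap edge Q_gap: {fmt(derived['q_gap'])} nm^-1")
        lines.append(f"  dynamic cluster size d_gap: {fmt(derived['d_gap_nm'])} nm "
                     f"(interval {fmt(lo)}-{fmt(hi)} nm)")
    lines.append("")
    return "\n".join(lines) + "\n"
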