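"""End-to-end orchestration: distances -> selection -> ACF -> fit -> rates.

The pipeline chains the library modules in the order a relaxation
analysis of an MD trajectory proceeds: measure the metal--proton
distance per frame, compress the series with the Haar wavelet selection
to pick representative conformations, compute and fit the fluctuation
autocorrelation, evaluate the spectral density and dipolar constant,
and report T1, T2, R1, R2.  Every stage writes its artifact to the
output directory together with the configuration hash and seed so a
rerun with the same configuration is reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import owsca
from .correlation import (
    FitOptions,
    ModelFreeFit,
    autocorrelation_binned,
    autocorrelation_fft,
)
from .owsca import SelectionPolicy, SelectionResult, select_conformations
from .relaxation import (
    PhysicalSettings,
    RelaxationResult,
    build_report,
    dipolar_constant,
    larmor_frequency,
    relaxation_rates,
    write_report,
)
from .trajectory import (
    DistanceTrajectory,
    extract_min_vh_distances,
    read_distance_series,
    write_distance_series,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_config"]

logger = logging.getLogger("spinrelax")

_COORD_SUFFIXES = (".pdb", ".xyz")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one relaxation run needs.

    ``acf_source`` picks whether the autocorrelation is computed on the
    full trajectory or on the wavelet-selected conformations;
    ``selected_acf_mode`` chooses between the lag-binned estimate on the
    true (non-uniform) selection times ("binned", default) and
    re-gridding the selection onto a uniform effective stride
    ("regrid").
    """

    input_path: str
    input_format: str = "auto"  # csv, tsv, pdb, xyz
    label: str = "system"
    dt_ps: float = 100.0  # stride assigned to coordinate inputs
    policy: SelectionPolicy = field(default_factory=SelectionPolicy)
    fit_options: FitOptions = field(default_factory=FitOptions)
    settings: PhysicalSettings = field(default_factory=PhysicalSettings)
    equation_set: str = "as_printed"
    acf_source: str = "full"
    selected_acf_mode: str = "binned"
    output_dir: str = "spinrelax_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.acf_source not in ("full", "selected"):
            raise ValueError(
                f"acf_source must be 'full' or 'selected', got "
                f"{self.acf_source!r}"
            )
        if self.selected_acf_mode not in ("binned", "regrid"):
            raise ValueError(
                "selected_acf_mode must be 'binned' or 'regrid', got "
                f"{self.selected_acf_mode!r}"
            )

    def to_json_dict(self) -> dict:
        return {
            "input_path": str(self.input_path),
            "input_format": self.input_format,
            "label": self.label,
            "dt_ps": self.dt_ps,
            "policy": {
                "energy_fraction": self.policy.energy_fraction,
                "min_keep": self.policy.min_keep,
                "max_keep": self.policy.max_keep,
                "max_level": self.policy.max_level,
            },
            "fit_options": {
                "max_lag_fraction": self.fit_options.max_lag_fraction,
            },
            "settings": self.settings.to_json_dict(),
            "equation_set": self.equation_set,
            "acf_source": self.acf_source,
            "selected_acf_mode": self.selected_acf_mode,
            "seed": self.seed,
        }

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_json_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML or JSON mapping."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    policy = SelectionPolicy(**raw.pop("policy", {}))
    fit_options = FitOptions(**raw.pop("fit_options", {}))
    settings = PhysicalSettings(**raw.pop("settings", {}))
    return PipelineConfig(
        policy=policy, fit_options=fit_options, settings=settings, **raw
    )


@dataclass(frozen=True)
class PipelineResult:
    """Artifacts of one pipeline run."""

    trajectory: DistanceTrajectory
    selection: SelectionResult
    fit: ModelFreeFit
    relaxation: RelaxationResult
    phi: float
    config: PipelineConfig


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _run_stage(name: str, fn):
    logger.debug("stage %s", name)
    try:
        return fn()
    except Exception as exc:
        logger.error("stage %s failed: %s", name, exc)
        raise PipelineStageError(name, exc) from exc


def _load_trajectory(config: PipelineConfig) -> DistanceTrajectory:
    path = Path(config.input_path)
    fmt = config.input_format
    if fmt == "auto":
        suffix = path.suffix.lower()
        fmt = suffix.lstrip(".") if suffix else "csv"
    if fmt in ("csv", "tsv"):
        return read_distance_series(path, fmt=fmt)
    if fmt in ("pdb", "xyz"):
        return extract_min_vh_distances(path, dt_ps=config.dt_ps)
    raise ValueError(f"unsupported input format {fmt!r}")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage in order and write all artifacts.

    Deterministic stages are bit-identical on rerun with the same
    configuration; the seed only matters when the input itself is
    generated.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config": config.to_json_dict(), "config_hash": config.config_hash}

    traj = _run_stage("read", lambda: _load_trajectory(config))
    write_distance_series(traj, out / "distances.csv")
    logger.info(
        "%s: %d frames, dt=%g ps, phi=%.3f A",
        config.label, traj.n_frames, traj.dt, traj.phi,
    )

    selection = _run_stage(
        "select", lambda: select_conformations(traj, config.policy)
    )
    owsca.write_selection(
        selection, out / "selection.txt", out / "selection.json"
    )
    logger.info(
        "selection: %d of %d frames (%.1f%% fluctuation energy captured)",
        selection.n_selected, traj.n_frames,
        100.0 * selection.energy_fraction_captured,
    )

    def _acf_stage():
        if config.acf_source == "full":
            return autocorrelation_fft(traj), traj.phi
        idx = selection.selected_frame_ids
        phi_sel = float(traj.distances[idx].mean())
        if config.selected_acf_mode == "binned":
            return autocorrelation_binned(traj, idx), phi_sel
        from .trajectory import restrict_to_selection

        return autocorrelation_fft(restrict_to_selection(traj, idx)), phi_sel

    acf, phi = _run_stage("acf", _acf_stage)
    acf.write_tsv(out / "acf.tsv")

    fit = _run_stage("fit", lambda: _fit(acf, config))
    fit.write_json(out / "fit.json", extra=meta)
    logger.info(
        "model-free fit: tau_c=%.1f ps, S2=%.3f, tau_e=%.1f ps (rms %.2e)",
        fit.params.tau_c, fit.params.S2, fit.params.tau_e, fit.residual_rms,
    )

    def _relax_stage():
        K = dipolar_constant(phi, config.settings)
        return K, relaxation_rates(
            fit.params, K, config.settings, config.equation_set
        )

    K, relax = _run_stage("relax", _relax_stage)
    w0 = larmor_frequency(config.settings)
    logger.info(
        "omega0=%.4g 1/s, K=%.4g 1/s^2, equation set %s: "
        "T1=%.4g s, T2=%.4g s, R1=%.4g 1/s, R2=%.4g 1/s",
        w0, K.K, config.equation_set, relax.T1, relax.T2, relax.R1, relax.R2,
    )
    report = build_report([(config.label, relax, phi)])
    write_report(report, out / "relaxation.tsv", out / "relaxation.json")
    with open(out / "run.json", "w") as fh:
        json.dump(
            {
                **meta,
                "phi_angstrom": phi,
                "n_selected": selection.n_selected,
                "fit": fit.to_json_dict(),
                "relaxation": relax.to_json_dict(),
            },
            fh,
            indent=2,
        )
    return PipelineResult(
        trajectory=traj,
        selection=selection,
        fit=fit,
        relaxation=relax,
        phi=phi,
        config=config,
    )


def _fit(acf, config: PipelineConfig) -> ModelFreeFit:
    from .correlation import fit_model_free

    return fit_model_free(acf, config.fit_options)
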