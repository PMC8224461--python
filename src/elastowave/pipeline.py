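"""End-to-end synthetic experiments: phantom repeatability and anisotropy.

Each experiment simulates repeated removal/replacement trials on a set of
samples with known ground-truth elasticity, pushes every trial through the
full modality chain (encode -> displacement -> spatiotemporal map ->
group velocity -> Young's modulus), and summarizes agreement and
repeatability with Bland-Altman, ICC and MAPE statistics.  Everything is
deterministic given the configured seed.
"""
from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field as dc_field
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .displacement import loupas_displacement, oce_phase_to_displacement
from .elasticity import rayleigh_shear_ratio, ym_rayleigh, ym_shear
from .errors import ConfigurationError, EstimationError, ParameterError
from .stats import bland_altman, icc, mape
from .synthetic import (
    anisotropic_speed_profile,
    default_pulse,
    encode_oce_frames,
    encode_us_iq,
    make_displacement_field,
    make_trial_ensemble,
    oce_geometry,
    use_geometry,
)
from .types import MaterialSpec, PulseSpec, SpatioTemporalMap, TrialEnsemble, VelocityEstimate
from .velocimetry import estimate_group_velocity
from .wavefield import depth_average, directional_filter, split_bilateral

__all__ = [
    "ExperimentConfig",
    "ExperimentReport",
    "run_phantom_experiment",
    "run_anisotropy_experiment",
    "measure_trial_speed",
    "recompute_summaries",
]

log = logging.getLogger("elastowave.pipeline")

#: Default phantom set: four stiffness levels spanning the soft-tissue
#: gelatin range (~10-40 kPa, shear speeds ~1.8-3.7 m/s), two phantoms each.
DEFAULT_MATERIALS = tuple(
    MaterialSpec(young_modulus=e * 1e3, label=f"{lbl}-{i}")
    for lbl, e in (("8pct", 10.0), ("10pct", 17.0), ("12pct", 27.0), ("14pct", 40.0))
    for i in (1, 2)
)


@dataclass
class ExperimentConfig:
    """Parameters of a synthetic side-by-side elastography experiment."""

    materials: Sequence[MaterialSpec] = DEFAULT_MATERIALS
    modalities: Sequence[str] = ("OCE", "USE")
    n_trials: int = 5
    intertrial_rel_sd: float = 0.015  # removal/replacement jitter, fraction of speed
    oce_phase_noise_sd: float = 0.1  # rad
    use_noise_rel: float = 0.1  # fraction of IQ signal amplitude
    seed: int = 0
    correction_method: str = "exact_secular"  # Rayleigh-to-shear correction
    use_directional_filter: bool = True  # f-k filtering in the USE chain
    oce_directional_filter: bool = False  # the OCE chain splits sides only
    depth_kernel: int = 5
    ensemble_kernel: int = 2
    exclusion: float = 0.5e-3  # near-field exclusion zone, m
    density: float = 1000.0  # kg/m^3
    poisson_ratio: float = 0.5
    oce_pulse_amplitude: Optional[float] = None  # m; None -> modality default
    use_pulse_amplitude: Optional[float] = None
    oce_geometry_kwargs: dict = dc_field(default_factory=dict)
    use_geometry_kwargs: dict = dc_field(default_factory=dict)
    # anisotropy experiment inputs (fiber-parallel / perpendicular speeds)
    c_parallel: Optional[float] = None
    c_perpendicular: Optional[float] = None
    angles: Sequence[float] = (0.0, 45.0, 90.0)

    def __post_init__(self) -> None:
        if len(self.materials) < 1:
            raise ConfigurationError("need at least one material")
        if self.n_trials < 2:
            raise ConfigurationError("need at least 2 trials per sample")
        for m in self.modalities:
            if m not in ("OCE", "USE"):
                raise ConfigurationError(f"unknown modality {m!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["materials"] = [asdict(m) for m in self.materials]
        d["modalities"] = list(self.modalities)
        d["angles"] = list(self.angles)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        mats = []
        for m in d.pop("materials", []):
            m = dict(m)
            if "speed" in m:  # ground truth given as shear speed
                rho = m.get("density", 1000.0)
                m["young_modulus"] = 3.0 * rho * float(m.pop("speed")) ** 2
            mats.append(MaterialSpec(**m))
        if mats:
            d["materials"] = mats
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class ExperimentReport:
    """Per-trial results plus recomputable summary statistics."""

    trials: pd.DataFrame
    summaries: dict
    config_hash: str
    seed: int
    package_version: str
    kind: str = "phantom"

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "config_hash": self.config_hash,
            "seed": self.seed,
            "package_version": self.package_version,
            "summaries": self.summaries,
            "trials": self.trials.to_dict(orient="records"),
        }

    def save(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
        self.trials.to_csv(os.path.join(out_dir, "trials.csv"), index=False)
        rows = []
        for modality, s in self.summaries.get("per_modality", {}).items():
            for variant in ("ba_raw", "ba_normalized"):
                for mean, diff in s[variant]["points"]:
                    rows.append(
                        {"modality": modality, "variant": variant, "mean": mean,
                         "difference": diff}
                    )
        pd.DataFrame(rows).to_csv(os.path.join(out_dir, "ba_points.csv"), index=False)


def _child_seed(*keys: int) -> int:
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2**31))


def _estimate_with_directional_filter(
    st_map: SpatioTemporalMap, exclusion: float
) -> VelocityEstimate:
    """USE-style estimation: isolate each propagation direction in the f-k
    domain, then fit the matching side of the split map."""
    side_ests = []
    for direction in ("left", "right"):
        filtered = directional_filter(st_map, direction)
        left, right = split_bilateral(filtered, exclusion=exclusion)
        side = left if direction == "left" else right
        if side is None:
            continue
        try:
            side_ests.append(estimate_group_velocity(side, exclusion=exclusion))
        except EstimationError:
            continue
    if not side_ests:
        raise EstimationError("directional-filtered estimation failed on both sides")
    speeds = {}
    fits = []
    for est in side_ests:
        for f in est.side_fits:
            speeds[f.side] = f.speed
            fits.append(f)
    valid = [v for v in speeds.values() if v is not None]
    return VelocityEstimate(
        speed=float(np.mean(valid)),
        side_speeds=(speeds.get("left"), speeds.get("right")),
        slope=float(np.mean([e.slope for e in side_ests])),
        slope_se=float(np.mean([e.slope_se for e in side_ests])),
        r_squared=float(np.mean([e.r_squared for e in side_ests])),
        side_fits=tuple(fits),
    )


def measure_trial_speed(
    modality: str,
    wave_speed: float,
    config: ExperimentConfig,
    seed: int,
    pulse: Optional[PulseSpec] = None,
) -> VelocityEstimate:
    """Simulate one acquisition at ``wave_speed`` and run the full modality
    chain back to a group-velocity estimate (of the simulated wave itself:
    the Rayleigh-to-shear conversion is the caller's concern)."""
    if modality == "OCE":
        geom = oce_geometry(**config.oce_geometry_kwargs)
    else:
        geom = use_geometry(**config.use_geometry_kwargs)
    amplitude = (
        config.oce_pulse_amplitude if modality == "OCE" else config.use_pulse_amplitude
    )
    pulse = pulse or default_pulse(modality, amplitude=amplitude)
    fld = make_displacement_field(geom, wave_speed, pulse, seed=seed)
    if modality == "OCE":
        frames = encode_oce_frames(fld, noise_sd_phase=config.oce_phase_noise_sd, seed=seed)
        disp = oce_phase_to_displacement(frames)
        st_map = depth_average(disp)
        if config.oce_directional_filter:
            return _estimate_with_directional_filter(st_map, config.exclusion)
        return estimate_group_velocity(st_map, exclusion=config.exclusion)
    frames = encode_us_iq(fld, noise_sd=config.use_noise_rel, seed=seed)
    disp = loupas_displacement(
        frames, depth_kernel=config.depth_kernel, ensemble_kernel=config.ensemble_kernel
    )
    st_map = depth_average(disp)
    if config.use_directional_filter:
        return _estimate_with_directional_filter(st_map, config.exclusion)
    return estimate_group_velocity(st_map, exclusion=config.exclusion)


def _run_samples(
    config: ExperimentConfig,
    samples: Sequence[tuple[str, float, Optional[float]]],
) -> pd.DataFrame:
    """Run all trials for ``samples``: (sample_id, true shear speed, true E)."""
    ratio = rayleigh_shear_ratio(config.poisson_ratio, config.correction_method)
    rows = []
    for si, (sample_id, c_true, e_true) in enumerate(samples):
        ens = make_trial_ensemble(
            base_speed=c_true,
            n_trials=config.n_trials,
            intertrial_sd=config.intertrial_rel_sd * c_true,
            seed=_child_seed(config.seed, si, 999),
            sample_id=sample_id,
        )
        for ti, c_trial in enumerate(ens.speeds):
            for mi, modality in enumerate(config.modalities):
                seed = _child_seed(config.seed, si, ti, mi)
                # OCE tracks the surface (Rayleigh) wave, slower than shear
                wave_speed = c_trial * ratio if modality == "OCE" else c_trial
                row = {
                    "sample_id": sample_id,
                    "trial": ti + 1,
                    "modality": modality,
                    "true_shear_speed_mps": c_trial,
                    "true_modulus_kpa": (e_true / 1e3) if e_true is not None else np.nan,
                }
                try:
                    est = measure_trial_speed(modality, wave_speed, config, seed)
                    if modality == "OCE":
                        shear_speed = est.speed / ratio
                        modulus = ym_rayleigh(
                            est.speed, config.poisson_ratio, config.density
                        ).young_modulus
                    else:
                        shear_speed = est.speed
                        modulus = ym_shear(est.speed, config.density).young_modulus
                    row.update(
                        raw_speed_mps=est.speed,
                        shear_speed_mps=shear_speed,
                        modulus_kpa=modulus / 1e3,
                        r_squared=est.r_squared,
                        status="ok",
                    )
                except (EstimationError, ParameterError) as exc:
                    log.warning(
                        "trial failed sample=%s trial=%d modality=%s seed=%d: %s",
                        sample_id, ti + 1, modality, seed, exc,
                    )
                    row.update(
                        raw_speed_mps=np.nan,
                        shear_speed_mps=np.nan,
                        modulus_kpa=np.nan,
                        r_squared=np.nan,
                        status=f"failed: {exc}",
                    )
                rows.append(row)
                log.info(
                    "sample=%s trial=%d modality=%s seed=%d speed=%.4f",
                    sample_id, ti + 1, modality, seed, row.get("shear_speed_mps", np.nan),
                )
    return pd.DataFrame(rows)


def _summarize(trials: pd.DataFrame, config: ExperimentConfig) -> dict:
    per_modality: dict[str, Any] = {}
    for modality in config.modalities:
        sub = trials[(trials.modality == modality) & (trials.status == "ok")]
        if sub.empty:
            per_modality[modality] = {"error": "no successful trials"}
            continue
        ensembles = [
            TrialEnsemble(sample_id=str(sid), speeds=grp.shear_speed_mps.to_numpy())
            for sid, grp in sub.groupby("sample_id", sort=False)
            if len(grp) >= 2
        ]
        ba_raw = bland_altman(ensembles, normalized=False)
        ba_norm = bland_altman(ensembles, normalized=True)
        summary: dict[str, Any] = {
            "ba_raw": _ba_dict(ba_raw),
            "ba_normalized": _ba_dict(ba_norm),
            "per_sample_mean_speed_mps": {
                e.sample_id: float(e.speeds.mean()) for e in ensembles
            },
        }
        pivot = sub.pivot_table(
            index="sample_id", columns="trial", values="shear_speed_mps"
        )
        if pivot.notna().all().all() and pivot.shape[0] >= 2 and pivot.shape[1] >= 2:
            r = icc(pivot.to_numpy())
            summary["icc"] = {
                "value": r.icc,
                "model": r.model_label,
                "var_between_subjects": r.var_between_subjects,
                "var_between_raters": r.var_between_raters,
                "var_residual": r.var_residual,
            }
        ref = sub.groupby("sample_id", sort=False).true_modulus_kpa.mean()
        meas = sub.groupby("sample_id", sort=False).modulus_kpa.mean()
        if ref.notna().all():
            summary["mape_modulus_pct"] = mape(meas.to_numpy(), ref.to_numpy())
            summary["mape_speed_pct"] = mape(
                sub.shear_speed_mps.to_numpy(), sub.true_shear_speed_mps.to_numpy()
            )
        per_modality[modality] = summary
    return {"per_modality": per_modality}


def _ba_dict(ba) -> dict:
    return {
        "bias": ba.bias,
        "loa_upper": ba.loa_upper,
        "loa_lower": ba.loa_lower,
        "sd_differences": ba.sd_differences,
        "normalized": ba.normalized,
        "points": [[float(a), float(b)] for a, b in ba.points],
    }


def run_phantom_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Repeatability/accuracy experiment on homogeneous phantoms.

    Every material's ground-truth shear speed follows from its modulus as
    ``c = sqrt(E / (3 rho))``; each of ``n_trials`` removal/replacement
    trials jitters that speed, is acquired and analyzed by each modality
    chain, and converted back to a modulus.  Summaries: Bland-Altman (raw
    and normalized), ICC(2,1) with samples as subjects and trials as raters,
    and MAPE of the recovered moduli against ground truth.
    """
    samples = [
        (m.label or f"sample{i}", m.shear_speed, m.young_modulus)
        for i, m in enumerate(config.materials)
    ]
    trials = _run_samples(config, samples)
    _require_some_success(trials)
    return ExperimentReport(
        trials=trials,
        summaries=_summarize(trials, config),
        config_hash=config.config_hash,
        seed=config.seed,
        package_version=__version__,
        kind="phantom",
    )


def run_anisotropy_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Fiber-angle experiment on an anisotropic sample.

    Ground-truth speed at each angle follows the elliptical profile between
    the fiber-parallel and fiber-perpendicular speeds; each angle is measured
    ``n_trials`` times per modality.  The report adds per-angle mean +- SD
    and an ICC with angles as subjects.
    """
    if config.c_parallel is None or config.c_perpendicular is None:
        raise ConfigurationError(
            "anisotropy experiment needs c_parallel and c_perpendicular"
        )
    samples = []
    for angle in config.angles:
        c = anisotropic_speed_profile(config.c_parallel, config.c_perpendicular, angle)
        samples.append((f"angle{angle:g}", c, None))
    trials = _run_samples(config, samples)
    _require_some_success(trials)
    summaries = _summarize(trials, config)
    for modality in config.modalities:
        sub = trials[(trials.modality == modality) & (trials.status == "ok")]
        if sub.empty:
            continue
        g = sub.groupby("sample_id", sort=False).shear_speed_mps
        summaries["per_modality"][modality]["per_angle"] = {
            sid: {"mean_mps": float(m), "sd_mps": float(s)}
            for sid, m, s in zip(g.mean().index, g.mean(), g.std(ddof=1))
        }
    return ExperimentReport(
        trials=trials,
        summaries=summaries,
        config_hash=config.config_hash,
        seed=config.seed,
        package_version=__version__,
        kind="anisotropy",
    )


def _require_some_success(trials: pd.DataFrame) -> None:
    ok_per_sample = trials[trials.status == "ok"].groupby("sample_id").size()
    missing = set(trials.sample_id) - set(ok_per_sample.index)
    if missing:
        raise EstimationError(f"no successful trial for sample(s): {sorted(missing)}")


def recompute_summaries(report: ExperimentReport, config: ExperimentConfig) -> dict:
    """Recompute the summary block from the report's own per-trial table
    (self-consistency audit)."""
    return _summarize(report.trials, config)
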