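"""In-silico sequential-imaging experiments from a single config file.

Orchestrates the full label-image-remove cycle: simulate each round's
acquisition (with residual carryover from the previous round), localize and
filter, register rounds to the first round's reference image, render, and
report cross-talk per invader step and accepted-localization counts per
round.  Every stochastic stage is driven by seeds derived deterministically
from the experiment seed, so re-running from the echoed config reproduces the
report bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .kinetics import KineticsModel, fit_trace
from .localize import FitConfig, localize_stack
from .quantify import crosstalk, register_rounds, render, round_counts, movie_to_trace
from .simulate import (
    CameraModel,
    ClusterSpec,
    FilamentSpec,
    GroundTruthScene,
    PhotophysicsParams,
    RoundSpec,
    make_scene,
    simulate_round,
    simulate_timecourse_movie,
)

__all__ = ["ExperimentConfig", "ExperimentReport", "ConfigError",
           "validate_config", "run_experiment", "parse_quantity"]


class ConfigError(ValueError):
    """Config validation failed; ``errors`` lists each violation."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid config:\n  " + "\n  ".join(errors))


class StageError(RuntimeError):
    """A pipeline stage failed; names the stage and round."""


_UNIT_SCALES = {
    "concentration": {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "μM": 1e-6,
                      "µM": 1e-6, "nM": 1e-9, "pM": 1e-12},
    "length_um": {"um": 1.0, "μm": 1.0, "µm": 1.0, "nm": 1e-3, "mm": 1e3},
    "time_s": {"s": 1.0, "sec": 1.0, "ms": 1e-3, "min": 60.0, "h": 3600.0},
    "rate_hz": {"Hz": 1.0, "kHz": 1e3},
}

_QTY = re.compile(r"^\s*([+-]?\d+(?:\.\d*)?(?:[eE][+-]?\d+)?)\s*([^\s]*)\s*$")


def parse_quantity(value, kind: str) -> float:
    """Normalize a config quantity to its base unit.

    Numbers pass through (assumed already in the base unit: molar,
    micrometer, second, or hertz).  Strings may carry a unit suffix, e.g.
    ``"4.87 uM"`` -> 4.87e-6 M, ``"5 min"`` -> 300 s, ``"106.7 nm"`` ->
    0.1067 um.
    """
    if isinstance(value, (int, float)):
        return float(value)
    m = _QTY.match(str(value))
    if not m:
        raise ValueError(f"cannot parse quantity {value!r}")
    num, unit = float(m.group(1)), m.group(2)
    if not unit:
        return num
    scales = _UNIT_SCALES[kind]
    if unit not in scales:
        raise ValueError(f"unknown {kind} unit {unit!r} in {value!r}")
    return num * scales[unit]


@dataclass
class ExperimentConfig:
    """Validated, defaults-filled description of one in-silico experiment."""

    scene_structures: list
    rounds: list[RoundSpec]
    camera: CameraModel
    photophysics: PhotophysicsParams
    fit: FitConfig
    kinetics: KineticsModel
    field_size_um: tuple[float, float]
    n_frames: int = 2000
    background: float = 5.0
    psf_sigma_px: float = 1.3
    scene_seed: int = 0
    seed: int = 0
    stage_shifts_px: list[tuple[float, float]] = field(default_factory=list)
    crosstalk_check: bool = True
    timecourse: dict | None = None
    raw: dict = field(default_factory=dict)

    def target_ids(self) -> list[str]:
        out = []
        for s in self.scene_structures:
            if s.target_id not in out:
                out.append(s.target_id)
        return out


def _build_structures(entries, errors):
    out = []
    for i, e in enumerate(entries):
        kind = e.get("type")
        try:
            if kind == "filament":
                out.append(FilamentSpec(
                    target_id=str(e["target_id"]),
                    length_um=parse_quantity(e.get("length", 2.0), "length_um"),
                    site_spacing_um=parse_quantity(e.get("site_spacing", 0.02), "length_um"),
                    n=int(e.get("n", 1)),
                    start_um=tuple(e["start_um"]) if "start_um" in e else None,
                    angle_deg=e.get("angle_deg"),
                ))
            elif kind == "cluster":
                out.append(ClusterSpec(
                    target_id=str(e["target_id"]),
                    radius_um=parse_quantity(e.get("radius", 0.075), "length_um"),
                    mean_sites=float(e.get("mean_sites", 30.0)),
                    n=int(e.get("n", 10)),
                ))
            else:
                errors.append(f"scene.structures[{i}].type: expected "
                              f"'filament' or 'cluster', got {kind!r}")
        except KeyError as k:
            errors.append(f"scene.structures[{i}]: missing key {k}")
        except (TypeError, ValueError) as exc:
            errors.append(f"scene.structures[{i}]: {exc}")
    return out


def validate_config(source) -> ExperimentConfig:
    """Schema-check a config (path, YAML text, or dict), filling defaults and
    normalizing units; raises :class:`ConfigError` listing every violation
    with its key path."""
    if isinstance(source, dict):
        raw = source
    else:
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError(["config root must be a mapping"])

    errors: list[str] = []

    scene = raw.get("scene", {})
    structures = _build_structures(scene.get("structures", []), errors)
    if not structures:
        errors.append("scene.structures: at least one structure required")
    try:
        fs = scene.get("field_size_um", [6.8, 6.8])
        field_size = (float(fs[0]), float(fs[1]))
        if field_size[0] <= 0 or field_size[1] <= 0:
            errors.append("scene.field_size_um: must be > 0")
    except (TypeError, ValueError, IndexError):
        errors.append("scene.field_size_um: expected [x, y] in micrometers")
        field_size = (6.8, 6.8)

    cam_raw = dict(raw.get("camera", {}))
    camera = CameraModel()
    try:
        kwargs = {}
        if "pixel_size" in cam_raw:
            kwargs["pixel_size_um"] = parse_quantity(cam_raw.pop("pixel_size"), "length_um")
        if "frame_shape" in cam_raw:
            kwargs["frame_shape"] = tuple(int(v) for v in cam_raw.pop("frame_shape"))
        if "frame_rate" in cam_raw:
            kwargs["frame_rate_hz"] = parse_quantity(cam_raw.pop("frame_rate"), "rate_hz")
        kwargs.update({k: float(v) for k, v in cam_raw.items()
                       if k in ("em_gain", "adu_offset", "adu_per_electron",
                                "read_noise_adu", "pixel_size_um")})
        unknown = set(cam_raw) - set(kwargs)
        for k in sorted(unknown):
            errors.append(f"camera.{k}: unknown key")
        camera = CameraModel(**kwargs)
    except ValueError as exc:
        errors.append(f"camera: {exc}")

    try:
        photophysics = PhotophysicsParams(**raw.get("photophysics", {}))
    except (TypeError, ValueError) as exc:
        errors.append(f"photophysics: {exc}")
        photophysics = PhotophysicsParams()

    try:
        fit = FitConfig(**raw.get("fit", {}))
    except (TypeError, ValueError) as exc:
        errors.append(f"fit: {exc}")
        fit = FitConfig()

    kin_raw = dict(raw.get("kinetics", {}))
    try:
        if "invader_conc" in kin_raw:
            kin_raw["invader_conc"] = parse_quantity(kin_raw["invader_conc"], "concentration")
        if "t_invader" in kin_raw:
            kin_raw["t_invader"] = parse_quantity(kin_raw["t_invader"], "time_s")
        for key in ("k_disp", "bleach_rate", "residual_fraction"):
            if key in kin_raw:
                kin_raw[key] = float(kin_raw[key])  # YAML "1.0e5" arrives as str
        kin = KineticsModel(**kin_raw)
    except (TypeError, ValueError) as exc:
        errors.append(f"kinetics: {exc}")
        kin = KineticsModel()

    rounds: list[RoundSpec] = []
    shifts: list[tuple[float, float]] = []
    target_ids = {s.target_id for s in structures}
    for i, r in enumerate(raw.get("rounds", [])):
        try:
            spec = RoundSpec(
                round_index=int(r.get("round_index", i + 1)),
                target_id=str(r["target_id"]),
                label_prob=float(r.get("label_prob", 0.9)),
                carryover_residual=float(r.get("carryover_residual", 0.0)),
            )
            if spec.target_id not in target_ids:
                errors.append(
                    f"rounds[{i}].target_id: {spec.target_id!r} not in scene "
                    f"targets {sorted(target_ids)}"
                )
            rounds.append(spec)
            sh = r.get("stage_shift_px", [0.0, 0.0])
            shifts.append((float(sh[0]), float(sh[1])))
        except KeyError as k:
            errors.append(f"rounds[{i}]: missing key {k}")
        except (TypeError, ValueError) as exc:
            errors.append(f"rounds[{i}]: {exc}")
    if not rounds:
        errors.append("rounds: at least one round required")

    n_frames = int(raw.get("n_frames", 2000))
    if n_frames < 1:
        errors.append("n_frames: must be >= 1")
    background = float(raw.get("background", 5.0))
    if background < 0:
        errors.append("background: must be >= 0")

    if errors:
        raise ConfigError(errors)

    return ExperimentConfig(
        scene_structures=structures,
        rounds=rounds,
        camera=camera,
        photophysics=photophysics,
        fit=fit,
        kinetics=kin,
        field_size_um=field_size,
        n_frames=n_frames,
        background=background,
        psf_sigma_px=float(raw.get("psf_sigma_px", 1.3)),
        scene_seed=int(scene.get("seed", raw.get("seed", 0))),
        seed=int(raw.get("seed", 0)),
        stage_shifts_px=shifts,
        crosstalk_check=bool(raw.get("crosstalk_check", True)),
        timecourse=raw.get("timecourse"),
        raw=raw,
    )


@dataclass
class ExperimentReport:
    """Everything the experiment measured, plus provenance to recompute it."""

    per_round: pd.DataFrame  # round, target_id, count, dx, dy
    cv_per_target: dict[str, float]
    crosstalk: list[dict]
    trace_fit: dict | None
    image_paths: dict[int, str]
    provenance: dict

    def to_json(self) -> str:
        return json.dumps({
            "per_round": self.per_round.to_dict(orient="records"),
            "cv_per_target": self.cv_per_target,
            "crosstalk": self.crosstalk,
            "trace_fit": self.trace_fit,
            "image_paths": {str(k): v for k, v in self.image_paths.items()},
            "provenance": self.provenance,
        }, indent=2, default=float)


def _round_seed(base: int, tag: int) -> int:
    ss = np.random.SeedSequence([int(base), int(tag)])
    return int(ss.generate_state(1)[0] % (2**31))


def _reference_image(scene: GroundTruthScene, camera: CameraModel) -> np.ndarray:
    """Pseudo-brightfield reference: a smooth, target-independent image of
    the whole cell (all binding sites, every round), used for inter-round
    registration the way the saved brightfield image re-aligns the stage."""
    from .psf import add_emitters
    img = np.zeros(camera.frame_shape)
    pos = scene.sites_px(camera.pixel_size_um)
    if len(pos):
        add_emitters(img, pos[:, 0], pos[:, 1],
                     np.full(len(pos), 100.0), 2.0)
    return img


def _shift_scene(scene: GroundTruthScene, shift_px, pixel_size_um) -> GroundTruthScene:
    if shift_px == (0.0, 0.0):
        return scene
    d = np.array(shift_px) * pixel_size_um
    return GroundTruthScene(
        sites=scene.sites + d[None, :], target_ids=scene.target_ids,
        field_size_um=scene.field_size_um, structures=scene.structures,
        seed=scene.seed,
    )


def run_experiment(config: ExperimentConfig, out_dir: str | Path | None = None) -> ExperimentReport:
    """Run the complete in-silico sequential-imaging experiment.

    Per round: simulate the acquisition, localize and filter, register the
    mean-intensity reference image against round 1 (the computational
    replacement for brightfield re-alignment) and correct the localizations,
    and render.  Between consecutive rounds, an equal-length post-invader
    acquisition of the just-imaged target (fresh labeling off, only the
    carryover fraction dye-bound) quantifies cross-talk as the after/before
    localization ratio.  Artifacts and a JSON report are written under
    ``out_dir`` when given.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        (out / "config_echo.yaml").write_text(yaml.safe_dump(config.raw))

    scene = make_scene(config.scene_structures, config.field_size_um,
                       seed=config.scene_seed)
    for i, r in enumerate(config.rounds):
        if r.target_id not in set(scene.target_ids):
            raise ConfigError([f"rounds[{i}].target_id {r.target_id!r} has no "
                               "sites in the scene"])

    all_locs: list[pd.DataFrame] = []
    per_round_rows = []
    xtalk: list[dict] = []
    image_paths: dict[int, str] = {}
    ref_img = None
    prev_labeled = None
    prev_count = None
    shifts = config.stage_shifts_px or [(0.0, 0.0)] * len(config.rounds)

    for i, rspec in enumerate(config.rounds):
        stage = f"round {rspec.round_index} ({rspec.target_id})"
        shifted = _shift_scene(scene, shifts[i], config.camera.pixel_size_um)
        try:
            sim = simulate_round(
                shifted,
                rspec, config.photophysics, config.camera,
                n_frames=config.n_frames,
                seed=_round_seed(config.seed, rspec.round_index),
                psf_sigma_px=config.psf_sigma_px,
                background=config.background,
                previous_labeled=prev_labeled,
            )
        except Exception as exc:
            raise StageError(f"simulate failed at {stage}: {exc}") from exc
        try:
            locs = localize_stack(sim.movie, config.fit)
        except Exception as exc:
            raise StageError(f"localize failed at {stage}: {exc}") from exc

        bf_img = _reference_image(shifted, config.camera)
        if ref_img is None:
            ref_img = bf_img
            dx = dy = 0.0
        else:
            dx, dy = register_rounds(ref_img, bf_img)
            locs = locs.assign(x=locs["x"] - dx, y=locs["y"] - dy)
        locs = locs.assign(round=rspec.round_index, target_id=rspec.target_id)
        all_locs.append(locs)
        n_acc = int(locs["accepted"].sum())
        per_round_rows.append({
            "round": rspec.round_index, "target_id": rspec.target_id,
            "count": n_acc, "dx_px": dx, "dy_px": dy,
            "n_candidates": len(locs),
        })

        if out is not None:
            locs.to_csv(out / f"locs_round{rspec.round_index}.csv", index=False)
            acc = locs[locs["accepted"]]
            if len(acc):
                sr = render(acc, zoom=10.0,
                            extent=(0, config.camera.frame_shape[1],
                                    0, config.camera.frame_shape[0]))
                img_path = out / f"sr_round{rspec.round_index}.tif"
                _write_sr(sr, img_path)
                image_paths[rspec.round_index] = str(img_path)

        # Post-invader cross-talk acquisition: what survives of this round's
        # labels after displacement, imaged at equal length.
        if config.crosstalk_check and i + 1 < len(config.rounds):
            residual = config.rounds[i + 1].carryover_residual
            check_spec = RoundSpec(
                round_index=rspec.round_index, target_id=rspec.target_id,
                label_prob=0.0, carryover_residual=residual,
            )
            sim_after = simulate_round(
                scene, check_spec, config.photophysics, config.camera,
                n_frames=config.n_frames,
                seed=_round_seed(config.seed, 1000 + rspec.round_index),
                psf_sigma_px=config.psf_sigma_px,
                background=config.background,
                previous_labeled=sim.labeled_sites,
            )
            locs_after = localize_stack(sim_after.movie, config.fit)
            ct = crosstalk(n_acc, locs_after)
            xtalk.append({
                "after_round": rspec.round_index,
                "carryover_residual": residual,
                "n_before": ct.n_before, "n_after": ct.n_after,
                "ratio": ct.ratio, "percent": ct.percent,
            })

        prev_labeled = sim.labeled_sites
        prev_count = n_acc

    combined = pd.concat(all_locs, ignore_index=True)
    rc = round_counts(combined)
    per_round = pd.DataFrame(per_round_rows)

    trace_fit = None
    if config.timecourse:
        tc = config.timecourse
        model = config.kinetics
        movie = simulate_timecourse_movie(
            scene, model, config.camera,
            duration_s=parse_quantity(tc.get("duration", 300.0), "time_s"),
            frame_rate_hz=parse_quantity(tc.get("frame_rate", 2.0), "rate_hz"),
            photons_per_frame=float(tc.get("photons_per_frame", 30.0)),
            background=config.background,
            psf_sigma_px=config.psf_sigma_px,
            target_id=tc.get("target_id"),
            seed=_round_seed(config.seed, 99991),
        )
        times, _, norm = movie_to_trace(movie)
        res = fit_trace(times, norm, model.t_invader,
                        invader_conc=model.invader_conc)
        trace_fit = {
            "k_eff_per_s": res.fitted_model.k_eff,
            "k_disp_per_M_s": res.fitted_model.k_disp,
            "residual_fraction": res.fitted_model.residual_fraction,
            "bleach_rate_per_s": res.fitted_model.bleach_rate,
            "fit_rmse": res.fit_rmse,
            "percent_reduction_corrected": res.percent_reduction_corrected,
            "percent_reduction_raw": res.percent_reduction_raw,
        }

    cfg_text = yaml.safe_dump(config.raw, sort_keys=True)
    report = ExperimentReport(
        per_round=per_round,
        cv_per_target=rc.cv_per_target,
        crosstalk=xtalk,
        trace_fit=trace_fit,
        image_paths=image_paths,
        provenance={
            "sdstorm_version": __version__,
            "seed": config.seed,
            "scene_seed": config.scene_seed,
            "n_frames": config.n_frames,
            "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        },
    )
    if out is not None:
        (out / "report.json").write_text(report.to_json())
        combined.to_csv(out / "locs_all.csv", index=False)
    return report


def _write_sr(sr, path: Path) -> None:
    import tifffile
    tifffile.imwrite(str(path), sr.pixels.astype(np.float32))
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        arr = sr.pixels
        hi = np.percentile(arr[arr > 0], 99.5) if (arr > 0).any() else 1.0
        plt.imsave(str(path.with_suffix(".png")),
                   np.clip(arr / max(hi, 1e-12), 0, 1), cmap="hot")
    except Exception:
        pass
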