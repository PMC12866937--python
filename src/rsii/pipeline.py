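"""End-to-end pipeline: images + pressure -> RSII surface maps.

Stages: TV-regularized registration of the systolic/diastolic pair, wall
mid-surface extraction and circumferential strain, tension recovery on the
deformed surface, and the SII/RSII integrity maps with summaries.  Each
stage is also available as an individual function (and CLI subcommand)
consuming the previous stage's artifacts.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as _io
from .integrity import compute_integrity
from .kinematics import KinematicsParams, compute_wall_strain
from .phantom import generate_frame_pair, preset
from .registration import RegistrationParams, register_tv
from .tension import TensionConfig, solve_tension

logger = logging.getLogger("rsii")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Inputs, per-stage parameters and output location for one run."""

    # either a phantom preset name ...
    phantom: str | None = "fusiform"
    phantom_overrides: dict = field(default_factory=dict)
    # ... or patient-style file inputs
    fixed_path: str | None = None     # systolic frame
    moving_path: str | None = None    # diastolic frame
    labels_path: str | None = None    # diastolic label map

    output_dir: str = "rsii_out"
    seed: int = 0
    registration: RegistrationParams = field(default_factory=RegistrationParams)
    kinematics: KinematicsParams = field(default_factory=KinematicsParams)
    tension: TensionConfig = field(default_factory=TensionConfig)
    exclusion_mm: float = 15.0        # geodesic distance from the fixed ends
    rsii_abs_numerator: bool = False  # all-positive RSII reading
    write_outputs: bool = True

    def __post_init__(self) -> None:
        if self.phantom is None:
            for name, p in (
                ("fixed", self.fixed_path),
                ("moving", self.moving_path),
                ("labels", self.labels_path),
            ):
                if p is None:
                    raise ValueError(f"either a phantom preset or {name}_path is required")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name} input does not exist: {p}")
        self.kinematics.seed = self.seed

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        doc.update(overrides)
        for key, klass in (
            ("registration", RegistrationParams),
            ("kinematics", KinematicsParams),
            ("tension", TensionConfig),
        ):
            if key in doc and isinstance(doc[key], dict):
                doc[key] = klass(**doc[key])
        return cls(**doc)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run register -> strain -> tension -> integrity; returns the summary.

    The returned dict has the RSII surface (``mesh``), the ``summary``
    (99th percentiles, mean |SII|, counts) and output paths if written.
    Deterministic for a fixed config and seed.
    """
    out_dir = Path(config.output_dir)
    manifest = _io.RunManifest(
        stage="run", config=config.to_dict(), seeds={"seed": config.seed}
    )

    if config.phantom is not None:
        spec = preset(config.phantom, seed=config.seed, **config.phantom_overrides)
        dia, sys_, labels, _truth = generate_frame_pair(spec)
        fixed, moving = sys_, dia
    else:
        fixed = _io.read_image(config.fixed_path)
        moving = _io.read_image(config.moving_path)
        labels = _io.read_labels(config.labels_path)
        for p in (config.fixed_path, config.moving_path, config.labels_path):
            manifest.add_input(p)

    logger.info("stage 1/4: deformable registration")
    fld = register_tv(fixed, moving, config.registration)

    logger.info("stage 2/4: wall surface and circumferential strain")
    strain_mesh = compute_wall_strain(
        labels, fld, config.tension.thickness, config.kinematics
    )

    logger.info("stage 3/4: wall tension (%s backend)", config.tension.backend)
    tens = solve_tension(strain_mesh, config.tension)
    strain_mesh.point_data["t_max"] = tens.t_max
    strain_mesh.point_data["t_min"] = tens.t_min
    strain_mesh.point_data["tension_tensor"] = tens.tensor

    logger.info("stage 4/4: integrity indices")
    result = compute_integrity(
        strain_mesh,
        strain_mesh.point_data["circ_strain"],
        tens.tension,
        strain_flags=strain_mesh.point_data["strain_flag"],
        boundary_distance_mm=config.exclusion_mm,
        abs_numerator=config.rsii_abs_numerator,
    )

    out = {"mesh": strain_mesh, "summary": result.summaries, "integrity": result}
    if config.write_outputs:
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "surface": _io.write_surface(strain_mesh, out_dir / "wall_rsii.vtp"),
            "summary": _io.write_summary(
                {**result.summaries, "config": config.to_dict()},
                out_dir / "summary.json",
            ),
            "field": _io.write_image(fld, out_dir / "displacement.mha"),
            "manifest": manifest.write(out_dir / "manifest.json"),
        }
        out["paths"] = paths
    return out
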