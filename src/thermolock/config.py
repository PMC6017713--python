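"""Schema-validated run configuration (YAML/JSON).

Keys carry explicit unit suffixes; lengths are millimetres at this boundary
(matching how the workflow is reported) and converted to SI on entry to the
library.  Unknown keys are rejected before any computation starts.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import phantom as ph
from .model import BoundarySpec, Layer, LayerStack, SpectralGrid

__all__ = ["RunConfig", "load_config", "config_hash"]

MM = 1e-3


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class LayerCfg(_Strict):
    thickness_mm: float = Field(gt=0)
    conductivity_w_m_k: float = Field(gt=0)
    density_kg_m3: float = Field(gt=0)
    heat_capacity_j_kg_k: float = Field(gt=0)

    def to_layer(self) -> Layer:
        return Layer(self.thickness_mm * MM, self.conductivity_w_m_k,
                     self.density_kg_m3, self.heat_capacity_j_kg_k)


class BoundaryCfg(_Strict):
    h_up_w_m2_k: float = Field(default=10.0, ge=0)
    h_dn_w_m2_k: float = Field(default=0.0, ge=0)
    tau_up_k: float = 0.0
    tau_dn_k: float = 0.0

    def to_boundary(self) -> BoundarySpec:
        return BoundarySpec(self.h_up_w_m2_k, self.h_dn_w_m2_k,
                            self.tau_up_k, self.tau_dn_k)


class ResistorGroupCfg(_Strict):
    depth_mm: float = Field(gt=0)
    count: int = Field(ge=1)
    spacing_mm: float = Field(gt=0)
    y_offset_mm: float = 0.0

    def to_group(self) -> ph.ResistorGroup:
        return ph.ResistorGroup(self.depth_mm * MM, self.count,
                                self.spacing_mm * MM, self.y_offset_mm * MM)


class PhantomCfg(_Strict):
    material: LayerCfg = LayerCfg(thickness_mm=14.0, conductivity_w_m_k=0.155,
                                  density_kg_m3=1090.0,
                                  heat_capacity_j_kg_k=1670.0)
    groups: list[ResistorGroupCfg] | None = None
    footprint_x_mm: float = 3.0
    footprint_y_mm: float = 1.7
    resistance_ohm: float = Field(default=120.0, gt=0)
    source_model: str = "planar"
    h_up_w_m2_k: float = Field(default=10.0, ge=0)
    h_dn_w_m2_k: float = Field(default=0.0, ge=0)

    def to_phantom(self) -> ph.PhantomSpec:
        kwargs = dict(material=self.material.to_layer(),
                      footprint_x=self.footprint_x_mm * MM,
                      footprint_y=self.footprint_y_mm * MM,
                      resistance=self.resistance_ohm,
                      source_model=self.source_model,
                      h_up=self.h_up_w_m2_k, h_dn=self.h_dn_w_m2_k)
        if self.groups is not None:
            kwargs["groups"] = tuple(g.to_group() for g in self.groups)
        return ph.PhantomSpec(**kwargs)


class DriveCfg(_Strict):
    amplitude_v: float = Field(default=7.2, ge=0)
    f_elec_hz: float = Field(default=0.05, gt=0)
    mask: list[bool] | None = None
    scales: list[float] | None = None

    def to_drive(self) -> ph.DriveSpec:
        return ph.DriveSpec(self.amplitude_v, self.f_elec_hz,
                            None if self.mask is None else tuple(self.mask),
                            None if self.scales is None else tuple(self.scales))


class CameraCfg(_Strict):
    nx: int = Field(default=160, ge=8)
    ny: int = Field(default=120, ge=8)
    pixel_mm: float = Field(default=0.4, gt=0)
    frame_rate_hz: float | None = None
    cycles: int = Field(default=12, ge=1)
    noise_sigma_k: float = Field(default=0.05, ge=0)

    def to_camera(self) -> ph.CameraSpec:
        return ph.CameraSpec(self.nx, self.ny, self.pixel_mm * MM,
                             self.frame_rate_hz, self.cycles,
                             self.noise_sigma_k)


class ProcessingCfg(_Strict):
    demod: str = "thermal"  # demodulate at the doubled (thermal) frequency
    snr_roi: list[int] | None = None  # [y0, y1, x0, x1]; default full image
    fwhm_axis: str = "y"


class ReconstructionCfg(_Strict):
    enabled: bool = True
    depth_mm: float = Field(default=3.0, gt=0)
    noise_level: float | None = Field(default=None, gt=0)


class RunConfig(_Strict):
    phantom: PhantomCfg = PhantomCfg()
    drive: DriveCfg = DriveCfg()
    camera: CameraCfg = CameraCfg()
    processing: ProcessingCfg = ProcessingCfg()
    reconstruction: ReconstructionCfg = ReconstructionCfg()
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.processing.demod not in ("thermal", "dc"):
            raise ValueError("processing.demod must be 'thermal' or 'dc'")
        if self.reconstruction.depth_mm * MM >= \
                self.phantom.material.thickness_mm * MM:
            raise ValueError("reconstruction depth must be inside the slab")
        return self

    def grid(self) -> SpectralGrid:
        return self.camera.to_camera().grid()


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return RunConfig.model_validate(data or {})


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
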