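"""Schema-validated, flat key-value run configuration.

The on-disk format is a flat YAML mapping with dotted section keys,
e.g.::

    channel.width_um: 200
    channel.depth_um: 60
    fluid.density: 984
    fluid.viscosity: 7.5e-4
    fluid.temperature_K: 302
    forcing.vmax_um_s: 250
    forcing.freq_hz: 0.25
    forcing.phase_rad: 0
    forcing.exponent: 4.5
    imaging.pixel_size_um: 0.4
    imaging.frame_rate_hz: 10
    qc.length_tolerance: 0.10
    qc.focal_slab_um: 10

Unknown keys are rejected so typos fail before any computation.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .flow import ChannelGeometry, FlowModel, FluidProperties, OscillatoryForcing

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class ChannelSection(_Strict):
    width_um: float = Field(200.0, gt=0)
    depth_um: float = Field(60.0, gt=0)
    length_mm: float = Field(30.0, gt=0)
    observation_offset_um: float = Field(30.0, ge=0)


class FluidSection(_Strict):
    density: float = Field(984.0, gt=0)
    viscosity: float = Field(7.5e-4, gt=0)
    temperature_K: float = Field(302.0, gt=0)


class ForcingSection(_Strict):
    vmax_um_s: float = Field(250.0, ge=0)
    freq_hz: float = Field(0.25, gt=0)
    phase_rad: float = 0.0
    exponent: float = Field(4.5, ge=2)


class ImagingSection(_Strict):
    pixel_size_um: float = Field(0.4, gt=0)
    frame_rate_hz: float = Field(10.0, gt=0)
    sigma_px: float = Field(1.2, gt=0)
    peak_intensity: float = Field(1000.0, gt=0)
    background: float = Field(100.0, ge=0)
    noise: str = "poisson"


class QcSection(_Strict):
    length_tolerance: float = Field(0.10, ge=0)
    focal_slab_um: float = Field(10.0, gt=0)
    mad_k: float = Field(5.0, gt=0)
    mid_channel_um: float = Field(40.0, gt=0)


class MechanicsSection(_Strict):
    decay_convention: str = "2d"
    young_modulus_kpa: float = Field(2.0, gt=0)
    young_modulus_x_kpa: float = Field(20.0, gt=0)
    tangent_step_um: float = Field(0.4, gt=0)


class RunConfig(_Strict):
    """Validated configuration for a full pipeline run."""

    channel: ChannelSection = ChannelSection()
    fluid: FluidSection = FluidSection()
    forcing: ForcingSection = ForcingSection()
    imaging: ImagingSection = ImagingSection()
    qc: QcSection = QcSection()
    mechanics: MechanicsSection = MechanicsSection()
    seed: int = 0

    def flow_model(self) -> FlowModel:
        import numpy as np

        return FlowModel(
            geometry=ChannelGeometry(
                width=self.channel.width_um * 1e-6,
                depth=self.channel.depth_um * 1e-6,
                length=self.channel.length_mm * 1e-3,
                observation_z_offset=self.channel.observation_offset_um * 1e-6,
            ),
            fluid=FluidProperties(
                density=self.fluid.density,
                viscosity=self.fluid.viscosity,
                temperature=self.fluid.temperature_K,
            ),
            forcing=OscillatoryForcing(
                vmax=self.forcing.vmax_um_s * 1e-6,
                omega=2.0 * np.pi * self.forcing.freq_hz,
                phase=self.forcing.phase_rad,
                blunting_exponent=self.forcing.exponent,
            ),
        )

    def flat_dict(self) -> dict:
        out = {}
        for section, model in self.model_dump().items():
            if isinstance(model, dict):
                for k, v in model.items():
                    out[f"{section}.{k}"] = v
            else:
                out[section] = model
        return out


def load_config(path: str | Path) -> RunConfig:
    """Read a flat dotted-key YAML file into a validated RunConfig."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a flat key-value mapping")
    nested: dict = {}
    for key, value in raw.items():
        parts = str(key).split(".")
        if len(parts) == 1:
            nested[parts[0]] = value
        elif len(parts) == 2:
            nested.setdefault(parts[0], {})[parts[1]] = value
        else:
            raise ValueError(f"config keys are section.name pairs, got {key!r}")
    return RunConfig(**nested)
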