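"""Schema-validated pipeline configuration (JSON; unknown keys rejected).

Physical quantities carry explicit units in their key names (``_s``,
``_hz``, ``_angstrom``, ``_ppm``).  Defaults reproduce the measurement
conditions: 38 kHz MAS for the REDOR and exchange experiments on a 600 MHz
spectrometer, protein-ligand mixing times of 64/96/144 rotor periods.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field

from .powder import PowderScheme
from .spinsim import DEFAULT_MIXING_TIMES_S, RedorSequenceParams

__all__ = ["PipelineConfig", "load_config"]


class PipelineConfig(BaseModel):
    """Top-level configuration for the synthetic end-to-end pipeline."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    mas_rate_hz: float = 38_000.0
    larmor_deph_hz: float = 564.6e6
    mixing_times_s: list[float] = Field(
        default_factory=lambda: list(DEFAULT_MIXING_TIMES_S)
    )
    pulse_length_deph_s: float = 0.0
    csa_span_ppm: float = 60.0
    csa_asymmetry: float = 1.0
    powder_scheme: str = "spiral"
    powder_n_orient: int = 128
    powder_n_gamma: int = 8
    rmsd_threshold: float = 0.2
    noise_s_ratio: float = 0.05
    n_models: int = 10

    def sequence_params(self) -> RedorSequenceParams:
        return RedorSequenceParams(
            mas_rate_hz=self.mas_rate_hz,
            mixing_times_s=tuple(self.mixing_times_s),
            pulse_length_deph_s=self.pulse_length_deph_s,
            csa_span_ppm=self.csa_span_ppm,
            csa_asymmetry=self.csa_asymmetry,
            larmor_deph_hz=self.larmor_deph_hz,
            powder=PowderScheme(
                self.powder_scheme, self.powder_n_orient, self.powder_n_gamma
            ),
        )


def load_config(path) -> PipelineConfig:
    return PipelineConfig.model_validate(json.loads(Path(path).read_text()))
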