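"""YAML configuration for simulation runs.

One flat document collects the tunables of a campaign; anything omitted
falls back to the package defaults, so a config together with a seed fully
reproduces a run.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .lr1 import DEFAULT_CELL_TYPES, CellTypeParams
from .solver import INTRA_G_DEFAULT

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    # geometry / architecture
    length_um: float = 3000.0
    width_um: float = 150.0
    node_spacing_um: float = 5.0
    cell_length_um: float = 100.0
    cell_width_um: float = 15.0
    jitter: float = 0.3
    # coupling
    g_ref_us: float | None = None  # None -> calibrate
    intra_g_us: float = INTRA_G_DEFAULT
    coupling: str = "baseline"
    # membrane (per cell type: gna_max, gsi_scale, tau_d_scale, tau_f_scale,
    # gk_scale)
    cell_types: dict = field(
        default_factory=lambda: {
            name: {
                "gna_max": p.gna_max,
                "gsi_scale": p.gsi_scale,
                "tau_d_scale": p.tau_d_scale,
                "tau_f_scale": p.tau_f_scale,
                "gk_scale": p.gk_scale,
            }
            for name, p in DEFAULT_CELL_TYPES.items()
        }
    )
    # pacing / numerics
    cl_ms: float = 300.0
    n_beats: int = 1
    stim_amplitude: float = 100.0
    stim_duration_ms: float = 2.0
    stim_zone_um: float = 100.0
    dt_ms: float = 0.005
    # sweep
    p_step: float = 0.1
    realizations: int = 20
    scm_mix: str = "mixed_2to1"
    seed0: int = 0

    def cell_params(self) -> dict[str, CellTypeParams]:
        return {
            name: CellTypeParams(name, **vals)
            for name, vals in self.cell_types.items()
        }


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig(**data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=False))
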