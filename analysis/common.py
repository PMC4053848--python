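"""Shared plumbing for the numbered analysis drivers."""

from pathlib import Path

import yaml

from smaugkit.simulate import SimulationConfig

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"


def load_config() -> dict:
    with open(ROOT / "analysis" / "config.yaml") as fh:
        return yaml.safe_load(fh)


def simulation_config(cfg: dict) -> SimulationConfig:
    return SimulationConfig(**cfg["simulation"])


def outdir() -> Path:
    RESULTS.mkdir(exist_ok=True)
    return RESULTS
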