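"""Run configuration: validated settings for the end-to-end pipeline."""

from __future__ import annotations

from datetime import date
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, model_validator

from .compounds import CLASSES, STUDY_COMPOUNDS
from .ingest import DEFAULT_WINDOW_END, DEFAULT_WINDOW_START
from .simulate import SyntheticConfig


class RunConfig(BaseModel):
    """Everything one pipeline run needs, loadable from YAML.

    ``mode`` selects the input: ``synthetic`` draws a corpus from the
    generator (the packaged default emulates the study conditions), while
    ``faers`` ingests dollar-delimited quarterly tables from ``input_dir``
    (demo.txt / drug.txt / reac.txt / indi.txt).
    """

    mode: Literal["synthetic", "faers"] = "synthetic"
    input_dir: Optional[Path] = None
    synthetic: Optional[SyntheticConfig] = None
    drugs: list[str] = Field(default_factory=lambda: list(STUDY_COMPOUNDS))
    classes: dict[str, list[str]] = Field(
        default_factory=lambda: {k: list(v) for k, v in CLASSES.items()}
    )
    terms: list[str] = Field(default_factory=lambda: ["sedation", "somnolence"])
    window_start: date = DEFAULT_WINDOW_START
    window_end: date = DEFAULT_WINDOW_END
    estimator: Literal["woolf", "exact"] = "woolf"
    level: float = Field(default=0.95, gt=0, lt=1)
    min_cases: int = Field(default=1, ge=1)
    correct_zero_cells: bool = False
    suspect_only: bool = False
    seed: int = 0
    out_dir: Path = Path("pvror-out")

    @model_validator(mode="after")
    def _mode_inputs(self) -> "RunConfig":
        if self.mode == "faers" and self.input_dir is None:
            raise ValueError("faers mode requires input_dir")
        if not self.drugs and not self.classes:
            raise ValueError("at least one drug or class exposure must be configured")
        if self.window_start > self.window_end:
            raise ValueError("window_start is after window_end")
        return self


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)
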