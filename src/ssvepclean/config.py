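"""Run configuration: a validated, serializable description of a full
pipeline run (I/O, channel roles, filters, cleaner, classifiers,
evaluation, master seed).

Unknown keys are rejected so typos fail loudly, and every run can emit
a resolved snapshot sufficient to reproduce it.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field


class FilterSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: Literal["notch_bandstop", "bandpass"]
    band: tuple[float, float]
    order: int = 4
    zero_phase: bool = False


class NetSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    hidden_units: int = 64
    dropout: float = 0.5
    max_epochs: int = 40
    batch_size: int = 64
    val_fraction: float = 0.125
    patience: int = 3
    n_runs: int = 3
    learning_rate: float = 1e-3


class CleanerSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    aux: str | list[str] = "all"  # "all", "best", or an explicit channel list
    sd_convention: Literal["population", "sample"] = "population"


class FbccaSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    bands: list[tuple[float, float]] = Field(
        default_factory=lambda: [(6, 90), (14, 90), (22, 90), (30, 90), (38, 90)]
    )
    order: int = 4
    weights: Optional[list[float]] = None  # None -> n^-1.25 + 0.25


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    data_dir: Optional[str] = None
    data_format: Literal["csv", "edf"] = "csv"
    role_map: dict[str, str] = Field(default_factory=dict)
    filters: list[FilterSettings] = Field(default_factory=list)
    window_s: float = 1.0
    stim_freqs: list[float] = Field(default_factory=lambda: [7.0, 8.0, 9.0])
    n_harmonics: int = 3
    cleaner: CleanerSettings = Field(default_factory=CleanerSettings)
    svm_C: float = 1.0
    net: NetSettings = Field(default_factory=NetSettings)
    fbcca: FbccaSettings = Field(default_factory=FbccaSettings)
    methods: list[str] = Field(default_factory=lambda: ["svm", "cca"])
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yml", ".yaml")):
            import yaml

            return cls.model_validate(yaml.safe_load(text))
        return cls.model_validate(json.loads(text))

    def snapshot(self, path: str | Path) -> None:
        """Write the fully resolved config next to the run outputs."""
        Path(path).write_text(self.model_dump_json(indent=1))
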