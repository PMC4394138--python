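"""Run configuration: one serializable object holding every tunable.

The only clinically fixed runtime parameter is the decision threshold of 0.5;
everything else (montage, smoothing window, collar, SVM hyperparameters,
audification and display options, threshold grid, seed) is a documented
package default. The configuration round-trips losslessly through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .simulate import BIPOLAR_PAIRS

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    seed: int = 0
    montage_pairs: list[tuple[str, str]] = field(default_factory=lambda: list(BIPOLAR_PAIRS))
    smoothing_window_epochs: int = 15
    threshold: float = 0.5  # fixed for clinical use
    collar_s: float = 32.0
    svm_c: float = 1.0
    svm_gamma: str | float = "scale"
    gain_floor: float = 0.2
    stretch_factor: float = 100.0
    audio_rate_hz: int = 32000
    grid_start: float = 0.0
    grid_stop: float = 1.0
    grid_step: float = 0.01
    # synthetic cohort
    n_records: int = 6
    record_duration_s: float = 600.0
    n_seizures_per_record: int = 3
    seizure_amplitude_uv: float = 100.0
    background_amplitude_uv: float = 30.0
    sample_rate_hz: float = 256.0

    def threshold_grid(self) -> np.ndarray:
        n = int(round((self.grid_stop - self.grid_start) / self.grid_step)) + 1
        return np.round(np.linspace(self.grid_start, self.grid_stop, n), 10)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["montage_pairs"] = [list(p) for p in d["montage_pairs"]]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["montage_pairs"] = [tuple(p) for p in d.get("montage_pairs", BIPOLAR_PAIRS)]
        return cls(**d)
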