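"""Run configuration: every threshold of the pipeline in one place.

Defaults reproduce the study protocol: 100 Hz raw signals, 5-s working
epochs (cut-points printed per minute are scaled by len/60), the
13 mg / 50 mg / 60-min nonwear rule, 0.01 g calibration exclusion,
16 h / 4 days / 3 weekdays / 1 weekend-day validity, the four published
cut-point sets, 7-9 h sleep / 8 h SB / 30 min MVPA guidelines and the
-20..+20 min reallocation grid.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .compliance import GuidelineThresholds
from .features import CutpointSet, DEFAULT_CUTPOINTS
from .metrics import CountsConfig


@dataclass
class RunConfig:
    seed: int = 0
    sample_rate: float = 100.0
    epoch_len: float = 5.0
    metrics: tuple = ("ENMO", "MAD", "CPM_VA", "CPM_VM")
    cutpoints: dict = field(default_factory=lambda: dict(DEFAULT_CUTPOINTS))
    counts: CountsConfig = field(default_factory=CountsConfig)
    noise_sd: float = 0.005
    nonwear_window_min: float = 60.0
    nonwear_step_min: float = 15.0
    nonwear_sd_mg: float = 13.0
    nonwear_range_mg: float = 50.0
    calib_max_error_g: float = 0.01
    min_wear_hours: float = 16.0
    min_valid_days: int = 4
    min_weekdays: int = 3
    min_weekend_days: int = 1
    ig_bin_width_mg: float = 25.0
    guidelines: GuidelineThresholds = field(default_factory=GuidelineThresholds)
    realloc_min: int = -20
    realloc_max: int = 20
    covariates: tuple = ("sex", "age", "education", "smoking",
                         "med_glucose", "med_lipid", "med_bp", "pathology")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cutpoints"] = {m: asdict(cp) for m, cp in self.cutpoints.items()}
        return d

    def config_hash(self) -> str:
        """Stable short hash embedded in every artifact manifest."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "cutpoints" in d:
            d["cutpoints"] = {m: CutpointSet(**cp) for m, cp in d["cutpoints"].items()}
        if "counts" in d:
            c = d["counts"]
            c["band_edges"] = tuple(c.get("band_edges", (0.29, 1.63)))
            d["counts"] = CountsConfig(**c)
        if "guidelines" in d:
            d["guidelines"] = GuidelineThresholds(**d["guidelines"])
        for k in ("metrics", "covariates"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)
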