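"""Run configuration: one YAML document covering every tunable stage."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .detection import DetectionParams
from .errors import ConfigurationError
from .synthetic import CohortConfig, PhenotypeMaps


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    detection: DetectionParams = field(default_factory=DetectionParams)
    cv_seed: int = 0
    cv_folds: int = 10
    feature_sets: tuple = ("la_only",)
    output_dir: str = "limbacc_out"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["feature_sets"] = list(self.feature_sets)
        return d

    def config_hash(self) -> str:
        """Stable short hash embedded in outputs for provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cohort_raw = dict(raw.get("cohort", {}))
        maps_raw = cohort_raw.pop("maps", {})
        if maps_raw:
            for key in ("spasm_rates",):
                if key in maps_raw:
                    maps_raw[key] = tuple(maps_raw[key])
            cohort_raw["maps"] = PhenotypeMaps(**maps_raw)
        for key in ("lems_range", "spasticity_probs"):
            if key in cohort_raw:
                cohort_raw[key] = tuple(cohort_raw[key])
        return cls(
            cohort=CohortConfig(**cohort_raw),
            detection=DetectionParams(**raw.get("detection", {})),
            cv_seed=raw.get("cv_seed", 0),
            cv_folds=raw.get("cv_folds", 10),
            feature_sets=tuple(raw.get("feature_sets", ("la_only",))),
            output_dir=raw.get("output_dir", "limbacc_out"),
        )
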