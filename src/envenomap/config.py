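"""Run configuration: YAML parsing, validation, seed derivation."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .models import ALGORITHM_NAMES

#: protocol defaults of the modelling workflow
DEFAULTS = {
    "min_dist_km": 1.0,
    "n_background": 5000,
    "n_reps": 20,
    "train_fraction": 0.7,
    "vif_threshold": 10.0,
}


@dataclass
class RunConfig:
    env_path: str
    ecoregions_path: str
    cities_path: str
    occurrences_path: str
    output_dir: str
    species: list[str] = field(default_factory=list)  # empty = all in file
    min_dist_km: float = DEFAULTS["min_dist_km"]
    n_background: int = DEFAULTS["n_background"]
    algorithms: list[str] = field(default_factory=lambda: list(ALGORITHM_NAMES))
    hyperparameters: dict = field(default_factory=dict)  # per-algorithm overrides
    n_reps: int = DEFAULTS["n_reps"]
    train_fraction: float = DEFAULTS["train_fraction"]
    vif_threshold: float = DEFAULTS["vif_threshold"]
    ensemble_weighting: str = "uniform"  # "uniform" | "auc"
    exposure_definition: str = "richness"  # "richness" | "union"
    allow_presence_cells: bool = False
    master_seed: int = 0

    def validate(self) -> None:
        """Raise ValueError naming the offending field."""
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError(f"train_fraction: must be in (0, 1), got {self.train_fraction}")
        if self.n_background < 1:
            raise ValueError(f"n_background: must be >= 1, got {self.n_background}")
        if self.n_reps < 1:
            raise ValueError(f"n_reps: must be >= 1, got {self.n_reps}")
        if self.min_dist_km < 0:
            raise ValueError(f"min_dist_km: must be >= 0, got {self.min_dist_km}")
        if self.vif_threshold <= 1.0:
            raise ValueError(f"vif_threshold: must be > 1, got {self.vif_threshold}")
        if self.ensemble_weighting not in ("uniform", "auc"):
            raise ValueError(f"ensemble_weighting: unknown mode {self.ensemble_weighting!r}")
        if self.exposure_definition not in ("richness", "union"):
            raise ValueError(f"exposure_definition: unknown mode {self.exposure_definition!r}")
        bad = [a for a in self.algorithms if a not in ALGORITHM_NAMES]
        if bad:
            raise ValueError(f"algorithms: unknown algorithm(s) {bad}")
        if not self.algorithms:
            raise ValueError("algorithms: at least one algorithm required")
        for p_field in ("env_path", "ecoregions_path", "cities_path", "occurrences_path"):
            if not getattr(self, p_field):
                raise ValueError(f"{p_field}: required")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        cfg = cls(**payload)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def stage_seed(master_seed: int, stage: str, context: str = "") -> int:
    """Derive a per-stage (optionally per-species) seed from the master seed.

    Seeds come from the first 4 bytes of SHA-256 over
    ``"{master}:{stage}:{context}"``, reduced below 2**31, so any stage
    can be rerun in isolation with the exact seed the pipeline used.
    """
    digest = hashlib.sha256(f"{master_seed}:{stage}:{context}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def template_yaml() -> str:
    """Fully defaulted config template for the ``init`` subcommand."""
    cfg = RunConfig(
        env_path="env.tif",
        ecoregions_path="ecoregions.tif",
        cities_path="cities.csv",
        occurrences_path="occurrences.csv",
        output_dir="outputs",
    )
    return yaml.safe_dump(cfg.to_dict(), sort_keys=False)
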