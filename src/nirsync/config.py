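"""Pipeline configuration: defaults, profiles, YAML round trip, provenance."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class PipelineConfig:
    """All tunable parameters of the end-to-end pipeline.

    The ``full`` profile carries the design values of the original study
    (16-channel montage, 2x30 trials per condition, 60 s rests, 1000
    permutations); the ``test`` profile shrinks session length, montage and
    permutation count for desk-scale runs.
    """

    profile: str = "full"
    # simulation
    layout: str = "rps-16"
    n_dyads: int = 31
    trials_per_block: int = 30
    rest_s: float = 60.0
    fs_hz: float = 7.81
    kappa: dict = field(
        default_factory=lambda: {
            "FreePlay": 0.70,
            "PredictionDifferent": 0.55,
            "PredictionSame": 0.55,
            "Control": 0.0,
            "Rest": 0.30,
        }
    )
    roi_gain: dict = field(default_factory=lambda: {"FreePlay|rTPJ": 1.3})
    coupling_band_hz: tuple = (0.05, 0.16)
    # preprocessing
    qc_band_hz: tuple = (0.8, 1.5)
    qc_snr_min: float = 2.0
    p_smooth: float = 0.99
    filter_low_hz: float = 0.01
    filter_high_hz: float = 0.50
    dpf: float = 6.0
    extinction_table: str = "compiled-nir-2wl"
    # coherence
    dj: float = 1.0 / 12.0
    omega0: float = 6.0
    band_hz: tuple = (0.05, 0.16)
    exclude_coi: bool = True
    chromophore: str = "HbR"
    min_part_s: float = 120.0
    # permutation / inference
    n_permutations: int = 1000
    seed: int = 0

    def coupling_gains(self) -> dict:
        return {tuple(k.split("|")): v for k, v in self.roi_gain.items()}

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        c = cls(**d)
        c.coupling_band_hz = tuple(c.coupling_band_hz)
        c.qc_band_hz = tuple(c.qc_band_hz)
        c.band_hz = tuple(c.band_hz)
        return c


def test_profile(seed: int = 0) -> PipelineConfig:
    """Desk-scale profile: 6 dyads, short sessions, 50 permutations."""
    return PipelineConfig(
        profile="test",
        layout="mini-8",
        n_dyads=6,
        trials_per_block=6,
        rest_s=30.0,
        min_part_s=40.0,
        n_permutations=50,
        seed=seed,
    )


def get_profile(name: str, seed: int = 0) -> PipelineConfig:
    if name == "full":
        return PipelineConfig(seed=seed)
    if name == "test":
        return test_profile(seed)
    raise ValueError(f"unknown profile {name!r}")
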