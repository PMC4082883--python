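"""Run configuration: cost weights and Gabor/FCM hyperparameters.

Loadable from a YAML/JSON mapping so CLI runs are reproducible from a single
file.  Unknown keys are rejected to catch typos.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .image_core import ValidationError


@dataclass
class GaborFcmConfig:
    orientations: list[float] = field(
        default_factory=lambda: [0.0, 30.0, 60.0, 90.0, 120.0, 150.0]
    )
    gamma: float = 0.5
    phi: float = 0.0
    sigma_rule: float = 0.56       # envelope std = sigma_rule / f
    smoothing_factor: float = 2.0  # energy smoothing = factor * sigma
    c: int = 10
    m: float = 2.0
    eps: float = 1.0e-5
    max_iter: int = 300
    seed: int = 0


@dataclass
class LumpwireConfig:
    w_z: float = 0.43
    w_g: float = 0.43
    w_d: float = 0.14
    log_sigma: float = 1.0           # LoG scale for the classic f_Z
    presmooth_sigma: float | None = None  # optional Gaussian before gradients
    gabor_fcm: GaborFcmConfig = field(default_factory=GaborFcmConfig)

    @classmethod
    def from_mapping(cls, data: dict) -> "LumpwireConfig":
        data = dict(data or {})
        gf_data = data.pop("gabor_fcm", {})
        _check_keys(data, cls)
        _check_keys(gf_data, GaborFcmConfig)
        return cls(**data, gabor_fcm=GaborFcmConfig(**gf_data))

    @classmethod
    def from_yaml(cls, path) -> "LumpwireConfig":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return asdict(self)


def _check_keys(data: dict, cls) -> None:
    known = {f.name for f in fields(cls)} - {"gabor_fcm"}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(
            f"unknown config keys for {cls.__name__}: {sorted(unknown)}"
        )
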