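"""Architecture bookkeeping and the serializable run configuration.

The receptive-field closed form is exposed under two conventions: the
``as_printed`` variant multiplies strides over layers 1..i (including
layer i's own stride); the ``standard`` variant multiplies over
1..i-1, the usual convention in the literature.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from typing import Optional, Sequence

__all__ = [
    "LayerSpec",
    "EncodingConfig",
    "GroupingConfig",
    "FlowConfig",
    "TrackingConfig",
    "InferenceConfig",
    "RunConfig",
    "compute_receptive_field",
    "load_config",
    "save_config",
]


@dataclass(frozen=True)
class LayerSpec:
    kernel_size: int
    stride: int = 1

    def __post_init__(self):
        if self.kernel_size < 1:
            raise ValueError("kernel_size must be >= 1")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


def compute_receptive_field(
    layers: Sequence[LayerSpec],
    rf_convention: str = "as_printed",
) -> int:
    """Closed-form receptive field of a stack of convolutional layers.

    ``RF = 1 + sum_i (K_i - 1) * prod_j S_j`` with the product running over
    ``j = 1..i`` (``as_printed``) or ``j = 1..i-1`` (``standard``).
    """
    if not layers:
        raise ValueError("layer list must be nonempty")
    if rf_convention not in ("as_printed", "standard"):
        raise ValueError("rf_convention must be 'as_printed' or 'standard'")
    rf = 1
    prod = 1
    for layer in layers:
        if rf_convention == "as_printed":
            prod *= layer.stride
            rf += (layer.kernel_size - 1) * prod
        else:
            rf += (layer.kernel_size - 1) * prod
            prod *= layer.stride
    return rf


# ---------------------------------------------------------------------------
# Run configuration schema
# ---------------------------------------------------------------------------


def _check(cond: bool, key: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"config key '{key}': {msg}")


@dataclass
class EncodingConfig:
    sigma_base: float = 1.0
    paf_sigma: float = 5.0
    output_stride: int = 1
    class_radius: float = 5.0

    def validate(self) -> None:
        _check(self.sigma_base > 0, "encoding.sigma_base", "must be positive")
        _check(self.paf_sigma > 0, "encoding.paf_sigma", "must be positive")
        _check(
            self.output_stride in (1, 2, 4, 8),
            "encoding.output_stride",
            "must be one of 1, 2, 4, 8",
        )
        _check(self.class_radius > 0, "encoding.class_radius", "must be positive")


@dataclass
class GroupingConfig:
    min_connection_score: float = 0.05
    n_line_samples: int = 10
    allow_singletons: bool = False
    max_instances: Optional[int] = None

    def validate(self) -> None:
        _check(
            self.n_line_samples >= 2, "grouping.n_line_samples", "must be >= 2"
        )
        _check(
            self.max_instances is None or self.max_instances >= 1,
            "grouping.max_instances",
            "must be >= 1 or null",
        )


@dataclass
class FlowConfig:
    levels: int = 3
    patch_size: int = 21

    def validate(self) -> None:
        _check(self.levels >= 1, "tracking.flow.levels", "must be >= 1")
        _check(
            self.patch_size >= 3 and self.patch_size % 2 == 1,
            "tracking.flow.patch_size",
            "must be an odd integer >= 3",
        )


@dataclass
class TrackingConfig:
    window_size: int = 5
    cost_threshold: Optional[float] = None
    flow: FlowConfig = field(default_factory=FlowConfig)

    def validate(self) -> None:
        _check(self.window_size >= 1, "tracking.window_size", "must be >= 1")
        _check(
            self.cost_threshold is None or self.cost_threshold > 0,
            "tracking.cost_threshold",
            "must be positive or null",
        )
        self.flow.validate()


@dataclass
class InferenceConfig:
    peak_threshold: float = 0.2

    def validate(self) -> None:
        _check(
            0.0 <= self.peak_threshold <= 1.0,
            "inference.peak_threshold",
            "must be in [0, 1]",
        )


@dataclass
class RunConfig:
    """All user-controlled parameters, serializable to plain JSON.

    Unknown keys are rejected on load; defaults are filled and written
    back explicitly on save.
    """

    encoding: EncodingConfig = field(default_factory=EncodingConfig)
    grouping: GroupingConfig = field(default_factory=GroupingConfig)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    skeleton: Optional[dict] = None
    provenance: dict = field(default_factory=dict)

    def validate(self) -> None:
        self.encoding.validate()
        self.grouping.validate()
        self.tracking.validate()
        self.inference.validate()

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        def build(dc_type, payload, prefix):
            if not isinstance(payload, dict):
                raise ValueError(f"config key '{prefix}': expected an object")
            known = {f.name: f for f in fields(dc_type)}
            unknown = set(payload) - set(known)
            if unknown:
                raise ValueError(
                    f"unknown config key '{prefix}.{sorted(unknown)[0]}'"
                )
            kwargs = {}
            for name, value in payload.items():
                if name == "flow":
                    kwargs[name] = build(FlowConfig, value, f"{prefix}.flow")
                else:
                    kwargs[name] = value
            return dc_type(**kwargs)

        unknown = set(data) - {
            "encoding",
            "grouping",
            "tracking",
            "inference",
            "skeleton",
            "provenance",
        }
        if unknown:
            raise ValueError(f"unknown config key '{sorted(unknown)[0]}'")
        cfg = cls(
            encoding=build(EncodingConfig, data.get("encoding", {}), "encoding"),
            grouping=build(GroupingConfig, data.get("grouping", {}), "grouping"),
            tracking=build(TrackingConfig, data.get("tracking", {}), "tracking"),
            inference=build(InferenceConfig, data.get("inference", {}), "inference"),
            skeleton=data.get("skeleton"),
            provenance=data.get("provenance", {}),
        )
        cfg.validate()
        return cfg


def save_config(cfg: RunConfig, path) -> None:
    cfg.validate()
    with open(path, "w") as f:
        json.dump(cfg.to_dict(), f, indent=2)


def load_config(path) -> RunConfig:
    with open(path) as f:
        data = json.load(f)
    return RunConfig.from_dict(data)
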