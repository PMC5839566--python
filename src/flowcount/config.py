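"""Run configuration: nested parameter blocks with lossless YAML I/O."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .background import PbasParams
from .blobs import MorphParams, RoiConfig
from .sizing import DEFAULT_CHANNEL_WIDTH_UM
from .still import StillCountParams

__all__ = ["FlowParams", "RunConfig", "load_config", "save_config",
           "default_config", "config_hash"]


@dataclass
class FlowParams:
    """Parameters of the flow-video pipeline."""

    roi: RoiConfig | None = None
    morph: MorphParams = field(default_factory=MorphParams)
    pbas: PbasParams = field(default_factory=PbasParams)
    line_column: float | None = None        # full-frame x; default mid-ROI
    direction_policy: str = "any"
    min_area: float = 600.0
    max_area: float = 6000.0
    max_match_dist: float = 30.0
    patience: int = 5
    color_segmentation: bool = False
    n_color_clusters: int = 3
    channel_width_um: float = DEFAULT_CHANNEL_WIDTH_UM
    channel_width_px: float | None = None   # default: ROI height
    size_at: str = "crossing"               # {"crossing", "max"}


@dataclass
class RunConfig:
    """Top-level configuration of one analysis run."""

    mode: str = "flow"                      # {"still", "flow"}
    sample_type: str = "glochidia"          # {"beads", "helminth", "glochidia"}
    seed: int = 0
    input_path: str | None = None
    output_dir: str | None = None
    still: StillCountParams = field(default_factory=StillCountParams)
    flow: FlowParams = field(default_factory=FlowParams)

    def validate(self) -> None:
        if self.mode not in ("still", "flow"):
            raise ValueError("mode must be 'still' or 'flow'")
        if self.sample_type not in ("beads", "helminth", "glochidia"):
            raise ValueError("unknown sample_type")


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


def to_dict(config: RunConfig) -> dict:
    return _to_plain(config)


def _build(cls, data):
    if data is None:
        return None
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        sub = {"roi": RoiConfig, "morph": MorphParams, "pbas": PbasParams,
               "still": StillCountParams, "flow": FlowParams}.get(f.name)
        if sub is not None and isinstance(v, dict):
            v = _build(sub, v)
        elif isinstance(v, list) and f.name in ("intensity_range",
                                                "element_size"):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def from_dict(data: dict) -> RunConfig:
    return _build(RunConfig, data)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(config), fh, sort_keys=True)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return from_dict(yaml.safe_load(fh))


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(to_dict(config), sort_keys=True, default=str)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def default_config(sample_type: str = "glochidia") -> RunConfig:
    """Mode-appropriate defaults for each supported sample type."""
    if sample_type == "beads":
        return RunConfig(mode="still", sample_type="beads")
    if sample_type == "helminth":
        flow = FlowParams(
            morph=MorphParams(element_shape="rectangle", element_size=5),
            color_segmentation=True)
        return RunConfig(mode="flow", sample_type="helminth", flow=flow)
    if sample_type == "glochidia":
        flow = FlowParams(
            morph=MorphParams(element_shape="ellipse", element_size=(7, 5)))
        return RunConfig(mode="flow", sample_type="glochidia", flow=flow)
    raise ValueError(f"unknown sample_type {sample_type!r}")
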