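import numpy as np
import pytest

from flowcount import FlowSceneSpec, default_config, generate_flow_video
from flowcount.blobs import RoiConfig


def flow_config_for(spec: FlowSceneSpec, sample_type: str = "glochidia",
                    seed: int = 0, **overrides):
    """Analysis config matched to a generated scene's geometry."""
    cfg = default_config(sample_type)
    cfg.seed = seed
    cfg.flow.roi = RoiConfig(
        x=0, y=max(spec.channel_top - 6, 0), width=spec.frame_width,
        height=min(spec.channel_width_px + 12,
                   spec.frame_height - max(spec.channel_top - 6, 0)),
        mode="helminth" if sample_type == "helminth" else "glochidia")
    cfg.flow.channel_width_px = spec.channel_width_px
    # expected ellipse area ~ pi/4 * major * minor
    a_exp = np.pi / 4 * spec.major_axis_mean * spec.minor_axis_mean
    cfg.flow.min_area = 0.3 * a_exp
    cfg.flow.max_area = 3.0 * a_exp
    cfg.flow.max_match_dist = 3.0 * spec.velocity
    for k, v in overrides.items():
        setattr(cfg.flow, k, v)
    return cfg


@pytest.fixture(scope="session")
def small_flow_scene():
    """Shared high-contrast scene: 5 targets plus sub-threshold debris."""
    spec = FlowSceneSpec(n_objects=5, n_debris=10, contrast_mode="high",
                         seed=7)
    frames, gt = generate_flow_video(spec)
    return spec, frames, gt


@pytest.fixture(scope="session")
def helminth_scene():
    """Shared low-contrast (helminth-like) scene with 3 targets."""
    spec = FlowSceneSpec(n_objects=3, contrast_mode="low", seed=11,
                         major_axis_mean=50, minor_axis_mean=35)
    frames, gt = generate_flow_video(spec)
    return spec, frames, gt
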