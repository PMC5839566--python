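"""Pixel-based adaptive background subtraction (PBAS-style).

Each pixel keeps a bank of ``n_samples`` recent background intensities, a
per-pixel decision distance ``R(x)`` and a per-pixel inverse update
probability ``T(x)``.  A pixel is foreground when fewer than
``min_matches`` bank samples lie within ``R(x)`` of the current intensity.
Background-classified pixels stochastically refresh one bank sample with
probability ``1/T(x)`` and, with the same probability, refresh a random
sample of a random 8-neighbour with that neighbour's current intensity --
the spatial diffusion that slowly absorbs objects left static in the
scene.  ``R(x)`` tracks a running average of the minimal bank distance
(the scene's local dynamics) and ``T(x)`` rises on persistent foreground
so that true objects are not learned into the background.

The model is grayscale: colour frames are converted to luminance first.
A deliberately simple fallback (running-average background with a fixed
threshold) is available via ``simple_mode`` for debugging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .still import as_gray_u8

__all__ = ["PbasParams", "BackgroundState", "init_background",
           "segment_and_update"]


@dataclass
class PbasParams:
    """All internal constants, exposed for configuration.

    Defaults follow the published values of the pixel-based adaptive
    segmenter literature; none is treated as ground truth.
    """

    n_samples: int = 20           # bank size B
    min_matches: int = 2          # #min
    r_initial: float = 18.0
    r_lower: float = 18.0
    r_scale: float = 5.0
    r_inc_dec: float = 0.05
    t_initial: float = 16.0
    t_lower: float = 2.0
    t_upper: float = 200.0
    t_inc: float = 1.0
    t_dec: float = 0.05
    dmin_alpha: float = 0.05      # EMA rate of the mean-minimal-distance map
    neighbor_update: bool = True
    simple_mode: bool = False
    simple_alpha: float = 0.05
    simple_threshold: float = 25.0


@dataclass
class BackgroundState:
    bank: np.ndarray              # (B, H, W) float32
    r: np.ndarray                 # (H, W) decision threshold R(x)
    t: np.ndarray                 # (H, W) inverse update probability T(x)
    dmin_avg: np.ndarray          # (H, W) running mean minimal distance
    params: PbasParams
    rng: np.random.Generator
    frame_count: int = 0
    simple_bg: np.ndarray | None = None


def init_background(frames, params: PbasParams | None = None,
                    seed: int | np.random.Generator = 0) -> BackgroundState:
    """Seed the sample bank from one or more initial frames.

    With fewer than ``n_samples`` frames, the bank is filled by
    replicating the first frame with small spatial-neighbourhood jitter
    (each sample drawn from a random 8-neighbour), as is standard for
    single-frame initialization.
    """
    params = params or PbasParams()
    frames = [np.asarray(f) for f in frames]
    if len(frames) == 0:
        raise ValueError("need at least one frame to initialize background")
    gray = [as_gray_u8(f).astype(np.float32) for f in frames]
    h, w = gray[0].shape
    for g in gray:
        if g.shape != (h, w):
            raise ValueError("all initialization frames must share dimensions")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    B = params.n_samples
    bank = np.empty((B, h, w), dtype=np.float32)
    if len(gray) >= B:
        for k in range(B):
            bank[k] = gray[k]
    else:
        base = gray[0]
        rows = np.arange(h)[:, None]
        cols = np.arange(w)[None, :]
        bank[0] = base
        for k in range(1, B):
            dr = rng.integers(-1, 2, size=(h, w))
            dc = rng.integers(-1, 2, size=(h, w))
            rr = np.clip(rows + dr, 0, h - 1)
            cc = np.clip(cols + dc, 0, w - 1)
            bank[k] = base[rr, cc]
    state = BackgroundState(
        bank=bank,
        r=np.full((h, w), params.r_initial, dtype=np.float32),
        t=np.full((h, w), params.t_initial, dtype=np.float32),
        dmin_avg=np.full((h, w), params.r_initial / params.r_scale,
                         dtype=np.float32),
        params=params, rng=rng,
        simple_bg=gray[0].copy() if params.simple_mode else None)
    return state


def segment_and_update(state: BackgroundState, frame: np.ndarray):
    """Classify one frame and adapt the model.

    Returns ``(state, mask)`` with a boolean foreground mask; the state is
    updated in place.  Deterministic for a fixed state RNG.
    """
    p = state.params
    gray = as_gray_u8(np.asarray(frame)).astype(np.float32)
    if gray.shape != state.bank.shape[1:]:
        raise ValueError(
            f"frame shape {gray.shape} does not match model "
            f"{state.bank.shape[1:]}")
    state.frame_count += 1

    if p.simple_mode:
        mask = np.abs(gray - state.simple_bg) > p.simple_threshold
        state.simple_bg += p.simple_alpha * (gray - state.simple_bg)
        return state, mask

    diff = np.abs(state.bank - gray[None])
    matches = (diff < state.r[None]).sum(axis=0)
    fg = matches < p.min_matches
    bg = ~fg

    dmin = diff.min(axis=0)
    # track scene dynamics where the pixel is background
    state.dmin_avg[bg] += p.dmin_alpha * (dmin[bg] - state.dmin_avg[bg])

    # adapt R(x) toward r_scale * dmin_avg
    hi = state.r > state.dmin_avg * p.r_scale
    state.r[hi] *= (1.0 - p.r_inc_dec)
    state.r[~hi] *= (1.0 + p.r_inc_dec)
    np.clip(state.r, p.r_lower, None, out=state.r)

    # adapt T(x): slow down learning where foreground persists
    denom = np.maximum(state.dmin_avg, 1e-3)
    state.t[fg] += p.t_inc / denom[fg]
    state.t[bg] -= p.t_dec / denom[bg]
    np.clip(state.t, p.t_lower, p.t_upper, out=state.t)

    # stochastic bank refresh on background pixels
    h, w = gray.shape
    upd = bg & (state.rng.random((h, w)) < 1.0 / state.t)
    if upd.any():
        ks = state.rng.integers(0, p.n_samples, size=int(upd.sum()))
        rr, cc = np.nonzero(upd)
        state.bank[ks, rr, cc] = gray[rr, cc]
        if p.neighbor_update:
            dr = state.rng.integers(-1, 2, size=rr.size)
            dc = state.rng.integers(-1, 2, size=rr.size)
            nr = np.clip(rr + dr, 0, h - 1)
            nc = np.clip(cc + dc, 0, w - 1)
            ks2 = state.rng.integers(0, p.n_samples, size=rr.size)
            state.bank[ks2, nr, nc] = gray[nr, nc]
    return state, fg
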