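"""Correlation-targeted synthesis of image pairs.

Given a differentiable feature extractor with "constrained" (shallow) and
"target" (deep) taps, this module builds pairs of images whose target-tap
feature correlations follow a prescribed schedule (similarity levels from
r = 0 to r = 1) while constrained-tap correlations are held near a fixed
value, so pairs differ *only* in their deep-feature overlap.

The procedure has three phases:

1. **Endpoint channel selection** — optimize one image per channel of the
   deepest target layer, then pick the k least inter-correlated channel
   images and form them into k/2 endpoint pairs.
2. **Image initialization** — for each endpoint pair and similarity
   level, gradient-ascend two noise images on a weighted sum of the two
   endpoint channels (own channel at weight 1, pairmate channel at the
   intended correlation).
3. **Correlation tuning** — gradient-descend the squared difference
   between each tap's achieved inter-image correlation and its target,
   alternating updates between the two images.

Pixel gradients are smoothed by Laplacian-pyramid band normalization, and
the full init+tune procedure can be repeated over several "volleys" with
the image magnified between volleys; gradients are applied inside a
moving window so rarely-updated border pixels can be cropped at the end.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from math import comb, floor

import numpy as np
import pandas as pd
from skimage.transform import resize

from .features import Image, ToyConvNet, extract_features

__all__ = [
    "EndpointPair",
    "SynthesisSpec",
    "SynthesizedPair",
    "StimulusSet",
    "ValidationReport",
    "intended_schedule",
    "laplacian_regularize",
    "channel_image",
    "select_endpoints",
    "initialize_pair",
    "tune_pair",
    "multiscale_synthesize",
    "synthesize_grid",
    "validate_set",
    "pair_rng",
    "UndefinedCorrelationError",
    "OverCropError",
    "ConfigError",
]

_EXHAUSTIVE_SUBSET_LIMIT = 50_000
_FLAT_GRAD_TOL = 1e-12
_FLAT_GRAD_PATIENCE = 10


class ConfigError(ValueError):
    """Invalid synthesis configuration."""


class UndefinedCorrelationError(ValueError):
    """A tap produced a zero-variance activation vector."""


class OverCropError(RuntimeError):
    """The iteration-count crop would remove more than half of the pixels."""


@dataclass(frozen=True)
class EndpointPair:
    """Two channels of a target layer anchoring one similarity spectrum."""

    layer_id: str
    channel_a: int
    channel_b: int

    def __post_init__(self) -> None:
        if self.channel_a == self.channel_b:
            raise ConfigError("endpoint channels must differ")


@dataclass
class SynthesisSpec:
    """All tunable knobs of the synthesis procedure.

    ``schedule`` (the per-level intended target-tap correlation) defaults
    to ``intended_schedule(n_levels)``: linear from 0 to 1.
    """

    n_levels: int = 8
    constrained_target: float = 0.25
    init_iters: int = 200
    tune_iters: int = 200
    volleys: int = 3
    magnification: float = 1.4
    window_fraction: float = 0.9
    crop_quantile: float = 0.1
    step_size: float = 0.05
    pyramid_levels: int = 4
    image_size: int = 64
    seed: int = 0
    schedule: list[float] | None = None

    def __post_init__(self) -> None:
        if self.volleys < 1:
            raise ConfigError("volleys must be >= 1")
        if self.volleys > 1 and self.magnification <= 1:
            raise ConfigError("magnification must be > 1")
        if not 0 < self.window_fraction <= 1:
            raise ConfigError("window_fraction must be in (0, 1]")
        if not 0 <= self.crop_quantile < 1:
            raise ConfigError("crop_quantile must be in [0, 1)")
        if self.step_size <= 0:
            raise ConfigError("step_size must be positive")
        if self.schedule is None:
            self.schedule = intended_schedule(self.n_levels)
        else:
            s = list(self.schedule)
            if len(s) != self.n_levels or any(
                b <= a for a, b in zip(s, s[1:])
            ) or s[0] != 0 or s[-1] != 1:
                raise ConfigError("schedule must increase strictly from 0 to 1")


@dataclass
class SynthesizedPair:
    image_a: Image
    image_b: Image
    level: int
    endpoint: EndpointPair
    intended: dict[str, float]
    achieved: dict[str, float]
    cost_trace: np.ndarray
    endpoint_index: int = 0


@dataclass
class StimulusSet:
    """Grid of synthesized pairs over endpoints x similarity levels."""

    pairs: list[SynthesizedPair]
    n_endpoints: int
    n_levels: int
    spec: SynthesisSpec | None = None

    @property
    def n_images(self) -> int:
        return 2 * len(self.pairs)


def intended_schedule(n_levels: int = 8) -> list[float]:
    """Linearly spaced intended correlations: 0 at level 1, 1 at level n."""
    if n_levels < 2:
        raise ConfigError("need at least 2 similarity levels")
    return list(np.linspace(0.0, 1.0, n_levels))


def pair_rng(seed: int, endpoint_index: int, level: int) -> np.random.Generator:
    """The per-pair random stream (noise starts, window positions)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int(endpoint_index), int(level)])
    )


def noise_image(rng: np.random.Generator, size: int | tuple[int, int]) -> Image:
    """Gray-centered uniform noise start, matching a mid-range pixel prior."""
    if isinstance(size, int):
        size = (size, size)
    return Image(rng.uniform(0.4, 0.6, size=(size[0], size[1], 3)))


# -- Laplacian pyramid gradient regularization ---------------------------

def _pyramid_split(arr: np.ndarray, levels: int) -> list[np.ndarray]:
    bands: list[np.ndarray] = []
    cur = arr
    for _ in range(levels - 1):
        h, w = cur.shape[:2]
        if min(h, w) < 4:
            warnings.warn("image too small for requested pyramid levels; reducing")
            break
        down = resize(
            cur, ((h + 1) // 2, (w + 1) // 2), order=1, anti_aliasing=True,
            preserve_range=True,
        )
        up = resize(down, (h, w), order=1, preserve_range=True)
        bands.append(cur - up)
        cur = down
    bands.append(cur)
    return bands


def _pyramid_merge(bands: list[np.ndarray]) -> np.ndarray:
    out = bands[-1]
    for band in reversed(bands[:-1]):
        out = resize(out, band.shape[:2], order=1, preserve_range=True) + band
    return out


def laplacian_regularize(gradient: np.ndarray, pyramid_levels: int) -> np.ndarray:
    """Equalize the RMS energy of the gradient's frequency bands.

    Splitting the raw pixel gradient into Laplacian-pyramid bands and
    rescaling each band to unit RMS suppresses the high-frequency edges
    that activation maximization otherwise favors, letting low-frequency
    structure and color through.  Shape is preserved.
    """
    if pyramid_levels < 1:
        raise ConfigError("pyramid_levels must be >= 1")
    gradient = np.asarray(gradient, dtype=np.float64)
    bands = _pyramid_split(gradient, pyramid_levels)
    normed = []
    for band in bands:
        rms = np.sqrt(np.mean(band**2))
        normed.append(band / (rms + 1e-12))
    return _pyramid_merge(normed)


# -- correlation machinery ----------------------------------------------

def _pearson(a: np.ndarray, b: np.ndarray, name: str = "") -> float:
    ac = a - a.mean()
    bc = b - b.mean()
    na = np.linalg.norm(ac)
    nb = np.linalg.norm(bc)
    if na == 0 or nb == 0:
        raise UndefinedCorrelationError(
            f"zero-variance activation vector at tap {name!r}"
        )
    return float(ac @ bc / (na * nb))


def _pearson_and_grad(a: np.ndarray, b: np.ndarray, name: str = ""):
    """Pearson r(a, b) and its gradient with respect to ``a``."""
    ac = a - a.mean()
    bc = b - b.mean()
    na = np.linalg.norm(ac)
    nb = np.linalg.norm(bc)
    if na == 0 or nb == 0:
        raise UndefinedCorrelationError(
            f"zero-variance activation vector at tap {name!r}"
        )
    u = ac / na
    v = bc / nb
    r = float(u @ v)
    grad = (v - r * u) / na  # already mean-free, so centering adjoint is a no-op
    return r, grad


# -- shared gradient-step machinery --------------------------------------

def _draw_window(
    rng: np.random.Generator, shape: tuple[int, int], fraction: float
) -> tuple[slice, slice] | None:
    """Square moving window, uniform over positions fully inside the image."""
    if fraction >= 1.0:
        return None
    h, w = shape
    wh = max(1, int(np.ceil(fraction * h)))
    ww = max(1, int(np.ceil(fraction * w)))
    r0 = int(rng.integers(0, h - wh + 1))
    c0 = int(rng.integers(0, w - ww + 1))
    return slice(r0, r0 + wh), slice(c0, c0 + ww)


def _apply_step(
    pixels: np.ndarray,
    raw_grad: np.ndarray,
    spec: SynthesisSpec,
    sign: float,
    window: tuple[slice, slice] | None,
) -> tuple[np.ndarray, bool]:
    """One (regularized, windowed, normalized) gradient step on the pixels.

    Returns the updated pixels and whether the gradient was non-flat.
    """
    g = laplacian_regularize(raw_grad, spec.pyramid_levels)
    if window is not None:
        mask = np.zeros(pixels.shape[:2], dtype=bool)
        mask[window] = True
        g = np.where(mask[:, :, None], g, 0.0)
    scale = np.mean(np.abs(g))
    if scale < _FLAT_GRAD_TOL:
        return pixels, False
    g = g / scale
    return np.clip(pixels + sign * spec.step_size * g, 0.0, 1.0), True


def _bump_iter_count(
    iter_count: np.ndarray | None, window: tuple[slice, slice] | None
) -> None:
    if iter_count is None:
        return
    if window is None:
        iter_count += 1.0
    else:
        iter_count[window] += 1.0


# -- phase 1: channel images + endpoint selection -------------------------

def _channel_objective(extractor: ToyConvNet, layer_id: str, channel: int):
    """Objective: raw mean activation of one channel of one tap.

    Operates on the pre-normalization channel means (the normalized tap
    read-out has zero mean by construction).
    """
    tap = extractor.tap(layer_id)
    if not 0 <= channel < tap.n_channels:
        raise ConfigError(
            f"channel {channel} out of range for tap {layer_id!r}"
            f" ({tap.n_channels} channels)"
        )

    def objective(acts: dict[str, np.ndarray], chan_means: dict[str, np.ndarray]):
        value = float(chan_means[layer_id][channel])
        g = np.zeros(tap.n_channels)
        g[channel] = 1.0
        return value, {}, {layer_id: g}

    return objective


def _ascend(
    extractor: ToyConvNet,
    image: Image,
    objective,
    iters: int,
    spec: SynthesisSpec,
    rng: np.random.Generator | None,
    window_fraction: float,
    iter_count: np.ndarray | None,
) -> tuple[Image, np.ndarray]:
    """Maximize a scalar of tapped activations by projected gradient ascent."""
    pixels = image.pixels.copy()
    trace = []
    best_val = -np.inf
    best_pixels = pixels.copy()
    flat_streak = 0
    for _ in range(iters):
        acts, cache = extractor.forward(pixels, cache=True)
        means = {c["tap_id"]: c["chan_mean"] for c in cache}
        val, tap_grads, chan_grads = objective(acts, means)
        trace.append(val)
        if val > best_val:
            best_val = val
            best_pixels = pixels.copy()
        raw = extractor.backward(cache, tap_grads, chan_grads)
        window = (
            _draw_window(rng, pixels.shape[:2], window_fraction)
            if rng is not None
            else None
        )
        _bump_iter_count(iter_count, window)
        pixels, moved = _apply_step(pixels, raw, spec, +1.0, window)
        flat_streak = 0 if moved else flat_streak + 1
        if flat_streak >= _FLAT_GRAD_PATIENCE:
            warnings.warn("flat objective for 10 consecutive iterations")
            break
    if iters > 0:
        acts, cache = extractor.forward(pixels, cache=True)
        means = {c["tap_id"]: c["chan_mean"] for c in cache}
        val, _, _ = objective(acts, means)
        trace.append(val)
        if val > best_val:
            best_val = val
            best_pixels = pixels
    out = Image(best_pixels, image.iter_count.copy())
    return out, np.asarray(trace)


def channel_image(
    extractor: ToyConvNet,
    layer_id: str,
    channel: int,
    iters: int,
    spec: SynthesisSpec,
    rng: np.random.Generator | None = None,
    start: Image | None = None,
) -> Image:
    """Image maximizing the mean activation of one (layer, channel)."""
    objective = _channel_objective(extractor, layer_id, channel)
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([int(spec.seed), hash(layer_id) % (2**31), channel])
        )
    if start is None:
        start = noise_image(rng, spec.image_size)
    if iters == 0:
        return start
    img, _ = _ascend(
        extractor, start, objective, iters, spec, rng, 1.0, None
    )
    return img


def select_endpoints(
    channel_images: list[Image],
    extractor: ToyConvNet,
    target_taps: list[str] | None = None,
    k: int = 16,
    endpoint_layer: str | None = None,
) -> list[EndpointPair]:
    """Pick the k least inter-correlated channel images; pair them into k/2.

    ``channel_images[i]`` is the optimized image for channel ``i`` of the
    endpoint layer (the deepest target tap unless given).  Subset choice
    minimizes the total absolute inter-correlation of the chosen k —
    exhaustively when the subset count is small, otherwise by greedy
    backward elimination (repeatedly dropping the image with the largest
    mean absolute correlation to the rest).  Survivors are paired
    greedily by ascending absolute correlation.
    """
    n = len(channel_images)
    if k > n:
        raise ConfigError(f"k={k} exceeds the {n} available channel images")
    if k < 2 or k % 2:
        raise ConfigError("k must be an even integer >= 2")
    if target_taps is None:
        target_taps = extractor.target_taps
    if endpoint_layer is None:
        endpoint_layer = target_taps[-1]

    feats = np.stack(
        [
            np.concatenate(
                [v for v in extract_features(extractor, img, target_taps).values()]
            )
            for img in channel_images
        ]
    )
    corr = np.corrcoef(feats)
    abs_corr = np.abs(corr)
    np.fill_diagonal(abs_corr, 0.0)

    if comb(n, k) <= _EXHAUSTIVE_SUBSET_LIMIT:
        best_total, best_subset = np.inf, None
        for subset in itertools.combinations(range(n), k):
            idx = np.asarray(subset)
            total = abs_corr[np.ix_(idx, idx)].sum() / 2.0
            if total < best_total - 1e-15:
                best_total, best_subset = total, list(subset)
        chosen = best_subset
    else:
        chosen = list(range(n))
        while len(chosen) > k:
            sub = abs_corr[np.ix_(chosen, chosen)]
            worst = int(np.argmax(sub.mean(axis=1)))
            chosen.pop(worst)

    # pair survivors: ascending |r|, greedily disjoint
    cand = sorted(
        ((abs_corr[i, j], i, j) for i, j in itertools.combinations(chosen, 2)),
        key=lambda t: (t[0], t[1], t[2]),
    )
    used: set[int] = set()
    pairs: list[EndpointPair] = []
    for _, i, j in cand:
        if i in used or j in used:
            continue
        pairs.append(EndpointPair(endpoint_layer, i, j))
        used.update((i, j))
    return pairs


# -- phase 2: weighted-channel initialization -----------------------------

def initialize_pair(
    extractor: ToyConvNet,
    endpoint: EndpointPair,
    weight: float,
    which: str,
    spec: SynthesisSpec,
    rng: np.random.Generator,
    start: Image | None = None,
    init_iters: int | None = None,
    window_fraction: float = 1.0,
    iter_count: np.ndarray | None = None,
) -> Image:
    """Ascend one image on own-channel + weight x pairmate-channel activation.

    For image A the "own" channel is ``endpoint.channel_a`` (weighted 1)
    and the pairmate channel is weighted by the intended correlation; for
    image B the roles swap.
    """
    if not 0 <= weight <= 1:
        raise ConfigError("weight must be in [0, 1]")
    if which not in ("A", "B"):
        raise ConfigError("which must be 'A' or 'B'")
    own = endpoint.channel_a if which == "A" else endpoint.channel_b
    other = endpoint.channel_b if which == "A" else endpoint.channel_a
    obj_own = _channel_objective(extractor, endpoint.layer_id, own)
    obj_other = _channel_objective(extractor, endpoint.layer_id, other)

    def objective(acts, means):
        v1, _, g1 = obj_own(acts, means)
        v2, _, g2 = obj_other(acts, means)
        g = {endpoint.layer_id: g1[endpoint.layer_id] + weight * g2[endpoint.layer_id]}
        return v1 + weight * v2, {}, g

    if start is None:
        start = noise_image(rng, spec.image_size)
    iters = spec.init_iters if init_iters is None else init_iters
    if iters == 0:
        return start
    img, _ = _ascend(
        extractor, start, objective, iters, spec, rng, window_fraction, iter_count
    )
    return img


# -- phase 3: correlation tuning ------------------------------------------

def pair_targets(
    extractor: ToyConvNet, spec: SynthesisSpec, level_target: float
) -> dict[str, float]:
    """Per-tap intended correlations: constant at constrained taps,
    the level's schedule value at target taps."""
    targets = {lid: spec.constrained_target for lid in extractor.constrained_taps}
    targets.update({lid: float(level_target) for lid in extractor.target_taps})
    return targets


def achieved_correlations(
    extractor: ToyConvNet, image_a: Image, image_b: Image
) -> dict[str, float]:
    """Fresh forward passes; Pearson r between A and B vectors per tap."""
    fa = extractor.forward(image_a.pixels)
    fb = extractor.forward(image_b.pixels)
    return {lid: _pearson(fa[lid], fb[lid], lid) for lid in extractor.tap_ids}


def tune_pair(
    extractor: ToyConvNet,
    image_a: Image,
    image_b: Image,
    targets: dict[str, float],
    tune_iters: int,
    spec: SynthesisSpec,
    rng: np.random.Generator | None = None,
    window_fraction: float = 1.0,
    iter_count: np.ndarray | None = None,
    level: int = 0,
    endpoint: EndpointPair | None = None,
    endpoint_index: int = 0,
) -> SynthesizedPair:
    """Drive per-tap inter-image correlations to their targets.

    Minimizes ``sum_l (r_l - t_l)^2`` by alternating pixel updates
    between the two images.  The returned pair holds the best-so-far
    images (so the cost trace is non-increasing) and correlations
    re-measured on them by fresh forward passes.
    """
    for lid in targets:
        extractor.tap(lid)
    tap_ids = list(targets)
    pixels = {"A": image_a.pixels.copy(), "B": image_b.pixels.copy()}
    acts = {w: extractor.forward(pixels[w]) for w in ("A", "B")}

    def total_cost(fa, fb) -> float:
        return sum(
            (_pearson(fa[lid], fb[lid], lid) - targets[lid]) ** 2 for lid in tap_ids
        )

    best_cost = total_cost(acts["A"], acts["B"])
    best_pixels = {w: pixels[w].copy() for w in ("A", "B")}
    trace = [best_cost]
    flat_streak = 0
    for i in range(tune_iters):
        upd, other = ("A", "B") if i % 2 == 0 else ("B", "A")
        f_upd, cache = extractor.forward(pixels[upd], cache=True)
        f_oth = acts[other]
        tap_grads = {}
        cost = 0.0
        for lid in tap_ids:
            r, dr = _pearson_and_grad(f_upd[lid], f_oth[lid], lid)
            resid = r - targets[lid]
            cost += resid**2
            tap_grads[lid] = 2.0 * resid * dr
        if cost < best_cost:
            best_cost = cost
            best_pixels = {w: pixels[w].copy() for w in ("A", "B")}
        trace.append(best_cost)
        raw = extractor.backward(cache, tap_grads)
        window = (
            _draw_window(rng, pixels[upd].shape[:2], window_fraction)
            if rng is not None
            else None
        )
        _bump_iter_count(iter_count, window)
        new_pixels, moved = _apply_step(pixels[upd], raw, spec, -1.0, window)
        flat_streak = 0 if moved else flat_streak + 1
        pixels[upd] = new_pixels
        acts[upd] = extractor.forward(new_pixels)
        if flat_streak >= _FLAT_GRAD_PATIENCE:
            break
    final_cost = total_cost(acts["A"], acts["B"])
    if final_cost < best_cost:
        best_cost = final_cost
        best_pixels = pixels
    trace.append(best_cost)

    out_a = Image(best_pixels["A"], image_a.iter_count.copy())
    out_b = Image(best_pixels["B"], image_b.iter_count.copy())
    achieved = achieved_correlations(extractor, out_a, out_b)
    intended = dict(targets)
    if endpoint is None:
        endpoint = EndpointPair(extractor.target_taps[-1], 0, 1)
    return SynthesizedPair(
        image_a=out_a,
        image_b=out_b,
        level=level,
        endpoint=endpoint,
        intended=intended,
        achieved=achieved,
        cost_trace=np.asarray(trace),
        endpoint_index=endpoint_index,
    )


# -- multi-scale driver ----------------------------------------------------

def _round_half_up(x: float) -> int:
    return int(floor(x + 0.5))


def _magnify(pixels: np.ndarray, factor: float) -> np.ndarray:
    h, w = pixels.shape[:2]
    new = (_round_half_up(h * factor), _round_half_up(w * factor))
    out = resize(pixels, new, order=1, preserve_range=True, anti_aliasing=False)
    return out


def _crop_bounds(values: np.ndarray, threshold: float) -> tuple[int, int]:
    lo, hi = 0, len(values)
    while lo < hi and values[lo] < threshold:
        lo += 1
    while hi > lo and values[hi - 1] < threshold:
        hi -= 1
    return lo, hi


def crop_by_iter_count(
    image_a: Image, image_b: Image, iter_count: np.ndarray, crop_quantile: float
) -> tuple[Image, Image, np.ndarray]:
    """Strip boundary rows/columns whose mean update count is low.

    The threshold is the ``crop_quantile`` quantile of the per-row (resp.
    per-column) mean counts; both images of a pair share one update-count
    map so their crops agree and activation vectors stay comparable.
    """
    row_means = iter_count.mean(axis=1)
    col_means = iter_count.mean(axis=0)
    r0, r1 = _crop_bounds(row_means, np.quantile(row_means, crop_quantile))
    c0, c1 = _crop_bounds(col_means, np.quantile(col_means, crop_quantile))
    h, w = iter_count.shape
    kept = (r1 - r0) * (c1 - c0)
    if kept < 0.5 * h * w:
        raise OverCropError(
            f"crop keeps {kept}/{h * w} pixels "
            f"(rows {r0}:{r1} of {h}, cols {c0}:{c1} of {w})"
        )
    sl = (slice(r0, r1), slice(c0, c1))
    cropped_count = iter_count[sl]
    a = Image(image_a.pixels[sl], cropped_count.copy())
    b = Image(image_b.pixels[sl], cropped_count.copy())
    return a, b, cropped_count


def multiscale_synthesize(
    extractor: ToyConvNet,
    endpoint: EndpointPair,
    level: int,
    spec: SynthesisSpec,
    endpoint_index: int = 0,
    rng: np.random.Generator | None = None,
) -> SynthesizedPair:
    """Full init+tune procedure per volley, with magnification and crop.

    With ``volleys=1``, ``window_fraction=1`` and ``crop_quantile=0``
    this reduces exactly to two :func:`initialize_pair` calls followed by
    one :func:`tune_pair` call on the same random stream.
    """
    if not 1 <= level <= spec.n_levels:
        raise ConfigError(f"level must be in 1..{spec.n_levels}")
    t_level = spec.schedule[level - 1]
    targets = pair_targets(extractor, spec, t_level)
    if rng is None:
        rng = pair_rng(spec.seed, endpoint_index, level)

    img_a = noise_image(rng, spec.image_size)
    img_b = noise_image(rng, spec.image_size)
    iter_count = np.zeros(img_a.shape, dtype=np.float64)
    pair: SynthesizedPair | None = None
    for volley in range(spec.volleys):
        img_a = initialize_pair(
            extractor, endpoint, t_level, "A", spec, rng,
            start=img_a, window_fraction=spec.window_fraction,
            iter_count=iter_count,
        )
        img_b = initialize_pair(
            extractor, endpoint, t_level, "B", spec, rng,
            start=img_b, window_fraction=spec.window_fraction,
            iter_count=iter_count,
        )
        pair = tune_pair(
            extractor, img_a, img_b, targets, spec.tune_iters, spec, rng,
            window_fraction=spec.window_fraction, iter_count=iter_count,
            level=level, endpoint=endpoint, endpoint_index=endpoint_index,
        )
        img_a, img_b = pair.image_a, pair.image_b
        if volley < spec.volleys - 1:
            img_a = Image(np.clip(_magnify(img_a.pixels, spec.magnification), 0, 1))
            img_b = Image(np.clip(_magnify(img_b.pixels, spec.magnification), 0, 1))
            iter_count = _magnify(iter_count, spec.magnification)
    assert pair is not None
    if spec.crop_quantile > 0:
        img_a, img_b, iter_count = crop_by_iter_count(
            img_a, img_b, iter_count, spec.crop_quantile
        )
        pair.achieved = achieved_correlations(extractor, img_a, img_b)
    img_a.iter_count = iter_count.copy()
    img_b.iter_count = iter_count.copy()
    pair.image_a, pair.image_b = img_a, img_b
    return pair


def synthesize_grid(
    extractor: ToyConvNet,
    spec: SynthesisSpec,
    n_endpoints: int = 8,
    channel_iters: int = 50,
    endpoints: list[EndpointPair] | None = None,
    progress: bool = False,
) -> StimulusSet:
    """Endpoint selection plus the full endpoints x levels synthesis grid."""
    if endpoints is None:
        layer = extractor.target_taps[-1]
        n_channels = extractor.tap(layer).n_channels
        if 2 * n_endpoints > n_channels:
            raise ConfigError(
                f"{n_endpoints} endpoint pairs need {2 * n_endpoints} channels; "
                f"target layer {layer!r} has {n_channels}"
            )
        imgs = [
            channel_image(extractor, layer, ch, channel_iters, spec)
            for ch in range(n_channels)
        ]
        endpoints = select_endpoints(imgs, extractor, k=2 * n_endpoints)
    pairs = []
    for e_idx, endpoint in enumerate(endpoints):
        for level in range(1, spec.n_levels + 1):
            if progress:
                print(f"endpoint {e_idx + 1}/{len(endpoints)} level {level}")
            pairs.append(
                multiscale_synthesize(extractor, endpoint, level, spec, e_idx)
            )
    return StimulusSet(pairs, len(endpoints), spec.n_levels, spec)


def desk_scale_spec(seed: int = 0) -> SynthesisSpec:
    """Desk-scale validation settings for a full 8 x 8 grid.

    Single volley at 64 x 64 with 100 init + 100 tune iterations, full
    gradient window and no crop: small enough to synthesize all 64 pairs
    (128 images) on one CPU in a few minutes while exercising every
    phase of the procedure except the multi-scale magnification loop.
    """
    return SynthesisSpec(
        init_iters=100,
        tune_iters=100,
        volleys=1,
        window_fraction=1.0,
        crop_quantile=0.0,
        image_size=64,
        seed=seed,
    )


def synthesize_validation_grid(seed: int = 0, extractor: ToyConvNet | None = None):
    """Full desk-scale grid (endpoint selection + 64 pairs) on a toy extractor."""
    from .features import make_toy_extractor

    if extractor is None:
        extractor = make_toy_extractor(seed=seed)
    spec = desk_scale_spec(seed)
    stimset = synthesize_grid(extractor, spec, n_endpoints=8, channel_iters=50)
    return stimset, extractor


# -- validation ------------------------------------------------------------

@dataclass
class ValidationReport:
    """Achieved-vs-intended summary for a stimulus grid.

    ``pair_table`` holds one row per pair per tap (achieved and intended
    r); ``second_order`` the intended-vs-achieved Pearson correlation per
    target tap across pairs (NaN when achieved values have no variance);
    ``constrained_summary`` mean and SD of achieved r per constrained tap.
    """

    pair_table: pd.DataFrame
    second_order: dict[str, float]
    constrained_summary: dict[str, tuple[float, float]]


def validate_set(stimulus_set: StimulusSet, extractor: ToyConvNet) -> ValidationReport:
    expected = stimulus_set.n_endpoints * stimulus_set.n_levels
    if len(stimulus_set.pairs) != expected:
        raise ValueError(
            f"incomplete stimulus set: {len(stimulus_set.pairs)} pairs, "
            f"expected {expected}"
        )
    rows = []
    for pair in stimulus_set.pairs:
        achieved = achieved_correlations(extractor, pair.image_a, pair.image_b)
        for lid, r in achieved.items():
            rows.append(
                {
                    "endpoint_index": pair.endpoint_index,
                    "level": pair.level,
                    "tap": lid,
                    "role": extractor.tap(lid).role,
                    "intended": pair.intended.get(lid, np.nan),
                    "achieved": r,
                }
            )
    table = pd.DataFrame(rows)
    second_order: dict[str, float] = {}
    for lid in extractor.target_taps:
        sub = table[table["tap"] == lid]
        if sub["achieved"].std() == 0 or sub["intended"].std() == 0:
            second_order[lid] = float("nan")
        else:
            second_order[lid] = float(
                np.corrcoef(sub["intended"], sub["achieved"])[0, 1]
            )
    constrained_summary = {
        lid: (
            float(table.loc[table["tap"] == lid, "achieved"].mean()),
            float(table.loc[table["tap"] == lid, "achieved"].std(ddof=1)),
        )
        for lid in extractor.constrained_taps
    }
    return ValidationReport(table, second_order, constrained_summary)
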