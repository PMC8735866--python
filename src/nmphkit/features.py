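"""Pluggable differentiable feature extractors.

The synthesis engine only needs two things from a feature extractor: a
deterministic forward pass that yields a flattened activation vector at
each tapped layer, and the gradient of any scalar function of those
activations with respect to the input pixels.  This module defines that
contract and provides a small fixed-random-weight convolutional network
(:class:`ToyConvNet`) that satisfies it, so the whole synthesis pipeline
is testable at desk scale without pretrained weights.

Images are height x width x 3 arrays with values in [0, 1].  Activations
are flattened channel-major (channel, row, column), a fixed order chosen
for reproducibility.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from PIL import Image as PILImage

__all__ = [
    "Image",
    "LayerTap",
    "ToyConvNet",
    "make_toy_extractor",
    "extract_features",
    "TapNotFoundError",
    "InvalidInputError",
    "save_image",
    "load_image",
]


class TapNotFoundError(KeyError):
    """Requested layer id is not a tap of the extractor."""


class InvalidInputError(ValueError):
    """Image violates the pixel contract (non-finite or wrong shape)."""


@dataclass
class Image:
    """Optimizable image: pixels in [0, 1] plus a per-pixel update count.

    ``iter_count`` records how many times each pixel location was inside
    the moving gradient window, which later drives the boundary crop.
    """

    pixels: np.ndarray  # (H, W, 3) float64 in [0, 1]
    iter_count: np.ndarray | None = None  # (H, W) float64, >= 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise InvalidInputError(
                f"pixels must be (H, W, 3), got {self.pixels.shape}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise InvalidInputError("pixels contain non-finite values")
        if self.iter_count is None:
            self.iter_count = np.zeros(self.pixels.shape[:2], dtype=np.float64)
        else:
            self.iter_count = np.asarray(self.iter_count, dtype=np.float64)
            if self.iter_count.shape != self.pixels.shape[:2]:
                raise InvalidInputError("iter_count shape mismatch")
            if np.any(self.iter_count < 0):
                raise InvalidInputError("iter_count must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def copy(self) -> "Image":
        return Image(self.pixels.copy(), self.iter_count.copy())


@dataclass(frozen=True)
class LayerTap:
    """One tapped layer: its id, role in synthesis, and depth."""

    layer_id: str
    role: str  # "constrained" | "target"
    depth_rank: int
    n_channels: int

    def __post_init__(self) -> None:
        if self.role not in ("constrained", "target"):
            raise ValueError(f"unknown tap role {self.role!r}")


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, z)


def _conv_same(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """'same' cross-correlation.  x: (Cin, H, W), w: (Cout, Cin, k, k)."""
    k = w.shape[-1]
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k), axis=(1, 2))  # (Cin, H, W, k, k)
    return np.einsum("chwij,ocij->ohw", win, w, optimize=True)


def _conv_same_input_grad(gy: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Gradient of _conv_same w.r.t. x: full correlation with flipped kernel."""
    k = w.shape[-1]
    p = k // 2
    gp = np.pad(gy, ((0, 0), (p, p), (p, p)))
    win = sliding_window_view(gp, (k, k), axis=(1, 2))  # (Cout, H, W, k, k)
    return np.einsum("ohwij,ocij->chw", win, w[:, :, ::-1, ::-1], optimize=True)


def _avgpool2(a: np.ndarray) -> np.ndarray:
    """2x2 average pool, floor mode (trailing odd row/column dropped)."""
    c, h, w = a.shape
    h2, w2 = h // 2, w // 2
    t = a[:, : 2 * h2, : 2 * w2].reshape(c, h2, 2, w2, 2)
    return t.mean(axis=(2, 4))


def _avgpool2_grad(g: np.ndarray, in_shape: tuple[int, int, int]) -> np.ndarray:
    c, h, w = in_shape
    h2, w2 = g.shape[1], g.shape[2]
    out = np.zeros(in_shape, dtype=g.dtype)
    expanded = np.repeat(np.repeat(g, 2, axis=1), 2, axis=2) / 4.0
    out[:, : 2 * h2, : 2 * w2] = expanded
    return out


class ToyConvNet:
    """Fixed-random-weight convolutional hierarchy with tapped layers.

    Each layer is a 3x3 'same' convolution followed by a softplus
    nonlinearity (smooth, so pixel gradients match finite differences to
    high precision); layers after the first are preceded by 2x2 average
    pooling, giving a spatial hierarchy loosely analogous to successive
    stages of a vision network.  Shallow taps play the "constrained" role
    during synthesis and the deepest tap(s) the "target" role.

    Tap read-outs are response-normalized: each channel's activation map
    is standardized (zero mean, unit variance over spatial positions)
    before flattening.  Without this, inter-image Pearson correlations of
    raw softplus features are dominated by image-independent channel-gain
    structure and sit near 1 for *any* two images; normalization (in the
    spirit of the local response normalization used by classic vision
    networks) makes the full correlation range reachable.  Channel
    maximization objectives instead address the raw (pre-normalization)
    per-channel mean activations, which the normalized read-out would
    erase by construction.
    """

    def __init__(
        self,
        weights: list[np.ndarray],
        biases: list[np.ndarray],
        taps: list[LayerTap],
        config: dict | None = None,
    ) -> None:
        if len(weights) != len(taps):
            raise ValueError("one tap per layer expected")
        self.weights = weights
        self.biases = biases
        self.taps = sorted(taps, key=lambda t: t.depth_rank)
        self._tap_by_id = {t.layer_id: t for t in self.taps}
        if len(self._tap_by_id) != len(self.taps):
            raise ValueError("layer ids must be unique")
        self.config = config or {}

    # -- contract surface ------------------------------------------------
    @property
    def tap_ids(self) -> list[str]:
        return [t.layer_id for t in self.taps]

    @property
    def constrained_taps(self) -> list[str]:
        return [t.layer_id for t in self.taps if t.role == "constrained"]

    @property
    def target_taps(self) -> list[str]:
        return [t.layer_id for t in self.taps if t.role == "target"]

    def tap(self, layer_id: str) -> LayerTap:
        try:
            return self._tap_by_id[layer_id]
        except KeyError:
            raise TapNotFoundError(layer_id) from None

    def activation_maps(self, pixels: np.ndarray) -> dict[str, np.ndarray]:
        """Forward pass returning normalized (C, H, W) tap maps."""
        acts, _ = self._forward(pixels, keep_cache=False)
        return acts

    def forward(
        self, pixels: np.ndarray, cache: bool = False
    ) -> dict[str, np.ndarray] | tuple[dict[str, np.ndarray], list]:
        """Flattened (channel-major) normalized activation vector per tap.

        With ``cache=True`` also returns the intermediates needed by
        :meth:`backward`.
        """
        acts, cache_list = self._forward(pixels, keep_cache=cache)
        flat = {k: v.ravel() for k, v in acts.items()}
        if cache:
            return flat, cache_list
        return flat

    def channel_means(self, pixels: np.ndarray) -> dict[str, np.ndarray]:
        """Raw (pre-normalization) per-channel mean activation per tap."""
        _, cache = self._forward(pixels, keep_cache=True)
        return {c["tap_id"]: c["chan_mean"] for c in cache}

    def backward(
        self,
        cache: list,
        tap_grads: dict[str, np.ndarray] | None = None,
        chan_grads: dict[str, np.ndarray] | None = None,
    ) -> np.ndarray:
        """Pixel gradient of a scalar of tapped activations.

        ``tap_grads`` maps layer ids to flattened cotangents of the
        *normalized* feature vectors; ``chan_grads`` maps layer ids to
        per-channel cotangents of the *raw* channel-mean activations.
        The return value has the (H, W, 3) shape of the input image.
        """
        tap_grads = tap_grads or {}
        chan_grads = chan_grads or {}
        for lid in (*tap_grads, *chan_grads):
            self.tap(lid)
        grad_next: np.ndarray | None = None
        for layer in reversed(range(len(self.weights))):
            c = cache[layer]
            tap_id, z, a_shape, pre_pool_shape = (
                c["tap_id"], c["z"], c["a_shape"], c["pre_pool_shape"],
            )
            n_spatial = a_shape[1] * a_shape[2]
            ga = np.zeros(a_shape, dtype=np.float64)
            if tap_id in tap_grads:
                gy = np.asarray(tap_grads[tap_id], dtype=np.float64).reshape(a_shape)
                # response-normalization VJP, per channel over spatial dims
                y, sigma = c["y"], c["sigma"]
                gym = gy.mean(axis=(1, 2), keepdims=True)
                gyy = (gy * y).mean(axis=(1, 2), keepdims=True)
                ga += (gy - gym - y * gyy) / sigma
            if tap_id in chan_grads:
                gc = np.asarray(chan_grads[tap_id], dtype=np.float64)
                ga += gc[:, None, None] / n_spatial
            if grad_next is not None:
                ga += grad_next
            gz = ga * _sigmoid(z)
            gx = _conv_same_input_grad(gz, self.weights[layer])
            if layer > 0:
                # undo the pooling that preceded this layer's convolution
                grad_next = _avgpool2_grad(gx, pre_pool_shape)
            else:
                grad_next = gx
        assert grad_next is not None
        return np.moveaxis(grad_next, 0, -1)

    # -- internals -------------------------------------------------------
    def _forward(self, pixels: np.ndarray, keep_cache: bool):
        pixels = np.asarray(pixels, dtype=np.float64)
        if pixels.ndim != 3 or pixels.shape[2] != 3:
            raise InvalidInputError(f"expected (H, W, 3) pixels, got {pixels.shape}")
        if not np.all(np.isfinite(pixels)):
            raise InvalidInputError("pixels contain non-finite values")
        x = np.moveaxis(pixels, -1, 0)  # (3, H, W)
        acts: dict[str, np.ndarray] = {}
        cache: list[dict] = []
        for layer, (w, b, tap) in enumerate(zip(self.weights, self.biases, self.taps)):
            pre_pool_shape = x.shape
            if layer > 0:
                x = _avgpool2(x)
            z = _conv_same(x, w) + b[:, None, None]
            a = _softplus(z)
            mu = a.mean(axis=(1, 2), keepdims=True)
            sigma = np.sqrt(((a - mu) ** 2).mean(axis=(1, 2), keepdims=True) + 1e-10)
            y = (a - mu) / sigma
            acts[tap.layer_id] = y
            cache.append(
                {
                    "tap_id": tap.layer_id,
                    "z": z if keep_cache else None,
                    "y": y if keep_cache else None,
                    "sigma": sigma if keep_cache else None,
                    "chan_mean": mu.reshape(-1),
                    "a_shape": a.shape,
                    "pre_pool_shape": pre_pool_shape,
                }
            )
            x = a
        return acts, cache


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def make_toy_extractor(
    seed: int,
    n_layers: int = 3,
    channels: tuple[int, ...] | list[int] = (8, 8, 16),
    n_target_layers: int = 1,
    weight_scale: float = 1.5,
) -> ToyConvNet:
    """Build a deterministic toy extractor from a seed.

    Parameters
    ----------
    seed:
        Master seed; identical seeds give bitwise-identical extractors.
    n_layers:
        Number of conv layers (>= 2: the constrained and target roles
        need distinct depths).
    channels:
        Output channels per layer; its length must equal ``n_layers``.
    n_target_layers:
        How many of the deepest taps act as correlation targets; all
        shallower taps are constrained.
    weight_scale:
        Multiplier on the 1/sqrt(fan_in) weight standard deviation;
        values slightly above 1 keep deep activations from flattening
        out under repeated pooling.
    """
    if n_layers < 2:
        raise ValueError("need n_layers >= 2 (distinct constrained and target layers)")
    channels = tuple(int(c) for c in channels)
    if len(channels) != n_layers:
        raise ValueError("len(channels) must equal n_layers")
    if any(c <= 0 for c in channels):
        raise ValueError("channels must be positive")
    if not 1 <= n_target_layers < n_layers:
        raise ValueError("n_target_layers must be in [1, n_layers)")

    rng = np.random.default_rng(seed)
    weights, biases, taps = [], [], []
    c_in = 3
    for layer, c_out in enumerate(channels):
        fan_in = c_in * 9
        w = rng.standard_normal((c_out, c_in, 3, 3)) * (weight_scale / np.sqrt(fan_in))
        b = rng.standard_normal(c_out) * 0.1
        role = "target" if layer >= n_layers - n_target_layers else "constrained"
        taps.append(LayerTap(f"conv{layer + 1}", role, layer, c_out))
        weights.append(w)
        biases.append(b)
        c_in = c_out
    config = {
        "seed": int(seed),
        "n_layers": int(n_layers),
        "channels": list(channels),
        "n_target_layers": int(n_target_layers),
        "weight_scale": float(weight_scale),
    }
    return ToyConvNet(weights, biases, taps, config)


def extract_features(
    extractor: ToyConvNet, image: Image | np.ndarray, taps: list[str] | None = None
) -> dict[str, np.ndarray]:
    """Flattened activation vectors for the requested taps.

    Deterministic: the same image always yields identical vectors.
    """
    pixels = image.pixels if isinstance(image, Image) else np.asarray(image)
    if taps is None:
        taps = extractor.tap_ids
    for lid in taps:
        extractor.tap(lid)
    acts = extractor.forward(pixels)
    return {lid: acts[lid] for lid in taps}


# -- extractor config + image round-tripping -----------------------------

def save_extractor_config(extractor: ToyConvNet, path: str | Path) -> None:
    if not extractor.config:
        raise ValueError("extractor has no serializable config")
    Path(path).write_text(json.dumps(extractor.config, indent=2))


def load_extractor_config(path: str | Path) -> ToyConvNet:
    cfg = json.loads(Path(path).read_text())
    return make_toy_extractor(
        seed=cfg["seed"],
        n_layers=cfg["n_layers"],
        channels=cfg["channels"],
        n_target_layers=cfg["n_target_layers"],
        weight_scale=cfg.get("weight_scale", 1.5),
    )


def save_image(image: Image | np.ndarray, path: str | Path) -> None:
    """Write pixels as 8-bit RGB PNG (values scaled x255, rounded)."""
    pixels = image.pixels if isinstance(image, Image) else np.asarray(image)
    arr = np.rint(np.clip(pixels, 0.0, 1.0) * 255.0).astype(np.uint8)
    PILImage.fromarray(arr, mode="RGB").save(Path(path), format="PNG")


def load_image(path: str | Path) -> Image:
    arr = np.asarray(PILImage.open(Path(path)).convert("RGB"), dtype=np.float64)
    return Image(arr / 255.0)
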