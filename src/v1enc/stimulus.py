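"""Model-input construction.

Each trial's input to the encoder is a 6-channel tensor: the dataset-
normalized image, the same image additionally centered by its own mean, and
four constant planes broadcasting the merged object box (x, y, w, h).
Responses are standardized by the per-neuron training-set scale, and
anatomical coordinates are mapped per subject into (-1, 1) per axis.
"""

from __future__ import annotations

import numpy as np

from .objects import YoloBox


def build_input(
    image: np.ndarray,
    image_mean: float,
    image_std: float,
    box: YoloBox,
    image_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Assemble the (6, H, W) stimulus tensor for one trial.

    Channel 1 is ``(I - image_mean) / image_std`` (dataset statistics);
    channel 2 subtracts that channel's own per-image mean; channels 3-6 are
    the object-box fractions broadcast over the frame.

    ``image_shape`` optionally pins the expected (H, W); pass the simulator's
    reduced shape when working at reduced resolution.
    """
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 2:
        raise ValueError(f"image must be 2-D, got shape {image.shape}")
    if image_shape is not None and image.shape != tuple(image_shape):
        raise ValueError(f"image shape {image.shape} != expected {tuple(image_shape)}")
    if not image_std > 0:
        raise ValueError(f"image_std must be positive, got {image_std}")
    h, w = image.shape
    norm = (image - np.float32(image_mean)) / np.float32(image_std)
    centered = norm - norm.mean(dtype=np.float64).astype(np.float32)
    out = np.empty((6, h, w), dtype=np.float32)
    out[0] = norm
    out[1] = centered
    out[2] = box.x
    out[3] = box.y
    out[4] = box.w
    out[5] = box.h
    return out


def build_inputs(
    images: np.ndarray,
    image_mean: float,
    image_std: float,
    boxes: list[YoloBox],
) -> np.ndarray:
    """Vectorized :func:`build_input` over a stack of images -> (N, 6, H, W)."""
    images = np.asarray(images, dtype=np.float32)
    if images.ndim != 3:
        raise ValueError("images must be (N, H, W)")
    if len(boxes) != len(images):
        raise ValueError("one YoloBox per image required")
    if not image_std > 0:
        raise ValueError(f"image_std must be positive, got {image_std}")
    n, h, w = images.shape
    out = np.empty((n, 6, h, w), dtype=np.float32)
    norm = (images - np.float32(image_mean)) / np.float32(image_std)
    out[:, 0] = norm
    out[:, 1] = norm - norm.mean(axis=(1, 2), keepdims=True)
    bx = np.array([[b.x, b.y, b.w, b.h] for b in boxes], dtype=np.float32)
    out[:, 2:6] = bx[:, :, None, None]
    return out


def standardize_responses(responses: np.ndarray, response_std: np.ndarray) -> np.ndarray:
    """Divide responses elementwise by the per-neuron scale ``s_r``.

    Works on a single trial vector (m,) or a stack (N, m).
    """
    responses = np.asarray(responses, dtype=np.float64)
    s = np.asarray(response_std, dtype=np.float64)
    if responses.shape[-1] != s.shape[-1]:
        raise ValueError(f"length mismatch: responses {responses.shape} vs s_r {s.shape}")
    if np.any(s <= 0):
        raise ValueError("all entries of s_r must be positive")
    return responses / s


def normalize_coordinates(coords: np.ndarray) -> np.ndarray:
    """Map per-neuron anatomical coordinates into [-1, 1] per axis.

    Each axis is centered by its mean, then divided by the post-centering
    absolute maximum, so every axis touches -1 or +1. A constant axis is
    degenerate geometry and raises.
    """
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2:
        raise ValueError("coords must be (n, d)")
    if coords.shape[0] < 2:
        raise ValueError("need at least two neurons to normalize coordinates")
    centered = coords - coords.mean(axis=0, keepdims=True)
    scale = np.abs(centered).max(axis=0)
    if np.any(scale == 0):
        axis = int(np.flatnonzero(scale == 0)[0])
        raise ValueError(f"coordinate axis {axis} is constant; cannot normalize")
    return centered / scale
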