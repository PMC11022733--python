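"""The encoding model: a shared convolutional core and per-subject Gaussian
readouts.

The core has five convolutional layers with channel widths 32, 128, 256,
256, 256. The first layer downscales the 6-channel stimulus with a 4x4
kernel at stride 4; the remaining layers preserve the spatial shape and the
last three are depth-separable (depthwise k x k followed by pointwise 1x1).
Every layer is followed by batch normalization and ELU, so a 144x256 input
yields a (256, 36, 64) feature map.

Each neuron reads the core output at a single spatial position: its
receptive-field center ``mu`` in (-1, 1)^2, produced from the neuron's
normalized anatomical coordinates by a small position network (3 -> 30 -> 2,
ELU hidden, Tanh output). During training the sampling position is drawn as
``mu + Sigma @ eps`` with per-neuron 2x2 spread ``Sigma`` (clamped to the
frame); at evaluation the position is ``mu`` exactly. The 256-channel
feature vector at that position (bilinear interpolation, align-corners) is
combined linearly per neuron and passed through ``ELU(.) + 1``, keeping
predictions strictly positive as the Poisson loss requires.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _nn
from ._nn import Adam, BatchNorm2d, Conv2d, DepthwiseConv2d, ELU, Linear, Param, Sequential


@dataclass
class CoreConfig:
    n_layers: int = 5
    channels: tuple[int, ...] = (32, 128, 256, 256, 256)
    in_channels: int = 6
    first_kernel: int = 4
    first_stride: int = 4
    hidden_kernel: int = 3          # layers 2-5; odd so padding preserves shape
    depth_separable_layers: tuple[int, ...] = (3, 4, 5)

    def __post_init__(self) -> None:
        if len(self.channels) != self.n_layers:
            raise ValueError("channels must list one width per layer")
        if self.first_kernel != self.first_stride:
            raise ValueError("first layer uses kernel size equal to its stride")
        if self.hidden_kernel % 2 != 1:
            raise ValueError("hidden kernel must be odd to preserve shape")

    @property
    def out_channels(self) -> int:
        return self.channels[-1]

    def feature_shape(self, image_shape: tuple[int, int]) -> tuple[int, int]:
        h, w = image_shape
        if h % self.first_stride or w % self.first_stride:
            raise ValueError(f"image shape {image_shape} not divisible by stride {self.first_stride}")
        return h // self.first_stride, w // self.first_stride


def build_core(config: CoreConfig, rng: np.random.Generator) -> Sequential:
    """Assemble the five-layer core per the configuration."""
    layers: list[_nn.Layer] = []
    pad = config.hidden_kernel // 2
    c_prev = config.in_channels
    for i, c in enumerate(config.channels, start=1):
        if i == 1:
            layers.append(Conv2d(c_prev, c, config.first_kernel, stride=config.first_stride, pad=0, rng=rng))
        elif i in config.depth_separable_layers:
            layers.append(DepthwiseConv2d(c_prev, config.hidden_kernel, pad=pad, rng=rng))
            layers.append(Conv2d(c_prev, c, 1, stride=1, pad=0, rng=rng))
        else:
            layers.append(Conv2d(c_prev, c, config.hidden_kernel, stride=1, pad=pad, rng=rng))
        layers.append(BatchNorm2d(c))
        layers.append(ELU())
        c_prev = c
    return Sequential(layers)


def core_forward(x: np.ndarray, core: Sequential, training: bool = False) -> np.ndarray:
    """Run the core on a (B, 6, H, W) batch -> (B, 256, H/4, W/4)."""
    if x.ndim != 4:
        raise ValueError(f"expected a 4-D batch, got shape {x.shape}")
    return core.forward(np.asarray(x, dtype=np.float32), training)


# ---------------------------------------------------------------------------
# Gaussian readout
# ---------------------------------------------------------------------------

def _bilinear_weights(pos: np.ndarray, hf: int, wf: int, with_grad: bool = False):
    """Dense (m, hf*wf) interpolation-weight matrix for positions in [-1,1]^2
    under the align-corners convention ((-1,-1) -> outermost cell centers).

    With ``with_grad`` also returns dM/dgx and dM/dgy, the derivatives with
    respect to the continuous grid coordinates.
    """
    m = len(pos)
    gx = (pos[:, 0] + 1.0) * 0.5 * (wf - 1)
    gy = (pos[:, 1] + 1.0) * 0.5 * (hf - 1)
    x0 = np.clip(np.floor(gx).astype(int), 0, max(wf - 2, 0))
    y0 = np.clip(np.floor(gy).astype(int), 0, max(hf - 2, 0))
    tx = (gx - x0).astype(np.float32)
    ty = (gy - y0).astype(np.float32)
    x1 = np.minimum(x0 + 1, wf - 1)
    y1 = np.minimum(y0 + 1, hf - 1)
    rows = np.arange(m)
    M = np.zeros((m, hf * wf), dtype=np.float32)
    corners = [
        (y0, x0, (1 - tx) * (1 - ty)),
        (y0, x1, tx * (1 - ty)),
        (y1, x0, (1 - tx) * ty),
        (y1, x1, tx * ty),
    ]
    for yy, xx, wgt in corners:
        np.add.at(M, (rows, yy * wf + xx), wgt)
    if not with_grad:
        return M
    dMx = np.zeros_like(M)
    dMy = np.zeros_like(M)
    for yy, xx, wx, wy in [
        (y0, x0, -(1 - ty), -(1 - tx)),
        (y0, x1, (1 - ty), -tx),
        (y1, x0, -ty, (1 - tx)),
        (y1, x1, ty, tx),
    ]:
        np.add.at(dMx, (rows, yy * wf + xx), wx.astype(np.float32))
        np.add.at(dMy, (rows, yy * wf + xx), wy.astype(np.float32))
    return M, dMx, dMy


def sample_position(
    mu: np.ndarray,
    sigma: np.ndarray,
    training: bool,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Readout position rule: ``mu + Sigma @ eps`` clamped to [-1, 1]^2 while
    training, ``mu`` exactly at evaluation."""
    mu = np.atleast_2d(np.asarray(mu, dtype=np.float64))
    if not training:
        return mu
    if rng is None:
        raise ValueError("training-mode sampling needs an rng")
    sigma = np.asarray(sigma, dtype=np.float64)
    if sigma.ndim == 2:
        sigma = np.broadcast_to(sigma, (len(mu), 2, 2))
    eps = rng.standard_normal((len(mu), 2))
    return np.clip(mu + np.einsum("mij,mj->mi", sigma, eps), -1.0, 1.0)


class GaussianReadout:
    """Per-subject readout: position network, per-neuron spread ``Sigma``,
    and per-neuron linear feature weights."""

    HIDDEN = 30

    def __init__(
        self,
        coords_norm: np.ndarray,
        n_channels: int,
        rng: np.random.Generator,
        sigma_init: float = 0.1,
    ):
        coords_norm = np.asarray(coords_norm, dtype=np.float32)
        if coords_norm.ndim != 2 or coords_norm.shape[1] != 3:
            raise ValueError("coords_norm must be (m, 3)")
        self.coords = coords_norm
        m = len(coords_norm)
        self.n_neurons = m
        self.n_channels = n_channels
        self.fc1 = Linear(3, self.HIDDEN, rng=rng)
        self.fc2 = Linear(self.HIDDEN, 2, rng=rng)
        self.sigma = Param(rng.uniform(-sigma_init, sigma_init, size=(m, 2, 2)))
        self.w = Param(np.full((m, n_channels), 1.0 / n_channels))
        self.b = Param(np.zeros(m))

    def params(self) -> list[Param]:
        return self.fc1.params() + self.fc2.params() + [self.sigma, self.w, self.b]

    # -- position network ---------------------------------------------------
    def positions_mu(self, training: bool = False) -> np.ndarray:
        """mu for every neuron, in (-1, 1)^2."""
        h_pre = self.coords @ self.fc1.W.value + self.fc1.b.value
        h = _nn.elu(h_pre)
        out_pre = h @ self.fc2.W.value + self.fc2.b.value
        mu = np.tanh(out_pre)
        if training:
            self._mu_cache = (h_pre, h, mu)
        return mu

    def forward(
        self,
        features: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """(B, C, Hf, Wf) feature maps -> (B, m) positive predictions."""
        bsz, c, hf, wf = features.shape
        if c != self.n_channels:
            raise ValueError(f"expected {self.n_channels} feature channels, got {c}")
        mu = self.positions_mu(training)
        if training:
            eps = rng.standard_normal((self.n_neurons, 2))
            raw = mu + np.einsum("mij,mj->mi", self.sigma.value.astype(np.float64), eps)
            pos = np.clip(raw, -1.0, 1.0)
            M, dMx, dMy = _bilinear_weights(pos, hf, wf, with_grad=True)
        else:
            pos = mu
            M = _bilinear_weights(pos, hf, wf)
        fflat = features.reshape(bsz * c, hf * wf)
        Fc = (fflat @ M.T).reshape(bsz, c, self.n_neurons)  # (B, C, m)
        wT = self.w.value.T  # (C, m)
        z = (Fc * wT[None]).sum(axis=1) + self.b.value
        out = np.where(z > 0, z + 1.0, np.exp(np.minimum(z, 0.0))).astype(np.float32)
        if training:
            self._cache = (features.shape, fflat, Fc, z, out, M, dMx, dMy, eps, raw, hf, wf)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        """Gradient of the loss w.r.t. the feature maps; accumulates all
        readout parameter gradients (including the position network via the
        bilinear-sampling derivative)."""
        fshape, fflat, Fc, z, out, M, dMx, dMy, eps, raw, hf, wf = self._cache
        bsz, c = fshape[0], fshape[1]
        dz = (dout * np.where(z > 0, 1.0, out)).astype(np.float32)  # ELU' is out for z<0
        self.w.grad += np.einsum("bm,bcm->mc", dz, Fc, optimize=True)
        self.b.grad += dz.sum(axis=0)
        Q = dz[:, None, :] * self.w.value.T[None, :, :]  # (B, C, m): dL/dFc
        dfeat = (Q.reshape(bsz * c, self.n_neurons) @ M).reshape(fshape)

        # position gradient through the bilinear weights
        Gx = (fflat @ dMx.T).reshape(bsz, c, self.n_neurons)
        Gy = (fflat @ dMy.T).reshape(bsz, c, self.n_neurons)
        dgx = (Q * Gx).sum(axis=(0, 1))
        dgy = (Q * Gy).sum(axis=(0, 1))
        dpos = np.stack([dgx * 0.5 * (wf - 1), dgy * 0.5 * (hf - 1)], axis=1)
        dpos[(raw < -1.0) | (raw > 1.0)] = 0.0  # clamp blocks the gradient
        self.sigma.grad += dpos[:, :, None] * eps[:, None, :]

        h_pre, h, mu = self._mu_cache
        dpre2 = (dpos * (1.0 - mu**2)).astype(np.float32)
        self.fc2.W.grad += h.T @ dpre2
        self.fc2.b.grad += dpre2.sum(axis=0)
        dh = dpre2 @ self.fc2.W.value.T
        dpre1 = dh * np.where(h_pre > 0, 1.0, h + 1.0).astype(np.float32)
        self.fc1.W.grad += self.coords.T @ dpre1
        self.fc1.b.grad += dpre1.sum(axis=0)
        return dfeat

    def sdict(self) -> dict[str, np.ndarray]:
        return {
            "coords": self.coords,
            "fc1.W": self.fc1.W.value,
            "fc1.b": self.fc1.b.value,
            "fc2.W": self.fc2.W.value,
            "fc2.b": self.fc2.b.value,
            "sigma": self.sigma.value,
            "w": self.w.value,
            "b": self.b.value,
        }

    def load(self, state: dict[str, np.ndarray]) -> None:
        self.fc1.W.value[...] = state["fc1.W"]
        self.fc1.b.value[...] = state["fc1.b"]
        self.fc2.W.value[...] = state["fc2.W"]
        self.fc2.b.value[...] = state["fc2.b"]
        self.sigma.value[...] = state["sigma"]
        self.w.value[...] = state["w"]
        self.b.value[...] = state["b"]


def readout_position(coords_norm: np.ndarray, readout: GaussianReadout) -> np.ndarray:
    """Receptive-field centers for arbitrary normalized coordinates, using a
    readout's position network."""
    coords_norm = np.asarray(coords_norm, dtype=np.float32)
    h = _nn.elu(coords_norm @ readout.fc1.W.value + readout.fc1.b.value)
    return np.tanh(h @ readout.fc2.W.value + readout.fc2.b.value)


def readout_forward(
    features: np.ndarray,
    position: np.ndarray,
    w: np.ndarray,
    b: float,
) -> np.ndarray:
    """Single-neuron readout at an explicit position: bilinear feature lookup
    then ``ELU(w . f + b) + 1``. ``features`` is (C, Hf, Wf)."""
    c, hf, wf = features.shape
    M = _bilinear_weights(np.atleast_2d(np.asarray(position, dtype=np.float64)), hf, wf)
    f = (features.reshape(c, -1) @ M.T).ravel()
    z = float(np.dot(w, f) + b)
    return np.float64(z + 1.0 if z > 0 else np.exp(z))


# ---------------------------------------------------------------------------
# Full model
# ---------------------------------------------------------------------------

@dataclass
class ModelParams:
    """A shared core plus one Gaussian readout per subject."""

    core_config: CoreConfig
    core: Sequential
    readouts: dict[str, GaussianReadout]
    split_seed: int | None = None

    @classmethod
    def init(
        cls,
        core_config: CoreConfig,
        subject_coords: dict[str, np.ndarray],
        seed: int,
        split_seed: int | None = None,
    ) -> "ModelParams":
        """Fresh model: Xavier-normal weights, zero biases, readout feature
        weights 1/256 and Sigma ~ U(-0.1, 0.1)."""
        rng = np.random.default_rng(seed)
        core = build_core(core_config, rng)
        readouts = {
            sid: GaussianReadout(coords, core_config.out_channels, rng)
            for sid, coords in subject_coords.items()
        }
        return cls(core_config=core_config, core=core, readouts=readouts, split_seed=split_seed)

    def params(self) -> list[Param]:
        out = self.core.params()
        for r in self.readouts.values():
            out += r.params()
        return out

    def forward(
        self,
        batch: np.ndarray,
        subject_id: str,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        if subject_id not in self.readouts:
            raise KeyError(f"no readout for subject {subject_id!r}")
        features = core_forward(batch, self.core, training)
        return self.readouts[subject_id].forward(features, training, rng)

    def backward(self, dout: np.ndarray, subject_id: str) -> None:
        dfeat = self.readouts[subject_id].backward(dout)
        self.core.backward(dfeat)

    # -- checkpointing ------------------------------------------------------
    def state(self) -> dict[str, np.ndarray]:
        out = {f"core/{k}": v.copy() for k, v in self.core.sdict().items()}
        for sid, r in self.readouts.items():
            for k, v in r.sdict().items():
                out[f"readout/{sid}/{k}"] = v.copy()
        return out

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        self.core.load({k.split("/", 1)[1]: v for k, v in state.items() if k.startswith("core/")})
        for sid, r in self.readouts.items():
            prefix = f"readout/{sid}/"
            r.load({k[len(prefix):]: v for k, v in state.items() if k.startswith(prefix)})

    def save(self, path) -> None:
        import dataclasses as dc

        meta = {
            "schema": 1,
            "core_config": dc.asdict(self.core_config),
            "subjects": sorted(self.readouts),
            "split_seed": self.split_seed,
        }
        arrays = self.state()
        arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load_checkpoint(cls, path) -> "ModelParams":
        with np.load(path) as f:
            arrays = {k: f[k] for k in f.files}
        meta = json.loads(bytes(arrays.pop("__meta__")).decode())
        cc = meta["core_config"]
        cc["channels"] = tuple(cc["channels"])
        cc["depth_separable_layers"] = tuple(cc["depth_separable_layers"])
        config = CoreConfig(**cc)
        rng = np.random.default_rng(0)
        readouts = {}
        for sid in meta["subjects"]:
            coords = arrays[f"readout/{sid}/coords"]
            readouts[sid] = GaussianReadout(coords, config.out_channels, rng)
        model = cls(
            core_config=config,
            core=build_core(config, rng),
            readouts=readouts,
            split_seed=meta["split_seed"],
        )
        model.load_state({k: v for k, v in arrays.items() if not k.endswith("/coords")})
        return model


def model_forward(
    batch: np.ndarray,
    params: ModelParams,
    subject_id: str,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-trial, per-neuron positive predictions in standardized units."""
    return params.forward(batch, subject_id, training, rng)
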