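"""Dataset container, on-disk layout, train/validation resplitting, and a
synthetic mouse-V1 simulator.

The container mirrors the public SENSORIUM layout closely enough that a thin
adapter can read the real recordings, while the simulator provides desk-scale
datasets with known ground truth: per-trial grayscale stimuli, per-neuron
ΔF/F-like accumulated responses, anatomical coordinates with retinotopic
structure, dataset statistics, and a repeated-stimulus test split.

On disk one subject is a directory::

    subject/
      meta.yaml          # subject_id, shapes, split labels, repeat ids
      images/            # trial_000000.npy ... (H, W) float arrays
      responses/         # trial_000000.npy ... (m,) float arrays
      meta/statistics.npz   # image_mean, image_std, response_std
      meta/coords.npy       # (m, 3) anatomical coordinates
      meta/ground_truth.npz # synthetic datasets only

All statistics use population (divide-by-N) variance, matching the metrics
module.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

SPLITS = ("train", "validation", "live_test", "final_test")


@dataclass
class Dataset:
    """One subject's trials: stimuli, responses, neuron geometry, statistics
    and split labels."""

    images: np.ndarray        # (N, H, W) float32 raw intensities
    responses: np.ndarray     # (N, m) nonnegative ΔF/F accumulations
    coords: np.ndarray        # (m, 3) anatomical x, y, z (arbitrary units)
    image_mean: float         # Ī over train+validation images
    image_std: float          # s_I over train+validation images
    response_std: np.ndarray  # (m,) s_r over train+validation trials
    split_labels: np.ndarray  # (N,) strings from SPLITS
    repeat_ids: np.ndarray    # (N,) stimulus identity (groups repeats)
    subject_id: str = "synthetic-0"

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float32)
        self.responses = np.asarray(self.responses, dtype=np.float32)
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.response_std = np.asarray(self.response_std, dtype=np.float64)
        self.split_labels = np.asarray(self.split_labels, dtype=object)
        self.repeat_ids = np.asarray(self.repeat_ids, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        if self.images.ndim != 3:
            raise ValueError("images must be (N, H, W)")
        n = len(self.images)
        if len(self.responses) != n:
            raise ValueError(f"{len(self.responses)} response vectors for {n} images")
        m = self.n_neurons
        if self.coords.shape != (m, 3):
            raise ValueError(f"coords must be ({m}, 3), got {self.coords.shape}")
        if self.response_std.shape != (m,):
            raise ValueError("response_std must have one entry per neuron")
        if not self.image_std > 0:
            raise ValueError("image_std must be positive")
        if np.any(self.response_std <= 0):
            raise ValueError("all entries of response_std must be positive")
        if self.split_labels.shape != (n,) or self.repeat_ids.shape != (n,):
            raise ValueError("split_labels and repeat_ids must have one entry per trial")
        bad = set(self.split_labels) - set(SPLITS)
        if bad:
            raise ValueError(f"unknown split labels: {sorted(bad)}")

    @property
    def n_trials(self) -> int:
        return len(self.images)

    @property
    def n_neurons(self) -> int:
        return self.responses.shape[1]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.images.shape[1], self.images.shape[2]

    def indices(self, split: str) -> np.ndarray:
        if split not in SPLITS:
            raise ValueError(f"unknown split {split!r}")
        return np.flatnonzero(self.split_labels == split)


@dataclass(frozen=True)
class SplitSpec:
    """A re-drawn train/validation partition of the non-test trials."""

    train_indices: np.ndarray
    validation_indices: np.ndarray
    seed: int

    def validate(self, pool: np.ndarray | None = None) -> None:
        tr = set(self.train_indices.tolist())
        va = set(self.validation_indices.tolist())
        if tr & va:
            raise ValueError("train and validation indices overlap")
        if pool is not None and tr | va != set(pool.tolist()):
            raise ValueError("split does not cover the train+validation pool")


@dataclass
class GroundTruth:
    """Generative parameters of a synthetic dataset (for recovery tests)."""

    rf_center: np.ndarray   # (m, 2) in (-1, 1)^2 stimulus-plane units
    rf_sigma: np.ndarray    # (m,) Gaussian RF width, same units
    gain: np.ndarray        # (m,) positive response gain
    noise_model: str = "none"
    noise_sigma: float = 0.0


def make_splits(dataset: Dataset, n_splits: int, seed: int) -> list[SplitSpec]:
    """Draw ``n_splits`` fresh train/validation partitions of the non-test
    pool, each with the original validation size; split k uses seed+k."""
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    train = dataset.indices("train")
    val = dataset.indices("validation")
    if len(train) == 0 or len(val) == 0:
        raise ValueError("dataset must have non-empty train and validation pools")
    pool = np.concatenate([train, val])
    out = []
    for k in range(n_splits):
        rng = np.random.default_rng(seed + k)
        new_val = np.sort(rng.choice(pool, size=len(val), replace=False))
        new_train = np.setdiff1d(pool, new_val)
        spec = SplitSpec(train_indices=new_train, validation_indices=new_val, seed=seed + k)
        spec.validate(pool)
        out.append(spec)
    return out


# ---------------------------------------------------------------------------
# Synthetic V1 simulator
# ---------------------------------------------------------------------------

@dataclass
class SimulatorConfig:
    """Settings of the synthetic V1 simulator.

    Defaults emulate one SENSORIUM-scale recording session at reduced neuron
    count: 144x256 stimuli, ~4.5k training images, 100 test stimuli with 10
    repeats, Gaussian trial noise. Each neuron is a linear-nonlinear unit: a
    2-D Gaussian receptive field on the normalized image followed by ELU+1
    rectification and a positive gain, with RF centers laid out retinotopically
    across the cortical coordinate cloud.
    """

    n_neurons: int = 1000
    n_train_images: int = 4000
    n_validation_images: int = 500
    n_test_images: int = 100
    n_repeats: int = 10
    image_shape: tuple[int, int] = (144, 256)
    noise_model: str = "gaussian"     # none | gaussian | poisson
    noise_sigma: float = 0.4          # gaussian trial noise, response units
    poisson_scale: float = 5.0        # events per response unit for poisson noise
    rf_center_range: float = 0.8      # centers uniform in (-range, range)^2
    rf_sigma_range: tuple[float, float] = (0.10, 0.18)  # stimulus-plane units
    gain_log_sigma: float = 0.3       # gains ~ lognormal(0, this)
    drive_gain: float = 2.0           # contrast factor before rectification
    image_smooth_frac: float = 1 / 24  # Gaussian blur sigma as fraction of height
    test_split: str = "final_test"
    subject_id: str = "synthetic-0"
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["image_shape"] = list(self.image_shape)
        d["rf_sigma_range"] = list(self.rf_sigma_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulatorConfig":
        d = dict(d)
        if "image_shape" in d:
            d["image_shape"] = tuple(d["image_shape"])
        if "rf_sigma_range" in d:
            d["rf_sigma_range"] = tuple(d["rf_sigma_range"])
        return cls(**d)


def _elu1(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x + 1.0, np.exp(np.minimum(x, 0.0)))


def _smooth_noise_images(n: int, shape: tuple[int, int], sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Blurred white noise rescaled to intensity range ~[0, 255]; the blur
    gives the spatial correlation natural images have and the simulator's
    neurons need to express smooth receptive-field tuning."""
    h, w = shape
    out = np.empty((n, h, w), dtype=np.float32)
    for i in range(n):
        field = gaussian_filter(rng.standard_normal((h, w)), sigma=sigma, mode="reflect")
        field /= max(field.std(), 1e-12)
        out[i] = np.clip(128.0 + 45.0 * field, 0.0, 255.0)
    return out


def rf_kernels(
    rf_center: np.ndarray,
    rf_sigma: np.ndarray,
    image_shape: tuple[int, int],
) -> np.ndarray:
    """Unit-mass 2-D Gaussian receptive fields rasterized on the stimulus
    frame -> (m, H, W). Centers live in (-1,1)^2 with x horizontal (width)
    and y vertical (height); widths are isotropic in normalized units with
    one unit = half the frame height."""
    h, w = image_shape
    ys = np.linspace(-1.0, 1.0, h)
    xs = np.linspace(-1.0, 1.0, w) * (w / h)  # preserve pixel isotropy
    cx = rf_center[:, 0][:, None, None] * (w / h)
    cy = rf_center[:, 1][:, None, None]
    sig = rf_sigma[:, None, None]
    g = np.exp(-((xs[None, None, :] - cx) ** 2 + (ys[None, :, None] - cy) ** 2) / (2.0 * sig**2))
    g /= g.sum(axis=(1, 2), keepdims=True)
    return g.astype(np.float32)


def clean_responses(
    images_norm: np.ndarray,
    truth: GroundTruth,
    drive_gain: float,
) -> np.ndarray:
    """Noise-free responses (N, m): gain * (ELU(drive_gain * <I_norm, G>) + 1)."""
    h, w = images_norm.shape[1:]
    g = rf_kernels(truth.rf_center, truth.rf_sigma, (h, w))
    drive = images_norm.reshape(len(images_norm), -1) @ g.reshape(len(g), -1).T
    return truth.gain[None, :] * _elu1(drive_gain * drive)


def generate_synthetic_dataset(config: SimulatorConfig) -> tuple[Dataset, GroundTruth]:
    """Simulate one subject with known receptive-field ground truth.

    Repeats of a test stimulus share the clean response and differ only by
    trial noise; Gaussian noise is rectified at zero to keep responses in
    ΔF/F-like nonnegative units. Cortical (x, y) coordinates follow the RF
    centers up to small scatter, giving the retinotopic structure the
    readout's position network is meant to recover; z takes ten discrete
    imaging depths.
    """
    cfg = config
    for name in ("n_neurons", "n_train_images", "n_test_images", "n_repeats"):
        if getattr(cfg, name) < 1:
            raise ValueError(f"{name} must be >= 1")
    if cfg.noise_model not in ("none", "gaussian", "poisson"):
        raise ValueError(f"unknown noise model {cfg.noise_model!r}")
    rng = np.random.default_rng(cfg.seed)
    m = cfg.n_neurons
    h, w = cfg.image_shape

    rf_center = rng.uniform(-cfg.rf_center_range, cfg.rf_center_range, size=(m, 2))
    rf_sigma = rng.uniform(*cfg.rf_sigma_range, size=m)
    gain = np.exp(rng.normal(0.0, cfg.gain_log_sigma, size=m))
    truth = GroundTruth(
        rf_center=rf_center,
        rf_sigma=rf_sigma,
        gain=gain,
        noise_model=cfg.noise_model,
        noise_sigma=cfg.noise_sigma if cfg.noise_model == "gaussian" else 0.0,
    )

    # cortical coordinates: retinotopic in (x, y), layered in z (micron-like units)
    scatter = 15.0
    coords = np.empty((m, 3))
    coords[:, 0] = 400.0 * rf_center[:, 0] + rng.normal(0.0, scatter, m)
    coords[:, 1] = 400.0 * rf_center[:, 1] + rng.normal(0.0, scatter, m)
    coords[:, 2] = rng.choice(np.linspace(150.0, 400.0, 10), size=m)

    n_tr, n_va, n_te = cfg.n_train_images, cfg.n_validation_images, cfg.n_test_images
    sigma_px = cfg.image_smooth_frac * h
    unique_images = _smooth_noise_images(n_tr + n_va + n_te, (h, w), sigma_px, rng)
    image_mean = float(unique_images[: n_tr + n_va].mean())
    image_std = float(unique_images[: n_tr + n_va].std())

    norm = (unique_images - image_mean) / image_std
    clean_unique = clean_responses(norm, truth, cfg.drive_gain)

    # trial table: train and validation trials are unique stimuli; each test
    # stimulus is shown n_repeats times
    reps = cfg.n_repeats
    trial_image_idx = np.concatenate(
        [np.arange(n_tr + n_va), np.repeat(np.arange(n_tr + n_va, n_tr + n_va + n_te), reps)]
    )
    images = unique_images[trial_image_idx]
    clean = clean_unique[trial_image_idx]
    repeat_ids = trial_image_idx.copy()
    split_labels = np.array(
        ["train"] * n_tr + ["validation"] * n_va + [cfg.test_split] * (n_te * reps), dtype=object
    )

    if cfg.noise_model == "none":
        responses = clean.copy()
    elif cfg.noise_model == "gaussian":
        responses = np.maximum(clean + rng.normal(0.0, cfg.noise_sigma, clean.shape), 0.0)
    else:  # poisson
        responses = rng.poisson(clean * cfg.poisson_scale).astype(np.float64) / cfg.poisson_scale

    trainval = responses[: n_tr + n_va]
    response_std = trainval.std(axis=0)
    response_std = np.maximum(response_std, 1e-6)  # guard pathological tiny configs

    dataset = Dataset(
        images=images,
        responses=responses,
        coords=coords,
        image_mean=image_mean,
        image_std=image_std,
        response_std=response_std,
        split_labels=split_labels,
        repeat_ids=repeat_ids,
        subject_id=cfg.subject_id,
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# Disk layout
# ---------------------------------------------------------------------------

def save_dataset(dataset: Dataset, path, ground_truth: GroundTruth | None = None) -> None:
    """Write a subject directory (see module docstring for the layout)."""
    root = Path(path)
    (root / "images").mkdir(parents=True, exist_ok=True)
    (root / "responses").mkdir(exist_ok=True)
    (root / "meta").mkdir(exist_ok=True)
    for i in range(dataset.n_trials):
        np.save(root / "images" / f"trial_{i:06d}.npy", dataset.images[i])
        np.save(root / "responses" / f"trial_{i:06d}.npy", dataset.responses[i])
    np.savez(
        root / "meta" / "statistics.npz",
        image_mean=dataset.image_mean,
        image_std=dataset.image_std,
        response_std=dataset.response_std,
    )
    np.save(root / "meta" / "coords.npy", dataset.coords)
    meta = {
        "subject_id": dataset.subject_id,
        "n_trials": int(dataset.n_trials),
        "n_neurons": int(dataset.n_neurons),
        "image_shape": list(dataset.image_shape),
        "split_labels": [str(s) for s in dataset.split_labels],
        "repeat_ids": [int(r) for r in dataset.repeat_ids],
    }
    with open(root / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    if ground_truth is not None:
        np.savez(
            root / "meta" / "ground_truth.npz",
            rf_center=ground_truth.rf_center,
            rf_sigma=ground_truth.rf_sigma,
            gain=ground_truth.gain,
            noise_model=np.array(ground_truth.noise_model),
            noise_sigma=ground_truth.noise_sigma,
        )


def load_dataset(path) -> Dataset:
    """Read a subject directory written by :func:`save_dataset`.

    Raises ``FileNotFoundError`` naming the statistics file when it is
    missing and ``ValueError`` naming the first offending trial on a missing
    response file or an image shape mismatch.
    """
    root = Path(path)
    meta_path = root / "meta.yaml"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing metadata file {meta_path}")
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)
    stats_path = root / "meta" / "statistics.npz"
    if not stats_path.exists():
        raise FileNotFoundError(f"missing statistics file {stats_path}")
    stats = np.load(stats_path)
    n = int(meta["n_trials"])
    shape = tuple(meta["image_shape"])
    images = np.empty((n, *shape), dtype=np.float32)
    responses = np.empty((n, int(meta["n_neurons"])), dtype=np.float32)
    for i in range(n):
        img_path = root / "images" / f"trial_{i:06d}.npy"
        resp_path = root / "responses" / f"trial_{i:06d}.npy"
        if not img_path.exists():
            raise ValueError(f"trial {i}: missing image file {img_path}")
        if not resp_path.exists():
            raise ValueError(f"trial {i}: missing response file {resp_path}")
        img = np.load(img_path)
        if img.shape != shape:
            raise ValueError(f"trial {i}: image shape {img.shape} != {shape}")
        images[i] = img
        responses[i] = np.load(resp_path)
    return Dataset(
        images=images,
        responses=responses,
        coords=np.load(root / "meta" / "coords.npy"),
        image_mean=float(stats["image_mean"]),
        image_std=float(stats["image_std"]),
        response_std=np.asarray(stats["response_std"]),
        split_labels=np.array(meta["split_labels"], dtype=object),
        repeat_ids=np.array(meta["repeat_ids"], dtype=np.int64),
        subject_id=str(meta["subject_id"]),
    )


def load_ground_truth(path) -> GroundTruth:
    """Read the generative parameters stored with a synthetic subject."""
    f = np.load(Path(path) / "meta" / "ground_truth.npz")
    return GroundTruth(
        rf_center=f["rf_center"],
        rf_sigma=f["rf_sigma"],
        gain=f["gain"],
        noise_model=str(f["noise_model"]),
        noise_sigma=float(f["noise_sigma"]),
    )
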