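"""Offline generative and veridical replay through a truncated network.

The nightly procedure: capture the activation maps the training images
induce at a chosen pooling cut point, spatially downsample them, fit one
multivariate normal per class over the flattened maps (mean + covariance),
draw novel "imagined" samples from each class distribution, upsample them
back to the cut layer's resolution, and train the truncated network on the
samples with their class labels.  Veridical replay skips the distribution
entirely and replays the captured activations themselves, undownsampled.

Fitted covariances are typically singular (dimension can exceed the number
of fitting samples), so a small diagonal jitter is added and each
distribution is factorized once (Cholesky, with an eigenvalue-clipping
fallback); drawing n samples then costs one factorization plus n
matrix-vector products.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import (LayeredClassifier, OptimizerConfig, TruncatedHead,
                      activations_at, truncate_at)

__all__ = [
    "ActivationDistribution",
    "ReplayConfig",
    "ReplayBatch",
    "downsample_activations",
    "upsample_activations",
    "fit_class_distribution",
    "sample_distribution",
    "capture_veridical",
    "replay_night",
    "fit_all_classes",
    "sample_all_classes",
]

#: Per-cut-point spatial downsampling used before fitting the Gaussian.
DEFAULT_DOWNSAMPLE = {"pool_1": 8, "pool_2": 4, "pool_3": 4, "pool_4": 2, "pool_5": 1}


@dataclass(frozen=True)
class ReplayConfig:
    """Knobs of the generative replay pipeline."""

    downsample_factors: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_DOWNSAMPLE))
    n_samples_per_class: int | None = None  # None -> per-class training count
    covariance_jitter: float = 1e-6        # x mean diagonal entry, added to the diagonal
    clip_nonnegative: bool = False

    def factor_for(self, cut_point: str) -> int:
        f = int(self.downsample_factors.get(cut_point, 1))
        if f < 1:
            raise ValueError(f"downsample factor for {cut_point} must be >= 1")
        return f


@dataclass
class ActivationDistribution:
    """Class-conditional Gaussian over downsampled, flattened activations."""

    class_id: int
    cut_point: str
    mean: np.ndarray
    covariance: np.ndarray
    spatial_shape: tuple[int, int, int]     # (h, w, c) after downsampling
    orig_spatial_shape: tuple[int, int, int]  # (H, W, C) at the cut layer
    downsample_factor: int
    n_fit: int
    _chol: np.ndarray | None = field(default=None, repr=False)

    @property
    def dim(self) -> int:
        return int(np.prod(self.spatial_shape))

    def factor(self) -> np.ndarray:
        """Lower-triangular-ish factor L with L @ L.T = covariance (cached)."""
        if self._chol is None:
            cov = np.asarray(self.covariance, dtype=np.float64)
            try:
                self._chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                vals, vecs = np.linalg.eigh(cov)
                if vals.min() < -1e-6 * max(vals.max(), 1.0):
                    raise FloatingPointError(
                        f"covariance for class {self.class_id} at {self.cut_point} is "
                        f"not PSD after regularization (min eigenvalue {vals.min():.3g})")
                self._chol = vecs * np.sqrt(np.clip(vals, 0.0, None))
        return self._chol


@dataclass
class ReplayBatch:
    """Activation arrays at full cut-layer resolution plus class labels."""

    arrays: np.ndarray       # (n, H, W, C)
    labels: np.ndarray       # (n,)
    provenance: str          # "generative" | "veridical"

    def __post_init__(self) -> None:
        if self.provenance not in ("generative", "veridical"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if len(self.arrays) != len(self.labels):
            raise ValueError("arrays and labels length mismatch")


# ---------------------------------------------------------------------------
# Spatial resampling
# ---------------------------------------------------------------------------


def downsample_activations(act: np.ndarray, factor: int) -> np.ndarray:
    """Per-channel block-mean pooling with block size factor x factor.

    Works on a single (H, W, C) map or a stack (n, H, W, C).  Sides that the
    factor does not divide are edge-padded up to the next multiple first.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    act = np.asarray(act)
    single = act.ndim == 3
    if single:
        act = act[None]
    n, h, w, c = act.shape
    if factor > h or factor > w:
        raise ValueError(f"factor {factor} exceeds spatial side ({h}x{w})")
    if factor == 1:
        out = act.copy()
        return out[0] if single else out
    ph = (-h) % factor
    pw = (-w) % factor
    if ph or pw:
        act = np.pad(act, ((0, 0), (0, ph), (0, pw), (0, 0)), mode="edge")
        h, w = h + ph, w + pw
    # gather each block contiguously and reduce once; the round trip
    # down(up(x, f), f) == x holds to within one rounding ulp
    blocks = (act.reshape(n, h // factor, factor, w // factor, factor, c)
              .transpose(0, 1, 3, 5, 2, 4)
              .reshape(n, h // factor, w // factor, c, factor * factor))
    out = blocks.mean(axis=-1)
    return out[0] if single else out


def upsample_activations(act: np.ndarray, factor: int,
                         target_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Nearest-neighbour replication of each cell into a factor x factor block.

    ``target_shape`` crops the result back to (H, W) when the original side
    was not a multiple of the factor (the padding rule's inverse).
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    act = np.asarray(act)
    single = act.ndim == 3
    if single:
        act = act[None]
    out = np.repeat(np.repeat(act, factor, axis=1), factor, axis=2)
    if target_shape is not None:
        out = out[:, :target_shape[0], :target_shape[1], :]
    return out[0] if single else out


# ---------------------------------------------------------------------------
# Distribution fitting and sampling
# ---------------------------------------------------------------------------


def fit_class_distribution(acts, class_id: int, cut_point: str,
                           cfg: ReplayConfig | None = None) -> ActivationDistribution:
    """Fit the single per-class Gaussian from that class's activation maps."""
    cfg = cfg or ReplayConfig()
    acts = np.asarray(acts, dtype=np.float64)
    if acts.ndim != 4 or len(acts) < 2:
        raise ValueError("need at least 2 activation maps of shape (H, W, C)")
    orig_shape = tuple(acts.shape[1:])
    factor = cfg.factor_for(cut_point)
    down = downsample_activations(acts, factor)
    spatial_shape = tuple(down.shape[1:])
    flat = down.reshape(len(down), -1)
    mean = flat.mean(axis=0)
    cov = np.cov(flat, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    diag_mean = float(np.mean(np.diag(cov)))
    jitter = cfg.covariance_jitter * max(diag_mean, 1e-30)
    cov[np.diag_indices_from(cov)] += jitter
    return ActivationDistribution(
        class_id=class_id, cut_point=cut_point, mean=mean, covariance=cov,
        spatial_shape=spatial_shape, orig_spatial_shape=orig_shape,
        downsample_factor=factor, n_fit=len(acts))


def sample_distribution(dist: ActivationDistribution, n: int,
                        rng: np.random.Generator,
                        clip_nonnegative: bool = False) -> ReplayBatch:
    """Draw n novel activation patterns and upsample them to the cut layer."""
    if n < 1:
        raise ValueError("n must be >= 1")
    chol = dist.factor()
    z = rng.standard_normal((n, dist.dim))
    flat = dist.mean[None, :] + z @ chol.T
    if clip_nonnegative:
        np.clip(flat, 0.0, None, out=flat)
    maps = flat.reshape(n, *dist.spatial_shape)
    full = upsample_activations(maps, dist.downsample_factor,
                                target_shape=dist.orig_spatial_shape[:2])
    labels = np.full(n, dist.class_id, dtype=np.int64)
    return ReplayBatch(arrays=full.astype(np.float32), labels=labels,
                       provenance="generative")


def capture_veridical(model: LayeredClassifier, cut_point: str, data,
                      split: str = "train", augment=None,
                      rng: np.random.Generator | None = None,
                      images: np.ndarray | None = None) -> ReplayBatch:
    """Exact activations of every image in the split, undownsampled.

    ``images`` substitutes the views the network actually processed during
    the preceding training epoch (the augmented copies); ``augment`` with
    ``rng`` draws fresh augmented views instead.
    """
    X, y = data.arrays(split)
    if len(X) == 0:
        raise ValueError(f"{split} split is empty")
    if images is not None:
        X = images
    elif augment is not None:
        X = augment(X, rng)
    acts = activations_at(model, cut_point, X, channel_means=data.channel_means)
    return ReplayBatch(arrays=acts, labels=y.copy(), provenance="veridical")


# ---------------------------------------------------------------------------
# Night phase
# ---------------------------------------------------------------------------


def replay_night(model: LayeredClassifier, cut_point: str,
                 batches: "ReplayBatch | list[ReplayBatch]",
                 opt: OptimizerConfig, rng: np.random.Generator,
                 head: TruncatedHead | None = None) -> float:
    """One epoch of truncated-network training on replay samples.

    All classes' batches are pooled and shuffled; only layers after the cut
    are updated (the head shares weight storage with the parent model, so
    the consolidation persists when the network is "reattached" the next
    day).  Returns the mean replay loss.
    """
    if isinstance(batches, ReplayBatch):
        batches = [batches]
    arrays = np.concatenate([b.arrays for b in batches])
    labels = np.concatenate([b.labels for b in batches])
    if head is None:
        head = truncate_at(model, cut_point)
    if tuple(arrays.shape[1:]) != head.input_shape:
        raise ValueError(
            f"replay arrays of shape {arrays.shape[1:]} do not match cut layer "
            f"{head.input_shape}")
    return head.train_epoch(arrays, labels, opt, rng)


# ---------------------------------------------------------------------------
# Convenience wrappers used by the experiment protocols
# ---------------------------------------------------------------------------


def fit_all_classes(model: LayeredClassifier, cut_point: str, data,
                    cfg: ReplayConfig, augment=None,
                    rng: np.random.Generator | None = None,
                    images: np.ndarray | None = None,
                    ) -> dict[int, ActivationDistribution]:
    """Capture training-split activations and fit one Gaussian per class.

    ``images`` substitutes the augmented views the network processed during
    the day epoch; ``augment``/``rng`` draws fresh augmented copies instead.
    """
    X, y = data.arrays("train")
    if images is not None:
        X = images
    elif augment is not None:
        X = augment(X, rng)
    acts = activations_at(model, cut_point, X, channel_means=data.channel_means)
    dists: dict[int, ActivationDistribution] = {}
    for c in sorted(set(int(v) for v in y)):
        dists[c] = fit_class_distribution(acts[y == c], c, cut_point, cfg)
    return dists


def sample_all_classes(dists: dict[int, "ActivationDistribution"], n_per_class: int,
                       rng: np.random.Generator,
                       clip_nonnegative: bool = False) -> list[ReplayBatch]:
    return [sample_distribution(dists[c], n_per_class, rng, clip_nonnegative)
            for c in sorted(dists)]


# ---------------------------------------------------------------------------
# Distribution store
# ---------------------------------------------------------------------------


def save_distributions(dists: dict[int, ActivationDistribution], path) -> None:
    """Archive fitted class distributions; round-trips bit-exactly."""
    arrays: dict[str, np.ndarray] = {}
    for c in sorted(dists):
        d = dists[c]
        tag = f"class{c:04d}"
        arrays[f"{tag}_mean"] = d.mean
        arrays[f"{tag}_cov"] = d.covariance
        arrays[f"{tag}_meta"] = np.array([
            d.class_id, *d.spatial_shape, *d.orig_spatial_shape,
            d.downsample_factor, d.n_fit], dtype=np.int64)
        arrays[f"{tag}_cut"] = np.frombuffer(d.cut_point.encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_distributions(path) -> dict[int, ActivationDistribution]:
    """Load an archive written by :func:`save_distributions`."""
    out: dict[int, ActivationDistribution] = {}
    with np.load(path) as blob:
        tags = sorted({k.rsplit("_", 1)[0] for k in blob.files})
        for tag in tags:
            meta = blob[f"{tag}_meta"]
            dist = ActivationDistribution(
                class_id=int(meta[0]),
                cut_point=bytes(blob[f"{tag}_cut"]).decode(),
                mean=blob[f"{tag}_mean"],
                covariance=blob[f"{tag}_cov"],
                spatial_shape=tuple(int(v) for v in meta[1:4]),
                orig_spatial_shape=tuple(int(v) for v in meta[4:7]),
                downsample_factor=int(meta[7]),
                n_fit=int(meta[8]))
            out[dist.class_id] = dist
    return out
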