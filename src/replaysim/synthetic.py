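"""Procedural multi-class image categories with tunable similarity and difficulty.

Each category is a :class:`CategoryPrototype`: a vector of real feature
parameters defining a two-grating texture (mean orientation, base
frequency, relative angle, stripe sharpness, mixing weight, contrast), a
weak color tint, occluder-blob tendencies and a background brightness.
Rendering an image jitters the class parameters, draws per-render
backgrounds, phases and occluders, and adds pixel noise; all within-class
jitters increase monotonically with the prototype's ``difficulty``.  A
``grouped`` similarity mode makes classes share most feature parameters
(differing only by a small per-class offset), emulating a set of
conceptually similar categories.

The module also provides the training-time augmentation pipeline (rotation,
shift, zoom, horizontal flip, reflection fill) and an image-folder PNG
writer/reader, so every downstream stage runs with no external data.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "CategoryPrototype",
    "DatasetBundle",
    "AugmentConfig",
    "generate_prototypes",
    "render_image",
    "build_dataset",
    "augment_image",
    "augment_batch",
    "save_imagefolder",
    "load_imagefolder",
    "DEFAULT_SPLIT",
]

#: Desk-scale default per-class split, the canonical 117:13:5 ratio divided by 5.
DEFAULT_SPLIT = (234, 26, 10)

#: feature_params layout: mean orientation | base frequency | relative
#: grating angle | stripe sharpness | mixing weight | contrast amplitude |
#: tint RGB (3) | blob count tendency | blob size tendency | background
#: brightness.
N_FEATURES = 12


@dataclass(frozen=True)
class CategoryPrototype:
    """Generator parameters of one image category."""

    class_id: int
    feature_params: np.ndarray
    difficulty: float = 0.5
    similarity_group: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.difficulty <= 1.0:
            raise ValueError("difficulty must be in [0, 1]")
        if len(self.feature_params) != N_FEATURES:
            raise ValueError(f"feature_params must have length {N_FEATURES}")


@dataclass(frozen=True)
class AugmentConfig:
    """Random augmentation bounds; border regions are reflection-filled."""

    max_rotation_deg: float = 20.0
    max_shift_frac: float = 0.2
    max_zoom_frac: float = 0.2
    horizontal_flip: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_rotation_deg <= 180.0:
            raise ValueError("max_rotation_deg must be in [0, 180]")
        for name in ("max_shift_frac", "max_zoom_frac"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class DatasetBundle:
    """Per-split image arrays with labels, plus generation provenance.

    Images are float32 H×W×3 in [0, 1], stacked per split; ``labels`` map
    each image to its class id.  ``channel_means`` are the training-split
    per-channel means, used as the preprocessing offset downstream.
    """

    images: dict[str, np.ndarray]
    labels: dict[str, np.ndarray]
    prototypes: list[CategoryPrototype]
    generation_seed: int | None
    channel_means: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.channel_means is None:
            self.channel_means = self.images["train"].mean(axis=(0, 1, 2))

    @property
    def n_classes(self) -> int:
        return len(self.prototypes)

    def arrays(self, split: str) -> tuple[np.ndarray, np.ndarray]:
        if split not in self.images:
            raise ValueError(f"unknown split {split!r}")
        return self.images[split], self.labels[split]

    def class_indices(self, split: str, class_id: int) -> np.ndarray:
        return np.flatnonzero(self.labels[split] == class_id)

    def subsample_train(self, n_per_class: int, seed: int = 0) -> "DatasetBundle":
        """Bundle with at most ``n_per_class`` training images per class."""
        rng = np.random.default_rng(np.random.SeedSequence([0x5AB5, seed]))
        keep: list[np.ndarray] = []
        for proto in self.prototypes:
            idx = self.class_indices("train", proto.class_id)
            if n_per_class < len(idx):
                idx = np.sort(rng.choice(idx, size=n_per_class, replace=False))
            keep.append(idx)
        sel = np.concatenate(keep)
        images = dict(self.images)
        labels = dict(self.labels)
        images["train"] = self.images["train"][sel]
        labels["train"] = self.labels["train"][sel]
        return DatasetBundle(images=images, labels=labels, prototypes=self.prototypes,
                             generation_seed=self.generation_seed)


# ---------------------------------------------------------------------------
# Prototype generation
# ---------------------------------------------------------------------------


def _draw_features(rng: np.random.Generator,
                   freq_range: tuple[float, float] = (2.5, 7.0)) -> np.ndarray:
    """Class identity lives in texture relations, not absolute pose.

    The class-defining parameters are chosen to survive the training-time
    augmentations: the *relative* angle between two gratings (rotation- and
    shift-robust), their frequency *ratio* (zoom-invariant), and the stripe
    sharpness.  Absolute orientation, absolute frequency, backgrounds and
    occluding blobs vary per render, so low-level image statistics overlap
    heavily across classes — class-discriminative structure only emerges at
    intermediate spatial scales, as with natural image categories.
    """
    f = np.empty(N_FEATURES)
    f[0] = rng.uniform(0.0, np.pi)               # mean orientation of grating 1
    f[1] = rng.uniform(*freq_range)              # base frequency (cycles/image)
    f[2] = rng.uniform(0.0, np.pi)               # relative angle of grating 2
    f[3] = rng.uniform(1.0, 3.0)                 # stripe sharpness exponent
    f[4] = rng.uniform(0.3, 0.7)                 # mixing weight between gratings
    f[5] = rng.uniform(0.4, 0.6)                 # contrast amplitude
    f[6:9] = rng.uniform(0.3, 0.7, 3)            # tint RGB (weak, heavily jittered)
    f[9] = rng.uniform(0.5, 1.5)                 # occluder blob count tendency
    f[10] = rng.uniform(0.04, 0.09)              # occluder blob size tendency
    f[11] = rng.uniform(0.45, 0.75)              # background brightness
    return f


def generate_prototypes(n_classes: int, seed: int, similarity_mode: str = "none",
                        difficulty_profile: "np.ndarray | list[float] | None" = None,
                        freq_range: tuple[float, float] = (2.5, 7.0),
                        ) -> list[CategoryPrototype]:
    """Deterministically draw ``n_classes`` pairwise-distinct prototypes.

    ``similarity_mode='grouped'`` draws a single base feature vector and
    gives each class only a small offset from it, so classes share most of
    their structure.  ``difficulty_profile`` assigns per-class difficulty;
    empty/None means a uniform default of 0.5.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    if similarity_mode not in ("none", "grouped"):
        raise ValueError(f"unknown similarity_mode {similarity_mode!r}")
    profile = np.asarray(difficulty_profile if difficulty_profile is not None else [],
                         dtype=float)
    if profile.size == 0:
        profile = np.full(n_classes, 0.5)
    if len(profile) != n_classes:
        raise ValueError("difficulty_profile length must equal n_classes")

    rng = np.random.default_rng(np.random.SeedSequence([0x9E01, seed]))
    protos: list[CategoryPrototype] = []
    if similarity_mode == "grouped":
        base = _draw_features(rng, freq_range)
        lo, hi = _feature_bounds()
        for c in range(n_classes):
            offset = rng.normal(0.0, 1.0, N_FEATURES) * 0.08 * (hi - lo)
            f = np.clip(base + offset, lo, hi)
            protos.append(CategoryPrototype(class_id=c, feature_params=f,
                                            difficulty=float(profile[c]),
                                            similarity_group=0))
    else:
        for c in range(n_classes):
            protos.append(CategoryPrototype(class_id=c, feature_params=_draw_features(rng, freq_range),
                                            difficulty=float(profile[c])))
    for i in range(len(protos)):
        for j in range(i + 1, len(protos)):
            if np.array_equal(protos[i].feature_params, protos[j].feature_params):
                raise RuntimeError("degenerate draw: two prototypes coincide")
    return protos


def _feature_bounds() -> tuple[np.ndarray, np.ndarray]:
    lo = np.array([0.0, 2.5, 0.0, 1.0, 0.3, 0.4, 0.3, 0.3, 0.3, 0.5, 0.04, 0.45])
    hi = np.array([np.pi, 7.0, np.pi, 3.0, 0.7, 0.6, 0.7, 0.7, 0.7, 1.5, 0.09, 0.75])
    return lo, hi


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _noise_scale(difficulty: float) -> float:
    # strictly increasing in difficulty; nonzero floor keeps classes non-trivial
    return 0.15 + 0.85 * difficulty


def render_image(prototype: CategoryPrototype, variation_seed, size=(64, 64)) -> np.ndarray:
    """Render one within-class variation of a prototype; float32 in [0, 1]."""
    h, w = size
    if h < 16 or w < 16:
        raise ValueError("image size must be at least 16x16")
    if isinstance(variation_seed, np.random.SeedSequence):
        rng = np.random.default_rng(variation_seed)
    else:
        rng = np.random.default_rng(np.random.SeedSequence([0x11A6, int(variation_seed)]))
    s = _noise_scale(prototype.difficulty)
    f = prototype.feature_params

    # within-class orientation spread is comparable to the augmentation's
    # rotation range, so augmented real images stay class-informative; the
    # relative angle between the gratings is rotation-robust on top of that
    theta1 = f[0] + rng.normal(0.0, 0.35 * s)
    dtheta = f[2] + rng.normal(0.0, 0.20 * s)
    theta2 = theta1 + dtheta
    freq1 = float(np.clip(f[1] * (1.0 + rng.normal(0.0, 0.08 * s)), 1.5, 10.0))
    freq2 = float(np.clip(freq1 * 1.7 * (1.0 + rng.normal(0.0, 0.05 * s)), 1.5, 14.0))
    sharp = float(np.clip(f[3] * (1.0 + rng.normal(0.0, 0.10 * s)), 1.0, 3.5))
    mix = float(np.clip(f[4] + rng.normal(0.0, 0.10 * s), 0.05, 0.95))
    amp = float(np.clip(f[5] * (1.0 + rng.normal(0.0, 0.20 * s)), 0.1, 0.6))
    tint = np.clip(f[6:9] + rng.normal(0.0, 0.25, 3), 0.0, 1.0)

    yy, xx = np.mgrid[0:h, 0:w]
    u = xx / (w - 1)
    v = yy / (h - 1)

    # background: per-render brightness, color cast and gradient (class-uninformative)
    bgb = float(np.clip(f[11] + rng.normal(0.0, 0.10), 0.2, 0.9))
    ga = rng.uniform(0.0, 2 * np.pi)
    grad = u * np.cos(ga) + v * np.sin(ga)
    bg_color = np.clip(bgb + rng.normal(0.0, 0.05, 3), 0.0, 1.0)
    img = bg_color[None, None, :] + rng.uniform(0.0, 0.25) * (grad - 0.5)[:, :, None]

    # class-defining texture: mixture of two oriented gratings
    p1 = rng.uniform(0.0, 2 * np.pi)
    p2 = rng.uniform(0.0, 2 * np.pi)
    s1 = np.sin(2 * np.pi * freq1 * (u * np.cos(theta1) + v * np.sin(theta1)) + p1)
    s2 = np.sin(2 * np.pi * freq2 * (u * np.cos(theta2) + v * np.sin(theta2)) + p2)
    w1 = np.sign(s1) * np.abs(s1) ** (1.0 / sharp)
    w2 = np.sign(s2) * np.abs(s2) ** (1.0 / sharp)
    pattern = mix * w1 + (1.0 - mix) * w2
    chan_gain = 0.7 + 0.6 * (tint - 0.5)  # mostly luminance contrast, mild color cast
    img += amp * pattern[:, :, None] * chan_gain[None, None, :]

    # occluder blobs: positions and colors are per render, only their count
    # and size tendencies are class parameters
    n_blobs = int(np.clip(np.rint(f[9] + rng.normal(0.0, 1.0)), 0, 6))
    for _ in range(n_blobs):
        cx, cy = rng.uniform(0.1, 0.9, 2)
        r = max(f[10] * (1.0 + rng.uniform(-0.4, 0.4)), 0.02)
        color = rng.uniform(0.0, 1.0, 3)
        alpha = 0.6 * np.exp(-(((u - cx) ** 2 + (v - cy) ** 2) / (2 * r ** 2)))
        img += alpha[:, :, None] * (color[None, None, :] - img)

    img += rng.normal(0.0, 0.02 + 0.03 * s, size=(h, w, 3))
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def build_dataset(prototypes: list[CategoryPrototype], n_train: int, n_val: int,
                  n_test: int, size=(64, 64), seed: int = 0) -> DatasetBundle:
    """Render disjoint train/val/test splits with exact per-class counts."""
    for name, n in (("n_train", n_train), ("n_val", n_val), ("n_test", n_test)):
        if n < 1:
            raise ValueError(f"{name} must be >= 1")
    counts = {"train": n_train, "val": n_val, "test": n_test}
    images = {s: [] for s in counts}
    labels = {s: [] for s in counts}
    for proto in prototypes:
        base = np.random.SeedSequence([0xDA7A, seed, proto.class_id])
        children = base.spawn(n_train + n_val + n_test)
        k = 0
        for split, n in counts.items():
            for _ in range(n):
                images[split].append(render_image(proto, children[k], size=size))
                labels[split].append(proto.class_id)
                k += 1
    return DatasetBundle(
        images={s: np.stack(images[s]) for s in counts},
        labels={s: np.asarray(labels[s], dtype=np.int64) for s in counts},
        prototypes=list(prototypes),
        generation_seed=seed,
    )


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------


def augment_image(image: np.ndarray, cfg: AugmentConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Random rotation/shift/zoom/flip with reflection fill.

    Transform parameters are drawn uniformly within the config bounds (one
    draw per call); the composite affine map is applied once with bilinear
    interpolation about the image center, and any exposed border is filled
    by reflecting the image content.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("image must be HxWx3")
    h, w, _ = img.shape

    theta = np.deg2rad(rng.uniform(-cfg.max_rotation_deg, cfg.max_rotation_deg))
    ty = rng.uniform(-cfg.max_shift_frac, cfg.max_shift_frac) * h
    tx = rng.uniform(-cfg.max_shift_frac, cfg.max_shift_frac) * w
    zoom = 1.0 + rng.uniform(-cfg.max_zoom_frac, cfg.max_zoom_frac)
    flip = bool(cfg.horizontal_flip and rng.random() < 0.5)

    if flip:
        img = img[:, ::-1, :]

    if theta == 0.0 and tx == 0.0 and ty == 0.0 and zoom == 1.0:
        return np.ascontiguousarray(img, dtype=np.float32)

    # affine_transform maps output coords o -> input coords a @ o + offset;
    # we want input = a @ (o - center - shift) + center with a = (R S)^{-1}
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    rot = np.array([[cos_t, -sin_t], [sin_t, cos_t]])
    a = np.linalg.inv(rot * zoom)
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    shift = np.array([ty, tx])
    offset2 = center - a @ (center + shift)
    mat = np.zeros((3, 3))
    mat[:2, :2] = a
    mat[2, 2] = 1.0
    offset = np.array([offset2[0], offset2[1], 0.0])
    out = ndimage.affine_transform(img, mat, offset=offset, order=1,
                                   mode="reflect", output=np.float64)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def _reflect_indices(idx: np.ndarray, n: int) -> np.ndarray:
    """Mirror integer sample indices into [0, n) (half-sample symmetric)."""
    idx = np.mod(idx, 2 * n)
    return np.where(idx >= n, 2 * n - 1 - idx, idx)


def augment_batch(images: np.ndarray, cfg: AugmentConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Vectorized :func:`augment_image` over a stack of images.

    Draws the same per-image transform parameters in the same order as
    ``augment_image`` and applies one bilinear gather with reflection fill
    for the whole batch; results agree with the per-image path to
    interpolation tolerance.
    """
    images = np.asarray(images)
    if images.ndim != 4 or images.shape[3] != 3:
        raise ValueError("images must be n x H x W x 3")
    n, h, w, _ = images.shape
    theta = np.empty(n)
    ty = np.empty(n)
    tx = np.empty(n)
    zoom = np.empty(n)
    flip = np.zeros(n, dtype=bool)
    for i in range(n):
        theta[i] = np.deg2rad(rng.uniform(-cfg.max_rotation_deg, cfg.max_rotation_deg))
        ty[i] = rng.uniform(-cfg.max_shift_frac, cfg.max_shift_frac) * h
        tx[i] = rng.uniform(-cfg.max_shift_frac, cfg.max_shift_frac) * w
        zoom[i] = 1.0 + rng.uniform(-cfg.max_zoom_frac, cfg.max_zoom_frac)
        if cfg.horizontal_flip:
            flip[i] = rng.random() < 0.5

    # input = a @ (o - center - shift) + center, with a = (R S)^{-1}
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    a00 = cos_t / zoom
    a01 = sin_t / zoom
    a10 = -sin_t / zoom
    a11 = cos_t / zoom
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    oy = cy - (a00 * (cy + ty) + a01 * (cx + tx))
    ox = cx - (a10 * (cy + ty) + a11 * (cx + tx))

    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    sy = a00[:, None, None] * yy + a01[:, None, None] * xx + oy[:, None, None]
    sx = a10[:, None, None] * yy + a11[:, None, None] * xx + ox[:, None, None]
    # flip acts on the source image, i.e. mirror the source column coordinate
    sx = np.where(flip[:, None, None], (w - 1) - sx, sx)

    y0 = np.floor(sy).astype(np.int64)
    x0 = np.floor(sx).astype(np.int64)
    fy = (sy - y0).astype(np.float32)[..., None]
    fx = (sx - x0).astype(np.float32)[..., None]
    y0r = _reflect_indices(y0, h)
    y1r = _reflect_indices(y0 + 1, h)
    x0r = _reflect_indices(x0, w)
    x1r = _reflect_indices(x0 + 1, w)
    # single flat gather per corner
    flat = np.ascontiguousarray(images).reshape(n * h * w, 3)
    bn = np.arange(n, dtype=np.int64)[:, None, None] * h
    b00 = ((bn + y0r) * w + x0r).ravel()
    b01 = ((bn + y0r) * w + x1r).ravel()
    b10 = ((bn + y1r) * w + x0r).ravel()
    b11 = ((bn + y1r) * w + x1r).ravel()
    shape = (n, h, w, 3)
    g00 = flat.take(b00, axis=0).reshape(shape)
    g01 = flat.take(b01, axis=0).reshape(shape)
    g10 = flat.take(b10, axis=0).reshape(shape)
    g11 = flat.take(b11, axis=0).reshape(shape)
    out = ((1 - fy) * ((1 - fx) * g00 + fx * g01)
           + fy * ((1 - fx) * g10 + fx * g11))
    return np.clip(out, 0.0, 1.0).astype(np.float32)


# ---------------------------------------------------------------------------
# Image-folder I/O
# ---------------------------------------------------------------------------


def save_imagefolder(bundle: DatasetBundle, root) -> None:
    """Write ``<root>/<split>/class_<id>/<index>.png`` (8-bit PNG)."""
    root = Path(root)
    for split, X in bundle.images.items():
        y = bundle.labels[split]
        for c in sorted(set(int(v) for v in y)):
            d = root / split / f"class_{c:03d}"
            d.mkdir(parents=True, exist_ok=True)
            for i, idx in enumerate(np.flatnonzero(y == c)):
                arr = np.clip(np.rint(X[idx] * 255.0), 0, 255).astype(np.uint8)
                Image.fromarray(arr).save(d / f"{i:05d}.png")


def load_imagefolder(root) -> DatasetBundle:
    """Read an image-folder tree back into a bundle (8-bit quantized)."""
    root = Path(root)
    images: dict[str, list[np.ndarray]] = {}
    labels: dict[str, list[int]] = {}
    class_ids: set[int] = set()
    for split_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        split = split_dir.name
        images[split] = []
        labels[split] = []
        for class_dir in sorted(p for p in split_dir.iterdir() if p.is_dir()):
            m = re.fullmatch(r"class_(\d+)", class_dir.name)
            if m is None:
                raise ValueError(f"unexpected class directory name {class_dir.name!r}")
            c = int(m.group(1))
            class_ids.add(c)
            for png in sorted(class_dir.glob("*.png")):
                arr = np.asarray(Image.open(png), dtype=np.float32) / 255.0
                images[split].append(arr)
                labels[split].append(c)
    if "train" not in images or not images["train"]:
        raise ValueError(f"no train split found under {root}")
    protos = [CategoryPrototype(class_id=c, feature_params=np.zeros(N_FEATURES))
              for c in sorted(class_ids)]
    return DatasetBundle(
        images={s: np.stack(v) for s, v in images.items()},
        labels={s: np.asarray(v, dtype=np.int64) for s, v in labels.items()},
        prototypes=protos,
        generation_seed=None,
    )
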