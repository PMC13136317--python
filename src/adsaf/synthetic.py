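"""Seeded synthetic lung-image generator.

Emulates, at desk scale, the two radiological archetypes the fusion gate is
meant to arbitrate between:

* **local** regime — the class signal is a small focal lesion: a zero-mean,
  band-limited speckle patch (thresholded filtered noise under a tapered
  window, *not* a plain disk) placed inside an elliptical lung field for
  class 1 only.  Because the patch has zero mean, detecting it requires
  sensitivity to local texture energy rather than to brightness, which is
  what a convolutional stream is good at.
* **global** regime — classes differ only in a diffuse, low-frequency
  intensity layout: a smoothed quadrant-parity field (class 0 brighter in
  the top-left/bottom-right quadrants, class 1 in the other diagonal);
  local texture statistics are matched.  The field has zero mean in every
  row, column and border strip, so translation-covariant features pooled
  over space carry no class signal (any net hemifield difference would be
  linearly recoverable from a derivative feature plus pooling); separating
  the classes requires knowing *where* brightness sits, which is what
  position-aware (transformer) features provide.
* **mixed** — each image independently carries one of the two signal types.

Each subject additionally receives a constant intensity offset drawn once,
so subject-wise splitting has real structure to respect.  The whole dataset
is a pure function of its :class:`~adsaf.config.SyntheticSpec` (seed
included).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

from .config import ConfigError, DomainShiftParams, SyntheticSpec

BASE_INTENSITY = 0.45
SMOOTH_FIELD_STD = 0.02


@dataclass
class LabeledImage:
    pixels: np.ndarray        # (H, W) in [0, 1]
    label: int
    subject_id: str
    regime_tag: str           # {"local", "global", "none"}


@dataclass
class ImageDataset:
    """Array-of-structs view of a labeled image collection."""

    images: np.ndarray        # (N, H, W) float in [0, 1]
    labels: np.ndarray        # (N,) int
    subject_ids: np.ndarray   # (N,) str
    regime_tags: np.ndarray   # (N,) str
    lesion_masks: Optional[np.ndarray] = None   # (N, H, W) bool

    def __len__(self) -> int:
        return self.images.shape[0]

    def __getitem__(self, i: int) -> LabeledImage:
        return LabeledImage(self.images[i], int(self.labels[i]),
                            str(self.subject_ids[i]), str(self.regime_tags[i]))

    def subset(self, idx) -> "ImageDataset":
        idx = np.asarray(idx)
        return ImageDataset(
            images=self.images[idx],
            labels=self.labels[idx],
            subject_ids=self.subject_ids[idx],
            regime_tags=self.regime_tags[idx],
            lesion_masks=None if self.lesion_masks is None else self.lesion_masks[idx],
        )


# ---------------------------------------------------------------------------
# building blocks


def lung_field_mask(size: int) -> np.ndarray:
    """Elliptical 'lung field' footprint centred in the frame."""
    y, x = np.mgrid[0:size, 0:size]
    cy = cx = (size - 1) / 2.0
    ry, rx = 0.44 * size, 0.38 * size
    return ((y - cy) / ry) ** 2 + ((x - cx) / rx) ** 2 <= 1.0


def make_lesion_patch(size: int, contrast: float, rng: np.random.Generator):
    """Zero-mean band-limited speckle patch with a raised-cosine taper.

    Returns ``(patch, footprint)`` where ``footprint`` marks pixels whose
    taper weight is non-negligible.
    """
    noise = rng.standard_normal((size, size))
    high = noise - gaussian_filter(noise, sigma=max(size / 3.0, 1.0))
    win1 = np.hanning(size + 2)[1:-1]
    taper = np.outer(win1, win1)
    patch = high * taper
    patch -= patch.mean()
    sd = patch.std()
    if sd > 0:
        patch = patch * (contrast / sd)
    return patch, taper > 0.1


def quadrant_parity_field(size: int, strength: float, sign: float) -> np.ndarray:
    """Smoothed diagonal quadrant-contrast layout with peak amplitude ``strength``.

    ``sign=+1`` is brighter in the top-left and bottom-right quadrants.
    Every row and column of the field sums to zero, so the two classes
    (``sign=+1`` vs ``-1``) are indistinguishable to pooled
    translation-covariant features.
    """
    y, x = np.mgrid[0:size, 0:size]
    base = np.where((y < size / 2) != (x < size / 2), -1.0, 1.0)
    f = gaussian_filter(base, sigma=size / 8.0, mode="wrap")
    f *= strength / np.abs(f).max()
    return sign * f


def _stripe_field(size: int, strength: float, axis: int) -> np.ndarray:
    # layout patterns for extra classes beyond the binary default
    t = np.cos(2.0 * np.pi * np.arange(size) / size) * strength
    if axis == 0:
        return np.repeat(t[:, None], size, axis=1)
    return np.repeat(t[None, :], size, axis=0)


def _class_pattern(label: int, sig_type: str, spec: SyntheticSpec,
                   mask: np.ndarray, rng: np.random.Generator):
    """Additive class signal and lesion footprint for one image."""
    size = spec.image_size
    field = np.zeros((size, size))
    footprint = np.zeros((size, size), dtype=bool)
    if label >= 2:     # extra classes carry stripe-layout patterns
        field += _stripe_field(size, spec.diffuse_gradient_strength,
                               axis=0 if label == 2 else 1)
        return field, footprint
    if sig_type == "local":
        if label == 1:
            L = spec.lesion_size
            patch, pf = make_lesion_patch(L, spec.lesion_contrast, rng)
            ys, xs = np.where(mask)
            ok = (ys >= L // 2 + 1) & (ys < size - L // 2 - 1) \
                & (xs >= L // 2 + 1) & (xs < size - L // 2 - 1)
            pick = rng.integers(0, ok.sum())
            cy, cx = ys[ok][pick], xs[ok][pick]
            y0, x0 = cy - L // 2, cx - L // 2
            field[y0:y0 + L, x0:x0 + L] += patch
            footprint[y0:y0 + L, x0:x0 + L] = pf
        else:
            # consume the same number of draws so class 0/1 images stay
            # pairwise comparable under a fixed seed
            rng.standard_normal((spec.lesion_size, spec.lesion_size))
            rng.integers(0, 2 ** 31)
    else:              # global layout signal
        sign = 1.0 if label == 0 else -1.0
        field += quadrant_parity_field(size, spec.diffuse_gradient_strength, sign)
        rng.standard_normal((spec.lesion_size, spec.lesion_size))
        rng.integers(0, 2 ** 31)
    return field, footprint


# ---------------------------------------------------------------------------
# generation


def generate_dataset(spec: SyntheticSpec) -> ImageDataset:
    """Generate ``n_subjects * images_per_subject`` labeled images.

    Deterministic: identical spec (seed included) gives bit-identical
    arrays.  Labels are balanced within each subject, so overall class
    balance is tight by construction.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    mask = lung_field_mask(size)
    K = spec.n_classes

    images, labels, subjects, tags, masks = [], [], [], [], []
    for s in range(spec.n_subjects):
        sid = f"subj{s:04d}"
        offset = rng.normal(0.0, spec.subject_offset_std)
        lab = np.tile(np.arange(K), spec.images_per_subject // K + 1)[: spec.images_per_subject]
        lab = rng.permutation(lab)
        for label in lab:
            if spec.regime == "mixed":
                sig_type = "local" if rng.random() < spec.mixed_local_fraction else "global"
            else:
                sig_type = spec.regime
            smooth = gaussian_filter(rng.standard_normal((size, size)), sigma=size / 8.0)
            sd = smooth.std()
            if sd > 0:
                smooth *= SMOOTH_FIELD_STD / sd
            signal, footprint = _class_pattern(int(label), sig_type, spec, mask, rng)
            noise = rng.normal(0.0, spec.background_noise_std, size=(size, size))
            img = BASE_INTENSITY + offset + smooth + signal + noise
            images.append(np.clip(img, 0.0, 1.0))
            labels.append(int(label))
            subjects.append(sid)
            tags.append(sig_type)
            masks.append(footprint)

    ds = ImageDataset(
        images=np.asarray(images),
        labels=np.asarray(labels, dtype=int),
        subject_ids=np.asarray(subjects, dtype=object),
        regime_tags=np.asarray(tags, dtype=object),
        lesion_masks=np.asarray(masks),
    )
    if spec.domain_shift is not None:
        ds = apply_domain_shift(ds, spec.domain_shift, seed=spec.seed + 1)
    return ds


def apply_domain_shift(dataset: ImageDataset, shift: DomainShiftParams,
                       seed: int = 0) -> ImageDataset:
    """Gamma contrast warp then additive Gaussian noise, clipped to [0, 1].

    Labels, subject IDs and regime tags are preserved.
    """
    shift.validate()
    rng = np.random.default_rng(seed)
    imgs = np.clip(dataset.images, 0.0, 1.0) ** shift.gamma
    if shift.extra_noise_std > 0:
        imgs = imgs + rng.normal(0.0, shift.extra_noise_std, size=imgs.shape)
    return ImageDataset(
        images=np.clip(imgs, 0.0, 1.0),
        labels=dataset.labels.copy(),
        subject_ids=dataset.subject_ids.copy(),
        regime_tags=dataset.regime_tags.copy(),
        lesion_masks=None if dataset.lesion_masks is None else dataset.lesion_masks.copy(),
    )


# ---------------------------------------------------------------------------
# designed separability statistics (used by sanity checks and baselines)


def highpass_energy(images: np.ndarray, sigma: float = 1.5) -> np.ndarray:
    """Mean squared high-pass residual per image (local-texture statistic)."""
    out = np.empty(len(images))
    for i, im in enumerate(images):
        hp = im - gaussian_filter(im, sigma)
        out[i] = np.mean(hp ** 2)
    return out


def quadrant_contrast(images: np.ndarray) -> np.ndarray:
    """Diagonal quadrant contrast per image (the designed global statistic).

    Mean over the top-left + bottom-right quadrants minus mean over the
    other diagonal; positive for class 0 layouts, negative for class 1.
    """
    h, w = images.shape[1] // 2, images.shape[2] // 2
    tl = images[:, :h, :w].mean(axis=(1, 2))
    br = images[:, h:, w:].mean(axis=(1, 2))
    tr = images[:, :h, w:].mean(axis=(1, 2))
    bl = images[:, h:, :w].mean(axis=(1, 2))
    return 0.5 * (tl + br) - 0.5 * (tr + bl)


def threshold_classifier_accuracy(stat: np.ndarray, labels: np.ndarray) -> float:
    """Accuracy of the better-signed midpoint threshold on a 1-D statistic."""
    m0, m1 = stat[labels == 0].mean(), stat[labels == 1].mean()
    thr = 0.5 * (m0 + m1)
    pred = (stat > thr).astype(int) if m1 > m0 else (stat <= thr).astype(int)
    return float((pred == labels).mean())


# ---------------------------------------------------------------------------
# persistence: PNG directory + CSV manifest


def save_dataset(dataset: ImageDataset, out_dir: str) -> str:
    """Write 8-bit PNGs plus ``manifest.csv``; returns the manifest path."""
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for i in range(len(dataset)):
        fname = f"img{i:05d}.png"
        arr = np.round(np.clip(dataset.images[i], 0, 1) * 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(os.path.join(out_dir, fname))
        rows.append({
            "filename": fname,
            "label": int(dataset.labels[i]),
            "subject_id": str(dataset.subject_ids[i]),
            "regime_tag": str(dataset.regime_tags[i]),
        })
    manifest = os.path.join(out_dir, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_dataset(data_dir: str) -> ImageDataset:
    """Read a PNG directory + manifest written by :func:`save_dataset`."""
    manifest = os.path.join(data_dir, "manifest.csv")
    if not os.path.exists(manifest):
        raise ConfigError(f"no manifest.csv found in {data_dir}")
    df = pd.read_csv(manifest)
    required = {"filename", "label", "subject_id"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"manifest {manifest} is missing columns: {sorted(missing)}")
    images = []
    for fname in df["filename"]:
        path = os.path.join(data_dir, fname)
        if not os.path.exists(path):
            raise ConfigError(f"image listed in manifest not found: {path}")
        with Image.open(path) as im:
            images.append(np.asarray(im.convert("L"), dtype=float) / 255.0)
    tags = df["regime_tag"].astype(str).to_numpy() if "regime_tag" in df.columns \
        else np.full(len(df), "none", dtype=object)
    return ImageDataset(
        images=np.asarray(images),
        labels=df["label"].to_numpy(dtype=int),
        subject_ids=df["subject_id"].astype(str).to_numpy(dtype=object),
        regime_tags=tags.astype(object),
    )
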