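"""CT intensity pipeline, paired augmentation, case split, and flip TTA.

The intensity chain emulates standard abdominal-CT preparation: clamp
Hounsfield units to a soft-tissue window ([-200, 250] HU by default,
which removes air and dense bone), rescale to [0, 1], then apply
contrast-limited adaptive histogram equalization (CLAHE) to sharpen
boundaries between tissues of similar density.

Augmentation applies the same geometric transform to image and mask:
random horizontal/vertical flips, a random crop removing at most 10% of
each axis followed by a resize back, and a translation of up to ±10%
per axis. Masks are always interpolated nearest-neighbor and
re-binarized.

Dataset splitting is by case (volume), never by slice, so no patient
leaks across the train/validation/test boundary.
"""

from __future__ import annotations

import numpy as np
from skimage import exposure, transform


__all__ = ["window_ct", "apply_clahe", "augment_pair", "split_cases",
           "tta_predict", "SplitSpec", "AugmentConfig"]


def window_ct(hu: np.ndarray, low: float = -200.0, high: float = 250.0) -> np.ndarray:
    """Clamp HU values to [low, high] and rescale linearly to [0, 1]."""
    if low >= high:
        raise ValueError(f"window bounds must satisfy low < high, got [{low}, {high}]")
    hu = np.asarray(hu, dtype=np.float64)
    return (np.clip(hu, low, high) - low) / (high - low)


def apply_clahe(img: np.ndarray, clip_limit: float = 0.01,
                tile_grid: tuple = (8, 8)) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on a [0,1] image."""
    img = np.asarray(img, dtype=np.float64)
    if img.min() < 0.0 or img.max() > 1.0:
        raise ValueError("apply_clahe expects an image in [0, 1]")
    if np.ptp(img) == 0.0:
        return img.copy()  # constant image: nothing to equalize
    kernel = (max(1, img.shape[0] // tile_grid[0]),
              max(1, img.shape[1] // tile_grid[1]))
    out = exposure.equalize_adapthist(img, kernel_size=kernel,
                                      clip_limit=clip_limit)
    return np.clip(out, 0.0, 1.0)


class AugmentConfig:
    """Probabilities and magnitudes for the paired augmentation."""

    def __init__(self, p_hflip: float = 0.5, p_vflip: float = 0.5,
                 p_crop: float = 0.5, p_translate: float = 0.5,
                 max_crop: float = 0.10, max_translate: float = 0.10):
        self.p_hflip = p_hflip
        self.p_vflip = p_vflip
        self.p_crop = p_crop
        self.p_translate = p_translate
        self.max_crop = max_crop
        self.max_translate = max_translate


def augment_pair(img: np.ndarray, mask: np.ndarray, rng_seed,
                 config: AugmentConfig | None = None):
    """Apply one random geometric transform identically to image and mask.

    Order: flips, then crop-and-resize, then translation. Translation
    pads the image with its minimum (air-equivalent) and the mask with
    background.
    """
    cfg = config or AugmentConfig()
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    img = np.asarray(img, dtype=np.float64)
    mask = np.asarray(mask)
    if img.shape != mask.shape:
        raise ValueError(f"image shape {img.shape} != mask shape {mask.shape}")
    h, w = img.shape

    if rng.random() < cfg.p_hflip:
        img, mask = img[:, ::-1], mask[:, ::-1]
    if rng.random() < cfg.p_vflip:
        img, mask = img[::-1, :], mask[::-1, :]

    if rng.random() < cfg.p_crop:
        ch = int(round(h * rng.uniform(0, cfg.max_crop)))
        cw = int(round(w * rng.uniform(0, cfg.max_crop)))
        top = rng.integers(0, ch + 1)
        left = rng.integers(0, cw + 1)
        sub_img = img[top:h - (ch - top), left:w - (cw - left)]
        sub_mask = mask[top:h - (ch - top), left:w - (cw - left)]
        img = transform.resize(sub_img, (h, w), order=1, mode="edge",
                               anti_aliasing=False)
        mask = transform.resize(sub_mask.astype(np.float64), (h, w), order=0,
                                mode="edge", anti_aliasing=False)

    if rng.random() < cfg.p_translate:
        dy = int(round(h * rng.uniform(-cfg.max_translate, cfg.max_translate)))
        dx = int(round(w * rng.uniform(-cfg.max_translate, cfg.max_translate)))
        fill = img.min()
        img = _shift2d(img, dy, dx, fill)
        mask = _shift2d(np.asarray(mask, dtype=np.float64), dy, dx, 0.0)

    mask = (np.asarray(mask, dtype=np.float64) > 0.5).astype(np.uint8)
    return img, mask


def _shift2d(arr: np.ndarray, dy: int, dx: int, fill: float) -> np.ndarray:
    out = np.full_like(arr, fill)
    h, w = arr.shape
    ys_src = slice(max(0, -dy), min(h, h - dy))
    ys_dst = slice(max(0, dy), min(h, h + dy))
    xs_src = slice(max(0, -dx), min(w, w - dx))
    xs_dst = slice(max(0, dx), min(w, w + dx))
    out[ys_dst, xs_dst] = arr[ys_src, xs_src]
    return out


class SplitSpec:
    """Disjoint case-level train/validation/test partition."""

    def __init__(self, train, val, test, ratio=(8, 1, 1)):
        self.train = list(train)
        self.val = list(val)
        self.test = list(test)
        self.ratio = tuple(ratio)
        all_ids = self.train + self.val + self.test
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("splits are not disjoint")

    def split_of(self, case_id) -> str:
        for name in ("train", "val", "test"):
            if case_id in getattr(self, name):
                return name
        raise KeyError(case_id)

    def as_dict(self) -> dict:
        return {"train": self.train, "val": self.val, "test": self.test,
                "ratio": list(self.ratio)}


def split_cases(case_ids, ratio=(8, 1, 1), rng_seed=0) -> SplitSpec:
    """Seeded case-level split with largest-remainder rounding.

    When every ratio entry is positive, each split receives at least one
    case (hence the three-case minimum): with few cases the rounding
    would otherwise starve the smallest split.
    """
    case_ids = list(case_ids)
    if len(case_ids) < 3:
        raise ValueError(f"need at least 3 cases to split, got {len(case_ids)}")
    if len(ratio) != 3 or any(r < 0 for r in ratio) or sum(ratio) <= 0:
        raise ValueError(f"invalid split ratio {ratio}")
    rng = np.random.default_rng(rng_seed)
    order = list(rng.permutation(len(case_ids)))
    n = len(case_ids)
    total = float(sum(ratio))
    quotas = [n * r / total for r in ratio]
    sizes = [int(np.floor(q)) for q in quotas]
    remainders = [q - s for q, s in zip(quotas, sizes)]
    for _ in range(n - sum(sizes)):
        i = int(np.argmax(remainders))
        sizes[i] += 1
        remainders[i] = -1.0
    if all(r > 0 for r in ratio):
        for i in range(3):  # guarantee a nonempty split
            while sizes[i] == 0:
                donor = int(np.argmax(sizes))
                sizes[donor] -= 1
                sizes[i] += 1
    shuffled = [case_ids[i] for i in order]
    train = shuffled[:sizes[0]]
    val = shuffled[sizes[0]:sizes[0] + sizes[1]]
    test = shuffled[sizes[0] + sizes[1]:]
    return SplitSpec(train, val, test, ratio)


# ----------------------------------------------------------------------
# test-time augmentation
# ----------------------------------------------------------------------

_TTA_TRANSFORMS = (
    (lambda a: a, lambda a: a),
    (lambda a: a[:, :, ::-1, :], lambda a: a[:, :, ::-1, :]),      # h-flip
    (lambda a: a[:, ::-1, :, :], lambda a: a[:, ::-1, :, :]),      # v-flip
    (lambda a: a[:, ::-1, ::-1, :], lambda a: a[:, ::-1, ::-1, :]) # hv-flip
)


def tta_predict(model, img: np.ndarray) -> np.ndarray:
    """Flip test-time augmentation: average of inverse-mapped predictions.

    ``model`` needs a ``predict(batch) -> probabilities`` method; both
    accept NHWC batches (a single HW or HWC image is promoted).
    """
    arr = np.asarray(img)
    squeeze_batch = arr.ndim < 4
    if arr.ndim == 2:
        arr = arr[None, :, :, None]
    elif arr.ndim == 3:
        arr = arr[None, ...]
    acc = None
    for fwd, inv in _TTA_TRANSFORMS:
        pred = model.predict(np.ascontiguousarray(fwd(arr)))
        pred = inv(pred)
        acc = pred.copy() if acc is None else acc + pred
    out = acc / len(_TTA_TRANSFORMS)
    return out[0] if squeeze_batch else out
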