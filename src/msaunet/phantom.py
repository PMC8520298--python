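"""Synthetic CT-like liver phantoms with exact ground-truth masks.

Each slice is a Hounsfield-unit image containing one smooth organ-like
blob (a random ellipse modulated by low-frequency radial harmonics)
filled at liver-like intensity (60 ± 10 HU by default) over a piecewise
background: air outside the body, a fat-density body oval, a muscle
region, and a bone-density insert, plus Gaussian noise. The blob's area
and centroid drift smoothly across the slices of a case, mimicking how
a liver grows and shrinks through an axial stack.

These phantoms let the whole pipeline — preprocessing, training,
evaluation, CLI — run end-to-end with no external download. They are
*not* anatomically realistic CT: no organ texture, no partial-volume
boundaries, no scanner artifacts.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["PhantomSpec", "CTSlice", "generate_case", "generate_dataset",
           "read_dataset", "HU_PNG_OFFSET"]

HU_PNG_OFFSET = 1024  # PNG16 stores hu + offset, losslessly for [-1000, 1000]


@dataclass(frozen=True)
class CTSlice:
    """One CT slice: HU image, optional paired mask, identifiers."""

    hu: np.ndarray
    mask: np.ndarray | None
    case_id: str
    slice_index: int
    spacing: tuple | None = None


@dataclass(frozen=True)
class PhantomSpec:
    size: tuple = (64, 64)
    n_cases: int = 10
    slices_per_case: int = 8
    organ_hu_mean: float = 60.0
    organ_hu_std: float = 10.0
    background_hu_levels: tuple = (-1000.0, -100.0, 40.0, 400.0)
    noise_std: float = 15.0
    area_range: tuple = (0.05, 0.40)
    rng_seed: int = 0

    def validate(self):
        h, w = self.size
        if h % 16 or w % 16:
            raise ValueError(f"phantom size {self.size} must be divisible by 16")
        lo, hi = self.area_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError(f"infeasible area range {self.area_range}")
        if self.n_cases < 1 or self.slices_per_case < 1:
            raise ValueError("need at least one case and one slice")


def _blob_mask(h: int, w: int, center, axes, angle, harmonics) -> np.ndarray:
    """Boolean mask of an ellipse warped by low-frequency radial harmonics."""
    yy, xx = np.mgrid[0:h, 0:w]
    dy = (yy - center[0]) / axes[0]
    dx = (xx - center[1]) / axes[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dx + sa * dy
    v = -sa * dx + ca * dy
    r = np.sqrt(u ** 2 + v ** 2)
    theta = np.arctan2(v, u)
    boundary = np.ones_like(r)
    for k, (amp, phase) in harmonics.items():
        boundary += amp * np.cos(k * theta + phase)
    return r <= boundary


def _largest_component(mask: np.ndarray) -> np.ndarray:
    from scipy import ndimage

    labels, n = ndimage.label(mask)
    if n <= 1:
        return mask
    sizes = ndimage.sum(mask, labels, range(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def generate_case(spec: PhantomSpec, case_index: int) -> list:
    """Generate one case (an ordered list of :class:`CTSlice`).

    Deterministic in ``(spec.rng_seed, case_index)``. HU values are
    rounded to integers (as in real CT) and clamped to [-1000, 1000];
    the mask is the exact blob interior.
    """
    spec.validate()
    h, w = spec.size
    rng = np.random.default_rng([spec.rng_seed, case_index])
    case_id = f"case_{case_index:03d}"

    air, fat, muscle, bone = spec.background_hu_levels
    lo_frac, hi_frac = spec.area_range
    # per-case anatomy: body oval, muscle band, bone insert
    body_axes = (h * rng.uniform(0.42, 0.48), w * rng.uniform(0.42, 0.48))
    bone_center = (h * rng.uniform(0.7, 0.85), w * rng.uniform(0.4, 0.6))
    bone_axes = (h * rng.uniform(0.05, 0.09), w * rng.uniform(0.08, 0.14))

    # organ trajectory: centroid and scale drift smoothly over slices
    base_center = np.array([h * rng.uniform(0.38, 0.5), w * rng.uniform(0.38, 0.55)])
    drift = rng.uniform(-0.04, 0.04, size=2) * np.array([h, w])
    base_axes = np.array([h, w]) * rng.uniform(0.16, 0.24, size=2)
    angle = rng.uniform(0, np.pi)
    harmonics = {k: (rng.uniform(0.02, 0.08), rng.uniform(0, 2 * np.pi))
                 for k in (2, 3, 5)}
    phase = rng.uniform(0, 2 * np.pi)

    slices = []
    n_s = spec.slices_per_case
    for s in range(n_s):
        t = s / max(n_s - 1, 1)
        center = base_center + drift * (t - 0.5) * 2
        scale = 1.0 + 0.15 * np.sin(np.pi * t + phase) * 0.5
        axes = base_axes * scale

        mask = None
        for _ in range(40):
            mask = _largest_component(
                _blob_mask(h, w, center, axes, angle, harmonics))
            frac = mask.mean()
            if lo_frac <= frac <= hi_frac:
                break
            # rescale axes toward the middle of the feasible band
            mid = (lo_frac + hi_frac) / 2.0
            factor = 1.5 if frac == 0 else float(np.sqrt(np.clip(mid / frac, 0.5, 2.0)))
            axes = np.clip(axes * factor, 2.0, (h * 0.45, w * 0.45))
        else:
            raise ValueError(
                f"could not place an organ blob with area in {spec.area_range}"
            )

        yy, xx = np.mgrid[0:h, 0:w]
        body = (((yy - h / 2) / body_axes[0]) ** 2
                + ((xx - w / 2) / body_axes[1]) ** 2) <= 1.0
        muscle_region = body & (yy > h * 0.62)
        bone_region = (((yy - bone_center[0]) / bone_axes[0]) ** 2
                       + ((xx - bone_center[1]) / bone_axes[1]) ** 2) <= 1.0

        hu = np.full((h, w), air, dtype=np.float64)
        hu[body] = fat
        hu[muscle_region] = muscle
        hu[bone_region & body] = bone
        organ = rng.normal(spec.organ_hu_mean, spec.organ_hu_std, size=(h, w))
        hu[mask] = organ[mask]
        hu += rng.normal(0.0, spec.noise_std, size=(h, w))
        hu = np.clip(np.round(hu), -1000, 1000)

        slices.append(CTSlice(hu=hu, mask=mask.astype(np.uint8),
                              case_id=case_id, slice_index=s,
                              spacing=(1.0, 1.0)))
    return slices


def generate_dataset(spec: PhantomSpec, out_dir, split_seed: int | None = None):
    """Write ``n_cases`` phantom cases as PNG pairs plus a manifest CSV.

    Layout: ``out_dir/case_XXX/img_YYY.png`` (uint16, HU + 1024) and
    ``mask_YYY.png`` (uint8, {0, 255}); ``out_dir/manifest.csv`` lists
    case_id, slice_index, paths, and the 8:1:1 case-level split.
    Returns the manifest path.
    """
    from .preprocessing import split_cases

    spec.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    case_ids = [f"case_{i:03d}" for i in range(spec.n_cases)]
    split = split_cases(case_ids, (8, 1, 1),
                        spec.rng_seed if split_seed is None else split_seed)

    rows = []
    for i in range(spec.n_cases):
        slices = generate_case(spec, i)
        case_dir = out_dir / slices[0].case_id
        case_dir.mkdir(exist_ok=True)
        for sl in slices:
            img_path = case_dir / f"img_{sl.slice_index:03d}.png"
            mask_path = case_dir / f"mask_{sl.slice_index:03d}.png"
            iio.imwrite(img_path,
                        (sl.hu + HU_PNG_OFFSET).astype(np.uint16))
            iio.imwrite(mask_path, (sl.mask * 255).astype(np.uint8))
            rows.append({
                "case_id": sl.case_id,
                "slice_index": sl.slice_index,
                "img_path": str(img_path.relative_to(out_dir)),
                "mask_path": str(mask_path.relative_to(out_dir)),
                "split": split.split_of(sl.case_id),
            })

    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        fh.write(f"# phantom manifest; images are uint16 PNG of HU + {HU_PNG_OFFSET}\n")
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
        writer.writeheader()
        writer.writerows(rows)
    return manifest


def read_dataset(manifest_path):
    """Read a PNG-pairs dataset back into per-split CTSlice lists."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    slices = {"train": [], "val": [], "test": []}
    with open(manifest_path) as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    for row in csv.DictReader(lines):
        hu = iio.imread(root / row["img_path"]).astype(np.float64) - HU_PNG_OFFSET
        mask = (iio.imread(root / row["mask_path"]) > 0).astype(np.uint8)
        slices[row["split"]].append(
            CTSlice(hu=hu, mask=mask, case_id=row["case_id"],
                    slice_index=int(row["slice_index"])))
    return slices


def manifest_checksum(manifest_path) -> str:
    """SHA-256 of the manifest file contents."""
    return hashlib.sha256(Path(manifest_path).read_bytes()).hexdigest()
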