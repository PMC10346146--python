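"""Synthetic abdominal-CT-like phantoms for training and evaluation at desk scale.

Each phantom is a 2-D grayscale slice with up to eight "organ" regions —
boundary-perturbed ellipses with class-specific intensity distributions —
placed by rejection sampling inside anatomy-inspired regions of the canvas,
over a textured background with additive Gaussian noise.  The left and right
kidney deliberately share one intensity distribution and differ only in
position, so telling them apart requires spatial context rather than local
appearance — the situation long-range feature mixing is meant to help with.

Everything is deterministic given (spec, seed); datasets are built from
per-sample child seeds recorded in a JSON manifest, so any sample can be
regenerated bit-for-bit from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from dataclasses import asdict, dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from PIL import Image

__all__ = [
    "ORGAN_NAMES",
    "GenerationError",
    "PhantomSpec",
    "SegSample",
    "DatasetSplit",
    "generate_phantom",
    "generate_dataset",
    "regenerate_from_manifest",
    "write_fixtures",
    "load_fixtures",
    "export_nifti",
]

ORGAN_NAMES = ("Aorta", "Gallbladder", "Kidney (L)", "Kidney (R)",
               "Liver", "Pancreas", "Spleen", "Stomach")

# per class (ids 1..8): intensity mean, intensity sigma, area-fraction range,
# centre box (x0, x1, y0, y1) as fractions of the canvas.  The kidneys share
# an intensity and sit in mirrored boxes low in the slice; the liver is the
# largest structure, high and lateral; the aorta is small, bright and medial.
_ORGAN_DEFAULTS = (
    (0.85, 0.02, (0.008, 0.014), (0.40, 0.60, 0.44, 0.66)),  # aorta
    (0.30, 0.02, (0.008, 0.016), (0.12, 0.32, 0.52, 0.70)),  # gallbladder
    (0.55, 0.02, (0.014, 0.024), (0.65, 0.88, 0.76, 0.92)),  # kidney (L)
    (0.55, 0.02, (0.014, 0.024), (0.12, 0.35, 0.76, 0.92)),  # kidney (R)
    (0.45, 0.02, (0.035, 0.060), (0.10, 0.38, 0.15, 0.42)),  # liver
    (0.65, 0.02, (0.010, 0.020), (0.62, 0.85, 0.50, 0.68)),  # pancreas
    (0.75, 0.02, (0.020, 0.035), (0.68, 0.92, 0.15, 0.40)),  # spleen
    (0.22, 0.02, (0.025, 0.045), (0.38, 0.58, 0.12, 0.35)),  # stomach
)

_MAX_ASPECT = 1.2       # ellipse axis ratio bound (area preserved)
_N_HARMONICS = 4        # Fourier boundary perturbation harmonics
_MAX_AMP = 0.03         # per-harmonic amplitude bound; radius within +-12 %


class GenerationError(RuntimeError):
    """Raised when organ placement cannot satisfy the spec's constraints."""


@dataclass(frozen=True)
class PhantomSpec:
    """Statistical description of one phantom family.

    Size fractions are of the canvas area; centroid distances are fractions
    of the canvas side, so specs are resolution-independent.
    """

    image_size: int = 224
    n_classes: int = 8
    intensity_means: Tuple[float, ...] = tuple(o[0] for o in _ORGAN_DEFAULTS)
    intensity_sigmas: Tuple[float, ...] = tuple(o[1] for o in _ORGAN_DEFAULTS)
    size_ranges: Tuple[Tuple[float, float], ...] = tuple(o[2] for o in _ORGAN_DEFAULTS)
    center_boxes: Tuple[Tuple[float, float, float, float], ...] = tuple(o[3] for o in _ORGAN_DEFAULTS)
    shape_family: str = "blob"  # "blob" (perturbed ellipse) | "ellipse"
    noise_sigma: float = 0.03
    background_mean: float = 0.08
    background_sigma: float = 0.02
    min_centroid_dist: float = 0.10   # fraction of canvas side, all pairs
    max_centroid_dist: float = 0.95   # each organ within this of some other
    spacing_mm: float = 1.0

    def __post_init__(self):
        if not 1 <= self.n_classes <= 8:
            raise ValueError("n_classes must be between 1 and 8")
        for lo, hi in self.size_ranges[: self.n_classes]:
            if not (0.0 < lo < hi < 0.25):
                raise ValueError("size fractions must lie in (0, 0.25)")
        if self.shape_family not in ("blob", "ellipse"):
            raise ValueError("shape_family must be 'blob' or 'ellipse'")
        if self.min_centroid_dist * self.image_size >= self.image_size * math.sqrt(2):
            raise ValueError("min centroid distance infeasible for the canvas")

    def spec_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()


@dataclass
class SegSample:
    """One image / label-mask pair: the unit of training and evaluation."""

    image: np.ndarray        # (3, H, W) float32 in [0, 1], replicated grayscale
    mask: np.ndarray         # (H, W) uint8 in {0..n_classes}
    spacing_mm: float = 1.0
    seed: Optional[int] = None


@dataclass
class DatasetSplit:
    train: List[SegSample]
    test: List[SegSample]
    manifest: dict


def _rasterize_blob(size: int, cx: float, cy: float, a: float, b: float, theta: float,
                    amps: np.ndarray, phases: np.ndarray) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    dx, dy = xx - cx, yy - cy
    ct, st = math.cos(theta), math.sin(theta)
    u = (ct * dx + st * dy) / a
    v = (-st * dx + ct * dy) / b
    rho = np.hypot(u, v)
    phi = np.arctan2(v, u)
    f = np.ones_like(rho)
    for k in range(1, len(amps) + 1):
        f += amps[k - 1] * np.cos(k * phi + phases[k - 1])
    return rho <= f


def generate_phantom(spec: PhantomSpec, seed: int) -> SegSample:
    """Deterministically generate one phantom from (spec, seed).

    Organs are placed largest-first; a placement is accepted when every
    pairwise centroid distance clears both the spec minimum and the sum of
    the shapes' outer radii (so classes never overlap), and the organ sits
    within ``max_centroid_dist`` of an already placed one.
    """
    size = spec.image_size
    area = size * size
    rng = np.random.default_rng(seed)
    classes = list(range(1, spec.n_classes + 1))
    order = sorted(classes, key=lambda c: -spec.size_ranges[c - 1][1])

    for _restart in range(25):
        placed = {}  # class -> (cx, cy, outer_radius, mask)
        ok = True
        for c in order:
            lo, hi = spec.size_ranges[c - 1]
            x0, x1, y0, y1 = spec.center_boxes[c - 1]
            success = False
            for _try in range(250):
                frac = rng.uniform(lo + 0.25 * (hi - lo), hi - 0.25 * (hi - lo))
                aspect = rng.uniform(1.0, _MAX_ASPECT)
                if rng.random() < 0.5:
                    aspect = 1.0 / aspect
                theta = rng.uniform(0.0, math.pi)
                if spec.shape_family == "blob":
                    amps = rng.uniform(-_MAX_AMP, _MAX_AMP, _N_HARMONICS)
                    phases = rng.uniform(0.0, 2 * math.pi, _N_HARMONICS)
                else:
                    amps = np.zeros(_N_HARMONICS)
                    phases = np.zeros(_N_HARMONICS)
                # mean of f^2 over angle is 1 + sum(amp^2)/2; solve a*b for the
                # requested pixel area
                ab = frac * area / (math.pi * (1.0 + 0.5 * float(np.sum(amps ** 2))))
                r = math.sqrt(ab)
                a, b = r * aspect, r / aspect
                outer = (1.0 + float(np.sum(np.abs(amps)))) * max(a, b)
                margin = outer + 1.5
                cx_lo, cx_hi = max(x0 * size, margin), min(x1 * size, size - 1 - margin)
                cy_lo, cy_hi = max(y0 * size, margin), min(y1 * size, size - 1 - margin)
                if cx_lo >= cx_hi or cy_lo >= cy_hi:
                    continue
                cx = rng.uniform(cx_lo, cx_hi)
                cy = rng.uniform(cy_lo, cy_hi)
                good = True
                near_someone = not placed
                for (ox, oy, orad, _m) in placed.values():
                    d = math.hypot(cx - ox, cy - oy)
                    if d < max(spec.min_centroid_dist * size, outer + orad + 1.0):
                        good = False
                        break
                    if d <= spec.max_centroid_dist * size:
                        near_someone = True
                if not (good and near_someone):
                    continue
                blob = _rasterize_blob(size, cx, cy, a, b, theta, amps, phases)
                placed[c] = (cx, cy, outer, blob)
                success = True
                break
            if not success:
                ok = False
                break
        if ok:
            break
    else:
        raise GenerationError(
            "could not place all organ classes under the centroid-distance and "
            "overlap constraints; relax size ranges, centre boxes or distances"
        )

    mask = np.zeros((size, size), dtype=np.uint8)
    img = rng.normal(spec.background_mean, spec.background_sigma, (size, size))
    for c in classes:
        _, _, _, blob = placed[c]
        mask[blob] = c
        img[blob] = spec.intensity_means[c - 1] + rng.normal(
            0.0, spec.intensity_sigmas[c - 1], int(blob.sum())
        )
    img += rng.normal(0.0, spec.noise_sigma, (size, size))
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    image = np.repeat(img[None], 3, axis=0)
    return SegSample(image=image, mask=mask, spacing_mm=spec.spacing_mm, seed=int(seed))


def generate_dataset(spec: PhantomSpec, n: int, seed: int, split: float = 0.7) -> DatasetSplit:
    """n phantoms from child seeds of ``seed``, split disjointly train/test.

    The train count is floor(split * n) (430 at 7:3 gives 301 / 129); the
    manifest records the spec, its hash, and each sample's seed and subset.
    """
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    if not 0.0 < split < 1.0:
        raise ValueError("split ratio must lie strictly between 0 and 1")
    state = np.random.SeedSequence(seed).generate_state(n + 1)
    sample_seeds = [int(s) for s in state[:n]]
    samples = [generate_phantom(spec, s) for s in sample_seeds]
    perm = np.random.default_rng(int(state[n])).permutation(n)
    n_train = int(math.floor(split * n))
    train_idx = set(int(i) for i in perm[:n_train])
    manifest = {
        "seed": int(seed),
        "n": int(n),
        "split": float(split),
        "spec": asdict(spec),
        "spec_hash": spec.spec_hash(),
        "samples": [
            {"index": i, "seed": sample_seeds[i],
             "subset": "train" if i in train_idx else "test"}
            for i in range(n)
        ],
    }
    train = [samples[i] for i in range(n) if i in train_idx]
    test = [samples[i] for i in range(n) if i not in train_idx]
    return DatasetSplit(train=train, test=test, manifest=manifest)


def regenerate_from_manifest(manifest: dict) -> DatasetSplit:
    """Rebuild every sample bit-for-bit from a dataset manifest."""
    spec_dict = dict(manifest["spec"])
    for key in ("intensity_means", "intensity_sigmas"):
        spec_dict[key] = tuple(spec_dict[key])
    spec_dict["size_ranges"] = tuple(tuple(r) for r in spec_dict["size_ranges"])
    spec_dict["center_boxes"] = tuple(tuple(b) for b in spec_dict["center_boxes"])
    spec = PhantomSpec(**spec_dict)
    train, test = [], []
    for entry in manifest["samples"]:
        sample = generate_phantom(spec, entry["seed"])
        (train if entry["subset"] == "train" else test).append(sample)
    return DatasetSplit(train=train, test=test, manifest=manifest)


_PALETTE = [
    (0, 0, 0), (230, 25, 75), (60, 180, 75), (255, 225, 25), (0, 130, 200),
    (245, 130, 48), (145, 30, 180), (70, 240, 240), (240, 50, 230),
]


def _mask_to_png(mask: np.ndarray, path: str) -> None:
    img = Image.fromarray(mask, mode="P")
    palette = []
    for rgb in _PALETTE:
        palette.extend(rgb)
    img.putpalette(palette)
    img.save(path)


def write_fixtures(dataset: DatasetSplit, out_dir: str, format: str = "png") -> str:
    """Write a dataset to disk (8-bit RGB PNG images + indexed PNG masks, or
    one ``.npz`` bundle per sample) and return the manifest path."""
    if format not in ("png", "npz"):
        raise ValueError("format must be 'png' or 'npz'")
    os.makedirs(out_dir, exist_ok=True)
    manifest = dict(dataset.manifest)
    manifest["format"] = format
    files = []
    idx = 0
    for subset, samples in (("train", dataset.train), ("test", dataset.test)):
        for sample in samples:
            stem = f"sample_{idx:04d}"
            try:
                if format == "png":
                    rgb = np.clip(np.round(sample.image * 255), 0, 255).astype(np.uint8)
                    img_path = os.path.join(out_dir, f"{stem}_image.png")
                    mask_path = os.path.join(out_dir, f"{stem}_mask.png")
                    Image.fromarray(rgb.transpose(1, 2, 0)).save(img_path)
                    _mask_to_png(sample.mask, mask_path)
                    entry = {"image": os.path.basename(img_path),
                             "mask": os.path.basename(mask_path)}
                else:
                    bundle_path = os.path.join(out_dir, f"{stem}.npz")
                    np.savez(bundle_path, image=sample.image, mask=sample.mask,
                             spacing_mm=sample.spacing_mm)
                    entry = {"bundle": os.path.basename(bundle_path)}
            except OSError as exc:
                raise OSError(f"failed to write fixture {stem} under {out_dir}: {exc}") from exc
            entry.update({"subset": subset, "seed": sample.seed,
                          "spacing_mm": sample.spacing_mm})
            files.append(entry)
            idx += 1
    manifest["files"] = files
    manifest_path = os.path.join(out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest_path


def load_fixtures(manifest_path: str) -> DatasetSplit:
    """Read back a fixture directory written by :func:`write_fixtures`.

    PNG images are 8-bit quantized; masks round-trip exactly.
    """
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    base = os.path.dirname(os.path.abspath(manifest_path))
    train, test = [], []
    for entry in manifest["files"]:
        if "bundle" in entry:
            with np.load(os.path.join(base, entry["bundle"])) as data:
                image = data["image"].astype(np.float32)
                mask = data["mask"].astype(np.uint8)
        else:
            rgb = np.asarray(Image.open(os.path.join(base, entry["image"])), dtype=np.float32)
            image = (rgb / 255.0).transpose(2, 0, 1)
            mask = np.asarray(Image.open(os.path.join(base, entry["mask"])), dtype=np.uint8)
        sample = SegSample(image=image, mask=mask,
                           spacing_mm=float(entry.get("spacing_mm", 1.0)),
                           seed=entry.get("seed"))
        (train if entry["subset"] == "train" else test).append(sample)
    return DatasetSplit(train=train, test=test, manifest=manifest)


def export_nifti(samples: Sequence[SegSample], image_path: str, mask_path: str) -> None:
    """Optional NIfTI export: stack 2-D slices into (H, W, n) volumes."""
    import nibabel as nib

    images = np.stack([s.image[0] for s in samples], axis=-1).astype(np.float32)
    masks = np.stack([s.mask for s in samples], axis=-1).astype(np.uint8)
    affine = np.diag([samples[0].spacing_mm, samples[0].spacing_mm, 1.0, 1.0])
    nib.save(nib.Nifti1Image(images, affine), image_path)
    nib.save(nib.Nifti1Image(masks, affine), mask_path)
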