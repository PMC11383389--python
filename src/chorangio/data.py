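"""Data model, file I/O and label composition.

On disk a dataset is a JSON manifest plus per-slice files: float32 TIFF images
(lossless round-trip), indexed-PNG masks (palette indices 0/1/2) and optional
NIfTI cubes (image volume + vessel and sublayer label volumes).  In memory a
B-scan is a small dataclass; labeled samples carry a binary vessel mask and a
3-class sublayer mask of the same spatial shape.

Label composition follows the subtask decomposition of the segmentor: the
final 3-class map {0: background, 1: SV, 2: HV} is the elementwise (Hadamard)
product of the binary vessel map with the {0, 1, 2} sublayer map.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile
from PIL import Image

from .phantom import PhantomCube, PhantomSample

__all__ = [
    "BScan",
    "LabelVolume",
    "combine_labels",
    "write_sample",
    "write_dataset",
    "read_dataset",
    "write_cube",
    "read_cube",
]

MASK_PALETTE = [0, 0, 0, 220, 60, 60, 60, 90, 220] + [0] * (256 * 3 - 9)


@dataclass
class BScan:
    """One OCT B-scan with optional ground truth and physical spacing."""

    image: np.ndarray
    vessel_mask: np.ndarray | None = None
    sublayer_mask: np.ndarray | None = None
    domain_tag: str = "hd"
    axial_spacing_um: float = 3.9
    lateral_spacing_mm: float = 12.0 / 128

    def __post_init__(self):
        for m in (self.vessel_mask, self.sublayer_mask):
            if m is not None and m.shape != self.image.shape:
                raise ValueError(
                    f"mask shape {m.shape} != image shape {self.image.shape}"
                )


@dataclass
class LabelVolume:
    """Composed 3-class label stack {0: background, 1: SV, 2: HV}."""

    labels: np.ndarray
    axial_spacing_um: float
    lateral_spacing_mm: float
    slice_spacing_mm: float

    def __post_init__(self):
        vals = np.unique(self.labels)
        if not np.isin(vals, [0, 1, 2]).all():
            raise ValueError(f"label volume contains values outside {{0,1,2}}: {vals}")


def combine_labels(vessel_mask: np.ndarray, sublayer_mask: np.ndarray) -> np.ndarray:
    """Compose vessel and sublayer masks into the {bg, SV, HV} label map.

    Elementwise product: a vessel pixel inside the Sattler band becomes 1 (SV),
    inside the Haller band 2 (HV), anything else background.  Works for 2-D
    slices and 3-D stacks alike.
    """
    vessel_mask = np.asarray(vessel_mask)
    sublayer_mask = np.asarray(sublayer_mask)
    if vessel_mask.shape != sublayer_mask.shape:
        raise ValueError("vessel/sublayer shape mismatch")
    if not np.isin(vessel_mask, [0, 1]).all():
        raise ValueError("vessel mask must be binary")
    if not np.isin(sublayer_mask, [0, 1, 2]).all():
        raise ValueError("sublayer mask values must be in {0,1,2}")
    return (vessel_mask.astype(np.uint8) * sublayer_mask.astype(np.uint8))


# ---------------------------------------------------------------------------
# slice-level I/O
# ---------------------------------------------------------------------------

def _write_mask_png(mask: np.ndarray, path: Path):
    im = Image.fromarray(mask.astype(np.uint8), mode="P")
    im.putpalette(MASK_PALETTE)
    im.save(path)


def _read_mask_png(path: Path) -> np.ndarray:
    return np.asarray(Image.open(path), dtype=np.uint8)


def write_sample(sample, out_dir: Path, stem: str, with_masks: bool = True) -> dict:
    """Write one sample (image TIFF + optional mask PNGs); returns the manifest
    entry."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    image = np.asarray(sample.image, dtype=np.float32)
    img_path = out_dir / f"{stem}_image.tif"
    tifffile.imwrite(img_path, image)
    entry = {
        "image": img_path.name,
        "domain": sample.domain_tag,
        "vessel_mask": None,
        "sublayer_mask": None,
    }
    if isinstance(sample, PhantomSample):
        entry["axial_spacing_um"] = sample.params.axial_spacing
        entry["lateral_spacing_mm"] = sample.params.lateral_spacing
    else:
        entry["axial_spacing_um"] = sample.axial_spacing_um
        entry["lateral_spacing_mm"] = sample.lateral_spacing_mm
    if with_masks and sample.vessel_mask is not None:
        vp = out_dir / f"{stem}_vessel.png"
        lp = out_dir / f"{stem}_layers.png"
        _write_mask_png(sample.vessel_mask, vp)
        _write_mask_png(sample.sublayer_mask, lp)
        entry["vessel_mask"] = vp.name
        entry["sublayer_mask"] = lp.name
    return entry


def write_dataset(samples, out_dir: Path, cubes=(), manifest_name: str = "manifest.json",
                  label_source: bool = True) -> Path:
    """Write samples (+ optional cubes) and a JSON manifest.

    HD samples are written with masks (source/labeled role), low-quality
    samples without, unless `label_source` is disabled.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, s in enumerate(samples):
        with_masks = label_source and s.domain_tag == "hd"
        entries.append(write_sample(s, out_dir, f"{s.domain_tag}_{i:04d}", with_masks))
    cube_entries = []
    for i, cube in enumerate(cubes):
        cube_entries.append(write_cube(cube, out_dir, f"cube_{i:03d}"))
    manifest = {"version": 1, "samples": entries, "cubes": cube_entries}
    path = out_dir / manifest_name
    path.write_text(json.dumps(manifest, indent=2))
    return path


def _load_entry(entry: dict, root: Path) -> BScan:
    img_path = root / entry["image"]
    if not img_path.exists():
        raise FileNotFoundError(f"manifest references missing file: {img_path}")
    image = tifffile.imread(img_path).astype(np.float32)
    masks = {}
    for key in ("vessel_mask", "sublayer_mask"):
        name = entry.get(key)
        if name is None:
            masks[key] = None
            continue
        p = root / name
        if not p.exists():
            raise FileNotFoundError(f"manifest references missing file: {p}")
        masks[key] = _read_mask_png(p)
    return BScan(
        image=image,
        vessel_mask=masks["vessel_mask"],
        sublayer_mask=masks["sublayer_mask"],
        domain_tag=entry["domain"],
        axial_spacing_um=entry.get("axial_spacing_um", 3.9),
        lateral_spacing_mm=entry.get("lateral_spacing_mm", 12.0 / 128),
    )


def read_dataset(manifest_path: Path) -> tuple[list[BScan], list[BScan]]:
    """Load a manifest into (labeled source set, unlabeled target set).

    HD samples must carry both masks; masks on low-quality samples are dropped
    with a warning (the target set is unlabeled by definition).
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    root = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    source, target = [], []
    for entry in manifest["samples"]:
        scan = _load_entry(entry, root)
        if scan.domain_tag == "hd":
            if scan.vessel_mask is None or scan.sublayer_mask is None:
                raise ValueError(f"source sample {entry['image']} lacks a mask")
            source.append(scan)
        else:
            if scan.vessel_mask is not None or scan.sublayer_mask is not None:
                warnings.warn(
                    f"target sample {entry['image']} carries masks; ignored",
                    stacklevel=2,
                )
                scan.vessel_mask = None
                scan.sublayer_mask = None
            target.append(scan)
    if not target:
        raise ValueError("target set empty (self-training impossible)")
    return source, target


# ---------------------------------------------------------------------------
# cube I/O (NIfTI)
# ---------------------------------------------------------------------------

def write_cube(cube: PhantomCube, out_dir: Path, stem: str) -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    p = cube.slices[0].params
    # axes (T, H, W); record spacings in the affine diagonal (mm)
    affine = np.diag([cube.slice_spacing, p.axial_spacing / 1000.0,
                      cube.lateral_spacing, 1.0])
    names = {}
    for name, vol in (("image", cube.image_volume().astype(np.float32)),
                      ("vessel", cube.vessel_volume().astype(np.uint8)),
                      ("layers", cube.sublayer_volume().astype(np.uint8))):
        path = out_dir / f"{stem}_{name}.nii"
        nib.save(nib.Nifti1Image(vol, affine), path)
        names[name] = path.name
    return {
        "image": names["image"],
        "vessel_mask": names["vessel"],
        "sublayer_mask": names["layers"],
        "fovea_center": list(cube.fovea_center),
        "slice_spacing_mm": cube.slice_spacing,
        "lateral_spacing_mm": cube.lateral_spacing,
        "axial_spacing_um": p.axial_spacing,
    }


def read_cube(entry: dict, root: Path) -> dict:
    """Load a cube manifest entry into arrays + metadata."""
    root = Path(root)
    out = dict(entry)
    out["image"] = np.asarray(nib.load(root / entry["image"]).dataobj, dtype=np.float32)
    for key in ("vessel_mask", "sublayer_mask"):
        if entry.get(key):
            out[key] = np.asarray(nib.load(root / entry[key]).dataobj, dtype=np.uint8)
    return out
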