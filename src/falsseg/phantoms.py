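"""Synthetic MRI-like phantoms with exact polygon labels.

Each phantom is a grayscale image containing a smooth, low-frequency
"brain" blob plus Gaussian noise, with 0-3 elliptical lesions drawn inside
the blob.  The three lesion classes (glioma / meningioma / pituitary) differ
in intensity contrast and internal texture.  Every lesion carries an exact
24-vertex polygon discretisation of its ellipse boundary, written in the
YOLO segmentation label dialect (one ``class x1 y1 ... xk yk`` line per
instance, coordinates normalised to [0, 1]).

The generator is fully deterministic: the same (seed, index) pair always
yields byte-identical images and labels, and train/val splits draw from
disjoint index ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image
from skimage.draw import polygon as sk_polygon

CLASS_NAMES = ("glioma", "meningioma", "pituitary")


@dataclass
class PhantomSpec:
    image_size: int = 640
    num_classes: int = 3
    lesions_per_image: tuple[int, int] = (0, 3)
    lesion_axes: tuple[float, float] = (12.0, 120.0)  # semi-axis range at 640 px
    contrast: tuple[float, float] = (0.15, 0.6)
    noise_sigma: float = 0.03
    polygon_vertices: int = 24
    seed: int = 0
    class_names: tuple[str, ...] = CLASS_NAMES

    def axes_at_size(self) -> tuple[float, float]:
        """Semi-axis range at `image_size`.

        The range scales with the image so that smaller renderings keep the
        scene composition of the reference 640 px phantoms, with a 6 px
        floor: a lesion whose semi-axis falls below the coarsest feature
        stride is a downscaling artifact, not a meaningful target.
        """
        f = self.image_size / 640.0
        return (max(self.lesion_axes[0] * f, 6.0), max(self.lesion_axes[1] * f, 8.0))


@dataclass
class Instance:
    class_id: int
    polygon: np.ndarray  # (K, 2) normalised xy
    mask: np.ndarray | None = None  # binary HxW


@dataclass
class PhantomSample:
    image: np.ndarray  # uint8 HxW
    instances: list[Instance] = field(default_factory=list)


def _rng_for(spec: PhantomSpec, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, index]))


def _brain_background(rng: np.random.Generator, s: int) -> tuple[np.ndarray, np.ndarray]:
    """Smooth elliptical blob with low-frequency internal structure.

    Returns (image float in [0,1], blob mask)."""
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float32)
    cy, cx = s / 2 + rng.uniform(-0.03, 0.03) * s, s / 2 + rng.uniform(-0.03, 0.03) * s
    ry, rx = s * rng.uniform(0.33, 0.42), s * rng.uniform(0.28, 0.38)
    d = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
    blob = d < 1.0
    # low-frequency texture: a few random cosine modes
    tex = np.zeros((s, s), np.float32)
    for _ in range(6):
        fy, fx = rng.uniform(0.5, 3.0, 2)
        ph = rng.uniform(0, 2 * np.pi, 2)
        tex += rng.uniform(0.02, 0.08) * np.cos(
            2 * np.pi * fy * yy / s + ph[0]
        ) * np.cos(2 * np.pi * fx * xx / s + ph[1])
    img = np.where(blob, 0.45 + 0.25 * (1 - d) + tex, 0.02).astype(np.float32)
    return img, blob


def _ellipse_polygon(cx, cy, a, b, theta, k, s) -> np.ndarray:
    t = np.linspace(0, 2 * np.pi, k, endpoint=False)
    ex = a * np.cos(t)
    ey = b * np.sin(t)
    x = cx + ex * np.cos(theta) - ey * np.sin(theta)
    y = cy + ex * np.sin(theta) + ey * np.cos(theta)
    pts = np.stack([x, y], axis=1) / s
    return np.clip(pts, 0.0, 1.0)


def rasterize_polygon(poly_norm: np.ndarray, s: int) -> np.ndarray:
    mask = np.zeros((s, s), bool)
    rr, cc = sk_polygon(poly_norm[:, 1] * s, poly_norm[:, 0] * s, shape=(s, s))
    mask[rr, cc] = True
    return mask


def generate_phantom(spec: PhantomSpec, index: int) -> PhantomSample:
    rng = _rng_for(spec, index)
    s = spec.image_size
    img, blob = _brain_background(rng, s)
    lo, hi = spec.lesions_per_image
    n_lesions = int(rng.integers(lo, hi + 1))
    amin, amax = spec.axes_at_size()
    amax = min(amax, s / 2.0 - 2.0)
    instances: list[Instance] = []
    ys, xs = np.nonzero(blob)
    for _ in range(n_lesions):
        cls = int(rng.integers(0, spec.num_classes))
        for _attempt in range(20):
            j = int(rng.integers(0, len(ys)))
            cy, cx = float(ys[j]), float(xs[j])
            a = float(rng.uniform(amin, amax))
            b = float(a * rng.uniform(0.5, 1.0))
            theta = float(rng.uniform(0, np.pi))
            # keep the lesion inside the image with a small margin
            r = max(a, b)
            if r < cx < s - r and r < cy < s - r:
                break
        else:
            continue
        poly = _ellipse_polygon(cx, cy, a, b, theta, spec.polygon_vertices, s)
        mask = rasterize_polygon(poly, s)
        contrast = float(rng.uniform(*spec.contrast))
        # class-dependent appearance: bright / bright+texture / dark
        if cls == 0:
            val = img + contrast * mask
        elif cls == 1:
            # internal texture whose period scales with the lesion so the
            # class signature survives at every lesion size
            yy, xx = np.mgrid[0:s, 0:s]
            period = max(3.0, a / 2.0)
            ripple = 0.25 * np.sin(2 * np.pi * (yy + xx) / period)
            val = img + (contrast * (1.0 + ripple)) * mask
        else:
            val = img - contrast * mask
        img = val.astype(np.float32)
        instances.append(Instance(cls, poly, mask))
    img = img + rng.normal(0, spec.noise_sigma, (s, s)).astype(np.float32)
    img8 = (np.clip(img, 0, 1) * 255).round().astype(np.uint8)
    return PhantomSample(img8, instances)


# ---------------------------------------------------------------------------
# dataset I/O (YOLO-segmentation layout)
# ---------------------------------------------------------------------------


def write_dataset(spec: PhantomSpec, n_train: int, n_val: int, out_dir) -> Path:
    """Write a YOLO-seg dataset; returns the path of the dataset YAML."""
    out = Path(out_dir)
    for split in ("train", "val"):
        (out / "images" / split).mkdir(parents=True, exist_ok=True)
        (out / "labels" / split).mkdir(parents=True, exist_ok=True)
    counts = {"train": (0, n_train), "val": (n_train, n_train + n_val)}
    for split, (a, b) in counts.items():
        for i in range(a, b):
            sample = generate_phantom(spec, i)
            stem = f"phantom_{i:05d}"
            Image.fromarray(sample.image, mode="L").save(
                out / "images" / split / f"{stem}.png"
            )
            lines = []
            for inst in sample.instances:
                coords = " ".join(f"{v:.6f}" for v in inst.polygon.ravel())
                lines.append(f"{inst.class_id} {coords}")
            (out / "labels" / split / f"{stem}.txt").write_text(
                "\n".join(lines) + ("\n" if lines else "")
            )
    meta = {
        "path": str(out),
        "train": "images/train",
        "val": "images/val",
        "nc": spec.num_classes,
        "names": list(spec.class_names[: spec.num_classes]),
        "image_size": spec.image_size,
    }
    ypath = out / "dataset.yaml"
    ypath.write_text(yaml.safe_dump(meta, sort_keys=False))
    return ypath


class LabelError(ValueError):
    pass


def parse_label_file(path) -> list[Instance]:
    instances = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        tok = line.split()
        try:
            cls = int(tok[0])
            vals = [float(v) for v in tok[1:]]
        except ValueError as e:
            raise LabelError(f"{path}:{ln}: malformed token ({e})") from None
        if len(vals) < 6 or len(vals) % 2:
            raise LabelError(
                f"{path}:{ln}: need an even count of >=6 coordinates, got {len(vals)}"
            )
        poly = np.array(vals, dtype=np.float64).reshape(-1, 2)
        instances.append(Instance(cls, poly))
    return instances


def read_yolo_seg_labels(dataset_dir, split: str = "train"):
    """Read (image path, instances) pairs, paired by file stem."""
    root = Path(dataset_dir)
    img_dir = root / "images" / split
    lbl_dir = root / "labels" / split
    out = []
    for img_path in sorted(img_dir.glob("*.png")):
        lbl = lbl_dir / (img_path.stem + ".txt")
        instances = parse_label_file(lbl) if lbl.exists() else []
        out.append((img_path, instances))
    return out


def load_image(path, size: int | None = None) -> np.ndarray:
    """Load a grayscale PNG as a (3, H, W) float32 array in [0, 1] (the
    single channel replicated to the 3 channels the network stem expects)."""
    im = Image.open(path).convert("L")
    if size is not None and im.size != (size, size):
        im = im.resize((size, size), Image.BILINEAR)
    arr = np.asarray(im, np.float32) / 255.0
    return np.repeat(arr[None], 3, axis=0)
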