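"""Synthetic annotated potato-damage scenes and YOLO-txt dataset I/O.

The generator emulates the statistical structure of a broken-skin inspection
dataset: one or two roughly elliptical tubers with low-frequency brown peel
texture on a dark conveyor-like background, each bearing zero to several
irregular lighter ("broken skin") patches.  Every patch is annotated with the
tight axis-aligned bounding box of its pixel mask.  Scenes are deterministic
given (spec, seed).

Augmentations follow the standard detection set: horizontal flip, translation,
rotation, brightness/contrast adjustment, and scaling, with boxes transformed
consistently (rotation replaces a box by the axis-aligned hull of its rotated
corners; boxes are clipped to bounds and dropped when less than 25% of their
area stays visible).

Datasets are written in the YOLO directory layout: ``images/{split}/*.png``
plus ``labels/{split}/*.txt`` with normalized ``class cx cy w h`` lines and a
YAML descriptor, split 8:1:1 into train/val/test.
"""

from __future__ import annotations

import dataclasses
import pathlib

import numpy as np
import yaml
from PIL import Image
from scipy import ndimage

from .boxes import corners_to_yolo, yolo_to_corners

__all__ = ["SceneSpec", "AnnotatedImage", "generate_scene", "augment",
           "generate_dataset", "write_dataset", "load_split", "AUGMENT_OPS"]

AUGMENT_OPS = ("hflip", "translate", "rotate", "brightness_contrast", "scale")
MIN_VISIBLE_FRACTION = 0.25


@dataclasses.dataclass
class SceneSpec:
    """Parameters of one synthetic annotated potato image.

    Defaults describe the emulated inspection conditions; ranges are sampled
    uniformly per scene.
    """
    height: int = 128
    width: int = 128
    n_potatoes: tuple[int, int] = (1, 2)
    axis_fraction: tuple[float, float] = (0.22, 0.40)   # semi-axis / min(H,W)
    peel_color: tuple = ((0.42, 0.60), (0.28, 0.42), (0.14, 0.26))  # RGB bands
    n_damage: tuple[int, int] = (1, 3)
    damage_area_fraction: tuple[float, float] = (0.01, 0.06)  # of potato area
    damage_color: tuple = ((0.72, 0.90), (0.58, 0.76), (0.30, 0.50))
    background: tuple[float, float] = (0.03, 0.09)
    noise_sigma: float = 0.015

    def __post_init__(self):
        for lo, hi in (self.n_potatoes, self.axis_fraction, self.n_damage,
                       self.damage_area_fraction, self.background):
            if hi < lo:
                raise ValueError("spec ranges must be nonempty (hi >= lo)")
        if not 0 < self.damage_area_fraction[1] < 0.5:
            raise ValueError("damage area fraction must lie in (0, 0.5)")
        if self.axis_fraction[0] <= 0:
            raise ValueError("zero-area potatoes are not a valid spec")


@dataclasses.dataclass
class AnnotatedImage:
    """RGB float image in [0,1] (H,W,3) with per-patch boxes and classes.

    ``masks`` carries the generator's per-patch boolean masks when the image
    is freshly generated (None after augmentation or disk round-trips).
    """
    image: np.ndarray
    boxes: np.ndarray        # (N, 4) corner form, pixels
    classes: np.ndarray      # (N,) int
    split: str | None = None
    masks: list | None = None


def _smooth_noise(rng, h, w, scale, sigma):
    coarse = rng.normal(0, 1, (max(h // scale, 2), max(w // scale, 2)))
    up = ndimage.zoom(coarse, (h / coarse.shape[0], w / coarse.shape[1]), order=1)
    return ndimage.gaussian_filter(up[:h, :w], sigma)


def _ellipse_mask(h, w, cy, cx, ay, ax, angle):
    yy, xx = np.mgrid[0:h, 0:w]
    c, s = np.cos(angle), np.sin(angle)
    u = (xx - cx) * c + (yy - cy) * s
    v = -(xx - cx) * s + (yy - cy) * c
    return (u / ax) ** 2 + (v / ay) ** 2 <= 1.0


def generate_scene(spec: SceneSpec, seed: int) -> AnnotatedImage:
    """Render one annotated scene deterministically from (spec, seed)."""
    rng = np.random.default_rng(seed)
    h, w = spec.height, spec.width
    img = np.empty((h, w, 3))
    img[:] = rng.uniform(*spec.background)
    img += 0.01 * _smooth_noise(rng, h, w, 16, 2.0)[..., None]

    n_pot = int(rng.integers(spec.n_potatoes[0], spec.n_potatoes[1] + 1))
    boxes, classes, patch_masks = [], [], []
    potato_masks = []
    for _ in range(n_pot):
        ax = rng.uniform(*spec.axis_fraction) * min(h, w)
        ay = rng.uniform(*spec.axis_fraction) * min(h, w) * rng.uniform(0.7, 1.0)
        cx = rng.uniform(0.3 * w, 0.7 * w)
        cy = rng.uniform(0.3 * h, 0.7 * h)
        angle = rng.uniform(0, np.pi)
        mask = _ellipse_mask(h, w, cy, cx, ay, ax, angle)
        base = np.array([rng.uniform(*b) for b in spec.peel_color])
        texture = _smooth_noise(rng, h, w, 8, 1.5)
        shade = 1.0 + 0.18 * texture
        for c in range(3):
            img[..., c] = np.where(mask, base[c] * shade, img[..., c])
        potato_masks.append((mask, cx, cy, ax, ay, angle))

    for mask, cx, cy, ax, ay, angle in potato_masks:
        area = mask.sum()
        n_dmg = int(rng.integers(spec.n_damage[0], spec.n_damage[1] + 1))
        dmg_color = np.array([rng.uniform(*b) for b in spec.damage_color])
        for _ in range(n_dmg):
            frac = rng.uniform(*spec.damage_area_fraction)
            r = max(2.0, np.sqrt(frac * area / np.pi) * 1.3)
            # sample a patch center well inside the tuber
            for _ in range(50):
                t = rng.uniform(0, 2 * np.pi)
                rad = np.sqrt(rng.uniform(0, 0.55))
                px = cx + rad * ax * np.cos(t) * np.cos(angle) - rad * ay * np.sin(t) * np.sin(angle)
                py = cy + rad * ax * np.cos(t) * np.sin(angle) + rad * ay * np.sin(t) * np.cos(angle)
                if 1 <= px < w - 1 and 1 <= py < h - 1:
                    break
            yy, xx = np.mgrid[0:h, 0:w]
            disk = (xx - px) ** 2 + (yy - py) ** 2 <= r ** 2
            blob_noise = _smooth_noise(rng, h, w, 4, 1.0)
            patch = disk & (blob_noise > np.quantile(blob_noise[disk], 0.3) if disk.any() else disk)
            patch &= mask
            # keep the connected component containing the center
            lab, _ = ndimage.label(patch)
            cy_i, cx_i = int(round(py)), int(round(px))
            if patch.any():
                lbl = lab[cy_i, cx_i]
                if lbl == 0:
                    lbl = np.argmax(np.bincount(lab[patch]))
                patch = lab == lbl
            if patch.sum() < 6:
                continue
            edge = ndimage.gaussian_filter(patch.astype(float), 0.8)
            # broken skin is distinctly lighter than intact peel
            lighten = np.clip(0.9 + 0.25 * _smooth_noise(rng, h, w, 4, 1.0), 0.8, 1.15)
            for c in range(3):
                img[..., c] = np.where(patch, dmg_color[c] * lighten, img[..., c])
            img += 0.05 * edge[..., None] * (dmg_color - img) * 0.5
            rows = np.where(patch.any(axis=1))[0]
            cols = np.where(patch.any(axis=0))[0]
            boxes.append([cols[0], rows[0], cols[-1] + 1, rows[-1] + 1])
            classes.append(0)
            patch_masks.append(patch)

    img += rng.normal(0, spec.noise_sigma, img.shape)
    img = np.clip(img, 0, 1)
    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
    return AnnotatedImage(img, boxes, np.asarray(classes, dtype=int),
                          masks=patch_masks)


def _clip_boxes(boxes, classes, w, h, ref_areas):
    if len(boxes) == 0:
        return boxes.reshape(-1, 4), classes
    clipped = boxes.copy()
    clipped[:, [0, 2]] = clipped[:, [0, 2]].clip(0, w)
    clipped[:, [1, 3]] = clipped[:, [1, 3]].clip(0, h)
    vis = (clipped[:, 2] - clipped[:, 0]).clip(0) * (clipped[:, 3] - clipped[:, 1]).clip(0)
    keep = vis >= MIN_VISIBLE_FRACTION * ref_areas
    return clipped[keep], classes[keep]


def augment(img: AnnotatedImage, op: str, params: dict | None = None,
            seed: int = 0) -> AnnotatedImage:
    """Apply one augmentation with consistent image/box transforms."""
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    h, w = img.image.shape[:2]
    boxes, classes = img.boxes.copy(), img.classes.copy()
    areas = (boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1]) if len(boxes) else np.empty(0)

    if op == "hflip":
        out = img.image[:, ::-1].copy()
        if len(boxes):
            boxes = np.stack([w - boxes[:, 2], boxes[:, 1],
                              w - boxes[:, 0], boxes[:, 3]], axis=1)
    elif op == "translate":
        dx = int(params.get("dx", rng.integers(-w // 5, w // 5 + 1)))
        dy = int(params.get("dy", rng.integers(-h // 5, h // 5 + 1)))
        out = np.zeros_like(img.image)
        src = img.image[max(0, -dy):h - max(0, dy), max(0, -dx):w - max(0, dx)]
        out[max(0, dy):max(0, dy) + src.shape[0],
            max(0, dx):max(0, dx) + src.shape[1]] = src
        if len(boxes):
            boxes[:, [0, 2]] += dx
            boxes[:, [1, 3]] += dy
        boxes, classes = _clip_boxes(boxes, classes, w, h, areas)
    elif op == "rotate":
        angle = float(params.get("angle", rng.uniform(-30, 30)))
        out = ndimage.rotate(img.image, angle, axes=(1, 0), reshape=False,
                             order=1, mode="constant", cval=0.0)
        out = np.clip(out, 0, 1)
        if len(boxes):
            # image rotation by `angle` (axes=(1,0)) maps input coordinates
            # through the inverse rotation about the image center
            th = np.deg2rad(angle)
            c, s = np.cos(th), np.sin(th)
            ctr = np.array([w / 2 - 0.5, h / 2 - 0.5])
            corners = boxes[:, [0, 1, 2, 1, 2, 3, 0, 3]].reshape(-1, 4, 2) - ctr
            rot = corners @ np.array([[c, s], [-s, c]]).T + ctr
            boxes = np.concatenate([rot.min(axis=1), rot.max(axis=1)], axis=1)
            hull_areas = (boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1])
            boxes, classes = _clip_boxes(boxes, classes, w, h, hull_areas)
    elif op == "brightness_contrast":
        alpha = float(params.get("alpha", rng.uniform(0.8, 1.2)))
        beta = float(params.get("beta", rng.uniform(-0.08, 0.08)))
        out = np.clip(alpha * (img.image - 0.5) + 0.5 + beta, 0, 1)
    elif op == "scale":
        factor = float(params.get("factor", rng.uniform(0.8, 1.2)))
        zoomed = ndimage.zoom(img.image, (factor, factor, 1), order=1)
        out = np.zeros_like(img.image)
        zh, zw = zoomed.shape[:2]
        # paste the zoomed image centered on the canvas
        ty, tx = (h - zh) // 2, (w - zw) // 2
        sy, sx = max(0, -ty), max(0, -tx)
        dy, dx = max(0, ty), max(0, tx)
        ch = min(zh - sy, h - dy)
        cw = min(zw - sx, w - dx)
        out[dy:dy + ch, dx:dx + cw] = zoomed[sy:sy + ch, sx:sx + cw]
        if len(boxes):
            boxes = boxes * factor + np.array([tx, ty, tx, ty])
            boxes, classes = _clip_boxes(boxes, classes, w, h, areas * factor ** 2)
    else:
        raise ValueError(f"unknown augmentation {op!r}; choose from {AUGMENT_OPS}")

    return AnnotatedImage(out, boxes.reshape(-1, 4), classes, img.split)


def generate_dataset(n: int, spec: SceneSpec | None = None, seed: int = 0,
                     augment_per_image: int = 2) -> list[AnnotatedImage]:
    """n original scenes plus `augment_per_image` augmented copies of each.

    The default multiplicity of 2 grows the set threefold, approximating the
    601 -> 1864 growth of a flip/translate/rotate/photometric/scale policy.
    """
    spec = spec or SceneSpec()
    rng = np.random.default_rng(seed)
    scenes = []
    for i in range(n):
        scene = generate_scene(spec, int(rng.integers(0, 2 ** 31)))
        scenes.append(scene)
        ops = rng.choice(len(AUGMENT_OPS), size=augment_per_image, replace=False)
        for k in ops:
            scenes.append(augment(scene, AUGMENT_OPS[int(k)],
                                  seed=int(rng.integers(0, 2 ** 31))))
    return scenes


def _split_counts(n: int, ratios=(8, 1, 1)) -> list[int]:
    total = sum(ratios)
    raw = [n * r / total for r in ratios]
    counts = [int(np.floor(x)) for x in raw]
    # largest-remainder apportionment
    order = np.argsort([c - x for c, x in zip(counts, raw)])
    for i in range(n - sum(counts)):
        counts[order[i]] += 1
    return counts


def write_dataset(scenes, out_dir, split=(8, 1, 1), seed: int = 0) -> dict:
    """Write a YOLO-layout dataset with a deterministic 8:1:1 split."""
    if len(scenes) < 10:
        raise ValueError("need at least 10 scenes to split 8:1:1")
    out = pathlib.Path(out_dir)
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(scenes))
    counts = _split_counts(len(scenes), split)
    names = ["train", "val", "test"]
    assignment = {}
    start = 0
    for name, c in zip(names, counts):
        for i in idx[start:start + c]:
            assignment[int(i)] = name
        start += c

    for name in names:
        (out / "images" / name).mkdir(parents=True, exist_ok=True)
        (out / "labels" / name).mkdir(parents=True, exist_ok=True)
    for i, scene in enumerate(scenes):
        name = assignment[i]
        stem = f"img_{i:05d}"
        arr = (np.clip(scene.image, 0, 1) * 255).round().astype(np.uint8)
        Image.fromarray(arr).save(out / "images" / name / f"{stem}.png")
        h, w = scene.image.shape[:2]
        lines = []
        if len(scene.boxes):
            norm = corners_to_yolo(scene.boxes, w, h)
            for cls, b in zip(scene.classes, norm):
                lines.append(f"{int(cls)} " + " ".join(f"{v:.6f}" for v in b))
        # empty-annotation images still get an (empty) label file
        (out / "labels" / name / f"{stem}.txt").write_text(
            "\n".join(lines) + ("\n" if lines else ""))

    desc = {"path": str(out), "names": {0: "damage"},
            "train": "images/train", "val": "images/val", "test": "images/test",
            "counts": dict(zip(names, counts))}
    (out / "dataset.yaml").write_text(yaml.safe_dump(desc))
    return desc


def load_split(data_dir, split: str = "train") -> list[AnnotatedImage]:
    """Read a written split back into memory (boxes in pixel corner form)."""
    root = pathlib.Path(data_dir)
    scenes = []
    for img_path in sorted((root / "images" / split).glob("*.png")):
        arr = np.asarray(Image.open(img_path), dtype=np.float64) / 255.0
        h, w = arr.shape[:2]
        label = root / "labels" / split / (img_path.stem + ".txt")
        boxes, classes = [], []
        if label.exists():
            for line in label.read_text().splitlines():
                parts = line.split()
                if len(parts) == 5:
                    classes.append(int(parts[0]))
                    boxes.append([float(v) for v in parts[1:]])
        if boxes:
            boxes = yolo_to_corners(np.asarray(boxes), w, h)
        else:
            boxes = np.empty((0, 4))
        scenes.append(AnnotatedImage(arr, boxes, np.asarray(classes, dtype=int), split))
    return scenes
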