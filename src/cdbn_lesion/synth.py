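"""Synthetic 32x32 retinal-fundus patches for the three lesion classes.

The real patches this generator emulates come from fundus photographs:
warm orange-red background tissue with tonal variation, occasional dark
vessel segments, and two lesion types — hard exudates (bright yellowish
lipid deposits, clustered blobs with irregular boundaries) and
microhemorrhages (small dark-red roundish bleeding spots). Healthy patches
show only background texture and vessels.

The appearance models are deliberately stylized (Gaussian blobs with
radial wobble, smooth value-noise texture, straight vessel streaks): the
goal is reproducible statistical class structure for testing the learning
pipeline, not photorealism. Two difficulty presets order the task:
``separable`` has strong lesion contrast and mild jitter, ``realistic``
weakens contrast and widens the tonal/noise variation so the classes
overlap more.

Everything is seeded: a patch is a pure function of (class, config, seed),
and a dataset derives per-patch seeds from one master seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "CLASSES",
    "DEFAULT_COUNTS",
    "GeneratorConfig",
    "PatchDataset",
    "generate_patch",
    "generate_dataset",
    "load_dataset",
]

#: canonical class order used everywhere (confusion matrices, encodings)
CLASSES: tuple[str, str, str] = ("hard_exudate", "microhemorrhage", "healthy")

#: per-class patch counts of the reference cohort (hard exudates,
#: microhemorrhages, healthy)
DEFAULT_COUNTS: tuple[int, int, int] = (755, 718, 700)

PATCH_SIDE = 32


@dataclass(frozen=True)
class GeneratorConfig:
    """Class-conditional appearance parameters (8-bit intensity units)."""

    background_rgb: tuple[float, float, float] = (172.0, 96.0, 52.0)
    tonal_jitter: float = 2.5           # std of the global per-patch color shift
    texture_amplitude: float = 10.0     # std of the smooth background texture
    vessel_probability: float = 0.3     # chance a healthy patch shows a streak
    vessel_width: float = 2.0           # px
    vessel_depth: float = 45.0          # intensity drop along the streak
    exudate_blob_range: tuple[int, int] = (2, 3)
    exudate_radius: float = 9.0         # px, mean blob radius
    exudate_brightness: float = 130.0
    spot_count_range: tuple[int, int] = (4, 7)
    spot_radius: float = 5.5            # px
    spot_darkness: float = 180.0
    noise_level: float = 2.0            # std of i.i.d. pixel noise
    difficulty: str = "separable"

    def __post_init__(self) -> None:
        if not 0.0 <= self.vessel_probability <= 1.0:
            raise ValueError("vessel_probability must lie in [0, 1]")
        for name in ("vessel_width", "exudate_radius", "spot_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.difficulty not in ("separable", "realistic"):
            raise ValueError("difficulty must be 'separable' or 'realistic'")

    @classmethod
    def separable(cls) -> "GeneratorConfig":
        """Strong class contrast, mild jitter — the testing preset."""
        return cls()

    @classmethod
    def realistic(cls) -> "GeneratorConfig":
        """Weaker lesions, wider tonal variation, heavier noise."""
        return cls(
            tonal_jitter=22.0,
            texture_amplitude=12.0,
            vessel_probability=0.5,
            exudate_brightness=34.0,
            exudate_radius=3.5,
            exudate_blob_range=(1, 4),
            spot_darkness=35.0,
            spot_radius=2.2,
            spot_count_range=(1, 5),
            noise_level=9.0,
            difficulty="realistic",
        )

    @classmethod
    def preset(cls, name: str) -> "GeneratorConfig":
        if name == "separable":
            return cls.separable()
        if name == "realistic":
            return cls.realistic()
        raise ValueError(f"unknown difficulty preset {name!r}")


def _smooth_noise(rng: np.random.Generator, amplitude: float, coarse: int = 2) -> np.ndarray:
    """Low-frequency value noise: coarse Gaussian grid, bilinear upsample.

    The default 2x2 grid gives a ~16 px correlation length, so healthy
    background varies on a coarser scale than either lesion type.
    """
    grid = rng.normal(0.0, amplitude, size=(coarse, coarse))
    zoomed = ndimage.zoom(grid, PATCH_SIDE / coarse, order=1, mode="nearest")
    return zoomed[:PATCH_SIDE, :PATCH_SIDE]


def _radial_mask(
    rng: np.random.Generator, center: tuple[float, float], radius: float, wobble: float
) -> np.ndarray:
    """Soft blob mask in [0, 1] with an irregular (angle-modulated) boundary."""
    yy, xx = np.mgrid[0:PATCH_SIDE, 0:PATCH_SIDE].astype(np.float64)
    dy, dx = yy - center[0], xx - center[1]
    dist = np.hypot(dy, dx)
    angle = np.arctan2(dy, dx)
    # low-order Fourier wobble of the radius makes the boundary irregular
    a1, b1, a2, b2 = rng.normal(0.0, wobble, size=4)
    r_eff = radius * (1.0 + a1 * np.cos(angle) + b1 * np.sin(angle)
                      + a2 * np.cos(2 * angle) + b2 * np.sin(2 * angle))
    r_eff = np.clip(r_eff, 0.5, None)
    return np.exp(-0.5 * (dist / r_eff) ** 2)


def _vessel_mask(rng: np.random.Generator, width: float) -> np.ndarray:
    """Soft mask of a straight vessel streak crossing the patch."""
    theta = rng.uniform(0.0, np.pi)
    # signed distance from a line through a random interior point
    cy, cx = rng.uniform(8, 24, size=2)
    yy, xx = np.mgrid[0:PATCH_SIDE, 0:PATCH_SIDE].astype(np.float64)
    dist = np.abs(-(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta))
    return np.exp(-0.5 * (dist / (width / 2.0)) ** 2)


def generate_patch(cls: str, cfg: GeneratorConfig, seed: int) -> np.ndarray:
    """Render one 32x32x3 8-bit patch for the given class.

    The same (cls, cfg, seed) triple always yields identical bytes.
    """
    if cls not in CLASSES:
        raise ValueError(f"unknown class {cls!r}; expected one of {CLASSES}")
    rng = np.random.default_rng(seed)

    img = np.empty((PATCH_SIDE, PATCH_SIDE, 3), dtype=np.float64)
    shift = rng.normal(0.0, cfg.tonal_jitter, size=3)
    texture = _smooth_noise(rng, cfg.texture_amplitude)
    chan_gain = (1.0, 0.8, 0.6)  # texture follows overall pigmentation
    for c in range(3):
        img[:, :, c] = cfg.background_rgb[c] + shift[c] + chan_gain[c] * texture

    if cls == "healthy":
        # healthy tissue: background texture, often crossed by a vessel
        if rng.random() < cfg.vessel_probability:
            vm = _vessel_mask(rng, cfg.vessel_width)
            img[:, :, 0] -= 0.7 * cfg.vessel_depth * vm
            img[:, :, 1] -= 1.0 * cfg.vessel_depth * vm
            img[:, :, 2] -= 0.6 * cfg.vessel_depth * vm
    elif cls == "hard_exudate":
        lo, hi = cfg.exudate_blob_range
        n_blobs = int(rng.integers(lo, hi + 1))
        cluster = rng.uniform(8, 24, size=2)  # blobs cluster around one site
        for _ in range(n_blobs):
            center = cluster + rng.normal(0.0, 3.5, size=2)
            radius = cfg.exudate_radius * rng.uniform(0.6, 1.4)
            mask = _radial_mask(rng, tuple(center), radius, wobble=0.18)
            amp = cfg.exudate_brightness * rng.uniform(0.8, 1.2)
            img[:, :, 0] += amp * mask          # bright yellowish: R and G up
            img[:, :, 1] += 0.9 * amp * mask
            img[:, :, 2] += 0.25 * amp * mask
    elif cls == "microhemorrhage":
        lo, hi = cfg.spot_count_range
        n_spots = int(rng.integers(lo, hi + 1))
        for _ in range(n_spots):
            center = tuple(rng.uniform(4, 28, size=2))
            radius = cfg.spot_radius * rng.uniform(0.7, 1.3)
            mask = _radial_mask(rng, center, radius, wobble=0.10)
            amp = cfg.spot_darkness * rng.uniform(0.8, 1.2)
            img[:, :, 0] -= 0.55 * amp * mask   # dark red: everything down,
            img[:, :, 1] -= 1.0 * amp * mask    # green most, red least
            img[:, :, 2] -= 0.7 * amp * mask

    if cfg.noise_level > 0:
        img += rng.normal(0.0, cfg.noise_level, size=img.shape)

    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


@dataclass
class PatchDataset:
    """Labeled patches plus per-patch generation provenance."""

    patches: np.ndarray                 # (N, 32, 32, 3) uint8
    labels: list[str]
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.patches.ndim != 4 or self.patches.shape[1:] != (PATCH_SIDE, PATCH_SIDE, 3):
            raise ValueError(f"patches must be (N, 32, 32, 3), got {self.patches.shape}")
        if len(self.labels) != self.patches.shape[0]:
            raise ValueError("one label per patch required")
        bad = set(self.labels) - set(CLASSES)
        if bad:
            raise ValueError(f"unknown labels {bad}")

    def __len__(self) -> int:
        return self.patches.shape[0]

    def class_counts(self) -> dict[str, int]:
        return {c: self.labels.count(c) for c in CLASSES}

    def subsample(self, max_patches: int, seed: int = 0) -> "PatchDataset":
        """Class-stratified subsample of at most ``max_patches`` patches."""
        if len(self) <= max_patches:
            return self
        rng = np.random.default_rng(seed)
        labels = np.asarray(self.labels)
        keep: list[int] = []
        per_class = max_patches // len(CLASSES)
        for c in CLASSES:
            idx = np.flatnonzero(labels == c)
            take = min(per_class, idx.size)
            keep.extend(rng.choice(idx, size=take, replace=False))
        keep = sorted(keep)
        return PatchDataset(
            patches=self.patches[keep],
            labels=[self.labels[i] for i in keep],
            provenance=[self.provenance[i] for i in keep] if self.provenance else [],
        )


def generate_dataset(
    cfg: GeneratorConfig,
    counts: tuple[int, int, int] = DEFAULT_COUNTS,
    master_seed: int = 0,
    out_dir: str | Path | None = None,
) -> PatchDataset:
    """Generate a full labeled dataset; optionally write PNGs + manifest.

    Per-patch seeds are derived from ``master_seed`` through numpy's
    SeedSequence, so the whole dataset is a pure function of the master
    seed. With ``out_dir`` set, 8-bit PNGs and a ``manifest.csv`` with
    columns ``filename,label,seed`` are written there.
    """
    if any(c < 1 for c in counts):
        raise ValueError("all class counts must be positive")
    total = int(sum(counts))
    seeds = np.random.SeedSequence(master_seed).generate_state(total) & 0x7FFFFFFF

    patches = np.empty((total, PATCH_SIDE, PATCH_SIDE, 3), dtype=np.uint8)
    labels: list[str] = []
    provenance: list[dict] = []
    i = 0
    for cls, count in zip(CLASSES, counts):
        for _ in range(count):
            seed = int(seeds[i])
            patches[i] = generate_patch(cls, cfg, seed)
            labels.append(cls)
            provenance.append({"class": cls, "seed": seed, "difficulty": cfg.difficulty})
            i += 1
    ds = PatchDataset(patches=patches, labels=labels, provenance=provenance)
    if out_dir is not None:
        _write_dataset(ds, Path(out_dir))
    return ds


def _write_dataset(ds: PatchDataset, out_dir: Path) -> None:
    from PIL import Image

    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(len(ds)):
        name = f"patch_{i:05d}.png"
        Image.fromarray(ds.patches[i]).save(out_dir / name)
        rows.append((name, ds.labels[i], ds.provenance[i]["seed"] if ds.provenance else ""))
    with open(out_dir / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "label", "seed"])
        writer.writerows(rows)


def load_dataset(data_dir: str | Path, manifest: str | Path | None = None) -> PatchDataset:
    """Read a PNG directory back through its CSV manifest."""
    from PIL import Image

    data_dir = Path(data_dir)
    manifest = Path(manifest) if manifest is not None else data_dir / "manifest.csv"
    patches, labels, prov = [], [], []
    with open(manifest, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "filename" not in reader.fieldnames or "label" not in reader.fieldnames:
            raise ValueError(f"manifest {manifest} must have columns filename,label[,seed]")
        for row in reader:
            arr = np.asarray(Image.open(data_dir / row["filename"]).convert("RGB"))
            patches.append(arr)
            labels.append(row["label"])
            prov.append({"class": row["label"], "seed": row.get("seed", "")})
    if not patches:
        raise ValueError(f"manifest {manifest} lists no patches")
    return PatchDataset(patches=np.stack(patches), labels=labels, provenance=prov)
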