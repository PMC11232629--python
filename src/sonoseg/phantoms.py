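"""Seeded ultrasound-like speckle phantoms with paired nerve masks.

Each phantom emulates the statistical structure of clinical B-mode nerve
scans rather than their physics: a dark background crossed by a few
smooth hyperechoic tissue bands, at most one hypoechoic target (the
"nerve") with a brighter rim and a deliberately ambiguous boundary, all
multiplied by fully developed speckle — the squared magnitude of a
spatially smoothed complex Gaussian field, i.e. Rayleigh-type intensity
with the characteristic positive skew.  Pixel values are normalised to
[0, 1]; the ground-truth mask is the exact pre-blur target support.

Generation is content-addressed: sample ``index`` under a ``PhantomSpec``
is a pure function of ``(spec.seed, index)``, so datasets are enumerable
lazily and reproducible bit-for-bit.

File dialect: 8-bit grayscale PNG (TIFF also readable), masks as
single-channel PNG with values {0, 255}, paired by filename stem with a
``_mask`` suffix.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage


class PhantomError(ValueError):
    pass


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters for one family of phantoms.

    ``target_probability`` is the chance a frame contains a nerve at all;
    the benchmark this emulates also contains nerve-absent frames.
    """

    image_size: tuple[int, int] = (128, 128)
    target_probability: float = 0.8
    target_axes: tuple[float, float] = (10.0, 22.0)   # semi-axis range, px
    boundary_blur: float = 1.5                        # Gaussian sigma, px
    speckle_scale: float = 0.6                        # 0 = none, 1 = full
    speckle_corr: float = 1.2                         # field smoothing, px
    band_count: int = 3
    seed: int = 0

    def __post_init__(self):
        h, w = self.image_size
        if h < 32 or w < 32:
            raise PhantomError("image size must be at least 32x32")
        lo, hi = self.target_axes
        if not (0 < lo <= hi):
            raise PhantomError("target axes range must be positive and ordered")
        if hi >= min(h, w) / 2:
            raise PhantomError("target axes must be smaller than min(H, W)/2")
        if self.boundary_blur < 0:
            raise PhantomError("boundary blur sigma must be >= 0")
        if not 0 <= self.target_probability <= 1:
            raise PhantomError("target probability must lie in [0, 1]")
        if not 0 <= self.speckle_scale <= 1:
            raise PhantomError("speckle scale must lie in [0, 1]")
        if self.band_count < 0:
            raise PhantomError("band count must be >= 0")


@dataclass
class PhantomSample:
    image: np.ndarray          # float32 in [0, 1], shape (H, W)
    mask: np.ndarray           # uint8 in {0, 1}, shape (H, W)
    provenance: dict

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise PhantomError("image and mask shapes differ")


@dataclass(frozen=True)
class DatasetSplit:
    train: tuple[int, ...]
    validation: tuple[int, ...]
    test: tuple[int, ...]

    def __post_init__(self):
        parts = (set(self.train), set(self.validation), set(self.test))
        total = len(self.train) + len(self.validation) + len(self.test)
        if len(parts[0] | parts[1] | parts[2]) != total:
            raise PhantomError("split partitions overlap")


def _speckle(rng: np.random.Generator, shape, corr: float) -> np.ndarray:
    """Unit-mean Rayleigh-type intensity: |smoothed complex Gaussian|^2."""
    re = ndimage.gaussian_filter(rng.standard_normal(shape), corr)
    im = ndimage.gaussian_filter(rng.standard_normal(shape), corr)
    intensity = re * re + im * im
    return intensity / intensity.mean()


def generate_phantom(spec: PhantomSpec, index: int) -> PhantomSample:
    """Render phantom ``index`` of the family described by ``spec``."""
    if index < 0:
        raise PhantomError("sample index must be non-negative")
    h, w = spec.image_size
    rng = np.random.default_rng([spec.seed, int(index)])

    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)

    # background: dark base plus smooth hyperechoic tissue bands whose
    # centreline undulates slowly across the image
    image = np.full((h, w), 0.18)
    for _ in range(spec.band_count):
        y0 = rng.uniform(0.1 * h, 0.9 * h)
        thickness = rng.uniform(0.04 * h, 0.12 * h)
        amp = rng.uniform(0.15, 0.4)
        wobble = rng.uniform(0.02 * h, 0.08 * h)
        phase = rng.uniform(0, 2 * np.pi)
        centre = y0 + wobble * np.sin(2 * np.pi * xx / w + phase)
        image += amp * np.exp(-0.5 * ((yy - centre) / thickness) ** 2)

    # optional hypoechoic target: rotated ellipse with a low-order radial
    # perturbation of the boundary, darkened interior, brighter rim
    mask = np.zeros((h, w), dtype=np.uint8)
    geometry: dict = {"present": False}
    if rng.uniform() < spec.target_probability:
        lo, hi = spec.target_axes
        a, b = rng.uniform(lo, hi, size=2)
        margin = hi + 4
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        theta = rng.uniform(0, np.pi)
        n_harm = rng.integers(2, 5)
        amps = rng.uniform(0.0, 0.12, size=n_harm)
        phases = rng.uniform(0, 2 * np.pi, size=n_harm)

        dy, dx = yy - cy, xx - cx
        u = np.cos(theta) * dx + np.sin(theta) * dy
        v = -np.sin(theta) * dx + np.cos(theta) * dy
        radius = np.sqrt((u / a) ** 2 + (v / b) ** 2)
        ang = np.arctan2(v / b, u / a)
        boundary = 1.0 + sum(amp * np.cos(k * ang + ph)
                             for k, (amp, ph) in
                             enumerate(zip(amps, phases), start=2))
        mask = (radius <= boundary).astype(np.uint8)

        rim = ndimage.binary_dilation(mask, iterations=2) & ~mask.astype(bool)
        image = np.where(mask, image * 0.35 + 0.02, image)
        image = np.where(rim, image + 0.25, image)
        geometry = {"present": True, "centre": (cy, cx), "axes": (a, b),
                    "theta": theta}

    # multiplicative speckle, boundary blur, clip to [0, 1]
    if spec.speckle_scale > 0:
        s = _speckle(rng, (h, w), spec.speckle_corr)
        image = image * ((1.0 - spec.speckle_scale) + spec.speckle_scale * s)
    if spec.boundary_blur > 0:
        image = ndimage.gaussian_filter(image, spec.boundary_blur)
    image = np.clip(image, 0.0, 1.0).astype(np.float32)

    provenance = {"seed": spec.seed, "index": int(index), "geometry": geometry,
                  "spec": dataclasses.asdict(spec)}
    return PhantomSample(image=image, mask=mask, provenance=provenance)


def make_dataset(spec: PhantomSpec, n: int) -> list[PhantomSample]:
    """Materialise samples 0..n-1 (use :func:`iter_dataset` for lazy access)."""
    return list(iter_dataset(spec, n))


def iter_dataset(spec: PhantomSpec, n: int):
    if n < 1:
        raise PhantomError("dataset size must be >= 1")
    for index in range(n):
        yield generate_phantom(spec, index)


def split_dataset(n: int, test_fraction: float, seed: int,
                  val_fraction: float | None = None) -> DatasetSplit:
    """Random disjoint partition of indices 0..n-1.

    ``floor(n * test_fraction)`` indices go to the test set.  With
    ``val_fraction=None`` the remainder is assigned to validation (the
    benchmark's published two-way accounting); otherwise
    ``floor(n * val_fraction)`` go to validation and the rest to train.
    """
    if not 0 < test_fraction < 1:
        raise PhantomError("test fraction must lie strictly in (0, 1)")
    if val_fraction is not None and not 0 <= val_fraction < 1:
        raise PhantomError("validation fraction must lie in [0, 1)")
    perm = np.random.default_rng(seed).permutation(n)
    n_test = int(np.floor(n * test_fraction))
    test = tuple(int(i) for i in perm[:n_test])
    rest = perm[n_test:]
    if val_fraction is None:
        return DatasetSplit(train=(), validation=tuple(int(i) for i in rest),
                            test=test)
    n_val = int(np.floor(n * val_fraction))
    if n_test + n_val > n:
        raise PhantomError("test and validation fractions exceed the dataset")
    val = tuple(int(i) for i in rest[:n_val])
    train = tuple(int(i) for i in rest[n_val:])
    return DatasetSplit(train=train, validation=val, test=test)


# ---------------------------------------------------------------------------
# image / mask file I/O
# ---------------------------------------------------------------------------


def write_sample(path: str | Path, sample: PhantomSample) -> tuple[Path, Path]:
    """Write ``<stem>.png`` (8-bit image) and ``<stem>_mask.png`` ({0, 255})."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img_path = path.with_suffix(".png")
    mask_path = path.with_name(path.stem + "_mask.png")
    iio.imwrite(img_path, np.round(sample.image * 255).astype(np.uint8))
    iio.imwrite(mask_path, (sample.mask * 255).astype(np.uint8))
    return img_path, mask_path


def _read_gray(path: Path) -> np.ndarray:
    if not path.exists():
        raise FileNotFoundError(f"missing file: {path}")
    arr = iio.imread(path)
    if arr.ndim == 3:
        if not (arr == arr[..., :1]).all():
            raise PhantomError(f"{path}: expected a grayscale image")
        arr = arr[..., 0]
    if arr.ndim != 2:
        raise PhantomError(f"{path}: expected a 2-D grayscale image")
    return arr


def read_sample(path: str | Path) -> PhantomSample:
    """Read an image/mask pair written by :func:`write_sample`."""
    path = Path(path)
    img_path = path if path.suffix else path.with_suffix(".png")
    mask_path = img_path.with_name(img_path.stem + "_mask.png")
    image = _read_gray(img_path).astype(np.float32) / 255.0
    raw_mask = _read_gray(mask_path)
    values = np.unique(raw_mask)
    if not np.isin(values, (0, 255)).all():
        raise PhantomError(
            f"{mask_path}: mask values must be exactly {{0, 255}}, "
            f"found {values.tolist()}")
    mask = (raw_mask // 255).astype(np.uint8)
    if image.shape != mask.shape:
        raise PhantomError(
            f"{img_path} / {mask_path}: image {image.shape} and mask "
            f"{mask.shape} sizes differ")
    return PhantomSample(image=image, mask=mask,
                         provenance={"path": str(img_path)})


def load_directory(directory: str | Path) -> list[PhantomSample]:
    """Load every image/mask pair in a directory, pairing by stem name."""
    directory = Path(directory)
    images, masks = {}, {}
    for f in sorted(directory.iterdir()):
        if f.suffix.lower() not in (".png", ".tif", ".tiff"):
            continue
        if f.stem.endswith("_mask"):
            masks[f.stem[:-5]] = f
        else:
            images[f.stem] = f
    unpaired = sorted(set(images) ^ set(masks))
    if unpaired:
        raise PhantomError(
            f"{directory}: unpaired image/mask stems: {unpaired}")
    if not images:
        raise PhantomError(f"{directory}: no image/mask pairs found")
    return [read_sample(images[stem]) for stem in sorted(images)]
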