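"""Synthetic ultrasound nodule phantoms.

Each image carries one hypoechoic (darker-than-background) nodule on a
speckled background.  The nodule boundary is an ellipse modulated by a small
set of radial harmonics:

    r(theta) = r_ellipse(theta; a, b, rot) * (1 + sum_k a_k cos(k*theta + phi_k))

Benign-like nodules draw small total harmonic amplitude (smooth, regular
boundary); malignant-like nodules draw large amplitude over higher harmonics
(irregular, lobulated boundary).  The two amplitude ranges are disjoint by
construction, so the classes are separable by boundary shape alone — which
is exactly the property the downstream saliency/shape analysis probes.

Speckle is emulated as a smoothed, exponentiated Gaussian field applied
multiplicatively; it is a visual stand-in for ultrasound texture, not an
acoustic simulation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

BENIGN = "benign"
MALIGNANT = "malignant"

#: Default per-class boundary-perturbation ranges: (harmonics, amp_lo, amp_hi).
#: Benign boundaries are near-elliptical; malignant ones carry strong
#: higher-harmonic lobulation.  The ranges are disjoint so that the total
#: amplitude separates the classes by construction.
BENIGN_HARMONICS = ((2, 3), 0.0, 0.05)
MALIGNANT_HARMONICS = ((3, 4, 5, 6, 7, 8), 0.15, 0.35)


@dataclass(frozen=True)
class NoduleSpec:
    """Parametric description of one nodule: perturbed-ellipse boundary."""

    center: tuple[float, float]  # (row, col), pixels
    semi_axes: tuple[float, float]  # (a, b), pixels
    rotation: float  # radians
    perturb_harmonics: tuple[int, ...] = ()
    perturb_amplitudes: tuple[float, ...] = ()
    perturb_phases: tuple[float, ...] = ()
    contrast: float = 0.6  # in (0, 1]: how much darker the nodule is
    label: str = BENIGN

    def __post_init__(self):
        a, b = self.semi_axes
        if a <= 0 or b <= 0:
            raise ValueError("semi_axes must be strictly positive")
        if not (0.0 < self.contrast <= 1.0):
            raise ValueError("contrast must lie in (0, 1]")
        if len(self.perturb_harmonics) != len(self.perturb_amplitudes) or len(
            self.perturb_amplitudes
        ) != len(self.perturb_phases):
            raise ValueError("harmonics, amplitudes and phases must align")
        if self.total_amplitude >= 1.0:
            raise ValueError("total perturbation amplitude must be < 1 (radius would vanish)")
        if self.label not in (BENIGN, MALIGNANT):
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def total_amplitude(self) -> float:
        return float(sum(abs(a) for a in self.perturb_amplitudes))

    @property
    def max_radius(self) -> float:
        """Upper bound on the boundary radius over all angles."""
        return max(self.semi_axes) * (1.0 + self.total_amplitude)

    def fits_in(self, shape: tuple[int, int], margin: float = 1.0) -> bool:
        r, c = self.center
        h, w = shape
        m = self.max_radius + margin
        return r - m >= 0 and c - m >= 0 and r + m < h and c + m < w


@dataclass
class LabeledImage:
    """One rendered phantom: pixels in [0,1], label, ground-truth mask."""

    pixels: np.ndarray
    label: str
    truth_mask: np.ndarray | None = None
    seed: int | None = None
    spec: NoduleSpec | None = None


@dataclass
class DatasetManifest:
    records: list[tuple[str, str, int]] = field(default_factory=list)  # (path, label, seed)

    @property
    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, label, _ in self.records:
            counts[label] = counts.get(label, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["path", "label", "seed"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DatasetManifest":
        return cls(records=[(str(p), str(l), int(s)) for p, l, s in zip(df["path"], df["label"], df["seed"])])


def ellipse_radius(theta, a: float, b: float, rotation: float = 0.0):
    """Polar radius of an ellipse with semi-axes a (along rotation) and b."""
    t = np.asarray(theta, dtype=float) - rotation
    return (a * b) / np.sqrt((b * np.cos(t)) ** 2 + (a * np.sin(t)) ** 2)


def boundary_radius(spec: NoduleSpec, theta):
    """Boundary radius r(theta) of the perturbed ellipse, strictly positive."""
    a, b = spec.semi_axes
    r = ellipse_radius(theta, a, b, spec.rotation)
    t = np.asarray(theta, dtype=float)
    mod = np.ones_like(t)
    for k, amp, phi in zip(spec.perturb_harmonics, spec.perturb_amplitudes, spec.perturb_phases):
        mod = mod + amp * np.cos(k * t + phi)
    out = r * mod
    if np.any(out <= 0):
        raise ValueError("perturbation amplitudes drive the boundary radius non-positive")
    return out


def rasterize_mask(spec: NoduleSpec, shape: tuple[int, int]) -> np.ndarray:
    """Binary mask of the nodule: pixel inside iff its polar radius about the
    center is below the boundary radius at its angle."""
    if not spec.fits_in(shape):
        raise ValueError("nodule does not fit inside the image bounds")
    rows = np.arange(shape[0])[:, None] - spec.center[0]
    cols = np.arange(shape[1])[None, :] - spec.center[1]
    rho = np.hypot(rows, cols)
    theta = np.arctan2(rows, cols) % (2 * np.pi)
    mask = rho < boundary_radius(spec, theta)
    # keep only the component containing the center (extreme perturbations
    # could in principle pinch off satellites)
    lab, n = ndimage.label(mask)  # 4-connected by default
    if n > 1:
        centre_lab = lab[int(round(spec.center[0])), int(round(spec.center[1]))]
        mask = lab == centre_lab
    return mask


def render_speckle(
    mask: np.ndarray,
    spec: NoduleSpec,
    rng_seed: int,
    background_level: float = 0.55,
    noise_sigma: float = 0.25,
    smooth_px: float = 1.5,
    edge_soft_px: float = 1.0,
) -> LabeledImage:
    """Render the phantom: multiplicative speckle background, nodule interior
    darkened by ``spec.contrast``, clipped to [0, 1].  Deterministic in
    ``rng_seed``."""
    rng = np.random.default_rng(rng_seed)
    shape = mask.shape
    if noise_sigma > 0:
        g = rng.normal(0.0, noise_sigma, size=shape)
        g = ndimage.gaussian_filter(g, smooth_px)
        # re-standardize after smoothing so noise_sigma keeps its meaning
        std = g.std()
        if std > 0:
            g = g * (noise_sigma / std)
        speckle = np.exp(g - 0.5 * noise_sigma**2)
    else:
        speckle = np.ones(shape)
    img = background_level * speckle
    # soften the nodule edge by ~1 px so it is not a hard analytic contour
    soft = ndimage.gaussian_filter(mask.astype(float), edge_soft_px) if edge_soft_px else mask.astype(float)
    img = img * (1.0 - spec.contrast * soft)
    img = np.clip(img, 0.0, 1.0)
    return LabeledImage(pixels=img, label=spec.label, truth_mask=mask.astype(bool), seed=rng_seed, spec=spec)


def _draw_spec(rng: np.random.Generator, label: str, shape: tuple[int, int],
               harmonics_cfg=None, radius_frac=(0.18, 0.28), contrast=(0.45, 0.75),
               center_jitter: float = 0.06) -> NoduleSpec:
    # Placement emulates the clinical convention of ROI crops: the nodule
    # sits near the image center (± a small jitter) and occupies a large
    # fraction of the frame.
    harmonics, lo, hi = harmonics_cfg or (BENIGN_HARMONICS if label == BENIGN else MALIGNANT_HARMONICS)
    side = min(shape)
    for _ in range(100):
        mean_r = rng.uniform(*radius_frac) * side
        ecc = rng.uniform(1.0, 1.5)
        a, b = mean_r * ecc, mean_r / ecc
        total = rng.uniform(lo, hi)
        ks = list(harmonics)
        weights = rng.dirichlet(np.ones(len(ks)))
        amps = tuple(float(total * w) for w in weights)
        phases = tuple(float(rng.uniform(0, 2 * np.pi)) for _ in ks)
        max_r = max(a, b) * (1.0 + total) + 2.0
        margin = 4.0
        if 2 * max_r + 2 * margin >= side:
            continue
        jr = center_jitter * side
        cr = shape[0] / 2 + rng.uniform(-jr, jr)
        cc = shape[1] / 2 + rng.uniform(-jr, jr)
        cr = float(np.clip(cr, max_r + margin, shape[0] - max_r - margin))
        cc = float(np.clip(cc, max_r + margin, shape[1] - max_r - margin))
        spec = NoduleSpec(
            center=(float(cr), float(cc)),
            semi_axes=(float(a), float(b)),
            rotation=float(rng.uniform(0, np.pi)),
            perturb_harmonics=tuple(ks),
            perturb_amplitudes=amps,
            perturb_phases=phases,
            contrast=float(rng.uniform(*contrast)),
            label=label,
        )
        if spec.fits_in(shape):
            return spec
    raise RuntimeError("could not place a nodule inside the image bounds")


def generate_dataset(
    n_benign: int = 415,
    n_malignant: int = 93,
    image_shape: tuple[int, int] = (224, 224),
    master_seed: int = 0,
    benign_harmonics=BENIGN_HARMONICS,
    malignant_harmonics=MALIGNANT_HARMONICS,
) -> tuple[list[LabeledImage], DatasetManifest]:
    """Generate a labelled phantom dataset, deterministic in ``master_seed``.

    Default counts (415 benign / 93 malignant) mirror a clinically typical
    ~4.46:1 benign:malignant imbalance.
    """
    if n_benign < 0 or n_malignant < 0:
        raise ValueError("counts must be non-negative")
    images: list[LabeledImage] = []
    manifest = DatasetManifest()
    labels = [BENIGN] * n_benign + [MALIGNANT] * n_malignant
    for i, label in enumerate(labels):
        seed = (master_seed * 100003 + i * 7919 + 13) % (2**31 - 1)
        rng = np.random.default_rng(seed)
        cfg = benign_harmonics if label == BENIGN else malignant_harmonics
        spec = _draw_spec(rng, label, image_shape, harmonics_cfg=cfg)
        mask = rasterize_mask(spec, image_shape)
        img = render_speckle(mask, spec, rng_seed=seed)
        images.append(img)
        manifest.records.append((f"img_{i:05d}_{label}.png", label, seed))
    return images, manifest


def write_dataset(images: list[LabeledImage], manifest: DatasetManifest, outdir: str | Path,
                  params: dict | None = None) -> Path:
    """Write 8-bit grayscale PNGs + CSV manifest (+ JSON parameter sidecar)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for img, (path, _, _) in zip(images, manifest.records):
        arr = np.clip(np.round(img.pixels * 255), 0, 255).astype(np.uint8)
        iio.imwrite(outdir / path, arr)
        if img.truth_mask is not None:
            iio.imwrite(outdir / (Path(path).stem + "_mask.png"),
                        (img.truth_mask.astype(np.uint8) * 255))
    manifest.to_frame().to_csv(outdir / "manifest.csv", index=False)
    sidecar = {"n_images": len(images), "class_counts": manifest.class_counts}
    if params:
        sidecar.update(params)
    (outdir / "generation_params.json").write_text(json.dumps(sidecar, indent=2))
    return outdir / "manifest.csv"


def read_dataset(manifest_csv: str | Path) -> tuple[list[LabeledImage], DatasetManifest]:
    """Load a dataset previously written by :func:`write_dataset`."""
    manifest_csv = Path(manifest_csv)
    df = pd.read_csv(manifest_csv)
    manifest = DatasetManifest.from_frame(df)
    root = manifest_csv.parent
    images = []
    for path, label, seed in manifest.records:
        arr = iio.imread(root / path).astype(float) / 255.0
        mask_path = root / (Path(path).stem + "_mask.png")
        mask = iio.imread(mask_path) > 127 if mask_path.exists() else None
        images.append(LabeledImage(pixels=arr, label=label, truth_mask=mask, seed=int(seed)))
    return images, manifest


def spec_to_dict(spec: NoduleSpec) -> dict:
    return asdict(spec)
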