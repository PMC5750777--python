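"""Synthetic segmented-cell images and planted feature tables.

The image generator emulates the qualitative morphology of the seven
Pap-smear cell classes: along the normal → carcinoma axis the nucleus
grows, darkens and becomes more irregular, the cytoplasm shrinks and the
texture coarsens, so the nucleus/cytoplasm ratio rises monotonically with
disease grade. Cells are an ellipse-with-perturbed-boundary nucleus inside
a larger cytoplasm blob on a bright background, with Gaussian texture
noise; masks use the canonical 0/1/2 encoding.

The feature-table generator plants class-informative Gaussian columns
among pure-noise columns and returns the ground-truth informative index
set — the oracle fixture for wrapper feature selection.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cells import SegmentedCell, save_cell

#: The seven cell classes, ordered along the normal → carcinoma axis.
CLASS_NAMES = [
    "superficial_squamous",
    "intermediate_squamous",
    "columnar",
    "mild_dysplasia",
    "moderate_dysplasia",
    "severe_dysplasia",
    "carcinoma_in_situ",
]

#: Per-class cell counts matching the Herlev distribution (total 917).
HERLEV_COUNTS = {
    "superficial_squamous": 74,
    "intermediate_squamous": 70,
    "columnar": 98,
    "mild_dysplasia": 150,
    "moderate_dysplasia": 182,
    "severe_dysplasia": 146,
    "carcinoma_in_situ": 197,
}


@dataclasses.dataclass(frozen=True)
class CellClassSpec:
    """Generation parameters of one cell class.

    Radii are in pixels, brightness in 0–255 intensity units. The
    ``irregularity`` amplitude perturbs the nucleus boundary radius
    (fraction of the base radius); ``texture_sd`` is the intensity noise
    standard deviation, ``grain`` its correlation length in pixels.
    """
    name: str
    nucleus_radius: tuple[float, float]
    cytoplasm_radius: tuple[float, float]
    nucleus_brightness: float
    cytoplasm_brightness: float
    noise_sd: float
    irregularity: float
    grain: float

    def __post_init__(self) -> None:
        if self.nucleus_radius[1] >= self.cytoplasm_radius[0]:
            raise ValueError("nucleus radius range must sit below cytoplasm radius range")
        for b in (self.nucleus_brightness, self.cytoplasm_brightness):
            if not 0 <= b <= 255:
                raise ValueError("brightness must lie in [0, 255]")


#: Defaults reproducing the qualitative class ordering: nucleus size, N/C
#: ratio, darkness and texture coarseness all increase with grade.
DEFAULT_CLASS_SPECS = {
    "superficial_squamous":  CellClassSpec("superficial_squamous",  (4.0, 5.5),   (30.0, 34.0), 190.0, 185.0, 5.0, 0.04, 1.0),
    "intermediate_squamous": CellClassSpec("intermediate_squamous", (5.5, 7.0),   (29.0, 33.0), 175.0, 180.0, 6.0, 0.05, 1.2),
    "columnar":              CellClassSpec("columnar",              (7.0, 9.0),   (26.0, 30.0), 160.0, 172.0, 8.0, 0.07, 1.4),
    "mild_dysplasia":        CellClassSpec("mild_dysplasia",        (9.5, 12.0),  (25.0, 29.0), 145.0, 165.0, 10.0, 0.10, 1.7),
    "moderate_dysplasia":    CellClassSpec("moderate_dysplasia",    (12.0, 14.5), (24.0, 28.0), 128.0, 158.0, 12.0, 0.13, 2.0),
    "severe_dysplasia":      CellClassSpec("severe_dysplasia",      (14.5, 17.0), (22.0, 26.0), 110.0, 148.0, 15.0, 0.17, 2.3),
    "carcinoma_in_situ":     CellClassSpec("carcinoma_in_situ",     (17.0, 19.5), (21.0, 25.0), 92.0, 140.0, 18.0, 0.21, 2.6),
}

BACKGROUND_BRIGHTNESS = 228.0


def _blob_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    radius: float,
    irregularity: float,
    rng: np.random.Generator,
    aspect: float = 1.0,
) -> np.ndarray:
    """Filled ellipse-ish blob with a low-order harmonic boundary perturbation."""
    rr, cc = np.indices(shape)
    dy = (rr - center[0]) * aspect
    dx = cc - center[1]
    r = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    boundary = np.ones(shape)
    for harmonic in (2, 3, 5):
        amp = irregularity * rng.uniform(0.3, 1.0) / 3.0
        phase = rng.uniform(0, 2 * np.pi)
        boundary += amp * np.cos(harmonic * theta + phase)
    return r <= radius * boundary


def _textured(
    shape: tuple[int, int],
    mean: float,
    sd: float,
    grain: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian noise field with approximate correlation length ``grain``."""
    noise = rng.normal(0.0, sd, size=shape)
    if grain > 1.0:
        from scipy.ndimage import gaussian_filter
        smooth = gaussian_filter(noise, sigma=grain / 2.0)
        # restore the requested marginal sd after smoothing
        s = smooth.std()
        if s > 0:
            noise = smooth * (sd / s)
    return mean + noise


def generate_cell(
    spec: CellClassSpec,
    rng: np.random.Generator,
    image_size: int = 96,
) -> SegmentedCell:
    """One synthetic segmented cell drawn from a class spec."""
    shape = (image_size, image_size)
    center = image_size / 2.0
    cyto_r = rng.uniform(*spec.cytoplasm_radius)
    nuc_r = rng.uniform(*spec.nucleus_radius)
    aspect = rng.uniform(1.0, 1.0 + spec.irregularity)

    cyto = _blob_mask(shape, (center, center), cyto_r, spec.irregularity / 2.0, rng)
    # nucleus offset stays small enough to keep it inside the cytoplasm
    max_off = max(cyto_r - nuc_r * (1.0 + spec.irregularity) - 2.0, 0.0)
    off = rng.uniform(-max_off / 2.0, max_off / 2.0, size=2)
    nucleus = _blob_mask(
        shape, (center + off[0], center + off[1]), nuc_r, spec.irregularity, rng, aspect
    )
    nucleus &= cyto  # construction invariant: nucleus inside the cell

    mask = np.zeros(shape, dtype=np.int64)
    mask[cyto] = 1
    mask[nucleus] = 2

    intensity = _textured(shape, BACKGROUND_BRIGHTNESS, 4.0, 1.0, rng)
    intensity[cyto] = _textured(shape, spec.cytoplasm_brightness, spec.noise_sd, spec.grain, rng)[cyto]
    intensity[nucleus] = _textured(shape, spec.nucleus_brightness, spec.noise_sd * 1.2, spec.grain, rng)[nucleus]
    intensity = np.clip(np.round(intensity), 0, 255)
    return SegmentedCell(intensity=intensity, mask=mask)


def generate_dataset(
    counts: dict[str, int] | None = None,
    seed: int = 0,
    image_size: int = 96,
    class_specs: dict[str, CellClassSpec] | None = None,
) -> tuple[list[SegmentedCell], list[str]]:
    """Generate a labelled list of synthetic cells (Herlev-style counts)."""
    counts = dict(counts or HERLEV_COUNTS)
    class_specs = class_specs or DEFAULT_CLASS_SPECS
    rng = np.random.default_rng(seed)
    cells, labels = [], []
    for name in CLASS_NAMES:
        n = counts.get(name, 0)
        for _ in range(n):
            cells.append(generate_cell(class_specs[name], rng, image_size))
            labels.append(name)
    return cells, labels


def write_dataset(
    out_dir: str | Path,
    counts: dict[str, int] | None = None,
    seed: int = 0,
    image_size: int = 96,
) -> pd.DataFrame:
    """Write PNG image/mask pairs in a class-per-directory layout + manifest."""
    out_dir = Path(out_dir)
    cells, labels = generate_dataset(counts, seed, image_size)
    records = []
    per_class: dict[str, int] = {}
    for cell, label in zip(cells, labels):
        i = per_class.get(label, 0)
        per_class[label] = i + 1
        cls_dir = out_dir / label
        cls_dir.mkdir(parents=True, exist_ok=True)
        img = cls_dir / f"{label}_{i:04d}.png"
        msk = cls_dir / f"{label}_{i:04d}_mask.png"
        save_cell(cell, img, msk)
        records.append({"cell_id": f"{label}_{i:04d}", "label": label,
                        "image": str(img.relative_to(out_dir)),
                        "mask": str(msk.relative_to(out_dir))})
    manifest = pd.DataFrame(records)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    (out_dir / "generation.json").write_text(json.dumps(
        {"seed": seed, "image_size": image_size,
         "counts": {k: int(per_class.get(k, 0)) for k in CLASS_NAMES}}))
    return manifest


def generate_feature_table(
    n: int,
    d_informative: int,
    d_noise: int,
    effect_size: float,
    n_classes: int,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Gaussian table with planted class-informative columns.

    Informative columns have class-conditional means spaced
    ``effect_size`` standard deviations apart (class means drawn on a grid
    with per-column random sign/permutation so no single column separates
    all classes); noise columns are iid standard normal. Returns the table
    (``label`` column + feature columns) and the informative column
    indices (0-based, into the feature columns).
    """
    if n < n_classes * 10:
        raise ValueError("need at least 10 samples per class")
    rng = np.random.default_rng(seed)
    labels = np.arange(n) % n_classes
    rng.shuffle(labels)

    d = d_informative + d_noise
    X = rng.normal(size=(n, d))
    for j in range(d_informative):
        class_means = effect_size * rng.permutation(n_classes).astype(float)
        X[:, j] += class_means[labels]
    informative = np.arange(d_informative)

    cols = {f"f{j:02d}": X[:, j] for j in range(d)}
    table = pd.DataFrame({"label": labels, **cols})
    return table, informative
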