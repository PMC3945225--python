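"""Quantification of mitotic chromatin retention from fluorescence images.

Per cell, mean eGFP intensity is measured in five regions each on mitotic
chromatin, in the nucleocytoplasm, and outside the cell (background). The
retention ratio is

    (mean chromatin - mean background) / (mean nucleocytoplasm - mean background)

where the compartment value is the average of its five region means. Groups
of cells are summarized as mean +/- SEM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, MitobookError
from .simulate import SyntheticImage

N_REGIONS = 5


@dataclass
class RetentionMeasurement:
    cell_id: str
    chromatin: tuple[float, ...]  # five ROI mean intensities
    nucleocytoplasm: tuple[float, ...]
    background: tuple[float, ...]

    def validate(self) -> None:
        for name, vals in (("chromatin", self.chromatin),
                           ("nucleocytoplasm", self.nucleocytoplasm),
                           ("background", self.background)):
            if len(vals) != N_REGIONS:
                raise ConfigError(f"{name}: exactly {N_REGIONS} region means required")


@dataclass
class GroupSummary:
    label: str
    n: int
    mean: float
    sem: float  # sample SD / sqrt(n); 0 by convention when n == 1
    single_cell: bool = False  # flags the n == 1 convention

    def validate(self) -> None:
        if self.n < 1 or self.sem < 0:
            raise MitobookError("invalid group summary")


def roi_mean(image: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean of the pixels under a boolean mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ConfigError("ROI mask shape does not match the image")
    if not mask.any():
        raise ConfigError("empty ROI mask")
    return float(np.asarray(image, dtype=float)[mask].mean())


def retention_ratio(m: RetentionMeasurement) -> float:
    """Background-corrected chromatin / nucleocytoplasm intensity ratio."""
    m.validate()
    bg = float(np.mean(m.background))
    chrom = float(np.mean(m.chromatin)) - bg
    cyto = float(np.mean(m.nucleocytoplasm)) - bg
    if cyto <= 0:
        raise MitobookError(
            "background-corrected nucleocytoplasm intensity is not positive; "
            "ratio undefined (saturated signal or failed background ROI)"
        )
    return chrom / cyto


def group_summary(label: str, ratios: list[float]) -> GroupSummary:
    if not ratios:
        raise ConfigError("empty group")
    arr = np.asarray(ratios, dtype=float)
    n = len(arr)
    sem = float(arr.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    out = GroupSummary(label, n, float(arr.mean()), sem, single_cell=(n == 1))
    out.validate()
    return out


def sample_rois(
    mask: np.ndarray,
    n: int = N_REGIONS,
    size: int = 3,
    seed: int = 0,
) -> list[np.ndarray]:
    """n disjoint size x size square ROIs fully inside a compartment mask."""
    mask = np.asarray(mask, dtype=bool)
    rng = np.random.default_rng([seed, 61])
    # candidate top-left corners where the full square fits in the mask
    ok = np.ones_like(mask)
    for dy in range(size):
        for dx in range(size):
            shifted = np.zeros_like(mask)
            shifted[: mask.shape[0] - dy, : mask.shape[1] - dx] = mask[dy:, dx:]
            ok &= shifted
    coords = np.argwhere(ok)
    if len(coords) < n:
        raise MitobookError("compartment too small to host the requested ROIs")
    rois: list[np.ndarray] = []
    taken = np.zeros_like(mask)
    for idx in rng.permutation(len(coords)):
        y, x = coords[idx]
        if taken[y: y + size, x: x + size].any():
            continue
        roi = np.zeros_like(mask)
        roi[y: y + size, x: x + size] = True
        rois.append(roi)
        taken |= roi
        if len(rois) == n:
            return rois
    raise MitobookError("could not place disjoint ROIs")


def measure_image(
    image: SyntheticImage, cell_id: str = "cell", seed: int = 0
) -> RetentionMeasurement:
    """Sample five regions per compartment from a synthetic image and record
    their mean intensities."""
    comps = (
        image.chromatin_mask,
        image.nucleocytoplasm_mask,
        image.background_mask,
    )
    means = []
    for i, mask in enumerate(comps):
        rois = sample_rois(mask, seed=seed * 3 + i)
        means.append(tuple(roi_mean(image.pixels, r) for r in rois))
    m = RetentionMeasurement(cell_id, *means)
    m.validate()
    return m
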