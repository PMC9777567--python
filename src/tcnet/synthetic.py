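"""Seeded synthetic generators with known dependence structure.

These define the study conditions for validation: (i) mutually independent
Gaussian channels, whose true Total Correlation is exactly zero; (ii) a
six-variable mixture of three independent Gaussians and a three-variable
Gaussian Markov chain (Y1 -> Y2 -> Y3), the clustering benchmark; (iii)
modular block-structured "ROI" series with one latent factor per block, for
parameter-recovery tests; (iv) a tiny labeled 4D image for extraction tests.

Every generator is bit-reproducible given its arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import TimeSeriesMatrix, ValidationError
from .evaluation import Partition

__all__ = [
    "gen_independent_gaussians",
    "gen_dependent_mixture",
    "dependent_mixture_covariance",
    "gen_modular_blocks",
    "modular_block_covariance",
    "gen_labeled_image",
    "LabeledImage",
]


def gen_independent_gaussians(
    n_vars: int = 3, n_samples: int = 1000, seed: int = 0
) -> TimeSeriesMatrix:
    """I.i.d. standard-normal columns; ground-truth TC is exactly 0 bits."""
    if n_vars < 2:
        raise ValidationError("need at least 2 variables")
    rng = np.random.default_rng(seed)
    vals = rng.standard_normal((n_samples, n_vars))
    names = [f"X{i + 1}" for i in range(n_vars)]
    return TimeSeriesMatrix(vals, names)


def dependent_mixture_covariance(coupling_sd: float = 0.5) -> np.ndarray:
    """Population covariance of the raw (un-standardised) chain Y1,Y2,Y3
    with Y2 = Y1 + e2, Y3 = Y2 + e3, e ~ N(0, coupling_sd^2)."""
    s2 = coupling_sd ** 2
    return np.array([
        [1.0, 1.0, 1.0],
        [1.0, 1.0 + s2, 1.0 + s2],
        [1.0, 1.0 + s2, 1.0 + 2 * s2],
    ])


def gen_dependent_mixture(
    n_samples: int = 500, coupling_sd: float = 0.5, seed: int = 0
) -> tuple[TimeSeriesMatrix, Partition]:
    """Dependent/independent six-variable mixture.

    X1..X3 are i.i.d. N(0,1) and independent of everything; the Y group is a
    Gaussian Markov chain Y1 ~ N(0,1), Y2 = Y1 + e2, Y3 = Y2 + e3 with
    e ~ N(0, coupling_sd^2).  Columns are z-scored on output.  Returns the
    series and the ground-truth partition {{X1},{X2},{X3},{Y1,Y2,Y3}}.
    """
    if coupling_sd <= 0:
        raise ValidationError("coupling_sd must be positive")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_samples, 3))
    y1 = rng.standard_normal(n_samples)
    y2 = y1 + coupling_sd * rng.standard_normal(n_samples)
    y3 = y2 + coupling_sd * rng.standard_normal(n_samples)
    vals = np.column_stack([x, y1, y2, y3])
    vals = (vals - vals.mean(axis=0)) / vals.std(axis=0, ddof=0)
    names = ["X1", "X2", "X3", "Y1", "Y2", "Y3"]
    truth = Partition.from_blocks([{"X1"}, {"X2"}, {"X3"}, {"Y1", "Y2", "Y3"}])
    return TimeSeriesMatrix(vals, names), truth


def modular_block_covariance(block_sizes: list[int], within_rho: float) -> np.ndarray:
    """Population covariance of the modular generator: block-diagonal with
    equicorrelation ``within_rho`` inside each block, unit variances."""
    p = sum(block_sizes)
    cov = np.eye(p)
    start = 0
    for b in block_sizes:
        cov[start:start + b, start:start + b] = (
            within_rho * np.ones((b, b)) + (1 - within_rho) * np.eye(b)
        )
        start += b
    return cov


def gen_modular_blocks(
    block_sizes: list[int] | tuple[int, ...] = (4, 4, 4),
    within_rho: float = 0.6, n_samples: int = 2000, seed: int = 0,
) -> tuple[TimeSeriesMatrix, Partition]:
    """Block-structured Gaussian series: one latent factor per block,
    variable = sqrt(rho)*factor + sqrt(1-rho)*noise, blocks independent.

    Within-block population correlation is exactly ``within_rho``; returns
    the series and the block partition.
    """
    if not (0 <= within_rho < 1):
        raise ValidationError("within_rho must be in [0, 1)")
    rng = np.random.default_rng(seed)
    cols, names, blocks = [], [], []
    for bi, b in enumerate(block_sizes):
        factor = rng.standard_normal(n_samples)
        block_names = set()
        for v in range(b):
            noise = rng.standard_normal(n_samples)
            cols.append(np.sqrt(within_rho) * factor + np.sqrt(1 - within_rho) * noise)
            name = f"B{bi + 1}V{v + 1}"
            names.append(name)
            block_names.add(name)
        blocks.append(block_names)
    ts = TimeSeriesMatrix(np.column_stack(cols), names)
    return ts, Partition.from_blocks(blocks)


@dataclass
class LabeledImage:
    """4D image + integer label volume + atlas lookup, for extraction tests."""

    image4d: "object"          # nibabel Nifti1Image, shape (x, y, z, t)
    labels3d: "object"         # nibabel Nifti1Image, integer labels, 0 = background
    lookup: pd.DataFrame       # columns: id, name, group
    region_courses: np.ndarray  # (t, n_regions) planted time courses


def gen_labeled_image(
    shape: tuple[int, int, int] = (6, 6, 4),
    n_regions: int = 4, n_timepoints: int = 40,
    noise_sd: float = 0.1, seed: int = 0,
):
    """Synthetic labeled 4D image: each region's voxels share a planted
    N(0,1) time course plus i.i.d. voxel noise.  Label 0 is background (the
    first spatial block); regions are contiguous integer blocks 1..n_regions.
    """
    import nibabel as nib

    n_vox = int(np.prod(shape))
    if n_regions + 1 > n_vox:
        raise ValidationError("more regions than voxels")
    rng = np.random.default_rng(seed)
    courses = rng.standard_normal((n_timepoints, n_regions))
    # contiguous flat blocks: block 0 = background, blocks 1..n_regions
    labels_flat = np.floor(
        np.arange(n_vox) * (n_regions + 1) / n_vox
    ).astype(np.int16)
    data = np.zeros((n_vox, n_timepoints))
    for r in range(1, n_regions + 1):
        mask = labels_flat == r
        data[mask] = courses[:, r - 1][None, :] + \
            noise_sd * rng.standard_normal((mask.sum(), n_timepoints))
    img4d = data.reshape(shape + (n_timepoints,))
    affine = np.eye(4)
    lookup = pd.DataFrame({
        "id": np.arange(1, n_regions + 1),
        "name": [f"region_{r}" for r in range(1, n_regions + 1)],
        "group": [f"group_{(r - 1) % 2}" for r in range(1, n_regions + 1)],
    })
    return LabeledImage(
        image4d=nib.Nifti1Image(img4d, affine),
        labels3d=nib.Nifti1Image(labels_flat.reshape(shape), affine),
        lookup=lookup,
        region_courses=courses,
    )
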