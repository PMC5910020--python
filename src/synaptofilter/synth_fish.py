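"""Synthetic 3-channel FISH + retrobead z-stacks with exact ground truth.

Scenes emulate 40x confocal stacks of tissue sections: disk-shaped somata
in a marker channel spanning 2-4 adjacent 1 µm z-slices, diffraction-limited
transcript puncta (Gaussian spots) placed only inside soma masks in the
probe channel, and granular tracer aggregates in a bead channel for a
labeled subset of cells.  Per-cell probe counts follow a two-component
Poisson mixture (negative cells ~ Poisson(lambda_neg), positive cells ~
Poisson(lambda_pos)), the substrate for puncta-count classification.

Ground truth records exactly what was placed: every punctum center lies
inside its soma mask, so noiseless end-to-end counting must reproduce the
truth table exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import ImageStack, ValidationError


@dataclass(frozen=True)
class FishSceneParams:
    """Generative parameters for one synthetic scene.

    ``punctum_amplitude / read_noise_sd`` is the scene's peak SNR; the
    default is noiseless (read_noise_sd = 0) so that generated stacks are
    exact test substrates, with noise switched on explicitly.
    """

    shape_zyx: tuple[int, int, int] = (5, 512, 512)
    n_cells: int = 60
    soma_radius_px: tuple[float, float] = (13.0, 16.0)
    soma_z_extent: tuple[int, int] = (2, 4)
    cell_gap_px: float = 3.0
    marker_intensity: float = 100.0
    lambda_neg: float = 1.0
    lambda_pos: float = 25.0
    fraction_positive: float = 0.7
    bead_fraction: float = 0.5
    bead_aggregates: tuple[int, int] = (4, 8)
    bead_intensity: float = 120.0
    bead_sigma_px: float = 1.6
    punctum_sigma_px: float = 1.2
    punctum_amplitude: float = 80.0
    puncta_min_sep_px: float = 4.5
    clutter_count: int = 0
    background: float = 10.0
    read_noise_sd: float = 0.0
    poisson_noise: bool = False
    pixel_size_um: float = 0.3
    z_step_um: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_pos <= self.lambda_neg:
            raise ValidationError("lambda_pos must exceed lambda_neg")
        if not 0 <= self.fraction_positive <= 1:
            raise ValidationError("fraction_positive must be in [0, 1]")


def _add_gaussian_spot(
    img: np.ndarray, cy: float, cx: float, amp: float, sigma: float
) -> None:
    r = int(np.ceil(4 * sigma))
    y0, y1 = max(int(cy) - r, 0), min(int(cy) + r + 1, img.shape[0])
    x0, x1 = max(int(cx) - r, 0), min(int(cx) + r + 1, img.shape[1])
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += amp * np.exp(
        -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2)
    )


def _place_centers(
    rng: np.random.Generator, params: FishSceneParams
) -> list[tuple[float, float, float]]:
    """Non-overlapping (cy, cx, radius) placements; error when infeasible."""
    _, ny, nx = params.shape_zyx
    placed: list[tuple[float, float, float]] = []
    attempts = 0
    max_attempts = 400 * max(params.n_cells, 1)
    while len(placed) < params.n_cells:
        if attempts > max_attempts:
            raise ValidationError(
                f"could not place {params.n_cells} non-overlapping cells in "
                f"a {ny}x{nx} frame after {max_attempts} attempts"
            )
        attempts += 1
        r = rng.uniform(*params.soma_radius_px)
        cy = rng.uniform(r + 2, ny - r - 2)
        cx = rng.uniform(r + 2, nx - r - 2)
        ok = all(
            np.hypot(cy - py, cx - px) >= r + pr + params.cell_gap_px
            for py, px, pr in placed
        )
        if ok:
            placed.append((cy, cx, r))
    return placed


def _dart_throw(
    rng: np.random.Generator,
    cy: float,
    cx: float,
    r_max: float,
    n_wanted: int,
    min_sep: float,
) -> list[tuple[float, float]]:
    """Place up to ``n_wanted`` points inside a disk with minimum spacing."""
    pts: list[tuple[float, float]] = []
    for _ in range(n_wanted):
        for _ in range(300):
            rho = r_max * np.sqrt(rng.random())
            theta = rng.uniform(0, 2 * np.pi)
            y, x = cy + rho * np.sin(theta), cx + rho * np.cos(theta)
            if all(np.hypot(y - py, x - px) >= min_sep for py, px in pts):
                pts.append((y, x))
                break
        else:
            break  # disk saturated; truth records what was placed
    return pts


def generate_stack(
    params: FishSceneParams,
    counts_override: Sequence[int] | None = None,
) -> tuple[ImageStack, pd.DataFrame]:
    """Generate a scene and its ground-truth table.

    Returns the stack (channels: 0 marker, 1 probe, 2 bead) and a table
    with one row per cell: centroid, radius, z span, placed puncta counts
    per channel, and the generative class flags.  ``counts_override`` pins
    per-cell probe counts deterministically (for construction tests).
    """
    rng = np.random.default_rng(params.seed)
    nz, ny, nx = params.shape_zyx
    vox = np.zeros((3, nz, ny, nx), dtype=np.float64)

    centers = _place_centers(rng, params)
    if counts_override is not None and len(counts_override) != len(centers):
        raise ValidationError("counts_override length must equal n_cells")

    rows = []
    for i, (cy, cx, r) in enumerate(centers):
        z_extent = int(rng.integers(params.soma_z_extent[0],
                                    params.soma_z_extent[1] + 1))
        z_extent = min(z_extent, nz)
        z0 = int(rng.integers(0, nz - z_extent + 1))
        # marker soma: filled disk across its z-slices
        yy, xx = np.mgrid[0:ny, 0:nx]
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        for z in range(z0, z0 + z_extent):
            vox[0, z][disk] += params.marker_intensity

        if counts_override is not None:
            n_puncta = int(counts_override[i])
            positive = None
        else:
            positive = bool(rng.random() < params.fraction_positive)
            lam = params.lambda_pos if positive else params.lambda_neg
            n_puncta = int(rng.poisson(lam))
        pts = _dart_throw(rng, cy, cx, max(r - 2.0, 1.0), n_puncta,
                          params.puncta_min_sep_px)
        for py, px in pts:
            z = int(rng.integers(z0, z0 + z_extent))
            _add_gaussian_spot(vox[1, z], py, px,
                               params.punctum_amplitude, params.punctum_sigma_px)

        bead_positive = bool(rng.random() < params.bead_fraction)
        n_bead = 0
        if bead_positive:
            n_bead = int(rng.integers(params.bead_aggregates[0],
                                      params.bead_aggregates[1] + 1))
            bpts = _dart_throw(rng, cy, cx, max(r - 2.0, 1.0), n_bead,
                               params.puncta_min_sep_px)
            n_bead = len(bpts)
            for py, px in bpts:
                z = int(rng.integers(z0, z0 + z_extent))
                _add_gaussian_spot(vox[2, z], py, px,
                                   params.bead_intensity, params.bead_sigma_px)

        rows.append(
            {
                "cell": i,
                "cy": cy,
                "cx": cx,
                "radius": r,
                "z_start": z0,
                "z_extent": z_extent,
                "count_probe": len(pts),
                "count_bead": n_bead,
                "probe_positive": positive,
                "bead_positive": bead_positive,
            }
        )

    # extracellular clutter (off by default): spots outside every soma
    for _ in range(params.clutter_count):
        for _ in range(200):
            y, x = rng.uniform(2, ny - 2), rng.uniform(2, nx - 2)
            if all(np.hypot(y - cy, x - cx) > r + 2 for cy, cx, r in centers):
                z = int(rng.integers(0, nz))
                _add_gaussian_spot(vox[1, z], y, x,
                                   params.punctum_amplitude,
                                   params.punctum_sigma_px)
                break

    vox += params.background
    if params.poisson_noise:
        vox = rng.poisson(vox).astype(np.float64)
    if params.read_noise_sd > 0:
        vox += rng.normal(0.0, params.read_noise_sd, size=vox.shape)
    np.clip(vox, 0.0, None, out=vox)

    stack = ImageStack(
        voxels=vox,
        pixel_size_xy=params.pixel_size_um,
        z_step=params.z_step_um,
        channel_roles={"marker": 0, "probe": 1, "bead": 2},
    )
    return stack, pd.DataFrame(rows)
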