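"""Synthetic data generator for every pipeline input.

Produces bright-field-like / fluorescence microscopy image pairs of
immobilized yeast cells with a per-cell ground-truth table, low-resolution
fluorescence scans of a 5 x 5 mm compartment, and Bernoulli
viability-staining outcomes.  The generator and the classifier are
co-calibrated: circular cells are rendered as discs (E ~ 0), elongated
cells as ellipses with axis ratios in [1.5, 1.8] (E in ~[0.75, 0.84]) and
shmoos as an ellipse fused with a polar protrusion lobe (E >= 0.87), so
every rendered cell's noise-free geometry classifies to its generating
class under the default thresholds.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence``; identical parameters give byte-identical
images and tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import draw

from .diffusion import InvalidParameterError
from .response import DoseResponseParams, phenotype_distribution
from .scans import ScanImage

__all__ = [
    "MicroscopySynthParams",
    "synth_phenotype_field",
    "synth_scan",
    "synth_viability",
    "render_cell_mask",
]

# Shape constants shared by rendering and the ground-truth contract.
ELONGATED_RATIO_RANGE = (1.5, 1.8)
SHMOO_BODY_RATIO = 1.6
SHMOO_LOBE_FRACTION = 0.45
SHMOO_LOBE_OFFSET = 1.25  # lobe center, in units of the body's major semi-axis


@dataclass(frozen=True)
class MicroscopySynthParams:
    """Rendering parameters for synthetic microscopy fields.

    Defaults: 16 fields of view spaced 0.3 mm apart (first centered
    0.15 mm beyond the compartment boundary), 600 x 600 px at 0.5 um/px,
    cells of mean radius 10 px.  ``foreground_level`` is the bright-field
    cell intensity over ``background_level``; fluorescence pixel values
    are each cell's true reporter intensity.
    """

    positions: int = 16
    spacing_mm: float = 0.3
    offset_mm: float = 0.15
    cells_per_position: int = 60
    image_size: tuple[int, int] = (600, 600)
    pixel_size_um: float = 0.5
    cell_radius_mean_px: float = 10.0
    cell_radius_sd_px: float = 1.0
    noise_sd: float = 4.0
    background_level: float = 20.0
    foreground_level: float = 120.0
    psf_sigma: float = 1.0
    fluorescence_scatter: float = 0.10
    survival_prob: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.positions < 1 or self.cells_per_position < 0:
            raise InvalidParameterError("positions >= 1 and cells_per_position >= 0 required")
        if min(self.spacing_mm, self.pixel_size_um, self.cell_radius_mean_px,
               self.psf_sigma) <= 0:
            raise InvalidParameterError("geometric parameters must be positive")
        if not 0.0 <= self.survival_prob <= 1.0:
            raise InvalidParameterError("survival_prob must lie in [0, 1]")


def render_cell_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    radius: float,
    phenotype: str,
    axis_ratio: float,
    orientation: float,
) -> np.ndarray:
    """Noise-free boolean mask of one cell, as the generator draws it.

    Circular cells are discs of the given radius; elongated cells are
    area-preserving ellipses (semi-axes r*sqrt(ratio), r/sqrt(ratio));
    shmoos are a ratio-1.6 body ellipse fused with a protrusion lobe of
    0.45 r centered 1.25 major-semi-axes from the body center.
    """
    mask = np.zeros(shape, dtype=bool)
    cy, cx = center
    if phenotype == "circular":
        rr, cc = draw.disk((cy, cx), radius, shape=shape)
        mask[rr, cc] = True
        return mask
    if phenotype == "elongated":
        a = radius * math.sqrt(axis_ratio)
        b = radius / math.sqrt(axis_ratio)
        rr, cc = draw.ellipse(cy, cx, a, b, shape=shape, rotation=orientation)
        mask[rr, cc] = True
        return mask
    if phenotype == "shmoo":
        a = radius * math.sqrt(SHMOO_BODY_RATIO)
        b = radius / math.sqrt(SHMOO_BODY_RATIO)
        rr, cc = draw.ellipse(cy, cx, a, b, shape=shape, rotation=orientation)
        mask[rr, cc] = True
        d = SHMOO_LOBE_OFFSET * a
        ly = cy + d * math.cos(orientation)
        lx = cx + d * math.sin(orientation)
        rr, cc = draw.disk((ly, lx), SHMOO_LOBE_FRACTION * radius, shape=shape)
        mask[rr, cc] = True
        return mask
    raise InvalidParameterError(f"unknown phenotype {phenotype!r}")


def _cell_footprint_radius(radius: float, phenotype: str, axis_ratio: float) -> float:
    """Half-extent of the cell along its longest direction, for placement."""
    if phenotype == "circular":
        return radius
    if phenotype == "elongated":
        return radius * math.sqrt(axis_ratio)
    a = radius * math.sqrt(SHMOO_BODY_RATIO)
    return SHMOO_LOBE_OFFSET * a + SHMOO_LOBE_FRACTION * radius


def _place_centers(
    rng: np.random.Generator,
    footprints: np.ndarray,
    shape: tuple[int, int],
    gap: float = 4.0,
    max_tries_per_cell: int = 2000,
) -> np.ndarray:
    """Rejection-sample non-overlapping cell centers away from the border.

    ``footprints`` holds each cell's half-extent (px); two cells must be
    separated by the sum of their footprints plus ``gap``.
    """
    centers: list[tuple[float, float]] = []
    placed_fp: list[float] = []
    for fp in footprints:
        margin = fp + gap
        for _ in range(max_tries_per_cell):
            cy = rng.uniform(margin, shape[0] - margin)
            cx = rng.uniform(margin, shape[1] - margin)
            if all(
                (cy - y) ** 2 + (cx - x) ** 2 >= (fp + other + gap) ** 2
                for (y, x), other in zip(centers, placed_fp)
            ):
                centers.append((cy, cx))
                placed_fp.append(fp)
                break
        else:
            raise InvalidParameterError(
                f"could not place {len(footprints)} non-overlapping cells in a "
                f"{shape} image; reduce cells_per_position or cell size"
            )
    return np.array(centers)


def synth_phenotype_field(
    profile: Sequence[float] | Sequence[tuple[float, float, float]],
    params: MicroscopySynthParams,
    dose: DoseResponseParams | None = None,
    fluorescence_levels: Sequence[float] | None = None,
) -> tuple[list[tuple[np.ndarray, np.ndarray]], pd.DataFrame]:
    """Render microscopy image pairs along the modeled gradient.

    ``profile`` gives, per position, either the local pheromone
    concentration in nM (class probabilities then come from
    :func:`pherosim.response.phenotype_distribution` with ``dose``) or an
    explicit (p_circular, p_elongated, p_shmoo) triple.
    ``fluorescence_levels`` optionally fixes each position's mean reporter
    intensity; by default it scales with the shmoo-response activation
    between background and foreground levels.

    Returns a list of (bright_field, fluorescence) float image pairs, one
    per position, and the ground-truth table with one row per rendered
    cell (position, center, radius, axis ratio, orientation, true class,
    true fluorescence, viability flag).
    """
    profile = list(profile)
    if len(profile) != params.positions:
        raise InvalidParameterError(
            f"profile length {len(profile)} != positions {params.positions}"
        )
    dose = dose or DoseResponseParams()

    probs: list[tuple[float, float, float]] = []
    for entry in profile:
        if np.isscalar(entry):
            probs.append(phenotype_distribution(float(entry), dose).as_tuple())
        else:
            p = tuple(float(v) for v in entry)
            if len(p) != 3 or abs(sum(p) - 1.0) > 1e-9:
                raise InvalidParameterError(f"class probabilities must sum to 1, got {p}")
            probs.append(p)

    if fluorescence_levels is None:
        from .response import hill

        fluorescence_levels = [
            params.background_level
            + (params.foreground_level - params.background_level)
            * (float(hill(float(entry), dose.ec50, dose.hill_coefficient))
               if np.isscalar(entry) else float(entry[2]))
            for entry in profile
        ]
    elif len(fluorescence_levels) != params.positions:
        raise InvalidParameterError("fluorescence_levels length must match positions")

    ss = np.random.SeedSequence(params.seed)
    child_seeds = ss.spawn(params.positions)

    images: list[tuple[np.ndarray, np.ndarray]] = []
    records: list[dict] = []
    classes = ("circular", "elongated", "shmoo")
    shape = params.image_size

    for pos in range(params.positions):
        rng = np.random.default_rng(child_seeds[pos])
        n = params.cells_per_position
        bf = np.full(shape, params.background_level, dtype=float)
        fl = np.full(shape, params.background_level, dtype=float)
        if n > 0:
            kinds = rng.choice(3, size=n, p=probs[pos])
            radii = np.clip(
                rng.normal(params.cell_radius_mean_px, params.cell_radius_sd_px, n),
                0.5 * params.cell_radius_mean_px,
                1.5 * params.cell_radius_mean_px,
            )
            ratios = rng.uniform(*ELONGATED_RATIO_RANGE, size=n)
            angles = rng.uniform(0.0, math.pi, size=n)
            footprints = np.array([
                _cell_footprint_radius(
                    radii[i], classes[kinds[i]],
                    ratios[i] if classes[kinds[i]] == "elongated" else SHMOO_BODY_RATIO,
                )
                for i in range(n)
            ])
            centers = _place_centers(rng, footprints, shape)
            scatter = rng.lognormal(
                mean=-0.5 * params.fluorescence_scatter**2,
                sigma=params.fluorescence_scatter,
                size=n,
            )
            viable = rng.random(n) < params.survival_prob
            for i in range(n):
                phen = classes[kinds[i]]
                ratio = float(ratios[i]) if phen == "elongated" else (
                    SHMOO_BODY_RATIO if phen == "shmoo" else 1.0
                )
                mask = render_cell_mask(
                    shape, tuple(centers[i]), float(radii[i]), phen, ratio, float(angles[i])
                )
                true_fl = float(fluorescence_levels[pos] * scatter[i])
                bf[mask] = params.foreground_level
                fl[mask] = true_fl
                records.append(
                    {
                        "position_index": pos,
                        "distance_mm": params.offset_mm + pos * params.spacing_mm,
                        "row": centers[i][0],
                        "col": centers[i][1],
                        "radius_px": float(radii[i]),
                        "axis_ratio": ratio,
                        "orientation": float(angles[i]),
                        "true_class": phen,
                        "true_fluorescence": true_fl,
                        "viable": bool(viable[i]),
                    }
                )
        bf = ndi.gaussian_filter(bf, params.psf_sigma)
        fl = ndi.gaussian_filter(fl, params.psf_sigma)
        bf += rng.normal(0.0, params.noise_sd, shape)
        fl += rng.normal(0.0, params.noise_sd, shape)
        images.append((bf, fl))

    truth = pd.DataFrame(
        records,
        columns=[
            "position_index", "distance_mm", "row", "col", "radius_px",
            "axis_ratio", "orientation", "true_class", "true_fluorescence", "viable",
        ],
    )
    return images, truth


def synth_scan(
    expected_curve: Callable[[np.ndarray], np.ndarray],
    pixel_size_mm: float = 0.1,
    compartment_mm: float = 5.0,
    pad_px: int = 10,
    background: float = 100.0,
    dynamic_range: float = 1000.0,
    noise_sd: float = 5.0,
    edge_attenuation: tuple[float, float] | None = None,
    seed: int = 0,
) -> tuple[ScanImage, pd.DataFrame]:
    """Render a compartment fluorescence scan from an expected-intensity curve.

    ``expected_curve`` maps distance from the compartment boundary (mm,
    on [0, compartment_mm]) to relative intensity (1.0 = the constitutive
    reference plateau).  Pixel intensity is
    ``background + curve * dynamic_range`` plus Gaussian noise; the
    optional edge attenuation multiplies the curve by
    ``1 - a * exp(-d / w)`` (disabled by default), mimicking the reduced
    signal right at the boundary seen in scans.

    Returns the :class:`ScanImage` (ROI covering the compartment,
    boundary on the left edge) and a truth table with the per-column
    distance and noise-free relative intensity.
    """
    if pixel_size_mm <= 0 or compartment_mm <= 0:
        raise InvalidParameterError("pixel_size_mm and compartment_mm must be > 0")
    n_cols = int(round(compartment_mm / pixel_size_mm))
    n_rows = n_cols
    distances = (np.arange(n_cols) + 0.5) * pixel_size_mm
    rel = np.asarray(expected_curve(distances), dtype=float)
    if edge_attenuation is not None:
        a, w = edge_attenuation
        rel = rel * (1.0 - a * np.exp(-distances / w))

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    shape = (n_rows + 2 * pad_px, n_cols + 2 * pad_px)
    img = np.full(shape, background, dtype=float)
    img[pad_px:pad_px + n_rows, pad_px:pad_px + n_cols] += rel[None, :] * dynamic_range
    img += rng.normal(0.0, noise_sd, shape)

    scan = ScanImage(
        image=img,
        pixel_size_mm=pixel_size_mm,
        roi=(pad_px, pad_px + n_rows, pad_px, pad_px + n_cols),
        boundary_edge="left",
    )
    truth = pd.DataFrame({"distance_mm": distances, "relative_intensity": rel})
    return scan, truth


def synth_viability(n_cells: int, survival_prob: float, seed: int = 0) -> tuple[int, int]:
    """Bernoulli viability-staining outcomes: (n_alive, n_stained)."""
    if n_cells < 1:
        raise InvalidParameterError("n_cells must be >= 1")
    if not 0.0 <= survival_prob <= 1.0:
        raise InvalidParameterError("survival_prob must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_alive = int(rng.binomial(n_cells, survival_prob))
    return n_alive, n_cells - n_alive
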