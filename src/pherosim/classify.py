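"""Cell segmentation, eccentricity-based phenotype classification and spatial profiles.

Yeast cells responding to the pheromone gradient change shape: unexposed
cells stay circular, partially responding cells elongate, and fully
responding cells grow a mating projection (shmoo).  The sole shape
feature used here is the eccentricity E of the best-fit ellipse from the
region's central second moments — E = sqrt(1 - b^2/a^2) — split into
three classes by two thresholds.  Cells are detected in bright-field-like
images (objects brighter than background), measured in the matched
fluorescence channel, and binned by field-of-view position into a spatial
phenotype profile versus distance from the compartment boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import filters, measure, morphology, segmentation
from skimage.feature import peak_local_max

from .diffusion import InvalidParameterError

__all__ = [
    "ClassThresholds",
    "SegmentedCell",
    "SpatialPhenotypeProfile",
    "segment",
    "cell_eccentricity",
    "classify_cell",
    "mean_cell_fluorescence",
    "measure_cells",
    "spatial_profile",
    "shmoo_extent",
    "load_position_images",
]

PHENOTYPES = ("circular", "elongated", "shmoo")

#: Degenerate (collinear) regions get this eccentricity instead of 1.0.
ECC_CLAMP = 0.999


@dataclass(frozen=True)
class ClassThresholds:
    """Eccentricity cut points between the three shape classes.

    circular: E < e_circ_max; elongated: e_circ_max <= E < e_shmoo_min;
    shmoo: E >= e_shmoo_min.
    """

    e_circ_max: float = 0.60
    e_shmoo_min: float = 0.85

    def __post_init__(self) -> None:
        if not 0.0 < self.e_circ_max < self.e_shmoo_min < 1.0:
            raise InvalidParameterError(
                f"require 0 < e_circ_max < e_shmoo_min < 1, got "
                f"({self.e_circ_max}, {self.e_shmoo_min})"
            )


@dataclass
class SegmentedCell:
    """One detected cell with its shape, class and fluorescence readouts."""

    label: int
    centroid: tuple[float, float]
    area: float
    eccentricity: float
    mean_fluorescence: float
    position_index: int
    distance_to_boundary: float
    phenotype: str


def segment(
    image: np.ndarray,
    sigma: float = 1.0,
    area_min: int = 100,
    area_max: int = 5000,
    split_touching: bool = True,
    min_split_distance: int = 10,
    rel_peak: float = 0.5,
    clear_border: bool = True,
) -> np.ndarray:
    """Label individual cells in a bright-field-like image.

    Chain: Gaussian smoothing -> Otsu threshold (foreground = brighter
    side) -> hole filling -> distance-transform watershed to split
    touching cells -> area filter -> border-region removal.  Watershed
    markers are local maxima of the distance transform, kept only if at
    least ``rel_peak`` of their component's maximum, so a shmoo's small
    protrusion lobe does not split off its body while two genuinely
    touching cells of similar size do separate.

    A blank or constant image yields zero regions, not an error.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise InvalidParameterError("expected a 2-D grayscale image")
    if not np.all(np.isfinite(img)):
        raise InvalidParameterError("image intensities must be finite")
    if np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=np.int32)

    smoothed = filters.gaussian(img, sigma=sigma, preserve_range=True)
    if np.ptp(smoothed) == 0:
        return np.zeros(img.shape, dtype=np.int32)
    mask = smoothed > filters.threshold_otsu(smoothed)
    mask = ndi.binary_fill_holes(mask)

    if split_touching:
        distance = ndi.distance_transform_edt(mask)
        comp_labels, n_comp = ndi.label(mask)
        peaks = peak_local_max(
            distance,
            min_distance=min_split_distance,
            labels=comp_labels,
            exclude_border=False,
        )
        markers = np.zeros(mask.shape, dtype=np.int32)
        comp_max = ndi.maximum(distance, comp_labels, index=np.arange(1, n_comp + 1))
        next_id = 1
        for r, c in peaks:
            comp = comp_labels[r, c]
            if distance[r, c] >= rel_peak * comp_max[comp - 1]:
                markers[r, c] = next_id
                next_id += 1
        if next_id > 1:
            labels = segmentation.watershed(-distance, markers, mask=mask)
        else:
            labels = comp_labels
    else:
        labels, _ = ndi.label(mask)

    if clear_border:
        labels = segmentation.clear_border(labels)

    out = np.zeros(labels.shape, dtype=np.int32)
    next_id = 1
    for region in measure.regionprops(labels):
        if area_min <= region.area <= area_max:
            out[labels == region.label] = next_id
            next_id += 1
    return out


def cell_eccentricity(region: np.ndarray | measure._regionprops.RegionProperties) -> float:
    """Eccentricity of the best-fit ellipse from central second moments.

    Accepts a boolean region mask or a precomputed regionprops entry.
    E = sqrt(1 - lambda_min / lambda_max) for the inertia eigenvalues of
    the region; degenerate (collinear) regions are clamped to 0.999.
    """
    if isinstance(region, np.ndarray):
        mask = region.astype(bool)
        if mask.sum() < 5:
            raise InvalidParameterError("region must contain at least 5 pixels")
        props = measure.regionprops(mask.astype(np.uint8))[0]
    else:
        props = region
        if props.area < 5:
            raise InvalidParameterError("region must contain at least 5 pixels")
    ecc = float(props.eccentricity)
    if not ecc < 1.0:
        return ECC_CLAMP
    return min(ecc, ECC_CLAMP)


def classify_cell(eccentricity: float, thresholds: ClassThresholds) -> str:
    """Assign circular / elongated / shmoo by half-open eccentricity bands."""
    if not 0.0 <= eccentricity < 1.0:
        raise InvalidParameterError(f"eccentricity must lie in [0, 1), got {eccentricity}")
    if eccentricity < thresholds.e_circ_max:
        return "circular"
    if eccentricity < thresholds.e_shmoo_min:
        return "elongated"
    return "shmoo"


def mean_cell_fluorescence(labels: np.ndarray, fluorescence: np.ndarray) -> pd.Series:
    """Mean fluorescence under each labeled region, indexed by label."""
    labels = np.asarray(labels)
    fluor = np.asarray(fluorescence, dtype=float)
    if labels.shape != fluor.shape:
        raise InvalidParameterError(
            f"label image {labels.shape} and fluorescence image {fluor.shape} differ"
        )
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        return pd.Series(dtype=float, name="mean_fluorescence")
    means = ndi.mean(fluor, labels=labels, index=ids)
    return pd.Series(means, index=pd.Index(ids, name="label"), name="mean_fluorescence")


def measure_cells(
    bf_image: np.ndarray,
    fl_image: np.ndarray | None,
    position_index: int,
    thresholds: ClassThresholds | None = None,
    spacing_mm: float = 0.3,
    offset_mm: float = 0.15,
    interior_erosion: int = 3,
    **segment_kwargs,
) -> pd.DataFrame:
    """Segment one field of view and measure every cell.

    Returns one row per cell with centroid, area, eccentricity, class,
    mean fluorescence and the field's distance from the compartment
    boundary (``offset_mm + position_index * spacing_mm``).
    Fluorescence is averaged over each cell's interior (mask eroded by
    ``interior_erosion`` px) so blur-diluted edge pixels do not bias the
    estimate; cells too small to survive the erosion fall back to the
    full mask.
    """
    thresholds = thresholds or ClassThresholds()
    labels = segment(bf_image, **segment_kwargs)
    if fl_image is not None:
        fluor = mean_cell_fluorescence(labels, fl_image)
        if interior_erosion > 0:
            interior = labels * ndi.binary_erosion(labels > 0, iterations=interior_erosion)
            inner = mean_cell_fluorescence(interior, fl_image)
            fluor.update(inner)
    else:
        fluor = pd.Series(dtype=float)
    rows = []
    distance = offset_mm + position_index * spacing_mm
    for region in measure.regionprops(labels):
        ecc = cell_eccentricity(region)
        rows.append(
            {
                "label": region.label,
                "position_index": position_index,
                "distance_mm": distance,
                "row": region.centroid[0],
                "col": region.centroid[1],
                "area_px": int(region.area),
                "eccentricity": ecc,
                "phenotype": classify_cell(ecc, thresholds),
                "mean_fluorescence": float(fluor.get(region.label, np.nan)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "label", "position_index", "distance_mm", "row", "col",
            "area_px", "eccentricity", "phenotype", "mean_fluorescence",
        ],
    )


@dataclass
class SpatialPhenotypeProfile:
    """Per-distance counts and fractions of the three shape classes.

    ``fractions`` holds NaN at distances with no detected cells.
    """

    distances: np.ndarray
    counts: pd.DataFrame
    fractions: pd.DataFrame

    def to_dataframe(self) -> pd.DataFrame:
        out = self.counts.add_prefix("n_").join(self.fractions.add_prefix("f_"))
        out.insert(0, "distance_mm", self.distances)
        return out.reset_index(drop=True)


def spatial_profile(
    cells: pd.DataFrame,
    positions: Sequence[int],
    spacing_mm: float = 0.3,
    offset_mm: float = 0.15,
) -> SpatialPhenotypeProfile:
    """Aggregate per-cell classes into a phenotype profile over distance.

    ``positions`` is the acquisition plan (field-of-view indices); every
    cell must carry a position index present in the plan.
    """
    plan = list(positions)
    unknown = set(cells["position_index"]) - set(plan)
    if unknown:
        raise InvalidParameterError(f"cells reference positions outside the plan: {sorted(unknown)}")
    distances = np.array([offset_mm + i * spacing_mm for i in plan])
    counts = pd.DataFrame(0, index=pd.Index(plan, name="position_index"), columns=list(PHENOTYPES))
    if len(cells):
        tab = cells.groupby(["position_index", "phenotype"]).size().unstack(fill_value=0)
        for ph in PHENOTYPES:
            if ph in tab:
                counts.loc[tab.index, ph] = tab[ph]
    totals = counts.sum(axis=1)
    fractions = counts.div(totals.where(totals > 0), axis=0)
    return SpatialPhenotypeProfile(distances=distances, counts=counts, fractions=fractions)


def shmoo_extent(profile: SpatialPhenotypeProfile, min_detect_fraction: float = 0.05) -> float:
    """Farthest distance (mm) whose shmoo fraction reaches the detect floor.

    With ``min_detect_fraction = 0`` this is the farthest occupied
    position; returns 0.0 if no position qualifies.
    """
    if len(profile.distances) == 0:
        raise InvalidParameterError("profile is empty")
    frac = profile.fractions["shmoo"].to_numpy()
    occupied = ~np.isnan(frac)
    hit = occupied & (frac >= min_detect_fraction)
    if not hit.any():
        return 0.0
    return float(profile.distances[np.flatnonzero(hit)[-1]])


def load_position_images(
    directory: str | Path,
    position_index: int,
    pattern: str = "position_{index:02d}_{channel}.tif",
) -> tuple[np.ndarray, np.ndarray | None]:
    """Read the (bright-field, fluorescence) TIFF pair for one position."""
    import tifffile

    directory = Path(directory)
    bf_path = directory / pattern.format(index=position_index, channel="bf")
    fl_path = directory / pattern.format(index=position_index, channel="fl")
    bf = tifffile.imread(bf_path)
    fl = tifffile.imread(fl_path) if fl_path.exists() else None
    return bf, fl
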