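"""Nucleus delineation and per-cell morphometric quantification.

Every cellular object is summarised as a fixed vector of 15 morphometric
properties covering size, shape, boundary texture and intensity. The list is
frozen (:data:`FEATURE_NAMES`); all downstream stages (dictionary learning,
sparse coding, subtyping) operate on these 15 numbers per cell.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.color import rgb2gray
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import perimeter as _perimeter
from skimage.measure import regionprops
from skimage.segmentation import watershed

#: Canonical, ordered names of the 15 per-nucleus morphometric properties.
FEATURE_NAMES: tuple[str, ...] = (
    "area",
    "perimeter",
    "equivalent_diameter",
    "major_axis_length",
    "minor_axis_length",
    "aspect_ratio",
    "eccentricity",
    "orientation",
    "solidity",
    "extent",
    "circularity",
    "boundary_roughness",
    "mean_intensity",
    "intensity_sd",
    "intensity_range",
)

N_FEATURES = len(FEATURE_NAMES)

#: Columns of a nucleus feature table: ids/coordinates, then the 15 features,
#: then the border flag.
TABLE_COLUMNS = ("object_id", "cx", "cy", *FEATURE_NAMES, "border")


def _to_nuclear_channel(image: np.ndarray) -> np.ndarray:
    """Reduce an RGB image to a single nuclear-signal channel.

    For H&E-like input the hematoxylin (nuclear) signal is dark; a grayscale
    inversion is used as a proxy so that nuclei are bright. Single-channel
    input is returned unchanged.
    """
    if image.ndim == 3 and image.shape[-1] in (3, 4):
        gray = rgb2gray(image[..., :3])
        return 1.0 - gray
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {image.shape}")
    return image


def segment_nuclei(
    image: np.ndarray,
    min_area: int = 30,
    max_area: int = 5000,
    sigma: float = 1.0,
    min_peak_distance: int = 5,
) -> np.ndarray:
    """Delineate nuclei in an intensity image.

    Pipeline: nuclear-channel extraction, Gaussian smoothing, Otsu threshold,
    distance-transform watershed to split touching objects, then an area
    filter. Labels are relabelled consecutively from 1.

    Parameters
    ----------
    image:
        2-D intensity array (RGB accepted; reduced to a nuclear channel).
    min_area, max_area:
        Inclusive area bounds in pixels; objects outside are removed.
    sigma:
        Gaussian smoothing scale before thresholding.
    min_peak_distance:
        Minimum separation of watershed seed peaks, in pixels.

    Returns
    -------
    ndarray
        Integer label mask, same shape as ``image``, background 0.
    """
    chan = _to_nuclear_channel(np.asarray(image, dtype=float))
    if chan.ndim != 2:
        raise ValueError("segment_nuclei requires a 2-D image")

    smoothed = gaussian(chan, sigma=sigma, preserve_range=True)
    if np.ptp(smoothed) <= 0:
        return np.zeros(chan.shape, dtype=np.int32)
    thresh = threshold_otsu(smoothed)
    binary = smoothed > thresh
    if not binary.any():
        return np.zeros(chan.shape, dtype=np.int32)

    distance = ndi.distance_transform_edt(binary)
    peaks = peak_local_max(
        distance, min_distance=min_peak_distance, labels=binary, exclude_border=False
    )
    markers = np.zeros(chan.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    markers, _ = ndi.label(markers > 0)
    labels = watershed(-distance, markers, mask=binary)

    # area filter + consecutive relabelling
    out = np.zeros_like(labels, dtype=np.int32)
    next_label = 1
    for region in regionprops(labels):
        if min_area <= region.area <= max_area:
            out[labels == region.label] = next_label
            next_label += 1
    return out


def _convex_perimeter(region) -> float:
    return _perimeter(region.image_convex, neighborhood=4)


def extract_morphometry(
    mask: np.ndarray, image: np.ndarray, slide_id: str | None = None
) -> pd.DataFrame:
    """Compute the 15-property morphometric vector for every labelled object.

    Objects touching the image border are flagged in the ``border`` column but
    retained (dropping them would bias cellular density estimates).

    Returns a :class:`~pandas.DataFrame` with columns :data:`TABLE_COLUMNS`
    (object_id, centroid ``cx``/``cy`` with x = column, the 15 features, and
    the border flag), one row per object, ordered by label.
    """
    mask = np.asarray(mask)
    chan = _to_nuclear_channel(np.asarray(image, dtype=float))
    if mask.shape != chan.shape:
        raise ValueError("mask and image must have the same shape")

    h, w = mask.shape
    rows = []
    for region in regionprops(mask, intensity_image=chan):
        a = float(region.area)
        p = max(float(region.perimeter), 1e-8)
        major = float(region.axis_major_length)
        minor = float(region.axis_minor_length)
        intens = region.image_intensity[region.image]
        hull_p = max(_convex_perimeter(region), 1e-8)
        minr, minc, maxr, maxc = region.bbox
        border = minr == 0 or minc == 0 or maxr == h or maxc == w
        feats = {
            "area": a,
            "perimeter": p,
            "equivalent_diameter": float(region.equivalent_diameter_area),
            "major_axis_length": major,
            "minor_axis_length": minor,
            "aspect_ratio": major / max(minor, 1e-8),
            "eccentricity": float(region.eccentricity),
            "orientation": float(region.orientation),
            "solidity": float(region.solidity),
            "extent": float(region.extent),
            "circularity": 4.0 * np.pi * a / p**2,
            "boundary_roughness": p / hull_p,
            "mean_intensity": float(intens.mean()),
            "intensity_sd": float(intens.std()),
            "intensity_range": float(intens.max() - intens.min()),
        }
        cy, cx = region.centroid
        rows.append(
            {"object_id": int(region.label), "cx": float(cx), "cy": float(cy), **feats,
             "border": bool(border)}
        )

    table = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
    if len(table):
        vals = table[list(FEATURE_NAMES)].to_numpy(float)
        if not np.all(np.isfinite(vals)):
            warnings.warn("non-finite morphometric values encountered", stacklevel=2)
    if slide_id is not None:
        table.insert(0, "slide_id", slide_id)
    return table


def standardize(
    tables: pd.DataFrame | list[pd.DataFrame] | np.ndarray,
    stats: tuple[np.ndarray, np.ndarray] | None = None,
    sd_floor: float = 1e-8,
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Z-score the 15 morphometric features.

    When ``stats`` is omitted, per-feature mean/SD are computed over all rows
    and returned so they can be stored with a trained dictionary and re-applied
    to new cohorts. SDs below ``sd_floor`` are floored, so constant columns map
    to zero rather than NaN.

    Parameters
    ----------
    tables:
        A feature table (or list of tables) with the canonical feature
        columns, or a raw ``(n, 15)`` array in canonical order.
    stats:
        Optional ``(means, sds)`` pair of length-15 arrays to apply.

    Returns
    -------
    (Z, (means, sds))
        Standardized ``(n, 15)`` matrix and the statistics used.
    """
    if isinstance(tables, list):
        X = np.vstack([t[list(FEATURE_NAMES)].to_numpy(float) for t in tables])
    elif isinstance(tables, pd.DataFrame):
        X = tables[list(FEATURE_NAMES)].to_numpy(float)
    else:
        X = np.asarray(tables, dtype=float)
    if X.ndim != 2 or X.shape[1] != N_FEATURES:
        raise ValueError(f"expected (n, {N_FEATURES}) features, got {X.shape}")

    if stats is None:
        means = X.mean(axis=0)
        sds = X.std(axis=0)
    else:
        means = np.asarray(stats[0], dtype=float)
        sds = np.asarray(stats[1], dtype=float)
        if means.shape != (N_FEATURES,) or sds.shape != (N_FEATURES,):
            raise ValueError("stats must cover all 15 features")
    sds = np.maximum(sds, sd_floor)
    return (X - means) / sds, (means, sds)
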