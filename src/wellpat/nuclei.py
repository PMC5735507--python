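"""Nucleus detection and interior/exterior localization.

Stained nuclei are detected per fluorescence channel by Gaussian
smoothing, background subtraction, global thresholding, connected
components with an area filter and optional watershed splitting of
touching nuclei; detections are reduced to intensity-weighted centroids
in micrometres.

Each nucleus is then assigned to a well by minimum Euclidean
centroid-to-centroid distance and classified as *interior* (distance at
most the inner well radius — the boundary counts as interior) or
*exterior*, which covers both the annular lip and the flat substrate
beyond it.  Analyses that mirror the 400-well random-sampling protocol
assign among the sampled wells only; the ``in_sampled_set`` flag
records whether the nucleus actually belongs to the sampled
neighbourhood (its nearest well over the full array is a sampled one),
which is what restricts the summary statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .detect import WellDetectionSet
from .errors import AssignmentError, DegenerateThresholdError
from .layout import ArrayLayout


@dataclass(frozen=True)
class NucleusParams:
    """Detection operators and their scales.

    ``blur_sigma_um`` defaults to half the nominal nucleus radius;
    the area filter keeps components between ``min_area_factor`` and
    ``max_area_factor`` times the nominal nucleus area ``pi r^2``.
    """

    nucleus_radius_um: float = 7.0
    blur_sigma_um: float | None = None
    min_area_factor: float = 0.25
    max_area_factor: float = 4.0
    split_touching: bool = True

    @property
    def sigma_um(self) -> float:
        return (
            self.blur_sigma_um
            if self.blur_sigma_um is not None
            else self.nucleus_radius_um / 2.0
        )


@dataclass(frozen=True)
class NucleusSet:
    """Detected nucleus centroids for one channel."""

    nuclei: pd.DataFrame  # columns nucleus_id, x_um, y_um, channel
    channel: str
    params: NucleusParams

    @property
    def n(self) -> int:
        return len(self.nuclei)

    def centroids_um(self) -> np.ndarray:
        return self.nuclei[["x_um", "y_um"]].to_numpy(dtype=float)


_EMPTY_NUCLEI = pd.DataFrame(
    {
        "nucleus_id": pd.Series(dtype=int),
        "x_um": pd.Series(dtype=float),
        "y_um": pd.Series(dtype=float),
        "channel": pd.Series(dtype=str),
    }
)


def detect_nuclei(
    channel_image: np.ndarray,
    pixel_scale_um_per_px: float,
    params: NucleusParams = NucleusParams(),
    channel: str = "all",
) -> NucleusSet:
    """Detect nucleus centroids in one fluorescence channel.

    Pipeline: Gaussian blur -> median background subtraction -> global
    Otsu threshold (floored at a 4-sigma robust noise level so sparse
    fields cannot pull the threshold into the background mode) ->
    8-connected components -> optional watershed split seeded at local
    maxima -> area filter -> intensity-weighted centroids.

    Raises
    ------
    DegenerateThresholdError
        If the image is exactly constant (no threshold exists).
    """
    img = np.asarray(channel_image, dtype=np.float64)
    if float(np.ptp(img)) == 0.0:
        raise DegenerateThresholdError("constant image; no threshold separates signal")
    s = pixel_scale_um_per_px
    sigma_px = params.sigma_um / s

    blurred = ndimage.gaussian_filter(img, sigma=sigma_px)
    # background level and noise from a strided subsample — the image
    # is overwhelmingly background, so this matches the full medians
    sub = blurred[::4, ::4]
    bg_level = float(np.median(sub))
    bgsub = blurred - bg_level

    otsu = threshold_otsu(bgsub)
    # robust noise floor: 4 sigma of the background estimated by MAD
    mad = float(np.median(np.abs(sub - bg_level)))
    floor = 4.0 * 1.4826 * mad
    thr = max(otsu, floor)
    mask = bgsub > thr
    if not mask.any():
        return NucleusSet(nuclei=_EMPTY_NUCLEI.copy(), channel=channel, params=params)

    labels, n_labels = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    areas = np.bincount(labels.ravel())[1:]

    if params.split_touching and n_labels:
        # only components large enough to hold two nuclei are worth a
        # splitting pass; singles (the vast majority) are left intact.
        # Lower quartile rather than median: robust to fields where
        # multiplets are common
        typical = float(np.quantile(areas, 0.25))
        split_ids = np.nonzero(areas > 1.6 * typical)[0] + 1
        if len(split_ids):
            labels = _split_components(
                labels, bgsub, split_ids, areas, typical, n_labels, params, s
            )

    nominal_area_px = math.pi * (params.nucleus_radius_um / s) ** 2
    lo = params.min_area_factor * nominal_area_px
    hi = params.max_area_factor * nominal_area_px

    flat = labels.ravel()
    nz = flat > 0
    flat_nz = flat[nz]
    weights = np.clip(bgsub.ravel()[nz], 0.0, None)
    n_final = int(flat.max())
    area = np.bincount(flat_nz, minlength=n_final + 1)[1:]
    wsum = np.bincount(flat_nz, weights=weights, minlength=n_final + 1)[1:]
    rows_idx, cols_idx = np.nonzero(labels)
    wr = np.bincount(flat_nz, weights=weights * rows_idx, minlength=n_final + 1)[1:]
    wc = np.bincount(flat_nz, weights=weights * cols_idx, minlength=n_final + 1)[1:]

    keep = (area >= lo) & (area <= hi) & (wsum > 0)
    r = wr[keep] / wsum[keep]
    c = wc[keep] / wsum[keep]
    nuclei = pd.DataFrame(
        {
            "nucleus_id": np.arange(int(keep.sum())),
            "x_um": (c + 0.5) * s,
            "y_um": (r + 0.5) * s,
            "channel": channel,
        }
    )
    if len(nuclei) == 0:
        nuclei = _EMPTY_NUCLEI.copy()
    return NucleusSet(nuclei=nuclei, channel=channel, params=params)


def _split_components(
    labels: np.ndarray,
    bgsub: np.ndarray,
    split_ids: np.ndarray,
    areas: np.ndarray,
    typical_area: float,
    n_labels: int,
    params: NucleusParams,
    pixel_scale: float,
) -> np.ndarray:
    """Split multi-nucleus components in their bounding boxes.

    Components with two or more resolvable intensity maxima are split
    by seeded watershed.  Tightly overlapping pairs whose blurred spots
    fuse into a single maximum leave only an area signature; those are
    split geometrically into ``round(area / typical_area)`` parts by
    k-means on the component's pixel positions, initialized along its
    principal axis (deterministic).
    """
    min_dist = max(int(round(params.nucleus_radius_um / pixel_scale)), 1)
    next_label = n_labels + 1
    boxes = ndimage.find_objects(labels)
    for lab_id in (int(i) for i in split_ids):
        sl = boxes[lab_id - 1]
        if sl is None:
            continue
        sub_mask = labels[sl] == lab_id
        sub_img = bgsub[sl]
        seeds = peak_local_max(
            sub_img,
            labels=sub_mask.astype(int),
            min_distance=min_dist,
            exclude_border=False,
        )
        if len(seeds) >= 2:
            markers = np.zeros(sub_mask.shape, dtype=int)
            markers[tuple(seeds.T)] = np.arange(1, len(seeds) + 1)
            ws = watershed(-sub_img, markers=markers, mask=sub_mask)
            region = labels[sl]
            region[sub_mask] = ws[sub_mask] + (next_label - 1)
            next_label += len(seeds)
            continue
        est_n = int(round(areas[lab_id - 1] / typical_area))
        if est_n < 2:
            continue
        parts = _principal_axis_kmeans(sub_mask, est_n)
        region = labels[sl]
        region[sub_mask] = parts[sub_mask] + (next_label - 1)
        next_label += est_n


    return labels


def _principal_axis_kmeans(sub_mask: np.ndarray, k: int) -> np.ndarray:
    """Deterministic k-way split of a mask along its principal axis."""
    pts = np.argwhere(sub_mask).astype(float)
    mu = pts.mean(axis=0)
    centered = pts - mu
    cov = centered.T @ centered / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, np.argmax(evals)]
    proj = centered @ axis
    qs = np.quantile(proj, (np.arange(k) + 0.5) / k)
    init = mu + qs[:, None] * axis
    # few Lloyd iterations are enough for a dumbbell-shaped mask
    assign = np.zeros(len(pts), dtype=int)
    for _ in range(10):
        d2 = ((pts[:, None, :] - init[None, :, :]) ** 2).sum(axis=2)
        new_assign = d2.argmin(axis=1)
        if np.array_equal(new_assign, assign):
            assign = new_assign
            break
        assign = new_assign
        for j in range(k):
            sel = assign == j
            if sel.any():
                init[j] = pts[sel].mean(axis=0)
    out = np.zeros(sub_mask.shape, dtype=int)
    out[tuple(pts.astype(int).T)] = assign + 1
    return out


ASSIGNMENT_COLUMNS = [
    "nucleus_id",
    "well_id",
    "distance_um",
    "location",
    "in_sampled_set",
]


def assign_nearest_well(
    nucleus_set: NucleusSet,
    detections: WellDetectionSet,
    use_sampled_only: bool = True,
) -> pd.DataFrame:
    """Assign every nucleus to its nearest well by Euclidean distance.

    With ``use_sampled_only`` (the 400-well protocol) the assigned well
    and distance are computed against the sampled subset; ties break
    toward the lowest well id.  ``in_sampled_set`` flags nuclei whose
    nearest well over *all* detections belongs to the sampled subset —
    i.e. nuclei lying in the neighbourhood the sampling selected.
    """
    if detections.n_wells == 0:
        raise AssignmentError("no detected wells to assign against")
    all_centers = detections.centers_um()
    all_ids = detections.wells["well_id"].to_numpy()

    if use_sampled_only:
        if len(detections.sampled_ids) == 0:
            raise AssignmentError("use_sampled_only=True but no sampled wells")
        in_sample = np.isin(all_ids, detections.sampled_ids)
        target_centers = all_centers[in_sample]
        target_ids = all_ids[in_sample]
    else:
        target_centers = all_centers
        target_ids = all_ids

    pts = nucleus_set.centroids_um()
    if len(pts) == 0:
        return pd.DataFrame(columns=ASSIGNMENT_COLUMNS)

    well_id, dist = _nearest_with_tiebreak(target_centers, target_ids, pts)

    if use_sampled_only:
        near_all_id, _ = _nearest_with_tiebreak(all_centers, all_ids, pts)
        in_sampled = np.isin(near_all_id, detections.sampled_ids)
    else:
        in_sampled = np.ones(len(pts), dtype=bool)

    return pd.DataFrame(
        {
            "nucleus_id": nucleus_set.nuclei["nucleus_id"].to_numpy(),
            "well_id": well_id,
            "distance_um": dist,
            "location": pd.Series([None] * len(pts), dtype=object),
            "in_sampled_set": in_sampled,
        }
    )


def _nearest_with_tiebreak(
    centers: np.ndarray, ids: np.ndarray, pts: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest centre per point; exact-distance ties -> lowest id."""
    tree = cKDTree(centers)
    k = min(4, len(centers))
    d, idx = tree.query(pts, k=k)
    if k == 1:
        d, idx = d[:, None], idx[:, None]
    out_id = np.empty(len(pts), dtype=ids.dtype)
    out_d = np.empty(len(pts), dtype=float)
    for i in range(len(pts)):
        dmin = d[i, 0]
        tied = idx[i][np.abs(d[i] - dmin) <= 1e-9 * max(dmin, 1.0)]
        out_id[i] = ids[tied].min()
        out_d[i] = dmin
    return out_id, out_d


def classify_location(
    assignment: pd.DataFrame, layout: ArrayLayout
) -> pd.DataFrame:
    """Fill the interior/exterior call from the recorded distances.

    A nucleus is *interior* iff its distance to the assigned well
    centre is at most the inner radius (boundary inclusive); the lip
    (inner < d <= outer) and everything beyond are *exterior*.
    """
    out = assignment.copy()
    out["location"] = np.where(
        out["distance_um"].to_numpy(dtype=float) <= layout.inner_radius_um,
        "interior",
        "exterior",
    )
    return out
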