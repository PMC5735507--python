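"""Well detection by normalized 2-D cross-correlation.

A noise-free annulus template is correlated against the phase channel;
each score-map local maximum above threshold becomes a well detection
after greedy non-maximum suppression and subpixel quadratic refinement.
The zero-normalized cross-correlation (ZNCC) at template position
``(i, j)`` is

    ncc(i, j) = sum[(f - mean_w(f)) * (t - mean(t))]
                / sqrt(sum (f - mean_w(f))^2 * sum (t - mean(t))^2)

with the window mean ``mean_w`` taken over the template support, so the
score is invariant to local affine intensity changes and bounded in
[-1, 1].  The fast path uses an FFT convolution for the numerator and
integral images for the window sums; a direct double-loop path with the
same conventions is kept for verification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter
from scipy.signal import fftconvolve
from scipy.spatial import cKDTree

from .errors import (
    DegenerateTemplateError,
    ResolutionError,
    SamplingError,
    TemplateSizeError,
)
from .layout import ArrayLayout
from .scene import Optics, _smooth_edge

DEFAULT_NCC_THRESHOLD = 0.5
DEFAULT_NMS_FACTOR = 0.8  # NMS radius as a fraction of the lattice pitch
DEFAULT_N_SAMPLE = 400
_VAR_EPS = 1e-10  # relative variance floor below which a window counts as flat


@dataclass(frozen=True)
class WellTemplate:
    """Synthetic matching template: one noise-free well annulus."""

    raster: np.ndarray
    center_offset_px: tuple[float, float]  # (row, col) of the well centre
    inner_radius_px: float
    outer_radius_px: float

    def __post_init__(self) -> None:
        if float(np.ptp(self.raster)) == 0.0:
            raise DegenerateTemplateError("template has zero intensity variance")


@dataclass(frozen=True)
class WellDetectionSet:
    """Detected well centres with scores, plus the analysis subset."""

    wells: pd.DataFrame  # columns well_id, x_um, y_um, ncc_score
    ncc_threshold: float
    sampled_ids: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    rng_seed: int | None = None

    @property
    def n_wells(self) -> int:
        return len(self.wells)

    def centers_um(self, sampled_only: bool = False) -> np.ndarray:
        df = self.wells
        if sampled_only:
            df = df[df["well_id"].isin(self.sampled_ids)]
        return df[["x_um", "y_um"]].to_numpy(dtype=float)

    def to_frame(self) -> pd.DataFrame:
        df = self.wells.copy()
        df["is_sampled"] = df["well_id"].isin(self.sampled_ids)
        return df


def synthesize_template(layout: ArrayLayout, optics: Optics = Optics()) -> WellTemplate:
    """Render one noise-free annulus with the phase-channel conventions."""
    s = layout.pixel_scale_um_per_px
    r_out_px = layout.outer_radius_um / s
    if layout.inner_radius_um / s < 2.0:
        raise ResolutionError(
            f"inner radius {layout.inner_radius_um} um is under 2 px at {s} um/px"
        )
    half = math.ceil(r_out_px)
    side = 2 * half + 1
    c = half  # well centre at the central pixel
    ij = np.arange(side)
    rr = np.hypot(ij[None, :] - c, ij[:, None] - c) * s
    profile = _smooth_edge(rr, layout.inner_radius_um, optics.edge_sigma_um) * (
        1.0 - _smooth_edge(rr, layout.outer_radius_um, optics.edge_sigma_um)
    )
    raster = optics.phase_background + optics.ring_amplitude * profile
    return WellTemplate(
        raster=raster,
        center_offset_px=(float(c), float(c)),
        inner_radius_px=layout.inner_radius_um / s,
        outer_radius_px=r_out_px,
    )


def _check_sizes(image: np.ndarray, template: np.ndarray) -> None:
    if template.shape[0] > image.shape[0] or template.shape[1] > image.shape[1]:
        raise TemplateSizeError(
            f"template {template.shape} exceeds image {image.shape}"
        )
    if float(np.ptp(template)) == 0.0:
        raise DegenerateTemplateError("template has zero intensity variance")


def _pad_for_full_map(image: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Pad with the image median so the valid map covers every centre pixel."""
    th, tw = template.shape
    pr0, pr1 = (th - 1) // 2, th // 2
    pc0, pc1 = (tw - 1) // 2, tw // 2
    return np.pad(
        image, ((pr0, pr1), (pc0, pc1)), mode="constant",
        constant_values=float(np.median(image)),
    )


def ncc_map(
    image: np.ndarray,
    template: np.ndarray,
    method: str = "fft",
    pad: bool = True,
) -> np.ndarray:
    """Zero-normalized cross-correlation score map.

    With ``pad=True`` (default) the image is median-padded by half the
    template so the returned map has the image's shape and
    ``map[i, j]`` scores the template centred on pixel ``(i, j)``.
    With ``pad=False`` only fully-contained offsets are scored and
    ``map[i, j]`` corresponds to template top-left at ``(i, j)``.
    Windows with (near-)zero variance score 0.
    """
    image = np.asarray(image, dtype=np.float64)
    template = np.asarray(template, dtype=np.float64)
    _check_sizes(image, template)
    if pad:
        image = _pad_for_full_map(image, template)
    if method == "fft":
        return _ncc_fft(image, template)
    if method == "direct":
        return _ncc_direct(image, template)
    raise ValueError(f"unknown method {method!r}")


def _window_sums(image: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Sliding-window sums over all valid offsets via a summed-area table."""
    th, tw = shape
    sat = np.zeros((image.shape[0] + 1, image.shape[1] + 1))
    np.cumsum(image, axis=0, out=sat[1:, 1:])
    np.cumsum(sat[1:, 1:], axis=1, out=sat[1:, 1:])
    return (
        sat[th:, tw:] - sat[:-th, tw:] - sat[th:, :-tw] + sat[:-th, :-tw]
    )


def _ncc_fft(image: np.ndarray, template: np.ndarray) -> np.ndarray:
    th, tw = template.shape
    n = th * tw
    t0 = template - template.mean()
    t_norm = math.sqrt(float((t0**2).sum()))
    if t_norm == 0.0:
        raise DegenerateTemplateError("template has zero intensity variance")

    # numerator: since sum(t0)=0, sum[(f - mean_w) t0] = sum[f t0].
    # Large mosaics correlate in float32: ~1e-6 relative error, far
    # below any detection threshold, at a fraction of the cost.
    if image.size > 4_000_000:
        num = fftconvolve(
            image.astype(np.float32), t0[::-1, ::-1].astype(np.float32), mode="valid"
        ).astype(np.float64)
    else:
        num = fftconvolve(image, t0[::-1, ::-1], mode="valid")

    win_sum = _window_sums(image, template.shape)
    win_sum2 = _window_sums(image**2, template.shape)
    win_var = win_sum2 - win_sum**2 / n
    np.clip(win_var, 0.0, None, out=win_var)

    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / (np.sqrt(win_var) * t_norm)
    # flat windows: exact variance 0 up to FFT roundoff, which is
    # relative to the window power — zero those scores by convention
    out[win_var <= _VAR_EPS * win_sum2 + _VAR_EPS] = 0.0
    np.nan_to_num(out, copy=False)
    return np.clip(out, -1.0, 1.0)


def _ncc_direct(image: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Literal double-loop ZNCC; O(H W h w), verification only."""
    th, tw = template.shape
    t0 = template - template.mean()
    t_norm = math.sqrt(float((t0**2).sum()))
    oh = image.shape[0] - th + 1
    ow = image.shape[1] - tw + 1
    out = np.zeros((oh, ow))
    for i in range(oh):
        for j in range(ow):
            win = image[i : i + th, j : j + tw]
            f0 = win - win.mean()
            f_var = float((f0**2).sum())
            if f_var <= _VAR_EPS * float((win**2).sum()) + _VAR_EPS:
                out[i, j] = 0.0
            else:
                out[i, j] = float((f0 * t0).sum()) / (math.sqrt(f_var) * t_norm)
    return np.clip(out, -1.0, 1.0)


def _quadratic_offset(s_minus: float, s0: float, s_plus: float) -> float:
    denom = s_minus - 2.0 * s0 + s_plus
    if denom >= 0.0:  # not a local max along this axis
        return 0.0
    delta = 0.5 * (s_minus - s_plus) / denom
    return float(np.clip(delta, -0.5, 0.5))


def detect_wells(
    score_map: np.ndarray,
    layout: ArrayLayout,
    ncc_threshold: float = DEFAULT_NCC_THRESHOLD,
    min_separation_um: float | None = None,
) -> WellDetectionSet:
    """Pick well centres from a centred NCC score map.

    Local maxima at or above ``ncc_threshold`` are accepted greedily in
    descending score with non-maximum suppression at
    ``min_separation_um`` (default 0.8 x pitch); ties in score break by
    row-major position.  Each accepted peak is refined to subpixel by a
    separable quadratic fit over its 3x3 neighbourhood and converted to
    micrometres.  An empty detection set (no peak above threshold) is
    returned, not raised.
    """
    if min_separation_um is None:
        min_separation_um = DEFAULT_NMS_FACTOR * layout.pitch_um
    score_map = np.asarray(score_map, dtype=float)

    is_peak = (score_map >= ncc_threshold) & (
        score_map >= maximum_filter(score_map, size=3, mode="nearest")
    )
    pr, pc = np.nonzero(is_peak)
    scores = score_map[pr, pc]
    # descending score, row-major tie-break
    order = np.lexsort((pc, pr, -scores))
    pr, pc, scores = pr[order], pc[order], scores[order]

    sep_px = min_separation_um / layout.pixel_scale_um_per_px
    kept: list[int] = []
    kept_rc: list[tuple[int, int]] = []
    cell: dict[tuple[int, int], list[int]] = {}
    cs = max(sep_px, 1.0)
    for k in range(len(scores)):
        r, c = int(pr[k]), int(pc[k])
        gi, gj = int(r / cs), int(c / cs)
        ok = True
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for m in cell.get((gi + di, gj + dj), ()):
                    rr, cc = kept_rc[m]
                    if (r - rr) ** 2 + (c - cc) ** 2 < sep_px**2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            cell.setdefault((gi, gj), []).append(len(kept))
            kept_rc.append((r, c))
            kept.append(k)

    h, w = score_map.shape
    rows = []
    for idx, k in enumerate(kept):
        r, c = kept_rc[idx]
        dr = dc = 0.0
        if 0 < r < h - 1:
            dr = _quadratic_offset(score_map[r - 1, c], score_map[r, c], score_map[r + 1, c])
        if 0 < c < w - 1:
            dc = _quadratic_offset(score_map[r, c - 1], score_map[r, c], score_map[r, c + 1])
        x_um, y_um = layout.px_to_um(np.array([r + dr, c + dc]))
        rows.append((idx, float(x_um), float(y_um), float(scores[k])))

    wells = pd.DataFrame(rows, columns=["well_id", "x_um", "y_um", "ncc_score"])
    if len(wells) == 0:
        wells = wells.astype({"well_id": int})
    return WellDetectionSet(wells=wells, ncc_threshold=float(ncc_threshold))


def sample_wells(
    detections: WellDetectionSet,
    n: int = DEFAULT_N_SAMPLE,
    rng_seed: int | None = None,
) -> WellDetectionSet:
    """Uniform sample of ``n`` detected wells without replacement."""
    if n > detections.n_wells:
        raise SamplingError(
            f"requested {n} wells but only {detections.n_wells} detected"
        )
    rng = np.random.default_rng(rng_seed)
    ids = detections.wells["well_id"].to_numpy()
    sampled = np.sort(rng.choice(ids, size=n, replace=False))
    return replace(detections, sampled_ids=sampled, rng_seed=rng_seed)


def detection_errors_um(
    detections: WellDetectionSet, true_centers_um: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Match detections to true centres; returns (distances_um, true_index).

    Each detection is matched to its nearest true centre — a QC helper
    for synthetic scenes where truth is known.
    """
    tree = cKDTree(np.asarray(true_centers_um, dtype=float))
    det = detections.centers_um()
    d, idx = tree.query(det)
    return d, idx
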