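"""Synthetic microwell scenes: cell placement and image rendering.

``sample_cells`` draws a ground-truth cell table for one array under a
:class:`~wellpat.conditions.SeedingCondition`; ``render_scene`` turns
layout + ground truth into a four-channel image set that mimics the
acquisition used on real arrays: a phase-contrast-like channel showing
the well rings, a blue all-nuclei channel, a red dead/dying-nuclei
channel and a green live-cytoplasm channel (rendered for completeness,
never quantified).

The rendering model is deliberately simple: wells are smooth-edged
annuli, nuclei are Gaussian spots (nuclear stain blurred by a wide-field
PSF), noise is Gaussian read noise plus shot noise in the high-count
Gaussian approximation.  See docs/methods.md for what this does and
does not emulate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import erf

from .conditions import SeedingCondition
from .errors import ConfigError, ResolutionError
from .layout import ArrayLayout

GROUND_TRUTH_COLUMNS = ["cell_id", "x_um", "y_um", "well_id", "is_interior", "is_dead"]


@dataclass(frozen=True)
class SceneGroundTruth:
    """True cell positions and labels for one synthetic array."""

    cells: pd.DataFrame  # columns GROUND_TRUTH_COLUMNS
    condition: SeedingCondition
    layout: ArrayLayout

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass(frozen=True)
class Optics:
    """Rendering parameters.

    Intensities are fractions of the dynamic range of the output bit
    depth.  The nucleus spot sigma combines the nominal nuclear radius
    with the PSF width in quadrature (a stained nucleus imaged through
    a low-NA 4x objective is well approximated by a Gaussian blob).
    """

    psf_sigma_um: float = 2.0
    nucleus_radius_um: float = 7.0
    cyto_radius_um: float = 15.0
    background: float = 0.05
    nucleus_amplitude: float = 0.30
    cyto_amplitude: float = 0.10
    phase_background: float = 0.50
    ring_amplitude: float = -0.25  # dark annulus on brighter background
    edge_sigma_um: float = 1.0  # softness of the annulus edges
    read_noise_frac: float = 0.02
    shot_noise: bool = True
    bit_depth: int = 16

    @property
    def dynamic_range(self) -> float:
        return float(2**self.bit_depth - 1)

    @property
    def spot_sigma_um(self) -> float:
        return math.hypot(self.nucleus_radius_um / 2.0, self.psf_sigma_um)


@dataclass(frozen=True)
class ImageSet:
    """One rendered scene; all channels share shape and pixel scale."""

    phase: np.ndarray
    nuclei_all: np.ndarray
    nuclei_dead: np.ndarray
    live_cyto: np.ndarray
    pixel_scale_um_per_px: float

    def __post_init__(self) -> None:
        shapes = {
            self.phase.shape,
            self.nuclei_all.shape,
            self.nuclei_dead.shape,
            self.live_cyto.shape,
        }
        if len(shapes) != 1:
            raise ConfigError(f"channel shapes differ: {shapes}")

    @property
    def channels(self) -> dict[str, np.ndarray]:
        return {
            "phase": self.phase,
            "nuclei_all": self.nuclei_all,
            "nuclei_dead": self.nuclei_dead,
            "live_cyto": self.live_cyto,
        }


def _draw_occupancy(
    rng: np.random.Generator, condition: SeedingCondition, n_wells: int
) -> np.ndarray:
    """Per-well cell counts under the condition's loading model."""
    if condition.occupancy_dist is not None:
        ks = np.array(sorted(condition.occupancy_dist), dtype=int)
        ps = np.array([condition.occupancy_dist[k] for k in ks], dtype=float)
        ps = ps / ps.sum()
        return ks[rng.choice(len(ks), size=n_wells, p=ps)]
    return rng.poisson(condition.poisson_lambda, size=n_wells)


def sample_cells(
    layout: ArrayLayout,
    condition: SeedingCondition,
    rng: np.random.Generator | int | None = None,
    lip_fraction: float = 0.5,
) -> SceneGroundTruth:
    """Draw ground-truth cell positions for one array.

    Per well, a cell count is drawn from the condition's occupancy
    model.  Each cell independently lands in the well interior with
    probability ``p_interior`` (uniform over the inner disk); otherwise
    it is exterior — on the annular lip with probability
    ``lip_fraction`` or on the flat substrate within one pitch of the
    well centre.  Exterior positions are rejection-sampled so that no
    exterior cell sits inside any well's inner radius and every cell
    stays inside the footprint.  Dead/dying labels are i.i.d. Bernoulli
    with the condition's ``dead_fraction``.
    """
    if not 0.0 <= lip_fraction <= 1.0:
        raise ConfigError("lip_fraction outside [0, 1]")
    if rng is None:
        rng = condition.rng_seed
    rng = np.random.default_rng(rng)

    centers = layout.well_centers
    counts = _draw_occupancy(rng, condition, layout.n_wells)
    tree = cKDTree(centers) if layout.n_wells else None
    w, h = layout.footprint_um
    r_in, r_out, pitch = (
        layout.inner_radius_um,
        layout.outer_radius_um,
        layout.pitch_um,
    )

    rows: list[tuple] = []
    cell_id = 0
    for well_id, n in enumerate(counts):
        cx, cy = centers[well_id]
        for _ in range(int(n)):
            interior = bool(rng.random() < condition.p_interior)
            if interior:
                r = r_in * math.sqrt(rng.random())
                th = rng.random() * 2 * math.pi
                x, y = cx + r * math.cos(th), cy + r * math.sin(th)
            else:
                on_lip = rng.random() < lip_fraction
                lo2, hi2 = (r_in**2, r_out**2) if on_lip else (r_out**2, pitch**2)
                for _attempt in range(200):
                    r = math.sqrt(lo2 + (hi2 - lo2) * rng.random())
                    th = rng.random() * 2 * math.pi
                    x, y = cx + r * math.cos(th), cy + r * math.sin(th)
                    if not (0.0 <= x <= w and 0.0 <= y <= h):
                        continue
                    # exterior cells must not fall inside any well interior
                    d, _ = tree.query([x, y])
                    if d > r_in:
                        break
                else:  # pragma: no cover - pathological geometry only
                    x, y = cx + r_out + 1.0, cy
            dead = bool(rng.random() < condition.dead_fraction)
            rows.append((cell_id, x, y, well_id, interior, dead))
            cell_id += 1

    cells = pd.DataFrame(rows, columns=GROUND_TRUTH_COLUMNS)
    if len(cells) == 0:
        cells = pd.DataFrame(
            {
                "cell_id": pd.Series(dtype=int),
                "x_um": pd.Series(dtype=float),
                "y_um": pd.Series(dtype=float),
                "well_id": pd.Series(dtype=int),
                "is_interior": pd.Series(dtype=bool),
                "is_dead": pd.Series(dtype=bool),
            }
        )
    return SceneGroundTruth(cells=cells, condition=condition, layout=layout)


def _smooth_edge(r: np.ndarray, r0: float, sigma: float) -> np.ndarray:
    """0 -> 1 transition of width ``sigma`` centred at radius ``r0``."""
    return 0.5 * (1.0 + erf((r - r0) / (sigma * math.sqrt(2.0))))


def _add_annulus(
    canvas: np.ndarray,
    layout: ArrayLayout,
    cx: float,
    cy: float,
    amplitude: float,
    edge_sigma_um: float,
) -> None:
    s = layout.pixel_scale_um_per_px
    half = layout.outer_radius_um + 4 * edge_sigma_um
    h, w = canvas.shape
    c0 = max(int((cx - half) / s), 0)
    c1 = min(int((cx + half) / s) + 2, w)
    r0 = max(int((cy - half) / s), 0)
    r1 = min(int((cy + half) / s) + 2, h)
    if c0 >= c1 or r0 >= r1:
        return
    xs = (np.arange(c0, c1) + 0.5) * s - cx
    ys = (np.arange(r0, r1) + 0.5) * s - cy
    rr = np.hypot(xs[None, :], ys[:, None])
    profile = _smooth_edge(rr, layout.inner_radius_um, edge_sigma_um) * (
        1.0 - _smooth_edge(rr, layout.outer_radius_um, edge_sigma_um)
    )
    canvas[r0:r1, c0:c1] += amplitude * profile


def _add_spots(
    canvas: np.ndarray,
    layout: ArrayLayout,
    xs_um: np.ndarray,
    ys_um: np.ndarray,
    amplitude: float,
    sigma_um: float,
) -> None:
    s = layout.pixel_scale_um_per_px
    half = 4.0 * sigma_um
    h, w = canvas.shape
    for cx, cy in zip(xs_um, ys_um):
        c0 = max(int((cx - half) / s), 0)
        c1 = min(int((cx + half) / s) + 2, w)
        r0 = max(int((cy - half) / s), 0)
        r1 = min(int((cy + half) / s) + 2, h)
        if c0 >= c1 or r0 >= r1:
            continue
        px = (np.arange(c0, c1) + 0.5) * s - cx
        py = (np.arange(r0, r1) + 0.5) * s - cy
        g = np.exp(-(px[None, :] ** 2 + py[:, None] ** 2) / (2.0 * sigma_um**2))
        canvas[r0:r1, c0:c1] += amplitude * g


def render_phase(
    layout: ArrayLayout, optics: Optics = Optics()
) -> np.ndarray:
    """Noise-free phase-contrast-like channel: every well as an annulus."""
    canvas = np.full(layout.shape_px, optics.phase_background, dtype=np.float32)
    for cx, cy in layout.well_centers:
        _add_annulus(canvas, layout, cx, cy, optics.ring_amplitude, optics.edge_sigma_um)
    return canvas


def _apply_noise(
    frac_image: np.ndarray, optics: Optics, rng: np.random.Generator
) -> np.ndarray:
    # shot noise in the high-count Gaussian approximation N(0, sqrt(I))
    # and Gaussian read noise, combined into one draw:
    # N(0, sqrt(I)) + N(0, r) = N(0, sqrt(I + r^2))
    dr = optics.dynamic_range
    img = (frac_image * dr).astype(np.float32)
    var = np.zeros_like(img)
    if optics.shot_noise:
        var += np.clip(img, 0, None)
    if optics.read_noise_frac > 0:
        var += np.float32((optics.read_noise_frac * dr) ** 2)
    if var.any():
        img += rng.standard_normal(img.shape, dtype=np.float32) * np.sqrt(var)
    return img


def _quantize(img: np.ndarray, optics: Optics) -> np.ndarray:
    dr = optics.dynamic_range
    dtype = np.uint16 if optics.bit_depth > 8 else np.uint8
    return np.clip(np.rint(img), 0, dr).astype(dtype)


def render_scene(
    layout: ArrayLayout,
    ground_truth: SceneGroundTruth,
    optics: Optics = Optics(),
    rng: np.random.Generator | int | None = None,
    noise: bool = True,
    render_live_cyto: bool = True,
) -> ImageSet:
    """Render the four acquisition channels for one scene.

    Noise is applied last from a seeded generator; ``noise=False``
    yields the deterministic noise-free render.  Raises
    :class:`ResolutionError` if the nucleus spot would span fewer than
    two pixels at the layout's pixel scale.
    """
    s = layout.pixel_scale_um_per_px
    if 2.0 * optics.nucleus_radius_um / s < 2.0:
        raise ResolutionError(
            f"nucleus diameter {2 * optics.nucleus_radius_um} um is under "
            f"2 px at {s} um/px"
        )
    rng = np.random.default_rng(rng)
    cells = ground_truth.cells
    dead = cells["is_dead"].to_numpy(dtype=bool) if len(cells) else np.zeros(0, bool)
    xs = cells["x_um"].to_numpy(dtype=float)
    ys = cells["y_um"].to_numpy(dtype=float)

    phase = render_phase(layout, optics)

    nuclei_all = np.full(layout.shape_px, optics.background, dtype=np.float32)
    _add_spots(nuclei_all, layout, xs, ys, optics.nucleus_amplitude, optics.spot_sigma_um)

    nuclei_dead = np.full(layout.shape_px, optics.background, dtype=np.float32)
    _add_spots(
        nuclei_dead,
        layout,
        xs[dead],
        ys[dead],
        optics.nucleus_amplitude,
        optics.spot_sigma_um,
    )

    live_cyto = np.full(layout.shape_px, optics.background, dtype=np.float32)
    if render_live_cyto:
        cyto_sigma = math.hypot(optics.cyto_radius_um / 2.0, optics.psf_sigma_um)
        _add_spots(
            live_cyto, layout, xs[~dead], ys[~dead], optics.cyto_amplitude, cyto_sigma
        )

    channels = {}
    for name, img in (
        ("phase", phase),
        ("nuclei_all", nuclei_all),
        ("nuclei_dead", nuclei_dead),
        ("live_cyto", live_cyto),
    ):
        if noise and (name != "live_cyto" or render_live_cyto):
            out = _apply_noise(img, optics, rng)
        else:
            out = img * optics.dynamic_range
        channels[name] = _quantize(out, optics)

    return ImageSet(pixel_scale_um_per_px=s, **channels)
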