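"""Cell sampling and image rendering."""

import math

import numpy as np
import pytest
from scipy.spatial import cKDTree

import wellpat as wp
from wellpat.errors import ResolutionError
from wellpat.scene import Optics

from conftest import make_ground_truth


def _dist_to_own_well(gt):
    centers = gt.layout.well_centers[gt.cells["well_id"].to_numpy()]
    return np.hypot(
        gt.cells["x_um"].to_numpy() - centers[:, 0],
        gt.cells["y_um"].to_numpy() - centers[:, 1],
    )


def test_sampling_is_reproducible_under_fixed_seed(small_layout):
    cond = wp.condition_defaults("HME1", 100, True)
    a = wp.sample_cells(small_layout, cond, rng=7)
    b = wp.sample_cells(small_layout, cond, rng=7)
    assert a.cells.equals(b.cells)
    c = wp.sample_cells(small_layout, cond, rng=8)
    assert not a.cells.equals(c.cells)


def test_deterministic_limit_every_well_one_interior_cell(small_layout):
    cond = wp.SeedingCondition(
        name="limit",
        density_cells_per_mL=1.0,
        occupancy_dist={1: 1.0},
        p_interior=1.0,
        dead_fraction=0.0,
    )
    gt = wp.sample_cells(small_layout, cond, rng=0)
    assert gt.n_cells == small_layout.n_wells
    assert gt.cells["is_interior"].all()
    assert sorted(gt.cells["well_id"]) == list(range(small_layout.n_wells))


def test_interior_cells_lie_within_inner_radius_exactly(small_layout):
    cond = wp.condition_defaults("MDA-MB-231", 200, True)
    gt = wp.sample_cells(small_layout, cond, rng=3)
    d = _dist_to_own_well(gt)
    interior = gt.cells["is_interior"].to_numpy()
    assert (d[interior] <= small_layout.inner_radius_um).all()
    assert (d[~interior] > small_layout.inner_radius_um).all()


def test_exterior_cells_avoid_every_well_interior_and_stay_in_footprint(
    small_layout,
):
    cond = wp.condition_defaults("HME1", 200, False)  # mostly exterior
    gt = wp.sample_cells(small_layout, cond, rng=5)
    ext = gt.cells[~gt.cells["is_interior"]]
    pts = ext[["x_um", "y_um"]].to_numpy()
    w, h = small_layout.footprint_um
    assert (pts[:, 0] >= 0).all() and (pts[:, 0] <= w).all()
    assert (pts[:, 1] >= 0).all() and (pts[:, 1] <= h).all()
    d, _ = cKDTree(small_layout.well_centers).query(pts)
    assert (d > small_layout.inner_radius_um).all()


def test_empirical_interior_fraction_within_3_se():
    layout = wp.build_layout(footprint_um=(2400.0, 2400.0))
    p = 0.82
    cond = wp.SeedingCondition(
        name="frac",
        density_cells_per_mL=1.0,
        occupancy_dist={25: 1.0},  # force >= 10000 cells cheaply
        p_interior=p,
    )
    gt = wp.sample_cells(layout, cond, rng=11)
    assert gt.n_cells >= 10_000
    frac = gt.cells["is_interior"].mean()
    se = math.sqrt(p * (1 - p) / gt.n_cells)
    assert abs(frac - p) < 3 * se


def test_single_cell_occupancy_matches_generator_parameter():
    layout = wp.default_layout()  # 2980 wells
    cond = wp.condition_defaults("K562", 100, True)
    gt = wp.sample_cells(layout, cond, rng=2)
    counts = gt.cells.groupby("well_id").size()
    frac1 = (counts == 1).sum() / layout.n_wells
    p1 = cond.occupancy_dist[1]
    se = math.sqrt(p1 * (1 - p1) / layout.n_wells)
    assert abs(frac1 - p1) < 3 * se


def test_poisson_loading_matches_closed_form():
    layout = wp.default_layout()
    lam = wp.poisson_lambda_from_density(100_000)
    cond = wp.SeedingCondition(
        name="poisson", density_cells_per_mL=100_000.0, p_interior=0.5
    )
    gt = wp.sample_cells(layout, cond, rng=4)
    counts = gt.cells.groupby("well_id").size()
    n = layout.n_wells
    occ = np.bincount(
        np.minimum(counts.reindex(range(n), fill_value=0).to_numpy(), 10), minlength=11
    )
    for k in range(4):
        p = math.exp(-lam) * lam**k / math.factorial(k)
        # 99% multinomial CI per bin
        half = 2.576 * math.sqrt(p * (1 - p) / n)
        assert abs(occ[k] / n - p) < half, f"bin {k}"


def test_dead_flags_follow_dead_fraction(small_layout):
    cond = wp.condition_defaults("MDA-MB-231", 400, True)
    gt = wp.sample_cells(small_layout, cond, rng=6)
    frac = gt.cells["is_dead"].mean()
    se = math.sqrt(0.03 * 0.97 / gt.n_cells)
    assert abs(frac - 0.03) < 4 * se


# ---------------------------------------------------------------- rendering


def test_empty_scene_renders_uniform_background(tiny_layout):
    gt = make_ground_truth(tiny_layout, np.zeros((0, 2)))
    images = wp.render_scene(tiny_layout, gt, Optics(), noise=False)
    bg = round(Optics().background * Optics().dynamic_range)
    assert (images.nuclei_all == bg).all()
    assert (images.nuclei_dead == bg).all()


def test_single_spot_renders_at_the_true_position(tiny_layout):
    pos = (211.0, 147.0)
    gt = make_ground_truth(tiny_layout, [pos])
    images = wp.render_scene(tiny_layout, gt, Optics(), noise=False)
    r, c = np.unravel_index(np.argmax(images.nuclei_all), images.nuclei_all.shape)
    x, y = tiny_layout.px_to_um(np.array([float(r), float(c)]))
    s = tiny_layout.pixel_scale_um_per_px
    assert abs(x - pos[0]) <= s and abs(y - pos[1]) <= s


def test_spot_integral_matches_gaussian_quadrature(tiny_layout):
    optics = Optics()
    gt = make_ground_truth(tiny_layout, [(300.0, 300.0)])
    images = wp.render_scene(tiny_layout, gt, optics, noise=False)
    # the quantized background level, not the pre-quantization float —
    # a 0.25 DN rounding bias over the full canvas would otherwise leak in
    bg = float(np.median(images.nuclei_all))
    total = float((images.nuclei_all.astype(float) - bg).sum())
    sigma_px = optics.spot_sigma_um / tiny_layout.pixel_scale_um_per_px
    expected = optics.nucleus_amplitude * optics.dynamic_range * 2 * math.pi * sigma_px**2
    assert total == pytest.approx(expected, rel=0.02)


def test_dead_channel_renders_only_dead_cells(tiny_layout):
    gt = make_ground_truth(
        tiny_layout, [(150.0, 150.0), (400.0, 400.0)], dead=[True, False]
    )
    images = wp.render_scene(tiny_layout, gt, Optics(), noise=False)
    bg = round(Optics().background * Optics().dynamic_range)
    dead_signal = images.nuclei_dead.astype(float) - bg
    r, c = np.unravel_index(np.argmax(dead_signal), dead_signal.shape)
    x, y = tiny_layout.px_to_um(np.array([float(r), float(c)]))
    assert math.hypot(x - 150.0, y - 150.0) < 2 * tiny_layout.pixel_scale_um_per_px
    # the live cell's position carries no dead-channel signal
    rc = tiny_layout.um_to_px(np.array([400.0, 400.0])).round().astype(int)
    assert dead_signal[rc[0], rc[1]] == 0


def test_rendered_shape_and_dtype(tiny_layout):
    gt = make_ground_truth(tiny_layout, np.zeros((0, 2)))
    images = wp.render_scene(tiny_layout, gt, Optics(), noise=False)
    assert images.phase.shape == tiny_layout.shape_px
    assert images.phase.dtype == np.uint16


def test_render_is_bit_reproducible(tiny_layout):
    cond = wp.condition_defaults("HME1", 100, True)
    gt = wp.sample_cells(tiny_layout, cond, rng=1)
    a = wp.render_scene(tiny_layout, gt, Optics(), rng=9, noise=True)
    b = wp.render_scene(tiny_layout, gt, Optics(), rng=9, noise=True)
    assert (a.nuclei_all == b.nuclei_all).all()
    assert (a.phase == b.phase).all()


def test_coarse_pixel_scale_raises_resolution_error():
    layout = wp.build_layout(footprint_um=(600.0, 600.0), pixel_scale_um_per_px=10.0)
    gt = make_ground_truth(layout, [(300.0, 300.0)])
    with pytest.raises(ResolutionError):
        wp.render_scene(layout, gt, Optics(), noise=False)
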