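"""Optical disector: Z histogram, guard zones, counting-frame rule, Nv, CE."""

import numpy as np
import pytest

from neurostereo import (CountingWindow, DisectorConfig, StudyConfig,
                         ZHistogram, ce_number, disector_pipeline,
                         estimate_nv, estimate_total_number, generate_phantom,
                         optical_disector_tally, section_phantom,
                         select_counting_window, zaxis_histogram)
from neurostereo.number import DisectorTally, frame_accepts
from neurostereo.phantom import NEURON


def _tally(sum_q, n_frames, t_bar, per_section=None):
    q_each, rem = divmod(sum_q, n_frames)
    fields = [(0, 0.0, 0.0, q_each + (1 if i < rem else 0), t_bar)
              for i in range(n_frames)]
    return DisectorTally(sum_q=sum_q, sum_frames=n_frames,
                         mean_thickness=t_bar, fields=fields,
                         per_section_q=per_section or [sum_q])


# -- Z-axis histogram -------------------------------------------------------

def test_histogram_uniform_depths(rng):
    t = 23.0
    z = rng.uniform(0, t, 5000)
    hist = zaxis_histogram(np.column_stack([z, np.full(5000, t)]))
    assert hist.percentages.sum() == pytest.approx(100.0)
    assert np.all(np.abs(hist.percentages - 10.0) < 2.5)


def test_histogram_degenerate_top():
    pairs = np.column_stack([np.zeros(50), np.full(50, 23.0)])
    hist = zaxis_histogram(pairs)
    assert hist.percentages[0] == 100.0
    assert np.all(hist.percentages[1:] == 0.0)


def test_histogram_detects_lost_caps(rng):
    t = 23.0
    z = rng.uniform(0.1 * t, t, 2000)  # no events in the top 10%
    hist = zaxis_histogram(np.column_stack([z, np.full(2000, t)]))
    assert hist.percentages[0] == 0.0


def test_histogram_rejects_bad_depths():
    with pytest.raises(ValueError):
        zaxis_histogram(np.array([[25.0, 23.0]]))
    with pytest.raises(ValueError):
        zaxis_histogram(np.empty((0, 2)))


# -- counting window --------------------------------------------------------

def test_window_uniform_arithmetic():
    hist = ZHistogram(np.full(10, 10.0))
    win = select_counting_window(hist, 0.10, 0.20, 23.0)
    assert win.height == pytest.approx(16.1)
    assert win.included_nucleus_fraction == pytest.approx(70.0)


def test_window_no_guards_is_identity():
    hist = ZHistogram(np.full(10, 10.0))
    win = select_counting_window(hist, 0.0, 0.0, 23.0)
    assert win.height == pytest.approx(23.0)
    assert win.included_nucleus_fraction == pytest.approx(100.0)


def test_window_captures_mid_section_concentration():
    # mass concentrated mid-section: guards exclude little
    bins = np.array([0.0, 5.0, 15.0, 20.0, 20.0, 20.0, 15.0, 5.0, 0.0, 0.0])
    win = select_counting_window(ZHistogram(bins), 0.10, 0.20, 23.0)
    assert win.included_nucleus_fraction > 70.0


def test_window_rejects_full_guards():
    hist = ZHistogram(np.full(10, 10.0))
    with pytest.raises(ValueError):
        select_counting_window(hist, 0.6, 0.4, 23.0)


# -- unbiased counting frame ------------------------------------------------

def test_frame_rule_interior_and_forbidden():
    side = 10.0
    # centred nucleus: counted
    assert frame_accepts(5.0, 5.0, 2.0, 0.0, 0.0, side).all()
    # touching the left forbidden line: rejected
    assert not frame_accepts(0.0, 5.0, 2.0, 0.0, 0.0, side).any()
    # touching the bottom forbidden line: rejected
    assert not frame_accepts(5.0, 0.0, 2.0, 0.0, 0.0, side).any()
    # touching only the acceptance (top/right) edges: counted
    assert frame_accepts(10.0, 5.0, 2.0, 0.0, 0.0, side).all()
    assert frame_accepts(5.0, 10.0, 2.0, 0.0, 0.0, side).all()
    # on the upward extension of the left edge above the frame: rejected
    assert not frame_accepts(0.0, 14.0, 2.0, 0.0, 0.0, side).any()
    # on the downward extension of the right edge below the frame: rejected,
    # even though the circle does not overlap this frame at all
    assert not frame_accepts(10.0, -1.0, 2.0, 0.0, 0.0, side).any()


def test_frame_tiling_counts_each_profile_once(rng):
    """Over a tiling of frames, every circle is counted exactly once."""
    side = 10.0
    centers = rng.uniform(5.0, 45.0, size=(200, 2))
    radii = rng.uniform(0.5, 2.0, size=200)
    counts = np.zeros(200, dtype=int)
    for fx in np.arange(-10.0, 51.0, side):
        for fy in np.arange(-10.0, 51.0, side):
            counts += frame_accepts(centers[:, 0], centers[:, 1], radii,
                                    fx, fy, side)
    assert np.all(counts == 1)


def test_exhaustive_disector_recovers_every_cell():
    cfg = StudyConfig(groups=("control",), neuron_count_true=300,
                      glia_per_neuron_mean=0.0, seed=3)
    ph = generate_phantom(cfg, "control", 0)
    stack = section_phantom(ph, seed=1)
    side = np.sqrt(3492.0)
    dc = DisectorConfig(step_x=side, step_y=side, frame_placement="cover")
    win = CountingWindow(0.0, 0.0, stack.mean_thickness, 100.0)
    tally = optical_disector_tally(stack, dc, win, seed=2)
    assert tally.sum_q == ph.true_counts[NEURON]


def test_empty_stack_counts_zero_with_frames_placed():
    cfg = StudyConfig(groups=("control",), neuron_count_true=0,
                      glia_per_neuron_mean=0.0, seed=1)
    with pytest.warns(UserWarning):
        ph = generate_phantom(cfg, "control", 0)
    with pytest.warns(UserWarning):
        stack = section_phantom(ph, seed=0)
    win = CountingWindow(0.1, 0.2, 16.1, 70.0)
    tally = optical_disector_tally(stack, DisectorConfig(), win, seed=0)
    assert tally.sum_q == 0
    assert tally.sum_frames > 0


# -- Nv and N ---------------------------------------------------------------

def test_nv_formula_hand_value():
    tally = _tally(100, 200, 23.0)
    cfg = DisectorConfig(frame_area=3492.0, block_advance=25.0)
    win = CountingWindow(0.0, 0.0, 15.0, 100.0)
    nv = estimate_nv(tally, cfg, win)
    assert nv == pytest.approx(100 / (200 * 3492.0 * 15.0) * (23.0 / 25.0))
    assert nv == pytest.approx(8.782e-6, rel=1e-3)


def test_nv_zero_counts():
    tally = _tally(0, 50, 23.0)
    nv = estimate_nv(tally, DisectorConfig(), CountingWindow(0, 0, 15.0, 100.0))
    assert nv == 0.0


def test_nv_linearity_in_frames():
    cfg = DisectorConfig()
    win = CountingWindow(0.0, 0.0, 15.0, 100.0)
    nv1 = estimate_nv(_tally(100, 200, 23.0), cfg, win)
    nv2 = estimate_nv(_tally(100, 400, 23.0), cfg, win)
    assert nv2 == pytest.approx(nv1 / 2.0)


def test_thickness_correction_cancels_when_t_equals_ba():
    cfg = DisectorConfig(block_advance=25.0)
    win = CountingWindow(0.0, 0.0, 15.0, 100.0)
    nv = estimate_nv(_tally(100, 200, 25.0), cfg, win)
    assert nv == pytest.approx(100 / (200 * cfg.frame_area * 15.0))


def test_total_number_product():
    est = estimate_total_number(8.782e-6, 3.0e7)
    assert est.n_total == pytest.approx(263.5, rel=1e-3)
    assert estimate_total_number(1.0e-5, 0.0).n_total == 0.0


# -- CE of the number estimate ---------------------------------------------

def test_ce_number_poisson_term():
    tally = _tally(400, 40, 23.0, per_section=[40] * 10)
    # constant per-section counts leave only the end-term of the SURS part
    assert ce_number(tally) == pytest.approx(1 / np.sqrt(400), rel=0.02)
    tally500 = _tally(500, 50, 23.0, per_section=[50] * 10)
    assert ce_number(tally500) == pytest.approx(0.0447, abs=0.002)


def test_ce_number_surs_term_matches_brute_force():
    q = [40, 42, 41, 39, 40, 41, 40, 39, 41, 40]
    total = sum(q)
    c0 = sum(x * x for x in q)
    c1 = sum(q[i] * q[i + 1] for i in range(len(q) - 1))
    c2 = sum(q[i] * q[i + 2] for i in range(len(q) - 2))
    expected = np.sqrt(1.0 / total + ((3 * c0 - 4 * c1 + c2) / 240.0) / total**2)
    tally = _tally(total, 40, 23.0, per_section=q)
    assert ce_number(tally) == pytest.approx(expected)


def test_ce_number_rejects_zero_counts():
    with pytest.raises(ValueError):
        ce_number(_tally(0, 10, 23.0))


# -- end-to-end recovery ----------------------------------------------------

def test_disector_pipeline_recovers_truth(small_config):
    ph = generate_phantom(small_config, "control", 0)
    stack = section_phantom(ph, seed=1)
    est, tally, win = disector_pipeline(stack, ph.true_volume, seed=2)
    assert tally.sum_q > 0
    assert 0 < win.height < stack.mean_thickness
    assert est.n_total == pytest.approx(ph.true_counts[NEURON], rel=0.25)
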