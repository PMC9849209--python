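"""Focus detection, skewness, heatmaps and colocalisation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conjview import (
    FocusParams,
    classify_focus,
    colocalise,
    detect_foci,
    heatmap,
    skewness,
)
from conjview.foci import FocusDetection


def _spot_patch(amplitudes_positions, shape=(41, 41), base=100.0, sigma=1.3):
    img = np.full(shape, base)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for amp, (y, x) in amplitudes_positions:
        img += amp / (2 * math.pi * sigma**2) * np.exp(
            -((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma**2)
        )
    return img


def test_single_spot_detected_at_subpixel_accuracy():
    img = _spot_patch([(2000.0, (20.3, 18.7))])
    mask = np.ones(img.shape, bool)
    dets = detect_foci(img, mask, "ypet", pixel_size_um=1.0)
    assert len(dets) == 1
    assert math.hypot(dets[0].y_um - 20.3, dets[0].x_um - 18.7) <= 0.5


def test_no_foci_returns_empty_list_not_error():
    img = np.full((21, 21), 50.0)
    assert detect_foci(img, np.ones((21, 21), bool), "ypet") == []


def test_small_patch_rejected():
    with pytest.raises(ValueError):
        detect_foci(np.zeros((4, 4)), np.ones((4, 4), bool), "ypet")


def test_intensity_additive_with_amplitude():
    """Doubling the rendered amplitude doubles the measured intensity (5%)."""
    d1 = detect_foci(_spot_patch([(2000.0, (20, 20))]), np.ones((41, 41), bool), "ypet")
    d2 = detect_foci(_spot_patch([(4000.0, (20, 20))]), np.ones((41, 41), bool), "ypet")
    assert d2[0].intensity / d1[0].intensity == pytest.approx(2.0, rel=0.05)


def test_35_to_1_intensity_pair_recovered():
    img = _spot_patch([(35 * 2000.0, (12, 10)), (2000.0, (30, 30))])
    dets = detect_foci(img, np.ones((41, 41), bool), "ypet")
    assert len(dets) == 2
    ratio = max(d.intensity for d in dets) / min(d.intensity for d in dets)
    assert ratio == pytest.approx(35.0, rel=0.10)


# ---------------------------------------------------------------------------
# skewness


def _skew_bruteforce(values):
    """Plain-Python moment computation, independent of the implementation."""
    n = len(values)
    mean = sum(values) / n
    m2 = sum((v - mean) ** 2 for v in values) / n
    m3 = sum((v - mean) ** 3 for v in values) / n
    return m3 / m2**1.5


def test_skewness_hand_example():
    assert skewness(np.array([1, 1, 1, 1, 10.0])) == pytest.approx(1.5, abs=1e-12)


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2**32 - 1), st.integers(10, 10_000))
def test_skewness_matches_bruteforce_moments(seed, n):
    x = np.random.default_rng(seed).normal(5.0, 2.0, n) ** 2
    assert skewness(x) == pytest.approx(_skew_bruteforce(list(x)), rel=1e-12)


@settings(max_examples=20, deadline=None)
@given(st.integers(0, 2**32 - 1), st.floats(0.1, 50.0), st.floats(-100.0, 100.0))
def test_skewness_invariant_under_affine_gain(seed, a, b):
    x = np.random.default_rng(seed).exponential(3.0, 500)
    assert skewness(a * x + b) == pytest.approx(skewness(x), rel=1e-6)


def test_skewness_degenerate_cases():
    with pytest.raises(ValueError):
        skewness(np.array([1.0, 2.0]))
    with pytest.warns(UserWarning):
        assert math.isnan(skewness(np.ones(10)))


def test_conjugating_cells_are_more_skewed_than_vegetative(default_field):
    """Cells hosting a bright conjugative focus concentrate fluorescence
    far more than vegetative cells with replicative foci only."""
    res = default_field
    movie = res.truth.movie
    conj_sk, veg_sk = [], []
    truth = res.truth.foci_truth
    for f in range(0, movie.n_frames, 5):
        lab = res.truth.labels[f]
        conj_cells = set(
            truth[(truth.frame == f) & (truth.focus_class == "conjugative")].cell_id
        )
        img = movie.channels["ypet"][f]
        for cid in np.unique(lab)[1:]:
            vals = img[lab == cid]
            (conj_sk if cid in conj_cells else veg_sk).append(skewness(vals))
    assert np.mean(conj_sk) > 2 * np.mean(veg_sk)


# ---------------------------------------------------------------------------
# classification and heatmaps


def test_classification_rules():
    bright_peripheral = FocusDetection(1, 0, "ypet", 0, 0, l=0.45, d=0.45, intensity=5000)
    assert classify_focus(bright_peripheral) == "conjugative"
    interior = FocusDetection(1, 0, "ypet", 0, 0, l=0.0, d=0.0, intensity=500)
    assert classify_focus(interior) == "replicative"
    red = FocusDetection(1, 0, "mcherry", 0, 0, l=0.1, d=0.0, intensity=500)
    assert classify_focus(red) == "parB"


def test_generator_labelled_foci_classified_consistently(default_field):
    """Detections matched to scripted foci agree with the scripted class."""
    res = default_field
    px = res.truth.movie.pixel_size_um
    truth = res.truth.foci_truth
    fp = res.foci[res.foci.channel == "ypet"]
    agree = total = 0
    for f, tg in truth[truth.channel == "ypet"].groupby("frame"):
        pg = fp[fp.frame == f]
        if len(pg) == 0:
            continue
        for _, r in tg.iterrows():
            d = np.hypot(pg.x_um - r.x_px * px, pg.y_um - r.y_px * px)
            j = d.idxmin()
            if d[j] <= 2 * px:
                total += 1
                agree += pg.loc[j, "focus_class"] == r.focus_class
    assert total > 500
    assert agree / total >= 0.90


def test_heatmap_density_normalisation_and_single_focus():
    f = FocusDetection(1, 0, "ypet", 0, 0, l=0.0, d=0.0, intensity=1.0)
    grid = heatmap([f], bins=(20, 10))
    assert grid.grid.sum() == pytest.approx(1.0)
    assert grid.grid.max() == 1.0  # all density in one bin
    li = np.argmax(grid.grid.sum(axis=1))
    assert li in (9, 10)  # midcell bin


def test_heatmap_mirror_fold_is_exactly_symmetric():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(
        {"l": rng.uniform(-0.5, 0.5, 300), "d": rng.uniform(-0.5, 0.5, 300)}
    )
    grid = heatmap(df, mirror_fold=True)
    np.testing.assert_array_equal(grid.grid, grid.grid[::-1, :])
    assert grid.grid.sum() == pytest.approx(1.0)


def test_recipient_entry_foci_are_polar(default_field):
    """Marginal |l| density of recipient-side conjugative foci peaks in the
    outer quartile, matching the configured polar-entry mixture."""
    res = default_field
    donor_roots = set(res.classes.loc[res.classes.cell_class == "donor", "root"])
    conj = res.foci[
        (res.foci.channel == "ypet")
        & (res.foci.focus_class == "conjugative")
        & (~res.foci.track_id.isin(donor_roots))
    ]
    assert len(conj) > 20
    assert np.median(np.abs(conj.l)) > 0.25
    hist, _ = np.histogram(np.abs(conj.l), bins=4, range=(0, 0.5))
    assert hist.argmax() == 3


def test_colocalise_trivial_and_jittered():
    a = pd.DataFrame({"frame": [0, 0, 1], "x_um": [1.0, 2.0, 3.0], "y_um": [1.0, 2.0, 3.0]})
    assert colocalise(a, a.copy(), radius_um=0.1) == 1.0
    far = a.copy()
    far[["x_um", "y_um"]] += 10.0
    assert colocalise(a, far, radius_um=0.5) == 0.0
    rng = np.random.default_rng(7)
    n = 200
    base = pd.DataFrame(
        {
            "frame": np.repeat(np.arange(20), 10),
            "x_um": rng.uniform(0, 16, n),
            "y_um": rng.uniform(0, 16, n),
        }
    )
    jit = base.copy()
    jit[["x_um", "y_um"]] += rng.normal(0, 0.065, (n, 2))  # ~1 px jitter
    assert colocalise(base, jit, radius_um=3 * 0.065) >= 0.95
    with pytest.warns(UserWarning):
        assert math.isnan(colocalise(base.iloc[:0], jit, radius_um=1.0))


def test_detection_recall_and_precision_on_fixture(default_field):
    """Scripted foci at SNR >= 3: recall and precision both >= 0.95
    (2 px matching radius against the generator's focus table)."""
    res = default_field
    px = res.truth.movie.pixel_size_um
    for ch in ("ypet", "mcherry"):
        t = res.truth.foci_truth[res.truth.foci_truth.channel == ch]
        p = res.foci[res.foci.channel == ch]
        hit = 0
        for f, tg in t.groupby("frame"):
            pg = p[p.frame == f]
            if len(pg) == 0:
                continue
            for _, r in tg.iterrows():
                if np.hypot(pg.x_um - r.x_px * px, pg.y_um - r.y_px * px).min() <= 2 * px:
                    hit += 1
        phit = 0
        for f, pg in p.groupby("frame"):
            tg = t[t.frame == f]
            if len(tg) == 0:
                continue
            for _, r in pg.iterrows():
                if np.hypot(tg.x_px * px - r.x_um, tg.y_px * px - r.y_um).min() <= 2 * px:
                    phit += 1
        assert hit / len(t) >= 0.95, f"recall too low on {ch}"
        assert phit / len(p) >= 0.95, f"precision too low on {ch}"
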