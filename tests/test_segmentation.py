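"""Segmentation and tracking against generator ground truth."""

import numpy as np
import pytest

from conjview import (
    OpticsConfig,
    SegmentationConfig,
    SimScenario,
    measure_channels,
    render_movie,
    sample_population,
    segment_frame,
    segment_movie,
    snr,
    track_cells,
)
from conftest import map_roots_to_truth


@pytest.fixture(scope="module")
def noiseless_frame():
    optics = OpticsConfig(shot_noise=False, read_noise_sd=0.0)
    sc = SimScenario(n_pairs=3, n_extra_donors=2, n_extra_recipients=2, n_frames=2, optics=optics)
    cells, events = sample_population(sc, 31)
    rr = render_movie(cells, events, None, sc, 32)
    return sc, cells, rr


def test_noiseless_field_segments_every_cell_with_high_iou(noiseless_frame):
    sc, cells, rr = noiseless_frame
    cfg = SegmentationConfig(pixel_size_um=sc.optics.pixel_size_um)
    lab, recs = segment_frame(rr.movie.channels["phase"][0], cfg)
    truth = rr.labels[0]
    n_true = sum(1 for c in cells if c.alive(0))
    assert len(recs) == n_true
    for c in cells:
        if not c.alive(0):
            continue
        tmask = truth == c.cell_id
        vals, cnts = np.unique(lab[tmask][lab[tmask] > 0], return_counts=True)
        assert len(vals) >= 1
        match = vals[cnts.argmax()]
        pmask = lab == match
        iou = (tmask & pmask).sum() / (tmask | pmask).sum()
        assert iou >= 0.8


def test_blank_frame_yields_no_regions():
    lab, recs = segment_frame(np.full((64, 64), 100.0))
    assert recs == [] and lab.max() == 0


def test_cell_length_estimated_within_ten_percent(noiseless_frame):
    sc, cells, rr = noiseless_frame
    cfg = SegmentationConfig(pixel_size_um=sc.optics.pixel_size_um)
    lab, recs = segment_frame(rr.movie.channels["phase"][0], cfg)
    truth = rr.labels[0]
    for rec in recs:
        m = lab == rec.label
        vals, cnts = np.unique(truth[m][truth[m] > 0], return_counts=True)
        c = next(cc for cc in cells if cc.cell_id == vals[cnts.argmax()])
        assert rec.length_um == pytest.approx(c.length_um(0.0, sc), rel=0.10)


def test_snr_is_plain_mean_ratio():
    assert snr(200.0, 100.0) == pytest.approx(2.0)
    assert snr(100.0, 100.0) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        snr(100.0, 0.0)


def test_snr_invariant_under_global_gain(default_field):
    """Multiplying every pixel by a constant leaves per-cell SNR unchanged."""
    movie = default_field.truth.movie
    labels = default_field.labels
    cfg = SegmentationConfig(pixel_size_um=movie.pixel_size_um)
    _, per_frame = segment_movie(movie, cfg)
    cells_a, _ = measure_channels(movie, labels, per_frame)
    scaled = type(movie)(
        channels={ch: 3.0 * arr for ch, arr in movie.channels.items()},
        pixel_size_um=movie.pixel_size_um,
        frame_interval_min=movie.frame_interval_min,
    )
    _, per_frame_b = segment_movie(movie, cfg)
    cells_b, _ = measure_channels(scaled, labels, per_frame_b)
    np.testing.assert_allclose(
        cells_a["snr_ypet"].to_numpy(), cells_b["snr_ypet"].to_numpy(), rtol=1e-5
    )


def test_static_population_tracks_without_divisions():
    sc = SimScenario(n_pairs=2, n_frames=15, doubling_time_min=1e6)
    cells, events = sample_population(sc, 41)
    rr = render_movie(cells, events, None, sc, 42)
    cfg = SegmentationConfig(pixel_size_um=sc.optics.pixel_size_um)
    labels, per_frame = segment_movie(rr.movie, cfg)
    tracks = track_cells(labels, per_frame, cfg)
    assert all(t.children is None for t in tracks)
    assert len(tracks) == len(cells)
    for t in tracks:
        assert set(t.frames) == set(range(sc.n_frames))


def test_scripted_divisions_detected_at_the_right_frame(default_field):
    res = default_field
    truth_div = {
        c.cell_id: c.division_frame
        for c in res.truth.cells
        if c.division_frame is not None and c.parent is None
    }
    root_truth = map_roots_to_truth(res)
    found = total = 0
    for t in res.tracks:
        tc = root_truth.get(t.track_id)
        if tc not in truth_div:
            continue
        total += 1
        if t.children is not None:
            kid_start = min(
                tr.start for tr in res.tracks if tr.track_id in t.children
            )
            if abs(kid_start - truth_div[tc]) <= 1:
                found += 1
    assert total > 0
    assert found / total >= 0.9


def test_identities_never_swap(default_field):
    """Each track's mask overlaps the same ground-truth cell (or its
    offspring) on every frame it exists."""
    res = default_field
    descendants: dict[int, set[int]] = {}
    kids = {c.cell_id: c.children for c in res.truth.cells}
    def clan(cid):
        out = {cid}
        stack = [cid]
        while stack:
            ch = kids.get(stack.pop())
            if ch:
                out.update(ch)
                stack.extend(ch)
        return out
    root_truth = map_roots_to_truth(res)
    for t in res.tracks:
        if t.parent is not None or t.track_id not in root_truth:
            continue
        allowed = clan(root_truth[t.track_id])
        for f in sorted(t.frames)[::7]:
            m = res.labels[f] == t.frames[f]
            vals, cnts = np.unique(
                res.truth.labels[f][m][res.truth.labels[f][m] > 0], return_counts=True
            )
            assert int(vals[cnts.argmax()]) in allowed


def test_tracking_requires_two_frames():
    with pytest.raises(ValueError):
        track_cells(np.zeros((1, 8, 8), dtype=np.int32), [[]])
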