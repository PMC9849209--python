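"""Event annotation: classification, frame arithmetic, censoring, summaries."""

import numpy as np
import pandas as pd
import pytest

from conjview import (
    EventConfig,
    annotate_event,
    appearance_offset_distribution,
    classify_cell,
    copy_number_dynamics,
    detect_multiple_acquisitions,
    expression_windows,
)
from conjview.params import GeneProgram, SimScenario
from conjview.population import Acquisition, GroundTruthEvent, draw_truncated_normal
from conjview.render import reporter_trace
from conftest import map_roots_to_truth, truth_class_of


# ---------------------------------------------------------------------------
# classification


def test_classify_cell_rules():
    cfg = EventConfig()
    assert classify_cell(np.full(30, 1.0), set(), cfg) == "donor"
    assert classify_cell(np.full(30, 2.5), set(), cfg) == "recipient"
    assert classify_cell(np.full(30, 2.5), {10, 11, 12, 13}, cfg) == "transconjugant"
    # a lone-frame red detection is flicker, not a focus
    assert classify_cell(np.full(30, 2.5), {10}, cfg) == "recipient"


def test_population_classification_accuracy(default_field):
    """Donor / recipient / transconjugant confusion accuracy >= 95%."""
    res = default_field
    r2t = map_roots_to_truth(res)
    want = truth_class_of(res)
    ok = n = 0
    for _, row in res.classes.iterrows():
        tc = r2t.get(row.root)
        if tc is None:
            continue
        n += 1
        ok += row.cell_class == want[tc]
    assert n >= 30
    assert ok / n >= 0.95


# ---------------------------------------------------------------------------
# frame arithmetic and censoring


def test_lifespan_is_exact_frame_arithmetic():
    """Appearance f=10, disappearance f=13 at 1 min/frame -> 3 min."""
    tls = annotate_event({10: (0.4, -0.4), 11: (0.4, -0.4), 12: (0.4, -0.4)}, {}, 60, 1.0)
    assert len(tls) == 1
    assert tls[0].ssb_appear_frame == 10
    assert tls[0].ssb_disappear_frame == 13
    assert tls[0].lifespan_min == 3.0


def test_lag_and_duplications_from_red_runs():
    ssb = {f: (0.4, -0.4) for f in (5, 6, 7)}
    parb = {f: 1 for f in range(9, 20)} | {f: 2 for f in range(20, 30)} | {f: 3 for f in range(30, 60)}
    tls = annotate_event(ssb, parb, 60, 1.0)
    t = tls[0]
    assert t.parb_appear_frame == 9
    assert t.conversion_lag_min == 4.0
    assert t.dup1_frame == 20 and t.dup1_interval_min == 11.0
    assert t.dup2_frame == 30 and t.dup2_interval_min == 10.0


def test_focus_running_into_movie_end_is_right_censored():
    ssb = {f: (0.4, -0.4) for f in range(55, 60)}
    tls = annotate_event(ssb, {}, 60, 1.0)
    assert tls[0].lifespan_censored
    assert tls[0].lifespan_min is None
    assert tls[0].conversion_censored  # too little movie left to call failure


def test_missing_conversion_with_ample_movie_is_a_true_failure():
    ssb = {f: (0.4, -0.4) for f in (5, 6, 7)}
    tls = annotate_event(ssb, {}, 60, 1.0)
    assert tls[0].parb_appear_frame is None
    assert not tls[0].conversion_censored


def test_event_ordering_invariant_on_annotated_events(default_field):
    ev = default_field.events
    first = ev[ev.acquisition_index == 1]
    for _, r in first.iterrows():
        if pd.notna(r.parb_appear_frame):
            assert r.ssb_appear_frame <= r.parb_appear_frame
            if pd.notna(r.dup1_frame):
                assert r.parb_appear_frame <= r.dup1_frame
                if pd.notna(r.dup2_frame):
                    assert r.dup1_frame <= r.dup2_frame


def test_annotated_frames_match_scripted_times(default_field):
    """>= 90% of annotated appearance/conversion frames within +-1 frame of
    the scripted event times."""
    res = default_field
    r2t = map_roots_to_truth(res)
    truth = {e.recipient_id: e for e in res.truth.events}
    good = total = 0
    first = res.events[res.events.acquisition_index == 1]
    for _, row in first.iterrows():
        e = truth.get(r2t.get(row.recipient_id))
        if e is None:
            continue
        total += 1
        ok = abs(row.ssb_appear_frame - e.t_entry_start_frame) <= 1
        if pd.notna(row.parb_appear_frame) and e.t_conversion_frame is not None:
            ok = ok and abs(row.parb_appear_frame - e.t_conversion_frame) <= 1
        good += ok
    assert total >= 5
    assert good / total >= 0.9


# ---------------------------------------------------------------------------
# offsets and repeated acquisitions


def _events_frame(rows):
    base = dict(
        acquisition_index=1,
        donor_appear_frame=np.nan,
        ssb_appear_frame=0,
        frame_interval_min=1.0,
        parb_appear_frame=np.nan,
        recipient_id=0,
        donor_id=-1,
        pore_l=0.0,
        pore_d=0.0,
    )
    return pd.DataFrame([{**base, **r} for r in rows])


def test_offset_distribution_all_simultaneous():
    ev = _events_frame(
        [dict(recipient_id=i, ssb_appear_frame=5, donor_appear_frame=5) for i in range(10)]
    )
    out = appearance_offset_distribution(ev)
    assert out["proportions"][0] == 1.0 and out["n"] == 10


def test_offset_distribution_single_donor_later():
    ev = _events_frame([dict(recipient_id=0, ssb_appear_frame=5, donor_appear_frame=6)])
    out = appearance_offset_distribution(ev)
    assert out["proportions"][1] == 1.0


def test_offset_proportions_recovered(default_field):
    out = appearance_offset_distribution(default_field.events)
    # configured: 77.8% simultaneous, remainder donor-later; small-n binomial check
    n = out["n"]
    assert n >= 5
    p0 = out["proportions"][0]
    assert abs(p0 - 0.778) <= 3 * np.sqrt(0.778 * 0.222 / n)


def test_same_pore_flagging():
    ev = _events_frame(
        [
            dict(recipient_id=1, acquisition_index=1, pore_l=0.45, pore_d=-0.40, donor_id=3),
            dict(recipient_id=1, acquisition_index=2, pore_l=0.47, pore_d=-0.42, donor_id=3),
            dict(recipient_id=2, acquisition_index=1, pore_l=0.45, pore_d=-0.40, donor_id=3),
            dict(recipient_id=2, acquisition_index=2, pore_l=-0.40, pore_d=0.40, donor_id=4),
        ]
    )
    out = detect_multiple_acquisitions(ev, pore_match_radius=0.1)
    rep = out[out.acquisition_index == 2].set_index("recipient_id")
    assert bool(rep.loc[1, "same_pore"]) and bool(rep.loc[1, "same_donor"])
    assert not bool(rep.loc[2, "same_pore"]) and not bool(rep.loc[2, "same_donor"])
    first = out[out.acquisition_index == 1]
    assert first["same_pore"].isna().all()


# ---------------------------------------------------------------------------
# copy-number dynamics


def test_constant_count_has_zero_slope():
    df = pd.DataFrame(dict(group="donor", t_min=np.arange(10.0), count=np.ones(10)))
    out = copy_number_dynamics(df)
    assert out["groups"]["donor"]["slope"] == pytest.approx(0.0, abs=1e-12)


def test_scripted_slope_ratio_recovered_exactly():
    t = np.arange(0.0, 21.0)
    s = 0.05
    df = pd.concat(
        [
            pd.DataFrame(dict(group="donor", t_min=t, count=1 + s * t)),
            pd.DataFrame(dict(group="transconjugant", t_min=t, count=1 + 1.75 * s * t)),
        ]
    )
    out = copy_number_dynamics(df)
    assert out["slope_ratio"] == pytest.approx(1.75, rel=0.05)


def test_duplication_driven_slope_matches_interval_rate():
    """Duplications every ~10.4 then ~10.1 min give a fitted slope close to
    1/10.25 foci per minute over the quasi-linear window."""
    rng = np.random.default_rng(1)
    rows = []
    for cid in range(200):
        d1 = draw_truncated_normal(rng, 10.4, 4.7)
        d2 = d1 + draw_truncated_normal(rng, 10.1, 5.1)
        d3 = d2 + draw_truncated_normal(rng, 10.1, 5.1)
        for t in range(5, 26):
            rows.append(
                dict(group="transconjugant", t_min=t, count=1 + (t >= d1) + (t >= d2) + (t >= d3))
            )
    out = copy_number_dynamics(pd.DataFrame(rows))
    assert out["groups"]["transconjugant"]["slope"] == pytest.approx(1 / 10.25, rel=0.20)


def test_too_few_points_flagged():
    df = pd.DataFrame(dict(group="donor", t_min=[0.0, 1.0], count=[1, 1]))
    assert copy_number_dynamics(df)["groups"]["donor"]["slope"] is None


# ---------------------------------------------------------------------------
# expression windows


def _traces(gene, n_cells=30, n_frames=110, seed=2):
    sc = SimScenario(n_pairs=1, n_frames=n_frames)
    rng = np.random.default_rng(seed)
    rows = []
    for cid in range(n_cells):
        tau = rng.uniform(2, 8)
        dur = draw_truncated_normal(rng, 2.9, 1.1)
        conv = tau + dur + rng.gamma(0.87, 1.25)
        ev = GroundTruthEvent(
            0, 1, 2,
            [Acquisition(1, 1, tau, tau + dur, tau, tau + 2.5, 0.4, -0.4, 0.25, 0.4)],
            conv, conv - tau, [conv + 10, conv + 20],
        )
        p = reporter_trace(gene, ev, sc)
        snr = (1.0 + p * 0.5) * rng.normal(1, 0.02, len(p))
        for f in range(n_frames):
            rows.append(dict(cell_id=cid, t_min=f - int(np.ceil(conv)), snr=snr[f]))
    return pd.DataFrame(rows)


def test_constant_snr_gives_empty_window():
    rows = [
        dict(cell_id=c, t_min=t, snr=2.0) for c in range(10) for t in range(-10, 80)
    ]
    out = expression_windows(pd.DataFrame(rows))
    assert out["window_min"] is None


def test_frpo_gene_window_spans_conversion_and_shuts_off():
    """Single-stranded-promoter reporter: production is already running at
    conversion, peaks in the first post-conversion interval, and stops
    25-35 min after conversion."""
    out = expression_windows(_traces(GeneProgram()))
    lo, hi = out["window_min"]
    assert lo <= 0
    assert 25 <= hi <= 35
    assert 0 <= out["peak_interval_start_min"] < 10


def test_frpo_deletion_abolishes_the_window():
    out = expression_windows(_traces(GeneProgram(frpo_present=False)))
    assert out["window_min"] is None


def test_maintenance_gene_plateaus_late():
    gene = GeneProgram(
        gene_class="maintenance",
        onset_relative_to="conversion",
        onset_min=5,
        peak_min=30,
        shutoff_min=None,
        plateau_min=75,
        production_rate=0.5,
    )
    out = expression_windows(_traces(gene))
    lo, hi = out["window_min"]
    assert lo >= 0  # nothing before conversion
    assert hi >= 60  # sustained accumulation toward the late plateau
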