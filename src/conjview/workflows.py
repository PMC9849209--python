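"""End-to-end pipelines: simulate -> render -> segment -> foci -> events.

These are the entry points the analysis scripts, the test suite and the
acceptance script all share, so that every reported number is produced by
the same code path a user would run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import (
    EventConfig,
    annotate_movie,
    appearance_offset_distribution,
    expression_windows,
    summarise_events,
)
from .foci import FocusParams, detect_foci_movie
from .params import ExpressionProgram, SimScenario
from .population import sample_population
from .render import RenderResult, render_movie
from .segmentation import (
    SegmentationConfig,
    measure_channels,
    segment_movie,
    track_cells,
)

__all__ = ["FieldResult", "run_field", "run_experiment", "recovery_scenario", "expression_traces"]


@dataclass
class FieldResult:
    events: pd.DataFrame  # pipeline-annotated events
    classes: pd.DataFrame  # lineage classification
    cells: pd.DataFrame  # per-cell per-frame measurements
    foci: pd.DataFrame  # focus detections
    truth: RenderResult  # generator ground truth (+ rendered movie)
    tracks: list = field(default_factory=list)
    labels: np.ndarray | None = None


def recovery_scenario(n_pairs: int = 10, n_frames: int = 60) -> SimScenario:
    """The default study conditions: 1 min/frame fields of mating triplets."""
    return SimScenario(
        n_pairs=n_pairs,
        n_extra_donors=1,
        n_extra_recipients=1,
        n_frames=n_frames,
        frame_interval_min=1.0,
    )


def run_field(
    scenario: SimScenario,
    seed: int,
    event_config: EventConfig | None = None,
    focus_params: FocusParams | None = None,
    keep_images: bool = True,
) -> FieldResult:
    """Full pipeline on one synthetic field of view."""
    cells, events = sample_population(scenario, seed)
    rr = render_movie(cells, events, None, scenario, seed + 1)
    seg_cfg = SegmentationConfig(pixel_size_um=scenario.optics.pixel_size_um)
    labels, per_frame = segment_movie(rr.movie, seg_cfg)
    tracks = track_cells(labels, per_frame, seg_cfg)
    track_of_label = {
        (f, lab): t.track_id for t in tracks for f, lab in t.frames.items()
    }
    cells_df, _bg = measure_channels(rr.movie, labels, per_frame, tracks)
    foci_df = detect_foci_movie(
        rr.movie, labels, per_frame, params=focus_params, track_of_label=track_of_label
    )
    ev_df, classes = annotate_movie(
        cells_df,
        foci_df,
        tracks,
        scenario.n_frames,
        scenario.frame_interval_min,
        event_config,
    )
    if not keep_images:
        rr.movie.channels = {}
        rr.labels = np.zeros((0,), dtype=np.int32)
    return FieldResult(
        events=ev_df,
        classes=classes,
        cells=cells_df,
        foci=foci_df,
        truth=rr,
        tracks=tracks,
        labels=labels if keep_images else None,
    )


def run_experiment(
    scenario: SimScenario,
    n_fields: int,
    seed: int,
    event_config: EventConfig | None = None,
) -> dict:
    """Pipeline over many independent fields; pooled event statistics.

    Returns the pooled pipeline events/truth tables and the headline
    summary (conversion success, multi-acquisition fraction and flags,
    Ssb->ParB lag, duplication intervals, lifespans, appearance offsets).
    """
    ss = np.random.SeedSequence(seed)
    field_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_fields)]
    ev_all, truth_all, cls_all = [], [], []
    for i, fs in enumerate(field_seeds):
        res = run_field(scenario, fs, event_config=event_config, keep_images=False)
        for df, acc in ((res.events, ev_all), (res.truth.events_truth, truth_all), (res.classes, cls_all)):
            df = df.copy()
            df["field"] = i
            # track/cell ids are per-field; offset them so pooled ids are unique
            for col in ("recipient_id", "donor_id", "root"):
                if col in df.columns:
                    df[col] = df[col].where(df[col] < 0, df[col] + i * 1_000_000)
            acc.append(df)
    events = pd.concat(ev_all, ignore_index=True) if ev_all else pd.DataFrame()
    truth = pd.concat(truth_all, ignore_index=True) if truth_all else pd.DataFrame()
    classes = pd.concat(cls_all, ignore_index=True) if cls_all else pd.DataFrame()
    summary = summarise_events(events) if len(events) else {}
    summary["offsets"] = appearance_offset_distribution(events) if len(events) else {}
    if len(events):
        rep = events[events["acquisition_index"] >= 2]
        sd = rep["same_donor"].dropna()
        summary["same_donor_fraction"] = float(sd.mean()) if len(sd) else float("nan")
        sp = rep.loc[rep["same_donor"] == True, "same_pore"].dropna()  # noqa: E712
        summary["same_pore_fraction"] = float(sp.mean()) if len(sp) else float("nan")
    return {"events": events, "truth": truth, "classes": classes, "summary": summary}


def expression_traces(
    scenario: SimScenario,
    seed: int,
    reporter_gene: str = "frpo_leading",
    expression: ExpressionProgram | None = None,
) -> pd.DataFrame:
    """Measured reporter SNR traces aligned to conversion (t = 0).

    Renders one field with the chosen reporter gene, runs the pipeline, and
    returns tidy (cell_id, t_min, snr) rows for every converted lineage.
    """
    cells, events = sample_population(scenario, seed)
    rr = render_movie(cells, events, expression, scenario, seed + 1, reporter_gene=reporter_gene)
    seg_cfg = SegmentationConfig(pixel_size_um=scenario.optics.pixel_size_um)
    labels, per_frame = segment_movie(rr.movie, seg_cfg)
    tracks = track_cells(labels, per_frame, seg_cfg)
    track_of_label = {(f, lab): t.track_id for t in tracks for f, lab in t.frames.items()}
    cells_df, _ = measure_channels(rr.movie, labels, per_frame, tracks)
    foci_df = detect_foci_movie(rr.movie, labels, per_frame, track_of_label=track_of_label)
    ev_df, _classes = annotate_movie(
        cells_df, foci_df, tracks, scenario.n_frames, scenario.frame_interval_min
    )
    from .events import lineage_series

    snr_series = lineage_series(cells_df, tracks, "snr_sfgfp", mode="mean")
    rows = []
    conv = ev_df[(ev_df["acquisition_index"] == 1) & ev_df["parb_appear_frame"].notna()]
    dt = scenario.frame_interval_min
    for _, row in conv.iterrows():
        root = int(row["recipient_id"])
        if root not in snr_series:
            continue
        f0 = int(row["parb_appear_frame"])
        for f, v in snr_series[root].items():
            rows.append(dict(cell_id=root, t_min=(int(f) - f0) * dt, snr=float(v)))
    return pd.DataFrame(rows)
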