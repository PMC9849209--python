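"""Cell-type classification and conjugation-event timing.

Cells are classified from the red (mCh-ParB) channel: donors carry no
ParB and sit at autofluorescence level, recipients show diffuse red
signal, and transconjugants show one or more persistent red foci (ParB
binds its site only once the incoming plasmid is double stranded). Event
annotation then reads the focus time series of each recipient lineage:

* a persistent membrane-proximal Ssb focus marks ssDNA entry (appearance /
  disappearance frames, lifespan),
* the first persistent ParB focus marks the ss-to-dsDNA conversion,
* the first frames with >= 2 and >= 3 ParB foci mark the first and second
  plasmid duplications,
* a further Ssb conjugative focus in an already-converted cell is a new
  acquisition, flagged same-donor / same-pore by comparing the inferred
  donor identity and normalised pore coordinates.

All lags are exact frame arithmetic: lag_min = frame difference x frame
interval. Events cut short by the end of the movie are right-censored and
never contribute to mean lags. After a division, quantification continues
over the daughters (lineage-summed focus counts, daughter-mean SNR by
default).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .segmentation import Track

__all__ = [
    "EventConfig",
    "EventTimeline",
    "classify_cell",
    "classify_lineages",
    "annotate_movie",
    "annotate_event",
    "appearance_offset_distribution",
    "detect_multiple_acquisitions",
    "copy_number_dynamics",
    "expression_windows",
    "lineage_series",
    "summarise_events",
]


@dataclass
class EventConfig:
    persistence_frames: int = 2  # debounce: red focus must persist >= p frames
    # conjugative Ssb foci are ~35x brighter than replicative ones and far
    # above the detection threshold, so flicker debounce is unnecessary and
    # would drop genuinely brief (sub-2-frame) transfers
    ssb_persistence_frames: int = 1
    merge_gap_frames: int = 1  # bridge single-frame detection dropouts
    recipient_snr_min: float = 1.25  # diffuse red above donor autofluorescence
    donor_match_radius_um: float = 3.0  # donor focus to recipient focus
    donor_offset_window_min: tuple[float, float] = (-3.0, 4.0)
    pore_match_radius: float = 0.1  # in (l, d) space
    conversion_censor_min: float = 15.0  # movie must extend this far past entry
    dup_censor_min: float = 25.0
    expected_interval_min: dict[str, float] = field(
        default_factory=lambda: {"lag": 1.0, "duplication": 5.0}
    )


@dataclass
class EventTimeline:
    """Annotated timing of one acquisition within a mating pair."""

    pair_id: int
    recipient_id: int  # lineage-root track id
    donor_id: Optional[int]
    acquisition_index: int
    ssb_appear_frame: Optional[int]
    ssb_disappear_frame: Optional[int]
    donor_appear_frame: Optional[int]
    parb_appear_frame: Optional[int]
    dup1_frame: Optional[int]
    dup2_frame: Optional[int]
    pore_l: float
    pore_d: float
    frame_interval_min: float
    lifespan_censored: bool = False
    conversion_censored: bool = False
    dup_censored: bool = False
    same_donor: Optional[bool] = None
    same_pore: Optional[bool] = None

    @property
    def lifespan_min(self) -> Optional[float]:
        if self.ssb_appear_frame is None or self.ssb_disappear_frame is None or self.lifespan_censored:
            return None
        return (self.ssb_disappear_frame - self.ssb_appear_frame) * self.frame_interval_min

    @property
    def conversion_lag_min(self) -> Optional[float]:
        if self.parb_appear_frame is None or self.ssb_appear_frame is None:
            return None
        return (self.parb_appear_frame - self.ssb_appear_frame) * self.frame_interval_min

    @property
    def dup1_interval_min(self) -> Optional[float]:
        if self.dup1_frame is None or self.parb_appear_frame is None:
            return None
        return (self.dup1_frame - self.parb_appear_frame) * self.frame_interval_min

    @property
    def dup2_interval_min(self) -> Optional[float]:
        if self.dup2_frame is None or self.dup1_frame is None:
            return None
        return (self.dup2_frame - self.dup1_frame) * self.frame_interval_min


# ---------------------------------------------------------------------------
# lineage plumbing


def _lineage_roots(tracks: list[Track]) -> dict[int, int]:
    """track_id -> root track_id of its lineage."""
    by_id = {t.track_id: t for t in tracks}
    root: dict[int, int] = {}
    for t in tracks:
        r = t
        while r.parent is not None and r.parent in by_id:
            r = by_id[r.parent]
        root[t.track_id] = r.track_id
    return root


def lineage_series(
    cells: pd.DataFrame,
    tracks: list[Track],
    column: str,
    mode: str = "mean",
) -> dict[int, pd.Series]:
    """Per-lineage time series, continued through divisions.

    ``mode='mean'`` averages over the daughters alive on a frame (the
    default for concentration-like quantities such as SNR); ``mode='sum'``
    totals them (for extensive quantities such as focus counts).
    """
    if mode not in ("mean", "sum"):
        raise ValueError("mode must be 'mean' or 'sum'")
    root = _lineage_roots(tracks)
    df = cells.copy()
    df["root"] = df["track_id"].map(root)
    agg = df.groupby(["root", "frame"])[column].agg(mode)
    return {int(r): s.droplevel(0) for r, s in agg.groupby(level=0)}


def _persistent_runs(frames: set[int], p: int, gap: int) -> list[tuple[int, int]]:
    """Maximal runs (start, end inclusive) of presence, bridging short gaps,
    keeping only runs of at least ``p`` frames."""
    if not frames:
        return []
    fs = sorted(frames)
    runs = [[fs[0], fs[0]]]
    for f in fs[1:]:
        if f - runs[-1][1] <= gap + 1:
            runs[-1][1] = f
        else:
            runs.append([f, f])
    return [(a, b) for a, b in runs if b - a + 1 >= p]


# ---------------------------------------------------------------------------
# classification


def classify_cell(
    red_snr: np.ndarray,
    red_focus_frames: set[int],
    config: EventConfig | None = None,
) -> str:
    """donor / recipient / transconjugant from the red-channel evidence."""
    cfg = config or EventConfig()
    runs = _persistent_runs(red_focus_frames, cfg.persistence_frames, cfg.merge_gap_frames)
    if runs:
        return "transconjugant"
    snr_med = float(np.nanmedian(np.asarray(red_snr, dtype=float)))
    if snr_med > cfg.recipient_snr_min:
        return "recipient"
    return "donor"


def classify_lineages(
    cells: pd.DataFrame,
    foci: pd.DataFrame,
    tracks: list[Track],
    config: EventConfig | None = None,
) -> pd.DataFrame:
    """Classify every lineage root; returns root, class and evidence."""
    cfg = config or EventConfig()
    root = _lineage_roots(tracks)
    snr_series = lineage_series(cells, tracks, "snr_mcherry", mode="mean")
    red = foci[foci["channel"] == "mcherry"].copy()
    red["root"] = red["track_id"].map(root)
    rows = []
    for r, series in snr_series.items():
        focus_frames = set(red.loc[red["root"] == r, "frame"].astype(int))
        cls = classify_cell(series.to_numpy(), focus_frames, cfg)
        rows.append(dict(root=r, cell_class=cls, median_red_snr=float(series.median())))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# event annotation


def annotate_event(
    ssb_frames: dict[int, tuple[float, float]],
    parb_frames: dict[int, int],
    n_frames: int,
    frame_interval_min: float,
    config: EventConfig | None = None,
    pair_id: int = 0,
    recipient_id: int = 0,
) -> list[EventTimeline]:
    """Annotate the acquisitions of one recipient lineage.

    ``ssb_frames`` maps frame -> (l, d) of the conjugative Ssb focus;
    ``parb_frames`` maps frame -> number of ParB foci. Returns one timeline
    per detected acquisition (empty if the cell never shows an Ssb focus).
    """
    cfg = config or EventConfig()
    dt = frame_interval_min
    ssb_runs = _persistent_runs(set(ssb_frames), cfg.ssb_persistence_frames, cfg.merge_gap_frames)
    first_ssb = ssb_runs[0][0] if ssb_runs else None

    def _dominant_run(frames_set: set[int], not_before: Optional[int]) -> Optional[int]:
        """Start of the longest persistent run (earliest on ties).

        ParB marks double-stranded plasmid permanently, so the genuine
        signal is the long-lived run; brief runs are stray detections from
        neighbouring cells during transient mask merges. Runs starting
        before ``not_before`` (the focus cannot precede the ssDNA that
        templates it) are ignored.
        """
        runs = _persistent_runs(frames_set, cfg.persistence_frames, cfg.merge_gap_frames)
        if not_before is not None:
            runs = [r for r in runs if r[0] >= not_before - 1]
        if not runs:
            return None
        best = max(runs, key=lambda r: (r[1] - r[0], -r[0]))
        return best[0]

    parb_present = {f for f, n in parb_frames.items() if n >= 1}
    conv_frame = _dominant_run(parb_present, first_ssb)

    dup1_frame = dup2_frame = None
    if conv_frame is not None:
        ge2 = {f for f, n in parb_frames.items() if n >= 2}
        ge3 = {f for f, n in parb_frames.items() if n >= 3}
        dup1_frame = _dominant_run(ge2, conv_frame)
        dup2_frame = _dominant_run(ge3, dup1_frame)

    timelines: list[EventTimeline] = []
    for i, (a, b) in enumerate(ssb_runs):
        ls = [ssb_frames[f][0] for f in range(a, b + 1) if f in ssb_frames]
        ds = [ssb_frames[f][1] for f in range(a, b + 1) if f in ssb_frames]
        censored_life = b >= n_frames - 1
        is_first = i == 0
        tl = EventTimeline(
            pair_id=pair_id,
            recipient_id=recipient_id,
            donor_id=None,
            acquisition_index=i + 1,
            ssb_appear_frame=a,
            ssb_disappear_frame=b + 1 if not censored_life else None,
            donor_appear_frame=None,
            parb_appear_frame=conv_frame if is_first else None,
            dup1_frame=dup1_frame if is_first else None,
            dup2_frame=dup2_frame if is_first else None,
            pore_l=float(np.mean(ls)) if ls else np.nan,
            pore_d=float(np.mean(ds)) if ds else np.nan,
            frame_interval_min=dt,
            lifespan_censored=censored_life,
        )
        if is_first:
            if conv_frame is None:
                remaining = (n_frames - 1 - a) * dt
                tl.conversion_censored = remaining < cfg.conversion_censor_min
            else:
                if dup1_frame is None or dup2_frame is None:
                    remaining = (n_frames - 1 - conv_frame) * dt
                    tl.dup_censored = remaining < cfg.dup_censor_min
        timelines.append(tl)
    # order invariant: an acquisition cannot precede the previous one
    for t1, t2 in zip(timelines, timelines[1:]):
        assert t1.ssb_appear_frame <= t2.ssb_appear_frame
    return timelines


def annotate_movie(
    cells: pd.DataFrame,
    foci: pd.DataFrame,
    tracks: list[Track],
    n_frames: int,
    frame_interval_min: float,
    config: EventConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annotate all conjugation events of a movie.

    Returns (events table, lineage classification table). ``cells`` is the
    tidy per-cell per-frame table from ``measure_channels`` augmented with
    track ids; ``foci`` the detection table from ``detect_foci_movie``.
    """
    cfg = config or EventConfig()
    if "duplication" in cfg.expected_interval_min and frame_interval_min not in (
        cfg.expected_interval_min["duplication"],
        cfg.expected_interval_min["lag"],
    ):
        warnings.warn(
            f"frame interval {frame_interval_min} min differs from the "
            "intervals this analysis was configured for",
            stacklevel=2,
        )
    root = _lineage_roots(tracks)
    classes = classify_lineages(cells, foci, tracks, cfg)
    cls_of = dict(zip(classes["root"], classes["cell_class"]))
    fo = foci.copy()
    fo["root"] = fo["track_id"].map(root)

    # donor-side conjugative foci, indexed by frame for proximity matching
    donor_roots = {r for r, c in cls_of.items() if c == "donor"}
    dfoci = fo[(fo["channel"] == "ypet") & (fo["focus_class"] == "conjugative") & fo["root"].isin(donor_roots)]

    timelines: list[EventTimeline] = []
    for r, c in cls_of.items():
        if c == "donor":
            continue
        mine = fo[fo["root"] == r]
        ssb = mine[(mine["channel"] == "ypet") & (mine["focus_class"] == "conjugative")]
        ssb_frames: dict[int, tuple[float, float]] = {}
        for f, grp in ssb.groupby("frame"):
            top = grp.loc[grp["intensity"].idxmax()]
            ssb_frames[int(f)] = (float(top["l"]), float(top["d"]))
        parb = mine[mine["channel"] == "mcherry"]
        parb_frames = {int(f): int(len(g)) for f, g in parb.groupby("frame")}
        tls = annotate_event(
            ssb_frames,
            parb_frames,
            n_frames,
            frame_interval_min,
            cfg,
            pair_id=r,
            recipient_id=r,
        )
        # infer the donor of each acquisition: nearest donor-lineage
        # conjugative focus around the recipient-side appearance
        for tl in tls:
            if tl.ssb_appear_frame is None:
                continue
            w0 = tl.ssb_appear_frame + cfg.donor_offset_window_min[0] / frame_interval_min
            w1 = tl.ssb_appear_frame + cfg.donor_offset_window_min[1] / frame_interval_min
            cand = dfoci[(dfoci["frame"] >= w0) & (dfoci["frame"] <= w1)]
            if len(cand) == 0:
                continue
            # recipient focus position on the appearance frame
            rf = ssb.loc[ssb["frame"] == tl.ssb_appear_frame]
            if len(rf) == 0:
                continue
            rx, ry = float(rf.iloc[0]["x_um"]), float(rf.iloc[0]["y_um"])
            dist = np.hypot(cand["x_um"] - rx, cand["y_um"] - ry)
            near = cand[dist <= cfg.donor_match_radius_um]
            if len(near) == 0:
                continue
            best_root = near.loc[dist.loc[near.index].idxmin(), "root"]
            tl.donor_id = int(best_root)
            df_frames = set(near.loc[near["root"] == best_root, "frame"].astype(int))
            druns = _persistent_runs(df_frames, 1, cfg.merge_gap_frames)
            if druns:
                tl.donor_appear_frame = druns[0][0]
        timelines.extend(tls)

    events = pd.DataFrame(
        [
            dict(
                pair_id=t.pair_id,
                recipient_id=t.recipient_id,
                donor_id=t.donor_id if t.donor_id is not None else -1,
                acquisition_index=t.acquisition_index,
                ssb_appear_frame=t.ssb_appear_frame,
                ssb_disappear_frame=t.ssb_disappear_frame,
                donor_appear_frame=t.donor_appear_frame,
                parb_appear_frame=t.parb_appear_frame,
                dup1_frame=t.dup1_frame,
                dup2_frame=t.dup2_frame,
                pore_l=t.pore_l,
                pore_d=t.pore_d,
                lifespan_min=t.lifespan_min,
                conversion_lag_min=t.conversion_lag_min,
                dup1_interval_min=t.dup1_interval_min,
                dup2_interval_min=t.dup2_interval_min,
                lifespan_censored=t.lifespan_censored,
                conversion_censored=t.conversion_censored,
                dup_censored=t.dup_censored,
                frame_interval_min=t.frame_interval_min,
            )
            for t in timelines
        ]
    )
    if len(events):
        events = detect_multiple_acquisitions(events, cfg.pore_match_radius)
    return events, classes


# ---------------------------------------------------------------------------
# summaries


def appearance_offset_distribution(events: pd.DataFrame) -> dict:
    """Proportions of donor-vs-transconjugant focus appearance offsets.

    Offsets (donor frame - recipient frame, in minutes) are binned into the
    four observed classes {-1, 0, +1, +2}; anything outside is reported
    under ``other``.
    """
    first = events[(events["acquisition_index"] == 1) & events["donor_appear_frame"].notna()]
    dt = first["frame_interval_min"] if len(first) else 1.0
    offs = (first["donor_appear_frame"] - first["ssb_appear_frame"]) * dt
    n = len(offs)
    out = {"n": int(n), "proportions": {}, "other": 0.0}
    if n == 0:
        return out
    for k in (-1, 0, 1, 2):
        out["proportions"][k] = float((offs == k).mean())
    out["other"] = float((~offs.isin([-1, 0, 1, 2])).mean())
    return out


def detect_multiple_acquisitions(
    events: pd.DataFrame, pore_match_radius: float = 0.1
) -> pd.DataFrame:
    """Flag repeated acquisitions as same-donor / same-pore.

    A same-pore repeat lands within ``pore_match_radius`` (Euclidean in the
    normalised (l, d) plane) of an earlier acquisition of the same cell.
    """
    ev = events.copy()
    ev["same_donor"] = pd.array([None] * len(ev), dtype="boolean")
    ev["same_pore"] = pd.array([None] * len(ev), dtype="boolean")
    for rid, grp in ev.groupby("recipient_id"):
        grp = grp.sort_values("acquisition_index")
        prev: list[tuple[float, float, int]] = []
        for idx, row in grp.iterrows():
            if row["acquisition_index"] > 1 and prev:
                known_prev = [d for (_, _, d) in prev if d != -1]
                if row["donor_id"] != -1 and known_prev:
                    ev.loc[idx, "same_donor"] = bool(row["donor_id"] in known_prev)
                # donor unidentifiable on either side: leave the flag unset
                same_pore = any(
                    math.hypot(row["pore_l"] - l, row["pore_d"] - d) <= pore_match_radius
                    for (l, d, _) in prev
                )
                ev.loc[idx, "same_pore"] = bool(same_pore)
            prev.append((row["pore_l"], row["pore_d"], row["donor_id"]))
    return ev


def copy_number_dynamics(
    counts: pd.DataFrame,
    group_col: str = "group",
    time_col: str = "t_min",
    count_col: str = "count",
) -> dict:
    """Mean plasmid-focus count vs aligned time, with per-group linear fits.

    Transconjugant series are aligned to ParB appearance (t = 0), donor
    series to cell birth. Returns per-group mean curves, least-squares
    slopes (foci/min) and the slope ratio (later group / first group).
    """
    out: dict = {"groups": {}}
    slopes = {}
    for g, grp in counts.groupby(group_col):
        t = grp[time_col].to_numpy(float)
        y = grp[count_col].to_numpy(float)
        curve = grp.groupby(time_col)[count_col].agg(["mean", "std", "count"])
        if len(curve) < 3:
            slopes[g] = None
            out["groups"][g] = {"curve": curve, "slope": None}
            continue
        slope, intercept = np.polyfit(t, y, 1)
        slopes[g] = float(slope)
        out["groups"][g] = {"curve": curve, "slope": float(slope), "intercept": float(intercept)}
    keys = list(slopes)
    if len(keys) == 2 and all(slopes[k] for k in keys):
        out["slope_ratio"] = slopes[keys[1]] / slopes[keys[0]]
    return out


def expression_windows(
    traces: pd.DataFrame,
    interval_min: float = 10.0,
    alpha: float = 0.05,
    epsilon: float = 0.05,
    min_cells: int = 5,
    cell_col: str = "cell_id",
    time_col: str = "t_min",
    snr_col: str = "snr",
) -> dict:
    """Production window from per-cell reporter SNR fold increases.

    FI over each non-overlapping interval (anchored at the conversion,
    t = 0) is SNR(t + interval) / SNR(t) per cell; an interval is
    productive when the across-cell mean FI exceeds 1 (one-sided
    one-sample t-test at ``alpha``). The window is the maximal run of at
    least two consecutive productive intervals (a single significant
    interval is within the expected false-positive count at ``alpha``);
    the peak is the interval of largest mean FI within the window; the
    plateau starts at the first interval after which mean FI stays below
    1 + epsilon. Traces must be aligned (conversion = 0) and cover at
    least one interval.
    """
    wide = traces.pivot_table(index=cell_col, columns=time_col, values=snr_col)
    times = np.array(sorted(wide.columns))
    if len(times) < 2:
        raise ValueError("traces must cover at least one interval")
    dt = times[1] - times[0]
    step = max(int(round(interval_min / dt)), 1)
    # non-overlapping intervals with a boundary at t = 0
    starts = np.array(
        [
            t
            for i, t in enumerate(times[: len(times) - step])
            if abs(t / (dt * step) - round(t / (dt * step))) < 1e-9
        ]
    )
    mean_fi, sig = [], []
    keep = []
    for t0 in starts:
        partner = t0 + step * dt
        if partner not in wide.columns:
            continue
        keep.append(t0)
        fi = (wide[partner] / wide[t0]).dropna()
        if len(fi) < min_cells:
            # too few lineages reach this aligned time to test anything
            mean_fi.append(np.nan)
            sig.append(False)
            continue
        if float(fi.std(ddof=1)) == 0:
            mean_fi.append(float(fi.mean()))
            sig.append(bool(fi.mean() > 1 + epsilon))
            continue
        res = stats.ttest_1samp(fi, 1.0, alternative="greater")
        mean_fi.append(float(fi.mean()))
        sig.append(bool(res.pvalue < alpha))
    starts = np.array(keep)
    mean_fi_arr = np.array(mean_fi)
    # maximal run of >= 2 consecutive productive intervals
    best = (0, None, None)
    i = 0
    while i < len(sig):
        if sig[i]:
            j = i
            while j + 1 < len(sig) and sig[j + 1]:
                j += 1
            if j - i + 1 >= 2 and j - i + 1 > best[0]:
                best = (j - i + 1, (float(starts[i]), float(starts[j] + interval_min)), (i, j))
            i = j + 1
        else:
            i += 1
    window = best[1]
    peak = None
    if window is not None:
        i0, j0 = best[2]
        seg = mean_fi_arr[i0 : j0 + 1]
        peak = float(starts[i0 + int(np.nanargmax(seg))])
    plateau = None
    valid = np.isfinite(mean_fi_arr)
    for i, t0 in enumerate(starts):
        tail = mean_fi_arr[i:][valid[i:]]
        if tail.size and np.all(tail <= 1 + epsilon):
            plateau = float(t0)
            break
    return {
        "window_min": window,
        "peak_interval_start_min": peak,
        "plateau_start_min": plateau,
        "interval_starts_min": starts.tolist(),
        "mean_fold_increase": mean_fi_arr.tolist(),
        "significant": sig,
    }


def summarise_events(events: pd.DataFrame) -> dict:
    """Headline statistics of an annotated event table."""
    first = events[events["acquisition_index"] == 1]
    assessable = first[(first["parb_appear_frame"].notna()) | (~first["conversion_censored"])]
    converted = assessable[assessable["parb_appear_frame"].notna()]
    multi_base = converted
    n_multi = 0
    if len(events):
        per_cell = events.groupby("recipient_id")["acquisition_index"].max()
        conv_ids = set(converted["recipient_id"])
        n_multi = int(sum(per_cell.get(r, 1) > 1 for r in conv_ids))
    lif = first.loc[~first["lifespan_censored"], "lifespan_min"].dropna()
    lag = converted["conversion_lag_min"].dropna()
    d1 = converted["dup1_interval_min"].dropna()
    d2 = converted["dup2_interval_min"].dropna()
    return {
        "n_events": int(len(first)),
        "n_assessable": int(len(assessable)),
        "conversion_success_fraction": float(len(converted) / len(assessable)) if len(assessable) else np.nan,
        "multi_acquisition_fraction": float(n_multi / len(multi_base)) if len(multi_base) else np.nan,
        "lifespan_mean_min": float(lif.mean()) if len(lif) else np.nan,
        "lifespan_sd_min": float(lif.std(ddof=1)) if len(lif) > 1 else np.nan,
        "conversion_lag_mean_min": float(lag.mean()) if len(lag) else np.nan,
        "conversion_lag_sd_min": float(lag.std(ddof=1)) if len(lag) > 1 else np.nan,
        "dup1_interval_mean_min": float(d1.mean()) if len(d1) else np.nan,
        "dup1_interval_sd_min": float(d1.std(ddof=1)) if len(d1) > 1 else np.nan,
        "dup2_interval_mean_min": float(d2.mean()) if len(d2) else np.nan,
        "n_lifespan": int(len(lif)),
        "n_lag": int(len(lag)),
        "n_dup1": int(len(d1)),
        "n_dup2": int(len(d2)),
    }
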