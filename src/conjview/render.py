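"""Rendering of synthetic multi-channel time-lapse movies.

Four channels are produced, mirroring the imaging setup of conjugation
experiments:

* ``phase``    — a cell-body channel (cells bright over background),
* ``ypet``     — Ssb-Ypet: diffuse cytoplasm + replicative foci, plus the
                 bright membrane-proximal conjugative foci during transfer,
* ``mcherry``  — mCh-ParB: diffuse in recipients, focal after the
                 ss-to-dsDNA conversion (one focus per plasmid copy),
* ``sfgfp``    — a plasmid-encoded reporter fusion whose production is
                 driven by the configured gene-expression program.

Every fluorophore is rendered as diffuse cytoplasmic signal plus Gaussian
spots, then passed through a Poisson–Gaussian camera model. The Ssb channel
obeys a strict per-cell redistribution rule: the cell's total Ssb
fluorescence budget is fixed, and during transfer the conjugative focus
takes 35x the vegetative replicative-focus intensity while replicative foci
drop to half, the balance coming out of the diffuse pool — so the
integrated per-cell signal is conserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .params import ExpressionProgram, GeneProgram, OpticsConfig, SimScenario
from .population import GroundTruthEvent, SimCell

__all__ = ["MovieStack", "RenderResult", "render_movie", "reporter_trace"]

CHANNELS = ("phase", "ypet", "mcherry", "sfgfp")


@dataclass
class MovieStack:
    """Multi-channel time-lapse: each channel a (T, Y, X) array."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    frame_interval_min: float

    def __post_init__(self) -> None:
        shapes = {ch: a.shape for ch, a in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")

    @property
    def n_frames(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape[1:]


@dataclass
class RenderResult:
    movie: MovieStack
    labels: np.ndarray  # (T, Y, X) int32 ground-truth masks, 0 = background
    cells_truth: pd.DataFrame  # one row per cell per frame
    foci_truth: pd.DataFrame  # one row per rendered focus per frame
    events_truth: pd.DataFrame  # one row per acquisition
    cells: list[SimCell] = field(default_factory=list)
    events: list[GroundTruthEvent] = field(default_factory=list)


@dataclass
class SignalConfig:
    """Fluorophore intensity levels (camera counts)."""

    ssb_replicative_integrated: float = 2000.0
    ssb_budget_foci_equivalents: float = 45.0  # total cell budget, units of A
    conjugative_gain: float = 35.0  # conjugative focus = 35 x replicative
    replicative_dimming: float = 0.5  # replicative during transfer
    parb_focus_integrated: float = 3000.0
    parb_diffuse_per_px: float = 55.0  # diffuse mCh-ParB in recipients
    reporter_scale_per_px: float = 30.0  # green counts/px per reporter unit
    green_autofluor_per_px: float = 3.0
    donor_reporter_units: float = 2.0  # steady-state reporter in donors
    phase_level: float = 400.0


def _norm_to_um(cell: SimCell, l: float, d: float, t_min: float, scenario: SimScenario) -> tuple[float, float]:
    """Map normalised cell coordinates (l, d) to absolute µm position."""
    length = cell.length_um(t_min, scenario)
    u = np.array([math.cos(cell.angle_rad), math.sin(cell.angle_rad)])
    n = np.array([-u[1], u[0]])
    p = cell.center_at(t_min, scenario) + l * length * u + d * cell.width_um * n
    return float(p[0]), float(p[1])


def _capsule_patch(cell: SimCell, t_min: float, scenario: SimScenario, shape: tuple[int, int]):
    """Boolean capsule mask of the cell on its bounding patch.

    Returns (y-slice, x-slice, mask) or None when fully outside the field.
    """
    px = scenario.optics.pixel_size_um
    (x0, y0), (x1, y1) = cell.endpoints_um(t_min, scenario) / px
    r = cell.width_um / 2.0 / px
    pad = int(math.ceil(r)) + 2
    xmin = max(int(min(x0, x1) - pad), 0)
    xmax = min(int(max(x0, x1) + pad) + 1, shape[1])
    ymin = max(int(min(y0, y1) - pad), 0)
    ymax = min(int(max(y0, y1) + pad) + 1, shape[0])
    if xmin >= xmax or ymin >= ymax:
        return None
    yy, xx = np.mgrid[ymin:ymax, xmin:xmax]
    # distance from pixel centres to the centreline segment
    vx, vy = x1 - x0, y1 - y0
    seg2 = vx * vx + vy * vy
    if seg2 == 0:
        t = np.zeros_like(xx, dtype=float)
    else:
        t = np.clip(((xx - x0) * vx + (yy - y0) * vy) / seg2, 0.0, 1.0)
    dx = xx - (x0 + t * vx)
    dy = yy - (y0 + t * vy)
    mask = dx * dx + dy * dy <= r * r
    return slice(ymin, ymax), slice(xmin, xmax), mask


def _add_spot(img: np.ndarray, x_px: float, y_px: float, integrated: float, sigma: float) -> None:
    """Accumulate a 2D Gaussian of given integrated intensity."""
    if integrated <= 0:
        return
    rad = int(math.ceil(4 * sigma))
    xmin = max(int(x_px) - rad, 0)
    xmax = min(int(x_px) + rad + 1, img.shape[1])
    ymin = max(int(y_px) - rad, 0)
    ymax = min(int(y_px) + rad + 1, img.shape[0])
    if xmin >= xmax or ymin >= ymax:
        return
    yy, xx = np.mgrid[ymin:ymax, xmin:xmax]
    g = np.exp(-((xx - x_px) ** 2 + (yy - y_px) ** 2) / (2 * sigma * sigma))
    img[ymin:ymax, xmin:xmax] += integrated / (2 * math.pi * sigma * sigma) * g


def reporter_trace(
    gene: GeneProgram,
    event: GroundTruthEvent,
    scenario: SimScenario,
    dt_min: float | None = None,
) -> np.ndarray:
    """Reporter protein level (arbitrary units) per movie frame for one cell.

    Production switches on at the gene's onset (relative to ssDNA entry for
    single-stranded Frpo-type promoters, to conversion for double-stranded
    ones), ramps to its peak rate, and decays once the template switches
    state (conversion shuts ss promoters off; duplication-amplified ds
    promoters plateau late). Protein is diluted by exponential growth.
    """
    dt = scenario.frame_interval_min if dt_min is None else dt_min
    n = scenario.n_frames
    t = np.arange(n) * dt
    rate = np.zeros(n)
    r0 = gene.effective_rate
    if r0 > 0:
        if gene.onset_relative_to == "ssDNA_entry":
            t_on = event.acquisitions[0].entry_start_min + gene.onset_min
        else:
            if event.conversion_min is None:
                t_on = None
            else:
                t_on = event.conversion_min + gene.onset_min
        if t_on is not None:
            ramp_min = max(gene.peak_min - gene.onset_min, dt)
            active = t >= t_on
            rate[active] = r0 * np.clip((t[active] - t_on) / ramp_min, 0.0, 1.0)
            if gene.gene_class in ("leading_ss", "leading_opposite_strand"):
                # ss promoter: template becomes double-stranded at conversion
                t_off = (
                    event.conversion_min
                    if event.conversion_min is not None
                    else event.acquisitions[0].entry_end_min + 2.0
                )
                tau = max(((gene.shutoff_min or 30.0) - gene.maturation_min) / 3.0, 2.0)
                late = t >= t_off
                rate[late] = r0 * np.exp(-(t[late] - t_off) / tau)
            elif gene.plateau_min is not None and event.conversion_min is not None:
                # maintenance genes: saturate toward the late plateau
                t_pl = event.conversion_min + gene.plateau_min
                tau = gene.plateau_min / 3.0
                rate = np.where(t >= t_pl, rate * np.exp(-(t - t_pl) / tau), rate)
    # translation + fluorophore maturation delays visible protein
    shift = int(round(gene.maturation_min / dt))
    if shift > 0:
        rate = np.concatenate([np.zeros(shift), rate[: n - shift]])
    delta = math.log(2.0) / scenario.doubling_time_min  # dilution by growth
    p = np.zeros(n)
    for i in range(1, n):
        p[i] = p[i - 1] + dt * (rate[i - 1] - delta * p[i - 1])
    return p


def _lineage_alive(cells_by_id: dict[int, SimCell], root: int, frame: int) -> list[SimCell]:
    out, stack = [], [root]
    while stack:
        cid = stack.pop()
        c = cells_by_id[cid]
        if c.alive(frame):
            out.append(c)
        elif c.children is not None:
            stack.extend(c.children)
    return out


# well-separated axial slots of segregated plasmid copies per copy count
# (single new plasmid near its entry pole, then spreading to quarter-like
# positions as it duplicates — always resolvable at the rendered length)
_PARB_SLOTS = {
    1: [(-0.3, 0.05)],
    2: [(-0.28, 0.05), (0.28, -0.05)],
    3: [(-0.32, 0.05), (0.0, 0.0), (0.32, -0.05)],
    4: [(-0.36, 0.05), (-0.12, -0.05), (0.12, 0.05), (0.36, -0.05)],
}


def render_movie(
    cells: list[SimCell],
    events: list[GroundTruthEvent],
    expression: ExpressionProgram | None,
    scenario: SimScenario,
    rng_seed: int,
    signal: SignalConfig | None = None,
    reporter_gene: str = "frpo_leading",
) -> RenderResult:
    """Render the sampled population into a noisy multi-channel movie.

    The returned ground truth (label images, per-frame cell table, per-frame
    focus table, per-acquisition event table) is what detection and timing
    accuracy are measured against.
    """
    optics: OpticsConfig = scenario.optics
    sig = signal or SignalConfig()
    expr = expression or ExpressionProgram.default()
    if reporter_gene not in expr.genes:
        raise KeyError(f"reporter gene {reporter_gene!r} not in expression program")
    gene = expr.genes[reporter_gene]
    rng = np.random.default_rng(rng_seed)
    shape = scenario.field_shape
    n = scenario.n_frames
    dt = scenario.frame_interval_min
    px = optics.pixel_size_um
    sigma = optics.psf_sigma_px
    cells_by_id = {c.cell_id: c for c in cells}
    A = sig.ssb_replicative_integrated
    budget = sig.ssb_budget_foci_equivalents * A

    # stable per-cell replicative-focus geometry
    rep_geo: dict[int, list[tuple[float, float]]] = {}
    for c in cells:
        g = np.random.default_rng(rng_seed + 7919 * c.cell_id)
        rep_geo[c.cell_id] = [
            (-0.25 + g.uniform(-0.05, 0.05), g.uniform(-0.12, 0.12)),
            (0.25 + g.uniform(-0.05, 0.05), g.uniform(-0.12, 0.12)),
        ]

    # per-event reporter traces (rendered on the recipient lineage)
    traces = {ev.recipient_id: reporter_trace(gene, ev, scenario) for ev in events}

    # diffuse/body components are rendered sharp then PSF-blurred at the
    # end of each frame; focus spots are drawn at PSF width directly
    out = {ch: np.zeros((n, *shape), dtype=np.float32) for ch in CHANNELS}
    diffuse_acc = {ch: np.zeros(shape, dtype=np.float32) for ch in CHANNELS}
    labels = np.zeros((n, *shape), dtype=np.int32)
    cell_rows: list[dict] = []
    foci_rows: list[dict] = []

    def spot(ch: str, frame: int, cell: SimCell, l: float, d: float, integ: float, cls: str, t_min: float):
        x_um, y_um = _norm_to_um(cell, l, d, t_min, scenario)
        _add_spot(out[ch][frame], x_um / px, y_um / px, integ, sigma)
        foci_rows.append(
            dict(
                frame=frame,
                cell_id=cell.cell_id,
                channel=ch,
                x_px=x_um / px,
                y_px=y_um / px,
                l=l,
                d=d,
                integrated=integ,
                focus_class=cls,
            )
        )

    for f in range(n):
        t_min = f * dt
        bleach = (1.0 - optics.bleach_rate_per_frame) ** f
        alive = [c for c in cells if c.alive(f)]
        patches = {}
        for c in alive:
            patch = _capsule_patch(c, t_min, scenario, shape)
            if patch is None:
                continue
            ys, xs, m = patch
            patches[c.cell_id] = patch
            labels[f, ys, xs][m] = c.cell_id
            area = int(m.sum())
            diffuse_acc["phase"][ys, xs] += sig.phase_level * m
            cell_rows.append(
                dict(
                    frame=f,
                    cell_id=c.cell_id,
                    role=c.role,
                    parent=c.parent if c.parent is not None else 0,
                    x_um=float(c.center_at(t_min, scenario)[0]),
                    y_um=float(c.center_at(t_min, scenario)[1]),
                    angle_rad=c.angle_rad,
                    length_um=c.length_um(t_min, scenario),
                    width_um=c.width_um,
                    area_px=area,
                )
            )

        # ---- Ssb channel: budget redistribution ----------------------
        conj_foci: dict[int, list[tuple[float, float]]] = {}
        for ev in events:
            for acq in ev.acquisitions:
                if acq.entry_start_min <= t_min < acq.entry_end_min:
                    conj_foci.setdefault(ev.recipient_id, []).append(
                        (acq.pore_l_recipient, acq.pore_d_recipient)
                    )
                if acq.donor_appear_min <= t_min < acq.donor_end_min:
                    conj_foci.setdefault(acq.donor_id, []).append(
                        (acq.pore_l_donor, acq.pore_d_donor)
                    )
        for c in alive:
            if c.cell_id not in patches:
                continue
            ys, xs, m = patches[c.cell_id]
            area = max(int(m.sum()), 1)
            conj = conj_foci.get(c.cell_id, [])
            rep_A = A * (sig.replicative_dimming if conj else 1.0)
            conj_A = sig.conjugative_gain * A
            total_foci = 2 * rep_A + len(conj) * conj_A
            diffuse = max(budget - total_foci, 0.0) / area
            diffuse_acc["ypet"][ys, xs] += diffuse * m
            for l, d in rep_geo[c.cell_id]:
                spot("ypet", f, c, l, d, rep_A, "replicative", t_min)
            for l, d in conj:
                spot("ypet", f, c, l, d, conj_A, "conjugative", t_min)

        # ---- mCherry channel ----------------------------------------
        for c in alive:
            if c.role != "recipient" or c.cell_id not in patches:
                continue
            ys, xs, m = patches[c.cell_id]
            diffuse_acc["mcherry"][ys, xs] += sig.parb_diffuse_per_px * bleach * m
        for ev in events:
            if ev.conversion_min is None or t_min < ev.conversion_min:
                continue
            count = 1 + sum(1 for tdup in ev.duplication_min if t_min >= tdup)
            hosts = _lineage_alive(cells_by_id, ev.recipient_id, f)
            hosts = [h for h in hosts if h.cell_id in patches]
            if not hosts:
                continue
            pore = ev.acquisitions[0]
            # distribute copies round-robin over the daughters, then place
            # each host's share at well-separated slots
            per_host = [count // len(hosts)] * len(hosts)
            for j in range(count % len(hosts)):
                per_host[j] += 1
            for host, n_copies in zip(hosts, per_host):
                if n_copies == 0:
                    continue
                if n_copies == 1 and count == 1 and len(hosts) == 1:
                    # a single just-converted plasmid sits near its entry pole
                    sgn = 1.0 if pore.pore_l_recipient >= 0 else -1.0
                    slots = [(sgn * 0.3, pore.pore_d_recipient * 0.4)]
                else:
                    slots = _PARB_SLOTS[min(n_copies, 4)][:n_copies]
                for l, d in slots:
                    spot("mcherry", f, host, l, d, sig.parb_focus_integrated * bleach, "parB", t_min)

        # ---- reporter channel ---------------------------------------
        for c in alive:
            if c.cell_id not in patches:
                continue
            ys, xs, m = patches[c.cell_id]
            level = sig.green_autofluor_per_px
            if c.role == "donor":
                level += sig.donor_reporter_units * sig.reporter_scale_per_px
            else:
                root = c.cell_id
                while root not in traces and cells_by_id[root].parent is not None:
                    root = cells_by_id[root].parent
                if root in traces:
                    level += traces[root][f] * sig.reporter_scale_per_px
            diffuse_acc["sfgfp"][ys, xs] += level * m

        # ---- optics: diffuse/body components pass through the PSF ----
        # (focus spots were drawn at PSF width already; the body channel
        # uses a tighter transmitted-light blur)
        for ch in CHANNELS:
            blur = 0.8 if ch == "phase" else sigma
            out[ch][f] += ndi.gaussian_filter(diffuse_acc[ch], blur)
            diffuse_acc[ch][:] = 0.0

    # ---- camera model -----------------------------------------------
    for ch in CHANNELS:
        img = out[ch] + optics.background
        if optics.shot_noise:
            img = rng.poisson(img).astype(np.float32)
        if optics.read_noise_sd > 0:
            img = img + rng.normal(0.0, optics.read_noise_sd, img.shape).astype(np.float32)
        out[ch] = np.maximum(img, 0.0)

    movie = MovieStack(channels=out, pixel_size_um=px, frame_interval_min=dt)
    ev_rows = []
    for ev in events:
        for acq in ev.acquisitions:
            ev_rows.append(
                dict(
                    pair_id=ev.pair_id,
                    recipient_id=ev.recipient_id,
                    donor_id=acq.donor_id,
                    acquisition_index=acq.acquisition_index,
                    entry_start_min=acq.entry_start_min,
                    entry_end_min=acq.entry_end_min,
                    donor_appear_min=acq.donor_appear_min,
                    donor_end_min=acq.donor_end_min,
                    pore_l_recipient=acq.pore_l_recipient,
                    pore_d_recipient=acq.pore_d_recipient,
                    pore_l_donor=acq.pore_l_donor,
                    pore_d_donor=acq.pore_d_donor,
                    same_donor=acq.same_donor,
                    same_pore=acq.same_pore,
                    converted=ev.conversion_min is not None,
                    conversion_min=ev.conversion_min if ev.conversion_min is not None else np.nan,
                    conversion_lag_min=ev.conversion_lag_min if ev.conversion_lag_min is not None else np.nan,
                    dup1_min=ev.duplication_min[0] if len(ev.duplication_min) > 0 else np.nan,
                    dup2_min=ev.duplication_min[1] if len(ev.duplication_min) > 1 else np.nan,
                )
            )
    return RenderResult(
        movie=movie,
        labels=labels,
        cells_truth=pd.DataFrame(cell_rows),
        foci_truth=pd.DataFrame(foci_rows),
        events_truth=pd.DataFrame(ev_rows),
        cells=cells,
        events=events,
    )
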