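"""Sampling of synthetic mating populations and ground-truth transfer events.

Each field of view holds a grid of mating-pair slots. A slot is a sandwich
of three parallel rods — donor, recipient, second donor — so that repeated
plasmid acquisitions can originate from either the same or a different
donor, as happens in dense mating populations. Event times follow the
measured kinetics: transfer starts at a uniformly random time within the
configured window (cells engage at any cell-cycle stage), the
transconjugant-side Ssb focus lives for the transfer duration,
ss-to-dsDNA conversion succeeds with probability
``conversion_success_prob`` after a zero-truncated-normal lag, and
converted cells may acquire further T-strand copies.

Cells grow exponentially and divide at twice their birth length; a division
that would interrupt a scripted focus sequence (an ongoing acquisition, or
the conversion/duplication run) is deferred until the sequence completes,
after which plasmid foci are distributed over the daughters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .params import SimScenario

__all__ = ["SimCell", "Acquisition", "GroundTruthEvent", "sample_population", "draw_truncated_normal"]


@dataclass
class SimCell:
    """A rod-shaped cell with exponential length growth.

    Geometry is a capsule: total length = centerline endpoint distance +
    width. The cell grows about its fixed centre and divides into two
    daughters of ~half length when it doubles its birth length.
    """

    cell_id: int
    role: str  # donor | recipient
    center_um: tuple[float, float]  # (x, y) at birth
    angle_rad: float
    birth_length_um: float
    width_um: float
    birth_frame: int
    division_frame: Optional[int] = None  # first frame the daughters exist
    parent: Optional[int] = None
    children: Optional[tuple[int, int]] = None
    birth_age_frac: float = 0.0  # cell-cycle phase at birth_frame, in [0, 1)
    plasmid_copies: list[int] = field(default_factory=list)  # lineage count per frame
    # daughters elongate away from the septum: the pole facing the septum
    # stays anchored while the cell grows outward (anchor_sign = direction
    # of growth along the axis; None = free cell growing about its centre)
    anchor_um: Optional[tuple[float, float]] = None
    anchor_sign: float = 0.0
    max_length_um: Optional[float] = None  # crowding cap (microcolony packing)

    def length_um(self, t_min: float, scenario: SimScenario) -> float:
        """Length at absolute movie time ``t_min`` (exponential growth)."""
        t0 = self.birth_frame * scenario.frame_interval_min
        phase = self.birth_age_frac + max(t_min - t0, 0.0) / scenario.doubling_time_min
        length = self.birth_length_um * 2.0 ** min(phase, 1.0)
        if self.max_length_um is not None:
            length = min(length, self.max_length_um)
        return length

    def center_at(self, t_min: float, scenario: SimScenario) -> np.ndarray:
        if self.anchor_um is None:
            return np.asarray(self.center_um)
        u = np.array([math.cos(self.angle_rad), math.sin(self.angle_rad)])
        offset = self.length_um(t_min, scenario) / 2.0
        return np.asarray(self.anchor_um) + self.anchor_sign * offset * u

    def endpoints_um(self, t_min: float, scenario: SimScenario) -> np.ndarray:
        half = (self.length_um(t_min, scenario) - self.width_um) / 2.0
        u = np.array([math.cos(self.angle_rad), math.sin(self.angle_rad)])
        c = self.center_at(t_min, scenario)
        return np.stack([c - half * u, c + half * u])

    def alive(self, frame: int) -> bool:
        end = self.division_frame if self.division_frame is not None else 10**9
        return self.birth_frame <= frame < end


@dataclass
class Acquisition:
    """One T-strand transfer into a recipient (acquisition_index >= 1)."""

    donor_id: int
    acquisition_index: int
    entry_start_min: float
    entry_end_min: float  # recipient-side Ssb focus disappearance
    donor_appear_min: float
    donor_end_min: float
    pore_l_recipient: float
    pore_d_recipient: float
    pore_l_donor: float
    pore_d_donor: float
    same_donor: bool = True
    same_pore: bool = True


@dataclass
class GroundTruthEvent:
    """Full scripted history of one recipient's plasmid acquisition(s)."""

    pair_id: int
    donor_id: int  # donor of the first acquisition
    recipient_id: int
    acquisitions: list[Acquisition]
    conversion_min: Optional[float]  # None = conversion failed
    conversion_lag_min: Optional[float]
    duplication_min: list[float]  # times the copy count reaches 2, 3, ...
    frame_interval_min: float = 1.0

    def frame_of(self, t_min: Optional[float]) -> Optional[int]:
        """First frame index at or after an event time (frame f is at f*dt)."""
        if t_min is None:
            return None
        return int(math.ceil(t_min / self.frame_interval_min - 1e-9))

    @property
    def t_entry_start_frame(self) -> int:
        return self.frame_of(self.acquisitions[0].entry_start_min)

    @property
    def t_entry_end_frame(self) -> int:
        return self.frame_of(self.acquisitions[0].entry_end_min)

    @property
    def t_conversion_frame(self) -> Optional[int]:
        return self.frame_of(self.conversion_min)

    @property
    def duplication_frames(self) -> list[int]:
        return [self.frame_of(t) for t in self.duplication_min]

    @property
    def script_end_min(self) -> float:
        """Time after which no new scripted focus appears in the pair."""
        ends = [a.entry_end_min for a in self.acquisitions]
        ends += [a.donor_end_min for a in self.acquisitions]
        if self.conversion_min is not None:
            ends.append(self.conversion_min)
        ends.extend(self.duplication_min)
        return max(ends)


def draw_truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal(mean, sd) truncated at zero, by rejection."""
    if sd == 0:
        return max(mean, 0.0)
    while True:
        x = rng.normal(mean, sd)
        if x > 0:
            return x


def _draw_recipient_pore(rng: np.random.Generator, d_sign: float) -> tuple[float, float]:
    """Entry pores sit in the polar regions, at the membrane facing a donor."""
    l = math.copysign(0.5 - abs(rng.normal(0.0, 0.08)), rng.choice([-1.0, 1.0]))
    l = float(np.clip(l, -0.5, 0.5))
    d = d_sign * float(np.clip(abs(rng.normal(0.42, 0.04)), 0.30, 0.45))
    return l, d


def _draw_donor_pore(rng: np.random.Generator, d_sign: float) -> tuple[float, float]:
    """Exit pores prefer the quarter positions, at the cell periphery."""
    l = float(np.clip(rng.choice([-1.0, 1.0]) * rng.normal(0.25, 0.07), -0.5, 0.5))
    d = d_sign * float(np.clip(abs(rng.normal(0.42, 0.04)), 0.30, 0.45))
    return l, d


def _slot_layout(scenario: SimScenario) -> list[tuple[float, float]]:
    """Centres (µm) of triplet slots on a grid that fits the field of view."""
    h, w = scenario.field_shape
    px = scenario.optics.pixel_size_um
    field_w, field_h = w * px, h * px
    # a slot must hold a freshly divided pair at end-of-movie growth
    slot_w = scenario.cell_length_um_mean * 2.0 + 0.2
    slot_h = 3 * scenario.optics.cell_width_um + 0.9
    ncol = max(int(field_w // slot_w), 1)
    nrow = max(int(field_h // slot_h), 1)
    return [
        ((c + 0.5) * field_w / ncol, (r + 0.5) * field_h / nrow)
        for r in range(nrow)
        for c in range(ncol)
    ]


def sample_population(
    scenario: SimScenario, rng_seed: int
) -> tuple[list[SimCell], list[GroundTruthEvent]]:
    """Draw the cells and scripted transfer events of one field of view.

    Deterministic given (scenario, seed). ``scenario.n_pairs == 0`` yields
    an empty event list, not an error.
    """
    rng = np.random.default_rng(rng_seed)
    kp = scenario.kinetics
    dt = scenario.frame_interval_min
    cells: list[SimCell] = []
    events: list[GroundTruthEvent] = []
    centres = _slot_layout(scenario)
    n_slots_needed = scenario.n_pairs + scenario.n_extra_donors + scenario.n_extra_recipients
    if n_slots_needed > len(centres):
        raise ValueError(
            f"scenario needs {n_slots_needed} slots but the field fits {len(centres)}"
        )
    order = rng.permutation(len(centres))
    next_id = 1
    gap_um = scenario.optics.cell_width_um + 0.2  # centre spacing within a slot
    min_division_min: dict[int, float] = {}

    def new_cell(role: str, center, angle) -> SimCell:
        nonlocal next_id
        # floor keeps every cell comfortably rod-shaped (aspect >> 1.5)
        birth_len = max(
            rng.normal(scenario.cell_length_um_mean / 1.45, scenario.cell_length_um_sd / 1.45),
            1.7,
        )
        cell = SimCell(
            cell_id=next_id,
            role=role,
            center_um=(float(center[0]), float(center[1])),
            angle_rad=angle,
            birth_length_um=birth_len,
            width_um=scenario.optics.cell_width_um,
            birth_frame=0,
            birth_age_frac=rng.uniform(0.0, 1.0),
        )
        next_id += 1
        cells.append(cell)
        return cell

    for k in range(scenario.n_pairs):
        cx, cy = centres[order[k]]
        angle = rng.uniform(-0.06, 0.06)  # nearly horizontal rods
        nrm = np.array([-math.sin(angle), math.cos(angle)])
        donor_a = new_cell("donor", np.array([cx, cy]) - gap_um * nrm, angle)
        recip = new_cell("recipient", np.array([cx, cy]), angle)
        donor_b = new_cell("donor", np.array([cx, cy]) + gap_um * nrm, angle)

        # --- first acquisition ---------------------------------------
        converted = rng.random() < kp.conversion_success_prob
        duration = draw_truncated_normal(
            rng, kp.transfer_duration_min, kp.transfer_duration_sd_min
        )
        # The Ssb->ParB lag decomposes as transfer duration + a post-transfer
        # conversion delay, so conversion always follows entry completion;
        # the printed lag moments are recovered because
        # mean_lag = mean_duration + mean_delay and the variances add.
        lag = None
        if converted:
            d_mean, d_sd = kp.conversion_delay_mean_sd
            # gamma law: positive waiting time with the exact target moments
            k_shape = (d_mean / d_sd) ** 2
            delay = rng.gamma(k_shape, d_sd**2 / d_mean)
            if scenario.conversion_during_transfer:
                # complementary-strand synthesis may begin before transfer
                # completes: the delay then runs from mid-transfer
                lag = max(duration / 2.0 + delay, duration * 0.6)
            else:
                lag = duration + delay
        tau = rng.uniform(scenario.entry_start_min, scenario.entry_start_max)
        offsets = sorted(scenario.donor_offset_probs)
        probs = [scenario.donor_offset_probs[o] for o in offsets]
        off = float(rng.choice(offsets, p=probs))
        donor_life = draw_truncated_normal(
            rng, kp.donor_lifespan_min.mean, kp.donor_lifespan_min.sd
        )
        lr, dr = _draw_recipient_pore(rng, d_sign=-1.0)  # faces donor_a
        ld, dd = _draw_donor_pore(rng, d_sign=+1.0)  # faces the recipient
        acqs = [
            Acquisition(
                donor_id=donor_a.cell_id,
                acquisition_index=1,
                entry_start_min=tau,
                entry_end_min=tau + duration,
                donor_appear_min=tau + off,
                donor_end_min=tau + off + donor_life,
                pore_l_recipient=lr,
                pore_d_recipient=dr,
                pore_l_donor=ld,
                pore_d_donor=dd,
            )
        ]
        conv = tau + lag if converted else None

        # --- duplications (copy count 1 -> 2 -> 3 -> ...) -------------
        dups: list[float] = []
        if converted:
            t_dup = conv + draw_truncated_normal(
                rng, kp.dup1_interval_min.mean, kp.dup1_interval_min.sd
            )
            dups.append(t_dup)
            for _ in range(kp.max_copies_before_division - 2):
                t_dup = t_dup + draw_truncated_normal(
                    rng, kp.dup2_interval_min.mean, kp.dup2_interval_min.sd
                )
                dups.append(t_dup)

        # --- possible further acquisition -----------------------------
        if converted and rng.random() < kp.multi_acquisition_prob:
            start2 = conv + rng.uniform(*scenario.reacquisition_delay_min)
            same_donor = rng.random() < kp.same_donor_prob
            if same_donor:
                donor2, dsign = donor_a, -1.0
                same_pore = rng.random() < kp.same_pore_prob
            else:
                donor2, dsign = donor_b, +1.0
                same_pore = False
            if same_pore:
                lr2 = float(np.clip(lr + rng.normal(0.0, scenario.pore_jitter), -0.5, 0.5))
                dr2 = float(np.clip(dr + rng.normal(0.0, scenario.pore_jitter), -0.45, -0.30))
            else:
                lr2, dr2 = _draw_recipient_pore(rng, d_sign=dsign)
            ld2, dd2 = _draw_donor_pore(rng, d_sign=-dsign)
            dur2 = draw_truncated_normal(
                rng, kp.transfer_duration_min, kp.transfer_duration_sd_min
            )
            off2 = float(rng.choice(offsets, p=probs))
            life2 = draw_truncated_normal(
                rng, kp.donor_lifespan_min.mean, kp.donor_lifespan_min.sd
            )
            acqs.append(
                Acquisition(
                    donor_id=donor2.cell_id,
                    acquisition_index=2,
                    entry_start_min=start2,
                    entry_end_min=start2 + dur2,
                    donor_appear_min=start2 + off2,
                    donor_end_min=start2 + off2 + life2,
                    pore_l_recipient=lr2,
                    pore_d_recipient=dr2,
                    pore_l_donor=ld2,
                    pore_d_donor=dd2,
                    same_donor=same_donor,
                    same_pore=same_pore,
                )
            )

        event = GroundTruthEvent(
            pair_id=k,
            donor_id=donor_a.cell_id,
            recipient_id=recip.cell_id,
            acquisitions=acqs,
            conversion_min=conv,
            conversion_lag_min=lag,
            duplication_min=dups,
            frame_interval_min=dt,
        )
        events.append(event)

        # lineage-level plasmid copy count per frame
        t_frames = np.arange(scenario.n_frames) * dt
        copies = np.zeros(scenario.n_frames, dtype=int)
        if conv is not None:
            copies[t_frames >= conv] = 1
            for j, tdup in enumerate(dups):
                copies[t_frames >= tdup] = 2 + j
        recip.plasmid_copies = copies.tolist()

        guard = event.script_end_min + 1.0
        min_division_min[recip.cell_id] = guard
        min_division_min[donor_a.cell_id] = guard
        min_division_min[donor_b.cell_id] = guard

    for j in range(scenario.n_extra_donors):
        cx, cy = centres[order[scenario.n_pairs + j]]
        new_cell("donor", np.array([cx, cy]), rng.uniform(-0.06, 0.06))
    for j in range(scenario.n_extra_recipients):
        cx, cy = centres[order[scenario.n_pairs + scenario.n_extra_donors + j]]
        new_cell("recipient", np.array([cx, cy]), rng.uniform(-0.06, 0.06))

    _schedule_divisions(cells, scenario, min_division_min)
    return cells, events


def _schedule_divisions(
    cells: list[SimCell],
    scenario: SimScenario,
    min_division_min: dict[int, float],
) -> None:
    """Split every cell that completes its cycle during the movie.

    Daughters are centred on the two halves of the mother and inherit role
    and orientation; a daughter may divide again within the movie.
    """
    dt = scenario.frame_interval_min
    queue = list(cells)
    next_id = max((c.cell_id for c in cells), default=0) + 1
    while queue:
        cell = queue.pop(0)
        remaining = (1.0 - cell.birth_age_frac) * scenario.doubling_time_min
        t_div = cell.birth_frame * dt + remaining
        t_div = max(t_div, min_division_min.get(cell.cell_id, 0.0))
        f_div = int(math.ceil(t_div / dt))
        if f_div >= scenario.n_frames:
            continue
        cell.division_frame = f_div
        length = cell.length_um(f_div * dt, scenario)
        u = np.array([math.cos(cell.angle_rad), math.sin(cell.angle_rad)])
        c0 = cell.center_at(f_div * dt, scenario)
        kids = []
        off = length / 4.0 + scenario.septation_gap_um / 2.0
        for s in (-1.0, +1.0):
            kid = SimCell(
                cell_id=next_id,
                role=cell.role,
                center_um=tuple(c0 + s * off * u),
                angle_rad=cell.angle_rad,
                birth_length_um=length / 2.0,
                width_um=cell.width_um,
                birth_frame=f_div,
                parent=cell.cell_id,
                birth_age_frac=0.0,
                anchor_um=tuple(c0 + s * (scenario.septation_gap_um / 2.0) * u),
                anchor_sign=s,
                # crowding: a daughter pair must stay inside its grid slot
                max_length_um=(
                    scenario.cell_length_um_mean * 2.0 - 0.3 - scenario.septation_gap_um
                )
                / 2.0,
            )
            next_id += 1
            kids.append(kid)
            cells.append(kid)
            queue.append(kid)
        cell.children = (kids[0].cell_id, kids[1].cell_id)
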