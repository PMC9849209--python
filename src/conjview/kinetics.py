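"""Deterministic ssDNA bookkeeping during a single transfer event.

During conjugation the TraI relaxase-helicase unwinds the plasmid duplex in
the donor, the T-strand is translocated through the T4SS into the recipient,
and rolling-circle replication (RCR) re-synthesises the complementary strand
of the retained strand in the donor. Because unwinding is faster than both
removal processes, ssDNA transiently accumulates on the donor side; the
recipient side accumulates the incoming T-strand until the ss-to-dsDNA
conversion. Each pool is a piecewise-linear closed form of the three rates,
and a focus is called "visible" in a compartment once its ssDNA exceeds a
detection threshold (the amount needed to recruit a microscopically
resolvable number of Ssb molecules).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import KineticParams

__all__ = ["SsdnaTrajectories", "simulate_ssdna_kinetics", "first_crossing_s"]


@dataclass
class SsdnaTrajectories:
    """Closed-form ssDNA trajectories (nt) on a fixed time grid (s)."""

    t_s: np.ndarray
    unwound_nt: np.ndarray
    transferred_nt: np.ndarray
    rcr_complemented_nt: np.ndarray
    donor_ssdna_nt: np.ndarray
    recipient_ssdna_nt: np.ndarray
    donor_visible: np.ndarray
    recipient_visible: np.ndarray

    def visibility_onset_s(self, compartment: str) -> float:
        """Time of first visibility (s); ``inf`` if never visible."""
        vis = self.donor_visible if compartment == "donor" else self.recipient_visible
        idx = np.flatnonzero(vis)
        return float(self.t_s[idx[0]]) if idx.size else float("inf")


def simulate_ssdna_kinetics(
    params: KineticParams,
    dt_s: float = 0.1,
    detection_threshold_nt: int = 5000,
    t_max_s: float | None = None,
) -> SsdnaTrajectories:
    """Evaluate the piecewise-linear ssDNA pools of one transfer event.

    unwound(t)      = min(helicase_rate * t, L)
    transferred(t)  = min(transfer_rate * t, unwound(t), L)
    rcr(t)          = min(rcr_rate * t, unwound(t), L)
    donor ssDNA     = (unwound - transferred) + (unwound - rcr)
    recipient ssDNA = transferred (until conversion, outside this scope)
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be > 0")
    L = float(params.plasmid_length_nt)
    h, tr, rc = params.helicase_rate_nt_s, params.transfer_rate_nt_s, params.rcr_rate_nt_s
    if t_max_s is None:
        # run until every pool has completed (slowest of the three rates)
        t_max_s = 1.05 * L / min(h, tr, rc)
    t = np.arange(0.0, t_max_s + dt_s, dt_s)
    unwound = np.minimum(h * t, L)
    transferred = np.minimum.reduce([tr * t, unwound, np.full_like(t, L)])
    rcr = np.minimum.reduce([rc * t, unwound, np.full_like(t, L)])
    donor = (unwound - transferred) + (unwound - rcr)
    recipient = transferred
    return SsdnaTrajectories(
        t_s=t,
        unwound_nt=unwound,
        transferred_nt=transferred,
        rcr_complemented_nt=rcr,
        donor_ssdna_nt=donor,
        recipient_ssdna_nt=recipient,
        donor_visible=donor >= detection_threshold_nt,
        recipient_visible=recipient >= detection_threshold_nt,
    )


def first_crossing_s(t_s: np.ndarray, y: np.ndarray, threshold: float) -> float:
    """First grid time at which ``y`` reaches ``threshold`` (inf if never)."""
    idx = np.flatnonzero(y >= threshold)
    return float(t_s[idx[0]]) if idx.size else float("inf")
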