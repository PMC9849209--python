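"""Parameter containers for the conjugation simulator and pipeline.

The defaults encode the measured kinetics of F-plasmid conjugative transfer
between *E. coli* cells: TraI helicase unwinding at ~1120 nt/s, T-strand
translocation at ~620 nt/s, rolling-circle complementary-strand synthesis at
~650-750 nt/s, a ~4 min lag between ssDNA entry (Ssb focus) and
ss-to-dsDNA conversion (ParB focus), ~10 min plasmid duplication intervals,
an 83.3% conversion success rate and a 40% multiple-acquisition rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml


@dataclass
class MeanSd:
    """A mean/sd pair describing a zero-truncated normal draw (minutes)."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass
class KineticParams:
    """Rates, lags and branching probabilities of the transfer model.

    Rates are nt/s; lags and intervals are minutes (mean/sd of a normal
    truncated at zero); probabilities are Bernoulli success fractions.
    """

    plasmid_length_nt: int = 108_000
    helicase_rate_nt_s: float = 1120.0
    helicase_rate_sd_nt_s: float = 160.0
    transfer_rate_nt_s: float = 620.0
    rcr_rate_nt_s: float = 700.0
    conversion_lag_min: MeanSd = field(default_factory=lambda: MeanSd(4.0, 1.6))
    dup1_interval_min: MeanSd = field(default_factory=lambda: MeanSd(10.4, 4.7))
    dup2_interval_min: MeanSd = field(default_factory=lambda: MeanSd(10.1, 5.1))
    conversion_success_prob: float = 0.833
    multi_acquisition_prob: float = 0.40
    same_donor_prob: float = 0.92
    same_pore_prob: float = 0.79
    max_copies_before_division: int = 4
    # per-event spread of the transfer duration (the conjugative-focus
    # lifespan in the transconjugant is 2.9 +/- 1.1 min for the 108 kb
    # plasmid at 620 nt/s); the donor-side focus is shorter lived.
    transfer_duration_sd_min: float = 1.1
    donor_lifespan_min: MeanSd = field(default_factory=lambda: MeanSd(2.5, 1.1))

    def __post_init__(self) -> None:
        if isinstance(self.conversion_lag_min, (tuple, list)):
            self.conversion_lag_min = MeanSd(*self.conversion_lag_min)
        if isinstance(self.dup1_interval_min, (tuple, list)):
            self.dup1_interval_min = MeanSd(*self.dup1_interval_min)
        if isinstance(self.dup2_interval_min, (tuple, list)):
            self.dup2_interval_min = MeanSd(*self.dup2_interval_min)
        if isinstance(self.donor_lifespan_min, (tuple, list)):
            self.donor_lifespan_min = MeanSd(*self.donor_lifespan_min)
        for name in ("helicase_rate_nt_s", "transfer_rate_nt_s", "rcr_rate_nt_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.plasmid_length_nt <= 0:
            raise ValueError("plasmid_length_nt must be > 0")
        for name in (
            "conversion_success_prob",
            "multi_acquisition_prob",
            "same_donor_prob",
            "same_pore_prob",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def transfer_duration_min(self) -> float:
        """Mean time to translocate the full plasmid (min)."""
        return self.plasmid_length_nt / self.transfer_rate_nt_s / 60.0

    @property
    def conversion_delay_mean_sd(self) -> tuple[float, float]:
        """Moments of the post-transfer conversion delay.

        The Ssb->ParB lag is transfer duration + conversion delay; the
        delay moments are chosen so the lag reproduces the configured
        lag mean/sd exactly (the delay itself is drawn from a gamma law,
        positive by construction).
        """
        from scipy import stats

        a = -self.transfer_duration_min / self.transfer_duration_sd_min
        # truncated-at-zero moments of the transfer duration
        phi, Phi = stats.norm.pdf(a), 1.0 - stats.norm.cdf(a)
        shift = phi / Phi
        d_mean = self.transfer_duration_min + self.transfer_duration_sd_min * shift
        d_var = self.transfer_duration_sd_min**2 * (1 + a * shift - shift**2)
        m = max(self.conversion_lag_min.mean - d_mean, 0.2)
        s = math.sqrt(max(self.conversion_lag_min.sd**2 - d_var, 0.04))
        return m, s


@dataclass
class GeneProgram:
    """Expression timing of one reporter class.

    ``leading_ss`` genes sit in the leading region behind single-stranded
    (Frpo-type) promoters: transcription starts while the incoming plasmid
    is still single stranded, so protein onset is tied to ssDNA entry and
    production shuts off a fixed time after the ss-to-dsDNA conversion.
    ``maintenance`` (and ``tra``) genes need a double-stranded promoter and
    only switch on after conversion, plateauing much later. With
    ``frpo_present`` False a leading_ss gene produces nothing.
    """

    gene_class: str = "leading_ss"  # leading_ss | leading_opposite_strand | maintenance | tra
    onset_relative_to: str = "ssDNA_entry"  # ssDNA_entry | conversion
    onset_min: float = 0.0
    peak_min: float = 5.0
    shutoff_min: Optional[float] = 30.0
    plateau_min: Optional[float] = None
    frpo_present: bool = True
    production_rate: float = 1.0  # SNR units accumulated per minute at peak
    maturation_min: float = 6.0  # translation + fluorophore maturation delay

    def __post_init__(self) -> None:
        known = {"leading_ss", "leading_opposite_strand", "maintenance", "tra"}
        if self.gene_class not in known:
            raise ValueError(f"unknown gene_class {self.gene_class!r}")
        if self.gene_class == "leading_ss" and self.onset_relative_to != "ssDNA_entry":
            raise ValueError("leading_ss genes are timed from ssDNA entry")
        times = [t for t in (self.onset_min, self.peak_min, self.shutoff_min) if t is not None]
        if times != sorted(times):
            raise ValueError("require onset <= peak <= shutoff")

    @property
    def effective_rate(self) -> float:
        if self.gene_class == "leading_ss" and not self.frpo_present:
            return 0.0
        return self.production_rate


@dataclass
class ExpressionProgram:
    """Named collection of gene programs rendered into the reporter channel."""

    genes: dict[str, GeneProgram] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "ExpressionProgram":
        return cls(
            genes={
                "frpo_leading": GeneProgram(),
                "frpo_deleted": GeneProgram(frpo_present=False),
                "maintenance": GeneProgram(
                    gene_class="maintenance",
                    onset_relative_to="conversion",
                    onset_min=5.0,
                    peak_min=30.0,
                    shutoff_min=None,
                    plateau_min=75.0,
                    production_rate=0.5,
                ),
            }
        )


@dataclass
class OpticsConfig:
    """Rendering / noise model of the synthetic microscope."""

    pixel_size_um: float = 0.065
    psf_sigma_px: float = 1.3
    background: float = 100.0  # camera offset + medium fluorescence, counts
    read_noise_sd: float = 2.0
    shot_noise: bool = True
    bleach_rate_per_frame: float = 0.0  # exponential decay of the red channel
    cell_width_um: float = 1.0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.psf_sigma_px <= 0:
            raise ValueError("pixel size and PSF sigma must be positive")


@dataclass
class SimScenario:
    """Population layout and acquisition settings of one synthetic movie."""

    n_pairs: int = 10
    n_extra_donors: int = 0
    n_extra_recipients: int = 0
    field_shape: tuple[int, int] = (256, 256)
    n_frames: int = 60
    frame_interval_min: float = 1.0
    entry_start_min: float = 2.0
    entry_start_max: float = 8.0
    doubling_time_min: float = 100.0
    cell_length_um_mean: float = 2.6
    cell_length_um_sd: float = 0.4
    septation_gap_um: float = 0.18  # daughter separation at division
    conversion_during_transfer: bool = False
    # second-acquisition delay after conversion, uniform draw (min)
    reacquisition_delay_min: tuple[float, float] = (2.0, 12.0)
    pore_jitter: float = 0.03  # same-pore positional jitter, normalised units
    # donor-vs-transconjugant focus appearance offset (minutes): probability
    # of each offset class; 77.8% simultaneous, remainder donor-later
    donor_offset_probs: dict[int, float] = field(
        default_factory=lambda: {0: 0.778, 1: 0.16, 2: 0.062}
    )
    kinetics: KineticParams = field(default_factory=KineticParams)
    optics: OpticsConfig = field(default_factory=OpticsConfig)

    def __post_init__(self) -> None:
        if self.frame_interval_min not in (1.0, 5.0):
            # non-default cadences are allowed but announced
            import warnings

            warnings.warn(
                f"frame_interval_min={self.frame_interval_min} is outside the "
                "usual {1, 5} min acquisition cadences",
                stacklevel=2,
            )
        total = sum(self.donor_offset_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("donor_offset_probs must sum to 1")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["field_shape"] = list(self.field_shape)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimScenario":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["field_shape"] = tuple(d["field_shape"])
        d["donor_offset_probs"] = {int(k): v for k, v in d["donor_offset_probs"].items()}
        d["reacquisition_delay_min"] = tuple(d["reacquisition_delay_min"])
        kp = d.get("kinetics", {})
        for key in ("conversion_lag_min", "dup1_interval_min", "dup2_interval_min", "donor_lifespan_min"):
            if key in kp and isinstance(kp[key], dict):
                kp[key] = MeanSd(**kp[key])
        d["kinetics"] = KineticParams(**kp)
        d["optics"] = OpticsConfig(**d.get("optics", {}))
        return cls(**d)


def truncated_normal_mean(mean: float, sd: float) -> float:
    """Analytic mean of a normal(mean, sd) truncated at zero.

    The generator draws all lags/intervals from zero-truncated normals, so
    recovery checks compare against this, not the raw mean.
    """
    from scipy import stats

    if sd == 0:
        return mean
    alpha = -mean / sd
    return mean + sd * stats.norm.pdf(alpha) / (1.0 - stats.norm.cdf(alpha))
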