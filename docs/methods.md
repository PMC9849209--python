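# Methods

## The generative model

One transfer event between an adjacent donor and recipient is scripted as
follows (all defaults in `conjview.params.KineticParams`):

* **ssDNA bookkeeping.** Within an event, unwinding, transfer and
  rolling-circle complementary-strand synthesis are deterministic
  piecewise-linear pools: `unwound(t) = min(h·t, L)`,
  `transferred(t) = min(r_t·t, unwound, L)`, `rcr(t) = min(r_c·t, unwound,
  L)`, with donor ssDNA `= (unwound − transferred) + (unwound − rcr)` and
  recipient ssDNA `= transferred`. Defaults: `L = 108,000` nt,
  `h = 1120` nt/s, `r_t = 620` nt/s, `r_c = 700` nt/s. A compartment's
  focus is "visible" when its pool exceeds a detection threshold (default
  5,000 nt — roughly the ssDNA needed to recruit a resolvable number of
  Ssb molecules; the argument operates at the level of average rates, so no
  stochastic single-molecule model is attempted).
* **Event times.** The transconjugant-side focus lives for the transfer
  duration, drawn from a normal(2.9, 1.1 min) truncated at zero
  (2.9 min = L / r_t). The ss-to-dsDNA conversion succeeds with
  probability 0.833; its lag after focus appearance is
  `duration + delay`, where the delay is gamma-distributed with moments
  chosen so that the lag's mean/SD are exactly the configured 4 ± 1.6 min.
  This decomposition (rather than an independent truncated-normal lag)
  guarantees the ordering `entry_end < conversion` that defines the
  observable sequence — the Ssb focus disappears, then the ParB focus
  forms — without biasing either marginal; the configured moments
  decompose consistently (2.9 + 1.1 = 4.0; 1.1² + 1.16² ≈ 1.6²). A config
  switch `conversion_during_transfer` instead lets the delay run from
  mid-transfer; it is off by default and asserted nowhere.
* **Duplications.** After conversion the copy count steps 1→2→3→4 at
  zero-truncated-normal intervals (10.4 ± 4.7, then 10.1 ± 5.1 min),
  capped at 4 copies before division.
* **Repeated acquisitions.** A converted transconjugant re-acquires a
  T-strand with probability 0.40, from the same donor with probability
  0.92, through the same pore (coordinates jittered by σ = 0.03 normalised
  units) with probability 0.79; otherwise the second flanking donor and a
  freshly drawn pore are used. The re-entry starts uniformly 2–12 min
  after conversion.
* **Pore geometry.** Entry pores in recipients are polar
  (`|l| = 0.5 − |N(0, 0.08)|`) and membrane-proximal
  (`|d| ≈ 0.42 ± 0.04`, clipped to [0.30, 0.45] so the rendered spot
  centre stays inside the cell); donor exit pores prefer the quarter
  positions (`l ~ ±N(0.25, 0.07)`) at the periphery. These are qualitative
  mixtures matching published localisation heatmaps, which give peaks, not
  parametric laws.
* **Appearance offsets.** The donor-side focus appears simultaneously with
  the transconjugant's in 77.8% of events, 1 min later in 16%, 2 min later
  in 6.2% (configurable per offset class, −1 min allowed); its lifespan is
  truncated-normal 2.5 ± 1.1 min.

## Cells and rendering

Cells are capsules (length = centreline + width, width 1 µm) on a grid of
mating-triplet slots (donor/recipient/donor stacked with ~0.2 µm gaps,
~3 px at the default 0.065 µm/px — adjacent at optical resolution yet
separable by the watershed). Growth is exponential with a 100 min doubling
time (slow-growth room-temperature imaging conditions); division occurs at
twice birth length, splits the mother into two daughters separated by a
0.18 µm septation gap, and each daughter elongates away from the septum.
Two idealisations keep lineages inside their slot: divisions that would
interrupt a scripted focus sequence are deferred until the sequence
completes, and daughters stop elongating at a crowding cap. Both mimic
real constraints (crowded microcolonies, and the rarity of division during
a ~10-min event window) but are idealisations: real transconjugants can
divide mid-sequence, and the pipeline's lineage-level counting handles
that case (tested by dividing transconjugants carrying ParB foci after
their duplication run).

Channels: cell body (uniform level per cell), Ssb-Ypet, mCh-ParB, sfGFP.
Fluorophores render as diffuse cytoplasmic signal plus Gaussian spots
(σ = 1.3 px). Diffuse and body components are PSF-blurred; spots are drawn
at PSF width directly. The Ssb channel enforces a fixed per-cell budget of
45 replicative-focus equivalents: vegetative cells show two replicative
foci (integrated intensity A = 2000 counts each) plus diffuse signal;
during transfer each conjugative focus takes 35A and replicative foci drop
to 0.5A, the difference leaving the diffuse pool, so the per-cell
integrated signal is constant (the redistribution observed in vivo).
Recipients carry diffuse mCh-ParB (≈1.55× background SNR); each
double-stranded plasmid copy adds one ParB focus, placed at well-separated
axial slots (a single new copy near its entry pole, segregating toward
quarter positions as it duplicates). Camera model: Poisson shot noise over
signal + background (100 counts), Gaussian read noise (σ = 2), optional
per-frame exponential bleaching of the red channel (off by default).

The reporter model: production rate ramps from the gene's onset (ssDNA
entry for single-stranded Frpo-type promoters, conversion for
double-stranded promoters) to its peak, decays exponentially once the
template converts (time constant `(shutoff − maturation)/3`, i.e. ~8 min
for the default 30-min shutoff), is delayed by 6 min of translation +
fluorophore maturation, and is diluted by growth. With `frpo_present =
False` the rate is zero. Maintenance-class genes saturate toward a late
plateau (default 75 min) instead of shutting off.

## Pipeline choices

* **Segmentation** — median-background subtraction, Gaussian smoothing
  (σ = 1 px), Otsu threshold, hole filling, then watershed on the smoothed
  distance transform. Markers are connected components of
  `EDT ≥ 0.55 × (width/2)`: exactly one marker per rod ridge, while thin
  noise bridges between cells stay below threshold and are cut at the
  neck. (Generic h-maxima markers were tried first and discarded: on
  digitised rods they fragment on sub-pixel ridge bumps yet cannot split
  rods merged along their full length.) Filters: area ≥ 50 px, aspect
  ≥ 1.5. Cell width is recovered from the capsule area identity
  `area = w(L − w) + πw²/4`; length is the principal-axis extent.
* **Tracking** — greedy largest-overlap linking; a 1→2 split whose parts
  each hold ≥ 30% of the mother's area is a division; a "division" whose
  smaller product dies within 2 frames is repaired as watershed flicker.
  Lineage queries continue through divisions with daughter-mean (SNR) or
  daughter-sum (focus count) aggregation.
* **Focus detection** — difference of Gaussians (σ 1 and 3 px), local
  maxima with prominence ≥ 5 robust σ of the in-cell band-pass, subpixel
  3×3 centroid, intensity = integrated signal above the cell's median
  cytoplasm over a 7×7 window. Two guards matter in practice: peaks up to
  3 px outside a mask are assigned to the nearest cell (membrane-proximal
  conjugative foci blur past the slightly eroded Otsu boundary), and the
  integrated intensity must exceed 3× the window's shot-noise scale
  (suppresses rare consecutive-frame noise doublets that would otherwise
  debounce into fake ParB runs). Classification: `|d| ≥ 0.3` →
  conjugative, else replicative; red-channel foci are ParB.
* **Event annotation** — conjugative-focus runs bridge 1-frame detection
  gaps; ParB runs additionally require 2-frame persistence, and the
  conversion/duplication frames come from the *longest* persistent red run
  starting at/after Ssb appearance, because genuine ParB signal is
  permanent while cross-cell stray detections during transient mask merges
  are brief. Conjugative runs use persistence 1: these foci are ~35× over
  threshold, so debounce only discards genuinely short transfers and
  biases the recovered lag. All lags are exact frame arithmetic. Events
  cut by the movie end are right-censored (conversion needs ≥ 15 min of
  movie past appearance to be called a failure; duplications ≥ 25 min past
  conversion) and censored fields never enter means.
* **Expression windows** — per-cell fold increase over non-overlapping
  10-min intervals anchored at conversion; an interval is productive when
  a one-sided t-test across ≥ 5 cells rejects FI ≤ 1 at α = 0.05; the
  window is the longest run of ≥ 2 productive intervals (a single
  significant interval is within the α-level false-positive expectation).
* **Statistics** — Mann–Whitney is exact (rank-sum distribution by
  dynamic programming over doubled midranks, ties handled exactly) for
  combined n ≤ 25, tie-corrected normal approximation beyond; the
  two-sided p is the permutation mass of `|U − n₁n₂/2|` at least as large
  as observed. Dunnett's many-to-one comparisons use the multivariate-t
  implementation in scipy. Transfer rates round to the nearest 10 nt/s,
  the convention that reproduces both 620 (108 kb / 2.9 min) and 770
  (4.6 Mb / 100 min).

## Study conditions and problem sizes

The recovery experiment uses 500 mating pairs: 50 independent 256×256 px
fields of 10 triplet slots, 60 frames at 1 min/frame, entry starting
uniformly 2–8 min into the movie. Duplication intervals are measured on
the same 1 min/frame movies — bleaching is off in the generator, so the
reason real experiments switch to 5 min/frame for duplication timing does
not apply here; the events module warns (rather than refuses) when an
interval-sensitive measurement runs at an unexpected cadence. Analysis
scripts run a 15-field version of the same experiment; the acceptance
script runs the full 50.

## What passing tests do and do not show

The generator emulates the features the pipeline measures — rod geometry,
focus photometry and redistribution, event sequencing, camera noise — but
not real-microscopy nuisances: no phase-contrast halo or debris, no focus
drift or z-blur, no cell curvature or filamentation, no mechanical
cell–cell pushing, no fluorophore maturation stochasticity, and pair
geometry is a regular grid rather than a crowded mat. Recovery of the
configured parameters therefore validates the measurement chain's logic
and calibration, not its robustness to every real-world artefact; the
segmentation stage in particular is deliberately simple and sits behind a
single interface so a stronger segmenter can be substituted.

## Known limitations

* Donor-side ssDNA is tracked as a single pool (retained strand +
  unsent T-strand); the split is not observable in the data the model is
  built on.
* The ±164 nt/s uncertainty printed alongside the 620 nt/s rate is not
  reproduced: simple relative-error propagation of ±1.1 min on 2.9 min
  gives ≈ ±235 nt/s, and the original propagation method is unstated. The
  package reports the point estimate and leaves uncertainty propagation to
  the caller.
* Cells whose entire transfer falls between frame ticks (duration shorter
  than one frame interval) are invisible at any persistence setting; at
  the default kinetics this is < 1% of events.
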