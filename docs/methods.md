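# Methods

This note records the models, parameter choices and numerical conventions
behind `eeslab`, and what the synthetic-data generator does and does not
capture.

## Paddle geometry and coordinate encoding

The high-density paddle is modelled as a regular 12 × 5 grid of 60 contacts.
The exact row/column arrangement of the physical device is not public; the
default was chosen so the contact count (60), mediolateral treatment width
(14.5 mm) and rostrocaudal span (40 mm) are all honoured simultaneously,
giving centre-to-centre pitches of 3.625 mm (mediolateral) and ≈3.636 mm
(rostrocaudal). The quoted 0.7/0.9 mm spacing figures are inter-contact
gaps, not pitches; both interpretations are expressible through
`PaddleSpec`. The paddle frame places the left-most caudal contact at the
origin with x increasing to the animal's right and y rostrally.

Registration to anatomy uses a least-squares 2D affine fit between observed
landmark positions (e.g. from a radiograph) and the nominal grid; the fit
absorbs skew between the paddle and the imaging plane and reports its RMS
residual. Radiograph image processing itself is out of scope — landmark
coordinates are inputs.

Normalization maps each coordinate axis to the half-open unit interval by
`(v − min) / (span·(1 + 1e−9))`; the inflation factor is the smallest
perturbation that makes the maximum fall strictly below 1, so the
`[0, 1)` encoding contract is exact rather than approximate. Stimulation
amplitude and frequency use the same convention over their tested ranges.
An explicit extent override supports normalizing stacked two-paddle
configurations to a common frame.

## Switch matrix and demultiplexing

The 24:64 matrix gives every output a block of ≥4 candidate inputs. The
proprietary block assignment is unpublished; the default assigns output *o*
the inputs {o, o+1, o+2, o+3} mod 24. This round-robin pattern satisfies
the two published properties — four-way redundancy and tolerance of any
three broken conductors while rastering all 60 electrodes — and is
configurable. Validation rejects a request iff a switch is outside its
block or an output is driven by two inputs; one input fanning out to
several outputs is allowed (anodic ties). Time is 0-based with half-open
`[start, end)` segments; outputs 60–63 exist in the matrix but carry no
electrode and are ignored during demultiplexing. Unrouted samples are
masked, never zero-filled, so downstream statistics cannot silently ingest
fabricated zeros.

## Synthetic recruitment model

Muscle activation is a distance-gated sigmoid:

    d_m   = sqrt(w_ml (x − px_m)² + (y − py_m)²)
    thr_m = θ0 + κ · max(0, d_m − r0) + contra_m
    a_m   = σ((A − thr_m)/s) · g(f)

with θ0 = 250 µA (base threshold), κ = 45 µA/mm (distance gain),
s = 80 µA (recruitment slope), r0 = 2 mm (capture plateau), w_ml = 0.8
(anisotropy), a 200 µA contralateral penalty, and a mild saturating
frequency gain g(f) = (f/(f+25)) normalized so g(100 Hz) = 1. The
anisotropic metric and plateau encode two qualitative features of dorsal
recruitment: threshold varies more steeply along the rostrocaudal axis than
across a root-entry region, and is flat in a pool's immediate
neighbourhood. The six default muscles (bilateral biceps femoris,
gastrocnemius, extensor digitorum longus) have lateralized pools in the
caudal half of the paddle, giving the ipsilateral-recruits-cheaper property
and a high-response caudal region. Trial-to-trial variability is a
lognormal multiplicative gain (CV 0.15) plus half-normal baseline noise
(sd 0.01). Default amplitudes are five values spanning 100–1500 µA (the
upper end being the maximum amplitude a comfortable-range protocol would
test) at 10/25/50/100 Hz with four repeats and 1–2 s uniform inter-train
intervals.

`clustered_pools_ground_truth` is the planted-structure configuration used
by the cluster-recovery experiments: n pools on the paddle midline, one per
rostrocaudal band, centred on each band's median row. Its parameters are
chosen by construction so that the planted partition is the *only*
structure: the plateau radius (5.5 mm) exceeds the largest anisotropic
distance from any electrode to its band's pool (5.39 mm with w_ml = 0.3),
making all within-band response profiles identical up to noise, and the
steep distance gain (1200 µA/mm) puts every cross-band threshold beyond the
tested amplitude range. Violating either bound plants spurious
sub-structure (e.g. corner-electrode subclusters) that silhouette selection
will faithfully find.

EMG traces are stimulus-locked bursts (decaying 180 Hz oscillations, one
per pulse in the 300 ms train) scaled by activation, over Gaussian baseline
noise plus a 60 Hz mains component so the notch stage does real work. The
generator does **not** model volume conduction, motor-unit physiology,
kinematics, electrode impedance drift, or movement artifact; passing tests
demonstrate that the analysis code recovers what it is designed to recover
under its stated statistical assumptions, not that those assumptions hold
in vivo.

ECAP sweeps place a triphasic Ricker (Gaussian second-derivative) template
of ~150 µs support at latency d/v per bipole, with 1/d amplitude decay,
Gaussian latency jitter (default sd 10 µs), a fast-decaying stimulus
artifact at t = 0, and additive noise, sampled at 1 MHz. Only the peak-time
structure is load-bearing. SEP trials mix a shared smooth component c(t)
with channel-specific components u_i(t) as ρ·c + (1−ρ)·u_i, so the expected
inter-channel correlation rises monotonically with ρ.

## EMG feature conventions

- Rectified AUC is the plain sum of absolute sample values over a 500 ms
  stimulation-triggered epoch (unnormalized units: signal · samples).
- Envelope: zero-phase 4th-order Butterworth high-pass at 3 Hz, zero-phase
  IIR notch (60 Hz, Q 35), then RMS over 300 ms windows hopping by half a
  window; edge windows are zero-padded and the output grid is one value per
  hop.
- Normalization is per-muscle min–max to [0, 1]; the joint option pools
  additional tables (e.g. monopolar rows) before computing the per-muscle
  extrema so monopolar and bipolar responses share one scale.
- Recruitment-curve dispersion is the population (n) standard deviation; a
  single repeat reports sd = 0.
- The 33 % threshold snaps to the tested amplitude grid (no interpolation)
  and takes the reference maximum either from the curve itself or from a
  caller-supplied global maximum (the mode used when comparing electrodes
  on a common scale); "not reached" is NaN.
- The selectivity index is the ratio form a_m/Σa with 0/0 → 0, so indices
  sum to exactly 0 or 1. The ratio form was chosen over margin-based
  variants for boundedness and testability.

## Clustering

Feature rows are (electrode, repeat) pairs; columns are the rAUC for every
(muscle, amplitude) pair, one block per frequency, horizontally
concatenated. Columns pass through a maximum-likelihood Yeo–Johnson power
transform with standardization (delegated to scikit-learn), which is
monotone per column; constant columns are rejected rather than silently
zeroed. The 2D embedding is pluggable: seeded UMAP by default, a principal
plane (PCA) backend where exact determinism or closed-form checks matter.
Spectral clustering uses a symmetrized 10-nearest-neighbour affinity with a
seeded k-means assignment step; the cluster count is the silhouette argmax
over k ∈ 2..16. k = 1 has no silhouette, so a single-cluster structure is
reported through the null-band diagnostic instead: on unclustered data the
maximum mean silhouette over candidate k stays well below the separated-
blob regime (empirically ≈0.33–0.42 versus >0.9). Electrodes take the
modal label of their four repeats, ties breaking to the lowest label id.

## Evoked potentials

ECAP analysis averages 50-trial epochs, low-passes the mean at 2 kHz with a
forward-backward (zero-phase) filter so latencies are not shifted, and
takes single-trial peak latencies as the maximum absolute deflection after
a configurable post-stimulus blanking window (default 50 µs; the recording
protocol minimizes artifact by pulse-shape choice, so blanking is a guard,
not a reconstruction step). Conduction velocity pools all (bipole, trial)
latency points into one OLS fit of latency on distance and reports the
inverse slope; a non-positive slope is flagged non-physiologic rather than
returned as a velocity. Peak polarity is |amplitude| by default with a
negative-peak option.

Uniqueness is 1 − mean |zero-lag Pearson r| over a channel's pairs and
trials; constant channels make r undefined and those pairs are excluded and
reported. The Kruskal–Wallis wrapper flags the all-identical degenerate
case (zero rank variance) and reports H = 0, p = 1 instead of dividing by
zero.

## Forward surrogate and grid posterior

The forward model is a fully connected network, two hidden layers of 64
rectifier units, trained with Adam (learning rate 3e−3, batch 128) on mean
absolute error — the L1 objective penalizes errors linearly, limiting the
influence of outlier trials. A 15 % validation split drives early stopping
(patience 40 epochs, max 500) and the best-validation weights are restored;
initialization, the split and batch order all derive from one seed, so
training is bit-reproducible. Outputs are clamped non-negative. The
implementation is a compact numpy trainer because the squared-loss fitters
in standard toolkits do not expose an L1 objective.

Density ablation removes 30 then 14 contacts (60 → 30 → 16, nested).
Stratified removal uses checkerboard parity followed by even spatial
subsampling, preserving the paddle's span; a seeded uniform-random mode
exists for sensitivity analysis. Conditions (electrode, amplitude,
frequency) are split 60/40 into training and held-out sets (1200 → 480
held out with the default design); evaluation uses per-condition means over
the four repeats, split by whether the stimulating electrode was in the
model's training set, with a uniform-random baseline drawn per muscle
between 0 and the training-set maximum.

The inverse model is an explicit grid posterior,
p(θ) ∝ exp(−‖f(θ) − target‖₁/τ), normalized to sum to 1 over the grid. The
temperature defaults to the model's held-in L1 (floored at 1e−3): the
scale at which the surrogate cannot distinguish candidates. An amortized
inverse network could sit behind the same interface; the grid is preferred
here because it is deterministic, needs no extra training, and produces the
same posterior-density artifacts. Proposal generation takes the grid
argmax, snaps (x, y) to the nearest contact (Euclidean distance, ties to
the lowest electrode id) and clamps amplitude to the comfortable limits,
recording any clamp.

In the closed-loop ablation experiment the posterior axes default to the
deliverable stimulus set — the tested amplitudes and frequencies and the
contact coordinates — mirroring the protocol constraint that proposals must
be deliverable; a dense spatial grid is available by option. Each proposal
is delivered 10 times in the simulator with fresh trial noise, as are the
original held-out parameters ("ground-truth repeats"); the repeat
distribution is the natural-variability floor against which proposal errors
are compared with a Kruskal–Wallis test. With delivery noise forced to
exactly zero that floor degenerates to a point mass at 0 and the rank test
flags arbitrarily small surrogate error, so the noiseless configuration is
used only for the exact self-consistency check (a target generated by the
model at a grid point is recovered as the posterior argmax at low
temperature), while distributional comparisons run at the generator's
stated trial noise.

Data-cleaning rules for upstream pipelines (outlier, unreliable-repeat and
subthreshold removal) are exposed as configurable simple rules rather than
reverse-engineered thresholds.

## Problem sizes

The test suite and acceptance script run at the design sizes the analyses
are specified for: 5 × 4 × 60 × 4 = 4800-trial sessions, 50-trial ECAP
sweeps at bipole distances (7.3, 17.0, 26.7, 31.6) mm, 20-seed recovery
sweeps for conduction velocity, 5–20 seed sweeps for cluster recovery,
100 random demultiplexing round trips and all 2024 three-fault conductor
sets. The full suite completes in well under five minutes on one CPU.

## Known limitations

- The recruitment model is phenomenological; it contains no volume
  conductor, fiber-diameter distribution or reflex circuitry, so absolute
  thresholds and selectivity magnitudes are not predictions.
- The switch-matrix block assignment is a stand-in satisfying the published
  redundancy properties, not the proprietary netlist.
- Bipolar-stimulation parameter inference and kinematic objectives are out
  of scope; the forward surrogate covers monopolar conditions only.
- Conduction-velocity estimates assume a single propagating component; the
  peak picker will follow whichever component dominates the blanked window.
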