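# Methods

## The decoding problem

A two-class motor-imagery BCI session records EEG (fast, electrophysiological)
and fNIRS (slow, haemodynamic) simultaneously while the subject imagines
left- or right-hand movement. fNIRS-only decoding is hampered by the low
sampling rate (12.5 Hz), the sluggish haemodynamic response and, above all,
by how few effective samples each 10 s trial contributes to the spatial
covariance estimates that CSP-style methods need. The package implements a
cross-modal remedy: the spatial covariance structure of the simultaneously
recorded EEG — plentiful, fast, well estimated — is mixed into the fNIRS
covariance estimates before the spatial filters are computed.

## Spatial filtering

Classical CSP takes the two class-average, trace-normalised spatial
covariances `R1, R2`, whitens the composite `R = R1 + R2` with
`P = Λ^(-1/2) Uᵀ` (eigendecomposition `R = U Λ Uᵀ`), diagonalises the
whitened class-1 covariance `S1 = P R1 Pᵀ = B λ1 Bᵀ` and keeps the `m`
eigenvectors at each end of the spectrum: `W = B̃ᵀ P`, 2m spatial filters.
Because `S1 + S2 = I` under this whitening, the eigenvalues of the two
classes are complementary (`λ1 + λ2 = 1`); a filter that maximises one
class's variance automatically minimises the other's. Features are the
normalised log-variances `f_j = log(var(w_j X) / Σ_j var(w_j X))`, so
`Σ_j exp(f_j) = 1` per trial.

The regularized variant replaces each class covariance with

    Σ_c(β, γ) = (1 − γ) Ω_c(β) + (γ/N) tr[Ω_c(β)] I
    Ω_c(β)    = [(1 − β) R_c + β R̂_c] / [(1 − β) M_c + β M̂_c]

where `R_c` sums the (trace-normalised) covariances of the `M_c` fNIRS
training trials and `R̂_c` those of the `M̂_c` EEG trials. β mixes in the
generic modality; γ shrinks toward a scaled identity and preserves the trace
exactly. Trace normalisation of every per-trial covariance is what makes
microvolt-scale EEG and micromolar-scale fNIRS commensurable inside the
β-mixture.

With 8 channels the textbook `m = 5` would ask for 10 filters from an
8-dimensional space; `m` is therefore clamped to `floor(N/2)` by default.
An `allow_overlap` flag reproduces the 2m = 10 feature dimension by letting
the middle eigenvectors appear in both halves.

## Channel matching

The β-mixture adds covariance matrices entry by entry, so row *i* of the
fNIRS covariance must refer to cortical territory comparable to row *i* of
the EEG covariance. The matching procedure runs FastICA per modality,
selects the two task-carrying components, ranks each modality's channels by
their absolute mixing weight on those components (each column normalised to
unit maximum, combined by the per-channel maximum, stable sort), and pairs
the two rankings position by position. The pair count defaults to the
smaller channel set (8), so transfer operates on the 8 best-matched channels
of each modality.

Component selection differs per modality:

* **EEG** — score = mean absolute difference of the class-conditional Welch
  power spectra (in dB) over the 8–30 Hz band; the sensorimotor-rhythm
  band-power contrast (ERD) lives there.
* **fNIRS** — left/right spectra are uninformative at haemodynamic
  timescales, so the score is the grand-average evoked change
  `|mean over trials (task-window mean − rest-window mean)|` of each source
  (task 5–10 s, rest 0–2.5 s; both configurable). Taking the absolute value
  *after* averaging across trials is deliberate: an evoked response has a
  consistent sign across trials and accumulates, slow physiological noise
  averages out, and the score stays invariant to the ICA sign ambiguity.
  A pre-cue rest window would be preferable but the fNIRS epochs span only
  0–10 s, so the earliest in-trial samples (HRF still near zero) serve as
  rest.

Three implementation choices matter for robustness and were adopted after
the straightforward alternatives failed on synthetic ground truth:

1. **Reduced fNIRS model order.** The optical signals are slow and heavily
   autocorrelated; 60 trials × 10 s contain only a few hundred effective
   samples, nowhere near enough to estimate a 24-component unmixing. The
   fNIRS ICA therefore runs on the leading 6-dimensional PCA subspace
   (configurable). EEG, with ~10⁵ effective samples for 8 channels, uses the
   full channel count.
2. **Diverse greedy selection.** FastICA often splits one physiological
   source across several components that share a topography. Selection is
   greedy by score, and a candidate whose mixing column correlates with the
   first pick above |r| = 0.8 is skipped, so the two picks describe distinct
   sources.
3. **Best of three runs.** FastICA is a non-convex optimisation and can
   merge the two haemodynamic sources. Three independently seeded runs are
   scored by the *weaker* of their two selected evoked-change scores — a run
   that found two distinct task-responsive topographies scores high — and
   the best run wins.

FastICA uses the tanh contrast with symmetric updates. scikit-learn's formal
tolerance criterion rarely triggers on 8-channel data even when the estimate
is accurate, so a completed fit that hits the iteration limit is accepted
with a warning; hard numerical failures still raise after seeded restarts.

## Ensemble and classification

Rather than tuning (β, γ), the ensemble evaluates the fixed grid
β ∈ {0, 0.01, 0.1, 0.2, 0.4, 0.6} × γ ∈ {0, 0.001, 0.01, 0.1, 0.2}
(30 pairs, β-major order). Each pair yields a filter bank, 2m log-variance
features, and a one-dimensional Fisher-LDA projection (pooled covariance
with ridge `1e-6·tr/d`; bias at the midpoint of the class means). The 30
projections are concatenated into the trial representation and classified
by KNN with k = 15 (odd, ≤ 20 enforced; clamped for very small training
sets) under the city-block metric — distances are computed per dimension
and summed — with distance ties broken toward the lower training index.
LDA columns are deliberately not standardised before KNN; a z-scored
variant is one flag away.

Comparators: classical CSP on one modality (raw 2m log-variances + KNN, no
LDA); R-CSP-CV, which picks the single grid pair with the best stratified
inner-5-fold accuracy on the training set (ties to the first pair in grid
order) and refits it; and the channel-wise HbO baseline (per-channel
temporal mean amplitude + KNN). All fitting — ICA matching included — uses
training folds only.

## The synthetic-session generator

The generator emulates one subject's paired session: 60 trials (30 per
class), 8 motor-cortex EEG channels at 200 Hz spanning −3..7 s around the
cue, 24 fNIRS channels at 12.5 Hz spanning the 0..10 s task. Four latent
cortical sources (two discriminative) are mixed into both modalities through
*different* channel weightings that share only the source identities — the
exact assumption of the transfer method. Mixing columns are localized
non-negative Gaussian bumps along the channel axis (unit norm, full rank):
optical channels weight a concentration source non-negatively, and a compact
cortical patch projects a single-signed magnitude topography onto a small
electrode set. Localization keeps the columns well conditioned.

**EEG**: discriminative sources are 8–30 Hz oscillations with log-normal
burst envelopes (depth 0.3, ~0.3 Hz envelope bandwidth) whose task-window
(t ≥ 0) variance is scaled by `1 ∓ erd_depth` / `1 ± erd_depth`
contralaterally (default depth 0.6); background sources are identical but
class-blind. The envelope reflects the waxing/waning of real sensorimotor
rhythms, and it is also what makes the sources super-Gaussian — a stationary
band-limited Gaussian process is invisible to ICA. Channel noise is 1/f
(pink), scaled to the configured EEG SNR.

**fNIRS**: each discriminative source carries
`amplitude × (boxcar ⊛ double-gamma HRF)` (peak 6 s, undershoot 16 s, ratio
1/6, unit peak), multiplied by a per-trial log-normal-ish gain (sd 0.5,
floored at 0.2) and summed with a source-specific slow fluctuation (0.3 ×
amplitude). Lateralization is fully contralateral by default
(`hrf_lateralization = 1`: a source responds only in its preferred class);
partial values interpolate, 0 makes the classes identical (the null
control). The trial-gain jitter and source noise model genuine physiological
variability, and they are also what renders the two haemodynamic sources
mutually independent — without them both sources are scalar multiples of one
HRF curve and no source-separation method could tell them apart. Channel
noise is dominated by channel-independent slow fluctuations (σ ≈ 1.5 s
Gaussian-smoothed white noise) plus a Mayer wave whose frequency jitters
around 0.1 Hz per channel, a small uncentred linear drift, and a small
white component (weights 1.0 / 0.6 / 0.6 / 0.3 before scaling to the
configured fNIRS SNR). The default `snr_fnirs = 0.7` puts single-modality
fNIRS decoding in the low-to-mid-60 % range that motivates transfer in the
first place; `snr_eeg = 5` leaves EEG decodable at ceiling. HbR is −0.3 ×
the HbO signal component plus independent noise.

What the generator does **not** model: inter-subject variability (one
subject per session), optode geometry and photon migration, motion
artifacts, ocular or cardiac EEG artifacts, and any coupling between the
EEG and fNIRS *noise* processes. Passing tests therefore show that the
pipeline recovers planted cross-modal structure under realistic noise
statistics — not that it reproduces any subject's absolute accuracy on real
recordings.

## Numerical choices

* Zero-phase (forward–backward) Butterworth filters: order 4 for the EEG
  bands, order 3 for the fragile 0.01–0.1 Hz fNIRS band.
* Z-scoring uses the population SD (divide by n), per trial per channel;
  channels whose SD falls below `1e-12·max(|mean|, 1)` raise a degenerate-
  input error naming the channel.
* Beer–Lambert conversion solves the 2×2 extinction system per sample by
  `numpy.linalg.solve`; defaults 760/850 nm, DPF 6.0, 3 cm separation,
  extinction coefficients from the standard compiled tables.
* Eigen-sorts are stable; equal eigenvalues keep their original order.
* The composite covariance gets a `1e-12·tr/N` ridge only when its condition
  number exceeds 1e12; a singular composite raises an error suggesting
  γ > 0.
* Half-open time windows `[start, end)`; sample *i* covers `t0 + i/fs`.

## Problem sizes

The evaluation suite and the acceptance script run sessions of 60 trials —
the size of one subject's recording in the protocol the package targets —
with 5-fold stratified cross-validation; recovery and ordering statistics
aggregate 20 seeded sessions, and the acceptance script averages 3 sessions
per method. Published-table statistics are exact recomputations from the
bundled 29-subject per-subject accuracy tables.

## Known limitations

* Channel matching is only as good as the fNIRS ICA; at very low fNIRS SNR
  the ranked pairing degrades toward arbitrary and transfer becomes neutral
  rather than harmful (the ensemble contains β = 0 members).
* The two selected components are not matched across modalities by source
  identity; when the rankings interleave the two sources differently per
  modality, the transferred covariance structure is partially misaligned.
* The pooled t-test treats per-subject accuracies of different methods as
  independent samples, exactly as the published analysis does, although the
  samples are paired by subject.
* Reverse transfer (fNIRS → EEG) is out of scope.
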