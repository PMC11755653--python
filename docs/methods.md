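# Methods

## Scope and data model

The package analyzes whole-night (or any-length) multichannel EEG in
EDF/EDF+ format, restricted to the 19 channels of the International
10–20 montage (`Fp1 … Pz`, ear reference) in one fixed canonical order;
every downstream matrix indexes channels in that order, which removes
any possibility of silent transposition.  Extra polysomnography channels
in a file are ignored.  The sampling rate is taken from the EDF header;
a disagreement between channels is an error, never a silent resample.
Missing samples are represented by an explicit per-sample mask — any
wavelet window or smoothing window overlapping masked data produces a
masked estimate, which is excluded from all averages.

A cohort is a delimited manifest `subject_id, path, ahi[, group]`.  The
group rule is: control iff `0 ≤ AHI ≤ 15` events/hour, otherwise the
main (OSA) group; the boundary value 15 is assigned to control, and an
explicit group column that disagrees with the rule is kept but logged.

## Windowed Morlet transform

Coefficients are parameterized directly by frequency:

    W(f, t0) = √f ∫_{t0−4/f}^{t0+4/f} x(t) ψ*(f, t−t0) dt,
    ψ(f, τ) = (f/π)^¼ e^{iω₀fτ} e^{−f²τ²/2},  ω₀ = 2π.

* **Window.**  The Gaussian envelope has SD `1/f` s; the ±4/f window
  truncates it at four SDs (amplitude `e⁻⁸` of the peak).  Windows that
  exit the recording are *masked, not zero-padded*: padding would bias
  low-frequency synchronization near the edges of a night.
* **Leading factor.**  The prefactor is `√f`, the L²-style normalization
  consistent with the `(f/π)^¼` envelope; a plain-`f` alternative is
  available (`cwt_prefactor="linear"`).  Because the cross spectrum is
  normalized per (f, t) point, this choice cannot affect any
  synchronization value — asserted by a test.
* **Quadrature.**  Trapezoidal rule on the native sample grid
  (`dt = 1/fs`).  The integrand is band-limited and smooth; at 100 Hz
  this is accurate through 30 Hz, and the discrete sum is verified to
  `1e−6` relative error against an independent direct-summation oracle.
  The FFT-based implementation evaluates exactly that sum.
* **Grids.**  Six analysis bands (0.25–1, 1–4, 4–8, 8–12, 12–20,
  20–30 Hz), each with 32 linearly spaced frequencies including both
  endpoints, so the band quadrature below is exact under the trapezoid
  rule.  The synchronization time grid `t0` steps by 0.1 s (the
  synchronization time course is smooth on the analyzed scales; band
  and time averages are insensitive to refinement).  Both counts are
  configuration fields.

One analyzed band starts at 0.25 Hz although typical acquisition
bandpasses begin at 0.5 Hz; the package analyzes whatever spectral
content the file contains and leaves any re-filtering to the user.

## Synchronization estimator

With `W_i = a_i + i b_i`, the normalized mutual wavelet spectrum

    Re = (a_i a_j + b_i b_j)/(|W_i||W_j|),  Im = (b_i a_j − a_i b_j)/(|W_i||W_j|)

is the unit phasor `e^{i(φ_i−φ_j)}` of the instantaneous phase
difference.  Pointwise its modulus is identically 1 — `Re² + Im² ≡ 1`
algebraically for any two nonzero coefficients — so a pointwise modulus
carries no information.  The estimator therefore time-averages the
phasor first:

    WB(f, t) = | moving average of (Re + i·Im) over max(2 s, 8/f) |.

This is a sliding-window phase-locking value.  The window floor of
8 cycles keeps the estimate stable down to the lowest band (at 0.25 Hz
the window is 32 s); the 2 s default floor governs frequencies above
4 Hz.  Both are configuration fields and are echoed into every run
report.  The degenerate single-sample window (WB ≡ 1 everywhere) is
kept reachable in the API and asserted by a regression test as
documentation of why smoothing is mandatory.

Numerical safeguards: coefficients whose modulus falls below `1e−12`
times their per-frequency RMS are masked before normalization (the
phase ratio is undefined at exact zeros), and the final modulus is
clipped to [0, 1] — mathematically a bound, so any excursion is pure
round-off, as with correlation coefficients.  A WB point is valid only
when the full smoothing window is valid for both channels; a
band-integral time point is valid only when every in-band frequency is
valid there; the whole-record mean runs over valid points only.  A
frequency whose window exceeds the valid span is masked entirely, with
a warning.

Properties enforced by tests: boundedness in [0, 1]; exact symmetry
under channel exchange; invariance under positive rescaling of either
channel; WB = 1 for a recording paired with itself and for constant
phase lags; monotone increase with programmed coupling strength.

## Spatial maps and statistics

Per band, the 171 pair means fill a symmetric 19×19 matrix with unit
diagonal ("maximum single connection").  Group matrices are computed by
averaging *per-subject whole-record means* — each subject contributes
equally, regardless of the groups' sizes — with per-cell counts kept
when subjects have masked cells.  The difference scheme is
`control − main` with zero diagonal; positive cells mark
control-dominant connections.

The severity analysis correlates each (pair, band) mean with AHI across
the pooled cohort (both groups; the correlation targets severity as a
continuous variable, not group membership).  The default coefficient is
Pearson with the two-sided t-test `t = r√((n−2)/(1−r²))`, df `n−2`;
Spearman (Pearson on midranks) is available because AHI is heavily
skewed.  Group comparisons per cell use the two-sided Mann–Whitney U
test — exact null distribution when `n1·n2 ≤ 400` and the pooled sample
is tie-free, otherwise the tie-corrected normal approximation — with
significance at `p ≤ 0.001`.  No multiple-comparison correction is
applied by default across the 171×6 cells; an optional
Benjamini–Hochberg column can be requested explicitly.

## Synthetic cohorts

The generator targets exactly the quantity the estimator measures:
band-limited phase locking.

* **Oscillators.**  Each band component is `cos(Φ(t) + θ(t))` with a
  narrow-band FM carrier: instantaneous frequency wanders smoothly
  (Gaussian noise with ~0.5 s correlation time, SD = bandwidth/4,
  clipped to the half-bandwidth) around the band center, with the FM
  bandwidth set to half the band width so ≥ 80% of the power stays
  in-band (tested by periodogram).
* **Coupling.**  A coupled pair shares one latent carrier per band; each
  member receives independent Wiener phase jitter with variance rate
  `(1 − ε) · D`, `D = 2.5 rad²/s` by default.  `ε = 1` gives identical
  phases (WB → 1); `ε = 0` gives an unboundedly diffusing phase
  difference (the chance floor of the windowed estimator, ≈ 0.5 for the
  2 s windows).  Because drivers are latent per pair, a channel can
  belong to at most one coupled pair per band; the default scheme
  couples the eight homologous left–right pairs (Fp1–Fp2 … T5–T6),
  which are disjoint, in all six bands.  Uncoupled channels carry
  private, jitter-free oscillators, plus white measurement noise
  (SD 0.3) on every channel.
* **Cohorts.**  AHI is drawn per group from lognormal distributions
  matching the clinical group medians (control: median 2, σ = 0.8,
  clipped to [0, 15]; main: median 44, σ = 0.5, clipped to (15, 120]);
  group sizes default to 33 control / 39 main.  Each programmed coupling
  declines linearly with severity, `ε(AHI) = clip(ε₀ + s·AHI, 0, 1)`
  with `ε₀ = 0.95`, `s = −0.012`, plus a per-(subject, band, pair)
  Gaussian heterogeneity term (SD 0.12) representing biological
  between-subject variability.  The slope and heterogeneity were fixed
  once, by a single large-cohort calibration run, so that the
  *population* correlation between the delta-band C3–C4 synchronization
  mean and AHI is ≈ −0.8 (measured −0.79 at n = 300); replicated
  72-subject cohorts then recover that value within Fisher-z sampling
  error, and a zero-slope cohort yields a calibrated ~5% false-positive
  rate at p < 0.05.
* **Determinism.**  All randomness derives from integer key tuples fed
  to `numpy.random.default_rng`, keyed by (seed, band, canonical channel
  or pair index, subject index).  Cohorts are bit-reproducible, subjects
  are independent of generation order, and restricting the montage to a
  channel subset reproduces exactly the signals those channels would
  carry in the full montage.

What the generator does *not* emulate: sleep architecture (stages,
spindles, K-complexes), apnea event morphology, 1/f background spectra,
volume conduction, or artifacts.  Passing tests therefore demonstrate
that the estimator recovers programmed phase coupling and programmed
severity effects under controlled conditions — not that any specific
clinical effect size would be reproduced on real recordings, which are
not publicly available.

## Problem sizes used in validation

Surrogate studies ship at desk scale, chosen because whole-record means
are duration-invariant in expectation: 600 s pairs for the coupling
sweep (5 ε values × 20 seeds) and for the 20 replicated 72-subject
correlation-recovery cohorts (analyzing the programmed C3–C4 pair);
120 s recordings for the 100-test null-calibration study and the demo
cohort under `analysis/`; 60 s pairs for the 1,000-pair boundedness
sweep.  Full-night durations are a configuration choice, not a
structural one.

## EDF handling

Reading goes through MNE after a light-weight header scan that
validates channel presence (case-insensitive, alias-aware: T7/T8/P7/P8
map to T3/T4/T5/T6) and per-channel rates before any data are loaded;
non-microvolt physical dimensions produce a warning only, since the
estimator is amplitude-invariant.  Writing (needed only for synthetic
cohorts) uses a minimal built-in 16-bit EDF writer with per-channel
auto-scaled physical ranges (~6×10⁻⁵ relative quantization); round
trips are verified to within one quantization step.

## Known limitations

* The sliding-window length is the one genuinely free parameter of the
  estimator; absolute WB values (including the chance floor) depend on
  it, so comparisons are only meaningful at a fixed window
  configuration, which every output therefore records.
* The exact-zero coefficient floor is relative to the per-frequency RMS;
  recordings that are identically zero over long stretches produce
  masked (not zero) synchronization there.
* The Mann–Whitney exact mode is limited to `n1·n2 ≤ 400`; larger
  tie-free cohorts use the normal approximation.
* The generator's disjoint-pair constraint means arbitrary dense
  coupling graphs cannot be synthesized; schemes are validated and
  rejected rather than approximated.
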