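# Methods

This note records the scoring model, the conventions chosen where the
verbal rules leave room, the synthetic-data model the tests rely on, and
known limitations.

## Scoring model

The scorer implements the SINBAR visual rules for REM sleep without
atonia as a deterministic pipeline per EMG channel:

1. resample to 256 Hz (cubic spline through the original samples);
2. extract maximal runs of consecutive REM epochs from the hypnogram
   (runs ≥ 150 s are *REM periods*, shorter runs *REM bouts*);
3. build an artefact mask (arousal + respiratory everywhere, snore on the
   chin only, electrode detachment where the 30 s rolling RMS < 0.05 mV);
4. per period, estimate the baseline amplitude (minimum artefact-free
   rolling-window RMS, 30 s then 15 s fallback) and propagate to
   unmeasurable periods (previous first, then next) and bouts (nearest
   period);
5. compute the 30 ms / 15 ms RMS track on each artefact-free run, flag
   samples strictly above 2× baseline, and merge flagged runs into
   increased-activity events (seed runs > 0.1 s; gaps < 0.25 s absorbed);
6. score 30 s epochs as tonic when event time inside the epoch is ≥ 15 s,
   elevate the epoch baseline to the RMS over the activity spans and
   re-detect phasic events inside the epoch;
7. flag 3 s mini-epochs as phasic/any by event overlap and tonic-epoch
   membership, and aggregate counts, percentages and bout statistics.

## Parameters

All constants live in `DetectionParams` (units in field comments):
working rate 256 Hz; RMS window 30 ms stepped 15 ms; activity threshold
2× baseline (strict); minimum event seed 0.1 s (strict); terminating gap
0.25 s (closed); phasic ≤ 5 s; intermediate ≤ 15 s; tonic fraction 0.5 of
a 30 s epoch (closed); mini-epoch 3 s; REM-period minimum 150 s;
detachment threshold 0.05 mV RMS; baseline windows 30 s / 15 s; optional
band filters 10–100 Hz with 50 Hz notch. They are the published rule set
and are exposed, not meant to be tuned.

## Grid and boundary conventions

- **Time grid.** Window start indices are `round(i · 0.015 · fs)` samples;
  at 256 Hz a 30 ms window is 8 samples and steps alternate between 3 and
  4 samples. Every full window is kept; the final partial window is
  dropped.
- **Slab semantics.** The i-th track value stands for the 15 ms slab
  `[i·15 ms, (i+1)·15 ms)`. A run of k flagged slabs has duration k·15 ms;
  event boundaries therefore lie on the 15 ms grid.
- **Strict vs closed.** "Exceeding twice the baseline" is strict `>`;
  "interruptions of ≥ 0.25 s" is closed (a gap of exactly 0.25 s ends an
  event); "≥ 50 %" tonic coverage is closed (15.0 s of activity is tonic).
  An event lasting exactly 5 s is phasic; durations in (5 s, 15 s] are
  intermediate (the duration axis is continuous, so the verbal 5.0/5.1
  gap is closed by assigning it to intermediate).
- **Event formation.** Clusters of flagged runs connected by gaps
  < 0.25 s form one event iff the cluster contains at least one run
  > 0.1 s; the event spans from the first to the last flagged slab of the
  cluster. A cluster of only sub-0.1 s runs is no event regardless of its
  total span.
- **Masks as intervals.** Artefact masks are kept as exact interval sets
  (merged, clipped to REM) rather than a sampled boolean series; this is
  equivalent at the grid resolution but exact at mini-epoch boundaries.
- **Epoch validity.** A 3 s mini-epoch is excluded from scoring and from
  denominators if any part of it is masked; a 30 s epoch is excluded from
  tonic scoring on the same any-overlap basis. This is the conservative
  reading of counting "artefact-free (mini-)epochs".
- **Detachment.** The 0.05 mV criterion is evaluated with the 30 s
  baseline window stepped at 15 ms (detachment means sustained silence);
  each sub-threshold window flags its whole span.
- **Baseline search.** Candidate windows step at 15 ms (per-sample search
  would be indistinguishable at EMG timescales and 100× the compute);
  "continuously artefact-free" means the window contains no masked time.
  Nearest-period distance for bouts uses interval midpoints, ties to the
  earlier period; inheritance chains resolve transitively, previous
  direction first.
- **Tonic rescoring.** The elevated baseline is the RMS of the raw signal
  over the union of increased-activity spans inside the epoch (those
  spans are what made the epoch tonic). Rescoring is confined to the
  epoch's own span, replaces its phasic/intermediate events, and does not
  revisit the tonic decision itself (no fixed-point iteration): the tonic
  flag is decided once against the period baseline.
- **Events longer than 15 s** in an epoch that fails the 50 % rule count
  toward neither phasic nor any activity (the literal reading of the
  "any" rule, which caps event duration at 15 s).
- **Reported events.** Inside a tonic epoch the event CSV carries one
  `tonic` row spanning the epoch's activity (clipped to the epoch) plus
  the post-rescoring phasic/intermediate events; original sub-events are
  superseded there. Outside tonic epochs events are reported as detected,
  categorised by duration.
- **Combined channels** use union positivity ("bilateral FDS" = left OR
  right) over the intersection of the constituent channels' valid
  mini-epochs — the only denominator under which every counted mini-epoch
  is assessable on every channel. (A union-denominator variant would
  inflate the denominator with mini-epochs some channels cannot assess.)

## Artefact policies

Two first-class modes mirror common practice: `full` (arousal +
respiratory + snore-on-chin + detachment) and `arousal-only` (scored
arousals only, no signal-derived exclusions). They are selected with
`--policy`; everything downstream is identical.

## Text dialects

Vendor exports differ and no grammar is standardised. Hypnogram and event
files are parsed through a declarative `TextDialect` (timestamp format,
separator, case-insensitive stage vocabulary); the shipped default —
`HH:MM:SS,fff; STAGE`, one 30 s epoch per line, events as
`start; end-or-duration` — is a best-effort reconstruction of a common
vendor export and should be adapted via configuration, not code, for
other systems. Clock times are anchored to the EDF header start time,
with midnight rollover.

## Synthetic-data model

`synthetic_fixtures` generates recordings with the statistical structure
the rules assume: a stationary band-limited (10–100 Hz, the recording
band, so opt-in filtering is a near-no-op) background at a requested
baseline RMS, plus injected bursts of controlled ratio, duration and
placement with 10 ms cosine ramps. Artefacts are injected as labelled
intervals in the event files, not as waveforms.

The background is **soft-limited** at 1.6× its RMS (tanh compression,
then re-normalised). Unclipped Gaussian noise exceeds twice the estimated
baseline in ≈ 8·10⁻⁴ of 30 ms windows; such excursions within 0.25 s of a
burst would be merged into the event by the absorption rule and shift its
boundary by up to 0.25 s on ≈ 1 % of burst edges. The soft limit provably
keeps every background window below the detection threshold (peak
amplitude 1.7× RMS < 2× the smallest achievable baseline estimate), so
threshold crossings come from injected bursts only and the geometric
boundary guarantee — ramp plus one RMS window, 45 ms — holds. The
compression barely changes the noise character (RMS re-normalised,
band unchanged).

Default study conditions: per-channel baseline 0.1 mV (comfortably above
the 0.05 mV detachment threshold), burst ratios drawn from 3–6× baseline,
phasic durations 0.2–4 s, intermediate 6–14 s, tonic 16–25 s; one burst
per REM epoch, every generated REM segment ≥ 150 s with two quiet leading
epochs so a clean 30 s baseline window always exists; burst edges keep
> 0.12 s clear of the 3 s grid so intended mini-epoch overlap sets are
robust to the 45 ms boundary tolerance. `verify_against_truth` matches
detected events to truth by interval overlap and reports per-category
precision/recall and boundary errors.

What fixtures do **not** model: physiological EMG spectra, ECG crosstalk,
respiration or movement waveform artefacts, non-stationary background
tone. Passing the recovery tests therefore demonstrates the rule
implementation, not robustness to real-world artefact content. At burst
ratios near the 3× lower end, the windowed RMS of a *noise* burst can dip
below threshold at an edge and truncate the detected event by more than
45 ms on roughly 1 % of edges — an intrinsic property of threshold
detection on stochastic signals, visible as occasional larger
`max_boundary_error_ms` values in the acceptance report. The
tonic-rescoring check instead uses an analytic two-level fixture (a 32 Hz
carrier whose 30 ms window RMS is exactly constant) so the 3×/1.5×
geometry is deterministic.

## Problem sizes

The test suite and acceptance script use fixtures of roughly 8–100 sleep
epochs (4–50 min of signal at 256 Hz, single channel), 1000 randomised
2–60 s signals for the brute-force equivalence check, and burst censuses
up to 20 per category — sizes at which every check runs in seconds while
exercising all code paths at full temporal resolution.

## EDF handling

Reading goes through `mne` (EDF/EDF+C; discontinuous EDF+D files are
rejected after a header check, and amplitudes are converted to mV from
the EDF physical dimension). Writing is needed only for fixtures; a
minimal 16-bit EDF writer with 1 s records and a per-channel symmetric
physical range produces files whose round-trip error is below one
quantisation step (≈ 2·10⁻⁵ mV at fixture amplitudes).

## Limitations

- The scorer classifies no artefacts beyond the stated detachment rule;
  artefact intervals are inputs.
- Tonic scoring inherits the known high inter-scorer variability of chin
  tonic activity; the rules are applied literally.
- The vendor text dialect is a reconstruction; files from other systems
  may need a custom `TextDialect`.
- Percent summaries are reported as computed; no diagnostic cut-offs are
  applied.
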