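# atonia

Automated scoring of **REM sleep without atonia (RSWA)** from surface-EMG
polysomnography, following the SINBAR visual scoring rules for tonic,
phasic and "any" muscle activity.

During healthy REM sleep, skeletal muscle tone is actively suppressed.
Its failure — RSWA — is the polysomnographic hallmark of REM sleep
behaviour disorder (RBD), an early marker of α-synucleinopathies such as
Parkinson's disease. Quantifying RSWA by eye is slow and scorer-dependent;
`atonia` scores it algorithmically from an EDF recording, a 30-s-epoch
hypnogram, and plain-text event lists (arousals, optionally respiratory and
snore events), for the muscles the SINBAR montage uses: mentalis (chin),
flexor digitorum superficialis (FDS, forearms) and tibialis anterior
(TA, lower legs).

## Scoring rules

All amplitudes are RMS values in mV. For each EMG channel, resampled to
256 Hz:

- **RMS track.** The RMS of a 30 ms sliding window, stepped every 15 ms,
  gives an amplitude track at 15 ms resolution.
- **Baseline.** Each *REM period* (≥ 150 s of continuous REM) gets a
  baseline amplitude *b* = the lowest RMS of a 30 s rolling window lying
  entirely in artefact-free REM; if no clean 30 s window exists, 15 s
  windows are tried; failing that the baseline is inherited from the
  previous (else next) period. REM bouts shorter than 150 s take the
  baseline of the nearest period. Spans with rolling RMS < 0.05 mV are
  treated as electrode detachment and excluded.
- **Activity events.** Track samples exceeding 2·*b* (strict) are activity
  bouts. Runs of bouts longer than 0.1 s seed events; neighbouring bouts
  are absorbed across sub-threshold gaps shorter than 0.25 s, iterated to a
  fixed point, so a gap ≥ 0.25 s ends an event ("increased activity").
- **Tonic.** A 30 s REM epoch is tonic when increased activity covers
  ≥ 50 % of it (≥ 15 s). The epoch's baseline is then elevated to the RMS
  of the activity spans and phasic detection is repeated inside the epoch,
  so only bouts at twice the background tonic level survive.
- **Phasic / any.** Events of 0.1–5 s are phasic, 5–15 s intermediate.
  Each 30 s epoch splits into ten 3 s mini-epochs: a mini-epoch is *phasic*
  if it overlaps a phasic event, and *any* if it overlaps a phasic or
  intermediate event or lies in a tonic epoch.
- **Artefacts.** Arousal and respiratory events are excluded on every
  channel; snore events on the chin only. Mini-epochs (and, for tonic,
  epochs) touched by an artefact are removed from numerator and
  denominator. Percentages are per artefact-free REM (mini-)epochs.

Outputs: a CSV of exact event timestamps, a per-channel summary (counts,
percentages, mean bout maximum amplitude and duration), and combined-channel
percentages (e.g. mentalis *any* + bilateral FDS *any*, union positivity
over jointly valid mini-epochs).

## Worked example

The package ships a synthetic-fixture generator that produces an EDF plus
hypnogram and event files with known injected bursts:

```bash
atonia fixtures generate --seed 7 --phasic 4 --intermediate 2 --tonic 1 \
    --out-dir fixture
atonia score fixture/recording.edf \
    --hypnogram fixture/sleep_profile.txt \
    --channel-map "EMG Ment=mentalis" \
    --arousal fixture/arousal.txt --out-dir out
```

`out/channel_summary.csv` then contains (abridged):

| role | n_epochs_valid | n_mini_valid | n_tonic | n_phasic | n_any | pct_tonic | pct_phasic | pct_any |
|------|---------------|--------------|---------|----------|-------|-----------|------------|---------|
| mentalis | 9 | 90 | 1 | 7 | 27 | 11.1 | 7.8 | 30.0 |

The single 20 s burst makes one of the nine valid epochs tonic (11.1 %);
the four phasic bursts cover seven 3 s mini-epochs (7.8 % — bursts may
straddle a mini-epoch boundary); "any" adds the mini-epochs of the two
intermediate bursts and all ten mini-epochs of the tonic epoch (30.0 %).
`out/events.csv` lists every event with millisecond timestamps, e.g.

```
channel,category,start_s,end_s,duration_s,max_amplitude_mv
mentalis,phasic,241.425,243.975,2.55,0.727874783755133
mentalis,tonic,392.325,412.41,20.085,0.7269284030184199
```

`atonia fixtures verify --dir fixture` re-scores a generated fixture and
reports per-category precision/recall and boundary errors against the
ground truth.

The same pipeline is available as a library:

```python
from atonia import Role, read_recording, parse_sleep_profile, score_recording

rec = read_recording("night.edf", {"EMG Ment": Role.MENTALIS})
hyp = parse_sleep_profile("sleep_profile.txt",
                          recording_start=rec.recording_start)
result = score_recording(rec, hyp, policy="full")
```

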