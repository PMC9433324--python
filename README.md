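# crossmap

Analysis pipeline for hippocampal recordings from pairs of bats flying in a
long tunnel, where neurons switch between coding the bat's own position and a
conjunctive, often non-separable, code for position by interbat distance.
Since the original recordings are not public, a first-class synthetic-data
module generates full sessions (paired trajectories, model-neuron spike
trains, echolocation click trains and audio) so every analysis stage is
testable end to end.

## What is implemented

| module | contents |
| --- | --- |
| `crossmap.synth` | generative model neurons (multi-field place maps with heterogeneous distance-modulation profiles and hotspots, non-separability knob `x_sep`), trial spike counts by path integration, full paired-flight sessions, click trains and wideband audio rendering |
| `crossmap.behavior` | trajectory cleaning/resampling to 100 Hz, flight extraction (speed, ball margins, U-turn trimming), segmentation into solo / cross-over / tracking with the signed interbat-distance convention (negative = approaching) |
| `crossmap.echolocation` | click detection on MAD-normalised audio (duration, rise-time, ICI, band-ratio and time-of-arrival criteria), click-rate profiles, attention split by median click rate, random-bisection modulation test, peri-click controls |
| `crossmap.tuning` | occupancy-normalised tuning curves (position 0.5 m / distance 2 m / per-field 30-bin variants), spatial information, the five-step place-field detector, movement-variable controls |
| `crossmap.shuffles` | the two surrogate generators (rigid circular shift; solo spikes projected onto cross-over behaviour), corrected per-bin significance (0.5% two-sided with adjacency and edge rules), 1D distance-cell classification, switch times |
| `crossmap.maps2d` | 3 x 3 m distance-by-position rate maps and cluster-based patch statistics against the max-cluster-score null |
| `crossmap.svd` | matrix cropping/iterative completion, singular-spectrum indices lambda and alpha, multiplied-map significance, cross-validated dimensionality and projection dimension |
| `crossmap.decoding` | simultaneous Bayesian decoding of distance and position (leave-one-out, 1 s windows, coverage and prior terms), sliding-window tuning-change profiles, ML/PV decoding of simulated populations and the non-separability decoding study |

## CLI

```bash
crossmap simulate --seed 1 --n-cells 20 --out session.h5   # synthetic session
crossmap segment session.h5 --out flights.csv              # behavioural modes
crossmap clicks  session.h5                                # attention split
crossmap tune    session.h5 --n-shuffle 1000               # 1D distance cells
crossmap patches session.h5 --n-shuffle 1000               # 2D patch table
crossmap svd     session.h5                                # separability
crossmap decode  session.h5                                # decode summary
crossmap simstudy --scale desk --seed 0                    # decoding study
```

Sessions are HDF5 (`/bat{0,1}/trajectory`, `/cells/<id>/spike_times`,
`/clicks/bat{0,1}/times`); tables are CSV.

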