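# mitoscreen

A screening pipeline for **microglia mitochondrial membrane potential (ΔΨm)**
in acute brain slices. Microglia loaded with the potentiometric dye TMRE
respond to the immune stimulant LPS with a large, *staged* rise in TMRE
fluorescence — three progressive depolarization states (S1–S3) that begin in
the soma and radiate outward through the branches to the endfeet — while
neighbouring neurons show only a modest rise to a plateau. Because the TSPO
inverse agonist emapunil attenuates this response in a compartment-specific
way, the staged ΔΨm response is usable as a drug-screening readout for
neuroinflammation. `mitoscreen` implements that readout end to end:

* **synthetic data** (`mitoscreen.synthdata`) — seeded trace- and image-level
  simulation of the canonical response kinetics for every condition
  (baseline / LPS / LPS+emapunil / emapunil-only), with ground-truth manifests;
* **segmentation** (`mitoscreen.segment`) — EGFP-channel cell segmentation and
  automatic partition of each microglia into soma / branches / endfeet, plus
  ROI trace extraction from two-channel TIFF stacks;
* **kinetics** (`mitoscreen.kinetics`) — percent change from baseline
  (`100·(F−F0)/F0`), rate of change (%/s), slope angle
  (`atan` of the %/min slope, in degrees), and detection of progressive
  states on the rate trace;
* **statistics** (`mitoscreen.stats`) — t-tests, one-way and repeated-measures
  ANOVA, and a per-(compartment × state × metric) treatment screen report;
* **CLI** (`mitoscreen`) — `simulate`, `segment`, `kinetics`, `report`, `full`.

The model at the core: after treatment at t=0, the noise-free percent-change
response of compartment *c* is

```
pct_c(t) = Σ_s A[s,c] · ramp(t; onset_s, duration_s)
```

a sum of linear ramps, one per state *s*, with amplitudes `A` (% of baseline)
attenuated multiplicatively under emapunil. The canonical parameter set uses
state onsets 6.06 / 14.06 / 23.50 min, durations 2.02 / 2.07 / 3.00 min, and
whole-cell amplitudes summing to 253.12%; neurons ramp to a 50% plateau by
9 min and then decline slowly.

## Worked example

```python
import dataclasses
import mitoscreen as ms

params = ms.make_default_parameters("lps", "microglia")
trace = ms.simulate_trace(dataclasses.replace(params, noise_sd=0.0))
pct = ms.percent_change(trace, baseline_window=(-300, 0))
print(round(pct.value_at(1800.0), 2))      # 253.12  (% gain 30 min post-LPS)

seg = ms.detect_states(pct)
for i, s in enumerate(seg.states, 1):
    print(f"S{i}: onset {s.onset/60:.2f} min, duration {s.duration/60:.2f} min")
# S1: onset 5.93 min, duration 2.28 min
# S2: onset 14.02 min, duration 2.18 min
# S3: onset 23.68 min, duration 2.65 min
```

The detected onsets sit within a few seconds of the generative 6.06 / 14.06 /
23.50 min values (the 30 s smoothing window shifts ramp edges slightly).

A full synthetic screen (4 conditions × 10 cells, analysis, report):

```bash
mitoscreen full --seed 1 --out run/
```

writes `run/metrics/metrics.csv`, `run/metrics/summary.csv` and
`run/report/screen.{json,csv,md}`. With the canonical defaults the report
flags the soma and endfeet percent change as significantly reduced by
emapunil (p < 1e-6 at n=10) and the branches as not significant — the
compartment-specific attenuation pattern the screen is designed to detect.

The `analysis/` scripts run the same steps as a narrative sequence
(`01_simulate_cohort.py` → `04_imaging_validation.py`), writing tables under
`results/`.

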