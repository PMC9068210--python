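# zahnreihen

Tooth replacement wave analysis for polyphyodont dentitions.

Reptiles replace their teeth throughout life in an ordered pattern: waves
of replacement sweep along the jaw, so that teeth belonging to one wave —
erupted functional teeth and their unerupted successors — form a
*Zahnreihe*, a series in which each more rostral tooth is more mature than
the next caudal one. The horizontal distance between successive
Zahnreihen, in tooth-position units, is the *Z-spacing*: values above 2
indicate waves sweeping rostral→caudal, exactly 2 simple alternation
between odd- and even-numbered positions, and values below 2 reversed
waves. This package implements that analysis as a reusable pipeline for
comparative odontology, with the dentitions of the early-diverging
ceratopsians *Yinlong downsi*, *Chaoyangsaurus youngi* and
*Hualianceratops wucaiwanensis* packaged as worked datasets.

## What it does

* **Ordinal staging** — functional teeth are staged F1–F4 from denticle
  wear, lingual wear-facet concavity, pulp-cavity development and evidence
  of an incoming successor; replacement teeth are staged R1–R3 from crown
  development. Both ladders unify onto a single 7-step maturity score
  (R1=1 … F4=7) used as the y-axis of the Zahnreihen graph.
* **Zahnreihe reconstruction** — greedy rostral→caudal segmentation of the
  (position, maturity) graph into maximal strictly-descending runs, with a
  configurable tolerance for empty positions.
* **Z-spacing estimation** — positional offsets between adjacent runs at
  matched maturity levels (linear interpolation along runs), pairwise and
  mean, with rostral/caudal regional means and the wave-direction call.
* **Replacement ratios and ontogeny** — RT/FT ratios per jaw quadrant and
  size-ordered ontogenetic series with a monotonicity flag.
* **Wave simulator** — a periodic replacement-wave model with known true
  Z-spacing, for parameter-recovery validation of the whole pipeline.
* **CSV dialect + fixtures** — readers/writers for per-tooth observation
  tables and packaged fixtures transcribing the published specimen data.

## Worked example

```python
from zahnreihen import load_fixture, analyze_quadrant

(v18638,) = load_fixture("v18638_right_maxilla_stages")
report = analyze_quadrant(v18638.quadrants[0])
print([[p.label for p in run.points] for run in report.zahnreihen])
print([p.label for p in report.exceptions])
print(report.mean_spacing, report.direction.value)
```

prints

```
[['M1', 'M2', 'M3'], ['M5', 'M6'], ['M8', 'M9', 'rM10'], ['M10', 'M11']]
['rM1', 'rM2', 'M13']
2.75 rostral_to_caudal
```

— the right maxilla of the smallest *Yinlong* (IVPP V18638) carries four
Zahnreihen (M1–M3, M5–M6, M8–rM10, M10–M11) with rM1, rM2 and M13 left
over as exceptions; the mean Z-spacing exceeds 2, so replacement waves
sweep rostral→caudal, and the rostral half of the row is wider-spaced
than the caudal half (`report.rostral_mean > report.caudal_mean`),
i.e. the caudal region replaces faster.

The same pipeline is available from the shell:

```sh
zahnreihen analyze --fixture v18638_right_maxilla_stages \
    --report v18638.json --plot v18638.svg
zahnreihen simulate --n 13 --z 2.5 --seed 42 --out sim.csv
zahnreihen recover --z-grid 1.5:3.5:0.5 --reps 200 --noise 0 --seed 1
```

`recover` simulates dentitions at each true Z, re-estimates Z through the
full pipeline and prints bias and RMSE per grid point.

## Layout

```
src/zahnreihen/
  model.py      staging schemes, maturity ladder, domain types
  analysis.py   segmentation, Z-spacing, direction, ratios, ontogeny
  simulate.py   replacement-wave simulator and recovery experiments
  io.py         CSV dialect, packaged fixtures, report serialization
  plotting.py   Zahnreihen graphs (position vs maturity stage)
  cli.py        click entry points (analyze / simulate / recover)
  fixtures/     packaged specimen data (CSV)
docs/methods.md the model, estimators and design choices in detail
```
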