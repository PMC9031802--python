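# cardioflow

Quantification of cardiomyocyte contraction/relaxation velocity and Ca²⁺
transient kinetics from fluorescence microscopy video, plus a synthetic
video generator that provides ground truth for every analysis stage.

Two analysis branches share a common peak-detection core:

* **Contraction** — dense Horn–Schunck optical flow between consecutive
  frames; each flow field is reduced to one scalar by averaging the top
  1/3000 fraction of per-pixel magnitudes, giving a velocity trace in
  pixels/s. Peaks in the trace are paired into contraction → relaxation
  events, from which TTP, (ΔF/ΔT)max, contraction/relaxation durations,
  inter-peak delay and beating frequency are derived.
* **Calcium** — per-pixel temporal-minimum background subtraction,
  zero-excluded mean green intensity normalized to a maximum of 255,
  frame-difference spark series (Sp_Intensity, Sp_Area at a fixed
  threshold of 10), and per-transient kinetics: T₀, TTP, T₉₀, width at
  10% height, (ΔF/ΔT)max and the spark count preceding each transient.

Group results are normalized to control = 100% and compared with a
two-tailed Welch t-test (two groups) or one-way ANOVA (more), with the
recording as the statistical unit.

## CLI

```sh
# generate a synthetic recording (TIFF stack + ground-truth manifest)
cardioflow synth calcium --out synth/ --seed 3
cardioflow synth contraction --out synth/ --seed 3
cardioflow synth grouppair --out groups/ --seed 3 --config gen.yaml

# analyze a video (or a directory of videos)
cardioflow analyze --mode contraction --input video.tif --out results/
cardioflow analyze --mode calcium --input synth/calcium.tif --out results/

# compare a metric between two result directories (control = 100%)
cardioflow compare --control ctrl_results/ --treated drug_results/ \
    --metric dfdt_max
```

Input containers: multi-page TIFF (fps read from ImageJ metadata) and
uncompressed AVI; 16-bit input is rescaled linearly to the 8-bit range by
the data-type maximum. When the container carries no frame rate, pass
`--fps` (kinetics are reported in seconds, so no default is assumed).
Analysis parameters live in one YAML with `flow.*`, `peaks.*`, `calcium.*`
and `stats.*` sections (see `cardioflow.config.DEFAULTS`); every run
writes the fully resolved config next to its outputs.

## Layout

```
src/cardioflow/
  video_io.py          video/trace loading and saving (TIFF, AVI, CSV)
  _avi.py              minimal uncompressed AVI reader/writer
  optical_flow.py      Horn–Schunck flow, top-fraction velocity trace
  trace_kinetics.py    baseline, peak detection, event pairing, summaries
  calcium_analysis.py  background, intensity/spark series, transients
  synth_data.py        synthetic videos with recorded ground truth
  report.py            group normalization and statistics
  pipeline.py, cli.py, config.py
```
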