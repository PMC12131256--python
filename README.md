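# probemech

Measurement-to-inference pipeline for the bending mechanics of plant
probe-tool materials: from raw four-point-bending force–displacement traces
to flexural rigidity (EI), elastic modulus (E), quality control, and
mixed-model comparisons across tool-selection groupings — plus a synthetic
bending-study generator so every stage is testable without field data.

## What it does

- **ingest** — reads two-column force–displacement trace files
  (delimiter-sniffed, optional header, configurable units) and a
  sample-metadata table (cross-section dimensions in field units, category
  flags); everything is normalised to strict SI at the boundary.
- **mechanics** — extracts the initial slope of each curve (toe-region
  exclusion + longest early window with r² ≥ 0.99), converts it to
  EI = slope·a·(3L² − 4a²)/48 for a support span `L` and probe offset `a`,
  computes the second moment of area (πR⁴/4 circular, WD³/12 rectangular),
  derives E = EI/I, and drops samples with E > 35 GPa (strict) as QC failures.
- **groups** — assigns samples to four comparison schemes (tool-source
  species yes/no; species preference rank; individual plant used/not-used;
  raw material type) and classifies preference ranks from tool-assemblage
  frequency shares (≥ 11.7 % most preferred, ≤ 10 % less preferred).
- **stats** — fits REML linear mixed models of log EI (with log I as a
  covariate) or log E against each scheme with a per-plant random intercept;
  reports type-II F tests with Satterthwaite denominator df, Tukey-adjusted
  pairwise contrasts of estimated marginal means, and back-transformed
  percent rigidity differences (median or EMM basis). The random-intercept
  REML engine is implemented here (closed per-group algebra, profiled
  variance ratio) and is cross-checked in the tests against statsmodels
  `MixedLM`, R `lme4`, and balanced-design closed forms.
- **synth** — generates hierarchical cohorts (species → plant → sample,
  default 3 samples per plant) with log-normal per-material moduli,
  material-dependent cross-sections at probe-tool dimensions, and renders
  raw traces with optional toe regions and force noise; ground truth is
  returned alongside, enabling end-to-end recovery checks.
- **cli/pipeline** — orchestrates full runs and writes delimited artifact
  tables plus a JSON run log with QC accounting.

## CLI

```sh
# simulate a cohort (metadata + traces + ground truth)
probemech simulate --seed 1 --out scratch/cohort

# mechanics only: derived per-sample table
probemech mechanics --traces scratch/cohort/traces \
    --metadata scratch/cohort/metadata.csv --geometry 0.1,0.025 \
    --out scratch/run

# full analysis (mechanics + schemes + mixed models)
probemech analyze --traces scratch/cohort/traces \
    --metadata scratch/cohort/metadata.csv --geometry 0.1,0.025 \
    --out scratch/run

# everything in one go
probemech all --seed 1 --out scratch/full
```

`--geometry L,a` gives the rig's support span and probe offset in metres;
there are no defaults for real data because they are apparatus constants.
A YAML `--config` can supply any of the flags plus slope-extraction settings.

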