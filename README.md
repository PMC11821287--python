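# edna-ageclock

Epigenetic age clocks for fish larvae from environmental-DNA methylation
summaries.

Nanopore sequencing of eDNA filtered from rearing water preserves base
modifications, so per-site methylation levels (5mC, 5hmC, other modified
cytosines, 6mA) can be summarized straight from the reads.  Over the first
weeks post-hatch, methylation at a set of mitogenomic sites changes
rapidly with age.  This package turns those per-sample bedMethyl summaries
into an **epigenetic clock**: it reconciles calls across the three
modification-calling submodels, detects differentially methylated "aging
sites", and fits grouped penalized regressions

    age ≈ b0 + X β,   penalty  λ Σ_g w_g [ α‖β_g‖₂ + ((1−α)/2)‖β_g‖₂² ]

over an exhaustive grid of penalty-mixing values α ∈ {0, 0.01, …, 1},
grouping schemes (all 16 subsets of the site features gene, modification
type, mean coverage, mean reliability, pasted into group labels), and
fold re-randomizations, selecting the best clock by the dual
standardized-MAE criterion (z-scored cross-validated MAE + z-scored
training MAE; MAE is the *median* absolute error).  It also computes the
standard long-read mapping QC metrics (read accuracy and read identity
from CIGAR operations) and per-gene importance reports, and ships a
synthetic-data generator with planted ground truth so the whole pipeline
is testable without sequencing data.

Audience: anyone building methylation age models from nanopore
methylation summaries at low coverage — eDNA epigenetics, larval ecology,
or small-n clock methodology in general.

## Worked example

Generate a synthetic dataset with planted signal, detect aging sites, and
fit a clock:

```sh
edna-ageclock simulate --preset planted --seed 4 --out-dir demo/
edna-ageclock sites --bedmethyl-dir demo/ --genbank demo/annotation.gb \
    --ages 10,12,14,17,19,24 --out demo/sites.tsv
edna-ageclock fit --sites demo/sites.tsv --dataset full \
    --alpha-step 0.1 --bootstrap 5 --seed 1 \
    --out demo/clock.json demo/summary.tsv
edna-ageclock predict --clock demo/clock.json --sites demo/sites.tsv
```

which prints:

```
candidates 110 (+6 conflicts dropped) -> covered 100 -> aging 10
wrote demo/sites.tsv
best clock [full]: scheme=coverage alpha=1.00 cv_mae=0.104 d train_mae=0.030 d n_selected=8
known 10 DPH -> predicted 10.00 DPH
known 12 DPH -> predicted 12.03 DPH
known 14 DPH -> predicted 14.10 DPH
known 17 DPH -> predicted 17.03 DPH
known 19 DPH -> predicted 18.98 DPH
known 24 DPH -> predicted 23.86 DPH
```

Reading this: of 116 planted sites, the 6 contradictory
(5mC-by-one-submodel, 5hmC-by-the-other) sites were dropped, 10 of the
remaining 110 lacked coverage at some age, and exactly the 10 planted
spike/ramp trajectories were detected as aging sites.  The winning
candidate grouped sites by rounded mean coverage at α = 1 and keeps 8 of
the 10 sites; on this noise-free fixture it predicts the six known ages to
about a tenth of a day both in cross-validation (`cv_mae`) and in training
(`train_mae`).  `importance --clock demo/clock.json` then attributes the
coefficient mass to genes.

The same pipeline runs end-to-end from one config file:
`edna-ageclock run --config run.yaml` (see `ednaclock.pipeline.RunConfig`
for the keys), writing `sites.tsv`, per-dataset clock JSONs and importance
tables, a grid summary, QC metrics, and the stage-by-stage site counts.

## Layout

```
src/ednaclock/
  io.py         bedMethyl / GenBank / SAM readers, clock JSON
  qc.py         read accuracy & identity from CIGAR counts
  sites.py      submodel reconciliation, aging-site detection, design matrix
  solver.py     group elastic-net path solver (numba BCD + ridge Woodbury)
  clock.py      CV, grid search, dual-MAE selection, prediction, importance
  synthetic.py  generator with planted ground truth and presets
  pipeline.py   end-to-end orchestration from a YAML config
  cli.py        `edna-ageclock` subcommands
docs/methods.md   model, assumptions, parameter choices, limitations
```
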