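# colonyscreen

Quality-controlled fitness scoring for arrayed-colony chemical-genomic
screens.

Chemical-genomic screens pin single-gene mutant libraries as dense colony
arrays (384/1536 per plate) onto agar under many chemical or environmental
stresses, and read colony size (or integral opacity) as a proxy for
fitness. Turning those per-plate quantifications into interpretable fitness
scores requires correcting systematic plate artefacts, catching the
laboratory errors that large screens inevitably accumulate (mislabelled
plates, mis-pinned colonies, failed detection), and choosing a statistic
that matches the screen's design. `colonyscreen` implements that whole
chain for three screen designs:

* **big** — large multi-condition screens scored with the **S-score**, a
  modified t-statistic comparing a mutant's replicate colony sizes in one
  condition with that mutant's own median across all conditions (the mutant
  as its own "simulated wildtype"):

  *S* = (μ_exp − μ_cont) / √(s²_exp/n_exp + s²_cont/n_cont)

  Scores per plate are rescaled to an interquartile range of 1.35, so the
  conventional outlier fence sits near ±2 and hits are called at *S* > 2
  (gain of fitness) and *S* < −3 (defect; stricter because loss-of-function
  phenotypes dominate).
* **small** — targeted screens with a handful of strains/conditions, where
  the S-score's distributional assumptions fail; scored as wildtype-relative
  fitness ratios with t-based 95% CIs and one-way ANOVA significance.
* **gi** — single/double-knockout plates scored against the multiplicative
  epistasis null *F*(AB)_expected = *F*(A) × *F*(B), with positive
  (alleviating) and negative (synergistic) interaction calls.

It consumes the tab-separated per-plate output of colony image-analysis
tools (the Iris format: `row`, `column` and one column per measured
phenotype), plus a plate-layout table naming the strain at each position.
Everything is importable as a library; a thin `colonyscreen` CLI wires the
pipelines end to end. A synthetic-screen generator
(`colonyscreen.synthetic_plates`) produces Iris files with known ground
truth — edge effects, plate-scale jitter, mis-pins, injected fitness
effects, correlated operon profiles — so every stage is testable without
external data.

## Worked example

Simulate a small 5-condition screen with one strain given a 4-fold growth
defect in one condition, then score it:

```python
from colonyscreen import iris_io, normalization, scoring
from colonyscreen.synthetic_plates import SimulationConfig, simulate_big

cfg = SimulationConfig(n_rows=8, n_cols=12, n_conditions=5, n_replicates=3,
                       effects={("gene0001", "cond01"): 0.25}, seed=1)
ds = simulate_big(cfg).dataset()
ds = iris_io.remove_stray_zeros(ds)
ds, report = normalization.normalize_dataset(ds)
m = scoring.call_significance(
    scoring.scale_scores(scoring.sscore_matrix(ds)))
print(round(m.by_gene().loc["gene0001", "cond01"], 2),
      m.calls.iloc[0, 0], sep="\n")
```

```
-31.66
negative-hit
```

The injected defect scores far below the −3 hit threshold; unperturbed
cells score near zero. The same flow from the shell, via files:

```sh
colonyscreen simulate big --out screen/ --seed 1
colonyscreen big --input-dir screen/ --layout screen/layout.tsv \
    --out results/ --normality-threshold 80
```

writes the normalized dataset, QC report and data-loss curves, the removed
plates/conditions, the scaled S-score matrix with significance calls, and a
clustered CDT/GTR/ATR export (uncentred Pearson distance, average linkage)
for tree-viewer programs.

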