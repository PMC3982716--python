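# mirscore

A small analysis library for linking loss of DNMT3b-regulating
microRNAs to the **breast-cancer hypermethylator phenotype** — a subset
of breast cancer cell lines with DNMT hyperactivity, DNMT3b
overexpression and methylation-dependent silencing of a nine-gene
biomarker panel. It is written for bench scientists and computational
biologists analysing TaqMan-style qPCR panels of candidate regulatory
miRs (miR-29c, miR-148a/b, miR-26a/b, miR-203) across cell-line cohorts.

The pipeline covers, as importable functions plus a thin `mirscore` CLI:

1. **Comparative-Ct quantification** — replicate Ct values are averaged
   and converted to relative quantities against a normalizer assay
   (RNU66 for miRs, β-actin for mRNAs) and a calibrator sample
   (MCF12A):
   ΔCt = Ct(target) − Ct(normalizer), ΔΔCt = ΔCt(sample) − ΔCt(calibrator),
   RQ = 2^−ΔΔCt. "Undetermined" wells are carried as censored values.
2. **Threshold classification** — per miR, an exhaustive search for the
   expression cutoff maximising the fraction of **correct assignments
   (CA)** of hypermethylator vs non-hypermethylator status, with
   sensitivity, specificity, PPV and NPV.
3. **miR scores** — per sample, the count of panel miRs expressed
   strictly below threshold (0–6); groups compared by unpaired
   two-tailed t-test, reported mean ± SEM.
4. **Correlations** — Pearson r (two-tailed p via the t transform on
   n−2 df) of the miR score against promoter-methylation and
   biomarker-gene-expression scores, and the full pairwise miR
   co-regulation matrix.
5. **Perturbation summaries** — pre-miR / antagomir transfection arms
   as fold change (ratio of arm means) and percent reduction vs the
   untransfected control, with star annotations.
6. **Synthetic cohorts** — a seeded Ct-level simulator of the 10+6
   two-group design, plus a reconstructed 16-cell-line reference cohort
   for desk-scale verification.

## Worked example

```python
import mirscore as ms

cohort = ms.reference_cohort("prose")
expr = ms.relative_expression(ms.reference_ct_table("prose"))
rq = expr.rq.loc[cohort.labels.index]

models = [ms.fit_threshold(rq[m].to_numpy(), cohort.labels.to_numpy(), marker_id=m)
          for m in rq.columns]
scores = ms.mir_scores(ms.make_calls(rq, models))
cmp = ms.compare_groups(scores, cohort.labels)
print(f"{cmp.mean_pos:.2f}±{cmp.sem_pos:.2f} vs {cmp.mean_neg:.2f}±{cmp.sem_neg:.2f}, "
      f"p = {cmp.p_value:.1e}")
```

prints

```
4.90±0.46 vs 0.83±0.40, p = 3.0e-05
```

i.e. hypermethylator lines lose on average ~5 of the 6 regulatory miRs
while non-hypermethylator lines lose ~1, and the difference is far
beyond chance. Running `python examples/02_thresholds_and_scores.py`
shows the per-miR diagnostics this is built from, e.g. miR-148b
CA 94% (sens 100%, spec 83%, PPV 91%, NPV 100%) and miR-29c CA 69%
(sens 60%, spec 83%, PPV 86%, NPV 56%). The `examples/` directory has
one short script per capability.

The CLI mirrors the library:
`mirscore simulate --seed 1 --out-dir sim/` then
`mirscore report --ct sim/ct.tsv --labels sim/annotations.tsv --out-dir out/`
writes the full TSV + JSON report bundle.

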