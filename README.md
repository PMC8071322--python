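# circdiv

Circular RNAs (circRNAs) arise from back-splicing — the covalent joining of a
downstream exon end to an upstream exon start — and appear in linear-reference
alignments as split reads in reversed genomic order. `circdiv` is a Python
package for cohort-scale circRNA analysis of paired-end tumor RNAseq, aimed at
researchers studying circRNA expression as a prognostic signal (e.g. in stage
I/II colon cancer):

* **Detection**: back-splice junctions are called from chimeric alignment
  configurations (primary + SA-tagged supplementary segment on the same
  chromosome and strand, mate inside the circle), requiring ≥ 5 distinct
  supporting fragments at an exact breakpoint, and annotated against GENCODE-
  style exon boundaries with zero tolerance — unmatched junctions are kept as
  novel.
* **Circ–linear correlation**: linear gene counts are TMM-normalized
  (re-implemented, validated against edgeR) and Pearson-correlated with each
  circRNA's junction reads.
* **Cohort structure**: circRNAs are encoded present/absent per sample
  (present ⇔ ≥ 5 junction fragments); recurrent circRNAs (≥ 20 samples) enter
  an indicator-matrix multiple correspondence analysis projecting samples and
  circRNA states onto one plane.
* **Survival**: per-sample circRNA *diversity* `d_i` (number of present
  circRNAs) is tested against disease-free survival by Cox regression on
  `ln(d_i+1)` (Breslow ties), by Kaplan–Meier tertile curves, and by the
  logrank test for trend; individual circRNAs by detected-vs-not logrank/Cox.
* **Association screening**: presence/absence versus clinical categories
  (relapse, stage, side, MSI, CMS) by exact Fisher tests — 2×2 in exact
  rational arithmetic, Freeman–Halton for r×c — with Benjamini–Hochberg FDR
  per variable, significant at q < 0.10.
* **Synthetic cohort generator**: no public cohort of this kind exists, so
  the package generates one (SAM alignments, GTF, counts, clinical table)
  with planted ground truth: known junctions, a diversity hazard ratio of
  0.60 per unit `ln(d+1)`, a protective circRNA (HR 0.22), and circRNA–MSI/CMS
  associations (odds ratio 8) at the shape of a 181-patient stage I/II cohort.

## Worked example

Simulate a cohort and run the full pipeline:

```sh
circdiv simulate --seed 1 --out cohort/
circdiv detect --gtf cohort/annotation.gtf --out calls \
    $(for f in cohort/alignments/*.sam; do echo --sam $f; done)
```

or, end to end from Python:

```python
from circdiv import SimulationConfig, simulate_cohort, RunConfig, run_all

cohort = simulate_cohort(SimulationConfig(), seed=1)
paths = cohort.write("cohort/", alignments=True)
summary = run_all(RunConfig(
    sam_files=paths["alignments"], gtf=str(paths["gtf"]),
    gene_counts=str(paths["counts"]), clinical=str(paths["clinical"]),
    out_dir="run/",
))
```

The summary printed for seed 1:

```json
{
 "n_samples": 181,
 "catalog_size": 300,
 "n_annotated": 213,
 "recurrent_circ": 152,
 "correlation_classes": {"n_negative": 0, "n_poor": 17, "n_positive": 93, "n_undefined": 0},
 "mca_total_inertia": 1.0000000000000009,
 "diversity_cox": {"HR": 0.481, "ci": [0.318, 0.728], "p": 0.00054},
 "logrank_trend_p": 0.0036
}
```

Reading it: all 300 planted junctions were recovered (`catalog_size`), 213 of
them sit exactly on exon boundaries of annotated genes, and 152 recur in at
least 20 of the 181 samples. Most recurrent circRNAs correlate positively
with their host gene's normalized expression. The MCA total inertia is
exactly 1, as it must be for all-binary input. The diversity Cox fit
recovers a protective effect (HR 0.481, CI excluding 1): samples with many
distinct circRNAs relapse less, which is the planted signal — here the
fitted HR is stronger than the planted per-unit HR 0.60 because the cohort
also contains a planted protective circRNA whose presence correlates with
diversity. The tertile trend test agrees (p ≈ 0.004).

Per-stage outputs (catalog TSV/BED, junction-count matrix, correlations, MCA
coordinates, survival fits, association table) are written under the run
directory; `--make-plots` adds MCA and KM SVGs.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the pipeline's main end-to-end result from scratch: it simulates
the default 181-sample cohort with the given seed, writes per-sample SAM
alignments, runs detection → normalization/correlation → presence/MCA/
diversity → survival → association screening through the same public API the
tests use, prints the run summary, and writes the results JSON to `--out`
(~40 s on one CPU).
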