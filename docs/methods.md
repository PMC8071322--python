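# Methods

## Problem and scope

`circdiv` re-implements, as a reusable and tested pipeline, a circular-RNA
(circRNA) analysis for tumor cohorts with paired-end RNAseq: detection of
back-splice junctions from chimeric alignments against a linear reference,
exact annotation against gene exon boundaries, TMM normalization of the linear
gene counts and circ–linear correlation, a present/absent cohort encoding with
multiple correspondence analysis (MCA), a circRNA-*diversity* survival
analysis (Kaplan–Meier, logrank-for-trend, Cox regression), and Fisher-exact
association screening against clinical categories with Benjamini–Hochberg FDR.
Because cohorts of this kind are typically not publicly deposited, the package
ships a first-class synthetic cohort generator with known ground truth; every
stage is validated against it and against independent oracles.

## Back-splice detection

A fragment supports a candidate circle when one read aligns in two pieces on
the same chromosome and strand — one piece soft-clipped on its left that
*starts* at the circle start, one soft-clipped on its right that *ends* at the
circle end — with the right-clipped piece mapping downstream of the
left-clipped one (the reversed genomic order that distinguishes a back-splice
from a linear splice chimera), and the read's mate aligning entirely inside
`[start, end]`. Chimeric segments are taken from the SA auxiliary tag of the
primary line; reads with more than one SA entry are rejected (the two-locus
configuration must be unique). The reference span of a segment is
`pos … pos + (M/D/N/=/X lengths) − 1`; this is the only derivation consistent
with the exon-boundary region convention used throughout
(`chrom:start-end`, 1-based inclusive; BED export alone is 0-based half-open).

Support counts distinct fragment names, never alignment lines, so duplicated
records cannot inflate a junction. Junctions need `min_reads = 5` supporting
fragments per sample. Annotation is exact: a junction belongs to a gene iff
its start equals an exon start and its end an exon end of that gene on the
same strand (0 bp slop by default; `--annot-slop` exists for exploration
only). Unmatched junctions are kept as `NOVEL`; real cohorts show a
substantial novel fraction, and collapsing it away would bias diversity.

Decisions where the method description was open:

* the ≥5-fragment threshold is applied **per sample**; cohort presence is
  derived from per-sample calls;
* junction strand is the primary segment's strand, and opposite-strand
  junctions at identical coordinates stay distinct (`--stranded false`
  collapses them);
* mate containment is strict (`full`), with `overlap` as an option;
* MAPQ is not filtered by default; duplicate-flagged records are dropped by
  default.

## TMM normalization

The trimmed mean of M-values is re-implemented rather than delegated: for
sample *k* against the reference *r* (the sample whose upper-quartile of
counts/library-size is closest to the cohort mean), over genes nonzero in
both,

    M_g = log2((y_gk/N_k)/(y_gr/N_r)),  A_g = ½·log2((y_gk/N_k)(y_gr/N_r)),
    w_g = [(N_k−y_gk)/(N_k·y_gk) + (N_r−y_gr)/(N_r·y_gr)]⁻¹,
    f_k = 2^(Σ w_g M_g / Σ w_g)

after discarding the extreme 30 % of genes by M and 5 % by A (rank-based
double trim), then rescaling all factors to geometric mean 1. The test suite
checks the implementation to 1e-8 against edgeR's `calcNormFactors` via
`Rscript` and to 1e-10 against a written-out formula oracle. Normalized
expression is counts per million on the effective library `N_k·f_k`.
Junction counts enter correlations raw — only the gene counts are normalized.
Correlation classes: negative (R < 0), poor (0 ≤ R < 0.3), positive
(R ≥ 0.3); R = 0.3 is classed positive (half-open poor band). Correlations
use the linear scale across all samples with absent cells as 0 junction
reads; `--log1p` and `--present-only` expose the alternative readings.

## Presence, diversity, MCA

A circRNA is *present* in a sample iff its junction-fragment count is ≥ 5 —
the same threshold that defines detection. circRNA diversity is the per-sample
count of present circRNAs, `d_i`, Cox-modelled as `ln(d_i + 1)` (the
log base and +1 offset are configurable; natural log is the default and the
transform used is logged). Tertiles cut at the 1/3 and 2/3 empirical
quantiles with inclusive lower edges, so ties fall deterministically into the
lower group. Recurrence filtering keeps circRNAs present in ≥ 20 samples.

MCA is the indicator-matrix variant (no Burt matrix, no Greenacre
correction): with N samples and Q binary circRNA variables, the N × 2Q
indicator matrix Z (one "present" and one "absent" column each) gives
P = Z/(NQ), row masses 1/N, column masses c; the standardized residual
S = D_r^(−1/2)(P − rcᵀ)D_c^(−1/2) is decomposed by SVD, eigenvalues are
squared singular values, and principal coordinates are D^(−1/2)·U·Σ
(samples) and D^(−1/2)·V·Σ (categories). For all-binary input the total
inertia is exactly 1, the origin is the average profile, and each
present/absent pair has its mass-weighted centroid at the origin — all
asserted in tests. Axis signs are fixed by making the largest-|loading|
category positive, so plots reproduce across runs. Constant columns are
dropped with a warning.

## Survival statistics

Kaplan–Meier estimation is delegated to lifelines. The logrank machinery is
authored because the trend variant shares its internals: over distinct event
times, per-group observed events O_g, expected events E_g = d_t·n_g/n_t, and
the hypergeometric covariance
`V = Σ_t d_t(n_t−d_t)/(n_t−1)·(diag(n_g/n_t) − (n_g/n_t)(n_g/n_t)ᵀ)`.
The K-sample statistic is `(O−E)ᵀV⁻(O−E)` on K−1 df; the trend statistic for
ordered scores s is `[Σ s_g(O_g−E_g)]²/(sᵀVs)` on 1 df. With two groups and
scores (0, 1) the trend test reduces to the plain logrank exactly (tested
algebraically), and the two-group logrank equals the squared Cox score test
under Breslow ties (tested numerically). lifelines'
`multivariate_logrank_test` serves as an independent cross-check.

Cox regression maximizes the partial likelihood via statsmodels `PHReg`,
Breslow tie handling by default (the convention of the mainstream clinical
packages; Efron optional), with SE from the inverse observed information,
HR = exp(β), two-sided 95 % Wald intervals on the log scale (z = 1.96), and
Wald p-values. A monotone likelihood (complete separation — e.g. a presence
column coinciding with the event indicator) is flagged `converged = False`
and the CI suppressed rather than reported. Single-circRNA screens code
detection as 1 against a "not detected" reference, so HR < 1 means detection
is protective. DFS enters in months with surgery as time zero; no delayed
entry.

## Exact association tests

The two-sided Fisher p uses the point-probability rule in **exact rational
arithmetic** (`math.comb` + `Fraction`): a competing table with the observed
margins counts iff its hypergeometric probability is ≤ the observed one under
exact integer comparison. This removes the float tie-tolerance ambiguity of
library implementations and lets the test suite demand |Δp| < 1e-12 against a
full-margin enumeration oracle over every 2×2 table with grand total ≤ 40.
A zero margin yields p = 1 with a warning. The r×c generalization
(Freeman–Halton) enumerates margin-compatible tables exactly, switching to
seeded Monte-Carlo sampling (reported with its standard error) when the
enumeration exceeds `mc_threshold`; empty rows/columns are dropped first.
BH correction runs per clinical variable across the circRNAs tested, with
significance at q < 0.10. CMS "unclassified" samples are excluded from CMS
tables unless requested. Relapse is screened by Fisher on relapse status;
survival fits for individual circRNAs are reported separately.

Note that exact discrete p-values carry an atom at 1 (the modal-table mass,
≈0.1–0.2 at cohort margins), so the permutation-null acceptance check asserts
validity (sub-uniformity) of the raw p and uniformity of its standard
tie-randomized version; the raw p of a discrete test cannot be uniform.

## The synthetic cohort: what it emulates and what it does not

Defaults copy the target study's printed shape: 181 samples, 300 planted
circRNAs with a 29 % novel fraction, four near-ubiquitous circles (prevalence
177/181), MSI prevalence 44/181, ~16 % event fraction (29/181), stage II
115/181, right-sided 92/181, uniform censoring on 12–96 months (median
follow-up ≈ 53 months). Per-circ prevalences follow Beta(0.35, 2), giving a
sparse catalog in which roughly half the planted circles recur in ≥ 20 of 181
samples. A per-sample log-odds random effect (sd 1.5) models varying circRNA
yield between tumors; its magnitude was fixed a priori so the spread of
ln(d+1) matches what the published diversity hazard ratio's confidence width
implies (SE(β̂) ≈ 0.24 at 29 events requires sd(ln(d+1)) ≈ 0.8). Junction
fragments per present cell are 5 + NB(mean 10, dispersion 0.5) — presence and
the detection threshold coincide by construction — and 5 % of absent cells
carry 1–4 stray fragments to exercise the threshold. Clinical covariates are
generated from the fixed presence matrix: hazards
`h_i = h0·exp(β_d·(x_i−x̄) + ln(HR_c)·protective_i)` with β_d = ln 0.60 and
HR_c = 0.22, h0 solved by root-finding so the expected event fraction hits
the target; MSI (OR 8) and CMS (OR 8 toward CMS1) are drawn *conditionally*
on their planted circle's presence so the odds ratio and the marginal
prevalence hold simultaneously. Host-gene means track junction counts
(`host_coupling = 1`), reproducing the mostly-positive circ–linear
correlation profile of real cohorts.

Alignments realize every planted fragment as three SAM records (primary
junction segment with SA tag, supplementary segment, in-circle mate) plus
linear background pairs and forward-splice decoy chimeras that a correct
detector must reject. Reads carry no sequence or sequencing errors —
detection operates on alignment geometry, not sequence — and there are no
isoforms, GC bias, multimapping or rolling-circle multimers. A green
round-trip therefore establishes that the detector inverts the stated
alignment geometry exactly; it does not establish robustness to aligner
idiosyncrasies on real data.

Because one latent yield effect drives all circles, non-planted circRNAs are
genuinely (not spuriously) correlated with diversity, MSI and outcome in this
world; power statements in the tests always refer to the planted circle
specifically.

## Numerical choices

* TMM trims are rank-based (ties keep edgeR's behavior); samples sharing no
  nonzero gene with the reference get factor 1 with a warning.
* MCA discards singular values below 1e-12 (the centering removes the trivial
  axis analytically).
* Cox convergence requires max |score| below tolerance and |β| < 15;
  otherwise the fit is flagged separated.
* Fisher 2×2 distributions are memoized by margins, making cohort-scale
  screens (hundreds of tables on n = 181) run in seconds despite exact
  big-integer arithmetic.
* Monte-Carlo r×c p-values use an add-one estimator (never exactly 0) and are
  seeded; the seed is surfaced through every CLI.
* Tertile cuts use pandas' linear interpolation quantiles; assignment is by
  `≤` so ties never straddle groups.

## Known limitations

* Detection trusts the aligner's SA geometry; no realignment or sequence
  check of the junction is attempted.
* Only univariable Cox models are provided (no adjusted models, diagnostics,
  or competing risks).
* The Freeman–Halton enumeration grows combinatorially; large sparse r×c
  tables fall back to Monte-Carlo estimation.
* The generator's clinical model is exponential/proportional-hazards by
  construction, so it cannot probe robustness to non-proportional hazards.
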