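"""Synthetic stand-in cohort: alignments, counts, and clinical metadata.

The study cohort this package targets (181 chemonaive stage I/II colon tumors
with paired-end RNAseq) is not publicly deposited, so every pipeline stage is
exercised against a generated cohort with known ground truth. The generator
emits:

* a GTF annotation of non-overlapping multi-exon genes;
* per-sample SAM alignments in which planted back-splice junctions appear as
  split reads (primary + supplementary segment with complementary soft clips
  and an SA tag, same chromosome/strand, reversed genomic order) whose mates
  fall inside the circle, plus linear background pairs and forward-splice
  decoy chimeras that a correct detector must reject;
* a genes x samples count matrix with log-normal library sizes, negative-
  binomial noise and an optional composition spike to exercise TMM;
* clinical metadata (DFS months, relapse event, stage, side, MSI, CMS) drawn
  from an exponential proportional-hazards model with a planted diversity
  effect (default HR 0.60 per unit ln(d+1)), a planted protective circRNA
  (default HR 0.22), and planted circRNA-MSI/CMS associations (default odds
  ratio 8), with uniform censoring tuned to a ~16% event fraction.

Default dimensions copy the target cohort's shape: 181 samples, 44 MSI,
29 relapses, 300 planted circRNAs of which a paper-like fraction is "novel"
(off exon boundaries). Per-sample circRNA yield varies via a log-odds random
effect so the diversity spread matches what the printed confidence interval
of the diversity hazard ratio implies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from scipy.optimize import brentq

from .io_formats import GeneModel

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedCohort",
    "simulate_annotation",
    "plant_circles",
    "simulate_presence_counts",
    "simulate_alignments",
    "simulate_counts",
    "simulate_clinical",
    "simulate_cohort",
]


@dataclass
class SimulationConfig:
    # cohort shape
    n_samples: int = 181
    n_genes: int = 120
    n_circ: int = 300
    # annotation geometry
    n_chroms: int = 4
    exons_per_gene: tuple[int, int] = (4, 12)
    exon_length: tuple[int, int] = (150, 450)
    intron_length: tuple[int, int] = (300, 1500)
    intergenic: tuple[int, int] = (2000, 6000)
    # circRNA planting
    novel_fraction: float = 0.29  # mirrors the known/novel catalog split
    presence_beta: tuple[float, float] = (0.35, 2.0)  # per-circ prevalence prior
    sample_effect_sd: float = 1.5  # log-odds random effect on per-sample yield
    n_hot_circ: int = 4  # near-ubiquitous circRNAs (177/181-like)
    hot_prevalence: float = 177 / 181
    junction_nb_mean: float = 10.0  # extra fragments above the 5-read floor
    junction_nb_dispersion: float = 0.5
    subthreshold_prob: float = 0.05  # absent cells with 1-4 stray fragments
    # linear counts
    gene_mean_log: tuple[float, float] = (math.log(300.0), 1.0)
    library_sigma: float = 0.4
    count_dispersion: float = 0.1
    host_coupling: float = 1.0  # host-gene expression tracks junction counts
    spike_n_genes: int = 10
    spike_fold: float = 8.0
    spike_n_samples: int = 1
    # clinical model
    beta_diversity: float = math.log(0.60)  # per unit ln(d+1)
    protective_hr: float = 0.22
    protective_prevalence: float = 94 / 181
    msi_prevalence: float = 44 / 181
    msi_odds_ratio: float = 8.0
    cms_proportions: tuple[tuple[str, float], ...] = (
        ("CMS1", 0.14),
        ("CMS2", 0.37),
        ("CMS3", 0.13),
        ("CMS4", 0.23),
        ("unclassified", 0.13),
    )
    cms_odds_ratio: float = 8.0
    cms_target: str = "CMS1"
    stage2_prop: float = 115 / 181
    right_prop: float = 92 / 181
    event_fraction: float = 29 / 181
    censor_months: tuple[float, float] = (12.0, 96.0)
    # read geometry
    read_length: int = 100
    min_clip: int = 20
    n_background_pairs: int = 200
    n_decoy_pairs: int = 30
    with_noise: bool = False
    seed: int = 0


@dataclass
class GroundTruth:
    circs: pd.DataFrame  # region, chrom, strand, start, end, gene_id, gene_name, exon_span, novel
    counts: pd.DataFrame  # circ regions x samples planted fragment counts
    presence: pd.DataFrame  # samples x circ regions (counts >= 5)
    protective_circ: str
    msi_circ: str
    cms_circ: str
    params: dict


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    genes: list[GeneModel]
    gtf_text: str
    truth: GroundTruth
    gene_counts: pd.DataFrame
    clinical: pd.DataFrame

    def write(self, out_dir, alignments: bool = False) -> dict:
        """Write GTF, counts, clinical and ground truth (optionally SAMs)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "gtf": out / "annotation.gtf",
            "counts": out / "gene_counts.tsv",
            "clinical": out / "clinical.tsv",
            "truth_counts": out / "truth_junction_counts.tsv",
        }
        paths["gtf"].write_text(self.gtf_text)
        self.gene_counts.to_csv(paths["counts"], sep="\t")
        self.clinical.to_csv(paths["clinical"], sep="\t")
        self.truth.counts.to_csv(paths["truth_counts"], sep="\t")
        if alignments:
            sam_dir = out / "alignments"
            paths["alignments"] = simulate_alignments(self.config, self.truth, self.genes, sam_dir)
        return paths


def _sample_ids(n: int) -> list[str]:
    return [f"S{i:03d}" for i in range(1, n + 1)]


# ---------------------------------------------------------------- annotation


def simulate_annotation(config: SimulationConfig, seed: int | None = None) -> tuple[list[GeneModel], str]:
    """Place non-overlapping multi-exon genes on a small synthetic genome."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    per_chrom = math.ceil(config.n_genes / config.n_chroms) if config.n_genes else 0
    genes: list[GeneModel] = []
    lines: list[str] = []
    gi = 0
    for ci in range(1, config.n_chroms + 1):
        chrom = f"chr{ci}"
        cursor = 1
        for _ in range(per_chrom):
            if gi >= config.n_genes:
                break
            cursor += int(rng.integers(*config.intergenic))
            n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"SYNG{gi + 1:05d}"
            gene_name = f"GENE{gi + 1}"
            exons = []
            pos = cursor
            for e in range(1, n_exons + 1):
                length = int(rng.integers(*config.exon_length))
                exons.append((e, pos, pos + length - 1))
                pos += length + int(rng.integers(*config.intron_length))
            cursor = exons[-1][2] + 1
            model = GeneModel(gene_id, gene_name, chrom, strand, exons)
            genes.append(model)
            gi += 1
            gstart, gend = exons[0][1], exons[-1][2]
            attrs = f'gene_id "{gene_id}"; gene_name "{gene_name}";'
            lines.append(f"{chrom}\tsim\tgene\t{gstart}\t{gend}\t.\t{strand}\t.\t{attrs}")
            tx = f'{attrs} transcript_id "{gene_id}.t1";'
            lines.append(f"{chrom}\tsim\ttranscript\t{gstart}\t{gend}\t.\t{strand}\t.\t{tx}")
            for num, es, ee in exons:
                lines.append(
                    f"{chrom}\tsim\texon\t{es}\t{ee}\t.\t{strand}\t.\t{tx} exon_number \"{num}\";"
                )
    if gi < config.n_genes:
        raise ValueError("genome too small for requested genes")
    gtf = "##format: gtf\n##provider: circdiv-sim\n" + "\n".join(lines) + ("\n" if lines else "")
    return genes, gtf


def chrom_lengths(genes: list[GeneModel], pad: int = 10_000) -> dict[str, int]:
    lengths: dict[str, int] = {}
    for g in genes:
        end = g.exons[-1][2] + pad
        lengths[g.chrom] = max(lengths.get(g.chrom, pad), end)
    return lengths


# ---------------------------------------------------------------- circles


def plant_circles(config: SimulationConfig, genes: list[GeneModel], rng: np.random.Generator) -> pd.DataFrame:
    """Choose circRNA regions: exact exon-boundary spans, plus off-boundary novels.

    Circles must comfortably hold a junction read and its mate
    (span >= 2.5 read lengths).
    """
    min_span = int(config.read_length * 2.5)
    rows = []
    seen = set()
    n_novel = int(round(config.n_circ * config.novel_fraction))
    n_annot = config.n_circ - n_novel
    attempts = 0
    while len(rows) < config.n_circ:
        attempts += 1
        if attempts > 200 * config.n_circ:
            raise ValueError("could not place requested circles; enlarge genes")
        gene = genes[int(rng.integers(len(genes)))]
        n_ex = len(gene.exons)
        i = int(rng.integers(n_ex))
        j = int(rng.integers(i, n_ex))
        start = gene.exons[i][1]
        end = gene.exons[j][2]
        novel = len(rows) >= n_annot
        if novel:
            # shift boundaries off any exon edge (intronic/exonic offsets)
            start += int(rng.integers(3, 40))
            end -= int(rng.integers(3, 40))
        if end - start + 1 < min_span:
            continue
        key = (gene.chrom, gene.strand, start, end)
        if key in seen:
            continue
        seen.add(key)
        rows.append(
            {
                "region": f"{gene.chrom}:{start}-{end}",
                "chrom": gene.chrom,
                "strand": gene.strand,
                "start": start,
                "end": end,
                "gene_id": "NOVEL" if novel else gene.gene_id,
                "gene_name": "NOVEL" if novel else gene.gene_name,
                "exon_span": "" if novel else (
                    f"{gene.exons[i][0]}" if i == j else f"{gene.exons[i][0]}-{gene.exons[j][0]}"
                ),
                "novel": novel,
            }
        )
    return pd.DataFrame(rows).set_index("region")


def simulate_presence_counts(
    config: SimulationConfig, circs: pd.DataFrame, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Planted per-sample junction-fragment counts and the implied presence.

    Per-circ prevalences follow a Beta prior; a per-sample log-odds effect
    models varying circRNA yield. Present cells draw 5 + NB fragments, absent
    cells are 0 apart from occasional sub-threshold strays. Three special
    circRNAs get fixed prevalences: the survival-protective one, and the
    MSI- and CMS-associated ones.
    """
    samples = _sample_ids(config.n_samples)
    n_c = len(circs)
    prev = rng.beta(*config.presence_beta, size=n_c).clip(0.01, 0.97)
    for k in range(min(config.n_hot_circ, n_c)):
        prev[k] = config.hot_prevalence
    # reserve three mid-prevalence circs for the planted clinical effects
    special = {}
    annotated = [i for i, novel in enumerate(circs["novel"]) if not novel]
    picks = rng.choice(annotated[config.n_hot_circ:], size=3, replace=False)
    for name, idx, p in zip(
        ("protective", "msi", "cms"), picks, (config.protective_prevalence, 0.45, 0.45)
    ):
        prev[idx] = p
        special[name] = circs.index[idx]

    alpha = rng.normal(0.0, config.sample_effect_sd, size=config.n_samples)
    logit = np.log(prev / (1 - prev))
    prob = 1.0 / (1.0 + np.exp(-(logit[None, :] + alpha[:, None])))
    present = rng.random((config.n_samples, n_c)) < prob

    nb_mean = config.junction_nb_mean
    nb_disp = config.junction_nb_dispersion
    shape = 1.0 / nb_disp
    extra = rng.poisson(rng.gamma(shape, nb_mean * nb_disp, size=present.shape))
    counts = np.where(present, 5 + extra, 0)
    stray = (~present) & (rng.random(present.shape) < config.subthreshold_prob)
    counts = np.where(stray, rng.integers(1, 5, size=present.shape), counts)

    counts_df = pd.DataFrame(counts.T, index=circs.index, columns=samples, dtype=int)
    presence_df = pd.DataFrame(counts.T.T >= 5, index=samples, columns=circs.index)
    return counts_df, presence_df, special


# ---------------------------------------------------------------- alignments


def _segment(header, name, chrom, pos1, cigar, strand, flag, mate_chrom, mate_pos1, sa=None):
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.reference_name = chrom
    a.reference_start = pos1 - 1
    a.cigarstring = cigar
    a.flag = flag | (0x10 if strand == "-" else 0)
    a.mapping_quality = 60
    a.next_reference_name = mate_chrom
    a.next_reference_start = mate_pos1 - 1
    if sa:
        a.set_tag("SA", sa)
    return a


def simulate_alignments(
    config: SimulationConfig,
    truth: GroundTruth,
    genes: list[GeneModel],
    out_dir,
) -> dict[str, str]:
    """Write one SAM per sample realizing the planted junction-fragment counts.

    Each junction fragment becomes three records: the junction read's primary
    segment (right-soft-clipped, ending at the circle end) with an SA tag
    pointing at the left-soft-clipped segment at the circle start, that
    supplementary segment, and the mate aligned inside the circle. Linear
    background pairs and forward-splice decoy chimeras are added per sample.
    Deterministic given the config seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lengths = chrom_lengths(genes)
    chroms = sorted(lengths)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": int(lengths[c])} for c in chroms],
        }
    )
    rl = config.read_length
    circ_rows = truth.circs
    paths: dict[str, str] = {}
    for sample in truth.counts.columns:
        path = out / f"{sample}.sam"
        paths[sample] = str(path)
        with pysam.AlignmentFile(str(path), "w", header=header) as sam:
            frag_i = 0
            col = truth.counts[sample]
            for region, k in col.items():
                if k == 0:
                    continue
                row = circ_rows.loc[region]
                chrom, strand = row["chrom"], row["strand"]
                start, end = int(row["start"]), int(row["end"])
                for _ in range(int(k)):
                    frag_i += 1
                    name = f"{sample}:frag{frag_i}"
                    u = int(rng.integers(config.min_clip, rl - config.min_clip + 1))
                    up_pos = end - u + 1  # right-clipped segment: ends circle
                    up_cigar = f"{u}M{rl - u}S"
                    down_pos = start  # left-clipped segment: starts circle
                    down_cigar = f"{u}S{rl - u}M"
                    if end - start + 1 < rl:
                        continue  # circle shorter than the mate read
                    mate_pos = int(rng.integers(start, end - rl + 2))
                    mate_strand = "-" if strand == "+" else "+"
                    sa_primary = f"{chrom},{down_pos},{strand},{down_cigar},60,0;"
                    sa_supp = f"{chrom},{up_pos},{strand},{up_cigar},60,0;"
                    flag1 = 0x1 | 0x40 | (0x20 if mate_strand == "-" else 0)
                    sam.write(_segment(header, name, chrom, up_pos, up_cigar, strand, flag1, chrom, mate_pos, sa_primary))
                    sam.write(_segment(header, name, chrom, down_pos, down_cigar, strand, flag1 | 0x800, chrom, mate_pos, sa_supp))
                    flag2 = 0x1 | 0x80 | (0x20 if strand == "-" else 0)
                    sam.write(_segment(header, name, chrom, mate_pos, f"{rl}M", mate_strand, flag2, chrom, up_pos))
            # linear background pairs
            for b in range(config.n_background_pairs):
                gene = genes[int(rng.integers(len(genes)))]
                gstart, gend = gene.exons[0][1], gene.exons[-1][2]
                if gend - gstart < 2 * rl + 50:
                    continue
                p1 = int(rng.integers(gstart, gend - 2 * rl))
                p2 = p1 + rl + int(rng.integers(0, 50))
                name = f"{sample}:bg{b}"
                sam.write(_segment(header, name, gene.chrom, p1, f"{rl}M", "+", 0x1 | 0x40 | 0x20, gene.chrom, p2))
                sam.write(_segment(header, name, gene.chrom, p2, f"{rl}M", "-", 0x1 | 0x80, gene.chrom, p1))
            # forward-splice decoys: right-clipped segment UPSTREAM of the
            # left-clipped one (linear splice order) -> must not be called
            for dnum in range(config.n_decoy_pairs):
                chrom = chroms[int(rng.integers(len(chroms)))]
                p1 = int(rng.integers(1000, lengths[chrom] - 5000))
                gap = int(rng.integers(500, 2000))
                u = int(rng.integers(config.min_clip, rl - config.min_clip + 1))
                name = f"{sample}:decoy{dnum}"
                first_cigar = f"{u}M{rl - u}S"  # read start, low coordinate
                second_pos = p1 + u + gap
                second_cigar = f"{u}S{rl - u}M"
                mate_pos = second_pos + rl + 10
                sa1 = f"{chrom},{second_pos},+,{second_cigar},60,0;"
                sa2 = f"{chrom},{p1},+,{first_cigar},60,0;"
                sam.write(_segment(header, name, chrom, p1, first_cigar, "+", 0x1 | 0x40 | 0x20, chrom, mate_pos, sa1))
                sam.write(_segment(header, name, chrom, second_pos, second_cigar, "+", 0x1 | 0x40 | 0x20 | 0x800, chrom, mate_pos, sa2))
                sam.write(_segment(header, name, chrom, mate_pos, f"{rl}M", "-", 0x1 | 0x80, chrom, p1))
            if config.with_noise:
                for nnum in range(20):
                    chrom = chroms[int(rng.integers(len(chroms)))]
                    p1 = int(rng.integers(1000, lengths[chrom] - 2000))
                    other = chroms[int(rng.integers(len(chroms)))]
                    p2 = int(rng.integers(1000, lengths[other] - 2000))
                    name = f"{sample}:noise{nnum}"
                    sa = f"{other},{p2},+,50S50M,0,0;"
                    sam.write(_segment(header, name, chrom, p1, "50M50S", "+", 0x1 | 0x40, chrom, p1 + 300, sa))
                    sam.write(_segment(header, name, chrom, p1 + 300, "100M", "-", 0x1 | 0x80, chrom, p1))
    return paths


# ---------------------------------------------------------------- counts


def simulate_counts(config: SimulationConfig, rng: np.random.Generator | None = None,
                    genes: list[GeneModel] | None = None,
                    truth: GroundTruth | None = None) -> pd.DataFrame:
    """Genes x samples negative-binomial counts with log-normal library sizes.

    A configurable subset of genes is composition-shifted (``spike_fold``) in
    the first ``spike_n_samples`` samples to give TMM something to correct.
    When ground truth is supplied and ``host_coupling`` > 0, the mean of each
    annotated circRNA's host gene tracks that circRNA's junction counts, so
    circ-linear correlations are mostly positive as in real cohorts.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    samples = _sample_ids(config.n_samples)
    gene_ids = [g.gene_id for g in genes] if genes else [f"SYNG{i + 1:05d}" for i in range(config.n_genes)]
    n_g = len(gene_ids)
    base = rng.lognormal(*config.gene_mean_log, size=n_g)
    lib = rng.lognormal(0.0, config.library_sigma, size=config.n_samples)
    mean = np.outer(base, lib)
    if truth is not None and config.host_coupling > 0:
        gene_pos = {g: i for i, g in enumerate(gene_ids)}
        for region, row in truth.circs.iterrows():
            gi = gene_pos.get(row["gene_id"])
            if gi is None:
                continue
            c = truth.counts.loc[region].to_numpy(dtype=float)
            mean[gi, :] *= 1.0 + config.host_coupling * c / (c.mean() + 1.0)
    if config.spike_n_genes and config.spike_n_samples:
        spiked = rng.choice(n_g, size=min(config.spike_n_genes, n_g), replace=False)
        mean[np.ix_(spiked, np.arange(config.spike_n_samples))] *= config.spike_fold
    disp = config.count_dispersion
    if disp > 0:
        lam = rng.gamma(1.0 / disp, mean * disp)
    else:
        lam = mean
    counts = rng.poisson(lam)
    return pd.DataFrame(counts, index=gene_ids, columns=samples, dtype=int)


# ---------------------------------------------------------------- clinical


def _event_fraction(h: np.ndarray, a: float, b: float) -> float:
    """P(T < C) averaged over subjects, T ~ Exp(h_i), C ~ U(a, b)."""
    with np.errstate(over="ignore"):
        p = 1.0 - (np.exp(-h * a) - np.exp(-h * b)) / (h * (b - a))
    return float(np.mean(p))


def _conditional_binary(prevalence: float, odds_ratio: float, p_present: float) -> tuple[float, float]:
    """P(flag|absent), P(flag|present) with given marginal prevalence and OR."""

    def marginal(pa):
        odds_a = pa / (1 - pa)
        pb = odds_ratio * odds_a / (1 + odds_ratio * odds_a)
        return p_present * pb + (1 - p_present) * pa - prevalence

    lo, hi = 1e-9, prevalence
    if marginal(hi) < 0:
        hi = 1 - 1e-9
    pa = brentq(marginal, lo, hi)
    odds_a = pa / (1 - pa)
    pb = odds_ratio * odds_a / (1 + odds_ratio * odds_a)
    return pa, pb


def simulate_clinical(
    config: SimulationConfig,
    truth: GroundTruth,
    seed: int | None = None,
) -> pd.DataFrame:
    """Clinical table generated from the fixed presence matrix.

    Hazard: h_i = h0 * exp(beta_d * (x_i - mean x) + beta_c * protective_i)
    with x_i = ln(d_i + 1); h0 solved so the expected event fraction under the
    uniform censoring window matches the configured target. MSI and CMS are
    drawn conditionally on their planted circRNA's presence so the configured
    odds ratios and marginal prevalences both hold.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed if seed is None else seed, 13])
    )
    presence = truth.presence
    samples = presence.index
    d = presence.sum(axis=1).to_numpy(dtype=float)
    x = np.log(d + 1.0)
    prot = presence[truth.protective_circ].to_numpy(dtype=float)
    lin = config.beta_diversity * (x - x.mean()) + math.log(config.protective_hr) * (prot - prot.mean())
    a, b = config.censor_months

    def achieved(log_h0):
        return _event_fraction(np.exp(log_h0 + lin), a, b) - config.event_fraction

    try:
        log_h0 = brentq(achieved, -12.0, 3.0)
    except ValueError:
        import warnings

        warnings.warn(
            f"target event fraction {config.event_fraction:.3f} unattainable; "
            f"achieved {_event_fraction(np.exp(-12 + lin), a, b):.3f}-"
            f"{_event_fraction(np.exp(3 + lin), a, b):.3f}"
        )
        log_h0 = -1.0
    h = np.exp(log_h0 + lin)
    t_event = rng.exponential(1.0 / h)
    censor = rng.uniform(a, b, size=len(samples))
    time = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)
    time = np.maximum(time, 0.01)

    msi_present = presence[truth.msi_circ].to_numpy()
    pa, pb = _conditional_binary(config.msi_prevalence, config.msi_odds_ratio, float(msi_present.mean()))
    msi = np.where(rng.random(len(samples)) < np.where(msi_present, pb, pa), "MSI", "MSS")

    cms_present = presence[truth.cms_circ].to_numpy()
    labels = [k for k, _ in config.cms_proportions]
    base = np.array([v for _, v in config.cms_proportions])
    boosted = base * np.where(np.array(labels) == config.cms_target, config.cms_odds_ratio, 1.0)
    boosted = boosted / boosted.sum()
    p_c = float(cms_present.mean())
    resid = (base - p_c * boosted) / (1 - p_c)
    resid = np.clip(resid, 1e-6, None)
    resid = resid / resid.sum()
    cms = np.empty(len(samples), dtype=object)
    for i in range(len(samples)):
        probs = boosted if cms_present[i] else resid
        cms[i] = labels[int(rng.choice(len(labels), p=probs))]

    stage = np.where(rng.random(len(samples)) < config.stage2_prop, "II", "I")
    side = np.where(rng.random(len(samples)) < config.right_prop, "right", "left")

    return pd.DataFrame(
        {
            "dfs_months": time,
            "event": event,
            "relapse": np.where(event == 1, "yes", "no"),
            "stage": stage,
            "side": side,
            "msi": msi,
            "cms": cms,
        },
        index=pd.Index(samples, name="sample_id"),
    )


# ---------------------------------------------------------------- orchestration


def simulate_cohort(config: SimulationConfig | None = None, seed: int | None = None) -> SimulatedCohort:
    """Generate annotation, planted circles, counts and clinical metadata.

    Alignments are produced on demand (``cohort.write(out, alignments=True)``
    or :func:`simulate_alignments`) because they dominate runtime and disk.
    Fully deterministic given (config, seed).
    """
    config = config or SimulationConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    genes, gtf_text = simulate_annotation(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    circs = plant_circles(config, genes, rng)
    counts, presence, special = simulate_presence_counts(config, circs, rng)
    truth = GroundTruth(
        circs=circs,
        counts=counts,
        presence=presence,
        protective_circ=special["protective"],
        msi_circ=special["msi"],
        cms_circ=special["cms"],
        params={
            "beta_diversity": config.beta_diversity,
            "protective_hr": config.protective_hr,
            "msi_odds_ratio": config.msi_odds_ratio,
            "cms_odds_ratio": config.cms_odds_ratio,
            "seed": config.seed,
        },
    )
    gene_counts = simulate_counts(config, genes=genes, truth=truth)
    clinical = simulate_clinical(config, truth)
    return SimulatedCohort(
        config=config,
        genes=genes,
        gtf_text=gtf_text,
        truth=truth,
        gene_counts=gene_counts,
        clinical=clinical,
    )
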