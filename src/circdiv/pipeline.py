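"""End-to-end orchestration: detect -> correlate -> MCA/diversity -> survival -> associations.

One RunConfig drives every stage with the analysis defaults surfaced
explicitly (min_reads 5, min_samples 20, correlation boundary 0.3, FDR 0.10,
3 diversity tertiles). Every stage writes its own TSV outputs under the run
directory and contributes to a single JSON summary; a stage failure aborts
with the stage name while earlier outputs are preserved.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association_tests, circ_detect, cohort_matrix, io_formats, linear_norm, survival_stats

__all__ = ["RunConfig", "PipelineError", "run_all"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    sam_files: dict  # sample id -> SAM/BAM path
    gtf: str
    gene_counts: str  # genes x samples TSV
    clinical: str  # clinical TSV indexed by sample id
    out_dir: str
    min_reads: int = 5
    min_samples: int = 20
    correlation_boundary: float = 0.3
    fdr_threshold: float = 0.10
    n_tertiles: int = 3
    variables: tuple = ("relapse", "stage", "side", "msi", "cms")
    mate_containment: str = "full"
    seed: int = 0
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                logger.error("stage %s: failed (%s)", name, exc)
                raise PipelineError(name, exc) from exc

        return wrapper

    return deco


@_stage("detect")
def _detect(config: RunConfig, out: Path):
    genes = io_formats.read_gtf(config.gtf)
    per_sample = {}
    diagnostics = {}
    for sample, path in config.sam_files.items():
        diag = circ_detect.DetectDiagnostics()
        evidence = circ_detect.extract_split_candidates(io_formats.read_sam(path), diagnostics=diag)
        evidence = circ_detect.require_mate_in_circle(evidence, config.mate_containment, diagnostics=diag)
        junctions = circ_detect.call_junctions(evidence, min_reads=config.min_reads)
        per_sample[sample] = circ_detect.annotate(junctions, genes)
        diagnostics[sample] = diag.as_dict()
    catalog, matrix = circ_detect.merge_cohort(per_sample)
    io_formats.write_catalog(catalog, str(out / "circdiv"))
    matrix.to_csv(out / "junction_counts.tsv", sep="\t")
    with open(out / "detect_diagnostics.json", "w") as fh:
        json.dump(diagnostics, fh, indent=1)
    return genes, catalog, matrix


@_stage("correlate")
def _correlate(config: RunConfig, out: Path, catalog, matrix):
    counts = pd.read_csv(config.gene_counts, sep="\t", index_col=0)
    factors = linear_norm.tmm_factors(counts)
    expr = linear_norm.normalized_expression(counts, factors)
    host = {str(c.region): c.gene_id for c in catalog if c.gene_id != circ_detect.NOVEL}
    correlations = linear_norm.circ_linear_correlation(
        matrix, expr, host, min_samples_present=config.min_samples, boundary=config.correlation_boundary
    )
    frame = pd.DataFrame(
        [(c.circ_id, c.gene_id, c.r, c.n, c.r_class) for c in correlations],
        columns=["region", "gene_id", "R", "n", "class"],
    )
    frame.to_csv(out / "correlations.tsv", sep="\t", index=False)
    factors.factors.rename("tmm_factor").to_csv(out / "tmm_factors.tsv", sep="\t")
    summary = linear_norm.summarize_correlations(correlations, config.correlation_boundary) if correlations else None
    return correlations, summary


@_stage("cohort")
def _cohort(config: RunConfig, out: Path, matrix, clinical):
    presence = cohort_matrix.make_presence(matrix, min_reads=config.min_reads)
    recurrent = cohort_matrix.recurrence_filter(presence, min_samples=config.min_samples)
    div = cohort_matrix.diversity(presence)
    div.to_csv(out / "diversity.tsv", sep="\t")
    result = cohort_matrix.mca(recurrent)
    pd.Series(result.eigenvalues, name="eigenvalue").to_csv(out / "mca_eigenvalues.tsv", sep="\t")
    result.sample_coords.to_csv(out / "mca_sample_coords.tsv", sep="\t")
    result.category_coords.to_csv(out / "mca_category_coords.tsv", sep="\t")
    if config.make_plots:
        _plot_mca(result, clinical, out / "mca.svg")
    return presence, recurrent, div, result


@_stage("survival")
def _survival(config: RunConfig, out: Path, div, presence, clinical):
    records = [
        survival_stats.SurvivalRecord(s, float(row["dfs_months"]), int(row["event"]))
        for s, row in clinical.iterrows()
    ]
    ids = [r.sample_id for r in records]
    x = div["log_diversity"].reindex(ids)
    cox = survival_stats.cox_fit(records, pd.DataFrame({"log_diversity": x}, index=ids))
    groups = cohort_matrix.tertiles(div["diversity"].reindex(ids))
    order = {"low": 1, "intermediate": 2, "high": 3}
    trend = survival_stats.logrank_trend(
        records, groups.labels.map(order).to_numpy(), scores=(1, 2, 3)
    )
    rows = [
        {
            "model": "cox_log_diversity",
            "coef": cox.coef.iloc[0],
            "HR": cox.hr.iloc[0],
            "ci_lower": cox.ci_lower.iloc[0],
            "ci_upper": cox.ci_upper.iloc[0],
            "p": cox.p.iloc[0],
        },
        {"model": "logrank_trend_tertiles", "coef": np.nan, "HR": np.nan,
         "ci_lower": np.nan, "ci_upper": np.nan, "p": trend.p},
    ]
    pd.DataFrame(rows).to_csv(out / "survival_fits.tsv", sep="\t", index=False)
    if config.make_plots:
        _plot_km(records, groups.labels.reindex(ids), out / "km_diversity_tertiles.svg")
    return cox, trend, records


@_stage("associate")
def _associate(config: RunConfig, out: Path, recurrent, clinical):
    frames = []
    screens = {}
    for variable in config.variables:
        try:
            results = association_tests.associate_screen(
                recurrent, clinical, variable, fdr_threshold=config.fdr_threshold, seed=config.seed
            )
        except ValueError as exc:
            logger.warning("skipping variable %s: %s", variable, exc)
            continue
        screens[variable] = results
        frames.append(
            pd.DataFrame(
                [
                    {"region": r.circ_id, "variable": variable, "p": r.p, "FDR": r.q,
                     "significant": r.significant}
                    for r in results
                ]
            )
        )
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["region", "variable", "p", "FDR", "significant"]
    )
    table.to_csv(out / "associations.tsv", sep="\t", index=False)
    return screens, table


def _plot_mca(result, clinical, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    sc = result.sample_coords
    cc = result.category_coords
    ax.scatter(sc.iloc[:, 0], sc.iloc[:, 1], s=18, c="0.4", marker="o", label="samples")
    present = cc.index.str.endswith(":present")
    ax.scatter(cc.loc[present].iloc[:, 0], cc.loc[present].iloc[:, 1], s=24, c="tab:red",
               marker="^", label="present")
    ax.scatter(cc.loc[~present].iloc[:, 0], cc.loc[~present].iloc[:, 1], s=24, c="tab:blue",
               marker="^", label="absent")
    ax.axhline(0, lw=0.5, c="k")
    ax.axvline(0, lw=0.5, c="k")
    ax.set_xlabel(f"axis 1 ({result.eigenvalues[0]:.3f})")
    ax.set_ylabel(f"axis 2 ({result.eigenvalues[1]:.3f})" if result.eigenvalues.size > 1 else "axis 2")
    ax.legend()
    fig.savefig(path, format="svg")
    plt.close(fig)


def _plot_km(records, groups, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from lifelines import KaplanMeierFitter

    fig, ax = plt.subplots(figsize=(7, 5))
    times = np.array([r.dfs_time for r in records])
    events = np.array([r.event for r in records])
    for label, color in (("low", "tab:red"), ("intermediate", "tab:blue"), ("high", "tab:green")):
        mask = (groups == label).to_numpy()
        if mask.sum() == 0:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask], label=f"{label} (n={mask.sum()})")
        kmf.plot_survival_function(ax=ax, ci_show=False, color=color)
    ax.set_xlabel("months since surgery")
    ax.set_ylabel("disease-free survival")
    fig.savefig(path, format="svg")
    plt.close(fig)


def run_all(config: RunConfig) -> dict:
    """Run every stage in order and write a run summary.

    Returns the summary dict (also written as ``summary.json``); intermediate
    artifacts land in ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    logger.info("run parameters: %s", {k: v for k, v in asdict(config).items() if k != "sam_files"})

    for name, path in (("gtf", config.gtf), ("gene_counts", config.gene_counts), ("clinical", config.clinical)):
        if not Path(path).exists():
            raise PipelineError("detect" if name == "gtf" else name, FileNotFoundError(path))

    genes, catalog, matrix = _detect(config, out)
    clinical = pd.read_csv(config.clinical, sep="\t", index_col=0)
    correlations, corr_summary = _correlate(config, out, catalog, matrix)
    presence, recurrent, div, mca_result = _cohort(config, out, matrix, clinical)
    cox, trend, records = _survival(config, out, div, presence, clinical)
    screens, assoc_table = _associate(config, out, recurrent, clinical)

    summary = {
        "n_samples": int(matrix.shape[1]),
        "catalog_size": int(matrix.shape[0]),
        "n_annotated": int(sum(1 for c in catalog if c.gene_id != circ_detect.NOVEL)),
        "recurrent_circ": int(recurrent.shape[1]),
        "correlation_classes": {
            k: corr_summary[k] for k in ("n_negative", "n_poor", "n_positive", "n_undefined")
        } if corr_summary else None,
        "mca_eigenvalues": [float(v) for v in mca_result.eigenvalues[:5]],
        "mca_total_inertia": mca_result.total_inertia,
        "diversity_cox": {
            "HR": float(cox.hr.iloc[0]),
            "ci": [float(cox.ci_lower.iloc[0]), float(cox.ci_upper.iloc[0])],
            "p": float(cox.p.iloc[0]),
        },
        "logrank_trend_p": float(trend.p),
        "n_significant_associations": int(assoc_table["significant"].sum()) if len(assoc_table) else 0,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    return summary
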