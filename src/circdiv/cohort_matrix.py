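"""Present/absent encoding, circRNA diversity, and multiple correspondence analysis.

circRNA expression is sparse across a cohort — for most genes only the linear
transcript is seen in most samples — so instead of imputing missing expression
levels each circRNA is scored categorically as "present" (>= min_reads
junction fragments) or "absent". The samples x circRNAs boolean table supports
three downstream views: per-sample circRNA *diversity* (the number of distinct
circRNAs present, the prognostic statistic), recurrence filtering (circRNAs in
>= 20 samples), and an indicator-matrix MCA projecting samples and circRNA
states onto a shared principal plane where (0,0) is the average profile.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MCAResult",
    "DiversityGroups",
    "make_presence",
    "recurrence_filter",
    "diversity",
    "mca",
    "tertiles",
]

logger = logging.getLogger(__name__)


@dataclass
class MCAResult:
    eigenvalues: np.ndarray  # descending, nontrivial axes
    sample_coords: pd.DataFrame  # N x K principal coordinates
    category_coords: pd.DataFrame  # 2Q x K, rows "<circ>:present"/"<circ>:absent"
    total_inertia: float
    n_axes: int


@dataclass
class DiversityGroups:
    labels: pd.Series  # sample -> low / intermediate / high
    cuts: tuple[float, float]


def make_presence(junction_count_matrix: pd.DataFrame, min_reads: int = 5) -> pd.DataFrame:
    """Samples x circRNAs boolean presence from a circRNAs x samples count matrix.

    A circRNA is present in a sample iff its supporting-fragment count is at
    least ``min_reads`` — the same threshold that defines a detected junction.
    """
    return (junction_count_matrix.T >= min_reads).astype(bool)


def recurrence_filter(presence: pd.DataFrame, min_samples: int = 20) -> pd.DataFrame:
    """Keep circRNAs present in at least ``min_samples`` samples."""
    n_present = presence.sum(axis=0)
    keep = n_present[n_present >= min_samples].index
    logger.info("recurrence filter: kept %d of %d circRNAs (min_samples=%d)",
                len(keep), presence.shape[1], min_samples)
    if len(keep) == 0:
        raise ValueError(f"no circRNA is present in at least {min_samples} samples")
    return presence[keep]


def diversity(presence: pd.DataFrame, scope: pd.Index | None = None) -> pd.DataFrame:
    """Per-sample circRNA diversity d_i and its log transform ln(d_i + 1).

    ``scope`` restricts the columns counted (e.g. the recurrence-filtered set);
    the default counts all detected circRNAs.
    """
    cols = presence.columns if scope is None else [c for c in presence.columns if c in set(scope)]
    d = presence[list(cols)].sum(axis=1).astype(int)
    return pd.DataFrame({"diversity": d, "log_diversity": np.log(d + 1.0)})


def mca(presence: pd.DataFrame, n_axes: int = 2) -> MCAResult:
    """Indicator-matrix multiple correspondence analysis of a presence table.

    Builds the N x 2Q indicator matrix Z (one "present" and one "absent"
    column per circRNA), forms the correspondence matrix P = Z/(NQ), centers
    and standardizes S = D_r^(-1/2) (P - r c^T) D_c^(-1/2), and takes its SVD.
    Eigenvalues are squared singular values; principal coordinates are
    D^(-1/2) U S (samples) and D^(-1/2) V S (categories). For Q binary
    variables with no constant column the total inertia is exactly 1.
    Axis signs are fixed by making the largest-|coordinate| category positive.
    """
    if presence.shape[0] < 2:
        raise ValueError("MCA needs at least 2 samples")
    nunique = presence.nunique(axis=0)
    constant = nunique[nunique < 2].index
    if len(constant):
        warnings.warn(f"dropping {len(constant)} constant circRNA column(s) before MCA")
        presence = presence.drop(columns=constant)
    n, q = presence.shape
    if q < 2:
        raise ValueError("MCA needs at least 2 non-constant circRNA columns")

    x = presence.to_numpy(dtype=float)
    # interleave present/absent indicator columns per circRNA
    z = np.empty((n, 2 * q))
    z[:, 0::2] = x
    z[:, 1::2] = 1.0 - x
    cat_labels = []
    for c in presence.columns:
        cat_labels += [f"{c}:present", f"{c}:absent"]

    p = z / (n * q)
    r = np.full(n, 1.0 / n)
    c = p.sum(axis=0)
    s = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    u, sig, vt = np.linalg.svd(s, full_matrices=False)

    keep = sig > 1e-12
    u, sig, vt = u[:, keep], sig[keep], vt[keep, :]
    k = sig.size
    if k < 2:
        warnings.warn(f"only {k} informative MCA axis/axes available")

    f = (u * sig) / np.sqrt(r)[:, None]
    g = (vt.T * sig) / np.sqrt(c)[:, None]
    # reproducible axis orientation
    for j in range(k):
        if g[np.argmax(np.abs(g[:, j])), j] < 0:
            f[:, j] *= -1.0
            g[:, j] *= -1.0

    axes = [f"axis{j + 1}" for j in range(k)]
    return MCAResult(
        eigenvalues=sig**2,
        sample_coords=pd.DataFrame(f, index=presence.index, columns=axes),
        category_coords=pd.DataFrame(g, index=cat_labels, columns=axes),
        total_inertia=float(np.sum(sig**2)),
        n_axes=min(n_axes, k),
    )


def tertiles(values: "pd.Series | np.ndarray") -> DiversityGroups:
    """Split diversity values into three equal quantile groups.

    Cut points are the 1/3 and 2/3 empirical quantiles; assignment uses
    inclusive lower edges (v <= q1/3 -> low), so ties at a cut fall into the
    lower group deterministically.
    """
    s = pd.Series(values).astype(float)
    if s.size < 3:
        raise ValueError("need at least 3 samples to form tertiles")
    if s.nunique() == 1:
        raise ValueError("cannot form 3 groups: all values identical")
    q1 = float(s.quantile(1 / 3))
    q2 = float(s.quantile(2 / 3))
    labels = pd.Series(
        np.where(s <= q1, "low", np.where(s <= q2, "intermediate", "high")),
        index=s.index,
    )
    return DiversityGroups(labels=labels, cuts=(q1, q2))
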