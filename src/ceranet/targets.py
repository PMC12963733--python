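"""Cis and trans target-gene assignment, plus the correlation primitives.

Cis targets are protein-coding genes whose genomic span lies within a
fixed window (default 100 kb, inclusive) of a differential lncRNA's span
on the same chromosome, strand ignored.  Trans targets are genes whose
expression correlates with the lncRNA across samples with |Pearson r|
strictly above 0.95 at p < 0.05.

The Pearson and Spearman primitives here are used pipeline-wide (the
ceRNA screen imports them) so that every recorded correlation is
reproducible by calling one function.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, ConstantInputError, InsufficientDataError


# ---------------------------------------------------------------------------
# Correlation primitives
# ---------------------------------------------------------------------------

def _validate_xy(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape or x.ndim != 1:
        raise InsufficientDataError("x and y must be 1-D and of equal length")
    if len(x) < 3:
        raise InsufficientDataError("correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation of a constant vector is undefined")


def _t_pvalue(r: float, n: int) -> float:
    """Two-sided p for a correlation via the t transform with n-2 df."""
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation and its two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _validate_xy(x, y)
    xm = x - x.mean()
    ym = y - y.mean()
    r = float(np.dot(xm, ym) / np.sqrt(np.dot(xm, xm) * np.dot(ym, ym)))
    r = max(-1.0, min(1.0, r))
    return r, _t_pvalue(r, len(x))


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Rank correlation (average ranks for ties) with the t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _validate_xy(x, y)
    return pearson(stats.rankdata(x), stats.rankdata(y))


def pearson_matrix(
    rows_a: pd.DataFrame, rows_b: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Pearson r and p between the rows of two aligned matrices.

    Rows with zero variance get ``r = nan`` (they cannot be screened).
    """
    if list(rows_a.columns) != list(rows_b.columns):
        raise AlignmentError("matrices must share identical sample columns")
    n = rows_a.shape[1]
    if n < 3:
        raise InsufficientDataError("correlation needs n >= 3")
    a = rows_a.to_numpy(dtype=float)
    b = rows_b.to_numpy(dtype=float)
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt((a * a).sum(axis=1))
    sb = np.sqrt((b * b).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a @ b.T) / np.outer(sa, sb)
    r[~np.isfinite(r)] = np.nan
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p[np.abs(r) >= 1.0] = 0.0
    p[np.isnan(r)] = np.nan
    return r, p


# ---------------------------------------------------------------------------
# Cis assignment
# ---------------------------------------------------------------------------

def span_gap(
    start_a: int, end_a: int, start_b: int, end_b: int
) -> int:
    """Distance between two 1-based inclusive spans; 0 when they overlap."""
    return max(0, max(start_a, start_b) - min(end_a, end_b))


def cis_targets(
    de_lncrnas: pd.DataFrame,
    coding_genes: pd.DataFrame,
    window: int = 100_000,
) -> pd.DataFrame:
    """Pair each lncRNA with the coding genes within ``window`` bp.

    Both inputs are span tables with columns ``transcript_id``,
    ``chromosome``, ``start``, ``end``.  A pair is reported when the spans
    share a chromosome and their gap is at most ``window`` (inclusive
    boundary; overlapping spans get distance 0).  Strand is ignored.
    """
    rows = []
    genes_by_chrom = dict(tuple(coding_genes.groupby("chromosome", sort=False)))
    for lnc in de_lncrnas.itertuples(index=False):
        genes = genes_by_chrom.get(lnc.chromosome)
        if genes is None:
            continue
        gs = genes["start"].to_numpy()
        ge = genes["end"].to_numpy()
        gap = np.maximum(
            0, np.maximum(lnc.start, gs) - np.minimum(lnc.end, ge)
        )
        hit = gap <= window
        for gid, d in zip(genes.loc[hit, "transcript_id"], gap[hit]):
            rows.append(
                {
                    "lncrna_id": lnc.transcript_id,
                    "gene_id": gid,
                    "mode": "cis",
                    "distance": int(d),
                    "r": np.nan,
                    "p_value": np.nan,
                }
            )
    out = pd.DataFrame(
        rows, columns=["lncrna_id", "gene_id", "mode", "distance", "r", "p_value"]
    )
    return out.drop_duplicates(subset=["lncrna_id", "gene_id"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Trans assignment
# ---------------------------------------------------------------------------

def trans_targets(
    lnc_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    r_threshold: float = 0.95,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Pairs with |Pearson r| strictly above ``r_threshold`` and p below
    ``p_threshold`` across the shared sample columns."""
    if list(lnc_expr.columns) != list(gene_expr.columns):
        raise AlignmentError("expression matrices must share sample columns")
    r, p = pearson_matrix(lnc_expr, gene_expr)
    keep = (np.abs(r) > r_threshold) & (p < p_threshold)
    keep &= ~np.isnan(r)
    li, gi = np.nonzero(keep)
    out = pd.DataFrame(
        {
            "lncrna_id": lnc_expr.index.to_numpy()[li],
            "gene_id": gene_expr.index.to_numpy()[gi],
            "mode": "trans",
            "distance": pd.array([pd.NA] * len(li), dtype="Int64"),
            "r": r[li, gi],
            "p_value": p[li, gi],
        }
    )
    return out.reset_index(drop=True)


def log_normalized(counts: pd.DataFrame) -> pd.DataFrame:
    """log1p of depth-normalized counts (median-of-ratios factors).

    The variance-stabilized scale on which the pipeline computes all
    expression correlations.
    """
    from .de import normalize_counts

    norm, _ = normalize_counts(counts)
    return np.log1p(norm)
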