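"""Differential expression of count data via a conditional NB exact test.

The screen thresholds raw p-values at 0.05 and |log2FC| at 0.26.  The test
behind the p-values is a self-contained conditional negative-binomial exact
test: counts are first brought to equal effective library sizes
(median-of-ratios factors by default, robust to asymmetric composition),
then, for each feature, the split of the total count ``t = sum_a + sum_b``
between the two groups is compared with its null distribution

    P(Y_a = a | t)  proportional to  f_NB(a; n_a mu, phi / n_a)
                                   * f_NB(t - a; n_b mu, phi / n_b)

where ``mu = t / (n_a + n_b)`` is the pooled per-sample mean and the NB is
parameterized by (mean, dispersion) with variance ``mean + phi * mean**2``
(a group sum of n i.i.d. NB(mu, phi) draws is NB(n mu, phi / n)).  The
two-sided p-value follows the minimum-likelihood rule: the sum of the
probabilities of all splits no more likely than the observed one.  At
``phi = 0`` this reduces to the conditional binomial exact test.

A common dispersion is estimated by the method of moments across features;
no per-feature shrinkage is attempted.  p-values are used raw — no FDR —
matching the stated screen criteria.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .config import Thresholds
from .errors import AlignmentError, DegenerateInputError, ParameterError

# Relative log-probability slack when collecting "no more likely" outcomes,
# guarding against ties broken by floating-point noise.
_MINLIKE_TOL = 1e-7


# ---------------------------------------------------------------------------
# Normalisation and descriptive quantities
# ---------------------------------------------------------------------------

def compute_fpkm(
    counts: pd.DataFrame,
    transcript_lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped fragments.

    ``fpkm = counts * 1e9 / (length_bp * library_size)``.  Library sizes
    default to the column sums of ``counts``.
    """
    lengths = transcript_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = counts.index[lengths.isna()][:5].tolist()
        raise AlignmentError(f"missing transcript lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ParameterError("transcript lengths must be > 0")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = library_sizes.reindex(counts.columns)
    if library_sizes.isna().any() or (library_sizes <= 0).any():
        raise ParameterError("library sizes must be > 0 for every sample")
    return counts * 1e9 / np.outer(lengths.to_numpy(), library_sizes.to_numpy())


def normalize_counts(
    counts: pd.DataFrame, method: str = "median_of_ratios"
) -> tuple[pd.DataFrame, pd.Series]:
    """Remove per-sample depth/composition factors from a count matrix.

    ``median_of_ratios`` (the default) divides each sample by the median
    ratio of its counts to the per-feature geometric mean, computed over
    features expressed in every sample — robust to strong, asymmetric
    differential expression, which biases simple total-count scaling.
    ``total`` scales each sample to the geometric-mean library size.
    Returns the normalized matrix and the per-sample divisors.
    """
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise DegenerateInputError("a sample has zero total counts")
    if method == "median_of_ratios":
        arr = counts.to_numpy(dtype=float)
        everywhere = (arr > 0).all(axis=1)
        if everywhere.any():
            pos = arr[everywhere]
            ref = np.exp(np.log(pos).mean(axis=1))
            factors = np.median(pos / ref[:, None], axis=0)
            if np.all(factors > 0):
                divisors = pd.Series(factors, index=counts.columns)
                return counts / divisors, divisors
        method = "total"  # no feature expressed everywhere: fall back
    if method != "total":
        raise ParameterError(f"unknown normalization method {method!r}")
    target = float(np.exp(np.mean(np.log(lib.to_numpy(dtype=float)))))
    divisors = lib / target
    return counts / divisors, divisors


def log2_fold_change(
    mean_a: float | np.ndarray,
    mean_b: float | np.ndarray,
    pseudocount: float = 1.0,
) -> float | np.ndarray:
    """log2((mean_b + pseudocount) / (mean_a + pseudocount))."""
    if pseudocount <= 0:
        raise ParameterError("pseudocount must be > 0")
    return np.log2(
        (np.asarray(mean_b, dtype=float) + pseudocount)
        / (np.asarray(mean_a, dtype=float) + pseudocount)
    )


def relative_expression_ddct(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative quantity by the 2^-ddCt method (qPCR validation utility)."""
    for v in (ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator):
        if not np.isfinite(v):
            raise ParameterError("Ct values must be finite")
    ddct = (ct_target_sample - ct_ref_sample) - (
        ct_target_calibrator - ct_ref_calibrator
    )
    return float(2.0 ** (-ddct))


# ---------------------------------------------------------------------------
# Dispersion
# ---------------------------------------------------------------------------

def estimate_common_dispersion(
    counts: pd.DataFrame, groups: pd.Series | np.ndarray
) -> float:
    """Method-of-moments common NB dispersion on (normalized) counts.

    For each feature and group with mean ``m`` and variance ``s^2``,
    ``(s^2 - m) / m^2`` estimates the dispersion; group values are pooled
    by degrees of freedom and averaged across features, floored at zero.
    """
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 1:
        raise ParameterError("no groups given")
    for g in labels:
        if int((groups == g).sum()) < 2:
            raise ParameterError(f"group {g!r} needs >= 2 samples")
    if not (counts.to_numpy() > 0).any():
        raise DegenerateInputError("all-zero count matrix")
    phi_num = np.zeros(len(counts))
    phi_den = np.zeros(len(counts))
    for g in labels:
        sub = counts.loc[:, groups == g].to_numpy(dtype=float)
        n_g = sub.shape[1]
        m = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        ok = m > 0
        w = n_g - 1
        phi_num[ok] += w * (s2[ok] - m[ok]) / m[ok] ** 2
        phi_den[ok] += w
    valid = phi_den > 0
    if not valid.any():
        raise DegenerateInputError("no feature has positive counts in any group")
    per_feature = phi_num[valid] / phi_den[valid]
    return max(0.0, float(per_feature.mean()))


# ---------------------------------------------------------------------------
# Conditional NB exact test
# ---------------------------------------------------------------------------

def _nb_logpmf(k: np.ndarray, mean: float, phi: float) -> np.ndarray:
    """log pmf of NB with the (mean, dispersion) parameterization.

    ``phi = 0`` is the Poisson limit.
    """
    k = np.asarray(k, dtype=float)
    if phi == 0.0:
        return k * np.log(mean) - mean - gammaln(k + 1.0)
    r = 1.0 / phi
    return (
        gammaln(k + r) - gammaln(r) - gammaln(k + 1.0)
        + r * np.log(r / (r + mean))
        + k * np.log(mean / (r + mean))
    )


def nb_exact_test(
    sum_a: int, sum_b: int, n_a: int, n_b: int, phi: float
) -> float:
    """Two-sided conditional NB exact test for a two-group count split.

    ``sum_a`` / ``sum_b`` are group totals of counts already normalized to
    equal effective library sizes; ``n_a`` / ``n_b`` are replicate counts;
    ``phi`` is the common per-sample NB dispersion.  Returns the
    minimum-likelihood two-sided p-value in (0, 1]; ``t = 0`` gives 1 by
    convention (the split carries no information).
    """
    if sum_a < 0 or sum_b < 0:
        raise ParameterError("group sums must be >= 0")
    if n_a < 1 or n_b < 1:
        raise ParameterError("replicate counts must be >= 1")
    if phi < 0:
        raise ParameterError("dispersion must be >= 0")
    sum_a, sum_b = int(round(sum_a)), int(round(sum_b))
    t = sum_a + sum_b
    if t == 0:
        return 1.0
    mu = t / (n_a + n_b)
    support = np.arange(t + 1)
    logp = _nb_logpmf(support, n_a * mu, phi / n_a) + _nb_logpmf(
        support[::-1], n_b * mu, phi / n_b
    )
    logp -= logsumexp(logp)
    observed = logp[sum_a]
    keep = logp <= observed + _MINLIKE_TOL
    p = float(np.exp(logsumexp(logp[keep])))
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# Calling
# ---------------------------------------------------------------------------

def call_de(
    results: pd.DataFrame,
    lfc_threshold: float = 0.26,
    p_threshold: float = 0.05,
    lfc_strict: bool = False,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Flag significant features and tally up/down counts.

    ``significant`` requires ``p < p_threshold`` and ``|log2FC| >=
    lfc_threshold`` (strictly greater when ``lfc_strict``).  Direction
    follows the sign of the fold change.
    """
    if lfc_threshold < 0 or p_threshold <= 0:
        raise ParameterError("thresholds must be positive")
    out = results.copy()
    lfc = out["log2_fc"].to_numpy(dtype=float)
    pv = out["p_value"].to_numpy(dtype=float)
    if lfc_strict:
        passes_lfc = np.abs(lfc) > lfc_threshold
    else:
        passes_lfc = np.abs(lfc) >= lfc_threshold
    sig = (pv < p_threshold) & passes_lfc
    direction = np.where(lfc > 0, "up", np.where(lfc < 0, "down", "none"))
    out["direction"] = direction
    out["significant"] = sig
    n_up = int(((direction == "up") & sig).sum())
    n_down = int(((direction == "down") & sig).sum())
    return out, {"up": n_up, "down": n_down, "total": n_up + n_down}


def de_table(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    tissue: str | None = None,
    thresholds: Thresholds | None = None,
    pseudocount: float = 1.0,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Full two-group DE screen on a count matrix.

    Samples are selected by condition (optionally within one tissue),
    normalized to a common library size, a common dispersion is estimated
    unless given, and each feature gets a conditional NB exact p-value and
    a pseudocounted log2 fold change (condition_b over condition_a).
    """
    thresholds = thresholds or Thresholds()
    meta = samples
    if tissue is not None:
        meta = meta[meta["tissue"] == tissue]
    sel_a = meta.loc[meta["condition"] == condition_a, "sample_id"].tolist()
    sel_b = meta.loc[meta["condition"] == condition_b, "sample_id"].tolist()
    if not sel_a or not sel_b:
        raise ParameterError(
            f"no samples for contrast {condition_b} vs {condition_a}"
            + (f" in tissue {tissue}" if tissue else "")
        )
    missing = [s for s in sel_a + sel_b if s not in counts.columns]
    if missing:
        raise AlignmentError(f"samples missing from count matrix: {missing[:5]}")
    sub = counts[sel_a + sel_b]
    norm, _ = normalize_counts(sub)
    group = np.array(["a"] * len(sel_a) + ["b"] * len(sel_b))
    if dispersion is None:
        dispersion = estimate_common_dispersion(norm, group)
    mean_a = norm[sel_a].mean(axis=1)
    mean_b = norm[sel_b].mean(axis=1)
    sums_a = norm[sel_a].sum(axis=1).round().astype(int)
    sums_b = norm[sel_b].sum(axis=1).round().astype(int)
    pvals = np.array(
        [
            nb_exact_test(a, b, len(sel_a), len(sel_b), dispersion)
            for a, b in zip(sums_a, sums_b)
        ]
    )
    table = pd.DataFrame(
        {
            "feature_id": counts.index,
            "base_mean_a": mean_a.to_numpy(),
            "base_mean_b": mean_b.to_numpy(),
            "log2_fc": log2_fold_change(
                mean_a.to_numpy(), mean_b.to_numpy(), pseudocount
            ),
            "p_value": pvals,
        }
    )
    table, _ = call_de(
        table,
        lfc_threshold=thresholds.lfc,
        p_threshold=thresholds.de_p,
        lfc_strict=thresholds.lfc_strict,
    )
    table.attrs["dispersion"] = float(dispersion)
    table.attrs["contrast"] = f"{condition_b}_vs_{condition_a}"
    return table


def significant_ids(table: pd.DataFrame) -> set[str]:
    return set(table.loc[table["significant"], "feature_id"])


def direction_map(table: pd.DataFrame) -> dict[str, str]:
    """feature -> up/down for significant features (used for network nodes)."""
    sig = table[table["significant"]]
    return dict(zip(sig["feature_id"], sig["direction"]))
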