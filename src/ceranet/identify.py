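"""lncRNA nomination: structural filter, 4-tool consensus, novelty, summary.

A transcript is nominated as a lncRNA when it has at least two exons, a
mature length above 200 bp, and all four coding-potential tools (CNCI,
CPC2, CPAT, PFAM) call it noncoding.  "Length" here is the mature
transcript length — the sum of exon lengths — which is how assembly tools
report lncRNA length; the genomic span plays no role in the filter.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import CODING_TOOLS
from .errors import EmptyClassError, IncompleteCallsError
from .types import TranscriptRecord


def structural_filter(
    transcripts: Sequence[TranscriptRecord],
    min_exons: int = 2,
    min_length: int = 200,
) -> list[TranscriptRecord]:
    """Keep transcripts with >= ``min_exons`` exons and length strictly
    greater than ``min_length`` bp.  Order is preserved; idempotent."""
    return [
        t for t in transcripts
        if t.n_exons >= min_exons and t.length > min_length
    ]


def calls_by_transcript(calls: pd.DataFrame) -> dict[str, dict[str, str]]:
    """Pivot a tidy (transcript_id, tool, verdict) table to nested dicts."""
    out: dict[str, dict[str, str]] = {}
    for tid, tool, verdict in calls[["transcript_id", "tool", "verdict"]].itertuples(index=False):
        out.setdefault(tid, {})[tool] = verdict
    return out


def consensus_noncoding(
    candidates: Iterable[str | TranscriptRecord],
    calls: pd.DataFrame | Mapping[str, Mapping[str, str]],
) -> list[str]:
    """Candidates that every one of the four tools calls noncoding.

    Raises :class:`IncompleteCallsError` if any candidate lacks a verdict
    from any tool.  Order of ``candidates`` is preserved.
    """
    if isinstance(calls, pd.DataFrame):
        calls = calls_by_transcript(calls)
    kept = []
    for c in candidates:
        tid = c.transcript_id if isinstance(c, TranscriptRecord) else c
        verdicts = calls.get(tid)
        if verdicts is None or any(tool not in verdicts for tool in CODING_TOOLS):
            raise IncompleteCallsError(
                f"transcript {tid} is missing coding-potential verdicts"
            )
        if all(verdicts[tool] == "noncoding" for tool in CODING_TOOLS):
            kept.append(tid)
    return kept


def classify_novelty(
    lncrna_ids: Iterable[str], reference_lncrna_ids: Iterable[str]
) -> pd.Series:
    """Label each id ``known`` if present in the reference, else ``novel``."""
    ref = set(reference_lncrna_ids)
    ids = list(lncrna_ids)
    return pd.Series(
        ["known" if i in ref else "novel" for i in ids], index=ids, name="novelty"
    )


def apply_novelty(
    transcripts: Sequence[TranscriptRecord], known_ids: Iterable[str]
) -> list[TranscriptRecord]:
    """Relabel lncRNA records as ``lncRNA_known`` / ``lncRNA_novel``."""
    known = set(known_ids)
    out = []
    for t in transcripts:
        if t.biotype.startswith("lncRNA"):
            label = "lncRNA_known" if t.transcript_id in known else "lncRNA_novel"
            out.append(t.with_biotype(label))
        else:
            out.append(t)
    return out


def summarize_features(
    transcripts: Sequence[TranscriptRecord],
    expression: pd.DataFrame | None = None,
    classes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-class genomic characteristics.

    One row per biotype present in the input: transcript count, mean mature
    length (bp), mean exon count, mean and total ORF length (nt), and — when
    an FPKM matrix is supplied — quartiles of log1p(FPKM) over all features
    of the class and all samples.  Requesting a class with no members via
    ``classes`` raises :class:`EmptyClassError`.
    """
    present: dict[str, list[TranscriptRecord]] = {}
    for t in transcripts:
        present.setdefault(t.biotype, []).append(t)
    if classes is not None:
        missing = [c for c in classes if c not in present]
        if missing:
            raise EmptyClassError(f"no transcripts in class(es): {', '.join(missing)}")
        wanted = list(classes)
    else:
        wanted = sorted(present)
    rows = []
    for cls in wanted:
        recs = present[cls]
        row = {
            "biotype": cls,
            "n": len(recs),
            "mean_length": float(np.mean([r.length for r in recs])),
            "mean_exons": float(np.mean([r.n_exons for r in recs])),
            "mean_orf_length": float(np.mean([r.orf_length for r in recs])),
            "total_orf_length": int(sum(r.orf_length for r in recs)),
        }
        if expression is not None:
            ids = [r.transcript_id for r in recs if r.transcript_id in expression.index]
            if ids:
                vals = np.log1p(expression.loc[ids].to_numpy(dtype=float)).ravel()
                q1, q2, q3 = np.percentile(vals, [25, 50, 75])
                row.update(
                    log_expr_q25=float(q1),
                    log_expr_median=float(q2),
                    log_expr_q75=float(q3),
                )
            else:
                row.update(
                    log_expr_q25=np.nan, log_expr_median=np.nan, log_expr_q75=np.nan
                )
        rows.append(row)
    return pd.DataFrame(rows)


def identify_lncrnas(
    transcripts: Sequence[TranscriptRecord],
    calls: pd.DataFrame | Mapping[str, Mapping[str, str]],
    min_exons: int = 2,
    min_length: int = 200,
) -> list[str]:
    """Full nomination: structural filter then 4-tool noncoding consensus."""
    candidates = structural_filter(transcripts, min_exons, min_length)
    return consensus_noncoding(candidates, calls)
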