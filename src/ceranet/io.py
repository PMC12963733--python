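"""Readers and writers for the plain-text formats the pipeline exchanges.

Annotations travel as GTF (1-based, inclusive; ``transcript`` and ``exon``
features carrying ``gene_id``, ``transcript_id`` and ``gene_biotype``).
Everything else is TSV.  All writers are deterministic: given identical
in-memory objects they produce byte-identical files.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd

from .types import TranscriptRecord

_GTF_SOURCE = "ceranet"


def write_gtf(records: Sequence[TranscriptRecord], path: str | Path) -> None:
    """Write transcripts and their exons as GTF."""
    with open(path, "w") as fh:
        for r in records:
            attrs = (
                f'gene_id "{r.gene_id}"; transcript_id "{r.transcript_id}"; '
                f'gene_biotype "{r.biotype}"; orf_length "{r.orf_length}";'
            )
            fh.write(
                f"{r.chromosome}\t{_GTF_SOURCE}\ttranscript\t{r.start}\t{r.end}"
                f"\t.\t{r.strand}\t.\t{attrs}\n"
            )
            for s, e in r.exons:
                fh.write(
                    f"{r.chromosome}\t{_GTF_SOURCE}\texon\t{s}\t{e}"
                    f"\t.\t{r.strand}\t.\t"
                    f'gene_id "{r.gene_id}"; transcript_id "{r.transcript_id}";\n'
                )


def read_gtf(path: str | Path) -> list[TranscriptRecord]:
    """Parse a GTF into transcript records (via gffutils)."""
    db = gffutils.create_db(
        str(path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )
    records = []
    for t in db.features_of_type("transcript"):
        exons = tuple(
            (e.start, e.end)
            for e in db.children(t, featuretype="exon", order_by="start")
        )
        attrs = t.attributes
        records.append(
            TranscriptRecord(
                transcript_id=attrs["transcript_id"][0],
                gene_id=attrs["gene_id"][0],
                chromosome=t.seqid,
                strand=t.strand,
                start=t.start,
                end=t.end,
                exons=exons,
                biotype=attrs.get("gene_biotype", ["candidate"])[0],
                orf_length=int(attrs.get("orf_length", ["0"])[0]),
            )
        )
    return records


def write_matrix(matrix: pd.DataFrame, path: str | Path, index_name: str = "feature_id") -> None:
    out = matrix.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_id_list(ids: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i in ids:
            fh.write(f"{i}\n")


def read_id_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_term_map(path: str | Path) -> pd.DataFrame:
    """Read a term->gene map: 2-column TSV or GMT-dialect lines.

    GMT lines are ``term<TAB>description<TAB>gene1<TAB>gene2...``; the
    detection rule is simply whether the first data line has more than two
    columns.
    """
    with open(path) as fh:
        first = fh.readline()
    n_cols = len(first.rstrip("\n").split("\t"))
    if n_cols <= 2:
        df = pd.read_csv(path, sep="\t")
        if list(df.columns[:2]) != ["term_id", "gene_id"]:
            df.columns = ["term_id", "gene_id"] + list(df.columns[2:])
        return df[["term_id", "gene_id"]]
    rows = []
    with open(fh.name if hasattr(fh, "name") else path) as fh2:
        for line in fh2:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            term = parts[0]
            for gene in parts[2:]:
                if gene:
                    rows.append({"term_id": term, "gene_id": gene})
    return pd.DataFrame(rows, columns=["term_id", "gene_id"])


def atomic_write_text(text: str, path: str | Path) -> None:
    """Write text to ``path`` atomically (write to temp file, then rename)."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name)
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
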