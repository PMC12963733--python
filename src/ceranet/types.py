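"""Core record types shared across modules.

Expression matrices are plain :class:`pandas.DataFrame` objects (features in
rows, samples in columns) accompanied by a sample metadata frame with
columns ``sample_id``, ``tissue``, ``condition``, ``replicate``.  The richer
records below carry the genomic structure that frames cannot.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import ParameterError


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript with its genomic span and exon structure.

    Coordinates are 1-based and inclusive, as in GTF.  ``orf_length`` is in
    nucleotides.  ``biotype`` is one of ``mRNA``, ``lncRNA``,
    ``lncRNA_known``, ``lncRNA_novel`` or ``candidate``.
    """

    transcript_id: str
    gene_id: str
    chromosome: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    biotype: str
    orf_length: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ParameterError(
                f"{self.transcript_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ParameterError(f"{self.transcript_id}: bad strand {self.strand!r}")
        prev_end = None
        for s, e in self.exons:
            if s > e or s < self.start or e > self.end:
                raise ParameterError(
                    f"{self.transcript_id}: exon ({s}, {e}) outside span"
                )
            if prev_end is not None and s <= prev_end:
                raise ParameterError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = e
        if not self.exons:
            raise ParameterError(f"{self.transcript_id}: no exons")

    @property
    def length(self) -> int:
        """Mature transcript length: sum of exon lengths."""
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def with_biotype(self, biotype: str) -> "TranscriptRecord":
        return TranscriptRecord(
            self.transcript_id, self.gene_id, self.chromosome, self.strand,
            self.start, self.end, self.exons, biotype, self.orf_length,
        )


def records_to_frame(records: Iterable[TranscriptRecord]) -> pd.DataFrame:
    """Flatten transcript records to a span table (one row per transcript)."""
    rows = [
        {
            "transcript_id": r.transcript_id,
            "gene_id": r.gene_id,
            "chromosome": r.chromosome,
            "strand": r.strand,
            "start": r.start,
            "end": r.end,
            "length": r.length,
            "n_exons": r.n_exons,
            "biotype": r.biotype,
            "orf_length": r.orf_length,
        }
        for r in records
    ]
    cols = [
        "transcript_id", "gene_id", "chromosome", "strand", "start", "end",
        "length", "n_exons", "biotype", "orf_length",
    ]
    return pd.DataFrame(rows, columns=cols)


@dataclass(frozen=True)
class PlantedTriad:
    """Ground-truth ceRNA triple planted by the simulator."""

    lncrna_id: str
    mirna_id: str
    mrna_id: str
    latent_loading: float

    def as_tuple(self) -> tuple[str, str, str]:
        return (self.lncrna_id, self.mirna_id, self.mrna_id)


def triads_to_frame(triads: Sequence[PlantedTriad]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lncrna_id": t.lncrna_id,
                "mirna_id": t.mirna_id,
                "mrna_id": t.mrna_id,
                "latent_loading": t.latent_loading,
            }
            for t in triads
        ],
        columns=["lncrna_id", "mirna_id", "mrna_id", "latent_loading"],
    )
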