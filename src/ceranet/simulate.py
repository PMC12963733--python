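"""Synthetic HPG-axis RNA-seq study with planted ceRNA signal.

The generator emulates the statistical structure that the downstream screen
assumes, so that every stage of the pipeline can be exercised and scored
against known truth without any sequencing data:

* an annotation of mRNA and lncRNA transcripts placed on synthetic
  chromosomes (GTF-compatible spans and exon chains);
* negative-binomial count matrices for mRNA, lncRNA and miRNA over
  2 conditions x 3 tissues x ``n_replicates_per_condition`` samples;
* planted (lncRNA, miRNA, mRNA) triads coupled through one latent factor
  per triad: per sample ``s`` the triad's latent ``z_s ~ N(0, 1)`` enters
  the log-mean of the lncRNA and mRNA with loading ``+beta`` and of the
  miRNA with loading ``-beta``, which forces the sign structure the ceRNA
  correlation screen tests (positive lncRNA-mRNA, negative miRNA-target);
* a condition effect of ``+-delta/2`` log2 units on each differentially
  expressed feature (all triad members, plus a random background subset),
  applied to the log-mean so that DE truth and coupling truth are
  independent knobs;
* noisy coding/noncoding votes from four named tools;
* miRNA-target interaction tables containing every planted link, a set of
  shared "support" miRNAs per planted pair (real ceRNA pairs share several
  miRNA response elements, which is exactly what the hypergeometric
  shared-miRNA test detects), and independent background links.

Counts follow NB(mean, phi) with variance ``mean + phi * mean**2``;
``phi = 0`` degenerates to Poisson.  All randomness flows from
``config.seed`` through fixed per-stage child streams (see
:mod:`ceranet.config`), so identical configurations give identical output
field for field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io
from .config import CONDITIONS, TISSUES, CODING_TOOLS, SimConfig, stage_rng
from .errors import AlignmentError, ParameterError, SizingError
from .types import PlantedTriad, TranscriptRecord, records_to_frame, triads_to_frame

_LN2 = math.log(2.0)


def mirna_ids(config: SimConfig) -> list[str]:
    """miRNA identifiers (miRNAs have no genomic annotation here)."""
    return [f"MIR{i:04d}" for i in range(config.n_mirna)]


def support_pool_ids(config: SimConfig) -> list[str]:
    """miRNAs reserved as shared-support candidates (never DE, never triad)."""
    return mirna_ids(config)[config.n_mirna - config.n_support_mirna_pool:]


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def generate_annotation(
    config: SimConfig,
) -> tuple[list[TranscriptRecord], pd.DataFrame]:
    """Place mRNA and lncRNA transcripts on synthetic chromosomes.

    Returns the transcript records and a chromosome size table.  Exon
    chains are disjoint, sorted, and contained in the transcript span; the
    mature length (sum of exon lengths) equals the drawn transcript length.
    """
    config.validate()
    rng = stage_rng(config.seed, "annotation")
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    sizes = pd.DataFrame(
        {"chromosome": chroms, "length": config.chromosome_length}
    )
    records: list[TranscriptRecord] = []
    specs = [
        ("MRNA", "mRNA", config.n_mrna, config.mrna_length_range,
         config.mrna_exon_range),
        ("LNC", "lncRNA", config.n_lncrna, config.lncrna_length_range,
         config.lncrna_exon_range),
    ]
    for prefix, biotype, n, length_range, exon_range in specs:
        for i in range(n):
            tid = f"{prefix}{i:04d}"
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            n_exons = int(rng.integers(exon_range[0], exon_range[1] + 1))
            exon_lens = _partition_length(rng, length, n_exons, config.min_exon_length)
            introns = (
                rng.integers(100, 5001, size=n_exons - 1)
                if n_exons > 1 else np.array([], dtype=int)
            )
            span = length + int(introns.sum())
            if span >= config.chromosome_length:
                raise SizingError(
                    f"{tid}: span {span} bp does not fit on a "
                    f"{config.chromosome_length} bp chromosome"
                )
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(1, config.chromosome_length - span + 1))
            exons = []
            pos = start
            for j, el in enumerate(exon_lens):
                exons.append((pos, pos + int(el) - 1))
                if j < n_exons - 1:
                    pos += int(el) + int(introns[j])
            strand = "+" if rng.random() < 0.5 else "-"
            if biotype == "mRNA":
                orf = int(rng.integers(
                    max(30, int(0.3 * length)), max(31, int(0.8 * length))
                ))
            else:
                # lncRNA open reading frames stay short (< 300 nt)
                orf = int(rng.integers(30, min(291, max(31, length // 3))))
            records.append(
                TranscriptRecord(
                    transcript_id=tid,
                    gene_id=f"{tid}.g",
                    chromosome=chrom,
                    strand=strand,
                    start=start,
                    end=exons[-1][1],
                    exons=tuple(exons),
                    biotype=biotype,
                    orf_length=orf,
                )
            )
    return records, sizes


def _partition_length(
    rng: np.random.Generator, length: int, n_exons: int, min_exon: int
) -> np.ndarray:
    """Split ``length`` into ``n_exons`` parts, each >= ``min_exon``."""
    if length < n_exons * min_exon:
        raise SizingError(
            f"length {length} cannot host {n_exons} exons of >= {min_exon} bp"
        )
    extra = rng.multinomial(length - n_exons * min_exon, [1.0 / n_exons] * n_exons)
    return extra + min_exon


# ---------------------------------------------------------------------------
# Planted truth
# ---------------------------------------------------------------------------

def plant_triads(config: SimConfig) -> list[PlantedTriad]:
    """Choose the planted (lncRNA, miRNA, mRNA) triples.

    Each feature belongs to at most one triad; miRNAs from the support
    reservoir are never triad members.
    """
    config.validate()
    rng = stage_rng(config.seed, "truth")
    n = config.n_planted_triads
    lnc = [f"LNC{i:04d}" for i in rng.choice(config.n_lncrna, n, replace=False)]
    avail_mirna = config.n_mirna - config.n_support_mirna_pool
    mir = [f"MIR{i:04d}" for i in rng.choice(avail_mirna, n, replace=False)]
    mr = [f"MRNA{i:04d}" for i in rng.choice(config.n_mrna, n, replace=False)]
    return [
        PlantedTriad(lnc[i], mir[i], mr[i], config.coupling_beta)
        for i in range(n)
    ]


def build_samples(config: SimConfig) -> pd.DataFrame:
    """Sample sheet: tissues x conditions x replicates, in fixed order."""
    rows = []
    for tissue in TISSUES:
        for condition in CONDITIONS:
            for rep in range(1, config.n_replicates_per_condition + 1):
                rows.append(
                    {
                        "sample_id": f"{tissue}_{condition}_{rep:02d}",
                        "tissue": tissue,
                        "condition": condition,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class ExpressionTruth:
    """Ground truth emitted alongside the count matrices."""

    de_truth: pd.DataFrame  # feature_id, feature_class, is_de, direction
    triad_directions: dict[str, int] = field(default_factory=dict)

    def de_ids(self, feature_class: str | None = None) -> set[str]:
        df = self.de_truth
        if feature_class is not None:
            df = df[df["feature_class"] == feature_class]
        return set(df.loc[df["is_de"], "feature_id"])


def generate_expression(
    annotation: Sequence[TranscriptRecord],
    config: SimConfig,
    triads: Sequence[PlantedTriad],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, ExpressionTruth]:
    """Draw NB count matrices with planted coupling and condition effects.

    Returns ``(mrna_counts, lncrna_counts, mirna_counts, samples, truth)``.
    Matrices are features x samples; the sample sheet carries tissue,
    condition and replicate.  The condition effect is ``direction * delta``
    log2 units (brooding over laying), applied half to each condition so
    the grand mean is unchanged.
    """
    config.validate()
    if config.nb_dispersion_phi < 0:
        raise ParameterError("nb_dispersion_phi must be >= 0")
    ids = {
        "mrna": [r.transcript_id for r in annotation if r.biotype == "mRNA"],
        "lncrna": [r.transcript_id for r in annotation if r.biotype.startswith("lncRNA")],
        "mirna": mirna_ids(config),
    }
    _check_triads(triads, ids)
    samples = build_samples(config)
    n_samples = len(samples)
    cond_sign = np.where(samples["condition"].values == CONDITIONS[1], 0.5, -0.5)

    # --- differential-expression truth -----------------------------------
    rng_de = stage_rng(config.seed, "de_truth")
    triad_dirs = rng_de.choice([-1, 1], size=len(triads))
    de_dir: dict[str, int] = {}
    for t, d in zip(triads, triad_dirs):
        de_dir[t.lncrna_id] = int(d)
        de_dir[t.mrna_id] = int(d)
        de_dir[t.mirna_id] = -int(d)  # miRNA moves opposite its targets
    pool = set(support_pool_ids(config))
    for cls in ("mrna", "lncrna", "mirna"):
        candidates = [f for f in ids[cls] if f not in de_dir and f not in pool]
        k = int(round(config.background_de_fraction * len(candidates)))
        if k > 0:
            chosen = rng_de.choice(len(candidates), size=k, replace=False)
            dirs = rng_de.choice([-1, 1], size=k)
            for j, d in zip(chosen, dirs):
                de_dir[candidates[j]] = int(d)

    # --- count model -------------------------------------------------------
    rng = stage_rng(config.seed, "expression")
    z = rng.standard_normal((len(triads), n_samples))
    lo, hi = config.baseline_log_mean_range
    delta_e = config.condition_shift_delta * _LN2
    matrices: dict[str, pd.DataFrame] = {}
    triad_row = {
        "mrna": {t.mrna_id: i for i, t in enumerate(triads)},
        "lncrna": {t.lncrna_id: i for i, t in enumerate(triads)},
        "mirna": {t.mirna_id: i for i, t in enumerate(triads)},
    }
    loading_sign = {"mrna": 1.0, "lncrna": 1.0, "mirna": -1.0}
    for cls in ("mrna", "lncrna", "mirna"):
        feats = ids[cls]
        baseline = rng.uniform(lo, hi, size=len(feats))
        log_mean = np.tile(baseline[:, None], (1, n_samples))
        for row, fid in enumerate(feats):
            ti = triad_row[cls].get(fid)
            if ti is not None:
                beta = triads[ti].latent_loading
                log_mean[row] += loading_sign[cls] * beta * z[ti]
            d = de_dir.get(fid, 0)
            if d:
                log_mean[row] += d * delta_e * cond_sign
        mean = np.exp(log_mean)
        if config.nb_dispersion_phi == 0:
            counts = rng.poisson(mean)
        else:
            shape = 1.0 / config.nb_dispersion_phi
            lam = rng.gamma(shape, config.nb_dispersion_phi * mean)
            counts = rng.poisson(lam)
        matrices[cls] = pd.DataFrame(
            counts, index=feats, columns=samples["sample_id"].tolist()
        )

    de_rows = []
    for cls in ("mrna", "lncrna", "mirna"):
        for fid in ids[cls]:
            d = de_dir.get(fid, 0)
            de_rows.append(
                {
                    "feature_id": fid,
                    "feature_class": cls,
                    "is_de": d != 0,
                    "direction": d,
                }
            )
    truth = ExpressionTruth(
        de_truth=pd.DataFrame(de_rows),
        triad_directions={t.lncrna_id: int(d) for t, d in zip(triads, triad_dirs)},
    )
    return matrices["mrna"], matrices["lncrna"], matrices["mirna"], samples, truth


def _check_triads(triads: Sequence[PlantedTriad], ids: dict[str, list[str]]) -> None:
    lnc, mir, mr = set(ids["lncrna"]), set(ids["mirna"]), set(ids["mrna"])
    seen: set[str] = set()
    for t in triads:
        if t.lncrna_id not in lnc or t.mirna_id not in mir or t.mrna_id not in mr:
            raise AlignmentError(f"triad {t.as_tuple()} references unknown features")
        for fid in t.as_tuple():
            if fid in seen:
                raise ParameterError(f"feature {fid} belongs to more than one triad")
            seen.add(fid)


# ---------------------------------------------------------------------------
# Coding-potential votes
# ---------------------------------------------------------------------------

def generate_coding_calls(
    annotation: Sequence[TranscriptRecord], config: SimConfig
) -> pd.DataFrame:
    """Per-transcript verdicts from the four coding-potential tools.

    Each verdict equals the true biotype with probability ``1 - flip_rate``
    and is flipped otherwise, independently per transcript and tool.
    """
    rate = config.coding_call_flip_rate
    if not 0.0 <= rate <= 1.0:
        raise ParameterError("coding_call_flip_rate must be in [0, 1]")
    rng = stage_rng(config.seed, "coding_calls")
    flips = rng.random((len(annotation), len(CODING_TOOLS))) < rate
    rows = []
    for i, rec in enumerate(annotation):
        truth_coding = rec.biotype == "mRNA"
        for j, tool in enumerate(CODING_TOOLS):
            coding = truth_coding ^ bool(flips[i, j])
            rows.append(
                {
                    "transcript_id": rec.transcript_id,
                    "tool": tool,
                    "verdict": "coding" if coding else "noncoding",
                }
            )
    return pd.DataFrame(rows, columns=["transcript_id", "tool", "verdict"])


# ---------------------------------------------------------------------------
# Interaction tables
# ---------------------------------------------------------------------------

def generate_interactions(
    annotation: Sequence[TranscriptRecord],
    triads: Sequence[PlantedTriad],
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """miRNA->lncRNA and miRNA->mRNA link tables.

    Every planted triad contributes its two links plus links from
    ``n_support_mirnas`` reservoir miRNAs to *both* pair members; each
    remaining (miRNA, target) pair is included independently with
    ``background_interaction_rate``.
    """
    config.validate()
    rng = stage_rng(config.seed, "interactions")
    mirs = mirna_ids(config)
    lnc_ids = [r.transcript_id for r in annotation if r.biotype.startswith("lncRNA")]
    mrna_ids_ = [r.transcript_id for r in annotation if r.biotype == "mRNA"]
    rate = config.background_interaction_rate

    lnc_links: set[tuple[str, str]] = set()
    mrna_links: set[tuple[str, str]] = set()
    bg_lnc = rng.random((len(mirs), len(lnc_ids))) < rate
    bg_mrna = rng.random((len(mirs), len(mrna_ids_))) < rate
    for i, j in zip(*np.nonzero(bg_lnc)):
        lnc_links.add((mirs[i], lnc_ids[j]))
    for i, j in zip(*np.nonzero(bg_mrna)):
        mrna_links.add((mirs[i], mrna_ids_[j]))

    pool = support_pool_ids(config)
    for t in triads:
        lnc_links.add((t.mirna_id, t.lncrna_id))
        mrna_links.add((t.mirna_id, t.mrna_id))
        if config.n_support_mirnas > 0 and pool:
            chosen = rng.choice(len(pool), size=config.n_support_mirnas, replace=False)
            for c in chosen:
                lnc_links.add((pool[c], t.lncrna_id))
                mrna_links.add((pool[c], t.mrna_id))

    def _frame(links: set[tuple[str, str]]) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(links), columns=["mirna_id", "target_id"]
        )

    return _frame(lnc_links), _frame(mrna_links)


# ---------------------------------------------------------------------------
# Annotation terms and the known-lncRNA reference
# ---------------------------------------------------------------------------

def generate_term_map(
    annotation: Sequence[TranscriptRecord], config: SimConfig
) -> pd.DataFrame:
    """Random term->gene map over the mRNA ids (for enrichment testing)."""
    rng = stage_rng(config.seed, "terms")
    mrna = [r.transcript_id for r in annotation if r.biotype == "mRNA"]
    lo, hi = config.term_size_range
    rows = []
    for i in range(config.n_terms):
        size = int(rng.integers(lo, min(hi, len(mrna)) + 1))
        genes = rng.choice(len(mrna), size=size, replace=False)
        term = f"TERM{i:03d}"
        for g in sorted(genes):
            rows.append({"term_id": term, "gene_id": mrna[g]})
    return pd.DataFrame(rows, columns=["term_id", "gene_id"])


def select_known_lncrnas(
    annotation: Sequence[TranscriptRecord], config: SimConfig
) -> list[str]:
    """Reference list splitting true lncRNAs into known vs novel."""
    rng = stage_rng(config.seed, "known")
    lnc = [r.transcript_id for r in annotation if r.biotype.startswith("lncRNA")]
    k = int(round(config.known_lncrna_fraction * len(lnc)))
    if k == 0:
        return []
    chosen = rng.choice(len(lnc), size=k, replace=False)
    return [lnc[i] for i in sorted(chosen)]


# ---------------------------------------------------------------------------
# Bundled dataset
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """Everything one simulated study produces, in memory."""

    config: SimConfig
    annotation: list[TranscriptRecord]
    chrom_sizes: pd.DataFrame
    triads: list[PlantedTriad]
    mrna_counts: pd.DataFrame
    lncrna_counts: pd.DataFrame
    mirna_counts: pd.DataFrame
    samples: pd.DataFrame
    truth: ExpressionTruth
    coding_calls: pd.DataFrame
    mirna_lncrna: pd.DataFrame
    mirna_mrna: pd.DataFrame
    term_map: pd.DataFrame
    known_lncrna_ids: list[str]

    @property
    def true_lncrna_ids(self) -> set[str]:
        return {
            r.transcript_id
            for r in self.annotation
            if r.biotype.startswith("lncRNA")
        }

    def counts(self, feature_class: str) -> pd.DataFrame:
        return {
            "mrna": self.mrna_counts,
            "lncrna": self.lncrna_counts,
            "mirna": self.mirna_counts,
        }[feature_class]

    def transcript_lengths(self) -> pd.Series:
        return pd.Series(
            {r.transcript_id: r.length for r in self.annotation}, name="length"
        )

    def write(self, outdir: str | Path) -> dict[str, int]:
        """Write every artifact as plain text; returns per-file row counts."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_gtf(self.annotation, outdir / "annotation.gtf")
        io.write_table(self.chrom_sizes, outdir / "chrom_sizes.tsv")
        io.write_matrix(self.mrna_counts, outdir / "mrna_counts.tsv")
        io.write_matrix(self.lncrna_counts, outdir / "lncrna_counts.tsv")
        io.write_matrix(self.mirna_counts, outdir / "mirna_counts.tsv")
        io.write_table(self.samples, outdir / "samples.tsv")
        io.write_table(self.coding_calls, outdir / "coding_calls.tsv")
        io.write_table(self.mirna_lncrna, outdir / "interactions_mirna_lncrna.tsv")
        io.write_table(self.mirna_mrna, outdir / "interactions_mirna_mrna.tsv")
        io.write_table(self.term_map, outdir / "term_map.tsv")
        io.write_table(triads_to_frame(self.triads), outdir / "truth_triads.tsv")
        io.write_table(self.truth.de_truth, outdir / "truth_de.tsv")
        io.write_id_list(self.known_lncrna_ids, outdir / "known_lncrna_ids.txt")
        counts = {
            "annotation.gtf": len(self.annotation),
            "chrom_sizes.tsv": len(self.chrom_sizes),
            "mrna_counts.tsv": len(self.mrna_counts),
            "lncrna_counts.tsv": len(self.lncrna_counts),
            "mirna_counts.tsv": len(self.mirna_counts),
            "samples.tsv": len(self.samples),
            "coding_calls.tsv": len(self.coding_calls),
            "interactions_mirna_lncrna.tsv": len(self.mirna_lncrna),
            "interactions_mirna_mrna.tsv": len(self.mirna_mrna),
            "term_map.tsv": len(self.term_map),
            "truth_triads.tsv": len(self.triads),
            "truth_de.tsv": len(self.truth.de_truth),
            "known_lncrna_ids.txt": len(self.known_lncrna_ids),
        }
        return counts


def generate_dataset(config: SimConfig) -> SyntheticDataset:
    """Run every generator stage in order and bundle the results."""
    annotation, chrom_sizes = generate_annotation(config)
    triads = plant_triads(config)
    mrna, lnc, mir, samples, truth = generate_expression(annotation, config, triads)
    calls = generate_coding_calls(annotation, config)
    int_lnc, int_mrna = generate_interactions(annotation, triads, config)
    terms = generate_term_map(annotation, config)
    known = select_known_lncrnas(annotation, config)
    return SyntheticDataset(
        config=config,
        annotation=annotation,
        chrom_sizes=chrom_sizes,
        triads=triads,
        mrna_counts=mrna,
        lncrna_counts=lnc,
        mirna_counts=mir,
        samples=samples,
        truth=truth,
        coding_calls=calls,
        mirna_lncrna=int_lnc,
        mirna_mrna=int_mrna,
        term_map=terms,
        known_lncrna_ids=known,
    )


def annotation_frame(dataset: SyntheticDataset) -> pd.DataFrame:
    return records_to_frame(dataset.annotation)
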