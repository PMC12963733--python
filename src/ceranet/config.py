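"""Configuration objects and the random-stream splitting scheme.

All randomness in the simulator flows from a single root seed.  Each
generator stage draws from its own child stream, obtained by spawning a
:class:`numpy.random.SeedSequence` with a fixed per-stage key, so that any
stage can be re-run in isolation and still reproduce exactly what a full
run would have produced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import yaml

from .errors import ValidationError

#: Tissues of the hypothalamus-pituitary-gonadal axis emulated by the simulator.
TISSUES: tuple[str, ...] = ("hypothalamus", "pituitary", "ovary")

#: Physiological states contrasted by the differential-expression screen.
CONDITIONS: tuple[str, str] = ("laying", "brooding")

#: Coding-potential assessment tools whose verdicts are intersected.
CODING_TOOLS: tuple[str, ...] = ("CNCI", "CPC2", "CPAT", "PFAM")

# Fixed spawn keys: one independent child stream per generator stage.
_STAGE_KEYS = {
    "annotation": 0,
    "truth": 1,        # planted triad membership
    "de_truth": 2,     # condition-effect assignment
    "expression": 3,   # latent factors and count noise
    "coding_calls": 4,
    "interactions": 5,
    "terms": 6,
    "known": 7,        # known/novel lncRNA split
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Return the child random generator for one simulator stage."""
    if stage not in _STAGE_KEYS:
        raise KeyError(f"unknown random stream {stage!r}")
    ss = np.random.SeedSequence(seed, spawn_key=(_STAGE_KEYS[stage],))
    return np.random.default_rng(ss)


@dataclass
class SimConfig:
    """Parameters of the synthetic HPG-axis RNA-seq study.

    The defaults define the benchmark conditions under which planted ceRNA
    triads are expected to be recoverable by the full screen: 50 triads
    coupled through a latent factor with loading ``coupling_beta = 1.5``,
    negative-binomial dispersion 0.1, 15 replicates per tissue and
    condition, and a 2 % background miRNA-target interaction rate.
    """

    seed: int = 1

    # Genome layout
    n_chromosomes: int = 6
    chromosome_length: int = 10_000_000

    # Feature counts per class
    n_mrna: int = 300
    n_lncrna: int = 100
    n_mirna: int = 80

    # Study design: samples = tissues x conditions x replicates
    n_replicates_per_condition: int = 15

    # Planted ceRNA signal
    n_planted_triads: int = 50
    coupling_beta: float = 1.5
    #: Extra miRNAs linked to both members of each planted lncRNA-mRNA pair,
    #: emulating the multiple shared binding sites that the hypergeometric
    #: shared-miRNA test is designed to detect.
    n_support_mirnas: int = 3
    #: Number of miRNAs (taken from the end of the id range) reserved as the
    #: pool from which support miRNAs are drawn; pool members never receive a
    #: condition effect and never belong to a planted triad.
    n_support_mirna_pool: int = 12

    # Condition effect (differential expression truth)
    condition_shift_delta: float = 4.0  # log2 units, brooding over laying
    background_de_fraction: float = 0.2

    # Count model
    nb_dispersion_phi: float = 0.1
    baseline_log_mean_range: tuple[float, float] = (3.0, 5.5)  # natural log

    # Interaction tables and coding-potential votes
    background_interaction_rate: float = 0.02
    coding_call_flip_rate: float = 0.0

    # Transcript structure
    lncrna_length_range: tuple[int, int] = (300, 5_000)
    mrna_length_range: tuple[int, int] = (500, 8_000)
    lncrna_exon_range: tuple[int, int] = (2, 6)
    mrna_exon_range: tuple[int, int] = (4, 15)

    # Known/novel split and synthetic annotation terms
    known_lncrna_fraction: float = 0.65
    n_terms: int = 40
    term_size_range: tuple[int, int] = (10, 40)

    #: Minimum exon length used when partitioning a transcript into exons.
    min_exon_length: int = 30

    def validate(self) -> None:
        """Raise :class:`ValidationError` listing every invalid field."""
        bad: list[str] = []
        for name in (
            "n_chromosomes", "chromosome_length", "n_replicates_per_condition",
        ):
            if getattr(self, name) < 1:
                bad.append(f"{name} must be >= 1")
        for name in (
            "n_mrna", "n_lncrna", "n_mirna", "n_planted_triads",
            "n_support_mirnas", "n_support_mirna_pool", "n_terms",
        ):
            if getattr(self, name) < 0:
                bad.append(f"{name} must be >= 0")
        for name in (
            "background_interaction_rate", "coding_call_flip_rate",
            "background_de_fraction", "known_lncrna_fraction",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                bad.append(f"{name} must be in [0, 1]")
        if self.nb_dispersion_phi < 0:
            bad.append("nb_dispersion_phi must be >= 0")
        if self.n_planted_triads > 0:
            avail_mirna = self.n_mirna - self.n_support_mirna_pool
            if self.n_planted_triads > min(self.n_lncrna, avail_mirna, self.n_mrna):
                bad.append(
                    "n_planted_triads exceeds available features "
                    "(miRNA pool excludes the support reservoir)"
                )
        if self.n_support_mirnas > self.n_support_mirna_pool:
            bad.append("n_support_mirnas must be <= n_support_mirna_pool")
        for name in (
            "baseline_log_mean_range", "lncrna_length_range",
            "mrna_length_range", "lncrna_exon_range", "mrna_exon_range",
            "term_size_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                bad.append(f"{name} must be an increasing pair")
        for cls, lr, er in (
            ("lncrna", self.lncrna_length_range, self.lncrna_exon_range),
            ("mrna", self.mrna_length_range, self.mrna_exon_range),
        ):
            if er[0] < 1:
                bad.append(f"{cls}_exon_range must start at >= 1")
            if lr[0] < er[1] * self.min_exon_length:
                bad.append(
                    f"{cls}_length_range[0] too short for {er[1]} exons of "
                    f">= {self.min_exon_length} bp"
                )
        if bad:
            raise ValidationError("; ".join(bad))

    def n_samples(self) -> int:
        return len(TISSUES) * len(CONDITIONS) * self.n_replicates_per_condition

    @classmethod
    def study_scale(cls, **overrides: Any) -> "SimConfig":
        """Preset matching the sequenced study design: 3 replicates per
        tissue and condition (18 samples in total)."""
        overrides.setdefault("n_replicates_per_condition", 3)
        return cls(**overrides)


@dataclass
class Thresholds:
    """Screen thresholds; defaults are the published criteria."""

    lfc: float = 0.26          # |log2FC| cut for differential expression
    lfc_strict: bool = False   # False: |log2FC| >= lfc; True: strictly >
    de_p: float = 0.05         # raw p cut for differential expression
    cis_window: int = 100_000  # bp, inclusive, either side of the lncRNA span
    trans_r: float = 0.95      # |Pearson r| must strictly exceed this
    trans_p: float = 0.05
    scc_max: float = -0.7      # Spearman(miRNA, target) must be <= this
    pcc_min: float = 0.9       # Pearson(lncRNA, mRNA) must strictly exceed this
    hypergeom_p: float = 0.05  # shared-miRNA over-representation cut
    enrich_p: float = 0.05     # enrichment "significant" tier
    enrich_p_strong: float = 0.01  # enrichment "highly significant" tier

    def validate(self) -> None:
        bad = []
        for name in ("de_p", "trans_p", "hypergeom_p", "enrich_p", "enrich_p_strong"):
            if not 0.0 < getattr(self, name) <= 1.0:
                bad.append(f"{name} must be in (0, 1]")
        if self.lfc < 0:
            bad.append("lfc must be >= 0")
        if self.cis_window < 0:
            bad.append("cis_window must be >= 0")
        if not 0.0 <= self.trans_r <= 1.0:
            bad.append("trans_r must be in [0, 1]")
        if not -1.0 <= self.scc_max <= 1.0:
            bad.append("scc_max must be in [-1, 1]")
        if not -1.0 <= self.pcc_min <= 1.0:
            bad.append("pcc_min must be in [-1, 1]")
        if bad:
            raise ValidationError("; ".join(bad))


@dataclass
class Comparison:
    """One differential contrast: condition_b over condition_a, optionally
    restricted to a single tissue (``tissue=None`` pools all tissues)."""

    label: str = "brooding_vs_laying"
    tissue: str | None = None
    condition_a: str = "laying"
    condition_b: str = "brooding"


@dataclass
class PipelineConfig:
    """Everything needed for a deterministic end-to-end run."""

    seed: int = 1
    simulate: SimConfig = field(default_factory=SimConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    comparisons: list[Comparison] = field(
        default_factory=lambda: [Comparison()]
    )
    #: Pseudocount (in normalized counts) used for log2 fold changes.
    pseudocount: float = 1.0

    def validate(self) -> None:
        self.simulate.validate()
        self.thresholds.validate()
        labels = [c.label for c in self.comparisons]
        if len(set(labels)) != len(labels):
            raise ValidationError("comparison labels must be unique")
        for c in self.comparisons:
            if c.tissue is not None and c.tissue not in TISSUES:
                raise ValidationError(f"unknown tissue {c.tissue!r}")
            for cond in (c.condition_a, c.condition_b):
                if cond not in CONDITIONS:
                    raise ValidationError(f"unknown condition {cond!r}")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        data = dict(data)
        sim = data.pop("simulate", {})
        thr = data.pop("thresholds", {})
        comps = data.pop("comparisons", None)
        cfg = cls(
            simulate=SimConfig(**_coerce_pairs(sim)),
            thresholds=Thresholds(**thr),
            **data,
        )
        if comps is not None:
            cfg.comparisons = [Comparison(**c) for c in comps]
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        """Stable hash of the full configuration (for the run manifest)."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()


def _coerce_pairs(sim: dict[str, Any]) -> dict[str, Any]:
    """YAML round-trips tuples as lists; restore the pair fields."""
    out = dict(sim)
    for key, val in out.items():
        if key.endswith("_range") and isinstance(val, Sequence):
            out[key] = tuple(val)
    return out
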