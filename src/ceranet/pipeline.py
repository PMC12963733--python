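"""Deterministic end-to-end orchestration of the analysis stages.

Stages run in dependency order — simulate, identify, de, targets, enrich,
cerna — exchanging plain-text artifacts inside one output directory.  A
run manifest records the configuration hash, the seed and per-stage row
counts; re-running with an identical configuration yields byte-identical
artifacts.  Logging goes to stderr; stdout stays machine-readable.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Callable, Sequence

import pandas as pd

from . import __version__, de, identify, io, network, targets
from .config import Comparison, PipelineConfig
from .enrich import enrich
from .errors import DependencyError, ParameterError
from .simulate import SimConfig, generate_dataset
from .types import records_to_frame

log = logging.getLogger("ceranet")

STAGES: tuple[str, ...] = ("simulate", "identify", "de", "targets", "enrich", "cerna")

# Files each stage needs before it can start (subset sufficient to detect
# a missing upstream stage; paths relative to the run directory).
_REQUIRES: dict[str, list[str]] = {
    "simulate": [],
    "identify": ["simulate/annotation.gtf", "simulate/coding_calls.tsv"],
    "de": ["simulate/samples.tsv", "identify/lncrna_ids.txt"],
    "targets": ["simulate/annotation.gtf", "de"],
    "enrich": ["simulate/term_map.tsv", "targets"],
    "cerna": ["simulate/interactions_mirna_lncrna.tsv", "de"],
}


def _check_requirements(stage: str, outdir: Path, cfg: PipelineConfig) -> None:
    for req in _REQUIRES[stage]:
        if req == "de":
            missing = [
                c.label for c in cfg.comparisons
                if not (outdir / "de" / f"de_lncrna_{c.label}.tsv").exists()
            ]
            if missing:
                raise DependencyError(
                    f"stage '{stage}' needs stage 'de' (missing DE tables for "
                    f"{', '.join(missing)})"
                )
        elif req == "targets":
            if not (outdir / "targets").exists():
                raise DependencyError(f"stage '{stage}' needs stage 'targets'")
        elif not (outdir / req).exists():
            owner = req.split("/")[0]
            raise DependencyError(
                f"stage '{stage}' needs '{req}' from stage '{owner}'"
            )


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, outdir: Path) -> dict[str, int]:
    sim = SimConfig(**{**cfg.simulate.__dict__, "seed": cfg.seed})
    dataset = generate_dataset(sim)
    return dataset.write(outdir / "simulate")


def stage_identify(cfg: PipelineConfig, outdir: Path) -> dict[str, int]:
    sim_dir = outdir / "simulate"
    records = io.read_gtf(sim_dir / "annotation.gtf")
    calls = io.read_table(sim_dir / "coding_calls.tsv")
    lnc_ids = identify.identify_lncrnas(records, calls)
    known = io.read_id_list(sim_dir / "known_lncrna_ids.txt")
    novelty = identify.classify_novelty(lnc_ids, known)

    # Characteristics on the identified set plus mRNAs, FPKM from counts.
    labelled = identify.apply_novelty(
        [r for r in records if r.biotype == "mRNA" or r.transcript_id in set(lnc_ids)],
        known,
    )
    counts = pd.concat(
        [io.read_matrix(sim_dir / "mrna_counts.tsv"),
         io.read_matrix(sim_dir / "lncrna_counts.tsv")]
    )
    lengths = pd.Series({r.transcript_id: r.length for r in records})
    fpkm = de.compute_fpkm(counts, lengths)
    summary = identify.summarize_features(labelled, fpkm)

    dest = outdir / "identify"
    dest.mkdir(parents=True, exist_ok=True)
    io.write_id_list(lnc_ids, dest / "lncrna_ids.txt")
    nov = novelty.rename_axis("transcript_id").reset_index()
    io.write_table(nov, dest / "novelty.tsv")
    io.write_table(summary, dest / "characteristics.tsv")
    return {
        "lncrna_ids.txt": len(lnc_ids),
        "novelty.tsv": len(nov),
        "characteristics.tsv": len(summary),
    }


def stage_de(cfg: PipelineConfig, outdir: Path) -> dict[str, int]:
    sim_dir = outdir / "simulate"
    samples = io.read_table(sim_dir / "samples.tsv")
    lnc_ids = io.read_id_list(outdir / "identify" / "lncrna_ids.txt")
    dest = outdir / "de"
    dest.mkdir(parents=True, exist_ok=True)
    counts_by_class = {
        "mrna": io.read_matrix(sim_dir / "mrna_counts.tsv"),
        "lncrna": io.read_matrix(sim_dir / "lncrna_counts.tsv"),
        "mirna": io.read_matrix(sim_dir / "mirna_counts.tsv"),
    }
    # only identified lncRNAs enter the lncRNA screen
    counts_by_class["lncrna"] = counts_by_class["lncrna"].loc[
        [i for i in counts_by_class["lncrna"].index if i in set(lnc_ids)]
    ]
    rows: dict[str, int] = {}
    for comp in cfg.comparisons:
        for cls, counts in counts_by_class.items():
            table = de.de_table(
                counts,
                samples,
                condition_a=comp.condition_a,
                condition_b=comp.condition_b,
                tissue=comp.tissue,
                thresholds=cfg.thresholds,
                pseudocount=cfg.pseudocount,
            )
            name = f"de_{cls}_{comp.label}.tsv"
            io.write_table(table, dest / name)
            rows[name] = len(table)
    return rows


def stage_targets(cfg: PipelineConfig, outdir: Path) -> dict[str, int]:
    sim_dir = outdir / "simulate"
    records = io.read_gtf(sim_dir / "annotation.gtf")
    spans = records_to_frame(records)
    mrna_spans = spans[spans["biotype"] == "mRNA"]
    samples = io.read_table(sim_dir / "samples.tsv")
    mrna_counts = io.read_matrix(sim_dir / "mrna_counts.tsv")
    lnc_counts = io.read_matrix(sim_dir / "lncrna_counts.tsv")
    dest = outdir / "targets"
    dest.mkdir(parents=True, exist_ok=True)
    rows: dict[str, int] = {}
    for comp in cfg.comparisons:
        de_lnc = pd.read_csv(outdir / "de" / f"de_lncrna_{comp.label}.tsv", sep="\t")
        sig = de.significant_ids(de_lnc)
        lnc_spans = spans[spans["transcript_id"].isin(sig)]
        cis = targets.cis_targets(lnc_spans, mrna_spans, cfg.thresholds.cis_window)

        sel = _comparison_samples(samples, comp)
        log_expr_lnc = targets.log_normalized(lnc_counts[sel])
        log_expr_mrna = targets.log_normalized(mrna_counts[sel])
        lnc_sub = log_expr_lnc.loc[[i for i in log_expr_lnc.index if i in sig]]
        if len(lnc_sub):
            trans = targets.trans_targets(
                lnc_sub, log_expr_mrna,
                cfg.thresholds.trans_r, cfg.thresholds.trans_p,
            )
        else:
            trans = targets.trans_targets(
                log_expr_lnc.iloc[:0], log_expr_mrna,
                cfg.thresholds.trans_r, cfg.thresholds.trans_p,
            )
        io.write_table(cis, dest / f"cis_targets_{comp.label}.tsv")
        io.write_table(trans, dest / f"trans_targets_{comp.label}.tsv")
        rows[f"cis_targets_{comp.label}.tsv"] = len(cis)
        rows[f"trans_targets_{comp.label}.tsv"] = len(trans)
    return rows


def stage_enrich(cfg: PipelineConfig, outdir: Path) -> dict[str, int]:
    term_map = io.read_term_map(outdir / "simulate" / "term_map.tsv")
    dest = outdir / "enrich"
    dest.mkdir(parents=True, exist_ok=True)
    rows: dict[str, int] = {}
    for comp in cfg.comparisons:
        for mode in ("cis", "trans"):
            pairs = pd.read_csv(
                outdir / "targets" / f"{mode}_targets_{comp.label}.tsv", sep="\t"
            )
            study = sorted(set(pairs["gene_id"].astype(str)))
            result = enrich(
                study, None, term_map,
                p_significant=cfg.thresholds.enrich_p,
                p_strong=cfg.thresholds.enrich_p_strong,
            )
            name = f"enrichment_{mode}_{comp.label}.tsv"
            io.write_table(result, dest / name)
            rows[name] = len(result)
    return rows


def stage_cerna(cfg: PipelineConfig, outdir: Path) -> dict[str, int]:
    sim_dir = outdir / "simulate"
    samples = io.read_table(sim_dir / "samples.tsv")
    int_lnc = io.read_table(sim_dir / "interactions_mirna_lncrna.tsv")
    int_mrna = io.read_table(sim_dir / "interactions_mirna_mrna.tsv")
    counts = {
        cls: io.read_matrix(sim_dir / f"{cls}_counts.tsv")
        for cls in ("mrna", "lncrna", "mirna")
    }
    dest = outdir / "cerna"
    dest.mkdir(parents=True, exist_ok=True)
    rows: dict[str, int] = {}
    for comp in cfg.comparisons:
        tables = {
            cls: pd.read_csv(outdir / "de" / f"de_{cls}_{comp.label}.tsv", sep="\t")
            for cls in ("mrna", "lncrna", "mirna")
        }
        sel = _comparison_samples(samples, comp)
        expr = {
            cls: targets.log_normalized(counts[cls][sel])
            for cls in ("mrna", "lncrna", "mirna")
        }
        triads = network.build_triads(
            de.significant_ids(tables["lncrna"]),
            de.significant_ids(tables["mirna"]),
            de.significant_ids(tables["mrna"]),
            int_lnc,
            int_mrna,
            expr["lncrna"],
            expr["mirna"],
            expr["mrna"],
            cfg.thresholds,
        )
        directions: dict[str, str] = {}
        for tbl in tables.values():
            directions.update(de.direction_map(tbl))
        net = network.assemble_network(triads, directions, comparison=comp.label)
        stats = network.network_stats(net)
        io.write_table(triads, dest / f"triads_{comp.label}.tsv")
        net_dir = dest / f"network_{comp.label}"
        network.export_network(net, net_dir, formats=("tsv", "sif"))
        stats_out = {
            "comparison": comp.label,
            "n_nodes": stats["n_nodes"],
            "n_edges": stats["n_edges"],
            "classes": stats["classes"],
            "hubs": stats["hubs"],
        }
        with open(dest / f"network_stats_{comp.label}.json", "w") as fh:
            json.dump(stats_out, fh, sort_keys=True, indent=2)
            fh.write("\n")
        rows[f"triads_{comp.label}.tsv"] = len(triads)
        rows[f"network_{comp.label}/edges.tsv"] = stats["n_edges"]
        rows[f"network_{comp.label}/nodes.tsv"] = stats["n_nodes"]
    return rows


def _comparison_samples(samples: pd.DataFrame, comp: Comparison) -> list[str]:
    meta = samples
    if comp.tissue is not None:
        meta = meta[meta["tissue"] == comp.tissue]
    meta = meta[meta["condition"].isin([comp.condition_a, comp.condition_b])]
    return meta["sample_id"].tolist()


_STAGE_FUNCS: dict[str, Callable[[PipelineConfig, Path], dict[str, int]]] = {
    "simulate": stage_simulate,
    "identify": stage_identify,
    "de": stage_de,
    "targets": stage_targets,
    "enrich": stage_enrich,
    "cerna": stage_cerna,
}


# ---------------------------------------------------------------------------
# Runner
# ---------------------------------------------------------------------------

def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    stages: Sequence[str] | None = None,
) -> dict:
    """Execute the requested stages in dependency order; return the manifest.

    The manifest (also written to ``manifest.json``) records the config
    hash, seed, package version and per-stage output row counts — nothing
    time-dependent, so identical runs produce identical trees.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if stages is None:
        stages = STAGES
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ParameterError(f"unknown stage(s): {', '.join(unknown)}")
    ordered = [s for s in STAGES if s in set(stages)]
    manifest_stages = []
    for stage in ordered:
        _check_requirements(stage, outdir, config)
        t0 = time.perf_counter()
        rows = _STAGE_FUNCS[stage](config, outdir)
        dt = time.perf_counter() - t0
        log.info("stage %-9s %6.2fs  %s", stage, dt,
                 ", ".join(f"{k}={v}" for k, v in rows.items()))
        manifest_stages.append({"name": stage, "row_counts": rows})
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "stages": manifest_stages,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=2)
        fh.write("\n")
    return manifest
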