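"""Planted-triad recovery benchmark: the whole screen against known truth.

Chains every analysis stage in memory — simulate, identify lncRNAs, call
differential expression per class, screen ceRNA triads — and scores the
accepted triads against the planted ones.  The contrast pools all tissues
(the generator plants one global condition effect and no tissue effect,
so pooling is the matched analysis; per-tissue contrasts are available
through the pipeline configuration).
"""

from __future__ import annotations

from dataclasses import replace

import pandas as pd

from . import de, identify, network, targets
from .config import SimConfig, Thresholds
from .simulate import SyntheticDataset, generate_dataset
from .types import triads_to_frame


def run_screen(
    dataset: SyntheticDataset, thresholds: Thresholds | None = None
) -> dict:
    """Run identification, DE and the triad screen on a generated dataset.

    Returns a dict with the identified lncRNA ids, the per-class DE
    tables, the accepted triads, the assembled network and the recovery
    scores against the planted truth.
    """
    thr = thresholds or Thresholds()
    lnc_ids = set(
        identify.identify_lncrnas(dataset.annotation, dataset.coding_calls)
    )
    counts = {
        "mrna": dataset.mrna_counts,
        "lncrna": dataset.lncrna_counts.loc[
            [i for i in dataset.lncrna_counts.index if i in lnc_ids]
        ],
        "mirna": dataset.mirna_counts,
    }
    tables = {
        cls: de.de_table(
            counts[cls],
            dataset.samples,
            condition_a="laying",
            condition_b="brooding",
            thresholds=thr,
        )
        for cls in ("mrna", "lncrna", "mirna")
    }
    expr = {
        cls: targets.log_normalized(dataset.counts(cls))
        for cls in ("mrna", "lncrna", "mirna")
    }
    triads = network.build_triads(
        de.significant_ids(tables["lncrna"]),
        de.significant_ids(tables["mirna"]),
        de.significant_ids(tables["mrna"]),
        dataset.mirna_lncrna,
        dataset.mirna_mrna,
        expr["lncrna"],
        expr["mirna"],
        expr["mrna"],
        thr,
    )
    directions: dict[str, str] = {}
    for tbl in tables.values():
        directions.update(de.direction_map(tbl))
    net = network.assemble_network(triads, directions, comparison="brooding_vs_laying")
    scores = network.score_triads(triads, triads_to_frame(dataset.triads))
    return {
        "lncrna_ids": lnc_ids,
        "de_tables": tables,
        "triads": triads,
        "network": net,
        "scores": scores,
    }


def recover_planted_triads(
    seed: int,
    config: SimConfig | None = None,
    thresholds: Thresholds | None = None,
) -> dict:
    """Generate a dataset with ``seed`` and run the full screen on it."""
    config = config or SimConfig()
    config = replace(config, seed=seed)
    dataset = generate_dataset(config)
    result = run_screen(dataset, thresholds)
    result["dataset"] = dataset
    return result


def recovery_summary(seeds: list[int], config: SimConfig | None = None) -> pd.DataFrame:
    """Sensitivity/precision table over several simulation seeds."""
    rows = []
    for seed in seeds:
        scores = recover_planted_triads(seed, config)["scores"]
        rows.append({"seed": seed, **scores})
    return pd.DataFrame(rows)
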