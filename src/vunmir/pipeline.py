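"""End-to-end orchestration: simulated libraries -> clean unique reads ->
predicted miRNA genes -> families -> expression matrix -> differential
expression and PCA, with ground-truth evaluation helpers."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import pandas as pd

from .families import FamilyCluster, assign_family_names, cluster_families
from .hairpin import CriteriaThresholds, HairpinCandidate, MiRNAGene, predict_from_reads
from .preprocess import Library, UniqueRead, collapse_unique, filter_annotated, trim_library
from .stats import classify_drought_associated, pca_expression, quantify_mature, tptm_matrix
from .synthetic import GroundTruth, SimulatedLibraries, SyntheticDesign, design_truth, simulate_libraries


@dataclass
class PipelineResult:
    truth: GroundTruth
    sim: SimulatedLibraries
    libraries: list[Library]
    totals: dict[str, int]  # clean reads per library (N of the AC test)
    unique_reads: list[UniqueRead]  # after contaminant filtering
    removed_by_set: dict[str, int]
    genes: list[MiRNAGene]
    candidates: list[HairpinCandidate]
    clusters: list[FamilyCluster]
    counts: pd.DataFrame  # mature x library raw counts
    tptm: pd.DataFrame
    differential: pd.DataFrame


def run_pipeline(
    design: SyntheticDesign | None = None,
    thresholds: CriteriaThresholds = CriteriaThresholds(),
    reference_matures: Mapping[str, str] | None = None,
    backend: str | Callable = "builtin",
    min_copies: int = 10,
) -> PipelineResult:
    """Run the whole discovery and expression workflow on one synthetic
    experiment.  Deterministic given the design seed."""
    design = design or SyntheticDesign()
    truth = design_truth(design)
    sim = simulate_libraries(truth, design)

    per_lib_inserts = []
    totals: dict[str, int] = {}
    for lib, reads in zip(sim.libraries, sim.reads):
        inserts, _rejects = trim_library(reads, design.adapter)
        per_lib_inserts.append(inserts)
        totals[lib.id] = len(inserts)
    libraries = [
        Library(l.id, l.genotype, l.condition, totals[l.id]) for l in sim.libraries
    ]

    unique = collapse_unique(per_lib_inserts)
    filtered, removed = filter_annotated(unique, truth.annotations)

    genes, candidates = predict_from_reads(
        filtered,
        {"genome": truth.reference},
        thresholds=thresholds,
        min_copies=min_copies,
        backend=backend,
    )

    matures = []
    for g in genes:
        if g.mature_seq not in matures:
            matures.append(g.mature_seq)
    clusters = assign_family_names(
        cluster_families(matures), reference_matures or {}
    )

    mature_ids = {f"mat{i + 1:03d}": m for i, m in enumerate(matures)}
    lib_ids = [l.id for l in libraries]
    counts = quantify_mature(filtered, mature_ids, lib_ids)
    tm = tptm_matrix(counts, totals)
    differential = classify_drought_associated(counts, totals)
    differential.insert(0, "mature", [mature_ids[i] for i in differential.index])

    return PipelineResult(
        truth=truth,
        sim=sim,
        libraries=libraries,
        totals=totals,
        unique_reads=filtered,
        removed_by_set=removed,
        genes=genes,
        candidates=candidates,
        clusters=clusters,
        counts=counts,
        tptm=tm,
        differential=differential,
    )


def evaluate_recovery(result: PipelineResult) -> dict[str, float]:
    """Compare predicted genes against the planted ground truth.

    recall: fraction of planted matures recovered exactly;
    precision: fraction of predicted genes whose mature is a planted mature;
    false_decoy_calls: predicted genes falling in decoy or contaminant loci.
    """
    planted = {p.mature_seq for p in result.truth.planted}
    predicted = [g.mature_seq for g in result.genes]
    tp = sum(1 for m in predicted if m in planted)
    recall = len({m for m in predicted if m in planted}) / len(planted)
    precision = tp / len(predicted) if predicted else 1.0

    bad_loci = result.truth.decoy_loci + result.truth.contaminant_loci
    n_bad = 0
    for g in result.genes:
        c = g.precursor
        for rid, lo, hi in bad_loci:
            if c.reference_id == rid and c.start < hi and c.end > lo:
                n_bad += 1
                break
    return {
        "recall": recall,
        "precision": precision,
        "false_decoy_calls": float(n_bad),
        "n_planted": float(len(planted)),
        "n_predicted": float(len(predicted)),
    }


def drought_recovery(result: PipelineResult) -> dict[str, float]:
    """Power check: are the planted drought-regulated matures classified as
    drought-associated?"""
    mature_by_seq = {}
    for mid, row in zip(result.differential["mature"], result.differential.itertuples()):
        mature_by_seq[mid] = row
    regulated = [p for p in result.truth.planted if p.drought_log2fc != (0.0, 0.0)]
    if not regulated:
        return {"power": float("nan"), "n_regulated": 0.0}
    found = 0
    for p in regulated:
        row = mature_by_seq.get(p.mature_seq)
        if row is not None and getattr(row, "associated"):
            found += 1
    return {"power": found / len(regulated), "n_regulated": float(len(regulated))}
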