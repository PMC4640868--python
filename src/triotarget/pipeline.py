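"""End-to-end orchestration: files in, prioritized candidate table out.

Runs the three evidence layers over a study bundle (per-line expression
TSVs, per-line peak BEDs, a gene model, a cohort matrix + copy-number
metadata) and intersects them into the final candidate list.  This is the
path the CLI ``run`` subcommand and the acceptance script exercise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import cistrome, cohort, integrate, transcriptome
from .synthdata import SimulationResult


@dataclass
class StudyResult:
    responses: dict[str, list[transcriptome.ResponseRecord]]
    annotations: dict[str, cistrome.AnnotationResult]
    groups: pd.Series
    sam: cohort.SamResult
    cohort_q: dict[str, float]
    candidates: list[integrate.IntegratedCandidate]
    overlaps: list[integrate.OverlapSummary]


def run_study(
    expression_paths: Mapping[str, str | Path],
    peak_paths: Mapping[str, str | Path],
    genes_path: str | Path,
    cohort_expression_path: str | Path,
    cohort_samples_path: str | Path,
    index_gene: str,
    seed: int,
    min_abundance: float = 1.0,
    response_threshold: float = 0.25,
    window: int = 100_000,
    amp_threshold: float = 1.5,
    nonamp_threshold: float = 1.1,
    percentile: float = 75.0,
    n_perm: int = 200,
    fdr_threshold: float = 0.10,
    cohort_scale: str = "log2",
) -> StudyResult:
    """Run knockdown response, peak annotation and cohort SAM, then integrate."""
    gene_models = cistrome.load_gene_models(genes_path)

    responses: dict[str, list[transcriptome.ResponseRecord]] = {}
    annotations: dict[str, cistrome.AnnotationResult] = {}
    for line in sorted(expression_paths):
        table = transcriptome.load_expression(expression_paths[line], line)
        responses[line] = transcriptome.compute_response(
            table, min_abundance=min_abundance, threshold=response_threshold
        )
        peaks = cistrome.load_peaks(peak_paths[line])
        annotations[line] = cistrome.annotate_peaks(peaks, gene_models, window=window)

    study = cohort.load_cohort(
        cohort_expression_path, cohort_samples_path, index_gene, scale=cohort_scale
    )
    groups = cohort.define_groups(
        study, amp_threshold=amp_threshold, nonamp_threshold=nonamp_threshold,
        percentile=percentile,
    )
    sam = cohort.sam_two_class(study.expression, groups, n_perm=n_perm, seed=seed)
    over = cohort.overexpressed_in_amplified(sam, fdr_threshold)
    q_by_gene = dict(zip(sam.genes, sam.q))
    cohort_q = {g: float(q_by_gene[g]) for g in over}

    candidates = integrate.integrate_candidates(
        responses,
        {line: annotations[line].gene_best_rank for line in annotations},
        cohort_q,
        fdr_threshold=fdr_threshold,
    )
    regulated = {
        line: {r.gene for r in recs if r.call in ("down", "up")}
        for line, recs in responses.items()
    }
    peak_genes = {line: set(annotations[line].gene_best_rank) for line in annotations}
    overlaps = integrate.overlap_summary(regulated, peak_genes)
    return StudyResult(responses, annotations, groups, sam, cohort_q, candidates, overlaps)


def run_bundle(sim: SimulationResult, seed: int, **kwargs) -> StudyResult:
    """Run the pipeline on a synthetic bundle produced by ``synthdata.simulate``."""
    return run_study(
        {line: sim.paths[f"expr_{line}"] for line in sim.lines},
        {line: sim.paths[f"peaks_{line}"] for line in sim.lines},
        sim.paths["genes"],
        sim.paths["cohort_expression"],
        sim.paths["cohort_samples"],
        sim.config.index_gene,
        seed=seed,
        **kwargs,
    )
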