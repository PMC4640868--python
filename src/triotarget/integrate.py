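"""Triple-evidence candidate integration.

A gene is nominated as a direct target when, in some cell line, it is
(1) downregulated upon factor knockdown, (2) associated with a called
binding peak within the annotation window, and (3) overexpressed in
amplified tumors of the cohort (d > 0 at q below the FDR bound).  The
output is a per-line candidate table carrying the three evidence values
verbatim (knockdown/control ratio, best peak rank, cohort q), the shape of
a classic integrative-"omics" prioritization table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

from .transcriptome import InputError, ResponseRecord


@dataclass(frozen=True)
class IntegratedCandidate:
    cell_line: str
    gene: str
    ratio: float
    peak_rank: int
    cohort_fdr: float


@dataclass
class OverlapSummary:
    """Per cell line: regulated vs peak-associated gene sets and their overlap."""

    cell_line: str
    n_regulated: int
    n_peak_associated: int
    n_intersection: int

    @property
    def frac_regulated_with_peak(self) -> float:
        return self.n_intersection / self.n_regulated if self.n_regulated else 0.0

    @property
    def frac_peak_associated_regulated(self) -> float:
        return self.n_intersection / self.n_peak_associated if self.n_peak_associated else 0.0


def integrate_candidates(
    responses: Mapping[str, Sequence[ResponseRecord]],
    peak_ranks: Mapping[str, Mapping[str, int]],
    cohort_q: Mapping[str, float],
    direction: str = "down",
    fdr_threshold: float = 0.10,
    same_line: bool = True,
) -> list[IntegratedCandidate]:
    """Genes with all three evidence layers, per cell line.

    ``cohort_q`` maps genes overexpressed in the amplified group (d > 0) to
    their SAM q; genes absent from it fail the cohort layer.  With
    ``same_line`` (default) the knockdown response and the peak must come
    from the same cell line, matching a per-line prioritization table; the
    cross-line union mode accepts a peak from any line.  Rows are sorted
    within line by ascending ratio, ties by gene.
    """
    all_resp_genes = {r.gene for recs in responses.values() for r in recs}
    all_peak_genes = {g for ranks in peak_ranks.values() for g in ranks}
    if not (all_resp_genes & all_peak_genes) and all_resp_genes and all_peak_genes:
        raise InputError("no shared gene identifiers between responses and peak annotations")

    union_ranks: dict[str, int] = {}
    for ranks in peak_ranks.values():
        for g, r in ranks.items():
            if g not in union_ranks or r < union_ranks[g]:
                union_ranks[g] = r

    out: list[IntegratedCandidate] = []
    for line in sorted(responses):
        ranks = peak_ranks.get(line, {}) if same_line else union_ranks
        rows = []
        for rec in responses[line]:
            if rec.call != direction:
                continue
            if rec.gene not in ranks:
                continue
            q = cohort_q.get(rec.gene)
            if q is None or q > fdr_threshold:
                continue
            rows.append((rec.ratio, rec.gene, ranks[rec.gene], q))
        for ratio, gene, rank, q in sorted(rows):
            out.append(IntegratedCandidate(line, gene, ratio, rank, q))
    return out


def candidates_frame(candidates: Sequence[IntegratedCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.cell_line, c.gene, c.ratio, c.peak_rank, c.cohort_fdr) for c in candidates],
        columns=["cell_line", "gene", "ratio", "peak_rank", "cohort_fdr"],
    )


def render_candidates(candidates: Sequence[IntegratedCandidate]) -> pd.DataFrame:
    """Presentation-layer view with the cohort FDR rendered as a percentage."""
    frame = candidates_frame(candidates)
    frame["cohort_fdr"] = [f"{100 * q:.1f}" for q in frame["cohort_fdr"]]
    frame = frame.rename(columns={"cohort_fdr": "cohort_fdr_pct"})
    return frame


def overlap_summary(
    regulated: Mapping[str, set[str]],
    peak_associated: Mapping[str, set[str]],
) -> list[OverlapSummary]:
    """Per-line counts and both-direction fractions of the regulated /
    peak-associated gene-set overlap."""
    out = []
    for line in sorted(regulated):
        reg = set(regulated[line])
        pk = set(peak_associated.get(line, set()))
        out.append(OverlapSummary(line, len(reg), len(pk), len(reg & pk)))
    return out


def hypergeometric_overlap(query: set[str], reference: set[str], universe_size: int) -> float:
    """One-sided hypergeometric tail P(X >= |query & reference|).

    The null draws |query| genes from a universe of ``universe_size``
    containing |reference| marked genes.
    """
    if universe_size < len(query | reference):
        raise InputError(
            f"universe_size {universe_size} smaller than |query ∪ reference| = {len(query | reference)}"
        )
    k = len(query & reference)
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, universe_size, len(reference), len(query)))
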