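"""Knockdown-response quantification from per-cell-line expression tables.

The entry point of the pipeline: for each cell line an expression table
(gene x condition, RPKM-like units) is reduced to per-gene knockdown/control
ratios, classified into down / up / unchanged / not_measured, and compared
across lines (consistency sets, top-gene lists, pairwise correlation of
log-ratio profiles).

Conventions, applied throughout:

* a gene is *well measured* when its abundance is >= ``min_abundance``
  (default 1 RPKM) in BOTH the knockdown and control conditions;
* "at least ``threshold`` changed" is inclusive: at the default 25%
  threshold, ratio <= 0.75 is down and ratio >= 1.25 is up;
* every tie (equal ratios, equal metrics) is broken by ascending gene
  identifier so all outputs are byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class InputError(ValueError):
    """Raised when an input file or table violates the format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionTable:
    """Gene x condition abundance matrix for one cell line.

    ``data`` is indexed by gene identifier; ``knockdown`` / ``control`` name
    the two required condition columns (other condition columns may be
    present and are ignored by the response computation).
    """

    cell_line: str
    data: pd.DataFrame
    knockdown: str = "knockdown"
    control: str = "control"

    def __post_init__(self) -> None:
        for col in (self.knockdown, self.control):
            if col not in self.data.columns:
                raise InputError(
                    f"{self.cell_line}: required condition column {col!r} missing "
                    f"(found {list(self.data.columns)})"
                )
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise InputError(f"{self.cell_line}: duplicate gene row {dup!r}")
        values = self.data[[self.knockdown, self.control]]
        numeric = values.apply(pd.to_numeric, errors="coerce")
        bad = numeric.isna() & values.notna()
        if bad.any().any() or values.isna().any().any():
            gene = values.index[(bad | values.isna()).any(axis=1)][0]
            raise InputError(f"{self.cell_line}: non-numeric abundance in row {gene!r}")
        arr = numeric.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            gene = values.index[~np.isfinite(arr).all(axis=1)][0]
            raise InputError(f"{self.cell_line}: non-finite abundance in row {gene!r}")
        if (arr < 0).any():
            gene = values.index[(arr < 0).any(axis=1)][0]
            raise InputError(f"{self.cell_line}: negative abundance in row {gene!r}")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)


@dataclass(frozen=True)
class ResponseRecord:
    """Per-gene knockdown response: ratio, categorical call, down-rank."""

    gene: str
    ratio: float | None
    call: str  # down | up | unchanged | not_measured
    rank_down: int | None = None


@dataclass
class ConsistencySet:
    """Genes called in ``direction`` in at least ``min_lines`` cell lines."""

    direction: str
    min_lines: int
    genes: set[str]
    per_line_membership: dict[str, dict[str, bool]]


@dataclass
class CorrelationResult:
    """Pairwise Pearson correlation of per-line log2-ratio profiles."""

    lines: list[str]
    r: pd.DataFrame
    p_adj: pd.DataFrame
    gene_universe: list[str]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def load_expression(
    path: str | Path,
    cell_line: str,
    knockdown: str = "knockdown",
    control: str = "control",
) -> ExpressionTable:
    """Read a TSV expression table (first column gene, header names conditions)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    return ExpressionTable(cell_line=cell_line, data=frame, knockdown=knockdown, control=control)


def write_responses(responses: Sequence[ResponseRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        [(r.gene, r.ratio, r.call, r.rank_down) for r in responses],
        columns=["gene", "ratio", "call", "rank_down"],
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def well_measured(table: ExpressionTable, min_abundance: float = 1.0) -> set[str]:
    """Genes with abundance >= ``min_abundance`` in both conditions (inclusive)."""
    kd = table.data[table.knockdown].astype(float)
    ctrl = table.data[table.control].astype(float)
    keep = (kd >= min_abundance) & (ctrl >= min_abundance)
    return set(table.data.index[keep])


def compute_response(
    table: ExpressionTable,
    min_abundance: float = 1.0,
    threshold: float = 0.25,
) -> list[ResponseRecord]:
    """Classify every gene of ``table`` by its knockdown/control ratio.

    Well-measured genes get ratio = knockdown / control and a call of
    ``down`` (ratio <= 1 - threshold), ``up`` (ratio >= 1 + threshold) or
    ``unchanged``; genes failing the abundance filter are ``not_measured``.
    ``rank_down`` (1 = most downregulated) is assigned among down genes by
    ascending ratio, ties by gene identifier.
    """
    if not 0 < threshold < 1:
        raise InputError(f"threshold must be in (0, 1), got {threshold}")
    measured = well_measured(table, min_abundance)
    kd = table.data[table.knockdown].astype(float)
    ctrl = table.data[table.control].astype(float)

    records: dict[str, ResponseRecord] = {}
    down: list[tuple[float, str]] = []
    for gene in table.data.index:
        if gene not in measured or ctrl[gene] == 0:
            with np.errstate(over="ignore"):
                ratio = float(kd[gene] / ctrl[gene]) if ctrl[gene] > 0 else None
            if ratio is not None and not np.isfinite(ratio):
                ratio = None
            records[gene] = ResponseRecord(gene, ratio, "not_measured")
            continue
        ratio = float(kd[gene] / ctrl[gene])
        if ratio <= 1.0 - threshold:
            call = "down"
            down.append((ratio, gene))
        elif ratio >= 1.0 + threshold:
            call = "up"
        else:
            call = "unchanged"
        records[gene] = ResponseRecord(gene, ratio, call)

    for rank, (ratio, gene) in enumerate(sorted(down), start=1):
        records[gene] = ResponseRecord(gene, ratio, "down", rank_down=rank)
    return [records[g] for g in table.data.index]


def consistency(
    responses: Mapping[str, Sequence[ResponseRecord]],
    direction: str,
    min_lines: int,
) -> ConsistencySet:
    """Genes called ``direction`` in at least ``min_lines`` of the given lines."""
    if direction not in ("down", "up"):
        raise InputError(f"direction must be 'down' or 'up', got {direction!r}")
    if min_lines > len(responses):
        raise InputError(
            f"min_lines={min_lines} exceeds the {len(responses)} supplied lines"
        )
    called: dict[str, set[str]] = {
        line: {r.gene for r in recs if r.call == direction}
        for line, recs in responses.items()
    }
    candidates = sorted(set().union(*called.values())) if called else []
    members = {
        g for g in candidates if sum(g in called[line] for line in called) >= min_lines
    }
    membership = {
        line: {g: (g in called[line]) for g in candidates} for line in called
    }
    return ConsistencySet(direction, min_lines, members, membership)


def top_genes(
    responses: Sequence[ResponseRecord],
    n: int = 100,
    direction: str = "down",
) -> list[str]:
    """Top ``n`` most extreme genes called in ``direction`` (fewer if fewer qualify)."""
    if n < 1:
        raise InputError(f"n must be >= 1, got {n}")
    qualifying = [(r.ratio, r.gene) for r in responses if r.call == direction]
    if direction == "down":
        ordered = sorted(qualifying)
    elif direction == "up":
        ordered = sorted(qualifying, key=lambda t: (-t[0], t[1]))
    else:
        raise InputError(f"direction must be 'down' or 'up', got {direction!r}")
    return [gene for _, gene in ordered[:n]]


def cross_line_correlation(
    responses: Mapping[str, Sequence[ResponseRecord]],
    n: int = 100,
    correction: str = "bonferroni",
) -> CorrelationResult:
    """Pairwise Pearson correlation of log2-ratio profiles over union-of-top genes.

    The gene universe is the union, across lines, of each line's top-``n``
    down and top-``n`` up genes.  Each line contributes log2(ratio) for the
    universe genes it measures; correlation per pair uses genes measured in
    both lines.  p-values come from the two-sided Pearson test, adjusted by
    Bonferroni over the number of line pairs (the only multiplicity in play).
    Pairs sharing fewer than 3 genes are reported as NaN.
    """
    if len(responses) < 2:
        raise InputError("need at least two lines for cross-line correlation")
    lines = sorted(responses)
    universe: set[str] = set()
    for line in lines:
        universe.update(top_genes(responses[line], n=n, direction="down"))
        universe.update(top_genes(responses[line], n=n, direction="up"))
    universe_sorted = sorted(universe)

    profiles = {}
    for line in lines:
        by_gene = {r.gene: r for r in responses[line]}
        vals = {}
        for g in universe_sorted:
            rec = by_gene.get(g)
            if rec is not None and rec.call != "not_measured" and rec.ratio and rec.ratio > 0:
                vals[g] = np.log2(rec.ratio)
        profiles[line] = vals

    k = len(lines)
    n_pairs = k * (k - 1) // 2
    r = pd.DataFrame(np.eye(k), index=lines, columns=lines)
    p_adj = pd.DataFrame(np.zeros((k, k)), index=lines, columns=lines)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = profiles[lines[i]], profiles[lines[j]]
            shared = sorted(set(a) & set(b))
            if len(shared) < 3:
                rij, pij = np.nan, np.nan
            else:
                x = np.array([a[g] for g in shared])
                y = np.array([b[g] for g in shared])
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    rij, pij = np.nan, np.nan
                else:
                    res = stats.pearsonr(x, y)
                    rij = float(res.statistic)
                    if correction == "bonferroni":
                        pij = min(1.0, float(res.pvalue) * n_pairs)
                    elif correction == "none":
                        pij = float(res.pvalue)
                    else:
                        raise InputError(f"unknown correction {correction!r}")
            r.iloc[i, j] = r.iloc[j, i] = rij
            p_adj.iloc[i, j] = p_adj.iloc[j, i] = pij
    return CorrelationResult(lines, r, p_adj, universe_sorted)
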