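"""Two-class gene-set enrichment analysis.

Genes are ranked by a signal-to-noise metric between two sample classes,
then each gene set is scored with the weighted Kolmogorov-Smirnov running
sum: walking down the ranked list, in-set genes increment the sum by
|metric|^p (normalized to total 1 over the set) and out-of-set genes
decrement it by 1/(N - N_hit).  The enrichment score (ES) is the signed
maximum deviation; significance and normalization come from phenotype
(label) permutations, with a gene-permutation fallback for very small
classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .transcriptome import InputError


@dataclass
class GeneSet:
    name: str
    genes: set[str]
    source: str = "builtin"

    def __post_init__(self) -> None:
        if not self.genes:
            raise InputError(f"gene set {self.name!r} is empty")


@dataclass
class EnrichmentResult:
    set_name: str
    size: int  # members present in the ranked data
    es: float
    nes: float
    p_nominal: float
    fdr: float
    leading_edge: list[str]


def load_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file (name, description, members...); empty sets are skipped
    with a warning and duplicate members collapsed."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise InputError(f"{path}:{lineno}: malformed GMT line (need name + description)")
            members = {m for m in fields[2:] if m}
            if not members:
                warnings.warn(f"{path}:{lineno}: gene set {fields[0]!r} has no members; skipped")
                continue
            sets.append(GeneSet(fields[0], members, source=str(path)))
    return sets


def rank_signal_to_noise(
    expression: pd.DataFrame,
    labels: pd.Series | Mapping[str, str],
    class_a: str,
    class_b: str,
    sigma_floor_frac: float = 0.2,
    eps: float = 1e-8,
) -> pd.Series:
    """Signal-to-noise ranking metric (mu_A - mu_B)/(sigma_A + sigma_B).

    Each class standard deviation is floored at max(sigma_floor_frac * |mu|,
    eps), the convention of the desktop GSEA implementation.  Returned as a
    Series ordered by descending metric, ties broken by gene identifier.
    """
    labels = pd.Series(labels)
    ia = [c for c in expression.columns if labels.get(c) == class_a]
    ib = [c for c in expression.columns if labels.get(c) == class_b]
    if len(ia) < 2 or len(ib) < 2:
        raise InputError(
            f"signal-to-noise needs >= 2 samples per class (got {len(ia)} vs {len(ib)})"
        )
    A = expression[ia].to_numpy(dtype=float)
    B = expression[ib].to_numpy(dtype=float)
    mua, mub = A.mean(axis=1), B.mean(axis=1)
    sda = np.maximum(A.std(axis=1, ddof=1), np.maximum(sigma_floor_frac * np.abs(mua), eps))
    sdb = np.maximum(B.std(axis=1, ddof=1), np.maximum(sigma_floor_frac * np.abs(mub), eps))
    metric = (mua - mub) / (sda + sdb)
    out = pd.Series(metric, index=expression.index, name="s2n")
    order = sorted(zip(-out.to_numpy(), out.index))
    return out.loc[[g for _, g in order]]


def enrichment_score(
    ranked: pd.Series,
    gene_set: GeneSet | set[str],
    p: float = 1.0,
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted KS enrichment score for one gene set on a ranked metric.

    Returns (ES, running profile, leading edge).  The profile has one entry
    per ranked gene; ES is the value at its maximal |deviation| (first such
    position on ties).  With p = 0 this reduces to the classic KS statistic
    on set ranks.
    """
    members = gene_set.genes if isinstance(gene_set, GeneSet) else set(gene_set)
    genes = ranked.index.to_numpy()
    hit = np.isin(genes, list(members))
    n = len(genes)
    nh = int(hit.sum())
    if nh == 0:
        raise InputError("gene set has no members in the ranked list")
    if nh == n:
        raise InputError("gene set covers every ranked gene (miss denominator zero)")
    w = np.abs(ranked.to_numpy(dtype=float)) ** p
    wr = np.where(hit, w, 0.0)
    total = wr.sum()
    if total == 0:  # all in-set metrics exactly 0: fall back to equal weights
        wr = hit / nh
        total = 1.0
    steps = wr / total - (~hit) / (n - nh)
    profile = np.cumsum(steps)
    imax = int(np.argmax(np.abs(profile)))
    es = float(profile[imax])
    if es >= 0:
        leading = [g for g, h in zip(genes[: imax + 1], hit[: imax + 1]) if h]
    else:
        leading = [g for g, h in zip(genes[imax:], hit[imax:]) if h]
    return es, profile, leading


def _perm_es(
    expression: pd.DataFrame,
    labels: pd.Series,
    class_a: str,
    class_b: str,
    member_sets: list[set[str]],
    n_perm: int,
    rng: np.random.Generator,
    weight: float,
    mode: str,
) -> np.ndarray:
    """ES for each (permutation, set); phenotype mode permutes labels, gene
    mode permutes the gene assignment of the observed ranking."""
    out = np.empty((n_perm, len(member_sets)))
    if mode == "phenotype":
        lab_values = labels.loc[list(expression.columns)].to_numpy().copy()
        cols = list(expression.columns)
        for b in range(n_perm):
            perm = pd.Series(rng.permutation(lab_values), index=cols)
            ranked = rank_signal_to_noise(expression, perm, class_a, class_b)
            for k, members in enumerate(member_sets):
                out[b, k] = enrichment_score(ranked, members, p=weight)[0]
    else:
        ranked = rank_signal_to_noise(expression, labels, class_a, class_b)
        metrics = ranked.to_numpy()
        gene_arr = ranked.index.to_numpy()
        for b in range(n_perm):
            shuffled = pd.Series(metrics, index=rng.permutation(gene_arr))
            for k, members in enumerate(member_sets):
                out[b, k] = enrichment_score(shuffled, members, p=weight)[0]
    return out


def gsea_two_class(
    expression: pd.DataFrame,
    labels: pd.Series | Mapping[str, str],
    sets: Sequence[GeneSet],
    class_a: str,
    class_b: str,
    n_perm: int = 200,
    seed: int = 0,
    weight: float = 1.0,
    min_size: int = 15,
    max_size: int = 500,
    permutation: str = "auto",
) -> list[EnrichmentResult]:
    """Full two-class GSEA: ES, NES, nominal p and NES-based FDR per set.

    NES = ES / mean(|permuted ES of the same sign|).  Nominal p is the
    one-sided empirical probability with +1 smoothing.  FDR compares each
    set's NES with the pooled permutation NES distribution of the same sign,
    clipped to [0, 1].  ``permutation`` is "phenotype", "gene", or "auto"
    (gene permutation when either class has < 7 samples, since the phenotype
    permutation space is then too small for stable tail estimates).
    """
    if n_perm < 10:
        raise InputError(f"n_perm must be >= 10, got {n_perm}")
    labels = pd.Series(labels)
    ranked = rank_signal_to_noise(expression, labels, class_a, class_b)
    present = set(ranked.index)
    eligible: list[GeneSet] = []
    member_sets: list[set[str]] = []
    for gs in sets:
        members = gs.genes & present
        if min_size <= len(members) <= max_size and len(members) < len(present):
            eligible.append(gs)
            member_sets.append(members)
    if not eligible:
        return []

    n_a = sum(labels.get(c) == class_a for c in expression.columns)
    n_b = sum(labels.get(c) == class_b for c in expression.columns)
    mode = permutation
    if mode == "auto":
        mode = "gene" if min(n_a, n_b) < 7 else "phenotype"
    if mode not in ("phenotype", "gene"):
        raise InputError(f"permutation must be 'phenotype', 'gene' or 'auto', got {mode!r}")

    observed = np.array([enrichment_score(ranked, m, p=weight)[0] for m in member_sets])
    leading = [enrichment_score(ranked, m, p=weight)[2] for m in member_sets]
    rng = np.random.default_rng(seed)
    perm = _perm_es(expression, labels, class_a, class_b, member_sets, n_perm, rng, weight, mode)

    def _norm(es_val: float, perm_col: np.ndarray) -> float:
        same = perm_col[perm_col >= 0] if es_val >= 0 else perm_col[perm_col < 0]
        denom = float(np.abs(same).mean()) if len(same) else np.nan
        return es_val / denom if denom and np.isfinite(denom) and denom > 0 else np.nan

    nes = np.array([_norm(observed[k], perm[:, k]) for k in range(len(eligible))])
    nes_perm = np.array(
        [[_norm(perm[b, k], perm[:, k]) for k in range(len(eligible))] for b in range(n_perm)]
    )

    results = []
    pooled = nes_perm[np.isfinite(nes_perm)]
    for k, gs in enumerate(eligible):
        es_val, nes_val = float(observed[k]), float(nes[k])
        col = perm[:, k]
        same = col[col >= 0] if es_val >= 0 else col[col < 0]
        more = (same >= es_val).sum() if es_val >= 0 else (same <= es_val).sum()
        p_nom = float((1 + more) / (1 + len(same)))
        if np.isfinite(nes_val):
            if nes_val >= 0:
                num_pool = pooled[pooled >= 0]
                obs_pool = nes[np.isfinite(nes) & (nes >= 0)]
                frac_perm = (num_pool >= nes_val).mean() if len(num_pool) else 1.0
                frac_obs = (obs_pool >= nes_val).mean() if len(obs_pool) else 1.0
            else:
                num_pool = pooled[pooled < 0]
                obs_pool = nes[np.isfinite(nes) & (nes < 0)]
                frac_perm = (num_pool <= nes_val).mean() if len(num_pool) else 1.0
                frac_obs = (obs_pool <= nes_val).mean() if len(obs_pool) else 1.0
            fdr = float(np.clip(frac_perm / max(frac_obs, 1e-12), 0.0, 1.0))
        else:
            fdr = 1.0
        results.append(
            EnrichmentResult(gs.name, len(member_sets[k]), es_val, nes_val, p_nom, fdr, leading[k])
        )
    return results


def write_enrichment(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            (r.set_name, r.size, r.es, r.nes, r.p_nominal, r.fdr, ",".join(r.leading_edge))
            for r in results
        ],
        columns=["set", "size", "es", "nes", "p_nominal", "fdr", "leading_edge"],
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
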