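"""Tumor-cohort stratification and two-class SAM differential analysis.

A cohort is a gene x sample expression matrix plus a per-sample tumor/normal
copy-number ratio at one index locus (e.g. NKX2-1 on 14q13).  Samples are
stratified by amplification status (ratio > 1.5 amplified, < 1.1
non-amplified, otherwise indeterminate and excluded) and gated on high
expression of the index gene (top quartile of the cohort, inclusive).  The
amplified/highly-expressed and non-amplified/highly-expressed groups are
then compared gene by gene with the SAM statistic

    d_i = (mean_A,i - mean_B,i) / (s_i + s0)

where s_i is the pooled-variance standard error and s0 a small "fudge"
constant chosen to stabilise the spread of d across the range of s.  False
discovery rates come from label permutations: for a cutoff Delta, genes with
|d_(i) - dbar_(i)| > Delta (order statistics vs their permutation-expected
values) are called, and the per-gene q is the smallest estimated FDR at
which that gene is called.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .transcriptome import InputError

AMPLIFIED = "amplified"
NON_AMPLIFIED = "non_amplified"
INDETERMINATE = "indeterminate"

AMP_HIGH = "amplified_high"
NONAMP_HIGH = "nonamplified_high"
EXCLUDED = "excluded"


@dataclass
class CohortStudy:
    """Gene x sample expression with per-sample copy-number at the index locus.

    ``scale`` declares whether ``expression`` is already log2 ("log2") or
    linear; linear data is log2(x + 1)-transformed on construction since the
    SAM statistic assumes a roughly additive scale.
    """

    expression: pd.DataFrame  # genes x samples
    cn_ratio: pd.Series  # per sample
    index_gene: str
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.index_gene not in self.expression.index:
            raise InputError(f"index gene {self.index_gene!r} not in expression matrix")
        if not set(self.expression.columns) <= set(self.cn_ratio.index):
            missing = sorted(set(self.expression.columns) - set(self.cn_ratio.index))
            raise InputError(f"samples without copy-number ratio: {missing[:5]}")
        self.cn_ratio = self.cn_ratio.loc[self.expression.columns].astype(float)
        if (self.cn_ratio <= 0).any():
            raise InputError("copy-number ratios must be positive")
        arr = self.expression.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise InputError("expression matrix contains non-finite values")
        if self.scale == "linear":
            if (arr < 0).any():
                raise InputError("linear-scale expression must be non-negative")
            self.expression = np.log2(self.expression + 1.0)
            self.scale = "log2"
        elif self.scale != "log2":
            raise InputError(f"scale must be 'log2' or 'linear', got {self.scale!r}")

    @property
    def genes(self) -> list[str]:
        return list(self.expression.index)

    @property
    def samples(self) -> list[str]:
        return list(self.expression.columns)


def load_cohort(
    expression_path: str | Path,
    samples_path: str | Path,
    index_gene: str,
    scale: str = "log2",
) -> CohortStudy:
    """Read the expression matrix TSV and the sample metadata TSV (sample, cn_ratio)."""
    expr = pd.read_csv(expression_path, sep="\t", index_col=0)
    meta = pd.read_csv(samples_path, sep="\t")
    if "sample" not in meta.columns or "cn_ratio" not in meta.columns:
        raise InputError("sample metadata must have 'sample' and 'cn_ratio' columns")
    cn = meta.set_index("sample")["cn_ratio"]
    return CohortStudy(expr, cn, index_gene, scale)


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------

def call_amplification(
    cn_ratio: float, amp_threshold: float = 1.5, nonamp_threshold: float = 1.1
) -> str:
    """Amplified (> amp_threshold, strict), non-amplified (< nonamp_threshold,
    strict) or indeterminate."""
    if nonamp_threshold > amp_threshold:
        raise InputError(
            f"nonamp_threshold {nonamp_threshold} exceeds amp_threshold {amp_threshold}"
        )
    if cn_ratio <= 0:
        raise InputError(f"copy-number ratio must be positive, got {cn_ratio}")
    if cn_ratio > amp_threshold:
        return AMPLIFIED
    if cn_ratio < nonamp_threshold:
        return NON_AMPLIFIED
    return INDETERMINATE


def high_expression_gate(values: pd.Series, percentile: float = 75.0) -> set[str]:
    """Samples at or above the given percentile of index-gene expression.

    The cut is the linear-interpolation quantile of the full cohort
    distribution and membership is inclusive (>= cut), so with all-equal
    values every sample passes.
    """
    if len(values) < 4:
        raise InputError("high-expression gate needs at least 4 samples")
    cut = float(np.percentile(values.to_numpy(dtype=float), percentile))
    return set(values.index[values >= cut])


def define_groups(
    study: CohortStudy,
    amp_threshold: float = 1.5,
    nonamp_threshold: float = 1.1,
    percentile: float = 75.0,
) -> pd.Series:
    """Label each sample amplified_high / nonamplified_high / excluded."""
    high = high_expression_gate(study.expression.loc[study.index_gene], percentile)
    labels = {}
    for sample in study.samples:
        status = call_amplification(
            float(study.cn_ratio[sample]), amp_threshold, nonamp_threshold
        )
        if sample in high and status == AMPLIFIED:
            labels[sample] = AMP_HIGH
        elif sample in high and status == NON_AMPLIFIED:
            labels[sample] = NONAMP_HIGH
        else:
            labels[sample] = EXCLUDED
    return pd.Series(labels, name="group").loc[study.samples]


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

@dataclass
class SamResult:
    genes: list[str]
    d: np.ndarray
    s: np.ndarray
    q: np.ndarray
    s0: float
    n_perm: int
    seed: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"d": self.d, "s": self.s, "q": self.q}, index=self.genes)


def _pooled_stats(X: np.ndarray, ia: np.ndarray, ib: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    na, nb = len(ia), len(ib)
    A, B = X[:, ia], X[:, ib]
    ma, mb = A.mean(axis=1), B.mean(axis=1)
    ss = ((A - ma[:, None]) ** 2).sum(axis=1) + ((B - mb[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / na + 1.0 / nb) * ss / (na + nb - 2))
    return ma - mb, s


def select_s0(diff: np.ndarray, s: np.ndarray) -> float:
    """Fudge constant: the percentile of {s_i} minimizing the coefficient of
    variation of the d-spread across quantile bins of s."""
    n = len(s)
    alphas = np.arange(0, 101, 5)
    candidates = np.percentile(s, alphas)
    n_bins = min(100, max(3, n // 20))
    edges = np.percentile(s, np.linspace(0, 100, n_bins + 1))
    bin_idx = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, n_bins - 1)
    best_s0, best_cv = float(candidates[0]), np.inf
    for s0 in candidates:
        d = diff / (s + s0)
        spreads = []
        for b in range(n_bins):
            db = d[bin_idx == b]
            if len(db) < 2:
                continue
            mad = np.median(np.abs(db - np.median(db))) / 0.64
            spreads.append(mad)
        spreads = np.asarray(spreads)
        if len(spreads) < 2 or spreads.mean() == 0:
            continue
        cv = spreads.std(ddof=1) / spreads.mean()
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def sam_two_class(
    expression: pd.DataFrame,
    labels: pd.Series | Mapping[str, str],
    group_a: str = AMP_HIGH,
    group_b: str = NONAMP_HIGH,
    n_perm: int = 200,
    seed: int = 0,
    s0: float | None = None,
) -> SamResult:
    """Two-class SAM with label-permutation FDR.

    d > 0 means higher expression in ``group_a``.  ``s0`` overrides the
    automatic fudge-constant selection (s0 = 0 recovers the plain pooled-
    variance t-like ratio).  Identical seed and inputs give identical q.
    """
    if n_perm < 10:
        raise InputError(f"n_perm must be >= 10, got {n_perm}")
    labels = pd.Series(labels)
    cols = [c for c in expression.columns if labels.get(c) in (group_a, group_b)]
    lab = labels.loc[cols].to_numpy()
    ia = np.flatnonzero(lab == group_a)
    ib = np.flatnonzero(lab == group_b)
    if len(ia) < 2 or len(ib) < 2:
        raise InputError(
            f"need >= 2 samples per group (got {len(ia)} {group_a!r}, {len(ib)} {group_b!r})"
        )
    X = expression[cols].to_numpy(dtype=float)
    genes = list(expression.index)
    n_genes = len(genes)

    diff, s = _pooled_stats(X, ia, ib)
    if s0 is None:
        if np.all(s == 0):
            raise InputError("all genes have zero within-group variance; set s0 explicitly")
        s0 = select_s0(diff, s)
    if np.any((s + s0) == 0):
        # constant rows with s0 = 0: d defined as 0 when the means agree
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where((s + s0) > 0, diff / (s + s0), np.where(diff == 0, 0.0, np.inf * np.sign(diff)))
        if not np.isfinite(d).all():
            raise InputError("zero variance with nonzero mean difference and s0 = 0")
    else:
        d = diff / (s + s0)

    rng = np.random.default_rng(seed)
    na = len(ia)
    all_idx = np.concatenate([ia, ib])
    perm_sorted = np.empty((n_perm, n_genes))
    for b in range(n_perm):
        shuffled = rng.permutation(all_idx)
        pa, pb = shuffled[:na], shuffled[na:]
        pdiff, ps = _pooled_stats(X, pa, pb)
        with np.errstate(invalid="ignore", divide="ignore"):
            pdv = np.where((ps + s0) > 0, pdiff / (ps + s0), 0.0)
        perm_sorted[b] = np.sort(pdv)
    dbar = perm_sorted.mean(axis=0)

    order = np.argsort(d, kind="stable")
    d_sorted = d[order]
    gap = d_sorted - dbar

    # pi0 from the central 50% of the permuted d distribution
    q25, q75 = np.percentile(perm_sorted, [25, 75])
    pi0 = min(1.0, np.count_nonzero((d > q25) & (d < q75)) / (0.5 * n_genes))

    deltas = np.unique(np.abs(gap))
    if len(deltas) > 300:
        deltas = np.unique(np.percentile(deltas, np.linspace(0, 100, 300)))
    deltas = np.concatenate([[0.0], deltas])

    q = np.ones(n_genes)
    flat = perm_sorted  # rows already sorted
    for delta in deltas:
        up = gap > delta
        lo = gap < -delta
        cutup = d_sorted[up].min() if up.any() else np.inf
        cutlow = d_sorted[lo].max() if lo.any() else -np.inf
        called = (d_sorted >= cutup) | (d_sorted <= cutlow)
        n_called = int(called.sum())
        if n_called == 0:
            continue
        # per-permutation false calls beyond the cutpoints
        false = (
            n_genes
            - np.array([np.searchsorted(row, cutup, side="left") for row in flat])
            + np.array([np.searchsorted(row, cutlow, side="right") for row in flat])
        )
        fdr = min(1.0, pi0 * float(np.median(false)) / n_called)
        q[called] = np.minimum(q[called], fdr)

    q_genes = np.empty(n_genes)
    q_genes[order] = q
    return SamResult(genes, d, s, q_genes, float(s0), n_perm, seed)


def overexpressed_in_amplified(sam: SamResult, fdr_threshold: float = 0.10) -> set[str]:
    """Genes significantly higher in the amplified group: d > 0 and q <= threshold."""
    return {
        g for g, d, q in zip(sam.genes, sam.d, sam.q) if d > 0 and q <= fdr_threshold
    }


def write_sam(sam: SamResult, path: str | Path) -> None:
    frame = sam.frame()
    frame["direction"] = np.where(sam.d > 0, "up_in_a", np.where(sam.d < 0, "up_in_b", "none"))
    frame.to_csv(path, sep="\t", float_format="%.6g")
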