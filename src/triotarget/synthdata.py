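"""Seeded synthetic-data generator with planted ground truth.

Emits every input the pipeline consumes — per-line expression tables,
peak BEDs, a gene model BED on a synthetic genome, the genome FASTA with
consensus-motif instances inserted into true peak windows, a tumor-cohort
expression matrix with per-sample copy-number ratios, and a GMT collection
with one planted coordinated set among decoys — together with a truth table
naming the planted direct and indirect targets.

The generator reproduces the statistical regime the analysis assumes, on
the scale the analysis operates at (RPKM-like ratios, not read counts):

* multiplicative log-normal noise on abundances, so observed knockdown /
  control ratios scatter around the planted ratio and straddle the 25%
  call threshold for effects near it;
* direct targets carry both a sub-threshold knockdown ratio and a binding
  peak a few kb from their TSS (within the 100 kb annotation window);
  indirect targets carry the expression response only;
* a fraction of genes sits below the RPKM filter in the control condition
  to exercise the not_measured path;
* amplified cohort samples carry elevated index-locus expression (dosage)
  and an expression shift at the planted direct targets;
* TSSs sit on a regular grid whose spacing exceeds twice the maximum
  planted peak offset, so every true peak is nearest to its own target.

All randomness flows from one integer seed through a single generator in a
fixed order of draws, so identical seeds give byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .integrate import IntegratedCandidate
from .transcriptome import InputError

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults define the reference conditions."""

    seed: int
    n_genes: int = 2000
    n_lines: int = 3
    n_direct_targets: int = 50
    n_indirect_targets: int = 100
    kd_ratio_range: tuple[float, float] = (0.2, 0.7)  # planted knockdown/control
    null_ratio_sigma: float = 0.05  # ln-scale jitter of unregulated ratios around 1
    expression_noise_sigma: float = 0.15  # ln-scale multiplicative noise per condition
    baseline_log_mean: float = 3.0  # ln-scale RPKM baseline (e^3 ~ 20 RPKM)
    baseline_log_sd: float = 1.0
    fraction_below_rpkm_filter: float = 0.05
    gene_spacing: int = 10_000
    genes_per_contig: int = 100
    tss_offset: int = 5_000
    peak_distance_sigma: float = 2_000.0
    peak_max_offset: int = 4_500
    peak_presence_rate: float = 0.9  # per line, per direct target
    n_decoy_peaks: int = 500
    fraction_orphan_peaks: float = 0.1  # decoys on a geneless contig
    motif: str = "CACTY"
    motif_insertion_rate: float = 0.9
    n_amplified: int = 40
    n_nonamplified: int = 200
    n_indeterminate: int = 60
    cn_amplified_range: tuple[float, float] = (1.55, 4.0)
    cn_nonamplified_range: tuple[float, float] = (0.7, 1.08)
    cn_indeterminate_range: tuple[float, float] = (1.12, 1.48)
    amplified_effect_log2: float = 1.5  # shift at direct targets, units of noise SD
    cohort_noise_sd: float = 1.0
    cohort_baseline_mean: float = 6.0
    cohort_baseline_sd: float = 1.0
    index_gene: str = "NKX2-1"
    index_effect_log2: float = 2.0  # dosage-driven index-gene shift in amplified samples
    planted_set_size: int = 20
    n_decoy_sets: int = 10

    def __post_init__(self) -> None:
        if self.n_direct_targets + self.n_indirect_targets > self.n_genes:
            raise InputError("more planted targets than genes")
        if not (0 < self.kd_ratio_range[0] <= self.kd_ratio_range[1]):
            raise InputError("kd_ratio_range must be positive and ordered")
        if self.peak_max_offset * 2 >= self.gene_spacing:
            raise InputError("peak_max_offset must be below half the gene spacing")
        for name in ("n_genes", "n_lines", "n_direct_targets", "n_indirect_targets",
                     "n_decoy_peaks", "n_amplified", "n_nonamplified", "n_indeterminate"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")


@dataclass
class SimulationResult:
    out_dir: Path
    lines: list[str]
    paths: dict[str, Path]
    truth: pd.DataFrame
    config: SimulationConfig

    @property
    def direct_targets(self) -> set[str]:
        return set(self.truth.index[self.truth["is_direct_target"]])


def _wrap_fasta(seq: bytes, width: int = 80) -> str:
    return "\n".join(
        seq[i : i + width].decode() for i in range(0, len(seq), width)
    )


def simulate(config: SimulationConfig, out_dir: str | Path) -> SimulationResult:
    """Write the full synthetic study bundle into ``out_dir``."""
    rng = np.random.default_rng(config.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    width = max(4, len(str(config.n_genes)))
    genes = [f"G{i:0{width}d}" for i in range(1, config.n_genes + 1)]
    lines = [f"line{i + 1}" for i in range(config.n_lines)]

    # --- planted roles -----------------------------------------------------
    n_low = int(round(config.fraction_below_rpkm_filter * config.n_genes))
    shuffled = list(rng.permutation(genes))
    low_expr = set(shuffled[:n_low])
    eligible = shuffled[n_low:]
    direct = sorted(eligible[: config.n_direct_targets])
    indirect = sorted(eligible[config.n_direct_targets:
                               config.n_direct_targets + config.n_indirect_targets])
    direct_set, indirect_set = set(direct), set(indirect)

    lo, hi = config.kd_ratio_range
    planted_ratio = pd.DataFrame(1.0, index=genes, columns=lines)
    for line in lines:
        for g in genes:
            if g in direct_set or g in indirect_set:
                planted_ratio.loc[g, line] = rng.uniform(lo, hi)
            else:
                planted_ratio.loc[g, line] = float(
                    np.exp(rng.normal(0.0, config.null_ratio_sigma))
                )

    # --- gene model on a synthetic genome ----------------------------------
    n_contigs = int(np.ceil(config.n_genes / config.genes_per_contig))
    contig_len = 2 * config.tss_offset + config.gene_spacing * config.genes_per_contig
    contigs = {f"chr{i + 1}": contig_len for i in range(n_contigs)}
    contigs["chrU"] = 200_000  # geneless contig: its peaks stay unassigned

    models = []  # (gene, chrom, strand, tss, start, end)
    tss_of: dict[str, tuple[str, int]] = {}
    for i, g in enumerate(genes):
        chrom = f"chr{i // config.genes_per_contig + 1}"
        tss = config.tss_offset + (i % config.genes_per_contig) * config.gene_spacing
        strand = "+" if rng.random() < 0.5 else "-"
        span = int(rng.integers(500, 4000))
        if strand == "+":
            start, end = tss, tss + span
        else:
            start, end = tss + 1 - span, tss + 1
        models.append((chrom, max(0, start), end, g, 0, strand))
        tss_of[g] = (chrom, tss)
    genes_bed = out / "genes.bed"
    with open(genes_bed, "w") as fh:
        for chrom, start, end, g, score, strand in models:
            fh.write(f"{chrom}\t{start}\t{end}\t{g}\t{score}\t{strand}\n")
    paths["genes"] = genes_bed

    # --- per-line expression tables ----------------------------------------
    sigma = config.expression_noise_sigma
    for line in lines:
        baseline = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd,
                                     config.n_genes))
        for j, g in enumerate(genes):
            if g in low_expr:
                baseline[j] = rng.uniform(0.05, 0.8)
        noise_c = np.exp(rng.normal(0.0, sigma, config.n_genes))
        noise_k = np.exp(rng.normal(0.0, sigma, config.n_genes))
        control = baseline * noise_c
        knockdown = baseline * planted_ratio[line].to_numpy() * noise_k
        frame = pd.DataFrame({"knockdown": knockdown, "control": control}, index=genes)
        frame.index.name = "gene"
        p = out / f"expr_{line}.tsv"
        frame.to_csv(p, sep="\t", float_format="%.6g")
        paths[f"expr_{line}"] = p

    # --- peaks per line + motif placements ---------------------------------
    motif_targets: list[tuple[str, int]] = []  # (chrom, insertion start)
    peak_distance = pd.DataFrame(np.nan, index=genes, columns=lines)
    motif_len = len(config.motif)
    for line in lines:
        rows = []
        for g in direct:
            if rng.random() >= config.peak_presence_rate:
                continue
            chrom, tss = tss_of[g]
            d = int(np.clip(round(rng.normal(0.0, config.peak_distance_sigma)),
                            -config.peak_max_offset, config.peak_max_offset))
            center = tss + d
            w = int(rng.integers(150, 400))
            start = max(0, center - w // 2)
            score = float(rng.uniform(20.0, 100.0))
            rows.append((chrom, start, start + w, f"{line}_peak_{g}", score))
            peak_distance.loc[g, line] = d
            if rng.random() < config.motif_insertion_rate:
                ins = center - 45 + int(rng.integers(0, 86 - motif_len))
                motif_targets.append((chrom, max(0, ins)))
        gene_chroms = [c for c in contigs if c != "chrU"]
        n_orphan = int(round(config.fraction_orphan_peaks * config.n_decoy_peaks))
        for k in range(config.n_decoy_peaks):
            if k < n_orphan:
                chrom = "chrU"
            else:
                chrom = gene_chroms[int(rng.integers(0, len(gene_chroms)))]
            w = int(rng.integers(150, 400))
            start = int(rng.integers(0, contigs[chrom] - w))
            score = float(rng.uniform(1.0, 60.0))
            rows.append((chrom, start, start + w, f"{line}_decoy_{k}", score))
        p = out / f"peaks_{line}.bed"
        with open(p, "w") as fh:
            for chrom, start, end, name, score in rows:
                fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score:.4f}\n")
        paths[f"peaks_{line}"] = p

    # --- genome FASTA with motif instances ---------------------------------
    genome: dict[str, bytearray] = {}
    for chrom, length in contigs.items():
        idx = rng.integers(0, 4, size=length)
        genome[chrom] = bytearray(_BASES[idx].tobytes())
    iupac = {"A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT", "S": "CG",
             "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT", "H": "ACT",
             "V": "ACG", "N": "ACGT"}
    for chrom, ins in motif_targets:
        instance = "".join(
            iupac[ch][int(rng.integers(0, len(iupac[ch])))] for ch in config.motif.upper()
        )
        genome[chrom][ins : ins + motif_len] = instance.encode()
    genome_fa = out / "genome.fa"
    with open(genome_fa, "w") as fh:
        for chrom in contigs:
            fh.write(f">{chrom}\n{_wrap_fasta(bytes(genome[chrom]))}\n")
    paths["genome"] = genome_fa

    # --- tumor cohort -------------------------------------------------------
    n_samples = config.n_amplified + config.n_nonamplified + config.n_indeterminate
    samples = [f"S{i:04d}" for i in range(1, n_samples + 1)]
    status = (["amplified"] * config.n_amplified
              + ["non_amplified"] * config.n_nonamplified
              + ["indeterminate"] * config.n_indeterminate)
    order = rng.permutation(n_samples)
    status = [status[i] for i in order]
    cn = np.empty(n_samples)
    for i, st in enumerate(status):
        if st == "amplified":
            cn[i] = rng.uniform(*config.cn_amplified_range)
        elif st == "non_amplified":
            cn[i] = rng.uniform(*config.cn_nonamplified_range)
        else:
            cn[i] = rng.uniform(*config.cn_indeterminate_range)

    baseline = rng.normal(config.cohort_baseline_mean, config.cohort_baseline_sd,
                          config.n_genes)
    expr = (baseline[:, None]
            + rng.normal(0.0, config.cohort_noise_sd, (config.n_genes, n_samples)))
    amp_cols = np.array([st == "amplified" for st in status])
    direct_rows = np.array([g in direct_set for g in genes])
    expr[np.ix_(direct_rows, amp_cols)] += config.amplified_effect_log2
    index_expr = 8.0 + rng.normal(0.0, 1.0, n_samples)
    index_expr[amp_cols] += config.index_effect_log2
    cohort = pd.DataFrame(expr, index=genes, columns=samples)
    cohort.loc[config.index_gene] = index_expr
    cohort.index.name = "gene"
    p = out / "cohort_expression.tsv"
    cohort.to_csv(p, sep="\t", float_format="%.6g")
    paths["cohort_expression"] = p
    meta = pd.DataFrame({"sample": samples, "cn_ratio": cn})
    p = out / "cohort_samples.tsv"
    meta.to_csv(p, sep="\t", index=False, float_format="%.6g")
    paths["cohort_samples"] = p

    # --- gene sets ----------------------------------------------------------
    nulls = sorted(set(genes) - direct_set - indirect_set - low_expr)
    nulls = list(rng.permutation(nulls))
    gmt = out / "sets.gmt"
    with open(gmt, "w") as fh:
        planted = direct[: config.planted_set_size]
        fh.write("PLANTED_DIRECT_RESPONSE\tsynthetic planted set\t" + "\t".join(planted) + "\n")
        for k in range(config.n_decoy_sets):
            members = nulls[k * config.planted_set_size : (k + 1) * config.planted_set_size]
            fh.write(f"DECOY_{k + 1:02d}\tsynthetic decoy set\t" + "\t".join(members) + "\n")
    paths["gmt"] = gmt

    # --- truth table --------------------------------------------------------
    truth = pd.DataFrame(index=pd.Index(genes, name="gene"))
    truth["is_direct_target"] = [g in direct_set for g in genes]
    truth["is_indirect_target"] = [g in indirect_set for g in genes]
    truth["is_below_filter"] = [g in low_expr for g in genes]
    for line in lines:
        truth[f"ratio_{line}"] = planted_ratio[line]
        truth[f"peak_distance_{line}"] = peak_distance[line]
    truth["cohort_shift_log2"] = np.where(
        truth["is_direct_target"], config.amplified_effect_log2, 0.0
    )
    p = out / "truth.tsv"
    truth.to_csv(p, sep="\t", float_format="%.6g")
    paths["truth"] = p

    manifest = {
        "seed": config.seed,
        "lines": lines,
        "index_gene": config.index_gene,
        "files": {k: str(v.name) for k, v in paths.items()},
    }
    mp = out / "manifest.yaml"
    with open(mp, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    paths["manifest"] = mp

    return SimulationResult(out, lines, paths, truth, config)


@dataclass
class RecoveryMetrics:
    tp: int
    fp: int
    fn: int
    precision: float | None  # None when no candidates were produced
    recall: float


def evaluate_recovery(
    candidates: Sequence[IntegratedCandidate], truth: pd.DataFrame
) -> RecoveryMetrics:
    """Precision/recall of nominated genes against the planted direct targets."""
    if truth.empty:
        raise InputError("empty truth table")
    planted = set(truth.index[truth["is_direct_target"]])
    nominated = {c.gene for c in candidates}
    tp = len(nominated & planted)
    fp = len(nominated - planted)
    fn = len(planted - nominated)
    precision = tp / len(nominated) if nominated else None
    recall = tp / len(planted) if planted else 0.0
    return RecoveryMetrics(tp, fp, fn, precision, recall)
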