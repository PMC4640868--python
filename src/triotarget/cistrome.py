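"""ChIP peak annotation, TSS-distance profiling and IUPAC consensus scanning.

Peaks (BED, 0-based half-open) are assigned to the nearest transcription
start site on the same chromosome within a window (default 100 kb), with a
strand-oriented signed distance (positive = downstream of the TSS in the
gene's direction).  Windows around the strongest gene-associated peaks can
be extracted from a genome FASTA and scanned for an IUPAC consensus such as
the Nkx2 site CACTY (extended form CHCTY), with a per-sequence nucleotide
shuffle as enrichment background.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from pyfaidx import Fasta

from .transcriptome import InputError

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    score: float
    rank: int  # 1 = strongest
    summit: int | None = None


@dataclass(frozen=True)
class GeneModel:
    gene: str
    chrom: str
    strand: str
    tss: int
    span_start: int
    span_end: int


@dataclass(frozen=True)
class PeakAnnotation:
    peak: Peak
    gene: str | None
    distance: int | None  # signed bp, strand-oriented; None when unassigned


@dataclass
class AnnotationResult:
    """Per-peak annotations plus the gene -> best (lowest) peak rank map."""

    annotations: list[PeakAnnotation]
    gene_best_rank: dict[str, int]

    @property
    def assigned(self) -> list[PeakAnnotation]:
        return [a for a in self.annotations if a.gene is not None]


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    offset: int  # 0-based, plus-strand coordinates
    strand: str
    matched: str


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def _rank_peaks(raw: list[tuple[str, int, int, float, int | None]]) -> list[Peak]:
    order = sorted(range(len(raw)), key=lambda i: (-raw[i][3], raw[i][0], raw[i][1]))
    peaks = [None] * len(raw)
    for rank, i in enumerate(order, start=1):
        chrom, start, end, score, summit = raw[i]
        peaks[i] = Peak(chrom, start, end, score, rank, summit)
    return peaks  # type: ignore[return-value]


def load_peaks(path: str | Path) -> list[Peak]:
    """Read a BED file of called peaks; ranks assigned by descending score.

    Columns: chrom, start, end[, name[, score]].  Score ties are broken by
    (chrom, start) so ranks are reproducible.
    """
    raw: list[tuple[str, int, int, float, int | None]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise InputError(f"{path}:{lineno}: start {start} >= end {end}")
            score = 0.0
            if len(fields) >= 5 and fields[4] not in ("", "."):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise InputError(f"{path}:{lineno}: non-numeric score") from exc
            if score < 0:
                raise InputError(f"{path}:{lineno}: negative score")
            raw.append((fields[0], start, end, score, None))
    return _rank_peaks(raw)


_GENE_ID_RE = re.compile(r'gene_id\s+"([^"]+)"')


def load_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED6 (0-based) or GTF (1-based, converted on load).

    The format is chosen by extension (.gtf/.gff vs anything else = BED).
    For + strand genes the TSS is the span start; for − strand it is the
    last base of the span (half-open end − 1).
    """
    path = Path(path)
    models: list[GeneModel] = []
    if path.suffix.lower() in (".gtf", ".gff"):
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 9:
                    raise InputError(f"{path}:{lineno}: expected 9 GTF columns")
                if fields[2] != "gene":
                    continue
                m = _GENE_ID_RE.search(fields[8])
                if m is None:
                    raise InputError(f"{path}:{lineno}: no gene_id attribute")
                start, end = int(fields[3]) - 1, int(fields[4])  # to 0-based half-open
                strand = fields[6]
                models.append(_make_gene(m.group(1), fields[0], strand, start, end, f"{path}:{lineno}"))
    else:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 6:
                    raise InputError(f"{path}:{lineno}: expected 6 BED columns (need strand)")
                models.append(
                    _make_gene(fields[3], fields[0], fields[5], int(fields[1]), int(fields[2]), f"{path}:{lineno}")
                )
    seen: set[str] = set()
    for g in models:
        if g.gene in seen:
            raise InputError(f"{path}: duplicate gene {g.gene!r}")
        seen.add(g.gene)
    return models


def _make_gene(gene: str, chrom: str, strand: str, start: int, end: int, where: str) -> GeneModel:
    if strand not in ("+", "-"):
        raise InputError(f"{where}: strand must be + or -, got {strand!r}")
    if start >= end:
        raise InputError(f"{where}: empty span for gene {gene!r}")
    tss = start if strand == "+" else end - 1
    return GeneModel(gene, chrom, strand, tss, start, end)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def peak_reference_point(peak: Peak, reference: str = "midpoint") -> int:
    if reference == "summit" and peak.summit is not None:
        return peak.summit
    if reference not in ("midpoint", "summit"):
        raise InputError(f"reference must be 'midpoint' or 'summit', got {reference!r}")
    return (peak.start + peak.end) // 2


def annotate_peaks(
    peaks: Sequence[Peak],
    genes: Iterable[GeneModel],
    window: int = 100_000,
    reference: str = "midpoint",
) -> AnnotationResult:
    """Assign each peak to its nearest TSS within ``window`` bp.

    Nearest is by absolute distance between the peak reference point
    (midpoint, or summit when recorded and requested) and the TSS, among
    genes on the peak's chromosome; ties go to the lexicographically first
    gene identifier.  The signed distance is strand-oriented: positive
    means the peak lies downstream of the TSS.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    # sort genes by (TSS, gene id) so searchsorted neighbors + id tie-break work
    chrom_arrays = {}
    for chrom, gs in by_chrom.items():
        gs.sort(key=lambda g: (g.tss, g.gene))
        chrom_arrays[chrom] = np.array([g.tss for g in gs])

    annotations: list[PeakAnnotation] = []
    best_rank: dict[str, int] = {}
    for peak in peaks:
        gs = by_chrom.get(peak.chrom)
        if not gs:
            annotations.append(PeakAnnotation(peak, None, None))
            continue
        ref = peak_reference_point(peak, reference)
        tss = chrom_arrays[peak.chrom]
        i = int(np.searchsorted(tss, ref))
        # candidates straddling the insertion point; scan outwards for ties
        cand: list[GeneModel] = []
        best = None
        for j in range(max(0, i - 1), min(len(gs), i + 1)):
            cand.append(gs[j])
        # include any gene sharing the minimal distance (equal-TSS duplicates)
        dmin = min(abs(g.tss - ref) for g in cand)
        lo = i - 1
        while lo >= 0 and abs(gs[lo].tss - ref) == dmin:
            cand.append(gs[lo])
            lo -= 1
        hi = i + 1
        while hi < len(gs) and abs(gs[hi].tss - ref) == dmin:
            cand.append(gs[hi])
            hi += 1
        cand = [g for g in cand if abs(g.tss - ref) == dmin]
        chosen = min(cand, key=lambda g: g.gene)
        if dmin > window:
            annotations.append(PeakAnnotation(peak, None, None))
            continue
        signed = ref - chosen.tss
        if chosen.strand == "-":
            signed = -signed
        annotations.append(PeakAnnotation(peak, chosen.gene, int(signed)))
        if chosen.gene not in best_rank or peak.rank < best_rank[chosen.gene]:
            best_rank[chosen.gene] = peak.rank
    return AnnotationResult(annotations, best_rank)


def tss_distance_profile(
    annotations: Sequence[PeakAnnotation], bin_width: int
) -> dict[int, int]:
    """Histogram of signed TSS distances of assigned peaks.

    Returns a map from the left edge of each half-open bin
    [edge, edge + bin_width) to its count; only non-empty bins appear.
    """
    if bin_width <= 0:
        raise InputError(f"bin_width must be positive, got {bin_width}")
    counts: dict[int, int] = {}
    for a in annotations:
        if a.gene is None:
            continue
        edge = int(np.floor(a.distance / bin_width)) * bin_width
        counts[edge] = counts.get(edge, 0) + 1
    return dict(sorted(counts.items()))


def extract_peak_windows(
    annotations: Sequence[PeakAnnotation],
    genome: str | Path | Fasta,
    width: int = 100,
    top: int = 500,
    reference: str = "midpoint",
) -> list[tuple[str, str]]:
    """Sequences of ``width`` bp centered on the top gene-associated peaks.

    Peaks are selected by ascending rank among assigned peaks; windows are
    clipped at chromosome ends and uppercased.  The sequence id records the
    clipped interval and the peak rank.
    """
    fasta = genome if isinstance(genome, Fasta) else Fasta(str(genome))
    assigned = sorted((a for a in annotations if a.gene is not None), key=lambda a: a.peak.rank)
    out: list[tuple[str, str]] = []
    for a in assigned[:top]:
        peak = a.peak
        if peak.chrom not in fasta:
            raise InputError(f"chromosome {peak.chrom!r} missing from FASTA")
        chrom_len = len(fasta[peak.chrom])
        center = peak_reference_point(peak, reference)
        lo = max(0, center - width // 2)
        hi = min(chrom_len, center + (width - width // 2))
        seq = str(fasta[peak.chrom][lo:hi]).upper()
        out.append((f"{peak.chrom}:{lo}-{hi}|rank{peak.rank}", seq))
    return out


# ---------------------------------------------------------------------------
# motif scanning
# ---------------------------------------------------------------------------

def iupac_regex(pattern: str) -> re.Pattern:
    parts = []
    for ch in pattern.upper():
        if ch not in IUPAC:
            raise InputError(f"invalid IUPAC character {ch!r} in pattern {pattern!r}")
        opts = IUPAC[ch]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    # lookahead so overlapping matches are all reported
    return re.compile(f"(?=({''.join(parts)}))")


def scan_motif(
    sequences: Sequence[tuple[str, str]],
    pattern: str = "CACTY",
    both_strands: bool = True,
) -> tuple[list[MotifHit], dict[str, int]]:
    """All exact IUPAC matches of ``pattern`` in each sequence.

    Minus-strand hits are reported at plus-strand offsets (the leftmost base
    of the match on the plus strand) with strand '−'; ``matched`` is the
    minus-strand text, which satisfies the pattern.
    """
    rx = iupac_regex(pattern)
    L = len(pattern)
    hits: list[MotifHit] = []
    counts: dict[str, int] = {}
    for seq_id, seq in sequences:
        seq = seq.upper()
        n = 0
        for m in rx.finditer(seq):
            hits.append(MotifHit(seq_id, m.start(), "+", m.group(1)))
            n += 1
        if both_strands:
            rc = reverse_complement(seq)
            for m in rx.finditer(rc):
                offset = len(seq) - m.start() - L
                hits.append(MotifHit(seq_id, offset, "-", m.group(1)))
                n += 1
        counts[seq_id] = n
    return hits, counts


def motif_enrichment(
    sequences: Sequence[tuple[str, str]],
    pattern: str = "CACTY",
    n_shuffles: int = 100,
    seed: int = 0,
    both_strands: bool = True,
) -> tuple[float, float]:
    """Fold enrichment and empirical p of motif counts vs nucleotide shuffles.

    Background preserves each sequence's base composition (per-sequence
    letter permutation).  fold = observed / mean shuffled count (0 when
    nothing is observed); p = (1 + #{shuffled >= observed}) / (n_shuffles + 1),
    so p is never below 1 / (n_shuffles + 1).
    """
    if not sequences:
        raise InputError("motif_enrichment requires at least one sequence")
    if n_shuffles < 1:
        raise InputError(f"n_shuffles must be >= 1, got {n_shuffles}")
    rng = np.random.default_rng(seed)
    _, counts = scan_motif(sequences, pattern, both_strands)
    observed = sum(counts.values())
    shuffled_totals = np.empty(n_shuffles)
    arrays = [np.frombuffer(seq.upper().encode(), dtype="S1") for _, seq in sequences]
    for b in range(n_shuffles):
        total = 0
        shuf = []
        for arr in arrays:
            perm = rng.permutation(arr)
            shuf.append(("s", perm.tobytes().decode()))
        _, c = scan_motif(shuf, pattern, both_strands)
        shuffled_totals[b] = sum(c.values())
    mean_bg = float(shuffled_totals.mean())
    if observed == 0:
        fold = 0.0
    elif mean_bg == 0:
        fold = float("inf")
    else:
        fold = observed / mean_bg
    p = (1 + int((shuffled_totals >= observed).sum())) / (n_shuffles + 1)
    return fold, float(p)
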