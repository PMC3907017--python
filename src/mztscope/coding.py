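"""Coding-potential metrics: six-frame maximal ORF length and codon-bias LLR.

The codon-bias score compares, for each codon, its usage frequency
conditional on the encoded amino acid in coding versus noncoding sequence:

    LLR_i = log2(c_i / n_i)

where ``c_i`` and ``n_i`` are the likelihoods of codon *i* conditional on
its amino acid in the coding and noncoding corpora. A transcript is scored
by summing LLR_i over every codon-aligned 90-bp window in all six reading
frames; the reported score is the maximum over all windows. Under the coding
model the expected per-codon LLR is a mixture of per-class Kullback-Leibler
divergences and hence non-negative; under the noncoding model it is
non-positive, which is what makes the max-window score a discriminator.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

BASES = "ACGT"
ALL_CODONS = [a + b + c for a in BASES for b in BASES for c in BASES]
STOP_CODONS = tuple(standard_dna_table.stop_codons)

#: codon -> amino-acid class; stop codons form their own class "*" so that
#: their relative usage still contributes to the conditional LLR.
CODON_TO_AA: dict[str, str] = {
    **standard_dna_table.forward_table,
    **{c: "*" for c in STOP_CODONS},
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CodonLLRTable:
    """Per-codon conditional likelihoods and log-likelihood ratios (bits).

    Invariant: within every amino-acid class the coding likelihoods sum to 1
    and the noncoding likelihoods sum to 1.
    """

    coding: Mapping[str, float]  # c_i, conditional on amino acid
    noncoding: Mapping[str, float]  # n_i, conditional on amino acid
    llr: Mapping[str, float]  # log2(c_i / n_i)

    def __post_init__(self) -> None:
        for table in (self.coding, self.noncoding):
            sums: dict[str, float] = {}
            for codon, p in table.items():
                sums[CODON_TO_AA[codon]] = sums.get(CODON_TO_AA[codon], 0.0) + p
            for aa, s in sums.items():
                if abs(s - 1.0) > 1e-9:
                    raise ValueError(
                        f"conditional likelihoods for class {aa!r} sum to {s}"
                    )


def _read_frequency_table(path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "triplet" not in cols:
        raise ValueError(f"{path}: need a 'triplet' column")
    value_col = next(
        (cols[c] for c in ("frequency", "count", "weight") if c in cols), None
    )
    if value_col is None:
        raise ValueError(f"{path}: need a 'frequency' or 'count' column")
    freqs = {
        str(t).upper(): float(v) for t, v in zip(df[cols["triplet"]], df[value_col])
    }
    missing = set(ALL_CODONS) - set(freqs)
    if missing:
        raise ValueError(f"{path}: missing triplets {sorted(missing)[:5]}...")
    if any(v < 0 for v in freqs.values()):
        raise ValueError(f"{path}: negative frequency")
    return freqs


def build_llr_table(coding_path, noncoding_path) -> CodonLLRTable:
    """Build a :class:`CodonLLRTable` from two 64-triplet frequency TSVs.

    Raw weights (counts or frequencies) are rescaled to a common total of
    1000 (codon-usage per-mil convention); any amino-acid class containing a
    zero weight receives 0.5 pseudo-counts on every codon of that class
    before conditional normalization, which keeps every LLR finite while
    leaving zero-free classes untouched.
    """
    raw_c = _read_frequency_table(coding_path)
    raw_n = _read_frequency_table(noncoding_path)
    cond_c = _conditional_normalize(raw_c)
    cond_n = _conditional_normalize(raw_n)
    llr = {
        codon: float(np.log2(cond_c[codon] / cond_n[codon]))
        for codon in ALL_CODONS
    }
    return CodonLLRTable(coding=cond_c, noncoding=cond_n, llr=llr)


def _conditional_normalize(raw: dict[str, float]) -> dict[str, float]:
    total = sum(raw.values())
    if total <= 0:
        raise ValueError("frequency table sums to zero")
    scaled = {c: 1000.0 * v / total for c, v in raw.items()}
    by_class: dict[str, list[str]] = {}
    for codon in ALL_CODONS:
        by_class.setdefault(CODON_TO_AA[codon], []).append(codon)
    cond: dict[str, float] = {}
    for codons in by_class.values():
        values = {c: scaled[c] for c in codons}
        if any(v == 0.0 for v in values.values()):
            values = {c: v + 0.5 for c, v in values.items()}
        class_total = sum(values.values())
        if class_total <= 0:
            raise ValueError("empty amino-acid class after smoothing")
        for c in codons:
            cond[c] = values[c] / class_total
    return cond


def load_default_tables() -> CodonLLRTable:
    """LLR table from the packaged synthetic coding/noncoding frequency TSVs."""
    data = resources.files("mztscope") / "data"
    return build_llr_table(
        data / "codon_coding_synthetic.tsv",
        data / "triplet_noncoding_synthetic.tsv",
    )


def default_frequency_tables() -> tuple[dict[str, float], dict[str, float]]:
    """Raw (coding, noncoding) per-mil frequency tables as packaged."""
    data = resources.files("mztscope") / "data"
    return (
        _read_frequency_table(data / "codon_coding_synthetic.tsv"),
        _read_frequency_table(data / "triplet_noncoding_synthetic.tsv"),
    )


# ---------------------------------------------------------------------------
# ORF length
# ---------------------------------------------------------------------------

def _clean(seq: str) -> str:
    seq = seq.upper()
    return "".join(b if b in "ACGTN" else "N" for b in seq)


def max_orf_aa(sequence: str) -> int:
    """Maximal ORF length in amino acids over all six reading frames.

    An ORF runs from an ATG to the first in-frame stop; the initial Met is
    counted, the stop is not. A run that reaches the sequence end without a
    stop is counted in full. Codons containing N never act as start or stop.
    """
    seq = _clean(sequence)
    if not seq:
        return 0
    best = 0
    for strand_seq in (seq, revcomp(seq)):
        for offset in range(3):
            codons = [
                strand_seq[i : i + 3]
                for i in range(offset, len(strand_seq) - 2, 3)
            ]
            start: int | None = None
            for i, codon in enumerate(codons):
                if "N" in codon:
                    continue
                if codon in STOP_CODONS:
                    if start is not None:
                        best = max(best, i - start)
                        start = None
                elif codon == "ATG" and start is None:
                    start = i
            if start is not None:  # open-ended run, no stop before the end
                best = max(best, len(codons) - start)
    return best


# ---------------------------------------------------------------------------
# Max-window LLR
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodingScores:
    """Coding-potential metrics for one sequence or spliced transcript."""

    max_orf_aa: int
    max_llr: float
    best_frame: str  # e.g. "+0" / "-2": strand and frame offset of the max
    best_window_start: int  # bp offset of the window within the frame strand


def max_window_llr(
    sequence: str, table: CodonLLRTable, window_bp: int = 90
) -> CodingScores:
    """Maximum codon-LLR sum over sliding codon-aligned windows, six frames.

    Windows of ``window_bp`` slide by one codon within each frame. Sequences
    shorter than ``window_bp`` are scored over each frame's single maximal
    codon run. Codons containing N contribute 0. Window sums use compensated
    summation (``math.fsum``), so scores are independent of summation order
    and reproduce exhaustive per-window enumeration exactly.
    """
    import math

    if window_bp % 3 != 0:
        raise ValueError("window_bp must be divisible by 3")
    seq = _clean(sequence)
    if len(seq) < 3:
        raise ValueError("sequence must be at least 3 bp")
    w = window_bp // 3
    best: tuple[float, str, int] | None = None
    for strand, strand_seq in (("+", seq), ("-", revcomp(seq))):
        for offset in range(3):
            n_codons = (len(strand_seq) - offset) // 3
            if n_codons == 0:
                continue
            llrs = [
                table.llr.get(strand_seq[offset + 3 * i : offset + 3 * i + 3], 0.0)
                if "N" not in strand_seq[offset + 3 * i : offset + 3 * i + 3]
                else 0.0
                for i in range(n_codons)
            ]
            frame = f"{strand}{offset}"
            if len(seq) < window_bp:
                score = math.fsum(llrs)
                if best is None or score > best[0]:
                    best = (score, frame, offset)
            else:
                if n_codons < w:
                    continue  # no complete window in this frame
                for i in range(n_codons - w + 1):
                    score = math.fsum(llrs[i : i + w])
                    if best is None or score > best[0]:
                        best = (score, frame, offset + 3 * i)
    if best is None:
        raise ValueError("no scorable frame")
    score, frame, start = best
    return CodingScores(
        max_orf_aa=max_orf_aa(sequence),
        max_llr=score,
        best_frame=frame,
        best_window_start=start,
    )


# ---------------------------------------------------------------------------
# Scoring gene models against a genome
# ---------------------------------------------------------------------------

def transcript_sequence(model, genome: Mapping[str, str]) -> str:
    """Strand-corrected spliced transcript sequence of a gene model."""
    try:
        chrom_seq = genome[model.chrom]
    except KeyError:
        raise KeyError(f"model {model.model_id}: chromosome {model.chrom} absent")
    chrom_seq = str(chrom_seq)
    for e in model.exons:
        if e.end > len(chrom_seq):
            raise ValueError(
                f"model {model.model_id}: exon {e} outside genome bounds"
            )
    spliced = "".join(chrom_seq[e.start : e.end] for e in model.exons)
    if model.strand == "-":
        spliced = revcomp(spliced)
    return spliced.upper()


def score_models(
    models, genome: Mapping[str, str], table: CodonLLRTable, window_bp: int = 90
) -> dict[str, CodingScores]:
    """Score each model's spliced transcript; keys are model ids."""
    return {
        m.model_id: max_window_llr(transcript_sequence(m, genome), table, window_bp)
        for m in models
    }


def load_genome(path: str) -> dict[str, str]:
    """Read a FASTA file into a chrom -> sequence dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome(genome: Mapping[str, str], path: str, width: int = 70) -> None:
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
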