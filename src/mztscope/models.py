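"""Core domain types shared across the pipeline.

All genomic coordinates are 0-based half-open internally; GFF/GTF 1-based
inclusive coordinates are converted at the I/O boundary.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class Interval:
    """A genomic interval, 0-based half-open.

    ``strand`` is one of ``+``, ``-`` or ``.`` (strandless).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        """True if the two intervals share >= 1 bp on the same chromosome.

        Strand is deliberately ignored; callers enforce strand contracts.
        """
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "Interval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def key(self) -> tuple:
        """Exact-identity key (chrom, start, end, strand)."""
        return (self.chrom, self.start, self.end, self.strand)


@dataclass
class GeneModel:
    """A spliced (or flagged single-exon) transcript model.

    Exons are sorted by start, non-overlapping, and share one chromosome and
    strand. ``status`` holds annotation status codes (see
    :mod:`mztscope.xtev`); ``gene_id`` is assigned by shared-exon grouping.
    """

    model_id: str
    exons: list[Interval]
    source: str = "reference"
    gene_id: str | None = None
    status: set[str] = field(default_factory=set)
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.model_id:
            raise ValueError("model_id must be non-empty")
        if not self.exons:
            raise ValueError(f"model {self.model_id} has no exons")
        self.exons = sorted(self.exons, key=lambda e: (e.start, e.end))
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(
                f"model {self.model_id}: exons must share one chrom and strand"
            )
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"model {self.model_id}: overlapping exons {a} / {b}"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> Interval:
        return Interval(self.chrom, self.start, self.end, self.strand)

    @property
    def spliced(self) -> bool:
        return len(self.exons) >= 2

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def first_exon(self) -> Interval:
        """Strand-aware first exon (rightmost on the minus strand)."""
        if self.strand == "-":
            return self.exons[-1]
        return self.exons[0]

    def five_prime(self) -> int:
        """Position of the 5' end (start of transcription)."""
        return self.end if self.strand == "-" else self.start

    def introns(self) -> list[Interval]:
        """Intron intervals (donor..acceptor, genomic orientation)."""
        return [
            Interval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
            if b.start > a.end
        ]

    def exon_keys(self) -> set[tuple]:
        return {e.key() for e in self.exons}

    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def structural_eq(self, other: "GeneModel") -> bool:
        return (
            self.model_id == other.model_id
            and self.exons == other.exons
            and self.source == other.source
        )


class GeneModelSet:
    """A collection of gene models with unique ids and interval lookup."""

    def __init__(self, models: Iterable[GeneModel] = ()):
        self._models: dict[str, GeneModel] = {}
        for m in models:
            self.add(m)

    def add(self, model: GeneModel) -> None:
        if model.model_id in self._models:
            raise ValueError(f"duplicate model_id {model.model_id!r}")
        self._models[model.model_id] = model

    def __len__(self) -> int:
        return len(self._models)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self._models.values())

    def __contains__(self, model_id: str) -> bool:
        return model_id in self._models

    def __getitem__(self, model_id: str) -> GeneModel:
        return self._models[model_id]

    def ids(self) -> list[str]:
        return list(self._models)

    def overlapping(self, query: Interval, stranded: bool = False) -> list[GeneModel]:
        """Models whose span overlaps ``query`` (>= 1 bp)."""
        hits = []
        for m in self._models.values():
            if m.chrom != query.chrom:
                continue
            if stranded and query.strand != "." and m.strand != query.strand:
                continue
            if m.start < query.end and query.start < m.end:
                hits.append(m)
        return hits

    def structural_eq(self, other: "GeneModelSet") -> bool:
        if set(self._models) != set(other._models):
            return False
        return all(
            self._models[k].structural_eq(other._models[k]) for k in self._models
        )


@dataclass(frozen=True)
class Peak:
    """A (strandless) ChIP-seq peak such as an H3K4me3 interval."""

    interval: Interval
    score: float | None = None

    def __post_init__(self) -> None:
        if self.score is not None and self.score < 0:
            raise ValueError("peak score must be non-negative")


@dataclass(frozen=True)
class JunctionRecord:
    """A splice junction (intron interval) with spliced-read support."""

    interval: Interval
    read_support: int = 0

    def __post_init__(self) -> None:
        if self.read_support < 0:
            raise ValueError("read_support must be >= 0")


class SignalTrack:
    """Per-chromosome step coverage (e.g. RNAPII ChIP enrichment).

    Intervals within a chromosome are non-overlapping and carry non-negative
    values. Positions absent from the track contribute 0 to means, so the
    mean over a region is total signal mass divided by region length.
    """

    def __init__(self, records: Iterable[tuple[str, int, int, float]] = ()):
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            if value < 0:
                raise ValueError("signal values must be >= 0")
            if not 0 <= start < end:
                raise ValueError(f"invalid signal interval {chrom}:{start}-{end}")
            per_chrom.setdefault(chrom, []).append((start, end, value))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._values: dict[str, np.ndarray] = {}
        for chrom, recs in per_chrom.items():
            recs.sort()
            for (s1, e1, _), (s2, _, _) in zip(recs, recs[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"overlapping signal intervals on {chrom} at {s2} < {e1}"
                    )
            self._starts[chrom] = np.array([r[0] for r in recs], dtype=np.int64)
            self._ends[chrom] = np.array([r[1] for r in recs], dtype=np.int64)
            self._values[chrom] = np.array([r[2] for r in recs], dtype=float)

    def mean(self, interval: Interval) -> float:
        """Length-weighted mean signal over ``interval`` (uncovered bases = 0)."""
        length = len(interval)
        if length <= 0:
            raise ValueError("mean over zero-length interval")
        starts = self._starts.get(interval.chrom)
        if starts is None:
            return 0.0
        ends = self._ends[interval.chrom]
        values = self._values[interval.chrom]
        lo = bisect.bisect_right(ends.tolist(), interval.start)
        hi = bisect.bisect_left(starts.tolist(), interval.end)
        if lo >= hi:
            return 0.0
        ov = np.minimum(ends[lo:hi], interval.end) - np.maximum(
            starts[lo:hi], interval.start
        )
        ov = np.clip(ov, 0, None)
        return float((ov * values[lo:hi]).sum() / length)

    def records(self) -> list[tuple[str, int, int, float]]:
        out = []
        for chrom in sorted(self._starts):
            for s, e, v in zip(
                self._starts[chrom], self._ends[chrom], self._values[chrom]
            ):
                out.append((chrom, int(s), int(e), float(v)))
        return out


class ConservationTrack(SignalTrack):
    """phastCons-style per-base conservation scores in [0, 1], with gaps.

    Unlike :class:`SignalTrack`, uncovered positions are *missing*, not zero:
    means are taken over covered bases only.
    """

    def __init__(self, records: Iterable[tuple[str, int, int, float]] = ()):
        records = list(records)
        for _, _, _, v in records:
            if not 0.0 <= v <= 1.0:
                raise ValueError("conservation scores must lie in [0, 1]")
        super().__init__(records)

    def mean_covered(self, intervals: Iterable[Interval]) -> float | None:
        """Mean score over covered bases of ``intervals``; None if none covered."""
        total = 0.0
        covered = 0
        for interval in intervals:
            starts = self._starts.get(interval.chrom)
            if starts is None:
                continue
            ends = self._ends[interval.chrom]
            values = self._values[interval.chrom]
            lo = bisect.bisect_right(ends.tolist(), interval.start)
            hi = bisect.bisect_left(starts.tolist(), interval.end)
            if lo >= hi:
                continue
            ov = np.minimum(ends[lo:hi], interval.end) - np.maximum(
                starts[lo:hi], interval.start
            )
            ov = np.clip(ov, 0, None)
            total += float((ov * values[lo:hi]).sum())
            covered += int(ov.sum())
        if covered == 0:
            return None
        return total / covered


@dataclass
class QpcrTable:
    """RT-qPCR cycle-threshold (Ct) measurements for ddCt fold changes.

    ``rows`` maps (gene, stage) -> Ct; ``normalizer`` is the reference gene
    (e.g. odc1) and ``reference_stage`` the stage fold changes are relative to.
    """

    rows: Mapping[tuple[str, str], float]
    normalizer: str
    reference_stage: str

    def __post_init__(self) -> None:
        for (gene, stage), ct in self.rows.items():
            if ct <= 0:
                raise ValueError(f"Ct must be > 0 (gene {gene}, stage {stage})")

    def ct(self, gene: str, stage: str) -> float:
        try:
            return self.rows[(gene, stage)]
        except KeyError:
            raise KeyError(f"no Ct for gene {gene!r} at stage {stage!r}") from None
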