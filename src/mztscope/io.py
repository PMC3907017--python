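"""Readers and writers for the standard formats the pipeline touches.

GFF3/GTF files are parsed through :mod:`gffutils` (in-memory database);
BED, bedGraph and TSV tables through :mod:`pandas`. Internal coordinates
are 0-based half-open; GFF/GTF 1-based inclusive coordinates are converted
here at the boundary.
"""

from __future__ import annotations

import os
from typing import Iterable

import gffutils
import pandas as pd

from .models import (
    ConservationTrack,
    GeneModel,
    GeneModelSet,
    Interval,
    JunctionRecord,
    Peak,
    QpcrTable,
    SignalTrack,
)


class ParseError(ValueError):
    """Raised when an input file does not conform to its declared dialect."""


def _infer_dialect(path: str) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".gff", ".gff3"):
        return "gff3"
    if ext == ".gtf":
        return "gtf"
    if ext == ".bed":
        return "bed12"
    raise ParseError(f"cannot infer dialect from extension {ext!r}; pass dialect=")


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

_TRANSCRIPT_TYPES = {"mRNA", "transcript", "lnc_RNA", "ncRNA", "lincRNA"}


def parse_gene_models(path: str, dialect: str | None = None) -> GeneModelSet:
    """Parse gene models from a GFF3, GTF or BED12 file.

    GFF/GTF transcript/exon hierarchies are resolved; 1-based inclusive
    coordinates become 0-based half-open. BED12 blocks become exons.
    """
    dialect = dialect or _infer_dialect(path)
    if dialect == "bed12":
        return _parse_bed12(path)
    if dialect not in ("gff3", "gtf"):
        raise ParseError(f"unknown dialect {dialect!r}")
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except gffutils.exceptions.EmptyInputError:
        return GeneModelSet()
    except Exception as exc:  # gffutils raises a zoo of parse exceptions
        raise ParseError(f"failed to parse {path}: {exc}") from exc

    models = GeneModelSet()
    exons_by_parent: dict[str, list[gffutils.Feature]] = {}
    for exon in db.features_of_type("exon"):
        parents = exon.attributes.get("Parent") or exon.attributes.get(
            "transcript_id"
        )
        if not parents:
            raise ParseError(
                f"{path}: exon at line-less feature {exon.id} has no parent"
            )
        for parent in parents:
            exons_by_parent.setdefault(parent, []).append(exon)

    transcript_meta: dict[str, gffutils.Feature] = {}
    for ttype in _TRANSCRIPT_TYPES:
        for tr in db.features_of_type(ttype):
            tid = tr.id
            if dialect == "gtf":
                tid = tr.attributes.get("transcript_id", [tr.id])[0]
            transcript_meta[tid] = tr

    for tid, exon_feats in exons_by_parent.items():
        exons = []
        for f in exon_feats:
            # GFF/GTF start is 1-based inclusive -> subtract 1; end unchanged
            exons.append(Interval(f.seqid, f.start - 1, f.end, f.strand))
        meta = transcript_meta.get(tid)
        source = "reference"
        attrs: dict = {}
        if meta is not None:
            tr_iv = Interval(meta.seqid, meta.start - 1, meta.end, meta.strand)
            for e in exons:
                if e.start < tr_iv.start or e.end > tr_iv.end:
                    raise ParseError(
                        f"{path}: exon {e} outside transcript span of {tid}"
                    )
            source = meta.source if meta.source not in (".", "") else "reference"
            attrs = {
                k: v[0] if len(v) == 1 else list(v)
                for k, v in meta.attributes.items()
                if k not in ("ID", "Parent")
            }
        gene_id = attrs.pop("gene_id", None)
        status = set(str(attrs.pop("xtev_status", "")).split(",")) - {""}
        models.add(
            GeneModel(
                model_id=tid,
                exons=exons,
                source=attrs.pop("model_source", source),
                gene_id=gene_id,
                status=status,
                attributes=attrs,
            )
        )
    return models


def _parse_bed12(path: str) -> GeneModelSet:
    models = GeneModelSet()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(f"{path}:{lineno}: BED12 needs 12 columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                name, strand = fields[3], fields[5]
                block_count = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if len(sizes) != block_count or len(starts) != block_count:
                raise ParseError(
                    f"{path}:{lineno}: blockCount does not match block lists"
                )
            exons = [
                Interval(chrom, start + off, start + off + size, strand)
                for off, size in zip(starts, sizes)
            ]
            if exons[-1].end != end:
                raise ParseError(
                    f"{path}:{lineno}: blocks do not reach chromEnd"
                )
            models.add(GeneModel(model_id=name, exons=exons, source="reference"))
    return models


def write_gene_models(
    models: GeneModelSet, path: str, dialect: str = "gff3"
) -> None:
    """Write a model set as GFF3 or BED12; output re-parses to an equal set."""
    if dialect == "gff3":
        _write_gff3(models, path)
    elif dialect == "bed12":
        _write_bed12(models, path)
    else:
        raise ParseError(f"unknown dialect {dialect!r}")


def _write_gff3(models: GeneModelSet, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in sorted(models, key=lambda m: (m.chrom, m.start, m.model_id)):
            attrs = [f"ID={m.model_id}", f"model_source={m.source}"]
            if m.gene_id:
                attrs.append(f"gene_id={m.gene_id}")
            if m.status:
                attrs.append(f"xtev_status={','.join(sorted(m.status))}")
            for k, v in m.attributes.items():
                attrs.append(f"{k}={v}")
            fh.write(
                "\t".join(
                    [
                        m.chrom,
                        m.source,
                        "transcript",
                        str(m.start + 1),  # back to 1-based inclusive
                        str(m.end),
                        ".",
                        m.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )
            for i, e in enumerate(m.exons, start=1):
                fh.write(
                    "\t".join(
                        [
                            m.chrom,
                            m.source,
                            "exon",
                            str(e.start + 1),
                            str(e.end),
                            ".",
                            m.strand,
                            ".",
                            f"ID={m.model_id}.exon{i};Parent={m.model_id}",
                        ]
                    )
                    + "\n"
                )


def _write_bed12(models: GeneModelSet, path: str) -> None:
    with open(path, "w") as fh:
        for m in sorted(models, key=lambda m: (m.chrom, m.start, m.model_id)):
            sizes = ",".join(str(len(e)) for e in m.exons)
            starts = ",".join(str(e.start - m.start) for e in m.exons)
            fh.write(
                "\t".join(
                    [
                        m.chrom,
                        str(m.start),
                        str(m.end),
                        m.model_id,
                        "0",
                        m.strand,
                        str(m.start),
                        str(m.end),
                        "0",
                        str(m.n_exons),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Peaks, signal, junctions, conservation
# ---------------------------------------------------------------------------

def parse_peaks(path: str) -> list[Peak]:
    """Parse a BED3+ file of (strandless) peaks; column 5 becomes the score."""
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end")
            score = None
            if len(fields) >= 5 and fields[4] not in (".", ""):
                score = float(fields[4])
            peaks.append(Peak(Interval(fields[0], start, end), score=score))
    return peaks


def write_peaks(peaks: Iterable[Peak], path: str) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            score = "." if p.score is None else f"{p.score:g}"
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}"
                f"\tpeak\t{score}\n"
            )


def parse_signal(path: str) -> SignalTrack:
    """Parse a bedGraph file into a :class:`SignalTrack`."""
    return SignalTrack(_read_bedgraph(path))


def parse_conservation(path: str) -> ConservationTrack:
    """Parse a bedGraph of per-base conservation scores in [0, 1]."""
    return ConservationTrack(_read_bedgraph(path))


def _read_bedgraph(path: str):
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: bedGraph needs 4 columns")
            try:
                records.append(
                    (fields[0], int(fields[1]), int(fields[2]), float(fields[3]))
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_signal(track: SignalTrack, path: str) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.records():
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def parse_junctions(path: str) -> list[JunctionRecord]:
    """Parse a BED-like junction table: chrom, start, end, name, support, strand."""
    juncs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ParseError(f"{path}:{lineno}: junction BED needs 5+ columns")
            strand = fields[5] if len(fields) > 5 else "."
            try:
                juncs.append(
                    JunctionRecord(
                        Interval(fields[0], int(fields[1]), int(fields[2]), strand),
                        read_support=int(fields[4]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return juncs


def write_junctions(junctions: Iterable[JunctionRecord], path: str) -> None:
    with open(path, "w") as fh:
        for i, j in enumerate(junctions):
            iv = j.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tjunc{i}"
                f"\t{j.read_support}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------

class CountTable:
    """Per-exon read counts keyed by (model_id, exon_index, stage, library).

    Absent combinations read as 0. ``library`` is ``PA`` (polyA-selected) or
    ``RZ`` (ribosomal-RNA-depleted); a pooled count sums all conditions.
    """

    LIBRARIES = ("PA", "RZ")

    def __init__(self, counts: dict[tuple[str, int, str, str], int] | None = None):
        self._counts: dict[tuple[str, int, str, str], int] = {}
        if counts:
            for key, value in counts.items():
                self.set(key, value)

    def set(self, key: tuple[str, int, str, str], value: int) -> None:
        model_id, exon_index, stage, library = key
        if library not in self.LIBRARIES:
            raise ValueError(f"library must be PA or RZ, got {library!r}")
        if value < 0:
            raise ValueError(f"negative count for {key}")
        if key in self._counts:
            raise ValueError(f"duplicate count key {key}")
        self._counts[key] = int(value)

    def get(self, model_id: str, exon_index: int, stage: str, library: str) -> int:
        return self._counts.get((model_id, exon_index, stage, library), 0)

    def pooled(self, model_id: str, exon_index: int) -> int:
        """Total count over all stages and libraries for one exon."""
        return sum(
            v
            for (mid, idx, _, _), v in self._counts.items()
            if mid == model_id and idx == exon_index
        )

    def items(self):
        return self._counts.items()

    def __len__(self) -> int:
        return len(self._counts)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"model_id": m, "exon_index": i, "stage": s, "library": l, "count": c}
            for (m, i, s, l), c in self._counts.items()
        ]
        return pd.DataFrame(
            rows, columns=["model_id", "exon_index", "stage", "library", "count"]
        )


def parse_counts(path: str) -> CountTable:
    """Parse a per-exon count TSV with columns model_id, exon_index, stage,
    library, count."""
    df = pd.read_csv(path, sep="\t")
    required = {"model_id", "exon_index", "stage", "library", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if (df["count"] < 0).any():
        bad = df.index[df["count"] < 0][0]
        raise ParseError(f"{path}: negative count at row {bad}")
    table = CountTable()
    for row in df.itertuples(index=False):
        try:
            table.set(
                (str(row.model_id), int(row.exon_index), str(row.stage),
                 str(row.library)),
                int(row.count),
            )
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    return table


def write_counts(table: CountTable, path: str) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def parse_totals(path: str) -> dict[tuple[str, str], int]:
    """Parse per-library total mapped read counts: stage, library, total_mapped."""
    df = pd.read_csv(path, sep="\t")
    required = {"stage", "library", "total_mapped"}
    if required - set(df.columns):
        raise ParseError(f"{path}: need columns {sorted(required)}")
    return {
        (str(r.stage), str(r.library)): int(r.total_mapped)
        for r in df.itertuples(index=False)
    }


def parse_qpcr(path: str, normalizer: str, reference_stage: str) -> QpcrTable:
    """Parse a Ct table with columns gene, stage, ct."""
    df = pd.read_csv(path, sep="\t")
    if {"gene", "stage", "ct"} - set(df.columns):
        raise ParseError(f"{path}: need columns gene, stage, ct")
    rows = {
        (str(r.gene), str(r.stage)): float(r.ct) for r in df.itertuples(index=False)
    }
    return QpcrTable(rows=rows, normalizer=normalizer, reference_stage=reference_stage)
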