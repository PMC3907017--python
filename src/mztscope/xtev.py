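"""Evidence-based gene-model validation, updating and discovery.

The annotation pipeline runs five steps: (1) collect gene models;
(2) update them with assembly/EST evidence linked by shared splice
junctions; (3) validate expression from pooled RNA-seq exon counts;
(4) validate transcription start sites against H3K4me3 peaks, with
RNAPII-supported upstream rescue and downstream alternative-TSS flagging;
(5) choose one representative model per gene. Evidence transcripts that do
not overlap any annotated exon become new gene models (NGM); those with
both expression support and a validated 5' H3K4me3 peak form the
doubly-validated NGM-vv subset.

Status codes (mutually exclusive TSS triple per model):
``TSS_VALIDATED`` (V, first exon overlaps a peak), ``TSS_UPSTREAM_RESCUED``
(U), ``NO_TSS_PEAK`` (X); plus ``EXPRESSED``, ``DOWNSTREAM_ALT_TSS``,
``SELECTED``, ``NGM``, ``NGM_VV`` and ``SINGLE_EXON_EXCLUDED``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

from .io import CountTable
from .models import (
    GeneModel,
    GeneModelSet,
    Interval,
    JunctionRecord,
    Peak,
    SignalTrack,
)

TSS_VALIDATED = "TSS_VALIDATED"
TSS_UPSTREAM_RESCUED = "TSS_UPSTREAM_RESCUED"
NO_TSS_PEAK = "NO_TSS_PEAK"
EXPRESSED = "EXPRESSED"
DOWNSTREAM_ALT_TSS = "DOWNSTREAM_ALT_TSS"
SELECTED = "SELECTED"
NGM = "NGM"
NGM_VV = "NGM_VV"
SINGLE_EXON_EXCLUDED = "SINGLE_EXON_EXCLUDED"


@dataclass
class XtevConfig:
    min_junction_reads: int = 5
    expressed_exon_min_reads: int = 3
    expressed_exon_fraction: Fraction = Fraction(1, 3)
    rnapii_body_ratio: float = 0.5
    max_upstream_search: int = 50_000  # bp; rescue-peak search cap
    ngm_same_strand_only: bool = False  # strand-blind overlap by default
    require_est_and_rnaseq: bool = False  # NGM-vv: expression AND EST

    def __post_init__(self) -> None:
        if self.min_junction_reads <= 0 or self.expressed_exon_min_reads <= 0:
            raise ValueError("read thresholds must be > 0")
        if not 0 < self.expressed_exon_fraction <= 1:
            raise ValueError("expressed_exon_fraction must lie in (0, 1]")
        if self.rnapii_body_ratio <= 0:
            raise ValueError("rnapii_body_ratio must be > 0")


# ---------------------------------------------------------------------------
# Elementary rules
# ---------------------------------------------------------------------------

def filter_junctions(
    junctions: list[JunctionRecord], min_reads: int = 5
) -> list[JunctionRecord]:
    """Keep junctions with at least ``min_reads`` spliced reads."""
    return [j for j in junctions if j.read_support >= min_reads]


def group_gene_models(models: GeneModelSet) -> dict[str, str]:
    """Assign gene ids: models sharing >= 1 identical exon are one gene.

    Exon identity is the exact (chrom, start, end, strand) tuple; gene id is
    the lexicographically smallest member model id. Connected components are
    found by union-find over the shared-exon relation.
    """
    parent: dict[str, str] = {m.model_id: m.model_id for m in models}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    by_exon: dict[tuple, str] = {}
    for m in sorted(models, key=lambda m: m.model_id):
        for key in m.exon_keys():
            if key in by_exon:
                union(by_exon[key], m.model_id)
            else:
                by_exon[key] = m.model_id
    return {m.model_id: find(m.model_id) for m in models}


def update_models_with_evidence(
    models: GeneModelSet,
    evidence: GeneModelSet,
    junctions: list[JunctionRecord],
) -> GeneModelSet:
    """Add evidence exons to models linked by a shared splice junction.

    Evidence transcripts qualify when all their introns are supported (by
    the filtered junction set or by an annotated model's own introns); they
    update a model when they share >= 1 exact intron on the same strand.
    Contributed exons are merged with the originals (overlaps unioned, so
    original exons are extended, never removed) and tagged by position:
    5'/3' extension or internal.
    """
    supported = {j.interval.key() for j in junctions}
    for m in models:
        supported.update(iv.key() for iv in m.introns())
    usable = [
        e
        for e in sorted(evidence, key=lambda e: e.model_id)
        if e.spliced and all(iv.key() in supported for iv in e.introns())
    ]
    ev_by_intron: dict[tuple, list[GeneModel]] = {}
    for e in usable:
        for iv in e.introns():
            ev_by_intron.setdefault(iv.key(), []).append(e)

    updated = GeneModelSet()
    for m in sorted(models, key=lambda m: m.model_id):
        linked: dict[str, GeneModel] = {}
        for iv in m.introns():
            for e in ev_by_intron.get(iv.key(), []):
                linked[e.model_id] = e
        if not linked:
            updated.add(m)
            continue
        merged = _merge_exons(
            m.exons,
            [
                exon
                for e in sorted(linked.values(), key=lambda e: e.model_id)
                for exon in e.exons
            ],
        )
        if [iv for iv in merged] == m.exons:
            updated.add(m)
            continue
        provenance = _tag_added_exons(m, merged)
        new = GeneModel(
            model_id=m.model_id,
            exons=merged,
            source="updated",
            gene_id=m.gene_id,
            status=set(m.status),
            attributes={**m.attributes, "added_exons": provenance},
        )
        updated.add(new)
    return updated


def _merge_exons(
    original: list[Interval], added: list[Interval]
) -> list[Interval]:
    intervals = sorted(original + added, key=lambda e: (e.start, e.end))
    merged: list[Interval] = []
    for iv in intervals:
        if merged and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                last = merged.pop()
                merged.append(Interval(last.chrom, last.start, iv.end, last.strand))
        else:
            merged.append(iv)
    return merged


def _tag_added_exons(model: GeneModel, merged: list[Interval]) -> list[str]:
    tags = []
    original_keys = model.exon_keys()
    for iv in merged:
        if iv.key() in original_keys:
            continue
        if iv.end <= model.start:
            side = "5prime" if model.strand == "+" else "3prime"
        elif iv.start >= model.end:
            side = "3prime" if model.strand == "+" else "5prime"
        else:
            side = "internal"
        tags.append(f"{iv.start}-{iv.end}:{side}")
    return tags


def is_expressed(
    model: GeneModel,
    pooled_counts: dict[tuple[str, int], int],
    config: XtevConfig | None = None,
) -> bool:
    """True when >= 1/3 of the model's exons hold >= 3 pooled reads.

    The fraction is compared exactly (as rationals), with thresholds from
    ``config``.
    """
    cfg = config or XtevConfig()
    n = model.n_exons
    if n == 0:
        raise ValueError(f"model {model.model_id} has no exons")
    n_expr = sum(
        1
        for i in range(n)
        if pooled_counts.get((model.model_id, i), 0)
        >= cfg.expressed_exon_min_reads
    )
    return Fraction(n_expr, n) >= cfg.expressed_exon_fraction


def expressed_exon_count(
    model: GeneModel,
    pooled_counts: dict[tuple[str, int], int],
    min_reads: int = 3,
) -> int:
    return sum(
        1
        for i in range(model.n_exons)
        if pooled_counts.get((model.model_id, i), 0) >= min_reads
    )


def validate_tss(model: GeneModel, peaks: list[Peak]) -> bool:
    """True when the strand-aware first exon overlaps a peak by >= 1 bp."""
    if model.strand not in ("+", "-"):
        raise ValueError(f"model {model.model_id} is unstranded")
    first = model.first_exon()
    return any(first.overlaps(p.interval) for p in peaks)


@dataclass
class RescueResult:
    peak: Peak
    putative_tss: int
    region: Interval | None  # peak-to-gene gap the RNAPII test ran over
    rnapii_ratio: float


def rescue_upstream_tss(
    gene_models: list[GeneModel],
    peaks: list[Peak],
    rnapii: SignalTrack,
    all_models: GeneModelSet,
    config: XtevConfig | None = None,
) -> RescueResult | None:
    """Look for an upstream TSS when no model of the gene validated.

    The nearest strand-aware upstream peak (within the search cap) rescues
    the gene when (a) no model of a *different* gene lies between peak and
    5' exon and (b) the mean RNAPII over that gap is at least
    ``rnapii_body_ratio`` times the gene-body mean (first-exon start to
    last-exon end, introns included). The gap excludes the peak and the 5'
    exon; a zero-length gap passes the RNAPII test trivially.
    """
    cfg = config or XtevConfig()
    if not gene_models:
        raise ValueError("empty gene")
    chrom = gene_models[0].chrom
    strand = gene_models[0].strand
    gene_ids = {m.gene_id for m in gene_models}
    gstart = min(m.start for m in gene_models)
    gend = max(m.end for m in gene_models)
    body = Interval(chrom, gstart, gend, strand)

    if strand == "+":
        upstream = [
            p
            for p in peaks
            if p.interval.chrom == chrom
            and p.interval.end <= gstart
            and gstart - p.interval.end <= cfg.max_upstream_search
        ]
        upstream.sort(key=lambda p: -p.interval.end)  # nearest first
    else:
        upstream = [
            p
            for p in peaks
            if p.interval.chrom == chrom
            and p.interval.start >= gend
            and p.interval.start - gend <= cfg.max_upstream_search
        ]
        upstream.sort(key=lambda p: p.interval.start)

    body_mean = rnapii.mean(body)
    for peak in upstream:
        if strand == "+":
            gap = (peak.interval.end, gstart)
        else:
            gap = (gend, peak.interval.start)
        region = (
            Interval(chrom, gap[0], gap[1], strand) if gap[0] < gap[1] else None
        )
        if region is not None:
            blockers = [
                m
                for m in all_models.overlapping(region)
                if m.gene_id not in gene_ids
            ]
            if blockers:
                continue
            if body_mean > 0:
                ratio = rnapii.mean(region) / body_mean
            else:
                ratio = float("inf")
            if ratio < cfg.rnapii_body_ratio:
                continue
        else:
            ratio = float("inf")
        tss = peak.interval.end if strand == "+" else peak.interval.start
        return RescueResult(
            peak=peak, putative_tss=tss, region=region, rnapii_ratio=ratio
        )
    return None


def flag_downstream_alt_tss(model: GeneModel, peaks: list[Peak]) -> bool:
    """Peak within the model span strictly downstream of the first exon."""
    if model.strand not in ("+", "-"):
        raise ValueError(f"model {model.model_id} is unstranded")
    first = model.first_exon()
    if model.strand == "+":
        if first.end >= model.end:
            return False
        region = Interval(model.chrom, first.end, model.end, model.strand)
    else:
        if model.start >= first.start:
            return False
        region = Interval(model.chrom, model.start, first.start, model.strand)
    return any(region.overlaps(p.interval) for p in peaks)


def select_representative(
    gene_models: list[GeneModel],
    pooled_counts: dict[tuple[str, int], int],
    config: XtevConfig | None = None,
) -> str:
    """Pick the most likely model of a gene.

    Criteria in decreasing importance: validated TSS (V or U), number of
    expressed exons, number of exons; ties broken by longest genomic span,
    then smallest model id.
    """
    cfg = config or XtevConfig()
    if not gene_models:
        raise ValueError("empty gene")

    def key(m: GeneModel):
        validated = bool(
            {TSS_VALIDATED, TSS_UPSTREAM_RESCUED} & m.status
        )
        n_expr = expressed_exon_count(
            m, pooled_counts, cfg.expressed_exon_min_reads
        )
        return (
            0 if validated else 1,
            -n_expr,
            -m.n_exons,
            -(m.end - m.start),
            m.model_id,
        )

    return min(gene_models, key=key).model_id


def identify_ngm(
    candidates: GeneModelSet,
    reference: GeneModelSet,
    config: XtevConfig | None = None,
) -> tuple[set[str], set[str]]:
    """Split candidates into new gene models and excluded single-exon models.

    NGM: spliced candidates with zero exonic overlap (>= 1 bp, strand-blind
    by default) against any reference exon. Unspliced single-exon
    candidates are routed to the exclusion list.
    """
    cfg = config or XtevConfig()
    ref_exons: dict[str, list[Interval]] = {}
    for m in reference:
        ref_exons.setdefault(m.chrom, []).extend(m.exons)
    ngm: set[str] = set()
    single: set[str] = set()
    for cand in candidates:
        if not cand.spliced:
            single.add(cand.model_id)
            continue
        overlap = False
        for exon in cand.exons:
            for ref in ref_exons.get(cand.chrom, []):
                if cfg.ngm_same_strand_only and ref.strand != exon.strand:
                    continue
                if exon.overlaps(ref):
                    overlap = True
                    break
            if overlap:
                break
        if not overlap:
            ngm.add(cand.model_id)
    return ngm, single


def classify_ngm_vv(
    ngm_ids: set[str],
    candidates: GeneModelSet,
    expressed_ids: set[str],
    est_supported_ids: set[str],
    peaks: list[Peak],
    config: XtevConfig | None = None,
) -> set[str]:
    """NGM with expression (RNA-seq or EST) support and a validated TSS."""
    cfg = config or XtevConfig()
    out = set()
    for mid in ngm_ids:
        cand = candidates[mid]
        if cfg.require_est_and_rnaseq:
            supported = mid in expressed_ids and mid in est_supported_ids
        else:
            supported = mid in expressed_ids or mid in est_supported_ids
        if supported and validate_tss(cand, peaks):
            out.add(mid)
    return out


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

@dataclass
class AnnotationResult:
    models: GeneModelSet  # annotated working set (reference + alternates)
    candidates: GeneModelSet  # evidence models tested for NGM
    genes: dict[str, list[str]]  # gene_id -> member model ids
    gene_status: dict[str, str]  # gene_id -> "V" | "U" | "X"
    selected: dict[str, str]  # gene_id -> representative model id
    rescued_tss: dict[str, int]  # gene_id -> putative upstream TSS
    ngm: set[str] = field(default_factory=set)
    ngm_vv: set[str] = field(default_factory=set)
    single_exon_excluded: set[str] = field(default_factory=set)
    log: list[dict] = field(default_factory=list)

    def status_of(self, model_id: str) -> set[str]:
        if model_id in self.models:
            return self.models[model_id].status
        return self.candidates[model_id].status


def _pooled(counts: CountTable) -> dict[tuple[str, int], int]:
    pooled: dict[tuple[str, int], int] = {}
    for (mid, ei, _, _), c in counts.items():
        pooled[(mid, ei)] = pooled.get((mid, ei), 0) + c
    return pooled


def run_pipeline(
    reference: GeneModelSet,
    evidence: GeneModelSet,
    junctions: list[JunctionRecord],
    counts: CountTable,
    peaks: list[Peak],
    rnapii: SignalTrack,
    config: XtevConfig | None = None,
) -> AnnotationResult:
    """Run the five annotation steps and NGM/NGM-vv discovery.

    Evidence models sharing an identical exon with a reference model join
    that gene as alternate models (this is how fragmented "broken" models
    rejoin their gene); the remaining evidence models are NGM candidates.
    Every status transition is recorded in the machine-readable run log.
    """
    cfg = config or XtevConfig()
    log: list[dict] = []

    def note(model_id: str, status: str, rule: str) -> None:
        log.append({"model": model_id, "status": status, "rule": rule})

    # step 1-2: collect and update with junction-linked evidence
    kept_junctions = filter_junctions(junctions, cfg.min_junction_reads)
    updated = update_models_with_evidence(reference, evidence, kept_junctions)
    # fresh copies: statuses are computed by this run, and callers' model
    # objects must stay untouched
    working = GeneModelSet(
        GeneModel(
            model_id=m.model_id,
            exons=list(m.exons),
            source=m.source,
            attributes=dict(m.attributes),
        )
        for m in updated
    )

    # evidence sharing an exact exon with a reference model becomes an
    # alternate model of that gene; the rest are NGM candidates
    ref_exon_keys = {k for m in working for k in m.exon_keys()}
    candidates = GeneModelSet()
    for e in sorted(evidence, key=lambda e: e.model_id):
        if e.exon_keys() & ref_exon_keys:
            if e.model_id not in working:
                working.add(
                    GeneModel(
                        model_id=e.model_id,
                        exons=list(e.exons),
                        source=e.source,
                        attributes=dict(e.attributes),
                    )
                )
                note(e.model_id, "ALTERNATE", "shares exon with annotated model")
        else:
            candidates.add(
                GeneModel(
                    model_id=e.model_id,
                    exons=list(e.exons),
                    source=e.source,
                    attributes=dict(e.attributes),
                )
            )

    gene_of = group_gene_models(working)
    genes: dict[str, list[str]] = {}
    for m in working:
        m.gene_id = gene_of[m.model_id]
        genes.setdefault(m.gene_id, []).append(m.model_id)
    for members in genes.values():
        members.sort()

    # step 3: expression
    pooled = _pooled(counts)
    for m in working:
        if is_expressed(m, pooled, cfg):
            m.status.add(EXPRESSED)
            note(m.model_id, EXPRESSED, "1/3 of exons with >= 3 reads")

    # step 4: TSS validation, upstream rescue, downstream flags
    gene_status: dict[str, str] = {}
    rescued_tss: dict[str, int] = {}
    for gid, members in sorted(genes.items()):
        any_v = False
        for mid in members:
            m = working[mid]
            if validate_tss(m, peaks):
                m.status.add(TSS_VALIDATED)
                note(mid, TSS_VALIDATED, "first exon overlaps H3K4me3 peak")
                any_v = True
        if any_v:
            gene_status[gid] = "V"
            for mid in members:
                m = working[mid]
                if TSS_VALIDATED not in m.status:
                    m.status.add(NO_TSS_PEAK)
            continue
        rescue = rescue_upstream_tss(
            [working[mid] for mid in members], peaks, rnapii, working, cfg
        )
        if rescue is not None:
            gene_status[gid] = "U"
            rescued_tss[gid] = rescue.putative_tss
            for mid in members:
                working[mid].status.add(TSS_UPSTREAM_RESCUED)
                note(mid, TSS_UPSTREAM_RESCUED, "upstream peak + RNAPII bridge")
        else:
            gene_status[gid] = "X"
            for mid in members:
                working[mid].status.add(NO_TSS_PEAK)
                note(mid, NO_TSS_PEAK, "no peak, no rescue")
    for m in working:
        if flag_downstream_alt_tss(m, peaks):
            m.status.add(DOWNSTREAM_ALT_TSS)
            note(m.model_id, DOWNSTREAM_ALT_TSS, "downstream peak in span")

    # step 5: representative per gene
    selected: dict[str, str] = {}
    for gid, members in sorted(genes.items()):
        chosen = select_representative(
            [working[mid] for mid in members], pooled, cfg
        )
        selected[gid] = chosen
        working[chosen].status.add(SELECTED)
        note(chosen, SELECTED, "representative by (TSS, expressed exons, exons)")

    # discovery: NGM and NGM-vv among non-overlapping evidence
    ngm, single = identify_ngm(candidates, reference, cfg)
    expressed_ids = {
        c.model_id for c in candidates if is_expressed(c, pooled, cfg)
    }
    est_ids = {c.model_id for c in candidates if c.source == "est"}
    ngm_vv = classify_ngm_vv(ngm, candidates, expressed_ids, est_ids, peaks, cfg)
    for mid in sorted(single):
        candidates[mid].status.add(SINGLE_EXON_EXCLUDED)
        note(mid, SINGLE_EXON_EXCLUDED, "unspliced single-exon model")
    for mid in sorted(ngm):
        candidates[mid].status.add(NGM)
        note(mid, NGM, "no exonic overlap with annotated models")
    for mid in sorted(ngm_vv):
        candidates[mid].status.add(NGM_VV)
        note(mid, NGM_VV, "expression support + validated TSS")
    for mid in sorted(expressed_ids):
        candidates[mid].status.add(EXPRESSED)

    return AnnotationResult(
        models=working,
        candidates=candidates,
        genes=genes,
        gene_status=gene_status,
        selected=selected,
        rescued_tss=rescued_tss,
        ngm=ngm,
        ngm_vv=ngm_vv,
        single_exon_excluded=single,
        log=log,
    )
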