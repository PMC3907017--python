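"""Stepwise curation of doubly-validated new gene models into
high-confidence stand-alone lncRNA candidates.

Filters, applied to the NGM-vv set in order (the final set is the
intersection, so order only affects the attrition report):

1. maximal ORF <= 100 amino acids;
2. no downstream same-strand gene whose TSS status is X (no peak) or U
   (upstream-rescued) within the search distance — such a candidate is
   plausibly that gene's stray 5'-UTR fragment;
3. every exon's RPKM >= 1 (pooled maximum across stages/libraries);
4. splicing evidence: >= 1 intron exactly matching a supported junction;
5. an exclusion list consuming the results of manual homology screening
   (BLASTN/BLASTP), which is external to this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .coding import CodingScores
from .models import ConservationTrack, GeneModel, GeneModelSet, JunctionRecord
from .xtev import AnnotationResult


@dataclass
class CurationConfig:
    max_orf_aa: int = 100
    min_exon_rpkm: float = 1.0
    require_splicing_evidence: bool = True
    downstream_search_bp: int = 10_000
    exclusion_list: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.max_orf_aa <= 0 or self.min_exon_rpkm <= 0:
            raise ValueError("curation thresholds must be > 0")


def filter_orf(
    candidate_ids: set[str],
    scores: dict[str, CodingScores],
    max_aa: int = 100,
) -> set[str]:
    """Keep candidates whose six-frame maximal ORF is <= ``max_aa``."""
    missing = candidate_ids - set(scores)
    if missing:
        raise KeyError(f"no coding scores for {sorted(missing)[:3]}")
    return {mid for mid in candidate_ids if scores[mid].max_orf_aa <= max_aa}


def filter_downstream_gene(
    candidate_ids: set[str],
    candidates: GeneModelSet,
    annotation: AnnotationResult,
    max_distance: int = 10_000,
) -> set[str]:
    """Drop candidates that look like 5'-UTR fragments of a downstream gene.

    A candidate is removed iff the nearest downstream gene on the same
    strand (measured from the candidate's 3' end, within ``max_distance``)
    has TSS status X or U.
    """
    out = set()
    for mid in candidate_ids:
        cand = candidates[mid]
        neighbor = _nearest_downstream_gene(cand, annotation, max_distance)
        if neighbor is not None and annotation.gene_status.get(neighbor) in (
            "X",
            "U",
        ):
            continue
        out.add(mid)
    return out


def _nearest_downstream_gene(
    cand: GeneModel, annotation: AnnotationResult, max_distance: int
) -> str | None:
    best: tuple[int, str] | None = None
    three_prime = cand.end if cand.strand == "+" else cand.start
    for m in annotation.models:
        if m.chrom != cand.chrom or m.strand != cand.strand:
            continue
        if cand.strand == "+":
            distance = m.start - three_prime
        else:
            distance = three_prime - m.end
        if distance < 0 or distance > max_distance:
            continue
        if best is None or distance < best[0]:
            best = (distance, m.gene_id or m.model_id)
    return None if best is None else best[1]


def filter_exon_rpkm(
    candidate_ids: set[str],
    exon_rpkm: dict[str, list[float]],
    min_rpkm: float = 1.0,
) -> set[str]:
    """Keep candidates where *every* exon's RPKM is >= ``min_rpkm``."""
    missing = candidate_ids - set(exon_rpkm)
    if missing:
        raise KeyError(f"no exon RPKM for {sorted(missing)[:3]}")
    return {
        mid
        for mid in candidate_ids
        if all(v >= min_rpkm for v in exon_rpkm[mid])
    }


def filter_splicing(
    candidate_ids: set[str],
    candidates: GeneModelSet,
    junctions: list[JunctionRecord],
) -> set[str]:
    """Keep candidates with >= 1 intron exactly matching a supported junction."""
    supported = {j.interval.key() for j in junctions}
    # junction strand bookkeeping differs between sources; match coordinates
    supported_coords = {(c, s, e) for (c, s, e, _) in supported}
    out = set()
    for mid in candidate_ids:
        introns = candidates[mid].introns()
        if any(
            (iv.chrom, iv.start, iv.end) in supported_coords for iv in introns
        ):
            out.add(mid)
    return out


def apply_exclusion_list(
    candidate_ids: set[str], config: CurationConfig
) -> set[str]:
    """Remove manually excluded ids (homology screening results)."""
    return candidate_ids - config.exclusion_list


def mean_conservation(
    model: GeneModel, track: ConservationTrack
) -> float | None:
    """Length-weighted mean conservation over exonic bases; None when the
    track covers none of them."""
    return track.mean_covered(model.exons)


def candidate_exon_rpkm(
    candidates: GeneModelSet,
    counts,
    totals: dict[tuple[str, str], float],
) -> dict[str, list[float]]:
    """Per-exon RPKM per candidate: pooled maximum across (stage, library).

    A transcript strongly expressed at one stage should not fail the exon
    floor because other stages dilute an average.
    """
    by_exon: dict[tuple[str, int], dict[tuple[str, str], int]] = {}
    for (mid, ei, stage, lib), c in counts.items():
        by_exon.setdefault((mid, ei), {})[(stage, lib)] = c
    out: dict[str, list[float]] = {}
    for cand in candidates:
        values = []
        for ei, exon in enumerate(cand.exons):
            kb = len(exon) / 1000.0
            best = 0.0
            for (stage, lib), total in totals.items():
                count = by_exon.get((cand.model_id, ei), {}).get((stage, lib), 0)
                best = max(best, count / kb / (total / 1e6))
            values.append(best)
        out[cand.model_id] = values
    return out


@dataclass
class CurationReport:
    final_ids: set[str]
    table: pd.DataFrame  # one row per NGM-vv candidate, pass/fail per filter
    attrition: dict[str, int]  # survivors after each filter, in order


def curate(
    ngm_vv: set[str],
    candidates: GeneModelSet,
    scores: dict[str, CodingScores],
    annotation: AnnotationResult,
    exon_rpkm: dict[str, list[float]],
    junctions: list[JunctionRecord],
    conservation: ConservationTrack | None = None,
    config: CurationConfig | None = None,
) -> CurationReport:
    """Apply the curation filters in order and report per-filter attrition.

    The filters are intersective, so the final set does not depend on the
    order; the attrition trace follows the order documented above.
    """
    cfg = config or CurationConfig()
    orf_pass = filter_orf(ngm_vv, scores, cfg.max_orf_aa)
    down_pass = filter_downstream_gene(
        ngm_vv, candidates, annotation, cfg.downstream_search_bp
    )
    rpkm_pass = filter_exon_rpkm(ngm_vv, exon_rpkm, cfg.min_exon_rpkm)
    if cfg.require_splicing_evidence:
        splice_pass = filter_splicing(ngm_vv, candidates, junctions)
    else:
        splice_pass = set(ngm_vv)

    step1 = ngm_vv & orf_pass
    step2 = step1 & down_pass
    step3 = step2 & rpkm_pass
    step4 = step3 & splice_pass
    final = apply_exclusion_list(step4, cfg)

    rows = []
    for mid in sorted(ngm_vv):
        cand = candidates[mid]
        rows.append(
            {
                "model_id": mid,
                "orf_aa": scores[mid].max_orf_aa,
                "max_llr": scores[mid].max_llr,
                "pass_orf": mid in orf_pass,
                "pass_downstream": mid in down_pass,
                "pass_exon_rpkm": mid in rpkm_pass,
                "pass_splicing": mid in splice_pass,
                "excluded": mid in cfg.exclusion_list,
                "verdict": mid in final,
                "n_exons": cand.n_exons,
                "transcript_length_nt": cand.spliced_length(),
                "min_exon_rpkm": min(exon_rpkm[mid]) if exon_rpkm.get(mid) else 0.0,
                "mean_conservation": (
                    mean_conservation(cand, conservation)
                    if conservation is not None
                    else None
                ),
            }
        )
    table = pd.DataFrame(rows)
    attrition = {
        "ngm_vv": len(ngm_vv),
        "orf": len(step1),
        "downstream_gene": len(step2),
        "exon_rpkm": len(step3),
        "splicing": len(step4),
        "exclusion_list": len(final),
    }
    return CurationReport(final_ids=final, table=table, attrition=attrition)
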