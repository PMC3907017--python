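"""Expression quantification and maternal/embryonic transcript dynamics.

RPKM (reads per kilobase of exon model per million mapped reads) is
computed per exon and averaged over a gene's non-redundant exon set across
all isoforms. The PA/RZ log2 ratio — polyA-selected over ribo-depleted
expression — proxies the relative polyadenylation state of a transcript:
abundance cancels, poly(A) status does not.

Classification rules:

* maternal:      oocyte RPKM >= 1 in the PA or the RZ library;
* embryonic:     >= 10-fold increase over oocyte in any later stage (PA);
* RZ-enriched:   log2(PA/RZ) <= -0.5 at the queried stage (maternal genes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .io import CountTable
from .models import GeneModelSet, QpcrTable

DEFAULT_PSEUDOCOUNT = 0.01  # RPKM; small against the >= 1 working range


# ---------------------------------------------------------------------------
# RPKM
# ---------------------------------------------------------------------------

def compute_gene_rpkm(
    exon_counts: dict[tuple[str, int], int],
    models: GeneModelSet,
    total_mapped: float,
) -> dict[str, float]:
    """Per-gene RPKM for one (stage, library) condition.

    ``exon_counts`` maps (model_id, exon_index) to the unique-read count of
    that exon. Exon RPKM = count / (exon_kb) / (total_mapped millions); the
    gene value is the arithmetic mean over the gene's deduplicated exons
    across all isoforms (an exon shared by several isoforms contributes
    once, with the count of its lexicographically first carrier).
    Genes are ``gene_id`` groups where assigned, single models otherwise.
    """
    if total_mapped <= 0:
        raise ValueError("total_mapped must be > 0")
    per_gene_exons: dict[str, dict[tuple, float]] = {}
    for model in sorted(models, key=lambda m: m.model_id):
        gene = model.gene_id or model.model_id
        exons = per_gene_exons.setdefault(gene, {})
        for ei, exon in enumerate(model.exons):
            if len(exon) == 0:
                raise ValueError(f"zero-length exon in {model.model_id}")
            key = exon.key()
            if key in exons:
                continue  # non-redundant exon set: first carrier wins
            count = exon_counts.get((model.model_id, ei), 0)
            exons[key] = (
                count / (len(exon) / 1000.0) / (total_mapped / 1e6)
            )
    return {
        gene: float(np.mean(list(exons.values())))
        for gene, exons in per_gene_exons.items()
    }


@dataclass
class ExpressionMatrix:
    """Gene x (stage, library) RPKM values.

    ``rpkm`` has genes as the index and a (stage, library) MultiIndex on
    the columns; stages keep their given developmental order.
    """

    rpkm: pd.DataFrame
    stages: tuple[str, ...]

    def __post_init__(self) -> None:
        if (self.rpkm.values < 0).any():
            raise ValueError("RPKM values must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.rpkm.index)

    def library(self, lib: str) -> pd.DataFrame:
        """Gene x stage frame for one library, in stage order."""
        frame = self.rpkm.xs(lib, axis=1, level=1)
        return frame[[s for s in self.stages if s in frame.columns]]

    def value(self, gene: str, stage: str, lib: str) -> float:
        return float(self.rpkm.at[gene, (stage, lib)])


def build_expression_matrix(
    counts: CountTable,
    models: GeneModelSet,
    totals: dict[tuple[str, str], float],
    stages: tuple[str, ...],
) -> ExpressionMatrix:
    """Assemble the RPKM matrix over every (stage, library) with a total."""
    columns = [
        (stage, lib)
        for stage in stages
        for lib in ("PA", "RZ")
        if (stage, lib) in totals
    ]
    data = {}
    for stage, lib in columns:
        exon_counts = {
            (mid, ei): c
            for (mid, ei, s, l), c in counts.items()
            if s == stage and l == lib
        }
        data[(stage, lib)] = compute_gene_rpkm(
            exon_counts, models, totals[(stage, lib)]
        )
    frame = pd.DataFrame(data).fillna(0.0)
    frame.columns = pd.MultiIndex.from_tuples(columns, names=["stage", "library"])
    return ExpressionMatrix(rpkm=frame, stages=tuple(stages))


# ---------------------------------------------------------------------------
# PA/RZ ratios and class selection
# ---------------------------------------------------------------------------

def log2_pa_rz(
    matrix: ExpressionMatrix,
    stage: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.Series:
    """Per-gene log2((PA + pc) / (RZ + pc)) at one stage."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    try:
        pa = matrix.rpkm[(stage, "PA")]
        rz = matrix.rpkm[(stage, "RZ")]
    except KeyError as exc:
        raise KeyError(f"stage {stage!r} lacks a PA or RZ library") from exc
    return np.log2((pa + pseudocount) / (rz + pseudocount))


def select_maternal(
    matrix: ExpressionMatrix,
    oocyte_stage: str = "oocyte",
    threshold: float = 1.0,
) -> set[str]:
    """Genes with oocyte RPKM >= threshold in the PA or the RZ library."""
    cols = [
        (oocyte_stage, lib)
        for lib in ("PA", "RZ")
        if (oocyte_stage, lib) in matrix.rpkm.columns
    ]
    if not cols:
        raise KeyError(f"no {oocyte_stage!r} condition in matrix")
    mask = (matrix.rpkm[cols] >= threshold).any(axis=1)
    return set(matrix.rpkm.index[mask])


def select_embryonic(
    matrix: ExpressionMatrix,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    fold: float = 10.0,
    library: str = "PA",
    oocyte_stage: str = "oocyte",
) -> set[str]:
    """Genes with a >= ``fold`` increase over oocyte in any later stage."""
    frame = matrix.library(library)
    if oocyte_stage not in frame.columns:
        raise KeyError(f"no {oocyte_stage!r} stage in matrix")
    later = [s for s in frame.columns if s != oocyte_stage]
    if not later:
        raise ValueError("need at least one post-oocyte stage")
    ratio = (frame[later].add(pseudocount)).div(
        frame[oocyte_stage] + pseudocount, axis=0
    )
    return set(frame.index[(ratio >= fold).any(axis=1)])


def select_rz_enriched(
    matrix: ExpressionMatrix,
    stage: str,
    threshold: float = -0.5,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    require_maternal: bool = True,
    oocyte_stage: str = "oocyte",
) -> set[str]:
    """Maternal genes whose log2(PA/RZ) at ``stage`` is <= ``threshold``.

    The maternal-call prerequisite keeps silent genes (whose ratio is a
    pseudocount artifact) out of the set; disable with
    ``require_maternal=False``.
    """
    ratio = log2_pa_rz(matrix, stage, pseudocount)
    selected = set(ratio.index[ratio <= threshold])
    if require_maternal:
        selected &= select_maternal(matrix, oocyte_stage)
    return selected


def classify_genes(
    matrix: ExpressionMatrix,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    rz_stages: tuple[str, ...] = ("oocyte", "st6", "st9"),
) -> pd.DataFrame:
    """Boolean per-gene class calls: maternal, embryonic, rz_enriched@stage."""
    maternal = select_maternal(matrix)
    embryonic = select_embryonic(matrix, pseudocount)
    out = pd.DataFrame(index=matrix.rpkm.index)
    out["maternal"] = out.index.isin(maternal)
    out["embryonic"] = out.index.isin(embryonic)
    for stage in rz_stages:
        if (stage, "PA") in matrix.rpkm.columns:
            enriched = select_rz_enriched(matrix, stage, pseudocount=pseudocount)
            out[f"rz_enriched_{stage}"] = out.index.isin(enriched)
    return out


# ---------------------------------------------------------------------------
# Scaling, clustering, correlation
# ---------------------------------------------------------------------------

def scale_rows(frame: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Divide each row by its sum so expression profiles sum to one.

    All-zero rows are returned unchanged and flagged (second return value)
    rather than dropped, preserving the matrix shape.
    """
    sums = frame.sum(axis=1)
    zero = sums == 0
    scaled = frame.div(sums.where(~zero, 1.0), axis=0)
    scaled[zero] = 0.0
    return scaled, zero


@dataclass
class ClusterResult:
    labels: pd.Series  # gene -> cluster label in 1..k
    k: int
    seed: int
    transform: str


def cluster_kmeans(
    frame: pd.DataFrame,
    k: int,
    seed: int = 0,
    transform: str = "log",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> ClusterResult:
    """K-means over expression profiles (Euclidean, deterministic per seed).

    ``transform``: "log" clusters log2(RPKM + pseudocount); "scaled"
    clusters rows rescaled to sum one; "none" clusters raw values.
    """
    if not 1 <= k <= len(frame):
        raise ValueError(f"k={k} out of range for {len(frame)} genes")
    if transform == "log":
        data = np.log2(frame + pseudocount)
    elif transform == "scaled":
        data, _ = scale_rows(frame)
    elif transform == "none":
        data = frame
    else:
        raise ValueError(f"unknown transform {transform!r}")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(data.values) + 1
    return ClusterResult(
        labels=pd.Series(labels, index=frame.index),
        k=k,
        seed=seed,
        transform=transform,
    )


def correlation_matrix(
    matrix: ExpressionMatrix, method: str = "pearson"
) -> pd.DataFrame:
    """Condition x condition correlation of RPKM across genes.

    Zero-variance conditions give missing values (NaN) off the diagonal.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    if len(matrix.rpkm) < 2:
        raise ValueError("need at least two genes")
    corr = matrix.rpkm.corr(method=method)
    np.fill_diagonal(corr.values, 1.0)
    return corr


# ---------------------------------------------------------------------------
# Induction timing and peak stages
# ---------------------------------------------------------------------------

def induction_timing(
    matrix: ExpressionMatrix,
    embryonic_set: set[str],
    fold: float = 4.0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    library: str = "PA",
    oocyte_stage: str = "oocyte",
) -> pd.Series:
    """Cumulative fraction of embryonic genes induced >= ``fold`` by each stage.

    A gene counts from the earliest stage at which its expression reaches
    ``fold`` times the oocyte level; genes never reaching it contribute to
    no stage, so the series is non-decreasing with maximum <= 1.
    """
    if not embryonic_set:
        raise ValueError("empty embryonic set")
    missing = embryonic_set - set(matrix.rpkm.index)
    if missing:
        raise KeyError(f"genes not in matrix: {sorted(missing)[:3]}")
    frame = matrix.library(library).loc[sorted(embryonic_set)]
    later = [s for s in frame.columns if s != oocyte_stage]
    ratio = frame[later].add(pseudocount).div(
        frame[oocyte_stage] + pseudocount, axis=0
    )
    reached = ratio >= fold
    # earliest stage index at which each gene reaches the fold
    first = reached.values.argmax(axis=1)
    ever = reached.values.any(axis=1)
    counts = np.zeros(len(later))
    for idx, ok in zip(first, ever):
        if ok:
            counts[idx] += 1
    cumulative = np.cumsum(counts) / len(frame)
    return pd.Series(cumulative, index=later)


def peak_stage_fractions(
    matrix: ExpressionMatrix,
    embryonic_set: set[str],
    library: str = "PA",
) -> pd.Series:
    """Fraction of embryonic genes peaking at each stage (ties -> earliest)."""
    if not embryonic_set:
        raise ValueError("empty embryonic set")
    frame = matrix.library(library).loc[sorted(embryonic_set)]
    peak_idx = frame.values.argmax(axis=1)  # argmax takes the first maximum
    fractions = pd.Series(0.0, index=frame.columns)
    for idx in peak_idx:
        fractions.iloc[idx] += 1
    return fractions / len(frame)


# ---------------------------------------------------------------------------
# RT-qPCR fold changes
# ---------------------------------------------------------------------------

def ddct_fold_change(table: QpcrTable) -> pd.DataFrame:
    """2^-ddCt fold changes relative to the reference stage.

    dCt = Ct_gene - Ct_normalizer per stage; ddCt subtracts the reference
    stage's dCt; fold = 2^-ddCt (1.0 at the reference stage by definition).
    """
    genes = sorted({g for g, _ in table.rows} - {table.normalizer})
    stages = sorted({s for _, s in table.rows})
    records = []
    for gene in genes:
        ref_dct = table.ct(gene, table.reference_stage) - table.ct(
            table.normalizer, table.reference_stage
        )
        for stage in stages:
            if (gene, stage) not in table.rows:
                continue
            dct = table.ct(gene, stage) - table.ct(table.normalizer, stage)
            ddct = dct - ref_dct
            records.append(
                {"gene": gene, "stage": stage, "fold_change": 2.0 ** (-ddct)}
            )
    return pd.DataFrame(records, columns=["gene", "stage", "fold_change"])
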