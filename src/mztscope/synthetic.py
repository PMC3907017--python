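"""Seeded ground-truth generator for the whole pipeline.

Emulates a six-stage early-development RNA-seq experiment (oocyte to late
tailbud) with paired polyA-selected (PA) and ribo-depleted (RZ) libraries,
planted transcript classes, chromatin evidence and the assembly artifacts
the annotation pipeline is designed to catch:

* ``maternal_poly`` — polyadenylated maternal transcripts, high in oocyte.
* ``maternal_deadenylated`` — maternal transcripts whose PA/RZ log2 ratio is
  planted at or below -1 in oocyte, stage 6 and stage 9.
* ``maternal_embryonic`` — present in oocyte and modestly induced later
  (never 10-fold).
* ``embryonic_only`` — silent in oocyte, >= 10-fold induction at a random
  onset stage.
* ``lncRNA_standalone`` — spliced 2-4 exon noncoding transcripts with their
  own TSS and low expression, absent from the reference annotation (so they
  are discoverable as new gene models).

Artifacts: ``utr_fragment`` (spliced 5'-UTR fragments upstream of genes
whose annotated model is 5'-truncated, with the true-TSS H3K4me3 peak
upstream), ``broken_gene`` (two evidence halves each sharing exons with an
intact reference gene) and ``unspliced_single_exon`` models.

Counts are Poisson per exon with mean ``RPKM * exon_kb * depth`` where
``depth`` is the per-library total of mapped reads in millions — the exact
inverse of the RPKM formula. Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coding import ALL_CODONS, CODON_TO_AA, max_orf_aa
from .io import CountTable
from .models import (
    GeneModel,
    GeneModelSet,
    Interval,
    JunctionRecord,
    Peak,
    SignalTrack,
)

GENE_CLASSES = (
    "maternal_poly",
    "maternal_deadenylated",
    "maternal_embryonic",
    "embryonic_only",
    "lncRNA_standalone",
)
ARTIFACT_CLASSES = ("utr_fragment", "broken_gene", "unspliced_single_exon")
CODING_CLASSES = (
    "maternal_poly",
    "maternal_deadenylated",
    "maternal_embryonic",
    "embryonic_only",
)
DEFAULT_STAGES = ("oocyte", "st6", "st9", "st12", "st16", "st30")
#: stages at which deadenylated profiles must satisfy log2(PA/RZ) <= -0.5
DEADENYLATED_STAGES = ("oocyte", "st6", "st9")


@dataclass
class SyntheticConfig:
    seed: int = 42
    n_genes: dict[str, int] = field(
        default_factory=lambda: {c: 10 for c in GENE_CLASSES}
    )
    n_artifacts: dict[str, int] = field(
        default_factory=lambda: {c: 3 for c in ARTIFACT_CLASSES}
    )
    stages: tuple[str, ...] = DEFAULT_STAGES
    depth: float = 20.0  # total mapped reads per library, millions
    h3k4me3_dropout: float = 0.0
    genome_length: int = 1_500_000
    chrom: str = "chr1"
    #: planted log2(PA/RZ) range for deadenylated transcripts
    deadenylated_ratio: tuple[float, float] = (-2.5, -1.0)
    n_noise_junctions: int = 10
    peak_halfwidth: int = 200

    def __post_init__(self) -> None:
        for name, n in {**self.n_genes, **self.n_artifacts}.items():
            if n < 0:
                raise ValueError(f"negative count for class {name}")
        if not 0.0 <= self.h3k4me3_dropout <= 1.0:
            raise ValueError("h3k4me3_dropout must lie in [0, 1]")
        if not self.stages:
            raise ValueError("stages must be non-empty")
        if sum(self.n_genes.values()) == 0:
            raise ValueError("at least one gene class must be non-empty")


@dataclass
class PlantedGene:
    """Internal record of one planted transcription unit."""

    model_id: str
    label: str
    true_model: GeneModel  # intact structure (all true exons)
    reference_model: GeneModel | None  # as annotated (may be truncated/absent)
    evidence_models: list[GeneModel] = field(default_factory=list)
    profile: dict[tuple[str, str], float] = field(default_factory=dict)
    true_tss: int = 0
    truncated: bool = False
    has_peak: bool = True  # after dropout
    utr_exons: int = 0  # leading true exons that are UTR (noncoding)


@dataclass
class SyntheticTruth:
    config: SyntheticConfig
    genes: list[PlantedGene]
    genome: dict[str, str] = field(default_factory=dict)

    @property
    def labels(self) -> dict[str, str]:
        return {g.model_id: g.label for g in self.genes}

    @property
    def true_tss(self) -> dict[str, int]:
        return {g.model_id: g.true_tss for g in self.genes}

    @property
    def profiles(self) -> dict[str, dict[tuple[str, str], float]]:
        return {g.model_id: g.profile for g in self.genes}

    def by_label(self, label: str) -> list[PlantedGene]:
        return [g for g in self.genes if g.label == label]

    def totals(self) -> dict[tuple[str, str], int]:
        """Per-(stage, library) total mapped reads implied by the depth."""
        return {
            (stage, lib): int(self.config.depth * 1e6)
            for stage in self.config.stages
            for lib in ("PA", "RZ")
        }


# ---------------------------------------------------------------------------
# Truth generation
# ---------------------------------------------------------------------------

def _flat_profile(stages, pa: float, rz: float) -> dict:
    return {(s, "PA"): pa for s in stages} | {(s, "RZ"): rz for s in stages}


def _make_profile(rng, label: str, cfg: SyntheticConfig) -> dict:
    stages = cfg.stages
    if label == "maternal_poly":
        rz = rng.uniform(8, 50)
        ratio = rng.uniform(0.0, 0.4)
        prof = {}
        for i, s in enumerate(stages):
            decay = 0.85**i
            prof[(s, "RZ")] = rz * decay
            prof[(s, "PA")] = rz * decay * 2.0**ratio
        return prof
    if label == "maternal_deadenylated":
        rz = rng.uniform(8, 50)
        ratio = rng.uniform(*cfg.deadenylated_ratio)
        prof = {}
        for i, s in enumerate(stages):
            decay = 0.9**i
            prof[(s, "RZ")] = rz * decay
            prof[(s, "PA")] = rz * decay * 2.0**ratio
        return prof
    if label == "maternal_embryonic":
        base = rng.uniform(3, 20)
        rise = rng.uniform(1.5, 3.0)  # deliberately below the 10-fold filter
        prof = {}
        for i, s in enumerate(stages):
            level = base if i < 2 else base * rise
            prof[(s, "PA")] = level
            prof[(s, "RZ")] = level * rng.uniform(0.9, 1.1)
        return prof
    if label == "embryonic_only":
        onset = rng.integers(2, len(stages))  # st9 or later by default
        high = rng.uniform(5, 30)
        prof = {}
        for i, s in enumerate(stages):
            level = 0.02 if i < onset else high
            prof[(s, "PA")] = level
            prof[(s, "RZ")] = level * rng.uniform(0.9, 1.1)
        return prof
    if label == "lncRNA_standalone":
        # low expression: median about one-third of the coding classes
        level = rng.uniform(2, 8)
        onset = rng.integers(0, 3)
        prof = {}
        for i, s in enumerate(stages):
            val = level if i >= onset else 0.3 * level
            prof[(s, "PA")] = val
            prof[(s, "RZ")] = val * rng.uniform(0.9, 1.1)
        return prof
    raise ValueError(f"unknown label {label!r}")


def _split_lengths(rng, total: int, parts: int, minimum: int) -> list[int]:
    """Random composition of ``total`` into ``parts`` pieces >= minimum."""
    if parts * minimum > total:
        raise ValueError("cannot split")
    extra = total - parts * minimum
    if parts == 1:
        return [total]
    cuts = np.sort(rng.integers(0, extra + 1, size=parts - 1))
    pieces = np.diff(np.concatenate([[0], cuts, [extra]]))
    return [minimum + int(p) for p in pieces]


def _build_exons(chrom, strand, start, exon_lengths, intron_lengths):
    exons = []
    pos = start
    for i, elen in enumerate(exon_lengths):
        exons.append(Interval(chrom, pos, pos + elen, strand))
        pos += elen
        if i < len(intron_lengths):
            pos += intron_lengths[i]
    return exons, pos


def generate_truth(config: SyntheticConfig) -> SyntheticTruth:
    """Lay out the genome and plant genes, artifacts and expression profiles.

    Deterministic given ``config.seed``. Gene loci are separated by > 10 kb
    so curation's downstream-gene search (10 kb cap) never crosses loci
    except for the deliberately planted UTR-fragment/parent pairs.
    """
    rng = np.random.default_rng(config.seed)
    chrom = config.chrom
    genes: list[PlantedGene] = []
    cursor = 5_000

    n_utr = config.n_artifacts.get("utr_fragment", 0)
    n_broken = config.n_artifacts.get("broken_gene", 0)
    n_unspliced = config.n_artifacts.get("unspliced_single_exon", 0)
    # truncated (upstream-rescue) parents host the UTR fragments; they are
    # drawn from the maternal_embryonic quota first, then maternal_poly
    trunc_left = n_utr
    broken_left = n_broken

    order: list[tuple[str, int]] = []
    for label in GENE_CLASSES:
        for i in range(config.n_genes.get(label, 0)):
            order.append((label, i))

    for label, i in order:
        strand = "+" if rng.random() < 0.5 else "-"
        model_id = f"{label}_{i:03d}"
        profile = _make_profile(rng, label, config)
        truncated = False
        utr_exons = 0
        if label == "lncRNA_standalone":
            n_exons = int(rng.integers(2, 5))
            exon_lengths = [int(rng.integers(100, 350)) for _ in range(n_exons)]
        else:
            if trunc_left > 0 and label in ("maternal_embryonic", "maternal_poly"):
                truncated = True
                trunc_left -= 1
                utr_exons = 2
            n_cds_exons = int(rng.integers(4, 8)) if truncated else int(
                rng.integers(3, 8)
            )
            n_codons = int(rng.integers(max(120, 25 * n_cds_exons), 400))
            cds_lengths = _split_lengths(rng, 3 * n_codons, n_cds_exons, 60)
            if truncated:
                # two short leading (5') UTR exons, the future fragment
                exon_lengths = [
                    int(rng.integers(70, 140)),
                    int(rng.integers(70, 140)),
                ] + cds_lengths
            else:
                exon_lengths = cds_lengths
        # lengths above are in transcript order; introns likewise
        intron_lengths = [
            int(rng.integers(300, 1500)) for _ in range(len(exon_lengths) - 1)
        ]
        if truncated:
            # widen the gap between the UTR part and the annotated gene body
            intron_lengths[1] = int(rng.integers(1200, 2500))
        if strand == "-":
            # genomic order is the reverse of transcript order on the minus
            # strand, so the 5' UTR exons land rightmost
            exon_lengths = exon_lengths[::-1]
            intron_lengths = intron_lengths[::-1]
        gap = int(rng.integers(12_000, 18_000))
        start = cursor + gap
        exons, end = _build_exons(chrom, strand, start, exon_lengths, intron_lengths)
        cursor = end
        true_model = GeneModel(model_id=model_id, exons=list(exons), source="truth")
        g = PlantedGene(
            model_id=model_id,
            label=label,
            true_model=true_model,
            reference_model=None,
            profile=profile,
            truncated=truncated,
            utr_exons=utr_exons,
        )
        g.true_tss = true_model.five_prime()
        genes.append(g)

    # reference / evidence structure
    broken_candidates = [
        g
        for g in genes
        if g.label in ("maternal_poly", "maternal_deadenylated")
        and not g.truncated
        and g.true_model.n_exons >= 4
    ]
    for g in genes:
        tm = g.true_model
        if g.label == "lncRNA_standalone":
            ev = GeneModel(
                model_id=g.model_id + "_asm",
                exons=list(tm.exons),
                source="assembly" if rng.random() < 0.7 else "est",
            )
            g.evidence_models.append(ev)
            continue
        if g.truncated:
            # annotated model misses the two 5'-most (UTR) exons
            ordered = tm.exons if tm.strand == "+" else list(reversed(tm.exons))
            utr = ordered[: g.utr_exons]
            body = ordered[g.utr_exons :]
            g.reference_model = GeneModel(
                model_id=g.model_id,
                exons=sorted(body, key=lambda e: e.start),
                source="reference",
            )
            frag = GeneModel(
                model_id=g.model_id + "_utrfrag",
                exons=sorted(utr, key=lambda e: e.start),
                source="assembly",
            )
            g.evidence_models.append(frag)
        else:
            g.reference_model = GeneModel(
                model_id=g.model_id, exons=list(tm.exons), source="reference"
            )
    for g in rng.choice(
        np.array(broken_candidates, dtype=object),
        size=min(broken_left, len(broken_candidates)),
        replace=False,
    ):
        k = g.true_model.n_exons // 2
        g.evidence_models.append(
            GeneModel(
                model_id=g.model_id + "_brkA",
                exons=list(g.true_model.exons[:k]),
                source="est",
            )
        )
        g.evidence_models.append(
            GeneModel(
                model_id=g.model_id + "_brkB",
                exons=list(g.true_model.exons[k:]),
                source="est",
            )
        )

    # unspliced single-exon artifact models in their own loci
    for i in range(n_unspliced):
        gap = int(rng.integers(12_000, 16_000))
        start = cursor + gap
        length = int(rng.integers(300, 800))
        strand = "+" if rng.random() < 0.5 else "-"
        exon = Interval(chrom, start, start + length, strand)
        cursor = start + length
        level = float(rng.uniform(1, 5))
        g = PlantedGene(
            model_id=f"unspliced_{i:03d}",
            label="unspliced_single_exon",
            true_model=GeneModel(
                model_id=f"unspliced_{i:03d}", exons=[exon], source="truth"
            ),
            reference_model=None,
            profile=_flat_profile(config.stages, level, level),
        )
        g.true_tss = g.true_model.five_prime()
        g.evidence_models.append(
            GeneModel(
                model_id=f"unspliced_{i:03d}_asm", exons=[exon], source="assembly"
            )
        )
        genes.append(g)

    truth = SyntheticTruth(config=config, genes=genes)
    return truth


# ---------------------------------------------------------------------------
# Sequence synthesis
# ---------------------------------------------------------------------------

def _normalize_table(table: dict[str, float]) -> np.ndarray:
    p = np.array([table[c] for c in ALL_CODONS], dtype=float)
    total = p.sum()
    if total <= 0:
        raise ValueError("frequency table sums to zero")
    return p / total


def _sample_triplets(rng, p: np.ndarray, n: int) -> str:
    idx = rng.choice(len(ALL_CODONS), size=n, p=p)
    return "".join(ALL_CODONS[i] for i in idx)


_COMP = str.maketrans("ACGT", "TGCA")


def synthesize_sequences(
    truth: SyntheticTruth,
    coding_table: dict[str, float],
    noncoding_table: dict[str, float],
    max_lnc_orf_aa: int = 100,
) -> dict[str, str]:
    """Fill the genome: coding exons codon-wise from ``coding_table`` (ATG
    start, in-frame terminal stop), everything else triplet-wise from
    ``noncoding_table``. lncRNA transcripts are rejection-sampled until
    their six-frame maximal ORF is <= ``max_lnc_orf_aa``.
    """
    cfg = truth.config
    rng = np.random.default_rng(cfg.seed + 1)
    p_nc = _normalize_table(noncoding_table)
    p_cod = _normalize_table(coding_table)
    sense = [i for i, c in enumerate(ALL_CODONS) if CODON_TO_AA[c] != "*"]
    stops = [i for i, c in enumerate(ALL_CODONS) if CODON_TO_AA[c] == "*"]
    p_sense = p_cod[sense] / p_cod[sense].sum()
    p_stop = p_cod[stops] / p_cod[stops].sum()

    length = max(
        cfg.genome_length,
        max(g.true_model.end for g in truth.genes) + 5_000,
    )
    n_trip = -(-length // 3)
    background = _sample_triplets(rng, p_nc, n_trip)[:length]
    genome = np.frombuffer(background.encode(), dtype="S1").copy()

    def paste(seq: str, exons, strand: str) -> None:
        if strand == "-":
            seq = seq.translate(_COMP)[::-1]
        pos = 0
        for e in sorted(exons, key=lambda e: e.start):
            piece = seq[pos : pos + len(e)]
            genome[e.start : e.end] = np.frombuffer(piece.encode(), dtype="S1")
            pos += len(e)

    def sample_cds(n_nt: int) -> str:
        n_codons = n_nt // 3
        body = "".join(
            ALL_CODONS[sense[i]]
            for i in rng.choice(len(sense), size=n_codons - 2, p=p_sense)
        )
        stop = ALL_CODONS[stops[rng.choice(len(stops), p=p_stop)]]
        return "ATG" + body + stop

    def sample_noncoding_transcript(n_nt: int) -> str:
        while True:
            seq = _sample_triplets(rng, p_nc, -(-n_nt // 3))[:n_nt]
            if max_orf_aa(seq) <= max_lnc_orf_aa:
                return seq

    for g in truth.genes:
        tm = g.true_model
        ordered = tm.exons if tm.strand == "+" else list(reversed(tm.exons))
        if g.label in CODING_CLASSES:
            utr = ordered[: g.utr_exons]
            cds_exons = ordered[g.utr_exons :]
            if utr:
                utr_len = sum(len(e) for e in utr)
                paste(sample_noncoding_transcript(utr_len), utr, tm.strand)
            cds_len = sum(len(e) for e in cds_exons)
            paste(sample_cds(cds_len), cds_exons, tm.strand)
        elif g.label == "lncRNA_standalone":
            paste(
                sample_noncoding_transcript(tm.spliced_length()),
                tm.exons,
                tm.strand,
            )
        # unspliced artifacts keep the noncoding background
    truth.genome = {cfg.chrom: genome.tobytes().decode()}
    return truth.genome


# ---------------------------------------------------------------------------
# Counts, junctions, chromatin, evidence
# ---------------------------------------------------------------------------

def _all_models(truth: SyntheticTruth):
    """(model, profile) pairs for every model counts are generated for."""
    out = []
    for g in truth.genes:
        if g.reference_model is not None:
            out.append((g.reference_model, g.profile))
        for ev in g.evidence_models:
            out.append((ev, g.profile))
    return out


def simulate_counts(
    truth: SyntheticTruth, config: SyntheticConfig | None = None
) -> tuple[CountTable, list[JunctionRecord]]:
    """Poisson per-exon counts and supported junctions for every emitted model.

    Expected count = RPKM * exon_kb * depth (depth in millions of mapped
    reads), the inverse of the RPKM formula. Introns of expressed spliced
    models receive support >= 5; noise junctions get support in 1..4.
    """
    cfg = config or truth.config
    rng = np.random.default_rng(cfg.seed + 2)
    table = CountTable()
    for model, profile in _all_models(truth):
        for ei, exon in enumerate(model.exons):
            kb = len(exon) / 1000.0
            for stage in cfg.stages:
                for lib in ("PA", "RZ"):
                    rpkm = profile.get((stage, lib), 0.0)
                    mean = rpkm * kb * cfg.depth
                    count = int(rng.poisson(mean)) if mean > 0 else 0
                    if count:
                        table.set((model.model_id, ei, stage, lib), count)

    junctions: dict[tuple, int] = {}
    for g in truth.genes:
        expressed = any(v > 0.5 for v in g.profile.values())
        if not expressed or not g.true_model.spliced:
            continue
        for intron in g.true_model.introns():
            key = intron.key()
            if key not in junctions:
                junctions[key] = 5 + int(rng.poisson(15))
    records = [
        JunctionRecord(Interval(*key), support)
        for key, support in junctions.items()
    ]
    occupied = sorted(
        (g.true_model.start, g.true_model.end) for g in truth.genes
    )
    genome_end = max(e for _, e in occupied) + 4_000
    for _ in range(cfg.n_noise_junctions):
        start = int(rng.integers(1_000, genome_end))
        records.append(
            JunctionRecord(
                Interval(
                    cfg.chrom,
                    start,
                    start + int(rng.integers(200, 1_000)),
                    "+" if rng.random() < 0.5 else "-",
                ),
                read_support=int(rng.integers(1, 5)),
            )
        )
    return table, records


def simulate_chromatin(
    truth: SyntheticTruth, config: SyntheticConfig | None = None
) -> tuple[list[Peak], SignalTrack]:
    """H3K4me3 peaks at true TSSs (with dropout) and RNAPII body signal.

    Truncated genes get their peak at the *true* (upstream) TSS — over the
    planted UTR-fragment exons, never over the annotated first exon — plus
    bridging RNAPII signal at 0.8x the gene-body level so the upstream-TSS
    rescue test can succeed. UTR fragments get no peak of their own.
    Unspliced artifact models get no peak.
    """
    cfg = config or truth.config
    rng = np.random.default_rng(cfg.seed + 3)
    peaks: list[Peak] = []
    signal_parts: list[tuple[str, int, int, float]] = []
    hw = cfg.peak_halfwidth
    for g in truth.genes:
        expressed = any(v > 0.5 for v in g.profile.values())
        g.has_peak = False
        if g.label == "unspliced_single_exon" or not expressed:
            continue
        tm = g.true_model
        total = sum(g.profile.values())
        body_value = 1.0 + total / 20.0
        if g.truncated:
            ref = g.reference_model
            ordered = tm.exons if tm.strand == "+" else list(reversed(tm.exons))
            first_utr = ordered[0]
            center = first_utr.start if tm.strand == "+" else first_utr.end
            peaks.append(
                Peak(Interval(cfg.chrom, max(0, center - hw), center + hw))
            )
            g.has_peak = True
            signal_parts.append((cfg.chrom, ref.start, ref.end, body_value))
            if tm.strand == "+":
                bridge = (center + hw, ref.start)
            else:
                bridge = (ref.end, center - hw)
            if bridge[0] < bridge[1]:
                signal_parts.append(
                    (cfg.chrom, bridge[0], bridge[1], 0.8 * body_value)
                )
        else:
            if rng.random() < cfg.h3k4me3_dropout:
                signal_parts.append((cfg.chrom, tm.start, tm.end, body_value))
                continue
            center = g.true_tss
            peaks.append(
                Peak(Interval(cfg.chrom, max(0, center - hw), center + hw))
            )
            g.has_peak = True
            signal_parts.append((cfg.chrom, tm.start, tm.end, body_value))
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start))
    return peaks, SignalTrack(signal_parts)


def emit_evidence(
    truth: SyntheticTruth, config: SyntheticConfig | None = None
) -> tuple[GeneModelSet, GeneModelSet]:
    """(reference, evidence) model sets.

    The reference omits the planted lncRNAs (discoverable as new gene
    models) and carries truncated models for the rescue-case genes; the
    evidence set holds lncRNA transcripts, UTR fragments, broken-gene halves
    and unspliced single-exon models.
    """
    reference = GeneModelSet()
    evidence = GeneModelSet()
    for g in truth.genes:
        if g.reference_model is not None:
            reference.add(g.reference_model)
        for ev in g.evidence_models:
            evidence.add(ev)
    return reference, evidence


@dataclass
class SyntheticBundle:
    """Everything the downstream modules consume, generated in one call."""

    truth: SyntheticTruth
    genome: dict[str, str]
    reference: GeneModelSet
    evidence: GeneModelSet
    counts: CountTable
    junctions: list[JunctionRecord]
    peaks: list[Peak]
    rnapii: SignalTrack
    totals: dict[tuple[str, str], int]


def generate_bundle(
    config: SyntheticConfig | None = None,
    coding_table: dict[str, float] | None = None,
    noncoding_table: dict[str, float] | None = None,
) -> SyntheticBundle:
    """Generate the full deterministic dataset for one configuration."""
    from .coding import default_frequency_tables

    config = config or SyntheticConfig()
    if coding_table is None or noncoding_table is None:
        coding_table, noncoding_table = default_frequency_tables()
    truth = generate_truth(config)
    genome = synthesize_sequences(truth, coding_table, noncoding_table)
    counts, junctions = simulate_counts(truth, config)
    peaks, rnapii = simulate_chromatin(truth, config)
    reference, evidence = emit_evidence(truth, config)
    return SyntheticBundle(
        truth=truth,
        genome=genome,
        reference=reference,
        evidence=evidence,
        counts=counts,
        junctions=junctions,
        peaks=peaks,
        rnapii=rnapii,
        totals=truth.totals(),
    )
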