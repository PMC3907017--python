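import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from mztscope.expression import (
    ExpressionMatrix,
    build_expression_matrix,
    classify_genes,
    cluster_kmeans,
    compute_gene_rpkm,
    correlation_matrix,
    ddct_fold_change,
    induction_timing,
    log2_pa_rz,
    peak_stage_fractions,
    scale_rows,
    select_embryonic,
    select_maternal,
    select_rz_enriched,
)
from mztscope.models import GeneModel, GeneModelSet, Interval, QpcrTable

STAGES = ("oocyte", "st6", "st9", "st12", "st16", "st30")


def make_matrix(values: dict[str, dict[tuple[str, str], float]]) -> ExpressionMatrix:
    frame = pd.DataFrame(values).T
    frame.columns = pd.MultiIndex.from_tuples(
        frame.columns, names=["stage", "library"]
    )
    return ExpressionMatrix(rpkm=frame.fillna(0.0), stages=STAGES)


def flat(pa, rz, overrides=None):
    prof = {}
    for s in STAGES:
        prof[(s, "PA")] = pa
        prof[(s, "RZ")] = rz
    prof.update(overrides or {})
    return prof


# ---------------------------------------------------------------------------
# RPKM
# ---------------------------------------------------------------------------

class TestGeneRpkm:
    def test_closed_form(self):
        models = GeneModelSet(
            [GeneModel("m1", [Interval("chr1", 0, 1000, "+")])]
        )
        rpkm = compute_gene_rpkm({("m1", 0): 10}, models, 1_000_000)
        assert rpkm["m1"] == pytest.approx(10.0)

    def test_gene_value_is_mean_over_exons(self):
        models = GeneModelSet(
            [
                GeneModel(
                    "m1",
                    [Interval("chr1", 0, 1000, "+"), Interval("chr1", 2000, 3000, "+")],
                )
            ]
        )
        # exon RPKMs 4 and 6 -> gene 5
        rpkm = compute_gene_rpkm({("m1", 0): 4, ("m1", 1): 6}, models, 1_000_000)
        assert rpkm["m1"] == pytest.approx(5.0)

    def test_shared_exon_counts_once_across_isoforms(self):
        shared = Interval("chr1", 0, 1000, "+")
        other = Interval("chr1", 2000, 3000, "+")
        models = GeneModelSet(
            [
                GeneModel("iso1", [shared], gene_id="g"),
                GeneModel("iso2", [shared, other], gene_id="g"),
            ]
        )
        counts = {("iso1", 0): 4, ("iso2", 0): 4, ("iso2", 1): 6}
        rpkm = compute_gene_rpkm(counts, models, 1_000_000)
        # exons {A(4), A, B(6)} -> mean of {4, 6} = 5, not 4.67
        assert rpkm["g"] == pytest.approx(5.0)

    def test_linear_in_counts_inverse_in_depth(self):
        rng = np.random.default_rng(3)
        models = GeneModelSet(
            [
                GeneModel(
                    f"m{i}",
                    [
                        Interval("chr1", 10_000 * i + j * 2000,
                                 10_000 * i + j * 2000 + int(rng.integers(100, 900)),
                                 "+")
                        for j in range(3)
                    ],
                )
                for i in range(5)
            ]
        )
        counts = {
            (f"m{i}", j): int(rng.integers(0, 500))
            for i in range(5)
            for j in range(3)
        }
        base = compute_gene_rpkm(counts, models, 2_000_000)
        doubled = compute_gene_rpkm(
            {k: 2 * v for k, v in counts.items()}, models, 2_000_000
        )
        deeper = compute_gene_rpkm(counts, models, 4_000_000)
        for g in base:
            assert doubled[g] == pytest.approx(2 * base[g])
            assert deeper[g] == pytest.approx(base[g] / 2)

    def test_invalid_inputs(self):
        models = GeneModelSet([GeneModel("m1", [Interval("chr1", 0, 10, "+")])])
        with pytest.raises(ValueError):
            compute_gene_rpkm({}, models, 0)


# ---------------------------------------------------------------------------
# Ratios and selections at their printed boundaries
# ---------------------------------------------------------------------------

@pytest.fixture()
def boundary_matrix():
    """Twelve genes covering every classification boundary."""
    near_half = 0.70710678  # just below 2**-0.5: log2 is -0.500000004
    above_half = 2 ** -0.49
    return make_matrix(
        {
            # maternal boundaries
            "mat_pa_edge": flat(0.0, 0.0, {("oocyte", "PA"): 1.0}),
            "mat_rz_only": flat(0.5, 1.2),
            "mat_below": flat(0.99, 0.99),
            # embryonic boundaries (PA library)
            "emb_edge": flat(0.5, 0.5, {("st12", "PA"): 5.0}),
            "emb_below": flat(0.5, 0.5, {("st12", "PA"): 4.9}),
            "emb_zero_oocyte": flat(3.0, 3.0, {("oocyte", "PA"): 0.0,
                                                ("oocyte", "RZ"): 0.0}),
            # RZ-enrichment boundaries at oocyte (maternal via RZ >= 1);
            # values chosen so the 0.01 pseudocount gives exact ratios
            "rz_edge": flat(4.0 * near_half - 0.01, 3.99),
            "rz_above": flat(4.0 * above_half - 0.01, 3.99),
            "rz_dyadic": flat(1.99, 3.99),  # (PA+pc)/(RZ+pc) = 0.5 exactly
            "rz_nonmaternal": flat(0.1, 0.4),  # ratio -2 but not maternal
            # fillers
            "silent": flat(0.0, 0.0),
            "steady": flat(2.0, 2.0),
        }
    )


class TestClassBoundaries:
    def test_maternal_selection(self, boundary_matrix):
        maternal = select_maternal(boundary_matrix)
        assert "mat_pa_edge" in maternal  # oocyte PA exactly 1.0
        assert "mat_rz_only" in maternal  # RZ 1.2 suffices ("PA or RZ")
        assert "mat_below" not in maternal  # 0.99 in both
        assert "silent" not in maternal

    def test_embryonic_selection(self, boundary_matrix):
        emb = select_embryonic(boundary_matrix, pseudocount=0.0)
        assert "emb_edge" in emb  # fold exactly 10
        assert "emb_below" not in emb  # fold 9.8
        emb_pc = select_embryonic(boundary_matrix, pseudocount=0.01)
        assert "emb_zero_oocyte" in emb_pc  # (3.01)/(0.01) ~ 301

    def test_rz_enrichment(self, boundary_matrix):
        enriched = select_rz_enriched(boundary_matrix, "oocyte")
        assert "rz_edge" in enriched  # at the -0.5 boundary (from below)
        assert "rz_above" not in enriched  # -0.49
        assert "rz_nonmaternal" not in enriched  # maternal call required
        assert "rz_dyadic" in enriched
        # equality is included: the dyadic ratio sits exactly on log2 = -1
        at_minus_one = select_rz_enriched(
            boundary_matrix, "oocyte", threshold=-1.0
        )
        assert "rz_dyadic" in at_minus_one
        without_maternal = select_rz_enriched(
            boundary_matrix, "oocyte", require_maternal=False
        )
        assert "rz_nonmaternal" in without_maternal

    def test_threshold_monotonicity(self, boundary_matrix):
        for loose, tight in [(1.0, 2.0), (2.0, 4.0)]:
            assert select_maternal(boundary_matrix, threshold=tight) <= (
                select_maternal(boundary_matrix, threshold=loose)
            )
        for loose, tight in [(5.0, 10.0), (10.0, 20.0)]:
            assert select_embryonic(boundary_matrix, fold=tight) <= (
                select_embryonic(boundary_matrix, fold=loose)
            )
        for loose, tight in [(-0.5, -1.0), (-1.0, -2.0)]:
            assert select_rz_enriched(
                boundary_matrix, "oocyte", threshold=tight
            ) <= select_rz_enriched(boundary_matrix, "oocyte", threshold=loose)


class TestLogRatio:
    def test_symmetry_and_pseudocount(self):
        m = make_matrix({"g": flat(5.0, 5.0), "z": flat(0.0, 0.0)})
        ratios = log2_pa_rz(m, "oocyte")
        assert ratios["g"] == pytest.approx(0.0)
        assert ratios["z"] == pytest.approx(0.0)  # 0/0 under pseudocount

    def test_half_ratio(self):
        m = make_matrix({"g": flat(1.0, 2.0)})
        assert log2_pa_rz(m, "st9", pseudocount=1e-12)["g"] == pytest.approx(
            -1.0
        )

    def test_missing_library_errors(self):
        frame = pd.DataFrame(
            {("oocyte", "PA"): {"g": 1.0}},
        )
        frame.columns = pd.MultiIndex.from_tuples(frame.columns)
        m = ExpressionMatrix(rpkm=frame, stages=("oocyte",))
        with pytest.raises(KeyError):
            log2_pa_rz(m, "oocyte")


# ---------------------------------------------------------------------------
# Scaling / clustering / correlation
# ---------------------------------------------------------------------------

class TestScaleRows:
    def test_rows_sum_to_one_and_zero_rows_flagged(self):
        frame = pd.DataFrame(
            {"a": [2.0, 2.0, 4.0], "b": [7.0, 0.0, 0.0], "z": [0.0, 0.0, 0.0]}
        ).T
        scaled, zero = scale_rows(frame)
        assert scaled.loc["a"].tolist() == [0.25, 0.25, 0.5]
        assert scaled.loc["b"].tolist() == [1.0, 0.0, 0.0]
        assert scaled.loc["z"].tolist() == [0.0, 0.0, 0.0]
        assert zero.tolist() == [False, False, True]
        sums = scaled.sum(axis=1)
        assert abs(sums["a"] - 1.0) < 1e-9 and abs(sums["b"] - 1.0) < 1e-9

    def test_single_column(self):
        scaled, _ = scale_rows(pd.DataFrame({"s": {"g": 7.0}}))
        assert scaled.loc["g", "s"] == pytest.approx(1.0)


class TestKmeans:
    def _two_groups(self):
        rng = np.random.default_rng(0)
        rows = {}
        for i in range(12):
            rows[f"early{i}"] = [10, 10, 1, 1, 1, 1] + rng.normal(0, 0.05, 6)
        for i in range(12):
            rows[f"late{i}"] = [1, 1, 1, 1, 10, 10] + rng.normal(0, 0.05, 6)
        return pd.DataFrame(rows).T

    def test_recovers_separated_groups(self):
        frame = self._two_groups()
        result = cluster_kmeans(frame, k=2, seed=1, transform="scaled")
        truth = [0] * 12 + [1] * 12
        assert adjusted_rand_score(truth, result.labels.values) == 1.0

    def test_deterministic_and_k_edge_cases(self):
        frame = self._two_groups()
        a = cluster_kmeans(frame, k=4, seed=9, transform="log")
        b = cluster_kmeans(frame, k=4, seed=9, transform="log")
        assert (a.labels == b.labels).all()
        one = cluster_kmeans(frame, k=1, seed=0, transform="none")
        assert set(one.labels) == {1}
        with pytest.raises(ValueError):
            cluster_kmeans(frame, k=len(frame) + 1, seed=0)


def brute_force_corr(a: np.ndarray, b: np.ndarray, method: str) -> float:
    if method == "spearman":
        a = np.argsort(np.argsort(a)).astype(float)
        b = np.argsort(np.argsort(b)).astype(float)
    am, bm = a - a.mean(), b - b.mean()
    return float((am * bm).sum() / np.sqrt((am**2).sum() * (bm**2).sum()))


class TestCorrelation:
    def test_diagonal_and_known_values(self):
        m = make_matrix(
            {
                "g1": {("oocyte", "PA"): 1.0, ("oocyte", "RZ"): 2.0, ("st9", "PA"): 1.0},
                "g2": {("oocyte", "PA"): 2.0, ("oocyte", "RZ"): 4.0, ("st9", "PA"): 4.0},
                "g3": {("oocyte", "PA"): 3.0, ("oocyte", "RZ"): 6.0, ("st9", "PA"): 9.0},
            }
        )
        pearson = correlation_matrix(m, "pearson")
        spearman = correlation_matrix(m, "spearman")
        assert np.allclose(np.diag(pearson.values), 1.0)
        # y = 2x: perfect linear correlation
        assert pearson.loc[("oocyte", "PA"), ("oocyte", "RZ")] == pytest.approx(1.0)
        # y = x^2 on (1,2,3): monotone but not linear
        assert spearman.loc[("oocyte", "PA"), ("st9", "PA")] == pytest.approx(1.0)
        assert pearson.loc[("oocyte", "PA"), ("st9", "PA")] < 1.0

    def test_matches_textbook_implementation(self):
        rng = np.random.default_rng(13)
        values = rng.uniform(0, 50, size=(10, 6))
        frame = pd.DataFrame(
            values,
            index=[f"g{i}" for i in range(10)],
            columns=pd.MultiIndex.from_product(
                [("oocyte", "st9", "st30"), ("PA", "RZ")]
            ),
        )
        m = ExpressionMatrix(rpkm=frame, stages=("oocyte", "st9", "st30"))
        for method in ("pearson", "spearman"):
            corr = correlation_matrix(m, method)
            for i in range(6):
                for j in range(6):
                    want = brute_force_corr(values[:, i], values[:, j], method)
                    assert corr.iloc[i, j] == pytest.approx(want, abs=1e-12)

    def test_zero_variance_condition_is_missing(self):
        m = make_matrix(
            {
                "g1": {("oocyte", "PA"): 1.0, ("st9", "PA"): 5.0},
                "g2": {("oocyte", "PA"): 1.0, ("st9", "PA"): 6.0},
            }
        )
        corr = correlation_matrix(m, "pearson")
        assert np.isnan(corr.loc[("oocyte", "PA"), ("st9", "PA")])


# ---------------------------------------------------------------------------
# Induction timing / peak stages
# ---------------------------------------------------------------------------

class TestTiming:
    def test_cumulative_fraction_by_first_fold_stage(self):
        rows = {}
        for name, onset in [("a", "st9"), ("b", "st9"), ("c", "st12"), ("d", "st30")]:
            prof = flat(1.0, 1.0)
            seen = False
            for s in STAGES:
                if s == onset:
                    seen = True
                if seen and s != "oocyte":
                    prof[(s, "PA")] = 8.0
            rows[name] = prof
        m = make_matrix(rows)
        timing = induction_timing(m, {"a", "b", "c", "d"}, fold=4)
        assert timing["st9"] == pytest.approx(0.5)
        assert timing["st12"] == pytest.approx(0.75)
        assert timing["st30"] == pytest.approx(1.0)

    def test_peak_fractions_partition_with_earliest_tie(self):
        m = make_matrix(
            {
                "flat": flat(2.0, 2.0),
                "late": flat(1.0, 1.0, {("st30", "PA"): 9.0}),
            }
        )
        fracs = peak_stage_fractions(m, {"flat", "late"})
        assert fracs.sum() == pytest.approx(1.0)
        assert fracs["oocyte"] == pytest.approx(0.5)  # flat gene ties -> earliest
        assert fracs["st30"] == pytest.approx(0.5)

    def test_empty_set_errors(self, boundary_matrix):
        with pytest.raises(ValueError):
            induction_timing(boundary_matrix, set())


# ---------------------------------------------------------------------------
# qPCR fold change
# ---------------------------------------------------------------------------

class TestDdct:
    def test_reference_stage_is_fold_one(self):
        table = QpcrTable(
            {("g", "st9"): 20.0, ("odc1", "st9"): 18.0},
            normalizer="odc1",
            reference_stage="st9",
        )
        out = ddct_fold_change(table).set_index(["gene", "stage"])
        assert out.loc[("g", "st9"), "fold_change"] == pytest.approx(1.0)

    def test_worked_example_and_inverse(self):
        # stage: dCt = 20-18 = 2; reference: dCt = 22-18 = 4; ddCt = -2 -> 4x
        table = QpcrTable(
            {
                ("g", "st10"): 20.0,
                ("odc1", "st10"): 18.0,
                ("g", "st9"): 22.0,
                ("odc1", "st9"): 18.0,
                ("h", "st10"): 21.0,
                ("h", "st9"): 20.0,
            },
            normalizer="odc1",
            reference_stage="st9",
        )
        out = ddct_fold_change(table).set_index(["gene", "stage"])
        assert out.loc[("g", "st10"), "fold_change"] == pytest.approx(4.0)
        # h: ddCt = (21-18) - (20-18) = 1 -> fold 0.5
        assert out.loc[("h", "st10"), "fold_change"] == pytest.approx(0.5)

    def test_missing_normalizer_errors(self):
        table = QpcrTable(
            {("g", "st9"): 20.0}, normalizer="odc1", reference_stage="st9"
        )
        with pytest.raises(KeyError):
            ddct_fold_change(table)


# ---------------------------------------------------------------------------
# Recovery of planted classes on the synthetic bundle
# ---------------------------------------------------------------------------

class TestRecovery:
    def test_planted_classes_recovered(self, bundle):
        """Threshold classifiers recover >= 95% of planted class calls;
        errors arise only from Poisson noise at class boundaries."""
        truth = bundle.truth
        matrix = build_expression_matrix(
            bundle.counts, bundle.reference, bundle.totals, truth.config.stages
        )
        calls = classify_genes(matrix)
        total = correct = 0
        for g in truth.genes:
            if g.reference_model is None or g.label == "unspliced_single_exon":
                continue
            row = calls.loc[g.model_id]
            checks = [
                (bool(row["maternal"]), g.label.startswith("maternal")),
                (bool(row["embryonic"]), g.label == "embryonic_only"),
            ]
            for stage in ("oocyte", "st6", "st9"):
                checks.append(
                    (
                        bool(row[f"rz_enriched_{stage}"]),
                        g.label == "maternal_deadenylated",
                    )
                )
            for got, want in checks:
                total += 1
                correct += got == want
        assert correct / total >= 0.95
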