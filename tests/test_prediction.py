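import numpy as np
import pytest
from scipy import stats

from onfhost.measures import DegenerateInputError, GenomeFeatures, MeasureConfig
from onfhost.prediction import (
    RANKS,
    DissimilarityMatrix,
    TaxonomyTable,
    compute_matrix,
    predict_consensus,
    predict_nearest,
    ranksum_taxa,
)
from onfhost.sequence_io import SequenceRecord

from conftest import make_record


def lineage(genus, family="f0", order="o0", klass="c0", phylum="p0",
            domain="d0"):
    return {
        "genus": genus, "family": family, "order": order,
        "class": klass, "phylum": phylum, "domain": domain,
    }


def matrix_of(rows, virus_ids=None, host_ids=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    virus_ids = virus_ids or [f"v{i}" for i in range(rows.shape[0])]
    host_ids = host_ids or [f"h{j}" for j in range(rows.shape[1])]
    return DissimilarityMatrix(
        virus_ids=virus_ids, host_ids=host_ids, scores=rows,
        config=MeasureConfig("d2star", k=2, order=0),
    )


@pytest.fixture
def tax3():
    return TaxonomyTable(
        rows={"h0": lineage("g1"), "h1": lineage("g2"), "h2": lineage("g3")}
    )


class TestComputeMatrix:
    def test_identical_virus_host_scores_zero(self):
        seq = "ACGTACGGTACGTTACGACGT" * 20
        v = SequenceRecord("v", [seq])
        h = SequenceRecord("h", [seq])
        m = compute_matrix([v], [h], MeasureConfig("d2star", k=2, order=0))
        assert m.scores[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_pairwise_calls(self, rng):
        from onfhost.measures import compute_score

        config = MeasureConfig("d2star", k=3, order=1)
        vs = [make_record(rng, 300, f"v{i}") for i in range(2)]
        hs = [make_record(rng, 300, f"h{j}") for j in range(3)]
        m = compute_matrix(vs, hs, config)
        for i, v in enumerate(vs):
            for j, h in enumerate(hs):
                single = compute_score(GenomeFeatures(v), GenomeFeatures(h), config)
                assert m.scores[i, j] == single

    def test_host_subset_is_column_subset(self, rng):
        config = MeasureConfig("Eu", k=2, order=0)
        vs = [make_record(rng, 200, f"v{i}") for i in range(2)]
        hs = [make_record(rng, 200, f"h{j}") for j in range(4)]
        full = compute_matrix(vs, hs, config)
        sub = full.subset_hosts(["h3", "h1"])
        np.testing.assert_array_equal(sub.scores, full.scores[:, [3, 1]])
        assert sub.host_ids == ["h3", "h1"]

    def test_degenerate_genome_named(self, rng):
        config = MeasureConfig("d2star", k=2, order=0)
        good = make_record(rng, 200, "good")
        bad = SequenceRecord("homopoly", ["A" * 100])
        with pytest.raises(DegenerateInputError, match="homopoly"):
            compute_matrix([good], [good, bad], config)

    def test_tsv_round_trip(self, tmp_path, rng):
        config = MeasureConfig("d2", k=2, order=0)
        m = compute_matrix(
            [make_record(rng, 150, "v0")],
            [make_record(rng, 150, f"h{j}") for j in range(3)],
            config,
        )
        p = tmp_path / "m.tsv"
        m.to_tsv(p)
        back = DissimilarityMatrix.from_tsv(p, config)
        np.testing.assert_array_equal(back.scores, m.scores)  # exact (repr)
        assert back.host_ids == m.host_ids


class TestPredictNearest:
    def test_argmin(self, tax3):
        preds = predict_nearest(matrix_of([[0.3, 0.1, 0.2]]), tax3)
        p = preds.predictions["v0"]
        assert p.taxa["genus"] == "g2"
        assert p.best_score == pytest.approx(0.1)
        assert p.supporting_hosts == ["h1"]

    def test_threshold_gate(self, tax3):
        preds = predict_nearest(matrix_of([[0.3, 0.1, 0.2]]), tax3, threshold=0.05)
        p = preds.predictions["v0"]
        assert all(p.taxa[r] is None for r in RANKS)
        assert p.supporting_hosts == []

    def test_threshold_inclusive(self, tax3):
        preds = predict_nearest(matrix_of([[0.3, 0.1, 0.2]]), tax3, threshold=0.1)
        assert preds.predictions["v0"].taxa["genus"] == "g2"

    def test_tie_break_deterministic_and_uniform(self, tax3):
        m = matrix_of([[0.1, 0.1, 0.5]])
        first = predict_nearest(m, tax3, seed=123).predictions["v0"].taxa["genus"]
        again = predict_nearest(m, tax3, seed=123).predictions["v0"].taxa["genus"]
        assert first == again
        picks = [
            predict_nearest(m, tax3, seed=s).predictions["v0"].taxa["genus"]
            for s in range(1000)
        ]
        frac_g1 = sum(p == "g1" for p in picks) / 1000
        assert abs(frac_g1 - 0.5) < 0.05

    def test_missing_host_errors(self):
        tax = TaxonomyTable(rows={"h0": lineage("g1")})
        with pytest.raises(KeyError, match="h1"):
            predict_nearest(matrix_of([[0.1, 0.2]]), tax)

    def test_unknown_taxon_gives_no_prediction_at_rank(self):
        tax = TaxonomyTable(rows={"h0": lineage("unknown", family="f9")})
        p = predict_nearest(matrix_of([[0.1]]), tax).predictions["v0"]
        assert p.taxa["genus"] is None
        assert p.taxa["family"] == "f9"


class TestPredictConsensus:
    def test_n1_equals_nearest(self, rng):
        hosts = {f"h{j}": lineage(f"g{j % 3}", family=f"f{j % 2}") for j in range(6)}
        tax = TaxonomyTable(rows=hosts)
        scores = rng.random((5, 6))
        m = matrix_of(scores, host_ids=list(hosts))
        near = predict_nearest(m, tax, seed=0)
        cons = predict_consensus(m, tax, n=1, seed=0)
        for v in near.predictions:
            assert near.predictions[v].taxa == cons.predictions[v].taxa

    def test_clear_majority(self):
        genera = ["gA", "gA", "gB", "gA", "gC"]
        tax = TaxonomyTable(
            rows={f"h{j}": lineage(genera[j]) for j in range(5)}
        )
        m = matrix_of([[0.1, 0.2, 0.3, 0.4, 0.5]])
        p = predict_consensus(m, tax, n=5).predictions["v0"]
        assert p.taxa["genus"] == "gA"

    def test_vote_tie_uniform(self):
        genera = ["gA", "gA", "gB", "gB"]
        tax = TaxonomyTable(rows={f"h{j}": lineage(genera[j]) for j in range(4)})
        m = matrix_of([[0.1, 0.2, 0.3, 0.4]])
        picks = [
            predict_consensus(m, tax, n=4, seed=s).predictions["v0"].taxa["genus"]
            for s in range(1000)
        ]
        frac = sum(p == "gA" for p in picks) / 1000
        assert abs(frac - 0.5) < 0.05

    def test_unknown_never_wins(self):
        genera = ["unknown", "unknown", "gB"]
        tax = TaxonomyTable(rows={f"h{j}": lineage(genera[j]) for j in range(3)})
        m = matrix_of([[0.1, 0.2, 0.3]])
        p = predict_consensus(m, tax, n=3, seed=1).predictions["v0"]
        assert p.taxa["genus"] == "gB"

    def test_threshold_on_best_score(self, tax3):
        m = matrix_of([[0.3, 0.2, 0.25]])
        p = predict_consensus(m, tax3, n=3, threshold=0.1).predictions["v0"]
        assert all(p.taxa[r] is None for r in RANKS)

    def test_invalid_n(self, tax3):
        with pytest.raises(ValueError):
            predict_consensus(matrix_of([[0.1, 0.2, 0.3]]), tax3, n=4)


class TestThresholdMonotonicity:
    def test_raising_threshold_never_loses_predictions(self, rng):
        hosts = {f"h{j}": lineage(f"g{j}") for j in range(8)}
        tax = TaxonomyTable(rows=hosts)
        m = matrix_of(rng.random((10, 8)), host_ids=list(hosts))
        predicted_sets = []
        for t in (0.05, 0.1, 0.3, 0.6, 1.0):
            preds = predict_nearest(m, tax, threshold=t, seed=0)
            predicted_sets.append(
                {v for v, p in preds.predictions.items()
                 if p.taxa["genus"] is not None}
            )
        for a, b in zip(predicted_sets, predicted_sets[1:]):
            assert a <= b


class TestColumnOrderInvariance:
    def test_prediction_invariant_to_host_order(self, rng):
        hosts = {f"h{j}": lineage(f"g{j}") for j in range(6)}
        tax = TaxonomyTable(rows=hosts)
        scores = rng.random((4, 6))
        m = matrix_of(scores, host_ids=list(hosts))
        perm = rng.permutation(6)
        m2 = matrix_of(scores[:, perm], host_ids=[f"h{j}" for j in perm])
        p1 = predict_nearest(m, tax, seed=0)
        p2 = predict_nearest(m2, tax, seed=0)
        for v in p1.predictions:
            assert p1.predictions[v].taxa == p2.predictions[v].taxa


class TestRanksum:
    def test_extreme_separation_detected(self):
        hosts = {}
        scores = []
        for j in range(20):
            hosts[f"a{j}"] = lineage("gA")
            scores.append(0.1)
        for j in range(200):
            hosts[f"b{j}"] = lineage(f"g{j % 5 + 1}")
            scores.append(0.9)
        tax = TaxonomyTable(rows=hosts)
        hits = ranksum_taxa(np.array(scores), list(hosts), tax, "genus")
        assert hits and hits[0][0] == "gA"
        assert hits[0][1] < 0.05

    def test_type_one_error_controlled(self):
        rng = np.random.default_rng(4242)
        hosts = {f"h{j}": lineage(f"g{j % 6}") for j in range(60)}
        tax = TaxonomyTable(rows=hosts)
        false_hits = 0
        n_rep = 500
        for _ in range(n_rep):
            scores = rng.random(60)
            if ranksum_taxa(scores, list(hosts), tax, "genus"):
                false_hits += 1
        # binomial(500, 0.05): mean 25, sd ~4.9; allow ~3 sd
        assert false_hits <= 40

    def test_single_host_taxon_lacks_power(self):
        rng = np.random.default_rng(7)
        hosts = {"solo": lineage("gSolo")}
        scores = [0.01]
        for j in range(999):
            hosts[f"h{j}"] = lineage(f"g{j % 10}")
            scores.append(float(rng.uniform(0.2, 1.0)))
        tax = TaxonomyTable(rows=hosts)
        hits = ranksum_taxa(np.array(scores), list(hosts), tax, "genus")
        assert "gSolo" not in [t for t, _ in hits]

    def test_degenerate_partition_errors(self):
        hosts = {f"h{j}": lineage("gOnly") for j in range(5)}
        tax = TaxonomyTable(rows=hosts)
        with pytest.raises(ValueError, match="distinct taxa"):
            ranksum_taxa(np.arange(5.0), list(hosts), tax, "genus")


class TestTaxonomyIO:
    def test_tsv_round_trip(self, tmp_path):
        tax = TaxonomyTable(
            rows={"hA": lineage("g1"), "hB": lineage("unknown", family="f2")}
        )
        p = tmp_path / "tax.tsv"
        tax.to_tsv(p)
        back = TaxonomyTable.from_tsv(p)
        assert back.rows == tax.rows

    def test_bad_header_rejected(self, tmp_path):
        p = tmp_path / "tax.tsv"
        p.write_text("host\tgenus\n")
        with pytest.raises(ValueError):
            TaxonomyTable.from_tsv(p)
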