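"""Local-model training contracts, pair scoring, screening and edge export."""
import numpy as np
import pytest

import blmdti as b
from blmdti import blm


def _toy_kernel(n, ids, seed=0):
    rng = np.random.default_rng(seed)
    base = rng.random((n, n))
    vals = (base + base.T) / 2 * 0.5
    np.fill_diagonal(vals, 1.0)
    return b.SimilarityMatrix(ids=tuple(ids), values=vals)


@pytest.fixture
def toy():
    cids = tuple(f"c{i}" for i in range(6))
    pids = tuple(f"p{j}" for j in range(4))
    edges = {("c0", "p0"), ("c1", "p0"), ("c2", "p1"), ("c0", "p1"),
             ("c3", "p2"), ("c4", "p2")}
    # p3 has no positives; c5 has no positives
    inter = b.InteractionSet(compound_ids=cids, protein_ids=pids,
                             edges=frozenset(edges), protein_class="GPCR")
    return _toy_kernel(6, cids, 1), _toy_kernel(4, pids, 2), inter


class TestTrainLocalModel:
    def test_zero_positive_anchor_untrainable(self, toy):
        chem, _, inter = toy
        model = b.train_local_model("p3", blm.COMPOUND_SIDE, chem, inter)
        assert not model.trainable
        assert np.all(model.decision(np.zeros((2, 6))) == blm.UNTRAINABLE_SCORE)

    def test_all_positive_anchor_untrainable(self):
        cids, pids = ("c0", "c1"), ("p0",)
        inter = b.InteractionSet(compound_ids=cids, protein_ids=pids,
                                 edges=frozenset({("c0", "p0"), ("c1", "p0")}),
                                 protein_class="GPCR")
        model = b.train_local_model("p0", blm.COMPOUND_SIDE, _toy_kernel(2, cids), inter)
        assert not model.trainable

    def test_exclusion_removes_entity(self, toy):
        chem, _, inter = toy
        model = b.train_local_model("p0", blm.COMPOUND_SIDE, chem, inter, exclude={"c0"})
        assert "c0" not in model.training_ids
        assert len(model.training_ids) == 5

    def test_unknown_anchor_rejected(self, toy):
        chem, _, inter = toy
        with pytest.raises(b.ContractError):
            b.train_local_model("p9", blm.COMPOUND_SIDE, chem, inter)

    def test_held_in_positives_score_positive_on_clean_clusters(self, clean_dataset, clean_kernels):
        """Training-set consistency: with cleanly separable clusters the
        fitted model rescoring its own training points puts every known
        positive on the positive side."""
        _, chem, _ = clean_kernels
        inter = clean_dataset.interactions
        for t in inter.protein_ids:
            model = b.train_local_model(t, blm.COMPOUND_SIDE, chem, inter)
            if not model.trainable:
                continue
            idx = np.array([chem.index_of(e) for e in model.training_ids])
            scores = model.decision(chem.values[np.ix_(idx, idx)])
            assert np.all(scores[model.labels == 1] > 0)


class TestScorePair:
    def test_modes_and_aggregation_order(self, toy):
        chem, seq, inter = toy
        smax = b.score_pair("c0", "p0", chem, seq, inter, aggregation="max")
        smean = b.score_pair("c0", "p0", chem, seq, inter, aggregation="mean")
        assert smax.mode == blm.PAIR
        assert smax.score >= smean.score
        assert smax.predicted == (smax.score > 0)

    def test_both_sides_untrainable_sentinel(self, toy):
        chem, seq, inter = toy
        # c5 has no positives (protein side untrainable); p3 has none
        # (compound side untrainable)
        ps = b.score_pair("c5", "p3", chem, seq, inter)
        assert ps.score == blm.UNTRAINABLE_SCORE
        assert not ps.predicted
        assert "both_untrainable" in ps.flags

    def test_one_side_fallback(self, toy):
        chem, seq, inter = toy
        # p3 untrainable on the compound side; c0 trainable on the protein side
        ps = b.score_pair("c0", "p3", chem, seq, inter)
        assert np.isfinite(ps.score)
        assert "compound_side_untrainable" in ps.flags

    def test_unknown_ids_rejected(self, toy):
        chem, seq, inter = toy
        with pytest.raises(b.ContractError):
            b.score_pair("cX", "p0", chem, seq, inter)

    def test_entity_order_insensitivity(self, clean_dataset, clean_kernels):
        """Permuting the order of training entities (kernels and id lists
        alike) moves no score by more than 1e-8."""
        _, chem, seq = clean_kernels
        inter = clean_dataset.interactions
        rng = np.random.default_rng(0)
        pc = rng.permutation(chem.n)
        pp = rng.permutation(seq.n)
        chem2 = b.SimilarityMatrix(ids=tuple(np.array(chem.ids)[pc]),
                                   values=chem.values[np.ix_(pc, pc)])
        seq2 = b.SimilarityMatrix(ids=tuple(np.array(seq.ids)[pp]),
                                  values=seq.values[np.ix_(pp, pp)])
        inter2 = b.InteractionSet(
            compound_ids=tuple(np.array(inter.compound_ids)[pc]),
            protein_ids=tuple(np.array(inter.protein_ids)[pp]),
            edges=inter.edges, protein_class=inter.protein_class)
        for c in inter.compound_ids[:4]:
            for t in inter.protein_ids[:3]:
                s1 = b.score_pair(c, t, chem, seq, inter).score
                s2 = b.score_pair(c, t, chem2, seq2, inter2).score
                assert abs(s1 - s2) <= 1e-8


class TestScreening:
    def test_query_equal_to_training_compound_scores_identically(self, clean_dataset, clean_kernels):
        fps, chem, _ = clean_kernels
        inter = clean_dataset.interactions
        t = inter.protein_ids[0]
        model = b.train_local_model(t, blm.COMPOUND_SIDE, chem, inter)
        # query block = the kernel rows themselves
        block = chem.values
        scores = b.screen_queries(block, list(chem.ids), chem, inter, targets=[t])
        col = [inter.compound_ids.index(e) for e in model.training_ids]
        own = model.decision(chem.values[:, col])
        got = {s.compound_id: s.score for s in scores}
        for i, cid in enumerate(chem.ids):
            assert got[cid] == pytest.approx(own[i], abs=1e-12)

    def test_enriched_cluster_ranks_higher(self, clean_dataset, clean_kernels):
        """Queries from the cluster matched to a target's family outrank
        queries from the other cluster (median score)."""
        fps, chem, _ = clean_kernels
        inter = clean_dataset.interactions
        clusters = clean_dataset.compound_clusters
        families = clean_dataset.protein_families
        scores = b.screen_queries(chem.values, list(chem.ids), chem, inter)
        for t in inter.protein_ids:
            fam = families[t]
            s_t = [s for s in scores if s.protein_id == t]
            if not s_t:
                continue
            matched = [s.score for s in s_t if clusters[s.compound_id] == fam]
            other = [s.score for s in s_t if clusters[s.compound_id] != fam]
            assert np.median(matched) > np.median(other)

    def test_all_zero_query_row_flagged(self, clean_dataset, clean_kernels):
        _, chem, _ = clean_kernels
        inter = clean_dataset.interactions
        block = np.zeros((1, inter.n_compounds))
        scores = b.screen_queries(block, ["methane_like"], chem, inter,
                                  targets=[inter.protein_ids[0]])
        assert scores[0].flags == ("low_information",)
        assert np.isfinite(scores[0].score)  # the model's bias-only response

    def test_misaligned_block_rejected(self, clean_dataset, clean_kernels):
        _, chem, _ = clean_kernels
        with pytest.raises(b.ContractError):
            b.screen_queries(np.zeros((1, 3)), ["q"], chem, clean_dataset.interactions)


class TestExportEdges:
    def _scores(self):
        return [b.PairScore("c1", "p1", 2.0, blm.PAIR),
                b.PairScore("c2", "p1", 0.5, blm.PAIR),
                b.PairScore("c3", "p2", 1.0, blm.PAIR),
                b.PairScore("c4", "p2", -0.5, blm.PAIR),
                b.PairScore("c5", "p3", -2.0, blm.PAIR)]

    def test_threshold_and_sorting(self, tmp_path):
        out = tmp_path / "edges.tsv"
        n = b.export_edges(self._scores(), out, threshold=0)
        lines = out.read_text().splitlines()
        assert n == 3
        assert lines[0].startswith("compound_id\t")
        assert [l.split("\t")[0] for l in lines[1:]] == ["c1", "c3", "c2"]

    def test_empty_and_infinite_threshold(self, tmp_path):
        out = tmp_path / "edges.tsv"
        assert b.export_edges([], out) == 0
        assert out.read_text().splitlines() == ["compound_id\tprotein_id\tscore\tmode"]
        assert b.export_edges(self._scores(), out, threshold=float("inf")) == 0
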