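"""Atom masking, bond masking, edge attention, and the rank diagnostic."""

import numpy as np
import pytest
from scipy import stats

from eqscore.attribution import (AttributionResult, atom_masking,
                                 attention_attribution, bond_masking,
                                 distance_rank_correlation,
                                 top_protein_atoms)
from eqscore.egnn import ModelConfig, init_params, predict
from eqscore.exceptions import DiagnosticError
from eqscore.graphs import featurize
from eqscore.structures_io import AtomRecord, Complex

from conftest import rigid_motion


@pytest.fixture(scope="module")
def params():
    return init_params(ModelConfig.desk(seed=4))


def _line_complex():
    """One polar ligand atom facing three protein atoms at staggered range."""
    atoms = [
        AtomRecord(0, "N", (0.0, 0.0, 0.0), True, hbond_role="donor"),
        AtomRecord(1, "C", (1.6, 0.0, 0.0), True),
        AtomRecord(2, "O", (-3.0, 0.0, 0.0), False, "UNK", 1, "A", "O1",
                   "acceptor"),
        AtomRecord(3, "C", (-4.5, 1.0, 0.0), False, "UNK", 2, "A", "C2"),
        AtomRecord(4, "C", (0.0, 5.5, 0.0), False, "UNK", 3, "A", "C3"),
    ]
    return Complex("line", atoms)


class TestAtomMasking:
    def test_deterministic(self, synthetic_graph, params):
        graph, _, _ = synthetic_graph
        a = atom_masking(params, graph)
        b = atom_masking(params, graph)
        assert a.atom_scores == b.atom_scores
        assert a.baseline_score == b.baseline_score

    def test_isolated_atom_score_is_pooling_change(self, params):
        """Oracle: removing an edgeless atom only changes the pooled mean,
        so the score must match a direct re-prediction of the reduced
        graph (manual pooling arithmetic equals the model on both sides)."""
        atoms = [
            AtomRecord(0, "N", (0.0, 0.0, 0.0), True, hbond_role="donor"),
            AtomRecord(1, "O", (-3.0, 0.0, 0.0), False, "UNK", 1, "A", "O1",
                       "acceptor"),
            AtomRecord(2, "C", (50.0, 50.0, 50.0), False, "UNK", 2, "A",
                       "C2"),  # isolated: beyond every cutoff
        ]
        graph = featurize(Complex("iso", atoms))
        incident = np.isin(graph.edge_index, [2]).any(axis=0)
        assert not incident.any()
        result = atom_masking(params, graph)
        reduced = graph.without_nodes({2})
        expected = result.baseline_score - predict(reduced, params).score
        assert result.atom_scores[2] == pytest.approx(expected, abs=1e-12)

    def test_sole_ligand_atom_skipped_with_warning(self, params):
        atoms = [
            AtomRecord(0, "N", (0.0, 0.0, 0.0), True, hbond_role="donor"),
            AtomRecord(1, "O", (-3.0, 0.0, 0.0), False, "UNK", 1, "A", "O1",
                       "acceptor"),
        ]
        graph = featurize(Complex("solo", atoms))
        with pytest.warns(UserWarning, match="no ligand atoms"):
            result = atom_masking(params, graph)
        assert 0 not in result.atom_scores
        assert 1 in result.atom_scores


class TestBondMasking:
    def test_matches_brute_force_re_prediction(self, params):
        """Oracle: independent loop deleting each eligible undirected edge
        and re-running the model."""
        graph = featurize(_line_complex())
        result = bond_masking(params, graph, max_dist=6.0)
        baseline = predict(graph, params).score
        src, dst = graph.edge_index
        dist = np.linalg.norm(graph.positions[src] - graph.positions[dst],
                              axis=1)
        lp = graph.edge_attrs[:, 1].astype(bool)
        seen = set()
        for e in np.nonzero(lp & (dist < 6.0))[0]:
            i, j = int(src[e]), int(dst[e])
            pair = (min(i, j), max(i, j))
            if pair in seen:
                continue
            seen.add(pair)
            drop = ((src == i) & (dst == j)) | ((src == j) & (dst == i))
            expected = baseline - predict(graph.without_edges(drop),
                                          params).score
            lig, prot = (i, j) if graph.is_ligand[i] else (j, i)
            key = (int(graph.source_atom_ids[lig]),
                   int(graph.source_atom_ids[prot]))
            assert result.edge_scores[key] == pytest.approx(expected,
                                                            abs=1e-12)
        assert len(result.edge_scores) == len(seen)

    def test_distance_convention_excludes_long_edges(self, params):
        graph = featurize(_line_complex())
        result = bond_masking(params, graph, max_dist=4.0)
        # ligand N (id 0) to protein C3 (id 4) sits at 5.5 A: not scored
        assert (0, 4) not in result.edge_scores
        assert (0, 2) in result.edge_scores  # 3.0 A contact is scored

    def test_attention_zeroed_edge_scores_zero(self, synthetic_graph,
                                               params):
        graph, _, _ = synthetic_graph
        mask = np.ones(graph.n_edges)
        src, dst = graph.edge_index
        lp = np.nonzero(graph.edge_attrs[:, 1])[0]
        i, j = int(src[lp[0]]), int(dst[lp[0]])
        pair_mask = ((src == i) & (dst == j)) | ((src == j) & (dst == i))
        mask[pair_mask] = 0.0
        base = predict(graph, params, edge_mask=mask).score
        deleted = predict(graph.without_edges(pair_mask), params,
                          edge_mask=mask[~pair_mask]).score
        assert abs(base - deleted) < 1e-5

    def test_no_eligible_edges_warns(self, params):
        atoms = [
            AtomRecord(0, "N", (0.0, 0.0, 0.0), True, hbond_role="donor"),
            AtomRecord(1, "O", (-8.0, 0.0, 0.0), False, "UNK", 1, "A", "O1",
                       "acceptor"),
        ]
        graph = featurize(Complex("far", atoms))
        with pytest.warns(UserWarning, match="no eligible edges"):
            result = bond_masking(params, graph, max_dist=4.0)
        assert result.edge_scores == {}


class TestAttentionAttribution:
    def test_scores_in_unit_interval(self, synthetic_graph, params):
        graph, _, _ = synthetic_graph
        result = attention_attribution(params, graph)
        values = np.array(list(result.edge_scores.values()))
        assert np.all((values >= 0) & (values <= 1))

    def test_single_lp_edge_is_top_ranked(self, params):
        atoms = [
            AtomRecord(0, "N", (0.0, 0.0, 0.0), True, hbond_role="donor"),
            AtomRecord(1, "O", (-3.0, 0.0, 0.0), False, "UNK", 1, "A", "O1",
                       "acceptor"),
        ]
        graph = featurize(Complex("one-edge", atoms))
        result = attention_attribution(params, graph)
        assert list(result.edge_scores) == [(0, 1)]
        assert top_protein_atoms(result, 1)[0][0] == 1

    def test_invariant_under_rigid_motion(self, synthetic_graph, params):
        graph, complex_, _ = synthetic_graph
        rng = np.random.default_rng(11)
        rotation, translation = rigid_motion(rng, reflect=True)
        moved = featurize(complex_.transformed(rotation, translation))
        a = attention_attribution(params, graph)
        b = attention_attribution(params, moved)
        assert set(a.edge_scores) == set(b.edge_scores)
        for key in a.edge_scores:
            assert a.edge_scores[key] == pytest.approx(b.edge_scores[key],
                                                       abs=1e-6)


class TestTopProteinAtoms:
    def _result(self, edge_scores, protein_ids):
        return AttributionResult(
            method="edge_attention", atom_scores={},
            edge_scores=edge_scores, baseline_score=0.0,
            is_ligand={i: i not in protein_ids
                       for pair in edge_scores for i in pair})

    def test_k_must_be_positive(self):
        result = self._result({(0, 10): 0.5}, {10})
        with pytest.raises(ValueError):
            top_protein_atoms(result, 0)

    def test_shared_protein_atom_deduplicated_with_best_score(self):
        result = self._result({(0, 10): 0.9, (1, 10): 0.7, (2, 11): 0.5},
                              {10, 11})
        top = top_protein_atoms(result, 3)
        assert top == [(10, 0.9), (11, 0.5)]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sort_and_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        protein_ids = set(range(100, 112))
        edge_scores = {(int(l), int(p)): float(rng.random())
                       for l in range(8) for p in rng.choice(
                           sorted(protein_ids), size=4, replace=False)}
        result = self._result(edge_scores, protein_ids)
        k = 7
        ranked = sorted(edge_scores.items(), key=lambda kv: (-kv[1], kv[0]))
        best = {}
        for (_, p), s in ranked[:k]:  # brute-force scan
            if p not in best or s > best[p]:
                best[p] = s
        expected = sorted(best.items(), key=lambda kv: (-kv[1], kv[0]))
        assert top_protein_atoms(result, k) == expected


class TestDistanceRankCorrelation:
    def _complex_with_scores(self, scores_by_distance):
        """Protein atoms at increasing distance from one polar ligand atom."""
        atoms = [AtomRecord(0, "N", (0.0, 0.0, 0.0), True,
                            hbond_role="donor")]
        edge_scores = {}
        for i, (dist, score) in enumerate(scores_by_distance, start=1):
            atoms.append(AtomRecord(i, "O", (dist, 0.0, 0.0), False, "UNK",
                                    i, "A", f"O{i}", "acceptor"))
            edge_scores[(0, i)] = score
        complex_ = Complex("ranked", atoms)
        result = AttributionResult(
            method="edge_attention", atom_scores={},
            edge_scores=edge_scores, baseline_score=0.0,
            is_ligand={a.atom_id: a.is_ligand for a in atoms})
        return complex_, result

    def test_perfectly_ordered_scores_give_rho_one(self):
        complex_, result = self._complex_with_scores(
            [(3.0, 0.9), (4.0, 0.7), (5.0, 0.5), (6.0, 0.3)])
        assert distance_rank_correlation(result, complex_, k=4) == \
            pytest.approx(1.0)

    def test_anti_ordered_scores_give_rho_minus_one(self):
        complex_, result = self._complex_with_scores(
            [(3.0, 0.1), (4.0, 0.3), (5.0, 0.5), (6.0, 0.9)])
        assert distance_rank_correlation(result, complex_, k=4) == \
            pytest.approx(-1.0)

    def test_matches_rank_then_pearson_arithmetic(self):
        """Oracle: textbook Spearman = Pearson on average ranks."""
        rng = np.random.default_rng(21)
        pairs = [(float(d), float(rng.random()))
                 for d in rng.uniform(3, 8, size=10)]
        complex_, result = self._complex_with_scores(pairs)
        rho = distance_rank_correlation(result, complex_, k=10)
        top = top_protein_atoms(result, 10)
        scores = np.array([s for _, s in top])
        dists = np.array([abs(complex_.atom_by_id(i).position[0])
                          for i, _ in top])
        ranks_s = stats.rankdata(scores)
        ranks_d = stats.rankdata(-dists)
        expected = np.corrcoef(ranks_s, ranks_d)[0, 1]
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_requires_polar_ligand_atom(self):
        atoms = [AtomRecord(0, "C", (0.0, 0.0, 0.0), True),
                 AtomRecord(1, "C", (3.0, 0.0, 0.0), False, "UNK", 1, "A",
                            "C1")]
        result = AttributionResult(
            method="edge_attention", atom_scores={},
            edge_scores={(0, 1): 0.5, (0, 2): 0.4, (0, 3): 0.3},
            baseline_score=0.0, is_ligand={0: True, 1: False})
        with pytest.raises(DiagnosticError):
            distance_rank_correlation(result, Complex("apolar", atoms), k=3)

    def test_small_k_rejected(self, synthetic_graph, params):
        graph, complex_, _ = synthetic_graph
        result = attention_attribution(params, graph)
        with pytest.raises(ValueError):
            distance_rank_correlation(result, complex_, k=2)
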