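"""Input attribution for the equivariant scoring function.

Three procedures are provided:

* **atom masking** — score(i) = f(graph) - f(graph without atom i), where
  removal deletes the atom and its incident edges;
* **bond masking** — per eligible edge (intermolecular edges whose endpoint
  distance is below 4 Angstrom by default, both directions removed
  together), score = f(graph) - f(graph without that edge);
* **edge attention** — the final layer's attention weights on
  ligand-protein edges, read directly from the forward pass; direction
  pairs of one undirected contact are averaged, and each protein atom is
  scored by the maximum over its incident intermolecular edges.

A diagnostic is included: the Spearman rank correlation between the scores
of the top-k protein atoms and (negated) distance to the nearest polar
ligand atom, so that positive correlation means higher-scored protein atoms
sit closer to ligand donors/acceptors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .egnn import ModelParams, predict
from .exceptions import DiagnosticError
from .graphs import ComplexGraph
from .structures_io import Complex

__all__ = [
    "AttributionResult",
    "atom_masking",
    "bond_masking",
    "attention_attribution",
    "top_protein_atoms",
    "distance_rank_correlation",
    "BOND_MASKING_MAX_DIST",
]

#: Intermolecular masking convention: only edges shorter than this are scored.
BOND_MASKING_MAX_DIST = 4.0


@dataclass
class AttributionResult:
    method: str                      # atom_masking | bond_masking | edge_attention
    atom_scores: dict                # atom_id -> score
    edge_scores: dict                # (atom_id, atom_id) -> score
    baseline_score: float
    is_ligand: dict = field(default_factory=dict)   # atom_id -> bool


def _edge_distances(graph: ComplexGraph) -> np.ndarray:
    src, dst = graph.edge_index
    return np.linalg.norm(graph.positions[src] - graph.positions[dst], axis=1)


def _undirected_pairs(graph: ComplexGraph, mask: np.ndarray) -> dict:
    """Group directed edge indices by undirected node pair, within a mask."""
    pairs: dict = {}
    src, dst = graph.edge_index
    for e in np.nonzero(mask)[0]:
        key = (min(src[e], dst[e]), max(src[e], dst[e]))
        pairs.setdefault(key, []).append(int(e))
    return pairs


def atom_masking(params: ModelParams, graph: ComplexGraph
                 ) -> AttributionResult:
    """Score each atom by the prediction drop when it is removed."""
    if graph.n_nodes < 2:
        raise ValueError("atom masking needs at least 2 atoms")
    baseline = predict(graph, params).score
    atom_scores = {}
    n_ligand = int(graph.is_ligand.sum())
    for node in range(graph.n_nodes):
        if graph.is_ligand[node] and n_ligand == 1:
            warnings.warn(f"skipping atom {graph.source_atom_ids[node]}: "
                          "removal would leave no ligand atoms")
            continue
        masked = graph.without_nodes({node})
        atom_scores[int(graph.source_atom_ids[node])] = (
            baseline - predict(masked, params).score)
    return AttributionResult(
        method="atom_masking", atom_scores=atom_scores, edge_scores={},
        baseline_score=baseline,
        is_ligand={int(i): bool(l) for i, l in
                   zip(graph.source_atom_ids, graph.is_ligand)})


def bond_masking(params: ModelParams, graph: ComplexGraph,
                 max_dist: float = BOND_MASKING_MAX_DIST,
                 intermolecular_only: bool = True) -> AttributionResult:
    """Score eligible edges by the prediction drop when they are deleted.

    Both directions of an undirected contact are removed together and the
    contact receives one score.  Protein atoms inherit the maximum score
    over their incident scored edges.
    """
    distances = _edge_distances(graph)
    eligible = distances < max_dist
    if intermolecular_only:
        eligible &= graph.edge_attrs[:, 1].astype(bool)
    pairs = _undirected_pairs(graph, eligible)
    baseline = predict(graph, params).score

    edge_scores, atom_scores = {}, {}
    if not pairs:
        warnings.warn("bond masking found no eligible edges")
    for (i, j), directed in pairs.items():
        drop = np.zeros(graph.n_edges, dtype=bool)
        drop[directed] = True
        masked = graph.without_edges(drop)
        score = baseline - predict(masked, params).score
        id_i = int(graph.source_atom_ids[i])
        id_j = int(graph.source_atom_ids[j])
        if graph.is_ligand[i] and not graph.is_ligand[j]:
            key = (id_i, id_j)
        elif graph.is_ligand[j] and not graph.is_ligand[i]:
            key = (id_j, id_i)
        else:
            key = (min(id_i, id_j), max(id_i, id_j))
        edge_scores[key] = score
        for node, atom_id in ((i, id_i), (j, id_j)):
            if not graph.is_ligand[node]:
                atom_scores[atom_id] = max(atom_scores.get(atom_id, -np.inf),
                                           score)
    return AttributionResult(
        method="bond_masking", atom_scores=atom_scores,
        edge_scores=edge_scores, baseline_score=baseline,
        is_ligand={int(i): bool(l) for i, l in
                   zip(graph.source_atom_ids, graph.is_ligand)})


def attention_attribution(params: ModelParams, graph: ComplexGraph
                          ) -> AttributionResult:
    """Read the final layer's attention weights as edge importances.

    Ligand-protein edge keys are oriented (ligand_atom_id, protein_atom_id);
    the two directions of a contact are averaged.
    """
    result = predict(graph, params)
    lp_mask = graph.edge_attrs[:, 1].astype(bool)
    pairs = _undirected_pairs(graph, lp_mask)

    edge_scores, atom_scores = {}, {}
    for (i, j), directed in pairs.items():
        score = float(np.mean(result.attention[directed]))
        lig, prot = (i, j) if graph.is_ligand[i] else (j, i)
        key = (int(graph.source_atom_ids[lig]),
               int(graph.source_atom_ids[prot]))
        edge_scores[key] = score
        prot_id = key[1]
        atom_scores[prot_id] = max(atom_scores.get(prot_id, -np.inf), score)
    return AttributionResult(
        method="edge_attention", atom_scores=atom_scores,
        edge_scores=edge_scores, baseline_score=result.score,
        is_ligand={int(i): bool(l) for i, l in
                   zip(graph.source_atom_ids, graph.is_ligand)})


def top_protein_atoms(result: AttributionResult, k: int) -> list:
    """Protein endpoints of the k highest-scoring edges.

    Deduplicated keeping the best score; ordered by score descending with
    atom_id as the deterministic tie-break.  Returns [(atom_id, score)].
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if not result.edge_scores:
        raise ValueError("attribution result has no edge scores")
    edges = sorted(result.edge_scores.items(),
                   key=lambda kv: (-kv[1], kv[0]))[:k]
    best: dict = {}
    for (a, b), score in edges:
        for atom_id in (a, b):
            if result.is_ligand.get(atom_id, False):
                continue
            if atom_id not in best or score > best[atom_id]:
                best[atom_id] = score
    return sorted(best.items(), key=lambda kv: (-kv[1], kv[0]))


def distance_rank_correlation(result: AttributionResult, complex_: Complex,
                              k: int = 10, nearest_polar: bool = True
                              ) -> float:
    """Spearman rho between top-k protein-atom scores and closeness.

    For each of the k highest-scoring protein atoms, the distance to the
    nearest polar ligand atom (N/O or any atom with a donor/acceptor role)
    is computed; rho is the Spearman rank correlation between the scores
    and the negated distances, with average ranks for ties, so rho > 0
    means higher-scored atoms sit closer to polar ligand atoms.
    """
    if k < 3:
        raise ValueError("rank correlation needs k >= 3")
    reference = [a for a in complex_.ligand_atoms
                 if (a.element in ("N", "O") or a.hbond_role != "none")
                 or not nearest_polar]
    if not reference:
        raise DiagnosticError("complex has no polar ligand atom")
    ref_pos = np.array([a.position for a in reference])

    top = top_protein_atoms(result, k)
    scores, closeness = [], []
    for atom_id, score in top:
        atom = complex_.atom_by_id(atom_id)
        dist = float(np.min(np.linalg.norm(ref_pos
                                           - np.asarray(atom.position),
                                           axis=1)))
        scores.append(score)
        closeness.append(-dist)
    if len(scores) < 3:
        raise DiagnosticError(
            f"only {len(scores)} distinct protein atoms in the top {k} edges")
    rho = stats.spearmanr(scores, closeness).statistic
    return float(rho)
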