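"""Graph representation of a bound complex.

Nodes carry a 12-wide binary feature vector: a one-hot over an 11-element
type vocabulary (unknown elements map to an "other" bucket or are rejected)
plus one bit flagging ligand atoms.  Edges connect atom pairs within a
class-dependent distance cutoff — 10 Angstrom for ligand-protein pairs and
2 Angstrom for intramolecular (ligand-ligand / protein-protein) pairs, so
intramolecular connectivity closely follows covalent structure while
intermolecular connectivity is expansive.  Edges are emitted in both
directions and typed by a one-hot over {LL, LP, PP}.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateGraphError, VocabularyError
from .structures_io import Complex

__all__ = [
    "TypeVocabulary",
    "ComplexGraph",
    "DEFAULT_VOCABULARY",
    "featurize",
    "build_edges",
    "LP_CUTOFF",
    "INTRA_CUTOFF",
    "EDGE_CLASSES",
]

LP_CUTOFF = 10.0
INTRA_CUTOFF = 2.0
EDGE_CLASSES = ("LL", "LP", "PP")


@dataclass(frozen=True)
class TypeVocabulary:
    """Ordered element vocabulary; length + ligand bit = node feature width."""

    elements: tuple = ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "B",
                       "other")
    other_bucket_policy: str = "map"  # "map" -> last slot, or "reject"

    def __post_init__(self):
        if len(set(self.elements)) != len(self.elements):
            raise ValueError("duplicate elements in vocabulary")
        if self.other_bucket_policy not in ("map", "reject"):
            raise ValueError("other_bucket_policy must be 'map' or 'reject'")

    @property
    def width(self) -> int:
        return len(self.elements) + 1  # + ligand flag bit

    def index(self, element: str) -> int:
        try:
            return self.elements.index(element)
        except ValueError:
            if self.other_bucket_policy == "map":
                return len(self.elements) - 1
            raise VocabularyError(
                f"element {element!r} not in vocabulary") from None


DEFAULT_VOCABULARY = TypeVocabulary()


@dataclass
class ComplexGraph:
    """Positions, node features, typed directed edges of one complex."""

    positions: np.ndarray          # n x 3, Angstrom
    node_features: np.ndarray      # n x width, binary
    edge_index: np.ndarray         # 2 x m (source, destination)
    edge_attrs: np.ndarray         # m x 3, one-hot over EDGE_CLASSES
    source_atom_ids: np.ndarray    # n, AtomRecord ids
    is_ligand: np.ndarray          # n, bool
    vocabulary: TypeVocabulary = field(default=DEFAULT_VOCABULARY)
    lp_cutoff: float = LP_CUTOFF
    intra_cutoff: float = INTRA_CUTOFF

    @property
    def n_nodes(self) -> int:
        return self.positions.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_index.shape[1]

    def validate(self) -> None:
        n, m = self.n_nodes, self.n_edges
        assert self.positions.shape == (n, 3)
        assert self.node_features.shape == (n, self.vocabulary.width)
        assert self.edge_index.shape == (2, m)
        assert self.edge_attrs.shape == (m, 3)
        if m:
            assert self.edge_index.min() >= 0
            assert self.edge_index.max() < n
            assert not np.any(self.edge_index[0] == self.edge_index[1])
            assert np.all(self.edge_attrs.sum(axis=1) == 1)
        row_sums = self.node_features.sum(axis=1)
        assert np.all((row_sums == 1) | (row_sums == 2))

    def without_nodes(self, drop: set) -> "ComplexGraph":
        """Delete nodes (by graph index) and their incident edges."""
        keep = np.array([i for i in range(self.n_nodes) if i not in drop])
        remap = -np.ones(self.n_nodes, dtype=int)
        remap[keep] = np.arange(keep.size)
        src, dst = self.edge_index
        mask = np.isin(src, keep) & np.isin(dst, keep)
        edge_index = np.vstack([remap[src[mask]], remap[dst[mask]]])
        return ComplexGraph(
            positions=self.positions[keep],
            node_features=self.node_features[keep],
            edge_index=edge_index,
            edge_attrs=self.edge_attrs[mask],
            source_atom_ids=self.source_atom_ids[keep],
            is_ligand=self.is_ligand[keep],
            vocabulary=self.vocabulary,
            lp_cutoff=self.lp_cutoff, intra_cutoff=self.intra_cutoff)

    def without_edges(self, drop_mask: np.ndarray) -> "ComplexGraph":
        """Delete the edges flagged in ``drop_mask`` (length m boolean)."""
        keep = ~np.asarray(drop_mask, dtype=bool)
        return ComplexGraph(
            positions=self.positions,
            node_features=self.node_features,
            edge_index=self.edge_index[:, keep],
            edge_attrs=self.edge_attrs[keep],
            source_atom_ids=self.source_atom_ids,
            is_ligand=self.is_ligand,
            vocabulary=self.vocabulary,
            lp_cutoff=self.lp_cutoff, intra_cutoff=self.intra_cutoff)

    # -- serialization ---------------------------------------------------
    def save(self, path) -> None:
        header = json.dumps({
            "elements": list(self.vocabulary.elements),
            "other_bucket_policy": self.vocabulary.other_bucket_policy,
            "lp_cutoff": self.lp_cutoff, "intra_cutoff": self.intra_cutoff,
        })
        np.savez_compressed(
            path, positions=self.positions, node_features=self.node_features,
            edge_index=self.edge_index, edge_attrs=self.edge_attrs,
            source_atom_ids=self.source_atom_ids, is_ligand=self.is_ligand,
            header=np.frombuffer(header.encode(), dtype=np.uint8))

    @classmethod
    def load(cls, path) -> "ComplexGraph":
        data = np.load(path)
        header = json.loads(bytes(data["header"]).decode())
        vocab = TypeVocabulary(tuple(header["elements"]),
                               header["other_bucket_policy"])
        return cls(positions=data["positions"],
                   node_features=data["node_features"],
                   edge_index=data["edge_index"],
                   edge_attrs=data["edge_attrs"],
                   source_atom_ids=data["source_atom_ids"],
                   is_ligand=data["is_ligand"].astype(bool),
                   vocabulary=vocab, lp_cutoff=header["lp_cutoff"],
                   intra_cutoff=header["intra_cutoff"])


def build_edges(positions: np.ndarray, is_ligand: np.ndarray,
                lp_cutoff: float = LP_CUTOFF,
                intra_cutoff: float = INTRA_CUTOFF):
    """Distance-cutoff edges, both directions, typed LL/LP/PP.

    A pair i != j is connected iff its Euclidean distance is <= the cutoff
    for its class (closed boundary).  Returns (edge_index 2 x m,
    edge_attrs m x 3).
    """
    if lp_cutoff < intra_cutoff or intra_cutoff <= 0:
        raise ValueError("require lp_cutoff >= intra_cutoff > 0")
    positions = np.asarray(positions, dtype=float)
    is_ligand = np.asarray(is_ligand, dtype=bool)
    n = positions.shape[0]
    if n < 2:
        raise DegenerateGraphError(
            f"need at least 2 atoms to build edges, got {n}")

    diff = positions[:, None, :] - positions[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    mixed = is_ligand[:, None] != is_ligand[None, :]
    cutoff = np.where(mixed, lp_cutoff, intra_cutoff)
    adj = dist <= cutoff
    np.fill_diagonal(adj, False)

    src, dst = np.nonzero(adj)
    m = src.size
    edge_attrs = np.zeros((m, 3), dtype=np.int64)
    both_ligand = is_ligand[src] & is_ligand[dst]
    neither = ~is_ligand[src] & ~is_ligand[dst]
    edge_attrs[both_ligand, 0] = 1                       # LL
    edge_attrs[~both_ligand & ~neither, 1] = 1           # LP
    edge_attrs[neither, 2] = 1                           # PP
    return np.vstack([src, dst]).astype(np.int64), edge_attrs


def featurize(complex_: Complex, vocab: TypeVocabulary = DEFAULT_VOCABULARY,
              lp_cutoff: float = LP_CUTOFF,
              intra_cutoff: float = INTRA_CUTOFF) -> ComplexGraph:
    """Turn a (pocket-extracted) Complex into a ComplexGraph."""
    n = len(complex_.atoms)
    positions = complex_.positions
    is_ligand = complex_.is_ligand
    node_features = np.zeros((n, vocab.width), dtype=np.int64)
    for i, atom in enumerate(complex_.atoms):
        node_features[i, vocab.index(atom.element)] = 1
        if atom.is_ligand:
            node_features[i, -1] = 1
    edge_index, edge_attrs = build_edges(positions, is_ligand,
                                         lp_cutoff, intra_cutoff)
    graph = ComplexGraph(
        positions=positions, node_features=node_features,
        edge_index=edge_index, edge_attrs=edge_attrs,
        source_atom_ids=np.array([a.atom_id for a in complex_.atoms]),
        is_ligand=is_ligand, vocabulary=vocab,
        lp_cutoff=lp_cutoff, intra_cutoff=intra_cutoff)
    graph.validate()
    return graph
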