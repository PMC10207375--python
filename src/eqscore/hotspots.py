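"""Hotspot maps: ranked protein atoms aggregated across bound structures.

Attribution on a single bound structure yields an importance score for each
pocket protein atom; repeating this over a fragment screen and averaging per
protein atom (matched across structures by chain / residue index / atom
name) produces a hotspot map — a ranked list of protein atoms with
coordinates and a donor/acceptor pharmacophore type, consumable by
fragment-elaboration tools.

Two further operations support validation: a simplified geometric hydrogen-
bond counter (a protein atom becomes a hotspot when a complementary polar
ligand atom lies within hydrogen-bonding distance in strictly more than
``min_count`` structures), and a stability analysis that recomputes the
top-k hotspot set on random subsets of the screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .attribution import AttributionResult
from .structures_io import Complex

__all__ = [
    "Hotspot",
    "HotspotMap",
    "aggregate_hotspots",
    "geometric_hotspots",
    "hotspot_stability",
    "StabilityReport",
]

_DONOR_CAPABLE = {"donor", "both"}
_ACCEPTOR_CAPABLE = {"acceptor", "both"}


@dataclass(frozen=True)
class Hotspot:
    protein_atom_key: tuple          # (chain, residue_index, atom_name)
    position: tuple
    pharmacophore_type: str          # donor | acceptor
    mean_score: float
    n_structures: int
    rank: int


@dataclass
class HotspotMap:
    target_id: str
    hotspots: list
    provenance: list = field(default_factory=list)

    def top(self, k: int) -> list:
        return self.hotspots[:k]

    def top_keys(self, k: int) -> set:
        return {h.protein_atom_key for h in self.hotspots[:k]}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "rank": h.rank, "chain": h.protein_atom_key[0],
            "residue_index": h.protein_atom_key[1],
            "atom_name": h.protein_atom_key[2],
            "type": h.pharmacophore_type, "mean_score": h.mean_score,
            "n_structures": h.n_structures,
            "x": h.position[0], "y": h.position[1], "z": h.position[2],
        } for h in self.hotspots])


def _pharmacophore_type(role: str, donor_evidence: float,
                        acceptor_evidence: float) -> str:
    if role == "donor":
        return "donor"
    if role == "acceptor":
        return "acceptor"
    # "both" / "none": decide by complementary-partner evidence, ties -> donor
    return "acceptor" if acceptor_evidence > donor_evidence else "donor"


def aggregate_hotspots(results: list, target_id: str = "target",
                       normalize: bool = False) -> HotspotMap:
    """Average per-structure attribution scores per protein atom.

    ``results`` is a list of (Complex, AttributionResult) pairs sharing a
    reference protein.  Each protein atom's mean is taken over the
    structures in which it received a score (the pocket shell varies per
    ligand, so not every atom is scored everywhere).  ``normalize`` min-max
    scales each structure's scores to [0, 1] before averaging.
    """
    if not results:
        raise ValueError("aggregate_hotspots needs at least one result")
    per_atom_scores: dict = {}
    atom_info: dict = {}
    donor_evidence: dict = {}
    acceptor_evidence: dict = {}
    provenance = []

    for complex_, result in results:
        provenance.append(complex_.complex_id)
        by_id = {a.atom_id: a for a in complex_.atoms}
        scores = dict(result.atom_scores)
        if normalize and scores:
            values = np.array(list(scores.values()), dtype=float)
            lo, hi = values.min(), values.max()
            span = hi - lo if hi > lo else 1.0
            scores = {k: (v - lo) / span for k, v in scores.items()}
        for atom_id, score in scores.items():
            atom = by_id[atom_id]
            if atom.is_ligand:
                continue
            key = atom.key
            per_atom_scores.setdefault(key, []).append(float(score))
            atom_info[key] = atom
        # complementary-partner evidence for ambiguous pharmacophore types
        for (lig_id, prot_id), score in result.edge_scores.items():
            lig = by_id.get(lig_id)
            prot = by_id.get(prot_id)
            if lig is None or prot is None or not lig.is_ligand:
                continue
            key = prot.key
            if lig.hbond_role in _ACCEPTOR_CAPABLE:
                donor_evidence[key] = donor_evidence.get(key, 0.0) + score
            if lig.hbond_role in _DONOR_CAPABLE:
                acceptor_evidence[key] = (acceptor_evidence.get(key, 0.0)
                                          + score)

    if not per_atom_scores:
        raise ValueError("no shared protein atoms received scores")

    rows = []
    for key, values in per_atom_scores.items():
        atom = atom_info[key]
        rows.append((key, atom, float(np.mean(values)), len(values)))
    rows.sort(key=lambda r: (-r[2], r[0]))
    hotspots = [
        Hotspot(protein_atom_key=key, position=tuple(atom.position),
                pharmacophore_type=_pharmacophore_type(
                    atom.hbond_role, donor_evidence.get(key, 0.0),
                    acceptor_evidence.get(key, 0.0)),
                mean_score=mean, n_structures=count, rank=rank)
        for rank, (key, atom, mean, count) in enumerate(rows, start=1)
    ]
    return HotspotMap(target_id, hotspots, provenance)


def geometric_hotspots(complexes: list, hbond_dist: float = 3.5,
                       min_count: int = 5, target_id: str = "target"
                       ) -> HotspotMap:
    """Count-based baseline with simplified hydrogen-bond geometry.

    A protein atom is "highlighted" in a structure when a complementary-role
    polar ligand atom (donor opposite acceptor) lies within ``hbond_dist``.
    Atoms highlighted in strictly more than ``min_count`` structures become
    hotspots, ranked by count.
    """
    counts: dict = {}
    atom_info: dict = {}
    provenance = []
    for complex_ in complexes:
        provenance.append(complex_.complex_id)
        lig_donors = np.array([a.position for a in complex_.ligand_atoms
                               if a.hbond_role in _DONOR_CAPABLE])
        lig_acceptors = np.array([a.position for a in complex_.ligand_atoms
                                  if a.hbond_role in _ACCEPTOR_CAPABLE])
        for atom in complex_.protein_atoms:
            partners = []
            if atom.hbond_role in _DONOR_CAPABLE and lig_acceptors.size:
                partners.append(lig_acceptors)
            if atom.hbond_role in _ACCEPTOR_CAPABLE and lig_donors.size:
                partners.append(lig_donors)
            if not partners:
                continue
            pos = np.asarray(atom.position)
            dmin = min(float(np.min(np.linalg.norm(p - pos, axis=1)))
                       for p in partners)
            if dmin <= hbond_dist:
                counts[atom.key] = counts.get(atom.key, 0) + 1
                atom_info[atom.key] = atom

    rows = [(key, count) for key, count in counts.items()
            if count > min_count]
    rows.sort(key=lambda r: (-r[1], r[0]))
    hotspots = []
    for rank, (key, count) in enumerate(rows, start=1):
        atom = atom_info[key]
        hotspots.append(Hotspot(
            protein_atom_key=key, position=tuple(atom.position),
            pharmacophore_type=("donor" if atom.hbond_role in _DONOR_CAPABLE
                                else "acceptor"),
            mean_score=float(count), n_structures=count, rank=rank))
    return HotspotMap(target_id, hotspots, provenance)


@dataclass
class StabilityReport:
    subset_sizes: list
    mean_jaccard: dict              # size -> mean Jaccard with full top-k
    inclusion_frequency: pd.DataFrame  # per atom key x size
    full_top_keys: set
    n_repeats: int
    top_k: int


def hotspot_stability(results: list, subset_sizes: list,
                      n_repeats: int = 40, top_k: int = 5, seed: int = 0,
                      normalize: bool = False) -> StabilityReport:
    """Resampling stability of the top-k hotspot set.

    For each subset size, ``n_repeats`` random subsets of the per-structure
    attribution results are drawn without replacement; the hotspot map is
    recomputed each time and its top-k set compared (Jaccard) with the
    full-data top-k.  Also reports how often each protein atom enters the
    top-k at each size.
    """
    n = len(results)
    for size in subset_sizes:
        if size > n:
            raise ValueError(f"subset size {size} exceeds {n} structures")
    full = aggregate_hotspots(results, normalize=normalize)
    full_top = full.top_keys(top_k)
    rng = np.random.default_rng(seed)

    mean_jaccard = {}
    freq_rows: dict = {}
    for size in subset_sizes:
        jaccards = []
        counts: dict = {}
        for _ in range(n_repeats):
            pick = rng.choice(n, size=size, replace=False)
            subset = [results[i] for i in pick]
            top = aggregate_hotspots(subset,
                                     normalize=normalize).top_keys(top_k)
            union = full_top | top
            jaccards.append(len(full_top & top) / len(union) if union
                            else 1.0)
            for key in top:
                counts[key] = counts.get(key, 0) + 1
        mean_jaccard[size] = float(np.mean(jaccards))
        for key, count in counts.items():
            freq_rows.setdefault(key, {})[size] = count / n_repeats

    frequency = pd.DataFrame.from_dict(freq_rows, orient="index").fillna(0.0)
    frequency = frequency.reindex(sorted(frequency.columns), axis=1)
    return StabilityReport(subset_sizes=list(subset_sizes),
                           mean_jaccard=mean_jaccard,
                           inclusion_frequency=frequency,
                           full_top_keys=full_top,
                           n_repeats=n_repeats, top_k=top_k)
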