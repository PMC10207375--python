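"""Train/test leakage filters and size-matched random control subsets.

A training item is removed when it is too similar to *any* test item:
ligands by Tanimoto similarity of 2048-bit Morgan fingerprints (radius 2)
strictly above 0.8, proteins by global-alignment sequence identity strictly
above 0.8.  Items that cannot be parsed are removed too.  Test sets pass
through untouched.  Size-matched random subsets — sampled uniformly from
the unfiltered training set so they may still contain test-similar items —
serve as controls separating the effect of debiasing from the effect of
shrinking the training set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SplitManifest",
    "RemovalRecord",
    "ligand_similarity_filter",
    "sequence_identity_filter",
    "random_matched_subset",
    "tanimoto_similarity",
    "sequence_identity",
]

LIGAND_SIMILARITY_THRESHOLD = 0.8
SEQUENCE_IDENTITY_THRESHOLD = 0.8


@dataclass(frozen=True)
class RemovalRecord:
    reason: str            # ligand_similarity | sequence_identity | parse_failure | random_subsample
    offending_test_id: str = ""
    similarity: float = float("nan")


@dataclass
class SplitManifest:
    kept_ids: list
    removed: dict                      # id -> RemovalRecord
    thresholds: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self):
        overlap = set(self.kept_ids) & set(self.removed)
        if overlap:
            raise ValueError(f"ids both kept and removed: {sorted(overlap)}")

    @property
    def removed_ids(self) -> list:
        return sorted(self.removed)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"id": i, "kept": True, "reason": "", "offending_test_id": "",
                 "similarity": float("nan")} for i in self.kept_ids]
        rows += [{"id": i, "kept": False, "reason": r.reason,
                  "offending_test_id": r.offending_test_id,
                  "similarity": r.similarity}
                 for i, r in sorted(self.removed.items())]
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {"n_kept": len(self.kept_ids), "n_removed": len(self.removed),
                "thresholds": self.thresholds, "seed": self.seed}

    def save(self, csv_path, json_path=None) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        if json_path is not None:
            with open(json_path, "w") as handle:
                json.dump(self.summary(), handle, indent=2)


# -- ligand similarity ---------------------------------------------------

def _as_mol(structure):
    """Accept an RDKit Mol, a SMILES string, or a structure file path."""
    from rdkit import Chem

    if structure is None:
        return None
    if isinstance(structure, Chem.Mol):
        return structure
    text = str(structure)
    if text.endswith(".sdf"):
        supplier = Chem.SDMolSupplier(text, removeHs=False)
        return next(iter(supplier), None)
    if text.endswith(".mol2"):
        return Chem.MolFromMol2File(text, removeHs=False)
    return Chem.MolFromSmiles(text)


def _fingerprint(mol, fp_bits: int, fp_radius: int):
    from rdkit.Chem import rdFingerprintGenerator

    generator = rdFingerprintGenerator.GetMorganGenerator(
        radius=fp_radius, fpSize=fp_bits)
    return generator.GetFingerprint(mol)


def tanimoto_similarity(mol_a, mol_b, fp_bits: int = 2048,
                        fp_radius: int = 2) -> float:
    """Tanimoto similarity of Morgan fingerprints of two molecules."""
    from rdkit import DataStructs

    fp_a = _fingerprint(_as_mol(mol_a), fp_bits, fp_radius)
    fp_b = _fingerprint(_as_mol(mol_b), fp_bits, fp_radius)
    return float(DataStructs.TanimotoSimilarity(fp_a, fp_b))


def ligand_similarity_filter(train_ligands: dict, test_ligands: dict,
                             threshold: float = LIGAND_SIMILARITY_THRESHOLD,
                             fp_bits: int = 2048, fp_radius: int = 2
                             ) -> SplitManifest:
    """Remove train ligands whose max Tanimoto over test ligands exceeds
    the threshold (strict inequality).

    Values may be RDKit Mols, SMILES strings, or SDF/MOL2 paths.
    Unparseable train ligands are removed with reason ``parse_failure``.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    from rdkit import DataStructs

    test_fps = {}
    for test_id, structure in test_ligands.items():
        mol = _as_mol(structure)
        if mol is not None:
            test_fps[test_id] = _fingerprint(mol, fp_bits, fp_radius)

    kept, removed = [], {}
    for train_id in sorted(train_ligands):
        mol = _as_mol(train_ligands[train_id])
        if mol is None:
            removed[train_id] = RemovalRecord("parse_failure")
            continue
        fp = _fingerprint(mol, fp_bits, fp_radius)
        best, best_id = -1.0, ""
        for test_id, test_fp in test_fps.items():
            sim = DataStructs.TanimotoSimilarity(fp, test_fp)
            if sim > best:
                best, best_id = sim, test_id
        if best > threshold:
            removed[train_id] = RemovalRecord("ligand_similarity", best_id,
                                              float(best))
        else:
            kept.append(train_id)
    return SplitManifest(kept, removed,
                         thresholds={"tanimoto": threshold,
                                     "fp_bits": fp_bits,
                                     "fp_radius": fp_radius})


# -- sequence identity ---------------------------------------------------

def _make_aligner():
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    # gap penalties non-commensurate with the match score: co-optimal
    # alignments then share the same match and gap counts, making
    # matches / alignment-length well-defined
    aligner.open_gap_score = -2.51
    aligner.extend_gap_score = -0.53
    return aligner


def sequence_identity(seq_a: str, seq_b: str,
                      denominator: str = "alignment") -> float:
    """Identity = matches / alignment length from one global alignment.

    Scoring: match 1, mismatch 0, affine gaps (open -2.51, extend -0.53).
    ``denominator`` may be ``alignment`` (default, includes gap columns) or
    ``shorter`` (length of the shorter sequence).
    """
    if not seq_a or not seq_b:
        return 0.0
    aligner = _make_aligner()
    alignment = aligner.align(seq_a, seq_b)[0]
    a_row, b_row = alignment[0], alignment[1]
    matches = sum(1 for x, y in zip(a_row, b_row)
                  if x == y and x != "-")
    if denominator == "alignment":
        denom = len(a_row)
    elif denominator == "shorter":
        denom = min(len(seq_a), len(seq_b))
    else:
        raise ValueError("denominator must be 'alignment' or 'shorter'")
    return matches / denom


def _chains(value):
    if isinstance(value, str):
        return [value]
    return list(value)


def sequence_identity_filter(train_seqs: dict, test_seqs: dict,
                             threshold: float = SEQUENCE_IDENTITY_THRESHOLD,
                             denominator: str = "alignment"
                             ) -> SplitManifest:
    """Remove train proteins with identity to any test protein above the
    threshold (strict inequality).

    Values may be single sequences or lists of chain sequences; multi-chain
    identity is the maximum over chain pairs.  Empty sequences are removed
    with reason ``parse_failure``.
    """
    kept, removed = [], {}
    for train_id in sorted(train_seqs):
        chains = [c for c in _chains(train_seqs[train_id]) if c]
        if not chains:
            removed[train_id] = RemovalRecord("parse_failure")
            continue
        best, best_id = -1.0, ""
        for test_id, test_value in test_seqs.items():
            for test_chain in _chains(test_value):
                if not test_chain:
                    continue
                for train_chain in chains:
                    ident = sequence_identity(train_chain, test_chain,
                                              denominator)
                    if ident > best:
                        best, best_id = ident, test_id
        if best > threshold:
            removed[train_id] = RemovalRecord("sequence_identity", best_id,
                                              float(best))
        else:
            kept.append(train_id)
    return SplitManifest(kept, removed,
                         thresholds={"sequence_identity": threshold,
                                     "denominator": denominator})


# -- random matched subsets ----------------------------------------------

def random_matched_subset(train_ids: list, target_size: int,
                          seed: int = 0) -> SplitManifest:
    """Uniform sample without replacement, reproducible by seed."""
    train_ids = list(train_ids)
    if target_size > len(train_ids):
        raise ValueError(f"target_size {target_size} exceeds "
                         f"{len(train_ids)} available ids")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(train_ids), size=target_size, replace=False)
    kept_set = {train_ids[i] for i in pick}
    kept = [i for i in train_ids if i in kept_set]
    removed = {i: RemovalRecord("random_subsample")
               for i in train_ids if i not in kept_set}
    return SplitManifest(kept, removed,
                         thresholds={"target_size": target_size}, seed=seed)
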