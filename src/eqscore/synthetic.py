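"""Synthetic protein-pocket/ligand complexes with planted interactions.

The generator emulates the statistical structure the attribution and
hotspot analyses rely on: binding is driven by a small number of polar
donor-acceptor contacts at hydrogen-bonding distance, embedded in a shell
of nonpolar pocket atoms that are too far from the ligand to interact.
Ligand atoms form a compact cluster; planted contacts place complementary
donor/acceptor pairs at ``contact_distance`` +/- 0.1 Angstrom; every other
ligand-protein pair is kept at >= 4.5 Angstrom.  Decoy poses are rigid-body
perturbations of the ligand that break contacts.  All generators are pure
functions of (spec, seed).

Also provided: a fragment screen sharing one reference pocket across
structures (for hotspot aggregation), a docking-score table with a planted
hotspot-quality ordering (for the Delta-SLE statistics), and fragment
enumeration by cutting acyclic single bonds outside functional groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import GenerationError
from .graphs import featurize
from .structures_io import AtomRecord, Complex
from .training import LabeledExample

__all__ = [
    "SyntheticSpec",
    "PlantedTruth",
    "generate_complex",
    "generate_pose_dataset",
    "generate_affinity_dataset",
    "generate_fragment_screen",
    "generate_score_table",
    "enumerate_fragments",
    "FragmentCut",
    "count_intact_contacts",
]

#: Geometry of the synthetic pocket (Angstrom).
LIGAND_RADIUS = 5.0          # ligand atoms sampled in a ball of this radius
LIGAND_MIN_SEP = 3.0         # minimum ligand-ligand separation
NONCONTACT_MIN_DIST = 4.5    # floor for every non-planted ligand-protein pair
POCKET_SHELL = (4.6, 5.8)    # shell of nonpolar pocket atoms around the ligand
POCKET_MIN_SEP = 2.5         # minimum pocket-pocket separation
CONTACT_TOLERANCE = 0.1      # planted distance jitter
INTACT_CONTACT_MAX = 3.5     # a planted pair still counts as a contact below this
_MAX_TRIES = 400


@dataclass(frozen=True)
class SyntheticSpec:
    seed: int = 0
    n_ligand_atoms: int = 12
    n_pocket_atoms: int = 24
    n_planted_contacts: int = 4
    contact_distance: float = 2.9
    decoy_perturbation: float = 3.0
    label_rule_k: int = 3
    noise_sigma: float = 0.1

    def __post_init__(self):
        if self.n_planted_contacts > min(self.n_ligand_atoms,
                                         self.n_pocket_atoms):
            raise ValueError("more planted contacts than atoms to carry them")
        if not 0 < self.contact_distance < 6.0:
            raise ValueError("contact_distance must lie inside the pocket "
                             "radius")
        if self.label_rule_k < 1:
            raise ValueError("label_rule_k must be >= 1")


@dataclass
class PlantedTruth:
    contacts: list              # [(ligand_atom_id, protein_atom_id)]
    true_label: int
    true_contact_count: int


def _sample_cluster(rng, n, radius, min_sep):
    points = []
    for _ in range(n):
        for _attempt in range(_MAX_TRIES):
            candidate = rng.uniform(-radius, radius, size=3)
            if np.linalg.norm(candidate) > radius:
                continue
            if all(np.linalg.norm(candidate - p) >= min_sep for p in points):
                points.append(candidate)
                break
        else:
            raise GenerationError(
                f"could not pack {n} ligand atoms at separation {min_sep} "
                f"inside radius {radius}")
    return np.array(points)


def _unit(vector, rng=None):
    norm = np.linalg.norm(vector)
    if norm < 1e-9:
        vector = rng.normal(size=3) if rng is not None else np.array([1.0, 0,
                                                                      0])
        norm = np.linalg.norm(vector)
    return vector / norm


def _place_partner(rng, anchor, centroid, ligand_pos, placed, distance):
    """Place a contact partner near ``anchor``, far from everything else."""
    for _attempt in range(_MAX_TRIES):
        direction = _unit(anchor - centroid + rng.normal(scale=0.4, size=3),
                          rng)
        d = distance + rng.uniform(-CONTACT_TOLERANCE, CONTACT_TOLERANCE)
        candidate = anchor + d * direction
        others = np.linalg.norm(ligand_pos - candidate, axis=1)
        others = np.delete(others,
                           int(np.argmin(np.linalg.norm(ligand_pos - anchor,
                                                        axis=1))))
        if others.size and others.min() < NONCONTACT_MIN_DIST:
            continue
        if any(np.linalg.norm(candidate - p) < POCKET_MIN_SEP
               for p in placed):
            continue
        return candidate
    raise GenerationError("could not place a planted contact partner "
                          "satisfying the distance floor")


def _place_shell_atom(rng, ligand_pos, centroid, placed,
                      min_centroid_dist=0.0):
    for _attempt in range(_MAX_TRIES):
        anchor = ligand_pos[rng.integers(len(ligand_pos))]
        direction = _unit(anchor - centroid + rng.normal(scale=0.6, size=3),
                          rng)
        # walk outward along the ray until the nearest-ligand distance
        # enters the shell band (another ligand atom may be the nearest)
        offset = rng.uniform(0.0, 0.2)
        for t in np.arange(POCKET_SHELL[0] + offset, 10.0, 0.2):
            candidate = anchor + t * direction
            dmin = np.linalg.norm(ligand_pos - candidate, axis=1).min()
            if dmin > POCKET_SHELL[1]:
                break
            if dmin < NONCONTACT_MIN_DIST:
                continue
            if min_centroid_dist and (np.linalg.norm(candidate - centroid)
                                      < min_centroid_dist):
                continue
            if any(np.linalg.norm(candidate - p) < POCKET_MIN_SEP
                   for p in placed):
                continue
            return candidate
    raise GenerationError("could not place a pocket shell atom")


def _build_complex(spec, ligand_pos, ligand_elements, ligand_roles,
                   pocket_pos, pocket_elements, pocket_roles, complex_id):
    atoms = []
    for i in range(len(ligand_pos)):
        atoms.append(AtomRecord(
            atom_id=i, element=ligand_elements[i],
            position=tuple(ligand_pos[i]), is_ligand=True,
            atom_name=f"{ligand_elements[i]}{i + 1}",
            hbond_role=ligand_roles[i]))
    offset = len(atoms)
    for j in range(len(pocket_pos)):
        atoms.append(AtomRecord(
            atom_id=offset + j, element=pocket_elements[j],
            position=tuple(pocket_pos[j]), is_ligand=False,
            residue_name="UNK", residue_index=j + 1, chain="A",
            atom_name=f"{pocket_elements[j]}{j + 1}",
            hbond_role=pocket_roles[j]))
    return Complex(complex_id, atoms, pocket_applied=True)


def generate_complex(spec: SyntheticSpec, complex_id: str | None = None):
    """One synthetic bound structure with planted donor-acceptor contacts.

    Returns (Complex, PlantedTruth).  Reproducible from spec.seed: the
    rejection sampler restarts deterministically (continuing the same
    random stream) if a layout dead-ends.
    """
    rng = np.random.default_rng(spec.seed)
    last_error = None
    for _restart in range(6):
        try:
            return _generate_complex_once(spec, rng, complex_id)
        except GenerationError as error:
            last_error = error
    raise last_error


def _generate_complex_once(spec, rng, complex_id):
    ligand_pos = _sample_cluster(rng, spec.n_ligand_atoms, LIGAND_RADIUS,
                                 LIGAND_MIN_SEP)
    centroid = ligand_pos.mean(axis=0)

    # contact anchors: the most outward ligand atoms, so the partner can sit
    # outside the cluster without violating the non-contact distance floor
    outward = np.argsort(-np.linalg.norm(ligand_pos - centroid, axis=1))
    anchors = list(outward[:spec.n_planted_contacts])

    ligand_elements = ["C"] * spec.n_ligand_atoms
    ligand_roles = ["none"] * spec.n_ligand_atoms
    pocket_pos, pocket_elements, pocket_roles = [], [], []
    contacts = []
    for c, anchor_idx in enumerate(anchors):
        partner = _place_partner(rng, ligand_pos[anchor_idx], centroid,
                                 ligand_pos, pocket_pos,
                                 spec.contact_distance)
        if c % 2 == 0:
            ligand_elements[anchor_idx], ligand_roles[anchor_idx] = "N", "donor"
            pocket_elements.append("O")
            pocket_roles.append("acceptor")
        else:
            ligand_elements[anchor_idx], ligand_roles[anchor_idx] = ("O",
                                                                     "acceptor")
            pocket_elements.append("N")
            pocket_roles.append("donor")
        pocket_pos.append(partner)
        contacts.append((int(anchor_idx), spec.n_ligand_atoms + c))

    for _ in range(spec.n_pocket_atoms - spec.n_planted_contacts):
        pocket_pos.append(_place_shell_atom(rng, ligand_pos, centroid,
                                            pocket_pos))
        pocket_elements.append("C")
        pocket_roles.append("none")

    complex_ = _build_complex(
        spec, ligand_pos, ligand_elements, ligand_roles,
        np.array(pocket_pos), pocket_elements, pocket_roles,
        complex_id or f"synthetic-{spec.seed}")
    truth = PlantedTruth(
        contacts=contacts,
        true_label=int(spec.n_planted_contacts >= spec.label_rule_k),
        true_contact_count=spec.n_planted_contacts)
    return complex_, truth


def count_intact_contacts(complex_: Complex, truth: PlantedTruth,
                          max_dist: float = INTACT_CONTACT_MAX) -> int:
    """How many planted pairs are still within hydrogen-bonding reach."""
    count = 0
    for lig_id, prot_id in truth.contacts:
        a = np.asarray(complex_.atom_by_id(lig_id).position)
        b = np.asarray(complex_.atom_by_id(prot_id).position)
        if np.linalg.norm(a - b) <= max_dist:
            count += 1
    return count


def _random_rotation(rng):
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    matrix = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(matrix)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _perturb_ligand(rng, complex_, magnitude):
    """Rigidly move the ligand: random rotation about its centroid plus a
    translation of the given magnitude."""
    ligand_ids = [a.atom_id for a in complex_.ligand_atoms]
    positions = {a.atom_id: np.asarray(a.position) for a in complex_.atoms}
    lig_pos = np.array([positions[i] for i in ligand_ids])
    center = lig_pos.mean(axis=0)
    rotation = _random_rotation(rng) if magnitude > 0 else np.eye(3)
    shift = magnitude * _unit(rng.normal(size=3), rng)
    new_atoms = []
    for atom in complex_.atoms:
        if atom.is_ligand:
            moved = rotation @ (np.asarray(atom.position) - center) \
                + center + shift
            new_atoms.append(replace(atom, position=tuple(moved)))
        else:
            new_atoms.append(atom)
    return Complex(complex_.complex_id + "-decoy", new_atoms,
                   complex_.pocket_applied)


def generate_pose_dataset(spec: SyntheticSpec, n_examples: int,
                          seed: int = 0):
    """Balanced binder/decoy dataset with geometry-derived labels.

    Binders keep the planted contacts; decoys rigidly perturb the ligand
    until fewer than ``label_rule_k`` contacts remain intact.  The label is
    1 iff the intact-contact count is >= label_rule_k, recomputable from the
    emitted coordinates.  Binder/decoy variants of one base structure share
    a group_id.  Returns (examples, complexes, truths).
    """
    if n_examples < 2:
        raise ValueError("need at least 2 examples")
    rng = np.random.default_rng(seed)
    examples, complexes, truths = [], [], []
    n_pairs = (n_examples + 1) // 2
    for pair in range(n_pairs):
        base_seed = int(rng.integers(2**31 - 1))
        base, truth = generate_complex(replace(spec, seed=base_seed),
                                       complex_id=f"sys{pair}")
        for kind in ("binder", "decoy"):
            if len(examples) == n_examples:
                break
            variant = base
            if kind == "decoy":
                if spec.decoy_perturbation == 0:
                    variant = _perturb_ligand(rng, base, 0.0)
                else:
                    for _attempt in range(60):
                        variant = _perturb_ligand(rng, base,
                                                  spec.decoy_perturbation)
                        if count_intact_contacts(variant, truth) \
                                < spec.label_rule_k:
                            break
                    else:
                        raise GenerationError(
                            "could not break contacts with perturbation "
                            f"{spec.decoy_perturbation}")
            label = int(count_intact_contacts(variant, truth)
                        >= spec.label_rule_k)
            examples.append(LabeledExample(graph=featurize(variant),
                                           label=float(label),
                                           group_id=f"sys{pair}"))
            complexes.append(variant)
            truths.append(PlantedTruth(truth.contacts, label,
                                       count_intact_contacts(variant, truth)))
    return examples, complexes, truths


def generate_affinity_dataset(spec: SyntheticSpec, n_examples: int,
                              seed: int = 0):
    """Affinity labels equal to the planted-contact count plus Gaussian
    noise (clipped at zero), with the contact count varied per example."""
    rng = np.random.default_rng(seed)
    examples, complexes, truths = [], [], []
    for i in range(n_examples):
        count = int(rng.integers(0, spec.n_planted_contacts + 1))
        base_seed = int(rng.integers(2**31 - 1))
        complex_, truth = generate_complex(
            replace(spec, seed=base_seed, n_planted_contacts=count),
            complex_id=f"aff{i}")
        label = max(0.0, count + rng.normal(0.0, spec.noise_sigma))
        examples.append(LabeledExample(graph=featurize(complex_),
                                       label=float(label),
                                       group_id=f"aff{i}"))
        complexes.append(complex_)
        truths.append(truth)
    return examples, complexes, truths


def generate_fragment_screen(spec: SyntheticSpec, n_structures: int,
                             seed: int = 0, n_sites: int = 5,
                             site_probabilities=None, n_fillers: int = 6):
    """A screen of bound structures sharing one reference pocket.

    A fixed scaffold of nonpolar "filler" ligand atoms sits at the pocket
    center in every structure; ``n_sites`` polar contact sites surround it.
    Site 0 (the dominant site) is occupied in every structure, site j with
    probability ``site_probabilities[j]``.  An occupied site places a
    complementary polar ligand atom at contact distance from the site's
    protein atom; an unoccupied site contributes no ligand atom, leaving its
    protein atom 4.5-6 Angstrom from the scaffold — the same non-contact
    geometry band the single-complex generator enforces, so screens stay in
    the training distribution.  Returns (complexes, occupancy, site_keys)
    where ``occupancy`` is an n_structures x n_sites boolean array and
    ``site_keys`` the protein-atom keys of the sites ordered dominant
    first.
    """
    if site_probabilities is None:
        site_probabilities = [1.0, 0.8, 0.6, 0.4, 0.3][:n_sites]
    if len(site_probabilities) != n_sites:
        raise ValueError("need one probability per site")
    rng = np.random.default_rng(seed)

    site_reach = 5.5          # partner distance from its anchor filler atom
    for _pocket_attempt in range(40):
        ok = True
        try:
            fillers = _sample_cluster(rng, n_fillers, 3.5, 3.0)
        except GenerationError:
            continue
        centroid = fillers.mean(axis=0)
        # site partners: outward rays from filler anchors, mutually spread
        partners, site_atoms, anchors = [], [], []
        for j in range(n_sites):
            for _attempt in range(_MAX_TRIES):
                anchor = fillers[rng.integers(n_fillers)]
                direction = _unit(anchor - centroid
                                  + rng.normal(scale=0.8, size=3), rng)
                partner = anchor + site_reach * direction
                site_atom = partner - spec.contact_distance * direction
                dmin = np.linalg.norm(fillers - partner, axis=1).min()
                if not NONCONTACT_MIN_DIST <= dmin <= 6.0:
                    continue
                if any(np.linalg.norm(partner - p) < 5.0 for p in partners):
                    continue
                # the occupied-site ligand atom must respect the floor
                # against every other pocket atom placed so far
                if any(np.linalg.norm(site_atom - p)
                       < NONCONTACT_MIN_DIST + 0.1 for p in partners):
                    continue
                if any(np.linalg.norm(partner - s)
                       < NONCONTACT_MIN_DIST + 0.1 for s in site_atoms):
                    continue
                if np.linalg.norm(fillers - site_atom,
                                  axis=1).min() < 2.2:
                    continue
                partners.append(partner)
                site_atoms.append(site_atom)
                anchors.append(anchor)
                break
            else:
                ok = False
                break
        if not ok:
            continue
        # nonpolar shell, anchored to the fixed fillers so membership in the
        # 4.5-6 A band holds in every structure
        shell = []
        placed = list(partners)
        for _ in range(spec.n_pocket_atoms - n_sites):
            for _attempt in range(_MAX_TRIES):
                pos = _place_shell_atom(rng, fillers, centroid, placed)
                if min(np.linalg.norm(pos - s) for s in site_atoms) \
                        < NONCONTACT_MIN_DIST + 0.1:
                    continue
                shell.append(pos)
                placed.append(pos)
                break
            else:
                ok = False
                break
        if ok:
            break
    else:
        raise GenerationError("could not lay out a feasible screen pocket")

    pocket_atoms = []
    for j, partner in enumerate(partners):
        element, role = ("O", "acceptor") if j % 2 == 0 else ("N", "donor")
        pocket_atoms.append(AtomRecord(
            atom_id=j, element=element, position=tuple(partner),
            is_ligand=False, residue_name="UNK", residue_index=j + 1,
            chain="A", atom_name=f"{element}{j + 1}", hbond_role=role))
    for k, pos in enumerate(shell):
        pocket_atoms.append(AtomRecord(
            atom_id=n_sites + k, element="C", position=tuple(pos),
            is_ligand=False, residue_name="UNK",
            residue_index=n_sites + k + 1, chain="A",
            atom_name=f"C{n_sites + k + 1}", hbond_role="none"))
    site_keys = [a.key for a in pocket_atoms[:n_sites]]
    complementary = {"acceptor": ("N", "donor"), "donor": ("O", "acceptor")}

    complexes = []
    occupancy = np.zeros((n_structures, n_sites), dtype=bool)
    for s in range(n_structures):
        active = np.array([rng.random() < p for p in site_probabilities])
        active[0] = True
        occupancy[s] = active
        lig_records = []
        atom_id = 1000  # ligand ids disjoint from pocket ids
        for i, pos in enumerate(fillers):
            lig_records.append(AtomRecord(
                atom_id=atom_id, element="C", position=tuple(pos),
                is_ligand=True, atom_name=f"C{atom_id}", hbond_role="none"))
            atom_id += 1
        for j, partner in enumerate(partners):
            if not active[j]:
                continue
            direction = _unit(np.asarray(partner) - anchors[j], rng)
            d = spec.contact_distance + rng.uniform(-CONTACT_TOLERANCE,
                                                    CONTACT_TOLERANCE)
            pos = np.asarray(partner) - d * direction
            element, role = complementary[pocket_atoms[j].hbond_role]
            lig_records.append(AtomRecord(
                atom_id=atom_id, element=element, position=tuple(pos),
                is_ligand=True, atom_name=f"{element}{atom_id}",
                hbond_role=role))
            atom_id += 1
        complexes.append(Complex(f"screen{s}", lig_records + pocket_atoms,
                                 pocket_applied=True))
    return complexes, occupancy, site_keys


def generate_score_table(n_hotspots: int = 5, n_fragments: int = 16,
                         n_molecules: int = 25, effect_size: float = 2.5,
                         seed: int = 0):
    """Docking-score table with a planted hotspot-quality ordering.

    Per-molecule ligand efficiencies are drawn as N(effect_size * quality,
    1) for elaborations and N(0, 1) for the ground-truth molecule, then
    multiplied by the heavy-atom count to give docking scores, so the
    quality shift is expressed in pooled standard deviations of LE.
    Hotspot identities are shuffled; returns (table, true_order) with
    ``true_order`` the hotspot labels from best to worst.
    """
    if min(n_hotspots, n_fragments, n_molecules) < 1:
        raise ValueError("all counts must be >= 1")
    rng = np.random.default_rng(seed)
    quality = (np.linspace(1.0, 0.0, n_hotspots) if n_hotspots > 1
               else np.array([1.0]))
    labels = rng.permutation(np.arange(1, n_hotspots + 1))
    true_order = [int(h) for h in labels[np.argsort(-quality)]]

    rows = []
    for h, label in enumerate(labels):
        for f in range(n_fragments):
            heavy_gt = int(rng.integers(8, 16))
            le_gt = rng.normal(0.0, 1.0)
            rows.append({"molecule_id": f"gt-f{f}-h{label}",
                         "fragment_id": f"frag{f}",
                         "hotspot_rank": int(label),
                         "docking_score": le_gt * heavy_gt,
                         "heavy_atoms": heavy_gt, "is_ground_truth": True})
            for m in range(n_molecules):
                heavy = int(rng.integers(15, 31))
                le = rng.normal(effect_size * quality[h], 1.0)
                rows.append({"molecule_id": f"m{m}-f{f}-h{label}",
                             "fragment_id": f"frag{f}",
                             "hotspot_rank": int(label),
                             "docking_score": le * heavy,
                             "heavy_atoms": heavy,
                             "is_ground_truth": False})
    return pd.DataFrame(rows), true_order


# -- fragment enumeration -------------------------------------------------

#: Bonds with both endpoints inside one match of these patterns are never cut.
FUNCTIONAL_GROUP_SMARTS = (
    "[NX3][CX3](=[OX1])",        # amide
    "[CX3](=[OX1])[OX2][#6]",    # ester
    "[SX4](=[OX1])(=[OX1])[NX3]",  # sulfonamide
    "[NX3](=O)=O",               # nitro (neutral form)
    "[N+](=O)[O-]",              # nitro (charge-separated form)
)


@dataclass(frozen=True)
class FragmentCut:
    smiles: str
    exit_atom: int               # index of the dummy atom in the fragment
    cut_bond: tuple              # (atom_i, atom_j) indices in the parent
    fragment: object = field(compare=False, hash=False, default=None)


def enumerate_fragments(molecule) -> list:
    """Fragments from cutting acyclic single bonds outside functional groups.

    ``molecule`` may be an RDKit Mol or a SMILES string.  Each eligible cut
    yields both sides, each carrying a dummy atom at the cut site (the exit
    point for elaboration).  Returns a list of :class:`FragmentCut`.
    """
    from rdkit import Chem

    mol = Chem.MolFromSmiles(molecule) if isinstance(molecule, str) \
        else molecule
    if mol is None:
        raise ValueError("molecule could not be parsed")

    protected_pairs = set()
    for smarts in FUNCTIONAL_GROUP_SMARTS:
        pattern = Chem.MolFromSmarts(smarts)
        for match in mol.GetSubstructMatches(pattern):
            match_set = set(match)
            for a in match_set:
                for b in match_set:
                    if a < b:
                        protected_pairs.add((a, b))

    cuts = []
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if (min(i, j), max(i, j)) in protected_pairs:
            continue
        fragmented = Chem.FragmentOnBonds(mol, [bond.GetIdx()],
                                          addDummies=True)
        pieces = Chem.GetMolFrags(fragmented, asMols=True,
                                  sanitizeFrags=False)
        for piece in pieces:
            dummy = next(a.GetIdx() for a in piece.GetAtoms()
                         if a.GetAtomicNum() == 0)
            cuts.append(FragmentCut(
                smiles=Chem.MolToSmiles(piece), exit_atom=dummy,
                cut_bond=(i, j), fragment=piece))
    return cuts
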