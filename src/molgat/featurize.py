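"""Node features: 14 atomic + 21 global (15 chemical + 6 geometric) = 35.

Every node of a molecular graph carries 35 fixed (non-learned) features:

* 14 atomic features describing the atom itself, three of which
  (atomic mass, van der Waals radius, covalent radius) are rescaled by
  fixed affine maps so their ranges are commensurate with the other
  entries;
* 15 molecule-level chemical descriptors (ring/aromaticity flags,
  H-bond donor/acceptor counts, TPSA, molecular weight, ...) broadcast
  identically to every node;
* 6 conformer-derived geometric descriptors (volume, per-axis extents,
  dipole magnitude, orientation angle), also broadcast.

Broadcasting global descriptors to every node gives the message-passing
layers direct access to whole-molecule information that they are poor at
extracting themselves (oversmoothing, limited expressivity), which is
the central design idea of this package.

Geometry conventions (the source descriptors leave these open; the
choices are documented in docs/methods.md):

* conformers come from seeded ETKDG distance-geometry embedding followed
  by MMFF94 relaxation (UFF fallback when MMFF has no parameters);
* the dipole is ``|sum_i q_i r_i|`` in units of elementary charge times
  Angstrom, with MMFF94 partial charges and Gasteiger as fallback;
* the orientation angle is the angle between the first principal axis of
  the centered heavy-atom coordinates and the x-axis, in [0, pi], with
  the eigenvector sign fixed deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, Descriptors, rdMolDescriptors

__all__ = [
    "PAULING_ELECTRONEGATIVITY",
    "GeometryFailure",
    "AtomFeatures",
    "MolecularDescriptors",
    "GeometryDescriptors",
    "FEATURE_NAMES",
    "N_ATOM_FEATURES",
    "N_GLOBAL_FEATURES",
    "N_FEATURES",
    "scale_atomic_mass",
    "scale_vdw_radius",
    "scale_covalent_radius",
    "atom_features",
    "molecular_descriptors",
    "geometry_descriptors",
    "node_feature_matrix",
]

# Pauling electronegativities, indexed by atomic number (Z = 1..86).
# Elements with no defined Pauling value (noble gases except Xe, and a
# few others) are absent; atoms of those elements get the value 0 and
# the has_electronegativity flag cleared.
PAULING_ELECTRONEGATIVITY: dict[int, float] = {
    1: 2.20, 3: 0.98, 4: 1.57, 5: 2.04, 6: 2.55, 7: 3.04, 8: 3.44, 9: 3.98,
    11: 0.93, 12: 1.31, 13: 1.61, 14: 1.90, 15: 2.19, 16: 2.58, 17: 3.16,
    19: 0.82, 20: 1.00, 21: 1.36, 22: 1.54, 23: 1.63, 24: 1.66, 25: 1.55,
    26: 1.83, 27: 1.88, 28: 1.91, 29: 1.90, 30: 1.65, 31: 1.81, 32: 2.01,
    33: 2.18, 34: 2.55, 35: 2.96, 36: 3.00,
    37: 0.82, 38: 0.95, 39: 1.22, 40: 1.33, 41: 1.60, 42: 2.16, 43: 1.90,
    44: 2.20, 45: 2.28, 46: 2.20, 47: 1.93, 48: 1.69, 49: 1.78, 50: 1.96,
    51: 2.05, 52: 2.10, 53: 2.66, 54: 2.60,
    55: 0.79, 56: 0.89, 57: 1.10, 58: 1.12, 59: 1.13, 60: 1.14, 62: 1.17,
    64: 1.20, 66: 1.22, 67: 1.23, 68: 1.24, 69: 1.25, 71: 1.27,
    72: 1.30, 73: 1.50, 74: 2.36, 75: 1.90, 76: 2.20, 77: 2.20, 78: 2.28,
    79: 2.54, 80: 2.00, 81: 1.62, 82: 2.33, 83: 2.02, 84: 2.00, 85: 2.20,
}

_HYBRIDIZATION_CODE = {
    Chem.HybridizationType.UNSPECIFIED: 0,
    Chem.HybridizationType.S: 1,
    Chem.HybridizationType.SP: 2,
    Chem.HybridizationType.SP2: 3,
    Chem.HybridizationType.SP3: 4,
    Chem.HybridizationType.SP3D: 5,
    Chem.HybridizationType.SP3D2: 6,
}


class GeometryFailure(RuntimeError):
    """Conformer embedding, relaxation, or charge assignment failed.

    Callers decide whether to drop the molecule (see
    chem_io.drop_failed_geometry); the benchmark protocol drops it with
    a logged warning.
    """

    def __init__(self, smiles: str, reason: str):
        super().__init__(f"geometry failure for {smiles!r}: {reason}")
        self.smiles = smiles
        self.reason = reason


# --- scaled atomic properties ---------------------------------------------

def scale_atomic_mass(mass: float) -> float:
    """Affine rescaling of an atomic mass in Da: (A - 10.812) / 116.092."""
    if mass <= 0:
        raise ValueError(f"atomic mass must be positive, got {mass}")
    return (mass - 10.812) / 116.092


def scale_vdw_radius(r: float) -> float:
    """Affine rescaling of a van der Waals radius in Angstrom: (R - 1.5) / 0.6."""
    if r <= 0:
        raise ValueError(f"van der Waals radius must be positive, got {r}")
    return (r - 1.5) / 0.6


def scale_covalent_radius(r: float) -> float:
    """Affine rescaling of a covalent radius in Angstrom: (R - 0.64) / 0.76."""
    if r <= 0:
        raise ValueError(f"covalent radius must be positive, got {r}")
    return (r - 0.64) / 0.76


# --- atomic features -------------------------------------------------------

@dataclass(frozen=True)
class AtomFeatures:
    """The 14 per-atom features, in fixed order."""

    atom_degree: int            # heavy-atom neighbor count
    atomic_number: int
    num_hydrogens: int          # total attached H, implicit + explicit
    atomic_valence: int
    num_radical_electrons: int
    atom_formal_charge: int
    atom_hybridization: int     # 0..6: unspecified,s,sp,sp2,sp3,sp3d,sp3d2
    electronegativity: float    # Pauling; 0 when undefined
    has_electronegativity: int
    has_implicit_hydrogens: int
    hydroxyl_group: int         # O bonded to >=1 H and exactly 1 heavy neighbor
    atomic_mass_scaled: float
    vdw_radius_scaled: float
    covalent_radius_scaled: float

    def flatten(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in dc_fields(self)],
                        dtype=np.float64)


def atom_features(mol: Chem.Mol, atom_index: int) -> AtomFeatures:
    """Compute the 14 atomic features for one atom of a parsed molecule."""
    if not 0 <= atom_index < mol.GetNumAtoms():
        raise IndexError(f"atom index {atom_index} out of range")
    atom = mol.GetAtomWithIdx(atom_index)
    z = atom.GetAtomicNum()
    en = PAULING_ELECTRONEGATIVITY.get(z)
    pt = Chem.GetPeriodicTable()
    is_hydroxyl = (
        z == 8 and atom.GetTotalNumHs() >= 1 and atom.GetDegree() == 1
    )
    return AtomFeatures(
        atom_degree=atom.GetDegree(),
        atomic_number=z,
        num_hydrogens=atom.GetTotalNumHs(),
        atomic_valence=atom.GetTotalValence(),
        num_radical_electrons=atom.GetNumRadicalElectrons(),
        atom_formal_charge=atom.GetFormalCharge(),
        atom_hybridization=_HYBRIDIZATION_CODE.get(atom.GetHybridization(), 0),
        electronegativity=en if en is not None else 0.0,
        has_electronegativity=int(en is not None),
        has_implicit_hydrogens=int(atom.GetNumImplicitHs() > 0),
        hydroxyl_group=int(is_hydroxyl),
        atomic_mass_scaled=scale_atomic_mass(pt.GetAtomicWeight(z)),
        vdw_radius_scaled=scale_vdw_radius(pt.GetRvdw(z)),
        covalent_radius_scaled=scale_covalent_radius(pt.GetRcovalent(z)),
    )


# --- molecule-level chemical descriptors -----------------------------------

@dataclass(frozen=True)
class MolecularDescriptors:
    """The 15 molecule-level chemical descriptors, in fixed order.

    num_hbond_donors uses the Lipinski donor definition and hbd the
    toolkit's default donor definition; both are kept because they can
    disagree and both are part of the fixed feature list.
    """

    has_ring: int
    is_aromatic: int
    formal_charge: int
    min_degree: int
    num_hbond_donors: int
    num_rings: int
    num_rotatable_bonds: int
    polar_surface_area: float   # topological PSA, Angstrom^2
    molecular_weight: float     # Da
    num_atoms: int              # heavy atoms = graph nodes
    hba: int
    hbd: int
    fraction_sp2: float
    valence: int                # sum of atom total valences
    general_electronegativity: float

    def flatten(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in dc_fields(self)],
                        dtype=np.float64)


def molecular_descriptors(mol: Chem.Mol) -> MolecularDescriptors:
    """Compute the 15 molecule-level chemical descriptors."""
    atoms = list(mol.GetAtoms())
    if not atoms:
        raise ValueError("empty molecule")
    ens = [PAULING_ELECTRONEGATIVITY[a.GetAtomicNum()] for a in atoms
           if a.GetAtomicNum() in PAULING_ELECTRONEGATIVITY]
    n_sp2 = sum(a.GetHybridization() == Chem.HybridizationType.SP2
                for a in atoms)
    return MolecularDescriptors(
        has_ring=int(mol.GetRingInfo().NumRings() > 0),
        is_aromatic=int(any(a.GetIsAromatic() for a in atoms)),
        formal_charge=Chem.GetFormalCharge(mol),
        min_degree=min(a.GetDegree() for a in atoms),
        num_hbond_donors=Descriptors.NumHDonors(mol),
        num_rings=rdMolDescriptors.CalcNumRings(mol),
        num_rotatable_bonds=rdMolDescriptors.CalcNumRotatableBonds(mol),
        polar_surface_area=rdMolDescriptors.CalcTPSA(mol),
        molecular_weight=Descriptors.MolWt(mol),
        num_atoms=mol.GetNumAtoms(),
        hba=rdMolDescriptors.CalcNumHBA(mol),
        hbd=rdMolDescriptors.CalcNumHBD(mol),
        fraction_sp2=n_sp2 / len(atoms),
        valence=sum(a.GetTotalValence() for a in atoms),
        general_electronegativity=float(np.mean(ens)) if ens else 0.0,
    )


# --- conformer-derived geometric descriptors -------------------------------

@dataclass(frozen=True)
class GeometryDescriptors:
    """The 6 conformer-derived geometric descriptors, in fixed order."""

    volume: float               # grid-based molecular volume, Angstrom^3
    width: float                # x-extent of heavy atoms, Angstrom
    length: float               # y-extent
    height: float               # z-extent
    dipole_moment: float        # |sum q_i r_i|, e*Angstrom
    orientation_angle: float    # first principal axis vs x-axis, rad, [0, pi]

    def flatten(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in dc_fields(self)],
                        dtype=np.float64)


def _embed_conformer(mol: Chem.Mol, smiles: str, seed: int) -> Chem.Mol:
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) & 0x7FFFFFFF
    if AllChem.EmbedMolecule(molh, params) != 0:
        raise GeometryFailure(smiles, "conformer embedding failed")
    try:
        if AllChem.MMFFHasAllMoleculeParams(molh):
            AllChem.MMFFOptimizeMolecule(molh)
        else:
            AllChem.UFFOptimizeMolecule(molh)
    except Exception as exc:  # rdkit raises bare RuntimeError on FF setup
        raise GeometryFailure(smiles, f"force-field relaxation failed: {exc}")
    return molh


def _partial_charges(molh: Chem.Mol, smiles: str) -> np.ndarray:
    props = AllChem.MMFFGetMoleculeProperties(molh)
    if props is not None:
        return np.array(
            [props.GetMMFFPartialCharge(i) for i in range(molh.GetNumAtoms())]
        )
    AllChem.ComputeGasteigerCharges(molh)
    q = np.array([a.GetDoubleProp("_GasteigerCharge") for a in molh.GetAtoms()])
    if not np.all(np.isfinite(q)):
        raise GeometryFailure(smiles, "partial charge assignment failed")
    return q


def geometry_descriptors(mol: Chem.Mol, seed: int) -> GeometryDescriptors:
    """Embed one 3D conformer (deterministic in seed) and measure it.

    Width/length/height are heavy-atom coordinate ranges along x/y/z
    after force-field relaxation; the volume is the toolkit's grid-based
    molecular volume of the same conformer.

    Raises GeometryFailure when embedding or charge assignment fails.
    """
    smiles = Chem.MolToSmiles(mol)
    molh = _embed_conformer(mol, smiles, seed)
    conf = molh.GetConformer()
    coords = np.array(
        [list(conf.GetAtomPosition(i)) for i in range(molh.GetNumAtoms())]
    )
    heavy = np.array([a.GetAtomicNum() != 1 for a in molh.GetAtoms()])
    hcoords = coords[heavy]
    extents = hcoords.max(axis=0) - hcoords.min(axis=0)
    q = _partial_charges(molh, smiles)
    dipole = float(np.linalg.norm(q @ coords))
    volume = float(AllChem.ComputeMolVolume(molh))
    return GeometryDescriptors(
        volume=volume,
        width=float(extents[0]),
        length=float(extents[1]),
        height=float(extents[2]),
        dipole_moment=dipole,
        orientation_angle=_orientation_angle(hcoords),
    )


def _orientation_angle(coords: np.ndarray) -> float:
    """Angle between the first principal axis of coords and the x-axis.

    The principal eigenvector's sign is arbitrary, so it is fixed by
    making its largest-magnitude component positive; the resulting angle
    lies in [0, pi] and is deterministic.  A single point has no
    principal axis and gets angle 0.
    """
    if len(coords) < 2:
        return 0.0
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(coords)
    eigval, eigvec = np.linalg.eigh(cov)
    v = eigvec[:, -1]
    k = int(np.argmax(np.abs(v)))
    if v[k] < 0:
        v = -v
    return float(np.arccos(np.clip(v[0], -1.0, 1.0)))


# --- assembled node-feature matrix -----------------------------------------

N_ATOM_FEATURES = 14
N_GLOBAL_FEATURES = 21
N_FEATURES = 35

FEATURE_NAMES: tuple[str, ...] = tuple(
    [f.name for f in dc_fields(AtomFeatures)]
    + [f.name for f in dc_fields(MolecularDescriptors)]
    + [f.name for f in dc_fields(GeometryDescriptors)]
)
assert len(FEATURE_NAMES) == N_FEATURES


def node_feature_matrix(mol: Chem.Mol, seed: int) -> np.ndarray:
    """The N x 35 node-feature matrix of a parsed molecule.

    Row i holds the atomic features of atom i (SMILES order) followed by
    the 21 molecule-level entries, which are identical in every row.
    GeometryFailure propagates to the caller.
    """
    n = mol.GetNumAtoms()
    glob = np.concatenate(
        [molecular_descriptors(mol).flatten(),
         geometry_descriptors(mol, seed).flatten()]
    )
    out = np.empty((n, N_FEATURES), dtype=np.float64)
    for i in range(n):
        out[i, :N_ATOM_FEATURES] = atom_features(mol, i).flatten()
        out[i, N_ATOM_FEATURES:] = glob
    return out


#: Conformer seed used by the pipeline when none is supplied.  A single
#: fixed value keeps geometry features identical across experiments so
#: per-SMILES features can be cached.
DEFAULT_CONFORMER_SEED = 7

_MATRIX_CACHE: dict[tuple[str, int], np.ndarray] = {}


def featurize_smiles(smiles: str, seed: int = DEFAULT_CONFORMER_SEED,
                     cache: bool = True) -> np.ndarray:
    """node_feature_matrix for a raw SMILES string, with memoization.

    Parsing goes through graph_build.parse_smiles so node order stays
    pinned to the input string.  GeometryFailure propagates.
    """
    key = (smiles, seed)
    if cache and key in _MATRIX_CACHE:
        return _MATRIX_CACHE[key]
    from .graph_build import parse_smiles

    mat = node_feature_matrix(parse_smiles(smiles), seed)
    if cache:
        _MATRIX_CACHE[key] = mat
    return mat
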