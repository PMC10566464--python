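"""Synthetic training fixtures: molecules, geometries and spin-system labels.

The generator assembles small organic molecules (H/C/O/N/F/S/P/Cl, chains,
branches, optional 3-/4-membered rings, optional stereocenters) from a
fragment grammar, featurizes them with the standard conformer-ensemble
pipeline, and attaches labels from a smooth, deterministic label model:

* chemical shifts are a sum of substituent, ring-strain, partial-charge and
  through-space (heteroatom distance) contributions;
* vicinal proton couplings (3JHH) are the Boltzmann-weighted ensemble
  average of a Karplus-style cosine of each conformer's dihedral — the
  averaged observable NMR actually measures — so the conformer ensemble
  genuinely carries label-relevant information;
* geminal/long-range protons and one-bond C-H couplings use smooth
  distance-decay / substituent forms.

Two label channels are produced.  The experimental channel adds
heteroscedastic noise — a fraction of molecules is "poorly referenced" and
gets a larger sigma, and protons bound to O/N (exchangeable, solvent
sensitive) carry extra noise; the ab initio channel is the clean value
plus a fixed systematic offset and a small noise term.  Everything is
deterministic for a fixed spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem.EnumerateStereoisomers import (
    EnumerateStereoisomers,
    StereoEnumerationOptions,
)

from .chem import (
    ConformerEnsemble,
    FeatureConfig,
    MoleculeGraph,
    featurize,
    generate_conformers,
    mol_from_smiles,
)
from .model import COUPLING_CLASSES, SHIFT_CLASSES, coupling_class_masks

HETEROATOMS = ("O", "N", "F", "S", "P", "Cl")

# Karplus-style vicinal coupling: J(theta) = A cos^2(theta) + B cos(theta) + C
KARPLUS_A, KARPLUS_B, KARPLUS_C = 7.0, -1.0, 1.1


def karplus(theta: np.ndarray) -> np.ndarray:
    """Vicinal 3JHH coupling (Hz) as a function of the H-X-Y-H dihedral."""
    c = np.cos(theta)
    return KARPLUS_A * c * c + KARPLUS_B * c + KARPLUS_C


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions of the synthetic dataset.

    Noise defaults emulate user-contributed experimental shift data
    (heteroscedastic: ``hetero_fraction`` of molecules carry
    ``hetero_factor`` times the base sigma) next to a nearly noiseless
    ab initio channel with a fixed global offset per parameter class.
    """

    n_molecules: int = 200
    elements: tuple = ("C", "O", "N", "F", "Cl")
    size_range: tuple = (3, 6)  # heavy-atom budget per molecule
    ring_fraction: float = 0.35  # fraction with a 3-/4-membered ring
    stereo_fraction: float = 0.2
    n_conformers: int = 16
    sigma_exp_shift: dict = field(
        default_factory=lambda: {"1H": 0.15, "13C": 1.0}
    )
    hetero_fraction: float = 0.25
    hetero_factor: float = 3.0
    exchangeable_factor: float = 3.0  # extra sigma for O/N-bound protons
    sigma_exp_coupling: float = 0.5  # Hz, homoscedastic
    ab_offset_shift: dict = field(default_factory=lambda: {"1H": 0.3, "13C": 2.0})
    ab_offset_coupling: float = 0.2  # Hz
    sigma_ab_shift: float = 0.05
    sigma_ab_coupling: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.size_range[0] < 2:
            raise ValueError("chains need at least two heavy atoms")
        if not 0 <= self.ring_fraction <= 1:
            raise ValueError("ring_fraction must be a probability")


@dataclass
class LabeledExample:
    """A featurized molecule with two-channel spin-system labels.

    Shift arrays have shape (N, n_shift_classes, 2) with channel 0 =
    experimental, channel 1 = ab initio; coupling arrays have shape
    (N, N, n_coupling_classes, 2) and are symmetric.  Presence masks share
    those shapes.  ``region`` is "B" for molecules containing a 3- or
    4-membered ring, "A" otherwise.
    """

    graph: MoleculeGraph
    shift_targets: np.ndarray
    shift_masks: np.ndarray
    coupling_targets: np.ndarray
    coupling_masks: np.ndarray
    molecule_id: str
    region: str = "A"
    mol: Chem.Mol | None = None
    ensemble: ConformerEnsemble | None = None
    clean_shifts: np.ndarray | None = None
    clean_couplings: np.ndarray | None = None
    noise_scale: float = 1.0


# ---------------------------------------------------------------------------
# fragment-grammar molecule generation


# ring cores with their heavy-atom counts (charged against the size budget)
_RING_CORES = (
    ("C1CC1", 3),
    ("C1CCC1", 4),
    ("OC1CC1", 4),
    ("C1OC1", 3),
    ("C1COC1", 4),
)
_BRANCHES = ("(C)", "(F)", "(Cl)", "(O)", "(N)")


def _random_chain(rng, spec: FixtureSpec, length: int) -> str:
    tokens = ["C", "C"]  # guarantee an H-C-C-H vicinal pair
    prev_hetero = False
    for _ in range(length - 2):
        if not prev_hetero and rng.random() < 0.28:
            sym = rng.choice([e for e in spec.elements if e in ("O", "N", "S")] or ["C"])
            tokens.append(str(sym))
            prev_hetero = True
        else:
            tokens.append("C")
            prev_hetero = False
    # sprinkle branches on carbon positions (never the first)
    out = []
    for i, t in enumerate(tokens):
        out.append(t)
        if t == "C" and i > 0 and rng.random() < 0.15:
            branch = rng.choice(
                [b for b in _BRANCHES if b.strip("()") in spec.elements or b == "(C)"]
            )
            out.append(str(branch))
    return "".join(out)


def _random_smiles(rng, spec: FixtureSpec) -> str:
    budget = int(rng.integers(spec.size_range[0], spec.size_range[1] + 1))
    if rng.random() < spec.ring_fraction:
        core, core_size = _RING_CORES[int(rng.integers(0, len(_RING_CORES)))]
        # chains may attach on either side of the ring (different ring
        # atoms), which keeps the ring sub-space diverse under dedup
        pre = "C" * int(rng.integers(0, 3))
        chain_len = max(2, budget - core_size)
        return pre + core + _random_chain(rng, spec, chain_len)
    return _random_chain(rng, spec, budget)


def _assign_stereo(rng, mol: Chem.Mol) -> Chem.Mol:
    opts = StereoEnumerationOptions(maxIsomers=8, onlyUnassigned=True, unique=True)
    isomers = list(EnumerateStereoisomers(mol, options=opts))
    if len(isomers) <= 1:
        return mol
    return isomers[int(rng.integers(0, len(isomers)))]


def split_by_region(examples, test_fraction: float = 0.25):
    """Deterministic train/test split stratified by region so both regions
    are represented proportionally in the held-out set."""
    train, test = [], []
    for region in ("A", "B"):
        members = [ex for ex in examples if ex.region == region]
        k = max(1, int(round(test_fraction * len(members)))) if members else 0
        train.extend(members[: len(members) - k])
        test.extend(members[len(members) - k :])
    return train, test


def generate_molecules(spec: FixtureSpec) -> list:
    """Sample ``n_molecules`` distinct molecules (canonical-SMILES dedup)."""
    rng = np.random.default_rng(spec.seed)
    seen, out = set(), []
    attempts = 0
    max_attempts = 200 * spec.n_molecules + 1000
    while len(out) < spec.n_molecules and attempts < max_attempts:
        attempts += 1
        smi = _random_smiles(rng, spec)
        flat = Chem.MolFromSmiles(smi)
        if flat is None:
            continue
        if rng.random() < spec.stereo_fraction:
            flat = _assign_stereo(rng, flat)
        canon = Chem.MolToSmiles(flat)
        if canon in seen:
            continue
        seen.add(canon)
        out.append(mol_from_smiles(canon))
    if len(out) < spec.n_molecules:
        raise RuntimeError(
            f"fragment grammar exhausted: {len(out)}/{spec.n_molecules} molecules"
        )
    return out


# ---------------------------------------------------------------------------
# label model


def _in_small_ring(mol: Chem.Mol, idx: int) -> bool:
    ri = mol.GetRingInfo()
    return ri.IsAtomInRingOfSize(idx, 3) or ri.IsAtomInRingOfSize(idx, 4)


def clean_shift_labels(mol: Chem.Mol, ensemble: ConformerEnsemble) -> np.ndarray:
    """Deterministic per-atom clean shifts, shape (N, n_shift_classes);
    entries are defined only where the class matches the nucleus."""
    from rdkit.Chem import rdPartialCharges

    rdPartialCharges.ComputeGasteigerCharges(mol)
    n = mol.GetNumAtoms()
    w = ensemble.weights
    diff = ensemble.coords[:, :, None, :] - ensemble.coords[:, None, :, :]
    dbar = np.einsum("k,kij->ij", w, np.sqrt((diff**2).sum(-1)))

    het_idx = [
        a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() in ("O", "N", "F", "Cl")
    ]
    out = np.zeros((n, len(SHIFT_CLASSES)))
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        q = atom.GetDoubleProp("_GasteigerCharge")
        q = q if np.isfinite(q) else 0.0
        if atom.GetSymbol() == "H":
            heavy = atom.GetNeighbors()[0]
            base = {"C": 1.0, "O": 3.0, "N": 2.0}.get(heavy.GetSymbol(), 1.5)
            beta_het = sum(
                1
                for nb in heavy.GetNeighbors()
                if nb.GetSymbol() in ("O", "N", "F", "Cl")
            )
            through_space = sum(
                np.exp(-dbar[i, h] / 1.2) for h in het_idx if h != heavy.GetIdx()
            )
            val = (
                base
                + 0.7 * beta_het
                - 0.9 * _in_small_ring(mol, heavy.GetIdx())
                + 4.0 * q
                + 2.0 * through_space
            )
            out[i, SHIFT_CLASSES.index("1H")] = val
        elif atom.GetSymbol() == "C":
            nbs = atom.GetNeighbors()
            n_heavy = sum(1 for nb in nbs if nb.GetSymbol() != "H")
            n_o = sum(1 for nb in nbs if nb.GetSymbol() == "O")
            n_n = sum(1 for nb in nbs if nb.GetSymbol() == "N")
            n_x = sum(1 for nb in nbs if nb.GetSymbol() in ("F", "Cl"))
            val = (
                25.0
                + 7.0 * n_heavy
                + 22.0 * n_o
                + 12.0 * n_n
                + 16.0 * n_x
                - 22.0 * _in_small_ring(mol, i)
                + 30.0 * q
            )
            out[i, SHIFT_CLASSES.index("13C")] = val
    return out


def conformer_dihedrals(ensemble: ConformerEnsemble, path: tuple) -> np.ndarray:
    """Per-conformer absolute dihedral (radians) along a 4-atom path,
    computed directly from the stored conformer coordinates."""
    i, a, b, j = path
    angles = np.empty(ensemble.n_conformers)
    for k in range(ensemble.n_conformers):
        p = ensemble.coords[k]
        b1, b2, b3 = p[a] - p[i], p[b] - p[a], p[j] - p[b]
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        m1 = np.cross(n1, b2 / np.linalg.norm(b2))
        ang = np.arctan2(m1 @ n2, n1 @ n2)
        angles[k] = abs(ang)
    return angles


def ensemble_karplus(ensemble: ConformerEnsemble, path: tuple) -> float:
    """Boltzmann-weighted mean over conformers of the Karplus coupling —
    the ensemble-averaged observable, as NMR actually measures it."""
    return float(ensemble.weights @ karplus(conformer_dihedrals(ensemble, path)))


def _shortest_path(mol: Chem.Mol, i: int, j: int) -> tuple:
    return tuple(Chem.GetShortestPath(mol, int(i), int(j)))


def clean_coupling_labels(mol: Chem.Mol, ensemble: ConformerEnsemble) -> np.ndarray:
    """Deterministic clean couplings, shape (N, N, n_coupling_classes),
    symmetric, defined exactly on the coupling-class masks."""
    from rdkit.Chem import rdPartialCharges

    rdPartialCharges.ComputeGasteigerCharges(mol)
    n = mol.GetNumAtoms()
    masks = coupling_class_masks(mol)
    w = ensemble.weights
    diff = ensemble.coords[:, :, None, :] - ensemble.coords[:, None, :, :]
    dbar = np.einsum("k,kij->ij", w, np.sqrt((diff**2).sum(-1)))

    out = np.zeros((n, n, len(COUPLING_CLASSES)))
    for ci, cls in enumerate(COUPLING_CLASSES):
        mask = masks[cls]
        for i, j in zip(*np.nonzero(np.triu(mask, k=1))):
            i, j = int(i), int(j)
            if cls == "1JCH":
                c_idx = i if mol.GetAtomWithIdx(i).GetSymbol() == "C" else j
                c_atom = mol.GetAtomWithIdx(c_idx)
                n_het = sum(
                    1
                    for nb in c_atom.GetNeighbors()
                    if nb.GetSymbol() in ("O", "N", "F", "Cl")
                )
                val = (
                    125.0
                    + 38.0 * _in_small_ring(mol, c_idx)
                    + 9.0 * n_het
                    + 25.0 * (dbar[i, j] - 1.09)
                )
            elif cls == "2JHH":
                common = _shortest_path(mol, i, j)[1]
                n_het = sum(
                    1
                    for nb in mol.GetAtomWithIdx(common).GetNeighbors()
                    if nb.GetSymbol() in ("O", "N", "F", "Cl")
                )
                val = -12.4 + 1.8 * n_het + 5.0 * (dbar[i, j] - 1.78)
            elif cls == "3JHH":
                val = ensemble_karplus(ensemble, _shortest_path(mol, i, j))
            else:  # 4JHH
                val = 1.3 * np.exp(-dbar[i, j] / 1.1)
            out[i, j, ci] = out[j, i, ci] = val
    return out


# ---------------------------------------------------------------------------
# assembling labeled examples


def generate_fixtures(
    spec: FixtureSpec, feature_config: FeatureConfig | None = None
) -> list:
    """Generate, featurize and label ``spec.n_molecules`` examples."""
    feature_config = feature_config or FeatureConfig(
        n_conformers=spec.n_conformers
    )
    mols = generate_molecules(spec)
    examples = []
    for i, mol in enumerate(mols):
        mol_seed = (spec.seed * 1_000_003 + 7919 * i) & 0x7FFFFFFF
        ensemble = generate_conformers(
            mol,
            feature_config.n_conformers,
            seed=mol_seed,
            temperature=feature_config.temperature,
            mmff_iters=feature_config.mmff_iters,
        )
        graph = featurize(
            mol, feature_config, molecule_id=f"fix{i}", ensemble=ensemble
        )
        examples.append(
            label_example(spec, mol, ensemble, graph, index=i, molecule_id=f"fix{i}")
        )
    return examples


def label_example(
    spec: FixtureSpec,
    mol: Chem.Mol,
    ensemble: ConformerEnsemble,
    graph: MoleculeGraph,
    index: int,
    molecule_id: str,
) -> LabeledExample:
    rng = np.random.default_rng((spec.seed * 2_000_003 + 104_729 * index) & 0x7FFFFFFF)
    n = mol.GetNumAtoms()
    nsc, ncc = len(SHIFT_CLASSES), len(COUPLING_CLASSES)

    clean_s = clean_shift_labels(mol, ensemble)
    clean_j = clean_coupling_labels(mol, ensemble)
    masks = coupling_class_masks(mol)
    jmask = np.stack([masks[c] for c in COUPLING_CLASSES], axis=-1)

    noisy = rng.random() < spec.hetero_fraction
    scale = spec.hetero_factor if noisy else 1.0

    # exchangeable (O/N-bound) protons carry extra experimental noise:
    # their shifts are solvent/exchange sensitive in real spectra
    exchangeable = np.ones(n)
    for atom in mol.GetAtoms():
        if atom.GetSymbol() == "H" and atom.GetNeighbors()[0].GetSymbol() in (
            "O",
            "N",
        ):
            exchangeable[atom.GetIdx()] = spec.exchangeable_factor

    shift_targets = np.zeros((n, nsc, 2))
    shift_masks = np.zeros((n, nsc, 2), dtype=bool)
    for ci, cls in enumerate(SHIFT_CLASSES):
        nucleus = "H" if cls == "1H" else "C"
        present = np.array([a.GetSymbol() == nucleus for a in mol.GetAtoms()])
        sig_e = spec.sigma_exp_shift[cls] * scale
        per_atom_sig = sig_e * (exchangeable if cls == "1H" else 1.0)
        exp = clean_s[:, ci] + rng.normal(0.0, 1.0, size=n) * per_atom_sig
        ab = (
            clean_s[:, ci]
            + spec.ab_offset_shift[cls]
            + rng.normal(0.0, spec.sigma_ab_shift, size=n)
        )
        shift_targets[:, ci, 0] = np.where(present, exp, 0.0)
        shift_targets[:, ci, 1] = np.where(present, ab, 0.0)
        shift_masks[:, ci, 0] = present
        shift_masks[:, ci, 1] = present

    # symmetric noise draws for couplings (one draw per unordered pair)
    def sym_noise(sig):
        raw = rng.normal(0.0, sig, size=(ncc, n, n))
        upper = np.triu(raw, k=1)  # np.triu acts on the trailing two axes
        sym = upper + np.swapaxes(upper, 1, 2)
        return np.moveaxis(sym, 0, -1)

    coupling_targets = np.zeros((n, n, ncc, 2))
    coupling_targets[..., 0] = clean_j + sym_noise(spec.sigma_exp_coupling)
    coupling_targets[..., 1] = (
        clean_j + spec.ab_offset_coupling + sym_noise(spec.sigma_ab_coupling)
    )
    coupling_targets *= jmask[..., None]
    coupling_masks = np.repeat(jmask[..., None], 2, axis=-1)

    region = "B" if any(_in_small_ring(mol, a.GetIdx()) for a in mol.GetAtoms()) else "A"
    return LabeledExample(
        graph=graph,
        shift_targets=shift_targets,
        shift_masks=shift_masks,
        coupling_targets=coupling_targets,
        coupling_masks=coupling_masks,
        molecule_id=molecule_id,
        region=region,
        mol=mol,
        ensemble=ensemble,
        clean_shifts=clean_s,
        clean_couplings=clean_j,
        noise_scale=scale,
    )
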