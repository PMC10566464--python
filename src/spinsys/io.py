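"""Readers, writers and caches: SMILES/SDF input with acceptance filters,
prediction JSON, HDF5 feature cache and model checkpoints."""

from __future__ import annotations

import json
from dataclasses import dataclass

import h5py
import numpy as np
from rdkit import Chem

from .chem import (
    MAX_ATOMS,
    FeatureConfig,
    FeaturizationError,
    MoleculeGraph,
    validate_molecule,
)
from .model import COUPLING_CLASSES, SHIFT_CLASSES, ModelConfig, SpinSystemNetwork


@dataclass
class ReadResult:
    molecules: list  # (molecule_id, Chem.Mol) pairs
    rejected: list  # (record_index, reason) pairs


def _accept(mol: Chem.Mol, max_atoms: int) -> str | None:
    """Return a rejection reason, or None when accepted."""
    try:
        validate_molecule(mol, max_atoms)
    except FeaturizationError as err:
        if "max_atoms" in str(err) or "atoms exceeds" in str(err):
            return "max_atoms"
        return "element"
    return None


def read_molecules(
    path, fmt: str = "smiles", max_atoms: int = MAX_ATOMS, strict: bool = False
) -> ReadResult:
    """Read molecules from a SMILES file (one per line) or an SDF (V2000),
    add explicit hydrogens, and apply the element/size acceptance filters.
    Rejections are recorded with their reason; in strict mode any rejection
    aborts."""
    accepted, rejected = [], []

    def handle(i, mol, label):
        if mol is None:
            rejected.append((i, "unparseable"))
            return
        mol = Chem.AddHs(mol)
        reason = _accept(mol, max_atoms)
        if reason is None:
            accepted.append((label or f"mol{i}", mol))
        else:
            rejected.append((i, reason))

    if fmt == "smiles":
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                handle(i, Chem.MolFromSmiles(parts[0]),
                       parts[1] if len(parts) > 1 else "")
    elif fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False)
        for i, mol in enumerate(supplier):
            name = mol.GetProp("_Name") if mol and mol.HasProp("_Name") else ""
            handle(i, mol, name)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if strict and rejected:
        raise FeaturizationError(f"rejected records in strict mode: {rejected}")
    return ReadResult(accepted, rejected)


def write_sdf(mols, path) -> None:
    writer = Chem.SDWriter(str(path))
    try:
        for mol_id, mol in mols:
            mol.SetProp("_Name", mol_id)
            writer.write(mol)
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# prediction JSON


def predictions_to_json(predictions: list, path=None) -> str:
    """Serialize per-molecule predictions.

    ``predictions`` entries are dicts with molecule_id, smiles, elements,
    shift_value/shift_sigma (N, n_shift_classes) restricted by nucleus, and
    coupling_value/coupling_sigma (N, N, n_coupling_classes) with a mask.
    Couplings are emitted once per unordered pair with i < j.
    """
    doc = []
    for p in predictions:
        elements = p["elements"]
        shifts = []
        for ci, cls in enumerate(SHIFT_CLASSES):
            nucleus = "H" if cls == "1H" else "C"
            for i, el in enumerate(elements):
                if el != nucleus:
                    continue
                shifts.append(
                    {
                        "atom_idx": int(i),
                        "nucleus": cls,
                        "value_ppm": float(p["shift_value"][i, ci]),
                        "uncertainty_ppm": float(p["shift_sigma"][i, ci]),
                    }
                )
        couplings = []
        for ci, cls in enumerate(COUPLING_CLASSES):
            mask = np.triu(np.asarray(p["coupling_mask"][..., ci]), k=1)
            for i, j in zip(*np.nonzero(mask)):
                couplings.append(
                    {
                        "i": int(i),
                        "j": int(j),
                        "class": cls,
                        "value_hz": float(p["coupling_value"][i, j, ci]),
                        "uncertainty_hz": float(p["coupling_sigma"][i, j, ci]),
                    }
                )
        doc.append(
            {
                "molecule_id": p["molecule_id"],
                "smiles": p.get("smiles", ""),
                "shifts": shifts,
                "couplings": couplings,
            }
        )
    text = json.dumps(doc, indent=1)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def predictions_from_json(path) -> list:
    with open(path) as fh:
        return json.load(fh)


def write_shift_sdf(entries, path) -> None:
    """SDF export with predicted shifts in the property block.

    ``entries`` are (mol, prediction) pairs where the prediction exposes
    shift_value / shift_sigma / shift_mask arrays (see SpinSystemPrediction);
    each nucleus class becomes one property listing "atom_idx value sigma"
    triples.
    """
    writer = Chem.SDWriter(str(path))
    try:
        for mol, pred in entries:
            out = Chem.Mol(mol)
            for ci, cls in enumerate(SHIFT_CLASSES):
                rows = [
                    f"{i} {pred.shift_value[i, ci]:.4f} {pred.shift_sigma[i, ci]:.4f}"
                    for i in np.nonzero(pred.shift_mask[:, ci])[0]
                ]
                if rows:
                    out.SetProp(f"PREDICTED_SHIFTS_{cls}", "\n".join(rows))
            writer.write(out)
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# HDF5 feature cache


def write_feature_cache(path, graphs, config: FeatureConfig) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["feature_fingerprint"] = config.fingerprint()
        for g in graphs:
            grp = fh.create_group(g.molecule_id)
            grp.create_dataset("x", data=g.x)
            grp.create_dataset("g_adj", data=g.g_adj)
            grp.create_dataset("g_feat", data=g.g_feat)
            grp.attrs["smiles"] = g.smiles
            grp.attrs["elements"] = ",".join(g.elements)


def read_feature_cache(path, config: FeatureConfig | None = None) -> list:
    out = []
    with h5py.File(path, "r") as fh:
        if config is not None:
            stored = fh.attrs.get("feature_fingerprint", "")
            if stored != config.fingerprint():
                raise ValueError(
                    "feature cache was built with a different feature config"
                )
        for mol_id in fh:
            grp = fh[mol_id]
            x = grp["x"][...]
            out.append(
                MoleculeGraph(
                    x=x,
                    g_adj=grp["g_adj"][...],
                    g_feat=grp["g_feat"][...],
                    atom_mask=np.ones(x.shape[0], dtype=bool),
                    elements=tuple(grp.attrs["elements"].split(",")),
                    molecule_id=mol_id,
                    smiles=grp.attrs["smiles"],
                )
            )
    return out


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(path, fitted, feature_config: FeatureConfig) -> None:
    """Single-file archive: weights, model config, standardization
    constants and the feature-config fingerprint."""
    from dataclasses import asdict

    cfg = asdict(fitted.model_config)
    cfg["adjacency_powers"] = list(cfg["adjacency_powers"])
    cfg["shift_classes"] = list(cfg["shift_classes"])
    cfg["coupling_classes"] = list(cfg["coupling_classes"])
    arrays = {f"param_{i}": a for i, a in enumerate(fitted.network.state_arrays())}
    s = fitted.standardizer
    np.savez(
        path,
        model_config=json.dumps(cfg),
        feature_fingerprint=feature_config.fingerprint(),
        shift_mu=s.shift_mu,
        shift_sd=s.shift_sd,
        coupling_mu=s.coupling_mu,
        coupling_sd=s.coupling_sd,
        f_v=np.array(feature_config.f_v),
        f_e=np.array(feature_config.f_e),
        **arrays,
    )


def load_checkpoint(path, feature_config: FeatureConfig):
    """Rebuild a FittedModel; refuses to load if the feature configuration
    fingerprint does not match the one the checkpoint was trained with."""
    from .training import FittedModel, Standardizer

    with np.load(path, allow_pickle=False) as data:
        stored = str(data["feature_fingerprint"])
        if stored != feature_config.fingerprint():
            raise ValueError(
                "checkpoint feature fingerprint mismatch; refusing to load"
            )
        cfg_dict = json.loads(str(data["model_config"]))
        cfg_dict["adjacency_powers"] = tuple(cfg_dict["adjacency_powers"])
        cfg_dict["shift_classes"] = tuple(cfg_dict["shift_classes"])
        cfg_dict["coupling_classes"] = tuple(cfg_dict["coupling_classes"])
        config = ModelConfig(**cfg_dict)
        net = SpinSystemNetwork(config, int(data["f_v"]), int(data["f_e"]))
        n_params = len(net.parameters())
        net.load_state_arrays([data[f"param_{i}"] for i in range(n_params)])
        standardizer = Standardizer(
            shift_mu=data["shift_mu"],
            shift_sd=data["shift_sd"],
            coupling_mu=data["coupling_mu"],
            coupling_sd=data["coupling_sd"],
        )
    return FittedModel(
        network=net,
        standardizer=standardizer,
        model_config=config,
        feature_fingerprint=stored,
        history=[],
    )
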