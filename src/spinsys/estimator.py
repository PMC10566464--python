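"""sklearn-style estimator facade over the trainer and predictor."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from sklearn.base import BaseEstimator

from .chem import FeatureConfig, featurize, mol_from_smiles
from .fixtures import LabeledExample
from .model import (
    COUPLING_CLASSES,
    SHIFT_CLASSES,
    ModelConfig,
    coupling_class_masks,
)
from .training import DisagreementConfig, TrainConfig, train_model


@dataclass
class SpinSystemPrediction:
    """Predicted spin system of one molecule.

    Shift entries are defined per nucleus class where the atom matches the
    nucleus; coupling entries are symmetric and defined on the per-class
    pair masks.  Uncertainties are bootstrap-head standard deviations and
    are nonnegative.
    """

    molecule_id: str
    smiles: str
    elements: tuple
    shift_value: np.ndarray  # (N, n_shift_classes)
    shift_sigma: np.ndarray
    shift_mask: np.ndarray  # (N, n_shift_classes) bool
    coupling_value: np.ndarray  # (N, N, n_coupling_classes)
    coupling_sigma: np.ndarray
    coupling_mask: np.ndarray  # (N, N, n_coupling_classes) bool

    def shift_dict(self) -> dict:
        """Per-class 1D arrays of shifts in atom-index order (DP4 input)."""
        out = {}
        for ci, cls in enumerate(SHIFT_CLASSES):
            m = self.shift_mask[:, ci]
            out[cls] = self.shift_value[m, ci]
        return out


class SpinSystemRegressor(BaseEstimator):
    """Fit/predict interface to the full spin-system network.

    ``fit`` consumes :class:`LabeledExample` objects (see
    :mod:`spinsys.fixtures` for how to build them from molecules and
    labels); ``predict`` consumes RDKit molecules, SMILES strings or
    pre-built LabeledExamples and returns per-molecule
    :class:`SpinSystemPrediction` objects with bootstrap uncertainties.
    All estimator parameters are plain constructor arguments so the class
    composes with sklearn model selection.
    """

    def __init__(
        self,
        hidden_dim: int = 64,
        n_message_layers: int = 2,
        n_decode_layers: int = 2,
        n_bootstraps: int = 10,
        p_include: float = 0.5,
        aggregation: str = "mean",
        adjacency_powers: tuple = (2, 3),
        include_self_loops: bool = True,
        epochs: int = 60,
        patience: int = 20,
        lr: float = 3e-3,
        batch_size: int = 32,
        val_fraction: float = 0.1,
        lambda_disagreement: float = 5.0,
        disagreement_offset: float = 1.0,
        base_loss: str = "l1",
        n_conformers: int = 50,
        dtype: str = "float32",
        seed: int = 0,
        verbose: bool = False,
    ):
        self.hidden_dim = hidden_dim
        self.n_message_layers = n_message_layers
        self.n_decode_layers = n_decode_layers
        self.n_bootstraps = n_bootstraps
        self.p_include = p_include
        self.aggregation = aggregation
        self.adjacency_powers = adjacency_powers
        self.include_self_loops = include_self_loops
        self.epochs = epochs
        self.patience = patience
        self.lr = lr
        self.batch_size = batch_size
        self.val_fraction = val_fraction
        self.lambda_disagreement = lambda_disagreement
        self.disagreement_offset = disagreement_offset
        self.base_loss = base_loss
        self.n_conformers = n_conformers
        self.dtype = dtype
        self.seed = seed
        self.verbose = verbose

    # -- config assembly ----------------------------------------------------

    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            hidden_dim=self.hidden_dim,
            n_message_layers=self.n_message_layers,
            n_decode_layers=self.n_decode_layers,
            adjacency_powers=tuple(self.adjacency_powers),
            include_self_loops=self.include_self_loops,
            aggregation=self.aggregation,
            n_bootstraps=self.n_bootstraps,
            p_include=self.p_include,
            seed=self.seed,
            dtype=self.dtype,
        )

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs,
            patience=self.patience,
            lr=self.lr,
            batch_size=self.batch_size,
            val_fraction=self.val_fraction,
            disagreement=DisagreementConfig(
                lam=self.lambda_disagreement,
                offset=self.disagreement_offset,
                base_loss=self.base_loss,
            ),
            seed=self.seed,
            verbose=self.verbose,
        )

    def _feature_config(self) -> FeatureConfig:
        return FeatureConfig(n_conformers=self.n_conformers)

    # -- sklearn protocol ---------------------------------------------------

    def fit(self, X, y=None):
        """Fit on a list of :class:`LabeledExample`."""
        examples = list(X)
        if not examples:
            raise ValueError("empty training set")
        self.fitted_ = train_model(
            examples, self._model_config(), self._train_config()
        )
        self.history_ = self.fitted_.history
        self.n_features_in_ = examples[0].graph.x.shape[1]
        return self

    def _as_examples(self, X):
        examples = []
        for i, item in enumerate(X):
            if isinstance(item, LabeledExample):
                examples.append(item)
                continue
            mol = mol_from_smiles(item) if isinstance(item, str) else item
            graph = featurize(
                mol,
                self._feature_config(),
                seed=self.seed + i,
                molecule_id=f"pred{i}",
            )
            n = graph.n_atoms
            nsc, ncc = len(SHIFT_CLASSES), len(COUPLING_CLASSES)
            examples.append(
                LabeledExample(
                    graph=graph,
                    shift_targets=np.zeros((n, nsc, 2)),
                    shift_masks=np.zeros((n, nsc, 2), bool),
                    coupling_targets=np.zeros((n, n, ncc, 2)),
                    coupling_masks=np.zeros((n, n, ncc, 2), bool),
                    molecule_id=f"pred{i}",
                    mol=mol,
                )
            )
        return examples

    def predict(self, X, channel: str = "experimental"):
        """Predict spin systems; ``channel`` selects the output channel
        ("experimental" or "ab_initio")."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "fitted_")
        ch = 0 if channel == "experimental" else 1
        examples = self._as_examples(X)
        raw = self.fitted_.predict_examples(examples)
        out = []
        for ex in examples:
            p = raw[ex.molecule_id]
            mol = ex.mol
            if mol is None:
                mol = Chem.AddHs(Chem.MolFromSmiles(ex.graph.smiles))
            masks = coupling_class_masks(mol)
            cmask = np.stack([masks[c] for c in COUPLING_CLASSES], axis=-1)
            smask = np.zeros((ex.graph.n_atoms, len(SHIFT_CLASSES)), bool)
            for ci, cls in enumerate(SHIFT_CLASSES):
                nucleus = "H" if cls == "1H" else "C"
                smask[:, ci] = [el == nucleus for el in ex.graph.elements]
            out.append(
                SpinSystemPrediction(
                    molecule_id=ex.molecule_id,
                    smiles=ex.graph.smiles,
                    elements=ex.graph.elements,
                    shift_value=p["shift_value"][..., ch],
                    shift_sigma=p["shift_sigma"][..., ch],
                    shift_mask=smask,
                    coupling_value=p["coupling_value"][..., ch] * cmask,
                    coupling_sigma=p["coupling_sigma"][..., ch] * cmask,
                    coupling_mask=cmask,
                )
            )
        return out

    def score(self, X, y=None):
        """Negative experimental-channel MAE over all supervised entries
        (sklearn convention: greater is better)."""
        from .training import collect_errors

        errs = np.concatenate(
            [e for e, _ in collect_errors(self.fitted_, list(X)).values()]
        )
        return -float(np.abs(errs).mean())
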