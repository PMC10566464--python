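"""Losses, the training loop, evaluation metrics and the region experiment.

The trainer jointly fits per-atom shift channels and per-pair coupling
channels.  Losses are computed in standardized units (per parameter class,
training-set mean/std) so nucleus classes with very different numeric
ranges contribute comparably; the disagreement-regularization weight is
computed from the *raw* label disagreement, keeping the fixed 1 ppm
denominator offset meaningful.

Disagreement regularization (shift channels, per supervised atom):

    if both channels labeled:   L = L_a + [lambda / (|phi_a - phi_e| + 1)] L_e
    if one channel labeled:     L = loss along that channel

so strong experimental/ab initio agreement up-weights the experimental
channel, disagreement shifts trust toward ab initio, and lambda = 0 reduces
exactly to ab-initio-only training on dual-labeled atoms.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from ._autodiff import Adam, Tensor
from .fixtures import LabeledExample
from .model import (
    COUPLING_CLASSES,
    SHIFT_CLASSES,
    ModelConfig,
    SpinSystemNetwork,
)
from .uncertainty import assign_bootstraps, ensemble_predict

EXP, AB = 0, 1  # channel indices


@dataclass(frozen=True)
class DisagreementConfig:
    lam: float = 5.0
    offset: float = 1.0  # ppm (or Hz when applied to couplings)
    base_loss: str = "l1"

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")
        if self.base_loss not in ("l1", "huber"):
            raise ValueError("base loss must be 'l1' or 'huber'")


@dataclass
class TrainConfig:
    epochs: int = 60
    patience: int = 20
    lr: float = 3e-3
    lr_final_frac: float = 0.05  # cosine-anneal to this fraction of lr
    val_every: int = 1  # validate every k-th epoch
    batch_size: int = 32
    val_fraction: float = 0.1
    disagreement: DisagreementConfig = field(default_factory=DisagreementConfig)
    couple_disagreement: bool = False  # apply disagreement to couplings (Hz offset)
    seed: int = 0
    verbose: bool = False


# ---------------------------------------------------------------------------
# disagreement loss


def disagreement_weights(phi_a, phi_e, mask_a, mask_e, cfg: DisagreementConfig):
    """Per-entry loss weights (w_a, w_e) implementing the agreement rule."""
    if cfg.lam < 0:
        raise ValueError("lambda must be nonnegative")
    phi_a, phi_e = np.asarray(phi_a, float), np.asarray(phi_e, float)
    mask_a, mask_e = np.asarray(mask_a, bool), np.asarray(mask_e, bool)
    both = mask_a & mask_e
    w = cfg.lam / (np.abs(phi_a - phi_e) + cfg.offset)
    w_a = mask_a.astype(float)
    w_e = np.where(both, w, mask_e.astype(float))
    w_e = w_e * mask_e
    return w_a, w_e


def _base_loss_np(err: np.ndarray, kind: str) -> np.ndarray:
    if kind == "l1":
        return np.abs(err)
    delta = 1.0
    a = np.abs(err)
    return np.where(a <= delta, 0.5 * a * a, delta * (a - 0.5 * delta))


def disagreement_loss(
    pred_a,
    pred_e,
    phi_a,
    phi_e,
    cfg: DisagreementConfig | None = None,
    mask_a=None,
    mask_e=None,
) -> float:
    """Scalar disagreement-regularized loss over supervised atoms (NumPy
    reference form; the trainer applies the same weights inside autodiff)."""
    cfg = cfg or DisagreementConfig()
    pred_a, pred_e = np.asarray(pred_a, float), np.asarray(pred_e, float)
    phi_a, phi_e = np.asarray(phi_a, float), np.asarray(phi_e, float)
    mask_a = np.ones_like(phi_a, bool) if mask_a is None else np.asarray(mask_a, bool)
    mask_e = np.ones_like(phi_e, bool) if mask_e is None else np.asarray(mask_e, bool)
    w_a, w_e = disagreement_weights(phi_a, phi_e, mask_a, mask_e, cfg)
    la = _base_loss_np(pred_a - phi_a, cfg.base_loss)
    le = _base_loss_np(pred_e - phi_e, cfg.base_loss)
    supervised = (mask_a | mask_e).sum()
    if supervised == 0:
        return 0.0
    return float((w_a * la + w_e * le).sum() / supervised)


# ---------------------------------------------------------------------------
# standardization


@dataclass
class Standardizer:
    shift_mu: np.ndarray  # (nsc, 2)
    shift_sd: np.ndarray
    coupling_mu: np.ndarray  # (ncc, 2)
    coupling_sd: np.ndarray

    @classmethod
    def fit(cls, examples) -> "Standardizer":
        """Per-class constants, pooled over the two label channels — the
        channels must share a standardization so the network's additive
        experimental correction is meaningful in standardized space."""
        nsc, ncc = len(SHIFT_CLASSES), len(COUPLING_CLASSES)
        smu, ssd = np.zeros((nsc, 2)), np.ones((nsc, 2))
        cmu, csd = np.zeros((ncc, 2)), np.ones((ncc, 2))
        for ci in range(nsc):
            vals = np.concatenate(
                [
                    ex.shift_targets[:, ci, ch][ex.shift_masks[:, ci, ch]]
                    for ex in examples
                    for ch in range(2)
                ]
            )
            if vals.size:
                smu[ci, :] = vals.mean()
                ssd[ci, :] = max(vals.std(), 1e-6)
        for ci in range(ncc):
            vals = np.concatenate(
                [
                    ex.coupling_targets[..., ci, ch][ex.coupling_masks[..., ci, ch]]
                    for ex in examples
                    for ch in range(2)
                ]
            )
            if vals.size:
                cmu[ci, :] = vals.mean()
                csd[ci, :] = max(vals.std(), 1e-6)
        return cls(smu, ssd, cmu, csd)


# ---------------------------------------------------------------------------
# batching


class _Batch:
    def __init__(self, examples, standardizer, train_cfg, model_cfg):
        n_max = max(ex.graph.n_atoms for ex in examples)
        b = len(examples)
        f_v = examples[0].graph.x.shape[1]
        f_e = examples[0].graph.g_feat.shape[2]
        nsc, ncc = len(SHIFT_CLASSES), len(COUPLING_CLASSES)
        self.x = np.zeros((b, n_max, f_v))
        self.g_adj = np.zeros((b, n_max, n_max, 5))
        self.g_feat = np.zeros((b, n_max, n_max, f_e))
        self.atom_mask = np.zeros((b, n_max), dtype=bool)
        st = np.zeros((b, n_max, nsc, 2))
        sm = np.zeros((b, n_max, nsc, 2), dtype=bool)
        ct = np.zeros((b, n_max, n_max, ncc, 2))
        cm = np.zeros((b, n_max, n_max, ncc, 2), dtype=bool)
        self.head_mask = np.zeros((b, model_cfg.n_bootstraps))
        for k, ex in enumerate(examples):
            n = ex.graph.n_atoms
            self.x[k, :n] = ex.graph.x
            self.g_adj[k, :n, :n] = ex.graph.g_adj
            self.g_feat[k, :n, :n] = ex.graph.g_feat
            self.atom_mask[k, :n] = ex.graph.atom_mask
            st[k, :n] = ex.shift_targets
            sm[k, :n] = ex.shift_masks
            ct[k, :n, :n] = ex.coupling_targets
            cm[k, :n, :n] = ex.coupling_masks
            subset = assign_bootstraps(
                ex.molecule_id,
                model_cfg.n_bootstraps,
                model_cfg.p_include,
                model_cfg.seed,
            )
            self.head_mask[k, list(subset)] = 1.0 / len(subset)

        s = standardizer
        self.shift_targets_std = (st - s.shift_mu) / s.shift_sd
        self.coupling_targets_std = (ct - s.coupling_mu) / s.coupling_sd

        dis = train_cfg.disagreement
        wa, we = disagreement_weights(
            st[..., AB], st[..., EXP], sm[..., AB], sm[..., EXP], dis
        )
        self.shift_w = np.stack([we, wa], axis=-1)  # channel order (EXP, AB)
        if train_cfg.couple_disagreement:
            cwa, cwe = disagreement_weights(
                ct[..., AB], ct[..., EXP], cm[..., AB], cm[..., EXP], dis
            )
            self.coupling_w = np.stack([cwe, cwa], axis=-1)
        else:
            self.coupling_w = cm.astype(float)
        self.shift_masks = sm
        self.coupling_masks = cm
        # per-class supervised-entry counts for the batch mean
        self.shift_counts = np.maximum(
            sm.any(axis=-1).sum(axis=(0, 1)), 1
        )  # (nsc,)
        self.coupling_counts = np.maximum(
            cm.any(axis=-1).sum(axis=(0, 1, 2)), 1
        )  # (ncc,)
        self.examples = examples
        self._fwd_cache = {}

    def forward_cache(self, net):
        """Constant forward inputs, cached per network configuration."""
        key = (net.config.dtype, tuple(net.config.adjacency_powers),
               net.config.include_self_loops)
        if key not in self._fwd_cache:
            self._fwd_cache[key] = net.make_cache(
                self.x, self.g_adj, self.g_feat, self.atom_mask
            )
        return self._fwd_cache[key]

    def loss_cache(self, dtype):
        key = ("loss", np.dtype(dtype).name)
        if key not in self._fwd_cache:
            h = self.head_mask.shape[1]
            self._fwd_cache[key] = {
                "st": Tensor(self.shift_targets_std.astype(dtype)),
                "ct": Tensor(self.coupling_targets_std.astype(dtype)),
                "sw": Tensor(
                    (self.shift_w / self.shift_counts[None, None, :, None]).astype(
                        dtype
                    )
                ),
                "cw": Tensor(
                    (
                        self.coupling_w
                        / self.coupling_counts[None, None, None, :, None]
                    ).astype(dtype)
                ),
                "hw_s": Tensor(self.head_mask.T.reshape(h, -1, 1, 1, 1).astype(dtype)),
                "hw_c": Tensor(
                    self.head_mask.T.reshape(h, -1, 1, 1, 1, 1).astype(dtype)
                ),
            }
        return self._fwd_cache[key]


def make_batches(examples, standardizer, train_cfg, model_cfg):
    order = sorted(range(len(examples)), key=lambda i: examples[i].graph.n_atoms)
    batches = []
    for start in range(0, len(order), train_cfg.batch_size):
        chunk = [examples[i] for i in order[start : start + train_cfg.batch_size]]
        batches.append(_Batch(chunk, standardizer, train_cfg, model_cfg))
    return batches


# ---------------------------------------------------------------------------
# fitted model container


@dataclass
class FittedModel:
    network: SpinSystemNetwork
    standardizer: Standardizer
    model_config: ModelConfig
    feature_fingerprint: str
    history: list

    def _forward_batch(self, batch: _Batch):
        return self.network.forward_cached(batch.forward_cache(self.network))

    def predict_examples(self, examples, train_cfg=None):
        """Ensemble predictions (all heads): de-standardized values and
        head-spread uncertainties for shifts and couplings."""
        model_cfg = self.model_config
        tc = train_cfg or TrainConfig(batch_size=32)
        out = {}
        for batch in make_batches(examples, self.standardizer, tc, model_cfg):
            s_out, c_out = self._forward_batch(batch)
            s_heads = s_out.data  # (H, B, N, nsc, 2)
            c_heads = c_out.data
            s_val, s_unc = ensemble_predict(s_heads)
            c_val, c_unc = ensemble_predict(c_heads)
            s = self.standardizer
            s_val = s_val * s.shift_sd + s.shift_mu
            s_unc = s_unc * s.shift_sd
            c_val = c_val * s.coupling_sd + s.coupling_mu
            c_unc = c_unc * s.coupling_sd
            for k, ex in enumerate(batch.examples):
                n = ex.graph.n_atoms
                out[ex.molecule_id] = {
                    "shift_value": s_val[k, :n],
                    "shift_sigma": s_unc[k, :n],
                    "coupling_value": c_val[k, :n, :n],
                    "coupling_sigma": c_unc[k, :n, :n],
                }
        return out


# ---------------------------------------------------------------------------
# training loop


def _batch_loss(net, batch, base_loss="l1"):
    s_out, c_out = net.forward_cached(batch.forward_cache(net))
    lc = batch.loss_cache(s_out.dtype)
    s_pred = (s_out * lc["hw_s"]).sum(axis=0)
    c_pred = (c_out * lc["hw_c"]).sum(axis=0)
    s_err = (s_pred - lc["st"]).abs()
    c_err = (c_pred - lc["ct"]).abs()
    return (s_err * lc["sw"]).sum() + (c_err * lc["cw"]).sum()


def _val_mae(fitted: FittedModel, batches):
    """Mean standardized MAE (experimental channel) over all classes."""
    total, count = 0.0, 0
    for batch in batches:
        s_out, c_out = fitted._forward_batch(batch)
        s_val, _ = ensemble_predict(s_out.data)
        c_val, _ = ensemble_predict(c_out.data)
        se = np.abs(s_val - batch.shift_targets_std)[..., EXP]
        ce = np.abs(c_val - batch.coupling_targets_std)[..., EXP]
        sm = batch.shift_masks[..., EXP]
        cm = batch.coupling_masks[..., EXP]
        total += se[sm].sum() + ce[cm].sum()
        count += sm.sum() + cm.sum()
    return total / max(count, 1)


def train_model(
    examples,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    val_examples=None,
) -> FittedModel:
    """Fit the network on labeled examples; deterministic given the configs."""
    if not examples:
        raise ValueError("empty training set")
    model_config = model_config or ModelConfig()
    train_config = train_config or TrainConfig()
    rng = np.random.default_rng(train_config.seed)

    if val_examples is None and train_config.val_fraction > 0 and len(examples) >= 10:
        n_val = max(1, int(len(examples) * train_config.val_fraction))
        perm = rng.permutation(len(examples))
        val_examples = [examples[i] for i in perm[:n_val]]
        examples = [examples[i] for i in perm[n_val:]]

    standardizer = Standardizer.fit(examples)
    f_v = examples[0].graph.x.shape[1]
    f_e = examples[0].graph.g_feat.shape[2]
    net = SpinSystemNetwork(model_config, f_v, f_e)
    fitted = FittedModel(
        network=net,
        standardizer=standardizer,
        model_config=model_config,
        feature_fingerprint="",
        history=[],
    )

    batches = make_batches(examples, standardizer, train_config, model_config)
    val_batches = (
        make_batches(val_examples, standardizer, train_config, model_config)
        if val_examples
        else []
    )
    opt = Adam(net.parameters(), lr=train_config.lr)
    best_val, best_state, patience_left = np.inf, None, train_config.patience
    base = train_config.disagreement.base_loss

    for epoch in range(train_config.epochs):
        # cosine annealing keeps early progress fast and settles the L1 fit
        frac = epoch / max(train_config.epochs - 1, 1)
        floor = train_config.lr_final_frac
        opt.lr = train_config.lr * (
            floor + (1 - floor) * 0.5 * (1 + np.cos(np.pi * frac))
        )
        order = rng.permutation(len(batches))
        epoch_loss = 0.0
        for bi in order:
            batch = batches[bi]
            opt.zero_grad()
            loss = _batch_loss(net, batch, base)
            lval = float(loss.data)
            if not np.isfinite(lval):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}"
                )
            loss.backward()
            opt.step()
            epoch_loss += lval
        record = {"epoch": epoch, "train_loss": epoch_loss / len(batches)}
        is_last = epoch == train_config.epochs - 1
        if val_batches and (epoch % train_config.val_every == 0 or is_last):
            vm = _val_mae(fitted, val_batches)
            record["val_mae"] = vm
            if vm < best_val - 1e-6:
                best_val, patience_left = vm, train_config.patience
                best_state = net.state_arrays()
            else:
                patience_left -= 1
        fitted.history.append(record)
        if train_config.verbose:
            print(record)
        if val_batches and patience_left <= 0:
            break
    if best_state is not None:
        net.load_state_arrays(best_state)
    return fitted


# ---------------------------------------------------------------------------
# metrics


def mae(errors) -> float:
    errors = np.asarray(errors, float)
    return float(np.abs(errors).mean())


def rolling_error_curves(abs_errors, uncertainties, window_frac: float = 0.1):
    """Sort predictions by uncertainty and compute rolling-window MAE and
    rolling 95th-percentile error.  Window = ``window_frac`` of the count
    (at least 2)."""
    abs_errors = np.asarray(abs_errors, float)
    uncertainties = np.asarray(uncertainties, float)
    order = np.argsort(uncertainties, kind="stable")
    e = abs_errors[order]
    n = e.size
    w = max(2, int(round(window_frac * n)))
    centers, roll_mae, roll_p95 = [], [], []
    for start in range(0, n - w + 1):
        win = e[start : start + w]
        centers.append(float(uncertainties[order][start + w // 2]))
        roll_mae.append(float(win.mean()))
        roll_p95.append(float(np.percentile(win, 95)))
    return np.array(centers), np.array(roll_mae), np.array(roll_p95)


def error_uncertainty_correlation(abs_errors, uncertainties) -> float:
    abs_errors = np.asarray(abs_errors, float)
    uncertainties = np.asarray(uncertainties, float)
    if abs_errors.size < 2 or np.std(abs_errors) == 0 or np.std(uncertainties) == 0:
        return 0.0
    return float(stats.pearsonr(uncertainties, abs_errors)[0])


def confident_mae(abs_errors, uncertainties, q: float) -> float:
    """MAE of the top-``q`` most confident (lowest-uncertainty) fraction."""
    abs_errors = np.asarray(abs_errors, float)
    uncertainties = np.asarray(uncertainties, float)
    order = np.argsort(uncertainties, kind="stable")
    k = max(1, int(round(q * abs_errors.size)))
    return float(abs_errors[order][:k].mean())


def collect_errors(fitted: FittedModel, examples, channel: int = EXP):
    """Flatten per-entry |error| and uncertainty per parameter class."""
    preds = fitted.predict_examples(examples)
    out = {}
    for ci, cls in enumerate(SHIFT_CLASSES):
        errs, uncs = [], []
        for ex in examples:
            p = preds[ex.molecule_id]
            m = ex.shift_masks[:, ci, channel]
            errs.append(
                np.abs(p["shift_value"][m, ci, channel] - ex.shift_targets[m, ci, channel])
            )
            uncs.append(p["shift_sigma"][m, ci, channel])
        out[cls] = (np.concatenate(errs), np.concatenate(uncs))
    for ci, cls in enumerate(COUPLING_CLASSES):
        errs, uncs = [], []
        for ex in examples:
            p = preds[ex.molecule_id]
            m = np.triu(ex.coupling_masks[..., ci, channel], k=1)
            errs.append(
                np.abs(
                    p["coupling_value"][..., ci, channel][m]
                    - ex.coupling_targets[..., ci, channel][m]
                )
            )
            uncs.append(p["coupling_sigma"][..., ci, channel][m])
        out[cls] = (np.concatenate(errs), np.concatenate(uncs))
    return out


def history_to_csv(history, path) -> None:
    """Write the per-epoch training history as CSV."""
    import pandas as pd

    pd.DataFrame(history).to_csv(path, index=False)


def report_to_csv(report: dict, path) -> None:
    """Flatten a metrics report to one CSV row per parameter class."""
    import pandas as pd

    rows = []
    for cls, entry in report.items():
        row = {
            "class": cls,
            "mae": entry["mae"],
            "n": entry["n"],
            "corr_error_uncertainty": entry["corr_error_uncertainty"],
        }
        for q, v in entry["confident_mae"].items():
            row[f"confident_mae_top{int(q * 100)}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def evaluate(fitted: FittedModel, examples, channel: int = EXP) -> dict:
    """Per-class metrics report: MAE, error/uncertainty correlation,
    confidence-filtered MAE (top 50/80/100%), rolling error curves."""
    report = {}
    for cls, (errs, uncs) in collect_errors(fitted, examples, channel).items():
        if errs.size == 0:
            continue
        centers, rmae, rp95 = rolling_error_curves(errs, uncs)
        report[cls] = {
            "mae": mae(errs),
            "n": int(errs.size),
            "corr_error_uncertainty": error_uncertainty_correlation(errs, uncs),
            "confident_mae": {
                q: confident_mae(errs, uncs, q) for q in (0.5, 0.8, 1.0)
            },
            "rolling_uncertainty": centers.tolist(),
            "rolling_mae": rmae.tolist(),
            "rolling_p95": rp95.tolist(),
        }
    return report


# ---------------------------------------------------------------------------
# region (small-ring analogue) experiment


def _mask_example(ex: LabeledExample, keep_exp: bool, keep_ab: bool, ab_as_exp=False):
    st = ex.shift_targets.copy()
    sm = ex.shift_masks.copy()
    ct = ex.coupling_targets.copy()
    cm = ex.coupling_masks.copy()
    if ab_as_exp:
        st[..., EXP] = st[..., AB]
        sm[..., EXP] = sm[..., AB]
        ct[..., EXP] = ct[..., AB]
        cm[..., EXP] = cm[..., AB]
        keep_exp, keep_ab = True, False
    if not keep_exp:
        sm[..., EXP] = False
        cm[..., EXP] = False
    if not keep_ab:
        sm[..., AB] = False
        cm[..., AB] = False
    return replace(
        ex,
        shift_targets=st,
        shift_masks=sm,
        coupling_targets=ct,
        coupling_masks=cm,
    )


def _region_mae(fitted, test_examples, region, class_name="1H"):
    ci = SHIFT_CLASSES.index(class_name)
    preds = fitted.predict_examples(test_examples)
    errs = []
    for ex in test_examples:
        if ex.region != region:
            continue
        m = ex.shift_masks[:, ci, EXP]
        p = preds[ex.molecule_id]
        errs.append(np.abs(p["shift_value"][m, ci, EXP] - ex.shift_targets[m, ci, EXP]))
    return mae(np.concatenate(errs)) if errs else np.nan


def ring_partition_experiment(
    train_examples,
    test_examples,
    lambdas=(5.0,),
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
) -> dict:
    """Train the four configurations of the small-ring analogue and report
    per-region experimental 1H MAE on held-out data.

    * baseline            -- experimental labels from both regions
    * experimental_control -- experimental labels from region A only
    * ab_initio_control   -- region-A experimental + region-B ab initio
                             trained directly (ab values placed on the
                             experimental channel)
    * disagreement(lam)   -- region-A experimental + ab initio everywhere,
                             disagreement-regularized loss
    """
    regions = {ex.region for ex in train_examples}
    if "B" not in regions or "A" not in regions:
        raise ValueError("training set must contain both regions")
    model_config = model_config or ModelConfig()
    train_config = train_config or TrainConfig()

    def run(examples, lam=None):
        tc = train_config
        if lam is not None:
            tc = replace(tc, disagreement=replace(tc.disagreement, lam=lam))
        fitted = train_model(examples, model_config, tc)
        return {
            "region_A_mae": _region_mae(fitted, test_examples, "A"),
            "region_B_mae": _region_mae(fitted, test_examples, "B"),
        }

    results = {}
    baseline_set = [_mask_example(ex, True, False) for ex in train_examples]
    results["baseline"] = run(baseline_set)

    exp_ctrl = [
        _mask_example(ex, True, False) for ex in train_examples if ex.region == "A"
    ]
    results["experimental_control"] = run(exp_ctrl)

    ab_ctrl = [
        _mask_example(ex, True, False)
        if ex.region == "A"
        else _mask_example(ex, False, False, ab_as_exp=True)
        for ex in train_examples
    ]
    results["ab_initio_control"] = run(ab_ctrl)

    for lam in lambdas:
        dis_set = [
            _mask_example(ex, ex.region == "A", True) for ex in train_examples
        ]
        results[f"disagreement_lambda_{lam:g}"] = run(dis_set, lam=lam)
    return results
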