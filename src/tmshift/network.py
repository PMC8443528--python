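"""The baseline ΔTm predictor and its training protocol.

A single-hidden-layer network (19 inputs → 64 rectified units → 1 linear
output) is trained with mean-square error on 60% of the data, with 30% held
out to drive early stopping and 10% for independent testing.  Before
splitting, the dataset is extended with "mock wild-type" rows — wild-type →
wild-type pseudo-mutations with ΔTm = 0, fifteen per protein, sampled from
that protein's annotated residues — which anchors the identity substitution
at zero.  Training is replicated over independent random splits; the final
model is the replicate with the best validation RMSE (a deterministic rule).

The forward/reverse symmetry experiment retrains the same architecture on
the dataset doubled with reversed mutations (wt/mut swapped, ΔTm negated,
wild-type structural features copied unchanged) and compares test error on
forward mutations against forward-only training.

The network is implemented directly in numpy (Adam optimizer, seeded
minibatch shuffling), which keeps training byte-for-byte reproducible for a
given seed on a single CPU.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats as _scipy_stats

from .dataset import MutationDataset, MutationEntry
from .features import (
    N_FEATURES,
    Normalizer,
    PropertyTable,
    apply_normalizer,
    encode_mutation,
    fit_normalizer,
)
from .structure import StructuralFeatures

__all__ = [
    "NetConfig",
    "SplitSpec",
    "TrainedBaseline",
    "EvalMetrics",
    "augment_with_wt",
    "augment_with_reversed",
    "split_dataset",
    "train_baseline",
    "replicate_training",
    "predict",
    "predict_vectors",
    "evaluate",
    "run_symmetry_experiment",
]


@dataclass
class NetConfig:
    """Architecture and optimization settings for the baseline network."""

    hidden_units: int = 64
    activation: str = "relu"
    max_epochs: int = 2000
    early_stop_patience: int = 50
    learning_rate: float = 1e-3
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.early_stop_patience < 1:
            raise ValueError("early_stop_patience must be >= 1")
        if self.activation != "relu":
            raise ValueError("only the rectifier hidden activation is supported")


@dataclass
class SplitSpec:
    """Random-split fractions for train / validation (early stop) / test."""

    fractions: tuple[float, float, float] = (0.6, 0.3, 0.1)
    seed: int = 0

    def __post_init__(self):
        if any(f <= 0 for f in self.fractions):
            raise ValueError("split fractions must be positive")
        if abs(sum(self.fractions) - 1.0) > 1e-12:
            raise ValueError("split fractions must sum to 1")


@dataclass
class TrainedBaseline:
    """Fitted 19→64→1 predictor: weights, its normalizer, config, history."""

    w1: np.ndarray  # (19, hidden)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (hidden, 1)
    b2: np.ndarray  # (1,)
    normalizer: Normalizer
    config: NetConfig
    history: list[dict] = field(default_factory=list)
    split_id: str = ""
    best_epoch: int = -1

    def forward(self, x_normalized: np.ndarray) -> np.ndarray:
        h = np.maximum(x_normalized @ self.w1 + self.b1, 0.0)
        return (h @ self.w2 + self.b2).ravel()

    def to_json(self) -> str:
        return json.dumps(
            {
                "w1": self.w1.tolist(),
                "b1": self.b1.tolist(),
                "w2": self.w2.tolist(),
                "b2": self.b2.tolist(),
                "normalizer": self.normalizer.to_dict(),
                "config": asdict(self.config),
                "history": self.history,
                "split_id": self.split_id,
                "best_epoch": self.best_epoch,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TrainedBaseline":
        d = json.loads(text)
        return cls(
            w1=np.asarray(d["w1"], dtype=float),
            b1=np.asarray(d["b1"], dtype=float),
            w2=np.asarray(d["w2"], dtype=float),
            b2=np.asarray(d["b2"], dtype=float),
            normalizer=Normalizer.from_dict(d["normalizer"]),
            config=NetConfig(**d["config"]),
            history=d["history"],
            split_id=d["split_id"],
            best_epoch=d["best_epoch"],
        )


@dataclass
class EvalMetrics:
    """RMSE, Pearson r and the |error|-band shares.

    Bands follow the convention [0,1), [1,4], (5,∞), [10,∞): the last two
    overlap by construction and the (4,5] gap is not covered.
    """

    rmse: float
    pearson_r: float | None
    error_band_fractions: dict[str, float]
    r_undefined: bool = False


def _featurize(
    entries, table: PropertyTable
) -> tuple[np.ndarray, np.ndarray]:
    X = np.empty((len(entries), N_FEATURES), dtype=float)
    y = np.empty(len(entries), dtype=float)
    for i, e in enumerate(entries):
        if not e.is_annotated:
            raise ValueError(
                f"entry {e.protein_id} {e.wt_aa}{e.residue_number}{e.mut_aa} is not annotated"
            )
        X[i] = encode_mutation(
            e.wt_aa, e.mut_aa, StructuralFeatures(e.rsa, e.avg_b, e.ss_code), table
        )
        y[i] = e.d_tm
    return X, y


def augment_with_wt(
    ds: MutationDataset, n_per_protein: int = 15, seed: int = 0
) -> MutationDataset:
    """Extend the dataset with mock wild-type→wild-type rows (ΔTm = 0).

    For each protein, ``n_per_protein`` annotated residues are sampled with
    replacement from its entries; proteins with no annotated entries are
    skipped with a warning.  Original entries are untouched.
    """
    rng = np.random.default_rng(seed)
    out = MutationDataset(
        entries=list(ds.entries),
        provenance=ds.provenance,
        validation_report=list(ds.validation_report),
    )
    if n_per_protein == 0:
        return out
    by_protein: dict[str, list[MutationEntry]] = {}
    for e in ds:
        if e.is_annotated:
            by_protein.setdefault(e.protein_id, []).append(e)
    for pid in ds.proteins():
        pool = by_protein.get(pid)
        if not pool:
            warnings.warn(f"protein {pid} has no annotated residues; skipped in WT augmentation")
            continue
        picks = rng.integers(0, len(pool), size=n_per_protein)
        for k in picks:
            src = pool[int(k)]
            out.entries.append(
                MutationEntry(
                    protein_id=src.protein_id,
                    chain=src.chain,
                    residue_number=src.residue_number,
                    wt_aa=src.wt_aa,
                    mut_aa=src.wt_aa,  # identity substitution
                    tm_wt=src.tm_wt,
                    d_tm=0.0,
                    ph=src.ph,
                    technique=src.technique,
                    rsa=src.rsa,
                    avg_b=src.avg_b,
                    ss_code=src.ss_code,
                )
            )
    return out


def augment_with_reversed(ds: MutationDataset) -> MutationDataset:
    """Double the dataset with reversed mutations.

    Each reversed row swaps wt/mut, negates ΔTm, keeps the wild-type
    structural features unchanged, and uses the mutant's Tm (tm_wt + ΔTm) as
    its reference Tm.
    """
    out = MutationDataset(
        entries=list(ds.entries),
        provenance=ds.provenance,
        validation_report=list(ds.validation_report),
    )
    for e in ds:
        out.entries.append(
            MutationEntry(
                protein_id=e.protein_id,
                chain=e.chain,
                residue_number=e.residue_number,
                wt_aa=e.mut_aa,
                mut_aa=e.wt_aa,
                tm_wt=e.tm_wt + e.d_tm,
                d_tm=-e.d_tm,
                ph=e.ph,
                technique=e.technique,
                rsa=e.rsa,
                avg_b=e.avg_b,
                ss_code=e.ss_code,
            )
        )
    return out


def split_dataset(
    ds: MutationDataset, spec: SplitSpec | None = None
) -> tuple[MutationDataset, MutationDataset, MutationDataset]:
    """Seeded random partition into train/validation/test.

    Sizes are floor(n·f) for train and validation, remainder to test.
    """
    spec = spec or SplitSpec()
    n = len(ds)
    if n < 10:
        raise ValueError("dataset too small to split (need >= 10 entries)")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    n_train = int(math.floor(n * spec.fractions[0]))
    n_val = int(math.floor(n * spec.fractions[1]))
    parts = (perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :])
    out = []
    for tag, idx in zip(("train", "validation", "test"), parts):
        out.append(
            MutationDataset(
                entries=[ds.entries[i] for i in idx],
                provenance=f"{ds.provenance}|{tag}|seed={spec.seed}",
            )
        )
    return tuple(out)


def _adam_train(
    X: np.ndarray,
    y: np.ndarray,
    Xv: np.ndarray,
    yv: np.ndarray,
    cfg: NetConfig,
) -> tuple[dict, list[dict], int]:
    rng = np.random.default_rng(cfg.seed)
    n_in, n_h = X.shape[1], cfg.hidden_units
    # He initialization for the rectified layer
    params = {
        "w1": rng.normal(0.0, math.sqrt(2.0 / n_in), size=(n_in, n_h)),
        "b1": np.zeros(n_h),
        "w2": rng.normal(0.0, math.sqrt(2.0 / n_h), size=(n_h, 1)),
        "b2": np.zeros(1),
    }
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(v) for k, v in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0

    def mse(p, Xa, ya):
        h = np.maximum(Xa @ p["w1"] + p["b1"], 0.0)
        pred = (h @ p["w2"] + p["b2"]).ravel()
        return float(np.mean((pred - ya) ** 2))

    best = {k: val.copy() for k, val in params.items()}
    best_val = math.inf
    best_epoch = 0
    history: list[dict] = []
    since_improve = 0
    n = X.shape[0]
    bs = min(cfg.batch_size, n)

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            xb, yb = X[idx], y[idx]
            z1 = xb @ params["w1"] + params["b1"]
            h = np.maximum(z1, 0.0)
            pred = (h @ params["w2"] + params["b2"]).ravel()
            err = pred - yb
            if not np.all(np.isfinite(err)):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(lr={cfg.learning_rate}, batch={bs})"
                )
            g_out = (2.0 / len(idx)) * err[:, None]  # d MSE / d pred
            grads = {
                "w2": h.T @ g_out,
                "b2": g_out.sum(axis=0),
            }
            g_h = (g_out @ params["w2"].T) * (z1 > 0)
            grads["w1"] = xb.T @ g_h
            grads["b1"] = g_h.sum(axis=0)
            t += 1
            for k in params:
                m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
                m_hat = m[k] / (1 - beta1**t)
                v_hat = v[k] / (1 - beta2**t)
                params[k] -= cfg.learning_rate * m_hat / (np.sqrt(v_hat) + eps)

        train_mse = mse(params, X, y)
        val_mse = mse(params, Xv, yv)
        history.append({"epoch": epoch, "train_mse": train_mse, "val_mse": val_mse})
        if val_mse < best_val:
            best_val = val_mse
            best_epoch = epoch
            best = {k: val.copy() for k, val in params.items()}
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= cfg.early_stop_patience:
                break
    return best, history, best_epoch


def train_baseline(
    train: MutationDataset,
    validation: MutationDataset,
    cfg: NetConfig | None = None,
    table: PropertyTable | None = None,
    normalizer: Normalizer | None = None,
    split_id: str = "",
) -> TrainedBaseline:
    """Fit the network on the training split with validation-driven early
    stopping; weights from the best-validation epoch are returned.

    The normalizer is fitted on the training split unless one is supplied;
    it is reused verbatim for the validation inputs (no leakage).
    """
    if len(train) == 0 or len(validation) == 0:
        raise ValueError("train and validation sets must be non-empty")
    cfg = cfg or NetConfig()
    table = table or PropertyTable.default()
    X, y = _featurize(train.entries, table)
    Xv, yv = _featurize(validation.entries, table)
    norm = normalizer or fit_normalizer(X)
    Xn = apply_normalizer(norm, X)
    Xvn = apply_normalizer(norm, Xv)
    best, history, best_epoch = _adam_train(Xn, y, Xvn, yv, cfg)
    return TrainedBaseline(
        w1=best["w1"],
        b1=best["b1"],
        w2=best["w2"],
        b2=best["b2"],
        normalizer=norm,
        config=cfg,
        history=history,
        split_id=split_id,
        best_epoch=best_epoch,
    )


def predict_vectors(model: TrainedBaseline, raw_vectors: np.ndarray) -> np.ndarray:
    """Predict ΔTm (°C) from raw (unnormalized) 19-feature vectors."""
    Xn = apply_normalizer(model.normalizer, np.atleast_2d(raw_vectors))
    return model.forward(Xn)


def predict(
    model: TrainedBaseline, entries, table: PropertyTable | None = None
) -> np.ndarray:
    """Predict ΔTm (°C) for annotated entries; deterministic, one per entry."""
    table = table or PropertyTable.default()
    X, _ = _featurize(list(entries), table)
    return predict_vectors(model, X)


def evaluate(predictions, observations) -> EvalMetrics:
    """RMSE, Pearson r and |error|-band shares between predictions and
    observations."""
    p = np.asarray(predictions, dtype=float)
    o = np.asarray(observations, dtype=float)
    if p.shape != o.shape or p.ndim != 1:
        raise ValueError("predictions and observations must be equal-length 1-D")
    if len(p) < 2:
        raise ValueError("need at least 2 points to evaluate")
    resid = p - o
    rmse = float(np.sqrt(np.mean(resid**2)))
    r_undefined = bool(np.std(p) == 0 or np.std(o) == 0)
    r = None if r_undefined else float(_scipy_stats.pearsonr(p, o).statistic)
    a = np.abs(resid)
    bands = {
        "lt_1": float(np.mean(a < 1)),
        "1_to_4": float(np.mean((a >= 1) & (a <= 4))),
        "gt_5": float(np.mean(a > 5)),
        "ge_10": float(np.mean(a >= 10)),
    }
    return EvalMetrics(
        rmse=rmse, pearson_r=r, error_band_fractions=bands, r_undefined=r_undefined
    )


def replicate_training(
    ds: MutationDataset,
    n_replicates: int = 20,
    cfg: NetConfig | None = None,
    split_seeds: list[int] | None = None,
    fractions: tuple[float, float, float] = (0.6, 0.3, 0.1),
    table: PropertyTable | None = None,
) -> dict:
    """Train one network per random split and select by validation RMSE.

    Returns a dict with ``replicates`` (list of dicts holding the model, its
    split seed and train/validation/test metrics), ``selected`` (index of the
    best-validation-RMSE replicate; ties broken by split seed, so selection
    is invariant to replicate order) and ``dispersion`` (min/median/max test
    RMSE across replicates).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    cfg = cfg or NetConfig()
    table = table or PropertyTable.default()
    seeds = split_seeds if split_seeds is not None else list(range(n_replicates))
    if len(seeds) != n_replicates:
        raise ValueError("split_seed_list length must equal n_replicates")

    replicates = []
    for seed in seeds:
        tr, va, te = split_dataset(ds, SplitSpec(fractions=fractions, seed=seed))
        model = train_baseline(tr, va, cfg, table=table, split_id=f"seed={seed}")
        metrics = {
            "train": evaluate(predict(model, tr.entries, table), [e.d_tm for e in tr]),
            "validation": evaluate(predict(model, va.entries, table), [e.d_tm for e in va]),
            "test": evaluate(predict(model, te.entries, table), [e.d_tm for e in te]),
        }
        replicates.append({"split_seed": seed, "model": model, "metrics": metrics})

    selected = min(
        range(n_replicates),
        key=lambda i: (replicates[i]["metrics"]["validation"].rmse, replicates[i]["split_seed"]),
    )
    test_rmses = sorted(r["metrics"]["test"].rmse for r in replicates)
    dispersion = {
        "min_test_rmse": test_rmses[0],
        "median_test_rmse": float(np.median(test_rmses)),
        "max_test_rmse": test_rmses[-1],
    }
    return {"replicates": replicates, "selected": selected, "dispersion": dispersion}


def run_symmetry_experiment(
    ds: MutationDataset,
    cfg: NetConfig | None = None,
    seeds: list[int] | None = None,
    table: PropertyTable | None = None,
) -> dict:
    """Compare forward-only training against forward-plus-reversed training.

    For each seed the forward dataset is split 60/30/10; one network is
    trained on the forward train/validation parts and one on those parts
    doubled with reversed mutations.  Both are evaluated on the same forward
    test part.  The prediction asymmetry statistic mean |pred(a→b) +
    pred(b→a)| is reported for the reverse-trained model on the test pairs.
    """
    cfg = cfg or NetConfig()
    table = table or PropertyTable.default()
    seeds = seeds if seeds is not None else list(range(5))
    per_seed = []
    for seed in seeds:
        tr, va, te = split_dataset(ds, SplitSpec(seed=seed))
        obs = [e.d_tm for e in te]

        fwd_cfg = NetConfig(**{**asdict(cfg), "seed": cfg.seed + seed})
        m_fwd = train_baseline(tr, va, fwd_cfg, table=table, split_id=f"fwd-seed={seed}")
        rmse_fwd = evaluate(predict(m_fwd, te.entries, table), obs).rmse

        tr_rev = augment_with_reversed(tr)
        va_rev = augment_with_reversed(va)
        m_rev = train_baseline(tr_rev, va_rev, fwd_cfg, table=table, split_id=f"rev-seed={seed}")
        rmse_rev = evaluate(predict(m_rev, te.entries, table), obs).rmse

        fwd_pred = predict(m_rev, te.entries, table)
        rev_te = MutationDataset(entries=list(augment_with_reversed(te).entries[len(te):]))
        rev_pred = predict(m_rev, rev_te.entries, table)
        asym = float(np.mean(np.abs(fwd_pred + rev_pred)))
        per_seed.append(
            {
                "seed": seed,
                "rmse_forward_only": rmse_fwd,
                "rmse_forward_plus_reversed": rmse_rev,
                "prediction_asymmetry": asym,
            }
        )
    return {
        "per_seed": per_seed,
        "median_rmse_forward_only": float(
            np.median([d["rmse_forward_only"] for d in per_seed])
        ),
        "median_rmse_forward_plus_reversed": float(
            np.median([d["rmse_forward_plus_reversed"] for d in per_seed])
        ),
    }
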