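"""Trainable folding-stability predictors under a common contract.

Every model family maps an amino-acid sequence to a predicted folding free
energy ΔG (kcal/mol) and is trained under the same protocol: mini-batch
optimisation with gradient accumulation (a global batch realised from
smaller local batches), early stopping once the validation metric has not
improved for a fixed number of optimizer steps ("patience"), and the
returned state is the *best-validation* checkpoint rather than the last.

Families:

``kmer_ridge``
    Ridge regression on character k-mer counts (k-mers of length 1..k,
    default k = 3). Closed-form fit; the fast CPU baseline.

``tiny_transformer``
    A compact single-block transformer encoder (NumPy throughout, manual
    backpropagation, Adam) with a regression head that reads the
    representation of a start token prepended to the sequence — the head
    placement used when fine-tuning protein language models for
    whole-sequence regression. ``init_mode="pretrained"`` seeds the
    residue embeddings with standardized physicochemical descriptors as
    an informative prior; ``"random"`` starts from scratch.
"""

from __future__ import annotations

import abc
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.linear_model import Ridge

from .errors import ConfigError, InvalidSequenceError

logger = logging.getLogger(__name__)

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AA20)

PAD, START = 0, 1
TOKEN_OF = {aa: i + 2 for i, aa in enumerate(AA20)}
VOCAB_SIZE = 2 + len(AA20)

#: Per-residue physicochemical descriptors (columns: Kyte-Doolittle
#: hydropathy, net charge at pH 7, side-chain volume Å³, polarity flag,
#: helix propensity). Standardized at init time; used as informative
#: starting embeddings under ``init_mode="pretrained"``.
AA_DESCRIPTORS = {
    "A": (1.8, 0.0, 88.6, 0.0, 1.42), "C": (2.5, 0.0, 108.5, 0.0, 0.70),
    "D": (-3.5, -1.0, 111.1, 1.0, 1.01), "E": (-3.5, -1.0, 138.4, 1.0, 1.51),
    "F": (2.8, 0.0, 189.9, 0.0, 1.13), "G": (-0.4, 0.0, 60.1, 0.0, 0.57),
    "H": (-3.2, 0.1, 153.2, 1.0, 1.00), "I": (4.5, 0.0, 166.7, 0.0, 1.08),
    "K": (-3.9, 1.0, 168.6, 1.0, 1.16), "L": (3.8, 0.0, 166.7, 0.0, 1.21),
    "M": (1.9, 0.0, 162.9, 0.0, 1.45), "N": (-3.5, 0.0, 114.1, 1.0, 0.67),
    "P": (-1.6, 0.0, 112.7, 0.0, 0.57), "Q": (-3.5, 0.0, 143.8, 1.0, 1.11),
    "R": (-4.5, 1.0, 173.4, 1.0, 0.98), "S": (-0.8, 0.0, 89.0, 1.0, 0.77),
    "T": (-0.7, 0.0, 116.1, 1.0, 0.83), "V": (4.2, 0.0, 140.0, 0.0, 1.06),
    "W": (-0.9, 0.0, 227.8, 0.0, 1.08), "Y": (-1.3, 0.0, 193.6, 1.0, 0.69),
}


@dataclass(frozen=True)
class TrainingConfig:
    """Shared training protocol knobs.

    ``global_batch_size`` must be a multiple of ``local_batch_size``; the
    ratio is realised by gradient accumulation, so the optimizer sees one
    step per global batch. ``patience_steps`` counts optimizer steps since
    the last validation improvement. ``precision`` is accepted for config
    compatibility and is a no-op on CPU.
    """

    local_batch_size: int = 128
    global_batch_size: int = 2048
    patience_steps: int = 500
    learning_rate: float = 1e-3
    max_steps: int = 2000
    seed: int = 0
    precision: str = "float32"
    init_mode: str = "random"  # "pretrained" | "random"
    # model-family hyperparameters
    kmer_k: int = 3
    ridge_alpha: float = 1.0
    d_model: int = 24
    d_ff: int = 48
    max_len: int = 96

    def __post_init__(self):
        if self.global_batch_size % self.local_batch_size != 0:
            raise ConfigError("global_batch_size must be a multiple of local_batch_size")
        if self.patience_steps < 1:
            raise ConfigError("patience_steps must be >= 1")
        if self.init_mode not in ("pretrained", "random"):
            raise ConfigError(f"unknown init_mode {self.init_mode!r}")


@dataclass
class TrainingLog:
    history: list = field(default_factory=list)  # dicts: step, train_loss, val_loss
    best_step: int = 0
    best_val_loss: float = float("inf")
    final_val_loss: float = float("inf")
    stopped_reason: str = ""

    def record(self, step: int, train_loss: float, val_loss: float) -> None:
        self.history.append(
            {"step": step, "train_loss": float(train_loss), "val_loss": float(val_loss)}
        )


def _validate_sequences(sequences: Sequence[str]) -> None:
    errors = []
    for i, s in enumerate(sequences):
        if not s:
            errors.append((i, s, "empty sequence"))
        elif not set(s) <= _AA_SET:
            errors.append((i, s, f"invalid residues {sorted(set(s) - _AA_SET)}"))
    if errors:
        raise InvalidSequenceError(errors)


def data_fingerprint(sequences: Iterable[str], targets: Iterable[float]) -> str:
    payload = "\n".join(
        f"{s}\t{t:.6f}" for s, t in sorted(zip(sequences, targets))
    ).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


class Predictor(abc.ABC):
    """Contract: fit on (train, validation), then deterministic predict."""

    family: str = "abstract"

    def __init__(self, config: TrainingConfig | None = None):
        self.config = config or TrainingConfig()
        self.metadata: dict = {"family": self.family}
        self._fitted = False

    @abc.abstractmethod
    def fit(
        self,
        train_sequences: Sequence[str],
        train_y: np.ndarray,
        val_sequences: Sequence[str],
        val_y: np.ndarray,
    ) -> TrainingLog: ...

    @abc.abstractmethod
    def predict(self, sequences: Sequence[str]) -> np.ndarray:
        """One finite ΔG (kcal/mol) per input, in input order."""


class KmerRidgePredictor(Predictor):
    """Ridge regression on counts of k-mers of length 1..k."""

    family = "kmer_ridge"

    def fit(self, train_sequences, train_y, val_sequences, val_y):
        _validate_sequences(train_sequences)
        _validate_sequences(val_sequences)
        self._vectorizer = CountVectorizer(
            analyzer="char", ngram_range=(1, self.config.kmer_k), lowercase=False
        )
        X = self._vectorizer.fit_transform(train_sequences)
        self._model = Ridge(alpha=self.config.ridge_alpha, random_state=self.config.seed)
        self._model.fit(X, np.asarray(train_y, dtype=float))
        self._fitted = True

        log = TrainingLog()
        train_loss = float(np.mean((self._model.predict(X) - train_y) ** 2))
        val_loss = float(np.mean((self.predict(val_sequences) - val_y) ** 2))
        log.record(0, train_loss, val_loss)
        log.best_step = 0
        log.best_val_loss = log.final_val_loss = val_loss
        log.stopped_reason = "closed_form"
        self.metadata.update(
            {
                "family": self.family,
                "best_step": 0,
                "train_fingerprint": data_fingerprint(train_sequences, train_y),
                "n_features": int(X.shape[1]),
            }
        )
        return log

    def predict(self, sequences):
        if not self._fitted:
            raise ConfigError("predictor is not fitted")
        sequences = list(sequences)
        if not sequences:
            return np.empty(0)
        _validate_sequences(sequences)
        return self._model.predict(self._vectorizer.transform(sequences))


# --------------------------------------------------------------------------
# tiny transformer (NumPy, manual backprop)
# --------------------------------------------------------------------------

def _tokenize(sequences: Sequence[str], max_len: int) -> tuple[np.ndarray, np.ndarray]:
    """(tokens, mask), each (B, L); position 0 is the start token."""
    L = min(max(len(s) for s in sequences) + 1, max_len)
    toks = np.zeros((len(sequences), L), dtype=np.int64)
    mask = np.zeros((len(sequences), L), dtype=np.float64)
    for b, s in enumerate(sequences):
        s = s[: max_len - 1]
        toks[b, 0] = START
        toks[b, 1 : 1 + len(s)] = [TOKEN_OF[c] for c in s]
        mask[b, : 1 + len(s)] = 1.0
    return toks, mask


def _init_params(config: TrainingConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    d, h = config.d_model, config.d_ff
    sd = 0.08
    p = {
        "E": rng.normal(0, sd, (VOCAB_SIZE, d)),
        "P": rng.normal(0, sd, (config.max_len, d)),
        "Wq": rng.normal(0, sd, (d, d)),
        "Wk": rng.normal(0, sd, (d, d)),
        "Wv": rng.normal(0, sd, (d, d)),
        "Wo": rng.normal(0, sd, (d, d)),
        "W1": rng.normal(0, sd, (d, h)),
        "b1": np.zeros(h),
        "W2": rng.normal(0, sd, (h, d)),
        "b2": np.zeros(d),
        "w_out": rng.normal(0, sd, d),
        "b_out": np.zeros(()),
    }
    if config.init_mode == "pretrained":
        desc = np.array([AA_DESCRIPTORS[aa] for aa in AA20])
        desc = (desc - desc.mean(0)) / desc.std(0)
        k = min(desc.shape[1], d)
        p["E"][2:, :k] = desc[:, :k]
    return p


def _forward(p, toks, mask):
    d = p["Wq"].shape[0]
    L = toks.shape[1]
    X0 = p["E"][toks] + p["P"][:L]
    Q, K, V = X0 @ p["Wq"], X0 @ p["Wk"], X0 @ p["Wv"]
    S = Q @ K.transpose(0, 2, 1) / np.sqrt(d)
    S = S - 1e9 * (1.0 - mask[:, None, :])
    S = S - S.max(axis=-1, keepdims=True)
    expS = np.exp(S)
    A = expS / expS.sum(axis=-1, keepdims=True)
    AV = A @ V
    X1 = X0 + AV @ p["Wo"]
    Z = X1 @ p["W1"] + p["b1"]
    F1 = np.maximum(Z, 0.0)
    X2 = X1 + F1 @ p["W2"] + p["b2"]
    yhat = X2[:, 0, :] @ p["w_out"] + p["b_out"]
    cache = (toks, mask, X0, Q, K, V, A, AV, X1, F1, X2)
    return yhat, cache


def _backward(p, cache, dyhat):
    toks, mask, X0, Q, K, V, A, AV, X1, F1, X2 = cache
    B, L, d = X0.shape
    g = {k: np.zeros_like(v) for k, v in p.items()}

    g["w_out"] = X2[:, 0, :].T @ dyhat
    g["b_out"] = np.asarray(dyhat.sum())
    dX2 = np.zeros_like(X2)
    dX2[:, 0, :] = np.outer(dyhat, p["w_out"])

    # FFN (residual)
    dX1 = dX2.copy()
    dF1 = dX2 @ p["W2"].T
    g["W2"] = F1.reshape(-1, F1.shape[-1]).T @ dX2.reshape(-1, d)
    g["b2"] = dX2.sum(axis=(0, 1))
    dZ = dF1 * (F1 > 0)
    g["W1"] = X1.reshape(-1, d).T @ dZ.reshape(-1, dZ.shape[-1])
    g["b1"] = dZ.sum(axis=(0, 1))
    dX1 += dZ @ p["W1"].T

    # attention (residual)
    dX0 = dX1.copy()
    dAVWo = dX1
    g["Wo"] = AV.reshape(-1, d).T @ dAVWo.reshape(-1, d)
    dAV = dAVWo @ p["Wo"].T
    dA = dAV @ V.transpose(0, 2, 1)
    dV = A.transpose(0, 2, 1) @ dAV
    dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
    dS /= np.sqrt(d)
    dQ = dS @ K
    dK = dS.transpose(0, 2, 1) @ Q
    g["Wq"] = X0.reshape(-1, d).T @ dQ.reshape(-1, d)
    g["Wk"] = X0.reshape(-1, d).T @ dK.reshape(-1, d)
    g["Wv"] = X0.reshape(-1, d).T @ dV.reshape(-1, d)
    dX0 += dQ @ p["Wq"].T + dK @ p["Wk"].T + dV @ p["Wv"].T

    g["P"][:L] = dX0.sum(axis=0)
    np.add.at(g["E"], toks.reshape(-1), dX0.reshape(-1, d))
    return g


class TinyTransformerPredictor(Predictor):
    """Single-block transformer encoder with a start-token regression head.

    Trained with Adam, MSE loss, gradient accumulation to the global batch
    size, and early stopping on validation loss with the configured
    patience; the returned state is the best-validation checkpoint.
    """

    family = "tiny_transformer"

    def _val_loss(self, p, val_sequences, val_y):
        preds = self._predict_with(p, val_sequences)
        return float(np.mean((preds - val_y) ** 2))

    def _predict_with(self, p, sequences, chunk=256):
        out = []
        for i in range(0, len(sequences), chunk):
            toks, mask = _tokenize(sequences[i : i + chunk], self.config.max_len)
            yhat, _ = _forward(p, toks, mask)
            out.append(yhat)
        return np.concatenate(out)

    def fit(self, train_sequences, train_y, val_sequences, val_y):
        cfg = self.config
        _validate_sequences(train_sequences)
        _validate_sequences(val_sequences)
        train_sequences = list(train_sequences)
        train_y = np.asarray(train_y, dtype=float)
        val_y = np.asarray(val_y, dtype=float)

        rng = np.random.default_rng(cfg.seed)
        p = _init_params(cfg, rng)
        # target centering/scaling stabilises the head at init
        self._y_mean, self._y_std = float(train_y.mean()), float(train_y.std() or 1.0)
        y_n = (train_y - self._y_mean) / self._y_std
        yv_n = (val_y - self._y_mean) / self._y_std

        m = {k: np.zeros_like(v) for k, v in p.items()}
        v_adam = {k: np.zeros_like(v) for k, v in p.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        n_accum = cfg.global_batch_size // cfg.local_batch_size
        n = len(train_sequences)

        log = TrainingLog()
        best_p = {k: a.copy() for k, a in p.items()}
        order = rng.permutation(n)
        cursor = 0

        for step in range(1, cfg.max_steps + 1):
            grads = {k: np.zeros_like(a) for k, a in p.items()}
            micro_losses = []
            for _ in range(n_accum):
                if cursor + cfg.local_batch_size > n:
                    order = rng.permutation(n)
                    cursor = 0
                idx = order[cursor : cursor + min(cfg.local_batch_size, n)]
                cursor += cfg.local_batch_size
                seqs = [train_sequences[i] for i in idx]
                toks, mask = _tokenize(seqs, cfg.max_len)
                yhat, cache = _forward(p, toks, mask)
                resid = yhat - y_n[idx]
                micro_losses.append(float(np.mean(resid**2)))
                g = _backward(p, cache, 2.0 * resid / len(idx))
                for k in grads:
                    grads[k] += g[k]
            for k in grads:
                grads[k] /= n_accum

            for k in p:
                m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                v_adam[k] = beta2 * v_adam[k] + (1 - beta2) * grads[k] ** 2
                mhat = m[k] / (1 - beta1**step)
                vhat = v_adam[k] / (1 - beta2**step)
                p[k] = p[k] - cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)

            val_loss = self._val_loss(p, val_sequences, yv_n)
            log.record(step, float(np.mean(micro_losses)), val_loss)
            if val_loss < log.best_val_loss:
                log.best_val_loss = val_loss
                log.best_step = step
                best_p = {k: a.copy() for k, a in p.items()}
            elif step - log.best_step >= cfg.patience_steps:
                log.stopped_reason = f"patience ({cfg.patience_steps} steps without improvement)"
                break
        else:
            log.stopped_reason = "max_steps"
        log.final_val_loss = log.history[-1]["val_loss"]

        self._params = best_p
        self._fitted = True
        self.metadata.update(
            {
                "family": self.family,
                "best_step": log.best_step,
                "n_steps_run": log.history[-1]["step"],
                "train_fingerprint": data_fingerprint(train_sequences, train_y),
                "init_mode": cfg.init_mode,
            }
        )
        return log

    def predict(self, sequences):
        if not self._fitted:
            raise ConfigError("predictor is not fitted")
        sequences = list(sequences)
        if not sequences:
            return np.empty(0)
        _validate_sequences(sequences)
        return self._predict_with(self._params, sequences) * self._y_std + self._y_mean


MODEL_FAMILIES = {
    "kmer_ridge": KmerRidgePredictor,
    "tiny_transformer": TinyTransformerPredictor,
}


def train_predictor(
    model_family: str,
    train_records: pd.DataFrame,
    validation_records: pd.DataFrame,
    config: TrainingConfig | None = None,
) -> tuple[Predictor, TrainingLog]:
    """Train one predictor under the early-stopping protocol.

    ``train_records`` / ``validation_records`` follow the curated schema
    (``protein_sequence``, ``mean_dG``); rows lacking a ΔG target are
    ignored. The sets must be disjoint by protein sequence, and validation
    must be non-empty (checkpoint selection is undefined otherwise).
    """
    if model_family not in MODEL_FAMILIES:
        raise ConfigError(
            f"unknown model family {model_family!r}; choose from {sorted(MODEL_FAMILIES)}"
        )
    train = train_records.dropna(subset=["mean_dG"])
    val = validation_records.dropna(subset=["mean_dG"])
    if val.empty:
        raise ConfigError("validation set is empty; checkpoint selection undefined")
    if train.empty:
        raise ConfigError("training set is empty")
    overlap = set(train["protein_sequence"]) & set(val["protein_sequence"])
    if overlap:
        raise ConfigError(
            f"train/validation share {len(overlap)} protein sequence(s); sets must be disjoint"
        )
    predictor = MODEL_FAMILIES[model_family](config)
    log = predictor.fit(
        train["protein_sequence"].tolist(),
        train["mean_dG"].to_numpy(),
        val["protein_sequence"].tolist(),
        val["mean_dG"].to_numpy(),
    )
    return predictor, log


def train_single_domain_ensemble(
    records: pd.DataFrame,
    model_family: str = "kmer_ridge",
    config: TrainingConfig | None = None,
    min_records: int = 30,
    domains: Sequence[str] | None = None,
) -> tuple[dict[str, Predictor], list[dict]]:
    """One independently trained predictor per domain.

    ``records`` carry curated fields plus ``split_label``; each domain's
    own train/validation rows are used under the same protocol as
    ``train_predictor``. Domains below ``min_records`` usable rows are
    skipped with a log entry. ``domains`` restricts the ensemble (e.g. to
    matched partners only).
    """
    ensemble: dict[str, Predictor] = {}
    skip_log: list[dict] = []
    wanted = sorted(set(domains)) if domains is not None else sorted(records["domain_id"].unique())
    for domain_id in wanted:
        grp = records.loc[records["domain_id"] == domain_id].dropna(subset=["mean_dG"])
        train = grp.loc[grp["split_label"] == "train"]
        val = grp.loc[grp["split_label"] == "validation"]
        if len(train) + len(val) < min_records or val.empty or train.empty:
            skip_log.append(
                {"domain_id": domain_id, "n_train": len(train), "n_validation": len(val),
                 "reason": f"fewer than {min_records} usable records"}
            )
            continue
        predictor, _ = train_predictor(model_family, train, val, config)
        ensemble[domain_id] = predictor
    if skip_log:
        logger.info("single-domain ensemble: skipped %d domain(s)", len(skip_log))
    return ensemble, skip_log


def save_predictor(predictor: Predictor, path: str | Path) -> None:
    """Serialize to a versioned two-file archive (<path>.json + <path>.npz)."""
    path = Path(path)
    meta = {
        "format_version": 1,
        "family": predictor.family,
        "config": asdict(predictor.config),
        "metadata": predictor.metadata,
    }
    arrays: dict[str, np.ndarray] = {}
    if isinstance(predictor, TinyTransformerPredictor):
        arrays = {f"param_{k}": v for k, v in predictor._params.items()}
        meta["y_scale"] = [predictor._y_mean, predictor._y_std]
    elif isinstance(predictor, KmerRidgePredictor):
        vocab = predictor._vectorizer.vocabulary_
        meta["vocabulary"] = {k: int(v) for k, v in vocab.items()}
        arrays = {
            "coef": predictor._model.coef_,
            "intercept": np.asarray(predictor._model.intercept_),
        }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    np.savez(path.with_suffix(".npz"), **arrays)


def load_predictor(path: str | Path) -> Predictor:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    arrays = np.load(path.with_suffix(".npz"))
    config = TrainingConfig(**meta["config"])
    family = meta["family"]
    if family == "tiny_transformer":
        predictor = TinyTransformerPredictor(config)
        predictor._params = {k[len("param_"):]: arrays[k] for k in arrays.files}
        predictor._y_mean, predictor._y_std = meta["y_scale"]
    elif family == "kmer_ridge":
        predictor = KmerRidgePredictor(config)
        predictor._vectorizer = CountVectorizer(
            analyzer="char", ngram_range=(1, config.kmer_k), lowercase=False,
            vocabulary=meta["vocabulary"],
        )
        predictor._model = Ridge(alpha=config.ridge_alpha)
        predictor._model.coef_ = arrays["coef"]
        predictor._model.intercept_ = float(arrays["intercept"])
    else:
        raise ConfigError(f"unknown serialized family {family!r}")
    predictor.metadata = meta["metadata"]
    predictor._fitted = True
    return predictor
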