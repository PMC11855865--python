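"""Risk models over encoded visit sequences.

Four families, sharing one training/evaluation contract:

* ``LR`` — logistic regression on a binary presence-of-code bag (order- and
  time-blind baseline), fitted with scikit-learn.
* ``RNN`` — stacked tanh recurrent network over visit embeddings.
* ``TLSTM`` — time-aware LSTM: before each step the long-term memory is
  discounted by ``g(dt) = 1 / log(e + dt)`` of the elapsed days since the
  previous visit, so stale history decays while recent history persists.
* ``RETAIN`` — two-level attention model: visit-level (alpha) and
  code-dimension-level (beta) attention computed by recurrent networks run
  in reverse time, combined into a context vector that feeds a linear head.

The neural families run on the package's own reverse-mode autodiff engine.
Training uses Adam, binary cross-entropy, and early stopping on validation
AUROC with a configurable patience; the classification threshold for
precision/recall/F1 is frozen as the max-F1 point on the validation split
before the test split is touched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import precision_recall_curve, roc_auc_score

from .autodiff import Adam, Tensor, bce_with_logits, no_grad, sigmoid
from .encoding import EncodedSequence

log = logging.getLogger(__name__)

MODEL_KINDS = ("LR", "RNN", "TLSTM", "RETAIN")


@dataclass
class ModelConfig:
    model_kind: str = "RETAIN"
    embedding_dim: int = 128
    hidden_dim: int = 128
    dropout: float = 0.2
    n_layers: int = 2
    vocab_cap: int = 30_000
    patience: int = 3
    max_epochs: int = 30
    learning_rate: float = 1e-3
    weight_decay: float = 1e-2
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        if min(self.embedding_dim, self.hidden_dim, self.n_layers,
               self.patience, self.max_epochs, self.batch_size) <= 0:
            raise ValueError("model dimensions and schedule must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")


@dataclass
class FittedModel:
    model_kind: str
    config: ModelConfig
    vocab_size: int
    params: dict
    history: list[float] = field(default_factory=list)  # per-epoch val AUROC
    stopped_epoch: int = 0
    threshold: float = 0.5
    base_rate: float = 0.5


@dataclass
class EvalReport:
    auroc: float
    precision: float
    recall: float
    f1: float
    threshold: float
    n_cases: int
    n_controls: int


def tlstm_decay(delta_days) -> np.ndarray | float:
    """Elapsed-time memory discount ``1 / log(e + dt)``: 1 at dt = 0,
    strictly decreasing, always positive."""
    arr = np.asarray(delta_days, dtype=np.float64)
    if np.any(arr < 0):
        raise ValueError("delta_days must be non-negative")
    out = 1.0 / np.log(np.e + arr)
    return float(out) if np.isscalar(delta_days) or arr.ndim == 0 else out


# --------------------------------------------------------------------------
# featurization
# --------------------------------------------------------------------------

def presence_bag(sample: EncodedSequence, vocab_size: int) -> np.ndarray:
    """Binary presence-of-code vector over the whole sequence (LR view)."""
    x = np.zeros(vocab_size, dtype=np.float64)
    for idxs, _ in sample.visits:
        for i in idxs:
            x[i] = 1.0
    return x


def _pad_batch(samples: list[EncodedSequence], vocab_size: int):
    """Multi-hot (B,T,V), day gaps (B,T), validity mask (B,T)."""
    b = len(samples)
    t = max((s.length for s in samples), default=1) or 1
    x = np.zeros((b, t, vocab_size), dtype=np.float64)
    dt = np.zeros((b, t), dtype=np.float64)
    mask = np.zeros((b, t), dtype=np.float64)
    for bi, s in enumerate(samples):
        for ti, (idxs, delta) in enumerate(s.visits):
            x[bi, ti, list(idxs)] = 1.0
            dt[bi, ti] = delta
            mask[bi, ti] = 1.0
    return x, dt, mask


def _reverse_valid(x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Flip each sequence's valid prefix in time, keeping padding at the end."""
    out = np.zeros_like(x)
    for bi in range(x.shape[0]):
        n = int(mask[bi].sum())
        out[bi, :n] = x[bi, :n][::-1]
    return out


# --------------------------------------------------------------------------
# parameter initialisation
# --------------------------------------------------------------------------

def _init(rng: np.random.Generator, *shape) -> Tensor:
    std = 1.0 / np.sqrt(shape[0])
    return Tensor(rng.normal(0.0, std, size=shape), requires_grad=True)


def _zeros(*shape) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


def _init_params(kind: str, vocab_size: int, cfg: ModelConfig,
                 rng: np.random.Generator) -> dict:
    d, h = cfg.embedding_dim, cfg.hidden_dim
    p: dict[str, Tensor] = {"E": _init(rng, vocab_size, d)}
    if kind == "RNN":
        for l in range(cfg.n_layers):
            fan = d if l == 0 else h
            p[f"Wx{l}"], p[f"Wh{l}"], p[f"b{l}"] = (
                _init(rng, fan, h), _init(rng, h, h), _zeros(h))
    elif kind == "TLSTM":
        for l in range(cfg.n_layers):
            fan = d if l == 0 else h
            # zero-init decomposition: the cell starts as a plain LSTM with
            # intact memory and learns which component should decay
            p[f"Wd{l}"], p[f"bd{l}"] = _zeros(h, h), _zeros(h)
            for gate in "fiog":
                p[f"W{gate}{l}"] = _init(rng, fan, h)
                p[f"U{gate}{l}"] = _init(rng, h, h)
                p[f"b{gate}{l}"] = _zeros(h)
            p[f"bf{l}"].data += 1.0  # forget-gate bias: retain memory early
    elif kind == "RETAIN":
        p.update(
            Wg=_init(rng, d, h), Ug=_init(rng, h, h), bg=_zeros(h),
            wa=_init(rng, h, 1), ba=_zeros(1),
            Wh=_init(rng, d, h), Uh=_init(rng, h, h), bh=_zeros(h),
            Wb=_init(rng, h, d), bb=_zeros(d),
        )
    if kind == "RETAIN":
        p["Wo"], p["bo"] = _init(rng, d, 1), _zeros(1)
    else:
        p["Wo"], p["bo"] = _init(rng, h, 1), _zeros(1)
    return p


# --------------------------------------------------------------------------
# forward passes
# --------------------------------------------------------------------------

def _embed(x: np.ndarray, params: dict, drop_mask: np.ndarray | None):
    b, t, v = x.shape
    emb = Tensor(x.reshape(b * t, v)) @ params["E"]  # (B*T, D)
    if drop_mask is not None:
        emb = emb * drop_mask
    return emb, b, t


def _rnn_logits(x, dt, mask, params, cfg, drop_mask=None) -> Tensor:
    del dt
    emb, b, t = _embed(x, params, drop_mask)
    d = cfg.embedding_dim
    steps = [emb[np.arange(b * t).reshape(b, t)[:, ti]] for ti in range(t)]
    for l in range(cfg.n_layers):
        h = Tensor(np.zeros((b, cfg.hidden_dim)))
        outs = []
        for ti in range(t):
            m = mask[:, ti : ti + 1]
            h_new = (steps[ti] @ params[f"Wx{l}"] + h @ params[f"Wh{l}"]
                     + params[f"b{l}"]).tanh()
            h = h_new * m + h * (1.0 - m)
            outs.append(h)
        steps = outs
        d = cfg.hidden_dim
    return (steps[-1] @ params["Wo"] + params["bo"]).reshape(b)


def _tlstm_logits(x, dt, mask, params, cfg, drop_mask=None) -> Tensor:
    emb, b, t = _embed(x, params, drop_mask)
    steps = [emb[np.arange(b * t).reshape(b, t)[:, ti]] for ti in range(t)]
    decay = tlstm_decay(dt)  # (B,T), constant w.r.t. parameters
    for l in range(cfg.n_layers):
        h = Tensor(np.zeros((b, cfg.hidden_dim)))
        c = Tensor(np.zeros((b, cfg.hidden_dim)))
        outs = []
        for ti in range(t):
            m = mask[:, ti : ti + 1]
            g_dt = decay[:, ti : ti + 1]
            c_short = (c @ params[f"Wd{l}"] + params[f"bd{l}"]).tanh()
            c_adj = (c - c_short) + c_short * g_dt
            xt = steps[ti]
            fg = (xt @ params[f"Wf{l}"] + h @ params[f"Uf{l}"] + params[f"bf{l}"]).sigmoid()
            ig = (xt @ params[f"Wi{l}"] + h @ params[f"Ui{l}"] + params[f"bi{l}"]).sigmoid()
            og = (xt @ params[f"Wo{l}"] + h @ params[f"Uo{l}"] + params[f"bo{l}"]).sigmoid()
            gg = (xt @ params[f"Wg{l}"] + h @ params[f"Ug{l}"] + params[f"bg{l}"]).tanh()
            c_new = fg * c_adj + ig * gg
            h_new = og * c_new.tanh()
            h = h_new * m + h * (1.0 - m)
            c = c_new * m + c * (1.0 - m)
            outs.append(h)
        steps = outs
    return (steps[-1] @ params["Wo"] + params["bo"]).reshape(b)


def _retain_logits(x, dt, mask, params, cfg, drop_mask=None) -> Tensor:
    del dt
    xr = _reverse_valid(x, mask)  # attention runs in reverse time
    emb, b, t = _embed(xr, params, drop_mask)
    idx = np.arange(b * t).reshape(b, t)
    v_steps = [emb[idx[:, ti]] for ti in range(t)]

    ga = Tensor(np.zeros((b, cfg.hidden_dim)))
    hb = Tensor(np.zeros((b, cfg.hidden_dim)))
    e_list, beta_list = [], []
    for ti in range(t):
        m = mask[:, ti : ti + 1]
        ga_new = (v_steps[ti] @ params["Wg"] + ga @ params["Ug"] + params["bg"]).tanh()
        ga = ga_new * m + ga * (1.0 - m)
        hb_new = (v_steps[ti] @ params["Wh"] + hb @ params["Uh"] + params["bh"]).tanh()
        hb = hb_new * m + hb * (1.0 - m)
        e_list.append(ga @ params["wa"] + params["ba"])           # (B,1)
        beta_list.append((hb @ params["Wb"] + params["bb"]).tanh())  # (B,D)

    # masked softmax over visits (shift by the running max for stability)
    shift = np.max(
        np.concatenate([e.data for e in e_list], axis=1), axis=1, keepdims=True
    )
    exps = [
        (e - shift).exp() * mask[:, ti : ti + 1] for ti, e in enumerate(e_list)
    ]
    denom = exps[0]
    for ex in exps[1:]:
        denom = denom + ex
    denom = denom + 1e-12

    ctx = Tensor(np.zeros((b, cfg.embedding_dim)))
    for ti in range(t):
        alpha = exps[ti] / denom
        ctx = ctx + alpha * beta_list[ti] * v_steps[ti]
    return (ctx @ params["Wo"] + params["bo"]).reshape(b)


_FORWARD = {"RNN": _rnn_logits, "TLSTM": _tlstm_logits, "RETAIN": _retain_logits}


# --------------------------------------------------------------------------
# training / prediction / evaluation
# --------------------------------------------------------------------------

def _neural_predict(model: FittedModel, samples: list[EncodedSequence],
                    chunk: int = 512) -> np.ndarray:
    out = np.empty(len(samples))
    fwd = _FORWARD[model.model_kind]
    with no_grad():
        for lo in range(0, len(samples), chunk):
            part = samples[lo : lo + chunk]
            nonempty = [s for s in part if s.length > 0]
            if nonempty:
                x, dt, mask = _pad_batch(nonempty, model.vocab_size)
                probs = sigmoid(fwd(x, dt, mask, model.params, model.config).data)
            it = iter(probs if nonempty else [])
            for j, s in enumerate(part):
                out[lo + j] = next(it) if s.length > 0 else model.base_rate
    return out


def predict_proba(model: FittedModel, samples: list[EncodedSequence]) -> np.ndarray:
    """Batched 90-day outcome probabilities."""
    if model.model_kind == "LR":
        coef, intercept = model.params["coef"], model.params["intercept"]
        x = np.stack([presence_bag(s, model.vocab_size) for s in samples])
        return sigmoid(x @ coef + intercept)
    return _neural_predict(model, samples)


def predict_risk(model: FittedModel, sample: EncodedSequence) -> float:
    """Outcome probability for one sample; an empty sequence falls back to
    the training base rate (logged)."""
    if sample.length == 0 and model.model_kind != "LR":
        log.warning("empty sequence for patient %s: returning base rate",
                    sample.patient_id)
    return float(predict_proba(model, [sample])[0])


def _check_two_classes(samples: list[EncodedSequence], name: str) -> np.ndarray:
    y = np.array([s.label for s in samples])
    if len(samples) == 0 or len(np.unique(y)) < 2:
        raise ValueError(f"{name} split must contain both classes")
    return y


def _max_f1_threshold(y: np.ndarray, p: np.ndarray) -> float:
    prec, rec, thr = precision_recall_curve(y, p)
    f1 = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec + 1e-300), 0.0)
    best = int(np.argmax(f1[:-1])) if len(thr) else 0
    return float(thr[best]) if len(thr) else 0.5


def train(
    kind: str,
    train_samples: list[EncodedSequence],
    val_samples: list[EncodedSequence],
    config: ModelConfig,
    vocab_size: int,
) -> FittedModel:
    """Fit one model family with early stopping on validation AUROC."""
    y_train = _check_two_classes(train_samples, "training")
    y_val = _check_two_classes(val_samples, "validation")
    base_rate = float(y_train.mean())

    if kind == "LR":
        x = np.stack([presence_bag(s, vocab_size) for s in train_samples])
        clf = LogisticRegression(max_iter=2000, solver="lbfgs")
        clf.fit(x, y_train)
        model = FittedModel(
            "LR", config, vocab_size,
            {"coef": clf.coef_.ravel().astype(np.float64),
             "intercept": float(clf.intercept_[0])},
            stopped_epoch=1, base_rate=base_rate,
        )
        p_val = predict_proba(model, val_samples)
        model.history = [float(roc_auc_score(y_val, p_val))]
        model.threshold = _max_f1_threshold(y_val, p_val)
        return model

    if kind not in _FORWARD:
        raise ValueError(f"unknown model kind {kind!r}")
    rng = np.random.default_rng(config.seed)
    params = _init_params(kind, vocab_size, config, rng)
    model = FittedModel(kind, config, vocab_size, params, base_rate=base_rate)
    opt = Adam(list(params.values()), lr=config.learning_rate,
               weight_decay=config.weight_decay)
    fwd = _FORWARD[kind]

    trainable = [s for s in train_samples if s.length > 0]
    y_tr = np.array([s.label for s in trainable], dtype=np.float64)
    best_auc, best_params, wait = -np.inf, None, 0

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(trainable))
        for lo in range(0, len(order), config.batch_size):
            sel = order[lo : lo + config.batch_size]
            batch = [trainable[i] for i in sel]
            x, dt, mask = _pad_batch(batch, vocab_size)
            drop = None
            if config.dropout > 0:
                keep = 1.0 - config.dropout
                drop = (rng.random((x.shape[0] * x.shape[1],
                                    config.embedding_dim)) < keep) / keep
            logits = fwd(x, dt, mask, params, config, drop_mask=drop)
            loss = bce_with_logits(logits, y_tr[sel])
            opt.zero_grad()
            loss.backward()
            opt.step()

        p_val = _neural_predict(model, val_samples)
        auc = float(roc_auc_score(y_val, p_val))
        model.history.append(auc)
        model.stopped_epoch = epoch
        if auc > best_auc + 1e-6:
            best_auc, wait = auc, 0
            best_params = {k: v.data.copy() for k, v in params.items()}
        else:
            wait += 1
            if wait >= config.patience:
                break

    if best_params is not None:
        for k, v in params.items():
            v.data = best_params[k]
    p_val = _neural_predict(model, val_samples)
    model.threshold = _max_f1_threshold(y_val, p_val)
    return model


def evaluate(model: FittedModel, test_samples: list[EncodedSequence]) -> EvalReport:
    """AUROC (rank statistic, tie-aware) plus precision/recall/F1 at the
    threshold frozen on the validation split."""
    y = _check_two_classes(test_samples, "test")
    p = predict_proba(model, test_samples)
    auroc = float(roc_auc_score(y, p))
    pred = (p >= model.threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return EvalReport(auroc, precision, recall, f1, model.threshold,
                      int(y.sum()), int((1 - y).sum()))


def save_model(model: FittedModel, path: str) -> None:
    """Checkpoint: parameter arrays in one .npz next to a JSON sidecar
    (model kind, config, vocabulary size, threshold)."""
    import dataclasses
    import json

    arrays = {
        k: (v.data if isinstance(v, Tensor) else np.asarray(v))
        for k, v in model.params.items()
    }
    np.savez(path, **arrays)
    sidecar = {
        "model_kind": model.model_kind,
        "config": dataclasses.asdict(model.config),
        "vocab_size": model.vocab_size,
        "threshold": model.threshold,
        "base_rate": model.base_rate,
        "stopped_epoch": model.stopped_epoch,
        "history": model.history,
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_model(path: str) -> FittedModel:
    import json

    with open(str(path) + ".json") as fh:
        meta = json.load(fh)
    npz = np.load(str(path))
    kind = meta["model_kind"]
    params: dict = {}
    for k in npz.files:
        arr = npz[k]
        if kind == "LR":
            params[k] = float(arr) if arr.ndim == 0 else arr
        else:
            params[k] = Tensor(arr, requires_grad=True)
    model = FittedModel(
        kind, ModelConfig(**meta["config"]), int(meta["vocab_size"]), params,
        history=list(meta["history"]), stopped_epoch=int(meta["stopped_epoch"]),
        threshold=float(meta["threshold"]), base_rate=float(meta["base_rate"]),
    )
    return model


def make_logistic_model(coef: np.ndarray, intercept: float,
                        config: ModelConfig | None = None) -> FittedModel:
    """Construct an LR model directly from known weights (closed-form and
    perturbation checks)."""
    coef = np.asarray(coef, dtype=np.float64)
    return FittedModel(
        "LR", config or ModelConfig(model_kind="LR"), coef.size,
        {"coef": coef, "intercept": float(intercept)}, stopped_epoch=1,
    )
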