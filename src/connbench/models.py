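"""The five benchmark classifiers behind one train/score/gradient contract.

Architectures (widths fixed by the benchmark definition; N = input features):

* ``svm``    — RBF-kernel support vector machine (scikit-learn), bandwidth
  ``gamma='scale'``, regularization C tuned on the validation set; scores are
  a logistic (Platt-style) squashing of decision values fitted on training data.
* ``fcn``    — fully connected net N-500-30-2, dropout 0.5 after both hidden
  layers, softmax cross-entropy.
* ``ae_fcn`` — autoencoder N-300-150-300-N trained jointly with a classifier
  head that consumes the reconstruction (N-300-16-2); loss = MSE + CE with
  unit weights.
* ``gcn``    — transductive Chebyshev graph convolution over the population
  graph, channels N-128-128-2, loss masked to training nodes.
* ``ev_gcn`` — edge-variational GCN: trainable PAE population graph (sex+site),
  edge dropout during training, four 16-channel Chebyshev layers whose outputs
  are concatenated (64 = 16 x 4) and fed to an MLP 64-256-2.

All neural models train full-batch with Adam and pick their iteration count by
validation accuracy over a checkpoint grid.  ``class_scores`` rows always sum
to one; ``input_gradient`` returns the gradient of the requested class's
pre-softmax logit with respect to the input features (the saliency target used
by SmoothGrad), and is checked against finite differences in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .autodiff import Adam, Tensor, concat, cross_entropy, softmax
from .graphs import PAE, edge_dropout

__all__ = [
    "ModelSpec",
    "default_spec",
    "cheb_gconv",
    "train_svm",
    "train_fcn",
    "train_ae_fcn",
    "train_gcn",
    "train_ev_gcn",
    "train_model",
    "save_model",
    "load_model",
    "ARCHITECTURES",
]

ARCHITECTURES = ("svm", "fcn", "ae_fcn", "gcn", "ev_gcn")


@dataclass(frozen=True)
class ModelSpec:
    architecture: str
    input_dim: int
    dropout: float = 0.5
    cheb_k: int = 3
    lr: float = 1e-3
    weight_decay: float = 5e-4
    max_epochs: int = 300
    eval_every: int = 10
    C_grid: tuple = (0.1, 1.0, 10.0)
    edge_dropout_rate: float = 0.3
    pae_embed_dim: int = 8
    ce_weight: float = 1.0  # AE-FCN: weight of the classification loss
    head_on_bottleneck: bool = False  # AE-FCN variant: classify the 150-d code
    seed: int = 0

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.input_dim < 1:
            raise ValueError("input_dim must be positive")


def default_spec(architecture: str, input_dim: int, seed: int = 0, **overrides) -> ModelSpec:
    """Per-architecture defaults (graph models use a larger learning rate)."""
    base = dict(architecture=architecture, input_dim=input_dim, seed=seed)
    if architecture in ("gcn", "ev_gcn"):
        base["lr"] = 5e-3
        base["dropout"] = 0.0
    spec = ModelSpec(**base)
    return replace(spec, **overrides) if overrides else spec


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------


class _Linear:
    def __init__(self, fan_in: int, fan_out: int, rng: np.random.Generator):
        s = np.sqrt(6.0 / (fan_in + fan_out))
        self.W = Tensor(rng.uniform(-s, s, size=(fan_in, fan_out)), requires_grad=True)
        self.b = Tensor(np.zeros(fan_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    @property
    def params(self):
        return [self.W, self.b]


def _dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or rate == 0:
        return x
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)


def _cheb_terms(L: Tensor | np.ndarray, X: Tensor, K: int) -> list[Tensor]:
    """[T_0(L)X, ..., T_{K-1}(L)X] via the Chebyshev recursion on X directly."""
    Lt = L if isinstance(L, Tensor) else Tensor(L)
    terms = [X]
    if K > 1:
        terms.append(Lt @ X)
    for _ in range(2, K):
        terms.append(2.0 * (Lt @ terms[-1]) - terms[-2])
    return terms


class _ChebLayer:
    def __init__(self, fan_in: int, fan_out: int, K: int, rng: np.random.Generator):
        s = np.sqrt(6.0 / (fan_in * K + fan_out))
        self.W = [
            Tensor(rng.uniform(-s, s, size=(fan_in, fan_out)), requires_grad=True)
            for _ in range(K)
        ]
        self.b = Tensor(np.zeros(fan_out), requires_grad=True)
        self.K = K

    def __call__(self, L, X: Tensor) -> Tensor:
        terms = _cheb_terms(L, X, self.K)
        out = terms[0] @ self.W[0]
        for k in range(1, self.K):
            out = out + terms[k] @ self.W[k]
        return out + self.b

    @property
    def params(self):
        return list(self.W) + [self.b]


def cheb_gconv(X: np.ndarray, L_tilde: np.ndarray, W: list[np.ndarray], K: int) -> np.ndarray:
    """Reference Chebyshev graph convolution: sum_k T_k(L~) X W_k (no bias)."""
    if K < 1 or len(W) != K:
        raise ValueError("need one weight matrix per Chebyshev order")
    X = np.asarray(X, dtype=float)
    L_tilde = np.asarray(L_tilde, dtype=float)
    if L_tilde.shape[0] != X.shape[0]:
        raise ValueError("graph size and node-feature rows disagree")
    terms = [X]
    if K > 1:
        terms.append(L_tilde @ X)
    for _ in range(2, K):
        terms.append(2.0 * L_tilde @ terms[-1] - terms[-2])
    return sum(t @ w for t, w in zip(terms, W))


def _check_finite_loss(loss: Tensor, epoch: int, architecture: str):
    if not np.isfinite(loss.data):
        raise RuntimeError(
            f"{architecture} training diverged: non-finite loss {loss.data!r} at epoch {epoch}"
        )


def _accuracy(scores: np.ndarray, y: np.ndarray) -> float:
    return float((scores.argmax(axis=1) == y).mean())


@dataclass
class TrainingHistory:
    """Validation accuracy (and optional extra-set scores) per checkpoint epoch."""

    epochs: list[int] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    extra_scores: dict[str, list[np.ndarray]] = field(default_factory=dict)

    def record(self, epoch: int, val_acc: float, extras: dict[str, np.ndarray]):
        self.epochs.append(epoch)
        self.val_acc.append(val_acc)
        for name, scores in extras.items():
            self.extra_scores.setdefault(name, []).append(scores)

    def scores_at(self, name: str, epoch: int) -> np.ndarray:
        return self.extra_scores[name][self.epochs.index(epoch)]

    @property
    def best_epoch(self) -> int:
        return self.epochs[int(np.argmax(self.val_acc))]


# ---------------------------------------------------------------------------
# inductive classifiers (svm, fcn, ae_fcn)
# ---------------------------------------------------------------------------


class TrainedClassifier:
    """Common contract: probability-like class scores and input gradients."""

    architecture: str
    is_transductive = False

    def class_scores(self, X: np.ndarray) -> np.ndarray:  # (m, 2), rows sum to 1
        raise NotImplementedError

    def input_gradient(self, x: np.ndarray, cls: int) -> np.ndarray:
        raise NotImplementedError

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.class_scores(X).argmax(axis=1)


class SVMClassifier(TrainedClassifier):
    architecture = "svm"

    def __init__(self, svc: SVC, platt: LogisticRegression, C: float):
        self._svc = svc
        self._platt = platt
        self.C = C
        self.selected = {"C": C}

    def class_scores(self, X: np.ndarray) -> np.ndarray:
        d = self._svc.decision_function(np.asarray(X, dtype=float))
        p1 = self._platt.predict_proba(d.reshape(-1, 1))[:, 1]
        return np.column_stack([1.0 - p1, p1])

    def input_gradient(self, x, cls):
        raise NotImplementedError(
            "the kernel SVM does not expose input gradients; saliency analysis "
            "supports the differentiable architectures only"
        )


def train_svm(
    X: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> SVMClassifier:
    """RBF-kernel SVM; C picked by validation accuracy over ``spec.C_grid``."""
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    best = None
    for C in spec.C_grid:
        svc = SVC(kernel="rbf", gamma="scale", C=C)
        svc.fit(X, y)
        acc = (
            float((svc.predict(X_val) == y_val).mean())
            if X_val is not None
            else float((svc.predict(X) == y).mean())
        )
        if best is None or acc > best[0]:
            best = (acc, C, svc)
    _, C, svc = best
    d_train = svc.decision_function(X).reshape(-1, 1)
    platt = LogisticRegression(C=1e6)
    platt.fit(d_train, y)
    return SVMClassifier(svc, platt, C)


class _NetClassifier(TrainedClassifier):
    """Shared scoring/gradient logic for the feed-forward nets."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.selected: dict = {}

    def _logits(self, x: Tensor) -> Tensor:
        raise NotImplementedError

    def class_scores(self, X: np.ndarray) -> np.ndarray:
        return softmax(self._logits(Tensor(np.atleast_2d(np.asarray(X, dtype=float))))).data

    def input_gradient(self, x: np.ndarray, cls: int) -> np.ndarray:
        xt = Tensor(np.asarray(x, dtype=float).reshape(1, -1), requires_grad=True)
        logit = self._logits(xt)[0, int(cls)]
        logit.backward()
        return xt.grad.ravel()


class FCNClassifier(_NetClassifier):
    architecture = "fcn"

    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        super().__init__(spec)
        self.l1 = _Linear(spec.input_dim, 500, rng)
        self.l2 = _Linear(500, 30, rng)
        self.l3 = _Linear(30, 2, rng)

    @property
    def params(self):
        return self.l1.params + self.l2.params + self.l3.params

    def forward(self, x: Tensor, training=False, rng=None) -> Tensor:
        h = _dropout(self.l1(x).relu(), self.spec.dropout, rng, training)
        h = _dropout(self.l2(h).relu(), self.spec.dropout, rng, training)
        return self.l3(h)

    _logits = forward


class AEFCNClassifier(_NetClassifier):
    architecture = "ae_fcn"

    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        super().__init__(spec)
        N = spec.input_dim
        self.enc1 = _Linear(N, 300, rng)
        self.enc2 = _Linear(300, 150, rng)
        self.dec1 = _Linear(150, 300, rng)
        self.dec2 = _Linear(300, N, rng)
        head_in = 150 if spec.head_on_bottleneck else N
        self.cls1 = _Linear(head_in, 300, rng)
        self.cls2 = _Linear(300, 16, rng)
        self.cls3 = _Linear(16, 2, rng)

    @property
    def params(self):
        layers = [self.enc1, self.enc2, self.dec1, self.dec2, self.cls1, self.cls2, self.cls3]
        return [p for l in layers for p in l.params]

    def forward(self, x: Tensor, training=False, rng=None):
        code = self.enc2(self.enc1(x).relu()).relu()
        recon = self.dec2(self.dec1(code).relu())
        head_in = code if self.spec.head_on_bottleneck else recon
        h = _dropout(self.cls1(head_in).relu(), self.spec.dropout, rng, training)
        h = _dropout(self.cls2(h).relu(), self.spec.dropout, rng, training)
        return recon, self.cls3(h)

    def _logits(self, x: Tensor) -> Tensor:
        return self.forward(x)[1]

    def loss(self, x: Tensor, y: np.ndarray, training=False, rng=None) -> Tensor:
        recon, logits = self.forward(x, training=training, rng=rng)
        mse = ((recon - x) ** 2).mean()
        return mse + self.spec.ce_weight * cross_entropy(logits, y)


def _train_feedforward(model, X, y, spec, X_val, y_val, extra_eval, loss_fn):
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(spec.seed + 1)
    opt = Adam(model.params, lr=spec.lr, weight_decay=spec.weight_decay)
    Xt = Tensor(np.asarray(X, dtype=float))
    history = TrainingHistory()
    best = (-np.inf, 0, None)
    for epoch in range(1, spec.max_epochs + 1):
        loss = loss_fn(model, Xt, y, rng)
        _check_finite_loss(loss, epoch, spec.architecture)
        opt.zero_grad()
        loss.backward()
        opt.step()
        if epoch % spec.eval_every == 0 or epoch == spec.max_epochs:
            val_acc = (
                _accuracy(model.class_scores(X_val), np.asarray(y_val, dtype=int))
                if X_val is not None
                else _accuracy(model.class_scores(X), y)
            )
            extras = {
                name: model.class_scores(Xe) for name, Xe in (extra_eval or {}).items()
            }
            history.record(epoch, val_acc, extras)
            if val_acc > best[0]:
                best = (val_acc, epoch, [p.data.copy() for p in model.params])
    if best[2] is not None:
        for p, snap in zip(model.params, best[2]):
            p.data = snap
    model.selected = {"epochs": best[1], "val_acc": best[0]}
    model.history = history
    return model


def train_fcn(X, y, spec: ModelSpec, X_val=None, y_val=None, extra_eval=None) -> FCNClassifier:
    model = FCNClassifier(spec, np.random.default_rng(spec.seed))

    def loss_fn(m, Xt, yy, rng):
        return cross_entropy(m.forward(Xt, training=True, rng=rng), yy)

    return _train_feedforward(model, X, y, spec, X_val, y_val, extra_eval, loss_fn)


def train_ae_fcn(X, y, spec: ModelSpec, X_val=None, y_val=None, extra_eval=None) -> AEFCNClassifier:
    model = AEFCNClassifier(spec, np.random.default_rng(spec.seed))

    def loss_fn(m, Xt, yy, rng):
        return m.loss(Xt, yy, training=True, rng=rng)

    return _train_feedforward(model, X, y, spec, X_val, y_val, extra_eval, loss_fn)


# ---------------------------------------------------------------------------
# transductive classifiers (gcn, ev_gcn)
# ---------------------------------------------------------------------------


class _TransductiveClassifier(TrainedClassifier):
    is_transductive = True

    def __init__(self, spec: ModelSpec, X_all: np.ndarray):
        self.spec = spec
        self.X_all = np.asarray(X_all, dtype=float)
        self.selected: dict = {}
        self._cache = None

    def _forward_all(self, X: Tensor) -> Tensor:
        raise NotImplementedError

    def all_scores(self) -> np.ndarray:
        if self._cache is None:
            logits = self._forward_all(Tensor(self.X_all))
            self._cache = softmax(logits).data
        return self._cache

    def class_scores(self, node_ids) -> np.ndarray:
        return self.all_scores()[np.asarray(node_ids, dtype=int)]

    def input_gradient(self, node_id: int, cls: int, row_override=None) -> np.ndarray:
        """d logit[node, cls] / d x_node with the population graph held fixed."""
        X = self.X_all.copy()
        if row_override is not None:
            X[node_id] = row_override
        Xt = Tensor(X, requires_grad=True)
        logit = self._forward_all(Xt)[int(node_id), int(cls)]
        logit.backward()
        return Xt.grad[int(node_id)].copy()


class GCNClassifier(_TransductiveClassifier):
    architecture = "gcn"

    def __init__(self, spec: ModelSpec, L_tilde: np.ndarray, X_all, rng):
        super().__init__(spec, X_all)
        self.L_tilde = np.asarray(L_tilde, dtype=float)
        K = spec.cheb_k
        self.g1 = _ChebLayer(spec.input_dim, 128, K, rng)
        self.g2 = _ChebLayer(128, 128, K, rng)
        self.g3 = _ChebLayer(128, 2, K, rng)

    @property
    def params(self):
        return self.g1.params + self.g2.params + self.g3.params

    def _forward_all(self, X: Tensor) -> Tensor:
        h = self.g1(self.L_tilde, X).relu()
        h = self.g2(self.L_tilde, h).relu()
        return self.g3(self.L_tilde, h)


class EVGCNClassifier(_TransductiveClassifier):
    architecture = "ev_gcn"

    def __init__(self, spec: ModelSpec, pheno: np.ndarray, X_all, rng):
        super().__init__(spec, X_all)
        self.pheno = np.asarray(pheno, dtype=float)
        self.pae = PAE(self.pheno.shape[1], embed_dim=spec.pae_embed_dim, seed=spec.seed)
        K = spec.cheb_k
        self.gcs = [
            _ChebLayer(spec.input_dim, 16, K, rng),
            _ChebLayer(16, 16, K, rng),
            _ChebLayer(16, 16, K, rng),
            _ChebLayer(16, 16, K, rng),
        ]
        self.mlp1 = _Linear(64, 256, rng)
        self.mlp2 = _Linear(256, 2, rng)
        self.train_pae = True

    @property
    def params(self):
        ps = [p for g in self.gcs for p in g.params] + self.mlp1.params + self.mlp2.params
        if self.train_pae:
            ps += self.pae.params
        return ps

    @staticmethod
    def _laplacian_from_weights(W: Tensor, mask: np.ndarray | None = None) -> Tensor:
        """Differentiable L~ = -D^-1/2 W D^-1/2 (lambda_max = 2 bound)."""
        if mask is not None:
            W = W * Tensor(mask)
        deg = W.sum(axis=1) + 1e-8
        inv = deg ** (-0.5)
        n = W.shape[0]
        return -(W * inv.reshape(n, 1) * inv.reshape(1, n))

    def _forward_from(self, X: Tensor, L: Tensor) -> Tensor:
        outs = []
        h = X
        for g in self.gcs:
            h = g(L, h).relu()
            outs.append(h)
        fused = concat(outs, axis=1)  # n x 64
        return self.mlp2(self.mlp1(fused).relu())

    def _forward_all(self, X: Tensor) -> Tensor:
        W = Tensor(self.pae.weights(self.pheno).data)  # graph fixed at evaluation
        return self._forward_from(X, self._laplacian_from_weights(W))

    def training_forward(self, X: Tensor, drop_seed: int) -> Tensor:
        W = self.pae.weights(self.pheno)
        _, mask = edge_dropout(
            np.ones_like(W.data), self.spec.edge_dropout_rate, seed=drop_seed
        )
        return self._forward_from(X, self._laplacian_from_weights(W, mask))


def _check_masks(masks: dict, n: int):
    for a in ("train", "val", "test"):
        if a not in masks:
            raise ValueError(f"missing mask {a!r}")
    m = np.zeros(n, dtype=int)
    for a in ("train", "val", "test"):
        m[np.asarray(masks[a], dtype=int)] += 1
    if m.max() > 1:
        raise ValueError("train/val/test masks overlap")


def _train_transductive(model, y, masks, spec, extra_eval):
    y = np.asarray(y, dtype=int)
    n = model.X_all.shape[0]
    _check_masks(masks, n)
    tr = np.asarray(masks["train"], dtype=int)
    va = np.asarray(masks["val"], dtype=int)
    w = np.zeros(n)
    w[tr] = 1.0
    y_loss = np.where(w > 0, y, 0)  # labels outside the loss mask are never read
    opt = Adam(model.params, lr=spec.lr, weight_decay=spec.weight_decay)
    Xt = Tensor(model.X_all)
    history = TrainingHistory()
    best = (-np.inf, 0, None)
    for epoch in range(1, spec.max_epochs + 1):
        if isinstance(model, EVGCNClassifier):
            logits = model.training_forward(Xt, drop_seed=spec.seed + 7919 * epoch)
        else:
            logits = model._forward_all(Xt)
        loss = cross_entropy(logits, y_loss, sample_weight=w)
        _check_finite_loss(loss, epoch, spec.architecture)
        opt.zero_grad()
        loss.backward()
        opt.step()
        if epoch % spec.eval_every == 0 or epoch == spec.max_epochs:
            model._cache = None
            scores = model.all_scores()
            val_acc = _accuracy(scores[va], y[va])
            extras = {name: scores[np.asarray(ids, dtype=int)] for name, ids in (extra_eval or {}).items()}
            history.record(epoch, val_acc, extras)
            if val_acc > best[0]:
                best = (val_acc, epoch, [p.data.copy() for p in model.params])
    if best[2] is not None:
        for p, snap in zip(model.params, best[2]):
            p.data = snap
    model._cache = None
    model.selected = {"epochs": best[1], "val_acc": best[0]}
    model.history = history
    return model


def train_gcn(X_all, L_tilde, y, masks, spec: ModelSpec, extra_eval=None) -> GCNClassifier:
    model = GCNClassifier(spec, L_tilde, X_all, np.random.default_rng(spec.seed))
    return _train_transductive(model, y, masks, spec, extra_eval)


def train_ev_gcn(X_all, pheno, y, masks, spec: ModelSpec, extra_eval=None) -> EVGCNClassifier:
    model = EVGCNClassifier(spec, pheno, X_all, np.random.default_rng(spec.seed))
    return _train_transductive(model, y, masks, spec, extra_eval)


def _checkpoint_params(model) -> list[Tensor]:
    if isinstance(model, EVGCNClassifier):
        return (
            [p for g in model.gcs for p in g.params]
            + model.mlp1.params
            + model.mlp2.params
            + model.pae.params
        )
    return model.params


def save_model(model, path) -> None:
    """Serialize a neural classifier checkpoint: spec + seed + weights.

    The kernel SVM is cheap to refit and is not serialized.
    """
    import json
    from dataclasses import asdict

    if isinstance(model, SVMClassifier):
        raise NotImplementedError("SVM checkpoints are not serialized; refit instead")
    meta = {
        "architecture": model.architecture,
        "spec": asdict(model.spec),
        "selected": getattr(model, "selected", {}),
    }
    arrays = {f"param_{i}": p.data for i, p in enumerate(_checkpoint_params(model))}
    if isinstance(model, GCNClassifier):
        arrays["L_tilde"] = model.L_tilde
    if isinstance(model, _TransductiveClassifier):
        arrays["X_all"] = model.X_all
    if isinstance(model, EVGCNClassifier):
        arrays["pheno"] = model.pheno
    np.savez(path, meta=np.array(json.dumps(meta)), **arrays)


def load_model(path):
    """Reconstruct a serialized neural classifier bit-identically."""
    import json

    with np.load(path, allow_pickle=False) as blob:
        meta = json.loads(str(blob["meta"]))
        spec_dict = meta["spec"]
        spec_dict["C_grid"] = tuple(spec_dict["C_grid"])
        spec = ModelSpec(**spec_dict)
        rng = np.random.default_rng(spec.seed)
        arch = meta["architecture"]
        if arch == "fcn":
            model = FCNClassifier(spec, rng)
        elif arch == "ae_fcn":
            model = AEFCNClassifier(spec, rng)
        elif arch == "gcn":
            model = GCNClassifier(spec, blob["L_tilde"], blob["X_all"], rng)
        elif arch == "ev_gcn":
            model = EVGCNClassifier(spec, blob["pheno"], blob["X_all"], rng)
        else:
            raise ValueError(f"cannot load architecture {arch!r}")
        for i, p in enumerate(_checkpoint_params(model)):
            p.data = blob[f"param_{i}"]
    model.selected = dict(meta["selected"])
    return model


def train_model(architecture: str, **kwargs):
    """Dispatch helper used by the evaluation pipelines."""
    trainers = {
        "svm": train_svm,
        "fcn": train_fcn,
        "ae_fcn": train_ae_fcn,
        "gcn": train_gcn,
        "ev_gcn": train_ev_gcn,
    }
    return trainers[architecture](**kwargs)
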