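"""Scoring models for triple-association prediction.

Three estimators complete the binary drug x gene x disease tensor:

* :class:`GTDTripleClassifier` — generalized tensor decomposition.  Each
  entity gets an r-dimensional latent vector (a_i, b_j, c_k) produced by
  an affine fusion of its learned ID embedding with its similarity row;
  the score of a cell is sigma(h . (a_i * b_j * c_k)) with a learned
  output-weight vector h.  With sigma = identity and h = 1 this is
  exactly CP decomposition.

* :class:`MLPTripleClassifier` — the same fused latents are refined
  independently per role by a tower-shaped multi-layer perceptron
  (widths shrinking upward) before the element-wise product and head.

* :class:`EnsembleTripleClassifier` — runs both paths with separate
  parameters and concatenates their interaction vectors in front of a
  single shared output layer (NeuMF-style merge), so both paths keep
  their own gradients.

All three follow the scikit-learn estimator protocol (``fit`` /
``predict_proba`` / ``get_params``) over an (n, 3) integer array of
(drug, gene, disease) index triples and binary labels.
"""

from __future__ import annotations

import copy

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from ._nn import ACTIVATIONS, Adam, Dense, Embedding, bce_loss_and_grad, sigmoid

ROLE_AXES = {"drug": 0, "gene": 1, "disease": 2}


# ---------------------------------------------------------------------------
# Functional forms (pure, used directly by tests and by the estimators)


def fuse_features(id_embedding, similarity_row, weight, bias, activation="relu"):
    """Affine map of concat(id embedding, similarity row) to rank dimensions."""
    x = np.concatenate([np.asarray(id_embedding, float), np.asarray(similarity_row, float)])
    if weight.shape[0] != x.size:
        raise ValueError(f"fusion weight expects input {weight.shape[0]}, got {x.size}")
    return ACTIVATIONS[activation](x @ weight + bias)


def gtd_score(a, b, c, h, activation="sigmoid"):
    """sigma(h . (a * b * c)) for equal-length latent vectors."""
    a, b, c, h = (np.asarray(v, float) for v in (a, b, c, h))
    if not (a.shape == b.shape == c.shape == h.shape):
        raise ValueError("gtd_score requires equal-length a, b, c, h")
    return float(ACTIVATIONS[activation](np.array(h @ (a * b * c))))


def cp_reconstruct(A, B, C):
    """Full-tensor CP reconstruction x_ijk = sum_r A_ir B_jr C_kr.

    This is the degenerate GTD with identity activation and h = 1.
    """
    return np.einsum("ir,jr,kr->ijk", A, B, C)


def mlp_forward(layers, z0):
    """Apply a tower of (W, b, activation) layers to ``z0``."""
    z = np.asarray(z0, float)
    for W, b, act in layers:
        if z.shape[-1] != W.shape[0]:
            raise ValueError(f"tower layer expects width {W.shape[0]}, got {z.shape[-1]}")
        z = ACTIVATIONS[act](z @ W + b)
    return z


def mlp_score(towers, a, b, c, h, activation="sigmoid"):
    """sigma(h . (phi_dr(a) * phi_ge(b) * phi_di(c)))."""
    za, zb, zc = (mlp_forward(t, v) for t, v in zip(towers, (a, b, c)))
    return gtd_score(za, zb, zc, h, activation)


def ensemble_score(gtd_latents, mlp_latents, towers, h, activation="sigmoid"):
    """sigma(h' . concat(a_G*b_G*c_G, phi_dr(a_M)*phi_ge(b_M)*phi_di(c_M)))."""
    ag, bg, cg = (np.asarray(v, float) for v in gtd_latents)
    u_g = ag * bg * cg
    za, zb, zc = (mlp_forward(t, v) for t, v in zip(towers, mlp_latents))
    u_m = za * zb * zc
    u = np.concatenate([u_g, u_m])
    h = np.asarray(h, float)
    if h.shape != u.shape:
        raise ValueError("ensemble head length must equal r + final tower width")
    return float(ACTIVATIONS[activation](np.array(h @ u)))


# ---------------------------------------------------------------------------
# Internal differentiable network blocks


class _FusionBlock:
    """Per-role ID embedding + affine fusion to the shared rank."""

    def __init__(self, shape, sims, rank, activation, rng):
        self.sims = sims  # list of (n_role, n_role) arrays or None
        self.embeddings = [Embedding(n, rank, rng) for n in shape]
        self.fusions = [
            Dense(rank + (s.shape[1] if s is not None else 0), rank, activation, rng)
            for n, s in zip(shape, sims)
        ]

    def forward(self, idx):
        lats = []
        for axis in range(3):
            e = self.embeddings[axis].forward(idx[:, axis])
            s = self.sims[axis]
            x = e if s is None else np.concatenate([e, s[idx[:, axis]]], axis=1)
            lats.append(self.fusions[axis].forward(x))
        return lats

    def latents(self, axis, n):
        """Fused latent vectors for all entities of one role."""
        idx = np.arange(n)
        e = self.embeddings[axis].E[idx]
        s = self.sims[axis]
        x = e if s is None else np.concatenate([e, s[idx]], axis=1)
        pre = x @ self.fusions[axis].W + self.fusions[axis].b
        return ACTIVATIONS[self.fusions[axis].activation](pre)

    def backward(self, dlats):
        for axis in range(3):
            dx = self.fusions[axis].backward(dlats[axis])
            d_emb = dx[:, : self.embeddings[axis].E.shape[1]]
            self.embeddings[axis].backward(d_emb)

    def parameters(self):
        out = []
        for m in (*self.embeddings, *self.fusions):
            out.extend(m.parameters())
        return out


class _GTDNet:
    def __init__(self, shape, sims, rank, fusion_activation, rng):
        self.fusion = _FusionBlock(shape, sims, rank, fusion_activation, rng)
        self.head = Dense(rank, 1, "identity", rng, bias=False)

    def forward(self, idx):
        self._lats = self.fusion.forward(idx)
        a, b, c = self._lats
        self._u = a * b * c
        return self.head.forward(self._u)[:, 0]

    def backward(self, dlogit):
        du = self.head.backward(dlogit[:, None])
        a, b, c = self._lats
        self.fusion.backward([du * b * c, du * a * c, du * a * b])

    def parameters(self):
        return self.fusion.parameters() + self.head.parameters()


def _make_tower(rank, widths, rng):
    """Dense stack; ReLU on hidden layers, linear output layer."""
    layers, n_in = [], rank
    for li, w in enumerate(widths):
        act = "identity" if li == len(widths) - 1 else "relu"
        layers.append(Dense(n_in, w, act, rng))
        n_in = w
    return layers


def _tower_forward(tower, z):
    for layer in tower:
        z = layer.forward(z)
    return z


def _tower_backward(tower, dz):
    for layer in reversed(tower):
        dz = layer.backward(dz)
    return dz


class _MLPNet:
    def __init__(self, shape, sims, rank, widths, fusion_activation, rng):
        self.fusion = _FusionBlock(shape, sims, rank, fusion_activation, rng)
        self.towers = [_make_tower(rank, widths, rng) for _ in range(3)]
        self.head = Dense(widths[-1], 1, "identity", rng, bias=False)

    def forward(self, idx):
        self._lats = self.fusion.forward(idx)
        self._z = [_tower_forward(t, v) for t, v in zip(self.towers, self._lats)]
        za, zb, zc = self._z
        self._u = za * zb * zc
        return self.head.forward(self._u)[:, 0]

    def backward(self, dlogit):
        du = self.head.backward(dlogit[:, None])
        za, zb, zc = self._z
        dz = [du * zb * zc, du * za * zc, du * za * zb]
        dlats = [_tower_backward(t, d) for t, d in zip(self.towers, dz)]
        self.fusion.backward(dlats)

    def parameters(self):
        out = self.fusion.parameters()
        for t in self.towers:
            for layer in t:
                out.extend(layer.parameters())
        return out + self.head.parameters()


class _EnsembleNet:
    """GTD and MLP paths with separate parameters; interaction vectors
    concatenated before one shared output layer."""

    def __init__(self, shape, sims, rank, widths, fusion_activation, rng, share_fusion=False):
        self.fusion_g = _FusionBlock(shape, sims, rank, fusion_activation, rng)
        self.fusion_m = (
            self.fusion_g
            if share_fusion
            else _FusionBlock(shape, sims, rank, fusion_activation, rng)
        )
        self.share_fusion = share_fusion
        self.towers = [_make_tower(rank, widths, rng) for _ in range(3)]
        self.head = Dense(rank + widths[-1], 1, "identity", rng, bias=False)
        self.rank = rank

    def forward(self, idx):
        self._lg = self.fusion_g.forward(idx)
        self._lm = self.fusion_m.forward(idx)
        ag, bg, cg = self._lg
        self._z = [_tower_forward(t, v) for t, v in zip(self.towers, self._lm)]
        za, zb, zc = self._z
        self._u = np.concatenate([ag * bg * cg, za * zb * zc], axis=1)
        return self.head.forward(self._u)[:, 0]

    def backward(self, dlogit):
        du = self.head.backward(dlogit[:, None])
        du_g, du_m = du[:, : self.rank], du[:, self.rank:]
        ag, bg, cg = self._lg
        za, zb, zc = self._z
        dz = [du_m * zb * zc, du_m * za * zc, du_m * za * zb]
        dlm = [_tower_backward(t, d) for t, d in zip(self.towers, dz)]
        dlg = [du_g * bg * cg, du_g * ag * cg, du_g * ag * bg]
        if self.share_fusion:
            self.fusion_g.backward([x + y for x, y in zip(dlg, dlm)])
        else:
            self.fusion_g.backward(dlg)
            self.fusion_m.backward(dlm)

    def parameters(self):
        out = self.fusion_g.parameters()
        if not self.share_fusion:
            out += self.fusion_m.parameters()
        for t in self.towers:
            for layer in t:
                out.extend(layer.parameters())
        return out + self.head.parameters()


# ---------------------------------------------------------------------------
# Estimators


class _BaseTripleClassifier(BaseEstimator, ClassifierMixin):
    """Shared fit loop: Adam on binary cross-entropy with optional
    early stopping on validation AUC."""

    def __init__(
        self,
        rank=8,
        similarities=None,
        shape=None,
        learning_rate=1e-3,
        max_epochs=200,
        patience=10,
        min_epochs=50,
        batch_size=256,
        fusion_activation="relu",
        random_state=None,
    ):
        self.rank = rank
        self.similarities = similarities
        self.shape = shape
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.min_epochs = min_epochs
        self.batch_size = batch_size
        self.fusion_activation = fusion_activation
        self.random_state = random_state

    # subclasses build the differentiable network
    def _build(self, shape, sims, rng):  # pragma: no cover - abstract
        raise NotImplementedError

    def _resolve_shape(self, X):
        if self.shape is not None:
            return tuple(self.shape)
        if self.similarities:
            return tuple(
                np.asarray(self.similarities[r]).shape[0]
                for r in ("drug", "gene", "disease")
            )
        return tuple(int(X[:, a].max()) + 1 for a in range(3))

    def _sim_list(self, shape):
        sims = []
        for role, n in zip(("drug", "gene", "disease"), shape):
            s = (self.similarities or {}).get(role)
            if s is not None:
                s = np.asarray(s, float)
                if s.shape != (n, n):
                    raise ValueError(f"{role} similarity shape {s.shape} != ({n}, {n})")
            sims.append(s)
        return sims

    @staticmethod
    def _check_X(X):
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("X must be an (n, 3) array of (drug, gene, disease) indices")
        return X.astype(np.int64)

    def fit(self, X, y, validation_data=None):
        from .evaluation import auc as _auc

        X = self._check_X(X)
        y = np.asarray(y, float).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("labels must be binary")
        shape = self._resolve_shape(X)
        if X.size and (X.max(axis=0) >= np.array(shape)).any():
            raise ValueError("triple index outside tensor shape")

        rng = np.random.default_rng(self.random_state)
        net = self._build(shape, self._sim_list(shape), rng)
        opt = Adam(net.parameters(), lr=self.learning_rate)

        n = X.shape[0]
        history = {"loss": [], "val_auc": []}
        best_auc, best_state, best_epoch, bad = -np.inf, None, 0, 0
        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                sel = order[start : start + self.batch_size]
                p = sigmoid(net.forward(X[sel]))
                loss, dlogit = bce_loss_and_grad(p, y[sel])
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}: {loss!r}"
                    )
                opt.zero_grad()
                net.backward(dlogit)
                opt.step()
                epoch_loss += loss * len(sel)
            history["loss"].append(epoch_loss / n)

            if validation_data is not None:
                Xv, yv = validation_data
                pv = sigmoid(net.forward(self._check_X(Xv)))
                va = _auc(np.asarray(yv).ravel(), pv)
                history["val_auc"].append(va)
                if va > best_auc + 1e-12:
                    best_auc, bad, best_epoch = va, 0, epoch
                    best_state = copy.deepcopy([p for p, _ in net.parameters()])
                else:
                    bad += 1
                    # a warm-up window lets the model escape the early
                    # transient where validation AUC dips below random
                    if bad >= self.patience and epoch + 1 >= self.min_epochs:
                        break

        if best_state is not None:
            for (p, _), saved in zip(net.parameters(), best_state):
                p[...] = saved

        self.net_ = net
        self.shape_ = shape
        self.history_ = history
        self.n_epochs_ = len(history["loss"])
        self.best_epoch_ = best_epoch if validation_data is not None else None
        self.classes_ = np.array([0, 1])
        return self

    def decision_function(self, X):
        check_is_fitted(self, "net_")
        return self.net_.forward(self._check_X(X))

    def predict_proba(self, X):
        p = sigmoid(self.decision_function(X))
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def score_tensor(self):
        """Predicted probabilities for every cell (use on small tensors)."""
        check_is_fitted(self, "net_")
        I, J, K = self.shape_
        grid = np.stack(np.meshgrid(np.arange(I), np.arange(J), np.arange(K), indexing="ij"), -1)
        return sigmoid(self.net_.forward(grid.reshape(-1, 3))).reshape(I, J, K)


class GTDTripleClassifier(_BaseTripleClassifier):
    """Generalized tensor decomposition: sigma(h . (a_i * b_j * c_k))."""

    def _build(self, shape, sims, rng):
        return _GTDNet(shape, sims, self.rank, self.fusion_activation, rng)

    def latent_vectors(self, role):
        """Fused r-dimensional latents for all entities of ``role``."""
        check_is_fitted(self, "net_")
        axis = ROLE_AXES[role]
        return self.net_.fusion.latents(axis, self.shape_[axis])

    def head_weights(self):
        """Learned output-weight vector h over latent dimensions."""
        check_is_fitted(self, "net_")
        return self.net_.head.W[:, 0].copy()


class MLPTripleClassifier(_BaseTripleClassifier):
    """Per-role tower MLP over fused latents; widths shrink upward
    (default [2r, r, r // 2])."""

    def __init__(
        self,
        rank=8,
        tower_widths=None,
        similarities=None,
        shape=None,
        learning_rate=1e-3,
        max_epochs=200,
        patience=10,
        min_epochs=50,
        batch_size=256,
        fusion_activation="relu",
        random_state=None,
    ):
        super().__init__(
            rank=rank,
            similarities=similarities,
            shape=shape,
            learning_rate=learning_rate,
            max_epochs=max_epochs,
            patience=patience,
            min_epochs=min_epochs,
            batch_size=batch_size,
            fusion_activation=fusion_activation,
            random_state=random_state,
        )
        self.tower_widths = tower_widths

    def _widths(self):
        if self.tower_widths is not None:
            w = list(self.tower_widths)
            if any(a < b for a, b in zip(w, w[1:])):
                raise ValueError("tower widths must be non-increasing")
            return w
        r = self.rank
        return [2 * r, r, max(1, r // 2)]

    def _build(self, shape, sims, rng):
        return _MLPNet(shape, sims, self.rank, self._widths(), self.fusion_activation, rng)

    def latent_vectors(self, role):
        """Tower outputs for all entities of ``role``."""
        check_is_fitted(self, "net_")
        axis = ROLE_AXES[role]
        z = self.net_.fusion.latents(axis, self.shape_[axis])
        return mlp_forward(
            [(l.W, l.b, l.activation) for l in self.net_.towers[axis]], z
        )

    def head_weights(self):
        """Learned output-weight vector h over tower-output dimensions."""
        check_is_fitted(self, "net_")
        return self.net_.head.W[:, 0].copy()


class EnsembleTripleClassifier(MLPTripleClassifier):
    """GTD + MLP ensemble: both interaction vectors concatenated before a
    single learned output weight vector of length r + final tower width."""

    def __init__(
        self,
        rank=8,
        tower_widths=None,
        share_fusion=False,
        similarities=None,
        shape=None,
        learning_rate=1e-3,
        max_epochs=200,
        patience=10,
        min_epochs=50,
        batch_size=256,
        fusion_activation="relu",
        random_state=None,
    ):
        super().__init__(
            rank=rank,
            tower_widths=tower_widths,
            similarities=similarities,
            shape=shape,
            learning_rate=learning_rate,
            max_epochs=max_epochs,
            patience=patience,
            min_epochs=min_epochs,
            batch_size=batch_size,
            fusion_activation=fusion_activation,
            random_state=random_state,
        )
        self.share_fusion = share_fusion

    def _build(self, shape, sims, rng):
        return _EnsembleNet(
            shape, sims, self.rank, self._widths(), self.fusion_activation, rng,
            share_fusion=self.share_fusion,
        )

    def latent_vectors(self, role, path="both"):
        """Per-entity latents: GTD-path fused vectors, MLP-path tower
        outputs, or their concatenation (default)."""
        check_is_fitted(self, "net_")
        axis = ROLE_AXES[role]
        n = self.shape_[axis]
        lg = self.net_.fusion_g.latents(axis, n)
        lm = mlp_forward(
            [(l.W, l.b, l.activation) for l in self.net_.towers[axis]],
            self.net_.fusion_m.latents(axis, n),
        )
        if path == "gtd":
            return lg
        if path == "mlp":
            return lm
        if path == "both":
            return np.concatenate([lg, lm], axis=1)
        raise ValueError(f"unknown path {path!r}")

    def head_weights(self, path="both"):
        """Learned output weights over the concatenated interaction
        vector, sliceable per path to match :meth:`latent_vectors`."""
        check_is_fitted(self, "net_")
        h = self.net_.head.W[:, 0]
        if path == "gtd":
            return h[: self.rank].copy()
        if path == "mlp":
            return h[self.rank:].copy()
        if path == "both":
            return h.copy()
        raise ValueError(f"unknown path {path!r}")


MODEL_REGISTRY = {
    "gtd": GTDTripleClassifier,
    "mlp": MLPTripleClassifier,
    "ensemble": EnsembleTripleClassifier,
}
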