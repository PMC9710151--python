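"""A compact neural-network backend with per-layer freezing.

Implements exactly what the transfer models need: fully-connected layers and
single-feature-per-step recurrent layers (GRU, LSTM, bidirectional LSTM),
trained with Adam on a softmax cross-entropy loss, with a boolean trainable
mask per weight-bearing layer.  Frozen layers receive no gradient updates,
so their weights stay bit-identical through fine-tuning — the property the
freeze-plan machinery relies on and the tests assert exactly.

Everything is NumPy; training is deterministic given the seed.  Gradients of
every layer are validated against numerical differentiation in the test
suite.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _glorot(rng, shape, dtype):
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    """Base class; subclasses hold ``params`` and ``grads`` dicts."""

    is_recurrent = False

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def param_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def zero_grads(self):
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def spec(self) -> dict:
        raise NotImplementedError


class Dense(Layer):
    """Fully connected layer, optional ReLU."""

    def __init__(self, n_in: int, n_out: int, activation: str = "relu",
                 rng=None, dtype=np.float32):
        super().__init__()
        self.n_in, self.n_out, self.activation = n_in, n_out, activation
        rng = rng or np.random.default_rng(0)
        self.params = {"W": _glorot(rng, (n_in, n_out), dtype),
                       "b": np.zeros(n_out, dtype=dtype)}

    def forward(self, x, train=False):
        self._x = x if train else None
        z = x @ self.params["W"] + self.params["b"]
        if self.activation == "relu":
            z = np.maximum(z, 0.0)
        if train:
            self._z = z
        return z

    def backward(self, dout):
        if self.activation == "relu":
            dout = dout * (self._z > 0)
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T

    def spec(self):
        return {"kind": "dense", "n_in": self.n_in, "n_out": self.n_out,
                "activation": self.activation}


class GRU(Layer):
    """Gated recurrent unit over (batch, T, n_in) inputs.

    Gate order in the stacked parameter matrices is (update z, reset r,
    candidate h).
    """

    is_recurrent = True

    def __init__(self, n_in: int, n_hidden: int, return_sequences: bool = False,
                 rng=None, dtype=np.float32):
        super().__init__()
        self.n_in, self.n_hidden = n_in, n_hidden
        self.return_sequences = return_sequences
        rng = rng or np.random.default_rng(0)
        h = n_hidden
        self.params = {
            "W": _glorot(rng, (n_in, 3 * h), dtype),
            "U": _glorot(rng, (h, 3 * h), dtype),
            "b": np.zeros(3 * h, dtype=dtype),
        }

    def forward(self, x, train=False):
        B, T, _ = x.shape
        h = self.n_hidden
        W, U, b = self.params["W"], self.params["U"], self.params["b"]
        xp = x.reshape(B * T, -1) @ W
        xp = (xp + b).reshape(B, T, 3 * h)
        hs = np.zeros((B, T + 1, h), dtype=x.dtype)
        cache = [] if train else None
        for t in range(T):
            h_prev = hs[:, t]
            rec = h_prev @ U
            z = _sigmoid(xp[:, t, :h] + rec[:, :h])
            r = _sigmoid(xp[:, t, h:2 * h] + rec[:, h:2 * h])
            rh = r * h_prev
            hh = np.tanh(xp[:, t, 2 * h:] + rh @ U[:, 2 * h:])
            hs[:, t + 1] = (1 - z) * h_prev + z * hh
            if train:
                cache.append((z, r, hh, rh))
        if train:
            self._cache = (x, xp, hs, cache)
        return hs[:, 1:] if self.return_sequences else hs[:, -1]

    def backward(self, dout):
        x, xp, hs, cache = self._cache
        B, T, _ = x.shape
        h = self.n_hidden
        W, U = self.params["W"], self.params["U"]
        dW = np.zeros_like(W)
        dU = np.zeros_like(U)
        db = np.zeros_like(self.params["b"])
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, h), dtype=x.dtype)
        for t in range(T - 1, -1, -1):
            dh = dh_next + (dout[:, t] if self.return_sequences else 0)
            if not self.return_sequences and t == T - 1:
                dh = dh_next + dout
            z, r, hh, rh = cache[t]
            h_prev = hs[:, t]
            dz = dh * (hh - h_prev)
            dhh = dh * z
            dah = dhh * (1 - hh**2)
            d_rh = dah @ U[:, 2 * h:].T
            dr = d_rh * h_prev
            daz = dz * z * (1 - z)
            dar = dr * r * (1 - r)
            da = np.concatenate([daz, dar, dah], axis=1)
            dW += x[:, t].T @ da
            db += da.sum(axis=0)
            dU[:, :2 * h] += h_prev.T @ np.concatenate([daz, dar], axis=1)
            dU[:, 2 * h:] += rh.T @ dah
            dx[:, t] = da @ W.T
            dh_next = (dh * (1 - z) + d_rh * r
                       + daz @ U[:, :h].T + dar @ U[:, h:2 * h].T)
        self.grads = {"W": dW, "U": dU, "b": db}
        return dx

    def spec(self):
        return {"kind": "gru", "n_in": self.n_in, "n_hidden": self.n_hidden,
                "return_sequences": self.return_sequences}


class LSTM(Layer):
    """LSTM over (batch, T, n_in) inputs; gate order (i, f, o, g)."""

    is_recurrent = True

    def __init__(self, n_in: int, n_hidden: int, return_sequences: bool = False,
                 rng=None, dtype=np.float32):
        super().__init__()
        self.n_in, self.n_hidden = n_in, n_hidden
        self.return_sequences = return_sequences
        rng = rng or np.random.default_rng(0)
        h = n_hidden
        b = np.zeros(4 * h, dtype=dtype)
        b[h:2 * h] = 1.0  # forget-gate bias init
        self.params = {
            "W": _glorot(rng, (n_in, 4 * h), dtype),
            "U": _glorot(rng, (h, 4 * h), dtype),
            "b": b,
        }

    def forward(self, x, train=False):
        B, T, _ = x.shape
        h = self.n_hidden
        W, U, b = self.params["W"], self.params["U"], self.params["b"]
        xp = (x.reshape(B * T, -1) @ W + b).reshape(B, T, 4 * h)
        hs = np.zeros((B, T + 1, h), dtype=x.dtype)
        cs = np.zeros((B, T + 1, h), dtype=x.dtype)
        cache = [] if train else None
        for t in range(T):
            a = xp[:, t] + hs[:, t] @ U
            i = _sigmoid(a[:, :h])
            f = _sigmoid(a[:, h:2 * h])
            o = _sigmoid(a[:, 2 * h:3 * h])
            g = np.tanh(a[:, 3 * h:])
            cs[:, t + 1] = f * cs[:, t] + i * g
            tc = np.tanh(cs[:, t + 1])
            hs[:, t + 1] = o * tc
            if train:
                cache.append((i, f, o, g, tc))
        if train:
            self._cache = (x, hs, cs, cache)
        return hs[:, 1:] if self.return_sequences else hs[:, -1]

    def backward(self, dout):
        x, hs, cs, cache = self._cache
        B, T, _ = x.shape
        h = self.n_hidden
        W, U = self.params["W"], self.params["U"]
        dW = np.zeros_like(W)
        dU = np.zeros_like(U)
        db = np.zeros_like(self.params["b"])
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, h), dtype=x.dtype)
        dc_next = np.zeros((B, h), dtype=x.dtype)
        for t in range(T - 1, -1, -1):
            dh = dh_next.copy()
            if self.return_sequences:
                dh += dout[:, t]
            elif t == T - 1:
                dh += dout
            i, f, o, g, tc = cache[t]
            do = dh * tc
            dc = dc_next + dh * o * (1 - tc**2)
            di = dc * g
            df = dc * cs[:, t]
            dg = dc * i
            dc_next = dc * f
            da = np.concatenate([
                di * i * (1 - i), df * f * (1 - f), do * o * (1 - o),
                dg * (1 - g**2)], axis=1)
            dW += x[:, t].T @ da
            dU += hs[:, t].T @ da
            db += da.sum(axis=0)
            dx[:, t] = da @ W.T
            dh_next = da @ U.T
        self.grads = {"W": dW, "U": dU, "b": db}
        return dx

    def spec(self):
        return {"kind": "lstm", "n_in": self.n_in, "n_hidden": self.n_hidden,
                "return_sequences": self.return_sequences}


class BiLSTM(Layer):
    """Bidirectional LSTM: forward + reversed-sequence LSTM, outputs concatenated.

    Output width is ``2 * n_hidden``; with ``return_sequences=False`` the
    final forward state is concatenated with the final backward state (the
    one that has read the whole sequence right-to-left).
    """

    is_recurrent = True

    def __init__(self, n_in: int, n_hidden: int, return_sequences: bool = False,
                 rng=None, dtype=np.float32):
        super().__init__()
        self.n_in, self.n_hidden = n_in, n_hidden
        self.return_sequences = return_sequences
        rng = rng or np.random.default_rng(0)
        self.fwd = LSTM(n_in, n_hidden, return_sequences=True, rng=rng, dtype=dtype)
        self.bwd = LSTM(n_in, n_hidden, return_sequences=True, rng=rng, dtype=dtype)

    @property
    def params(self):
        out = {f"fwd_{k}": v for k, v in self.fwd.params.items()}
        out.update({f"bwd_{k}": v for k, v in self.bwd.params.items()})
        return out

    @params.setter
    def params(self, value):
        if value:  # base-class __init__ assigns {}
            for k, v in value.items():
                side, name = k.split("_", 1)
                getattr(self, side).params[name] = v

    @property
    def grads(self):
        out = {f"fwd_{k}": v for k, v in self.fwd.grads.items()}
        out.update({f"bwd_{k}": v for k, v in self.bwd.grads.items()})
        return out

    @grads.setter
    def grads(self, value):
        pass  # grads live on the two sub-layers

    def forward(self, x, train=False):
        hf = self.fwd.forward(x, train=train)                    # (B,T,h)
        hb = self.bwd.forward(x[:, ::-1], train=train)[:, ::-1]  # re-aligned
        if self.return_sequences:
            return np.concatenate([hf, hb], axis=2)
        return np.concatenate([hf[:, -1], hb[:, 0]], axis=1)

    def backward(self, dout):
        h = self.n_hidden
        B = dout.shape[0]
        if self.return_sequences:
            df, db_ = dout[..., :h], dout[..., h:]
        else:
            T = self.fwd._cache[0].shape[1]
            df = np.zeros((B, T, h), dtype=dout.dtype)
            db_ = np.zeros((B, T, h), dtype=dout.dtype)
            df[:, -1] = dout[:, :h]
            db_[:, 0] = dout[:, h:]
        dx = self.fwd.backward(df)
        dx += self.bwd.backward(db_[:, ::-1])[:, ::-1]
        return dx

    def spec(self):
        return {"kind": "bilstm", "n_in": self.n_in, "n_hidden": self.n_hidden,
                "return_sequences": self.return_sequences}


_LAYER_KINDS = {"dense": Dense, "gru": GRU, "lstm": LSTM, "bilstm": BiLSTM}


def layer_from_spec(spec: dict, rng=None, dtype=np.float32) -> Layer:
    kwargs = {k: v for k, v in spec.items() if k != "kind"}
    return _LAYER_KINDS[spec["kind"]](rng=rng, dtype=dtype, **kwargs)


def softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SequentialNet:
    """A stack of layers trained with Adam on softmax cross-entropy.

    The final layer emits logits (one per class); a recurrent first layer
    receives the feature vector reshaped to a (batch, n_features, 1)
    sequence.  ``trainable`` is a boolean mask over layers; frozen layers are
    skipped by the optimizer entirely, so their weights never change.
    """

    def __init__(self, layers: list[Layer]):
        self.layers = layers
        self.trainable = [True] * len(layers)
        self._adam_state: dict = {}

    # -- structure ---------------------------------------------------------

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def param_count(self) -> int:
        return sum(l.param_count() for l in self.layers)

    def set_trainable(self, mask: list[bool]) -> None:
        if len(mask) != len(self.layers):
            raise ValueError(
                f"mask length {len(mask)} != number of layers {len(self.layers)}")
        self.trainable = [bool(m) for m in mask]

    def get_weights(self) -> list[dict[str, np.ndarray]]:
        return [{k: v.copy() for k, v in l.params.items()} for l in self.layers]

    def set_weights(self, weights) -> None:
        for layer, w in zip(self.layers, weights):
            for k in layer.params:
                np.copyto(layer.params[k], w[k])

    def copy(self) -> "SequentialNet":
        clone = SequentialNet([layer_from_spec(l.spec(),
                                               dtype=next(iter(l.params.values())).dtype)
                               for l in self.layers])
        clone.set_weights(self.get_weights())
        return clone

    # -- forward / predict -------------------------------------------------

    def _shape_input(self, X):
        X = np.asarray(X, dtype=next(iter(self.layers[0].params.values())).dtype)
        if self.layers[0].is_recurrent and X.ndim == 2:
            X = X[:, :, None]
        return X

    def forward(self, X, train=False):
        out = self._shape_input(X)
        for layer in self.layers:
            out = layer.forward(out, train=train)
        return out

    def predict_proba(self, X) -> np.ndarray:
        return softmax(self.forward(X, train=False))

    def predict(self, X) -> np.ndarray:
        return self.forward(X, train=False).argmax(axis=1)

    # -- training ----------------------------------------------------------

    def _adam_step(self, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self._t = getattr(self, "_t", 0) + 1
        t = self._t
        for li, layer in enumerate(self.layers):
            if not self.trainable[li]:
                continue
            for name, g in layer.grads.items():
                key = (li, name)
                if key not in self._adam_state:
                    self._adam_state[key] = (np.zeros_like(g), np.zeros_like(g))
                m, v = self._adam_state[key]
                m = beta1 * m + (1 - beta1) * g
                v = beta2 * v + (1 - beta2) * g * g
                self._adam_state[key] = (m, v)
                mhat = m / (1 - beta1**t)
                vhat = v / (1 - beta2**t)
                p = layer.params[name] if not isinstance(layer, BiLSTM) else None
                update = (lr * mhat / (np.sqrt(vhat) + eps)).astype(g.dtype)
                if isinstance(layer, BiLSTM):
                    side, pname = name.split("_", 1)
                    getattr(layer, side).params[pname] -= update
                else:
                    p -= update

    def loss_and_grad(self, X, y_onehot):
        logits = self.forward(X, train=True)
        probs = softmax(logits)
        n = X.shape[0]
        loss = -np.log(np.clip(probs[np.arange(n), y_onehot.argmax(axis=1)],
                               1e-12, None)).mean()
        dlogits = (probs - y_onehot) / n
        dout = dlogits.astype(logits.dtype)
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return loss

    def fit(
        self,
        X,
        y,
        epochs: int = 50,
        batch_size: int = 32,
        lr: float = 1e-3,
        seed: int = 0,
        X_val=None,
        y_val=None,
    ) -> dict:
        """Mini-batch Adam training; deterministic given ``seed``.

        ``epochs=0`` leaves every weight untouched.  Returns a history dict
        with per-epoch training loss and (if given) validation accuracy.
        """
        y = np.asarray(y)
        n_classes = self.layers[-1].params["b"].shape[0] \
            if not isinstance(self.layers[-1], BiLSTM) else 2
        onehot = np.eye(n_classes, dtype=np.float64)[y]
        rng = np.random.default_rng(seed)
        n = len(y)
        history = {"loss": [], "val_accuracy": []}
        for _ in range(epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                losses.append(self.loss_and_grad(X[idx], onehot[idx]))
                self._adam_step(lr)
            history["loss"].append(float(np.mean(losses)))
            if X_val is not None:
                history["val_accuracy"].append(
                    float(100.0 * np.mean(self.predict(X_val) == np.asarray(y_val))))
        return history

    # -- persistence (runtime checkpoints) ----------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arch = [l.spec() for l in self.layers]
        arrays = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.params.items():
                arrays[f"layer{i}__{k}"] = v
        np.savez(path.with_suffix(".npz"), **arrays)
        path.with_suffix(".json").write_text(json.dumps(arch))

    @classmethod
    def load(cls, path: str | Path) -> "SequentialNet":
        path = Path(path)
        arch = json.loads(path.with_suffix(".json").read_text())
        data = np.load(path.with_suffix(".npz"))
        net = cls([layer_from_spec(s) for s in arch])
        for i, layer in enumerate(net.layers):
            w = {k: data[f"layer{i}__{k}"] for k in layer.params}
            if isinstance(layer, BiLSTM):
                layer.params = w
            else:
                layer.params.update(w)
        return net
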