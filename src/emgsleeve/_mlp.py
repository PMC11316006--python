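"""Minimal feed-forward network used by the gesture decoder.

Fully connected layers with batch normalization, ReLU and inverted
dropout, trained with Adam under a one-cycle learning-rate policy.  Two
heads are supported: a softmax classifier with label-smoothing
cross-entropy, and a linear regressor with mean-squared-error loss whose
predictions are truncated to per-target training bounds.  Everything is
plain numpy, seeded through one generator, so training is deterministic
given (data, seed).  Training runs in float32 for speed; inference runs
in float64 one layer at a time, so batched and row-by-row (streaming)
prediction agree to numerical precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FittingError

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1
_DTYPE = np.float32


class _Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        # He initialization (ReLU network)
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)).astype(_DTYPE)
        self.b = np.zeros(n_out, dtype=_DTYPE)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.gw = self._x.T @ g
        self.gb = g.sum(axis=0)
        return g @ self.w.T

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]


class _BatchNorm:
    def __init__(self, n: int):
        self.gamma = np.ones(n, dtype=_DTYPE)
        self.beta = np.zeros(n, dtype=_DTYPE)
        self.run_mean = np.zeros(n, dtype=_DTYPE)
        self.run_var = np.ones(n, dtype=_DTYPE)
        self.ggamma = np.zeros(n, dtype=_DTYPE)
        self.gbeta = np.zeros(n, dtype=_DTYPE)

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=0)
        var = x.var(axis=0)
        self.run_mean = ((1 - _BN_MOMENTUM) * self.run_mean + _BN_MOMENTUM * mu).astype(_DTYPE)
        self.run_var = ((1 - _BN_MOMENTUM) * self.run_var + _BN_MOMENTUM * var).astype(_DTYPE)
        self._istd = 1.0 / np.sqrt(var + _BN_EPS)
        self._xhat = (x - mu) * self._istd
        return self.gamma * self._xhat + self.beta

    def backward(self, g: np.ndarray) -> np.ndarray:
        n = g.shape[0]
        self.ggamma = (g * self._xhat).sum(axis=0)
        self.gbeta = g.sum(axis=0)
        gx = self.gamma * g
        return self._istd / n * (
            n * gx - gx.sum(axis=0) - self._xhat * (gx * self._xhat).sum(axis=0)
        )

    def params(self):
        return [(self.gamma, self.ggamma), (self.beta, self.gbeta)]


def one_cycle_lr(
    step: int, total_steps: int, lr_max: float, pct_start: float = 0.3,
    div_start: float = 25.0, div_final: float = 1e4,
) -> float:
    """Cosine one-cycle: warm up to lr_max, then anneal far below it."""
    t = step / max(total_steps - 1, 1)
    lr0, lr_end = lr_max / div_start, lr_max / div_final
    if t < pct_start:
        p = t / pct_start
        return lr0 + (lr_max - lr0) * 0.5 * (1 - np.cos(np.pi * p))
    p = (t - pct_start) / max(1 - pct_start, 1e-12)
    return lr_max + (lr_end - lr_max) * 0.5 * (1 - np.cos(np.pi * p))


@dataclass
class TrainingCurve:
    loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)


class MLP:
    """Stack of [Linear -> BatchNorm -> ReLU -> Dropout] blocks + linear head."""

    def __init__(
        self,
        n_in: int,
        hidden: tuple[int, ...],
        n_out: int,
        dropout: float,
        seed: int,
        task: str,  # "classify" | "regress"
        label_smoothing: float = 0.1,
    ):
        if not 0 <= dropout < 1:
            raise FittingError("dropout must be in [0, 1)")
        self.rng = np.random.default_rng(seed)
        self.dropout = dropout
        self.task = task
        self.label_smoothing = label_smoothing
        self.linears: list[_Linear] = []
        self.bns: list[_BatchNorm] = []
        last = n_in
        for h in hidden:
            self.linears.append(_Linear(last, h, self.rng))
            self.bns.append(_BatchNorm(h))
            last = h
        self.head = _Linear(last, n_out, self.rng)
        self.out_lo: np.ndarray | None = None  # regression truncation bounds
        self.out_hi: np.ndarray | None = None
        self.curves: list[TrainingCurve] = []

    # -- training-mode forward/backward ------------------------------------

    def _forward_train(self, x: np.ndarray) -> np.ndarray:
        self._masks = []
        self._relu_masks = []
        for lin, bn in zip(self.linears, self.bns):
            x = bn.forward(lin.forward(x))
            x = np.maximum(x, 0.0)
            self._relu_masks.append(x > 0)
            if self.dropout > 0:
                m = (self.rng.random(x.shape, dtype=_DTYPE) >= self.dropout) / _DTYPE(
                    1 - self.dropout
                )
                x = x * m
                self._masks.append(m)
            else:
                self._masks.append(None)
        return self.head.forward(x)

    def _backward(self, gout: np.ndarray) -> None:
        g = self.head.backward(gout)
        for lin, bn, m, rm in zip(
            self.linears[::-1], self.bns[::-1], self._masks[::-1], self._relu_masks[::-1]
        ):
            if m is not None:
                g = g * m
            g = g * rm
            g = lin.backward(bn.backward(g))

    def _layers(self):
        return self.linears + self.bns + [self.head]

    # -- losses -------------------------------------------------------------

    @staticmethod
    def _softmax(z: np.ndarray) -> np.ndarray:
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def _loss_grad(self, out: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
        n = out.shape[0]
        if self.task == "classify":
            p = self._softmax(out)
            k = out.shape[1]
            eps = self.label_smoothing
            q = np.full_like(p, eps / k)
            q[np.arange(n), y] += 1.0 - eps
            loss = float(-(q * np.log(p + 1e-12)).sum() / n)
            return loss, ((p - q) / n).astype(_DTYPE)
        resid = out - y
        return float((resid**2).mean()), (2.0 * resid / resid.size).astype(_DTYPE)

    # -- training -----------------------------------------------------------

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int,
        lr_max: float = 1e-3,
        batch_size: int = 64,
    ) -> TrainingCurve:
        """One full one-cycle training run (call again to fine-tune)."""
        x = np.asarray(x, dtype=_DTYPE)
        n = x.shape[0]
        if n < 2:
            raise FittingError("need at least 2 training rows")
        if self.task == "regress":
            y = np.asarray(y, dtype=_DTYPE)
            self.out_lo = y.min(axis=0).astype(np.float64)
            self.out_hi = y.max(axis=0).astype(np.float64)
        m_state: dict[int, np.ndarray] = {}
        v_state: dict[int, np.ndarray] = {}
        scratch: dict[int, np.ndarray] = {}
        for layer in self._layers():
            for arr, _g in layer.params():
                m_state[id(arr)] = np.zeros_like(arr)
                v_state[id(arr)] = np.zeros_like(arr)
                scratch[id(arr)] = np.zeros_like(arr)
        steps_per_epoch = max(1, int(np.ceil(n / batch_size)))
        total = epochs * steps_per_epoch
        curve = TrainingCurve()
        step = 0
        t_adam = 0
        for _ep in range(epochs):
            order = self.rng.permutation(n)
            for s in range(steps_per_epoch):
                idx = order[s * batch_size : (s + 1) * batch_size]
                if len(idx) < 2:
                    continue  # batch norm needs >= 2 rows
                out = self._forward_train(x[idx])
                loss, g = self._loss_grad(out, y[idx])
                self._backward(g)
                lr = _DTYPE(one_cycle_lr(step, total, lr_max))
                t_adam += 1
                bc1 = _DTYPE(1 - 0.9**t_adam)
                bc2 = _DTYPE(1 - 0.999**t_adam)
                for layer in self._layers():
                    for arr, grad in layer.params():
                        # in-place Adam: gradients are consumed, scratch reused
                        mk, vk, s = m_state[id(arr)], v_state[id(arr)], scratch[id(arr)]
                        np.multiply(grad, grad, out=s)
                        vk *= _DTYPE(0.999)
                        s *= _DTYPE(0.001)
                        vk += s
                        mk *= _DTYPE(0.9)
                        grad *= _DTYPE(0.1)
                        mk += grad
                        np.divide(vk, bc2, out=s)
                        np.sqrt(s, out=s)
                        s += _DTYPE(1e-8)
                        np.divide(mk, s, out=s)
                        s *= lr / bc1
                        arr -= s
                curve.loss.append(loss)
                curve.lr.append(float(lr))
                step += 1
        self.curves.append(curve)
        return curve

    # -- inference (float64, batch-size independent) ------------------------

    def decision(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        for lin, bn in zip(self.linears, self.bns):
            x = x @ lin.w.astype(np.float64) + lin.b.astype(np.float64)
            xhat = (x - bn.run_mean.astype(np.float64)) / np.sqrt(
                bn.run_var.astype(np.float64) + _BN_EPS
            )
            x = np.maximum(
                bn.gamma.astype(np.float64) * xhat + bn.beta.astype(np.float64), 0.0
            )
        return x @ self.head.w.astype(np.float64) + self.head.b.astype(np.float64)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        if self.task != "classify":
            raise FittingError("predict_proba is for classifiers")
        return self._softmax(self.decision(x))

    def predict(self, x: np.ndarray) -> np.ndarray:
        out = self.decision(x)
        if self.task == "classify":
            return out.argmax(axis=1)
        return np.clip(out, self.out_lo, self.out_hi)

    def reinit_head(self, n_out: int) -> None:
        """Fresh output layer (class-set mismatch when fine-tuning)."""
        self.head = _Linear(self.head.w.shape[0], n_out, self.rng)
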