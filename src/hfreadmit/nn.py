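"""Minimal numpy implementation of the three-branch feed-forward classifier.

Architecture: each input block (timed state samples, demographics, severity
scores) feeds its own branch of fully-connected ReLU layers (three by
default); batch normalization follows the first hidden layer of each branch
and 20% dropout follows the first, second and third hidden layers.  Branch
outputs are concatenated, passed through one post-concatenation hidden
layer, and a 2-unit softmax produces the class probabilities.  Training
uses Adam on the categorical cross-entropy.

Everything is deterministic given the seed: initialization, shuffling and
dropout masks all draw from one ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ThreeBranchNet", "Adam"]


class Dense:
    def __init__(self, n_in, n_out, rng):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.dW = self._x.T @ g
        self.db = g.sum(axis=0)
        return g @ self.W.T

    def params(self):
        return [("W", self), ("b", self)]


class ReLU:
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask

    def params(self):
        return []


class BatchNorm:
    def __init__(self, n, momentum=0.1, eps=1e-5):
        self.gamma = np.ones(n)
        self.beta = np.zeros(n)
        self.run_mean = np.zeros(n)
        self.run_var = np.ones(n)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train):
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.run_mean = (1 - self.momentum) * self.run_mean + self.momentum * mu
            self.run_var = (1 - self.momentum) * self.run_var + self.momentum * var
        else:
            mu, var = self.run_mean, self.run_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mu) / self._std
        self._train_n = x.shape[0]
        return self.gamma * self._xhat + self.beta

    def backward(self, g):
        # standard batch-norm backward through the batch statistics
        n = self._train_n
        self.dgamma = (g * self._xhat).sum(axis=0)
        self.dbeta = g.sum(axis=0)
        gx = g * self.gamma
        return (
            gx - gx.mean(axis=0) - self._xhat * (gx * self._xhat).mean(axis=0)
        ) / self._std if n > 1 else gx / self._std

    def params(self):
        return [("gamma", self), ("beta", self)]


class Dropout:
    def __init__(self, rate, rng):
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask

    def params(self):
        return []


_GRAD_NAME = {"W": "dW", "b": "db", "gamma": "dgamma", "beta": "dbeta"}


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(getattr(layer, name)) for name, layer in params]
        self.v = [np.zeros_like(getattr(layer, name)) for name, layer in params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (name, layer) in enumerate(self.params):
            g = getattr(layer, _GRAD_NAME[name])
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            setattr(
                layer, name, getattr(layer, name) - self.lr * mhat / (np.sqrt(vhat) + self.eps)
            )


def _branch(n_in, sizes, dropout, rng):
    layers = []
    for i, n_out in enumerate(sizes):
        layers.append(Dense(n_in, n_out, rng))
        if i == 0:
            layers.append(BatchNorm(n_out))
        layers.append(ReLU())
        if i < 3:  # dropout after the first, second and third hidden layers
            layers.append(Dropout(dropout, rng))
        n_in = n_out
    return layers, n_in


class ThreeBranchNet:
    """Three parallel branches -> concatenation -> hidden layer(s) -> softmax."""

    def __init__(self, input_widths, branch_sizes=(128, 64, 32), post_size=64,
                 n_post_layers=1, dropout=0.2, seed=0):
        if any(w < 1 for w in input_widths):
            raise ValueError("all input widths must be >= 1")
        self.rng = np.random.default_rng(seed)
        self.input_widths = tuple(input_widths)
        self.branches = []
        concat = 0
        for w in input_widths:
            layers, out = _branch(w, branch_sizes, dropout, self.rng)
            self.branches.append(layers)
            concat += out
        self.post = []
        n_in = concat
        for _ in range(n_post_layers):
            self.post += [Dense(n_in, post_size, self.rng), ReLU()]
            n_in = post_size
        self.out = Dense(n_in, 2, self.rng)

    # -- forward / backward -------------------------------------------------
    def _forward(self, parts, train):
        outs = []
        for x, layers in zip(parts, self.branches):
            h = x
            for layer in layers:
                h = layer.forward(h, train)
            outs.append(h)
        self._splits = np.cumsum([o.shape[1] for o in outs])[:-1]
        h = np.concatenate(outs, axis=1)
        for layer in self.post:
            h = layer.forward(h, train)
        return self.out.forward(h, train)

    def _backward(self, g):
        g = self.out.backward(g)
        for layer in reversed(self.post):
            g = layer.backward(g)
        for gpart, layers in zip(np.split(g, self._splits, axis=1), self.branches):
            h = gpart
            for layer in reversed(layers):
                h = layer.backward(h)

    def predict_proba(self, parts):
        logits = self._forward(parts, train=False)
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def train_step(self, parts, y_onehot, optimizer):
        logits = self._forward(parts, train=True)
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        proba = e / e.sum(axis=1, keepdims=True)
        n = y_onehot.shape[0]
        loss = -np.log(np.clip((proba * y_onehot).sum(axis=1), 1e-12, None)).mean()
        self._backward((proba - y_onehot) / n)
        optimizer.step()
        return loss

    # -- parameter handling -------------------------------------------------
    def all_layers(self):
        return [l for branch in self.branches for l in branch] + self.post + [self.out]

    def parameters(self):
        return [p for layer in self.all_layers() for p in layer.params()]

    def get_state(self):
        state = []
        for layer in self.all_layers():
            for name, owner in layer.params():
                state.append(getattr(owner, name).copy())
            if isinstance(layer, BatchNorm):
                state += [layer.run_mean.copy(), layer.run_var.copy()]
        return state

    def set_state(self, state):
        it = iter(state)
        for layer in self.all_layers():
            for name, owner in layer.params():
                setattr(owner, name, next(it).copy())
            if isinstance(layer, BatchNorm):
                layer.run_mean = next(it).copy()
                layer.run_var = next(it).copy()
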