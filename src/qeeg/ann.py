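"""Small feedforward classifier trained by conjugate-gradient minimisation of
the squared output error.

The network has 1-3 sigmoidal hidden layers and a single sigmoid output unit
thresholded at 0.5 (outcomes coded SF = 1, NSF = 0).  Training runs
scipy's nonlinear conjugate gradient in short rounds with early stopping on a
held-out validation split (the weights with the lowest validation error are
kept).  Inputs are standardised with training-split statistics only.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class FeedforwardNet:
    """Fully connected sigmoid network with a flat parameter vector."""

    def __init__(self, n_inputs: int, hidden_sizes: list[int], seed=None):
        self.sizes = [n_inputs, *hidden_sizes, 1]
        rng = np.random.default_rng(seed)
        self._shapes = []
        params = []
        for fan_in, fan_out in zip(self.sizes[:-1], self.sizes[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            params.append(rng.uniform(-limit, limit, size=fan_in * fan_out))
            params.append(np.zeros(fan_out))
            self._shapes.append((fan_in, fan_out))
        self.params = np.concatenate(params)

    def _unpack(self, params: np.ndarray):
        weights, offset = [], 0
        for fan_in, fan_out in self._shapes:
            w = params[offset: offset + fan_in * fan_out].reshape(fan_in, fan_out)
            offset += fan_in * fan_out
            b = params[offset: offset + fan_out]
            offset += fan_out
            weights.append((w, b))
        return weights

    def forward(self, X: np.ndarray, params: np.ndarray | None = None) -> np.ndarray:
        a = X
        for w, b in self._unpack(self.params if params is None else params):
            a = _sigmoid(a @ w + b)
        return a[:, 0]

    def loss_grad(self, params: np.ndarray, X: np.ndarray, y: np.ndarray):
        """Mean squared output error and its gradient (backprop)."""
        weights = self._unpack(params)
        activations = [X]
        a = X
        for w, b in weights:
            a = _sigmoid(a @ w + b)
            activations.append(a)
        out = activations[-1][:, 0]
        n = X.shape[0]
        resid = out - y
        loss = float(np.mean(resid ** 2))

        grads = []
        delta = (2.0 / n) * resid[:, None] * (activations[-1] * (1 - activations[-1]))
        for layer in range(len(weights) - 1, -1, -1):
            w, _ = weights[layer]
            a_prev = activations[layer]
            gw = a_prev.T @ delta
            gb = delta.sum(axis=0)
            grads.append((gw, gb))
            if layer > 0:
                delta = (delta @ w.T) * activations[layer] * (1 - activations[layer])
        flat = []
        for gw, gb in reversed(grads):
            flat.append(gw.ravel())
            flat.append(gb)
        return loss, np.concatenate(flat)

    def mse(self, X: np.ndarray, y: np.ndarray, params=None) -> float:
        return float(np.mean((self.forward(X, params) - y) ** 2))


def train_network(
    net: FeedforwardNet,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    max_rounds: int = 60,
    iters_per_round: int = 5,
    patience: int = 6,
) -> FeedforwardNet:
    """Conjugate-gradient training with validation-based early stopping.

    CG runs in rounds of ``iters_per_round`` iterations; after each round the
    validation MSE is checked and the best parameters are retained.  Training
    stops after ``patience`` rounds without improvement, on CG convergence,
    or after ``max_rounds`` rounds.
    """
    params = net.params.copy()
    best_params = params.copy()
    best_val = net.mse(X_val, y_val, params)
    wait = 0
    for _ in range(max_rounds):
        res = optimize.minimize(
            net.loss_grad, params, args=(X_train, y_train),
            method="CG", jac=True, options={"maxiter": iters_per_round},
        )
        params = res.x
        val = net.mse(X_val, y_val, params)
        if val < best_val - 1e-9:
            best_val = val
            best_params = params.copy()
            wait = 0
        else:
            wait += 1
            if wait >= patience:
                break
        if res.success:  # CG converged on the training loss
            break
    net.params = best_params
    return net


# ---------------------------------------------------------------------------
# splitting / single training run
# ---------------------------------------------------------------------------

def stratified_split(y: np.ndarray, rng: np.random.Generator,
                     fractions=(0.70, 0.15, 0.15)):
    """Stratified random 70/15/15 split -> (train_idx, val_idx, test_idx).

    Each class is shuffled and allocated proportionally, which guarantees
    both classes appear in the training split whenever each has >= 2
    members."""
    y = np.asarray(y)
    train, val, test = [], [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n = idx.size
        n_train = max(1, int(round(fractions[0] * n)))
        n_val = int(round(fractions[1] * n))
        n_train = min(n_train, n)
        n_val = min(n_val, n - n_train)
        train.append(idx[:n_train])
        val.append(idx[n_train: n_train + n_val])
        test.append(idx[n_train + n_val:])
    train = np.concatenate(train)
    val = np.concatenate(val)
    test = np.concatenate(test)
    if test.size == 0 or val.size == 0:
        raise ValueError("cohort too small for a 70/15/15 split")
    return train, val, test


def _standardize(train: np.ndarray, *others):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return tuple(((a - mu) / sd) for a in (train, *others))


def confusion_matrix_2x2(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    """2x2 counts with rows = true (SF, NSF) and columns = predicted
    (SF, NSF)."""
    cm = np.zeros((2, 2))
    cm[0, 0] = np.sum((y_true == 1) & (y_pred == 1))  # TP
    cm[0, 1] = np.sum((y_true == 1) & (y_pred == 0))  # FN
    cm[1, 0] = np.sum((y_true == 0) & (y_pred == 1))  # FP
    cm[1, 1] = np.sum((y_true == 0) & (y_pred == 0))  # TN
    return cm


def train_once(X: np.ndarray, y: np.ndarray, sizes: list[int], seed,
               max_retries: int = 5):
    """One repetition: split, standardise, train, evaluate on the test split.

    Returns (confusion matrix, test MSE, trained net).  A degenerate split
    (training fold missing a class) is resampled a bounded number of times.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    ss = np.random.SeedSequence(seed)
    for attempt in range(max_retries):
        split_ss, init_ss = ss.spawn(2)
        rng = np.random.default_rng(split_ss)
        tr, va, te = stratified_split(y, rng)
        if len(np.unique(y[tr])) == 2:
            break
        ss = np.random.SeedSequence([seed, attempt + 1])
    else:
        raise ValueError("could not build a training split containing both classes")

    X_tr, X_va, X_te = _standardize(X[tr], X[va], X[te])
    net = FeedforwardNet(X.shape[1], list(sizes), seed=init_ss)
    train_network(net, X_tr, y[tr], X_va, y[va])
    out = net.forward(X_te)
    pred = (out >= 0.5).astype(int)
    cm = confusion_matrix_2x2(y[te].astype(int), pred)
    mse = float(np.mean((out - y[te]) ** 2))
    return cm, mse, net
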