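"""Small fully connected blocks (two hidden layers, Swish, He init) on the
autodiff Vars, with a flat parameter store keyed by name."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad


def swish(x: ad.Var) -> ad.Var:
    """x * sigmoid(x), numerically stable: the exponential is only ever
    taken of a non-positive argument."""
    m = x.data >= 0
    e = ad.exp(ad.where(m, ad.neg(x), x))     # exp(-|x|)
    return ad.where(m, ad.div(x, ad.add(e, 1.0)),
                    ad.div(ad.mul(x, e), ad.add(e, 1.0)))


class MLP:
    """Two-hidden-layer perceptron; parameters live in a shared dict."""

    def __init__(self, params: dict, name: str, n_in: int, hidden, n_out: int,
                 rng: np.random.Generator):
        self.name = name
        sizes = [n_in, *hidden, n_out]
        self.keys = []
        for k in range(len(sizes) - 1):
            wk, bk = f"{name}.W{k}", f"{name}.b{k}"
            # He initialization, appropriate for the Swish/ReLU family
            params[wk] = rng.normal(
                0.0, np.sqrt(2.0 / sizes[k]), (sizes[k], sizes[k + 1]))
            params[bk] = np.zeros(sizes[k + 1])
            self.keys.append((wk, bk))

    def __call__(self, x: ad.Var, p: dict) -> ad.Var:
        last = len(self.keys) - 1
        for k, (wk, bk) in enumerate(self.keys):
            x = ad.add(ad.dot(x, p[wk]), p[bk])
            if k != last:
                x = swish(x)
        return x
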