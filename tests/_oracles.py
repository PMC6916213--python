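"""Independent scalar-arithmetic oracles used only by the tests.

Everything here is written with plain Python loops over ``math`` scalars so
it shares no code path with the vectorized implementation it checks.
"""

from __future__ import annotations

import math


def scalar_sigmoid(z: float) -> float:
    return 1.0 / (1.0 + math.exp(-z))


def scalar_lstm_step(x_t, h_prev, c_prev, w):
    """One LSTM step, element by element.

    ``w`` is a dict with keys W_hi/W_hf/W_ho/W_hg (L x L nested lists),
    W_xi/W_xf/W_xo/W_xg (v x L), b_i/b_f/b_o/b_g (length-L lists).
    """
    L = len(h_prev)
    v = len(x_t)

    def gate(name_h, name_x, name_b, squash):
        out = []
        for j in range(L):
            z = w[name_b][j]
            for a in range(L):
                z += w[name_h][a][j] * h_prev[a]
            for a in range(v):
                z += w[name_x][a][j] * x_t[a]
            out.append(squash(z))
        return out

    i = gate("W_hi", "W_xi", "b_i", scalar_sigmoid)
    f = gate("W_hf", "W_xf", "b_f", scalar_sigmoid)
    o = gate("W_ho", "W_xo", "b_o", scalar_sigmoid)
    g = gate("W_hg", "W_xg", "b_g", math.tanh)
    c = [f[j] * c_prev[j] + i[j] * g[j] for j in range(L)]
    h = [o[j] * math.tanh(c[j]) for j in range(L)]
    return h, c


def scalar_lstm_forward(xs, w, L):
    """Iterated scalar steps from the zero state; returns the T x L hidden rows."""
    h = [0.0] * L
    c = [0.0] * L
    rows = []
    for x_t in xs:
        h, c = scalar_lstm_step(x_t, h, c, w)
        rows.append(h)
    return rows


def random_scalar_weights(rng, L, v, scale=0.5):
    def mat(r, c):
        return [[rng.uniform(-scale, scale) for _ in range(c)] for _ in range(r)]

    w = {}
    for g in "ifog":
        w[f"W_h{g}"] = mat(L, L)
        w[f"W_x{g}"] = mat(v, L)
        w[f"b_{g}"] = [rng.uniform(-scale, scale) for _ in range(L)]
    return w
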