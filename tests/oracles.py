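"""Independent brute-force reference implementations of the evaluation
statistics, written as direct summation loops. These are deliberately naive
and share no code with the package; tests compare the package's vectorized
metrics against them.
"""

from __future__ import annotations

import math


def _mean(xs):
    return sum(xs) / len(xs)


def _pop_var(xs):
    mu = _mean(xs)
    return sum((x - mu) ** 2 for x in xs) / len(xs)


def corr_to_avg_brute(responses, predictions, neuron):
    """Pearson correlation between per-image repeat means and predictions,
    by direct summation. ``responses``: list over images of lists of repeat
    vectors; ``predictions``: list over images of vectors."""
    rbar = [_mean([rep[neuron] for rep in img]) for img in responses]
    o = [p[neuron] for p in predictions]
    mr, mo = _mean(rbar), _mean(o)
    num = sum((a - mr) * (b - mo) for a, b in zip(rbar, o))
    den = math.sqrt(sum((a - mr) ** 2 for a in rbar) * sum((b - mo) ** 2 for b in o))
    if den == 0:
        return float("nan")
    return num / den


def fev_brute(responses, neuron):
    """(Var[r] - sigma_eps^2) / Var[r] with population variances."""
    pooled = [rep[neuron] for img in responses for rep in img]
    total = _pop_var(pooled)
    noise = _mean([_pop_var([rep[neuron] for rep in img]) for img in responses])
    if total == 0:
        return float("nan")
    return (total - noise) / total


def feve_brute(responses, predictions, neuron):
    """1 - (MSE - sigma_eps^2) / (Var[r] - sigma_eps^2)."""
    pooled = [rep[neuron] for img in responses for rep in img]
    total = _pop_var(pooled)
    noise = _mean([_pop_var([rep[neuron] for rep in img]) for img in responses])
    sq = 0.0
    n = 0
    for img, pred in zip(responses, predictions):
        for rep in img:
            sq += (rep[neuron] - pred[neuron]) ** 2
            n += 1
    mse = sq / n
    if total - noise <= 0:
        return float("nan")
    return 1.0 - (mse - noise) / (total - noise)


def distance_curve_brute(cells, vectors):
    """All-pairs rank-distance similarity curve on a small grid.

    ``cells``: list of (x, y, z) coordinates of non-missing cells;
    ``vectors``: matching list of value lists. Returns [(k, mean corr), ...]
    by explicitly sorting, building the full correlation matrix and averaging
    each off-diagonal.
    """
    ref = cells[0]

    def sqdist(c):
        acc = 0.0
        for a, b in zip(c, ref):
            acc += (a - b) ** 2
        return acc

    order = sorted(range(len(cells)), key=lambda i: (sqdist(cells[i]), i))
    vs = [vectors[i] for i in order]

    def corr(a, b):
        ma, mb = _mean(a), _mean(b)
        num = sum((x - ma) * (y - mb) for x, y in zip(a, b))
        den = math.sqrt(sum((x - ma) ** 2 for x in a) * sum((y - mb) ** 2 for y in b))
        return float("nan") if den == 0 else num / den

    n = len(vs)
    C = [[corr(vs[i], vs[j]) for j in range(n)] for i in range(n)]
    out = []
    for k in range(n):
        diag = [C[i][i + k] for i in range(n - k)]
        vals = [d for d in diag if not math.isnan(d)]
        out.append((k, _mean(vals) if vals else float("nan")))
    return out
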