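import math

import numpy as np
import pytest

from pseudogrn import ExpressionMatrix, RunConfig


@pytest.fixture
def small_expr():
    """3 genes x 8 cells with a monotone structure along the cell index."""
    rng = np.random.default_rng(7)
    t = np.linspace(0, 1, 8)
    values = np.vstack([2 * t, 1 - t + 1, 0.5 + 0 * t]) + 0.01 * rng.random((3, 8))
    return ExpressionMatrix(values, ["gA", "gB", "gC"], [f"c{i}" for i in range(8)])


@pytest.fixture
def default_cfg():
    return RunConfig()


# ---------------------------------------------------------------------------
# Independent oracles (brute force, kept free of package internals)
# ---------------------------------------------------------------------------

def brute_force_f_divergence(p, q, family):
    """Direct elementwise summation of sum_i q_i f(p_i/q_i)."""
    def kl(a, b):
        return sum(ai * math.log(ai / bi) for ai, bi in zip(a, b))

    if family == "f_kl":
        return kl(p, q)
    if family == "s_kl":
        return 0.5 * (kl(p, q) + kl(q, p))
    if family == "js":
        m = [(pi + qi) / 2 for pi, qi in zip(p, q)]
        return 0.5 * kl(p, m) + 0.5 * kl(q, m)
    if family == "pearson":
        return sum(qi * (pi / qi - 1) ** 2 for pi, qi in zip(p, q))
    if family == "neyman":
        return sum(qi * (1 - pi / qi) ** 2 / (pi / qi) for pi, qi in zip(p, q))
    if family == "s_pearson":
        return 0.5 * (
            brute_force_f_divergence(p, q, "pearson")
            + brute_force_f_divergence(q, p, "pearson")
        )
    raise ValueError(family)


def brute_force_energy(x, z):
    """All-ordered-pairs V-statistic 2E|x-z| - E|x-x'| - E|z-z'|."""
    x = np.asarray(x, float)
    z = np.asarray(z, float)
    exy = np.abs(x[:, None] - z[None, :]).mean()
    exx = np.abs(x[:, None] - x[None, :]).mean()
    ezz = np.abs(z[:, None] - z[None, :]).mean()
    return 2 * exy - exx - ezz


def brute_force_greedy(d, target, candidates, lam):
    """Step-by-step reimplementation of the penalized greedy selection.

    ``d`` is a dict (regulator, gene) -> score. Returns a list of
    (regulator, adjusted_score, rank).
    """
    remaining = sorted(candidates)
    chosen = []
    out = []
    while remaining:
        scores = {}
        for x in remaining:
            if not chosen:
                scores[x] = d[(x, target)]
            else:
                pen = sum(d[(x, y)] for y in chosen) / len(chosen)
                scores[x] = d[(x, target)] - lam * pen
        best = min(
            (x for x in remaining if scores[x] == max(scores.values()))
        )  # lexicographic among exact ties
        out.append((best, scores[best], len(out) + 1))
        chosen.append(best)
        remaining.remove(best)
    return out


def random_discrete_pair(rng, max_bins=16):
    b = int(rng.integers(2, max_bins + 1))
    p = rng.random(b) + 0.05
    q = rng.random(b) + 0.05
    return p / p.sum(), q / q.sum()
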