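"""First-order time-lagged divergence scores between gene profiles.

The directed score D(X‖Z) compares the distribution of regulator X's
smoothed profile at window t with target Z's profile at window t+lag.
Six f-divergences are estimated on a shared pseudocount histogram; three
integral probability metrics (Wasserstein-1, energy, Cramér) act on the
raw samples.
"""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import wasserstein_distance

from .config import F_DIVERGENCES, IPM_MEASURES, RunConfig
from .pseudotime import SmoothedTrajectory

logger = logging.getLogger("pseudogrn")


@dataclass
class DiscretePair:
    """Two positive probability vectors on shared histogram bins."""

    support_edges: np.ndarray
    p: np.ndarray  # lagged regulator sample
    q: np.ndarray  # target sample

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        for name, v in (("p", self.p), ("q", self.q)):
            if abs(v.sum() - 1.0) > 1e-12:
                raise ValueError(f"{name} must sum to 1 (got {v.sum()!r})")
            if np.any(v <= 0):
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class DivergenceMatrix:
    """Regulator × gene table of lagged divergence scores."""

    regulators: list[str]
    genes: list[str]
    scores: np.ndarray
    measure: str

    def score(self, regulator: str, gene: str) -> float:
        return float(
            self.scores[self.regulators.index(regulator), self.genes.index(gene)]
        )

    def to_long_frame(self) -> pd.DataFrame:
        recs = [
            (r, g, self.scores[i, j])
            for i, r in enumerate(self.regulators)
            for j, g in enumerate(self.genes)
        ]
        return pd.DataFrame(recs, columns=["regulator", "target", "score"])


def lagged_samples(
    traj: SmoothedTrajectory, regulator: str, target: str, lag: int
):
    """Lag-aligned window samples: X windows 1..T−l, Z windows 1+l..T."""
    T = traj.n_windows
    if T <= lag:
        raise ValueError(f"need more than lag={lag} windows, have {T}")
    x = traj.gene_profile(regulator)
    z = traj.gene_profile(target)
    if lag == 0:
        return x.copy(), z.copy()
    return x[:-lag].copy(), z[lag:].copy()


def shared_histogram(
    x_sample: np.ndarray, z_sample: np.ndarray, n_bins: int = 10, pseudocount: float = 0.5
) -> DiscretePair:
    """Estimate two densities on shared equal-width bins with smoothing.

    Bins span the pooled min–max (last bin right-closed); each sample's
    bin counts get ``pseudocount`` added before normalization, so ratio
    divergences stay finite. A zero-width pooled range degenerates to
    uniform distributions for both samples.
    """
    x = np.asarray(x_sample, dtype=float)
    z = np.asarray(z_sample, dtype=float)
    if x.size == 0 or z.size == 0:
        raise ValueError("samples must be non-empty")
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    pooled = np.concatenate([x, z])
    lo, hi = pooled.min(), pooled.max()
    if hi <= lo:
        logger.info("degenerate constant pooled sample; using uniform distributions")
        edges = lo + np.arange(n_bins + 1, dtype=float)
        u = np.full(n_bins, 1.0 / n_bins)
        return DiscretePair(edges, u.copy(), u.copy())
    edges = np.linspace(lo, hi, n_bins + 1)
    cx, _ = np.histogram(x, bins=edges)
    cz, _ = np.histogram(z, bins=edges)
    p = (cx + pseudocount) / (cx.sum() + n_bins * pseudocount)
    q = (cz + pseudocount) / (cz.sum() + n_bins * pseudocount)
    return DiscretePair(edges, p, q)


def _kl(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sum(a * np.log(a / b)))


def f_divergence(pair: DiscretePair, family: str) -> float:
    """Discrete f-divergence Σ q·f(p/q) for the supported families.

    ``f_kl``: f(u)=u ln u; ``pearson``: f(u)=(u−1)²; ``neyman``:
    f(u)=(1−u)²/u; ``s_kl``/``s_pearson``: the mean of the two
    directions; ``js``: Jensen–Shannon with the midpoint mixture.
    Natural logarithms throughout.
    """
    p, q = pair.p, pair.q
    if family == "f_kl":
        val = _kl(p, q)
    elif family == "s_kl":
        val = 0.5 * (_kl(p, q) + _kl(q, p))
    elif family == "js":
        m = 0.5 * (p + q)
        val = 0.5 * _kl(p, m) + 0.5 * _kl(q, m)
    elif family == "pearson":
        val = float(np.sum((p - q) ** 2 / q))
    elif family == "neyman":
        val = float(np.sum((q - p) ** 2 / p))
    elif family == "s_pearson":
        val = 0.5 * float(np.sum((p - q) ** 2 / q) + np.sum((q - p) ** 2 / p))
    else:
        raise ValueError(f"unknown f-divergence family {family!r}")
    return max(val, 0.0)


def _pooled_cdfs(x: np.ndarray, z: np.ndarray):
    v = np.unique(np.concatenate([x, z]))
    F = np.searchsorted(np.sort(x), v, side="right") / x.size
    G = np.searchsorted(np.sort(z), v, side="right") / z.size
    return v, F, G


def ipm_distance(
    x_sample: np.ndarray,
    z_sample: np.ndarray,
    kind: str,
    cramer_weighted: bool = False,
) -> float:
    """Integral probability metric between two 1-D empirical samples.

    ``wasserstein``: ∫|F−G| dv (equal sizes: mean |difference| of the
    sorted samples). ``energy``: 2·E|X−Z| − E|X−X′| − E|Z−Z′| as the
    all-pairs V-statistic, computed via its CDF form 2∫(F−G)² dv.
    ``cramer``: unweighted Σ_j (F(v_j)−G(v_j))² over the distinct pooled
    values, or the spacing-weighted integral when ``cramer_weighted``.
    """
    x = np.asarray(x_sample, dtype=float)
    z = np.asarray(z_sample, dtype=float)
    if x.size == 0 or z.size == 0:
        raise ValueError("samples must be non-empty")
    if kind == "wasserstein":
        return float(wasserstein_distance(x, z))
    v, F, G = _pooled_cdfs(x, z)
    sq = (F - G) ** 2
    if kind == "energy":
        if v.size < 2:
            return 0.0
        return float(2.0 * np.sum(sq[:-1] * np.diff(v)))
    if kind == "cramer":
        if cramer_weighted:
            if v.size < 2:
                return 0.0
            return float(np.sum(sq[:-1] * np.diff(v)))
        return float(np.sum(sq))
    raise ValueError(f"unknown IPM kind {kind!r}")


def pair_score(
    traj: SmoothedTrajectory, regulator: str, target: str, cfg: RunConfig
) -> float:
    """D(X‖Z) for one ordered gene pair under the configured measure."""
    x, z = lagged_samples(traj, regulator, target, cfg.lag)
    if cfg.measure in F_DIVERGENCES:
        pair = shared_histogram(x, z, cfg.n_bins, cfg.pseudocount)
        return f_divergence(pair, cfg.measure)
    return ipm_distance(x, z, cfg.measure, cfg.cramer_weighted)


def score_matrix(
    traj: SmoothedTrajectory, regulators: list[str], cfg: RunConfig
) -> DivergenceMatrix:
    """Lagged divergence D(X‖Z) for every regulator X and every gene Z.

    Regulator–regulator entries are included because the redundancy
    penalty of the greedy selection needs them; the diagonal is computed
    but never used for edges.
    """
    start = time.perf_counter()
    genes = list(traj.gene_ids)
    scores = np.zeros((len(regulators), len(genes)))
    for i, r in enumerate(regulators):
        for j, g in enumerate(genes):
            scores[i, j] = pair_score(traj, r, g, cfg)
    logger.info(
        "scored %d x %d gene pairs with %s (lag=%d) in %.3fs",
        len(regulators), len(genes), cfg.measure, cfg.lag,
        time.perf_counter() - start,
    )
    return DivergenceMatrix(list(regulators), genes, scores, cfg.measure)
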