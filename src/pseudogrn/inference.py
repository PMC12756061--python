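"""Penalized non-redundant regulator selection and edge signing.

For each target Z the candidate regulators are picked greedily: the
first by raw divergence D(X‖Z), the rest by the adjusted score
D*(X‖Z) = D(X‖Z) − λ/|S| · Σ_{Y∈S} D(X‖Y), which rewards relevance to
the target and penalizes redundancy with already-selected regulators
(an mRMR-style rule). Edges with recorded D* > 0 are kept and signed by
the partial correlation of the lag-aligned profiles: positive →
activation, negative → inhibition.
"""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .divergence import DivergenceMatrix, lagged_samples
from .pseudotime import SmoothedTrajectory

logger = logging.getLogger("pseudogrn")


@dataclass
class SelectionEntry:
    regulator: str
    adjusted_score: float  # D* recorded at the moment of selection
    rank: int  # 1-based selection order


@dataclass
class RegulatorSelection:
    """Full greedy ordering of one target's candidate regulators."""

    target: str
    entries: list[SelectionEntry]
    lam: float


@dataclass
class Edge:
    regulator: str
    target: str
    score: float  # recorded D* of the retained regulator
    rank: int


@dataclass
class SignedEdge:
    regulator: str
    target: str
    score: float
    sign: str  # "activation" | "inhibition"
    partial_corr: float
    rank: int


@dataclass
class SignedNetwork:
    edges: list[SignedEdge] = field(default_factory=list)

    def edge_set(self) -> set[tuple[str, str]]:
        return {(e.regulator, e.target) for e in self.edges}


def greedy_select(
    D: DivergenceMatrix, target: str, candidates: list[str], lam: float
) -> RegulatorSelection:
    """Greedy penalized ranking of all candidates for one target.

    The first pick is argmax D(X‖Z) and records its raw divergence as
    D*; every later pick records D*(X‖Z) = D(X‖Z) − λ/|S|·Σ_{Y∈S} D(X‖Y)
    evaluated at its selection step. Recorded scores are never revised
    afterwards. Ties break lexicographically by regulator id.
    """
    if target in candidates:
        raise ValueError(f"target {target!r} must not be its own candidate")
    if lam < 0:
        raise ValueError("lam must be non-negative")
    cands = sorted(set(candidates))
    if not cands:
        logger.warning("no candidate regulators for target %r", target)
        return RegulatorSelection(target, [], lam)

    d_to_target = {x: D.score(x, target) for x in cands}
    selected: list[str] = []
    penalty_sum = {x: 0.0 for x in cands}  # running Σ_{Y∈S} D(X‖Y)
    entries: list[SelectionEntry] = []
    remaining = list(cands)  # kept sorted: lexicographic tie-break for free

    while remaining:
        if not selected:
            dstar = {x: d_to_target[x] for x in remaining}
        else:
            k = len(selected)
            dstar = {
                x: d_to_target[x] - lam / k * penalty_sum[x] for x in remaining
            }
        best = remaining[0]
        for x in remaining[1:]:
            if dstar[x] > dstar[best]:
                best = x
        entries.append(SelectionEntry(best, dstar[best], len(entries) + 1))
        remaining.remove(best)
        selected.append(best)
        for x in remaining:
            penalty_sum[x] += D.score(x, best)
    return RegulatorSelection(target, entries, lam)


def threshold_edges(selections: list[RegulatorSelection]) -> list[Edge]:
    """Keep every (regulator → target) whose recorded D* is strictly > 0."""
    edges = [
        Edge(e.regulator, sel.target, e.adjusted_score, e.rank)
        for sel in selections
        for e in sel.entries
        if e.adjusted_score > 0.0
    ]
    logger.info("thresholded to %d edges across %d targets", len(edges), len(selections))
    return edges


def partial_corr(
    traj: SmoothedTrajectory,
    regulator: str,
    target: str,
    conditioning: list[str],
    lag: int = 1,
) -> float:
    """Partial correlation of X's lagged and Z's led window samples.

    Both samples are residualized against the lagged samples of the
    conditioning genes (ordinary least squares with intercept; a 1e-6
    ridge is added when the normal equations are near-singular) and the
    Pearson correlation of the residuals is returned. With an empty
    conditioning set this is the plain Pearson correlation. Samples too
    short to support the regression (fewer than |C|+3 points) fall back
    to the unconditional correlation with a warning.
    """
    if regulator in conditioning or target in conditioning:
        raise ValueError("conditioning set must exclude the edge endpoints")
    x, z = lagged_samples(traj, regulator, target, lag)
    n = x.size
    cond = sorted(set(conditioning))
    if cond and n < len(cond) + 3:
        logger.warning(
            "sample of length %d too short to condition on %d genes for edge "
            "%s -> %s; using unconditional correlation", n, len(cond), regulator, target,
        )
        cond = []
    if cond:
        C = np.stack([lagged_samples(traj, c, target, lag)[0] for c in cond], axis=1)
        A = np.column_stack([np.ones(n), C])
        AtA = A.T @ A
        if np.linalg.cond(AtA) > 1e8:
            logger.info("near-singular conditioning design for %s -> %s; adding ridge",
                        regulator, target)
            AtA = AtA + 1e-6 * np.eye(AtA.shape[0])
        solve = np.linalg.solve
        x = x - A @ solve(AtA, A.T @ x)
        z = z - A @ solve(AtA, A.T @ z)
    else:
        x = x - x.mean()
        z = z - z.mean()
    sx = float(np.sqrt(np.sum(x * x)))
    sz = float(np.sqrt(np.sum(z * z)))
    if sx == 0.0 or sz == 0.0:
        return 0.0
    return float(np.clip(np.dot(x, z) / (sx * sz), -1.0, 1.0))


def sign_network(
    edges: list[Edge], traj: SmoothedTrajectory, cfg: RunConfig
) -> SignedNetwork:
    """Label each retained edge activation/inhibition by partial correlation.

    The conditioning set of edge X → Z is Z's other retained regulators.
    A partial correlation of exactly 0 is labeled activation with a
    warning (tie rule).
    """
    start = time.perf_counter()
    parents: dict[str, list[str]] = {}
    for e in edges:
        parents.setdefault(e.target, []).append(e.regulator)
    signed: list[SignedEdge] = []
    for e in edges:
        cond = [p for p in parents[e.target] if p != e.regulator]
        r = partial_corr(traj, e.regulator, e.target, cond, cfg.lag)
        if r == 0.0:
            logger.warning(
                "partial correlation exactly 0 for %s -> %s; labeling activation",
                e.regulator, e.target,
            )
        sign = "activation" if r >= 0.0 else "inhibition"
        signed.append(SignedEdge(e.regulator, e.target, e.score, sign, r, e.rank))
    logger.info("signed %d edges in %.3fs", len(signed), time.perf_counter() - start)
    return SignedNetwork(signed)
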