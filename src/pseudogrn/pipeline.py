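"""End-to-end driver: pseudotime → divergence → selection → signing."""
from __future__ import annotations

import logging
import time

import pandas as pd

from .config import RunConfig
from .divergence import score_matrix
from .inference import RegulatorSelection, SignedNetwork, greedy_select, sign_network, threshold_edges
from .io import ExpressionMatrix
from .pseudotime import (
    diffusion_pseudotime,
    load_precomputed_pseudotime,
    order_and_smooth,
    pca_pseudotime,
    preprocess,
)

logger = logging.getLogger("pseudogrn")


def compute_pseudotime(expr: ExpressionMatrix, cfg: RunConfig, pseudotime_file=None):
    if cfg.pseudotime_method == "pca":
        return pca_pseudotime(expr, cfg.root_cell)
    if cfg.pseudotime_method == "diffmap":
        return diffusion_pseudotime(
            expr, cfg.root_cell, cfg.diffmap_n_neighbors, cfg.diffmap_n_comps
        )
    if pseudotime_file is None:
        raise ValueError("precomputed pseudotime requires a pseudotime file")
    return load_precomputed_pseudotime(pseudotime_file, expr)


def run_pipeline(
    expr: ExpressionMatrix,
    tfs: list[str] | None,
    cfg: RunConfig,
    pseudotime_file=None,
) -> tuple[SignedNetwork, list[RegulatorSelection]]:
    """Run the four inference steps and return the signed network.

    ``tfs`` restricts candidate regulators; ``None`` makes every gene a
    candidate for every other gene. The run is deterministic: identical
    inputs and configuration reproduce the identical network.
    """
    cfg.validate()
    start = time.perf_counter()
    if tfs is not None:
        missing = [t for t in tfs if t not in expr.gene_ids]
        if missing:
            raise ValueError(f"TF {missing[0]!r} not present in the expression matrix")
        regulators = list(dict.fromkeys(tfs))
    else:
        regulators = list(expr.gene_ids)

    # Step 1: pseudotime, ordering and smoothing
    prepped = preprocess(expr, cfg.do_normalize)
    pt = compute_pseudotime(prepped, cfg, pseudotime_file)
    traj = order_and_smooth(prepped, pt, cfg.window_width, cfg.window_step)

    # Step 2: time-lagged divergence for all regulator/gene pairs
    D = score_matrix(traj, regulators, cfg)

    # Step 3: penalized non-redundant selection per target
    selections = []
    for target in expr.gene_ids:
        U = [r for r in regulators if r != target]
        selections.append(greedy_select(D, target, U, cfg.lam))
    edges = threshold_edges(selections)

    # Step 4: partial-correlation signing
    net = sign_network(edges, traj, cfg)
    logger.info(
        "pipeline finished: %d edges (measure=%s, lam=%g, lag=%d) in %.3fs",
        len(net.edges), cfg.measure, cfg.lam, cfg.lag, time.perf_counter() - start,
    )
    return net, selections


def selections_to_frame(selections: list[RegulatorSelection]) -> pd.DataFrame:
    """Long table ``target regulator rank adjusted_score`` of all rankings."""
    recs = [
        (sel.target, e.regulator, e.rank, e.adjusted_score)
        for sel in selections
        for e in sel.entries
    ]
    return pd.DataFrame(recs, columns=["target", "regulator", "rank", "adjusted_score"])
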