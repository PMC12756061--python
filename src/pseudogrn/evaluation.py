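"""AUROC / AUPRC evaluation of a ranked edge table against a reference.

The evaluation universe is every ordered TF → gene pair over the
reference gene set, minus self-pairs; pairs absent from the score table
rank with score 0. AUROC uses the Mann–Whitney formulation with midrank
tie handling; AUPRC is non-interpolated average precision with tied
scores processed as one block (both via scikit-learn).
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score


def _as_score_dict(scores) -> dict[tuple[str, str], float]:
    if isinstance(scores, dict):
        d = {(str(r), str(t)): float(s) for (r, t), s in scores.items()}
    else:
        df = pd.DataFrame(scores)
        d = {
            (str(r), str(t)): float(s)
            for r, t, s in zip(df["regulator"], df["target"], df["score"])
        }
    for (r, t), s in d.items():
        if not np.isfinite(s):
            raise ValueError(f"non-finite score for pair {r!r} -> {t!r}")
    return d


def _universe(
    reference: set[tuple[str, str]],
    genes: list[str] | None,
    tfs: list[str] | None,
):
    ref = {(str(r), str(t)) for r, t in reference if r != t}
    if not ref:
        raise ValueError("reference edge set is empty")
    if genes is None:
        genes = sorted({g for e in ref for g in e})
    else:
        genes = [str(g) for g in genes]
    if tfs is None:
        tfs = sorted({r for r, _ in ref})
    else:
        tfs = [str(t) for t in tfs]
    pairs = [(r, g) for r in tfs for g in genes if r != g]
    ref = ref & set(pairs)
    return pairs, ref


def _labels_and_scores(scores, reference, genes=None, tfs=None):
    table = _as_score_dict(scores)
    pairs, ref = _universe(reference, genes, tfs)
    y = np.array([1 if p in ref else 0 for p in pairs])
    s = np.array([table.get(p, 0.0) for p in pairs])
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("no reference edge lies inside the evaluation universe")
    if n_pos == len(pairs):
        raise ValueError("reference covers every candidate pair; no negatives")
    return y, s


def auroc(scores, reference, genes=None, tfs=None) -> float:
    """Area under the ROC curve of the ranked candidate pairs.

    ``scores`` is a (regulator, target, score) table or dict;
    ``reference`` a set of directed true edges. ``genes``/``tfs``
    override the evaluation universe (defaults: genes and regulators
    appearing in the reference).
    """
    y, s = _labels_and_scores(scores, reference, genes, tfs)
    return float(roc_auc_score(y, s))


def auprc(scores, reference, genes=None, tfs=None) -> float:
    """Average precision of the ranked candidate pairs (see :func:`auroc`)."""
    y, s = _labels_and_scores(scores, reference, genes, tfs)
    return float(average_precision_score(y, s))
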