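"""Run configuration shared by every pipeline stage.

All tunables of the method live here: pseudotime backend, divergence
measure, time lag (in smoothed-window units), sliding-window geometry,
the redundancy penalty ``lam`` and the histogram estimator settings used
by the f-divergence families.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

logger = logging.getLogger("pseudogrn")

PSEUDOTIME_METHODS = ("pca", "diffmap", "precomputed")
F_DIVERGENCES = ("f_kl", "s_kl", "js", "pearson", "s_pearson", "neyman")
IPM_MEASURES = ("wasserstein", "energy", "cramer")
MEASURES = F_DIVERGENCES + IPM_MEASURES


@dataclass
class RunConfig:
    """Parameters of one inference run.

    Attributes
    ----------
    pseudotime_method:
        ``pca``, ``diffmap`` or ``precomputed`` (import a table produced by
        an external trajectory tool such as Slingshot or PHATE).
    measure:
        One of six f-divergences (``f_kl``, ``s_kl``, ``js``, ``pearson``,
        ``s_pearson``, ``neyman``) or three integral probability metrics
        (``wasserstein``, ``energy``, ``cramer``).
    lag:
        First-order time lag between regulator and target, counted in
        smoothed windows. Default 1 (Markov assumption).
    window_width, window_step:
        Sliding-window smoothing geometry over pseudotime-ordered cells.
    lam:
        Redundancy penalty of the greedy regulator selection; larger
        values yield sparser networks.
    n_bins, pseudocount:
        Shared-histogram density estimator used by the f-divergence
        families (ignored by the IPMs, which act on raw samples).
    root_cell:
        Optional cell id anchoring pseudotime at 0.
    normalize:
        Median-library-size scaling + log1p before pseudotime. ``None``
        means the method default: on for pca/diffmap, off for precomputed.
    cramer_weighted:
        Switch the Cramér estimator from the unweighted sum of squared
        CDF differences to the spacing-weighted (Cramér–von Mises style)
        integral.
    """

    pseudotime_method: str = "pca"
    measure: str = "cramer"
    lag: int = 1
    window_width: int = 5
    window_step: int = 1
    lam: float = 1.5
    n_bins: int = 10
    pseudocount: float = 0.5
    root_cell: str | None = None
    seed: int = 0
    normalize: bool | None = None
    cramer_weighted: bool = False
    diffmap_n_neighbors: int = 15
    diffmap_n_comps: int = 10

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.pseudotime_method not in PSEUDOTIME_METHODS:
            raise ValueError(
                f"unknown pseudotime method {self.pseudotime_method!r}; "
                f"choose from {PSEUDOTIME_METHODS}"
            )
        if self.measure not in MEASURES:
            raise ValueError(
                f"unknown measure {self.measure!r}; choose from {MEASURES}"
            )
        if self.lag < 1:
            raise ValueError("lag must be a positive integer")
        if self.window_width < 1 or self.window_step < 1:
            raise ValueError("window_width and window_step must be positive")
        if self.lam < 0:
            raise ValueError("lam must be non-negative")
        if self.n_bins < 2:
            raise ValueError("n_bins must be at least 2")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")

    @property
    def do_normalize(self) -> bool:
        if self.normalize is not None:
            return self.normalize
        return self.pseudotime_method != "precomputed"


_BOOL_STRINGS = {"true": True, "false": False, "1": True, "0": False,
                 "yes": True, "no": False}


def load_config_file(path: str | Path) -> dict:
    """Parse a flat ``key=value`` configuration file into a dict.

    Lines starting with ``#`` and blank lines are ignored. Values are
    coerced to the declared type of the matching :class:`RunConfig`
    field; unknown keys raise.
    """
    field_types = {f.name: f.type for f in dataclasses.fields(RunConfig)}
    out: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key not in field_types:
            raise ValueError(f"{path}:{lineno}: unknown configuration key {key!r}")
        out[key] = _coerce(key, value, field_types[key])
    return out


def _coerce(key: str, value: str, ftype: str):
    ftype = str(ftype)
    if "bool" in ftype:
        try:
            return _BOOL_STRINGS[value.lower()]
        except KeyError:
            raise ValueError(f"cannot parse boolean {value!r} for {key}") from None
    if "int" in ftype:
        return int(value)
    if "float" in ftype:
        return float(value)
    return value
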