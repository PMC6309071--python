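"""Stratified analyses of inferred exponents and distances, plus baselines.

These are the downstream analyses used to sanity-check the inference:
contrasting contact counts between high- and low-exponent beads,
comparing intra- vs inter-domain pairs inside a fixed contact band,
stratifying by genomic separation, and the fixed-exponent (alpha = 1/3)
and random-exponent baselines the per-pair model is measured against.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import BenchmarkDistances, ContactMatrix, TadIntervals
from .alpha import (
    ClusteringStrengthModel,
    OptimizationConfig,
    WishDistances,
    row_weights,
)
from .mds import fish_correlation

__all__ = [
    "StratifiedDistribution",
    "alpha_percentile_contrast",
    "tad_stratify",
    "genomic_distance_stratify",
    "fixed_alpha_distances",
    "random_alpha_distances",
    "tune_lambdas",
]


@dataclass
class StratifiedDistribution:
    """Named groups of values with per-group summary statistics."""

    groups: dict[str, np.ndarray] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = []
        for label, vals in self.groups.items():
            vals = np.asarray(vals, dtype=float)
            if len(vals):
                rows.append(
                    {
                        "group": label,
                        "n": len(vals),
                        "median": float(np.median(vals)),
                        "q1": float(np.percentile(vals, 25)),
                        "q3": float(np.percentile(vals, 75)),
                        "mean": float(vals.mean()),
                    }
                )
            else:
                rows.append(
                    {"group": label, "n": 0, "median": np.nan, "q1": np.nan,
                     "q3": np.nan, "mean": np.nan}
                )
        return pd.DataFrame(rows)

    def median(self, label: str) -> float:
        vals = self.groups[label]
        return float(np.median(vals)) if len(vals) else np.nan

    def to_tidy_frame(self) -> pd.DataFrame:
        parts = [
            pd.DataFrame({"group": label, "value": np.asarray(vals, dtype=float)})
            for label, vals in self.groups.items()
        ]
        return (
            pd.concat(parts, ignore_index=True)
            if parts
            else pd.DataFrame(columns=["group", "value"])
        )


def _alpha_array(alpha) -> np.ndarray:
    return np.asarray(getattr(alpha, "alpha", alpha), dtype=float)


def _extreme_beads(alpha: np.ndarray, q: float) -> tuple[np.ndarray, np.ndarray]:
    """Top-q and bottom-q bead sets among beads with defined alpha.

    Ties at the quantile boundary are broken by lower bead index
    (stable ordering), so the sets are always well defined.
    """
    valid = np.nonzero(np.isfinite(alpha))[0]
    k = max(int(np.ceil(q * len(valid))), 1)
    order = valid[np.lexsort((valid, alpha[valid]))]  # by alpha, then index
    return order[-k:], order[:k]


def alpha_percentile_contrast(
    cm: ContactMatrix, alpha, q: float = 0.10
) -> StratifiedDistribution:
    """Contacts between top-q-exponent bead pairs vs bottom-q pairs.

    Reproduces the diagnostic that beads with large inferred exponents
    (high clustering) share more contacts than beads with small ones.
    Zero contacts are excluded.
    """
    if not (0.0 < q <= 0.5):
        raise ValueError("q must be in (0, 0.5]")
    a = _alpha_array(alpha)
    top, bottom = _extreme_beads(a, q)
    if len(top) < 2 or len(bottom) < 2:
        raise ValueError("fewer than 2 beads in a percentile group")
    c = cm.masked()

    def _pair_contacts(beads: np.ndarray) -> np.ndarray:
        sub = c[np.ix_(beads, beads)]
        vals = sub[np.triu_indices(len(beads), k=1)]
        return vals[vals > 0]

    return StratifiedDistribution(
        groups={"top": _pair_contacts(top), "bottom": _pair_contacts(bottom)}
    )


def _pairs_of(values) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(values, WishDistances):
        return values.i, values.j, values.delta
    items = sorted(values.items())
    ii = np.array([min(k) for k, _ in items], dtype=int)
    jj = np.array([max(k) for k, _ in items], dtype=int)
    vv = np.array([v for _, v in items], dtype=float)
    return ii, jj, vv


def tad_stratify(
    values,
    tads: TadIntervals,
    contact_band: tuple[float, float] | None = None,
    cm: ContactMatrix | None = None,
) -> StratifiedDistribution:
    """Split pair values into intra-domain / inter-domain / outside groups.

    ``values`` maps bead pairs to a quantity (a ``WishDistances`` or a
    ``{(i, j): value}`` dict).  A pair is *intra* when both beads fall in
    the same domain interval, *inter* when they fall in two different
    domains, and *outside* when either bead is not covered by any domain
    (reported explicitly rather than silently merged).  When
    ``contact_band = (lo, hi)`` is given, only pairs with
    ``lo <= c_ij <= hi`` enter (requires ``cm``).
    """
    ii, jj, vv = _pairs_of(values)
    n = (cm.n if cm is not None else int(max(jj.max(initial=0), ii.max(initial=0)) + 1))
    labels = tads.bead_labels(n)
    if contact_band is not None:
        if cm is None:
            raise ValueError("contact_band requires the contact matrix")
        lo, hi = contact_band
        c = cm.masked()
        keep = (c[ii, jj] >= lo) & (c[ii, jj] <= hi)
        ii, jj, vv = ii[keep], jj[keep], vv[keep]
    li, lj = labels[ii], labels[jj]
    intra = (li >= 0) & (li == lj)
    outside = (li < 0) | (lj < 0)
    inter = ~intra & ~outside
    groups = {
        "intra": vv[intra],
        "inter": vv[inter],
        "outside": vv[outside],
    }
    for name in ("intra", "inter"):
        if len(groups[name]) == 0:
            raise ValueError(f"empty group: {name}")
    return StratifiedDistribution(groups=groups)


def genomic_distance_stratify(
    values, bins: list[tuple[int, int]] | None = None
) -> StratifiedDistribution:
    """Group pair values by bead separation |i - j|.

    Bin membership follows the bracket convention [lo1, hi1], (lo2, hi2],
    ...: the first bin is closed on both ends, later bins are left-open
    and right-closed.  Default bins: [1, 5], (5, 10], (10, 15], (15, 20].
    Empty bins are reported as empty, not dropped.
    """
    if bins is None:
        bins = [(1, 5), (5, 10), (10, 15), (15, 20)]
    for (a0, b0), (a1, b1) in itertools.combinations(bins, 2):
        if max(a0, a1) < min(b0, b1):
            raise ValueError("bins overlap")
    ii, jj, vv = _pairs_of(values)
    sep = np.abs(jj - ii)
    groups = {}
    for idx, (lo, hi) in enumerate(bins):
        inside = (sep > lo) & (sep <= hi)
        if idx == 0:
            inside |= sep == lo
        label = f"[{lo}, {hi}]" if idx == 0 else f"({lo}, {hi}]"
        groups[label] = vv[inside]
    return StratifiedDistribution(groups=groups)


def fixed_alpha_distances(cm: ContactMatrix, alpha_fixed: float = 1.0 / 3.0) -> WishDistances:
    """Baseline wish distances with one global exponent (classically 1/3)."""
    if not (0.0 < alpha_fixed <= 1.0):
        raise ValueError("alpha_fixed must be in (0, 1]")
    c = cm.masked()
    ii, jj = np.nonzero(np.triu(c, k=1))
    cv = c[ii, jj]
    delta = np.exp(-alpha_fixed * np.log(cv))
    return WishDistances(
        n=cm.n, i=ii, j=jj, delta=delta,
        alpha=np.full(len(cv), alpha_fixed), contact=cv,
    )


def random_alpha_distances(cm: ContactMatrix, seed: int = 0) -> WishDistances:
    """Baseline with per-pair exponents drawn uniformly on [0, 1] (seeded)."""
    c = cm.masked()
    ii, jj = np.nonzero(np.triu(c, k=1))
    cv = c[ii, jj]
    rng = np.random.default_rng(seed)
    aij = rng.uniform(0.0, 1.0, size=len(cv))
    delta = np.exp(-aij * np.log(cv))
    return WishDistances(n=cm.n, i=ii, j=jj, delta=delta, alpha=aij, contact=cv)


def tune_lambdas(
    cm: ContactMatrix,
    bench: BenchmarkDistances,
    lambda1_grid=(0.1, 1.0, 10.0),
    lambda2_grid=(0.5, 1.0),
    lambda3_grid=(0.0, 0.1, 1.0),
    base_config: OptimizationConfig | None = None,
    blocks=None,
) -> tuple[OptimizationConfig, float, pd.DataFrame]:
    """Grid-search the objective weights against a benchmark distance table.

    Returns the best configuration, its Pearson correlation with the
    benchmark, and the full grid as a DataFrame.  Correlation with
    imaging distances is positive-is-better, so the grid maximizes r.
    """
    base = base_config or OptimizationConfig()
    rows = []
    best_cfg, best_r = None, -np.inf
    for l1 in lambda1_grid:
        for l2 in lambda2_grid:
            for l3 in lambda3_grid:
                cfg = OptimizationConfig(
                    lambda1=l1, lambda2=l2, lambda3=l3,
                    p0=base.p0, max_triples=base.max_triples,
                    max_triangles=base.max_triangles, tol=base.tol,
                    gtol=base.gtol, max_iter=base.max_iter,
                    seed=base.seed, backend=base.backend,
                    min_contact=base.min_contact,
                )
                res = ClusteringStrengthModel(cm, config=cfg).fit()
                wd = res.wish_distances()
                try:
                    r = fish_correlation(wd, bench, blocks=blocks)
                except ValueError:
                    r = np.nan
                rows.append(
                    {"lambda1": l1, "lambda2": l2, "lambda3": l3,
                     "pearson_r": r, "status": res.solver_status}
                )
                if np.isfinite(r) and r > best_r:
                    best_r, best_cfg = float(r), cfg
    if best_cfg is None:
        raise ValueError("no grid point produced a usable correlation")
    return best_cfg, best_r, pd.DataFrame(rows)
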