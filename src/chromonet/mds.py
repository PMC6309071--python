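"""3D coordinate reconstruction from wish distances, and structure comparison.

The second-stage optimization is a metric MDS with normalized stress

    argmin  sum_{c_ij > 0} (d_ij - delta_ij)^2 / delta_ij^2
          + sum_{c_ij = 0} (d_ij - R)^2 / R^2

where d_ij is the Euclidean distance in the candidate embedding and R
caps the distance of pairs with no observed contact (default: the
maximum wish distance).  Because the target distances were already
optimized under triangle-inequality and box constraints, this solve is
unconstrained: a gradient-based local optimizer (L-BFGS-B) is run from a
classical-MDS warm start plus seeded random restarts, and the best
restart is returned, centered at the origin.

Also here: Kabsch rigid superposition (proper rotation by default, with
reflection-allowed and scale-fitting options for cross-method
comparison), resolution coarsening of distance matrices, and Pearson
scoring against external benchmark distance tables (FISH-style probes
spanning blocks of beads).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

from .alpha import WishDistances
from .io import BenchmarkDistances

__all__ = [
    "MdsConfig",
    "Structure3D",
    "StructureModel",
    "reconstruct",
    "pairwise_distances",
    "average_to_resolution",
    "genomic_blocks",
    "average_to_genomic_resolution",
    "kabsch_superpose",
    "kabsch_rmsd",
    "fish_correlation",
]


@dataclass
class MdsConfig:
    """Settings for the stress minimization.

    ``R`` defaults to the maximum wish distance.  ``zero_pair_cap``
    optionally subsamples the (dominant) set of zero-contact pairs for
    tractability at high resolution; by default all are kept.
    """

    R: float | None = None
    max_iter: int = 2000
    tol: float = 1e-12          # L-BFGS-B ftol
    seed: int = 0
    n_restarts: int = 4
    include_zero_pairs: bool = True
    zero_pair_cap: int | None = None
    classical_init: bool = True

    def __post_init__(self) -> None:
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass
class Structure3D:
    """Reconstructed per-bead 3D coordinates (arbitrary units)."""

    coords: np.ndarray
    bin_size: int = 40_000
    chrom: str = "chr"
    stress: float | None = None
    converged: bool = True
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n, 3)")

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    def pairwise_distances(self) -> np.ndarray:
        return pairwise_distances(self)

    def summary(self) -> str:
        lines = [
            "3D reconstruction",
            "=" * 44,
            f"beads        {self.n:>10d}",
            f"stress       {self.stress if self.stress is not None else float('nan'):>10.6g}",
            f"converged    {str(self.converged):>10s}",
        ]
        for k in ("seed", "n_restarts", "R", "n_wish_pairs", "n_zero_pairs"):
            if k in self.provenance:
                lines.append(f"{k:<13}{self.provenance[k]:>10}")
        return "\n".join(lines)

    def save_report(self, path) -> None:
        out = {
            "n": self.n,
            "stress": self.stress,
            "converged": self.converged,
            **self.provenance,
        }
        with open(path, "w") as fh:
            json.dump(out, fh, indent=2)


class StructureModel:
    """Embeds wish distances in 3D by minimizing the capped normalized stress."""

    def __init__(self, wd: WishDistances, config: MdsConfig | None = None):
        if len(wd) == 0:
            raise ValueError("empty wish-distance set")
        if len(wd) == 1 and wd.n > 2:
            raise ValueError("degenerate wish-distance set: a single pair cannot "
                             "position more than two beads")
        self.wd = wd
        self.config = config or MdsConfig()
        cfg = self.config
        self.n = wd.n
        self.R = float(wd.max_delta if cfg.R is None else cfg.R)
        if self.R < wd.max_delta:
            raise ValueError("R must be >= the maximum wish distance")
        # mappable = bead participates in at least one observed pair
        mappable = np.zeros(self.n, dtype=bool)
        mappable[wd.i] = True
        mappable[wd.j] = True
        self.mappable = mappable
        self._build_pairs()

    def _build_pairs(self) -> None:
        cfg = self.config
        n = self.n
        obs = set(zip(self.wd.i.tolist(), self.wd.j.tolist()))
        zi, zj = [], []
        if cfg.include_zero_pairs and n > 2:
            iu, ju = np.triu_indices(n, k=1)
            keep = np.array(
                [
                    (a, b) not in obs and (self.mappable[a] or self.mappable[b])
                    for a, b in zip(iu, ju)
                ]
            )
            zi, zj = iu[keep], ju[keep]
            if cfg.zero_pair_cap is not None and len(zi) > cfg.zero_pair_cap:
                rng = np.random.default_rng(cfg.seed)
                sel = rng.choice(len(zi), size=cfg.zero_pair_cap, replace=False)
                zi, zj = zi[sel], zj[sel]
        self.pi = np.concatenate([self.wd.i, np.asarray(zi, dtype=int)])
        self.pj = np.concatenate([self.wd.j, np.asarray(zj, dtype=int)])
        self.target = np.concatenate(
            [self.wd.delta, np.full(len(zi), self.R)]
        )
        self.n_zero_pairs = len(zi)

    # stress ----------------------------------------------------------
    def stress(self, coords: np.ndarray) -> float:
        diff = coords[self.pi] - coords[self.pj]
        d = np.sqrt(np.sum(diff * diff, axis=1))
        r = (d - self.target) / self.target
        return float(r @ r)

    def _stress_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        coords = x.reshape(self.n, 3)
        diff = coords[self.pi] - coords[self.pj]
        d = np.sqrt(np.sum(diff * diff, axis=1))
        d = np.maximum(d, 1e-12)
        resid = (d - self.target) / self.target**2
        f = float(np.sum((d - self.target) ** 2 / self.target**2))
        coef = 2.0 * resid / d
        contrib = coef[:, None] * diff
        grad = np.zeros_like(coords)
        np.add.at(grad, self.pi, contrib)
        np.add.at(grad, self.pj, -contrib)
        return f, grad.ravel()

    # initialization --------------------------------------------------
    def _classical_init(self) -> np.ndarray:
        """Torgerson double-centering on the target-filled distance matrix."""
        n = self.n
        dm = np.full((n, n), self.R)
        np.fill_diagonal(dm, 0.0)
        dm[self.wd.i, self.wd.j] = self.wd.delta
        dm[self.wd.j, self.wd.i] = self.wd.delta
        d2 = dm**2
        jmat = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * jmat @ d2 @ jmat
        vals, vecs = np.linalg.eigh(b)
        order = np.argsort(vals)[::-1][: min(3, n)]
        lam = np.clip(vals[order], 0.0, None)
        out = np.zeros((n, 3))
        out[:, : len(order)] = vecs[:, order] * np.sqrt(lam)
        return out

    def fit(self) -> Structure3D:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        scale = float(np.mean(self.wd.delta))
        best_x, best_f, any_converged = None, np.inf, False
        init_stresses, final_stresses = [], []
        for r in range(cfg.n_restarts):
            if r == 0 and cfg.classical_init:
                x0 = self._classical_init().ravel()
            else:
                x0 = (rng.standard_normal((self.n, 3)) * scale).ravel()
            init_stresses.append(self.stress(x0.reshape(self.n, 3)))
            res = minimize(
                self._stress_grad,
                x0,
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": cfg.max_iter, "ftol": cfg.tol, "gtol": 1e-12},
            )
            final_stresses.append(float(res.fun))
            any_converged = any_converged or bool(res.success)
            if res.fun < best_f:
                best_f, best_x = float(res.fun), res.x
        coords = best_x.reshape(self.n, 3)
        coords = coords - coords.mean(axis=0)
        return Structure3D(
            coords=coords,
            stress=best_f,
            converged=any_converged,
            provenance={
                "seed": cfg.seed,
                "n_restarts": cfg.n_restarts,
                "R": self.R,
                "n_wish_pairs": len(self.wd),
                "n_zero_pairs": self.n_zero_pairs,
                "restart_initial_stress": init_stresses,
                "restart_final_stress": final_stresses,
            },
        )


def reconstruct(wd: WishDistances, cfg: MdsConfig | None = None) -> Structure3D:
    """Functional wrapper around :class:`StructureModel`."""
    return StructureModel(wd, config=cfg).fit()


def pairwise_distances(s) -> np.ndarray:
    """Symmetric Euclidean distance matrix of a structure (zero diagonal)."""
    coords = np.asarray(getattr(s, "coords", s), dtype=float)
    return squareform(pdist(coords))


def average_to_resolution(d: np.ndarray, factor: int) -> np.ndarray:
    """Coarsen a distance matrix by block-averaging ``factor`` beads per block.

    NaN entries (undefined distances) are excluded from block means;
    trailing partial blocks are included.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return d.copy()
    n = d.shape[0]
    edges = list(range(0, n, factor)) + [n]
    blocks = [(edges[t], edges[t + 1]) for t in range(len(edges) - 1)]
    return _block_average(d, blocks)


def genomic_blocks(n: int, bin_size: int, target_bp: int) -> list[tuple[int, int]]:
    """Bead intervals covering coarse genomic windows of ``target_bp``.

    Defined on genomic coordinates, so non-integer bead ratios (e.g.
    40 kb -> 500 kb, ratio 12.5) produce alternating block sizes.
    A bead belongs to the window containing its start coordinate.
    """
    starts = np.arange(n) * bin_size
    labels = starts // target_bp
    blocks = []
    for lab in np.unique(labels):
        idx = np.nonzero(labels == lab)[0]
        blocks.append((int(idx[0]), int(idx[-1]) + 1))
    return blocks


def average_to_genomic_resolution(
    d: np.ndarray, bin_size: int, target_bp: int
) -> np.ndarray:
    return _block_average(d, genomic_blocks(d.shape[0], bin_size, target_bp))


def _block_average(d: np.ndarray, blocks: list[tuple[int, int]]) -> np.ndarray:
    nb = len(blocks)
    out = np.full((nb, nb), np.nan)
    for a, (i0, i1) in enumerate(blocks):
        for b, (j0, j1) in enumerate(blocks):
            sub = d[i0:i1, j0:j1]
            good = np.isfinite(sub)
            if good.any():
                out[a, b] = float(sub[good].mean())
    return out


@dataclass
class KabschResult:
    rmsd: float
    rmsd_reflection: float
    rotation: np.ndarray
    translation: np.ndarray
    scale: float


def kabsch_superpose(
    a, b, allow_reflection: bool = False, fit_scale: bool = False
) -> KabschResult:
    """Optimal rigid superposition of structure ``b`` onto ``a``.

    Proper rotations only by default (the determinant of the rotation is
    forced to +1); the reflection-allowed RMSD is always reported in the
    result because embeddings from distance data carry a mirror
    ambiguity.  ``fit_scale`` additionally fits a global scale, for
    comparing structures produced in different distance units.
    """
    xa = np.asarray(getattr(a, "coords", a), dtype=float)
    xb = np.asarray(getattr(b, "coords", b), dtype=float)
    if xa.shape != xb.shape:
        raise ValueError(f"structure sizes differ: {xa.shape} vs {xb.shape}")
    if xa.shape[0] < 3:
        raise ValueError("need at least 3 beads for superposition")

    ca, cb = xa.mean(axis=0), xb.mean(axis=0)
    pa, pb = xa - ca, xb - cb

    def _solve(reflect_ok: bool) -> tuple[float, np.ndarray, float]:
        h = pb.T @ pa
        u, sing, vt = np.linalg.svd(h)
        sign = np.sign(np.linalg.det(vt.T @ u.T))
        if reflect_ok:
            d = np.ones(3)
        else:
            d = np.array([1.0, 1.0, sign])
        rot = vt.T @ np.diag(d) @ u.T
        if fit_scale:
            denom = float(np.sum(pb * pb))
            s = float(np.sum(sing * d)) / denom if denom > 0 else 1.0
        else:
            s = 1.0
        resid = pa - s * (pb @ rot.T)
        return float(np.sqrt(np.mean(np.sum(resid**2, axis=1)))), rot, s

    rmsd_proper, rot_p, s_p = _solve(False)
    rmsd_refl, rot_r, s_r = _solve(True)
    if allow_reflection:
        rmsd, rot, s = rmsd_refl, rot_r, s_r
    else:
        rmsd, rot, s = rmsd_proper, rot_p, s_p
    return KabschResult(
        rmsd=rmsd,
        rmsd_reflection=rmsd_refl,
        rotation=rot,
        translation=ca - s * (rot @ cb),
        scale=s,
    )


def kabsch_rmsd(a, b, allow_reflection: bool = False, fit_scale: bool = False) -> float:
    return kabsch_superpose(a, b, allow_reflection, fit_scale).rmsd


def fish_correlation(
    d,
    bench: BenchmarkDistances,
    blocks: list[tuple[tuple[int, int], tuple[int, int]]] | None = None,
) -> float:
    """Pearson correlation between model distances and a benchmark table.

    ``d`` is a dense distance matrix (NaN = undefined) or a
    :class:`WishDistances`.  When ``blocks`` are supplied — one pair of
    half-open bead intervals per benchmark record, as for imaging probes
    wider than one bead — each benchmark distance is compared against
    the mean model distance over all inter-block bead pairs.
    """
    if isinstance(d, WishDistances):
        dm = d.dense()
    else:
        dm = np.asarray(d, dtype=float)
    model_vals, ref_vals = [], []
    if blocks is not None:
        if len(blocks) != len(bench):
            raise ValueError("need one block pair per benchmark record")
        for ((a0, a1), (b0, b1)), ref in zip(blocks, bench.d):
            sub = dm[a0:a1, b0:b1]
            good = np.isfinite(sub)
            if good.any():
                model_vals.append(float(sub[good].mean()))
                ref_vals.append(float(ref))
    else:
        for i, j, ref in zip(bench.i, bench.j, bench.d):
            v = dm[i, j]
            if np.isfinite(v):
                model_vals.append(float(v))
                ref_vals.append(float(ref))
    if len(model_vals) < 3:
        raise ValueError(
            f"fewer than 3 usable benchmark records ({len(model_vals)})"
        )
    r, _ = pearsonr(model_vals, ref_vals)
    return float(r)
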