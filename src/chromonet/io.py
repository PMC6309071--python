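"""Readers and writers for the plain-text formats the pipeline consumes.

Contact matrices come in two neutral carriers: dense whitespace-delimited
``n x n`` text and sparse COO triples (``i j value`` per line, 0-based bead
indices).  Domain intervals arrive as standard BED (0-based, half-open, bp
coordinates) and are converted to bead intervals.  Structures go out as XYZ
(``bead x y z``) or a minimal one-CA-per-bead PDB that any molecular viewer
can render.  Benchmark distance tables (FISH / ChIA-PET style) are TSV.

All bead indices are 0-based throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ContactMatrix",
    "TadIntervals",
    "BenchmarkDistances",
    "read_contact_matrix",
    "write_contact_matrix",
    "read_tads",
    "read_benchmark",
    "write_benchmark",
    "write_structure",
    "read_structure",
]

#: relative asymmetry beyond which an input matrix is rejected instead of
#: being silently symmetrized
ASYMMETRY_TOLERANCE = 1e-6


@dataclass
class ContactMatrix:
    """A normalized, symmetric intra-chromosomal contact matrix.

    Each row/column corresponds to one fixed-size genomic bin ("bead").
    The matrix is symmetrized by averaging on construction; asymmetry
    beyond :data:`ASYMMETRY_TOLERANCE` (relative) is an error, because
    normalized matrices legitimately carry only tiny float asymmetry.
    Diagonal entries are retained but treated as zero (self-contacts are
    never used) by :meth:`masked`.
    """

    values: np.ndarray
    bin_size: int = 40_000
    chrom: str = "chr"

    def __post_init__(self) -> None:
        m = np.asarray(self.values, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"contact matrix must be square, got shape {m.shape}")
        if m.shape[0] < 3:
            raise ValueError(f"need at least 3 beads, got {m.shape[0]}")
        bad = np.where(np.isnan(m).any(axis=1))[0]
        if bad.size:
            raise ValueError(f"NaN entries in contact matrix at row {bad[0]}")
        neg = np.where((m < 0).any(axis=1))[0]
        if neg.size:
            raise ValueError(f"negative contact value at row {neg[0]}")
        scale = max(float(np.abs(m).max()), 1e-300)
        asym = float(np.abs(m - m.T).max()) / scale
        if asym > ASYMMETRY_TOLERANCE:
            raise ValueError(
                f"matrix asymmetric beyond tolerance (relative asymmetry {asym:.3g})"
            )
        self.values = 0.5 * (m + m.T)
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def masked(self) -> np.ndarray:
        """Contact values with the diagonal zeroed (self-contacts ignored)."""
        out = self.values.copy()
        np.fill_diagonal(out, 0.0)
        return out


@dataclass
class TadIntervals:
    """Non-overlapping, sorted half-open bead-index intervals [start, end)."""

    intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        iv = sorted((int(a), int(b)) for a, b in self.intervals)
        for a, b in iv:
            if a < 0 or b <= a:
                raise ValueError(f"invalid interval [{a}, {b})")
        for (a0, b0), (a1, b1) in zip(iv, iv[1:]):
            if a1 < b0:
                raise ValueError(f"overlapping intervals [{a0},{b0}) and [{a1},{b1})")
        self.intervals = iv

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[tuple[int, int]]:
        return iter(self.intervals)

    def bead_labels(self, n: int) -> np.ndarray:
        """Per-bead domain index, -1 for beads outside every interval."""
        lab = np.full(n, -1, dtype=int)
        for t, (a, b) in enumerate(self.intervals):
            lab[a : min(b, n)] = t
        return lab


@dataclass
class BenchmarkDistances:
    """External reference distances between bead pairs (FISH-style tables)."""

    i: np.ndarray
    j: np.ndarray
    d: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.i = np.asarray(self.i, dtype=int)
        self.j = np.asarray(self.j, dtype=int)
        self.d = np.asarray(self.d, dtype=float)
        if not (self.i.shape == self.j.shape == self.d.shape):
            raise ValueError("i, j, d must have equal length")
        if np.any(self.i == self.j):
            raise ValueError("benchmark records must have i != j")
        if np.any(self.d <= 0):
            raise ValueError("benchmark distances must be positive")
        if not self.labels:
            self.labels = [""] * len(self.d)

    def __len__(self) -> int:
        return len(self.d)


def read_contact_matrix(
    path: str | Path,
    fmt: str = "dense",
    bin_size: int = 40_000,
    n: int | None = None,
    chrom: str = "chr",
) -> ContactMatrix:
    """Read a contact matrix from ``dense`` or ``coo`` text.

    Dense: whitespace-delimited ``n x n`` numbers.  COO: one ``i j value``
    triple per line with 0-based bead indices; ``n`` may be declared
    explicitly or is inferred as ``max index + 1``.  The result is
    symmetrized by averaging with its transpose.
    """
    path = Path(path)
    if fmt == "dense":
        try:
            m = np.loadtxt(path, dtype=float, ndmin=2)
        except ValueError as exc:
            raise ValueError(f"could not parse dense matrix {path}: {exc}") from exc
        if m.shape[0] != m.shape[1]:
            raise ValueError(
                f"{path}: dense matrix is not square ({m.shape[0]}x{m.shape[1]})"
            )
    elif fmt == "coo":
        tri = np.loadtxt(path, dtype=float, ndmin=2)
        if tri.size == 0:
            raise ValueError(f"{path}: empty COO file")
        if tri.shape[1] != 3:
            raise ValueError(f"{path}: COO lines must be 'i j value'")
        ii = tri[:, 0].astype(int)
        jj = tri[:, 1].astype(int)
        vv = tri[:, 2]
        size = int(max(ii.max(), jj.max())) + 1 if n is None else int(n)
        if size <= max(ii.max(), jj.max()):
            raise ValueError(f"{path}: declared n={size} smaller than max index")
        m = np.zeros((size, size))
        m[ii, jj] = vv
        m[jj, ii] = vv
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'dense' or 'coo')")
    return ContactMatrix(values=m, bin_size=bin_size, chrom=chrom)


def write_contact_matrix(cm: ContactMatrix, path: str | Path, fmt: str = "dense") -> None:
    path = Path(path)
    if fmt == "dense":
        np.savetxt(path, cm.values, fmt="%.12g")
    elif fmt == "coo":
        i, j = np.nonzero(np.triu(cm.values))
        with open(path, "w") as fh:
            for a, b in zip(i, j):
                fh.write(f"{a} {b} {cm.values[a, b]:.12g}\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_tads(path: str | Path, bin_size: int = 40_000) -> TadIntervals:
    """Read BED intervals (bp, 0-based half-open) and convert to bead indices.

    bp -> bead conversion is ``floor(start / bin_size)``,
    ``ceil(end / bin_size)``.  Overlaps after conversion are an error.
    """
    intervals: list[tuple[int, int]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: BED line needs chrom/start/end")
        start, end = int(parts[1]), int(parts[2])
        if end <= start:
            raise ValueError(f"{path}:{lineno}: end <= start")
        intervals.append((start // bin_size, math.ceil(end / bin_size)))
    return TadIntervals(intervals)


def read_benchmark(path: str | Path) -> BenchmarkDistances:
    """Read a benchmark table: TSV/whitespace columns ``i j distance [label]``.

    A header line is tolerated and skipped.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    # drop a header row if the first row is not numeric
    try:
        float(df.iloc[0, 0])
    except ValueError:
        df = df.iloc[1:].reset_index(drop=True)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: need at least 3 columns (i, j, distance)")
    labels = df.iloc[:, 3].astype(str).tolist() if df.shape[1] > 3 else []
    return BenchmarkDistances(
        i=df.iloc[:, 0].astype(float).astype(int).to_numpy(),
        j=df.iloc[:, 1].astype(float).astype(int).to_numpy(),
        d=df.iloc[:, 2].astype(float).to_numpy(),
        labels=labels,
    )


def write_benchmark(bench: BenchmarkDistances, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("i\tj\tdistance\tlabel\n")
        for a, b, d, lab in zip(bench.i, bench.j, bench.d, bench.labels):
            fh.write(f"{a}\t{b}\t{d:.12g}\t{lab}\n")


def _coords_of(obj) -> np.ndarray:
    coords = getattr(obj, "coords", obj)
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError(f"expected (n, 3) coordinates, got shape {coords.shape}")
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates cannot be written")
    return coords


def write_structure(coords, path: str | Path, fmt: str = "xyz") -> None:
    """Write 3D bead coordinates as XYZ lines or a minimal CA-only PDB.

    The PDB writer emits one pseudo-atom per bead (CA records, sequential
    residue numbers modulo PDB's 4-digit field) so standard molecular
    viewers can render the chain; it is a writer only, not a general PDB
    implementation.
    """
    xyz = _coords_of(coords)
    path = Path(path)
    if fmt == "xyz":
        with open(path, "w") as fh:
            for idx, (x, y, z) in enumerate(xyz):
                fh.write(f"{idx} {x:.6f} {y:.6f} {z:.6f}\n")
    elif fmt == "pdb":
        with open(path, "w") as fh:
            for idx, (x, y, z) in enumerate(xyz):
                serial = (idx + 1) % 100_000
                resseq = (idx + 1) % 10_000
                fh.write(
                    f"ATOM  {serial:5d}  CA  GLY A{resseq:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
                )
            fh.write("END\n")
    else:
        raise ValueError(f"unknown structure format {fmt!r}")


def read_structure(path: str | Path) -> np.ndarray:
    """Read XYZ lines (``bead x y z``) back into an (n, 3) array."""
    data = np.loadtxt(path, dtype=float, ndmin=2)
    if data.shape[1] != 4:
        raise ValueError(f"{path}: expected 4 columns (bead, x, y, z)")
    order = np.argsort(data[:, 0])
    return data[order, 1:4]
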