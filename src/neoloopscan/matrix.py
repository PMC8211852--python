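"""Binned contact matrices: construction, balancing, expectation, scaling.

The container keeps one sparse upper-triangle count matrix per chromosome
pair. Knight-Ruiz balancing weights are stored per chromosome; masked
(under-covered) bins carry NaN weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

from .genome import GenomeModel

__all__ = [
    "ContactMatrix",
    "DecayProfile",
    "KrReport",
    "bin_contacts",
    "kr_balance",
    "expected_by_distance",
    "cis_depth_normalize",
    "read_pairs",
    "write_pairs",
]


@dataclass
class KrReport:
    converged: bool
    iterations: int
    residual: float
    method: str = "knight-ruiz"


@dataclass
class DecayProfile:
    """Mean (balanced) contact value per diagonal distance, in bins."""

    values: np.ndarray  # mean at distance d
    counts: np.ndarray  # unmasked pairs contributing at distance d

    def expected(self, d: int) -> float:
        d = min(abs(int(d)), len(self.values) - 1)
        return float(self.values[d])


class ContactMatrix:
    """Sparse per-chromosome-pair contact counts at one bin size."""

    def __init__(self, genome: GenomeModel, binsize: int):
        self.genome = genome
        self.binsize = int(binsize)
        self._data: dict[tuple[str, str], sp.csr_matrix] = {}
        self.weights: dict[str, np.ndarray] = {}

    # -- construction ---------------------------------------------------
    def _shape(self, c1: str, c2: str) -> tuple[int, int]:
        return self.genome.n_bins(c1, self.binsize), self.genome.n_bins(c2, self.binsize)

    def add_pair(self, c1: str, c2: str, mat: sp.spmatrix) -> None:
        key = (c1, c2)
        m = sp.csr_matrix(mat)
        if key in self._data:
            m = self._data[key] + m
        self._data[key] = m

    def pairs(self) -> Iterable[tuple[str, str]]:
        return self._data.keys()

    def cis_chroms(self) -> list[str]:
        return [c1 for (c1, c2) in self._data if c1 == c2]

    def matrix(self, c1: str, c2: str) -> sp.csr_matrix:
        key = (c1, c2)
        if key not in self._data:
            return sp.csr_matrix(self._shape(c1, c2))
        return self._data[key]

    def dense(self, chrom: str, balanced: bool = False) -> np.ndarray:
        """Symmetric dense cis matrix; balanced applies KR weights (NaN masked)."""
        m = self.matrix(chrom, chrom).toarray()
        m = m + np.triu(m, 1).T
        if balanced:
            w = self.weights.get(chrom)
            if w is None:
                raise ValueError(f"no balancing weights for {chrom}; run kr_balance first")
            m = m * np.outer(w, w)
        return m

    # -- totals ---------------------------------------------------------
    @property
    def cis_total(self) -> float:
        return float(sum(m.sum() for (c1, c2), m in self._data.items() if c1 == c2))

    @property
    def trans_total(self) -> float:
        return float(sum(m.sum() for (c1, c2), m in self._data.items() if c1 != c2))

    def scaled(self, factor: float) -> "ContactMatrix":
        out = ContactMatrix(self.genome, self.binsize)
        for key, m in self._data.items():
            out._data[key] = m * factor
        out.weights = {c: w.copy() for c, w in self.weights.items()}
        return out

    def copy(self) -> "ContactMatrix":
        return self.scaled(1.0)

    # -- I/O --------------------------------------------------------------
    def write(self, prefix: str | Path) -> None:
        """COO TSV (chrom1 bin1 chrom2 bin2 value) plus a JSON sidecar."""
        prefix = Path(prefix)
        with open(prefix.with_suffix(".coo.tsv"), "w") as fh:
            fh.write("chrom1\tbin1\tchrom2\tbin2\tvalue\n")
            for (c1, c2), m in sorted(self._data.items()):
                coo = m.tocoo()
                for i, j, v in zip(coo.row, coo.col, coo.data):
                    fh.write(f"{c1}\t{i}\t{c2}\t{j}\t{v:.6g}\n")
        side = {
            "binsize": self.binsize,
            "chromosomes": self.genome.chromosomes,
            "cis_total": self.cis_total,
            "weights": {c: [None if np.isnan(x) else x for x in w] for c, w in self.weights.items()},
        }
        with open(prefix.with_suffix(".json"), "w") as fh:
            json.dump(side, fh)

    @classmethod
    def read(cls, prefix: str | Path, genome: GenomeModel | None = None) -> "ContactMatrix":
        prefix = Path(prefix)
        with open(prefix.with_suffix(".json")) as fh:
            side = json.load(fh)
        if genome is None:
            genome = GenomeModel(side["chromosomes"], binsize=side["binsize"])
        out = cls(genome, side["binsize"])
        buf: dict[tuple[str, str], list[tuple[int, int, float]]] = {}
        with open(prefix.with_suffix(".coo.tsv")) as fh:
            next(fh)
            for line in fh:
                c1, b1, c2, b2, v = line.split("\t")
                buf.setdefault((c1, c2), []).append((int(b1), int(b2), float(v)))
        for (c1, c2), triples in buf.items():
            i, j, v = zip(*triples)
            shape = out._shape(c1, c2)
            out._data[(c1, c2)] = sp.csr_matrix(sp.coo_matrix((v, (i, j)), shape=shape))
        out.weights = {
            c: np.array([np.nan if x is None else x for x in w], dtype=float)
            for c, w in side.get("weights", {}).items()
        }
        return out


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def bin_contacts(
    records,
    genome: GenomeModel,
    binsize: int,
) -> ContactMatrix:
    """Bin 1-based contact records into a :class:`ContactMatrix`.

    ``records`` is an iterable of ``(chrom1, pos1, chrom2, pos2[, count])``
    tuples or a DataFrame with those columns. Bin index is
    ``(pos - 1) // binsize``; pairs are folded to canonical orientation
    (genome chromosome order, ``i <= j`` in cis); total count is conserved.
    """
    import pandas as pd

    if isinstance(records, pd.DataFrame):
        rows = records.itertuples(index=False)
    else:
        rows = records

    buf: dict[tuple[str, str], dict[tuple[int, int], float]] = {}
    for rec in rows:
        if len(rec) == 4:
            c1, p1, c2, p2 = rec
            cnt = 1.0
        else:
            c1, p1, c2, p2, cnt = rec[:5]
        b1 = genome.bin_of(c1, int(p1), binsize)
        b2 = genome.bin_of(c2, int(p2), binsize)
        cc1, cc2, swapped = genome.canonical_pair(c1, c2)
        if swapped:
            b1, b2 = b2, b1
        if cc1 == cc2 and b1 > b2:
            b1, b2 = b2, b1
        buf.setdefault((cc1, cc2), {})[(b1, b2)] = buf.setdefault((cc1, cc2), {}).get((b1, b2), 0.0) + float(cnt)

    out = ContactMatrix(genome, binsize)
    for (c1, c2), cells in buf.items():
        ij = np.array(list(cells.keys()), dtype=int)
        v = np.fromiter(cells.values(), dtype=float, count=len(cells))
        n1, n2 = out._shape(c1, c2)
        out._data[(c1, c2)] = sp.csr_matrix(sp.coo_matrix((v, (ij[:, 0], ij[:, 1])), shape=(n1, n2)))
    return out


# ---------------------------------------------------------------------------
# Knight-Ruiz balancing
# ---------------------------------------------------------------------------

def mask_bins(dense: np.ndarray, percentile: float = 1.0) -> np.ndarray:
    """Boolean mask of usable bins: nonzero marginal above the percentile cut."""
    marg = dense.sum(axis=0)
    nonzero = marg[marg > 0]
    if len(nonzero) == 0:
        return np.zeros(len(marg), dtype=bool)
    cut = np.percentile(nonzero, percentile)
    # relative slack so near-tied marginals (e.g. an already balanced
    # matrix) are not masked by interpolation noise in the percentile
    return marg >= max(cut * (1.0 - 1e-4), np.finfo(float).tiny)


def _kr_bnewt(A: np.ndarray, tol: float, max_outer: int) -> tuple[np.ndarray, KrReport]:
    """Knight-Ruiz inner-outer Newton iteration for doubly stochastic scaling."""
    n = A.shape[0]
    e = np.ones(n)
    x = e.copy()
    delta, Delta = 0.1, 3.0
    g, etamax = 0.9, 0.1
    eta = etamax
    rt = tol**2
    v = x * (A @ x)
    rk = 1.0 - v
    rho_km1 = rk @ rk
    rout = rold = rho_km1
    it = 0
    mvp = 0
    while rout > rt and it < max_outer:
        it += 1
        k = 0
        rho_km2 = rho_km1
        innertol = max(eta**2 * rout, rt)
        y = e.copy()
        while rho_km1 > innertol:
            k += 1
            if k == 1:
                Z = rk / v
                p = Z
                rho_km1 = rk @ Z
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            w = x * (A @ (x * p)) + v * p
            alpha = rho_km1 / (p @ w)
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                if delta == 0:
                    break
                ind = ap < 0
                gamma = ((delta - y[ind]) / ap[ind]).min()
                y = y + gamma * ap
                break
            if ynew.max() >= Delta:
                ind = ynew > Delta
                gamma = ((Delta - y[ind]) / ap[ind]).min()
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = rk @ Z
            mvp += 1
            if mvp > 50 * n:
                break
        x = x * y
        v = x * (A @ x)
        rk = 1.0 - v
        rho_km1 = rk @ rk
        rout = rho_km1
        rat = rout / rold
        rold = rout
        res_norm = np.sqrt(rout)
        eta = g * rat
        eta = min(max(eta, 0.5 * etamax * rout / res_norm if res_norm > 0 else eta), etamax)
    return x, KrReport(converged=rout <= rt, iterations=it, residual=float(np.sqrt(max(rout, 0.0))))


def _sinkhorn(A: np.ndarray, tol: float, max_iter: int = 3000) -> tuple[np.ndarray, KrReport]:
    n = A.shape[0]
    x = np.ones(n)
    res = np.inf
    for it in range(max_iter):
        s = x * (A @ x)
        res = float(np.abs(s - 1.0).max())
        if res < tol:
            return x, KrReport(True, it, res, method="sinkhorn")
        x = x / np.sqrt(s)
    return x, KrReport(False, max_iter, res, method="sinkhorn")


def kr_balance(
    matrix: ContactMatrix,
    chrom: str,
    tolerance: float = 1e-6,
    max_iterations: int = 300,
) -> tuple[np.ndarray, KrReport]:
    """Knight-Ruiz balance one cis matrix; weights stored on the container.

    Weights ``w`` satisfy ``sum_j w_i M_ij w_j = 1`` on unmasked bins at
    convergence; masked bins get NaN. Falls back to Sinkhorn iteration when
    the Newton scheme stalls; if that also fails, the last iterate is
    returned with ``converged=False``.
    """
    dense = matrix.dense(chrom)
    keep = mask_bins(dense)
    if keep.sum() < 2:
        raise ValueError(f"{chrom}: fewer than 2 unmasked bins, cannot balance")
    A = dense[np.ix_(keep, keep)]
    x, report = _kr_bnewt(A, tolerance, max_iterations)
    if not report.converged:
        x2, rep2 = _sinkhorn(A, tolerance)
        if rep2.residual < report.residual:
            x, report = x2, rep2
    w = np.full(dense.shape[0], np.nan)
    w[keep] = x
    matrix.weights[chrom] = w
    return w, report


# ---------------------------------------------------------------------------
# expected-by-distance and depth normalization
# ---------------------------------------------------------------------------

def expected_by_distance(matrix: ContactMatrix, chrom: str, balanced: bool = False) -> DecayProfile:
    """Mean contact value per diagonal offset over unmasked bin pairs."""
    dense = matrix.dense(chrom, balanced=balanced)
    if balanced:
        valid = ~np.isnan(matrix.weights[chrom])
        dense = np.where(np.outer(valid, valid), dense, np.nan)
    else:
        valid = mask_bins(matrix.dense(chrom))
        dense = np.where(np.outer(valid, valid), dense, np.nan)
    n = dense.shape[0]
    values = np.zeros(n)
    counts = np.zeros(n, dtype=int)
    for d in range(n):
        diag = np.diagonal(dense, offset=d)
        ok = ~np.isnan(diag)
        counts[d] = int(ok.sum())
        values[d] = float(diag[ok].mean()) if counts[d] else 0.0
    return DecayProfile(values=values, counts=counts)


def cis_depth_normalize(
    matrices: Sequence[ContactMatrix],
    target: float | None = None,
) -> list[ContactMatrix]:
    """Scale each matrix so its cis total equals a common target.

    Default target is 1e6 ("contacts per million cis pairs"). Within-matrix
    entry ratios are unchanged.
    """
    if len(matrices) == 0:
        raise ValueError("need at least one matrix")
    tgt = 1e6 if target is None else float(target)
    out = []
    for m in matrices:
        ct = m.cis_total
        if ct <= 0:
            raise ValueError("matrix has zero cis total; cannot depth-normalize")
        out.append(m.scaled(tgt / ct))
    return out


# ---------------------------------------------------------------------------
# pairs text I/O
# ---------------------------------------------------------------------------

def write_pairs(records, path: str | Path, genome: GenomeModel, binsize: int | None = None) -> None:
    """Whitespace-separated ``chrom1 pos1 chrom2 pos2 count`` with # header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# pairs-like contact records; positions 1-based\n")
        for name, length in genome.chromosomes.items():
            fh.write(f"# chromsize: {name} {length}\n")
        if binsize:
            fh.write(f"# binsize: {binsize}\n")
        for rec in records:
            fh.write(" ".join(str(x) for x in rec) + "\n")


def read_pairs(path: str | Path) -> tuple[list[tuple], dict[str, int], int | None]:
    """Read a pairs-like file; returns (records, chromsizes, binsize)."""
    records: list[tuple] = []
    chromsizes: dict[str, int] = {}
    binsize = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("chromsize:"):
                    _, name, length = body.split()
                    chromsizes[name] = int(length)
                elif body.startswith("binsize:"):
                    binsize = int(body.split()[1])
                continue
            parts = line.split()
            c1, p1, c2, p2 = parts[0], int(parts[1]), parts[2], int(parts[3])
            cnt = float(parts[4]) if len(parts) > 4 else 1.0
            records.append((c1, p1, c2, p2, cnt))
    return records, chromsizes, binsize
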