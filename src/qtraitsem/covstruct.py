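"""Genetic covariance structures: the (S, V) pair produced by multivariate LDSC.

S is the p x p genetic covariance matrix (SNP heritabilities on the diagonal,
coheritabilities off it).  V is the sampling covariance matrix of the
half-vectorized S, of dimension m x m with m = p(p+1)/2; its diagonal holds
squared standard errors of the elements of S and its off-diagonals capture
dependence between estimation errors, e.g. from participant sample overlap.

All half-vectorization in this package uses the lower triangle in
column-major order: (1,1), (2,1), ..., (p,1), (2,2), (3,2), ..., (p,p).
The rows/columns of V must follow the same ordering.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CovStruct",
    "vech",
    "unvech",
    "vech_index",
    "smooth_to_pd",
    "to_correlation",
    "load_covstruct",
    "write_covstruct",
    "SmoothResult",
]

_S_SYM_TOL = 1e-10
_V_SYM_TOL = 1e-8

VECH_CONVENTION = "lower-triangle column-major: (1,1),(2,1),...,(p,1),(2,2),...,(p,p)"


def vech(M: np.ndarray) -> np.ndarray:
    """Half-vectorize a symmetric matrix (lower triangle, column-major)."""
    M = np.asarray(M, dtype=float)
    q = M.shape[0]
    if M.shape != (q, q):
        raise ValueError(f"vech expects a square matrix, got shape {M.shape}")
    rows, cols = np.tril_indices(q)
    # tril_indices is row-major over the lower triangle; column-major order of
    # the lower triangle is obtained by sorting on (col, row).
    order = np.lexsort((rows, cols))
    return M[rows[order], cols[order]]


def unvech(v: Sequence[float], q: int) -> np.ndarray:
    """Inverse of :func:`vech` for a q x q symmetric matrix."""
    v = np.asarray(v, dtype=float)
    m = q * (q + 1) // 2
    if v.shape != (m,):
        raise ValueError(f"unvech: expected length {m} for q={q}, got {v.shape}")
    M = np.zeros((q, q))
    rows, cols = np.tril_indices(q)
    order = np.lexsort((rows, cols))
    M[rows[order], cols[order]] = v
    M[cols[order], rows[order]] = v
    return M


def vech_index(i: int, j: int, p: int) -> int:
    """Position of element (i, j) (0-based) of a p x p symmetric matrix in vech order."""
    if i < j:
        i, j = j, i
    return j * p - j * (j - 1) // 2 + (i - j)


class SmoothResult(NamedTuple):
    matrix: np.ndarray
    smoothed: bool
    max_change: float


def smooth_to_pd(M: np.ndarray, min_eigenvalue: float = 0.0) -> SmoothResult:
    """Project a symmetric matrix to the nearest one with eigenvalues >= floor.

    Eigenvalue clipping in the Frobenius metric: eigenvalues below
    ``min_eigenvalue`` are raised to it and the matrix recomposed.  If no
    eigenvalue violates the floor the input is returned unchanged.  Used to
    make indefinite LDSC-derived S or V matrices usable as weight matrices.
    """
    M = np.asarray(M, dtype=float)
    eigval, eigvec = np.linalg.eigh(M)
    tol = 1e-10 * max(1.0, float(np.abs(eigval).max(initial=0.0)))
    if eigval.min() >= min_eigenvalue - tol:
        return SmoothResult(M, False, 0.0)
    clipped = np.maximum(eigval, min_eigenvalue)
    out = (eigvec * clipped) @ eigvec.T
    out = (out + out.T) / 2.0
    return SmoothResult(out, True, float(np.abs(out - M).max()))


def to_correlation(cs: "CovStruct") -> np.ndarray:
    """Genetic correlation matrix rg_jk = S_jk / sqrt(S_jj * S_kk)."""
    d = np.diag(cs.S)
    bad = np.flatnonzero(d <= 0)
    if bad.size:
        names = ", ".join(cs.trait_names[i] for i in bad)
        raise ValueError(
            f"cannot standardize: non-positive heritability for trait(s) {names}"
        )
    inv_sd = 1.0 / np.sqrt(d)
    R = cs.S * np.outer(inv_sd, inv_sd)
    np.fill_diagonal(R, 1.0)
    return R


@dataclass
class CovStruct:
    """A validated (S, V, trait names) triple.

    Parameters
    ----------
    trait_names
        Ordered, unique trait identifiers; the row/column order of ``S``
        defines the canonical trait order for everything downstream.
    S
        p x p symmetric genetic covariance matrix.
    V
        m x m symmetric sampling covariance matrix of vech(S), m = p(p+1)/2.
    provenance
        Free-text metadata carried through serialization.
    """

    trait_names: list[str]
    S: np.ndarray
    V: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.trait_names = list(self.trait_names)
        self.S = np.asarray(self.S, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        p = len(self.trait_names)
        if p == 0:
            raise ValueError("trait_names must be non-empty")
        if len(set(self.trait_names)) != p:
            raise ValueError("trait_names must be unique")
        if self.S.shape != (p, p):
            raise ValueError(f"S must be {p}x{p}, got {self.S.shape}")
        m = p * (p + 1) // 2
        if self.V.shape != (m, m):
            raise ValueError(
                f"V must be {m}x{m} for p={p}, got {self.V.shape[0]}x{self.V.shape[1]}"
            )
        if np.abs(self.S - self.S.T).max() > _S_SYM_TOL:
            raise ValueError(f"S is asymmetric beyond tolerance {_S_SYM_TOL}")
        if np.abs(self.V - self.V.T).max() > _V_SYM_TOL:
            raise ValueError(f"V is asymmetric beyond tolerance {_V_SYM_TOL}")
        if np.any(np.diag(self.V) < 0):
            raise ValueError("V has negative diagonal entries (squared SEs)")
        # enforce exact symmetry after validation
        self.S = (self.S + self.S.T) / 2.0
        self.V = (self.V + self.V.T) / 2.0

    @property
    def p(self) -> int:
        return len(self.trait_names)

    @property
    def m(self) -> int:
        return self.p * (self.p + 1) // 2

    def index_of(self, name: str) -> int:
        try:
            return self.trait_names.index(name)
        except ValueError:
            raise KeyError(f"trait {name!r} not in covariance structure") from None

    def subset(self, names: Sequence[str]) -> "CovStruct":
        """Restrict to the given traits, in the given order.

        The sub-block of V is extracted consistently with the vech convention:
        sub-element (a, b) maps to the full vech position of the corresponding
        original trait pair.
        """
        pos = [self.index_of(n) for n in names]
        S_sub = self.S[np.ix_(pos, pos)]
        q = len(pos)
        idx = []
        for c in range(q):
            for r in range(c, q):
                idx.append(vech_index(pos[r], pos[c], self.p))
        idx = np.asarray(idx)
        V_sub = self.V[np.ix_(idx, idx)]
        return CovStruct(list(names), S_sub, V_sub, dict(self.provenance))

    def smoothed(self, min_eigenvalue: float = 1e-10) -> "CovStruct":
        """Return a copy with S and V floored to positive definiteness."""
        sS = smooth_to_pd(self.S, min_eigenvalue)
        sV = smooth_to_pd(self.V, min_eigenvalue)
        for label, res in (("S", sS), ("V", sV)):
            if res.smoothed:
                warnings.warn(
                    f"{label} was not positive definite; eigenvalues floored at "
                    f"{min_eigenvalue:g} (max elementwise change {res.max_change:.3g})",
                    stacklevel=2,
                )
        return CovStruct(self.trait_names, sS.matrix, sV.matrix, dict(self.provenance))


def load_covstruct(path: str | Path, format: str = "json_bundle") -> CovStruct:
    """Load a covariance structure from disk.

    ``json_bundle``: a single JSON document with keys ``trait_names``, ``S``
    (list of rows), ``V`` (list of rows) and optional ``provenance``.

    ``tsv_pair``: a directory holding ``S.tsv`` (trait names as header and
    leading label column) and ``V.tsv`` (no header), plus a one-line sidecar
    ``V.convention.txt`` naming the vech ordering.
    """
    path = Path(path)
    if format == "json_bundle":
        with open(path) as fh:
            doc = json.load(fh)
        for key in ("trait_names", "S", "V"):
            if key not in doc:
                raise ValueError(f"json bundle missing key {key!r}")
        return CovStruct(
            doc["trait_names"],
            np.asarray(doc["S"], dtype=float),
            np.asarray(doc["V"], dtype=float),
            doc.get("provenance", {}),
        )
    if format == "tsv_pair":
        s_df = pd.read_csv(path / "S.tsv", sep="\t", index_col=0, float_precision="round_trip")
        names = [str(c) for c in s_df.columns]
        if list(map(str, s_df.index)) != names:
            raise ValueError("S.tsv row labels do not match column header")
        V = pd.read_csv(
            path / "V.tsv", sep="\t", header=None, float_precision="round_trip"
        ).to_numpy(dtype=float)
        return CovStruct(names, s_df.to_numpy(dtype=float), V, {"source": str(path)})
    raise ValueError(f"unknown format {format!r}; use 'tsv_pair' or 'json_bundle'")


def write_covstruct(cs: CovStruct, path: str | Path, format: str = "json_bundle") -> None:
    """Serialize a covariance structure (inverse of :func:`load_covstruct`)."""
    path = Path(path)
    if format == "json_bundle":
        doc = {
            "trait_names": cs.trait_names,
            "S": cs.S.tolist(),
            "V": cs.V.tolist(),
            "provenance": cs.provenance,
            "vech_convention": VECH_CONVENTION,
        }
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
        return
    if format == "tsv_pair":
        path.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(cs.S, index=cs.trait_names, columns=cs.trait_names).to_csv(
            path / "S.tsv", sep="\t"
        )
        pd.DataFrame(cs.V).to_csv(path / "V.tsv", sep="\t", header=False, index=False)
        (path / "V.convention.txt").write_text(VECH_CONVENTION + "\n")
        return
    raise ValueError(f"unknown format {format!r}; use 'tsv_pair' or 'json_bundle'")
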