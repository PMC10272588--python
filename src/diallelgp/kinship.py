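"""Relationship kernels and in-silico single-cross genotype matrices.

Four kernels are built here:

* ``Gp`` — parental genomic relationship from centered, standardized
  markers, ``Wp Wp' / p`` (average diagonal ~1, so the GCA variance is on
  the residual scale);
* ``Ga`` — additive relationship of single crosses (VanRaden scaling),
  ``Z Z' / (2 sum p_i (1 - p_i))`` with columns centered by ``2 p_i``;
* ``Gd`` — dominance relationship, ``Zd Zd' / (4 sum (p_i(1-p_i))^2)`` with
  the heterozygosity codes centered by ``2 p_i (1 - p_i)``;
* ``H`` — the specific-combining-ability kernel of crosses, the
  parent-order-symmetrized subset of the Kronecker product ``Gp x Gp``.

Single-cross genotypes are assembled in silico from fully homozygous
parents: the additive code is the parental mean dosage and the dominance
code flags loci where the parents carry different homozygotes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "HybridDesign",
    "HybridGenotypes",
    "KinshipMatrix",
    "cross_id",
    "build_hybrid_genotypes",
    "gp_matrix",
    "additive_G",
    "dominance_G",
    "sca_kernel",
]

RIDGE = 1e-6  # added to kernel diagonals before any inverse downstream


def cross_id(a, b) -> str:
    return f"{a}x{b}"


@dataclass
class HybridDesign:
    """Ordered list of unordered parent pairs with observed/to-predict flags."""

    crosses: list  # [(parent_a, parent_b), ...]
    observed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.crosses = [tuple(c) for c in self.crosses]
        seen = set()
        for a, b in self.crosses:
            if a == b:
                raise ValueError(f"self-cross {a} x {b} not allowed")
            key = frozenset((a, b))
            if key in seen:
                raise ValueError(f"duplicated cross {a} x {b}")
            seen.add(key)
        if self.observed is None:
            self.observed = np.ones(len(self.crosses), dtype=bool)
        else:
            self.observed = np.asarray(self.observed, dtype=bool)
            if len(self.observed) != len(self.crosses):
                raise ValueError("observed flags do not match crosses")

    def __len__(self) -> int:
        return len(self.crosses)

    @property
    def cross_ids(self) -> np.ndarray:
        return np.asarray([cross_id(a, b) for a, b in self.crosses], dtype=object)

    @property
    def parents(self) -> list:
        out: list = []
        for a, b in self.crosses:
            for x in (a, b):
                if x not in out:
                    out.append(x)
        return out

    def subset(self, index) -> "HybridDesign":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return HybridDesign(
            crosses=[self.crosses[i] for i in index], observed=self.observed[index]
        )

    @classmethod
    def full_diallel(cls, parents, observed=True) -> "HybridDesign":
        crosses = [
            (parents[i], parents[j])
            for i in range(len(parents))
            for j in range(i + 1, len(parents))
        ]
        return cls(crosses=crosses, observed=np.full(len(crosses), observed))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parent_a": [a for a, _ in self.crosses],
                "parent_b": [b for _, b in self.crosses],
                "observed": self.observed,
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class HybridGenotypes:
    """Additive (0/1/2) and dominance (0/1) codes of in-silico crosses."""

    cross_ids: np.ndarray
    marker_ids: np.ndarray
    W_A: np.ndarray
    W_D: np.ndarray

    def allele_freq(self) -> np.ndarray:
        return self.W_A.mean(axis=0) / 2.0


@dataclass
class KinshipMatrix:
    ids: np.ndarray
    values: np.ndarray
    kind: str  # Gp | Ga | Gd | H

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError(f"{self.kind} kernel is not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def regularized(self, ridge: float = RIDGE) -> np.ndarray:
        return self.values + ridge * np.eye(self.n)

    def subset(self, ids) -> "KinshipMatrix":
        lookup = {i: k for k, i in enumerate(self.ids)}
        idx = np.array([lookup[i] for i in ids])
        return KinshipMatrix(
            ids=np.asarray(ids, dtype=object),
            values=self.values[np.ix_(idx, idx)],
            kind=self.kind,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="id")

    @classmethod
    def read(cls, path, kind: str) -> "KinshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(ids=df.index.to_numpy(dtype=object), values=df.to_numpy(float), kind=kind)


def build_hybrid_genotypes(G_parents: GenotypeMatrix, design: HybridDesign) -> HybridGenotypes:
    """Combine homozygous parental genotypes into single-cross codes.

    ``W_A`` is the parental mean dosage per marker (0, 1 or 2); ``W_D`` is 1
    exactly where the two parents carry different homozygotes. Parent order
    within a cross is immaterial.
    """
    het = np.argwhere(G_parents.dosages == 1.0)
    if het.size:
        i, j = het[0]
        raise ValueError(
            f"heterozygous parent dosage at line {G_parents.line_ids[i]!r}, "
            f"marker {G_parents.marker_ids[j]!r}; run hybrid-panel QC first"
        )
    if np.isnan(G_parents.dosages).any():
        raise ValueError("missing parent dosages; impute first")
    lookup = {l: i for i, l in enumerate(G_parents.line_ids)}
    try:
        ia = np.array([lookup[a] for a, _ in design.crosses])
        ib = np.array([lookup[b] for _, b in design.crosses])
    except KeyError as e:
        raise KeyError(f"cross parent {e} not in genotype matrix") from None
    Da, Db = G_parents.dosages[ia], G_parents.dosages[ib]
    return HybridGenotypes(
        cross_ids=design.cross_ids,
        marker_ids=G_parents.marker_ids.copy(),
        W_A=(Da + Db) / 2.0,
        W_D=(Da != Db).astype(float),
    )


def gp_matrix(G_parents: GenotypeMatrix) -> KinshipMatrix:
    """Parental genomic relationship from centered + standardized markers.

    Columns are centered and scaled to unit (population) variance, then
    ``Gp = Wp Wp' / p``; the mean diagonal equals 1 exactly under this
    scaling.
    """
    X = G_parents.dosages
    if np.isnan(X).any():
        raise ValueError("missing dosages; impute first")
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = G_parents.marker_ids[sd == 0][:5]
        raise ValueError(f"zero-variance (monomorphic) markers: {bad}")
    W = (X - X.mean(axis=0)) / sd
    Gp = W @ W.T / G_parents.n_markers
    return KinshipMatrix(ids=G_parents.line_ids, values=Gp, kind="Gp")


def additive_G(hyb: HybridGenotypes) -> KinshipMatrix:
    """Additive relationship of single crosses, VanRaden scaling.

    Allele frequencies are taken from the cross matrix itself (the modeled
    population); columns are centered by ``2 p_i`` and the kernel is
    normalized by ``2 sum p_i (1 - p_i)``.
    """
    p = hyb.allele_freq()
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all markers monomorphic across crosses")
    Z = hyb.W_A - 2.0 * p
    return KinshipMatrix(ids=hyb.cross_ids, values=Z @ Z.T / denom, kind="Ga")


def dominance_G(hyb: HybridGenotypes) -> KinshipMatrix:
    """Dominance relationship from heterozygosity codes.

    Columns of ``W_D`` are centered by ``2 p_i (1 - p_i)`` and the kernel is
    normalized by ``4 sum (p_i (1 - p_i))^2``.
    """
    if not hyb.W_D.any():
        raise ValueError("degenerate dominance matrix: no heterozygous cross anywhere")
    p = hyb.allele_freq()
    denom = 4.0 * np.sum((p * (1.0 - p)) ** 2)
    Zd = hyb.W_D - 2.0 * p * (1.0 - p)
    return KinshipMatrix(ids=hyb.cross_ids, values=Zd @ Zd.T / denom, kind="Gd")


def sca_kernel(
    Gp: KinshipMatrix, design: HybridDesign, symmetrize: bool = True
) -> KinshipMatrix:
    """Specific-combining-ability kernel: the cross-indexed subset of the
    Kronecker product ``Gp x Gp``.

    Crosses are unordered, so by default the entry for crosses (i,j),(k,l)
    is the parent-order-symmetrized ``0.5 * (Gp[i,k] Gp[j,l] + Gp[i,l]
    Gp[j,k])``; ``symmetrize=False`` gives the plain Kronecker lookup
    ``Gp[i,k] Gp[j,l]``.
    """
    lookup = {i: k for k, i in enumerate(Gp.ids)}
    try:
        ia = np.array([lookup[a] for a, _ in design.crosses])
        ib = np.array([lookup[b] for _, b in design.crosses])
    except KeyError as e:
        raise KeyError(f"unknown parent id {e}") from None
    G = Gp.values
    H = G[np.ix_(ia, ia)] * G[np.ix_(ib, ib)]
    if symmetrize:
        H = 0.5 * (H + G[np.ix_(ia, ib)] * G[np.ix_(ib, ia)])
    return KinshipMatrix(ids=design.cross_ids, values=H, kind="H")
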