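"""Genomic diallel analysis: GCA/SCA mixed model, SCA-based heterotic
groups, tester election, and North Carolina II cross enumeration.

The diallel model is ``y = Z_P g_P + Z_H h + e`` on the adjusted cross
means, where the general-combining-ability effects ``g_P`` of the parents
are correlated by the parental genomic kernel ``Gp`` (each cross's row of
``Z_P`` sums its two parents) and the specific-combining-ability effects
``h`` of the crosses are correlated by the Kronecker-derived kernel ``H``.

High SCA between two parents indicates complementary allele frequencies and
hence heterosis, so parents are partitioned into heterotic groups by
K-means on the completed SCA matrix: within a group SCA is low, between
groups high. Each group's tester is the line whose predicted crosses with
the opposite group are best on average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import lmm, structure
from .kinship import HybridDesign, KinshipMatrix, cross_id

__all__ = [
    "DiallelFit",
    "SCAMatrix",
    "HeteroticPartition",
    "fit_diallel",
    "complete_sca_matrix",
    "heterotic_partition",
    "choose_testers",
    "enumerate_ncii",
    "partition_concordance",
]


@dataclass
class DiallelFit:
    gca: pd.Series  # per parent
    sca: pd.Series  # per observed cross
    var_gca: float
    var_sca: float
    var_resid: float
    loglik: float
    fit: lmm.LMMFit


@dataclass
class SCAMatrix:
    """Parents x parents symmetric SCA surface; zero diagonal by convention
    (no self-crosses)."""

    parents: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.parents = np.asarray(self.parents, dtype=object)
        n = len(self.parents)
        if self.values.shape != (n, n):
            raise ValueError("SCA matrix shape does not match parents")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("SCA matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("SCA diagonal must be zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.parents, columns=self.parents)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="parent")


@dataclass
class HeteroticPartition:
    """Group label per parent, one tester per group, and provenance."""

    parents: np.ndarray
    groups: np.ndarray  # ints 1..k
    testers: dict | None = None  # group -> parent id
    trait: str | None = None

    def __post_init__(self) -> None:
        self.parents = np.asarray(self.parents, dtype=object)
        self.groups = np.asarray(self.groups, dtype=int)
        if len(self.parents) != len(self.groups):
            raise ValueError("groups do not match parents")
        if self.testers is not None:
            for g, t in self.testers.items():
                members = self.parents[self.groups == g]
                if t not in members:
                    raise ValueError(f"tester {t!r} not in group {g}")

    @property
    def k(self) -> int:
        return len(np.unique(self.groups))

    def members(self, g: int) -> np.ndarray:
        return self.parents[self.groups == g]

    def to_frame(self) -> pd.DataFrame:
        testers = self.testers or {}
        return pd.DataFrame(
            {
                "parent": self.parents,
                "group": self.groups,
                "is_tester": [testers.get(g) == p for p, g in zip(self.parents, self.groups)],
                "trait": self.trait,
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def fit_diallel(
    means: lmm.AdjustedMeans,
    design: HybridDesign,
    Gp: KinshipMatrix,
    H: KinshipMatrix,
) -> DiallelFit:
    """Fit the two-kernel GCA/SCA model on observed crosses.

    The response is the adjusted mean of each observed cross; rows of the
    GCA incidence carry a 1 for each of the cross's two parents.
    """
    obs = design.subset(design.observed)
    ids = obs.cross_ids
    missing = [c for c in ids if c not in means.values.index]
    if missing:
        raise KeyError(f"crosses without adjusted means: {missing[:5]}")
    y = means.values.loc[ids].to_numpy(dtype=float)

    parents = list(Gp.ids)
    pindex = {p: i for i, p in enumerate(parents)}
    for a, b in obs.crosses:
        if a not in pindex or b not in pindex:
            raise KeyError(f"cross parent missing from Gp: {(a, b)}")
    used = np.zeros(len(parents), dtype=bool)
    Zp = np.zeros((len(obs), len(parents)))
    for r, (a, b) in enumerate(obs.crosses):
        Zp[r, pindex[a]] = 1.0
        Zp[r, pindex[b]] = 1.0
        used[pindex[a]] = used[pindex[b]] = True
    if not used.all():
        unused = np.asarray(parents, dtype=object)[~used]
        raise ValueError(f"parents appearing in no observed cross: {unused[:5]}")

    Hobs = H.subset(ids)
    spec = lmm.LMMSpec(
        y=y,
        X=np.ones((len(y), 1)),
        fixed_names=["intercept"],
        random=[
            lmm.RandomTerm("gca", Z=Zp, K=Gp.values, levels=np.asarray(parents, dtype=object)),
            lmm.RandomTerm("sca", Z=np.eye(len(y)), K=Hobs.values, levels=ids),
        ],
    )
    fit = lmm.reml_fit(spec)
    return DiallelFit(
        gca=fit.blups["gca"],
        sca=fit.blups["sca"],
        var_gca=fit.varcomps["gca"],
        var_sca=fit.varcomps["sca"],
        var_resid=fit.varcomps["residual"],
        loglik=fit.loglik,
        fit=fit,
    )


def complete_sca_matrix(
    dfit: DiallelFit, Gp: KinshipMatrix, design: HybridDesign
) -> SCAMatrix:
    """SCA surface over all parent pairs: observed pairs take their BLUPs,
    unobserved pairs take kernel-based BLUP predictions (shrunk toward 0
    when unrelated to any observed cross)."""
    from .kinship import sca_kernel

    parents = list(Gp.ids)
    pindex = {p: i for i, p in enumerate(parents)}
    n = len(parents)
    S = np.zeros((n, n))
    obs = design.subset(design.observed)
    observed_pairs = {frozenset(c) for c in obs.crosses}
    todo = [
        (parents[i], parents[j])
        for i in range(n)
        for j in range(i + 1, n)
        if frozenset((parents[i], parents[j])) not in observed_pairs
    ]
    for (a, b), val in zip(obs.crosses, dfit.sca.to_numpy()):
        S[pindex[a], pindex[b]] = S[pindex[b], pindex[a]] = val
    if todo:
        full = HybridDesign(
            crosses=list(obs.crosses) + todo,
            observed=np.r_[np.ones(len(obs), bool), np.zeros(len(todo), bool)],
        )
        Hfull = sca_kernel(Gp, full)
        Kcross = Hfull.values[len(obs):, : len(obs)]
        pred = lmm.blup_predict(dfit.fit, "sca", Kcross)
        for (a, b), val in zip(todo, pred):
            S[pindex[a], pindex[b]] = S[pindex[b], pindex[a]] = val
    return SCAMatrix(parents=np.asarray(parents, dtype=object), values=S)


def heterotic_partition(
    S: SCAMatrix, k: int = 2, seed: int | None = None
) -> HeteroticPartition:
    """K-means on the rows of the completed SCA matrix.

    Parents whose SCA profiles are alike (low SCA with the same partners,
    high with the others) cluster together; between-group crosses carry the
    high SCA, i.e. the heterosis.
    """
    if k > len(S.parents):
        raise ValueError("more groups than parents")
    res = structure.kmeans_partition(S.values, k_range=[k], seed=seed)
    return HeteroticPartition(parents=S.parents, groups=res.labels)


def choose_testers(
    partition: HeteroticPartition,
    dfit: DiallelFit,
    S: SCAMatrix,
    rule: str = "cross_value",
) -> HeteroticPartition:
    """Elect one tester per group.

    ``rule="cross_value"`` (default) scores each candidate line i of group
    g by the mean predicted value of its crosses to the opposite group(s),
    ``mean_j (gca_i + gca_j + sca_ij)``; ``rule="gca"`` ranks by the
    candidate's GCA alone. Ties break toward the lexicographically first
    line id.
    """
    if rule not in ("cross_value", "gca"):
        raise ValueError("rule must be 'cross_value' or 'gca'")
    pidx = {p: i for i, p in enumerate(S.parents)}
    testers: dict[int, object] = {}
    for g in np.unique(partition.groups):
        members = partition.members(g)
        others = partition.parents[partition.groups != g]
        if len(members) == 0 or len(others) == 0:
            raise ValueError(f"empty group or empty complement for group {g}")
        best = None
        for cand in sorted(members, key=str):
            if rule == "gca":
                score = float(dfit.gca[cand])
            else:
                score = float(
                    np.mean(
                        [
                            dfit.gca[cand] + dfit.gca[o] + S.values[pidx[cand], pidx[o]]
                            for o in others
                        ]
                    )
                )
            if best is None or score > best[0] + 1e-12:
                best = (score, cand)
        testers[int(g)] = best[1]
    return HeteroticPartition(
        parents=partition.parents,
        groups=partition.groups,
        testers=testers,
        trait=partition.trait,
    )


def enumerate_ncii(partition: HeteroticPartition, base: HybridDesign | None = None) -> HybridDesign:
    """All between-group crosses of a two-group partition (North Carolina
    design II); within-group pairs are excluded. Observed flags are carried
    over from ``base`` where the pair occurs there."""
    if partition.k != 2:
        raise ValueError("NCII enumeration requires exactly 2 groups")
    g1, g2 = np.unique(partition.groups)
    a_side = partition.members(g1)
    b_side = partition.members(g2)
    observed_pairs = (
        {frozenset(c): o for c, o in zip(base.crosses, base.observed)} if base else {}
    )
    crosses, flags = [], []
    for a in a_side:
        for b in b_side:
            crosses.append((a, b))
            flags.append(observed_pairs.get(frozenset((a, b)), False))
    return HybridDesign(crosses=crosses, observed=np.asarray(flags, dtype=bool))


def partition_concordance(
    p1: HeteroticPartition, p2: HeteroticPartition
) -> tuple[float, float]:
    """Agreement between two 2-group partitions of the same parents.

    Group labels of the second partition are aligned to the first (identity
    or swap, whichever agrees more); returns the Pearson correlation of the
    aligned 0/1 membership vectors (the phi coefficient) and the fraction
    of groups with the same elected tester (nan when either partition lacks
    testers).
    """
    if not np.array_equal(np.sort(p1.parents), np.sort(p2.parents)):
        raise ValueError("partitions cover different parent sets")
    order = {p: i for i, p in enumerate(p1.parents)}
    idx2 = np.argsort([order[p] for p in p2.parents])
    m1 = (p1.groups == np.unique(p1.groups)[0]).astype(float)
    g2 = p2.groups[idx2]
    m2 = (g2 == np.unique(g2)[0]).astype(float)
    if (m2 != m1).mean() > 0.5:
        m2 = 1.0 - m2  # swap alignment
    if m1.std() == 0 or m2.std() == 0:
        raise ValueError("degenerate single-group partition")
    r = float(np.corrcoef(m1, m2)[0, 1])
    coincidence = np.nan
    if p1.testers and p2.testers:
        t1 = set(p1.testers.values())
        t2 = set(p2.testers.values())
        coincidence = len(t1 & t2) / max(len(t1), len(t2))
    return r, float(coincidence)
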