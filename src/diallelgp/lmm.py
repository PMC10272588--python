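"""Multi-kernel REML mixed-model engine, stage-1 adjusted means, and BLUP
prediction for unobserved levels.

The model is ``y = X b + sum_r Z_r u_r + e`` with ``u_r ~ N(0, s2_r K_r)``
and residuals either homogeneous (``e ~ N(0, s2_e I)``) or with an
independent variance per residual group (one group per trial environment).

Variance components are estimated by EM-REML. Each EM step is guaranteed
not to decrease the restricted log-likelihood; by default an
average-information (Newton-type) step is attempted first and is accepted
only when it improves the likelihood, falling back to EM otherwise, so the
monotonicity guarantee is preserved while convergence is much faster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

__all__ = [
    "RandomTerm",
    "LMMSpec",
    "LMMFit",
    "TrialData",
    "AdjustedMeans",
    "ConvergenceWarning",
    "reml_fit",
    "blup_predict",
    "stage1_blues",
]

VAR_FLOOR = 1e-8
RIDGE = 1e-6


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class RandomTerm:
    """One random effect: incidence ``Z`` (n x q), kernel ``K`` (q x q,
    ``None`` for identity), and the q level identifiers."""

    name: str
    Z: np.ndarray
    K: np.ndarray | None = None
    levels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        if self.K is not None:
            self.K = np.asarray(self.K, dtype=float)
            if self.K.shape != (self.Z.shape[1], self.Z.shape[1]):
                raise ValueError(f"kernel of term {self.name!r} does not match incidence")
        if self.levels is None:
            self.levels = np.arange(self.Z.shape[1])
        self.levels = np.asarray(self.levels, dtype=object)


@dataclass
class LMMSpec:
    y: np.ndarray
    X: np.ndarray
    fixed_names: list
    random: list
    residual_groups: np.ndarray | None = None  # None = homogeneous

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        n = len(self.y)
        if self.X.shape[0] != n:
            raise ValueError("X rows do not match y")
        for t in self.random:
            if t.Z.shape[0] != n:
                raise ValueError(f"incidence of term {t.name!r} does not match y")
        if self.residual_groups is not None:
            self.residual_groups = np.asarray(self.residual_groups)
            if len(self.residual_groups) != n:
                raise ValueError("residual groups do not match y")


@dataclass
class LMMFit:
    varcomps: dict  # term name -> sigma^2 (residual groups as "residual[g]")
    beta: pd.Series
    beta_cov: np.ndarray
    blups: dict  # term name -> pd.Series over levels
    kernels: dict  # term name -> K actually used (identity materialized)
    loglik: float
    converged: bool
    n_iter: int
    history: list = field(default_factory=list)

    @property
    def residual_variance(self) -> float:
        vals = [v for k, v in self.varcomps.items() if k.startswith("residual")]
        return float(np.mean(vals))


def _residual_masks(spec: LMMSpec):
    if spec.residual_groups is None:
        return [("residual", np.ones(len(spec.y), dtype=bool))]
    groups = pd.unique(spec.residual_groups)
    return [(f"residual[{g}]", spec.residual_groups == g) for g in groups]


class _State:
    """All per-iteration quantities at one variance-component vector."""

    def __init__(self, theta, y, X, Gs, masks):
        n = len(y)
        V = np.zeros((n, n))
        for th, G in zip(theta[: len(Gs)], Gs):
            V += th * G
        diag = np.zeros(n)
        for th, (_, m) in zip(theta[len(Gs):], masks):
            diag[m] += th
        V[np.diag_indices(n)] += diag
        c, low = linalg.cho_factor(V, lower=True)
        self.logdetV = 2.0 * np.log(np.diag(c)).sum()
        self.Vinv = linalg.cho_solve((c, low), np.eye(n))
        self.ViX = self.Vinv @ X
        self.Viy = self.Vinv @ y
        self.XtViX = X.T @ self.ViX
        cx, lowx = linalg.cho_factor(self.XtViX)
        self.logdetXtViX = 2.0 * np.log(np.diag(cx)).sum()
        self._cx = (cx, lowx)
        self.beta = linalg.cho_solve(self._cx, X.T @ self.Viy)
        self.Py = self.Viy - self.ViX @ self.beta
        self.yPy = float(y @ self.Py)
        self.loglik = -0.5 * (self.logdetV + self.logdetXtViX + self.yPy)
        # per-component quadratic forms and traces of P G
        self.t = []
        self.trPG = []
        self.w = []  # G_r @ Py, for AI
        for G in Gs:
            GPy = G @ self.Py
            self.t.append(float(self.Py @ GPy))
            A = self.ViX.T @ (G @ self.ViX)
            self.trPG.append(float(np.sum(self.Vinv * G) - np.trace(linalg.cho_solve(self._cx, A))))
            self.w.append(GPy)
        for _, m in masks:
            self.t.append(float(self.Py[m] @ self.Py[m]))
            A = self.ViX[m].T @ self.ViX[m]
            self.trPG.append(
                float(self.Vinv.diagonal()[m].sum() - np.trace(linalg.cho_solve(self._cx, A)))
            )
            wm = np.zeros(len(self.Py))
            wm[m] = self.Py[m]
            self.w.append(wm)

    def applyP(self, v):
        return self.Vinv @ v - self.ViX @ linalg.cho_solve(self._cx, self.ViX.T @ v)


def reml_fit(
    spec: LMMSpec,
    max_iter: int = 200,
    tol: float = 1e-8,
    method: str = "ai",
    var_floor: float = VAR_FLOOR,
) -> LMMFit:
    """Estimate variance components by REML and solve the mixed-model
    equations at the estimates.

    ``method="ai"`` attempts average-information steps with an EM fallback
    whenever the AI proposal does not improve the restricted likelihood;
    ``method="em"`` uses pure EM updates. Initialization splits the total
    phenotypic variance equally among all components. Non-convergence
    raises a :class:`ConvergenceWarning` and returns the last iterate
    flagged.
    """
    if method not in ("ai", "em"):
        raise ValueError("method must be 'ai' or 'em'")
    y, X = spec.y, spec.X
    n, f = X.shape
    if np.linalg.matrix_rank(X) < f:
        raise ValueError("fixed-effect design is rank deficient")
    if n < f + 2:
        raise ValueError("too few observations for the fixed-effect design")
    Gs = []
    for t in spec.random:
        G = t.Z @ t.K @ t.Z.T if t.K is not None else t.Z @ t.Z.T
        Gs.append(G)
    masks = _residual_masks(spec)
    q = [t.Z.shape[1] for t in spec.random] + [int(m.sum()) for _, m in masks]
    names = [t.name for t in spec.random] + [name for name, _ in masks]
    n_comp = len(q)

    vtot = float(np.var(y, ddof=1)) if n > 1 else 1.0
    theta = np.full(n_comp, max(vtot, var_floor) / n_comp)
    state = _State(theta, y, X, Gs, masks)
    history = [state.loglik]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        new_theta = None
        new_state = None
        if method == "ai":
            for scale in (1.0, 0.5, 0.1):
                prop = _ai_step(theta, state, n_comp, var_floor, scale)
                if prop is None:
                    continue
                try:
                    cand = _State(prop, y, X, Gs, masks)
                except np.linalg.LinAlgError:
                    continue
                if cand.loglik >= state.loglik - 1e-10:
                    new_theta, new_state = prop, cand
                    break
        if new_state is None:
            prop = _em_step(theta, state, q, var_floor)
            new_theta, new_state = prop, _State(prop, y, X, Gs, masks)
            if new_state.loglik < state.loglik - 1e-6:
                # EM is monotone in exact arithmetic; a material drop means
                # numerical trouble (near-singular V) -- stop at current point.
                warnings.warn("REML stopped on numerical likelihood decrease", ConvergenceWarning)
                break
        delta = new_state.loglik - state.loglik
        theta, state = new_theta, new_state
        history.append(state.loglik)
        if abs(delta) < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"REML did not converge in {it} iterations", ConvergenceWarning)

    varcomps = dict(zip(names, map(float, theta)))
    blups = {}
    kernels = {}
    for t, th in zip(spec.random, theta):
        K = t.K if t.K is not None else np.eye(t.Z.shape[1])
        u = th * K @ (t.Z.T @ state.Py)
        blups[t.name] = pd.Series(u, index=t.levels)
        kernels[t.name] = K
    beta_cov = linalg.cho_solve(state._cx, np.eye(f))
    return LMMFit(
        varcomps=varcomps,
        beta=pd.Series(state.beta, index=spec.fixed_names),
        beta_cov=beta_cov,
        blups=blups,
        kernels=kernels,
        loglik=float(state.loglik),
        converged=converged,
        n_iter=it,
        history=history,
    )


def _em_step(theta, state, q, var_floor):
    new = theta.copy()
    for i in range(len(theta)):
        new[i] = theta[i] + theta[i] ** 2 * (state.t[i] - state.trPG[i]) / q[i]
    return np.maximum(new, var_floor)


def _ai_step(theta, state, n_comp, var_floor, scale=1.0):
    """Average-information Newton proposal with an active set: components
    driven to the floor are fixed there and the step re-solved for the rest."""
    AI = np.empty((n_comp, n_comp))
    Pw = [state.applyP(state.w[j]) for j in range(n_comp)]
    for i in range(n_comp):
        for j in range(i, n_comp):
            AI[i, j] = AI[j, i] = 0.5 * float(state.w[i] @ Pw[j])
    score = np.array([-0.5 * (state.trPG[i] - state.t[i]) for i in range(n_comp)])
    free = np.ones(n_comp, dtype=bool)
    prop = theta.copy()
    for _ in range(n_comp):
        idx = np.flatnonzero(free)
        if idx.size == 0:
            break
        sub = AI[np.ix_(idx, idx)] + 1e-10 * np.eye(idx.size)
        try:
            delta = np.linalg.solve(sub, score[idx])
        except np.linalg.LinAlgError:
            return None
        prop[idx] = theta[idx] + scale * delta
        bound = idx[prop[idx] < var_floor]
        if bound.size == 0:
            break
        prop[bound] = var_floor
        free[bound] = False
    prop = np.maximum(prop, var_floor)
    if not np.all(np.isfinite(prop)):
        return None
    return prop


def blup_predict(fit: LMMFit, term: str, kernel_cross: np.ndarray, ridge: float = RIDGE) -> np.ndarray:
    """Predict random effects of unobserved levels from a fitted term.

    ``kernel_cross`` relates new levels (rows) to the term's training
    levels (columns, in training order). The prediction is ``K_new,train
    (K_train + ridge I)^-1 u_hat``; a zero cross-kernel row returns the
    prior mean 0.
    """
    if term not in fit.blups:
        raise KeyError(f"no random term {term!r} in fit")
    u = fit.blups[term].to_numpy()
    K = fit.kernels[term]
    kernel_cross = np.atleast_2d(np.asarray(kernel_cross, dtype=float))
    if kernel_cross.shape[1] != len(u):
        raise ValueError("cross-kernel columns do not match training levels")
    return kernel_cross @ linalg.solve(
        K + ridge * np.eye(len(u)), u, assume_a="pos"
    )


# ---------------------------------------------------------------------------
# Stage-1 adjusted means from multi-environment augmented-block trials
# ---------------------------------------------------------------------------


@dataclass
class TrialData:
    """Plot-level records: env, block (nested in env), entry, is_check, and
    one or more trait columns."""

    records: pd.DataFrame

    REQUIRED = ("env", "block", "entry", "is_check")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"trial table lacks columns {missing}")
        if not self.traits:
            raise ValueError("trial table has no trait columns")

    @property
    def traits(self) -> list:
        return [c for c in self.records.columns if c not in self.REQUIRED]

    def write(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "TrialData":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class AdjustedMeans:
    """Entry -> BLUE for one trait (checks excluded)."""

    trait: str
    values: pd.Series

    def write(self, path) -> None:
        self.values.rename("blue").to_csv(path, sep="\t", index_label="entry")


def stage1_blues(
    trial: TrialData, trait: str | None = None, residual_mode: str = "per_env"
) -> tuple[AdjustedMeans, LMMFit]:
    """Adjusted entry means across environments of an augmented-block trial.

    Fixed effects: environments (sum-to-zero coded, so entry coefficients
    are already means across environments), entries, checks, and check x
    environment interactions. Random: blocks nested within environments.
    Residual variance is independent per environment by default
    (``residual_mode="homogeneous"`` pools it). Entries are fixed so the
    returned BLUEs are not shrunken; checks are excluded from the output.
    """
    if residual_mode not in ("per_env", "homogeneous"):
        raise ValueError("residual_mode must be 'per_env' or 'homogeneous'")
    df = trial.records
    trait = trait or trial.traits[0]
    if trait not in trial.traits:
        raise KeyError(f"unknown trait {trait!r}")
    df = df.loc[df[trait].notna()].reset_index(drop=True)
    y = df[trait].to_numpy(dtype=float)
    envs = pd.unique(df["env"])
    entries = pd.unique(df.loc[~df["is_check"].astype(bool), "entry"])
    checks = pd.unique(df.loc[df["is_check"].astype(bool), "entry"])
    if len(entries) == 0:
        raise ValueError("no non-check entries")
    env_idx = pd.Categorical(df["env"], categories=envs).codes
    n, l = len(df), len(envs)

    cols, names = [], []
    is_check = df["is_check"].astype(bool).to_numpy()
    for g in entries:
        cols.append(((df["entry"] == g) & ~is_check).to_numpy(float))
        names.append(f"entry[{g}]")
    for c in checks:
        cols.append(((df["entry"] == c) & is_check).to_numpy(float))
        names.append(f"check[{c}]")
    # sum-to-zero environment contrasts: entry BLUEs = means across envs
    for e in range(l - 1):
        col = np.where(env_idx == e, 1.0, 0.0) - np.where(env_idx == l - 1, 1.0, 0.0)
        cols.append(col)
        names.append(f"env[{envs[e]}]")
    for c in checks:
        cmask = ((df["entry"] == c) & is_check).to_numpy(float)
        for e in range(l - 1):
            col = cmask * (
                np.where(env_idx == e, 1.0, 0.0) - np.where(env_idx == l - 1, 1.0, 0.0)
            )
            cols.append(col)
            names.append(f"check_env[{c},{envs[e]}]")
    X = np.column_stack(cols)
    keep = _independent_columns(X)
    if not keep.all():
        dropped = [names[i] for i in np.flatnonzero(~keep)]
        warnings.warn(f"dropping {len(dropped)} confounded design columns: {dropped[:4]}")
        X = X[:, keep]
        names = [nm for nm, k in zip(names, keep) if k]

    blockkey = df["env"].astype(str) + "/" + df["block"].astype(str)
    blocks = pd.unique(blockkey)
    Zb = (blockkey.to_numpy()[:, None] == blocks[None, :]).astype(float)
    random = [RandomTerm(name="block", Z=Zb, K=None, levels=blocks)]
    residual_groups = df["env"].to_numpy() if residual_mode == "per_env" else None

    spec = LMMSpec(y=y, X=X, fixed_names=names, random=random, residual_groups=residual_groups)
    fit = reml_fit(spec)
    blues = pd.Series(
        {g: fit.beta[f"entry[{g}]"] for g in entries if f"entry[{g}]" in fit.beta.index}
    )
    return AdjustedMeans(trait=trait, values=blues), fit


def _independent_columns(X: np.ndarray) -> np.ndarray:
    """Boolean mask of a maximal linearly independent column subset
    (greedy, in input order) via pivoted QR."""
    rank = np.linalg.matrix_rank(X)
    keep = np.zeros(X.shape[1], dtype=bool)
    if rank == X.shape[1]:
        keep[:] = True
        return keep
    _, _, piv = linalg.qr(X, mode="economic", pivoting=True)
    keep[np.sort(piv[:rank])] = True
    return keep
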