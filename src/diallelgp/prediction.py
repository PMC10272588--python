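"""Additive-dominance GBLUP of single crosses with replicated k-fold
cross-validation, heritabilities, accuracy, and selection coincidence.

The model is ``y = 1 mu + Z a + Z d + e`` on adjusted cross means with
``a ~ N(0, Ga s2_a)`` and ``d ~ N(0, Gd s2_d)``. Broad-sense heritability
is ``(s2_a + s2_d) / (s2_a + s2_d + s2_e)``; narrow-sense drops the
dominance term from the numerator. Predictive ability is the Pearson
correlation between predicted genetic values (GEBV = a_hat + d_hat) and
observed adjusted means on validation folds; accuracy scales it by
``1 / sqrt(H2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import lmm
from .kinship import KinshipMatrix

__all__ = [
    "ADGBLUPFit",
    "CVResult",
    "CoincidenceTable",
    "fit_ad_gblup",
    "cv_alpha",
    "prediction_metrics",
    "selection_coincidence",
]


@dataclass
class ADGBLUPFit:
    mu: float
    additive: pd.Series
    dominance: pd.Series
    var_a: float
    var_d: float
    var_e: float
    fit: lmm.LMMFit

    @property
    def H2(self) -> float:
        return (self.var_a + self.var_d) / (self.var_a + self.var_d + self.var_e)

    @property
    def h2(self) -> float:
        return self.var_a / (self.var_a + self.var_d + self.var_e)

    @property
    def gebv(self) -> pd.Series:
        return self.additive + self.dominance


@dataclass
class CVResult:
    """Replicated k-fold validation record."""

    ability: pd.DataFrame  # columns: replicate, fold, n_valid, ability
    ability_per_rep: pd.Series  # replicate -> pooled predictive ability
    folds: pd.DataFrame  # columns: replicate, cross, fold
    predictions: pd.DataFrame  # columns: replicate, cross, observed, predicted
    n_folds: int
    n_reps: int
    seed: int | None

    @property
    def mean_ability(self) -> float:
        return float(self.ability_per_rep.mean())


@dataclass
class CoincidenceTable:
    """Selected-fraction overlap between two rankings, in percent."""

    table: pd.DataFrame  # columns: intensity, n_selected, coincidence
    direction: str = "higher"


def fit_ad_gblup(
    means: lmm.AdjustedMeans, Ga: KinshipMatrix, Gd: KinshipMatrix
) -> ADGBLUPFit:
    """Two-kernel REML fit of the additive-dominance model on cross means."""
    ids = list(means.values.index)
    if set(ids) - set(Ga.ids) or set(ids) - set(Gd.ids):
        raise KeyError("kernels do not cover all crosses with adjusted means")
    Ga_s = Ga.subset(ids)
    Gd_s = Gd.subset(ids)
    y = means.values.to_numpy(dtype=float)
    n = len(y)
    Z = np.eye(n)
    ids_arr = np.asarray(ids, dtype=object)
    spec = lmm.LMMSpec(
        y=y,
        X=np.ones((n, 1)),
        fixed_names=["mu"],
        random=[
            lmm.RandomTerm("additive", Z=Z, K=Ga_s.values, levels=ids_arr),
            lmm.RandomTerm("dominance", Z=Z, K=Gd_s.values, levels=ids_arr),
        ],
    )
    fit = lmm.reml_fit(spec)
    return ADGBLUPFit(
        mu=float(fit.beta["mu"]),
        additive=fit.blups["additive"],
        dominance=fit.blups["dominance"],
        var_a=fit.varcomps["additive"],
        var_d=fit.varcomps["dominance"],
        var_e=fit.varcomps["residual"],
        fit=fit,
    )


def _fold_assignment(ids, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Random partition into folds with sizes differing by at most 1."""
    n = len(ids)
    folds = np.resize(np.arange(n_folds), n)
    rng.shuffle(folds)
    return folds


def cv_alpha(
    means: lmm.AdjustedMeans,
    Ga: KinshipMatrix,
    Gd: KinshipMatrix,
    folds: int = 5,
    reps: int = 4,
    seed: int | None = None,
) -> CVResult:
    """Replicated random k-fold (CV-alpha) validation of the AD-GBLUP model.

    Per replicate, crosses are partitioned into ``folds`` near-equal folds;
    each fold in turn is masked, the model refit on the remainder, and
    validation GEBVs are predicted through the kernel rows linking masked
    to training crosses. Predictive ability is pooled per replicate as the
    Pearson correlation of predicted vs observed over all validation sets.
    """
    ids = np.asarray(means.values.index, dtype=object)
    n = len(ids)
    if n < folds:
        raise ValueError("fewer crosses than folds")
    if n // folds < 3:
        raise ValueError("folds would contain fewer than 3 crosses")
    rng = np.random.default_rng(seed)
    Ga_s = Ga.subset(list(ids))
    Gd_s = Gd.subset(list(ids))
    y = means.values.to_numpy(dtype=float)

    rows, fold_rows, pred_rows, per_rep = [], [], [], {}
    for rep in range(reps):
        assignment = _fold_assignment(ids, folds, rng)
        rep_pred = np.full(n, np.nan)
        for f in range(folds):
            valid = assignment == f
            train = ~valid
            sub_means = lmm.AdjustedMeans(
                trait=means.trait, values=means.values.iloc[np.flatnonzero(train)]
            )
            sub_Ga = KinshipMatrix(ids[train], Ga_s.values[np.ix_(train, train)], "Ga")
            sub_Gd = KinshipMatrix(ids[train], Gd_s.values[np.ix_(train, train)], "Gd")
            fit = fit_ad_gblup(sub_means, sub_Ga, sub_Gd)
            a_pred = lmm.blup_predict(fit.fit, "additive", Ga_s.values[np.ix_(valid, train)])
            d_pred = lmm.blup_predict(fit.fit, "dominance", Gd_s.values[np.ix_(valid, train)])
            gebv = a_pred + d_pred
            rep_pred[valid] = gebv
            rows.append(
                {
                    "replicate": rep,
                    "fold": f,
                    "n_valid": int(valid.sum()),
                    "ability": _safe_corr(gebv, y[valid]),
                }
            )
        for i, cid in enumerate(ids):
            fold_rows.append({"replicate": rep, "cross": cid, "fold": int(assignment[i])})
            pred_rows.append(
                {"replicate": rep, "cross": cid, "observed": y[i], "predicted": rep_pred[i]}
            )
        per_rep[rep] = _safe_corr(rep_pred, y)
    return CVResult(
        ability=pd.DataFrame(rows),
        ability_per_rep=pd.Series(per_rep),
        folds=pd.DataFrame(fold_rows),
        predictions=pd.DataFrame(pred_rows),
        n_folds=folds,
        n_reps=reps,
        seed=seed,
    )


def _safe_corr(a, b) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def prediction_metrics(cv: CVResult, fit: ADGBLUPFit) -> pd.Series:
    """Per-replicate prediction accuracy: predictive ability divided by the
    square root of broad-sense heritability, clamped to [-1, 1]."""
    H2 = fit.H2
    if H2 <= 0:
        raise ZeroDivisionError("H2 = 0: accuracy undefined")
    return (cv.ability_per_rep / np.sqrt(H2)).clip(-1.0, 1.0)


def selection_coincidence(
    means: lmm.AdjustedMeans,
    gebvs: pd.Series,
    intensities=(1, 10, 20, 30, 40),
    direction: str = "higher",
) -> CoincidenceTable:
    """Percent overlap of the top selections by adjusted means vs GEBVs.

    For each intensity s (percent), the top ``ceil(s*n/100)`` crosses by
    each ranking are selected (bottom when ``direction="lower"``);
    coincidence is 100 x |intersection| / selection size. Intensities whose
    selection would be empty are reported as nan.
    """
    if direction not in ("higher", "lower"):
        raise ValueError("direction must be 'higher' or 'lower'")
    common = means.values.index.intersection(gebvs.index)
    if len(common) != len(means.values) or len(common) != len(gebvs):
        raise ValueError("rankings cover different cross sets")
    n = len(common)
    sign = -1.0 if direction == "higher" else 1.0
    by_pheno = (sign * means.values.loc[common]).sort_values(kind="stable").index
    by_gebv = (sign * gebvs.loc[common]).sort_values(kind="stable").index
    rows = []
    for s in intensities:
        k = int(np.ceil(s * n / 100.0))
        if k == 0:
            rows.append({"intensity": s, "n_selected": 0, "coincidence": np.nan})
            continue
        overlap = len(set(by_pheno[:k]) & set(by_gebv[:k]))
        rows.append({"intensity": s, "n_selected": k, "coincidence": 100.0 * overlap / k})
    return CoincidenceTable(table=pd.DataFrame(rows), direction=direction)
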