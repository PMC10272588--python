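"""End-to-end workflow orchestration and the cross-platform concordance report.

One run executes, per marker panel: QC (both branches) -> population
structure -> kernels -> stage-1 adjusted means (when plot-level phenotypes
are supplied) -> GCA/SCA diallel fit -> heterotic groups and testers ->
NCII enumeration -> additive-dominance prediction with cross-validation.
Every intermediate is written as delimited text into the run directory with
a JSON manifest, and the concordance report is assembled purely from those
on-disk intermediates.

The master seed fans out deterministically: one child seed per (stage,
panel) pair via ``numpy.random.SeedSequence(master_seed).spawn``.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diallel, genotypes, kinship, lmm, prediction, structure

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "concordance_report"]

log = logging.getLogger("diallelgp")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and panel."""

    def __init__(self, stage: str, panel: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for panel {panel!r}: {cause}")
        self.stage, self.panel, self.cause = stage, panel, cause


@dataclass
class PipelineConfig:
    panels: list  # [{"name":..., "path":..., "format":...}, ...]
    phenotypes: str | None = None
    pheno_kind: str = "plots"  # plots | means
    outdir: str = "run"
    cross_separator: str = "x"
    min_call_rate: float = 0.90
    r2_max: float = 0.99
    maf_min: float = 0.05
    k_range: tuple = (2, 3, 4, 5, 6, 7, 8)
    n_components: int = 3
    groups_k: int = 2
    tester_rule: str = "cross_value"
    residual_mode: str = "per_env"
    folds: int = 5
    reps: int = 4
    intensities: tuple = (1, 10, 20, 30, 40)
    direction: str = "higher"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


def _parse_design(entries, sep: str) -> kinship.HybridDesign:
    crosses = []
    for e in entries:
        parts = str(e).split(sep)
        if len(parts) != 2:
            raise ValueError(f"entry {e!r} is not a cross id (expected 'A{sep}B')")
        crosses.append(tuple(parts))
    return kinship.HybridDesign(crosses=crosses)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow; returns {panel: {...}} plus writes the run
    directory. Any stage failure raises :class:`PipelineError` naming the
    stage; artifacts written up to that point are retained."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_log(outdir / "pipeline.log")
    config.to_yaml(outdir / "config.yaml")
    seeds = iter(np.random.SeedSequence(config.seed).spawn(4 * len(config.panels) + 4))
    manifest: dict = {"panels": {}, "seed": config.seed}

    trial = means_by_trait = None
    design = None
    if config.phenotypes:
        if config.pheno_kind == "plots":
            trial = lmm.TrialData.read(config.phenotypes)
            hybrids = trial.records.loc[~trial.records["is_check"].astype(bool), "entry"]
            design = _parse_design(pd.unique(hybrids), config.cross_separator)
        else:
            df = pd.read_csv(config.phenotypes, sep="\t", index_col=0)
            means_by_trait = {
                t: lmm.AdjustedMeans(trait=t, values=df[t].dropna()) for t in df.columns
            }
            design = _parse_design(df.index, config.cross_separator)

    results: dict = {}
    for panel in config.panels:
        name = panel["name"]
        pdir = outdir / f"panel_{name}"
        pdir.mkdir(exist_ok=True)
        res: dict = {}
        art: dict = {}
        log.info("panel %s: reading %s", name, panel.get("path"))
        try:
            G = panel.get("matrix")
            if G is None:
                G = genotypes.read_genotypes(panel["path"], panel.get("format", "dosage-table"))
        except Exception as e:  # noqa: BLE001
            raise PipelineError("read", name, e)

        res, art = _structure_stage(G, config, pdir, next(seeds), res, art, name)
        if design is not None:
            res, art = _diallel_stage(
                G, design, trial, means_by_trait, config, pdir, next(seeds), res, art, name
            )
            res, art = _prediction_stage(
                G, design, config, pdir, next(seeds), res, art, name
            )
        manifest["panels"][name] = art
        results[name] = res

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    if len(config.panels) >= 2:
        report = concordance_report(outdir)
        report.to_csv(outdir / "concordance_report.tsv", sep="\t", index=False)
        manifest["concordance_report"] = "concordance_report.tsv"
        results["concordance"] = report
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return results


def _setup_log(path) -> None:
    log.setLevel(logging.INFO)
    if not any(isinstance(h, logging.FileHandler) for h in log.handlers):
        fh = logging.FileHandler(path)
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(fh)


def _structure_stage(G, config, pdir, seed_seq, res, art, name):
    try:
        Gq, report = genotypes.qc_parent_panel(G, config.min_call_rate, config.r2_max)
        report.write(pdir / "qc_parent_report.tsv")
        art["qc_parent_report"] = "qc_parent_report.tsv"
        D = structure.rogers_distance(Gq)
        D.write(pdir / "rogers.tsv")
        art["rogers"] = "rogers.tsv"
        k_ord = min(10, D.n)
        P = structure.pcoa(D, k=k_ord)
        pd.DataFrame(
            P.coordinates, index=P.ids, columns=[f"PCo{i + 1}" for i in range(k_ord)]
        ).to_csv(pdir / "pcoa.tsv", sep="\t", index_label="line")
        art["pcoa"] = "pcoa.tsv"
        seed = int(seed_seq.generate_state(1)[0] % (2**31))
        clusters = structure.kmeans_partition(
            P.coordinates[:, : config.n_components], config.k_range, seed=seed
        )
        pd.DataFrame({"line": Gq.line_ids, "cluster": clusters.labels}).to_csv(
            pdir / "clusters.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            {"k": list(clusters.wss), "wss": list(clusters.wss.values())}
        ).to_csv(pdir / "wss.tsv", sep="\t", index=False)
        art["clusters"] = "clusters.tsv"
        art["wss"] = "wss.tsv"
        res.update(structure_panel=Gq, rogers=D, pcoa=P, clusters=clusters)
        log.info("panel %s: structure done (chosen k=%d)", name, clusters.k)
        return res, art
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("structure", name, e)


def _diallel_stage(G, design, trial, means_by_trait, config, pdir, seed_seq, res, art, name):
    try:
        parents = design.parents
        Gq, _ = genotypes.qc_parent_panel(G, config.min_call_rate, config.r2_max)
        Gsub = Gq.subset_lines(parents)
        Gh, hreport = genotypes.qc_hybrid_panel(Gsub, config.maf_min, design=design)
        hreport.write(pdir / "qc_hybrid_report.tsv")
        art["qc_hybrid_report"] = "qc_hybrid_report.tsv"
        Gp = kinship.gp_matrix(Gh)
        Gp.write(pdir / "gp.tsv")
        art["gp"] = "gp.tsv"
        H = kinship.sca_kernel(Gp, design)

        if means_by_trait is None:
            means_by_trait = {}
            for trait in trial.traits:
                means, _ = lmm.stage1_blues(trial, trait, config.residual_mode)
                means.write(pdir / f"blues_{trait}.tsv")
                art[f"blues_{trait}"] = f"blues_{trait}.tsv"
                means_by_trait[trait] = means
        res["means_by_trait"] = means_by_trait
        res["hybrid_panel"] = Gh
        res["gp"] = Gp

        seed = int(seed_seq.generate_state(1)[0] % (2**31))
        res["diallel"] = {}
        for trait, means in means_by_trait.items():
            dfit = diallel.fit_diallel(means, design, Gp, H)
            S = diallel.complete_sca_matrix(dfit, Gp, design)
            S.write(pdir / f"sca_matrix_{trait}.tsv")
            part = diallel.heterotic_partition(S, k=config.groups_k, seed=seed)
            part.trait = trait
            part = diallel.choose_testers(part, dfit, S, rule=config.tester_rule)
            part.write(pdir / f"partition_{trait}.tsv")
            ncii = diallel.enumerate_ncii(part, base=design)
            ncii.write(pdir / f"ncii_{trait}.tsv")
            pd.Series(
                {
                    "var_gca": dfit.var_gca,
                    "var_sca": dfit.var_sca,
                    "var_resid": dfit.var_resid,
                    "loglik": dfit.loglik,
                }
            ).to_csv(pdir / f"diallel_varcomps_{trait}.tsv", sep="\t", header=False)
            for key in ("sca_matrix", "partition", "ncii", "diallel_varcomps"):
                art[f"{key}_{trait}"] = f"{key}_{trait}.tsv"
            res["diallel"][trait] = {"fit": dfit, "sca": S, "partition": part, "ncii": ncii}
            log.info(
                "panel %s trait %s: diallel varcomps GCA=%.4g SCA=%.4g resid=%.4g; tester(s) %s",
                name, trait, dfit.var_gca, dfit.var_sca, dfit.var_resid, part.testers,
            )
        return res, art
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("diallel", name, e)


def _prediction_stage(G, design, config, pdir, seed_seq, res, art, name):
    try:
        Gh = res["hybrid_panel"]
        obs = design.subset(design.observed)
        hyb = kinship.build_hybrid_genotypes(Gh, obs)
        Ga = kinship.additive_G(hyb)
        Gd = kinship.dominance_G(hyb)
        seed = int(seed_seq.generate_state(1)[0] % (2**31))
        res["prediction"] = {}
        for trait, means in res["means_by_trait"].items():
            common = [c for c in obs.cross_ids if c in means.values.index]
            sub = lmm.AdjustedMeans(trait=trait, values=means.values.loc[common])
            fit = prediction.fit_ad_gblup(sub, Ga, Gd)
            cv = prediction.cv_alpha(sub, Ga, Gd, config.folds, config.reps, seed=seed)
            acc = prediction.prediction_metrics(cv, fit)
            coin = prediction.selection_coincidence(
                sub, fit.gebv.loc[common], config.intensities, config.direction
            )
            summary = pd.DataFrame(
                {
                    "replicate": cv.ability_per_rep.index,
                    "ability": cv.ability_per_rep.to_numpy(),
                    "accuracy": acc.to_numpy(),
                    "H2": fit.H2,
                    "h2": fit.h2,
                }
            )
            summary.to_csv(pdir / f"cv_{trait}.tsv", sep="\t", index=False)
            coin.table.to_csv(pdir / f"coincidence_{trait}.tsv", sep="\t", index=False)
            pd.Series(
                {"var_a": fit.var_a, "var_d": fit.var_d, "var_e": fit.var_e,
                 "H2": fit.H2, "h2": fit.h2}
            ).to_csv(pdir / f"adgblup_varcomps_{trait}.tsv", sep="\t", header=False)
            art[f"cv_{trait}"] = f"cv_{trait}.tsv"
            art[f"coincidence_{trait}"] = f"coincidence_{trait}.tsv"
            art[f"adgblup_varcomps_{trait}"] = f"adgblup_varcomps_{trait}.tsv"
            res["prediction"][trait] = {"fit": fit, "cv": cv, "accuracy": acc, "coincidence": coin}
            log.info(
                "panel %s trait %s: mean PA=%.3f H2=%.3f h2=%.3f",
                name, trait, cv.mean_ability, fit.H2, fit.h2,
            )
        return res, art
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("prediction", name, e)


def concordance_report(run_dir) -> pd.DataFrame:
    """Assemble all pairwise between-panel concordance statistics from the
    on-disk intermediates of a finished run: Mantel r/p between Rogers
    distance matrices, Kendall tau between cluster partitions, the leading
    eigenvector R-squared, heterotic-partition correlation, tester
    coincidence, and mean predictive abilities. No new model fits happen
    here."""
    run_dir = Path(run_dir)
    with open(run_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    panels = sorted(manifest["panels"])
    if len(panels) < 2:
        raise ValueError("concordance report requires at least 2 panels")
    seed = int(manifest.get("seed", 0))
    rows = []
    for a, b in itertools.combinations(panels, 2):
        da, db = run_dir / f"panel_{a}", run_dir / f"panel_{b}"
        Da = structure.DistanceMatrix.read(da / "rogers.tsv")
        Db = structure.DistanceMatrix.read(db / "rogers.tsv")
        mant = structure.mantel_test(Da, Db, seed=seed)
        ca = pd.read_csv(da / "clusters.tsv", sep="\t")["cluster"]
        cb = pd.read_csv(db / "clusters.tsv", sep="\t")["cluster"]
        tau, tau_p, _ = structure.kendall_coincidence(ca, cb)
        Pa = pd.read_csv(da / "pcoa.tsv", sep="\t", index_col=0)
        Pb = pd.read_csv(db / "pcoa.tsv", sep="\t", index_col=0)
        k = min(Pa.shape[1], Pb.shape[1])
        Az = (Pa.iloc[:, :k] - Pa.iloc[:, :k].mean()) / Pa.iloc[:, :k].std(ddof=0)
        Bz = (Pb.iloc[:, :k] - Pb.iloc[:, :k].mean()) / Pb.iloc[:, :k].std(ddof=0)
        grid = (Az.to_numpy().T @ Bz.to_numpy() / len(Pa)) ** 2
        pd.DataFrame(grid, index=Az.columns, columns=Bz.columns).to_csv(
            run_dir / f"eigvec_r2_{a}_{b}.tsv", sep="\t", index_label="eigvec"
        )
        r2_11 = float(grid[0, 0])
        base = {
            "panel_a": a,
            "panel_b": b,
            "mantel_r": mant.r,
            "mantel_p": mant.p,
            "kendall_tau": tau,
            "kendall_p": tau_p,
            "eigvec1_r2": r2_11,
        }
        traits = sorted(
            p.name[len("partition_"):-len(".tsv")]
            for p in da.glob("partition_*.tsv")
        )
        if not traits:
            rows.append({**base, "trait": None})
        for trait in traits:
            pa = _read_partition(da / f"partition_{trait}.tsv")
            pb = _read_partition(db / f"partition_{trait}.tsv")
            r, coin = diallel.partition_concordance(pa, pb)
            row = {**base, "trait": trait, "partition_r": r, "tester_coincidence": coin}
            for side, d in (("a", da), ("b", db)):
                cv_path = d / f"cv_{trait}.tsv"
                if cv_path.exists():
                    cv = pd.read_csv(cv_path, sep="\t")
                    row[f"mean_ability_{side}"] = float(cv["ability"].mean())
            rows.append(row)
    return pd.DataFrame(rows)


def _read_partition(path) -> diallel.HeteroticPartition:
    df = pd.read_csv(path, sep="\t")
    testers = {
        int(g): df.loc[(df["group"] == g) & df["is_tester"], "parent"].iloc[0]
        for g in df["group"].unique()
        if ((df["group"] == g) & df["is_tester"]).any()
    }
    return diallel.HeteroticPartition(
        parents=df["parent"].to_numpy(dtype=object),
        groups=df["group"].to_numpy(),
        testers=testers or None,
        trait=df["trait"].iloc[0] if "trait" in df else None,
    )
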