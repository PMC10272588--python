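"""Synthetic germplasm, multi-platform genotyping, and field-trial generator.

Emulates the study system the analysis chain assumes: a structured panel of
fully homozygous (inbred) lines in a handful of subpopulations, an
incomplete diallel among a subset of parents, several marker-platform views
of differing density/ascertainment/missingness, additive + dominance
genetic effects, and multi-environment augmented-block trials (blocks of
entries plus replicated checks). A truth record carries everything needed
for recovery tests: pool labels, per-marker effects, true hybrid values,
and the generating variances.

Population structure uses a hierarchical Balding-Nichols construction: an
ancestral allele frequency per marker, with per-pool frequencies drawn from
a Beta distribution around it whose spread is governed by a single
Fst-like ``divergence`` knob.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .kinship import HybridDesign, build_hybrid_genotypes
from .lmm import TrialData

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimStudy",
    "simulate_parents",
    "simulate_platform_views",
    "simulate_diallel_design",
    "simulate_genetic_effects",
    "simulate_trial_data",
    "simulate_study",
]


@dataclass
class SimConfig:
    """Generator settings; defaults mirror the emulated study.

    330 lines in 6 subpopulations, 45 diallel parents realizing ~76% of the
    possible crosses, 8 environments with augmented blocks of 16 entries
    plus 2 checks. ``divergence`` is the Fst-like spread of pool allele
    frequencies around the ancestral frequency. Variances are in squared
    trait units.
    """

    n_lines: int = 330
    n_markers: int = 12000
    n_pools: int = 6
    divergence: float = 0.15
    n_diallel_parents: int = 45
    cross_fraction: float = 751 / 990
    var_additive: float = 1.0
    var_dominance: float = 0.5
    var_residual: float = 1.0
    var_env: float = 1.0
    var_block: float = 0.25
    n_envs: int = 8
    block_size: int = 16
    n_checks: int = 2
    n_chrom: int = 10
    genotyping_error: float = 0.0
    directional_dominance: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_lines",
            "n_markers",
            "n_pools",
            "n_diallel_parents",
            "n_envs",
            "block_size",
            "n_checks",
            "n_chrom",
        ):
            if getattr(self, name) < (0 if name == "n_checks" else 1):
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.divergence < 1.0:
            raise ValueError("divergence must lie in [0, 1)")
        if not 0.0 < self.cross_fraction <= 1.0:
            raise ValueError("cross_fraction must lie in (0, 1]")
        for name in ("var_additive", "var_dominance", "var_residual", "var_env", "var_block"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_diallel_parents > self.n_lines:
            raise ValueError("n_diallel_parents exceeds n_lines")
        if self.n_diallel_parents < 2:
            raise ValueError("need at least 2 diallel parents")


@dataclass
class SimTruth:
    """Ground truth of one simulated study."""

    pool_labels: np.ndarray
    marker_effects_additive: np.ndarray | None = None
    marker_effects_dominance: np.ndarray | None = None
    true_hybrid_values: pd.Series | None = None
    true_varcomps: dict = field(default_factory=dict)
    design: HybridDesign | None = None
    check_values: np.ndarray | None = None

    def write(self, path) -> None:
        """Structured text dump (one section per field)."""
        with open(path, "w") as fh:
            fh.write("[pool_labels]\n")
            for i, lab in enumerate(self.pool_labels):
                fh.write(f"{i}\t{lab}\n")
            if self.true_varcomps:
                fh.write("[true_varcomps]\n")
                for k, v in self.true_varcomps.items():
                    fh.write(f"{k}\t{v}\n")
            if self.true_hybrid_values is not None:
                fh.write("[true_hybrid_values]\n")
                self.true_hybrid_values.to_csv(fh, sep="\t", header=False)


@dataclass
class SimStudy:
    """Bundle of all artifacts from one end-to-end simulation."""

    config: SimConfig
    parents: GenotypeMatrix
    views: list
    design: HybridDesign
    truth: SimTruth
    trial: TrialData


def _pool_frequencies(p_anc: np.ndarray, divergence: float, n_pools: int, rng) -> np.ndarray:
    """Balding-Nichols: pool freq ~ Beta(p(1-F)/F, (1-p)(1-F)/F)."""
    if divergence == 0.0:
        return np.tile(p_anc, (n_pools, 1))
    a = p_anc * (1.0 - divergence) / divergence
    b = (1.0 - p_anc) * (1.0 - divergence) / divergence
    return rng.beta(a, b, size=(n_pools, len(p_anc)))


def simulate_parents(config: SimConfig, rng=None) -> tuple[GenotypeMatrix, SimTruth]:
    """Fully homozygous structured parental panel (dosages in {0, 2}).

    Ancestral frequencies are Uniform(0.1, 0.9) so near-fixed markers do
    not dominate; markers monomorphic across the whole panel are redrawn.
    Lines are spread over pools as evenly as possible; markers over
    ``n_chrom`` synthetic chromosomes with 1-based positions.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n, m = config.n_lines, config.n_markers
    pools = np.arange(n) % config.n_pools + 1
    D = np.empty((n, m))
    todo = np.arange(m)
    for _ in range(100):
        p_anc = rng.uniform(0.1, 0.9, size=len(todo))
        pf = _pool_frequencies(p_anc, config.divergence, config.n_pools, rng)
        draws = rng.random((n, len(todo)))
        D[:, todo] = 2.0 * (draws < pf[pools - 1, :]).astype(float)
        mono = D[:, todo].std(axis=0) == 0
        todo = todo[mono]
        if len(todo) == 0:
            break
    else:  # pragma: no cover - would need pathological settings
        raise RuntimeError("could not generate polymorphic markers")
    chrom = np.array([f"chr{(j % config.n_chrom) + 1}" for j in range(m)], dtype=object)
    pos = np.array([j // config.n_chrom + 1 for j in range(m)])
    G = GenotypeMatrix(
        line_ids=np.array([f"L{i + 1:03d}" for i in range(n)], dtype=object),
        marker_ids=np.array([f"M{j + 1:05d}" for j in range(m)], dtype=object),
        dosages=D,
        chrom=chrom,
        pos=pos,
    )
    return G, SimTruth(pool_labels=pools)


def simulate_platform_views(
    G: GenotypeMatrix,
    panels,
    seed=None,
    ref_lines=None,
    error_rate: float = 0.0,
) -> list:
    """Marker-panel views of one panel: ``panels`` is a list of
    ``(size, ascertainment_mode, missing_rate)`` tuples.

    Mode ``"random"`` samples markers uniformly; ``"biased"`` samples with
    probability proportional to the minor-allele frequency in a reference
    subset of lines (array-style ascertainment; default reference = first
    20% of lines). Missingness is injected completely at random; an
    optional genotyping ``error_rate`` flips homozygote calls.
    """
    if not panels:
        raise ValueError("empty panel request")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if ref_lines is None:
        ref_lines = G.line_ids[: max(2, G.n_lines // 5)]
    ref = G.subset_lines(list(ref_lines))
    views = []
    for size, mode, missing_rate in panels:
        if size > G.n_markers:
            raise ValueError(f"panel size {size} exceeds {G.n_markers} markers")
        if mode == "random":
            idx = rng.choice(G.n_markers, size=size, replace=False)
        elif mode == "biased":
            w = ref.maf() + 1e-6
            idx = rng.choice(G.n_markers, size=size, replace=False, p=w / w.sum())
        else:
            raise ValueError(f"unknown ascertainment mode {mode!r}")
        view = G.subset_markers(np.sort(idx))
        D = view.dosages
        if error_rate > 0:
            flip = rng.random(D.shape) < error_rate
            D = np.where(flip & ~np.isnan(D), 2.0 - D, D)
        if missing_rate > 0:
            D = np.where(rng.random(D.shape) < missing_rate, np.nan, D)
        view.dosages = D
        views.append(view)
    return views


def simulate_diallel_design(config: SimConfig, truth: SimTruth, G: GenotypeMatrix, rng) -> HybridDesign:
    """Pick diallel parents evenly across pools and realize a random
    ``cross_fraction`` of the full diallel as observed."""
    parents: list = []
    pool_ids = np.unique(truth.pool_labels)
    per_pool = {p: list(G.line_ids[truth.pool_labels == p]) for p in pool_ids}
    i = 0
    while len(parents) < config.n_diallel_parents:
        pool = pool_ids[i % len(pool_ids)]
        if per_pool[pool]:
            parents.append(per_pool[pool].pop(0))
        i += 1
    full = HybridDesign.full_diallel(parents)
    n_obs = max(1, int(round(config.cross_fraction * len(full))))
    observed = np.zeros(len(full), dtype=bool)
    observed[rng.choice(len(full), size=n_obs, replace=False)] = True
    return HybridDesign(crosses=full.crosses, observed=observed)


def simulate_genetic_effects(
    G: GenotypeMatrix, config: SimConfig, design: HybridDesign | None = None, rng=None
) -> SimTruth:
    """Per-marker additive and dominance effects scaled to the target
    variances over the simulated crosses.

    Additive effects are drawn i.i.d. normal; dominance effects are
    half-normal by default (``directional_dominance``), so heterozygosity
    raises the trait and inter-pool crosses express heterosis. Both sets are
    rescaled so the realized variance of their contribution to the true
    hybrid values equals the configured variance exactly over the design's
    crosses.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if G.dosages.std(axis=0).max() == 0:
        raise ValueError("all markers monomorphic; cannot assign effects")
    if design is None:
        design = HybridDesign.full_diallel(list(G.line_ids[: config.n_diallel_parents]))
    hyb = build_hybrid_genotypes(G.subset_lines(design.parents), design)
    m = G.n_markers

    alpha = rng.normal(size=m)
    add = hyb.W_A @ alpha
    sd = add.std()
    alpha = alpha * np.sqrt(config.var_additive) / sd if sd > 0 else np.zeros(m)
    if config.var_additive == 0:
        alpha = np.zeros(m)

    delta = rng.normal(size=m)
    if config.directional_dominance:
        # heterosis arises from dominance toward the favorable allele:
        # heterozygosity raises the trait, as in yield of inter-pool crosses
        delta = np.abs(delta)
    dom = hyb.W_D @ delta
    sd = dom.std()
    delta = delta * np.sqrt(config.var_dominance) / sd if sd > 0 else np.zeros(m)
    if config.var_dominance == 0:
        delta = np.zeros(m)

    values = hyb.W_A @ alpha + hyb.W_D @ delta
    return SimTruth(
        pool_labels=np.empty(0),
        marker_effects_additive=alpha,
        marker_effects_dominance=delta,
        true_hybrid_values=pd.Series(values, index=hyb.cross_ids),
        true_varcomps={
            "additive": config.var_additive,
            "dominance": config.var_dominance,
            "residual": config.var_residual,
        },
        design=design,
    )


def simulate_trial_data(
    hybrid_values: pd.Series,
    config: SimConfig,
    rng=None,
    check_values: np.ndarray | None = None,
    trait: str = "trait",
) -> TrialData:
    """Multi-environment augmented-block trial around true hybrid values.

    Per environment, entries are shuffled and chunked into blocks of
    ``block_size`` (last block may be short); every block additionally
    carries each of the ``n_checks`` checks once. An observation is
    ``true value + env effect + block effect + residual`` with an
    independent residual variance per environment (environment-specific
    factors Uniform(0.5, 1.5) around ``var_residual``). Checks are not
    genotyped: they carry fixed true values at the quartiles of the hybrid
    value distribution.
    """
    if config.n_envs < 1:
        raise ValueError("need at least one environment")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    entries = np.asarray(hybrid_values.index, dtype=object)
    values = hybrid_values.to_numpy(dtype=float)
    if check_values is None:
        qs = np.linspace(0.25, 0.75, config.n_checks) if config.n_checks else []
        check_values = np.quantile(values, qs) if config.n_checks else np.empty(0)
    check_ids = np.array([f"CHECK{c + 1}" for c in range(config.n_checks)], dtype=object)

    env_eff = rng.normal(0.0, np.sqrt(config.var_env), size=config.n_envs)
    resid_var = config.var_residual * rng.uniform(0.5, 1.5, size=config.n_envs)
    rows = []
    for e in range(config.n_envs):
        order = rng.permutation(len(entries))
        n_blocks = int(np.ceil(len(entries) / config.block_size))
        for b in range(n_blocks):
            members = order[b * config.block_size : (b + 1) * config.block_size]
            block_eff = rng.normal(0.0, np.sqrt(config.var_block))
            for i in members:
                rows.append(
                    {
                        "env": f"E{e + 1}",
                        "block": f"B{b + 1}",
                        "entry": entries[i],
                        "is_check": False,
                        trait: values[i]
                        + env_eff[e]
                        + block_eff
                        + rng.normal(0.0, np.sqrt(resid_var[e])),
                    }
                )
            for c in range(config.n_checks):
                rows.append(
                    {
                        "env": f"E{e + 1}",
                        "block": f"B{b + 1}",
                        "entry": check_ids[c],
                        "is_check": True,
                        trait: check_values[c]
                        + env_eff[e]
                        + block_eff
                        + rng.normal(0.0, np.sqrt(resid_var[e])),
                    }
                )
    return TrialData(pd.DataFrame(rows))


def simulate_study(config: SimConfig, panels=None) -> SimStudy:
    """Run the full generator chain under one master seed.

    ``panels`` defaults to three views emulating a biased-ascertainment
    array of near-full density and two reduced-representation panels of
    ~80% and ~40% density with higher missingness.
    """
    seeds = np.random.SeedSequence(config.seed).spawn(5)
    rngs = [np.random.default_rng(s) for s in seeds]
    G, truth = simulate_parents(config, rng=rngs[0])
    if panels is None:
        m = config.n_markers
        panels = [
            (int(0.9 * m), "biased", 0.02),
            (int(0.8 * m), "random", 0.05),
            (int(0.4 * m), "random", 0.10),
        ]
    views = simulate_platform_views(G, panels, seed=rngs[1], error_rate=config.genotyping_error)
    design = simulate_diallel_design(config, truth, G, rngs[2])
    effects = simulate_genetic_effects(G, config, design=design, rng=rngs[3])
    truth.marker_effects_additive = effects.marker_effects_additive
    truth.marker_effects_dominance = effects.marker_effects_dominance
    truth.true_hybrid_values = effects.true_hybrid_values
    truth.true_varcomps = effects.true_varcomps
    truth.design = design
    obs_values = effects.true_hybrid_values[design.observed]
    trial = simulate_trial_data(obs_values, config, rng=rngs[4])
    return SimStudy(config=config, parents=G, views=views, design=design, truth=truth, trial=trial)
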