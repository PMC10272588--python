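"""Genotype containers, file IO, and the two-branch marker QC cascade.

Dosages code the count of the alternate (second-listed) allele per line and
marker: 0 and 2 are the homozygotes, 1 the heterozygote, ``nan`` missing.
Two QC branches are kept throughout the pipeline:

* the *structure* branch (:func:`qc_parent_panel`) retains heterozygous and
  rare markers so diversity analyses see all variability, and
* the *prediction* branch (:func:`qc_hybrid_panel`) additionally drops
  markers heterozygous in any parent, cross-chromosome duplicates, and
  markers rare among the derived single crosses.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "QCReport",
    "EmptyPanelError",
    "read_genotypes",
    "write_dosage_table",
    "write_vcf",
    "impute_missing",
    "qc_parent_panel",
    "qc_hybrid_panel",
]

_EPS = 1e-9  # guards exact-boundary threshold comparisons against FP error


class EmptyPanelError(ValueError):
    """All markers were removed by a filter step."""


@dataclass
class GenotypeMatrix:
    """Lines x markers allele-dosage matrix with optional marker coordinates.

    Parameters
    ----------
    line_ids, marker_ids
        Unique identifiers for rows and columns.
    dosages
        Float array of shape ``(n_lines, n_markers)`` with values in
        ``{0, 1, 2, nan}``.
    chrom, pos
        Optional per-marker coordinates (1-based positions).
    biallelic
        Per-marker flag; sites read from multi-allelic VCF records carry
        ``False`` and are removed by :func:`qc_parent_panel`.
    """

    line_ids: np.ndarray
    marker_ids: np.ndarray
    dosages: np.ndarray
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None
    biallelic: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.line_ids = np.asarray(self.line_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        for name, ids in (("line", self.line_ids), ("marker", self.marker_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicated {name} ids")
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            bad = obs[~np.isin(obs, (0.0, 1.0, 2.0))]
            raise ValueError(f"dosages outside {{0,1,2,nan}}: {bad[:5]}")
        if self.chrom is not None:
            self.chrom = np.asarray(self.chrom, dtype=object)
        if self.pos is not None:
            self.pos = np.asarray(self.pos, dtype=int)
        if self.biallelic is None:
            self.biallelic = np.ones(len(self.marker_ids), dtype=bool)
        else:
            self.biallelic = np.asarray(self.biallelic, dtype=bool)

    # -- basic properties -------------------------------------------------
    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per marker."""
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per marker, ignoring missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def is_homozygous(self) -> bool:
        obs = self.dosages[~np.isnan(self.dosages)]
        return not (obs == 1.0).any()

    # -- subsetting -------------------------------------------------------
    def subset_markers(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            line_ids=self.line_ids.copy(),
            marker_ids=self.marker_ids[index],
            dosages=self.dosages[:, index],
            chrom=None if self.chrom is None else self.chrom[index],
            pos=None if self.pos is None else self.pos[index],
            biallelic=self.biallelic[index],
        )

    def subset_lines(self, line_ids) -> "GenotypeMatrix":
        lookup = {l: i for i, l in enumerate(self.line_ids)}
        missing = [l for l in line_ids if l not in lookup]
        if missing:
            raise KeyError(f"unknown line ids: {missing[:5]}")
        idx = np.array([lookup[l] for l in line_ids])
        return GenotypeMatrix(
            line_ids=np.asarray(line_ids, dtype=object),
            marker_ids=self.marker_ids.copy(),
            dosages=self.dosages[idx, :],
            chrom=None if self.chrom is None else self.chrom.copy(),
            pos=None if self.pos is None else self.pos.copy(),
            biallelic=self.biallelic.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.line_ids, columns=self.marker_ids)


@dataclass
class QCReport:
    """Ordered, chained record of marker-filter steps.

    Each step is ``(name, markers_in, markers_removed, markers_out)`` with
    ``markers_out = markers_in - markers_removed``, and consecutive steps
    chain (the output of step *k* is the input of step *k+1*).
    """

    steps: list = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def add(self, name: str, markers_in: int, markers_removed: int) -> None:
        markers_out = markers_in - markers_removed
        if self.steps and self.steps[-1][3] != markers_in:
            raise ValueError("QC steps do not chain")
        if markers_out < 0:
            raise ValueError("removed more markers than present")
        self.steps.append((name, markers_in, markers_removed, markers_out))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.steps, columns=["step", "markers_in", "markers_removed", "markers_out"]
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------

_IUPAC_HET = {"R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC"}


def read_genotypes(path, format: str) -> GenotypeMatrix:
    """Read a genotype matrix from ``vcf``, ``hapmap`` or ``dosage-table``."""
    if format == "vcf":
        return _read_vcf(path)
    if format == "hapmap":
        return _read_hapmap(path)
    if format == "dosage-table":
        return _read_dosage_table(path)
    raise ValueError(f"unknown format {format!r}; expected vcf, hapmap or dosage-table")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    lines = np.asarray(vcf.samples, dtype=object)
    marker_ids, chrom, pos, biallelic, rows = [], [], [], [], []
    for i, v in enumerate(vcf):
        marker_ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}")
        chrom.append(v.CHROM)
        pos.append(v.POS)
        biallelic.append(len(v.ALT) == 1)
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = np.asarray(v.gt_types, dtype=float)
        dose = np.where(gt == 3, 2.0, gt)
        dose[gt == 2] = np.nan
        rows.append(dose)
    if not rows:
        raise ValueError(f"no variant records in {path}")
    return GenotypeMatrix(
        line_ids=lines,
        marker_ids=np.asarray(marker_ids, dtype=object),
        dosages=np.asarray(rows).T,
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos, dtype=int),
        biallelic=np.asarray(biallelic, dtype=bool),
    )


def _read_hapmap(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    meta_cols = df.columns[:11]
    sample_cols = df.columns[11:]
    if len(sample_cols) == 0:
        raise ValueError("HapMap file has no sample columns")
    alleles = df[meta_cols[1]].str.split("/", expand=True)
    alt = alleles[1].to_numpy()  # dosage counts the second-listed allele
    dosages = np.full((len(sample_cols), len(df)), np.nan)
    for j in range(len(df)):
        a2 = alt[j]
        for i, col in enumerate(sample_cols):
            call = df.iloc[j][col]
            if call in ("NN", "N", "NA", "--", None) or pd.isna(call):
                continue
            if len(call) == 1:
                call = _IUPAC_HET.get(call, call * 2)
            dosages[i, j] = sum(1 for a in call if a == a2)
    return GenotypeMatrix(
        line_ids=np.asarray(sample_cols, dtype=object),
        marker_ids=df[meta_cols[0]].to_numpy(dtype=object),
        dosages=dosages,
        chrom=df[meta_cols[2]].to_numpy(dtype=object),
        pos=df[meta_cols[3]].astype(int).to_numpy(),
    )


def _read_dosage_table(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    return GenotypeMatrix(
        line_ids=df.index.to_numpy(dtype=object),
        marker_ids=df.columns.to_numpy(dtype=object),
        dosages=df.to_numpy(dtype=float),
    )


def write_dosage_table(G: GenotypeMatrix, path) -> None:
    G.to_frame().to_csv(path, sep="\t", index_label="line")


def write_vcf(G: GenotypeMatrix, path) -> None:
    """Write diploid GT records; synthesizes chrom/pos when absent."""
    chrom = G.chrom if G.chrom is not None else np.array(["1"] * G.n_markers, dtype=object)
    pos = G.pos if G.pos is not None else np.arange(1, G.n_markers + 1)
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    for c in pd.unique(chrom):
        buf.write(f"##contig=<ID={c}>\n")
    buf.write(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(map(str, G.line_ids))
        + "\n"
    )
    for j in range(G.n_markers):
        calls = [
            gt_map.get(d, "./.") if not np.isnan(d) else "./."
            for d in G.dosages[:, j]
        ]
        buf.write(
            f"{chrom[j]}\t{pos[j]}\t{G.marker_ids[j]}\tA\tT\t.\tPASS\t.\tGT\t"
            + "\t".join(calls)
            + "\n"
        )
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# Imputation and the QC cascade
# ---------------------------------------------------------------------------


def impute_missing(G: GenotypeMatrix) -> GenotypeMatrix:
    """Per-marker mode imputation; ties broken toward the lower dosage.

    Intended for inbred panels where most markers are near-fixed within the
    panel, so the mode is a reasonable fill-in. Requires at least one
    observed call per marker.
    """
    D = G.dosages.copy()
    miss = np.isnan(D)
    if not miss.any():
        return replace(G, dosages=D)
    fully_missing = miss.all(axis=0)
    if fully_missing.any():
        bad = G.marker_ids[fully_missing][:5]
        raise ValueError(f"fully missing markers (apply call-rate filter first): {bad}")
    # counts of dosage 0/1/2 per marker; argmax takes the lowest on ties
    counts = np.stack([(D == v).sum(axis=0) for v in (0.0, 1.0, 2.0)])
    mode = counts.argmax(axis=0).astype(float)
    D[miss] = np.broadcast_to(mode, D.shape)[miss]
    return replace(G, dosages=D)


def _ld_prune_keep(D: np.ndarray, chrom: np.ndarray | None, r2_max: float) -> np.ndarray:
    """Greedy in-order LD prune: drop a marker whose squared correlation with
    any earlier *kept* marker exceeds ``r2_max``. Per chromosome when
    coordinates are available, otherwise over all pairs."""
    n, p = D.shape
    keep = np.ones(p, dtype=bool)
    groups = (
        [np.arange(p)]
        if chrom is None
        else [np.flatnonzero(chrom == c) for c in pd.unique(chrom)]
    )
    mu = D.mean(axis=0)
    sd = D.std(axis=0)
    Z = np.zeros_like(D)
    ok = sd > 0
    Z[:, ok] = (D[:, ok] - mu[ok]) / sd[ok] / np.sqrt(n)  # columns unit norm
    for idx in groups:
        kept_cols: list[int] = []
        for j in idx:
            if sd[j] == 0:  # monomorphic: correlation undefined, cannot be in LD
                kept_cols.append(j)
                continue
            if kept_cols:
                r = Z[:, kept_cols].T @ Z[:, j]
                if (r * r).max() > r2_max + _EPS:
                    keep[j] = False
                    continue
            kept_cols.append(j)
    return keep


def qc_parent_panel(
    G: GenotypeMatrix, min_call_rate: float = 0.90, r2_max: float = 0.99
) -> tuple[GenotypeMatrix, QCReport]:
    """Structure-branch QC: call rate >= threshold, biallelic only, mode
    imputation, then near-perfect-LD pruning.

    Markers observed in less than ``min_call_rate`` of lines are removed
    (a marker at exactly the threshold is retained). Heterozygous and rare
    markers survive this branch by design.
    """
    report = QCReport(params={"min_call_rate": min_call_rate, "r2_max": r2_max})

    keep = G.call_rate() >= min_call_rate - _EPS
    report.add("call_rate", G.n_markers, int((~keep).sum()))
    G = G.subset_markers(keep)

    keep = G.biallelic.copy()
    report.add("biallelic", G.n_markers, int((~keep).sum()))
    G = G.subset_markers(keep)
    if G.n_markers == 0:
        raise EmptyPanelError("no markers left after biallelic filter")

    G = impute_missing(G)
    report.add("impute", G.n_markers, 0)

    keep = _ld_prune_keep(G.dosages, G.chrom, r2_max)
    report.add("ld_prune", G.n_markers, int((~keep).sum()))
    G = G.subset_markers(keep)
    if G.n_markers == 0:
        raise EmptyPanelError("no markers left after QC")
    return G, report


def qc_hybrid_panel(
    G: GenotypeMatrix,
    maf_min: float = 0.05,
    design=None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Prediction-branch QC on a panel already through :func:`qc_parent_panel`.

    Removes markers heterozygous in any parent, duplicate marker content
    across chromosomes (identical dosage vectors, first kept), and markers
    with minor allele frequency below ``maf_min`` among the derived single
    crosses. With ``design=None`` the cross allele frequencies equal the
    parental ones (every parent contributes equally in a full diallel);
    passing a :class:`~diallelgp.kinship.HybridDesign` uses the realized
    cross set instead.
    """
    report = QCReport(params={"maf_min": maf_min})
    if np.isnan(G.dosages).any():
        raise ValueError("hybrid-panel QC expects an imputed (complete) matrix")

    keep = ~(G.dosages == 1.0).any(axis=0)
    report.add("heterozygous_parent", G.n_markers, int((~keep).sum()))
    G = G.subset_markers(keep)

    keep = _duplicate_content_keep(G)
    report.add("cross_chrom_duplicate", G.n_markers, int((~keep).sum()))
    G = G.subset_markers(keep)

    if design is None:
        p = G.allele_freq()
    else:
        from .kinship import build_hybrid_genotypes

        hyb = build_hybrid_genotypes(G, design)
        p = hyb.W_A.mean(axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    keep = maf >= maf_min - _EPS
    report.add("maf", G.n_markers, int((~keep).sum()))
    G = G.subset_markers(keep)
    if G.n_markers == 0:
        raise EmptyPanelError("no markers left after hybrid-panel QC")
    return G, report


def _duplicate_content_keep(G: GenotypeMatrix) -> np.ndarray:
    """Keep the first occurrence of each dosage vector; drop later identical
    markers on a *different* chromosome (any later identical marker when no
    coordinates are present)."""
    keep = np.ones(G.n_markers, dtype=bool)
    seen: dict[bytes, int] = {}
    for j in range(G.n_markers):
        key = G.dosages[:, j].tobytes()
        if key in seen:
            first = seen[key]
            if G.chrom is None or G.chrom[j] != G.chrom[first]:
                keep[j] = False
        else:
            seen[key] = j
    return keep
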