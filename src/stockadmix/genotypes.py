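"""Genotype matrices: I/O, quality filtering and missing-data imputation.

The analysis operates on one genotype matrix per wild lake paired with its
domestic hatchery reference panel. Genotypes are diploid allele counts
(0/1/2, ``-1`` for missing). Filtering follows the study design for
reduced-representation (GBS/RAD) data: drop individuals with too much
missingness, drop non-biallelic and low-MAF loci, and keep a single SNP per
RAD locus to limit linkage disequilibrium between markers.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1

ROLE_WILD = "wild"
ROLE_DOMESTIC = "domestic"

_LOCUS_ID_RE = re.compile(r"^(?P<locus>.+)_(?P<snp>\d+)$")


@dataclass
class GenotypeMatrix:
    """Individuals x loci diploid genotype matrix with population metadata.

    Attributes
    ----------
    genotypes:
        ``(n_individuals, n_loci)`` int array of alternate-allele counts in
        ``{0, 1, 2}``; missing calls are ``MISSING`` (-1).
    individual_ids, populations, roles:
        Per-individual metadata; ``roles`` is ``"wild"`` or ``"domestic"``.
    locus_ids, snp_positions:
        Per-SNP RAD locus identifier and the SNP's position within that
        locus (used by the one-SNP-per-locus filter).
    chrom, pos:
        Optional genomic coordinates (1-based, as in VCF).
    multiallelic:
        Per-SNP flag; multi-allelic records are retained on read and removed
        by the biallelic filter.
    """

    genotypes: np.ndarray
    individual_ids: list[str]
    populations: list[str]
    roles: list[str]
    locus_ids: list[str]
    snp_positions: np.ndarray
    chrom: list[str] | None = None
    pos: np.ndarray | None = None
    multiallelic: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int16)
        n_ind, n_loc = self.genotypes.shape
        if not (len(self.individual_ids) == len(self.populations) == len(self.roles) == n_ind):
            raise ValueError("individual metadata length does not match genotype rows")
        if len(self.locus_ids) != n_loc or len(self.snp_positions) != n_loc:
            raise ValueError("locus metadata length does not match genotype columns")
        valid = np.isin(self.genotypes, (MISSING, 0, 1, 2))
        if not valid.all():
            bad = np.unique(self.genotypes[~valid])
            raise ValueError(f"genotype values outside {{0,1,2,missing}}: {bad.tolist()}")
        if self.multiallelic is None:
            self.multiallelic = np.zeros(n_loc, dtype=bool)
        self.snp_positions = np.asarray(self.snp_positions, dtype=np.int64)

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    def missing_fraction(self) -> np.ndarray:
        """Per-individual fraction of missing calls."""
        return (self.genotypes == MISSING).mean(axis=1)

    def take_individuals(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            genotypes=self.genotypes[idx],
            individual_ids=[self.individual_ids[i] for i in idx],
            populations=[self.populations[i] for i in idx],
            roles=[self.roles[i] for i in idx],
        )

    def take_loci(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            genotypes=self.genotypes[:, idx],
            locus_ids=[self.locus_ids[i] for i in idx],
            snp_positions=self.snp_positions[idx],
            chrom=None if self.chrom is None else [self.chrom[i] for i in idx],
            pos=None if self.pos is None else self.pos[idx],
            multiallelic=self.multiallelic[idx],
        )

    def allele_frequencies(self, rows: np.ndarray | None = None) -> np.ndarray:
        """Alternate-allele frequency per locus over non-missing calls.

        Loci with no observed calls get ``nan``.
        """
        g = self.genotypes if rows is None else self.genotypes[rows]
        observed = g != MISSING
        counts = np.where(observed, g, 0).sum(axis=0)
        n_obs = observed.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_obs > 0, counts / (2.0 * n_obs), np.nan)


@dataclass
class FilterConfig:
    """Thresholds of the genotype quality filters.

    ``maf_min`` removes loci with minor allele frequency strictly below it
    (a locus at exactly the threshold is kept); ``max_ind_missing`` removes
    individuals whose missing fraction is at or above it (only individuals
    with strictly less missingness are kept).
    """

    maf_min: float = 0.10
    max_ind_missing: float = 0.20
    one_snp_per_locus: bool = True
    biallelic_only: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError(f"maf_min must be in [0, 0.5], got {self.maf_min}")
        if not 0.0 <= self.max_ind_missing < 1.0:
            raise ValueError(f"max_ind_missing must be in [0, 1), got {self.max_ind_missing}")


@dataclass
class FilterReport:
    removed_individuals: list[str] = field(default_factory=list)
    retention: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# I/O


def read_labels(path) -> pd.DataFrame:
    labels = pd.read_csv(path)
    required = {"individual_id", "population", "role"}
    if missing := required - set(labels.columns):
        raise ValueError(f"label file {path} lacks columns: {sorted(missing)}")
    bad_roles = set(labels["role"]) - {ROLE_WILD, ROLE_DOMESTIC}
    if bad_roles:
        raise ValueError(f"unknown roles in {path}: {sorted(bad_roles)}")
    return labels


def _split_locus_id(vcf_id: str, chrom: str, pos: int) -> tuple[str, int]:
    # RAD convention "<locus>_<snp position within locus>"; otherwise group
    # by chromosome with the genomic position as within-locus position.
    if vcf_id and (m := _LOCUS_ID_RE.match(vcf_id)):
        return m.group("locus"), int(m.group("snp"))
    return str(chrom), int(pos)


def read_vcf(path: str, labels_path: str) -> GenotypeMatrix:
    """Read a VCF (GT field) plus a population-label CSV.

    Multi-allelic records are kept but flagged for the biallelic filter.
    Positions stay 1-based as written.
    """
    from cyvcf2 import VCF

    labels = read_labels(labels_path).set_index("individual_id")
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on parse failure
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in labels.index]
    if unknown:
        raise ValueError(f"samples missing from label file: {unknown}")

    rows: list[np.ndarray] = []
    locus_ids: list[str] = []
    snp_positions: list[int] = []
    chroms: list[str] = []
    positions: list[int] = []
    multi: list[bool] = []
    for record_no, variant in enumerate(vcf, start=1):
        gts = variant.genotype.array()
        if gts.shape[1] < 2:
            raise ValueError(f"non-diploid record at line-level record {record_no} in {path}")
        alleles = gts[:, :2]
        missing_mask = (alleles < 0).any(axis=1)
        g = (alleles > 0).sum(axis=1).astype(np.int16)
        g[missing_mask] = MISSING
        rows.append(g)
        locus, snp_pos = _split_locus_id(variant.ID or "", variant.CHROM, variant.POS)
        locus_ids.append(locus)
        snp_positions.append(snp_pos)
        chroms.append(variant.CHROM)
        positions.append(variant.POS)
        multi.append(len(variant.ALT) > 1)
    if not rows:
        raise ValueError(f"no variant records in {path}")

    return GenotypeMatrix(
        genotypes=np.column_stack(rows) if len(rows) > 1 else np.asarray(rows[0])[:, None],
        individual_ids=samples,
        populations=[str(labels.loc[s, "population"]) for s in samples],
        roles=[str(labels.loc[s, "role"]) for s in samples],
        locus_ids=locus_ids,
        snp_positions=np.asarray(snp_positions),
        chrom=chroms,
        pos=np.asarray(positions, dtype=np.int64),
        multiallelic=np.asarray(multi, dtype=bool),
    )


def write_vcf(G: GenotypeMatrix, path: str) -> None:
    """Write biallelic records as a minimal VCF v4.2 (GT only, ./. missing)."""
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(G.individual_ids) + "\n")
        for j in range(G.n_loci):
            chrom = G.chrom[j] if G.chrom is not None else "1"
            pos = int(G.pos[j]) if G.pos is not None else j + 1
            vid = f"{G.locus_ids[j]}_{int(G.snp_positions[j])}"
            calls = "\t".join(gt_codes[int(g)] for g in G.genotypes[:, j])
            fh.write(f"{chrom}\t{pos}\t{vid}\tA\tC\t.\tPASS\t.\tGT\t{calls}\n")


def write_labels(G: GenotypeMatrix, path: str) -> None:
    pd.DataFrame(
        {
            "individual_id": G.individual_ids,
            "population": G.populations,
            "role": G.roles,
        }
    ).to_csv(path, index=False)


def write_012(G: GenotypeMatrix, path: str) -> None:
    """Tab-separated individuals x loci matrix, -1 for missing."""
    df = pd.DataFrame(
        G.genotypes,
        index=pd.Index(G.individual_ids, name="individual_id"),
        columns=[f"{loc}_{int(p)}" for loc, p in zip(G.locus_ids, G.snp_positions)],
    )
    df.to_csv(path, sep="\t")


def read_012(path: str, labels_path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = read_labels(labels_path).set_index("individual_id")
    unknown = [s for s in df.index if s not in labels.index]
    if unknown:
        raise ValueError(f"samples missing from label file: {unknown}")
    g = df.to_numpy()
    g = np.where(pd.isna(g), MISSING, g).astype(np.int16)
    locus_ids, snp_positions = [], []
    for col in df.columns:
        locus, snp = _split_locus_id(str(col), str(col), 0)
        locus_ids.append(locus)
        snp_positions.append(snp)
    return GenotypeMatrix(
        genotypes=g,
        individual_ids=[str(s) for s in df.index],
        populations=[str(labels.loc[s, "population"]) for s in df.index],
        roles=[str(labels.loc[s, "role"]) for s in df.index],
        locus_ids=locus_ids,
        snp_positions=np.asarray(snp_positions),
    )


# ---------------------------------------------------------------------------
# Filtering


def filter_individuals(
    G: GenotypeMatrix, cfg: FilterConfig | None = None
) -> tuple[GenotypeMatrix, FilterReport]:
    """Keep individuals with missing fraction strictly below the threshold."""
    cfg = cfg or FilterConfig()
    frac = G.missing_fraction()
    keep = frac < cfg.max_ind_missing
    removed = [iid for iid, k in zip(G.individual_ids, keep) if not k]
    if not keep.any():
        raise ValueError(
            "all individuals removed by the missingness filter; "
            f"review max_ind_missing={cfg.max_ind_missing}"
        )
    report = FilterReport(removed_individuals=removed)
    return G.take_individuals(np.flatnonzero(keep)), report


def filter_loci(
    G: GenotypeMatrix, cfg: FilterConfig | None = None
) -> tuple[GenotypeMatrix, FilterReport]:
    """Biallelic filter, then MAF filter, then one SNP per locus.

    MAF is computed over the non-missing calls of the combined wild +
    domestic pair. Within each locus the SNP with the lowest within-locus
    position survives. Retention counts after each step are reported.
    """
    cfg = cfg or FilterConfig()
    report = FilterReport(retention={"input": G.n_loci})

    if cfg.biallelic_only:
        G = G.take_loci(np.flatnonzero(~G.multiallelic))
    report.retention["biallelic"] = G.n_loci

    freq = G.allele_frequencies()
    with np.errstate(invalid="ignore"):
        maf = np.minimum(freq, 1.0 - freq)
    keep = ~np.isnan(maf) & (maf >= cfg.maf_min)
    G = G.take_loci(np.flatnonzero(keep))
    report.retention["maf"] = G.n_loci

    if cfg.one_snp_per_locus and G.n_loci:
        first: dict[str, int] = {}
        for j, (locus, snp) in enumerate(zip(G.locus_ids, G.snp_positions)):
            if locus not in first or snp < G.snp_positions[first[locus]]:
                first[locus] = j
        G = G.take_loci(np.sort(np.fromiter(first.values(), dtype=np.int64)))
    report.retention["one_per_locus"] = G.n_loci

    if G.n_loci == 0:
        raise ValueError("no loci survive filtering; review thresholds")
    return G, report


def impute_missing(G: GenotypeMatrix, seed: int) -> GenotypeMatrix:
    """Replace missing calls by binomial draws from population allele frequencies.

    Each missing genotype at locus j for an individual in population P is
    drawn as Binomial(2, p) with p the alternate-allele frequency at j among
    P's observed calls; loci unobserved within P fall back to the pooled
    frequency. Observed calls are never altered; results are reproducible
    under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    g = G.genotypes.copy()
    pooled = G.allele_frequencies()
    pops = np.asarray(G.populations)
    for pop in pd.unique(pops):
        rows = np.flatnonzero(pops == pop)
        p = G.allele_frequencies(rows)
        undefined = np.isnan(p)
        if undefined.any():
            p = np.where(undefined, pooled, p)
        if np.isnan(p).any():
            bad = [G.locus_ids[j] for j in np.flatnonzero(np.isnan(p))]
            raise ValueError(f"allele frequency undefined even pooled at loci {bad[:5]}")
        sub = g[rows]
        miss = sub == MISSING
        if miss.any():
            draws = rng.binomial(2, np.broadcast_to(p, sub.shape)[miss])
            sub[miss] = draws.astype(np.int16)
            g[rows] = sub
    return replace(G, genotypes=g)


def filter_pipeline(
    G: GenotypeMatrix, cfg: FilterConfig | None = None, impute_seed: int | None = None
) -> tuple[GenotypeMatrix, FilterReport]:
    """Individual filter, locus filters, optional imputation, one report."""
    cfg = cfg or FilterConfig()
    G, ind_report = filter_individuals(G, cfg)
    G, loc_report = filter_loci(G, cfg)
    loc_report.removed_individuals = ind_report.removed_individuals
    if impute_seed is not None:
        G = impute_missing(G, impute_seed)
        if (G.genotypes == MISSING).any():  # pragma: no cover - safety net
            warnings.warn("missing calls remain after imputation")
    return G, loc_report
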