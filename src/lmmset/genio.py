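"""Genotype I/O, quality control, encoding and SNP-set construction.

Reads and writes PLINK 1 binary filesets (BED/BIM/FAM, SNP-major), applies the
standard per-SNP and per-individual quality-control filters used in GWAS
cohorts, mean-imputes missing calls, and groups SNPs into named sets (explicit
set files, gene ranges, or overlapping centimorgan windows along the map).

Dosages are stored as the count of the *minor* allele (0/1/2), the additive
encoding assumed by every downstream model.  Missing calls are represented as
``numpy.nan`` in a float matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# PLINK 1 two-bit call -> dosage of allele A1 (nan = missing)
_BED_DECODE = np.array([2.0, np.nan, 1.0, 0.0])


class FormatError(ValueError):
    """Raised when an input file is not in the expected format."""


class IntegrityError(ValueError):
    """Raised when files of one dataset disagree on dimensions or keys."""


class EmptyDataError(ValueError):
    """Raised when filtering removes every SNP (or every individual)."""


@dataclass(frozen=True)
class SnpRecord:
    """Metadata for one SNP: identifier, map position and alleles."""

    snp_id: str
    chromosome: str
    position_bp: int
    position_cm: float
    allele_minor: str
    allele_major: str

    def __post_init__(self):
        if self.position_bp < 0:
            raise ValueError(f"negative bp position for {self.snp_id}")


@dataclass
class GenotypeData:
    """An in-memory cohort: individuals, SNP metadata, dosages and phenotype.

    ``dosage`` is an n x s float matrix with entries in {0, 1, 2, nan}
    counting minor alleles.  ``phenotype`` is a length-n float vector
    (case-control cohorts are coded 0/1).
    """

    individuals: list[tuple[str, str]]
    snps: list[SnpRecord]
    dosage: np.ndarray
    phenotype: np.ndarray | None = None

    def __post_init__(self):
        n, s = self.dosage.shape
        if n != len(self.individuals) or s != len(self.snps):
            raise IntegrityError(
                f"dosage is {self.dosage.shape} but there are "
                f"{len(self.individuals)} individuals and {len(self.snps)} SNPs"
            )
        ids = [r.snp_id for r in self.snps]
        if len(set(ids)) != len(ids):
            raise IntegrityError("duplicate SNP ids in dataset")
        if self.phenotype is not None and len(self.phenotype) != n:
            raise IntegrityError("phenotype length does not match cohort size")

    @property
    def n(self) -> int:
        return self.dosage.shape[0]

    @property
    def s(self) -> int:
        return self.dosage.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.snps]

    def snp_index(self) -> dict[str, int]:
        return {r.snp_id: j for j, r in enumerate(self.snps)}

    def subset(self, indiv_idx=None, snp_idx=None) -> "GenotypeData":
        indiv_idx = np.arange(self.n) if indiv_idx is None else np.asarray(indiv_idx)
        snp_idx = np.arange(self.s) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeData(
            individuals=[self.individuals[i] for i in indiv_idx],
            snps=[self.snps[j] for j in snp_idx],
            dosage=self.dosage[np.ix_(indiv_idx, snp_idx)].copy(),
            phenotype=None if self.phenotype is None else self.phenotype[indiv_idx].copy(),
        )

    def has_genetic_map(self) -> bool:
        """True if any SNP carries a nonzero centimorgan coordinate."""
        return any(r.position_cm != 0.0 for r in self.snps)

    def map_cm(self) -> np.ndarray:
        """Per-SNP genetic-map coordinate in centimorgans.

        When the map column is absent (all zeros), falls back to the common
        1 cM ~ 1 Mb heuristic on the physical position, with a warning.
        """
        if self.has_genetic_map():
            return np.array([r.position_cm for r in self.snps])
        logger.warning(
            "no genetic-map (cM) coordinates present; approximating 1 cM ~ 1 Mb "
            "from physical positions for window building and exclusion"
        )
        return np.array([r.position_bp / 1e6 for r in self.snps])


@dataclass(frozen=True)
class SnpSet:
    """A named, ordered group of SNP ids to be tested jointly."""

    set_id: str
    snp_ids: tuple[str, ...]

    def __post_init__(self):
        if len(self.snp_ids) == 0:
            raise ValueError(f"set {self.set_id} is empty")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError(f"set {self.set_id} contains duplicate SNP ids")

    def __len__(self) -> int:
        return len(self.snp_ids)


@dataclass
class QcReport:
    """Counts of removals per quality-control rule."""

    n_indiv_removed_missing: int = 0
    n_snp_removed_maf: int = 0
    n_snp_removed_missing: int = 0
    n_snp_removed_hwe: int = 0

    def total_snps_removed(self) -> int:
        return (
            self.n_snp_removed_maf
            + self.n_snp_removed_missing
            + self.n_snp_removed_hwe
        )


# ---------------------------------------------------------------------------
# PLINK 1 binary I/O
# ---------------------------------------------------------------------------

def _read_fam(fam_path) -> pd.DataFrame:
    fam = pd.read_csv(
        fam_path, sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    if fam.shape[1] != 6:
        raise FormatError(f"{fam_path}: FAM file must have 6 columns")
    return fam


def _read_bim(bim_path) -> pd.DataFrame:
    bim = pd.read_csv(
        bim_path, sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "bp", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    return bim


def _phenotype_from_file(path, keys: list[tuple[str, str]]) -> np.ndarray:
    """Read a whitespace-separated FID IID PHENO file keyed on the FAM order."""
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    if df.shape[1] < 3:
        raise FormatError(f"{path}: phenotype file needs FID IID PHENO columns")
    # tolerate an optional header line
    try:
        float(df.iloc[0, 2])
    except ValueError:
        df = df.iloc[1:]
    lookup = {(r[0], r[1]): float(r[2]) for r in df.itertuples(index=False)}
    return np.array([lookup.get(k, np.nan) for k in keys])


def read_plink(bed_path, bim_path, fam_path, pheno_source=None) -> GenotypeData:
    """Read a PLINK 1 binary fileset into a :class:`GenotypeData`.

    The returned dosage counts the minor allele: if the file's counted allele
    (A1) turns out to be the major one by observed frequency, the column is
    flipped and the allele labels swapped.  Individuals with a missing
    phenotype are dropped (with a log message).

    Parameters
    ----------
    pheno_source
        ``None`` to take the phenotype from FAM column 6, or a path to a
        whitespace-separated ``FID IID PHENO`` file (optional header).
    """
    fam = _read_fam(fam_path)
    bim = _read_bim(bim_path)
    n, s = len(fam), len(bim)

    with open(bed_path, "rb") as fh:
        raw = fh.read()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(
            f"{bed_path}: bad magic bytes {raw[:3].hex()} "
            "(expected 6c1b01: PLINK 1 SNP-major BED)"
        )
    bytes_per_snp = (n + 3) // 4
    payload = np.frombuffer(raw[3:], dtype=np.uint8)
    if payload.size != bytes_per_snp * s:
        raise IntegrityError(
            f"{bed_path}: payload of {payload.size} bytes inconsistent with "
            f"{n} individuals x {s} SNPs ({bytes_per_snp * s} expected)"
        )
    # unpack two-bit calls, little-endian within each byte
    codes = payload.reshape(s, bytes_per_snp)
    calls = np.empty((s, bytes_per_snp * 4), dtype=np.uint8)
    for shift in range(4):
        calls[:, shift::4] = (codes >> (2 * shift)) & 0b11
    dosage = _BED_DECODE[calls[:, :n]].T.copy()  # n x s dosage of A1

    snps = []
    for j, row in enumerate(bim.itertuples(index=False)):
        a_minor, a_major = row.a1, row.a2
        col = dosage[:, j]
        obs = col[~np.isnan(col)]
        if obs.size and obs.mean() / 2.0 > 0.5:
            dosage[:, j] = 2.0 - col
            a_minor, a_major = a_major, a_minor
        snps.append(
            SnpRecord(
                snp_id=row.snp_id, chromosome=str(row.chrom),
                position_bp=int(row.bp), position_cm=float(row.cm),
                allele_minor=a_minor, allele_major=a_major,
            )
        )

    keys = list(zip(fam["fid"], fam["iid"]))
    if pheno_source is None:
        pheno = fam["pheno"].astype(float).to_numpy()
        pheno = np.where(pheno == -9.0, np.nan, pheno)
        vals = set(np.unique(pheno[~np.isnan(pheno)]))
        if vals and vals <= {0.0, 1.0, 2.0} and 2.0 in vals:
            # PLINK case/control convention: 1=control, 2=case, 0=missing
            pheno = np.where(pheno == 0.0, np.nan, pheno - 1.0)
            logger.info("FAM phenotype recoded from 1/2 case-control to 0/1")
    else:
        pheno = _phenotype_from_file(pheno_source, keys)

    keep = ~np.isnan(pheno)
    if not keep.all():
        logger.info("dropping %d individuals with missing phenotype", (~keep).sum())
    data = GenotypeData(
        individuals=[k for k, ok in zip(keys, keep) if ok],
        snps=snps,
        dosage=dosage[keep],
        phenotype=pheno[keep],
    )
    return data


def write_plink(data: GenotypeData, prefix) -> None:
    """Write ``data`` as PLINK 1 BED/BIM/FAM (A1 = minor allele).

    Phenotype is written to FAM column 6 as-is (missing -> -9).
    """
    prefix = str(prefix)
    n, s = data.n, data.s
    with open(prefix + ".bim", "w") as fh:
        for r in data.snps:
            fh.write(
                f"{r.chromosome}\t{r.snp_id}\t{r.position_cm:g}\t{r.position_bp}"
                f"\t{r.allele_minor}\t{r.allele_major}\n"
            )
    pheno = data.phenotype
    with open(prefix + ".fam", "w") as fh:
        for i, (fid, iid) in enumerate(data.individuals):
            if pheno is None or np.isnan(pheno[i]):
                p = "-9"
            else:
                p = f"{pheno[i]:g}"
            fh.write(f"{fid}\t{iid}\t0\t0\t0\t{p}\n")

    # encode: dosage of A1 -> 2-bit PLINK call
    code = np.full(data.dosage.T.shape, 0b01, dtype=np.uint8)  # missing
    dT = data.dosage.T
    code[dT == 2.0] = 0b00
    code[dT == 1.0] = 0b10
    code[dT == 0.0] = 0b11
    bytes_per_snp = (n + 3) // 4
    padded = np.full((s, bytes_per_snp * 4), 0b00, dtype=np.uint8)
    padded[:, :n] = code
    packed = np.zeros((s, bytes_per_snp), dtype=np.uint8)
    for shift in range(4):
        packed |= padded[:, shift::4] << (2 * shift)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def minor_allele_frequency(dosage: np.ndarray) -> np.ndarray:
    """Per-column frequency of the counted (minor) allele, ignoring missing."""
    with np.errstate(invalid="ignore"):
        return np.nanmean(dosage, axis=0) / 2.0


def hwe_chisq_pvalue(dosage_col: np.ndarray) -> float:
    """1-df chi-square goodness-of-fit test of Hardy-Weinberg proportions.

    Observed genotype counts are compared with the counts expected at the
    observed allele frequency; monomorphic columns return P = 1.
    """
    obs = dosage_col[~np.isnan(dosage_col)]
    m = obs.size
    if m == 0:
        return 1.0
    counts = np.array([(obs == 0).sum(), (obs == 1).sum(), (obs == 2).sum()], float)
    q = (2 * counts[2] + counts[1]) / (2 * m)
    exp = m * np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
    mask = exp > 0
    chi2 = float(((counts[mask] - exp[mask]) ** 2 / exp[mask]).sum())
    return float(stats.chi2.sf(chi2, df=1))


def qc_filter(
    data: GenotypeData,
    maf_min: float = 0.05,
    missing_rate_max: float = 0.10,
    hwe_alpha: float = 0.001,
    indiv_missing_max: float = 0.10,
) -> tuple[GenotypeData, QcReport]:
    """Apply the standard cohort QC filters.

    Individuals with a missing-call fraction strictly above
    ``indiv_missing_max`` are removed first; SNP statistics are then computed
    on the remaining cohort.  A SNP is removed when its minor-allele frequency
    is strictly below ``maf_min``, its missing rate strictly above
    ``missing_rate_max``, or its Hardy-Weinberg chi-square P-value strictly
    below ``hwe_alpha``.
    """
    for name, v in [("maf_min", maf_min), ("missing_rate_max", missing_rate_max),
                    ("indiv_missing_max", indiv_missing_max)]:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    if not 0.0 < hwe_alpha < 1.0:
        raise ValueError(f"hwe_alpha={hwe_alpha} outside (0, 1)")

    report = QcReport()
    miss_ind = np.isnan(data.dosage).mean(axis=1)
    keep_ind = miss_ind <= indiv_missing_max
    report.n_indiv_removed_missing = int((~keep_ind).sum())
    if not keep_ind.any():
        raise EmptyDataError("all individuals removed by missingness filter")
    if not keep_ind.all():
        data = data.subset(indiv_idx=np.flatnonzero(keep_ind))

    maf = minor_allele_frequency(data.dosage)
    miss_snp = np.isnan(data.dosage).mean(axis=0)
    fail_maf = maf < maf_min
    fail_miss = miss_snp > missing_rate_max
    hwe_p = np.array([hwe_chisq_pvalue(data.dosage[:, j]) for j in range(data.s)])
    fail_hwe = hwe_p < hwe_alpha

    report.n_snp_removed_maf = int(fail_maf.sum())
    report.n_snp_removed_missing = int(fail_miss.sum())
    report.n_snp_removed_hwe = int(fail_hwe.sum())
    keep_snp = ~(fail_maf | fail_miss | fail_hwe)
    if not keep_snp.any():
        raise EmptyDataError("all SNPs removed by QC filters")
    out = data.subset(snp_idx=np.flatnonzero(keep_snp))
    return out, report


def encode_and_impute(data: GenotypeData) -> np.ndarray:
    """Return the 0/1/2 dosage matrix with missing calls mean-imputed.

    Each missing entry is replaced by the observed mean of its column; a
    column with no observed calls is an error (it cannot survive QC).
    """
    X = data.dosage.astype(float).copy()
    missing = np.isnan(X)
    if missing.any():
        n_obs = (~missing).sum(axis=0)
        if (n_obs == 0).any():
            bad = [data.snps[j].snp_id for j in np.flatnonzero(n_obs == 0)]
            raise EmptyDataError(f"columns with no observed genotypes: {bad}")
        col_means = np.nansum(X, axis=0) / n_obs
        X[missing] = np.broadcast_to(col_means, X.shape)[missing]
    return X


# ---------------------------------------------------------------------------
# Set construction
# ---------------------------------------------------------------------------

def _resolve(snp_ids, known: dict[str, int], set_id: str) -> list[str]:
    kept, dropped = [], []
    for sid in snp_ids:
        (kept if sid in known else dropped).append(sid)
    if dropped:
        logger.warning("set %s: dropping %d unresolvable SNP ids (e.g. %s)",
                       set_id, len(dropped), dropped[0])
    return kept


def read_set_file(path, data: GenotypeData) -> list[SnpSet]:
    """Read a two-column TSV (set_id, snp_id) into SnpSets."""
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["set_id", "snp_id"],
                     dtype=str, comment="#")
    known = data.snp_index()
    out = []
    for set_id, grp in df.groupby("set_id", sort=True):
        ids = list(dict.fromkeys(grp["snp_id"]))  # dedupe, keep order
        ids = _resolve(ids, known, set_id)
        if ids:
            out.append(SnpSet(set_id=str(set_id), snp_ids=tuple(ids)))
        else:
            logger.warning("set %s has no resolvable SNPs; omitted", set_id)
    if not out:
        raise EmptyDataError(f"{path}: no usable sets")
    return out


def sets_from_gene_ranges(path, data: GenotypeData, flank_bp: int = 0) -> list[SnpSet]:
    """Build sets from a gene-range TSV: chrom, start, end, name.

    Coordinates in the file are 1-based inclusive; a SNP belongs to a gene
    when start - flank <= bp <= end + flank on the same chromosome.  Ranges
    covering no SNPs are omitted with a warning.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None,
                     names=["chrom", "start", "end", "name"],
                     dtype={"chrom": str, "name": str}, comment="#")
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for r in data.snps:
        by_chrom.setdefault(r.chromosome, []).append((r.position_bp, r.snp_id))
    out = []
    for row in df.itertuples(index=False):
        lo, hi = int(row.start) - flank_bp, int(row.end) + flank_bp
        members = [sid for bp, sid in sorted(by_chrom.get(str(row.chrom), []))
                   if lo <= bp <= hi]
        if members:
            out.append(SnpSet(set_id=str(row.name), snp_ids=tuple(members)))
        else:
            logger.warning("gene range %s covers no SNPs; omitted", row.name)
    out.sort(key=lambda s: s.set_id)
    if not out:
        raise EmptyDataError(f"{path}: no gene range covers any SNP")
    return out


def sets_from_cm_windows(data: GenotypeData, width_cm: float = 1.0) -> list[SnpSet]:
    """Overlapping genetic-map windows of ``width_cm`` with half-width step.

    Windows are [start, start + w) with start advancing by w/2 from the first
    SNP on each chromosome.  Singleton windows are dropped (only multi-SNP
    windows form sets), as are windows whose membership duplicates the
    previous window's.
    """
    if width_cm <= 0:
        raise ValueError("window width must be positive")
    cm = data.map_cm()
    out = []
    chroms: dict[str, list[int]] = {}
    for j, r in enumerate(data.snps):
        chroms.setdefault(r.chromosome, []).append(j)
    step = width_cm / 2.0
    for chrom in sorted(chroms):
        idx = sorted(chroms[chrom], key=lambda j: cm[j])
        pos = np.array([cm[j] for j in idx])
        start = np.floor(pos[0] / step) * step
        prev_members: tuple[str, ...] | None = None
        while start <= pos[-1]:
            inside = [idx[i] for i in np.flatnonzero((pos >= start) & (pos < start + width_cm))]
            members = tuple(data.snps[j].snp_id for j in inside)
            if len(members) >= 2 and members != prev_members:
                out.append(SnpSet(
                    set_id=f"chr{chrom}:{start:.2f}cM",
                    snp_ids=members,
                ))
                prev_members = members
            start += step
    out.sort(key=lambda s: s.set_id)
    if not out:
        raise EmptyDataError("no non-singleton windows found")
    return out


def build_sets(data: GenotypeData, mode: str, **params) -> list[SnpSet]:
    """Dispatch set construction: ``from_file``, ``gene_ranges`` or ``cm_windows``."""
    if mode == "from_file":
        return read_set_file(params["path"], data)
    if mode == "gene_ranges":
        return sets_from_gene_ranges(params["path"], data,
                                     flank_bp=params.get("flank_bp", 0))
    if mode == "cm_windows":
        return sets_from_cm_windows(data, width_cm=params.get("width_cm", 1.0))
    raise ValueError(f"unknown set construction mode: {mode!r}")
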