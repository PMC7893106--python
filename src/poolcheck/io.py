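"""Reading, writing, validation and alignment of pool-genotyping inputs.

Two tables drive everything downstream:

* a **genotype matrix** of per-animal allele dosages (0/1/2 copies of the
  modeled allele, ``NA`` for missing) over the SNPs of a genotyping array,
  and
* a **pool frequency table** of measured allele frequencies for each
  constructed DNA pool, with metadata recording the pooling method and the
  construction / extraction replicate.

Dosage divided by two is an individual's allele frequency; it is the random
covariate of the contribution model, so the per-SNP mean frequency across
animals is the expected pool frequency under exactly equal contributions.

TSV is the canonical interchange format.  A VCF convenience reader is
provided for biallelic SNPs (dosage = ALT allele count).  SNPs are keyed by
id string only; genomic coordinates play no role.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "PoolFrequencyTable",
    "AlignedDataset",
    "DropReport",
    "PoolDataError",
    "read_genotype_matrix",
    "write_genotype_matrix",
    "read_pool_frequencies",
    "write_pool_frequencies",
    "align",
]

#: metadata columns of the pool table, in canonical order
POOL_META_COLUMNS = ("pool_id", "method", "construction_replicate", "extraction_replicate")

_VALID_DOSAGES = frozenset({"0", "1", "2", "NA"})


class PoolDataError(ValueError):
    """Raised for malformed or inconsistent input tables."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise PoolDataError(f"duplicate {what} {x!r}")
        seen.add(x)


@dataclass
class GenotypeMatrix:
    """Per-animal dosages of the modeled (A/ALT) allele across SNPs.

    ``dosages`` is an ``(n_animals, n_snps)`` float array with values in
    {0, 1, 2} or NaN for missing.  The modeled allele is taken exactly as
    oriented in the input file; the contribution model is symmetric under
    jointly flipping genotype and pool frequencies, so only consistency
    between the two inputs matters (enforced by shared SNP ids).
    """

    animal_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.animal_ids = [str(a) for a in self.animal_ids]
        self.snp_ids = [str(s) for s in self.snp_ids]
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.animal_ids), len(self.snp_ids)):
            raise PoolDataError(
                f"dosage array shape {self.dosages.shape} does not match "
                f"{len(self.animal_ids)} animals x {len(self.snp_ids)} SNPs"
            )
        _check_unique(self.animal_ids, "animal id")
        _check_unique(self.snp_ids, "snp id")
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise PoolDataError(
                f"invalid dosage {self.dosages[i, j]!r} for animal "
                f"{self.animal_ids[i]!r} at SNP {self.snp_ids[j]!r}; expected 0, 1, 2 or NA"
            )

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def g(self) -> np.ndarray:
        """Individual allele frequencies, dosage / 2 (the model covariate)."""
        return self.dosages / 2.0

    @property
    def mean_frequency(self) -> np.ndarray:
        """Per-SNP mean of dosage/2 across animals (equal-contribution expectation)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            return np.nanmean(self.g, axis=0)

    def subset_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {s: j for j, s in enumerate(self.snp_ids)}
        idx = [pos[s] for s in snp_ids]
        return GenotypeMatrix(list(self.animal_ids), [self.snp_ids[j] for j in idx],
                              self.dosages[:, idx].copy())

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.animal_ids == other.animal_ids
            and self.snp_ids == other.snp_ids
            and np.array_equal(self.dosages, other.dosages, equal_nan=True)
        )


@dataclass
class PoolFrequencyTable:
    """Measured allele frequencies of constructed pools, with pool metadata.

    ``frequencies`` is ``(n_pools, n_snps)`` in [0, 1] (NaN = missing).
    ``metadata`` is indexed by pool id and carries ``method``,
    ``construction_replicate`` and ``extraction_replicate``; the triple must
    be unique per pool.
    """

    pool_ids: list[str]
    snp_ids: list[str]
    frequencies: np.ndarray
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.pool_ids = [str(p) for p in self.pool_ids]
        self.snp_ids = [str(s) for s in self.snp_ids]
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.frequencies.shape != (len(self.pool_ids), len(self.snp_ids)):
            raise PoolDataError(
                f"frequency array shape {self.frequencies.shape} does not match "
                f"{len(self.pool_ids)} pools x {len(self.snp_ids)} SNPs"
            )
        _check_unique(self.pool_ids, "pool id")
        _check_unique(self.snp_ids, "snp id")
        bad = ~(np.isnan(self.frequencies)
                | ((self.frequencies >= 0.0) & (self.frequencies <= 1.0)))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise PoolDataError(
                f"pool frequency {self.frequencies[i, j]} outside [0, 1] for pool "
                f"{self.pool_ids[i]!r} at SNP {self.snp_ids[j]!r}"
            )
        meta = self.metadata
        missing = [c for c in POOL_META_COLUMNS[1:] if c not in meta.columns]
        if missing:
            raise PoolDataError(f"pool metadata lacks columns {missing}")
        if list(meta.index) != self.pool_ids:
            meta = meta.loc[self.pool_ids]
        self.metadata = meta
        triples = list(zip(meta["method"], meta["construction_replicate"],
                           meta["extraction_replicate"]))
        if len(set(triples)) != len(triples):
            dup = next(t for t in triples if triples.count(t) > 1)
            raise PoolDataError(
                f"(method, construction_replicate, extraction_replicate) not unique: {dup}"
            )

    @property
    def n_pools(self) -> int:
        return len(self.pool_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def methods(self) -> list[str]:
        return list(self.metadata["method"])

    def frequencies_for(self, pool_id: str) -> np.ndarray:
        try:
            i = self.pool_ids.index(pool_id)
        except ValueError:
            raise PoolDataError(f"unknown pool id {pool_id!r}") from None
        return self.frequencies[i]

    def subset_snps(self, snp_ids: Sequence[str]) -> "PoolFrequencyTable":
        pos = {s: j for j, s in enumerate(self.snp_ids)}
        idx = [pos[s] for s in snp_ids]
        return PoolFrequencyTable(list(self.pool_ids), [self.snp_ids[j] for j in idx],
                                  self.frequencies[:, idx].copy(), self.metadata.copy())

    def equals(self, other: "PoolFrequencyTable") -> bool:
        return (
            self.pool_ids == other.pool_ids
            and self.snp_ids == other.snp_ids
            and np.allclose(self.frequencies, other.frequencies, equal_nan=True,
                            rtol=0, atol=1e-12)
            and self.metadata.reset_index(drop=True).equals(
                other.metadata.reset_index(drop=True))
        )


# ---------------------------------------------------------------------------
# TSV / VCF readers and writers
# ---------------------------------------------------------------------------

def read_genotype_matrix(path: str | Path, format: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix from TSV (canonical) or VCF (convenience).

    TSV layout: header row of animal ids after a leading ``snp_id`` column;
    one row per SNP, cells in {0, 1, 2, NA}.  Malformed cells raise a parse
    error naming the offending data row and column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _read_genotype_tsv(path)
    if format == "vcf":
        return _read_genotype_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_genotype_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise PoolDataError(f"{path}: expected a snp_id column plus >=1 animal column")
    animal_ids = list(df.columns[1:])
    snp_ids = list(df.iloc[:, 0])
    cells = df.iloc[:, 1:].to_numpy(dtype=object)
    n_rows, n_cols = cells.shape
    dosages = np.empty((n_rows, n_cols), dtype=float)
    for i in range(n_rows):
        for j in range(n_cols):
            v = str(cells[i, j]).strip()
            if v not in _VALID_DOSAGES:
                raise PoolDataError(
                    f"{path}: invalid dosage {v!r} at row {i + 1}, column {j + 1} "
                    f"(SNP {snp_ids[i]!r}, animal {animal_ids[j]!r}); expected 0, 1, 2 or NA"
                )
            dosages[i, j] = np.nan if v == "NA" else float(v)
    return GenotypeMatrix(animal_ids, snp_ids, dosages.T)


def _read_genotype_vcf(path: Path) -> GenotypeMatrix:
    """Dosage = ALT allele count from GT; biallelic SNVs only, others skipped."""
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("VCF ingestion requires the optional cyvcf2 dependency") from exc
    vcf = VCF(str(path))
    animal_ids = list(vcf.samples)
    snp_ids: list[str] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        sid = var.ID if var.ID not in (None, ".", "") else f"{var.CHROM}:{var.POS}"
        gts = np.asarray(var.genotypes, dtype=object)
        dos = np.empty(len(animal_ids), dtype=float)
        for k, gt in enumerate(gts):
            alleles = [a for a in gt[:-1] if a != -1]
            dos[k] = np.nan if not alleles else float(sum(1 for a in alleles if a > 0))
        snp_ids.append(sid)
        rows.append(dos)
    if n_skipped:
        warnings.warn(f"{path}: skipped {n_skipped} non-biallelic VCF record(s)")
    if not rows:
        raise PoolDataError(f"{path}: no biallelic records found")
    return GenotypeMatrix(animal_ids, snp_ids, np.vstack(rows).T)


def write_genotype_matrix(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write the canonical genotype TSV (snp_id column, one column per animal)."""
    cols = {"snp_id": gm.snp_ids}
    for i, a in enumerate(gm.animal_ids):
        col = gm.dosages[i]
        cols[a] = ["NA" if np.isnan(v) else str(int(v)) for v in col]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_pool_frequencies(path: str | Path) -> PoolFrequencyTable:
    """Read the pool TSV: metadata columns then one frequency column per SNP."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in POOL_META_COLUMNS if c not in df.columns]
    if missing:
        raise PoolDataError(f"{path}: pool table lacks columns {missing}")
    snp_cols = [c for c in df.columns if c not in POOL_META_COLUMNS]
    if not snp_cols:
        raise PoolDataError(f"{path}: pool table has no SNP columns")
    meta = df[list(POOL_META_COLUMNS)].copy()
    meta["pool_id"] = meta["pool_id"].astype(str)
    meta = meta.set_index("pool_id")
    freqs = df[snp_cols].to_numpy(dtype=float)
    return PoolFrequencyTable(list(meta.index), snp_cols, freqs, meta)


def write_pool_frequencies(pft: PoolFrequencyTable, path: str | Path) -> None:
    meta = pft.metadata.reset_index()
    freq = pd.DataFrame(pft.frequencies, columns=pft.snp_ids)
    pd.concat([meta, freq], axis=1).to_csv(path, sep="\t", index=False,
                                           float_format="%.10g", na_rep="NA")


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

@dataclass
class DropReport:
    """Accounting of SNPs dropped (and monomorphic SNPs tallied) by ``align``."""

    input_intersection: int
    retained: int
    dropped_missing_genotype: list[str] = field(default_factory=list)
    dropped_missing_frequency: list[str] = field(default_factory=list)
    monomorphic: list[str] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return len(set(self.dropped_missing_genotype) | set(self.dropped_missing_frequency))


@dataclass
class AlignedDataset:
    """Genotypes and pool frequencies restricted to a common, complete SNP set."""

    genotypes: GenotypeMatrix
    pools: PoolFrequencyTable
    drop_report: DropReport
    _workspace: object = field(default=None, repr=False, compare=False)

    @property
    def snp_ids(self) -> list[str]:
        return self.genotypes.snp_ids

    @property
    def n_snps(self) -> int:
        return self.genotypes.n_snps

    @property
    def n_animals(self) -> int:
        return self.genotypes.n_animals


def align(genotypes: GenotypeMatrix, pools: PoolFrequencyTable,
          drop_missing: bool = True) -> AlignedDataset:
    """Restrict both tables to their common SNPs, in genotype-matrix order.

    With ``drop_missing`` (default), any SNP with a missing dosage in any
    animal or a missing frequency in any pool is dropped (listwise deletion;
    no imputation).  Monomorphic SNPs — identical dosage across all animals —
    are *retained* but tallied in the drop report: they carry no contrast
    among animal contributions, only residual information.
    """
    common = [s for s in genotypes.snp_ids if s in set(pools.snp_ids)]
    if not common:
        raise PoolDataError("genotype matrix and pool table share no SNP ids")
    report = DropReport(input_intersection=len(common), retained=0)
    gset = {s: j for j, s in enumerate(genotypes.snp_ids)}
    pset = {s: j for j, s in enumerate(pools.snp_ids)}
    keep: list[str] = []
    for s in common:
        if drop_missing and np.isnan(genotypes.dosages[:, gset[s]]).any():
            report.dropped_missing_genotype.append(s)
            continue
        if drop_missing and np.isnan(pools.frequencies[:, pset[s]]).any():
            report.dropped_missing_frequency.append(s)
            continue
        keep.append(s)
    if not keep:
        raise PoolDataError("no SNPs remain after missing-data filtering")
    gm = genotypes.subset_snps(keep)
    pf = pools.subset_snps(keep)
    mono = np.nanmax(gm.dosages, axis=0) == np.nanmin(gm.dosages, axis=0)
    report.monomorphic = [s for s, flag in zip(keep, mono) if flag]
    report.retained = len(keep)
    return AlignedDataset(gm, pf, report)
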