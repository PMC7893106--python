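"""Synthetic genotypes and DNA pools with known contribution structure.

The generator emulates a pool-construction experiment: the same n animals
enter every pool with target weight 1/n, but each construction method
(white-blood-cell count, spectrofluorometric DNA, spectrophotometric DNA,
raw blood volume) perturbs the realized weights with its own characteristic
spread.  Weights for pool j are

    w_ij  ∝  max(0, 1/n + s_i + a_i^(M) + b_ij),

where ``s_i`` is an optional animal effect shared across all methods,
``a_i^(M) ~ N(0, ρ_M σ_M²)`` is shared by every pool of method M (so pools
within a method are correlated with correlation ≈ ρ_M), and
``b_ij ~ N(0, (1−ρ_M) σ_M²)`` is pool-specific.  After optional
contamination multipliers the weights are renormalized to sum to one.  The
measured pool frequency is the weight-mixture of individual allele
frequencies plus homoskedastic array noise, clipped to [0, 1]:

    y_js = Σ_i w_ij g_is + e_js,   e_js ~ N(0, σ_a²).

Ground truth (weights, deviations, realized per-pool SD) is recorded so that
the downstream variance-component and correlation estimators can be checked
for recovery.  The generator models the *net* effect of quantification error
on weights; it does not simulate hematology counts, pipetting or extraction
chemistry as physical processes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, PoolFrequencyTable

__all__ = [
    "MethodSpec",
    "PoolDesign",
    "ContaminationSpec",
    "SimulationTruth",
    "simulate_genotypes",
    "simulate_pool_set",
    "study_scale_design",
    "canonical_contamination",
    "cbc_dilution_records",
    "write_truth",
]


@dataclass(frozen=True)
class MethodSpec:
    """One pooling method: its name, contribution-weight SD and within-method
    correlation of animal deviations across the method's pools."""

    name: str
    contribution_sd: float
    within_correlation: float = 0.95

    def __post_init__(self) -> None:
        if self.contribution_sd < 0:
            raise ValueError(f"{self.name}: contribution_sd must be >= 0")
        if not 0.0 <= self.within_correlation <= 1.0:
            raise ValueError(f"{self.name}: within_correlation must be in [0, 1]")


@dataclass
class PoolDesign:
    """Factorial design: methods x constructed pools x extraction replicates.

    The replicate hierarchy (constructed pool, then extraction) is collapsed
    into the single within-method correlation of :class:`MethodSpec`; the two
    tiers are an extension point, not separately parameterized here.
    ``shared_sd`` adds an animal effect common to *all* pools of all methods,
    which induces a nonzero between-method contribution correlation.
    """

    methods: tuple[MethodSpec, ...]
    constructed_pools: int = 3
    extractions: int = 3
    n_animals: int = 50
    n_snps: int = 5000
    freq_low: float = 0.05
    freq_high: float = 0.95
    array_noise_sd: float = 0.003
    shared_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.methods = tuple(self.methods)
        if not self.methods:
            raise ValueError("design needs at least one method")
        if self.constructed_pools < 1 or self.extractions < 1:
            raise ValueError("constructed_pools and extractions must be >= 1")
        if self.array_noise_sd < 0 or self.shared_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.n_snps < self.n_animals:
            warnings.warn(
                f"n_snps={self.n_snps} < n_animals={self.n_animals}: the "
                "contribution model will be under-identified"
            )

    @property
    def pools_per_method(self) -> int:
        return self.constructed_pools * self.extractions

    @property
    def n_pools(self) -> int:
        return len(self.methods) * self.pools_per_method

    def pool_ids(self) -> list[str]:
        return [
            f"{m.name} {c}-{e}"
            for m in self.methods
            for c in range(1, self.constructed_pools + 1)
            for e in range(1, self.extractions + 1)
        ]


@dataclass(frozen=True)
class ContaminationSpec:
    """Overrepresentation of specific animals in one pool (cross-contamination)."""

    pool_id: str
    animal_ids: tuple[str, ...]
    multiplier: float = 3.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "animal_ids", tuple(self.animal_ids))
        if self.multiplier <= 1.0:
            raise ValueError("contamination multiplier must be > 1")
        if not self.animal_ids:
            raise ValueError("contamination needs at least one animal")


@dataclass
class SimulationTruth:
    """Ground truth of a simulated pool set.

    ``weights`` is (n_pools, n_animals), each row summing to 1; deviations
    are ``w_ij − 1/n`` (the quantity whose SD the mixed model estimates).
    """

    pool_ids: list[str]
    animal_ids: list[str]
    weights: np.ndarray
    method_sd: dict[str, float]
    contamination: tuple[ContaminationSpec, ...] = ()
    truncated_fraction: dict[str, float] = field(default_factory=dict)

    @property
    def deviations(self) -> np.ndarray:
        return self.weights - 1.0 / self.weights.shape[1]

    @property
    def realized_sd(self) -> pd.Series:
        """Per-pool SD of the true contribution deviations (ddof=1)."""
        return pd.Series(self.deviations.std(axis=1, ddof=1), index=self.pool_ids)

    def weights_for(self, pool_id: str) -> np.ndarray:
        return self.weights[self.pool_ids.index(pool_id)]


def simulate_genotypes(
    n_animals: int,
    n_snps: int,
    freq_low: float = 0.05,
    freq_high: float = 0.95,
    rng: np.random.Generator | int | None = None,
) -> GenotypeMatrix:
    """Draw biallelic dosages: p_s ~ Uniform(freq_low, freq_high) per SNP,
    then two independent allele draws per animal (dosage ~ Binomial(2, p_s))."""
    if n_animals < 2 or n_snps < 1:
        raise ValueError("need n_animals >= 2 and n_snps >= 1")
    if not (0.0 <= freq_low <= freq_high <= 1.0):
        raise ValueError(f"invalid allele-frequency bounds [{freq_low}, {freq_high}]")
    rng = np.random.default_rng(rng)
    p = rng.uniform(freq_low, freq_high, size=n_snps)
    dosages = rng.binomial(2, p, size=(n_animals, n_snps)).astype(float)
    animal_ids = [f"A{i + 1:03d}" for i in range(n_animals)]
    snp_ids = [f"SNP{j + 1:05d}" for j in range(n_snps)]
    return GenotypeMatrix(animal_ids, snp_ids, dosages)


def simulate_pool_set(
    genotypes: GenotypeMatrix,
    design: PoolDesign,
    contamination: Sequence[ContaminationSpec] = (),
    rng: np.random.Generator | int | None = None,
) -> tuple[PoolFrequencyTable, SimulationTruth]:
    """Generate the pool frequency table and its ground truth for one design.

    Uses ``rng`` if given, else ``design.seed``.  Warns when more than 10% of
    a pool's raw weights truncate at zero (the realized SD is then distorted
    relative to the nominal method SD).
    """
    n = genotypes.n_animals
    if design.n_animals != n:
        raise ValueError(
            f"design.n_animals={design.n_animals} does not match genotype matrix ({n})"
        )
    if rng is None:
        if design.seed is None:
            raise ValueError("no rng given and design.seed is unset")
        rng = np.random.default_rng(design.seed)
    else:
        rng = np.random.default_rng(rng)

    contam_by_pool: dict[str, ContaminationSpec] = {}
    valid_ids = set(design.pool_ids())
    animal_pos = {a: i for i, a in enumerate(genotypes.animal_ids)}
    for spec in contamination:
        if spec.pool_id not in valid_ids:
            raise ValueError(f"contamination targets unknown pool {spec.pool_id!r}")
        for a in spec.animal_ids:
            if a not in animal_pos:
                raise ValueError(f"contamination names unknown animal {a!r}")
        contam_by_pool[spec.pool_id] = spec

    g = genotypes.g  # (n, m)
    m = genotypes.n_snps
    shared = rng.normal(0.0, design.shared_sd, size=n) if design.shared_sd > 0 else np.zeros(n)

    pool_ids: list[str] = []
    rows_meta: list[dict] = []
    weights = np.empty((design.n_pools, n))
    freqs = np.empty((design.n_pools, m))
    truncated: dict[str, float] = {}
    k = 0
    for mspec in design.methods:
        sd, rho = mspec.contribution_sd, mspec.within_correlation
        a_method = rng.normal(0.0, np.sqrt(rho) * sd, size=n)
        for c in range(1, design.constructed_pools + 1):
            for e in range(1, design.extractions + 1):
                pid = f"{mspec.name} {c}-{e}"
                b = rng.normal(0.0, np.sqrt(1.0 - rho) * sd, size=n)
                raw = 1.0 / n + shared + a_method + b
                n_trunc = int((raw < 0).sum())
                truncated[pid] = n_trunc / n
                if n_trunc > 0.10 * n:
                    warnings.warn(
                        f"pool {pid}: {n_trunc}/{n} raw weights truncated at zero; "
                        "realized contribution SD is distorted"
                    )
                w = np.clip(raw, 0.0, None)
                spec = contam_by_pool.get(pid)
                if spec is not None:
                    for a in spec.animal_ids:
                        w[animal_pos[a]] *= spec.multiplier
                w = w / w.sum()
                y = w @ g + rng.normal(0.0, design.array_noise_sd, size=m)
                pool_ids.append(pid)
                rows_meta.append({
                    "method": mspec.name,
                    "construction_replicate": c,
                    "extraction_replicate": e,
                })
                weights[k] = w
                freqs[k] = np.clip(y, 0.0, 1.0)
                k += 1

    meta = pd.DataFrame(rows_meta, index=pd.Index(pool_ids, name="pool_id"))
    table = PoolFrequencyTable(pool_ids, list(genotypes.snp_ids), freqs, meta)
    truth = SimulationTruth(
        pool_ids=pool_ids,
        animal_ids=list(genotypes.animal_ids),
        weights=weights,
        method_sd={m_.name: m_.contribution_sd for m_ in design.methods},
        contamination=tuple(contamination),
        truncated_fraction=truncated,
    )
    return table, truth


def study_scale_design(n_snps: int = 5000, seed: int | None = None,
                      n_animals: int = 50) -> PoolDesign:
    """Default study-scale design: 4 methods x 3 constructed pools x 3 extractions.

    The method SDs follow the qualitative ordering reported for this kind of
    experiment — volume pooling worst, fluorometric quantification
    intermediate, cell-count and spectrophotometric pooling best and similar —
    with within-method correlations near 1.  The magnitudes are generator
    defaults on the weight scale (target weight 1/50 = 0.02), not estimates
    from any real data set.
    """
    methods = (
        MethodSpec("CBC", 0.003, 0.95),
        MethodSpec("Fluor", 0.006, 0.95),
        MethodSpec("Spec", 0.003, 0.95),
        MethodSpec("Volume", 0.012, 0.95),
    )
    return PoolDesign(methods=methods, n_animals=n_animals, n_snps=n_snps, seed=seed)


def canonical_contamination(genotypes: GenotypeMatrix,
                             multiplier: float = 3.0) -> list[ContaminationSpec]:
    """The canonical cross-contamination scenario: 3 adjacent animals spill
    into the last CBC pool and 1 animal into the last Fluor pool."""
    ids = genotypes.animal_ids
    if len(ids) < 11:
        raise ValueError("scenario needs at least 11 animals")
    return [
        ContaminationSpec("CBC 3-3", tuple(ids[4:7]), multiplier),
        ContaminationSpec("Fluor 3-3", (ids[10],), multiplier),
    ]


def cbc_dilution_records(n_samples: int = 50, replicates: int = 3,
                         target_cells: float = 5.0e3,
                         volume_ul: float = 200.0) -> pd.DataFrame:
    """Bookkeeping of the cell-count dilution step: one dilution per sample per
    count replicate (default 50 x 3 = 150), each to the target white-blood-cell
    concentration in the stated volume."""
    rows = [
        {"sample": f"A{i + 1:03d}", "replicate": r + 1,
         "target_cells": target_cells, "volume_ul": volume_ul}
        for i in range(n_samples) for r in range(replicates)
    ]
    return pd.DataFrame(rows)


def write_truth(truth: SimulationTruth, path) -> None:
    """Long-format truth TSV: pool_id, animal_id, true_weight."""
    recs = [
        {"pool_id": p, "animal_id": a, "true_weight": truth.weights[i, j]}
        for i, p in enumerate(truth.pool_ids)
        for j, a in enumerate(truth.animal_ids)
    ]
    pd.DataFrame(recs).to_csv(path, sep="\t", index=False, float_format="%.10g")
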