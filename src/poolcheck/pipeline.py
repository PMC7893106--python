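"""End-to-end orchestration: simulate or ingest, fit, filter, compare.

The pipeline runs the full evaluation in order — load or simulate the
genotype matrix and pool table, align, fit the univariate contribution
model per pool, flag and exclude cross-contaminated pools, fit all
bivariate pool pairs among the retained pools, and run the PERMANOVA and
Kruskal-Wallis comparisons — writing TSV/JSON outputs and a run manifest
sufficient to reproduce the run.

Reproducibility: one root seed is split by ``numpy.random.SeedSequence``
into named substreams (simulation draws, permutation draws), so changing
the permutation count never perturbs the simulated data and vice versa.
REML fitting itself is deterministic.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import (correlation_matrix_from_pairs, correlation_to_distance,
                      kruskal_wallis, method_summary, permanova)
from .io import (AlignedDataset, align, read_genotype_matrix,
                 read_pool_frequencies, write_genotype_matrix,
                 write_pool_frequencies)
from .pairs import fit_all_pairs
from .reml import blup_contributions, filter_contaminated_pools, fit_univariate
from .simulate import (ContaminationSpec, MethodSpec, PoolDesign,
                       canonical_contamination, study_scale_design,
                       simulate_genotypes, simulate_pool_set, write_truth)

__all__ = ["RunConfig", "RunManifest", "ConfigError", "run_pipeline",
           "make_fixtures", "FIXTURE_SCALES"]


class ConfigError(ValueError):
    """Invalid run configuration (reported before any computation)."""


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Either ``genotypes_path``/``pools_path`` (ingest mode) or ``design``
    (simulation mode) must be set.  ``seed`` is mandatory: simulation and the
    permutation test both consume it.
    """

    output_dir: str | Path
    seed: int | None = None
    genotypes_path: str | Path | None = None
    pools_path: str | Path | None = None
    design: PoolDesign | None = None
    contamination: list[ContaminationSpec] = field(default_factory=list)
    flag_threshold: float = 3.0
    n_perm: int = 9999
    distance_transform: str = "one_minus_r"
    estimate_residual_corr: bool = True

    def validate(self) -> None:
        sim = self.design is not None
        ingest = self.genotypes_path is not None and self.pools_path is not None
        if sim == ingest:
            raise ConfigError(
                "exactly one of simulation (design) or ingestion "
                "(genotypes_path + pools_path) must be configured"
            )
        if self.seed is None:
            raise ConfigError("seed is mandatory (simulation and permutation "
                              "stages are stochastic)")
        if self.flag_threshold <= 0:
            raise ConfigError("flag_threshold must be > 0")
        if self.n_perm < 99:
            raise ConfigError("n_perm must be >= 99")
        if self.distance_transform not in ("one_minus_r", "sqrt_two_one_minus_r"):
            raise ConfigError(f"unknown distance_transform {self.distance_transform!r}")

    @property
    def simulate(self) -> bool:
        return self.design is not None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        design = None
        if "simulate" in raw:
            s = raw["simulate"]
            if s.get("design") == "study":
                design = study_scale_design(n_snps=int(s.get("n_snps", 5000)))
            else:
                methods = tuple(
                    MethodSpec(m["name"], float(m["contribution_sd"]),
                               float(m.get("within_correlation", 0.95)))
                    for m in s["methods"]
                )
                design = PoolDesign(
                    methods=methods,
                    constructed_pools=int(s.get("constructed_pools", 3)),
                    extractions=int(s.get("extractions", 3)),
                    n_animals=int(s.get("n_animals", 50)),
                    n_snps=int(s.get("n_snps", 5000)),
                    array_noise_sd=float(s.get("array_noise_sd", 0.003)),
                    shared_sd=float(s.get("shared_sd", 0.0)),
                )
        contamination = [
            ContaminationSpec(c["pool_id"], tuple(c["animal_ids"]),
                              float(c.get("multiplier", 3.0)))
            for c in raw.get("contamination", [])
        ]
        inputs = raw.get("inputs", {})
        return cls(
            output_dir=raw["output_dir"],
            seed=raw.get("seed"),
            genotypes_path=inputs.get("genotypes"),
            pools_path=inputs.get("pools"),
            design=design,
            contamination=contamination,
            flag_threshold=float(raw.get("flag_threshold", 3.0)),
            n_perm=int(raw.get("n_perm", 9999)),
            distance_transform=raw.get("distance_transform", "one_minus_r"),
            estimate_residual_corr=bool(raw.get("residual_correlation", True)),
        )


@dataclass
class StageRecord:
    name: str
    outputs: dict[str, str] = field(default_factory=dict)  # name -> sha256
    warnings: list[str] = field(default_factory=list)
    elapsed_s: float = 0.0


@dataclass
class RunManifest:
    config: dict[str, Any]
    version: str
    stages: list[StageRecord] = field(default_factory=list)
    exclusions: dict[str, str] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "config": self.config,
            "version": self.version,
            "stages": [asdict(s) for s in self.stages],
            "exclusions": self.exclusions,
            "counts": self.counts,
        }
        return json.dumps(payload, indent=2, default=str)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Stage:
    """Context that records warnings, timing and output digests for one stage."""

    def __init__(self, manifest: RunManifest, name: str):
        self.record = StageRecord(name)
        manifest.stages.append(self.record)

    def __enter__(self) -> "_Stage":
        self._t0 = time.perf_counter()
        self._catcher = warnings.catch_warnings(record=True)
        self._captured = self._catcher.__enter__()
        warnings.simplefilter("always")
        return self

    def __exit__(self, exc_type, exc, tb) -> None:
        self.record.warnings.extend(str(w.message) for w in self._captured)
        self._catcher.__exit__(exc_type, exc, tb)
        self.record.elapsed_s = round(time.perf_counter() - self._t0, 4)
        if exc is not None:
            raise RuntimeError(
                f"pipeline stage {self.record.name!r} failed: {exc}; see the "
                "partial manifest for completed stages"
            ) from exc

    def output(self, path: Path) -> None:
        self.record.outputs[path.name] = _digest(path)


def _config_echo(config: RunConfig) -> dict[str, Any]:
    echo = asdict(config)
    echo["output_dir"] = str(echo["output_dir"])
    return echo


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages; returns the manifest (also written to the output dir).

    Identical config + seed gives byte-identical result tables.  A stage
    failure halts the run with the partial manifest written.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=_config_echo(config), version=__version__)
    root = np.random.SeedSequence(config.seed)
    sim_ss, perm_ss = root.spawn(2)

    try:
        # ---------------- stage 1: data -----------------------------------
        with _Stage(manifest, "data") as st:
            if config.simulate:
                design = config.design
                rng = np.random.default_rng(sim_ss)
                genotypes = simulate_genotypes(
                    design.n_animals, design.n_snps,
                    design.freq_low, design.freq_high, rng)
                pools, truth = simulate_pool_set(
                    genotypes, design, config.contamination, rng)
                write_genotype_matrix(genotypes, out / "genotypes.tsv")
                write_pool_frequencies(pools, out / "pools.tsv")
                write_truth(truth, out / "truth.tsv")
                for name in ("genotypes.tsv", "pools.tsv", "truth.tsv"):
                    st.output(out / name)
            else:
                genotypes = read_genotype_matrix(config.genotypes_path)
                pools = read_pool_frequencies(config.pools_path)
            manifest.counts["pools_generated"] = pools.n_pools

        # ---------------- stage 2: align -----------------------------------
        with _Stage(manifest, "align") as st:
            data = align(genotypes, pools)
            manifest.counts["snps_retained"] = data.n_snps
            manifest.counts["snps_dropped"] = data.drop_report.n_dropped
            manifest.counts["snps_monomorphic"] = len(data.drop_report.monomorphic)

        # ---------------- stage 3: univariate fits + flags ------------------
        with _Stage(manifest, "univariate") as st:
            fits = {pid: fit_univariate(data, pid) for pid in pools.pool_ids}
            reports = {pid: blup_contributions(f, data, config.flag_threshold)
                       for pid, f in fits.items()}
            fit_rows = [
                {"pool_id": pid, "method": pools.metadata.loc[pid, "method"],
                 "sigma_u": f.sigma_u, "sigma_e": f.sigma_e,
                 "loglik": f.loglik, "boundary": f.boundary}
                for pid, f in fits.items()
            ]
            pd.DataFrame(fit_rows).to_csv(out / "univariate_fits.tsv", sep="\t",
                                          index=False, float_format="%.10g")
            blup_rows = [
                {"pool_id": pid, "animal_id": a, "blup": b, "score": s,
                 "flagged": bool(fl)}
                for pid, rep in reports.items()
                for a, b, s, fl in zip(rep.animal_ids, rep.blups, rep.scores, rep.flags)
            ]
            pd.DataFrame(blup_rows).to_csv(out / "blup_reports.tsv", sep="\t",
                                           index=False, float_format="%.10g")
            st.output(out / "univariate_fits.tsv")
            st.output(out / "blup_reports.tsv")
            for f in fits.values():
                st.record.warnings.extend(f"{f.pool_id}: {w}" for w in f.warnings)

        # ---------------- stage 4: contamination filter ---------------------
        with _Stage(manifest, "filter") as st:
            filt = filter_contaminated_pools(reports)
            manifest.exclusions = filt.excluded
            manifest.counts["pools_retained"] = len(filt.retained)
            for m in sorted(set(pools.methods)):
                manifest.counts[f"retained_{m}"] = sum(
                    1 for pid in filt.retained
                    if pools.metadata.loc[pid, "method"] == m)
            (out / "retained_pools.txt").write_text(
                "\n".join(filt.retained) + "\n")
            (out / "exclusions.json").write_text(
                json.dumps(filt.excluded, indent=2) + "\n")
            st.output(out / "retained_pools.txt")
            st.output(out / "exclusions.json")

        # ---------------- stage 5: bivariate pair grid ----------------------
        with _Stage(manifest, "pairs") as st:
            grid = fit_all_pairs(
                data, filt.retained,
                {pid: fits[pid] for pid in filt.retained},
                estimate_residual_corr=config.estimate_residual_corr)
            manifest.counts["pair_fits"] = len(grid.fits)
            manifest.counts["pair_failures"] = len(grid.failures)
            grid.to_frame().to_csv(out / "pairs.tsv", sep="\t", index=False,
                                   float_format="%.10g")
            st.output(out / "pairs.tsv")

        # ---------------- stage 6: comparison -------------------------------
        with _Stage(manifest, "compare") as st:
            methods_map = {pid: pools.metadata.loc[pid, "method"]
                           for pid in filt.retained}
            corr = correlation_matrix_from_pairs(grid, methods_map)
            dist = correlation_to_distance(corr, config.distance_transform)
            corr.to_frame().to_csv(out / "correlation_matrix.tsv", sep="\t",
                                   float_format="%.10g")
            dist.to_frame().to_csv(out / "distance_matrix.tsv", sep="\t",
                                   float_format="%.10g")
            perm_rng = np.random.default_rng(perm_ss)
            perm = permanova(dist, n_perm=config.n_perm, seed=perm_rng)
            retained_fits = {pid: fits[pid] for pid in filt.retained}
            kw = kruskal_wallis(
                [fits[pid].sigma_u for pid in filt.retained],
                [methods_map[pid] for pid in filt.retained])
            summary = method_summary(grid, retained_fits, methods_map)
            (out / "permanova.json").write_text(json.dumps({
                "pseudo_F": perm.f, "R2": perm.r2, "p": perm.p,
                "n_perm": perm.n_perm, "method": perm.method,
                "group_sizes": perm.group_sizes, "seed": config.seed,
            }, indent=2) + "\n")
            (out / "kruskal_wallis.json").write_text(json.dumps({
                "H": kw.h, "df": kw.df, "p": kw.p, "warning": kw.warning,
            }, indent=2) + "\n")
            summary.correlation_summary.to_csv(out / "correlation_summary.tsv",
                                               sep="\t", index=False,
                                               float_format="%.10g")
            summary.sd_summary.to_csv(out / "sd_summary.tsv", sep="\t",
                                      index=False, float_format="%.10g")
            summary.sd_by_pool.to_csv(out / "sd_by_pool.tsv", sep="\t",
                                      index=False, float_format="%.10g")
            for name in ("correlation_matrix.tsv", "distance_matrix.tsv",
                         "permanova.json", "kruskal_wallis.json",
                         "correlation_summary.tsv", "sd_summary.tsv",
                         "sd_by_pool.tsv"):
                st.output(out / name)
    finally:
        (out / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest


#: named fixture scales: (n_animals, n_snps, design builder)
FIXTURE_SCALES = ("tiny", "test", "study")


def _fixture_design(scale: str) -> tuple[PoolDesign, int]:
    if scale == "tiny":
        methods = (MethodSpec("CBC", 0.08, 0.95), MethodSpec("Volume", 0.15, 0.95))
        return PoolDesign(methods=methods, constructed_pools=1, extractions=1,
                          n_animals=3, n_snps=8, array_noise_sd=0.02), 20240101
    if scale == "test":
        methods = (MethodSpec("CBC", 0.005, 0.95), MethodSpec("Fluor", 0.01, 0.95),
                   MethodSpec("Spec", 0.005, 0.95), MethodSpec("Volume", 0.02, 0.95))
        return PoolDesign(methods=methods, constructed_pools=1, extractions=2,
                          n_animals=20, n_snps=1000), 20240102
    if scale == "study":
        return study_scale_design(n_snps=5000), 20240103
    raise ValueError(f"unknown fixture scale {scale!r}; choose from {FIXTURE_SCALES}")


def make_fixtures(scale: str, out_dir: str | Path, seed: int | None = None) -> Path:
    """Write seeded genotype/pool/truth fixture files at a named scale."""
    design, default_seed = _fixture_design(scale)
    rng = np.random.default_rng(seed if seed is not None else default_seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tiny scale is deliberately undersized
        genotypes = simulate_genotypes(design.n_animals, design.n_snps,
                                       design.freq_low, design.freq_high, rng)
        pools, truth = simulate_pool_set(genotypes, design, (), rng)
    write_genotype_matrix(genotypes, out / "genotypes.tsv")
    write_pool_frequencies(pools, out / "pools.tsv")
    write_truth(truth, out / "truth.tsv")
    return out
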