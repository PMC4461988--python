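"""Pipeline orchestration: configuration and the end-to-end analysis run.

Stages run in the order the analysis logic requires: locus filtering
(HWE, then LD), F-statistics and AMOVA on the retained loci, sibmating
rate from F_IS, and closed-form DMP predictions over a sex-allele grid.
Every stochastic stage draws its seed from the run seed and logs it, so a
rerun with the same configuration is deterministic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as csdio
from .filtering import filter_loci
from .model import CSDModelSpec, dmp_band, sibmating_from_fis
from .popgen import amova, global_fstats, pairwise_fst, per_field_fis

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

_KNOWN_KEYS = {
    "genotypes",
    "genotype_format",
    "hierarchy",
    "out_dir",
    "seed",
    "n_permutations",
    "n_bootstrap",
    "hwe_chain_steps",
    "hwe_dememorization",
    "ld_permutations",
    "em_starts",
    "hwe_alpha",
    "ld_alpha",
    "skip_ld",
    "model",
    "k_grid",
    "dmp_obs",
    "log_level",
}


@dataclass
class RunConfig:
    """Configuration for :func:`run_pipeline`.

    The statistical-test sizes default to values that complete a
    study-sized dataset in minutes; they can be raised to match heavier
    reference settings (e.g. 10^6 HWE chain steps, 16,000 LD
    permutations) when runtime is no concern.
    """

    genotypes: str
    out_dir: str
    seed: int
    genotype_format: str = "auto"  # 'genepop' | 'csv' | 'auto'
    hierarchy: str | None = None
    n_permutations: int = 200
    n_bootstrap: int = 2000
    hwe_chain_steps: int = 20_000
    hwe_dememorization: int = 2_000
    ld_permutations: int = 100
    em_starts: int = 5
    hwe_alpha: float = 0.05
    ld_alpha: float = 0.05
    skip_ld: bool = False
    model: int = 2
    k_grid: tuple[int, int] = (3, 100)
    dmp_obs: float | None = None
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in data:
            raise ValueError("seed is mandatory")
        if "k_grid" in data:
            data["k_grid"] = tuple(data["k_grid"])
        return cls(**data)


def _load_matrix(config: RunConfig):
    fmt = config.genotype_format
    path = config.genotypes
    if fmt == "auto":
        fmt = "genepop" if str(path).endswith((".gen", ".genepop", ".txt")) else "csv"
    region_of = csdio.read_hierarchy_map(config.hierarchy) if config.hierarchy else None
    if fmt == "genepop":
        return csdio.read_genepop(path, region_of=region_of)
    matrix = csdio.read_genotype_csv(path)
    if region_of:
        matrix.region_of.update(region_of)
    return matrix


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write report tables.

    Returns a dict of in-memory results (the same objects written to
    ``config.out_dir``).  Raises with the failing stage named.
    """
    logging.basicConfig(level=config.log_level)
    rng = np.random.default_rng(config.seed)
    results: dict = {}
    stage = "load"
    try:
        matrix = _load_matrix(config)
        logger.info(
            "loaded %d individuals x %d loci (missing %.1f%%)",
            matrix.n_individuals, matrix.n_loci, 100 * matrix.missing_rate(),
        )

        stage = "filter"
        seed = int(rng.integers(2**31))
        logger.info("locus filtering (seed %d)", seed)
        filt = filter_loci(
            matrix,
            hwe_alpha=config.hwe_alpha,
            ld_alpha=config.ld_alpha,
            seed=seed,
            chain_steps=config.hwe_chain_steps,
            dememorization=config.hwe_dememorization,
            n_permutations=0 if config.skip_ld else config.ld_permutations,
            em_starts=config.em_starts,
        )
        results["locus_reports"] = filt.reports
        retained = matrix.subset_loci(filt.retained)
        logger.info("retained %d of %d loci", len(filt.retained), matrix.n_loci)

        stage = "fstats"
        seed = int(rng.integers(2**31))
        logger.info("F-statistics (seed %d)", seed)
        fstats = global_fstats(retained, n_bootstrap=config.n_bootstrap, seed=seed)
        results["fstats"] = fstats
        results["per_field"] = per_field_fis(retained)

        stage = "pairwise"
        seed = int(rng.integers(2**31))
        logger.info("pairwise F_ST (seed %d)", seed)
        fst, pval = pairwise_fst(retained, n_permutations=config.n_permutations, seed=seed)
        results["pairwise_fst"] = fst
        results["pairwise_p"] = pval

        stage = "amova"
        results["amova"] = amova(retained)

        stage = "load-model"
        fis = fstats.f_is
        alpha = sibmating_from_fis(fis)
        ci = fstats.ci.get("f_is", (fis, fis))
        alpha_lo = sibmating_from_fis(max(ci[0], 0.0))
        alpha_hi = sibmating_from_fis(ci[1])
        rows = []
        for k in range(config.k_grid[0], config.k_grid[1] + 1):
            spec = CSDModelSpec(
                n_sex_loci=config.model, k=k, l=k, alpha=alpha
            ) if config.model == 2 else CSDModelSpec(n_sex_loci=1, k=k, alpha=alpha)
            band = dmp_band(alpha_lo, alpha_hi, spec)
            row = {
                "k": k,
                "dmp": band.dmp,
                "dmp_low": band.band_low,
                "dmp_high": band.band_high,
            }
            if config.dmp_obs is not None:
                row["consistent"] = band.contains(config.dmp_obs)
            rows.append(row)
        results["dmp_predictions"] = pd.DataFrame(rows)
        results["sibmating"] = pd.DataFrame(
            [{"f_is": fis, "alpha": alpha, "alpha_low": alpha_lo, "alpha_high": alpha_hi}]
        )

        stage = "write"
        csdio.write_reports(results, config.out_dir)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return results
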