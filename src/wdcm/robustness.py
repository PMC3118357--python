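"""Missing-data robustness: mask cells at random, re-run the pipeline,
and score stability with the Cluster Overlap Ratio.

The experiment clusters the complete matrix once, then for each missing
fraction repeatedly masks that fraction of observed cells completely at
random, re-screens and re-clusters, and compares the incomplete-data
clustering against the complete-data one with COR. Masking operates on
individual cells (not whole genes or arrays): tolerating scattered missing
values without imputation is precisely what the method claims.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix, Partition
from .evaluation import cluster_overlap_ratio
from .hub_clustering import HubConfig, hub_cluster
from .weibull import FitConfig, ScreenResult, screen_genes

__all__ = ["RobustnessConfig", "RobustnessResult", "mask_matrix", "robustness_experiment", "run_pipeline"]

DEFAULT_FRACTIONS = (0.05, 0.10, 0.15, 0.20, 0.25)


@dataclass(frozen=True)
class RobustnessConfig:
    """Missing fractions, repetitions, base seed and pipeline settings."""

    missing_fractions: tuple[float, ...] = DEFAULT_FRACTIONS
    n_runs: int = 100
    seed: int = 0
    fit_cfg: FitConfig = field(default_factory=FitConfig)
    hub_cfg: HubConfig = field(default_factory=HubConfig)

    def __post_init__(self) -> None:
        if not self.missing_fractions:
            raise ValueError("need at least one missing fraction")
        for f in self.missing_fractions:
            if not 0 < f < 1:
                raise ValueError(f"missing fraction {f} must be in (0, 1)")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


@dataclass
class RobustnessResult:
    """Per-run COR values and per-fraction means."""

    runs: pd.DataFrame  # columns: fraction, run, n_genes, k, cor
    mean_cor: dict[float, float]
    complete_partition: Partition
    complete_screen: ScreenResult


def _run_seed(base_seed: int, fraction: float, run: int) -> int:
    """Deterministic per-run seed; independent streams per (fraction, run)."""
    ss = np.random.SeedSequence([int(base_seed), int(round(fraction * 1e6)), int(run)])
    return int(ss.generate_state(1)[0] % (2**31))


def mask_matrix(mat: ExpressionMatrix, fraction: float, seed: int) -> ExpressionMatrix:
    """Mask exactly round(fraction × #observed) observed cells, MCAR.

    Cells are chosen uniformly without replacement among currently observed
    cells, reproducibly from ``seed``. Pre-existing missing cells are left
    untouched.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    out = mat.copy()
    observed = np.flatnonzero(~np.isnan(out.values.ravel()))
    n_mask = int(round(fraction * observed.size))
    chosen = rng.choice(observed, size=n_mask, replace=False)
    out.values.ravel()[chosen] = np.nan
    return out


def run_pipeline(
    mat: ExpressionMatrix,
    fit_cfg: FitConfig | None = None,
    hub_cfg: HubConfig | None = None,
) -> tuple[ScreenResult, Partition]:
    """Screen a matrix and cluster the accepted parameter pairs."""
    screen = screen_genes(mat, fit_cfg or FitConfig())
    if screen.n_accepted == 0:
        raise ValueError("pipeline: no gene passed the goodness-of-fit screen")
    partition = hub_cluster(screen.params, hub_cfg or HubConfig())
    return screen, partition


def robustness_experiment(
    mat: ExpressionMatrix, cfg: RobustnessConfig | None = None
) -> RobustnessResult:
    """Run the masking experiment and tabulate COR per fraction and run.

    The complete matrix is screened and clustered once; each masked run is
    screened and clustered independently and scored by COR against the
    complete-data partition, over the genes accepted in that masked run
    (genes the complete run did not cluster are excluded from COR). Runs in
    which no gene survives screening are recorded with COR = NaN and
    excluded from the per-fraction mean, with a warning.
    """
    cfg = cfg or RobustnessConfig()
    complete_screen, complete_part = run_pipeline(mat, cfg.fit_cfg, cfg.hub_cfg)

    rows: list[dict] = []
    for frac in cfg.missing_fractions:
        for run in range(cfg.n_runs):
            seed = _run_seed(cfg.seed, frac, run)
            masked = mask_matrix(mat, frac, seed)
            try:
                screen, part = run_pipeline(masked, cfg.fit_cfg, cfg.hub_cfg)
            except ValueError:
                warnings.warn(
                    f"fraction {frac}, run {run}: no gene accepted; COR undefined",
                    UserWarning,
                )
                rows.append(
                    dict(fraction=frac, run=run, n_genes=0, k=0, cor=np.nan)
                )
                continue
            incomplete = part.restrict(complete_part.assignments)
            if not incomplete.assignments:
                warnings.warn(
                    f"fraction {frac}, run {run}: no overlap with the complete "
                    "clustering; COR undefined",
                    UserWarning,
                )
                cor = np.nan
            else:
                cor = cluster_overlap_ratio(complete_part, incomplete)
            rows.append(
                dict(
                    fraction=frac,
                    run=run,
                    n_genes=len(part.assignments),
                    k=part.k,
                    cor=cor,
                )
            )
    runs = pd.DataFrame(rows, columns=["fraction", "run", "n_genes", "k", "cor"])
    mean_cor = {
        float(f): float(sub["cor"].mean())
        for f, sub in runs.groupby("fraction", sort=True)
    }
    return RobustnessResult(
        runs=runs,
        mean_cor=mean_cor,
        complete_partition=complete_part,
        complete_screen=complete_screen,
    )
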