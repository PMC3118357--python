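"""Synthetic expression matrices with known ground truth.

Generates the generative setting the method assumes: each gene's values are
i.i.d. draws from its own Weibull distribution, and genes fall into clusters
because their (scale, shape) parameters concentrate around shared cluster
centers. Optionally a fraction of genes are contaminants drawn from a
non-Weibull family (moment-matched so they are not trivially rejected on
range alone), and a fraction of cells is masked completely at random.

The default configuration — four well-separated parameter blobs of 75 genes
each observed over 50 samples — is the reference condition used throughout
the test-bench and examples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .data_io import ExpressionMatrix, Partition
from .weibull import ParameterTable

__all__ = ["SimConfig", "SimulatedData", "simulate_matrix", "weibull_mean_var", "PRESETS"]

_DEFAULT_CENTERS = ((1.0, 1.0), (1.0, 6.0), (6.0, 1.0), (6.0, 6.0))


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration.

    k
        Number of planted clusters; ``centers`` must list k (scale, shape)
        pairs with positive coordinates.
    genes_per_cluster, n_samples
        Genes per planted cluster and observations per gene.
    jitter_sd
        Within-cluster standard deviation of the truncated-Gaussian jitter
        added to the cluster center, in the same units as (a, b).
    contaminant_fraction
        Fraction of all genes replaced by draws from ``contaminant_family``
        (``gaussian_mixture``: two well-separated modes, or ``uniform``),
        moment-matched to a randomly chosen center.
    missing_fraction
        Fraction of cells masked completely at random, applied last.
    """

    k: int = 4
    genes_per_cluster: int = 75
    n_samples: int = 50
    centers: tuple[tuple[float, float], ...] = _DEFAULT_CENTERS
    jitter_sd: float = 0.15
    contaminant_fraction: float = 0.0
    contaminant_family: str = "gaussian_mixture"
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1 or self.genes_per_cluster < 1 or self.n_samples < 1:
            raise ValueError("k, genes_per_cluster and n_samples must be >= 1")
        if len(self.centers) != self.k:
            raise ValueError(f"need {self.k} centers, got {len(self.centers)}")
        for a, b in self.centers:
            if a <= 0 or b <= 0:
                raise ValueError("center coordinates must be positive")
        for name, frac in (
            ("contaminant_fraction", self.contaminant_fraction),
            ("missing_fraction", self.missing_fraction),
        ):
            if not 0 <= frac < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.contaminant_family not in ("gaussian_mixture", "uniform"):
            raise ValueError(f"unknown contaminant_family {self.contaminant_family!r}")


@dataclass
class SimulatedData:
    matrix: ExpressionMatrix
    truth: Partition  # planted labels for the non-contaminant genes
    true_params: ParameterTable  # planted (a, b) of the non-contaminant genes
    contaminant_ids: set[str]


def weibull_mean_var(a: float, b: float) -> tuple[float, float]:
    """Mean a·Γ(1+1/b) and variance a²[Γ(1+2/b) − Γ(1+1/b)²] of Weibull(a, b)."""
    g1 = special.gamma(1.0 + 1.0 / b)
    g2 = special.gamma(1.0 + 2.0 / b)
    return a * g1, a * a * (g2 - g1 * g1)


def _jitter_center(
    center: tuple[float, float], sd: float, rng: np.random.Generator
) -> tuple[float, float]:
    """Center + truncated Gaussian jitter, both coordinates kept positive."""
    if sd == 0.0:
        return center
    for _ in range(100):
        a = center[0] + rng.normal(0.0, sd)
        b = center[1] + rng.normal(0.0, sd)
        if a > 0 and b > 0:
            return a, b
    raise RuntimeError(
        f"could not draw positive jittered parameters around {center} "
        f"with sd {sd} in 100 tries"
    )


def _positive_draws(
    draw, n: int, rng: np.random.Generator, max_rounds: int = 100
) -> np.ndarray:
    """Resample a vectorized sampler until all values are positive (truncation)."""
    x = draw(n)
    for _ in range(max_rounds):
        bad = x <= 0
        if not bad.any():
            return x
        x[bad] = draw(int(bad.sum()))
    x[x <= 0] = 1e-6
    return x


def _contaminant_values(
    center: tuple[float, float], n: int, family: str, rng: np.random.Generator
) -> np.ndarray:
    """Non-Weibull values moment-matched to Weibull(center).

    gaussian_mixture: equal-weight modes at μ ± 0.95σ with component sd
    0.312σ, so mean and variance match while the shape is strongly bimodal.
    uniform: flat on μ ± √3 σ. Negatives are resampled (truncation).
    """
    mu, var = weibull_mean_var(*center)
    sigma = np.sqrt(var)
    if family == "gaussian_mixture":
        delta = 0.95 * sigma
        comp_sd = np.sqrt(max(var - delta * delta, 1e-12))

        def draw(m: int) -> np.ndarray:
            signs = rng.choice((-1.0, 1.0), size=m)
            return mu + signs * delta + rng.normal(0.0, comp_sd, size=m)

    else:  # uniform
        half = np.sqrt(3.0) * sigma

        def draw(m: int) -> np.ndarray:
            return rng.uniform(mu - half, mu + half, size=m)

    return _positive_draws(draw, n, rng)


def simulate_matrix(cfg: SimConfig) -> SimulatedData:
    """Generate a matrix with planted Weibull clusters.

    Gene i of cluster c receives parameters center_c plus truncated-Gaussian
    jitter and n_samples i.i.d. Weibull draws; a ``contaminant_fraction`` of
    genes (chosen uniformly) are instead drawn from the configured
    non-Weibull family; finally a ``missing_fraction`` of cells is masked
    MCAR. Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    m = cfg.k * cfg.genes_per_cluster
    n = cfg.n_samples
    gene_ids = [f"g{i:04d}" for i in range(m)]
    planted = np.repeat(np.arange(cfg.k), cfg.genes_per_cluster)

    n_cont = int(round(cfg.contaminant_fraction * m))
    cont_idx = set(rng.choice(m, size=n_cont, replace=False).tolist()) if n_cont else set()

    values = np.empty((m, n), dtype=float)
    truth_genes: list[str] = []
    truth_labels: list[int] = []
    param_genes: list[str] = []
    param_points: list[tuple[float, float]] = []
    contaminant_ids: set[str] = set()

    for i in range(m):
        if i in cont_idx:
            center = cfg.centers[rng.integers(cfg.k)]
            values[i] = _contaminant_values(center, n, cfg.contaminant_family, rng)
            contaminant_ids.add(gene_ids[i])
            continue
        a, b = _jitter_center(cfg.centers[planted[i]], cfg.jitter_sd, rng)
        values[i] = a * rng.weibull(b, size=n)
        truth_genes.append(gene_ids[i])
        truth_labels.append(int(planted[i]))
        param_genes.append(gene_ids[i])
        param_points.append((a, b))

    if cfg.missing_fraction > 0:
        n_mask = int(round(cfg.missing_fraction * m * n))
        flat = rng.choice(m * n, size=n_mask, replace=False)
        values.ravel()[flat] = np.nan

    matrix = ExpressionMatrix(gene_ids, [f"s{j:03d}" for j in range(n)], values)
    truth = Partition.from_labels(truth_genes, truth_labels)
    true_params = ParameterTable(
        param_genes, np.array(param_points, dtype=float).reshape(-1, 2)
    )
    return SimulatedData(matrix, truth, true_params, contaminant_ids)


#: Named generator configurations for the CLI and examples.
PRESETS: dict[str, SimConfig] = {
    "four-blobs": SimConfig(),
    "two-blobs-contaminated": SimConfig(
        k=2,
        genes_per_cluster=125,
        n_samples=100,
        centers=((2.0, 1.5), (5.0, 4.0)),
        contaminant_fraction=0.2,
    ),
}
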