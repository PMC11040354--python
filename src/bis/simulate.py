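"""Synthetic scRNA-seq generation with known ground truth.

Two corruption protocols are provided:

* :func:`simulate_groups` — a Splat-style hierarchical gamma-Poisson group
  simulation: gamma gene means with lognormal expression outliers, per-group
  lognormal differential-expression factors, lognormal library sizes,
  BCV-driven overdispersion (per-gene inverse-chi-square inflation), Poisson
  counts, and finally a logistic expression-dependent dropout that zeroes
  entries with probability decreasing in the entry's underlying mean.
* :func:`downsample_counts` — binomial thinning of a deep reference matrix at
  a gamma-distributed per-cell capture efficiency, the standard benchmark
  construction when a high-depth "truth" is available.

:func:`synth_bulk` builds matched pseudo-bulk samples (noisy per-gene means
of the true counts) so the bulk-consistency term of the imputation model can
be exercised end to end on synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .data_io import ExpressionMatrix

__all__ = [
    "SimParams",
    "SimulatedDataset",
    "simulate_groups",
    "logistic_dropout_prob",
    "downsample_counts",
    "synth_bulk",
]

#: Stage names, in order, used to derive one independent RNG stream per
#: generative stage from the single user-facing seed.
_STAGES = (
    "gene_means", "outliers", "de_factors", "groups",
    "lib_sizes", "bcv", "cell_means", "poisson", "dropout",
)


@dataclass(frozen=True)
class SimParams:
    """Parameters of the group simulation.

    Defaults follow the published Splat defaults; ``n_cells``, ``n_genes``
    and ``group_prob`` default to the benchmark configuration (2000 cells,
    500 genes, five groups at probabilities 0.2/0.15/0.25/0.1/0.3).
    ``dropout_mid`` shifts the logistic dropout midpoint on the ln-mean
    scale: larger values zero more entries.
    """

    n_cells: int = 2000
    n_genes: int = 500
    group_prob: tuple[float, ...] = (0.2, 0.15, 0.25, 0.1, 0.3)
    mean_shape: float = 0.6
    mean_rate: float = 0.3
    lib_loc: float = 11.0
    lib_scale: float = 0.2
    outlier_prob: float = 0.05
    outlier_loc: float = 4.0
    outlier_scale: float = 0.5
    de_prob: float = 0.1
    de_fac_loc: float = 0.1
    de_fac_scale: float = 0.4
    bcv_common: float = 0.1
    bcv_df: float = 60.0
    dropout_mid: float = 1.5
    dropout_shape: float = -1.0
    seed: int = 0

    def __post_init__(self) -> None:
        gp = np.asarray(self.group_prob, dtype=float)
        if gp.ndim != 1 or gp.size == 0 or np.any(gp < 0) or abs(gp.sum() - 1.0) > 1e-9:
            raise ValueError("group_prob must be a probability vector summing to 1")
        for name in ("mean_shape", "mean_rate", "lib_scale", "outlier_scale",
                     "de_fac_scale", "bcv_common", "bcv_df"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_cells < 1 or self.n_genes < 1:
            raise ValueError("n_cells and n_genes must be at least 1")
        for name in ("outlier_prob", "de_prob"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["group_prob"] = list(self.group_prob)
        return d


@dataclass
class SimulatedDataset:
    """Paired truth/corruption with the mask of dropout events."""

    true_counts: ExpressionMatrix
    observed_counts: ExpressionMatrix
    group_labels: np.ndarray
    dropout_mask: np.ndarray
    params: SimParams

    def zero_fraction(self) -> float:
        """Fraction of zero entries in the observed matrix."""
        return float(np.mean(self.observed_counts.values == 0))


def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    streams = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {name: np.random.default_rng(s) for name, s in zip(_STAGES, streams)}


def logistic_dropout_prob(log_mean: float | np.ndarray, mid: float, shape: float) -> float | np.ndarray:
    """Dropout probability 1 / (1 + exp(-shape * (log_mean - mid))).

    With the conventional ``shape = -1`` this decreases from 1 toward 0 as
    ``log_mean`` grows past ``mid``: weakly expressed entries are the ones
    most likely to be zeroed.
    """
    from scipy.special import expit

    out = expit(shape * (np.asarray(log_mean, dtype=float) - mid))
    return float(out) if np.isscalar(log_mean) or np.ndim(log_mean) == 0 else out


def _lognormal_factors(rng: np.random.Generator, n: int, sel_prob: float,
                       down_prob: float, loc: float, scale: float) -> np.ndarray:
    """Multiplicative factors: 1 for unselected entries, lognormal^(+/-1) else."""
    facs = np.ones(n)
    selected = rng.random(n) < sel_prob
    draws = rng.lognormal(loc, scale, n)
    down = rng.random(n) < down_prob
    draws = np.where(down, 1.0 / draws, draws)
    facs[selected] = draws[selected]
    return facs


def simulate_groups(p: SimParams) -> SimulatedDataset:
    """Run the hierarchical group simulation and apply logistic dropout.

    The generative chain, one independent RNG stream per stage so a fixed
    seed reproduces the dataset bitwise:

    1. gene base means ~ Gamma(mean_shape, rate=mean_rate); with probability
       ``outlier_prob`` a gene's mean is replaced by median(mean) x factor,
       factor ~ LogNormal(outlier_loc, outlier_scale);
    2. per-group DE factors: each gene is DE in each group with probability
       ``de_prob``, factor ~ LogNormal(de_fac_loc, de_fac_scale), inverted
       with probability 1/2;
    3. cell group labels ~ Categorical(group_prob);
    4. expected library sizes ~ LogNormal(lib_loc, lib_scale);
    5. per-cell means = (group gene means normalized to proportions) x
       library size;
    6. overdispersion: per-entry BCV = (bcv_common + 1/sqrt(mean)) *
       sqrt(bcv_df / chi2_g) with one chi-square draw per gene; gene-cell
       means ~ Gamma(1/BCV^2, scale = mean * BCV^2);
    7. true counts ~ Poisson(gene-cell mean);
    8. dropout: each entry zeroed with probability
       ``logistic_dropout_prob(ln mean, dropout_mid, dropout_shape)``.
    """
    rngs = _stage_rngs(p.seed)
    n, g = p.n_cells, p.n_genes
    k = len(p.group_prob)

    base_means = rngs["gene_means"].gamma(p.mean_shape, 1.0 / p.mean_rate, g)
    r_out = rngs["outliers"]
    is_outlier = r_out.random(g) < p.outlier_prob
    out_facs = r_out.lognormal(p.outlier_loc, p.outlier_scale, g)
    base_means[is_outlier] = out_facs[is_outlier] * np.median(base_means)

    de = np.vstack([
        _lognormal_factors(rngs["de_factors"], g, p.de_prob, 0.5,
                           p.de_fac_loc, p.de_fac_scale)
        for _ in range(k)
    ])
    group_means = base_means[None, :] * de                      # k x genes

    groups = rngs["groups"].choice(k, size=n, p=np.asarray(p.group_prob))
    lib_sizes = rngs["lib_sizes"].lognormal(p.lib_loc, p.lib_scale, n)

    props = group_means / group_means.sum(axis=1, keepdims=True)
    cell_base = props[groups] * lib_sizes[:, None]              # cells x genes

    chi = rngs["bcv"].chisquare(p.bcv_df, g)
    bcv = (p.bcv_common + 1.0 / np.sqrt(cell_base)) * np.sqrt(p.bcv_df / chi)[None, :]
    shape_mat = 1.0 / bcv**2
    cell_means = rngs["cell_means"].gamma(shape_mat, cell_base * bcv**2)

    true = rngs["poisson"].poisson(cell_means).astype(float)

    with np.errstate(divide="ignore"):
        log_mean = np.log(cell_means)
    pi = logistic_dropout_prob(log_mean, p.dropout_mid, p.dropout_shape)
    dropped = rngs["dropout"].random((n, g)) < pi
    observed = np.where(dropped, 0.0, true)
    # the mask records realized dropout events: expressed entries zeroed
    mask = dropped & (true > 0)

    cells = [f"cell{i+1}" for i in range(n)]
    genes = [f"gene{j+1}" for j in range(g)]
    return SimulatedDataset(
        true_counts=ExpressionMatrix(true, cells, genes, "raw_counts"),
        observed_counts=ExpressionMatrix(observed, cells, genes, "raw_counts"),
        group_labels=np.array([f"group{i+1}" for i in groups]),
        dropout_mask=mask,
        params=p,
    )


def downsample_counts(
    true_counts: ExpressionMatrix,
    efficiency_mean: float = 0.1,
    efficiency_cv: float = 0.3,
    seed: int = 0,
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Binomially thin integer counts at a random per-cell efficiency.

    Each cell's capture efficiency is drawn from a Gamma distribution with
    the given mean and coefficient of variation (clipped to (0, 1]); each
    observed count is Binomial(true count, efficiency).
    """
    vals = true_counts.values
    if not np.allclose(vals, np.round(vals)):
        raise ValueError("downsample_counts requires integer true counts")
    if not 0 < efficiency_mean <= 1:
        raise ValueError("efficiency_mean must be in (0, 1]")
    if efficiency_cv < 0:
        raise ValueError("efficiency_cv must be nonnegative")
    rng = np.random.default_rng(seed)
    n = true_counts.n_rows
    if efficiency_cv == 0:
        eff = np.full(n, efficiency_mean)
    else:
        shape = 1.0 / efficiency_cv**2
        scale = efficiency_mean / shape
        eff = rng.gamma(shape, scale, n)
    eff = np.clip(eff, np.finfo(float).tiny, 1.0)
    observed = rng.binomial(vals.astype(np.int64), eff[:, None]).astype(float)
    return true_counts.with_values(observed, layer_tag="raw_counts"), eff


def synth_bulk(
    true_counts: ExpressionMatrix,
    n_samples: int = 3,
    noise_cv: float = 0.1,
    seed: int = 0,
) -> ExpressionMatrix:
    """Matched pseudo-bulk: noisy per-gene means of the true counts.

    Each sample is the per-gene mean across cells multiplied by gene-wise
    lognormal noise with unit mean and coefficient of variation ``noise_cv``,
    emulating the expression consistency between matched bulk and true
    single-cell profiles.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be at least 1")
    rng = np.random.default_rng(seed)
    gene_mean = true_counts.values.mean(axis=0)
    g = true_counts.n_cols
    if noise_cv == 0:
        noise = np.ones((n_samples, g))
    else:
        sigma2 = np.log1p(noise_cv**2)
        # mu chosen so E[lognormal] = 1
        noise = rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), (n_samples, g))
    values = gene_mean[None, :] * noise
    samples = [f"bulk{i+1}" for i in range(n_samples)]
    return ExpressionMatrix(values, samples, list(true_counts.col_ids), "raw_counts")
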