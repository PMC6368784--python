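"""Per-sample genome abundance models.

Four sample designs are supported, all built on a lognormal base
distribution (the standard null model for microbial community abundance):

* ``single`` — one sample, abundances i.i.d. Lognormal(mu, sigma);
  defaults mu=1, sigma=2 on the underlying normal, sigma=0 degenerates to
  a uniform community.
* ``differential`` — n independent lognormal samples (conditions altered
  between samplings; no cross-sample coupling).
* ``replicates`` — one base draw D_0, replicate i = D_0 + Gaussian noise
  (batch effects); sample 0 is D_0 itself.
* ``timeseries`` — Markov chain: D_i = D_{i-1} + Gaussian noise, or the
  damped lognormal form D_i = (D_{i-1} + Lognormal)/2.

Additive noise can push values negative; negatives are clamped to zero
(genome absent in that sample). A log-space variant adds the noise to
ln D instead, which keeps values positive by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_MU = 1.0
DEFAULT_SIGMA = 2.0


@dataclass
class AbundanceMatrix:
    """Genomes x samples abundance values D_0..D_{n-1}."""

    genome_ids: list[str]
    values: np.ndarray  # shape (G, n), all >= 0
    mode: str
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.genome_ids):
            raise ValueError("row count does not match genome id count")
        if (self.values < 0).any():
            raise ValueError("negative abundance value")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def sample(self, i: int) -> dict[str, float]:
        return dict(zip(self.genome_ids, self.values[:, i]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.genome_ids, name="genome_id"),
            columns=[f"sample_{i}" for i in range(self.n_samples)],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def _check(genome_ids: list[str], sigma: float) -> None:
    if not genome_ids:
        raise ValueError("need at least one genome")
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")


def single_sample(
    genome_ids: list[str],
    rng: np.random.Generator,
    mu: float = DEFAULT_MU,
    sigma: float = DEFAULT_SIGMA,
) -> AbundanceMatrix:
    """One lognormal community sample (sigma=0: all genomes equal)."""
    _check(genome_ids, sigma)
    vals = rng.lognormal(mean=mu, sigma=sigma, size=(len(genome_ids), 1))
    return AbundanceMatrix(genome_ids, vals, "single", mu, sigma)


def differential(
    genome_ids: list[str],
    n: int,
    rng: np.random.Generator,
    mu: float = DEFAULT_MU,
    sigma: float = DEFAULT_SIGMA,
    sample_rngs: list[np.random.Generator] | None = None,
) -> AbundanceMatrix:
    """n independent lognormal samples.

    ``sample_rngs`` (one generator per sample) makes each sample's draw
    independent of how many samples the run requests, so sample i is
    individually reproducible from its own derived seed.
    """
    _check(genome_ids, sigma)
    if n < 2:
        raise ValueError(f"differential mode needs n >= 2 samples, got {n}")
    g = len(genome_ids)
    if sample_rngs is None:
        vals = rng.lognormal(mean=mu, sigma=sigma, size=(g, n))
    else:
        vals = np.column_stack(
            [sample_rngs[i].lognormal(mean=mu, sigma=sigma, size=g) for i in range(n)]
        )
    return AbundanceMatrix(genome_ids, vals, "differential", mu, sigma)


def replicates(
    genome_ids: list[str],
    n: int,
    rng: np.random.Generator,
    mu: float = DEFAULT_MU,
    sigma: float = DEFAULT_SIGMA,
    noise_sd: float = 1.0,
    log_space: bool = False,
    base: np.ndarray | None = None,
    sample_rngs: list[np.random.Generator] | None = None,
) -> AbundanceMatrix:
    """n replicate samples of one base community draw.

    Sample 0 is the base draw D_0; samples 1..n-1 add N(0, noise_sd)
    per cell (on the linear scale by default, clamped at zero; on the log
    scale if ``log_space``). A designed community vector can be supplied
    as ``base`` in place of the fresh lognormal D_0 draw.
    """
    _check(genome_ids, sigma)
    if n < 1:
        raise ValueError(f"replicates mode needs n >= 1 samples, got {n}")
    g = len(genome_ids)
    if base is None:
        base = rng.lognormal(mean=mu, sigma=sigma, size=g)
    else:
        base = np.asarray(base, dtype=float)
        if base.shape != (g,):
            raise ValueError("base vector length does not match genome count")
    vals = np.empty((g, n))
    vals[:, 0] = base
    for i in range(1, n):
        r = rng if sample_rngs is None else sample_rngs[i]
        eps = r.normal(0.0, noise_sd, size=g)
        if log_space:
            vals[:, i] = np.exp(np.log(base) + eps)
        else:
            vals[:, i] = np.maximum(base + eps, 0.0)
    return AbundanceMatrix(genome_ids, vals, "replicates", mu, sigma)


def timeseries(
    genome_ids: list[str],
    n: int,
    rng: np.random.Generator,
    mu: float = DEFAULT_MU,
    sigma: float = DEFAULT_SIGMA,
    mode: str = "gaussian",
    noise_sd: float = 1.0,
    log_space: bool = False,
    base: np.ndarray | None = None,
    sample_rngs: list[np.random.Generator] | None = None,
) -> AbundanceMatrix:
    """Markov time series of n samples.

    ``gaussian``: D_i = D_{i-1} + N(0, noise_sd), clamped at zero
    (log-space variant adds the noise to ln D). ``lognormal``:
    D_i = (D_{i-1} + Lognormal(mu, sigma)) / 2, a damped recurrence whose
    mean converges geometrically to the lognormal mean.
    """
    _check(genome_ids, sigma)
    if n < 2:
        raise ValueError(f"timeseries mode needs n >= 2 samples, got {n}")
    if mode not in ("gaussian", "lognormal"):
        raise ValueError(f"unknown timeseries mode {mode!r}; use 'gaussian' or 'lognormal'")
    g = len(genome_ids)
    vals = np.empty((g, n))
    if base is None:
        vals[:, 0] = rng.lognormal(mean=mu, sigma=sigma, size=g)
    else:
        base = np.asarray(base, dtype=float)
        if base.shape != (g,):
            raise ValueError("base vector length does not match genome count")
        vals[:, 0] = base
    for i in range(1, n):
        prev = vals[:, i - 1]
        r = rng if sample_rngs is None else sample_rngs[i]
        if mode == "gaussian":
            eps = r.normal(0.0, noise_sd, size=g)
            if log_space:
                with np.errstate(divide="ignore"):
                    vals[:, i] = np.where(prev > 0, np.exp(np.log(prev) + eps), 0.0)
            else:
                vals[:, i] = np.maximum(prev + eps, 0.0)
        else:
            eps = r.lognormal(mean=mu, sigma=sigma, size=g)
            vals[:, i] = (prev + eps) / 2.0
    return AbundanceMatrix(genome_ids, vals, f"timeseries-{mode}", mu, sigma)


def normalize(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Per-sample relative abundances (each sample sums to 1)."""
    sums = matrix.values.sum(axis=0)
    if (sums <= 0).any():
        bad = [i for i, s in enumerate(sums) if s <= 0]
        raise ValueError(f"samples {bad} have zero total abundance; cannot normalize")
    return AbundanceMatrix(
        matrix.genome_ids, matrix.values / sums, matrix.mode, matrix.mu, matrix.sigma
    )
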