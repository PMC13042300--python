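"""Bootstrapped effect of food deprivation.

The headline statistic: for one strain, resample the fed and the food-deprived
percent-exiting samples with replacement (10,000 replicates by default), form
the element-wise difference (food-deprived minus fed) within each replicate,
and summarize the replicate means — their average (the effect estimate), the
average of the per-replicate standard deviations, and a trimmed percentile
95% confidence interval obtained by discarding the extreme 2.5% of replicate
means on each side and taking the remaining extremes as bounds.

When the two groups have unequal sizes, both are resampled at the smaller N.
The summaries feed a downstream ANOVA with a pseudo-N of N_fed + N_fd - 1
(two groups collapse into one difference sample, costing one degree of
freedom).

An exhaustive-enumeration oracle computes the exact expectations of the
per-replicate mean and SD for small samples, for validation.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .assay_data import GroupSample

__all__ = [
    "BootstrapConfig",
    "BootstrapResult",
    "resample_with_replacement",
    "percentile_ci",
    "bootstrap_difference",
    "enumerate_bootstrap_oracle",
]

_GENERATOR = "PCG64"  # numpy bit generator backing every bootstrap stream


@dataclass(frozen=True)
class BootstrapConfig:
    """Replication count, CI tail mass, seed, and SD convention.

    ``sd_ddof=1`` (sample SD, denominator m-1) is the default, matching common
    spreadsheet and stats-package behavior.
    """

    n_reps: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    sd_ddof: int = 1

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError(f"n_reps must be >= 1, got {self.n_reps}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if int(self.alpha / 2 * self.n_reps) * 2 >= self.n_reps:
            raise ValueError("trimming would remove every replicate mean")
        if self.sd_ddof not in (0, 1):
            raise ValueError("sd_ddof must be 0 or 1")


@dataclass(frozen=True)
class BootstrapResult:
    """Replicate summaries of the bootstrapped difference (food-deprived - fed)."""

    replicate_means: np.ndarray
    replicate_sds: np.ndarray
    mean_of_means: float
    mean_of_sds: float
    ci_low: float
    ci_high: float
    m_pairs: int       # resample size per replicate = min(N_fed, N_fd)
    pseudo_n: int      # N_fed + N_fd - 1, the downstream-ANOVA sample size
    n_fed: int
    n_fd: int
    n_reps: int
    seed: int
    sd_ddof: int
    generator: str = _GENERATOR

    def to_dict(self) -> dict:
        """Scalar summaries + provenance (no replicate vectors)."""
        return {
            "mean_of_means": self.mean_of_means,
            "mean_of_sds": self.mean_of_sds,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "m_pairs": self.m_pairs,
            "pseudo_n": self.pseudo_n,
            "n_fed": self.n_fed,
            "n_fd": self.n_fd,
            "n_reps": self.n_reps,
            "seed": self.seed,
            "sd_ddof": self.sd_ddof,
            "generator": self.generator,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def replicate_means_to_csv(self, path) -> None:
        """Full replicate-mean vector, one value per line, for audit."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("replicate_mean\n")
            for v in self.replicate_means:
                fh.write(f"{v!r}\n")


def resample_with_replacement(
    values: Sequence[float], m: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``m`` values independently and uniformly from ``values``."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot resample an empty vector")
    if m < 1:
        raise ValueError(f"resample size must be >= 1, got {m}")
    idx = rng.integers(0, values.size, size=m)
    return values[idx]


def percentile_ci(
    replicate_means: Sequence[float], alpha: float = 0.05
) -> tuple[float, float]:
    """Trimmed percentile interval: drop ``floor(alpha/2 * R)`` values from each
    end of the sorted replicate means and return the remaining extremes."""
    x = np.sort(np.asarray(replicate_means, dtype=float))
    r = x.size
    if r == 0:
        raise ValueError("empty replicate vector")
    k = int(np.floor(alpha / 2.0 * r))
    if 2 * k >= r:
        raise ValueError(f"trimming {k} per side removes all {r} elements")
    return float(x[k]), float(x[r - 1 - k])


def _as_values(sample) -> np.ndarray:
    if isinstance(sample, GroupSample):
        return sample.values
    return np.asarray(sample, dtype=float)


def bootstrap_difference(
    fed, fd, config: BootstrapConfig | None = None
) -> BootstrapResult:
    """Bootstrapped distribution of the difference food-deprived minus fed.

    Each replicate draws ``m = min(N_fed, N_fd)`` values with replacement from
    each group, differences them element-wise (fd - fed), and records the mean
    and SD of the difference vector.  A single PCG64 stream seeded from the
    config supplies first the fed index block (n_reps × m draws) and then the
    fd index block, so identical (data, config) give bit-identical results.

    ``fed`` and ``fd`` may be :class:`~foragestat.assay_data.GroupSample` or
    plain numeric sequences.
    """
    config = config or BootstrapConfig()
    fed_v = _as_values(fed)
    fd_v = _as_values(fd)
    if fed_v.size == 0 or fd_v.size == 0:
        raise ValueError("both groups must be nonempty")

    m = min(fed_v.size, fd_v.size)
    rng = np.random.Generator(np.random.PCG64(config.seed))
    fed_idx = rng.integers(0, fed_v.size, size=(config.n_reps, m))
    fd_idx = rng.integers(0, fd_v.size, size=(config.n_reps, m))
    diff = fd_v[fd_idx] - fed_v[fed_idx]

    means = diff.mean(axis=1)
    if m == 1 and config.sd_ddof == 1:
        warnings.warn(
            "per-replicate SD is undefined at m=1 with ddof=1; reporting 0",
            RuntimeWarning,
            stacklevel=2,
        )
        sds = np.zeros(config.n_reps)
    else:
        sds = diff.std(axis=1, ddof=config.sd_ddof)

    ci_low, ci_high = percentile_ci(means, config.alpha)
    return BootstrapResult(
        replicate_means=means,
        replicate_sds=sds,
        mean_of_means=float(means.mean()),
        mean_of_sds=float(sds.mean()),
        ci_low=ci_low,
        ci_high=ci_high,
        m_pairs=m,
        pseudo_n=int(fed_v.size + fd_v.size - 1),
        n_fed=int(fed_v.size),
        n_fd=int(fd_v.size),
        n_reps=config.n_reps,
        seed=config.seed,
        sd_ddof=config.sd_ddof,
    )


def enumerate_bootstrap_oracle(
    fed, fd, sd_ddof: int = 1, max_tuples: int = 2_000_000
) -> tuple[float, float]:
    """Exact E[replicate mean] and E[replicate SD] by exhaustive enumeration.

    Within a replicate the m difference entries are i.i.d. draws from the
    N_fed × N_fd equiprobable pairwise differences, so the enumeration runs
    over all (N_fed·N_fd)^m equiprobable m-tuples of differences — feasible
    only for small samples, which is exactly the oracle's remit.
    """
    fed_v = _as_values(fed)
    fd_v = _as_values(fd)
    if fed_v.size == 0 or fd_v.size == 0:
        raise ValueError("both groups must be nonempty")
    m = min(fed_v.size, fd_v.size)
    pool = (fd_v[None, :] - fed_v[:, None]).ravel()  # all pairwise differences
    n_tuples = pool.size**m
    if n_tuples > max_tuples:
        raise ValueError(
            f"enumeration over {n_tuples} tuples exceeds cap {max_tuples}; "
            "groups too large for the exact oracle"
        )
    grids = np.meshgrid(*([pool] * m), indexing="ij")
    tuples = np.stack([g.ravel() for g in grids], axis=1)  # (n_tuples, m)
    exact_mean = float(tuples.mean(axis=1).mean())
    if m == 1 and sd_ddof == 1:
        exact_sd = 0.0  # mirrors bootstrap_difference's degenerate-m convention
    else:
        exact_sd = float(tuples.std(axis=1, ddof=sd_ddof).mean())
    return exact_mean, exact_sd
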