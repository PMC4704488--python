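"""Seeded generators for every input the analysis pipeline consumes.

Each generator is a pure function of its parameters and a
:class:`RandomSpec`, so reruns reproduce outputs bit-for-bit, and each
dataset comes with a :class:`SyntheticTruth` record of the parameters it
was drawn from.  The generators emulate:

* noisy (miRNA level, reporter ratio) calibration pairs obeying
  non-cooperative Hill repression (multiplicative log-normal noise);
* bimodal log-normal reporter-ratio samples;
* state-fraction time courses from two-state first-order kinetics with
  binomial gating noise (a finite cell sample per timepoint);
* dye-dilution log-fluorescence samples with division-cycle structure
  (component d sits ln 2 below the undivided peak per division).

All intensity/ratio distributions live on the natural-log scale
internally; any log10 conversion happens at I/O only.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .interconversion_kinetics import SwitchingRates, analytic_fraction
from .reporter_model import ReporterCalibration, hill_response
from .state_mixture import LN2, LogNormalMixture

__all__ = [
    "RandomSpec",
    "SyntheticTruth",
    "as_generator",
    "gen_calibration_pairs",
    "gen_ratio_sample",
    "gen_timecourse",
    "gen_dye_dilution",
]


@dataclass(frozen=True)
class RandomSpec:
    """Reproducible random stream: a seed plus a short consumer name.

    The same (seed, stream_id) always produces the identical stream on one
    platform; different stream_ids from one seed give statistically
    independent streams (the stream name is folded into the seed sequence
    entropy via CRC-32).
    """

    seed: int
    stream_id: str = "default"

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise InvalidInputError("seed must be a non-negative integer")

    def generator(self) -> np.random.Generator:
        entropy = (int(self.seed), zlib.crc32(self.stream_id.encode("utf-8")))
        return np.random.default_rng(np.random.SeedSequence(entropy))

    def child(self, stream_id: str) -> "RandomSpec":
        """Derived spec with the same seed and a new stream name."""
        return RandomSpec(seed=self.seed, stream_id=stream_id)


def as_generator(rng, stream_id: str = "default") -> np.random.Generator:
    """Coerce a RandomSpec, Generator, int seed, or None into a Generator."""
    if rng is None:
        return np.random.default_rng()
    if isinstance(rng, np.random.Generator):
        return rng
    if isinstance(rng, RandomSpec):
        return rng.generator()
    if isinstance(rng, (int, np.integer)):
        return RandomSpec(seed=int(rng), stream_id=stream_id).generator()
    raise InvalidInputError(f"cannot interpret {rng!r} as a random source")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth sidecar for one generated dataset."""

    generator_name: str
    true_params: dict
    n_samples: int

    def to_dict(self) -> dict:
        return {
            "generator_name": self.generator_name,
            "true_params": self.true_params,
            "n_samples": self.n_samples,
        }


def _lognormal_noise(gen: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean multiplicative log-normal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    s2 = np.log1p(cv * cv)
    return gen.lognormal(mean=-0.5 * s2, sigma=np.sqrt(s2), size=size)


def gen_calibration_pairs(calib: ReporterCalibration, miRNA_levels, noise_cv: float,
                          rng) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Noisy calibration pairs: Hill response times log-normal noise.

    Each ratio is ``hill_response(level)`` multiplied by unit-mean
    log-normal noise with the given coefficient of variation, so ratios
    stay strictly positive.
    """
    levels = np.asarray(miRNA_levels, dtype=float)
    if levels.size == 0:
        raise InvalidInputError("miRNA level sequence must be non-empty")
    if np.any(levels < 0):
        raise InvalidInputError("miRNA levels must be non-negative")
    if noise_cv < 0:
        raise InvalidInputError("noise_cv must be non-negative")
    gen = as_generator(rng, "gen_calibration_pairs")
    ratios = hill_response(calib, levels) * _lognormal_noise(gen, noise_cv, levels.size)
    table = pd.DataFrame({"mirna_level": levels, "ratio": ratios})
    truth = SyntheticTruth(
        generator_name="gen_calibration_pairs",
        true_params={"K": calib.K, "n": calib.n, "r0": calib.r0, "noise_cv": noise_cv},
        n_samples=int(levels.size),
    )
    return table, truth


def gen_ratio_sample(mixture: LogNormalMixture, n: int, rng) -> tuple[np.ndarray, SyntheticTruth]:
    """I.i.d. draws from a two-component log-normal reporter-ratio mixture."""
    if n < 1:
        raise InvalidInputError("n must be at least 1")
    gen = as_generator(rng, "gen_ratio_sample")
    comp = gen.random(n) >= mixture.w_high  # False -> high-activity component
    mus = np.where(comp, mixture.mu_low, mixture.mu_high)
    sigmas = np.where(comp, mixture.sigma_low, mixture.sigma_high)
    ratios = np.exp(gen.normal(mus, sigmas))
    truth = SyntheticTruth(
        generator_name="gen_ratio_sample",
        true_params=mixture.to_dict(),
        n_samples=int(n),
    )
    return ratios, truth


def gen_timecourse(rates: SwitchingRates, f0_high: float, times_divisions,
                   n_cells_per_timepoint: int, rng) -> tuple[pd.DataFrame, SyntheticTruth]:
    """State-fraction time course with binomial gating noise.

    At each timepoint the number of high-state cells among
    ``n_cells_per_timepoint`` sampled cells is a binomial draw with success
    probability equal to the analytic high-state fraction.
    """
    t = np.asarray(times_divisions, dtype=float)
    if np.any(t < 0):
        raise InvalidInputError("times must be non-negative")
    if n_cells_per_timepoint < 1:
        raise InvalidInputError("need at least one cell per timepoint")
    gen = as_generator(rng, "gen_timecourse")
    f = np.atleast_1d(analytic_fraction(rates, f0_high, t))
    n_high = gen.binomial(n_cells_per_timepoint, f)
    table = pd.DataFrame({
        "t_divisions": t,
        "n_high": n_high,
        "n_total": np.full(t.size, n_cells_per_timepoint),
    })
    truth = SyntheticTruth(
        generator_name="gen_timecourse",
        true_params={"k_hl": rates.k_hl, "k_lh": rates.k_lh, "f0_high": f0_high},
        n_samples=int(t.size * n_cells_per_timepoint),
    )
    return table, truth


def gen_dye_dilution(mu0: float, sigma: float, division_weights, n: int,
                     rng) -> tuple[np.ndarray, SyntheticTruth]:
    """Log dye-intensity sample with division-cycle structure.

    Draws from a Gaussian mixture whose component d has mean
    ``mu0 - d*ln 2`` (two-fold dye dilution per division) and shared sigma.
    """
    if sigma <= 0:
        raise InvalidInputError("sigma must be positive")
    if n < 1:
        raise InvalidInputError("n must be at least 1")
    w = np.asarray(division_weights, dtype=float)
    if w.size == 0 or np.any(w < 0) or not np.isclose(w.sum(), 1.0, atol=1e-9):
        raise InvalidInputError("division weights must be non-negative and sum to 1")
    gen = as_generator(rng, "gen_dye_dilution")
    d = gen.choice(w.size, size=n, p=w / w.sum())
    x = gen.normal(mu0 - d * LN2, sigma)
    truth = SyntheticTruth(
        generator_name="gen_dye_dilution",
        true_params={"mu0": mu0, "sigma": sigma,
                     "division_weights": [float(v) for v in w]},
        n_samples=int(n),
    )
    return x, truth
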