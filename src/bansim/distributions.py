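"""Samplers for the three input-uncertainty families of the model.

Every model input is drawn independently from one of three families:

* a normal distribution clipped to its physical support by *resampling*
  (so no probability mass piles up at the bounds),
* a BetaPERT distribution — a Beta rescaled onto [min, max] with shape
  set by the most-likely value (classical shape constant ``lambda = 4``),
  used for unit prices reported as a range,
* a lognormal parameterized by its *arithmetic* mean and SD, used for
  right-skewed length-of-stay effects.

All samplers share the zero-variance convention: a null dispersion
returns the central value exactly, which makes fully deterministic model
runs possible. Randomness flows through a :class:`numpy.random.Generator`
so a fixed seed reproduces draws bit-for-bit.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "RESAMPLE_CAP",
    "random_stream",
    "sample_normal",
    "betapert_mean",
    "betapert_shape",
    "sample_betapert",
    "lognormal_params_from_moments",
    "sample_lognormal_from_moments",
]

#: Maximum rejection-sampling attempts for a clipped normal before the
#: sampler errors out; makes pathological user tables fail loudly.
RESAMPLE_CAP = 1000

#: Alias for the random stream type the samplers consume.
RandomStream = np.random.Generator


def random_stream(seed: int | np.random.SeedSequence | None = None) -> RandomStream:
    """Return a seeded random stream (a NumPy PCG64 generator)."""
    return np.random.default_rng(seed)


def sample_normal(
    mean: float,
    sd: float,
    lower: float = -math.inf,
    upper: float = math.inf,
    rng: RandomStream | None = None,
) -> float:
    """Draw from Normal(mean, sd) restricted to [lower, upper] by resampling.

    Rejection sampling keeps the shape of the distribution inside the
    bounds instead of piling mass at the edges (as clamping would).
    ``sd = 0`` returns ``mean`` exactly.

    Raises
    ------
    ValueError
        If ``sd < 0`` or ``lower >= upper``.
    RuntimeError
        If no draw lands inside the bounds within ``RESAMPLE_CAP``
        attempts (the bounds exclude essentially all probability mass).
    """
    if sd < 0:
        raise ValueError(f"sd must be >= 0, got {sd}")
    if not lower < upper:
        raise ValueError(f"need lower < upper, got [{lower}, {upper}]")
    if sd == 0:
        return float(mean)
    if rng is None:
        rng = random_stream()
    for _ in range(RESAMPLE_CAP):
        x = rng.normal(mean, sd)
        if lower <= x <= upper:
            return float(x)
    raise RuntimeError(
        f"clipped normal(mean={mean}, sd={sd}) produced no draw in "
        f"[{lower}, {upper}] after {RESAMPLE_CAP} attempts"
    )


def _check_pert(min_: float, mode: float, max_: float) -> None:
    if not (min_ <= mode <= max_) or not min_ < max_:
        raise ValueError(
            f"BetaPERT needs min <= mode <= max and min < max, "
            f"got ({min_}, {mode}, {max_})"
        )


def betapert_mean(min_: float, mode: float, max_: float) -> float:
    """Closed-form mean of the BetaPERT: ``(min + 4*mode + max) / 6``."""
    _check_pert(min_, mode, max_)
    return (min_ + 4.0 * mode + max_) / 6.0


def betapert_shape(min_: float, mode: float, max_: float) -> tuple[float, float]:
    """Beta shape parameters (alpha, beta) of the PERT on [min, max]."""
    _check_pert(min_, mode, max_)
    span = max_ - min_
    alpha = 1.0 + 4.0 * (mode - min_) / span
    beta = 1.0 + 4.0 * (max_ - mode) / span
    return alpha, beta


def sample_betapert(
    min_: float, mode: float, max_: float, rng: RandomStream | None = None
) -> float:
    """Draw from BetaPERT(min, mode, max); always within [min, max]."""
    alpha, beta = betapert_shape(min_, mode, max_)
    if rng is None:
        rng = random_stream()
    return float(min_ + (max_ - min_) * rng.beta(alpha, beta))


def lognormal_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Underlying-normal (mu, sigma) matching an arithmetic mean and SD.

    Solves ``exp(mu + sigma^2/2) = mean`` and
    ``mean^2 (exp(sigma^2) - 1) = sd^2``:

        sigma^2 = ln(1 + sd^2 / mean^2),   mu = ln(mean) - sigma^2 / 2.

    ``sd = 0`` collapses to ``(ln mean, 0)``.
    """
    if mean <= 0:
        raise ValueError(f"lognormal arithmetic mean must be > 0, got {mean}")
    if sd < 0:
        raise ValueError(f"sd must be >= 0, got {sd}")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def sample_lognormal_from_moments(
    mean: float, sd: float, rng: RandomStream | None = None
) -> float:
    """Draw a strictly positive lognormal with the given arithmetic moments."""
    mu, sigma = lognormal_params_from_moments(mean, sd)
    if sigma == 0:
        return float(mean)
    if rng is None:
        rng = random_stream()
    return float(rng.lognormal(mu, sigma))
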