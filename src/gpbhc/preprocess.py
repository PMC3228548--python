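"""Replicate averaging, normalization, and the empirical-Bayes noise prior.

The clustering model works on replicate-averaged profiles, each gene
normalized to mean 0 and standard deviation 1 across time points.  When
replicates are available, their scatter around the averages yields an
estimate ``sigma_m_sq`` of the measurement-error variance of an averaged
observation, which anchors a weakly informative Gamma prior on the total
noise variance of the Gaussian process: the prior density is equal at
``sigma_m_sq`` and at 1 (the approximate total variance after
normalization), and its mode sits between them at ``Omega`` times that
common density.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataset import DatasetError, TimeSeriesDataset

logger = logging.getLogger(__name__)

DEFAULT_OMEGA = 100.0


class CalibrationError(ValueError):
    """Raised when the Gamma noise prior cannot be calibrated."""


@dataclass(frozen=True)
class NoisePrior:
    """Gamma(alpha, beta) prior on the GP noise variance.

    ``flat=True`` marks the no-replicate case: a flat prior on the noise
    variance, with ``alpha``/``beta`` unused.
    """

    sigma_m_sq: float
    alpha: float
    beta: float
    omega: float = DEFAULT_OMEGA
    flat: bool = False

    @property
    def mode(self) -> float:
        if self.flat:
            raise ValueError("flat prior has no mode")
        return (self.alpha - 1.0) / self.beta

    def log_density(self, x: float) -> float:
        if self.flat:
            return 0.0
        return float(stats.gamma.logpdf(x, a=self.alpha, scale=1.0 / self.beta))

    @classmethod
    def make_flat(cls, sigma_m_sq: float = float("nan")) -> "NoisePrior":
        return cls(sigma_m_sq=sigma_m_sq, alpha=float("nan"),
                   beta=float("nan"), flat=True)


def average_replicates(raw: np.ndarray) -> np.ndarray:
    """Mean over the replicate axis of a ``(R, G, T)`` array.

    Missing whole replicate columns (NaN) are ignored; partially missing
    cells are rejected upstream by :class:`TimeSeriesDataset`.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 3 or raw.shape[0] < 1:
        raise DatasetError("raw must be a non-empty (replicate, gene, time) array")
    with np.errstate(invalid="ignore"):
        return np.nanmean(raw, axis=0)


def normalize_genes(profiles: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scale each gene profile to mean 0, sample standard deviation 1.

    Returns ``(normalized, mean, sd)`` so that the identical affine map can
    be applied to the raw replicate values.  Sample (n-1) standard
    deviation is used, the common convention in expression analysis.
    """
    profiles = np.asarray(profiles, dtype=float)
    mean = profiles.mean(axis=1)
    sd = profiles.std(axis=1, ddof=1)
    bad = np.flatnonzero(sd <= 0)
    if bad.size:
        raise DatasetError(
            f"constant expression profile (sd = 0) for gene index {bad[0]}; "
            "remove degenerate genes before clustering"
        )
    return (profiles - mean[:, None]) / sd[:, None], mean, sd


def estimate_measurement_variance(
    raw: np.ndarray, averages: np.ndarray | None = None
) -> float:
    """Measurement-error variance of an averaged observation.

    With ``R`` replicates everywhere this is

        sigma_m^2 = sum_{t,g,r} (y_{r,g,t} - ybar_{g,t})^2 / (R (GRT - 1)),

    i.e. (total replicate scatter) / (GRT - 1), deflated by 1/R because
    the clustered observations are replicate means.  With ragged counts
    ``R_{g,t}`` the generalization used here replaces ``R`` by the mean
    replicate count and ``GRT`` by the total number of measurements; the
    balanced formula is recovered when all counts are equal.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 3:
        raise DatasetError("raw must be a (replicate, gene, time) array")
    counts = (~np.isnan(raw)).sum(axis=0)  # (G, T)
    if (counts < 2).all():
        raise DatasetError(
            "no replicate information (R = 1 everywhere); use a flat prior"
        )
    if averages is None:
        averages = average_replicates(raw)
    dev = raw - averages[None, :, :]
    ss = float(np.nansum(dev * dev))
    n_total = float(counts.sum())
    r_mean = n_total / counts.size
    denom = r_mean * (n_total - 1.0)
    return ss / denom


def solve_gamma_prior(sigma_m_sq: float, omega: float = DEFAULT_OMEGA) -> NoisePrior:
    """Calibrate the Gamma(alpha, beta) noise-variance prior.

    Solves the two constraints

        g(1) = g(sigma_m_sq)          (equal density at the anchors)
        g(mode) = omega * g(1)        (mode omega-fold higher)

    for the Gamma density g with mode (alpha - 1)/beta.  Writing
    s = sigma_m_sq, the first constraint forces
    beta = -(alpha - 1) log(s) / (1 - s), which pins the mode at
    m = (1 - s)/(-log s) for every alpha; the second is then linear in
    (alpha - 1), giving a closed form:

        alpha = 1 + log(omega) / (log m + c (1 - m)),   c = -log(s)/(1 - s)
        beta  = (alpha - 1) c
    """
    s = float(sigma_m_sq)
    if not (0.0 < s < 1.0):
        raise CalibrationError(
            f"sigma_m_sq must lie in (0, 1); got {s!r}. The averaged, "
            "normalized data have total variance ~1, so a measurement-error "
            "variance outside (0, 1) cannot anchor the prior."
        )
    if omega <= 1.0:
        raise CalibrationError("omega must exceed 1 for a peaked prior")
    c = -np.log(s) / (1.0 - s)
    m = 1.0 / c  # mode implied by g(1) = g(s)
    denom = np.log(m) + c * (1.0 - m)
    if denom <= 0:
        raise CalibrationError(
            f"degenerate calibration geometry for sigma_m_sq={s}"
        )
    alpha = 1.0 + np.log(omega) / denom
    beta = (alpha - 1.0) * c
    prior = NoisePrior(sigma_m_sq=s, alpha=float(alpha), beta=float(beta),
                       omega=float(omega), flat=False)
    # sanity: constraints hold to tight relative tolerance
    r1 = prior.log_density(1.0) - prior.log_density(s)
    r2 = prior.log_density(prior.mode) - prior.log_density(1.0) - np.log(omega)
    if abs(r1) > 1e-8 or abs(r2) > 1e-8:
        raise CalibrationError(
            f"calibration residuals too large: {r1:.3e}, {r2:.3e}"
        )
    return prior


def preprocess(
    dataset: TimeSeriesDataset,
    omega: float = DEFAULT_OMEGA,
    use_replicate_prior: bool = True,
) -> NoisePrior:
    """Average replicates, normalize profiles, and calibrate the noise prior.

    Mutates ``dataset`` in place (fills ``profiles``/``norm_mean``/
    ``norm_sd``) and returns the :class:`NoisePrior`.  Falls back to a flat
    prior when replicates are absent, when requested, or when the
    measurement-error estimate falls outside the calibratable range.
    """
    averages = average_replicates(dataset.raw)
    profiles, mean, sd = normalize_genes(averages)
    dataset.profiles = profiles
    dataset.norm_mean = mean
    dataset.norm_sd = sd
    if not use_replicate_prior or not dataset.has_replicates:
        if use_replicate_prior and not dataset.has_replicates:
            logger.info("no replicates available; using a flat noise prior")
        return NoisePrior.make_flat()
    # put replicates on the normalized scale the GP sees
    raw_norm = (dataset.raw - mean[None, :, None]) / sd[None, :, None]
    avg_norm = (averages - mean[:, None]) / sd[:, None]
    sigma_m_sq = estimate_measurement_variance(raw_norm, avg_norm)
    try:
        return solve_gamma_prior(sigma_m_sq, omega)
    except CalibrationError as exc:
        logger.warning("noise-prior calibration failed (%s); using flat prior", exc)
        return NoisePrior.make_flat(sigma_m_sq)
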