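"""Container for replicated gene-expression time-course data.

A dataset holds the raw replicate measurements ``y[r, g, t]`` (replicate,
gene, time), the vector of observation times, and — once :func:`preprocess`
has run — the replicate-averaged, per-gene normalized profiles that the
clustering model consumes.  Replicates may be ragged only by whole
replicate column: for a given time point the trailing replicate slots may
be entirely absent (NaN), never individual cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


class DatasetError(ValueError):
    """Raised for structurally invalid expression datasets."""


@dataclass
class TimeSeriesDataset:
    """Gene x (time x replicate) expression data with metadata.

    Parameters
    ----------
    gene_ids
        ``G`` unique gene identifiers.
    times
        Strictly increasing vector of ``T`` observation times.
    raw
        Array of shape ``(R, G, T)``; missing replicate columns are NaN
        across all genes for that ``(r, t)`` slot.
    """

    gene_ids: list[str]
    times: np.ndarray
    raw: np.ndarray
    profiles: np.ndarray | None = None
    norm_mean: np.ndarray | None = None
    norm_sd: np.ndarray | None = None
    replicate_counts: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.ndim != 3:
            raise DatasetError("raw must be a (replicate, gene, time) array")
        R, G, T = self.raw.shape
        if R < 1 or G < 1 or T < 2:
            raise DatasetError(
                f"need R >= 1, G >= 1, T >= 2; got R={R}, G={G}, T={T}"
            )
        if len(self.gene_ids) != G:
            raise DatasetError("gene_ids length does not match raw gene axis")
        if len(set(self.gene_ids)) != G:
            raise DatasetError("duplicate gene identifiers")
        if self.times.shape != (T,):
            raise DatasetError("times length does not match raw time axis")
        if not np.all(np.diff(self.times) > 0):
            raise DatasetError("times must be strictly increasing")
        self._check_missing_pattern()

    def _check_missing_pattern(self) -> None:
        """Missing values are allowed only as whole (replicate, time) columns."""
        nan = np.isnan(self.raw)
        col_all = nan.all(axis=1)   # (R, T): column entirely missing
        col_any = nan.any(axis=1)
        if not np.array_equal(col_all, col_any):
            raise DatasetError(
                "missing cells must span whole replicate columns; "
                "partial missing data is not supported"
            )
        counts = (~col_all).sum(axis=0)  # replicates available per time
        if (counts < 1).any():
            raise DatasetError("every time point needs at least one replicate")
        # per-(g,t) replicate count; constant across genes by construction
        self.replicate_counts = np.broadcast_to(
            counts, (self.raw.shape[1], self.raw.shape[2])
        ).copy()
        if col_all.any():
            logger.warning(
                "dropping %d missing replicate column(s) from averaging",
                int(col_all.sum()),
            )

    # -- convenience ----------------------------------------------------

    @property
    def G(self) -> int:
        return self.raw.shape[1]

    @property
    def T(self) -> int:
        return self.raw.shape[2]

    @property
    def R(self) -> int:
        return self.raw.shape[0]

    @property
    def n_observations(self) -> int:
        """N = G * T, the number of averaged observations."""
        return self.G * self.T

    @property
    def has_replicates(self) -> bool:
        return bool((self.replicate_counts >= 2).any())

    @property
    def value_range(self) -> float:
        """max - min over the normalized averaged observations.

        The constant outlier density in the mixture likelihood is
        1 / range, taken over the whole dataset.
        """
        if self.profiles is None:
            raise DatasetError("dataset not preprocessed; call preprocess()")
        return float(np.nanmax(self.profiles) - np.nanmin(self.profiles))

    def profile_vector(self, members: "np.ndarray | list[int]") -> np.ndarray:
        """Time-major stacked profile vector for a gene subset.

        Values are ordered all genes at t_1, then t_2, ... so the pooled
        covariance matrix has the block structure the fast solver expects.
        """
        if self.profiles is None:
            raise DatasetError("dataset not preprocessed; call preprocess()")
        return self.profiles[np.asarray(members, dtype=int)].T.ravel()
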