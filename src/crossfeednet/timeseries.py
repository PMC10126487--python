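"""Community-turnover statistics on species-by-time abundance tables.

The central quantity is the *abruptness* index: the Bray-Curtis
dissimilarity between the average community compositions of two adjacent
fixed-width time windows.  For a window width ``w`` and a (1-based) time
point ``t`` the two windows are the inclusive ranges ``[t-w+1, t]`` and
``[t+1, t+w]``; each day's column is first normalized to relative
abundances, the windows are averaged per species, and the Bray-Curtis
dissimilarity between the two averaged compositions is the abruptness at
``t``.  Values above 0.5 indicate that more than half of the community
composition turned over between the windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import distance as _sdist

__all__ = [
    "AbundanceSeries",
    "AbruptnessSeries",
    "relative_abundance",
    "bray_curtis",
    "abruptness",
]


@dataclass
class AbundanceSeries:
    """Species-by-time abundance matrix with integer day labels.

    Values are unitless non-negative counts or coverages; days must be
    strictly increasing but need not be calendar-contiguous (sampling
    schedules with gaps are common).
    """

    species_ids: list[str]
    day_labels: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.day_labels = np.asarray(self.day_labels, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D species x days matrix")
        if self.values.shape != (len(self.species_ids), len(self.day_labels)):
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.species_ids)} species x {len(self.day_labels)} days"
            )
        if np.any(self.values < 0):
            raise ValueError("abundances must be non-negative")
        if len(self.day_labels) > 1 and np.any(np.diff(self.day_labels) <= 0):
            raise ValueError("day labels must be strictly increasing")

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_days(self) -> int:
        return len(self.day_labels)

    def column(self, day: int) -> np.ndarray:
        """Abundance vector for a given day label."""
        idx = np.flatnonzero(self.day_labels == day)
        if idx.size == 0:
            raise KeyError(f"day {day} not present in series")
        return self.values[:, idx[0]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.species_ids, name="species"),
            columns=[f"day_{d}" for d in self.day_labels],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AbundanceSeries":
        days = [int(str(c).removeprefix("day_")) for c in frame.columns]
        return cls(list(frame.index.astype(str)), np.array(days), frame.to_numpy(float))

    @classmethod
    def from_tsv(cls, path) -> "AbundanceSeries":
        return cls.from_frame(pd.read_csv(path, sep="\t", index_col=0))


@dataclass
class AbruptnessSeries:
    """Abruptness values ``a_t`` for every time point where both windows fit."""

    t: np.ndarray
    a: np.ndarray
    window_w: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "abruptness": self.a})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @property
    def argmax_day(self) -> int:
        """Day label at which abruptness peaks."""
        return int(self.t[int(np.argmax(self.a))])


def relative_abundance(series: AbundanceSeries) -> AbundanceSeries:
    """Normalize every day's column to sum to one.

    Idempotent; zero rows are preserved.  A day whose column is entirely
    zero has no defined composition and raises ``ValueError``.
    """
    sums = series.values.sum(axis=0)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise ValueError(
            f"day {int(series.day_labels[zero[0]])} has an all-zero abundance column"
        )
    return AbundanceSeries(
        list(series.species_ids), series.day_labels.copy(), series.values / sums
    )


def bray_curtis(u, v) -> float:
    """Bray-Curtis dissimilarity sum|u-v| / sum(u+v) in [0, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have the same length")
    if np.any(u < 0) or np.any(v < 0):
        raise ValueError("abundance vectors must be non-negative")
    if u.sum() == 0 and v.sum() == 0:
        raise ValueError("Bray-Curtis is undefined for two all-zero vectors")
    return float(_sdist.braycurtis(u, v))


def abruptness(
    series: AbundanceSeries,
    w: int = 5,
    require_contiguous_days: bool = False,
) -> AbruptnessSeries:
    """Windowed community-turnover index along a time series.

    For each sample position where ``w`` samples fit on both sides,
    compute the Bray-Curtis dissimilarity between the mean
    relative-abundance composition of the trailing window (positions
    ``t-w+1..t``) and the leading window (``t+1..t+w``).

    Parameters
    ----------
    series
        Abundance series; columns are normalized internally.
    w
        Window width in samples (the classic choice is 5 days).
    require_contiguous_days
        If True, a time point is reported only when the 2w day labels
        spanning both windows are consecutive integers; with irregular
        sampling the default builds windows over available consecutive
        samples instead.
    """
    if w < 1:
        raise ValueError("window width must be >= 1")
    n = series.n_days
    if n < 2 * w:
        raise ValueError(f"need at least 2*w={2 * w} days, got {n}")
    rel = relative_abundance(series).values
    ts, vals = [], []
    for i in range(w - 1, n - w):  # i = 0-based position of window-1 end
        if require_contiguous_days:
            span = series.day_labels[i - w + 1 : i + w + 1]
            if np.any(np.diff(span) != 1):
                continue
        left = rel[:, i - w + 1 : i + 1].mean(axis=1)
        right = rel[:, i + 1 : i + w + 1].mean(axis=1)
        ts.append(int(series.day_labels[i]))
        vals.append(bray_curtis(left, right))
    return AbruptnessSeries(np.array(ts, dtype=int), np.array(vals, dtype=float), w)
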