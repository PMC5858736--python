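"""Decision/density codings, lag-pair construction and autocorrelation.

Decision ratings {none, 2, 3, 4A, 4B, 4C, 5} map to three groups
(N = normal / unmarked, B = benign, M = malignant) and to ordinal codes
0-6 in the listed order.  Densities 1-4 collapse into three groups
(fatty, fibroglandular, heterogeneous/dense).  Lag-pair datasets pair
the current decision with features of up to five preceding cases, never
spanning a session boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CodingError, DataError, DegenerateSeriesError

DECISION_ORDER = ("none", "2", "3", "4A", "4B", "4C", "5")
DECISION_GROUPS = {
    "none": "N",
    "2": "B",
    "3": "B",
    "4A": "M",
    "4B": "M",
    "4C": "M",
    "5": "M",
}
_ORDINAL = {cat: i for i, cat in enumerate(DECISION_ORDER)}
#: 6-level merge: {4C, 5} collapse onto one top code.
_ORDINAL_6 = {"none": 0, "2": 1, "3": 2, "4A": 3, "4B": 4, "4C": 5, "5": 5}

DENSITY_GROUP_ORDER = ("fatty", "fibroglandular", "heterogeneous/dense")
_DENSITY_GROUPS = {
    1: "fatty",
    2: "fibroglandular",
    3: "heterogeneous/dense",
    4: "heterogeneous/dense",
}


@dataclass(frozen=True)
class DecisionCoding:
    category: str
    group: str
    ordinal_code: int


def map_decision(rating) -> DecisionCoding:
    """Total mapping from a rating token (or absent) to its coding."""
    if rating is None:
        rating = "none"
    rating = str(rating)
    if rating not in DECISION_GROUPS:
        raise CodingError(f"unknown rating token {rating!r}")
    return DecisionCoding(
        category=rating, group=DECISION_GROUPS[rating], ordinal_code=_ORDINAL[rating]
    )


def decision_ordinal(rating, levels: int = 7) -> int:
    """Ordinal code of a rating under the 7- or 6-level coding."""
    coding = map_decision(rating)
    if levels == 7:
        return coding.ordinal_code
    if levels == 6:
        return _ORDINAL_6[coding.category]
    raise CodingError(f"levels must be 6 or 7, got {levels!r}")


def map_density(density) -> str:
    """Density 1-4 to its three-level group."""
    try:
        density = int(density)
    except (TypeError, ValueError):
        raise CodingError(f"density must be an integer 1..4, got {density!r}") from None
    if density not in _DENSITY_GROUPS:
        raise CodingError(f"density must be 1..4, got {density!r}")
    return _DENSITY_GROUPS[density]


@dataclass
class LagPairDataset:
    """Rows pairing the current decision with lagged features.

    Columns: ``D0`` (response), then ``F0, P0``, then ``Fj, Pj, Dj`` for
    j = 1..lag.  ``m`` equals the sum over segments of
    ``max(0, segment_length - lag)``.
    """

    lag: int
    frame: pd.DataFrame
    n_segments: int

    @property
    def m(self) -> int:
        return len(self.frame)


def lag_columns(lag: int) -> list[str]:
    cols = ["D0", "F0", "P0"]
    for j in range(1, lag + 1):
        cols += [f"F{j}", f"P{j}", f"D{j}"]
    return cols


def build_lag_pairs(readings: pd.DataFrame, lag: int) -> LagPairDataset:
    """Build the lag-``lag`` dataset for one reader.

    ``readings`` must hold one reader's rows with columns ``order_index``,
    ``session_segment``, ``decision``, ``density`` and ``fd``; rows are
    taken in ``order_index`` order and lagged features never cross a
    session boundary.
    """
    if not 0 <= lag <= 5:
        raise ValueError(f"lag must lie in 0..5, got {lag}")
    required = {"order_index", "session_segment", "decision", "density", "fd"}
    missing = required - set(readings.columns)
    if missing:
        raise DataError(f"readings frame missing column(s) {sorted(missing)}")
    frame = readings.sort_values("order_index")
    if frame["fd"].isna().any():
        raise DataError("FD missing for one or more readings")

    rows = []
    n_segments = 0
    for _, seg in frame.groupby("session_segment", sort=True):
        n_segments += 1
        dec = seg["decision"].tolist()
        dens = seg["density"].tolist()
        fd = seg["fd"].tolist()
        for n in range(lag, len(seg)):
            row = {"D0": dec[n], "F0": fd[n], "P0": map_density(dens[n])}
            for j in range(1, lag + 1):
                row[f"F{j}"] = fd[n - j]
                row[f"P{j}"] = map_density(dens[n - j])
                row[f"D{j}"] = dec[n - j]
            rows.append(row)
    return LagPairDataset(
        lag=lag,
        frame=pd.DataFrame(rows, columns=lag_columns(lag)),
        n_segments=n_segments,
    )


@dataclass
class ACFResult:
    lags: np.ndarray
    r: np.ndarray
    band: float
    n: int

    @property
    def significant(self) -> np.ndarray:
        return np.abs(self.r) > self.band


def autocorrelation(series, max_lag: int) -> ACFResult:
    """Biased sample ACF with the +-1.96/sqrt(n) 95% band.

    r_k = sum (x_t - mean)(x_{t+k} - mean) / sum (x_t - mean)^2.
    Lags 1..max_lag are reported; r_0 = 1 by construction.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    if n < max_lag + 2:
        raise ValueError(f"need at least max_lag + 2 = {max_lag + 2} points, got {n}")
    centered = x - x.mean()
    denom = float((centered**2).sum())
    if denom == 0.0:
        raise DegenerateSeriesError("series has zero variance")
    r = np.array(
        [float((centered[:-k] * centered[k:]).sum()) / denom for k in range(1, max_lag + 1)]
    )
    return ACFResult(lags=np.arange(1, max_lag + 1), r=r, band=1.96 / np.sqrt(n), n=n)


def decision_series(decisions, levels: int = 7) -> np.ndarray:
    """Ordinal-coded decision sequence for ACF/ANOVA use."""
    return np.array([decision_ordinal(d, levels) for d in decisions], dtype=float)
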