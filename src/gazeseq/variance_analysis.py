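"""Multifactor fixed-effects ANOVA on lag-pair datasets.

The response is the ordinal decision code.  Terms are factor symbols
``F0..F5`` (continuous FD, standardized), ``P0..P5`` (3-level density
group) and ``D1..D5`` (decision category), with ``A:B:C`` denoting an
interaction.  Each term gets a partial (drop-one, Type-II-style) F test:
the full model containing every requested term is compared against the
model omitting that term.
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, RankDeficiencyError, SpecificationError
from .sequence_context import (
    DECISION_ORDER,
    DENSITY_GROUP_ORDER,
    LagPairDataset,
    decision_series,
)

_FACTOR_RE = re.compile(r"^([FPD])([0-5])$")

#: Maximum columns a single term may expand to before it is refused.
MAX_TERM_COLUMNS = 2000

#: Interaction terms shipped as the published-style preset (deduplicated).
PRESET_TERMS = [
    "F0:P0:F1:D1:F2:P2:D2",
    "F0:F1:F3:F4:F5",
    "F0:F2:F3:F4",
    "F0:P0:F1:P1:D1:D2",
    "F0:F1:F2:F3:F4:F5",
    "F0:F3:F4:F5",
    "P0:F0:F1:P1:D1:F2:P2:D2:F3:P3:D3",
    "P0:F0:F1:P1:D1:P2:D2",
    "P0:F1:P1:D1",
    "F0:F1:P1:D1:F2:P2:D2",
    "P0:F0:F1:P1:D1:F2:P2:D2:P3:D3",
    "D1:D2:D3:D4",
    "P0:F0:F1:P1:D1",
    "F0:D1:F2:P2:D2",
    "F0:P1:D1:F2:P2:D2",
    "P0:F0:F1:P1:D1:F2:P2:D2:P3",
    "F0:F1:F3:F4",
    "P0:F0:F1:P1:D1:F2:P2:D2:F3:P3:D3:F4:P4:D4",
    "D1:D2:D3:D5",
    "P0:F0:F1:P1:D1:F2:P2:D2:F3:P3:D3:F4:P4:D4:P5:F5",
    "P0:F0:F1:P1:D1:F2:P2:D2:F3:D3",
    "F1:P1:D1:F2:P2:D2",
    "P0:F1:D1:F2:P2:D2",
]


@dataclass(frozen=True)
class TermSpec:
    factors: tuple[str, ...]

    @classmethod
    def parse(cls, text: str) -> "TermSpec":
        factors = tuple(f.strip() for f in text.split(":") if f.strip())
        if not factors:
            raise SpecificationError(f"empty term {text!r}")
        if len(set(factors)) != len(factors):
            raise SpecificationError(f"duplicate factor within term {text!r}")
        for f in factors:
            if not _FACTOR_RE.match(f):
                raise SpecificationError(f"invalid factor symbol {f!r} in term {text!r}")
            if f.startswith("D") and f == "D0":
                raise SpecificationError("D0 is the response, not a factor")
        return cls(factors=factors)

    @property
    def name(self) -> str:
        return ":".join(self.factors)


def _as_termspecs(terms) -> list[TermSpec]:
    out = []
    for t in terms:
        out.append(t if isinstance(t, TermSpec) else TermSpec.parse(str(t)))
    return out


def _factor_columns(df: pd.DataFrame, factor: str) -> np.ndarray:
    """Coded column block for one factor symbol (n x k)."""
    if factor not in df.columns:
        raise SpecificationError(
            f"factor {factor!r} not present; dataset lag depth too small"
        )
    col = df[factor]
    if factor.startswith("F"):
        x = col.to_numpy(dtype=float)
        sd = x.std(ddof=0)
        x = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        return x[:, None]
    canonical = DENSITY_GROUP_ORDER if factor.startswith("P") else DECISION_ORDER
    observed = [lev for lev in canonical if (col == lev).any()]
    if len(observed) < len(canonical):
        warnings.warn(
            f"factor {factor}: dropping unobserved level(s) "
            f"{sorted(set(canonical) - set(observed))}",
            stacklevel=3,
        )
    # treatment coding: first observed level is the reference
    return np.column_stack(
        [(col == lev).to_numpy(dtype=float) for lev in observed[1:]]
    ) if len(observed) > 1 else np.zeros((len(col), 0))


def encode_design(dataset, terms) -> dict[str, np.ndarray]:
    """Expand terms into design-matrix blocks (term name -> n x k array).

    Categorical factors are treatment coded on observed levels;
    continuous factors standardized; interactions are elementwise
    products over the factors' column sets.
    """
    df = dataset.frame if isinstance(dataset, LagPairDataset) else dataset
    specs = _as_termspecs(terms)
    cache: dict[str, np.ndarray] = {}
    blocks: dict[str, np.ndarray] = {}
    for spec in specs:
        width = 1
        for f in spec.factors:
            if f not in cache:
                cache[f] = _factor_columns(df, f)
            width *= cache[f].shape[1]
        if width > MAX_TERM_COLUMNS:
            raise SpecificationError(
                f"term {spec.name!r} expands to {width} columns "
                f"(> {MAX_TERM_COLUMNS}); full-factorial designs are refused"
            )
        parts = [cache[f] for f in spec.factors]
        cols = [
            np.prod(np.column_stack(combo), axis=1)
            for combo in itertools.product(*(p.T for p in parts))
        ]
        blocks[spec.name] = (
            np.column_stack(cols) if cols else np.zeros((len(df), 0))
        )
    return blocks


def _sse(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def fixed_effects_anova(
    dataset,
    terms,
    alpha: float = 0.05,
    response: str = "D0",
    levels: int = 7,
) -> pd.DataFrame:
    """Partial F tests for each term; returns an effect table.

    Columns: term, F, p, df_num, df_den, significant.  ``response`` is
    ``"D0"`` (ordinal-coded decision) or the name of a numeric column.
    """
    df = dataset.frame if isinstance(dataset, LagPairDataset) else dataset
    specs = _as_termspecs(terms)
    if not specs:
        raise SpecificationError("at least one term is required")
    if response == "D0":
        y = decision_series(df["D0"], levels=levels)
    else:
        y = df[response].to_numpy(dtype=float)

    blocks = encode_design(df, specs)
    names = [s.name for s in specs]
    X_full = np.column_stack([np.ones(len(df))] + [blocks[n] for n in names])
    n, p_full = X_full.shape
    if n <= p_full + 1:
        raise DataError(
            f"{n} rows cannot support {p_full} design columns (need rows > columns + 1)"
        )
    rank_full = np.linalg.matrix_rank(X_full)
    if rank_full < p_full:
        aliased = []
        for name in names:
            X_red = np.column_stack(
                [np.ones(len(df))] + [blocks[m] for m in names if m != name]
            )
            if np.linalg.matrix_rank(X_red) == rank_full:
                aliased.append(name)
        raise RankDeficiencyError(
            f"design matrix is rank deficient (rank {rank_full} < {p_full}); "
            f"aliased term(s): {aliased or names}"
        )

    sse_full = _sse(X_full, y)
    df_den = n - p_full
    # a perfect (zero-residual) fit would make the F ratio 0/0; snap tiny
    # sums of squares to zero relative to the response scale
    tol = 1e-10 * max(float(y @ y), 1.0)
    rows = []
    for name in names:
        k = blocks[name].shape[1]
        if k == 0:
            rows.append((name, 0.0, 1.0, 0, df_den, False))
            continue
        X_red = np.column_stack(
            [np.ones(len(df))] + [blocks[m] for m in names if m != name]
        )
        delta = max(_sse(X_red, y) - sse_full, 0.0)
        if sse_full <= tol:
            fval = np.inf if delta > tol else 0.0
        else:
            fval = (delta / k) / (sse_full / df_den)
        pval = float(stats.f.sf(fval, k, df_den))
        rows.append((name, float(fval), pval, k, df_den, pval < alpha))
    return pd.DataFrame(
        rows, columns=["term", "F", "p", "df_num", "df_den", "significant"]
    )
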