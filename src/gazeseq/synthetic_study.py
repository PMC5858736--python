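"""Synthetic reader studies with injectable sequential context bias.

The simulator emulates a screening study: a shared case set (malignant /
benign / normal with parenchymal densities 1-4), readers in three
experience tiers, per-reader randomized case order with optional session
breaks, fixation-saccade gaze scanpaths whose complexity is tunable, and
diagnostic decisions with a tunable pull toward the previous decision
(``bias_alpha``).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CompositionError
from .gaze_io import DEFAULT_GEOMETRY, DisplayGeometry, GazeStream

PATHOLOGIES = ("normal", "benign", "malignant")
RATING_SETS = {
    "normal": ("none",),
    "benign": ("2", "3"),
    "malignant": ("4A", "4B", "4C", "5"),
}
RATING_TO_PATHOLOGY = {
    rating: pathology for pathology, ratings in RATING_SETS.items() for rating in ratings
}

DEFAULT_COMPOSITION = {"malignant": 0.5, "benign": 0.25, "normal": 0.25}
DEFAULT_DENSITY_WEIGHTS = {1: 0.25, 2: 0.25, 3: 0.25, 4: 0.25}

TIERS = ("N", "A", "E")
DEFAULT_READERS_PER_TIER = {"N": 3, "A": 4, "E": 3}
#: Tier accuracies are conventions (N < A < E), not calibrated estimates.
DEFAULT_TIER_ACCURACY = {"N": 0.55, "A": 0.65, "E": 0.75}


@dataclass(frozen=True)
class Case:
    case_id: str
    pathology: str
    density: int
    truth_rating: str

    def __post_init__(self) -> None:
        if self.pathology not in PATHOLOGIES:
            raise ValueError(f"unknown pathology {self.pathology!r}")
        if self.density not in (1, 2, 3, 4):
            raise ValueError(f"density must be 1..4, got {self.density!r}")
        if self.truth_rating not in RATING_SETS[self.pathology]:
            raise ValueError(
                f"truth_rating {self.truth_rating!r} inconsistent with {self.pathology!r}"
            )


@dataclass(frozen=True)
class ReaderProfile:
    reader_id: str
    tier: str
    accuracy: float
    bias_alpha: float = 0.0
    complexity_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise ValueError(f"tier must be one of {TIERS}, got {self.tier!r}")
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy must lie in [0, 1]")
        if not 0.0 <= self.bias_alpha <= 1.0:
            raise ValueError("bias_alpha must lie in [0, 1]")


@dataclass
class Reading:
    reader_id: str
    case_id: str
    order_index: int
    session_segment: int
    scanpath: GazeStream
    decision: str


def substream(*parts) -> np.random.Generator:
    """Independent RNG derived by stable hashing of the given parts.

    Regenerating one reading never perturbs another: each (seed,
    reader, case) tuple maps to its own stream.
    """
    token = "\x1f".join(str(p) for p in parts).encode()
    digest = hashlib.sha256(token).digest()
    return np.random.default_rng(np.random.SeedSequence(int.from_bytes(digest[:16], "big")))


def largest_remainder_quotas(n: int, fractions: dict) -> dict:
    """Integer quotas summing to ``n`` via largest-remainder rounding.

    Ties on the fractional remainder are broken by descending fraction,
    then by key order, so the result is deterministic.
    """
    keys = list(fractions)
    exact = {k: n * fractions[k] for k in keys}
    quotas = {k: int(math.floor(exact[k])) for k in keys}
    shortfall = n - sum(quotas.values())
    order = sorted(
        keys, key=lambda k: (-(exact[k] - quotas[k]), -fractions[k], keys.index(k))
    )
    for k in order[:shortfall]:
        quotas[k] += 1
    return quotas


def _validate_fractions(fractions: dict, allowed, what: str) -> None:
    unknown = [k for k in fractions if k not in allowed]
    if unknown:
        raise CompositionError(f"unknown {what} key(s): {unknown}")
    if any(v < 0 for v in fractions.values()):
        raise CompositionError(f"{what} fractions must be non-negative")
    total = float(sum(fractions.values()))
    if abs(total - 1.0) > 1e-9:
        raise CompositionError(f"{what} fractions sum to {total!r}, expected 1")


def generate_case_set(
    n: int,
    composition: dict | None = None,
    density_weights: dict | None = None,
    seed: int = 0,
) -> list[Case]:
    """Generate ``n`` cases with exact pathology quotas.

    Pathology counts follow largest-remainder rounding of ``composition``;
    densities are drawn from ``density_weights``; the ground-truth rating
    is uniform within the pathology's rating set.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    composition = dict(composition) if composition is not None else dict(DEFAULT_COMPOSITION)
    density_weights = (
        dict(density_weights) if density_weights is not None else dict(DEFAULT_DENSITY_WEIGHTS)
    )
    _validate_fractions(composition, PATHOLOGIES, "composition")
    _validate_fractions(density_weights, (1, 2, 3, 4), "density weight")

    quotas = largest_remainder_quotas(n, composition)
    labels = [p for p in PATHOLOGIES for _ in range(quotas.get(p, 0))]
    rng = substream(seed, "case-set")
    rng.shuffle(labels)

    densities = sorted(density_weights)
    dens_p = np.array([density_weights[d] for d in densities], dtype=float)
    dens_p = dens_p / dens_p.sum()
    width = len(str(n))
    cases = []
    for idx, pathology in enumerate(labels):
        density = int(rng.choice(densities, p=dens_p))
        rating = str(rng.choice(RATING_SETS[pathology]))
        cases.append(
            Case(
                case_id=f"case{idx + 1:0{width}d}",
                pathology=pathology,
                density=density,
                truth_rating=rating,
            )
        )
    return cases


def generate_scanpath(
    case: Case,
    profile: ReaderProfile,
    duration: float = 10.0,
    rate: float = 60.0,
    geometry: DisplayGeometry = DEFAULT_GEOMETRY,
    complexity: float = 0.5,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> GazeStream:
    """Simulate a fixation-saccade scanpath in the global display frame.

    ``complexity`` in [0, 1] monotonically increases both the number of
    fixation clusters (Poisson mean) and their spatial dispersion, so the
    box-counting dimension of the resulting trajectory increases with it
    on average.  Sample count is ``floor(duration * rate)``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if rate <= 0:
        raise ValueError("rate must be positive")
    if not 0.0 <= complexity <= 1.0:
        raise ValueError("complexity must lie in [0, 1]")
    n = int(math.floor(duration * rate))
    if n < 1:
        raise ValueError("duration * rate must yield at least one sample")
    if rng is None:
        rng = substream(seed, "scanpath", profile.reader_id, case.case_id)

    width = float(geometry.total_width)
    height = float(geometry.height)

    # floor of 3 clusters keeps even low-complexity paths spatially extended
    n_fix = 3 + int(rng.poisson(30.0 * complexity))
    n_fix = max(1, min(n_fix, n // 5 if n >= 5 else 1))
    spread = 0.12 + 0.88 * complexity  # fraction of each half-extent used
    cx, cy = width / 2.0, height / 2.0
    fx = rng.uniform(cx - spread * width / 2, cx + spread * width / 2, n_fix)
    fy = rng.uniform(cy - spread * height / 2, cy + spread * height / 2, n_fix)

    sacc_len = 3 if n_fix > 1 else 0
    n_sacc = sacc_len * (n_fix - 1)
    dwell = np.full(n_fix, (n - n_sacc) // n_fix)
    dwell[: (n - n_sacc) - int(dwell.sum())] += 1

    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    jitter = 6.0
    for i in range(n_fix):
        xs.append(fx[i] + rng.normal(0.0, jitter, dwell[i]))
        ys.append(fy[i] + rng.normal(0.0, jitter, dwell[i]))
        if i < n_fix - 1:
            frac = np.linspace(0.0, 1.0, sacc_len + 2)[1:-1]
            xs.append(fx[i] + frac * (fx[i + 1] - fx[i]))
            ys.append(fy[i] + frac * (fy[i + 1] - fy[i]))
    x = np.clip(np.concatenate(xs), 0.0, width - 1e-6)
    y = np.clip(np.concatenate(ys), 0.0, height - 1e-6)
    t = np.arange(n, dtype=float) / rate
    display = np.minimum((x // geometry.width).astype(int) + 1, geometry.n_displays)
    return GazeStream(t=t, x=x, y=y, display=display, rate=rate)


def generate_decision(
    case: Case,
    profile: ReaderProfile,
    previous_decision: str | None = None,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> str:
    """Draw one diagnostic decision (a rating token).

    With probability ``bias_alpha`` the decision copies the pathology
    group of ``previous_decision``; otherwise the base model reports the
    true pathology with probability ``accuracy`` and a uniformly chosen
    wrong pathology otherwise.  The rating is uniform within the chosen
    group's rating set.
    """
    if rng is None:
        rng = substream(seed, "decision", profile.reader_id, case.case_id)
    if previous_decision is not None and rng.random() < profile.bias_alpha:
        group_pathology = RATING_TO_PATHOLOGY[previous_decision]
    else:
        if rng.random() < profile.accuracy:
            group_pathology = case.pathology
        else:
            others = [p for p in PATHOLOGIES if p != case.pathology]
            group_pathology = str(rng.choice(others))
    return str(rng.choice(RATING_SETS[group_pathology]))


def make_reader_profiles(
    n_readers_per_tier: dict | None = None,
    tier_accuracy: dict | None = None,
    bias_alpha: float = 0.0,
    complexity_gain: float = 1.0,
) -> list[ReaderProfile]:
    counts = dict(n_readers_per_tier or DEFAULT_READERS_PER_TIER)
    accuracy = dict(DEFAULT_TIER_ACCURACY)
    accuracy.update(tier_accuracy or {})
    profiles = []
    for tier in TIERS:
        for k in range(int(counts.get(tier, 0))):
            profiles.append(
                ReaderProfile(
                    reader_id=f"{tier}{k + 1}",
                    tier=tier,
                    accuracy=accuracy[tier],
                    bias_alpha=bias_alpha,
                    complexity_gain=complexity_gain,
                )
            )
    return profiles


def _case_complexity(case: Case, profile: ReaderProfile, rng: np.random.Generator) -> float:
    base = (case.density - 1) / 3.0  # denser parenchyma -> harder search
    value = profile.complexity_gain * (0.15 + 0.8 * base) + 0.05 * rng.standard_normal()
    # floor keeps every scanpath spatially extended enough for a box-count fit
    return float(np.clip(value, 0.05, 1.0))


def generate_study(
    n_readers_per_tier: dict | None = None,
    n_cases: int = 100,
    session_breaks: dict | None = None,
    composition: dict | None = None,
    density_weights: dict | None = None,
    tier_accuracy: dict | None = None,
    bias_alpha: float = 0.0,
    complexity_gain: float = 1.0,
    duration: float = 10.0,
    rate: float = 60.0,
    geometry: DisplayGeometry = DEFAULT_GEOMETRY,
    seed: int = 0,
) -> tuple[list[Reading], list[Case]]:
    """Generate a full study: shared case set, per-reader random order.

    ``session_breaks`` maps reader_id to strictly increasing order
    indices in [1, n_cases - 1]; the session segment increments at each
    break and the decision chain restarts (no carried-over bias).
    """
    cases = generate_case_set(n_cases, composition, density_weights, seed)
    profiles = make_reader_profiles(
        n_readers_per_tier, tier_accuracy, bias_alpha, complexity_gain
    )
    session_breaks = session_breaks or {}
    readings: list[Reading] = []
    for profile in profiles:
        breaks = list(session_breaks.get(profile.reader_id, []))
        if breaks != sorted(set(breaks)) or any(
            not 1 <= b <= n_cases - 1 for b in breaks
        ):
            raise ValueError(
                f"session breaks for {profile.reader_id} must be strictly "
                f"increasing indices in [1, {n_cases - 1}]"
            )
        break_set = set(breaks)
        perm = substream(seed, "order", profile.reader_id).permutation(n_cases)
        segment = 0
        previous: str | None = None
        for order_index, case_index in enumerate(perm):
            if order_index in break_set:
                segment += 1
                previous = None
            case = cases[case_index]
            rng = substream(seed, "reading", profile.reader_id, case.case_id)
            complexity = _case_complexity(case, profile, rng)
            scanpath = generate_scanpath(
                case, profile, duration, rate, geometry, complexity, rng=rng
            )
            decision = generate_decision(case, profile, previous, rng=rng)
            readings.append(
                Reading(
                    reader_id=profile.reader_id,
                    case_id=case.case_id,
                    order_index=order_index,
                    session_segment=segment,
                    scanpath=scanpath,
                    decision=decision,
                )
            )
            previous = decision
    return readings, cases


def cases_to_frame(cases: list[Case]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "case_id": [c.case_id for c in cases],
            "pathology": [c.pathology for c in cases],
            "density": [c.density for c in cases],
            "truth_rating": [c.truth_rating for c in cases],
        }
    )


def readings_to_frame(readings: list[Reading]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "reader_id": [r.reader_id for r in readings],
            "case_id": [r.case_id for r in readings],
            "order_index": [r.order_index for r in readings],
            "session_segment": [r.session_segment for r in readings],
            "decision": [r.decision for r in readings],
        }
    )
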