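import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gazeseq import fractal, synthetic_study as ss
from gazeseq.errors import CompositionError
from gazeseq.sequence_context import DECISION_GROUPS

from conftest import GLOBAL_FRAME


class TestGenerateCaseSet:
    def test_default_composition_quotas(self):
        cases = ss.generate_case_set(100, seed=0)
        counts = Counter(c.pathology for c in cases)
        assert counts == {"malignant": 50, "benign": 25, "normal": 25}

    def test_small_n_exact_quotas(self):
        counts = Counter(c.pathology for c in ss.generate_case_set(4, seed=0))
        assert counts == {"malignant": 2, "benign": 1, "normal": 1}

    def test_invalid_composition_raises(self):
        with pytest.raises(CompositionError):
            ss.generate_case_set(10, composition={"malignant": 0.7, "benign": 0.7})

    def test_n_below_one_raises(self):
        with pytest.raises(ValueError):
            ss.generate_case_set(0)

    def test_truth_rating_consistent_with_pathology(self):
        for case in ss.generate_case_set(60, seed=3):
            assert case.truth_rating in ss.RATING_SETS[case.pathology]

    def test_determinism(self):
        a = ss.generate_case_set(50, seed=9)
        b = ss.generate_case_set(50, seed=9)
        assert a == b

    @settings(max_examples=30, deadline=None)
    @given(
        n=st.integers(1, 300),
        w=st.tuples(
            st.floats(0.01, 1), st.floats(0.01, 1), st.floats(0.01, 1)
        ),
    )
    def test_quota_exactness_property(self, n, w):
        total = sum(w)
        comp = {
            "normal": w[0] / total,
            "benign": w[1] / total,
            "malignant": w[2] / total,
        }
        comp["malignant"] = 1.0 - comp["normal"] - comp["benign"]
        cases = ss.generate_case_set(n, composition=comp, seed=1)
        counts = Counter(c.pathology for c in cases)
        # independent largest-remainder oracle
        exact = {k: n * v for k, v in comp.items()}
        floors = {k: math.floor(v) for k, v in exact.items()}
        left = n - sum(floors.values())
        order = sorted(
            comp,
            key=lambda k: (
                -(exact[k] - floors[k]),
                -comp[k],
                list(comp).index(k),
            ),
        )
        for k in order[:left]:
            floors[k] += 1
        assert {k: counts.get(k, 0) for k in comp} == floors


class TestGenerateScanpath:
    @pytest.fixture()
    def case_and_profile(self):
        case = ss.Case("c1", "malignant", 3, "4B")
        profile = ss.ReaderProfile("A1", "A", 0.65)
        return case, profile

    def test_sample_count(self, case_and_profile):
        case, profile = case_and_profile
        stream = ss.generate_scanpath(case, profile, duration=10, rate=60, seed=0)
        assert len(stream) == 600

    def test_samples_inside_bounds(self, case_and_profile, geometry):
        case, profile = case_and_profile
        for seed in range(5):
            stream = ss.generate_scanpath(
                case, profile, duration=3, rate=60, complexity=1.0, seed=seed
            )
            assert (stream.x >= 0).all() and (stream.x < geometry.total_width).all()
            assert (stream.y >= 0).all() and (stream.y < geometry.height).all()

    def test_timestamps_strictly_increasing(self, case_and_profile):
        case, profile = case_and_profile
        stream = ss.generate_scanpath(case, profile, duration=2, rate=60, seed=1)
        assert (np.diff(stream.t) > 0).all()

    def test_invalid_args(self, case_and_profile):
        case, profile = case_and_profile
        with pytest.raises(ValueError):
            ss.generate_scanpath(case, profile, duration=0, rate=60)
        with pytest.raises(ValueError):
            ss.generate_scanpath(case, profile, duration=1, rate=-5)

    def test_determinism(self, case_and_profile):
        case, profile = case_and_profile
        a = ss.generate_scanpath(case, profile, duration=2, rate=60, seed=7)
        b = ss.generate_scanpath(case, profile, duration=2, rate=60, seed=7)
        assert (a.x == b.x).all() and (a.y == b.y).all() and (a.t == b.t).all()

    def test_mean_fd_increases_with_complexity(self, case_and_profile):
        case, profile = case_and_profile
        fds = {}
        for cx in (0.1, 0.9):
            vals = [
                fractal.fd_of_stream(
                    ss.generate_scanpath(
                        case, profile, duration=3, rate=60, complexity=cx, seed=s
                    ),
                    grid_size=256,
                    frame=GLOBAL_FRAME,
                ).fd
                for s in range(50)
            ]
            fds[cx] = np.mean(vals)
        assert fds[0.1] < fds[0.9]

    def test_complexity_fd_spearman(self, case_and_profile):
        from scipy.stats import spearmanr

        case, profile = case_and_profile
        rng = np.random.default_rng(0)
        comps = rng.uniform(0, 1, 200)
        fds = [
            fractal.fd_of_stream(
                ss.generate_scanpath(
                    case, profile, duration=3, rate=60, complexity=float(c), seed=i
                ),
                grid_size=256,
                frame=GLOBAL_FRAME,
            ).fd
            for i, c in enumerate(comps)
        ]
        assert spearmanr(comps, fds).statistic >= 0.5


def _decision_chain(alpha, accuracy, n, seed):
    profile = ss.ReaderProfile("A1", "A", accuracy, bias_alpha=alpha)
    cases = ss.generate_case_set(n, seed=seed)
    rng = np.random.default_rng(seed)
    decisions, previous = [], None
    for case in cases:
        d = ss.generate_decision(case, profile, previous, rng=rng)
        decisions.append(d)
        previous = d
    return decisions


def _repeat_rate(decisions):
    pairs = list(zip(decisions[:-1], decisions[1:]))
    return np.mean([DECISION_GROUPS[a] == DECISION_GROUPS[b] for a, b in pairs])


class TestGenerateDecision:
    def test_perfect_reader_matches_truth(self):
        profile = ss.ReaderProfile("E1", "E", accuracy=1.0, bias_alpha=0.0)
        for case in ss.generate_case_set(30, seed=2):
            d = ss.generate_decision(case, profile, None, seed=5)
            assert ss.RATING_TO_PATHOLOGY[d] == case.pathology

    def test_determinism(self):
        case = ss.Case("c1", "benign", 2, "3")
        profile = ss.ReaderProfile("N1", "N", 0.5, bias_alpha=0.3)
        assert ss.generate_decision(case, profile, "5", seed=4) == ss.generate_decision(
            case, profile, "5", seed=4
        )

    def test_unbiased_chain_lag1_acf_within_band(self):
        from gazeseq.sequence_context import autocorrelation, decision_series

        decisions = _decision_chain(0.0, 0.5, 5000, seed=0)
        res = autocorrelation(decision_series(decisions), 1)
        assert abs(res.r[0]) < res.band

    def test_bias_raises_repeat_probability(self):
        biased = _repeat_rate(_decision_chain(0.5, 0.5, 5000, seed=1))
        unbiased = _repeat_rate(_decision_chain(0.0, 0.5, 5000, seed=1))
        assert biased - unbiased >= 0.2

    def test_repeat_probability_monotone_in_alpha(self):
        rates = []
        for alpha in (0.0, 0.25, 0.5, 0.75):
            reps = [
                _repeat_rate(_decision_chain(alpha, 0.5, 150, seed=s))
                for s in range(30)
            ]
            rates.append(np.mean(reps))
        assert all(a <= b for a, b in zip(rates, rates[1:]))


class TestGenerateStudy:
    def test_total_readings(self):
        readings, cases = ss.generate_study(
            n_readers_per_tier={"N": 1, "A": 1, "E": 1},
            n_cases=12,
            duration=0.2,
            seed=0,
        )
        assert len(readings) == 36 and len(cases) == 12

    def test_each_reader_sees_full_case_set(self, small_study):
        readings, cases = small_study
        case_ids = sorted(c.case_id for c in cases)
        for reader in {r.reader_id for r in readings}:
            seen = sorted(r.case_id for r in readings if r.reader_id == reader)
            assert seen == case_ids

    def test_session_segments_from_breaks(self, small_study):
        readings, _ = small_study
        for r in readings:
            assert r.session_segment == (0 if r.order_index < 20 else 1)

    def test_order_randomized_per_reader(self):
        readings, _ = ss.generate_study(
            n_readers_per_tier={"N": 2, "A": 0, "E": 0},
            n_cases=30,
            duration=0.2,
            seed=3,
        )
        orders = {
            reader: [r.case_id for r in sorted(
                (x for x in readings if x.reader_id == reader),
                key=lambda x: x.order_index,
            )]
            for reader in ("N1", "N2")
        }
        assert orders["N1"] != orders["N2"]

    def test_invalid_break_raises(self):
        with pytest.raises(ValueError):
            ss.generate_study(
                n_readers_per_tier={"N": 1, "A": 0, "E": 0},
                n_cases=10,
                session_breaks={"N1": [10]},
                duration=0.2,
            )

    def test_determinism(self):
        kwargs = dict(
            n_readers_per_tier={"N": 1, "A": 0, "E": 0},
            n_cases=8,
            duration=0.5,
            seed=21,
        )
        ra, _ = ss.generate_study(**kwargs)
        rb, _ = ss.generate_study(**kwargs)
        for a, b in zip(ra, rb):
            assert a.decision == b.decision
            assert (a.scanpath.x == b.scanpath.x).all()
            assert (a.scanpath.y == b.scanpath.y).all()
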