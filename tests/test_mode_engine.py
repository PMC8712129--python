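import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import modeselect as ms
from modeselect.mode_engine import (
    AdaptiveState,
    Archive,
    Individual,
    IterationLogger,
    archive_insert,
    binomial_crossover,
    crowding_distance,
    dominates,
    end_iteration,
    init_population,
    mo_select,
    mutate_with_archive,
    nondominated_subset,
    record_success,
    repair_bounds,
    sample_Cr,
    sample_F,
)


def brute_nondominated(points):
    """O(n^2) oracle: keep p iff no q dominates it."""
    out = []
    for i, p in enumerate(points):
        if not any(
            all(qk <= pk for qk, pk in zip(q, p)) and any(qk < pk for qk, pk in zip(q, p))
            for j, q in enumerate(points)
            if j != i
        ):
            out.append(p)
    return out


def brute_crowding(front):
    """Sort-free reference crowding distance."""
    pts = np.asarray(front, dtype=float)
    n, k = pts.shape
    if n <= 2:
        return np.full(n, np.inf)
    dist = np.zeros(n)
    for j in range(k):
        vals = pts[:, j]
        rng = vals.max() - vals.min()
        for i in range(n):
            below = vals[vals < vals[i]]
            above = vals[vals > vals[i]]
            if below.size == 0 or above.size == 0:
                dist[i] = np.inf
            elif rng > 0 and np.isfinite(dist[i]):
                dist[i] += (above.min() - below.max()) / rng
    return dist


class TestDominance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((1, 2), (1, 3), True),
            ((1, 2), (1, 2), False),
            ((1, 3), (2, 2), False),
            ((2, 2), (1, 3), False),
        ],
    )
    def test_definition(self, a, b, expected):
        assert dominates(a, b) is expected

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            dominates((1, 2), (1, 2, 3))

    @given(
        st.lists(
            st.tuples(st.integers(0, 5), st.integers(0, 5), st.integers(0, 5)),
            min_size=3,
            max_size=12,
        )
    )
    @settings(max_examples=150, deadline=None)
    def test_strict_partial_order(self, pts):
        for a in pts:
            assert not dominates(a, a)  # irreflexive
        for a in pts:
            for b in pts:
                if dominates(a, b):
                    assert not dominates(b, a)  # antisymmetric
                for c in pts:
                    if dominates(a, b) and dominates(b, c):
                        assert dominates(a, c)  # transitive


class TestNondominatedSubset:
    @pytest.mark.parametrize(
        "pts,expected",
        [
            ([(1, 2), (2, 1), (2, 2)], [(1, 2), (2, 1)]),
            ([(1, 1), (1, 1), (1, 1)], [(1, 1), (1, 1), (1, 1)]),
            ([(3,), (1,), (2,)], [(1,)]),
        ],
    )
    def test_known_cases(self, pts, expected):
        assert nondominated_subset(pts) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            nondominated_subset([])

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            k = rng.integers(2, 4)
            pts = [tuple(v) for v in rng.integers(0, 8, size=(rng.integers(2, 40), k))]
            assert nondominated_subset(pts) == brute_nondominated(pts)


class TestCrowdingDistance:
    def test_hand_case(self):
        d = crowding_distance([(0, 2), (1, 1), (2, 0)])
        assert d[0] == np.inf and d[2] == np.inf
        assert d[1] == pytest.approx(2.0)

    def test_small_fronts_all_infinite(self):
        assert np.all(np.isinf(crowding_distance([(1, 2)])))
        assert np.all(np.isinf(crowding_distance([(1, 2), (2, 1)])))

    def test_zero_range_objective_contributes_nothing(self):
        d = crowding_distance([(0, 5), (1, 5), (2, 5), (3, 5)])
        # objective 2 constant: interior distances come from objective 1 only
        assert d[1] == pytest.approx(2 / 3)
        assert d[2] == pytest.approx(2 / 3)

    def test_matches_independent_reimplementation(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            k = rng.integers(2, 4)
            raw = rng.random(size=(rng.integers(3, 25), k))
            front = np.asarray(brute_nondominated([tuple(r) for r in raw]))
            ours = crowding_distance(front)
            ref = brute_crowding(front)
            finite = np.isfinite(ref)
            assert np.array_equal(np.isfinite(ours), finite)
            assert np.allclose(ours[finite], ref[finite], atol=1e-12)


def _ind(objs, pos=None):
    objs = np.asarray(objs, dtype=float)
    if pos is None:
        pos = np.random.default_rng(abs(hash(objs.tobytes())) % 2**31).random(3)
    return Individual(np.asarray(pos, dtype=float), objs)


class TestArchiveInsert:
    def test_empty_archive_accepts_anything(self):
        arc = Archive(capacity=3)
        assert archive_insert(arc, _ind((5, 5)))
        assert len(arc) == 1

    def test_dominating_solution_purges(self):
        arc = Archive(capacity=5)
        archive_insert(arc, _ind((1, 2)))
        archive_insert(arc, _ind((2, 1)))
        assert archive_insert(arc, _ind((0, 0)))
        assert len(arc) == 1
        assert arc.members[0].objectives.tolist() == [0, 0]

    def test_dominated_candidate_rejected(self):
        arc = Archive(capacity=5)
        archive_insert(arc, _ind((1, 1)))
        assert not archive_insert(arc, _ind((2, 2)))
        assert len(arc) == 1

    def test_full_archive_evicts_min_crowding(self):
        arc = Archive(capacity=3)
        for objs in [(0, 4), (4, 0), (2, 2)]:
            archive_insert(arc, _ind(objs))
        # (1.9, 2.2) is mutually nondominated; the enlarged set's most
        # crowded member must leave
        accepted = archive_insert(arc, _ind((1.9, 2.2)))
        assert len(arc) == 3
        assert arc.last_event == "evicted"
        if accepted:
            evicted = arc.last_evicted
            enlarged = [(0, 4), (4, 0), (2, 2), (1.9, 2.2)]
            dist = crowding_distance(enlarged)
            assert tuple(evicted.objectives) == tuple(
                np.asarray(enlarged[int(np.argmin(dist))], dtype=float)
            )

    def test_duplicate_position_rejected(self):
        arc = Archive(capacity=5)
        pos = np.array([0.1, 0.2, 0.3])
        archive_insert(arc, Individual(pos.copy(), np.array([1.0, 1.0])))
        assert not archive_insert(arc, Individual(pos.copy(), np.array([1.0, 1.0])))
        assert len(arc) == 1

    @pytest.mark.parametrize("capacity", [5, 50])
    def test_fuzzed_invariants(self, capacity):
        """Randomized insertions: nondominance, capacity, purge/evict rules."""
        rng = np.random.default_rng(capacity)
        arc = Archive(capacity=capacity)
        for t in range(2500):
            kobj = 2 if capacity == 5 else 3
            s = Individual(rng.random(4), np.floor(rng.random(kobj) * 6))
            before = [m.objectives.copy() for m in arc.members]
            accepted = archive_insert(arc, s)
            objs = [tuple(m.objectives) for m in arc.members]
            assert len(arc) <= capacity
            # pairwise nondominance against the oracle
            assert sorted(map(tuple, nondominated_subset(objs))) == sorted(objs)
            if arc.last_event == "purged":
                assert accepted
                assert not any(
                    dominates(s.objectives, m.objectives) for m in arc.members
                )
            if arc.last_event == "evicted":
                assert arc.last_evicted is not None
                enlarged = before + [s.objectives]
                dist = crowding_distance(enlarged)
                min_d = dist.min()
                evicted_objs = arc.last_evicted.objectives
                matches = [
                    i for i, o in enumerate(enlarged)
                    if np.array_equal(o, evicted_objs)
                ]
                assert any(dist[i] == min_d for i in matches)


class TestAdaptiveParameters:
    def test_F_truncation_and_mean(self):
        rng = np.random.default_rng(0)
        draws = np.array([sample_F(rng) for _ in range(100_000)])
        assert draws.min() > 0 and draws.max() <= 2
        # Monte-Carlo mean of N(0.5, 0.3^2) truncated to (0, 2]
        assert draws.mean() == pytest.approx(0.52, abs=0.02)

    def test_Cr_truncated_by_resampling(self):
        rng = np.random.default_rng(1)
        state = AdaptiveState(cr_mean=0.5)
        draws = np.array([sample_Cr(state, rng) for _ in range(100_000)])
        assert draws.min() >= 0 and draws.max() <= 1
        assert draws.mean() == pytest.approx(0.5, abs=0.01)
        # at the boundary the distribution stays continuous: no point mass
        state0 = AdaptiveState(cr_mean=0.0)
        draws0 = np.array([sample_Cr(state0, rng) for _ in range(10_000)])
        assert (draws0 == 0.0).mean() < 0.01
        assert draws0.mean() > 0.02

    def test_success_pool_and_median_reset(self):
        state = AdaptiveState(cr_mean=0.37)
        for v in (0.2, 0.8, 0.5):
            record_success(state, v)
        assert state.success_pool == [0.2, 0.8, 0.5]
        end_iteration(state)
        assert state.cr_mean == 0.5
        assert state.success_pool == []
        end_iteration(state)  # empty pool: mean unchanged
        assert state.cr_mean == 0.5
        record_success(state, 0.2)
        record_success(state, 0.8)
        end_iteration(state)  # even-size median = midpoint
        assert state.cr_mean == pytest.approx(0.5)


class TestVariationOperators:
    def test_mutation_F_zero_returns_archive_member(self):
        rng = np.random.default_rng(0)
        pop = init_population(5, 4, rng)
        arc = Archive(capacity=2)
        member = Individual(np.full(4, 0.25), np.array([1.0]))
        archive_insert(arc, member)
        donor = mutate_with_archive(pop, arc, 0, F=0.0, rng=rng)
        assert np.allclose(donor, member.position)

    def test_mutation_empty_archive_rejected(self):
        rng = np.random.default_rng(0)
        pop = init_population(5, 4, rng)
        with pytest.raises(ValueError):
            mutate_with_archive(pop, Archive(capacity=2), 0, 0.5, rng)

    def test_crossover_extremes(self):
        rng = np.random.default_rng(0)
        t = np.zeros(10)
        d = np.ones(10)
        assert np.array_equal(binomial_crossover(t, d, 1.0, rng), d)
        trial = binomial_crossover(t, d, 0.0, rng)
        assert trial.sum() == 1  # exactly the forced component
        assert np.array_equal(binomial_crossover(np.zeros(1), np.ones(1), 0.0, rng),
                              np.ones(1))

    def test_repair_bounds(self):
        assert np.allclose(repair_bounds(np.array([-0.2, 0.5, 1.7])), [0, 0.5, 1])
        v = np.array([0.1, 0.9])
        assert np.array_equal(repair_bounds(v), v)
        assert np.allclose(repair_bounds(np.array([-1.0, -2.0])), [0, 0])


class TestMoSelect:
    def test_dominance_cases(self):
        arc = Archive(capacity=4)
        target = _ind((2, 2), pos=[0.1, 0.1, 0.1])
        trial = _ind((1, 1), pos=[0.9, 0.9, 0.9])
        survivor, replaced = mo_select(target, trial, arc)
        assert survivor is trial and replaced
        survivor, replaced = mo_select(trial, _ind((3, 3)), arc)
        assert survivor is trial and not replaced

    def test_nondominated_trial_follows_archive_verdict(self):
        arc = Archive(capacity=4)
        archive_insert(arc, _ind((0, 0), pos=[0.5, 0.5, 0.5]))
        target = _ind((1, 3), pos=[0.2, 0.2, 0.2])
        trial = _ind((3, 1), pos=[0.7, 0.7, 0.7])  # dominated by (0,0) in archive
        survivor, replaced = mo_select(target, trial, arc)
        assert survivor is target and not replaced


class TestRunMode:
    def _toy(self, x):
        return np.array([x.sum(), (1 - x).sum()])

    def test_determinism(self):
        cfg = ms.RunConfig(NP=10, Na=20, Ite=20, seed=3)
        a = ms.run_mode(self._toy, 4, cfg)
        b = ms.run_mode(self._toy, 4, cfg)
        assert len(a) == len(b)
        for ma, mb in zip(a.members, b.members):
            assert np.array_equal(ma.position, mb.position)
            assert np.array_equal(ma.objectives, mb.objectives)

    def test_archive_seeded_with_initial_front(self):
        calls = []

        def probe(x):
            calls.append(x.copy())
            return np.array([x.sum(), (1 - x).sum()])

        cfg = ms.RunConfig(NP=8, Na=50, Ite=1, seed=5)
        ms.run_mode(probe, 3, cfg)
        initial = [tuple(probe_call) for probe_call in calls[:8]]
        assert len(initial) == 8  # every initial individual evaluated

    def test_constant_objective_no_crash(self):
        cfg = ms.RunConfig(NP=6, Na=5, Ite=10, seed=0)
        arc = ms.run_mode(lambda x: np.array([1.0, 1.0]), 3, cfg)
        assert 1 <= len(arc) <= 5
        positions = [tuple(m.position) for m in arc.members]
        assert len(set(positions)) == len(positions)  # distinct representatives

    def test_toy_front_improves(self):
        cfg = ms.RunConfig(NP=20, Na=50, Ite=50, seed=1)
        logger = IterationLogger(keep_fronts=True)
        arc = ms.run_mode(self._toy, 5, cfg, logger=logger)
        objs = arc.objective_matrix()
        # f1 + f2 == M on every archive member (the whole simplex is the front)
        assert np.allclose(objs.sum(axis=1), 5.0)
        assert objs[:, 0].max() - objs[:, 0].min() > 0.8 * 5.0


class TestRunDeSingle:
    def test_greedy_monotone_and_elite_capacity(self):
        cfg = ms.RunConfig(NP=10, Na=6, Ite=30, seed=2)
        logger = IterationLogger()
        best, elite = ms.run_de_single(lambda x: float(x[0]), 1, cfg, logger=logger)
        assert len(elite) <= 6
        fits = [r["f1_min"] for r in logger.rows]
        assert all(b <= a + 1e-12 for a, b in zip(fits, fits[1:]))
        worst = max(e.objectives[0] for e in elite)
        assert best.objectives[0] <= worst
        assert best.objectives[0] == pytest.approx(0.0, abs=0.05)

    def test_single_objective_agreement_with_greedy_dominance(self):
        # with one objective, Pareto dominance is the greedy order
        assert dominates((1.0,), (2.0,))
        assert not dominates((2.0,), (1.0,))
        assert not dominates((1.0,), (1.0,))
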