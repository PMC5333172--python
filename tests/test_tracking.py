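"""Trajectory reconstruction: vicinity, matching, rebirths, lifetimes,
core sites and neighbour classes.

The multi-generation histories here are hand-constructed; expected
event labels and lifetimes were enumerated by hand from the matching
rules (vicinity = three site lengths containing the site).
"""

import numpy as np
import pytest

from regevo.annotation import TFBS
from regevo.tracking import (
    classify_neighbors,
    classify_rebirths,
    core_sites,
    fixed_coordinate_core,
    lifetimes,
    step_match,
    track_individuals,
    trajectory_table,
    vicinity,
)

from oracles import optimal_assignment_oracle


def S(start, tf="A", locus="hb", length=10, strand="+", E=5.0):
    return TFBS(tf, locus, start, length, strand, E)


class TestVicinity:
    def test_three_site_lengths_containing_the_site(self):
        assert vicinity(S(100)) == (90, 120)

    def test_clipped_at_locus_start(self):
        assert vicinity(S(0)) == (0, 20)

    def test_clipped_at_locus_end(self):
        assert vicinity(S(95, length=10), locus_length=100) == (85, 100)

    @pytest.mark.parametrize("start,L", [(50, 6), (200, 12), (30, 8)])
    def test_unclipped_length_is_3L(self, start, L):
        a, b = vicinity(S(start, length=L))
        assert b - a == 3 * L


class TestStepMatch:
    def test_identical_annotations_all_persist(self):
        sites = [S(10), S(40, tf="B"), S(90)]
        ev = step_match(sites, sites)
        assert len(ev.persists) == 3
        assert not ev.moves and not ev.deaths and not ev.births

    def test_move_within_vicinity(self):
        ev = step_match([S(100)], [S(110)])
        assert ev.moves == [(0, 0)] and not ev.deaths and not ev.births

    def test_distant_site_is_death_plus_birth(self):
        ev = step_match([S(100)], [S(150)])
        assert ev.deaths == [0] and ev.births == [0] and not ev.moves

    def test_different_tf_never_matches(self):
        ev = step_match([S(100, tf="A")], [S(105, tf="B")])
        assert ev.deaths == [0] and ev.births == [0]

    def test_nearest_candidate_wins_with_low_coordinate_tiebreak(self):
        old = [S(100)]
        new = [S(92), S(108)]  # equidistant -> smaller coordinate
        ev = step_match(old, new)
        assert ev.moves == [(0, 0)]
        assert ev.births == [1]

    def test_counts_conserved(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            old = [
                S(int(rng.integers(0, 400)), tf=f"T{rng.integers(2)}")
                for _ in range(rng.integers(0, 8))
            ]
            new = [
                S(int(rng.integers(0, 400)), tf=f"T{rng.integers(2)}")
                for _ in range(rng.integers(0, 8))
            ]
            # drop accidental duplicates
            old = list({s.key(): s for s in old}.values())
            new = list({s.key(): s for s in new}.values())
            ev = step_match(old, new)
            assert len(old) == len(ev.persists) + len(ev.moves) + len(ev.deaths)
            assert len(new) == len(ev.persists) + len(ev.moves) + len(ev.births)

    @pytest.mark.parametrize("seed", range(10))
    def test_greedy_matches_optimal_assignment(self, seed):
        """On small random histories the greedy matcher agrees with the
        exhaustive minimum-displacement assignment."""
        rng = np.random.default_rng(100 + seed)
        starts = rng.choice(np.arange(0, 300, 7), size=6, replace=False)
        old = [S(int(s)) for s in sorted(starts[:3])]
        new = [S(int(s + rng.integers(-12, 13))) for s in sorted(starts[3:])]
        new = list({s.key(): s for s in new}.values())
        ev = step_match(old, new)
        pe, mo, de, bi = optimal_assignment_oracle(old, new, vicinity)
        assert set(ev.persists) == pe
        assert len(ev.moves) == len(mo)
        assert set(ev.deaths) == de
        assert len(ev.births) == len(bi)


def run_history(history):
    return track_individuals(history)


class TestHistories:
    """Hand-enumerated multi-generation histories (>= 10 cases)."""

    def test_steady_persistence(self):
        h = [[S(10)], [S(10)], [S(10)]]
        trajs = run_history(h)
        assert len(trajs) == 1
        t = trajs[0]
        assert t.origin == "initial" and t.alive and t.moves == 0
        assert lifetimes(trajs, 2) == [(2, True)]

    def test_single_move_then_persist(self):
        h = [[S(100)], [S(108)], [S(108)]]
        t = run_history(h)[0]
        assert t.moves == 1 and t.alive and t.starts == [100, 108, 108]

    def test_death_without_successor(self):
        h = [[S(100)], [], []]
        trajs = run_history(h)
        assert trajs[0].death_generation == 1
        assert lifetimes(trajs, 2) == [(1, False)]

    def test_birth_far_from_wildtype(self):
        h = [[S(10)], [S(10), S(300)], [S(10), S(300)]]
        trajs = run_history(h)
        assert len(trajs) == 2
        assert trajs[1].origin == "born" and trajs[1].origin_generation == 1

    def test_rebirth_at_dead_wildtype_coordinates(self):
        h = [[S(100)], [], [S(100)]]
        trajs = run_history(h)
        assert trajs[0].death_generation == 1
        assert trajs[1].origin == "rebirth" and trajs[1].rebirth_of == 0
        assert trajs[1].origin_generation == 2

    def test_rebirth_in_vicinity_not_exact(self):
        h = [[S(100)], [], [S(112)]]  # 112 within [90,120)
        trajs = run_history(h)
        assert trajs[1].origin == "rebirth" and trajs[1].rebirth_of == 0

    def test_birth_near_living_wildtype_is_plain_birth(self):
        # wild-type site alive: a second site in its vicinity is a birth
        h = [[S(100)], [S(100), S(112, strand="-")], [S(100), S(112, strand="-")]]
        trajs = run_history(h)
        assert trajs[0].alive
        assert trajs[1].origin == "born" and trajs[1].rebirth_of is None

    def test_rebirth_does_not_resurrect_lifetime(self):
        h = [[S(100)], [], [S(100)], [S(100)]]
        trajs = run_history(h)
        lt = dict(zip(range(len(trajs)), lifetimes(trajs, 3)))
        assert lt[0] == (1, False)   # original: died at g=1
        assert lt[1] == (1, True)    # rebirth lineage: g=2..3, censored

    def test_two_sites_swap_distances_deterministically(self):
        # two same-TF sites move; each matched to its nearest candidate
        h = [[S(100), S(140)], [S(104), S(136)]]
        trajs = run_history(h)
        assert trajs[0].starts == [100, 104]
        assert trajs[1].starts == [140, 136]
        assert all(t.moves == 1 for t in trajs)

    def test_move_chain_across_generations(self):
        h = [[S(100)], [S(110)], [S(120)], [S(130)]]
        t = run_history(h)[0]
        assert t.alive and t.moves == 3 and t.starts == [100, 110, 120, 130]

    def test_interleaved_death_birth_different_tf(self):
        h = [
            [S(100, tf="A"), S(200, tf="B")],
            [S(205, tf="B")],
            [S(205, tf="B"), S(101, tf="A")],
        ]
        trajs = run_history(h)
        a = next(t for t in trajs if t.tf == "A" and t.origin == "initial")
        b = next(t for t in trajs if t.tf == "B")
        r = next(t for t in trajs if t.tf == "A" and t.origin != "initial")
        assert a.death_generation == 1
        assert b.alive and b.moves == 1
        assert r.origin == "rebirth" and r.rebirth_of == trajs.index(a)

    def test_cross_locus_sites_never_interact(self):
        h = [
            [S(100, locus="hb"), S(100, locus="Kr")],
            [S(100, locus="hb")],
            [S(100, locus="hb"), S(104, locus="Kr")],
        ]
        trajs = run_history(h)
        kr = [t for t in trajs if t.locus == "Kr"]
        assert kr[0].death_generation == 1
        assert kr[1].origin == "rebirth" and kr[1].rebirth_of == 1

    def test_exact_match_beats_move(self):
        # a persisting site is never stolen as a move target
        h = [[S(100), S(110)], [S(110)]]
        trajs = run_history(h)
        assert trajs[0].death_generation == 1
        assert trajs[1].alive and trajs[1].moves == 0


class TestClassifyRebirths:
    def test_no_same_tf_wildtype_on_locus(self):
        out = classify_rebirths([S(50, tf="Z")], [S(100, tf="A")], {0})
        assert out == [None]

    def test_only_dead_wildtype_eligible(self):
        wt = [S(100), S(300)]
        out = classify_rebirths([S(102)], wt, set())
        assert out == [None]
        out = classify_rebirths([S(102)], wt, {0})
        assert out == [0]


class TestCoreAndNeighbors:
    def make_trajs(self):
        G = 4
        h = [
            [S(100), S(130), S(400, tf="B"), S(107, tf="B", E=2.0)],
            [S(100), S(130), S(400, tf="B"), S(107, tf="B", E=2.0)],
            [S(100), S(400, tf="B")],
            [S(100), S(400, tf="B")],
            [S(100), S(400, tf="B")],
        ]
        return run_history(h), G

    def test_core_extraction(self):
        trajs, G = self.make_trajs()
        core = core_sites(trajs, G)
        assert core == [0, 2]
        assert fixed_coordinate_core(trajs, G) == [0, 2]

    def test_initial_but_dead_not_core(self):
        trajs, G = self.make_trajs()
        assert 1 not in core_sites(trajs, G)

    def test_neighbor_classes_with_precedence(self):
        trajs, G = self.make_trajs()
        core = core_sites(trajs, G)
        cls = classify_neighbors(core, trajs, coop_range=50)
        # traj 1: same TF, 20 bp from core site at 100 -> cooperative
        assert cls[1] == "cooperative"
        # traj 3: different TF overlapping core site -> overlapping
        assert cls[3] == "overlapping"

    def test_cooperative_precedence_over_overlap(self):
        G = 2
        h = [
            [S(100), S(105), S(100, tf="B", strand="-")],
            [S(100), S(105), S(100, tf="B", strand="-")],
            [S(100), S(105), S(100, tf="B", strand="-")],
        ]
        trajs = run_history(h)
        core = core_sites(trajs, G)
        cls = classify_neighbors([c for c in core if c == 0], trajs, coop_range=50)
        # same-TF site overlapping a core site is cooperative, not overlapping
        assert cls[1] == "cooperative"
        assert cls[2] == "overlapping"

    def test_trajectory_table_shape(self):
        trajs, G = self.make_trajs()
        df = trajectory_table(trajs, G)
        assert len(df) == len(trajs)
        assert set(df.columns) >= {
            "tf", "locus", "origin", "lifetime", "censored", "core", "neighbor_class",
        }
        assert df["core"].sum() == 2


class TestLifetimes:
    def test_born_then_died(self):
        h = [[], [], [], [], [], [S(10)]] + [[S(10)]] * 6 + [[]]
        # born at g=5, died at g=12
        trajs = run_history(h)
        assert trajs[0].origin_generation == 5
        assert trajs[0].death_generation == 12
        assert lifetimes(trajs, 13)[0] == (7, False)

    def test_initial_survivor_censored_at_G(self):
        G = 9
        h = [[S(10)]] * (G + 1)
        assert lifetimes(run_history(h), G) == [(G, True)]


class TestMoveMode:
    def test_start_mode_requires_start_inside_vicinity(self):
        # old site vicinity is [90, 120)
        old = [S(100, length=10)]
        # candidate interval [112, 122) overlaps the window and also
        # starts inside it: a move under both readings
        assert step_match(old, [S(112)], move_mode="overlap").moves == [(0, 0)]
        assert step_match(old, [S(112)], move_mode="start").moves == [(0, 0)]
        # candidate [119, 129) overlaps but its start 119 is still inside
        assert step_match(old, [S(119)], move_mode="start").moves == [(0, 0)]
        # candidate [85, 95) overlaps the window but starts before it:
        # move under 'overlap', death + birth under 'start'
        cand = [S(85)]
        assert step_match(old, cand, move_mode="overlap").moves == [(0, 0)]
        ev = step_match(old, cand, move_mode="start")
        assert ev.deaths == [0] and ev.births == [0]

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="move_mode"):
            step_match([], [], move_mode="nearest")
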