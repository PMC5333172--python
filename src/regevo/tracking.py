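"""TFBS trajectory reconstruction across generations.

Between consecutive generations of the tracked individual, sites are
matched by identity first (same tf, start, length, strand -> persist),
then greedily by proximity: an unmatched old site S moved if an
unmatched new site of the same factor overlaps the vicinity of S -- the
window three times the site length, flanking and containing it,
``[start - L, start + 2L)``.  Old sites with no match died; new sites
with no match are births.  A birth overlapping the vicinity of the
wild-type (generation-0) coordinates of a same-factor site whose
trajectory is currently dead is a rebirth; it starts a new trajectory
that carries a link to the wild-type site but does not extend the old
trajectory's lifetime.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotation import TFBS

Interval = tuple[int, int]


def vicinity(site: TFBS, locus_length: int | None = None) -> Interval:
    """Window of three site lengths centred on the site, clipped."""
    L = site.length
    a = site.start - L
    b = site.start + 2 * L
    if locus_length is not None:
        b = min(b, locus_length)
    return (max(0, a), b)


# ---------------------------------------------------------------------------
# Step matching


@dataclass
class StepEvents:
    """One-to-one assignment between two consecutive annotations.

    ``persists`` and ``moves`` are (old_index, new_index) pairs;
    ``deaths`` old indices; ``births`` new indices.  Counts are
    conserved: len(old) = persists + moves + deaths and
    len(new) = persists + moves + births.
    """

    persists: list[tuple[int, int]] = field(default_factory=list)
    moves: list[tuple[int, int]] = field(default_factory=list)
    deaths: list[int] = field(default_factory=list)
    births: list[int] = field(default_factory=list)


def step_match(
    old_sites: Sequence[TFBS],
    new_sites: Sequence[TFBS],
    move_mode: str = "overlap",
) -> StepEvents:
    """Classify persist / move / death / birth between two generations.

    Greedy move matching processes unmatched old sites in coordinate
    order; each takes the nearest (by start distance, ties to the
    smaller coordinate) unmatched same-factor new site counted as
    "within the vicinity" of the old site.  ``move_mode`` chooses the
    reading of that phrase: 'overlap' (default) accepts a candidate
    whose interval overlaps the vicinity window; 'start' requires the
    candidate's start coordinate to lie inside it.
    """
    if move_mode not in ("overlap", "start"):
        raise ValueError("move_mode must be 'overlap' or 'start'")
    ev = StepEvents()
    new_free = set(range(len(new_sites)))
    # pass 1: exact identity
    new_by_key: dict[tuple, int] = {}
    for j, s in enumerate(new_sites):
        new_by_key[(s.tf, s.locus, s.start, s.length, s.strand)] = j
    old_free = []
    for i, s in enumerate(old_sites):
        j = new_by_key.get((s.tf, s.locus, s.start, s.length, s.strand))
        if j is not None and j in new_free:
            ev.persists.append((i, j))
            new_free.discard(j)
        else:
            old_free.append(i)
    # pass 2: greedy vicinity moves
    old_free.sort(key=lambda i: (old_sites[i].locus, old_sites[i].start))
    for i in old_free:
        s = old_sites[i]
        va, vb = vicinity(s)
        best = None
        for j in new_free:
            t = new_sites[j]
            if t.tf != s.tf or t.locus != s.locus:
                continue
            if move_mode == "overlap":
                if not (t.start < vb and va < t.end):
                    continue
            elif not (va <= t.start < vb):
                continue
            cand = (abs(t.start - s.start), t.start, j)
            if best is None or cand < best:
                best = cand
        if best is None:
            ev.deaths.append(i)
        else:
            j = best[2]
            ev.moves.append((i, j))
            new_free.discard(j)
    ev.births = sorted(new_free)
    return ev


# ---------------------------------------------------------------------------
# Trajectories


@dataclass
class Trajectory:
    """One tracked TFBS lineage.

    ``origin`` is 'initial', 'born' or 'rebirth'; a rebirth links (via
    ``rebirth_of``) to the index of the wild-type trajectory whose
    vicinity it appeared in.  ``starts``/``strands``/``energies`` hold
    one entry per generation of the contiguous life span
    ``origin_generation .. death_generation-1`` (or through the final
    generation when still alive).
    """

    tf: str
    locus: str
    length: int
    origin: str
    origin_generation: int
    rebirth_of: int | None = None
    starts: list[int] = field(default_factory=list)
    strands: list[str] = field(default_factory=list)
    energies: list[float] = field(default_factory=list)
    death_generation: int | None = None
    moves: int = 0

    @property
    def alive(self) -> bool:
        return self.death_generation is None

    @property
    def E_wt(self) -> float:
        """Energy at the trajectory's first generation."""
        return self.energies[0]

    def coordinate_at(self, generation: int) -> tuple[int, str] | None:
        k = generation - self.origin_generation
        if k < 0 or k >= len(self.starts):
            return None
        return self.starts[k], self.strands[k]

    def interval_at(self, generation: int) -> Interval | None:
        c = self.coordinate_at(generation)
        if c is None:
            return None
        return (c[0], c[0] + self.length)

    def alive_at(self, generation: int) -> bool:
        return self.coordinate_at(generation) is not None


def classify_rebirths(
    births: Sequence[TFBS],
    wildtype_sites: Sequence[TFBS],
    dead_wt_ids: set[int],
) -> list[int | None]:
    """For each birth, the wild-type site id it rebinds, or None.

    A birth is a rebirth when it overlaps the vicinity of the wild-type
    coordinates of a same-factor site whose initial trajectory is
    currently dead; the nearest such site wins.
    """
    out: list[int | None] = []
    for b in births:
        best = None
        for wid in dead_wt_ids:
            w = wildtype_sites[wid]
            if w.tf != b.tf or w.locus != b.locus:
                continue
            va, vb = vicinity(w)
            if b.start < vb and va < b.end:
                cand = (abs(b.start - w.start), w.start, wid)
                if best is None or cand < best:
                    best = cand
        out.append(None if best is None else best[2])
    return out


def track_individuals(
    tracked_annotations: Sequence[Sequence[TFBS]],
) -> list[Trajectory]:
    """Reconstruct all trajectories from the per-generation tracked sites.

    ``tracked_annotations[g]`` is the site list of the tracked
    individual at generation g (generation 0 = wild type).  Trajectory
    index order: the generation-0 sites first (these are the wild-type
    trajectories rebirths link to), then births in order of appearance.
    """
    gens = list(tracked_annotations)
    if not gens:
        return []
    trajs: list[Trajectory] = []
    wt_sites = list(gens[0])
    active: dict[int, int] = {}  # current site index -> trajectory index
    for i, s in enumerate(wt_sites):
        trajs.append(
            Trajectory(
                tf=s.tf,
                locus=s.locus,
                length=s.length,
                origin="initial",
                origin_generation=0,
                starts=[s.start],
                strands=[s.strand],
                energies=[s.E],
            )
        )
        active[i] = i

    for g in range(1, len(gens)):
        old, new = list(gens[g - 1]), list(gens[g])
        ev = step_match(old, new)
        next_active: dict[int, int] = {}
        for i, j in ev.persists + ev.moves:
            t = trajs[active[i]]
            t.starts.append(new[j].start)
            t.strands.append(new[j].strand)
            t.energies.append(new[j].E)
            next_active[j] = active[i]
        for _, j in ev.moves:
            trajs[next_active[j]].moves += 1
        for i in ev.deaths:
            trajs[active[i]].death_generation = g
        # rebirth bookkeeping against currently dead wild-type lineages
        dead_wt = {
            wid
            for wid in range(len(wt_sites))
            if trajs[wid].death_generation is not None
        }
        links = classify_rebirths([new[j] for j in ev.births], wt_sites, dead_wt)
        for j, link in zip(ev.births, links):
            s = new[j]
            trajs.append(
                Trajectory(
                    tf=s.tf,
                    locus=s.locus,
                    length=s.length,
                    origin="rebirth" if link is not None else "born",
                    origin_generation=g,
                    rebirth_of=link,
                    starts=[s.start],
                    strands=[s.strand],
                    energies=[s.E],
                )
            )
            next_active[j] = len(trajs) - 1
        active = next_active
    return trajs


# ---------------------------------------------------------------------------
# Lifetimes and site classes


def lifetimes(
    trajectories: Sequence[Trajectory], n_generations: int
) -> list[tuple[int, bool]]:
    """(lifetime, censored) per trajectory.

    Lifetime is death - origin generation; lineages alive at the end of
    the run are right-censored at ``n_generations - origin``.
    """
    out = []
    for t in trajectories:
        if t.death_generation is None:
            out.append((n_generations - t.origin_generation, True))
        else:
            out.append((t.death_generation - t.origin_generation, False))
    return out


def core_sites(
    trajectories: Sequence[Trajectory], n_generations: int
) -> list[int]:
    """Indices of core trajectories: initial sites alive at every
    generation 0..n_generations (moves allowed)."""
    return [
        i
        for i, t in enumerate(trajectories)
        if t.origin == "initial"
        and t.death_generation is None
        and len(t.starts) >= n_generations + 1
    ]


def fixed_coordinate_core(
    trajectories: Sequence[Trajectory], n_generations: int
) -> list[int]:
    """The subset of core trajectories that never moved at all."""
    return [
        i
        for i in core_sites(trajectories, n_generations)
        if len(set(trajectories[i].starts)) == 1
    ]


def _edge_distance(a: Interval, b: Interval) -> int:
    if a[0] < b[1] and b[0] < a[1]:
        return 0
    return b[0] - a[1] if b[0] >= a[1] else a[0] - b[1]


def classify_neighbors(
    core: Sequence[int],
    trajectories: Sequence[Trajectory],
    coop_range: int = 50,
) -> dict[int, str]:
    """Classify non-core trajectories relative to the core sites.

    'cooperative': same factor, within ``coop_range`` bp (edge-to-edge)
    of at least one core site; 'overlapping': interval intersects a core
    site's (and not cooperative); 'other' otherwise.  Cooperative takes
    precedence.  Intervals are compared at the non-core trajectory's
    origin generation, where the core site is guaranteed alive.
    """
    core_set = set(core)
    out: dict[int, str] = {}
    for i, t in enumerate(trajectories):
        if i in core_set:
            continue
        g0 = t.origin_generation
        iv = (t.starts[0], t.starts[0] + t.length)
        label = "other"
        overlaps = False
        for c in core:
            civ = trajectories[c].interval_at(g0)
            if civ is None:
                continue
            same_locus = trajectories[c].locus == t.locus
            if not same_locus:
                continue
            d = _edge_distance(iv, civ)
            if trajectories[c].tf == t.tf and d <= coop_range:
                label = "cooperative"
                break
            if d == 0:
                overlaps = True
        if label != "cooperative" and overlaps:
            label = "overlapping"
        out[i] = label
    return out


def trajectory_table(
    trajectories: Sequence[Trajectory], n_generations: int, coop_range: int = 50
):
    """Tidy per-trajectory summary (one row per lineage)."""
    import pandas as pd

    core = core_sites(trajectories, n_generations)
    neighbor = classify_neighbors(core, trajectories, coop_range)
    lt = lifetimes(trajectories, n_generations)
    rows = []
    for i, t in enumerate(trajectories):
        rows.append(
            {
                "trajectory": i,
                "tf": t.tf,
                "locus": t.locus,
                "origin": t.origin,
                "origin_generation": t.origin_generation,
                "rebirth_of": t.rebirth_of if t.rebirth_of is not None else -1,
                "death_generation": (
                    t.death_generation if t.death_generation is not None else -1
                ),
                "lifetime": lt[i][0],
                "censored": lt[i][1],
                "moves": t.moves,
                "E_wt": t.E_wt,
                "core": i in set(core),
                "neighbor_class": neighbor.get(i, "core"),
            }
        )
    return pd.DataFrame(rows)
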