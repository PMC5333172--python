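"""Summary statistics over evolution records and trajectories.

Implements the figure-level quantities of the study: coarse-grained
per-bin binding energies and their dE, per-set energy dynamics and CVs,
low/high-energy site ratios, affinity-set and generation correlation
matrices, bootstrapped two-sample Kolmogorov-Smirnov tests, rms/energy
correlations per epoch, and single-site knockout score distributions.
Pearson correlation is used throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import SiteAnnotation, TFBS
from .expression import ExpressionState, ModelParams, TimeGrid, knockout_scores
from .tracking import Trajectory, classify_neighbors, core_sites

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Containers


@dataclass
class BinProfile:
    """Per-bin binding energy (score units per bp) for one or more
    generations; bins of fixed width tile each locus, a site straddling
    a bin edge is assigned to the bin containing its start."""

    locus_lengths: Mapping[str, int]
    bin_width: int
    E_bin: np.ndarray  # (n_generations, n_bins) or (n_bins,)
    bin_labels: list[tuple[str, int]]  # (locus, bin start)

    @property
    def n_bins(self) -> int:
        return len(self.bin_labels)

    def dE(self) -> np.ndarray:
        """dE_bin = E_bin(g) - E_bin(generation 0)."""
        E = np.atleast_2d(self.E_bin)
        return E - E[0]


@dataclass
class CorrelationMatrix:
    labels: list
    matrix: np.ndarray
    n: np.ndarray | None = None


@dataclass
class KSResult:
    statistic: float
    p_value: float
    n_boot: int


# ---------------------------------------------------------------------------
# Bin energies


def _bin_edges(length: int, bin_width: int) -> np.ndarray:
    return np.arange(0, length, bin_width)


def bin_energy(
    sites: SiteAnnotation | Sequence[TFBS],
    locus_lengths: Mapping[str, int],
    bin_width: int = 180,
) -> BinProfile:
    """Summed site energy per bin, normalised by the bin's length.

    The trailing bin of a locus may be shorter than ``bin_width``; its
    own length is used for normalisation so E_bin is per bp everywhere.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    labels: list[tuple[str, int]] = []
    widths: list[int] = []
    offsets: dict[str, int] = {}
    for locus, L in locus_lengths.items():
        offsets[locus] = len(labels)
        for start in _bin_edges(L, bin_width):
            labels.append((locus, int(start)))
            widths.append(min(bin_width, L - start))
    E = np.zeros(len(labels))
    for s in sites:
        if s.locus not in offsets:
            continue
        b = offsets[s.locus] + s.start // bin_width
        E[b] += s.E
    E /= np.asarray(widths, dtype=float)
    return BinProfile(dict(locus_lengths), bin_width, E, labels)


def bin_energy_dynamics(
    records, locus_lengths: Mapping[str, int], bin_width: int = 180
) -> BinProfile:
    """Elite-averaged E_bin per generation, stacked (G+1, n_bins)."""
    rows = []
    labels = None
    for rec in records:
        profs = [
            bin_energy(sites, locus_lengths, bin_width) for sites in rec.elite_sites
        ]
        labels = profs[0].bin_labels
        rows.append(np.mean([p.E_bin for p in profs], axis=0))
    return BinProfile(dict(locus_lengths), bin_width, np.array(rows), labels)


# ---------------------------------------------------------------------------
# Energy dynamics per site set


def _is_new(site: TFBS, founder_keys: set) -> bool:
    return site.key() not in founder_keys


def energy_dynamics(
    records,
    selector: str = "all",
    trajectories: Sequence[Trajectory] | None = None,
) -> pd.DataFrame:
    """Per-generation mean E and CV (SD/mean) for a set of sites.

    ``selector``: 'all' or 'new' average across the elite individuals
    of each generation ('new' = sites whose (tf, locus, start, strand)
    is absent from the founder annotation); 'tracked-initial' and
    'core' follow the tracked individual's trajectories.
    """
    n_gen = len(records) - 1
    if selector in ("tracked-initial", "core"):
        if trajectories is None:
            raise ValueError(f"selector {selector!r} requires trajectories")
        if selector == "core":
            idx = core_sites(trajectories, n_gen)
        else:
            idx = [i for i, t in enumerate(trajectories) if t.origin == "initial"]
        rows = []
        for g in range(n_gen + 1):
            es = [
                trajectories[i].energies[g - trajectories[i].origin_generation]
                for i in idx
                if trajectories[i].alive_at(g)
            ]
            rows.append(_mean_cv(g, np.asarray(es)))
        return pd.DataFrame(rows)

    founder_keys = {s.key() for s in records[0].elite_sites[0]}
    rows = []
    for rec in records:
        es = []
        for sites in rec.elite_sites:
            for s in sites:
                if selector == "all" or (
                    selector == "new" and _is_new(s, founder_keys)
                ):
                    es.append(s.E)
        rows.append(_mean_cv(rec.generation, np.asarray(es, dtype=float)))
    return pd.DataFrame(rows)


def _mean_cv(g: int, es: np.ndarray) -> dict:
    if len(es) == 0:
        return {"generation": g, "mean_E": np.nan, "cv": np.nan, "n": 0}
    m = float(es.mean())
    cv = float(es.std() / m) if m != 0 else np.nan
    return {"generation": g, "mean_E": m, "cv": cv, "n": len(es)}


def low_high_ratio(
    energy_lists: Sequence[Sequence[float]], threshold: float = 4.0
) -> np.ndarray:
    """Per-generation (#E < threshold) / (#E >= threshold); NaN when the
    denominator is zero."""
    out = np.empty(len(energy_lists))
    for g, es in enumerate(energy_lists):
        es = np.asarray(list(es), dtype=float)
        hi = int((es >= threshold).sum())
        lo = len(es) - hi
        out[g] = np.nan if hi == 0 else lo / hi
    return out


# ---------------------------------------------------------------------------
# Correlation matrices


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def affinity_set_correlation(
    trajectories: Sequence[Trajectory],
    n_generations: int,
    n_sets: int = 35,
) -> CorrelationMatrix:
    """Correlations between temporal mean-E profiles of affinity sets.

    Initial-origin trajectories are ranked by wild-type energy and split
    into ``n_sets`` near-equal contiguous sets (remainders fill the
    leading, lowest-affinity sets).  Per generation each set averages E
    over its alive members; set pairs are correlated across generations
    on jointly defined entries.
    """
    initial = [t for t in trajectories if t.origin == "initial"]
    if len(initial) < n_sets:
        raise ValueError(
            f"need at least n_sets={n_sets} initial trajectories, have {len(initial)}"
        )
    order = sorted(range(len(initial)), key=lambda i: (initial[i].E_wt, i))
    base, rem = divmod(len(initial), n_sets)
    sizes = [base + (1 if k < rem else 0) for k in range(n_sets)]
    series = np.full((n_sets, n_generations + 1), np.nan)
    pos = 0
    for k, size in enumerate(sizes):
        members = [initial[i] for i in order[pos : pos + size]]
        pos += size
        for g in range(n_generations + 1):
            es = [
                t.energies[g - t.origin_generation] for t in members if t.alive_at(g)
            ]
            if es:
                series[k, g] = np.mean(es)
    mat = np.full((n_sets, n_sets), np.nan)
    nmat = np.zeros((n_sets, n_sets), dtype=int)
    for a in range(n_sets):
        for b in range(a, n_sets):
            joint = ~np.isnan(series[a]) & ~np.isnan(series[b])
            nmat[a, b] = nmat[b, a] = int(joint.sum())
            r = _pearson(series[a][joint], series[b][joint])
            mat[a, b] = mat[b, a] = r
    return CorrelationMatrix(list(range(1, n_sets + 1)), mat, nmat)


def generation_correlation(profile: BinProfile) -> CorrelationMatrix:
    """G x G Pearson matrix of E_bin vectors across bins."""
    E = np.atleast_2d(profile.E_bin)
    G = E.shape[0]
    sd = E.std(axis=1)
    with np.errstate(invalid="ignore"):
        mat = np.corrcoef(E)
    mat = np.asarray(mat, dtype=float)
    mat[sd == 0, :] = np.nan
    mat[:, sd == 0] = np.nan
    return CorrelationMatrix(list(range(G)), mat)


# ---------------------------------------------------------------------------
# Bootstrapped Kolmogorov-Smirnov test


def ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample KS statistic: sup distance of the empirical CDFs."""
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    z = np.concatenate([a, b])
    ca = np.searchsorted(a, z, side="right") / len(a)
    cb = np.searchsorted(b, z, side="right") / len(b)
    return float(np.abs(ca - cb).max())


def ks_bootstrap(
    sample_a,
    sample_b,
    n_boot: int = 999,
    rng: np.random.Generator | int | None = None,
) -> KSResult:
    """Bootstrapped two-sample KS test.

    The null distribution pools both samples and redraws two samples of
    the original sizes with replacement; the p-value uses the +1
    correction ``p = (1 + #{boot >= observed}) / (n_boot + 1)``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    na, nb = len(a), len(b)
    obs = ks_statistic(a, b)
    pooled = np.concatenate([a, b])
    idx = rng.integers(0, na + nb, size=(n_boot, na + nb))
    boot = np.empty(n_boot)
    for k in range(n_boot):
        z = pooled[idx[k]]
        boot[k] = ks_statistic(z[:na], z[na:])
    p = (1 + int((boot >= obs - 1e-12).sum())) / (n_boot + 1)
    return KSResult(obs, float(p), n_boot)


# ---------------------------------------------------------------------------
# rms-score / energy correlations


def rms_energy_correlation(
    records,
    selector: str = "all",
    trajectories: Sequence[Trajectory] | None = None,
    epoch_bounds: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Per-epoch Pearson correlation between the generation mean
    rms-score of individuals and the generation mean E of a site set.

    Epoch boundaries default to thirds of the run.  A constant series
    within an epoch yields a NaN correlation, flagged in 'defined'.
    """
    mean_F = np.array([rec.F_all.mean() for rec in records])
    ed = energy_dynamics(records, selector, trajectories)
    mean_E = ed["mean_E"].to_numpy()
    G = len(records)
    if epoch_bounds is None:
        epoch_bounds = [0, G // 3, 2 * G // 3, G]
    rows = []
    for e in range(len(epoch_bounds) - 1):
        sl = slice(epoch_bounds[e], epoch_bounds[e + 1])
        x, y = mean_F[sl], mean_E[sl]
        ok = ~np.isnan(x) & ~np.isnan(y)
        r = _pearson(x[ok], y[ok])
        rows.append(
            {
                "epoch": e,
                "start": epoch_bounds[e],
                "stop": epoch_bounds[e + 1],
                "pearson_r": r,
                "n": int(ok.sum()),
                "defined": not np.isnan(r),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Knockout score distributions


def site_groups_from_tracking(
    trajectories: Sequence[Trajectory], n_generations: int, coop_range: int = 50
) -> dict[str, set]:
    """Founder-site keys per group: core / cooperative / overlapping /
    non-core, derived from the tracked trajectories."""
    core = core_sites(trajectories, n_generations)
    neighbor = classify_neighbors(core, trajectories, coop_range)

    def key_of(t: Trajectory):
        return (t.tf, t.locus, t.starts[0], t.strands[0])

    initial = [
        (i, t) for i, t in enumerate(trajectories) if t.origin == "initial"
    ]
    groups: dict[str, set] = {
        "core": set(),
        "cooperative": set(),
        "overlapping": set(),
        "non-core": set(),
    }
    core_set = set(core)
    for i, t in initial:
        k = key_of(t)
        if i in core_set:
            groups["core"].add(k)
        else:
            groups["non-core"].add(k)
            cls = neighbor.get(i)
            if cls in ("cooperative", "overlapping"):
                groups[cls].add(k)
    return groups


def knockout_score_distributions(
    wildtype_annotation: SiteAnnotation,
    params: ModelParams,
    U: ExpressionState,
    profiles,
    groups: Mapping[str, set],
    grid: TimeGrid | None = None,
    n_boot: int = 499,
    rng=None,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Knockout score samples per site group plus pairwise KS tests.

    Every founder site is knocked out once; scores are then grouped by
    the (tf, locus, start, strand) keys in ``groups``; an 'all' group is
    always included.  Returns (samples per group, KS comparison table).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    sites = list(wildtype_annotation)
    scores = knockout_scores(wildtype_annotation, params, U, profiles, grid)
    by_key = {s.key(): sc for s, sc in zip(sites, scores)}
    samples: dict[str, np.ndarray] = {"all": np.asarray(scores)}
    for name, keys in groups.items():
        samples[name] = np.array([by_key[k] for k in keys if k in by_key])
    rows = []
    names = [n for n in samples if len(samples[n]) > 1]
    for a_i, na in enumerate(names):
        for nb in names[a_i + 1 :]:
            res = ks_bootstrap(samples[na], samples[nb], n_boot=n_boot, rng=rng)
            rows.append(
                {
                    "group_a": na,
                    "group_b": nb,
                    "ks_statistic": res.statistic,
                    "p_value": res.p_value,
                    "n_a": len(samples[na]),
                    "n_b": len(samples[nb]),
                }
            )
    return samples, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Site counts (turnover dynamics)


def site_count_dynamics(records) -> pd.DataFrame:
    """Elite-averaged total / initial-coordinate / new site counts per
    generation (the turnover summary behind the site-number dynamics)."""
    founder_keys = {s.key() for s in records[0].elite_sites[0]}
    rows = []
    for rec in records:
        tot = [len(sites) for sites in rec.elite_sites]
        new = [
            sum(1 for s in sites if s.key() not in founder_keys)
            for sites in rec.elite_sites
        ]
        rows.append(
            {
                "generation": rec.generation,
                "total_mean": float(np.mean(tot)),
                "initial_mean": float(np.mean(tot)) - float(np.mean(new)),
                "new_mean": float(np.mean(new)),
            }
        )
    return pd.DataFrame(rows)
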