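"""Thermodynamic activation + reaction-diffusion expression model.

Maps a site annotation to spatiotemporal mRNA/protein expression.  The
model is a documented surrogate with the structure of hybrid
thermodynamic gap-gene circuits:

* each site s of factor f with energy E is occupied with probability
  ``phi = q / (1 + q)``, ``q = K_f * c_f * exp(beta * (E - E_ref_f))``
  where ``c_f`` is the factor concentration in the nucleus and
  ``E_ref_f`` the weakest callable score of the factor's PWM;
* same-factor sites within the cooperativity range boost one another in
  a single fixed-point pass, ``q' = q * (1 + omega * sum phi_nbr)``;
* the activation probability of gene a is
  ``P_on = logistic(sum_s T_{f(s)->a} * phi'_s + theta_a)``;
* gene products follow reaction-diffusion dynamics on a row of nuclei
  with zero-flux boundaries::

      dm_a(i)/dt = R_a P_on,a(i,t) - lambda_a m + D_a (m_{i-1} + m_{i+1} - 2 m_i)
      dp_a(i)/dt = r_a m - rho_a p + D'_a lap(p)

The four gap factors (Hb, Kr, Gt, Kni) read their concentrations from
the simulated protein state, closing the gap-gap feedback loop; Bcd,
Cad, Tll and Hkb are time-constant external profiles.

Integration uses an exponential-Euler scheme: the linear decay is
integrated exactly, synthesis and diffusion explicitly.  For D = 0 and
constant activation this reproduces the closed form
``m(t) = (R P / lambda)(1 - exp(-lambda t))`` to machine precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.special import expit

from .annotation import SiteAnnotation, TFBS

logger = logging.getLogger(__name__)

#: gap factor -> gene whose protein provides its concentration
GENE_OF_TF = {"Hb": "hb", "Kr": "Kr", "Gt": "gt", "Kni": "kni"}

PRODUCTS = ["mRNA", "protein"]


class SimulationError(RuntimeError):
    """Raised when integration produces non-finite concentrations."""


#: factors already warned about as having no concentration source
_WARNED_INERT_TFS: set[str] = set()


# ---------------------------------------------------------------------------
# Parameters


@dataclass
class ModelParams:
    """Free parameters of the expression model.

    Per-gene arrays follow the order of ``genes``.  ``T`` holds signed,
    dimensionless regulatory weights (activator > 0, repressor < 0) per
    (tf, gene); ``K`` the concentration scale (1/conc) per tf; ``e_ref``
    the reference energy per tf (score units), by convention the PWM
    scan threshold so the weakest callable site has ``q = K c``.
    """

    genes: list[str]
    R: np.ndarray
    lam: np.ndarray
    D: np.ndarray
    r: np.ndarray
    rho: np.ndarray
    Dp: np.ndarray
    theta: np.ndarray
    K: dict[str, float]
    T: dict[str, dict[str, float]]
    e_ref: dict[str, float] = field(default_factory=dict)
    omega: float = 0.5
    coop_range: int = 50
    beta: float = 0.35

    def __post_init__(self):
        G = len(self.genes)
        for name in ("R", "lam", "D", "r", "rho", "Dp", "theta"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape == ():
                arr = np.full(G, float(arr))
            if arr.shape != (G,):
                raise ValueError(f"{name} must have shape ({G},)")
            setattr(self, name, arr)
        for name in ("R", "lam", "D", "r", "rho", "Dp"):
            if (getattr(self, name) < 0).any():
                raise ValueError(f"{name} must be non-negative")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")

    @classmethod
    def default(
        cls,
        genes: Sequence[str] | None = None,
        tf_specs=None,
        weight: float = 0.9,
        **overrides,
    ) -> "ModelParams":
        """Defaults producing patterned, mid-range dynamics at desk scale.

        ``tf_specs`` (objects with ``.name`` and ``.role_sign``) supply
        the sign structure of the regulatory weights; magnitudes are a
        uniform ``weight``.
        """
        if tf_specs is None:
            from .synthetic import default_tf_specs

            tf_specs = default_tf_specs(genes or ["hb", "Kr", "gt", "kni"])
        genes = list(genes) if genes is not None else ["hb", "Kr", "gt", "kni"]
        T = {
            spec.name: {g: weight * spec.role_sign.get(g, 0) for g in genes}
            for spec in tf_specs
        }
        kw = dict(
            genes=genes,
            R=1.0,
            lam=0.5,
            D=0.02,
            r=1.0,
            rho=0.5,
            Dp=0.05,
            theta=-1.5,
            K={spec.name: 0.6 for spec in tf_specs},
            T=T,
            e_ref={},
            omega=0.5,
            coop_range=50,
            beta=0.35,
        )
        kw.update(overrides)
        return cls(**kw)

    def set_reference_energies(self, pwms) -> "ModelParams":
        """Set per-factor reference energy to each PWM's scan threshold."""
        self.e_ref = {p.tf: float(p.threshold) for p in pwms}
        return self

    def gene_index(self, gene: str) -> int:
        return self.genes.index(gene)


@dataclass
class TimeGrid:
    """Integration grid; observation times must lie on the step grid."""

    t_end: float = 6.0
    dt: float = 0.02
    obs_times: np.ndarray = None

    def __post_init__(self):
        if self.obs_times is None:
            self.obs_times = np.arange(1.0, self.t_end + 1e-9, 1.0)
        self.obs_times = np.asarray(self.obs_times, dtype=float)
        steps = self.obs_times / self.dt
        if not np.allclose(steps, np.rint(steps), atol=1e-6):
            raise ValueError("obs_times must be integer multiples of dt")
        if (self.obs_times > self.t_end + 1e-9).any() or (self.obs_times <= 0).any():
            raise ValueError("obs_times must lie in (0, t_end]")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_end / self.dt))

    @property
    def obs_steps(self) -> np.ndarray:
        return np.rint(self.obs_times / self.dt).astype(int)


@dataclass
class ExpressionState:
    """u[product, gene, nucleus, time]; product 0 = mRNA, 1 = protein."""

    u: np.ndarray
    genes: list[str]
    obs_times: np.ndarray

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim != 4 or self.u.shape[0] != 2:
            raise ValueError("expression array must be (2, genes, nuclei, times)")


# ---------------------------------------------------------------------------
# Single-site / single-nucleus operations (reference surface)


def site_occupancy(site: TFBS, tf_conc: float, params: ModelParams) -> float:
    """Thermodynamic occupancy of one site at a given TF concentration."""
    if tf_conc < 0:
        raise ValueError("tf_conc must be >= 0")
    e_ref = params.e_ref.get(site.tf, 0.0)
    q = params.K[site.tf] * tf_conc * np.exp(params.beta * (site.E - e_ref))
    return float(q / (1.0 + q))


def _coop_pairs(sites: Sequence[TFBS], coop_range: int):
    """Index pairs of same-TF, same-locus sites within the cooperativity
    range (edge-to-edge distance, overlap counts as distance 0)."""
    pairs = []
    order = sorted(range(len(sites)), key=lambda i: (sites[i].locus, sites[i].tf, sites[i].start))
    for a_pos, i in enumerate(order):
        si = sites[i]
        for j in order[a_pos + 1 :]:
            sj = sites[j]
            if sj.locus != si.locus or sj.tf != si.tf:
                break
            if sj.start - si.end > coop_range:
                continue
            pairs.append((i, j))
    return pairs


def activation_probability(
    sites: Sequence[TFBS],
    gene: str,
    concentrations: Mapping[str, float],
    params: ModelParams,
) -> float:
    """P_on for one gene in one nucleus, from that gene's sites.

    ``concentrations`` must provide every factor appearing among the
    sites; a missing factor raises.  Cooperativity applies one
    fixed-point pass of the same-factor neighbour boost.
    """
    sites = list(sites)
    for s in sites:
        if s.tf not in concentrations:
            raise KeyError(f"missing concentration for TF {s.tf!r}")
    q = np.array(
        [
            params.K[s.tf]
            * concentrations[s.tf]
            * np.exp(params.beta * (s.E - params.e_ref.get(s.tf, 0.0)))
            for s in sites
        ]
    )
    phi = q / (1.0 + q)
    boost = np.zeros(len(sites))
    for i, j in _coop_pairs(sites, params.coop_range):
        boost[i] += phi[j]
        boost[j] += phi[i]
    q2 = q * (1.0 + params.omega * boost)
    phi2 = q2 / (1.0 + q2)
    gi = params.gene_index(gene)
    act = sum(
        params.T[s.tf][gene] * phi2[k] for k, s in enumerate(sites)
    ) + params.theta[gi]
    return float(expit(act))


# ---------------------------------------------------------------------------
# Batched simulation


class _Compiled:
    """Precompiled regulatory input for a batch of annotations."""

    __slots__ = (
        "n_ann", "G", "n", "act_base", "src", "w", "T", "A",
        "starts", "urows", "has_gap",
    )


def _compile_batch(annotations, params: ModelParams, profiles) -> _Compiled:
    genes = params.genes
    G = len(genes)
    gene_idx = {g: i for i, g in enumerate(genes)}
    n_list = {len(p.values) for p in profiles.values()}
    if len(n_list) != 1:
        raise ValueError("external profiles must share the number of nuclei")
    n = n_list.pop()
    if n < 3:
        raise ValueError("need at least 3 nuclei")
    NK = len(annotations)

    gap_src_of_tf = {
        tf: gene_idx[g] for tf, g in GENE_OF_TF.items() if g in gene_idx
    }

    act_base = np.tile(
        np.repeat(params.theta[None, :], NK, axis=0).reshape(NK * G)[:, None], (1, n)
    )

    g_dest: list[int] = []
    g_src: list[int] = []
    g_w: list[float] = []
    g_T: list[float] = []
    coop_groups: list[tuple[int, list[TFBS], list[int]]] = []
    skipped_tfs = set()

    for k, ann in enumerate(annotations):
        ext_sites: list[TFBS] = []
        gap_sites: list[TFBS] = []
        for s in ann:
            if s.locus not in gene_idx:
                continue
            if s.tf in gap_src_of_tf:
                gap_sites.append(s)
            elif s.tf in profiles:
                ext_sites.append(s)
            else:
                skipped_tfs.add(s.tf)
        # static external contribution, cooperativity included
        if ext_sites:
            q = np.empty((len(ext_sites), n))
            for i, s in enumerate(ext_sites):
                w = params.K[s.tf] * np.exp(
                    params.beta * (s.E - params.e_ref.get(s.tf, 0.0))
                )
                q[i] = w * profiles[s.tf].values
            phi = q / (1.0 + q)
            boost = np.zeros_like(phi)
            for i, j in _coop_pairs(ext_sites, params.coop_range):
                boost[i] += phi[j]
                boost[j] += phi[i]
            q2 = q * (1.0 + params.omega * boost)
            phi2 = q2 / (1.0 + q2)
            for i, s in enumerate(ext_sites):
                row = k * G + gene_idx[s.locus]
                act_base[row] += params.T[s.tf][s.locus] * phi2[i]
        # dynamic gap-factor sites
        base = len(g_dest)
        for s in gap_sites:
            g_dest.append(k * G + gene_idx[s.locus])
            g_src.append(k * G + gap_src_of_tf[s.tf])
            g_w.append(
                params.K[s.tf]
                * float(np.exp(params.beta * (s.E - params.e_ref.get(s.tf, 0.0))))
            )
            g_T.append(params.T[s.tf][s.locus])
        if gap_sites:
            coop_groups.append((base, gap_sites, list(range(base, base + len(gap_sites)))))

    new_skips = skipped_tfs - _WARNED_INERT_TFS
    if new_skips:
        _WARNED_INERT_TFS.update(new_skips)
        logger.warning(
            "simulate: no concentration source for TFs %s; their sites are inert",
            sorted(new_skips),
        )

    c = _Compiled()
    c.n_ann, c.G, c.n = NK, G, n
    c.act_base = act_base
    c.has_gap = len(g_dest) > 0
    if c.has_gap:
        dest = np.asarray(g_dest)
        order = np.argsort(dest, kind="stable")
        c.src = np.asarray(g_src)[order]
        c.w = np.asarray(g_w)[order][:, None]
        c.T = np.asarray(g_T)[order][:, None]
        dest_sorted = dest[order]
        c.urows, c.starts = np.unique(dest_sorted, return_index=True)
        # cooperativity pairs, remapped through the sort order
        inv = np.empty(len(dest), dtype=int)
        inv[order] = np.arange(len(dest))
        rows, cols = [], []
        for base, sites, idxs in coop_groups:
            for i, j in _coop_pairs(sites, params.coop_range):
                a, b = inv[idxs[i]], inv[idxs[j]]
                rows += [a, b]
                cols += [b, a]
        if rows:
            S = len(dest)
            c.A = sparse.csr_matrix(
                (np.ones(len(rows)), (rows, cols)), shape=(S, S)
            )
        else:
            c.A = None
    else:
        c.src = c.w = c.T = c.A = None
        c.urows = c.starts = None
    return c


def _laplacian(x: np.ndarray, out: np.ndarray) -> np.ndarray:
    """Nearest-neighbour Laplacian with zero-flux boundaries, row-wise."""
    out[:, 1:-1] = x[:, 2:] + x[:, :-2] - 2.0 * x[:, 1:-1]
    out[:, 0] = x[:, 1] - x[:, 0]
    out[:, -1] = x[:, -2] - x[:, -1]
    return out


def simulate_batch(
    annotations: Sequence[SiteAnnotation],
    params: ModelParams,
    grid: TimeGrid | None = None,
    profiles: Mapping | None = None,
    initial: tuple[np.ndarray, np.ndarray] | None = None,
) -> list[ExpressionState | None]:
    """Integrate the model for many annotations simultaneously.

    Returns one ExpressionState per annotation; an entry is None when
    that individual's dynamics produced non-finite values (the caller
    decides how to penalise it).
    """
    if profiles is None:
        raise ValueError("external TF profiles are required")
    grid = grid or TimeGrid()
    comp = _compile_batch(annotations, params, profiles)
    NK, G, n = comp.n_ann, comp.G, comp.n

    dt = grid.dt
    # exponential-Euler weights: decay exact, synthesis/diffusion explicit
    lam_col = np.tile(params.lam, NK)[:, None]
    rho_col = np.tile(params.rho, NK)[:, None]
    R_col = np.tile(params.R, NK)[:, None]
    r_col = np.tile(params.r, NK)[:, None]
    D_col = np.tile(params.D, NK)[:, None]
    Dp_col = np.tile(params.Dp, NK)[:, None]
    with np.errstate(invalid="ignore"):
        am = np.exp(-lam_col * dt)
        bm = np.where(lam_col > 0, -np.expm1(-lam_col * dt) / np.where(lam_col > 0, lam_col, 1.0), dt)
        ap = np.exp(-rho_col * dt)
        bp = np.where(rho_col > 0, -np.expm1(-rho_col * dt) / np.where(rho_col > 0, rho_col, 1.0), dt)
    if dt * float(max(params.D.max(initial=0), params.Dp.max(initial=0))) * 4 >= 1.0:
        raise ValueError("dt too large for stable explicit diffusion")

    if initial is not None:
        m = np.array(initial[0], dtype=float).reshape(NK * G, n)
        p = np.array(initial[1], dtype=float).reshape(NK * G, n)
    else:
        m = np.zeros((NK * G, n))
        p = np.zeros((NK * G, n))

    obs_steps = set(int(s) for s in grid.obs_steps)
    nT = len(grid.obs_times)
    out = np.empty((NK, 2, G, n, nT))
    obs_i = 0

    lap_m = np.empty_like(m)
    lap_p = np.empty_like(p)
    omega = params.omega

    for step in range(1, grid.n_steps + 1):
        act = comp.act_base.copy()
        if comp.has_gap:
            C = p[comp.src]
            q = comp.w * C
            phi = q / (1.0 + q)
            if comp.A is not None and omega > 0:
                q *= 1.0 + omega * (comp.A @ phi)
                phi = q / (1.0 + q)
            contrib = comp.T * phi
            sums = np.add.reduceat(contrib, comp.starts, axis=0)
            act[comp.urows] += sums
        Pon = expit(act)
        _laplacian(m, lap_m)
        _laplacian(p, lap_p)
        m_old = m
        m = m * am + bm * (R_col * Pon + D_col * lap_m)
        p = p * ap + bp * (r_col * m_old + Dp_col * lap_p)
        np.maximum(m, 0.0, out=m)
        np.maximum(p, 0.0, out=p)
        if step in obs_steps:
            out[:, 0, :, :, obs_i] = m.reshape(NK, G, n)
            out[:, 1, :, :, obs_i] = p.reshape(NK, G, n)
            obs_i += 1

    results: list[ExpressionState | None] = []
    for k in range(NK):
        u = out[k]
        if np.isfinite(u).all():
            results.append(ExpressionState(u, list(params.genes), grid.obs_times))
        else:
            results.append(None)
    return results


def simulate(
    annotation: SiteAnnotation,
    params: ModelParams,
    grid: TimeGrid | None = None,
    profiles: Mapping | None = None,
    initial=None,
) -> ExpressionState:
    """Integrate the model for one annotation (see ``simulate_batch``)."""
    res = simulate_batch([annotation], params, grid, profiles, initial)[0]
    if res is None:
        raise SimulationError(
            "expression dynamics produced non-finite values; "
            "check rates and dt for stability"
        )
    return res


# ---------------------------------------------------------------------------
# Fitness


def rms_score(u, U) -> float:
    """Root-mean-square deviation between two expression states.

    ``F = sqrt( (1/N) * sum_{p,a,i,t} (u - U)^2 )`` over the full
    observation grid (N = number of terms).
    """
    ua = u.u if isinstance(u, ExpressionState) else np.asarray(u, dtype=float)
    Ua = U.u if isinstance(U, ExpressionState) else np.asarray(U, dtype=float)
    if ua.shape != Ua.shape:
        raise ValueError(f"shape mismatch {ua.shape} vs {Ua.shape}")
    return float(np.sqrt(np.mean((ua - Ua) ** 2)))


def site_knockout_score(
    annotation: SiteAnnotation,
    site: TFBS,
    params: ModelParams,
    U: ExpressionState,
    profiles,
    grid: TimeGrid | None = None,
) -> float:
    """Regulatory rms-score of a site: F after deleting it.

    The sequence is unchanged; only the annotation loses the site.
    Larger scores mean stronger influence on expression.
    """
    u = simulate(annotation.without(site), params, grid, profiles)
    return rms_score(u, U)


def knockout_scores(
    annotation: SiteAnnotation,
    params: ModelParams,
    U: ExpressionState,
    profiles,
    grid: TimeGrid | None = None,
    sites: Sequence[TFBS] | None = None,
) -> np.ndarray:
    """Knockout scores for many sites at once (batched integration)."""
    sites = list(sites) if sites is not None else list(annotation)
    anns = [annotation.without(s) for s in sites]
    states = simulate_batch(anns, params, grid, profiles)
    return np.array(
        [np.inf if st is None else rms_score(st, U) for st in states]
    )
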