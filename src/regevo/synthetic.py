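"""Synthetic inputs for the regulatory-evolution pipeline.

An empirically grounded version of this pipeline would annotate
~18 kb regulatory regions of the four Drosophila gap genes (hb, Kr,
gt, kni) with empirical PWMs for eight factors (Bcd, Cad, Hb, Gt, Kr,
Kni, Tll, Hkb), filter sites with DNase accessibility and curated
CRM/footprint data, and drive expression with a fitted thermodynamic
model.  None of those inputs ship with this package; this module generates statistical
stand-ins with the structure the downstream analysis assumes:

* PWMs of controllable information content, including a repetitive
  homopolymer (polyA-like) motif for Hb, whose self-overlapping hits
  reproduce the motif-redundancy phenomenon;
* regulatory loci of i.i.d. background sequence with planted consensus
  (strong) or mismatched (weak) sites, plus accessibility masks, CRM
  intervals and footprint intervals covering the planted sites;
* anterior-posterior concentration profiles of the four external
  factors (Bcd anterior-exponential, Cad posterior, Tll/Hkb terminal
  peaks) along a row of nuclei;
* a self-consistent wild-type expression target computed from the seed
  genotype, which guarantees the founder has rms-score 0.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from . import expression
from .annotation import PWM, annotate_genotype, threshold_for_pvalue
from .seqs import decode, encode, random_seq, revcomp

GAP_GENES = ["hb", "Kr", "gt", "kni"]
TF_NAMES = ["Bcd", "Cad", "Hb", "Gt", "Kr", "Kni", "Tll", "Hkb"]
EXTERNAL_TFS = ["Bcd", "Cad", "Tll", "Hkb"]

#: Qualitative sign structure of the gap network used by default, the
#: classic maternal-activation / mutual-repression motif: Bcd and Cad
#: activate zygotic targets, each gap gene autoactivates and represses
#: the other three, and the terminal factors repress the trunk genes
#: (Tll sparing hb, whose posterior domain it promotes).  Every factor
#: regulates every target, as in fitted gap-gene circuit models.
DEFAULT_ROLES = {
    "Bcd": {"hb": +1, "Kr": +1, "gt": +1, "kni": +1},
    "Cad": {"hb": -1, "Kr": +1, "gt": +1, "kni": +1},
    "Hb": {"hb": +1, "Kr": -1, "gt": -1, "kni": -1},
    "Gt": {"hb": -1, "Kr": -1, "gt": +1, "kni": -1},
    "Kr": {"hb": -1, "Kr": +1, "gt": -1, "kni": -1},
    "Kni": {"hb": -1, "Kr": -1, "gt": -1, "kni": +1},
    "Tll": {"hb": +1, "Kr": -1, "gt": -1, "kni": -1},
    "Hkb": {"hb": -1, "Kr": -1, "gt": -1, "kni": -1},
}


# ---------------------------------------------------------------------------
# Specs


@dataclass
class TFSpec:
    """Specification of one transcription factor's motif and roles."""

    name: str
    role_sign: dict[str, int]
    motif_length: int = 8
    info_content: float = 1.25
    repetitive: bool = False

    def __post_init__(self):
        if self.motif_length < 4:
            raise ValueError(f"{self.name}: motif_length must be >= 4")

    def validate_roles(self, genes: Sequence[str]) -> None:
        missing = [g for g in genes if g not in self.role_sign]
        if missing:
            raise ValueError(f"{self.name}: roles undefined for genes {missing}")


@dataclass
class PlantedSite:
    """A site planted into a synthetic locus.

    ``position`` may be None, in which case a free position is drawn at
    generation time.  ``tier`` is 'strong' (exact consensus) or 'weak'
    (consensus with 1-2 mismatches).
    """

    tf: str
    position: int | None = None
    tier: str = "strong"
    strand: str | None = None
    locus: str | None = None


@dataclass
class LocusSpec:
    """Specification of one synthetic regulatory locus."""

    gene: str
    length: int = 2000
    accessible_fraction: float = 1.0
    planted_sites: list[PlantedSite] | None = None
    n_planted: int = 15

    def __post_init__(self):
        if not 0.0 <= self.accessible_fraction <= 1.0:
            raise ValueError(f"{self.gene}: accessible_fraction must be in [0,1]")


@dataclass
class TFProfile:
    """Concentration of one TF per nucleus along the A-P axis."""

    tf: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError(f"{self.tf}: negative concentrations")


def default_tf_specs(genes: Sequence[str] = GAP_GENES) -> list[TFSpec]:
    """The eight default factors; Hb carries the repetitive polyA motif."""
    specs = []
    for name in TF_NAMES:
        roles = {g: DEFAULT_ROLES[name].get(g, 0) for g in genes}
        if name == "Hb":
            specs.append(
                TFSpec(name, roles, motif_length=10, info_content=0.9, repetitive=True)
            )
        else:
            specs.append(TFSpec(name, roles, motif_length=8, info_content=1.25))
    return specs


def default_locus_specs(
    genes: Sequence[str] = GAP_GENES, length: int = 2000, n_planted: int = 15
) -> list[LocusSpec]:
    return [LocusSpec(gene=g, length=length, n_planted=n_planted) for g in genes]


# ---------------------------------------------------------------------------
# PWMs


def _entropy(p_major: float) -> float:
    minor = (1.0 - p_major) / 3.0
    h = 0.0
    if p_major > 0:
        h -= p_major * math.log2(p_major)
    if minor > 0:
        h -= 3 * minor * math.log2(minor)
    return h


def _major_prob_for_ic(ic: float) -> float:
    """Dominant-base probability giving a column the requested IC (bits)."""
    # IC(p) = 2 - H(p) is monotone on p in [0.25, 1]
    if ic <= 0:
        return 0.25
    if ic >= 2:
        return 1.0
    return brentq(lambda p: (2.0 - _entropy(p)) - ic, 0.25 + 1e-12, 1.0 - 1e-12)


def make_pwm(
    spec: TFSpec,
    rng_seed: int,
    scan_pvalue: float = 5e-3,
    high_pvalue: float = 1.5e-3,
) -> PWM:
    """Build a log-odds PWM realizing the spec's information content.

    Per-column IC is jittered up to +-10% around the target (so the
    realized mean stays well within 15% of the target).  Repetitive
    motifs take a homopolymer-A consensus; together with both-strand
    scanning this makes polyA and polyT tracts dense with
    self-overlapping hits, mimicking the Hb motif.  The scan threshold
    and the stricter condition-(1) threshold are calibrated to exact
    per-window tail probabilities on uniform background.
    """
    if not 0.0 < spec.info_content <= 2.0:
        raise ValueError(
            f"{spec.name}: info_content {spec.info_content} infeasible for a "
            f"4-letter alphabet (must be in (0, 2] bits/column)"
        )
    rng = np.random.default_rng(rng_seed)
    L = spec.motif_length
    if spec.repetitive:
        consensus = np.zeros(L, dtype=np.uint8)  # homopolymer A
    else:
        consensus = rng.integers(0, 4, size=L).astype(np.uint8)
    ics = spec.info_content * rng.uniform(0.9, 1.1, size=L)
    ics = np.clip(ics, 1e-3, 2.0)
    matrix = np.empty((L, 4))
    for j in range(L):
        p_major = _major_prob_for_ic(float(ics[j]))
        minor = (1.0 - p_major) / 3.0
        col = np.full(4, minor)
        col[consensus[j]] = p_major
        matrix[j] = np.log2(col / 0.25)
    threshold = threshold_for_pvalue(matrix, scan_pvalue)
    high = threshold_for_pvalue(matrix, high_pvalue)
    return PWM(spec.name, matrix, threshold, high_threshold=high)


def make_pwms(
    specs: Sequence[TFSpec],
    rng_seed: int,
    scan_pvalue: float = 5e-3,
    high_pvalue: float = 1.5e-3,
) -> list[PWM]:
    """One PWM per spec, with per-TF seeds split from ``rng_seed``."""
    ss = np.random.SeedSequence(rng_seed)
    children = ss.spawn(len(specs))
    return [
        make_pwm(
            spec,
            int(child.generate_state(1)[0] & 0x7FFFFFFF),
            scan_pvalue,
            high_pvalue,
        )
        for spec, child in zip(specs, children)
    ]


# ---------------------------------------------------------------------------
# Genotype


@dataclass
class Genotype:
    """Four (by default) named regulatory loci plus interval annotations.

    ``loci`` maps locus name (the target gene) to a uint8 code array.
    Interval sets are 0-based half-open, per locus.  The represented
    (mutable) sequence is the union of the accessibility intervals.
    """

    locus_names: list[str]
    loci: dict[str, np.ndarray]
    accessibility: dict[str, list[tuple[int, int]]]
    crms: dict[str, list[tuple[int, int]]]
    footprints: dict[str, list[tuple[int, int]]]
    planted: list = field(default_factory=list)
    _accessible_idx: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def locus_length(self, locus: str) -> int:
        return len(self.loci[locus])

    @property
    def locus_lengths(self) -> dict[str, int]:
        return {name: len(self.loci[name]) for name in self.locus_names}

    def accessible_positions(self, locus: str) -> np.ndarray:
        """Indices of mutable (accessible) positions in a locus, cached."""
        if locus not in self._accessible_idx:
            mask = np.zeros(len(self.loci[locus]), dtype=bool)
            for a, b in self.accessibility[locus]:
                mask[a:b] = True
            self._accessible_idx[locus] = np.nonzero(mask)[0]
        return self._accessible_idx[locus]

    def copy(self) -> "Genotype":
        return Genotype(
            locus_names=list(self.locus_names),
            loci={k: v.copy() for k, v in self.loci.items()},
            accessibility=self.accessibility,
            crms=self.crms,
            footprints=self.footprints,
            planted=self.planted,
            _accessible_idx=self._accessible_idx,
        )

    def sequences_equal(self, other: "Genotype") -> bool:
        return all(
            np.array_equal(self.loci[k], other.loci[k]) for k in self.locus_names
        )


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for a, b in sorted(ivs):
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def _coverage(ivs: list[tuple[int, int]]) -> int:
    return sum(b - a for a, b in ivs)


def make_genotype(
    loci: Sequence[LocusSpec],
    pwms: Sequence[PWM],
    rng_seed: int,
    gc: float = 0.5,
    allow_overlap: bool = False,
    mask_pad: int = 10,
    n_crms: int = 2,
    crm_fraction: float = 0.15,
) -> Genotype:
    """Generate a founder genotype with planted sites and interval sets.

    Background is i.i.d. (uniform by default, GC-biased via ``gc``).
    Strong-tier planted sites carry the exact motif consensus, weak-tier
    ones 1-2 mismatches; strands are drawn at random unless specified.
    The accessibility mask always covers planted sites (padded), random
    intervals are added up to ``accessible_fraction``; footprints are the
    exact planted intervals; CRMs are ``n_crms`` random intervals per
    locus jointly covering about ``crm_fraction`` of it.
    """
    rng = np.random.default_rng(rng_seed)
    pwm_by_tf = {p.tf: p for p in pwms}
    genotype_loci: dict[str, np.ndarray] = {}
    accessibility: dict[str, list] = {}
    crms: dict[str, list] = {}
    footprints: dict[str, list] = {}
    planted_out: list[PlantedSite] = []
    names: list[str] = []

    for spec in loci:
        name = spec.gene
        names.append(name)
        L = spec.length
        seq = random_seq(rng, L, gc=gc)

        wanted = list(spec.planted_sites) if spec.planted_sites is not None else None
        if wanted is None:
            wanted = _default_roster(spec, rng)
        # capacity check
        total_bp = sum(pwm_by_tf[p.tf].length for p in wanted)
        if not allow_overlap and total_bp > 0.5 * L:
            raise ValueError(
                f"{name}: planted density ({total_bp} bp of motifs) exceeds "
                f"half the locus capacity ({L} bp)"
            )
        occupied: list[tuple[int, int]] = []
        placed: list[PlantedSite] = []
        for p in wanted:
            mlen = pwm_by_tf[p.tf].length
            if p.position is not None:
                pos = p.position
                if not 0 <= pos <= L - mlen:
                    raise ValueError(
                        f"{name}: planted site {p.tf}@{pos} outside locus [0,{L})"
                    )
                if not allow_overlap and any(
                    pos < b and a < pos + mlen for a, b in occupied
                ):
                    raise ValueError(
                        f"{name}: planted site {p.tf}@{pos} overlaps another"
                    )
            else:
                pos = _draw_free_position(rng, L, mlen, occupied, allow_overlap)
            strand = p.strand or ("+" if rng.random() < 0.5 else "-")
            motif = encode(pwm_by_tf[p.tf].consensus)
            if p.tier == "weak":
                motif = motif.copy()
                n_mm = int(rng.integers(1, 3))
                for j in rng.choice(len(motif), size=n_mm, replace=False):
                    motif[j] = (motif[j] + rng.integers(1, 4)) % 4
            if strand == "-":
                motif = revcomp(motif)
            seq[pos : pos + mlen] = motif
            occupied.append((pos, pos + mlen))
            placed.append(PlantedSite(p.tf, pos, p.tier, strand, locus=name))

        genotype_loci[name] = seq
        planted_out.extend(placed)

        # accessibility: planted intervals padded, then random fill
        mask = [
            (max(0, a - mask_pad), min(L, b + mask_pad)) for a, b in occupied
        ]
        mask = _merge_intervals(mask)
        target = int(round(spec.accessible_fraction * L))
        attempts = 0
        while _coverage(mask) < target and attempts < 10_000:
            span = min(int(rng.integers(100, 400)), L)
            a = int(rng.integers(0, L - span + 1))
            mask = _merge_intervals(mask + [(a, a + span)])
            attempts += 1
        if spec.accessible_fraction >= 1.0:
            mask = [(0, L)]
        accessibility[name] = mask

        crm_span = max(30, int(crm_fraction * L / max(n_crms, 1)))
        locus_crms = []
        for _ in range(n_crms):
            a = int(rng.integers(0, max(1, L - crm_span)))
            locus_crms.append((a, min(L, a + crm_span)))
        crms[name] = _merge_intervals(locus_crms)
        footprints[name] = [(a, b) for a, b in occupied]

    g = Genotype(
        locus_names=names,
        loci=genotype_loci,
        accessibility=accessibility,
        crms=crms,
        footprints=footprints,
        planted=planted_out,
    )
    return g


def _default_roster(spec: LocusSpec, rng: np.random.Generator) -> list[PlantedSite]:
    """Draw a planted-site roster biased towards activators.

    External activators (Bcd, Cad) are overrepresented so every locus
    responds to the maternal gradients; 60% of sites are strong tier.
    """
    weights = {
        "Bcd": 0.20,
        "Cad": 0.20,
        "Hb": 0.12,
        "Gt": 0.08,
        "Kr": 0.08,
        "Kni": 0.08,
        "Tll": 0.12,
        "Hkb": 0.12,
    }
    tfs = list(weights)
    p = np.array([weights[t] for t in tfs])
    p /= p.sum()
    roster = []
    for _ in range(spec.n_planted):
        tf = tfs[int(rng.choice(len(tfs), p=p))]
        tier = "strong" if rng.random() < 0.6 else "weak"
        roster.append(PlantedSite(tf, None, tier))
    return roster


def _draw_free_position(rng, L, mlen, occupied, allow_overlap, max_tries=2000):
    for _ in range(max_tries):
        pos = int(rng.integers(0, L - mlen + 1))
        if allow_overlap or not any(pos < b and a < pos + mlen for a, b in occupied):
            return pos
    raise ValueError("could not place planted site: locus too crowded")


# ---------------------------------------------------------------------------
# TF profiles


@dataclass
class ProfileShapes:
    """Shape parameters of the external TF gradients (nucleus units)."""

    c_max: float = 1.0
    bcd_decay: float = 8.0
    cad_decay: float = 10.0
    tll_width: float = 2.5
    hkb_width: float = 1.2


def make_tf_profiles(
    n_nuclei: int, shapes: ProfileShapes | None = None
) -> dict[str, TFProfile]:
    """External-factor gradients along a row of ``n_nuclei`` nuclei.

    Bcd is anterior-high exponential (value(i)/value(0) = exp(-i/lambda)
    exactly), Cad the posterior mirror, Tll and Hkb symmetric terminal
    peaks maximal at the two boundary nuclei.
    """
    if n_nuclei < 4:
        raise ValueError("need at least 4 nuclei")
    shapes = shapes or ProfileShapes()
    i = np.arange(n_nuclei, dtype=float)
    rev = n_nuclei - 1 - i
    bcd = shapes.c_max * np.exp(-i / shapes.bcd_decay)
    cad = shapes.c_max * np.exp(-rev / shapes.cad_decay)
    tll = 0.5 * shapes.c_max * (
        np.exp(-i / shapes.tll_width) + np.exp(-rev / shapes.tll_width)
    )
    hkb = 0.5 * shapes.c_max * (
        np.exp(-i / shapes.hkb_width) + np.exp(-rev / shapes.hkb_width)
    )
    return {
        "Bcd": TFProfile("Bcd", bcd),
        "Cad": TFProfile("Cad", cad),
        "Tll": TFProfile("Tll", tll),
        "Hkb": TFProfile("Hkb", hkb),
    }


# ---------------------------------------------------------------------------
# Wild type


def make_wildtype(
    genotype: Genotype,
    params: "expression.ModelParams",
    pwms: Sequence[PWM],
    profiles: dict[str, TFProfile],
    grid: "expression.TimeGrid | None" = None,
):
    """Compute the wild-type expression target from the seed genotype.

    Returns ``(U, founder_annotation)``.  Because the fitness reference
    is the founder's own model output, the unmutated founder scores
    exactly F = 0.
    """
    ann = annotate_genotype(genotype, pwms)
    U = expression.simulate(ann, params, grid or expression.TimeGrid(), profiles)
    return U, ann
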