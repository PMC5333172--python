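"""TFBS prediction and filtering.

A PWM here is a per-position log2-odds matrix against a uniform
background; a predicted site is any window, on either strand, scoring at
least the PWM threshold.  The binding energy ``E`` of a site is defined
as its log-odds score (score units), following the convention that the
affinity ranking of sites is monotone in the score.

Predicted sites pass into the model only if they satisfy at least one of
three inclusion conditions mimicking the use of chromatin accessibility,
curated regulatory modules, and curated footprints:

1. score at least a (higher) score cutoff AND fully inside an
   accessibility interval;
2. overlapping (>= 1 bp) a CRM interval;
3. overlapping (>= 1 bp) a footprint interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .seqs import as_codes

logger = logging.getLogger(__name__)

Interval = tuple[int, int]


# ---------------------------------------------------------------------------
# PWM


@dataclass
class PWM:
    """Position weight matrix (log2-odds, uniform background).

    Parameters
    ----------
    tf:
        Transcription factor name.
    matrix:
        ``(motif_length, 4)`` array of log2-odds scores, columns ordered
        A, C, G, T.
    threshold:
        Minimum window score for a predicted site.
    high_threshold:
        Optional stricter cutoff used by inclusion condition (1);
        defaults to ``threshold`` when absent.
    """

    tf: str
    matrix: np.ndarray
    threshold: float
    high_threshold: float | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"PWM matrix must be (L, 4), got {self.matrix.shape}")
        if self.threshold > self.max_score + 1e-9:
            raise ValueError(
                f"PWM threshold {self.threshold} exceeds max achievable "
                f"score {self.max_score}"
            )

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        from .seqs import decode

        return decode(self.matrix.argmax(axis=1).astype(np.uint8))

    def probabilities(self, background: float = 0.25) -> np.ndarray:
        """Per-column base probabilities implied by the log-odds matrix."""
        p = background * np.exp2(self.matrix)
        return p / p.sum(axis=1, keepdims=True)

    def information_content(self) -> np.ndarray:
        """Per-column information content in bits."""
        p = self.probabilities()
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log2(p / 0.25), 0.0)
        return terms.sum(axis=1)

    def reverse_complement(self) -> "PWM":
        return replace(self, matrix=self.matrix[::-1, ::-1].copy())


def score_distribution(
    matrix: np.ndarray, precision: float = 1e-3
) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the window score on uniform random sequence.

    Scores are discretised to multiples of ``precision`` and the
    per-column score distributions are convolved.  Returns
    ``(scores, probabilities)`` with scores ascending.
    """
    matrix = np.asarray(matrix, dtype=float)
    M = np.rint(matrix / precision).astype(np.int64)
    dist = np.array([1.0])
    base = 0
    for col in M:
        cmin = int(col.min())
        shifts = col - cmin
        new = np.zeros(len(dist) + int(shifts.max()) + 1)
        for s in shifts:
            new[s : s + len(dist)] += 0.25 * dist
        dist = new
        base += cmin
    scores = (base + np.arange(len(dist))) * precision
    return scores, dist


def threshold_for_pvalue(
    matrix: np.ndarray, pvalue: float, precision: float = 1e-3
) -> float:
    """Smallest score whose exceedance probability is <= ``pvalue``.

    Exceedance is P(score >= s) per window per strand under the uniform
    background.  If no score achieves the requested tail, the maximum
    achievable score is returned.
    """
    scores, dist = score_distribution(matrix, precision)
    tail = np.cumsum(dist[::-1])[::-1]
    ok = tail <= pvalue
    if not ok.any():
        return float(scores[-1])
    return float(scores[int(np.argmax(ok))])


# ---------------------------------------------------------------------------
# Sites


@dataclass(slots=True)
class TFBS:
    """A predicted binding site on the forward coordinate system.

    ``E`` is the PWM log-odds score of the site; ``E_wt`` is filled by
    the tracking machinery with the energy the site (or its tracked
    ancestor) had in the founder sequence, where applicable.
    """

    tf: str
    locus: str
    start: int
    length: int
    strand: str
    E: float
    E_wt: float | None = None

    @property
    def end(self) -> int:
        return self.start + self.length

    @property
    def interval(self) -> Interval:
        return (self.start, self.start + self.length)

    def key(self) -> tuple:
        return (self.tf, self.locus, self.start, self.strand)


@dataclass
class SiteAnnotation:
    """All predicted sites of one genotype, sorted by (locus, start).

    Exact duplicates (same tf, locus, start, strand) are forbidden.
    """

    sites: list[TFBS] = field(default_factory=list)
    genotype: object | None = None

    def __post_init__(self):
        self.sites = sorted(
            self.sites, key=lambda s: (s.locus, s.start, s.tf, s.strand)
        )
        seen = set()
        for s in self.sites:
            k = s.key()
            if k in seen:
                raise ValueError(f"duplicate site {k}")
            seen.add(k)

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)

    def by_locus(self, locus: str) -> list[TFBS]:
        return [s for s in self.sites if s.locus == locus]

    def energies(self) -> np.ndarray:
        return np.array([s.E for s in self.sites], dtype=float)

    def without(self, site: TFBS) -> "SiteAnnotation":
        """Copy of the annotation with one site removed (knockout)."""
        kept = [s for s in self.sites if s.key() != site.key()]
        if len(kept) == len(self.sites):
            raise ValueError(f"site {site.key()} not present in annotation")
        return SiteAnnotation(sites=kept, genotype=self.genotype)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "tf": [s.tf for s in self.sites],
                "locus": [s.locus for s in self.sites],
                "start": [s.start for s in self.sites],
                "end": [s.end for s in self.sites],
                "strand": [s.strand for s in self.sites],
                "E": [s.E for s in self.sites],
            }
        )


# ---------------------------------------------------------------------------
# Scanning


def scan_pwm(sequence, pwm: PWM, locus: str = "") -> list[TFBS]:
    """Score every window on both strands, reporting hits >= threshold.

    Coordinates are 0-based half-open on the forward strand; a minus
    strand hit at start i means the reverse complement of the window
    [i, i+L) matches the motif.  Windows containing ambiguous bases are
    skipped (counted in a debug log line).
    """
    codes = as_codes(sequence)
    L = pwm.length
    if len(codes) < L:
        raise ValueError(
            f"sequence length {len(codes)} shorter than motif length {L}"
        )
    windows = sliding_window_view(codes, L)
    valid = (windows < 4).all(axis=1)
    n_skipped = int((~valid).sum())
    if n_skipped:
        logger.debug(
            "scan_pwm(%s, %s): skipped %d windows with ambiguous bases",
            pwm.tf,
            locus,
            n_skipped,
        )
    idx = np.arange(L)
    safe = np.where(windows < 4, windows, 0)
    fwd = pwm.matrix[idx, safe].sum(axis=1)
    rc = pwm.matrix[::-1, ::-1]
    rev = rc[idx, safe].sum(axis=1)

    hits: list[TFBS] = []
    for strand, scores in (("+", fwd), ("-", rev)):
        for i in np.nonzero(valid & (scores >= pwm.threshold))[0]:
            hits.append(
                TFBS(pwm.tf, locus, int(i), L, strand, float(scores[i]))
            )
    hits.sort(key=lambda s: (s.start, s.strand))
    return hits


# ---------------------------------------------------------------------------
# Inclusion conditions


def _intervals_for(ivs, locus: str) -> Sequence[Interval]:
    if isinstance(ivs, Mapping):
        return ivs.get(locus, ())
    return ivs


def _contained(iv: Interval, ivset: Sequence[Interval]) -> bool:
    return any(a <= iv[0] and iv[1] <= b for a, b in ivset)


def _overlaps(iv: Interval, ivset: Sequence[Interval]) -> bool:
    return any(a < iv[1] and iv[0] < b for a, b in ivset)


def apply_inclusion(
    sites: Iterable[TFBS],
    masks,
    crms,
    footprints,
    high_score_threshold,
) -> list[TFBS]:
    """Keep sites passing at least one of the three inclusion conditions.

    ``masks``/``crms``/``footprints`` are sequences of 0-based half-open
    intervals, or mappings locus -> such sequences.
    ``high_score_threshold`` is a float or a mapping tf -> float.

    Condition (1) requires full containment in an accessibility
    interval ("located in"); conditions (2) and (3) require >= 1 bp
    overlap ("overlapped with").
    """
    kept = []
    for s in sites:
        if isinstance(high_score_threshold, Mapping):
            hs = high_score_threshold[s.tf]
        else:
            hs = high_score_threshold
        iv = s.interval
        if (
            (s.E >= hs and _contained(iv, _intervals_for(masks, s.locus)))
            or _overlaps(iv, _intervals_for(crms, s.locus))
            or _overlaps(iv, _intervals_for(footprints, s.locus))
        ):
            kept.append(s)
    return kept


def annotate_genotype(genotype, pwms: Sequence[PWM]) -> SiteAnnotation:
    """Scan all PWMs over all loci of a genotype and apply inclusion.

    The genotype provides the accessibility / CRM / footprint interval
    sets; each PWM's ``high_threshold`` (falling back to its scan
    threshold) is used for inclusion condition (1).
    """
    high = {p.tf: (p.high_threshold if p.high_threshold is not None else p.threshold) for p in pwms}
    sites: list[TFBS] = []
    for locus in genotype.locus_names:
        seq = genotype.loci[locus]
        for pwm in pwms:
            hits = scan_pwm(seq, pwm, locus=locus)
            sites.extend(
                apply_inclusion(
                    hits,
                    genotype.accessibility,
                    genotype.crms,
                    genotype.footprints,
                    high,
                )
            )
    return SiteAnnotation(sites=sites, genotype=genotype)


# ---------------------------------------------------------------------------
# Overlap statistics


def overlap_fractions(
    annotation: SiteAnnotation | Sequence[TFBS],
    per_tf: bool = False,
    count_mode: str = "pairs",
):
    """Fraction of overlapping events among predicted sites.

    An event is an unordered pair of sites on the same locus with
    intersecting intervals; with ``per_tf`` both sites must be of the
    same TF and a fraction is returned for each TF.  The fraction is
    #events / #sites.  ``count_mode='sites'`` instead counts sites
    involved in at least one overlap (alternative reading; see docs).

    Empty site sets yield 0 with a warning.
    """
    sites = list(annotation)
    if per_tf:
        tfs = sorted({s.tf for s in sites})
        return {
            tf: overlap_fractions(
                [s for s in sites if s.tf == tf], per_tf=False, count_mode=count_mode
            )
            for tf in tfs
        }
    if not sites:
        logger.warning("overlap_fractions: empty annotation, returning 0")
        return 0.0
    events = 0
    touched: set[int] = set()
    order = sorted(range(len(sites)), key=lambda i: (sites[i].locus, sites[i].start))
    for a_pos, i in enumerate(order):
        si = sites[i]
        for j in order[a_pos + 1 :]:
            sj = sites[j]
            if sj.locus != si.locus or sj.start >= si.end:
                break
            # sj.start < si.end and sj.start >= si.start -> intersecting
            events += 1
            touched.add(i)
            touched.add(j)
    if count_mode == "sites":
        return len(touched) / len(sites)
    return events / len(sites)
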