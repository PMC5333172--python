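"""Standard-format input/output.

FASTA goes through Biopython; BED (0-based half-open) and the plain
PWM matrix format are simple line formats written and parsed here with
line-precise error reporting.  The PWM file is::

    >NAME LENGTH THRESHOLD [HIGH_THRESHOLD]
    a_score c_score g_score t_score      (one row per motif position)

Site BED6 uses name = TF and score = round(E * 100), so site energies
round-trip at 0.01 score-unit precision.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import PWM, SiteAnnotation, TFBS
from .seqs import decode, encode


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(loci: Mapping[str, np.ndarray], path) -> None:
    records = [
        SeqRecord(Seq(decode(codes)), id=name, description="")
        for name, codes in loci.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, np.ndarray]:
    return {rec.id: encode(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# BED


def write_bed(path, rows: Sequence[tuple]) -> None:
    """Write BED lines; each row is (chrom, start, end[, name, score, strand])."""
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_bed(path) -> list[tuple]:
    """Parse BED3/BED6; malformed lines raise with their line number."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates: {line!r}"
                ) from exc
            if start < 0 or end < start:
                raise ValueError(f"{path}:{lineno}: invalid interval [{start},{end})")
            if len(fields) >= 6:
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric score: {fields[4]!r}"
                    ) from exc
                if fields[5] not in ("+", "-", "."):
                    raise ValueError(f"{path}:{lineno}: bad strand {fields[5]!r}")
                out.append((fields[0], start, end, fields[3], score, fields[5]))
            else:
                out.append((fields[0], start, end))
    return out


def sites_to_bed(annotation: SiteAnnotation | Sequence[TFBS], path) -> None:
    """BED6 with name = TF and score = E * 100 rounded."""
    write_bed(
        path,
        [
            (s.locus, s.start, s.end, s.tf, int(round(s.E * 100)), s.strand)
            for s in annotation
        ],
    )


def bed_to_sites(path) -> SiteAnnotation:
    sites = []
    for row in read_bed(path):
        if len(row) < 6:
            raise ValueError(f"{path}: site BED requires 6 fields, got {len(row)}")
        chrom, start, end, name, score, strand = row
        sites.append(TFBS(name, chrom, start, end - start, strand, score / 100.0))
    return SiteAnnotation(sites=sites)


def intervals_to_bed(intervals: Mapping[str, Sequence[tuple]], path) -> None:
    rows = []
    for locus, ivs in intervals.items():
        rows.extend((locus, a, b) for a, b in ivs)
    write_bed(path, rows)


def bed_to_intervals(path) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    for row in read_bed(path):
        out.setdefault(row[0], []).append((row[1], row[2]))
    return out


# ---------------------------------------------------------------------------
# PWM files


def write_pwm(pwm: PWM, path) -> None:
    with open(path, "w") as fh:
        header = f">{pwm.tf} {pwm.length} {pwm.threshold!r}"
        if pwm.high_threshold is not None:
            header += f" {pwm.high_threshold!r}"
        fh.write(header + "\n")
        for row in pwm.matrix:
            fh.write(" ".join(repr(float(x)) for x in row) + "\n")


def read_pwm(path) -> PWM:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines or not lines[0].startswith(">"):
        raise ValueError(f"{path}:1: PWM file must start with a '>' header")
    head = lines[0][1:].split()
    if len(head) not in (3, 4):
        raise ValueError(f"{path}:1: header must be '>name length threshold [high]'")
    name, length = head[0], int(head[1])
    threshold = float(head[2])
    high = float(head[3]) if len(head) == 4 else None
    if len(lines) - 1 != length:
        raise ValueError(
            f"{path}: expected {length} matrix rows, found {len(lines) - 1}"
        )
    matrix = np.empty((length, 4))
    for i, ln in enumerate(lines[1:], start=2):
        vals = ln.split()
        if len(vals) != 4:
            raise ValueError(f"{path}:{i}: expected 4 columns, got {len(vals)}")
        matrix[i - 2] = [float(v) for v in vals]
    return PWM(name, matrix, threshold, high_threshold=high)


# ---------------------------------------------------------------------------
# Tables and expression dumps


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def expression_to_table(state, path) -> None:
    """Long-format dump: product, gene, nucleus, time, value."""
    u = state.u
    rows = []
    for pi, product in enumerate(("mRNA", "protein")):
        for gi, gene in enumerate(state.genes):
            for ni in range(u.shape[2]):
                for ti, t in enumerate(state.obs_times):
                    rows.append((product, gene, ni, t, u[pi, gi, ni, ti]))
    pd.DataFrame(
        rows, columns=["product", "gene", "nucleus", "time", "value"]
    ).to_csv(path, sep="\t", index=False)
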