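"""Post-scan reporting: major-QTL calls, cross-trait overlap, genome sums.

These summaries follow common reporting conventions for multi-genome QTL
tables: a QTL is "major" when it explains more than a cutoff share of the
genotypic variance (strictly); QTL of two traits overlap when they map to
the same chromosome within a fixed cM window; and per-genome totals simply
sum the single-QTL pG values over each subgenome's chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GENOMES, genome_of


@dataclass
class TraitComparison:
    trait_a: str
    trait_b: str
    pairs: list  # (chromosome, QTLRecord from a, QTLRecord from b)
    n_overlap: int


def classify_major(qtls, cutoff: float = 10.0) -> list:
    """QTL whose overall pG strictly exceeds ``cutoff`` percent."""
    return [q for q in qtls if q.pg_overall > cutoff]


def _interval_gap(a, b) -> float:
    """Gap in cM between two support intervals (0 when they touch/overlap)."""
    return max(0.0, a.ci_lo - b.ci_hi, b.ci_lo - a.ci_hi)


def find_overlaps(qtls_a, qtls_b, window: float = 10.0, rule: str = "interval",
                  trait_a: str = "trait_a", trait_b: str = "trait_b") -> TraitComparison:
    """Match QTL of two traits that fall within ``window`` cM on the same
    chromosome.

    ``rule="interval"`` (default) measures the gap between support
    intervals; ``rule="point"`` the distance between peak positions.
    Matching is greedy by smallest gap and each QTL matches at most once;
    the result is symmetric in the two lists.
    """
    if rule not in ("interval", "point"):
        raise ValueError("rule must be 'interval' or 'point'")
    candidates = []
    for i, qa in enumerate(qtls_a):
        for j, qb in enumerate(qtls_b):
            if qa.chromosome != qb.chromosome:
                continue
            gap = (_interval_gap(qa, qb) if rule == "interval"
                   else abs(qa.position - qb.position))
            if gap <= window:
                candidates.append((gap, qa.chromosome, min(qa.position, qb.position),
                                   i, j))
    used_a: set = set()
    used_b: set = set()
    pairs = []
    for gap, chrom, _, i, j in sorted(candidates):
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((chrom, qtls_a[i], qtls_b[j]))
    pairs.sort(key=lambda t: (genome_of(t[0]), t[0], t[1].position))
    return TraitComparison(trait_a, trait_b, pairs, len(pairs))


def genome_summary(qtls, gmap=None) -> pd.DataFrame:
    """Per-genome sums of overall and per-family pG (indexed by genome).

    The genome label comes from the chromosome name; ``gmap`` is accepted
    for API symmetry but not required.
    """
    fams: list = []
    for q in qtls:
        for f in q.pg_family:
            if f not in fams:
                fams.append(f)
    rows = {}
    for g in GENOMES:
        on_g = [q for q in qtls if genome_of(q.chromosome) == g]
        if not on_g:
            continue
        row = {"pg": float(sum(q.pg_overall for q in on_g))}
        for f in fams:
            row[f"pg_{f}"] = float(sum(q.pg_family.get(f, 0.0) for q in on_g))
        rows[g] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "genome"
    if df.empty:
        df = pd.DataFrame(columns=["pg"] + [f"pg_{f}" for f in fams])
        df.index.name = "genome"
    return df


def overlap_frame(comparison: TraitComparison) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (chrom, qa.position, qa.ci_lo, qa.ci_hi,
             qb.position, qb.ci_lo, qb.ci_hi)
            for chrom, qa, qb in comparison.pairs
        ],
        columns=["chromosome", "pos_a", "ci_lo_a", "ci_hi_a",
                 "pos_b", "ci_lo_b", "ci_hi_b"],
    )
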