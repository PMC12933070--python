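"""Codon-usage-bias metrics, %MinMax profiles and benchmark ranking.

All codon-level metrics (relative adaptiveness w, CSI, rare-codon stats,
sequence identity, Jaccard similarity, %MinMax) are defined over sense codons;
terminal stop codons are stripped before scoring.  GC and GC3 are nucleotide
conventions: GC over the whole sequence, GC3 over third codon positions.

CSI — the geometric mean of per-codon relative adaptiveness w_k = x_k/x_max —
plays the role of a codon adaptation index computed directly from the host's
genome-wide usage table.  A codon is *rare* when its relative synonymous
frequency is below 0.3 and below the uniform-pick probability 1/|family|.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .corpus import CodonUsageTable
from .genetic_code import STANDARD_CODE, codons_of

RARE_THRESHOLD = 0.3


class UnscoredCodonError(ValueError):
    """A codon whose amino acid is unobserved (w undefined) in the table."""


def relative_adaptiveness(table: CodonUsageTable, codon: str) -> float:
    """w = x / x_family_max for a sense codon; in (0, 1], 1 for the family max."""
    aa = STANDARD_CODE.amino_acid(codon)
    if aa == "*":
        raise ValueError(f"stop codon {codon} has no relative adaptiveness")
    if aa in table.unobserved:
        raise UnscoredCodonError(f"amino acid {aa} unobserved in usage table")
    return table.w[(aa, codon)]


def csi(cds: str, table: CodonUsageTable, pseudocount: float = 0.0) -> float:
    """Codon Similarity Index: geometric mean of w over the sense codons.

    A codon never observed in the host table has w = 0 and an undefined log;
    this is reported with its position unless ``pseudocount`` > 0, in which
    case w is floored at that value.
    """
    codons = codons_of(cds)
    if not codons:
        raise ValueError("no sense codons in CDS")
    total = 0.0
    for k, codon in enumerate(codons):
        w = relative_adaptiveness(table, codon)
        if w <= 0.0:
            if pseudocount > 0.0:
                w = pseudocount
            else:
                raise UnscoredCodonError(
                    f"codon {codon} at position {k} has w=0 in the host table"
                )
        total += math.log(w)
    return math.exp(total / len(codons))


def gc_content(cds: str) -> float:
    """(G + C) / length over the full nucleotide sequence."""
    if not cds:
        raise ValueError("empty sequence")
    bad = set(cds) - set("ACGT")
    if bad:
        raise ValueError(f"invalid characters: {sorted(bad)}")
    return (cds.count("G") + cds.count("C")) / len(cds)


def gc3_content(cds: str) -> float:
    """Fraction of third codon positions that are G or C (stop excluded)."""
    codons = codons_of(cds)
    if not codons:
        raise ValueError("no sense codons in CDS")
    hits = sum(1 for c in codons if c[2] in "GC")
    return hits / len(codons)


def rare_codon_stats(cds: str, table: CodonUsageTable) -> Tuple[int, float]:
    """(count, fraction) of rare codons: x < 0.3 and x < Avg, both strict."""
    codons = codons_of(cds)
    if not codons:
        raise ValueError("no sense codons in CDS")
    count = 0
    for codon in codons:
        aa = STANDARD_CODE.amino_acid(codon)
        if aa in table.unobserved:
            raise UnscoredCodonError(f"amino acid {aa} unobserved in usage table")
        x = table.x[(aa, codon)]
        if x < RARE_THRESHOLD and x < table.Avg[aa]:
            count += 1
    return count, count / len(codons)


def sequence_identity(cds_x: str, cds_y: str) -> float:
    """Fraction of positions with the identical codon (codon granularity)."""
    cx, cy = codons_of(cds_x), codons_of(cds_y)
    if len(cx) != len(cy):
        raise ValueError(f"codon-length mismatch: {len(cx)} vs {len(cy)}")
    if not cx:
        raise ValueError("empty sequences")
    return sum(a == b for a, b in zip(cx, cy)) / len(cx)


def jaccard_similarity(cds_x: str, cds_y: str) -> float:
    """|A∩B| / |A∪B| over the sets of unique sense codons used."""
    a, b = set(codons_of(cds_x)), set(codons_of(cds_y))
    if not a or not b:
        raise ValueError("empty sequence")
    return len(a & b) / len(a | b)


# ---------------------------------------------------------------------------
# %MinMax
# ---------------------------------------------------------------------------

@dataclass
class MinMaxProfile:
    """Sliding-window %MinMax scores along a CDS.

    Positive scores mark clusters of frequently used codons (+100 = every
    window codon is its family's most frequent), negative scores clusters of
    rare codons; 0 means the window's actual usage equals the family average.
    """

    window_size: int
    scores: List[float]
    positions: List[int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"center_codon": self.positions, "minmax": self.scores})


def minmax_profile(
    cds: str, table: CodonUsageTable, window_size: int = 17
) -> MinMaxProfile:
    """%MinMax over sliding windows of ``window_size`` codons (default 17).

    Per window: with X_actual/X_max/X_min/X_avg the window means of the actual
    codon frequency, family maximum, family minimum and family mean, the score
    is +100·(X_actual−X_avg)/(X_max−X_avg) when X_actual > X_avg, otherwise
    −100·(X_avg−X_actual)/(X_avg−X_min); 0 when actual equals average.
    """
    if window_size < 1 or window_size % 2 == 0:
        raise ValueError("window_size must be an odd positive integer")
    codons = codons_of(cds)
    n = len(codons)
    if n < window_size:
        raise ValueError(f"sequence has {n} codons < window {window_size}")
    actual = np.empty(n)
    fmax = np.empty(n)
    fmin = np.empty(n)
    favg = np.empty(n)
    for k, codon in enumerate(codons):
        aa = STANDARD_CODE.amino_acid(codon)
        if aa in table.unobserved:
            raise UnscoredCodonError(f"amino acid {aa} unobserved in usage table")
        fam = sorted(STANDARD_CODE.synonymous_codons(aa))
        xs = [table.x[(aa, c)] for c in fam]
        actual[k] = table.x[(aa, codon)]
        fmax[k] = max(xs)
        fmin[k] = min(xs)
        favg[k] = sum(xs) / len(xs)
    scores: List[float] = []
    positions: List[int] = []
    half = window_size // 2
    for start in range(n - window_size + 1):
        sl = slice(start, start + window_size)
        xa, xmx, xmn, xav = (
            actual[sl].mean(), fmax[sl].mean(), fmin[sl].mean(), favg[sl].mean(),
        )
        if xa > xav:
            score = 100.0 * (xa - xav) / (xmx - xav)
        elif xa < xav:
            score = -100.0 * (xav - xa) / (xav - xmn)
        else:
            score = 0.0
        scores.append(score)
        positions.append(start + half)
    return MinMaxProfile(window_size=window_size, scores=scores, positions=positions)


# ---------------------------------------------------------------------------
# Benchmark ranking
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkTable:
    """Outcome values (e.g. titers): rows = proteins, columns = algorithms."""

    titers: pd.DataFrame
    optical_density: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.titers.isna().any().any():
            raise ValueError("missing cells in outcome table")
        if (self.titers.values < 0).any():
            raise ValueError("negative outcome values")
        if self.optical_density is not None and (
            self.optical_density.shape != self.titers.shape
        ):
            raise ValueError("optical-density matrix shape mismatch")


def benchmark_rank(bt: BenchmarkTable) -> pd.DataFrame:
    """Per-algorithm #BestTiter and AggregatedScore (row-normalized sums).

    #BestTiter counts the proteins for which the algorithm attains the row
    maximum (ties credit every tied algorithm); AggregatedScore sums each
    row's values normalized to the row maximum, so it is bounded by the number
    of proteins.  When optical densities are supplied a ``specific
    productivity`` (titer/OD) matrix is attached as ``result.attrs``.
    """
    t = bt.titers
    if t.shape[0] < 1 or t.shape[1] < 2:
        raise ValueError("need ≥1 protein and ≥2 algorithms")
    row_max = t.max(axis=1)
    if (row_max == 0).any():
        bad = list(t.index[row_max == 0])
        raise ValueError(f"all-zero outcome row(s): {bad}")
    norm = t.div(row_max, axis=0)
    best = norm.eq(1.0)
    out = pd.DataFrame(
        {
            "best_titer_count": best.sum(axis=0).astype(int),
            "aggregated_score": norm.sum(axis=0),
        }
    )
    out.index.name = "algorithm"
    if bt.optical_density is not None:
        out.attrs["specific_productivity"] = bt.titers / bt.optical_density
    return out


def metric_outcome_correlations(
    metrics: pd.DataFrame, outcome: Sequence[float], method: str = "pearson"
) -> pd.Series:
    """Correlation of each metric column against the outcome vector.

    ``method`` is "pearson" (default) or "spearman".  Zero-variance columns
    are reported as NaN (undefined), never coerced to 0.
    """
    y = np.asarray(outcome, dtype=float)
    if len(y) < 3 or metrics.shape[0] != len(y):
        raise ValueError("need ≥3 constructs and matching row counts")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    fn = _stats.pearsonr if method == "pearson" else _stats.spearmanr
    vals = {}
    for col in metrics.columns:
        x = metrics[col].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            vals[col] = float("nan")
        else:
            vals[col] = float(fn(x, y)[0])
    return pd.Series(vals, name=f"{method}_r")


def sequence_report(
    records: Sequence[Tuple[str, str]], table: CodonUsageTable
) -> pd.DataFrame:
    """Per-sequence metric table (csi, gc, gc3, rare count/fraction)."""
    rows = []
    for rid, cds in records:
        count, frac = rare_codon_stats(cds, table)
        rows.append(
            {
                "id": rid,
                "n_codons": len(codons_of(cds)),
                "csi": csi(cds, table),
                "gc": gc_content(cds),
                "gc3": gc3_content(cds),
                "rare_count": count,
                "rare_fraction": frac,
            }
        )
    return pd.DataFrame(rows).set_index("id")


def pairwise_matrices(
    records: Sequence[Tuple[str, str]]
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """All-vs-all codon identity and Jaccard similarity matrices."""
    ids = [rid for rid, _ in records]
    n = len(ids)
    ident = np.ones((n, n))
    jac = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident[i, j] = ident[j, i] = sequence_identity(records[i][1], records[j][1])
            jac[i, j] = jac[j, i] = jaccard_similarity(records[i][1], records[j][1])
    return (
        pd.DataFrame(ident, index=ids, columns=ids),
        pd.DataFrame(jac, index=ids, columns=ids),
    )
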