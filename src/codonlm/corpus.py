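"""Paired protein/CDS corpus: parsing, validation, tokenization, splitting.

The training unit is a :class:`SequencePair` — one protein with its verified
coding sequence.  Terminal stop codons are kept on the stored CDS (the decoder
must learn to emit them) but are excluded from codon-usage counting and from
every downstream codon-usage-bias metric, which are defined over sense codons.
"""

from __future__ import annotations

import collections
import functools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from Bio import SeqIO

from .genetic_code import (
    AMINO_ACIDS,
    SENSE_CODONS,
    STANDARD_CODE,
    STOP_CODONS,
    Verdict,
    codons_of,
    normalize_dna,
    validate_cds,
)

logger = logging.getLogger("codonlm")

START, END, PAD = "<START>", "<END>", "<PAD>"

#: Stop codon appended to the token track when the source CDS lacks one;
#: TAA is the most common stop in yeast genomes.
DEFAULT_STOP = "TAA"


@dataclass(frozen=True)
class SequencePair:
    """One protein sequence and its validated coding sequence."""

    id: str
    protein: str
    cds: str
    source: str = ""

    def __post_init__(self) -> None:
        verdict = validate_cds(self.cds, self.protein)
        if not verdict.ok:
            raise ValueError(f"invalid pair {self.id!r}: {verdict.value}")


@dataclass(frozen=True)
class TokenVocabulary:
    """Dense, 0-based, stable token indexing for both sequence tracks.

    Amino-acid track: the 20 canonical residues (alphabetical), then
    ``<START>``, ``<END>``, ``<PAD>`` (23 tokens).  Codon track: the 61 sense
    codons (alphabetical), the 3 stop codons, then ``<START>``, ``<PAD>``
    (66 tokens).  ``<PAD>`` always holds the final index on each track so it
    can be masked out of the loss.
    """

    aa_tokens: Tuple[str, ...]
    codon_tokens: Tuple[str, ...]

    @classmethod
    def standard(cls) -> "TokenVocabulary":
        aa = tuple(AMINO_ACIDS) + (START, END, PAD)
        codon = SENSE_CODONS + tuple(sorted(STOP_CODONS)) + (START, PAD)
        return cls(aa_tokens=aa, codon_tokens=codon)

    @functools.cached_property
    def aa_index(self) -> Dict[str, int]:
        return {t: i for i, t in enumerate(self.aa_tokens)}

    @functools.cached_property
    def codon_index(self) -> Dict[str, int]:
        return {t: i for i, t in enumerate(self.codon_tokens)}

    @property
    def aa_pad(self) -> int:
        return len(self.aa_tokens) - 1

    @property
    def codon_pad(self) -> int:
        return len(self.codon_tokens) - 1

    def to_dict(self) -> dict:
        return {"aa_tokens": list(self.aa_tokens), "codon_tokens": list(self.codon_tokens)}

    @classmethod
    def from_dict(cls, d: dict) -> "TokenVocabulary":
        return cls(aa_tokens=tuple(d["aa_tokens"]), codon_tokens=tuple(d["codon_tokens"]))


@dataclass
class RejectionRecord:
    id: str
    rule: str


def _first_token(header: str) -> str:
    return header.split()[0] if header.split() else header


def build_pairs(
    cds_fasta: Path | str,
    protein_fasta: Optional[Path | str] = None,
    source: str = "",
    deduplicate: bool = True,
) -> Tuple[List[SequencePair], List[RejectionRecord]]:
    """Read CDS (and optionally protein) FASTA into validated pairs.

    When ``protein_fasta`` is absent, proteins are derived by translation.
    Records failing any hygiene rule (non-triplet, ambiguous base, internal
    stop, translation mismatch, unmatched identifier, non-canonical residue)
    are logged with the failed rule rather than raised.  Identical
    (protein, cds) duplicates are removed to prevent train/test leakage.
    """
    cds_records = list(SeqIO.parse(str(cds_fasta), "fasta"))
    if not cds_records:
        raise ValueError(f"no FASTA records in {cds_fasta}")

    proteins: Optional[Dict[str, str]] = None
    if protein_fasta is not None:
        proteins = {
            _first_token(rec.id): str(rec.seq).upper().rstrip("*")
            for rec in SeqIO.parse(str(protein_fasta), "fasta")
        }

    pairs: List[SequencePair] = []
    rejections: List[RejectionRecord] = []
    seen: set = set()
    for rec in cds_records:
        rid = _first_token(rec.id)
        cds = normalize_dna(str(rec.seq))
        if proteins is not None:
            if rid not in proteins:
                rejections.append(RejectionRecord(rid, "unmatched identifier"))
                continue
            protein = proteins[rid]
            verdict = validate_cds(cds, protein)
            if not verdict.ok:
                rejections.append(RejectionRecord(rid, verdict.value))
                continue
        else:
            try:
                protein = STANDARD_CODE.translate(cds)
            except Exception:
                verdict = validate_cds(cds, "")
                rule = verdict.value if not verdict.ok else "untranslatable"
                rejections.append(RejectionRecord(rid, rule))
                continue
            if not protein:
                rejections.append(RejectionRecord(rid, "empty translation"))
                continue
        if deduplicate and (protein, cds) in seen:
            rejections.append(RejectionRecord(rid, "duplicate pair"))
            continue
        seen.add((protein, cds))
        pairs.append(SequencePair(id=rid, protein=protein, cds=cds, source=source))

    if not pairs:
        raise ValueError(f"zero surviving pairs from {cds_fasta}")
    logger.info("build_pairs: %d pairs, %d rejections", len(pairs), len(rejections))
    return pairs, rejections


def write_rejection_log(rejections: Sequence[RejectionRecord], path: Path | str) -> None:
    with open(path, "w") as fh:
        fh.write("id\trule\n")
        for r in rejections:
            fh.write(f"{r.id}\t{r.rule}\n")


# ---------------------------------------------------------------------------
# Tokenization
# ---------------------------------------------------------------------------

def tokenize_pair(
    pair: SequencePair, vocab: TokenVocabulary, max_len: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Encode one pair as aligned integer tracks of length ``max_len``.

    Amino-acid track: ``<START>`` residues ``<END>`` then padding.  Codon
    track: ``<START>`` codons (with a terminal stop appended when the source
    CDS lacks one) then padding.  Both tracks need ``len(protein) + 2`` slots.
    """
    L = len(pair.protein)
    if L + 2 > max_len:
        raise ValueError(f"pair {pair.id!r}: length {L}+2 exceeds max_len={max_len}")
    aa_idx = vocab.aa_index
    codon_idx = vocab.codon_index

    aa_track = [aa_idx[START]]
    for sym in pair.protein:
        aa_track.append(aa_idx[sym])
    aa_track.append(aa_idx[END])
    aa_track.extend([vocab.aa_pad] * (max_len - len(aa_track)))

    codons = codons_of(pair.cds, drop_terminal_stop=False)
    if codons[-1] not in STOP_CODONS:
        logger.debug("pair %s lacks terminal stop; appending %s", pair.id, DEFAULT_STOP)
        codons = codons + [DEFAULT_STOP]
    codon_track = [codon_idx[START]]
    codon_track.extend(codon_idx[c] for c in codons)
    codon_track.extend([vocab.codon_pad] * (max_len - len(codon_track)))
    return np.asarray(aa_track, dtype=np.int64), np.asarray(codon_track, dtype=np.int64)


def detokenize(
    aa_track: np.ndarray, codon_track: np.ndarray, vocab: TokenVocabulary
) -> Tuple[str, str]:
    """Exact inverse of :func:`tokenize_pair` over non-pad positions."""
    aa_syms = [vocab.aa_tokens[i] for i in aa_track if i != vocab.aa_pad]
    if aa_syms[0] != START or aa_syms[-1] != END:
        raise ValueError("amino-acid track missing <START>/<END> frame")
    protein = "".join(aa_syms[1:-1])
    codon_syms = [vocab.codon_tokens[i] for i in codon_track if i != vocab.codon_pad]
    if codon_syms[0] != START:
        raise ValueError("codon track missing <START>")
    cds = "".join(codon_syms[1:])
    return protein, cds


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

@dataclass
class CorpusSplit:
    """Disjoint train/validation/test partition of a corpus, seeded."""

    train: List[SequencePair]
    validation: List[SequencePair]
    test: List[SequencePair]
    seed: int

    @property
    def all_pairs(self) -> List[SequencePair]:
        return self.train + self.validation + self.test


def split_corpus(pairs: Sequence[SequencePair], seed: int) -> CorpusSplit:
    """80/20 train/test split, then 20% of the training portion as validation.

    Sizes are ``ceil(0.2 N)`` test and ``ceil(0.2 (N - test))`` validation;
    sampling is uniform without replacement and reproducible under ``seed``.
    """
    n = len(pairs)
    if n < 5:
        raise ValueError(f"need at least 5 pairs to split, got {n}")
    n_test = math.ceil(0.2 * n)
    n_val = math.ceil(0.2 * (n - n_test))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    test = [pairs[i] for i in order[:n_test]]
    validation = [pairs[i] for i in order[n_test : n_test + n_val]]
    train = [pairs[i] for i in order[n_test + n_val :]]
    return CorpusSplit(train=train, validation=validation, test=test, seed=seed)


def internal_split(pairs: Sequence[SequencePair], seed: int) -> Tuple[List[SequencePair], List[SequencePair]]:
    """20% validation carve-out used by the full-data refit (no test set)."""
    n = len(pairs)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    n_val = math.ceil(0.2 * n)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    validation = [pairs[i] for i in order[:n_val]]
    train = [pairs[i] for i in order[n_val:]]
    return train, validation


# ---------------------------------------------------------------------------
# Codon usage table
# ---------------------------------------------------------------------------

@dataclass
class CodonUsageTable:
    """Per-amino-acid relative synonymous codon frequencies and weights.

    ``x[(aa, codon)]`` is codon ``codon``'s share among the synonymous codons
    of ``aa`` (rows sum to 1); ``w[(aa, codon)] = x / max_family_x`` is the
    relative adaptiveness; ``Avg[aa] = 1/|family|`` is the uniform-pick
    probability.  Amino acids never observed in the corpus are listed in
    ``unobserved`` and have no x/w rows.
    """

    counts: Dict[Tuple[str, str], int]
    x: Dict[Tuple[str, str], float]
    w: Dict[Tuple[str, str], float]
    Avg: Dict[str, float]
    unobserved: frozenset = frozenset()

    def observed_amino_acids(self) -> List[str]:
        return [aa for aa in AMINO_ACIDS if aa not in self.unobserved]

    def frequency(self, codon: str) -> float:
        aa = STANDARD_CODE.amino_acid(codon)
        if aa == "*":
            raise ValueError(f"stop codon {codon} has no usage-table row")
        if aa in self.unobserved:
            raise KeyError(f"amino acid {aa} unobserved in usage table")
        return self.x[(aa, codon)]

    def to_frame(self):
        import pandas as pd

        rows = []
        for aa in AMINO_ACIDS:
            for codon in sorted(STANDARD_CODE.synonymous_codons(aa)):
                rows.append(
                    {
                        "amino_acid": aa,
                        "codon": codon,
                        "count": self.counts.get((aa, codon), 0),
                        "x": self.x.get((aa, codon), float("nan")),
                        "w": self.w.get((aa, codon), float("nan")),
                        "Avg": self.Avg[aa],
                    }
                )
        return pd.DataFrame(rows)

    def to_tsv(self, path: Path | str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: Path | str) -> "CodonUsageTable":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        counts: Dict[Tuple[str, str], int] = {}
        x: Dict[Tuple[str, str], float] = {}
        w: Dict[Tuple[str, str], float] = {}
        Avg: Dict[str, float] = {}
        observed = set()
        for row in df.itertuples(index=False):
            key = (row.amino_acid, row.codon)
            counts[key] = int(row.count)
            Avg[row.amino_acid] = float(row.Avg)
            if not (isinstance(row.x, float) and math.isnan(row.x)):
                x[key] = float(row.x)
                w[key] = float(row.w)
                observed.add(row.amino_acid)
        unobserved = frozenset(set(AMINO_ACIDS) - observed)
        return cls(counts=counts, x=x, w=w, Avg=Avg, unobserved=unobserved)


def compute_usage_table(pairs: Iterable[SequencePair]) -> CodonUsageTable:
    """Count sense codons across a corpus and derive x, w and Avg.

    Terminal stop codons are excluded — usage and every downstream metric are
    defined over sense codons only.
    """
    counter: collections.Counter = collections.Counter()
    n_pairs = 0
    for pair in pairs:
        n_pairs += 1
        for codon in codons_of(pair.cds, drop_terminal_stop=True):
            counter[codon] += 1
    if n_pairs == 0:
        raise ValueError("empty corpus")

    counts: Dict[Tuple[str, str], int] = {}
    x: Dict[Tuple[str, str], float] = {}
    w: Dict[Tuple[str, str], float] = {}
    Avg: Dict[str, float] = {}
    unobserved = set()
    for aa in AMINO_ACIDS:
        family = sorted(STANDARD_CODE.synonymous_codons(aa))
        Avg[aa] = 1.0 / len(family)
        fam_counts = {c: counter.get(c, 0) for c in family}
        total = sum(fam_counts.values())
        for c, k in fam_counts.items():
            counts[(aa, c)] = k
        if total == 0:
            unobserved.add(aa)
            continue
        fam_x = {c: k / total for c, k in fam_counts.items()}
        x_max = max(fam_x.values())
        for c, xc in fam_x.items():
            x[(aa, c)] = xc
            w[(aa, c)] = xc / x_max
    return CodonUsageTable(
        counts=counts, x=x, w=w, Avg=Avg, unobserved=frozenset(unobserved)
    )


def default_max_len(pairs: Sequence[SequencePair]) -> int:
    """Longest protein plus the <START>/<END> frame."""
    return max(len(p.protein) for p in pairs) + 2


def write_fasta(records: Iterable[Tuple[str, str]], path: Path | str, width: int = 70) -> None:
    """Write (id, sequence) records as wrapped FASTA."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
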