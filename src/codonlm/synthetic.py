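"""Synthetic paired protein/CDS corpora with controllable codon usage.

Stands in for a real genome's CDS–protein pairs so the whole pipeline is
testable without downloads.  Proteins are sampled i.i.d. from an amino-acid
composition; codons are drawn either from a per-residue distribution
(order 0, a pure frequency sampler) or from a distribution conditioned on the
*previous residue* (order 1).  The order-1 conditioning is deliberately on the
neighbouring amino acid — visible to a sequence encoder but invisible to any
context-free frequency method — so a model that beats the unigram Bayes bound
on such a corpus has demonstrably learned context.

:func:`bayes_optimal_accuracy` computes the exact expected per-codon accuracy
of the best possible predictor given the generator, the yardstick every
accuracy claim in the test-suite is measured against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np

from .corpus import SequencePair, write_fasta
from .genetic_code import AMINO_ACIDS, STANDARD_CODE

#: context symbol for the first residue (no previous residue exists)
START_CONTEXT = "^"


def _family(aa: str) -> List[str]:
    return sorted(STANDARD_CODE.synonymous_codons(aa))


def _validate_dist(name: str, probs: Mapping[str, float], support: List[str]) -> None:
    if set(probs) != set(support):
        raise ValueError(f"{name}: support mismatch")
    arr = np.array([probs[c] for c in support])
    if (arr < 0).any() or abs(arr.sum() - 1.0) > 1e-12:
        raise ValueError(f"{name}: not a probability vector (sum={arr.sum()})")


@dataclass(frozen=True)
class CodonModel:
    """Synonymous-codon choice model of order 0 or 1.

    Order 0: ``probs[aa]`` is a distribution over the family of ``aa``.
    Order 1: ``probs[(context, aa)]`` with context every amino acid plus
    :data:`START_CONTEXT` for the first residue.
    """

    order: int
    probs: Mapping

    def __post_init__(self) -> None:
        if self.order not in (0, 1):
            raise ValueError("order must be 0 or 1")
        if self.order == 0:
            for aa in AMINO_ACIDS:
                _validate_dist(f"p({aa})", self.probs[aa], _family(aa))
        else:
            contexts = list(AMINO_ACIDS) + [START_CONTEXT]
            for ctx in contexts:
                for aa in AMINO_ACIDS:
                    _validate_dist(f"p({aa}|{ctx})", self.probs[(ctx, aa)], _family(aa))

    def distribution(self, aa: str, context: Optional[str] = None) -> Dict[str, float]:
        if self.order == 0:
            return dict(self.probs[aa])
        ctx = context if context is not None else START_CONTEXT
        return dict(self.probs[(ctx, aa)])

    def to_dict(self) -> dict:
        if self.order == 0:
            return {"order": 0, "probs": {aa: self.probs[aa] for aa in AMINO_ACIDS}}
        return {
            "order": 1,
            "probs": {f"{ctx}|{aa}": d for (ctx, aa), d in self.probs.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CodonModel":
        if d["order"] == 0:
            return cls(order=0, probs=d["probs"])
        probs = {}
        for key, dist in d["probs"].items():
            ctx, aa = key.split("|")
            probs[(ctx, aa)] = dist
        return cls(order=1, probs=probs)


# -- model factories ---------------------------------------------------------

def uniform_codon_model() -> CodonModel:
    """Every synonymous codon equally likely (no usage bias at all)."""
    probs = {aa: {c: 1.0 / len(_family(aa)) for c in _family(aa)} for aa in AMINO_ACIDS}
    return CodonModel(order=0, probs=probs)


def biased_codon_model(strength: float = 2.0) -> CodonModel:
    """Order-0 bias: within each family p_k ∝ strength^{-k} (geometric decay)."""
    if strength <= 1.0:
        raise ValueError("strength must exceed 1")
    probs = {}
    for aa in AMINO_ACIDS:
        fam = _family(aa)
        raw = np.array([strength ** -k for k in range(len(fam))])
        raw /= raw.sum()
        probs[aa] = {c: float(p) for c, p in zip(fam, raw)}
    return CodonModel(order=0, probs=probs)


def deterministic_codon_model(offset: int = 0) -> CodonModel:
    """Exactly one codon per amino acid (the ``offset``-th family member)."""
    probs = {}
    for aa in AMINO_ACIDS:
        fam = _family(aa)
        pick = fam[offset % len(fam)]
        probs[aa] = {c: 1.0 if c == pick else 0.0 for c in fam}
    return CodonModel(order=0, probs=probs)


def context_codon_model(p_major: float = 0.9) -> CodonModel:
    """Order-1 model: the preferred codon rotates with the previous residue.

    For amino acid ``aa`` (index i) after context residue r (index j) the
    family member at position (i + j) mod |family| receives probability
    ``p_major``; the rest share the remainder uniformly.  The first-residue
    context row is the uniform-context marginal, so no context carries
    information at position 0.
    """
    if not 0.0 < p_major <= 1.0:
        raise ValueError("p_major must be in (0, 1]")
    probs: Dict[Tuple[str, str], Dict[str, float]] = {}
    for i, aa in enumerate(AMINO_ACIDS):
        fam = _family(aa)
        k = len(fam)
        rows = []
        for j, ctx in enumerate(AMINO_ACIDS):
            if k == 1:
                row = {fam[0]: 1.0}
            else:
                rest = (1.0 - p_major) / (k - 1)
                row = {c: rest for c in fam}
                row[fam[(i + j) % k]] = p_major
            probs[(ctx, aa)] = row
            rows.append(row)
        probs[(START_CONTEXT, aa)] = {
            c: float(np.mean([r[c] for r in rows])) for c in fam
        }
    return CodonModel(order=1, probs=probs)


# -- spec and generation -----------------------------------------------------

@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Conditions of a simulated CDS corpus.

    Defaults are the standard fixture: 2,000 sequences of 30–120 residues with
    uniform amino-acid composition and the order-1 context model at
    ``p_major = 0.9`` — small enough to train the codon language model to
    convergence in minutes on one CPU, structured enough that context
    learning is detectable against the unigram bound.
    """

    n_sequences: int = 2000
    min_length: int = 30
    max_length: int = 120
    aa_composition: Tuple[float, ...] = tuple([1.0 / 20] * 20)
    codon_model: CodonModel = field(default_factory=context_codon_model)
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be positive")
        if not 1 <= self.min_length <= self.max_length:
            raise ValueError("need 1 <= min_length <= max_length")
        comp = np.asarray(self.aa_composition)
        if comp.shape != (20,) or (comp < 0).any() or abs(comp.sum() - 1.0) > 1e-12:
            raise ValueError("aa_composition must be a 20-vector summing to 1")
        if (comp == 0).all():
            raise ValueError("degenerate composition")

    def to_json(self, path: Path | str) -> None:
        doc = {
            "n_sequences": self.n_sequences,
            "min_length": self.min_length,
            "max_length": self.max_length,
            "aa_composition": list(self.aa_composition),
            "codon_model": self.codon_model.to_dict(),
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: Path | str) -> "SyntheticGenomeSpec":
        doc = json.loads(Path(path).read_text())
        return cls(
            n_sequences=doc["n_sequences"],
            min_length=doc["min_length"],
            max_length=doc["max_length"],
            aa_composition=tuple(doc["aa_composition"]),
            codon_model=CodonModel.from_dict(doc["codon_model"]),
            seed=doc["seed"],
        )


def generate_corpus(spec: SyntheticGenomeSpec) -> List[SequencePair]:
    """Sample a corpus; every pair passes CDS validation, terminal TAA appended.

    Reproducible: identical spec (including seed) yields identical pairs.
    """
    rng = np.random.default_rng(spec.seed)
    comp = np.asarray(spec.aa_composition)
    aa_arr = np.array(list(AMINO_ACIDS))
    pairs: List[SequencePair] = []
    for i in range(spec.n_sequences):
        L = int(rng.integers(spec.min_length, spec.max_length + 1))
        residues = aa_arr[rng.choice(20, size=L, p=comp)]
        codons = []
        prev: Optional[str] = None
        for sym in residues:
            dist = spec.codon_model.distribution(sym, context=prev)
            fam = sorted(dist)
            p = np.array([dist[c] for c in fam])
            codons.append(fam[int(rng.choice(len(fam), p=p))])
            prev = sym
        protein = "".join(residues)
        cds = "".join(codons) + "TAA"
        pairs.append(SequencePair(id=f"syn_{i:05d}", protein=protein, cds=cds, source="synthetic"))
    return pairs


def write_corpus_fasta(
    pairs: List[SequencePair], cds_path: Path | str, protein_path: Path | str
) -> None:
    """Write the corpus as a standard paired FASTA (CDS + protein)."""
    write_fasta([(p.id, p.cds) for p in pairs], cds_path)
    write_fasta([(p.id, p.protein) for p in pairs], protein_path)


# -- Bayes oracle ------------------------------------------------------------

def _mean_inverse_length(spec: SyntheticGenomeSpec) -> float:
    lengths = np.arange(spec.min_length, spec.max_length + 1)
    return float(np.mean(1.0 / lengths))


def bayes_optimal_accuracy(
    spec: SyntheticGenomeSpec, order: Optional[int] = None
) -> float:
    """Expected per-codon accuracy of the optimal predictor for ``spec``.

    ``order=None`` gives the full-information oracle (it sees whatever context
    the generator used).  ``order=0`` forces a context-free (unigram)
    predictor — on an order-1 generator this is the frequency-method ceiling
    that a context-aware model must beat.  Positions are weighted exactly:
    the first residue (start context) contributes E[1/L] of positions.
    """
    comp = np.asarray(spec.aa_composition)
    model = spec.codon_model
    if order is None:
        order = model.order
    f_first = _mean_inverse_length(spec)

    if model.order == 0:
        # context carries no information; both predictors coincide
        return float(
            sum(q * max(model.probs[aa].values()) for q, aa in zip(comp, AMINO_ACIDS))
        )

    if order == 1:
        acc_rest = 0.0
        for qc, ctx in zip(comp, AMINO_ACIDS):
            for q, aa in zip(comp, AMINO_ACIDS):
                acc_rest += qc * q * max(model.probs[(ctx, aa)].values())
        acc_first = sum(
            q * max(model.probs[(START_CONTEXT, aa)].values())
            for q, aa in zip(comp, AMINO_ACIDS)
        )
        return float(f_first * acc_first + (1.0 - f_first) * acc_rest)

    # unigram bound of an order-1 generator: marginalise the context away
    acc = 0.0
    for q, aa in zip(comp, AMINO_ACIDS):
        fam = _family(aa)
        marg = {}
        for c in fam:
            rest = sum(
                qc * model.probs[(ctx, aa)][c] for qc, ctx in zip(comp, AMINO_ACIDS)
            )
            first = model.probs[(START_CONTEXT, aa)][c]
            marg[c] = f_first * first + (1.0 - f_first) * rest
        acc += q * max(marg.values())
    return float(acc)


def default_fixture_spec(seed: int = 7) -> SyntheticGenomeSpec:
    """The standard order-1 training fixture (2,000 pairs, 30–120 residues)."""
    return SyntheticGenomeSpec(seed=seed)
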