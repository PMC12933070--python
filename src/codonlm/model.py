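"""GRU encoder–decoder codon language model.

The model learns a host's amino-acid→codon mapping from paired protein/CDS
data.  A bidirectional GRU encoder turns the amino-acid sequence (framed by
<START>/<END>) into one context vector per position; the decoder combines the
embedding of the previous codon (through a codon-side dense layer) with the
position-aligned encoder context (through an amino-acid-side dense layer) and
feeds the pair through a unidirectional GRU and a softmax projection over the
codon vocabulary.  Because one codon is emitted per residue the coupling is
strictly position-aligned; no attention is used.

Training uses teacher forcing with a pad-masked categorical cross-entropy on
integer codon targets and early stopping on validation loss; generation is
greedy and autoregressive, by default constrained to the synonymous family of
the current residue so the output back-translates exactly.

Everything is plain numpy with hand-written backpropagation through time —
the networks involved are small enough that single-threaded CPU training
converges in minutes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .corpus import (
    END,
    PAD,
    START,
    CorpusSplit,
    SequencePair,
    TokenVocabulary,
    internal_split,
    tokenize_pair,
)
from .genetic_code import STANDARD_CODE, STOP_CODONS, UnknownResidueError

logger = logging.getLogger("codonlm")

DTYPE = np.float64


@dataclass
class ModelConfig:
    """Hyperparameters of the codon language model.

    The first five fields are the searchable architecture hyperparameters:
    the two embedding dimensions, the encoder width (per direction) and the
    two decoder dense-layer sizes.  The remainder control optimisation.
    """

    aa_embedding_dim: int = 16
    codon_embedding_dim: int = 16
    encoder_units: int = 32
    decoder_codon_dense_size: int = 32
    decoder_aa_dense_size: int = 32
    decoder_units: int = 64
    learning_rate: float = 3e-3
    batch_size: int = 32
    max_epochs: int = 100
    early_stop_patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "aa_embedding_dim",
            "codon_embedding_dim",
            "encoder_units",
            "decoder_codon_dense_size",
            "decoder_aa_dense_size",
            "decoder_units",
            "batch_size",
            "max_epochs",
            "early_stop_patience",
        ):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _glorot(rng: np.random.Generator, shape: Tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


# ---------------------------------------------------------------------------
# GRU layer (batched over time, pad positions carry the hidden state through)
# ---------------------------------------------------------------------------

def _gru_forward(X, mask, Wx, Wh, b, reverse=False):
    """Run a GRU over X (T, B, din); returns hidden states (T, B, U) + cache.

    Convention: h' = z*h + (1-z)*n with update gate z, reset gate r and
    candidate n = tanh(x W_n + (r*h) W_hn).  Masked (pad) steps leave the
    hidden state unchanged.
    """
    T, B, _ = X.shape
    U = Wh.shape[0]
    Whz, Whr, Whn = Wh[:, :U], Wh[:, U : 2 * U], Wh[:, 2 * U :]
    XP = X @ Wx + b
    h = np.zeros((B, U), dtype=DTYPE)
    H = np.empty((T, B, U), dtype=DTYPE)
    Hprev = np.empty_like(H)
    Z = np.empty_like(H)
    R = np.empty_like(H)
    N = np.empty_like(H)
    steps = range(T - 1, -1, -1) if reverse else range(T)
    for t in steps:
        xp = XP[t]
        z = _sigmoid(xp[:, :U] + h @ Whz)
        r = _sigmoid(xp[:, U : 2 * U] + h @ Whr)
        n = np.tanh(xp[:, 2 * U :] + (r * h) @ Whn)
        Hprev[t], Z[t], R[t], N[t] = h, z, r, n
        h_new = z * h + (1.0 - z) * n
        m = mask[t][:, None]
        h = m * h_new + (1.0 - m) * h
        H[t] = h
    cache = {"X": X, "Hprev": Hprev, "Z": Z, "R": R, "N": N, "mask": mask, "reverse": reverse}
    return H, cache


def _gru_backward(dH, cache, Wx, Wh):
    """Backpropagate through :func:`_gru_forward`; dH is (T, B, U)."""
    X = cache["X"]
    T, B, _ = X.shape
    U = Wh.shape[0]
    Whz, Whr, Whn = Wh[:, :U], Wh[:, U : 2 * U], Wh[:, 2 * U :]
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(3 * U, dtype=DTYPE)
    dX = np.empty_like(X)
    dh = np.zeros((B, U), dtype=DTYPE)
    steps = range(T) if cache["reverse"] else range(T - 1, -1, -1)
    for t in steps:
        dht = dh + dH[t]
        m = cache["mask"][t][:, None]
        h_prev, z, r, n = cache["Hprev"][t], cache["Z"][t], cache["R"][t], cache["N"][t]
        dh_new = dht * m
        dh_prev = dht * (1.0 - m) + dh_new * z
        dz = dh_new * (h_prev - n)
        dn = dh_new * (1.0 - z)
        dn_pre = dn * (1.0 - n * n)
        drh = dn_pre @ Whn.T
        dWh[:, 2 * U :] += (r * h_prev).T @ dn_pre
        dh_prev += drh * r
        dr = drh * h_prev
        dz_pre = dz * z * (1.0 - z)
        dr_pre = dr * r * (1.0 - r)
        dWh[:, :U] += h_prev.T @ dz_pre
        dh_prev += dz_pre @ Whz.T
        dWh[:, U : 2 * U] += h_prev.T @ dr_pre
        dh_prev += dr_pre @ Whr.T
        dxp = np.concatenate([dz_pre, dr_pre, dn_pre], axis=1)
        dWx += X[t].reshape(B, -1).T @ dxp
        db += dxp.sum(axis=0)
        dX[t] = dxp @ Wx.T
        dh = dh_prev
    return dX, dWx, dWh, db


def _gru_step(x, h, Wx, Wh, b):
    """Single inference step of the same GRU cell; x (B, din), h (B, U)."""
    U = Wh.shape[0]
    xp = x @ Wx + b
    z = _sigmoid(xp[:, :U] + h @ Wh[:, :U])
    r = _sigmoid(xp[:, U : 2 * U] + h @ Wh[:, U : 2 * U])
    n = np.tanh(xp[:, 2 * U :] + (r * h) @ Wh[:, 2 * U :])
    return z * h + (1.0 - z) * n


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class DecodeResult:
    cds: str
    early_terminated: bool = False


class CodonLM:
    """The encoder–decoder codon language model (see module docstring)."""

    def __init__(self, config: ModelConfig, vocab: TokenVocabulary):
        self.config = config
        self.vocab = vocab
        self.history: Dict[str, List[float]] = {}
        self.trained = False
        self.best_epoch: int = -1
        self.params = self._init_params()
        self._sense_stop_ids = np.array(
            [i for i, t in enumerate(vocab.codon_tokens) if t not in (START, PAD)],
            dtype=np.int64,
        )
        self._stop_ids = np.array(
            sorted(vocab.codon_index[c] for c in STOP_CODONS), dtype=np.int64
        )

    # -- construction -------------------------------------------------------

    def _init_params(self) -> Dict[str, np.ndarray]:
        c = self.config
        rng = np.random.default_rng(c.seed)
        Va, Vc = len(self.vocab.aa_tokens), len(self.vocab.codon_tokens)
        U, D = c.encoder_units, c.decoder_units
        Dc, Da = c.decoder_codon_dense_size, c.decoder_aa_dense_size
        p: Dict[str, np.ndarray] = {}
        p["Ea"] = (rng.standard_normal((Va, c.aa_embedding_dim)) * 0.1).astype(DTYPE)
        p["Ec"] = (rng.standard_normal((Vc, c.codon_embedding_dim)) * 0.1).astype(DTYPE)
        for side in ("enc_f", "enc_b"):
            p[f"{side}_Wx"] = _glorot(rng, (c.aa_embedding_dim, 3 * U))
            p[f"{side}_Wh"] = _glorot(rng, (U, 3 * U))
            p[f"{side}_b"] = np.zeros(3 * U, dtype=DTYPE)
        p["Wcd"] = _glorot(rng, (c.codon_embedding_dim, Dc))
        p["bcd"] = np.zeros(Dc, dtype=DTYPE)
        p["Wad"] = _glorot(rng, (2 * U, Da))
        p["bad"] = np.zeros(Da, dtype=DTYPE)
        p["dec_Wx"] = _glorot(rng, (Dc + Da, 3 * D))
        p["dec_Wh"] = _glorot(rng, (D, 3 * D))
        p["dec_b"] = np.zeros(3 * D, dtype=DTYPE)
        p["Wout"] = _glorot(rng, (D, Vc))
        p["bout"] = np.zeros(Vc, dtype=DTYPE)
        return p

    def num_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    # -- teacher-forced forward / backward ----------------------------------

    def _encode(self, aa: np.ndarray):
        """aa (B, Ta) int → per-position context H (Ta, B, 2U) + caches."""
        p = self.params
        aa_mask = (aa != self.vocab.aa_pad).astype(DTYPE).T
        Xa = p["Ea"][aa].transpose(1, 0, 2)
        Hf, cf = _gru_forward(Xa, aa_mask, p["enc_f_Wx"], p["enc_f_Wh"], p["enc_f_b"])
        Hb, cb = _gru_forward(
            Xa, aa_mask, p["enc_b_Wx"], p["enc_b_Wh"], p["enc_b_b"], reverse=True
        )
        H = np.concatenate([Hf, Hb], axis=2)
        return H, (cf, cb)

    def _forward_loss(self, aa, dec_in, targets, compute_grads=True):
        """Teacher-forced loss (+ gradients) on one padded batch.

        aa (B, Ta), dec_in (B, Td), targets (B, Td); Ta must be ≥ Td + 1 so
        decoder step t can read encoder position t+1 (residue t, or <END> for
        the terminal stop step).
        """
        p = self.params
        vocab = self.vocab
        B, Td = dec_in.shape
        U = self.config.encoder_units
        Dc = self.config.decoder_codon_dense_size

        H, (cf, cb) = self._encode(aa)
        C = H[1 : Td + 1]  # (Td, B, 2U), encoder context aligned to codon steps
        Xc = p["Ec"][dec_in].transpose(1, 0, 2)  # (Td, B, dc)
        U1p = Xc @ p["Wcd"] + p["bcd"]
        U1 = np.maximum(U1p, 0.0)
        U2p = C @ p["Wad"] + p["bad"]
        U2 = np.maximum(U2p, 0.0)
        Xd = np.concatenate([U1, U2], axis=2)
        dec_mask = (targets != vocab.codon_pad).astype(DTYPE).T  # (Td, B)
        Hd, cd = _gru_forward(Xd, dec_mask, p["dec_Wx"], p["dec_Wh"], p["dec_b"])
        logits = Hd @ p["Wout"] + p["bout"]  # (Td, B, Vc)

        tgt = targets.T  # (Td, B)
        logits_sh = logits - logits.max(axis=2, keepdims=True)
        expl = np.exp(logits_sh)
        P = expl / expl.sum(axis=2, keepdims=True)
        n_tok = dec_mask.sum()
        ar_t = np.arange(Td)[:, None]
        ar_b = np.arange(B)[None, :]
        safe_tgt = np.where(tgt == vocab.codon_pad, 0, tgt)
        logp = np.log(P[ar_t, ar_b, safe_tgt] + 1e-300)
        loss = float(-(logp * dec_mask).sum() / n_tok)
        pred = logits.argmax(axis=2)
        acc = float(((pred == tgt) * dec_mask).sum() / n_tok)
        if not compute_grads:
            return loss, acc, None

        g: Dict[str, np.ndarray] = {}
        dlogits = P.copy()
        dlogits[ar_t, ar_b, safe_tgt] -= 1.0
        dlogits *= dec_mask[:, :, None] / n_tok
        D = self.config.decoder_units
        Vc = len(vocab.codon_tokens)
        g["Wout"] = Hd.reshape(-1, D).T @ dlogits.reshape(-1, Vc)
        g["bout"] = dlogits.sum(axis=(0, 1))
        dHd = dlogits @ p["Wout"].T
        dXd, g["dec_Wx"], g["dec_Wh"], g["dec_b"] = _gru_backward(
            dHd, cd, p["dec_Wx"], p["dec_Wh"]
        )
        dU1 = dXd[:, :, :Dc] * (U1p > 0)
        dU2 = dXd[:, :, Dc:] * (U2p > 0)
        dc_dim = self.config.codon_embedding_dim
        g["Wcd"] = Xc.reshape(-1, dc_dim).T @ dU1.reshape(-1, Dc)
        g["bcd"] = dU1.sum(axis=(0, 1))
        dXc = dU1 @ p["Wcd"].T
        Da = self.config.decoder_aa_dense_size
        g["Wad"] = C.reshape(-1, 2 * U).T @ dU2.reshape(-1, Da)
        g["bad"] = dU2.sum(axis=(0, 1))
        dC = dU2 @ p["Wad"].T
        dH = np.zeros_like(H)
        dH[1 : Td + 1] = dC
        dXa_f, g["enc_f_Wx"], g["enc_f_Wh"], g["enc_f_b"] = _gru_backward(
            dH[:, :, :U], cf, p["enc_f_Wx"], p["enc_f_Wh"]
        )
        dXa_b, g["enc_b_Wx"], g["enc_b_Wh"], g["enc_b_b"] = _gru_backward(
            dH[:, :, U:], cb, p["enc_b_Wx"], p["enc_b_Wh"]
        )
        dXa = dXa_f + dXa_b
        g["Ea"] = np.zeros_like(p["Ea"])
        np.add.at(g["Ea"], aa, dXa.transpose(1, 0, 2))
        g["Ec"] = np.zeros_like(p["Ec"])
        np.add.at(g["Ec"], dec_in, dXc.transpose(1, 0, 2))
        return loss, acc, g

    # -- batching ------------------------------------------------------------

    def _batches(self, pairs: Sequence[SequencePair], rng: Optional[np.random.Generator]):
        """Length-sorted padded batches; batch order shuffled when rng given."""
        bs = self.config.batch_size
        order = sorted(range(len(pairs)), key=lambda i: len(pairs[i].protein))
        chunks = [order[i : i + bs] for i in range(0, len(order), bs)]
        if rng is not None:
            rng.shuffle(chunks)
        for chunk in chunks:
            Lmax = max(len(pairs[i].protein) for i in chunk)
            max_len = Lmax + 2
            aa = np.empty((len(chunk), max_len), dtype=np.int64)
            codon = np.empty((len(chunk), max_len), dtype=np.int64)
            for row, i in enumerate(chunk):
                aa[row], codon[row] = tokenize_pair(pairs[i], self.vocab, max_len)
            yield aa, codon[:, :-1], codon[:, 1:]

    def evaluate(self, pairs: Sequence[SequencePair]) -> Tuple[float, float]:
        """Teacher-forced (loss, token accuracy), token-weighted over pairs."""
        if not pairs:
            raise ValueError("empty pair list")
        tot_loss = tot_acc = tot_n = 0.0
        for aa, dec_in, tgt in self._batches(pairs, rng=None):
            n = float((tgt != self.vocab.codon_pad).sum())
            loss, acc, _ = self._forward_loss(aa, dec_in, tgt, compute_grads=False)
            tot_loss += loss * n
            tot_acc += acc * n
            tot_n += n
        return tot_loss / tot_n, tot_acc / tot_n

    # -- training ------------------------------------------------------------

    def fit(
        self,
        train_pairs: Sequence[SequencePair],
        val_pairs: Sequence[SequencePair],
        verbose: bool = False,
    ) -> "CodonLM":
        """Train with teacher forcing; early-stop on validation loss.

        Keeps the parameters of the best-validation epoch.  Reproducible:
        initialisation and batch shuffling both derive from ``config.seed``.
        """
        if not train_pairs or not val_pairs:
            raise ValueError("empty train or validation set")
        c = self.config
        rng = np.random.default_rng(c.seed + 1)
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(vv) for k, vv in self.params.items()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0
        best_val = np.inf
        best_params = None
        best_epoch = -1
        hist: Dict[str, List[float]] = {
            "train_loss": [],
            "val_loss": [],
            "val_accuracy": [],
        }
        for epoch in range(c.max_epochs):
            ep_loss = ep_n = 0.0
            for aa, dec_in, tgt in self._batches(train_pairs, rng):
                loss, _, grads = self._forward_loss(aa, dec_in, tgt)
                if not np.isfinite(loss):
                    raise FloatingPointError(f"non-finite loss at epoch {epoch}")
                gnorm = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
                scale = min(1.0, 5.0 / (gnorm + 1e-12))
                step += 1
                lr_t = c.learning_rate * np.sqrt(1 - b2 ** step) / (1 - b1 ** step)
                for k, gk in grads.items():
                    gk = gk * scale
                    m[k] = b1 * m[k] + (1 - b1) * gk
                    v[k] = b2 * v[k] + (1 - b2) * gk * gk
                    self.params[k] -= lr_t * m[k] / (np.sqrt(v[k]) + eps)
                n = float((tgt != self.vocab.codon_pad).sum())
                ep_loss += loss * n
                ep_n += n
            val_loss, val_acc = self.evaluate(val_pairs)
            hist["train_loss"].append(ep_loss / ep_n)
            hist["val_loss"].append(val_loss)
            hist["val_accuracy"].append(val_acc)
            if verbose:
                logger.info(
                    "epoch %d train_loss=%.4f val_loss=%.4f val_acc=%.4f",
                    epoch, ep_loss / ep_n, val_loss, val_acc,
                )
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_params = {k: p.copy() for k, p in self.params.items()}
                best_epoch = epoch
            elif epoch - best_epoch >= c.early_stop_patience:
                break
        if best_params is not None:
            self.params = best_params
        self.history = hist
        self.best_epoch = best_epoch
        self.trained = True
        return self

    # -- generation ----------------------------------------------------------

    def _decode_step(self, prev_idx: int, h: np.ndarray, c_t: np.ndarray):
        p = self.params
        u1 = np.maximum(p["Ec"][prev_idx][None, :] @ p["Wcd"] + p["bcd"], 0.0)
        u2 = np.maximum(c_t[None, :] @ p["Wad"] + p["bad"], 0.0)
        x = np.concatenate([u1, u2], axis=1)
        h = _gru_step(x, h, p["dec_Wx"], p["dec_Wh"], p["dec_b"])
        logits = (h @ p["Wout"] + p["bout"])[0]
        return h, logits

    def decode(self, protein: str, constrained: bool = True) -> DecodeResult:
        """Greedy autoregressive back-translation of ``protein``.

        Constrained mode restricts each step's argmax to the synonymous family
        of the current residue (so the result always translates back to the
        input) and the terminal step to the stop codons.  Unconstrained mode
        takes the global argmax; emitting a stop before the final position is
        reported as early termination with the truncated sequence.
        """
        for sym in protein:
            if sym not in STANDARD_CODE.families:
                raise UnknownResidueError(f"non-canonical residue {sym!r}")
        vocab = self.vocab
        aa_idx = vocab.aa_index
        aa = np.array(
            [[aa_idx[START], *(aa_idx[s] for s in protein), aa_idx[END]]],
            dtype=np.int64,
        )
        H, _ = self._encode(aa)  # (L+2, 1, 2U)
        h = np.zeros((1, self.config.decoder_units), dtype=DTYPE)
        prev = vocab.codon_index[START]
        codons: List[str] = []
        L = len(protein)
        for t in range(L + 1):
            h, logits = self._decode_step(prev, h, H[t + 1, 0])
            if t < L:
                if constrained:
                    fam = STANDARD_CODE.synonymous_codons(protein[t])
                    allowed = np.array(sorted(vocab.codon_index[c] for c in fam))
                else:
                    allowed = self._sense_stop_ids
            else:
                allowed = self._stop_ids
            pick = int(allowed[np.argmax(logits[allowed])])
            token = vocab.codon_tokens[pick]
            if t < L and token in STOP_CODONS:
                logger.warning("early stop codon at position %d of %d", t, L)
                return DecodeResult(cds="".join(codons) + token, early_terminated=True)
            codons.append(token)
            prev = pick
        return DecodeResult(cds="".join(codons), early_terminated=False)

    def optimize_sequence(self, protein: str, constrained: bool = True) -> str:
        """Codon-optimized CDS for ``protein`` (terminal stop codon included)."""
        return self.decode(protein, constrained=constrained).cds

    # -- evaluation in fully-predictive mode ---------------------------------

    def prediction_accuracy(
        self, pairs: Sequence[SequencePair]
    ) -> Tuple[np.ndarray, float]:
        """Per-sequence fraction of sense codons predicted exactly.

        Fully predictive: each step's previous-codon input is the model's own
        (unconstrained) prediction, not the reference codon.  Stop steps are
        not scored.  Returns (per-sequence vector, mean over sequences).
        """
        if not pairs:
            raise ValueError("empty pair list")
        vocab = self.vocab
        aa_idx = vocab.aa_index
        accs = np.empty(len(pairs))
        for i, pair in enumerate(pairs):
            L = len(pair.protein)
            aa = np.array(
                [[aa_idx[START], *(aa_idx[s] for s in pair.protein), aa_idx[END]]],
                dtype=np.int64,
            )
            H, _ = self._encode(aa)
            h = np.zeros((1, self.config.decoder_units), dtype=DTYPE)
            prev = vocab.codon_index[START]
            ref = [vocab.codon_index[pair.cds[3 * k : 3 * k + 3]] for k in range(L)]
            hits = 0
            for t in range(L):
                h, logits = self._decode_step(prev, h, H[t + 1, 0])
                allowed = self._sense_stop_ids
                pick = int(allowed[np.argmax(logits[allowed])])
                if pick == ref[t]:
                    hits += 1
                prev = pick
            accs[i] = hits / L
        return accs, float(accs.mean())

    # -- introspection -------------------------------------------------------

    def extract_embeddings(self):
        """The learned amino-acid and codon embedding tables, row-labelled.

        Returns two pandas DataFrames (index = token, columns = dim_0..) in
        vocabulary order, ready for external projection (e.g. UMAP).
        """
        if not self.trained:
            raise RuntimeError("model is untrained; embeddings are noise")
        import pandas as pd

        Ea, Ec = self.params["Ea"], self.params["Ec"]
        aa_df = pd.DataFrame(
            Ea, index=list(self.vocab.aa_tokens),
            columns=[f"dim_{j}" for j in range(Ea.shape[1])],
        )
        codon_df = pd.DataFrame(
            Ec, index=list(self.vocab.codon_tokens),
            columns=[f"dim_{j}" for j in range(Ec.shape[1])],
        )
        return aa_df, codon_df

    # -- persistence ----------------------------------------------------------

    def save(self, directory: Path | str) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savez(d / "weights.npz", **self.params)
        (d / "config.json").write_text(json.dumps(self.config.to_dict(), indent=1))
        (d / "vocab.json").write_text(json.dumps(self.vocab.to_dict(), indent=1))
        meta = {"trained": self.trained, "history": self.history}
        (d / "history.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, directory: Path | str) -> "CodonLM":
        d = Path(directory)
        config = ModelConfig.from_dict(json.loads((d / "config.json").read_text()))
        vocab = TokenVocabulary.from_dict(json.loads((d / "vocab.json").read_text()))
        model = cls(config, vocab)
        with np.load(d / "weights.npz") as npz:
            model.params = {k: npz[k].astype(DTYPE) for k in npz.files}
        meta = json.loads((d / "history.json").read_text())
        model.trained = meta["trained"]
        model.history = meta["history"]
        return model


# ---------------------------------------------------------------------------
# Convenience entry points
# ---------------------------------------------------------------------------

def build_model(config: ModelConfig, vocab: Optional[TokenVocabulary] = None) -> CodonLM:
    return CodonLM(config, vocab or TokenVocabulary.standard())


def train(config: ModelConfig, split: CorpusSplit, verbose: bool = False) -> CodonLM:
    """Train on a corpus split (train + validation; test untouched)."""
    model = build_model(config)
    return model.fit(split.train, split.validation, verbose=verbose)


def refit_full(
    config: ModelConfig, all_pairs: Sequence[SequencePair], verbose: bool = False
) -> CodonLM:
    """Final fit on the complete corpus; an internal 20% validation carve-out
    still drives early stopping (no test reservation)."""
    tr, val = internal_split(all_pairs, seed=config.seed)
    model = build_model(config)
    return model.fit(tr, val, verbose=verbose)
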