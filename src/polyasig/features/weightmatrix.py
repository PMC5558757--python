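"""Position-specific dinucleotide weight matrices and sequence log-odds scores."""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

DINUCLEOTIDES = tuple("".join(p) for p in itertools.product("ACGT", repeat=2))
_DI_INDEX = {d: i for i, d in enumerate(DINUCLEOTIDES)}
_NT_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an ACGT string as an int array (A=0, C=1, G=2, T=3)."""
    try:
        return np.array([_NT_CODE[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-ACGT character {exc.args[0]!r} in sequence") from None


def dinucleotide_ids(codes: np.ndarray) -> np.ndarray:
    """Lexicographic dinucleotide index (AA=0 .. TT=15) at each step."""
    return 4 * codes[..., :-1] + codes[..., 1:]


@dataclass
class WeightMatrix2mer:
    """16 x (L-1) position-specific dinucleotide probability matrix.

    Rows follow the fixed lexicographic dinucleotide order AA..TT; ``Pb`` is
    the per-dinucleotide background probability (uniform 1/16 by default).
    """

    p: np.ndarray
    L: int
    pseudocount: float
    Pb: np.ndarray = field(default_factory=lambda: np.full(16, 1.0 / 16))

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        self.Pb = np.asarray(self.Pb, dtype=float)
        if self.p.shape != (16, self.L - 1):
            raise ValueError(f"matrix shape {self.p.shape} != (16, {self.L - 1})")


def fit_weight_matrix(train_seqs: list[str], pseudocount: float = 1.0) -> WeightMatrix2mer:
    """Fit a dinucleotide weight matrix on same-length training sequences.

    p_ij = (count of dinucleotide i at step j + pseudocount) / (n + 16 * pseudocount).
    One matrix per class is fitted by calling this on each class's sequences.
    """
    if not train_seqs:
        raise ValueError("empty training set")
    L = len(train_seqs[0])
    if any(len(s) != L for s in train_seqs):
        raise ValueError("training sequences have unequal lengths")
    if L < 2:
        raise ValueError("sequences must contain at least one dinucleotide")
    codes = np.stack([encode_sequence(s) for s in train_seqs])
    ids = dinucleotide_ids(codes)  # (n, L-1)
    counts = np.zeros((16, L - 1))
    for j in range(L - 1):
        counts[:, j] = np.bincount(ids[:, j], minlength=16)
    n = len(train_seqs)
    p = (counts + pseudocount) / (n + 16 * pseudocount)
    return WeightMatrix2mer(p=p, L=L, pseudocount=pseudocount)


def score_2mer(seq: str, wm: WeightMatrix2mer, mode: str = "matched") -> float:
    """Log2 odds score of a sequence under a fitted dinucleotide matrix.

    ``matched`` (default) sums log2(p_rj,j / Pb_rj) over the observed
    dinucleotide at each step.  ``literal`` additionally counts every
    unmatched row as log2(1 / Pb_i) — a constant offset under uniform
    background that shifts both class scores equally.
    """
    if len(seq) != wm.L:
        raise ValueError(f"sequence length {len(seq)} != matrix length {wm.L}")
    ids = dinucleotide_ids(encode_sequence(seq))
    probs = wm.p[ids, np.arange(wm.L - 1)]
    if np.any(probs <= 0):
        raise ValueError(
            "zero probability encountered; refit the matrix with pseudocount > 0"
        )
    score = float(np.sum(np.log2(probs / wm.Pb[ids])))
    if mode == "literal":
        neglog_pb = -np.log2(wm.Pb)
        score += float((wm.L - 1) * neglog_pb.sum() - neglog_pb[ids].sum())
    elif mode != "matched":
        raise ValueError(f"unknown mode {mode!r}")
    return score
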