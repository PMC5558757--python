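"""Per-position information gain between true and pseudo signal classes."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .weightmatrix import encode_sequence

HEXAMER_POSITIONS = range(100, 106)


def positional_entropy(c1: float, c2: float) -> float:
    """Two-class entropy (bits) of counts (c1, c2), with 0*log2(0) := 0.

    The same formula yields E(P,X) from per-nucleotide class counts and E(P)
    from the class totals.
    """
    if c1 < 0 or c2 < 0:
        raise ValueError("counts must be non-negative")
    total = c1 + c2
    if total == 0:
        raise ValueError("entropy undefined for (0, 0) counts")
    e = 0.0
    for c in (c1, c2):
        if c > 0:
            f = c / total
            e -= f * np.log2(f)
    return float(e)


@dataclass
class PositionalGainProfile:
    """Fitted per-position class counts, entropies, gain and log-ratio.

    Arrays span the full window; hexamer positions (100-105) are masked out of
    ``gain`` and excluded from scoring/selection since the hexamer is identical
    in both classes by construction.
    """

    counts_true: np.ndarray  # (L, 4)
    counts_pseudo: np.ndarray  # (L, 4)
    n_true: int
    n_pseudo: int
    E_PX: np.ndarray  # (L, 4)
    E_P: np.ndarray  # (L,)
    gain: np.ndarray  # (L,), 0 at masked positions
    class_log_ratio: np.ndarray  # (L, 4)
    mask: np.ndarray  # (L,) bool, True where position participates
    mode: str
    pseudocount: float

    @property
    def L(self) -> int:
        return len(self.gain)


def fit_gain_profile(
    seqs: list[str],
    labels,
    mode: str = "weighted",
    pseudocount: float = 1.0,
    hexamer_span: tuple[int, int] = (100, 106),
) -> PositionalGainProfile:
    """Fit the positional gain profile on labeled training sequences.

    weighted (default): Gain(P) = E(P) - sum_X w_X * E(P,X), with
    w_X = (occurrences of X at P) / (total sequences); always >= 0.
    literal: Gain(P) = E(P) - sum_X E(P,X), the unweighted printed form,
    which may be negative.
    """
    if mode not in ("weighted", "literal"):
        raise ValueError(f"unknown mode {mode!r}")
    labels = np.asarray(labels)
    if len(seqs) != len(labels):
        raise ValueError("seqs and labels length mismatch")
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present to fit a gain profile")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences have unequal lengths")
    codes = np.stack([encode_sequence(s) for s in seqs])
    true_codes = codes[labels == 1]
    pseudo_codes = codes[labels == 0]
    n1, n2 = len(true_codes), len(pseudo_codes)

    onehot = np.eye(4)
    counts_true = onehot[true_codes].sum(axis=0)  # (L, 4)
    counts_pseudo = onehot[pseudo_codes].sum(axis=0)

    def _entropy(c1: np.ndarray, c2: np.ndarray) -> np.ndarray:
        total = c1 + c2
        with np.errstate(divide="ignore", invalid="ignore"):
            f1 = np.where(total > 0, c1 / np.maximum(total, 1e-300), 0.0)
            f2 = np.where(total > 0, c2 / np.maximum(total, 1e-300), 0.0)
            t1 = np.where(f1 > 0, -f1 * np.log2(np.maximum(f1, 1e-300)), 0.0)
            t2 = np.where(f2 > 0, -f2 * np.log2(np.maximum(f2, 1e-300)), 0.0)
        return t1 + t2

    E_PX = _entropy(counts_true, counts_pseudo)  # (L, 4)
    E_P = np.full(L, positional_entropy(n1, n2))

    if mode == "weighted":
        w = (counts_true + counts_pseudo) / (n1 + n2)
        gain = E_P - (w * E_PX).sum(axis=1)
    else:
        gain = E_P - E_PX.sum(axis=1)

    # smoothed per-position log2 ratio of class-conditional nucleotide frequency
    f_true = (counts_true + pseudocount) / (n1 + 4 * pseudocount)
    f_pseudo = (counts_pseudo + pseudocount) / (n2 + 4 * pseudocount)
    class_log_ratio = np.log2(f_true / f_pseudo)

    mask = np.ones(L, dtype=bool)
    lo, hi = hexamer_span
    mask[lo:hi] = False
    gain = np.where(mask, gain, 0.0)
    if mode == "weighted":
        # clip tiny negative float noise; true weighted gain is non-negative
        gain = np.where(mask & (gain < 0) & (gain > -1e-12), 0.0, gain)

    return PositionalGainProfile(
        counts_true=counts_true, counts_pseudo=counts_pseudo,
        n_true=n1, n_pseudo=n2, E_PX=E_PX, E_P=E_P, gain=gain,
        class_log_ratio=class_log_ratio, mask=mask, mode=mode,
        pseudocount=pseudocount,
    )


def gain_score(seq: str, profile: PositionalGainProfile) -> float:
    """Gain-weighted class log-ratio summed over non-hexamer positions.

    High values suggest a true signal, low values a pseudo signal; the score
    is exactly 0 when no position carries any gain.
    """
    if len(seq) != profile.L:
        raise ValueError(f"sequence length {len(seq)} != profile length {profile.L}")
    codes = encode_sequence(seq)
    lr = profile.class_log_ratio[np.arange(profile.L), codes]
    return float(np.sum(profile.gain[profile.mask] * lr[profile.mask]))


def select_top_positions(
    profile: PositionalGainProfile, n_up: int = 20, n_down: int = 20,
    flank: int = 100, hexamer_len: int = 6,
) -> tuple[list[int], list[int]]:
    """The highest-gain positions in each flank, ties broken by smaller index."""
    up_range = [p for p in range(flank) if profile.mask[p]]
    down_range = [p for p in range(flank + hexamer_len, profile.L) if profile.mask[p]]
    if n_up > len(up_range) or n_down > len(down_range):
        raise ValueError("requested more positions than available in a flank")

    def top(positions: list[int], n: int) -> list[int]:
        return sorted(positions, key=lambda p: (-profile.gain[p], p))[:n]

    return top(up_range, n_up), top(down_range, n_down)


def top_position_frequencies(
    seq: str, positions_up: list[int], positions_down: list[int]
) -> np.ndarray:
    """A/C/G/T frequencies at the selected positions: 4 downstream then 4 upstream."""
    codes = encode_sequence(seq)
    out = []
    for group in (positions_down, positions_up):
        if any(p < 0 or p >= len(seq) for p in group):
            raise ValueError("selected position out of sequence range")
        counts = np.bincount(codes[group], minlength=4)
        out.append(counts / len(group))
    return np.concatenate(out)
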