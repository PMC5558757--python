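"""Numeric DNA structural profiles from bundled k-mer conversion tables."""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .weightmatrix import encode_sequence


@dataclass(frozen=True)
class StructuralScale:
    """One physicochemical conversion table mapping every k-mer to a number."""

    name: str
    k: int
    table: dict[str, float]

    def __post_init__(self):
        if self.k not in (2, 3):
            raise ValueError("word size must be 2 or 3")
        expected = {"".join(p) for p in itertools.product("ACGT", repeat=self.k)}
        missing = expected - self.table.keys()
        if missing:
            raise ValueError(f"scale {self.name} missing k-mers: {sorted(missing)[:4]}...")

    def lookup_vector(self) -> np.ndarray:
        """Values in lexicographic k-mer order for vectorized indexing."""
        kmers = ("".join(p) for p in itertools.product("ACGT", repeat=self.k))
        return np.array([self.table[m] for m in kmers])


def load_scales() -> list[StructuralScale]:
    """Load the 16 bundled scales, sorted by name for a stable registry order."""
    root = resources.files("polyasig.features").joinpath("data/scales")
    scales = []
    for entry in sorted(root.iterdir(), key=lambda e: e.name):
        if not entry.name.endswith(".tsv"):
            continue
        table = {}
        for line in entry.read_text().splitlines():
            if not line or line.startswith("kmer"):
                continue
            kmer, value = line.split("\t")
            table[kmer] = float(value)
        k = len(next(iter(table)))
        scales.append(StructuralScale(name=entry.name[:-4], k=k, table=table))
    return scales


def structural_profile(seq: str, scale: StructuralScale) -> np.ndarray:
    """Per-position numeric profile of a sequence: element t = table[seq[t:t+k]].

    Length is len(seq) - k + 1.  Computed per flank in the feature registry so
    no value spans the hexamer or the flank junction.
    """
    codes = encode_sequence(seq)
    if len(codes) < scale.k:
        raise ValueError("sequence shorter than word size")
    ids = codes[: len(codes) - scale.k + 1].copy()
    for offset in range(1, scale.k):
        ids = ids * 4 + codes[offset: len(codes) - scale.k + 1 + offset]
    return scale.lookup_vector()[ids]


def window_average(
    profile_up: np.ndarray, profile_down: np.ndarray, window: int = 25,
    flank_len: int = 100,
) -> np.ndarray:
    """Mean profile value per 25-nt subsequence: 4 upstream + 4 downstream.

    A profile value belongs to the subsequence containing its k-mer start, so
    each flank contributes exactly flank_len / window features, ordered
    5'->3' upstream then 5'->3' downstream.
    """
    if flank_len % window != 0:
        raise ValueError("flank length must be a multiple of the window size")
    n_win = flank_len // window
    out = []
    for profile in (profile_up, profile_down):
        starts = np.arange(len(profile))
        for w in range(n_win):
            sel = (starts >= w * window) & (starts < (w + 1) * window)
            if not sel.any():
                raise ValueError("empty structural window")
            out.append(float(profile[sel].mean()))
    return np.array(out)
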