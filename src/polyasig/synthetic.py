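"""Synthetic labeled PAS / pseudo-PAS datasets with controllable positional signal.

True-class flank positions are drawn from per-position distributions that
interpolate between a uniform background and fixed enrichment templates
(a T/GT-rich downstream-element band and a C/T-rich upstream band for the
"strong" kind; an A-enriched downstream band and milder upstream contrast for
the "weak" kind).  Pseudo-class flanks are always background.  Both classes
carry the variant hexamer at window positions 100-105.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import FLANK, HEXAMER_LEN, WINDOW_LEN, PASSequence, VariantDataset

NUCLEOTIDES = "ACGT"
BACKGROUND = np.full(4, 0.25)

#: Enriched band geometry (window coordinates).  Downstream band sits at
#: +15..+40 relative to the hexamer end; upstream band at -40..-16 relative
#: to the hexamer start.
UPSTREAM_BAND = range(60, 85)
DOWNSTREAM_BAND = range(121, 147)

_TEMPLATES = {
    # kind -> (upstream-band distribution, downstream-band distribution)
    "strong": (np.array([0.15, 0.35, 0.10, 0.40]),   # C/T-rich upstream element
               np.array([0.10, 0.05, 0.15, 0.70])),  # T/GT-rich downstream element
    "weak": (np.array([0.30, 0.25, 0.15, 0.30]),     # more variable upstream
             np.array([0.50, 0.05, 0.10, 0.35])),    # A-enriched downstream
}
_DEFAULT_VARIANT = {"strong": "AATAAA", "weak": "AAGAAA"}


@dataclass
class SyntheticProfile:
    variant: str
    p_true: np.ndarray  # (206, 4); hexamer rows are one-hot placeholders
    p_pseudo: np.ndarray
    signal_strength: float

    def __post_init__(self):
        for name in ("p_true", "p_pseudo"):
            p = np.asarray(getattr(self, name), dtype=float)
            if p.shape != (WINDOW_LEN, 4):
                raise ValueError(f"{name} must have shape ({WINDOW_LEN}, 4)")
            if np.any(p < 0) or not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{name} rows must be valid probability vectors")
            setattr(self, name, p)
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength must lie in [0, 1]")


def default_profiles(kind: str, signal_strength: float,
                     variant: str | None = None) -> SyntheticProfile:
    """Profile whose true class interpolates background -> enrichment template."""
    if kind not in _TEMPLATES:
        raise ValueError(f"kind must be one of {sorted(_TEMPLATES)}, got {kind!r}")
    variant = variant or _DEFAULT_VARIANT[kind]
    up_tpl, dn_tpl = _TEMPLATES[kind]
    p_true = np.tile(BACKGROUND, (WINDOW_LEN, 1))
    s = signal_strength
    for pos in UPSTREAM_BAND:
        p_true[pos] = (1 - s) * BACKGROUND + s * up_tpl
    for pos in DOWNSTREAM_BAND:
        p_true[pos] = (1 - s) * BACKGROUND + s * dn_tpl
    p_pseudo = np.tile(BACKGROUND, (WINDOW_LEN, 1))
    hexamer_onehot = np.eye(4)[[NUCLEOTIDES.index(c) for c in variant]]
    p_true[FLANK:FLANK + HEXAMER_LEN] = hexamer_onehot
    p_pseudo[FLANK:FLANK + HEXAMER_LEN] = hexamer_onehot
    return SyntheticProfile(
        variant=variant, p_true=p_true, p_pseudo=p_pseudo,
        signal_strength=signal_strength,
    )


def _draw(p: np.ndarray, n: int, rng: np.random.Generator) -> list[str]:
    cum = np.cumsum(p, axis=1)  # (206, 4)
    u = rng.random((n, WINDOW_LEN))
    codes = (u[:, :, None] > cum[None, :, :]).sum(axis=2)
    lut = np.array(list(NUCLEOTIDES))
    return ["".join(row) for row in lut[codes]]


def generate_dataset(profile: SyntheticProfile, n_true: int, n_pseudo: int,
                     seed: int) -> VariantDataset:
    """Draw a labeled dataset; deterministic per seed, true records first."""
    if n_true < 0 or n_pseudo < 0:
        raise ValueError("record counts must be non-negative")
    rng = np.random.default_rng(seed)
    records = []
    for label, p, n in (("true_pas", profile.p_true, n_true),
                        ("pseudo_pas", profile.p_pseudo, n_pseudo)):
        for seq in _draw(p, n, rng):
            records.append(PASSequence(
                seq=seq, variant=profile.variant, label=label, source="synthetic",
            ))
    return VariantDataset(variant=profile.variant, records=records)


def dataset_to_fasta_records(dataset: VariantDataset) -> list[tuple[str, str]]:
    """(id, sequence) pairs with label and variant encoded in the header."""
    return [
        (f"{dataset.variant}|{r.label}|{i}", r.seq)
        for i, r in enumerate(dataset.records)
    ]
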