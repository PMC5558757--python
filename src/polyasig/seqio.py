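"""Sequence I/O: FASTA/GTF/BED handling, window extraction and pseudo-site sampling.

All internal coordinates are 0-based half-open.  GTF input (1-based, inclusive)
is converted on read.  A labeled window is always 206 nt: 100-nt flanks around
a 6-nt signal hexamer occupying window positions 100-105.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

WINDOW_LEN = 206
FLANK = 100
HEXAMER_LEN = 6
HEXAMER_SLICE = slice(100, 106)

#: The 12 signal hexamer variants handled by the pipeline.
VARIANTS = (
    "AATAAA", "ATTAAA", "AAGAAA", "AAAAAG", "AATACA", "TATAAA",
    "ACTAAA", "AGTAAA", "GATAAA", "AATATA", "CATAAA", "AATAGA",
)
STRONG_VARIANTS = frozenset({"AATAAA", "ATTAAA"})
WEAK_VARIANTS = tuple(v for v in VARIANTS if v not in STRONG_VARIANTS)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaFormatError(ValueError):
    """Malformed FASTA input; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class GTFFormatError(ValueError):
    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class WindowBoundaryError(ValueError):
    """Requested window overruns the contig or contains N."""


@dataclass(frozen=True)
class PASSequence:
    """One labeled 206-nt window around a signal hexamer."""

    seq: str
    variant: str
    label: str  # true_pas | pseudo_pas
    chrom: str | None = None
    strand: str | None = None
    hexamer_start: int | None = None
    source: str = "benchmark"  # benchmark | gencode | synthetic

    def __post_init__(self):
        if len(self.seq) != WINDOW_LEN:
            raise ValueError(f"window must be {WINDOW_LEN} nt, got {len(self.seq)}")
        if self.seq[HEXAMER_SLICE] != self.variant:
            raise ValueError(
                f"hexamer at positions 100-105 is {self.seq[HEXAMER_SLICE]!r}, "
                f"expected variant {self.variant!r}"
            )
        if self.label not in ("true_pas", "pseudo_pas"):
            raise ValueError(f"bad label {self.label!r}")
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def upstream(self) -> str:
        return self.seq[:FLANK]

    @property
    def downstream(self) -> str:
        return self.seq[FLANK + HEXAMER_LEN:]


@dataclass
class VariantDataset:
    """All records for one hexamer variant."""

    variant: str
    records: list[PASSequence] = field(default_factory=list)

    def __post_init__(self):
        for r in self.records:
            if r.variant != self.variant:
                raise ValueError(
                    f"record variant {r.variant} != dataset variant {self.variant}"
                )

    @property
    def n_true(self) -> int:
        return sum(r.label == "true_pas" for r in self.records)

    @property
    def n_pseudo(self) -> int:
        return sum(r.label == "pseudo_pas" for r in self.records)

    def labels(self) -> np.ndarray:
        """Binary labels: 1 for true_pas, 0 for pseudo_pas."""
        return np.array([int(r.label == "true_pas") for r in self.records])

    def sequences(self) -> list[str]:
        return [r.seq for r in self.records]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def classify_variant(hexamer: str) -> str:
    """Categorize a hexamer: strong / weak / unknown."""
    if hexamer in STRONG_VARIANTS:
        return "strong"
    if hexamer in WEAK_VARIANTS:
        return "weak"
    return "unknown"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[tuple[str, str]]:
    """Parse a FASTA file into an order-preserving list of (id, sequence).

    Sequences are uppercased.  Raises :class:`FastaFormatError` with the line
    number on malformed input (sequence before header, empty file).
    """
    records: list[tuple[str, list[str]]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0] if line[1:].strip() else ""
                if not name:
                    raise FastaFormatError("empty FASTA header", lineno)
                records.append((name, []))
            else:
                if not records:
                    raise FastaFormatError("sequence data before first header", lineno)
                records[-1][1].append(line.upper())
    if not records:
        raise FastaFormatError("empty FASTA file", 1)
    return [(name, "".join(chunks)) for name, chunks in records]


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Window extraction
# ---------------------------------------------------------------------------

def extract_pas_window(
    genome: Mapping[str, str],
    chrom: str,
    strand: str,
    hexamer_start: int,
    allow_n: bool = False,
) -> str:
    """Return the 206-nt sense-strand window around a hexamer.

    ``hexamer_start`` is the 0-based genomic coordinate of the leftmost hexamer
    base.  The genomic interval is symmetric, so the same slice serves both
    strands; for '-' it is reverse-complemented so the hexamer reads in
    transcript orientation at window positions 100-105.
    """
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} not in genome")
    contig = genome[chrom]
    start = hexamer_start - FLANK
    end = hexamer_start + HEXAMER_LEN + FLANK
    if start < 0 or end > len(contig):
        raise WindowBoundaryError(
            f"window [{start},{end}) overruns contig {chrom} of length {len(contig)}"
        )
    window = contig[start:end].upper()
    if strand == "-":
        window = reverse_complement(window)
    elif strand != "+":
        raise ValueError(f"bad strand {strand!r}")
    if "N" in window and not allow_n:
        raise WindowBoundaryError(f"window at {chrom}:{start}-{end} contains N")
    return window


def extract_true_pas(
    genome: Mapping[str, str],
    intervals: Sequence[tuple[str, str, int, int]],
    variants: Sequence[str] = VARIANTS,
    source: str = "gencode",
) -> list[PASSequence]:
    """Extract true-PAS windows for annotated signal intervals.

    Intervals are (chrom, strand, start, end) 0-based half-open; those whose
    extracted hexamer is not one of ``variants``, that overrun the contig, or
    that contain N are skipped.
    """
    wanted = set(variants)
    out = []
    for chrom, strand, start, end in intervals:
        if end - start != HEXAMER_LEN or chrom not in genome:
            continue
        try:
            window = extract_pas_window(genome, chrom, strand, start)
        except WindowBoundaryError:
            continue
        hexamer = window[HEXAMER_SLICE]
        if hexamer in wanted:
            out.append(PASSequence(
                seq=window, variant=hexamer, label="true_pas", chrom=chrom,
                strand=strand, hexamer_start=start, source=source,
            ))
    return out


# ---------------------------------------------------------------------------
# GTF / BED
# ---------------------------------------------------------------------------

def parse_polya_gtf(path, feature_kind: str = "polyA_signal") -> list[tuple[str, str, int, int]]:
    """Parse GENCODE-style polyA feature lines from a GTF.

    Returns (chrom, strand, start, end) tuples in 0-based half-open
    coordinates for lines whose feature field equals ``feature_kind``.
    """
    out = []
    any_feature = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise GTFFormatError(f"expected >= 8 tab-separated fields, got {len(fields)}", lineno)
            chrom, _source, feature, start, end, _score, strand, _frame = fields[:8]
            any_feature = True
            if feature != feature_kind:
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise GTFFormatError(f"non-integer coordinates {start!r}/{end!r}", lineno) from None
            if strand not in ("+", "-"):
                raise GTFFormatError(f"bad strand {strand!r}", lineno)
            out.append((chrom, strand, start_i - 1, end_i))
    if not out and any_feature:
        warnings.warn(
            f"no {feature_kind!r} features found in {path}", stacklevel=2
        )
    return out


def write_bed6(records: Iterable[PASSequence], path) -> None:
    """BED6 export of windows with genomic provenance (name=variant, score=0)."""
    with open(path, "w") as fh:
        for r in records:
            if r.chrom is None or r.hexamer_start is None:
                continue
            start = r.hexamer_start - FLANK
            end = r.hexamer_start + HEXAMER_LEN + FLANK
            fh.write(f"{r.chrom}\t{start}\t{end}\t{r.variant}\t0\t{r.strand}\n")


# ---------------------------------------------------------------------------
# Pseudo-PAS sampling
# ---------------------------------------------------------------------------

def _hexamer_occurrences(chrom_seq: str, variant: str) -> list[tuple[str, int]]:
    """All (strand, leftmost-coordinate) occurrences of the hexamer with full flanks."""
    occ = []
    for strand, needle in (("+", variant), ("-", reverse_complement(variant))):
        pos = chrom_seq.find(needle)
        while pos != -1:
            if pos - FLANK >= 0 and pos + HEXAMER_LEN + FLANK <= len(chrom_seq):
                occ.append((strand, pos))
            pos = chrom_seq.find(needle, pos + 1)
    return sorted(occ)


def sample_pseudo_pas(
    chrom_seq: str,
    variant: str,
    exclude: Iterable[tuple[int, int]],
    n: int,
    seed: int,
    chrom: str | None = None,
) -> list[PASSequence]:
    """Sample n pseudo-PAS windows for a variant from one chromosome sequence.

    Scans both strands, drops occurrences whose hexamer interval intersects the
    exclusion set (0-based half-open), then samples without replacement.
    Deterministic for fixed (seed, inputs).
    """
    chrom_seq = chrom_seq.upper()
    excl = sorted(exclude)

    def excluded(pos: int) -> bool:
        h0, h1 = pos, pos + HEXAMER_LEN
        return any(h0 < e1 and e0 < h1 for e0, e1 in excl)

    genome = {"_": chrom_seq}
    candidates = []
    for strand, pos in _hexamer_occurrences(chrom_seq, variant):
        if excluded(pos):
            continue
        try:
            window = extract_pas_window(genome, "_", strand, pos)
        except WindowBoundaryError:  # contains N
            continue
        candidates.append((strand, pos, window))
    if len(candidates) < n:
        raise ValueError(
            f"requested {n} pseudo-PAS windows but only {len(candidates)} "
            f"eligible occurrences of {variant}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=n, replace=False)
    out = []
    for idx in sorted(chosen):
        strand, pos, window = candidates[idx]
        out.append(PASSequence(
            seq=window, variant=variant, label="pseudo_pas", chrom=chrom,
            strand=strand, hexamer_start=pos, source="benchmark",
        ))
    return out
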