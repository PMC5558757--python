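"""The versioned 218-value feature registry and fitted extractor.

Registry layout (version 1.0), 218 values total:

    2   class log-odds scores from the two dinucleotide weight matrices
    1   positional information-gain score
    8   nucleotide frequencies at the 40 most discriminant positions
  128   16 structural scales x 8 windowed averages (4 upstream + 4 downstream)
    8   mono-nucleotide frequencies per flank
   32   dinucleotide frequencies per flank
   24   in-frame codon-position nucleotide frequencies (3 frames x 4 nt x 2
        flanks, frames anchored at the hexamer edge)
   15   whole-window descriptors over the 200 nt of flank sequence
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np

from ..seqio import FLANK, HEXAMER_LEN, WINDOW_LEN
from .gain import (
    PositionalGainProfile,
    fit_gain_profile,
    gain_score,
    select_top_positions,
    top_position_frequencies,
)
from .structural import StructuralScale, load_scales, structural_profile, window_average
from .weightmatrix import (
    DINUCLEOTIDES,
    WeightMatrix2mer,
    dinucleotide_ids,
    encode_sequence,
    fit_weight_matrix,
    score_2mer,
)

REGISTRY_VERSION = "1.0"
N_FEATURES = 218
NUCLEOTIDES = "ACGT"


def registry_names(scales: list[StructuralScale]) -> list[str]:
    names = ["pas_score", "pseudo_pas_score", "gain_score"]
    names += [f"topfreq_dn_{n}" for n in NUCLEOTIDES]
    names += [f"topfreq_up_{n}" for n in NUCLEOTIDES]
    for scale in scales:
        names += [f"struct_{scale.name}_up{w}" for w in range(1, 5)]
        names += [f"struct_{scale.name}_dn{w}" for w in range(1, 5)]
    names += [f"mono_up_{n}" for n in NUCLEOTIDES]
    names += [f"mono_dn_{n}" for n in NUCLEOTIDES]
    names += [f"di_up_{d}" for d in DINUCLEOTIDES]
    names += [f"di_dn_{d}" for d in DINUCLEOTIDES]
    for flank in ("up", "dn"):
        for frame in range(3):
            names += [f"codon_{flank}_f{frame}_{n}" for n in NUCLEOTIDES]
    names += [f"global_freq_{n}" for n in NUCLEOTIDES]
    names += [
        "gc_content", "at_content", "gc_skew", "at_skew",
        "mono_entropy", "di_entropy", "cpg_obs_exp", "purine_fraction",
        "longest_run_A", "longest_run_T", "longest_run_any",
    ]
    return names


def _max_run(mask: np.ndarray) -> int:
    if not mask.any():
        return 0
    m = np.concatenate(([0], mask.astype(np.int8), [0]))
    d = np.diff(m)
    return int((np.where(d == -1)[0] - np.where(d == 1)[0]).max())


def _distribution_entropy(freqs: np.ndarray) -> float:
    nz = freqs[freqs > 0]
    return float(-(nz * np.log2(nz)).sum())


@dataclass
class FittedFeatureExtractor:
    """All training-dependent components needed to emit a feature vector."""

    wm_true: WeightMatrix2mer
    wm_pseudo: WeightMatrix2mer
    gain_profile: PositionalGainProfile
    top_up: list[int]
    top_down: list[int]
    scales: list[StructuralScale]
    registry_version: str = REGISTRY_VERSION

    @classmethod
    def fit(
        cls,
        train_seqs: list[str],
        labels,
        pseudocount: float = 1.0,
        gain_mode: str = "weighted",
        n_top: int = 20,
        scales: list[StructuralScale] | None = None,
    ) -> "FittedFeatureExtractor":
        labels = np.asarray(labels)
        true_seqs = [s for s, y in zip(train_seqs, labels) if y == 1]
        pseudo_seqs = [s for s, y in zip(train_seqs, labels) if y == 0]
        if not true_seqs or not pseudo_seqs:
            raise ValueError("both classes required to fit the feature extractor")
        wm_true = fit_weight_matrix(true_seqs, pseudocount=pseudocount)
        wm_pseudo = fit_weight_matrix(pseudo_seqs, pseudocount=pseudocount)
        profile = fit_gain_profile(
            train_seqs, labels, mode=gain_mode, pseudocount=pseudocount
        )
        top_up, top_down = select_top_positions(profile, n_up=n_top, n_down=n_top)
        return cls(
            wm_true=wm_true, wm_pseudo=wm_pseudo, gain_profile=profile,
            top_up=top_up, top_down=top_down,
            scales=scales if scales is not None else load_scales(),
        )

    @property
    def names(self) -> list[str]:
        return registry_names(self.scales)

    def checksum(self) -> str:
        """Digest of every fitted array; used by leakage-guard tests."""
        h = hashlib.sha256()
        for arr in (
            self.wm_true.p, self.wm_pseudo.p, self.gain_profile.gain,
            self.gain_profile.class_log_ratio,
            np.asarray(self.top_up), np.asarray(self.top_down),
        ):
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()

    # -- extraction --------------------------------------------------------

    def extract(self, seq: str) -> np.ndarray:
        """The 218-value feature vector for one 206-nt sequence."""
        if len(seq) != WINDOW_LEN:
            raise ValueError(f"expected a {WINDOW_LEN}-nt window, got {len(seq)} nt")
        if "N" in seq:
            raise ValueError("sequence contains N; features are defined over ACGT")
        codes = encode_sequence(seq)
        up, dn = seq[:FLANK], seq[FLANK + HEXAMER_LEN:]
        up_codes, dn_codes = codes[:FLANK], codes[FLANK + HEXAMER_LEN:]

        values = [
            score_2mer(seq, self.wm_true),
            score_2mer(seq, self.wm_pseudo),
            gain_score(seq, self.gain_profile),
        ]
        values.extend(top_position_frequencies(seq, self.top_up, self.top_down))

        for scale in self.scales:
            prof_up = structural_profile(up, scale)
            prof_dn = structural_profile(dn, scale)
            values.extend(window_average(prof_up, prof_dn))

        for fl in (up_codes, dn_codes):
            values.extend(np.bincount(fl, minlength=4) / len(fl))
        for fl in (up_codes, dn_codes):
            ids = dinucleotide_ids(fl)
            values.extend(np.bincount(ids, minlength=16) / len(ids))

        # in-frame codon positions, frames anchored at the hexamer edge
        up_frames = (FLANK - 1 - np.arange(FLANK)) % 3
        dn_frames = np.arange(FLANK) % 3
        for fl, frames in ((up_codes, up_frames), (dn_codes, dn_frames)):
            for f in range(3):
                sel = fl[frames == f]
                values.extend(np.bincount(sel, minlength=4) / len(sel))

        flanks = np.concatenate([up_codes, dn_codes])
        mono = np.bincount(flanks, minlength=4) / len(flanks)
        values.extend(mono)
        a, c, g, t = mono
        gc, at = g + c, a + t
        values.append(gc)
        values.append(at)
        values.append((g - c) / gc if gc > 0 else 0.0)
        values.append((a - t) / at if at > 0 else 0.0)
        values.append(_distribution_entropy(mono))
        di_counts = (
            np.bincount(dinucleotide_ids(up_codes), minlength=16)
            + np.bincount(dinucleotide_ids(dn_codes), minlength=16)
        )
        values.append(_distribution_entropy(di_counts / di_counts.sum()))
        cg_freq = di_counts[6] / di_counts.sum()  # index of 'CG'
        values.append(cg_freq / (c * g) if c > 0 and g > 0 else 0.0)
        values.append(a + g)
        run_a = max(_max_run(up_codes == 0), _max_run(dn_codes == 0))
        run_t = max(_max_run(up_codes == 3), _max_run(dn_codes == 3))
        run_any = max(
            max(_max_run(fl == code) for code in range(4))
            for fl in (up_codes, dn_codes)
        )
        values.extend([run_a, run_t, run_any])

        out = np.asarray(values, dtype=float)
        if len(out) != N_FEATURES:
            raise AssertionError(f"registry emitted {len(out)} values, expected {N_FEATURES}")
        return out

    def extract_batch(self, seqs: list[str]) -> np.ndarray:
        return np.stack([self.extract(s) for s in seqs])

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        gp = self.gain_profile
        return {
            "registry_version": self.registry_version,
            "wm_true": {"p": self.wm_true.p.tolist(), "L": self.wm_true.L,
                        "pseudocount": self.wm_true.pseudocount},
            "wm_pseudo": {"p": self.wm_pseudo.p.tolist(), "L": self.wm_pseudo.L,
                          "pseudocount": self.wm_pseudo.pseudocount},
            "gain_profile": {
                "counts_true": gp.counts_true.tolist(),
                "counts_pseudo": gp.counts_pseudo.tolist(),
                "n_true": gp.n_true, "n_pseudo": gp.n_pseudo,
                "E_PX": gp.E_PX.tolist(), "E_P": gp.E_P.tolist(),
                "gain": gp.gain.tolist(),
                "class_log_ratio": gp.class_log_ratio.tolist(),
                "mask": gp.mask.tolist(), "mode": gp.mode,
                "pseudocount": gp.pseudocount,
            },
            "top_up": list(self.top_up),
            "top_down": list(self.top_down),
            "scales": [
                {"name": s.name, "k": s.k, "table": s.table} for s in self.scales
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedFeatureExtractor":
        gp = d["gain_profile"]
        return cls(
            wm_true=WeightMatrix2mer(p=np.asarray(d["wm_true"]["p"]),
                                     L=d["wm_true"]["L"],
                                     pseudocount=d["wm_true"]["pseudocount"]),
            wm_pseudo=WeightMatrix2mer(p=np.asarray(d["wm_pseudo"]["p"]),
                                       L=d["wm_pseudo"]["L"],
                                       pseudocount=d["wm_pseudo"]["pseudocount"]),
            gain_profile=PositionalGainProfile(
                counts_true=np.asarray(gp["counts_true"]),
                counts_pseudo=np.asarray(gp["counts_pseudo"]),
                n_true=gp["n_true"], n_pseudo=gp["n_pseudo"],
                E_PX=np.asarray(gp["E_PX"]), E_P=np.asarray(gp["E_P"]),
                gain=np.asarray(gp["gain"]),
                class_log_ratio=np.asarray(gp["class_log_ratio"]),
                mask=np.asarray(gp["mask"], dtype=bool), mode=gp["mode"],
                pseudocount=gp["pseudocount"],
            ),
            top_up=list(d["top_up"]), top_down=list(d["top_down"]),
            scales=[StructuralScale(s["name"], s["k"], s["table"])
                    for s in d["scales"]],
            registry_version=d["registry_version"],
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path) -> "FittedFeatureExtractor":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
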