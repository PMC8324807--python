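"""Synthetic amplicon FASTQ generation with paired ground truth.

Emulates the deep-sequencing input of the PAM screen: each read is one
full-length amplicon whose PAM slot carries a library 4-mer and whose target
codon is either the unedited TGG or one of the three stop codons produced by
cytosine base editing.  Reads are emitted on either strand and corrupted by a
simple substitution/N/adapter error model, so the cleaning and anchoring
stages of the pipeline have exactly the artifacts they claim to remove.

Every generated read set ships with a :class:`TruthTable` holding the
realized per-read genotypes, which downstream tests use as an exact oracle.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .amplicon import (
    AmpliconTemplate,
    CodonState,
    EDITED_STATES,
    synthesize_amplicon,
)

__all__ = [
    "ReadErrorModel",
    "TruthTable",
    "generate_library_reads",
    "make_mixture_weights",
    "write_fastq",
    "DEFAULT_EDIT_TRIPLET",
]

# Stop-codon outcome split (TGA, TAG, TAA).  The screen's mutation pattern
# has TGA most frequent, then TAA, then TAG; the magnitudes are a modelling
# choice preserving that ordering and are configurable.
DEFAULT_EDIT_TRIPLET = {"TGA": 0.5, "TAG": 0.2, "TAA": 0.3}

_BASE_CODES = np.frombuffer(b"ACGTN", dtype=np.uint8)
_CODE_OF = {b: i for i, b in enumerate("ACGTN")}
# complement in 0..4 code space: A<->T, C<->G, N->N
_COMP_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


@dataclass(frozen=True)
class ReadErrorModel:
    """Per-base sequencing error model for generated reads.

    Substitution and N rates are per base; ``adapter_rate`` is the fraction
    of reads carrying a 3' adapter read-through tail.  Error bases receive
    ``quality_low``, correct bases ``quality_high`` (Phred+33 downstream).
    Defaults approximate cleaned short-read amplicon data: ~0.2% substitution
    error, rare Ns, occasional adapter tails.
    """

    substitution_rate: float = 0.002
    n_rate: float = 0.0005
    adapter_seq: str = "AGATCGGAAGAGCACACGTC"
    adapter_rate: float = 0.01
    quality_high: int = 37
    quality_low: int = 10

    def __post_init__(self) -> None:
        for nm in ("substitution_rate", "n_rate", "adapter_rate"):
            v = getattr(self, nm)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{nm} must be a probability, got {v}")
        for nm in ("quality_high", "quality_low"):
            q = getattr(self, nm)
            if not 2 <= q <= 41:
                raise ValueError(f"{nm} must be a Phred score in [2, 41], got {q}")
        if self.adapter_rate > 0 and not self.adapter_seq:
            raise ValueError("adapter_rate > 0 requires a non-empty adapter_seq")

    @classmethod
    def noiseless(cls) -> "ReadErrorModel":
        return cls(substitution_rate=0.0, n_rate=0.0, adapter_rate=0.0)


@dataclass
class TruthTable:
    """Realized ground truth of a generated read set.

    ``counts`` maps (pam, CodonState) to the number of reads generated with
    that genotype; ``records`` is a per-read table (read_id, pam, state,
    strand) in emission order.  Counts always sum to ``n_reads``.
    """

    counts: dict[tuple[str, CodonState], int]
    records: pd.DataFrame
    seed: int
    n_reads: int
    params: dict = field(default_factory=dict)

    def count(self, pam: str, state: CodonState) -> int:
        return self.counts.get((pam, state), 0)

    def pam_totals(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for (pam, _state), n in self.counts.items():
            out[pam] = out.get(pam, 0) + n
        return out

    def edited_fraction(self, pam: str) -> float:
        """Realized fraction of this PAM's reads generated as edited."""
        tot = sum(n for (p, _s), n in self.counts.items() if p == pam)
        if tot == 0:
            raise ValueError(f"no reads generated for PAM {pam}")
        ed = sum(
            n for (p, s), n in self.counts.items() if p == pam and s.is_edited
        )
        return ed / tot

    def to_tsv(self, path, sidecar_json=None) -> None:
        rows = [
            {"pam": pam, "state": state.name, "count": n}
            for (pam, state), n in sorted(
                self.counts.items(), key=lambda kv: (kv[0][0], kv[0][1].name)
            )
        ]
        pd.DataFrame(rows, columns=["pam", "state", "count"]).to_csv(
            path, sep="\t", index=False
        )
        if sidecar_json is not None:
            with open(sidecar_json, "w") as fh:
                json.dump(
                    {"seed": self.seed, "n_reads": self.n_reads, "params": self.params},
                    fh,
                    indent=2,
                )


def make_mixture_weights(
    ratio_functional_to_invalid: tuple[int, int],
    functional_pam: str,
    invalid_pam: str,
) -> dict[str, float]:
    """Two-strain mixture weights, e.g. functional:invalid = 1:15 or 1:99."""
    a, b = ratio_functional_to_invalid
    if a <= 0 or b <= 0:
        raise ValueError("mixture ratio parts must be positive")
    if functional_pam == invalid_pam:
        raise ValueError("functional and invalid PAMs must differ")
    return {functional_pam: float(a), invalid_pam: float(b)}


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE_OF[b] for b in seq], dtype=np.uint8)


def _decode_row(codes: np.ndarray) -> str:
    return _BASE_CODES[codes].tobytes().decode("ascii")


def generate_library_reads(
    weights: dict[str, float],
    edited_fraction: dict[str, float] | float,
    template: AmpliconTemplate,
    n_reads: int,
    error_model: ReadErrorModel | None = None,
    seed: int = 0,
    *,
    edit_triplet: dict[str, float] | None = None,
    revcomp_prob: float = 0.5,
    read_id_prefix: str = "read",
) -> tuple[list[tuple[str, str, str]], TruthTable]:
    """Generate one amplicon read set plus its ground truth.

    Each read's PAM is drawn from the normalized ``weights``; its codon is
    edited with probability ``edited_fraction[pam]`` and the edit outcome is
    drawn from ``edit_triplet`` (TGA/TAG/TAA).  The clean amplicon is then
    emitted on the forward or reverse strand and corrupted by
    ``error_model``.  Deterministic given ``seed``.

    Returns
    -------
    reads : list of (read_id, sequence, quality) tuples (Phred+33 quality).
    truth : TruthTable of realized genotypes.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if not weights:
        raise ValueError("weights must be non-empty")
    pams = sorted(weights)
    w = np.array([float(weights[p]) for p in pams])
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be non-negative and not all zero")
    w = w / w.sum()
    if isinstance(edited_fraction, (int, float)):
        ef = np.full(len(pams), float(edited_fraction))
    else:
        ef = np.array([float(edited_fraction.get(p, 0.0)) for p in pams])
    if (ef < 0).any() or (ef > 1).any():
        raise ValueError("edited fractions must be probabilities")
    triplet = dict(DEFAULT_EDIT_TRIPLET if edit_triplet is None else edit_triplet)
    tp = np.array([triplet["TGA"], triplet["TAG"], triplet["TAA"]], dtype=float)
    if (tp < 0).any() or tp.sum() <= 0:
        raise ValueError("edit triplet must be non-negative and not all zero")
    tp = tp / tp.sum()
    em = error_model if error_model is not None else ReadErrorModel()

    rng = np.random.default_rng(seed)
    L = template.total_length
    states = (CodonState.UNEDITED_TGG,) + EDITED_STATES  # indices 0..3

    # genotype draws
    pam_idx = rng.choice(len(pams), size=n_reads, p=w)
    edited = rng.random(n_reads) < ef[pam_idx]
    edit_kind = rng.choice(3, size=n_reads, p=tp)  # 0=TGA 1=TAG 2=TAA
    state_idx = np.where(edited, 1 + edit_kind, 0)
    rev = rng.random(n_reads) < revcomp_prob

    # clean amplicons per realized (pam, state), encoded 0..3
    variant_cache: dict[tuple[int, int], np.ndarray] = {}
    seqs = np.empty((n_reads, L), dtype=np.uint8)
    for i in range(n_reads):
        key = (int(pam_idx[i]), int(state_idx[i]))
        enc = variant_cache.get(key)
        if enc is None:
            enc = _encode(
                synthesize_amplicon(template, pams[key[0]], states[key[1]])
            )
            variant_cache[key] = enc
        seqs[i] = enc

    # strand flip before sequencing error
    if rev.any():
        seqs[rev] = _COMP_CODE[seqs[rev][:, ::-1]]

    quals = np.full((n_reads, L), em.quality_high, dtype=np.uint8)
    if em.substitution_rate > 0:
        sub = rng.random((n_reads, L)) < em.substitution_rate
        shift = rng.integers(1, 4, size=int(sub.sum()), dtype=np.uint8)
        seqs[sub] = (seqs[sub] + shift) % 4
        quals[sub] = em.quality_low
    if em.n_rate > 0:
        nmask = rng.random((n_reads, L)) < em.n_rate
        seqs[nmask] = 4
        quals[nmask] = em.quality_low
    has_adapter = (
        rng.random(n_reads) < em.adapter_rate
        if em.adapter_rate > 0
        else np.zeros(n_reads, dtype=bool)
    )

    width = max(6, len(str(n_reads)))
    adapter_qual = chr(33 + em.quality_high) * len(em.adapter_seq)
    reads: list[tuple[str, str, str]] = []
    for i in range(n_reads):
        seq = _decode_row(seqs[i])
        qual = (quals[i] + 33).tobytes().decode("ascii")
        if has_adapter[i]:
            seq += em.adapter_seq
            qual += adapter_qual
        reads.append((f"{read_id_prefix}{i:0{width}d}", seq, qual))

    counts: dict[tuple[str, CodonState], int] = {}
    for i in range(n_reads):
        key = (pams[pam_idx[i]], states[state_idx[i]])
        counts[key] = counts.get(key, 0) + 1
    records = pd.DataFrame(
        {
            "read_id": [r[0] for r in reads],
            "pam": [pams[j] for j in pam_idx],
            "state": [states[j].name for j in state_idx],
            "strand": np.where(rev, "rev", "fwd"),
        }
    )
    truth = TruthTable(
        counts=counts,
        records=records,
        seed=seed,
        n_reads=n_reads,
        params={
            "edit_triplet": triplet,
            "revcomp_prob": revcomp_prob,
            "error_model": asdict(em),
            "template": template.name,
        },
    )
    return reads, truth


def write_fastq(reads, path) -> None:
    """Write (read_id, seq, qual) tuples as Phred+33 FASTQ (gzip if *.gz)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
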