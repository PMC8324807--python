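"""Amplicon construct model for base-editing survival screening (BESS).

The screen places a randomized PAM slot (NNNN by default) upstream of a
counterselectable ``upp`` variant whose sixth codon is TGG.  A cytosine base
editor converts the TGG tryptophan codon into one of the three stop codons
reachable by C·G→T·A editing (TAG, TGA, TAA), inactivating ``upp`` and letting
the cell survive 5-fluorouracil.  Everything downstream of sequencing reduces
to two questions per read: which 4-mer sits in the PAM slot, and which codon
sits in the target slot.  This module owns that layout: the template
coordinates, PAM enumeration and IUPAC pattern matching, the codon-state
classification, and ground-truth amplicon synthesis for the read generator.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field

import yaml

__all__ = [
    "CodonState",
    "AmpliconTemplate",
    "DEFAULT_TEMPLATE",
    "enumerate_pams",
    "matches_iupac",
    "count_matching",
    "classify_codon",
    "synthesize_amplicon",
    "reverse_complement",
]

DNA_BASES = "ACGT"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: IUPAC nucleotide one-letter codes and the base classes they denote.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

STOP_CODONS = frozenset({"TAG", "TGA", "TAA"})


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


class CodonState(enum.Enum):
    """Outcome classes for the target TGG codon.

    The three EDITED states are exactly the stop codons reachable from TGG by
    C·G→T·A conversion on either strand (the Gs of TGG are Cs on the antisense
    strand).  Any other 3-mer — including 3-mers containing N — is OTHER:
    such reads are tallied in the denominator but never counted as edited.
    """

    UNEDITED_TGG = "TGG"
    EDITED_TAG = "TAG"
    EDITED_TGA = "TGA"
    EDITED_TAA = "TAA"
    OTHER = "other"

    @property
    def codon(self) -> str:
        if self is CodonState.OTHER:
            raise ValueError("OTHER has no canonical codon")
        return self.value

    @property
    def is_edited(self) -> bool:
        return self in EDITED_STATES


EDITED_STATES = (CodonState.EDITED_TGA, CodonState.EDITED_TAG, CodonState.EDITED_TAA)

_CODON_TO_STATE = {
    "TGG": CodonState.UNEDITED_TGG,
    "TAG": CodonState.EDITED_TAG,
    "TGA": CodonState.EDITED_TGA,
    "TAA": CodonState.EDITED_TAA,
}


def enumerate_pams(k: int) -> list[str]:
    """All 4**k k-mers over {A,C,G,T} in lexicographic order (A<C<G<T).

    Parameters
    ----------
    k : int
        PAM length, 1 ≤ k ≤ 8.  The screen's randomized library is k=4
        (256 sequences); k=3 covers the NNN design where canonical NGG is
        1/16 of the library.
    """
    if not isinstance(k, int) or not 1 <= k <= 8:
        raise ValueError(f"PAM length must be an integer in [1, 8], got {k!r}")
    return ["".join(p) for p in itertools.product(DNA_BASES, repeat=k)]


def matches_iupac(seq: str, pattern: str) -> bool:
    """True iff each base of ``seq`` belongs to the IUPAC class in ``pattern``.

    Used to evaluate PAM groups such as NGGN, NGCB (B = C/G/T) or NYGY.
    """
    if len(seq) != len(pattern):
        raise ValueError(
            f"sequence length {len(seq)} != pattern length {len(pattern)}"
        )
    seq, pattern = seq.upper(), pattern.upper()
    bad = set(pattern) - set(IUPAC_CODES)
    if bad:
        raise ValueError(f"illegal IUPAC code(s) {sorted(bad)} in pattern")
    bad = set(seq) - set(DNA_BASES)
    if bad:
        raise ValueError(f"illegal base(s) {sorted(bad)} in sequence")
    return all(base in IUPAC_CODES[code] for base, code in zip(seq, pattern))


def count_matching(pattern: str, k: int) -> int:
    """Number of k-mers in the full library matching an IUPAC pattern.

    ``count_matching("NGGN", 4) == 16`` — the 16 NGGN members of the NNNN
    library; ``count_matching("NGG", 3) == 16`` — NGG is 1/16 of NNN.
    """
    if len(pattern) != k:
        raise ValueError(f"pattern length {len(pattern)} != k={k}")
    return sum(matches_iupac(p, pattern) for p in enumerate_pams(k))


def classify_codon(codon: str) -> CodonState:
    """Classify a 3-mer at the target slot into a :class:`CodonState`."""
    if len(codon) != 3:
        raise ValueError(f"codon must have length 3, got {codon!r}")
    return _CODON_TO_STATE.get(codon.upper(), CodonState.OTHER)


@dataclass(frozen=True)
class AmpliconTemplate:
    """Coordinates and constant sequence of the sequenced amplicon.

    The construct is, 5'→3' on the template strand::

        [ anchor5 | PAM slot | anchor3 (constant, contains the target codon) ]

    ``anchor3`` spans from the end of the PAM slot to the end of the amplicon
    and carries ``reference_codon`` at ``codon_slot``; every other position is
    constant.  Read classification needs only these coordinates, never the
    literal bases, so any user template with the same layout works.

    Parameters
    ----------
    pam_report_strand : {"as_template", "reverse_complement"}
        Orientation in which extracted PAM 4-mers are reported.  PAMs are
        conventionally written on the protospacer strand so the canonical
        motif reads NGG; set ``reverse_complement`` if the sequenced template
        strand is the opposite one.
    """

    name: str
    anchor5: str
    pam_length: int
    anchor3: str
    codon_offset: int  # codon start relative to the start of anchor3
    reference_codon: str = "TGG"
    pam_report_strand: str = "as_template"
    anchor5_start: int = 0

    def __post_init__(self) -> None:
        for nm in ("anchor5", "anchor3", "reference_codon"):
            s = getattr(self, nm)
            if not s or set(s) - set(DNA_BASES):
                raise ValueError(f"{nm} must be a non-empty A/C/G/T string")
        if len(self.anchor5) < 8:
            raise ValueError("anchor5 must be at least 8 nt for anchoring")
        if self.pam_length < 1:
            raise ValueError("pam_length must be positive")
        if len(self.reference_codon) != 3:
            raise ValueError("reference_codon must be a 3-mer")
        if self.reference_codon in STOP_CODONS:
            raise ValueError("reference_codon must encode an amino acid, not a stop")
        if not 0 <= self.codon_offset <= len(self.anchor3) - 3:
            raise ValueError("codon_slot must lie inside anchor3")
        got = self.anchor3[self.codon_offset : self.codon_offset + 3]
        if got != self.reference_codon:
            raise ValueError(
                f"anchor3 carries {got!r} at the codon slot, "
                f"expected reference codon {self.reference_codon!r}"
            )
        if self.pam_report_strand not in ("as_template", "reverse_complement"):
            raise ValueError(
                "pam_report_strand must be 'as_template' or 'reverse_complement'"
            )
        if self.anchor5_start < 0:
            raise ValueError("anchor5_start must be non-negative")

    # -- derived coordinates (template coordinates, 0-based half-open) -------

    @property
    def pam_slot(self) -> tuple[int, int]:
        start = self.anchor5_start + len(self.anchor5)
        return (start, start + self.pam_length)

    @property
    def codon_slot(self) -> tuple[int, int]:
        start = self.pam_slot[1] + self.codon_offset
        return (start, start + 3)

    @property
    def total_length(self) -> int:
        return self.pam_slot[1] + len(self.anchor3)

    @property
    def linker(self) -> str:
        """Constant sequence between the PAM slot and the target codon."""
        return self.anchor3[: self.codon_offset]

    @property
    def min_read_span(self) -> int:
        """Bases needed from the anchor5 start through the target codon."""
        return self.codon_slot[1] - self.anchor5_start

    # -- sequence construction ----------------------------------------------

    def reference_sequence(self, pam: str | None = None) -> str:
        """Unedited amplicon with ``pam`` (default: N-filled slot)."""
        if pam is None:
            pam = "N" * self.pam_length
        return synthesize_amplicon(self, pam, CodonState.UNEDITED_TGG, _allow_n=True)

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "anchor5": self.anchor5,
            "pam_length": self.pam_length,
            "anchor3": self.anchor3,
            "codon_offset": self.codon_offset,
            "reference_codon": self.reference_codon,
            "pam_report_strand": self.pam_report_strand,
            "anchor5_start": self.anchor5_start,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AmpliconTemplate":
        known = {f for f in cls.__dataclass_fields__}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown template keys: {sorted(extra)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AmpliconTemplate":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_fasta(self, path) -> None:
        """Write the unedited reference amplicon (N-filled PAM slot) as FASTA."""
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        rec = SeqRecord(
            Seq(self.reference_sequence()),
            id=self.name,
            description=f"unedited reference amplicon, {self.total_length} bp",
        )
        with open(path, "w") as fh:
            seqio_write([rec], fh, "fasta")


def synthesize_amplicon(
    template: AmpliconTemplate,
    pam: str,
    state: CodonState,
    *,
    _allow_n: bool = False,
) -> str:
    """Ground-truth amplicon for one (PAM, codon-state) genotype.

    The PAM is given in reporting orientation; when the template reports PAMs
    as reverse complements, the slot receives the reverse complement of
    ``pam``.  OTHER has no canonical sequence and is rejected.
    """
    pam = pam.upper()
    if len(pam) != template.pam_length:
        raise ValueError(
            f"PAM length {len(pam)} != template pam_length {template.pam_length}"
        )
    allowed = set(DNA_BASES) | ({"N"} if _allow_n else set())
    if set(pam) - allowed:
        raise ValueError(f"invalid PAM {pam!r}")
    if state is CodonState.OTHER:
        raise ValueError("OTHER state has no canonical amplicon sequence")
    if template.pam_report_strand == "reverse_complement":
        pam = reverse_complement(pam)
    body = (
        template.anchor3[: template.codon_offset]
        + state.codon
        + template.anchor3[template.codon_offset + 3 :]
    )
    return template.anchor5 + pam + body


# Synthetic default template: 152-bp amplicon with a 20-nt 5' anchor, a 4-nt
# PAM slot, a 6-nt linker, then a short ORF whose sixth codon is the TGG
# target.  The constant bases are an arbitrary fixed synthetic sequence with
# the documented layout; real analyses supply their own template.
_DEFAULT_FILLER = (
    "AATTATGTGTAGAATTTCACTAATACTTCAACGGCGTTGCATGCTCATTA"
    "CAAACTACCGCTATAGTGAACGCGCGATTGGCATCAATTTTCGGTCGGTATAAT"
)

DEFAULT_TEMPLATE = AmpliconTemplate(
    name="bess_default_152bp",
    anchor5="TCCAGTCGCTACAAGGTGAA",
    pam_length=4,
    #         linker  M  A  V  L  K  W(target)
    anchor3="GGTACC" + "ATGGCAGTTCTGAAA" + "TGG" + _DEFAULT_FILLER,
    codon_offset=21,
    reference_codon="TGG",
    pam_report_strand="as_template",
)

assert DEFAULT_TEMPLATE.total_length == 152
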