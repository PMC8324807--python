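"""Read cleaning, construct anchoring and per-PAM outcome tallying.

Raw amplicon reads are cleaned (adapter trimming, poly-N and low-quality
filters), then the construct is located by matching the template's constant
5' anchor on both strands with a bounded number of substitutions.  On a
unique best hit the 4-mer in the PAM slot and the 3-mer in the target codon
slot are extracted and the codon classified; results accumulate into a
:class:`PamTally` with full accounting of every rejected read.

Anchor matching is substitution-only (no indels) and uses a pigeonhole seed
scheme: the anchor is split into ``max_mm + 1`` chunks, so any placement with
at most ``max_mm`` mismatches contains at least one exact chunk.  Candidate
offsets found by exact chunk search are then scored by full Hamming distance
over the anchor plus the constant PAM-to-codon linker, which makes the
locator exactly equivalent to an exhaustive sliding-window scan while
staying fast.  Ties for the best placement are rejected as ambiguous: the
pipeline never guesses a PAM.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field, asdict

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .amplicon import AmpliconTemplate, CodonState, classify_codon, reverse_complement

__all__ = [
    "CleanParams",
    "Rejection",
    "PamObservation",
    "PamTally",
    "clean_read",
    "extract_observation",
    "process_fastq",
    "TALLY_COLUMNS",
]

TALLY_COLUMNS = ["pam", "n_total", "n_TGG", "n_TGA", "n_TAG", "n_TAA", "n_other"]

_STATE_COL = {
    CodonState.UNEDITED_TGG: "n_TGG",
    CodonState.EDITED_TGA: "n_TGA",
    CodonState.EDITED_TAG: "n_TAG",
    CodonState.EDITED_TAA: "n_TAA",
    CodonState.OTHER: "n_other",
}


@dataclass(frozen=True)
class Rejection:
    """A read dropped by cleaning or extraction, with the reason why."""

    reason: str


@dataclass(frozen=True)
class PamObservation:
    """One classified read: its PAM 4-mer, codon state and placement."""

    read_id: str
    pam: str
    state: CodonState
    strand: str  # "fwd" | "rev"
    anchor_mismatches: int


@dataclass(frozen=True)
class CleanParams:
    """Cleaning thresholds.

    The screen's published processing names the operations (adapter removal,
    poly-N and low-quality filtering) without parameters; these defaults are
    the conventional ones and are all configurable.
    """

    adapter_seq: str = "AGATCGGAAGAGCACACGTC"
    adapter_seed_len: int = 10
    adapter_max_mm: int = 1
    max_n_frac: float = 0.1
    min_mean_q: float = 20.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_n_frac <= 1.0:
            raise ValueError("max_n_frac must be in [0, 1]")
        if self.adapter_seed_len < 1:
            raise ValueError("adapter_seed_len must be positive")


def _hamming(a: str, b: str) -> int:
    # N never matches a template base
    return sum(x != y for x, y in zip(a, b))


def _find_adapter(seq: str, adapter: str, seed_len: int, max_mm: int) -> int | None:
    """Leftmost start of a 3' adapter match (>= seed_len bases, <= max_mm)."""
    if not adapter:
        return None
    n = len(seq)
    for i in range(0, n - seed_len + 1):
        m = min(len(adapter), n - i)
        if _hamming(seq[i : i + m], adapter[:m]) <= max_mm:
            return i
    return None


def clean_read(
    record: tuple[str, str, str],
    params: CleanParams,
    min_len: int = 1,
) -> tuple[str, str, str] | Rejection:
    """Clean one FASTQ record: trim 3' adapter, filter poly-N / low quality.

    ``min_len`` is the minimum post-trim length required for extraction
    (normally the template's anchor-through-codon span).  Returns the kept
    (id, seq, qual) or a :class:`Rejection` with reason in
    {adapter_only, too_short, too_many_N, low_quality}.
    """
    rid, seq, qual = record
    if len(seq) != len(qual):
        raise ValueError(f"read {rid}: sequence/quality length mismatch")
    if len(seq) == 0:
        return Rejection("too_short")
    pos = _find_adapter(
        seq.upper(), params.adapter_seq.upper(), params.adapter_seed_len,
        params.adapter_max_mm,
    )
    if pos is not None:
        if pos == 0:
            return Rejection("adapter_only")
        seq, qual = seq[:pos], qual[:pos]
    if len(seq) < min_len:
        return Rejection("too_short")
    if seq.upper().count("N") / len(seq) > params.max_n_frac:
        return Rejection("too_many_N")
    mean_q = sum(map(ord, qual)) / len(qual) - 33.0
    if mean_q < params.min_mean_q:
        return Rejection("low_quality")
    return rid, seq, qual


def _anchor_chunks(anchor: str, max_mm: int) -> list[tuple[str, int]]:
    """Split the anchor into max_mm+1 near-equal (chunk, offset) seeds."""
    k = max_mm + 1
    n = len(anchor)
    bounds = [round(j * n / k) for j in range(k + 1)]
    return [(anchor[a:b], a) for a, b in zip(bounds, bounds[1:]) if b > a]


def _candidate_offsets(seq: str, chunks, max_offset: int) -> set[int]:
    cands: set[int] = set()
    for chunk, rel in chunks:
        start = seq.find(chunk)
        while start != -1:
            off = start - rel
            if 0 <= off <= max_offset:
                cands.add(off)
            start = seq.find(chunk, start + 1)
    return cands


def extract_observation(
    record: tuple[str, str, str],
    template: AmpliconTemplate,
    max_anchor_mm: int = 2,
    min_base_q: int = 20,
) -> PamObservation | Rejection:
    """Locate the construct in a cleaned read and classify PAM + codon.

    Scans the read and its reverse complement for the template's 5' anchor
    and the constant linker between PAM slot and codon, each allowing at most
    ``max_anchor_mm`` substitutions (no indels).  On a unique best-scoring
    placement the PAM 4-mer and codon 3-mer are extracted; extracted bases
    with Phred quality below ``min_base_q`` are masked to N.  An N in the PAM
    rejects the read (``ambiguous_pam``); an N in the codon classifies it
    OTHER.  Rejection reasons: no_anchor, ambiguous, ambiguous_pam.
    """
    rid, seq, qual = record
    seq = seq.upper()
    anchor = template.anchor5
    linker = template.linker
    la, lp = len(anchor), template.pam_length
    span = template.min_read_span
    if len(seq) < span:
        return Rejection("no_anchor")
    chunks = _anchor_chunks(anchor, max_anchor_mm)
    max_offset = len(seq) - span

    hits: list[tuple[int, str, int]] = []  # (score, strand, offset)
    for strand, s in (("fwd", seq), ("rev", reverse_complement(seq))):
        for off in sorted(_candidate_offsets(s, chunks, max_offset)):
            amm = _hamming(s[off : off + la], anchor)
            if amm > max_anchor_mm:
                continue
            lstart = off + la + lp
            lmm = _hamming(s[lstart : lstart + len(linker)], linker)
            if lmm > max_anchor_mm:
                continue
            hits.append((amm + lmm, strand, off))
    if not hits:
        return Rejection("no_anchor")
    best = min(h[0] for h in hits)
    top = [h for h in hits if h[0] == best]
    if len(top) > 1:
        return Rejection("ambiguous")
    score, strand, off = top[0]

    if strand == "rev":
        seq = reverse_complement(seq)
        qual = qual[::-1]
    pam_start = off + la
    codon_start = pam_start + lp + template.codon_offset
    pam = list(seq[pam_start : pam_start + lp])
    codon = list(seq[codon_start : codon_start + 3])
    for j in range(lp):
        if ord(qual[pam_start + j]) - 33 < min_base_q:
            pam[j] = "N"
    for j in range(3):
        if ord(qual[codon_start + j]) - 33 < min_base_q:
            codon[j] = "N"
    pam_s = "".join(pam)
    if "N" in pam_s:
        return Rejection("ambiguous_pam")
    if template.pam_report_strand == "reverse_complement":
        pam_s = reverse_complement(pam_s)
    state = classify_codon("".join(codon))
    anchor_mm = _hamming(seq[off : off + la], anchor)
    return PamObservation(rid, pam_s, state, strand, anchor_mm)


@dataclass
class PamTally:
    """Per-PAM codon-state counts plus run-level QC accounting.

    Invariants: per PAM, ``n_total`` equals the sum of the five state
    columns; ``reads_in = reads_cleaned_out + cleaning rejections`` and
    ``reads_cleaned_out = classified + extraction rejections``.
    """

    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    reads_in: int = 0
    reads_cleaned_out: int = 0
    rejected: dict[str, int] = field(default_factory=dict)

    def add(self, obs: PamObservation) -> None:
        row = self.counts.get(obs.pam)
        if row is None:
            row = {c: 0 for c in TALLY_COLUMNS[1:]}
            self.counts[obs.pam] = row
        row["n_total"] += 1
        row[_STATE_COL[obs.state]] += 1

    def reject(self, reason: str) -> None:
        self.rejected[reason] = self.rejected.get(reason, 0) + 1

    @property
    def n_classified(self) -> int:
        return sum(r["n_total"] for r in self.counts.values())

    def row(self, pam: str) -> dict[str, int]:
        return dict(self.counts.get(pam, {c: 0 for c in TALLY_COLUMNS[1:]}))

    def n_edited(self, pam: str) -> int:
        r = self.row(pam)
        return r["n_TGA"] + r["n_TAG"] + r["n_TAA"]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"pam": p, **self.counts[p]} for p in sorted(self.counts)
        ]
        return pd.DataFrame(rows, columns=TALLY_COLUMNS)

    def to_tsv(self, path, qc_json=None) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
        if qc_json is not None:
            with open(qc_json, "w") as fh:
                json.dump(self.qc(), fh, indent=2)

    def qc(self) -> dict:
        return {
            "reads_in": self.reads_in,
            "reads_cleaned_out": self.reads_cleaned_out,
            "reads_classified": self.n_classified,
            "reads_rejected_by_reason": dict(sorted(self.rejected.items())),
        }

    @classmethod
    def from_tsv(cls, path) -> "PamTally":
        df = pd.read_csv(path, sep="\t", dtype={"pam": str})
        missing = set(TALLY_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"tally file {path} missing columns {sorted(missing)}")
        tally = cls()
        for rec in df.to_dict("records"):
            pam = rec.pop("pam")
            tally.counts[pam] = {c: int(rec[c]) for c in TALLY_COLUMNS[1:]}
            expected = sum(
                tally.counts[pam][c] for c in TALLY_COLUMNS[2:]
            )
            if tally.counts[pam]["n_total"] != expected:
                raise ValueError(f"tally row {pam}: n_total != sum of states")
        tally.reads_in = tally.reads_cleaned_out = tally.n_classified
        return tally

    @classmethod
    def from_counts(cls, counts: dict[str, dict[str, int]]) -> "PamTally":
        tally = cls()
        for pam, row in counts.items():
            full = {c: int(row.get(c, 0)) for c in TALLY_COLUMNS[1:]}
            if "n_total" not in row:
                full["n_total"] = sum(full[c] for c in TALLY_COLUMNS[2:])
            tally.counts[pam] = full
        tally.reads_in = tally.reads_cleaned_out = tally.n_classified
        return tally


def _open_text(path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def process_fastq(
    files,
    template: AmpliconTemplate,
    clean_params: CleanParams | None = None,
    max_anchor_mm: int = 2,
    min_base_q: int = 20,
    rejection_log=None,
) -> PamTally:
    """Stream FASTQ file(s) through cleaning and extraction into a PamTally.

    ``files`` is a path or list of paths (plain or gzipped, Phred+33).
    ``rejection_log``, if given, receives one TSV row per rejected read.
    Deterministic for fixed inputs.
    """
    if isinstance(files, (str, bytes)) or hasattr(files, "__fspath__"):
        files = [files]
    params = clean_params if clean_params is not None else CleanParams()
    min_len = template.min_read_span
    tally = PamTally()
    log_fh = open(rejection_log, "w") if rejection_log else None
    if log_fh:
        log_fh.write("read_id\tstage\treason\n")
    try:
        for path in files:
            try:
                fh = _open_text(path)
            except OSError as exc:
                raise OSError(f"cannot read FASTQ file {path}: {exc}") from exc
            with fh:
                try:
                    for title, seq, qual in FastqGeneralIterator(fh):
                        rid = title.split(None, 1)[0]
                        tally.reads_in += 1
                        kept = clean_read((rid, seq, qual), params, min_len)
                        if isinstance(kept, Rejection):
                            tally.reject(kept.reason)
                            if log_fh:
                                log_fh.write(f"{rid}\tcleaning\t{kept.reason}\n")
                            continue
                        tally.reads_cleaned_out += 1
                        obs = extract_observation(
                            kept, template, max_anchor_mm, min_base_q
                        )
                        if isinstance(obs, Rejection):
                            tally.reject(obs.reason)
                            if log_fh:
                                log_fh.write(f"{rid}\textraction\t{obs.reason}\n")
                            continue
                        tally.add(obs)
                except ValueError as exc:
                    raise ValueError(f"malformed FASTQ in {path}: {exc}") from exc
    finally:
        if log_fh:
            log_fh.close()
    return tally
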