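"""Independent brute-force references used to validate the fast paths.

These deliberately avoid the package's seed-based candidate search and the
simulator's update loop: extraction is an exhaustive sliding-window Hamming
scan over every offset on both strands, and the screen recursion is the
closed-form two-strain odds algebra.
"""

from besskit.amplicon import classify_codon, reverse_complement
from besskit.processing import Rejection


def brute_force_extract(record, template, max_anchor_mm=2, min_base_q=20):
    """Exhaustive-scan reference for extract_observation (same contract)."""
    rid, seq, qual = record
    seq = seq.upper()
    anchor, linker = template.anchor5, template.linker
    la, lp = len(anchor), template.pam_length
    span = template.min_read_span
    if len(seq) < span:
        return Rejection("no_anchor")
    hits = []
    for strand, s in (("fwd", seq), ("rev", reverse_complement(seq))):
        for off in range(len(s) - span + 1):
            amm = sum(a != b for a, b in zip(s[off : off + la], anchor))
            if amm > max_anchor_mm:
                continue
            lst = off + la + lp
            lmm = sum(
                a != b for a, b in zip(s[lst : lst + len(linker)], linker)
            )
            if lmm > max_anchor_mm:
                continue
            hits.append((amm + lmm, strand, off))
    if not hits:
        return Rejection("no_anchor")
    best = min(h[0] for h in hits)
    top = [h for h in hits if h[0] == best]
    if len(top) > 1:
        return Rejection("ambiguous")
    _, strand, off = top[0]
    if strand == "rev":
        seq, qual = reverse_complement(seq), qual[::-1]
    pam_start = off + la
    codon_start = pam_start + lp + template.codon_offset
    pam = "".join(
        "N" if ord(qual[pam_start + j]) - 33 < min_base_q else seq[pam_start + j]
        for j in range(lp)
    )
    codon = "".join(
        "N" if ord(qual[codon_start + j]) - 33 < min_base_q else seq[codon_start + j]
        for j in range(3)
    )
    if "N" in pam:
        return Rejection("ambiguous_pam")
    if template.pam_report_strand == "reverse_complement":
        pam = reverse_complement(pam)
    return (pam, classify_codon(codon), strand)


def two_strain_recursion(p_functional, pi_f, s, rounds, mu=0.0):
    """Step-by-step expected-proportion recursion for a two-strain mixture.

    Functional lineage edits with probability pi_f per round, invalid with
    mu only; unedited cells carry relative fitness s. Returns the functional
    lineage's total proportion after each round (list of length rounds+1).
    """
    f_u, f_e = p_functional, 0.0
    i_u, i_e = 1.0 - p_functional, 0.0
    out = [p_functional]
    for _ in range(rounds):
        conv_f = f_u * min(1.0, pi_f + mu)
        conv_i = i_u * mu
        f_e, f_u = f_e + conv_f, (f_u - conv_f) * s
        i_e, i_u = i_e + conv_i, (i_u - conv_i) * s
        tot = f_e + f_u + i_e + i_u
        f_e, f_u, i_e, i_u = (x / tot for x in (f_e, f_u, i_e, i_u))
        out.append(f_e + f_u)
    return out
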