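"""Per-PAM screen statistics: editing efficiency, enrichment, calls.

Definitions
-----------
BE efficiency of a PAM is the fraction of its classified reads whose target
codon carries a C·G→T·A stop conversion (TGA/TAG/TAA); OTHER codons count in
the denominator but never the numerator.  The enrichment factor (EF) of a
PAM is the proportion of *edited* reads with that PAM in the enriched
library divided by the proportion of all reads with that PAM in the initial
library; it is undefined (NaN, flagged) when the PAM is absent from the
initial library.  A PAM is *functional* when its efficiency exceeds 1% of
reads, and *enriched* when its EF exceeds 1 — both strictly.

All proportions use classified reads (reads that passed cleaning and
anchoring) as the denominator; this choice is recorded in output metadata.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats as sps

from .processing import PamTally

__all__ = [
    "be_efficiency",
    "mutation_pattern",
    "enrichment_factor",
    "fold_enrichment",
    "round_fold",
    "call_functional",
    "call_enriched",
    "uniformity_check",
    "compute_stats_table",
    "merge_replicates",
    "FUNCTIONAL_THRESHOLD",
    "ENRICHED_THRESHOLD",
    "STATS_COLUMNS",
]

FUNCTIONAL_THRESHOLD = 0.01  # "more than 1% of reads edited", strict
ENRICHED_THRESHOLD = 1.0  # "enrichment factor greater than 1", strict

STATS_COLUMNS = [
    "pam",
    "n_initial",
    "n_enriched",
    "n_enriched_edited",
    "efficiency",
    "freq_initial",
    "freq_enriched_edited",
    "enrichment_factor",
    "functional",
    "enriched",
]


def be_efficiency(row: dict) -> float:
    """Edited-read fraction for one PAM's tally row; NaN when no reads."""
    total = row["n_total"]
    if total < 1:
        return math.nan
    return (row["n_TGA"] + row["n_TAG"] + row["n_TAA"]) / total


def mutation_pattern(tally: PamTally, pam: str | None = None) -> dict[str, float]:
    """Normalized proportions of the three stop outcomes (TGA, TAG, TAA).

    Pooled over all PAMs by default, or restricted to one PAM.  The screen's
    characteristic pattern is TGA most frequent, then TAA, then TAG.
    """
    pams = [pam] if pam is not None else list(tally.counts)
    sums = {"TGA": 0, "TAG": 0, "TAA": 0}
    for p in pams:
        row = tally.row(p)
        for k in sums:
            sums[k] += row[f"n_{k}"]
    total = sum(sums.values())
    if total == 0:
        raise ValueError("no edited reads; mutation pattern undefined")
    return {k: v / total for k, v in sums.items()}


def enrichment_factor(
    initial: PamTally,
    enriched: PamTally,
    pam: str,
    numerator: str = "edited",
) -> float:
    """Enrichment factor for one PAM.

    EF(p) = [edited reads with PAM p in the enriched library / classified
    reads in the enriched library] ÷ [reads with PAM p in the initial
    library / classified reads in the initial library].  NaN when p is
    absent from the initial library.  ``numerator="all"`` switches the
    enriched-library numerator to all reads of p (sensitivity analysis).
    """
    if numerator not in ("edited", "all"):
        raise ValueError("numerator must be 'edited' or 'all'")
    n_init_total = initial.n_classified
    n_enr_total = enriched.n_classified
    if n_init_total == 0 or n_enr_total == 0:
        raise ValueError("both tallies must contain classified reads")
    p_init = initial.row(pam)["n_total"] / n_init_total
    if p_init == 0.0:
        return math.nan
    num = (
        enriched.n_edited(pam)
        if numerator == "edited"
        else enriched.row(pam)["n_total"]
    )
    return (num / n_enr_total) / p_init


def fold_enrichment(p_initial: float, p_final: float) -> float:
    """Ratio of final to initial proportion of a genotype in the population."""
    if not 0.0 < p_initial <= 1.0:
        raise ValueError(f"initial proportion must be in (0, 1], got {p_initial}")
    if not 0.0 <= p_final <= 1.0:
        raise ValueError(f"final proportion must be in [0, 1], got {p_final}")
    return p_final / p_initial


def round_fold(x: float) -> int:
    """Round a fold value to integer, half away from zero (9.26 → 9, 55.2 → 55)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def call_functional(efficiency, threshold: float = FUNCTIONAL_THRESHOLD):
    """Strictly-greater functional call; NaN efficiency is never functional."""
    eff = np.asarray(efficiency, dtype=float)
    out = (eff > threshold) & ~np.isnan(eff)
    return bool(out) if out.ndim == 0 else out


def call_enriched(ef, threshold: float = ENRICHED_THRESHOLD):
    """Strictly-greater enriched call; undefined (NaN) EF is never enriched."""
    vals = np.asarray(ef, dtype=float)
    out = (vals > threshold) & ~np.isnan(vals)
    return bool(out) if out.ndim == 0 else out


def uniformity_check(initial: PamTally, k: int = 4) -> dict[str, float]:
    """Goodness of fit of the initial library to the uniform 1/4^k design.

    Returns the chi-square statistic and p-value against equal expected
    counts over all 4^k PAMs (absent PAMs count 0), the coefficient of
    variation of per-PAM frequencies, and the min/max frequency.  This is
    the operational reading of the library being "evenly represented":
    a 4^k-category library admits no meaningful univariate normality test.
    """
    from .amplicon import enumerate_pams

    pams = enumerate_pams(k)
    obs = np.array([initial.row(p)["n_total"] for p in pams], dtype=float)
    n = obs.sum()
    if (obs > 0).sum() < 2 or n < len(pams):
        raise ValueError("insufficient counts for a uniformity check")
    chi2, pval = sps.chisquare(obs)
    freqs = obs / n
    return {
        "chi2": float(chi2),
        "p_value": float(pval),
        "cv": float(freqs.std(ddof=0) / freqs.mean()),
        "min_freq": float(freqs.min()),
        "max_freq": float(freqs.max()),
        "n_reads": float(n),
        "n_categories": float(len(pams)),
    }


def compute_stats_table(
    initial: PamTally,
    enriched: PamTally,
    functional_threshold: float = FUNCTIONAL_THRESHOLD,
    enriched_threshold: float = ENRICHED_THRESHOLD,
    ef_numerator: str = "edited",
) -> pd.DataFrame:
    """Full per-PAM statistics table from an initial and an enriched tally.

    One row per PAM seen in either library; efficiency and the functional
    call come from the enriched library, the enrichment factor from both.
    """
    n_init = initial.n_classified
    n_enr = enriched.n_classified
    if n_init == 0 or n_enr == 0:
        raise ValueError("both tallies must contain classified reads")
    pams = sorted(set(initial.counts) | set(enriched.counts))
    rows = []
    for p in pams:
        r_enr = enriched.row(p)
        n_ed = enriched.n_edited(p)
        eff = be_efficiency(r_enr)
        freq_init = initial.row(p)["n_total"] / n_init
        if freq_init > 0:
            num = n_ed if ef_numerator == "edited" else r_enr["n_total"]
            ef = (num / n_enr) / freq_init
        else:
            ef = math.nan
        rows.append(
            {
                "pam": p,
                "n_initial": initial.row(p)["n_total"],
                "n_enriched": r_enr["n_total"],
                "n_enriched_edited": n_ed,
                "efficiency": eff,
                "freq_initial": freq_init,
                "freq_enriched_edited": n_ed / n_enr,
                "enrichment_factor": ef,
                "functional": call_functional(eff, functional_threshold),
                "enriched": call_enriched(ef, enriched_threshold),
            }
        )
    df = pd.DataFrame(rows, columns=STATS_COLUMNS)
    df.attrs["ef_numerator"] = ef_numerator
    df.attrs["denominator"] = "classified_reads"
    df.attrs["functional_threshold"] = functional_threshold
    df.attrs["enriched_threshold"] = enriched_threshold
    return df


def merge_replicates(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Merge per-replicate stats tables over a common PAM set.

    Keeps each replicate's efficiency and enrichment factor as suffixed
    columns, adds their arithmetic means, and consensus calls (functional /
    enriched in *all* replicates).  Replicates must cover identical PAM
    sets; a mismatch raises with the differing PAMs listed.
    """
    if len(tables) < 2:
        raise ValueError("need at least two replicate tables")
    sets = [set(t["pam"]) for t in tables]
    union, inter = set.union(*sets), set.intersection(*sets)
    if union != inter:
        raise ValueError(
            f"replicate PAM sets differ; not shared by all: {sorted(union - inter)}"
        )
    merged = pd.DataFrame({"pam": sorted(union)})
    eff_cols, ef_cols, fun_cols, enr_cols = [], [], [], []
    for i, t in enumerate(tables, start=1):
        t = t.set_index("pam")
        for src, dst, bucket in (
            ("efficiency", f"efficiency_rep{i}", eff_cols),
            ("enrichment_factor", f"enrichment_factor_rep{i}", ef_cols),
            ("functional", f"functional_rep{i}", fun_cols),
            ("enriched", f"enriched_rep{i}", enr_cols),
        ):
            merged[dst] = t.loc[merged["pam"], src].to_numpy()
            bucket.append(dst)
    merged["efficiency_mean"] = merged[eff_cols].mean(axis=1)
    merged["enrichment_factor_mean"] = merged[ef_cols].mean(axis=1)
    merged["functional_consensus"] = merged[fun_cols].all(axis=1)
    merged["enriched_consensus"] = merged[enr_cols].all(axis=1)
    return merged
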