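"""End-to-end orchestration: simulate → process → stats → report.

Each stage reads and writes plain-text artifacts in the run's output
directory, so stages can be rerun independently (the CLI exposes them as
subcommands).  Every run writes its resolved config and a manifest with a
checksum per artifact; two runs with identical config and seed produce
identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os

from .amplicon import enumerate_pams
from .config import RunConfig
from .processing import PamTally, process_fastq
from .reads import write_fastq
from .selection import (
    couple_to_reads,
    init_population,
    run_screen,
    trajectory_frame,
)
from .stats import compute_stats_table, mutation_pattern, uniformity_check
from .viz import write_reports

__all__ = ["run_pipeline", "demo_config", "STAGES", "PipelineError"]

STAGES = ("simulate", "process", "stats", "report")

log = logging.getLogger("besskit")


class PipelineError(RuntimeError):
    """A stage could not run (missing dependency, bad stage name)."""


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def demo_config(seed: int = 0, n_reads: int = 200_000, n_active: int = 40,
                outdir: str = "bess_demo") -> RunConfig:
    """Packaged demo: a 2-round 256-PAM screen with 40 editable PAMs.

    The 16 NGGN PAMs get editing probabilities spread around 0.1 (the
    canonical-PAM calibration: roughly one cell in ten survives 5-Fu after
    induction), the other active PAMs span 0.02–0.30, and each active PAM
    has a distinct activity so efficiency rankings are well defined.  The
    remaining PAMs are inert and should be purged by the two rounds of
    counterselection.  Background escape is off: the demo isolates
    editing-driven enrichment so the active set is exactly recoverable.
    """
    pams = enumerate_pams(4)
    nggn = [p for p in pams if p[1:3] == "GG"]
    others = [p for p in pams if p not in nggn]
    n_extra = max(0, n_active - len(nggn))
    extra = others[:: len(others) // max(1, n_extra)][:n_extra]
    edit_prob = {
        p: 0.08 + 0.04 * i / max(1, len(nggn) - 1) for i, p in enumerate(nggn)
    }
    for i, p in enumerate(extra):
        edit_prob[p] = 0.02 + 0.28 * i / max(1, len(extra) - 1)
    return RunConfig.from_dict(
        {
            "seed": seed,
            "outdir": outdir,
            "generator": {"n_reads": n_reads},
            "screen": {
                "edit_prob": edit_prob,
                "background_escape": 0.0,
                "rounds": 2,
                "mode": "deterministic",
            },
        }
    )


def run_pipeline(config: RunConfig, stages=STAGES) -> dict:
    """Execute the requested stages in order; returns the artifact manifest.

    Stage contract: ``simulate`` writes initial/enriched FASTQ plus truth
    tables; ``process`` turns FASTQs into tally TSVs; ``stats`` combines the
    two tallies into the per-PAM stats table; ``report`` renders the
    heatmap/logo/wheel bundle.  Later stages load whatever an earlier run
    left in ``config.outdir``, so partial reruns are possible; a missing
    prerequisite raises :class:`PipelineError`.
    """
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise PipelineError(f"unknown stage(s) {unknown}; valid: {list(STAGES)}")
    stages = [s for s in STAGES if s in stages]
    out = config.outdir
    os.makedirs(out, exist_ok=True)
    config.to_yaml(os.path.join(out, "resolved_config.yaml"))
    artifacts: dict[str, str] = {"resolved_config": os.path.join(out, "resolved_config.yaml")}

    def path(name: str) -> str:
        return os.path.join(out, name)

    if "simulate" in stages:
        log.info("simulate: %d-round screen, seed=%d", config.screen.rounds, config.seed)
        pop0 = init_population({p: 1.0 for p in enumerate_pams(config.template.pam_length)})
        traj = run_screen(pop0, config.screen)
        trajectory_frame(traj).to_csv(path("trajectory.tsv"), sep="\t", index=False)
        em = config.generator.error_model()
        gen = config.generator
        for label, pop, sub in (
            ("initial", traj[0], 1),
            ("enriched", traj[-1], 2),
        ):
            reads, truth = couple_to_reads(
                pop, config.template, gen.n_reads, em,
                seed=config.seed * 2 + sub,
                edit_triplet=gen.edit_triplet, revcomp_prob=gen.revcomp_prob,
                read_id_prefix=f"{label}_",
            )
            write_fastq(reads, path(f"{label}.fastq"))
            truth.to_tsv(path(f"{label}_truth.tsv"), path(f"{label}_truth.json"))
            artifacts[f"{label}_fastq"] = path(f"{label}.fastq")
            artifacts[f"{label}_truth"] = path(f"{label}_truth.tsv")
        artifacts["trajectory"] = path("trajectory.tsv")

    if "process" in stages:
        for label in ("initial", "enriched"):
            fq = path(f"{label}.fastq")
            if not os.path.exists(fq) and os.path.exists(fq + ".gz"):
                fq += ".gz"
            if not os.path.exists(fq):
                raise PipelineError(
                    f"process stage needs {fq}; run the simulate stage or "
                    f"place FASTQ files in {out}"
                )
            log.info("process: %s", fq)
            tally = process_fastq(
                fq, config.template, config.cleaning,
                config.extraction.max_anchor_mm, config.extraction.min_base_q,
            )
            tally.to_tsv(path(f"{label}_tally.tsv"), path(f"{label}_qc.json"))
            artifacts[f"{label}_tally"] = path(f"{label}_tally.tsv")
            artifacts[f"{label}_qc"] = path(f"{label}_qc.json")

    if "stats" in stages:
        for label in ("initial", "enriched"):
            if not os.path.exists(path(f"{label}_tally.tsv")):
                raise PipelineError(
                    f"stats stage needs {label}_tally.tsv in {out}; "
                    "run the process stage first"
                )
        initial = PamTally.from_tsv(path("initial_tally.tsv"))
        enriched = PamTally.from_tsv(path("enriched_tally.tsv"))
        table = compute_stats_table(
            initial, enriched,
            config.stats.functional_threshold,
            config.stats.enriched_threshold,
            config.stats.ef_numerator,
        )
        table.to_csv(path("pam_stats.tsv"), sep="\t", index=False)
        summary = {
            "n_functional": int(table["functional"].sum()),
            "n_enriched": int(table["enriched"].sum()),
            "mutation_pattern_enriched": mutation_pattern(enriched),
            "functional_threshold": config.stats.functional_threshold,
            "enriched_threshold": config.stats.enriched_threshold,
            "ef_numerator": config.stats.ef_numerator,
        }
        try:
            summary["initial_uniformity"] = uniformity_check(
                initial, config.template.pam_length
            )
        except ValueError as exc:
            summary["initial_uniformity"] = {"warning": str(exc)}
        with open(path("stats_summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2)
        artifacts["pam_stats"] = path("pam_stats.tsv")
        artifacts["stats_summary"] = path("stats_summary.json")

    if "report" in stages:
        if not os.path.exists(path("pam_stats.tsv")):
            raise PipelineError(
                f"report stage needs pam_stats.tsv in {out}; run stats first"
            )
        import pandas as pd

        table = pd.read_csv(path("pam_stats.tsv"), sep="\t", dtype={"pam": str})
        rep = write_reports(
            table, out, prefix="bess",
            metadata={"seed": config.seed, "outdir": out},
        )
        artifacts.update(rep)

    manifest = {
        name: {"path": os.path.relpath(p, out), "sha256": _sha256(p)}
        for name, p in sorted(artifacts.items())
    }
    with open(path("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
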