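"""End-to-end design workflow.

The design loop: enumerate and filter candidate spacers in the target
region, solve the configured ILP for an optimal set, evaluate genome-wide
off-target windows, and — if the off/on ratio fails the threshold — remove
the worst-offending spacer from the candidate pool and re-solve.  The loop
terminates with status ``ok`` when a set passes, ``exhausted`` when the
pool empties, ``infeasible`` when the formulation-2 floor becomes
unreachable, or ``no_candidates`` when enumeration finds nothing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .candidates import (
    BindingSite,
    PamPattern,
    build_binding_map,
    enumerate_candidates,
    filter_excluded,
)
from .genome_io import GenomeSequence, Region, extract_region, read_fasta
from .offtarget import OffTargetReport, evaluate_set, sites_to_bed
from .scoring import get_scorer
from .select import (
    STATUS_EMPTY,
    STATUS_INFEASIBLE,
    SelectionInstance,
    SgRNASet,
    select_max_activity,
    select_min_sgrnas,
)

__all__ = [
    "DesignConfig",
    "DesignResult",
    "run_design",
    "accessibility_survey",
    "write_outputs",
]

logger = logging.getLogger(__name__)

HIGH_DENSITY_FLOOR = 25  # expected sites per 50 kb empirically needed for imaging
HIGH_DENSITY_WINDOW = 50_000


@dataclass
class DesignConfig:
    """All tunables of one design run.

    ``constraint`` is the spacer-count cap K under formulation 1 and the
    activity floor T under formulation 2.  ``window`` defaults to the
    target-region length when left as None.  ``seed`` is recorded and
    forwarded to solver backends that accept one (the bundled HiGHS
    backend is deterministic and takes none).
    """

    genome: str | None = None
    target: Region | None = None
    spacer_len: int = 20
    pam: str = "NGG"
    formulation: int = 1
    constraint: float = 10
    max_mm: int = 3
    gap: int = 30
    window: int | None = None
    ratio_threshold: float = 0.2
    excluded: list[str] = field(default_factory=lambda: ["TTTT"])
    seed: int = 0
    out_prefix: str | None = None

    def __post_init__(self) -> None:
        if self.formulation not in (1, 2):
            raise ValueError("formulation must be 1 or 2")
        if self.constraint <= 0:
            raise ValueError("constraint must be positive")
        if self.ratio_threshold <= 0:
            raise ValueError("ratio threshold must be positive")


@dataclass
class IterationLog:
    pool_size: int
    objective: float
    set_size: int
    off_max_window: float
    ratio: float
    offender: str | None


@dataclass
class DesignResult:
    status: str  # ok | infeasible | exhausted | no_candidates
    sgrna_set: SgRNASet
    report: OffTargetReport | None
    on_target_sites: list[BindingSite]
    iterations: int
    removed: list[str]
    log: list[IterationLog]
    config: DesignConfig


def _solve(instance: SelectionInstance) -> SgRNASet:
    if instance.formulation == 1:
        return select_max_activity(instance)
    return select_min_sgrnas(instance)


def run_design(config: DesignConfig, genome: GenomeSequence | None = None) -> DesignResult:
    """Run the full iterative design loop for one target region."""
    if genome is None:
        if config.genome is None:
            raise ValueError("no genome given (config.genome or genome argument)")
        genome = read_fasta(config.genome)
    target = config.target
    if target is None:
        raise ValueError("config.target is required")
    target_seq = extract_region(genome, target)
    pam = PamPattern(config.pam)
    window = config.window if config.window is not None else len(target)
    scorer = get_scorer(config.spacer_len, config.pam)

    candidates = enumerate_candidates(target_seq, pam, config.spacer_len)
    candidates = filter_excluded(candidates, config.excluded)
    if not candidates:
        return DesignResult(
            status="no_candidates",
            sgrna_set=SgRNASet(status=STATUS_EMPTY),
            report=None,
            on_target_sites=[],
            iterations=0,
            removed=[],
            log=[],
            config=config,
        )

    binding_map = build_binding_map(
        candidates, target_seq, pam, config.max_mm,
        chrom=target.chrom, offset=target.start,
    )
    for sites in binding_map.values():
        for s in sites:
            s.score = scorer(s)

    pool = [c.spacer for c in candidates]
    removed: list[str] = []
    log: list[IterationLog] = []
    iterations = 0
    while pool:
        iterations += 1
        sites = [s for sp in pool for s in binding_map[sp]]
        instance = SelectionInstance(
            spacers=pool,
            sites=sites,
            gap=config.gap,
            formulation=config.formulation,
            K=int(config.constraint) if config.formulation == 1 else None,
            T=float(config.constraint) if config.formulation == 2 else None,
        )
        sgset = _solve(instance)
        if sgset.status == STATUS_INFEASIBLE:
            logger.info(
                "iteration %d: activity floor %.3g unreachable with pool of %d "
                "(best achievable %.3f)",
                iterations, config.constraint, len(pool), sgset.best_achievable or 0.0,
            )
            return DesignResult(
                status="infeasible",
                sgrna_set=sgset,
                report=None,
                on_target_sites=[],
                iterations=iterations,
                removed=removed,
                log=log,
                config=config,
            )
        if not sgset.spacers or sgset.on_target_score <= 0:
            break  # nothing with positive activity can be selected
        report = evaluate_set(
            sgset.spacers, sgset.on_target_score, genome, pam,
            config.max_mm, target, window, scorer, config.ratio_threshold,
        )
        offender = None
        if not report.passed:
            from .offtarget import worst_offender

            offender = worst_offender(report.per_sgrna_max)
        log.append(
            IterationLog(
                pool_size=len(pool),
                objective=sgset.on_target_score,
                set_size=len(sgset.spacers),
                off_max_window=report.off_score,
                ratio=report.ratio,
                offender=offender,
            )
        )
        logger.info(
            "iteration %d: pool=%d set=%d objective=%.3f off_max=%.3f ratio=%.3f%s",
            iterations, len(pool), len(sgset.spacers), sgset.on_target_score,
            report.off_score, report.ratio,
            f" offender={offender}" if offender else " PASS",
        )
        if report.passed:
            return DesignResult(
                status="ok",
                sgrna_set=sgset,
                report=report,
                on_target_sites=sgset.counted_sites,
                iterations=iterations,
                removed=removed,
                log=log,
                config=config,
            )
        pool = [sp for sp in pool if sp != offender]
        removed.append(offender)
    return DesignResult(
        status="exhausted",
        sgrna_set=SgRNASet(status=STATUS_EMPTY),
        report=None,
        on_target_sites=[],
        iterations=iterations,
        removed=removed,
        log=log,
        config=config,
    )


def accessibility_survey(
    genome: GenomeSequence,
    window: int = HIGH_DENSITY_WINDOW,
    set_size: int = 10,
    site_floor: int = HIGH_DENSITY_FLOOR,
    spacer_len: int = 20,
    pam: str = "NGG",
    max_mm: int = 3,
    gap: int = 30,
    excluded: list[str] | None = None,
) -> float:
    """Fraction of fixed windows for which a small sgRNA set reaches a floor.

    The genome is partitioned per contig into consecutive non-overlapping
    windows of the given size (a trailing partial window is ignored); each
    window is designed for with formulation 1 at K = ``set_size`` and
    counted accessible when the optimal expected-activity total reaches
    ``site_floor``.  This is the accessible-region coverage statistic: the
    default floor of 25 expected sites per 50 kb window is the empirical
    density needed for an imaging signal to stand out.
    """
    if excluded is None:
        excluded = ["TTTT"]
    pam_pat = PamPattern(pam)
    scorer = get_scorer(spacer_len, pam)
    total = 0
    accessible = 0
    for chrom, seq in genome.items():
        for wstart in range(0, len(seq) - window + 1, window):
            total += 1
            wseq = seq[wstart : wstart + window]
            try:
                cands = enumerate_candidates(wseq, pam_pat, spacer_len)
            except ValueError:
                continue
            cands = filter_excluded(cands, excluded)
            if not cands:
                if site_floor <= 0:
                    accessible += 1
                continue
            bmap = build_binding_map(cands, wseq, pam_pat, max_mm, chrom=chrom, offset=wstart)
            sites = [s for ss in bmap.values() for s in ss]
            for s in sites:
                s.score = scorer(s)
            inst = SelectionInstance(
                spacers=[c.spacer for c in cands],
                sites=sites,
                gap=gap,
                formulation=1,
                K=set_size,
            )
            best = select_max_activity(inst)
            if best.on_target_score >= site_floor:
                accessible += 1
    if total == 0:
        raise ValueError("no full window fits in the genome")
    return accessible / total


def _config_dict(config: DesignConfig) -> dict:
    d = asdict(config)
    if config.target is not None:
        d["target"] = {
            "chrom": config.target.chrom,
            "start": config.target.start,
            "end": config.target.end,
        }
    return d


def write_outputs(result: DesignResult, prefix) -> dict[str, Path]:
    """Write the selected set (TSV), site BEDs, and a JSON run report.

    Produces ``<prefix>.sgrnas.tsv``, ``<prefix>.on_target.bed``,
    ``<prefix>.off_target.bed`` and ``<prefix>.report.json``; returns the
    path of each.  Files are deterministic for a given result.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "sgrnas": prefix.with_suffix(".sgrnas.tsv"),
        "on_bed": prefix.with_suffix(".on_target.bed"),
        "off_bed": prefix.with_suffix(".off_target.bed"),
        "report": prefix.with_suffix(".report.json"),
    }
    by_spacer: dict[str, list[BindingSite]] = {sp: [] for sp in result.sgrna_set.spacers}
    for s in result.sgrna_set.counted_sites:
        by_spacer[s.owner].append(s)
    rows = ["spacer\tn_sites\tscore"]
    for sp in result.sgrna_set.spacers:
        score = sum(s.score for s in by_spacer[sp])
        rows.append(f"{sp}\t{len(by_spacer[sp])}\t{score:.6g}")
    paths["sgrnas"].write_text("\n".join(rows) + "\n")
    paths["on_bed"].write_text(sites_to_bed(result.sgrna_set.counted_sites))
    off_sites = result.report.sites if result.report else []
    paths["off_bed"].write_text(sites_to_bed(off_sites))
    report = {
        "status": result.status,
        "config": _config_dict(result.config),
        "spacers": result.sgrna_set.spacers,
        "on_target_score": result.sgrna_set.on_target_score,
        "n_counted_sites": len(result.sgrna_set.counted_sites),
        "off_max_window_score": result.report.off_score if result.report else None,
        "ratio": result.report.ratio if result.report else None,
        "iterations": result.iterations,
        "removed": result.removed,
        "best_achievable": result.sgrna_set.best_achievable,
    }
    paths["report"].write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return paths
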