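"""Genome-wide off-target search and sliding-window evaluation.

The off-target activity of a selected sgRNA set is the maximum, over all
fixed-width windows in the genome outside the target region, of the summed
activity of the set's binding sites whose start coordinate falls in the
window.  The set passes when the ratio of this off-target maximum to the
on-target activity is below a threshold (default 0.2); otherwise the
spacer with the highest own-sites-only window score is the next candidate
for removal.

The search engine here is a built-in exhaustive scanner: every PAM-anchored
locus on both strands is tested against every spacer at the configured
mismatch cap, so there are no heuristic misses.  An external engine (e.g.
an Aho-Corasick or index-based search tool) can be plugged in through
:class:`OffTargetEngine` as long as it returns the same site records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np

from .candidates import (
    BindingSite,
    PamPattern,
    encode_codes,
    find_pam_sites,
    site_pam_at,
    site_spacer_at,
)
from .genome_io import GenomeSequence, Region

__all__ = [
    "OffTargetReport",
    "OffTargetEngine",
    "scan_offtargets",
    "max_window_score",
    "activity_ratio",
    "worst_offender",
    "evaluate_set",
    "sites_to_bed",
]


class OffTargetEngine(Protocol):
    """Contract for a pluggable off-target search engine."""

    def __call__(
        self,
        spacers: list[str],
        genome: GenomeSequence,
        pam: PamPattern,
        max_mm: int,
        target: Region | None,
    ) -> list[BindingSite]: ...


@dataclass
class OffTargetReport:
    """Everything the design loop needs to accept or reject a set."""

    sites: list[BindingSite]
    max_window: tuple[str | None, int | None, float]
    per_sgrna_max: dict[str, float]
    on_score: float
    off_score: float
    ratio: float
    threshold: float
    passed: bool
    window: int


def scan_offtargets(
    spacers: list[str],
    genome: GenomeSequence,
    pam: PamPattern,
    max_mm: int,
    target: Region | None = None,
) -> list[BindingSite]:
    """Exhaustively find all off-target binding sites of the given spacers.

    Every PAM-anchored locus in the genome, on both strands, whose
    spacer-region Hamming distance to a spacer is <= ``max_mm`` is
    reported, except sites overlapping the target region (overlap by even
    one base excludes the site from the off-target list: boundary-straddling
    sites are handled by the windowing as off-target only when fully clear).
    """
    if not spacers:
        raise ValueError("no spacers to scan")
    spacer_len = len(spacers[0])
    pam_len = len(pam)
    spacer_mat = np.stack([encode_codes(s) for s in spacers])
    out: list[BindingSite] = []
    for chrom, seq in genome.items():
        loci = find_pam_sites(seq, pam, spacer_len)
        if target is not None:
            loci = [
                (pos, strand)
                for pos, strand in loci
                if not target.overlaps(chrom, pos, pos + spacer_len + pam_len)
            ]
        if not loci:
            continue
        site_spacers = [
            site_spacer_at(seq, pos, strand, spacer_len, pam_len)
            for pos, strand in loci
        ]
        site_mat = np.stack([encode_codes(s) for s in site_spacers])
        dist = (spacer_mat[:, None, :] != site_mat[None, :, :]).sum(axis=2)
        for gi, spacer in enumerate(spacers):
            for si in np.nonzero(dist[gi] <= max_mm)[0]:
                pos, strand = loci[si]
                out.append(
                    BindingSite(
                        chrom=chrom,
                        start=pos,
                        strand=strand,
                        spacer_seq=site_spacers[si],
                        pam_seq=site_pam_at(seq, pos, strand, spacer_len, pam_len),
                        mismatches=int(dist[gi, si]),
                        owner=spacer,
                    )
                )
    out.sort(key=lambda s: (s.chrom, s.start, s.strand, s.owner))
    return out


def max_window_score(
    sites: list[BindingSite], window: int
) -> tuple[str | None, int | None, float]:
    """Best-scoring length-``window`` interval over the given scored sites.

    A site belongs to a window when its start coordinate lies inside it.
    Since moving a window's left edge right to the next site start can only
    gain sites, the per-base sliding maximum is attained at a window whose
    left edge coincides with a site start, so only those windows are
    evaluated (two-pointer sweep per contig).  Windows never span contig
    boundaries.  Returns (None, None, 0.0) when there are no sites.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    best: tuple[str | None, int | None, float] = (None, None, 0.0)
    by_chrom: dict[str, list[BindingSite]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom in sorted(by_chrom):
        ss = sorted(by_chrom[chrom], key=lambda s: s.start)
        starts = [s.start for s in ss]
        scores = [s.score for s in ss]
        right = 0
        running = 0.0
        for left in range(len(ss)):
            if right < left:
                right, running = left, 0.0
            while right < len(ss) and starts[right] < starts[left] + window:
                running += scores[right]
                right += 1
            if running > best[2]:
                best = (chrom, starts[left], running)
            running -= scores[left]
    return best


def activity_ratio(on_score: float, off_score: float) -> float:
    """Off-target to on-target activity ratio; a set passes when < threshold.

    Defined as off/on so that small is good: 0 means no off-target activity
    anywhere, and a value near 1 means some window elsewhere in the genome
    accumulates as much activity as the target itself.
    """
    if on_score <= 0:
        raise ValueError("on-target activity must be positive to form a ratio")
    return off_score / on_score


def worst_offender(per_sgrna_max: dict[str, float]) -> str:
    """The spacer with the largest own-sites-only max window score.

    Ties break lexicographically by spacer so the removal loop is
    deterministic.
    """
    if not per_sgrna_max:
        raise ValueError("empty per-sgRNA score map")
    return min(per_sgrna_max, key=lambda sp: (-per_sgrna_max[sp], sp))


def evaluate_set(
    spacers: list[str],
    on_score: float,
    genome: GenomeSequence,
    pam: PamPattern,
    max_mm: int,
    target: Region,
    window: int,
    scorer: Callable[[BindingSite], float],
    threshold: float,
    engine: OffTargetEngine = scan_offtargets,
) -> OffTargetReport:
    """Run the off-target search and windowed evaluation for one set."""
    sites = engine(spacers, genome, pam, max_mm, target)
    for s in sites:
        s.score = scorer(s)
    max_win = max_window_score(sites, window) if sites else (None, None, 0.0)
    per_sgrna = {}
    for sp in spacers:
        own = [s for s in sites if s.owner == sp]
        per_sgrna[sp] = max_window_score(own, window)[2] if own else 0.0
    ratio = activity_ratio(on_score, max_win[2])
    return OffTargetReport(
        sites=sites,
        max_window=max_win,
        per_sgrna_max=per_sgrna,
        on_score=on_score,
        off_score=max_win[2],
        ratio=ratio,
        threshold=threshold,
        passed=ratio < threshold,
        window=window,
    )


def sites_to_bed(sites: list[BindingSite]) -> str:
    """Serialize sites as BED6 (name = owner spacer, score = 1000 x activity)."""
    lines = [
        f"{s.chrom}\t{s.start}\t{s.end}\t{s.owner}\t{round(1000 * s.score)}\t{s.strand}"
        for s in sites
    ]
    return "\n".join(lines) + ("\n" if lines else "")
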