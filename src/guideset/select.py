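"""Optimal sgRNA-set selection by integer linear programming.

Two formulations over binary variables x_j (spacer j selected) and y_i
(binding site i counted), with linking constraints y_i <= x_owner(i) and
pairwise exclusion y_i + y_k <= 1 for every conflicting site pair:

* formulation 1 — maximize the total counted activity sum_i s_i * y_i
  subject to at most K selected spacers;
* formulation 2 — minimize the number of selected spacers subject to a
  counted-activity floor sum_i s_i * y_i >= T.

Two sites conflict when their start coordinates are closer than the
minimum gap g, or when they sit at the identical (start, strand) locus
under different owners (the same physical locus may only be counted once).
Models are solved to proven optimality with the HiGHS mixed-integer solver
behind :func:`scipy.optimize.milp`; a brute-force enumerator over spacer
subsets (with a max-weight independent-set dynamic program for the site
layer) serves as an independent oracle at small instance sizes.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .candidates import BindingSite

__all__ = [
    "SelectionInstance",
    "SgRNASet",
    "conflict_pairs",
    "select_max_activity",
    "select_min_sgrnas",
    "brute_force_select",
    "verify_set",
]

STATUS_OPTIMAL = "optimal"
STATUS_INFEASIBLE = "infeasible"
STATUS_EMPTY = "empty"


@dataclass
class SelectionInstance:
    """One selection problem: candidate spacers, scored sites, constraints."""

    spacers: list[str]
    sites: list[BindingSite]
    gap: int = 30
    formulation: int = 1
    K: int | None = None  # max spacer count (formulation 1)
    T: float | None = None  # activity floor (formulation 2)

    def __post_init__(self) -> None:
        if self.formulation not in (1, 2):
            raise ValueError("formulation must be 1 or 2")
        if self.gap < 0:
            raise ValueError("gap must be >= 0")
        if self.formulation == 1 and (self.K is None or self.K < 1):
            raise ValueError("formulation 1 requires K >= 1")
        if self.formulation == 2 and (self.T is None or self.T <= 0):
            raise ValueError("formulation 2 requires T > 0")
        owners = set(self.spacers)
        for s in self.sites:
            if s.owner not in owners:
                raise ValueError(f"site owner {s.owner!r} not among candidates")


@dataclass
class SgRNASet:
    """A selected sgRNA set with its counted sites and total activity.

    ``spacers`` is sorted lexicographically and ``counted_sites`` by
    coordinate so equally-optimal solver outputs serialize reproducibly.
    For an infeasible formulation-2 instance, ``status`` is "infeasible"
    and ``best_achievable`` carries the maximum activity reachable with
    every candidate selected.
    """

    spacers: list[str] = field(default_factory=list)
    counted_sites: list[BindingSite] = field(default_factory=list)
    on_target_score: float = 0.0
    status: str = STATUS_OPTIMAL
    best_achievable: float | None = None

    def __post_init__(self) -> None:
        self.spacers = sorted(self.spacers)
        self.counted_sites = sorted(
            self.counted_sites, key=lambda s: (s.chrom, s.start, s.strand)
        )


def conflict_pairs(sites: list[BindingSite], gap: int) -> list[tuple[int, int]]:
    """Unordered index pairs whose site starts are closer than ``gap``.

    Computed in one sweep over sites sorted by start; pairs on different
    contigs never conflict.  With gap 0 the list is empty.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    order = sorted(range(len(sites)), key=lambda i: (sites[i].chrom, sites[i].start))
    pairs: list[tuple[int, int]] = []
    for a, i in enumerate(order):
        for k in order[a + 1 :]:
            if sites[k].chrom != sites[i].chrom:
                break
            if sites[k].start - sites[i].start >= gap:
                break
            pairs.append((min(i, k), max(i, k)))
    pairs.sort()
    return pairs


def _same_locus_pairs(sites: list[BindingSite]) -> list[tuple[int, int]]:
    """Pairs of sites at the identical (chrom, start, strand) locus."""
    by_locus: dict[tuple[str, int, str], list[int]] = {}
    for i, s in enumerate(sites):
        by_locus.setdefault((s.chrom, s.start, s.strand), []).append(i)
    pairs = []
    for idxs in by_locus.values():
        pairs.extend(combinations(idxs, 2))
    return pairs


def _exclusion_pairs(sites: list[BindingSite], gap: int) -> set[tuple[int, int]]:
    return set(conflict_pairs(sites, gap)) | set(_same_locus_pairs(sites))


def _solve_milp(instance: SelectionInstance) -> tuple[int, np.ndarray | None]:
    """Build and solve the 0/1 program; returns (status_code, values)."""
    n, m = len(instance.spacers), len(instance.sites)
    owner_idx = {sp: j for j, sp in enumerate(instance.spacers)}
    scores = np.array([s.score for s in instance.sites], dtype=float)

    rows, cols, vals, lb, ub = [], [], [], [], []
    r = 0
    for i, site in enumerate(instance.sites):  # y_i - x_owner <= 0
        rows += [r, r]
        cols += [n + i, owner_idx[site.owner]]
        vals += [1.0, -1.0]
        lb.append(-np.inf)
        ub.append(0.0)
        r += 1
    for i, k in sorted(_exclusion_pairs(instance.sites, instance.gap)):
        rows += [r, r]
        cols += [n + i, n + k]
        vals += [1.0, 1.0]
        lb.append(-np.inf)
        ub.append(1.0)
        r += 1
    if instance.formulation == 1:
        rows += [r] * n
        cols += list(range(n))
        vals += [1.0] * n
        lb.append(-np.inf)
        ub.append(float(instance.K))
        r += 1
        c = np.concatenate([np.zeros(n), -scores])
    else:
        rows += [r] * m
        cols += [n + i for i in range(m)]
        vals += list(scores)
        lb.append(float(instance.T))
        ub.append(np.inf)
        r += 1
        c = np.concatenate([np.ones(n), np.zeros(m)])

    nvar = n + m
    A = sparse.csr_matrix((vals, (rows, cols)), shape=(r, nvar))
    res = milp(
        c,
        constraints=LinearConstraint(A, lb, ub),
        integrality=np.ones(nvar),
        bounds=Bounds(0, 1),
        options={"mip_rel_gap": 0.0},
    )
    if res.status == 2:
        return 2, None
    if not res.success:
        raise RuntimeError(f"MILP solver failed: status {res.status} ({res.message})")
    return 0, res.x


def _build_set(instance: SelectionInstance, x: np.ndarray) -> SgRNASet:
    n = len(instance.spacers)
    sel = [sp for j, sp in enumerate(instance.spacers) if x[j] > 0.5]
    counted = [s for i, s in enumerate(instance.sites) if x[n + i] > 0.5]
    return SgRNASet(
        spacers=sel,
        counted_sites=counted,
        on_target_score=float(sum(s.score for s in counted)),
    )


def select_max_activity(instance: SelectionInstance) -> SgRNASet:
    """Formulation 1: maximize counted activity with at most K spacers."""
    if instance.formulation != 1:
        raise ValueError("instance is not a formulation-1 problem")
    if not instance.spacers:
        return SgRNASet(status=STATUS_EMPTY)
    status, x = _solve_milp(instance)
    assert status == 0  # formulation 1 is always feasible (empty selection)
    return _build_set(instance, x)


def select_min_sgrnas(instance: SelectionInstance) -> SgRNASet:
    """Formulation 2: minimize spacer count subject to activity >= T.

    An unreachable floor yields status "infeasible" with the best
    achievable activity (all candidates selected) attached, rather than a
    silently empty set.
    """
    if instance.formulation != 2:
        raise ValueError("instance is not a formulation-2 problem")
    if not instance.spacers:
        return SgRNASet(status=STATUS_EMPTY)
    status, x = _solve_milp(instance)
    if status == 2:
        relaxed = SelectionInstance(
            spacers=instance.spacers,
            sites=instance.sites,
            gap=instance.gap,
            formulation=1,
            K=len(instance.spacers),
        )
        best = select_max_activity(relaxed)
        return SgRNASet(
            status=STATUS_INFEASIBLE,
            best_achievable=best.on_target_score,
        )
    return _build_set(instance, x)


def _max_weight_sites(
    sites: list[BindingSite], idxs: list[int], gap: int
) -> float:
    """Max total score of a conflict-free subset of the given sites.

    Conflicts are interval-like on the start coordinate, so a dynamic
    program over sites sorted by start with a prefix-max lookup solves the
    max-weight independent set exactly.  With gap 0, only identical
    (start, strand) loci conflict and a per-locus max suffices.
    """
    if not idxs:
        return 0.0
    total = 0.0
    by_chrom: dict[str, list[int]] = {}
    for i in idxs:
        by_chrom.setdefault(sites[i].chrom, []).append(i)
    for idx in by_chrom.values():
        if gap == 0:
            best: dict[tuple[int, str], float] = {}
            for i in idx:
                key = (sites[i].start, sites[i].strand)
                best[key] = max(best.get(key, 0.0), sites[i].score)
            total += sum(best.values())
            continue
        idx.sort(key=lambda i: sites[i].start)
        starts = [sites[i].start for i in idx]
        f: list[float] = []  # best total using site a as the rightmost
        prefix: list[float] = []  # running max of f
        for a, i in enumerate(idx):
            j = bisect_right(starts, starts[a] - gap, 0, a)
            base = prefix[j - 1] if j > 0 else 0.0
            f.append(base + sites[i].score)
            prefix.append(max(prefix[-1], f[-1]) if prefix else f[-1])
        total += prefix[-1]
    return total


def brute_force_select(instance: SelectionInstance) -> SgRNASet:
    """Exact optimum by exhaustive enumeration of spacer subsets.

    Test oracle only; refuses instances above 15 candidates or 30 sites.
    Within each subset the site layer is solved exactly as a max-weight
    independent set on the start-coordinate conflict structure.  Returns
    objective-carrying results (spacer identities are whatever subset first
    achieved the optimum in enumeration order).
    """
    n, m = len(instance.spacers), len(instance.sites)
    if n > 15 or m > 30:
        raise ValueError(f"instance too large for brute force ({n} cands, {m} sites)")
    if n == 0:
        return SgRNASet(status=STATUS_EMPTY)
    sites_by_owner: dict[str, list[int]] = {sp: [] for sp in instance.spacers}
    for i, s in enumerate(instance.sites):
        sites_by_owner[s.owner].append(i)

    best_subset: tuple[str, ...] | None = None
    best_score = -1.0
    best_card = n + 1
    for size in range(0, n + 1):
        for subset in combinations(instance.spacers, size):
            if instance.formulation == 1 and size > instance.K:
                continue
            idxs = [i for sp in subset for i in sites_by_owner[sp]]
            score = _max_weight_sites(instance.sites, idxs, instance.gap)
            if instance.formulation == 1:
                if score > best_score + 1e-12:
                    best_score, best_subset = score, subset
            else:
                if score >= instance.T - 1e-9 and size < best_card:
                    best_card, best_score, best_subset = size, score, subset
        if instance.formulation == 2 and best_subset is not None:
            break  # sizes enumerated in increasing order: first hit is minimal
    if instance.formulation == 2 and best_subset is None:
        all_score = _max_weight_sites(instance.sites, list(range(m)), instance.gap)
        return SgRNASet(status=STATUS_INFEASIBLE, best_achievable=all_score)
    return SgRNASet(
        spacers=list(best_subset),
        on_target_score=max(best_score, 0.0),
    )


def verify_set(instance: SelectionInstance, result: SgRNASet) -> None:
    """Independently recheck a solution against the instance constraints.

    Raises AssertionError on any violation: unselected owner, counted pair
    closer than the gap, double-counted locus, score mismatch, or a broken
    cardinality/floor constraint.
    """
    sel = set(result.spacers)
    for s in result.counted_sites:
        assert s.owner in sel, f"counted site owned by unselected spacer {s.owner}"
    cs = sorted(result.counted_sites, key=lambda s: (s.chrom, s.start))
    for a, b in zip(cs, cs[1:]):
        if a.chrom == b.chrom:
            assert b.start - a.start >= instance.gap or (
                instance.gap == 0 and (a.start, a.strand) != (b.start, b.strand)
            ), f"counted sites at {a.start} and {b.start} violate gap {instance.gap}"
            assert (a.start, a.strand) != (b.start, b.strand), "locus counted twice"
    recomputed = sum(s.score for s in result.counted_sites)
    assert abs(recomputed - result.on_target_score) < 1e-9, "score mismatch"
    if instance.formulation == 1 and result.status == STATUS_OPTIMAL:
        assert len(result.spacers) <= instance.K, "too many spacers for K"
    if instance.formulation == 2 and result.status == STATUS_OPTIMAL:
        assert result.on_target_score >= instance.T - 1e-9, "activity floor violated"
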