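"""Binding-activity scoring.

A site's activity is the probability-like CFD-style score: a product over
mismatched spacer positions of a position- and base-pair-specific penalty
in [0, 1], equal to 1.0 for a perfect match.  The activity of a set of
sites is the sum of per-site scores, interpretable as the expected number
of bound probes.

The mismatch-penalty model is only defined for the 20 nt spacer + 3 nt NGG
PAM geometry (a 23 bp site).  Any other geometry falls back to uniform
scoring, where every binding site counts 1.0 regardless of mismatches.

The bundled penalty table (``data/cfd_mismatch_penalties.synthetic.tsv``)
is a synthetic stand-in constructed with the qualitative structure of
published cutting-frequency measurements — PAM-proximal mismatches are
penalized far more than PAM-distal ones, and rG:dT / rU:dG wobble pairings
are the best tolerated — not the published measurements themselves.  A
custom table in the same TSV layout can be supplied instead.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Callable

from .candidates import BindingSite

__all__ = [
    "CfdTable",
    "site_score",
    "uniform_site_score",
    "set_activity",
    "get_scorer",
    "load_default_table",
]

logger = logging.getLogger(__name__)

SPACER_LEN_CFD = 20
PAM_CFD = "NGG"

_DNA_TO_RNA = {"A": "A", "C": "C", "G": "G", "T": "U"}


class CfdTable:
    """Mismatch penalties keyed by (spacer position 1..20, RNA base, DNA base).

    Position 1 is the PAM-distal (5') end of the spacer; position 20 is
    adjacent to the PAM.  The RNA base is the guide base at that position
    (spacer T written as U) and the DNA base is the protospacer base it
    faces.  All penalties lie in [0, 1].
    """

    def __init__(self, penalties: dict[tuple[int, str, str], float]):
        for (pos, rna, dna), p in penalties.items():
            if not (1 <= pos <= SPACER_LEN_CFD):
                raise ValueError(f"position {pos} outside 1..{SPACER_LEN_CFD}")
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"penalty {p} for ({pos},{rna},{dna}) outside [0,1]")
        self.penalties = dict(penalties)

    @classmethod
    def from_tsv(cls, path) -> "CfdTable":
        """Load a table from TSV with columns position, rna_base, dna_base, penalty."""
        penalties: dict[tuple[int, str, str], float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("position"):
                    continue
                pos, rna, dna, pen = line.split("\t")
                penalties[(int(pos), rna, dna)] = float(pen)
        return cls(penalties)

    def penalty(self, position: int, rna_base: str, dna_base: str) -> float:
        return self.penalties[(position, rna_base, dna_base)]


def load_default_table() -> CfdTable | None:
    """Load the bundled synthetic penalty table; None if the resource is missing."""
    try:
        ref = resources.files("guideset.data").joinpath(
            "cfd_mismatch_penalties.synthetic.tsv"
        )
        with resources.as_file(ref) as path:
            return CfdTable.from_tsv(Path(path))
    except (FileNotFoundError, ModuleNotFoundError):
        return None


def site_score(spacer: str, site_spacer: str, table: CfdTable) -> float:
    """CFD-style score of one site: product of penalties over mismatches.

    Both sequences must be 20-mers and the spacer must be N-free.  An N in
    the site at a mismatched position contributes penalty 0 (an unknown
    base cannot be assumed to bind).
    """
    if len(spacer) != SPACER_LEN_CFD or len(site_spacer) != SPACER_LEN_CFD:
        raise ValueError("site_score requires two 20-mers")
    if "N" in spacer:
        raise ValueError("spacer must not contain N")
    score = 1.0
    for i, (g, d) in enumerate(zip(spacer, site_spacer)):
        if g == d:
            continue
        if d == "N":
            return 0.0
        score *= table.penalty(i + 1, _DNA_TO_RNA[g], d)
    return score


def uniform_site_score(site: BindingSite) -> float:
    """Uniform fallback: every binding site scores 1.0."""
    return 1.0


def set_activity(sites: list[BindingSite], scorer: Callable[[BindingSite], float]) -> float:
    """Total expected activity of a list of sites (0.0 for an empty list)."""
    return float(sum(scorer(s) for s in sites))


def get_scorer(
    spacer_len: int, pam: str, table: CfdTable | None = None
) -> Callable[[BindingSite], float]:
    """Pick the scoring mode for a design geometry.

    The mismatch-penalty model applies only to the 20 nt spacer + NGG PAM
    (23 bp site) geometry; every other geometry scores uniformly.  If the
    penalty table cannot be loaded the scorer also degrades to uniform,
    with a logged warning.
    """
    if spacer_len == SPACER_LEN_CFD and pam.upper() == PAM_CFD:
        tbl = table if table is not None else load_default_table()
        if tbl is None:
            logger.warning(
                "mismatch-penalty table unavailable; falling back to uniform scoring"
            )
            return uniform_site_score
        return lambda site: site_score(site.owner, site.spacer_seq, tbl)
    return uniform_site_score
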