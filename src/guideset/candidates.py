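"""Candidate sgRNA enumeration and mismatch-tolerant binding-site mapping.

A candidate sgRNA is any distinct spacer sequence whose spacer+PAM layout
occurs at least once, fully contained, in the target region on either
strand.  Binding sites for a candidate are all PAM-anchored loci whose
spacer-region Hamming distance to the candidate is at most a user-set
mismatch cap; mismatches are counted over the spacer only, while the PAM at
a site must match the IUPAC pattern exactly.

Genomic N never matches anything: it disqualifies a PAM position outright
and always counts as a spacer mismatch.  Spacers containing N are never
candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_io import reverse_complement

__all__ = [
    "PamPattern",
    "CandidateSgRNA",
    "BindingSite",
    "IUPAC_SETS",
    "iupac_match",
    "find_pam_sites",
    "enumerate_candidates",
    "filter_excluded",
    "build_binding_map",
]

IUPAC_SETS: dict[str, frozenset[str]] = {
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

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_N_CODE = 4


@dataclass(frozen=True)
class PamPattern:
    """A 3'-of-spacer PAM motif given as an IUPAC string, e.g. ``NGG``."""

    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("PAM pattern must be non-empty")
        bad = set(self.pattern.upper()) - set(IUPAC_SETS)
        if bad:
            raise ValueError(f"invalid IUPAC code(s) in PAM: {sorted(bad)}")
        object.__setattr__(self, "pattern", self.pattern.upper())

    def __len__(self) -> int:
        return len(self.pattern)

    def matches(self, seq: str) -> bool:
        """True iff ``seq`` matches the pattern (genomic N never matches)."""
        if len(seq) != len(self.pattern):
            return False
        return all(iupac_match(p, b) for p, b in zip(self.pattern, seq))


@dataclass
class CandidateSgRNA:
    """A distinct spacer with its exact-match loci inside the target region.

    ``exact_loci`` holds ``(position, strand)`` pairs where position is the
    0-based leftmost coordinate of the full spacer+PAM site on the forward
    strand, regardless of strand.
    """

    spacer: str
    exact_loci: list[tuple[int, str]] = field(default_factory=list)


@dataclass
class BindingSite:
    """One PAM-anchored locus attributed to an owning spacer.

    ``start`` is the leftmost forward-strand coordinate of the full
    spacer+PAM site.  ``spacer_seq`` is the protospacer read in guide
    orientation (reverse-complemented for '-' sites) so it aligns
    position-by-position with the owner spacer; ``mismatches`` is the exact
    Hamming distance between the two over the spacer region.  ``score`` is
    filled in by the scoring layer.
    """

    chrom: str
    start: int
    strand: str
    spacer_seq: str
    pam_seq: str
    mismatches: int
    owner: str
    score: float = 0.0

    @property
    def end(self) -> int:
        return self.start + len(self.spacer_seq) + len(self.pam_seq)


def iupac_match(pattern_char: str, base: str) -> bool:
    """True iff ``base`` is allowed by the IUPAC ``pattern_char``.

    A genomic N matches no pattern character, including pattern N: an
    undetermined base cannot be relied on to form part of a PAM.
    """
    try:
        allowed = IUPAC_SETS[pattern_char]
    except KeyError:
        raise ValueError(f"invalid IUPAC code {pattern_char!r}") from None
    return base in allowed  # "N" is in no allowed set


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


# precomputed: ASCII byte -> base code (everything unexpected -> N)
_ASCII_TO_CODE = np.full(128, _N_CODE, dtype=np.uint8)
for _b, _c in _BASE_CODE.items():
    _ASCII_TO_CODE[ord(_b)] = _c


def encode_codes(seq: str) -> np.ndarray:
    """Encode a normalized DNA string as uint8 codes (A=0,C=1,G=2,T=3,N=4)."""
    return _ASCII_TO_CODE[_encode(seq)]


def _pattern_match_positions(codes: np.ndarray, pattern: str) -> np.ndarray:
    """Start positions where ``pattern`` (IUPAC) matches the coded sequence."""
    n, p = len(codes), len(pattern)
    if n < p:
        return np.empty(0, dtype=np.int64)
    ok = np.ones(n - p + 1, dtype=bool)
    for j, pc in enumerate(pattern):
        allowed = np.zeros(5, dtype=bool)
        for base in IUPAC_SETS[pc]:
            allowed[_BASE_CODE[base]] = True
        ok &= allowed[codes[j : n - p + 1 + j]]
    return np.nonzero(ok)[0]


def find_pam_sites(
    seq: str, pam: PamPattern, spacer_len: int
) -> list[tuple[int, str]]:
    """Enumerate fully-contained spacer+PAM layouts on both strands.

    Forward sites are ``[spacer][PAM]`` occurrences; reverse sites are the
    reverse-complement layout, i.e. ``[revcomp(PAM)][revcomp(spacer)]`` read
    on the forward strand.  Each entry is ``(position, strand)`` with
    position the 0-based leftmost coordinate of the full site on the
    forward strand.  Results are sorted by (position, strand) for
    deterministic downstream iteration.
    """
    if spacer_len < 1:
        raise ValueError("spacer_len must be >= 1")
    codes = encode_codes(seq)
    site_len = spacer_len + len(pam)
    out: list[tuple[int, str]] = []
    if len(codes) >= site_len:
        # forward: PAM occupies [i+spacer_len, i+site_len)
        fwd = _pattern_match_positions(codes, pam.pattern)
        for p in fwd:
            i = int(p) - spacer_len
            if 0 <= i <= len(codes) - site_len:
                out.append((i, "+"))
        # reverse: forward-strand image of the PAM sits at the left edge
        rc_pam = pam.pattern.translate(_IUPAC_COMPLEMENT)[::-1]
        rev = _pattern_match_positions(codes, rc_pam)
        for p in rev:
            i = int(p)
            if i <= len(codes) - site_len:
                out.append((i, "-"))
    out.sort()
    return out


def site_spacer_at(seq: str, pos: int, strand: str, spacer_len: int, pam_len: int) -> str:
    """The protospacer at a site, read in guide orientation."""
    if strand == "+":
        return seq[pos : pos + spacer_len]
    return reverse_complement(seq[pos + pam_len : pos + pam_len + spacer_len])


def site_pam_at(seq: str, pos: int, strand: str, spacer_len: int, pam_len: int) -> str:
    """The PAM at a site, read in guide orientation."""
    if strand == "+":
        return seq[pos + spacer_len : pos + spacer_len + pam_len]
    return reverse_complement(seq[pos : pos + pam_len])


def enumerate_candidates(
    target_seq: str, pam: PamPattern, spacer_len: int = 20
) -> list[CandidateSgRNA]:
    """Group PAM-anchored sites in the target by their (distinct) spacer.

    Spacers containing N are dropped.  Candidates are returned in order of
    first occurrence along the target.
    """
    if not target_seq:
        raise ValueError("target sequence is empty")
    pam_len = len(pam)
    by_spacer: dict[str, CandidateSgRNA] = {}
    for pos, strand in find_pam_sites(target_seq, pam, spacer_len):
        spacer = site_spacer_at(target_seq, pos, strand, spacer_len, pam_len)
        if "N" in spacer:
            continue
        cand = by_spacer.get(spacer)
        if cand is None:
            cand = by_spacer[spacer] = CandidateSgRNA(spacer)
        cand.exact_loci.append((pos, strand))
    return list(by_spacer.values())


def filter_excluded(
    candidates: list[CandidateSgRNA], substrings: list[str]
) -> list[CandidateSgRNA]:
    """Drop candidates whose spacer contains any excluded substring.

    Used e.g. to remove TTTT-containing spacers, which can terminate sgRNA
    expression prematurely under a U6 promoter.  Order is preserved; the
    operation is idempotent.
    """
    subs = [s.upper() for s in substrings if s]
    if not subs:
        return list(candidates)
    return [c for c in candidates if not any(s in c.spacer for s in subs)]


def load_excluded(path) -> list[str]:
    """Read excluded substrings from a file.

    Accepts either one substring per line (blank lines and ``#`` comments
    ignored) or a YAML list.
    """
    import yaml

    text = open(path).read()
    loaded = yaml.safe_load(text)
    if isinstance(loaded, list):
        return [str(s).upper() for s in loaded]
    return [
        line.strip().upper()
        for line in text.splitlines()
        if line.strip() and not line.strip().startswith("#")
    ]


class BindingMap(dict):
    """Map from spacer sequence to its list of :class:`BindingSite`."""


def build_binding_map(
    candidates: list[CandidateSgRNA],
    target_seq: str,
    pam: PamPattern,
    max_mm: int,
    chrom: str = "target",
    offset: int = 0,
) -> BindingMap:
    """All mismatch-tolerant binding sites of each candidate in the target.

    For every candidate spacer, every PAM-anchored locus in ``target_seq``
    whose spacer-region Hamming distance is <= ``max_mm`` becomes a
    :class:`BindingSite` (distance inclusive; an N in the locus counts as a
    mismatch).  ``offset`` shifts reported coordinates so they can be
    expressed on the parent contig ``chrom``.
    """
    if max_mm < 0:
        raise ValueError("max_mm must be >= 0")
    result = BindingMap((c.spacer, []) for c in candidates)
    if not candidates:
        return result
    spacer_len = len(candidates[0].spacer)
    pam_len = len(pam)
    loci = find_pam_sites(target_seq, pam, spacer_len)
    if not loci:
        return result

    site_spacers = [
        site_spacer_at(target_seq, pos, strand, spacer_len, pam_len)
        for pos, strand in loci
    ]
    site_mat = np.stack([encode_codes(s) for s in site_spacers])  # (n_sites, L)
    cand_mat = np.stack([encode_codes(c.spacer) for c in candidates])

    # chunk candidates so the (chunk, n_sites, L) comparison stays small
    chunk = max(1, int(4e7) // max(1, site_mat.size))
    for lo in range(0, len(candidates), chunk):
        sub = cand_mat[lo : lo + chunk]
        # N in the site (code 4) never equals a spacer code, so it counts
        # as a mismatch automatically
        dist = (sub[:, None, :] != site_mat[None, :, :]).sum(axis=2)
        for ci, cand in enumerate(candidates[lo : lo + chunk]):
            sites = result[cand.spacer]
            for si in np.nonzero(dist[ci] <= max_mm)[0]:
                pos, strand = loci[si]
                sites.append(
                    BindingSite(
                        chrom=chrom,
                        start=offset + pos,
                        strand=strand,
                        spacer_seq=site_spacers[si],
                        pam_seq=site_pam_at(target_seq, pos, strand, spacer_len, pam_len),
                        mismatches=int(dist[ci, si]),
                        owner=cand.spacer,
                    )
                )
    return result
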