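"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive and self-contained — plain Python
loops, a local IUPAC table and a local reverse complement — so the
oracles share no code path with the implementation they check.
"""

from __future__ import annotations

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def pam_ok(pam: str, chunk: str) -> bool:
    return len(chunk) == len(pam) and all(
        b in IUPAC[p] for p, b in zip(pam, chunk)  # genomic N is in no set
    )


def naive_pam_sites(seq: str, pam: str, spacer_len: int) -> list[tuple[int, str]]:
    """Every fully-contained spacer+PAM layout, testing each offset directly."""
    site_len = spacer_len + len(pam)
    out = []
    for i in range(len(seq) - site_len + 1):
        if pam_ok(pam, seq[i + spacer_len : i + site_len]):
            out.append((i, "+"))
        # reverse strand: the site read 5'->3' on the minus strand is
        # revcomp(seq[i:i+site_len]); its PAM is the last len(pam) bases
        rc = revcomp(seq[i : i + site_len])
        if pam_ok(pam, rc[spacer_len:]):
            out.append((i, "-"))
    out.sort()
    return out


def naive_site_spacer(seq: str, pos: int, strand: str, spacer_len: int, pam_len: int) -> str:
    if strand == "+":
        return seq[pos : pos + spacer_len]
    return revcomp(seq[pos : pos + spacer_len + pam_len])[:spacer_len]


def naive_candidates(seq: str, pam: str, spacer_len: int) -> dict[str, list[tuple[int, str]]]:
    """Distinct N-free spacers mapped to their exact loci."""
    out: dict[str, list[tuple[int, str]]] = {}
    for pos, strand in naive_pam_sites(seq, pam, spacer_len):
        sp = naive_site_spacer(seq, pos, strand, spacer_len, len(pam))
        if "N" in sp:
            continue
        out.setdefault(sp, []).append((pos, strand))
    return out


def hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


def naive_binding_map(
    spacers: list[str], seq: str, pam: str, max_mm: int, spacer_len: int
) -> dict[str, list[tuple[int, str, int]]]:
    """All (pos, strand, mismatches) per spacer by all-pairs comparison."""
    loci = naive_pam_sites(seq, pam, spacer_len)
    out = {sp: [] for sp in spacers}
    for sp in spacers:
        for pos, strand in loci:
            d = hamming(sp, naive_site_spacer(seq, pos, strand, spacer_len, len(pam)))
            if d <= max_mm:
                out[sp].append((pos, strand, d))
    return out


def naive_max_window(sites: list[tuple[str, int, float]], window: int) -> float:
    """Max window sum over EVERY integer window start (per contig)."""
    best = 0.0
    chroms = {c for c, _, _ in sites}
    for chrom in chroms:
        ss = [(p, sc) for c, p, sc in sites if c == chrom]
        if not ss:
            continue
        lo = min(p for p, _ in ss) - window
        hi = max(p for p, _ in ss)
        for t in range(lo, hi + 1):
            total = sum(sc for p, sc in ss if t <= p < t + window)
            best = max(best, total)
    return best


def naive_max_window_dense(sites: list[tuple[str, int, float]], window: int) -> float:
    """Max window sum over EVERY integer start, via per-base accumulation.

    Same definition as :func:`naive_max_window` but deposits each site's
    score at its start coordinate in a dense array and evaluates every
    integer window start with a prefix sum, so it stays exhaustive at
    50 kb scale.
    """
    import numpy as np

    best = 0.0
    for chrom in {c for c, _, _ in sites}:
        ss = [(p, sc) for c, p, sc in sites if c == chrom]
        hi = max(p for p, _ in ss)
        dense = np.zeros(hi + window + 1)
        for p, sc in ss:
            dense[p] += sc
        csum = np.concatenate([[0.0], np.cumsum(dense)])
        # window starting at t covers starts [t, t+window)
        sums = csum[window:] - csum[:-window]
        best = max(best, float(sums.max()))
    return best


def naive_conflict_pairs(starts_chroms: list[tuple[str, int]], gap: int) -> set[tuple[int, int]]:
    out = set()
    for i in range(len(starts_chroms)):
        for k in range(i + 1, len(starts_chroms)):
            ci, si = starts_chroms[i]
            ck, sk = starts_chroms[k]
            if ci == ck and abs(si - sk) < gap:
                out.add((i, k))
    return out
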