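"""Deterministic synthetic genomes with planted guide clusters.

Fixtures emulate the structure the designer exploits in real genomes: a
target region containing a cluster of near-identical protospacer copies
(what an imaging design needs), optional decoy clusters elsewhere (what
the off-target window check must catch), and an i.i.d. uniform random
background.  Everything is reproducible from (seed, spec) alone, and the
generator returns an exact ground-truth table of every planted site so
enumeration and scoring can be checked against planted truth.

Real genomes differ in ways the background does not model — repeat
families, GC skew, N-gaps — so planted-truth recovery shows correctness
of the scanning and selection machinery, not performance on hg38.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome_io import GenomeSequence, Region, reverse_complement
from .pipeline import DesignConfig

__all__ = ["PlantedCluster", "FixtureSpec", "make_genome", "case_profile"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class PlantedCluster:
    """A run of copies of one prototype spacer planted in a contig.

    Copies are placed every ``spacing`` bases starting at ``start``; each
    copy carries ``mismatches`` random substitutions in its spacer region
    and ends with a concrete PAM realization.  ``spacer`` may be left None
    to draw a random prototype (guaranteed free of ``avoid`` substrings).
    """

    chrom: str
    start: int
    copies: int
    spacer: str | None = None
    mismatches: int = 0
    spacing: int = 60
    strand: str = "+"
    pam_realization: str = "TGG"
    avoid: tuple[str, ...] = ("AAAA", "TTTT")


@dataclass
class FixtureSpec:
    seed: int
    contigs: dict[str, int]
    clusters: list[PlantedCluster] = field(default_factory=list)


@dataclass
class PlantedSite:
    chrom: str
    start: int
    strand: str
    owner: str  # prototype spacer
    mismatches: int
    site_spacer: str


def _random_spacer(rng: np.random.Generator, length: int, avoid: tuple[str, ...]) -> str:
    for _ in range(1000):
        sp = "".join(chr(b) for b in rng.choice(_BASES, size=length))
        if not any(a in sp for a in avoid):
            return sp
    raise RuntimeError("could not draw a spacer avoiding the excluded substrings")


def _mutate(rng: np.random.Generator, spacer: str, n_mm: int) -> str:
    if n_mm == 0:
        return spacer
    positions = rng.choice(len(spacer), size=n_mm, replace=False)
    out = list(spacer)
    for p in positions:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[rng.integers(len(choices))]
    return "".join(out)


def make_genome(
    spec: FixtureSpec, out_dir: str | Path | None = None
) -> tuple[GenomeSequence, list[PlantedSite]]:
    """Build the genome and exact ground truth for a fixture spec.

    Optionally writes ``genome.fa`` plus ground truth as ``truth.tsv`` and
    ``truth.bed`` under ``out_dir``.  After planting, any accidental exact
    background occurrence of a planted prototype (either strand) is
    rewritten so the ground truth stays exact.  Raises on an unsatisfiable
    spec (cluster outside its contig or overlapping copies).
    """
    rng = np.random.default_rng(spec.seed)
    arrays: dict[str, np.ndarray] = {
        name: rng.choice(_BASES, size=length)
        for name, length in spec.contigs.items()
    }
    truth: list[PlantedSite] = []
    occupied: dict[str, list[tuple[int, int]]] = {name: [] for name in spec.contigs}

    for cluster in spec.clusters:
        if cluster.chrom not in arrays:
            raise ValueError(f"unknown contig {cluster.chrom!r} in cluster")
        proto = cluster.spacer or _random_spacer(rng, 20, cluster.avoid)
        site_len = len(proto) + len(cluster.pam_realization)
        if cluster.spacing < site_len:
            raise ValueError("cluster spacing smaller than the planted site length")
        arr = arrays[cluster.chrom]
        for k in range(cluster.copies):
            pos = cluster.start + k * cluster.spacing
            if pos + site_len > len(arr):
                raise ValueError(
                    f"cluster copy {k} at {cluster.chrom}:{pos} exceeds contig"
                )
            for a, b in occupied[cluster.chrom]:
                if pos < b and pos + site_len > a:
                    raise ValueError("planted sites overlap")
            mutated = _mutate(rng, proto, cluster.mismatches)
            layout = mutated + cluster.pam_realization
            if cluster.strand == "-":
                layout = reverse_complement(layout)
            arr[pos : pos + site_len] = np.frombuffer(
                layout.encode("ascii"), dtype=np.uint8
            )
            occupied[cluster.chrom].append((pos, pos + site_len))
            truth.append(
                PlantedSite(
                    chrom=cluster.chrom,
                    start=pos,
                    strand=cluster.strand,
                    owner=proto,
                    mismatches=cluster.mismatches,
                    site_spacer=mutated,
                )
            )

    _screen_accidental_copies(arrays, truth, occupied, rng)
    genome = GenomeSequence(
        {name: arr.tobytes().decode("ascii") for name, arr in arrays.items()}
    )
    truth.sort(key=lambda t: (t.chrom, t.start, t.strand))
    if out_dir is not None:
        _write_fixture(genome, truth, Path(out_dir))
    return genome, truth


def _screen_accidental_copies(
    arrays: dict[str, np.ndarray],
    truth: list[PlantedSite],
    occupied: dict[str, list[tuple[int, int]]],
    rng: np.random.Generator,
) -> None:
    """Rewrite background bases that form exact copies of a planted spacer."""
    protos = {t.owner for t in truth}
    for proto in sorted(protos):
        patterns = {proto, reverse_complement(proto)}
        for chrom, arr in arrays.items():
            seq = arr.tobytes().decode("ascii")
            for pattern in patterns:
                start = seq.find(pattern)
                while start != -1:
                    end = start + len(pattern)
                    planted = any(
                        start < b and end > a for a, b in occupied[chrom]
                    )
                    if not planted:
                        mid = start + len(pattern) // 2
                        cur = chr(arr[mid])
                        arr[mid] = ord(
                            [b for b in "ACGT" if b != cur][rng.integers(3)]
                        )
                        seq = arr.tobytes().decode("ascii")
                        start = seq.find(pattern)  # rescan after the edit
                    else:
                        start = seq.find(pattern, start + 1)


def _write_fixture(genome: GenomeSequence, truth: list[PlantedSite], out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "genome.fa", "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(out_dir / "truth.tsv", "w") as fh:
        fh.write("chrom\tstart\tstrand\towner\tmismatches\tsite_spacer\n")
        for t in truth:
            fh.write(
                f"{t.chrom}\t{t.start}\t{t.strand}\t{t.owner}\t"
                f"{t.mismatches}\t{t.site_spacer}\n"
            )
    with open(out_dir / "truth.bed", "w") as fh:
        for t in truth:
            end = t.start + len(t.site_spacer) + 3
            fh.write(f"{t.chrom}\t{t.start}\t{end}\t{t.owner}\t0\t{t.strand}\n")


def case_profile(formulation: int = 1, region: Region | None = None) -> DesignConfig:
    """The published case-study parameter profile.

    Constraint 10 (spacer cap under formulation 1, activity floor under
    formulation 2), PAM NGG, up to 3 mismatches, off/on ratio threshold
    0.2, 30 bp minimum gap between counted sites, and AAAA/TTTT excluded
    from spacers.  The target region is left to the caller.
    """
    return DesignConfig(
        target=region,
        spacer_len=20,
        pam="NGG",
        formulation=formulation,
        constraint=10,
        max_mm=3,
        gap=30,
        ratio_threshold=0.2,
        excluded=["AAAA", "TTTT"],
    )
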