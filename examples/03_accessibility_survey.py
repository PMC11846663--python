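"""Survey which genome windows an sgRNA set could light up.

Partitions a toy genome into 3 kb windows and asks, window by window,
whether one sgRNA can reach 25 expected binding sites (the empirical
density needed for an imaging signal).  Dense repeat clusters were planted
in 4 of the 10 windows, so single-guide coverage is 40%; allowing a set of
guides raises coverage in genomes without such repeats.
"""

from guideset import accessibility_survey
from guideset.synthetic import FixtureSpec, PlantedCluster, make_genome

window = 3000
spec = FixtureSpec(
    seed=9,
    contigs={"g": 10 * window},
    clusters=[PlantedCluster("g", w * window + 500, 30, spacing=60)
              for w in (0, 3, 5, 8)],
)
genome, _ = make_genome(spec)

for set_size, floor in [(1, 25), (1, 5), (10, 5)]:
    frac = accessibility_survey(genome, window=window, set_size=set_size,
                                site_floor=floor)
    print(f"set of {set_size:>2} sgRNA(s), floor {floor:>2} expected sites: "
          f"{frac:.0%} of windows accessible")
print("\nWindows with a planted 30-copy cluster are reachable by a single "
      "guide; elsewhere a floor of 5 needs a multi-guide set.")
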