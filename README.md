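# guideset

Design **sets** of single-guide RNAs (sgRNAs) for CRISPR imaging.

Fluorescent labeling of a genomic locus with dCas9 needs many bound probes
clustered inside the target region to lift the signal over background — a
single sgRNA only achieves that in repetitive DNA. `guideset` makes
non-repetitive loci imageable by selecting a small *set* of sgRNAs whose
combined binding sites tile the target, while guaranteeing that no window
elsewhere in the genome accumulates comparable binding activity.

## Method

For a target region the pipeline:

1. **Enumerates candidates** — every distinct N-free 20 nt spacer whose
   spacer+PAM layout (`NGG` by default, any IUPAC pattern accepted) occurs in
   the target on either strand; spacers containing excluded substrings
   (default `TTTT`, which can terminate expression from a U6 promoter) are
   dropped.
2. **Maps binding sites** — for each candidate, every PAM-anchored locus in
   the target within a Hamming-distance mismatch cap (default ≤ 3, spacer
   region only).
3. **Scores sites** — a CFD-style multiplicative model: a perfect match
   scores 1, and each mismatch multiplies in a penalty that depends on its
   spacer position (PAM-proximal mismatches cost most) and base pair. A
   set's **on-target activity** `sum_i s_i` is the expected number of bound
   probes. Geometries other than 20 nt + NGG fall back to uniform scoring.
4. **Selects the set by integer linear programming** over binaries
   `x_j` (spacer selected) and `y_i` (site counted), with `y_i ≤ x_owner(i)`
   and `y_i + y_k ≤ 1` for sites closer than the minimum gap (30 bp default):

   * **formulation 1** — maximize `Σ s_i y_i` subject to `Σ x_j ≤ K`;
   * **formulation 2** — minimize `Σ x_j` subject to `Σ s_i y_i ≥ T`.

   Solved to proven optimality with HiGHS (`scipy.optimize.milp`).
5. **Checks off-targets** — an exhaustive genome-wide scan finds every
   mismatch-tolerant site of the selected spacers outside the target; the
   off-target activity is the maximum summed score over all sliding windows
   (window = target length by default). If `off/on ≥ 0.2` the worst-offending
   sgRNA is removed from the candidate pool and selection repeats until a set
   passes or candidates are exhausted.

An `accessibility_survey` utility partitions a genome into fixed windows and
reports the fraction for which a set of ≤ n sgRNAs reaches an
expected-binding-site floor (25 sites per 50 kb is the empirical density
needed for imaging).

The bundled mismatch-penalty table is a clearly labelled **synthetic
stand-in** with the qualitative structure of published cutting-frequency
measurements; swap in a measured table via `CfdTable.from_tsv` (columns
`position`, `rna_base`, `dna_base`, `penalty`).

## Worked example

`examples/01_design_sgrna_set.py` plants four guide clusters in a 3 kb
target of a 30 kb synthetic genome plus a genome-wide decoy cluster copying
the strongest prototype, then runs both formulations:

```
formulation 1 (max activity, <= 10 sgRNAs):
  status            ok
  sgRNAs selected   10
  counted sites     20
  on-target score   20.00   (expected number of bound probes in the target)
  off/on ratio      0.0000   (max off-target window / on-target; pass < 0.2)
  iterations        2; removed ['AATCGGGACACTGAGATTTG']

formulation 2 (min sgRNAs, activity >= 10):
  status            ok
  sgRNAs selected   3
  counted sites     11
  on-target score   11.00
  off/on ratio      0.0000
  iterations        2; removed ['AATCGGGACACTGAGATTTG']
```

The decoyed prototype fails the off-target window check on the first
iteration and is removed; the re-solved sets pass. Formulation 1 packs 20
expected probes into the target with 10 guides; formulation 2 reaches the
floor of 10 with only 3. `examples/02_score_binding_sites.py` and
`examples/03_accessibility_survey.py` walk through the scoring model and the
window survey.

## Command line

```bash
guideset design --genome genome.fa --region chr1:1001-3000 \
    --formulation 2 --constraint 10 --out results/run
guideset survey --genome genome.fa --window 50000 --set-size 10
```

`--region` takes 1-based inclusive browser coordinates (internally 0-based
half-open). `design` writes a selected-spacer TSV, on/off-target BED6 files
and a JSON run report; every flag can instead live in a YAML file passed via
`--config` (flags win). Note the documented ratio convention: the tested
quantity is *off/on*, and a set passes when it is **below** the threshold.

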