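# barconcord

Tools for checking how well morphology-based species identifications agree
with species boundaries inferred from COI DNA barcodes.

DNA-barcoding surveys assign each specimen a **morphospecies** name by
classical taxonomic examination and, independently, delimit **putative
species** (OTUs) from the barcode sequences alone. Where the two disagree —
one morphospecies scattered across several OTUs, or several morphospecies
merged into one — the discordance points at overlooked diversity,
misidentification, or imperfect species delineation. `barconcord`
implements the full desk side of such a survey for anyone comparing a
specimen collection against a local reference library: distance
computation, four routes to putative species, reference-library matching,
and the discordance bookkeeping itself.

## What it computes

* **Uncorrected p-distances with pairwise deletion.** For aligned sequences
  x, y the distance is `d(x,y) = m/c`, where c counts sites at which both
  carry an unambiguous base (A/C/G/T) and m the mismatches among them.
  Alignments are first trimmed so all retained sequences share at least 150
  unambiguous sites; pairs sharing fewer than a configurable overlap are
  reported as undefined rather than estimated.
* **Barcode-gap delimitation** (ABGD-style): sort all pairwise distances,
  find the first significant gap above a prior intraspecific divergence P
  (a gap is significant when it exceeds X times the local mean spacing),
  cluster below the gap midpoint, and recurse within clusters. A scan over
  log-spaced priors (default 10⁻⁴…10⁻¹) reproduces the familiar
  groups-versus-prior curve.
* **Single-linkage OTUs** at 2.2% as a local stand-in for BIN-style
  clustering, including the short-sequence fallback: a query outside the
  partition adopts its best match's group when similarity over ≥300 shared
  sites is ≥99%.
* **Single-threshold GMYC.** On a time-calibrated ultrametric genealogy the
  mixed Yule-coalescent model places a threshold T separating speciation
  from coalescent branching. Each inter-event interval k contributes
  `log b_k − b_k x_k` with total rate
  `b_k = λ_b·n_k^{p_b} + λ_w·Σ_j n_{j,k}(n_{j,k}−1)^{p_w}`,
  where n_k counts between-species lineages and n_{j,k} the lineages of
  cluster j. The fit maximizes over T and the rates; a likelihood-ratio
  test against a single-process null (χ², 3 df) judges significance.
  Externally computed partitions (e.g. bPTP, true BINs) are imported from
  two-column TSV files and treated as additional methods.
* **Reference matching and flags.** Per study sequence, up to 100 reference
  matches above 80% similarity (provisional references excluded),
  classified by name agreement; morphospecies flagged *divergent-novel*
  when no reference comes within 5%, and *first-barcode* when their name is
  absent from the library.
* **Discordance classification.** Per morphospecies: category S (split) or
  L (lump), resolution flag R when the delimitation methods disagree
  (`_` when unanimous), and context H when the issue is visible within the
  study's own specimens versus A only after merging with the reference
  library. Provisionally named morphospecies additionally get a resolution
  verdict (separate putative species / grouped with a described species /
  mixed) plus their nearest reference below 5%.
* **A calibrated synthetic-data generator** (Jukes-Cantor evolution over a
  pure-birth species tree, configurable barcode gap, injectable splits,
  lumps, misidentifications, provisional names and short fragments) so
  every stage is testable without downloads.

## Worked example

```python
import barconcord as bc

ds = bc.generate(bc.SyntheticConfig(n_species=6, samples_per_species=4,
                                    seed=42))
dm = bc.p_distance_matrix(ds.sequences)
rep = bc.calibration_report(ds.sequences, ds.truth.assignment)
print(f"{rep['max_intra']:.4f} {rep['min_inter']:.4f}")
print(bc.abgd_partition(dm, prior=0.02).n_groups())
print(bc.single_linkage_partition(dm, threshold=0.022).n_groups())
```

prints

```
0.0185 0.1154
6
6
```

— realized within-species divergence tops out at 1.85%, the closest species
pair sits at 11.5% (a barcode-gap ratio of 6.2), and both distance-based
methods recover the 6 simulated species exactly. Running the discordance
classifier on a 5-species dataset with an injected cryptic split and lump
(`examples/04_concordance_report.py`) prints

```
Species 01                          S—_—H
Species 04, Species 04-B            L—_—H
Species 03                          concordant
Species 05                          concordant
```

i.e. the label shared by two true species is split by all methods within
the study data (`S—_—H`), and the species carrying two labels is lumped by
all methods (`L—_—H`).

The `examples/` directory holds one short script per capability;
`barconcord --help` exposes the same stages as shell subcommands
(`simulate`, `distances`, `delimit`, `match`, `concord`, `run-all`).

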