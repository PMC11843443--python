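# phyloloc

Gene-age dating and subcellular-localization evolution statistics for
*Drosophila*-style phylostratigraphy.

## The problem

When during a lineage's history did each gene originate, and how does a
protein's subcellular address change as its gene ages?  Phylostratigraphy
answers the first question by parsimony: a gene is assigned to the branch
(phylostratum) implied by the most distantly diverging outgroup clade that
still carries a syntenic ortholog.  On a *Drosophila*-like reference tree the
strata run from br-2 (oldest, pre-dating the deepest outgroup) to br6
(species-specific), collapsing into four age classes — oldest (br-2), older
(br-1), old (br0, the genus MRCA) and young (br1–br6).

Given per-gene ages, the package quantifies how localization structure
covaries with age:

- **fixation rates** per branch, (births − deaths) / branch span in MY;
- **localization enrichment**: observed vs expected protein counts per
  (branch, compartment) cell, expected = `total_c · n_b / N`, excess
  = (O − E)/E × 100, Fisher exact tests with BH correction;
- **co-localization**: within a branch, the fraction of single-compartment
  protein pairs sharing a compartment, against 100 equal-size resamples of
  comparison pairs (target-vs-other-branch, or all pairs);
- **co-function**: pairs sharing a pathway, expected at rate
  `p_co = Σᵢ P²(Kᵢ)` over the pathway universe;
- **interaction modularity**: STRING-style physical links (score > 700),
  a 9×9 per-gene interaction-density matrix, and repeated sampling of
  interaction pairs split into within-compartment (WC) vs
  between-compartment (BC) groups;
- **sequence divergence**: greedy identity clustering (0.5 identity, word
  length 3), cluster filters, and the average pairwise divergence *D* per
  compartment;
- **paralog relocalization**: duplication-age classification
  (ancient = br-2→br-1/br0, br-1→br0; else recent) and the K/KE/S/E/SE
  partition of offspring-vs-parent localization sets, with K-vs-non-K
  sequence similarity and mutation-position comparisons.

A first-class synthetic-data generator emulates all six input classes
(presence matrices, localization probability tables, physical links, pathway
annotations, paralog tables + FASTA, GTF) with controllable branch birth
rates, outgroup loss, age-dependent compartment preferences, a
within-compartment edge preference, a co-function boost and
compartment-dependent substitution rates — retaining ground truth so every
analysis can be validated by parameter recovery.

## Worked example

```python
import phyloloc as pl

# fixation-rate arithmetic from published branch counts
rate = pl.fixation_rate(births=714, deaths=218, span_my=7)
print("br0 fixation rate:", round(rate.rate, 3), "->", rate.rounded(), "genes/MY")

# simulate inputs, date the genes, test extracellular enrichment
ds = pl.simulate(pl.SimulationParams(n_genes=500, n_edges=2000, seed=7))
ages = pl.assign_ages(ds.presence, pl.default_clade_map())
recovered = sum(ages[g] == b for g, b in ds.truth.true_branch.items())
print(f"recovered {recovered}/{len(ages)} true branches")

from phyloloc.localization import called_sets_from_table
called = called_sets_from_table(ds.localization)
table = pl.enrichment(ds.truth.true_branch, called, group_by_age_class=True)
row = table[(table.group == "young") & (table.compartment == "Extracellular")].iloc[0]
print(f"young/Extracellular: observed {row.observed}, expected {row.expected:.1f}, "
      f"excess {row.excess_pct:+.0f}%, Fisher p = {row.fisher_p:.2e}")
```

prints

```
br0 fixation rate: 70.857 -> 71.0 genes/MY
recovered 500/500 true branches
young/Extracellular: observed 17, expected 6.3, excess +168%, Fisher p = 1.82e-05
```

The rate 71 genes/MY is the loss-corrected br0 fixation rate from its
published inputs; branch recovery is exact because no outgroup loss was
simulated; and the positive excess shows the planted young-extracellular
skew recovered as a localization enrichment.

## Command line

Every stage is also a CLI subcommand over one run directory:

```sh
phyloloc simulate --seed 1 --outdir run/     # write all six synthetic inputs
phyloloc run-all  --seed 1 --outdir run/     # simulate + age + enrich + pairs
                                             #   + diverge + ppi + paralogs
```

`run/manifest.json` records the configuration, seed, per-stage row counts and
output hashes; a rerun with the same config reproduces identical hashes.

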