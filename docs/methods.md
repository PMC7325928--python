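# Methods

## The problem

Ticks — especially nymphs and males — carry very little endogenous
microbial DNA. When 16S rRNA amplicon libraries are built from such
low-biomass specimens, DNA introduced by homogenization beads,
extraction kits and PCR reagents can make up a large share of the final
reads, and the less template a specimen contributes, the larger that
share becomes. Negative controls carried through each processing step
(homogenization controls, extraction controls, amplification controls)
capture the contaminant community of that step, and positive controls
(a mock community) verify the run itself. `tickdecon` implements the
control-based procedure for separating contaminant OTUs from genuine
tick-microbiota OTUs, together with the downstream contamination-rate
and alpha-diversity analyses and a ground-truthed simulator.

## Contaminant classification

Two rules are applied to every OTU, using only the negative controls
(positive controls are excluded from every pooled total and maximum):

1. **Main-contaminant rule.** Pool the reads of each negative-control
   category. An OTU holding strictly more than 1% of any single
   category's pooled reads is a main contaminant. The rule is scale-free
   (invariant under rescaling the control columns), so it is meaningful
   only when controls carry substantial contaminant mass.

2. **Cross-talk interval rule.** Index misassignment on the flow cell
   ("cross-talk") moves a small fraction ε of every OTU's reads into
   other libraries, so controls legitimately contain traces of genuine
   OTUs. Under this null, the count of OTU *i* observed in a control is
   modelled as Binomial(N_i, ε), where N_i is the OTU's dataset-wide
   total and ε = 0.0002 (0.02%) by default. Because ε is taken from the
   literature rather than estimated from the run, the decision point is
   not the expectation εN_i but the upper bound U_i of the two-sided 99%
   confidence interval of that law (the 0.995 binomial quantile). An OTU
   whose maximum single-control count M_i strictly exceeds U_i is a
   contaminant; an OTU at or below U_i is consistent with cross-talk
   alone. When both rules fire, the call records `main_1pct`.

   The interval is deliberately conservative: U_i is a quantile of the
   *total* leak Binomial(N_i, ε), whereas any single control receives
   only its share of that leak (roughly ε·N_i/(S−1) in expectation over
   S libraries). Under a pure cross-talk null the false-flag probability
   of the rule is therefore far below the nominal 1% tail mass; the
   acceptance suite measures 0% over 50 simulated datasets. No
   multiplicity correction is applied across OTUs or controls — the
   interval is applied per OTU, and the conservatism above absorbs the
   multiplicity in practice; this is a documented caveat, not a claim of
   exact error control.

   M_i is the maximum over all negative controls pooled. A per-category
   variant (compare each category's maximum against U_i) is provably
   identical — the maximum over the union equals the maximum of the
   per-category maxima, and U_i depends only on N_i — so no separate
   mode exists.

   Options: `family="poisson"` replaces the binomial quantile with a
   Poisson(εN) quantile (convenient for very large N, differs by at most
   one count in practice); `one_sided=True` uses the 0.99 quantile
   instead of the 0.995 one. Whether the original procedure's interval
   was one- or two-sided is not determinable from its description; the
   two-sided bound is the stricter default.

3. **Reverse (spill) check.** The logic above assumes controls are not
   contaminated *by* the samples beyond cross-talk. The check takes the
   most abundant genuine OTU (in tick data the *Ca.* Midichloria
   endosymbiont) and verifies no negative control carries more of its
   reads than the expected cross-talk count εN. Controls exceeding it
   are listed, and the CLI can be made to fail on them.

## Table-level pre-filters

Before classification the OTU table is cleaned in one pass: OTUs whose
dataset-wide total is below 0.005% of the grand total (computed over all
columns, controls included, before any removal; retention uses ≥) are
dropped, and OTUs that are organellar (any rank named Mitochondria or
Chloroplast, case-insensitive) or lack a domain-level affiliation
(`unknown` / `multi-affiliated`) are removed. The two filters are
idempotent; they commute only if the rare threshold is anchored to the
original grand total, because removing organellar reads first lowers
the total — the pipeline applies the rare filter first for this reason.

## Contamination rates and the depth floor

A specimen's contamination rate is the fraction of its reads in flagged
OTUs, computed on the table *before* removal (but after the
pre-filters). Rates are binned per instar with breaks at 20% and 50%;
bins are left-closed ([0,0.2), [0.2,0.5), [0.5,1]). After removal,
samples retaining fewer than 500 reads are dropped — including samples
that were deep enough before filtering.

## Diversity measures

Observed richness (OTUs with nonzero count), Shannon entropy
H = −Σ p_i ln p_i (natural log; base exposed), Gini–Simpson 1 − Σ p_i²
(the Σp² "dominance" and inverse forms are options, since "Simpson
index" is ambiguous across tools), and Faith's PD — the branch length
of the minimal subtree connecting a sample's OTUs to the root, root
connection included by default (the dominant convention of phylogenetic
diversity software; a no-root option subtracts the root-to-MRCA path).
`diversity_impact` fixes the eligible sample set first (≥ 500 reads
after removal) and computes every measure on that same set before and
after removal, so comparisons are paired. No rarefaction is performed.

## Statistical comparisons

* Pearson chi-square of independence (no Yates correction by default)
  on instar × contamination-category counts.
* Paired Wilcoxon signed-rank for filtered vs unfiltered diversity:
  zero differences dropped, exact null for n ≤ 25 without ties, normal
  approximation with tie-corrected variance otherwise. The paired form
  is the default because the same samples are measured in both states;
  an unpaired rank-sum variant is provided. Note the signed-rank test is
  not invariant under monotone transforms of the values (its ranks are
  of difference magnitudes); the rank-sum and Kruskal–Wallis tests are.
* Kruskal–Wallis with mid-rank tie correction between instars, p from
  chi-square with k − 1 df.

All p-values are two-sided; degenerate inputs (all differences zero,
all values identical) report p = 1 with a warning rather than erroring.

## The simulator

`simulate_dataset` draws, per library, in a fixed order (nymphs, males,
females, HC, EC, AC):

* **Genuine community** (specimens only): a shared tick profile whose
  top OTU has expected share `dominant_otu_fraction` (default 0.4,
  emulating a dominant endosymbiont) and whose remaining OTUs decay
  geometrically with lognormal jitter. Per-specimen composition is
  Dirichlet-multinomial around that profile (`dm_concentration`,
  default 200). The genuine read total is a gamma-mixed Poisson
  (negative binomial, size `depth_dispersion` = 5) with mean
  `depth_mean` × biomass; `depth_mean` defaults to 2000 so a biomass-1
  specimen averages ≈ 4000 total reads, comparable to a typical
  low-biomass tick run, and female biomass defaults to 5× nymph/male.
* **Kit contaminants**: one profile shared by every homogenized or
  extracted library (specimens, HC, EC) at a Poisson absolute level of
  `kit_share` × `contaminant_background_reads` (0.85 × 2000 by
  default) — constant in absolute reads, so low-biomass libraries show
  higher contaminant fractions. This is the biomass mechanism the
  method exists to counteract, and it is what makes nymph contamination
  rates (~53%) exceed female ones (~18–20%) at the defaults.
* **Amplification contaminants**: a distinct profile added to *every*
  library at the remaining 15% of the background; AC controls contain
  only these (plus cross-talk), mirroring the contrast between
  homogenization/extraction and PCR-only control communities.
* **Cross-talk**: for each OTU a Binomial(N_i, rate) number of reads is
  drawn out of its source libraries without replacement (multivariate
  hypergeometric) and reassigned uniformly across the other libraries.
  Per-OTU totals and the grand total are conserved exactly.

Control-plate sizes default to 12/12/21 (HC/EC/AC). Specimen counts
default to 100/30/30 — the full pipeline plus classification then runs
in well under a second, so replicate studies (20–50 datasets) used by
the tests and the acceptance script stay fast.

What the simulator does **not** emulate: taxonomic realism of the
contaminant OTUs (labels are placeholders), sequencing error and
chimeras (handled upstream of an OTU table), plate structure in
cross-talk (leaks are uniform, not neighbour-biased), batch-to-batch
variation in reagent lots, and genuine OTUs shared with contaminant
genera. Passing tests therefore show the procedure behaves correctly
under its own assumptions, not that those assumptions hold for any
particular real dataset.

## Numerical and design notes

* The binomial quantile comes from `scipy.stats.binom.ppf`; tests verify
  it against direct CDF summation for every N ≤ 10,000 at three rates.
* The threshold comparison is strict (M > U), matching "above the upper
  threshold"; ties at the bound are not flagged.
* Classification is a pure function of its inputs; identical tables give
  identical calls.
* BIOM 2.1 I/O uses the BIOM `Table` shipped inside scikit-bio with
  HDF5 storage via h5py; TSV I/O round-trips exactly, with an empty
  (0-OTU) table degrading to a header-only file.
* Category aliases HC/EC/AC/PC are accepted case-insensitively in
  metadata files.
* A sample with zero total reads has undefined Shannon/Simpson and an
  undefined contamination rate; these are reported as NaN (or raise, in
  the scalar functions) rather than silently becoming 0.

## Known limitations

* The cross-talk rate ε is an external constant, not estimated from the
  run; if the true rate differs substantially, the interval rule's
  operating point shifts accordingly.
* The 1% rule's flag set depends on the contaminant mass actually
  captured by the controls; near-empty controls make it fire on traces.
  The classifier therefore reports which rule fired so users can weigh
  the evidence.
* Faith PD requires every present OTU to be a leaf of the supplied
  tree; extra tree leaves are fine, missing ones are an error rather
  than a silent drop.
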