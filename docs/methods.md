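# Methods

## The problem

Water-crowfoots (*Ranunculus* section *Batrachium*) hybridize freely in
rivers, and the hybrids are often sterile morphological intermediates that
cannot be identified from form alone. Two molecular signals resolve them:

1. **Nuclear ITS additivity.** The ribosomal ITS region is biparentally
   inherited. A first-generation hybrid carries both parental ribotype
   copies, so direct Sanger sequencing shows a double peak at every column
   where the parents differ. Base callers record the double peak as the
   IUPAC ambiguity code whose base set is the *union* of the parental bases
   — an "additive polymorphism". The pattern of additive columns against a
   reference panel of parental ribotypes identifies the parental species
   pair.
2. **Plastid maternal inheritance.** Chloroplasts are maternally inherited
   in these plants, so a hybrid's plastid haplotype (assigned by nearest
   reference over two intergenic spacers, rpl32-trnL and petL-psbE) names
   the seed parent. The other ITS parent is then the pollen donor, which
   orients the cross and, aggregated over samples, measures how
   unidirectional the hybridization is.

## Site classification

For a query row and a candidate parent pair, every aligned column gets one
of six labels. Writing `U(a,b)` for the IUPAC union:

| label | condition |
|---|---|
| GAPPED | any of the three symbols is `-`, or the query is `N` |
| INVARIANT | parents equal, query equal to them |
| ADDITIVE | parents differ, query = `U(a,b)` |
| PARENT_A / PARENT_B | parents differ, query equals one parent |
| RESIDUAL | anything else |

Notes on the corners:

* `N` in a query carries no additive evidence (it is compatible with
  everything), so it is counted with GAPPED and excluded from scoring.
* When one parent's code subsumes the other's, a query equal to the wider
  code satisfies both the ADDITIVE and the PARENT definitions; ADDITIVE
  takes precedence. This corner cannot occur with single-base panel
  sequences.
* PARENT_A/PARENT_B at columns where the parents differ is *expected* in
  real hybrids — one copy's peak often drops out of the trace — so such
  columns count toward neither additive evidence nor residual noise.

The classifier is checked exhaustively against a truth-table oracle over
all 16^3 symbol triples and on random 650-column rows.

## The 1-bp indel and the shifted superposition

When the two parents differ by a single-base indel (here: one species
carries a diagnostic extra base near alignment column 30), the two
co-amplified templates fall out of register downstream of it: both
polymerases emit one base per trace position, so at aligned column
*i* ≥ *g* (gap column *g* in the shorter parent) the trace superposes
`long[i]` with the shorter parent's base that is aligned at column *i+1*.
`shifted_superposition` tests each downstream column for
`query ⊇ U(long[i], short[i+1])` and declares the shift consistent when at
least `1 − τ_noise` of testable columns pass (default `τ_noise = 0.05`).

When the shift is consistent, `score_pair` judges downstream columns
against the offset model instead of the plain column union: an exact match
to the offset union counts as ADDITIVE where the *aligned* parents differ
and INVARIANT where they agree; a strict subset (peak dropout) counts as
parent-only; only offset-inconsistent columns are RESIDUAL. This keeps
`n_additive` on the same scale as for indel-free pairs — the biologically
additive columns — while the register offset itself is explained rather
than flagged, and the indel is carried separately in
`PairScore.indel_shift`. The model is applied only to single-column indels;
multi-base indels between ribotypes are treated as GAPPED columns and
excluded.

## Parentage calling

Per sample, against a panel of named ribotypes (`species|ribotype` — a
species may contribute several regional ribotype variants):

1. **Species check.** Nearest single ribotype by mismatch count over
   columns where both carry a base. Distance ≤ `τ_species` (default 2,
   the scale of within-species ribotype variation) → SPECIES.
2. **Pair scan.** Every unordered cross-species ribotype pair is scored;
   pairs are ranked by `n_residual` ascending, then `n_additive`
   descending, then `n_parent_only` ascending, then lexicographic species
   pair and ribotype names — fully deterministic. Best pair with
   `n_residual ≤ τ_residual` (default 2) → F1_HYBRID; with more residuals
   → COMPLEX_HYBRID; no pair with any additive site → UNRESOLVED.
3. **Third-parent ranking** (complex hybrids). Each remaining panel
   ribotype is scored by how many residual columns it explains as an exact
   three-way union in which it contributes a base outside the pair union
   (under the offset model downstream of a consistent shift). Candidates
   are ranked by explained count.

`constant_additive_positions` intersects the per-sample additive sets of a
hybrid group, separating the constant additive core of the group from
additive sites private to individual samples.

### Identifiability of three-way hybrids

A three-way hybrid's ITS is an unordered superposition of three ribotypes;
nothing in the additive pattern says which two crossed first. When the
third lineage's private contribution is comparable in size to a pair
partner's, the residual-minimizing ranking may place a different two of
the three true contributors in the "pair", with the remaining true parent
emerging as the top third candidate. The identifiable quantity — and the
one the tests assert — is the *contributor trio* (best pair plus top third
candidate), recovered in 100% of noise-free synthetic replicates. The
pair/third partition itself agrees with the generator's bookkeeping only
about two-thirds of the time and is not a meaningful error when it flips.

## Cross orientation and directionality

A hybrid's haplotype per marker is the nearest reference by mismatch count
(ties broken lexicographically and flagged; unassigned beyond
`δ_max = 2`, which accommodates the slightly deviating within-clade
variants seen in the survey data). Each marker's haplotype maps, through a
species→haplotype table, to a set of species; intersected with the two ITS
parents this gives exactly one maternal candidate (ORIENTED), both parents
(shared haplotype — UNORIENTED), or none. Markers nominating different
maternal parents give CONFLICT. The directionality statistic is the
fraction of ORIENTED crosses whose paternal species is the focal pollen
donor; UNORIENTED/CONFLICT are excluded from the denominator and reported
as counts. The packaged default species map encodes the survey's reference
clades (rpl32-trnL A/C/D/I, petL-psbE A/C/F); it is overridable, and
simulated bundles ship their own map.

## Regional summary arithmetic

Per (region, locality): species vs hybrid individual counts (UNRESOLVED
samples excluded and reported). Per region: percent hybrid individuals
(denominator: all classified individuals), percent of localities with
hybrids, and percent of hybrid-only localities — both with the number of
river sites *studied* in the region as denominator (21 and 19 in the two
survey regions), which is the denominator that reproduces the published
locality percentages. Percentages are rounded half-up to integers for
reporting; raw ratios are retained. The packaged survey fixture is a
synthetic reconstruction: per-locality counts are an even split consistent
with the published aggregates (66 individuals / 48 hybrids / 16 hybrid
localities / 1 co-occurrence site in Lithuania; 36 / 13 / 6 / 3 in Central
European Russia), not a transcript of the original supplementary table.

## The synthetic-data generator

`simulate.SimConfig` defines the study conditions; all randomness flows
from one integer seed through numpy's PCG64 (`default_rng`), and identical
seeds give byte-identical FASTA/TSV output.

* **Panel.** Species ribotypes are mutated independently from a random
  ancestral sequence. The per-lineage substitution rate `q` is solved from
  the requested *pairwise* divergence `p` via `p = 2q(1−q) + (2/3)q²`
  (substitutions uniform over the three alternative bases), so the
  expected differing-column count per species pair is `L·p` — 19.5 at the
  default `L = 650`, `p = 0.03`, the scale of the published per-group
  additive counts. Within-species ribotype variants are drawn at
  `0.003`/column (1–2 substitutions). An optional single-base indel gives
  one species a base at column 30 where all others carry a gap.
* **Hybrids.** F1 ITS = column-wise parental union; for an indel pair the
  one-base-offset superposition is applied downstream. Three-way hybrids
  add a third parent's base at 6 columns (default) where it falls outside
  the pair union. Dropout noise collapses each ambiguous column to a
  single contributing base independently with the stated probability.
  Plastid rows are copied verbatim from the maternal parent's haplotype
  for both markers; under `FIXED_NON_FOCAL` the focal species (default
  *circinatus*, the survey's pollen donor) is always paternal.
* **Not modelled:** concerted evolution / partial homogenization of ITS
  copies, PCR drift and recombination, sequencing quality gradients along
  the read, within-individual plastid heteroplasmy, backcross genotypes
  beyond the three-way union, and missing data. Passing recovery tests
  therefore show the inference is correct *under the additive-consensus
  model*, not that real traces are always this clean.

## Problem sizes and numerical choices

Tests and the acceptance script use 100 synthetic F1s and 50 three-way
hybrids at `L = 650` with a 4-species panel — the survey's own scale —
which keeps the whole suite under ~10 s. All thresholds (`τ_species = 2`,
`τ_residual = 2`, `τ_noise = 0.05`, `δ_max = 2`) are explicit package
defaults chosen from the variation the survey data tolerates
(within-species ribotypes 1–2 substitutions apart; a within-clade plastid
variant at distance 1); they are configurable and not fitted quantities.
All ranking ties break lexicographically, so every verdict is
deterministic given the inputs and configuration.

## Known limitations

* Direct-sequencing additivity cannot distinguish an F1 from later
  generations that retain both parental ITS arrays; "F1" here means
  "two-parent additive pattern".
* A hybrid of two species sharing a plastid haplotype can never be
  oriented (reported UNORIENTED, excluded from directionality).
* Ribotype variants more than `τ_species` substitutions from every panel
  entry will not be called SPECIES even if conspecific; the panel must
  represent local ribotype variation.
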