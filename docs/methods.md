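# Methods

## Facet persistence

A finite 1-D point set `S ⊂ ℤ≥0` (nucleotide positions of one letter)
induces, at each radius `r`, the Vietoris–Rips complex `Δ_r`: a vertex
subset is a face iff all pairwise distances are `≤ r` (closed threshold).
On a line this is the clique complex of an interval graph, so its maximal
cliques are exactly the maximal contiguous windows of span `≤ r`; the
engine uses this fast path and is cross-checked, in tests, against
Bron–Kerbosch maximal-clique enumeration on the threshold graph and
against exhaustive subset enumeration.

The facets of `Δ_r` index the minimal primes `P_σ` of the
Stanley–Reisner ideal `I(Δ_r)` (generated by the minimal non-faces;
`minimal_nonfaces` computes these by subset enumeration, bounded at 15
vertices). As `r` grows, a simplex becomes a facet when it becomes
maximal and dies when a larger clique absorbs it. Because the filtration
is nested and cliques only grow, facet status is contiguous in `r`; the
barcode builder asserts this and fails loudly if it is ever violated.

Conventions where a choice had to be made:

* **Closed threshold** (`d ≤ r`) for Rips edges, so unit-spaced positions
  connect at `r = 1` — consistent with the worked primer example.
* **Facets are maximal faces of the full clique complex**, not of a
  truncated skeleton: a triangle stops being a facet when a 4-clique
  swallows it. Higher-dimensional facets are computed (they drive deaths)
  but only dimensions 0–2 are reported.
* **Death at grid resolution**: the recorded death is the smallest grid
  radius at which facet status is lost. With integer positions and the
  integer grid this is exact.
* **Bars alive at the last grid radius** get death `+∞` (JSON `null`).
* **Persistence rate at r = 0** is defined as 0 (the count/radius
  quotient is otherwise undefined; a constant placeholder is harmless to
  tree models and avoids duplicating the count feature).
* Positions are 1-based sequence indices, but any non-negative integers
  are accepted: every feature is translation-invariant (tested), so the
  origin convention cannot affect outputs.

The homology comparator computes Rips persistent homology in dimensions
0–2: H0 by union-find over edge insertions, H1/H2 by mod-2 reduction of
the boundary matrix over simplices up to dimension 3 (dense enumeration,
bounded at 50 points). Field coefficients are mod 2, the standard choice
for Rips barcodes. For collinear inputs H1 and H2 are provably empty;
this is asserted property-style over random instances.

## Featurization

Grid: `r = 0, 1, …, 49`, shared by every channel and sample so feature
columns align across sequences. Per channel: facet counts for dimensions
0–2 (150 values) then persistence rates (150), radius-major; channels in
the fixed order A, C, G, T/U → 1200 dims. T and U share one channel, so
DNA and RNA occupy the same feature space; strands mixing T and U are
rejected at curation but the featurizer itself is total. Only k = 1
channels are implemented; the position-set machinery is generic enough
to serve as an extension hook for k-mer channels. No PCA or other
projection is applied to the nucleic features. Reverse complementation
is *not* an invariance (channels are per-letter); a test pins this.

## Protein embeddings

The production backend is ESM2-t36 (3B), exposed behind a provider
contract: final-layer (layer 36) residue representations, mean-pooled
over residues, giving 2560 dims. "Aggregating across 36 layers" admits
several readings; final-layer mean pooling is the standard fixed-length
ESM2 recipe and the `provider_tag` records the choice so alternatives can
coexist. Sequences beyond 1022 residues are truncated with a warning;
non-standard residues map to X. Embeddings are cached per (provider,
sequence) within a run.

The mock provider draws a 2560-dim standard-normal vector from a PRNG
seeded by (salt, SHA-256 of the residue string): deterministic,
platform-stable, distinct across sequences. It preserves *identity*
information only — no biochemistry — so pipeline tests exercise plumbing
and the nucleic signal path, not protein-side learning.

## Regression and evaluation

A single `GradientBoostingRegressor` inside a scikit-learn pipeline with
`StandardScaler`: 10 000 estimators, depth 7, `min_samples_split` 3,
learning rate 0.01, `sqrt` feature subsampling, subsample 0.7, squared
error loss, fixed seed. The `fast` profile reduces only the tree count
to 500 for tests and quick runs; on the synthetic benchmark the boosting
objective is already converged there (identical CV PCC at 500–3000
trees). Standardization is fitted on training folds only — an
instrumented test verifies the scaler never sees held-out rows.

Cross-validation: shuffled k-fold (default k = 10), repeated over seeds.
Two protocol styles are reported because pooling is ambiguous in common
practice: per-seed metrics on pooled out-of-fold predictions
(mean ± sd over seeds) and per-fold metrics (mean ± sd over folds).

Labels: stored as ΔG = −1.3633·pKd kcal/mol. PCC and RMSE are invariant
to the global sign flip, so the sign convention is purely physical
(binding free energies are negative); the scale-only variant
(`signed=False`) converts error magnitudes between scales.

## Curation

Filters run in order, each rejection tagged with the first failing rule:
mixed T/U bases; assay temperature ≠ 298 K (when enforced); qualified
labels (`~`, `<`, `>`); strand shorter than the policy minimum (5 for
benchmark-style curation, 1 for the relaxed variant); non-standard
bases; optionally, RNA records not flagged as bona-fide RNA-binding
proteins (the flag must be supplied — no annotation lookup is
performed). Records with non-standard bases are rejected by default;
`strip_nonstandard` instead deletes the offending positions *before* the
length filter, an opt-in because deletion changes position geometry, the
very signal the features encode. Curation is idempotent and
order-stable. Temperature absent from the input is "unknown" and passes
only when the 298 K requirement is off.

## Synthetic benchmark

`generate_fixture` emulates a curated affinity table: protein lengths
50–300 with a per-protein basic-residue (K/R) enrichment drawn from
U(0.05, 0.35); strand lengths 5–45 nt (the benchmark strand-length
range), half DNA half RNA, uniform composition; all records at 298 K
with clean numeric labels. The planted label is

    pKd = 4.0 + 0.25·|S_{T/U}| + 0.10·mean-NN-gap(S_A)
              + 0.5·(K/R fraction) + N(0, noise_sd)

The first two terms are directly encoded by the CAP features (the
dimension-0 count at r = 0 *is* the channel size; the gap structure
shapes the curves), so the nucleic signal dominates and is recoverable
under mock embeddings; the K/R term is deliberately small — under mock
embeddings it is irreducible noise, and it only becomes learnable with a
real protein backend. Coefficients give pKd ≈ 5–9, a realistic affinity
range. What passing recovery tests shows: the featurization preserves
channel-occupancy and spacing information and the harness has no
leakage. What it does not show: performance on real complexes, where the
label depends on chemistry none of the planted terms capture.

Problem sizes in the default test run are chosen to keep the suite quick
at desk scale: 200 random point sets (n ≤ 12, radii 0–12) for oracle
equivalence, 100-sample fixtures and the 500-tree profile for
end-to-end runs.

## Known limitations

* Benchmark results on PDBbind-derived sets (S186-style) require the
  externally supplied tables plus ESM2 weights; the repository supports
  that workflow (`--profile paper --provider esm2`) but cannot verify it
  hermetically.
* The facet engine's fast path is specific to 1-D point sets; the
  Bron–Kerbosch path handles general threshold graphs but is exponential
  in the worst case.
* `minimal_nonfaces` (15 vertices) and `homology_barcode` (50 points) use
  enumeration-scale algorithms by design; they are illustrative
  comparators, not production TDA.
* No secondary-structure, thermodynamic, or learned nucleic-acid
  descriptors; no k > 1 channels; no hyperparameter search.
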