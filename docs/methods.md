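# Methods

This note documents the models and procedures implemented in `chemocart`,
the parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical conventions that
make every run deterministic.

## Spectral processing

Input is centroided MS/MS in MGF; vendor raw files and mzML are out of
scope (conversion is upstream). Spectra missing a CHARGE key are assumed
singly charged, consistent with a workflow built around [M+H]⁺ / [M+Na]⁺
species.

Two filters de-noise each spectrum before any comparison:

1. **Precursor exclusion** — remove every fragment within ±17 Da of the
   precursor m/z. The interval is closed (a peak exactly at precursor ± 17
   is removed); inclusivity is a measure-zero choice fixed for
   testability.
2. **Windowed top-k** — keep a peak only if it ranks among the 6 most
   intense within ±50 Da of its own m/z. Rank ties break toward the
   lower-m/z peak. Both filters are idempotent.

**Consensus clustering.** The published workflow used MS-Cluster, whose
internals (multi-round hashed clustering) we do not reproduce. The
contract it must satisfy — 1.0 Da parent tolerance, 0.5 Da fragment
tolerance, consensus spectra under 3 members discarded — is implemented as
a deterministic single-pass greedy pass: spectra are visited in ascending
precursor order; a spectrum joins the open cluster with the highest
modified cosine among those within the parent tolerance and above the
merge-cosine gate (default 0.7, configurable), otherwise it seeds a new
cluster. Consensus peak lists merge member peaks within the fragment
tolerance into intensity-weighted mean m/z with summed intensity, then
re-apply the windowed top-k filter (we apply the filter both before
clustering and after merging). Member counts are conserved: spectra in =
clustered + discarded, asserted by tests.

**Abundance proxy.** The original study quantified features by LC peak
area; chromatographic feature extraction is out of scope here, so a
feature's per-sample abundance is the sum of its member scans' precursor
intensities (second PEPMASS value), falling back to spectral counts when
precursor intensity is absent.

## Modified cosine

Candidate peak pairs match directly (|Δm| ≤ τ) or shifted by the precursor
mass difference. Intensities are square-root transformed (the convention
of the networking platform; configurable to `none`, which the exact-value
oracle tests use) and L2-normalized per spectrum. A one-to-one matching is
chosen greedily by descending intensity product, ties broken by smaller
m/z deviation then lower m/z; the score is the sum of matched products.
Greedy matching is standard practice and deterministic; tests bound it by
a maximum-weight-assignment oracle and check equality on conflict-free
spectra, and cross-check values against an independent implementation.

**Matched-peak threshold.** The edge rule "more than four matched peaks"
is implemented as ≥ `min_matched_peaks` with default 4 — the convention of
the platform the workflow derives from. The literal reading (≥ 5) is a
single configuration change (`min_matched_peaks=5`).

## Molecular network

All feature pairs are scored; edges require cosine strictly above 0.6 and
≥ 4 matched peaks, then reciprocal rank: each endpoint must be in the
other's top-10 neighbors, ranked by cosine, then matched peaks, then
smaller |precursor Δ|, then lexicographic id (so rank-K ties are
deterministic). Pruning never adds edges and is invariant under node
permutation. Families are connected components with ≥ 2 nodes, numbered by
decreasing size; singletons are listed separately, matching the reporting
convention of family-abundance figures. No maximum-family-size splitting
is applied. Dereplication passes library spectra through the same two
filters, applies the same edge thresholds, and reports the best hit per
feature (full hit lists behind a flag) plus a match-rate summary counting
both features and their underlying spectra.

## Chemodiversity

- **Metrics.** Bray-Curtis Σ|x−y|/Σ(x+y) on abundances and binary Jaccard
  on presence sets. The source workflow's methods text names
  Binary-Jaccard while its ordination figures name Bray-Curtis; both are
  implemented and Bray-Curtis is the default for figure-style outputs.
  All-zero samples are defined to be at distance 1 from non-empty samples
  and 0 from each other (logged). Presence means abundance strictly > 0;
  no minimum-abundance floor is applied (configurable upstream of the
  table).
- **PCoA.** Gower double-centering of −½d², symmetric eigendecomposition;
  axes ordered by decreasing eigenvalue; axes with negative eigenvalues
  are reported but excluded from coordinates (no Lingoes/Cailliez
  correction); proportion explained is over positive eigenvalues; each
  axis's sign is fixed so its first non-zero loading is positive, making
  output deterministic. Verified against an independent implementation
  and by exact distance reconstruction on Euclidean inputs (≤ 1e−9).
- **Rarefaction** draws samples (not spectra) without replacement — the
  sample-level reading matches a rarefaction curve whose x-axis is library
  size — with 20 iterations by default, seeded; at full depth the curve is
  seed-independent by construction.
- **Cross-dataset overlap** cannot use feature ids (datasets are clustered
  independently), so feature identity across datasets is spectral:
  precursors within the parent tolerance and modified cosine ≥ the edge
  threshold. Matching features pool into identity groups (connected
  components of the match graph).
- **Site uniqueness** attributes single-site features to their site and
  reports two normalizations — percent of all detected features and
  percent of single-site features — because the figure being emulated is
  ambiguous between them. Percent-of-all plus the shared remainder sums
  to 100 by construction.

## Chemogeography

Binning produces all 2ⁿ presence patterns over the ordered site list
(default: the study's eight sites); the all-zero pattern is retained as a
node for hypercube integrity but holds no features. The bin network is the
n-hypercube: n·2ⁿ⁻¹ edges, every node of degree n, bipartite and
connected — all asserted by enumeration in tests. Node color position is
min(count / 10000, 1) on a white-to-red scale.

Map rendering formalizes the verbal description of the original
visualization tool (which published neither its σ nor its blending
formula): spot placement rings co-located samples at radius 2·spot_radius
around the site anchor in deterministic angular order; per-spot feature
intensities are scaled to [0, 100] across spots after log10(1+x) when the
scale is logarithmic (linear scaling is invariant under multiplying all
abundances by a constant); pixel blending is log-space linear
interpolation, rendered = background^(1−w) · color^w per channel with
Gaussian weight w = exp(−d²/2σ²) truncated at the spot radius. w = 1
reproduces the spot color exactly and pixels beyond every spot radius keep
the background bit-for-bit. Defaults: spot_radius 12 px, σ 5 px — chosen
so spots read clearly at the default 640×360 canvas; both are
configuration.

## Annotation

Atomic masses are IUPAC monoisotopic values hard-coded to 6 decimals
(H 1.007825, C 12, N 14.003074, O 15.994915, S 31.972071, Cl 34.968853,
Na 22.989770, …) with the electron mass (0.000549 Da) subtracted per
positive charge — required for the sub-ppm targets. Adduct m/z is
(M + Σ atom masses − z·e)/z. RDBE is C − H/2 + N/2 + 1 with halogens
counted as hydrogen.

Residue and delta dictionaries are TSV data files (not code) so
nonproteinogenic units can be added without code changes; Leu/Ile is a
single intentionally degenerate entry, and Ala/N-Me-Gly are isobaric
entries reported jointly when either matches. Neutral-loss sequencing is
linear-series annotation only — cyclic-peptide ring-opening enumeration is
out of scope (ring closure is inferred from RDBE and NMR, which this
package does not handle). Unmatched losses are flagged, never guessed, and
the terminal fragment mass is reported verbatim: for the published
C₁₀H₁₃O⁺ terminal fragment the recorded observed mass sits ~14 ppm from
the theoretical ion mass, and the package surfaces that discrepancy rather
than resolving it. Analog deltas match pairwise precursor differences
against the dictionary at 0.02 Da tolerance (monoisotopic matching; the
nominal "34 Da" and "14 Da" shifts are the rounded dictionary values).
Chlorine counting compares the normalized M/M+2/… envelope against
binomial (0.7577/0.2423)ⁿ patterns for n ≤ max_cl; best n minimizes the
squared error between probability vectors and the score 1 − err/2 ∈ [0, 1].

## Synthetic study conditions

The generator emulates the statistical structure the pipeline must
resolve, not the instrument physics:

- 20 scaffolds per dataset, each spawning Poisson(3) analogs from the
  delta menu {±CH₂, ±H₂, +O, ±(Phe↔Leu)}; analogs shift the precursor and
  a Bernoulli(0.5) subset of peaks, exercising both matching modes of the
  modified cosine, mirroring how homologous series co-fragment.
- 20–60 fragment peaks per spectrum, log-normal intensities; eight sites
  with the study's codes and approximate regional anchor coordinates
  (documented placeholders); 2 samples per site; per-feature site
  patterns drawn with 0.2 per-site inclusion probability (so roughly half
  of detected features are multi-site, matching the regime where a
  majority of molecules occur at more than one location); 3–8 replicate
  scans per occupied sample; m/z jitter SD 0.01 Da; intensity CV 0.2; 2
  spurious low-intensity peaks per scan; library coverage 0.05 of
  scaffolds (the sparse-match regime of under-explored collections).
- Geometry guarantees identifiability: scaffold base precursors sit on a
  70 Da grid (wider than twice the largest analog delta plus the parent
  tolerance) and fragment peaks on a 2 Da grid, so at zero noise the
  pipeline must recover the planted features *exactly*, and multi-dataset
  runs interleave private scaffolds of different datasets onto disjoint
  grid slots so cross-dataset overlap estimates cannot be inflated by
  precursor coincidences.

What this does **not** emulate — and hence what passing tests do not
establish about real data: chromatographic co-elution and peak-area
quantification, adduct multiplicity and in-source fragmentation, charge
states above 1+, mass-accuracy drift, true fragmentation chemistry
(fragments are random positions, not bond cleavages), and the scale of a
repository-level comparison (desk-scale runs use tens of scaffolds and
thousands of spectra; the statistics are chosen to be meaningful at that
size).

## Determinism and error handling

Every stochastic step consumes a `numpy` generator seeded from the run
seed; identical seeds give byte-identical MGF/TSV outputs and identical
manifests (up to timestamp). Every output file embeds a provenance record
(tool version, seed, parameter hash): a `#` comment line for MGF/TSV, an
XML comment for GraphML, a `_provenance` key for JSON and a tEXt chunk for
PNG. Malformed MGF raises a parse error naming the line; metadata tables
are validated for duplicate ids, coordinate bounds and unknown site codes
(folded into OTHER with a warning). The CLI exits 0 on success, 1 on usage
errors, 2 on data errors.

## Known limitations

- The greedy consensus clustering is order-dependent by construction
  (precursor-sorted, deterministic) and is a stand-in for the published
  tool's multi-round algorithm; it satisfies the same tolerances and
  discard rule but will not reproduce that tool's cluster boundaries on
  borderline real data.
- Dereplication implements identity search only; analog/variable-mass
  library search modes are not provided (the modified cosine's shift
  matching covers the analog case within families).
- The spatial renderer is a faithful formalization of a verbally described
  visualization; its σ/radius defaults are package choices, not published
  values.
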