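# Methods

## Marker pairing through an intermediate genome

Markers are exported to FASTA with the full key (species, linkage group,
cM, marker id) encoded in the header, aligned to the reference genome of a
related species, and filtered in one of two modes:

* **standard** (homology) — a marker is retained only with a *single*
  reported placement at MAPQ ≥ 10. "Single" means no secondary or
  alternative placements at all (`n_hits == 1`), which deliberately
  discards loci still present in two similar copies after WGD.
* **homeolog** — for a non-duplicated outgroup map compared against a
  duplicated genome: MAPQ floor 2, up to `max_hits` placements retained per
  marker, ranked by MAPQ then leftmost coordinate. `max_hits` defaults to 2
  because each pre-duplication chromosome has at most two salmonid
  homeologs; it is configurable upward. With the builtin exact-substring
  mapper, whose quality model is binary (60 unique / 0 multi-hit), the
  homeolog floor is 0; the ≥ 2 default applies to aligner-produced SAM.

Pairing is greedy and global per contig: all cross-species candidate pairs
within `max_distance_bp` (default 10,000,000) are sorted by distance and
accepted in order, skipping candidates whose marker is already used —
greedy sequential nearest-pair selection, not optimal bipartite matching,
matching the published tool's semantics. Distance is measured
start-to-start; alignment length and strand are ignored (markers are short
reads; only proximity matters). Equal distances break by contig label,
lower coordinate, then marker ids, so results are deterministic. In
homeolog mode each outgroup marker may pair once per distinct retained
placement; target markers stay single-use. Internal genomic coordinates
are 0-based half-open; SAM input is converted on read.

The reciprocal-best-hit baseline scores marker pairs by shared distinct
k-mers (k = 12) with an exact-identity override; ties for best hit yield
no pair. External hit tables can replace the builtin scorer.

## Homology, arms and homeologs

Linkage-group correspondence requires the top Oxford-grid cell to hold at
least `min_pairs = 5` pairs and at least `dominance = 2.0` times the
runner-up. These defaults are deliberately permissive: genuine homologous
cells in data of this type carry tens of pairs, and no published numeric
rule exists to inherit. A group corresponding to several counterparts is
split along its cM axis by ordering counterpart blocks by median position
and requiring at least 5 cM between consecutive blocks (largest-gap 1-D
clustering with k = number of counterparts); overlapping blocks leave the
group ambiguous rather than force a split. Arm labels a/b/c follow
ascending cM; cytogenetic p/q labels from other studies are treated as
aliases of a/b, not computed.

Homeolog assignment gives each outgroup chromosome the two target groups
with most pair support as its `.1`/`.2` rows; fewer than two supported
targets leave the second row missing, more than two flag the chromosome
ambiguous (the bundled salmonid matrix shows this regime in Lake
Whitefish, where several homeolog pairs collapse onto single linkage
groups — probable pseudolinkage). The `.1`/`.2` orientation is a
convention, not biology, so consensus merging anchors it to one named
reference species and resolves conflicts across comparisons by majority,
recording provenance per cell.

## Fusion/fission parsimony

Each multi-arm linkage group contributes its consecutive arm adjacencies
(k − 1 for k arms) — the stepwise-fusion model, not all-pairs — and each
distinct adjacency becomes a binary character that is absent above the
root (the pre-duplication karyotype is acrocentric). The engine
enumerates all ancestral-state assignments exactly (trees here have ≤ ~16
tips) and keeps the minimum-cost history with gain = loss = 1, preferring
among minima fewer gains (single origin), then deeper gains, then a fixed
lexicographic order. Classification: a gain retained in ≥ 2 extant species
is a conserved fusion; a loss on an internal branch (≥ 2 descendant tips)
is a conserved fission; the rest are species-specific. Every placed event
is emitted to a ledger row so tallies can be audited cell by cell.

Two characters of the bundled salmonid dataset carry curated origin
constraints (`salmonid_conventions.json`), because their published
placements are not derivable from any uniform cost rule:

* **15.1–4.1** is constrained to a single origin (one gain on the deep
  branch shared by Atlantic Salmon, Brook Charr and *Oncorhynchus*,
  followed by three fissions), although three independent fusions of the
  same two arms would cost one event less. This is the reconstruction the
  source analysis displays; the constrained search still places the gains
  and the minimal losses itself.
* **13.2–2.2** is constrained to independent origins (a gain on the
  Chinook/Coho stem plus a Pink Salmon-specific gain), although a single
  deeper gain with one clade loss ties it at two events — the uniform
  tie-break (fewer gains) would otherwise pick the single origin. The
  structurally symmetric character 9.1–11.1 resolves the *opposite* way in
  the source analysis, which is why no uniform rule can reproduce both.

Without these constraints the engine's uniform rule yields 15 conserved
fusions, 5 conserved fissions, 89 species-specific fusions and 3
species-specific fissions on the same inputs (three multi-origin
characters shift); the per-event ledger makes the difference auditable.

### Encoding of the bundled arm-homology matrix

Cells are linkage-group labels with an optional arm letter. A trailing `?`
marks weak orthology evidence but a definite placement and is kept. Lake
Whitefish rows where both homeologs of a chromosome resolve to the same
map arm (2.1/2.2, 6.1/6.2, 20.1/20.2, 22.1/22.2) are encoded as both
ancestral arms on that linkage group, ordered by ancestral label — the
pseudolinkage interpretation. The split assignment of arm 16.1 across two
whitefish groups has no single placement and is encoded as unplaced.
Under this encoding Lake Whitefish contributes 10 fusions (40 chromosomes,
50 arms), one of them the root-conserved 9.2–17.1.

## Inversion detection

Within one grid cell, monotonicity is evaluated on ordinal ranks of the
second species' cM values (robust to uneven marker spacing). Maximal
descending step-runs claim their endpoints; remaining stretches form
ascending segments; segments shorter than the noise tolerance (default 2;
a single discordant step spans 2 markers, so tolerance 3 absorbs lone
blips) merge into their larger neighbour. A descending segment is called
a putative inversion only with ≥ `min_run = 5` supporting pairs and
ascending flanks of ≥ `min_flank = 3` pairs on *both* sides — markers that
fit a linkage group poorly tend to be pushed to its distal ends during map
construction, so distal reversed runs are never called, and a fully
reversed track is an orientation flip, not an inversion. The thresholds
are package defaults chosen well below the support of showcase calls in
real data (≈ 12 pairs) but above single-marker noise; no published numeric
rule exists. Pericentric vs paracentric classification is span-overlap
against a centromere cM interval; absent centromere data the relation is
"unknown". Cross-species conservation of an inversion is reported as
per-species-pair call presence; no phylogenetic reconstruction of
inversion origin is attempted.

## Synthetic data generator

The generator emulates: a contiguous reference genome (one contig per
post-WGD arm; marker-length windows separated by arm-specific random
spacers), two or more species' maps whose markers are substrings of that
genome, known arm homology, programmed fusions/fissions/inversions on a
species tree, a non-duplicated outgroup, residual tetraploidy, and marker
dropout. Defaults: 5 ancestral chromosomes, 30 markers per arm, 80 bp
markers (typical trimmed RAD read length), 120 bp spacers, homeolog
divergence 0.05/site, tetraploid fraction 0.3, arm span 75 cM with a
10 cM gap between fused arms, no mutation/dropout/jitter (the noise-free
regime is the primary recovery surface; noise is opt-in). Residual
tetraploidy is emulated purely as windows kept identical between
homeologs: markers there are ambiguous in duplicated species (dropped by
standard filtering, like isoloci) and are what lets outgroup markers hit
both homeologs. cM positions are scaled window positions with optional
Gaussian jitter followed by re-sorting; recombination-rate heterogeneity,
coalescent genotypes and RAD library chemistry are out of scope. Passing
recovery tests on these data therefore demonstrates the pipeline's logic
(filtering, matching, clustering, parsimony, run detection) — not
robustness to alignment error, assembly collapse or map-order error in
real data.

Mutation draws one uniform per site regardless of rate, so increasing the
rate under a fixed seed gives nested mutation sets and monotonically
fewer exactly-mapping markers. All outputs are byte-identical under a
fixed config.

## Problem sizes

The test suite and the acceptance script run at desk scale: the salmonid
analysis places 96 binary characters on a 9-tip tree by exhaustive
enumeration (256 assignments per character, well under a second), and the
end-to-end synthetic recovery uses 4 species × ≤ 300 markers on a ~60 kb
genome with the builtin exact mapper, a few seconds in total. These sizes
were chosen because they already exercise every code path the larger real
datasets would; the pairing stage scales linearly in candidate pairs and
accepts external aligner output for genome-scale use.

## Known limitations

* The builtin mapper is exact-match only; diverged markers require an
  external aligner.
* Greedy matching is order-dependent by design (it reproduces the original
  tool's semantics); it is not guaranteed to maximize pair count.
* Homeolog `.1`/`.2` suffixes are conventional and only comparable across
  species after consensus anchoring.
* The parsimony model is binary per adjacency and ignores linkage between
  characters (a triple fusion is two independent characters).
* Inversion calls give cM spans, not breakpoints, and inherit any
  map-order error in the input maps.
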