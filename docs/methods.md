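# Methods

## The consensus model

AMPK substrate recognition is modeled as a degenerate position-constrained
motif over an 11-residue window, offsets −6..+4 around the candidate
phosphoacceptor. Three residue classes drive the constraints — basic
β = {R, K, H}, hydrophobic ϕ = {M, L, I, F, V}, phosphoacceptor {S, T} —
which are pairwise disjoint, so a residue belongs to at most one class.
Matching is exact and Boolean: a window either satisfies a tier's
constraint set or it does not. No positional scoring, surface-accessibility
or docking-site modeling is attempted; the presence of a consensus window
is a necessary-signature argument, not a sufficient one, and downstream
validation is assumed.

The three tiers encode the full consensus and its documented variant forms:

- **strict** — required: β at −6, ϕ at −5, β at −4, S/T at 0, ϕ at +4.
  The positions −3..−1 and +1..+3 are unconstrained.
- **relaxed** — required: S/T at 0, ϕ at +4, and ϕ at −5 *or* −4
  (inclusive or). All basic requirements become optional. This is the
  minimal superset covering both variant forms (basics absent at −6/−4;
  hydrophobic shifted from −5 to −4). An exclusive-or reading of the
  −5/−4 alternative was considered and rejected: it has no biochemical
  rationale, and the inclusive form preserves strict ⊆ relaxed because a
  strict window's −4 residue is basic and therefore not hydrophobic. We
  also considered requiring at least one basic residue somewhere in
  −6..−1 at the relaxed tier; we chose not to, because the known
  substrate contexts the tier must cover include windows with no basic
  residue at all.
- **permissive** — required: S/T at 0 only. By default the complete
  11-mer must be present (`require_full_window=True`), which keeps the
  candidate set "all full S/T windows" rather than "all S/T residues";
  the flag can be disabled. This mirrors a fully degenerate search in
  which β and ϕ are unspecified, implemented as exact matching (a
  percentile-scoring search over the same pattern is a documented
  alternative, out of scope here).

Tier predicates are nested on complete windows:
match(strict) ⇒ match(relaxed) ⇒ match(permissive). Truncation is the one
wrinkle: a required constraint at an absent terminal position fails the
match, and the relaxed tier deliberately leaves −6 optional so that
near-N-terminal variant sites (a 10-mer with the acceptor at its 6th
residue) still match, while the default permissive tier rejects them for
lack of a full window. Scan reports therefore tally cumulatively — a site
counts at its best tier and at every looser tier — so the protein-level
nesting proteins(strict) ⊆ proteins(relaxed) ⊆ proteins(permissive) holds
structurally.

Non-standard residues are handled conservatively: X, B, Z, U, O never
satisfy β, ϕ or S/T; X, B, Z satisfy an unconstrained position; U and O do
not; `*` is a sequence terminator handled during input validation. This
means ambiguity codes can never create a site.

Motifs serialize to a small JSON config (class sets, per-offset
constraints, cross-position disjunctions, full-window flag), so a user
can define a different kinase's consensus without code changes.

## Scanning and reporting

Every S/T position of every protein is tested against each requested tier,
most stringent first; a site is emitted once, labelled with its best tier
(an option emits one row per matching tier instead). Output positions are
1-based residue indices, matching the Ser641/Ser268 reporting convention.
The site table has a fixed column order
(`protein_id, gene_symbol, position, residue, tier, window, window_start`)
for diffability, and window fields are the exact protein subsequence
actually present, with `window_start` giving its coordinate (a padded
display form marks absent terminal positions with `-`).

The two historical searches — a strict search of ENSEMBL and a fully
degenerate search of SWISS-PROT — are expressed purely as tier choices
over whatever FASTA the user supplies. Entry-level target counts depend on
the database release, so the tool records the input file's checksum in
`run_config.json` and makes no claim to reproduce counts from any
particular release.

## Background expectation

For an i.i.d. residue model with background frequencies *f*, a sequence of
length L has L − 10 complete windows and the per-window match
probabilities are

- strict: p_β² · p_ϕ² · p_ST
- relaxed: p_ST · p_ϕ · (1 − (1 − p_ϕ)²)  (inclusion–exclusion over −5/−4)
- permissive: p_ST

with p_β = f_R + f_K + f_H, p_ϕ = f_M + f_L + f_I + f_F + f_V,
p_ST = f_S + f_T. Under a uniform background each is built from
p_β = 3/20, p_ϕ = 5/20, p_ST = 2/20, giving a strict per-window
probability of 1.40625 × 10⁻⁴. The closed forms are verified in the test
suite by exhaustive enumeration of all 3¹¹ windows over a reduced
three-letter alphabet, and Monte-Carlo calibration checks that observed
strict-tier counts on 2,000 simulated proteins of length 100 fall inside
the central 99% Poisson interval around the expectation. Matches at
overlapping windows are weakly positively correlated, so the Poisson
interval is an approximation; at these expected counts (~25) the effect is
negligible.

## Synthetic proteomes and planted truth

`generate_background` draws i.i.d. sequences from either a uniform
background or approximate vertebrate proteome frequencies (shipped as a
JSON data file; serine ~8.3%, leucine ~10%). Lengths are uniform over a
range; all generators consume a single seed, so fixtures are bit-stable.

`plant_sites` overwrites non-overlapping 11-mers at random admissible
positions with windows sampled *tier-exactly*: strict windows are built by
sampling each constrained position from the background restricted to its
class; relaxed and permissive windows are rejection-sampled to exclude any
stricter tier's predicate. Because an 11-mer window fully determines all
tier predicates at its center, a planted site's detected tier cannot be
altered by flanking context, which is what makes recall exactly 1.0 a
meaningful invariant rather than a statistical outcome. Planting can
clobber pre-existing background sites inside the overwritten window;
background sites elsewhere are untouched.

What the generator does *not* emulate: domain architecture, compositional
bias, disorder, homology between entries, or phosphosite clustering.
Passing tests therefore demonstrate correctness of the scanning machinery
and its calibration under the i.i.d. model, not predictive performance on
real proteomes.

Synthetic full-length stand-ins for the two validated substrates are built
by embedding the published assay peptides into a background protein of the
real protein's approximate length so that the acceptor falls at residues
641 (strict context) and 268 (relaxed context). These exercise
whole-protein coordinate reporting at realistic residue numbers; they are
not the real sequences, and are labelled synthetic wherever they appear.

## Annotation and network layer

Functional categories are a user-supplied TSV (`protein_id, category,
evidence`); associations a TSV of protein pairs. Associations are an
input, not a computation: literature-curated interaction evidence has no
reproducible algorithmic form, so the network layer is deliberately
generic. Category representation counts each distinct target once,
split fractionally across its categories by default (proportions then sum
to 1 within 1e−9); a count-in-each policy is available since the original
pie-chart convention is unknowable. Unannotated targets fall into
`uncategorized`; annotation rows for non-target proteins warn and are
ignored.

The network is an undirected simple graph: nodes are scanned targets
(optionally plus flagged first-neighbor non-targets), self-loops are
dropped with a warning, duplicate pairs in either order collapse to one
edge keeping the first association-type label. "Central node" substrates
are ranked by **degree** within the subgraph induced by a functional
category — interconnectivity in the original sense is the number of
connections a target has, so degree is the faithful operationalization;
betweenness and eigenvector centrality are intentionally out of scope.
Ties break lexicographically by protein id for determinism. Exports: SIF
(one `a <type> b` line per edge, bare lines for isolated nodes), GraphML
(node attributes carried; multi-category labels are `;`-joined strings so
the round trip is exact), and edge-list TSV.

## Numerical and policy choices

- Background frequency tables must sum to 1 within 1e−9.
- Sequence deduplication (identical sequences → one representative) is
  off by default so entry-level counts match the input as given.
- Duplicate protein ids are a hard error naming both entries; identical
  sequences under different ids are legal.
- Scan output ordering is deterministic: input record order, then
  position, then tier rank (in per-tier-rows mode).
- The acceptance script scales its simulations to desk size
  (2,000 × 100-residue proteins for calibration; a 500-protein
  vertebrate-like proteome with 25 planted sites for the pipeline
  summary), sizes at which every quantity it reports is stable across
  seeds.

## Known limitations

- Exact Boolean matching cannot express graded site quality; two strict
  sites are indistinguishable.
- The i.i.d. background understates match-count variance on real
  proteomes (composition varies across proteins and regions).
- Degree centrality depends entirely on the supplied association table;
  sparse or biased tables yield sparse or biased hubs.
- ENSEMBL/UniProt header parsing covers the common dialect forms, not
  every historical variant.
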