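# Methods

This note documents the models, conventions and numerical choices
behind subfamkit, and what the synthetic benchmarks do and do not show.

## The subfamily model

The package formalizes a subfamily as a leaf set that forms a clade with
branch support strictly greater than `min_support` (default 0.5) in
**every** input tree, where trees are treated as unrooted and a clade is
either side of an internal-edge bipartition. "Appears consistently as a
clade" is read in the strictest sense — identical leaf sets across
trees (bipartition equality), not mere topological compatibility; a
relaxation to a majority of trees can be obtained by passing the
appropriate subset of trees explicitly.

Nested and overlapping candidates are resolved greedily: candidates are
sorted by decreasing size (ties: lexicographically smallest member) and
accepted unless they overlap an accepted clade, fall below `min_size`
(default 2 — singletons are "single long branches" and stay
unassigned), or exceed `max_fraction` (default 0.5) of all leaves. The
cap is an explicit stand-in for the manual curation that would otherwise
keep near-root bipartitions from swallowing the mid-depth subfamily
structure; it is a design choice, not a claim about how any published
classification was curated. Leaves in no accepted clade are reported
`UNASSIGNED` rather than forced into a cluster.

## Alignment and homolog search

Global (Needleman–Wunsch) and local (Smith–Waterman) alignment use
affine gaps where a run of k gap positions costs
`gap_open + (k−1)·gap_extend` — the opening penalty includes the first
position. Defaults are BLOSUM62 with open 10 / extend 0.5 and the
conventional gapped Karlin–Altschul constants λ = 0.267 nats, K = 0.041
for that matrix; all four are configurable. Traceback prefers diagonal,
then the gap consuming the first sequence, then the second, making
reported alignments deterministic. Percent identity divides identical
columns by **all** alignment columns, terminal gaps included; this is a
documented convention choice — alternatives (shorter-sequence or
ungapped-column denominators) change the number and can be computed from
the returned alignment directly.

Homolog collection keeps a database entry when some query reaches
E < 10⁻³ (E = K·m·n·e^(−λS) on the local score) **and** the aligned
query span covers ≥ 90% of the query. Coverage is measured on the local
alignment span, so a high-identity fragment fails the filter.
Composition-based statistics and low-complexity filtering are not
implemented.

Seed extension threads each new sequence independently onto the fixed
seed columns: the profile score of a residue against a column is the
mean substitution score against the column's residues, gaps cost
`gap_extend` per position (linear), and residues that would open a new
column — insertions relative to the seed — are dropped and logged.
Keeping the seed's coordinate system fixed is what makes reference
numbering and region definitions stable across the pipeline; the cost is
that genuinely novel insertions are invisible downstream.

Column trimming removes a column when its gap fraction is ≥ the
threshold (default 0.8, i.e. "gaps in at least 80% of rows" — removal
*at* the boundary), and is idempotent.

Conservation statistics use all rows in the modal-frequency denominator,
so gaps count against conservation; a 90%-conserved column in a
10-row alignment with one gap is *not* reported by the strict > 0.9
scan. Information content is log₂20 minus the Shannon entropy of
residue frequencies renormalized over non-gap rows, with no small-sample
correction (subfamily sizes vary too wildly for a single correction to
be honest; the uncorrected value is the documented default).

## Distances and trees

Distances use pairwise deletion (only columns where both rows carry a
residue). The Poisson correction d = −ln(1 − p) is the default model;
pairs with p ≥ 0.99 are treated as saturated and raise an error unless
clamping (d = 5.0 substitutions/site) is requested — silent saturation
would corrupt neighbor joining invisibly. Likelihood-based corrections
(JTT and relatives) are deliberately out of scope: trees built with such
models are imported as Newick instead.

Neighbor joining is the classic Q-criterion agglomeration. Ties in Q
are broken on the lexicographically smallest pair of cluster keys (a
cluster's key is its smallest leaf label), so results are reproducible
across platforms. Negative branch-length estimates are clamped to zero
with the total deficit logged. On additive matrices the algorithm
recovers the generating topology and branch lengths exactly (checked to
1e-9 in the suite against path distances and an exhaustive least-squares
quartet oracle).

Bootstrap supports resample trimmed-alignment columns with replacement
(same length), rebuild distance + NJ per replicate, and score each
internal edge of the reference tree by the fraction of successful
replicate trees containing the same bipartition. Replicates that hit a
saturated pair are skipped and counted; more than 20% skipped is an
error. The denominator is the number of successful replicates. A
single integer seeds the whole procedure.

Newick support labels follow a mixed dialect: numeric internal labels
are supports, values in (1, 100] are bootstrap percentages and divided
by 100, non-numeric labels are clade names. This accommodates both
bootstrap-proportion and percentage conventions in the same analysis.

Midpoint rooting places the root halfway along the longest leaf-to-leaf
path, ties broken by the lexicographically smallest leaf pair;
re-rooting preserves all leaf-to-leaf path lengths.

## Sequence annotation

All positional annotation is expressed in the numbering of a reference
row (for 2HADHs, the GHRB representative Q92LZ4_RHIME, PDB 5v7n) via an
alignment-column map. The catalytic triad is Arg230 / Glu259 / His277;
auxiliary checked positions are Val72, Gly73, Asp195, Asn227, Gly229 and
Gly231. Documented natural substitutions get their own labels
(Glu259→Gln "FDH-like"; His277→Lys "SERA-IIIK-like"; His277→Trp
"X4-like, catalysis questionable" — tryptophan cannot shuttle a proton);
everything else is "non-canonical", gaps are reported as such, and each
position receives exactly one label.

Cofactor preference is called from the adenine/ribose-pocket loop
(βB-αD): a conserved aspartate at the key loop position ⇒ NAD(H), the
`[ST]R[ST]X[RK]` fingerprint anywhere in the loop ⇒ NADP(H), neither ⇒
ambiguous, both ⇒ ambiguous with a conflict flag, no loop coverage ⇒
ambiguous with a no-coverage note.

The shipped region boundaries (β1-α1, β3-α3, β4-α4, α5, β5-αA, βB-αD,
βG-α5, αB′-βA′, PDXB-dim) are **curated approximations**: the underlying
loops are named in the structural literature but their exact reference
intervals are not tabulated anywhere authoritative. They are marked
`approximate=True`, live in a single place
(`RegionDefinitions.default()`), and can be replaced wholesale from a
TOML file; the key βB-αD aspartate position is likewise a single
configurable number (default 180).

## Structure analysis

Contact mapping is heavy-atom only (element ≠ H) on deposited
coordinates: a protein residue contacts the ligand when any heavy atom
lies ≤ radius (default 5.0 Å, boundary inclusive) from any ligand heavy
atom. No crystallographic symmetry expansion or biological-assembly
generation is performed — contacts contributed by symmetry mates are
invisible, a documented limitation. Residues from a chain other than
the ligand's are flagged as other-subunit and reported under primed
region names.

Het groups are classified as cofactors ({NAD, NAI, NAJ, NAP, NDP, TAP}),
excluded solvent/additives (HOH, SO4, PO4, GOL, EDO and common ions —
crystallization-cocktail compounds are not substrates), or candidate
substrates; both code sets are configurable. A complex is *binary* with
only a cofactor, *ternary* with cofactor and substrate, and a *true
ternary* only when their redox states match (reduced + reduced or
oxidized + oxidized); codes with unknown redox state never silently
promote to true ternary. Altloc resolution (highest occupancy, ties to
the alphabetically first identifier) happens at parse time; only the
first model of multi-model files is read.

When projecting contacts onto sequence regions, structure residue
numbers are taken as 1-based positions in the ungapped sequence of the
alignment row mapped to each chain — renumbered or insertion-coded
structures must be harmonized by the caller first.

## Kinetics

Efficiency is kcat/KM in M⁻¹s⁻¹ with KM in μM (K_1/2 accepted with a
flag for non-Michaelis–Menten enzymes). When all three of kcat, KM and
efficiency are reported, they must agree within 5% or the record is
flagged (the reported efficiency is kept). The best substrate per
enzyme maximizes efficiency, ties broken by smaller KM then
alphabetically; enzymes with no numeric efficiency at all (e.g. only
relative activities) are excluded from best-substrate statistics and
listed. "Accepted compound" counts any substrate with measured
activity; "pair with determined efficiency" requires the number itself
— the two counts deliberately differ. Duplicate
(enzyme, substrate, cofactor, source) rows are deduplicated keeping the
highest efficiency. Family medians are computed over best-flagged
records (median of an even set = mean of the central pair); the
all-records alternative is available by not flagging.

## The synthetic generator and what the benchmarks mean

`simulate_family` plants a star of subfamily stems (default stem scale
0.8 substitutions/site) whose leaves hang from random binary subtrees
with exponential branch lengths (default mean 0.05), over sequences of
300 columns, 6 subfamilies × 8 leaves — parameters chosen to emulate a
family of clearly separated, internally coherent subfamilies.
Substitutions follow a 20-state uniform-exchange Poisson process
(each event replaces the residue with one of the other 19 uniformly),
chosen over empirical matrices because it has a closed form: the
probability that a site differs across a path of length t is
p(t) = (19/20)(1 − e^(−20t/19)), which the suite verifies by Monte
Carlo. Invariant columns (catalytic positions) never mutate; motif
instances written at a subfamily root are held fixed within that
subfamily, emulating a conserved functional fingerprint. No indels are
simulated by default — the truth alignment is exact — and an optional
gap-injection mode exists solely to exercise trimming.

The reference recovery benchmark (distance → NJ → 3 × bootstrap(100) →
consensus, adjusted Rand index against the planted partition) is run at
the fixed planted condition above and achieves ARI = 1.0 there for any
choice of inference seeds. Two caveats define what this does and does
not show. First, a star radiation can *realize* chance affinities
between stems — shared-looking substitution patterns fixed in the
sequences themselves — which every bootstrap replicate then supports;
for some generator seeds the consensus therefore returns merged
super-clades within the size cap. This is a property of the data, not
an inference bug, and it is exactly the situation the max_fraction cap
and, in real analyses, manual curation address. Second, the generator
omits indels, rate heterogeneity, compositional bias and alignment
error, so perfect recovery here bounds only the pipeline's correctness,
not its robustness on real families.

Synthetic kinetics draw efficiencies log-normally around planted
per-subfamily medians (a point-mass law reproduces its median exactly)
and synthetic complexes place residues at controlled distances
straddling the contact radius, with hydrogens planted closer than every
heavy atom so that a mapper that failed to ignore them would be caught.

## Determinism and reproducibility

Every stochastic component (simulation, bootstrap, tree-set seeds) is
driven by explicit integer seeds. Re-running the pipeline with the same
config and seed produces byte-identical CSV/JSON outputs; to keep that
guarantee the provenance block records the config snapshot, seed and
package version but no wall-clock timestamps. Problem sizes in the test
suite and the acceptance script (small planted families, 100-replicate
oracle checks, 12-residue alignment oracles) were chosen so the whole
verification chain stays a matter of seconds to minutes while still
exercising every boundary rule at its exact threshold.
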