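# Methods

## What the package computes

The package decides, per protein, which signatures of siroheme sulfite
reductases it carries and assigns a family/group/subgroup/architecture
label, then (optionally) builds a distance-based tree over a set of
proteins to check clade structure. All decisions are rule-based and
deterministic; the only randomness anywhere is the synthetic-data
generator and bootstrap resampling, both driven by explicit seeds.

## Anchor profile

"Signature present" is defined relative to a packaged anchor profile
(`siroclass/data/anchor_profile.yaml`, version 1): a 296-residue Dsr-like
reference carrying four siroheme-site cysteines (positions 120, 125, 136,
141), four peripheral-cluster cysteines (190, 195, 200, 203), four
sulfite-binding Arg/Lys positions (41, 71, 101, 160, numbered SB1–SB4 from
the N-terminus), and one additional ferredoxin-type motif (230–240); plus a
140-residue cysteine-free FrhB-core reference. Both references are
synthetic (random filler around the planted signatures, cysteine-free
outside them) — they encode the *layout* of the real signatures, not real
sequence. This makes the classifier exactly testable: the generator and the
detector share one authoritative coordinate system. Real-sequence use is
supported by swapping in a curated profile with a real DsrB/FrhB reference
and its coordinates; nothing else changes. The non-conserved cysteine that
couples the cluster to siroheme in some DsrB proteins is deliberately not
an anchor: only conserved positions count toward presence.

## Anchor mapping and detection rules

Anchors are mapped onto a query by a three-state (Gotoh) affine-gap
alignment of the Dsr-like reference against the query with free terminal
gaps, so that a Dsr-like domain embedded in a longer chimera is not
penalized for its flanks. A site is occupied iff the query residue aligned
to its reference position is in the allowed set ({C} for cluster sites,
{R,K} for SB sites); a gapped column is unoccupied — absence of evidence at
the anchor. Presence thresholds default to all four cysteines for the
siroheme and peripheral sites (configurable down to 3 for degraded
sequences); the strict default reflects that the siroheme motif is the
family's universal, defining feature.

When the siroheme site is absent, the remaining Dsr-side features
(peripheral, additional, SB occupancy) are reported absent rather than read
off the alignment: without the universal feature the Dsr-side mapping is
not credible, and reading Arg/Lys "occupancy" off a forced alignment of an
unrelated protein would produce noise, not evidence. This choice also makes
the generator's ground truth exact for non-Dsr architectures.

The additional (`**`) cluster is searched as a ferredoxin-type Cys-spacing
motif — default C-x(2)-C-x(2)-C-x(3)-C, the canonical bacterial-ferredoxin
spacing, with configurable gap ranges — in the window strictly between the
last peripheral anchor (as mapped onto the query) and the C-terminus.
Motif matches are left-greedy and non-overlapping.

The FrhB core is detected by fitting the core reference into the query
(free-end-gap alignment) and normalizing the score by the reference
self-score; present iff the normalized score reaches the threshold
(default 0.5). On the packaged profile, true cores score ~1.0 and
composition-matched shuffles score ≤ ~0.1, so the threshold has a wide
margin. Ferredoxin extensions are counted strictly N-terminal and strictly
C-terminal of the detected core interval. For a chimera, architecture
classification uses only motifs between the core end and the first siroheme
anchor (the inter-domain linker window), because the Dsr-side additional
cluster also lies C-terminal of the core and must not masquerade as an
Fsr-N extension; the raw C-side count is still reported.

## Classification

The group rules (see README) are total over the 2×2×2×16 feature space;
every cell maps to exactly one label, verified by enumeration. Group II is
a first-class output even though it is a predicted intermediate with no
known representative — being able to report it is the point of the rule
engine. A missing SB4 yields no subgroup (not a fifth subgroup) because
subgroups are defined only by SB1–SB3 and SB4 is conserved across all
sulfite reductases. The FpoF/FdhB classes accept ≥2 extensions rather than
exactly 2, since spacing-based motif detection may merge or split motifs on
real sequences; the observed counts are recorded. The chimera rule demands
the FrhB-like region strictly before the Dsr-like region; the reverse order
is unclassified with a flag, as no such architecture is defined. A protein
with both N- and C-terminal extensions is flagged, not guessed.

## Alignment machinery

`global_align` is a standard three-state affine DP; a gap run of length L
costs `gap_open + (L-1)*gap_extend` (so BLOSUM62's conventional −11/−1
pairing applies unchanged). The packaged default substitution table is
BLOSUM62 extended to `X`; an identity table is available for tests and
oracles. Traceback tie-break is fixed (substitution, then gap-in-query,
then gap-in-ref), so outputs are deterministic; the optimum score itself is
cross-checked in the tests against both exhaustive enumeration (short
sequences) and an independent aligner implementation. The multiple
alignment is center-star (center = record with maximal summed pairwise
score, ties to the smallest id; merge by once-a-gap-always-a-gap), chosen
for determinism and simplicity; it is adequate for the closely related
families this package generates and is explicitly not equivalent to a
progressive aligner. Column trimming keeps exactly the columns whose gap
fraction is ≤ `max_gap_fraction` (default 0.5) and returns the new→old
column map; it is idempotent and may return zero columns.

## Distances, NJ, bootstrap, monophyly

Distances are computed over pairwise-complete (both ungapped) columns:
p-distance, or Poisson correction −ln(1−p) capped at −ln(ε) (ε = 0.05)
with the saturated pair flagged, since the logarithm degenerates near
p = 1. Pairwise deletion keeps the stage robust when trimming is disabled.
A pair with no comparable columns is an error naming the pair.

Neighbor joining is the classical Q-criterion agglomeration with two
determinism guarantees: ties in Q are broken by the lexicographically
smallest (leaf-name) pair, so taxon order cannot change the tree, and
negative branch lengths are clamped to zero with a count recorded on the
tree. On additive matrices NJ is exact; the tests verify path-metric
recovery below 1e-9 on random additive trees and topology agreement with an
independent NJ implementation.

Bootstrap support resamples alignment columns with replacement, rebuilds
the NJ tree per replicate, and maps the fraction of replicates containing
each bipartition onto the internal edges of the full-data tree (supports on
one tree, not a consensus). Replicates with undefined distances are
dropped, counted, and warned about. Monophyly of a taxon set means the set
is one side of some edge bipartition of the unrooted tree; an
outgroup-aware variant roots first and requires a proper clade.

## Synthetic data: what it emulates, and what it does not

The generator emulates families of homologs that differ by which signatures
they carry: templates for all 12 Dsr-LP labels, the Fsr chimera, the three
Fsr-N architectures, and a featureless control. Features are ablated by
substitution (Cys→Ala, Arg/Lys→Ala), never deletion, mirroring how the
natural subgroups differ at single residues while keeping coordinates
fixed. The chimera template is dimensioned like the archetypal enzyme: a
311-residue N-half (two ferredoxin blocks + core), a 13-residue linker,
and a 296-residue Dsr-like half starting at position 325, 620 residues in
total. Noise is iid per-site substitution (uniform over the 19 alternative
residues) at rate `mu` outside anchors and `anchor_mu` at anchors (default
0), plus Poisson-count indels of length 1–3 placed uniformly outside anchor
±2 neighborhoods, with anchor coordinates re-indexed. Default study
conditions used by the analysis scripts and the acceptance checks: 10
replicates per label at `mu = 0` for the recovery benchmark, and two
families of 8 at `mu = 0.03` for the clade checks.

What the generator does *not* emulate: tree-structured evolution (within a
family, sequences are iid perturbations of one template, so within-family
structure is star-like), realistic substitution processes (no BLOSUM-like
exchange preferences, no rate variation), domain shuffling, or real
divergence levels between families (between-family signal is exactly the
planted signature differences plus noise). Passing tests therefore show
that the detectors and rules are correct and robust to the modeled noise —
not that the thresholds are tuned for remote homology detection on real
proteomes, where a curated profile and possibly relaxed anchor thresholds
would be needed.

One bookkeeping consequence: the ground-truth vector for the chimera
records one raw C-terminal ferredoxin motif (the Dsr-side additional
cluster, which genuinely lies C-terminal of the core); the linker-window
count used for architecture classification is zero.

## Numerical and procedural choices

* Residue coordinates are 1-based inclusive everywhere; FASTA ids are the
  first header token, organisms a trailing bracketed suffix, and organism
  strings are reported verbatim (no normalization).
* All pipeline randomness flows from the single config seed; outputs are a
  pure function of (input bytes, config, seed), and the run log records the
  config but not its own location, so repeat runs are byte-identical.
* Traceback and Q-matrix ties use tolerances of 1e-9 and 1e-12 respectively;
  scores are float64 sums of table entries, so these are generous.
* Degenerate inputs: single-sequence inputs skip alignment, fewer than
  three sequences skip the tree (noted in the run log); an all-gapped
  anchor mapping is legal and yields an unoccupied site; a trimmed
  alignment may have zero columns, in which case the tree stage is skipped.
* Problem sizes in the shipped analyses (170-sequence benchmark, 16-taxon
  trees, 100 bootstrap replicates, 20-seed sweeps) were chosen so each
  stage is exercised well inside interactive runtimes while keeping the
  statistical checks meaningful.

## Known limitations

The center-star MSA can be arbitrarily worse than an optimal alignment for
distant sequences; the profile ships synthetic references, so real-data use
requires profile curation; context sublabels (FGltS(I)-α, aFsr-β,
FGltS(II)-α) require a user-supplied context table — without one, FpoF-family
members are not split into FpoF vs FqoF vs aFsr-β; and the phylogeny stage
deliberately reports bipartitions and supports without adjudicating between
conflicting sister-group arrangements.
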