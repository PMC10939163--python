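# Methods

This note records the model, the numerical choices, and the limits of
what the synthetic tests demonstrate.

## Structure model and torsions

Entries are Martin-numbered two-chain (H/L) Fv structures in PDB format,
named `<pdb>_<index>[P|H|N]`.  Martin numbers are treated as opaque
ordered labels — no renumbering is attempted, and insertion codes order
as blank < A < B within a number.  On reading, alternate locations keep
the highest-occupancy atom (ties keep the first); resolution comes from
`REMARK 2` and is *undefined* when absent, which fails the resolution
filter — the conservative reading for unannotated entries.

Backbone torsions follow the standard conventions, degrees in
(−180, 180]: &phi;(i) = C(i−1)–N(i)–CA(i)–C(i), &psi;(i) =
N(i)–CA(i)–C(i)–N(i+1), &omega;(i) = CA(i−1)–C(i−1)–N(i)–CA(i).  A
torsion is undefined at chain termini, when a contributing atom is
missing, or across a chain break, defined as a peptide C–N distance
> 2.5 Å (the bond is ~1.33 Å; anything approaching 2.5 Å is not a bond).
A peptide bond is *cis* when |&omega;| < 30°, a conventional cutoff
separating cis from trans and distorted-trans; it is configurable.

## Quality filter

Order matters and is fixed: resolution (> 2.8 Å or unknown; exactly
2.8 Å is retained) → missing V_H/V_L → missing CDR residues → CDR
C&alpha; B-factor (0, i.e. absent, or > 80 Å²) → cis non-proline in a CDR
of an *unbound* entry → [with pairing] both-forms retention → framework
RMSD → both-forms recheck.  "Missing CDR residue" is operationalized two
ways, both active: a Martin position observed in the CDR range of any
identical-sequence sibling but absent here, and a chain break between
consecutive CDR residues (the structural signature of an unmodelled
residue, and the only detectable signature when an antibody has a single
entry).  Only C&alpha; B-factors of CDR residues are inspected; other
atoms are ignored.

The framework-RMSD filter works at pair level: for each unbound/bound
pair the H- and L-chain frameworks are fitted separately and the larger
of the two RMSDs is compared with 1.0 Å (the conservative combination).
Entries left in no surviving pair are removed, then both-forms is
rechecked.  Each step records (in, rejections with reason codes, out);
`in − rejected = out` is asserted, and re-running the filter on its own
output rejects nothing.

## Superposition and the RMSD protocol

Rigid fitting is least-squares superposition via SVD of the covariance
matrix with the determinant correction that excludes reflections.
Near-collinear point sets (second singular value ≈ 0) raise an error
rather than returning an arbitrary rotation.  The independent check is a
hierarchical Euler-angle grid search over SO(3) (12° coarse grid, three
4-fold refinements), which agrees with the closed-form optimum to well
under 10⁻³ Å.

Local RMSD fits the CDR C&alpha; atoms on themselves; global RMSD fits
the chain-specific framework restricted to positions present in both
entries (≥ 3 required) and evaluates the CDR without refitting, so
local ≤ global holds by optimality on the measured atom set.  The flap
statistic is |global − local| per pair; medians over an antibody's
unbound × bound pairs feed the summary tables.  Range tables use
right-closed bins (a median of exactly 0.5 Å falls in the ≤ 0.5 bin).
Quartiles use linear interpolation between order statistics; the upper
fence is Q3 + 1.5·IQR.  The Mann–Whitney U test is two-sided, using the
exact null distribution when both samples have ≤ 20 observations and no
ties, and the tie-corrected normal approximation otherwise.  Summary
percentages pool antibody × CDR observations over the five non-H3 CDRs
by default; per-CDR-averaged percentages are available via
`pooling="mean"`.

## Torsion clustering

LRC group names render as `<CDR>-<length>-<allT|cisNN[,NN…]>`; multiple
cis positions sort ascending.  The embedding interleaves
(sin&phi;, cos&phi;, sin&psi;, cos&psi;) per residue; the distance is the
plain squared Euclidean distance of these vectors, equal to
&Sigma; 2−2cos(&Delta;) over the 2L angles, bounded by 8L, with a single
antipodal angle contributing exactly 4.

Affinity propagation is run with damping 0.9, at most 1000 iterations,
and convergence declared after 50 iterations of a stable exemplar set;
non-convergence raises with diagnostics rather than returning a partial
answer.  No jitter is added to the similarity matrix and argmax ties
resolve to the lowest index, so clustering is a deterministic function
of the input order.  Two degenerate inputs bypass message passing:
groups with < 2 members form one singleton cluster, and exactly-identical
point sets (where all messages stay zero and no exemplar can emerge)
form a single cluster with exemplar 0.  The preference (diagonal) is the
mean similarity over unordered non-self pairs, which on real data yields
moderate cluster counts; the number of clusters is an *output* here, not
a parameter.

Cartesian merging fits exemplar pairs on loop C&alpha; atoms and
requires, strictly, RMSD < 1.0 Å, max per-position C&alpha; displacement
< 1.5 Å and max C&beta; displacement < 1.9 Å.  Positions lacking a
C&beta; in either loop (glycine, unmodelled side chains) are skipped
rather than synthesizing a virtual C&beta; — with an all-glycine loop the
C&beta; test degenerates to vacuous, which is documented behavior.
Canonical clusters are connected components of the pass relation, so a
chain a–b–c merges even when a–c fails directly, and merging can never
split an AP cluster.

## Classification

The nearest AP cluster minimizes exemplar distance; ties (exactly equal
distances) prefer a cluster in the unbound loop's canonical cluster,
then the lowest id — the conservative, deterministic call.  The radius
test uses the located nearest cluster's own radius; singleton clusters
have radius 0, so membership there requires an exact torsional match and
otherwise falls through to the Cartesian-criteria path.  A bound loop
whose LRC group has no unbound counterpart (different length or cis
layout from every unbound loop) is non-canonical by definition: the
unbound space contains nothing it could match.  The H3-vs-rest test is a
2 × 2 table (H3 / pooled non-H3 × Sum(NR) / non-canonical); &chi;²
tests attach a warning when an expected cell drops below 1 and report an
undefined result on degenerate (zero-marginal) tables.

## Synthetic data: what it emulates, and what it does not

Chains are built residue-by-residue from ideal peptide geometry (N–CA
1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, standard angles) by natural-extension
placement, so measuring dihedrals on a built chain reproduces the inputs
to ~10⁻¹³ degrees.  C&beta; atoms are placed from the N–C–CA improper;
glycines omit them.  The framework is one fixed idealized scaffold
(alternating extended and helical stretches) shared by all entries, so
framework fitting is exact and CDR effects are isolated.  Each CDR is
re-placed by continuation from its N-side anchor using planted (&phi;,
&psi;, &omega;) values; the following framework residue receives only its
continued nitrogen (which defines the loop's final &psi;) while its
C&alpha;/C stay on the scaffold.  Loop closure is therefore **not**
enforced — the chain is open at that point.  No downstream stage requires
closed loops, and the torsion code treats the junction correctly, but
this is the generator's largest departure from real structures.

It has a quantitative consequence: without a closure constraint,
independent per-torsion noise accumulates along the loop into Cartesian
deviation (a lever-arm random walk that real, closed loops cannot
perform).  The cohort default within-cluster spread is therefore 2°
(wrapped normal; von Mises would be an acceptable alternative), chosen so
that planted clusters remain Cartesian-coherent relative to the
1.0/1.5/1.9 Å merge thresholds for every CDR length up to L1's 11
residues — a 20-seed sweep of worst-case exemplar-pair displacements
showed ~1.24 Å max-C&alpha; at 2° against the 1.5 Å threshold.  Real
canonical clusters tolerate larger torsional spread precisely because
closure constrains them; conclusions about recoverable spread do not
transfer from this generator to real data.

Planted structure per CDR: cluster c1; its "sister" c2, equal to c1 with
a compensating (&psi;_k +60°, &phi;_{k+1} −60°) rotation of the peptide
unit after residue 1 — torsionally far (D = 2.0) but Cartesian-close,
so affinity propagation separates the two while the Cartesian criteria
merge them into one canonical cluster; c3, with every residue in a
different Ramachandran region (a distinct canonical cluster); and a
positive-&phi; "novel" conformation matching nothing.  Bound entries
realize the planted change mode: exact torsion copies for *identical*
(guaranteeing a_B = a_u), donor-member copies from the sister or distinct
cluster for *AP shift* / *canonical shift* (guaranteeing within-radius
membership of the target), fresh novel samples for *non-canonical*, and
rigid rotation about the anchor–anchor axis for *flapping* (preserving
intra-loop geometry exactly, hence local RMSD ≡ 0).  This construction is
what "strong separation" means here: recovery is then a test of the
pipeline, not of sampling luck.  Quality defects are injected one per
antibody as an extra entry (bad resolution, missing chain, deleted CDR
residue, B-factor 85, cis non-proline with the sequence left unchanged,
framework deformation at 1.2 Å per-atom noise) so each is rejected at
exactly one filter step while its clean siblings survive.

Entries carry flat B-factors (20 Å²), occupancy 1.00, resolution 2.0 Å
unless overridden, and deterministic per-antibody sequences (the antibody
index is encoded in framework positions; CDRs cycle Ala/Ser/Gly; cis
sites become proline unless a cis *non*-proline is being planted).  There
are no side chains beyond C&beta;, no antigen coordinates, and no claim
of physical realism — passing tests demonstrate the pipeline's
correctness on data with known ground truth, not its behavior on
crystallographic noise.

## Problem sizes and determinism

Test and verification runs use cohorts of 9–84 antibodies (the
classification recovery check uses 60, matching its planted 60/20/10/10
mix over 360 antibody × CDR pairs), 50 clustering replicates of 20–100
loops, and 200 flapping trials; each check runs in seconds to tens of
seconds.  A pipeline run is a pure function of (input files, config):
iteration orders are sorted, clustering is jitter-free, and rerunning the
same configuration reproduces every output table byte for byte.  The
generator is bit-reproducible for a fixed seed.

## Known limitations

- Open-chain loop grafting (above) — the dominant simplification.
- The missing-residue filter recognizes absences only via group siblings
  or chain breaks; a terminally truncated CDR with an intact bond to its
  neighbor and no complete sibling would pass.
- The unbound conformational space is LRC-group-local: bound loops are
  only ever compared with unbound loops of identical length and cis
  layout.
- Exact-match sequence grouping stands in for 100%-identity clustering;
  this is equivalence, not approximation, but it means sequence-extraction
  differences (e.g. modified residues read as X) propagate into grouping.
- NMR multi-model files are read as their first model; no model-selection
  logic is provided.
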