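# Methods

This note documents the models and procedures implemented in
`haloscope`, the parameters that matter, the design choices made where
the design was genuinely open, and what the synthetic benchmarks do and
do not demonstrate.

## Sequence mining

**Motif notation.** Signature motifs are compiled from a compact
notation: `x` is exactly one arbitrary residue, a `.` immediately
following a wildcard widens it by one position (so `x.` spans two
residues), and consecutive wildcards merge. `GxGxxG` and `WxWxIP`
therefore match their classical 6-residue forms and `Fx.Px.SxG` spans 9
residues (`F??P??S?G`). Published sources write the halogenase motif in
more than one way; the compiler accepts any user-supplied pattern, so a
different reading is a one-flag change rather than a code change.

**Candidate screen.** A sequence passes when it contains at least one
hit of each of the three motifs *and* one hit per motif can be chosen
with strictly ascending start positions (flavin-binding motif first).
FDHs carry the Rossmann-type flavin motif N-terminally, and the order
requirement suppresses spurious combinatorial passes in large scans.
Greedy chaining (earliest feasible hit per motif) is exact for an
ordered-existence test. Indexing is 0-based half-open internally;
reports print 1-based starts.

**Distances and trees.** Pairwise distances are
1 − (identical aligned positions / aligned columns) over a global
alignment (Biopython `PairwiseAligner`, linear gap cost, BLOSUM62 by
default); gap columns count in the denominator, making the measure
monotone in divergence. Neighbor joining is the standard Saitou–Nei
agglomeration with Q-matrix ties broken by the lowest index pair and
negative inferred branch lengths clamped to zero; two taxa yield a
single evenly split edge. NJ is exact on additive matrices, which the
test suite exploits (random binary trees → path-length matrices →
recovery with Robinson–Foulds distance 0 and branch errors at machine
precision). Bootstrap resamples alignment columns with replacement;
replicate *r* uses seed `seed + r`, so supports are reproducible and
stream-safe; support is the percentage of replicates containing each
internal split of the full-data tree.

## Pocket mapping

**Occupancy.** A grid point is *free* iff its distance to the nearest
atom center exceeds `atom_radius + probe_radius` (defaults 1.7 + 1.4 Å,
i.e. a water-sized probe against carbon-like atoms). Clearance at a
point is distance-to-nearest-atom-center − `atom_radius`. The grid is
laid over the structure's bounding box with 1.0 Å default spacing and a
4 Å pad (wide enough that the first exterior band is collision-free).

**Enclosure (LIGSITE-style).** For each free point, 7 scan axes (±x,
±y, ±z and the four cube diagonals) are probed out to a 12 Å range
cutoff; an axis counts when protein blocks *both* directions. Points
blocked on ≥ 5 of 7 axes are enclosed; 6-connected components of
enclosed points with volume ≥ 50 Å³ are pockets, ranked by volume
(volume = cell count × spacing³). All parameters are exposed in
`GridParams`. The detector is deterministic for fixed inputs.

**Tunnel search.** The HOX tunnel is found by Dijkstra over the free
grid (26-neighbour connectivity) with edge cost
`step_length × (1 + 1/clearance)` — short paths are preferred but
narrow ones are penalised. The target is the *pocket core*: the
reachable pocket cell of maximal clearance (quarter-cell tolerance).
Targeting the pocket member nearest the start would be degenerate,
because with axis-scan enclosure an access channel is itself enclosed
and belongs to the pocket component — the path would end at the channel
mouth it started in. Routing to the core makes the reported length the
start→cavity-interior distance, which is the quantity of interest (the
~10 Å HOX path). An unreachable pocket returns an explicit "no tunnel"
value (`None`), distinct from malformed input, which raises.

**Pocket triage.** A pocket qualifies as the substrate site iff (a) the
catalytic-lysine side-chain nitrogen lies within 8 Å of some pocket
grid point, (b) the tunnel from the flavin start succeeds, and (c) when
per-pocket docking energies are supplied, the best energy is negative.
Criteria are evaluated on grid points, never centroids (deep pockets
have misleading centroids). Among qualifiers the largest pocket wins
and the report records which criteria each pocket failed. The Lys
reference is the terminal side-chain nitrogen; the acidic-residue
reference is the carboxylate-oxygen midpoint; both come from
configurable selectors (e.g. `A/79/NZ`, `A/307/centroid`) because
published residue numbering can be ambiguous at exactly the positions
that matter.

## Pose geometry

Distances are measured from the candidate ring **carbon** (not its
hydrogen) to the K79 and D307 references: docking outputs routinely
omit nonpolar hydrogens, so the carbon convention is the stable one.
The predicted halogenation site of a pose is the eligible carbon
(aromatic, ≥ 1 attached H) nearest the K79 reference, with ties broken
by symmetry class then index. Energies are held in kJ/mol; kcal/mol
inputs are converted with the exact factor 4.184 (the optimal-window
endpoints −20.92 and −35.56 kJ/mol are the images of −5.0 and −8.5
kcal/mol). Near-degenerate poses — within `delta_e_tol` (default
2.5 kJ/mol, chosen to cover the 2.10 kJ/mol gap of the known
two-regioisomer case with margin) of the best energy — are retained and
collapsed per symmetry class, keeping the best energy per class.

Symmetry classes come from canonical atom ranking with ties preserved
(RDKit), validated in the tests against a VF2 graph-automorphism oracle
on a small-molecule panel; atoms in one class are exchangeable by a
graph automorphism, so halogenation at any member yields the same
product.

## Substrate classification

Gates, both evaluated on the retained best-energy pose set:

* **G1, energy window** — class `optimal` for
  e_tight ≤ E ≤ e_weak (boundaries inclusive), `borderline_tight` for
  the band `tight_tolerance` (default 1.0 kJ/mol) past the tight bound.
  Borderline-tight is accepted by default: a hard cutoff at the printed
  bound would reject a confirmed strong substrate sitting 0.42 kJ/mol
  past it, so the band keeps both the printed rule and the printed
  outcome representable. Sign convention: energies are negative;
  "tighter" means more negative.
* **G2, geometry** — d(C···D307) ≤ 11.5 Å for the retained site.

The K79 distance is reported and compared across poses (the closer
orientation is the one consumed by a second halogenation) but is not an
accept/reject gate; a warning is emitted above 11.5 Å. No angular
orientation criterion is applied — no quantitative definition exists to
implement, and distances alone reproduce the intended calls.
Di-halogenation is flagged qualitatively (`dihalogenation_plausible`)
when a substrate's site class has ≥ 2 members or ≥ 2 outcomes are
retained; no quantitative rule is defensible from first principles
here. Every compound yields a structured call (including `no_site` /
`no_pose` reasons); screens reject duplicate compound ids and order
verdicts deterministically.

## Synthetic benchmarks

Generators are pure functions of (spec, seed); identical seeds give
byte-identical serialized outputs, and every generator returns a truth
record sufficient to score pipeline output without re-running it.

* **Sequences** — i.i.d. uniform residues with motif instances
  (wildcards randomized) overwritten at recorded positions; `"random"`
  planting places the three signature motifs at random non-overlapping
  ascending positions. Chance motif hits follow the closed form
  n_windows × (1/20)^(number of literals), which the tests check to 3σ.
* **Receptors** — blocks of carbon pseudo-atoms on a 2.0 Å lattice with
  ±0.2 Å jitter. Cavities are carved by removing lattice atoms within
  the cavity box inflated by the occupancy margin, then adding explicit
  wall-shell atoms exactly `atom_radius + probe_radius` outside each
  cavity face (and a cylindrical wall around the channel), so the free
  region — and hence the detected volume — tracks the analytic cavity
  volume to within grid discretisation (measured ≤ ~7% error, tested
  at 15%). The channel runs from the main cavity face to the block
  surface; truth records the analytic volume, the channel start, and
  the expected start→core tunnel length. Catalytic LYS/ASP reference
  atoms are placed 4 Å off the cavity wall, close enough to line the
  pocket without eroding it.
* **Poses** — ligand coordinates are placed so the planted site carbon
  sits exactly at the requested K79/D307 distances (feasibility checked
  against the triangle inequality) and every other heavy atom is
  strictly farther from the K79 reference; assignment must therefore
  recover the plant. Energies are *assigned*, not computed. A
  deliberately non-physical toy scorer (−2 kJ/mol per receptor atom
  within 4 Å) ships for tutorials only.
* **Screens** — `gen_screen(n_total, n_substrate, seed)` builds a
  receptor plus per-compound pose sets over a panel of biaryl-type
  chemotypes. Positives get in-window energies (−35 … −21.5 kJ/mol)
  and in-range geometry; negatives draw a failure mode from
  {too_weak, too_tight, d307 out of range, no eligible site},
  round-robin before randomisation so every gate is exercised even in
  small fixtures. Decoy poses sit ≥ 3.5 kJ/mol above the best pose,
  outside the degeneracy tolerance.

**What passing these benchmarks shows — and does not.** The benchmarks
validate the *decision machinery*: motif scanning is exact, NJ is exact
on additive inputs, the cavity detector recovers carved volumes, site
assignment is provably nearest-carbon, and the classifier reproduces
planted labels through a full file round-trip. They do not validate
docking accuracy, pose realism, energy models, conformational
flexibility, or water — pose coordinates are geometric stand-ins and
energies are assigned. On real data the pipeline's calls are only as
good as the upstream structure prediction and docking.

## Numerical choices and degenerate inputs

* Grid spacing 1.0 Å, probe 1.4 Å, atom radius 1.7 Å, enclosure 5/7
  axes, 12 Å range, min volume 50 Å³ — all configurable.
* NJ Q-matrix ties → lowest (i, j) pair; negative branches → 0.
* Energy-window boundaries inclusive; class sweep from tight to weak is
  monotone by construction.
* Empty structures, non-symmetric matrices, ragged alignments,
  infeasible pose geometry, and unknown config keys are rejected with
  specific errors; "no tunnel", "no plausible site", "no_site" and
  "no_pose" are explicit values, not exceptions.
* Pipeline stages are hashed (inputs + config) and skipped when up to
  date; per-compound parse failures are quarantined so one corrupt file
  cannot sink a screen. Problem sizes in the test and acceptance runs
  (200–1000 sequences, 5–10-taxon trees, ~12–23 Å half-blocks, 53
  compounds, 10 seeds) were chosen to exercise every code path at
  interactive runtimes.

## Known limitations

* The cavity detector is occupancy-only; no chemistry, protonation, or
  flexibility. Pocket counts on real predicted structures are method-
  and model-dependent, so the module is validated on synthetic geometry
  with analytic truth rather than on any particular enzyme model.
* Halide identity (Br vs Cl vs I) and conversion/kinetics are outside
  the model: the classifier predicts *whether* and *where*, not *how
  much*.
* The symmetry classes refine automorphism orbits via canonical
  ranking; the oracle comparison covers the small-molecule panel used
  here, not all graphs.
* Bootstrap supports are for the NJ/identity-distance pipeline itself;
  they are not a substitute for model-based phylogenetics.
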