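# Methods

`alloscope` analyzes molecular-dynamics trajectories of multi-domain
protein complexes for signatures of regulatory-domain detachment and its
effect on allosteric communication. The motivating system is the PI3Kα
heterodimer (catalytic subunit p110α, regulatory subunit p85α), where the
oncogenic charge-reversal mutation E545K in the helical domain weakens the
inhibitory nSH2–helical interface: the nSH2 domain of p85α rotates about
its 339–347 helix, separates from the helical domain by about 5 Å in
center-of-mass distance, and loses its interfacial hydrogen-bond network
in a stepwise fashion. All of the package's observables are generic;
nothing is specific to PI3Kα except the packaged domain map and the
synthetic preset described below.

## Data model and conventions

* Internal length unit is Å (the MDAnalysis native unit), times are ns,
  angles degrees. The distance-fluctuation rigidity criterion is stated in
  Å², which fixes Å as the natural internal unit.
* Residue numbers are taken verbatim from the input file (crystal/author
  numbering) and are always chain-qualified: the catalytic and regulatory
  chains contain overlapping residue numbers.
* No periodic-boundary unwrapping is performed. Inputs must be pre-imaged
  so the analyzed complex is whole in every frame; the tool does not
  attempt to repair split molecules.
* GRO files carry no chain identifiers; atoms loaded from GRO are assigned
  chain `A`. Multi-chain systems should use a PDB topology (the synthetic
  writer emits both).

## Geometric observables

Superposition is a per-frame least-squares rigid fit (rotation +
translation, via `scipy`'s Kabsch-style `align_vectors`) over a fit
selection, by default every Cα of the complex with the first frame as
reference — a full-complex fit makes relative domain motion, not global
drift, the signal. The fit is validated in tests against an independent
quaternion (QCP) superposition.

RMSD is computed per frame over a selection against the reference; RMSF
per residue at Cα as the root time-mean squared displacement from the
time-mean position. Per-region RMSF values (e.g. an activation-loop
average) are reported as the mean ± SD across the region's residues.

Center-of-mass distances are mass-weighted by default (a flag disables
weighting); no periodic-image correction is applied. The hinge angle φ is
the angle at the geometric center of an apex selection subtended by two
arm selections — for the nSH2 detachment: apex = helix 339–347, arms =
residue 545 and helix 400–410. Mass weighting is deliberately *not* used
for φ: the quantity is defined on geometric centers.

Solvent-accessible surface area is Shrake–Rupley quadrature with a
deterministic golden-spiral point set (960 points/atom by default), Bondi
radii and a 1.4 Å probe, evaluated for a selection in the context of the
full complex. At 960 points the single-sphere quadrature error is below
1%; tests verify the isolated-sphere and two-sphere closed forms.

## Hydrogen bonds and salt bridges

The geometric criterion is donor–acceptor distance ≤ 3.5 Å and
hydrogen–donor–acceptor deviation angle ≤ 30° (the GROMACS `hbond`
defaults). Donors are N/O atoms carrying a hydrogen of the same residue
within 1.25 Å in the analyzed frame — the topology model carries no bond
table, so covalent attachment is inferred geometrically. A heavy-atom
fallback (distance criterion only, deduplicated across directions) serves
Cα-resolution or hydrogen-free systems.

Occupancy tables tile the analyzed interval with consecutive
non-overlapping windows (default 50 ns; the last window may be partial). A
residue pair counts as bonded in a frame when at least one hydrogen bond
exists between its residues. Cells strictly below 50% occupancy are
flagged; exactly 50% is not flagged. The frame-weighted mean of a pair's
window occupancies equals its whole-trajectory occupancy (a conservation
law the tests enforce).

Salt bridges pair the positively charged side-chain nitrogens
(LYS NZ; ARG NE/NH1/NH2; HIS ND1/NE2) with carboxylate oxygens
(ASP OD1/OD2, GLU OE1/OE2) at a 4.0 Å default cutoff, with the same
windowed-occupancy semantics.

## Distance-fluctuation (DF) maps

DF_ij is the variance over a frame window of the scalar Cα–Cα distance
d_ij(t), accumulated with a numerically stable two-pass algorithm and
never materializing a frames × pairs array. Pairwise distances are
frame-internal, so no superposition is needed and DF is exactly invariant
under per-frame rigid motions. Values below 0.3 Å² indicate rigid-body
coordination between the residues — the regime that supports strong
allosteric communication; block summaries report the mean DF and the
fraction of inter-domain pairs strictly below the threshold. The default
analysis window matches the network window (trailing 200 ns),
configurable. A plotting helper renders maps on a black→red scale with the
0.3 Å² midpoint (black = rigid, red = plastic).

## Dynamical network analysis

Nodes are Cα atoms, one per residue. Motional correlation is the
normalized scalar covariance of 3-D displacements from the time-mean
position, C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨Δr_i²⟩⟨Δr_j²⟩) — the dot-product
convention, not per-axis Pearson (both exist in the literature; the
dot-product form is the one used by the established dynamical-network
tools). Static (zero-variance) nodes are flagged and excluded from edges.
The default analysis window is the trailing 200 ns of the trajectory.

Edges are restricted to persistent contacts: any heavy-atom pair of two
residues within 4.5 Å in ≥ 75% of the window's frames, excluding trivial
|i−j| ≤ 1 same-chain neighbours. For Cα-only models, where 4.5 Å heavy-atom
contacts do not exist, a larger Cα–Cα cutoff must be chosen to match the
bead density (the synthetic presets record their own cutoff in the
generated ground truth: 10 Å for the sparse four-block benchmark, 7.5 Å
for the protein-density detachment preset).

Edge weights are w_ij = −log|C_ij| with |C| clamped to [1e−8, 1], so
strongly correlated contacts are short and communication is read from
minimum-weight Dijkstra paths (deterministic lexicographic tie-breaking;
disconnection yields an explicit no-path result).

Communities come from the Girvan–Newman dendrogram: iterative removal of
one edge at a time with edge betweenness recomputed on the weighted
(distance) graph after every removal. The removal criterion is the
*weighted* Girvan–Newman rule: betweenness divided by the edge's affinity
|C|. The normalization matters — with pure distance-weighted betweenness,
whenever one community relays traffic between two others the relay's
internal edges accumulate more betweenness than any single inter-community
edge and the dendrogram dismembers the relay; dividing by affinity makes
weak inter-community edges outrank strong intra-community ones in all such
configurations. The retained partition maximizes modularity along the
dendrogram, evaluated on the original graph with |C| as the edge affinity
(modularity expects an affinity, not a cost; this choice is configurable).
Ties keep the coarser partition; an edgeless graph yields singleton
communities with modularity 0. For large graphs a patience parameter
bounds the dendrogram descent; small-graph oracles in the test suite run
the full descent and match exhaustive partition search.

Critical edges are inter-community edges ranked by betweenness; the top
edge per community pair is labelled critical and its endpoints are the
critical nodes joining those communities. Path comparison between two
networks (closed vs open state) reports both optimal paths, their weight
difference and a longer/shorter/equal verdict, treating disconnection as
an infinite-length side.

## Detachment events

`classify_states` labels each frame closed/open/transient from a
center-of-mass distance series: baseline = mean over a baseline window
(default the first 100 ns); frames whose smoothed distance (centered
running mean, default 5 ns) exceeds baseline + `open_offset` are open.
`open_offset` defaults to 5 Å — the magnitude of the observed nSH2–helical
separation. Because a threshold placed exactly at baseline + step makes
genuinely open frames straddle it, the pipeline's own analyses of noisy
series place the detection threshold at half the expected step (2.5 Å), a
conventional hysteresis midpoint; the planted step magnitude itself is
always measured as the difference of closed/open window means. Closed
excursions between two open stretches shorter than the dwell parameter
(default 50 ns) are relabelled transient re-attachments.

`annotate_steps` operationalizes the four-step detachment mechanism:

1. **Step 1** — first sustained drop of the total inter-domain
   hydrogen-bond count, detected by comparing adjacent sliding-window
   means (default 25 ns windows, minimum drop 1 bond) and refined to the
   locally largest drop;
2. **Step 2** — first open-state onset with the designated critical pair
   (default R340–E542, then R358–E542, L380–545, K382–Q546) broken in the
   occupancy table (window state = occupancy ≥ 0.5);
3. **Step 3** — first transient re-attachment with that pair re-formed;
4. **Step 4** — the permanent loss of the critical pair while the timeline
   remains open thereafter (complete dissociation).

Step onsets must increase strictly in time; later steps are omitted when
their signals never occur. These rules are this package's
operationalization of a narrated mechanism, validated on synthetic
schedules; they are deliberately simple two-window comparisons rather than
fitted change-point models, so every decision is auditable.

## Synthetic trajectories and what they do (not) show

The generator produces Cα-resolution bead trajectories: domains are bead
clouds with block-structured motional correlations, sampled per axis as
iid Gaussians that are empirically whitened and then colored by the
Cholesky factor of the planted covariance. This moment-matched sampling
makes the sample covariance of the generated displacements *exactly* equal
to the planted matrix in any finite sample (marginals remain Gaussian to
numerical precision), so ground-truth recovery tests measure estimator
correctness rather than Monte-Carlo luck. Moment matching requires more
frames than beads and falls back to a plain draw (with a warning)
otherwise.

Scheduled contacts are pseudo hydrogen-bond sites (donor N + H and
acceptor O placed at a fixed interface anchor: formed geometry
D···A = 2.9 Å with 5° deviation, broken 6 Å) and salt-bridge sites
(3.5 Å / 6 Å), positioned deterministically each frame so per-frame counts
and occupancies follow the schedule exactly. The scripted detachment
rotates the moving domain about an axis through its own center of mass and
translates it along the line joining the two domain centers, making the
planted center-of-mass step and hinge-angle change exact by construction.

`pi3k_like_preset` packages the detachment scenario: five domains with
crystal numbering (nSH2 B:322–428, helical A:526–643, C2 A:335–478,
kinase A:699–1067, iSH2 B:429–600; ~910 beads), 1000 frames at 1 ns
spacing, per-axis noise σ = 0.5 Å, intra-domain correlation 0.7 and
inter-domain 0.05 except a 0.45 nSH2–helical coupling — chosen so the
closed-state inter-domain distance fluctuation (≈ 2σ²(1−ρ) ≈ 0.275 Å²)
sits below the 0.3 Å² rigidity criterion, which the detachment then
destroys. The contact schedule plants the stepwise mechanism at 200 ns
(hydrogen bonds 4 → 2), 500 ns (open onset, critical pair lost, +5 Å COM
step, hinge 60°→90°), 670–710 ns (transient re-attachment; the
sub-threshold COM dip lasts 40 ns, inside the 50 ns transient dwell, while
the critical pair stays re-formed until 800 ns) and 800 ns (permanent
loss). Deterministic interface bead pairs (A:537/539/544 against
B:376/378/383, 3.5–4 Å apart when closed, ≥ 8.5 Å when open) make the
closed-state contact graph and its severing by the detachment
seed-independent at the preset's 7.5 Å Cα contact cutoff.

`four_block_preset` is the planted-partition benchmark: four 10-bead
blocks on a 16 Å square with 5 Å radius, so each block induces a complete
contact subgraph at a 10 Å Cα cutoff while interfaces stay narrow;
intra-/inter-block correlations 0.8 / 0.05 over 10⁴ frames.

What passing these tests shows: the estimators (correlation, DF,
occupancy, COM/hinge geometry), the graph algorithms and the event rules
recover planted structure exactly or within stated tolerances. What they
do not show: anything about force-field accuracy, sampling convergence or
real conformational kinetics — the generator has no dynamics (frames are
exchangeable), no solvent, no real side chains, and its hydrogen-bond
sites are geometric tokens. Conclusions about a real system still require
real trajectories.

## Numerical choices

* Correlation clamp 1e−8 before −log keeps weights finite; zero-variance
  nodes are excluded rather than clamped.
* State classification compares against the threshold with a 1e−9 guard to
  keep exact-equality cases stable in floating point.
* Girvan–Newman tie-breaks: among equal removal scores the
  lexicographically smallest edge; among equal modularities the earlier
  (coarser) partition. Dijkstra ties resolve to the lexicographically
  smallest node list. All runs are reproducible.
* DF and correlation estimators divide by the frame count (population
  convention), matching the generator's moment-matched normalization.
* The two-pass DF accumulation and the parallel-variance pooling identity
  agree to 1e−10 Å² in tests.

## Problem sizes

Default study sizes — the detachment preset at 1000 frames × ~930 atoms,
the four-block benchmark at 10⁴ frames × 40 beads, analytic limits at 10⁵
frames × 10 beads — were chosen so each stage's statistics are
well-resolved (window means at ≤ 0.05 Å standard error; exact recovery
under moment matching) while a complete analysis runs in seconds on one
CPU core.

## Known limitations

* No water-mediated hydrogen bonds, no ligand analysis, no
  protonation-state logic.
* Donor identification is geometric; exotic naming schemes (e.g. united
  hydrogens) need explicit criteria.
* Girvan–Newman with full betweenness recomputation is O(E²·V) and
  impractical beyond a few hundred nodes; use the patience bound or a node
  subset for large systems.
* The greedy dendrogram is not guaranteed to contain the global modularity
  optimum on arbitrary weighted graphs; the affinity-normalized removal
  rule removes the known relay pathology but is still a heuristic.
* `compare_runs` aligns community partitions on the intersection of node
  sets; disjoint runs produce an explicitly empty comparison.
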