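# alloscope

Trajectory analysis of regulatory-domain detachment and allosteric
communication in multi-domain protein complexes.

`alloscope` is built for the kind of question raised by the oncogenic
PI3Kα E545K mutation: the charge reversal weakens the inhibitory
interface between the nSH2 domain of the regulatory subunit (p85α) and
the helical domain of the catalytic subunit (p110α), and in molecular
dynamics the nSH2 domain rotates about its 339–347 helix, separates from
the helical domain by ~5 Å in center-of-mass distance, and sheds its
interfacial hydrogen bonds in a stepwise fashion. The package turns a
topology + trajectory + domain map into the complete set of observables
used to characterize such an event:

* **Geometry** — RMSD, per-residue RMSF, inter-domain center-of-mass
  distance time series, the hinge angle φ (apex helix 339–347; arms
  residue 545 and helix 400–410), Shrake–Rupley solvent accessibility.
* **Polar contacts** — hydrogen-bond detection (donor–acceptor ≤ 3.5 Å,
  H–donor–acceptor ≤ 30°), per-frame inter-domain counts, windowed
  per-pair occupancy tables (cells < 50% flagged), salt bridges.
* **Distance-fluctuation maps** — DF_ij = Var(d_ij) per Cα pair; values
  below 0.3 Å² mark rigid-body coordination able to carry allosteric
  communication.
* **Dynamical networks** — motional correlations
  C_ij = ⟨Δr_i·Δr_j⟩/√(⟨Δr_i²⟩⟨Δr_j²⟩) on contact-filtered residue graphs
  with edge weights −log|C_ij|; Girvan–Newman communities with
  modularity selection, critical inter-community edges, and optimal
  (Dijkstra) communication paths, e.g. 545 → R358.
* **Event annotation** — closed/open/transient state labels from the COM
  series plus the four-step detachment mechanism (hydrogen-bond count
  drop; open onset with loss of the critical R340–E542 pair; transient
  re-attachment; permanent pair loss).
* **Synthetic ground truth** — a generator of Cα-resolution trajectories
  with planted correlation blocks, scheduled hydrogen-bond/salt-bridge
  sites and a scripted hinge-rotation detachment, so every stage can be
  validated against known answers (see `docs/methods.md`).

## Worked example

The synthetic PI3Kα-like preset plants the full detachment scenario
(step times 200/500/670/800 ns, 5 Å separation, hinge 60°→90°) and the
pipeline recovers it:

```python
from alloscope import events, geometry, hbond
from alloscope.structure import pi3k_domain_map, select_domain
from alloscope.synthetic import generate, pi3k_like_preset

topology, trajectory, truth = generate(pi3k_like_preset(seed=7))
dmap = pi3k_domain_map()

nsh2 = select_domain(topology, dmap, "nSH2", "CA")
helical = select_domain(topology, dmap, "helical", "CA")
com = geometry.com_distance_timeseries(trajectory, nsh2, helical)

sel_a = select_domain(topology, dmap, "nSH2", "all")
sel_b = select_domain(topology, dmap, "helical", "all")
counts = hbond.interdomain_hbond_count(trajectory, sel_a, sel_b)
table = hbond.pair_occupancy(trajectory, sel_a, sel_b, window_ns=50.0)

timeline = events.classify_states(com, baseline_window=(0, 100), open_offset=2.5)
timeline = events.annotate_steps(timeline, counts, table)

print(f"closed-state COM distance: {com.values[:200].mean():.2f} A")
print(f"open-state COM distance:   {com.values[720:].mean():.2f} A")
for step in timeline.steps:
    print(f"Step {step.step} at {step.time_ns:4.0f} ns  ({step.signal}: {step.detail})")
```

prints

```
closed-state COM distance: 30.00 A
open-state COM distance:   35.02 A
Step 1 at  200 ns  (hbond_count_drop: total count drops by 2.00)
Step 2 at  500 ns  (open_onset: A:GLU542-B:ARG340 broken)
Step 3 at  670 ns  (transient_reattachment: A:GLU542-B:ARG340 re-formed)
Step 4 at  800 ns  (permanent_pair_loss: A:GLU542-B:ARG340 lost, complete dissociation)
```

The COM distance steps from 30 Å (closed) to 35 Å (open) — the planted
5 Å detachment — and the four mechanism steps are annotated at exactly the
planted onsets: the hydrogen-bond count drops 4 → 2 at 200 ns, the domain
opens as the critical R340–E542 pair breaks at 500 ns, a transient
re-attachment forms the pair again at 670 ns, and its permanent loss at
800 ns marks complete dissociation.

## Command line

Every stage is also a subcommand of the `alloscope` CLI:

```bash
alloscope synth --preset pi3k-like --frames 1000 --seed 7 --out scratch/toy
alloscope observables -t scratch/toy.pdb -x scratch/toy.xtc -o scratch/obs \
    --domains nSH2,helical --angle helix_339_347,residue_545,helix_400_410
alloscope hbonds     -t scratch/toy.pdb -x scratch/toy.xtc -o scratch/hb --window-ns 50
alloscope dfmap      -t scratch/toy.pdb -x scratch/toy.xtc -o scratch/df --threshold 0.3
alloscope network    -t scratch/toy.pdb -x scratch/toy.xtc -o scratch/net \
    --cutoff 7.5 --window last:200ns --path A:545-B:358
alloscope events     -t scratch/toy.pdb -x scratch/toy.xtc -o scratch/ev --offset 2.5
alloscope run --synthetic-preset -o scratch/full      # all stages + manifest.json
alloscope compare scratch/runA scratch/runB           # closed vs open side by side
```

`run` writes a manifest (inputs, parameters, version, per-output SHA-256
checksums) that makes a run reproducible; `compare` lines up two bundles
(COM means ± SD, hydrogen-bond totals, DF summaries, community agreement
as adjusted Rand index, path-weight differences).

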