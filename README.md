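# quadmsm

Markov-state-model (MSM) analysis of G-quadruplex unfolding ensembles: from
raw conformational trajectories to microstates, validated transition
matrices, metastable macrostates, transition-path-theory committors and
reactive fluxes, ranked unfolding pathways, and mean first passage times —
with per-state structural characterization (RMSD, residue-center distances,
hydrogen-bond occupancy).

## Who this is for

Simulators studying the (un)folding of small structured nucleic acids — the
motivating system is the thrombin-binding aptamer (TBA,
5′-GGTTGGTGTGGTTGG-3′), a two-tetrad chair-type G-quadruplex — who have an
ensemble of short trajectories (e.g. tens of ~100 ns runs saved as
multi-model PDB) and want the long-timescale kinetic picture: which
metastable intermediates exist, how the native quadruplex unfolds, through
which gateway states, and on what timescale. A synthetic-data module
provides planted Markov chains and a toy triple-well unfolding simulator, so
every stage of the analysis is testable against known ground truth without
any simulation data.

## The model

Frames **X**ₜ are discretized into microstates s(t) by greedy k-centers
clustering under backbone Kabsch RMSD. Transitions s(t) = i, s(t+τ) = j are
counted into C, symmetrized and row-normalized into a reversible,
row-stochastic transition matrix T with stationary distribution π (detailed
balance π_i T_ij = π_j T_ji holds by construction). Markovianity is checked
by the lag-independence of the implied timescales t_k = −τ/ln μ_k and by
residence-probability curves (model propagation πᵀT^h vs direct counts).
PCCA+ lumps microstates into metastable macrostates from the top right
eigenvectors. Between a native set A and an unfolded set B, transition path
theory gives the committors

    q⁺_i = Σ_j T_ij q⁺_j   (q⁺ = 0 on A, 1 on B),   q⁻ via the time-reversed chain,

reactive fluxes f_ij = π_i q⁻_i T_ij q⁺_j, net fluxes
f⁺_ij = max(f_ij − f_ji, 0), and unfolding pathways by iterative widest-path
decomposition. Mean first passage times solve
MFPT_i = t + Σ_j T_ij MFPT_j with MFPT = 0 on the target. See
`docs/methods.md` for conventions and numerical details.

## Worked example

Run the full pipeline on the built-in toy unfolding system (24 Brownian
walkers on a folded/connector/unfolded triple-well landscape, rendered as
15-bead structures):

```python
import numpy as np
from quadmsm.pipeline import run_pipeline, default_config

cfg = default_config()
cfg["input"].update({"n_traj": 24, "n_steps": 100_000, "save_stride": 500})
cfg["cluster"]["k"] = 30
cfg["report"]["n_samples"] = 60
res = run_pipeline(cfg, "example_run", seed=1)

macro = res["macro"]
A, B = res["endpoints"]
print(f"microstates: {res['cluster'].n_centers}  active: {res['model'].n_states}")
print(f"macrostate populations: {np.array2string(macro.populations, precision=3)}")
print(f"source (folded) state: {A[0]}   target (unfolded) state: {B[0]}")
for r, p in enumerate(res["pathways"], 1):
    print(f"pathway {r}: {p.label()}  fraction of reactive flux: {p.fraction:.3f}")
print(f"MFPT folded -> unfolded: {res['mfpt'].times[A[0]]:.1f} lag-time units")
```

prints

```
microstates: 30  active: 30
macrostate populations: [0.395 0.462 0.143]
source (folded) state: 1   target (unfolded) state: 0
pathway 1: 1-2-0  fraction of reactive flux: 1.000
MFPT folded -> unfolded: 976.0 lag-time units
```

Reading this: three macrostates are recovered — a folded basin (state 1,
population 0.46, mean backbone RMSD 0.8 Å against the reference, G1–G15
end-to-end distance 14.2 ± 0.6 Å), an unfolded basin (state 0, population
0.40, RMSD 10.5 Å, G1–G15 43.9 ± 1.1 Å — the extended strand), and a
low-population connector (state 2, population 0.14, intermediate geometry at
G1–G15 21.6 ± 4.0 Å). The single dominant unfolding pathway 1→2→0 passes
through the connector, exactly the planted topology, and the mean first
passage time from folded to unfolded is ~976 lag-time units. The artifact
directory (`example_run/`) contains every stage's output as plain text:
discrete trajectories, count/transition matrices, implied timescales,
PCCA+ memberships, residence-probability curves, committors, net fluxes,
ranked pathways, MFPTs, per-state summary tables with hydrogen-bond
occupancies, representative structures as PDB, and the macrostate network
as GraphML/GEXF.

The same pipeline runs from the command line:

```bash
quadmsm --seed 1 --outdir example_run run
quadmsm --outdir example_run tpt -a 1 -b 0
```

For real data, point `input.kind: pdb` at multi-model PDB trajectories in a
YAML config, set `cluster.selection: backbone` and a cutoff (e.g. 0.75 Å)
or k, and choose the lag on the implied-timescale plateau.

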