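# aridiv

Diversification-rate and ancestral-area analysis for dated phylogenies
(chronograms), packaged as a reusable, tested pipeline:

- **treeio** — Newick/NEXUS chronogram parsing with ultrametricity
  validation, branching-time extraction, posterior-sample subsampling, and
  tip-to-area tables.
- **bd_sim** — Yule / birth-death / piecewise-shift tree simulation
  conditioned on tip count, plus random tip pruning (incomplete-sampling
  experiments).
- **ltt** — lineage-through-time curves and a null-envelope comparison of an
  empirical curve against simulated trees.
- **rates** — whole-clade and per-node speciation-rate estimators, with and
  without a relative-extinction correction (ε).
- **shiftfit** — piecewise-constant reconstructed birth-death likelihood with
  a present-day sampling probability ρ, constant and k-shift maximum
  likelihood fits by exhaustive grid search over shift times, and
  likelihood-ratio model selection.
- **diva** — dispersal-vicariance (DIVA) ancestral-range optimization by
  dynamic programming over area subsets, S-DIVA frequency profiles over a
  tree sample, and dispersal-event counting.
- **synthetic_data** — truth-annotated synthetic studies (trees, pruning,
  simulated tip areas) so every stage is testable offline.
- **pipeline / cli** — an end-to-end analysis driven by a YAML config.

## CLI

```sh
aridiv synth -o study/                      # truth-annotated synthetic study
aridiv simulate -n 51 --lam 0.166 --reps 1000 --prune 28 -o sims/
aridiv ltt-test study/pruned.nwk sims/ -o ltt_out [--plot]
aridiv rates study/pruned.nwk --eps 0 --eps 0.5 --eps 0.9
aridiv shiftfit study/pruned.nwk --rho 0.45 --grid-step 0.1 --max-shifts 3
aridiv diva study/pruned.nwk study/areas.tsv -o diva_out
aridiv run --config config.yaml -o report.json
```

A minimal `config.yaml`:

```yaml
chronogram: study/pruned.nwk
total_species: 51
rho: 0.45
tree_sample: study/sample.nwk   # optional, for S-DIVA
area_table: study/areas.tsv     # optional, for S-DIVA
envelope_reps: 1000
grid_step: 0.1
max_shifts: 3
seed: 1
```

## Conventions worth knowing

- Ages are Ma before present; tips sit at age 0 exactly (trees within a
  relative tolerance of 1e-6 × crown age are snapped).
- Simulations condition on n tips by stopping at the first birth event that
  occurs while n lineages are extant, so Yule inter-event waits while k
  lineages exist are Exp(kλ), k = 2..n.
- The shift-fit likelihood is conditioned on the crown age and on survival
  of both crown lineages; `ShiftModel` epochs are present-to-past with
  ascending shift ages.
- DIVA: vicariance and single-area duplication are free; each unit-area
  dispersal or extinction costs 1; all cost-optimal states are reported.
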