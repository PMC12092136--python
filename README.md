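# nashnets

Given a binary strategy profile (an assumed Nash equilibrium for *n*
players), **nashnets** characterizes, verifies, counts, enumerates and
stochastically samples the interaction networks under which that
profile is a Nash equilibrium of one of three games played on the
network:

- **majority** — each player prefers the strategy held by a strict
  majority of its neighbors (strategic complements);
- **minority** — each player prefers the strategy held by a strict
  minority of its neighbors (strategic substitutes);
- **best-shot** public goods — contributing costs `c ∈ (0,1)`; in
  equilibrium the contributor set is an independent set that covers
  every non-contributor.

Vertices are labeled 1..n (isomorphic graphs with different labels are
distinct), edges are unordered pairs, and the whole graph space is
indexed by a canonical edge bitmask so every enumeration is
reproducible.

## Library overview

| module | contents |
|---|---|
| `nashnets.core` | `StrategyProfile`, `LabeledGraph`, `GameSpec`, `EquilibriumPolicy`, per-vertex satisfaction and `check_acceptable` |
| `nashnets.counting` | exact closed-form counts (`count_best_shot`, `count_majority_all_same`, …) with inclusion–exclusion primitives, arbitrary precision |
| `nashnets.enumeration` | `graph_space`, brute-force and structured enumeration of acceptable networks, composition sweeps, edge-count histograms |
| `nashnets.simulation` | random add/remove walks absorbed at the acceptable set, N1/N2 histograms, density-trend statistics |
| `nashnets.io` / `nashnets.fixtures` / `nashnets.cli` | edge-list TSV / adjacency CSV / profile JSON readers and writers, named scenarios, CLI |

```python
from nashnets import (Game, StrategyProfile, check_acceptable,
                      count_best_shot, enumerate_acceptable, LabeledGraph)

profile = StrategyProfile((1, 0, 1, 1, 0, 0))      # players 1,3,4 play 1
graph = LabeledGraph.from_edges(6, [(1, 2), (3, 5), (4, 6)])
check_acceptable(graph, profile, Game.BEST_SHOT).acceptable  # True

count_best_shot(3, 3).count                         # 2744
graphs, hist = enumerate_acceptable(profile, Game.MINORITY)
```

Degree-0 vertices in the majority/minority games fall outside the
strict best-response inequalities; the default *feasibility-vacuous*
policy accepts an isolated vertex exactly when no wiring could satisfy
its condition under the profile (`accept-all` / `reject-all` variants
are available via `EquilibriumPolicy` or `--policy`).

## Command line

```sh
nashnets check --graph g.tsv --profile p.json --game majority
nashnets count --game best-shot --n0 3 --n1 3 --json
nashnets enumerate --profile p.json --game minority --histogram n1.csv
nashnets sweep --n 5 --game majority --out sweep.csv
nashnets simulate --profile p.json --game minority --realizations 100 \
    --seed 7 --out sim.csv         # writes sim.csv + sim.csv.json sidecar
nashnets fixtures                  # list built-in scenarios
```

`simulate` runs a random edge add/remove walk from every graph in the
space (R independent realizations each), recording the first acceptable
network reached; the output CSV holds `edges,N1,N2,ratio` where N1 is
the acceptable-network histogram, N2 the first-hit histogram and ratio
a scaled N2/N1 (default scale 50 for majority, 0.5 otherwise).  With a
fixed `--seed` all outputs are byte-identical across runs.

Guards: brute force over the `2^(n(n-1)/2)` graph space is limited to
`n ≤ 7` by default (`brute_force_ceiling` in `--config`).

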