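# energyscape

Disconnectivity graphs and **metric disconnectivity graphs** for potential
energy landscapes.

A potential energy surface U(**r**) of an N-particle system has far too many
dimensions to look at directly.  A *disconnectivity graph* compresses it into
a tree: leaves are local minima drawn at their energies, and two minima join
at the lowest energy threshold at which they become mutually accessible —
the *minimax barrier*, the smallest possible value over connecting paths of
the highest transition-state energy en route.  Funnels appear as coherent
branches.  A plain disconnectivity graph, however, discards all structural
information.  A **metric** disconnectivity graph restores some of it by
placing each minimum along the horizontal axis (or two axes, in 3D) at the
value of a structural order parameter, with each internal node at the mean
of its descendant minima's values.

`energyscape` is for researchers who have (or can generate) databases of
minima and transition states — in the plain-text `min.data` / `ts.data`
dialect of stationary-point sampling codes — and want to see how structure
correlates with the energetic and kinetic organisation of the landscape.

## What's in the box

* **Tree construction** — sublevel-set selection (all minima connected to
  the global minimum below a threshold U_t), uniform energy-level lumping,
  funnel coloring, standard and metric layouts, 2D/3D matplotlib rendering,
  and a JSON graph document for lossless export/import.
* **Order parameters** over the sublevel set:
  * fraction of native contacts N_α/N_NC (contacts: bead pairs within
    1.167 σ, pairs within three beads along the chain excluded),
  * RMSd from the global minimum (Kabsch superposition, proper rotations
    only),
  * principal components of the ensemble after iterative best-fit
    alignment (Cartesian basis, or sines/cosines of backbone dihedrals),
    with back-projection of components onto structures,
  * Isomap: geodesic distances through a k-nearest-neighbour graph
    (k = 15 by default), embedded by classical multidimensional scaling.
* **A coarse-grained bead-chain protein model** with hydrophoBic /
  hydrophiLic / Neutral beads,

      U = Σ K_r (R − R_e)² + Σ K_θ (θ − θ_e)²
        + Σ [A (1 + cos φ) + B (1 + cos 3φ)]
        + Σ 4 ε [C (σ/R)¹² − D (σ/R)⁶],

  including the 69-bead frustrated β-barrel former
  B₉N₃(LB)₄N₃B₉N₃(LB)₄N₃B₉N₃(LB)₅L and its unfrustrated Gō variant,
  with analytic gradients, local minimization, basin-hopping and a linear
  interpolation barrier surrogate.
* **Synthetic generators** with ground truth — multi-funnel databases with
  known funnel labels, planted anisotropic Gaussian ensembles with known
  variance fractions, and curved 1-D conformational manifolds with known
  arc-length order — so every pipeline stage is testable without external
  data.

Energies are dimensionless multiples of ε and lengths multiples of σ
throughout.

## Worked example

Generate a three-funnel synthetic landscape, build its tree, compute the
first principal-component metric, and render the metric disconnectivity
graph:

```
$ energyscape simulate --seed 1 --out-dir landscape
75 minima, 74 transition states, 3 funnels -> landscape

$ energyscape tree --min-data landscape/min.data --ts-data landscape/ts.data \
      --coords landscape/coords.txt --ut -85 --delta-u 0.5 \
      --cut-level -88.5 --out tree.json
tree: 75 leaves, 41 internal nodes, 3 funnels -> tree.json

$ energyscape metric --min-data landscape/min.data --ts-data landscape/ts.data \
      --coords landscape/coords.txt --ut -85 --kind pc --component 1 \
      --out pc1.tsv
cartesian_pc1: 75 values -> pc1.tsv

$ energyscape render --tree tree.json --metric pc1.tsv --dims 2 \
      --color funnel --out pc1_graph.png
rendered 2D graph -> pc1_graph.png
```

What the numbers mean: the generator planted 3 funnels of 25 minima each
(global minimum at −100 ε, funnels joined by transition states at −88 ε),
connected within each funnel by a spanning tree — hence 74 transition
states.  Cutting the tree at −88.5 ε, just below the inter-funnel barrier,
recovers exactly 3 funnels.  The metric table holds one PC1 value per
minimum in σ:

```
# metric: cartesian_pc1
# reference: None
1 5.997830682176823
2 5.562471350776911
```

Because the funnels were displaced along a planted structural axis, the
PC1 values cluster by funnel and the three branches of `pc1_graph.png`
are cleanly separated horizontally — the structural story behind the
energetic one.

The same pipeline runs on real stationary-point databases by pointing
`--min-data` / `--ts-data` / `--coords` at your own files; `energyscape
bln basinhop` can generate small in-repo databases for the bead-chain
model.  Use two `--metric` tables and `--dims 3` for a 3D graph.

## Layout

```
src/energyscape/
  bln.py        bead-chain potential, minimization, basin-hopping
  database.py   min.data/ts.data I/O, sublevel sets, minimax barriers
  tree.py       threshold lumping, tree construction, coloring, layouts
  metrics.py    contacts, RMSd, ensemble PCA, Isomap
  synthetic.py  ground-truth generators
  render.py     2D/3D matplotlib rendering
  document.py   JSON graph documents
  cli.py        the `energyscape` command
docs/methods.md   model and algorithm notes, conventions, limitations
```
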