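# Methods

## Network model

The clotting cascade is modelled as a directed graph whose nodes are the
enzymes, zymogens, cofactor complexes and inhibitors of the coagulation
system and whose arrows point from a species to the species whose
formation it promotes (activation, complex assembly, or inhibitory
binding, all drawn uniformly as arrows, as pathway diagrams do). Edges
carry a dimensionless positive *line value* interpreted as path length;
the unperturbed network uses 10 everywhere. The packaged fixture has 41
nodes and 53 edges covering the extrinsic (tissue factor / VIIa),
intrinsic (contact activation through the VIIIa:IXa tenase complex) and
common (prothrombinase, thrombin, fibrin, XIIIa cross-linking) pathways
plus TFPI, antithrombin III, heparin, the protein C system,
alpha-2-macroglobulin and heparin cofactor II.

Two modelling caveats are worth stating plainly.  First, the
reciprocal-distance sum over ordered pairs is invariant under reversing
every arrow simultaneously (transposition exchanges d_ij and d_ji), so
none of the efficiency statistics can distinguish the two possible
global arrow conventions; the fixture stores arrows
activator-to-product.  Second, inhibitor arrows are structurally
identical to activation arrows in this model — network efficiency treats
every connection as contributing to cascade integrity.  That is a known
simplification of the efficiency formalism, not an oversight.

## Network efficiency

For a weighted directed graph G with shortest-path lengths d_ij,

    NE(G) = sum over ordered pairs (i, j), i != j, of 1 / d_ij,

with unreachable pairs contributing zero.  The ordered-pair convention
(rather than a sum over unordered pairs, or a mean) is fixed by
calibration against the published reference values of the fixture:
only the ordered-pair sum with no pair-count normalisation reproduces a
baseline NE of 17.822 on a 41-node network whose edges all have length
10 (a mean over the 1640 ordered pairs would be two orders of magnitude
smaller).  An `unordered_min` pair mode — min(d_ij, d_ji) over unordered
pairs — is provided for sensitivity analyses.  Shortest paths are
computed by Dijkstra's algorithm (via networkx), which requires the
strictly positive line values the data model already enforces.

Useful exact properties, all covered by tests: deleting any node or
edge, or increasing any line value, never increases NE; multiplying all
line values by c > 0 divides NE by exactly c; NE from Dijkstra equals NE
from exhaustive simple-path enumeration on small graphs.

Fragility scans delete one element at a time — a node together with its
incident edges, or a single edge — and rank elements by NE drop, ties
broken lexicographically for reproducibility.  On the fixture the most
fragile nodes are factor Xa (17.822 → 8.894), thrombin (→ 10.542) and
the VIIIa:IXa tenase complex, and the most fragile edges are the
tenase-mediated activation of factor X and the assembly of the tenase
complex itself — the cascade's narrowest bottleneck.

## Fixture calibration

The published efficiency values above are properties of one specific
hand-drawn pathway transcription whose machine-readable edge list is not
available.  The shipped fixture was therefore constructed in two steps:
a best-effort transcription of the Reactome-style clotting-cascade
topology (the backbone wiring of the three pathways and their
inhibitors), followed by a combinatorial calibration that searched over
a pool of biologically defensible arrows — contact-activation variants,
thrombin feedbacks, inhibitor attachment points — for a 41-node,
53-edge selection whose exact rational efficiency sums reproduce all
three published values at the published 3-decimal precision and whose
knockout rankings place factor Xa first, thrombin second and the tenase
complex third, with the tenase catalysis and assembly edges as the two
most fragile reactions.  The calibrated edge list is frozen as package
data (`data/clotting_cascade.tsv`); a regression test pins its node and
edge counts and the efficiency values.  One further documented
discrepancy: the source material states 53 edges in its text and 55 in
a figure caption; the fixture follows the text.

Because the efficiency statistics cannot identify the transcription
uniquely (many edge lists share these sums), the fixture should be read
as *a* calibrated representative consistent with every published
quantitative and ordinal constraint, not as a certified copy of the
original drawing.

## Line-value transformation

Docking scores enter as binding free energies BE in kcal/mol (negative
is favourable; positive scores are clamped to 0 on load, with a logged
count).  Per target, the reference energy BEs is the most negative
energy observed in the analysed table — the most potent binder — unless
an external reference is supplied.  A compound's effect on a target's
out-edges is

    LV = 10 ** (2.3 * |BE| / |BEs|),

so the reference ligand sets LV = 10^2.3 ≈ 199.53 (200 to three
significant figures), and the exponent is linear in the energy ratio.
Raw LV values below the baseline 10 (|BE|/|BEs| < 1/2.3 ≈ 0.435) are
floored at 10: without the floor a weak binder would *shorten* the
target's out-edges below their resting length and increase NE, i.e. a
non-binder would strengthen the cascade, which is physically backwards.
The floor is configurable (`TransformConfig(lv_floor=None)`) for
fidelity experiments.  Only out-edges of the scored target node are
reweighted; complexes containing a target are separate nodes and are
only perturbed if the score table names them explicitly.

## Compound estimation and screening

Per compound: reweight every scored target's out-edges, recompute NE,
report the decrease from baseline, rank by decrease (descending, ties
lexicographic).  The two-stage hierarchical screen ranks all compounds
under a fast scoring table, carries the top ceil(keep_fraction × n)
(at least one compound) into a slower, more accurate table, and re-ranks
the survivors; reference energies are recomputed per stage because each
scoring program has its own energy scale.  The drug–target network links
a compound to every target with |BE| at or above a caller-chosen
threshold; there is no default threshold because no principled universal
cutoff exists — it is a reporting choice, deliberately exposed as a
required parameter.

## Assay validation

Each clotting assay (aPTT, PT, TT) is summarised as a prolongation
ratio (t_sample − t_control) / t_control, and the sum of the three
ratios is the whole-cascade activity readout, since the three assays
probe the intrinsic, extrinsic and common pathway respectively.
Validation inner-joins predicted NE decreases with assay records on
compound id and reports the sample Pearson correlation (scipy), with
fewer than three common compounds an error.  Records with a missing
ratio are excluded, never zero-filled.

The packaged validation table transcribes the published panel of
fourteen compounds verbatim.  Two facts about that table are documented
rather than patched.  (1) In five of its fourteen rows the printed sum
column differs from the sum of the printed component ratios by exactly
0.001 — the components and the sum were evidently rounded independently
from unrounded measurements; the fixture keeps the printed sums in a
separate column (`printed_sum`) alongside the components.  (2) The
correlation between the printed activity sums and the printed NE
decreases evaluates to r ≈ 0.701, whereas the published headline value
is r = 0.671, presumably computed from unrounded activities that are not
machine-readable; the validation tests therefore accept r within ±0.05
of 0.671.  A single-target mode (`validate_against_target`) correlates
activity with |BE| on one named target — the conventional single-target
baseline — and is exercised on synthetic data only, because per-target
published scores are not available.

## Synthetic data

The generators emulate the study's shape without its chemistry:

- `generate_cascade` draws a weakly connected feed-forward DAG in
  topological order (each non-root node receives an arrow from an
  earlier node, extra forward arrows to the requested density, all line
  values 10).  `allow_feedback` adds back-arrows that close genuine
  forward paths, mimicking thrombin's amplification loops; the default
  stays acyclic, so tests on DAGs say nothing about cycle-rich real
  pathways unless the flag is used.
- `generate_scores` plants a potency gradient: compound k scores
  gradient[k] + Gaussian noise on every one of the n_targets
  highest-out-degree nodes (targets with no out-edges could not perturb
  the network), clamped nonpositive.  The default gradient spans −12 to
  −6 kcal/mol so every compound stays above the line-value floor and
  the planted order is strictly recoverable at zero noise.
- `generate_assays` sets each compound's activity sum to link_strength ×
  mean |BE| plus truncated Gaussian noise, split into three nonnegative
  component ratios by Dirichlet proportions.  Because NE decrease is a
  monotone but nonlinear function of |BE|, a noiseless linear link gives
  a rank correlation of exactly 1 against NE decreases while the Pearson
  correlation stays slightly below 1; tests assert accordingly.

All generators are deterministic in their seeds.  What passing synthetic
tests demonstrate: the pipeline's plumbing, rank recovery under planted
signal, and null behaviour under no signal.  What they do not
demonstrate: docking-score realism, correlated errors across related
targets, or assay noise structure.

## Numerical and scale choices

Problem sizes in the test suite are chosen to keep the full run around a
couple of minutes: brute-force oracle comparisons use ≤ 8-node graphs
(exhaustive simple-path enumeration is exponential), property sweeps use
200 random graphs, planted-rank recovery uses 100 trials of a 15-node /
8-compound / 4-target configuration.  The fixture computations
themselves are sub-second.  Floating-point comparisons against published
3-decimal values format the computed double with `%.3f` rather than
testing closeness, matching how the reference values were printed; the
calibration guarantees the exact rational sums sit strictly inside the
rounding windows, so the printed form is stable to summation order.

## Known limitations

- Inhibitors contribute to NE like activators; the formalism measures
  connectivity, not signed regulation.
- NE decrease saturates once every scored target's out-edges are near
  LV 200; compounds beyond that are indistinguishable.
- The published per-compound NE decreases cannot be recomputed from
  scratch because the underlying docking scores were never published;
  they ship as fixture data for validation arithmetic only.
- Reference energies computed within a compound set make every ranking
  relative to that set; pin references externally
  (`reference_energies` + `refs=`) for cross-set comparability.
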