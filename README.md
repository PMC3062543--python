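# cascade-ne

Network-efficiency analysis of the human clotting cascade for
multi-target anticoagulant screening.

## The problem

Virtual screening conventionally scores a compound against one target at
a time, but anticoagulant potency is a property of the whole coagulation
network: partially inhibiting several enzymes can shut the cascade down
more effectively than fully inhibiting one. `cascade-ne` implements a
network-based estimation scheme that turns multi-target docking scores
into perturbations of a weighted directed pathway graph and ranks
compounds by how much they degrade the graph's ability to transmit
influence.

## The model

The clotting cascade is a directed graph *G* of *N* enzymes, zymogens
and complexes; an arrow means the source species promotes formation of
the target species. Every arrow carries a positive **line value** (its
length as a path segment), 10 in the unperturbed network. The global
statistic is the **network efficiency**

    NE(G) = Σ_{i≠j} 1 / d_ij

where *d_ij* is the shortest weighted directed path length from node *i*
to node *j* and unreachable pairs contribute 0. Deleting a node or edge,
or lengthening any edge, can only lower NE; the drop measures how much
the cascade depends on that element.

A compound with binding energy *BE* (kcal/mol, ≤ 0) against a target
whose most potent observed binder has energy *BEs* stretches every
out-edge of that target node to

    LV = 10^(2.3 · |BE| / |BEs|)

so the reference ligand (BE = BEs) stretches them to 10^2.3 ≈ 200 and a
non-binder leaves them at the baseline 10 (raw values below 10 are
floored). Compounds are ranked by **NE decrease** = NE(intact) −
NE(reweighted); the larger the decrease, the more potent the predicted
whole-pathway anticoagulant effect. Predictions are validated by Pearson
correlation against the summed prolongation ratios of the three clinical
clotting assays (aPTT, PT, TT), Δratio = (t_sample − t_control) /
t_control.

The package ships a curated 41-node, 53-edge clotting-cascade network
(extrinsic, intrinsic and common pathways plus the physiological
inhibitors) and the published validation table of fourteen assayed
compounds.

## Worked example

```python
>>> import cascade_ne as cn
>>> net = cn.clotting_cascade_fixture()
>>> cn.network_efficiency(net).ne
17.822251082251086
>>> cn.network_efficiency(net.without_node("factor_xa")).ne
8.893571428571414
>>> scan = cn.node_knockout_scan(net)
>>> scan.head(3)[["element", "ne_after", "rank"]]
                   element   ne_after  rank
0                factor_xa   8.893571     1
1                 thrombin  10.541627     2
2  factor_viiia:factor_ixa  12.198333     3
```

Deleting factor Xa nearly halves the efficiency of the intact cascade
(17.822 → 8.894) and deleting thrombin drops it to 10.542, which is why
both enzymes are prime anticoagulant targets; the tenase complex
(VIIIa:IXa) ranks third.

Ranking compounds from a docking-score table and validating against the
packaged assay panel:

```python
>>> table = cn.load_scores("scores.csv")   # compound,target,binding_energy
>>> estimates = cn.estimate_compounds(net, table)
>>> report = cn.validate(estimates, cn.table1_fixture())
>>> report.n, round(report.pearson_r, 3)
```

With the published NE decreases of the fourteen validation compounds the
correlation against the summed assay activities is r ≈ 0.70 over n = 14
compounds.

The same operations are available from the shell:

```sh
cascade-ne knockout --mode node                 # fragility scan of the fixture
cascade-ne rank --scores scores.csv             # NE-decrease ranking
cascade-ne screen --stage1 a.csv --stage2 b.csv --keep 0.10
cascade-ne dtn --scores scores.csv --strong-threshold 6 --out dtn.graphml
cascade-ne validate --table1
cascade-ne simulate --spec spec.yaml --out-dir sim/
```

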