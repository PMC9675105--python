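# heteroprop

Protein function prediction by restart propagation on a heterogeneous
protein–domain network.

Network-based function prediction exploits the observation that interacting
proteins, proteins in the same complex and proteins sharing domain
composition tend to share Gene Ontology annotations. `heteroprop` fuses
those three evidence sources into one two-layer network and annotates a
target protein from its propagated functional partners. It is aimed at
computational biologists who have a PPI edge list, a complex catalog
(CYC2008-style), a protein–domain table (Pfam-style) and GAF annotations —
or who want a fully synthetic, seeded benchmark with planted structure.

## The model

A weighted PPI layer blends local topology with complex co-membership:

- `fs(u,v)` = 1 if `v` is both a direct and a level-2 neighbour of `u`,
  `α` if direct only, `1−α` if level-2 only, else 0 (with `0<α<1`);
- `ms(u,v) = |C_u ∩ C_v|² / (|C_u|·|C_v|)` over complex membership sets;
- `mpp(u,v) = β·fs(u,v) + (1−β)·ms(u,v)`.

Domains are compared through the cohesion of their protein lists: with
`S_PD(u,PL) = max_{p∈PL} mpp(u,p)`, the domain similarity `mdd(i,j)`
averages the `S_PD` of every protein in each list against its own list. The
blocks stack into `HBM = [[MPP, MPD], [MPDᵀ, MDD]]`, row-normalised into a
transition matrix in which a move probability `λ = 0.2` is reserved for
crossing between the protein and domain layers. Scores follow the random
walk with restart

```
pr⁽ᵗ⁺¹⁾ = (1−γ)·HBM_T·pr⁽ᵗ⁾ + γ·pr⁽⁰⁾,    γ = 0.5,
```

seeded with the target's weighted-PPI row (domains take the max over their
protein lists), iterated to an L1 tolerance. Candidate GO terms from all
positive-score partners are ranked by summed partner score, and the top `L`
are predicted, where `L` copies the annotation count of the best-scoring
annotated partner. Defaults follow the published calibration: `λ = 0.2`,
`γ = 0.5`, and per-ontology `β` of 0.8 (BP), 0.7 (MF), 0.9 (CC).

See `docs/methods.md` for assumptions, edge cases and the evaluation
protocol in detail.

## Worked example

```python
from heteroprop import FunctionPropagator, leave_one_out, roc_curve
from heteroprop.simulate import SyntheticConfig, generate_dataset

cfg = SyntheticConfig(n_proteins=60, n_complexes=12, complex_size_range=(5, 5),
                      p_intra=0.9, p_background=0.02, term_noise=0.1, seed=4)
graph, complexes, domains, annotations = generate_dataset(cfg)
model = FunctionPropagator().fit((graph, complexes, domains), annotations)

target = graph.proteins[0]
pred = model.predict_one(target, annotations=annotations.drop([target]))
print(f"{target}: L={pred.L}, converged in {pred.iterations} iterations")
for term, score in zip(pred.terms, pred.scores):
    print(f"  {term}  {score:.4f}")

report = leave_one_out(model, collect_rankings=True)
curve = roc_curve(report.rankings, annotations)
print(f"LOOCV: P={report.precision:.3f} R={report.recall:.3f} "
      f"F={report.f_measure:.3f} AUROC={curve.auroc:.3f}")
```

prints

```
P001: L=3, converged in 15 iterations
  GO:0000033  3.0663
  GO:0000035  3.0663
  GO:0000066  3.0663
LOOCV: P=0.836 R=0.822 F=0.829 AUROC=0.921
```

`P001`'s labels were hidden before predicting; the three predicted terms are
exactly its complex's planted signature (each scores ≈3.07, the summed
propagated score of the annotated partners carrying it), and `L=3` was copied
from the closest annotated partner. Hiding each protein in turn (LOOCV)
recovers the planted annotations with F = 0.83 on this 10 %-noise dataset,
and ranking quality gives AUROC = 0.92 on the top-K ladder.

The same pipeline is scriptable from the shell:

```sh
heteroprop simulate --seed 7 --out-dir data/
heteroprop predict  --ppi data/ppi.tsv --complexes data/complexes.tsv \
    --domains data/domains.tsv --gaf data/annotations.gaf \
    --target P001 --out pred.tsv
heteroprop evaluate --ppi data/ppi.tsv --complexes data/complexes.tsv \
    --domains data/domains.tsv --gaf data/annotations.gaf \
    --protocol loocv --out report.json --roc-out roc.tsv
```

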