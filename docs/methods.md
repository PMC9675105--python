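# Methods

## The model

The predictor assumes that a protein's functions can be read off its
*functional partners*: proteins that are close to it in a network that fuses
three kinds of evidence.

**Weighted PPI layer.** For a target protein $u$ with direct-neighbour set
$S_1$ and level-2-neighbour set $S_2$ (nodes reachable by a path of exactly
two edges), the topology similarity is

$$fs(u,v)=\begin{cases}1 & v\in S_1\cap S_2\\ \alpha & v\in S_1-S_2\\
1-\alpha & v\in S_2-S_1\\ 0 & \text{otherwise,}\end{cases}$$

with $0<\alpha<1$ weighting exclusive direct neighbours. Complex
co-membership gives the module similarity
$ms(u,v)=|C_u\cap C_v|^2/(|C_u||C_v|)$, where $C_u$ is the set of complexes
containing $u$ (zero when either set is empty). The edge weight is the blend
$mpp(u,v)=\beta\,fs(u,v)+(1-\beta)\,ms(u,v)$. Support is deliberately not
restricted to observed interactions: pure level-2 pairs and non-interacting
complex co-members also receive weight. The diagonal is zero.

**Domain layers.** Protein–domain incidence $mpd(u,dn)\in\{0,1\}$ is taken
as-is. Domains are compared through the cohesion of their protein lists
$PL(dn)$: with $S\_PD(u,PL)=\max_{p\in PL} mpp(u,p)$,

$$mdd(i,j)=\frac{\sum_{p\in PL(i)}S\_PD(p,PL(i))+\sum_{p\in PL(j)}S\_PD(p,PL(j))}
{|PL(i)|+|PL(j)|}.$$

Note the formula contains no cross-list term: a pair's similarity depends
only on each domain's own internal cohesion. This literal property is pinned
by a regression test rather than "fixed", since it is what the defining
formula says. The $mdd$ diagonal is evaluated by the same formula but zeroed
before normalisation so self-transitions cannot trap probability mass
(standard restart-walk practice; the source is silent on the point).

**Propagation.** The blocks stack into
$HBM=\begin{bmatrix}MPP&MPD\\MPD^T&MDD\end{bmatrix}$, row-normalised into a
transition matrix with a move probability $\lambda$ reserved for switching
layers: a protein with at least one domain spends $\lambda$ of its mass on
its domains and $1-\lambda$ on its weighted neighbours, and symmetrically
for domains; nodes without a cross-layer link keep all mass in their own
layer. Scores follow
$pr^{t+1}=(1-\gamma)\,HBM\_T\,pr^t+\gamma\,pr^0$, seeded with
$pr^0=[h(P);h(D)]$ where $h(p_i)=mpp(u,p_i)$ and
$h(d_j)=\max_{p\in PL(d_j)}h(p)$, iterated from $pr^0$ until the L1 change
drops below $\varepsilon$. For $\gamma>0$ the update contracts in L1 with
factor at most $1-\gamma$, so the fixed point is unique; a direct sparse
solve of $(I-(1-\gamma)T)\,pr=\gamma\,pr^0$ is shipped as an independent
oracle and the two routes agree to 1e-8 in the tests.

**Term selection.** Candidate terms are the union of the annotations of all
partners with positive propagated score (the target is excluded from its own
partner list; domain nodes carry no terms). A term's score sums the scores
of the partners annotated with it, candidates are ranked score-descending
(term ID ascending on ties), and the prediction takes the top $L$, where $L$
is the annotation count of the highest-scoring *annotated* partner (ties
take the larger count). Restricting to annotated partners keeps $L$
meaningful when the single closest partner happens to be unannotated, and is
consistent with "no annotated partner gives $L=0$".

## Parameters

| name | meaning | default | notes |
|---|---|---|---|
| `alpha` | exclusive direct-neighbour weight | 0.8 | no published default; direct neighbours dominate function sharing, so they are weighted near 1; exposed and swept in tests |
| `beta` | topology/module blend | per ontology: BP 0.8, MF 0.7, CC 0.9 | published sweep optima; explicit value overrides |
| `move_prob` ($\lambda$) | layer-switch mass | 0.2 | published value |
| `restart` ($\gamma$) | restart weight | 0.5 | published value |
| `epsilon` | L1 stop tolerance | 1e-6 | unstated in the source; with $\gamma=0.5$ the contraction bound gives roughly 20 iterations |
| `max_iter` | iteration cap | 1000 | non-convergence is flagged, not raised |
| `min_score` | partner-score floor | 0.0 | exact "> 0" partner rule; a floor is available because propagation leaves tiny positive mass widely |
| `orientation` | transition orientation | `row` | the literal row-stochastic reading of the update; a column-normalised variant is exposed for comparison |

## Numerical and edge-case choices

- **Row-sum law and its corner.** Transition rows sum to 1, or to 0 for
  nodes with no outgoing weight. The normalisation equations are implemented
  literally, which leaves one corner: a protein that carries a domain but
  has zero weighted-PPI row sum gets a row summing to $\lambda$ only (its
  protein part vanishes). Such nodes cannot arise from the planted-structure
  generator configurations used in the test suite (every domain-carrying
  protein there has a positive-weight co-member), and in real data they
  correspond to proteins with domain evidence but no usable interaction
  weight — their outgoing mass is simply damped.
- The branch conditions of the normalisation are read as "the source node
  has at least one cross-layer link" (the published index order is
  internally inconsistent).
- $pr^0$ is used unnormalised and no per-iteration renormalisation is
  applied; the iteration starts at $pr^0$.
- Ties are broken deterministically everywhere (term ID ascending after
  score descending; first-appearance ordering defines all matrix indices),
  so identical inputs give byte-identical outputs.
- Isolated nodes keep all-zero transition rows; with a zero restart vector
  the propagation returns exactly zero.

## Evaluation protocol

Leave-one-out CV hides one annotated protein's labels per round; k-fold CV
(default 10 folds, 1 repeat — a repeats flag exists) hides one random fold
at a time. Precision and recall are averaged over proteins and the reported
F-measure is the harmonic mean of those two averages (validated against the
published arithmetic: P/R pairs 0.504/0.523 and 0.584/0.604 give F 0.513 and
0.594 to three decimals). Proteins with empty truth are excluded; empty
predictions contribute P=R=0.

The ROC uses a top-$K$ ladder: per protein the ranked candidate list, padded
with the remaining term universe in term-ID order, defines the positives at
each cutoff $K$; TPR and FPR are averaged across proteins per $K$ and the
AUROC is the trapezoid over the averaged points with (0,0)/(1,1) anchors.
Averaging across proteins (rather than pooling) matches the stated
"average prediction performance over all testing proteins".

## The synthetic generator

The generator plants exactly the structure the method exploits: complexes
partition the proteome (an overlap option exists, default off), intra-complex
edges appear with probability `p_intra` and background edges with
`p_background`, each complex plants `domains_per_complex` domains and
`terms_per_complex` terms on its members, with `domain_leakage` rerouting a
domain assignment to a random protein and `term_noise` replacing an
annotation by a uniform random term. Leftover proteins receive only
background edges and noise annotations, exercising the empty-membership
path. A single seeded random stream drives everything, so a seed determines
the dataset down to file bytes.

Planted domains and terms are handed out as disjoint blocks of a shuffled
pool whenever the pool is large enough, so every planted feature has the
same baseline popularity. This matters for the permutation-null calibration:
with heterogeneous term popularity a frequency-counting ranker scores above
0.5 AUROC against shuffled labels (popular terms are both ranked higher and
likelier to sit in any truth set), which would make the null uninformative.

Defaults (120 proteins, 24 complexes of 3–6 members, 48 domains at 2 per
complex, 72 terms at 3 per complex, `p_intra` 0.9, `p_background` 0.01,
leakage 0.05, term noise 0.1) are a scaled-down analogue of the yeast-scale
inputs the method targets (thousands of proteins, ~400 complexes averaging
3–4 members, ~900 domain types, hundreds of terms). The evaluation-scale
suites use 20–160 proteins so the full LOOCV-with-ROC cycle runs in seconds.

What the generator does **not** emulate: scale-free degree distributions,
realistic complex-size and domain-popularity tails, annotation
incompleteness bias, or inter-term correlation from the GO hierarchy (terms
are flat labels throughout). Passing the planted-signal suites therefore
shows the machinery is correct and that the method recovers the structure
it assumes — not that it attains any particular accuracy on real yeast data.

One subtlety of small synthetic scales: under a permutation null, a hidden
protein's terms each lose exactly one of their $m$ carriers, and when all
complexes have the same size the low-score tier of the ranking degenerates
to carrier counting, detectably *anti*-ranking the held-out truth (null
AUROC well below 0.5). The null-calibration suite therefore uses dispersed
complex sizes (4–12, as real catalogs have), which makes the one-carrier
shift undetectable; at realistic carrier counts the effect is negligible
anyway.

## Known limitations

- Terms are flat labels; no ontology-hierarchy propagation or semantic
  similarity.
- The domain-similarity formula ignores cross-list relationships by
  construction (see above); this is faithful, not fixable here.
- Whole-matrix construction is dense in the number of domains; fine for
  thousands of domains, not engineered beyond that.
- The published headline accuracies on the yeast BioGRID/CYC2008/PFAM/GO
  inputs require those external downloads and are out of scope; readers for
  all four formats are provided.
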