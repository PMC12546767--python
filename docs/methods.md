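# Methods

## The model

`pocketrank` predicts protein–ligand binding affinity by embedding binding
pockets and ligands into one d-dimensional space and scoring every pair by
cosine similarity, `sim(p, l) = ⟨p̂, l̂⟩`.  Two encoders `E_p` and `E_l`
(independent trainable maps sharing only the output dimension) produce the
embeddings.  The reference encoders are linear maps or small one-hidden-layer
MLPs over simple features — latent factors for synthetic entities, hashed
Morgan count fingerprints (radius 2, 512 bits) for SMILES ligands, residue
composition plus hashed 2-mer counts for pocket sequences.  The encoder
contract is deliberately narrow so that heavier 3D encoders can be plugged in
without touching the objectives or workflows.

Training data are organised by **assay**: one experimental protocol, one
protein target, several measured ligands.  Affinity values are comparable
only within an assay (protocols, measurement kinds and units differ across
assays), which motivates the two training signals:

**Pharmacophore ranking (listwise).**  Within each assay the ligands are
ordered best-first on a canonical potency scale (p-scale, −log10 molar;
larger = stronger).  The observed order is modelled as a Plackett–Luce
sequential selection: at step k the k-th ranked ligand is drawn by a
temperature softmax over the candidate set of ligands no stronger than it,

    π(l_k | L^{≤k}, p) = exp(sim(p, l_k)/τ) / Σ_{j ∈ L^{≤k}} exp(sim(p, l_j)/τ),

and the per-assay loss is the decayed negative log-likelihood

    L_r = Σ_k μ_k · (−log π(l_k | L^{≤k}, p)),   μ_k = 1 / (|L| · ln(k+1)).

The `1/ln(k+1)` factor prioritises the top of the ranking; `1/|L|` stops
large assays from dominating.  Natural logarithms are used throughout (the
base is a convention; likelihoods make `ln` the natural choice).  The loss
depends on the order only, so it is invariant under any strictly monotone
transform of the measured values — exactly the property needed when assays
report in different units.

**Scaffold discrimination (contrastive).**  Pairs with a measured affinity
≤ 10 μM are positives.  For each active ligand of each assay, an in-batch
softmax contrasts its pocket against the batch's ligands (and symmetrically
its ligand against the batch's pockets):

    L_c = (1/|A|) Σ_i γ_i (L_i^{p→l} + L_i^{l→p}),   γ_i = 1/|L_i|,

with each direction normalised by the assay's active count `|L_i^a|`.
Cross-assay pairs whose assays share a protein target group (a UniProt-like
key) are excluded from the negatives: two assays on the same protein are
likely to share active ligands, so such pairs are potential false negatives.
The printed form of the pocket→ligand sum is ambiguous about whether
inactive ligands of the assay contribute numerator terms; this implementation
sums over active ligands only, since an inactive ligand has no positive
pocket pairing (the alternative is a one-line change).

**Pre-training** minimises `L = L_c + L_r` (unit weights) by Adam over
batches of assays; each step samples one pocket structure variant per assay
and a ligand subset.  The regression ablation (`regression_baseline_loss`)
replaces both terms with an affine-calibrated MSE against absolute potency;
it is undefined for percent-unit assays, which is the point of the ranking
formulation.

## Units and labels

Molar units (nM…M) convert to the p-scale exactly.  Density units (μg/mL)
get a p-scale on g/L that supports within-assay ranking but no absolute
activity label (the molar threshold is undefined without a molecular
weight).  Percent inhibition is **rank-only**: ordering is preserved
(higher % = stronger), no absolute scale exists, and percent assays never
produce active/inactive labels.  The 10 μM activity boundary is inclusive
(≤).  Rows with qualified relations ("<", ">") are dropped with a warning.
Ties in measured values form explicit tie groups, serialised stably by
ligand id; the ranking loss keeps tied ligands in each other's candidate
sets, so exact invariance to tie serialisation is only claimed for strict
orders.

## Knowledge-graph pocket refinement

A directed heterogeneous graph holds ligand→pocket edges for measured-active
pairs and pocket→pocket edges where the BLOSUM50 global alignment score
(scikit-bio backend; gap open 11, extend 1 — the matrix is prescribed, the
penalties are a standard protein default) exceeds half of the target
pocket's self-alignment score.  The criterion is asymmetric: B→A can exist
without A→B.  A query pocket embedding is refined by

    p* = γ₁·p_lig + γ₂·p_poc + (1 − γ₁ − γ₂)·p,

where `p_poc` attends over in-neighbour pocket embeddings, `p_lig` attends
over 2-hop ligand neighbours (each ligand passed through a 2-layer MLP Φ
together with a relation embedding — the connecting alignment score,
self-normalised and bucketised into 8 learned bins), and (γ₁, γ₂) live on
the simplex via a 3-way softmax over logits.  Multi-path ligands are
deduplicated keeping the best-scoring path; 2-hop sets are capped at 64
ligands, score-ranked.  Empty neighbour sets fall back to the query
embedding, so refinement on an empty graph is the identity — cold-start
pockets are never corrupted.

H-GNN parameters are trained post hoc with the encoders frozen: each step
picks a pocket, perturbs its embedding (Gaussian noise at half the mean
embedding norm) to emulate an unseen structure variant, refines it through
the graph, and asks it to retrieve its own active ligands with a softmax
cross-entropy against sampled negatives.  Φ is initialised as an exact
pass-through of the ligand part (paired-ReLU identity), so an untrained
refinement already lives in the ligand embedding space.

## Synthetic worlds

The generator manufactures the data shapes the method assumes, with a known
ground truth.  True potency is a noisy low-rank bilinear form:

    potency(p, l) = a + b·⟨pocket_factor_p, ligand_factor_l⟩ + ε,

with ligand factors unit-normalised (so the landscape is realisable by a
cosine-scoring model — within a pocket, inner-product order equals cosine
order), pocket factors at fixed norm √d, gain b = 2 p-units per unit inner
product, and the intercept a calibrated empirically so a configured fraction
of all pairs sits above the 10 μM boundary.  Noise ε (default 0) is frozen
into the oracle at generation, keeping it deterministic per seed.

On top of the landscape:

- **Assays** draw one pocket and a ligand subset and push oracle potency
  through an assay-specific strictly monotone unit transform — exact
  inversion for molar/density units, a random increasing piecewise-linear
  map onto [0, 100] for percent.  Each assay lists 1–3 pocket *variants*
  (small factor perturbations, sd 0.05, sharing the parent's landscape),
  and each parent pocket carries a random 40-mer sequence whose variants
  differ by 2 point mutations, so alignment-based graph construction works
  at small scale.
- **Screening libraries** rejection-sample fresh unit-norm ligands into
  n actives (potency ≥ boundary) and n×ratio decoys, optionally restricted
  to scaffold clusters absent among the actives.
- **Congeneric series** perturb one active parent ligand (component sd
  0.08, keeping pairwise feature cosines above 0.8) into 29 analogues in
  one scaffold cluster, reported in nM.
- **Scaffold clusters** are seeded k-means partitions of ligand factors;
  scaffold-disjoint splits are cluster-disjoint splits.

What the generator does **not** emulate: real chemistry (no conformers, no
synthesizability), assay-type ontologies, correlated experimental error,
activity cliffs sharper than the bilinear model allows.  Passing tests on
these worlds show the objectives, workflows and metrics behave as designed
when their assumptions hold; they say nothing about accuracy on real
screening decks.

## Numerical core

No autodiff framework is part of the dependency set; the package carries a
small reverse-mode engine (`_autodiff.py`) over numpy — the dozen operations
the losses need (matmul, broadcasting arithmetic, relu/tanh/exp/log/sqrt,
reductions, concat, stable logsumexp with a detached max shift) plus Adam.
Gradients are validated against central finite differences in the tests.
Row normalisation adds 1e-12 inside the square root so gradients stay
finite at the origin; masked softmax entries use an additive −1e30 rather
than −∞ to avoid NaN in fully-masked corner cases.

## Key parameters

| parameter | default | notes |
| --- | --- | --- |
| temperature τ (both losses) | 0.07 | common contrastive-learning scale; configurable per loss |
| embedding dim d | 16 (128 for MLP encoders) | desk-scale default; reference experiments use d = latent dim with linear encoders |
| activity boundary | 10 μM, inclusive | applied to molar units only |
| BEDROC α | 80.5 | early-recognition weight |
| EF fraction | 1% | top set size is ceil(fraction·N) |
| pre-training | 300–500 steps, 8 assays × ≤10 ligands per step, Adam lr 0.05 | deterministic given seed |
| fine-tuning | 150 steps, Adam lr 0.005, L2 anchor 2.0/|support| to the pre-trained weights | anchoring keeps tiny supports from erasing pre-trained structure |
| H-GNN | d_h = 2d, 300 steps, query noise 0.5 | trained post hoc, encoders frozen |
| pocket radius | 6.0 Å heavy-atom | pocket extraction from PDB; configurable |
| AL ε-schedule | 0.5 → 0.1 linear | exploration picks spread over unsampled scaffold clusters |

## Evaluation metrics

EF k% is `(active rate in top ⌈kN⌉) / (overall active rate)` — ceil, because
the top set must be nonempty at small fractions.  BEDROC uses the
Truchon–Bayly closed form (exponential sum over active ranks, RIE-normalised,
min–max rescaled); the implementation is checked against an independent
reference implementation and against analytic best/worst/random values.
r² is reported as squared Pearson correlation, the convention of the
relative binding free energy benchmark literature (a
coefficient-of-determination variant sits behind a flag).  Score ties are
broken stably by ligand id before any rank metric, since EF at 1% is
tie-sensitive.  Spearman uses average ranks on ties.

## Active learning

Campaigns are seeded and deterministic: a random seed batch, then per
iteration retrain-from-scratch (determinism; warm start behind a flag),
score the pool, acquire greedily or by ε-greedy exploration–exploitation
(ε decaying 0.5 → 0.1; exploration picks drawn from scaffold clusters not
yet sampled — the acquisition rule is the package's own concrete choice of
a qualitative strategy), label, record top-k% recall and r² against the
oracle.  The analytic null for recall is the labeled fraction (mean of the
hypergeometric overlap).  Surrogates: fine-tuned embedding model, or
fingerprint-feature baselines (linear regression, random forest, gradient
boosting).

## Problem sizes

Reference experiments are sized for a single CPU: worlds of 10–20 pockets ×
250–5,000 ligands in 8 latent dimensions, 20 assays × 15 ligands for
pre-training (300–500 steps), 1,005-ligand screening libraries (1:200),
29-ligand series, 5,000-ligand AL pools with 1% batches over 5 iterations ×
20 seeds.  These sizes make the whole pipeline — including the acceptance
script — reproducible in minutes while keeping every statistical property
testable.

## Known limitations

- The reference encoders cannot represent geometry; with real 3D encoders
  the same objectives apply but none of the synthetic-world guarantees
  carry over.
- The contrastive loss excludes *all* same-target cross-assay pairs from
  negatives, including measured inactives (conservative; matches the
  false-negative rationale, loses some true negatives).
- Tie-heavy assays (many equal reported values) make the Plackett–Luce
  factorisation only approximately invariant to tie serialisation.
- The H-GNN training procedure (post hoc, frozen encoders, noisy-query
  retrieval) is one defensible choice among several; joint training is not
  implemented.
- Density-unit assays contribute rankings but never labels; whether that
  matches common curation practice is an open question.
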