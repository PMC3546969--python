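# Methods

## Model and assumptions

Sites evolve independently under a time-reversible, time-homogeneous
Markov substitution model in its stationary state. Under reversibility
the likelihood of an alignment column is invariant to where the
traversal root is placed (pulley principle), so trees are stored
unrooted with an arbitrary reference root; a bifurcating Newick root is
suppressed on input and its two edges merged, giving N_b = 2N − 3
branches for N leaves. Rate matrices are normalised to one expected
substitution per site per unit branch length, so branch lengths are in
substitutions/site.

Two model constructions are available:

* **Amino-acid GTR** — `Q_ab = s_ab π_b` from a symmetric
  exchangeability matrix and stationary frequencies. The default
  pipeline model is the uniform-exchangeability (Poisson) variant with
  uniform or empirical frequencies; substitution mapping is known to be
  robust to the input model, and any exchangeability table can be
  supplied as TSV.
* **Mechanistic codon model** — codon rates are a nucleotide-level
  mutation term (GTR nucleotide exchangeabilities; multi-nucleotide
  changes within a codon scaled by ρ_multi^(d−1), so ρ_multi = 0 forbids
  them) times an amino-acid-level fixation factor h(β·w̄ + c), with w̄ a
  mean selective constraint per amino-acid replacement. The functional
  form of h is pluggable with default h(w) = exp(−w); the default w̄
  table is derived at run time from the BLOSUM62 log-odds matrix as half
  the dissimilarity ((s_aa + s_bb)/2 − s_ab)/2, clipped at zero, and can
  be replaced by any symmetric non-negative 20×20 table. Because the
  fixation factor is symmetric, the construction keeps the GTR form and
  is reversible by construction. ML fitting of the codon-model
  parameters is out of scope; parameters are inputs. For amino-acid
  data, equal codon usage converts amino-acid frequencies to codon
  frequencies.

Among-site rate variation uses the equal-probability discrete gamma
with mean-per-category rates (default 4 categories when a shape is
given; rate variation is off by default because the synthetic generator
evolves all sites at rate 1). Gaps and unknown residues (X/B/Z)
contribute all-ones conditional likelihoods (standard missing-data
treatment). Matrix exponentials use the eigendecomposition of the
symmetrised generator (real spectrum under reversibility), with
scipy's scaling-and-squaring as a fallback if the reconstruction is
non-finite.

## Substitution mapping

Per-site pruning retains the per-node conditional ("inside") arrays; a
second ("outside") pass computes, for every branch, the likelihood of
the data outside the child's subtree jointly with the parent-side
state. Their product with the branch transition matrix gives the joint
posterior of the branch's endpoint states, marginalised over rate
categories with the per-site category posteriors. Contracting that
joint with a characteristic change g_x(a → c) yields the posterior-mean
change v_x(site, branch). Per-node scaling keeps 200+-leaf columns away
from underflow. Correctness is pinned by brute-force enumeration over
internal-node states on ≤ 5-leaf trees (1e-10).

The twelve characteristic channels are the substitution indicator and
signed differences prop(to) − prop(from) of: volume, charge,
hydrogen-bonding capability (acceptor + donor combined into one scalar;
the sub-channels are also exposed), hydrophobicity, β-sheet propensity,
turn propensity, α-helix propensity, and the aromatic, branched,
cross-link and ionic class indicators. The class memberships (hydrogen
bond acceptors/donors, aromatic = his/phe/trp/tyr, branched =
ile/leu/val, cross-link = asn/gln/ser/thr, ionic = asp/glu/arg/lys at 1
and his at 0.1) are fixed; the numeric scales ship as a documented TSV
(Zamyatnin mean residue volumes, Kyte–Doolittle hydropathy, Chou–Fasman
propensities) and are user-overridable, as is the histidine charge
(default +0.5). Under a codon model g_x acts on the encoded amino
acids, so synonymous changes contribute nothing.

## Branch-length estimation

Coordinate-wise maximisation: for one branch at a time the inside and
outside arrays around it are recomputed, making the single-branch
profile likelihood an exact one-dimensional function, which is
maximised by bounded Brent after bracketing on a 25-point geometric
grid (the profile is flat to machine precision at large lengths, which
defeats plain golden-section search). Lengths are bounded to
[1e-8, 50]; cycling stops when a full cycle improves the total
log-likelihood by less than 1e-6 (at least one cycle, at most 20). The
2-state analytic MLE and the ascent property are tested.

## Scoring

Pearson coefficients are computed on centered vectors (uncentered
cosine available for audit); sites with zero vector variance are marked
degenerate and removed before inversion. The correlation matrix is
inverted directly when it is square-regular (more branches than sites,
condition number < 1e10); otherwise a ridge of 1e-6 is added, or the
pseudo-inverse used when ridge = 0. The partial correlations equal the
residual-regression definition (correlate the two sites' vectors after
projecting out all other sites' vectors) to 1e-8, which is the module's
central tested property.

Significance: a Pearson coefficient under the null satisfies
t = r√(df/(1−r²)) with df = N_b − 2; the threshold r_thr solves this at
the two-sided tail p = E / N_pairs with default E = 0.01.

Component scores: ζ_sub = max(0, R_sub); ζ_x = √(ζ_sub · s(R_x)) with
the sign rules: negative direction for volume, charge, hydrogen
bonding; positive for cross-link and ionic; both for hydrophobicity,
β-sheet and turn propensity, aromatic and branched. α-helix propensity
is computed and reported but not part of the overall score. The overall
combiner is the maximum of ζ_sub and the included components — each
component is already damped by ζ_sub through the geometric mean, so the
maximum preserves the per-component precision logic while keeping ζ in
[0, 1]; a clipped sum is available behind `combiner="sum"` for
sensitivity analysis. Filters: pairs involving the first or last
alignment column fall back to ζ_sub (terminal columns are alignment
artefact-prone); a site with more than 15 partners above r_thr is
excluded as anomalous; invariant columns (fewer than two observed
residues) are excluded by an explicit alignment-derived mask — their
substitution vectors are *almost* zero but retain a small posterior
mass on deep branches, so a variance test alone would not catch them.
Ranking is by ζ descending with a total tie-break order (ζ_sub, then
smaller i, then j), restricted to pairs ≥ 6 positions apart.

## Contact evaluation

Contacts are residue pairs with minimum heavy-atom distance strictly
below 5 Å (hydrogens excluded; the atom subset is configurable) and
sequence separation ≥ 6. PPV = TP/(TP+FP) over the top-k predictions;
MDPNT / MDTNP are mean Euclidean distances in the (i, j) index plane
from predictions to nearest true contact and from true contacts to
nearest prediction, both canonicalised to i < j. Structure residues are
matched to sites by 1-based target-sequence position; unresolved
residues drop out of both sets.

## Synthetic data generator

The generator defines the package's study conditions: a Yule
(pure-birth) tree via dendropy with default birth rate 12.0, chosen so
that 200-leaf trees have mean pairwise divergence ≈ 0.7
substitutions/site (the informative-diversity band 0.5–1.0); uncoupled
sites evolve under the base model; each coupled pair evolves as a
single 400-state reversible Markov process with stationary law
π(a)π(b)·exp(−β_c·φ(a, b)). The default compensatory potential is
φ = |q_a + q_b| + |z_a + z_b| with q the side-chain charge and z the
volume standardised under the base frequencies, i.e. charge
complementarity plus volume-sum conservation; a charge-only variant is
provided.

The pair process combines single-site moves (which reduce *exactly* to
two independent copies of the base process at β_c = 0 — the Kronecker-sum
identity is tested) with a concerted double-substitution channel:
product of the base exchangeabilities, weight ρ_pair = 1, gated by
1 − exp(−β_c·m) where m is the smaller potential penalty of the two
sequential intermediates. The gate encodes the biology being emulated —
a compensating mutation fixes on a timescale far shorter than a branch,
so a compensated change appears on the tree as both sites substituting
in the same branch, and the concerted channel only opens where the
stepwise path is blocked. It vanishes at β_c = 0, keeping the
decoupling limit exact. The process is normalised to one expected
substitution per site (two per pair), the same convention as every
single-site model: coupling shapes *which* substitutions occur, not how
many. Without this normalisation β_c = 5 freezes coupled sites almost
completely. Sampling is exact: root states from the stationary law,
endpoint states from spectral transition matrices edge by edge; no path
simulation is needed since only endpoint states are observed.

What the generator does *not* emulate: indels and alignment error, rate
heterotachy, sequence redundancy/weighting structure, multi-site (>2)
couplings, and real structural context beyond the planted-pair toy
contact map. Passing the recovery benchmark therefore shows the
inference machinery is sound at realistic divergence and family size,
not that real families reach the same accuracy.

## Benchmark configurations

* **Recovery**: 200 leaves, 50 sites, 8 planted pairs at β_c = 5,
  replicate seeds; top-8 predictions scored against the planted pairs.
  The benchmark runs on the generating branch lengths — re-estimating
  them is validated separately (analytic 2-state MLE, ascent tests) and
  adds nothing to a study where the true lengths are known.
* **Phylogenetic-correlation removal**: 200 leaves, 50 sites, no
  coupling, on deep Yule trees (birth rate 3.0, mean divergence ≈ 2.5)
  — the distant-homolog regime where branch-length heterogeneity makes
  raw Pearson substitution-probability correlations spuriously
  significant across many pairs; partial correlations push the
  significant fraction back to near the null rate (observed ratio
  ≈ 80–100×). At shallow divergence the phenomenon itself is weak, so
  the demonstration uses the deep regime; the recovery benchmark keeps
  the default one.

## Numerical choices and degenerate inputs

Detailed balance, row sums and normalisation are asserted at model
construction (1e-10/1e-12). Transition-matrix entries are clipped at
zero (eigendecomposition round-off). Missing branch lengths default to
0.1 with a warning. Two-leaf trees root at a leaf, giving the single
connecting branch. OTU pruning removes the shortest sub-threshold
pendant branch first and re-measures after every suppression, never
removes protected leaves, and refuses to go below 4 leaves. Column
masking keeps exactly the target's residue columns; reports use 1-based
target positions. Ties in ranking break deterministically; pipeline
outputs are byte-identical across reruns with fixed inputs and seed.

## Known limitations

Partial correlations remove only *linear* multiple dependences;
couplings mediated nonlinearly or through unmodelled partners (ligands,
oligomer interfaces) remain confounded. The Gaussian graphical reading
of the inverse correlation matrix requires N_b comfortably above the
number of sites; below that the ridge/pseudo-inverse fallback loses the
exact residual-regression equivalence. The hub-exclusion and
terminal-site rules use one fixed tier each (configurable), and the
overall-score combiner is a design choice validated on synthetic data
only.
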