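# Methods

This note documents the models, the numerical choices, and what the
synthetic-data generator does and does not establish.

## Units and coordinates

Native residue positions are 1-based indices into the canonical protein
sequence; alignment columns are 1-based; intervals are closed. Areas are Å²,
distances Å. All probabilities are on (0, 1).

## MAP construction

A modified alignment position (MAP) is one column of a family multiple
sequence alignment carrying ≥ 1 experimentally observed PTM from any member.
Projection is exact: a member's native position maps to the column where that
residue lands after gapping, and by construction can never land on a gap in
the member's own row. PTM table rows whose residue disagrees with the
canonical sequence, or that are flagged putative, are rejected and counted —
never silently kept.

**Conservation.** The upstream definition this feature descends from is not
restated in our sources, so the package defines it as: the fraction of family
members whose residue at the column matches *any* amino-acid identity
observed modified at that MAP, with gapped members counted in the
denominator. This is deterministic, bounded in (0, 1], and reduces to plain
fraction-identity when only one modified identity exists. It is an
interpretation; treat cross-dataset comparisons of the raw value with care.

**Neighbor features.** NC counts other MAPs of the same family within ± 2
columns (configurable window); NKC counts the known-function subset of those.
A MAP never counts toward its own neighborhood. Families are processed
independently; MAPs of overlapping families are never pooled.

**Labels.** A MAP is known-function iff any member observation is. The MAP's
known-function source count (KFSC) is the **maximum** source count over its
known observations — an aggregation the sources leave open; max preserves
"confidence of the best-supported observation". Bins are 1, 2, 3, 4, 5–10,
11+ with closed bounds.

## Structure features

**Chain qualification.** Only x-ray chains with **strictly more than 50**
resolved standard residues qualify. The resolved one-letter sequence, split
at residue-numbering discontinuities, must occur verbatim (leftmost, ordered,
non-overlapping) in the canonical sequence; any internal insertion or
substitution — the chimera signature — rejects the whole chain. Exact block
matching was chosen over scored alignment because the filter is binary and
exact matching is deterministic.

**SASA.** Shrake–Rupley with probe 1.4 Å, 960 test points per atom on a
deterministic golden-spiral lattice, Bondi-style van der Waals radii
(C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, H 1.20, Se 1.90; unknown elements
fall back to 1.70 with a warning). Coordinates are first expressed in a
molecule-intrinsic frame (principal axes, signs fixed by third moments) so
the result is invariant under rigid motion of the input to machine precision.
Convergence: doubling the lattice twice moves a 50-atom chain total by < 1%.
Absolute values differ from coarse-grained calculators used elsewhere; all
downstream use is feature/rank-based, so this changes calibration, not
semantics.

**Disorder fallback.** Per residue: resolved anywhere → mean SASA across
qualifying chains; unresolved and disorder tendency > 0.5 → the protein's
maximal observed per-residue SASA (a deliberately generous stand-in for a
fully exposed disordered residue); unresolved and tendency ≤ 0.5 → missing.
The mean-across-chains / max-for-fallback scheme is an interpretation of an
unspecified aggregation and is configurable.

**Interfaces.** A residue is interface-flagged iff any of its heavy atoms is
within 5.0 Å (configurable) of a heavy atom of a *different* chain of the
same structure — a geometric replacement for an external interface database.
MAP-level PPI is the fraction of structurally covered member residues that
are flagged; whether the original analysis used a binary or fractional PPI is
unstated, and the fraction degrades gracefully to binary for single-member
MAPs.

**Missing SASA.** MAPs with no structural coverage and no disorder fallback
keep a missing SASA in tables but enter the model as 0. This keeps the
six-feature vector dense; with inputs standardised on the training partition,
0 acts as "no structural evidence" rather than "buried".

## Models

Single-feature baselines are maximum-likelihood univariate logistic fits
(unpenalised; on suspected separation the fit falls back to a small ridge,
C = 10³, with a warning).

The network is 6 → 3 (tanh) → 1 (logistic). Training minimises cross-entropy
plus an L2 penalty of 1e-3 on the weight matrices (not biases) by full-batch
L-BFGS from a seed-controlled N(0, 0.5²) initialisation; inputs are
standardised on the training partition. A random 33% holdback is drawn once
(re-drawn up to 10 times if either partition lacks a class) and used for
validation ROC. Identical data and seed give bit-identical parameters. The
upstream training environment (optimiser, penalty, epochs) was unreported;
these choices are recorded in the model's JSON metadata.

AUC is the Mann–Whitney rank statistic (ties ½), identical to the area under
the threshold-sweep curve. AUC comparisons use DeLong's paired covariance:
the statistic (AUC₁ − AUC₂)²/Var(diff) is referred to χ²(1) — realising an
otherwise unspecified "chi-square comparison" of AUCs. The PTM-count
threshold sweep restricts to MAPs with PC ≤ t for t = 1..10, refits every
single-feature model and retrains the network per restriction. Per-KFSC-bin
AUC uses the bin's known MAPs as positives against all unknown MAPs.

## Hotspots, enrichment, variants

The hotspot threshold is the largest score with ≥ 90% of KFSC ≥ 11 MAPs at or
above it: with n sorted scores, the ⌊n(1 − 0.9)⌋-th order statistic (lower
interpolation, so the coverage contract holds exactly; an epsilon guards
binary-representation artefacts like 10 × 0.1 → 0.999…). Fewer than 10 such
MAPs is an error — the pipeline then falls back to the conventional default
0.196 with a warning.

Enrichment above a threshold t: observed = |subset ∧ score ≥ t|, expected =
|subset| · P(score ≥ t) under independence; the ratio is undefined when the
expectation is 0. Note the ratio is bounded by 1/P(score ≥ t).

Variants join MAPs by exact alignment-column match only; a variant at an
observed PTM site of the same protein is Type-1, otherwise Type-2 — the
classes are disjoint and exhaust the matches. Near-misses (adjacent columns)
are not counted as coincident. Pathogenic pools {pathogenic,
likely_pathogenic}, benign pools {benign, likely_benign}; "other" significance
is retained in joins but excluded from enrichment summaries.

## Coincidence networks

MAPs with ≥ 2 distinct PTM types form the coincident set; each MAP
contributes all C(k, 2) type pairs. Node occurrence counts coincident MAPs
containing the type; relative edge count = edge count / (occurrence(a) +
occurrence(b)), which compares pairs without bias toward abundant types; any
display scaling is cosmetic and excluded from analysis. Edges are typical
when the packaged residue-compatibility table (phospho S/T/Y; ubiquitin,
SUMO, NEDD, acetyl, succinyl K; methyl K/R; citrulline R; N-glyco N; O-glyco
S/T; hydroxy P/K; nitrosyl, palmitoyl, prenyl, disulfide C; myristoyl G —
user-overridable) gives intersecting residue sets. Outliers per
typical/atypical group use Tukey's upper fence Q3 + 1.5·IQR with linearly
interpolated quartiles; groups under 4 values are undefined.

## The synthetic world

The generator emulates the statistical shape of the real inputs, not their
biology:

- families of 2–360 members drawn from a geometric tail (mean ≈ 8 — most
  families are small), root sequences from eukaryotic-like residue
  frequencies, i.i.d. substitutions plus per-member deletions, so ungapping a
  row always reproduces the canonical sequence;
- PTMs at density 0.04/residue placed only on chemically compatible residues,
  with a type mix dominated by phosphorylation (61%) over ubiquitination,
  acetylation, glycosylation and others;
- known-function labels Bernoulli with log-odds linear in the standardised
  features, intercept −2.7 (≈ 6% positives, the observed class imbalance);
  the neighbor-known term accumulates sequentially in column order so
  positives cluster; KFSC is geometric on 1..68 plus a Poisson bonus
  increasing with the linear predictor, so high-KFSC MAPs score high;
- structures are idealised helical backbone + Cβ traces over a covered
  subrange (coverage 0.6–0.95), residue numbering equal to native positions;
  half the structures carry a docked partner chain translated to ~4 Å closest
  approach to create interfaces;
- variants at density 0.02/residue, half pathogenic with placement weight
  exp(2·z(score)) toward high-scoring MAPs and a 25% chance of sitting
  exactly on an observed PTM site (the ~1:3 Type-1:Type-2 regime), half
  benign placed uniformly.

All randomness flows from one seed through named substreams (CRC-keyed
`SeedSequence` children), so adding families never perturbs earlier ones and
identical config + seed reproduces files byte-for-byte.

What a green test does **not** establish: real protein folds (helical toys
have no buried cores, so absolute SASA distributions are unrealistically
high); evolutionary correlation structure (substitutions are i.i.d., so
conservation carries weaker signal than in real families); database-scale
class counts; or a benign-variant *depletion* trend — benign placement is
uniform, which yields a flat enrichment near 1 rather than the decreasing
trend real clinical data show (the decreasing pattern is exercised separately
with a score-avoiding subset).

## Degenerate inputs and edge behaviour

- No structure inputs: the pipeline runs in alignment-only mode (SASA
  missing, PPI 0) with a prominent warning.
- Constant feature: logistic fit returns slope 0 → AUC 0.5 rather than
  failing.
- Single-class labels: ROC and fits raise; training re-draws the holdback up
  to 10 times before raising.
- Fewer than 200 samples: network training refuses (too little data for a
  33% holdback to mean anything).
- Empty PTM table: empty MAP list, with a warning.

## Known limitations

- One canonical sequence per protein identifier; isoforms are out of scope.
- mmCIF and NMR structures are not parsed; PDB-format x-ray chains only.
- The conservation definition and the SASA aggregation scheme are documented
  interpretations (see above), not reproductions of an external tool.
- The coincidence analysis tabulates an alternative (e.g. zero-gap-penalty)
  alignment if supplied, but does not compute alignments itself.
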