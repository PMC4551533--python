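# Methods

## Read processing

Reads are treated as amplicons: the forward primer is anchored at
position 0, the reverse primer is scanned left to right after it and the
leftmost acceptable hit wins. Each primer tolerates up to
`floor(0.05 × primer length)` substitutions — one substitution for the
20-nt primers used here — and no insertions or deletions. `N` never
matches anything and so counts against the budget; regions containing `N`
after trimming are kept and treated as ordinary symbols downstream.
Reads failing either primer match are dropped (both primers must be
found). Everything from the reverse-primer hit onward, sequencing
adaptors included, is discarded, which is what makes the pipeline immune
to adaptor read-through. Regions outside 25 ± 2 nt are rejected. Base
qualities are parsed but never used: no quality filter is applied
anywhere in the pipeline.

Duplication of a pool is reported by default as
`100 × (total − unique) / total` (the FastQC-style fraction of reads that
are duplicates); the alternative reading "duplicates relative to unique",
`100 × (total − unique) / unique`, is available as a mode. Both are exact
functions of (total, unique); which convention produced any given
published table generally cannot be determined without the raw data, so
both are exposed.

## Fold enrichment

Enrichment of sequence *s* from reference round *r* (default: the
unselected library R0) to target round *t* is

    FE(s) = (c_t(s) / T_t) / (max(c_r(s), p) / T_r)

with counts `c`, pool depths `T`, and pseudocount `p = 1` read applied
only when the sequence is absent from the reference pool. The
pseudocount keeps enrichment finite while preserving the ordering among
observed sequences; it makes `FE` a lower bound for sequences the
reference pool simply failed to sample. Enrichment is computed on random
regions only — the primer regions are identical across all sequences and
carry no selection signal. Ranking sorts by enrichment descending with
ties broken by larger target count, then lexicographically, so results
are independent of input order. A consecutive-round analysis
(R_{k−1} → R_k) is available by passing any pool as the reference.

## Alignment identity and clustering

Identity between two sequences is `matches / alignment columns` of an
optimal global (end-to-end) Needleman–Wunsch alignment under match +1,
mismatch −1, gap −2 (linear). Gap columns are included in the
denominator; an alternative convention (divide by the shorter sequence
length) exists in clustering tools but is not used here. Among
score-optimal alignments the tie is broken deterministically: maximize
matched columns, then minimize gap columns. The DP optimizes this
lexicographic objective directly by encoding (score, matches, −gaps) in a
single integer with non-overlapping ranges; the kernel is JIT-compiled
and exact — no banding, no word-filter heuristics. Because identity (not
score) is thresholded, cluster verdicts are insensitive to moderate
changes of the score parameters; the tests assert this away from the
exact threshold boundary.

Clustering is a single greedy scan in count-descending order (ties
lexicographic): the first sequence seeds cluster 1, each later sequence
joins the highest-identity representative if that identity is ≥ 0.8
(ties: lowest cluster id) and otherwise seeds a new cluster. This is the
classic greedy incremental scheme; representatives are only guaranteed
pairwise-unmergeable under the scan order, not globally optimal.
Clustering runs on sequences with primers re-attached; homolog search
(below) runs on bare random regions, because the former asks about
whole-amplicon families while the latter asks whether the variable region
pre-existed in the library.

## Candidate screening

Candidates are annotated, never auto-deleted — in-silico filtering is a
reported decision, so each row carries booleans rather than being
dropped. A sequence is "in the negative pools" if it reaches a count
floor (default 1 read) in any counter-selection pool; the floor is
configurable because deep sequencing scatters singletons of everything
everywhere. A library homolog is any unselected-library sequence at ≥ 5
counts with identity strictly greater than 0.85. Parasites are sequences
reaching an abundance floor (default 10 reads) in at least one positive
and at least one negative pool: enrichment without selectivity is the
signature of amplification/collection artifacts. External
binding-potential Z-scores can be joined by sequence as a passive
annotation column.

## Binding model

Both assays share the quadratic mass-action isotherm. With total aptamer
`A` (constant), total protein `T` (varied) and dissociation constant
`Kd`, the complex concentration is

    [AT] = 0.5 · (A + T + Kd − √((A + T + Kd)² − 4·A·T))

(discriminant clamped at zero against round-off), and the signal is

    signal = constant / (1 + Kd / (T + [AT]))

This denominator form, `T + [AT]`, is implemented exactly as the assay
software's fitting equation uses it; it differs from the more
conventional bound-fraction form `constant · [AT] / A`, which is provided
as an alternate mode for comparison but is never the default. At `T = 0`
the printed form is 0/0-adjacent; the signal is defined there as 0 by
continuity, which the tests check against the ε → 0 limit. In the dilute
limit `A → 0` both forms collapse to the Langmuir isotherm
`constant · T / (T + Kd)`.

Fitting is unweighted nonlinear least squares over individual replicate
points (no replicate averaging), with `Kd` parameterized on the log scale
to enforce positivity. Initial values: `Kd₀` = median nonzero
concentration, `constant₀` = maximum observed signal. Standard errors
come from the Gauss–Newton curvature at the optimum, with the delta
method mapping log-K_d uncertainty back to the K_d scale. All-zero
signals raise an unidentifiability error; a K_d far above the titration
ceiling converges but with enormous (often non-finite) standard errors,
which is the honest answer for such designs. The Avogadro constant is
fixed at 6.02214076 × 10²³ for the library-combinatorics calculations.

## Simulator

The simulator reproduces the observable signatures of a CE-based
selection without modeling the wet lab mechanistically. Selection is
multinomial resampling: in each round every sequence gets a capture
weight

    w = capture_efficiency · bound_fraction(Kd_eff, [protein]) + carryover

with the bound fraction from the quadratic model at a nominal 10 nM DNA
concentration, and the next pool is a multinomial draw of exactly
`depth_per_round` reads from count-weighted `w`. `Kd_eff` is the
sequence's own K_d in positive rounds; in negative rounds planted binders
fall back to the background K_d (they have no affinity for the free tag).
Parasites bypass binding entirely: their weight is
`carryover × parasite_pcr_gain` in every round, which is what makes them
abundant in positive and negative pools alike. PCR bias is this single
multiplicative weight, not cycle-by-cycle amplification — sufficient to
produce parasites at a fraction of the cost.

Positive rounds chain; each negative round is sequenced as a side branch
off the current positive pool rather than being threaded into the chain.
Threading the literal counter-selection output forward would discard the
planted binders under the weight rule above, so the branch design keeps
the chain's selection dynamics while still producing realistic negative
pools (parasite-dominated, binders present only as a ~1% trickle of
carryover reads — which is why the negative-pool flag has a configurable
count floor).

Adaptor contamination is injected at sequencing time in **every** round
at a constant fraction of reads, not only into the library. This is
deliberate: it reproduces the empirical pattern of an adaptor-derived
sequence that tops the unselected library, persists through all rounds,
and shows fold enrichment ≈ 1 — the behavior of contamination introduced
during sequencing rather than selection.

Default study conditions (spelled out in `SimConfig`): 25-nt regions;
thymine-biased base probabilities (A 0.24, C 0.22, G 0.22, T 0.32),
reflecting the synthesis bias observed in ostensibly random libraries;
planted 8-nt motif `TGGTTGGT` (a G-quadruplex-like thrombin-aptamer core)
recognized with ≤ 1 mismatch, giving ~0.9% motif-bearing sequences in a
fresh library; K_d 10 nM for motif carriers vs 100 µM background; target
concentrations 50/10/5/1/0.5 nM over rounds, negative rounds at rounds 2
and 3 (50 nM tag); capture efficiency 0.3 and carryover 10⁻⁴, plausible
for collection windows in capillary separations; 5 parasites spiked at
0.1% each with gain 1000 (so their per-round weight ≈ 0.1, comparable to
a binder's); adaptor fraction 2%; depth 10⁵ reads/round. Depths are
kept at 10⁵ (analysis drivers: 2 × 10⁴) rather than the several-million
reads of a real Illumina run: the recovery properties of interest are
already stable at these depths and every run stays within seconds.

Simulated titrations add homoscedastic Gaussian noise with σ = 2% of the
saturating amplitude. Assay designs: APCE at A = 10 nM, 13 evenly spaced
concentrations 0–240 nM in triplicate (capillary injections are routinely
run in triplicate); anisotropy at A = 100 nM, 13 points 0–750 nM in
duplicate. The APCE condition with K_d = 390 nM is intentionally hard —
the dissociation constant lies 60% above the largest tested
concentration, so the median relative K_d error over 100 replicates sits
near 0.11–0.17 depending on the noise realization. That marginality is a
property of the design, not the estimator; the anisotropy condition
(K_d = 280 nM inside a 750 nM range, with ligand depletion sharpening the
curve) recovers K_d to ~4%.

## What the simulator does not capture

No sequencing-error model, chimera formation, or realistic quality
profiles; no paired-end structure or barcodes (demultiplexing happens
upstream in practice); no cycle-resolved PCR kinetics or by-product
formation; no secondary-structure-mediated biases. Consequently, tests
passing on simulated data demonstrate that the pipeline's logic is
correct and its thresholds behave as specified — they do not demonstrate
robustness to base-calling error or PCR chimeras in real data, where the
configurable count floors (negative-pool presence, parasite abundance,
homolog counts) are the intended defense.

## Numerical choices

- Alignment tie-breaks and all sort orders are fully deterministic, so
  every pipeline output is a pure function of (inputs, config, seed);
  reruns are byte-identical.
- Count ties sort lexicographically ascending; enrichment ties by target
  count then sequence.
- The quadratic's discriminant is clamped at 0; the fit terminates at
  relative tolerances of 1e-10 on parameters and residuals.
- Empty pools are errors wherever a statistic would be undefined
  (frequencies, duplication); empty inputs that have a natural value
  (deduplicating zero reads, clustering zero sequences) return empty
  results.
- Seeds: every stochastic routine takes a seed or NumPy `Generator`;
  library generation and all selection rounds consume a single generator
  stream so one integer reproduces an entire study bit-for-bit.
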