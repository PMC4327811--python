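# Methods

## Patterns and the match count N

A pattern P ∈ {0,1}^ℓ of weight k defines, at every window start i, the
spaced word S[i + P̂_1 − 1] … S[i + P̂_k − 1], the projection of the
window onto the match positions P̂. For a pattern set 𝒫 of m patterns
(all sharing ℓ and k), N(S1, S2, 𝒫) is the number of position pairs
(i, j) with a P-match, summed over P ∈ 𝒫 — equivalently the inner
product of the per-pattern spaced-word count vectors, which reduces to
the D2 score for a single contiguous pattern.

Counting projects every window to an integer code (2 bits per match
position, so weights up to 32 are supported), aggregates codes per
pattern with hash/sort primitives, and combines the two sequences'
count vectors: full mode sums products of occurrence counts, binary
mode counts distinct shared codes. Runtime is O((L1 + L2) · m · k);
the quadratic position-pair scan exists only as a guarded test oracle
(`brute_force_count`, refused above L1·L2 = 10⁷).

Canonical patterns start with a match position: a leading don't-care
only shifts every occurrence and would create duplicate-equivalent
patterns. Trailing don't-cares are allowed and change ℓ (hence the
fringe terms). Random pattern sets fix position 1 and draw the
remaining k − 1 match positions uniformly without replacement from
{2..ℓ}, rejecting duplicates, so a set is uniform over distinct
canonical patterns.

**Binary counts.** The repeat-robust variant is implemented as the
number of *distinct* spaced words occurring in both sequences per
pattern. A literal per-pattern 0/1 indicator would cap N^bin at m and
make the estimator degenerate; the distinct-word reading preserves the
estimator's scale while counting every repeat family once.

**Ambiguity characters.** A window contributes no spaced word if any
*match* position carries a non-ACGT character; don't-care positions are
unconstrained. The per-pattern count of valid window starts is recorded
and substitutes for L − ℓ + 1 in the estimators, so N runs shrink the
effective length instead of biasing the background correction.

**Strand-aware counting** computes forward and reverse-complement
counts separately and combines them (full: sum; binary: words shared
with either strand), rather than literally concatenating S2 with its
reverse complement, which would create junction-spanning artifact
windows.

## Distance estimators

With homologous match probability p and background match probability
q = Σ_a q_a², the global-homology expectation
E(N) = m[(L−ℓ+1)p^k + (L−ℓ)(L−ℓ+1)q^k] inverts to
p̂ = (N/(m(L−ℓ+1)) − (L−ℓ)q^k)^{1/k}, and the Jukes–Cantor transform
d = −(3/4)ln((4/3)p̂ − 1/3) gives substitutions per site. The local
variant replaces the homologous window count by L_Hom − ℓ + 1 and the
background count by L* = (L1−ℓ+1)(L2−ℓ+1) − L_Hom; the strand-aware
variant uses N from both strands with the background term doubled,
2(L2−ℓ)q^k. For unequal lengths without strand-aware counting the
homologous term uses the shorter sequence and the background term the
longer one, which keeps d_N and d_RC consistent as the strand option
toggles.

The k-th root is evaluated as exp(ln(radicand)/k) on the strictly
positive branch. Degenerate outcomes never raise mid-pipeline: a
`DistanceResult` carries a status — `radicand_nonpositive` when the
background-corrected count is ≤ 0 (expected for unrelated pairs),
`jc_domain_violation` when p̂ ≤ 1/4, `saturated` when p̂ > 1 is capped
to 1 (d = 0). The all-vs-all workflow substitutes a configurable
ceiling (default 10.0 substitutions per site) for non-ok pairs so
distance matrices stay complete for tree builders, and logs each
substitution; the recovery sweep instead drops undefined replicates and
reports the surviving count.

`q` defaults to the uniform-composition value 0.25, which is also the
assumption under which the variance derivation is valid; an empirical
q = Σ f_a² from the pooled pair composition is available as an option.

## Variance of N

Two match indicators whose windows are shifted by s against each other
in both sequences are constrained at n(P, P′, s) = |P̂ ∪ (P̂′ + s)|
positions, giving covariances p^n − p^{2k} (homologous) and
q^n − q^{2k} (background). Summing over ordered pattern pairs and
shifts s ∈ [−ℓ+1, ℓ−1]:

Var(N) ≈ (L−ℓ+1) Σ_{P,P′} Σ_s (p^{n(P,P′,s)} − p^{2k})
       + (L−ℓ+1)(L−ℓ) Σ_{P,P′} Σ_s (q^{n(P,P′,s)} − q^{2k}).

Notes on this approximation, verified by the Monte-Carlo tests:

- For the periodic pattern 10101, odd shifts overlap no match positions
  (n = 2k, zero terms) and even shifts reproduce the contiguous overlap
  profile, so its covariance sums equal those of the contiguous pattern
  of the same weight; Var(N) itself agrees once the window-count
  prefactors are matched (the periodic pattern spans two more
  positions), i.e. up to a fringe of order ℓ/L at equal L.
- The derivation assumes covariances vanish unless the window shifts
  agree in both sequences. When S2 is literally evolved from S1,
  "transposed" index pairs (i, j)/(j, i) are additionally positively
  correlated; the neglected contribution scales like
  ((p² + (1−p)²/3)/(4q))^k relative to the background term — about 20%
  of Var(N) at k = 3 but under 2% for k ≥ 8. Monte-Carlo agreement
  (2000 replicates at L = 1000, 3σ) is therefore exercised at
  contiguous weight 8, a regime where the closed form is valid; the
  formula should not be trusted quantitatively for weights below ~6 on
  ancestor-descendant pairs.
- At L = 16,000, k = 8 the computed ordering Var(N/m): contiguous >
  single non-periodic spaced pattern > random 10-pattern set reproduces
  the motivation for spaced and multiple patterns.

## Simulator

`random_sequence` draws the ancestor i.i.d. uniform over {A,C,G,T}.
`evolve_jc` substitutes each position independently with probability
(3/4)(1 − e^{−4d/3}) by one of the three other bases uniformly, so the
realized mismatch probability equals the Jukes–Cantor value exactly.
`apply_indels` scans ancestor coordinates; an event fires per position
with probability `indel_prob` (default condition 1%), is an insertion
of uniform random bases or a deletion with equal probability, and has
length uniform on 1..`indel_len_max` (default 50) — a symmetric model
whose expected length change is zero, consistent with pairs of
"average" length. Deletions may swallow downstream event positions,
which is accepted as part of the model. All operations take one seeded
generator; outputs are bit-reproducible given (config, seed).

What the simulator does *not* emulate: rate heterogeneity across sites,
transition/transversion bias, non-uniform composition, rearrangements,
and mosaic local homologies (the local-homology tests build a single
embedded segment explicitly). Passing recovery tests therefore show
correctness of the estimator under its own model assumptions, not
robustness to every feature of real genomes.

## Benchmark conditions and numerical choices

The recovery benchmarks simulate ungapped pairs of length 100,000 at
k = 9, ℓ = 15 (the defaults; the weight/length for simulated
benchmarks is an open modelling choice, and k = 9 with up to 30
don't-care positions mirrors the mitochondrial-scale genome setting
where m = 100 random patterns are used). The acceptance script uses 80
replicates per condition to pin the mean within a few hundredths of a
substitution per site at desk runtime; the test suite uses 30 (single
pattern, d = 0.8) and 50 (m = 100, d = 1.0) replicates, and scales
supporting simulations (recovery spot-checks, embedded homology,
indel-bias sweep) to lengths of 30–55 kb with reduced pattern counts,
sizes at which the checked effects are still well separated from
Monte-Carlo noise.

Near saturation the estimator is strongly nonlinear: the k-th root and
the logarithm amplify downward fluctuations of the background-corrected
radicand, so single-replicate estimates at d ≥ 0.8 scatter widely
(sd ≈ 0.2–0.3 at the benchmark conditions), replicates with a
nonpositive radicand are undefined and excluded, and the conditional
mean of the survivors carries a small upward bias (measured ≈ +0.02 at
d = 0.8, ≈ +0.05 at d = 1.0). This is intrinsic to inverting E(N) near
the JC domain boundary, not an implementation artifact — the empirical
mean and variance of N itself match the closed forms at these
conditions. Multiple patterns reduce the scatter roughly like 1/√m,
which is why the multiple-pattern estimator remains usable to d = 1.

With indels enabled, spaced-word windows straddling an indel boundary
lose their homologous match, so N_hom shrinks and distances are
systematically overestimated — the sweep tests assert this sign at
every grid point rather than a magnitude, since the model offers no
indel correction.

## Known limitations

- The estimators assume global (or explicitly delimited local)
  homology; for sequences sharing only unannotated local homology, d_N
  overestimates distance.
- No indel-aware correction; indels bias estimates upward.
- The variance formula assumes uniform composition and, as noted above,
  weight ≥ ~6 for quantitative accuracy on ancestor-descendant pairs.
- PHYLIP output truncates names to 10 characters in strict mode and
  refuses collisions (use relaxed mode for long names).
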