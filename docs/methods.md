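# Methods

## Profile HMMs and scoring

Models follow the Plan7 core topology: per node `k = 1..L` a match state
`M_k` (emission over the 20 standard amino acids), an insert state `I_k`
(`k < L`), a delete state `D_k`, and the seven core transitions (M→M/I/D,
I→M/I, D→M/D). Search runs in local mode: entry into any match state with
uniform probability `1/L`, exit after any match state, and unaligned flanks
emitted from the background so they contribute zero bits. Scores are
log₂-odds against the background ("bits"). Viterbi — not Forward — defines
hits and their boundaries, because it gives deterministic envelopes;
traceback ties are broken preferring match over delete over insert over a
fresh entry.

**Model building.** Alignment columns with gap fraction ≤ 0.5 (configurable)
become match states. Emissions are smoothed column frequencies,
`(counts + m·background) / (total + m)` with total pseudocount mass `m = 1`
distributed by the background; transitions are counted from per-row state
paths and smoothed with the analogous uniform prior over each state's
outgoing options. I→D and D→I, which the Plan7 core lacks, are folded into
I→M / dropped. The background defaults to uniform 1/20 and can be taken from
the training alignment. No sequence weighting is applied by default.

**E-values.** Bit scores of optimal local alignments to random sequences
follow a Gumbel law. Calibration scores `n_random = 1000` (tests use 500)
i.i.d. background sequences of length `2L` and fits Gumbel parameters by
maximum likelihood (`scipy.stats.gumbel_r.fit`); the per-domain E-value of a
hit with score `s` in a search space of `N` sequences is `N · SF(s)`. `N`
defaults to the number of target sequences in the search. The screen
discards hits with E-value **strictly greater than** 10⁻⁴, so a hit exactly
at the threshold is kept. Calibration is deterministic given its seed.
Highly conserved models produce a lumpy null-score distribution (scores
cluster by the number of consensus residues matched), which makes the Gumbel
fit conservative in the extreme tail; this only strengthens the 10⁻⁴ filter.

**Multi-hit search.** Per target, the best local alignment is found, its
envelope masked (masked residues may not be emitted by any model state, so
no alignment can cross them), and the search repeated up to 10 rounds until
the E-value fails. Masking restricts the feasible path set, so successive
bit scores are non-increasing. This is what surfaces a GH33 domain split by
an inserted I-domain as two sub-hits: crossing a long insertion inside one
alignment costs `log₂ t(M→I) + (ℓ−1)·log₂ t(I→I) + log₂ t(I→M)` bits, which
for realistic insert penalties far exceeds the ~`log₂ L` cost of starting a
second local hit.

## Architecture calls

A protein is called `IT_SIALIDASE` iff it carries ≥1 sialidase-model hit and
≥1 I-domain hit (E ≤ 10⁻⁴ each); `HYDROLYTIC_TYPE` iff it carries sialidase
hits only; otherwise `NONE` (an I-domain or CBM40 hit alone is not a
sialidase). Co-occurrence, not segmentation, is the primary criterion:
fragmentary coding sequences in draft genomes can truncate one GH33 sub-hit,
and requiring a clean split would lose those calls. Segmented-match evidence
is still computed and reported: two sialidase sub-hits with model coordinates
in order, a target gap of ≥ 30 residues between their envelopes, and ≥ 50%
of an I-domain envelope inside the gap. The 30-residue gap and 50% overlap
defaults reflect the geometry of the reference IT-sialidase (an I-domain of
roughly 190 residues inserted within a ~723-residue protein) and are
configurable. CBM40 is annotated independently of the call.

## Genome screen

Gene tables carry 1-based ordinal locus indices per replicon (GFF3 input is
ranked by start coordinate per seqid; sparse indices are renormalised to
consecutive). A canonical Nan cluster is any minimal same-replicon interval
of span ≤ 15 loci (both endpoints and intervening genes counted) containing
at least one NanA, NanK and NanE1 gene each. Windows never span replicon
boundaries — contig order in draft assemblies is arbitrary, so "consecutive
loci" is only meaningful within a replicon. `canonical_unclustered` is the
relaxed call (all three roles anywhere in the genome) and is implied by the
clustered call. The Bacteroides-type pathway call requires hits for the
NanA model (which covers the NanL aldolase), NanE2 and RokA; when no RokA
model is supplied the rule degrades to the two-component form with a logged
warning rather than failing. One gene may carry several roles. The summary
reports counts and percentages at integer-percent display precision with raw
values alongside, plus a consistency statistic: how many Bacteroides-type
strains also match NanE1 (expected to be none).

## Metagenome screen

A sample is one subject's translated coding sequences; it is positive for a
model when ≥1 sequence has a hit, and a sequence with several hits of one
model counts once. Two modes share the same summariser: sequence-level mode
runs the real search (used at reduced scale — the published screens pooled
14.1 million sequences, which is not desk-scale; the arithmetic is), and
count-level mode consumes per-sample hit counts. Percent-hit-sequences is a
pooled ratio per group (Σhits/Σsequences), not a mean of per-sample ratios;
sequences-per-hit (the "1 in N" figure) is the reciprocal per group.
Coding-sequence length is 3 × protein length when only proteins are given.
The group contrast reports prevalences, the risk ratio and a two-sided
Fisher exact p-value; it is descriptive, and degenerate contrasts (zero
positives in the reference group) are flagged rather than raised. Totals are
accumulated with `math.fsum`, so reports are invariant to sample order.

## Kinetics

* **Substrate inhibition.** `v = Vmax·S/(KM + S(1 + S/Ki))` — the standard
  uncompetitive substrate-inhibition form (the curve is unimodal with
  maximum at `S* = √(KM·Ki)` and `v(S*) = Vmax/(1 + 2√(KM/Ki))`). Fitted by
  bounded nonlinear least squares; starting values `Vmax₀ = 1.2·max(v)`,
  `KM₀ =` substrate at half-max on the ascending limb, `Ki₀ = max(S)`, which
  are robust on unimodal data. `weighting="relative"` (1/Y² weighting, as
  Prism offers) matches constant-CV measurement error; the default is
  unweighted. The plain Michaelis–Menten variant (Ki → ∞) is available and
  comparable by AICc. Standard errors come from the local curvature of the
  objective; `kcat = Vmax/[E]` and `kcat/KM` carry delta-method errors,
  `se(kcat/KM) = (kcat/KM)·√((se_kcat/kcat)² + (se_KM/KM)²)`. Units are
  explicit: substrate mM, rate µM·min⁻¹, enzyme concentration in the caller's
  named unit.
* **Progress curves.** `ln(S₀/Sₜ) = k·t`, fitted by linear regression through
  the origin, valid when `S ≪ KM` throughout; the curve must cover ≥ 50%
  substrate conversion (the standard protocol tracks the majority of the
  reaction) and all `Sₜ` must be positive. `kcat/KM = k/[E]`, with R²
  reported.
* **IC50.** `y = 100/(1 + 10^(log₁₀[I] − logIC50))` with Hill slope fixed at
  −1 (the normalized-response convention); a free-slope variant is selectable.
  Zero-inhibitor points anchor normalisation and are excluded from the
  log-scale fit. Data without a transition (all activities near 100% or near
  0%) yield a non-converged flag instead of a spurious estimate. Rescaling
  concentration units shifts logIC50 by the corresponding constant.

## Synthetic data: what it emulates, and what it does not

Generators are bit-reproducible given a seed and emit truth tables. The
default model bundle uses conserved synthetic profiles (~3.4 bits of
information per match state at the 0.9 conservation default) for eight
slots: sialidase (60 match states), I-domain (45), CBM40 (30) and the five
Nan/RokA gene models. IT constructs are built as GH33 N-segment + I-domain
emission + GH33 C-segment (split at the model midpoint by default), with a
CBM40 module prepended on a configurable fraction (default 0.75, matching
the association observed among IT-sialidases); hydrolytic constructs are
contiguous GH33 emissions; decoys are i.i.d. background residues, with
flanks drawn uniform 20–80 residues. Gene tables plant role triplets at
controlled spans on decoy backbones; cohorts draw per-sample positivity
Bernoulli(p) and hits-given-positive as 1 + Poisson(λ), the simplest
zero-inflated scheme consistent with "positive = ≥1 hit sequence".

What the generators do **not** emulate: real sequence divergence and
phylogenetic correlation (planted domains are draws from the search model
itself, so recovery rates on synthetic data are an upper bound on real-data
sensitivity), compositional bias, sequencing/assembly error, fragmented
coding sequences, operon structure beyond locus adjacency, and taxonomic
composition. Passing the planted-recovery tests therefore demonstrates that
the machinery (scoring, calibration, masking, classification, windowing,
arithmetic) is correct, not that the screen's real-world sensitivity equals
100%.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full pipeline at reduced,
seeded scale chosen as representative rather than exhaustive: a 220-protein
planted proteome (180 decoys / 20 hydrolytic / 20 IT), six-strain genome
fixtures, cohorts of hundreds of count-level samples, calibration with 500
random sequences per model, ≥200 random small instances for the
Viterbi-vs-enumeration check and 100 random tables for the cluster-detector
oracle. Count-level cohort mode reproduces the published 124-subject
arithmetic exactly, since it is pure arithmetic on the printed per-sample
structure.

For the substrate-inhibition replicate-recovery study (5% noise, 100 seeded
replicates, median |bias| < 2% per parameter) the assay design must carry
enough information for the stated tolerance: with a sparse 12-concentration
single-replicate design the per-fit sampling scatter of KM and Ki under 5%
noise is ~10%, so no estimator can achieve a 2% median error. The study
condition is therefore defined as a well-powered assay — 24 log-spaced
concentrations spanning 0.01–50 mM, 12 replicate measurements per
concentration, 5% CV (relative) Gaussian noise, and CV-matched relative
weighting in the fit — under which the median absolute bias is ~1–1.5% per
parameter with 100% convergence. Noiseless recovery uses the sparse
12-point design and recovers parameters to 0.1%.

Other numerical choices: probabilities are stored linearly and serialised as
natural logs; scoring uses log₂; emission/transition distributions must sum
to 1 within 1e-9; Viterbi traceback tolerates 1e-9 of float drift between
the vectorised fill and scalar recomputation; the delete-state recursion is
vectorised per row via a cumulative-max scan over `VM + t(M→D) − Σlog t(D→D)`.
Degenerate inputs: empty samples are zero-count summaries (draft metagenomes
can be empty), empty cohorts and empty strain lists are errors, masked-out
targets simply stop producing hits, and an all-equal calibration score
distribution (e.g. a zero-information model) is a calibration error.

## Known limitations

No Forward/posterior decoding, glocal mode, DNA alphabets or HMMER
acceleration filters; no exact HMMER score parity (the E-value machinery is
calibrated per model rather than using HMMER's two-tier envelope
statistics). The genome screen does not predict genes, infer taxonomy, or
analyse transporters; the metagenome screen does not assemble reads or
normalise abundances. Kinetics fits assume a single enzyme and substrate
(no global multi-substrate fits) and leave raw-signal-to-concentration
conversion to the caller. Parameters reported near detection limits
(non-identifiable KM or Ki) are flagged via convergence/boundary behaviour
rather than reproduced as printed bounds.
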