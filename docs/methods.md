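# Methods

## Problem and model

`litpriority` identifies *research priorities* in a time-stamped corpus of
publication abstracts, such as the pandemic-era coronavirus literature. The
pipeline has four stages.

**1. Vectorization.** Abstracts are lowercased, stripped of punctuation and
digits, lemmatized by a rule-plus-exception-lexicon lemmatizer, and cleaned
of stop lemmas (function words plus scientific boilerplate such as
"introduction" and "method"; the stop list is applied after lemmatization so
one entry covers all inflections). Lemmas with total count < 4 or document
frequency > 80% are pruned — "relative frequency" is read as the
document-frequency fraction, the standard corpus-pruning convention. The
corpus becomes an n x m matrix R with entries tf(i,j) * ln(n / df(j)): raw
term counts, unsmoothed idf, no row normalization. Ubiquitous (zero-idf)
terms are already removed by the 80% rule, so this bare TF-IDF variant is
well conditioned; the variant is isolated in `preprocess.build_tfidf` and
easy to swap.

**2. Hotspot discovery.** R is factorized as R ~ W H, W (n x k) and
H (k x m) non-negative, minimizing f(W,H) = 1/2 ||R - WH||_F^2. We adopt
the convention that W rows are documents and H rows are topics (the only
dimensionally consistent reading). The solver is alternating non-negative
least squares with HALS block-coordinate updates: each factor column is
solved exactly in turn, so the objective is non-increasing by construction,
and the value after every full sweep is recorded (`objective_trace_`).
Initialization is NNDSVD with seeded random fill of zeros (`nndsvdar`) for
determinism; purely random initialization is available behind the same
seed. Iteration stops when the per-sweep relative decrease falls below
`tol` (default 1e-5) or at `max_iter` (default 300, with a warning).
The estimator follows scikit-learn conventions (`fit`, `transform`,
`get_params`, trailing-underscore attributes) and its final objective is
cross-checked against scikit-learn's NMF in the test suite.

Each discovered topic ("research hotspot") is summarized by its top-5
H-row terms, ties broken lexicographically. Documents are hard-assigned to
their W-row argmax (ties to the lowest topic id; all-zero rows go to an
unassigned bucket). Membership probabilities are the column-normalized W:
p(d|t) sums to 1 over the corpus for each topic.

**3. Choosing k.** Two diagnostics are computed per candidate k:

* *Stability* (Greene-style): a reference model on all documents is
  compared with replicate models on random 80% document subsamples; topics
  are matched by Hungarian assignment maximizing depth-averaged top-term
  Jaccard agreement (mean over depths 1..20 of the Jaccard index of the
  top-d term sets), and the mean matched agreement in [0,1] is returned.
  Replicates use **random initialization**: with a deterministic NNDSVD
  start the replicates collapse onto near-identical optima even at
  misspecified k and stability saturates; random restarts restore the
  metric's sensitivity.
* *Divergence* (Arun-style): symmetric KL divergence between the
  normalized singular values of H and the normalized per-topic column
  norms of W (epsilon floor 1e-12 before normalization). Low values
  indicate a well-proportioned factorization. Note this statistic
  penalizes over-fitting (extra topics unbalance the two distributions)
  but *not* under-fitting: merging well-separated topics keeps the factors
  balanced and the divergence near zero.

Because of that asymmetry, a symmetric "rank stability high, rank
divergence low" combination systematically elects the smallest k on
sharply structured corpora. `select_k` therefore uses an asymmetric rule:
shortlist candidates whose stability is within 0.05 of the grid maximum,
drop shortlisted candidates whose divergence exceeds the shortlist minimum
by more than 0.10, and pick the **largest** surviving k. Preferring the
richer structure among jointly near-optimal candidates mirrors how these
diagnostics are used in practice — a too-small k merges distinct fields
into vague composites that can look both stable and low-divergence. The
full diagnostic grid is always returned for human override. On planted
corpora (~600 documents, k_true in {4, 6, 8}, grid 2..12) the rule
recovers the planted k in 26/30 seeded runs.

**4. Metric suite and classification.** The study period is split into
half-open consecutive windows of w days (default 7; a document dated on a
boundary belongs to the later window). Per topic t and window w:

* REC(t,w) = (documents of t in w) / (all documents in w) — effort
  coverage; per window the values sum to 1 minus the unassigned share.
* B(t,w) = mean days from the outbreak start to the publication dates of
  t's documents in w. A document published on the outbreak day itself
  would give a zero distance and an infinite response rate; it is offset
  to b_i = 1 day.
* E(t,w) = Shannon entropy (nats) of the within-cell renormalized
  membership probabilities q(d) = p(d|t) / sum_cell p(d|t). Natural log
  throughout; a different base would only rescale RRR uniformly. Cells
  with fewer than two documents get E = 0.
* RRR(t,w) = [sum_{d in cell} p(d|t)] / [B(t,w) * E(t,w)] — the topic's
  probability mass published in the window, discounted by its delay and
  its membership uncertainty. The numerator uses the *global* p(d|t), so
  it is informative (a within-cell normalization would make it identically
  1). Cells with E = 0 are left missing rather than infinite;
  classification uses the available cells.

REC trends are tested with the Mann-Kendall test: S = sum_{i<j}
sgn(x_j - x_i), tie-corrected Var(S) = [n(n-1)(2n+5) - sum_g
t_g(t_g-1)(2t_g+5)]/18, continuity-corrected Z, two-sided 5% level
(|Z| > 1.96). Series shorter than 4 after dropping missing values give a
flagged null result.

Each hotspot's RRR trajectory is typed by ordered rules
(`classify.classify_type`): fluctuating if there are >= 3 *material*
reversals (first differences with amplitude >= 25% of the series mean —
genuine event-driven swings are of the order of the mean, while Poisson
sampling jitter in a declining tail is ~10% and must not trigger the rule)
or if the coefficient of variation is >= 0.5; else emergency if the first
window's value is within 10% of the series maximum (a tolerance that
absorbs sampling noise in near-ties, resolving them toward the
faster-responding type); else persistent if the maximum falls in the
second window; else persistent/fluctuating by the sign of the RRR trend.
These thresholds operationalize archetypes that are normally judged by
inspecting the trajectories; they are exposed as parameters so
judgment-based labels can be reproduced. The priority region combines the
type letter (E/P/F) with the REC trend digit: 1 = significantly
decreasing, 3 = significantly increasing, 2 = otherwise stable.

## Synthetic study conditions

The generator (`synth`) emulates exactly the structure the metrics assume:
a 200-lemma vocabulary; k_true topic-word distributions from a symmetric
Dirichlet with concentration 0.04 (a handful of dominant terms per topic —
"sharp" topics); abstracts as i.i.d. bags of ~40 lemmas (Poisson, floor
5) from a single topic; 10 weekly windows starting 43 days after the
outbreak anchor (2019-12-12 outbreak, 2020-01-24 study start); and
per-(topic, window) Poisson counts around archetype-specific expected
volumes. The archetype shapes were derived from the identity
RRR(w) ~ n_w / (B_w ln n_w) with B_w growing linearly in w, so that
emergency topics peak in window 1 and decay ~43% over the period,
persistent topics peak in window 2 and decline slowly, and fluctuating
topics alternate high/low volume; the amplitudes leave the planted
structure detectable under Poisson noise without being trivial. Dates are
uniform within windows. Planted REC trend labels are computed from the
expected (noise-free) share series, not asserted by fiat.

What the generator does **not** emulate: real abstracts' syntax and
length variation, topic mixtures within a document, vocabulary growth over
time, non-English contamination, or duplicated records. Passing the
planted-recovery tests therefore demonstrates the correctness and
calibration of the machinery under its own model assumptions, not
performance on a real literature snapshot.

## Numerical choices and edge cases

* HALS denominators are floored at 1e-12; a dead component column is
  zeroed rather than divided by ~0.
* Objective monotonicity is asserted with a 1e-9 relative slack for
  floating-point accumulation.
* Dates must be full ISO-8601 days; year-only dates are rejected because
  weekly windows need day resolution. Records outside the study period
  are dropped, not clipped.
* English detection for untagged records is a character/function-word
  heuristic (>= 85% ASCII letters, plus at least one common English
  function word for texts of 10+ tokens); synthetic corpora always carry
  explicit tags.
* Fixed window counts (e.g. 10 windows over a longer period) exclude
  later documents by design; the auto mode covers the whole period and
  flags a short last window.
* The problem sizes used by the verification suite — ~600-document
  corpora for topic-count recovery, ~5,000-document corpora for archetype
  recovery, 2,000 null series for trend-test calibration — were chosen as
  the smallest sizes at which the planted effects are comfortably
  identifiable.

## Known limitations

* Hard topic assignment ignores mixed-topic documents; the entropy term
  only partially compensates.
* The Mann-Kendall normal approximation is used at series length 10,
  where it is slightly conservative (measured type-I error ~0.044 at
  nominal 0.05).
* select_k's preference for the largest near-optimal k assumes the
  stability curve drops sharply past the true k, which holds for sharp
  topics but may overselect on corpora with genuinely nested topic
  structure.
* The lemmatizer handles regular English inflection plus a small
  irregular lexicon; it is not a full morphological analyzer (derivational
  variants such as "infection"/"infectious" stay distinct).
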