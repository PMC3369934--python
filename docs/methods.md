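# Methods

## Model

The estimator treats a cluster of artifactually duplicated reads (ADRs)
as repeated noisy observations of one template. Clusters are recognised
purely combinatorially: reads sharing an exactly identical length-*l*
prefix, at abundance ≥ *n*. Under a uniform independent-sequence null,
the chance probability of one such bin is

    p(l, n) = 4^(-l) / n

computed in log space (4^-50 underflows long before float limits are a
concern for the joint expression). At the defaults (l=50, n=20),
p ≈ 3.9·10⁻³²; even 10⁶ reads give an expected chance-bin count of
~4·10⁻²⁶, so every observed bin is attributed to technical duplication.
The closed form is an anchor-matched working model, not a derivation from
a specific sampling process; both parameters are user-overridable
(`--prefix-length`, `--min-abundance`) to suit run scale.

Variation *within* a bin beyond the prefix is read as sequencing-process
error. Assumptions this rests on:

- bin members descend from a single template (guaranteed by the
  improbability argument, except for genuinely repetitive input such as
  amplicons — out of scope, documented as unsuitable);
- the consensus of ≥ 20 members recovers the template at essentially
  every position (majority vote is wrong only when the same error
  dominates the column, probability negligible at per-base error rates
  well below 50%);
- prefix bases carry no error information (they were selected for
  identity), so all summaries use non-prefix positions only.

## Per-bin alignment and classification

Non-prefix regions are star-aligned: the most frequent non-prefix string
seeds the alignment (ties: longest, then lexicographically smallest —
member order can never matter); every member is globally aligned to the
seed (Needleman–Wunsch, linear gaps, defaults +1 match / −1 mismatch /
−2 gap); pairwise gap patterns merge into a common column space with
per-junction insertion blocks (width = max insertion length over members,
shorter insertions left-aligned). A per-column majority vote calls the
consensus, followed by exactly one refinement pass (re-align everyone to
the voted consensus, re-vote) — bounded runtime, deterministic, and
sufficient for near-identical members.

Column conventions:

- consensus symbol = majority over {A,C,G,T,gap}; base ties break
  A<C<G<T; a base beats a gap on ties; majority-gap columns are
  *insertion columns* (no consensus base); columns where N holds the
  plurality are *masked* and excluded from all tallies (N votes never
  elect a base);
- substitutions are keyed by the **consensus** base: an error at a
  consensus-A position counts toward A_subst;
- insertions anchor to the nearest preceding ungapped consensus position
  (position 1 if none precedes);
- terminal gaps — a read starting after or ending before the consensus —
  are **not** deletions: read-length variation (e.g. 454-style) is not
  per-base error. Only internal gaps count.

Pairwise alignment is delegated to Biopython's `PairwiseAligner`; the
first optimal alignment it enumerates is taken, which is deterministic
for fixed inputs. Tests verify score optimality against a brute-force
enumeration of all alignments for short strings.

## Profiles and summaries

Reported positions are 1-based over the whole read: prefix positions
1..l (pure matches, bin abundance × prefix base — present so whole-read
profiles can be plotted), then consensus position i at l+i. The
per-position denominator is the position's total event count, including
insertions anchored there, so each percent row self-normalises to 100.
Zero-coverage positions are written blank (no data ≠ no error).

Summaries over covered non-prefix positions, in two forms:

- **weighted** (`Total_err`): each class's events over the grand event
  total — coverage-weighted, dominated by well-covered positions;
- **averaged** (`Total_avg_err`): mean over positions of the
  per-position percent — every position equal weight, more sensitive to
  high-error read tails.

In both forms Total = A_subst + T_subst + C_subst + G_subst + InDel
(InDel = insertions + deletions), exactly.

The table layout includes a `match_N` column for completeness; under the
classification above (read-N under a consensus base counts as a
substitution of that base, N-plurality columns are masked) it is always
zero.

## Simulator

The generator emulates what the estimator consumes, not a particular
instrument: an i.i.d. template genome (length 100 kb, GC 0.5 by
default) is fragmented at uniform starts with lengths from a
`fixed:N` or `lognormal:mu,sigma` law; `n_bins` templates are duplicated
to abundance-law-drawn copies (planted ADR bins) and the rest become
background singletons (default 2,000, exercising the abundance filter).
Per base, each copy is independently mutated: deletion with probability
`del_rate`, else substitution with `sub_rate` (uniform over the other
three bases), and independently an insertion of a uniform base after it
with `ins_rate`; an optional position ramp multiplies all three. Every
event is logged with read, position and type.

By default errors are withheld from the planted prefixes so bins stay
discoverable by exact binning. In real data a prefix error simply
fragments a bin; modelling that would only shrink bin sizes while
confounding validation of the error *measurement*, which uses non-prefix
bases only. `--errors-in-prefix` enables the realistic mode for
robustness checks.

The ground truth for validation is the *realized* per-base event rate
over the non-prefix template bases of the planted copies — the quantity
the weighted Total estimates. Features of real data the simulator does
not emulate: flowgram/homopolymer-structured 454 indels, calibrated
quality strings (FASTQ output uses a flat configurable Q), GC-dependent
coverage, chimeras. Passing validation therefore demonstrates correct
recovery of planted duplicate-cluster variation, not instrument realism.

## Validation conditions and problem sizes

The standard validation sweep runs five datasets at total injected rates
{0.5, 1, 2, 4, 8}%, each with 200 planted bins of abundance 20, read
length 150, prefix 50, and 2,000 background singletons (~400,000 scored
non-prefix events per dataset), splitting each total rate into
substitution:insertion:deletion = 0.8:0.1:0.1 — a substitution-dominant,
Illumina-like mix. Estimates regress on realized truth with R² ≈ 0.9999
(slope ~0.98). The per-rate three-standard-error recovery property is
defined and tested under substitution-only injection, where the
estimator is unbiased to ~0.2% relative; see limitations.

## Numerical and degenerate-input conventions

- Non-ACGTN input characters map to N with a warning rather than
  aborting; archives contain ambiguity codes and they are simply
  uninformative here.
- Bins whose prefix contains N are discarded whole.
- Phred offset auto-detection: any quality code < 64 in the first 10,000
  records ⇒ offset 33, else 64; records with empty quality strings
  default to 33.
- Bin order is always deterministic (abundance descending, then prefix),
  so seeded subsampling and outputs are reproducible; end-to-end runs
  with identical configuration produce byte-identical tables.
- A bin whose members all end at the prefix is skipped with a warning; a
  sample with no qualifying bins fails with "insufficient artifactual
  duplicate reads".
- Empty-profile aggregation returns an empty profile; summarising a
  profile with no covered non-prefix positions is an error.

## Known limitations

- **Indel detection bias.** When an insertion and a deletion fall within
  a few bases of each other, the optimal alignment under +1/−1/−2
  scoring replaces the two gaps with a short run of mismatches; the two
  indel events are lost (partly re-counted as substitutions). At an 8%
  total rate with 10% insertion and 10% deletion shares this costs ~5%
  of indel events, a ~2% relative underestimate of the total; at
  realistic (≤ 2%) rates the effect is an order of magnitude smaller.
  Insertion events also enter the weighted denominator, giving a further
  downward bias proportional to the insertion rate. Substitution-only
  error is recovered essentially unbiased.
- The count-weighted total is dominated by positions covered by many
  bins; samples with strongly position-dependent error are better read
  from the per-position profile or the averaged summary.
- Biological repeats (amplicons, rRNA, low-complexity or eukaryotic
  repetitive sequence) violate the single-template assumption and
  inflate apparent error; no automatic detection is attempted.
- Reverse-complement duplicates and fuzzy (error-containing) prefixes
  are not clustered; such reads simply fail to join bins, which loses
  data but does not bias the estimate.
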