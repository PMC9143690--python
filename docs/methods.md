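# Methods

This note documents the models and procedures implemented in `figlipase`,
the parameters that matter, the numerical choices, and what the synthetic
data generator does and does not emulate.

## Reference-anchored feature extraction

All sequence characterization is read off a pairwise alignment of a query
protein against a family reference. The aligner is a hand-written Gotoh
dynamic program (global, local and overlap modes) with affine gap costs: a
gap of length L costs `gap_open + gap_extend * L` (defaults 10 and 1,
BLOSUM62). Ties are broken by a fixed state preference — match/mismatch
over gap-in-query over gap-in-reference — applied identically in cell
selection and traceback, so alignments are bit-stable across platforms.
Terminal gaps are penalized in global mode; the overlap mode (free terminal
gaps) exists for anchoring short references but is off by default. The
ambiguity letter X scores the matrix minimum against everything, so it can
never beat a real residue and never satisfies a catalytic-site check.

**Catalytic triads.** A reference carries 1-based positions and expected
residues for the Ser-Asp-His triad. The query residue in each triad column
is compared with the expectation; the triad is complete only when all
three match exactly. Substitutions are reported as e.g. "Glu in place of
Ser", a query gap as "lacked His".

**Regions (β9 loop, lid, cap).** A region is a pair of anchored reference
positions. The extracted region is every query residue in the alignment
columns from the start-anchor column to the end-anchor column *inclusive*;
its length counts residues, so query gaps shorten it and insertions
lengthen it. Both anchors are included because the published loop/lid
strings include their anchor residues (loops start and end with His, lids
with Cys). When an anchor column holds a query gap the span is kept and
the observed anchor is recorded as absent; anchor substitutions (e.g. Phe
at the cap's Thr anchor) are recorded but not fatal. This handling of
gapped anchors is a design choice: the source analyses do not state one,
and keeping the span is the conservative option that never silently moves
a boundary.

**TAG-activity call.** A neutral lipase is a putative TAG hydrolase when
its β9 loop is strictly longer than 15 residues and its lid is at least 18
residues. The lid threshold is inclusive (≥ 18) by default and
configurable; on all tabulated data the distinction between ≥ 18 and > 18
is vacuous because the shortest printed lid is 19.

**Family assignment.** Best local-alignment score against the panel wins,
with ties broken by panel order; below `min_score` (default 80 raw score
under BLOSUM62/10/1) the query is left unassigned. The threshold is an
operating point, not a calibrated quantity: at typical lipase lengths
(~250–340 aa) true family members score in the hundreds and unrelated
random sequences far below, so results are insensitive to it over a wide
range.

The reference triad and anchor positions are configuration, not code: the
packaged panel is synthetic (see below), and user panels are supplied as a
YAML file with documented positions.

## Tandem duplication and exon structure

Tandem detection works on gene coordinates only (1-based inclusive, GFF3
convention; strand is ignored, as the underlying analyses never condition
on it). Within a scaffold, same-family genes sorted by (start, end, id)
are chained while at most `max_intervening` genes of any other family lie
between consecutive members; maximal chains of two or more genes are
clusters. One cluster counts as one duplication event regardless of size —
a three-member run is one event, not two pairs. The default
`max_intervening = 1` is recorded and configurable; the original
collinearity software did not publish its criterion, so quantitative
validation uses synthetic planted truth rather than published genome-scale
counts. Summaries report events, distinct scaffolds bearing clusters, and
the percentage of family genes inside clusters (one decimal).

Exon profiles are straight tallies: per-gene exon counts, a family-level
histogram with two-decimal percentages, and the intronless gene list
(exactly one exon).

## Codon adaptation index

Sharp–Li CAI: relative adaptiveness `w(c) = f(c) / max f` within each
synonymous codon family, CAI as the geometric mean of `w` over the codons
of a CDS (computed in log space). Methionine, tryptophan and stop codons
are excluded — singleton families carry no preference information.
Zero-frequency codons are floored at `w = 0.01` to keep logarithms finite;
the floor is configurable. A terminal stop codon is trimmed; an internal
stop or a length not divisible by three is an error. Expression classes:
high above 0.5, low below 0.03, intermediate between. CAI is invariant to
codon order and to concatenating a sequence with itself (checked to
1e−12), and equals 1 exactly when every informative codon is
family-optimal. The reference usage table is user input; the package does
not bundle any species' empirical table.

## Group count statistics

Two-or-more-group Kruskal–Wallis with midranks and the standard tie
correction; the statistic is reported to three decimals and the p-value
comes from the χ² upper tail with k − 1 degrees of freedom (the same
approximation standard statistical software uses — the published values
round identically under it). When every pooled observation is tied the
correction denominator vanishes and H is defined as 0 with p = 1. Ranking
uses `scipy.stats.rankdata`; the rest of the statistic is computed
explicitly, and the test suite cross-checks against both a from-scratch
midrank implementation and `scipy.stats.kruskal`.

Share summaries report each species' (neutral + acid) / total percentage
at one decimal with the min and max. Note one rounding quirk in the
published range "84.0–95.4%": the smallest tabulated share is 26/31 =
83.9% at one decimal, so the lower bound appears to have been rounded
upward in the original; the package reports 83.9.

## Birth–death gene-family model

A family's copy number evolves by a linear birth–death process with equal
per-copy gain and loss rate λ per unit branch length; zero is absorbing.
With α = λt/(1+λt), the transition probability from parent count s to
child count c is the closed-form kernel

    P(c | s, λt) = Σ_{j=0}^{min(s,c)} C(s,j) C(s+c−j−1, s−1) α^{s+c−2j} (1−2α)^j

computed in log-gamma space with explicit sign handling (1−2α is negative
for λt > 1) and the c = 0 column replaced by the exact extinction
probability α^s. The kernel is validated against the matrix exponential of
the truncated rate matrix (agreement ~1e−16) and rows sum to 1 within
1e−8 for s ≤ 10 and λt ≤ 0.5 at the default cap.

* **State space.** Counts are truncated at a cap M (default 100); an
  observed count above M is an error rather than a silent squeeze.
* **Likelihood.** Post-order sum-product (pruning) over states 0..M, with
  per-node rescaling to avoid underflow and all families processed as one
  matrix for speed. The root prior is uniform on 1..M — a family observed
  today existed at the root — matching the convention of conditioning on
  root presence; it is configurable.
* **Rate estimation.** λ̂ maximizes the summed log-likelihood over
  families by deterministic golden-section search on the user-supplied
  bracket (default 1e−6..1, relative tolerance 1e−6). Degenerate data with
  no observed change push λ̂ to the lower bound, by design.
* **Ancestral reconstruction.** Joint max-product (Viterbi-style) over
  states with ties broken toward the smaller count; per-branch net change
  and a two-sided tail probability under the fitted kernel: the kernel
  mass on child counts at least as far from the parent count as the
  reconstructed one, flagged at 0.05. The published analyses mark
  significant expansions without stating a procedure; this tail
  probability is the package's own, documented choice.
* **Simulation.** Forward sampling branch by branch from the kernel,
  reproducible under a seed; used for the parameter-recovery validation
  (median λ̂ over 20 seeded replicates of 500 families within 25% of the
  simulating rate; the test runs at cap 40 with root count 5 and
  12 leaves, which keeps the whole recovery suite under a minute).

The published ancestral copy numbers (≈23 neutral and ≈16 acid at the
Chalcidoidea root) are not reproduced here: they require a species tree
with branch lengths from an external publication that is not part of the
tabulated data. The module is validated by enumeration oracles and
simulation recovery instead.

## Synthetic data generator

The generator produces every input with known truth from one seed:

* **Proteins** derive from a fixed synthetic exemplar per family (built
  once from an internal constant seed; the neutral exemplar carries a
  planted Ser150/Asp176/His280 triad, His204/His224 loop anchors and
  Cys238/Cys262 lid anchors; the acid exemplar a triad plus Thr184/Asn308
  cap anchors). Copies are point-mutated at a configurable rate (default
  8%) outside protected columns (triad ± 1, anchors ± 3), region interiors
  are replaced by random sequence of the requested length, and a
  configurable fraction (default 4%, matching the few-percent incidence in
  real data) get a broken triad by substitution or deletion. Loop lengths
  default to mostly 15 with a tail above — the shape of the published
  distribution.
* **Genomes**: scaffolds with spaced genes, planted tandem arrays isolated
  by at least two filler genes (so default-parameter detection recovers
  exactly the planted clusters), and exon counts drawn from a configurable
  histogram spanning the observed 1–16 range.
* **CDS sets** with planted expression classes against a generated biased
  usage table (preferred codon 10, secondary 10·(1−bias), rest 0); "low"
  genes are written in zero-frequency codons of families with ≥ 3 members
  so they land at the adaptiveness floor.
* **Count tables** with 5 + 7 species and an additive NPFW shift on the
  neutral and acid families (defaults shaped like the real table), and
  **random binary trees** with uniform branch lengths.

What the generator does *not* emulate: real lipase biochemistry, realistic
substitution processes or phylogenetic correlation between sequences,
overlapping genes, alternative splicing, or annotation noise. Passing the
truth-recovery tests therefore shows the pipeline implements its own
definitions correctly on clean data; it does not certify performance on
noisy real annotations, where alignment-anchor placement and family
thresholds would need tuning against curated examples.

## Packaged fixtures

The two published tables ship as plain TSVs with frozen SHA-256 checksums
verified at load time; tests fail loudly on any drift. The count-table
fixture reproduces all printed marginals (grand total 481, neutral 259,
acid 182) and the loop/lid fixture is internally consistent (93/93 string
lengths equal printed lengths). One discrepancy between derived summaries
is worth noting: the longest lid in the table is the 60-residue
Spsp_neutral_25, while the 43-residue Abak_neutral_17 lid is sometimes
singled out as longest; the package asserts only the tabulated lengths.

## Problem sizes

The test suite runs everything at desk scale: alignments up to a few
hundred residues, enumeration oracles at sequence length ≤ 8, 200 random
tandem layouts of up to 50 genes, birth–death state caps of 12–50 for the
enumeration and oracle checks and 40 for recovery, and 20 × 500 simulated
families for rate recovery. These sizes were chosen so each validation is
decisive while the whole suite stays in the low minutes.
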