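# Methods

## The charge-composition model

The package treats a protein as a polyelectrolyte characterised entirely by
its primary structure. At urine pH (6–7) the side chains of aspartate (D)
and glutamate (E) are deprotonated (−1 each) and those of lysine (K) and
arginine (R) protonated (+1 each); every other side chain is taken as
neutral. Each protein of length *N* is therefore summarised by

* total charge = D + E + K + R (a count of fixed-charge residues),
* net charge = (K + R) − (D + E) (signed),
* and their percentages, value / *N* × 100.

Percentages, not counts, are the primary comparison variable: they
normalise for the large molecular-weight range of urinary proteins
(a 25 kDa and a 100 kDa protein with the same charge density are the same
polymer from an electrostatics standpoint). Assumptions worth keeping in
mind:

* **Histidine is not a fixed charge.** Its pKa (~6.5) sits inside the urine
  pH band, so it is only fractionally charged there; it enters the
  pH-dependent titration model but never the fixed-charge counts.
* **Termini are excluded from the counts** (side chains only) but included
  in the titration model.
* **Post-translational modifications are ignored.** Glycosylation and
  phosphorylation would generally add negative charge; sequences are scored
  as translated, using the full canonical entry including any signal
  peptide.
* Ambiguity/rare codes (B, Z, X, U, O) are accepted, count toward length,
  and never toward charge — a charge sign cannot be assigned to an
  ambiguity code.

## Isoelectric-point classification

For pI classification the package uses the standard Henderson–Hasselbalch
superposition: at pH *p* each basic group contributes
n / (1 + 10^(p − pKa)) and each acidic group −n / (1 + 10^(pKa − p)),
summed over D, E, C, Y, H, K, R and the two termini. The curve is strictly
decreasing in pH, so the pI is the unique root on [0, 14], found by
bisection to 0.001 pH (deterministic). Compositions whose modeled charge
never crosses zero on the interval (only acidic, or only basic, groups —
possible when termini are excluded) pin to the boundary 0.0 or 14.0 rather
than erroring; an error is raised only when there is no ionizable group at
all. The default pKa table follows the values published with the EMBOSS
`iep` program (D 3.9, E 4.1, C 8.5, Y 10.1, H 6.5, K 10.8, R 12.5,
N-terminus 8.6, C-terminus 3.6); other tables can be registered by name.
Classification thresholds are strict: pI < 5 is extreme-anionic, pI > 9
extreme-cationic, boundary values intermediate. The pI is classification
support; the headline group comparison runs on the fixed-charge metric.

## Group construction and truncation

`build_groups` assigns phase preference from paired mean relative
abundances, as given, with no re-normalisation: a matrix-list protein whose
urine abundance exceeds its matrix abundance is reassigned to the
urine-preferring group; urine-list proteins enter that group when their
relative abundance strictly exceeds the cutoff (default 0.5 %) and they are
not already matrix-assigned. A configurable exclusion list (default:
ubiquitin, whose identity became ambiguous across sequence-database
releases) is removed from both sides and reported.

`truncate_by_net_charge` removes matrix proteins with net charge %
strictly beyond ±5 % (default), splitting them into anionic and cationic
tails — under the polyelectrolyte-complexation hypothesis these are the
aggregation triggers, and the scientific question is whether the *weakly*
charged remainder still out-charges the urine group. Boundary values
exactly at the cutoff are retained, truncation is never applied to the
urine group, and the three outputs partition the input exactly, which makes
the operation idempotent on its own retained set.

## Statistics

Both tests are two-tailed and tie-aware, with exact small-sample options:

* **Spearman correlation** — ρ is the product-moment correlation of
  average ranks. The permutation p enumerates all n! orderings for n ≤ 7,
  uses 20 000 seeded Monte-Carlo permutations for 8 ≤ n ≤ 10, and the
  Student-t approximation (n − 2 df) above; the method used is recorded on
  the result. A constant vector is an error (ρ undefined).
* **Mann–Whitney U** — U from rank sums with average ranks. With
  n1 + n2 ≤ 20 and no cross-group ties the null is enumerated exactly over
  all C(n1+n2, n1) assignments; the two-tailed p is twice the smaller tail
  of that realised null, capped at 1 — tails are evaluated at the observed
  U itself because with ties the mirrored value n1·n2 − U need not be
  attainable. Otherwise a normal approximation with tie correction and a
  0.5 continuity correction is used. The continuity correction shifts
  mid-range p upward by roughly 0.5/σ_U·φ(0) (~0.008 at n1 = n2 = 15), an
  accepted conservatism that vanishes in the tails where conclusions live.
* **Summaries** — median (mid-point rule for even n), mean, and sample
  standard deviation (n − 1); a singleton group reports sd 0.

## The synthetic-data generator

The generator exists so the full pipeline is exercisable and statistically
testable without any sequence downloads. Per protein it draws a length from
a log-normal law (median 400 residues, σ 0.55 on the log scale, clamped to
[50, 1500] — matching the 25–100 kDa bulk of urinary proteins), a target
total charge % from a normal law, and a target net charge % from a normal
mixture, re-drawing the pair until |net| ≤ total (real charge clouds obey
this constraint geometrically; independent draws would not). The sequence
is then composed exactly: round(L·(total+net)/200) basic residues split
uniformly K/R, round(L·(total−net)/200) acidic split D/E, the remainder
drawn from a background composition (default uniform over the 16
non-charged standard residues — downstream metrics are insensitive to it),
and all positions shuffled. Rescoring any generated sequence reproduces its
targets to within 100/L percentage points per metric, and generation is
byte-reproducible per seed.

The bundled scenario encodes the study conditions the analysis targets:
a matrix-like population (n = 52, total 25 ± 6 %, net mixture with weights
0.15/0.72/0.13 at −9/0/+8 %, component σ 2 %) and a urine-like population
(n = 38, total 20 ± 4 %, net 0 ± 2 %). The extreme-component weights total
0.28, so the ±5 % truncation removes about 28 % of a matrix-like sample
(~15 of 52). What the generator deliberately does **not** emulate: real
amino-acid background frequencies, domain structure, PTMs, abundance
distributions, or any correlation between length and charge — so passing
tests demonstrate the pipeline's correctness and calibration under the
stated laws, not biological realism of the sequences themselves.

A note on the scenario's statistical power: with truncated-matrix totals
≈ N(25, 6²) at n ≈ 37 against N(20, 4²) at n = 38, the analytic
normal-approximation power of the two-tailed Mann–Whitney test at α = 0.01
is Φ((Φ(5/√52) − ½)·√(12·37·38/76) − 2.576) ≈ 0.89, and the calibration
test observes rejection in the corresponding fraction of its 100 fixed
seeds. The scenario parameters are the study conditions and are not tuned
to raise this figure. Under identical laws for both groups the observed
rejection rate at α = 0.05 stays inside the 99 % binomial band around the
nominal level.

## Numerical and formatting choices

* Percentages are computed and compared at full double precision; rounding
  to one decimal happens only when writing metrics tables and plot data
  (both round identically, so they are bit-consistent with each other).
* Metrics TSVs round-trip: integer count fields read back exactly; the
  tables double as annotation inputs for count-only workflows.
* FASTA parsing accepts UniProt `db|ACC|ID` headers and plain ones;
  sequences are uppercased, whitespace/gap/stop characters stripped, and
  validated against the accepted alphabet with the offending record named
  in errors.
* Pipeline runs are deterministic end to end for a fixed config and seed;
  reports carry no timestamps. Stage failures propagate with the stage
  name; degenerate inputs (single protein, constant metric) mark the
  affected statistics "insufficient n" instead of crashing. A sensitivity
  re-run excluding the single highest-total-charge% protein is always
  included, guarding the conclusion against one extreme protein.

## Problem sizes in the test suite

Exactness checks enumerate where enumeration is cheap (Mann–Whitney
n1+n2 ≤ 10 against brute-force label permutation, 200+ fuzzed cases;
Spearman n ≤ 7 against full n! enumeration; pI against a 10⁻⁴-step grid
scan on 100+ random compositions). Calibration uses n = 500 populations
for parameter recovery and 100 seeds each for power, sensitivity-direction
and type-I checks. These sizes give stable verdicts at interactive
runtimes.

## Known limitations

* Fixed-charge counting ignores PTM-derived charge, so real glyco- and
  phosphoproteins are more negative than their scored values.
* The titration model uses a single pKa table and no charge–charge
  interaction or environment shifts; pI values are classification-grade,
  not predictions of measured isoelectric focusing.
* Phase-preference assignment consumes published mean abundances as given;
  it does not model abundance uncertainty.
* The Spearman p for 8 ≤ n ≤ 10 is Monte-Carlo (seeded, 20 000 draws), so
  it carries ~0.003 simulation error at p ≈ 0.05.
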