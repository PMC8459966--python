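# stonecharge

Fixed-charge composition analysis of proteins that partition between
calcium-oxalate kidney-stone matrix and urine.

## The problem

The organic matrix of calcium-oxalate (CaOx) kidney stones contains hundreds
of urinary proteins, but their relative abundances differ sharply from urine:
some proteins prefer the stone matrix phase (MPPs, matrix-preferring
proteins), others the urine phase (UPPs). One proposed nucleation mechanism
is polyelectrolyte complexation — strongly anionic and strongly cationic
proteins aggregate electrostatically, and the resulting coacervate-like
aggregates then selectively recruit more weakly charged proteins. If that is
right, phase preference should be readable from primary structure alone,
through the residues that carry fixed charges at urine pH 6–7: aspartate (D),
glutamate (E), lysine (K) and arginine (R).

`stonecharge` implements that analysis as a reusable, tested pipeline for
anyone working with urinary or stone-matrix proteomics lists: given protein
sequences (FASTA) or per-protein residue-count tables, it computes for each
protein of length *N*

```
total charge      = D + E + K + R
net charge        = (K + R) − (D + E)
total charge %    = total charge / N × 100
net charge %      = net charge  / N × 100
```

and then

1. builds MPP/UPP groups from paired matrix/urine abundance tables
   (urine-dominant matrix proteins are reassigned; urine proteins above a
   0.5 % relative-abundance cutoff are added; configurable exclusions),
2. tests the association between extreme net charge and high total charge
   (two-tailed Spearman correlation of net charge % vs net charge number),
3. truncates the MPP list at net charge % beyond ±5 % (the putative
   aggregation triggers, split into anionic and cationic tails),
4. compares total charge % of the weakly charged remainder against UPPs
   (two-tailed Mann–Whitney U with exact small-sample enumeration, plus a
   sensitivity re-run dropping the single most charged protein),
5. classifies isoelectric points (Henderson–Hasselbalch titration model,
   bisection root; extremes are pI < 5 and pI > 9), and
6. emits per-protein metrics tables and tidy cluster-plot data
   (total % vs net % per group).

A synthetic-population generator produces MPP-like and UPP-like protein sets
with controlled charge composition, so the entire pipeline runs and is
testable with no external downloads.

## Worked example

Score the bundled canonical human HMGB1 sequence (a classic matrix protein:
enormously charged overall, yet nearly neutral):

```sh
$ stonecharge score data/hmgb1_human.fasta --out hmgb1_metrics.tsv
$ cat hmgb1_metrics.tsv
id	accession	length	D	E	K	R	total_charge	net_charge	total_charge_pct	net_charge_pct
HMGB1_HUMAN	P09429	215	19	37	43	8	107	-5	49.8	-2.3
```

Of HMGB1's 215 residues, 107 (49.8 %) carry a fixed charge, but the positives
and negatives almost cancel (net −5, i.e. −2.3 %) — exactly the profile of a
weakly-net-charged protein that still prefers the matrix phase.

Run the full pipeline on the bundled synthetic scenario (52 MPP-like vs 38
UPP-like proteins):

```sh
$ stonecharge run --synthetic --seed 1 --out demo/
{
  ...
  "truncation": {"removed_anionic": 5, "removed_cationic": 7, "retained": 40},
  "spearman_net_pct_vs_net_charge": {"rho": 0.9720380191663447, "p_two_tailed": 3.973697437387294e-33, "n": 52, "method": "t_approximation"},
  "mann_whitney_total_pct": {"U": 1289.0, "p_two_tailed": 1.2689633811241377e-07, "n1": 40, "n2": 38, "method": "normal_approximation"},
  "truncated_mpp_total_pct": {"n": 40, "median": 26.909924769682583, "mean": 26.870349667072237, "sd": 4.643540767887929},
  "upp_total_pct": {"n": 38, "median": 21.116705024932873, "mean": 20.45578836902899, "sd": 4.272105289820435},
  ...
}
```

Reading the output: the ±5 % truncation removes 12 of 52 matrix-like proteins
(5 strongly anionic, 7 strongly cationic); net charge % correlates almost
perfectly with net charge number across the MPP set (ρ = 0.97); and the
weakly charged matrix remainder still carries significantly more total charge
than the urine group (≈ 27 % vs ≈ 20 % of residues, p ≈ 1.3 × 10⁻⁷). The
`demo/` directory receives the per-protein metrics TSVs, cluster-plot data
and the JSON report. Other verbs (`score`, `partition`, `compare`,
`simulate`) expose the individual stages; `stonecharge --help` lists them.

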