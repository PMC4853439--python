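# Methods

## Seed-site model

A miRNA represses a transcript primarily through its seed, nucleotides 2–7
from the 5′ end. `scan_sites` declares a site wherever a 6-base UTR window is
the exact reverse complement of a miRNA's seed (U ≡ T across the RNA/DNA
boundary); because the duplex is antiparallel, miRNA nt 8 faces the UTR base
immediately 5′ of that window and nt 1 faces the base immediately 3′ of it.
The canonical site classes are assigned as upgrades of the 6mer:

* **7mer-m8** — the 5′-flanking base pairs miRNA nt 8;
* **7mer-A1** — the 3′-flanking base is an adenine. We use the adenine
  convention (the base must be A whether or not it pairs nt 1), which is the
  standard definition; a pairing-based alternative is available as
  `a1_rule="pair"`;
* **8mer** — both conditions hold.

Each match is reported once at the highest class it attains, with the
footprint coordinates of that class (6, 7 or 8 bases, 1-based inclusive in
c.\* coordinates, where c.\*1 is the first base 3′ of the stop codon).
Alongside the class we report `match_len`, the maximal contiguous run of
Watson–Crick pairs through the seed duplex: the 6 seed pairs, extended
5′-ward on the UTR against miRNA nt 8, 9, … until the first mismatch, plus
the nt-1 position when it genuinely pairs. Reporting both quantities lets a
user check either reading of an "8-base site" claim — a canonical 8mer or 8
contiguous pairs across nt 1–8.

Numerical/edge choices: windows containing N never match; lowercase input is
uppercased and treated as normal sequence; G:U wobble is not counted as a
pair by default (`allow_wobble=True` to change) because the model is perfect
complementarity; only the sense (mRNA) strand is scanned; only
single-nucleotide substitutions are accepted. Two miRNAs with identical
seeds yield two sites — identity is (mirna_id, start, site_type), and that
key also defines gained/lost sets in `diff_sites`, making the diff exactly
symmetric under swapping ref and alt. Output order is (start, mirna_id),
so identical inputs give byte-identical output.

## Association model

The default 2×2 table is the carrier (dominant) model — subjects with at
least one minor allele versus the rest — because a rare heterozygous variant
is naturally summarised that way; an allele-count model is available
(`model="allele"`). The test is Pearson's χ² without continuity correction
(Yates by flag); p comes from the df = 1 χ² survival function, two-sided.
The odds ratio is (a·d)/(b·c) with the 95 % Woolf interval
exp(ln OR ± z₀.₉₇₅·√(1/a+1/b+1/c+1/d)); the Haldane–Anscombe +0.5 correction
is applied to all four cells only when some cell is zero. Fisher's exact
test uses the conventional conditional two-sided rule (sum of hypergeometric
probabilities ≤ the observed table's), with the tail-doubling rule by flag.
MAF is the minor-allele count over 2n, folded into [0, 0.5]. No
multiple-testing correction is applied: the pipeline tests a single
candidate variant. A Hardy–Weinberg χ² on the controls is logged but is not
a result.

The packaged study-scale genotype table
(`synthetic_data.reconstructed_study_genotypes`) is a deterministic,
synthetic reconstruction from published summary counts: 15/378 case
carriers, and control heterozygote counts recovered from the reported
control minor-allele frequencies (round(0.009·2·1576) = 28 and
round(0.007·2·294) = 4, 32 of 1870 pooled). It reproduces the published
χ² p-value and odds ratio exactly, which is the consistency check that the
reconstruction — which is not itself printed as per-cell digits — is right.
No homozygous-minor subjects are included (none were reported), though the
code handles C/C generally.

## Phenotype statistics

Two-group comparisons default to the pooled-variance Student t test
(df = n₁+n₂−2), matching the common practice for ECG-interval comparisons;
Welch is a flag. The paired t acts on pre-computed differences. One-way
ANOVA uses the standard between/within decomposition; pairwise comparisons
reuse the pooled within-group mean square with df = N−k and are
Šidák-adjusted, p_adj = 1−(1−p)^m, where the family m is the explicitly
requested comparison list (e.g. each treatment against the same control),
not all pairs. All tests are two-sided. Summaries are mean ± SEM
(sd/√n, sample sd); at n = 1 the mean is reported and SEM and tests are
refused. Missing values are dropped per comparison and the drop counts
logged.

## qPCR quantification

Plasma miRNA is normalised to a fixed-amount spike-in added per fixed plasma
volume; expression is 2^−(Ct_target − Ct_spike) with no volumetric
correction — the spike-in input bookkeeping is metadata. Tissue mRNA uses a
housekeeping gene identically on triplicate-mean Cts; ΔCt is computed on
aggregated means, the usual instrument-software convention, not on
per-replicate pairings. Triplicates whose max pairwise spread exceeds 1.0
cycles (configurable) lose the single replicate farthest from the median
before averaging; no published rule exists for this, so it is a package
choice. Group fold change is the ratio of group mean expression values,
compared on the 2^−ΔCt scale by default (a log2 option exists, since the
scale of comparison is a genuinely open choice). Reporter assays form
per-well channel ratios with configurable orientation (reporter over
normalizer), average wells within a condition, and divide by the control
condition; fold changes are invariant to rescaling all raw luminescence.

## Synthetic-data generator

The generator exists so each stage can be validated closed-loop, and its
defaults are the study conditions, fixed once: 378 cases with carrier
probability 15/378 and 1870 controls with 32/1870 (implied generating odds
ratio 2.37); PR interval Normal(175, 20) ms shifted +30 ms in carriers so
the carrier mean (205 ms) crosses the 200 ms prolonged-conduction threshold
— cohort means are shown only graphically in the source study, so these
magnitudes are illustrative but clinically realistic; RR/QRS/QT
genotype-independent normals at typical adult values; plasma target Ct
Normal(30, 0.5) shifted +log2(3) ≈ 1.585 cycles in carriers against a
spike-in at Normal(20, 0.3), making the expected carrier/noncarrier
expression ratio exactly 1/3; UTR background uniform over {A,C,G,T}
(no GC bias by default); no homozygous-minor genotypes by default.

`plant_gain_variant` writes the alt-allele site of the requested class into
a random background, breaks it at one seed position on the reference allele,
suppresses incidental upgrades at the flanks, and verifies with the scanner
itself that the ref allele has no site and the alt allele exactly one,
resampling the background a bounded number of times. All generators are
pure functions of (config, seed).

What the generator does **not** emulate: linkage structure, population
stratification, genotyping error, non-normal ECG tails, qPCR efficiency
differences or plate effects. Passing closed-loop tests therefore
demonstrates correctness of the arithmetic under the stated model, not
robustness to real-cohort messiness.

## Validation design and problem sizes

The scanner is validated against an independent window-by-window enumeration
oracle (1,000 random instances, UTR ≤ 200 nt, library ≤ 50) and by diff
symmetry on 1,000 random variants. Fisher's exact p is checked against full
hypergeometric enumeration for every 2×2 table with total count ≤ 40,
exhaustive over symmetry-orbit representatives (row/column swap and
transposition invariance is itself asserted). t/F/χ² worked examples are
checked to 1e-6 against hand-derived values and numerically integrated
hand-written densities. Odds-ratio recovery uses 500 seeded cohort
replicates at the default configuration: nominal-95 % Woolf CI coverage must
land in [93 %, 97 %] and the median OR within ±20 % of the generating 2.37;
a null configuration (equal carrier probabilities) must give a median OR in
[0.8, 1.25]. Expression recovery uses 400 subjects split evenly by carrier
status. These sizes were chosen to make sampling error small relative to
each tolerance while keeping the suite quick.

## Known limitations

* No thermodynamic or context scoring; a seed match is necessary, not
  sufficient, for repression in vivo.
* Only c.\* SNVs are parsed — no indels, haplotypes or full HGVS grammar.
* The association module handles a single biallelic variant; it is not a
  GWAS tool (no covariates, no logistic regression).
* Amplification-efficiency correction and standard curves are out of scope;
  the 2^−ΔCt model assumes ~100 % efficiency for all assays.
* Validation of a specific published site prediction requires the real
  miRNA and UTR sequences, which this package does not download; the
  equivalent property is exercised on planted synthetic sites.
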