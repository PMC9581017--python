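# Methods

## Data model

Each sample is a table of peptide records: a raw sequence as exported by
the search engine, a cleaned sequence (parenthesised modification
annotations such as `M(+15.99)` and all non-letter characters stripped,
uppercased — this is what gets matched against FASTA), a UniProt
precursor accession, an intensity, a spectral count, and optional
retention time (minutes) and collision cross section (Å²). Exactly two
groups of samples are compared. Records whose accession is not in the
supplied proteome are discarded and counted; isoform accessions
(`P07911-2`) fall back to their base form. Duplicate rows with the same
cleaned sequence (e.g. modification variants) are kept as separate
records for abundance aggregation and collapsed to one sequence wherever
set semantics apply (peptide table rows, Venn counts). Blank or
non-numeric abundance cells become 0, since PEAKS leaves unquantified
features blank.

## Pre-processing chain

Order is fixed: log10 → normalization → peptide cutoffs → protein
cutoffs.

**log10.** Intensities v > 0 become log10(v); zeros stay 0 and are
flagged as missing rather than treated as abundance 1. The transform can
be skipped for data already on a log scale. Spectral counts are never
transformed.

**Normalization.** Both modes multiply every value of a sample by one
scale factor, independently for intensity and spectral count:

* global: factor = mean over samples of the sample totals, divided by
  this sample's total. Consequences (tested as invariants): the grand
  total is conserved, all nonzero sample totals become equal, and the
  operator is idempotent.
* housekeeping: the same with the per-sample totals of one anchor
  protein, the mean taken over the samples that contain it; samples
  without the protein are left unaltered. After application the anchor's
  total is equal across all samples containing it.

Samples with a zero total skip normalization with a warning. The
housekeeping formula can be read either as scaling only the anchor's
peptides or as scaling the whole sample; the whole-sample scale-factor
reading is implemented, since normalizing only the anchor would leave
the rest of the sample unbiased-corrected and defeat the purpose of an
anchor protein.

**Peptide cutoffs.** Records with intensity or spectral count strictly
below their thresholds are removed (equality survives: "below" means
<). RT and CCS outliers are flagged per sample — drift in these
quantities is a per-run phenomenon — as values strictly more than
3 population standard deviations from the sample mean. Values exactly at
mean ± 3σ survive. With fewer than 3 finite values or zero σ nothing is
flagged; missing values never are. On Gaussian data this retains 99.7%
of values (68-95-99.7 rule), which the acceptance script verifies on
10⁵ draws.

**Protein cutoffs** run after peptide cutoffs and are evaluated per
sample: a protein is dropped from a sample when its surviving records'
cumulative intensity or spectral count is below threshold or when fewer
than the minimum number of records remain. A protein can therefore
survive in one sample and not another, consistent with the per-sample
abundance model of the protein view.

## Protein-level comparison

Four metrics: sum or mean of intensity or spectral count over a
protein's records, per sample. Group statistics (mean, SD with n−1
denominator) are computed over the samples where the protein is present;
absence is missing data, not zero. With a single present sample the SD
is reported as 0 (no spread estimate exists). The difference score is
the absolute difference of group means. The group test is a two-sided
Welch (unequal-variance) t-test on the per-sample values, computed only
when both groups have ≥ 3 present samples; otherwise the p-value is
withheld (blank in the protein table, literal −1 in the peptide table).
Zero-variance degenerate cases are defined as p = 1 for identical
constant groups and p = 0 for different constant groups. No
multiple-testing correction is applied — p-values are exploratory
ranking aids, not confirmatory inference; apply Benjamini–Hochberg or
similar downstream if needed.

## Peptide-level coverage

Peptides are located at the first occurrence of their cleaned sequence
in the precursor FASTA sequence; coordinates are 1-based inclusive (a
19-mer starting at 588 ends at 606). Peptides occurring more than once
are counted at the first occurrence only; peptides not found at all
(isoform or database-version mismatches) are excluded from profiles and
listed in the profile's `unlocated` field. Per position, the overlap
count is the number of located records covering that residue and the
height is the sum of their metric values; in group-mean mode the height
is divided by the number of samples in the group (all samples, including
those without the protein), so stacked per-sample heights sum to
n_samples × group mean. The weight is the plain sum of the metric over
the scope's located records. The difference trace is the signed
element-wise height difference A − B.

## Characteristics

Computed per group over the pooled records of all the group's samples
(not per-sample averaged), for the whole peptidome or one protein. The
length distribution adds each record's metric value to its sequence
length's bin, so total bin mass equals the scope's total metric. Venn
counts use unique cleaned sequences irrespective of precursor. Amino-acid
profiles weight each residue (or only the first/last residue) by the
record's metric value and normalize to fractions; the letters
B, J, O, U, X, Z are skipped with a logged count.

## Synthetic data generator

`fixtures.FixtureSpec` defines one synthetic two-group experiment.
Defaults emulate a modest label-free peptidomics comparison: 20 proteins
of 200–400 residues, 5 samples per group, 10–30 peptides of 7–25
residues per protein, intensities 10^N(6, 0.8) (generated on the linear
scale so the log10 step is exercised), per-sample global bias
N(0, 0.15) log units emulating loading/instrument drift, spectral counts
1 + Poisson(5), RT ~ N(30, 5) min and CCS ~ N(400, 40) Å² with 1% gross
outliers displaced by 8–12 σ, and each pool peptide present in a given
sample with probability 0.9. Differential proteins get a log10 offset
added to their group-B intensities. Every sample draws from a stream
keyed by (seed, sample id), so adding samples never perturbs existing
ones, and all outputs are byte-identical under a fixed seed. A manifest
records true peptide locations, sample biases, outlier identities and
offsets for ground-truth tests.

What the generator does *not* emulate: missingness correlated with
abundance, shared chimeric/degenerate peptides across proteins, RT/CCS
structure (values are independent of sequence), modification strings in
exported sequences, or search-engine FDR behaviour. Passing tests
therefore demonstrate the pipeline's arithmetic and its recovery of
planted signals under idealized noise, not performance on real
instrument data.

## Numerical and design choices

* Tolerances: normalization invariants hold to 1e-9 relative; Welch
  p-values are compared to the reference implementation to 1e-9.
* Ties/degenerates: first FASTA record wins on duplicate accessions;
  first occurrence wins on repeated substrings; empty scopes yield empty
  (not error) outputs; an empty group of samples is an error.
* Problem sizes in the test suite (200-protein coverage oracle, 10⁵-draw
  Gaussian check, 5+5-sample recovery runs) were chosen as the smallest
  sizes at which the checked properties are unambiguous.
* The CLI config is YAML; table exports are CSV; characteristics export
  is JSON; figures are static matplotlib SVG/PNG. Exit codes: 0 success,
  2 config error, 3 ingestion error, 4 unknown accession.

## Limitations

Only two groups; only the two normalization schemes above (no quantile /
median / VSN, no imputation); no multiple-testing correction built in;
protein inference is taken from the input's accession column as-is; the
proteome FASTA must be supplied by the user and should match the
database used for the search, otherwise peptides fail location and are
excluded from coverage (they remain in abundance statistics).
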