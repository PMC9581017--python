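# peptidiff

Quantitative comparison of two groups of peptidomic samples.

Endogenous peptidomics (urine, wound fluid, CSF, ...) produces, per LC-MS/MS
run, a table of thousands of peptides with their precursor protein, an
intensity (chromatographic peak area) and a spectral count. Comparing a
patient group against a control group from such tables requires a chain of
unglamorous but consequential steps — log transformation, inter-sample
normalization, outlier and abundance filtering, peptide-to-protein
aggregation, per-residue coverage mapping — before any biology is visible.
`peptidiff` implements that chain as a library plus a small CLI, emitting
CSV/JSON tables and static figures.

## What it computes

Given per-sample CSVs (PEAKS-style column names such as `Peptide`,
`Accession`, `Area`, `SpC`/`#Feature`, optional `RT`/`CCS`, resolved
case-insensitively) and a proteome FASTA:

1. **Pre-processing** — intensities are log10-transformed (MS intensities
   are roughly log-normal; downstream tests assume Gaussian values).
   Optional normalization rescales each sample by a single factor per
   metric: *global*, N = (∑ⱼ Sⱼ / m) · p / ∑ᵢ pᵢ, equalizing every sample's
   total to the across-sample mean total; or *housekeeping*, the same with
   the totals of one user-chosen anchor protein (samples lacking it are
   left unaltered). Cutoffs then remove peptides below intensity /
   spectral-count thresholds and per-sample retention-time or CCS outliers
   beyond mean ± 3σ (the 68-95-99.7 rule, population σ, strict inequality);
   protein-level cumulative-abundance and minimum-peptide cutoffs are
   applied *after* peptide cutoffs.
2. **Protein view** — per protein and sample, the sum or mean of intensity
   or spectral count; per group, the mean ± SD over samples where the
   protein is present (absence is missing, not zero). The score
   |mean_A − mean_B| ranks proteins; a two-sided Welch t-test on the
   per-sample values gives a p-value when the protein appears in ≥ 3
   samples of each group (raw, no multiple-testing correction).
3. **Peptide view** — each peptide is located at its first occurrence in
   the precursor sequence (1-based inclusive coordinates); per-residue
   profiles count overlapping peptides and sum their abundance, stacked by
   sample or averaged per group, with an A−B difference trace. The peptide
   table reports group mean ± SD and the Welch p-value, printing the
   literal −1 when a peptide is present in fewer than 3 samples of either
   group.
4. **General characteristics** — abundance-weighted peptide-length
   distribution (a spectral count of 10 contributes twice a spectral count
   of 5), unique/shared/unique Venn counts of the two peptide sets, and
   abundance-weighted amino-acid profiles for the full sequence and the
   N-/C-terminal residues.

A deterministic synthetic-data generator (`peptidiff.fixtures`) emulates
PEAKS exports — peptides that are true substrings of a toy proteome,
log-normal intensities with per-sample bias, Poisson spectral counts,
injected RT/CCS outliers, optional planted differential proteins — with a
ground-truth manifest, so the whole pipeline is testable offline.

## Worked example

```sh
peptidiff fixtures --seed 42 --out data --n-proteins 8 --samples-per-group 5
peptidiff run --config config.yaml          # ingest + preprocess + protein view
peptidiff peptide-view --config config.yaml --accession PX0001
peptidiff characteristics --config config.yaml
```

with `config.yaml`:

```yaml
group_a: {label: groupA, files: [data/A1.csv, data/A2.csv, data/A3.csv, data/A4.csv, data/A5.csv]}
group_b: {label: groupB, files: [data/B1.csv, data/B2.csv, data/B3.csv, data/B4.csv, data/B5.csv]}
proteome: data/proteome.fasta
normalization: {mode: global}
cutoffs: {drop_rt_outliers: true}
metric: sum-intensity
output_dir: out
```

`out/protein_table.csv` then begins:

```
  mnemonic accession  n_peptides_a  n_peptides_b  mean_a   sd_a  mean_b  sd_b  difference  p_value
SYN001_TOY    PX0001           122           116 144.822  8.263 140.676 9.293       4.145    0.478
SYN002_TOY    PX0002           124           122 153.332  8.044 148.626 9.610       4.706    0.426
SYN003_TOY    PX0003           113           109 135.201 12.569 131.419 2.659       3.782    0.544
```

`mean_a`/`mean_b` are per-group means of the per-sample summed log10
intensities after global normalization; with no planted differential
signal, differences are small and no p-value is significant. The peptide
view for PX0001 lists each located peptide with its coordinates and group
statistics, e.g.

```
        sequence  start  end  mean_a  sd_a  mean_b  sd_b  n_samples_a  n_samples_b  p_value
CECYKQLYLINSGLAP     68   83   6.148 0.775   6.311 0.619            5            5    0.724
  CIQCWSDIFCIAQQ    171  184   5.673 0.244   6.327 0.195            4            5    0.005
```

and the peptidome characteristics JSON reports
`venn: {unique_a: 0, shared: 181, unique_b: 0}` — with the default 90%
per-sample presence probability, both groups draw the same peptide pool.

## Scope

`peptidiff` is the headless counterpart of interactive peptidome
visualisation web tools: it covers their computation (processing,
comparison, coverage, characteristics) but not web serving, hover
interactivity or live UniProt lookups — the proteome FASTA is always
supplied by the user.
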