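# Methods

## Problem and data model

Family-based genetic studies routinely shuttle the same pedigree +
genotype data between many analysis programs, each with its own input
dialect. `genodb` keeps one validated copy of the data in a single
SQLite file and serves it out on demand: as decoded genotype matrices
for region- or gene-based tests, or re-serialized as VCF or transposed
PLINK for external tools.

The database is a set of flat tables joined by integer *link* fields
(`locus_link`, `pedigree_link`, `person_link`) instead of foreign-key
cascades, so any subset of tables can be merged cheaply in pandas.
Two tables carry raw byte payloads:

- **phenotype_table** — one blob per person, 8 bytes per trait. An
  affection trait stores two little-endian int32s `(status, class)`
  with the LINKAGE coding 0 = unknown, 1 = unaffected, 2 = affected; a
  quantitative trait stores one little-endian float64, with −99.99 as
  the missing sentinel (kept even though NaN exists, so payloads match
  what a C producer would write byte-for-byte). Endianness is fixed to
  little regardless of platform, so database files are portable.
- **genotype_table** — one blob per person per chromosome, 2 bits per
  biallelic genotype, four genotypes per byte, first genotype in the
  least significant bit pair, following the PLINK .bed convention:
  `00` hom index-1, `01` missing, `10` het, `11` hom index-2. The
  payload is padded to a byte boundary, so up to three trailing
  "virtual marker" slots exist per chromosome.

## Offset arithmetic and lazy decoding

A session concatenates every person's per-chromosome vectors into one
*unified* vector, virtual markers included, and records a gap ledger:
per chromosome, the genome-wide ordinal of its first marker and the
2-bit slot where it starts (slots advance by `4⌈m_c/4⌉`). A marker's
`unified_offset` is then its `raw_offset` plus the accumulated padding
of preceding chromosomes, computable in O(#chromosomes). Decoding a
marker touches exactly one byte column of the unified matrix, so the
cost of any query is proportional to the markers requested, not to the
genome — this is what makes gene-by-gene iteration over a large panel
cheap.

Three decoders share this path and are mutually consistent through the
allele-index map:

- label pairs (`"12"`, `"AC"`; missing `"00"`),
- raw integers `(index₁ << 16) | index₂` (65537, 65538, 131074;
  missing 0). The phase-bearing code 131073 (2/1) is never produced —
  the packed format is unphased and normalizes heterozygotes to lower
  index first — but it is accepted by the dosage recode for
  compatibility with data encoded elsewhere,
- dosages 0/1/2 of the non-major allele (flip `d ← 2 − d` whenever the
  stored index-1 frequency is below 0.5), with NaN for missing. This is
  the input form burden/kernel-style gene tests expect, alongside the
  affection recode 0/1/2 → NaN/0/1.

## Import procedure

`.ped`/`.map` parsing is strict: ragged rows and non-numeric positions
report 1-based line numbers; more than two observed alleles at a marker
is refused outright (the 2-bit format cannot hold it). Markers are
sorted by (chromosome, physical position); a 4-column map whose third
column is not all zeros contributes a genetic map (number 0, cM) in
addition to the physical map (number 1, bp).

Allele frequencies are counts over non-missing calls; allele index 1 is
assigned to the major allele at import (ties broken lexicographically),
which makes downstream major-allele flips no-ops for freshly imported
data. Monomorphic markers get a placeholder second allele at frequency
0; all-missing markers are flagged in the import report.

Mendelian validation is a single trio pass over nuclear families: a
child genotype is inconsistent if it cannot receive one allele from
each non-missing parent genotype (each parent is checked independently,
so one missing parent still constrains homozygous children).
Inconsistent offspring genotypes are set to missing and counted; the
count is reported rather than treated as an error. Sex chromosomes are
stored as given, with no hemizygosity handling.

## Region iteration

Range inclusion is 1-based and inclusive at both ends
(`start ≤ pos ≤ end`), evaluated against the physical map. Range tables
are given with an R-style 1-based column-index vector; when no name
column is indicated, names are generated as `chr{c}:{start}-{end}`.
Gene selection resolves exact symbol first, then alias; every matching
transcript produces its own callback invocation (no union of
overlapping transcripts), and duplicate transcripts — same gene, same
start/end — are removed when the annotation table is loaded. Strand is
carried but never used for selection. Ranges with no markers are
skipped, with a printed diagnostic when the session is verbose.

## Fisher exact scan

For each marker the scan tabulates the fam trait against the genotype
label categories (missing genotypes excluded) and computes the
two-sided exact p-value by enumerating all tables with the observed
margins, summing the multivariate hypergeometric probabilities of the
tables no more probable than the observed one. As is conventional for
exact tests, "no more probable" is applied with a relative tolerance of
1e-7 on the probability, so results are comparable with other exact
implementations to well below 1e-10. Tables that degenerate to a single
row or column (e.g. a monomorphic marker) yield NaN rather than an
error. The 2-row case (the common trait-vs-genotype shape) is
enumerated vectorized over the first row; larger tables fall back to a
cell-by-cell recursion with feasibility pruning, which is practical for
the small category counts this scan produces but would not scale to
large many-row tables.

## Exporters

VCF output is v4.2, REF = allele index 1 (the major allele at import),
ALT = index 2, genotypes unphased (`0/0`, `0/1`, `1/1`, `./.`). The
body is written in fixed-size marker chunks (default 1,000) so peak
memory is bounded by the chunk; output bytes are identical for any
chunk size, and the `##filedate` header can be pinned for byte-level
reproducibility. Sidecars: `.fam` (6 columns), `.freq` (marker, allele,
frequency), `.map` (one row per marker per stored map), `.phe` (decoded
phenotypes; missing quantitative values written as `-9` in the PLINK
convention while −99.99 remains the internal sentinel), and `.pen` — a
documented stub assigning one fully penetrant class per affection
trait, because PLINK-style input carries no penetrance metadata. The
`.tped` writer emits real allele labels, lower index first, `0 0` for
missing.

## Synthetic data generator

The generator exists so every layer is testable without downloads. Its
defaults reproduce the scale the package is documented against: 20
nuclear pedigrees × (2 founders + 67 offspring) = 1,380 persons, 1,000
biallelic markers on a sub-range of chromosome 1 (positions 2–13 Mb),
MAF uniform on [0.05, 0.5], 1% missing genotypes, and one
affection-status trait with both genetic (cM = bp/10⁶) and physical
maps. Founder genotypes are Hardy–Weinberg draws at the true MAF;
offspring receive one gamete per parent, so generated trios are
Mendelian-consistent unless an error rate is injected. Affection status
is an independent Bernoulli draw at prevalence 0.5 — a balanced
case/control-style sheet with no genetic model, which is the right null
for exercising the Fisher scan; a single causal-marker odds-ratio knob
exists for power smoke tests.

What the generator does *not* emulate — and what passing tests
therefore do not establish about real data: linkage disequilibrium
between markers, realistic site-frequency spectra, varied pedigree
structures (loops, multiple generations, half-sibs), sex-linked
inheritance, genotyping-error structure beyond uniform missingness, and
any genotype–phenotype architecture beyond the single optional causal
marker.

## Test-suite problem sizes and oracles

Unit fixtures are small (5 pedigrees, ~40 markers, two chromosomes);
end-to-end checks run at the full 1,380 × 1,000 scale, which imports in
about two seconds. Oracles are independent of the paths they check:
bit-level decoding against a per-bit-pair brute force over all 256 byte
values; offset arithmetic against slot-by-slot enumeration; range
selection against a linear scan; the fam merge against a nested-loop
join; Fisher p-values against SciPy's exact 2×2 routine and R's
`fisher.test` for wider tables (SciPy's r×c default is Monte Carlo and
is not used as an oracle); VCF output against re-parsing with
cyvcf2/htslib. MAF recovery is judged on founder chromosomes, where the
binomial sampling model is exact — offspring genotypes are transmitted
copies of founder alleles and carry little extra frequency information,
so a whole-sample binomial standard error would be overconfident by
roughly √(n/(2·pedigrees)).

## Known limitations

Phase and multi-allelic markers are not representable in the 2-bit
path (legacy 2-byte polymorphic payloads are carried but not decoded);
pedigree loop-breaking is not implemented (the `*_brkloop` tables are
verbatim copies); the database supports a single writer; and dosage /
imputation-probability fields are passed through untouched.
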