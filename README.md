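# genodb

A SQLite-backed datastore for family genetic data with bit-packed
biallelic genotypes, lazy region-wise decompression, a gene/range
iteration framework, dosage recoding for gene-based tests, and
exporters to VCF and transposed PLINK.

## Who it is for

Statistical geneticists running gene- or region-based association
scans on pedigree data. A study's pedigree, marker, map, allele,
phenotype and genotype tables are validated once, stored in a single
portable SQLite file, and then served out repeatedly: as decoded
genotype matrices for the markers inside each gene transcript, as 0/1/2
minor-allele dosage matrices for burden/kernel tests, or re-serialized
as VCF / `.tped` for external programs.

## The core design

Genotypes at a biallelic marker take one of four states — homozygous
for allele 1, heterozygous, homozygous for allele 2, missing — so each
genotype needs only two bits. `genodb` packs four genotypes per byte
per person per chromosome (PLINK `.bed` bit convention, first genotype
in the least significant pair), pads each chromosome to a byte boundary
(up to three trailing "virtual marker" slots), and concatenates the
chromosome vectors into one unified vector per person. A small gap
ledger converts a marker's genome-wide ordinal (`raw_offset`) into its
slot in the unified vector (`unified_offset`), so decoding a set of
markers touches only their bytes: iterating over thousands of gene
regions never decompresses the whole panel.

On top of that sit:

- an importer for PLINK-style `.ped`/`.map` files that computes allele
  frequencies (index 1 = major allele), zeroes and counts
  trio-Mendelian inconsistencies, and packs the genotypes;
- a session layer that merges pedigree/person/phenotype tables into an
  8-column `fam` sample sheet and keeps phenotype rows, genotype rows
  and `fam` aligned under pruning;
- an iteration framework — `apply_to_ranges`, `apply_to_genes`,
  `apply_to_markers` — that invokes a user callback
  `(markers, range, session)` for every range or transcript containing
  markers, plus a bundled per-variant scan computing two-sided Fisher
  exact p-values (trait × genotype category) by full hypergeometric
  enumeration;
- exporters (VCF v4.2 written in 1,000-marker chunks with `.fam`,
  `.freq`, `.map`, `.phe`, `.pen` sidecars; PLINK `.tped`/`.tfam`);
- a seeded simulator of Mendelian-consistent nuclear-family datasets so
  everything above is testable without external data.

## Worked example

```python
import genodb
from genodb.synthdata import SimulationSpec, simulate_dataset
from genodb.regions import fisher_scan, genotype_counts

spec = SimulationSpec(seed=1)          # 20 pedigrees, 1,380 persons, 1,000 SNPs
ds = simulate_dataset(spec, "tut")
db, report = genodb.build_database(ds.ped_path, ds.map_path, "tut.db")
ses = genodb.open_session(db)
print(ses.counts())

ann, _ = genodb.simulate_annotations(spec, ds.markers, n_genes=3)
genodb.set_annotations(ses, ann)

def cb(markers, rng, session):
    print(genotype_counts(markers.iloc[:3], session).to_string(index=False))
    print(fisher_scan(markers.iloc[:3], rng, session).to_string())

genodb.apply_to_genes(ses, cb, genes=["GENE1"])
```

prints

```
{'locus_count': 1001, 'phenotype_count': 1, 'marker_count': 1000,
 'sample_count': 1380, 'compression': '2 bits', 'bits_per_genotype': 2.0}
MarkerName  n11  n12  n22  n_missing
    snp262  640  563  167         10
    snp263  372  685  306         17
    snp264  645  592  137          6
snp262    0.347901
snp263    0.276083
snp264    0.184835
...
```

The counts line says the database holds 1,001 loci (1,000 markers plus
the affection trait), stored at 2 bits per genotype. Each `n11/n12/n22`
row is the genotype histogram of one marker inside the `GENE1`
transcript, with allele 1 the major allele; the values below are the
per-marker Fisher exact p-values of trait against genotype — null
(uniform-ish) here, since the simulated trait has no genetic model.

The same steps are available from a shell:

```sh
genodb simulate --seed 1 --out tut
genodb import --ped tut.ped --map tut.map --db tut.db
genodb summary --db tut.db
genodb scan --db tut.db --ranges ranges.tsv --indices 1,2,3 --test fisher --out p.tsv
genodb export-vcf --db tut.db --out tut
```

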