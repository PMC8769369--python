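chip seq
chip sequencing
chip-chip
chip-seq
chip-sequencing
chromatin immunoprecipitation followed by sequencing
clinicogenomic
clinicogenomics
clip seq
clip sequencing
clip-seq
clip-sequencing
epigenome
epigenomes
epigenomic
epigenomics
eqtl
eqtls
exome
expression quantitative trait loci
ewas
genome
genome-scale
genome-wide
genomes
genomic
genomics
glycome
glycomes
glycomics
glycoproteome
glycoproteomes
glycoproteomic
glycoproteomics
gwas
high-throughput nucleotide sequencing
hits seq
hits sequencing
hits-seq
hits-sequencing
in situ proximity ligation
in-situ proximity ligation
interactome
interactomes
interactomic
interactomics
metabolome
metabolomes
metabolomic
metabolomics
metagenome
metagenomes
metagenomics
microarray
microarrays
multi-ome
multi-omes
multi-omic
multi-omics
multiome
multiomes
multiomic
multiomics
next generation sequencing
next generation-sequencing
next-generation sequencing
next-generation-sequencing
ngs
nutrigenome
nutrigenomes
nutrigenomic
nutrigenomics
oligonucleotide array sequence analysis
omics
onco-genome
onco-genomes
onco-genomics
onco-proteogenome
onco-proteogenomes
onco-proteogenomic
onco-proteogenomics
oncogenome
oncogenomes
oncogenomics
oncoproteogenome
oncoproteogenomes
oncoproteogenomic
oncoproteogenomics
par-clip
pharmacogenome
pharmacogenomes
pharmacogenomic
pharmacogenomics
phenome
phenomes
phenomic
phenomics
phosphoproteome
phosphoproteomes
phosphoproteomic
phosphorpoteomics
protein array
protein array analysis
protein interaction map
protein interaction mapping
protein interaction maps
protein interaction network
protein interaction networks
protein–protein interaction map
protein–protein interaction mapping
protein–protein interaction maps
protein–protein interaction network
protein–protein interaction networks
proteogenome
proteogenomes
proteogenomic
proteogenomics
proteome
proteomes
proteomic
proteomics
radiogenome
radiogenomes
radiogenomic
radiogenomics
rna seq
rna sequencing
rna-seq
rna-sequencing
rnaseq
toxicogenome
toxicogenomes
toxicogenomic
toxicogenomics
transcriptome
transcriptomes
transcriptomic
transcriptomics
wes
wgs
whole-exome
whole-genome
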