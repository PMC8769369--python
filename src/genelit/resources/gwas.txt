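gwas
genome wide association study
genome-wide association study
gwa study
gwa studies
whole genome association study
genome wide association scan
genome wide association analysis
genome-wide association scan
genome-wide association analysis
twas
transcriptome wide association study
transcriptome-wide association study
twa study
twa studies
whole transcriptome association study
transcriptome wide association scan
transcriptome wide association analysis
transcriptome-wide association scan
transcriptome-wide association analysis
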