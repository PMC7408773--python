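# Editable region definitions for constitutional MLH1 epimutation screening.
# GRCh37/hg19 coordinates, BED 0-based half-open.  MLH1_DMR is the ~1.6 kb
# differentially methylated region spanning the shared EPM2AIP1-MLH1
# promoter CpG island reported for constitutional epimutation carriers;
# MLH1_C and MLH1_D are the promoter subregions targeted by MS-MLPA
# confirmation.  Coordinates are approximate transcriptions and editable.
chr3	37033791	37035391	MLH1_DMR	dmr
chr3	37034595	37034665	MLH1_C	promoter
chr3	37034730	37034855	MLH1_D	promoter
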