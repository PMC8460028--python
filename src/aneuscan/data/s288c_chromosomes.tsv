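chrom	length
chr1	230000
chr2	813000
chr3	317000
chr4	1532000
chr5	577000
chr6	270000
chr7	1091000
chr8	562000
chr9	440000
chr10	746000
chr11	667000
chr12	1078000
chr13	924000
chr14	784000
chr15	1091000
chr16	948000
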