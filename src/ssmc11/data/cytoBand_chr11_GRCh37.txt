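# UCSC cytoBand format (chrom, chromStart, chromEnd, name, gieStain), 0-based half-open, GRCh37/hg19, chromosome 11 ideogram
chr11	0	2800000	p15.5	gneg
chr11	2800000	10700000	p15.4	gpos50
chr11	10700000	12700000	p15.3	gneg
chr11	12700000	16200000	p15.2	gpos50
chr11	16200000	21700000	p15.1	gneg
chr11	21700000	26100000	p14.3	gpos100
chr11	26100000	27200000	p14.2	gneg
chr11	27200000	31000000	p14.1	gpos75
chr11	31000000	36400000	p13	gneg
chr11	36400000	43500000	p12	gpos100
chr11	43500000	48800000	p11.2	gneg
chr11	48800000	51600000	p11.12	gpos75
chr11	51600000	53700000	p11.11	acen
chr11	53700000	55700000	q11	acen
chr11	55700000	59900000	q12.1	gpos75
chr11	59900000	61700000	q12.2	gneg
chr11	61700000	63400000	q12.3	gpos25
chr11	63400000	65900000	q13.1	gneg
chr11	65900000	68400000	q13.2	gpos25
chr11	68400000	70400000	q13.3	gneg
chr11	70400000	75200000	q13.4	gpos50
chr11	75200000	77100000	q13.5	gneg
chr11	77100000	85600000	q14.1	gpos100
chr11	85600000	88300000	q14.2	gneg
chr11	88300000	92800000	q14.3	gpos100
chr11	92800000	97200000	q21	gneg
chr11	97200000	102100000	q22.1	gpos100
chr11	102100000	102900000	q22.2	gneg
chr11	102900000	110400000	q22.3	gpos100
chr11	110400000	112500000	q23.1	gneg
chr11	112500000	114500000	q23.2	gpos50
chr11	114500000	121200000	q23.3	gneg
chr11	121200000	123900000	q24.1	gpos50
chr11	123900000	127800000	q24.2	gneg
chr11	127800000	130800000	q24.3	gpos50
chr11	130800000	135006516	q25	gneg
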