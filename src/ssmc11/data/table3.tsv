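# The five informative clinically normal carriers whose demonstrated trisomy
# intervals bound the minimal pericentric triplo-insensitive span.
# arm_class here records which arm the case is informative for.
case_id	karyotype_text	sex	clinical_status	shapes	mosaic	clone_counts	inheritance	groups	interval_chrom	interval_start	interval_end	build	modalities	phenotype_terms	arm_class	source_table
2	47,XY,+mar mat.ish min(11)(:p11.12→q11:)(RP11-397M16+,D11Z1+,RP11-77M17-)	male	normal	min	false		maternal		11	48303671	55700000	GRCh37	banding;ish		p	table3
A	46,XX,der(11).ish dup(11)(p11.2q11.1)(RP11-397M16++,D11Z1++,RP11-77M17+)	female	normal	unknown	false		unknown		11	48303671	55700000	GRCh37	banding;ish		p	table3
6	47,XX,+mar.ish r(11)(::p11.1→q12.2::)[10]/r(11)(::p11.1→q12.2::q12.2→p11.1::)[7]/min(:q12.2→p11.1::p11.1→q12.2:)[3](RP11-397M16-,D11Z1+,RP11-77M17+)	female	normal	r	false		unknown		11	51600000	57521103	GRCh37	banding;ish		q	table3
7	47,XY,+mar.ish min(11)(:p11.1→q12.1:)(RP11-397M16-,D11Z1+,RP11-77M17+).arr[hg19] 11q12.1(55,896,790_59,319,390)x3	male	normal	min	false		unknown		11	51600000	59319390	GRCh37	banding;ish;aCGH		q	table3
1	47,XY,+r(11)(::p11.12→q12.2::).arr[hg19] 11q12.1-12.2(51,095,992_60,473,821)x3	male	normal	r	false		unknown		11	51095992	60473821	GRCh37	banding;aCGH		q	table3
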