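case_id	karyotype_text	sex	clinical_status	shapes	mosaic	clone_counts	inheritance	groups	interval_chrom	interval_start	interval_end	build	modalities	phenotype_terms	arm_class	source_table
A	46,XX,der(11).ish dup(11)(p11.2q11.1)(RP11-397M16++,D11Z1++,RP11-77M17+)	female	normal	unknown	false		unknown		11	48303671	55700000	GRCh37	banding;ish			table2
B	46,XX,der(11)mat.ish dup(11)(p11.1q11)(D11Z1++)	female	normal	unknown	false		maternal						banding;ish			table2
C	46,XX,dup(11)(p11.2p11.1) LSI-FISH duplication size ∼6 Mb	female	abnormal	unknown	false		unknown						banding;ish	developmental delay	p	table2
D	46,XY,dup(11)(p12)	male	abnormal	unknown	false		unknown						banding	growth retardation;facial dysmorphism (unspecific);developmental delay;intellectual disability	p	table2
E	46,XY,dup(11)(p12p11.2)mat arr[hg19] 11p12p11.2(40,231,033_50,762,504)x3	male	abnormal	unknown	false		maternal		11	40231033	50762504	GRCh37	banding;aCGH	facial dysmorphism (unspecific);developmental delay	p	table2
F	46,XY,ins(11)(11; 11)(q14.5p14.1p11.2)	male	abnormal	unknown	false		unknown		11	30000000	51600000	GRCh37	banding	cleft palate;facial dysmorphism (unspecific);developmental delay	p	table2
G	mos 46,XY,dup(11)(q11q13.3)[29]/46,XY[6] arr[hg18] 11q11q13.3(56,000,000_78,750,000)	male	abnormal	unknown	true	29;6	unknown		11	56243424	79072352	GRCh37	banding;aCGH	facial dysmorphism (unspecific);heart defect;developmental delay	q	table2
H	mos 46,XY,dup(11)(q12.1q13.3)[53%]/46,XY[47%]	male	abnormal	unknown	true		unknown						banding	facial dysmorphism (unspecific);developmental delay	q	table2
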