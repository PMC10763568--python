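# The five informative clinically abnormal carriers whose demonstrated trisomy
# intervals bound where triplo-sensitive territory must begin on each arm.
# Case 10 is carried here with the table's own status=abnormal even though the
# cohort-wide counts place it among the unclear cases; see the phenotype notes.
# Coordinates are the published GRCh37 values (hg18 sources pre-converted).
case_id	karyotype_text	sex	clinical_status	shapes	mosaic	clone_counts	inheritance	groups	interval_chrom	interval_start	interval_end	build	modalities	phenotype_terms	arm_class	source_table
10	mos 47,XN,+mar[74%]/46,XN[26%].arr[hg19] 11p12∼11.2(42,922,228_50,768,675)x3	unknown	abnormal	unknown	true		unknown		11	42922228	50768675	GRCh37	banding;aCGH		p	table4
13	mos 47,XY,+mar[33%]/46,XY[67%].ish min(11)(:p12→q11:)(RP11-397M16+,D11Z1+,RP11-77M17-).arr[hg18] 11p12(40,190,000_54,700,000)x3	male	abnormal	min	true		unknown		11	40233424	54943424	GRCh37	banding;ish;aCGH	developmental delay;hypotonia	p	table4
E	46,XY,dup(11)(p12p11.2)mat arr[hg19] 11p12p11.2(40,231,033_50,762,504)x3	male	abnormal	unknown	false		maternal		11	40231033	50762504	GRCh37	banding;aCGH	facial dysmorphism (unspecific);developmental delay	p	table4
F	46,XY,ins(11)(11; 11)(q14.5p14.1p11.2)	male	abnormal	unknown	false		unknown		11	30000000	51600000	GRCh37	banding	cleft palate;facial dysmorphism (unspecific);developmental delay	p	table4
G	mos 46,XY,dup(11)(q11q13.3)[29]/46,XY[6] arr[hg18] 11q11q13.3(56,000,000_78,750,000)	male	abnormal	unknown	true	29;6	unknown		11	56243424	79072352	GRCh37	banding;aCGH	facial dysmorphism (unspecific);heart defect;developmental delay	q	table4
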