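# Arm-wise genotype-phenotype annotation: which cases contribute each sign to
# the 11p-cen-near and 11q-cen-near columns.
sign	p_cases	q_cases
growth retardation	D	29
blepharophimosis/ptosis		15
strabism		15
cleft palate	F
facial dysmorphism (unspecific)	D;E;F	15;G;H;29
heart defect		G;29
developmental delay	13;C;D;E;F	15;G;H;29
intellectual disability	D	15
hypotonia	13	29
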