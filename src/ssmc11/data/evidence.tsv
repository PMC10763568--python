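# Benign population copy-number gains (DGV/gnomAD) and pathogenic-report flank
# records (DECIPHER) used to refine the pericentric triplo-insensitive span.
# The pericentric-facing outer boundaries (benign: 47,675,469 / 60,516,539;
# pathogenic flanks: 45,048,321 / 61,479,322) are as published; the opposite
# ends of each interval are synthesized so the records are executable without
# database downloads (they only need to overlap the unrefined span / flank it).
record_id	classification	chrom	start	end	build	flank_only
dgv1111n100	benign	11	47675469	49100000	GRCh37	false
nsv832175	benign	11	59400000	60516539	GRCh37	false
DECIPHER-411500	pathogenic	11	44396000	45048321	GRCh37	true
DECIPHER-300792	pathogenic	11	61479322	62400000	GRCh37	true
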