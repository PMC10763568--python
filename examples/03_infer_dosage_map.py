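"""Infer the pericentric triplo-insensitive span and sensitive-start windows.

Pipeline: the five informative normal carriers bound the minimal insensitive
span; benign population gains (DGV/gnomAD) extend it to the refined span;
pathogenic patient reports (DECIPHER) and the informative abnormal carriers
bound where triplo-sensitive territory must begin on each arm.
"""

from ssmc11 import load_cytobands, load_packaged_cohort, build_dosage_map, report

bands = load_cytobands()
dmap = build_dosage_map(
    load_packaged_cohort("table3"),
    load_packaged_cohort("table4"),
    load_packaged_cohort("evidence"),
    bands.centromere_anchor,
)
print(report(dmap)["summary"])

# The refined span (47,675,469-60,516,539; 12.84 Mb) tolerates a third copy
# without clinical signs; the 2.63 Mb (11p) and 0.96 Mb (11q) windows are the
# remaining uncertainty about where dosage-sensitive territory starts.
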