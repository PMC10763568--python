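# FISH probe registry, GRCh37. D11Z1 (centromeric alpha satellite) is registered
# with the operational acen span in the printed-coordinate convention so that
# probe-resolved extents match published case tables verbatim.
D11Z1	11	51600000	55700000
RP11-397M16	11	48303671	48479496
RP11-77M17	11	57352936	57521103
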