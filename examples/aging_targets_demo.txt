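# Synthetic demo list of aging-associated target symbols for strategy 3.
# These are gene ids from the synthetic universe (mixed case to demonstrate
# case-insensitive matching), NOT a published aging-target list: supply your
# own curated list for real analyses.
g0031
G0032
g0033
G0041
G0042
G0101
G0205
g0310
G0400
G0499
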