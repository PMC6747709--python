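# Published calculated K_D fold-improvement ratios (parent K_D over
# predicted mutant K_D) that appear as printed numbers; the full per-mutant
# series exists only as a figure. Data, not computed output.
variant	fold_calculated	note
S109V	21.54	highest round-1 single
best_multi	162.58	best calculated improvement among multi-point mutants
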