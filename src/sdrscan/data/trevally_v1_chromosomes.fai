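scaffold_000114	24151137
scaffold_000147	28820665
scaffold_001154	27945907
scaffold_001701	22194978
scaffold_000836	22952508
scaffold_001460	31062029
scaffold_000312	24419205
scaffold_000453	26980729
scaffold_001891	28251306
scaffold_001025	26936208
scaffold_001200	18865379
scaffold_000118	26912610
scaffold_001584	22008664
scaffold_000429	25278635
scaffold_001123	23296617
scaffold_000874	26415528
scaffold_000314	22912052
scaffold_001965	19902634
scaffold_001072	19893011
scaffold_000070	24159416
scaffold_001800	27791086
scaffold_000657	25934954
scaffold_000099	16759215
scaffold_000328	11005663
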