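"""The desk-scale statistics of the study, recomputed from their inputs.

Each number here comes from printed counts, so this script needs no data
files and runs in well under a second.
"""

from termswitch.stats import binomial_two_tailed, fisher_two_tailed, tir

# Terminal-to-intermediate ratio: 177 switches whose ancestral state is
# one of the two terminal Watson-Crick pairs (types 1 and 3) against 65
# whose ancestor carries the intermediate (type 2).
print(f"TIR = {tir(177, 65, 0):.2f}")

# GU vs AC intermediates among the 76 observed AU<->GC intermediates.
print(f"GU vs AC (68/76 vs 0.5):      P = {binomial_two_tailed(68, 76, 0.5):.1e}")

# Switches at external stem positions: 126 of 482 against the fraction of
# external positions among all interacting positions (391/2074).
p0 = 391 / 2074
print(f"external positions (126/482): P = {binomial_two_tailed(126, 482, p0):.1e}")

# Same comparison restricted to non-GU-intermediate switches (40 of 102).
print(f"non-GU switches (40/102):     P = {binomial_two_tailed(40, 102, p0):.1e}")

# Fisher's exact test on a perfectly associated 2x2 table, for reference.
print(f"Fisher [[10,0],[0,10]]:       P = {fisher_two_tailed([[10, 0], [0, 10]]):.2e}")
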