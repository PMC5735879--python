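"""How many seed matches make an overlap significant?

The number of k-mer hits in a length-L overlap between reads with
per-base error rate e is modelled as Binomial(L, p) with p = (1-e)^(2k):
a seed survives only if all k bases are error-free on both reads.  An
overlap is kept only if its hit count reaches mu - 3*sigma.  This prints
the floor for the two seed sizes used by the two pipeline stages.
"""

from hisea import binomial_threshold

print(f"{'L':>7} {'e':>5} {'k':>3} {'p=(1-e)^2k':>12} {'mu-3sigma':>10}")
for L in (1000, 5000, 20000):
    for e in (0.10, 0.15):
        for k in (16, 12):
            p = (1 - e) ** (2 * k)
            thr = binomial_threshold(L, e, k)
            print(f"{L:>7} {e:>5.2f} {k:>3} {p:>12.6f} {thr:>10.2f}")

print("\nA negative floor means no overlap of that length can be rejected "
      "for lack of seeds; with k'=12 the floor is far more permissive than "
      "with k=16, which is why boundary extension uses the smaller seed.")
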