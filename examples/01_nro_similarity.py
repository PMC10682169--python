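"""Normalized reciprocal overlap (NRO) versus classical reciprocal overlap.

Noisy long-read alignment smears signature boundaries: two reads observing
the same deletion report slightly different intervals, typically one
nested/stretched relative to the other. Classical reciprocal overlap
(min of the two overlap ratios) punishes a 30 bp boundary spread on a
100 bp event as hard as a 1.5 kb spread on a 5 kb event, so no single
threshold fits both scales. NRO = 2*Overlap/(L1+L2) - nonoverlap/NO_Norm
scores the shared span symmetrically and penalizes the *absolute* number
of disagreeing bases, so one threshold (0.8) works across scales.
"""

from svclique import NroParams, SvSignature, classical_ro, nro

params = NroParams()  # threshold 0.8, NO_Norm 1000 bp


def deletion(start, end, read):
    return SvSignature("DEL", "chr1", start, end, read, "gap", length=end - start)


print("Two signatures of one event; the second smeared 15 bp outward per side")
print(f"{'event size':>10} {'NRO':>7} {'classical RO':>13}   edge at threshold 0.8?")
for size in (100, 500, 5000):
    a = deletion(10_000, 10_000 + size, "read_a")
    b = deletion(10_000 - 15, 10_000 + size + 15, "read_b")
    v_nro = nro(a, b, params)
    v_cls = classical_ro(a, b, params)
    verdict = f"NRO:{'yes' if v_nro > 0.8 else 'NO '}  classical:{'yes' if v_cls > 0.8 else 'NO '}"
    print(f"{size:>10} {v_nro:>7.3f} {v_cls:>13.3f}   {verdict}")

print()
print("Two genuinely different events, 200 bp apart:")
a = deletion(10_000, 11_000, "read_a")
b = deletion(10_200, 11_200, "read_b")
print(f"  1 kb deletions offset 200 bp: NRO={nro(a, b, params):.3f}, "
      f"classical={classical_ro(a, b, params):.3f} -> no edge under either")

print()
print("A 30 bp boundary spread sinks classical RO below 0.8 for the 100 bp")
print("event (0.769) while NRO keeps the pair connected (0.840); for large")
print("events the two criteria agree, and disjoint events stay separated")
print("because the non-overlap penalty drives NRO down (even negative).")
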