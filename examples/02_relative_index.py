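"""Relative usage-impact (UIF) indices against a national baseline.

Reproduces the worked half-year comparison of two herbarium datasets and
two Danish publishers against Denmark's aggregate usage impact. The
baseline is a ratio of sums (total downloads over total stored records),
so an index of 1.0 means national-average usage per stored record.
"""

from dui import relative_index

# unit -> (downloaded records d, stored records r), July-December window
units = {
    "AAU Herbarium dataset": (716_772, 110_357),
    "AAU PalmTransect dataset": (250_330, 148_720),
    "HUA publisher": (717_102, 259_077),
    "DanBIF publisher": (854_761, 4_995_544),
}
denmark = (1_571_863, 4_836_771)

print(f"{'unit':28s} {'abs UIF':>8s} {'vs DK':>7s}")
for name, (d, r) in units.items():
    idx = relative_index((d, r), [denmark], rounding="paper")
    print(f"{name:28s} {d / r:8.2f} {idx:7.2f}")

print()
print("The small herbarium publisher reaches 8.66 times the national")
print("downloads-per-stored-record rate; its herbarium dataset alone reaches")
print("20.31. The medium publisher (0.53) sits below the national average,")
print("which its own large record base dominates.")
print()
full = relative_index(units["AAU Herbarium dataset"], [denmark])
print(f"Full-precision mode gives {full:.2f} instead of 20.31: the rounded-")
print("input mode divides two-decimal impact factors, matching printed tables.")
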