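"""Harmonize receptor gene names across annotation releases.

Applies the packaged old→new rename map in one atomic pass: paralog
suffixes collapse (HsOr307.1 → HsOr307), one gene is recovered from a raw
locus accession, and one name pair is exchanged simultaneously.
"""

import chcscreen as c

rmap = c.default_rename_map()
old = ["HsOr307.1", "HsOr257.2", "HsOr258", "LOC105187615",
       "HsOr378", "HsOr379", "HsOr152"]
new = c.apply_rename_map(old, rmap)
for o, n in zip(old, new):
    mark = "  (unchanged)" if o == n else ""
    print(f"{o:>14} -> {n}{mark}")
print()
print("Note HsOr257.2 -> HsOr258 while the old HsOr258 -> HsOr386: the map is")
print("applied over the whole vocabulary at once, so both land on distinct")
print("names; applying it sequentially would be wrong.")
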