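"""Draw a pedigree with twins and a quantitative trait as an SVG.

Step 1 (data preparation) turns the pedigree into a layout table and then
a plot-element table that can be inspected or edited; step 2 renders the
elements to a deterministic SVG.  The continuous affection is shown as a
colour gradient split at a clinical threshold.
"""

from dataclasses import replace

from pedkit import (
    Pedigree,
    align,
    build_plot_elements,
    fixtures,
    generate_colors,
    render_svg,
)

base = fixtures()["twins"]
# attach a quantitative trait (say, a serum marker) to every individual
levels = {"F": 4.1, "M": 6.8, "T1": 9.2, "T2": 8.7, "D1": 3.0, "D2": 7.5}
ped = Pedigree([replace(r, affections=(levels[r.id],)) for r in base.records],
               base.relationships)

scale = generate_colors(ped.affection_values(0), threshold=6.5, n_breaks=4)
print(f"fill scale: {len(scale.intervals)} intervals, "
      f"threshold {scale.threshold} (values >= threshold drawn as affected)")

table = align(ped)                       # generations + x positions
elements = build_plot_elements(table, ped, scales={0: scale})
print(f"plot elements: {len(elements.symbols)} symbols, "
      f"{len(elements.connectors)} connectors "
      f"(incl. twin forks and the MZ bar)")

text = render_svg(elements, "twins.svg")
print(f"wrote twins.svg ({len(text)} bytes; rendering is byte-deterministic)")
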