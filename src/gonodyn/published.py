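"""Published six-species summary counts used as reference inputs.

Per-species counts of stage-contrast DEGs by enrichment mechanism, the
printed per-species totals, and the annotated-gene denominators, from a
published six-vertebrate gonadal-transcriptome comparison.  These serve as
fixed inputs for validating the aggregation and percentage operations; they
are not recomputed by this package.

Note the sea-bass categories sum to 4,130 while the printed total is 4,129
(an off-by-one in the source table); ``total_degs_printed`` records the
printed value, the aggregation operations enforce the exact partition.
"""

from __future__ import annotations

# category keys follow MechanismSummary: males_up / males_down / females_up /
# females_down / both_sexes.  ``total_genes`` is the annotated-feature count
# used as the denominator of the DEG fraction (for the mouse, the
# annotated-probe total rather than the table's coding-gene figure).
PUBLISHED_SPECIES_COUNTS: dict[str, dict[str, int]] = {
    "sea_bass": {
        "males_up": 333,
        "males_down": 254,
        "females_up": 1605,
        "females_down": 1646,
        "both_sexes": 292,
        "total_degs_printed": 4129,
        "total_genes": 20978,
    },
    "platyfish": {
        "males_up": 1652,
        "males_down": 1039,
        "females_up": 340,
        "females_down": 198,
        "both_sexes": 3013,
        "total_degs_printed": 6242,
        "total_genes": 24209,
    },
    "frog": {
        "males_up": 738,
        "males_down": 1309,
        "females_up": 1098,
        "females_down": 1753,
        "both_sexes": 536,
        "total_degs_printed": 5434,
        "total_genes": 20219,
    },
    "turtle": {
        "males_up": 371,
        "males_down": 441,
        "females_up": 1037,
        "females_down": 876,
        "both_sexes": 1605,
        "total_degs_printed": 4330,
        "total_genes": 28415,
    },
    "chicken": {
        "males_up": 432,
        "males_down": 266,
        "females_up": 361,
        "females_down": 308,
        "both_sexes": 2358,
        "total_degs_printed": 3725,
        "total_genes": 20937,
    },
    "mouse": {
        "males_up": 213,
        "males_down": 131,
        "females_up": 77,
        "females_down": 20,
        "both_sexes": 368,
        "total_degs_printed": 809,
        # annotated probes; the coding-gene figure in the source table is 18,138
        "total_genes": 25697,
    },
}

CATEGORY_KEYS = ("males_up", "males_down", "females_up", "females_down", "both_sexes")
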