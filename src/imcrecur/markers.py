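"""Default antibody panel used for cell phenotyping.

The 21 markers cover epithelium (cytokeratin, E-cadherin, beta-catenin),
hormone receptors (ER, PR), stroma and vasculature (aSMA, collagen I,
podoplanin, CD31, VEGF), immune lineages (CD45, CD3, CD4, CD8a, CD20,
CD68), signalling/proliferation (p53, pERK, pS6, Ki-67) and vimentin,
the intermediate-filament marker of interest.
"""

CLUSTERING_MARKERS: list[str] = [
    "aSMA",
    "vimentin",
    "cytokeratin",
    "CD31",
    "CD45",
    "ER",
    "CD4",
    "Ecad",
    "CD68",
    "p53",
    "CD20",
    "CD8a",
    "VEGF",
    "Bcatenin",
    "podoplanin",
    "Ki67",
    "collagenI",
    "CD3",
    "pERK",
    "PR",
    "pS6",
]

#: column prefix for arcsinh-transformed intensities in a cell table
ASINH_PREFIX = "asinh_"


def asinh_cols(markers: list[str]) -> list[str]:
    """Column names holding arcsinh-transformed values for *markers*."""
    return [ASINH_PREFIX + m for m in markers]
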