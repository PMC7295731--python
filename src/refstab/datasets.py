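"""Published stability rankings of a five-gene nematode reference panel.

Rankings of five candidate RT-qPCR reference genes (18S rRNA, actin,
GAPDH, UBC, alpha-tubulin) of the rice white-tip nematode
*Aphelenchoides besseyi*, evaluated under three experimental conditions
— the four life stages of population N10, the four life stages of
population S24, and mixed-stage nematodes of four populations — by the
comparative deltaCt method, geNorm, NormFinder and the RefFinder
comprehensive ranking. These tables are rank-arithmetic inputs for
cross-condition averaging and exclusion-sensitivity analyses.

geNorm ranks use the competition convention for its tied most-stable
pair (1, 1, 3, 4, 5). BestKeeper per-condition ranks were never
published; the UBC entries below are inferred from the published
comprehensive geometric means (e.g. mixed-stage UBC 1.189 =
(1*2*1*1)^(1/4) forces a BestKeeper rank of 2) and are marked as such.
"""

from __future__ import annotations

CONDITIONS = ("n10", "s24", "mixed")

GENES = ("18S rRNA", "actin", "GAPDH", "UBC", "a-tubulin")

#: method -> condition -> gene -> published stability rank
PUBLISHED_RANKS: dict[str, dict[str, dict[str, int]]] = {
    "delta_ct": {
        "n10": {"UBC": 1, "actin": 2, "18S rRNA": 3, "a-tubulin": 4, "GAPDH": 5},
        "s24": {"18S rRNA": 1, "UBC": 2, "GAPDH": 3, "actin": 4, "a-tubulin": 5},
        "mixed": {"UBC": 1, "GAPDH": 2, "a-tubulin": 3, "actin": 4, "18S rRNA": 5},
    },
    "genorm": {
        "n10": {"actin": 1, "a-tubulin": 1, "18S rRNA": 3, "UBC": 4, "GAPDH": 5},
        "s24": {"UBC": 1, "GAPDH": 1, "18S rRNA": 3, "actin": 4, "a-tubulin": 5},
        "mixed": {"UBC": 1, "GAPDH": 1, "a-tubulin": 3, "actin": 4, "18S rRNA": 5},
    },
    "normfinder": {
        "n10": {"UBC": 1, "18S rRNA": 2, "actin": 3, "a-tubulin": 4, "GAPDH": 5},
        "s24": {"UBC": 1, "18S rRNA": 2, "GAPDH": 3, "actin": 4, "a-tubulin": 5},
        "mixed": {"UBC": 1, "GAPDH": 2, "a-tubulin": 3, "actin": 4, "18S rRNA": 5},
    },
    "reffinder": {
        "n10": {"UBC": 1, "actin": 2, "18S rRNA": 3, "a-tubulin": 4, "GAPDH": 5},
        "s24": {"UBC": 1, "18S rRNA": 2, "GAPDH": 3, "actin": 4, "a-tubulin": 5},
        "mixed": {"UBC": 1, "GAPDH": 2, "a-tubulin": 3, "actin": 4, "18S rRNA": 5},
    },
}

#: BestKeeper ranks for UBC only, inferred from comprehensive geometric means
INFERRED_BESTKEEPER_UBC_RANKS = {"n10": 1, "s24": 2, "mixed": 2}

#: published per-condition deltaCt stability values (cycles)
DELTA_CT_STABILITY_VALUES = {
    "n10": {"UBC": 0.676, "actin": 0.685, "18S rRNA": 0.713, "a-tubulin": 0.722, "GAPDH": 1.059},
    "s24": {"18S rRNA": 0.793, "UBC": 0.800, "GAPDH": 0.955, "actin": 1.016, "a-tubulin": 1.343},
    "mixed": {"UBC": 0.544, "GAPDH": 0.580, "a-tubulin": 0.645, "actin": 0.808, "18S rRNA": 1.031},
}

#: published per-gene Ct extremes over the 12 samples (cycles)
CT_RANGES = {
    "18S rRNA": (10.22, 14.18),
    "actin": (19.40, 22.55),
    "GAPDH": (23.80, 26.24),
    "UBC": (24.46, 26.60),
    "a-tubulin": (23.94, 27.50),
}

#: published per-gene mean Ct over the 12 samples (cycles)
MEAN_CT = {
    "18S rRNA": 12.89,
    "actin": 21.12,
    "GAPDH": 24.85,
    "UBC": 25.53,
    "a-tubulin": 25.68,
}

#: published geNorm pairwise variations; n10 V(2,3) was never printed
V_SERIES = {
    "n10": {3: 0.195},
    "s24": {2: 0.185},
    "mixed": {2: 0.088},
}
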