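"""Published power-law statistics of the October-2009 GOA corpora.

The GOA (Gene Ontology Annotation) release of October 2009 covered,
among others, human (Hs), mouse (Mm), zebrafish (Dr), budding yeast
(Sc) and rat (Rn). The tables below carry the published corpus sizes
(total annotations and distinct GO ids per sub-ontology), the power-law
exponents beta and goodness-of-fit p-values fitted to each corpus, and
the exponents of the human/mouse corpora after splitting by evidence
class (HC: experimentally/manually supported codes; LC: electronic
annotation only). They serve as reference inputs for the cross-corpus
comparison operations: per-sub-ontology mean exponents, the HC-vs-LC
paired test, and the exponent-vs-corpus-size association.

The raw annotation files themselves are an external download and are
not shipped; refitting them is therefore out of reach here — these are
the published summary statistics, not values this package computed.
"""

from __future__ import annotations

from gozipf.exponent_comparison import ExponentRecord

#: (species, aspect) -> (total annotations, distinct GO ids), full corpora.
GOA_2009_CORPUS_SIZES: dict[tuple[str, str], tuple[int, int]] = {
    ("Hs", "CC"): (51_640, 889),
    ("Hs", "MF"): (55_781, 2_844),
    ("Hs", "BP"): (58_320, 5_259),
    ("Mm", "CC"): (45_933, 641),
    ("Mm", "MF"): (60_919, 2_318),
    ("Mm", "BP"): (59_133, 4_239),
    ("Dr", "CC"): (23_179, 304),
    ("Dr", "MF"): (47_651, 1_187),
    ("Dr", "BP"): (34_158, 1_513),
    ("Sc", "CC"): (29_563, 626),
    ("Sc", "MF"): (26_292, 1_611),
    ("Sc", "BP"): (31_797, 1_963),
    ("Rn", "CC"): (53_342, 50),
    ("Rn", "MF"): (63_050, 2_776),
    ("Rn", "BP"): (74_943, 5_411),
}

#: (species, aspect) -> (beta, GOF p-value), full corpora.
GOA_2009_EXPONENTS: dict[tuple[str, str], tuple[float, float]] = {
    ("Hs", "CC"): (1.73, 0.63),
    ("Hs", "MF"): (1.83, 0.55),
    ("Hs", "BP"): (2.04, 0.65),
    ("Mm", "CC"): (1.69, 0.74),
    ("Mm", "MF"): (1.76, 0.36),
    ("Mm", "BP"): (2.08, 0.97),
    ("Dr", "CC"): (1.62, 0.74),
    ("Dr", "MF"): (1.69, 0.91),
    ("Dr", "BP"): (1.88, 0.11),
    ("Sc", "CC"): (1.86, 0.29),
    ("Sc", "MF"): (1.88, 0.78),
    ("Sc", "BP"): (2.27, 0.42),
    ("Rn", "CC"): (1.68, 0.24),
    ("Rn", "MF"): (1.91, 0.85),
    ("Rn", "BP"): (2.38, 0.76),
}

#: (species, aspect) -> {"HC": (beta, p), "LC": (beta, p)}, human and mouse.
GOA_2009_HC_LC_EXPONENTS: dict[tuple[str, str], dict[str, tuple[float, float]]] = {
    ("Hs", "CC"): {"HC": (1.88, 0.37), "LC": (1.62, 0.11)},
    ("Hs", "MF"): {"HC": (2.05, 0.18), "LC": (1.75, 0.16)},
    ("Hs", "BP"): {"HC": (2.12, 0.37), "LC": (2.04, 0.62)},
    ("Mm", "CC"): {"HC": (1.90, 0.43), "LC": (1.50, 0.71)},
    ("Mm", "MF"): {"HC": (2.15, 0.65), "LC": (1.67, 0.03)},
    ("Mm", "BP"): {"HC": (2.60, 0.61), "LC": (1.62, 0.00)},
}


def goa_2009_exponent_records() -> list[ExponentRecord]:
    """The full-corpus published fits as :class:`ExponentRecord` rows."""
    records = []
    for (species, aspect), (beta, p) in GOA_2009_EXPONENTS.items():
        n_total, n_distinct = GOA_2009_CORPUS_SIZES[(species, aspect)]
        records.append(
            ExponentRecord(
                source_label=species,
                aspect=aspect,
                evidence_class="ALL",
                beta=beta,
                p_value=p,
                n_total=n_total,
                n_distinct=n_distinct,
            )
        )
    return records


def goa_2009_hc_lc_pairs() -> list[tuple[float, float]]:
    """(HC beta, LC beta) pairs for the six human/mouse corpora."""
    return [
        (v["HC"][0], v["LC"][0]) for v in GOA_2009_HC_LC_EXPONENTS.values()
    ]
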