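"""Default targeted panel and cohort parameterization.

The default assay panel covers 54 plasma metabolites from the compound
classes routinely targeted in pediatric neurometabolic profiling: amino
acids and related amines, glycolytic/TCA organic acids, purines, the
carnitine/acylcarnitine family, and microbiome-derived uremic solutes.
Baseline plasma concentrations (µM) are typical pediatric reference values;
the log2-scale dispersions and the between-metabolite correlation blocks
are plausible fabrications chosen to mimic the covariance structure of a
real targeted panel (see docs/methods.md) — no real cohort covariance is
encoded here.
"""

from __future__ import annotations

AMINO_ACIDS = [
    "alanine", "arginine", "aspartate", "glutamate", "glutamine",
    "glycine", "isoleucine", "leucine", "lysine", "methionine",
    "ornithine", "phenylalanine", "proline", "taurine", "threonine",
    "tyrosine", "valine",
]

AMINES = [
    "ethanolamine", "4-hydroxyproline", "3-aminoisobutyrate",
    "serotonin", "kynurenine",
]

ORGANIC_ACIDS = [
    "lactate", "pyruvate", "citrate", "malate", "2-ketoglutarate",
    "succinate", "dodecanedioate",
]

PURINES = ["urate", "xanthine", "hypoxanthine", "inosine"]

ACYLCARNITINES = [
    "carnitine", "acetylcarnitine", "propionylcarnitine",
    "butyrylcarnitine", "isovalerylcarnitine", "glutarylcarnitine",
    "hexanoylcarnitine", "octanoylcarnitine", "decanoylcarnitine",
    "lauroylcarnitine", "myristoylcarnitine", "palmitoylcarnitine",
    "stearoylcarnitine", "oleoylcarnitine", "hydroxybutyrylcarnitine",
]

MICROBIOME = [
    "p-cresol-sulfate", "3-indoxyl-sulfate", "indoleacetate",
    "indolelactate", "4-ethylphenylsulfate", "CMPF",
]

#: The 54-metabolite default panel, in canonical (grouped) order.
METABOLITES: list[str] = (
    AMINO_ACIDS + AMINES + ORGANIC_ACIDS + PURINES + ACYLCARNITINES + MICROBIOME
)

#: Purine catabolites released by red-cell lysis; unreliable in hemolyzed plasma.
HEMOLYSIS_SENSITIVE: frozenset[str] = frozenset({"xanthine", "urate", "hypoxanthine"})

#: Metabolites with >90% of measurements below the LLOQ in the default
#: configuration; excluded from ratio generation and, by default, from the
#: screened single-metabolite features.
LOW_QUANT_METABOLITES: tuple[str, ...] = (
    "CMPF", "4-ethylphenylsulfate", "dodecanedioate",
)

# Typical pediatric plasma concentration (µM) and log2-scale SD per metabolite.
_AA_SD = 0.30
_ORG_SD = 0.35
_ACYL_SD = 0.45
_MICRO_SD = 0.80

BASELINE: dict[str, tuple[float, float]] = {
    # amino acids
    "alanine": (350.0, _AA_SD), "arginine": (80.0, _AA_SD),
    "aspartate": (10.0, _AA_SD), "glutamate": (60.0, _AA_SD),
    "glutamine": (550.0, 0.25), "glycine": (230.0, _AA_SD),
    "isoleucine": (60.0, _AA_SD), "leucine": (110.0, _AA_SD),
    "lysine": (150.0, _AA_SD), "methionine": (25.0, _AA_SD),
    "ornithine": (60.0, _AA_SD), "phenylalanine": (55.0, 0.28),
    "proline": (180.0, _AA_SD), "taurine": (60.0, 0.40),
    "threonine": (120.0, _AA_SD), "tyrosine": (60.0, _AA_SD),
    "valine": (220.0, _AA_SD),
    # amines
    "ethanolamine": (8.0, 0.40), "4-hydroxyproline": (12.0, 0.45),
    "3-aminoisobutyrate": (2.0, 0.65), "serotonin": (1.0, 0.60),
    "kynurenine": (2.0, 0.35),
    # organic acids
    "lactate": (1500.0, _ORG_SD), "pyruvate": (70.0, _ORG_SD),
    "citrate": (110.0, 0.35), "malate": (8.0, _ORG_SD),
    "2-ketoglutarate": (10.0, _ORG_SD), "succinate": (5.0, _ORG_SD),
    "dodecanedioate": (0.3, 0.70),
    # purines
    "urate": (250.0, 0.30), "xanthine": (1.5, 0.45),
    "hypoxanthine": (4.0, 0.45), "inosine": (1.5, 0.50),
    # carnitine family
    "carnitine": (40.0, 0.30), "acetylcarnitine": (8.0, 0.40),
    "propionylcarnitine": (0.4, _ACYL_SD), "butyrylcarnitine": (0.25, _ACYL_SD),
    "isovalerylcarnitine": (0.12, _ACYL_SD), "glutarylcarnitine": (0.06, _ACYL_SD),
    "hexanoylcarnitine": (0.08, _ACYL_SD), "octanoylcarnitine": (0.15, _ACYL_SD),
    "decanoylcarnitine": (0.25, _ACYL_SD), "lauroylcarnitine": (0.10, _ACYL_SD),
    "myristoylcarnitine": (0.04, _ACYL_SD), "palmitoylcarnitine": (0.10, 0.35),
    "stearoylcarnitine": (0.04, 0.35), "oleoylcarnitine": (0.12, 0.35),
    "hydroxybutyrylcarnitine": (0.03, 0.50),
    # microbiome-derived
    "p-cresol-sulfate": (30.0, _MICRO_SD), "3-indoxyl-sulfate": (3.0, _MICRO_SD),
    "indoleacetate": (1.5, _MICRO_SD), "indolelactate": (0.6, _MICRO_SD),
    "4-ethylphenylsulfate": (0.05, _MICRO_SD), "CMPF": (0.2, _MICRO_SD),
}

#: (metabolite set, within-block Pearson correlation on the log2 scale)
CORRELATION_BLOCKS: list[tuple[tuple[str, ...], float]] = [
    (("leucine", "isoleucine", "valine"), 0.60),
    (("lactate", "pyruvate"), 0.50),
    (("citrate", "malate", "2-ketoglutarate", "succinate"), 0.40),
    (("urate", "xanthine", "hypoxanthine", "inosine"), 0.50),
    (("hexanoylcarnitine", "octanoylcarnitine", "decanoylcarnitine",
      "lauroylcarnitine"), 0.60),
    (("myristoylcarnitine", "palmitoylcarnitine", "stearoylcarnitine",
      "oleoylcarnitine"), 0.60),
    (("p-cresol-sulfate", "3-indoxyl-sulfate", "indoleacetate",
      "indolelactate"), 0.40),
]
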