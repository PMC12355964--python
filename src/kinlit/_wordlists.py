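"""Name pools for the synthetic corpus.

Enzyme names are chosen so that no two are within 0.90 normalized
edit-distance similarity of each other — a key with a different enzyme
can then never be admissible for cross-matching in the benchmark.
SMILES strings give each substrate a resolvable structure for the
compound-lookup fixtures.
"""

ENZYMES = (
    "alcohol dehydrogenase",
    "beta-galactosidase",
    "carbonic anhydrase II",
    "chymotrypsin",
    "glucose oxidase",
    "hexokinase",
    "lysozyme",
    "triosephosphate isomerase",
    "acetylcholinesterase",
    "catalase",
    "pyruvate kinase",
    "alkaline phosphatase",
    "lactate dehydrogenase",
    "urease",
    "tyrosinase",
    "ribonuclease A",
    "fumarase",
    "enolase",
    "aldolase",
    "peroxidase from horseradish",
    "glutathione S-transferase",
    "phosphoglucomutase",
    "citrate synthase",
    "adenosine deaminase",
)

ORGANISMS = (
    "Escherichia coli",
    "Saccharomyces cerevisiae",
    "Homo sapiens",
    "Bacillus subtilis",
    "Thermus thermophilus",
    "Pseudomonas aeruginosa",
    "Arabidopsis thaliana",
    "Rattus norvegicus",
    "Bos taurus",
    "Candida albicans",
    "Mycobacterium tuberculosis",
    "Drosophila melanogaster",
    "Pyrococcus furiosus",
    "Streptomyces coelicolor",
    "Aspergillus niger",
    "Zea mays",
    "Gallus gallus",
    "Sulfolobus solfataricus",
    "Lactobacillus plantarum",
    "Thermotoga maritima",
)

# (name, smiles)
SUBSTRATES = (
    ("glucose", "OCC1OC(O)C(O)C(O)C1O"),
    ("pyruvate", "CC(=O)C(=O)[O-]"),
    ("lactose", "OCC1OC(OC2C(O)C(O)C(O)OC2CO)C(O)C(O)C1O"),
    ("ethanol", "CCO"),
    ("acetaldehyde", "CC=O"),
    ("hydrogen peroxide", "OO"),
    ("fructose 1,6-bisphosphate", "OC(COP(=O)(O)O)C(O)C(O)C(=O)COP(=O)(O)O"),
    ("phosphoenolpyruvate", "OC(=O)C(=C)OP(=O)(O)O"),
    ("acetylcholine", "CC(=O)OCC[N+](C)(C)C"),
    ("glyceraldehyde 3-phosphate", "O=CC(O)COP(=O)(O)O"),
    ("fumarate", "OC(=O)/C=C/C(=O)O"),
    ("citrate", "OC(=O)CC(O)(CC(=O)O)C(=O)O"),
    ("adenosine", "OCC1OC(n2cnc3c(N)ncnc32)C(O)C1O"),
    ("tyrosine", "NC(Cc1ccc(O)cc1)C(=O)O"),
    ("urea", "NC(N)=O"),
    ("p-nitrophenyl phosphate", "O=[N+]([O-])c1ccc(OP(=O)(O)O)cc1"),
    ("glutathione", "NC(CCC(=O)NC(CS)C(=O)NCC(=O)O)C(=O)O"),
    ("2-phosphoglycerate", "OC(COP(=O)(O)O)C(=O)O"),
    ("dihydroxyacetone phosphate", "OCC(=O)COP(=O)(O)O"),
    ("benzyl penicillin", "CC1(C)SC2C(NC(=O)Cc3ccccc3)C(=O)N2C1C(=O)O"),
    ("maltose", "OCC1OC(OC2C(CO)OC(O)C(O)C2O)C(O)C(O)C1O"),
    ("glucose 6-phosphate", "OC1OC(COP(=O)(O)O)C(O)C(O)C1O"),
    ("oxaloacetate", "OC(=O)CC(=O)C(=O)O"),
    ("L-lactate", "CC(O)C(=O)O"),
    ("guanosine", "OCC1OC(n2cnc3c2NC(=O)NC3=O)C(O)C1O"),
    ("sucrose", "OCC1OC(CO)(OC2OC(CO)C(O)C(O)C2O)C(O)C1O"),
    ("galactose", "OCC1OC(O)C(O)C(O)C1O"),
    ("acetate", "CC(=O)[O-]"),
    ("malate", "OC(CC(=O)O)C(=O)O"),
    ("inosine", "OCC1OC(n2cnc3c2NC=NC3=O)C(O)C1O"),
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

FILLER_SENTENCES = (
    "Steady-state kinetic parameters were determined by nonlinear regression of initial rates.",
    "All measurements were performed in triplicate in 50 mM buffer.",
    "Initial velocities were recorded spectrophotometrically at 340 nm.",
    "Protein concentration was determined by the Bradford assay.",
    "The reaction was initiated by addition of enzyme and followed for five minutes.",
    "Kinetic constants were obtained by fitting the Michaelis-Menten equation.",
)
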