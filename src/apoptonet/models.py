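"""The encoded yeast apoptosis network and its in-silico humanized extensions.

The yeast model is a timed Boolean network of 73 species and 115 interactions
covering the acetic-acid, heat/osmotic-stress, H2O2, heavy-metal, drug and
pheromone routes to programmed cell death in *Saccharomyces cerevisiae*,
with a housekeeping pseudo-node (HK) feeding constitutively present proteins
and a single Apoptosis output.  Interactions carry timescales from
{0, 2, 4, 5, 6} (1 and 3 are reserved): housekeeping supply at t=0, stimulus
switches at t=2, primary signal propagation at t=4, the stress-phosphatase
feedback block (Slt2/Rlm1/Ptp2 and Hog1/Ptp3) at t=5, and terminal events —
caspase-gated apoptosis, Bir1 control, Stm1 accumulation — at t=6.

Two humanized variants insert human regulators in silico: the Bcl-2 family
(Bax/Bad/Bcl-2/Bcl-xL under Akt and UV control) and VCP (the human Cdc48
ortholog with its NFkB/IkB-alpha, IAP, caspase and gp130-Stat3 wiring and a
Survival output).

Translocating proteins (Nuc1, Mcd1, Stm1, Aif1, Nma111, Ste20, cytochrome c)
are represented as one node per compartment, which keeps the hypergraph free
of self-loops.
"""

from __future__ import annotations

from .logic import HyperArc, Literal, LogicalNetwork, NetworkIntegrityError, SpeciesNode, canonical_key
from .rules import parse_interaction

__all__ = [
    "YEAST_ALIASES",
    "build_yeast_network",
    "build_bcl2_extension",
    "build_vcp_extension",
]

# (name, compartment, role, description) — species-table order.
_YEAST_SPECIES = (
    ("ABNORMALTELOMER", "nucleus", "internal", "Abnormal telomerase"),
    ("ACETIC-ACID", "input", "input", "Chemical stimulus"),
    ("ADENYLATECYCLASE", "cytosol", "internal", "Lyase enzyme"),
    ("ADOZELESIN", "input", "input", "Drug"),
    ("AIF1-MT", "mitochondria", "internal", "Apoptosis-inducing factor in mitochondria"),
    ("AIF1-NUC", "nucleus", "internal", "Apoptosis-inducing factor in nucleus"),
    ("APOPTOSIS", "other", "output", "Cell death"),
    ("BIR1", "nucleus", "internal", "Baculoviral IAP repeat-containing protein 1"),
    ("CAMP", "cytosol", "internal", "Cyclic adenosine monophosphate"),
    ("CDC48", "cytosol", "internal", "Cell division cycle 48"),
    ("CDC6", "nucleus", "internal", "Cell division cycle 6"),
    ("CPR3", "mitochondria", "internal", "Cyclosporin-sensitive proline rotamase"),
    ("CU2", "input", "input", "Copper ion"),
    ("DESCYCLINCCDK8", "nucleus", "internal", "Destruction of cyclin C/CDK8"),
    ("CYTC-CYT", "cytosol", "internal", "Cytochrome c in cytosol"),
    ("CYTC-MT", "mitochondria", "internal", "Cytochrome c in mitochondria"),
    ("DNA-FRAG", "nucleus", "internal", "DNA fragmentation"),
    ("DRE2/TAH18", "cytosol", "internal", "Dre2-Tah18 complex"),
    ("EMC4", "cytosol", "internal", "ER membrane protein complex"),
    ("ESP1", "nucleus", "internal", "Separase"),
    ("FIS1", "mitochondria", "internal", "Mitochondrial fission"),
    ("FYV10", "cytosol", "internal", "Function required for yeast viability"),
    ("H2B", "nucleus", "internal", "Histone 2B"),
    ("H2O2", "input", "input", "Hydrogen peroxide"),
    ("HEAT", "input", "input", "Heat stress"),
    ("HK", "other", "constant", "Housekeeping function"),
    ("HOG1", "cytosol", "internal", "High osmolarity glycerol response"),
    ("HOG1-DEP", "nucleus", "internal", "Hog1-dependent genes"),
    ("HOS3", "nucleus", "internal", "Hda one similar"),
    ("KAP123", "cytosol", "internal", "Karyopherin"),
    ("MAPK", "cytosol", "internal", "MAP kinase cascade"),
    ("MATING", "input", "input", "Mating pheromone"),
    ("MCD1-MT", "mitochondria", "internal", "Mitotic chromosome determinant in mitochondria"),
    ("MCD1-NUC", "nucleus", "internal", "Mitotic chromosome determinant in nucleus"),
    ("MDV1", "mitochondria", "internal", "Mitochondrial division"),
    ("MEC1", "nucleus", "internal", "Mitosis entry checkpoint"),
    ("MG2", "input", "input", "Magnesium ion"),
    ("MMI1", "cytosol", "internal", "Translation machinery associated"),
    ("MSN2-4", "nucleus", "internal", "Multicopy suppressor of SNF1 mutation"),
    ("MT-ALT", "mitochondria", "internal", "Mitochondria alteration"),
    ("MT-FRAG", "mitochondria", "internal", "Mitochondria fragmentation"),
    ("NDI1", "mitochondria", "internal", "NADH dehydrogenase internal"),
    ("NMA111-CYT", "cytosol", "internal", "Nuclear mediator of apoptosis in cytosol"),
    ("NMA111-NUC", "nucleus", "internal", "Nuclear mediator of apoptosis in nucleus"),
    ("NUC1-MT", "mitochondria", "internal", "Nuclease 1 in mitochondria"),
    ("NUC1-NUC", "nucleus", "internal", "Nuclease 1 in nucleus"),
    ("PKA", "cytosol", "internal", "Protein kinase A"),
    ("POR1-2", "mitochondria", "internal", "Porin"),
    ("PROTOSOM", "cytosol", "internal", "Proteasome"),
    ("PTP2", "cytosol", "internal", "Protein tyrosine phosphatase 2"),
    ("PTP3", "cytosol", "internal", "Protein tyrosine phosphatase 3"),
    ("RAS2", "cytosol", "internal", "Homolog of RAS proto-oncogene"),
    ("RedActinDyn", "cytosol", "internal", "Reduced actin dynamics"),
    ("RLM1", "nucleus", "internal", "Resistance to lethality of MKK1P386 overexpression"),
    ("ROS-CYT", "cytosol", "internal", "Reactive oxygen species in cytosol"),
    ("ROS-MT", "mitochondria", "internal", "Reactive oxygen species in mitochondria"),
    ("RPD3", "nucleus", "internal", "Reduced potassium dependency"),
    ("SALT", "input", "input", "NaCl stress"),
    ("SDP1", "cytosol", "internal", "Stress-inducible dual-specificity phosphatase"),
    ("SLT2", "cytosol", "internal", "Cell-wall integrity MAP kinase"),
    ("SNO1", "cytosol", "internal", "SNZ proximal open reading frame"),
    ("SOD1", "cytosol", "internal", "Superoxide dismutase 1"),
    ("SOD2", "mitochondria", "internal", "Superoxide dismutase 2"),
    ("SRO7", "cytosol", "internal", "Suppressor of rho3"),
    ("STE20-CYT", "cytosol", "internal", "Sterile 20 in cytosol"),
    ("STE20-NUC", "nucleus", "internal", "Sterile 20 in nucleus"),
    ("STM1-CYT", "cytosol", "internal", "Translation initiation factor (Tif3) in cytosol"),
    ("STM1-NUC", "nucleus", "internal", "Translation initiation factor (Tif3) in nucleus"),
    ("STRESS", "input", "input", "Osmotic stress"),
    ("SVF1", "cytosol", "internal", "Survival factor"),
    ("TAT-D", "nucleus", "internal", "3'->5' exonuclease and endonuclease"),
    ("TOR1", "cytosol", "internal", "Target of rapamycin"),
    ("YCA1", "cytosol", "internal", "Metacaspase"),
)

#: Historical/variant spellings accepted on parse, keyed by canonical_key.
YEAST_ALIASES = {
    canonical_key(alias): target
    for alias, target in (
        ("AceticAcid", "ACETIC-ACID"),
        ("AIF-MT", "AIF1-MT"),
        ("AIF-NUC", "AIF1-NUC"),
        ("ABNORMALTELOMERASE", "ABNORMALTELOMER"),
        ("AbnormalTelomere", "ABNORMALTELOMER"),
        ("FVY10", "FYV10"),
        ("MatingPheromone", "MATING"),
        ("DesCyclinCCCDK8", "DESCYCLINCCDK8"),
        ("DesCYCLINCCDK8", "DESCYCLINCCDK8"),
        ("CytochromeC-CYT", "CYTC-CYT"),
        ("CytochromeC-MT", "CYTC-MT"),
        ("Proteasome", "PROTOSOM"),
        ("TatD", "TAT-D"),
        ("DNA-Fragmentation", "DNA-FRAG"),
        ("MT-Frag", "MT-FRAG"),
        ("Ros-MT", "ROS-MT"),
        ("Ros-CYT", "ROS-CYT"),
        ("Hog1Dep", "HOG1-DEP"),
        ("Akt", "AKT-SIGNALING"),
        ("AktSignaling", "AKT-SIGNALING"),
        ("Bcl-xL", "BCL-XL"),
        ("BclXL", "BCL-XL"),
        ("Bcl2", "BCL-2"),
        ("NFkB_Cyt", "NFKB-CYT"),
        ("NFkB_Nuc", "NFKB-NUC"),
        ("NFkB/IkBalpha", "NFKB/IKBA"),
        ("IkBalpha", "IKBA"),
        ("gp130/Stat3", "GP130-STAT3"),
    )
}

# (id, interaction, timescale, reference)
_YEAST_ARCS = (
    (1, "HK = AIF1-MT", 0, "housekeeping"),
    (2, "HK = DRE2/TAH18", 0, "housekeeping"),
    (3, "HK = EMC4", 0, "housekeeping"),
    (4, "HK = SVF1", 0, "housekeeping"),
    (5, "HK = FYV10", 0, "housekeeping"),
    (6, "HK = SOD2", 0, "housekeeping"),
    (7, "HK = SNO1", 0, "housekeeping"),
    (8, "HK = NDI1", 0, "housekeeping"),
    (9, "HK = POR1-2", 0, "housekeeping"),
    (10, "HK = MMI1", 0, "housekeeping"),
    (11, "HK = MCD1-MT", 0, "housekeeping"),
    (12, "HK = SRO7", 0, "housekeeping"),
    (13, "HK = CDC48", 0, "housekeeping"),
    (14, "HK = FIS1", 0, "housekeeping"),
    (15, "HK = MDV1", 0, "housekeeping"),
    (16, "HK = STM1-CYT", 0, "housekeeping"),
    (17, "= ACETIC-ACID", 2, "stimulus"),
    (18, "= ADOZELESIN", 2, "stimulus"),
    (19, "= CU2", 2, "stimulus"),
    (20, "= H2O2", 2, "stimulus"),
    (21, "= MATING", 2, "stimulus"),
    (22, "= MG2", 2, "stimulus"),
    (23, "= SALT", 2, "stimulus"),
    (24, "= HEAT", 2, "stimulus"),
    (25, "= STRESS", 2, "stimulus"),
    (26, "!SOD2 + NDI1 = ROS-MT", 4, "Li et al. 2006"),
    (27, "ACETIC-ACID = CYTC-MT", 4, "Ludovico et al. 2002"),
    (28, "CDC48 = CYTC-CYT", 4, "Eisenberg et al. 2007"),
    (29, "CYTC-CYT = YCA1", 4, "Eisenberg et al. 2007"),
    (30, "CYTC-MT = CYTC-CYT", 4, "Eisenberg et al. 2007"),
    (31, "MCD1-MT = CYTC-MT", 4, "Yang et al. 2008"),
    (32, "MEC1 = YCA1", 4, "Weinberger et al. 2005"),
    (33, "MT-FRAG = MT-ALT", 4, "Wissing et al. 2004"),
    (34, "!FYV10 = APOPTOSIS", 4, "Khoury et al. 2008"),
    (35, "2 CDC48 = ROS-CYT", 4, ""),
    (36, "CU2 + CPR3 = APOPTOSIS", 4, "Liang and Zhou 2007"),
    (37, "DNA-FRAG = APOPTOSIS", 4, "Madeo et al. 2004"),
    (38, "ESP1 = ROS-CYT", 4, "Yang et al. 2008"),
    (39, "MT-FRAG = YCA1", 4, "Eisenberg et al. 2007"),
    (40, "NMA111-CYT = NMA111-NUC", 4, "Walter et al. 2006"),
    (41, "NUC1-MT = KAP123", 4, "Buttner et al. 2007"),
    (42, "RAS2 = ADENYLATECYCLASE", 4, "Wood et al. 2004"),
    (43, "RAS2 = ROS-CYT", 4, "Kataoka et al. 1984"),
    (44, "RedActinDyn = ROS-CYT", 4, "Eisenberg et al. 2007"),
    (45, "RedActinDyn = YCA1", 4, "Madeo et al. 2004"),
    (46, "ROS-CYT = APOPTOSIS", 4, "Eisenberg et al. 2007"),
    (47, "ROS-CYT = YCA1", 4, "Madeo et al. 2002"),
    (48, "SALT = ROS-CYT", 4, "Wadskog et al. 2004"),
    (49, "SOD1 = ROS-CYT", 4, "Eisenberg et al. 2007"),
    (50, "STE20-NUC = H2B", 4, "Madeo et al. 2004"),
    (51, "STRESS = RPD3", 4, "Ahn et al. 2005"),
    (52, "TAT-D = DNA-FRAG", 4, "Qiu et al. 2005"),
    (53, "!SNO1 = APOPTOSIS", 4, "Khoury et al. 2008"),
    (54, "ABNORMALTELOMER = MEC1", 4, "Weinberger et al. 2005"),
    (55, "ADENYLATECYCLASE = CAMP", 4, "Schmelzle et al. 2004"),
    (56, "ADOZELESIN = CDC6", 4, "Blanchard et al. 2002"),
    (57, "AIF1-MT = AIF1-NUC", 4, "Wissing et al. 2004"),
    (58, "AIF1-NUC = H2B", 4, "Wissing et al. 2004"),
    (59, "APOPTOSIS =", 4, "output"),
    (60, "CDC6 = PROTOSOM", 4, "Blanchard et al. 2002"),
    (61, "ESP1 = MCD1-NUC", 4, "Yang et al. 2008"),
    (62, "H2O2 = NUC1-MT", 4, "Buttner et al. 2007"),
    (63, "H2O2 = ESP1", 4, "Yang et al. 2008"),
    (64, "H2O2 = HOS3", 4, "Carmona-Gutierrez et al. 2010"),
    (65, "HEAT = NMA111-CYT", 4, "Walter et al. 2006"),
    (66, "HOS3 = H2B", 4, "Carmona-Gutierrez et al. 2010"),
    (67, "KAP123 = NUC1-NUC", 4, "Buttner et al. 2007"),
    (68, "MAPK = STE20-CYT", 4, "Carmona-Gutierrez et al. 2010"),
    (69, "MATING = MAPK", 4, "Carmona-Gutierrez et al. 2010"),
    (70, "MG2 = TAT-D", 4, "Qiu et al. 2005"),
    (71, "MMI1 = MT-ALT", 4, "Eisenberg et al. 2007"),
    (72, "MT-ALT = MT-FRAG", 4, ""),
    (73, "NUC1-NUC = H2B", 4, "Buttner et al. 2007"),
    (74, "PKA = MT-ALT", 4, "Carmona-Gutierrez et al. 2010"),
    (75, "RAS2 = MT-ALT", 4, "Eisenberg et al. 2007"),
    (76, "RAS2 = PKA", 4, "Carmona-Gutierrez et al. 2010"),
    (77, "RedActinDyn = RAS2", 4, "Eisenberg et al. 2007"),
    (78, "RPD3 = H2B", 4, "Ahn et al. 2005"),
    (79, "STE20-CYT = STE20-NUC", 4, "Carmona-Gutierrez et al. 2010"),
    (80, "STRESS = ADENYLATECYCLASE", 4, "Schmelzle et al. 2004"),
    (81, "TOR1 = CAMP", 4, "Schmelzle et al. 2004"),
    (82, "TOR1 = RAS2", 4, "Schmelzle et al. 2004"),
    (83, "HEAT = SOD1", 4, ""),
    (84, "2 NDI1 = ROS-CYT", 4, ""),
    (85, "STRESS = TOR1", 4, "Schmelzle et al. 2004"),
    (86, "!PTP2 = SLT2", 5, "Hahn and Thiele 2002"),
    (87, "!PTP2 = HOG1", 5, "Hahn and Thiele 2002"),
    (88, "HOG1 = HOG1-DEP", 5, "Hahn and Thiele 2002"),
    (89, "!PTP3 = HOG1", 5, "Hahn and Thiele 2002"),
    (90, "!SDP1 = SLT2", 5, "Hahn and Thiele 2002"),
    (91, "!SLT2 = DESCYCLINCCDK8", 5, "Krasley et al. 2006"),
    (92, "!STRESS = SLT2", 5, "Hahn and Thiele 2002"),
    (93, "DESCYCLINCCDK8 = ROS-CYT", 5, "Krasley et al. 2006"),
    (94, "HEAT = PKA", 5, "Hahn and Thiele 2002"),
    (95, "HEAT = SLT2", 5, "Hahn and Thiele 2002"),
    (96, "HOG1 = RLM1", 5, "Hahn and Thiele 2002"),
    (97, "HOG1-DEP = PTP3", 5, "Hahn and Thiele 2002"),
    (98, "MSN2-4 = SDP1", 5, "Hahn and Thiele 2002"),
    (99, "PKA = MSN2-4", 5, "Hahn and Thiele 2002"),
    (100, "RLM1 = PTP2", 5, "Hahn and Thiele 2002"),
    (101, "RLM1 = SLT2", 5, "Hahn and Thiele 2002"),
    (102, "SLT2 = RLM1", 5, "Hahn and Thiele 2002"),
    (103, "STRESS = HOG1", 5, "Hahn and Thiele 2002"),
    (104, "!SRO7 + SALT = YCA1", 6, "Wadskog et al. 2004"),
    (105, "!STM1-NUC = DNA-FRAG", 6, "Ligr et al. 2001"),
    (106, "ACETIC-ACID + !SVF1 = ROS-CYT", 6, "Vander Heiden et al. 2002"),
    (107, "H2O2 + !EMC4 = ROS-CYT", 6, "Ring et al. 2008"),
    (108, "H2O2 + !SVF1 = ROS-CYT", 6, "Vander Heiden et al. 2002"),
    (109, "!FIS1 + MDV1 = MT-FRAG", 6, "Eisenberg et al. 2007"),
    (110, "!POR1-2 + ACETIC-ACID = APOPTOSIS", 6, "Pereira et al. 2007"),
    (111, "!POR1-2 + H2O2 = APOPTOSIS", 6, "Pereira et al. 2007"),
    (112, "H2O2 + !DRE2/TAH18 = MT-FRAG", 6, "Vernis et al. 2009"),
    (113, "YCA1 + !BIR1 = APOPTOSIS", 6, "Walter et al. 2006"),
    (114, "!NMA111-NUC = BIR1", 6, "Walter et al. 2006"),
    (115, "STM1-CYT + !PROTOSOM = STM1-NUC", 6, "Ligr et al. 2001"),
)


def _build(species_rows, arc_rows, name: str) -> LogicalNetwork:
    species = [SpeciesNode(*row) for row in species_rows]
    known = {canonical_key(s.name): s.name for s in species}
    arcs = [
        parse_interaction(rule, known, YEAST_ALIASES, arc_id=arc_id,
                          timescale=ts, reference=ref)
        for arc_id, rule, ts, ref in arc_rows
    ]
    return LogicalNetwork(species, arcs, name=name, aliases=YEAST_ALIASES)


def build_yeast_network() -> LogicalNetwork:
    """The full yeast apoptosis model: 73 species, 115 interactions, 9 inputs."""
    return _build(_YEAST_SPECIES, _YEAST_ARCS, "yeast-apoptosis")


# -- humanized extensions --------------------------------------------------

_BCL2_SPECIES = (
    ("UV", "input", "input", "UV irradiation"),
    ("AKT-SIGNALING", "input", "input", "Human Akt survival signalling"),
    ("P53", "nucleus", "internal", "Tumor suppressor p53"),
    ("BAD", "cytosol", "internal", "Bcl-2-associated death promoter"),
    ("BAX", "cytosol", "internal", "Bcl-2-associated X, pro-apoptotic"),
    ("BCL-2", "mitochondria", "internal", "B-cell lymphoma 2, anti-apoptotic"),
    ("BCL-XL", "mitochondria", "internal", "Bcl-extra-large, anti-apoptotic"),
)

# Akt phosphorylates Bad, dissociating it from the Bcl-2/Bcl-xL complex, so
# Bad is active only without Akt; active Bad sequesters Bcl-2/Bcl-xL.  UV
# stabilises p53 which induces Bax; Bax expressed in yeast releases
# cytochrome c, accumulates ROS and produces DNA fragmentation, and its
# apoptosis induction is gated by the anti-apoptotic Bcl proteins.
_BCL2_ARCS = (
    (201, "= UV", 2, "stimulus"),
    (202, "= AKT-SIGNALING", 2, "stimulus"),
    (203, "!AKT-SIGNALING = BAD", 4, "Datta et al. 1997"),
    (204, "!BAD = BCL-2", 4, "Datta et al. 1997"),
    (205, "!BAD = BCL-XL", 4, "Datta et al. 1997"),
    (206, "UV = P53", 4, "Kharbanda et al. 2000"),
    (207, "P53 = BAX", 4, "Kharbanda et al. 2000"),
    (208, "BAX = ROS-CYT", 4, "Madeo et al. 1999"),
    (209, "BAX = CYTC-CYT", 4, "Manon et al. 1997"),
    (210, "BAX = DNA-FRAG", 4, "Madeo et al. 1999"),
    (211, "BAX + !BCL-2 + !BCL-XL = APOPTOSIS", 6, "Sato et al. 1994"),
)

_VCP_SPECIES = (
    ("AKT-SIGNALING", "input", "input", "Human Akt survival signalling"),
    ("GP130-STAT3", "cytosol", "internal", "gp130/Stat3 survival pathway"),
    ("NFKB/IKBA", "cytosol", "internal", "NFkB/IkB-alpha complex dissociation"),
    ("IKBA", "cytosol", "internal", "IkB-alpha released for proteasomal degradation"),
    ("NFKB-CYT", "cytosol", "internal", "Active NFkB in cytosol"),
    ("NFKB-NUC", "nucleus", "internal", "Active NFkB in nucleus"),
    ("IAP", "cytosol", "internal", "Inhibitor-of-apoptosis family"),
    ("C-9-12", "cytosol", "internal", "Initiator caspases 9 and 12"),
    ("C-3-6-7", "cytosol", "internal", "Effector caspases 3, 6 and 7"),
    ("SURVIVAL", "other", "output", "Cell survival"),
)

# Akt acting through VCP dissociates IkB-alpha from NFkB (t=4); the freed
# NFkB activates (t=5) and translocates to the nucleus (t=6) driving
# survival and the IAP family, which keeps both caspase tiers shut; the
# parallel gp130-Stat3 branch also reaches survival.
_VCP_ARCS = (
    (301, "= AKT-SIGNALING", 2, "stimulus"),
    (302, "AKT-SIGNALING + VCP = NFKB/IKBA", 4, "Vandermoere et al. 2006"),
    (303, "NFKB/IKBA = IKBA", 4, "Vandermoere et al. 2006"),
    (304, "NFKB/IKBA = NFKB-CYT", 5, "Vandermoere et al. 2006"),
    (305, "NFKB-CYT = NFKB-NUC", 6, "Vandermoere et al. 2006"),
    (306, "NFKB-NUC = SURVIVAL", 6, "Vandermoere et al. 2006"),
    (307, "GP130-STAT3 = SURVIVAL", 6, "Braun and Zischka 2008"),
    (308, "AKT-SIGNALING + VCP = GP130-STAT3", 4, "Braun and Zischka 2008"),
    (309, "NFKB-NUC = IAP", 6, "Vandermoere et al. 2006"),
    (310, "CYTC-CYT + !IAP = C-9-12", 6, "Braun and Zischka 2008"),
    (311, "C-9-12 + !IAP = C-3-6-7", 6, "Braun and Zischka 2008"),
    (312, "C-3-6-7 = APOPTOSIS", 6, "Braun and Zischka 2008"),
)


def _check_base(base: LogicalNetwork, marker: str, extension: str) -> None:
    if canonical_key(marker) in {canonical_key(n) for n in base.species}:
        raise NetworkIntegrityError(
            f"{extension} extension already applied: species {marker!r} present"
        )


def build_bcl2_extension(base: LogicalNetwork | None = None) -> LogicalNetwork:
    """Yeast network plus the human Bcl-2 family module (Bax/Bad/Bcl-2/Bcl-xL)."""
    if base is None:
        base = build_yeast_network()
    _check_base(base, "BAX", "Bcl-2")
    species = list(base.species.values()) + [SpeciesNode(*row) for row in _BCL2_SPECIES]
    known = {canonical_key(s.name): s.name for s in species}
    arcs = list(base.arcs) + [
        parse_interaction(rule, known, YEAST_ALIASES, arc_id=i, timescale=ts,
                          reference=ref)
        for i, rule, ts, ref in _BCL2_ARCS
    ]
    return LogicalNetwork(species, arcs, name="yeast-apoptosis+bcl2",
                          aliases=YEAST_ALIASES)


def build_vcp_extension(base: LogicalNetwork | None = None) -> LogicalNetwork:
    """Yeast network with CDC48 replaced by human VCP and its downstream wiring.

    VCP inherits every CDC48 interaction, including the overexpression-gated
    ROS arc.
    """
    if base is None:
        base = build_yeast_network()
    _check_base(base, "VCP", "VCP")
    if "CDC48" not in base.species:
        raise NetworkIntegrityError("base network lacks CDC48; cannot humanize")

    def rename(name):
        return "VCP" if name == "CDC48" else name

    species = []
    for node in base.species.values():
        if node.name == "CDC48":
            node = SpeciesNode("VCP", node.compartment, node.role,
                               "Valosin-containing protein (human Cdc48 ortholog)")
        species.append(node)
    species += [SpeciesNode(*row) for row in _VCP_SPECIES]
    known = {canonical_key(s.name): s.name for s in species}

    arcs = []
    for arc in base.arcs:
        tail = tuple(Literal(rename(l.species), l.negated) for l in arc.tail)
        target = rename(arc.target) if arc.target else None
        arcs.append(HyperArc(arc.id, tail, target, arc.timescale, arc.reference,
                             arc.kind, arc.dose_gated))
    arcs += [
        parse_interaction(rule, known, YEAST_ALIASES, arc_id=i, timescale=ts,
                          reference=ref)
        for i, rule, ts, ref in _VCP_ARCS
    ]
    return LogicalNetwork(species, arcs, name="yeast-apoptosis+vcp",
                          aliases=YEAST_ALIASES)
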