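"""Reference results from the motivating case-control monocyte study.

A published integrated analysis of classical-monocyte DNA methylation
(Illumina EPIC, 12 systemic-sclerosis cases vs 12 controls) and gene
expression (RNA-seq, 16 cases vs 18 controls) reported 19 differentially
methylated CpGs (DMCs) and 1,272 differentially expressed transcripts at
FDR < 0.4.  The tables below hold the printed per-CpG summary rows and the
study-level counts; they are used as worked-example inputs and as scale
anchors for the synthetic-data generator (effect-size ranges), not as
substitutes for computation.
"""

from __future__ import annotations

import pandas as pd

#: CpGs tested after QC in the reference study.
N_CPGS_TESTED = 817_938
#: DMCs reported at FDR-adjusted p < 0.4.
N_DMCS_REPORTED = 19
#: Transcripts tested in the reference differential-expression analysis.
N_TRANSCRIPTS_TESTED = 25_369
#: Transcripts differentially expressed at FDR-adjusted p < 0.4.
N_DEGS_REPORTED = 1_272

#: Per-group sample sizes (methylation arm / expression arm).
N_METH_CASES, N_METH_CONTROLS = 12, 12
N_EXPR_CASES, N_EXPR_CONTROLS = 16, 18

# Reported top DMCs: probe, nearest gene, chromosome, position (kb),
# CpG-island relation, group mean betas, difference, p and BH-adjusted p.
_DMC_ROWS = [
    ("cg22805491", "NIN", "14", 51172, "OpenSea", 0.44, 0.53, 0.09, 2.99e-08, 0.02),
    ("cg24073653", "SLC41A2", "12", 105221, "OpenSea", 0.61, 0.69, 0.08, 2.92e-06, 0.20),
    ("cg19933320", "ZNF107", "7", 64125, "N_Shore", 0.33, 0.40, 0.08, 8.20e-06, 0.35),
    ("cg06548512", "LOC728989", "11", 46522, "Island", 0.63, 0.70, 0.07, 1.32e-07, 0.05),
    ("cg00832928", "SELENOT", "3", 150329, "Island", 0.61, 0.68, 0.07, 4.58e-07, 0.11),
    ("cg08653580", "CD5", "11", 60862, "OpenSea", 0.66, 0.73, 0.07, 1.21e-06, 0.16),
    ("cg12601237", "ST8SIA6", "10", 17429, "OpenSea", 0.71, 0.78, 0.07, 3.69e-06, 0.21),
    ("cg14115740", "FANCC", "9", 98055, "Island", 0.57, 0.64, 0.07, 4.74e-06, 0.24),
    ("cg22167498", "RAB11B-AS1", "19", 8451, "N_Shelf", 0.57, 0.62, 0.06, 1.00e-06, 0.16),
    ("cg23596249", "MARCHF1", "4", 165110, "Island", 0.51, 0.57, 0.06, 1.85e-06, 0.19),
    ("cg13704629", "DCAF4", "14", 73396, "S_Shelf", 0.56, 0.62, 0.06, 2.73e-06, 0.20),
    ("cg11652329", "P2RX6P", "22", 21399, "N_Shore", 0.61, 0.67, 0.05, 4.74e-06, 0.24),
    ("cg26715639", "S100A11", "1", 151986, "OpenSea", 0.60, 0.65, 0.05, 6.43e-06, 0.31),
    ("cg23493751", "CCR3", "3", 46205, "OpenSea", 0.75, 0.80, 0.05, 7.64e-06, 0.34),
    ("cg08288426", "ZSCAN29", "15", 43651, "OpenSea", 0.80, 0.76, -0.04, 1.51e-06, 0.17),
    ("cg18507060", "OAS3", "12", 113399, "OpenSea", 0.77, 0.81, 0.04, 5.48e-07, 0.11),
    ("cg10044900", "CFAP44", "3", 113058, "OpenSea", 0.76, 0.80, 0.04, 2.55e-06, 0.20),
    ("cg14929421", "ACTR3BP2", "2", 92318, "OpenSea", 0.52, 0.55, 0.03, 2.80e-06, 0.20),
    ("cg04331667", "CCDC71L", "7", 106171, "OpenSea", 0.80, 0.83, 0.03, 3.21e-06, 0.20),
]

# Reported top differentially expressed transcripts: gene, chromosome,
# start/end (kb), strand, log2 fold change, average log2 CPM, p, adjusted p.
_DEG_ROWS = [
    ("COL9A2", "1", 40766, 40883, "-", -1.18, 3.04, 1.26e-04, 0.25),
    ("OBSCN", "1", 228296, 228495, "+", -1.13, 2.13, 5.01e-04, 0.25),
    ("PPP1R14B", "11", 64012, 64114, "-", -0.65, 2.53, 2.17e-04, 0.25),
    ("GDAP1", "8", 75163, 75279, "+", 0.57, 4.10, 3.66e-04, 0.25),
    ("TMC8", "17", 76027, 76139, "+", -0.54, 6.38, 5.50e-05, 0.25),
    ("ZNF654", "3", 88088, 88194, "+", 0.43, 4.19, 2.37e-04, 0.25),
    ("KYNU", "2", 143535, 143735, "+", 0.43, 7.52, 3.25e-04, 0.25),
    ("KLF6", "10", 3818, 3927, "-", 0.42, 9.52, 1.94e-04, 0.25),
    ("INSIG2", "2", 118746, 118868, "+", 0.41, 3.65, 2.79e-04, 0.25),
    ("SLC35B3", "6", 8413, 8536, "-", 0.41, 4.39, 3.10e-04, 0.25),
    ("POT1", "7", 124470, 124670, "-", 0.41, 4.64, 4.27e-04, 0.25),
    ("HIVEP3", "1", 42284, 42484, "-", -0.40, 5.13, 2.65e-04, 0.25),
    ("HPSE", "4", 84216, 84356, "-", 0.40, 6.60, 6.95e-05, 0.25),
    ("MDM2", "12", 69102, 69239, "+", 0.37, 7.08, 1.42e-04, 0.25),
    ("ABHD5", "3", 43632, 43764, "+", 0.36, 5.80, 4.49e-04, 0.25),
    ("RNF146", "6", 127488, 127610, "+", 0.36, 5.85, 4.66e-04, 0.25),
    ("IVD", "15", 40598, 40714, "+", -0.34, 5.67, 2.20e-04, 0.25),
    ("SMARCA4", "19", 10972, 11172, "+", -0.31, 7.93, 2.97e-04, 0.25),
    ("PLD1", "3", 171428, 171628, "-", 0.27, 5.99, 1.78e-04, 0.25),
    ("CYTH4", "22", 37578, 37711, "+", -0.26, 7.88, 1.71e-04, 0.25),
]


def reported_dmcs() -> pd.DataFrame:
    """Reported top differentially methylated CpGs (19 rows)."""
    return pd.DataFrame(
        _DMC_ROWS,
        columns=[
            "probe_id", "nearest_gene", "chrom", "pos_kb", "island_relation",
            "control_mean_beta", "case_mean_beta", "difference", "p", "q",
        ],
    )


def reported_degs() -> pd.DataFrame:
    """Reported top differentially expressed transcripts (20 rows)."""
    return pd.DataFrame(
        _DEG_ROWS,
        columns=["gene", "chrom", "start_kb", "end_kb", "strand",
                 "logFC", "logCPM", "p", "q"],
    )
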