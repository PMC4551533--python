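"""Design constants and reported summary data for the HE4 CE-SELEX selection.

The selection this package models used a fixed-primer ssDNA library with a
25-nt random region, five positive selection rounds against HE4-GST at
decreasing protein concentration, and two negative (counter-selection)
rounds against free GST.  The constants below are the experiment's primer
sequences, its per-round sequencing summary, the candidate aptamers it
nominated, and their measured dissociation constants.  They serve as inputs
to the simulator and as reference points for the analysis drivers; nothing
in the pipeline machinery depends on them.
"""

from __future__ import annotations

import pandas as pd

#: Forward PCR/selection primer (read sense, 20 nt).  Synthesized 5'-FAM.
FORWARD_PRIMER = "AGCAGCACAGAGGTCAGATG"

#: Reverse-primer binding site as it appears on the library strand (20 nt).
#: The reverse PCR primer itself is the reverse complement of this.
REVERSE_PRIMER_SITE = "CCTATGCGTGCTACCGTGAA"

#: Reverse PCR primer (5'-biotin), reverse complement of the site above.
REVERSE_PRIMER = "TTCACGGTAGCACGCATAGG"

#: Length of the library's random region, in nucleotides.
RANDOM_REGION_LENGTH = 25

#: Illumina TruSeq universal adaptor; contamination by this sequence is a
#: recurrent artifact in sequenced SELEX pools.
ILLUMINA_ADAPTOR = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"

#: Protein (target) concentration per positive selection round, nM,
#: rounds R1..R5.
PROTEIN_CONC_SCHEDULE_NM = (50.0, 10.0, 5.0, 1.0, 0.5)

#: GST concentration used in the two negative rounds (R2-, R3-), nM.
NEGATIVE_PROTEIN_CONC_NM = (50.0, 25.0)

#: Per-run Illumina sequencing summary: round label, fraction sequenced,
#: number of reads, and percent sequence duplication.
SEQUENCING_RUNS = pd.DataFrame(
    [
        ("R0", "free", 6.7e6, 11.8),
        ("R1", "bound", 3.8e6, 13.0),
        ("R2+", "bound", 2.7e6, 14.0),
        ("R2-", "bound", 8.4e6, 12.4),
        ("R3+", "bound", 6.4e6, 14.0),
        ("R3-", "bound", 5.3e6, 20.0),
        ("R3-", "free", 6.2e6, 14.0),
        ("R4", "bound", 8.0e6, 24.1),
        ("R5", "bound", 10.1e6, 37.7),
    ],
    columns=["round_label", "fraction", "n_reads", "duplication_pct"],
)

#: Candidate aptamers nominated by the enrichment/clustering analysis:
#: selection round, fold-enrichment rank within that round, fold enrichment,
#: random-region sequence, external binding-potential Z-score, and the size
#: of the sequence cluster the candidate belongs to (None = not available).
CANDIDATES = pd.DataFrame(
    [
        ("A1", "R5", 1, 26.0, "TTATCGTACGACAGTCATCCTACAC", 10.75, 14),
        ("A3", "R5", 3, 22.0, "CACAGTGCGTCACATTTAGGGCATT", -7.06, 46),
        ("B10", "R4", 10, 14.0, "CAGTGCGTGCTTATTGGCGTAGCGTC", -2.08, 18),
        ("D3", "R2", 3, 12.0, "ATGGTCGCAAGAACTGAGAATTTAC", 1.6, 10),
        ("L1", "R0", 1, 1.0, "CCGTCTTCTGCTTGAAAAAAAAAAA", -15.9, None),
    ],
    columns=["id", "round", "rank", "enrichment", "sequence", "z_score", "cluster_size"],
)

#: Measured dissociation constants (nM) for the candidates against HE4-GST,
#: by fluorescence anisotropy and by affinity probe CE.  None = no
#: detectable interaction / not available.
KD_REPORTED_NM = pd.DataFrame(
    [
        ("A1", 2200.0, 390.0),
        ("A3", 9100.0, 500.0),
        ("B10", 280.0, 870.0),
        ("D3", 26000.0, None),
        ("L1", 750000.0, 300.0),
    ],
    columns=["id", "anisotropy_nM", "apce_nM"],
)

#: Aptamer concentrations held constant in the two binding assays, nM.
APCE_APTAMER_CONC_NM = 10.0
ANISOTROPY_APTAMER_CONC_NM = 100.0

#: Protein titration ceilings in the two assays, nM.
APCE_MAX_PROTEIN_NM = 240.0
ANISOTROPY_MAX_PROTEIN_NM = 750.0

#: Titration designs used when simulating the assays: evenly spaced
#: concentration grids over each assay's range.  APCE points are collected
#: in triplicate (CE injections are routinely run three times); anisotropy
#: plates in duplicate.
APCE_T_GRID_NM = tuple(float(t) for t in range(0, 241, 20))
APCE_REPLICATES = 3
ANISOTROPY_T_GRID_NM = tuple(750.0 * i / 12 for i in range(13))
ANISOTROPY_REPLICATES = 2
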