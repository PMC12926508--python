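"""Reported per-line summaries of the eight-line *Daphnia obtusa*
mutation-accumulation experiment.

These printed tables are inputs for desk-scale reproduction of the study's
headline arithmetic (pooled rates and confidence intervals, the conditional
spectrum, Ts/Tv, selection-corrected rates, N_e) without the raw sequencing
data.  Rates are per site per generation.
"""

LINES = ["13-507", "14-465", "20-479", "26-460",
         "27-508", "28-503", "33-427", "48-504"]

GENERATIONS = dict(zip(LINES, [507, 465, 479, 460, 508, 503, 427, 504]))

SNM_COUNTS = dict(zip(LINES, [112, 98, 246, 194, 164, 182, 208, 259]))
INDEL_COUNTS = dict(zip(LINES, [6, 3, 33, 27, 21, 18, 24, 48]))

SNM_RATES = dict(zip(LINES, [r * 1e-9 for r in
                             [1.26, 1.17, 3.08, 2.40, 1.83, 2.23, 2.76, 3.11]]))
INDEL_RATES = dict(zip(LINES, [r * 1e-10 for r in
                               [0.68, 0.36, 4.13, 3.33, 2.34, 2.21, 3.19, 5.77]]))

# six-type substitution counts and conditional rates (per site per generation),
# strand-collapsed, pyrimidine-centred keys
SIX_TYPE_COUNTS = {"C>T": 497, "T>C": 332, "T>A": 215,
                   "C>A": 186, "T>G": 144, "C>G": 89}
SIX_TYPE_RATES = {"C>T": 18.53e-10, "T>C": 8.59e-10, "T>A": 5.54e-10,
                  "C>A": 6.93e-10, "T>G": 3.71e-10, "C>G": 3.29e-10}

# LOH events per line and per-line LOH rates (per het site per generation)
LOH_EVENTS = dict(zip(LINES, [1, 0, 5, 6, 1, 8, 5, 22]))
LOH_RATES = dict(zip(LINES, [1.66e-6, 0.0, 8.36e-6, 2.40e-5,
                             1.02e-5, 5.60e-5, 6.05e-6, 1.36e-4]))

# selection-correction constants
NONSYN_GENOME_FRACTION = 0.21   # fraction of genomic sites that are nonsynonymous
NONSYN_DEFICIT = 0.47           # fractional under-observation of nonsynonymous SNMs
EXON_GENOME_FRACTION = 0.30     # fraction of the genome that is exonic
INDEL_EXON_DEFICIT = 0.71       # fractional under-observation of exonic indels

# synonymous-site diversity of the two natural populations
PI_S = {"RAP": 0.017, "EBG": 0.012}

# ancestral heterozygosity of the MA progenitor
ANCESTRAL_HET_FRACTION = 0.0057

# genome-wide GC content of the assembly
GENOME_GC = 0.409
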