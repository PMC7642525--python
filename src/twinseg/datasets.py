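"""Published recurrence tables from a six-family discordant-twin study.

A six-quartet exome study of monozygotic twins discordant for congenital
microtia-atresia reported (a) seven heterozygous de novo mutations in five
genes recurring in at least two families and (b) three genes recurrently
hit by CNVs across subjects. These encodings reproduce the per-family
variant lists and per-subject CNV carriers of those published tables so
the recurrence module can be exercised against known counts.

The HGVS labels, gene symbols, family memberships and subject IDs are as
published. Genomic coordinates were not printed and the ones used here are
SYNTHETIC stand-ins; they are internally consistent (the same variant gets
the same key in every family), which is all the recurrence analysis needs.
"""

from __future__ import annotations

import pandas as pd

from twinseg.cnvcall import CnvSegment
from twinseg.segfilter import CandidateEvent

# (gene, chrom, pos, ref, alt, hgvs_c, hgvs_p, functional_class, families)
_TABLE1 = [
    ("HOXA4", "7", 27170000, "A", "C", "c.920A>C", "p.H307P", "missense",
     ("II", "III", "V")),
    ("MUC6", "11", 1016000, "C", "T", "c.4553C>T", "p.T1518I", "missense",
     ("I", "IV")),
    ("MUC6", "11", 1017000, "C", "T", "c.5705C>T", "p.T1902I", "missense",
     ("I", "III")),
    ("CHST15", "10", 125800000, "AC", "A", "c.1366delC", "p.R456fs", "frameshift",
     ("I", "VI")),
    ("CHST15", "10", 125800100, "A", "AGCCC", "c.1356_1357insGCCC", "p.P453fs",
     "frameshift", ("III",)),
    ("TBX10", "11", 67600000, "C", "T", "c.791C>T", "p.P264L", "missense",
     ("I", "VI")),
    ("AMER1", "X", 64200000, "C", "T", "c.61C>T", "p.R21C", "missense",
     ("III", "V")),
]

# gene -> (synthetic interval, published carrier subjects)
_TABLE2 = {
    "UGT2B17": (("4", 69400000, 69430000), ("TWS01", "TWS06", "TWS18", "TWS12")),
    "OVOS": (("12", 8400000, 8430000), ("XH1535", "TWS06", "TWS18", "TWS22")),
    "KATNAL2": (("18", 46900000, 46980000), ("TWS06", "TWS12")),
}

#: One subject per family; "XH1535" is kept verbatim as published even
#: though it breaks the TWSxx naming scheme.
SUBJECT_FAMILY = {
    "TWS01": "I",
    "TWS06": "II",
    "XH1535": "III",
    "TWS12": "IV",
    "TWS18": "V",
    "TWS22": "VI",
}


def recurrent_variant_events() -> list[CandidateEvent]:
    """Per-family candidate events encoding the published variant table."""
    events = []
    for gene, chrom, pos, ref, alt, hgvs_c, hgvs_p, fclass, families in _TABLE1:
        for family in families:
            events.append(
                CandidateEvent(
                    family_id=family,
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    gene=gene,
                    functional_class=fclass,
                    hgvs_c=hgvs_c,
                    hgvs_p=hgvs_p,
                )
            )
    return events


def cnv_gene_intervals() -> pd.DataFrame:
    """Synthetic intervals for the three published CNV genes."""
    rows = [
        (gene, chrom, start, end)
        for gene, ((chrom, start, end), _) in _TABLE2.items()
    ]
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


def cnv_segments() -> list[CnvSegment]:
    """One called loss segment per published carrier, overlapping its gene."""
    segments = []
    for gene, ((chrom, start, end), subjects) in _TABLE2.items():
        for subject in subjects:
            segments.append(
                CnvSegment(
                    subject=subject,
                    chrom=chrom,
                    start=start,
                    end=end,
                    n_targets=5,
                    mean_log2_ratio=-1.0,
                    call="loss",
                )
            )
    return segments
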