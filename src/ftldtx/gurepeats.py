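"""GU(GT)-repeat content of gene sequences.

TDP-43 binds GU-rich stretches of pre-mRNA; on the DNA sense strand these
are alternating GT repeats.  This module counts overlapping occurrences of
the alternating motifs GTGT (tetramer), GTGTG (pentamer) and GTGTGT
(hexamer) in each gene's DNA sequence and classifies genes with
above-median content of any of the three as "high-GU" — putatively
TDP-43-regulated.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

_MOTIFS = {4: "GTGT", 5: "GTGTG", 6: "GTGTGT"}
_VALID = set("ACGTN")


def count_gu_kmers(sequence: str, k: int, *, overlapping: bool = True) -> int:
    """Occurrences of the alternating GT motif of length k in a DNA string.

    k must be 4, 5 or 6 (GTGT / GTGTG / GTGTGT).  Overlapping occurrences
    are counted by default; `overlapping=False` advances past each match.
    N matches nothing.
    """
    if k not in _MOTIFS:
        raise ValueError("k must be one of 4, 5, 6")
    seq = sequence.upper()
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    motif = _MOTIFS[k]
    if not overlapping:
        return seq.count(motif)
    count = 0
    start = 0
    while True:
        i = seq.find(motif, start)
        if i < 0:
            return count
        count += 1
        start = i + 1


def gu_profiles(sequences: Mapping[str, str], *, overlapping: bool = True) -> pd.DataFrame:
    """Per-gene overlapping counts c4, c5, c6 and sequence length."""
    rows = []
    for gene, seq in sequences.items():
        rows.append({
            "gene": gene,
            "c4": count_gu_kmers(seq, 4, overlapping=overlapping),
            "c5": count_gu_kmers(seq, 5, overlapping=overlapping),
            "c6": count_gu_kmers(seq, 6, overlapping=overlapping),
            "length": len(seq),
        })
    return pd.DataFrame(rows).set_index("gene")


def classify_high_gu(profiles: pd.DataFrame) -> set[str]:
    """Genes with strictly above-median c4 OR c5 OR c6.

    Medians are taken over all input genes (even-n midpoint); the
    disjunction means clearing any single criterion suffices.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 genes to define medians")
    med = profiles[["c4", "c5", "c6"]].median()
    high = (
        (profiles["c4"] > med["c4"])
        | (profiles["c5"] > med["c5"])
        | (profiles["c6"] > med["c6"])
    )
    return set(profiles.index[high])


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
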