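"""NAC core-motif scanning.

NAC-family transcription factors recognize a CGT[GA] core in promoter DNA.
The scanner counts every occurrence of the 4-mers CGTG and CGTA in a set of
promoter sequences (overlapping windows each counted; N never matches), on
the forward strand by default and optionally on both strands.
"""

from __future__ import annotations

import re

import pandas as pd

from .matrix_io import PromoterSet

__all__ = ["scan_cgt_motifs", "reverse_complement", "MOTIFS"]

MOTIFS = ("CGTG", "CGTA")
_PATTERN = re.compile(r"(?=(CGT[GA]))")
_COMP = str.maketrans("ACGTNRYSWKMBDHVU", "TGCANYRSWMKVHDBA")

HIT_COLUMNS = ["sequence_id", "offset", "strand", "motif"]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def scan_cgt_motifs(
    promoters: PromoterSet, both_strands: bool = False
) -> tuple[pd.DataFrame, pd.Series]:
    """Scan each promoter for CGT[GA] cores.

    Returns a hit table (sequence_id, 0-based offset, strand, motif) and a
    per-sequence count series. Minus-strand hits are reported in original
    (+ strand) coordinates: the offset where the reverse-complemented 4-mer
    begins on the forward sequence.
    """
    rows = []
    counts = {}
    for sid, seq in promoters.records:
        n = 0
        for m in _PATTERN.finditer(seq):
            rows.append((sid, m.start(), "+", m.group(1)))
            n += 1
        if both_strands:
            rc = reverse_complement(seq)
            L = len(seq)
            for m in _PATTERN.finditer(rc):
                rows.append((sid, L - 4 - m.start(), "-", m.group(1)))
                n += 1
        counts[sid] = n
    hits = pd.DataFrame(rows, columns=HIT_COLUMNS)
    if len(hits):
        hits = hits.sort_values(["sequence_id", "offset", "strand"], kind="mergesort")
        hits = hits.reset_index(drop=True)
    per_seq = pd.Series(counts, name="n_motifs", dtype=int)
    per_seq.index.name = "sequence_id"
    return hits, per_seq
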