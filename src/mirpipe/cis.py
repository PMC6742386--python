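"""Promoter extraction and cis-regulatory element counting.

The 1000 bp upstream of each precursor locus (strand-aware, truncated at
contig edges) serves as the promoter proxy. Named IUPAC consensus motifs
are counted at every (possibly overlapping) position, by default on both
strands; a palindromic consensus therefore counts each site once per
strand, a documented convention.
"""

from __future__ import annotations

import re
import warnings

import pandas as pd

from .io import IUPAC_CODES, Locus, NamedMotif, revcomp

DEFAULT_UPSTREAM = 1000

# Motif names reported for stress- and phytohormone-responsive promoter
# analysis; consensus strings are configurable stand-ins for database
# matrices and can be overridden from a motif TSV.
DEFAULT_MOTIFS = [
    NamedMotif("ARE", "AAACCA"),
    NamedMotif("Box-W1", "TTGACC"),
    NamedMotif("MBS", "CAACTG"),
    NamedMotif("CCAAT-box", "CAACGG"),
    NamedMotif("MBSII", "AAAAGTTAGTTA"),
    NamedMotif("GC-motif", "CCCCCG"),
    NamedMotif("HSE", "AAAAAATTTC"),
    NamedMotif("LTR", "CCGAAA"),
    NamedMotif("TC-rich repeats", "ATTTTCTTCA"),
    NamedMotif("WUN-motif", "AAATTTCCT"),
    NamedMotif("Box I", "TTTCAAA"),
    NamedMotif("G-box", "CACGTG"),
    NamedMotif("ABRE", "ACGTGGC"),
    NamedMotif("TGACG-motif", "TGACG"),
    NamedMotif("ERE", "ATTTCAAA"),
    NamedMotif("TCA-element", "CCATCTTTTT"),
    NamedMotif("TGA-element", "AACGAC"),
    NamedMotif("GARE-motif", "TCTGTTG"),
    NamedMotif("P-box", "CCTTTTG"),
    NamedMotif("TATC-box", "TATCCCA"),
]


def extract_promoter(genome: dict[str, str], locus: Locus,
                     upstream: int = DEFAULT_UPSTREAM) -> str:
    """Upstream sequence of a precursor locus, 5'->3' in its transcription
    direction; truncated at contig edges (empty sequence warns)."""
    contig = genome[locus.contig]
    if locus.strand == "+":
        start = max(0, locus.start - upstream)
        promoter = contig[start : locus.start]
    else:
        end = min(len(contig), locus.end + upstream)
        promoter = revcomp(contig[locus.end : end])
    if not promoter:
        warnings.warn(
            f"precursor at {locus.contig}:{locus.start}-{locus.end} has no "
            "upstream sequence", stacklevel=2,
        )
    return promoter


def iupac_regex(consensus: str) -> re.Pattern:
    """Compile an IUPAC consensus into an overlap-counting regex."""
    body = "".join(
        c if len(IUPAC_CODES[c]) == 1 else f"[{IUPAC_CODES[c]}]"
        for c in consensus
    )
    return re.compile(f"(?={body})")


def count_motif(sequence: str, motif: NamedMotif) -> int:
    """Occurrences of *motif* in *sequence* (both strands if configured),
    overlapping matches included."""
    pattern = iupac_regex(motif.consensus)
    count = len(pattern.findall(sequence))
    if motif.both_strands:
        count += len(pattern.findall(revcomp(sequence)))
    return count


def scan_motifs(promoter: str, motifs: list[NamedMotif]) -> dict[str, int]:
    """One promoter's motif-count row."""
    return {m.name: count_motif(promoter, m) for m in motifs}


def motif_count_matrix(
    genome: dict[str, str],
    loci: dict[str, Locus],
    motifs: list[NamedMotif] | None = None,
    upstream: int = DEFAULT_UPSTREAM,
) -> pd.DataFrame:
    """Precursor x motif count matrix with a Total column."""
    motifs = motifs if motifs is not None else DEFAULT_MOTIFS
    rows = {}
    for name in sorted(loci):
        promoter = extract_promoter(genome, loci[name], upstream)
        rows[name] = scan_motifs(promoter, motifs)
    matrix = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    matrix.index.name = "precursor"
    matrix["Total"] = matrix.sum(axis=1)
    return matrix
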