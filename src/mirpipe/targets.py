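"""Plant miRNA target scanning with an expectation-scored complementarity model.

Each transcript window of miRNA length is evaluated as a gapless duplex
against the miRNA: position p of the miRNA (1..L from its 5' end) faces
transcript position (window_start + L - p). A Watson-Crick pair costs 0,
a G:U wobble 0.5 and a mismatch 1.0; penalties in the seed region
(positions 2-13) are doubled. The expectation is the penalty total and
sites are reported up to a cutoff (default 3, the conventional plant
stringency). A mismatch or wobble facing positions 10-11 (the slicing
site) switches the predicted inhibition from cleavage to translation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ValidationError

DEFAULT_CUTOFF = 3.0
SEED_START, SEED_END = 2, 13          # 1-based, inclusive
CLEAVAGE_POSITIONS = (10, 11)
MISMATCH_PENALTY = 1.0
WOBBLE_PENALTY = 0.5
SEED_MULTIPLIER = 2.0

_BASE = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP = {0: 3, 1: 2, 2: 1, 3: 0}


@dataclass
class TargetHit:
    mirna: str
    transcript: str
    start: int                 # 0-based window start on the transcript
    expectation: float
    mode: str                  # "cleavage" | "translation"
    mirna_seq: str
    site_seq: str              # transcript window, 5'->3'


def _encode(seq: str, label: str) -> np.ndarray:
    try:
        return np.fromiter((_BASE[c] for c in seq), dtype=np.int8, count=len(seq))
    except KeyError as exc:
        raise ValidationError(f"{label}: non-nucleotide character {exc}") from None


def _penalties(mirna: np.ndarray, site_rev: np.ndarray) -> np.ndarray:
    """Per-position penalties for a miRNA against site bases in 3'->5' order."""
    comp = np.array([_COMP[b] for b in mirna], dtype=np.int8)
    wc = site_rev == comp
    wobble = ((mirna == _BASE["G"]) & (site_rev == _BASE["T"])) | (
        (mirna == _BASE["T"]) & (site_rev == _BASE["G"])
    )
    pen = np.where(wc, 0.0, np.where(wobble, WOBBLE_PENALTY, MISMATCH_PENALTY))
    positions = np.arange(1, mirna.size + 1)
    seed = (positions >= SEED_START) & (positions <= SEED_END)
    return np.where(seed, SEED_MULTIPLIER * pen, pen)


def score_duplex(mirna: str, site: str) -> float:
    """Expectation of a gapless duplex; *site* is the transcript window 5'->3'."""
    if len(mirna) != len(site):
        raise ValidationError("miRNA and target window must have equal length")
    m = _encode(mirna.upper().replace("U", "T"), "miRNA")
    s = _encode(site.upper().replace("U", "T"), "site")
    return float(_penalties(m, s[::-1]).sum())


def duplex_mode(mirna: str, site: str) -> str:
    """Cleavage unless a mismatch/wobble sits at miRNA position 10 or 11."""
    m = _encode(mirna.upper().replace("U", "T"), "miRNA")
    s = _encode(site.upper().replace("U", "T"), "site")
    comp = np.array([_COMP[b] for b in m], dtype=np.int8)
    wc = s[::-1] == comp
    for pos in CLEAVAGE_POSITIONS:
        if pos <= m.size and not wc[pos - 1]:
            return "translation"
    return "cleavage"


def find_targets(
    mirna_name: str,
    mirna: str,
    transcriptome: dict[str, str],
    cutoff: float = DEFAULT_CUTOFF,
) -> list[TargetHit]:
    """Scan every transcript window for sites with expectation <= cutoff.

    Hits are sorted by (expectation, transcript id, position).
    """
    mirna = mirna.upper().replace("U", "T")
    m = _encode(mirna, "miRNA")
    L = m.size
    comp = np.array([_COMP[b] for b in m], dtype=np.int8)
    positions = np.arange(1, L + 1)
    seed = (positions >= SEED_START) & (positions <= SEED_END)
    cleave_mask = np.isin(positions, CLEAVAGE_POSITIONS)

    hits: list[TargetHit] = []
    for tx_name in sorted(transcriptome):
        seq = transcriptome[tx_name]
        if len(seq) < L:
            continue
        enc = _encode(seq, tx_name)
        windows = np.lib.stride_tricks.sliding_window_view(enc, L)[:, ::-1]
        wc = windows == comp
        wobble = ((m[None, :] == _BASE["G"]) & (windows == _BASE["T"])) | (
            (m[None, :] == _BASE["T"]) & (windows == _BASE["G"])
        )
        pen = np.where(wc, 0.0, np.where(wobble, WOBBLE_PENALTY, MISMATCH_PENALTY))
        pen = np.where(seed[None, :], SEED_MULTIPLIER * pen, pen)
        expectation = pen.sum(axis=1)
        for start in np.nonzero(expectation <= cutoff)[0]:
            mode = "translation" if (~wc[start, cleave_mask]).any() else "cleavage"
            site = seq[start : start + L]
            hits.append(
                TargetHit(mirna_name, tx_name, int(start),
                          float(expectation[start]), mode, mirna, site)
            )
    hits.sort(key=lambda h: (h.expectation, h.transcript, h.start))
    return hits
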