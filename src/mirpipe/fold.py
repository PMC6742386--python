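"""Maximum base-pairing secondary structure and hairpin acceptance.

Novel miRNA loci are accepted or rejected on the secondary structure of the
genomic window around the candidate read. The fold is a Nussinov-style
maximum-matching dynamic programme over canonical pairs (A:T, G:C and the
G:T wobble, the DNA spelling of G:U) with a minimum hairpin loop of 3 nt.
This is a combinatorial stand-in for thermodynamic folding: it is exactly
reproducible, parameter-free, and oracle-checkable by exhaustive enumeration
on small sequences; a thermodynamic backend can be substituted behind the
same :class:`HairpinCall` contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

MIN_LOOP = 3

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
# allowed pairs: AT/TA, GC/CG, GT/TG; N pairs with nothing
_PAIRABLE = np.zeros((5, 5), dtype=bool)
for a, b in ("AT", "TA", "GC", "CG", "GT", "TG"):
    _PAIRABLE[_BASE_INDEX[a], _BASE_INDEX[b]] = True


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_INDEX.get(c, 4) for c in seq), dtype=np.int8, count=len(seq))


try:  # jitted DP kernel; the numpy path below is the fallback
    from numba import njit

    @njit(cache=False)
    def _dp_fill(pairable, n, min_loop):  # pragma: no cover - exercised via max_pairing
        dp = np.zeros((n + 1, n + 1), dtype=np.int32)
        for span in range(min_loop + 1, n):
            for i in range(0, n - span):
                j = i + span
                best = dp[i, j - 1]
                for k in range(i, j - min_loop):
                    if pairable[k, j]:
                        left = dp[i, k - 1] if k > i else 0
                        val = left + dp[k + 1, j - 1] + 1
                        if val > best:
                            best = val
                dp[i, j] = best
        return dp

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _dp_fill_numpy(pairable: np.ndarray, n: int, min_loop: int) -> np.ndarray:
    dp = np.zeros((n + 1, n + 1), dtype=np.int32)  # row n = empty pad
    for span in range(min_loop + 1, n):
        i = np.arange(0, n - span)
        j = i + span
        best = dp[i, j - 1].copy()
        for t in range(0, span - min_loop):
            k = i + t
            ok = pairable[k, j]
            if not ok.any():
                continue
            left = dp[i, k - 1] if t > 0 else 0
            val = left + dp[k + 1, j - 1] + 1
            np.copyto(best, np.maximum(best, val), where=ok)
        dp[i, j] = best
    return dp


def max_pairing(seq: str, min_loop: int = MIN_LOOP) -> tuple[list[tuple[int, int]], str]:
    """Maximum-cardinality nested pairing of *seq*.

    Returns the pair list (i<j, 0-based) of one maximum structure and its
    dot-bracket string. Ties are broken deterministically by the traceback
    order (prefer leaving the last base unpaired, then the 5'-most partner).

    dp[i, j] = max(dp[i, j-1], max_k dp[i, k-1] + dp[k+1, j-1] + 1) over
    pairable (k, j) with k <= j - min_loop - 1.
    """
    n = len(seq)
    if n == 0:
        return [], ""
    enc = _encode(seq)
    pairable = _PAIRABLE[enc[:, None], enc[None, :]]
    if _HAVE_NUMBA:
        dp = _dp_fill(pairable, n, min_loop)
    else:
        dp = _dp_fill_numpy(pairable, n, min_loop)

    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i < min_loop + 1:
            continue
        if dp[i, j] == dp[i, j - 1]:
            stack.append((i, j - 1))
            continue
        target = dp[i, j]
        for k in range(i, j - min_loop):
            if pairable[k, j]:
                left = dp[i, k - 1] if k > i else 0
                if left + dp[k + 1, j - 1] + 1 == target:
                    pairs.append((k, j))
                    if k > i:
                        stack.append((i, k - 1))
                    stack.append((k + 1, j - 1))
                    break

    brackets = ["."] * n
    for a, b in pairs:
        brackets[a] = "("
        brackets[b] = ")"
    return sorted(pairs), "".join(brackets)


@dataclass
class HairpinCall:
    """Verdict on whether a candidate read sits in one arm of a stem-loop."""

    window: str
    structure: str
    paired_fraction: float
    is_hairpin: bool
    arm: str  # "5p" | "3p" | "spans_loop" | "n/a"
    stem_positions: int = 0


@lru_cache(maxsize=4096)
def _fold_cached(seq: str) -> tuple[tuple[tuple[int, int], ...], str]:
    pairs, structure = max_pairing(seq)
    return tuple(pairs), structure


def call_hairpin(
    window: str,
    cand_start: int,
    cand_end: int,
    min_paired_fraction: float = 0.6,
    min_stem_positions: int = 18,
) -> HairpinCall:
    """Fold *window* and decide whether [cand_start, cand_end) lies in a stem arm.

    Acceptance requires the candidate to be entirely within one arm (every
    paired candidate base finds its partner on the same, outside flank), a
    paired fraction of candidate bases >= *min_paired_fraction*, and a stem
    of >= *min_stem_positions* paired positions (pairs enclosing the
    candidate's innermost pair, counted as positions, i.e. 2 per pair).
    """
    n = len(window)
    cand_len = cand_end - cand_start
    if not (0 <= cand_start < cand_end <= n):
        raise ValueError("candidate interval outside window")
    if n < cand_len + 15:
        # too little flank to form a stem on either side
        return HairpinCall(window, "." * n, 0.0, False, "n/a")

    pairs, structure = _fold_cached(window)
    partner = np.full(n, -1, dtype=np.int64)
    for a, b in pairs:
        partner[a] = b
        partner[b] = a

    cand_positions = np.arange(cand_start, cand_end)
    cand_partners = partner[cand_positions]
    paired_mask = cand_partners >= 0
    paired_fraction = float(paired_mask.mean()) if cand_len else 0.0

    if not paired_mask.any():
        return HairpinCall(window, structure, 0.0, False, "n/a")

    partners = cand_partners[paired_mask]
    if (partners >= cand_end).all():
        arm = "5p"
    elif (partners < cand_start).all():
        arm = "3p"
    else:
        arm = "spans_loop"

    stem_positions = 0
    if arm in ("5p", "3p"):
        # innermost candidate pair = the one with the tightest enclosed interval
        cand_pairs = [
            (min(int(p), int(q)), max(int(p), int(q)))
            for p, q in zip(cand_positions[paired_mask], partners)
        ]
        inner_i = max(a for a, _ in cand_pairs)
        inner_j = min(b for _, b in cand_pairs)
        stem_positions = 2 * sum(1 for a, b in pairs if a <= inner_i and b >= inner_j)

    is_hairpin = (
        arm in ("5p", "3p")
        and paired_fraction >= min_paired_fraction
        and stem_positions >= min_stem_positions
    )
    return HairpinCall(window, structure, paired_fraction, is_hairpin, arm, stem_positions)
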