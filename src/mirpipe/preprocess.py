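"""Raw-read filter cascade and unique-tag collapsing.

Raw FASTQ reads are trimmed of the 3' adapter, screened for adapter dimers,
missing adapters, low-complexity ("junk") inserts and out-of-range lengths,
collapsed to unique tags with per-library counts, and finally screened
against the non-miRNA contaminant classes (rRNA, tRNA, snRNA, snoRNA,
repeats, mRNA) by exact substring match. Every read receives exactly one
fate, so fate counts partition the raw read total.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache

import pandas as pd

from .io import CONTAMINANT_CLASSES

MIN_READ_LENGTH = 15
MAX_READ_LENGTH = 32

FATES = (
    "adapter_dimer",
    "no_3_adapter",
    "junk",
    "too_short",
    "too_long",
    *CONTAMINANT_CLASSES,
    "retained",
)


class AdapterRejection(Exception):
    """Internal signal: read rejected during adapter trimming."""

    def __init__(self, fate: str):
        self.fate = fate


def trim_adapter(read: str, adapter: str, min_prefix: int = 6) -> str:
    """Return the insert preceding the left-most 3' adapter occurrence.

    A full adapter match anywhere, or a >= *min_prefix*-nt prefix of the
    adapter flush with the read end, counts as found. An empty insert raises
    with fate ``adapter_dimer``; no match raises with fate ``no_3_adapter``.
    """
    if len(adapter) < min_prefix:
        raise ValueError(f"adapter must be at least {min_prefix} nt")
    pos = read.find(adapter)
    if pos < 0:
        # allow a truncated adapter prefix at the very end of the read
        for k in range(len(adapter) - 1, min_prefix - 1, -1):
            if read.endswith(adapter[:k]):
                pos = len(read) - k
                break
    if pos < 0:
        raise AdapterRejection("no_3_adapter")
    if pos == 0:
        raise AdapterRejection("adapter_dimer")
    return read[:pos]


_DINUC_PATTERNS = [
    re.compile(f"(?:{a}{b})+{a}?")
    for a in "ACGT"
    for b in "ACGT"
    if a != b
]


@lru_cache(maxsize=100_000)
def is_junk(seq: str) -> bool:
    """Low-complexity test: mononucleotide >= 80% of length, any dinucleotide
    tandem repeat covering >= 90%, or an ambiguous base present."""
    n = len(seq)
    if n == 0 or "N" in seq:
        return True
    counts = Counter(seq)
    top2 = sum(c for _, c in counts.most_common(2))
    if max(counts.values()) / n >= 0.8:
        return True
    if top2 / n >= 0.9:  # a 90% dinucleotide repeat needs two bases at 90%
        for pat in _DINUC_PATTERNS:
            best = max((m.end() - m.start() for m in pat.finditer(seq)), default=0)
            if best / n >= 0.9:
                return True
    return False


def filter_junk(seq: str) -> str:
    """Return ``junk`` or ``retained``."""
    return "junk" if is_junk(seq) else "retained"


def length_filter(seq: str, min_len: int = MIN_READ_LENGTH, max_len: int = MAX_READ_LENGTH) -> str:
    """Return ``too_short`` / ``too_long`` / ``retained`` for the insert length."""
    if len(seq) < min_len:
        return "too_short"
    if len(seq) > max_len:
        return "too_long"
    return "retained"


def classify_read(read: str, adapter: str) -> tuple[str, str | None]:
    """Apply the per-read cascade; returns (fate, insert-or-None)."""
    try:
        insert = trim_adapter(read, adapter)
    except AdapterRejection as rej:
        return rej.fate, None
    if is_junk(insert):
        return "junk", insert
    fate = length_filter(insert)
    if fate != "retained":
        return fate, insert
    return "retained", insert


def collapse_unique(inserts: list[str]) -> Counter:
    """Collapse a library's retained inserts to {sequence: count}."""
    return Counter(inserts)


def contaminant_fate(tag: str, contaminants: dict[str, dict[str, str]]) -> str:
    """First contaminant class (fixed order) containing *tag* as substring,
    else ``retained``."""
    for cls in CONTAMINANT_CLASSES:
        for seq in contaminants.get(cls, {}).values():
            if tag in seq:
                return cls
    return "retained"


@dataclass
class PreprocessResult:
    """Per-library unique-tag counts plus the full fate accounting."""

    tag_counts: pd.DataFrame          # index: sequence; columns: library names (retained tags)
    fate_summary: pd.DataFrame        # index: fate; columns: library names (read counts)
    tag_fates: dict[str, str] = field(default_factory=dict)
    raw_totals: dict[str, int] = field(default_factory=dict)

    @property
    def clean_totals(self) -> pd.Series:
        """Retained (clean) read totals per library — the normalization denominator."""
        return self.tag_counts.sum(axis=0)


def preprocess_libraries(
    libraries: dict[str, list[str]],
    adapter: str,
    contaminants: dict[str, dict[str, str]] | None = None,
) -> PreprocessResult:
    """Run the full cascade over {library_name: [raw read sequences]}.

    Contaminant screening operates on unique tags (a tag has one fate across
    all libraries); the fate summary counts reads, so per-library fate counts
    sum to the raw read total.
    """
    contaminants = contaminants or {}
    per_lib_counts: dict[str, Counter] = {}
    fate_counts: dict[str, Counter] = {}
    raw_totals: dict[str, int] = {}

    for lib, reads in libraries.items():
        raw_totals[lib] = len(reads)
        fates: Counter = Counter()
        retained: list[str] = []
        for read in reads:
            fate, insert = classify_read(read, adapter)
            if fate == "retained":
                retained.append(insert)
            else:
                fates[fate] += 1
        per_lib_counts[lib] = collapse_unique(retained)
        fate_counts[lib] = fates

    all_tags = sorted(set().union(*per_lib_counts.values()) if per_lib_counts else set())
    tag_fates = {tag: contaminant_fate(tag, contaminants) for tag in all_tags}

    kept_tags = [t for t in all_tags if tag_fates[t] == "retained"]
    data = {
        lib: [per_lib_counts[lib].get(t, 0) for t in kept_tags] for lib in libraries
    }
    tag_counts = pd.DataFrame(data, index=pd.Index(kept_tags, name="sequence"), dtype=int)

    for lib in libraries:
        for tag, fate in tag_fates.items():
            if fate != "retained":
                fate_counts[lib][fate] += per_lib_counts[lib].get(tag, 0)
        fate_counts[lib]["retained"] = sum(
            per_lib_counts[lib].get(t, 0) for t in kept_tags
        )
    fate_summary = pd.DataFrame(
        {lib: [fate_counts[lib].get(f, 0) for f in FATES] for lib in libraries},
        index=pd.Index(FATES, name="fate"),
        dtype=int,
    )
    return PreprocessResult(tag_counts, fate_summary, tag_fates, raw_totals)
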