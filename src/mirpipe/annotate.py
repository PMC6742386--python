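"""Tolerant tag-to-reference matching, the isomiR naming grammar,
hairpin-backed classification into the group taxonomy, and its inverse
(reconstructing a tag from a name).

A unique tag of 18-25 nt is aligned against annotated mature miRNAs
allowing length variation at both ends and at most one substitution strictly
inside the detected sequence. End extensions must copy the precursor
context, so an extended read still maps to its hairpin. The best match
minimises cost = |left_delta| + |right_delta| + 2 x substitutions; ties go
to the lexicographically smallest reference name.

Names encode the match: ``base_L-2R+2`` (two fewer bases on the left, two
more on the right), ``base_1ss8GA`` (reference G read as A at detected
position 8), and plain ``base`` for an exact match. Reads mapping to the
arm opposite the annotated mature get a ``-p5``/``-p3`` suffix on the
precursor stem name.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .fold import HairpinCall, call_hairpin
from .io import Locus, MatureRecord, ReferenceBundle, revcomp

GROUPS = ("1a", "1b", "2a", "2b", "3a", "3b", "4a", "others", "nohit")

MIN_MAP_LENGTH = 18
MAX_MAP_LENGTH = 25
DEFAULT_END_TOLERANCE = 4
DEFAULT_FLANK = 120
DEFAULT_MAX_GENOME_LOCI = 10


@dataclass
class MatchResult:
    """A tolerant alignment of a detected tag to a reference mature."""

    tag: str
    reference: str            # mature name
    arm: str                  # "annotated" | "opposite" | "n/a"
    left_delta: int           # + : detected has extra bases on the left
    right_delta: int
    substitutions: list[tuple[int, str, str]]  # (pos 1-based on detected, ref, obs)
    cost: float


@dataclass
class OppositeArmMatch:
    """A tag placed on the arm opposite the annotated mature."""

    tag: str
    precursor: str
    position: int             # 0-based start on the precursor
    candidate_arm: str        # "p5" | "p3"
    substitutions: list[tuple[int, str, str]]


@dataclass
class GenomeHit:
    contig: str
    strand: str
    start: int
    end: int

    def locus(self) -> Locus:
        return Locus(self.contig, self.strand, self.start, self.end)


@dataclass
class AnnotationRecord:
    tag: str
    group: str
    name: str
    match: MatchResult | None = None
    opposite: OppositeArmMatch | None = None
    hairpin: HairpinCall | None = None
    loci: list[GenomeHit] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Matching

def _mature_context(rec: MatureRecord, precursors: dict[str, str]) -> tuple[str, str]:
    prec = precursors[rec.precursor]
    return prec, prec[rec.start : rec.end]


def match_tag(
    tag: str,
    matures: dict[str, MatureRecord],
    precursors: dict[str, str],
    end_tolerance: int = DEFAULT_END_TOLERANCE,
    max_substitutions: int = 1,
) -> MatchResult | None:
    """Best tolerant match of *tag* against annotated matures, or None.

    Only tags of 18-25 nt are eligible; others raise ValueError (callers
    route them to the genome-only stages). Substitutions are forbidden at
    the first and last detected base; end extensions must equal the
    precursor context at the annotated interval.
    """
    if not MIN_MAP_LENGTH <= len(tag) <= MAX_MAP_LENGTH:
        raise ValueError(f"tag length {len(tag)} outside {MIN_MAP_LENGTH}-{MAX_MAP_LENGTH}")
    best: MatchResult | None = None
    best_key: tuple | None = None
    for name in sorted(matures):
        rec = matures[name]
        prec = precursors[rec.precursor]
        ref_len = rec.end - rec.start
        for left_delta in range(-end_tolerance, end_tolerance + 1):
            right_delta = len(tag) - ref_len - left_delta
            if abs(right_delta) > end_tolerance:
                continue
            start = rec.start - left_delta
            end = rec.end + right_delta
            if start < 0 or end > len(prec) or start >= end:
                continue
            variant = prec[start:end]
            subs = [
                (i + 1, r, o)
                for i, (r, o) in enumerate(zip(variant, tag))
                if r != o
            ]
            if len(subs) > max_substitutions:
                continue
            if any(pos == 1 or pos == len(tag) for pos, _, _ in subs):
                continue
            cost = abs(left_delta) + abs(right_delta) + 2 * len(subs)
            key = (cost, name, abs(left_delta), left_delta)
            if best_key is None or key < best_key:
                best_key = key
                best = MatchResult(tag, name, "annotated", left_delta, right_delta, subs, cost)
    return best


def match_opposite_arm(
    tag: str,
    matures: dict[str, MatureRecord],
    precursors: dict[str, str],
    end_tolerance: int = DEFAULT_END_TOLERANCE,
    max_substitutions: int = 1,
) -> OppositeArmMatch | None:
    """Place *tag* on a precursor outside the annotated mature's arm.

    The placement is exact at both ends with at most one internal
    substitution; positions overlapping the annotated mature interval
    (widened by the end tolerance) belong to the annotated arm and are
    excluded.
    """
    if not MIN_MAP_LENGTH <= len(tag) <= MAX_MAP_LENGTH:
        raise ValueError(f"tag length {len(tag)} outside {MIN_MAP_LENGTH}-{MAX_MAP_LENGTH}")
    for name in sorted(matures):
        rec = matures[name]
        prec = precursors[rec.precursor]
        lo = rec.start - end_tolerance
        hi = rec.end + end_tolerance
        for pos in range(0, len(prec) - len(tag) + 1):
            if pos + len(tag) > lo and pos < hi:
                continue  # overlaps the annotated arm region
            window = prec[pos : pos + len(tag)]
            subs = [
                (i + 1, r, o)
                for i, (r, o) in enumerate(zip(window, tag))
                if r != o
            ]
            if len(subs) > max_substitutions:
                continue
            if any(p == 1 or p == len(tag) for p, _, _ in subs):
                continue
            candidate_arm = "p5" if pos + len(tag) <= rec.start + end_tolerance else "p3"
            return OppositeArmMatch(tag, rec.precursor, pos, candidate_arm, subs)
    return None


def map_to_genome(
    tag: str,
    genome: dict[str, str],
    max_loci: int = DEFAULT_MAX_GENOME_LOCI,
) -> list[GenomeHit]:
    """All exact occurrences of *tag* on either genome strand.

    Stops after *max_loci* + 1 hits (enough to detect the over-cap case).
    """
    hits: list[GenomeHit] = []
    rc = revcomp(tag)
    for contig in sorted(genome):
        seq = genome[contig]
        for strand, query in (("+", tag), ("-", rc)):
            start = seq.find(query)
            while start >= 0:
                hits.append(GenomeHit(contig, strand, start, start + len(query)))
                if len(hits) > max_loci:
                    return hits
                start = seq.find(query, start + 1)
    return hits


# ---------------------------------------------------------------------------
# Naming grammar

_SUFFIX_RE = re.compile(
    r"^(?:L(?P<ld>[+-]\d+))?(?:R(?P<rd>[+-]\d+))?"
    r"(?:_?(?P<ns>\d+)ss(?P<sub>(?:\d+[ACGT][ACGT])+))?$"
)
_SUB_RE = re.compile(r"(\d+)([ACGT])([ACGT])")


def format_suffix(left_delta: int, right_delta: int,
                  substitutions: list[tuple[int, str, str]]) -> str:
    """Render the matching annotation, e.g. ``L-2R+2`` or ``R+1_1ss8GA``."""
    parts = []
    lr = ""
    if left_delta:
        lr += f"L{left_delta:+d}"
    if right_delta:
        lr += f"R{right_delta:+d}"
    if lr:
        parts.append(lr)
    if substitutions:
        body = "".join(f"{pos}{ref}{obs}" for pos, ref, obs in substitutions)
        parts.append(f"{len(substitutions)}ss{body}")
    return "_".join(parts)


def name_mirna(base_name: str, match: MatchResult | None = None,
               opposite_arm: str | None = None) -> str:
    """Compose a miRNA name from the reference base name and the match.

    An exact match keeps the base name; end shifts and substitutions are
    appended after an underscore; opposite-arm candidates are suffixed
    ``-p5``/``-p3`` on the precursor name instead.
    """
    if opposite_arm is not None:
        return f"{base_name}-{opposite_arm}"
    if match is None:
        return base_name
    suffix = format_suffix(match.left_delta, match.right_delta, match.substitutions)
    return f"{base_name}_{suffix}" if suffix else base_name


def parse_suffix(suffix: str) -> tuple[int, int, list[tuple[int, str, str]]]:
    """Parse a matching annotation back into (left_delta, right_delta, subs)."""
    m = _SUFFIX_RE.match(suffix)
    if m is None:
        raise ValueError(f"unparseable isomiR suffix {suffix!r}")
    left_delta = int(m.group("ld")) if m.group("ld") else 0
    right_delta = int(m.group("rd")) if m.group("rd") else 0
    subs: list[tuple[int, str, str]] = []
    if m.group("sub"):
        subs = [(int(p), r, o) for p, r, o in _SUB_RE.findall(m.group("sub"))]
        if int(m.group("ns")) != len(subs):
            raise ValueError(f"substitution count mismatch in {suffix!r}")
    return left_delta, right_delta, subs


def reconstruct_tag(mature: MatureRecord, precursors: dict[str, str], suffix: str) -> str:
    """Apply a matching-annotation suffix to the reference, yielding the tag.

    Inverse of :func:`name_mirna` for annotated-arm matches: extensions copy
    precursor context, trims remove reference bases, and ``ss`` entries
    substitute at 1-based detected positions.
    """
    left_delta, right_delta, subs = parse_suffix(suffix)
    prec = precursors[mature.precursor]
    start = mature.start - left_delta
    end = mature.end + right_delta
    if start < 0 or end > len(prec) or start >= end:
        raise ValueError(f"suffix {suffix!r} leaves the precursor bounds")
    seq = list(prec[start:end])
    for pos, ref, obs in subs:
        if not 1 <= pos <= len(seq):
            raise ValueError(f"substitution position {pos} outside detected sequence")
        if seq[pos - 1] != ref:
            raise ValueError(
                f"suffix {suffix!r}: reference base at {pos} is {seq[pos - 1]}, not {ref}"
            )
        seq[pos - 1] = obs
    return "".join(seq)


# ---------------------------------------------------------------------------
# Classification

@dataclass
class Annotator:
    """Classifies unique tags into the group taxonomy.

    Groups: 1a known specific-species miRNAs (incl. opposite-arm p5/p3
    candidates), 1b selected-species miRNAs whose precursor maps to the
    genome, 2a/2b selected-species matures with the tag on the genome
    (with/without a hairpin), 3a/3b selected matures without a genome hit,
    4a genome-mapped novel hairpin candidates, others = contaminants,
    nohit = everything else.
    """

    bundle: ReferenceBundle
    end_tolerance: int = DEFAULT_END_TOLERANCE
    flank: int = DEFAULT_FLANK
    max_genome_loci: int = DEFAULT_MAX_GENOME_LOCI
    min_paired_fraction: float = 0.6
    min_stem_positions: int = 18

    def __post_init__(self):
        self._selected_in_genome = {
            name
            for name, seq in self.bundle.selected_precursors.items()
            if map_to_genome(seq, self.bundle.genome, max_loci=1)
        }
        self._pc_serial = 0
        self._pc_names: dict[str, str] = {}

    # -- helpers -----------------------------------------------------------

    def _hairpin_at(self, hit: GenomeHit) -> HairpinCall:
        contig = self.bundle.genome[hit.contig]
        win_start = max(0, hit.start - self.flank)
        win_end = min(len(contig), hit.end + self.flank)
        window = contig[win_start:win_end]
        cand_start = hit.start - win_start
        cand_end = hit.end - win_start
        if hit.strand == "-":
            window = revcomp(window)
            cand_start, cand_end = len(window) - cand_end, len(window) - cand_start
        return call_hairpin(
            window, cand_start, cand_end,
            min_paired_fraction=self.min_paired_fraction,
            min_stem_positions=self.min_stem_positions,
        )

    def _novel_name(self, tag: str, arm: str, total_count: int) -> str:
        if tag not in self._pc_names:
            self._pc_serial += 1
            arm_label = {"5p": "5p", "3p": "3p"}.get(arm, "5p")
            self._pc_names[tag] = f"PC-{arm_label}-{self._pc_serial}_{total_count}"
        return self._pc_names[tag]

    # -- main entry --------------------------------------------------------

    def classify(self, tag: str, fate: str = "retained", total_count: int = 0) -> AnnotationRecord:
        """Assign *tag* its group and name (first matching rule wins)."""
        if fate != "retained":
            return AnnotationRecord(tag, "others", fate)

        mappable = MIN_MAP_LENGTH <= len(tag) <= MAX_MAP_LENGTH
        bundle = self.bundle

        if mappable:
            specific = match_tag(tag, bundle.specific_matures,
                                 bundle.specific_precursors, self.end_tolerance)
            if specific is not None:
                name = name_mirna(specific.reference, specific)
                return AnnotationRecord(tag, "1a", name, match=specific)

            opp = match_opposite_arm(tag, bundle.specific_matures,
                                     bundle.specific_precursors, self.end_tolerance)
            if opp is not None:
                name = name_mirna(opp.precursor, opposite_arm=opp.candidate_arm)
                return AnnotationRecord(tag, "1a", name, opposite=opp)

            selected = match_tag(tag, bundle.selected_matures,
                                 bundle.selected_precursors, self.end_tolerance)
            if selected is not None:
                rec = bundle.selected_matures[selected.reference]
                name = name_mirna(selected.reference, selected)
                if rec.precursor in self._selected_in_genome:
                    return AnnotationRecord(tag, "1b", name, match=selected)
                hits = map_to_genome(tag, bundle.genome, self.max_genome_loci)
                if hits and len(hits) <= self.max_genome_loci:
                    for hit in hits:
                        call = self._hairpin_at(hit)
                        if call.is_hairpin:
                            return AnnotationRecord(tag, "2a", name, match=selected,
                                                    hairpin=call, loci=hits)
                    return AnnotationRecord(tag, "2b", name, match=selected,
                                            loci=hits, hairpin=call)
                # no genome hit: 3a if a specific-mature match also exists
                group = "3a" if specific is not None else "3b"
                return AnnotationRecord(tag, group, name, match=selected)

        hits = map_to_genome(tag, bundle.genome, self.max_genome_loci)
        if hits and len(hits) <= self.max_genome_loci:
            for hit in hits:
                call = self._hairpin_at(hit)
                if call.is_hairpin:
                    name = self._novel_name(tag, call.arm, total_count)
                    return AnnotationRecord(tag, "4a", name, hairpin=call, loci=hits)
        return AnnotationRecord(tag, "nohit", "")
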