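"""Tolerant matching against annotated matures, with an exhaustive oracle."""

import numpy as np
import pytest

from mirpipe.annotate import match_opposite_arm, match_tag
from mirpipe.io import MatureRecord, revcomp


def _refs():
    """Two hand-built precursors with annotated matures."""
    m1 = "TGACCGTTAGCATCAGGTACC"        # 21 nt, G at detected position 8
    m2 = "CAGGTTCAAGTCGATCCAGTT"
    prec1 = "GGATC" + m1 + "CTAG" + "AGTTTCAA" + revcomp("GGATC" + m1 + "CTAG")
    prec2 = "TCCAA" + m2 + "GTCA" + "TCCGGATA" + revcomp("TCCAA" + m2 + "GTCA")
    precursors = {"MIR-A": prec1, "MIR-B": prec2}
    matures = {
        "miR-A-5p": MatureRecord("miR-A-5p", "MIR-A", 5, 26, "5p"),
        "miR-B-5p": MatureRecord("miR-B-5p", "MIR-B", 5, 26, "5p"),
    }
    return matures, precursors


MATURES, PRECURSORS = _refs()
M1 = PRECURSORS["MIR-A"][5:26]


class TestMatchTag:
    def test_exact_match_costs_nothing(self):
        match = match_tag(M1, MATURES, PRECURSORS)
        assert match is not None
        assert (match.left_delta, match.right_delta) == (0, 0)
        assert match.substitutions == []
        assert match.cost == 0
        assert match.reference == "miR-A-5p"

    def test_internal_substitution_reported_1based(self):
        assert M1[7] == "T"
        tag = M1[:7] + "G" + M1[8:]
        match = match_tag(tag, MATURES, PRECURSORS)
        assert match.substitutions == [(8, "T", "G")]
        assert match.cost == 2

    def test_end_variation_with_context_extension(self):
        # two fewer bases on the left, two precursor-context bases on the right
        prec = PRECURSORS["MIR-A"]
        tag = prec[7:28]
        match = match_tag(tag, MATURES, PRECURSORS)
        assert (match.left_delta, match.right_delta) == (-2, 2)
        assert match.cost == 4

    def test_substitution_at_first_or_last_base_disallowed(self):
        other = "G" if M1[0] != "G" else "C"
        tag = other + M1[1:]
        match = match_tag(tag, MATURES, PRECURSORS)
        # cannot be explained as a substitution at base 1; the only
        # remaining explanations are end shifts, which change context
        assert match is None or match.substitutions == [] or match.substitutions[0][0] != 1

    def test_out_of_range_tag_rejected(self):
        with pytest.raises(ValueError):
            match_tag("ACGTACGTACGTACGTA", MATURES, PRECURSORS)  # 17 nt
        with pytest.raises(ValueError):
            match_tag("ACGTACGTACGTACGTACGTACGTAC", MATURES, PRECURSORS)  # 26 nt


def _oracle_match(tag, matures, precursors, tol=4):
    """Exhaustive enumeration of all (left_delta, right_delta, substitution)
    explanations; independent of the implementation's search order."""
    candidates = []
    for name, rec in matures.items():
        prec = precursors[rec.precursor]
        for ld in range(-tol, tol + 1):
            for rd in range(-tol, tol + 1):
                start, end = rec.start - ld, rec.end + rd
                if start < 0 or end > len(prec) or start >= end:
                    continue
                variant = prec[start:end]
                if len(variant) != len(tag):
                    continue
                diffs = [
                    (i + 1, a, b) for i, (a, b) in enumerate(zip(variant, tag)) if a != b
                ]
                if len(diffs) > 1:
                    continue
                if diffs and diffs[0][0] in (1, len(tag)):
                    continue
                candidates.append((abs(ld) + abs(rd) + 2 * len(diffs), name, ld, rd, diffs))
    if not candidates:
        return None
    # cost, then reference name, then the declared end-shift tie-break
    return min(candidates, key=lambda c: (c[0], c[1], abs(c[2]), c[2]))


class TestOracleEquivalence:
    def test_matches_exhaustive_enumeration(self):
        """Random isomiRs and perturbations agree with brute-force search."""
        rng = np.random.default_rng(42)
        tags = []
        prec = PRECURSORS["MIR-A"]
        for _ in range(300):
            ld, rd = rng.integers(-3, 4, size=2)
            start, end = 5 - ld, 26 + rd
            if not (0 <= start < end <= len(prec)) or not 18 <= end - start <= 25:
                continue
            tag = list(prec[start:end])
            if rng.random() < 0.5:
                pos = int(rng.integers(1, len(tag) - 1))
                tag[pos] = "ACGT"[int(rng.integers(0, 4))]
            tags.append("".join(tag))
        assert len(tags) > 100
        for tag in tags:
            got = match_tag(tag, MATURES, PRECURSORS)
            expected = _oracle_match(tag, MATURES, PRECURSORS)
            if expected is None:
                assert got is None
            else:
                cost, name, ld, rd, subs = expected
                assert got.cost == cost
                assert got.reference == name
                assert (got.left_delta, got.right_delta, got.substitutions) == (ld, rd, subs)

    def test_reconstruction_invariant(self):
        """Applying deltas and substitutions to the reference rebuilds the tag."""
        rng = np.random.default_rng(7)
        prec = PRECURSORS["MIR-B"]
        for _ in range(100):
            ld, rd = (int(x) for x in rng.integers(-2, 3, size=2))
            start, end = 5 - ld, 26 + rd
            if not 18 <= end - start <= 25:
                continue
            tag = prec[start:end]
            match = match_tag(tag, MATURES, PRECURSORS)
            rec = MATURES[match.reference]
            p = PRECURSORS[rec.precursor]
            rebuilt = list(p[rec.start - match.left_delta : rec.end + match.right_delta])
            for pos, _ref, obs in match.substitutions:
                rebuilt[pos - 1] = obs
            assert "".join(rebuilt) == tag


class TestOppositeArm:
    def test_tag_on_other_arm_found(self):
        prec = PRECURSORS["MIR-A"]
        # the 3' arm is the reverse complement of the 5' arm (positions 38-68)
        tag = prec[40:61]
        opp = match_opposite_arm(tag, MATURES, PRECURSORS)
        assert opp is not None
        assert opp.precursor == "MIR-A"
        assert opp.candidate_arm == "p3"

    def test_annotated_arm_region_excluded(self):
        assert match_opposite_arm(M1, MATURES, PRECURSORS) is None
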