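"""Readers and writers for the formats the pipeline touches.

All sequences are stored internally as uppercase DNA over {A,C,G,T,N}:
U is normalized to T on input so genome contigs, reads and miRNA references
share one alphabet. Genomic intervals are 0-based half-open internally;
GFF3 (1-based, inclusive) is converted at this boundary.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pandas as pd
from Bio import SeqIO

VALID_BASES = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class ParseError(ValueError):
    """Malformed input file."""


class ValidationError(ValueError):
    """Structurally valid input that violates a pipeline contract."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(raw: str, *, path: str = "<str>", line: int = 0) -> str:
    """Uppercase, U→T; reject characters outside {A,C,G,T,N}."""
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - VALID_BASES
    if bad:
        raise ParseError(
            f"{path}:{line}: illegal sequence character(s) {sorted(bad)}"
        )
    return seq


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: sequence} mapping.

    Sequences are normalized (uppercase, U→T); malformed records raise
    :class:`ParseError` naming the offending line.
    """
    records: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    start_line = 0
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    if not chunks:
                        raise ParseError(f"{path}:{start_line}: record '{name}' has no sequence")
                    records[name] = "".join(chunks)
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
                if name in records:
                    raise ParseError(f"{path}:{lineno}: duplicate record '{name}'")
                chunks = []
                start_line = lineno
            else:
                if name is None:
                    raise ParseError(f"{path}:{lineno}: sequence before first header")
                chunks.append(normalize_sequence(line, path=str(path), line=lineno))
        if name is not None:
            if not chunks:
                raise ParseError(f"{path}:{start_line}: record '{name}' has no sequence")
            records[name] = "".join(chunks)
    return records


def write_fasta(records: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ

@dataclass
class FastqRead:
    name: str
    sequence: str
    quality: str


def read_fastq(path) -> Iterator[FastqRead]:
    """Iterate reads from a (possibly gzipped) Sanger FASTQ file.

    Mismatched sequence/quality lengths raise :class:`ParseError`; an empty
    file yields nothing. Sequences are normalized to the internal alphabet.
    """
    with _open_text(path) as fh:
        try:
            for rec in SeqIO.parse(fh, "fastq"):
                seq = normalize_sequence(str(rec.seq), path=str(path))
                qual = "".join(
                    chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                )
                yield FastqRead(rec.id, seq, qual)
        except ValueError as exc:  # Biopython signals malformed records this way
            raise ParseError(f"{path}: {exc}") from exc


def write_fastq(reads, path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.name}\n{read.sequence}\n+\n{read.quality}\n")


# ---------------------------------------------------------------------------
# GFF3 precursor loci

@dataclass(frozen=True)
class Locus:
    """0-based half-open genomic interval on a stranded contig."""

    contig: str
    strand: str  # "+" or "-"
    start: int   # 0-based inclusive
    end: int     # 0-based exclusive

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValidationError(f"bad strand {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValidationError(f"bad interval [{self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


def gff3_to_internal(start_1based: int, end_1based: int) -> tuple[int, int]:
    """GFF3 1-based inclusive coordinates → 0-based half-open."""
    return start_1based - 1, end_1based


def internal_to_gff3(start: int, end: int) -> tuple[int, int]:
    """0-based half-open coordinates → GFF3 1-based inclusive."""
    return start + 1, end


def read_gff3(path, genome: dict[str, str] | None = None) -> dict[str, Locus]:
    """Read precursor loci from GFF3 into {feature_id: Locus}.

    If *genome* is given, loci are validated against contig bounds.
    """
    loci: dict[str, Locus] = {}
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            contig, _src, _type, start, end, _score, strand, _phase, attrs = cols
            try:
                s1, e1 = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            feature_id = None
            for item in attrs.split(";"):
                if item.startswith("ID="):
                    feature_id = item[3:]
            if feature_id is None:
                raise ParseError(f"{path}:{lineno}: missing ID attribute")
            s0, e0 = gff3_to_internal(s1, e1)
            if genome is not None:
                if contig not in genome:
                    raise ValidationError(f"{path}:{lineno}: unknown contig {contig!r}")
                if not (0 <= s0 < e0 <= len(genome[contig])):
                    raise ValidationError(
                        f"{path}:{lineno}: interval [{s1},{e1}] outside contig "
                        f"{contig} (length {len(genome[contig])})"
                    )
            loci[feature_id] = Locus(contig, strand, s0, e0)
    return loci


def write_gff3(loci: dict[str, Locus], path, feature_type: str = "miRNA_primary_transcript") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, locus in loci.items():
            s1, e1 = internal_to_gff3(locus.start, locus.end)
            fh.write(
                f"{locus.contig}\tmirpipe\t{feature_type}\t{s1}\t{e1}\t.\t"
                f"{locus.strand}\t.\tID={name}\n"
            )


# ---------------------------------------------------------------------------
# Tables

def read_tsv_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


# ---------------------------------------------------------------------------
# Reference bundle

@dataclass
class MatureRecord:
    """A mature miRNA annotated on its precursor.

    The interval [start, end) is on the precursor sequence (0-based half-open);
    ``arm`` is "5p" or "3p".
    """

    name: str
    precursor: str
    start: int
    end: int
    arm: str


@dataclass
class NamedMotif:
    """A named cis-regulatory element consensus (IUPAC alphabet)."""

    name: str
    consensus: str
    both_strands: bool = True

    def __post_init__(self):
        if not self.consensus:
            raise ValidationError(f"motif {self.name}: empty consensus")
        bad = set(self.consensus.upper()) - set(IUPAC_CODES)
        if bad:
            raise ValidationError(f"motif {self.name}: non-IUPAC characters {sorted(bad)}")
        self.consensus = self.consensus.upper().replace("U", "T")


CONTAMINANT_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA", "repeat", "mRNA")


@dataclass
class ReferenceBundle:
    """Every reference substrate a pipeline run needs.

    specific_* refer to the species under study; selected_* to a related
    species whose miRBase-style entries extend the search space (for potato,
    typically a fellow Solanaceae member such as tomato).
    """

    specific_precursors: dict[str, str] = field(default_factory=dict)
    specific_matures: dict[str, MatureRecord] = field(default_factory=dict)
    selected_precursors: dict[str, str] = field(default_factory=dict)
    selected_matures: dict[str, MatureRecord] = field(default_factory=dict)
    genome: dict[str, str] = field(default_factory=dict)
    precursor_loci: dict[str, Locus] = field(default_factory=dict)
    contaminants: dict[str, dict[str, str]] = field(default_factory=dict)
    transcriptome: dict[str, str] = field(default_factory=dict)
    go_annotation: dict[str, set[str]] = field(default_factory=dict)
    go_categories: dict[str, str] = field(default_factory=dict)
    motif_table: list[NamedMotif] = field(default_factory=list)

    def validate(self) -> None:
        for rec in list(self.specific_matures.values()) + list(self.selected_matures.values()):
            pool = (
                self.specific_precursors
                if rec.precursor in self.specific_precursors
                else self.selected_precursors
            )
            prec = pool.get(rec.precursor)
            if prec is None:
                raise ValidationError(f"mature {rec.name}: unknown precursor {rec.precursor}")
            if not (0 <= rec.start < rec.end <= len(prec)):
                raise ValidationError(f"mature {rec.name}: interval outside precursor")
        for name, locus in self.precursor_loci.items():
            contig = self.genome.get(locus.contig)
            if contig is None or locus.end > len(contig):
                raise ValidationError(f"locus {name}: outside genome")

    # -- persistence -------------------------------------------------------

    def write(self, directory) -> None:
        """Write the bundle as plain-text files under *directory*."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_fasta(self.specific_precursors, directory / "specific_precursors.fa")
        write_fasta(self.selected_precursors, directory / "selected_precursors.fa")
        write_fasta(self.genome, directory / "genome.fa")
        write_fasta(self.transcriptome, directory / "transcriptome.fa")
        write_gff3(self.precursor_loci, directory / "precursor_loci.gff3")
        for which, matures in (("specific", self.specific_matures), ("selected", self.selected_matures)):
            rows = [
                {"name": m.name, "precursor": m.precursor, "start": m.start,
                 "end": m.end, "arm": m.arm}
                for m in matures.values()
            ]
            pd.DataFrame(rows).to_csv(directory / f"{which}_matures.tsv", sep="\t", index=False)
        for cls, seqs in self.contaminants.items():
            write_fasta(seqs, directory / f"contaminant_{cls}.fa")
        rows = [
            {"gene": g, "term": t, "category": self.go_categories.get(t, "BP")}
            for g, terms in self.go_annotation.items()
            for t in sorted(terms)
        ]
        pd.DataFrame(rows, columns=["gene", "term", "category"]).to_csv(
            directory / "go_annotation.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            [{"name": m.name, "consensus": m.consensus, "both_strands": m.both_strands}
             for m in self.motif_table]
        ).to_csv(directory / "motifs.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, directory) -> "ReferenceBundle":
        directory = Path(directory)
        bundle = cls(
            specific_precursors=read_fasta(directory / "specific_precursors.fa"),
            selected_precursors=read_fasta(directory / "selected_precursors.fa"),
            genome=read_fasta(directory / "genome.fa"),
            transcriptome=read_fasta(directory / "transcriptome.fa"),
        )
        bundle.precursor_loci = read_gff3(directory / "precursor_loci.gff3", bundle.genome)
        for which in ("specific", "selected"):
            table = pd.read_csv(directory / f"{which}_matures.tsv", sep="\t")
            matures = {
                row["name"]: MatureRecord(
                    row["name"], row["precursor"], int(row["start"]), int(row["end"]), row["arm"]
                )
                for _, row in table.iterrows()
            }
            setattr(bundle, f"{which}_matures", matures)
        for cls_name in CONTAMINANT_CLASSES:
            path = directory / f"contaminant_{cls_name}.fa"
            if path.exists():
                bundle.contaminants[cls_name] = read_fasta(path)
        go_path = directory / "go_annotation.tsv"
        if go_path.exists():
            table = pd.read_csv(go_path, sep="\t")
            for _, row in table.iterrows():
                bundle.go_annotation.setdefault(row["gene"], set()).add(row["term"])
                bundle.go_categories[row["term"]] = row["category"]
        motif_path = directory / "motifs.tsv"
        if motif_path.exists():
            table = pd.read_csv(motif_path, sep="\t")
            bundle.motif_table = [
                NamedMotif(row["name"], row["consensus"], bool(row["both_strands"]))
                for _, row in table.iterrows()
            ]
        bundle.validate()
        return bundle
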