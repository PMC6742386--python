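"""Synthetic study generator: reference bundles and small-RNA libraries
with known planted truth.

The generator emulates the study design the pipeline is built for: six
libraries (three control, three treated), planted known miRNAs of the
specific species, selected-species miRNAs (a configurable subset locatable
in the genome), novel hairpin loci, end-variant and single-substitution
isomiRs, 3' adapters, contaminant reads (rRNA/tRNA/snRNA/snoRNA/repeats/
mRNA plus junk, dimers and adapter-less reads) and planted fold changes
between conditions. Insert lengths concentrate at 21 nt within 15-32 nt.

Every read carries a truth label, so each downstream stage has a
ground-truth acceptance surface. A fixed seed yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    Locus,
    MatureRecord,
    NamedMotif,
    ReferenceBundle,
    ValidationError,
    revcomp,
)
from .preprocess import is_junk

# TruSeq small RNA 3' adapter
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

MATURE_LENGTH = 21
ARM_LENGTH = 30
LOOP_LENGTH = 8
MATURE_OFFSET = 5          # 5' context inside the arm (>= end tolerance headroom)

# insert-length profile for non-miRNA small RNA reads: 15..32 peaked at 21
_LENGTHS = np.arange(15, 33)
_LENGTH_WEIGHTS = 1.0 / (1.0 + np.abs(_LENGTHS - 21.0))
_LENGTH_WEIGHTS /= _LENGTH_WEIGHTS.sum()

# contaminant-compartment composition (sums to 1)
CONTAMINANT_WEIGHTS = {
    "rRNA": 0.25, "tRNA": 0.15, "snRNA": 0.08, "snoRNA": 0.07,
    "repeat": 0.15, "mRNA": 0.15, "junk": 0.15,
}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; defaults are the study conditions."""

    seed: int = 0
    n_libraries_per_condition: int = 3
    n_known_specific: int = 5
    n_known_selected: int = 4
    n_novel: int = 6
    contaminant_fraction: float = 0.2
    isomir_end_sd: float = 0.3           # mean |end shift| per end, support {-2..2}
    substitution_rate: float = 0.02      # per-read single internal substitution
    planted_fold_changes: dict[str, float] = field(default_factory=dict)
    library_depth: int = 100_000
    adapter: str = DEFAULT_ADAPTER
    read_length: int = 50
    genome_size: int = 50_000
    n_contigs: int = 4
    selected_in_genome_fraction: float = 0.5
    biological_cv: float = 0.25          # ln-scale replicate noise sigma (~25% CV)

    def validate(self) -> None:
        if not 0 <= self.contaminant_fraction < 1:
            raise ValidationError("contaminant_fraction must be in [0, 1)")
        if self.library_depth <= 0:
            raise ValidationError("library_depth must be positive")
        if any(fc <= 0 for fc in self.planted_fold_changes.values()):
            raise ValidationError("fold changes must be > 0")
        if not 0 <= self.isomir_end_sd < 2:
            raise ValidationError("isomir_end_sd must be in [0, 2)")
        if not 0 <= self.substitution_rate <= 1:
            raise ValidationError("substitution_rate must be in [0, 1]")
        if len(self.adapter) < 6:
            raise ValidationError("adapter must be at least 6 nt")

    @property
    def library_names(self) -> list[str]:
        n = self.n_libraries_per_condition
        return [f"C{i + 1}" for i in range(n)] + [f"T{i + 1}" for i in range(n)]

    @property
    def conditions(self) -> dict[str, str]:
        return {
            lib: ("control" if lib.startswith("C") else "treated")
            for lib in self.library_names
        }


@dataclass
class PlantedMirna:
    name: str                 # mature/truth name
    precursor_name: str
    kind: str                 # "specific" | "selected" | "novel"
    sequence: str             # mature (DNA alphabet)
    arm: str                  # "5p" | "3p"
    precursor_seq: str
    mature_start: int         # on the precursor
    mature_end: int
    in_genome: bool
    fold_change: float = 1.0
    base_weight: float = 1.0


@dataclass
class TruthTable:
    """Ground truth of one simulation."""

    mirnas: pd.DataFrame                       # per planted miRNA
    read_origins: dict[str, list[str]]         # library -> one label per read
    expected_proportions: pd.DataFrame         # miRNA x {control, treated}

    def origin_counts(self) -> pd.DataFrame:
        data = {
            lib: pd.Series(origins).value_counts()
            for lib, origins in self.read_origins.items()
        }
        return pd.DataFrame(data).fillna(0).astype(int)


# ---------------------------------------------------------------------------
# sequence helpers

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def _random_mature(rng: np.random.Generator, taken: set[str]) -> str:
    while True:
        seq = _random_seq(rng, MATURE_LENGTH)
        if seq not in taken and not is_junk(seq):
            return seq


def _build_precursor(rng: np.random.Generator, mature: str, arm: str) -> tuple[str, int, int]:
    """Stem-loop precursor = arm + loop + revcomp(arm), mature inside one arm."""
    pad_r = ARM_LENGTH - MATURE_OFFSET - MATURE_LENGTH
    arm5 = _random_seq(rng, MATURE_OFFSET) + mature + _random_seq(rng, pad_r)
    if arm == "3p":
        # put the mature on the 3' side: the 3p arm is revcomp(arm5), so seed
        # the 5' arm with revcomp(mature) instead
        arm5 = _random_seq(rng, MATURE_OFFSET) + revcomp(mature) + _random_seq(rng, pad_r)
    loop = _random_seq(rng, LOOP_LENGTH)
    prec = arm5 + loop + revcomp(arm5)
    if arm == "5p":
        start = MATURE_OFFSET
    else:
        # revcomp(arm5) = revcomp(pad_r part) + mature + revcomp(offset part)
        start = ARM_LENGTH + LOOP_LENGTH + pad_r
    end = start + MATURE_LENGTH
    assert prec[start:end] == mature
    return prec, start, end


def _default_fold_changes(mirnas: list[PlantedMirna]) -> dict[str, float]:
    """Study-like mixture: up- and down-regulation among known and novel."""
    fc: dict[str, float] = {}
    specific = [m for m in mirnas if m.kind == "specific"]
    novel = [m for m in mirnas if m.kind == "novel"]
    if len(specific) >= 1:
        fc[specific[0].name] = 4.0
    if len(specific) >= 2:
        fc[specific[1].name] = 0.25
    if len(novel) >= 1:
        fc[novel[0].name] = 4.0
    if len(novel) >= 2:
        fc[novel[1].name] = 0.25
    return fc


# ---------------------------------------------------------------------------
# reference bundle

def generate_reference_bundle(config: SimulationConfig) -> tuple[ReferenceBundle, list[PlantedMirna]]:
    """Build references, genome and annexes with planted, recorded truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    taken: set[str] = set()
    planted: list[PlantedMirna] = []

    def plant(kind: str, index: int, in_genome: bool) -> PlantedMirna:
        arm = "5p" if index % 2 == 0 else "3p"
        mature = _random_mature(rng, taken)
        taken.add(mature)
        prec, start, end = _build_precursor(rng, mature, arm)
        if kind == "specific":
            base = f"stu-miR{101 + index}"
            prec_name = f"stu-MIR{101 + index}"
        elif kind == "selected":
            base = f"sly-miR{201 + index}"
            prec_name = f"sly-MIR{201 + index}"
        else:
            base = f"novel-miR-{index + 1}"
            prec_name = f"novel-MIR-{index + 1}"
        m = PlantedMirna(
            name=f"{base}-{arm}", precursor_name=prec_name, kind=kind,
            sequence=mature, arm=arm, precursor_seq=prec,
            mature_start=start, mature_end=end, in_genome=in_genome,
        )
        planted.append(m)
        return m

    for i in range(config.n_known_specific):
        plant("specific", i, in_genome=True)
    n_sel_genome = int(np.ceil(config.n_known_selected * config.selected_in_genome_fraction))
    for i in range(config.n_known_selected):
        plant("selected", i, in_genome=i < n_sel_genome)
    for i in range(config.n_novel):
        plant("novel", i, in_genome=True)

    # fold changes
    fold_changes = dict(config.planted_fold_changes) or _default_fold_changes(planted)
    known_names = {m.name for m in planted}
    unknown = set(fold_changes) - known_names
    if unknown:
        raise ValidationError(f"fold changes planted for unknown miRNAs: {sorted(unknown)}")
    for m in planted:
        m.fold_change = fold_changes.get(m.name, 1.0)
        m.base_weight = float(rng.lognormal(0.0, 0.8))

    # genome: embed each in-genome precursor in random contigs, both strands
    to_place = [m for m in planted if m.in_genome]
    contig_len = config.genome_size // config.n_contigs
    margin = 160  # leaves full fold flanks inside the contig
    slot = len(max((m.precursor_seq for m in to_place), key=len, default="")) + 2 * margin
    per_contig = max(1, (contig_len - margin) // slot) if to_place else 1
    if to_place and per_contig * config.n_contigs < len(to_place):
        raise ValidationError(
            f"genome of {config.genome_size} nt cannot hold {len(to_place)} precursor loci"
        )
    contigs = {
        f"contig{i + 1}": list(_random_seq(rng, contig_len))
        for i in range(config.n_contigs)
    }
    loci: dict[str, Locus] = {}
    for idx, m in enumerate(to_place):
        contig_name = f"contig{(idx % config.n_contigs) + 1}"
        slot_idx = idx // config.n_contigs
        start = margin + slot_idx * slot + int(rng.integers(0, margin // 2))
        seq = m.precursor_seq
        strand = "+" if idx % 2 == 0 else "-"
        inserted = seq if strand == "+" else revcomp(seq)
        contigs[contig_name][start : start + len(inserted)] = list(inserted)
        loci[m.precursor_name] = Locus(contig_name, strand, start, start + len(inserted))
    genome = {name: "".join(chars) for name, chars in contigs.items()}

    # contaminants, regenerated until disjoint from every planted mature
    matures = [m.sequence for m in planted]

    def clean_contaminant(length: int) -> str:
        while True:
            seq = _random_seq(rng, length)
            if not any(mat in seq for mat in matures):
                return seq

    contaminants = {
        "rRNA": {f"rRNA-{i + 1}": clean_contaminant(600) for i in range(2)},
        "tRNA": {f"tRNA-{i + 1}": clean_contaminant(80) for i in range(3)},
        "snRNA": {f"snRNA-{i + 1}": clean_contaminant(150) for i in range(2)},
        "snoRNA": {f"snoRNA-{i + 1}": clean_contaminant(120) for i in range(2)},
        "repeat": {f"repeat-{i + 1}": clean_contaminant(400) for i in range(2)},
        "mRNA": {f"mRNA-{i + 1}": clean_contaminant(800) for i in range(3)},
    }

    # transcriptome with planted target sites for the fold-changed miRNAs
    transcriptome: dict[str, str] = {
        f"TX{i + 1:03d}": clean_contaminant(int(rng.integers(500, 1500)))
        for i in range(20)
    }
    regulated = [m for m in planted if m.fold_change != 1.0]
    target_genes: list[str] = []
    for i, m in enumerate(regulated):
        tx = f"TX{i + 1:03d}"
        seq = list(transcriptome[tx])
        site = list(revcomp(m.sequence))
        n_mut = i % 2  # alternate perfect and one-mismatch sites
        for _ in range(n_mut):
            pos = int(rng.integers(14, 18))  # outside seed, off the slicing site
            site[pos] = "ACGT"[(("ACGT".index(site[pos])) + 1) % 4]
        pos = int(rng.integers(100, len(seq) - len(site) - 100))
        seq[pos : pos + len(site)] = site
        transcriptome[tx] = "".join(seq)
        target_genes.append(tx)

    # GO annotation: a defense-response term enriched among target genes
    go_annotation: dict[str, set[str]] = {}
    go_categories = {
        "GO:0006952": "BP",  # defense response
        "GO:0006355": "BP",  # regulation of transcription
        "GO:0003700": "MF",  # DNA-binding transcription factor activity
        "GO:0016301": "MF",  # kinase activity
        "GO:0005634": "CC",  # nucleus
        "GO:0005886": "CC",  # plasma membrane
    }
    terms = sorted(go_categories)
    for gene in sorted(transcriptome):
        annots = {terms[int(rng.integers(0, len(terms)))]}
        if gene in target_genes:
            annots.add("GO:0006952")
        elif rng.random() < 0.1:
            annots.add("GO:0006952")
        go_annotation[gene] = annots

    bundle = ReferenceBundle(
        specific_precursors={
            m.precursor_name: m.precursor_seq for m in planted if m.kind == "specific"
        },
        specific_matures={
            m.name: MatureRecord(m.name, m.precursor_name, m.mature_start, m.mature_end, m.arm)
            for m in planted if m.kind == "specific"
        },
        selected_precursors={
            m.precursor_name: m.precursor_seq for m in planted if m.kind == "selected"
        },
        selected_matures={
            m.name: MatureRecord(m.name, m.precursor_name, m.mature_start, m.mature_end, m.arm)
            for m in planted if m.kind == "selected"
        },
        genome=genome,
        precursor_loci=loci,
        contaminants=contaminants,
        transcriptome=transcriptome,
        go_annotation=go_annotation,
        go_categories=go_categories,
        motif_table=[
            NamedMotif("TGACG-motif", "TGACG"),
            NamedMotif("G-box", "CACGTG"),
            NamedMotif("W-box", "TTGACY"),
        ],
    )
    bundle.validate()
    return bundle, planted


# ---------------------------------------------------------------------------
# read-level simulation

def _end_shift_probs(mean_abs: float) -> np.ndarray:
    """Symmetric distribution on {-2,-1,0,1,2} with E|shift| = mean_abs.

    Mass at |shift|=2 is half the mass at |shift|=1, so
    E|shift| = 2 p1 + 4 p2 = 4 p1 with p2 = p1 / 2.
    """
    p1 = mean_abs / 4.0
    p2 = p1 / 2.0
    p0 = 1.0 - 2 * (p1 + p2)
    return np.array([p2, p1, p0, p1, p2])


def expected_proportions(config: SimulationConfig, planted: list[PlantedMirna]) -> pd.DataFrame:
    """Exact per-condition read proportions implied by the planted model."""
    w = np.array([m.base_weight for m in planted])
    fc = np.array([m.fold_change for m in planted])
    cf = config.contaminant_fraction
    u_cont = cf / (1 - cf) * w.sum() if cf > 0 else 0.0
    out = {}
    for cond, weights in (("control", w), ("treated", w * fc)):
        total = weights.sum() + u_cont
        out[cond] = weights / total
    return pd.DataFrame(out, index=[m.name for m in planted])


def simulate_libraries(
    bundle: ReferenceBundle,
    planted: list[PlantedMirna],
    config: SimulationConfig,
) -> tuple[dict[str, list[str]], TruthTable]:
    """Draw the six raw-read libraries and their truth table.

    Returns ({library: [raw read strings]}, truth). Reads are insert +
    adapter, padded/truncated to the configured read length.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)  # distinct stream from the bundle
    props = expected_proportions(config, planted)
    shift_probs = _end_shift_probs(config.isomir_end_sd)
    shifts = np.array([-2, -1, 0, 1, 2])

    cont_classes = list(CONTAMINANT_WEIGHTS)
    cont_w = np.array([CONTAMINANT_WEIGHTS[c] for c in cont_classes])
    cont_seqs = {
        cls: list(bundle.contaminants.get(cls, {}).values()) for cls in cont_classes
    }

    def make_read(insert: str) -> str:
        read = insert + config.adapter
        if len(read) < config.read_length:
            read += "A" * (config.read_length - len(read))
        return read[: config.read_length]

    def mirna_read(m: PlantedMirna) -> str:
        prec = m.precursor_seq
        ld, rd = rng.choice(shifts, size=2, p=shift_probs)
        start = m.mature_start - ld
        end = m.mature_end + rd
        if start < 0 or end > len(prec) or end - start < 15:
            start, end = m.mature_start, m.mature_end
        insert = list(prec[start:end])
        if rng.random() < config.substitution_rate and len(insert) > 2:
            pos = int(rng.integers(1, len(insert) - 1))  # internal only
            insert[pos] = "ACGT"[("ACGT".index(insert[pos]) + rng.integers(1, 4)) % 4]
        return make_read("".join(insert))

    def contaminant_read(cls: str) -> str:
        if cls == "junk":
            kind = rng.integers(0, 4)
            if kind == 0:   # adapter dimer
                return make_read("")
            if kind == 1:   # no 3' adapter: insert fills the read
                return _random_seq(rng, config.read_length)
            if kind == 2:   # low complexity
                unit = ["A", "AC", "AG", "AT"][int(rng.integers(0, 4))]
                return make_read((unit * 20)[: int(rng.integers(16, 28))])
            length = int(rng.integers(8, 15)) if rng.random() < 0.5 else int(rng.integers(33, 41))
            return make_read(_random_seq(rng, length))
        seqs = cont_seqs[cls]
        seq = seqs[int(rng.integers(0, len(seqs)))]
        length = int(rng.choice(_LENGTHS, p=_LENGTH_WEIGHTS))
        length = min(length, len(seq))
        start = int(rng.integers(0, len(seq) - length + 1))
        return make_read(seq[start : start + length])

    libraries: dict[str, list[str]] = {}
    read_origins: dict[str, list[str]] = {}
    names = [m.name for m in planted]
    by_name = {m.name: m for m in planted}

    for lib in config.library_names:
        cond = config.conditions[lib]
        base = props[cond].to_numpy().copy()
        # replicate-level biological noise on the miRNA compartment; the
        # contaminant share is whatever the planted model leaves over
        noise = rng.lognormal(0.0, config.biological_cv, size=base.size)
        mirna_p = base * noise
        cont_total = 1.0 - base.sum()
        full_p = np.concatenate([mirna_p, cont_total * cont_w])
        full_labels = names + cont_classes
        counts = rng.multinomial(config.library_depth, full_p / full_p.sum())

        reads: list[str] = []
        origins: list[str] = []
        for label, count in zip(full_labels, counts):
            for _ in range(int(count)):
                if label in by_name:
                    reads.append(mirna_read(by_name[label]))
                else:
                    reads.append(contaminant_read(label))
                origins.append(label)
        order = rng.permutation(len(reads))
        libraries[lib] = [reads[i] for i in order]
        read_origins[lib] = [origins[i] for i in order]

    mirna_rows = pd.DataFrame(
        {
            "name": names,
            "kind": [m.kind for m in planted],
            "sequence": [m.sequence for m in planted],
            "arm": [m.arm for m in planted],
            "in_genome": [m.in_genome for m in planted],
            "fold_change": [m.fold_change for m in planted],
            "expected_control": props["control"].to_numpy(),
            "expected_treated": props["treated"].to_numpy(),
        }
    ).set_index("name")
    truth = TruthTable(mirna_rows, read_origins, props)
    return libraries, truth


def simulate_count_table(
    config: SimulationConfig,
    planted: list[PlantedMirna],
    seed: int | None = None,
) -> pd.DataFrame:
    """Count-level view of the same model (miRNA x library), skipping reads.

    Multinomial sampling of the per-library miRNA compartment with the same
    replicate-level log-normal noise the read simulator applies.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    props = expected_proportions(config, planted)
    names = [m.name for m in planted]
    data = {}
    for lib in config.library_names:
        cond = config.conditions[lib]
        base = props[cond].to_numpy()
        p = base * rng.lognormal(0.0, config.biological_cv, size=len(names))
        depth_mirna = int(round(config.library_depth * base.sum()))
        data[lib] = rng.multinomial(depth_mirna, p / p.sum())
    return pd.DataFrame(data, index=pd.Index(names, name="miRNA"))


def simulate_null_counts(
    n_features: int,
    n_per_group: int = 3,
    seed: int = 0,
    sigma: float = 0.5,
    mean_log: float = np.log(100.0),
) -> pd.DataFrame:
    """Null features: all replicates i.i.d. from one log-normal distribution."""
    rng = np.random.default_rng(seed)
    cols = [f"C{i + 1}" for i in range(n_per_group)] + [f"T{i + 1}" for i in range(n_per_group)]
    data = rng.lognormal(mean_log, sigma, size=(n_features, 2 * n_per_group))
    return pd.DataFrame(data, columns=cols)


def write_truth_table(truth: TruthTable, directory) -> None:
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    truth.mirnas.to_csv(directory / "truth_mirnas.tsv", sep="\t")
    rows = [
        {"library": lib, "read_index": i, "origin": origin}
        for lib, origins in truth.read_origins.items()
        for i, origin in enumerate(origins)
    ]
    pd.DataFrame(rows).to_csv(directory / "truth_reads.tsv", sep="\t", index=False)
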