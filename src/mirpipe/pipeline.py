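"""End-to-end orchestration: raw libraries -> annotated DE results.

Chains preprocessing, annotation/classification, per-miRNA count
aggregation, differential expression, target prediction, GO enrichment and
promoter motif scanning over one reference bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import cis, enrichment, targets
from .annotate import AnnotationRecord, Annotator
from .diffexpr import differential_expression
from .io import ReferenceBundle
from .preprocess import PreprocessResult, preprocess_libraries


@dataclass
class PipelineResult:
    preprocess: PreprocessResult
    annotations: dict[str, AnnotationRecord]       # tag -> record
    mirna_counts: pd.DataFrame                     # miRNA name x library
    de_table: pd.DataFrame
    target_hits: list[targets.TargetHit] = field(default_factory=list)
    go_results: list[enrichment.GOResult] = field(default_factory=list)
    motif_matrix: pd.DataFrame | None = None

    def annotation_table(self) -> pd.DataFrame:
        rows = []
        for tag, rec in self.annotations.items():
            rows.append(
                {
                    "tag": tag,
                    "group": rec.group,
                    "name": rec.name,
                    "reference": rec.match.reference if rec.match else "",
                    "left_delta": rec.match.left_delta if rec.match else 0,
                    "right_delta": rec.match.right_delta if rec.match else 0,
                    "substitutions": ";".join(
                        f"{p}{r}{o}" for p, r, o in (rec.match.substitutions if rec.match else [])
                    ),
                    "loci": ";".join(
                        f"{h.contig}:{h.start}-{h.end}({h.strand})" for h in rec.loci
                    ),
                    "is_hairpin": rec.hairpin.is_hairpin if rec.hairpin else False,
                }
            )
        return pd.DataFrame(rows).set_index("tag") if rows else pd.DataFrame()

    def target_table(self) -> pd.DataFrame:
        rows = [
            {
                "miRNA": h.mirna, "transcript": h.transcript, "start": h.start,
                "expectation": h.expectation, "mode": h.mode,
                "miRNA_seq": h.mirna_seq, "site_seq": h.site_seq,
            }
            for h in self.target_hits
        ]
        return pd.DataFrame(rows)

    def enrichment_table(self) -> pd.DataFrame:
        rows = [
            {
                "term": r.term, "category": r.category, "k": r.k, "n": r.n,
                "K": r.K, "N": r.N, "p_value": r.p_value, "significant": r.significant,
            }
            for r in self.go_results
        ]
        return pd.DataFrame(rows)


def aggregate_mirna_counts(
    tag_counts: pd.DataFrame,
    annotations: dict[str, AnnotationRecord],
    groups: tuple[str, ...] = ("1a", "1b", "2a", "2b", "3a", "3b", "4a"),
) -> pd.DataFrame:
    """Sum per-tag counts into per-miRNA counts for the annotated groups.

    All isomiRs of one named miRNA collapse onto that name.
    """
    keep = {
        tag: rec.name for tag, rec in annotations.items() if rec.group in groups
    }
    if not keep:
        return pd.DataFrame(columns=tag_counts.columns)
    sub = tag_counts.loc[list(keep)]
    sub = sub.assign(name=[keep[t] for t in sub.index])
    out = sub.groupby("name").sum()
    out.index.name = "miRNA"
    return out


def run_pipeline(
    libraries: dict[str, list[str]],
    bundle: ReferenceBundle,
    conditions: dict[str, str],
    adapter: str,
    end_tolerance: int = 4,
    de_alpha: float = 0.05,
    target_cutoff: float = 3.0,
    with_targets: bool = True,
    with_enrichment: bool = True,
    with_cis: bool = True,
) -> PipelineResult:
    """Run every stage; the DE-flagged miRNAs feed targets/enrichment/cis."""
    pre = preprocess_libraries(libraries, adapter, bundle.contaminants)
    annotator = Annotator(bundle, end_tolerance=end_tolerance)
    totals = pre.tag_counts.sum(axis=1)
    annotations = {
        tag: annotator.classify(tag, total_count=int(totals[tag]))
        for tag in pre.tag_counts.index
    }
    mirna_counts = aggregate_mirna_counts(pre.tag_counts, annotations)
    de = differential_expression(mirna_counts, conditions, clean_totals=pre.clean_totals)

    result = PipelineResult(pre, annotations, mirna_counts, de)
    flagged = de.index[de["significant_05"]]

    if with_targets and len(flagged):
        seqs = {
            rec.name: rec.tag
            for rec in annotations.values()
            if rec.name in set(flagged)
        }
        for name in sorted(seqs):
            result.target_hits.extend(
                targets.find_targets(name, seqs[name], bundle.transcriptome, target_cutoff)
            )
    if with_enrichment and result.target_hits:
        study = {h.transcript for h in result.target_hits}
        result.go_results = enrichment.go_enrich(
            study, bundle.go_annotation, bundle.go_categories, alpha=de_alpha
        )
    if with_cis and bundle.precursor_loci:
        result.motif_matrix = cis.motif_count_matrix(
            bundle.genome, bundle.precursor_loci,
            bundle.motif_table or None,
        )
    return result
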