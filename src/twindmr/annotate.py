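"""Genomic classification of DMRs against gene models and TFBS tracks.

Each DMR gets exactly one of seven categories — upstream, UTR5, exonic,
intronic, UTR3, downstream, intergenic — by a fixed priority that puts the
promoter flank first.  "Upstream" is the 2 kb flank 5' of the TSS on the
transcript's strand (clipped at the chromosome start); "downstream" the
matching flank 3' of the transcript end.  Any >= 1 bp overlap counts, the
intersectBed default.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .dmr import DMR
from .io import GeneModel, TFBSRecord

CATEGORY_PRIORITY = (
    "upstream", "UTR5", "exonic", "intronic", "UTR3", "downstream", "intergenic",
)


@dataclass(frozen=True)
class GeneLink:
    """One transcript touched by a DMR, with the feature that linked it."""

    gene_name: str
    transcript_id: str
    tss_position: int
    relation: str


@dataclass
class AnnotatedDMR:
    dmr: DMR
    category: str
    gene_links: list[GeneLink] = field(default_factory=list)
    tf_hits: list[str] = field(default_factory=list)


@dataclass
class CategorySummary:
    """Per-direction category counts/proportions plus promoter aggregates."""

    counts: dict[str, dict[str, int]]
    proportions: dict[str, dict[str, float]]
    n_promoter_dmrs: int
    n_tss: int
    n_genes: int

    def to_dict(self) -> dict:
        return {
            "counts": self.counts,
            "proportions": self.proportions,
            "n_promoter_dmrs": self.n_promoter_dmrs,
            "n_tss": self.n_tss,
            "n_genes": self.n_genes,
        }


def _transcript_features(
    model: GeneModel, upstream_bp: int, downstream_bp: int
) -> list[tuple[int, int, str]]:
    """(start, end, relation) intervals for one transcript, strand-aware."""
    feats: list[tuple[int, int, str]] = []
    if model.strand == "+":
        up = (max(0, model.tx_start - upstream_bp), model.tx_start)
        down = (model.tx_end, model.tx_end + downstream_bp)
    else:
        up = (model.tx_end, model.tx_end + upstream_bp)
        down = (max(0, model.tx_start - downstream_bp), model.tx_start)
    if up[0] < up[1]:
        feats.append((*up, "upstream"))
    if down[0] < down[1]:
        feats.append((*down, "downstream"))
    for s, e in model.utr5():
        feats.append((s, e, "UTR5"))
    for s, e in model.utr3():
        feats.append((s, e, "UTR3"))
    for s, e in model.coding_exons():
        feats.append((s, e, "exonic"))
    for s, e in model.introns():
        feats.append((s, e, "intronic"))
    return feats


class GeneAnnotator:
    """Interval-tree index over transcript features for batch classification."""

    def __init__(
        self,
        gene_models: list[GeneModel],
        upstream_bp: int = 2000,
        downstream_bp: int = 2000,
        priority: tuple[str, ...] = CATEGORY_PRIORITY,
    ):
        self.upstream_bp = upstream_bp
        self.downstream_bp = downstream_bp
        self.priority = priority
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for m in gene_models:
            for s, e, relation in _transcript_features(m, upstream_bp, downstream_bp):
                self._trees[m.chrom].addi(s, e, (relation, m))

    def classify(self, dmr: DMR) -> tuple[str, list[GeneLink]]:
        hits = self._trees[dmr.chrom].overlap(dmr.start, dmr.end)
        links: list[GeneLink] = []
        relations: set[str] = set()
        for iv in sorted(hits, key=lambda iv: (iv.begin, iv.end)):
            relation, model = iv.data
            relations.add(relation)
            links.append(
                GeneLink(model.gene_name, model.transcript_id, model.tss, relation)
            )
        for cat in self.priority:
            if cat in relations:
                return cat, links
        return "intergenic", links


def classify_dmr(
    dmr: DMR,
    gene_models: list[GeneModel],
    upstream_bp: int = 2000,
    downstream_bp: int = 2000,
) -> tuple[str, list[GeneLink]]:
    """One-shot classification of a single DMR (builds a throwaway index)."""
    return GeneAnnotator(gene_models, upstream_bp, downstream_bp).classify(dmr)


def annotate_dmrs(
    dmrs: list[DMR],
    gene_models: list[GeneModel],
    tfbs_records: list[TFBSRecord] | None = None,
    upstream_bp: int = 2000,
    downstream_bp: int = 2000,
) -> list[AnnotatedDMR]:
    annotator = GeneAnnotator(gene_models, upstream_bp, downstream_bp)
    annotated = []
    for dmr in dmrs:
        category, links = annotator.classify(dmr)
        annotated.append(AnnotatedDMR(dmr=dmr, category=category, gene_links=links))
    if tfbs_records is not None:
        per_dmr, _ = tfbs_in_dmrs(dmrs, tfbs_records)
        for a, hits in zip(annotated, per_dmr):
            a.tf_hits = hits
    return annotated


def summarize_categories(annotated_dmrs: list[AnnotatedDMR]) -> CategorySummary:
    """Counts and proportions per direction plus promoter dedup aggregates.

    Promoter aggregates count distinct upstream-category DMRs, the distinct
    TSS positions they link through upstream relations, and the distinct
    gene names behind those TSSs.
    """
    counts = {d: {c: 0 for c in CATEGORY_PRIORITY} for d in ("hyper", "hypo")}
    tss_seen: set[tuple[str, int]] = set()
    genes_seen: set[str] = set()
    n_promoter = 0
    for a in annotated_dmrs:
        counts[a.dmr.direction][a.category] += 1
        if a.category == "upstream":
            n_promoter += 1
            for link in a.gene_links:
                if link.relation == "upstream":
                    tss_seen.add((link.transcript_id, link.tss_position))
                    genes_seen.add(link.gene_name)
    proportions: dict[str, dict[str, float]] = {}
    for direction, cc in counts.items():
        total = sum(cc.values())
        if total:
            proportions[direction] = {c: cc[c] / total for c in CATEGORY_PRIORITY}
    return CategorySummary(
        counts=counts,
        proportions=proportions,
        n_promoter_dmrs=n_promoter,
        n_tss=len(tss_seen),
        n_genes=len(genes_seen),
    )


def tfbs_in_dmrs(
    dmrs: list[DMR], tfbs_records: list[TFBSRecord]
) -> tuple[list[list[str]], set[str]]:
    """Per-DMR TF hit lists and the distinct TF name set across all hits.

    A TFBS hits a DMR iff the half-open intervals overlap by >= 1 bp.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for t in tfbs_records:
        trees[t.chrom].addi(t.start, t.end, t.tf_name)
    per_dmr: list[list[str]] = []
    all_tfs: set[str] = set()
    for d in dmrs:
        names = sorted({iv.data for iv in trees[d.chrom].overlap(d.start, d.end)})
        per_dmr.append(names)
        all_tfs.update(names)
    return per_dmr, all_tfs


def write_annotated_tsv(annotated: list[AnnotatedDMR], path) -> None:
    """TSV: DMR coords, direction, category, gene_links, tf_hits."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tdirection\tcategory\tgene_links\ttf_hits\n")
        for a in annotated:
            links = ";".join(
                f"{l.gene_name}|{l.transcript_id}|{l.tss_position}|{l.relation}"
                for l in a.gene_links
            )
            fh.write(
                f"{a.dmr.chrom}\t{a.dmr.start}\t{a.dmr.end}\t{a.dmr.direction}\t"
                f"{a.category}\t{links}\t{';'.join(a.tf_hits)}\n"
            )
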