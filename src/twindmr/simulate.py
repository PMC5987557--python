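"""Synthetic inputs for the whole pipeline, with ground truth.

The generator emulates the statistical structure of RRBS-style CpG data:
clustered CpG placement (island/background renewal process), a strongly
bimodal baseline methylation mixture (most sites near 0 or near 1),
negative-binomial read depth, binomial methylated counts, planted
differential regions of known direction and effect, gene models and TFBS
tracks for annotation, and a clone-sequencing case/control cohort whose
expression decreases with promoter methylation.

Everything is a pure function of the configuration and its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    CloneMatrix,
    GeneModel,
    MethylomeSample,
    TFBSRecord,
    write_chrom_sizes,
    write_clone_matrix,
    write_cohort_table,
    write_cytosine_report,
    write_gene_models_refflat,
    write_tfbs_bed,
)


class SimulationConfigError(ValueError):
    """The requested simulation cannot be realised on the configured genome."""


@dataclass
class SimulationConfig:
    """Knobs of the paired-methylome simulation.

    CpG sites are laid down by a two-state renewal process: dense islands
    (mean spacing ``island_spacing`` bp, mean length ``island_length`` bp)
    alternating with sparse background.  Baseline methylation is a
    two-component Beta mixture concentrated near 0 and near 1.  Depth is
    negative binomial (``depth_mean``, dispersion ``depth_dispersion``);
    methylated counts are binomial in the true level.  ``n_dmrs`` regions
    of ``dmr_n_cpgs`` consecutive CpGs (confined to spans of at most
    ``dmr_max_span`` bp so they are window-detectable) get sample 1's true
    level shifted by exactly ±``dmr_delta``.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    island_spacing: float = 12.0
    background_spacing: float = 120.0
    island_length: float = 600.0
    background_length: float = 3000.0
    low_weight: float = 0.45
    low_beta: tuple[float, float] = (0.6, 12.0)
    high_beta: tuple[float, float] = (12.0, 0.6)
    level_concentration: float = 50.0
    depth_mean: float = 30.0
    depth_dispersion: float = 5.0
    n_dmrs: int = 50
    dmr_n_cpgs: int = 10
    dmr_delta: float = 0.4
    dmr_max_span: int = 150
    dmr_min_gap: int = 500
    direction_prob: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.dmr_delta <= 1):
            raise SimulationConfigError("dmr_delta must be in (0, 1]")
        if self.dmr_n_cpgs < 1:
            raise SimulationConfigError("dmr_n_cpgs must be >= 1")
        if not (0 <= self.direction_prob <= 1):
            raise SimulationConfigError("direction_prob must be in [0, 1]")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}

    @property
    def cpg_rate(self) -> float:
        """Expected CpGs per bp implied by the renewal parameters."""
        f_island = self.island_length / (self.island_length + self.background_length)
        return f_island / self.island_spacing + (1 - f_island) / self.background_spacing


@dataclass(frozen=True)
class TruthRegion:
    chrom: str
    start: int
    end: int
    direction: str
    delta: float
    n_cpgs: int


@dataclass
class TruthSet:
    """Planted regions plus per-site true levels for both samples."""

    regions: list[TruthRegion]
    true_levels: pd.DataFrame  # chrom, pos, level_1, level_2


# ---------------------------------------------------------------------------
# Methylome pair
# ---------------------------------------------------------------------------

def _cpg_positions(
    rng: np.random.Generator, length: int, cfg: SimulationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Clustered CpG coordinates on one chromosome (0-based, sorted).

    Returns (positions, segment ids); a segment is one island or one
    background stretch of the renewal process and defines the local
    methylation domain.
    """
    positions: list[int] = []
    seg_ids: list[int] = []
    pos = 0
    island = False
    seg = 0
    while pos < length:
        seg_mean = cfg.island_length if island else cfg.background_length
        seg_end = pos + max(1, int(rng.exponential(seg_mean)))
        spacing = cfg.island_spacing if island else cfg.background_spacing
        while pos < min(seg_end, length):
            pos += max(2, int(round(rng.exponential(spacing))) + 2)
            if pos < length:
                positions.append(pos)
                seg_ids.append(seg)
        pos = max(pos, seg_end)
        island = not island
        seg += 1
    return np.array(positions, dtype=np.int64), np.array(seg_ids, dtype=np.int64)


def _baseline_levels(
    rng: np.random.Generator, seg_ids: np.ndarray, cfg: SimulationConfig
) -> np.ndarray:
    """Locally correlated baseline levels: one bimodal draw per segment.

    Neighbouring CpGs share a methylation domain, as in real methylomes;
    each segment's domain level comes from the near-0/near-1 Beta mixture
    and per-site levels scatter around it with Beta noise of the
    configured concentration.
    """
    n = len(seg_ids)
    uniq, inverse = np.unique(seg_ids, return_inverse=True)
    low = rng.random(len(uniq)) < cfg.low_weight
    domain = np.empty(len(uniq))
    domain[low] = rng.beta(*cfg.low_beta, size=int(low.sum()))
    domain[~low] = rng.beta(*cfg.high_beta, size=int((~low).sum()))
    domain = np.clip(domain, 0.005, 0.995)
    site_domain = domain[inverse]
    c = cfg.level_concentration
    return rng.beta(site_domain * c, (1 - site_domain) * c, size=n)


def _nb_depth(rng: np.random.Generator, n: int, cfg: SimulationConfig) -> np.ndarray:
    size = cfg.depth_dispersion
    p = size / (size + cfg.depth_mean)
    return rng.negative_binomial(size, p, size=n)


def _pick_regions(
    rng: np.random.Generator,
    pos_by_chrom: dict[str, np.ndarray],
    cfg: SimulationConfig,
) -> list[tuple[str, int, int]]:
    """Choose non-overlapping runs of dmr_n_cpgs consecutive compact CpGs.

    Returns (chrom, first_site_index, last_site_index) triples; raises when
    the genome cannot host the requested number of well-separated regions.
    """
    k = cfg.dmr_n_cpgs
    candidates: list[tuple[str, int]] = []
    for chrom, pos in pos_by_chrom.items():
        if len(pos) < k:
            continue
        spans = pos[k - 1:] - pos[: len(pos) - k + 1]
        for i in np.flatnonzero(spans <= cfg.dmr_max_span):
            candidates.append((chrom, int(i)))
    order = rng.permutation(len(candidates))
    chosen: list[tuple[str, int, int]] = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    for j in order:
        if len(chosen) == cfg.n_dmrs:
            break
        chrom, i = candidates[j]
        pos = pos_by_chrom[chrom]
        lo = int(pos[i]) - cfg.dmr_min_gap
        hi = int(pos[i + k - 1]) + 2 + cfg.dmr_min_gap
        if any(not (hi <= s or e <= lo) for s, e in occupied.get(chrom, [])):
            continue
        occupied.setdefault(chrom, []).append((lo, hi))
        chosen.append((chrom, i, i + k - 1))
    if len(chosen) < cfg.n_dmrs:
        raise SimulationConfigError(
            f"genome too small/sparse for {cfg.n_dmrs} non-overlapping planted "
            f"regions (placed {len(chosen)})"
        )
    return sorted(chosen)


def simulate_methylome_pair(
    config: SimulationConfig,
) -> tuple[MethylomeSample, MethylomeSample, TruthSet]:
    """Paired methylomes with planted differential regions and ground truth.

    Inside a planted region the shared baseline is compressed into the
    feasible band and sample 1's level shifted by exactly ±dmr_delta, so
    every planted site carries the full effect; outside, the two samples
    share the same true level and differ only by binomial resampling.
    """
    rng = np.random.default_rng(config.seed)
    pos_by_chrom: dict[str, np.ndarray] = {}
    segs_by_chrom: dict[str, np.ndarray] = {}
    for chrom, length in config.chrom_sizes.items():
        pos_by_chrom[chrom], segs_by_chrom[chrom] = _cpg_positions(rng, length, config)
    regions = _pick_regions(rng, pos_by_chrom, config) if config.n_dmrs else []

    frames_1, frames_2, truth_frames = [], [], []
    truth_regions: list[TruthRegion] = []
    region_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, i0, i1 in regions:
        region_by_chrom.setdefault(chrom, []).append((i0, i1))

    for chrom, pos in pos_by_chrom.items():
        n = len(pos)
        base = _baseline_levels(rng, segs_by_chrom[chrom], config)
        lev1 = base.copy()
        lev2 = base.copy()
        for i0, i1 in region_by_chrom.get(chrom, []):
            hyper = rng.random() < config.direction_prob
            d = config.dmr_delta
            seg = slice(i0, i1 + 1)
            if hyper:
                lev2[seg] = base[seg] * (1 - d)
                lev1[seg] = lev2[seg] + d
            else:
                lev2[seg] = base[seg] * (1 - d) + d
                lev1[seg] = lev2[seg] - d
            truth_regions.append(
                TruthRegion(
                    chrom=chrom, start=int(pos[i0]), end=int(pos[i1]) + 2,
                    direction="hyper" if hyper else "hypo",
                    delta=d if hyper else -d, n_cpgs=i1 - i0 + 1,
                )
            )
        for lev, store in ((lev1, frames_1), (lev2, frames_2)):
            depth = _nb_depth(rng, n, config)
            meth = rng.binomial(depth, lev)
            store.append(
                pd.DataFrame(
                    {
                        "chrom": chrom, "pos": pos, "strand": "+",
                        "meth": meth, "unmeth": depth - meth,
                        "context": "CG", "tri": "CGG",
                    }
                )
            )
        truth_frames.append(
            pd.DataFrame({"chrom": chrom, "pos": pos, "level_1": lev1, "level_2": lev2})
        )

    s1 = MethylomeSample("sim_s1", pd.concat(frames_1, ignore_index=True))
    s2 = MethylomeSample("sim_s2", pd.concat(frames_2, ignore_index=True))
    truth = TruthSet(
        regions=sorted(truth_regions, key=lambda r: (r.chrom, r.start)),
        true_levels=pd.concat(truth_frames, ignore_index=True),
    )
    return s1, s2, truth


# ---------------------------------------------------------------------------
# Gene models and TFBS
# ---------------------------------------------------------------------------

def _make_transcript(
    rng: np.random.Generator, name: str, chrom: str, tx_start: int, strand: str,
    coding_prob: float = 0.9,
) -> GeneModel:
    n_exons = int(rng.integers(2, 6))
    exon_sizes = rng.integers(100, 500, size=n_exons)
    intron_sizes = rng.integers(200, 2000, size=n_exons - 1)
    exons = []
    cursor = tx_start
    for i in range(n_exons):
        exons.append((cursor, cursor + int(exon_sizes[i])))
        cursor = exons[-1][1] + (int(intron_sizes[i]) if i < n_exons - 1 else 0)
    tx_end = exons[-1][1]
    if rng.random() < coding_prob:
        cds_start = exons[0][0] + int(rng.integers(10, exon_sizes[0] - 10))
        cds_end = exons[-1][1] - int(rng.integers(10, exon_sizes[-1] - 10))
    else:
        cds_start = cds_end = tx_start
    return GeneModel(
        gene_name=name.split(".")[0], transcript_id=name, chrom=chrom,
        strand=strand, tx_start=tx_start, tx_end=tx_end,
        cds_start=cds_start, cds_end=cds_end, exons=tuple(exons),
    )


def simulate_gene_models(
    config: SimulationConfig,
    n_genes: int,
    promoter_regions: list[TruthRegion] | None = None,
    upstream_bp: int = 2000,
    rng: np.random.Generator | None = None,
) -> list[GeneModel]:
    """Non-overlapping random transcripts, optionally promoter-coupled.

    For each region in ``promoter_regions`` one transcript is placed so the
    region lies inside its upstream flank (TSS within ``upstream_bp``
    downstream of the region on the transcript's strand).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    sizes = config.chrom_sizes
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in sizes}
    models: list[GeneModel] = []

    def try_add(model: GeneModel) -> bool:
        if model.tx_end > sizes[model.chrom]:
            return False
        for s, e in occupied[model.chrom]:
            if not (model.tx_end <= s or e <= model.tx_start):
                return False
        occupied[model.chrom].append((model.tx_start, model.tx_end))
        models.append(model)
        return True

    for j, region in enumerate(promoter_regions or []):
        placed = False
        for _ in range(200):
            strand = "+" if rng.random() < 0.5 else "-"
            gap = int(rng.integers(0, max(1, upstream_bp - (region.end - region.start))))
            if strand == "+":
                tx_start = region.end + gap
                model = _make_transcript(rng, f"PGENE{j + 1}.1", region.chrom, tx_start, "+")
            else:
                # build left of the region so the TSS (tx_end - 1) faces it
                probe = _make_transcript(rng, f"PGENE{j + 1}.1", region.chrom, 0, "-")
                span = probe.tx_end - probe.tx_start
                tx_start = region.start - gap - span
                if tx_start < 0:
                    continue
                model = GeneModel(
                    gene_name=probe.gene_name, transcript_id=probe.transcript_id,
                    chrom=region.chrom, strand="-",
                    tx_start=tx_start, tx_end=tx_start + span,
                    cds_start=probe.cds_start + tx_start, cds_end=probe.cds_end + tx_start,
                    exons=tuple((s + tx_start, e + tx_start) for s, e in probe.exons),
                )
            if try_add(model):
                placed = True
                break
        if not placed:
            raise SimulationConfigError(
                f"could not place a promoter-coupled gene for region "
                f"{region.chrom}:{region.start}-{region.end}"
            )

    chroms = list(sizes)
    for j in range(n_genes - len(models)):
        for _ in range(200):
            chrom = chroms[int(rng.integers(len(chroms)))]
            strand = "+" if rng.random() < 0.5 else "-"
            tx_start = int(rng.integers(0, sizes[chrom] - 20_000))
            if try_add(_make_transcript(rng, f"GENE{j + 1}.1", chrom, tx_start, strand)):
                break
    return models


def simulate_tfbs(
    config: SimulationConfig,
    tf_names: list[str],
    n_sites: int,
    enrich_regions: list[TruthRegion] | None = None,
    enrichment: float = 1.0,
    rng: np.random.Generator | None = None,
) -> list[TFBSRecord]:
    """Random 6–20 bp named binding intervals, optionally DMR-enriched.

    With ``enrichment`` > 1 each site lands inside a planted region with
    probability enrichment-times its length share of the genome.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    sizes = config.chrom_sizes
    genome_len = sum(sizes.values())
    regions = enrich_regions or []
    region_len = sum(r.end - r.start for r in regions)
    p_region = 0.0
    if regions and enrichment > 0:
        p_region = enrichment * region_len / (
            enrichment * region_len + (genome_len - region_len)
        )
    chroms = list(sizes)
    out = []
    for i in range(n_sites):
        width = int(rng.integers(6, 21))
        if regions and rng.random() < p_region:
            r = regions[int(rng.integers(len(regions)))]
            start = int(rng.integers(r.start, max(r.start + 1, r.end - width)))
            chrom = r.chrom
        else:
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(0, sizes[chrom] - width))
        out.append(TFBSRecord(chrom, start, start + width, tf_names[i % len(tf_names)]))
    return out


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def simulate_cohort(
    seed: int,
    n_cases: int = 15,
    n_controls: int = 5,
    n_cpgs: int = 20,
    n_clones: int = 20,
    case_level: float = 0.7,
    control_level: float = 0.1,
    effect_penetrance: float = 0.8,
    expr_slope: float = 3.0,
    expr_sigma: float = 0.3,
) -> tuple[dict[str, CloneMatrix], pd.DataFrame]:
    """Clone matrices plus a cohort table with expression.

    Each affected case's clones are Bernoulli(case_level) per CpG; a case
    is affected with probability ``effect_penetrance``; everyone else is
    Bernoulli(control_level).  Expression is log-linear decreasing in the
    sample mean methylation with lognormal noise.
    """
    if not (0 <= case_level <= 1 and 0 <= control_level <= 1):
        raise ValueError("methylation levels must be in [0, 1]")
    if not (0 <= effect_penetrance <= 1):
        raise ValueError("effect_penetrance must be in [0, 1]")
    rng = np.random.default_rng(seed)
    positions = tuple(np.cumsum(rng.integers(10, 40, size=n_cpgs)) + 100)
    matrices: dict[str, CloneMatrix] = {}
    rows = []
    labels = [("case", i + 1) for i in range(n_cases)] + [
        ("control", i + 1) for i in range(n_controls)
    ]
    for group, i in labels:
        sid = f"{group}{i}"
        affected = group == "case" and rng.random() < effect_penetrance
        level = case_level if affected else control_level
        matrix = (rng.random((n_clones, n_cpgs)) < level).astype(float)
        cm = CloneMatrix(sid, positions, matrix)
        matrices[sid] = cm
        mean = float(matrix.mean())
        expression = float(np.exp(1.0 - expr_slope * mean + rng.normal(0, expr_sigma)))
        rows.append({"sample_id": sid, "group": group, "expression": expression})
    return matrices, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Whole-run writer
# ---------------------------------------------------------------------------

def write_truth_bed(regions: list[TruthRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.direction}\t{abs(r.delta):g}\t.\n")


def write_simulation(
    config: SimulationConfig,
    outdir: str | Path,
    n_genes: int = 30,
    n_promoter_coupled: int = 3,
    tf_names: tuple[str, ...] = ("GATA4", "NKX2-5", "ZIC3", "NR2F2", "TBX5"),
    n_tfbs: int = 300,
    cohort: bool = True,
) -> dict:
    """Generate and write every pipeline input under ``outdir``.

    Emits: s1.CX.gz, s2.CX.gz, chrom.sizes, genes.refflat, tfbs.bed,
    truth.bed, clones/<sample>.tsv and cohort.tsv.  Returns the manifest of
    written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    s1, s2, truth = simulate_methylome_pair(config)
    coupled = truth.regions[: min(n_promoter_coupled, len(truth.regions))]
    genes = simulate_gene_models(config, n_genes, promoter_regions=coupled)
    tfbs = simulate_tfbs(config, list(tf_names), n_tfbs,
                         enrich_regions=truth.regions, enrichment=10.0)
    paths = {
        "sample1": outdir / "s1.CX.gz",
        "sample2": outdir / "s2.CX.gz",
        "chrom_sizes": outdir / "chrom.sizes",
        "genes": outdir / "genes.refflat",
        "tfbs": outdir / "tfbs.bed",
        "truth": outdir / "truth.bed",
    }
    write_cytosine_report(s1, paths["sample1"])
    write_cytosine_report(s2, paths["sample2"])
    write_chrom_sizes(config.chrom_sizes, paths["chrom_sizes"])
    write_gene_models_refflat(genes, paths["genes"])
    write_tfbs_bed(tfbs, paths["tfbs"])
    write_truth_bed(truth.regions, paths["truth"])
    if cohort:
        matrices, table = simulate_cohort(config.seed + 3)
        clone_dir = outdir / "clones"
        clone_dir.mkdir(exist_ok=True)
        for sid, cm in matrices.items():
            write_clone_matrix(cm, clone_dir / f"{sid}.tsv")
        write_cohort_table(table, outdir / "cohort.tsv")
        paths["clones"] = clone_dir
        paths["cohort"] = outdir / "cohort.tsv"
    return {k: str(v) for k, v in paths.items()}
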