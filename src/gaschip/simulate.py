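"""Ground-truthed synthetic data with the structure the pipeline assumes.

The generator builds, deterministically under a seed:

* a multi-chromosome genome of i.i.d. bases at a configurable GC content;
* non-overlapping stranded multi-exon genes (introns >= 1 kb, genes spaced
  >= 25 kb apart so that every location category is placeable);
* a cohort of cloned binding sites whose midpoints are planted at least 1 bp
  inside their assigned category region (intron 1 / internal intron /
  < 10 kb upstream, strand-aware / intergenic);
* site sequences whose background is scrubbed motif-free by rejection
  sampling (any window matching the relaxed GAS pattern TTN5AA is redrawn),
  with exactly one GAS 9-mer inserted for canonical or general-only sites —
  so motif-class recovery by the scanner is a hard guarantee, and any test
  failure indicates a pipeline bug rather than generator noise;
* replicate assay tables: qPCR Ct pairs with Gaussian cycle noise around a
  true expression ratio, ChIP-qPCR Ct pairs encoding true percent-input
  levels, and firefly/Renilla wells with log-normal noise around a true fold
  induction.

Default cohort composition mirrors the 105-clone study cohort: location
counts {intergenic 49, upstream 12, intron1 14, internal_intron 30} and
motif classes {canonical 27, general_only 71, none 7}.

Every dataset is emitted together with its ground truth (true category,
target genes, motif class and offset per site; true assay parameters), which
is sufficient to score recovery exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genomic import ClonedSite, GeneModel, GenomeSequence
from .motifs import CANONICAL, GENERAL, scan_pattern

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Parameters of one synthetic dataset.

    Category and motif-class counts must sum to the same cohort size; default
    composition reproduces a 105-site clone cohort.
    """

    seed: int = 0
    n_chroms: int = 3
    chrom_length: int = 1_500_000
    gc_content: float = 0.41
    n_genes: int = 30
    exons_per_gene_range: tuple[int, int] = (2, 6)
    exon_length_range: tuple[int, int] = (100, 300)
    intron_length_range: tuple[int, int] = (1_000, 3_000)
    min_gene_spacing: int = 25_000
    category_counts: dict[str, int] = field(
        default_factory=lambda: {
            "intergenic": 49,
            "upstream_lt10kb": 12,
            "intron1": 14,
            "internal_intron": 30,
        }
    )
    motif_class_counts: dict[str, int] = field(
        default_factory=lambda: {"canonical": 27, "general_only": 71, "none": 7}
    )
    site_length_range: tuple[int, int] = (200, 1_000)
    upstream_window: int = 10_000
    # assay truth and noise
    ct_noise_sd: float = 0.2
    luc_cv: float = 0.1
    qpcr_replicates: int = 3
    luc_replicates: int = 3
    true_expression_fold: float = 4.0
    true_fold_induction: float = 5.0
    true_percent_input: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("STAT5b", "IL2"): 8.0,
            ("STAT5a", "IL2"): 4.0,
            ("STAT5b", "untreated"): 0.4,
            ("STAT5a", "untreated"): 0.3,
            ("IgG", "IL2"): 0.1,
            ("IgG", "untreated"): 0.1,
        }
    )
    input_fraction: float = 0.01

    @property
    def cohort_size(self) -> int:
        return sum(self.category_counts.values())

    def validate(self) -> None:
        if any(n < 0 for n in self.category_counts.values()):
            raise ValueError("category counts must be non-negative")
        if any(n < 0 for n in self.motif_class_counts.values()):
            raise ValueError("motif class counts must be non-negative")
        if sum(self.motif_class_counts.values()) != self.cohort_size:
            raise ValueError(
                "motif class counts must sum to the cohort size "
                f"({sum(self.motif_class_counts.values())} != {self.cohort_size})"
            )
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")


@dataclass
class GroundTruth:
    """True per-site labels and true assay parameters for scoring recovery."""

    sites: pd.DataFrame  # site_id, chrom, start, end, category, genes, ...
    assays: dict[str, float] = field(default_factory=dict)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent deterministic streams per stage
    return np.random.default_rng([config.seed, stream])


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(_BASES, size=length, p=p).tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Genome and gene layout
# ---------------------------------------------------------------------------

def simulate_genome_and_genes(
    config: SimConfig,
) -> tuple[GenomeSequence, list[GeneModel]]:
    """Random genome plus non-overlapping stranded multi-exon genes.

    Genes are packed left to right with at least ``min_gene_spacing`` bp
    between spans and a margin at each chromosome end, so every location
    category (including > 10 kb intergenic) stays placeable.
    """
    config.validate()
    rng = _rng(config, 1)
    genome = GenomeSequence(
        {
            f"chr{i + 1}": _random_dna(rng, config.chrom_length, config.gc_content)
            for i in range(config.n_chroms)
        }
    )
    margin = config.min_gene_spacing
    genes: list[GeneModel] = []
    cursors = {c: margin for c in genome.chrom_names}
    for i in range(config.n_genes):
        chrom = genome.chrom_names[i % config.n_chroms]
        n_exons = int(rng.integers(*config.exons_per_gene_range, endpoint=True))
        exon_lens = rng.integers(*config.exon_length_range, endpoint=True, size=n_exons)
        intron_lens = rng.integers(
            *config.intron_length_range, endpoint=True, size=n_exons - 1
        )
        span = int(exon_lens.sum() + intron_lens.sum())
        start = cursors[chrom]
        if start + span > config.chrom_length - margin:
            raise ValueError(
                f"cannot place gene {i + 1} on {chrom}: span {span} bp does not fit "
                f"(chrom_length={config.chrom_length}, min_gene_spacing={margin})"
            )
        exons = []
        pos = start
        for j in range(n_exons):
            exons.append((pos, pos + int(exon_lens[j])))
            pos += int(exon_lens[j])
            if j < n_exons - 1:
                pos += int(intron_lens[j])
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(
                gene_id=f"gene{i + 1:03d}",
                chrom=chrom,
                strand=strand,
                tx_start=start,
                tx_end=pos,
                exons=tuple(exons),
            )
        )
        spacing = margin + int(rng.integers(0, 10_000))
        cursors[chrom] = pos + spacing
    genes.sort(key=lambda g: (g.chrom, g.tx_start))
    return genome, genes


# ---------------------------------------------------------------------------
# Site placement
# ---------------------------------------------------------------------------

def _is_intergenic(mid: int, genes: list[GeneModel], window: int) -> bool:
    """Intergenic with >= 1 bp margin from every category boundary."""
    for g in genes:
        if g.tx_start - 1 <= mid <= g.tx_end:
            return False
        d = g.upstream_distance(mid)
        if d is not None and d <= window + 1:
            return False
    return True


def plant_sites(
    config: SimConfig,
    genome: GenomeSequence,
    genes: list[GeneModel],
) -> tuple[list[ClonedSite], GroundTruth]:
    """Place cloned-site intervals so each midpoint sits safely inside its
    assigned category region; returns the cohort plus per-site ground truth.

    Midpoints keep >= 1 bp of margin from every category boundary, and the
    construction guarantees the interval midpoint ((start + end) // 2)
    reproduces the planted position exactly.
    """
    config.validate()
    rng = _rng(config, 2)
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    placements: list[tuple[str, int, str, tuple[str, ...]]] = []
    window = config.upstream_window

    def genes_with_intron(min_introns: int) -> list[GeneModel]:
        return [g for g in genes if len(g.introns) >= min_introns]

    for _ in range(config.category_counts.get("intron1", 0)):
        pool = genes_with_intron(1)
        if not pool:
            raise ValueError("intron1 sites requested but no gene has an intron")
        g = pool[rng.integers(len(pool))]
        s, e, _ = next(
            iv for iv in g.introns_with_ordinals() if iv[2] == 1
        )
        mid = int(rng.integers(s + 1, e - 1))
        placements.append((g.chrom, mid, "intron1", (g.gene_id,)))

    for _ in range(config.category_counts.get("internal_intron", 0)):
        pool = genes_with_intron(2)
        if not pool:
            raise ValueError(
                "internal_intron sites requested but no gene has >= 2 introns"
            )
        g = pool[rng.integers(len(pool))]
        candidates = [iv for iv in g.introns_with_ordinals() if iv[2] >= 2]
        s, e, _ = candidates[rng.integers(len(candidates))]
        mid = int(rng.integers(s + 1, e - 1))
        placements.append((g.chrom, mid, "internal_intron", (g.gene_id,)))

    for _ in range(config.category_counts.get("upstream_lt10kb", 0)):
        if not genes:
            raise ValueError("upstream sites requested but there are no genes")
        g = genes[rng.integers(len(genes))]
        d = int(rng.integers(1, window))  # strictly inside (0, window)
        mid = g.tss - d if g.strand == "+" else g.tss + d
        if not 0 <= mid < genome.length(g.chrom):
            raise ValueError(f"upstream placement for {g.gene_id} falls off {g.chrom}")
        placements.append((g.chrom, mid, "upstream_lt10kb", (g.gene_id,)))

    n_intergenic = config.category_counts.get("intergenic", 0)
    max_tries = 200 * max(1, n_intergenic)
    placed = 0
    tries = 0
    while placed < n_intergenic:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                "could not place intergenic sites: genome too crowded for "
                f"the > {window} bp margin"
            )
        chrom = genome.chrom_names[rng.integers(config.n_chroms)]
        mid = int(rng.integers(1_000, genome.length(chrom) - 1_000))
        chrom_genes = by_chrom.get(chrom, [])
        if not _is_intergenic(mid, chrom_genes, window):
            continue
        left = [g for g in chrom_genes if g.tss < mid]
        right = [g for g in chrom_genes if g.tss > mid]
        flanks = []
        if left:
            flanks.append(max(left, key=lambda g: g.tss).gene_id)
        if right:
            flanks.append(min(right, key=lambda g: g.tss).gene_id)
        placements.append((chrom, mid, "intergenic", tuple(flanks)))
        placed += 1

    order = rng.permutation(len(placements))
    sites: list[ClonedSite] = []
    rows = []
    used: set[tuple[str, int, int]] = set()
    for rank, idx in enumerate(order, 1):
        chrom, mid, category, gene_ids = placements[idx]
        for _ in range(100):
            length = int(rng.integers(*config.site_length_range, endpoint=True))
            start = mid - length // 2
            end = start + length
            if start < 0 or end > genome.length(chrom):
                continue
            if (chrom, start, end) not in used:
                break
        else:
            raise ValueError(f"could not draw a unique interval around {chrom}:{mid}")
        used.add((chrom, start, end))
        site_id = f"site{rank:03d}"
        sites.append(ClonedSite(site_id=site_id, chrom=chrom, start=start, end=end))
        rows.append((site_id, chrom, start, end, category, ",".join(gene_ids)))
    truth = pd.DataFrame(
        rows, columns=["site_id", "chrom", "start", "end", "category", "genes"]
    )
    return sites, GroundTruth(sites=truth)


# ---------------------------------------------------------------------------
# Motif planting
# ---------------------------------------------------------------------------

def _scrub(seq: list[str], rng: np.random.Generator, protected: range | None,
           max_iter: int) -> None:
    """Redraw bases until no relaxed-pattern match survives outside `protected`.

    Mutates `seq` in place; bases inside `protected` are never touched.
    """
    for _ in range(max_iter):
        matches = scan_pattern("".join(seq), GENERAL)
        offending = [
            m
            for m in matches
            if protected is None or m.offset != protected.start
        ]
        if not offending:
            return
        m = offending[0]
        positions = [
            p
            for p in range(m.offset, m.offset + 9)
            if protected is None or p not in protected
        ]
        for p in positions:
            seq[p] = "ACGT"[rng.integers(4)]
    raise ValueError("motif-free background rejection did not converge")


def _draw_canonical(rng: np.random.Generator) -> str:
    return "TTC" + "".join("ACGT"[rng.integers(4)] for _ in range(3)) + "GAA"


def _draw_general_only(rng: np.random.Generator) -> str:
    # relaxed 9-mer that is NOT canonical (canonical iff base 2 == C and 6 == G)
    while True:
        mer = "TT" + "".join("ACGT"[rng.integers(4)] for _ in range(5)) + "AA"
        if not (mer[2] == "C" and mer[6] == "G"):
            return mer


def plant_motifs(
    sites: list[ClonedSite],
    config: SimConfig,
    truth: GroundTruth | None = None,
) -> tuple[list[ClonedSite], GroundTruth]:
    """Attach a motif-free background sequence to every site and insert one
    GAS 9-mer according to the configured motif-class composition.

    After insertion the sequence is re-scrubbed so the planted offset is the
    ONLY relaxed-pattern match (and general-only insertions are additionally
    guaranteed canonical-free), making class recovery exact by construction.
    """
    config.validate()
    if sum(config.motif_class_counts.values()) != len(sites):
        raise ValueError(
            "motif class counts must sum to the number of sites "
            f"({sum(config.motif_class_counts.values())} != {len(sites)})"
        )
    rng = _rng(config, 3)
    labels = [
        cls
        for cls in ("canonical", "general_only", "none")
        for _ in range(config.motif_class_counts.get(cls, 0))
    ]
    labels = [labels[i] for i in rng.permutation(len(labels))]
    out_sites: list[ClonedSite] = []
    rows = []
    for site, label in zip(sites, labels):
        length = site.end - site.start
        if length < 9:
            raise ValueError(f"site {site.site_id}: too short ({length} bp) for a motif")
        seq = list(_random_dna(rng, length, config.gc_content))
        offset: int | None = None
        if label == "none":
            _scrub(seq, rng, None, max_iter=20 * length)
        else:
            offset = int(rng.integers(0, length - 9 + 1))
            mer = (
                _draw_canonical(rng)
                if label == "canonical"
                else _draw_general_only(rng)
            )
            seq[offset : offset + 9] = mer
            protected = range(offset, offset + 9)
            _scrub(seq, rng, protected, max_iter=20 * length)
        out_sites.append(replace(site, sequence="".join(seq)))
        rows.append((site.site_id, label, offset))
    motif_truth = pd.DataFrame(
        rows, columns=["site_id", "motif_class", "motif_offset"]
    )
    if truth is not None:
        merged = truth.sites.merge(motif_truth, on="site_id", how="left")
        return out_sites, GroundTruth(sites=merged, assays=truth.assays)
    return out_sites, GroundTruth(sites=motif_truth)


# ---------------------------------------------------------------------------
# Assay tables
# ---------------------------------------------------------------------------

def simulate_assays(config: SimConfig) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Replicate qPCR, ChIP-qPCR and luciferase tables with known truth.

    qPCR: reference (housekeeping) Ct ~ 13.7, baseline target Ct ~ 30; the
    treated sample's true target Ct is shifted down by log2(true fold).
    ChIP-qPCR: input Ct ~ 25 at the configured input fraction; IP Cts encode
    the true percent-input levels per antibody x condition.  Luciferase:
    uninduced firefly/Renilla ratio 1.0, induced ratio equal to the true fold.
    """
    config.validate()
    rng = _rng(config, 4)
    sd = config.ct_noise_sd
    fold = config.true_expression_fold

    ct_ref_true = 13.7
    ct_base_true = 30.0
    qpcr_rows = []
    for condition, ct_target_true in (
        ("baseline", ct_base_true),
        ("treated", ct_base_true - np.log2(fold)),
    ):
        for rep in range(1, config.qpcr_replicates + 1):
            qpcr_rows.append(
                (
                    condition,
                    rep,
                    ct_target_true + rng.normal(0, sd),
                    ct_ref_true + rng.normal(0, sd),
                )
            )
    qpcr = pd.DataFrame(
        qpcr_rows, columns=["sample_id", "replicate_id", "ct_target", "ct_reference"]
    )

    ct_input_true = 25.0
    dilution = np.log2(1.0 / config.input_fraction)
    chip_rows = []
    for (antibody, condition), pct in config.true_percent_input.items():
        ct_ip_true = (ct_input_true - dilution) - np.log2(pct / 100.0)
        for rep in range(1, config.qpcr_replicates + 1):
            chip_rows.append(
                (
                    f"{antibody}_{condition}",
                    antibody,
                    condition,
                    rep,
                    ct_ip_true + rng.normal(0, sd),
                    ct_input_true + rng.normal(0, sd),
                    config.input_fraction,
                )
            )
    chip = pd.DataFrame(
        chip_rows,
        columns=[
            "sample_id",
            "antibody",
            "condition",
            "replicate_id",
            "ct_ip",
            "ct_input",
            "input_fraction",
        ],
    )

    luc_rows = []
    renilla_mean = 100.0
    firefly_unind_mean = 200.0
    for condition, firefly_mean in (
        ("uninduced", firefly_unind_mean),
        ("induced", firefly_unind_mean * config.true_fold_induction),
    ):
        for rep in range(1, config.luc_replicates + 1):
            luc_rows.append(
                (
                    "GAS_reporter",
                    condition,
                    rep,
                    firefly_mean * rng.lognormal(0, config.luc_cv),
                    renilla_mean * rng.lognormal(0, config.luc_cv),
                )
            )
    luc = pd.DataFrame(
        luc_rows,
        columns=["construct_id", "condition", "replicate_id", "firefly", "renilla"],
    )

    truth = GroundTruth(
        sites=pd.DataFrame(),
        assays={
            "true_expression_fold": fold,
            "true_fold_induction": config.true_fold_induction,
            **{
                f"true_percent_input_{ab}_{cond}": pct
                for (ab, cond), pct in config.true_percent_input.items()
            },
        },
    )
    return {"qpcr": qpcr, "chip": chip, "luciferase": luc}, truth


# ---------------------------------------------------------------------------
# Whole-dataset convenience
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimConfig, outdir: str | Path | None = None):
    """Generate genome, genes, sites (with sequences), assays and truth.

    When `outdir` is given, writes genome.fa, genes.gff3, genes.bed12,
    sites.bed, site_sequences.fa, the three assay TSVs, truth_sites.tsv and
    truth_assays.tsv — byte-identical for identical configs.
    """
    from .genomic import write_fasta, write_gene_models, write_sites

    genome, genes = simulate_genome_and_genes(config)
    sites, truth = plant_sites(config, genome, genes)
    sites, truth = plant_motifs(sites, config, truth)
    assay_tables, assay_truth = simulate_assays(config)
    truth.assays.update(assay_truth.assays)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(genome, outdir / "genome.fa")
        write_gene_models(genes, outdir / "genes.gff3", format="gff3")
        write_gene_models(genes, outdir / "genes.bed12", format="bed12")
        write_sites(sites, outdir / "sites.bed")
        write_fasta(
            {s.site_id: s.sequence for s in sites}, outdir / "site_sequences.fa"
        )
        truth.sites.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
        pd.Series(truth.assays, name="value").rename_axis("parameter").to_csv(
            outdir / "truth_assays.tsv", sep="\t"
        )
        for name, table in assay_tables.items():
            table.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    return genome, genes, sites, assay_tables, truth
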