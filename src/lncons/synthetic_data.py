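"""Self-contained two-genome fixture generator with known ground truth.

Emulates the study design the pipeline targets — two related species with
annotated protein-coding genes (PCGs) and lncRNAs, a whole-genome chain
alignment with planted conserved lncRNA loci, expression matrices with
planted co-expression modules, planted GO enrichments, divergent
(bidirectional) lncRNA-PCG pairs, and a four-stage temporal series with
planted monotone genes — so that every downstream stage can be tested
against a known truth without any external data.

Model sketch
------------
* Genomes: gene loci are laid out sequentially with randomized gaps on a
  configurable number of chromosomes; each planted conserved lncRNA locus
  in genome A gets a chain block mapping it (plus a flank) onto its genome
  B locus, a configurable fraction on the '-' strand of B. Non-conserved
  loci fall outside all chain blocks.
* Expression: a latent-factor model. Gene g in module m has
  ``x_gs = u_g * sqrt(c) * f_ms + eps`` with ``c = r / (1 - r)`` chosen so
  a pair of genes with loadings near 1 correlates at about the target
  within-module correlation ``r``. Planted lncRNA hubs get the maximal
  loading (u = 1); PCG loadings are drawn from ``loading_range``. Log-scale
  values are shifted by per-gene baselines and exponentiated to TPM-like
  positives; baselines are shared (with per-class jitter) between
  conserved partners, which induces the cross-species summary-expression
  correlation.
* Temporal series: planted "up" genes get log-scale stage means increasing
  by a fixed step per stage, "down" genes decreasing, others flat, with
  replicate noise of the configured standard deviation.
* GO: background term membership is Bernoulli at ``go_background_rate``;
  planted (term, module, fold) triples raise the membership probability by
  the stated fold inside the module.
* Conservation track: per-bin scores with planted class means, PCG exon >
  lncRNA exon > intergenic background.

All outputs are deterministic functions of ``config.seed``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .chain_liftover import Chain, ChainBlock
from .enrichment import GeneTermMap, InteractionScoreTable
from .genomic_io import AnnotationSet, ExpressionMatrix, TranscriptModel

# fixed stream ids so each component draws from an independent substream
_STREAM_GENOMES = 1
_STREAM_EXPR_A = 2
_STREAM_EXPR_B = 3
_STREAM_TEMPORAL = 4
_STREAM_GO = 5
_STREAM_TRACK = 6
_STREAM_INTERACT = 7


class SyntheticSizingError(ValueError):
    """Loci cannot be placed at the requested density."""


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic study; defaults mirror a small two-species
    brain-expression study design (sample counts close to the 80/66 human
    and rat samples of the motivating setting, four developmental stages,
    signed-network-recoverable module structure)."""

    seed: int = 0
    # genomes
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_pcg: int = 150
    n_lncrna: int = 40
    n_conserved_lnc: int = 20
    conserved_b_isoforms: int = 1  # B-side isoforms per conserved A locus
    conserved_minus_fraction: float = 0.3
    chain_flank: int = 500
    split_chains: bool = False  # emit 2-block chains with a gap
    # expression
    n_modules: int = 3
    module_size: int = 40
    n_module_lnc: int = 8  # conserved lncRNAs planted as module hubs
    within_module_cor: float = 0.55
    loading_range: tuple[float, float] = (0.5, 0.9)
    n_samples: int = 66
    noise_sd: float = 0.5
    baseline_mean: float = 2.0
    baseline_sd: float = 1.0
    cross_jitter_lnc: float | None = 1.3  # None: independent baselines
    cross_jitter_pcg: float | None = 0.8
    log_sd: float = 0.5  # per-gene log-scale spread of the dynamic part
    # temporal series (genome B)
    stages: tuple[str, ...] = ("W2", "W6", "W21", "W104")
    n_replicates_per_stage: int = 3
    n_monotone_up: int = 5
    n_monotone_down: int = 5
    temporal_step: float = 1.0  # log-TPM increment per stage
    # bidirectional promoter plants
    n_bidirectional: int = 3
    bidirectional_distances: tuple[int, ...] = (500, 2000, 2001)
    # GO plants
    n_go_terms: int = 50
    go_background_rate: float = 0.05
    enriched_terms: tuple[tuple[str, int, float], ...] = (
        ("GO:0007420", 0, 10.0),  # brain development
        ("GO:0007399", 1, 10.0),  # nervous system development
    )
    # distractor transcripts exercising the filter cascade (genome A)
    n_distractors_per_type: int = 2
    # conservation track
    cons_means: tuple[float, float, float] = (0.6, 0.4, 0.2)  # PCG/lnc/background
    cons_noise_sd: float = 0.05
    track_bin: int = 50

    def __post_init__(self) -> None:
        counts = [
            self.n_chroms, self.chrom_length, self.n_pcg, self.n_lncrna,
            self.n_conserved_lnc, self.n_modules, self.module_size,
            self.n_samples, self.n_monotone_up, self.n_monotone_down,
            self.n_bidirectional, self.n_go_terms,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.n_conserved_lnc > self.n_lncrna:
            raise ValueError("n_conserved_lnc cannot exceed n_lncrna")
        if self.n_bidirectional > self.n_conserved_lnc:
            raise ValueError("bidirectional plants must be conserved lncRNAs")
        if self.n_monotone_up + self.n_monotone_down > self.n_conserved_lnc:
            raise ValueError("monotone plants must fit in the conserved set")
        if self.n_module_lnc > self.n_conserved_lnc:
            raise ValueError("module lncRNA hubs must be conserved lncRNAs")
        if not 0 <= self.within_module_cor < 1:
            raise ValueError("within_module_cor must be in [0, 1)")
        if self.conserved_b_isoforms < 1:
            raise ValueError("conserved_b_isoforms must be >= 1")
        for term, module, fold in self.enriched_terms:
            if self.go_background_rate * fold > 1:
                raise ValueError(
                    f"fold {fold} for {term} makes membership probability > 1"
                )
            if module >= self.n_modules:
                raise ValueError(f"enriched term {term} targets missing module")

    @property
    def genome_sizes_a(self) -> dict[str, int]:
        return {f"chrA{i + 1}": self.chrom_length for i in range(self.n_chroms)}

    @property
    def genome_sizes_b(self) -> dict[str, int]:
        return {f"chrB{i + 1}": self.chrom_length for i in range(self.n_chroms)}


@dataclass
class SyntheticTruth:
    """Ground truth for every planted structure."""

    conserved_pairs: list[tuple[str, str]] = field(default_factory=list)
    module_assignment: dict[str, str] = field(default_factory=dict)
    trend_labels: dict[str, str] = field(default_factory=dict)
    bidirectional_pairs_a: list[tuple[str, str, int]] = field(default_factory=list)
    bidirectional_pairs_b: list[tuple[str, str, int]] = field(default_factory=list)
    enriched: list[tuple[str, str]] = field(default_factory=list)  # (module, term)
    lncrna_ids_a: list[str] = field(default_factory=list)
    lncrna_ids_b: list[str] = field(default_factory=list)
    pcg_ids_a: list[str] = field(default_factory=list)
    pcg_ids_b: list[str] = field(default_factory=list)
    pcg_orthologs: dict[str, str] = field(default_factory=dict)
    distractors_a: dict[str, str] = field(default_factory=dict)  # id -> kind

    def to_json(self, path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            data = json.load(fh)
        for key in ("conserved_pairs", "bidirectional_pairs_a",
                    "bidirectional_pairs_b", "enriched"):
            data[key] = [tuple(x) for x in data[key]]
        return cls(**data)


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def _make_exons(rng: np.random.Generator, start: int, n_exons: int,
                exon_range=(150, 300), intron_range=(100, 400)) -> list[tuple[int, int]]:
    exons = []
    pos = start
    for i in range(n_exons):
        length = int(rng.integers(*exon_range))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(*intron_range))
    return exons


class _GenomePlacer:
    """Sequential, gap-separated locus placement across chromosomes."""

    def __init__(self, genome_sizes: dict[str, int], rng: np.random.Generator,
                 margin: int = 10_000):
        self.sizes = genome_sizes
        self.rng = rng
        self.cursors = {c: margin for c in genome_sizes}
        self.chroms = sorted(genome_sizes)
        self._next = 0

    def place(self, length: int, gap_range=(3000, 8000)) -> tuple[str, int]:
        """Reserve *length* bases on the next chromosome (round-robin)."""
        for _ in range(len(self.chroms)):
            chrom = self.chroms[self._next % len(self.chroms)]
            self._next += 1
            start = self.cursors[chrom] + int(self.rng.integers(*gap_range))
            if start + length < self.sizes[chrom] - 1000:
                self.cursors[chrom] = start + length
                return chrom, start
        raise SyntheticSizingError(
            f"cannot place a {length}-base locus; genomes too dense"
        )


def generate_genomes(
    config: SyntheticConfig,
) -> tuple[AnnotationSet, AnnotationSet, list[Chain], SyntheticTruth]:
    """Build both genome annotations, the chain alignment, and the truth.

    Layout per genome: planted divergent lncRNA-PCG units, remaining
    conserved lncRNA loci, non-conserved lncRNAs, remaining PCGs, and (A
    only) the filter-cascade distractors. Each conserved locus gets one
    chain whose block(s) cover the locus plus ``chain_flank``.
    """
    rng = _rng(config, _STREAM_GENOMES)
    truth = SyntheticTruth()
    ann_a, ann_b = AnnotationSet(), AnnotationSet()
    chains: list[Chain] = []
    placer_a = _GenomePlacer(config.genome_sizes_a, rng)
    placer_b = _GenomePlacer(config.genome_sizes_b, rng)

    lnc_a_ids = [f"A_lnc{i:03d}" for i in range(config.n_lncrna)]
    pcg_a_ids = [f"A_pcg{i:03d}" for i in range(config.n_pcg)]
    lnc_b_ids = [f"B_lnc{i:03d}" for i in range(config.n_lncrna)]
    pcg_b_ids = [f"B_pcg{i:03d}" for i in range(config.n_pcg)]
    truth.lncrna_ids_a = list(lnc_a_ids)
    truth.pcg_ids_a = list(pcg_a_ids)
    truth.pcg_ids_b = list(pcg_b_ids)
    truth.pcg_orthologs = dict(zip(pcg_a_ids, pcg_b_ids))

    minus_flags = rng.random(config.n_conserved_lnc) < config.conserved_minus_fraction
    distances = [
        config.bidirectional_distances[i % len(config.bidirectional_distances)]
        for i in range(config.n_bidirectional)
    ]

    def add_lnc(ann: AnnotationSet, tid: str, chrom: str, start: int,
                strand: str, exon_template=None) -> TranscriptModel:
        if exon_template is None:
            exons = _make_exons(rng, start, int(rng.integers(2, 4)))
        else:
            exons = [(start + s, start + e) for s, e in exon_template]
        t = TranscriptModel(tid, tid.rsplit("_t", 1)[0] if "_t" in tid else tid,
                            chrom, strand, exons, biotype="lncRNA")
        ann.add(t)
        return t

    def add_pcg(ann: AnnotationSet, tid: str, chrom: str, start: int,
                strand: str) -> TranscriptModel:
        exons = _make_exons(rng, start, int(rng.integers(3, 6)))
        t = TranscriptModel(tid, tid, chrom, strand, exons, biotype="protein_coding")
        ann.add(t)
        return t

    def add_chain(idx: int, a_t: TranscriptModel, b_hull: tuple[str, int, int],
                  minus: bool) -> None:
        flank = config.chain_flank
        b_chrom, b_start, b_end = b_hull
        span = max(a_t.end - a_t.start, b_end - b_start) + 2 * flank
        t_start = a_t.start - flank
        q_fwd_start = b_start - flank
        q_size = config.genome_sizes_b[b_chrom]
        # an optional split puts a gap inside the flank, never in the locus
        gap = 100 if (config.split_chains and flank > 300) else 0
        span_total = span + gap
        if gap:
            first = 200
            blocks = [ChainBlock(first, gap, gap),
                      ChainBlock(span_total - first - gap, 0, 0)]
        else:
            blocks = [ChainBlock(span_total, 0, 0)]
        t_end = t_start + span_total
        if minus:
            q_start = q_size - (q_fwd_start + span_total)
            q_end = q_size - q_fwd_start
            q_strand = "-"
        else:
            q_start, q_end, q_strand = q_fwd_start, q_fwd_start + span_total, "+"
        chains.append(
            Chain(
                score=1000.0 + idx,
                t_name=a_t.chrom, t_size=config.genome_sizes_a[a_t.chrom],
                t_strand="+", t_start=t_start, t_end=t_end,
                q_name=b_chrom, q_size=q_size, q_strand=q_strand,
                q_start=q_start, q_end=q_end,
                blocks=blocks, chain_id=str(idx + 1),
            )
        )

    b_lnc_cursor = 0  # index into lnc_b_ids
    # 1) divergent bidirectional units (conserved lncRNAs 0..n_bidirectional-1)
    for i in range(config.n_bidirectional):
        d = distances[i]
        lnc_len_exons = _make_exons(rng, 0, 2)
        lnc_len = lnc_len_exons[-1][1]
        pcg_reserve = 2500
        unit_len = lnc_len + max(d, 0) + pcg_reserve
        chrom_a, start_a = placer_a.place(unit_len)
        a_lnc = add_lnc(ann_a, f"{lnc_a_ids[i]}_t1", chrom_a, start_a, "-",
                        exon_template=lnc_len_exons)
        a_pcg = add_pcg(ann_a, pcg_a_ids[i], chrom_a, a_lnc.end + d, "+")
        truth.bidirectional_pairs_a.append((a_lnc.transcript_id, a_pcg.transcript_id, d))
        # mirrored unit in B
        chrom_b, start_b = placer_b.place(unit_len)
        b_lnc = add_lnc(ann_b, f"{lnc_b_ids[b_lnc_cursor]}_t1", chrom_b, start_b, "-",
                        exon_template=lnc_len_exons)
        b_pcg = add_pcg(ann_b, pcg_b_ids[i], chrom_b, b_lnc.end + d, "+")
        truth.bidirectional_pairs_b.append((b_lnc.transcript_id, b_pcg.transcript_id, d))
        truth.conserved_pairs.append((a_lnc.transcript_id, b_lnc.transcript_id))
        add_chain(i, a_lnc, (chrom_b, b_lnc.start, b_lnc.end), bool(minus_flags[i]))
        b_lnc_cursor += 1

    # 2) remaining conserved lncRNA loci
    for i in range(config.n_bidirectional, config.n_conserved_lnc):
        template = _make_exons(rng, 0, int(rng.integers(2, 4)))
        lnc_len = template[-1][1]
        k = config.conserved_b_isoforms
        if (k - 1) * 50 >= lnc_len:
            raise SyntheticSizingError("too many B isoforms for the locus length")
        chrom_a, start_a = placer_a.place(lnc_len)
        a_lnc = add_lnc(ann_a, f"{lnc_a_ids[i]}_t1", chrom_a, start_a, "-"
                        if rng.random() < 0.5 else "+", exon_template=template)
        b_hull_len = lnc_len + (k - 1) * 50
        chrom_b, start_b = placer_b.place(b_hull_len)
        strand_b = "-" if minus_flags[i] else "+"
        gene_b = lnc_b_ids[b_lnc_cursor]
        for j in range(k):
            b_lnc = add_lnc(ann_b, f"{gene_b}_t{j + 1}", chrom_b,
                            start_b + j * 50, strand_b, exon_template=template)
            truth.conserved_pairs.append((a_lnc.transcript_id, b_lnc.transcript_id))
        add_chain(i, a_lnc, (chrom_b, start_b, start_b + b_hull_len),
                  bool(minus_flags[i]))
        b_lnc_cursor += 1

    # 3) non-conserved lncRNAs (both genomes, outside every chain)
    for i in range(config.n_conserved_lnc, config.n_lncrna):
        for ann, ids, placer in ((ann_a, lnc_a_ids, placer_a),
                                 (ann_b, lnc_b_ids, placer_b)):
            template = _make_exons(rng, 0, int(rng.integers(2, 4)))
            chrom, start = placer.place(template[-1][1])
            tid = ids[i] if ann is ann_a else lnc_b_ids[i]
            add_lnc(ann, f"{tid}_t1", chrom, start,
                    "+" if rng.random() < 0.5 else "-", exon_template=template)

    # 4) remaining PCGs
    for i in range(config.n_bidirectional, config.n_pcg):
        chrom, start = placer_a.place(2500)
        add_pcg(ann_a, pcg_a_ids[i], chrom, start, "+" if rng.random() < 0.5 else "-")
        chrom, start = placer_b.place(2500)
        add_pcg(ann_b, pcg_b_ids[i], chrom, start, "+" if rng.random() < 0.5 else "-")

    truth.lncrna_ids_a = [f"{g}_t1" for g in lnc_a_ids]
    truth.lncrna_ids_b = sorted(
        t.transcript_id for t in ann_b if t.biotype == "lncRNA"
    )

    # 5) filter-cascade distractors, genome A only
    plain_pcgs = [pcg_a_ids[i] for i in range(config.n_bidirectional, config.n_pcg)]
    for j in range(config.n_distractors_per_type):
        # too short: spliced length < 200
        chrom, start = placer_a.place(400)
        t = TranscriptModel(f"A_bad_short{j}", f"A_bad_short{j}", chrom, "+",
                            [(start, start + 70), (start + 170, start + 240)])
        ann_a.add(t)
        truth.distractors_a[t.transcript_id] = "too_short"
        # high coding potential
        template = _make_exons(rng, 0, 2)
        chrom, start = placer_a.place(template[-1][1])
        t = TranscriptModel(f"A_bad_coding{j}", f"A_bad_coding{j}", chrom, "+",
                            [(start + s, start + e) for s, e in template])
        ann_a.add(t)
        truth.distractors_a[t.transcript_id] = "coding"
        # not expressed
        template = _make_exons(rng, 0, 2)
        chrom, start = placer_a.place(template[-1][1])
        t = TranscriptModel(f"A_bad_silent{j}", f"A_bad_silent{j}", chrom, "-",
                            [(start + s, start + e) for s, e in template])
        ann_a.add(t)
        truth.distractors_a[t.transcript_id] = "not_expressed"
        # antisense of a PCG
        if plain_pcgs:
            host = ann_a[plain_pcgs[j % len(plain_pcgs)]]
            flipped = "-" if host.strand == "+" else "+"
            t = TranscriptModel(f"A_bad_anti{j}", f"A_bad_anti{j}", host.chrom,
                                flipped, list(host.exons[:2]))
            ann_a.add(t)
            truth.distractors_a[t.transcript_id] = "antisense"
        # single exon, no overlap
        chrom, start = placer_a.place(400)
        t = TranscriptModel(f"A_bad_single{j}", f"A_bad_single{j}", chrom, "+",
                            [(start, start + 400)])
        ann_a.add(t)
        truth.distractors_a[t.transcript_id] = "single_exon"

    # planted co-expression modules over genome A features; the hub lncRNAs
    # are the tail of the conserved set so some conserved families carry no
    # co-expression evidence (temporal/bidirectional plants use the head)
    module_lnc = [
        truth.lncrna_ids_a[i]
        for i in range(config.n_conserved_lnc - config.n_module_lnc,
                       config.n_conserved_lnc)
    ]
    per_module_lnc: dict[int, list[str]] = {m: [] for m in range(config.n_modules)}
    for i, lnc in enumerate(module_lnc):
        per_module_lnc[i % config.n_modules].append(lnc)
    pcg_pool = list(pcg_a_ids)
    cursor = 0
    for m in range(config.n_modules):
        members = list(per_module_lnc[m])
        need = config.module_size - len(members)
        if cursor + need > len(pcg_pool):
            raise SyntheticSizingError("not enough PCGs to fill the planted modules")
        members.extend(pcg_pool[cursor:cursor + need])
        cursor += need
        for g in members:
            truth.module_assignment[g] = f"P{m + 1}"

    # planted temporal trends on conserved genome-B lncRNAs (first isoforms)
    conserved_b_first = []
    seen_gene = set()
    for _, b in truth.conserved_pairs:
        gene = b.rsplit("_t", 1)[0]
        if gene not in seen_gene:
            seen_gene.add(gene)
            conserved_b_first.append(b)
    for i, b in enumerate(conserved_b_first):
        if i < config.n_monotone_up:
            truth.trend_labels[b] = "up"
        elif i < config.n_monotone_up + config.n_monotone_down:
            truth.trend_labels[b] = "down"
    for t in truth.lncrna_ids_b:
        truth.trend_labels.setdefault(t, "none")

    truth.enriched = [(f"P{m + 1}", term) for term, m, _ in config.enriched_terms]
    return ann_a, ann_b, chains, truth


def generate_coding_scores(
    config: SyntheticConfig, annotations: AnnotationSet, truth: SyntheticTruth,
) -> dict[str, float]:
    """Coding-potential scores: high for PCGs and 'coding' distractors, low
    for everything else."""
    rng = _rng(config, _STREAM_GENOMES + 100)
    scores = {}
    for t in sorted(annotations, key=lambda t: t.transcript_id):
        kind = truth.distractors_a.get(t.transcript_id)
        if t.biotype == "protein_coding" or kind == "coding":
            scores[t.transcript_id] = float(rng.uniform(0.6, 0.95))
        else:
            scores[t.transcript_id] = float(rng.uniform(0.02, 0.4))
    return scores


def _baselines(config: SyntheticConfig, truth: SyntheticTruth,
               rng: np.random.Generator) -> tuple[dict[str, float], dict[str, float]]:
    """Per-gene log-scale baselines, shared with jitter across conserved
    partners and PCG orthologs."""
    base_a: dict[str, float] = {}
    base_b: dict[str, float] = {}

    def fresh() -> float:
        return float(rng.normal(config.baseline_mean, config.baseline_sd))

    for tid in truth.lncrna_ids_a + list(truth.distractors_a):
        base_a[tid] = fresh()
    for tid in truth.pcg_ids_a:
        base_a[tid] = fresh()
    for a_id, b_id in truth.conserved_pairs:
        j = config.cross_jitter_lnc
        base_b[b_id] = fresh() if j is None else base_a[a_id] + float(rng.normal(0, j))
    for a_id, b_id in truth.pcg_orthologs.items():
        j = config.cross_jitter_pcg
        base_b[b_id] = fresh() if j is None else base_a[a_id] + float(rng.normal(0, j))
    for tid in truth.lncrna_ids_b:
        base_b.setdefault(tid, fresh())
    return base_a, base_b


def generate_expression(
    config: SyntheticConfig,
    annotations: AnnotationSet,
    truth: SyntheticTruth,
    species: str = "A",
) -> ExpressionMatrix:
    """TPM-like expression with the planted module structure (genome A) or
    baseline-only structure (genome B)."""
    if config.n_samples < 3:
        raise ValueError("n_samples must be >= 3 (correlation undefined below)")
    rng = _rng(config, _STREAM_EXPR_A if species == "A" else _STREAM_EXPR_B)
    base_rng = _rng(config, _STREAM_EXPR_A + 50)
    base_a, base_b = _baselines(config, truth, base_rng)
    baselines = base_a if species == "A" else base_b
    features = sorted(t.transcript_id for t in annotations)
    n = config.n_samples
    factors = rng.normal(size=(config.n_modules, n))
    module_index = {f"P{m + 1}": m for m in range(config.n_modules)}
    lnc_set = set(truth.lncrna_ids_a if species == "A" else truth.lncrna_ids_b)
    # loadings per module gene: planted lncRNA hubs get the maximum (1.0);
    # the factor scale is calibrated per module so the expected mean
    # pairwise within-module correlation equals within_module_cor
    loadings: dict[str, float] = {}
    lam_scale: dict[str, float] = {}
    if species == "A" and config.within_module_cor > 0:
        per_module: dict[str, list[str]] = {}
        for tid in features:
            label = truth.module_assignment.get(tid)
            if label is not None:
                per_module.setdefault(label, []).append(tid)
                loadings[tid] = (
                    1.0 if tid in lnc_set else float(rng.uniform(*config.loading_range))
                )
        for label, members in per_module.items():
            u = np.array([loadings[m] for m in members])
            lam_scale[label] = _calibrate_factor_scale(u, config.within_module_cor)
    values = np.empty((len(features), n))
    for i, tid in enumerate(features):
        sd_eps = config.noise_sd if config.noise_sd > 0 else 0.0
        eps = rng.normal(0, sd_eps, size=n)
        x = eps.copy()
        label = truth.module_assignment.get(tid) if species == "A" else None
        if label is not None and label in lam_scale:
            lam = (config.noise_sd or 1.0) * loadings[tid] * lam_scale[label]
            x = lam * factors[module_index[label]] + eps
        sd = x.std()
        if sd > 0:
            x = x / sd * config.log_sd
        mu = baselines.get(tid, config.baseline_mean)
        values[i] = np.exp(mu + x)
        kind = truth.distractors_a.get(tid)
        if species == "A" and kind == "not_expressed":
            values[i] = 0.0
    samples = [f"{species}_s{j:02d}" for j in range(n)]
    meta = {s: {"species": species} for s in samples}
    return ExpressionMatrix(
        pd.DataFrame(values, index=features, columns=samples), meta
    )


def _calibrate_factor_scale(u: np.ndarray, target: float) -> float:
    """Scale s such that the mean pairwise correlation of x_g = s*u_g*f + eps
    (unit-variance f and eps) over the given loadings equals *target*.

    cor(x_i, x_j) = s^2 u_i u_j / sqrt((s^2 u_i^2 + 1)(s^2 u_j^2 + 1)),
    which is monotone increasing in s; solved by bisection.
    """
    if len(u) < 2:
        return float(np.sqrt(target / (1 - target)))

    iu, ju = np.triu_indices(len(u), 1)

    def mean_cor(s: float) -> float:
        s2 = s * s
        num = s2 * u[iu] * u[ju]
        den = np.sqrt((s2 * u[iu] ** 2 + 1) * (s2 * u[ju] ** 2 + 1))
        return float(np.mean(num / den))

    lo, hi = 0.0, 1.0
    while mean_cor(hi) < target:
        hi *= 2
        if hi > 1e6:
            return hi
    for _ in range(60):
        mid = (lo + hi) / 2
        if mean_cor(mid) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def generate_temporal(
    config: SyntheticConfig, truth: SyntheticTruth
) -> ExpressionMatrix:
    """Stage-labelled genome-B lncRNA expression with planted monotone
    trends: log-scale stage means move by ``temporal_step`` per stage for
    'up'/'down' genes and stay flat otherwise."""
    if len(config.stages) < 2:
        raise ValueError("need >= 2 stages")
    if config.n_replicates_per_stage < 1:
        raise ValueError("need >= 1 replicate per stage")
    rng = _rng(config, _STREAM_TEMPORAL)
    features = sorted(truth.lncrna_ids_b)
    n_stage = len(config.stages)
    samples, meta = [], {}
    for s_idx, stage in enumerate(config.stages):
        for rep in range(config.n_replicates_per_stage):
            sid = f"B_{stage}_r{rep + 1}"
            samples.append(sid)
            meta[sid] = {"species": "B", "stage": stage}
    values = np.empty((len(features), len(samples)))
    for i, tid in enumerate(features):
        mu = config.baseline_mean
        trend = truth.trend_labels.get(tid, "none")
        col = 0
        for s_idx in range(n_stage):
            centered = s_idx - (n_stage - 1) / 2.0
            if trend == "up":
                level = mu + centered * config.temporal_step
            elif trend == "down":
                level = mu - centered * config.temporal_step
            else:
                level = mu
            for _ in range(config.n_replicates_per_stage):
                values[i, col] = np.exp(level + rng.normal(0, config.noise_sd))
                col += 1
    return ExpressionMatrix(
        pd.DataFrame(values, index=features, columns=samples), meta
    )


def generate_go(config: SyntheticConfig, truth: SyntheticTruth) -> GeneTermMap:
    """Gene->GO-term map over the genome-A PCG universe with planted
    module enrichments."""
    rng = _rng(config, _STREAM_GO)
    universe = sorted(truth.pcg_ids_a)
    planted = {term: (m, fold) for term, m, fold in config.enriched_terms}
    terms = sorted(set(planted) | {f"GO:{7000000 + i}" for i in range(config.n_go_terms)})
    module_of = truth.module_assignment
    term_genes: dict[str, set[str]] = {}
    for term in terms:
        genes = set()
        target = planted.get(term)
        for g in universe:
            p = config.go_background_rate
            if target is not None and module_of.get(g) == f"P{target[0] + 1}":
                p = min(1.0, config.go_background_rate * target[1])
            if rng.random() < p:
                genes.add(g)
        term_genes[term] = genes
    names = {"GO:0007420": "brain development",
             "GO:0007399": "nervous system development"}
    return GeneTermMap(term_genes=term_genes, universe=set(universe),
                       term_names={t: names.get(t, t) for t in terms})


def generate_interactions(
    config: SyntheticConfig, truth: SyntheticTruth, go_map: GeneTermMap
) -> InteractionScoreTable:
    """lncRNA-protein interaction scores (0-100): lncRNAs score high with
    the planted enriched-term genes of their own module, low elsewhere."""
    rng = _rng(config, _STREAM_INTERACT)
    planted_genes: dict[str, set[str]] = {}
    for module, term in truth.enriched:
        planted_genes.setdefault(module, set()).update(
            go_map.term_genes.get(term, set())
        )
    scores: dict[tuple[str, str], float] = {}
    module_members: dict[str, list[str]] = {}
    for g, m in truth.module_assignment.items():
        module_members.setdefault(m, []).append(g)
    lnc_set = set(truth.lncrna_ids_a)
    for module in sorted(module_members):
        members = sorted(module_members[module])
        lncs = [g for g in members if g in lnc_set]
        pcgs = [g for g in members if g not in lnc_set]
        hot = planted_genes.get(module, set())
        for lnc in lncs:
            for pcg in pcgs:
                if pcg in hot:
                    scores[(lnc, pcg)] = float(rng.uniform(55, 95))
                else:
                    scores[(lnc, pcg)] = float(rng.uniform(5, 50))
    return InteractionScoreTable(scores=scores)


def _merge_intervals(intervals: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    if not intervals:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    arr = np.array(merged, dtype=np.int64)
    return arr[:, 0], arr[:, 1]


def _covers(merged: tuple[np.ndarray, np.ndarray], pos: int) -> bool:
    starts, ends = merged
    i = int(np.searchsorted(starts, pos, side="right")) - 1
    return i >= 0 and pos < ends[i]


def generate_conservation_track(
    config: SyntheticConfig, annotations: AnnotationSet
) -> dict[str, np.ndarray]:
    """Per-base conservation scores as bedGraph-style interval arrays.

    PCG exon bases, lncRNA exon bases and intergenic background get their
    configured mean scores (PCG taking priority where classes overlap),
    with per-bin Gaussian noise clipped to [0, 1].
    """
    rng = _rng(config, _STREAM_TRACK)
    mean_pcg, mean_lnc, mean_bg = config.cons_means
    sizes = {}
    for t in annotations:
        sizes.setdefault(t.chrom, config.chrom_length)
        sizes[t.chrom] = max(sizes[t.chrom], t.end + 10_000)
    # exon class masks per chromosome
    out: dict[str, np.ndarray] = {}
    for chrom in sorted(sizes):
        length = sizes[chrom]
        boundaries = {0, length}
        pcg_iv, lnc_iv = [], []
        for t in annotations:
            if t.chrom != chrom:
                continue
            target = pcg_iv if t.biotype == "protein_coding" else lnc_iv
            if t.biotype in ("protein_coding", "lncRNA"):
                for s, e in t.exons:
                    target.append((s, e))
                    boundaries.update((s, e))
        cuts = sorted(boundaries)
        pcg_merged = _merge_intervals(pcg_iv)
        lnc_merged = _merge_intervals(lnc_iv)

        def klass(pos: int) -> float:
            if _covers(pcg_merged, pos):
                return mean_pcg
            if _covers(lnc_merged, pos):
                return mean_lnc
            return mean_bg

        rows: list[tuple[int, int, float]] = []
        for a, b in zip(cuts[:-1], cuts[1:]):
            mean = klass(a)
            pos = a
            while pos < b:
                end = min(pos + config.track_bin, b)
                rows.append((pos, end, mean))
                pos = end
        arr = np.array(rows, dtype=[("start", "i8"), ("end", "i8"), ("value", "f8")])
        if config.cons_noise_sd > 0:
            arr["value"] += rng.normal(0, config.cons_noise_sd, size=arr.size)
        arr["value"] = np.clip(arr["value"], 0.0, 1.0)
        out[chrom] = arr
    return out
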