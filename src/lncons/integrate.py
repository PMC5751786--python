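"""Evidence integration across the three annotation streams and the
end-to-end pipeline driver.

Each conserved lncRNA family is checked for three kinds of functional
evidence — membership in a GO-enriched co-expression module (plus
interaction support), a divergent (bidirectional) promoter shared with a
protein-coding gene, and a monotone temporal trend of a cross-species
partner — OR-ed over the family's member transcripts. The coverage summary
reports the annotated fraction and the Venn partition of the evidence
combinations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from . import __version__
from .chain_liftover import ChainIndex, lift_annotations, read_chain, write_chain
from .coexpression import (
    NetworkConfig,
    compare_connectivity,
    detect_modules,
    module_connectivity,
    signed_adjacency,
    topological_overlap,
)
from .conservation_score import (
    ScoreTrack,
    compare_groups,
    interval_score,
    sample_random_regions,
    score_transcripts,
)
from .enrichment import (
    GeneTermMap,
    InteractionScoreTable,
    annotate_lncrnas,
    enrich_partition,
    results_to_frame,
)
from .genomic_io import (
    AnnotationSet,
    read_expression,
    read_gtf,
    write_bedgraph,
    write_expression,
    write_gtf,
)
from .lncrna_filter import (
    FilterParams,
    LncRnaFamily,
    filter_lncrna_candidates,
    family_lookup,
    group_families,
)
from .neighborhood import (
    BidirectionalPair,
    conserved_neighbor_check,
    find_bidirectional_pairs,
    pairs_to_frame as bidir_frame,
)
from .orthology import (
    correlation_by_class,
    pair_conserved,
    pairs_to_frame,
    summarize_conservation,
)
from .synthetic_data import (
    SyntheticConfig,
    generate_coding_scores,
    generate_conservation_track,
    generate_expression,
    generate_genomes,
    generate_go,
    generate_interactions,
    generate_temporal,
)
from .temporal import classify_trends, map_trends_to_partner

logger = logging.getLogger(__name__)

EVIDENCE_KINDS = ("coexpression", "bidirectional", "temporal")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class FamilyEvidence:
    family_id: str
    coexpression: bool = False
    bidirectional: bool = False
    temporal: bool = False
    coexpression_terms: list[str] = field(default_factory=list)
    bidirectional_partners: list[str] = field(default_factory=list)
    temporal_trend: str = ""

    @property
    def annotated(self) -> bool:
        return self.coexpression or self.bidirectional or self.temporal

    def flags(self) -> frozenset[str]:
        return frozenset(
            kind for kind in EVIDENCE_KINDS if getattr(self, kind)
        )


@dataclass
class EvidenceTable:
    families: list[FamilyEvidence]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.families:
            rows.append(
                {
                    "family_id": f.family_id,
                    "coexpression": f.coexpression,
                    "bidirectional": f.bidirectional,
                    "temporal": f.temporal,
                    "annotated": f.annotated,
                    "coexpression_terms": ";".join(f.coexpression_terms),
                    "bidirectional_partners": ";".join(f.bidirectional_partners),
                    "temporal_trend": f.temporal_trend,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class CoverageSummary:
    n_families: int
    n_annotated: int
    fraction: float
    venn: dict[str, int]  # "+"-joined sorted evidence kinds -> count


def collect_evidence(
    families: Iterable[LncRnaFamily],
    lnc_annotations: Iterable,  # enrichment.LncRnaAnnotation
    bidir_pairs: Iterable[BidirectionalPair],
    trend_table: pd.DataFrame,
    strict: bool = True,
) -> EvidenceTable:
    """Family-level OR of member-level evidence.

    *trend_table* is the output of ``temporal.map_trends_to_partner``
    (genome-A transcripts with partner trends); trends ``up``, ``down`` and
    ``mixed`` count as temporal evidence. With ``strict``, evidence
    referencing a transcript that belongs to no family raises.
    """
    families = list(families)
    fam_of = family_lookup(families)

    def family_for(tid: str, source: str) -> str | None:
        fam = fam_of.get(tid)
        if fam is None and strict:
            raise PipelineError(
                f"{source} evidence references {tid}, which is in no family"
            )
        return fam

    ev = {f.family_id: FamilyEvidence(family_id=f.family_id) for f in families}
    for ann in lnc_annotations:
        fam = family_for(ann.lncrna_id, "coexpression")
        if fam is None:
            continue
        rec = ev[fam]
        rec.coexpression = True
        if ann.term_id not in rec.coexpression_terms:
            rec.coexpression_terms.append(ann.term_id)
    for pair in bidir_pairs:
        fam = family_for(pair.lncrna_id, "bidirectional")
        if fam is None:
            continue
        rec = ev[fam]
        rec.bidirectional = True
        if pair.pcg_id not in rec.bidirectional_partners:
            rec.bidirectional_partners.append(pair.pcg_id)
    for _, row in trend_table.iterrows():
        if row["trend"] not in ("up", "down", "mixed"):
            continue
        fam = family_for(row["a_transcript_id"], "temporal")
        if fam is None:
            continue
        rec = ev[fam]
        rec.temporal = True
        rec.temporal_trend = (
            row["trend"] if not rec.temporal_trend else "mixed"
            if rec.temporal_trend != row["trend"] else rec.temporal_trend
        )
    return EvidenceTable(families=[ev[f.family_id] for f in families])


def coverage_summary(table: EvidenceTable) -> CoverageSummary:
    """Annotated fraction and the exact Venn partition over the seven
    non-empty evidence combinations."""
    if not table.families:
        raise ValueError("empty evidence table")
    venn = {
        "+".join(combo): 0
        for r in (1, 2, 3)
        for combo in combinations(EVIDENCE_KINDS, r)
    }
    n_annotated = 0
    for fam in table.families:
        flags = fam.flags()
        if not flags:
            continue
        n_annotated += 1
        key = "+".join(k for k in EVIDENCE_KINDS if k in flags)
        venn[key] += 1
    return CoverageSummary(
        n_families=len(table.families),
        n_annotated=n_annotated,
        fraction=n_annotated / len(table.families),
        venn=venn,
    )


# ---------------------------------------------------------------------------
# end-to-end driver


@dataclass
class PipelineParams:
    """Analysis parameters of a pipeline run (study thresholds as defaults)."""

    min_length: int = 200
    max_coding: float = 0.5
    min_match: float = 0.95
    min_overlap: int = 1
    beta: int | None = 6
    min_module_size: int = 30
    tom_edge_cutoff: float = 0.2
    cut_height: float = 0.9
    alpha: float = 0.05
    correction: str = "none"
    max_dist: int = 2000
    min_ratio: float = 1.0
    n_random_regions: int = 100
    summary_stat: str = "median"


def simulate_inputs(config: SyntheticConfig, outdir: Path) -> dict:
    """Generate and write the full synthetic input bundle; returns the
    in-memory objects keyed by input name."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ann_a, ann_b, chains, truth = generate_genomes(config)
    scores_a = generate_coding_scores(config, ann_a, truth)
    scores_b = generate_coding_scores(config, ann_b, truth)
    expr_a = generate_expression(config, ann_a, truth, species="A")
    expr_b = generate_expression(config, ann_b, truth, species="B")
    temporal = generate_temporal(config, truth)
    go_map = generate_go(config, truth)
    interactions = generate_interactions(config, truth, go_map)
    track = generate_conservation_track(config, ann_a)

    write_gtf(ann_a, outdir / "genomeA.gtf")
    write_gtf(ann_b, outdir / "genomeB.gtf")
    write_chain(chains, outdir / "a_to_b.chain")
    for name, scores in (("coding_scores_a.tsv", scores_a),
                         ("coding_scores_b.tsv", scores_b)):
        pd.DataFrame(
            sorted(scores.items()), columns=["transcript_id", "score"]
        ).to_csv(outdir / name, sep="\t", index=False, float_format="%.6g")
    write_expression(expr_a, outdir / "expression_a.tsv", outdir / "samples_a.tsv")
    write_expression(expr_b, outdir / "expression_b.tsv", outdir / "samples_b.tsv")
    write_expression(temporal, outdir / "expression_temporal_b.tsv",
                     outdir / "samples_temporal_b.tsv")
    rows = [
        {"gene_id": g, "term_id": t, "term_name": go_map.term_names.get(t, t)}
        for t in sorted(go_map.term_genes)
        for g in sorted(go_map.term_genes[t])
    ]
    pd.DataFrame(rows, columns=["gene_id", "term_id", "term_name"]).to_csv(
        outdir / "gene_go.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [
            {"lncrna_id": l, "gene_id": g, "score": s}
            for (l, g), s in sorted(interactions.scores.items())
        ]
    ).to_csv(outdir / "interactions.tsv", sep="\t", index=False,
             float_format="%.6g")
    write_bedgraph(
        {c: [(r["start"], r["end"], r["value"]) for r in arr]
         for c, arr in track.items()},
        outdir / "conservation_a.bedGraph",
    )
    pd.DataFrame(
        sorted(truth.pcg_orthologs.items()), columns=["a_gene_id", "b_gene_id"]
    ).to_csv(outdir / "pcg_orthologs.tsv", sep="\t", index=False)
    truth.to_json(outdir / "truth.json")
    return {
        "ann_a": ann_a, "ann_b": ann_b, "chains": chains, "truth": truth,
        "scores_a": scores_a, "scores_b": scores_b,
        "expr_a": expr_a, "expr_b": expr_b, "temporal": temporal,
        "go_map": go_map, "interactions": interactions, "track": track,
    }


def run_pipeline(
    outdir,
    simulate: SyntheticConfig | None = None,
    inputs: Mapping[str, str] | None = None,
    params: PipelineParams | None = None,
    genome_sizes_a: Mapping[str, int] | None = None,
) -> dict:
    """Run the full analysis and write every intermediate table plus a JSON
    manifest. Returns a dict of in-memory results.

    Either *simulate* (a SyntheticConfig) or *inputs* (a mapping of input
    names to file paths: gtf_a, ref_gtf_a, gtf_b, ref_gtf_b, scores_a,
    scores_b, expr_a, expr_b, chain, go, temporal_expr, temporal_meta,
    orthologs, track) must be provided.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = params or PipelineParams()

    def require(name: str, stage: str):
        assert inputs is not None
        if name not in inputs:
            raise PipelineError(
                f"stage {stage}: required input {name!r} missing from config"
            )
        return inputs[name]

    if simulate is not None:
        data = simulate_inputs(simulate, outdir / "inputs")
        ann_a, ann_b = data["ann_a"], data["ann_b"]
        ref_a = ann_a.by_biotype("protein_coding")
        ref_b = ann_b.by_biotype("protein_coding")
        chains = data["chains"]
        scores_a, scores_b = data["scores_a"], data["scores_b"]
        expr_a, expr_b = data["expr_a"], data["expr_b"]
        temporal_expr = data["temporal"]
        go_map = data["go_map"]
        interactions = data["interactions"]
        track = ScoreTrack(data["track"])
        orthologs = data["truth"].pcg_orthologs
        sizes_a = simulate.genome_sizes_a
        seed = simulate.seed
    elif inputs is not None:
        ann_a = read_gtf(require("gtf_a", "filter"))
        ref_a = read_gtf(require("ref_gtf_a", "filter"))
        ann_b = read_gtf(require("gtf_b", "filter"))
        ref_b = read_gtf(require("ref_gtf_b", "filter"))
        scores_a = pd.read_csv(require("scores_a", "filter"), sep="\t",
                               index_col=0)["score"].to_dict()
        scores_b = pd.read_csv(require("scores_b", "filter"), sep="\t",
                               index_col=0)["score"].to_dict()
        expr_a = read_expression(require("expr_a", "filter"))
        expr_b = read_expression(require("expr_b", "filter"))
        chains = read_chain(require("chain", "liftover"))
        temporal_expr = read_expression(
            require("temporal_expr", "temporal"),
            require("temporal_meta", "temporal"),
        )
        go_map = None  # built after the universe is known
        interactions = None
        track = ScoreTrack.from_bedgraph(require("track", "conscore"))
        ortho_df = pd.read_csv(require("orthologs", "bidir"), sep="\t")
        orthologs = dict(zip(ortho_df["a_gene_id"], ortho_df["b_gene_id"]))
        sizes_a = dict(genome_sizes_a or {})
        seed = 0
    else:
        raise PipelineError("stage setup: neither simulate nor inputs provided")

    results: dict = {}

    # --- filter ---
    filter_params = FilterParams(
        min_length=params.min_length, max_coding_potential=params.max_coding
    )
    kept_a, report_a = filter_lncrna_candidates(
        list(ann_a), scores_a, expr_a, ref_a, filter_params
    )
    kept_b, report_b = filter_lncrna_candidates(
        list(ann_b), scores_b, expr_b, ref_b, filter_params
    )
    report_a.to_frame().to_csv(outdir / "filter_report_a.tsv", sep="\t",
                               index=False, float_format="%.6g")
    report_b.to_frame().to_csv(outdir / "filter_report_b.tsv", sep="\t",
                               index=False, float_format="%.6g")
    families_a = group_families(kept_a, prefix="FAMA")
    pd.DataFrame(
        [
            {"family_id": f.family_id, "chrom": f.span.chrom,
             "start": f.span.start, "end": f.span.end, "strand": f.strand,
             "members": ";".join(sorted(f.member_transcript_ids))}
            for f in families_a
        ]
    ).to_csv(outdir / "families_a.tsv", sep="\t", index=False)
    results["kept_a"], results["kept_b"] = kept_a, kept_b
    results["families_a"] = families_a

    # --- liftover + pairing ---
    index = ChainIndex(chains)
    lifted = lift_annotations(kept_a, index, min_match=params.min_match)
    pd.DataFrame(
        [
            {"transcript_id": tid, "status": r.status,
             "chrom": r.mapped.chrom if r.mapped else "",
             "start": r.mapped.start if r.mapped else -1,
             "end": r.mapped.end if r.mapped else -1,
             "match_fraction": round(r.match_fraction, 6), "chain_id": r.chain_id}
            for tid, r in sorted(lifted.items())
        ]
    ).to_csv(outdir / "lifted_a.tsv", sep="\t", index=False)
    b_lnc_set = AnnotationSet(t for t in kept_b if t.biotype == "lncRNA")
    pairs = pair_conserved(lifted, b_lnc_set, min_overlap=params.min_overlap)
    pairs_to_frame(pairs).to_csv(outdir / "conserved_pairs.tsv", sep="\t",
                                 index=False)
    summary = summarize_conservation(pairs, families_a)
    results["pairs"], results["summary"] = pairs, summary
    conserved_a = sorted({p.a_transcript_id for p in pairs})
    conserved_fams = {
        f.family_id for f in families_a
        if f.member_transcript_ids & set(conserved_a)
    }

    # --- cross-species expression correlation ---
    lnc_pairs = [(p.a_transcript_id, p.b_transcript_id) for p in pairs]
    pcg_pairs = list(orthologs.items())
    correlations = correlation_by_class(
        {"lncRNA": lnc_pairs, "PCG": pcg_pairs}, expr_a, expr_b,
        summary_stat=params.summary_stat,
    )
    results["correlations"] = correlations

    # --- conservation scores ---
    pcg_tx = [t for t in ann_a if t.biotype == "protein_coding"]
    lnc_tx = list(kept_a)
    scores_pcg, _ = score_transcripts(pcg_tx, track)
    scores_lnc, _ = score_transcripts(lnc_tx, track)
    if not sizes_a:
        raise PipelineError("stage conscore: genome sizes unknown")
    random_ivs = sample_random_regions(
        sizes_a, [t.span.end - t.span.start for t in lnc_tx],
        n=params.n_random_regions, seed=seed + 17, exclusions=ann_a,
    )
    random_scores = []
    for iv in random_ivs:
        try:
            random_scores.append(interval_score(iv, track))
        except ValueError:
            pass
    comparison = compare_groups(
        {"PCG": list(scores_pcg.values()), "lncRNA": list(scores_lnc.values()),
         "random": random_scores}
    )
    pd.DataFrame(
        [{"group": g, "median": comparison.medians[g]} for g in comparison.groups]
    ).to_csv(outdir / "conservation_medians.tsv", sep="\t", index=False,
             float_format="%.6g")
    results["conservation"] = comparison

    # --- co-expression network ---
    net_cfg = NetworkConfig(
        beta=params.beta, min_module_size=params.min_module_size,
        tom_edge_cutoff=params.tom_edge_cutoff, cut_height=params.cut_height,
    )
    pcg_ids_a = [t.transcript_id for t in ann_a if t.biotype == "protein_coding"]
    network_features = pcg_ids_a + conserved_a
    net_expr = expr_a.subset_features(network_features)
    adjacency = signed_adjacency(net_expr.values, net_cfg)
    tom = topological_overlap(adjacency)
    partition = detect_modules(tom, net_cfg)
    node_types = {t: "lncRNA" for t in conserved_a}
    node_types.update({t: "PCG" for t in pcg_ids_a})
    connectivity = module_connectivity(tom, partition, net_cfg, node_types)
    pd.DataFrame(
        sorted(partition.assignment.items()), columns=["node", "module"]
    ).to_csv(outdir / "modules.tsv", sep="\t", index=False)
    connectivity.frame.to_csv(outdir / "connectivity.tsv", sep="\t",
                              index=False, float_format="%.6g")
    try:
        stat, pval, medians = compare_connectivity(connectivity)
        results["connectivity_test"] = (stat, pval, medians)
    except ValueError as exc:
        logger.warning("connectivity comparison skipped: %s", exc)
        results["connectivity_test"] = None
    results["partition"] = partition
    results["connectivity"] = connectivity

    # --- GO enrichment + lncRNA annotation ---
    if go_map is None:
        universe = [g for g in pcg_ids_a if g in expr_a.values.index]
        go_map = GeneTermMap.from_tsv(require("go", "enrich"), universe=universe)
    enr = enrich_partition(
        partition, go_map, alpha=params.alpha, correction=params.correction,
        gene_filter=pcg_ids_a,
    )
    results_to_frame(enr).to_csv(outdir / "enrichment.tsv", sep="\t",
                                 index=False, float_format="%.6g")
    if interactions is None and inputs is not None and "interactions" in inputs:
        interactions = InteractionScoreTable.from_tsv(inputs["interactions"])
    annotations = annotate_lncrnas(partition, enr, conserved_a, go_map,
                                   interactions)
    pd.DataFrame(
        [vars(a) for a in annotations],
        columns=["lncrna_id", "module", "term_id", "p_value",
                 "interaction_supported"],
    ).to_csv(outdir / "lncrna_annotations.tsv", sep="\t", index=False,
             float_format="%.6g")
    results["enrichment"], results["annotations"] = enr, annotations

    # --- bidirectional pairs ---
    lnc_ann_a = AnnotationSet(kept_a)
    pcg_ann_a = ann_a.by_biotype("protein_coding")
    bidir_a = find_bidirectional_pairs(lnc_ann_a, pcg_ann_a,
                                       max_dist=params.max_dist, genome="A")
    lnc_ann_b = AnnotationSet(kept_b)
    pcg_ann_b = ann_b.by_biotype("protein_coding")
    conserved_bidir = conserved_neighbor_check(
        bidir_a, lnc_pairs, orthologs, lnc_ann_b, pcg_ann_b,
        max_dist=params.max_dist,
    )
    bidir_frame(bidir_a).to_csv(outdir / "bidirectional_a.tsv", sep="\t",
                                index=False)
    pd.DataFrame(
        [
            {"a_lncrna": pa.lncrna_id, "a_pcg": pa.pcg_id,
             "b_lncrna": pb.lncrna_id, "b_pcg": pb.pcg_id,
             "a_distance": pa.tss_distance, "b_distance": pb.tss_distance}
            for pa, pb in conserved_bidir
        ]
    ).to_csv(outdir / "bidirectional_conserved.tsv", sep="\t", index=False)
    results["bidir_a"], results["conserved_bidir"] = bidir_a, conserved_bidir

    # --- temporal trends ---
    stages = tuple(simulate.stages) if simulate is not None else tuple(
        dict.fromkeys(
            temporal_expr.sample_meta[s]["stage"] for s in temporal_expr.sample_ids
        )
    )
    calls = classify_trends(temporal_expr, stages=stages,
                            min_ratio=params.min_ratio)
    pd.DataFrame([vars(c) for c in calls]).to_csv(
        outdir / "trend_calls.tsv", sep="\t", index=False
    )
    trend_table = map_trends_to_partner(calls, lnc_pairs)
    trend_table.to_csv(outdir / "trend_partners.tsv", sep="\t", index=False)
    results["calls"], results["trend_table"] = calls, trend_table

    # --- integrate ---
    fam_conserved = [f for f in families_a if f.family_id in conserved_fams]
    evidence = collect_evidence(
        fam_conserved,
        annotations,
        [p for p in bidir_a
         if any(p.lncrna_id in f.member_transcript_ids for f in fam_conserved)],
        trend_table,
        strict=False,
    )
    evidence.to_frame().to_csv(outdir / "evidence.tsv", sep="\t", index=False)
    coverage = coverage_summary(evidence) if evidence.families else None
    if coverage is not None:
        with open(outdir / "coverage.json", "w") as fh:
            json.dump(
                {"n_families": coverage.n_families,
                 "n_annotated": coverage.n_annotated,
                 "fraction": round(coverage.fraction, 6),
                 "venn": coverage.venn},
                fh, indent=1, sort_keys=True,
            )
    results["evidence"], results["coverage"] = evidence, coverage

    manifest = {
        "tool": "lncons",
        "version": __version__,
        "seed": seed,
        "mode": "simulate" if simulate is not None else "files",
        "params": {k: v for k, v in vars(params).items()},
        "synthetic_config": (
            {k: list(v) if isinstance(v, tuple) else v
             for k, v in vars(simulate).items()}
            if simulate is not None else None
        ),
        "outputs": sorted(p.name for p in outdir.glob("*.tsv")),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    results["manifest"] = manifest
    return results


def load_pipeline_config(path) -> dict:
    """Load a YAML pipeline config with optional ``simulate``, ``inputs``
    and ``params`` sections."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out: dict = {}
    if raw.get("simulate"):
        sim = raw["simulate"] if isinstance(raw["simulate"], dict) else {}
        for key in ("stages", "bidirectional_distances", "loading_range",
                    "cons_means"):
            if key in sim:
                sim[key] = tuple(sim[key])
        if "enriched_terms" in sim:
            sim["enriched_terms"] = tuple(tuple(x) for x in sim["enriched_terms"])
        out["simulate"] = SyntheticConfig(**sim)
    if raw.get("inputs"):
        out["inputs"] = dict(raw["inputs"])
    if raw.get("params"):
        out["params"] = PipelineParams(**raw["params"])
    if raw.get("genome_sizes_a"):
        out["genome_sizes_a"] = dict(raw["genome_sizes_a"])
    return out
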