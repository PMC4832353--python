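"""Configuration, hit-table I/O and end-to-end pipeline orchestration.

The pipeline chains the stages detect -> filter -> validate -> synteny ->
motifs -> report over one query locus and one or two reference loci, and
is deterministic given (config, inputs).  Configuration is a flat
``section.key = value`` text format; every parameter has a default and
unknown keys are rejected.
"""
from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import fixtures
from .annotate_report import (coverage_fraction, overlap_enhancers,
                              bac_summary, SizeEstimateInputs,
                              scale_by_genome, extrapolate_by_coverage)
from .cns_detect import (LocalHit, ScoringScheme, local_align,
                         solve_karlin_altschul)
from .contig_map import nonredundant_span
from .hit_filter import cross_validate, mask_hits
from .motif_scan import default_motifs, scan_motifs
from .seqmodel import (AnnotationTrack, GenomicInterval, SequenceRecord,
                       TSV1_COLUMNS)
from .synteny import chain_colinear, count_inversions
from .synthetic_data import (EvolutionParams, simulate_locus, truth_overlap,
                             write_simulation)

logger = logging.getLogger("cnsfoot")

DEFAULTS: dict[str, dict] = {
    "global": {"seed": 0, "log_level": "INFO"},
    "simulate": {
        "tree": "((ref1:0.1,ref2:0.1):0.3,query:0.4)",
        "background_sub_rate": 1.0, "background_indel_rate": 0.02,
        "indel_mean_len": 3.0, "island_sub_rate": 0.15, "n_islands": 10,
        "island_min_len": 20, "island_max_len": 60, "n_genes": 3,
        "gene_min_len": 600, "gene_max_len": 1000,
        "te_insertion_rate": 0.37, "te_min_len": 300, "te_max_len": 1500,
        "inversion_prob": 0.1, "locus_length": 12000,
    },
    "detect": {"match": 1, "mismatch": -2, "gap_open": -5, "gap_extend": -2,
               "word_len": 7, "xdrop": 20, "evalue_max": 0.1},
    "filter": {"max_overlap_frac": 0.5},
    "validate": {"min_overlap_bp": 1},
    "synteny": {"use": "midpoint", "clear_break_min_displacement": 5},
    "motifs": {"max_gap": 5},
    "report": {"min_width": 25, "min_identity": 85.0},
}


@dataclass
class PipelineConfig:
    sections: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = {s: dict(v) for s, v in DEFAULTS.items()}
        for sec, kv in self.sections.items():
            if sec not in merged:
                raise ValueError(f"unknown config section {sec!r}")
            for key, value in kv.items():
                if key not in merged[sec]:
                    raise ValueError(f"unknown config key {sec}.{key}")
                merged[sec][key] = value
        self.sections = merged

    def __getitem__(self, section: str) -> dict:
        return self.sections[section]

    @property
    def seed(self) -> int:
        return int(self.sections["global"]["seed"])

    def evolution_params(self, seed: int | None = None) -> EvolutionParams:
        s = self.sections["simulate"]
        return EvolutionParams(
            tree=s["tree"],
            background_sub_rate=float(s["background_sub_rate"]),
            background_indel_rate=float(s["background_indel_rate"]),
            indel_mean_len=float(s["indel_mean_len"]),
            island_sub_rate=float(s["island_sub_rate"]),
            n_islands=int(s["n_islands"]),
            island_length_range=(int(s["island_min_len"]),
                                 int(s["island_max_len"])),
            n_genes=int(s["n_genes"]),
            gene_length_range=(int(s["gene_min_len"]),
                               int(s["gene_max_len"])),
            te_insertion_rate=float(s["te_insertion_rate"]),
            te_length_range=(int(s["te_min_len"]), int(s["te_max_len"])),
            inversion_prob=float(s["inversion_prob"]),
            locus_length=int(s["locus_length"]),
            seed=self.seed if seed is None else seed)

    def scoring_scheme(self) -> ScoringScheme:
        d = self.sections["detect"]
        return solve_karlin_altschul(ScoringScheme(
            match=int(d["match"]), mismatch=int(d["mismatch"]),
            gap_open=int(d["gap_open"]), gap_extend=int(d["gap_extend"])))

    def echo(self, path: Path) -> None:
        with open(path, "w") as fh:
            for sec in sorted(self.sections):
                for key in sorted(self.sections[sec]):
                    fh.write(f"{sec}.{key} = {self.sections[sec][key]}\n")


def load_config(path: str | Path | None) -> PipelineConfig:
    """Parse the flat ``section.key = value`` config format."""
    sections: dict[str, dict] = {}
    if path is not None:
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line or "." not in line.split("=", 1)[0]:
                    raise ValueError(
                        f"{path}:{lineno}: expected 'section.key = value'")
                key, value = (t.strip() for t in line.split("=", 1))
                sec, k = key.split(".", 1)
                sections.setdefault(sec, {})[k] = value
    return PipelineConfig(sections=sections)


def setup_logging(level: str = "INFO", logfile: Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers, force=True)


# ---------------------------------------------------------------------------
# hit-table I/O (the printed-table TSV dialect)
# ---------------------------------------------------------------------------

def write_hits_tsv(hits: list[LocalHit], path: str | Path) -> None:
    """Write hits in the 1-based-inclusive table dialect (query
    coordinates printed descending for minus-strand hits)."""
    rows = []
    for h in hits:
        r, q = h.ref_interval, h.query_interval
        qa, qb = (q.end, q.start + 1) if h.strand == "-" \
            else (q.start + 1, q.end)
        rows.append((r.start + 1, r.end, q.seq_id, qa, qb, h.pct_identity,
                     h.aln_length, h.mismatches, h.gap_opens, h.evalue,
                     h.bit_score, h.footnote or "."))
    pd.DataFrame(rows, columns=list(TSV1_COLUMNS)).to_csv(
        path, sep="\t", index=False)


def read_hits_tsv(path: str | Path) -> list[LocalHit]:
    df = pd.read_csv(path, sep="\t", dtype={"clone": str, "footnote": str})
    missing = set(TSV1_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing hit-table columns {missing}")
    hits = []
    for row in df.itertuples(index=False):
        qa, qb = int(row.query_start), int(row.query_end)
        if qa <= qb:
            q_iv = GenomicInterval(str(row.clone), qa - 1, qb, "+")
        else:
            q_iv = GenomicInterval(str(row.clone), qb - 1, qa, "-")
        foot = "" if str(row.footnote) in (".", "nan") else str(row.footnote)
        hits.append(LocalHit(
            ref_interval=GenomicInterval(
                "ref", int(row.ref_start) - 1, int(row.ref_end), "+"),
            query_interval=q_iv, strand=q_iv.strand, raw_score=0,
            bit_score=float(row.bitscore), evalue=float(row.evalue),
            pct_identity=float(row.pct_identity),
            aln_length=int(row.length), mismatches=int(row.mismatches),
            gap_opens=int(row.gap_opens), footnote=foot))
    return hits


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, outdir: str | Path,
                 query: SequenceRecord | None = None,
                 refs: list[SequenceRecord] | None = None,
                 coding_track: AnnotationTrack | None = None,
                 repeat_track: AnnotationTrack | None = None) -> dict:
    """Run detect -> filter -> validate -> synteny -> motifs -> report.

    With no explicit inputs a three-taxon locus is simulated from the
    config's simulate section and the truth tracks drive the filter and
    report stages.  Returns the report summary dict; all stage products
    are written under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    setup_logging(str(config["global"]["log_level"]),
                  outdir / "pipeline.log")
    config.echo(outdir / "config_echo.cfg")
    truth = None
    if query is None:
        params = config.evolution_params()
        logger.info("simulate: %s", params)
        records, truth = simulate_locus(params)
        write_simulation(records, truth, params, outdir / "simulated")
        query = records["query"]
        refs = [records["ref1"], records["ref2"]]
        coding_track = truth.genes["query"]
        repeat_track = truth.tes["query"]
    if not refs:
        raise ValueError("no reference sequences")

    scheme = config.scoring_scheme()
    d = config["detect"]
    per_ref_hits: list[list[LocalHit]] = []
    for ref in refs:
        logger.info("detect: query %s vs reference %s", query.id, ref.id)
        hits = local_align(query, ref, scheme,
                           word_len=int(d["word_len"]),
                           xdrop=int(d["xdrop"]),
                           evalue_max=float(d["evalue_max"]))
        per_ref_hits.append(hits)
        write_hits_tsv(hits, outdir / f"hits_{ref.id}.tsv")
        logger.info("detect: %d hits vs %s", len(hits), ref.id)

    fcfg = config["filter"]
    filtered: list[list[LocalHit]] = []
    for ref, hits in zip(refs, per_ref_hits):
        kept, report = mask_hits(
            hits, coding_track, repeat_track,
            max_overlap_frac=float(fcfg["max_overlap_frac"]))
        filtered.append(kept)
        write_hits_tsv(kept, outdir / f"filtered_{ref.id}.tsv")
        logger.info("filter vs %s: %d in, %d coding, %d repeat, %d kept",
                    ref.id, report.n_input, report.n_coding_removed,
                    report.n_repeat_removed, report.n_retained)

    blocks = filtered[0]
    n_recovered = None
    if len(filtered) > 1:
        validated = cross_validate(
            filtered[0], filtered[1],
            min_overlap_bp=int(config["validate"]["min_overlap_bp"]))
        n_recovered = sum(v.recovered for v in validated)
        blocks = [v.hit for v in validated if v.recovered]
        logger.info("validate: %d/%d blocks recovered by second reference",
                    n_recovered, len(validated))

    scfg = config["synteny"]
    chain = chain_colinear(
        blocks, clone_map=None, use=str(scfg["use"]),
        clear_break_min_displacement=int(
            scfg["clear_break_min_displacement"]))
    pd.DataFrame({
        "ref_start": [b.ref_interval.start for b in chain.blocks],
        "query_pos": chain.positions,
        "in_chain": [i in set(chain.chain_members)
                     for i in range(len(chain.blocks))],
        "strand": [b.strand for b in chain.blocks],
    }).to_csv(outdir / "synteny_dotplot.tsv", sep="\t", index=False)

    motif_hits = scan_motifs(query, default_motifs())
    with open(outdir / "motif_hits.bed", "w") as fh:
        for h in motif_hits:
            fh.write(f"{h.interval.seq_id}\t{h.interval.start}\t"
                     f"{h.interval.end}\t{h.motif}\t0\t{h.strand}\n")

    summary: dict = {
        "n_hits_per_ref": [len(h) for h in per_ref_hits],
        "n_filtered_per_ref": [len(f) for f in filtered],
        "n_recovered": n_recovered,
        "n_chain": len(chain.chain_members),
        "n_breaks": chain.n_breaks,
        "n_clear_breaks": chain.n_clear_breaks,
        "n_inversions": count_inversions(chain.blocks),
        "n_motif_hits": len(motif_hits),
    }
    if truth is not None:
        rec = truth_overlap(blocks, truth)
        summary["island_recovery_fraction"] = rec.recovery_fraction
        summary["n_spurious_hits"] = rec.n_spurious
    if blocks:
        summary["ref_coverage_fraction"] = coverage_fraction(
            blocks, GenomicInterval(refs[0].id, 0, len(refs[0])))
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("report: %s", summary)
    return summary


def fixture_report(outdir: str | Path | None = None) -> dict:
    """Run the non-detection stages on the packaged printed-table fixture
    and return the headline numbers of the reference-locus analysis."""
    hits = fixtures.table2_hits()
    virilis = fixtures.virilis_hits()
    cmap = fixtures.clone_map()
    validated = cross_validate(hits, virilis, min_overlap_bp=1)
    chain = chain_colinear(hits, clone_map=cmap)
    clones, gene_track, repeat_track = fixtures.table1_tracks()
    rows, totals, nonred = bac_summary(clones, gene_track, repeat_track,
                                       clone_map=cmap)
    enh = overlap_enhancers(hits, fixtures.enhancer_track(),
                            fixtures.category_map())
    cov = coverage_fraction(hits, fixtures.REF_LOCUS)
    inputs = SizeEstimateInputs(
        ref_locus_bp=104_000, ref_genome_bp=176e6, query_genome_bp=750e6,
        sequenced_bp=nonredundant_span(cmap), covered_fraction=0.78)
    summary = {
        "n_blocks": len(hits),
        "n_recovered": sum(v.recovered for v in validated),
        "n_chain": len(chain.chain_members),
        "n_breaks": chain.n_breaks,
        "n_clear_breaks": chain.n_clear_breaks,
        "clear_break_ref_starts": [
            chain.blocks[i].ref_interval.start + 1
            for i in chain.clear_breaks],
        "n_inversions": count_inversions(hits),
        "total_bp": totals.total_bp,
        "gene_bp": totals.gene_bp,
        "repeat_bp": totals.repeat_bp,
        "repeat_pct": totals.repeat_pct,
        "nonredundant_span_bp": nonredundant_span(cmap),
        "nonredundant_gene_bp": nonred.gene_bp if nonred else None,
        "wing_disc_blocks": enh.category_counts.get("wing_disc", 0),
        "utr_blocks": enh.category_counts.get("UTR", 0),
        "embryonic_ns_blocks": enh.category_counts.get("embryonic_ns", 0),
        "ref_coverage_fraction": round(cov, 4),
        "locus_size_genome_scaled_kb": round(
            scale_by_genome(inputs) / 1000, 1),
        # coverage extrapolation uses the published rounded 530-kb span
        "locus_size_coverage_kb": round(
            extrapolate_by_coverage(530_000, 0.78) / 1000, 1),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "fixture_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
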