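"""End-to-end orchestration: simulate/load → anchor → classify →
breakpoint-scan → gene-map → date, with machine-readable reports.

Every stage writes its intermediate to the output directory (anchors TSV,
blocks BED, mechanism JSON, flank FASTA, report JSON) and the report embeds
the effective configuration and its hash, so a run is reproducible
byte-for-byte from config + seed.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .anchors import chain_blocks, export_dotplot, find_anchors
from .breakpoints import (DEFAULT_FLANK_WINDOW, DEFAULT_MOTIF_PANEL,
                          annotate_repeats, extract_flanks,
                          find_inverted_repeats, scan_motif)
from .genemap import (check_orf, compare_intron_status, exon_skip_rescue,
                      percent_identity, splice_map)
from .io import read_fasta, read_gff3_gene, write_bed, write_fasta, write_json
from .ksclock import DEFAULT_CLOCK_RATE, estimate_divergence
from .locus import Locus
from .mechanism import (classify_mechanism, infer_breakpoints,
                        order_signature)
from .simulate import simulate_scenario

logger = logging.getLogger("circdup")

__all__ = [
    "RunConfig",
    "validate_config",
    "run_pipeline",
    "analyze_duplicate",
    "demo_config",
    "validate_report",
]

_SITE_LABELS = "ABCDEFGH"


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run. Either ``simulate`` is
    set (with a seed) or input paths are given."""

    outdir: str = "circdup_out"
    seed: int | None = None
    simulate: dict | None = None
    source_fasta: str | None = None
    target_fasta: str | None = None
    gene_gff3: str | None = None
    mrna_fasta: str | None = None
    repeat_library_fasta: str | None = None
    min_len: int = 20
    max_gap: int = 2000
    min_block_len: int = 500
    max_src_gap: int = 50_000
    tgt_slack: int = 1000
    window: int = DEFAULT_FLANK_WINDOW
    motif_panel: tuple[str, ...] = DEFAULT_MOTIF_PANEL
    inverted_repeat_min_len: int = 8
    inverted_repeat_max_mismatch: int = 0
    clock_rate: float = DEFAULT_CLOCK_RATE
    convention: str = "ks_over_r"

    def hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


_POSITIVE = ("min_len", "max_gap", "min_block_len", "max_src_gap",
             "tgt_slack", "window", "inverted_repeat_min_len", "clock_rate")


def _check(config_dict: dict) -> tuple[RunConfig, list[str]]:
    known = set(RunConfig.__dataclass_fields__)
    errors: list[str] = []
    clean = {}
    for key, value in config_dict.items():
        if key not in known:
            hint = difflib.get_close_matches(key, known, n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            errors.append(f"unknown key {key!r}{suggestion}")
            continue
        clean[key] = value
    if "motif_panel" in clean:
        clean["motif_panel"] = tuple(clean["motif_panel"])
    cfg = RunConfig(**clean)
    for name in _POSITIVE:
        if getattr(cfg, name) <= 0:
            errors.append(f"{name} must be positive "
                          f"(got {getattr(cfg, name)})")
    if cfg.inverted_repeat_max_mismatch < 0:
        errors.append("inverted_repeat_max_mismatch must be >= 0")
    if cfg.convention not in ("ks_over_r", "ks_over_2r"):
        errors.append(f"unknown convention {cfg.convention!r}")
    if cfg.simulate is not None and cfg.seed is None:
        errors.append("seed is required when simulation is requested")
    if cfg.simulate is None and not (cfg.source_fasta and cfg.target_fasta
                                     and cfg.mrna_fasta and cfg.gene_gff3):
        errors.append("either 'simulate' or all of source_fasta, "
                      "target_fasta, gene_gff3, mrna_fasta must be given")
    return cfg, errors


def validate_config(path) -> RunConfig:
    """Load, default and check a YAML/JSON config; all schema violations
    are reported at once."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} is not a mapping")
    cfg, errors = _check(raw)
    if errors:
        raise ValueError("invalid config:\n  - " + "\n  - ".join(errors))
    return cfg


def demo_config(outdir: str = "circdup_out", seed: int = 1) -> RunConfig:
    """The bundled demonstration scenario: one source locus with a 24-exon
    gene, one duplicate created through a ~28 kb circular intermediate and
    one single-block (order-uninformative) duplicate."""
    return RunConfig(
        outdir=outdir, seed=seed,
        simulate={
            "scenario": "demo",
            "excision_len": 28_000,
            "mutation_rate": 0.005,
        },
        min_block_len=200,
    )


def analyze_duplicate(source: Locus, target: Locus, mrna: str,
                      cds_mrna_span: tuple[int, int],
                      config: RunConfig | None = None,
                      repeat_library=None) -> dict:
    """Run every analysis stage on one (ancestral, duplicate) locus pair
    and return the per-duplicate report fragment."""
    cfg = config or RunConfig()
    report: dict = {"source_id": source.id, "target_id": target.id}

    anchors = find_anchors(source.seq, target.seq, min_len=cfg.min_len,
                           src_id=source.id, tgt_id=target.id)
    blocks = chain_blocks(anchors, max_gap=cfg.max_gap,
                          min_block_len=cfg.min_block_len)
    logger.info("%s vs %s: %d anchors, %d blocks kept",
                source.id, target.id, len(anchors), len(blocks))
    report["n_anchors"] = len(anchors)
    report["n_blocks"] = len(blocks)

    aln_src = splice_map(mrna, source)
    aln_tgt = splice_map(mrna, target)
    intron_flags = None
    intron_table = None
    if aln_src.mapped and aln_tgt.mapped:
        intron_table = compare_intron_status(aln_src, aln_tgt)
        intron_flags = list(intron_table.present_b)

    if not blocks:
        report["mechanism"] = {"mechanism": "retrocopy" if intron_flags
                               and not any(intron_flags) else "unmapped",
                               "notes": ["no synteny blocks"]}
        call = None
    else:
        signature = order_signature(blocks)
        call = classify_mechanism(signature, intron_report=intron_flags,
                                  max_src_gap=cfg.max_src_gap,
                                  tgt_slack=cfg.tgt_slack)
        if call.mechanism in ("direct", "circular_intermediate"):
            call = infer_breakpoints(call, blocks, source.seq, target.seq)
        report["mechanism"] = {
            "mechanism": call.mechanism,
            "rotation_offset": call.rotation_offset,
            "rotation_offset_blocks": call.rotation_offset_blocks,
            "circle_length": call.circle_length,
            "breakpoints_src": call.breakpoints_src,
            "breakpoints_tgt": call.breakpoints_tgt,
            "perm": list(signature.perm),
            "notes": call.notes,
        }

    # breakpoint neighborhoods on the source locus
    features: dict = {"inverted_repeats": [], "motifs": {},
                      "repeat_library_hits": []}
    if call is not None and call.breakpoints_src:
        bps = call.breakpoints_src
        flanks = [extract_flanks(source, bp, cfg.window,
                                 site_label=_SITE_LABELS[i % len(_SITE_LABELS)])
                  for i, bp in enumerate(bps)]
        outer_a, outer_d = flanks[0], flanks[-1]
        hits = find_inverted_repeats(
            outer_a.left + outer_a.right, outer_d.left + outer_d.right,
            min_len=cfg.inverted_repeat_min_len,
            max_mismatch=cfg.inverted_repeat_max_mismatch)
        features["inverted_repeats"] = [asdict(h) for h in hits]
        for fl in flanks:
            window_seq = fl.left + fl.right
            for motif in cfg.motif_panel:
                found = scan_motif(window_seq, motif, allow_revcomp=True)
                if found:
                    key = f"site_{fl.site_label}@{fl.center}"
                    features["motifs"].setdefault(key, []).extend(
                        {"motif": m.motif, "position": m.position,
                         "strand": m.strand} for m in found)
            if repeat_library:
                for ann in annotate_repeats(window_seq, repeat_library):
                    features["repeat_library_hits"].append(
                        {"site": fl.site_label, "label": ann.label,
                         "interval": list(ann.interval),
                         "identity": ann.identity, "strand": ann.strand})
    report["breakpoint_features"] = features

    # gene structure on the duplicate
    gm: dict = {"mapped": aln_tgt.mapped}
    if aln_tgt.mapped:
        gm["n_exons"] = aln_tgt.n_exons
        gm["identity"] = round(percent_identity(aln_tgt), 4)
        gm["intron_lengths"] = aln_tgt.intron_lengths
        if intron_table is not None:
            gm["introns_absent"] = int((~intron_table.present_b).sum())
        orf = check_orf(aln_tgt, target, cds_mrna_span)
        gm["orf"] = {"is_intact": orf.is_intact,
                     "premature_stops": orf.premature_stops,
                     "frame_ok_per_exon": orf.frame_ok_per_exon}
        if not orf.is_intact:
            gm["orf"]["rescue_sets"] = [list(s) for s in
                                        exon_skip_rescue(orf, aln_tgt, target)]
    report["gene_structure"] = gm

    # dating from the CDS pair
    if aln_src.mapped and aln_tgt.mapped:
        cs, ce = cds_mrna_span
        try:
            from .genemap import _map_mrna_to_spliced, _spliced_genomic
            g_src, _ = _spliced_genomic(aln_src, source)
            g_tgt, _ = _spliced_genomic(aln_tgt, target)
            cds_a = g_src[_map_mrna_to_spliced(aln_src, cs):
                          _map_mrna_to_spliced(aln_src, ce)]
            cds_b = g_tgt[_map_mrna_to_spliced(aln_tgt, cs):
                          _map_mrna_to_spliced(aln_tgt, ce)]
            est, div = estimate_divergence(cds_a, cds_b, rate=cfg.clock_rate,
                                           convention=cfg.convention)
            report["dating"] = {
                "ks": None if math.isnan(est.ds) else round(est.ds, 6),
                "ka": None if math.isnan(est.dn) else round(est.dn, 6),
                "n_codons": est.n_codons,
                "clock_rate": cfg.clock_rate,
                "convention": cfg.convention,
                "time_years": None if math.isnan(div.time_years)
                else round(div.time_years, 1),
            }
        except ValueError as exc:
            report["dating"] = {"error": str(exc)}
    return report


def _simulated_inputs(cfg: RunConfig):
    """Build the demo study condition: one source locus carrying a 24-exon
    gene; one duplicate created through a circular intermediate (default
    ~28 kb excision) and one plain single-block duplicate whose block order
    carries no mechanism signal."""
    import numpy as np

    from .simulate import make_gene_locus, make_random_locus, \
        simulate_duplication

    sim = dict(cfg.simulate or {})
    sim.pop("scenario", None)
    excision_len = sim.pop("excision_len", 28_000)
    mutation_rate = sim.pop("mutation_rate", 0.005)
    rng = np.random.default_rng(cfg.seed or 0)
    sub = lambda: int(rng.integers(0, 2**31 - 1))

    source, gene = make_gene_locus(flank_len=8000, seed=sub(),
                                   locus_id="ancestral")
    source.gene = gene
    gs, ge = gene.span
    mrna = gene.spliced_mrna(source.seq)
    pairs = []

    # duplicate 1: circular intermediate, rotated copy
    t1 = make_random_locus(12_000, sub(), locus_id="dup1_circular")
    lo = max(0, ge - excision_len)
    hi = min(gs, len(source) - excision_len)
    s = int(rng.integers(lo, hi + 1))
    cut = int(rng.integers(1000, excision_len - 1000))
    pairs.append(simulate_duplication(
        source, gene, t1, "circular_intermediate",
        excision_interval=(s, s + excision_len), circle_cut_offset=cut,
        insertion_point=int(rng.integers(0, len(t1))),
        mutation_rate=mutation_rate, seed=sub()))

    # duplicate 2: plain direct copy -> one block, order-uninformative
    t2 = make_random_locus(12_000, sub(), locus_id="dup2_single_block")
    margin = 500
    exc2 = (max(0, gs - margin), min(len(source), ge + margin))
    pairs.append(simulate_duplication(
        source, gene, t2, "direct", excision_interval=exc2,
        insertion_point=int(rng.integers(0, len(t2))),
        mutation_rate=mutation_rate, seed=sub()))

    targets = [p.target_locus_after for p in pairs]
    return source, gene, mrna, targets, [p.truth for p in pairs]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write intermediates + the final report JSON
    under ``config.outdir``. Rerunning with the same config and seed gives
    a byte-identical report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    truths = None
    if config.simulate is not None:
        source, gene, mrna, targets, truths = _simulated_inputs(config)
        cds_span = gene.cds_mrna_span()
        write_fasta([source] + targets, outdir / "loci.fasta")
        from .io import write_gff3
        write_gff3(source, outdir / "gene.gff3")
    else:
        source = read_fasta(config.source_fasta)[0]
        targets = read_fasta(config.target_fasta)
        gene = read_gff3_gene(config.gene_gff3)
        source.gene = gene
        mrna = read_fasta(config.mrna_fasta)[0].seq
        cds_span = gene.cds_mrna_span()

    repeat_library = None
    if config.repeat_library_fasta:
        repeat_library = [(l.id, l.seq)
                          for l in read_fasta(config.repeat_library_fasta)]

    report: dict = {
        "provenance": {
            "tool": "circdup",
            "version": __version__,
            "config": asdict(config),
            "config_hash": config.hash(),
            "seed": config.seed,
        },
        "duplicates": [],
    }
    for i, target in enumerate(targets):
        stage_name = f"{source.id}__{target.id}"
        try:
            anchors = find_anchors(source.seq, target.seq,
                                   min_len=config.min_len,
                                   src_id=source.id, tgt_id=target.id)
            export_dotplot(anchors, outdir / f"anchors_{stage_name}.tsv")
            blocks = chain_blocks(anchors, max_gap=config.max_gap,
                                  min_block_len=config.min_block_len)
            write_bed([(source.id, b.src_start, b.src_end,
                        f"block{b.block_id}") for b in blocks],
                      outdir / f"blocks_{stage_name}.source.bed")
            write_bed([(target.id, b.tgt_start, b.tgt_end,
                        f"block{b.block_id}") for b in blocks],
                      outdir / f"blocks_{stage_name}.target.bed")
            dup = analyze_duplicate(source, target, mrna, cds_span,
                                    config=config,
                                    repeat_library=repeat_library)
            if truths is not None:
                t = truths[i]
                dup["simulated_truth"] = {
                    "mechanism": t.mechanism,
                    "excision_interval": t.excision_interval,
                    "circle_cut_offset": t.circle_cut_offset,
                    "insertion_point": t.insertion_point,
                    "mutation_rate": t.mutation_rate,
                }
            report["duplicates"].append(dup)
            write_json(dup["mechanism"],
                       outdir / f"mechanism_{stage_name}.json")
        except Exception as exc:  # surface the failing stage, keep partials
            raise RuntimeError(
                f"pipeline stage failed for {stage_name}: {exc}") from exc
    validate_report(report)
    write_json(report, outdir / "report.json")
    return report


# --- minimal structural schema check ------------------------------------

_SCHEMA = {
    "provenance": dict,
    "duplicates": list,
}
_DUP_SCHEMA = {
    "source_id": str,
    "target_id": str,
    "mechanism": dict,
    "breakpoint_features": dict,
    "gene_structure": dict,
}


def validate_report(report: dict) -> None:
    """Check the report against the bundled structural schema; raises on
    violation."""
    for key, typ in _SCHEMA.items():
        if key not in report or not isinstance(report[key], typ):
            raise ValueError(f"report field {key!r} missing or wrong type")
    for dup in report["duplicates"]:
        for key, typ in _DUP_SCHEMA.items():
            if key not in dup or not isinstance(dup[key], typ):
                raise ValueError(
                    f"duplicate report field {key!r} missing or wrong type")
        if "mechanism" not in dup["mechanism"]:
            raise ValueError("mechanism call lacks a 'mechanism' field")
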