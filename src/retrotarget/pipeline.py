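"""End-to-end orchestration: simulate/scan -> annotate -> target -> phylo.

A plain nested-dict config pins every stage parameter (unknown keys are
rejected before any work starts); its hash, the global seed and the tool
version are stamped into a comment header of every report file, so a
rerun with the same config and seed yields a byte-identical report
directory.
"""
from __future__ import annotations

import copy as _copy
import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, Optional

import yaml
from Bio.Seq import Seq

from . import __version__
from .annotate import (ChdProfile, annotate_integrase, classify_copy,
                       classify_family, classify_junction, detect_ltr_pair,
                       finalize_nonltr_label)
from .intervals import GenomicInterval
from .io_formats import (read_alignment, read_fasta, read_trnascan_tabular,
                         write_bed, write_fasta, write_gff3, write_newick,
                         write_trnascan_tabular)
from .library import example_library, read_library, write_library
from .phylo import bootstrap
from .scan import CopyCall, ScanParams, chain_hits, import_hits, scan
from .simulate import GenomeSpec, InsertionProfile, generate
from .targeting import (TargetingConfig, assign_elements, call_targeting,
                        summarize_genome, trna_centric_scan)

log = logging.getLogger(__name__)

DEFAULT_CONFIG: Dict = {
    "seed": 0,
    "log_level": "INFO",
    "simulate": {
        "length": 500_000,
        "gc_fraction": 0.28,
        "n_trna": 40,
        "min_spacing": 100,
        "contig_name": "synth1",
        "library": "example",
        "profiles": [],
    },
    "scan": {
        "k": 12, "match": 1, "mismatch": -1, "gap_open": -5, "gap_extend": -1,
        "x_drop": 20, "min_hit_score": 30, "chain_max_gap": 2000,
    },
    "annotate": {
        "min_ltr_len": 80, "min_ltr_identity": 0.90, "end_window": 50,
        "junction_search_window": 40, "full_length_coverage": 0.95,
        "terminus_tol": 10, "solo_ltr_tol": 20, "solo_ltr_min_cov": 0.80,
        "solo_ltr_overhang": 40,
    },
    "target": {
        "flank_window": 3000, "assoc_max_gap": 500, "min_copies": 3,
        "side_consistency": 0.7, "n_permutations": 1000, "alpha": 0.01,
    },
    "phylo": {"bootstrap": 1000, "outgroup": None},
}

_PROFILE_KEYS = {
    "family", "n_copies", "side", "gap_min", "gap_max", "orientation_rule",
    "fraction_full_length", "fraction_solo_ltr", "trunc_min_bp",
    "trunc_max_frac", "substitution_rate", "indel_rate",
}


class ConfigError(ValueError):
    pass


def load_config(source=None) -> Dict:
    """Merge a config dict or YAML file over the defaults; reject unknown keys."""
    cfg = _copy.deepcopy(DEFAULT_CONFIG)
    if source is None:
        return cfg
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = source
    for key, val in user.items():
        if key not in cfg:
            raise ConfigError(f"unknown config key {key!r}")
        if isinstance(cfg[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"config section {key!r} must be a mapping")
            for k2, v2 in val.items():
                if k2 not in cfg[key]:
                    raise ConfigError(f"unknown config key {key}.{k2}")
                cfg[key][k2] = v2
        else:
            cfg[key] = val
    for prof in cfg["simulate"]["profiles"]:
        bad = set(prof) - _PROFILE_KEYS
        if bad:
            raise ConfigError(f"unknown profile keys {sorted(bad)}")
    return cfg


def config_hash(cfg: Dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _header(cfg: Dict) -> str:
    return (f"# retrotarget {__version__}\n"
            f"# seed={cfg['seed']} config_sha256={config_hash(cfg)}\n")


def _write_tsv(path, cfg, columns, rows) -> None:
    with open(path, "w") as fh:
        fh.write(_header(cfg))
        fh.write("#" + "\t".join(columns) + "\n")
        for r in rows:
            fh.write("\t".join("" if v is None else str(v) for v in r) + "\n")


class PipelineResult:
    """In-memory handles to everything a run produced."""

    def __init__(self):
        self.genome = None
        self.trnas = None
        self.truth = None
        self.library = None
        self.copies: list = []
        self.hits: list = []
        self.copy_classes: Dict[str, str] = {}
        self.consensus_annotations: Dict[str, dict] = {}
        self.assignments: list = []
        self.calls: Dict[str, object] = {}
        self.table1_rows: list = []
        self.genome_summary: dict = {}
        self.tree = None


def _simulate_stage(cfg: Dict, outdir: Path, result: PipelineResult) -> None:
    sim = cfg["simulate"]
    if sim["library"] == "example":
        result.library = example_library(cfg["seed"])
    else:
        result.library = read_library(sim["library"])
    spec = GenomeSpec(length=sim["length"], gc_fraction=sim["gc_fraction"],
                      n_trna=sim["n_trna"], min_spacing=sim["min_spacing"],
                      contig_name=sim["contig_name"], seed=cfg["seed"])
    profiles = [InsertionProfile(**p) for p in sim["profiles"]]
    genome, trnas, truth = generate(spec, profiles, result.library)
    result.genome, result.trnas, result.truth = genome, trnas, truth
    write_fasta(outdir / "genome.fa", genome)
    write_trnascan_tabular(outdir / "trnas.tab", trnas)
    write_gff3(outdir / "trnas.gff3",
               [(t.location, "tRNA", {"ID": t.id, "isotype": t.isotype}) for t in trnas])
    write_bed(outdir / "truth.bed", [(r.location, r.id) for r in truth])
    write_library(outdir / "library.json", result.library)
    manifest = [
        {"id": r.id, "family": r.family, "contig": r.location.contig,
         "start": r.location.start, "end": r.location.end,
         "strand": r.location.strand, "class": r.structural_class,
         "trna": r.trna_id, "side": r.side, "gap_bp": r.gap_bp,
         "nested": r.nested}
        for r in truth
    ]
    with open(outdir / "truth.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def _scan_stage(cfg: Dict, outdir: Path, result: PipelineResult,
                blast_table=None) -> None:
    params = ScanParams(**cfg["scan"])
    if blast_table is not None:
        result.copies = import_hits(blast_table, params=params)
        result.hits = [h for c in result.copies for h in c.hits]
    else:
        hits = []
        for name in sorted(result.library):
            hits.extend(scan(result.genome, result.library[name], params))
        result.hits = hits
        result.copies = chain_hits(hits, params)
    _write_tsv(outdir / "hits.tsv", cfg,
               ["query", "contig", "start", "end", "strand", "qstart", "qend",
                "pident", "score"],
               [(h.query, h.subject.contig, h.subject.start, h.subject.end,
                 h.subject.strand, h.query_span[0], h.query_span[1],
                 f"{h.percent_identity:.1f}", h.score) for h in result.hits])
    write_bed(outdir / "copies.bed", [(c.location, c.id) for c in result.copies])


def _annotate_stage(cfg: Dict, outdir: Path, result: PipelineResult) -> None:
    ann_cfg = cfg["annotate"]
    profile = ChdProfile.packaged()
    genome_seqs = dict(result.genome) if result.genome else {}
    rows = []
    for name in sorted(result.library):
        cons = result.library[name]
        pair = detect_ltr_pair(cons, min_len=ann_cfg["min_ltr_len"],
                               min_identity=ann_cfg["min_ltr_identity"],
                               end_window=ann_cfg["end_window"])
        if pair is not None and cons.ltr_spans is None:
            cons.ltr_spans = (pair.left_span, pair.right_span)
        junction = None
        if cons.element_class == "LTR" and cons.ltr_spans is not None:
            junction = classify_junction(cons, ann_cfg["junction_search_window"])
        integrase = None
        if cons.orf_spans:
            s, e = cons.orf_spans[-1]
            dna = cons.sequence[s:e]
            prot = str(Seq(dna[: len(dna) - len(dna) % 3]).translate()).rstrip("*")
            integrase = annotate_integrase(prot, chd_profile=profile)
        fam = classify_family(cons, integrase)
        result.consensus_annotations[name] = {
            "ltr_pair": pair, "junction": junction,
            "integrase": integrase, "family_class": fam,
        }
        chd = integrase.chd if integrase else None
        rows.append((
            name, cons.element_class, cons.length,
            pair.length if pair else None,
            junction.kind if junction else None,
            junction.offset_bp if junction else None,
            integrase.ctd_length if integrase and integrase.ctd_length is not None else "n.d.",
            chd.group if chd else None,
            fam.label,
        ))
    _write_tsv(outdir / "annotations.tsv", cfg,
               ["family", "class", "length", "ltr_length", "junction",
                "junction_offset", "in_ctd_aa", "chd_group", "label"], rows)

    for c in result.copies:
        cons = result.library[c.family]
        gseq = genome_seqs.get(c.location.contig)
        result.copy_classes[c.id] = classify_copy(
            c, cons, genome_seq=gseq,
            full_length_coverage=ann_cfg["full_length_coverage"],
            terminus_tol=ann_cfg["terminus_tol"],
            solo_ltr_tol=ann_cfg["solo_ltr_tol"],
            solo_ltr_min_cov=ann_cfg["solo_ltr_min_cov"],
            solo_ltr_overhang=ann_cfg["solo_ltr_overhang"])
    _write_tsv(outdir / "copy_classes.tsv", cfg,
               ["copy", "family", "contig", "start", "end", "strand", "class",
                "mean_identity"],
               [(c.id, c.family, c.location.contig, c.location.start,
                 c.location.end, c.location.strand, result.copy_classes[c.id],
                 f"{c.mean_identity:.1f}") for c in result.copies])


def _target_stage(cfg: Dict, outdir: Path, result: PipelineResult) -> None:
    tcfg = TargetingConfig(seed=cfg["seed"], **cfg["target"])
    result.assignments = assign_elements(result.copies, result.trnas, tcfg)
    genome_length = sum(len(s) for _, s in result.genome)
    all_spans = [(c.location.start, c.location.end) for c in result.copies]
    families = sorted({c.family for c in result.copies})
    n_tested = len(families)
    alpha = tcfg.alpha / n_tested if n_tested > 5 else tcfg.alpha  # Bonferroni
    for fam in families:
        fcfg = TargetingConfig(seed=tcfg.seed, alpha=alpha,
                               **{k: v for k, v in cfg["target"].items()
                                  if k != "alpha"})
        result.calls[fam] = call_targeting(
            fam, result.copies, result.assignments, result.trnas,
            genome_length, fcfg, exclusion_spans=all_spans)
        ann = result.consensus_annotations.get(fam)
        if ann is not None:
            call = result.calls[fam]
            ann["family_class"] = finalize_nonltr_label(
                ann["family_class"], call.verdict, call.side)
    _write_tsv(outdir / "assignments.tsv", cfg,
               ["copy", "trna", "side", "gap_bp", "nested", "intervening"],
               [(a.copy_id, a.trna_id, a.side, a.gap_bp, a.nested,
                 ",".join(a.intervening_elements)) for a in result.assignments])
    rows, summary = summarize_genome(
        result.copies, result.copy_classes, result.calls, result.assignments,
        result.trnas, result.library, genome_length)
    result.table1_rows, result.genome_summary = rows, summary
    _write_tsv(outdir / "table1.tsv", cfg,
               ["family", "consensus_length", "ltr_length", "total",
                "full_length_intact", "solo_ltr", "trna_specific",
                "window_5p", "window_3p"],
               [tuple(r.values()) for r in rows])
    srows = [(k, f"{v:.2f}" if isinstance(v, float) else v)
             for k, v in summary.items() if not isinstance(v, dict)]
    srows += [(f"trna_assoc_percent[{f}]", f"{v:.2f}")
              for f, v in summary.get("trna_assoc_percent_by_family", {}).items()]
    _write_tsv(outdir / "genome_summary.tsv", cfg, ["key", "value"], srows)


def _phylo_stage(cfg: Dict, outdir: Path, result: PipelineResult,
                 alignment_path) -> None:
    rows = read_alignment(alignment_path)
    tree = bootstrap(rows, n_reps=cfg["phylo"]["bootstrap"], seed=cfg["seed"])
    if cfg["phylo"]["outgroup"]:
        from .phylo import root_on
        tree = root_on(tree, [s.strip() for s in
                              str(cfg["phylo"]["outgroup"]).split(",")])
    result.tree = tree
    write_newick(outdir / "tree.nwk", tree)


def run_pipeline(config, inputs: Optional[Dict] = None, outdir="report"
                 ) -> PipelineResult:
    """Run all stages in order; returns in-memory results.

    ``inputs`` may provide paths: genome (FASTA), trnas (tRNAscan
    tabular), library (JSON), blast (outfmt-6 table replacing the
    scanner), alignment (for the phylo stage).  Without a genome input
    the ``simulate:`` config block must define profiles.
    """
    cfg = load_config(config) if not _is_loaded(config) else config
    inputs = inputs or {}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = PipelineResult()

    if inputs.get("genome"):
        result.genome = read_fasta(inputs["genome"])
        if not inputs.get("trnas"):
            raise ConfigError("stage target: tRNA annotations input missing")
        result.trnas = read_trnascan_tabular(inputs["trnas"])
        if inputs.get("library"):
            result.library = read_library(inputs["library"])
        else:
            result.library = example_library(cfg["seed"])
    elif cfg["simulate"]["profiles"]:
        _simulate_stage(cfg, outdir, result)
    else:
        raise ConfigError("stage scan: no genome input and no simulate profiles")

    _scan_stage(cfg, outdir, result, blast_table=inputs.get("blast"))
    _annotate_stage(cfg, outdir, result)
    _target_stage(cfg, outdir, result)
    if inputs.get("alignment"):
        _phylo_stage(cfg, outdir, result, inputs["alignment"])
    return result


def _is_loaded(config) -> bool:
    return isinstance(config, dict) and set(DEFAULT_CONFIG) <= set(config)
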