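"""End-to-end orchestration: find -> annotate -> project -> detect -> classify
-> characterize -> compare, with machine-readable reports.

Each stage is a plain function over the library types, so CLI
subcommands composed manually reproduce ``run-all`` outputs exactly.
All outputs are deterministic given the inputs: every table is sorted,
the report JSON uses sorted keys, and no timestamps are embedded.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__
from . import formats
from .cross_taxon import any_28s_character, gain_scenarios, presence_matrix, shared_sites
from .formats import CoverageTable, Msa, SequenceRecord
from .its_caller import (
    ItsCall,
    ItsSiteRegistry,
    classify_expansions,
    cross_its_homology,
    fragment_count,
    orf_scan,
    write_calls,
)
from .operon_finder import (
    OperonAnnotation,
    ScoringParams,
    annotate_operon,
    filter_rdna_contigs,
    read_segment_bounds,
    search_homologs,
    write_hits,
)
from .structure_map import (
    ExpansionReport,
    HelixMap,
    fold_region,
    interanchor_lengths,
    project_anchors,
    region_domains,
)

logger = logging.getLogger("itscan")


@dataclass
class Thresholds:
    e_max: float = 1e-5
    coverage_factor: float = 5.0
    expansion_factor: float = 4.0
    min_abs: int = 30
    orf_min_aa: int = 20
    background_stat: str = "median"
    fold_max_len: int = 400

    def __post_init__(self) -> None:
        for name in ("e_max", "coverage_factor", "expansion_factor", "min_abs", "orf_min_aa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")


@dataclass
class PipelineConfig:
    """Declarative run configuration; CLI flags override these keys."""

    outdir: str | Path = "itscan_out"
    # operon/alignment inputs
    msa: str | Path | None = None
    helix_map: str | Path | None = None
    registry: str | Path | None = None
    reference_segments: str | Path | None = None
    tree: str | Path | None = None
    # assembly inputs (find stage)
    assembly: str | Path | None = None
    coverage: str | Path | None = None
    reference: str | Path | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    scoring: ScoringParams = field(default_factory=ScoringParams)
    focal: tuple[str, ...] | None = None
    background: tuple[str, ...] | None = None
    lineages: dict[str, str] = field(default_factory=dict)
    log_level: str = "INFO"


# ---------------------------------------------------------------------------
# Stages

def find_stage(
    contigs: Sequence[SequenceRecord],
    coverage: CoverageTable,
    reference: SequenceRecord,
    bounds: Mapping[str, tuple[int, int]],
    scoring: ScoringParams,
    thresholds: Thresholds,
) -> tuple[list, list[str], list[OperonAnnotation]]:
    """Locate and annotate rDNA contigs in an assembly."""
    queries = [
        SequenceRecord(name, reference.residues[s:e])
        for name, (s, e) in bounds.items()
        if name in ("SSU", "5.8S", "LSU")
    ]
    hits = search_homologs(queries, contigs, scoring)
    kept = filter_rdna_contigs(
        hits, coverage, e_max=thresholds.e_max, factor=thresholds.coverage_factor
    )
    by_id = {c.id: c for c in contigs}
    annotations = [
        annotate_operon(
            by_id[cid], reference, bounds, scoring,
            e_max=thresholds.e_max, depth=coverage.depth(cid),
        )
        for cid in kept
    ]
    return hits, kept, annotations


def detect_stage(
    msa: Msa,
    helix_map: HelixMap,
    domains: Mapping[tuple[str, str], str],
    thresholds: Thresholds,
    focal: Sequence[str] | None = None,
    background: Sequence[str] | None = None,
) -> tuple[list, ExpansionReport]:
    """Project anchors, measure inter-anchor regions, flag expansions.

    By default every non-template row is tested as the focal species
    against all other rows; spacer-domain regions (ITS1/ITS2) are never
    tested — they are spacers already.
    """
    proj = project_anchors(msa, helix_map)
    regions = interanchor_lengths(proj, msa, domains=domains)
    regions = [r for r in regions if domains.get(r.region_id) not in (None, "spacer")]
    taxa = [r.id for r in msa.records if r.id != helix_map.template_id]
    focal_set = list(focal) if focal else taxa
    expansions = []
    skipped = []
    for sp in focal_set:
        bg = [t for t in (background or taxa) if t != sp]
        rep = detect_expansions_wrapper(regions, [sp], bg, thresholds)
        expansions.extend(rep.expansions)
        skipped.extend(rep.skipped)
    # deduplicate skip records
    seen = set()
    uniq_skipped = []
    for s in skipped:
        if s not in seen:
            seen.add(s)
            uniq_skipped.append(s)
    return regions, ExpansionReport(expansions=expansions, skipped=uniq_skipped)


def detect_expansions_wrapper(regions, focal, background, thresholds: Thresholds):
    from .structure_map import detect_expansions

    return detect_expansions(
        regions,
        focal,
        background,
        factor=thresholds.expansion_factor,
        min_abs=thresholds.min_abs,
        stat=thresholds.background_stat,
    )


def classify_stage(
    expansions,
    registry: ItsSiteRegistry,
    domains: Mapping[tuple[str, str], str],
    lineages: Mapping[str, str],
) -> list[ItsCall]:
    return classify_expansions(expansions, registry, domains, lineages)


def characterize_stage(
    calls: Sequence[ItsCall],
    operon_seqs: Mapping[str, str],
    scoring: ScoringParams,
    thresholds: Thresholds,
):
    """Attach ORF counts, folding pair density, and cross-ITS homology
    evidence to every call.  Folding of very long inserts is evaluated on
    a centred window of ``fold_max_len`` nt — base-pair maximisation is
    cubic and the density, not the exact structure, is the evidence."""
    for c in calls:
        seq = operon_seqs[c.species][c.interval[0] : c.interval[1]]
        orfs = orf_scan(seq, min_aa=thresholds.orf_min_aa)
        c.evidence["orf_count"] = len(orfs)
        c.evidence["max_orf_aa"] = max((o.aa_length for o in orfs), default=0)
        if seq:
            w = thresholds.fold_max_len
            window = seq if len(seq) <= w else seq[(len(seq) - w) // 2 :][:w]
            c.evidence["pair_density"] = round(fold_region(window).pair_density, 4)
    homology = cross_its_homology(calls, operon_seqs, scoring)
    if len(homology.labels) > 1:
        for i, c in enumerate(calls):
            row = homology.identity.iloc[i]
            c.evidence["max_cross_identity"] = round(float(row.max(skipna=True)), 4)
    return homology


def compare_stage(
    calls: Sequence[ItsCall],
    registry: ItsSiteRegistry,
    tree,
    taxa: Sequence[str],
) -> dict:
    pairs = shared_sites(registry)
    matrix = presence_matrix(calls, taxa, columns="region")
    out = {
        "shared_pairs": [
            {"site_a": p.site_a, "site_b": p.site_b, "region": list(p.region_id)}
            for p in pairs
        ],
        "presence_regions": {
            col: [t for t in taxa if bool(matrix.loc[t, col])]
            for col in matrix.columns
        },
    }
    if tree is not None:
        char = any_28s_character(calls, taxa)
        sc = gain_scenarios(tree, char)
        out["any_28S_character"] = {
            "present_in": sorted(t for t, v in char.items() if v),
            "fitch_changes": sc.fitch_changes,
            "gains_no_loss": sc.gains_no_loss,
            "dollo_losses_single_gain": sc.dollo_losses_single_gain,
            "single_ancestral_gain_possible": sc.gains_no_loss <= 1,
        }
    return out


# ---------------------------------------------------------------------------
# Schematic

def render_schematic(
    calls: Sequence[ItsCall],
    region_order: Sequence[tuple[str, str]],
    taxa: Sequence[str],
) -> str:
    """A Fig-1-style SVG: one 5.8S+28S bar per taxon, a tick per ITS call
    at its region's relative position; regions occupied in more than one
    taxon get a dashed vertical guide linking the shared positions."""
    width, bar_h, gap = 640, 14, 26
    left, right_pad, top = 110, 20, 30
    bar_w = width - left - right_pad
    n_regions = max(len(region_order), 1)
    x_of = {
        rid: left + bar_w * (i + 0.5) / n_regions
        for i, rid in enumerate(region_order)
    }
    height = top + len(taxa) * gap + 20
    svg = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}">',
        '<style>text{font:11px sans-serif}</style>',
    ]
    by_taxon: dict[str, list[ItsCall]] = {t: [] for t in taxa}
    for c in calls:
        if c.domain == "LSU" and c.species in by_taxon:
            by_taxon[c.species].append(c)
    region_users: dict[tuple[str, str], int] = {}
    for c in calls:
        if c.domain == "LSU":
            region_users[c.region_id] = region_users.get(c.region_id, 0) + 1
    for rid, n in sorted(region_users.items()):
        if n > 1 and rid in x_of:
            x = x_of[rid]
            svg.append(
                f'<line x1="{x:.1f}" y1="{top - 8}" x2="{x:.1f}" '
                f'y2="{height - 14}" stroke="#999" stroke-dasharray="3,3"/>'
            )
    for i, taxon in enumerate(taxa):
        y = top + i * gap
        svg.append(f'<text x="6" y="{y + bar_h - 3}">{taxon}</text>')
        svg.append(
            f'<rect x="{left}" y="{y}" width="{bar_w}" height="{bar_h}" '
            'fill="#cfd8dc" stroke="#455a64"/>'
        )
        for c in sorted(by_taxon[taxon], key=lambda c: c.region_id):
            if c.region_id not in x_of:
                continue
            x = x_of[c.region_id]
            color = "#d32f2f" if c.classification == "known_ITS" else "#f57c00"
            svg.append(
                f'<rect x="{x - 1.5:.1f}" y="{y - 2}" width="3" '
                f'height="{bar_h + 4}" fill="{color}"/>'
            )
    svg.append("</svg>")
    return "\n".join(svg)


# ---------------------------------------------------------------------------
# Orchestration

def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages and write artifacts + report JSON.

    Requires at least the MSA + helix map inputs; the find stage runs
    only when an assembly is configured.  Returns the report dict (also
    written to ``<outdir>/report.json``).
    """
    logging.basicConfig(stream=sys.stderr, level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "stages": {}}

    annotations: list[OperonAnnotation] = []
    if config.assembly is not None:
        contigs = formats.read_fasta(config.assembly)
        coverage = formats.parse_coverage(contigs, tsv=config.coverage)
        reference = formats.read_fasta(config.reference)[0]
        bounds = read_segment_bounds(config.reference_segments)
        logger.info("find: %d contigs", len(contigs))
        hits, kept, annotations = find_stage(
            contigs, coverage, reference, bounds, config.scoring, config.thresholds
        )
        write_hits(hits, outdir / "hits.tsv")
        formats.write_gff3(annotations, outdir / "operons.gff3")
        report["stages"]["find"] = {
            "contigs": len(contigs),
            "hits": len(hits),
            "rdna_contigs": kept,
            "complete_operons": sum(a.complete for a in annotations),
        }

    if config.msa is None or config.helix_map is None:
        report_path = outdir / "report.json"
        report_path.write_text(json.dumps(report, indent=1, sort_keys=True))
        return report

    msa = formats.read_msa(config.msa)
    helix_map = formats.read_helix_map(config.helix_map)
    helix_map.template_id = _pick_template(msa, helix_map)
    bounds = read_segment_bounds(config.reference_segments)
    domains = region_domains(helix_map, bounds)
    registry = (
        _load_registry(config.registry) if config.registry else ItsSiteRegistry([])
    )
    tree = formats.read_newick(config.tree) if config.tree else None

    regions, exp_report = detect_stage(
        msa, helix_map, domains, config.thresholds, config.focal, config.background
    )
    logger.info(
        "detect: %d regions, %d expansions", len(regions), len(exp_report.expansions)
    )
    calls = classify_stage(exp_report.expansions, registry, domains, config.lineages)
    operon_seqs = {
        r.id: r.degapped for r in msa.records if r.id != helix_map.template_id
    }
    characterize_stage(calls, operon_seqs, config.scoring, config.thresholds)
    write_calls(calls, outdir / "its_calls.tsv")

    taxa = sorted(operon_seqs)
    comparison = compare_stage(calls, registry, tree, taxa)
    region_order = [
        rid for rid in helix_map.region_ids() if domains.get(rid) == "LSU"
    ]
    (outdir / "schematic.svg").write_text(
        render_schematic(calls, region_order, taxa)
    )

    per_species = {
        sp: {
            "its_calls": sum(
                1
                for c in calls
                if c.species == sp
                and c.classification in ("known_ITS", "novel_candidate")
            ),
            "ssu_expansions": sum(
                1
                for c in calls
                if c.species == sp and c.classification == "ssu_expansion"
            ),
            "fragments_28s": fragment_count(calls, sp),
        }
        for sp in taxa
    }
    report["stages"]["detect"] = {
        "regions_tested": len(regions),
        "expansions": len(exp_report.expansions),
        "skipped_regions": [
            {"region": list(rid), "reason": why} for rid, why in exp_report.skipped
        ],
    }
    report["stages"]["classify"] = {
        "calls": len(calls),
        "known_ITS": sum(c.classification == "known_ITS" for c in calls),
        "novel_candidate": sum(c.classification == "novel_candidate" for c in calls),
        "ssu_expansion": sum(c.classification == "ssu_expansion" for c in calls),
    }
    report["calls"] = [
        {
            "species": c.species,
            "classification": c.classification,
            "site_id": c.site_id,
            "region": list(c.region_id),
            "interval": list(c.interval),
            "length": c.length,
            "domain": c.domain,
        }
        for c in sorted(calls, key=lambda c: (c.species, c.region_id))
    ]
    report["per_species"] = per_species
    report["comparison"] = comparison
    # reconciliation invariant: classification is total over expansions
    if report["stages"]["classify"]["calls"] != report["stages"]["detect"]["expansions"]:
        raise RuntimeError("stage counts do not reconcile: calls != expansions")
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def _pick_template(msa: Msa, helix_map: HelixMap) -> str:
    if helix_map.template_id in msa.ids():
        return helix_map.template_id
    # fall back to the conventional row name
    if "template" in msa.ids():
        return "template"
    raise ValueError(
        f"helix map template {helix_map.template_id!r} is not a row of the MSA"
    )


def _load_registry(path) -> ItsSiteRegistry:
    from .its_caller import read_registry

    return read_registry(path)


def run_from_bundle(
    bundle,
    outdir: str | Path,
    thresholds: Thresholds | None = None,
    run_find: bool = False,
) -> dict:
    """Run the pipeline directly on an in-memory synthetic bundle."""
    from .synthetic_data import write_bundle

    outdir = Path(outdir)
    paths = write_bundle(bundle, outdir / "bundle")
    config = PipelineConfig(
        outdir=outdir,
        msa=paths["msa"],
        helix_map=paths["helix_map"],
        registry=paths["registry"],
        reference_segments=paths["reference_segments"],
        tree=paths["tree"],
        thresholds=thresholds or Thresholds(),
        lineages=dict(bundle.config.lineages),
    )
    if run_find:
        config.assembly = paths["assembly"]
        config.coverage = paths["coverage"]
        config.reference = paths["reference"]
    return run_pipeline(config)
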