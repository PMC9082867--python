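"""Synthetic rRNA-operon bundles with planted ground truth.

The generator emulates the statistical structure the detection pipeline
assumes, so every stage is testable without downloads: an operon
(SSU-ITS1-5.8S-ITS2-LSU) whose conserved helix anchors evolve slowly
while divergent regions and spacers evolve fast and accumulate indels;
lineage-specific additional ITSs of arbitrary sequence planted at
inter-helix sites of chosen taxa; and a toy assembly in which rDNA
contigs carry several-fold the baseline read depth among low-coverage
decoy contigs.  Every bundle carries a truth table (planted sites,
segment boundaries, rDNA contig ids) and is byte-identical under a
fixed seed.

The default configuration mirrors the euglenozoan study design: an
outgroup, a diplonemid-like clade without extra ITSs, a euglenid-like
clade with 12 LSU ITS sites (plus a shared SSU expansion and two novel
sites in one taxon), a prokinetoplastid-like lineage without ITSs, and
a metakinetoplastid-like clade with 5 LSU sites, three of them at the
same inter-helix regions as euglenid sites.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np

from . import formats
from .formats import CoverageTable, Msa, SequenceRecord, parse_coverage
from .its_caller import ItsSite, ItsSiteRegistry, write_registry
from .structure_map import HelixAnchor, HelixMap, region_domains

_BASES = np.array(list("ACGT"))
_CLS_CODE = {"core": 0, "ES": 1, "spacer": 2}
_CODE_CLS = {v: k for k, v in _CLS_CODE.items()}

TEMPLATE_ID = "template"

DEFAULT_TREE = (
    "(Out:0.15,((Eug1:0.05,Eug2:0.05):0.06,((Dip1:0.04,Dip2:0.04):0.05,"
    "(Prok:0.08,(Kin1:0.03,Kin2:0.03):0.05):0.03):0.02):0.02);"
)

DEFAULT_LINEAGES = {
    "Out": "other",
    "Eug1": "euglenid",
    "Eug2": "euglenid",
    "Dip1": "other",
    "Dip2": "other",
    "Prok": "other",
    "Kin1": "kinetoplastid",
    "Kin2": "kinetoplastid",
}


@dataclass(frozen=True)
class PlantedIts:
    """One planted insertion: a site id (or None for an unregistered site),
    the carrier taxa, the target inter-anchor region (segment + region
    index, counted between consecutive core anchors of that segment), and
    the length range the insert is drawn from."""

    taxa: tuple[str, ...]
    segment: str = "LSU"
    region_index: int = 0
    length: tuple[int, int] = (800, 1200)
    site_id: str | None = None
    lineage: str = "other"


@dataclass(frozen=True)
class AssemblyModel:
    baseline_depth: float = 10.0
    rdna_multiplier: float = 20.0
    n_decoys: int = 60
    decoy_length: int = 5000
    flank: int = 300
    depth_jitter: float = 0.2


def _euglenozoan_planted() -> tuple[PlantedIts, ...]:
    eug = ("Eug1", "Eug2")
    kin = ("Kin1", "Kin2")
    specs = []
    # 12 euglenid LSU sites (eITS2..eITS13) at regions 0..10 and 12
    e_regions = [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12]
    for i, r in enumerate(e_regions, start=2):
        specs.append(
            PlantedIts(taxa=eug, region_index=r, site_id=f"eITS{i}", lineage="euglenid")
        )
    # 5 metakinetoplastid LSU sites; kITS5/6/7 share regions with eITS10/11/13
    for site, r in [("kITS3", 11), ("kITS4", 13), ("kITS5", 8), ("kITS6", 9), ("kITS7", 12)]:
        specs.append(
            PlantedIts(taxa=kin, region_index=r, site_id=site, lineage="kinetoplastid")
        )
    # a shared euglenid SSU expansion (retained in mature 18S, never an ITS)
    specs.append(
        PlantedIts(taxa=eug, segment="SSU", region_index=2, length=(900, 1300))
    )
    # two novel unregistered LSU sites in a single euglenid taxon
    specs.append(PlantedIts(taxa=("Eug2",), region_index=14, length=(800, 1200)))
    specs.append(PlantedIts(taxa=("Eug2",), region_index=15, length=(800, 1200)))
    return tuple(specs)


@dataclass
class SimulationConfig:
    seed: int = 0
    tree: str = DEFAULT_TREE
    segment_lengths: dict[str, int] = field(
        default_factory=lambda: {
            "SSU": 2000, "ITS1": 300, "5.8S": 160, "ITS2": 400, "LSU": 3500
        }
    )
    # per segment: (number of core helix anchors, number of ES anchors)
    anchor_plan: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"SSU": (6, 1), "5.8S": (2, 0), "LSU": (17, 0)}
    )
    core_stem: int = 10
    core_loop: int = 4
    es_anchor_len: int = 20
    # substitution-rate multipliers per site class (branch lengths are
    # expected substitutions/site at rate 1.0)
    rates: dict[str, float] = field(
        default_factory=lambda: {"core": 0.1, "ES": 2.0, "spacer": 3.0}
    )
    indel_rate: float = 0.02  # events per eligible site per unit branch length
    indel_mean_len: float = 4.0
    planted_its: tuple[PlantedIts, ...] = field(default_factory=_euglenozoan_planted)
    assembly: AssemblyModel = field(default_factory=AssemblyModel)
    lineages: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_LINEAGES))

    def validate(self) -> None:
        for seg, (nc, nes) in self.anchor_plan.items():
            if seg not in self.segment_lengths:
                raise ValueError(f"anchor plan references unknown segment {seg}")
            need = nc * (2 * self.core_stem + self.core_loop) + nes * self.es_anchor_len
            if need >= self.segment_lengths[seg]:
                raise ValueError(
                    f"{seg}: anchors need {need} nt but segment is only "
                    f"{self.segment_lengths[seg]} nt"
                )
        for r in self.rates.values():
            if r < 0:
                raise ValueError("negative substitution rate")


def compact_config(seed: int, planted: bool = True, n_sites: int = 5) -> SimulationConfig:
    """A small, fast bundle: 8 taxa, short operon, LSU sites planted in the
    kinetoplastid-like clade (or none, for specificity runs).  Planted
    lengths and region widths are chosen so every planted site exceeds the
    4x rule with a factor of at least five."""
    specs: tuple[PlantedIts, ...] = ()
    if planted:
        specs = tuple(
            PlantedIts(
                taxa=("Kin1", "Kin2"),
                region_index=2 * i,
                length=(250, 400),
                site_id=f"kITS{i + 1}",
                lineage="kinetoplastid",
            )
            for i in range(n_sites)
        )
    return SimulationConfig(
        seed=seed,
        segment_lengths={"SSU": 500, "ITS1": 80, "5.8S": 120, "ITS2": 100, "LSU": 1000},
        anchor_plan={"SSU": (3, 0), "5.8S": (2, 0), "LSU": (10, 0)},
        planted_its=specs,
        assembly=AssemblyModel(n_decoys=25, decoy_length=2000, flank=150),
    )


# ---------------------------------------------------------------------------
# Template construction

@dataclass
class TemplateBundle:
    record: SequenceRecord
    helix_map: HelixMap
    segments: dict[str, tuple[int, int]]
    classes: list[int]  # per template position, _CLS_CODE values


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def build_template(config: SimulationConfig, rng: np.random.Generator) -> TemplateBundle:
    """Deterministically build the template operon and its helix map.

    Core anchors are local hairpins — a random stem, a loop, and the
    stem's reverse complement — so the folding engine recovers at least
    stem-length base pairs from any anchor's extent.  Anchors are spread
    evenly inside their segment; everything between anchors is divergent
    (ES-class) sequence, and ITS1/ITS2 are spacer-class.
    """
    config.validate()
    seq_parts: list[str] = []
    classes: list[int] = []
    segments: dict[str, tuple[int, int]] = {}
    anchors: list[HelixAnchor] = []
    pos = 0
    core_n = 0
    es_n = 0
    core_len = 2 * config.core_stem + config.core_loop
    for seg in ("SSU", "ITS1", "5.8S", "ITS2", "LSU"):
        length = config.segment_lengths[seg]
        seg_start = pos
        if seg in ("ITS1", "ITS2"):
            seq_parts.append(_random_seq(rng, length))
            classes.extend([_CLS_CODE["spacer"]] * length)
            pos += length
        else:
            n_core, n_es = config.anchor_plan.get(seg, (0, 0))
            kinds = ["core"] * n_core
            # interleave ES anchors as evenly as possible
            for i in range(n_es):
                kinds.insert((i + 1) * (n_core // (n_es + 1) + 1), "ES")
            total_anchor = n_core * core_len + n_es * config.es_anchor_len
            n_gaps = len(kinds) + 1
            gap_base, extra = divmod(length - total_anchor, n_gaps)
            for i, kind in enumerate(kinds):
                gap = gap_base + (1 if i < extra else 0)
                seq_parts.append(_random_seq(rng, gap))
                classes.extend([_CLS_CODE["ES"]] * gap)
                pos += gap
                if kind == "core":
                    core_n += 1
                    stem = _random_seq(rng, config.core_stem)
                    loop = _random_seq(rng, config.core_loop)
                    seq_parts.append(stem + loop + formats.revcomp(stem))
                    classes.extend([_CLS_CODE["core"]] * core_len)
                    anchors.append(
                        HelixAnchor(
                            name=f"H{core_n}",
                            cls="core",
                            fp=(pos, pos + config.core_stem),
                            tp=(pos + config.core_stem + config.core_loop, pos + core_len),
                        )
                    )
                    pos += core_len
                else:
                    es_n += 1
                    seq_parts.append(_random_seq(rng, config.es_anchor_len))
                    classes.extend([_CLS_CODE["ES"]] * config.es_anchor_len)
                    anchors.append(
                        HelixAnchor(
                            name=f"ES{es_n}",
                            cls="ES",
                            fp=(pos, pos + config.es_anchor_len),
                        )
                    )
                    pos += config.es_anchor_len
            tail = length - (pos - seg_start)
            seq_parts.append(_random_seq(rng, tail))
            classes.extend([_CLS_CODE["ES"]] * tail)
            pos += tail
        segments[seg] = (seg_start, pos)
    residues = "".join(seq_parts)
    record = SequenceRecord(TEMPLATE_ID, residues)
    helix_map = HelixMap(
        template_id=TEMPLATE_ID, anchors=anchors, template_length=len(residues)
    )
    return TemplateBundle(record, helix_map, segments, classes)


# ---------------------------------------------------------------------------
# Evolution on a tree

def evolve_on_tree(
    template: TemplateBundle,
    tree: dendropy.Tree,
    rates: Mapping[str, float],
    indel_rate: float,
    indel_mean_len: float,
    rng: np.random.Generator,
) -> Msa:
    """Evolve the template along the tree; return the TRUE alignment.

    A single-parameter substitution process (equal exchangeabilities,
    uniform base frequencies) acts per site with a per-class rate
    multiplier; the per-branch change probability at class rate ``r``
    and branch length ``t`` is ``3/4 (1 - exp(-4/3 r t))``.  Indels
    (insertions and deletions, geometric lengths) occur only in ES and
    spacer classes; insertions open gap columns in all other rows, so
    the emitted alignment is exact by construction.  The unevolved
    template is kept as a row, which keeps the helix map's template
    coordinates valid for the alignment.
    """
    rate_of = np.array([rates["core"], rates["ES"], rates["spacer"]])
    rows: dict[str, list[str]] = {TEMPLATE_ID: list(template.record.residues)}
    classes: list[int] = list(template.classes)

    def mutate(parent: str, child: str, t: float) -> None:
        rows[child] = rows[parent].copy()
        row = rows[child]
        arr = np.array(row)
        codes = np.array(classes)
        is_base = np.isin(arr, _BASES)
        p = 0.75 * (1.0 - np.exp(-4.0 / 3.0 * rate_of[codes] * t))
        hit = is_base & (rng.random(arr.size) < p)
        idx = np.flatnonzero(hit)
        if idx.size:
            base_idx = np.searchsorted(_BASES, arr[idx])
            new_idx = (base_idx + rng.integers(1, 4, size=idx.size)) % 4
            arr[idx] = _BASES[new_idx]
            for i, ch in zip(idx, arr[idx]):
                row[i] = str(ch)
        # indels in divergent/spacer sites only
        def eligible() -> np.ndarray:
            a = np.array(row)
            c = np.array(classes)
            return np.flatnonzero(np.isin(a, _BASES) & np.isin(c, (1, 2)))

        elig = eligible()
        n_events = rng.poisson(indel_rate * t * elig.size) if elig.size else 0
        for _ in range(n_events):
            elig = eligible()
            if elig.size == 0:
                break
            L = min(int(rng.geometric(1.0 / indel_mean_len)), 50)
            anchor_pos = int(elig[rng.integers(elig.size)])
            if rng.random() < 0.5:  # deletion: gaps in this row only
                c, done = anchor_pos, 0
                while c < len(row) and done < L:
                    if classes[c] in (1, 2) and row[c] != "-":
                        row[c] = "-"
                        done += 1
                    c += 1
            else:  # insertion: new columns, gaps everywhere else
                ins = list(_random_seq(rng, L))
                cls = classes[anchor_pos]
                at = anchor_pos + 1
                for name, other in rows.items():
                    other[at:at] = ins if name == child else ["-"] * L
                classes[at:at] = [cls] * L

    counter = [0]

    def name_of(node: dendropy.Node) -> str:
        if node.is_leaf():
            return node.taxon.label
        counter[0] += 1
        return f"_internal{counter[0]}"

    node_names: dict[int, str] = {id(tree.seed_node): TEMPLATE_ID}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        child_name = name_of(node)
        node_names[id(node)] = child_name
        parent_name = node_names[id(node.parent_node)]
        t = node.edge.length or 0.0
        mutate(parent_name, child_name, t)

    leaf_names = [lf.taxon.label for lf in tree.leaf_node_iter()]
    records = [SequenceRecord(TEMPLATE_ID, "".join(rows[TEMPLATE_ID]))]
    records += [SequenceRecord(name, "".join(rows[name])) for name in leaf_names]
    return Msa(records)


# ---------------------------------------------------------------------------
# Planting ITSs

@dataclass
class PlantedBlock:
    site_id: str | None
    lineage: str
    region_id: tuple[str, str]
    domain: str
    taxa: tuple[str, ...]
    length: int
    intervals: dict[str, tuple[int, int]] = field(default_factory=dict)


def _segment_regions(
    helix_map: HelixMap, segments: Mapping[str, tuple[int, int]], segment: str
) -> list[tuple[HelixAnchor, HelixAnchor]]:
    s, e = segments[segment]
    inside = [a for a in helix_map.anchors if s <= a.extent[0] and a.extent[1] <= e]
    return list(zip(inside, inside[1:]))


def plant_its(
    msa: Msa,
    helix_map: HelixMap,
    segments: Mapping[str, tuple[int, int]],
    specs: Sequence[PlantedIts],
    rng: np.random.Generator,
) -> tuple[Msa, list[PlantedBlock]]:
    """Insert random-composition blocks at region midpoints of target taxa.

    One insert sequence is drawn per spec and placed in the same new
    alignment columns for every target taxon (within-lineage ITSs at one
    site are homologous); non-target rows, including the template, get
    gap columns, so template coordinates remain valid.  The returned
    truth blocks record each taxon's exact unaligned interval.
    """
    rows = {rec.id: list(rec.residues) for rec in msa.records}
    template_row = rows[helix_map.template_id]
    blocks: list[PlantedBlock] = []
    placements: list[tuple[int, int, PlantedBlock]] = []  # (column, length, block)
    for spec in specs:
        regions = _segment_regions(helix_map, segments, spec.segment)
        if spec.region_index >= len(regions):
            raise ValueError(
                f"segment {spec.segment} has only {len(regions)} inter-anchor "
                f"regions; spec asks for index {spec.region_index}"
            )
        left, right = regions[spec.region_index]
        midpoint = (left.extent[1] + right.extent[0]) // 2
        # the template row is re-scanned each time, so earlier insertions
        # (already gap columns in it) are automatically accounted for
        col_of = np.flatnonzero(np.array(template_row) != "-")
        col = int(col_of[midpoint])
        L = int(rng.integers(spec.length[0], spec.length[1] + 1))
        ins = list(_random_seq(rng, L))
        for name, row in rows.items():
            row[col:col] = ins if name in spec.taxa else ["-"] * L
        for i, (pcol, plen, blk) in enumerate(placements):
            if pcol >= col:
                placements[i] = (pcol + L, plen, blk)
        block = PlantedBlock(
            site_id=spec.site_id,
            lineage=spec.lineage,
            region_id=(left.name, right.name),
            domain=spec.segment,
            taxa=spec.taxa,
            length=L,
        )
        placements.append((col, L, block))
        blocks.append(block)
    # final unaligned intervals per carrier taxon
    for col, L, block in placements:
        for taxon in block.taxa:
            arr = np.array(rows[taxon][:col])
            start = int(np.sum(arr != "-"))
            block.intervals[taxon] = (start, start + L)
    new_msa = Msa([SequenceRecord(r.id, "".join(rows[r.id])) for r in msa.records])
    return new_msa, blocks


def registry_from_blocks(blocks: Sequence[PlantedBlock]) -> ItsSiteRegistry:
    entries = [
        ItsSite(b.site_id, b.lineage, b.region_id, b.domain)
        for b in blocks
        if b.site_id is not None
    ]
    return ItsSiteRegistry(entries)


# ---------------------------------------------------------------------------
# Assembly emulation

def make_assembly(
    operons: Mapping[str, str],
    model: AssemblyModel,
    rng: np.random.Generator,
) -> tuple[list[SequenceRecord], CoverageTable, dict[str, str]]:
    """Emit one SPAdes-style contig per operon plus low-coverage decoys.

    rDNA contigs carry ``baseline * rdna_multiplier`` depth; decoys are
    random sequence at jittered baseline depth and dominate the assembly
    length, as the single-copy fraction of a genome does.  Returns the
    contigs, the coverage table parsed back from the headers, and the
    truth map contig-id -> taxon for the rDNA contigs.
    """
    contigs: list[SequenceRecord] = []
    rdna: dict[str, str] = {}
    node = 0
    for taxon in sorted(operons):
        node += 1
        seq = (
            _random_seq(rng, model.flank) + operons[taxon] + _random_seq(rng, model.flank)
        )
        depth = model.baseline_depth * model.rdna_multiplier
        cid = f"NODE_{node}_length_{len(seq)}_cov_{depth:.1f}"
        contigs.append(SequenceRecord(cid, seq))
        rdna[cid] = taxon
    for _ in range(model.n_decoys):
        node += 1
        length = int(model.decoy_length * rng.uniform(0.7, 1.3))
        depth = model.baseline_depth * rng.uniform(
            1.0 - model.depth_jitter, 1.0 + model.depth_jitter
        )
        cid = f"NODE_{node}_length_{length}_cov_{depth:.1f}"
        contigs.append(SequenceRecord(cid, _random_seq(rng, length)))
    cov = parse_coverage(contigs)
    return contigs, cov, rdna


# ---------------------------------------------------------------------------
# Bundles

@dataclass
class Bundle:
    config: SimulationConfig
    template: TemplateBundle
    tree: dendropy.Tree
    msa: Msa
    blocks: list[PlantedBlock]
    registry: ItsSiteRegistry
    operons: dict[str, str]
    contigs: list[SequenceRecord]
    coverage: CoverageTable
    rdna_contigs: dict[str, str]
    domains: dict[tuple[str, str], str]

    def taxa(self) -> list[str]:
        return [r.id for r in self.msa.records if r.id != TEMPLATE_ID]

    def truth_its(self) -> set[tuple[str, tuple[str, str]]]:
        """Planted (species, region) pairs that are true additional ITSs
        (LSU-domain plants; SSU plants are expansion segments, not ITSs)."""
        out = set()
        for b in self.blocks:
            if b.domain == "LSU":
                for t in b.taxa:
                    out.add((t, b.region_id))
        return out


def generate_bundle(config: SimulationConfig, outdir: str | Path | None = None) -> Bundle:
    """Run the full generator; optionally write the bundle to ``outdir``.

    Emitted files: per-species operon FASTA, true MSA FASTA, helix map
    TSV, site registry TSV, reference (template) FASTA + segment bounds
    TSV, assembly FASTA, coverage TSV, newick tree, truth JSON, and the
    config echo.  Byte-identical across runs with the same config.
    """
    rng = np.random.default_rng(config.seed)
    template = build_template(config, rng)
    tree = dendropy.Tree.get(data=config.tree, schema="newick")
    msa0 = evolve_on_tree(
        template, tree, config.rates, config.indel_rate, config.indel_mean_len, rng
    )
    msa, blocks = plant_its(msa0, template.helix_map, template.segments,
                            config.planted_its, rng)
    registry = registry_from_blocks(blocks)
    operons = {
        rec.id: rec.degapped for rec in msa.records if rec.id != TEMPLATE_ID
    }
    contigs, coverage, rdna = make_assembly(operons, config.assembly, rng)
    domains = region_domains(template.helix_map, template.segments)
    bundle = Bundle(
        config=config,
        template=template,
        tree=tree,
        msa=msa,
        blocks=blocks,
        registry=registry,
        operons=operons,
        contigs=contigs,
        coverage=coverage,
        rdna_contigs=rdna,
        domains=domains,
    )
    if outdir is not None:
        write_bundle(bundle, outdir)
    return bundle


def _truth_dict(bundle: Bundle) -> dict:
    seg_bounds = {}
    tmpl_row = bundle.msa.row(TEMPLATE_ID).residues
    col_of = np.flatnonzero(np.frombuffer(tmpl_row.encode(), dtype="S1") != b"-")
    for rec in bundle.msa.records:
        if rec.id == TEMPLATE_ID:
            continue
        nongap = np.frombuffer(rec.residues.encode(), dtype="S1") != b"-"
        pre = np.concatenate([[0], np.cumsum(nongap)])
        seg_bounds[rec.id] = {
            seg: [int(pre[col_of[s]]), int(pre[col_of[e - 1] + 1])]
            for seg, (s, e) in bundle.template.segments.items()
        }
    return {
        "planted_its": [
            {
                "site_id": b.site_id,
                "lineage": b.lineage,
                "region": list(b.region_id),
                "domain": b.domain,
                "length": b.length,
                "intervals": {t: list(v) for t, v in sorted(b.intervals.items())},
            }
            for b in bundle.blocks
        ],
        "segment_bounds": seg_bounds,
        "rdna_contigs": bundle.rdna_contigs,
    }


def write_bundle(bundle: Bundle, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "operons": outdir / "operons.fasta",
        "msa": outdir / "msa.fasta",
        "helix_map": outdir / "helix_map.tsv",
        "registry": outdir / "registry.tsv",
        "reference": outdir / "reference.fasta",
        "reference_segments": outdir / "reference_segments.tsv",
        "assembly": outdir / "assembly.fasta",
        "coverage": outdir / "coverage.tsv",
        "tree": outdir / "tree.nwk",
        "truth": outdir / "truth.json",
        "config": outdir / "config.json",
    }
    formats.write_fasta(
        [SequenceRecord(t, s) for t, s in sorted(bundle.operons.items())],
        paths["operons"],
    )
    formats.write_msa(bundle.msa, paths["msa"])
    formats.write_helix_map(bundle.template.helix_map, paths["helix_map"])
    write_registry(bundle.registry, paths["registry"])
    formats.write_fasta([bundle.template.record], paths["reference"])
    with open(paths["reference_segments"], "w") as fh:
        for seg, (s, e) in bundle.template.segments.items():
            fh.write(f"{seg}\t{s}\t{e}\n")
    formats.write_fasta(bundle.contigs, paths["assembly"])
    formats.write_coverage(bundle.coverage, paths["coverage"])
    paths["tree"].write_text(bundle.config.tree + "\n")
    paths["truth"].write_text(json.dumps(_truth_dict(bundle), indent=1, sort_keys=True))
    cfg = asdict(bundle.config)
    paths["config"].write_text(json.dumps(cfg, indent=1, sort_keys=True, default=str))
    return paths


def bundle_digest(outdir: str | Path) -> dict[str, str]:
    """SHA-256 of every bundle file (determinism checks)."""
    out = {}
    for p in sorted(Path(outdir).iterdir()):
        if p.is_file():
            out[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out
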