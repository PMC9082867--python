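"""File formats and coordinate conventions.

Everything downstream shares the conventions fixed here:

* internal coordinates are 0-based half-open; GFF3 output is the single
  place where they are converted to 1-based inclusive;
* sequences are stored uppercase with RNA ``U`` normalised to DNA ``T``
  (folding code treats ``T`` as ``U`` again), so rDNA and rRNA views of
  the same molecule coexist;
* IUPAC ambiguity codes other than ``N`` are rejected rather than
  silently remapped — assemblies in scope are unambiguous consensus
  sequences.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """Malformed input file or record."""


_ALLOWED = set("ACGTN-")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def normalize_residues(residues: str) -> str:
    """Uppercase, map U->T, and validate the nucleotide alphabet.

    Gaps (``-``) are permitted so aligned rows pass through the same
    normalisation as unaligned sequences.  Idempotent.
    """
    out = residues.upper().replace("U", "T")
    bad = set(out) - _ALLOWED
    if bad:
        raise FormatError(
            f"unsupported residue(s) {sorted(bad)}; only A/C/G/T/U/N and '-' accepted"
        )
    return out


def revcomp(residues: str) -> str:
    """Reverse complement of a normalized DNA string (gap-free)."""
    return residues.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (possibly aligned, possibly empty)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(ch.isspace() for ch in self.id):
            raise FormatError(f"sequence id must be a non-empty token, got {self.id!r}")
        object.__setattr__(self, "residues", normalize_residues(self.residues))

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def degapped(self) -> str:
        return self.residues.replace("-", "")

    def reverse_complement(self) -> "SequenceRecord":
        return SequenceRecord(self.id, revcomp(self.residues), self.description)


@dataclass
class Msa:
    """A multiple sequence alignment: equal-width rows of gapped residues."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        widths = {len(r.residues) for r in self.records}
        if len(widths) > 1:
            raise FormatError(f"ragged alignment: row widths {sorted(widths)}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate row ids in alignment")
        self._index = {r.id: r for r in self.records}

    @property
    def width(self) -> int:
        return len(self.records[0].residues) if self.records else 0

    def row(self, seq_id: str) -> SequenceRecord:
        try:
            return self._index[seq_id]
        except KeyError:
            raise KeyError(f"no alignment row named {seq_id!r}") from None

    def ids(self) -> list[str]:
        return [r.id for r in self.records]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into normalized records (file order preserved).

    Multi-line sequences are concatenated; ``U`` becomes ``T`` and case is
    folded to upper.  A sequence line appearing before any ``>`` header is
    a :class:`FormatError` naming the offending line number.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FormatError(
                    f"{path.name}:{lineno}: sequence data before first '>' header"
                )
            break
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            SequenceRecord(rec.id, str(rec.seq), rec.description[len(rec.id):].strip())
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    seqs = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def read_msa(path: str | Path) -> Msa:
    return Msa(read_fasta(path))


def write_msa(msa: Msa, path: str | Path) -> None:
    write_fasta(msa.records, path)


# ---------------------------------------------------------------------------
# Coverage

@dataclass
class CoverageTable:
    """Per-contig length (nt) and mean read depth."""

    entries: dict[str, tuple[int, float]]  # id -> (length, depth)

    def __post_init__(self) -> None:
        for cid, (length, depth) in self.entries.items():
            if length <= 0:
                raise FormatError(f"contig {cid}: non-positive length {length}")
            if depth < 0:
                raise FormatError(f"contig {cid}: negative depth {depth}")

    def depth(self, contig_id: str) -> float:
        return self.entries[contig_id][1]

    def length(self, contig_id: str) -> int:
        return self.entries[contig_id][0]

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c, l, d) for c, (l, d) in self.entries.items()],
            columns=["contig", "length", "depth"],
        )


SPADES_HEADER = re.compile(r"^NODE_\d+_length_(\d+)_cov_([0-9.eE+-]+)$")


def parse_coverage(
    contigs: Sequence[SequenceRecord] | None = None,
    tsv: str | Path | None = None,
) -> CoverageTable:
    """Build a :class:`CoverageTable` from SPAdes-style headers and/or a TSV.

    The TSV has columns ``contig, depth[, length]`` (no header line).  When
    both sources cover a contig the TSV wins; a contig with neither a
    parsable ``NODE_<i>_length_<L>_cov_<c>`` header nor a TSV row is an
    error listing the offending ids.
    """
    if contigs is None and tsv is None:
        raise ValueError("need contigs and/or a coverage TSV")
    table: dict[str, tuple[int, float]] = {}
    lengths_from_seq: dict[str, int] = {}
    unresolved: list[str] = []
    if contigs is not None:
        for rec in contigs:
            lengths_from_seq[rec.id] = len(rec.residues)
            m = SPADES_HEADER.match(rec.id)
            if m:
                table[rec.id] = (int(m.group(1)), float(m.group(2)))
            else:
                unresolved.append(rec.id)
    if tsv is not None:
        df = pd.read_csv(tsv, sep="\t", header=None, comment="#")
        if df.shape[1] not in (2, 3):
            raise FormatError(
                f"coverage TSV must have 2 or 3 columns, found {df.shape[1]}"
            )
        for row in df.itertuples(index=False):
            cid = str(row[0])
            depth = float(row[1])
            if df.shape[1] == 3:
                length = int(row[2])
            elif cid in lengths_from_seq:
                length = lengths_from_seq[cid]
            else:
                raise FormatError(
                    f"coverage TSV row for {cid!r} lacks a length and the contig "
                    "sequence was not supplied"
                )
            table[cid] = (length, depth)
        unresolved = [c for c in unresolved if c not in table]
    if unresolved:
        raise FormatError(
            "contig(s) with neither SPAdes-style header nor TSV coverage row: "
            + ", ".join(unresolved)
        )
    return CoverageTable(table)


def write_coverage(cov: CoverageTable, path: str | Path) -> None:
    cov.to_frame()[["contig", "depth", "length"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# Helix map TSV

def read_helix_map(path: str | Path, template_id: str = "template"):
    """Read a helix-anchor TSV into a validated HelixMap.

    Columns: ``helix_name  class  fp_start  fp_end  tp_start  tp_end``
    (0-based half-open template coordinates; ``tp_*`` empty for
    single-strand anchors).  Lines starting with ``#`` are comments.
    """
    from .structure_map import HelixAnchor, HelixMap  # deferred: avoid cycle

    anchors = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"helix map line {lineno}: expected >=4 columns")
            name, cls = parts[0], parts[1]
            fp = (int(parts[2]), int(parts[3]))
            tp = None
            if len(parts) >= 6 and parts[4] != "" and parts[5] != "":
                tp = (int(parts[4]), int(parts[5]))
            anchors.append(HelixAnchor(name=name, cls=cls, fp=fp, tp=tp))
    anchors.sort(key=lambda a: a.fp[0])
    return HelixMap(template_id=template_id, anchors=anchors)


def write_helix_map(helix_map, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# helix_name\tclass\tfp_start\tfp_end\ttp_start\ttp_end\n")
        for a in helix_map.anchors:
            tp = (str(a.tp[0]), str(a.tp[1])) if a.tp is not None else ("", "")
            fh.write(f"{a.name}\t{a.cls}\t{a.fp[0]}\t{a.fp[1]}\t{tp[0]}\t{tp[1]}\n")


# ---------------------------------------------------------------------------
# GFF3

_GFF_TYPE = {
    "SSU": "rRNA_18S_rRNA",
    "ITS1": "internal_transcribed_spacer",
    "5.8S": "rRNA_5_8S_rRNA",
    "ITS2": "internal_transcribed_spacer",
    "LSU": "rRNA_28S_rRNA",
    "IGR": "intergenic_region",
}
_GFF_TYPE_BACK = {
    ("rRNA_18S_rRNA", None): "SSU",
    ("rRNA_5_8S_rRNA", None): "5.8S",
    ("rRNA_28S_rRNA", None): "LSU",
    ("intergenic_region", None): "IGR",
}


def write_gff3(annotations, path: str | Path, source: str = "itscan") -> None:
    """Write operon annotations as GFF3 (1-based inclusive coordinates).

    Each annotation becomes an ``operon`` parent feature spanning its
    segments, with one child feature per segment.  Ordering is
    deterministic: (contig id, operon start).  Empty intervals are
    rejected — an empty segment cannot be represented in the inclusive
    convention.
    """
    annotations = sorted(
        annotations,
        key=lambda a: (a.contig_id, min(s for s, _ in a.segments.values())),
    )
    lines = ["##gff-version 3"]
    counter: dict[str, int] = {}
    for ann in annotations:
        for name, (s, e) in ann.segments.items():
            if e <= s:
                raise FormatError(
                    f"segment {name} on {ann.contig_id}: empty/inverted interval "
                    f"[{s},{e}) cannot be written as GFF3"
                )
        counter[ann.contig_id] = counter.get(ann.contig_id, 0) + 1
        op_id = f"operon_{ann.contig_id}_{counter[ann.contig_id]}"
        start = min(s for s, _ in ann.segments.values())
        end = max(e for _, e in ann.segments.values())
        lines.append(
            "\t".join(
                [ann.contig_id, source, "operon", str(start + 1), str(end),
                 ".", ann.strand, ".", f"ID={op_id}"]
            )
        )
        for name, (s, e) in sorted(ann.segments.items(), key=lambda kv: kv[1][0]):
            attrs = f"ID={op_id}.{name};Parent={op_id};segment={name}"
            lines.append(
                "\t".join(
                    [ann.contig_id, source, _GFF_TYPE[name], str(s + 1), str(e),
                     ".", ann.strand, ".", attrs]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[dict]:
    """Parse GFF3 written by :func:`write_gff3` back to internal coordinates.

    Returns one dict per operon: ``{"contig_id", "strand", "segments"}``
    with 0-based half-open segment intervals.
    """
    operons: dict[str, dict] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise FormatError(f"malformed GFF3 line: {line!r}")
        contig, _src, ftype, start, end, _score, strand, _phase, attrs = cols
        attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
        if ftype == "operon":
            operons[attr["ID"]] = {"contig_id": contig, "strand": strand, "segments": {}}
        else:
            parent = attr["Parent"]
            seg = attr.get("segment")
            operons[parent]["segments"][seg] = (int(start) - 1, int(end))
    return list(operons.values())


# ---------------------------------------------------------------------------
# Newick

def read_newick(path_or_text: str | Path) -> dendropy.Tree:
    """Read a single newick tree; duplicate leaf labels are an error.

    Accepts either a path or a literal newick string (detected by the
    presence of ``(`` / ``;``).  Polytomies are allowed.
    """
    text = str(path_or_text)
    if "(" not in text and ";" not in text:
        text = Path(path_or_text).read_text()
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"newick parse error: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise FormatError("duplicate leaf labels in tree")
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)
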