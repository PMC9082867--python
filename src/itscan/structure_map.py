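"""Helix-anchored structure mapping and expansion detection.

Conserved secondary-structure helices (yeast-style numbering) act as
coordinate landmarks: their template coordinates are projected through a
structure-aware multiple alignment onto every sequence, the regions
between consecutive anchors are measured per species, and a region whose
length in a focal species exceeds a background summary by more than a
configurable factor (default 4x, with a 30-nt absolute guard) is flagged
as an expansion — the candidate surface for additional internal
transcribed spacers.

A small base-pair-maximisation folding engine (Watson-Crick + GU wobble,
minimum hairpin loop of 3) is included as a sanity/annotation aid; no
free-energy model is attempted, since structural element boundaries come
from the helix map, not from folding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .formats import Msa, SequenceRecord

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f

        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


ABSENT = None

TERMINUS_5 = "^"
TERMINUS_3 = "$"


@dataclass(frozen=True)
class HelixAnchor:
    """A conserved helix landmark on the template sequence.

    ``fp`` is the 5' strand interval; ``tp``, when present, is the 3'
    strand of the same helix.  The anchor's *extent* spans both strands
    (core helices here are local hairpins, so the extent is contiguous).
    """

    name: str
    cls: str  # "core" | "ES"
    fp: tuple[int, int]
    tp: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.cls not in ("core", "ES"):
            raise ValueError(f"anchor {self.name}: class must be core|ES, got {self.cls!r}")
        if self.fp[1] <= self.fp[0]:
            raise ValueError(f"anchor {self.name}: empty 5' interval {self.fp}")
        if self.tp is not None:
            if self.tp[1] <= self.tp[0]:
                raise ValueError(f"anchor {self.name}: empty 3' interval {self.tp}")
            if self.tp[0] < self.fp[1]:
                raise ValueError(f"anchor {self.name}: 3' strand overlaps 5' strand")

    @property
    def extent(self) -> tuple[int, int]:
        return (self.fp[0], self.tp[1] if self.tp is not None else self.fp[1])


@dataclass
class HelixMap:
    """Ordered helix anchors in template coordinates (0-based half-open)."""

    template_id: str
    anchors: list[HelixAnchor]
    template_length: int | None = None

    def __post_init__(self) -> None:
        names = [a.name for a in self.anchors]
        if len(set(names)) != len(names):
            raise ValueError("duplicate anchor names in helix map")
        prev = None
        for a in self.anchors:
            if prev is not None and a.extent[0] < prev.extent[1]:
                raise ValueError(
                    f"anchors {prev.name} and {a.name} overlap or are out of order"
                )
            prev = a
        if self.template_length is not None and self.anchors:
            if self.anchors[-1].extent[1] > self.template_length:
                raise ValueError("anchor extends past the template sequence")

    def anchor(self, name: str) -> HelixAnchor:
        for a in self.anchors:
            if a.name == name:
                return a
        raise KeyError(name)

    def region_ids(self) -> list[tuple[str, str]]:
        """Canonical inter-anchor region ids, including virtual termini."""
        names = [TERMINUS_5] + [a.name for a in self.anchors] + [TERMINUS_3]
        return list(zip(names, names[1:]))


@dataclass
class AnchorProjection:
    """Per-(sequence, anchor) intervals in unaligned sequence coordinates."""

    anchor_names: list[str]
    intervals: dict[str, dict[str, tuple[int, int] | None]]  # seq -> anchor -> ival
    seq_lengths: dict[str, int]

    def interval(self, seq_id: str, anchor: str) -> tuple[int, int] | None:
        return self.intervals[seq_id][anchor]


@dataclass(frozen=True)
class InterAnchorRegion:
    species: str
    region_id: tuple[str, str]
    interval: tuple[int, int]
    length: int
    domain: str | None = None
    skipped: tuple[str, ...] = ()


@dataclass(frozen=True)
class ExpansionSegment:
    species: str
    region_id: tuple[str, str]
    interval: tuple[int, int]
    length: int
    background_stat: float
    factor: float


@dataclass
class ExpansionReport:
    expansions: list[ExpansionSegment]
    skipped: list[tuple[tuple[str, str], str]]  # (region_id, reason)


def _gap_prefix(row: str) -> np.ndarray:
    """pre[c] = number of non-gap characters strictly before column c."""
    arr = np.frombuffer(row.encode(), dtype="S1") != b"-"
    return np.concatenate([[0], np.cumsum(arr)])


def project_anchors(msa: Msa, helix_map: HelixMap) -> AnchorProjection:
    """Project template anchor extents through the alignment onto every row.

    The template's gap pattern converts template coordinates to alignment
    columns; each row's prefix count of non-gap characters converts the
    columns to that row's unaligned coordinates.  An anchor fully gapped
    in a row is ABSENT (None).  Self-projection of the template
    reproduces the helix map exactly.
    """
    template = msa.row(helix_map.template_id)
    degapped = template.degapped
    if helix_map.template_length is not None and len(degapped) != helix_map.template_length:
        raise ValueError(
            f"de-gapped template row has length {len(degapped)}; helix map "
            f"expects {helix_map.template_length}"
        )
    if helix_map.anchors and helix_map.anchors[-1].extent[1] > len(degapped):
        raise ValueError("helix map coordinates exceed the de-gapped template row")
    col_of = np.flatnonzero(
        np.frombuffer(template.residues.encode(), dtype="S1") != b"-"
    )
    intervals: dict[str, dict[str, tuple[int, int] | None]] = {}
    seq_lengths: dict[str, int] = {}
    for rec in msa.records:
        pre = _gap_prefix(rec.residues)
        per: dict[str, tuple[int, int] | None] = {}
        for a in helix_map.anchors:
            s, e = a.extent
            c1, c2 = int(col_of[s]), int(col_of[e - 1]) + 1
            lo, hi = int(pre[c1]), int(pre[c2])
            per[a.name] = (lo, hi) if hi > lo else ABSENT
        intervals[rec.id] = per
        seq_lengths[rec.id] = int(pre[-1])
    return AnchorProjection(
        anchor_names=[a.name for a in helix_map.anchors],
        intervals=intervals,
        seq_lengths=seq_lengths,
    )


def interanchor_lengths(
    proj: AnchorProjection,
    msa: Msa | None = None,
    domains: Mapping[tuple[str, str], str] | None = None,
) -> list[InterAnchorRegion]:
    """Per-row gaps between consecutive present anchors (plus termini).

    Anchors ABSENT in a row are bridged to the next present anchor and
    recorded in ``skipped``; per row, anchor lengths plus region lengths
    sum exactly to the unaligned sequence length.
    """
    regions: list[InterAnchorRegion] = []
    domains = domains or {}
    for seq_id, per in proj.intervals.items():
        seq_len = proj.seq_lengths[seq_id]
        cursor = 0
        left = TERMINUS_5
        skipped: list[str] = []
        for name in proj.anchor_names:
            ival = per[name]
            if ival is ABSENT:
                skipped.append(name)
                continue
            rid = (left, name)
            regions.append(
                InterAnchorRegion(
                    species=seq_id,
                    region_id=rid,
                    interval=(cursor, ival[0]),
                    length=ival[0] - cursor,
                    domain=domains.get(rid),
                    skipped=tuple(skipped),
                )
            )
            cursor = ival[1]
            left = name
            skipped = []
        rid = (left, TERMINUS_3)
        regions.append(
            InterAnchorRegion(
                species=seq_id,
                region_id=rid,
                interval=(cursor, seq_len),
                length=seq_len - cursor,
                domain=domains.get(rid),
                skipped=tuple(skipped),
            )
        )
    return regions


def region_domains(
    helix_map: HelixMap, segments: Mapping[str, tuple[int, int]]
) -> dict[tuple[str, str], str]:
    """Assign each canonical inter-anchor region a domain.

    ``segments`` maps SSU/ITS1/5.8S/ITS2/LSU (and optionally IGR) to
    template intervals.  A region overlapping a spacer segment is
    ``spacer``; otherwise it inherits the rRNA segment containing it.
    """
    spacers = {"ITS1", "ITS2", "IGR"}
    out: dict[tuple[str, str], str] = {}
    bounds = {a.name: a.extent for a in helix_map.anchors}
    total = helix_map.template_length or (
        helix_map.anchors[-1].extent[1] if helix_map.anchors else 0
    )
    for left, right in helix_map.region_ids():
        lo = 0 if left == TERMINUS_5 else bounds[left][1]
        hi = total if right == TERMINUS_3 else bounds[right][0]
        domain = None
        for name, (s, e) in segments.items():
            if s <= lo and hi <= e:
                domain = "spacer" if name in spacers else name
                break
        if domain is None:
            # region straddles a segment boundary -> it contains spacer sequence
            overlap_spacer = any(
                name in spacers and s < hi and lo < e
                for name, (s, e) in segments.items()
            )
            if overlap_spacer or hi <= lo:
                domain = "spacer"
            else:
                best = max(
                    segments.items(),
                    key=lambda kv: min(hi, kv[1][1]) - max(lo, kv[1][0]),
                )
                domain = "spacer" if best[0] in spacers else best[0]
        out[(left, right)] = domain
    return out


def detect_expansions(
    regions: Sequence[InterAnchorRegion],
    focal: Iterable[str],
    background: Iterable[str],
    factor: float = 4.0,
    min_abs: int = 30,
    stat: str = "median",
) -> ExpansionReport:
    """Flag focal regions much longer than the cross-species background.

    A focal species is flagged in a region iff its region length exceeds
    ``factor`` times the background summary statistic AND the absolute
    excess is at least ``min_abs`` nt (which keeps the scale-free rule
    from firing on near-zero regions).  The background statistic is the
    median by default — robust when one background lineage also carries
    an insertion at the same site; ``max`` gives the strictest reading.
    Regions with fewer than two background species present are skipped
    and reported.
    """
    focal = set(focal)
    background = set(background)
    if focal & background:
        raise ValueError("focal and background species sets must be disjoint")
    by_region: dict[tuple[str, str], dict[str, InterAnchorRegion]] = {}
    for r in regions:
        by_region.setdefault(r.region_id, {})[r.species] = r
    expansions: list[ExpansionSegment] = []
    skipped: list[tuple[tuple[str, str], str]] = []
    for rid in sorted(by_region):
        present = by_region[rid]
        bg = sorted(present[sp].length for sp in background if sp in present)
        if len(bg) < 2:
            skipped.append((rid, f"background has {len(bg)} species with this region"))
            continue
        if stat == "median":
            bg_stat = float(np.median(bg))
        elif stat == "max":
            bg_stat = float(max(bg))
        elif stat == "mean":
            bg_stat = float(np.mean(bg))
        else:
            raise ValueError(f"unknown background statistic {stat!r}")
        for sp in sorted(focal):
            if sp not in present:
                continue
            reg = present[sp]
            if reg.length > factor * bg_stat and reg.length - bg_stat >= min_abs:
                expansions.append(
                    ExpansionSegment(
                        species=sp,
                        region_id=rid,
                        interval=reg.interval,
                        length=reg.length,
                        background_stat=bg_stat,
                        factor=(reg.length / bg_stat) if bg_stat > 0 else math.inf,
                    )
                )
    return ExpansionReport(expansions=expansions, skipped=skipped)


# ---------------------------------------------------------------------------
# Folding (base-pair maximisation)

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}
# admissible pairs: AU, UA, GC, CG, GU, UG
_PAIRS = np.zeros((5, 5), dtype=np.uint8)
for _a, _b in [(0, 3), (3, 0), (2, 1), (1, 2), (2, 3), (3, 2)]:
    _PAIRS[_a, _b] = 1

_MIN_LOOP = 3


@njit(cache=True)
def _nussinov_fill(enc: np.ndarray, pairs: np.ndarray, min_loop: int) -> np.ndarray:
    n = enc.shape[0]
    dp = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i + 1, j]
            for k in range(i + min_loop + 1, j + 1):
                if pairs[enc[i], enc[k]]:
                    inner = dp[i + 1, k - 1] if k - 1 >= i + 1 else 0
                    right = dp[k + 1, j] if k + 1 <= j else 0
                    cand = 1 + inner + right
                    if cand > best:
                        best = cand
            dp[i, j] = best
    return dp


@dataclass(frozen=True)
class FoldResult:
    structure: str  # dot-bracket, same length as the input
    pairs: int

    @property
    def pair_density(self) -> float:
        return 2.0 * self.pairs / len(self.structure) if self.structure else 0.0


def fold_region(seq: SequenceRecord | str, engine: str = "internal") -> FoldResult:
    """Maximum base pairing of a sequence with deterministic traceback.

    Internal engine: Nussinov-style dynamic programme over Watson-Crick
    plus GU pairs with a minimum hairpin loop of 3 unpaired bases; ties
    resolve by preferring position i unpaired, then the smallest pairing
    partner, so the dot-bracket output is reproducible.  DNA ``T`` is
    treated as ``U``; ``N`` never pairs.
    """
    if engine != "internal":
        raise ValueError(f"unknown folding engine {engine!r}")
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    if len(residues) == 0:
        raise ValueError("cannot fold an empty sequence")
    try:
        enc = np.array([_ENC[c] for c in residues.upper().replace("U", "T")],
                       dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"non-nucleotide residue {exc} in folding input") from None
    n = len(enc)
    dp = _nussinov_fill(enc, _PAIRS, _MIN_LOOP)
    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= _MIN_LOOP:
            continue
        if dp[i, j] == dp[i + 1, j]:
            stack.append((i + 1, j))
            continue
        for k in range(i + _MIN_LOOP + 1, j + 1):
            if _PAIRS[enc[i], enc[k]]:
                inner = dp[i + 1, k - 1] if k - 1 >= i + 1 else 0
                right = dp[k + 1, j] if k + 1 <= j else 0
                if dp[i, j] == 1 + inner + right:
                    structure[i] = "("
                    structure[k] = ")"
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    break
    return FoldResult(structure="".join(structure), pairs=int(dp[0, n - 1]))
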