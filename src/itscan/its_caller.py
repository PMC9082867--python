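"""Classifying expansion segments as additional ITSs.

An expansion flagged by the length rule is classified by a fixed rule
order: (1) its inter-anchor region matches a registry of known
additional-ITS sites -> a known ITS call citing that site; (2) else the
region lies in the SSU (18S) domain -> an SSU expansion segment, never
an ITS (18S expansions are retained in the mature rRNA); (3) else
(5.8S/LSU domain) -> a novel ITS candidate.  Calls carry evidence —
length factor, ORF content, cross-ITS homology, folding pair density —
used for reporting, not for the classification itself.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats import SequenceRecord, revcomp
from .operon_finder import ScoringParams, _aligner
from .structure_map import ExpansionSegment

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class ItsSite:
    site_id: str  # e.g. "eITS10", "kITS5"
    lineage: str  # "euglenid" | "kinetoplastid" | "other"
    region_id: tuple[str, str]
    domain: str | None = None  # "LSU" for 28S sites, "spacer" for 5.8S-flanking


@dataclass
class ItsSiteRegistry:
    entries: list[ItsSite]

    def __post_init__(self) -> None:
        ids = [e.site_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate site ids in registry")
        self._by_region: dict[tuple[str, str], list[ItsSite]] = {}
        for e in self.entries:
            self._by_region.setdefault(e.region_id, []).append(e)

    def sites_at(self, region_id: tuple[str, str]) -> list[ItsSite]:
        return sorted(self._by_region.get(region_id, []), key=lambda s: s.site_id)

    def __len__(self) -> int:
        return len(self.entries)


def read_registry(path: str | Path) -> ItsSiteRegistry:
    """Registry TSV: ``site_id  lineage  left_anchor  right_anchor  [domain]``."""
    entries = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        domain = parts[4] if len(parts) > 4 and parts[4] else None
        entries.append(
            ItsSite(parts[0], parts[1], (parts[2], parts[3]), domain)
        )
    return ItsSiteRegistry(entries)


def write_registry(reg: ItsSiteRegistry, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# site_id\tlineage\tleft_anchor\tright_anchor\tdomain\n")
        for e in reg.entries:
            fh.write(
                f"{e.site_id}\t{e.lineage}\t{e.region_id[0]}\t{e.region_id[1]}\t"
                f"{e.domain or ''}\n"
            )


def load_reference_registry() -> ItsSiteRegistry:
    """The curated euglenozoan site registry shipped with the package."""
    text = (resources.files("itscan") / "data" / "its_registry.tsv").read_text()
    entries = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        domain = parts[4] if len(parts) > 4 and parts[4] else None
        entries.append(ItsSite(parts[0], parts[1], (parts[2], parts[3]), domain))
    return ItsSiteRegistry(entries)


@dataclass
class ItsCall:
    species: str
    classification: str  # "known_ITS" | "novel_candidate" | "ssu_expansion"
    region_id: tuple[str, str]
    interval: tuple[int, int]
    length: int
    domain: str
    site_id: str | None = None
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.classification == "known_ITS" and self.site_id is None:
            raise ValueError("known_ITS call must cite a registry site")
        if self.classification == "ssu_expansion" and self.domain != "SSU":
            raise ValueError("ssu_expansion only valid in the SSU domain")
        if self.classification == "novel_candidate" and self.domain not in ("5.8S", "LSU"):
            raise ValueError("novel_candidate only valid in 5.8S/LSU domains")


def classify_expansions(
    expansions: Sequence[ExpansionSegment],
    registry: ItsSiteRegistry,
    domains: Mapping[tuple[str, str], str],
    lineages: Mapping[str, str] | None = None,
) -> list[ItsCall]:
    """Apply the classification rules, in order, to every expansion.

    Classification is total and deterministic: each expansion yields
    exactly one call.  When several registry sites share a region (a
    cross-lineage shared site), the site whose lineage matches the
    species' lineage (from ``lineages``) is cited; without lineage
    information the lexicographically first site id is used.
    """
    lineages = lineages or {}
    calls = []
    for exp in expansions:
        domain = domains.get(exp.region_id)
        if domain is None:
            raise KeyError(f"region {exp.region_id} missing from the domain map")
        if domain == "spacer":
            raise ValueError(
                f"region {exp.region_id} is a spacer (ITS1/ITS2) region; spacer "
                "regions are not classified — exclude them upstream"
            )
        evidence = {
            "factor": exp.factor,
            "background_stat": exp.background_stat,
        }
        sites = registry.sites_at(exp.region_id)
        if sites:
            chosen = next(
                (s for s in sites if s.lineage == lineages.get(exp.species)), sites[0]
            )
            cls, site_id = "known_ITS", chosen.site_id
        elif domain == "SSU":
            cls, site_id = "ssu_expansion", None
        else:
            cls, site_id = "novel_candidate", None
        calls.append(
            ItsCall(
                species=exp.species,
                classification=cls,
                region_id=exp.region_id,
                interval=exp.interval,
                length=exp.length,
                domain=domain,
                site_id=site_id,
                evidence=evidence,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# ORF scanning

@dataclass(frozen=True)
class OrfHit:
    frame: int  # +1,+2,+3,-1,-2,-3
    interval: tuple[int, int]  # on the input (forward) sequence, incl. stop codon
    aa_length: int  # residues incl. initiator Met, excl. stop
    partial: bool  # ran off the sequence end without a stop


def orf_scan(
    seq: SequenceRecord | str,
    min_aa: int = 20,
    both_strands: bool = True,
    require_atg: bool = True,
) -> list[OrfHit]:
    """Scan all reading frames for ORFs strictly longer than ``min_aa``.

    An ORF is ATG ... stop (standard genetic code); an ORF running off
    the sequence end is reported with ``partial=True``.  "Longer than"
    is read strictly: a 20-aa ORF is not reported at the default
    threshold.  With ``require_atg=False`` maximal stop-to-stop open
    frames are reported instead (the initiator convention is not
    universal).  Reverse-frame intervals are mapped back to forward
    coordinates.
    """
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    n = len(residues)
    hits: list[OrfHit] = []
    strands = [(+1, residues)] + ([(-1, revcomp(residues))] if both_strands else [])
    for sign, s in strands:
        for off in range(3):
            frame = sign * (off + 1)
            start: int | None = None if require_atg else off
            i = off
            while i + 3 <= n:
                codon = s[i : i + 3]
                if codon in STOP_CODONS:
                    if start is not None:
                        aa = (i - start) // 3
                        if aa > min_aa:
                            hits.append(_orf(sign, n, start, i + 3, aa, False))
                    start = None if require_atg else i + 3
                elif start is None and require_atg and codon == "ATG":
                    start = i
                i += 3
            if start is not None and start + 3 <= i:
                aa = (i - start) // 3
                if aa > min_aa:
                    hits.append(_orf(sign, n, start, i, aa, True))
    hits.sort(key=lambda h: (h.interval, h.frame))
    return hits


def _orf(sign: int, n: int, start: int, end: int, aa: int, partial: bool) -> OrfHit:
    frame_pos = start % 3 + 1
    if sign > 0:
        return OrfHit(frame=frame_pos, interval=(start, end), aa_length=aa, partial=partial)
    return OrfHit(frame=-frame_pos, interval=(n - end, n - start), aa_length=aa, partial=partial)


# ---------------------------------------------------------------------------
# Cross-ITS homology

def best_local_alignment(
    a: str, b: str, params: ScoringParams = ScoringParams()
) -> tuple[float, float, int]:
    """Best Smith-Waterman score, identity, and aligned length for a pair.

    Identity is identities over aligned (non-gap) columns of the best
    alignment; (0, 0.0, 0) when no positive-scoring alignment exists.
    """
    if not a or not b:
        return 0.0, 0.0, 0
    aligner = _aligner(params)
    alns = aligner.align(a, b)
    if alns.score <= 0:
        return 0.0, 0.0, 0
    best = alns[0]
    c = best.counts()
    cols = c.identities + c.mismatches
    ident = c.identities / cols if cols else 0.0
    return float(best.score), ident, int(cols)


@dataclass
class HomologyMatrix:
    labels: list[str]
    identity: pd.DataFrame
    score: pd.DataFrame
    aligned_len: pd.DataFrame

    def homologous_pairs(
        self, min_identity: float = 0.7, min_len: int = 50
    ) -> list[tuple[str, str]]:
        """Pairs reported as homologous: identity >= 0.7 over >= 50 nt.

        A report threshold only — homology never feeds back into
        classification.
        """
        out = []
        for i, j in itertools.combinations(range(len(self.labels)), 2):
            if (
                self.identity.iat[i, j] >= min_identity
                and self.aligned_len.iat[i, j] >= min_len
            ):
                out.append((self.labels[i], self.labels[j]))
        return out


def cross_its_homology(
    calls: Sequence[ItsCall],
    operon_seqs: Mapping[str, str],
    params: ScoringParams = ScoringParams(),
) -> HomologyMatrix:
    """All-vs-all best local identity between called ITS sequences.

    ``operon_seqs`` maps species to their unaligned operon sequence; the
    ITS sequence of each call is its interval slice.  The matrix is
    symmetric with the diagonal excluded (NaN).
    """
    labels = []
    seqs = []
    for c in calls:
        label = f"{c.species}:{c.site_id or '-'.join(c.region_id)}"
        labels.append(label)
        seqs.append(operon_seqs[c.species][c.interval[0] : c.interval[1]])
    k = len(labels)
    ident = np.full((k, k), np.nan)
    score = np.full((k, k), np.nan)
    alen = np.zeros((k, k))
    for i, j in itertools.combinations(range(k), 2):
        s, d, L = best_local_alignment(seqs[i], seqs[j], params)
        score[i, j] = score[j, i] = s
        ident[i, j] = ident[j, i] = d
        alen[i, j] = alen[j, i] = L
    return HomologyMatrix(
        labels=labels,
        identity=pd.DataFrame(ident, index=labels, columns=labels),
        score=pd.DataFrame(score, index=labels, columns=labels),
        aligned_len=pd.DataFrame(alen, index=labels, columns=labels),
    )


# ---------------------------------------------------------------------------
# Fragmentation summary

def fragment_count(calls: Sequence[ItsCall], species: str, domain: str = "28S") -> int:
    """Number of mature rRNA fragments implied by a species' ITS calls.

    N additional ITSs inside the 28S (LSU) domain cleave the mature rRNA
    into N+1 pieces; zero calls means a contiguous 28S.  SSU expansion
    segments never count — they are retained in the mature 18S.
    """
    domain = "LSU" if domain in ("28S", "LSU") else domain
    n_its = sum(
        1
        for c in calls
        if c.species == species
        and c.domain == domain
        and c.classification in ("known_ITS", "novel_candidate")
    )
    return n_its + 1


def write_calls(calls: Sequence[ItsCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "species\tclassification\tsite_id\tleft_anchor\tright_anchor\t"
            "start\tend\tlength\tdomain\tfactor\tbackground_stat\torf_count\t"
            "max_cross_identity\tpair_density\n"
        )
        for c in calls:
            ev = c.evidence
            factor = ev.get("factor", math.nan)
            fh.write(
                f"{c.species}\t{c.classification}\t{c.site_id or ''}\t"
                f"{c.region_id[0]}\t{c.region_id[1]}\t{c.interval[0]}\t{c.interval[1]}\t"
                f"{c.length}\t{c.domain}\t{factor:.3g}\t{ev.get('background_stat', '')}\t"
                f"{ev.get('orf_count', '')}\t{ev.get('max_cross_identity', '')}\t"
                f"{ev.get('pair_density', '')}\n"
            )


# adapter hooks for external characterisation tools (not reimplemented):
def attach_external_screen(calls: Sequence[ItsCall], table: pd.DataFrame,
                           column: str = "external_hit") -> None:
    """Attach rows of an external screening table (e.g. rRNA-model or
    database searches run outside this package) to call evidence by
    (species, site_id) match.  The table needs ``species`` and
    ``site_id`` columns; remaining columns are stored verbatim."""
    index = {(c.species, c.site_id): c for c in calls}
    for row in table.itertuples(index=False):
        key = (getattr(row, "species"), getattr(row, "site_id"))
        if key in index:
            index[key].evidence.setdefault(column, []).append(row._asdict())
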