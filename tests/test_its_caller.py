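"""Classification rules, six-frame ORF scanning vs a translation oracle,
cross-ITS homology vs a quadratic Smith-Waterman oracle, and fragment
arithmetic."""

import re

import numpy as np
import pytest
from Bio.Seq import Seq

from itscan.formats import SequenceRecord, revcomp
from itscan.its_caller import (
    ItsCall,
    ItsSite,
    ItsSiteRegistry,
    best_local_alignment,
    classify_expansions,
    cross_its_homology,
    fragment_count,
    load_reference_registry,
    orf_scan,
    read_registry,
    write_registry,
)
from itscan.operon_finder import ScoringParams
from itscan.structure_map import ExpansionSegment


def _exp(species="sp", region=("H54", "H55"), length=300, factor=6.2):
    return ExpansionSegment(
        species=species, region_id=region, interval=(1000, 1000 + length),
        length=length, background_stat=length / factor, factor=factor,
    )


REGISTRY = ItsSiteRegistry(
    [
        ItsSite("eITS10", "euglenid", ("H54", "H55"), "LSU"),
        ItsSite("kITS5", "kinetoplastid", ("H54", "H55"), "LSU"),
    ]
)
DOMAINS = {
    ("H54", "H55"): "LSU",
    ("H10", "H11"): "LSU",
    ("S3", "S4"): "SSU",
    ("S6", "h1"): "spacer",
}


class TestClassifyExpansions:
    def test_registry_match_wins(self):
        (call,) = classify_expansions([_exp()], REGISTRY, DOMAINS)
        assert call.classification == "known_ITS"
        assert call.site_id == "eITS10"  # deterministic without lineage info

    def test_lineage_breaks_shared_site_tie(self):
        (call,) = classify_expansions(
            [_exp()], REGISTRY, DOMAINS, lineages={"sp": "kinetoplastid"}
        )
        assert call.site_id == "kITS5"

    def test_ssu_domain_never_its(self):
        (call,) = classify_expansions([_exp(region=("S3", "S4"))], REGISTRY, DOMAINS)
        assert call.classification == "ssu_expansion"
        assert call.site_id is None

    def test_unregistered_lsu_is_novel(self):
        (call,) = classify_expansions([_exp(region=("H10", "H11"))], REGISTRY, DOMAINS)
        assert call.classification == "novel_candidate"
        assert call.evidence["factor"] == pytest.approx(6.2)

    def test_unmapped_region_rejected(self):
        with pytest.raises(KeyError):
            classify_expansions([_exp(region=("X", "Y"))], REGISTRY, DOMAINS)

    def test_spacer_region_rejected(self):
        with pytest.raises(ValueError, match="spacer"):
            classify_expansions([_exp(region=("S6", "h1"))], REGISTRY, DOMAINS)

    def test_total_and_deterministic(self):
        exps = [_exp(), _exp(region=("H10", "H11")), _exp(region=("S3", "S4"))]
        calls1 = classify_expansions(exps, REGISTRY, DOMAINS)
        calls2 = classify_expansions(exps, REGISTRY, DOMAINS)
        assert len(calls1) == len(exps)
        assert [(c.classification, c.site_id) for c in calls1] == [
            (c.classification, c.site_id) for c in calls2
        ]


class TestRegistryIO:
    def test_shipped_registry_counts(self):
        reg = load_reference_registry()
        lsu = [e for e in reg.entries if e.domain == "LSU"]
        assert sum(1 for e in lsu if e.lineage == "euglenid") == 12
        assert sum(1 for e in lsu if e.lineage == "kinetoplastid") == 5

    def test_round_trip(self, tmp_path):
        reg = load_reference_registry()
        p = tmp_path / "reg.tsv"
        write_registry(reg, p)
        back = read_registry(p)
        assert [(e.site_id, e.lineage, e.region_id, e.domain) for e in back.entries] == [
            (e.site_id, e.lineage, e.region_id, e.domain) for e in reg.entries
        ]

    def test_duplicate_site_ids_rejected(self):
        with pytest.raises(ValueError):
            ItsSiteRegistry(
                [ItsSite("x", "euglenid", ("a", "b")), ItsSite("x", "euglenid", ("c", "d"))]
            )


# ---------------------------------------------------------------------------
# ORF scanning

def _orf_oracle(seq, min_aa=20):
    """Six-frame translation + regex Met-to-stop scan (Biopython translation,
    fully independent of the codon-walking implementation)."""
    found = []
    n = len(seq)
    for sign, s in ((+1, seq), (-1, revcomp(seq))):
        for off in range(3):
            trimmed = s[off : off + 3 * ((n - off) // 3)]
            if not trimmed:
                continue
            prot = str(Seq(trimmed).translate())
            for m in re.finditer(r"M[^*]*", prot):
                aa = len(m.group(0))
                stopped = m.end() < len(prot) or prot.endswith("*")
                # regex group excludes '*': a stop right after counts as closed
                has_stop = m.end() < len(prot) and prot[m.end()] == "*"
                if aa > min_aa:
                    start = off + 3 * m.start()
                    end = off + 3 * (m.start() + aa) + (3 if has_stop else 0)
                    if sign > 0:
                        found.append((sign * (start % 3 + 1), (start, end), aa, not has_stop))
                    else:
                        found.append((sign * (start % 3 + 1), (n - end, n - start), aa, not has_stop))
    return sorted(found, key=lambda t: (t[1], t[0]))


class TestOrfScan:
    def test_threshold_is_strict(self):
        seq = "ATG" + "GCT" * 19 + "TAA"  # 20 aa including Met
        assert orf_scan(seq, both_strands=False) == []

    def test_threshold_boundary(self):
        seq = "ATG" + "GCT" * 20 + "TAA"  # 21 aa
        (hit,) = orf_scan(seq, both_strands=False)
        assert hit.frame == 1
        assert hit.aa_length == 21
        assert not hit.partial
        assert hit.interval == (0, len(seq))

    def test_partial_orf_flagged(self):
        seq = "ATG" + "GCT" * 25  # no stop
        (hit,) = [h for h in orf_scan(seq, both_strands=False)]
        assert hit.partial
        assert hit.aa_length == 26

    def test_empty_sequence(self):
        assert orf_scan("") == []

    def test_reverse_frame_coordinates(self):
        core = "ATG" + "GCT" * 22 + "TAA"
        seq = revcomp(core)
        (hit,) = orf_scan(seq)
        assert hit.frame < 0
        s, e = hit.interval
        assert revcomp(seq[s:e]) == core

    @pytest.mark.parametrize("seed", [7] + list(range(20)))
    def test_matches_six_frame_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(60, 601))
        seq = "".join(rng.choice(list("ACGT"), size=n))
        got = sorted(
            (h.frame, h.interval, h.aa_length, h.partial) for h in orf_scan(seq, min_aa=5)
        )
        assert got == sorted(_orf_oracle(seq, min_aa=5))


# ---------------------------------------------------------------------------
# Cross-ITS homology

def _sw_oracle(a, b, params=ScoringParams()):
    """Plain quadratic affine-gap Smith-Waterman (gap length L costs
    |gap_open| + L*|gap_extend|), scores only."""
    go, ge = -params.gap_open, -params.gap_extend
    n, m = len(a), len(b)
    NEG = float("-inf")
    best = 0.0
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (deletion from a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = params.match if a[i - 1] == b[j - 1] else params.mismatch
            M[i][j] = max(
                0.0,
                max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + sub,
            )
            X[i][j] = max(M[i - 1][j] - go - ge, X[i - 1][j] - ge)
            Y[i][j] = max(M[i][j - 1] - go - ge, Y[i][j - 1] - ge)
            best = max(best, M[i][j])
    return best


class TestCrossItsHomology:
    def test_identical_sequences_identity_one(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=120))
        score, ident, length = best_local_alignment(seq, seq)
        assert ident == 1.0
        assert score == 120
        assert length == 120

    def test_empty_call_set(self):
        mat = cross_its_homology([], {})
        assert mat.labels == []
        assert mat.identity.empty

    def test_symmetric_diagonal_excluded(self, rng):
        calls = []
        seqs = {}
        for i in range(3):
            sp = f"sp{i}"
            seqs[sp] = "".join(rng.choice(list("ACGT"), size=200))
            calls.append(
                ItsCall(
                    species=sp, classification="novel_candidate",
                    region_id=("H1", "H2"), interval=(0, 200), length=200,
                    domain="LSU",
                )
            )
        mat = cross_its_homology(calls, seqs)
        assert np.allclose(mat.identity.values, mat.identity.values.T, equal_nan=True)
        assert np.isnan(np.diag(mat.identity.values)).all()

    def test_score_matches_quadratic_dp_oracle_seeded_pair(self):
        rng = np.random.default_rng(3)
        a = "".join(rng.choice(list("ACGT"), size=200))
        b = "".join(rng.choice(list("ACGT"), size=200))
        score, ident, _ = best_local_alignment(a, b)
        assert score == _sw_oracle(a, b)
        assert 0.0 <= ident <= 1.0

    @pytest.mark.parametrize("seed", range(12))
    def test_score_matches_quadratic_dp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list("ACGT"), size=int(rng.integers(40, 100))))
        b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(40, 100))))
        assert best_local_alignment(a, b)[0] == _sw_oracle(a, b)

    def test_homologous_pair_report_threshold(self, rng):
        shared = "".join(rng.choice(list("ACGT"), size=80))
        seqs = {
            "a": shared + "".join(rng.choice(list("ACGT"), size=40)),
            "b": "".join(rng.choice(list("ACGT"), size=40)) + shared,
            "c": "".join(rng.choice(list("ACGT"), size=120)),
        }
        calls = [
            ItsCall(species=sp, classification="novel_candidate",
                    region_id=("H1", "H2"), interval=(0, 120), length=120,
                    domain="LSU")
            for sp in seqs
        ]
        mat = cross_its_homology(calls, seqs)
        pairs = mat.homologous_pairs()
        assert ("a:H1-H2", "b:H1-H2") in pairs
        assert len(pairs) == 1


# ---------------------------------------------------------------------------
# Fragment arithmetic

class TestFragmentCount:
    def _calls(self, n, species="sp", domain="LSU", cls="known_ITS"):
        return [
            ItsCall(
                species=species, classification=cls,
                region_id=(f"H{i}", f"H{i+1}"), interval=(0, 10), length=10,
                domain=domain, site_id=(f"s{i}" if cls == "known_ITS" else None),
            )
            for i in range(n)
        ]

    @pytest.mark.parametrize("n_its,expected", [(5, 6), (12, 13), (0, 1)])
    def test_its_to_fragment_arithmetic(self, n_its, expected):
        assert fragment_count(self._calls(n_its), "sp") == expected

    def test_ssu_expansions_do_not_count(self):
        calls = self._calls(3) + [
            ItsCall(species="sp", classification="ssu_expansion",
                    region_id=("S1", "S2"), interval=(0, 10), length=10,
                    domain="SSU")
        ]
        assert fragment_count(calls, "sp") == 4

    def test_restricted_to_species(self):
        calls = self._calls(3, species="a") + self._calls(2, species="b")
        assert fragment_count(calls, "a") == 4
        assert fragment_count(calls, "b") == 3
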