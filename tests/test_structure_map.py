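"""Anchor projection, inter-anchor lengths, the 4x expansion rule, and the
base-pair-maximisation folding engine."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from itscan.formats import Msa, SequenceRecord
from itscan.structure_map import (
    ABSENT,
    ExpansionSegment,
    HelixAnchor,
    HelixMap,
    InterAnchorRegion,
    detect_expansions,
    fold_region,
    interanchor_lengths,
    project_anchors,
)


def _map(anchors, template_id="t", length=None):
    return HelixMap(template_id=template_id, anchors=anchors, template_length=length)


# ---------------------------------------------------------------------------
# Projection

def _projection_oracle(msa, helix_map):
    """Brute-force per-column walk, independent of the numpy implementation."""
    template = msa.row(helix_map.template_id).residues
    col_of = [c for c, ch in enumerate(template) if ch != "-"]
    out = {}
    for rec in msa.records:
        per = {}
        for a in helix_map.anchors:
            s, e = a.extent
            cols = range(col_of[s], col_of[e - 1] + 1)
            positions = []
            upos = 0
            row = rec.residues
            for c, ch in enumerate(row):
                if ch != "-":
                    if c in cols:
                        positions.append(upos)
                    upos += 1
            per[a.name] = (positions[0], positions[-1] + 1) if positions else None
        out[rec.id] = per
    return out


class TestProjectAnchors:
    def test_gapless_identity(self):
        msa = Msa([SequenceRecord("t", "ACGTACGTACGT"),
                   SequenceRecord("a", "ACGTACGTACGT")])
        hm = _map([HelixAnchor("H1", "core", (2, 6))], length=12)
        proj = project_anchors(msa, hm)
        assert proj.interval("t", "H1") == (2, 6)
        assert proj.interval("a", "H1") == (2, 6)

    def test_fully_gapped_anchor_absent(self):
        msa = Msa([SequenceRecord("t", "ACGTACGT"),
                   SequenceRecord("a", "AC----GT")])
        hm = _map([HelixAnchor("H1", "core", (3, 5))], length=8)
        proj = project_anchors(msa, hm)
        assert proj.interval("a", "H1") is ABSENT

    def test_staggered_gaps_match_column_walk_oracle(self):
        msa = Msa([
            SequenceRecord("t", "AC-GTAC--GTACGT-A"),
            SequenceRecord("a", "ACCG-ACGTGT--GTAA"),
            SequenceRecord("b", "-CAGTAC-AG--CGTTA"),
        ])
        hm = _map(
            [HelixAnchor("H1", "core", (1, 4)), HelixAnchor("H2", "ES", (6, 10))],
        )
        proj = project_anchors(msa, hm)
        oracle = _projection_oracle(msa, hm)
        for rec in msa.records:
            for name in ("H1", "H2"):
                assert proj.interval(rec.id, name) == oracle[rec.id][name]

    def test_template_self_projection_identity(self, compact_bundle):
        proj = project_anchors(compact_bundle.msa, compact_bundle.template.helix_map)
        for a in compact_bundle.template.helix_map.anchors:
            assert proj.interval("template", a.name) == a.extent

    def test_missing_template_row_rejected(self):
        msa = Msa([SequenceRecord("a", "ACGT")])
        hm = _map([HelixAnchor("H1", "core", (0, 2))])
        with pytest.raises(KeyError):
            project_anchors(msa, hm)

    def test_template_length_mismatch_rejected(self):
        msa = Msa([SequenceRecord("t", "ACGT")])
        hm = _map([HelixAnchor("H1", "core", (0, 2))], length=99)
        with pytest.raises(ValueError, match="length"):
            project_anchors(msa, hm)


class TestInterAnchorLengths:
    def _regions(self, msa, hm):
        return interanchor_lengths(project_anchors(msa, hm), msa)

    def test_abutting_anchors_zero_region(self):
        seq = "A" * 30
        msa = Msa([SequenceRecord("t", seq)])
        hm = _map([HelixAnchor("H1", "core", (10, 20)),
                   HelixAnchor("H2", "core", (20, 30))])
        regions = {r.region_id: r for r in self._regions(msa, hm)}
        assert regions[("H1", "H2")].length == 0

    def test_gap_arithmetic(self):
        seq = "A" * 70
        msa = Msa([SequenceRecord("t", seq)])
        hm = _map([HelixAnchor("H1", "core", (10, 20)),
                   HelixAnchor("H2", "core", (50, 60))])
        regions = {r.region_id: r for r in self._regions(msa, hm)}
        assert regions[("H1", "H2")].length == 30
        assert regions[("^", "H1")].length == 10
        assert regions[("H2", "$")].length == 10

    def test_length_conservation_on_generated_operons(self, compact_bundle):
        # anchors + regions tile each unaligned sequence exactly
        hm = compact_bundle.template.helix_map
        proj = project_anchors(compact_bundle.msa, hm)
        regions = interanchor_lengths(proj, compact_bundle.msa)
        for rec in compact_bundle.msa.records:
            anchor_total = sum(
                (iv[1] - iv[0])
                for iv in (proj.interval(rec.id, a.name) for a in hm.anchors)
                if iv is not None
            )
            region_total = sum(r.length for r in regions if r.species == rec.id)
            assert anchor_total + region_total == len(rec.degapped)

    def test_absent_anchor_bridged_and_recorded(self):
        msa = Msa([
            SequenceRecord("t", "AAAACCCCGGGGTTTTAAAA"),
            SequenceRecord("a", "AAAACCCC----TTTTAAAA"),
        ])
        hm = _map([
            HelixAnchor("H1", "core", (4, 8)),
            HelixAnchor("H2", "core", (8, 12)),
            HelixAnchor("H3", "core", (12, 16)),
        ])
        regions = [r for r in self._regions(msa, hm) if r.species == "a"]
        ids = [r.region_id for r in regions]
        assert ("H1", "H3") in ids
        bridged = next(r for r in regions if r.region_id == ("H1", "H3"))
        assert bridged.skipped == ("H2",)


# ---------------------------------------------------------------------------
# Expansion detection

def _regions_from_lengths(lengths, region=("H1", "H2")):
    out = []
    for sp, ln in lengths.items():
        out.append(
            InterAnchorRegion(species=sp, region_id=region, interval=(100, 100 + ln),
                              length=ln)
        )
    return out


class TestDetectExpansions:
    def test_fourfold_rule_flags(self):
        regions = _regions_from_lengths({"f": 250, "b1": 50, "b2": 55, "b3": 60})
        rep = detect_expansions(regions, {"f"}, {"b1", "b2", "b3"})
        assert [e.species for e in rep.expansions] == ["f"]
        e = rep.expansions[0]
        assert e.background_stat == 55
        assert e.factor == pytest.approx(250 / 55)

    def test_below_threshold_not_flagged(self):
        regions = _regions_from_lengths({"f": 200, "b1": 50, "b2": 55, "b3": 60})
        rep = detect_expansions(regions, {"f"}, {"b1", "b2", "b3"})
        assert rep.expansions == []

    def test_min_abs_guards_degenerate_background(self):
        for focal_len, flagged in [(40, True), (20, False)]:
            regions = _regions_from_lengths({"f": focal_len, "b1": 0, "b2": 0, "b3": 0})
            rep = detect_expansions(regions, {"f"}, {"b1", "b2", "b3"})
            assert bool(rep.expansions) is flagged

    def test_small_background_skipped_with_reason(self):
        regions = _regions_from_lengths({"f": 250, "b1": 50})
        rep = detect_expansions(regions, {"f"}, {"b1"})
        assert rep.expansions == []
        assert rep.skipped and rep.skipped[0][0] == ("H1", "H2")

    def test_overlapping_focal_background_rejected(self):
        regions = _regions_from_lengths({"f": 10, "b": 10})
        with pytest.raises(ValueError):
            detect_expansions(regions, {"f"}, {"f", "b"})

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        bg=st.lists(st.integers(40, 120), min_size=3, max_size=8),
        focal=st.integers(0, 2000),
        scale=st.integers(2, 7),
        perm_seed=st.integers(0, 100),
    )
    def test_scale_free_and_order_free(self, bg, focal, scale, perm_seed):
        # the 4x rule is invariant to background order and (above min_abs)
        # to uniform positive scaling of all lengths
        rng = np.random.default_rng(perm_seed)
        lengths = {"f": focal} | {f"b{i}": v for i, v in enumerate(bg)}
        shuffled = dict(
            zip(rng.permutation(list(lengths)), [lengths[k] for k in rng.permutation(list(lengths))])
        )
        base = detect_expansions(
            _regions_from_lengths(lengths), {"f"}, set(lengths) - {"f"}
        )
        perm = detect_expansions(
            _regions_from_lengths({k: lengths[k] for k in rng.permutation(list(lengths))}),
            {"f"}, set(lengths) - {"f"},
        )
        assert bool(base.expansions) == bool(perm.expansions)
        if base.expansions and (focal - int(np.median(bg))) >= 30:
            scaled = detect_expansions(
                _regions_from_lengths({k: v * scale for k, v in lengths.items()}),
                {"f"}, set(lengths) - {"f"},
            )
            assert bool(scaled.expansions)


# ---------------------------------------------------------------------------
# Folding

def _brute_max_pairs(seq, i=None, j=None):
    """Exhaustive no-memo recursion over all admissible nested structures."""
    pairs = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
    s = seq.upper().replace("U", "T")
    if i is None:
        i, j = 0, len(s) - 1
    if i >= j:
        return 0
    best = _brute_max_pairs(s, i + 1, j)
    for k in range(i + 4, j + 1):
        if (s[i], s[k]) in pairs:
            cand = 1 + _brute_max_pairs(s, i + 1, k - 1) + _brute_max_pairs(s, k + 1, j)
            best = max(best, cand)
    return best


def _structure_valid(seq, structure):
    pairs = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
    s = seq.upper().replace("U", "T")
    stack = []
    seen = []
    for idx, ch in enumerate(structure):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                return False
            i = stack.pop()
            seen.append((i, idx))
    if stack:
        return False
    return all((s[i], s[j]) in pairs and j - i > 3 for i, j in seen)


class TestFoldRegion:
    def test_no_admissible_pair(self):
        assert fold_region("AAAA").structure == "...."

    def test_hairpin(self):
        res = fold_region("GGGAAAACCC")
        assert res.pairs == 3
        assert res.structure == "(((....)))"

    def test_loop_constraint_blocks_short_hairpin(self):
        # GC pair would need a 2-nt loop: not admissible
        assert fold_region("GAAC").pairs == 0

    def test_rna_dna_equivalence(self):
        assert fold_region("GGGAAAACCC").pairs == fold_region("GGGAAAACCC".replace("T", "U")).pairs

    def test_invalid_residue_rejected(self):
        with pytest.raises(ValueError):
            fold_region("ACG-")

    @pytest.mark.parametrize("seed", range(30))
    def test_pair_count_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 21))
        seq = "".join(rng.choice(list("ACGT"), size=n))
        res = fold_region(seq)
        assert res.pairs == _brute_max_pairs(seq)
        assert _structure_valid(seq, res.structure)
        assert res.structure.count("(") == res.pairs

    def test_anchor_hairpins_fold_back(self, compact_bundle):
        # template core anchors are engineered hairpins: folding any anchor
        # extent recovers at least stem-length pairs
        tpl = compact_bundle.template
        stem = compact_bundle.config.core_stem
        for a in tpl.helix_map.anchors[:4]:
            if a.cls != "core":
                continue
            s, e = a.extent
            assert fold_region(tpl.record.residues[s:e]).pairs >= stem
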