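"""Contig consolidation, clonotype partitioning and mutation counting."""

import random

import numpy as np
import pytest

from gcmab.germline import build_reference_set
from gcmab.repertoire import (
    ChainSelection,
    Contig,
    alignment_score,
    call_clonotypes,
    consolidate_contigs,
    count_mutations,
    infer_germline,
    junction_identity,
)

REFS = build_reference_set()
GERM, RMAP = REFS["IGHV1-sim*01"]


def hc(seq="ATG" * 20, junction=None, v="IGHV1-sim*01", j="IGHJ1-sim*01",
       c="IGHG1", expr=10.0, cell="cellA", sid="s1", frame=True, locus="IGH"):
    return Contig(
        cell_id=cell, locus=locus, sequence=seq, v_call=v, j_call=j, c_call=c,
        junction=junction, expression=expr, sequence_id=sid,
        frame_in_constant=frame, productive=True,
    )


class TestConsolidation:
    def test_merge_keeps_largest_of_same_rearrangement(self):
        short = hc(seq="A" * 480, sid="short")
        long = hc(seq="A" * 510, sid="long", expr=1.0)
        sel = consolidate_contigs([short, long])
        assert sel.heavy.sequence_id == "long"

    def test_missing_constant_region_discards_chain(self):
        sel = consolidate_contigs([hc(c=None)])
        assert sel.heavy is None and not sel.paired

    def test_out_of_frame_constant_discards_chain(self):
        sel = consolidate_contigs([hc(frame=False)])
        assert sel.heavy is None

    def test_highest_expression_wins_between_rearrangements(self):
        a = hc(locus="IGK", v="IGKV1-sim*01", j="IGKJ1-sim*01", c="IGKC",
               seq="AAA" * 30, expr=120, sid="a")
        b = hc(locus="IGK", v="IGKV2-sim*01", j="IGKJ1-sim*01", c="IGKC",
               seq="CCC" * 30, expr=45, sid="b")
        sel = consolidate_contigs([a, b])
        assert sel.light.sequence_id == "a"

    def test_empty_input_yields_empty_selection(self):
        sel = consolidate_contigs([])
        assert sel.heavy is None and sel.light is None and not sel.paired

    def test_selection_never_invents_sequence(
        self, bundle_noisefree, processed_noisefree
    ):
        # every selected chain is literally one of the cell's input contigs
        contigs = bundle_noisefree.contigs.set_index("sequence_id")
        for sel in processed_noisefree["selections"][:50]:
            for chain in (sel.heavy, sel.light):
                assert chain is not None
                row = contigs.loc[chain.sequence_id]
                assert row["cell_id"] == sel.cell_id
                assert row["sequence"] == chain.sequence

    def test_roundtrip_recovers_planted_true_pair(
        self, bundle_noisefree, processed_noisefree
    ):
        truth = bundle_noisefree.truth.chains.set_index(["cell_id", "locus"])
        for sel in processed_noisefree["selections"]:
            assert sel.paired
            assert sel.heavy.sequence_id == truth.loc[(sel.cell_id, "IGH"), "sequence_id"]
            light_locus = sel.light.locus
            assert sel.light.sequence_id == truth.loc[(sel.cell_id, light_locus), "sequence_id"]


def selection(cell, junction, v="IGHV1-sim*01"):
    seq = GERM + junction + "GCCAAA"
    return ChainSelection(cell_id=cell, heavy=hc(seq=seq, junction=junction, v=v, cell=cell))


class TestClonotypes:
    def test_identical_junctions_share_clonotype(self):
        a, b = selection("c1", "TGTGCG" * 6), selection("c2", "TGTGCG" * 6)
        assignments, clonos, _ = call_clonotypes([a, b])
        assert assignments["clonotype_id"].nunique() == 1

    def test_different_junction_length_blocks_split(self):
        a = selection("c1", "TGTGCG" * 6)  # 36 nt
        b = selection("c2", "TGT" + "TGTGCG" * 6)  # 39 nt
        assignments, *_ = call_clonotypes([a, b])
        assert assignments["clonotype_id"].nunique() == 2

    def test_cells_without_heavy_junction_are_excluded(self):
        good = selection("c1", "TGTGCG" * 6)
        bad = ChainSelection(cell_id="c2", heavy=None)
        assignments, _, excluded = call_clonotypes([good, bad])
        assert excluded == ["c2"] and len(assignments) == 1

    def test_partition_is_permutation_invariant(self, processed_noisefree):
        sels = processed_noisefree["selections"][:60]
        fwd, *_ = call_clonotypes(sels)
        rev, *_ = call_clonotypes(list(reversed(sels)))
        assert fwd.set_index("cell_id")["clonotype_id"].equals(
            rev.set_index("cell_id")["clonotype_id"]
        )

    def test_all_unique_junctions_give_one_clonotype_per_cell(self):
        rng = random.Random(0)
        sels = [
            selection(f"c{i}", "".join(rng.choice("ACGT") for _ in range(36)))
            for i in range(15)
        ]
        assignments, *_ = call_clonotypes(sels)
        assert assignments["clonotype_id"].nunique() == len(sels)

    def test_partition_matches_bruteforce_single_linkage(self, processed_noisefree):
        sels = processed_noisefree["selections"][:50]
        assignments, *_ = call_clonotypes(sels)
        called = {
            frozenset(grp["cell_id"])
            for _, grp in assignments.groupby("clonotype_id")
        }
        assert called == _bruteforce_partition(sels)

    def test_roundtrip_recovers_planted_clones(
        self, bundle_noisefree, processed_noisefree
    ):
        assignments, *_ = call_clonotypes(processed_noisefree["selections"])
        truth = bundle_noisefree.truth.cells
        called = {
            frozenset(g["cell_id"]) for _, g in assignments.groupby("clonotype_id")
        }
        planted = {
            frozenset(idx)
            for _, idx in truth.loc[assignments["cell_id"]]
            .groupby("clonotype_id")
            .groups.items()
        }
        assert called == planted


def _bruteforce_partition(selections, min_identity=0.8):
    """Independent oracle: explicit graph + breadth-first components."""
    nodes = [
        (s.cell_id, s.heavy.v_call.split("*")[0], s.heavy.junction)
        for s in selections
    ]
    adj = {c: set() for c, _, _ in nodes}
    for i, (ca, va, ja) in enumerate(nodes):
        for cb, vb, jb in nodes[i + 1 :]:
            if va == vb and len(ja) == len(jb):
                ident = sum(x == y for x, y in zip(ja, jb)) / len(ja)
                if ident >= min_identity:
                    adj[ca].add(cb)
                    adj[cb].add(ca)
    seen, comps = set(), set()
    for start in adj:
        if start in seen:
            continue
        comp, queue = set(), [start]
        while queue:
            node = queue.pop()
            if node in comp:
                continue
            comp.add(node)
            queue.extend(adj[node] - comp)
        seen |= comp
        comps.add(frozenset(comp))
    return comps


class TestMutationCounting:
    def test_self_comparison_counts_nothing(self):
        p = count_mutations(GERM, GERM, RMAP)
        assert p.total_count == 0 and not p.indel_flag

    def test_single_silent_cdr_substitution(self):
        # find a CDR codon-third position where GGG-like wobble is silent
        pos = 80  # inside CDR1 (78..114)
        codon_start = (pos // 3) * 3
        # craft germline with GGG at that codon; G->A at 3rd base is silent
        germ = GERM[:codon_start] + "GGG" + GERM[codon_start + 3 :]
        obs = germ[: codon_start + 2] + "A" + germ[codon_start + 3 :]
        p = count_mutations(obs, germ, RMAP)
        assert (p.cdr_count, p.fw_count, p.silent_count, p.nonsilent_count) == (1, 0, 1, 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_planted_profile_roundtrip(self, seed):
        from gcmab.simulate import plant_mutations

        mutated, muts = plant_mutations(GERM, RMAP, 7, seed=seed)
        p = count_mutations(mutated + "TGTGCG" * 6, GERM, RMAP)
        assert p.total_count == 7
        assert p.cdr_count == sum(m["region"] == "CDR" for m in muts)
        assert p.fw_count == sum(m["region"] == "FW" for m in muts)
        assert p.silent_count == sum(m["silent"] for m in muts)
        assert p.cdr_count + p.fw_count == p.silent_count + p.nonsilent_count

    def test_indels_flagged_not_counted(self):
        obs = GERM[:100] + GERM[103:]  # 3-nt deletion
        p = count_mutations(obs, GERM, RMAP)
        assert p.indel_flag and p.total_count == 0

    def test_low_coverage_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            count_mutations(GERM[:100], GERM, RMAP)

    def test_alignment_score_matches_dp_oracle(self):
        rng = random.Random(42)
        for _ in range(25):
            n, m = rng.randint(5, 60), rng.randint(5, 60)
            a = "".join(rng.choice("ACGT") for _ in range(n))
            b = "".join(rng.choice("ACGT") for _ in range(m))
            assert alignment_score(a, b) == pytest.approx(_dp_score(a, b))


def _dp_score(a, b, match=1, mismatch=-1, gap_open=-4, gap_extend=-1):
    """Exhaustive affine-gap global alignment with free end gaps (Gotoh)."""
    NEG = -1e18
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (consume a)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (consume b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = 0.0  # free leading end gap
    for j in range(1, m + 1):
        Y[0, j] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend)
    # free trailing end gaps: best over last row/column
    best = max(M[n, m], X[n, m], Y[n, m])
    for i in range(n + 1):
        best = max(best, M[i, m], Y[i, m])
    for j in range(m + 1):
        best = max(best, M[n, j], X[n, j])
    return best


class TestGermlineLookup:
    def test_known_allele_resolves(self):
        seq, rmap = infer_germline("IGHV1-sim*01", REFS)
        assert seq == GERM
        assert rmap.region_type_at(80) == "CDR"

    def test_unknown_allele_lists_available(self):
        with pytest.raises(KeyError, match="IGHV1-sim"):
            infer_germline("IGHV9-sim*01", REFS)

    def test_missing_allele_suffix_defaults_to_01(self):
        assert infer_germline("IGHV1-sim", REFS)[0] == GERM


def test_junction_identity_basics():
    assert junction_identity("ACGT", "ACGT") == 1.0
    assert junction_identity("ACGT", "ACGG") == 0.75
    with pytest.raises(ValueError):
        junction_identity("ACG", "ACGT")
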