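"""Generator contracts: determinism, planted structure, config validation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from gcmab.germline import build_reference_set
from gcmab.qc import lognormalize, split_ercc
from gcmab.simulate import SimConfig, plant_mutations, simulate_dataset


def small_config(**kw):
    base = dict(
        seed=2,
        n_cells_per_subset={"LZ": 30, "DZ": 30, "LZtoDZ": 10, "preMem": 6, "prePC": 6, "PC": 3},
        n_genes=300,
        n_clonotypes=40,
        qc_violator_fraction=0.1,
    )
    base.update(kw)
    return SimConfig(**base)


def test_same_seed_gives_identical_bundles():
    a = simulate_dataset(small_config())
    b = simulate_dataset(small_config())
    pd.testing.assert_frame_equal(a.counts, b.counts)
    pd.testing.assert_frame_equal(a.contigs, b.contigs)
    pd.testing.assert_frame_equal(a.elisa, b.elisa)
    pd.testing.assert_frame_equal(a.index_sort, b.index_sort)
    pd.testing.assert_frame_equal(a.truth.cells, b.truth.cells)


def test_different_seed_changes_counts():
    a = simulate_dataset(small_config())
    b = simulate_dataset(small_config(seed=3))
    assert not a.counts.equals(b.counts)


def test_zero_shm_rate_leaves_germline_untouched():
    bundle = simulate_dataset(small_config(shm_rate=0.0))
    assert (bundle.truth.chains["n_mut"] == 0).all()
    refs = bundle.germline_refs
    true_ids = set(bundle.truth.chains["sequence_id"])
    for row in bundle.contigs.itertuples(index=False):
        if row.sequence_id in true_ids:
            germ = refs[row.v_call][0]
            assert row.sequence.startswith(germ)


def test_noise_free_mfi_rank_matches_affinity_rank():
    bundle = simulate_dataset(small_config().noise_free())
    truth = bundle.truth.cells
    facs = bundle.index_sort.merge(bundle.well_map, on=["plate", "well"])
    mfi = facs.set_index("cell_id").loc[truth.index, "OVA-AF647"]
    order_mfi = np.argsort(mfi.to_numpy())
    order_aff = np.argsort(truth["affinity"].to_numpy())
    assert list(order_mfi) == list(order_aff)


def test_noise_free_elisa_threshold_decreases_with_affinity():
    bundle = simulate_dataset(small_config().noise_free())
    mabs = bundle.truth.mabs
    usable = mabs[~mabs["censored_above"] & ~mabs["censored_below"]]
    s = usable.sort_values("affinity")
    assert (np.diff(s["true_threshold_ng"]) <= 1e-9).all()


def test_clonotype_sizes_partition_the_cells():
    bundle = simulate_dataset(small_config())
    sizes = bundle.truth.cells.groupby("clonotype_id").size()
    assert sizes.sum() == bundle.config.n_cells


def test_planted_qc_violator_fraction():
    bundle = simulate_dataset(small_config())
    n_viol = (bundle.truth.cells["qc_violation"] != "").sum()
    assert n_viol == round(0.1 * bundle.config.n_cells)


def test_contig_multiplicity_and_true_chain_marking():
    bundle = simulate_dataset(small_config())
    truth_ids = set(bundle.truth.chains["sequence_id"])
    per_cell = bundle.contigs.groupby(["cell_id", "locus"]).size()
    assert per_cell.loc[:, "IGH"].between(1, 4).all()
    grouped = bundle.contigs.groupby("cell_id")
    for cell, grp in grouped:
        heavy_true = grp[(grp.locus == "IGH") & grp.sequence_id.isin(truth_ids)]
        light_true = grp[(grp.locus != "IGH") & grp.sequence_id.isin(truth_ids)]
        assert len(heavy_true) == 1 and len(light_true) == 1


def test_marker_contrast_in_own_subset(bundle_noisefree):
    from gcmab.annotate import DEFAULT_SIGNATURES, SUBSETS

    b = bundle_noisefree
    clean = b.truth.cells[b.truth.cells["qc_violation"] == ""]
    norm = lognormalize(b.counts[list(clean.index)])
    for subset in SUBSETS:
        sig = DEFAULT_SIGNATURES[subset]
        per_subset = {
            s: norm.loc[sig, clean.index[clean["subset"] == s]].mean().mean()
            for s in SUBSETS
        }
        own = per_subset.pop(subset)
        assert own > max(per_subset.values())


@pytest.mark.parametrize(
    "field,value,message",
    [
        ("shm_rate", -1.0, "shm_rate"),
        ("facs_noise_sd", -0.5, "facs_noise_sd"),
        ("dropout_rate", 1.5, "dropout_rate"),
        ("n_genes", 10, "n_genes"),
        ("n_cells_per_subset", {"LZ": 0, "DZ": 0}, "n_cells_per_subset"),
        ("clonotype_size_distribution", {0: 1.0}, "clonotype_size_distribution"),
    ],
)
def test_invalid_config_rejected_naming_field(field, value, message):
    cfg = small_config(**{field: value})
    with pytest.raises(ValueError, match=message):
        simulate_dataset(cfg)


# --- plant_mutations -------------------------------------------------------

REFS = build_reference_set()
GERM, RMAP = REFS["IGHV1-sim*01"]


def test_plant_zero_mutations_is_identity():
    seq, muts = plant_mutations(GERM, RMAP, 0, seed=0)
    assert seq == GERM and muts == []


@pytest.mark.parametrize("seed", range(8))
def test_planted_mutations_are_recorded_faithfully(seed):
    n = 7
    seq, muts = plant_mutations(GERM, RMAP, n, seed=seed)
    assert len(muts) == n
    diff = [i for i, (a, b) in enumerate(zip(GERM, seq)) if a != b]
    assert diff == sorted(m["position"] for m in muts)
    for m in muts:
        assert GERM[m["position"]] == m["ref"]
        assert seq[m["position"]] == m["alt"]
        assert m["region"] == RMAP.region_type_at(m["position"])
        # silent flag agrees with whole-protein translation of the single
        # substitution applied to the germline
        single = _apply_one(GERM, m)
        assert m["silent"] == (
            str(Seq(GERM).translate()) == str(Seq(single).translate())
        )


def _apply_one(germ, mutation):
    seq = list(germ)
    seq[mutation["position"]] = mutation["alt"]
    return "".join(seq)


def test_plant_mutations_rejects_excess():
    with pytest.raises(ValueError):
        plant_mutations(GERM, RMAP, len(GERM) + 1, seed=0)
    with pytest.raises(ValueError, match="region_map"):
        plant_mutations(GERM, None, 1, seed=0)
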