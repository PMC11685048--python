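"""Shared fixtures: simulated bundles and derived per-stage products."""

import warnings

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from gcmab import annotate, qc, repertoire
from gcmab.io import contigs_from_airr
from gcmab.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def bundle_noisefree():
    """Full-size cohort with every stochastic nuisance switched off."""
    return simulate_dataset(SimConfig(seed=11).noise_free())


@pytest.fixture(scope="session")
def bundle_noisy():
    """Default (noisy) simulation at full cohort size."""
    return simulate_dataset(SimConfig(seed=5))


@pytest.fixture(scope="session")
def processed_noisefree(bundle_noisefree):
    """QC, normalization, annotation and chain selection on the noise-free
    bundle, computed once for the whole session."""
    b = bundle_noisefree
    metrics = qc.compute_qc_metrics(b.counts, b.ercc_expected)
    report = qc.filter_cells(metrics)
    passing = list(report.index[report["pass_qc"]])
    norm = qc.lognormalize(b.counts[passing])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores = annotate.score_signatures(norm, seed=0)
        labels = annotate.gate_subsets(scores)
        phases = annotate.cell_cycle_phase(norm, seed=0)
    by_cell = {}
    for c in contigs_from_airr(b.contigs):
        if c.cell_id in set(passing):
            by_cell.setdefault(c.cell_id, []).append(c)
    selections = [
        repertoire.consolidate_contigs(cc) for _, cc in sorted(by_cell.items())
    ]
    return {
        "metrics": metrics,
        "report": report,
        "passing": passing,
        "norm": norm,
        "scores": scores,
        "labels": labels,
        "phases": phases,
        "selections": selections,
    }
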