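"""Pipeline driver: ordered stages from simulation to the integrated table.

Stages: simulate → qc → bcr / annotate / facs / elisa → integrate.  Each
stage reads its inputs from the output directory, writes its products and
records a manifest entry (input hashes, parameters, tool version); an
unchanged stage is skipped on re-run unless forced.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotate, cytometry, elisa as elisa_mod, io, qc, repertoire, simulate, stats

log = logging.getLogger("gcmab")

STAGES = ["simulate", "qc", "bcr", "annotate", "facs", "elisa", "integrate"]

_DEPS = {
    "simulate": [],
    "qc": ["simulate"],
    "bcr": ["simulate", "qc"],
    "annotate": ["qc"],
    "facs": ["simulate", "qc"],
    "elisa": ["simulate"],
    "integrate": ["qc", "bcr", "annotate", "facs", "elisa"],
}

_STAGE_OUTPUTS = {
    "simulate": ["sim/ground_truth.json"],
    "qc": ["qc_report.csv", "normalized.csv"],
    "bcr": ["chain_selection.csv", "clonotypes.csv", "mutations.csv"],
    "annotate": ["labels.csv"],
    "facs": ["facs.csv"],
    "elisa": ["elisa_results.csv"],
    "integrate": ["integrated_table.csv", "stats_report.json"],
}


@dataclass
class PipelineConfig:
    outdir: str = "gcmab_out"
    seed: int = 0
    sim_overrides: dict = field(default_factory=dict)
    qc_thresholds: dict = field(default_factory=dict)
    clonotype_params: dict = field(default_factory=lambda: {"junction_identity_min": 0.8})
    gating_thresholds: dict = field(default_factory=dict)
    scoring: dict = field(default_factory=lambda: {"n_bins": 24, "n_ctrl": 100})
    elisa_params: dict = field(default_factory=dict)  # e.g. {"od_threshold": 0.2}
    stats_params: dict = field(
        default_factory=lambda: {
            "censor_policy": "cap",
            "dunn_adjustment": "bonferroni",
            "background_cutoff": 1.0,
        }
    )

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = (
            yaml.safe_load(text)
            if str(path).endswith((".yml", ".yaml"))
            else json.loads(text)
        )
        return cls(**data)


def _manifest_path(outdir: Path) -> Path:
    return outdir / "manifest.json"


def _load_manifest(outdir: Path) -> dict:
    p = _manifest_path(outdir)
    return json.loads(p.read_text()) if p.exists() else {}


def _save_manifest(outdir: Path, manifest: dict) -> None:
    _manifest_path(outdir).write_text(json.dumps(manifest, indent=1, default=str))


def _stage_fingerprint(outdir: Path, stage: str, params: dict) -> dict:
    inputs = {}
    for dep in _DEPS[stage]:
        for rel in _STAGE_OUTPUTS[dep]:
            p = outdir / rel
            if p.exists():
                inputs[rel] = io.sha256_file(p)
    return {"params": params, "inputs": inputs, "version": io._version()}


def _check_deps(outdir: Path, stage: str) -> None:
    for dep in _DEPS[stage]:
        for rel in _STAGE_OUTPUTS[dep]:
            if not (outdir / rel).exists():
                raise FileNotFoundError(
                    f"stage {stage!r} needs output {rel!r}; run stage {dep!r} first"
                )


def run_pipeline(
    config: PipelineConfig, stages: list[str] | None = None, force: bool = False
) -> dict:
    """Run the requested stages in canonical order; returns the manifest."""
    stages = STAGES if stages is None else stages
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _load_manifest(outdir)

    runners = {
        "simulate": _run_simulate,
        "qc": _run_qc,
        "bcr": _run_bcr,
        "annotate": _run_annotate,
        "facs": _run_facs,
        "elisa": _run_elisa,
        "integrate": _run_integrate,
    }
    for stage in [s for s in STAGES if s in stages]:
        _check_deps(outdir, stage)
        params = _stage_params(config, stage)
        fingerprint = _stage_fingerprint(outdir, stage, params)
        outputs_exist = all((outdir / rel).exists() for rel in _STAGE_OUTPUTS[stage])
        if not force and outputs_exist and manifest.get(stage) == fingerprint:
            log.info("stage %s up to date; skipping", stage)
            continue
        log.info("running stage %s", stage)
        runners[stage](config, outdir)
        manifest[stage] = _stage_fingerprint(outdir, stage, params)
        _save_manifest(outdir, manifest)
    return manifest


def _stage_params(config: PipelineConfig, stage: str) -> dict:
    base = {"seed": config.seed}
    per_stage = {
        "simulate": config.sim_overrides,
        "qc": config.qc_thresholds,
        "bcr": config.clonotype_params,
        "annotate": {**config.scoring, **config.gating_thresholds},
        "facs": {},
        "elisa": config.elisa_params,
        "integrate": config.stats_params,
    }
    return {**base, **per_stage[stage]}


# --- stage implementations -------------------------------------------------


def _run_simulate(config: PipelineConfig, outdir: Path) -> None:
    sim_cfg = simulate.SimConfig(seed=config.seed, **config.sim_overrides)
    bundle = simulate.simulate_dataset(sim_cfg)
    bundle.write(outdir / "sim")


def _run_qc(config: PipelineConfig, outdir: Path) -> None:
    counts = io.read_counts_mtx(outdir / "sim" / "counts")
    ercc = io.read_csv(outdir / "sim" / "ercc_concentrations.csv").set_index("ercc_id")[
        "concentration"
    ]
    metrics = qc.compute_qc_metrics(counts, ercc)
    thresholds = qc.QCThresholds(**config.qc_thresholds)
    report = qc.filter_cells(metrics, thresholds)
    io.write_csv(report.reset_index(), outdir / "qc_report.csv", seed=config.seed)
    passing = report.index[report["pass_qc"]]
    norm = qc.lognormalize(counts[passing])
    io.write_csv(
        norm.reset_index(), outdir / "normalized.csv", seed=config.seed
    )


def _passing_cells(outdir: Path) -> list[str]:
    report = io.read_csv(outdir / "qc_report.csv")
    return report.loc[report["pass_qc"], "cell_id"].tolist()


def _run_bcr(config: PipelineConfig, outdir: Path) -> None:
    airr = io.read_airr(outdir / "sim" / "contigs_airr.tsv")
    refs = io.read_germline(
        outdir / "sim" / "germline.fasta", outdir / "sim" / "region_maps.json"
    )
    passing = set(_passing_cells(outdir))
    contigs = [c for c in io.contigs_from_airr(airr) if c.cell_id in passing]
    by_cell: dict[str, list] = {}
    for c in contigs:
        by_cell.setdefault(c.cell_id, []).append(c)
    selections = [
        repertoire.consolidate_contigs(cell_contigs)
        for _, cell_contigs in sorted(by_cell.items())
    ]

    sel_rows = []
    for sel in selections:
        sel_rows.append(
            {
                "cell_id": sel.cell_id,
                "paired": sel.paired,
                "heavy_sequence_id": sel.heavy.sequence_id if sel.heavy else "",
                "light_sequence_id": sel.light.sequence_id if sel.light else "",
            }
        )
    io.write_csv(pd.DataFrame(sel_rows), outdir / "chain_selection.csv", seed=config.seed)

    assignments, clonotypes, excluded = repertoire.call_clonotypes(
        selections, references=refs, **config.clonotype_params
    )
    io.write_csv(assignments, outdir / "clonotypes.csv", seed=config.seed)
    if excluded:
        log.warning("%d cells excluded from clonotyping", len(excluded))

    mut_rows = []
    for sel in selections:
        row = {"cell_id": sel.cell_id}
        for prefix, chain in (("vh", sel.heavy), ("vk", sel.light)):
            if chain is None:
                continue
            germ, rmap = repertoire.infer_germline(chain.v_call, refs)
            profile = repertoire.count_mutations(chain.sequence, germ, rmap)
            row.update(
                {
                    f"{prefix}_cdr": profile.cdr_count,
                    f"{prefix}_fw": profile.fw_count,
                    f"{prefix}_silent": profile.silent_count,
                    f"{prefix}_nonsilent": profile.nonsilent_count,
                    f"{prefix}_total": profile.total_count,
                    f"{prefix}_indel": profile.indel_flag,
                }
            )
        mut_rows.append(row)
    io.write_csv(pd.DataFrame(mut_rows), outdir / "mutations.csv", seed=config.seed)


def _run_annotate(config: PipelineConfig, outdir: Path) -> None:
    norm = io.read_csv(outdir / "normalized.csv", index_col=0)
    scoring = config.scoring
    scores = annotate.score_signatures(
        norm,
        n_bins=scoring.get("n_bins", 24),
        n_ctrl=scoring.get("n_ctrl", 100),
        seed=config.seed,
    )
    gcfg = annotate.GatingConfig()
    gcfg.thresholds.update(config.gating_thresholds)
    labels = annotate.gate_subsets(scores, gcfg)
    phases = annotate.cell_cycle_phase(
        norm,
        n_bins=scoring.get("n_bins", 24),
        n_ctrl=scoring.get("n_ctrl", 100),
        seed=config.seed,
    )
    out = scores.copy()
    out["subset"] = labels
    out = out.join(phases)
    io.write_csv(
        out.rename_axis("cell_id").reset_index(), outdir / "labels.csv", seed=config.seed
    )


def _run_facs(config: PipelineConfig, outdir: Path) -> None:
    table = io.read_index_csv(outdir / "sim" / "index_sort.csv")
    well_map = io.read_csv(outdir / "sim" / "well_map.csv")
    attached, report = cytometry.attach_index_sort(table, well_map)
    io.write_csv(attached.reset_index(), outdir / "facs.csv", seed=config.seed)
    (outdir / "facs_report.json").write_text(json.dumps(report, default=str))


def _run_elisa(config: PipelineConfig, outdir: Path) -> None:
    plate = io.read_csv(outdir / "sim" / "elisa_plates.csv")
    results = elisa_mod.threshold_table(
        plate, od_threshold=config.elisa_params.get("od_threshold")
    )
    io.write_csv(results, outdir / "elisa_results.csv", seed=config.seed)


def _run_integrate(config: PipelineConfig, outdir: Path) -> None:
    sp = config.stats_params
    labels = io.read_csv(outdir / "labels.csv").set_index("cell_id")
    clono = io.read_csv(outdir / "clonotypes.csv").set_index("cell_id")
    muts = io.read_csv(outdir / "mutations.csv").set_index("cell_id")
    facs = io.read_csv(outdir / "facs.csv").set_index("cell_id")
    elisa_res = io.read_csv(outdir / "elisa_results.csv")
    paired = io.read_csv(outdir / "chain_selection.csv").set_index("cell_id")[["paired"]]

    # per-cell ELISA results: mab_id is the cell_id for cell-derived mAbs
    cell_elisa = elisa_res[
        ~elisa_res["mab_id"].str.endswith("_germline")
    ].rename(columns={"mab_id": "cell_id"}).set_index("cell_id")

    truth_cells = io.read_ground_truth(outdir / "sim" / "ground_truth.json").cells
    meta = truth_cells[["sample"]].copy()

    table, join_report = stats.build_integrated_table(
        meta.loc[meta.index.isin(labels.index)],
        labels,
        paired,
        clono,
        muts,
        facs,
        cell_elisa,
    )

    report: dict = {"join_report": join_report}
    background = sp.get("background_cutoff", 1.0)

    vh = table.dropna(subset=["vh_total"])
    groups = {
        s: g["vh_total"].to_numpy() for s, g in vh.groupby("sample") if len(g) >= 2
    }
    if len(groups) >= 2:
        kd = stats.kruskal_dunn(groups, adjustment=sp.get("dunn_adjustment", "bonferroni"))
        report["mutations_by_sample"] = {
            "H": kd["H"], "p": kd["p"],
            "pairwise": kd["pairwise"].to_dict(orient="records"),
        }
    binding = table.dropna(subset=["asinh_OVA-AF647"])
    bgroups = {
        s: g["asinh_OVA-AF647"].to_numpy()
        for s, g in binding.groupby("subset")
        if len(g) >= 2
    }
    if len(bgroups) >= 2:
        kd = stats.kruskal_dunn(bgroups, adjustment=sp.get("dunn_adjustment", "bonferroni"))
        report["binding_by_subset"] = {
            "H": kd["H"], "p": kd["p"],
            "pairwise": kd["pairwise"].to_dict(orient="records"),
        }

    both = table.dropna(subset=["threshold_ng", "asinh_OVA-AF647"])
    if len(both) >= 3:
        fits = {}
        for policy in ("cap", "exclude"):
            try:
                fits[policy] = stats.semilog_fit(
                    both["threshold_ng"], both["asinh_OVA-AF647"],
                    censored=both["censored"], censor_policy=policy,
                )
            except ValueError as err:
                fits[policy] = {"error": str(err)}
        report["semilog_fit"] = fits

    summary = stats.summarize_clonotypes(table, background=background)
    io.write_csv(summary, outdir / "clonotype_summary.csv", seed=config.seed)
    report["selected_clonotypes"] = stats.select_clonotypes(summary)
    outliers = stats.detect_outliers(table, binding_cutoff=background)
    io.write_csv(
        outliers.reset_index()[["cell_id", "asinh_OVA-AF647", "threshold_ng"]],
        outdir / "outliers.csv", seed=config.seed,
    )
    report["n_outliers"] = int(len(outliers))

    io.write_csv(
        table.reset_index(), outdir / "integrated_table.csv", seed=config.seed
    )
    (outdir / "stats_report.json").write_text(
        json.dumps(report, indent=1, default=float)
    )
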