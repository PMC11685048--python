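"""Readers and writers for the pipeline's interchange formats.

Formats: MTX (+ row/column TSV) or CSV for count matrices, AIRR
rearrangement TSV for BCR contigs, FASTA + JSON region maps for germline
references, CSV for index-sort and ELISA plate tables, JSON for ground
truth and reports.  Text outputs carry a provenance comment header
(tool version, config hash, seed); readers skip ``#`` comment lines.
Parsers validate headers and basic invariants (non-negative counts, plate
geometry, unique keys) and reject rather than coerce.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import io as spio
from scipy import sparse

from .cytometry import validate_index_table
from .germline import RegionMap
from .repertoire import Contig

TOOL = "gcmab"

AIRR_COLUMNS = [
    "sequence_id", "cell_id", "locus", "v_call", "j_call", "c_call",
    "junction", "junction_aa", "sequence", "duplicate_count", "productive",
    "frame_in_constant",
]


def _version() -> str:
    from . import __version__

    return __version__


def config_hash(obj) -> str:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def provenance_lines(seed=None, cfg_hash: str | None = None) -> list[str]:
    lines = [f"# tool: {TOOL} {_version()}"]
    if cfg_hash is not None:
        lines.append(f"# config_hash: {cfg_hash}")
    if seed is not None:
        lines.append(f"# seed: {seed}")
    return lines


def write_csv(
    df: pd.DataFrame, path, seed=None, cfg_hash=None, index=False, sep=","
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in provenance_lines(seed, cfg_hash):
            fh.write(line + "\n")
        df.to_csv(fh, index=index, sep=sep, float_format="%.6g")
    return path


def read_csv(path, sep=",", **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", **kw)


# --- count matrices --------------------------------------------------------


def write_counts_mtx(counts: pd.DataFrame, outdir, seed=None) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mtx = outdir / "matrix.mtx"
    spio.mmwrite(
        str(mtx),
        sparse.csr_matrix(counts.to_numpy()),
        comment=" ".join(line.lstrip("# ") for line in provenance_lines(seed)),
        field="integer",
    )
    genes = outdir / "genes.tsv"
    cells = outdir / "cells.tsv"
    genes.write_text("\n".join(counts.index) + "\n")
    cells.write_text("\n".join(counts.columns) + "\n")
    return {"matrix": mtx, "genes": genes, "cells": cells}


def read_counts_mtx(outdir) -> pd.DataFrame:
    outdir = Path(outdir)
    mat = spio.mmread(str(outdir / "matrix.mtx")).toarray()
    genes = (outdir / "genes.tsv").read_text().splitlines()
    cells = (outdir / "cells.tsv").read_text().splitlines()
    if mat.shape != (len(genes), len(cells)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match {len(genes)} genes x "
            f"{len(cells)} cells"
        )
    if (mat < 0).any():
        raise ValueError("negative count in matrix")
    counts = pd.DataFrame(mat, index=pd.Index(genes, name="gene"),
                          columns=pd.Index(cells, name="cell_id"))
    if counts.index.duplicated().any():
        raise ValueError("duplicate gene ids in matrix rows")
    return counts


def read_counts_csv(path) -> pd.DataFrame:
    counts = read_csv(path, index_col=0)
    counts.index.name = "gene"
    counts.columns.name = "cell_id"
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative count in matrix")
    return counts


# --- AIRR rearrangement tables --------------------------------------------


def write_airr(contigs: pd.DataFrame, path, seed=None) -> Path:
    df = contigs.copy()
    missing = [c for c in AIRR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"contig table missing AIRR columns: {missing}")
    blank_aa = df["junction_aa"].isna() | (df["junction_aa"] == "")
    df.loc[blank_aa, "junction_aa"] = [
        str(Seq(j).translate()) if isinstance(j, str) and len(j) % 3 == 0 else ""
        for j in df.loc[blank_aa, "junction"]
    ]
    for flag in ("productive", "frame_in_constant"):
        df[flag] = df[flag].map({True: "T", False: "F"}).fillna("")
    df["c_call"] = df["c_call"].fillna("")
    return write_csv(df[AIRR_COLUMNS], path, seed=seed, sep="\t")


def read_airr(path) -> pd.DataFrame:
    df = read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in AIRR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"malformed AIRR header, missing: {missing}")
    if df["sequence_id"].duplicated().any():
        dup = df.loc[df["sequence_id"].duplicated(), "sequence_id"].iloc[0]
        raise ValueError(f"duplicate sequence_id {dup!r}")
    df["duplicate_count"] = df["duplicate_count"].astype(float)
    for flag in ("productive", "frame_in_constant"):
        df[flag] = df[flag].map({"T": True, "F": False, "": None})
    return df


def contigs_from_airr(df: pd.DataFrame) -> list[Contig]:
    out = []
    for row in df.itertuples(index=False):
        out.append(
            Contig(
                cell_id=row.cell_id,
                locus=row.locus,
                sequence=row.sequence,
                v_call=row.v_call,
                j_call=row.j_call,
                c_call=row.c_call or None,
                junction=row.junction or None,
                junction_aa=row.junction_aa or None,
                frame_in_constant=row.frame_in_constant,
                productive=row.productive,
                expression=float(row.duplicate_count),
                sequence_id=row.sequence_id,
            )
        )
    return out


# --- germline references ---------------------------------------------------


def write_germline(refs: dict, fasta_path, regions_path, seed=None) -> None:
    fasta_path, regions_path = Path(fasta_path), Path(regions_path)
    fasta_path.parent.mkdir(parents=True, exist_ok=True)
    records = [
        SeqRecord(Seq(seq), id=name, description="synthetic germline V segment")
        for name, (seq, _)
        in sorted(refs.items())
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    payload = {
        "_provenance": {"tool": f"{TOOL} {_version()}", "seed": seed},
        "region_maps": {name: rmap.to_dict() for name, (_, rmap) in sorted(refs.items())},
    }
    regions_path.write_text(json.dumps(payload, indent=1))


def read_germline(fasta_path, regions_path) -> dict:
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    payload = json.loads(Path(regions_path).read_text())
    maps = {
        name: RegionMap.from_dict(d) for name, d in payload["region_maps"].items()
    }
    missing = set(seqs) ^ set(maps)
    if missing:
        raise ValueError(f"FASTA and region map disagree on alleles: {sorted(missing)}")
    return {name: (seqs[name], maps[name]) for name in seqs}


# --- index-sort tables -----------------------------------------------------


def read_index_csv(path) -> pd.DataFrame:
    df = read_csv(path)
    # recover line numbers for geometry errors
    with open(path) as fh:
        lines = [
            (n, ln) for n, ln in enumerate(fh, start=1) if not ln.startswith("#")
        ]
    header_line = lines[0][0]
    try:
        return validate_index_table(df)
    except ValueError as err:
        msg = str(err)
        if "well" in msg:
            for offset, row in enumerate(df.itertuples(index=False)):
                try:
                    validate_index_table(pd.DataFrame([row._asdict()]))
                except ValueError:
                    raise ValueError(
                        f"{path}:{header_line + 1 + offset}: {msg}"
                    ) from None
        raise


# --- ground truth ----------------------------------------------------------


def write_ground_truth(truth, path, seed=None) -> Path:
    path = Path(path)
    payload = {
        "_provenance": {"tool": f"{TOOL} {_version()}", "seed": seed},
        "cells": truth.cells.reset_index().to_dict(orient="list"),
        "chains": truth.chains.to_dict(orient="list"),
        "mutations": {
            f"{cell}|{locus}": muts for (cell, locus), muts in truth.mutations.items()
        },
        "mabs": truth.mabs.to_dict(orient="list"),
        "selected_clonotypes": list(truth.selected_clonotypes),
        "od_threshold": truth.od_threshold,
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload))
    return path


def read_ground_truth(path):
    from .simulate import GroundTruth

    payload = json.loads(Path(path).read_text())
    cells = pd.DataFrame(payload["cells"]).set_index("cell_id")
    return GroundTruth(
        cells=cells,
        chains=pd.DataFrame(payload["chains"]),
        mutations={
            tuple(key.split("|")): muts
            for key, muts in payload["mutations"].items()
        },
        mabs=pd.DataFrame(payload["mabs"]),
        selected_clonotypes=payload["selected_clonotypes"],
        od_threshold=payload["od_threshold"],
    )


# --- bundle ---------------------------------------------------------------


def write_bundle(bundle, outdir, seed=None) -> dict:
    """Write every artifact of a simulated dataset; returns path manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = bundle.config.seed if seed is None else seed
    paths = {}
    paths.update(write_counts_mtx(bundle.counts, outdir / "counts", seed=seed))
    paths["ercc"] = write_csv(
        bundle.ercc_expected.rename_axis("ercc_id").reset_index(),
        outdir / "ercc_concentrations.csv", seed=seed,
    )
    paths["index_sort"] = write_csv(bundle.index_sort, outdir / "index_sort.csv", seed=seed)
    paths["well_map"] = write_csv(bundle.well_map, outdir / "well_map.csv", seed=seed)
    paths["contigs"] = write_airr(bundle.contigs, outdir / "contigs_airr.tsv", seed=seed)
    write_germline(
        bundle.germline_refs, outdir / "germline.fasta", outdir / "region_maps.json",
        seed=seed,
    )
    paths["germline"] = outdir / "germline.fasta"
    paths["region_maps"] = outdir / "region_maps.json"
    paths["elisa"] = write_csv(bundle.elisa, outdir / "elisa_plates.csv", seed=seed)
    paths["ground_truth"] = write_ground_truth(
        bundle.truth, outdir / "ground_truth.json", seed=seed
    )
    cfg = dataclasses.asdict(bundle.config)
    cfg["clonotype_size_distribution"] = {
        str(k): v for k, v in cfg["clonotype_size_distribution"].items()
    }
    (outdir / "sim_config.json").write_text(json.dumps(cfg, indent=1))
    paths["sim_config"] = outdir / "sim_config.json"
    return paths


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
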