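"""Synthetic integrative single-B-cell dataset with known ground truth.

Generates everything the downstream pipeline consumes — a UMI count matrix
with ERCC spike-in and mitochondrial rows, an index-sort fluorescence
table, reconstructed BCR contigs (AIRR layout), germline V references, and
ELISA dilution plates — together with the ground truth (subset labels,
clonotype partition, planted mutations, true affinities and binding
thresholds) needed to test every stage exactly.

Design choices, briefly:

* UMI counts follow a negative binomial per gene (gamma–Poisson, common
  dispersion) with subset-specific means; marker genes are modeled as
  subset-exclusive (mean ``marker_fold`` in their elevating subsets, 0
  elsewhere) — an idealization of graded real markers that makes
  noise-free recovery exact.  Spike-ins are Poisson (technical noise only)
  and exempt from dropout.
* Each clonotype owns a germline heavy/light allele pair and a founder
  junction; members carry the founder junction with ≤5% substitutions, so
  within-clone junction identity stays above any reasonable linkage
  threshold while distinct clones in the same (V gene, length) block are
  kept below 70% identity by rejection sampling.
* Somatic hypermutation is planted as Poisson-distributed substitutions in
  distinct codons of the V region; silent/non-silent flags come from codon
  translation of the single substitution, which therefore coincides with
  germline-vs-mutated codon comparison.
* Antigen affinity rises log-linearly with the number of non-silent CDR
  substitutions; surface fluorescence is ``scale·affinity`` with lognormal
  noise plus autofluorescence, and ELISA curves are saturation functions
  OD(a) = od_max·a/(a+K) with K inversely proportional to affinity.
* A configurable fraction of cells deliberately violates one QC criterion
  (low UMI total, few genes, high mitochondrial fraction, or scrambled
  spike-ins).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import annotate
from .germline import RegionMap, build_reference_set, is_silent

SAMPLES = ["d10p", "d20p", "d10s", "d20s"]
_BASES = "ACGT"

MITO_GENES_MOUSE = [
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Atp8", "mt-Atp6", "mt-Co3",
    "mt-Nd3", "mt-Nd4l", "mt-Nd4", "mt-Nd5", "mt-Nd6", "mt-Cytb",
]

FACS_CHANNELS = ["OVA-AF647", "CD19-BV421", "GL7-FITC", "CD38-PECy7", "CD138-BV605"]

QC_VIOLATION_KINDS = ["low_umi", "few_genes", "high_mito", "bad_ercc"]


@dataclass
class AffinityParams:
    """Planted CDR mutations → log-affinity; arbitrary affinity units."""

    log10_base: float = -0.35
    per_cdr_nonsilent: float = 0.33
    sd: float = 0.2
    background_fraction: float = 0.35
    background_affinity: float = 0.001


@dataclass
class ElisaParams:
    od_max: float = 3.0
    k_scale: float = 50.0
    replicate_noise_sd: float = 0.05
    n_dilutions: int = 8
    start_ng: float = 1000.0
    factor: float = 4.0
    n_replicates: int = 2
    negative_control_mean: float = 0.05
    negative_control_sd: float = 0.01
    n_negative_controls: int = 4


def _default_subset_counts() -> dict[str, int]:
    # cohort structure of the murine OVA GC study: 747 annotated cells
    return {"LZ": 331, "DZ": 300, "LZtoDZ": 55, "preMem": 29, "prePC": 27, "PC": 5}


def _default_size_distribution() -> dict[int, float]:
    # mostly singletons, a tail of expanded clones (~2 cells/clonotype)
    return {1: 0.64, 2: 0.18, 3: 0.08, 4: 0.04, 5: 0.03, 8: 0.02, 12: 0.01}


def _default_sample_proportions() -> dict[str, float]:
    # 145:205:295:124 cells in d10p:d20p:d10s:d20s
    total = 145 + 205 + 295 + 124
    return {
        "d10p": 145 / total,
        "d20p": 205 / total,
        "d10s": 295 / total,
        "d20s": 124 / total,
    }


def _default_shm_multiplier() -> dict[str, float]:
    # mutation load increases d10p -> d20p and d10s -> d20s
    return {"d10p": 0.6, "d20p": 1.0, "d10s": 1.2, "d20s": 1.8}


@dataclass
class SimConfig:
    seed: int = 0
    n_cells_per_subset: dict[str, int] = field(default_factory=_default_subset_counts)
    n_genes: int = 1000
    n_marker_genes_per_subset: int = 5
    n_ercc: int = 92
    n_mito: int = 13
    n_clonotypes: int = 375
    clonotype_size_distribution: dict[int, float] = field(
        default_factory=_default_size_distribution
    )
    shm_rate: float = 5.0
    sample_shm_multiplier: dict[str, float] = field(default_factory=_default_shm_multiplier)
    sample_proportions: dict[str, float] = field(
        default_factory=_default_sample_proportions
    )
    affinity_model: AffinityParams = field(default_factory=AffinityParams)
    facs_noise_sd: float = 0.4
    facs_scale: float = 50.0
    autofluorescence: float = 5.0
    elisa: ElisaParams = field(default_factory=ElisaParams)
    dropout_rate: float = 0.1
    marker_fold: float = 8.0
    cc_fold: float = 6.0
    qc_violator_fraction: float = 0.10
    count_noise: bool = True
    nb_dispersion: float = 2.0
    n_select_clonotypes: int = 5
    background_cutoff: float = 1.0  # asinh(MFI/100) positivity convention

    @property
    def n_cells(self) -> int:
        return sum(self.n_cells_per_subset.values())

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells_per_subset: total cell count must be >= 1")
        for name in (
            "n_genes", "n_marker_genes_per_subset", "n_ercc", "n_mito", "n_clonotypes"
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for subset, n in self.n_cells_per_subset.items():
            if subset not in annotate.SUBSETS:
                raise ValueError(f"n_cells_per_subset: unknown subset {subset!r}")
            if n < 0:
                raise ValueError(f"n_cells_per_subset[{subset}] must be >= 0")
        if self.shm_rate < 0:
            raise ValueError("shm_rate must be >= 0")
        if self.facs_noise_sd < 0:
            raise ValueError("facs_noise_sd must be >= 0")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if not self.clonotype_size_distribution:
            raise ValueError("clonotype_size_distribution must be non-empty")
        for size, p in self.clonotype_size_distribution.items():
            if size < 1 or p < 0:
                raise ValueError(
                    "clonotype_size_distribution: sizes >= 1 and weights >= 0 required"
                )
        n_named = len(annotate.DEFAULT_SIGNATURES["LZ"])
        if self.n_marker_genes_per_subset > n_named:
            raise ValueError(
                f"n_marker_genes_per_subset must be <= {n_named} (bundled markers)"
            )
        n_special = (
            6 * self.n_marker_genes_per_subset
            + len(annotate.S_PHASE_GENES)
            + len(annotate.G2M_PHASE_GENES)
            + self.n_mito
        )
        if self.n_genes <= n_special:
            raise ValueError(
                f"n_genes must exceed {n_special} (marker + cycle + mito genes)"
            )

    def noise_free(self) -> "SimConfig":
        """Copy of this config with every stochastic nuisance switched off.

        Counts become rounded expected values; FACS and ELISA noise, the
        affinity scatter and dropout are zeroed.  Planted structure (SHM,
        clonotypes, QC violators) remains."""
        return replace(
            self,
            dropout_rate=0.0,
            facs_noise_sd=0.0,
            count_noise=False,
            affinity_model=replace(self.affinity_model, sd=0.0),
            elisa=replace(
                self.elisa, replicate_noise_sd=0.0, negative_control_sd=0.0
            ),
        )


@dataclass
class GroundTruth:
    """Everything the generator knows and the pipeline should recover."""

    cells: pd.DataFrame  # indexed by cell_id
    chains: pd.DataFrame  # one row per (cell_id, locus)
    mutations: dict  # (cell_id, locus) -> list of planted mutation dicts
    mabs: pd.DataFrame  # one row per assayed mAb
    selected_clonotypes: list
    od_threshold: float


@dataclass
class SimBundle:
    config: SimConfig
    counts: pd.DataFrame  # genes (incl. ERCC) x cells
    ercc_expected: pd.Series
    index_sort: pd.DataFrame  # plate, well, channel columns
    well_map: pd.DataFrame  # plate, well, cell_id
    contigs: pd.DataFrame  # AIRR-style rearrangement table
    germline_refs: dict  # allele -> (sequence, RegionMap)
    elisa: pd.DataFrame  # long plate table: mab_id, amount_ng, replicate, od
    truth: GroundTruth

    def write(self, outdir, seed: Optional[int] = None) -> dict:
        from . import io

        return io.write_bundle(self, outdir, seed=seed)


def plant_mutations(
    germline: str,
    region_map: RegionMap,
    n_mut: int,
    seed,
) -> tuple[str, list[dict]]:
    """Plant ``n_mut`` substitutions in distinct codons of a germline V.

    Each mutation is recorded with its position, bases, CDR/FW region and
    silent flag (codon translation with the substitution applied alone).
    Restricting to one substitution per codon keeps that per-substitution
    flag identical to comparing the germline and fully mutated codons.
    """
    if region_map is None:
        raise ValueError("region_map is required")
    if n_mut < 0 or n_mut > len(germline):
        raise ValueError("n_mut must be in [0, len(germline)]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frame = region_map.frame
    n_codons = (len(germline) - frame) // 3
    if n_mut > n_codons:
        raise ValueError(f"n_mut={n_mut} exceeds the {n_codons} available codons")
    if n_mut == 0:
        return germline, []
    codons = rng.choice(n_codons, size=n_mut, replace=False)
    seq = list(germline)
    mutations = []
    for codon_idx in sorted(int(c) for c in codons):
        offset = int(rng.integers(0, 3))
        pos = frame + codon_idx * 3 + offset
        ref = germline[pos]
        alt = rng.choice([b for b in _BASES if b != ref])
        seq[pos] = alt
        mutations.append(
            {
                "position": pos,
                "ref": ref,
                "alt": str(alt),
                "region": region_map.region_type_at(pos),
                "silent": is_silent(germline, pos, str(alt), frame=frame),
            }
        )
    return "".join(seq), mutations


# ---------------------------------------------------------------------------
# internal generator pieces
# ---------------------------------------------------------------------------

_PHASE_PROBS = {
    "LZ": (0.55, 0.35, 0.10),
    "DZ": (0.15, 0.25, 0.60),
    "LZtoDZ": (0.15, 0.60, 0.25),
    "preMem": (0.90, 0.07, 0.03),
    "prePC": (0.30, 0.40, 0.30),
    "PC": (0.70, 0.20, 0.10),
}
_PHASES = [annotate.G1_LABEL, "S", "G2M"]

#: which subsets' marker genes are elevated in cells of a given subset
_ELEVATION = {
    "LZ": ["LZ"],
    "DZ": ["DZ"],
    "LZtoDZ": ["LZtoDZ", "LZ", "DZ"],
    "preMem": ["preMem", "LZ"],
    "prePC": ["prePC"],
    "PC": ["PC"],
}

_JUNCTION_LENGTHS = [30, 33, 36, 39, 42, 45, 48]
_CONST_STUB = {
    "IGH": "GCCAAAACGACACCCCCATCTGTCTAT",
    "IGK": "CGGGCTGATGCTGCACCAACTGTATCC",
    "IGL": "GGTCAGCCCAAGGCTGCCCCATCGGTC",
}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_BASES), size=length))


def _mutate_junction(rng: np.random.Generator, junction: str, max_sub: int) -> str:
    k = int(rng.integers(0, max_sub + 1))
    if k == 0:
        return junction
    seq = list(junction)
    for pos in rng.choice(len(seq), size=k, replace=False):
        seq[pos] = rng.choice([b for b in _BASES if b != seq[pos]])
    return "".join(seq)


def _identity(a: str, b: str) -> float:
    return sum(x == y for x, y in zip(a, b)) / len(a)


def _partition_sizes(rng, config: SimConfig) -> list[int]:
    """Clonotype sizes summing exactly to the total cell count."""
    sizes = sorted(config.clonotype_size_distribution)
    probs = np.array([config.clonotype_size_distribution[s] for s in sizes], float)
    probs /= probs.sum()
    out: list[int] = []
    remaining = config.n_cells
    for _ in range(config.n_clonotypes):
        if remaining <= 0:
            break
        s = int(rng.choice(sizes, p=probs))
        s = min(s, remaining)
        out.append(s)
        remaining -= s
    out.extend([1] * remaining)  # top up with singletons if clones ran out
    return out


def _cell_ids(n: int) -> tuple[list[str], pd.DataFrame]:
    """Sequential plate/well layout (96-well plates, A1..H12)."""
    rows = "ABCDEFGH"
    ids, map_rows = [], []
    for i in range(n):
        plate = f"p{i // 96 + 1}"
        well = f"{rows[(i % 96) // 12]}{(i % 96) % 12 + 1}"
        cid = f"{plate}.{well}"
        ids.append(cid)
        map_rows.append({"plate": plate, "well": well, "cell_id": cid})
    return ids, pd.DataFrame(map_rows)


def simulate_dataset(config: SimConfig | None = None) -> SimBundle:
    """Generate a full synthetic dataset bundle; deterministic given seed."""
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    refs = build_reference_set()
    heavy_alleles = sorted(a for a in refs if a.startswith("IGHV"))
    light_alleles = sorted(a for a in refs if a.startswith(("IGKV", "IGLV")))

    # --- cells: subsets, wells, phases -----------------------------------
    subsets = [
        s for s in annotate.SUBSETS for _ in range(config.n_cells_per_subset.get(s, 0))
    ]
    rng.shuffle(subsets)
    cell_ids, well_map = _cell_ids(config.n_cells)
    phases = [
        _PHASES[int(rng.choice(3, p=_PHASE_PROBS[s]))] for s in subsets
    ]

    # --- clonotypes -------------------------------------------------------
    sizes = _partition_sizes(rng, config)
    clono_ids = [f"cl{k:03d}" for k in range(1, len(sizes) + 1)]
    sample_names = sorted(config.sample_proportions)
    sample_p = np.array([config.sample_proportions[s] for s in sample_names], float)
    sample_p /= sample_p.sum()

    clono_meta = {}
    junction_blocks: dict = {}
    for cid, size in zip(clono_ids, sizes):
        h_allele = str(rng.choice(heavy_alleles))
        l_allele = str(rng.choice(light_alleles))
        jlen = int(rng.choice(_JUNCTION_LENGTHS))
        block = junction_blocks.setdefault((h_allele.split("*")[0], jlen), [])
        while True:
            junction = _random_seq(rng, jlen)
            if all(_identity(junction, other) < 0.7 for other in block):
                break
        block.append(junction)
        clono_meta[cid] = {
            "heavy_allele": h_allele,
            "light_allele": l_allele,
            "heavy_j": f"IGHJ{int(rng.integers(1, 5))}-sim*01",
            "light_j": (
                f"IGKJ{int(rng.integers(1, 5))}-sim*01"
                if l_allele.startswith("IGKV")
                else f"IGLJ{int(rng.integers(1, 4))}-sim*01"
            ),
            "junction": junction,
            "light_junction": _random_seq(rng, int(rng.choice(_JUNCTION_LENGTHS))),
            "sample": str(rng.choice(sample_names, p=sample_p)),
            "size": size,
        }
    cell_clono = [cid for cid, size in zip(clono_ids, sizes) for _ in range(size)]
    rng.shuffle(cell_clono)

    # --- QC violators -----------------------------------------------------
    n_viol = int(round(config.qc_violator_fraction * config.n_cells))
    violator_idx = rng.choice(config.n_cells, size=n_viol, replace=False)
    violations = {
        int(i): QC_VIOLATION_KINDS[k % len(QC_VIOLATION_KINDS)]
        for k, i in enumerate(sorted(int(v) for v in violator_idx))
    }

    # --- BCR chains, planted mutations, affinity --------------------------
    aff = config.affinity_model
    chain_rows, contig_rows, mutations_store = [], [], {}
    affinities = np.zeros(config.n_cells)
    cell_samples = []
    contig_counter = 0

    def add_contig(**kw):
        nonlocal contig_counter
        contig_counter += 1
        kw.setdefault("sequence_id", f"ctg{contig_counter:06d}")
        contig_rows.append(kw)
        return kw["sequence_id"]

    for i, cell in enumerate(cell_ids):
        clono = clono_meta[cell_clono[i]]
        sample = clono["sample"]
        cell_samples.append(sample)
        mult = config.sample_shm_multiplier.get(sample, 1.0)
        cdr_nonsilent_total = 0
        for locus_kind in ("heavy", "light"):
            allele = clono["heavy_allele"] if locus_kind == "heavy" else clono["light_allele"]
            germ_seq, rmap = refs[allele]
            locus = "IGH" if locus_kind == "heavy" else (
                "IGK" if allele.startswith("IGKV") else "IGL"
            )
            n_mut = min(int(rng.poisson(config.shm_rate * mult)), 40)
            mutated, muts = plant_mutations(germ_seq, rmap, n_mut, rng)
            cdr_nonsilent_total += sum(
                1 for m in muts if m["region"] == "CDR" and not m["silent"]
            )
            junction = (
                _mutate_junction(
                    rng, clono["junction"], max(1, len(clono["junction"]) // 20)
                )
                if locus == "IGH"
                else clono["light_junction"]
            )
            j_call = clono["heavy_j"] if locus == "IGH" else clono["light_j"]
            c_call = {"IGH": "IGHG1", "IGK": "IGKC", "IGL": "IGLC1"}[locus]
            true_seq = mutated + junction + _CONST_STUB[locus]
            expr = float(rng.integers(200, 800))
            true_id = add_contig(
                cell_id=cell, locus=locus, v_call=allele, j_call=j_call,
                c_call=c_call, junction=junction, sequence=true_seq,
                duplicate_count=expr, productive=True, frame_in_constant=True,
            )
            # decoys exercising each consolidation step
            n_decoy = int(rng.integers(0, 4 if locus == "IGH" else 3))
            for d in range(n_decoy):
                kind = int(rng.integers(0, 3))
                if kind == 0:  # same rearrangement, shorter (merged away)
                    cut = int(rng.integers(20, 80))
                    add_contig(
                        cell_id=cell, locus=locus, v_call=allele, j_call=j_call,
                        c_call=c_call, junction=junction,
                        sequence=true_seq[cut:],
                        duplicate_count=float(rng.integers(1, 1000)),
                        productive=True, frame_in_constant=True,
                    )
                elif kind == 1:  # no in-frame constant region (discarded)
                    decoy_j = _random_seq(rng, len(junction))
                    add_contig(
                        cell_id=cell, locus=locus, v_call=allele, j_call=j_call,
                        c_call=None, junction=decoy_j,
                        sequence=mutated + decoy_j + _CONST_STUB[locus],
                        duplicate_count=float(rng.integers(1, 1000)),
                        productive=False, frame_in_constant=False,
                    )
                else:  # competing rearrangement with lower expression
                    decoy_j = _random_seq(rng, len(junction))
                    add_contig(
                        cell_id=cell, locus=locus, v_call=allele, j_call=j_call,
                        c_call=c_call, junction=decoy_j,
                        sequence=mutated + decoy_j + _CONST_STUB[locus],
                        duplicate_count=float(rng.integers(0, int(expr))),
                        productive=True, frame_in_constant=True,
                    )
            chain_rows.append(
                {
                    "cell_id": cell, "locus": locus, "v_call": allele,
                    "junction": junction, "sequence_id": true_id,
                    "n_mut": len(muts),
                    "cdr": sum(m["region"] == "CDR" for m in muts),
                    "fw": sum(m["region"] == "FW" for m in muts),
                    "silent": sum(m["silent"] for m in muts),
                    "nonsilent": sum(not m["silent"] for m in muts),
                }
            )
            mutations_store[(cell, locus)] = muts

        if rng.random() < aff.background_fraction:
            affinities[i] = aff.background_affinity * np.exp(rng.normal(0, 0.3))
        else:
            affinities[i] = 10 ** (
                aff.log10_base
                + aff.per_cdr_nonsilent * cdr_nonsilent_total
                + rng.normal(0, aff.sd)
            )

    contigs = pd.DataFrame(contig_rows)[
        [
            "sequence_id", "cell_id", "locus", "v_call", "j_call", "c_call",
            "junction", "sequence", "duplicate_count", "productive",
            "frame_in_constant",
        ]
    ]
    contigs["junction_aa"] = ""  # filled by io on write; not used downstream

    # --- count matrix -----------------------------------------------------
    markers = {
        s: annotate.DEFAULT_SIGNATURES[s][: config.n_marker_genes_per_subset]
        for s in annotate.SUBSETS
    }
    marker_genes = [g for s in annotate.SUBSETS for g in markers[s]]
    cc_genes = annotate.S_PHASE_GENES + annotate.G2M_PHASE_GENES
    mito_genes = (
        MITO_GENES_MOUSE[: config.n_mito]
        if config.n_mito <= len(MITO_GENES_MOUSE)
        else MITO_GENES_MOUSE
        + [f"mt-sim{i}" for i in range(1, config.n_mito - len(MITO_GENES_MOUSE) + 1)]
    )
    n_background = config.n_genes - len(marker_genes) - len(cc_genes) - len(mito_genes)
    background_genes = [f"Gene{i:04d}" for i in range(1, n_background + 1)]
    endo_genes = background_genes + marker_genes + cc_genes + mito_genes
    ercc_ids = [f"ERCC-{i:05d}" for i in range(1, config.n_ercc + 1)]

    base = np.zeros(len(endo_genes))
    base[: n_background] = rng.lognormal(mean=np.log(3.0), sigma=1.0, size=n_background)
    gene_pos = {g: k for k, g in enumerate(endo_genes)}
    # mitochondrial fraction ~4.5% of the endogenous total
    endo_total = base.sum()
    mito_frac = 0.045
    for g in mito_genes:
        base[gene_pos[g]] = endo_total * mito_frac / (1 - mito_frac) / len(mito_genes)

    mean = np.tile(base[:, None], (1, config.n_cells))
    for i in range(config.n_cells):
        for s in _ELEVATION[subsets[i]]:
            for g in markers[s]:
                mean[gene_pos[g], i] = config.marker_fold
        phase_genes = (
            annotate.S_PHASE_GENES
            if phases[i] == "S"
            else annotate.G2M_PHASE_GENES if phases[i] == "G2M" else []
        )
        for g in phase_genes:
            mean[gene_pos[g], i] = config.cc_fold

    # spike-in ladder: 6 concentration levels, capture 0.5 counts per unit
    ercc_conc = np.array([2.0 ** (i % 6) for i in range(config.n_ercc)])
    ercc_mean = np.tile((0.5 * ercc_conc)[:, None], (1, config.n_cells))

    for i, kind in violations.items():
        if kind == "low_umi":
            mean[:, i] *= 0.08
        elif kind == "few_genes":
            keep = np.zeros(len(endo_genes), dtype=bool)
            keep[: max(1, n_background // 4)] = True
            for g in mito_genes:
                keep[gene_pos[g]] = True
            mean[~keep, i] = 0.0
        elif kind == "high_mito":
            for g in mito_genes:
                mean[gene_pos[g], i] *= 15.0
        elif kind == "bad_ercc":
            ercc_mean[:, i] = rng.permutation(ercc_mean[:, i])

    if config.count_noise:
        theta = config.nb_dispersion
        lam = np.where(
            mean > 0, rng.gamma(shape=theta, scale=np.maximum(mean, 1e-12) / theta), 0.0
        )
        endo_counts = rng.poisson(lam)
        if config.dropout_rate > 0:
            endo_counts = np.where(
                rng.random(endo_counts.shape) < config.dropout_rate, 0, endo_counts
            )
        ercc_counts = rng.poisson(ercc_mean)
    else:
        endo_counts = np.rint(mean).astype(int)
        ercc_counts = np.rint(ercc_mean).astype(int)

    counts = pd.DataFrame(
        np.vstack([endo_counts, ercc_counts]),
        index=pd.Index(endo_genes + ercc_ids, name="gene"),
        columns=pd.Index(cell_ids, name="cell_id"),
    )
    ercc_expected = pd.Series(ercc_conc, index=ercc_ids, name="concentration")

    # --- index-sort fluorescence ------------------------------------------
    mfi_ova = (
        config.facs_scale
        * affinities
        * np.exp(rng.normal(0, config.facs_noise_sd, config.n_cells))
        + config.autofluorescence
    )
    facs = well_map[["plate", "well"]].copy()
    facs["OVA-AF647"] = mfi_ova
    for ch in FACS_CHANNELS[1:]:
        level = rng.lognormal(np.log(300), 0.5, config.n_cells)
        if ch.startswith("CD138"):
            level = np.where(
                np.array(subsets) == "PC", level * 20, level * 0.1
            )
        facs[ch] = level
    asinh_ova = np.arcsinh(mfi_ova / 100.0)
    above_bg = asinh_ova > config.background_cutoff

    # --- cells table -------------------------------------------------------
    cells = pd.DataFrame(
        {
            "sample": cell_samples,
            "subset": subsets,
            "phase": phases,
            "clonotype_id": cell_clono,
            "affinity": affinities,
            "above_background": above_bg,
            "qc_violation": [
                violations.get(i, "") for i in range(config.n_cells)
            ],
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )

    # --- ELISA: mAbs from selected clonotypes ------------------------------
    # mAbs are made from QC-passing cells of clonotypes that qualify on
    # QC-passing evidence (size >= 5, >= 1 member above background), so the
    # generator's bookkeeping matches what the pipeline can see.
    ep = config.elisa
    clean = cells[cells["qc_violation"] == ""]
    by_clono = clean.groupby("clonotype_id")
    qualifying = sorted(
        cid
        for cid, grp in by_clono
        if len(grp) >= 5 and grp["above_background"].any()
    )
    n_sel = min(config.n_select_clonotypes, len(qualifying))
    selected = sorted(
        str(c) for c in rng.choice(qualifying, size=n_sel, replace=False)
    ) if n_sel else []

    amounts = ep.start_ng / ep.factor ** np.arange(ep.n_dilutions)
    neg_ods = np.clip(
        rng.normal(ep.negative_control_mean, ep.negative_control_sd, ep.n_negative_controls),
        0, None,
    )
    od_threshold = float(neg_ods.mean() + 3 * neg_ods.std(ddof=1))

    elisa_rows, mab_rows = [], []

    def add_mab(mab_id, clonotype_id, cell_id, affinity):
        K = ep.k_scale / max(affinity, 1e-12)
        a_star = K * od_threshold / (ep.od_max - od_threshold)
        censored_above = bool(
            ep.od_max * amounts[0] / (amounts[0] + K) < od_threshold
        )
        censored_below = bool(
            ep.od_max * amounts[-1] / (amounts[-1] + K) >= od_threshold
        )
        mab_rows.append(
            {
                "mab_id": mab_id, "clonotype_id": clonotype_id, "cell_id": cell_id,
                "affinity": affinity, "true_threshold_ng": a_star,
                "censored_above": censored_above, "censored_below": censored_below,
            }
        )
        for a in amounts:
            for r in range(1, ep.n_replicates + 1):
                od = ep.od_max * a / (a + K) + rng.normal(0, ep.replicate_noise_sd)
                elisa_rows.append(
                    {"mab_id": mab_id, "amount_ng": a, "replicate": r,
                     "od": max(float(od), 0.0)}
                )

    for cid in selected:
        add_mab(f"{cid}_germline", cid, None, aff.background_affinity)
        for cell in sorted(by_clono.get_group(cid).index):
            add_mab(cell, cid, cell, float(cells.loc[cell, "affinity"]))

    for od in neg_ods:
        elisa_rows.append(
            {"mab_id": "negative_control", "amount_ng": np.nan, "replicate": 1,
             "od": float(od)}
        )
    for a in amounts:  # high-affinity commercial positive control
        for r in range(1, ep.n_replicates + 1):
            od = ep.od_max * a / (a + 1.0) + rng.normal(0, ep.replicate_noise_sd)
            elisa_rows.append(
                {"mab_id": "positive_control", "amount_ng": a, "replicate": r,
                 "od": max(float(od), 0.0)}
            )

    truth = GroundTruth(
        cells=cells,
        chains=pd.DataFrame(chain_rows),
        mutations=mutations_store,
        mabs=pd.DataFrame(
            mab_rows,
            columns=[
                "mab_id", "clonotype_id", "cell_id", "affinity",
                "true_threshold_ng", "censored_above", "censored_below",
            ],
        ),
        selected_clonotypes=selected,
        od_threshold=od_threshold,
    )
    return SimBundle(
        config=config,
        counts=counts,
        ercc_expected=ercc_expected,
        index_sort=facs,
        well_map=well_map,
        contigs=contigs,
        germline_refs=refs,
        elisa=pd.DataFrame(elisa_rows),
        truth=truth,
    )
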