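"""BCR contig consolidation, clonotype calling and somatic-mutation counting.

Plate-based 5'-end scRNA-seq reconstructs several candidate immunoglobulin
contigs per cell.  Consolidation reduces them to one heavy (IGH) and one
light (IGK/IGL) chain per cell in three steps: contigs of the same V(D)J
rearrangement are merged keeping the largest sequence, contigs without an
in-frame constant region are discarded, and among remaining rearrangements
the highest-expressed one is retained per chain class.

Clonally related cells are grouped by heavy-chain evidence: same V gene,
same junction (CDR3) nucleotide length, and junction identity above a
threshold, clustered by single linkage.  Somatic hypermutation is counted
per chain against the inferred germline by end-free global alignment,
splitting substitutions by region (CDR vs framework) and by coding effect
(silent vs non-silent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner

from .germline import RegionMap, infer_germline, is_silent

HEAVY_LOCI = {"IGH"}
LIGHT_LOCI = {"IGK", "IGL"}


@dataclass
class Contig:
    """One reconstructed BCR chain contig of a single cell."""

    cell_id: str
    locus: str
    sequence: str
    v_call: str
    j_call: str
    c_call: str | None = None
    junction: str | None = None
    junction_aa: str | None = None
    frame_in_constant: bool | None = None
    productive: bool | None = None
    expression: float = 0.0
    sequence_id: str = ""

    def __post_init__(self) -> None:
        if self.locus not in HEAVY_LOCI | LIGHT_LOCI:
            raise ValueError(f"unknown locus {self.locus!r}")
        if self.expression < 0:
            raise ValueError("expression must be >= 0")
        if self.junction and self.junction not in self.sequence:
            raise ValueError(
                f"{self.sequence_id or self.cell_id}: junction is not a "
                "substring of the contig sequence"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def in_frame_constant(self) -> bool:
        """In-frame constant region; falls back on the productive flag when
        the annotator did not supply one, and is permissive when neither is
        present."""
        if self.frame_in_constant is not None:
            return bool(self.frame_in_constant)
        if self.productive is not None:
            return bool(self.productive)
        return True


@dataclass
class ChainSelection:
    cell_id: str
    heavy: Contig | None = None
    light: Contig | None = None

    @property
    def paired(self) -> bool:
        return self.heavy is not None and self.light is not None


@dataclass
class Clonotype:
    clonotype_id: str
    member_cell_ids: set
    v_gene: str
    junction_length: int
    representative_junction: str
    inferred_germline_vh: str | None = None

    @property
    def size(self) -> int:
        return len(self.member_cell_ids)


@dataclass
class MutationProfile:
    """Substitution counts of one chain vs its germline.

    total = CDR + FW = silent + non-silent; indels are flagged but never
    counted as mutations.
    """

    cdr_count: int = 0
    fw_count: int = 0
    silent_count: int = 0
    nonsilent_count: int = 0
    indel_flag: bool = False
    mutations: list = field(default_factory=list)

    @property
    def total_count(self) -> int:
        return self.cdr_count + self.fw_count


def _merge_key(c: Contig):
    return (c.locus, c.v_call, c.j_call, c.junction)


def consolidate_contigs(contigs: list[Contig]) -> ChainSelection:
    """Reduce one cell's contigs to at most one heavy and one light chain.

    Step 1 merges contigs of the same rearrangement — identical (locus,
    v_call, j_call, junction) — keeping the largest sequence.  Step 2
    discards contigs lacking an in-frame constant region.  Step 3 keeps,
    per chain class, the surviving contig with the highest expression.
    Deterministic tie-breaks: longer sequence, then higher expression,
    then sequence_id.
    """
    if not contigs:
        return ChainSelection(cell_id="", heavy=None, light=None)
    cell_ids = {c.cell_id for c in contigs}
    if len(cell_ids) != 1:
        raise ValueError(f"contigs from multiple cells: {sorted(cell_ids)}")
    cell_id = contigs[0].cell_id

    merged: dict = {}
    for c in sorted(contigs, key=lambda c: (-c.length, -c.expression, c.sequence_id)):
        merged.setdefault(_merge_key(c), c)
    survivors = [
        c for c in merged.values() if c.c_call and c.in_frame_constant
    ]

    def best(pool: list[Contig]) -> Contig | None:
        if not pool:
            return None
        return sorted(
            pool, key=lambda c: (-c.expression, -c.length, c.sequence_id)
        )[0]

    heavy = best([c for c in survivors if c.locus in HEAVY_LOCI])
    light = best([c for c in survivors if c.locus in LIGHT_LOCI])
    return ChainSelection(cell_id=cell_id, heavy=heavy, light=light)


def junction_identity(a: str, b: str) -> float:
    """Fraction of identical positions between equal-length junctions."""
    if len(a) != len(b):
        raise ValueError("junctions must have equal length")
    if not a:
        return 1.0
    return sum(x == y for x, y in zip(a, b)) / len(a)


def strip_allele(v_call: str) -> str:
    return v_call.split("*")[0]


def call_clonotypes(
    selections: list[ChainSelection],
    junction_identity_min: float = 0.8,
    references: dict | None = None,
) -> tuple[pd.DataFrame, dict[str, Clonotype], list[str]]:
    """Partition cells into clonotypes from heavy-chain evidence.

    Cells are blocked by (V gene, junction nt length) and single-linkage
    clustered within blocks, linking pairs whose junction identity is at
    least ``junction_identity_min``.  Cells lacking a heavy chain with a
    junction are excluded and reported.  Clonotype ids ``c1..cN`` are
    assigned by decreasing size then smallest member cell_id, so any
    permutation of the input yields the same named partition.

    Returns (per-cell assignment table, clonotype_id → Clonotype, excluded
    cell ids).
    """
    excluded: list[str] = []
    cells: list[tuple[str, str, str]] = []  # (cell_id, v_gene, junction)
    for sel in selections:
        h = sel.heavy
        if h is None or not h.junction or not h.v_call:
            excluded.append(sel.cell_id)
            continue
        cells.append((sel.cell_id, strip_allele(h.v_call), h.junction))
    cells.sort()

    parent = list(range(len(cells)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    blocks: dict = {}
    for idx, (_, v_gene, junction) in enumerate(cells):
        blocks.setdefault((v_gene, len(junction)), []).append(idx)
    for members in blocks.values():
        for i_pos, i in enumerate(members):
            for j in members[i_pos + 1 :]:
                if junction_identity(cells[i][2], cells[j][2]) >= junction_identity_min:
                    union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(len(cells)):
        groups.setdefault(find(i), []).append(i)
    ordered = sorted(
        groups.values(), key=lambda g: (-len(g), min(cells[i][0] for i in g))
    )

    clonotypes: dict[str, Clonotype] = {}
    rows = []
    for rank, members in enumerate(ordered, start=1):
        cid = f"c{rank}"
        member_cells = {cells[i][0] for i in members}
        v_gene = cells[members[0]][1]
        junctions = sorted(cells[i][2] for i in members)
        rep = max(junctions, key=lambda j: (junctions.count(j), j))
        germline = None
        if references is not None:
            try:
                germline = infer_germline(v_gene, references)[0]
            except KeyError:
                germline = None
        clonotypes[cid] = Clonotype(
            clonotype_id=cid,
            member_cell_ids=member_cells,
            v_gene=v_gene,
            junction_length=len(rep),
            representative_junction=rep,
            inferred_germline_vh=germline,
        )
        for i in members:
            rows.append(
                {
                    "cell_id": cells[i][0],
                    "clonotype_id": cid,
                    "v_gene": v_gene,
                    "junction": cells[i][2],
                    "junction_length": len(cells[i][2]),
                    "clonotype_size": len(members),
                }
            )
    assignments = (
        pd.DataFrame(
            rows,
            columns=[
                "cell_id",
                "clonotype_id",
                "v_gene",
                "junction",
                "junction_length",
                "clonotype_size",
            ],
        )
        .sort_values("cell_id")
        .reset_index(drop=True)
    )
    return assignments, clonotypes, excluded


def _make_aligner(
    match: float = 1, mismatch: float = -1, gap_open: float = -4, gap_extend: float = -1
) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    # end-free: terminal overhangs on either sequence are not penalized
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # Biopython < 1.86 naming
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def alignment_score(a: str, b: str) -> float:
    """End-free global alignment score under the default scoring scheme."""
    return float(_make_aligner().score(a, b))


def count_mutations(
    observed: str,
    germline: str,
    region_map: RegionMap,
    min_coverage: float = 0.8,
) -> MutationProfile:
    """Count substitutions of an observed chain vs its germline V region.

    The two sequences are aligned globally with free end gaps (match +1,
    mismatch −1, gap open −4, gap extend −1).  Each aligned substitution is
    attributed to the region (CDR/FW) of its germline position, and scored
    silent/non-silent by translating the germline codon against the codon
    with that single substitution applied.  Internal indels set
    ``indel_flag`` and are not counted.  Alignment covering less than
    ``min_coverage`` of the germline raises (sequence/germline mismatch).
    """
    if not germline:
        raise ValueError("empty germline sequence")
    aln = _make_aligner().align(germline, observed)[0]
    target_blocks, query_blocks = aln.aligned

    covered = sum(int(e - s) for s, e in target_blocks)
    if covered < min_coverage * len(germline):
        raise ValueError(
            "sequence/germline mismatch: alignment covers "
            f"{covered}/{len(germline)} germline positions"
        )

    profile = MutationProfile()
    # internal gaps between consecutive aligned blocks are indels
    for k in range(len(target_blocks) - 1):
        if (
            target_blocks[k + 1][0] > target_blocks[k][1]
            or query_blocks[k + 1][0] > query_blocks[k][1]
        ):
            profile.indel_flag = True

    for (ts, te), (qs, _qe) in zip(target_blocks, query_blocks):
        for off in range(int(te - ts)):
            g_pos = int(ts) + off
            ref = germline[g_pos]
            alt = observed[int(qs) + off]
            if ref == alt:
                continue
            region = region_map.region_type_at(g_pos)
            silent = is_silent(germline, g_pos, alt, frame=region_map.frame)
            if region == "CDR":
                profile.cdr_count += 1
            else:
                profile.fw_count += 1
            if silent:
                profile.silent_count += 1
            else:
                profile.nonsilent_count += 1
            profile.mutations.append(
                {
                    "position": g_pos,
                    "ref": ref,
                    "alt": alt,
                    "region": region,
                    "silent": silent,
                }
            )
    return profile
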