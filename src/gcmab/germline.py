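"""Synthetic germline V-region references and CDR/FW region maps.

The package ships an invented, fully controlled set of immunoglobulin
V-segment germline sequences (294 nt, in frame, no stop codons) named in
IMGT style with a ``-sim`` infix (e.g. ``IGHV1-sim*01``) so they can never
be mistaken for real alleles.  Every allele carries a region map labelling
each position as CDR or framework (FW), with 0-based half-open coordinates
and an explicit reading-frame offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

V_LENGTH = 294  # 98 codons, in frame

# FW/CDR layout shared by all synthetic alleles (0-based half-open, nt).
# Boundaries fall on codon boundaries so region labels respect the frame.
_REGION_LAYOUT = [
    ("FW1", "FW", 0, 78),
    ("CDR1", "CDR", 78, 114),
    ("FW2", "FW", 114, 165),
    ("CDR2", "CDR", 165, 192),
    ("FW3", "FW", 192, 294),
]

_STOP_CODONS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"

# Fixed internal seed: the reference set is part of the package surface and
# must be identical across runs and machines.
_REFERENCE_SEED = 294001


@dataclass(frozen=True)
class RegionMap:
    """CDR/FW annotation of a germline V segment.

    ``regions`` are (name, type, start, end) with type in {"CDR", "FW"},
    coordinates 0-based half-open on the germline sequence.  ``frame`` is
    the nt offset of the first complete codon.
    """

    frame: int = 0
    regions: tuple = field(default_factory=lambda: tuple(_REGION_LAYOUT))

    def region_type_at(self, pos: int) -> str:
        for _, rtype, start, end in self.regions:
            if start <= pos < end:
                return rtype
        raise IndexError(f"position {pos} outside region map (0..{self.end})")

    @property
    def end(self) -> int:
        return max(end for _, _, _, end in self.regions)

    def to_dict(self) -> dict:
        return {
            "frame": self.frame,
            "coordinates": "0-based half-open",
            "regions": [
                {"name": n, "type": t, "start": s, "end": e}
                for n, t, s, e in self.regions
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegionMap":
        regions = tuple(
            (r["name"], r["type"], int(r["start"]), int(r["end"]))
            for r in d["regions"]
        )
        return cls(frame=int(d.get("frame", 0)), regions=regions)


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    codons = []
    for _ in range(n_codons):
        while True:
            codon = "".join(rng.choice(list(_BASES), size=3))
            if codon not in _STOP_CODONS:
                break
        codons.append(codon)
    return "".join(codons)


def build_reference_set() -> dict[str, tuple[str, RegionMap]]:
    """Return the bundled allele→(sequence, region map) dictionary.

    Deterministic: the same set is produced on every call.
    """
    rng = np.random.default_rng(_REFERENCE_SEED)
    names = (
        [f"IGHV{i}-sim*01" for i in range(1, 9)]
        + [f"IGKV{i}-sim*01" for i in range(1, 7)]
        + ["IGLV1-sim*01", "IGLV2-sim*01"]
    )
    refs: dict[str, tuple[str, RegionMap]] = {}
    rmap = RegionMap()
    for name in names:
        refs[name] = (_random_orf(rng, V_LENGTH // 3), rmap)
    return refs


def infer_germline(
    v_call: str, references: dict[str, tuple[str, RegionMap]]
) -> tuple[str, RegionMap]:
    """Resolve a V-gene call to its germline sequence and region map.

    A call without an allele suffix resolves to allele ``*01`` (documented
    default-allele rule).  Unknown alleles raise with the available names.
    """
    if v_call in references:
        return references[v_call]
    if "*" not in v_call and f"{v_call}*01" in references:
        return references[f"{v_call}*01"]
    available = ", ".join(sorted(references))
    raise KeyError(f"unknown V allele {v_call!r}; available: {available}")


def translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


def is_silent(germline: str, pos: int, alt: str, frame: int = 0) -> bool:
    """Whether substituting ``alt`` at ``pos`` preserves the amino acid.

    The germline codon containing ``pos`` (in the reading frame starting at
    ``frame``) is compared with the same codon carrying only this
    substitution.  Positions upstream of the frame offset are treated as
    non-silent (no complete codon to compare).
    """
    if pos < frame:
        return False
    codon_start = frame + ((pos - frame) // 3) * 3
    if codon_start + 3 > len(germline):
        return False
    ref_codon = germline[codon_start : codon_start + 3]
    mut_codon = list(ref_codon)
    mut_codon[pos - codon_start] = alt
    return translate_codon(ref_codon) == translate_codon("".join(mut_codon))
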