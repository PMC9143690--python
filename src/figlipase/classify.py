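"""Lipase family assignment and reference-anchored sequence characterization.

A :class:`ReferenceSpec` describes one family exemplar: its sequence, the
1-based positions of the Ser-Asp-His catalytic triad, and anchored regions
(the beta-9 surface loop and the amphipathic lid of pancreatic-type neutral
lipases, the cap domain of gastric-type acid lipases).  Queries are aligned
to the reference and features are read off the alignment columns:

* a triad site is *complete* when the aligned query residue equals the
  expected residue (the ambiguity letter X never matches);
* a region spans the alignment columns between its two anchors inclusive,
  and its length is the number of query residues inside that span (query
  gaps shorten it; a query gap at an anchor column keeps the span but
  records the anchor as absent).

Neutral lipases are called putative TAG hydrolases when the beta-9 loop is
longer than 15 residues and the lid is at least 18 residues long.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml
from Bio.SeqUtils import seq3

from .align import Alignment, AlignmentParams, pairwise_align
from .formats import ProteinRecord

__all__ = [
    "RegionSpec",
    "TriadSite",
    "ReferenceSpec",
    "FamilyAssignment",
    "TriadReport",
    "RegionReport",
    "ActivityCall",
    "assign_family",
    "check_triad",
    "extract_region",
    "call_tag_activity",
    "check_cap",
    "characterize",
    "read_reference_panel",
    "write_reference_panel",
]

DEFAULT_LOOP_THRESHOLD = 15  # TAG call requires loop length strictly greater
DEFAULT_LID_THRESHOLD = 18  # TAG call requires lid length at least this
DEFAULT_MIN_FAMILY_SCORE = 80.0  # raw local-alignment score floor


@dataclass(frozen=True)
class TriadSite:
    """One catalytic position on the reference (1-based) and its residue."""

    name: str  # "Ser" | "Asp" | "His"
    position: int
    residue: str


@dataclass(frozen=True)
class RegionSpec:
    """An anchored region: two reference positions with expected residues."""

    kind: str  # beta9 | lid | cap
    start_position: int
    start_residue: str
    end_position: int
    end_residue: str

    def __post_init__(self) -> None:
        if self.start_position >= self.end_position:
            raise ValueError(f"region {self.kind}: anchors must be strictly increasing")


@dataclass(frozen=True)
class ReferenceSpec:
    family: str
    ref_id: str
    sequence: str
    triad: tuple[TriadSite, ...] = ()
    regions: tuple[RegionSpec, ...] = ()

    def __post_init__(self) -> None:
        positions = [t.position for t in self.triad]
        if len(set(positions)) != len(positions):
            raise ValueError("triad positions must be distinct")
        for t in self.triad:
            if not 1 <= t.position <= len(self.sequence):
                raise ValueError(f"triad position {t.position} outside reference")
            if self.sequence[t.position - 1] != t.residue:
                raise ValueError(
                    f"reference {self.ref_id}: residue at {t.position} is "
                    f"{self.sequence[t.position - 1]}, expected {t.residue}"
                )
        for r in self.regions:
            for pos, res in ((r.start_position, r.start_residue), (r.end_position, r.end_residue)):
                if self.sequence[pos - 1] != res:
                    raise ValueError(
                        f"reference {self.ref_id}: anchor residue mismatch at {pos}"
                    )

    def region(self, kind: str) -> RegionSpec:
        for r in self.regions:
            if r.kind == kind:
                return r
        raise KeyError(f"reference {self.ref_id} has no {kind!r} region")


@dataclass(frozen=True)
class FamilyAssignment:
    query_id: str
    family: str  # family name or "unassigned"
    score: float
    reference_id: str | None


@dataclass(frozen=True)
class TriadReport:
    query_id: str
    sites: tuple[tuple[str, str, str | None], ...]  # (name, expected, observed|None)
    complete: bool
    description: str


@dataclass(frozen=True)
class RegionReport:
    kind: str
    sequence: str
    length: int
    start_residue: str | None  # observed anchor residues; None = aligned to a gap
    end_residue: str | None
    passes: bool

    def __post_init__(self) -> None:
        if self.length != len(self.sequence):
            raise ValueError("region length must equal its sequence length")


@dataclass(frozen=True)
class ActivityCall:
    query_id: str
    putative_tag_hydrolase: bool
    loop_length: int
    lid_length: int
    loop_threshold: int
    lid_threshold: int

    @property
    def rule_trace(self) -> str:
        return (
            f"loop {self.loop_length} > {self.loop_threshold}: "
            f"{self.loop_length > self.loop_threshold}; "
            f"lid {self.lid_length} >= {self.lid_threshold}: "
            f"{self.lid_length >= self.lid_threshold}"
        )


def assign_family(
    query: ProteinRecord,
    panel: Sequence[ReferenceSpec],
    min_score: float = DEFAULT_MIN_FAMILY_SCORE,
    params: AlignmentParams | None = None,
) -> FamilyAssignment:
    """Best-scoring local alignment against the panel decides the family.

    Ties break by panel order (first reference with the best score wins);
    below ``min_score`` the query is left unassigned.
    """
    if not panel:
        raise ValueError("reference panel is empty")
    if params is None:
        params = AlignmentParams(mode="local")
    elif params.mode != "local":
        params = AlignmentParams(
            matrix_name=params.matrix_name,
            gap_open=params.gap_open,
            gap_extend=params.gap_extend,
            mode="local",
        )
    best_score, best_ref = float("-inf"), None
    for ref in panel:
        aln = pairwise_align(query.sequence, ref.sequence, params)
        if aln.score > best_score:
            best_score, best_ref = aln.score, ref
    if best_score >= min_score:
        return FamilyAssignment(query.id, best_ref.family, best_score, best_ref.ref_id)
    return FamilyAssignment(query.id, "unassigned", best_score, None)


def _aligned(query: ProteinRecord, ref: ReferenceSpec, params: AlignmentParams | None) -> Alignment:
    if params is None:
        params = AlignmentParams()
    return pairwise_align(query.sequence, ref.sequence, params)


def check_triad(
    query: ProteinRecord,
    ref: ReferenceSpec,
    params: AlignmentParams | None = None,
    alignment: Alignment | None = None,
) -> TriadReport:
    """Read the residues aligned to the reference triad positions.

    ``complete`` is true iff every site shows exactly the expected residue.
    Substitutions are described as "Glu in place of Ser"; a gap as
    "lacked His".
    """
    if not ref.triad:
        raise ValueError(f"reference {ref.ref_id} has no catalytic triad defined")
    aln = alignment if alignment is not None else _aligned(query, ref, params)
    sites = []
    problems = []
    for site in ref.triad:
        col = aln.ref_position_to_column(site.position)
        qpos = aln.column_to_query_position(col)
        observed = None if qpos is None else query.sequence[qpos - 1]
        sites.append((site.name, site.residue, observed))
        if observed is None:
            problems.append(f"lacked {site.name}")
        elif observed != site.residue:
            problems.append(f"{seq3(observed)} in place of {site.name}")
    complete = not problems
    description = "complete" if complete else "; ".join(problems)
    return TriadReport(query.id, tuple(sites), complete, description)


def extract_region(
    query: ProteinRecord,
    ref: ReferenceSpec,
    kind: str,
    params: AlignmentParams | None = None,
    alignment: Alignment | None = None,
) -> RegionReport:
    """Extract the query subsequence spanned by a region's anchor columns.

    The span runs from the start-anchor column to the end-anchor column
    inclusive; the extracted sequence is every query residue in that span
    (contiguous in the ungapped query).  ``passes`` is true when the span
    contains at least one query residue.
    """
    spec = ref.region(kind)
    aln = alignment if alignment is not None else _aligned(query, ref, params)
    c0 = aln.ref_position_to_column(spec.start_position)
    c1 = aln.ref_position_to_column(spec.end_position)
    segment = aln.aligned_query[c0 : c1 + 1].replace("-", "")
    start_obs = aln.aligned_query[c0] if aln.aligned_query[c0] != "-" else None
    end_obs = aln.aligned_query[c1] if aln.aligned_query[c1] != "-" else None
    return RegionReport(
        kind=kind,
        sequence=segment,
        length=len(segment),
        start_residue=start_obs,
        end_residue=end_obs,
        passes=len(segment) > 0,
    )


def call_tag_activity(
    loop: RegionReport,
    lid: RegionReport,
    query_id: str = "",
    loop_threshold: int = DEFAULT_LOOP_THRESHOLD,
    lid_threshold: int = DEFAULT_LID_THRESHOLD,
) -> ActivityCall:
    """TAG-hydrolase call for a neutral lipase from its loop and lid lengths."""
    if loop.kind != "beta9" or lid.kind != "lid":
        raise ValueError("expected a beta9 report and a lid report")
    verdict = loop.length > loop_threshold and lid.length >= lid_threshold
    return ActivityCall(query_id, verdict, loop.length, lid.length, loop_threshold, lid_threshold)


def check_cap(
    query: ProteinRecord,
    ref: ReferenceSpec,
    params: AlignmentParams | None = None,
    alignment: Alignment | None = None,
) -> RegionReport:
    """Cap-domain presence for an acid lipase (anchor substitutions allowed)."""
    return extract_region(query, ref, "cap", params=params, alignment=alignment)


def characterize(
    query: ProteinRecord,
    panel: Sequence[ReferenceSpec],
    min_score: float = DEFAULT_MIN_FAMILY_SCORE,
    params: AlignmentParams | None = None,
    loop_threshold: int = DEFAULT_LOOP_THRESHOLD,
    lid_threshold: int = DEFAULT_LID_THRESHOLD,
) -> dict:
    """Full per-gene report row: family, triad, regions, TAG call.

    Returns a plain dict ready for tabular output; fields not applicable to
    the assigned family are left empty.
    """
    fam = assign_family(query, panel, min_score=min_score, params=params)
    row = {
        "id": query.id,
        "family": fam.family,
        "family_score": fam.score,
        "triad_complete": "",
        "triad_description": "",
        "loop_seq": "",
        "loop_len": "",
        "lid_seq": "",
        "lid_len": "",
        "cap_present": "",
        "putative_TAG_hydrolase": "",
    }
    if fam.family == "unassigned":
        return row
    ref = next(r for r in panel if r.ref_id == fam.reference_id)
    aln = _aligned(query, ref, params)
    if ref.triad:
        triad = check_triad(query, ref, alignment=aln)
        row["triad_complete"] = triad.complete
        row["triad_description"] = triad.description
    kinds = {r.kind for r in ref.regions}
    if "beta9" in kinds and "lid" in kinds:
        loop = extract_region(query, ref, "beta9", alignment=aln)
        lid = extract_region(query, ref, "lid", alignment=aln)
        call = call_tag_activity(
            loop, lid, query.id, loop_threshold=loop_threshold, lid_threshold=lid_threshold
        )
        row.update(
            loop_seq=loop.sequence,
            loop_len=loop.length,
            lid_seq=lid.sequence,
            lid_len=lid.length,
            putative_TAG_hydrolase=call.putative_tag_hydrolase,
        )
    if "cap" in kinds:
        cap = check_cap(query, ref, alignment=aln)
        row["cap_present"] = cap.passes
    return row


# ---------------------------------------------------------------------------
# reference panel configuration (YAML)


def read_reference_panel(path: str | Path) -> list[ReferenceSpec]:
    """Load a reference panel from the YAML configuration format.

    Structure::

        references:
          - family: neutral
            id: HPL_like
            sequence: "MK..."
            triad: {ser: [153, S], asp: [177, D], his: [264, H]}
            regions:
              - {kind: beta9, start: [204, H], end: [224, H]}
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    panel = []
    for entry in doc["references"]:
        triad = tuple(
            TriadSite(name.capitalize(), int(pos), res)
            for name, (pos, res) in entry.get("triad", {}).items()
        )
        regions = tuple(
            RegionSpec(r["kind"], int(r["start"][0]), r["start"][1], int(r["end"][0]), r["end"][1])
            for r in entry.get("regions", [])
        )
        panel.append(
            ReferenceSpec(
                family=entry["family"],
                ref_id=entry["id"],
                sequence=entry["sequence"],
                triad=triad,
                regions=regions,
            )
        )
    return panel


def write_reference_panel(panel: Sequence[ReferenceSpec], path: str | Path) -> None:
    doc = {"references": []}
    for ref in panel:
        entry: dict = {"family": ref.family, "id": ref.ref_id, "sequence": ref.sequence}
        if ref.triad:
            entry["triad"] = {t.name.lower(): [t.position, t.residue] for t in ref.triad}
        if ref.regions:
            entry["regions"] = [
                {
                    "kind": r.kind,
                    "start": [r.start_position, r.start_residue],
                    "end": [r.end_position, r.end_residue],
                }
                for r in ref.regions
            ]
        doc["references"].append(entry)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
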