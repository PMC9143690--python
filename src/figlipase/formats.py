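"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates are 1-based inclusive (GFF3 convention) throughout
the package. Protein FASTA, GFF3 gene models, TSV count tables, tab-separated
codon usage tables and newick trees are handled here; the reference-lipase
configuration format lives in :mod:`figlipase.classify` next to the type it
builds.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ProteinRecord",
    "GeneModel",
    "CodonUsageTable",
    "CountTable",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_gff",
    "write_gff",
    "read_count_table",
    "write_count_table",
    "read_codon_usage",
    "write_codon_usage",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
#: the ambiguity letter is tolerated in input but never matches a catalytic residue
AMINO_ACIDS_X = AMINO_ACIDS | {"X"}

FAMILIES = ("neutral", "acid", "lipase2", "lipase3", "GDSL", "HSL")
GROUPS = ("PFW", "NPFW")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with a stable identifier.

    The species code, when present, is the 4-letter abbreviation used in the
    per-species count table (e.g. ``Abak``); gene identifiers follow the
    ``<species>_<family>_<n>`` convention (``Abak_neutral_17``).
    """

    id: str
    sequence: str
    species: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - AMINO_ACIDS_X
        if bad:
            raise FormatError(
                f"record {self.id!r}: non-amino-acid character(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """A gene with scaffold coordinates and an ordered exon list.

    Coordinates are 1-based inclusive.  ``family`` and
    ``has_signal_peptide`` are optional annotations; signal-peptide calls are
    accepted as input, never computed.
    """

    gene_id: str
    scaffold: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    family: str | None = None
    has_signal_peptide: bool | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(f"gene {self.gene_id!r}: start > end")
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id!r}: strand must be + or -")
        if not self.exons:
            raise FormatError(f"gene {self.gene_id!r}: no exons")
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise FormatError(f"gene {self.gene_id!r}: exon start > end")
            if s < self.start or e > self.end:
                raise FormatError(
                    f"gene {self.gene_id!r}: exon {s}-{e} outside gene span "
                    f"{self.start}-{self.end}"
                )
            if prev_end is not None and s <= prev_end:
                raise FormatError(
                    f"gene {self.gene_id!r}: exons unsorted or overlapping at {s}-{e}"
                )
            prev_end = e

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def intronless(self) -> bool:
        return len(self.exons) == 1


# the standard genetic code, used to validate codon usage tables
STOP_CODONS = ("TAA", "TAG", "TGA")
_BASES = "TCAG"
ALL_CODONS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)
SENSE_CODONS = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)


def _codon_to_aa() -> dict[str, str]:
    return {c: str(Seq(c).translate()) for c in SENSE_CODONS}


CODON_TO_AA = _codon_to_aa()
#: amino acid -> tuple of synonymous sense codons
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _c, _aa in CODON_TO_AA.items():
    SYNONYMOUS_FAMILIES.setdefault(_aa, ())
    SYNONYMOUS_FAMILIES[_aa] += (_c,)


@dataclass(frozen=True)
class CodonUsageTable:
    """Codon -> frequency (per thousand, or raw counts; only ratios matter)."""

    frequencies: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(SENSE_CODONS) - set(self.frequencies)
        if missing:
            raise FormatError(f"codon usage table missing codons: {sorted(missing)[:5]}...")
        neg = [c for c, f in self.frequencies.items() if f < 0]
        if neg:
            raise FormatError(f"negative frequency for codons {neg}")
        for aa, codons in SYNONYMOUS_FAMILIES.items():
            if all(self.frequencies[c] == 0 for c in codons):
                raise FormatError(f"synonymous family for {aa} has all-zero frequency")

    def __getitem__(self, codon: str) -> float:
        return self.frequencies[codon]


@dataclass
class CountTable:
    """Species x family gene counts with a PFW/NPFW group label per species.

    Backed by a DataFrame indexed by species with one integer column per
    family; ``groups`` maps each species to its ecological group.
    """

    counts: pd.DataFrame
    groups: dict[str, str]
    abbreviations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise FormatError("negative count in count table")
        missing = set(self.counts.index) - set(self.groups)
        if missing:
            raise FormatError(f"species without group label: {sorted(missing)}")
        bad = set(self.groups.values()) - set(GROUPS)
        if bad:
            raise FormatError(f"unknown group labels: {sorted(bad)}")

    @property
    def species(self) -> list[str]:
        return list(self.counts.index)

    @property
    def families(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def group_values(self, family_or_total: str) -> dict[str, list[int]]:
        """Split one family column (or the row totals) by group label."""
        col = self.totals if family_or_total == "total" else self.counts[family_or_total]
        out: dict[str, list[int]] = {g: [] for g in GROUPS}
        for sp, v in col.items():
            out[self.groups[sp]].append(int(v))
        return out


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, species_from_id: bool = True) -> list[ProteinRecord]:
    """Read a protein FASTA into validated records, order preserved.

    Duplicate ids, empty sequences and non-amino-acid letters raise
    :class:`FormatError` naming the offending record.  When
    ``species_from_id`` is set, a leading ``Xxxx_`` token of the id is taken
    as the 4-letter species code.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        species = None
        if species_from_id and "_" in rec.id:
            head = rec.id.split("_", 1)[0]
            if len(head) == 4 and head[0].isupper():
                species = head
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq).upper(), species=species))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def read_dna_fasta(path: str | Path) -> dict[str, str]:
    """Read a CDS FASTA into an id -> uppercase DNA string mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"duplicate id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"record {rec.id!r}: empty sequence")
        out[rec.id] = seq
    return out


def write_dna_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3


def _gff_attributes(text: str) -> dict[str, str]:
    out = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        if "=" not in item:
            raise FormatError(f"malformed GFF3 attribute {item!r}")
        k, v = item.split("=", 1)
        out[k] = v
    return out


def read_gff(path: str | Path) -> list[GeneModel]:
    """Read gene + exon features from a GFF3 file into :class:`GeneModel` s.

    Exons are linked to their gene through the ``Parent`` attribute and
    sorted by start; an exon outside its gene span or lacking a Parent is an
    error. The optional ``family`` and ``signal_peptide`` gene attributes are
    carried through.
    """
    genes: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            seqid, _, ftype, start, end, _, strand, _, attrs = fields
            attributes = _gff_attributes(attrs)
            if ftype == "gene":
                gid = attributes.get("ID")
                if gid is None:
                    raise FormatError(f"{path}:{lineno}: gene without ID")
                if gid in genes:
                    raise FormatError(f"{path}:{lineno}: duplicate gene ID {gid!r}")
                sp = attributes.get("signal_peptide")
                genes[gid] = dict(
                    gene_id=gid,
                    scaffold=seqid,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    family=attributes.get("family"),
                    has_signal_peptide=None if sp is None else sp.lower() == "true",
                )
                order.append(gid)
            elif ftype == "exon":
                parent = attributes.get("Parent")
                if parent is None:
                    raise FormatError(f"{path}:{lineno}: exon without Parent")
                exons.setdefault(parent, []).append((int(start), int(end)))
    models = []
    for gid in order:
        ex = sorted(exons.get(gid, []))
        if not ex:
            raise FormatError(f"gene {gid!r}: no exon features")
        models.append(GeneModel(exons=tuple(ex), **genes[gid]))
    return models


def write_gff(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = [f"ID={g.gene_id}"]
            if g.family is not None:
                attrs.append(f"family={g.family}")
            if g.has_signal_peptide is not None:
                attrs.append(f"signal_peptide={str(g.has_signal_peptide).lower()}")
            fh.write(
                f"{g.scaffold}\tfiglipase\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                + ";".join(attrs)
                + "\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.scaffold}\tfiglipase\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# count tables


def read_count_table(source: str | Path | io.StringIO) -> CountTable:
    """Read a species x family TSV with ``species``/``group`` columns.

    A ``total`` column, when present, is checked against the row sums;
    an ``abbreviation`` column is carried through. An empty body yields an
    empty table.
    """
    df = pd.read_csv(source, sep="\t", dtype={"species": str})
    required = {"species", "group"}
    if not df.empty and not required <= set(df.columns):
        raise FormatError(f"count table needs columns {sorted(required)}")
    if df.empty:
        return CountTable(counts=pd.DataFrame(), groups={})
    fam_cols = [c for c in df.columns if c not in ("species", "group", "abbreviation", "total")]
    counts = df.set_index("species")[fam_cols].astype(int)
    if "total" in df.columns:
        stated = df.set_index("species")["total"].astype(int)
        sums = counts.sum(axis=1)
        bad = sums[sums != stated]
        if len(bad):
            raise FormatError(
                f"stated total disagrees with row sum for species {list(bad.index)}"
            )
    groups = dict(zip(df["species"], df["group"]))
    abbr = dict(zip(df["species"], df["abbreviation"])) if "abbreviation" in df.columns else {}
    return CountTable(counts=counts, groups=groups, abbreviations=abbr)


def write_count_table(table: CountTable, path: str | Path) -> None:
    df = table.counts.copy()
    df.insert(0, "group", [table.groups[s] for s in df.index])
    if table.abbreviations:
        df.insert(0, "abbreviation", [table.abbreviations.get(s, "") for s in df.index])
    df["total"] = table.counts.sum(axis=1)
    df.index.name = "species"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# codon usage tables


def read_codon_usage(path: str | Path) -> CodonUsageTable:
    """Read a two-column ``codon<TAB>frequency`` table (T or U alphabet)."""
    freqs: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("codon"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected codon<TAB>frequency")
            codon = parts[0].upper().replace("U", "T")
            if len(codon) != 3 or set(codon) - set("ACGT"):
                raise FormatError(f"{path}:{lineno}: bad codon {parts[0]!r}")
            freqs[codon] = float(parts[1])
    for stop in STOP_CODONS:
        freqs.pop(stop, None)
    return CodonUsageTable(frequencies=freqs)


def write_codon_usage(table: CodonUsageTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("codon\tfrequency\n")
        for codon in SENSE_CODONS:
            fh.write(f"{codon}\t{table.frequencies[codon]:g}\n")
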