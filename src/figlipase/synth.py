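"""Synthetic inputs with known ground truth, plus the packaged fixtures.

Every stage of the pipeline can be exercised on data generated here:
proteins derived from fixed family exemplars with planted catalytic triads
and loop/lid/cap regions of controlled length, scaffolds with planted
tandem arrays and controlled exon counts, coding sequences with controlled
codon bias, per-species count tables with a group-wise offset, and random
species trees.  All randomness flows through one seed; the planted truth is
returned alongside the data.

The defaults emulate the shape of real fig-wasp lipase data at desk scale:
a species carries a few dozen lipases dominated by the neutral and acid
families, most neutral beta-9 loops sit at exactly 15 residues with a long
tail above, a few percent of triads are broken, and non-pollinator genomes
carry systematically more neutral and acid copies than pollinator genomes.

Two in-paper tables ship as packaged, checksummed TSV fixtures: the
12-species x 6-family count table and the 93 neutral-lipase loop/lid
sequence pairs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import NamedTuple

import dendropy
import numpy as np
import pandas as pd

from .classify import RegionSpec, ReferenceSpec, TriadSite
from .formats import (
    CodonUsageTable,
    CountTable,
    GeneModel,
    ProteinRecord,
    SENSE_CODONS,
    SYNONYMOUS_FAMILIES,
    read_count_table,
    write_count_table,
    write_dna_fasta,
    write_fasta,
    write_gff,
)

__all__ = [
    "SimConfig",
    "default_panel",
    "random_protein",
    "gen_protein_set",
    "gen_genome",
    "gen_codon_usage",
    "gen_cds_set",
    "gen_count_table",
    "gen_tree",
    "write_dataset",
    "fixture_table1",
    "fixture_table3",
    "Table3Entry",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_EXEMPLAR_SEED = 20220407  # fixed: the exemplar set is part of the package


def _plant(seq: list[str], pos1: int, residue: str) -> None:
    seq[pos1 - 1] = residue


def _build_exemplars() -> dict[str, str]:
    rng = np.random.default_rng(_EXEMPLAR_SEED)

    def draw(n: int) -> list[str]:
        return [_AA[i] for i in rng.integers(0, len(_AA), n)]

    neutral = draw(300)
    for pos, res in ((150, "S"), (176, "D"), (280, "H"),  # catalytic triad
                     (204, "H"), (224, "H"),  # beta-9 loop anchors
                     (238, "C"), (262, "C")):  # lid anchors
        _plant(neutral, pos, res)
    # no stray anchor letters immediately next to the anchors
    acid = draw(340)
    for pos, res in ((120, "S"), (330, "D"), (335, "H"), (184, "T"), (308, "N")):
        _plant(acid, pos, res)
    return {
        "neutral": "".join(neutral),
        "acid": "".join(acid),
        "lipase3": "".join(draw(250)),
        "GDSL": "".join(draw(240)),
        "HSL": "".join(draw(260)),
    }


EXEMPLARS = _build_exemplars()

NEUTRAL_TRIAD = (TriadSite("Ser", 150, "S"), TriadSite("Asp", 176, "D"), TriadSite("His", 280, "H"))
NEUTRAL_REGIONS = (
    RegionSpec("beta9", 204, "H", 224, "H"),
    RegionSpec("lid", 238, "C", 262, "C"),
)
ACID_TRIAD = (TriadSite("Ser", 120, "S"), TriadSite("Asp", 330, "D"), TriadSite("His", 335, "H"))
ACID_REGIONS = (RegionSpec("cap", 184, "T", 308, "N"),)


def default_panel() -> list[ReferenceSpec]:
    """The synthetic reference panel: one exemplar per lipase family."""
    return [
        ReferenceSpec("neutral", "SYN_neutral_ref", EXEMPLARS["neutral"],
                      triad=NEUTRAL_TRIAD, regions=NEUTRAL_REGIONS),
        ReferenceSpec("acid", "SYN_acid_ref", EXEMPLARS["acid"],
                      triad=ACID_TRIAD, regions=ACID_REGIONS),
        ReferenceSpec("lipase3", "SYN_lipase3_ref", EXEMPLARS["lipase3"]),
        ReferenceSpec("GDSL", "SYN_GDSL_ref", EXEMPLARS["GDSL"]),
        ReferenceSpec("HSL", "SYN_HSL_ref", EXEMPLARS["HSL"]),
    ]


@dataclass
class SimConfig:
    """All knobs of the generator; the seed fixes every output."""

    seed: int
    species: str = "Simw"
    # proteins
    family_counts: dict[str, int] = field(
        default_factory=lambda: {"neutral": 12, "acid": 8, "lipase3": 1, "GDSL": 1, "HSL": 1}
    )
    mutation_rate: float = 0.08
    broken_triad_fraction: float = 0.04
    loop_length_probs: dict[int, float] = field(
        default_factory=lambda: {13: 0.01, 15: 0.59, 20: 0.25, 23: 0.15}
    )
    lid_length_probs: dict[int, float] = field(
        default_factory=lambda: {15: 0.40, 17: 0.24, 21: 0.16, 24: 0.15, 30: 0.05}
    )
    # genome layout
    n_scaffolds: int = 5
    scaffold_length: int = 1_000_000
    planted_arrays: tuple[tuple[str, int], ...] = (
        ("neutral", 2), ("neutral", 2), ("acid", 3), ("acid", 2),
    )
    n_singletons: dict[str, int] = field(default_factory=lambda: {"neutral": 5, "acid": 3})
    exon_count_probs: dict[int, float] = field(
        default_factory=lambda: {1: 0.05, 4: 0.24, 5: 0.13, 6: 0.11, 7: 0.32, 8: 0.10, 16: 0.05}
    )
    # codon bias
    bias_strength: float = 0.7
    cds_class_counts: dict[str, int] = field(
        default_factory=lambda: {"high": 5, "intermediate": 5, "low": 2}
    )
    cds_length_aa: int = 150
    # count table / tree
    n_npfw: int = 5
    n_pfw: int = 7
    base_counts: dict[str, int] = field(
        default_factory=lambda: {"neutral": 17, "acid": 11, "lipase3": 1, "GDSL": 1, "HSL": 1}
    )
    npfw_shift: dict[str, int] = field(default_factory=lambda: {"neutral": 11, "acid": 9})
    count_noise: float = 1.0  # sd of the rounded gaussian jitter on counts
    branch_length_range: tuple[float, float] = (5.0, 50.0)


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(_AA[i] for i in rng.integers(0, len(_AA), length))


def _choice(rng: np.random.Generator, probs: dict[int, float]) -> int:
    keys = sorted(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    return int(rng.choice(keys, p=p / p.sum()))


def _protected_positions(ref: ReferenceSpec, flank: int = 3) -> set[int]:
    protected: set[int] = set()
    for t in ref.triad:
        protected.update(range(t.position - 1, t.position + 2))
    for r in ref.regions:
        for pos in (r.start_position, r.end_position):
            protected.update(range(pos - flank, pos + flank + 1))
    return {p for p in protected if p >= 1}


def _derive_sequence(
    rng: np.random.Generator,
    ref: ReferenceSpec,
    mutation_rate: float,
    region_lengths: dict[str, int] | None = None,
) -> tuple[list[str], dict[str, int]]:
    """One mutated copy of the exemplar, with region interiors resized.

    Walks the reference left to right so positions stay consistent while
    interiors change length; returns the sequence and the 0-based indices of
    the triad sites in the *derived* frame.
    """
    region_lengths = region_lengths or {}
    protected = _protected_positions(ref)
    interiors = {}  # start anchor position -> (end anchor position, new interior)
    for r in ref.regions:
        if r.kind in region_lengths:
            target = region_lengths[r.kind]
            span = r.end_position - r.start_position + 1
            if target < 2:
                raise ValueError(f"region {r.kind}: target length {target} below anchor pair")
            if target > span + 200:
                raise ValueError(f"region {r.kind}: target length {target} unreasonably large")
            interiors[r.start_position] = (r.end_position, random_protein(rng, target - 2))
    out: list[str] = []
    triad_idx: dict[str, int] = {}
    pos = 1
    while pos <= len(ref.sequence):
        site = next((t for t in ref.triad if t.position == pos), None)
        if site is not None:
            triad_idx[site.name] = len(out)
        ch = ref.sequence[pos - 1]
        if pos not in protected and rng.random() < mutation_rate:
            ch = _AA[int(rng.integers(0, len(_AA)))]
        out.append(ch)
        if pos in interiors:  # just emitted the start anchor
            end_pos, interior = interiors[pos]
            out.extend(interior)
            pos = end_pos  # resume at the end anchor
            continue
        pos += 1
    return out, triad_idx


def gen_protein_set(config: SimConfig) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Mutated-exemplar proteins with planted triads and region lengths.

    Returns the records and a truth table with one row per protein: family,
    planted triad state, planted loop/lid lengths and the implied TAG call.
    """
    rng = np.random.default_rng(config.seed)
    panel = {r.family: r for r in default_panel()}
    records: list[ProteinRecord] = []
    truth_rows: list[dict] = []
    for family in sorted(config.family_counts):
        n = config.family_counts[family]
        ref = panel[family]
        for k in range(1, n + 1):
            gene_id = f"{config.species}_{family}_{k}"
            loop_len = lid_len = None
            region_lengths = {}
            if family == "neutral":
                loop_len = _choice(rng, config.loop_length_probs)
                lid_len = _choice(rng, config.lid_length_probs)
                region_lengths = {"beta9": loop_len, "lid": lid_len}
            seq, triad_idx = _derive_sequence(rng, ref, config.mutation_rate, region_lengths)
            triad_complete = True
            triad_note = ""
            if ref.triad and rng.random() < config.broken_triad_fraction:
                site = ref.triad[int(rng.integers(0, len(ref.triad)))]
                idx = triad_idx[site.name]
                if rng.random() < 0.5:
                    seq[idx] = "E" if site.residue != "E" else "Q"
                    triad_note = f"substituted {site.name}"
                else:
                    del seq[idx]
                    triad_note = f"lacked {site.name}"
                triad_complete = False
            records.append(ProteinRecord(gene_id, "".join(seq), species=config.species))
            truth_rows.append(
                dict(
                    id=gene_id,
                    family=family,
                    triad_complete=triad_complete if ref.triad else "",
                    triad_note=triad_note,
                    loop_len=loop_len if loop_len is not None else "",
                    lid_len=lid_len if lid_len is not None else "",
                    tag_call=(loop_len > 15 and lid_len >= 18)
                    if family == "neutral"
                    else "",
                )
            )
    return records, pd.DataFrame(truth_rows)


def gen_genome(config: SimConfig) -> tuple[list[GeneModel], pd.DataFrame]:
    """Scaffold layouts with planted tandem arrays and exon counts.

    Arrays are isolated by at least two unrelated filler genes on either
    side, so clustering at the default ``max_intervening = 1`` recovers
    exactly the planted arrays.  Raises when the scaffold cannot hold its
    genes.
    """
    rng = np.random.default_rng(config.seed + 1)
    # assign each array and singleton to a scaffold round-robin after shuffle
    units: list[tuple[str, int]] = list(config.planted_arrays)
    for fam in sorted(config.n_singletons):
        units += [(fam, 1)] * config.n_singletons[fam]
    rng.shuffle(units)

    per_scaffold: list[list[tuple[str, int]]] = [[] for _ in range(config.n_scaffolds)]
    for i, unit in enumerate(units):
        per_scaffold[i % config.n_scaffolds].append(unit)

    genes: list[GeneModel] = []
    rows: dict[str, dict] = {}
    counter: dict[str, int] = {"filler": 0}
    for s_idx, scaffold_units in enumerate(per_scaffold):
        scaffold = f"scaffold_{s_idx + 1}"
        pos = 1
        # label sequence with >= 2 fillers around every planted unit, so
        # clustering with max_intervening = 1 cannot merge across units
        labels: list[str | None] = [None, None]
        unit_spans: list[tuple[str, int, int]] = []  # family, first index, size
        for fam, size in scaffold_units:
            unit_spans.append((fam, len(labels), size))
            labels.extend([fam] * size)
            labels.extend([None, None])
        ids_by_index: dict[int, str] = {}
        for li, fam in enumerate(labels):
            if fam is None:
                counter["filler"] += 1
                gid = f"{config.species}_other_{counter['filler']}"
                family = None
            else:
                counter[fam] = counter.get(fam, 0) + 1
                gid = f"{config.species}_{fam}_g{counter[fam]}"
                family = fam
            ids_by_index[li] = gid
            n_exons = _choice(rng, config.exon_count_probs)
            exons = []
            cursor = pos
            for _ in range(n_exons):
                elen = int(rng.integers(100, 301))
                exons.append((cursor, cursor + elen - 1))
                cursor += elen + int(rng.integers(50, 201))
            end = exons[-1][1]
            if end > config.scaffold_length:
                raise ValueError(
                    f"{scaffold}: genes exceed scaffold length {config.scaffold_length}"
                )
            genes.append(
                GeneModel(
                    gene_id=gid,
                    scaffold=scaffold,
                    start=pos,
                    end=end,
                    strand="+" if rng.random() < 0.5 else "-",
                    exons=tuple(exons),
                    family=family,
                )
            )
            rows[gid] = dict(
                id=gid, scaffold=scaffold, family=family or "", n_exons=n_exons, cluster=""
            )
            pos = end + int(rng.integers(200, 1001))
        for fam, first, size in unit_spans:
            if size >= 2:
                cluster_id = f"{scaffold}:{fam}:{first}"
                for k in range(size):
                    rows[ids_by_index[first + k]]["cluster"] = cluster_id
    return genes, pd.DataFrame(list(rows.values()))


def gen_codon_usage(config: SimConfig) -> CodonUsageTable:
    """A biased usage table: one preferred codon per synonymous family.

    The preferred codon gets frequency 10; one secondary codon gets
    ``10 * (1 - bias_strength)``; any remaining codons get 0 (floored to the
    minimum adaptiveness downstream).
    """
    rng = np.random.default_rng(config.seed + 2)
    freqs = {c: 0.0 for c in SENSE_CODONS}
    for aa in sorted(SYNONYMOUS_FAMILIES):
        codons = list(SYNONYMOUS_FAMILIES[aa])
        order = list(rng.permutation(len(codons)))
        freqs[codons[order[0]]] = 10.0
        if len(codons) > 1:
            freqs[codons[order[1]]] = 10.0 * (1.0 - config.bias_strength)
    return CodonUsageTable(freqs)


def gen_cds_set(
    config: SimConfig, usage: CodonUsageTable
) -> tuple[dict[str, str], pd.DataFrame]:
    """Coding sequences with planted expression classes under ``usage``.

    ``high`` genes use each family's preferred codon, ``intermediate`` the
    secondary codon, ``low`` a zero-frequency codon where one exists (the
    preferred codon otherwise, for 1- and 2-codon families).
    """
    rng = np.random.default_rng(config.seed + 3)
    ranked: dict[str, list[str]] = {}
    for aa, codons in SYNONYMOUS_FAMILIES.items():
        ranked[aa] = sorted(codons, key=lambda c: -usage[c])
    # amino acids with an unused (zero-frequency) codon in the table; a gene
    # written entirely in those codons lands at the adaptiveness floor
    floor_aas = "".join(
        sorted(aa for aa, cs in SYNONYMOUS_FAMILIES.items() if len(cs) >= 3 and aa not in "MW")
    )
    seqs: dict[str, str] = {}
    rows: list[dict] = []
    for cls in sorted(config.cds_class_counts):
        for k in range(1, config.cds_class_counts[cls] + 1):
            gid = f"{config.species}_cds_{cls}_{k}"
            if cls == "low":
                protein = "".join(
                    floor_aas[i]
                    for i in rng.integers(0, len(floor_aas), config.cds_length_aa)
                )
            else:
                protein = random_protein(rng, config.cds_length_aa)
            codons = ["ATG"]
            for aa in protein:
                if aa in ("M", "W"):
                    codons.append(ranked[aa][0])
                    continue
                options = ranked[aa]
                if cls == "high":
                    codons.append(options[0])
                elif cls == "intermediate":
                    codons.append(options[min(1, len(options) - 1)])
                else:
                    codons.append(options[-1])
            codons.append("TAA")
            seqs[gid] = "".join(codons)
            rows.append(dict(id=gid, expression_class=cls))
    return seqs, pd.DataFrame(rows)


def gen_count_table(config: SimConfig) -> CountTable:
    """Species x family counts with a positive NPFW shift on some families."""
    rng = np.random.default_rng(config.seed + 4)
    species = [f"NPFW_{i + 1}" for i in range(config.n_npfw)] + [
        f"PFW_{i + 1}" for i in range(config.n_pfw)
    ]
    groups = {sp: ("NPFW" if sp.startswith("NPFW") else "PFW") for sp in species}
    data = {}
    for fam in sorted(config.base_counts):
        base = config.base_counts[fam]
        shift = config.npfw_shift.get(fam, 0)
        col = []
        for sp in species:
            mean = base + (shift if groups[sp] == "NPFW" else 0)
            value = mean + int(round(rng.normal(0.0, config.count_noise)))
            col.append(max(value, 0))
        data[fam] = col
    counts = pd.DataFrame(data, index=pd.Index(species, name="species"))
    return CountTable(counts=counts, groups=groups)


def gen_tree(config: SimConfig, leaf_names: list[str] | None = None) -> dendropy.Tree:
    """A random rooted binary tree with uniform branch lengths."""
    rng = np.random.default_rng(config.seed + 5)
    if leaf_names is None:
        n = config.n_npfw + config.n_pfw
        leaf_names = [f"NPFW_{i + 1}" for i in range(config.n_npfw)] + [
            f"PFW_{i + 1}" for i in range(config.n_pfw)
        ]
        leaf_names = leaf_names[:n]
    lo, hi = config.branch_length_range

    def blen() -> float:
        return float(rng.uniform(lo, hi))

    subtrees = [f"{name}:{blen():.6f}" for name in leaf_names]
    while len(subtrees) > 1:
        i, jj = sorted(rng.choice(len(subtrees), size=2, replace=False))
        a, b = subtrees[i], subtrees[jj]
        merged_children = f"({a},{b})"
        rest = [s for k, s in enumerate(subtrees) if k not in (i, jj)]
        if rest:
            subtrees = rest + [f"{merged_children}:{blen():.6f}"]
        else:
            subtrees = [merged_children]
    newick = subtrees[0] + ";"
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def write_dataset(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate one full dataset and write every file the pipeline consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    records, protein_truth = gen_protein_set(config)
    paths["proteins"] = outdir / "proteins.fasta"
    write_fasta(records, paths["proteins"])
    paths["protein_truth"] = outdir / "protein_truth.tsv"
    protein_truth.to_csv(paths["protein_truth"], sep="\t", index=False)

    genes, genome_truth = gen_genome(config)
    paths["gff"] = outdir / "genes.gff3"
    write_gff(genes, paths["gff"])
    paths["genome_truth"] = outdir / "genome_truth.tsv"
    genome_truth.to_csv(paths["genome_truth"], sep="\t", index=False)

    usage = gen_codon_usage(config)
    paths["codon_usage"] = outdir / "codon_usage.tsv"
    from .formats import write_codon_usage

    write_codon_usage(usage, paths["codon_usage"])
    cds, cds_truth = gen_cds_set(config, usage)
    paths["cds"] = outdir / "cds.fasta"
    write_dna_fasta(cds, paths["cds"])
    paths["cds_truth"] = outdir / "cds_truth.tsv"
    cds_truth.to_csv(paths["cds_truth"], sep="\t", index=False)

    table = gen_count_table(config)
    paths["counts"] = outdir / "counts.tsv"
    write_count_table(table, paths["counts"])

    tree = gen_tree(config)
    paths["tree"] = outdir / "species.nwk"
    tree.write(
        path=str(paths["tree"]),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
    return paths


# ---------------------------------------------------------------------------
# in-paper fixtures


class Table3Entry(NamedTuple):
    species: str
    gene_id: str
    loop: str
    loop_length: int
    lid: str
    lid_length: int


_FIXTURE_SHA256 = {
    "lipase_counts.tsv": "74a8cf5ef06423168a419044f872f36a6dcee4c552fdce2d1b302f26b200d9cb",
    "neutral_loop_lid.tsv": "95763fc7bb9df6fe1565eb83e84cbf1936945d376e8661b69c8922ff14490d3f",
}


def _fixture_path(name: str) -> Path:
    path = resources.files("figlipase").joinpath("data", name)
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if digest != _FIXTURE_SHA256[name]:
        raise RuntimeError(f"packaged fixture {name} is corrupted (checksum mismatch)")
    return Path(str(path))


def fixture_table1() -> CountTable:
    """The published 12-species x 6-family lipase count table."""
    return read_count_table(_fixture_path("lipase_counts.tsv"))


def fixture_table3() -> list[Table3Entry]:
    """The 93 published neutral-lipase beta-9 loop / lid sequence pairs."""
    df = pd.read_csv(_fixture_path("neutral_loop_lid.tsv"), sep="\t")
    return [
        Table3Entry(
            r.species, r.gene_id, r.beta9_loop, int(r.loop_length), r.lid, int(r.lid_length)
        )
        for r in df.itertuples()
    ]
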