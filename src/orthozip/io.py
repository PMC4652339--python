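"""Reading and writing the package's plain-text interchange formats.

Proteomes travel as multi-record FASTA whose id line carries the
placement metadata as ``|``-separated key-value tags::

    >wheat_g12|species=wheat|chrom=3AS|pos=421337

Contig-derived records keep their ``contig|`` id prefix (tokens without
an ``=`` sign belong to the gene id).  Truth tables and score tables
are tab-separated; expression and Ct panels are CSV with one header
row of sample labels plus a ``group`` annotation row mapping each
sample to its condition/genotype.
"""

from __future__ import annotations

import io as _io
from typing import Iterable, Mapping, Sequence, TextIO, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .family import ProteinRecord
from .orthology import OrthologGroup, ScoreTable

PathOrHandle = Union[str, TextIO]


def _record_header(rec: ProteinRecord) -> str:
    chrom = rec.chromosome if rec.chromosome is not None else "unknown"
    arm = rec.arm if rec.arm in ("S", "L") else ""
    return f"{rec.id}|species={rec.species}|chrom={chrom}{arm}|pos={rec.position}"


def proteome_fasta_string(records: Sequence[ProteinRecord]) -> str:
    handle = _io.StringIO()
    write_proteome_fasta(records, handle)
    return handle.getvalue()


def write_proteome_fasta(records: Sequence[ProteinRecord], dest: PathOrHandle) -> None:
    seqs = [
        SeqRecord(Seq(rec.residues), id=_record_header(rec), description="")
        for rec in records
    ]
    if isinstance(dest, str):
        with open(dest, "w") as handle:
            SeqIO.write(seqs, handle, "fasta")
    else:
        SeqIO.write(seqs, dest, "fasta")


def _parse_header(header: str) -> tuple[str, dict[str, str]]:
    tokens = header.split("|")
    gid_parts = [t for t in tokens if "=" not in t]
    tags = dict(t.split("=", 1) for t in tokens if "=" in t)
    return "|".join(gid_parts), tags


def _parse_chrom(tag: str) -> tuple[str | None, str]:
    if tag in ("", "unknown"):
        return None, "unknown"
    if tag.startswith("u"):
        return tag, "unknown"
    if tag[-1] in ("S", "L"):
        return tag[:-1], tag[-1]
    return tag, "unknown"


def read_proteome_fasta(src: PathOrHandle) -> list[ProteinRecord]:
    records = []
    for seq_rec in SeqIO.parse(src, "fasta"):
        gid, tags = _parse_header(seq_rec.id)
        chrom, arm = _parse_chrom(tags.get("chrom", "unknown"))
        records.append(
            ProteinRecord(
                id=gid,
                species=tags.get("species", "unknown"),
                residues=str(seq_rec.seq),
                chromosome=chrom,
                arm=arm,
                position=int(tags.get("pos", 0)),
                is_contig=gid.startswith("contig|"),
            )
        )
    return records


def write_truth_groups_tsv(
    truth_groups: Mapping[tuple[str, str], Iterable[frozenset]], dest: PathOrHandle
) -> None:
    rows = []
    for (a, b), groups in sorted(truth_groups.items()):
        for i, members in enumerate(groups, start=1):
            for gid in sorted(members):
                rows.append((a, b, i, gid))
    frame = pd.DataFrame(rows, columns=["species_a", "species_b", "group", "gene_id"])
    frame.to_csv(dest, sep="\t", index=False)


def write_score_table_tsv(table: ScoreTable, dest: PathOrHandle) -> None:
    rows = [
        (p.query_id, p.subject_id, p.bit_score, p.overlap_fraction)
        for p in table.pairs.values()
    ]
    frame = pd.DataFrame(rows, columns=["query", "subject", "bits", "overlap"])
    frame.sort_values(["query", "subject"]).to_csv(dest, sep="\t", index=False)


def write_groups_tsv(groups: Sequence[OrthologGroup], dest: PathOrHandle) -> None:
    """InParanoid-table-shaped output: one row per group member."""
    rows = []
    for g in groups:
        for species, members in zip(g.species_pair, (g.members_a, g.members_b)):
            for gid, conf in members:
                role = "seed" if gid in (g.seed_a, g.seed_b) else "inparalog"
                rows.append((g.group_id, species, gid, role, conf))
    frame = pd.DataFrame(
        rows, columns=["group_id", "species", "gene_id", "role", "confidence"]
    )
    frame.to_csv(dest, sep="\t", index=False)


def write_panel_csv(
    panel: pd.DataFrame, sample_group: Mapping[str, str], dest: PathOrHandle
) -> None:
    """Genes x samples CSV with a ``group`` annotation row under the header."""
    annotated = pd.concat(
        [
            pd.DataFrame(
                [[sample_group[c] for c in panel.columns]],
                index=["group"],
                columns=panel.columns,
            ),
            panel,
        ]
    )
    annotated.to_csv(dest)


def read_panel_csv(src: PathOrHandle) -> tuple[pd.DataFrame, dict[str, str]]:
    raw = pd.read_csv(src, index_col=0)
    groups = raw.loc["group"].to_dict()
    panel = raw.drop(index="group").astype(float)
    return panel, groups
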