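"""FASTA / TSV input-output helpers."""

from __future__ import annotations

import csv

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import EngineeredPair, Substitution


def read_fasta(path) -> list[tuple[str, str]]:
    """(id, sequence) records from a FASTA file."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path, records) -> None:
    """Write (id, sequence) or (id, description, sequence) records."""
    out = []
    for rec in records:
        if len(rec) == 2:
            name, seq = rec
            desc = ""
        else:
            name, desc, seq = rec
        out.append(SeqRecord(Seq(seq), id=name, description=desc))
    SeqIO.write(out, str(path), "fasta")


def write_pair_fasta(path, pair: EngineeredPair) -> None:
    """Engineered chains as FASTA with design metadata in the headers."""
    write_fasta(
        path,
        [
            (
                f"{pair.design_name.replace(' ', '_')}_A",
                f"design={pair.design_name}|acceptor={pair.acceptor}"
                f"|donor={pair.donor_a}|subs={','.join(pair.compact('A')) or '-'}",
                pair.chain_a.sequence,
            ),
            (
                f"{pair.design_name.replace(' ', '_')}_B",
                f"design={pair.design_name}|acceptor={pair.acceptor}"
                f"|donor={pair.donor_b}|subs={','.join(pair.compact('B')) or '-'}",
                pair.chain_b.sequence,
            ),
        ],
    )


def write_substitutions_tsv(path, pair: EngineeredPair) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["chain", "wt", "imgt_position", "mut"])
        for side, subs in (("A", pair.subs_a), ("B", pair.subs_b)):
            for s in subs:
                w.writerow([side, s.wt, str(s.position), s.mut])


def read_substitutions_tsv(path) -> dict[str, list[Substitution]]:
    out: dict[str, list[Substitution]] = {"A": [], "B": []}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.setdefault(row["chain"], []).append(
                Substitution.parse(f"{row['wt']}{row['imgt_position']}{row['mut']}")
            )
    return out


def write_numbering_tsv(path, domain) -> None:
    """residue_index / imgt_label sidecar for a numbered domain."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["residue_index", "imgt_label", "residue"])
        for i, p in domain.numbering:
            w.writerow([i, str(p), domain.sequence[i]])


def write_contacts_tsv(path, cmap) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(
            ["kind", "chain_i", "res_i", "pos_i", "chain_j", "res_j", "pos_j", "min_distance"]
        )
        for c in cmap.contacts:
            w.writerow(
                [
                    c.kind,
                    c.res_i.chain,
                    c.res_i.residue_name,
                    c.res_i.imgt if c.res_i.imgt is not None else c.res_i.number,
                    c.res_j.chain,
                    c.res_j.residue_name,
                    c.res_j.imgt if c.res_j.imgt is not None else c.res_j.number,
                    f"{c.min_distance:.3f}",
                ]
            )
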