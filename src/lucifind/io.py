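"""FASTA readers/writers shared by the pipeline stages."""

from __future__ import annotations

import re

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .orf import Orf, Transcript

_TRINITY_ISOFORM = re.compile(r"_i\d+$")
_CLUSTER_TAG = re.compile(r"cluster=(\S+)")


def _infer_cluster(rec) -> str | None:
    m = _CLUSTER_TAG.search(rec.description)
    if m:
        return m.group(1)
    if _TRINITY_ISOFORM.search(rec.id):
        # Trinity isoform ids share the cluster/gene prefix before "_i<N>"
        return _TRINITY_ISOFORM.sub("", rec.id)
    return None


def read_transcript_fasta(path) -> list[Transcript]:
    """Load transcripts; cluster ids come from a ``cluster=`` header tag or
    a Trinity-style ``_i<N>`` isoform suffix, else are left unset."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(
            Transcript(
                id=rec.id, seq=str(rec.seq).upper(),
                cluster_id=_infer_cluster(rec),
            )
        )
    return out


def read_protein_fasta(path) -> list[tuple[str, str]]:
    """Load a protein database as (accession, sequence) pairs."""
    return [
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: list[tuple[str, str]], path, description: str = "") -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description=description)
        for name, seq in records
    ]
    SeqIO.write(recs, str(path), "fasta")


def write_orf_fasta(orfs: list[Orf], path) -> None:
    """Peptide FASTA with ``<id>|<start>-<end>|<strand><frame>|<class>`` headers."""
    write_fasta([(o.ref, o.peptide) for o in orfs], path)
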