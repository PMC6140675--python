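"""Open reading frame prediction from assembled transcripts.

ORFs are called purely structurally on both strands and all three frames:
within a frame, a *complete* ORF runs from the first ATG after the previous
stop codon to the nearest in-frame stop. Frame ends are covered by partial
classes: a leading stop-terminated stretch with no ATG is ``five_prime_partial``
(stop but no start), a trailing ATG-to-frame-end stretch with no stop is
``three_prime_partial``, and a stretch with neither is ``internal``.

The default minimum peptide length is 5 amino acids, low enough to keep
candidate short luciferin-precursor peptides. No coding-likelihood scoring
is applied; the caller decides what to do with partials (the downstream
"mature" filter keeps only complete ORFs).

Coordinates are 0-based half-open **on the reported strand**: for a minus
strand ORF, ``start``/``end`` index into the reverse complement of the
transcript. The stop codon, when present, is inside ``[start, end)`` but is
never part of the peptide.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    _CODON_TO_AA[_stop] = "*"

_VALID_NT = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

Completeness = str  # {"complete", "five_prime_partial", "three_prime_partial", "internal"}


@dataclass(frozen=True)
class Transcript:
    """An assembled transcript; ``cluster_id`` is the read-cluster label."""

    id: str
    seq: str
    cluster_id: str | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"transcript {self.id!r}: empty sequence")
        bad = set(self.seq.upper()) - _VALID_NT
        if bad:
            raise ValueError(
                f"transcript {self.id!r}: illegal characters {sorted(bad)}"
            )


@dataclass(frozen=True)
class Orf:
    transcript_id: str
    start: int  # 0-based inclusive, on the reported strand
    end: int  # 0-based exclusive, on the reported strand
    strand: str  # "+" or "-"
    frame: int  # 0, 1 or 2
    peptide: str
    completeness: Completeness

    @property
    def ref(self) -> str:
        """Stable identifier used in reports and FASTA headers."""
        return (
            f"{self.transcript_id}|{self.start}-{self.end}"
            f"|{self.strand}{self.frame}|{self.completeness}"
        )


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def translate(seq: str, strand: str = "+", frame: int = 0) -> str:
    """Translate one frame with the standard code; N-containing codons -> X.

    The trailing partial codon (if any) is dropped. Raises ``ValueError`` on
    characters outside {A, C, G, T, N} or a bad strand/frame.
    """
    seq = seq.upper()
    bad = set(seq) - _VALID_NT
    if bad:
        raise ValueError(f"illegal nucleotide characters: {sorted(bad)}")
    if strand not in "+-":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame!r}")
    if strand == "-":
        seq = revcomp(seq)
    out = []
    for k in range(frame, len(seq) - 2, 3):
        codon = seq[k : k + 3]
        out.append("X" if "N" in codon else _CODON_TO_AA[codon])
    return "".join(out)


def _frame_orfs(
    t_id: str, oriented: str, strand: str, frame: int, min_len: int
) -> list[Orf]:
    """Call ORFs within a single oriented frame."""
    aa = translate(oriented, "+", frame)  # oriented is already stranded
    n_codons = len(aa)
    if n_codons == 0:
        return []
    orfs: list[Orf] = []

    def emit(c0: int, c1: int, has_stop: bool, completeness: str) -> None:
        # codon window [c0, c1); has_stop means aa[c1-1] == "*"
        pep = aa[c0 : c1 - 1] if has_stop else aa[c0:c1]
        if len(pep) < min_len:
            return
        start = frame + 3 * c0
        end = frame + 3 * c1
        orfs.append(Orf(t_id, start, end, strand, frame, pep, completeness))

    stops = [k for k, x in enumerate(aa) if x == "*"]
    seg_start = 0
    for st in stops:
        seg = aa[seg_start:st]
        m = seg.find("M")
        if m >= 0:
            emit(seg_start + m, st + 1, True, "complete")
        elif seg_start == 0:
            # leading frame edge: stop present, start missing
            emit(0, st + 1, True, "five_prime_partial")
        seg_start = st + 1
    # open tail (or the whole frame when no stop occurs)
    if seg_start < n_codons:
        tail = aa[seg_start:]
        m = tail.find("M")
        if m >= 0:
            emit(seg_start + m, n_codons, False, "three_prime_partial")
        else:
            emit(seg_start, n_codons, False, "internal")
    return orfs


def find_orfs(t: Transcript, min_len: int = 5) -> list[Orf]:
    """Predict ORFs of >= ``min_len`` amino acids on both strands x 3 frames.

    Results are ordered plus strand before minus, then by start coordinate
    (on the reported strand), end, and frame.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    seq = t.seq.upper()
    out: list[Orf] = []
    for strand in "+-":
        oriented = seq if strand == "+" else revcomp(seq)
        stranded: list[Orf] = []
        for frame in range(3):
            stranded.extend(_frame_orfs(t.id, oriented, strand, frame, min_len))
        stranded.sort(key=lambda o: (o.start, o.end, o.frame))
        out.extend(stranded)
    return out


def longest_per_cluster(
    orfs: list[Orf], transcripts: list[Transcript]
) -> list[Orf]:
    """Keep the single longest ORF per read cluster.

    Ties go to the lexicographically smallest transcript id, then the
    smallest start. Every ORF's transcript must carry a ``cluster_id``.
    """
    cluster_of = {t.id: t.cluster_id for t in transcripts}
    best: dict[str, Orf] = {}
    for o in orfs:
        cid = cluster_of.get(o.transcript_id)
        if cid is None:
            raise ValueError(
                f"transcript {o.transcript_id!r} has no cluster_id"
            )
        cur = best.get(cid)
        if cur is None:
            best[cid] = o
            continue
        key = (-len(o.peptide), o.transcript_id, o.start)
        cur_key = (-len(cur.peptide), cur.transcript_id, cur.start)
        if key < cur_key:
            best[cid] = o
    return [best[cid] for cid in sorted(best)]
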