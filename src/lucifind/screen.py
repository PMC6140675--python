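"""Reciprocal bitscore homology screen against local and reference databases.

Each predicted peptide is searched against small curated "local" databases
(crustacean luciferases, photoproteins, luciferin-synthesis candidates) and
the best local hit below the E-value cutoff is re-checked against a large
curated reference database. The candidate is retained when the local
bitscore is **equal or higher** than the best reference bitscore — bitscores
rather than E-values, because bits are comparable across databases of very
different sizes. No E-value cutoff is applied on the reference side: even a
weak reference protein is allowed to outscore a weak local hit.

Rejected candidates are kept with their winning reference match, since a
negative screen ("these better matched calmodulin") is itself a result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .align import AlignmentHit, ScoringScheme, default_scheme, evalue, smith_waterman

Database = list[tuple[str, str]]  # (accession, peptide)


@dataclass
class ScreenResult:
    orf_ref: str
    local_db: str
    local_hit: AlignmentHit
    reference_hit: AlignmentHit | None
    retained: bool


def query_db(
    orf_peptide: str,
    db: Database,
    e_cutoff: float = 1e-5,
    scheme: ScoringScheme | None = None,
    query_id: str = "query",
) -> AlignmentHit | None:
    """Best-bitscore hit with E <= ``e_cutoff``, or None.

    Ties on bitscore break by lower E-value, then lexicographic accession.
    E-values use the total residue count of the searched database.
    """
    if not db:
        raise ValueError("database must be non-empty")
    scheme = scheme or default_scheme()
    db_residues = sum(len(seq) for _, seq in db)
    best: AlignmentHit | None = None
    for acc, seq in sorted(db, key=lambda x: x[0]):
        hit = smith_waterman(
            orf_peptide, seq, scheme, query_id=query_id, subject_id=acc
        )
        hit.evalue = evalue(hit.bitscore, len(orf_peptide), db_residues)
        if hit.evalue > e_cutoff:
            continue
        if (
            best is None
            or hit.bitscore > best.bitscore
            or (hit.bitscore == best.bitscore and hit.evalue < best.evalue)
        ):
            best = hit
    return best


def reciprocal_screen(
    orfs,
    local_dbs: dict[str, Database],
    reference_db: Database,
    e_cutoff: float = 1e-5,
    scheme: ScoringScheme | None = None,
) -> list[ScreenResult]:
    """Run every ORF against every local database with reference validation.

    ``orfs`` is an iterable of objects with ``ref`` and ``peptide``
    attributes (or (ref, peptide) pairs). Results are sorted by local
    database name, then descending local bitscore.
    """
    if not reference_db:
        raise ValueError("reference database must be non-empty")
    scheme = scheme or default_scheme()
    results: list[ScreenResult] = []
    for o in orfs:
        ref_id, peptide = (
            (o.ref, o.peptide) if hasattr(o, "peptide") else (o[0], o[1])
        )
        ref_hit: AlignmentHit | None = None
        ref_done = False
        for db_name, db in local_dbs.items():
            local_hit = query_db(
                peptide, db, e_cutoff, scheme, query_id=ref_id
            )
            if local_hit is None:
                continue
            if not ref_done:
                # no E-value cutoff on the reference side
                ref_hit = query_db(
                    peptide, reference_db, math.inf, scheme, query_id=ref_id
                )
                ref_done = True
            retained = (
                ref_hit is None or local_hit.bitscore >= ref_hit.bitscore
            )
            results.append(
                ScreenResult(
                    orf_ref=ref_id,
                    local_db=db_name,
                    local_hit=local_hit,
                    reference_hit=ref_hit,
                    retained=retained,
                )
            )
    results.sort(key=lambda r: (r.local_db, -r.local_hit.bitscore, r.orf_ref))
    return results


_COLUMNS = [
    "Taxon",
    "GenBank accession",
    "Percent identity",
    "Matching length",
    "E-value",
    "Bitscore",
]


def report_table(
    results: list[ScreenResult],
    taxon_map: dict[str, str] | None = None,
    retained_only: bool = True,
) -> pd.DataFrame:
    """Tabulate screen results in the published schema.

    One row per (retained) result: Taxon, GenBank accession, Percent
    identity, Matching length, E-value (2 significant figures, scientific
    notation), Bitscore. Accessions missing from ``taxon_map`` fall back to
    the accession itself with a warning.
    """
    import warnings

    taxon_map = taxon_map or {}
    rows = []
    for r in results:
        if retained_only and not r.retained:
            continue
        acc = r.local_hit.subject_id
        taxon = taxon_map.get(acc)
        if taxon is None:
            warnings.warn(f"no taxon mapping for accession {acc!r}")
            taxon = acc
        rows.append(
            {
                "Taxon": taxon,
                "GenBank accession": acc,
                "Percent identity": round(r.local_hit.pct_identity, 1),
                "Matching length": r.local_hit.match_length,
                "E-value": f"{r.local_hit.evalue:.1E}",
                "Bitscore": round(r.local_hit.bitscore, 1),
            }
        )
    return pd.DataFrame(rows, columns=_COLUMNS)


def rejected_table(
    results: list[ScreenResult], taxon_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Rejected candidates with the reference proteins that outscored them."""
    taxon_map = taxon_map or {}
    rows = []
    for r in results:
        if r.retained:
            continue
        rows.append(
            {
                "orf": r.orf_ref,
                "local_db": r.local_db,
                "local_accession": r.local_hit.subject_id,
                "local_bitscore": round(r.local_hit.bitscore, 1),
                "reference_winner": r.reference_hit.subject_id,
                "reference_bitscore": round(r.reference_hit.bitscore, 1),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "orf",
            "local_db",
            "local_accession",
            "local_bitscore",
            "reference_winner",
            "reference_bitscore",
        ],
    )
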