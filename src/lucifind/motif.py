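"""C-terminal FYY screening of mature ORFs.

Coelenterazine is plausibly built by cyclising a Phe-Tyr-Tyr tripeptide, so
proteins ending in exactly "FYY" are candidate luciferin precursors. The
screen is restricted to *mature* ORFs — those with both a start and a stop
codon — since a missing stop leaves the true C-terminus unknown. Matching
is exact and case-insensitive; no substitutions are tolerated.
"""

from __future__ import annotations

from dataclasses import dataclass

from .orf import Orf


@dataclass(frozen=True)
class FyyCandidate:
    orf_ref: str
    peptide: str

    @property
    def cterm3(self) -> str:
        return self.peptide[-3:]


def is_mature(o: Orf) -> bool:
    """True iff the ORF has both a start and a stop codon."""
    return o.completeness == "complete"


def find_cterm_fyy(orfs: list[Orf]) -> list[FyyCandidate]:
    """Mature ORFs whose final three residues (before the stop) are F, Y, Y."""
    out = []
    for o in orfs:
        if is_mature(o) and o.peptide.upper().endswith("FYY"):
            out.append(FyyCandidate(orf_ref=o.ref, peptide=o.peptide))
    return out
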