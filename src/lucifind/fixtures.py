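"""Synthetic transcriptomes, protein databases, peak lists and COI alignments.

Every generator plants known signal — homologous ORFs at a controlled
percent identity, FYY-terminated mature transcripts, isotopologue ions at a
known retention time, species clades at a controlled divergence — inside
realistic random background, and records the ground truth in a
:class:`TruthTable` so the downstream screens can be tested end to end
without any sequencing or LC-MS download.

Identity control substitutes residues drawn uniformly from the 19
alternatives at positions chosen without replacement, so the realised
identity is the closest achievable to the target. Decoy transcripts are
i.i.d. uniform nucleotides: at the database sizes used here the chance of a
spurious high-bitscore hit is vanishing. Chromatographic peaks are Gaussian
in retention time (0.2 min s.d. by default). COI divergence is simulated
with uniform (Jukes-Cantor-like) substitutions on a star-within-species /
split-between-species genealogy; mutation counts per branch are exact
(positions sampled without replacement) with the branch change
probabilities back-computed through the substitution process so that the
realised p-distances concentrate tightly on the requested within/between
divergences.

All generators are deterministic: the same seed and parameters give
byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from Bio.Data import CodonTable

from .isoms import PeakList
from .orf import Transcript

AA20 = "ACDEFGHIKLMNPQRSTVWY"
NT = "ACGT"

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODONS_FOR: dict[str, list[str]] = {}
for _codon, _aa in sorted(_TABLE.forward_table.items()):
    _CODONS_FOR.setdefault(_aa, []).append(_codon)
_STOP_CODONS = sorted(_TABLE.stop_codons)


@dataclass
class TruthTable:
    """Ground truth for one generated artefact bundle."""

    planted_homologs: list[tuple[str, str, float]] = field(default_factory=list)
    planted_fyy_ids: list[str] = field(default_factory=list)
    planted_peaks: list[tuple[float, float, float]] = field(default_factory=list)
    clade_assignments: dict[str, str] = field(default_factory=dict)

    def write_tsv(self, path) -> None:
        import pandas as pd

        rows = []
        for tid, acc, ident in self.planted_homologs:
            rows.append(("homolog", tid, acc, f"{ident:.4f}"))
        for tid in self.planted_fyy_ids:
            rows.append(("fyy", tid, "", ""))
        for mz, rt, inten in self.planted_peaks:
            rows.append(("peak", f"{mz:.6f}", f"{rt:.3f}", f"{inten:.1f}"))
        for taxon, species in sorted(self.clade_assignments.items()):
            rows.append(("clade", taxon, species, ""))
        pd.DataFrame(rows, columns=["kind", "a", "b", "c"]).to_csv(
            path, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# proteins and transcriptomes


def mutate_protein(seq: str, target_identity: float, seed: int) -> str:
    """Return ``seq`` with substitutions bringing identity to the target.

    The number of preserved positions is ``round(target_identity * len)``;
    substituted residues are drawn uniformly from the 19 alternatives, so no
    stop symbols can appear.
    """
    rng = np.random.default_rng(seed)
    return _mutate(seq, target_identity, rng)


def _mutate(
    seq: str, target_identity: float, rng: np.random.Generator,
    protect_first: bool = False,
) -> str:
    if not seq:
        raise ValueError("sequence must be non-empty")
    if not 0 < target_identity <= 1:
        raise ValueError("target identity must lie in (0, 1]")
    n = len(seq)
    n_sub = n - int(round(target_identity * n))
    candidates = np.arange(1 if protect_first else 0, n)
    n_sub = min(n_sub, len(candidates))
    positions = rng.choice(candidates, size=n_sub, replace=False)
    out = list(seq)
    for p in sorted(positions):
        alternatives = [a for a in AA20 if a != out[p]]
        out[p] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def random_protein(length: int, rng: np.random.Generator) -> str:
    body = "".join(AA20[i] for i in rng.integers(len(AA20), size=length - 1))
    return "M" + body


def gen_protein_db(
    n: int,
    seed: int,
    length_range: tuple[int, int] = (80, 160),
    prefix: str = "REF",
) -> list[tuple[str, str]]:
    """Random unrelated proteins, each starting with M."""
    rng = np.random.default_rng(seed)
    db = []
    for k in range(n):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        db.append((f"{prefix}{k + 1:04d}", random_protein(length, rng)))
    return db


def _back_translate(peptide: str, rng: np.random.Generator) -> str:
    codons = []
    for aa in peptide:
        options = _CODONS_FOR[aa]
        codons.append(options[rng.integers(len(options))])
    return "".join(codons)


def _random_nt(length: int, rng: np.random.Generator) -> str:
    return "".join(NT[i] for i in rng.integers(4, size=length))


@dataclass(frozen=True)
class PlantSpec:
    """One homolog to embed in the synthetic transcriptome."""

    source_id: str  # database accession of the source protein
    source_seq: str
    identity: float  # target identity fraction in (0, 1]
    mature: bool = True  # embed with both start and stop codon
    cluster_id: str | None = None


def gen_transcriptome(
    n_decoys: int,
    plants: list[PlantSpec],
    seed: int,
    decoy_length: tuple[int, int] = (200, 400),
    utr_length: tuple[int, int] = (20, 60),
) -> tuple[list[Transcript], TruthTable]:
    """Synthetic transcripts with planted homologous ORFs among decoys.

    A mature plant is embedded as ``5'UTR + TAA + ATG <codons> <stop> +
    3'UTR`` with the in-frame TAA guarding against upstream start codons, so
    the ORF caller recovers exactly the planted peptide as a complete ORF.
    A non-mature plant omits the stop codon and 3' UTR, yielding a
    three-prime-partial ORF. Decoys are uniform random nucleotides.
    """
    for p in plants:
        if not 0 < p.identity <= 1:
            raise ValueError(
                f"plant {p.source_id!r}: identity must lie in (0, 1]"
            )
    rng = np.random.default_rng(seed)
    transcripts: list[Transcript] = []
    truth = TruthTable()
    for k, p in enumerate(plants):
        protect = p.source_seq.startswith("M")
        mutated = _mutate(p.source_seq, p.identity, rng, protect_first=protect)
        if not mutated.startswith("M"):
            mutated = "M" + mutated[1:]
        utr5 = _random_nt(int(rng.integers(*utr_length)), rng)
        cds = _back_translate(mutated, rng)
        tid = f"plant_{k + 1:04d}"
        if p.mature:
            stop = _STOP_CODONS[rng.integers(len(_STOP_CODONS))]
            utr3 = _random_nt(int(rng.integers(*utr_length)), rng)
            seq = utr5 + "TAA" + cds + stop + utr3
        else:
            seq = utr5 + "TAA" + cds
        transcripts.append(
            Transcript(id=tid, seq=seq, cluster_id=p.cluster_id or tid)
        )
        truth.planted_homologs.append((tid, p.source_id, p.identity))
        if p.mature and mutated.endswith("FYY"):
            truth.planted_fyy_ids.append(tid)
    for k in range(n_decoys):
        length = int(rng.integers(decoy_length[0], decoy_length[1] + 1))
        tid = f"decoy_{k + 1:04d}"
        transcripts.append(
            Transcript(id=tid, seq=_random_nt(length, rng), cluster_id=tid)
        )
    return transcripts, truth


# ---------------------------------------------------------------------------
# LC-MS peak lists


def gen_peaklist(
    planted: list[tuple[float, float, float]],
    ppm_jitter: float = 2.0,
    noise_peaks: int = 0,
    seed: int = 0,
    peak_sd_min: float = 0.2,
    scan_interval_min: float = 0.05,
    min_intensity: float = 1.0,
) -> tuple[PeakList, TruthTable]:
    """Centroided scans with Gaussian chromatographic profiles.

    Each planted (m/z, rt_min, intensity) ion appears once per scan within
    +-4 s.d. of its apex; observed m/z is displaced by at most
    ``ppm_jitter``. Noise peaks are scattered uniformly over the run and the
    100-1000 m/z range, excluding a guard band of max(3 x jitter, 12) ppm
    around every planted m/z so that noise can never bleed into a 10 ppm
    extraction window.
    """
    if ppm_jitter < 0:
        raise ValueError("ppm_jitter must be non-negative")
    for mz, rt, inten in planted:
        if inten <= 0:
            raise ValueError("planted intensities must be positive")
        if rt < 0:
            raise ValueError("retention times must be non-negative")
    rng = np.random.default_rng(seed)
    truth = TruthTable(planted_peaks=list(planted))
    if not planted and noise_peaks == 0:
        return PeakList(scans=[]), truth
    rt_max = max((rt for _, rt, _ in planted), default=18.0) + 2.0
    n_scans = int(round(rt_max / scan_interval_min)) + 1
    rts = [round(i * scan_interval_min, 6) for i in range(n_scans)]
    scans: list[tuple[float, list[tuple[float, float]]]] = [
        (rt, []) for rt in rts
    ]
    for mz, rt0, inten in planted:
        for i, rt in enumerate(rts):
            dt = rt - rt0
            if abs(dt) > 4 * peak_sd_min:
                continue
            height = inten * math.exp(-0.5 * (dt / peak_sd_min) ** 2)
            if height < min_intensity:
                continue
            obs = mz * (1.0 + rng.uniform(-1, 1) * ppm_jitter * 1e-6)
            scans[i][1].append((obs, height))
    guard = max(3.0 * ppm_jitter, 12.0)
    for _ in range(noise_peaks):
        while True:
            mz = rng.uniform(100.0, 1000.0)
            if all(
                abs(mz - pmz) / pmz * 1e6 > guard for pmz, _, _ in planted
            ):
                break
        i = int(rng.integers(n_scans))
        scans[i][1].append((mz, float(rng.uniform(1e3, 1e4))))
    scans = [(rt, sorted(peaks)) for rt, peaks in scans]
    return PeakList(scans=scans), truth


# ---------------------------------------------------------------------------
# COI alignments


def _branch_change_prob(p_target: float) -> float:
    """Per-branch site-change probability q such that two such branches
    compose to an expected p-distance of ``p_target``.

    Under uniform substitution the per-site identity coefficient of a
    branch is s = 1 - (4/3) q and coefficients multiply along a path, with
    expected p-distance (3/4)(1 - s_path).
    """
    s_path = 1.0 - (4.0 / 3.0) * p_target
    if s_path <= 0:
        raise ValueError("divergence too large for uniform substitutions")
    return 0.75 * (1.0 - math.sqrt(s_path))


def _mutate_sites(seq: str, k: int, rng: np.random.Generator) -> str:
    positions = rng.choice(len(seq), size=k, replace=False)
    out = list(seq)
    for p in sorted(positions):
        alternatives = [b for b in NT if b != out[p]]
        out[p] = alternatives[rng.integers(3)]
    return "".join(out)


def gen_coi_alignment(
    species_sizes: list[int],
    within_div: float,
    between_div: float,
    length: int = 600,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], TruthTable]:
    """Aligned COI-like sequences with controlled within/between divergence.

    Each species' consensus diverges from a common ancestor and each
    individual diverges from its species consensus, with branch change
    probabilities solved so that the expected pairwise p-distance is
    ``within_div`` within species and ``between_div`` between species.
    Returns ([(taxon, sequence)], truth) with taxa named ``sp<i>_<j>``.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0 <= within_div < between_div <= 0.75:
        raise ValueError("need 0 <= within_div < between_div <= 0.75")
    rng = np.random.default_rng(seed)
    ancestor = _random_nt(length, rng)
    q_within = _branch_change_prob(within_div)
    # between-species branches act on top of the two within branches
    s_between = 1.0 - (4.0 / 3.0) * between_div
    s_within_pair = (1.0 - (4.0 / 3.0) * q_within) ** 2
    s_b = s_between / s_within_pair
    if s_b <= 0:
        raise ValueError("between_div too large for this within_div")
    q_between = 0.75 * (1.0 - math.sqrt(s_b))
    k_within = int(round(q_within * length))
    k_between = int(round(q_between * length))
    records: list[tuple[str, str]] = []
    truth = TruthTable()
    for si, size in enumerate(species_sizes):
        species = f"sp{si + 1}"
        consensus = _mutate_sites(ancestor, k_between, rng)
        for j in range(size):
            taxon = f"{species}_{j + 1}"
            seq = _mutate_sites(consensus, k_within, rng)
            records.append((taxon, seq))
            truth.clade_assignments[taxon] = species
    return records, truth
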