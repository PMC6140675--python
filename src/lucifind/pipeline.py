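"""End-to-end orchestration: ORF calling, homology and motif screens,
isotope-label detection, and COI delimitation, driven by one config.

Stages run in dependency order and each stage is skipped (with a logged
notice) when its inputs are not configured. Outputs are written once per
run directory and listed in a manifest with SHA-256 checksums; identical
config and seed give identical manifests.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import coi as coi_mod
from . import io as io_mod
from .isoms import (
    COMPOUNDS,
    IsotopologueIon,
    detect_labeled_ion,
    detection_table,
    read_peaklist,
)
from .motif import find_cterm_fyy
from .orf import find_orfs
from .screen import reciprocal_screen, rejected_table, report_table

log = logging.getLogger("lucifind")

LOCAL_DB_NAMES = ("luciferase", "photoprotein", "luciferin_ipns")


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    transcripts: str | None = None
    luciferase_db: str | None = None
    photoprotein_db: str | None = None
    luciferin_ipns_db: str | None = None
    reference_db: str | None = None
    taxon_map: str | None = None
    peaklist: str | None = None
    coi_alignment: str | None = None
    # cutoffs; defaults are the study's stated or conventional values
    evalue: float = 1e-5
    min_aa: int = 5
    ppm: float = 10.0
    coi_cutoff: float = 0.03
    standard_rt: float = 14.4
    rt_tol: float = 0.2
    compounds: str = "coelenteramine:0,8,9;coelenterazine:0"

    def __post_init__(self) -> None:
        if min(self.evalue, self.min_aa, self.ppm, self.coi_cutoff) <= 0:
            raise ValueError("all cutoffs must be positive")


_FLOAT_KEYS = {"evalue", "ppm", "coi_cutoff", "standard_rt", "rt_tol"}
_INT_KEYS = {"seed", "min_aa"}


def parse_config(path) -> RunConfig:
    """Parse a ``key = value`` config file (# starts a comment)."""
    kwargs: dict = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"bad config line: {line!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        if key in _FLOAT_KEYS:
            kwargs[key] = float(val)
        elif key in _INT_KEYS:
            kwargs[key] = int(val)
        else:
            kwargs[key] = val
    if "outdir" not in kwargs:
        raise ValueError("config must set outdir")
    return RunConfig(**kwargs)


def _require(path: str, what: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"{what} not found: {p}")
    return p


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _parse_compounds(spec: str) -> list[tuple[str, list[int]]]:
    out = []
    for part in spec.split(";"):
        part = part.strip()
        if not part:
            continue
        name, labels = part.split(":")
        out.append((name.strip(), [int(x) for x in labels.split(",")]))
    return out


def run_all(cfg: RunConfig) -> dict:
    """Execute all configured stages; returns the manifest mapping."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    report: dict = {"stages": {}, "outputs": {}}

    orfs = None
    if cfg.transcripts:
        path = _require(cfg.transcripts, "transcript FASTA")
        transcripts = io_mod.read_transcript_fasta(path)
        orfs = []
        for t in transcripts:
            orfs.extend(find_orfs(t, min_len=cfg.min_aa))
        io_mod.write_orf_fasta(orfs, outdir / "orfs.fasta")
        pd.DataFrame(
            [
                (o.transcript_id, o.start, o.end, o.strand, o.frame,
                 o.completeness, len(o.peptide))
                for o in orfs
            ],
            columns=["transcript_id", "start", "end", "strand", "frame",
                     "completeness", "peptide_aa"],
        ).to_csv(outdir / "orfs.tsv", sep="\t", index=False)
        outputs += [outdir / "orfs.fasta", outdir / "orfs.tsv"]
        report["stages"]["orf"] = {
            "transcripts": len(transcripts), "orfs": len(orfs)
        }
        log.info("orf: %d transcripts -> %d ORFs", len(transcripts), len(orfs))
    else:
        log.info("orf: no transcripts configured; skipped")

    local_paths = {
        "luciferase": cfg.luciferase_db,
        "photoprotein": cfg.photoprotein_db,
        "luciferin_ipns": cfg.luciferin_ipns_db,
    }
    configured_locals = {k: v for k, v in local_paths.items() if v}
    if orfs is not None and configured_locals and cfg.reference_db:
        local_dbs = {
            name: io_mod.read_protein_fasta(_require(p, f"{name} database"))
            for name, p in configured_locals.items()
        }
        reference = io_mod.read_protein_fasta(
            _require(cfg.reference_db, "reference database")
        )
        taxon_map = {}
        if cfg.taxon_map:
            tm = pd.read_csv(_require(cfg.taxon_map, "taxon map"), sep="\t")
            taxon_map = dict(zip(tm.iloc[:, 0], tm.iloc[:, 1]))
        results = reciprocal_screen(
            orfs, local_dbs, reference, e_cutoff=cfg.evalue
        )
        report_table(results, taxon_map).to_csv(
            outdir / "screen_retained.tsv", sep="\t", index=False
        )
        rejected_table(results, taxon_map).to_csv(
            outdir / "screen_rejected.tsv", sep="\t", index=False
        )
        outputs += [outdir / "screen_retained.tsv", outdir / "screen_rejected.tsv"]
        n_ret = sum(r.retained for r in results)
        report["stages"]["screen"] = {
            "candidates": len(results), "retained": n_ret
        }
        log.info("screen: %d candidates, %d retained", len(results), n_ret)
    else:
        log.info("screen: inputs incomplete; skipped")

    if orfs is not None:
        candidates = find_cterm_fyy(orfs)
        io_mod.write_fasta(
            [(c.orf_ref, c.peptide) for c in candidates],
            outdir / "fyy_candidates.fasta",
        )
        pd.DataFrame(
            [(c.orf_ref, c.peptide, c.cterm3) for c in candidates],
            columns=["orf", "peptide", "cterm3"],
        ).to_csv(outdir / "fyy_candidates.tsv", sep="\t", index=False)
        outputs += [outdir / "fyy_candidates.fasta", outdir / "fyy_candidates.tsv"]
        report["stages"]["motif"] = {"candidates": len(candidates)}
        log.info("motif: %d mature FYY candidates", len(candidates))

    if cfg.peaklist:
        pl = read_peaklist(_require(cfg.peaklist, "peak list"))
        reports = []
        for name, labels in _parse_compounds(cfg.compounds):
            formula = COMPOUNDS[name]
            for n13 in labels:
                ion = IsotopologueIon(formula=formula, n_13C=n13)
                reports.append(
                    detect_labeled_ion(
                        pl, ion, cfg.standard_rt, cfg.rt_tol, cfg.ppm
                    )
                )
        detection_table(reports).to_csv(
            outdir / "isotope_detections.tsv", sep="\t", index=False
        )
        outputs.append(outdir / "isotope_detections.tsv")
        n_det = sum(r.detected for r in reports)
        report["stages"]["isoms"] = {"ions": len(reports), "detected": n_det}
        log.info("isoms: %d ions searched, %d detected", len(reports), n_det)
    else:
        log.info("isoms: no peak list configured; skipped")

    if cfg.coi_alignment:
        aln = coi_mod.CoiAlignment.read(
            _require(cfg.coi_alignment, "COI alignment")
        )
        dm = coi_mod.distance_matrix(aln)
        dm.to_frame().to_csv(outdir / "coi_distances.tsv", sep="\t")
        clusters = coi_mod.threshold_clusters(dm, cfg.coi_cutoff)
        pd.DataFrame(
            [(i + 1, t) for i, c in enumerate(clusters) for t in c],
            columns=["cluster", "taxon"],
        ).to_csv(outdir / "coi_clusters.tsv", sep="\t", index=False)
        outputs += [outdir / "coi_distances.tsv", outdir / "coi_clusters.tsv"]
        if len(aln.taxa) >= 3:
            (outdir / "coi_nj.nwk").write_text(coi_mod.nj_tree(dm) + "\n")
            outputs.append(outdir / "coi_nj.nwk")
        report["stages"]["coi"] = {
            "taxa": len(aln.taxa), "clusters": len(clusters)
        }
        log.info("coi: %d taxa -> %d clusters", len(aln.taxa), len(clusters))
    else:
        log.info("coi: no alignment configured; skipped")

    manifest = pd.DataFrame(
        [(p.name, _sha256(p)) for p in outputs], columns=["file", "sha256"]
    )
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    report["outputs"] = dict(zip(manifest["file"], manifest["sha256"]))
    return report
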