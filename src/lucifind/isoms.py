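"""Exact-mass arithmetic for 13C-labelled ions and EIC detection.

Feeding experiments with uniformly 13C-labelled phenylalanine and tyrosine
shift the coelenterazine-pathway ions by one neutron-mass-defect unit
(13.0033548 - 12 = 1.0033548 Da) per incorporated label. This module
computes theoretical m/z values for such isotopologues as singly protonated
[M+H]+ ions, extracts ion chromatograms from centroided peak lists within a
ppm window, and reports detections against a standard's retention time.

Monoisotopic atomic masses (Da): C 12 (exact), H 1.00782503, N 14.0030740,
O 15.9949146, S 31.9720707, P 30.9737615; 13C 13.0033548. The adduct adds
the mass of a proton (1.00727646 Da), not of a hydrogen atom — the electron
mass matters at the fourth decimal of m/z.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MONOISOTOPIC = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.0030740,
    "O": 15.9949146,
    "S": 31.9720707,
    "P": 30.9737615,
}
MASS_13C = 13.0033548
PROTON = 1.00727646
LABEL_SHIFT = MASS_13C - MONOISOTOPIC["C"]

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    element_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = {e: c for e, c in self.element_counts.items() if c}
        if not counts:
            raise ValueError("formula must contain at least one element")
        if any(c < 0 for c in counts.values()):
            raise ValueError("element counts must be non-negative")
        object.__setattr__(self, "element_counts", counts)

    @classmethod
    def parse(cls, text: str) -> "MolecularFormula":
        """Parse a Hill-style formula string such as ``C17H15N3O``."""
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_RE.finditer(text):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r}")
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(
                m.group(2) or 1
            )
            pos = m.end()
        if pos != len(text) or not counts:
            raise ValueError(f"cannot parse formula {text!r}")
        return cls(counts)

    def __str__(self) -> str:
        return "".join(
            f"{e}{c if c > 1 else ''}"
            for e, c in sorted(self.element_counts.items())
        )


#: Compounds of the coelenterazine pathway searched by the label screen.
COMPOUNDS = {
    "coelenteramine": MolecularFormula.parse("C17H15N3O"),
    "coelenterazine": MolecularFormula.parse("C26H21N3O3"),
}


def monoisotopic_mass(f: MolecularFormula) -> float:
    """Sum of count x monoisotopic atomic mass over the formula."""
    try:
        return sum(
            c * MONOISOTOPIC[e] for e, c in f.element_counts.items()
        )
    except KeyError as exc:
        raise ValueError(f"unknown element {exc.args[0]!r}") from None


@dataclass(frozen=True)
class IsotopologueIon:
    """A [M+H]+ ion of ``formula`` with ``n_13C`` carbons labelled."""

    formula: MolecularFormula
    n_13C: int = 0
    adduct: str = "M+H"
    charge: int = 1

    def __post_init__(self) -> None:
        if self.adduct != "M+H" or self.charge != 1:
            raise ValueError("only singly protonated [M+H]+ is supported")
        if self.n_13C < 0:
            raise ValueError("label count must be non-negative")
        if self.n_13C > self.formula.element_counts.get("C", 0):
            raise ValueError("label count exceeds carbon count")

    @property
    def theoretical_mz(self) -> float:
        return labeled_mz(self.formula, self.n_13C)


def labeled_mz(
    f: MolecularFormula, n_13C: int = 0, adduct: str = "M+H"
) -> float:
    """Theoretical m/z of the singly protonated ion with ``n_13C`` labels.

    The label position never affects the value; only the count does.
    """
    if adduct != "M+H":
        raise ValueError("only the M+H adduct is supported")
    if n_13C < 0 or n_13C > f.element_counts.get("C", 0):
        raise ValueError("label count must be within the carbon count")
    return monoisotopic_mass(f) + n_13C * LABEL_SHIFT + PROTON


def ppm_error(observed: float, theoretical: float) -> float:
    """Absolute relative mass deviation in parts per million.

    Reports round this to one decimal place.
    """
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return abs(observed - theoretical) / theoretical * 1e6


@dataclass
class PeakList:
    """Centroided scans: (retention time in minutes, [(m/z, intensity)])."""

    scans: list[tuple[float, list[tuple[float, float]]]]

    def __post_init__(self) -> None:
        rts = [rt for rt, _ in self.scans]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise ValueError("scan retention times must be non-decreasing")
        for _, peaks in self.scans:
            if any(i < 0 for _, i in peaks):
                raise ValueError("intensities must be non-negative")


@dataclass
class Chromatogram:
    points: list[tuple[float, float]]
    target_mz: float
    tol_ppm: float

    @property
    def total_signal(self) -> float:
        return sum(i for _, i in self.points)


def read_peaklist(path) -> PeakList:
    """Read the TSV peak-list format (scan_index, rt_min, mz, intensity)."""
    df = pd.read_csv(path, sep="\t")
    scans = []
    for (_, rt), grp in df.groupby(["scan_index", "rt_min"], sort=True):
        scans.append(
            (float(rt), list(zip(grp["mz"].astype(float), grp["intensity"].astype(float))))
        )
    return PeakList(scans=scans)


def write_peaklist(pl: PeakList, path) -> None:
    rows = [
        (idx, rt, mz, inten)
        for idx, (rt, peaks) in enumerate(pl.scans)
        for mz, inten in peaks
    ]
    pd.DataFrame(
        rows, columns=["scan_index", "rt_min", "mz", "intensity"]
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_mzml(path) -> PeakList:
    """Read centroided MS1 scans from an mzML file (requires pyteomics)."""
    from pyteomics import mzml as _mzml

    scans = []
    with _mzml.read(str(path)) as reader:
        for spec in reader:
            if spec.get("ms level", 1) != 1:
                continue
            rt = float(
                spec["scanList"]["scan"][0]["scan start time"]
            )
            scans.append(
                (rt, list(zip(spec["m/z array"], spec["intensity array"])))
            )
    scans.sort(key=lambda x: x[0])
    return PeakList(scans=scans)


def extract_eic(
    pl: PeakList, target_mz: float, tol_ppm: float = 10.0
) -> Chromatogram:
    """Per-scan summed intensity within a closed +-tol_ppm window."""
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    # closed window; the 1e-9 relative slack keeps a peak placed exactly on
    # the boundary inside despite floating-point rounding
    half = target_mz * tol_ppm * 1e-6 * (1 + 1e-9)
    points = []
    for rt, peaks in pl.scans:
        total = sum(i for mz, i in peaks if abs(mz - target_mz) <= half)
        points.append((rt, total))
    return Chromatogram(points=points, target_mz=target_mz, tol_ppm=tol_ppm)


@dataclass
class DetectionReport:
    ion: IsotopologueIon
    detected: bool
    apex_rt: float | None = None
    apex_intensity: float | None = None
    area: float | None = None
    observed_mz: float | None = None
    ppm_error: float | None = None
    rt_match: bool | None = None


def detect_labeled_ion(
    pl: PeakList,
    ion: IsotopologueIon,
    standard_rt: float,
    rt_tol: float = 0.2,
    tol_ppm: float = 10.0,
) -> DetectionReport:
    """Detect an isotopologue ion by EIC apex and compare to a standard's RT.

    The apex is the EIC maximum (earliest scan on ties); the reported mass
    error compares the intensity-weighted mean m/z inside the window at the
    apex scan with the theoretical m/z. An all-zero EIC yields a
    not-detected report with no apex. ``rt_match`` is true iff the apex
    retention time is within ``rt_tol`` minutes of ``standard_rt``.
    """
    if rt_tol <= 0:
        raise ValueError("rt_tol must be positive")
    target = ion.theoretical_mz
    eic = extract_eic(pl, target, tol_ppm)
    if not eic.points or all(i == 0 for _, i in eic.points):
        return DetectionReport(ion=ion, detected=False)
    intens = np.array([i for _, i in eic.points])
    rts = np.array([rt for rt, _ in eic.points])
    k = int(np.argmax(intens))
    half = target * tol_ppm * 1e-6 * (1 + 1e-9)  # same closed window as the EIC
    apex_peaks = [
        (mz, i)
        for mz, i in pl.scans[k][1]
        if abs(mz - target) <= half
    ]
    wsum = sum(i for _, i in apex_peaks)
    obs = sum(mz * i for mz, i in apex_peaks) / wsum
    area = float(np.trapezoid(intens, rts)) if len(rts) > 1 else float(intens[0])
    return DetectionReport(
        ion=ion,
        detected=True,
        apex_rt=float(rts[k]),
        apex_intensity=float(intens[k]),
        area=area,
        observed_mz=float(obs),
        ppm_error=ppm_error(float(obs), target),
        rt_match=bool(abs(float(rts[k]) - standard_rt) <= rt_tol),
    )


def detection_table(reports: list[DetectionReport]) -> pd.DataFrame:
    """Tabulate detection reports; absent compounds appear as not detected."""
    rows = []
    for r in reports:
        rows.append(
            {
                "compound": str(r.ion.formula),
                "n_13C": r.ion.n_13C,
                "theoretical_mz": round(r.ion.theoretical_mz, 4),
                "detected": r.detected,
                "apex_rt_min": None if r.apex_rt is None else round(r.apex_rt, 2),
                "apex_intensity": r.apex_intensity,
                "area": r.area,
                "observed_mz": None if r.observed_mz is None else round(r.observed_mz, 4),
                "ppm_error": None if r.ppm_error is None else round(r.ppm_error, 1),
                "rt_match": r.rt_match,
            }
        )
    return pd.DataFrame(rows)
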