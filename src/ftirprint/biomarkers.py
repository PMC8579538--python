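"""Support-vector difference spectra and biomarker peak assignment.

The mean spectrum of the support vectors on each side of a fitted SVM
subproblem is contrasted; positive excursions of the difference attribute
to the first class, negative to the second. Peaks of the absolute
difference are picked by prominence and matched against a bundled
wavenumber-to-molecule reference table.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from ftirprint.classifiers import SvmModel, fit_svm_rbf, pair_support_vectors
from ftirprint.spectra_io import WavenumberGrid


@dataclass
class DifferenceSpectrum:
    grid: WavenumberGrid
    values: np.ndarray
    positive_class: str
    negative_class: str  # class label or "others"
    n_sv_pos: int
    n_sv_neg: int


@dataclass
class BiomarkerPeak:
    wavenumber: float
    signed_height: float
    assignment: str = ""
    assignment_distance: float = np.inf
    reference: str = ""


@dataclass
class AssignmentTable:
    """Wavenumber-to-molecular-annotation lookup."""

    frame: pd.DataFrame  # columns: wavenumber, assignment, reference

    def __post_init__(self) -> None:
        required = {"wavenumber", "assignment", "reference"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"assignment table needs columns {sorted(required)}")
        if self.frame.empty:
            raise ValueError("empty assignment table")


def load_assignment_table(path: str | Path | None = None) -> AssignmentTable:
    """Load the bundled molecular assignment reference (or a user CSV)."""
    if path is None:
        src = resources.files("ftirprint.data") / "molecular_assignments.csv"
        with resources.as_file(src) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    return AssignmentTable(frame=df)


def mean_sv_spectrum(
    m: SvmModel,
    class_label: str,
    contrast: str = "pairwise",
    other_class: str | None = None,
) -> np.ndarray:
    """Unweighted mean over unique support vectors of ``class_label``.

    ``pairwise``: SVs of the class active in the (class_label, other_class)
    one-vs-one subproblem. ``one_vs_others``: SVs of the class in a binary
    class-vs-pooled-rest fit (the model must be such a fit).
    """
    if contrast == "pairwise":
        if other_class is None:
            raise ValueError("pairwise contrast requires other_class")
        rows, _ = pair_support_vectors(m, class_label, other_class)
    elif contrast == "one_vs_others":
        mask = m.sv_class_labels == class_label
        rows = m.support_vectors[mask]
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    if rows.shape[0] == 0:
        raise ValueError(f"class {class_label!r} has no support vectors")
    return rows.mean(axis=0)


def difference_sv_spectrum(
    m: SvmModel,
    class_a: str,
    class_b: str,
    grid: WavenumberGrid,
    contrast: str = "pairwise",
) -> DifferenceSpectrum:
    """mean-SV(class_a) - mean-SV(class_b); positive excursions belong to a."""
    if contrast == "pairwise":
        rows_a, _ = pair_support_vectors(m, class_a, class_b)
        rows_b, _ = pair_support_vectors(m, class_b, class_a)
    else:
        mask_a = m.sv_class_labels == class_a
        mask_b = m.sv_class_labels == class_b
        rows_a = m.support_vectors[mask_a]
        rows_b = m.support_vectors[mask_b]
    if rows_a.shape[0] == 0 or rows_b.shape[0] == 0:
        raise ValueError("one of the contrasted classes has no support vectors")
    return DifferenceSpectrum(
        grid=grid,
        values=rows_a.mean(axis=0) - rows_b.mean(axis=0),
        positive_class=str(class_a),
        negative_class=str(class_b),
        n_sv_pos=rows_a.shape[0],
        n_sv_neg=rows_b.shape[0],
    )


def one_vs_others_difference(
    X_train: np.ndarray,
    labels: np.ndarray,
    class_label: str,
    grid: WavenumberGrid,
    cost: float = 10.0,
    gamma: float = 3.16,
) -> DifferenceSpectrum:
    """Dedicated class-vs-pooled-rest SVM fit and its SV difference spectrum."""
    labels = np.asarray(labels)
    binary = np.where(labels == class_label, str(class_label), "others")
    m = fit_svm_rbf(X_train, binary, cost=cost, gamma=gamma, probability=False)
    return difference_sv_spectrum(
        m, str(class_label), "others", grid, contrast="one_vs_others"
    )


def pick_peaks(
    d: DifferenceSpectrum,
    max_peaks: int = 12,
    min_prominence_frac: float = 0.1,
) -> list[BiomarkerPeak]:
    """Local extrema of |values| above a prominence fraction of the maximum.

    Returned sorted by |height| descending, truncated to ``max_peaks``;
    the signed height carries the sign of the difference at the extremum.
    """
    if max_peaks < 1:
        raise ValueError("max_peaks must be at least 1")
    if not 0 < min_prominence_frac <= 1:
        raise ValueError("min_prominence_frac must be in (0, 1]")
    mag = np.abs(d.values)
    vmax = mag.max()
    if vmax == 0:
        return []
    idx, _ = find_peaks(mag, prominence=min_prominence_frac * vmax)
    # interior endpoints of the grid can carry the global extremum
    for edge in (0, mag.size - 1):
        neighbour = 1 if edge == 0 else mag.size - 2
        if mag[edge] >= min_prominence_frac * vmax and mag[edge] > mag[neighbour]:
            idx = np.append(idx, edge)
    order = np.argsort(-mag[idx], kind="stable")
    idx = idx[order][:max_peaks]
    return [
        BiomarkerPeak(
            wavenumber=float(d.grid.values[i]),
            signed_height=float(d.values[i]),
        )
        for i in idx
    ]


def assign_peaks(
    peaks: list[BiomarkerPeak],
    table: AssignmentTable,
    tol: float = 8.0,
) -> list[BiomarkerPeak]:
    """Match each peak to the nearest table wavenumber within ``tol`` cm^-1.

    Ties resolve to the smaller table wavenumber; unmatched peaks keep an
    empty assignment. Input order is preserved.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    wn = table.frame["wavenumber"].to_numpy(dtype=float)
    out = []
    for p in peaks:
        dist = np.abs(wn - p.wavenumber)
        best = np.min(dist)
        if best <= tol:
            cands = np.where(dist == best)[0]
            row = table.frame.iloc[cands[np.argmin(wn[cands])]]
            out.append(
                BiomarkerPeak(
                    wavenumber=p.wavenumber,
                    signed_height=p.signed_height,
                    assignment=str(row["assignment"]),
                    assignment_distance=float(best),
                    reference=str(row["reference"]),
                )
            )
        else:
            out.append(
                BiomarkerPeak(
                    wavenumber=p.wavenumber, signed_height=p.signed_height
                )
            )
    return out


def biomarker_report(
    diffs: list[DifferenceSpectrum],
    table: AssignmentTable,
    max_peaks: int = 12,
    min_prominence_frac: float = 0.1,
    tol: float = 8.0,
) -> pd.DataFrame:
    """Tabular biomarker report: comparison, wavenumber, height, assignment."""
    rows = []
    for d in diffs:
        comparison = f"{d.positive_class} vs {d.negative_class}"
        for p in assign_peaks(pick_peaks(d, max_peaks, min_prominence_frac), table, tol):
            rows.append(
                {
                    "comparison": comparison,
                    "wavenumber": p.wavenumber,
                    "signed_height": p.signed_height,
                    "assignment": p.assignment,
                    "reference": p.reference,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["comparison", "wavenumber", "signed_height", "assignment", "reference"],
    )
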