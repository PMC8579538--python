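"""Spectral pre-processing: fingerprint cut, Savitzky-Golay differentiation,
vector normalization, mean-centering and rubber-band baseline correction.

The standard chain is cut -> SG 2nd derivative -> vector normalize, with
mean-centering deferred to model-fitting time so that test spectra are
centered by the training mean.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_filter

from ftirprint.spectra_io import SpectralDataset


class DegenerateSpectrumError(ValueError):
    """Raised when a spectrum cannot be normalized (zero norm)."""


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the pre-processing chain.

    Defaults reproduce the standard fingerprint workflow: cut to
    1800-900 cm^-1, 9-point quadratic Savitzky-Golay second derivative,
    unit-vector normalization.
    """

    cut_lo: float = 900.0
    cut_hi: float = 1800.0
    sg_window: int = 9
    sg_polyorder: int = 2
    sg_deriv: int = 2
    normalize: str = "vector"
    center: bool = True

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must be odd and greater than sg_polyorder")
        if self.sg_deriv > self.sg_polyorder:
            raise ValueError("sg_deriv must not exceed sg_polyorder")
        if self.cut_lo >= self.cut_hi:
            raise ValueError("cut_lo must be below cut_hi")
        if self.normalize not in ("vector", "none"):
            raise ValueError("normalize must be 'vector' or 'none'")


def cut_region(ds: SpectralDataset, lo: float, hi: float) -> SpectralDataset:
    """Restrict to grid points w with lo <= w <= hi (closed interval)."""
    if lo >= hi:
        raise ValueError(f"empty cut interval [{lo}, {hi}]")
    mask = (ds.grid.values >= lo) & (ds.grid.values <= hi)
    if not mask.any():
        raise ValueError(f"cut [{lo}, {hi}] does not overlap the grid")
    from ftirprint.spectra_io import WavenumberGrid

    return SpectralDataset(
        grid=WavenumberGrid(ds.grid.values[mask]),
        absorbance=ds.absorbance[:, mask].copy(),
        meta=list(ds.meta),
        provenance=ds.provenance + [f"cut[{lo},{hi}]"],
    )


def savitzky_golay(ds: SpectralDataset, cfg: PreprocessConfig) -> SpectralDataset:
    """Savitzky-Golay derivative along the wavenumber axis.

    Values are scaled to per-(cm^-1)^deriv units by dividing the polynomial
    coefficient by spacing**deriv. Boundary windows use the one-sided
    polynomial fit ('interp' mode) so output length equals input length.

    Because the grid is stored descending, differentiation with respect to
    ascending wavenumber requires a sign flip for odd derivative orders.
    """
    if len(ds.grid) < cfg.sg_window:
        raise ValueError("SG window longer than the spectrum")
    out = savgol_filter(
        ds.absorbance,
        window_length=cfg.sg_window,
        polyorder=cfg.sg_polyorder,
        deriv=cfg.sg_deriv,
        delta=ds.grid.spacing,
        axis=1,
        mode="interp",
    )
    if cfg.sg_deriv % 2 == 1 and ds.grid.descending:
        out = -out
    return replace(
        ds,
        absorbance=out,
        meta=list(ds.meta),
        provenance=ds.provenance
        + [f"sg[window={cfg.sg_window},poly={cfg.sg_polyorder},deriv={cfg.sg_deriv}]"],
    )


def vector_normalize(ds: SpectralDataset) -> SpectralDataset:
    """Scale every spectrum to unit Euclidean norm."""
    norms = np.linalg.norm(ds.absorbance, axis=1)
    bad = np.where(norms == 0)[0]
    if bad.size:
        raise DegenerateSpectrumError(
            f"zero-norm spectrum at row(s) {bad.tolist()}; cannot vector-normalize"
        )
    return replace(
        ds,
        absorbance=ds.absorbance / norms[:, None],
        meta=list(ds.meta),
        provenance=ds.provenance + ["vector_normalize"],
    )


def mean_center(
    train: SpectralDataset, apply_to: SpectralDataset | None = None
) -> tuple[SpectralDataset, SpectralDataset | None, np.ndarray]:
    """Center columns by the TRAIN mean; apply the same mean to ``apply_to``.

    Returns (centered train, centered apply_to or None, mean vector).
    """
    if train.n_spectra == 0:
        raise ValueError("cannot center an empty training set")
    mean = train.absorbance.mean(axis=0)
    out_train = replace(
        train,
        absorbance=train.absorbance - mean,
        meta=list(train.meta),
        provenance=train.provenance + ["mean_center[train]"],
    )
    out_apply = None
    if apply_to is not None:
        if apply_to.grid != train.grid:
            raise ValueError("grid mismatch between train and apply_to datasets")
        out_apply = replace(
            apply_to,
            absorbance=apply_to.absorbance - mean,
            meta=list(apply_to.meta),
            provenance=apply_to.provenance + ["mean_center[by train mean]"],
        )
    return out_train, out_apply, mean


def _lower_hull_baseline(w: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Lower convex-hull envelope of (w, y), evaluated at every w.

    ``w`` must be strictly increasing.
    """
    # Andrew's monotone chain, lower half only; robust to collinear input.
    chain: list[int] = []
    for i in range(w.size):
        while len(chain) >= 2:
            j, k = chain[-2], chain[-1]
            # pop non-left turns so only convex-from-below corners remain
            cross = (w[k] - w[j]) * (y[i] - y[j]) - (y[k] - y[j]) * (w[i] - w[j])
            if cross <= 0:
                chain.pop()
            else:
                break
        chain.append(i)
    idx = np.asarray(chain)
    return np.interp(w, w[idx], y[idx])


def rubberband_baseline(ds: SpectralDataset) -> SpectralDataset:
    """Subtract the lower convex-hull envelope from each spectrum.

    The corrected spectrum is non-negative and touches zero at both ends.
    """
    if ds.n_points < 3:
        raise ValueError("need at least 3 points for baseline correction")
    w = ds.grid.values
    flip = ds.grid.descending
    wx = w[::-1] if flip else w
    corrected = np.empty_like(ds.absorbance)
    for i, row in enumerate(ds.absorbance):
        y = row[::-1] if flip else row
        base = _lower_hull_baseline(wx, y)
        c = y - base
        corrected[i] = c[::-1] if flip else c
    return replace(
        ds,
        absorbance=corrected,
        meta=list(ds.meta),
        provenance=ds.provenance + ["rubberband_baseline"],
    )


def preprocess_pipeline(ds: SpectralDataset, cfg: PreprocessConfig) -> SpectralDataset:
    """Apply cut -> SG derivative -> vector normalization, in that order."""
    out = cut_region(ds, cfg.cut_lo, cfg.cut_hi)
    out = savitzky_golay(out, cfg)
    if cfg.normalize == "vector":
        out = vector_normalize(out)
    return out
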