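"""Reading, validating and writing spectral tables with hierarchical metadata.

A spectral table is a wide matrix (rows = spectra, columns = absorbance at
wavenumbers) together with a per-spectrum label that encodes the sampling
hierarchy: site, cane, leaf position, leaf side and replicate. Sites map
deterministically onto three geographic regions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

REGIONS = ("NEE", "NWE", "WS")
SITES = ("SOM", "SAP", "SLM", "SRC", "EDB", "ESA", "ESB")
LEAF_POSITIONS = ("New", "Height", "Mature")
LEAF_SIDES = ("upper", "lower", "unknown")

#: Fixed site-to-region assignment used throughout.
SITE_TO_REGION = {
    "SOM": "WS",
    "SAP": "WS",
    "SLM": "WS",
    "SRC": "WS",
    "EDB": "NEE",
    "ESA": "NWE",
    "ESB": "NWE",
}

#: Default label scheme: SITE_c<cane>_<position>_<side>_r<replicate>
DEFAULT_LABEL_RE = re.compile(
    r"^(?P<site>[A-Z]{3})"
    r"_c(?P<cane>\d+)"
    r"_(?P<position>New|Height|Mature)"
    r"(?:_(?P<side>upper|lower))?"
    r"_r(?P<replicate>\d+)$"
)


class GridError(ValueError):
    """Raised for non-uniform or non-monotone wavenumber grids."""


class MetadataError(ValueError):
    """Raised when a spectrum label cannot be parsed into sample metadata."""


class FormatError(ValueError):
    """Raised for structurally malformed spectral tables."""


def region_of(site: str) -> str:
    """Return the region code for a site code.

    Raises
    ------
    KeyError
        If the site code is unknown.
    """
    try:
        return SITE_TO_REGION[site]
    except KeyError:
        raise KeyError(
            f"unknown site code {site!r}; expected one of {sorted(SITE_TO_REGION)}"
        ) from None


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniformly spaced wavenumber axis, canonically descending.

    Ascending input is accepted and flipped to descending, the convention
    used by spectroscopic plots (high wavenumber on the left).
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise GridError("grid needs at least two wavenumber points")
        d = np.diff(v)
        if np.all(d > 0) or np.all(d < 0):
            pass
        else:
            raise GridError("wavenumber grid is not strictly monotone")
        step = abs(d[0])
        if not np.allclose(np.abs(d), step, rtol=1e-6, atol=0.0):
            raise GridError("wavenumber grid spacing is not uniform")
        object.__setattr__(self, "values", v)

    @property
    def spacing(self) -> float:
        """Absolute grid spacing in cm^-1."""
        return float(abs(self.values[1] - self.values[0]))

    @property
    def descending(self) -> bool:
        return bool(self.values[0] > self.values[-1])

    def canonicalized(self) -> "WavenumberGrid":
        """Return a descending copy (idempotent)."""
        if self.descending:
            return self
        return WavenumberGrid(self.values[::-1].copy())

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and np.array_equal(
            self.values, other.values
        )


@dataclass(frozen=True)
class SampleMeta:
    """Hierarchical identity of one spectrum."""

    site: str
    cane: int
    leaf_position: str
    leaf_side: str
    replicate: int

    def __post_init__(self) -> None:
        if self.site not in SITE_TO_REGION:
            raise MetadataError(f"unknown site {self.site!r}")
        if self.leaf_position not in LEAF_POSITIONS:
            raise MetadataError(f"unknown leaf position {self.leaf_position!r}")
        if self.leaf_side not in LEAF_SIDES:
            raise MetadataError(f"unknown leaf side {self.leaf_side!r}")

    @property
    def region(self) -> str:
        return SITE_TO_REGION[self.site]

    def label(self) -> str:
        side = "" if self.leaf_side == "unknown" else f"_{self.leaf_side}"
        return (
            f"{self.site}_c{self.cane}_{self.leaf_position}"
            f"{side}_r{self.replicate:02d}"
        )

    @classmethod
    def from_label(cls, label: str, pattern: re.Pattern | None = None) -> "SampleMeta":
        """Parse a spectrum label.

        ``pattern`` may supply a user regex with named groups ``site``,
        ``cane``, ``position``, ``side`` (optional) and ``replicate``.
        A missing side group is recorded as ``"unknown"``.
        """
        m = (pattern or DEFAULT_LABEL_RE).match(label)
        if m is None:
            raise MetadataError(f"cannot parse spectrum label {label!r}")
        g = m.groupdict()
        return cls(
            site=g["site"],
            cane=int(g["cane"]),
            leaf_position=g["position"],
            leaf_side=g.get("side") or "unknown",
            replicate=int(g["replicate"]),
        )


@dataclass
class SpectralDataset:
    """Absorbance matrix on a shared wavenumber grid plus per-row metadata."""

    grid: WavenumberGrid
    absorbance: np.ndarray
    meta: list[SampleMeta]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.ndim != 2:
            raise FormatError("absorbance must be a 2-D matrix")
        if self.absorbance.shape[1] != len(self.grid):
            raise FormatError(
                f"absorbance has {self.absorbance.shape[1]} columns but grid has "
                f"{len(self.grid)} points"
            )
        if self.absorbance.shape[0] != len(self.meta):
            raise FormatError(
                f"absorbance has {self.absorbance.shape[0]} rows but metadata has "
                f"{len(self.meta)} entries"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise FormatError("absorbance contains missing or non-finite values")
        if not self.grid.descending:
            self.grid = self.grid.canonicalized()
            self.absorbance = self.absorbance[:, ::-1].copy()

    @property
    def n_spectra(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_points(self) -> int:
        return self.absorbance.shape[1]

    def labels(self, field_name: str) -> np.ndarray:
        """Per-spectrum label array for ``region``, ``site``, etc."""
        return np.array([getattr(m, field_name) for m in self.meta])

    def subset(self, idx: Sequence[int] | np.ndarray) -> "SpectralDataset":
        idx = np.asarray(idx)
        return SpectralDataset(
            grid=self.grid,
            absorbance=self.absorbance[idx].copy(),
            meta=[self.meta[int(i)] for i in idx],
            provenance=self.provenance + [f"subset[n={len(idx)}]"],
        )

    def with_provenance(self, entry: str) -> "SpectralDataset":
        return replace(self, provenance=self.provenance + [entry])


def _dataset_from_frame(df: pd.DataFrame, label_pattern=None) -> SpectralDataset:
    try:
        wn = np.array([float(c) for c in df.columns])
    except ValueError as exc:
        raise FormatError(f"non-numeric wavenumber header: {exc}") from None
    grid = WavenumberGrid(wn)
    meta = []
    for i, lab in enumerate(df.index):
        try:
            meta.append(SampleMeta.from_label(str(lab), label_pattern))
        except MetadataError as exc:
            raise MetadataError(f"row {i} ({lab!r}): {exc}") from None
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise FormatError("table contains missing values")
    return SpectralDataset(grid=grid, absorbance=values, meta=meta)


def read_spectra_table(
    path: str | Path,
    dialect: str = "wide_csv",
    label_pattern: re.Pattern | None = None,
) -> SpectralDataset:
    """Read a spectral table.

    Dialects
    --------
    ``wide_csv`` / ``wide_tsv``
        First column ``label``, remaining columns numeric wavenumbers.
    ``two_column_txt_per_spectrum``
        ``path`` is a directory of per-spectrum two-column text files
        (wavenumber, absorbance); the filename stem is the label.
    """
    path = Path(path)
    if dialect in ("wide_csv", "wide_tsv"):
        sep = "," if dialect == "wide_csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        ds = _dataset_from_frame(df, label_pattern)
    elif dialect == "two_column_txt_per_spectrum":
        files = sorted(path.glob("*.txt"))
        if not files:
            raise FormatError(f"no .txt spectra found under {path}")
        rows, meta, grid = [], [], None
        for f in files:
            arr = np.loadtxt(f)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise FormatError(f"{f.name}: expected two columns")
            g = WavenumberGrid(arr[:, 0])
            y = arr[:, 1]
            if not g.descending:
                g, y = g.canonicalized(), y[::-1]
            if grid is None:
                grid = g
            elif g != grid:
                raise GridError(f"{f.name}: grid differs from first spectrum")
            rows.append(y)
            meta.append(SampleMeta.from_label(f.stem, label_pattern))
        ds = SpectralDataset(grid=grid, absorbance=np.vstack(rows), meta=meta)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return ds.with_provenance(f"read[{dialect}:{path.name}]")


def write_spectra_table(
    ds: SpectralDataset, path: str | Path, dialect: str = "wide_csv"
) -> None:
    """Write a dataset so that :func:`read_spectra_table` recovers it losslessly."""
    path = Path(path)
    if dialect in ("wide_csv", "wide_tsv"):
        sep = "," if dialect == "wide_csv" else "\t"
        df = pd.DataFrame(
            ds.absorbance,
            index=pd.Index([m.label() for m in ds.meta], name="label"),
            columns=[format(w, ".10g") for w in ds.grid.values],
        )
        df.to_csv(path, sep=sep, float_format="%.17g")
    elif dialect == "two_column_txt_per_spectrum":
        path.mkdir(parents=True, exist_ok=True)
        for m, row in zip(ds.meta, ds.absorbance):
            np.savetxt(
                path / f"{m.label()}.txt",
                np.column_stack([ds.grid.values, row]),
                fmt="%.17g",
            )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def metadata_frame(meta: Iterable[SampleMeta]) -> pd.DataFrame:
    """Tabular view of sample metadata (one row per spectrum)."""
    return pd.DataFrame(
        [
            {
                "region": m.region,
                "site": m.site,
                "cane": m.cane,
                "leaf_position": m.leaf_position,
                "leaf_side": m.leaf_side,
                "replicate": m.replicate,
            }
            for m in meta
        ]
    )
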