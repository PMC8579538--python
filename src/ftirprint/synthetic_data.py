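"""Synthetic spectrum and covariate generation with a hierarchical design.

Emulates a field study sampling 7 sites (grouped into 3 regions), 3 canes
per site, 3 leaves per cane (New/Height/Mature), 2 leaf sides and 10
replicate spectra per side: 1260 spectra from 63 leaves. Spectra are sums
of Gaussian bands in the fingerprint region plus polynomial baseline drift,
multiplicative scatter and additive noise. Class-specific amplitude factors
and band-centre shifts are injected at known wavenumbers and recorded in a
ground-truth sidecar so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ftirprint.spectra_io import (
    LEAF_POSITIONS,
    SITE_TO_REGION,
    SITES,
    SampleMeta,
    SpectralDataset,
    WavenumberGrid,
)

#: Default Gaussian band library: (centre cm^-1, width cm^-1, base amplitude).
DEFAULT_PEAKS = [
    (1736.0, 10.0, 0.55),
    (1725.0, 9.0, 0.45),
    (1678.0, 12.0, 0.50),
    (1662.0, 11.0, 0.60),
    (1648.0, 14.0, 0.90),
    (1608.0, 13.0, 0.50),
    (1586.0, 11.0, 0.40),
    (1546.0, 14.0, 0.75),
    (1512.0, 9.0, 0.35),
    (1481.0, 8.0, 0.30),
    (1446.0, 12.0, 0.45),
    (1158.0, 16.0, 0.55),
    (1034.0, 18.0, 0.85),
    (1015.0, 12.0, 0.80),
]

#: Default per-leaf-position global amplitude factors.
LEAF_POSITION_FACTORS = {"New": 0.92, "Height": 1.0, "Mature": 1.06}


@dataclass(frozen=True)
class ClassEffect:
    """A class-specific spectral perturbation at one band."""

    level: str  # "region" or "site"
    target: str  # class label the effect applies to
    wavenumber: float  # band centre the effect attaches to
    amplitude_factor: float = 1.0  # multiplicative amplitude change
    centre_shift: float = 0.0  # additive band-centre shift, cm^-1

    def __post_init__(self) -> None:
        if self.level not in ("region", "site"):
            raise ValueError("effect level must be 'region' or 'site'")
        if self.amplitude_factor <= 0:
            raise ValueError("amplitude factor must be positive")

    def applies_to(self, meta: SampleMeta) -> bool:
        value = meta.region if self.level == "region" else meta.site
        return value == self.target


@dataclass(frozen=True)
class SynthConfig:
    sites: tuple[str, ...] = SITES
    canes_per_site: int = 3
    leaves_per_cane: int = 3
    sides_per_leaf: int = 2
    replicates_per_side: int = 10
    grid_lo: float = 900.0
    grid_hi: float = 1800.0
    grid_step: float = 4.0
    peak_library: tuple = tuple(DEFAULT_PEAKS)
    effects: tuple[ClassEffect, ...] = ()
    baseline_order: int = 2
    baseline_sd: float = 0.02
    scatter_sd: float = 0.05
    noise_sd: float = 0.005
    leaf_position_effect_sd: float = 0.0
    within_site_amp_sd: float = 0.0  # per-leaf random amplitude wobble
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("scatter_sd", "noise_sd", "baseline_sd", "within_site_amp_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for s in self.sites:
            if s not in SITE_TO_REGION:
                raise ValueError(f"unknown site {s!r}")
        centres = {p[0] for p in self.peak_library}
        for e in self.effects:
            if e.wavenumber not in centres:
                raise ValueError(
                    f"effect at {e.wavenumber} cm^-1 matches no library band"
                )

    def grid(self) -> WavenumberGrid:
        values = np.arange(self.grid_hi, self.grid_lo - self.grid_step / 2, -self.grid_step)
        return WavenumberGrid(values)

    @property
    def n_spectra(self) -> int:
        return (
            len(self.sites)
            * self.canes_per_site
            * self.leaves_per_cane
            * self.sides_per_leaf
            * self.replicates_per_side
        )


@dataclass
class SynthTruth:
    """Ground truth per spectrum: enough to rebuild the noiseless signal."""

    config: SynthConfig
    rows: pd.DataFrame  # index aligned with the dataset rows

    def effect_wavenumbers(self) -> list[float]:
        return sorted({e.wavenumber for e in self.config.effects})


def generate_design(cfg: SynthConfig) -> list[SampleMeta]:
    """Full-factorial sample metadata in deterministic order.

    Leaf positions cycle New/Height/Mature within each cane.
    """
    meta = []
    for site in cfg.sites:
        for cane in range(1, cfg.canes_per_site + 1):
            for leaf_i in range(cfg.leaves_per_cane):
                position = LEAF_POSITIONS[leaf_i % len(LEAF_POSITIONS)]
                for side_i in range(cfg.sides_per_leaf):
                    side = ("upper", "lower")[side_i % 2]
                    for rep in range(1, cfg.replicates_per_side + 1):
                        meta.append(
                            SampleMeta(
                                site=site,
                                cane=cane,
                                leaf_position=position,
                                leaf_side=side,
                                replicate=rep,
                            )
                        )
    return meta


def _spectrum_rng(cfg: SynthConfig, index: int) -> np.random.Generator:
    """Counter-based substream: independent of other spectra's draws."""
    return np.random.default_rng(np.random.SeedSequence((cfg.seed, index)))


def noiseless_spectrum(
    meta: SampleMeta, cfg: SynthConfig, leaf_amp: float = 1.0
) -> np.ndarray:
    """Deterministic band structure for one sample (no baseline/noise)."""
    w = cfg.grid().values
    y = np.zeros_like(w)
    pos_factor = LEAF_POSITION_FACTORS.get(meta.leaf_position, 1.0)
    for centre, width, amp in cfg.peak_library:
        c, a = centre, amp
        for e in cfg.effects:
            if e.wavenumber == centre and e.applies_to(meta):
                a *= e.amplitude_factor
                c += e.centre_shift
        y += a * pos_factor * leaf_amp * np.exp(-0.5 * ((w - c) / width) ** 2)
    return y


def generate_spectrum(
    meta: SampleMeta, cfg: SynthConfig, index: int
) -> tuple[np.ndarray, dict]:
    """One spectrum plus its ground-truth record."""
    rng = _spectrum_rng(cfg, index)
    w = cfg.grid().values
    # per-leaf wobble keyed to the leaf, not the replicate, so replicates share it
    leaf_key = (
        cfg.seed,
        7919,  # namespace tag separating leaf streams from spectrum streams
        cfg.sites.index(meta.site),
        meta.cane,
        LEAF_POSITIONS.index(meta.leaf_position),
    )
    leaf_rng = np.random.default_rng(np.random.SeedSequence(leaf_key))
    leaf_amp = float(np.exp(leaf_rng.normal(0.0, cfg.within_site_amp_sd)))
    signal = noiseless_spectrum(meta, cfg, leaf_amp)
    # polynomial baseline on a normalized axis
    x = (w - w.mean()) / (w.max() - w.min())
    coefs = rng.normal(0.0, cfg.baseline_sd, size=cfg.baseline_order + 1)
    baseline = np.polyval(coefs, x)
    scatter = float(np.exp(rng.normal(0.0, cfg.scatter_sd)))
    noise = rng.normal(0.0, cfg.noise_sd, size=w.size)
    spectrum = scatter * (signal + baseline) + noise
    truth = {
        "index": index,
        "site": meta.site,
        "region": meta.region,
        "leaf_amp": leaf_amp,
        "scatter": scatter,
        "baseline_coefs": coefs.tolist(),
        "noise_substream": index,
    }
    return spectrum, truth


def generate_dataset(cfg: SynthConfig) -> tuple[SpectralDataset, SynthTruth]:
    """Generate the full design; reproducible and order-independent."""
    meta = generate_design(cfg)
    rows, truth_rows = [], []
    for i, m in enumerate(meta):
        y, t = generate_spectrum(m, cfg, i)
        rows.append(y)
        truth_rows.append(t)
    ds = SpectralDataset(
        grid=cfg.grid(),
        absorbance=np.vstack(rows),
        meta=meta,
        provenance=[f"synthetic[seed={cfg.seed},n={len(meta)}]"],
    )
    return ds, SynthTruth(config=cfg, rows=pd.DataFrame(truth_rows))


def default_region_effects(
    amplitude_factor: float = 1.5,
    centre_shift: float = 0.0,
    wavenumbers: tuple[float, ...] = (1015.0, 1608.0, 1158.0),
) -> tuple[ClassEffect, ...]:
    """Region-level effects at pectin/tannin/carbohydrate bands.

    The bands are well separated on the grid; adjacent bands (e.g. 1015 and
    1034) merge into one lobe after second differentiation and would defeat
    per-band recovery checks.

    NEE gets lowered amplitude plus a centre shift at the pectin bands;
    NWE and WS get opposite-signed amplitude changes at the tannin band so
    all three regions are mutually distinguishable.
    """
    effects = []
    for wn in wavenumbers:
        effects.append(
            ClassEffect(
                level="region",
                target="NEE",
                wavenumber=wn,
                amplitude_factor=1.0 / amplitude_factor,
                centre_shift=centre_shift,
            )
        )
    effects.append(
        ClassEffect(
            level="region", target="NWE",
            wavenumber=wavenumbers[0], amplitude_factor=amplitude_factor,
        )
    )
    return tuple(effects)


def default_site_effects(
    amplitude_factor: float = 1.3,
) -> tuple[ClassEffect, ...]:
    """Distinct single-band signatures per site (bands from the library)."""
    bands = [1748.0, 1755.0, 1161.0, 1103.0, 1728.0, 1512.0, 1446.0]
    lib_bands = [1736.0, 1725.0, 1158.0, 1015.0, 1678.0, 1512.0, 1446.0]
    return tuple(
        ClassEffect(
            level="site", target=site, wavenumber=lib_bands[i],
            amplitude_factor=amplitude_factor if i % 2 == 0 else 1.0 / amplitude_factor,
        )
        for i, site in enumerate(SITES)
    )


#: Plausible per-site soil means: (pH, %LOI, %water, Olsen P mg/kg, C:N).
DEFAULT_SOIL_MEANS = {
    "SOM": (6.1, 18.0, 35.0, 42.0, 12.5),
    "SAP": (6.4, 22.0, 40.0, 55.0, 12.0),
    "SLM": (6.0, 12.0, 28.0, 48.0, 13.0),
    "SRC": (5.8, 10.0, 25.0, 50.0, 13.5),
    "EDB": (4.9, 8.0, 20.0, 30.0, 19.0),
    "ESA": (6.6, 9.0, 22.0, 28.0, 12.8),
    "ESB": (6.5, 8.5, 21.0, 15.0, 16.0),
}

DEFAULT_SOIL_SDS = (0.15, 1.5, 2.5, 4.0, 0.6)


def generate_soil(
    site_means: dict | None = None,
    site_sds: tuple | None = None,
    replicates: int = 3,
    seed: int = 0,
    planted_outlier: tuple[str, int] | None = None,
    outlier_magnitude: float = 8.0,
) -> pd.DataFrame:
    """Per-site soil replicate table drawn from per-site normal laws.

    Values are truncated to physical ranges. ``planted_outlier=(site, rep)``
    pushes one row's %LOI and %water up by ``outlier_magnitude`` pooled SDs,
    mimicking an anomalous urban sample.
    """
    site_means = site_means or DEFAULT_SOIL_MEANS
    site_sds = site_sds or DEFAULT_SOIL_SDS
    if any(s < 0 for s in site_sds):
        raise ValueError("SDs must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for site, means in site_means.items():
        for rep in range(1, replicates + 1):
            vals = [
                rng.normal(mu, sd) if sd > 0 else float(mu)
                for mu, sd in zip(means, site_sds)
            ]
            if planted_outlier == (site, rep):
                vals[1] += outlier_magnitude * site_sds[1]
                vals[2] += outlier_magnitude * site_sds[2]
            rows.append(
                {
                    "site": site,
                    "replicate": rep,
                    "pH": float(np.clip(vals[0], 0.1, 13.9)),
                    "pct_LOI": float(np.clip(vals[1], 0.0, 100.0)),
                    "pct_water": float(np.clip(vals[2], 0.0, 100.0)),
                    "olsen_P": float(max(vals[3], 0.0)),
                    "C_to_N": float(max(vals[4], 0.1)),
                }
            )
    return pd.DataFrame(rows)


#: Regional climate covariates (one row per region), summer-season scale.
DEFAULT_CLIMATE = pd.DataFrame(
    {
        "region": ["NEE", "NWE", "WS"],
        "tmax": [19.5, 19.9, 17.8],
        "tmin": [10.8, 11.4, 10.6],
        "tmean": [15.2, 15.6, 14.2],
        "sunshine_h": [520.0, 540.0, 430.0],
        "rain_days": [35.0, 40.0, 55.0],
        "rain_ge1mm_days": [25.0, 28.0, 42.0],
        "airfrost_days": [0.0, 0.0, 0.0],
    }
)


def study_like_config(
    seed: int = 0,
    region_amplitude: float = 1.5,
    site_amplitude: float = 1.25,
    centre_shift: float = 4.0,
    noise_sd: float = 0.004,
    within_site_amp_sd: float = 0.04,
) -> SynthConfig:
    """Config with region- and site-level effects plus realistic nuisance
    structure, used by the end-to-end pipeline tests."""
    effects = default_region_effects(
        amplitude_factor=region_amplitude, centre_shift=centre_shift
    ) + default_site_effects(amplitude_factor=site_amplitude)
    return SynthConfig(
        effects=effects,
        noise_sd=noise_sd,
        within_site_amp_sd=within_site_amp_sd,
        seed=seed,
    )
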