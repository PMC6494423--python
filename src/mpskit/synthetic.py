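"""Synthetic localization and wide-field data with a known membrane-skeleton lattice.

The axonal membrane-associated periodic skeleton (MPS) is a quasi-1D lattice of
actin rings spaced ~190 nm along the axon, connected by spectrin tetramers.  A
STORM experiment on a spectrin subunit yields a list of fluorophore
localizations; when the lattice is intact the axial positions cluster on a ring
comb, and as the lattice disassembles an increasing share of localizations is
spatially random.  This module generates localization tables and matching
diffraction-limited image pairs from that generative picture, so the entire
analysis chain can be exercised against known ground truth.

Generative model for one axon
-----------------------------
``N ~ Poisson(density_per_um * axon_length_um)`` localizations.  Each one is
periodic with probability ``periodic_fraction``: its axial coordinate is
``k * period_nm + phase_nm + Normal(0, jitter_nm)`` with the ring index ``k``
uniform over the ``floor(L / period)`` complete rings.  Otherwise the axial
coordinate is ``Uniform(0, L)``.  Transverse (y) and depth (z) coordinates are
uniform across the axon diameter, and independent Gaussian localization error
is added to every coordinate.  Disassembly time courses are emulated purely by
lowering ``periodic_fraction`` (and optionally raising ``jitter_nm``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import ParameterError

__all__ = [
    "LatticeParams",
    "ConditionSpec",
    "LocalizationTable",
    "simulate_axon",
    "simulate_cohort",
    "simulate_widefield_pair",
    "td_timecourse",
    "TD_TIMECOURSE_FRACTIONS",
]

#: Periodic fraction per condition of the synthetic trophic-deprivation preset.
#: Emulates the qualitative decline of lattice order after NGF withdrawal.
TD_TIMECOURSE_FRACTIONS = {
    "NGF": 1.0,
    "TD_3h": 0.7,
    "TD_6h": 0.45,
    "TD_12h": 0.2,
}

_MAX_DIAMETER_NM = 700.0  # axon selection criterion: unbundled, diameter < 700 nm


@dataclass(frozen=True)
class LatticeParams:
    """Generative parameters of one axon's membrane periodic skeleton.

    Parameters
    ----------
    period_nm
        Ring spacing of the lattice; 190 nm for the actin/spectrin MPS.
    phase_nm
        Offset of the first ring from the axon origin, in ``[0, period_nm)``.
    jitter_nm
        Standard deviation of the Gaussian displacement of each localization
        from its ring center (lattice disorder).
    periodic_fraction
        Fraction ``f`` of localizations drawn from the ring comb; the rest are
        uniform along the axon.  ``f = 1`` is a fully ordered lattice,
        ``f = 0`` is complete spatial randomness.
    density_per_um
        Expected localizations per micron of axon length (Poisson).
    loc_precision_xy_nm, loc_precision_z_nm
        Localization error standard deviations (lateral, axial-depth).
    axon_length_um
        Axon segment length in microns.
    axon_diameter_nm
        Axon diameter; must not exceed 700 nm, matching the selection criterion
        for unbundled distal axons.
    """

    period_nm: float = 190.0
    phase_nm: float = 0.0
    jitter_nm: float = 10.0
    periodic_fraction: float = 1.0
    density_per_um: float = 500.0
    loc_precision_xy_nm: float = 10.0
    loc_precision_z_nm: float = 20.0
    axon_length_um: float = 38.0
    axon_diameter_nm: float = 300.0

    def __post_init__(self):
        if self.period_nm <= 0:
            raise ParameterError("period_nm must be positive")
        if not 0.0 <= self.phase_nm < self.period_nm:
            raise ParameterError("phase_nm must lie in [0, period_nm)")
        if self.jitter_nm < 0:
            raise ParameterError("jitter_nm must be >= 0")
        if not 0.0 <= self.periodic_fraction <= 1.0:
            raise ParameterError("periodic_fraction must lie in [0, 1]")
        if self.density_per_um <= 0:
            raise ParameterError("density_per_um must be positive")
        if self.loc_precision_xy_nm < 0 or self.loc_precision_z_nm < 0:
            raise ParameterError("localization precisions must be >= 0")
        if self.axon_length_um <= 0:
            raise ParameterError("axon_length_um must be positive")
        if not 0.0 < self.axon_diameter_nm <= _MAX_DIAMETER_NM:
            raise ParameterError(
                f"axon_diameter_nm must lie in (0, {_MAX_DIAMETER_NM:g}]"
            )

    @property
    def length_nm(self) -> float:
        return self.axon_length_um * 1000.0

    @property
    def n_rings(self) -> int:
        return int(self.length_nm // self.period_nm)


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental condition: a cohort of axons sharing lattice parameters."""

    label: str
    n_axons: int
    params: LatticeParams
    seed: int

    def __post_init__(self):
        if self.n_axons < 1:
            raise ParameterError("n_axons must be >= 1")


@dataclass
class LocalizationTable:
    """Molecular-coordinate list for one axon region.

    ``data`` holds columns ``axon_id, x_nm, y_nm[, z_nm][, frame]``; ``meta``
    carries provenance (seed, generative parameters, source file).
    """

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        cols = self.data.columns
        for required in ("axon_id", "x_nm", "y_nm"):
            if required not in cols:
                raise ParameterError(f"localization table lacks column {required!r}")
        coord_cols = [c for c in ("x_nm", "y_nm", "z_nm") if c in cols]
        values = self.data[coord_cols].to_numpy(dtype=float)
        if values.size and not np.all(np.isfinite(values)):
            raise ParameterError("localization coordinates must be finite")
        ids = self.data["axon_id"].unique()
        if len(ids) > 1:
            raise ParameterError("all rows of a table must share one axon_id")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def axon_id(self) -> str:
        return str(self.data["axon_id"].iloc[0]) if len(self.data) else ""

    def xy(self) -> np.ndarray:
        return self.data[["x_nm", "y_nm"]].to_numpy(dtype=float)


def simulate_axon(
    params: LatticeParams, seed: int, axon_id: str = "axon000"
) -> LocalizationTable:
    """Draw one axon's localizations from the lattice mixture model.

    Deterministic given ``(params, seed)``.  The axon runs along +x from 0 to
    its length; y and z are transverse/depth offsets about 0.
    """
    if not isinstance(params, LatticeParams):
        raise ParameterError("params must be a LatticeParams")
    length_nm = params.length_nm
    if length_nm < params.period_nm:
        raise ParameterError("axon shorter than one lattice period: no complete ring")

    rng = np.random.default_rng(seed)
    n = int(rng.poisson(params.density_per_um * params.axon_length_um))

    # Fixed draw order keeps the output reproducible across parameter values.
    is_periodic = rng.random(n) < params.periodic_fraction
    ring_index = rng.integers(0, params.n_rings, size=n)
    ring_jitter = rng.normal(0.0, params.jitter_nm, size=n)
    uniform_axial = rng.random(n) * length_nm
    comb_axial = ring_index * params.period_nm + params.phase_nm + ring_jitter
    axial = np.where(is_periodic, comb_axial, uniform_axial)

    half = params.axon_diameter_nm / 2.0
    y = rng.uniform(-half, half, size=n)
    z = rng.uniform(-half, half, size=n)

    x = axial + rng.normal(0.0, params.loc_precision_xy_nm, size=n)
    y = y + rng.normal(0.0, params.loc_precision_xy_nm, size=n)
    z = z + rng.normal(0.0, params.loc_precision_z_nm, size=n)

    data = pd.DataFrame(
        {
            "axon_id": np.repeat(axon_id, n),
            "x_nm": x,
            "y_nm": y,
            "z_nm": z,
            "frame": np.arange(n, dtype=np.int64),
        }
    )
    meta = {"seed": int(seed), "params": asdict(params)}
    return LocalizationTable(data, meta)


def _axon_seeds(seed: int, n: int) -> np.ndarray:
    """Counter-based per-axon seeds: reproducible and independent of iteration order."""
    return np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)


def simulate_cohort(spec: ConditionSpec):
    """Simulate a cohort of axons for one condition.

    Returns
    -------
    tables : list of LocalizationTable
    truth : pandas.DataFrame
        One row per axon with its id, seed and generative parameters.
    """
    seeds = _axon_seeds(spec.seed, spec.n_axons)
    tables = []
    records = []
    for i, axon_seed in enumerate(seeds):
        axon_id = f"{spec.label}_axon{i:03d}"
        table = simulate_axon(spec.params, int(axon_seed), axon_id=axon_id)
        table.meta["condition"] = spec.label
        tables.append(table)
        records.append(
            {"axon_id": axon_id, "condition": spec.label, "seed": int(axon_seed),
             **asdict(spec.params)}
        )
    return tables, pd.DataFrame.from_records(records)


def td_timecourse(
    seed: int,
    n_axons: int = 20,
    base_params: Optional[LatticeParams] = None,
    fractions: Optional[dict] = None,
) -> list:
    """Preset: four-condition disassembly time course with declining order.

    Periodic fraction falls from 1.0 (NGF) to 0.2 (12 h deprivation); all other
    lattice parameters are shared.  Per-condition seeds are derived from the
    top-level seed.
    """
    base = base_params if base_params is not None else LatticeParams()
    fractions = dict(fractions) if fractions is not None else dict(TD_TIMECOURSE_FRACTIONS)
    cond_seeds = np.random.SeedSequence(seed).generate_state(len(fractions), dtype=np.uint32)
    return [
        ConditionSpec(
            label=label,
            n_axons=n_axons,
            params=replace(base, periodic_fraction=f),
            seed=int(s),
        )
        for (label, f), s in zip(fractions.items(), cond_seeds)
    ]


def simulate_widefield_pair(
    params: LatticeParams,
    pixel_nm: float = 160.0,
    psf_sigma_nm: float = 250.0,
    coverage: float = 1.0,
    seed: int = 0,
    block_nm: float = 2000.0,
    signal: float = 1000.0,
    background: float = 10.0,
):
    """Simulate a registered two-channel wide-field image pair of one axon.

    The tubulin channel shows the whole axon as a filled ribbon; the spectrin
    channel carries signal on a ground-truth fraction ``coverage`` of the axon
    length (whole ``block_nm`` blocks, an exact count of them chosen at
    random).  Both channels are blurred by a Gaussian PSF and Poisson noise is
    added.  The realized covered fraction is recorded in the metadata.

    Returns an :class:`mpskit.occupancy.ImagePair`.
    """
    from .occupancy import ImagePair  # local import: occupancy does not import synthetic

    if pixel_nm <= 0 or psf_sigma_nm <= 0:
        raise ParameterError("pixel_nm and psf_sigma_nm must be positive")
    if not 0.0 <= coverage <= 1.0:
        raise ParameterError("coverage must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    length_nm = params.length_nm
    margin_nm = 4.0 * psf_sigma_nm
    n_cols = int(np.ceil((length_nm + 2 * margin_nm) / pixel_nm))
    n_rows = int(np.ceil((params.axon_diameter_nm + 2 * margin_nm) / pixel_nm))

    col_centers = (np.arange(n_cols) + 0.5) * pixel_nm
    row_centers = (np.arange(n_rows) + 0.5) * pixel_nm
    cy = n_rows * pixel_nm / 2.0
    in_x = (col_centers >= margin_nm) & (col_centers < margin_nm + length_nm)
    in_y = np.abs(row_centers - cy) <= params.axon_diameter_nm / 2.0
    ribbon = np.outer(in_y, in_x)

    n_blocks = max(1, int(round(length_nm / block_nm)))
    n_on = int(round(coverage * n_blocks))
    on_blocks = np.sort(rng.choice(n_blocks, size=n_on, replace=False))
    edges = margin_nm + np.linspace(0.0, length_nm, n_blocks + 1)
    block_of_col = np.clip(
        np.searchsorted(edges, col_centers, side="right") - 1, 0, n_blocks - 1
    )
    col_on = np.isin(block_of_col, on_blocks) & in_x
    spectrin_support = np.outer(in_y, col_on)

    sigma_px = psf_sigma_nm / pixel_nm

    def _render(support):
        ideal = background + signal * support.astype(float)
        blurred = ndimage.gaussian_filter(ideal, sigma_px)
        return rng.poisson(blurred).astype(np.uint16)

    tubulin = _render(ribbon)
    spectrin = _render(spectrin_support)
    meta = {
        "ribbon_support": ribbon,
        "spectrin_support": spectrin_support,
        "seed": int(seed),
        "params": asdict(params),
        "pixel_nm": float(pixel_nm),
        "psf_sigma_nm": float(psf_sigma_nm),
        "coverage_true": float(coverage),
        "coverage_realized": n_on / n_blocks,
        "signal": float(signal),
        "background": float(background),
    }
    return ImagePair(spectrin=spectrin, tubulin=tubulin, pixel_nm=pixel_nm, meta=meta)
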