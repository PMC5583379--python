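"""Peleg-Fermi cell-death model and ablation-area extraction.

Cell survival under pulsed-field exposure follows a Fermi (logistic) curve in
the local field magnitude E,

    S(E; N, tp) = 1 / (1 + exp((E - Ec(N, tp)) / k(N, tp))),
    D = 1 - S,

where Ec is the critical field at which half the cells die and k sets the
slope of the transition; both depend on the number of pulses N and the
single-pulse duration tp and were determined empirically in vitro.  The model
evaluates in kV/cm (the units in which Ec and k are published); field maps in
V/m are converted at this module's boundary.

The predicted ablation region at death probability p is the inclusive
super-level set {D >= p}; its area is the pixel count times the pixel area.
No connected-component filtering is applied by default (areas, not component
counts, are the endpoint); ``largest_component`` restricts the region to the
largest connected component for histology-like comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .constants import V_PER_M_PER_KV_PER_CM
from .grid import ScalarMap

__all__ = [
    "PulseProtocol",
    "PelegFermiParams",
    "AreaRecord",
    "MissingParameterError",
    "load_parameter_table",
    "lookup_params",
    "survival",
    "death_probability",
    "death_map",
    "predict_area",
    "area_curve",
]


@dataclass(frozen=True)
class PulseProtocol:
    """Electroporation pulse protocol.

    Defaults are the treatment protocol: two bursts of four 100 us pulses
    (8 pulses altogether) at 700 V with 5 kHz repetition frequency.
    """

    n_pulses: int = 8
    t_p: float = 100e-6
    amplitude_v: float = 700.0
    rep_freq_hz: float = 5000.0

    def __post_init__(self) -> None:
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")
        if self.t_p <= 0:
            raise ValueError("single-pulse duration t_p must be positive")


@dataclass(frozen=True)
class PelegFermiParams:
    """Survival-curve constants for one (N, tp) protocol, in kV/cm."""

    e_c: float
    k: float
    n_pulses: int = 8
    t_p: float = 100e-6

    def __post_init__(self) -> None:
        if self.e_c <= 0 or self.k <= 0:
            raise ValueError("e_c and k must be positive")


@dataclass
class AreaRecord:
    """Paired predicted/reference ablation areas at one probability level."""

    p: float
    a_ire: float
    a_he: float = np.nan
    case_id: str = ""

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError("probability level p must be in (0, 1)")
        if self.a_ire < 0 or (np.isfinite(self.a_he) and self.a_he < 0):
            raise ValueError("areas must be non-negative")


class MissingParameterError(KeyError):
    """No bundled (N, tp) entry for the requested protocol."""


def load_parameter_table(path=None) -> pd.DataFrame:
    """Load the (N, tp) -> (Ec, k) table; bundled table by default.

    Users may pass a CSV path with columns
    ``n_pulses, t_p_us, e_c_kv_cm, k_kv_cm`` to extend the bundled entries.
    """
    if path is None:
        with resources.files("iremap.data").joinpath("peleg_fermi.csv").open() as fh:
            return pd.read_csv(fh)
    return pd.read_csv(path)


def lookup_params(protocol: PulseProtocol, table: pd.DataFrame | None = None) -> PelegFermiParams:
    """Exact-match lookup of (Ec, k) for the protocol's (N, tp)."""
    if table is None:
        table = load_parameter_table()
    t_p_us = protocol.t_p * 1e6
    hit = table[
        (table["n_pulses"] == protocol.n_pulses)
        & (np.isclose(table["t_p_us"], t_p_us, rtol=1e-9, atol=1e-9))
    ]
    if hit.empty:
        avail = [
            f"(N={int(r.n_pulses)}, tp={r.t_p_us:g} us)" for r in table.itertuples()
        ]
        raise MissingParameterError(
            f"no survival-curve parameters for (N={protocol.n_pulses}, "
            f"tp={t_p_us:g} us); available: {', '.join(avail)}"
        )
    row = hit.iloc[0]
    return PelegFermiParams(
        e_c=float(row["e_c_kv_cm"]),
        k=float(row["k_kv_cm"]),
        n_pulses=protocol.n_pulses,
        t_p=protocol.t_p,
    )


def survival(e_kv_cm, params: PelegFermiParams):
    """Fermi survival fraction S(E) for field values in kV/cm.

    Accepts scalars or arrays; returns the same shape, values in [0, 1].
    """
    e = np.asarray(e_kv_cm, dtype=float)
    if np.any(e < 0):
        raise ValueError("field magnitude must be non-negative")
    s = 1.0 / (1.0 + np.exp((e - params.e_c) / params.k))
    if np.ndim(e_kv_cm) == 0:
        return float(s)
    return s


def death_probability(e_kv_cm, params: PelegFermiParams):
    """Cell-death probability D = 1 - S."""
    s = survival(e_kv_cm, params)
    return 1.0 - s


def death_map(e_map: ScalarMap, params: PelegFermiParams) -> ScalarMap:
    """Pointwise death probability of a field-magnitude map (V/m internally)."""
    if e_map.kind != "efield":
        raise ValueError(f"expected an efield map, got kind={e_map.kind!r}")
    if not np.all(np.isfinite(e_map.data)):
        raise ValueError("field map contains non-finite values")
    e_kv = e_map.data / V_PER_M_PER_KV_PER_CM
    d = death_probability(e_kv, params)
    return ScalarMap(d, e_map.grid, kind="death_probability")


def predict_area(
    d: ScalarMap, p: float, largest_component: bool = False
) -> tuple[float, np.ndarray]:
    """Ablation area (mm^2) and region at death-probability level ``p``.

    The region is the inclusive super-level set {D >= p}; with
    ``largest_component`` only its largest 8-connected component is kept.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    if d.kind != "death_probability":
        raise ValueError(f"expected a death_probability map, got kind={d.kind!r}")
    region = d.data >= p
    if largest_component and region.any():
        from scipy.ndimage import label

        labels, n = label(region, structure=np.ones((3, 3), dtype=int))
        if n > 1:
            sizes = np.bincount(labels.ravel())[1:]
            region = labels == (int(np.argmax(sizes)) + 1)
    area = float(region.sum()) * d.grid.pixel_area_mm2
    return area, region


def area_curve(
    d: ScalarMap, p_grid, case_id: str = "", largest_component: bool = False
) -> list[AreaRecord]:
    """Predicted areas over a strictly increasing grid of probability levels."""
    p_grid = list(p_grid)
    if not p_grid or any(not 0.0 < p < 1.0 for p in p_grid):
        raise ValueError("p_grid must be non-empty with levels in (0, 1)")
    if any(b <= a for a, b in zip(p_grid, p_grid[1:])):
        raise ValueError("p_grid must be strictly increasing")
    records = []
    for p in p_grid:
        area, _ = predict_area(d, p, largest_component=largest_component)
        records.append(AreaRecord(p=p, a_ire=area, case_id=case_id))
    return records
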