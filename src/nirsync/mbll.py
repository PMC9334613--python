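"""Modified Beer-Lambert law: extinction tables, forward and inverse maps.

The MBLL relates optical-density changes at two wavelengths to oxy-/deoxy-
hemoglobin concentration changes:

    dOD(lambda) = [eps_HbO(lambda)*dHbO + eps_HbR(lambda)*dHbR] * d * DPF(lambda)

with ``d`` the source-detector distance (cm) and DPF the differential
pathlength factor.  Extinction coefficients are tabulated in 1/(uM*cm) using
the natural-log OD convention; any self-consistent table/convention pairing
is acceptable because concentrations only enter downstream through coherence,
which is amplitude-invariant.
"""

from __future__ import annotations

import numpy as np

WAVELENGTHS_NM = (760, 850)
CHROMOPHORES = ("HbO", "HbR")

#: Extinction coefficients in 1/(uM*cm), natural-log convention
#: (compiled-literature values for the two standard NIRS wavelengths).
EXTINCTION_TABLES: dict[str, dict[int, dict[str, float]]] = {
    "compiled-nir-2wl": {
        760: {"HbO": 1.4866e-3, "HbR": 3.8437e-3},
        850: {"HbO": 2.5264e-3, "HbR": 1.7986e-3},
    },
}

DEFAULT_EXTINCTION_TABLE = "compiled-nir-2wl"
DEFAULT_DPF = {760: 6.0, 850: 6.0}


class ExtinctionError(ValueError):
    """Unknown or singular extinction configuration."""


def extinction_matrix(
    table_id: str = DEFAULT_EXTINCTION_TABLE,
    wavelengths: tuple[int, ...] = WAVELENGTHS_NM,
) -> np.ndarray:
    """(n_wavelengths x 2) matrix of extinction coefficients [HbO, HbR]."""
    try:
        table = EXTINCTION_TABLES[table_id]
    except KeyError:
        raise ExtinctionError(f"unknown extinction table {table_id!r}") from None
    try:
        E = np.array([[table[w][c] for c in CHROMOPHORES] for w in wavelengths])
    except KeyError as e:
        raise ExtinctionError(f"table {table_id!r} missing entry {e}") from None
    if E.shape[0] == E.shape[1] and abs(np.linalg.det(E)) < 1e-12:
        raise ExtinctionError(f"extinction matrix for {table_id!r} is singular")
    return E


def hb_to_od(
    hbo: np.ndarray,
    hbr: np.ndarray,
    *,
    dpf: dict[int, float] | None = None,
    distance_cm: float = 3.0,
    table_id: str = DEFAULT_EXTINCTION_TABLE,
    wavelengths: tuple[int, ...] = WAVELENGTHS_NM,
) -> np.ndarray:
    """Forward MBLL: concentrations (uM) -> OD changes.

    ``hbo``/``hbr`` are (..., time); the result gains a wavelength axis
    before time: (..., n_wavelengths, time).
    """
    dpf = dict(DEFAULT_DPF) if dpf is None else dpf
    E = extinction_matrix(table_id, wavelengths)
    path = np.array([distance_cm * dpf[w] for w in wavelengths])
    conc = np.stack([hbo, hbr], axis=-2)  # (..., 2, time)
    od = np.matmul(E, conc)               # (..., n_wavelengths, time)
    return od * path[:, None]


def od_to_hb_matrix(
    *,
    dpf: dict[int, float] | None = None,
    distance_cm: float = 3.0,
    table_id: str = DEFAULT_EXTINCTION_TABLE,
    wavelengths: tuple[int, ...] = WAVELENGTHS_NM,
) -> np.ndarray:
    """Inverse-MBLL 2x2 matrix M with [dHbO, dHbR] = M @ dOD(wavelengths)."""
    dpf = dict(DEFAULT_DPF) if dpf is None else dpf
    E = extinction_matrix(table_id, wavelengths)
    path = np.array([distance_cm * dpf[w] for w in wavelengths])
    A = E * path[:, None]
    return np.linalg.inv(A)
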