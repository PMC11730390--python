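"""Modified Beer–Lambert optics: DPF, extinction table, OD <-> concentration.

Concentration changes are expressed in µM, optical densities are
dimensionless (base-10), source–detector distance in cm, extinction
coefficients in 1/(mM·cm).
"""

from __future__ import annotations

import numpy as np

from .probe import ProbeLayout

#: Extinction coefficients epsilon[wavelength_nm] = (eps_HbO, eps_HbR)
#: in 1/(mM·cm).  One small self-consistent two-wavelength table is
#: shipped; the forward simulator and the inverse step both use it, so
#: round-trip correctness does not depend on any particular literature
#: compilation.
EXTINCTION_1_PER_MM_CM = {
    695.0: (0.300, 1.900),
    830.0: (1.000, 0.700),
}

# Coefficients of the general wavelength- and age-dependent DPF equation
# DPF(lambda, A) = a + b*A^c + d*lambda^3 + e*lambda^2 + f*lambda
_DPF_COEF = (223.3, 0.05624, 0.8493, -5.723e-7, 0.001245, -0.9025)


def compute_dpf(wavelength_nm: float, age_years: float) -> float:
    """Differential pathlength factor for a given wavelength and age.

    Valid for wavelengths in [650, 900] nm and age >= 0 years.  For a
    neonate (age 0) at the probe wavelengths this gives 5.31 (695 nm)
    and 4.67 (830 nm) to two decimals.
    """
    if not (650.0 <= wavelength_nm <= 900.0):
        raise ValueError(f"wavelength {wavelength_nm} nm outside [650, 900]")
    if age_years < 0:
        raise ValueError("age must be >= 0")
    a, b, c, d, e, f = _DPF_COEF
    lam = float(wavelength_nm)
    return a + b * float(age_years) ** c + d * lam ** 3 + e * lam ** 2 + f * lam


def _transfer_matrix(layout: ProbeLayout, extinction: dict, age_years: float) -> np.ndarray:
    """2x2 matrix M with dOD(lambda_i) = sum_j M[i, j] * conc_mM[j].

    Rows follow layout.wavelengths_nm, columns are (HbO, HbR).
    """
    if layout.n_wavelengths != 2:
        raise ValueError("exactly two wavelengths required")
    rows = []
    for lam in layout.wavelengths_nm:
        if lam not in extinction:
            raise ValueError(f"no extinction entry for {lam} nm")
        eps_hbo, eps_hbr = extinction[lam]
        dpf = compute_dpf(lam, age_years)
        rows.append([eps_hbo * layout.distance_cm * dpf,
                     eps_hbr * layout.distance_cm * dpf])
    m = np.asarray(rows)
    if abs(np.linalg.det(m)) < 1e-12:
        raise ValueError("extinction matrix is singular")
    return m


def conc_to_od(dhbo_um: np.ndarray, dhbr_um: np.ndarray, layout: ProbeLayout,
               extinction: dict | None = None, age_years: float = 0.0) -> np.ndarray:
    """Forward model: concentration changes (µM, shape (C, T)) to
    optical-density changes (shape (C, W, T))."""
    ext = EXTINCTION_1_PER_MM_CM if extinction is None else extinction
    m = _transfer_matrix(layout, ext, age_years)
    conc_mm = np.stack([dhbo_um, dhbr_um], axis=-2) * 1e-3  # (C, 2, T) in mM
    return np.einsum("wj,cjt->cwt", m, conc_mm)


def od_to_conc(dod: np.ndarray, layout: ProbeLayout,
               extinction: dict | None = None, age_years: float = 0.0):
    """Inverse modified Beer–Lambert: dOD (C, W, T) -> (dHbO, dHbR) in µM.

    Solves the per-channel, per-sample 2x2 linear system
    dOD(lambda) = [eps_HbO(lambda)·dHbO + eps_HbR(lambda)·dHbR]·d·DPF(lambda).
    """
    ext = EXTINCTION_1_PER_MM_CM if extinction is None else extinction
    m = _transfer_matrix(layout, ext, age_years)
    minv = np.linalg.inv(m)
    conc_mm = np.einsum("jw,cwt->cjt", minv, dod)
    conc_um = conc_mm * 1e3
    return conc_um[:, 0, :], conc_um[:, 1, :]
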