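"""Scan-specific grey->HU calibration and HU->mineral-density conversion.

Cone-beam CT scanners report vendor grey values, not Hounsfield units.  A
holder phantom with three materials of known HU — air (-1000), polyoxymethylene
(POM, 300) and polytetrafluoroethylene (PTFE, 950) — is imaged with every scan;
an ordinary-least-squares line through the three (ROI grey mean, reference HU)
points gives the scan-specific affine map to HU.

HU is then converted to hydroxyapatite-equivalent mass density via an additive
two-material mixture model at a 48 keV effective energy (the effective energy
of an 85 kV spectrum): a voxel is water plus an added mineral mass density
rho [g/cm^3], so its linear attenuation is

    mu(rho) = (mu/rho)_water * 1.0 + (mu/rho)_HA * rho

and, since HU = 1000 (mu - mu_water) / mu_water,

    rho(HU) = HU * (mu/rho)_water / (1000 * (mu/rho)_HA).

Mass attenuation coefficients are interpolated (log-log) at 48 keV from the
NIST XCOM photon cross-section database (total attenuation with coherent
scattering, cm^2/g); hydroxyapatite Ca10(PO4)6(OH)2 is combined from its
elements by mass fraction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .volume import Volume

#: reference HU of the phantom materials (air by definition of the HU scale)
REFERENCE_HU = {"air": -1000.0, "pom": 300.0, "ptfe": 950.0}

# NIST XCOM mass attenuation coefficients (cm^2/g, total w/ coherent)
# at 40 / 50 / 60 keV; interpolated log-log at the requested effective energy.
_XCOM_ENERGIES_KEV = np.array([40.0, 50.0, 60.0])
_XCOM_MU_RHO = {
    "water": np.array([0.2683, 0.2269, 0.2059]),
    "H": np.array([0.3458, 0.3355, 0.3260]),
    "O": np.array([0.2585, 0.2132, 0.1907]),
    "P": np.array([0.5158, 0.3896, 0.3267]),
    "Ca": np.array([1.019, 0.7451, 0.5940]),
}
# Ca10(PO4)6(OH)2 mass fractions (IUPAC 2021 atomic weights)
_HA_MASS_FRACTIONS = {"Ca": 0.39894, "P": 0.18499, "O": 0.41407, "H": 0.00200}
#: mass fraction of calcium in hydroxyapatite (HA-equiv -> calcium-mass density)
CALCIUM_FRACTION_HA = _HA_MASS_FRACTIONS["Ca"]


def _mu_rho_at(material: str, energy_kev: float) -> float:
    """Log-log interpolated mass attenuation coefficient, cm^2/g."""
    y = _XCOM_MU_RHO[material]
    return float(np.exp(np.interp(np.log(energy_kev),
                                  np.log(_XCOM_ENERGIES_KEV), np.log(y))))


def attenuation_table(energy_kev: float = 48.0) -> dict[str, float]:
    """Mass attenuation coefficients (cm^2/g) for water and hydroxyapatite."""
    mu_ha = sum(w * _mu_rho_at(el, energy_kev) for el, w in _HA_MASS_FRACTIONS.items())
    return {"water": _mu_rho_at("water", energy_kev), "hydroxyapatite": mu_ha}


@dataclass
class CalibrationCurve:
    """Affine grey->HU map fitted to the three phantom materials."""

    slope_hu_per_grey: float
    intercept_hu: float
    fit_residuals: dict[str, float]
    material_grey_means: dict[str, float]
    material_reference_hu: dict[str, float] = field(
        default_factory=lambda: dict(REFERENCE_HU))

    def __call__(self, grey: np.ndarray) -> np.ndarray:
        return self.slope_hu_per_grey * np.asarray(grey, float) + self.intercept_hu

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationCurve":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class DensityRelation:
    """Linear HU -> mineral mass density map at a single effective energy.

    ``units`` is ``"ha"`` (hydroxyapatite-equivalent mass density, the default)
    or ``"ca"`` (mass density of calcium only, i.e. scaled by the Ca mass
    fraction of hydroxyapatite).  Water (HU = 0) maps to 0 in either system.
    """

    slope_gcm3_per_hu: float
    intercept_gcm3: float
    energy_keV: float
    attenuation_table: dict[str, float]
    units: str = "ha"

    def density(self, hu: np.ndarray) -> np.ndarray:
        rho = self.slope_gcm3_per_hu * np.asarray(hu, float) + self.intercept_gcm3
        return np.clip(rho, 0.0, None)

    def hu(self, density_gcm3: np.ndarray) -> np.ndarray:
        """Inverse map (no clamping); used by the phantom generator."""
        return (np.asarray(density_gcm3, float) - self.intercept_gcm3) / self.slope_gcm3_per_hu

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))


def build_density_relation(table: dict[str, float] | None = None,
                           energy_kev: float = 48.0,
                           units: str = "ha") -> DensityRelation:
    """Derive the HU->density line from tabulated cross sections.

    Parameters
    ----------
    table
        Mapping with ``water`` and ``hydroxyapatite`` mass attenuation
        coefficients (cm^2/g) at ``energy_kev``.  Defaults to the built-in
        XCOM-derived values.
    units
        ``"ha"`` for HA-equivalent density, ``"ca"`` for calcium mass density.
    """
    if table is None:
        table = attenuation_table(energy_kev)
    for mat in ("water", "hydroxyapatite"):
        if mat not in table:
            raise ValueError(f"attenuation table is missing {mat!r}")
    mu_w, mu_ha = table["water"], table["hydroxyapatite"]
    if mu_ha <= mu_w:
        raise ValueError(
            "mineral coefficient must exceed water's (degenerate relation)")
    slope = mu_w / (1000.0 * mu_ha)  # g/cm^3 HA-equiv per HU
    if units == "ca":
        slope *= CALCIUM_FRACTION_HA
    elif units != "ha":
        raise ValueError(f"unknown unit system {units!r}")
    return DensityRelation(slope_gcm3_per_hu=slope, intercept_gcm3=0.0,
                           energy_keV=energy_kev, attenuation_table=dict(table),
                           units=units)


def extract_roi_stats(volume: Volume, roi: np.ndarray) -> tuple[float, float, int]:
    """Mean, SD and voxel count of grey values inside an ROI.

    ``roi`` is either a boolean mask of the volume's shape or an (N, 3) integer
    voxel-index array.
    """
    roi = np.asarray(roi)
    if roi.dtype == bool:
        if roi.shape != volume.shape:
            raise ValueError("boolean ROI shape does not match volume")
        idx = np.argwhere(roi)
    else:
        idx = roi.reshape(-1, 3).astype(np.intp)
    if idx.size == 0:
        raise ValueError("ROI is empty")
    shape = np.array(volume.shape)
    if (idx < 0).any() or (idx >= shape).any():
        raise ValueError("ROI extends outside the volume")
    if (idx == 0).any() or (idx == shape - 1).any():
        warnings.warn("ROI touches the volume boundary", stacklevel=2)
    vals = volume.data[idx[:, 0], idx[:, 1], idx[:, 2]]
    n = int(vals.size)
    sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
    return float(np.mean(vals)), sd, n


def cylinder_roi(shape: tuple[int, int, int], centre_xy: tuple[float, float],
                 radius_vox: float, z_range: tuple[int, int]) -> np.ndarray:
    """Boolean mask for an axis-aligned cylindrical ROI (world-coordinate ROIs
    from a scan protocol reduce to this on an isotropic grid)."""
    xx, yy = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    disc = (xx - centre_xy[0]) ** 2 + (yy - centre_xy[1]) ** 2 <= radius_vox**2
    mask = np.zeros(shape, bool)
    mask[:, :, z_range[0]:z_range[1]] = disc[:, :, None]
    return mask


def fit_calibration(grey_means: dict[str, float] | list[float],
                    reference_hu: dict[str, float] | list[float] | None = None,
                    ) -> CalibrationCurve:
    """Ordinary least squares line HU = a*grey + b through the 3 phantom points.

    Residuals are reported per material so downstream users can propagate
    calibration uncertainty.
    """
    if reference_hu is None:
        reference_hu = REFERENCE_HU
    if isinstance(grey_means, dict):
        mats = list(grey_means)
        grey = np.array([grey_means[m] for m in mats], float)
        refs = np.array([reference_hu[m] for m in mats], float)
    else:
        mats = list(REFERENCE_HU)
        grey = np.asarray(grey_means, float)
        if isinstance(reference_hu, dict):
            refs = np.array([reference_hu[m] for m in mats], float)
        else:
            refs = np.asarray(reference_hu, float)
    if len(grey) < 2:
        raise ValueError("need at least two phantom materials")
    if np.ptp(grey) == 0 or len(np.unique(grey)) < len(grey):
        raise ValueError("coincident grey means: singular calibration fit")
    order = np.argsort(grey)
    if not np.all(np.diff(refs[order]) > 0):
        warnings.warn("grey means not ordered like reference HU "
                      "(non-monotone phantom measurement)", stacklevel=2)
    slope, intercept = np.polyfit(grey, refs, 1)
    resid = refs - (slope * grey + intercept)
    return CalibrationCurve(
        slope_hu_per_grey=float(slope), intercept_hu=float(intercept),
        fit_residuals={m: float(r) for m, r in zip(mats, resid)},
        material_grey_means={m: float(g) for m, g in zip(mats, grey)},
        material_reference_hu={m: float(r) for m, r in zip(mats, refs)})


def grey_to_hu(volume: Volume, curve: CalibrationCurve) -> Volume:
    """Apply the fitted affine map voxelwise; the curve is kept in metadata."""
    hu = curve(volume.data)
    return volume.with_data(hu, kind="hu",
                            calibration={"slope": curve.slope_hu_per_grey,
                                         "intercept": curve.intercept_hu})


def hu_to_density(volume: Volume, relation: DensityRelation | None = None) -> Volume:
    """Convert HU to mineral mass density (g/cm^3), clamped below at 0."""
    if relation is None:
        relation = build_density_relation()
    rho = relation.density(volume.data)
    return volume.with_data(rho, kind="density",
                            density_units=relation.units,
                            density_slope=relation.slope_gcm3_per_hu)
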