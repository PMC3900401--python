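"""Site-occupancy quantitation of collagen post-translational modifications.

Collagen prolyl 3-hydroxylation and lysyl hydroxylation/glycosylation
are quantified from averaged full-scan ion intensities: all PTM
variants of a tryptic peptide appear together in the averaged scan,
and the percent occupancy of a modification is the summed intensity of
the modified variant ions over the total for all variants of that
peptide.

3-Hyp and 4-Hyp are isobaric (+15.9949 Da); when MS/MS shows that a
fraction phi of the +16 ion is carried by the alternative-site 4-Hyp
isomer, the corrected 3-Hyp occupancy removes that fraction from the
numerator while keeping it in the denominator (it is the same peptide,
differently modified):

    corrected % = 100 * (1 - phi) * I_+16 / (I_unmod + I_+16)

Pyridinoline cross-link measurements (HP, LP, mol/mol collagen) and
their HP/LP molar ratio, and telopeptide Hyl/Lys hydroxylation
percentages, are thin arithmetic over peak areas / ion intensities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import GAL_SHIFT_DA, GLCGAL_SHIFT_DA, OXYGEN_SHIFT_DA, PROTON_MASS_DA

logger = logging.getLogger(__name__)

#: Named modification shifts available to species definitions (Da).
KNOWN_SHIFTS = {
    "hyp": OXYGEN_SHIFT_DA,
    "hyl": OXYGEN_SHIFT_DA,
    "gal": GAL_SHIFT_DA,
    "glcgal": GLCGAL_SHIFT_DA,
}


@dataclass
class PeptideSpecies:
    """A peptide and the PTM variants considered for it."""

    label: str
    base_mass_Da: float
    modifications: list[tuple[str, float]] = field(default_factory=list)
    charges: list[int] = field(default_factory=lambda: [2])

    def __post_init__(self) -> None:
        if self.base_mass_Da <= 0:
            raise ValueError("base mass must be positive")
        if any(z < 1 for z in self.charges):
            raise ValueError("charges must be >= 1")


@dataclass
class ScanTable:
    """Averaged full-scan peak list (m/z strictly increasing)."""

    mz: np.ndarray
    intensity: np.ndarray
    retention_window: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be matched 1-D arrays")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z values must be strictly increasing")
        if np.any(~np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise ValueError("intensities must be finite and non-negative")

    def to_tsv(self, path) -> None:
        pd.DataFrame({"mz": self.mz, "intensity": self.intensity}).to_csv(
            path, sep="\t", index=False, float_format="%.10g"
        )


def read_scan(path) -> ScanTable:
    frame = pd.read_csv(path, sep="\t")
    return ScanTable(frame.iloc[:, 0].to_numpy(), frame.iloc[:, 1].to_numpy())


@dataclass
class OccupancyEstimate:
    site_label: str
    percent: float
    phi: float
    modified_intensity: float
    total_intensity: float
    defined: bool = True


@dataclass
class CrosslinkMeasurement:
    hp_mol_per_mol: float
    lp_mol_per_mol: float

    @property
    def ratio(self) -> float | None:
        """HP/LP molar ratio; undefined (None) when LP = 0."""
        if self.lp_mol_per_mol == 0:
            return None
        return self.hp_mol_per_mol / self.lp_mol_per_mol


# ---------------------------------------------------------------------------
# Operations


def mz_of(base_mass_Da: float, shifts_Da=(), charge: int = 1) -> float:
    """m/z of a (modified) peptide ion: (M + sum shifts + z*m_p) / z."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (base_mass_Da + float(np.sum(shifts_Da)) + charge * PROTON_MASS_DA) / charge


def match_ions(
    scan: ScanTable, targets, tol_ppm: float = 250.0
) -> np.ndarray:
    """Summed intensity of scan peaks within ``tol_ppm`` of each target m/z.

    A peak within tolerance of several targets is assigned to the
    nearest one (ties: the lower-index target) with a warning.
    """
    if tol_ppm <= 0:
        raise ValueError("tolerance must be positive")
    targets = np.asarray(targets, dtype=float)
    out = np.zeros(len(targets))
    for mz_peak, inten in zip(scan.mz, scan.intensity):
        dev = np.abs(targets - mz_peak)
        within = dev <= targets * tol_ppm * 1e-6
        if not within.any():
            continue
        if within.sum() > 1:
            logger.warning(
                "peak at m/z %.4f matches %d targets; assigned to nearest",
                mz_peak,
                int(within.sum()),
            )
        candidates = np.flatnonzero(within)
        best = candidates[np.argmin(dev[candidates])]
        out[best] += inten
    return out


def occupancy(
    intensities, modified: "list[int] | np.ndarray", site_label: str = ""
) -> OccupancyEstimate:
    """Percent occupancy = 100 * modified intensity / total intensity.

    ``intensities`` is per-variant; ``modified`` holds the indices of
    the modified variants.  A zero total is flagged undefined.
    """
    intensities = np.asarray(intensities, dtype=float)
    total = float(intensities.sum())
    mod = float(intensities[list(modified)].sum())
    if total <= 0:
        return OccupancyEstimate(site_label, float("nan"), 0.0, mod, total, defined=False)
    return OccupancyEstimate(site_label, 100.0 * mod / total, 0.0, mod, total)


def isobaric_correction(
    unmod_intensity: float,
    plus16_intensity: float,
    phi: float,
    site_label: str = "",
    exclude_confound_from_total: bool = False,
) -> OccupancyEstimate:
    """3-Hyp occupancy corrected for the isobaric 4-Hyp confound.

    A fraction ``phi`` of the +15.9949 Da ion belongs to the 4-Hyp
    isomer and is removed from the numerator.  By default it stays in
    the denominator (same peptide, differently modified); set
    ``exclude_confound_from_total`` to drop it there too.
    """
    if not 0.0 <= phi <= 1.0:
        raise ValueError("phi must lie in [0, 1]")
    numer = (1.0 - phi) * plus16_intensity
    denom = unmod_intensity + (
        numer if exclude_confound_from_total else plus16_intensity
    )
    if denom <= 0:
        return OccupancyEstimate(
            site_label, float("nan"), phi, numer, denom, defined=False
        )
    return OccupancyEstimate(site_label, 100.0 * numer / denom, phi, numer, denom)


def occupancy_across_charges(
    per_charge_intensities: "dict[int, np.ndarray]", modified
) -> OccupancyEstimate:
    """Intensity-weighted average of per-charge-state occupancies.

    Weighting each charge state by its total variant intensity makes the
    result identical to pooling the intensities before dividing.
    """
    percents, weights = [], []
    for z, intens in sorted(per_charge_intensities.items()):
        est = occupancy(intens, modified, site_label=f"z={z}")
        if est.defined:
            percents.append(est.percent)
            weights.append(est.total_intensity)
    if not weights:
        return OccupancyEstimate("", float("nan"), 0.0, 0.0, 0.0, defined=False)
    w = np.asarray(weights)
    p = float(np.average(percents, weights=w))
    return OccupancyEstimate("", p, 0.0, float("nan"), float(w.sum()))


def crosslink_ratio(
    hp_area: float,
    lp_area: float,
    response_factor_hp: float = 1.0,
    response_factor_lp: float = 1.0,
    collagen_moles: float = 1.0,
) -> CrosslinkMeasurement:
    """HP and LP contents (mol/mol collagen) and their molar ratio.

    Response factors default to 1 (relative quantitation).
    """
    if hp_area < 0 or lp_area < 0:
        raise ValueError("peak areas must be non-negative")
    if response_factor_hp <= 0 or response_factor_lp <= 0:
        raise ValueError("response factors must be positive")
    if collagen_moles <= 0:
        raise ValueError("collagen amount must be positive")
    return CrosslinkMeasurement(
        hp_mol_per_mol=hp_area * response_factor_hp / collagen_moles,
        lp_mol_per_mol=lp_area * response_factor_lp / collagen_moles,
    )


def telopeptide_hydroxylation(hyl_intensity: float, lys_intensity: float) -> float:
    """Percent hydroxylation from the Hyl / (Hyl + Lys) telopeptide ion ratio.

    Returns NaN when both intensities are zero.
    """
    total = hyl_intensity + lys_intensity
    if total <= 0:
        return float("nan")
    return 100.0 * hyl_intensity / total


# ---------------------------------------------------------------------------
# Species-table driven quantitation (CLI backend)


def read_species(path) -> pd.DataFrame:
    """Variant definition TSV: label, base_mass_da, shift_da, charges, modified.

    ``charges`` is a ';'-joined integer list, ``modified`` is 0/1.
    """
    frame = pd.read_csv(path, sep="\t")
    required = {"label", "base_mass_da", "shift_da", "charges", "modified"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"species file missing columns: {sorted(missing)}")
    return frame


def quantify_scan(
    scan: ScanTable,
    species: pd.DataFrame,
    phi: float = 0.0,
    tol_ppm: float = 250.0,
) -> pd.DataFrame:
    """Occupancy of the modified variants listed in a species table.

    Intensities are extracted per charge state and aggregated by
    intensity weighting; when ``phi`` > 0 and exactly one variant
    carries a bare +15.9949 Da shift, the isobaric correction is also
    reported.
    """
    charges = sorted(
        {int(z) for cell in species["charges"] for z in str(cell).split(";")}
    )
    per_charge: dict[int, np.ndarray] = {}
    for z in charges:
        rows = species[
            species["charges"].astype(str).str.split(";").apply(lambda zs: str(z) in zs)
        ]
        targets = [
            mz_of(row.base_mass_da, [row.shift_da], z) for row in rows.itertuples()
        ]
        per_charge[z] = match_ions(scan, targets, tol_ppm)
    # variant order is the species row order restricted to each charge
    modified_idx = [
        k
        for k, row in enumerate(species.itertuples())
        if int(row.modified) == 1
    ]
    pooled = np.zeros(len(species))
    for z, intens in per_charge.items():
        rows = [
            k
            for k, row in enumerate(species.itertuples())
            if str(z) in str(row.charges).split(";")
        ]
        for slot, k in enumerate(rows):
            pooled[k] += intens[slot]
    est = occupancy(pooled, modified_idx)
    records = [
        {
            "quantity": "occupancy_percent",
            "value": est.percent,
            "phi": 0.0,
            "defined": est.defined,
        }
    ]
    plus16 = [
        k
        for k, row in enumerate(species.itertuples())
        if abs(row.shift_da - OXYGEN_SHIFT_DA) < 1e-6
    ]
    if phi > 0 and len(plus16) == 1:
        unmod = [
            k for k, row in enumerate(species.itertuples()) if row.shift_da == 0.0
        ]
        corrected = isobaric_correction(
            pooled[unmod].sum() if unmod else 0.0, pooled[plus16[0]], phi
        )
        records.append(
            {
                "quantity": "corrected_3hyp_percent",
                "value": corrected.percent,
                "phi": phi,
                "defined": corrected.defined,
            }
        )
    return pd.DataFrame(records)
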