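"""MIRD-formalism organ dosimetry.

The MIRD schema factorizes the absorbed dose to a target region as
D(target) = A_tilde * S(target <- source), where A_tilde is the
cumulated activity (MBq*s) in the source region and the S-value is the
mean absorbed dose to the target per unit cumulated activity
(mGy/MBq*s).  Here S-values are obtained from voxel dose maps: the
mass-weighted mean target dose per simulated decay, scaled to one MBq*s
(10^6 decays).  The equivalent dose applies the radiation weighting
factor w_R (1 for electrons), and the total dose for an administration
folds in the cumulated activity of the chosen convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import inf

import numpy as np
import pandas as pd

from .errors import EmptyOrganError, GridMismatchError, ValidationError
from .phantom import CRITICAL_ORGANS, VoxelPhantom, organ_mass
from .source import AdministrationSpec, cumulated_activity
from .transport import DepositionLedger, DoseMap, MEV_TO_J

DECAYS_PER_MBQ_S = 1.0e6


def _target_dose_stats(dosemap: DoseMap, phantom: VoxelPhantom, target: str):
    """Mass-weighted mean target dose (cGy) and its standard error."""
    if dosemap.grid != phantom.grid:
        raise GridMismatchError("dose map and phantom grids differ")
    mask = phantom.organ_voxels(target)
    if not np.any(mask):
        raise EmptyOrganError(f"target organ {target!r} has no voxels")
    m = phantom.densities[mask].astype(np.float64)  # proportional to voxel mass
    d = dosemap.dose_cgy[mask]
    w = m / m.sum()
    mean = float(np.sum(w * d))
    rel = dosemap.relative_uncertainty[mask].astype(np.float64)
    sem_vox = np.where(np.isnan(rel), 0.0, rel) * d
    sem = float(np.sqrt(np.sum((w * sem_vox) ** 2)))
    return mean, sem


def s_value(
    dosemap: DoseMap,
    phantom: VoxelPhantom,
    target: str,
    n_histories: int | None = None,
) -> tuple[float, float]:
    """S(target <- source) in mGy/MBq*s, with propagated uncertainty.

    ``dosemap`` must be the transport product of decays in the source
    organ; ``n_histories`` defaults to the map's own history count.

    Returns ``(s, sigma_s)``.
    """
    n = n_histories if n_histories is not None else dosemap.n_histories
    if n < 1:
        raise ValidationError("n_histories must be >= 1")
    mean_cgy, sem_cgy = _target_dose_stats(dosemap, phantom, target)
    scale = 10.0 * DECAYS_PER_MBQ_S / n  # cGy -> mGy, per decay -> per MBq*s
    return mean_cgy * scale, sem_cgy * scale


def absorbed_fraction(
    ledger: DepositionLedger,
    dosemap: DoseMap,
    phantom: VoxelPhantom,
    target: str,
) -> float:
    """phi = energy deposited in the target / energy emitted."""
    if ledger.emitted_mev <= 0:
        raise ValidationError("ledger records no emitted energy")
    mask = phantom.organ_voxels(target)
    if not np.any(mask):
        raise EmptyOrganError(f"target organ {target!r} has no voxels")
    vox_mass_kg = phantom.densities[mask].astype(np.float64) * phantom.grid.voxel_volume * 1e-3
    e_target_mev = float(np.sum(dosemap.dose_cgy[mask] / 100.0 * vox_mass_kg)) / MEV_TO_J
    return e_target_mev / ledger.emitted_mev


def total_dose(s_mgy_per_mbq_s: float, admin: AdministrationSpec) -> float:
    """Total absorbed dose in Gy: D = S * A_tilde (mGy -> Gy)."""
    if s_mgy_per_mbq_s < 0:
        raise ValidationError("S-value must be >= 0")
    return s_mgy_per_mbq_s * cumulated_activity(admin) * 1e-3


def equivalent_dose_rate(
    s_mgy_per_mbq_s: float, activity_mbq: float, w_r: float = 1.0
) -> float:
    """Equivalent-dose rate in mSv/s at the given instantaneous activity:
    rate = w_R * S * A.  For beta radiation w_R = 1 and the equivalent
    dose rate equals the absorbed dose rate numerically."""
    if activity_mbq < 0:
        raise ValidationError("activity must be >= 0")
    if s_mgy_per_mbq_s < 0:
        raise ValidationError("S-value must be >= 0")
    return w_r * s_mgy_per_mbq_s * activity_mbq


@dataclass
class SValueRecord:
    sex: str
    bmi: float
    source_organ: str
    s_values: dict[str, float]  # target organ -> mGy/MBq*s
    uncertainties: dict[str, float] = field(default_factory=dict)

    def dominance_ratio(self) -> float:
        """Self-S over the largest cross-organ S in the record; +inf when
        every cross-organ S-value is zero."""
        self_s = self.s_values.get(self.source_organ)
        if self_s is None:
            raise ValidationError("record lacks the self S-value")
        cross = [v for k, v in self.s_values.items() if k != self.source_organ]
        if not cross:
            raise ValidationError("record lacks cross-organ S-values")
        peak = max(cross)
        return inf if peak == 0 else self_s / peak


@dataclass
class SValueTable:
    """Per-phantom S-value records plus provenance, Table-style layout."""

    records: list[SValueRecord]
    engine: str = "mc"
    n_histories: int = 0
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {"sex": r.sex, "bmi": r.bmi, "source_organ": r.source_organ}
            row.update({t: r.s_values[t] for t in r.s_values})
            rows.append(row)
        return pd.DataFrame(rows)

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            for t, s in r.s_values.items():
                rows.append(
                    {
                        "sex": r.sex,
                        "bmi": r.bmi,
                        "source_organ": r.source_organ,
                        "target_organ": t,
                        "s_value_mgy_per_mbq_s": s,
                        "relative_uncertainty": (
                            r.uncertainties.get(t, np.nan) / s if s > 0 else np.nan
                        ),
                    }
                )
        return pd.DataFrame(rows)

    def min_dominance_ratio(self) -> float:
        return min(r.dominance_ratio() for r in self.records)


def dominance_ratio(record: SValueRecord) -> float:
    """Module-level alias for :meth:`SValueRecord.dominance_ratio`."""
    return record.dominance_ratio()


def svalues_from_dosemap(
    dosemap: DoseMap,
    phantom: VoxelPhantom,
    source_organ: str = "liver",
    targets: tuple[str, ...] = CRITICAL_ORGANS,
) -> SValueRecord:
    """Compute one phantom's S-value record for all target organs."""
    spec = phantom.spec
    values, sigmas = {}, {}
    for t in targets:
        s, sig = s_value(dosemap, phantom, t)
        values[t], sigmas[t] = s, sig
    return SValueRecord(
        sex=spec.sex if spec else "unknown",
        bmi=spec.bmi if spec else float("nan"),
        source_organ=source_organ,
        s_values=values,
        uncertainties=sigmas,
    )


@dataclass
class DoseReport:
    """Organ absorbed/equivalent doses for one phantom and administration."""

    sex: str
    bmi: float
    admin: AdministrationSpec
    absorbed_dose_gy: dict[str, float]
    equivalent_dose_sv: dict[str, float]
    dose_rate_msv_per_s: dict[str, float]
    w_r: float = 1.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for organ in self.absorbed_dose_gy:
            rows.append(
                {
                    "sex": self.sex,
                    "bmi": self.bmi,
                    "organ": organ,
                    "absorbed_dose_gy": self.absorbed_dose_gy[organ],
                    "equivalent_dose_sv": self.equivalent_dose_sv[organ],
                    "dose_rate_msv_per_s": self.dose_rate_msv_per_s[organ],
                }
            )
        return pd.DataFrame(rows)


def dose_report(
    record: SValueRecord,
    admin: AdministrationSpec,
    w_r: float = 1.0,
    reference_activity_mbq: float | None = None,
) -> DoseReport:
    """Fold an S-value record into organ doses for an administration.

    Dose rates are quoted at ``reference_activity_mbq`` (defaults to the
    administered activity).
    """
    ref_a = reference_activity_mbq if reference_activity_mbq is not None else admin.activity_mbq
    absorbed = {t: total_dose(s, admin) for t, s in record.s_values.items()}
    equivalent = {t: w_r * d for t, d in absorbed.items()}
    rates = {t: equivalent_dose_rate(s, ref_a, w_r) for t, s in record.s_values.items()}
    return DoseReport(
        sex=record.sex,
        bmi=record.bmi,
        admin=admin,
        absorbed_dose_gy=absorbed,
        equivalent_dose_sv=equivalent,
        dose_rate_msv_per_s=rates,
        w_r=w_r,
    )
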