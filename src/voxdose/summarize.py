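"""Human-readable rendering of dose reports."""

from __future__ import annotations

from .mird import DoseReport


def print_dose_reports(reports: list[DoseReport]) -> str:
    """Plain-text table of organ doses, one block per phantom."""
    if not reports:
        return "(empty dose report set)"
    lines = []
    admin = reports[0].admin
    lines.append(
        f"Administration: {admin.activity_mbq:g} MBq, "
        f"T_eff = {admin.effective_half_life_h:g} h, "
        f"convention = {admin.convention}"
    )
    for rep in reports:
        lines.append(f"\n{rep.sex} BMI {rep.bmi:g}")
        for organ, dose in rep.absorbed_dose_gy.items():
            rate = rep.dose_rate_msv_per_s[organ]
            lines.append(
                f"  {organ:<8s} {dose:10.4g} Gy   "
                f"{rep.equivalent_dose_sv[organ]:10.4g} Sv   "
                f"{rate:.3e} mSv/s"
            )
    return "\n".join(lines)
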