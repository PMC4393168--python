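"""Gray-level / attenuation / mineral-density calibration.

Two linear maps connect the three intensity domains:

* gray -> mu:      mu (/cm) = gray_to_mu_factor x gray level
* mu   -> d.HAp:   d.HAp (mg/cm^3) = 136 x mu (/cm) - 142

The mu-domain line and the bone-classification threshold (mu >= 4.74 /cm,
i.e. d.HAp ~ 500 mg/cm^3) come from a hydroxyapatite-phantom calibration of
17.9 keV scans and are treated as canonical constants. The gray->mu factor
is scanner scaling, not physics, and is therefore a configuration parameter;
the default 7.97/136 makes the gray-domain density line d.HAp = 7.97 x gray
- 142 exactly consistent with the mu-domain line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: gray->mu scaling that makes the two printed calibration forms consistent.
DEFAULT_GRAY_TO_MU = 7.97 / 136.0


@dataclass(frozen=True)
class CalibrationLine:
    """Affine attenuation-to-density calibration plus the bone threshold."""

    slope_mu_to_dhap: float = 136.0      # (mg/cm^3) per (/cm)
    intercept_dhap: float = -142.0       # mg/cm^3
    gray_to_mu_factor: float = DEFAULT_GRAY_TO_MU  # (/cm) per gray level
    bone_mu_threshold: float = 4.74      # /cm
    bone_dhap_threshold: float = 500.0   # mg/cm^3

    def __post_init__(self):
        if self.slope_mu_to_dhap <= 0:
            raise ValueError("calibration slope must be positive")
        if self.gray_to_mu_factor <= 0:
            raise ValueError("gray_to_mu_factor must be positive")
        # The printed constants must agree with each other: the mu threshold
        # evaluated on the density line must land on the density threshold.
        resid = abs(
            self.slope_mu_to_dhap * self.bone_mu_threshold
            + self.intercept_dhap
            - self.bone_dhap_threshold
        )
        if resid > 5.0:
            raise ValueError(
                f"inconsistent calibration constants: 136*mu_thr+intercept is "
                f"{resid:.1f} mg/cm^3 away from the density threshold"
            )

    @property
    def bone_gray_threshold(self) -> float:
        """Gray level corresponding to the bone attenuation threshold."""
        return self.bone_mu_threshold / self.gray_to_mu_factor


def gray_to_mu(gray, cal: CalibrationLine = CalibrationLine()):
    """Linear attenuation coefficient (/cm) from 8-bit gray levels."""
    gray = np.asarray(gray, dtype=float)
    if np.any(gray < -1e-6):
        raise ValueError("gray values must be non-negative")
    out = cal.gray_to_mu_factor * np.maximum(gray, 0.0)
    return float(out) if out.ndim == 0 else out


def mu_to_dhap(mu, cal: CalibrationLine = CalibrationLine()):
    """Hydroxyapatite-equivalent density (mg/cm^3) from attenuation (/cm).

    Negative outputs are permitted: they simply mean attenuation below the
    mineralisation range of the calibration line.
    """
    mu = np.asarray(mu, dtype=float)
    out = cal.slope_mu_to_dhap * mu + cal.intercept_dhap
    return float(out) if out.ndim == 0 else out


def dhap_to_mu(dhap, cal: CalibrationLine = CalibrationLine()):
    """Inverse of :func:`mu_to_dhap`."""
    dhap = np.asarray(dhap, dtype=float)
    out = (dhap - cal.intercept_dhap) / cal.slope_mu_to_dhap
    return float(out) if out.ndim == 0 else out
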