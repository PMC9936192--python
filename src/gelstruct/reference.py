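"""Published reference parameter sets for acellular type-I collagen gels.

Fibre-aggregate model parameters reported for 2 and 3 mg/mL collagen gels
imaged by confocal fluorescence (CFM) and reflectance (CRM) microscopy,
fitted either from the covariance of segmented (binary) images or from the
correlation function and histogram of the grey-tone images.  ``phi_1`` is
the reported total fibre density, to be compared with the product
``phi_F * phi_A`` of the two-scale model.

These rows serve as consistency anchors and as realistic operating points
for simulation-based validation; they are not recomputable from raw data,
which is unreleased.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["GelReferenceRow", "GEL_REFERENCE_TABLE"]


@dataclass(frozen=True)
class GelReferenceRow:
    imaging: str  # "CFM" or "CRM"
    processing: str  # "binary" or "greytone"
    concentration_mg_ml: float
    phi_F: float
    phi_A: float
    D_F_um: float
    L_A_um: float
    phi_1: float


GEL_REFERENCE_TABLE: tuple[GelReferenceRow, ...] = (
    GelReferenceRow("CFM", "binary", 2.0, 0.76, 0.72, 1.9, 8.2, 0.55),
    GelReferenceRow("CFM", "binary", 3.0, 0.76, 0.69, 1.5, 6.3, 0.52),
    GelReferenceRow("CFM", "greytone", 2.0, 0.73, 0.32, 1.9, 6.6, 0.23),
    GelReferenceRow("CFM", "greytone", 3.0, 0.78, 0.49, 2.3, 7.7, 0.38),
    GelReferenceRow("CRM", "binary", 2.0, 0.60, 0.88, 0.7, 15.0, 0.53),
    GelReferenceRow("CRM", "binary", 3.0, 0.67, 0.90, 0.90, 13.0, 0.61),
    GelReferenceRow("CRM", "greytone", 2.0, 0.78, 0.41, 0.98, 7.6, 0.32),
    GelReferenceRow("CRM", "greytone", 3.0, 0.61, 0.56, 0.62, 14.0, 0.34),
)

#: Imaging parameters and pristine-gel densities of the spheroid time-lapse
#: series (CRM, 2 mg/mL unlabelled collagen, ~0.59 µm/px).
SPHEROID_IMAGING = {"b": 9.0, "Delta": 15.0, "sigma": 5.0}
SPHEROID_STRUCTURE = {"phi_A": 0.6, "phi_F": 0.5, "D_F_um": 2.0, "L_A_um": 19.0}
SPHEROID_PIXEL_SIZE_UM = 0.59
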