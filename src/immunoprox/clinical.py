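"""Deterministic clinical scoring formulas: IHC H-score and ALBI grading.

H-score summarises staining intensity of an immunohistochemistry marker as a
weighted percentage over a 4-bin intensity classification (0, 1+, 2+, 3+):

    H = 1 * %weak + 2 * %moderate + 3 * %strong,      range 0–300.

The albumin–bilirubin (ALBI) score is a liver-function index,

    ALBI = 0.66 * log10(bilirubin [µmol/L]) − 0.085 * albumin [g/L],

graded at published cutoffs: grade 1 for scores <= −2.60, grade 2 up to
−1.39, grade 3 above.  The *modified* ALBI grading further splits grade 2
at −2.270 into 2a/2b.  The formula works in µmol/L and g/L; conventional
clinical units (mg/dL bilirubin, g/dL albumin) are converted in the
constructor (factors 17.1 and 10).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "StainBinSummary",
    "AlbiInput",
    "h_score",
    "albi_score",
    "albi_grade",
    "BILIRUBIN_MGDL_TO_UMOLL",
    "ALBUMIN_GDL_TO_GL",
]

#: 1 mg/dL total bilirubin = 17.1 µmol/L.
BILIRUBIN_MGDL_TO_UMOLL = 17.1
#: 1 g/dL albumin = 10 g/L.
ALBUMIN_GDL_TO_GL = 10.0

#: Published ALBI grade cutoffs (score scale).
ALBI_CUTOFF_1_2 = -2.60
ALBI_CUTOFF_2_3 = -1.39
#: Modified-grading split of grade 2 into 2a/2b.
ALBI_CUTOFF_2A_2B = -2.270


@dataclass(frozen=True)
class StainBinSummary:
    """Percentages of cells in the 1+/2+/3+ intensity bins (0 bin implicit)."""

    pct_weak: float
    pct_moderate: float
    pct_strong: float

    def __post_init__(self) -> None:
        for name, v in (
            ("pct_weak", self.pct_weak),
            ("pct_moderate", self.pct_moderate),
            ("pct_strong", self.pct_strong),
        ):
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name} must be in [0, 100], got {v}")
        total = self.pct_weak + self.pct_moderate + self.pct_strong
        if total > 100.0 + 1e-9:
            raise ValueError(
                f"intensity-bin percentages sum to {total} > 100"
            )


@dataclass(frozen=True)
class AlbiInput:
    """Bilirubin (µmol/L) and albumin (g/L) for the ALBI formula.

    Use :meth:`from_conventional` for mg/dL bilirubin and g/dL albumin.
    """

    bilirubin_umol_l: float
    albumin_g_l: float

    def __post_init__(self) -> None:
        if not (self.bilirubin_umol_l > 0):
            raise ValueError(
                f"bilirubin must be positive, got {self.bilirubin_umol_l}"
            )
        if not (self.albumin_g_l > 0):
            raise ValueError(f"albumin must be positive, got {self.albumin_g_l}")

    @classmethod
    def from_conventional(cls, bilirubin_mg_dl: float, albumin_g_dl: float
                          ) -> "AlbiInput":
        return cls(
            bilirubin_umol_l=bilirubin_mg_dl * BILIRUBIN_MGDL_TO_UMOLL,
            albumin_g_l=albumin_g_dl * ALBUMIN_GDL_TO_GL,
        )


def h_score(s: StainBinSummary) -> float:
    """Weighted intensity score 1*%weak + 2*%moderate + 3*%strong, in [0, 300]."""
    return 1.0 * s.pct_weak + 2.0 * s.pct_moderate + 3.0 * s.pct_strong


def albi_score(a: AlbiInput) -> float:
    """0.66 * log10(bilirubin µmol/L) − 0.085 * albumin g/L."""
    return 0.66 * math.log10(a.bilirubin_umol_l) - 0.085 * a.albumin_g_l


def albi_grade(score: float, modified: bool = True) -> str:
    """Map an ALBI score to its grade.

    With ``modified`` (default) grade 2 is split at −2.270: grades are
    ``"1"`` (score <= −2.60), ``"2a"`` (−2.60 < score <= −2.270), ``"2b"``
    (−2.270 < score <= −1.39), ``"3"`` (score > −1.39).  The −2.270 boundary
    itself belongs to 2a, mirroring the <= convention of the published
    boundaries.  Without ``modified``, returns ``"1"`` / ``"2"`` / ``"3"``.
    """
    if not math.isfinite(score):
        raise ValueError(f"ALBI score must be finite, got {score}")
    if score <= ALBI_CUTOFF_1_2:
        return "1"
    if score > ALBI_CUTOFF_2_3:
        return "3"
    if not modified:
        return "2"
    return "2a" if score <= ALBI_CUTOFF_2A_2B else "2b"
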