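"""Asymmetry curves and the characteristic-number feature vector.

For each of ``n_lines`` equally spaced splitting lines through the center
of mass (default 45, i.e. 4-degree steps over 180 degrees) the two halves
of the lesion are compared by the matching distance between their size
functions, one curve per measuring function.  Each distance-versus-angle
curve is condensed into 11 characteristic numbers; with six measuring
functions this gives 66 asymmetry features, to which three global
features (area, perimeter, bumpiness) are appended, for a feature vector
of length 69.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .imaging import (
    LesionSegmentation,
    bumpiness,
    luminance,
    remove_hairs,
    segment_lesion,
)
from .measuring import (
    MF_BASES,
    MF_ORDER,
    DegenerateHalfError,
    SplittingLine,
    boundary_mf,
    color_mf,
    joint_normalize,
    mass_mf,
    negate_mf,
)
from .sfcore import compute_size_function, matching_distance, prune_diagram

__all__ = [
    "AsymmetryCurve",
    "CHARACTERISTIC_NAMES",
    "asymmetry_curve",
    "asymmetry_curves",
    "characteristic_numbers",
    "build_feature_vector",
    "feature_names",
]

CHARACTERISTIC_NAMES = (
    "min",
    "max",
    "average",
    "min_plus_90",
    "integral",
    "first_moment",
    "variation",
    "min_derivative",
    "max_derivative",
    "integral_abs_derivative",
    "variation_abs_derivative",
)


@dataclass
class AsymmetryCurve:
    """Matching distance between lesion halves as a function of the
    splitting-line angle; cyclic with period pi."""

    mf_id: str
    angles: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.angles.shape != self.values.shape:
            raise ValueError("angles/values length mismatch")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("curve values must be finite and non-negative")


def _half_pair_distance(gp, gm, config: PipelineConfig) -> float:
    gp, gm = joint_normalize(gp, gm)
    dp = prune_diagram(compute_size_function(gp), config.min_persistence)
    dm = prune_diagram(compute_size_function(gm), config.min_persistence)
    return matching_distance(dp, dm, cornerline_penalty=config.cornerline_penalty)


def _base_pairs(img, gray, seg, line):
    return {
        "boundary": (boundary_mf(seg, line, +1), boundary_mf(seg, line, -1)),
        "mass": (mass_mf(gray, seg, line, +1), mass_mf(gray, seg, line, -1)),
        "color": (color_mf(img, seg, line, +1), color_mf(img, seg, line, -1)),
    }


def asymmetry_curves(
    img: np.ndarray,
    seg: LesionSegmentation,
    config: PipelineConfig | None = None,
    n_lines: int | None = None,
) -> dict:
    """All six asymmetry curves of one lesion, sharing per-line sampling.

    Degenerate halves (all boundary points on one side of the line, or an
    empty mask intersection) score the cornerline penalty: a split that
    cannot even be formed is maximal asymmetry evidence.
    """
    config = config or PipelineConfig()
    n = n_lines if n_lines is not None else config.n_lines
    if n < 4:
        raise ValueError("n_lines must be >= 4")
    gray = luminance(img)
    angles = np.array([k * math.pi / n for k in range(n)])
    values = {mf: np.empty(n) for mf in MF_ORDER}
    for k, ang in enumerate(angles):
        line = SplittingLine(angle=float(ang), center=seg.center)
        try:
            pairs = _base_pairs(img, gray, seg, line)
        except DegenerateHalfError:
            for mf in MF_ORDER:
                values[mf][k] = config.cornerline_penalty
            continue
        for base in MF_BASES:
            gp, gm = pairs[base]
            values[base][k] = _half_pair_distance(gp, gm, config)
            values[base + "_neg"][k] = _half_pair_distance(
                negate_mf(gp), negate_mf(gm), config
            )
    return {
        mf: AsymmetryCurve(mf_id=mf, angles=angles, values=values[mf])
        for mf in MF_ORDER
    }


def asymmetry_curve(
    seg: LesionSegmentation,
    img: np.ndarray,
    mf_id: str,
    n_lines: int = 45,
    config: PipelineConfig | None = None,
) -> AsymmetryCurve:
    """Single-measuring-function asymmetry curve (see ``asymmetry_curves``)."""
    if mf_id not in MF_ORDER:
        raise ValueError(f"unknown measuring function {mf_id!r}")
    return asymmetry_curves(img, seg, config=config, n_lines=n_lines)[mf_id]


def characteristic_numbers(curve) -> np.ndarray:
    """The 11 summary statistics of a cyclic distance-versus-angle curve.

    With n samples over a period of pi, step ``dth = pi/n``, cyclic
    forward differences ``d_k = (c_{k+1} - c_k)/dth``:

    1. min, 2. max, 3. average,
    4. min plus the value 90 degrees from the (first) argmin — with an
       odd n that lands between two samples, so their mean is used,
    5. integral ``dth * sum(c)``, 6. first moment ``dth * sum(theta * c)``,
    7. total variation ``sum |c_{k+1} - c_k|``,
    8. min derivative, 9. max derivative,
    10. integral of |derivative|, 11. total variation of |derivative|.
    """
    c = np.asarray(curve.values if hasattr(curve, "values") else curve, dtype=float)
    n = len(c)
    if n < 4:
        raise ValueError("curve must have at least 4 samples")
    dth = math.pi / n
    theta = np.arange(n) * dth
    d = (np.roll(c, -1) - c) / dth
    kstar = int(np.argmin(c))
    at90 = 0.5 * (c[(kstar + n // 2) % n] + c[(kstar + (n + 1) // 2) % n])
    absd = np.abs(d)
    return np.array(
        [
            c.min(),
            c.max(),
            c.mean(),
            c.min() + at90,
            dth * c.sum(),
            dth * (theta * c).sum(),
            np.abs(np.roll(c, -1) - c).sum(),
            d.min(),
            d.max(),
            dth * absd.sum(),
            np.abs(np.roll(absd, -1) - absd).sum(),
        ]
    )


def curves_to_frame(curves: dict):
    """Asymmetry curves as a DataFrame: one row per angle, one column per
    measuring function (plus the angle itself)."""
    import pandas as pd

    first = curves[MF_ORDER[0]]
    data = {"angle": first.angles}
    for mf in MF_ORDER:
        data[mf] = curves[mf].values
    return pd.DataFrame(data)


def feature_names() -> list:
    names = [f"{mf}__{stat}" for mf in MF_ORDER for stat in CHARACTERISTIC_NAMES]
    names += ["area", "perimeter", "bumpiness"]
    return names


def build_feature_vector(
    img: np.ndarray, config: PipelineConfig | None = None, return_details: bool = False
):
    """Full per-image pipeline: hair removal, segmentation, six asymmetry
    curves, 66 characteristic numbers plus (area, perimeter, bumpiness).

    Returns a length-69 float vector (and, optionally, a dict with the
    segmentation and curves).  Deterministic for fixed input and config.
    """
    config = config or PipelineConfig()
    work = (
        remove_hairs(img, config.hair_strel_length)
        if config.hair_removal_enabled
        else img
    )
    seg = segment_lesion(
        work,
        smooth_radius=config.smooth_radius,
        min_area=config.min_area,
        contour_sigma=config.contour_sigma,
    )
    curves = asymmetry_curves(work, seg, config=config)
    parts = [characteristic_numbers(curves[mf]) for mf in MF_ORDER]
    vec = np.concatenate(
        parts + [np.array([seg.area, seg.perimeter, bumpiness(seg)])]
    )
    if not np.all(np.isfinite(vec)):
        raise ValueError("non-finite feature encountered")
    if return_details:
        return vec, {"segmentation": seg, "curves": curves}
    return vec
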