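"""BCECF ratiometric cytoplasmic-pH quantification.

BCECF's 490/440 nm excitation ratio rises sigmoidally with pH. An in-situ
calibration — cells clamped to known pH with nigericin/valinomycin
potassium buffers across pH 4-10 — fixes the four parameters of

    R(pH) = r_min + (r_max - r_min) / (1 + 10^(hill * (pKa - pH)))

after which sample ratios invert to pH in closed form. Image handling is
the minimal reduction used for such measurements: maximum projection of
z-stacks, background subtraction, and mean intensities over user-supplied
regions of interest (cytoplasm ROIs additionally report the 490/440
ratio of means; phagosome ROIs report pHrodo intensity only, since
pHrodo is not calibrated to absolute pH).
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "CalibrationCurve",
    "CalibrationError",
    "RoiSummary",
    "sigmoid_ratio",
    "fit_calibration",
    "ratio_to_ph",
    "max_project",
    "subtract_background",
    "roi_means",
]


class CalibrationError(ValueError):
    """Raised when a calibration cannot be fitted or used."""


def sigmoid_ratio(ph, r_min: float, r_max: float, pka: float, hill: float):
    """Four-parameter sigmoid of the 490/440 ratio as a function of pH."""
    return r_min + (r_max - r_min) / (1.0 + 10.0 ** (hill * (pka - np.asarray(ph, float))))


@dataclasses.dataclass(frozen=True)
class CalibrationCurve:
    r_min: float
    r_max: float
    pka: float
    hill: float
    residual_sd: float
    converged: bool
    ph_range: tuple[float, float] = (4.0, 10.0)

    def __post_init__(self) -> None:
        if self.r_max <= self.r_min:
            raise CalibrationError("r_max must exceed r_min")
        if self.hill <= 0:
            raise CalibrationError("hill slope must be positive")

    def ratio(self, ph):
        return sigmoid_ratio(ph, self.r_min, self.r_max, self.pka, self.hill)


def fit_calibration(ph_values: Sequence[float], ratios: Sequence[float]) -> CalibrationCurve:
    """Nonlinear least-squares fit of the 4-parameter sigmoid.

    Requires >= 5 distinct pH points spanning >= 3 pH units and a
    monotone trend (Spearman |rho| >= 0.5); initialization takes r_min and
    r_max from the data extremes, the pKa from the half-maximum crossing,
    and tries hill slopes {0.5, 1, 2}, keeping the best fit.
    """
    ph = np.asarray(ph_values, dtype=float)
    r = np.asarray(ratios, dtype=float)
    if ph.shape != r.shape:
        raise CalibrationError("ph and ratio arrays must have matching shapes")
    distinct = np.unique(ph)
    if distinct.size < 5:
        raise CalibrationError(f"need >= 5 distinct pH points, got {distinct.size}")
    if distinct.max() - distinct.min() < 3.0:
        raise CalibrationError("calibration must span >= 3 pH units")
    rho = stats.spearmanr(ph, r).statistic
    if abs(rho) < 0.5:
        raise CalibrationError(
            f"calibration not sigmoidal: ratio is not monotone in pH (Spearman rho = {rho:.2f})"
        )

    r_lo, r_hi = float(r.min()), float(r.max())
    span = max(r_hi - r_lo, 1e-6)
    half = (r_lo + r_hi) / 2.0
    pka0 = float(ph[np.argmin(np.abs(r - half))])
    lo = [-np.inf, -np.inf, ph.min() - 2.0, 1e-3]
    hi = [np.inf, np.inf, ph.max() + 2.0, 20.0]

    best = None
    for hill0 in (0.5, 1.0, 2.0):
        p0 = [r_lo - 0.05 * span, r_hi + 0.05 * span, pka0, hill0]
        try:
            popt, _ = optimize.curve_fit(
                sigmoid_ratio, ph, r, p0=p0, bounds=(lo, hi), maxfev=20_000
            )
        except (RuntimeError, ValueError):
            continue
        resid = r - sigmoid_ratio(ph, *popt)
        sse = float(resid @ resid)
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None or best[1][1] <= best[1][0]:
        raise CalibrationError("calibration fit failed to converge")
    sse, popt = best
    dof = max(ph.size - 4, 1)
    return CalibrationCurve(
        r_min=float(popt[0]),
        r_max=float(popt[1]),
        pka=float(popt[2]),
        hill=float(popt[3]),
        residual_sd=float(np.sqrt(sse / dof)),
        converged=True,
        ph_range=(float(ph.min()), float(ph.max())),
    )


def ratio_to_ph(curve: CalibrationCurve, ratio) -> tuple[np.ndarray | float, np.ndarray | bool]:
    """Invert ratios to pH in closed form.

    pH = pKa - log10((r_max - r_min)/(ratio - r_min) - 1) / hill. Ratios at
    or beyond the asymptotes are clamped to the calibrated pH range and
    flagged. Returns (ph, out_of_range); scalars in, scalars out.
    """
    if not curve.converged:
        raise CalibrationError("calibration did not converge; refusing to invert")
    scalar = np.isscalar(ratio)
    r = np.atleast_1d(np.asarray(ratio, dtype=float))
    if (r <= 0).any():
        raise CalibrationError("ratios must be positive")
    lo, hi = curve.ph_range
    out_of_range = (r <= curve.r_min) | (r >= curve.r_max)
    inside = np.clip(r, np.nextafter(curve.r_min, np.inf), np.nextafter(curve.r_max, -np.inf))
    ph = curve.pka - np.log10((curve.r_max - curve.r_min) / (inside - curve.r_min) - 1.0) / curve.hill
    ph = np.where(r <= curve.r_min, lo, np.where(r >= curve.r_max, hi, np.clip(ph, lo, hi)))
    out_of_range = out_of_range | (ph <= lo) | (ph >= hi)
    if scalar:
        return float(ph[0]), bool(out_of_range[0])
    return ph, out_of_range


def max_project(zstack: np.ndarray) -> np.ndarray:
    """Per-pixel maximum over the z axis (axis 0) of a z-stack."""
    zstack = np.asarray(zstack)
    if zstack.ndim != 3 or zstack.shape[0] < 1:
        raise CalibrationError("z-stack must be a non-empty 3-D array (z, y, x)")
    return zstack.max(axis=0)


def subtract_background(image: np.ndarray, background=None) -> np.ndarray:
    """Subtract a scalar or per-pixel background, clamping at zero.

    The default background estimate is the median of the lowest-decile
    pixels, a robust stand-in for an empty-field measurement.
    """
    image = np.asarray(image, dtype=float)
    if background is None:
        decile = np.quantile(image, 0.1)
        background = float(np.median(image[image <= decile]))
    background = np.asarray(background, dtype=float)
    if background.ndim and background.shape != image.shape:
        raise CalibrationError(
            f"background shape {background.shape} does not match image {image.shape}"
        )
    return np.clip(image - background, 0.0, None)


@dataclasses.dataclass(frozen=True)
class RoiSummary:
    roi_id: str
    kind: str  # cytoplasm | phagosome
    channel_means: dict[str, float]
    ratio: float | None = None  # 490/440 of means; cytoplasm ROIs only
    phrodo: float | None = None  # pHrodo mean; phagosome ROIs only


def roi_means(
    channels: Mapping[str, np.ndarray],
    roi_masks: Mapping[str, np.ndarray],
    kinds: Mapping[str, str] | None = None,
    ratio_channels: tuple[str, str] = ("490", "440"),
) -> list[RoiSummary]:
    """Mean intensity per channel over each region of interest.

    Cytoplasm ROIs also report the ratio of the 490 and 440 channel means
    (the quantity the calibration curve inverts); phagosome ROIs report
    the mean of the 'phrodo' channel. Empty or out-of-bounds masks raise,
    naming the ROI.
    """
    kinds = kinds or {}
    shapes = {ch: np.asarray(img).shape for ch, img in channels.items()}
    out: list[RoiSummary] = []
    for roi_id, mask in roi_masks.items():
        mask = np.asarray(mask, dtype=bool)
        for ch, shape in shapes.items():
            if mask.shape != shape:
                raise CalibrationError(
                    f"ROI {roi_id!r}: mask shape {mask.shape} does not match "
                    f"channel {ch!r} shape {shape}"
                )
        if not mask.any():
            raise CalibrationError(f"ROI {roi_id!r}: empty mask")
        means = {
            ch: float(np.asarray(img, dtype=float)[mask].mean())
            for ch, img in channels.items()
        }
        kind = kinds.get(roi_id, "cytoplasm")
        ratio = None
        phrodo = None
        if kind == "cytoplasm":
            num, den = ratio_channels
            if num in means and den in means:
                if means[den] <= 0:
                    raise CalibrationError(
                        f"ROI {roi_id!r}: denominator channel {den!r} mean is not positive"
                    )
                ratio = means[num] / means[den]
        elif kind == "phagosome":
            phrodo = means.get("phrodo")
        out.append(RoiSummary(roi_id=roi_id, kind=kind, channel_means=means,
                              ratio=ratio, phrodo=phrodo))
    return out
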