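"""Gel-lane densitometry and the per-nucleotide dissociation model.

The single-cycle processivity assay produces one densitometry trace per gel
lane (5'-end-labeled primer, so intensity is proportional to molecule count).
The analysis chain implemented here:

1. rolling-ball background subtraction — grayscale opening of the 1-D trace
   with a semicircular structuring element of the given radius;
2. ladder calibration — ordinary least squares of log10(length) on pixel
   position, giving an invertible pixel <-> length mapping;
3. macroscopic processivity — the intensity-weighted median product length
   (50% crossing of the cumulative corrected intensity, with sub-pixel linear
   interpolation);
4. the dissociation model: with full-length product L and median m, the
   incomplete fraction is f = (L - m)/L; spreading it evenly over the L
   template positions gives a per-nucleotide dissociation probability
   p = f/L, a per-nucleotide processivity 1 - p, and a template length
   N50 = 0.5/p at which half of initiated extensions terminate early (the
   exact geometric-survival alternative ln 2 / (-ln(1-p)) is reported
   alongside).

Lane-level ratio statistics (full-length fraction, primer incorporation
efficiency) live here as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize, stats


@dataclass
class LaneProfile:
    """A 1-D densitometry trace of one gel lane."""

    intensities: np.ndarray
    pixel_pitch: float = 100.0  # micrometres per pixel
    label: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 1 or self.intensities.size < 2:
            raise ValueError("lane profile must be a 1-D vector of length >= 2")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("lane profile intensities must be finite")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be > 0")

    def __len__(self) -> int:
        return self.intensities.size


@dataclass
class LadderCalibration:
    """Log-linear mobility calibration: log10(length) = slope * pixel + intercept."""

    bands: tuple[tuple[float, float], ...]  # (length nt, pixel)
    slope: float
    intercept: float
    r_squared: float

    def pixel_to_length(self, pixel) -> np.ndarray | float:
        out = 10.0 ** (self.slope * np.asarray(pixel, dtype=float) + self.intercept)
        return float(out) if np.isscalar(pixel) else out

    def length_to_pixel(self, length) -> np.ndarray | float:
        out = (np.log10(np.asarray(length, dtype=float)) - self.intercept) / self.slope
        return float(out) if np.isscalar(length) else out


class CalibrationError(ValueError):
    pass


class UndefinedStatisticError(ValueError):
    pass


# ---------------------------------------------------------------------------
# background subtraction
# ---------------------------------------------------------------------------


def rolling_ball_background(profile: LaneProfile, radius_um: float = 100.0):
    """Rolling-ball background of a 1-D lane profile.

    The background is the upper envelope of a disc of the given radius rolled
    beneath the trace — grayscale opening with a semicircular structuring
    element of radius ``radius_um / pixel_pitch`` pixels (edge-extended
    borders).  Returns ``(background, corrected)`` LaneProfiles with
    ``background <= profile`` and ``corrected >= 0`` pointwise.
    """
    if radius_um < profile.pixel_pitch:
        raise ValueError(
            f"rolling-ball radius ({radius_um} um) must be >= pixel pitch "
            f"({profile.pixel_pitch} um)"
        )
    r_px = radius_um / profile.pixel_pitch
    half = int(math.floor(r_px))
    offsets = np.arange(-half, half + 1)
    structure = np.sqrt(np.maximum(r_px**2 - offsets.astype(float) ** 2, 0.0))
    bg = ndimage.grey_opening(
        profile.intensities, structure=structure, mode="nearest"
    )
    bg = np.minimum(bg, profile.intensities)  # clamp float round-off
    corrected = profile.intensities - bg
    return (
        LaneProfile(bg, profile.pixel_pitch, f"{profile.label}:background"),
        LaneProfile(corrected, profile.pixel_pitch, f"{profile.label}:corrected"),
    )


# ---------------------------------------------------------------------------
# ladder calibration
# ---------------------------------------------------------------------------


def fit_ladder_calibration(bands: Sequence[tuple[float, float]]) -> LadderCalibration:
    """OLS fit of log10(ladder length) against band pixel position."""
    bands = tuple((float(L), float(px)) for L, px in bands)
    if len(bands) < 2:
        raise CalibrationError("ladder calibration needs at least 2 bands")
    lengths = np.array([b[0] for b in bands])
    pixels = np.array([b[1] for b in bands])
    if np.any(lengths <= 0):
        raise CalibrationError("ladder lengths must be > 0")
    if np.unique(pixels).size < 2:
        raise CalibrationError("ladder bands must span >= 2 distinct pixels")
    fit = stats.linregress(pixels, np.log10(lengths))
    if fit.slope == 0:
        raise CalibrationError("degenerate ladder: fitted slope is zero")
    return LadderCalibration(bands, float(fit.slope), float(fit.intercept),
                             float(fit.rvalue**2))


def pixel_to_length(cal: LadderCalibration, pixel) -> float:
    """Map a (possibly fractional) pixel position to cDNA length in nt."""
    return cal.pixel_to_length(pixel)


# ---------------------------------------------------------------------------
# weighted median / macroscopic processivity
# ---------------------------------------------------------------------------


def weighted_median_pixel(weights: np.ndarray) -> float:
    """Sub-pixel position of the 50% crossing of cumulative intensity.

    Pixel ``i`` spans ``[i - 0.5, i + 0.5]`` with uniform density; the
    crossing is interpolated linearly within the crossing pixel.  When the
    half-mass point falls exactly on a pixel boundary followed by a
    zero-weight plateau, the plateau midpoint is returned.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        w = np.clip(w, 0.0, None)
    total = w.sum()
    if total <= 0:
        raise UndefinedStatisticError("zero total intensity in analysis region")
    half = total / 2.0
    cum = np.cumsum(w)
    i = int(np.searchsorted(cum, half))
    prev = cum[i - 1] if i > 0 else 0.0
    if cum[i] > half:
        # ordinary crossing strictly inside pixel i (w[i] > 0 here)
        return (i - 0.5) + (half - prev) / w[i]
    # cum[i] == half exactly: the crossing sits on the boundary i + 0.5,
    # possibly followed by a zero-weight plateau -> return its midpoint.
    j = i + 1
    while j < w.size and w[j] == 0:
        j += 1
    return ((i + 0.5) + (j - 0.5)) / 2.0


def macroscopic_processivity(
    corrected: LaneProfile,
    cal: LadderCalibration,
    region: tuple[int, int] | None = None,
) -> float:
    """Median product length (nt) of the corrected lane intensity.

    ``region`` is a half-open pixel interval restricting the analysis;
    intensity is treated as molecule-proportional (end-labeled primer).
    """
    w = corrected.intensities
    start = 0
    if region is not None:
        start, stop = region
        if not (0 <= start < stop <= w.size):
            raise ValueError(f"region {region} outside profile of length {w.size}")
        w = w[start:stop]
    px = start + weighted_median_pixel(w)
    return float(cal.pixel_to_length(px))


def full_length_fraction(
    corrected: LaneProfile,
    full_band_window: tuple[int, int],
    product_region: tuple[int, int],
) -> float:
    """Signal in the full-length band window over total product signal."""
    a, b = full_band_window
    c, d = product_region
    n = len(corrected)
    if not (0 <= c < d <= n) or not (0 <= a <= b <= n):
        raise ValueError("windows must lie within the profile")
    if not (c <= a and b <= d):
        raise ValueError("full_band_window must be contained in product_region")
    w = np.clip(corrected.intensities, 0.0, None)
    denom = w[c:d].sum()
    if denom <= 0:
        raise UndefinedStatisticError("zero total product intensity")
    return float(w[a:b].sum() / denom)


def primer_incorporation_efficiency(
    extended_signal: float, unextended_primer_signal: float
) -> float:
    """Extension products over total primer (extended + unincorporated)."""
    if extended_signal < 0 or unextended_primer_signal < 0:
        raise ValueError("signals must be >= 0")
    total = extended_signal + unextended_primer_signal
    if total == 0:
        raise UndefinedStatisticError("both signals are zero")
    return extended_signal / total


def fold_change(efficiency: float, reference_efficiency: float) -> float:
    """Ratio of a mutant's primer incorporation efficiency to a reference."""
    if reference_efficiency == 0:
        raise UndefinedStatisticError("reference efficiency is zero")
    return efficiency / reference_efficiency


# ---------------------------------------------------------------------------
# dissociation model
# ---------------------------------------------------------------------------


@dataclass
class ProcessivityEstimate:
    """The derived statistic chain of the uniform-dissociation model.

    For the worked chain L=622, m=616: incomplete fraction 0.965%, per-nt
    dissociation probability 1.55e-5, per-nt processivity 99.998%,
    N50 (uniform model) 32,240 nt.
    """

    full_length: float
    median_length: float
    incomplete_fraction: float
    p_dissoc: float
    per_nt_processivity: float      # 1 - p, as a fraction
    n50_uniform: float | None       # 0.5 / p (evenly-distributed model)
    n50_geometric: float | None     # ln 2 / (-ln(1 - p))
    full_length_fraction: float | None = None
    label: str = ""

    @property
    def per_nt_processivity_pct(self) -> float:
        return 100.0 * self.per_nt_processivity

    @property
    def completion_pct(self) -> float:
        """Percentage of initiated extensions that reached the template end."""
        return 100.0 * (1.0 - self.incomplete_fraction)

    def as_dict(self) -> dict:
        return {
            "full_length_nt": self.full_length,
            "median_nt": self.median_length,
            "incomplete_fraction": self.incomplete_fraction,
            "p_dissoc": self.p_dissoc,
            "processivity_pct": self.per_nt_processivity_pct,
            "n50_uniform_nt": self.n50_uniform,
            "n50_geometric_nt": self.n50_geometric,
            "full_length_fraction": self.full_length_fraction,
        }


def processivity_model(full_length: float, median_length: float) -> ProcessivityEstimate:
    """Per-nucleotide dissociation chain from (full length, median length).

    incomplete fraction f = (L - m)/L; spreading f evenly over the L template
    positions gives p = f/L per nucleotide; N50_uniform = 0.5/p is the
    template length at which half of initiated extensions terminate early.
    m == L gives p = 0 and undefined (None) N50s.
    """
    L, m = float(full_length), float(median_length)
    if not (0 < m <= L):
        raise ValueError(f"median must satisfy 0 < median <= full_length, got {m} vs {L}")
    f = (L - m) / L
    p = f / L
    if p > 0:
        n50_u = 0.5 / p
        n50_g = math.log(2.0) / -math.log1p(-p)
    else:
        n50_u = n50_g = None
    return ProcessivityEstimate(
        full_length=L,
        median_length=m,
        incomplete_fraction=f,
        p_dissoc=p,
        per_nt_processivity=1.0 - p,
        n50_uniform=n50_u,
        n50_geometric=n50_g,
    )


# ---------------------------------------------------------------------------
# replicate aggregation
# ---------------------------------------------------------------------------


@dataclass
class ReplicateSummary:
    """Mean and sample standard deviation of each statistic over replicates."""

    n: int
    mean: dict[str, float]
    sd: dict[str, float] | None  # None when n == 1

    def as_frame(self):
        import pandas as pd

        rows = {"mean": self.mean}
        if self.sd is not None:
            rows["sd"] = self.sd
        return pd.DataFrame(rows)


def aggregate_replicates(estimates: Sequence[ProcessivityEstimate]) -> ReplicateSummary:
    """Per-statistic mean and sample sd (n - 1 denominator) over replicates."""
    if not estimates:
        raise ValueError("need at least one replicate")
    keys = [
        "median_nt", "incomplete_fraction", "p_dissoc", "processivity_pct",
        "n50_uniform_nt", "n50_geometric_nt",
    ]
    table = {k: [] for k in keys}
    for est in estimates:
        d = est.as_dict()
        for k in keys:
            table[k].append(d[k])
    mean = {}
    sd = {} if len(estimates) >= 2 else None
    for k, vals in table.items():
        if any(v is None for v in vals):
            mean[k] = float("nan")
            if sd is not None:
                sd[k] = float("nan")
            continue
        arr = np.asarray(vals, dtype=float)
        mean[k] = float(arr.mean())
        if sd is not None:
            sd[k] = float(arr.std(ddof=1))
    return ReplicateSummary(len(estimates), mean, sd)


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------


class ProcessivityModel:
    """Densitometry analysis of one gel lane against a ladder calibration.

    Parameters
    ----------
    lane:
        The raw lane profile (``LaneProfile`` or 1-D array).
    ladder_bands:
        Either a ``LadderCalibration`` or a sequence of (length nt, pixel)
        rows to fit one from.
    full_length:
        Expected full-length cDNA in nt (template minus primer offset).
    region:
        Optional half-open pixel interval restricting the product analysis.
    full_band_window:
        Pixel bounds of the full-length band, ``"auto"`` (Gaussian fitted to
        the terminal band, median +/- 3 sigma), or ``None`` to skip the
        full-length fraction.
    radius_um:
        Rolling-ball radius in micrometres.  Must be at least the pixel
        pitch; for a clean separation of background from bands it should be
        well above the band width.
    """

    def __init__(
        self,
        lane,
        ladder_bands,
        full_length: float,
        *,
        region: tuple[int, int] | None = None,
        full_band_window="auto",
        radius_um: float = 100.0,
        pixel_pitch: float = 100.0,
        label: str = "",
    ) -> None:
        self.lane = lane if isinstance(lane, LaneProfile) else LaneProfile(
            lane, pixel_pitch=pixel_pitch, label=label
        )
        if isinstance(ladder_bands, LadderCalibration):
            self.calibration = ladder_bands
        else:
            self.calibration = fit_ladder_calibration(ladder_bands)
        self.full_length = float(full_length)
        self.region = region
        self.full_band_window = full_band_window
        self.radius_um = float(radius_um)
        self.label = label

    @classmethod
    def from_files(cls, lane_path, ladder_path, full_length, **kwargs):
        from .io import read_ladder_table, read_lane_profile

        lane = read_lane_profile(lane_path)
        bands = read_ladder_table(ladder_path)
        return cls(lane, bands, full_length, **kwargs)

    def _auto_full_band_window(self, corrected: LaneProfile) -> tuple[int, int]:
        """Median +/- 3 sigma of a Gaussian fitted to the terminal band."""
        center = self.calibration.length_to_pixel(self.full_length)
        n = len(corrected)
        lo = max(0, int(center - 25))
        hi = min(n, int(center + 25) + 1)
        x = np.arange(lo, hi, dtype=float)
        y = corrected.intensities[lo:hi]

        def gauss(x, a, mu, sigma):
            return a * np.exp(-0.5 * ((x - mu) / sigma) ** 2)

        try:
            popt, _ = optimize.curve_fit(
                gauss, x, y,
                p0=[max(y.max(), 1e-9), center, 2.0],
                maxfev=2000,
            )
            mu, sigma = popt[1], abs(popt[2])
            if not (lo <= mu <= hi) or sigma <= 0 or sigma > (hi - lo):
                raise RuntimeError("implausible band fit")
        except (RuntimeError, ValueError):
            mu, sigma = center, 1.0
        a = max(0, int(math.floor(mu - 3 * sigma)))
        b = min(n, int(math.ceil(mu + 3 * sigma)) + 1)
        return a, b

    def fit(self) -> "ProcessivityResults":
        background, corrected = rolling_ball_background(self.lane, self.radius_um)
        median_nt = macroscopic_processivity(corrected, self.calibration, self.region)
        # calibration noise can push the measured median slightly past the
        # expected full length; the model chain clamps, the raw value is kept
        estimate = processivity_model(
            self.full_length, min(median_nt, self.full_length)
        )
        estimate.median_length = median_nt
        flf = None
        window = self.full_band_window
        if window == "auto":
            window = self._auto_full_band_window(corrected)
        if window is not None:
            region = self.region if self.region is not None else (0, len(corrected))
            a = max(window[0], region[0])
            b = min(window[1], region[1])
            flf = full_length_fraction(corrected, (a, b), region)
            estimate.full_length_fraction = flf
        estimate.label = self.label
        return ProcessivityResults(
            model=self,
            estimate=estimate,
            background=background,
            corrected=corrected,
            full_band_window=window,
        )


@dataclass
class ProcessivityResults:
    """Fitted densitometry results for one lane."""

    model: ProcessivityModel
    estimate: ProcessivityEstimate
    background: LaneProfile
    corrected: LaneProfile
    full_band_window: tuple[int, int] | None

    @property
    def median_nt(self) -> float:
        return self.estimate.median_length

    @property
    def calibration(self) -> LadderCalibration:
        return self.model.calibration

    def as_dict(self) -> dict:
        d = self.estimate.as_dict()
        d["calibration_r_squared"] = self.calibration.r_squared
        return d

    def summary(self) -> str:
        e = self.estimate
        lines = [
            "Single-cycle processivity analysis",
            "=" * 44,
            f"lane                      {self.model.label or '-'}",
            f"ladder fit R^2            {self.calibration.r_squared:.6f}",
            f"full-length cDNA (nt)     {e.full_length:.0f}",
            f"median product (nt)       {e.median_length:.1f}",
            f"incomplete fraction       {100 * e.incomplete_fraction:.3f}%",
            f"per-nt dissociation p     {e.p_dissoc:.3g}",
            f"per-nt processivity       {e.per_nt_processivity_pct:.3f}%",
        ]
        if e.n50_uniform is not None:
            lines.append(f"N50, uniform model (nt)   {e.n50_uniform:,.0f}")
            lines.append(f"N50, geometric (nt)       {e.n50_geometric:,.0f}")
        else:
            lines.append("N50                       undefined (p = 0)")
        if e.full_length_fraction is not None:
            lines.append(f"full-length fraction      {e.full_length_fraction:.3f}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot raw profile, background and corrected signal with the median."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        raw = self.model.lane.intensities
        ax.plot(raw, label="raw", lw=0.8, color="0.4")
        ax.plot(self.background.intensities, label="background", lw=0.8, ls="--")
        ax.plot(self.corrected.intensities, label="corrected", lw=1.0)
        med_px = self.calibration.length_to_pixel(self.estimate.median_length)
        ax.axvline(med_px, color="crimson", lw=1.0,
                   label=f"median = {self.estimate.median_length:.0f} nt")
        ax.set_xlabel("pixel")
        ax.set_ylabel("intensity")
        ax.legend(frameon=False, fontsize=8)
        return ax
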