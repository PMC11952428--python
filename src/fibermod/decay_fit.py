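"""Exponential-decay fits to the nucleosome-phased peaks flanking a site.

The aggregate 6mA profile around a bound motif oscillates with the
nucleosome repeat length; the heights of the methylation peaks in the
flanking linkers fall off roughly exponentially with distance from the
motif.  Fitting ``height = a * exp(-lam * d) + c`` to those peak heights
summarizes labeling efficiency (amplitude ``a``, the extrapolated value at
distance 0) and spatial constraint of the tethered enzyme (decay constant
``lam`` per bp; a larger ``lam`` means a tighter methylation distribution).
An optional nonnegative baseline ``c`` absorbs accessibility background so
it does not bias ``lam``; ``baseline=False`` gives the strict two-parameter
form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .profile_agg import AggregateProfile


class FitInfeasibleError(ValueError):
    """Too few usable peaks to attempt a decay fit."""


class FitFailedError(RuntimeError):
    """Nonlinear least squares did not converge; carries diagnostics."""


@dataclass
class PeakSet:
    """Flanking methylation peaks as (distance from center, height)."""

    d: np.ndarray  # bp distance >= 0
    height: np.ndarray  # methylated-fraction units
    flank: np.ndarray  # 'left' or 'right'

    def __len__(self) -> int:
        return self.d.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"d": self.d, "height": self.height,
                             "flank": self.flank})


@dataclass
class DecayFit:
    """Fitted exponential-decay parameters with curvature standard errors."""

    a: float
    lam: float
    c: float
    se_a: float
    se_lam: float
    se_c: float
    n_peaks: int
    rss: float
    degenerate: bool = False  # constant-height branch (a ~ 0)

    def predict(self, d):
        return self.a * np.exp(-self.lam * np.asarray(d, float)) + self.c

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "a": self.a, "lam": self.lam, "c": self.c, "se_a": self.se_a,
            "se_lam": self.se_lam, "se_c": self.se_c, "n_peaks": self.n_peaks,
            "rss": self.rss, "degenerate": self.degenerate,
        }])


def find_flank_peaks(profile: AggregateProfile, min_separation: int = 120,
                     exclude_halfwidth: int = 60,
                     max_offset: int = 1000) -> PeakSet:
    """Locate local maxima of a smoothed profile on both flanks of the site.

    Candidates are offsets strictly greater than both neighbors, outside the
    central exclusion zone and within ``max_offset``; they are accepted
    greedily in descending height subject to a mutual distance of at least
    ``min_separation`` bp (per flank).  Distances are folded to d = |offset|.
    """
    if profile.smoothing_window < 20:
        raise ValueError("find_flank_peaks expects a profile smoothed with "
                         "window >= 20 bp")
    f = profile.frac
    offs = profile.offsets
    finite = np.isfinite(f)
    cand = np.zeros(f.size, dtype=bool)
    cand[1:-1] = (finite[1:-1] & finite[:-2] & finite[2:]
                  & (f[1:-1] > f[:-2]) & (f[1:-1] > f[2:]))
    cand &= (np.abs(offs) >= exclude_halfwidth) & (np.abs(offs) <= max_offset)

    sel_d, sel_h, sel_flank = [], [], []
    for sign, name in ((1, "right"), (-1, "left")):
        side = cand & (np.sign(offs) == sign)
        idx = np.where(side)[0]
        idx = idx[np.argsort(f[idx])[::-1]]  # descending height
        taken: list[int] = []
        for i in idx:
            if all(abs(int(offs[i]) - t) >= min_separation for t in taken):
                taken.append(int(offs[i]))
                sel_d.append(abs(int(offs[i])))
                sel_h.append(float(f[i]))
                sel_flank.append(name)
    if len(sel_d) < 3:
        raise FitInfeasibleError(
            f"only {len(sel_d)} flanking peak(s) found; need >= 3 for a fit")
    order = np.argsort(sel_d)
    return PeakSet(d=np.asarray(sel_d, float)[order],
                   height=np.asarray(sel_h, float)[order],
                   flank=np.asarray(sel_flank)[order])


def period_averaged_heights(profile: AggregateProfile, peaks: PeakSet,
                            window: int) -> PeakSet:
    """Re-measure peak heights as the mean profile over ``window`` bp
    centered on each detected peak.

    Nucleosome positional jitter flattens the oscillation at large distances
    but conserves the accessible mass within each repeat, so heights averaged
    over one repeat length decay with the true envelope constant while point
    heights overestimate it.  Detection is typically done on a smoothed
    profile and re-measurement on the raw one.  The amplitude scale changes
    by roughly the linker fraction of the repeat.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    heights = []
    for d, flank in zip(peaks.d, peaks.flank):
        o = int(d) if flank == "right" else -int(d)
        mask = np.abs(profile.offsets - o) <= window // 2
        if not mask.any() or not np.isfinite(profile.frac[mask]).any():
            raise ValueError(f"peak at offset {o} has no profile support "
                             f"within ±{window // 2} bp")
        heights.append(float(np.nanmean(profile.frac[mask])))
    return PeakSet(d=peaks.d.copy(), height=np.asarray(heights),
                   flank=peaks.flank.copy())


def fit_decay(peaks: PeakSet, baseline: bool = True,
              max_restarts: int = 5) -> DecayFit:
    """Nonlinear least squares of ``a * exp(-lam * d) + c`` on pooled peaks.

    Parameters are bounded nonnegative.  Initialization: a = height range,
    c = min height, lam = ln(2)/500; bounded restarts perturb the starting
    point on failure.  Constant peak heights collapse to the degenerate
    branch a -> 0, c = height (flagged, not an error).
    """
    if len(peaks) < 3:
        raise FitInfeasibleError(f"need >= 3 peaks, got {len(peaks)}")
    d = peaks.d.astype(float)
    h = peaks.height.astype(float)

    hmin, hmax = float(h.min()), float(h.max())
    if np.ptp(h) < 1e-12:
        return DecayFit(a=0.0, lam=0.0, c=hmin, se_a=np.nan, se_lam=np.nan,
                        se_c=np.nan, n_peaks=len(peaks), rss=0.0,
                        degenerate=True)

    p0 = [max(hmax - hmin, 1e-6), np.log(2.0) / 500.0, max(hmin, 0.0)]
    if baseline:
        model = lambda x, a, lam, c: a * np.exp(-lam * x) + c  # noqa: E731
        bounds = ([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf])
        guess = p0
    else:
        model = lambda x, a, lam: a * np.exp(-lam * x)  # noqa: E731
        bounds = ([0.0, 0.0], [np.inf, np.inf])
        guess = p0[:2]

    rng = np.random.default_rng(0)
    last_err = None
    for attempt in range(max_restarts):
        try:
            popt, pcov = curve_fit(model, d, h, p0=guess, bounds=bounds,
                                   maxfev=20000)
            se = np.sqrt(np.maximum(np.diag(pcov), 0.0))
            resid = h - model(d, *popt)
            if baseline:
                a, lam, c = popt
                se_a, se_lam, se_c = se
            else:
                (a, lam), c = popt, 0.0
                (se_a, se_lam), se_c = se, 0.0
            return DecayFit(a=float(a), lam=float(lam), c=float(c),
                            se_a=float(se_a), se_lam=float(se_lam),
                            se_c=float(se_c), n_peaks=len(peaks),
                            rss=float(resid @ resid),
                            degenerate=bool(a < 1e-10))
        except RuntimeError as exc:
            last_err = exc
            guess = [g * rng.uniform(0.5, 2.0) for g in (p0 if baseline else p0[:2])]
    raise FitFailedError(
        f"decay fit failed after {max_restarts} restarts on {len(peaks)} "
        f"peaks (d range {d.min():.0f}-{d.max():.0f}): {last_err}")


def compare_fits(fit1: DecayFit, fit2: DecayFit):
    """Amplitude and decay-constant ratios of two fits, with first-order
    propagated uncertainties.  A larger lambda ratio means condition 1 labels
    with a tighter spatial distribution."""
    if fit2.a == 0.0 or fit2.lam == 0.0:
        raise ZeroDivisionError("reference fit has zero amplitude or decay "
                                "constant; ratios undefined")
    amp_ratio = fit1.a / fit2.a
    lam_ratio = fit1.lam / fit2.lam

    def rel(se, v):
        return (se / v) ** 2 if np.isfinite(se) and v != 0 else 0.0

    se_amp = abs(amp_ratio) * np.sqrt(rel(fit1.se_a, fit1.a) + rel(fit2.se_a, fit2.a))
    se_lam = abs(lam_ratio) * np.sqrt(rel(fit1.se_lam, fit1.lam)
                                      + rel(fit2.se_lam, fit2.lam))
    return {"amplitude_ratio": float(amp_ratio), "amplitude_ratio_se": float(se_amp),
            "lambda_ratio": float(lam_ratio), "lambda_ratio_se": float(se_lam)}
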