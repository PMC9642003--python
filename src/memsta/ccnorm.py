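"""Missing-wedge-aware cross-correlation cleaning.

The membrane dominates each subtomogram's cross-correlation with the
reference, and because of the missing wedge its signal depends on the view:
side views (latitude theta ~ 90 deg) correlate better than top/bottom views
(theta ~ 0), so bad particles at the equator can out-score real particles
at the poles and no single raw-CC threshold works.  The fix: per membrane
object, fit a polynomial to cc as a function of theta, subtract the fitted
trend, and re-centre at the object's mean CC.  On the adjusted scores a
single threshold separates real particles from junk at every latitude.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np

from .geometry import theta_of_matrices
from .particles import ParticleSet

__all__ = ["ThetaFit", "fit_cc_theta", "adjust_cc", "threshold_cc", "save_fits", "load_fits"]

GLOBAL_KEY = (-1, -1)  # pooled fallback fit


@dataclass
class ThetaFit:
    """Polynomial model of cc vs latitude angle for one membrane object.

    ``coefficients`` are in increasing-power order (numpy polynomial
    convention), theta in degrees.  ``pooled`` marks objects too small for
    their own fit, which received the global fit instead.
    """

    object_key: tuple[int, int]
    degree: int
    coefficients: np.ndarray
    cc_mean: float
    n_particles: int
    pooled: bool = False

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("non-finite polynomial coefficients")

    def predict(self, theta) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(theta, dtype=float), self.coefficients)


def _fit_poly(theta: np.ndarray, cc: np.ndarray, degree: int, trim: bool) -> np.ndarray:
    coeffs = np.polynomial.polynomial.polyfit(theta, cc, degree)
    if trim:
        # one robust pass: drop residuals beyond 3 MAD and refit
        resid = cc - np.polynomial.polynomial.polyval(theta, coeffs)
        mad = np.median(np.abs(resid - np.median(resid)))
        if mad > 0:
            keep = np.abs(resid - np.median(resid)) <= 3.0 * 1.4826 * mad
            if keep.sum() >= degree + 2:
                coeffs = np.polynomial.polynomial.polyfit(theta[keep], cc[keep], degree)
    return coeffs


def fit_cc_theta(
    pset: ParticleSet,
    degree: int = 3,
    min_per_object: int = 50,
    trim_outliers: bool = False,
) -> list[ThetaFit]:
    """Least-squares polynomial fits of cc on theta, one per membrane object.

    Objects with fewer than ``min_per_object`` particles cannot support a
    stable fit and receive the pooled global fit (flagged ``pooled``).  The
    global fit itself is always included under object_key (-1, -1).
    ``trim_outliers`` enables a single trimmed refit (drop residuals beyond
    3 scaled MADs), useful because the fit is computed in the presence of
    the very outliers it aims to expose.
    """
    if degree < 0:
        raise ValueError("degree must be >= 0")
    if len(pset) < degree + 2:
        raise ValueError(
            f"need at least degree+2 = {degree + 2} particles overall, have {len(pset)}"
        )
    theta = theta_of_matrices(pset.matrices)
    global_coeffs = _fit_poly(theta, pset.cc, degree, trim_outliers)
    fits = [
        ThetaFit(
            object_key=GLOBAL_KEY,
            degree=degree,
            coefficients=global_coeffs,
            cc_mean=float(pset.cc.mean()),
            n_particles=len(pset),
        )
    ]
    for key, idx in pset.groups():
        if len(idx) >= max(min_per_object, degree + 2):
            coeffs = _fit_poly(theta[idx], pset.cc[idx], degree, trim_outliers)
            pooled = False
        else:
            coeffs = global_coeffs
            pooled = True
        fits.append(
            ThetaFit(
                object_key=key,
                degree=degree,
                coefficients=coeffs,
                cc_mean=float(pset.cc[idx].mean()),
                n_particles=int(len(idx)),
                pooled=pooled,
            )
        )
    return fits


def adjust_cc(
    pset: ParticleSet, fits: list[ThetaFit], mode: str = "additive"
) -> ParticleSet:
    """Normalise cc across latitudes: cc_adj = cc - poly(theta) + cc_mean.

    The additive residual keeps within-theta spreads and rank order intact;
    a multiplicative variant (cc * cc_mean / poly(theta)) is available but
    is unstable where the fitted curve approaches zero.  Raw cc is left
    untouched.
    """
    if mode not in ("additive", "multiplicative"):
        raise ValueError("mode must be additive or multiplicative")
    by_key = {f.object_key: f for f in fits}
    theta = theta_of_matrices(pset.matrices)
    cc_adj = np.empty(len(pset))
    for key, idx in pset.groups():
        fit = by_key.get(key) or by_key.get(GLOBAL_KEY)
        if fit is None:
            raise ValueError(f"no CC/theta fit for object {key} and no pooled fallback")
        pred = fit.predict(theta[idx])
        if mode == "additive":
            cc_adj[idx] = pset.cc[idx] - pred + fit.cc_mean
        else:
            safe = np.where(np.abs(pred) < 1e-9, 1e-9, pred)
            cc_adj[idx] = pset.cc[idx] * fit.cc_mean / safe
    out = pset.copy()
    out.cc_adj = cc_adj
    out.log(f"adjust_cc: mode={mode}, {len(fits)} fits")
    return out


def threshold_cc(
    pset: ParticleSet,
    low: float = -np.inf,
    high: float = np.inf,
    use_adjusted: bool = True,
) -> ParticleSet:
    """Keep particles with low <= score <= high.

    ``use_adjusted`` thresholds cc_adj (requires :func:`adjust_cc` first);
    otherwise raw cc.  Per-object kept/removed counts go to the provenance
    log.
    """
    if low > high:
        raise ValueError("low threshold exceeds high threshold")
    if use_adjusted:
        if pset.cc_adj is None:
            raise ValueError("no adjusted scores present; run adjust_cc first")
        score = pset.cc_adj
    else:
        score = pset.cc
    keep = (score >= low) & (score <= high)
    out = pset.subset(keep)
    if len(out) == 0:
        warnings.warn("CC thresholding removed every particle", stacklevel=2)
    per_object = [
        f"({key[0]},{key[1]}): kept {int(keep[idx].sum())}/{len(idx)}"
        for key, idx in pset.groups()
    ]
    out.log(
        f"threshold_cc: [{low}, {high}] on {'cc_adj' if use_adjusted else 'cc'}; "
        + "; ".join(per_object)
    )
    return out


# -- fit (de)serialisation for the CLI --------------------------------------


def save_fits(fits: list[ThetaFit], path) -> None:
    payload = []
    for f in fits:
        d = asdict(f)
        d["object_key"] = list(f.object_key)
        d["coefficients"] = [float(c) for c in f.coefficients]
        payload.append(d)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_fits(path) -> list[ThetaFit]:
    with open(path) as fh:
        payload = json.load(fh)
    return [
        ThetaFit(
            object_key=tuple(d["object_key"]),
            degree=int(d["degree"]),
            coefficients=np.array(d["coefficients"]),
            cc_mean=float(d["cc_mean"]),
            n_particles=int(d["n_particles"]),
            pooled=bool(d.get("pooled", False)),
        )
        for d in payload
    ]
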