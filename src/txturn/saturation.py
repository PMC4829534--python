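"""Rarefaction curves and saturation model selection.

Two rarefaction axes probe whether transcriptome coverage of the common
genome is approaching a ceiling:

* taxa axis — cumulative union coverage as taxa are added in random orders
  (ongoing turnover between lineages keeps this curve growing);
* depth axis — union coverage as a fraction of the sequenced fragments is
  retained (within a fixed taxon set this saturates near the transcribed
  fraction).

Each mean curve is fitted with two competing models,

    logarithmic  y = a + b*ln(x)                       (ever increasing)
    asymptotic   y = A + (R0 - A)*exp(-exp(c)*x)       (saturating)

compared by BIC under a Gaussian likelihood; evidence strength is the
BIC-approximated Bayes factor exp(|dBIC|/2) with the conventional
Kass-Raftery support labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .presence import PresenceMatrix, binarize
from .windows import CommonGenomeMask, CountMatrix, normalize_by_subsampling

KASS_RAFTERY_BANDS = ((3.0, "not worth more than a bare mention"),
                      (20.0, "positive"),
                      (150.0, "strong"))
KASS_RAFTERY_TOP = "very strong"


@dataclass
class RarefactionCurve:
    """Mean/SD coverage as sampling units accumulate."""

    axis: str  # "taxa" or "depth"
    x: np.ndarray
    y_mean: np.ndarray
    y_sd: np.ndarray
    n_replicates: int
    replicates: np.ndarray | None = None  # n_replicates x len(x)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.x, "y_mean": self.y_mean,
                             "y_sd": self.y_sd,
                             "n": self.n_replicates})


def rarefy_taxa(presence: PresenceMatrix, n_orders: int = 100,
                seed: int = 0) -> RarefactionCurve:
    """Cumulative union coverage over random taxon addition orders.

    For each of ``n_orders`` random permutations of the taxa, record the
    fraction of masked windows present in at least one of the first k taxa,
    for k = 1..T.  The final point is the all-taxa union and is identical
    across orders.
    """
    if n_orders < 1:
        raise ValueError("n_orders must be >= 1")
    rng = np.random.default_rng(seed)
    V = presence.values.to_numpy(dtype=bool)
    n, T = V.shape
    if T < 2:
        raise ValueError("need >= 2 taxa to rarefy over taxa")
    curves = np.empty((n_orders, T))
    for o in range(n_orders):
        order = rng.permutation(T)
        seen = np.zeros(n, dtype=bool)
        for k, t in enumerate(order):
            seen |= V[:, t]
            curves[o, k] = seen.mean()
    return RarefactionCurve(
        axis="taxa", x=np.arange(1, T + 1, dtype=float),
        y_mean=curves.mean(axis=0), y_sd=curves.std(axis=0, ddof=0),
        n_replicates=n_orders, replicates=curves,
    )


def rarefy_depth(counts: CountMatrix, mask: CommonGenomeMask,
                 fractions=None, n_draws: int = 10, seed: int = 0,
                 tau: int = 1) -> RarefactionCurve:
    """Union coverage at decreasing fractions of retained fragments.

    Fragments are subsampled without replacement per sample (multivariate
    hypergeometric); coverage is the union across all taxa at threshold
    ``tau`` within the mask.  Fraction 1.0 reproduces the full-data
    coverage exactly with zero spread.
    """
    if fractions is None:
        fractions = np.round(np.arange(0.1, 1.01, 0.1), 10)
    fractions = np.asarray(sorted(fractions), dtype=float)
    if (fractions <= 0).any() or (fractions > 1).any():
        raise ValueError("fractions must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    totals = counts.counts.sum(axis=0)
    y = np.empty((len(fractions), n_draws))
    for fi, frac in enumerate(fractions):
        for d in range(n_draws):
            if frac == 1.0:
                sub = counts
            else:
                # per-sample targets: floor of fraction of that column total
                new = {}
                for s in counts.counts.columns:
                    target = int(np.floor(frac * totals[s]))
                    col = counts.counts[s].to_numpy()
                    new[s] = rng.multivariate_hypergeometric(col, target)
                sub = CountMatrix(
                    counts=pd.DataFrame(new, index=counts.counts.index),
                    samples=counts.samples.copy(),
                )
            pm = binarize(sub, tau=tau, mask=mask)
            y[fi, d] = float((pm.values.sum(axis=1) > 0).mean())
    y_sd = y.std(axis=1, ddof=0)
    y_sd[np.ptp(y, axis=1) == 0] = 0.0  # identical draws: exactly zero spread
    return RarefactionCurve(
        axis="depth", x=fractions, y_mean=y.mean(axis=1),
        y_sd=y_sd, n_replicates=n_draws, replicates=y.T,
    )


def _gaussian_bic(resid: np.ndarray, n_params: int) -> tuple:
    """(loglik, BIC) for a least-squares fit; the error SD counts as a
    parameter, matching the usual regression BIC."""
    n = len(resid)
    rss = float(resid @ resid)
    sigma2 = max(rss / n, 1e-300)
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    k = n_params + 1
    return loglik, k * np.log(n) - 2.0 * loglik


def support_label(bf: float) -> str:
    for bound, label in KASS_RAFTERY_BANDS:
        if bf <= bound:
            return label
    return KASS_RAFTERY_TOP


class SaturationModel:
    """Competing saturation models for a rarefaction curve.

    Fits the logarithmic model by ordinary least squares and the
    asymptotic (negative-exponential) model by nonlinear least squares
    with a self-start:

        A0 = max(y) + 0.05 * range(y),  R0_0 = min(y),  c0 = ln(1/median(x)),

    followed by up to 20 jittered restarts if the optimizer fails.

    Parameters
    ----------
    x, y : array-like
        Curve points (at least 4, since the asymptotic model has three
        parameters).
    weights : array-like, optional
        Inverse-variance weights (e.g. from replicate SDs); unweighted by
        default, which fits the mean curve directly.
    """

    def __init__(self, x, y, weights=None):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.x.ndim != 1 or self.x.shape != self.y.shape:
            raise ValueError("x and y must be 1-D and the same length")
        if len(self.x) < 4:
            raise ValueError("need >= 4 curve points to compare the models")
        if (self.x <= 0).any():
            raise ValueError("x must be positive (logarithmic model)")
        self.weights = None if weights is None else np.asarray(weights, float)

    @classmethod
    def from_curve(cls, curve: RarefactionCurve, weighted: bool = False,
                   per_replicate: bool = False) -> "SaturationModel":
        """Means mode (default) fits the summarized curve; per-replicate
        mode stacks every replicate's points, which keeps the model choice
        from being driven by the correlated Monte-Carlo error of the mean
        curve when replicates are few."""
        if per_replicate:
            if curve.replicates is None:
                raise ValueError("curve carries no replicate-level points")
            reps = np.asarray(curve.replicates, dtype=float)
            x = np.tile(curve.x, reps.shape[0])
            return cls(x, reps.ravel())
        w = None
        if weighted:
            sd = np.where(curve.y_sd > 0, curve.y_sd, np.nan)
            w = 1.0 / np.square(np.where(np.isnan(sd), np.nanmax(sd), sd))
        return cls(curve.x, curve.y_mean, weights=w)

    @staticmethod
    def asymptotic(x, A, R0, c):
        return A + (R0 - A) * np.exp(-np.exp(c) * x)

    def _fit_logarithmic(self) -> dict:
        X = np.column_stack([np.ones_like(self.x), np.log(self.x)])
        if self.weights is not None:
            wsq = np.sqrt(self.weights)
            coef, *_ = np.linalg.lstsq(X * wsq[:, None], self.y * wsq, rcond=None)
        else:
            coef, *_ = np.linalg.lstsq(X, self.y, rcond=None)
        pred = X @ coef
        loglik, bic = _gaussian_bic(self.y - pred, n_params=2)
        return {"params": {"a": coef[0], "b": coef[1]},
                "loglik": loglik, "bic": bic, "predict":
                lambda xx, c=coef: c[0] + c[1] * np.log(np.asarray(xx, float))}

    def _fit_asymptotic(self, n_restarts: int = 20, seed: int = 0) -> dict | None:
        y, x = self.y, self.x
        rng = np.random.default_rng(seed)
        span = max(y.max() - y.min(), 1e-6)
        p0 = np.array([y.max() + 0.05 * span, y.min(),
                       np.log(1.0 / np.median(x))])
        sigma = None
        if self.weights is not None:
            sigma = 1.0 / np.sqrt(self.weights)
        for attempt in range(n_restarts + 1):
            start = p0 if attempt == 0 else p0 * (1 + 0.3 * rng.standard_normal(3))
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, pcov = curve_fit(self.asymptotic, x, y, p0=start,
                                           sigma=sigma, maxfev=10000)
                pred = self.asymptotic(x, *popt)
                if not np.isfinite(pred).all():
                    continue
                loglik, bic = _gaussian_bic(y - pred, n_params=3)
                with np.errstate(invalid="ignore"):
                    se = np.sqrt(np.diag(pcov))
                return {"params": {"A": popt[0], "R0": popt[1], "c": popt[2]},
                        "stderr": {"A": se[0], "R0": se[1], "c": se[2]},
                        "loglik": loglik, "bic": bic,
                        "predict": lambda xx, p=popt: self.asymptotic(
                            np.asarray(xx, float), *p)}
            except (RuntimeError, ValueError):
                continue
        return None

    def fit(self) -> "SaturationResults":
        log_fit = self._fit_logarithmic()
        asym_fit = self._fit_asymptotic()
        converged = asym_fit is not None
        if not converged:
            warnings.warn(
                "asymptotic model failed to converge after restarts; "
                "logarithmic wins by default", RuntimeWarning, stacklevel=2)
            winner = "logarithmic"
            delta_bic = np.nan
            bf = np.nan
        else:
            delta_bic = asym_fit["bic"] - log_fit["bic"]
            winner = "logarithmic" if log_fit["bic"] <= asym_fit["bic"] \
                else "asymptotic"
            bf = float(np.exp(min(abs(delta_bic) / 2.0, 700)))
        return SaturationResults(self, log_fit, asym_fit, winner=winner,
                                 delta_bic=delta_bic, bayes_factor=bf,
                                 asymptotic_converged=converged)


@dataclass
class SaturationResults:
    """Fitted saturation comparison.

    Attributes of note: ``winner`` (model with the minimum BIC),
    ``bayes_factor`` = exp(|dBIC|/2), ``support`` (Kass-Raftery label),
    ``asymptote`` (estimated ceiling when the asymptotic model wins),
    ``doubled_prediction`` (winner's extrapolation at twice the current
    sampling).
    """

    model: SaturationModel
    logarithmic: dict
    asymptotic: dict | None
    winner: str
    delta_bic: float
    bayes_factor: float
    asymptotic_converged: bool = True
    notes: list = field(default_factory=list)

    @property
    def support(self) -> str:
        if not np.isfinite(self.bayes_factor):
            return "asymptotic fit failed"
        return support_label(self.bayes_factor)

    @property
    def asymptote(self) -> float | None:
        if self.asymptotic is None:
            return None
        return float(self.asymptotic["params"]["A"])

    @property
    def asymptote_plausible(self) -> bool | None:
        a = self.asymptote
        if a is None:
            return None
        return 0.0 < a <= 1.0

    @property
    def doubled_prediction(self) -> float:
        xmax = self.model.x.max()
        best = self.logarithmic if self.winner == "logarithmic" else self.asymptotic
        return float(best["predict"](2.0 * xmax))

    def predict(self, x, which: str | None = None) -> np.ndarray:
        which = which or self.winner
        fit = self.logarithmic if which == "logarithmic" else self.asymptotic
        if fit is None:
            raise ValueError("asymptotic model did not converge")
        return np.asarray(fit["predict"](x), dtype=float)

    def to_dict(self) -> dict:
        d = {
            "winner": self.winner,
            "delta_bic": None if not np.isfinite(self.delta_bic) else float(self.delta_bic),
            "bayes_factor": None if not np.isfinite(self.bayes_factor) else float(self.bayes_factor),
            "support": self.support,
            "doubled_prediction": self.doubled_prediction,
            "asymptotic_converged": self.asymptotic_converged,
            "logarithmic": {"params": {k: float(v) for k, v in
                                       self.logarithmic["params"].items()},
                            "bic": float(self.logarithmic["bic"])},
        }
        if self.asymptotic is not None:
            d["asymptotic"] = {"params": {k: float(v) for k, v in
                                          self.asymptotic["params"].items()},
                               "bic": float(self.asymptotic["bic"]),
                               "asymptote_plausible": self.asymptote_plausible}
        return d

    def summary(self) -> str:
        lines = ["Saturation model comparison",
                 "=" * 40,
                 f"n points: {len(self.model.x)}",
                 (f"logarithmic : a={self.logarithmic['params']['a']:.4g} "
                  f"b={self.logarithmic['params']['b']:.4g} "
                  f"BIC={self.logarithmic['bic']:.2f}")]
        if self.asymptotic is not None:
            p = self.asymptotic["params"]
            lines.append(f"asymptotic  : A={p['A']:.4g} R0={p['R0']:.4g} "
                         f"c={p['c']:.4g} BIC={self.asymptotic['bic']:.2f}")
        else:
            lines.append("asymptotic  : DID NOT CONVERGE (flagged)")
        lines += [f"winner      : {self.winner}",
                  f"Bayes factor: {self.bayes_factor:.3g} ({self.support})",
                  f"prediction at doubled sampling: {self.doubled_prediction:.4f}"]
        if self.winner == "asymptotic" and self.asymptote is not None:
            flag = "" if self.asymptote_plausible else "  [outside (0,1]]"
            lines.append(f"estimated asymptote: {self.asymptote:.4f}{flag}")
        return "\n".join(lines)


def fit_saturation(curve: RarefactionCurve, weighted: bool = False,
                   per_replicate: bool = False) -> SaturationResults:
    """Fit both saturation models to a rarefaction curve and select by BIC."""
    res = SaturationModel.from_curve(curve, weighted=weighted,
                                     per_replicate=per_replicate).fit()
    res.notes.append(
        "depth-curve points above 50% retained reads share fragments and are "
        "not statistically independent; no correction applied")
    return res
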