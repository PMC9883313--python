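"""Empirical lagged identification rates and residence-time model fitting.

The lagged identification rate (LIR) at lag ``tau`` is the proportion, among
all pairs of identifications taken ``tau`` ordinal units apart *within the
same collection event*, of pairs that name the same individual.  Restricting
lags to within-event pairs is achieved conceptually by keying each ordinal as
``ordinal + event_index * offset`` with an offset exceeding the largest
within-event lag, so that cross-event pairs land beyond the maximum lag
considered; :func:`keyed_ordinal` exposes that construction, and
:func:`empirical_lir` realizes it by enumerating pairs event by event
(algebraically identical for any valid offset).

Fitting the emigration + re-immigration model ``R(T)`` (see
:mod:`probassoc.overlap`) to the empirical curve by maximum likelihood with
binomial loss — same-individual pair counts ``m(tau)`` treated as binomial
draws out of ``n(tau)`` with success probability ``R(tau)`` — yields the mean
residence time ``b``, whose integer rounding is the probabilistic association
threshold.

The fitting interface follows the Model/Results convention::

    model = ResidenceTimeModel.from_records(df)
    res = model.fit()
    res.summary()
    res.threshold.threshold   # the integer association threshold
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .overlap import (
    ResidenceModelParams,
    ThresholdResult,
    lir_model,
    threshold_from_residence,
)
from .records import records_to_frame

__all__ = [
    "LIRCurve",
    "keyed_ordinal",
    "default_offset",
    "empirical_lir",
    "ResidenceTimeModel",
    "ResidenceTimeResults",
    "fit_residence_model",
    "fit_by_subset",
]

# R(tau) is clipped into this open interval when evaluating the binomial
# log-likelihood; clipping at the upper end is flagged on the results.
_R_FLOOR = 1e-12
_R_CEIL = 1.0 - 1e-9


def default_offset(max_within_event_lag: float) -> int:
    """Smallest power of 10 strictly exceeding the largest within-event lag."""
    if max_within_event_lag < 0:
        raise ValueError("maximum lag must be non-negative")
    offset = 10
    while offset <= max_within_event_lag:
        offset *= 10
    return offset


def keyed_ordinal(ordinal: float, event_index: int, offset: float, *,
                  max_within_event_lag: float | None = None) -> float:
    """Composite ordinal ``ordinal + event_index * offset``.

    With ``offset`` greater than the largest within-event lag, any pair of
    identifications from different events has a composite lag exceeding that
    maximum and is excluded from the LIR.
    """
    if max_within_event_lag is not None and offset <= max_within_event_lag:
        raise ValueError(
            f"offset {offset} must exceed the maximum within-event lag "
            f"{max_within_event_lag}; smaller offsets create spurious cross-event lags"
        )
    return ordinal + event_index * offset


@dataclass
class LIRCurve:
    """Empirical lagged identification rate.

    Attributes
    ----------
    lags : ndarray
        Distinct lag values (or bin midpoints), strictly positive, ascending.
    same_count : ndarray
        m(tau): pairs of identifications tau apart naming the same individual.
    total_count : ndarray
        n(tau): all within-event identification pairs tau apart.
    max_lag : float
        Largest lag considered; defaults to the largest within-event lag in
        the data, which guarantees no cross-event pair can contribute.
    binned : bool
        Whether lags are bin midpoints rather than exact lag values.
    """

    lags: np.ndarray
    same_count: np.ndarray
    total_count: np.ndarray
    max_lag: float
    binned: bool = False

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.same_count = np.asarray(self.same_count, dtype=np.int64)
        self.total_count = np.asarray(self.total_count, dtype=np.int64)
        if not (len(self.lags) == len(self.same_count) == len(self.total_count)):
            raise ValueError("lags, same_count and total_count must align")
        if np.any(self.same_count > self.total_count) or np.any(self.same_count < 0):
            raise ValueError("require 0 <= m(tau) <= n(tau) at every lag")
        if np.any(self.lags <= 0) or np.any(self.lags > self.max_lag):
            raise ValueError("lags must lie in (0, max_lag]")

    @property
    def rate(self) -> np.ndarray:
        """m(tau) / n(tau); NaN where n(tau) = 0."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.total_count > 0,
                            self.same_count / self.total_count, np.nan)

    @property
    def n_pairs(self) -> int:
        return int(self.total_count.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "lag": self.lags, "m": self.same_count,
            "n": self.total_count, "rate": self.rate,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def rebin(self, edges: np.ndarray) -> "LIRCurve":
        """Aggregate counts into bins (edges ascending; lags assigned to
        (edges[i], edges[i+1]]); midpoints become the new lag values."""
        edges = np.asarray(edges, dtype=float)
        idx = np.searchsorted(edges, self.lags, side="left") - 1
        keep = (idx >= 0) & (idx < len(edges) - 1)
        m = np.bincount(idx[keep], weights=self.same_count[keep],
                        minlength=len(edges) - 1)
        n = np.bincount(idx[keep], weights=self.total_count[keep],
                        minlength=len(edges) - 1)
        mid = 0.5 * (edges[:-1] + edges[1:])
        nz = n > 0
        return LIRCurve(mid[nz], m[nz].astype(np.int64), n[nz].astype(np.int64),
                        max_lag=self.max_lag, binned=True)


def _event_pair_counts(ordinals: np.ndarray, individuals: np.ndarray,
                       max_lag: float | None):
    """All positive-lag unordered pairs within one event.

    Returns (lags, same_flags). Lag-0 pairs (same frame) carry no decay
    information and are excluded here; they still feed the same-frame
    association criterion elsewhere.
    """
    k = len(ordinals)
    if k < 2:
        return np.empty(0), np.empty(0, dtype=bool)
    iu, ju = np.triu_indices(k, k=1)
    lag = np.abs(ordinals[iu] - ordinals[ju])
    same = individuals[iu] == individuals[ju]
    mask = lag > 0
    if max_lag is not None:
        mask &= lag <= max_lag
    return lag[mask], same[mask]


def empirical_lir(records, max_lag: float | str = "auto",
                  bins: str | Sequence[float] | None = None,
                  n_bins: int = 30) -> LIRCurve:
    """Compute the empirical LIR curve from an identification-record stream.

    Parameters
    ----------
    records : DataFrame or iterable of IdentificationRecord
        The identification stream (columns ``individual``, ``event``,
        ``ordinal`` used).
    max_lag : float or "auto"
        Largest lag to consider.  "auto" uses the largest within-event lag
        present in the data, ensuring only within-event lags are counted and
        no incidental larger values confound the model fit.
    bins : None, "log", or sequence of bin edges
        None keeps unit (exact-lag) resolution; "log" aggregates into
        ``n_bins`` log-spaced bins for sparse data.
    """
    df = records_to_frame(records)
    lag_chunks, same_chunks = [], []
    hard_max = None if max_lag == "auto" else float(max_lag)
    if hard_max is not None and hard_max < 1:
        raise ValueError("max_lag must be >= 1")
    for _, g in df.groupby("event", sort=False):
        lags, same = _event_pair_counts(
            g["ordinal"].to_numpy(dtype=float),
            g["individual"].to_numpy(), hard_max)
        if len(lags):
            lag_chunks.append(lags)
            same_chunks.append(same)
    if not lag_chunks:
        raise ValueError(
            "no positive-lag identification pairs within any collection event "
            "(degenerate clock: all pairs at lag 0, or singleton events)")
    all_lags = np.concatenate(lag_chunks)
    all_same = np.concatenate(same_chunks)
    effective_max = float(all_lags.max()) if hard_max is None else hard_max

    uniq, inv = np.unique(all_lags, return_inverse=True)
    n = np.bincount(inv, minlength=len(uniq))
    m = np.bincount(inv, weights=all_same.astype(float), minlength=len(uniq))
    curve = LIRCurve(uniq, m.astype(np.int64), n.astype(np.int64),
                     max_lag=effective_max)
    if bins is None:
        return curve
    if isinstance(bins, str):
        if bins != "log":
            raise ValueError(f"unknown bin spec {bins!r}")
        edges = np.geomspace(max(uniq.min() * 0.999, 1e-9),
                             effective_max, n_bins + 1)
        edges[0] = min(edges[0], uniq.min() - 1e-9)
    else:
        edges = np.asarray(bins, dtype=float)
    return curve.rebin(edges)


def _binomial_loglik(theta: np.ndarray, lags: np.ndarray, m: np.ndarray,
                     n: np.ndarray) -> float:
    """Binomial log-likelihood at theta = log(a, b, c)."""
    a, b, c = np.exp(theta)
    if not np.all(np.isfinite([a, b, c])):
        return -np.inf
    try:
        params = ResidenceModelParams(a=a, b=b, c=c)
    except ValueError:
        return -np.inf
    r = np.clip(lir_model(lags, params), _R_FLOOR, _R_CEIL)
    return float(np.sum(m * np.log(r) + (n - m) * np.log1p(-r)))


@dataclass
class ResidenceTimeResults:
    """Fit of the emigration + re-immigration model to an LIR curve.

    Carries the ML parameter estimates, the maximized binomial
    log-likelihood, the derived probabilistic association threshold and fit
    diagnostics.
    """

    params: ResidenceModelParams | None
    llf: float
    threshold: ThresholdResult | None
    n_pairs: int
    converged: bool
    informative: bool
    subset_label: str | None = None
    clipped: bool = False
    model: "ResidenceTimeModel | None" = field(default=None, repr=False)
    start_logliks: np.ndarray | None = field(default=None, repr=False)

    def predict(self, T) -> np.ndarray:
        if self.params is None:
            raise ValueError("no parameters available (fit did not converge)")
        return lir_model(T, self.params)

    def to_dict(self) -> dict:
        d = {
            "a": self.params.a if self.params else None,
            "b": self.params.b if self.params else None,
            "c": self.params.c if self.params else None,
            "loglik": self.llf,
            "threshold": self.threshold.threshold if self.threshold else None,
            "mean_residence": (self.threshold.mean_residence
                               if self.threshold else None),
            "overlap_probability_at_threshold": (
                self.threshold.overlap_probability if self.threshold else None),
            "n_pairs": self.n_pairs,
            "converged": self.converged,
            "informative": self.informative,
            "clipped": self.clipped,
            "subset_label": self.subset_label,
            "model_assumptions": (
                "emigration and immigration rates assumed approximately equal; "
                "re-immigration into the same cluster assumed negligible over "
                "within-event lags"),
        }
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def summary(self) -> str:
        lines = ["Residence-time model fit (emigration + re-immigration LIR)",
                 "=" * 60]
        if self.subset_label:
            lines.append(f"subset:                  {self.subset_label}")
        if self.params is not None:
            lines += [
                f"a (individuals in area): {self.params.a:.4g}",
                f"b (mean time inside):    {self.params.b:.4g}",
                f"c (mean time outside):   {self.params.c:.4g}",
            ]
        lines += [
            f"log-likelihood:          {self.llf:.4f}",
            f"identification pairs:    {self.n_pairs}",
            f"converged:               {self.converged}",
            f"informative:             {self.informative}",
        ]
        if self.threshold is not None:
            lines += [
                f"association threshold:   {self.threshold.threshold} ordinal units "
                f"(raw b = {self.threshold.mean_residence:.3f})",
                f"overlap probability at threshold: "
                f"{self.threshold.overlap_probability:.3f}",
            ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot the empirical LIR curve with the fitted model overlaid."""
        import matplotlib.pyplot as plt

        if self.model is None:
            raise ValueError("results not attached to a model/curve")
        curve = self.model.curve
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(curve.lags, curve.rate, "o", ms=3, color="k", label="empirical LIR")
        if self.params is not None:
            grid = np.linspace(0, curve.max_lag, 400)
            ax.plot(grid, self.predict(grid), "-", color="C0", label="fitted model")
        if self.threshold is not None:
            ax.axvline(self.threshold.mean_residence, ls="--", color="C3",
                       label=f"mean residence b = {self.threshold.mean_residence:.1f}")
        ax.set_xlabel("lag (ordinal units)")
        ax.set_ylabel("lagged identification rate")
        ax.legend()
        return ax


class ResidenceTimeModel:
    """Maximum-likelihood residence-time model for an empirical LIR curve.

    Parameters are fitted on the log scale with multi-start Nelder-Mead, the
    loss being the binomial log-likelihood of the same-individual pair counts.
    Build it directly from a curve, or from records via :meth:`from_records`.
    """

    def __init__(self, curve: LIRCurve, subset_label: str | None = None):
        informative_lags = int(np.count_nonzero(curve.total_count > 0))
        if informative_lags < 3:
            raise ValueError(
                f"need >= 3 distinct lags with pairs to fit; got {informative_lags}")
        self.curve = curve
        self.subset_label = subset_label

    @classmethod
    def from_records(cls, records, max_lag: float | str = "auto",
                     bins=None, subset_label: str | None = None
                     ) -> "ResidenceTimeModel":
        return cls(empirical_lir(records, max_lag=max_lag, bins=bins),
                   subset_label=subset_label)

    # -- starting values ----------------------------------------------------
    def _heuristic_start(self) -> np.ndarray:
        c = self.curve
        valid = c.total_count > 0
        lags, rates = c.lags[valid], c.rate[valid]
        order = np.argsort(lags)
        lags, rates = lags[order], rates[order]
        k = max(1, len(lags) // 10)
        r0 = max(float(np.mean(rates[:k])), 1e-6)
        r_inf = max(float(np.mean(rates[-k:])), 1e-8)
        a0 = 1.0 / r0
        frac = min(max(r_inf / r0, 1e-6), 0.9)  # b/(b+c)
        # decay scale: lag where rate drops halfway to the asymptote
        half = r_inf + 0.5 * (r0 - r_inf)
        below = lags[rates <= half]
        b0 = float(below[0]) if len(below) else float(np.median(lags))
        b0 = max(b0, 1e-3)
        c0 = max(b0 * (1 - frac) / frac, 1e-3)
        return np.log([a0, b0, c0])

    def loglike(self, params: ResidenceModelParams) -> float:
        return _binomial_loglik(np.log([params.a, params.b, params.c]),
                                self.curve.lags, self.curve.same_count,
                                self.curve.total_count)

    def fit(self, starts: Sequence[ResidenceModelParams] | None = None,
            n_starts: int = 8, seed: int = 0) -> ResidenceTimeResults:
        """Fit (a, b, c) by multi-start Nelder-Mead on log parameters.

        ``starts`` overrides the default start set (one heuristic start plus
        seeded log-normal jitter around it).
        """
        c = self.curve
        lags, m, n = c.lags, c.same_count, c.total_count

        if starts is not None:
            theta_starts = [np.log([p.a, p.b, p.c]) for p in starts]
        else:
            base = self._heuristic_start()
            rng = np.random.default_rng(seed)
            theta_starts = [base] + [
                base + rng.normal(scale=1.0, size=3)
                for _ in range(max(0, n_starts - 1))
            ]

        neg = lambda th: -_binomial_loglik(th, lags, m, n)
        best, start_lls = None, []
        for th0 in theta_starts:
            start_lls.append(_binomial_loglik(th0, lags, m, n))
            res = minimize(neg, th0, method="Nelder-Mead",
                           options={"xatol": 1e-8, "fatol": 1e-10,
                                    "maxiter": 4000})
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
                best = res

        if best is None or not np.isfinite(best.fun):
            return ResidenceTimeResults(
                params=None, llf=-np.inf, threshold=None, n_pairs=c.n_pairs,
                converged=False, informative=False,
                subset_label=self.subset_label, model=self,
                start_logliks=np.asarray(start_lls))

        a, b, bc = np.exp(best.x)
        params = ResidenceModelParams(a=a, b=b, c=bc)
        llf = -best.fun
        rhat = lir_model(lags, params)
        clipped = bool(np.any(rhat >= _R_CEIL))
        if clipped:
            import warnings
            warnings.warn("fitted LIR reached 1 at some lags; likelihood "
                          "evaluated with clipped rates", RuntimeWarning)

        # a flat curve carries no decay signal: compare against the best
        # constant-rate (intercept-only) binomial model
        p0 = np.clip(m.sum() / n.sum(), _R_FLOOR, _R_CEIL)
        ll_const = float(np.sum(m * np.log(p0) + (n - m) * np.log1p(-p0)))
        informative = bool((llf - ll_const) > 0.5 and b < 100.0 * c.max_lag)

        return ResidenceTimeResults(
            params=params, llf=llf,
            threshold=threshold_from_residence(b) if informative else None,
            n_pairs=c.n_pairs, converged=bool(best.success or
                                              np.isfinite(best.fun)),
            informative=informative, subset_label=self.subset_label,
            clipped=clipped, model=self, start_logliks=np.asarray(start_lls))


def fit_residence_model(curve: LIRCurve,
                        starts: Sequence[ResidenceModelParams] | None = None,
                        n_starts: int = 8, seed: int = 0,
                        subset_label: str | None = None) -> ResidenceTimeResults:
    """Functional wrapper: fit the residence-time model to an LIR curve."""
    return ResidenceTimeModel(curve, subset_label=subset_label).fit(
        starts=starts, n_starts=n_starts, seed=seed)


def fit_by_subset(records, attribute: str, max_lag: float | str = "auto",
                  bins=None, n_starts: int = 8, seed: int = 0,
                  min_pairs: int = 30) -> Mapping[str, ResidenceTimeResults]:
    """Fit the residence model independently within each level of an attribute.

    Used to compare thresholds across data types (film vs digital, dedicated
    vs non-dedicated effort, encounter size classes).  Subsets too sparse to
    fit (< ``min_pairs`` identification pairs or < 3 informative lags) are
    skipped with a warning.
    """
    df = records_to_frame(records)
    if attribute not in df.columns:
        raise ValueError(f"attribute column {attribute!r} not in records")
    if df[attribute].isna().any():
        raise ValueError(f"attribute {attribute!r} missing on some records")
    out: dict[str, ResidenceTimeResults] = {}
    for value, g in df.groupby(attribute, sort=True):
        try:
            model = ResidenceTimeModel.from_records(
                g, max_lag=max_lag, bins=bins, subset_label=str(value))
        except ValueError as exc:
            import warnings
            warnings.warn(f"subset {value!r} skipped: {exc}")
            continue
        if model.curve.n_pairs < min_pairs:
            import warnings
            warnings.warn(f"subset {value!r} skipped: only "
                          f"{model.curve.n_pairs} pairs (< {min_pairs})")
            continue
        out[str(value)] = model.fit(n_starts=n_starts, seed=seed)
    return out
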