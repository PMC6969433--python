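"""Multi-exponential dwell-time kinetics.

The dwell-time distribution of single-molecule binding events is modelled
as a mixture of 1-3 exponential decays.  Event durations are compiled into
a histogram with bins of one frame interval, and the expected count in bin
``i`` for components ``j = 1..m`` is

    mu_i = sum_j N_j * [exp(-t_i^L / tau_j) - exp(-t_i^R / tau_j)]
                 / [exp(-t_min / tau_j) - exp(-t_max / tau_j)]

so that ``N_j`` is the expected number of *observed* events in component
``j`` within the histogram support ``[t_min, t_max]`` and the event
fractions are ``f_j = N_j / sum_k N_k``.  The fit minimizes the Poisson
deviance

    D = 2 * sum_i [ y_i * ln(y_i / mu_i) - (y_i - mu_i) ]

(the term ``y ln(y/mu)`` taken as 0 when ``y = 0``) by differential
evolution over ``(log tau_j, N_j)``, followed by a Nelder-Mead polish.  A
reduced deviance ``D / (n_bins - 2m)`` near 1 indicates an adequate model.

Components whose fitted time constant matches a photobleach lifetime of the
label are only *lower bounds* on residence: the molecule outlived its dye.
:func:`classify_bleach_limited` flags such components and pools their
fractions into an "immobilized" fraction.

The statsmodels-style entry points are :class:`ExponentialMixtureModel`
(built from durations or an event table) and the
:class:`ExponentialMixtureResults` its ``fit`` methods return.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution, minimize
from scipy.special import gammaln
from scipy.stats import chi2

from .simulate import BleachModel

__all__ = [
    "DwellHistogram",
    "DEParams",
    "ExponentialMixtureModel",
    "ExponentialMixtureResults",
    "build_histogram",
    "model_counts",
    "poisson_deviance",
    "expected_deviance",
    "fit_multiexp",
    "select_model",
    "classify_bleach_limited",
    "compare_regions",
]


# ---------------------------------------------------------------------------
# histogram


@dataclass(frozen=True)
class DwellHistogram:
    """Binned dwell times: right-open uniform bins starting at one bin width."""

    bin_edges: np.ndarray  # length n_bins + 1, seconds
    counts: np.ndarray  # length n_bins, non-negative integers
    n_events: int  # events binned (excludes truncated)
    n_truncated: int = 0  # durations >= t_max, reported not binned

    @property
    def bin_width_s(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def n_bins(self) -> int:
        return len(self.counts)


def build_histogram(
    durations_s,
    bin_width_s: float = 1.0,
    t_max_s: float | None = None,
) -> DwellHistogram:
    """Compile event durations into a dwell-time histogram.

    Bins are right-open ``[t, t + w)`` with the first left edge at the bin
    width (the shortest observable dwell is one frame).  Durations at or
    beyond ``t_max_s`` are excluded from the histogram but counted in
    ``n_truncated``.
    """
    durations = np.asarray(durations_s, dtype=float)
    if durations.size == 0:
        raise ValueError("cannot build a histogram from zero durations")
    if bin_width_s <= 0:
        raise ValueError("bin_width_s must be positive")
    if np.any(durations < bin_width_s):
        raise ValueError("all durations must be >= bin_width_s (one frame)")
    if t_max_s is None:
        t_max_s = float(durations.max()) + bin_width_s
    n_bins = int(math.ceil((t_max_s - bin_width_s) / bin_width_s))
    if n_bins < 1:
        raise ValueError("t_max_s leaves no bins")
    edges = bin_width_s * (1.0 + np.arange(n_bins + 1))
    truncated = durations >= edges[-1]
    kept = durations[~truncated]
    counts, _ = np.histogram(kept, bins=edges)
    return DwellHistogram(
        bin_edges=edges,
        counts=counts.astype(np.int64),
        n_events=int(kept.size),
        n_truncated=int(truncated.sum()),
    )


# ---------------------------------------------------------------------------
# model & cost


def model_counts(taus, Ns, bin_edges, window_s: float | None = None) -> np.ndarray:
    """Expected bin counts of an exponential mixture on a histogram support.

    Each component is renormalized over ``[t_min, t_max]`` so that ``N_j``
    counts events inside the observed histogram support.

    ``window_s`` applies a finite-observation-window correction: when
    events are censored by excluding any that touch the first or last
    frame of a movie of length ``T = window_s``, the dwell times that
    survive censoring are distributed with density proportional to
    ``exp(-t / tau) * (1 - t / T)`` (a dwell ``t`` only survives if the
    molecule arrived in the first ``T - t`` of the window).  The bin mass
    then uses ``G(t) = exp(-t/tau) * (1 - (t + tau)/T)`` in place of the
    plain survival ``exp(-t/tau)``; ``window_s=None`` is the
    infinite-window (uncorrected) limit.
    """
    taus = np.atleast_1d(np.asarray(taus, dtype=float))
    Ns = np.atleast_1d(np.asarray(Ns, dtype=float))
    edges = np.asarray(bin_edges, dtype=float)
    if np.any(taus <= 0):
        raise ValueError("time constants must be positive")
    if taus.shape != Ns.shape:
        raise ValueError("taus and Ns must have the same length")
    if window_s is not None and edges[-1] > window_s:
        raise ValueError("histogram support exceeds the observation window")
    # integrated density at each edge, per component: (m, n_edges)
    surv = np.exp(-edges[None, :] / taus[:, None])
    if window_s is not None:
        surv = surv * (1.0 - (edges[None, :] + taus[:, None]) / window_s)
    norm = surv[:, 0] - surv[:, -1]
    mass = (surv[:, :-1] - surv[:, 1:]) / norm[:, None]
    return (Ns[:, None] * mass).sum(axis=0)


def poisson_deviance(y, mu) -> float:
    """Poisson deviance D = 2 sum[y ln(y/mu) - (y - mu)]; zero iff y == mu."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if y.shape != mu.shape:
        raise ValueError("y and mu must have the same shape")
    if np.any(mu <= 0):
        raise ValueError("expected counts must be strictly positive")
    term = np.zeros_like(y)
    pos = y > 0
    term[pos] = y[pos] * (np.log(y[pos]) - np.log(mu[pos]))
    return float(2.0 * np.sum(term - (y - mu)))


# ---------------------------------------------------------------------------
# fitting


@dataclass(frozen=True)
class DEParams:
    """Differential-evolution hyperparameters (recorded with every fit)."""

    strategy: str = "rand1bin"
    popsize: int = 15  # individuals per free parameter
    mutation: tuple[float, float] = (0.5, 1.0)  # dithered per generation
    recombination: float = 0.7
    tol: float = 1e-8
    maxiter: int = 1000


def _deviance_of(
    theta: np.ndarray,
    m: int,
    counts: np.ndarray,
    edges: np.ndarray,
    window_s: float | None,
) -> float:
    taus = np.exp(theta[:m])
    mu = model_counts(taus, theta[m:], edges, window_s)
    if np.any(mu <= 0) or not np.all(np.isfinite(mu)):
        return np.inf
    return poisson_deviance(counts, mu)


def _trimmed_dof(counts: np.ndarray, m: int) -> tuple[int, int]:
    """(n_bins kept, dof) after trimming trailing empty bins."""
    nz = np.nonzero(counts)[0]
    n_kept = int(nz[-1]) + 1 if nz.size else len(counts)
    return n_kept, n_kept - 2 * m


def expected_deviance(mu) -> float:
    """Expected Poisson deviance E[D] when the model with means ``mu`` is true.

    For well-populated bins each contributes ~1 (the chi-squared picture),
    but a bin with small mean contributes far less: E[D_i] -> 0 as mu -> 0.
    With one-frame bins most of a dwell histogram's support is nearly
    empty, so D/dof sits well below 1 even for a perfect model; D/E[D] is
    the calibrated goodness-of-fit statistic that stays near 1 regardless
    of binning.  Per bin, E[D_i] = 2 (E[y ln y] - mu ln mu), computed by
    summing the Poisson pmf for small mu and by the asymptotic
    1 + 1/(6 mu) beyond.
    """
    mu = np.asarray(mu, dtype=float)
    out = np.empty_like(mu)
    large = mu >= 30.0
    out[large] = 1.0 + 1.0 / (6.0 * mu[large])
    small = ~large
    if np.any(small):
        ms = mu[small][:, None]
        y = np.arange(1, 151, dtype=float)[None, :]
        log_pmf = -ms + y * np.log(ms) - gammaln(y + 1)
        e_ylny = np.sum(np.exp(log_pmf) * y * np.log(y), axis=1)
        out[small] = 2.0 * (e_ylny - mu[small] * np.log(mu[small]))
    return float(out.sum())


def fit_multiexp(
    hist: DwellHistogram,
    m: int,
    bounds: list[tuple[float, float]] | None = None,
    de_params: DEParams | None = None,
    seed: int = 0,
    window_s: float | None = None,
) -> "ExponentialMixtureResults":
    """Fit an m-component exponential mixture to a dwell histogram.

    Global search by differential evolution over ``(log tau_1..m, N_1..m)``
    with fixed, recorded hyperparameters, then a Nelder-Mead polish from
    the DE optimum.  Components are reported sorted by time constant.
    ``window_s`` enables the finite-window censoring correction of
    :func:`model_counts`.  Non-convergence is flagged on the result, never
    raised.
    """
    if m not in (1, 2, 3):
        raise ValueError("m must be 1, 2 or 3")
    de = de_params or DEParams()
    edges = hist.bin_edges
    counts = hist.counts.astype(float)
    t_max = float(edges[-1])
    if bounds is None:
        log_tau_bounds = (math.log(hist.bin_width_s), math.log(10.0 * t_max))
        n_bounds = (1e-3, 10.0 * max(1, hist.n_events))
        bounds = [log_tau_bounds] * m + [n_bounds] * m
    else:
        bounds = list(bounds)

    res = differential_evolution(
        _deviance_of,
        bounds,
        args=(m, counts, edges, window_s),
        strategy=de.strategy,
        popsize=de.popsize,
        mutation=de.mutation,
        recombination=de.recombination,
        tol=de.tol,
        maxiter=de.maxiter,
        seed=seed,
        polish=False,
    )
    theta = res.x
    deviance = float(res.fun)

    # derivative-free local polish; reject steps leaving the search box
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def _boxed(theta_: np.ndarray) -> float:
        if np.any(theta_ < lo) or np.any(theta_ > hi):
            return np.inf
        return _deviance_of(theta_, m, counts, edges, window_s)

    polish = minimize(_boxed, theta, method="Nelder-Mead",
                      options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
    if np.isfinite(polish.fun) and polish.fun <= deviance:
        theta = polish.x
        deviance = float(polish.fun)

    taus = np.exp(theta[:m])
    Ns = np.maximum(theta[m:], 1e-12)
    order = np.argsort(taus)
    taus, Ns = taus[order], Ns[order]
    n_kept, dof = _trimmed_dof(hist.counts, m)
    mu = model_counts(taus, Ns, edges, window_s)
    d_trim = poisson_deviance(counts[:n_kept], mu[:n_kept])
    reduced = d_trim / dof if dof > 0 else math.nan
    calibrated = d_trim / expected_deviance(mu[:n_kept])
    return ExponentialMixtureResults(
        taus=taus,
        event_counts=Ns,
        deviance=deviance,
        reduced_deviance=float(reduced),
        calibrated_reduced_deviance=float(calibrated),
        n_bins_fit=n_kept,
        dof=dof,
        converged=bool(res.success or polish.success),
        n_de_generations=int(res.nit),
        seed=seed,
        de_params=de,
        histogram=hist,
        window_s=window_s,
    )


def select_model(
    hist: DwellHistogram,
    m_candidates=(1, 2, 3),
    de_params: DEParams | None = None,
    seed: int = 0,
    min_tau_ratio: float = 3.0,
    min_fraction: float = 0.01,
    lrt_alpha: float = 0.01,
    window_s: float | None = None,
) -> "ExponentialMixtureResults":
    """Fit candidate component counts and pick the best-supported model.

    Fits with indistinct components (adjacent time-constant ratio below
    ``min_tau_ratio`` or any fraction below ``min_fraction``) are
    discarded.  Among the remaining, nested models are compared by a
    sequential deviance (likelihood-ratio) test: a larger model is adopted
    only when it lowers the deviance by more than the chi-squared critical
    value at ``lrt_alpha`` for its extra parameters.  The calibrated
    reduced deviance D / E[D] (see :func:`expected_deviance`), near 1 for
    an adequate model, is reported for every candidate as the absolute
    goodness-of-fit diagnostic.  All candidate diagnostics are kept on the
    result.
    """
    m_candidates = sorted(set(m_candidates))
    if not m_candidates or any(m not in (1, 2, 3) for m in m_candidates):
        raise ValueError("m_candidates must be a non-empty subset of {1, 2, 3}")
    fits = {
        m: fit_multiexp(hist, m, de_params=de_params, seed=seed, window_s=window_s)
        for m in m_candidates
    }
    converged = {m: f for m, f in fits.items() if f.converged}
    if not converged:
        raise RuntimeError("no candidate model converged")

    def distinct(f: ExponentialMixtureResults) -> bool:
        if np.any(f.fractions < min_fraction):
            return False
        return all(
            f.taus[j + 1] / f.taus[j] >= min_tau_ratio for j in range(len(f.taus) - 1)
        )

    admissible = {m: f for m, f in converged.items() if distinct(f)}
    if not admissible:
        admissible = converged
    order = sorted(admissible)
    best = order[0]
    for m in order[1:]:
        extra_params = 2 * (m - best)
        critical = chi2.ppf(1.0 - lrt_alpha, df=extra_params)
        if admissible[best].deviance - admissible[m].deviance > critical:
            best = m
    result = admissible[best]
    result.candidates = {
        m: {
            "taus": f.taus.tolist(),
            "fractions": f.fractions.tolist(),
            "deviance": f.deviance,
            "reduced_deviance": f.reduced_deviance,
            "calibrated_reduced_deviance": f.calibrated_reduced_deviance,
            "converged": f.converged,
            "admissible": m in admissible,
        }
        for m, f in fits.items()
    }
    return result


def classify_bleach_limited(
    result: "ExponentialMixtureResults",
    bleach: BleachModel,
    rel_tol: float = 0.35,
) -> "ExponentialMixtureResults":
    """Flag components whose apparent lifetime is set by photobleaching.

    A component is bleach-limited ("immobilized"; its tau is a lower bound
    on residence, not a dissociation time) if its time constant is within
    ``rel_tol`` relative tolerance of any bleach lifetime, or exceeds the
    longest one.  Returns a new result with flags set; the flagged
    fractions sum to ``immobilized_fraction``.
    """
    lifetimes = np.asarray(bleach.lifetimes_s, dtype=float)
    flags = np.array(
        [
            bool(
                np.any(np.abs(tau - lifetimes) / lifetimes <= rel_tol)
                or tau >= lifetimes.max()
            )
            for tau in result.taus
        ]
    )
    out = replace(result)
    out.bleach_limited = flags
    out.bleach_model = bleach
    out.candidates = result.candidates
    return out


# ---------------------------------------------------------------------------
# Model / Results


class ExponentialMixtureModel:
    """Dwell-time mixture model built from event durations.

    Parameters
    ----------
    durations_s
        Observed dwell times (seconds), each at least one bin width.
    bin_width_s
        Histogram bin width; defaults to the frame interval since observed
        durations are whole numbers of frames.
    t_max_s
        Histogram upper edge; defaults to the longest duration plus one bin.
    bleach
        Photobleach model used to flag bleach-limited components after
        fitting; optional.
    window_s
        Observation-window length (movie duration, seconds).  When given,
        fits use the finite-window censoring correction of
        :func:`model_counts`, appropriate for event tables censored by
        dropping first/last-frame events.
    """

    def __init__(
        self,
        durations_s,
        bin_width_s: float = 1.0,
        t_max_s: float | None = None,
        bleach: BleachModel | None = None,
        window_s: float | None = None,
    ):
        self.durations_s = np.asarray(durations_s, dtype=float)
        self.bin_width_s = bin_width_s
        self.t_max_s = t_max_s
        self.bleach = bleach
        self.window_s = window_s
        self.histogram = build_histogram(self.durations_s, bin_width_s, t_max_s)

    @classmethod
    def from_events(
        cls,
        events: pd.DataFrame,
        region: str | None = None,
        bin_width_s: float = 1.0,
        t_max_s: float | None = None,
        bleach: BleachModel | None = None,
        window_s: float | None = None,
    ) -> "ExponentialMixtureModel":
        """Build from a binding-event table (column ``duration_s``).

        ``region`` restricts to rows whose ``region`` column matches
        (e.g. ``"fibril"`` or ``"background"``).
        """
        if region is not None:
            events = events[events["region"] == region]
        return cls(events["duration_s"].to_numpy(), bin_width_s, t_max_s, bleach, window_s)

    def fit(
        self,
        m: int = 2,
        bounds=None,
        de_params: DEParams | None = None,
        seed: int = 0,
    ) -> "ExponentialMixtureResults":
        """Fit a fixed number of components; see :func:`fit_multiexp`."""
        result = fit_multiexp(self.histogram, m, bounds, de_params, seed, self.window_s)
        return self._attach(result)

    def fit_select(
        self,
        m_candidates=(1, 2, 3),
        de_params: DEParams | None = None,
        seed: int = 0,
    ) -> "ExponentialMixtureResults":
        """Fit candidate component counts and select; see :func:`select_model`."""
        result = select_model(
            self.histogram, m_candidates, de_params, seed, window_s=self.window_s
        )
        return self._attach(result)

    def _attach(self, result: "ExponentialMixtureResults") -> "ExponentialMixtureResults":
        result.model = self
        if self.bleach is not None:
            flagged = classify_bleach_limited(result, self.bleach)
            flagged.model = self
            return flagged
        return result


@dataclass
class ExponentialMixtureResults:
    """Fitted exponential-mixture decomposition of a dwell-time histogram."""

    taus: np.ndarray  # seconds, ascending
    event_counts: np.ndarray  # N_j, expected events per component in-window
    deviance: float
    reduced_deviance: float  # D / dof (classical; low-biased on sparse bins)
    calibrated_reduced_deviance: float  # D / E[D]; ~1 for an adequate model
    n_bins_fit: int
    dof: int
    converged: bool
    n_de_generations: int
    seed: int
    de_params: DEParams
    histogram: DwellHistogram
    window_s: float | None = None
    bleach_limited: np.ndarray | None = None
    bleach_model: BleachModel | None = None
    candidates: dict | None = field(default=None, compare=False)
    model: "ExponentialMixtureModel | None" = field(default=None, compare=False, repr=False)

    @property
    def m(self) -> int:
        return len(self.taus)

    @property
    def fractions(self) -> np.ndarray:
        """Event fractions f_j = N_j / sum(N); sum to 1."""
        return self.event_counts / self.event_counts.sum()

    @property
    def immobilized_fraction(self) -> float:
        """Summed fraction of bleach-limited components (0 if none flagged)."""
        if self.bleach_limited is None:
            return 0.0
        return float(self.fractions[self.bleach_limited].sum())

    def predicted_counts(self) -> np.ndarray:
        """Expected counts per histogram bin under the fitted model."""
        return model_counts(
            self.taus, self.event_counts, self.histogram.bin_edges, self.window_s
        )

    def conf_int(
        self, alpha: float = 0.05, n_boot: int = 200, seed: int = 0
    ) -> pd.DataFrame:
        """Bootstrap percentile confidence intervals for tau_j and f_j.

        Events are resampled with replacement and refit at the same
        component count (a lighter DE budget keeps refits affordable).
        Requires the result to have been produced by a model object.
        """
        if self.model is None:
            raise ValueError("conf_int requires a result fitted through a model")
        durations = self.model.durations_s
        rng = np.random.default_rng(seed)
        boot_de = DEParams(maxiter=150, tol=1e-6)
        taus_b = np.empty((n_boot, self.m))
        fracs_b = np.empty((n_boot, self.m))
        for b in range(n_boot):
            resampled = rng.choice(durations, size=durations.size, replace=True)
            hist = build_histogram(resampled, self.model.bin_width_s, self.model.t_max_s)
            sub_seed = int(rng.integers(0, 2**31 - 1))
            fit = fit_multiexp(
                hist, self.m, de_params=boot_de, seed=sub_seed, window_s=self.window_s
            )
            taus_b[b] = fit.taus
            fracs_b[b] = fit.fractions
        lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
        rows = []
        for j in range(self.m):
            rows.append(
                {
                    "component": j + 1,
                    "tau_s": self.taus[j],
                    "tau_lo": np.percentile(taus_b[:, j], lo),
                    "tau_hi": np.percentile(taus_b[:, j], hi),
                    "fraction": self.fractions[j],
                    "fraction_lo": np.percentile(fracs_b[:, j], lo),
                    "fraction_hi": np.percentile(fracs_b[:, j], hi),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable fit summary table."""
        lines = [
            "Exponential mixture dwell-time fit",
            "=" * 54,
            f"components:       {self.m}",
            f"events (binned):  {self.histogram.n_events}"
            + (f"  (+{self.histogram.n_truncated} truncated)" if self.histogram.n_truncated else ""),
            f"deviance:         {self.deviance:.2f}",
            f"reduced deviance: {self.reduced_deviance:.3f}  (dof={self.dof})",
            f"calibrated D/E[D]: {self.calibrated_reduced_deviance:.3f}",
            f"converged:        {self.converged}   seed={self.seed}",
            "-" * 54,
            f"{'comp':>4} {'tau (s)':>10} {'fraction':>9} {'N_j':>9}  bleach-limited",
        ]
        flags = self.bleach_limited if self.bleach_limited is not None else [None] * self.m
        for j in range(self.m):
            flag = {True: "yes", False: "no", None: "-"}[
                None if flags[j] is None else bool(flags[j])
            ]
            lines.append(
                f"{j + 1:>4} {self.taus[j]:>10.3g} {self.fractions[j]:>9.3f} "
                f"{self.event_counts[j]:>9.1f}  {flag}"
            )
        if self.bleach_limited is not None:
            lines.append("-" * 54)
            lines.append(f"immobilized fraction: {self.immobilized_fraction:.3f}")
        return "\n".join(lines)

    def plot(self, ax=None, log: bool = True):
        """Histogram with the fitted mixture overlaid (counts per bin)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        edges = self.histogram.bin_edges
        centers = 0.5 * (edges[:-1] + edges[1:])
        ax.step(centers, self.histogram.counts, where="mid", label="events")
        ax.plot(centers, self.predicted_counts(), label=f"{self.m}-exp fit")
        if log:
            ax.set_yscale("log")
        ax.set_xlabel("residence time (s)")
        ax.set_ylabel("events per bin")
        ax.legend()
        return ax

    def to_report(self) -> dict:
        """JSON-serializable fit report."""
        report = {
            "m": self.m,
            "tau_s": self.taus.tolist(),
            "fractions": self.fractions.tolist(),
            "event_counts": self.event_counts.tolist(),
            "deviance": self.deviance,
            "reduced_deviance": self.reduced_deviance,
            "calibrated_reduced_deviance": self.calibrated_reduced_deviance,
            "dof": self.dof,
            "converged": self.converged,
            "seed": self.seed,
            "n_events": self.histogram.n_events,
            "n_truncated": self.histogram.n_truncated,
            "window_s": self.window_s,
        }
        if self.bleach_limited is not None:
            report["bleach_limited"] = [bool(b) for b in self.bleach_limited]
            report["immobilized_fraction"] = self.immobilized_fraction
        if self.candidates is not None:
            report["candidates"] = self.candidates
        return report


def compare_regions(
    fibril_result: ExponentialMixtureResults | None,
    background_result: ExponentialMixtureResults | None,
    n_boot: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Side-by-side fibril vs background fit table with bootstrap CIs.

    A missing region (no events) yields rows marked unavailable.
    """
    frames = []
    for region, result in (("fibril", fibril_result), ("background", background_result)):
        if result is None:
            frames.append(pd.DataFrame([{"region": region, "available": False}]))
            continue
        ci = result.conf_int(n_boot=n_boot, seed=seed)
        ci.insert(0, "region", region)
        ci.insert(1, "available", True)
        frames.append(ci)
    return pd.concat(frames, ignore_index=True)
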