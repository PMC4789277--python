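"""Per-sample signal deconvolution with a three-component Poisson mixture.

Window counts from an MBD enrichment library mix three populations:
near-zero background, intermediate ambient/partially-enriched signal, and
strong enrichment over methylated DNA. Fitting the mixture per sample turns
each window count into a posterior probability that the window belongs to
the highest-rate (methylated) component.

Estimation is EM to a MAP estimate under weak conjugate priors — Gamma(1,
1e-3) on each rate and a symmetric Dirichlet(1) on the weights — which
coincides with maximum likelihood as the priors vanish. Initialization is
deterministic (count quantiles), so fits reproduce without a seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp


class DegenerateFitError(ValueError):
    """Raised when the data cannot identify the requested number of components."""


@dataclass
class ThreePoissonResults:
    """Fitted mixture for one sample.

    Rates are sorted ascending; the methylated component is the last
    (highest-rate) one. ``loglik_trace`` records the observed-data
    log-likelihood at each EM iteration.
    """

    sample: str
    rates: np.ndarray  # ascending
    weights: np.ndarray  # sum to 1
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    degenerate: bool = False  # True when fallback to fewer components was used

    @property
    def n_components(self) -> int:
        return len(self.rates)

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])

    def _log_joint(self, counts: np.ndarray) -> np.ndarray:
        counts = np.atleast_1d(np.asarray(counts))
        with np.errstate(divide="ignore"):  # zero weights are legal
            logw = np.log(self.weights)
        return logw[None, :] + stats.poisson.logpmf(
            counts[:, None], self.rates[None, :]
        )

    def component_posteriors(self, counts) -> np.ndarray:
        """Posterior membership over components for each count; rows sum to 1."""
        lj = self._log_joint(counts)
        return np.exp(lj - logsumexp(lj, axis=1, keepdims=True))

    def methylation_probability(self, counts) -> np.ndarray:
        """P(methylated component | count), i.e. the posterior of the top rate."""
        return self.component_posteriors(counts)[:, -1]

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "sample": self.sample,
                "component": k + 1,
                "rate": self.rates[k],
                "weight": self.weights[k],
                "converged": self.converged,
                "n_iter": self.n_iter,
                "degenerate": self.degenerate,
            }
            for k in range(self.n_components)
        ]
        return pd.DataFrame(rows)


class ThreePoissonMixture:
    """Poisson mixture model for one sample's retained window counts.

    Parameters
    ----------
    counts : array-like of int
        Non-negative window counts for a single sample.
    sample : str
        Sample id carried into results.
    """

    def __init__(self, counts, sample: str = "") -> None:
        counts = np.asarray(counts)
        if counts.size == 0:
            raise ValueError("no counts to fit")
        if (counts < 0).any() or not np.issubdtype(counts.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        # EM only sees the empirical distribution: aggregate by unique value
        self.values, self.multiplicities = np.unique(counts, return_counts=True)
        self.n = int(counts.size)
        self.sample = sample

    def fit(
        self,
        n_components: int = 3,
        max_iter: int = 500,
        tol: float = 1e-8,
        weight_floor: float = 1e-6,
        rate_floor: float = 1e-6,
        prior_rate: float = 1e-3,
        fallback: bool = True,
    ) -> ThreePoissonResults:
        """EM to the MAP estimate; components relabelled by ascending rate.

        Convergence is declared when the relative change in log-likelihood
        falls below ``tol``. The data may carry fewer modes than requested
        components — after filtering, a sample can show only background plus
        methylated signal, or a single methylated population — in which
        case surplus components split an existing mode into interchangeable
        halves and the top-component posterior becomes meaningless. With
        ``fallback`` true the model is therefore fit at every order from
        ``n_components`` down to one and the best fit by BIC is returned,
        flagged ``degenerate`` when it has fewer components than requested
        (a one-component fit assigns methylation probability 1 everywhere:
        all its windows are one population, already far above the
        even-coverage background that the filter removed). Fewer than two
        distinct count values raise :class:`DegenerateFitError`.
        """
        if len(self.values) < 2:
            raise DegenerateFitError(
                f"sample {self.sample!r}: {len(self.values)} distinct count "
                "values cannot identify any mixture"
            )
        if len(self.values) < n_components and not fallback:
            raise DegenerateFitError(
                f"sample {self.sample!r}: {len(self.values)} distinct count "
                f"values cannot identify {n_components} components"
            )
        if fallback:
            candidates = []
            for k in range(min(n_components, len(self.values)), 0, -1):
                res = self.fit(
                    n_components=k,
                    max_iter=max_iter,
                    tol=tol,
                    weight_floor=weight_floor,
                    rate_floor=rate_floor,
                    prior_rate=prior_rate,
                    fallback=False,
                )
                candidates.append(res)
            best = min(candidates, key=self._bic)
            best.degenerate = best.n_components < n_components
            return best
        rates, weights = self._initialize(n_components)
        x = self.values.astype(float)
        m = self.multiplicities.astype(float)
        trace = []
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            lj = np.log(weights)[None, :] + stats.poisson.logpmf(
                x[:, None], rates[None, :]
            )
            norm = logsumexp(lj, axis=1)
            trace.append(float(np.dot(m, norm)))
            resp = np.exp(lj - norm[:, None]) * m[:, None]  # weighted responsibilities
            nk = resp.sum(axis=0)
            rates = np.maximum(resp.T @ x / (nk + prior_rate), rate_floor)
            weights = np.maximum(nk / self.n, weight_floor)
            weights /= weights.sum()
            if len(trace) > 1:
                prev, cur = trace[-2], trace[-1]
                if abs(cur - prev) <= tol * max(1.0, abs(prev)):
                    converged = True
                    break
        order = np.argsort(rates)
        result = ThreePoissonResults(
            sample=self.sample,
            rates=rates[order],
            weights=weights[order],
            loglik_trace=np.asarray(trace),
            converged=converged,
            n_iter=it,
        )
        if n_components > 2 and fallback:
            reduced = self.fit(
                n_components=n_components - 1,
                max_iter=max_iter,
                tol=tol,
                weight_floor=weight_floor,
                rate_floor=rate_floor,
                prior_rate=prior_rate,
                fallback=False,
            )
            if self._bic(reduced) < self._bic(result):
                reduced.degenerate = True
                return reduced
        return result

    def _bic(self, res: ThreePoissonResults) -> float:
        n_params = 2 * res.n_components - 1
        return -2.0 * res.loglik + n_params * np.log(self.n)

    def _initialize(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        expanded_q = {3: [25, 75, 99], 2: [50, 99]}.get(
            k, list(np.linspace(25, 99, k))
        )
        # quantiles of the empirical distribution, offset to keep rates positive
        order = np.repeat(self.values, self.multiplicities)
        rates = np.percentile(order, expanded_q) + 0.1
        rates = np.maximum.accumulate(rates + np.arange(k) * 1e-3)
        weights = {3: np.array([0.6, 0.3, 0.1]), 2: np.array([0.8, 0.2])}.get(
            k, np.full(k, 1.0 / k)
        )
        return rates.astype(float), weights / weights.sum()


def fit_three_poisson(
    counts,
    sample: str = "",
    **kwargs,
) -> ThreePoissonResults:
    """Convenience wrapper: build the model and fit it."""
    return ThreePoissonMixture(counts, sample=sample).fit(**kwargs)


def fit_all_samples(
    counts_by_sample: dict[str, np.ndarray], **kwargs
) -> dict[str, ThreePoissonResults]:
    return {
        s: fit_three_poisson(c, sample=s, **kwargs)
        for s, c in counts_by_sample.items()
    }


def call_status(posteriors: np.ndarray, tau: float = 0.5) -> np.ndarray:
    """Binarize methylation posteriors: methylated iff p_meth >= tau."""
    if not (0 < tau < 1):
        raise ValueError("tau must be in (0, 1)")
    return np.asarray(posteriors) >= tau


def fit_report(fits: dict[str, ThreePoissonResults]) -> pd.DataFrame:
    rows = []
    for s, f in fits.items():
        row = {"sample": s}
        for k in range(3):
            row[f"lambda{k + 1}"] = f.rates[k] if k < f.n_components else np.nan
            row[f"pi{k + 1}"] = f.weights[k] if k < f.n_components else np.nan
        row.update(
            n_iter=f.n_iter, converged=f.converged, degenerate=f.degenerate
        )
        rows.append(row)
    return pd.DataFrame(rows)
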