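"""Promoter enrichment calling from tiling-array M-values.

The genome-wide distribution of smoothed probe M-values is modelled as a
mixture of two univariate Gaussians: N1 for probes in non-enriched
(background) regions and N2 for probes in enriched regions.  Parameters are
estimated by maximum likelihood via EM, each probe receives posterior
responsibilities under the fitted mixture and a maximum-a-posteriori (MAP)
class, and a promoter is called significantly enriched when at least 80% of
the probes mapping entirely within its window are assigned to the enriched
component.  Per-factor boolean calls combine into joint binding (e.g. a
PRC1 call requires joint enrichment of PC, Ph and Psc) by logical AND.

Conventions: components are relabeled after fitting so that the enriched
component has the larger mean (mu2 > mu1); a probe exactly on the decision
boundary (p2 = 0.5) goes to the background class, and the 80% rule itself is
deliberately conservative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

from .errors import DegenerateInputError, InsufficientDataError
from .promoters import contained_probe_indices

__all__ = [
    "Gmm2Params",
    "EnrichmentCall",
    "fit_gmm2",
    "gmm_posteriors",
    "map_classify",
    "call_promoter_enrichment",
    "call_enrichment_track",
    "joint_binding",
    "running_mean_smooth",
]


@dataclass
class Gmm2Params:
    """Fitted two-component univariate Gaussian mixture.

    Component 1 is background, component 2 is enriched (mu2 > mu1 by
    convention).  ``loglik_path`` retains the per-iteration log-likelihood
    of the best EM run (non-decreasing by the EM guarantee).
    """

    pi1: float
    pi2: float
    mu1: float
    sigma1: float
    mu2: float
    sigma2: float
    loglik: float
    n_iter: int
    converged: bool
    loglik_path: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_dict(self) -> dict:
        return {
            "pi1": self.pi1,
            "pi2": self.pi2,
            "mu1": self.mu1,
            "sigma1": self.sigma1,
            "mu2": self.mu2,
            "sigma2": self.sigma2,
            "loglik": self.loglik,
            "n_iter": self.n_iter,
            "converged": self.converged,
        }


@dataclass
class EnrichmentCall:
    """Promoter-level enrichment decision for one feature."""

    promoter_id: str
    feature: str
    n_probes: int
    frac_class2: float
    enriched: bool


def _em_run(
    x: np.ndarray,
    mu: np.ndarray,
    sigma: np.ndarray,
    pi: np.ndarray,
    tol: float,
    max_iter: int,
    variance_floor: float,
):
    """One EM run from a given starting point; returns params and loglik path."""
    n = len(x)
    path = []
    loglik = -np.inf
    converged = False
    it = 0
    log_2pi = np.log(2.0 * np.pi)
    for it in range(1, max_iter + 1):
        # E-step in log space (Gaussian log-density written out for speed)
        log_comp = np.stack(
            [
                np.log(pi[k])
                - np.log(sigma[k])
                - 0.5 * log_2pi
                - 0.5 * ((x - mu[k]) / sigma[k]) ** 2
                for k in range(2)
            ]
        )
        log_norm = logsumexp(log_comp, axis=0)
        new_loglik = float(log_norm.sum())
        resp = np.exp(log_comp - log_norm)
        # M-step
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-300)
        mu = (resp @ x) / nk
        var = np.maximum(
            (resp * (x - mu[:, None]) ** 2).sum(axis=1) / nk, variance_floor
        )
        sigma = np.sqrt(var)
        pi = nk / n
        path.append(new_loglik)
        if np.isfinite(loglik) and abs(new_loglik - loglik) < tol:
            converged = True
            loglik = new_loglik
            break
        loglik = new_loglik
    return mu, sigma, pi, loglik, it, converged, np.asarray(path)


def fit_gmm2(
    values,
    tol: float = 1e-8,
    max_iter: int = 500,
    variance_floor: float = 1e-6,
    n_init: int = 3,
    seed: int | None = 0,
) -> Gmm2Params:
    """Fit the two-component Gaussian mixture to probe values by EM.

    The first run starts from the 25th/75th data percentiles with pooled
    standard deviations and equal weights; ``n_init - 1`` additional seeded
    random restarts draw means from the data, and the run with the best
    log-likelihood is kept.  Variances are floored at ``variance_floor`` to
    prevent singular collapse.

    Raises
    ------
    InsufficientDataError
        Fewer than 10 finite values.
    DegenerateInputError
        All values identical (no spread to estimate).
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 10:
        raise InsufficientDataError(
            f"need at least 10 finite values, got {len(x)}"
        )
    if np.ptp(x) == 0:
        raise DegenerateInputError("all values identical; cannot fit mixture")

    pooled_sd = max(float(np.std(x)), np.sqrt(variance_floor))
    starts = [
        (
            np.percentile(x, [25.0, 75.0]),
            np.array([pooled_sd, pooled_sd]),
            np.array([0.5, 0.5]),
        )
    ]
    rng = np.random.default_rng(seed)
    for _ in range(max(0, n_init - 1)):
        mu0 = np.sort(rng.choice(x, size=2, replace=False))
        starts.append(
            (mu0, np.array([pooled_sd, pooled_sd]), np.array([0.5, 0.5]))
        )

    best = None
    for mu0, sigma0, pi0 in starts:
        result = _em_run(
            x, mu0.copy(), sigma0.copy(), pi0.copy(), tol, max_iter,
            variance_floor,
        )
        if best is None or result[3] > best[3]:
            best = result
    mu, sigma, pi, loglik, n_iter, converged, path = best
    order = np.argsort(mu)  # enriched component = larger mean
    mu, sigma, pi = mu[order], sigma[order], pi[order]
    return Gmm2Params(
        pi1=float(pi[0]),
        pi2=float(pi[1]),
        mu1=float(mu[0]),
        sigma1=float(sigma[0]),
        mu2=float(mu[1]),
        sigma2=float(sigma[1]),
        loglik=loglik,
        n_iter=n_iter,
        converged=converged,
        loglik_path=path,
    )


def gmm_posteriors(params: Gmm2Params, values) -> pd.DataFrame:
    """Posterior responsibilities of each probe under the fitted mixture.

    Returns a DataFrame (index = positional probe index of the finite
    values) with columns p1, p2 and map_class, where
    ``p2 = pi2 N(x; mu2, sigma2) / [pi1 N(x; mu1, sigma1) + pi2 N(x; mu2,
    sigma2)]``, computed in log space.  Non-finite values are skipped with
    a warning.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if not finite.all():
        warnings.warn(
            f"skipping {int((~finite).sum())} non-finite probe value(s)",
            stacklevel=2,
        )
    idx = np.nonzero(finite)[0]
    x = x[finite]
    log1 = np.log(params.pi1) + norm.logpdf(x, params.mu1, params.sigma1)
    log2 = np.log(params.pi2) + norm.logpdf(x, params.mu2, params.sigma2)
    # p2 = 1 / (1 + exp(log1 - log2)), stable logistic
    p2 = 0.5 * (1.0 + np.tanh(0.5 * (log2 - log1)))
    return pd.DataFrame(
        {
            "p1": 1.0 - p2,
            "p2": p2,
            "map_class": np.where(p2 > 0.5, 2, 1),
        },
        index=idx,
    )


def map_classify(posteriors) -> np.ndarray:
    """MAP class per probe: 2 iff p2 > 0.5; an exact tie goes to class 1."""
    if isinstance(posteriors, pd.DataFrame):
        p2 = posteriors["p2"].to_numpy()
    else:
        p2 = np.asarray(posteriors, dtype=float)
    return np.where(p2 > 0.5, 2, 1)


def call_promoter_enrichment(
    promoter_id: str,
    probe_classes,
    threshold: float = 0.8,
    feature: str = "feature",
) -> EnrichmentCall:
    """Call a promoter enriched when >= ``threshold`` of its probes are class 2.

    A promoter with zero contained probes is never enriched (frac_class2
    reported as 0).
    """
    classes = np.asarray(probe_classes)
    n = len(classes)
    frac = float((classes == 2).sum() / n) if n else 0.0
    return EnrichmentCall(
        promoter_id=promoter_id,
        feature=feature,
        n_probes=n,
        frac_class2=frac,
        enriched=bool(n >= 1 and frac >= threshold),
    )


def component_separation(params: Gmm2Params) -> float:
    """Ashman's D between the two fitted components.

    ``D = |mu2 - mu1| / sqrt((sigma1^2 + sigma2^2) / 2)``; values above ~2
    indicate a genuinely bimodal mixture.  When the fit is effectively
    unimodal, MAP classes carry no evidence of enrichment.
    """
    return abs(params.mu2 - params.mu1) / np.sqrt(
        0.5 * (params.sigma1**2 + params.sigma2**2)
    )


def call_enrichment_track(
    promoters: pd.DataFrame,
    track: pd.DataFrame,
    threshold: float = 0.8,
    feature: str = "feature",
    params: Gmm2Params | None = None,
    min_separation: float = 2.0,
    **fit_kwargs,
) -> tuple[pd.DataFrame, Gmm2Params]:
    """Genome-wide enrichment calls for every promoter against one track.

    Fits the mixture to all finite track values (unless ``params`` is
    given), MAP-classifies every probe, and applies the promoter rule to
    the probes entirely contained in each window.  Returns the call table
    (promoter_id, feature, n_probes, frac_class2, enriched) and the fitted
    parameters.

    When the fitted components are not separated (Ashman's D below
    ``min_separation``) the track is effectively unimodal — there is no
    distinct enriched population — and every probe is assigned to the
    background class rather than producing spurious calls; pass
    ``min_separation=0`` to disable the guard.
    """
    values = track["value"].to_numpy()
    if params is None:
        params = fit_gmm2(values[np.isfinite(values)], **fit_kwargs)
    classes = np.ones(len(values), dtype=np.int64)
    if component_separation(params) >= min_separation:
        post = gmm_posteriors(params, values)
        classes[post.index.to_numpy()] = post["map_class"].to_numpy()
    else:
        warnings.warn(
            "fitted mixture components overlap (Ashman's D "
            f"{component_separation(params):.2f} < {min_separation}); "
            "track treated as unimodal, no probes assigned to the enriched "
            "class",
            stacklevel=2,
        )
    rows = []
    for promoter_id, idx in contained_probe_indices(promoters, track):
        call = call_promoter_enrichment(
            promoter_id, classes[idx], threshold=threshold, feature=feature
        )
        rows.append(
            (
                call.promoter_id,
                call.feature,
                call.n_probes,
                call.frac_class2,
                call.enriched,
            )
        )
    calls = pd.DataFrame(
        rows,
        columns=["promoter_id", "feature", "n_probes", "frac_class2", "enriched"],
    )
    return calls, params


def joint_binding(calls: pd.DataFrame, features: list[str]) -> pd.Series:
    """Logical AND of boolean per-feature calls across ``features``.

    ``calls`` is a wide table indexed by promoter_id with one boolean
    column per feature.  A missing feature column raises a KeyError naming
    the feature.  A single-feature list degenerates to that column.
    """
    for feat in features:
        if feat not in calls.columns:
            raise KeyError(f"feature column not found: {feat!r}")
    if not features:
        raise ValueError("features list is empty")
    out = calls[features].all(axis=1)
    out.name = "bound"
    return out


def running_mean_smooth(track: pd.DataFrame, window: int = 5) -> pd.DataFrame:
    """Optional running-mean smoother for raw probe tracks (per chromosome)."""
    if window < 1:
        raise ValueError("window must be >= 1")
    out = track.copy()
    if window == 1:
        return out
    kernel = np.ones(window) / window
    for chrom, sub in out.groupby("chrom", sort=False):
        sub = sub.sort_values("start", kind="mergesort")
        smoothed = np.convolve(sub["value"].to_numpy(), kernel, mode="same")
        out.loc[sub.index, "value"] = smoothed
    return out
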