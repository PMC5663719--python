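"""EM for 1-D Gaussian mixtures as a model of greedy-competitive matching.

Each rendition of a target syllable is an observed pitch sample; each of
the learner's own motor syllables (motif syllables and calls) is a
Gaussian component whose mean is initialized at the syllable's current
pitch.  Running EM lets components migrate to the data modes while the
shared responsibility normalization implements soft competition: two
components are discouraged from explaining the same mode.  The resulting
component->nearest-target mapping can be compared with the discrete
musical-chairs dynamics.

Only 1-D pitch space is modelled; the mismatches under study are pitch-only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = ["GMMState", "em_fit", "assign_by_responsibility"]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class GMMState:
    K: int
    weights: np.ndarray
    means: np.ndarray  # semitones
    variances: np.ndarray  # semitones^2
    responsibilities: np.ndarray  # n x K
    log_likelihood: float
    n_iter: int = 0
    converged: bool = False
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "K": self.K,
                "weights": self.weights.tolist(),
                "means": self.means.tolist(),
                "variances": self.variances.tolist(),
                "log_likelihood": self.log_likelihood,
                "n_iter": self.n_iter,
                "converged": self.converged,
            },
            indent=2,
        )


def _log_gauss(x: np.ndarray, mean: np.ndarray, var: np.ndarray) -> np.ndarray:
    # x: (n,), mean/var: (K,) -> (n, K)
    d = x[:, None] - mean[None, :]
    return -0.5 * (_LOG2PI + np.log(var)[None, :] + d * d / var[None, :])


def em_fit(samples: Sequence[float], K: int,
           init_means: Optional[Sequence[float]] = None,
           tol: float = 1e-8, max_iter: int = 500,
           var_floor: float = 1e-4) -> GMMState:
    """Fit a K-component 1-D Gaussian mixture by plain EM.

    ``init_means`` seeds the component means (defaults to evenly spaced
    sample quantiles); weights start uniform and variances at the sample
    variance.  Iterates E (responsibilities) and M (weights, means,
    variances) steps until the log-likelihood improves by less than
    ``tol`` or ``max_iter`` is reached.  The log-likelihood is
    non-decreasing up to the variance floor; a component whose variance
    collapses is clamped to ``var_floor`` with a logged warning.
    """
    x = np.asarray(samples, dtype=float).ravel()
    n = x.size
    if n < K:
        raise ValueError(f"need at least K={K} samples, got {n}")
    if var_floor <= 0:
        raise ValueError("var_floor must be positive")

    if init_means is None:
        qs = (np.arange(K) + 0.5) / K
        means = np.quantile(x, qs)
    else:
        means = np.asarray(init_means, dtype=float).copy()
        if means.size != K:
            raise ValueError("init_means length must equal K")
    var0 = max(float(np.var(x)), var_floor)
    variances = np.full(K, var0)
    weights = np.full(K, 1.0 / K)

    msgs: list[str] = []
    ll_prev = -np.inf
    resp = np.full((n, K), 1.0 / K)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E step
        logp = _log_gauss(x, means, variances) + np.log(weights)[None, :]
        lse = np.logaddexp.reduce(logp, axis=1)
        resp = np.exp(logp - lse[:, None])
        ll = float(lse.sum())
        # M step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        d = x[:, None] - means[None, :]
        variances = (resp * d * d).sum(axis=0) / nk
        if (variances < var_floor).any():
            collapsed = np.flatnonzero(variances < var_floor)
            msg = f"variance clamped to floor for components {collapsed.tolist()}"
            if msg not in msgs:
                msgs.append(msg)
                warnings.warn(msg, RuntimeWarning, stacklevel=2)
            variances = np.maximum(variances, var_floor)
        if ll - ll_prev < tol and np.isfinite(ll_prev):
            converged = True
            ll_prev = ll
            break
        ll_prev = ll

    # final E pass so responsibilities/ll match the returned parameters
    logp = _log_gauss(x, means, variances) + np.log(weights)[None, :]
    lse = np.logaddexp.reduce(logp, axis=1)
    resp = np.exp(logp - lse[:, None])
    return GMMState(K=K, weights=weights, means=means, variances=variances,
                    responsibilities=resp, log_likelihood=float(lse.sum()),
                    n_iter=it, converged=converged, warnings=msgs)


def assign_by_responsibility(state: GMMState,
                             motor_init: dict[str, float],
                             target_pitches: dict[str, float]
                             ) -> dict[str, str]:
    """Map each motor syllable to the target its component converged on.

    ``motor_init`` gives the initial mean of each motor syllable's
    component (the order of ``motor_init`` must match the component order
    used in :func:`em_fit`).  Each converged component mean is matched to
    the nearest target pitch; the returned mapping is motor label ->
    target label.  If two components land on the same target the mapping
    is not injective — callers comparing against musical-chairs report
    that as a disagreement.
    """
    labels = list(motor_init.keys())
    if len(labels) != state.K:
        raise ValueError("motor_init must have one entry per component")
    t_labels = list(target_pitches.keys())
    t_pitch = np.asarray([target_pitches[t] for t in t_labels], dtype=float)
    mapping: dict[str, str] = {}
    for k, lab in enumerate(labels):
        j = int(np.argmin(np.abs(state.means[k] - t_pitch)))
        mapping[lab] = t_labels[j]
    return mapping
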