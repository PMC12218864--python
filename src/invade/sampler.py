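"""Shared MCMC machinery: Hamiltonian Monte Carlo with analytic gradients.

All Bayesian fits in the package run through :func:`hmc_sample`: a plain HMC
sampler with dual-averaging step-size adaptation (target acceptance 0.8),
windowed diagonal mass-matrix estimation during warmup, and jittered leapfrog
trajectory lengths. Parameters whose gradients are awkward (the Gaussian
process hyperparameters, which enter through a Cholesky factor) can be placed
in an auxiliary block updated by random-walk Metropolis-within-Gibbs with
Robbins–Monro scale adaptation.

Convergence diagnostics (rank-normalised split-R̂ and bulk effective sample
size) are computed with ArviZ.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = ["SampleResult", "hmc_sample", "split_rhat", "ess", "ConvergenceWarning"]


class ConvergenceWarning(UserWarning):
    """Raised (as a warning, not an error) when R-hat exceeds threshold."""


@dataclass
class SampleResult:
    """Post-warmup draws from :func:`hmc_sample`.

    ``draws`` has shape (chains, iters, dim); when an auxiliary
    Metropolis block was used its coordinates are appended after the HMC
    coordinates. ``divergences`` counts rejected trajectories with exploding
    energy error per chain.
    """

    draws: np.ndarray
    accept_rate: np.ndarray
    step_size: np.ndarray
    divergences: np.ndarray
    seed: int
    warmup: int
    param_names: list[str] | None = None

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    def pooled(self) -> np.ndarray:
        """Draws pooled across chains, shape (chains*iters, dim)."""
        return self.draws.reshape(-1, self.draws.shape[-1])

    def diagnostics(self, names: Sequence[str] | None = None) -> dict:
        """Per-parameter split-R̂ and bulk ESS."""
        if names is None:
            names = self.param_names or [
                f"p{i}" for i in range(self.draws.shape[-1])
            ]
        out = {}
        for i, nm in enumerate(names):
            x = self.draws[:, :, i]
            out[nm] = {"rhat": split_rhat(x), "ess": ess(x)}
        return out

    def check_convergence(self, rhat_max: float = 1.01) -> "SampleResult":
        """Warn (``ConvergenceWarning``) if any parameter's R̂ > rhat_max."""
        diag = self.diagnostics()
        bad = {k: v["rhat"] for k, v in diag.items() if np.isfinite(v["rhat"]) and v["rhat"] > rhat_max}
        if bad:
            worst = max(bad.values())
            warnings.warn(
                f"{len(bad)} parameter(s) with split-R-hat > {rhat_max} "
                f"(worst {worst:.3f}); treat estimates with caution",
                ConvergenceWarning,
                stacklevel=2,
            )
        return self


def split_rhat(x: np.ndarray) -> float:
    """Rank-normalised split-R̂ for one parameter, x shape (chains, iters).

    Returns NaN for constant chains (diagnostic undefined).
    """
    import arviz as az

    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 4:
        raise ValueError("need (chains>=2, iters>=4) draws")
    if np.allclose(x, x.flat[0]):
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.rhat(az.convert_to_dataset(x))["x"].values)


def ess(x: np.ndarray) -> float:
    """Bulk effective sample size for one parameter, x shape (chains, iters)."""
    import arviz as az

    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 4:
        raise ValueError("need (chains>=2, iters>=4) draws")
    if np.allclose(x, x.flat[0]):
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.ess(az.convert_to_dataset(x))["x"].values)


def _dual_averaging_state(eps0: float, target: float):
    return {
        "mu": math.log(10.0 * eps0),
        "log_eps": math.log(eps0),
        "log_eps_bar": 0.0,
        "h_bar": 0.0,
        "t": 0,
        "gamma": 0.05,
        "t0": 10.0,
        "kappa": 0.75,
        "target": target,
    }


def _dual_averaging_update(state: dict, accept_prob: float) -> float:
    state["t"] += 1
    t = state["t"]
    eta = 1.0 / (t + state["t0"])
    state["h_bar"] = (1 - eta) * state["h_bar"] + eta * (state["target"] - accept_prob)
    log_eps = state["mu"] - math.sqrt(t) / state["gamma"] * state["h_bar"]
    w = t ** (-state["kappa"])
    state["log_eps_bar"] = w * log_eps + (1 - w) * state["log_eps_bar"]
    state["log_eps"] = log_eps
    return math.exp(log_eps)


def hmc_sample(
    logp_grad: Callable,
    init: np.ndarray,
    chains: int = 2,
    warmup: int = 500,
    iters: int = 500,
    seed: int = 0,
    target_accept: float = 0.8,
    leapfrog_range: tuple[int, int] = (8, 32),
    init_jitter: float = 0.5,
    aux_init: np.ndarray | None = None,
    aux_scale: float = 0.3,
    aux_positive: bool = False,
    param_names: Sequence[str] | None = None,
    check: bool = False,
) -> SampleResult:
    """Sample a log-density with HMC (plus optional Metropolis aux block).

    Parameters
    ----------
    logp_grad
        ``f(theta) -> (logp, grad)`` — or, when ``aux_init`` is given,
        ``f(theta, aux) -> (logp, grad_theta)``; ``logp`` must include the
        aux prior since the Metropolis block reuses it.
    init
        Initial HMC coordinate vector; each chain starts at ``init`` plus
        N(0, init_jitter²) noise.
    aux_init
        Optional initial vector for a random-walk Metropolis block updated
        once per HMC iteration (used for GP hyperparameters). Stored after
        the HMC coordinates in the output draws.
    aux_positive
        If True, aux coordinates are proposed on the log scale (they must be
        strictly positive).

    Reproducible given ``seed``: identical seeds give identical draws.
    """
    init = np.asarray(init, dtype=float)
    dim = init.size
    has_aux = aux_init is not None
    aux_dim = 0 if not has_aux else np.asarray(aux_init, float).size
    total_dim = dim + aux_dim

    all_draws = np.empty((chains, iters, total_dim))
    acc_rates = np.empty(chains)
    final_eps = np.empty(chains)
    n_div = np.zeros(chains, dtype=int)

    lmin, lmax = leapfrog_range
    w1 = max(1, int(0.3 * warmup))
    w2 = max(w1 + 1, int(0.85 * warmup))

    for c in range(chains):
        rng = np.random.default_rng([seed, c, 7919])
        theta = init + init_jitter * rng.standard_normal(dim)
        aux = None if not has_aux else np.asarray(aux_init, float).copy()
        a_scale = aux_scale
        aux_acc_target = 0.3

        def f(th, au=None):
            if has_aux:
                return logp_grad(th, au)
            return logp_grad(th)

        lp, grad = f(theta, aux)
        if not np.isfinite(lp):
            # pull back toward init until density is finite
            for _ in range(50):
                theta = init + 0.01 * rng.standard_normal(dim)
                lp, grad = f(theta, aux)
                if np.isfinite(lp):
                    break
            else:
                raise ValueError("could not find a finite-density starting point")

        inv_mass = np.ones(dim)
        eps = 0.1
        da = _dual_averaging_state(eps, target_accept)
        mass_buf: list[np.ndarray] = []
        n_accept = 0

        for it in range(warmup + iters):
            in_warmup = it < warmup
            # --- HMC update of theta ---
            p = rng.standard_normal(dim) / np.sqrt(inv_mass)
            n_leap = int(rng.integers(lmin, lmax + 1))
            th_new, p_new, g_new = theta.copy(), p.copy(), grad.copy()
            lp_new = lp
            h0 = lp - 0.5 * float(p * inv_mass @ p)
            diverged = False
            for _ in range(n_leap):
                p_new = p_new + 0.5 * eps * g_new
                th_new = th_new + eps * inv_mass * p_new
                lp_new, g_new = f(th_new, aux)
                if not np.all(np.isfinite(g_new)) or not np.isfinite(lp_new):
                    diverged = True
                    break
                p_new = p_new + 0.5 * eps * g_new
            if diverged:
                a_prob = 0.0
            else:
                h1 = lp_new - 0.5 * float(p_new * inv_mass @ p_new)
                dh = h1 - h0
                if dh < -1000.0:
                    diverged = True
                    a_prob = 0.0
                else:
                    a_prob = min(1.0, math.exp(min(0.0, dh)))
            if diverged and not in_warmup:
                n_div[c] += 1
            if (not diverged) and rng.random() < a_prob:
                theta, lp, grad = th_new, lp_new, g_new
                if not in_warmup:
                    n_accept += 1
            if in_warmup:
                eps = _dual_averaging_update(da, a_prob)
                if w1 <= it < w2:
                    mass_buf.append(theta.copy())
                if it == w2 - 1 and len(mass_buf) >= 10:
                    samp = np.asarray(mass_buf)
                    var = samp.var(axis=0, ddof=1)
                    n = len(mass_buf)
                    inv_mass = (n / (n + 5.0)) * var + 1e-3 * (5.0 / (n + 5.0))
                    eps0 = math.exp(da["log_eps_bar"]) if da["t"] else eps
                    da = _dual_averaging_state(max(eps0, 1e-6), target_accept)
                if it == warmup - 1:
                    eps = math.exp(da["log_eps_bar"])
            # --- Metropolis update of aux block ---
            if has_aux:
                if aux_positive:
                    prop = aux * np.exp(a_scale * rng.standard_normal(aux_dim))
                    log_jac = float(np.sum(np.log(prop) - np.log(aux)))
                else:
                    prop = aux + a_scale * rng.standard_normal(aux_dim)
                    log_jac = 0.0
                lp_prop, g_prop = f(theta, prop)
                a = min(1.0, math.exp(min(0.0, lp_prop - lp + log_jac))) if np.isfinite(lp_prop) else 0.0
                if rng.random() < a:
                    aux, lp, grad = prop, lp_prop, g_prop
                if in_warmup:
                    a_scale = max(1e-3, a_scale * math.exp(0.5 * (a - aux_acc_target) / math.sqrt(it + 1)))
            if not in_warmup:
                j = it - warmup
                all_draws[c, j, :dim] = theta
                if has_aux:
                    all_draws[c, j, dim:] = aux

        acc_rates[c] = n_accept / iters
        final_eps[c] = eps

    res = SampleResult(
        draws=all_draws,
        accept_rate=acc_rates,
        step_size=final_eps,
        divergences=n_div,
        seed=seed,
        warmup=warmup,
        param_names=list(param_names) if param_names is not None else None,
    )
    if check:
        res.check_convergence()
    return res
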