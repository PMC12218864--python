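"""Posterior summaries: sign probabilities, nested intervals, effect curves.

Effects are reported three ways, mirroring the analysis's figures: the
posterior probability that the exposure slope is positive (P(+ve effect)),
central compatibility intervals at nested levels {95, 89, 80, 70, 60, 50}%,
and marginal effect curves that push each posterior draw through the inverse
link over a grid of exposure values with every other covariate held at its
(standardized) mean and the spatial field at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .models import PosteriorDraws

__all__ = [
    "DEFAULT_LEVELS",
    "EffectSummary",
    "p_positive",
    "compatibility_intervals",
    "marginal_effect_curve",
    "effect_matrix",
    "summarize_effect",
]

DEFAULT_LEVELS = (95, 89, 80, 70, 60, 50)


def _pooled(draws, parameter: str | None) -> np.ndarray:
    if isinstance(draws, PosteriorDraws):
        if parameter is None:
            raise ValueError("parameter name required with PosteriorDraws input")
        return draws.pooled(parameter)
    return np.asarray(draws, dtype=float).ravel()


def p_positive(draws, parameter: str | None = None) -> float:
    """Fraction of pooled post-warmup draws strictly greater than zero."""
    x = _pooled(draws, parameter)
    return float((x > 0).mean())


def compatibility_intervals(
    draws, parameter: str | None = None, levels: Sequence[float] = DEFAULT_LEVELS
) -> pd.DataFrame:
    """Central posterior intervals at the given percentage levels.

    Level L spans the ((100−L)/2, 100−(100−L)/2) quantiles, so intervals at
    decreasing levels are nested by construction.
    """
    x = _pooled(draws, parameter)
    rows = []
    for lv in levels:
        if not 0 < lv < 100:
            raise ValueError(f"interval level {lv} outside (0, 100)")
        tail = (100.0 - lv) / 200.0
        if len(x) < 1.0 / min(tail, 1 - tail):
            import warnings

            warnings.warn(
                f"only {len(x)} draws for a {lv}% interval; extreme quantiles unstable",
                stacklevel=2,
            )
        lo, hi = np.quantile(x, [tail, 1.0 - tail])
        rows.append({"level": lv, "lower": lo, "upper": hi})
    return pd.DataFrame(rows)


_INV_LINK = {"occupancy": expit, "count": np.exp, "night": expit}


def marginal_effect_curve(
    draws: PosteriorDraws,
    exposure_grid: Sequence[float],
    season: int = 1,
    levels: Sequence[float] = DEFAULT_LEVELS,
    lunar_at: float = 0.5,
    grid_is_standardized: bool = False,
) -> pd.DataFrame:
    """Response-scale marginal effect of the exposure over a grid.

    For each grid value the exposure is set to that value (converted to
    standardized units via the fit's scaling record unless
    ``grid_is_standardized``), all other covariates sit at 0 (their
    standardized mean), the spatial field at 0, and detection/camera nuisance
    parameters at their reference. Each posterior draw is pushed through the
    inverse link (logistic for occupancy and night proportion, exponential
    for counts); the night model's lunar covariate is held at ``lunar_at``.

    Grid points outside the observed exposure range (mean ± 3 sd once
    standardized) trigger an extrapolation warning but are still computed.
    """
    spec = draws.spec
    if spec is None:
        raise ValueError("draws carry no ModelSpec; fit via sample_posterior")
    grid = np.asarray(exposure_grid, dtype=float)
    if grid_is_standardized or spec.exposure not in draws.scaling:
        gstd = grid
    else:
        mu, sd = draws.scaling[spec.exposure]
        gstd = (grid - mu) / sd
    if np.any(np.abs(gstd) > 3.0):
        import warnings

        warnings.warn(
            "exposure grid extends beyond ±3 sd of the observed exposure; "
            "curve values there are extrapolation",
            stacklevel=2,
        )

    alpha = draws.pooled("alpha")
    beta = draws.pooled(f"beta[{spec.exposure},s{season}]")
    lin = alpha[None, :] + beta[None, :] * gstd[:, None]
    if spec.response == "night":
        lin = lin + draws.pooled(f"beta_lunar[s{season}]")[None, :] * lunar_at
        if spec.lunar_interaction:
            lin = lin + (
                draws.pooled(f"beta_op_lunar[s{season}]")[None, :]
                * gstd[:, None] * lunar_at
            )
    resp = _INV_LINK[spec.response](lin)

    out = pd.DataFrame({"exposure": grid, "median": np.median(resp, axis=1)})
    for lv in levels:
        tail = (100.0 - lv) / 200.0
        out[f"q{tail * 100:g}"] = np.quantile(resp, tail, axis=1)
        out[f"q{(1 - tail) * 100:g}"] = np.quantile(resp, 1 - tail, axis=1)
    return out


@dataclass(frozen=True)
class EffectSummary:
    """One cell of the effect matrix: species × season × scale × model."""

    species: str
    season: int
    scale: str  # "site_cover" | "square_volume"
    model: str  # "occupancy" | "count" | "night"
    p_positive: float
    intervals: tuple = field(default_factory=tuple, compare=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_positive <= 1.0:
            raise ValueError("p_positive must lie in [0, 1]")


def summarize_effect(
    draws: PosteriorDraws, species: str, season: int, scale: str
) -> EffectSummary:
    """Build an :class:`EffectSummary` for the exposure slope of a fit."""
    spec = draws.spec
    name = f"beta[{spec.exposure},s{season}]"
    ci = compatibility_intervals(draws, name)
    return EffectSummary(
        species=species,
        season=season,
        scale=scale,
        model=spec.response,
        p_positive=p_positive(draws, name),
        intervals=tuple(map(tuple, ci.to_numpy())),
    )


def effect_matrix(summaries: Sequence[EffectSummary]) -> pd.DataFrame:
    """Species × (season, scale, model) table of P(+ve effect).

    Rows are species in first-appearance order; missing cells stay NaN and
    duplicate cells are rejected.
    """
    if not summaries:
        return pd.DataFrame()
    seen = set()
    for s in summaries:
        key = (s.species, s.season, s.scale, s.model)
        if key in seen:
            raise ValueError(f"duplicate effect cell {key}")
        seen.add(key)
    species_order = list(dict.fromkeys(s.species for s in summaries))
    df = pd.DataFrame(
        [
            {"species": s.species, "season": s.season, "scale": s.scale,
             "model": s.model, "p_positive": s.p_positive}
            for s in summaries
        ]
    )
    mat = df.pivot_table(
        index="species", columns=["season", "scale", "model"],
        values="p_positive", aggfunc="first",
    )
    return mat.reindex(species_order)


def plot_effect_matrix(matrix: pd.DataFrame, path=None):
    """Heatmap of P(+ve effect): blue near 1, red near 0, white at 0.5."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1 + matrix.shape[1], 1 + 0.4 * matrix.shape[0]))
    im = ax.imshow(matrix.to_numpy(float), cmap="RdBu", vmin=0, vmax=1, aspect="auto")
    ax.set_yticks(range(matrix.shape[0]), matrix.index)
    ax.set_xticks(
        range(matrix.shape[1]),
        ["/".join(str(x) for x in c) for c in matrix.columns],
        rotation=90,
    )
    fig.colorbar(im, label="P(+ve effect)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_marginal_curve(curve: pd.DataFrame, levels=DEFAULT_LEVELS, path=None, ylabel="response"):
    """Marginal effect curve with nested shaded compatibility bands."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for i, lv in enumerate(sorted(levels, reverse=True)):
        tail = (100.0 - lv) / 200.0
        ax.fill_between(
            curve["exposure"], curve[f"q{tail * 100:g}"], curve[f"q{(1 - tail) * 100:g}"],
            alpha=0.18 + 0.04 * i, color="C0", lw=0,
        )
    ax.plot(curve["exposure"], curve["median"], color="C0")
    ax.set_xlabel("exposure")
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
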