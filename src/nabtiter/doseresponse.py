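"""Bayesian ND50 estimation from transduction curves.

The ND50 is the serum dilution at which transduction drops to 50% of the
antibody-free control.  Two fitting routes are provided, mirroring how each
kind of series behaves in practice:

* :class:`HillCurveModel` — a four-parameter Hill (4PL) curve

      y(x) = bottom + (top - bottom) / (1 + 2**(slope * (x - x50)))

  on the log2-dilution axis ``x = log2(dilution fraction)``, sampled with an
  affine-invariant ensemble MCMC (emcee).  Appropriate for clean sigmoidal
  series such as monoclonal-antibody calibrations.  Under the orientation
  convention, ``slope > 0`` and transduction decreases as serum content
  increases (x toward log2(1/4)).

* :class:`LinearND50Model` — Bayesian simple linear regression of
  transduction % on log2 dilution, with the ND50 taken as the posterior of
  the 50% crossing of the fitted line.  More robust for serum series whose
  curves are incomplete or non-sigmoidal, and therefore the default for all
  serum samples so both assay formats are compared on equal footing.

Both routes report the posterior median and a 95% equal-tailed credible
interval on the dilution scale, and both feed :func:`apply_censoring`:
an estimate weaker than the strongest tested serum concentration
(dilution fraction above 1/4, i.e. titer below 4) or the absence of a 50%
crossing yields a censored result displayed as the 1/1 placeholder titer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy.special import expit

from .normalize import CurvePoint, TransductionCurve

_LN2 = math.log(2.0)
_PARAM_NAMES = ("bottom", "top", "slope", "log2_nd50", "sigma")


@dataclass(frozen=True)
class HillPriors:
    """Weakly-informative priors for the four-parameter Hill fit.

    The assay constructs both asymptotes: the top sits near 100% of control
    by normalization and the bottom near 0% at saturating antibody.  The
    ND50 location prior is uniform over the tested log2-dilution range
    padded by ``nd50_pad_log2`` doublings on each side.
    """

    bottom_loc: float = 0.0
    bottom_scale: float = 20.0
    bottom_min: float = -10.0
    top_loc: float = 100.0
    top_scale: float = 20.0
    log_slope_loc: float = 0.0   # lognormal(0, 1) on the slope
    log_slope_scale: float = 1.0
    nd50_pad_log2: float = 2.0
    sigma_scale: float = 10.0    # half-Normal(0, 10) on the noise SD (%)


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings: 4 chains x 2000 post-warmup draws by default.

    The ensemble sampler runs ``walkers`` walkers with a mixture of
    differential-evolution moves (better mixing than the stretch move on
    this correlated 5-parameter posterior); retained steps are thinned by
    ``thin`` and chosen so the total post-warmup draw count is
    ``n_chains * draws_per_chain``.  Convergence is flagged when the
    split-chain rank-normalized R-hat of any parameter exceeds
    ``rhat_threshold``.
    """

    n_chains: int = 4
    draws_per_chain: int = 2000
    warmup: int = 500
    thin: int = 3
    walkers: int = 20
    rhat_threshold: float = 1.01

    @property
    def total_draws(self) -> int:
        return self.n_chains * self.draws_per_chain

    @property
    def kept_steps(self) -> int:
        return math.ceil(self.total_draws / self.walkers)


@dataclass
class ND50Result:
    """Titer estimate on the dilution scale with censoring status."""

    sample_id: str
    serotype: str
    format: str
    nd50: Optional[float]        # dilution fraction; None when no crossing
    ci_low: Optional[float]      # 95% credible interval (dilution fractions)
    ci_high: Optional[float]
    model: str                   # "hill" | "linear"
    censored: bool
    display_titer: Fraction      # 1/1 placeholder when censored

    def __post_init__(self):
        if self.censored:
            self.display_titer = Fraction(1, 1)
        elif self.nd50 is not None:
            # display convention: titers shown as 1/k with k the rounded
            # reciprocal dilution (the decimal nd50 stays authoritative)
            self.display_titer = Fraction(1, max(1, round(1.0 / self.nd50)))

    @property
    def log2_nd50(self) -> Optional[float]:
        return None if self.nd50 is None else math.log2(self.nd50)


def apply_censoring(
    raw_nd50: Optional[float],
    tested_dilutions: Sequence,
    *,
    ci: tuple = (None, None),
    sample_id: str = "",
    serotype: str = "",
    format: str = "",
    model: str = "linear",
) -> ND50Result:
    """Apply the placeholder-titer censoring rule.

    A raw estimate of ``None`` (no 50% crossing) or an estimate weaker than
    the strongest tested serum concentration (dilution fraction greater than
    max(tested), i.e. titer below the strongest tested titer) is censored
    and displayed as the 1/1 placeholder; anything else passes through.
    """
    if not tested_dilutions:
        raise ValueError("tested_dilutions must be non-empty")
    strongest = max(float(d) for d in tested_dilutions)
    censored = raw_nd50 is None or raw_nd50 > strongest * (1 + 1e-9)
    return ND50Result(
        sample_id=sample_id,
        serotype=serotype,
        format=format,
        nd50=raw_nd50,
        ci_low=None if censored else ci[0],
        ci_high=None if censored else ci[1],
        model=model,
        censored=censored,
        display_titer=Fraction(1, 1),
    )


def _curve_arrays(points) -> tuple:
    x = np.array([math.log2(float(p.dilution)) for p in points])
    m = np.array([p.mean_pct for p in points])
    s = np.array([p.sd_pct for p in points])
    n = np.array([p.n for p in points], dtype=float)
    return x, m, s, n


# ---------------------------------------------------------------------------
# four-parameter Hill model
# ---------------------------------------------------------------------------


class HillCurveModel:
    """Four-parameter Hill dose-response model for one transduction curve.

    The likelihood is Normal on the transduction-% scale.  Replicate
    information enters exactly through the per-dilution sufficient
    statistics (mean, SD, n): for n replicates with sample mean m and SD s,

        loglik = -n log sigma - [(n-1) s^2 + n (m - mu)^2] / (2 sigma^2) + const.

    Parameters are (bottom, top, slope, x50, sigma) with slope and sigma
    sampled on the log scale (lognormal / half-Normal priors).

    Because every point of a curve is divided by the same (noisy) control
    mean, normalization introduces a scale error shared across the whole
    curve.  When the curve carries a non-zero ``control_rse`` the model adds
    a shared scale nuisance c with log c ~ Normal(0, control_rse), fits
    mu_i = c * hill(x_i), and reports the ND50 from the descaled (true)
    curve — so credible intervals reflect the normalization uncertainty.
    """

    def __init__(
        self,
        curve: TransductionCurve,
        priors: Optional[HillPriors] = None,
        mcmc: Optional[MCMCConfig] = None,
    ):
        if len({p.dilution for p in curve.points}) < 4:
            raise ValueError(
                "Hill fit needs at least 4 distinct dilution points "
                "(one per parameter)"
            )
        self.curve = curve
        self.priors = priors or HillPriors()
        self.mcmc = mcmc or MCMCConfig()
        self._x, self._m, self._s, self._n = _curve_arrays(curve.points)
        pad = self.priors.nd50_pad_log2
        self._x50_lo = float(self._x.min()) - pad
        self._x50_hi = float(self._x.max()) + pad
        self.control_rse = float(getattr(curve, "control_rse", 0.0) or 0.0)
        self.ndim = 6 if self.control_rse > 0 else 5

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, sample_id: str = "", serotype: str = "",
                       format: str = "CSC", **kwargs) -> "HillCurveModel":
        """Build from a long table with columns dilution, transduction_pct.

        Replicate rows at the same dilution are aggregated to (mean, SD, n).
        """
        points = []
        for dilution, grp in df.groupby("dilution"):
            vals = np.asarray(grp["transduction_pct"], dtype=float)
            points.append(
                CurvePoint(
                    dilution=Fraction(dilution).limit_denominator(10**6),
                    mean_pct=float(vals.mean()),
                    sd_pct=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                    n=int(vals.size),
                )
            )
        points.sort(key=lambda p: float(p.dilution))
        curve = TransductionCurve(
            sample_id=sample_id, serotype=serotype, format=format,
            points=points, control_mean_rlu=float("nan"),
        )
        return cls(curve, **kwargs)

    # -- posterior density --------------------------------------------------

    def _log_post(self, theta: np.ndarray) -> np.ndarray:
        """Vectorized log posterior; theta has shape (k, 5) or (k, 6)."""
        theta = np.atleast_2d(theta)
        b, t, lsl, x50, lsg = theta[:, :5].T
        logc = theta[:, 5] if self.ndim == 6 else np.zeros(theta.shape[0])
        pr = self.priors
        ok = (
            (b >= pr.bottom_min)
            & (b < t)
            & (x50 >= self._x50_lo)
            & (x50 <= self._x50_hi)
            & (np.abs(lsl) < 20)
            & (lsg > -20)
            & (lsg < 20)
            & (np.abs(logc) < 2)
        )
        lp = np.full(theta.shape[0], -np.inf)
        if not ok.any():
            return lp
        b, t, lsl, x50, lsg, logc = (a[ok] for a in (b, t, lsl, x50, lsg, logc))
        slope = np.exp(lsl)
        sigma = np.exp(lsg)
        # priors (log slope ~ Normal == lognormal on slope; Jacobian for
        # sigma sampled on the log scale: + lsg)
        prior = (
            -0.5 * ((b - pr.bottom_loc) / pr.bottom_scale) ** 2
            - 0.5 * ((t - pr.top_loc) / pr.top_scale) ** 2
            - 0.5 * ((lsl - pr.log_slope_loc) / pr.log_slope_scale) ** 2
            - 0.5 * (sigma / pr.sigma_scale) ** 2
            + lsg
        )
        if self.ndim == 6:
            prior = prior - 0.5 * (logc / self.control_rse) ** 2
        z = slope[:, None] * (self._x[None, :] - x50[:, None])
        mu = b[:, None] + (t - b)[:, None] * expit(-_LN2 * z)
        mu = np.exp(logc)[:, None] * mu
        ntot = self._n.sum()
        ss = (self._n - 1) * self._s**2
        resid = (ss[None, :] + self._n[None, :] * (self._m[None, :] - mu) ** 2).sum(
            axis=1
        )
        loglik = -ntot * lsg - resid / (2.0 * sigma**2)
        lp[ok] = prior + loglik
        return lp

    def _initial_walkers(self, rng: np.random.Generator) -> np.ndarray:
        top0 = float(self._m.max())
        bot0 = max(float(self._m.min()), self.priors.bottom_min + 1.0)
        if top0 - bot0 < 1.0:
            top0, bot0 = bot0 + 1.0, bot0
        mid = 0.5 * (top0 + bot0)
        x50_0 = float(self._x[np.argmin(np.abs(self._m - mid))])
        x50_0 = min(max(x50_0, self._x50_lo + 0.1), self._x50_hi - 0.1)
        sig0 = max(float(np.nanmean(self._s)), 1.0)
        center = np.array([bot0, top0, 0.0, x50_0, math.log(sig0)])
        scale = np.array([2.0, 2.0, 0.2, 0.3, 0.2])
        if self.ndim == 6:
            center = np.append(center, 0.0)
            scale = np.append(scale, 0.5 * self.control_rse)
        nw = self.mcmc.walkers
        p0 = center + scale * rng.standard_normal((nw, self.ndim))
        p0[:, 0] = np.clip(p0[:, 0], self.priors.bottom_min, None)
        p0[:, 3] = np.clip(p0[:, 3], self._x50_lo, self._x50_hi)
        bad = p0[:, 0] >= p0[:, 1]
        p0[bad, 1] = p0[bad, 0] + 1.0
        return p0

    def fit(self, seed: int = 0) -> "HillCurveResults":
        """Run the ensemble sampler; reproducible given the seed."""
        rng = np.random.default_rng(seed)
        nw = self.mcmc.walkers
        moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
        sampler = emcee.EnsembleSampler(
            nw, self.ndim, self._log_post, vectorize=True, moves=moves
        )
        sampler.random_state = np.random.RandomState(
            int(np.random.SeedSequence(seed).generate_state(1)[0])
        ).get_state()
        p0 = self._initial_walkers(rng)
        total = self.mcmc.warmup + self.mcmc.kept_steps * self.mcmc.thin
        sampler.run_mcmc(p0, total, progress=False, skip_initial_state_check=True)
        chain = sampler.get_chain(discard=self.mcmc.warmup, thin=self.mcmc.thin)
        return HillCurveResults(self, chain, seed)


class HillCurveResults:
    """Posterior of a four-parameter Hill fit.

    Draws are exposed per parameter on the natural scale (slope and sigma
    exponentiated).  The ND50 is summarized from the posterior of the
    absolute 50%-of-control crossing, which for a draw with
    ``bottom < 50 < top`` sits at

        x = x50 + log2((top - 50) / (50 - bottom)) / slope.
    """

    def __init__(self, model: HillCurveModel, chain: np.ndarray, seed: int):
        self.model = model
        self.seed = seed
        self._chain = chain  # (steps, walkers, ndim)
        flat = chain.reshape(-1, model.ndim)
        self.draws = {
            "bottom": flat[:, 0],
            "top": flat[:, 1],
            "slope": np.exp(flat[:, 2]),
            "log2_nd50": flat[:, 3],
            "sigma": np.exp(flat[:, 4]),
        }
        if model.ndim == 6:
            self.draws["norm_scale"] = np.exp(flat[:, 5])
        self.rhat = self._compute_rhat()
        self.converged = all(v <= model.mcmc.rhat_threshold for v in self.rhat.values())

    def _compute_rhat(self) -> dict:
        # Walkers grouped into n_chains pseudo-chains (draws within a chain
        # pooled walker-major), giving n_chains x draws_per_chain draws per
        # parameter for the split-chain rank-normalized diagnostic.
        cfg = self.model.mcmc
        nw = cfg.walkers
        wpc = max(1, nw // cfg.n_chains)
        per_param = {
            "bottom": self._chain[:, :, 0],
            "top": self._chain[:, :, 1],
            "slope": np.exp(self._chain[:, :, 2]),
            "log2_nd50": self._chain[:, :, 3],
            "sigma": np.exp(self._chain[:, :, 4]),
        }
        if self.model.ndim == 6:
            per_param["norm_scale"] = np.exp(self._chain[:, :, 5])
        out = {}
        for name, arr in per_param.items():
            chains = np.stack(
                [
                    arr[:, g * wpc : (g + 1) * wpc].T.ravel()
                    for g in range(cfg.n_chains)
                ]
            )
            out[name] = float(az.rhat(az.convert_to_dataset({name: chains}))[name])
        return out

    # -- summaries ----------------------------------------------------------

    def summary(self) -> pd.DataFrame:
        """Posterior summary table (mean, sd, median, 95% CI, R-hat)."""
        rows = []
        for name in self.draws:
            d = self.draws[name]
            lo, med, hi = np.percentile(d, [2.5, 50.0, 97.5])
            rows.append(
                {
                    "param": name,
                    "mean": float(d.mean()),
                    "sd": float(d.std(ddof=1)),
                    "median": float(med),
                    "ci_2.5%": float(lo),
                    "ci_97.5%": float(hi),
                    "rhat": self.rhat[name],
                }
            )
        return pd.DataFrame(rows).set_index("param")

    def crossing_log2_draws(self) -> np.ndarray:
        """Posterior draws of the 50%-of-control crossing (log2 dilution)."""
        b, t = self.draws["bottom"], self.draws["top"]
        mask = (b < 50.0) & (t > 50.0)
        if not mask.any():
            return np.empty(0)
        ratio = (t[mask] - 50.0) / (50.0 - b[mask])
        return self.draws["log2_nd50"][mask] + np.log2(ratio) / self.draws["slope"][mask]

    @property
    def crossing_probability(self) -> float:
        """Posterior probability that the curve crosses 50% at all."""
        b, t = self.draws["bottom"], self.draws["top"]
        return float(((b < 50.0) & (t > 50.0)).mean())

    def nd50_result(self) -> ND50Result:
        """ND50 point estimate + 95% CI with the censoring rule applied.

        If fewer than half the posterior draws admit a 50% crossing the fit
        is treated as non-identifiable for the ND50 (flat / fully masked
        curve) and reported censored with no estimate.
        """
        curve = self.model.curve
        meta = dict(
            sample_id=curve.sample_id,
            serotype=curve.serotype,
            format=curve.format,
            model="hill",
        )
        if self.crossing_probability < 0.5:
            return apply_censoring(None, curve.dilutions, **meta)
        xc = self.crossing_log2_draws()
        lo, med, hi = np.percentile(xc, [2.5, 50.0, 97.5])
        return apply_censoring(
            float(2.0**med),
            curve.dilutions,
            ci=(float(2.0**lo), float(2.0**hi)),
            **meta,
        )

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Posterior-mean curve at log2 dilutions ``x``."""
        x = np.asarray(x, dtype=float)
        z = self.draws["slope"][:, None] * (x[None, :] - self.draws["log2_nd50"][:, None])
        mu = (
            self.draws["bottom"][:, None]
            + (self.draws["top"] - self.draws["bottom"])[:, None] * expit(-_LN2 * z)
        )
        return mu.mean(axis=0)

    def plot(self, ax=None):
        """Diagnostic plot: data points and the posterior-mean curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x, m, s, _ = _curve_arrays(self.model.curve.points)
        grid = np.linspace(x.min() - 1, x.max() + 1, 100)
        ax.errorbar(x, m, yerr=s, fmt="o", label="data")
        ax.plot(grid, self.predict(grid), label="posterior mean")
        ax.axhline(50.0, ls="--", color="gray")
        ax.set_xlabel("log2 serum dilution")
        ax.set_ylabel("transduction (% of control)")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# linear model
# ---------------------------------------------------------------------------


class LinearND50Model:
    """Bayesian simple linear regression of transduction % on log2 dilution.

    Uses the standard noninformative reference prior, giving the usual
    Normal-inverse-chi-square posterior over (intercept, slope, sigma^2);
    the ND50 posterior is the distribution of the 50% crossing of the line.
    With exactly two points (or a perfect fit) the posterior degenerates to
    the least-squares line and the crossing is deterministic.
    """

    def __init__(self, curve: TransductionCurve, window: Optional[tuple] = None):
        points = curve.points
        if window is not None:
            lo, hi = (float(Fraction(w)) for w in window)
            points = [p for p in points if lo <= float(p.dilution) <= hi]
        if len({p.dilution for p in points}) < 2:
            raise ValueError("linear fit needs at least 2 distinct dilution points")
        self.curve = curve
        self.points = points
        self._x, self._y, _, self._n = _curve_arrays(points)
        if np.ptp(self._x) == 0:
            raise ValueError("zero variance in predictor (all dilutions equal)")

    def fit(self, seed: int = 0, n_draws: int = 8000) -> "LinearND50Results":
        rng = np.random.default_rng(seed)
        x, y = self._x, self._y
        n = x.size
        X = np.column_stack([np.ones(n), x])
        xtx = X.T @ X
        xtx_inv = np.linalg.inv(xtx)
        beta_hat = xtx_inv @ X.T @ y
        resid = y - X @ beta_hat
        ssr = float(resid @ resid)
        dof = n - 2
        if dof <= 0 or ssr < 1e-12 * max(1.0, float(y @ y)):
            draws = np.tile(beta_hat, (n_draws, 1))
            return LinearND50Results(self, draws, deterministic=True, seed=seed)
        s2 = ssr / dof
        sigma2 = dof * s2 / rng.chisquare(dof, size=n_draws)
        L = np.linalg.cholesky(xtx_inv)
        noise = rng.standard_normal((n_draws, 2)) @ L.T
        draws = beta_hat[None, :] + np.sqrt(sigma2)[:, None] * noise
        return LinearND50Results(self, draws, deterministic=False, seed=seed)


class LinearND50Results:
    """Posterior of the linear ND50 fit (intercept/slope draws)."""

    #: slope must be credibly negative (transduction falling as serum
    #: content rises) for the 50% crossing to be meaningful
    SLOPE_SIGN_CONFIDENCE = 0.95

    def __init__(self, model: LinearND50Model, draws: np.ndarray,
                 deterministic: bool, seed: int):
        self.model = model
        self.draws = draws  # (n_draws, 2): intercept, slope
        self.deterministic = deterministic
        self.seed = seed

    @property
    def intercept_draws(self) -> np.ndarray:
        return self.draws[:, 0]

    @property
    def slope_draws(self) -> np.ndarray:
        return self.draws[:, 1]

    @property
    def prob_negative_slope(self) -> float:
        return float((self.slope_draws < 0).mean())

    def crossing_log2_draws(self) -> np.ndarray:
        """Draws of the log2 dilution where the fitted line hits 50%."""
        a, b = self.intercept_draws, self.slope_draws
        mask = b < 0
        return (50.0 - a[mask]) / b[mask]

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, d in (("intercept", self.intercept_draws),
                        ("slope", self.slope_draws)):
            lo, med, hi = np.percentile(d, [2.5, 50.0, 97.5])
            rows.append(
                {
                    "param": name,
                    "mean": float(d.mean()),
                    "sd": float(d.std(ddof=1)),
                    "median": float(med),
                    "ci_2.5%": float(lo),
                    "ci_97.5%": float(hi),
                }
            )
        return pd.DataFrame(rows).set_index("param")

    def nd50_result(self) -> ND50Result:
        """ND50 with censoring: requires a credibly negative slope."""
        curve = self.model.curve
        meta = dict(
            sample_id=curve.sample_id,
            serotype=curve.serotype,
            format=curve.format,
            model="linear",
        )
        if self.prob_negative_slope < self.SLOPE_SIGN_CONFIDENCE:
            return apply_censoring(None, curve.dilutions, **meta)
        xc = self.crossing_log2_draws()
        lo, med, hi = np.percentile(xc, [2.5, 50.0, 97.5])
        return apply_censoring(
            float(2.0**med),
            curve.dilutions,
            ci=(float(2.0**lo), float(2.0**hi)),
            **meta,
        )


# ---------------------------------------------------------------------------
# thin functional wrappers
# ---------------------------------------------------------------------------


def fit_hill(
    curve: TransductionCurve,
    priors: Optional[HillPriors] = None,
    mcmc: Optional[MCMCConfig] = None,
    seed: int = 0,
) -> HillCurveResults:
    """Fit the four-parameter Hill model; see :class:`HillCurveModel`."""
    return HillCurveModel(curve, priors=priors, mcmc=mcmc).fit(seed=seed)


def fit_linear_nd50(
    curve: TransductionCurve,
    window: Optional[tuple] = None,
    seed: int = 0,
    n_draws: int = 8000,
) -> ND50Result:
    """Linear-model ND50 with censoring applied; see :class:`LinearND50Model`."""
    return LinearND50Model(curve, window=window).fit(seed=seed, n_draws=n_draws).nd50_result()
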