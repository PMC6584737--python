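"""Maximum-likelihood fitting of mixture models to signed recall errors.

The standard mixture model describes the signed error e (degrees,
(-180, 180]) as a two-component mixture

    f(e) = (1 - G) * vM(e; 0, kappa) + G / 360

of a von Mises "memory" component centred on the target and a uniform
"guess" component; G is the guess rate and P = 1 - G the retention
probability. The swap model adds a third component of reports centred on
the non-target items:

    f(e) = (1 - G - B) * vM(e; 0, kappa)
         + (B / m) * sum_j vM(e - d_j; 0, kappa) + G / 360

where d_j are the signed target-to-non-target distances of that trial
and m the number of non-targets.

All densities are per degree (the von Mises density is rescaled from
radians by pi/180), so log-likelihoods are directly comparable across
models and to the uniform baseline n*log(1/360).

Precision is reported as the circular standard deviation of the memory
component, sd = sqrt(-2 ln R(kappa)) with R = I1/I0, converted to
degrees; it is a strictly decreasing function of kappa.

Fitting is plain multi-start bounded MLE (no priors): a moment-based
start plus Latin-hypercube starts over the bounds, refined with
L-BFGS-B. A brute-force grid oracle is provided for validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special
from scipy.stats import qmc

from .datamodel import MixtureFit
from .errors import FitError

__all__ = [
    "FitConfig",
    "MixtureModelFitter",
    "fit_mixture",
    "grid_oracle",
    "kappa_to_sd",
    "sd_to_kappa",
    "loglik_standard",
    "loglik_swap",
]

_DEG = math.pi / 180.0
_LOG_UNIFORM = math.log(1.0 / 360.0)
# kappa range used for sd <-> kappa inversion; R(1e-12) ~ 5e-13 gives
# sd ~ 430 deg, far beyond any fit bound
_KAPPA_LO = 1e-12
_KAPPA_HI = 1e8


def _bessel_ratio(kappa):
    """R(kappa) = I1(kappa)/I0(kappa), computed with scaled Bessels."""
    return special.i1e(kappa) / special.i0e(kappa)


def kappa_to_sd(kappa) -> float:
    """Circular standard deviation (degrees) of a von Mises with ``kappa``.

    sd = sqrt(-2 ln R(kappa)) * 180/pi, strictly decreasing in kappa.
    ``kappa`` = 0 gives the circular-uniform limit where the circular SD
    diverges; a ValueError is raised there.
    """
    kappa = float(kappa)
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if kappa == 0:
        raise ValueError("kappa = 0: circular SD is unbounded (uniform limit)")
    r = _bessel_ratio(kappa)
    return math.sqrt(-2.0 * math.log(r)) / _DEG


def sd_to_kappa(sd_deg) -> float:
    """Inverse of :func:`kappa_to_sd`, solved numerically.

    Raises ValueError for sd outside the attainable range (sd <= 0 or
    beyond the kappa -> 0 limit of the numerical bracket).
    """
    sd_deg = float(sd_deg)
    if sd_deg <= 0:
        raise ValueError("sd_deg must be > 0")
    lo_sd = kappa_to_sd(_KAPPA_HI)
    hi_sd = kappa_to_sd(_KAPPA_LO)
    if not lo_sd <= sd_deg <= hi_sd:
        raise ValueError(
            f"sd_deg = {sd_deg} outside the attainable range "
            f"[{lo_sd:.3g}, {hi_sd:.3g}] degrees"
        )
    f = lambda log_k: kappa_to_sd(math.exp(log_k)) - sd_deg
    log_k = optimize.brentq(
        f, math.log(_KAPPA_LO), math.log(_KAPPA_HI), xtol=1e-13, rtol=1e-15
    )
    return math.exp(log_k)


def _vm_logpdf_deg(errors_deg: np.ndarray, kappa: float) -> np.ndarray:
    """Log von Mises density per degree at signed errors (degrees).

    Uses exponentially scaled Bessel I0 so large kappa never overflows:
    log vM = kappa*(cos e - 1) - log(2 pi I0e(kappa)) + log(pi/180).
    """
    c = np.cos(errors_deg * _DEG)
    return kappa * (c - 1.0) - math.log(2.0 * math.pi * special.i0e(kappa)) + math.log(_DEG)


def _check_errors(errors) -> np.ndarray:
    e = np.asarray(errors, dtype=float)
    if e.ndim != 1:
        raise ValueError("errors must be a 1-D array of signed degrees")
    if not np.all(np.isfinite(e)):
        raise ValueError("errors contain non-finite values")
    if np.any(e <= -180.0) or np.any(e > 180.0):
        raise ValueError("signed errors must lie in (-180, 180]")
    return e


def loglik_standard(guess_rate: float, kappa: float, errors) -> float:
    """Log-likelihood of the standard mixture model (densities per degree)."""
    e = _check_errors(errors)
    if not 0.0 <= guess_rate <= 1.0:
        raise ValueError("guess_rate must be in [0, 1]")
    vm = np.exp(_vm_logpdf_deg(e, kappa))
    dens = (1.0 - guess_rate) * vm + guess_rate / 360.0
    if np.any(dens <= 0.0):
        return -np.inf
    return float(np.sum(np.log(dens)))


def loglik_swap(
    guess_rate: float, swap_rate: float, kappa: float, errors, nontarget_offsets
) -> float:
    """Log-likelihood of the swap model.

    ``nontarget_offsets`` is an (n_trials, m) array of signed
    target-to-non-target distances (degrees) for each trial.
    """
    e = _check_errors(errors)
    if nontarget_offsets is None:
        raise ValueError("swap model requires per-trial non-target offsets")
    d = np.asarray(nontarget_offsets, dtype=float)
    if d.ndim != 2 or d.shape[0] != e.shape[0]:
        raise ValueError("nontarget_offsets must be (n_trials, m)")
    if not np.all(np.isfinite(d)):
        raise ValueError("nontarget_offsets contain non-finite values")
    if guess_rate < 0 or swap_rate < 0 or guess_rate + swap_rate > 1.0 + 1e-12:
        raise ValueError("require G, B >= 0 and G + B <= 1")
    m = d.shape[1]
    vm_t = np.exp(_vm_logpdf_deg(e, kappa))
    vm_nt = np.exp(_vm_logpdf_deg(_wrap_signed(e[:, None] - d), kappa))
    p_mem = 1.0 - guess_rate - swap_rate
    dens = (
        p_mem * vm_t
        + (swap_rate / m) * vm_nt.sum(axis=1)
        + guess_rate / 360.0
    )
    if np.any(dens <= 0.0):
        return -np.inf
    return float(np.sum(np.log(dens)))


def _wrap_signed(d):
    d = np.asarray(d, dtype=float) % 360.0
    return np.where(d > 180.0, d - 360.0, d)


@dataclass
class FitConfig:
    """Configuration of the multi-start MLE.

    ``n_starts`` Latin-hypercube starts are drawn over the bounds (one is
    replaced by a method-of-moments start); ``sd_bounds`` are in degrees.
    """

    model: str = "standard"
    g_bounds: tuple[float, float] = (0.0, 1.0)
    b_bounds: tuple[float, float] = (0.0, 1.0)
    sd_bounds: tuple[float, float] = (1.0, 105.0)
    n_starts: int = 10
    tol: float = 1e-8
    seed: int = 0
    min_trials: int = 20

    def __post_init__(self):
        if self.model not in ("standard", "swap"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        for lo, hi, rng in (
            (*self.g_bounds, (0.0, 1.0)),
            (*self.b_bounds, (0.0, 1.0)),
        ):
            if not rng[0] <= lo < hi <= rng[1]:
                raise ValueError("probability bounds must be nested in [0, 1]")
        if not 0 < self.sd_bounds[0] < self.sd_bounds[1]:
            raise ValueError("invalid sd bounds")


def _moment_start(e: np.ndarray, cfg: FitConfig) -> tuple[float, float]:
    """Method-of-moments (G, sd) start.

    The fraction of |e| > 90 deg estimates G/2 under the mixture (the
    memory component contributes little mass there); the mean resultant
    length then gives kappa via R_bar = (1 - G) R(kappa).
    """
    g0 = float(np.clip(2.0 * np.mean(np.abs(e) > 90.0), 0.01, 0.95))
    rbar = float(np.hypot(np.mean(np.cos(e * _DEG)), np.mean(np.sin(e * _DEG))))
    r_mem = min(rbar / max(1.0 - g0, 1e-6), 0.999)
    if r_mem <= 1e-3:
        sd0 = cfg.sd_bounds[1]
    else:
        sd0 = math.sqrt(-2.0 * math.log(r_mem)) / _DEG
    sd0 = float(np.clip(sd0, cfg.sd_bounds[0], cfg.sd_bounds[1]))
    g0 = float(np.clip(g0, cfg.g_bounds[0] + 1e-3, cfg.g_bounds[1] - 1e-3))
    return g0, sd0


class MixtureModelFitter:
    """Multi-start bounded MLE for the standard / swap mixture models.

    Parameters are optimised as (G, log kappa) — and a second mixing
    coordinate for the swap model, mapped so G + B <= 1 holds by
    construction. Deterministic given ``config.seed``.
    """

    def __init__(self, config: FitConfig | None = None):
        self.config = config or FitConfig()

    # -- objective -----------------------------------------------------
    def _negloglik_standard(self, x, e, cos_e):
        g, log_k = x
        kappa = math.exp(log_k)
        log_vm = kappa * (cos_e - 1.0) - math.log(
            2.0 * math.pi * special.i0e(kappa)
        ) + math.log(_DEG)
        vm = np.exp(log_vm)
        dens = (1.0 - g) * vm + g / 360.0
        if np.any(dens <= 1e-300) or not np.all(np.isfinite(dens)):
            return 1e300, np.zeros(2)
        inv = 1.0 / dens
        nll = -float(np.sum(np.log(dens)))
        # analytic gradient
        d_g = -float(np.sum((1.0 / 360.0 - vm) * inv))
        a = _bessel_ratio(kappa)
        d_logk = -float(np.sum((1.0 - g) * vm * (cos_e - a) * inv)) * kappa
        return nll, np.array([d_g, d_logk])

    def _negloglik_swap(self, x, e, d):
        a1, a2, log_k = x
        g = a1
        b = (1.0 - a1) * a2
        kappa = math.exp(log_k)
        ll = loglik_swap(g, b, kappa, e, d)
        if not np.isfinite(ll):
            return 1e300
        return -ll

    # -- fitting -------------------------------------------------------
    def fit(self, errors, nontarget_offsets=None) -> MixtureFit:
        cfg = self.config
        e = _check_errors(errors)
        if e.shape[0] < cfg.min_trials:
            raise FitError(
                f"refusing to fit {e.shape[0]} trials "
                f"(floor is {cfg.min_trials}); supply more data or lower "
                "FitConfig.min_trials"
            )
        if cfg.model == "swap":
            if nontarget_offsets is None:
                raise ValueError("swap model requires nontarget_offsets")
            return self._fit_swap(e, np.asarray(nontarget_offsets, dtype=float))
        return self._fit_standard(e)

    def _starts(self, n_dims: int) -> np.ndarray:
        cfg = self.config
        if cfg.n_starts == 1:
            return np.full((1, n_dims), 0.5)
        sampler = qmc.LatinHypercube(d=n_dims, seed=cfg.seed)
        return sampler.random(n=cfg.n_starts - 1)

    def _fit_standard(self, e: np.ndarray) -> MixtureFit:
        cfg = self.config
        cos_e = np.cos(e * _DEG)
        lk_lo = math.log(sd_to_kappa(cfg.sd_bounds[1]))
        lk_hi = math.log(sd_to_kappa(cfg.sd_bounds[0]))
        bounds = [cfg.g_bounds, (lk_lo, lk_hi)]
        g0, sd0 = _moment_start(e, cfg)
        starts = [(g0, math.log(sd_to_kappa(sd0)))]
        for u in self._starts(2):
            g = cfg.g_bounds[0] + u[0] * (cfg.g_bounds[1] - cfg.g_bounds[0])
            lk = lk_lo + u[1] * (lk_hi - lk_lo)
            starts.append((g, lk))

        best = None
        n_fail = 0
        for idx, x0 in enumerate(starts):
            res = optimize.minimize(
                self._negloglik_standard,
                np.asarray(x0, dtype=float),
                args=(e, cos_e),
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"ftol": cfg.tol, "gtol": 1e-10},
            )
            if not np.isfinite(res.fun) or res.fun >= 1e299:
                n_fail += 1
                continue
            cand = (float(-res.fun), float(res.x[0]), float(res.x[1]), idx)
            if best is None or _better(cand, best, cfg.tol):
                best = cand
        if best is None:
            raise FitError(
                "all optimisation starts failed",
                diagnostics={"n_starts": len(starts), "n_failed": n_fail},
            )
        ll, g, log_k, _ = best
        kappa = math.exp(log_k)
        return MixtureFit(
            model="standard",
            guess_rate=g,
            kappa=kappa,
            sd_deg=kappa_to_sd(kappa),
            swap_rate=0.0,
            p_mem=1.0 - g,
            loglik=ll,
            n_trials=int(e.shape[0]),
        )

    def _fit_swap(self, e: np.ndarray, d: np.ndarray) -> MixtureFit:
        cfg = self.config
        lk_lo = math.log(sd_to_kappa(cfg.sd_bounds[1]))
        lk_hi = math.log(sd_to_kappa(cfg.sd_bounds[0]))
        bounds = [cfg.g_bounds, cfg.b_bounds, (lk_lo, lk_hi)]
        g0, sd0 = _moment_start(e, cfg)
        starts = [(g0, 0.1, math.log(sd_to_kappa(sd0)))]
        for u in self._starts(3):
            g = cfg.g_bounds[0] + u[0] * (cfg.g_bounds[1] - cfg.g_bounds[0])
            a2 = cfg.b_bounds[0] + u[1] * (cfg.b_bounds[1] - cfg.b_bounds[0])
            lk = lk_lo + u[2] * (lk_hi - lk_lo)
            starts.append((g, a2, lk))

        best = None
        n_fail = 0
        for idx, x0 in enumerate(starts):
            res = optimize.minimize(
                self._negloglik_swap,
                np.asarray(x0, dtype=float),
                args=(e, d),
                method="L-BFGS-B",
                bounds=bounds,
                options={"ftol": cfg.tol},
            )
            if not np.isfinite(res.fun) or res.fun >= 1e299:
                n_fail += 1
                continue
            cand = (float(-res.fun), float(res.x[0]), res.x, idx)
            if best is None or _better(cand, best, cfg.tol):
                best = cand
        if best is None:
            raise FitError(
                "all optimisation starts failed",
                diagnostics={"n_starts": len(starts), "n_failed": n_fail},
            )
        ll, g, x, _ = best
        b = (1.0 - x[0]) * x[1]
        kappa = math.exp(x[2])
        return MixtureFit(
            model="swap",
            guess_rate=float(g),
            kappa=float(kappa),
            sd_deg=kappa_to_sd(kappa),
            swap_rate=float(b),
            p_mem=float(1.0 - g - b),
            loglik=ll,
            n_trials=int(e.shape[0]),
        )


def _better(cand, best, tol) -> bool:
    """Higher loglik wins; near-ties broken by smaller G, then start index."""
    if cand[0] > best[0] + tol:
        return True
    if cand[0] < best[0] - tol:
        return False
    if cand[1] != best[1]:
        return cand[1] < best[1]
    return cand[3] < best[3]


def fit_mixture(errors, nontarget_offsets=None, config: FitConfig | None = None) -> MixtureFit:
    """Fit a mixture model to signed errors; see :class:`MixtureModelFitter`."""
    return MixtureModelFitter(config).fit(errors, nontarget_offsets)


def grid_oracle(
    errors,
    g_grid,
    sd_grid,
    b_grid=None,
    nontarget_offsets=None,
) -> tuple[dict, float]:
    """Exhaustive grid evaluation of the mixture log-likelihood.

    Returns the best grid point as a dict (keys ``guess_rate``,
    ``sd_deg`` and, for the swap model, ``swap_rate``) and its
    log-likelihood. Intended as a brute-force validation oracle for the
    optimizer, not for analysis use.
    """
    e = _check_errors(errors)
    g_grid = np.atleast_1d(np.asarray(g_grid, dtype=float))
    sd_grid = np.atleast_1d(np.asarray(sd_grid, dtype=float))
    if g_grid.size == 0 or sd_grid.size == 0:
        raise ValueError("empty grid")
    best_point, best_ll = None, -np.inf
    if b_grid is None:
        for sd in sd_grid:
            kappa = sd_to_kappa(sd)
            vm = np.exp(_vm_logpdf_deg(e, kappa))
            for g in g_grid:
                dens = (1.0 - g) * vm + g / 360.0
                with np.errstate(divide="ignore"):
                    ll = float(np.sum(np.log(dens)))
                if ll > best_ll:
                    best_ll = ll
                    best_point = {"guess_rate": float(g), "sd_deg": float(sd)}
    else:
        b_grid = np.atleast_1d(np.asarray(b_grid, dtype=float))
        if b_grid.size == 0:
            raise ValueError("empty grid")
        if nontarget_offsets is None:
            raise ValueError("swap-model grid requires nontarget_offsets")
        d = np.asarray(nontarget_offsets, dtype=float)
        m = d.shape[1]
        for sd in sd_grid:
            kappa = sd_to_kappa(sd)
            vm_t = np.exp(_vm_logpdf_deg(e, kappa))
            vm_nt = np.exp(_vm_logpdf_deg(_wrap_signed(e[:, None] - d), kappa)).sum(axis=1)
            for g in g_grid:
                for b in b_grid:
                    if g + b > 1.0:
                        continue
                    dens = (1.0 - g - b) * vm_t + (b / m) * vm_nt + g / 360.0
                    with np.errstate(divide="ignore"):
                        ll = float(np.sum(np.log(dens)))
                    if ll > best_ll:
                        best_ll = ll
                        best_point = {
                            "guess_rate": float(g),
                            "swap_rate": float(b),
                            "sd_deg": float(sd),
                        }
    if best_point is None:
        raise ValueError("no admissible grid point")
    return best_point, best_ll
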