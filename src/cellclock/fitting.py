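"""Likelihood maximization: parameter transforms, CMA-ES fits, joint
multi-condition fits, multistart analysis, period rescaling and
identifiability studies.

Parameters are optimized in an unconstrained coordinate system: periods,
diffusion coefficients and bump widths through logistic maps onto their
bounds, bump centers on the torus, bump weights through a logistic map
onto [-weight_bound, weight_bound] (weight 0 at coordinate 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .likelihood import FitConfig, dataset_loglik
from .model import CouplingBump, CouplingFunction, ModelParams
from .optim import cma_minimize
from .simulate import EventSequence, simulate_cohort

TWO_PI = 2.0 * math.pi

__all__ = ["FitResult", "ParamCoder", "fit", "fit_joint", "multistart",
           "rescale_params", "identifiability_study", "direction_call",
           "COUPLING_DISPLAY_THRESHOLD"]

#: coupling magnitude [rad/h] above which a fitted bump is considered real
COUPLING_DISPLAY_THRESHOLD = 2.0


def _sigmoid(u):
    return 1.0 / (1.0 + np.exp(-u))


def _logit(p):
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return np.log(p / (1.0 - p))


def _box(u, lo, hi):
    return lo + (hi - lo) * _sigmoid(u)


def _unbox(x, lo, hi):
    return _logit((x - lo) / (hi - lo))


@dataclass
class FitResult:
    params: ModelParams
    loglik: float
    per_trace: np.ndarray
    history: list
    seed: int
    n_evaluations: int
    converged: bool
    bound_saturated: bool = False
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"params": self.params.to_dict(), "loglik": self.loglik,
                "per_trace": list(map(float, self.per_trace)),
                "seed": self.seed, "n_evaluations": self.n_evaluations,
                "converged": self.converged,
                "bound_saturated": self.bound_saturated}


class ParamCoder:
    """Bijection between ModelParams and an unconstrained vector.

    Blocks: T1, T2, sigma1, sigma2, F1, F2 (each coupling block is
    n_bumps x [weight, mu_theta, mu_phi, s_theta, s_phi]).  Blocks not in
    ``config.free`` are held at the template's values.
    """

    def __init__(self, config: FitConfig, template: ModelParams | None = None):
        self.config = config
        self.template = template or ModelParams(
            T1=24.0, T2=22.0, sigma1=0.17, sigma2=0.25,
            F1=self._default_bumps(config.n_bumps[0]),
            F2=self._default_bumps(config.n_bumps[1]))
        self.blocks = []
        for name in ("T1", "T2", "sigma1", "sigma2"):
            if name in config.free:
                self.blocks.append((name, 1))
        for name, nb in (("F1", config.n_bumps[0]), ("F2", config.n_bumps[1])):
            if name in config.free and nb > 0:
                self.blocks.append((name, 5 * nb))
        self.dim = sum(n for _, n in self.blocks)

    @staticmethod
    def _default_bumps(n):
        rng = np.random.default_rng(12345)
        return CouplingFunction(tuple(
            CouplingBump(0.0, tuple(rng.uniform(0, TWO_PI, 2)), (0.7, 0.7))
            for _ in range(n)))

    def _bump_vector(self, F: CouplingFunction, nb: int) -> np.ndarray:
        cfg = self.config
        out = []
        bumps = list(F.bumps)[:nb]
        while len(bumps) < nb:
            bumps.append(CouplingBump(0.0, (math.pi, math.pi), (0.7, 0.7)))
        for b in bumps:
            out.extend([
                float(_unbox(b.K, -cfg.weight_bound, cfg.weight_bound)),
                b.center[0], b.center[1],
                float(_unbox(b.widths[0], *cfg.width_bounds)),
                float(_unbox(b.widths[1], *cfg.width_bounds)),
            ])
        return np.asarray(out)

    def _bumps_from(self, v: np.ndarray, nb: int) -> CouplingFunction:
        cfg = self.config
        bumps = []
        for i in range(nb):
            K, mt, mp, wt, wp = v[5 * i:5 * i + 5]
            bumps.append(CouplingBump(
                float(_box(K, -cfg.weight_bound, cfg.weight_bound)),
                (float(mt) % TWO_PI, float(mp) % TWO_PI),
                (float(_box(wt, *cfg.width_bounds)),
                 float(_box(wp, *cfg.width_bounds)))))
        return CouplingFunction(tuple(bumps))

    def encode(self, params: ModelParams) -> np.ndarray:
        cfg = self.config
        out = []
        for name, n in self.blocks:
            if name in ("T1", "T2"):
                out.append(float(_unbox(getattr(params, name), *cfg.period_bounds)))
            elif name in ("sigma1", "sigma2"):
                out.append(float(_unbox(getattr(params, name), *cfg.sigma_bounds)))
            else:
                nb = cfg.n_bumps[0 if name == "F1" else 1]
                out.extend(self._bump_vector(getattr(params, name), nb))
        return np.asarray(out)

    def decode(self, u: np.ndarray) -> ModelParams:
        cfg = self.config
        vals = {"T1": self.template.T1, "T2": self.template.T2,
                "sigma1": self.template.sigma1, "sigma2": self.template.sigma2,
                "F1": self.template.F1, "F2": self.template.F2}
        i = 0
        for name, n in self.blocks:
            v = u[i:i + n]
            i += n
            if name in ("T1", "T2"):
                vals[name] = float(_box(v[0], *cfg.period_bounds))
            elif name in ("sigma1", "sigma2"):
                vals[name] = float(_box(v[0], *cfg.sigma_bounds))
            else:
                nb = cfg.n_bumps[0 if name == "F1" else 1]
                vals[name] = self._bumps_from(v, nb)
        return ModelParams(**vals)

    def near_bounds(self, u: np.ndarray, margin: float = 6.0) -> bool:
        """Logistic coordinates beyond +-margin sit on a box bound."""
        i = 0
        for name, n in self.blocks:
            v = u[i:i + n]
            i += n
            if name in ("F1", "F2"):
                v = np.delete(v.reshape(-1, 5), [1, 2], axis=1).ravel()  # drop centers
            if np.any(np.abs(v) > margin):
                return True
        return False


def moment_init(dataset: list[EventSequence],
                config: FitConfig | None = None) -> ModelParams:
    """Method-of-moments starting point: intrinsic periods from the mean
    circadian / cell-cycle interval durations, diffusion coefficients from
    their SDs via the first-passage relation sigma = SD * 2*pi / T^(3/2),
    coupling functions at zero weight."""
    from .intervals import build_intervals, summarize_intervals

    config = config or FitConfig()
    table = build_intervals(dataset)

    def block(kind, default_T, default_s):
        s = summarize_intervals(table, kind)
        if s.n < 5 or not math.isfinite(s.mean):
            return default_T, default_s
        T = float(np.clip(s.mean, *config.period_bounds))
        sd = s.sd if math.isfinite(s.sd) else 0.15 * T
        sig = float(np.clip(sd * TWO_PI / T ** 1.5, *config.sigma_bounds))
        return T, sig

    T1, s1 = block("pp_any", 24.0, 0.17)
    T2, s2 = block("dd_any", 22.0, 0.25)
    coder = ParamCoder(config)
    zero = coder.template
    return ModelParams(T1=T1, T2=T2, sigma1=s1, sigma2=s2,
                       F1=_zero_weights(zero.F1), F2=_zero_weights(zero.F2))


def _zero_weights(F: CouplingFunction) -> CouplingFunction:
    return CouplingFunction(tuple(replace(b, K=0.0) for b in F.bumps))


def _random_centers(F: CouplingFunction, rng) -> CouplingFunction:
    return CouplingFunction(tuple(
        replace(b, center=tuple(rng.uniform(0, TWO_PI, 2))) for b in F.bumps))


def _grid_bump_init(dataset, config: FitConfig, seed: int,
                    base: ModelParams, which: str,
                    n_grid: int = 6, weights=(-6.0, -3.0, 3.0, 6.0)):
    """Coarse global scan for a single coupling bump.

    Evaluates the likelihood (one common seed) of a lone bump of default
    width at every point of an n_grid x n_grid torus grid and a few
    weights, on top of the uncoupled fit's periods and noise.  The winner
    seeds the local CMA refinement — a global-then-local strategy that
    keeps the coupled fits out of spurious local optima.
    """
    scan_seed = _gen_seed(seed, 999_979)
    centers = np.arange(n_grid) * TWO_PI / n_grid + TWO_PI / (2 * n_grid)
    zero = CouplingFunction.zero()
    best = (-math.inf, None)
    for K in weights:
        for mt in centers:
            for mp in centers:
                F = CouplingFunction((CouplingBump(K, (mt, mp), (0.7, 0.7)),))
                cand = ModelParams(
                    T1=base.T1, T2=base.T2, sigma1=base.sigma1,
                    sigma2=base.sigma2,
                    F1=F if which == "F1" else zero,
                    F2=F if which == "F2" else zero)
                total, _ = dataset_loglik(cand, dataset, config,
                                          seed=scan_seed)
                if total > best[0]:
                    best = (total, cand)
    # also consider no coupling at all as the starting point
    uncoupled = ModelParams(T1=base.T1, T2=base.T2, sigma1=base.sigma1,
                            sigma2=base.sigma2,
                            F1=_pad_zero(zero, config.n_bumps[0]) if which == "F1" else zero,
                            F2=_pad_zero(zero, config.n_bumps[1]) if which == "F2" else zero)
    total, _ = dataset_loglik(uncoupled, dataset, config, seed=scan_seed)
    params = best[1] if best[0] > total else uncoupled
    # pad the coupling to the configured bump count with zero-weight bumps
    nb = config.n_bumps[0 if which == "F1" else 1]
    F = getattr(params, which)
    return replace(params, **{which: _pad_zero(F, nb)})


def _pad_zero(F: CouplingFunction, nb: int) -> CouplingFunction:
    rng = np.random.default_rng(54321)
    bumps = list(F.bumps)[:nb]
    while len(bumps) < nb:
        bumps.append(CouplingBump(0.0, tuple(rng.uniform(0, TWO_PI, 2)),
                                  (0.7, 0.7)))
    return CouplingFunction(tuple(bumps))


def _gen_seed(base: int, gen: int) -> int:
    return int(np.random.SeedSequence([int(base), int(gen)]).generate_state(1)[0]
               % (2 ** 31))


def fit(dataset: list[EventSequence], config: FitConfig | None = None,
        init: ModelParams | None = None, seed: int | None = None) -> FitResult:
    """Maximize the dataset log-likelihood by CMA-ES.

    Common random numbers within each generation (shared generation seed)
    keep the likelihood noise from confusing selection; seeds refresh
    across generations so the optimizer cannot overfit one noise draw.
    """
    config = config or FitConfig()
    seed = config.seed if seed is None else seed
    if init is None:
        init = moment_init(dataset, config)
    coder = ParamCoder(config, template=init)
    x0 = coder.encode(init)

    def objective(u, gen):
        try:
            total, _ = dataset_loglik(coder.decode(u), dataset, config,
                                      seed=_gen_seed(seed, gen))
        except Exception:
            return 1e12
        return -total

    res = cma_minimize(objective, x0, sigma0=config.sigma0,
                       popsize=config.popsize, max_gens=config.max_gens,
                       seed=seed)
    # final comparison of the mean and the last best under one fixed seed
    final_seed = _gen_seed(seed, 10 ** 6)
    scores = []
    for u in (res.x_best, res.x_mean):
        try:
            total, per = dataset_loglik(coder.decode(u), dataset, config,
                                        seed=final_seed)
        except Exception:
            continue
        scores.append((total, per, u))
    if not scores:  # both end points degenerate: keep the best candidate
        u = res.x_best
        total, per = -math.inf, np.full(len(dataset), -math.inf)
        scores.append((total, per, u))
    total, per, u = max(scores, key=lambda s: s[0])
    return FitResult(params=coder.decode(u), loglik=total, per_trace=per,
                     history=res.history, seed=seed,
                     n_evaluations=res.n_evaluations + 2,
                     converged=res.converged,
                     bound_saturated=coder.near_bounds(u))


def fit_joint(datasets: dict[str, list[EventSequence]],
              config: FitConfig | None = None,
              shared: tuple[str, ...] = ("T1", "sigma1", "sigma2", "F1", "F2"),
              init: ModelParams | None = None,
              seed: int | None = None) -> FitResult:
    """One likelihood over several conditions with shared parameters.

    By default only the intrinsic cell-cycle period T2 varies between
    conditions; all other parameters are shared.  Returns a FitResult whose
    ``params`` holds the shared parameter copy and whose ``extra`` maps each
    condition to its full ModelParams.
    """
    config = config or FitConfig()
    if len(datasets) < 2:
        raise ValueError("need at least 2 conditions for a joint fit")
    per_cond = tuple(n for n in ("T1", "T2", "sigma1", "sigma2", "F1", "F2")
                     if n in config.free and n not in shared)
    if not per_cond:
        raise ValueError("no per-condition parameters; masks are inconsistent")
    seed = config.seed if seed is None else seed
    names = sorted(datasets)
    if init is None:
        init = moment_init([ev for d in datasets.values() for ev in d], config)
    shared_cfg = replace(config, free=tuple(n for n in config.free if n in shared))
    cond_cfg = replace(config, free=per_cond)
    shared_coder = ParamCoder(shared_cfg, template=init)
    cond_coder = ParamCoder(cond_cfg, template=init)
    dim = shared_coder.dim + len(names) * cond_coder.dim

    def split(u):
        out = []
        base = shared_coder.decode(u[:shared_coder.dim])
        for i, _ in enumerate(names):
            lo = shared_coder.dim + i * cond_coder.dim
            cc = ParamCoder(cond_cfg, template=base)
            out.append(cc.decode(u[lo:lo + cond_coder.dim]))
        return out

    def objective(u, gen):
        s = _gen_seed(seed, gen)
        try:
            ps = split(u)
            return -sum(dataset_loglik(p, datasets[nm], config, seed=s)[0]
                        for p, nm in zip(ps, names))
        except Exception:
            return 1e12

    x0 = np.zeros(dim)
    x0[:shared_coder.dim] = shared_coder.encode(init)
    for i in range(len(names)):
        lo = shared_coder.dim + i * cond_coder.dim
        x0[lo:lo + cond_coder.dim] = cond_coder.encode(init)
    res = cma_minimize(objective, x0, sigma0=config.sigma0,
                       popsize=config.popsize, max_gens=config.max_gens,
                       seed=seed)
    final_seed = _gen_seed(seed, 10 ** 6)
    best = None
    for u in (res.x_best, res.x_mean):
        ps = split(u)
        pieces = [dataset_loglik(p, datasets[nm], config, seed=final_seed)
                  for p, nm in zip(ps, names)]
        total = sum(t for t, _ in pieces)
        if best is None or total > best[0]:
            best = (total, pieces, ps, u)
    total, pieces, ps, u = best
    per = np.concatenate([p for _, p in pieces])
    return FitResult(params=ps[0], loglik=float(total), per_trace=per,
                     history=res.history, seed=seed,
                     n_evaluations=res.n_evaluations, converged=res.converged,
                     extra={"conditions": dict(zip(names, ps))})


def significant_bumps(params: ModelParams,
                      threshold: float = COUPLING_DISPLAY_THRESHOLD):
    """Bumps whose peak |K G| exceeds the display threshold, per function."""
    out = {"F1": [], "F2": []}
    for name in out:
        for b in getattr(params, name).bumps:
            peak = abs(b.K) * CouplingFunction((CouplingBump(
                1.0, b.center, b.widths),)).max_abs()
            if peak > threshold:
                out[name].append({"sign": 1 if b.K > 0 else -1,
                                  "center": b.center, "peak": peak})
    return out


def multistart(dataset: list[EventSequence], config: FitConfig | None = None,
               n_starts: int = 8, seed: int = 0):
    """Independent optimizations from random starting points.

    Returns (results sorted by log-likelihood, bump summary of the best
    solutions' above-threshold coupling bumps).
    """
    if n_starts < 2:
        raise ValueError("need at least 2 starts")
    config = config or FitConfig()
    base = moment_init(dataset, config)
    results = []
    for k in range(n_starts):
        rng = np.random.default_rng(_gen_seed(seed, 10_000 + k))
        init = ModelParams(
            T1=base.T1, T2=base.T2, sigma1=base.sigma1, sigma2=base.sigma2,
            F1=_random_centers(base.F1, rng), F2=_random_centers(base.F2, rng))
        results.append(fit(dataset, config, init=init,
                           seed=_gen_seed(seed, k)))
    results.sort(key=lambda r: r.loglik, reverse=True)
    summary = [significant_bumps(r.params) for r in results]
    return results, summary


def rescale_params(params: ModelParams, target_T1: float,
                   target_T2: float) -> ModelParams:
    """Replace the intrinsic periods, keeping noise and coupling fixed."""
    if target_T1 <= 0 or target_T2 <= 0:
        raise ValueError("target periods must be positive")
    return replace(params, T1=float(target_T1), T2=float(target_T2))


def direction_call(params: ModelParams, floor: float = 1.0,
                   dominance: float = 2.0) -> str:
    """Coupling directionality from the coupling-function magnitudes.

    'none' when both |F| maxima sit below ``floor`` [rad/h]; otherwise the
    direction whose magnitude dominates by at least ``dominance``-fold
    ('cc->clock' = cell cycle drives the clock via F1), or 'both' when
    neither dominates.
    """
    m1 = params.F1.max_abs() if params.F1.bumps else 0.0
    m2 = params.F2.max_abs() if params.F2.bumps else 0.0
    if max(m1, m2) < floor:
        return "none"
    if m1 >= dominance * m2:
        return "cc->clock"
    if m2 >= dominance * m1:
        return "clock->cc"
    return "both"


def identifiability_study(true_params: ModelParams, n_cells: int = 500,
                          seed: int = 0, config: FitConfig | None = None,
                          duration: float = 72.0) -> dict:
    """Simulate from known parameters, refit, and report recovery.

    Coupling directionality is decided by penalized likelihood comparison
    of three nested models fit to the same data with common random
    numbers: uncoupled, cell-cycle->clock coupling only (F1), and
    clock->cell-cycle only (F2); the coupled fits start from the
    uncoupled fit's periods and noise.  A coupled model must beat the
    uncoupled one under a BIC penalty (parameters x ln of the number of
    scored event factors) to claim a direction; 'both' is called when
    the two coupled models are inseparable.  This is far more robust at
    small sample sizes than reading the direction off a single
    unconstrained fit, where coupling terms can partially absorb period
    misfit.  Also reports period/noise recovery errors from the winning
    model.
    """
    config = config or FitConfig()
    dataset = simulate_cohort(true_params, n_cells, duration=duration,
                              seed=seed)
    base_free = ("T1", "T2", "sigma1", "sigma2")
    variants = {
        "none": replace(config, free=base_free, n_bumps=(0, 0)),
        "cc->clock": replace(config, free=base_free + ("F1",),
                             n_bumps=(config.n_bumps[0], 0)),
        "clock->cc": replace(config, free=base_free + ("F2",),
                             n_bumps=(0, config.n_bumps[1])),
    }
    n_par = {"none": 4, "cc->clock": 4 + 5 * config.n_bumps[0],
             "clock->cc": 4 + 5 * config.n_bumps[1]}
    # the uncoupled model is 4-dimensional and converges in few generations
    variants["none"] = replace(variants["none"],
                               max_gens=min(12, config.max_gens))
    fits = {"none": fit(dataset, variants["none"], seed=seed)}
    base = fits["none"].params
    for name in ("cc->clock", "clock->cc"):
        cfg_i = variants[name]
        warm = _grid_bump_init(dataset, cfg_i, seed, base,
                               "F1" if name == "cc->clock" else "F2")
        fits[name] = fit(dataset, cfg_i, init=warm, seed=seed)
    # honest comparison: one fixed seed for every model, and the uncoupled
    # reference also sees each coupled solution with its coupling removed,
    # so shared-parameter optimization quality cannot masquerade as coupling
    cmp_seed = _gen_seed(seed, 999_983)
    ll = {}
    for name, f in fits.items():
        ll[name], _ = dataset_loglik(f.params, dataset, config, seed=cmp_seed)
    for name in ("cc->clock", "clock->cc"):
        p = fits[name].params
        stripped = ModelParams(T1=p.T1, T2=p.T2, sigma1=p.sigma1,
                               sigma2=p.sigma2,
                               F1=_zero_weights(p.F1), F2=_zero_weights(p.F2))
        ll["none"] = max(ll["none"],
                         dataset_loglik(stripped, dataset, config,
                                        seed=cmp_seed)[0])
    n_obs = sum(len(ev.events) for ev in dataset)
    pen = math.log(max(n_obs, 2))
    bic = {name: pen * n_par[name] - 2 * ll[name] for name in fits}
    coupled = sorted(("cc->clock", "clock->cc"), key=lambda n: bic[n])
    if bic[coupled[0]] >= bic["none"]:
        direction = "none"
    elif abs(bic[coupled[0]] - bic[coupled[1]]) < 2.0:
        direction = "both"
    else:
        direction = coupled[0]
    best = fits[coupled[0]] if direction != "none" else fits["none"]
    est = best.params
    return {
        "true": true_params.to_dict(),
        "estimated": est.to_dict(),
        "errors": {
            "T1": est.T1 - true_params.T1, "T2": est.T2 - true_params.T2,
            "sigma1": est.sigma1 - true_params.sigma1,
            "sigma2": est.sigma2 - true_params.sigma2,
        },
        "max_F1": est.F1.max_abs() if est.F1.bumps else 0.0,
        "max_F2": est.F2.max_abs() if est.F2.bumps else 0.0,
        "bic": bic,
        "loglik": {name: fits[name].loglik for name in fits},
        "direction": direction,
        "true_direction": direction_call(true_params),
        "fits": fits,
    }
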