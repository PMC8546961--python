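"""Estimation machinery for G6PDH initial-rate kinetics.

The workflow mirrors standard practice for steady-state enzyme kinetics:

1. initial rates (V0) are read off reaction progress curves before 5% of the
   limiting substrate is consumed (:func:`estimate_v0`);
2. the non-parametric direct linear plot provides robust Km/Vmax seeds
   (:func:`direct_linear_plot`);
3. all design points are fitted simultaneously ("globally") to the
   rapid-equilibrium random-ordered rate law with relative (proportional
   error) weighting and a seeded multistart (:func:`global_fit`);
4. alternative mechanisms (with/without product inhibition, substrate
   inhibition or first-order enzyme inactivation) are discriminated by AICc
   and Akaike weights (:func:`compare_models`);
5. uncertainty is expressed as 95% confidence intervals from a parametric
   bootstrap with relative residual resampling (:func:`bootstrap_ci`);
6. the Selwyn test checks for enzyme inactivation: progress curves taken at
   different enzyme concentrations must superimpose when plotted against
   e0*t (:func:`selwyn_test`).

Enzyme inactivation enters the rate model through an optional per-observation
timestamp: an observation taken at time t is predicted as
v(t) = v_rate_law * exp(-decay_rate * t).
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import (ConvergenceError, EstimationError, InputError,
                     InsufficientDataError, InsufficientOverlapError,
                     UsageError)
from .kinetics import AssayMix, Cofactor, CofactorBranch, branch_rate

__all__ = [
    "RateObservation", "RateDataset", "ProgressCurve", "ModelSpec",
    "FitResult", "ModelComparison", "estimate_v0", "direct_linear_plot",
    "global_fit", "bootstrap_ci", "compare_models", "selwyn_test",
]

#: effectively-absent inhibition: large but finite so branch validation holds
_NO_INHIBITION = 1e30

#: default box bounds per free parameter (uM or 1/s; decay_rate in 1/s)
DEFAULT_BOUNDS = {
    "kcat": (1e-3, 1e5),
    "km_cofactor": (1e-2, 1e7),
    "ki_cofactor": (1e-2, 1e7),
    "km_g6p": (1e-2, 1e7),
    "kic_product": (1e-2, 1e8),
    "kis_cofactor": (1e-2, 1e8),
    "decay_rate": (1e-8, 10.0),
}


@dataclass(frozen=True)
class RateObservation:
    """One measured initial rate at a known mixture.

    ``time`` is the age of the assay at which the rate was observed (s); it is
    only consulted by models with first-order enzyme inactivation.
    """

    mix: AssayMix
    v0: float  # uM/s
    replicate_id: str = "r1"
    time: float = 0.0

    def __post_init__(self):
        if not math.isfinite(self.v0) or self.v0 < 0:
            raise InputError(f"v0 must be finite and >= 0, got {self.v0!r}")
        if self.time < 0:
            raise InputError("observation time must be >= 0")


@dataclass(frozen=True)
class RateDataset:
    """A set of initial-rate observations for one enzyme and cofactor branch."""

    observations: tuple
    enzyme_name: str = ""
    cofactor: Cofactor = Cofactor.NAD

    def __post_init__(self):
        object.__setattr__(self, "observations", tuple(self.observations))
        object.__setattr__(self, "cofactor", Cofactor(self.cofactor))
        if len(self.observations) < 1:
            raise InputError("RateDataset needs at least one observation")

    def cofactor_conc(self, obs: RateObservation) -> float:
        return obs.mix.nad_ox if self.cofactor is Cofactor.NAD else obs.mix.nadp_ox

    def n_design_points(self) -> int:
        return len({(o.mix.g6p, self.cofactor_conc(o)) for o in self.observations})

    def require_fittable(self):
        if self.n_design_points() < 6:
            raise InputError("fitting requires at least 6 distinct "
                             "(G6P, cofactor) design points")


@dataclass(frozen=True)
class ProgressCurve:
    """Product accumulation over time at fixed initial conditions."""

    times: tuple  # s, strictly increasing
    product: tuple  # uM
    mix: AssayMix
    s0: float  # uM initial limiting substrate

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.product, dtype=float)
        object.__setattr__(self, "times", tuple(t))
        object.__setattr__(self, "product", tuple(p))
        if t.size != p.size:
            raise InputError("times and product must have equal length")
        if t.size < 5:
            raise InputError("a progress curve needs at least 5 points")
        if not np.all(np.diff(t) > 0):
            raise InputError("times must be strictly increasing")
        if self.s0 <= 0:
            raise InputError("s0 must be positive")
        if np.any(p < -1e-9) or np.any(p > self.s0 * (1 + 1e-9)):
            raise InputError("product must stay within [0, s0]")


@dataclass(frozen=True)
class ModelSpec:
    """One candidate mechanism for fitting/discrimination."""

    product_inhibition: bool = False
    substrate_inhibition: bool = False
    enzyme_decay: bool = False
    bounds: dict = field(default_factory=dict)  # overrides of DEFAULT_BOUNDS
    name: str = ""

    def parameter_names(self) -> list[str]:
        names = ["kcat", "km_cofactor", "ki_cofactor", "km_g6p"]
        if self.product_inhibition:
            names.append("kic_product")
        if self.substrate_inhibition:
            names.append("kis_cofactor")
        if self.enzyme_decay:
            names.append("decay_rate")
        return names

    def parameter_bounds(self) -> dict[str, tuple[float, float]]:
        out = {}
        for name in self.parameter_names():
            lo, hi = self.bounds.get(name, DEFAULT_BOUNDS[name])
            if not (0 < lo < hi < math.inf):
                raise InputError(f"bounds for {name} must be finite and positive")
            out[name] = (lo, hi)
        return out

    def label(self) -> str:
        if self.name:
            return self.name
        bits = ["base"]
        if self.product_inhibition:
            bits.append("kic")
        if self.substrate_inhibition:
            bits.append("kis")
        if self.enzyme_decay:
            bits.append("decay")
        return "+".join(bits)

    def build_branch(self, cofactor: Cofactor, params: dict) -> CofactorBranch:
        return CofactorBranch(
            cofactor_id=cofactor,
            kcat=params["kcat"],
            km_cofactor=params["km_cofactor"],
            ki_cofactor=params["ki_cofactor"],
            km_g6p=params["km_g6p"],
            kic_product=params.get("kic_product", _NO_INHIBITION),
            kis_cofactor=params.get("kis_cofactor"),
        )

    def predict(self, data: RateDataset, params: dict) -> np.ndarray:
        branch = self.build_branch(data.cofactor, params)
        decay = params.get("decay_rate", 0.0)
        out = np.empty(len(data.observations))
        for i, obs in enumerate(data.observations):
            v = branch_rate(branch, obs.mix)
            if self.enzyme_decay:
                v *= math.exp(-decay * obs.time)
            out[i] = v
        return out


@dataclass
class FitResult:
    estimates: dict
    ssr: float
    aicc: float
    n_obs: int
    converged: bool
    seed: int
    model: str = ""
    ci95: dict = field(default_factory=dict)  # name -> (lo, hi)
    bootstrap_failures: int = 0

    def to_json(self) -> str:
        d = asdict(self)
        d["ci95"] = {k: list(v) for k, v in self.ci95.items()}
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FitResult":
        d = json.loads(text)
        d["ci95"] = {k: tuple(v) for k, v in d.get("ci95", {}).items()}
        return cls(**d)


@dataclass
class ModelComparison:
    labels: list
    aicc: dict  # label -> aicc
    weights: dict  # label -> Akaike weight
    selected: str
    fits: dict  # label -> FitResult
    excluded: dict = field(default_factory=dict)  # label -> reason

    def to_json(self) -> str:
        return json.dumps({
            "labels": self.labels, "aicc": self.aicc, "weights": self.weights,
            "selected": self.selected, "excluded": self.excluded,
        }, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Initial-rate extraction and seeding estimators


def estimate_v0(curve: ProgressCurve, consumption_cutoff: float = 0.05) -> float:
    """Initial rate from the early, nearly-linear part of a progress curve.

    Points with product <= cutoff*s0 are kept and fitted with a quadratic in
    time; the linear coefficient is the rate estimate.  A negative estimate
    is returned as-is with a warning (it signals noise, not chemistry).
    """
    t = np.asarray(curve.times)
    p = np.asarray(curve.product)
    keep = p <= consumption_cutoff * curve.s0
    if not keep[0]:
        raise InsufficientDataError(
            "first point already exceeds the consumption cutoff")
    # keep the initial contiguous run below the cutoff
    n_keep = int(np.argmin(keep)) if not keep.all() else keep.size
    if n_keep < 5:
        raise InsufficientDataError(
            f"only {n_keep} points below {consumption_cutoff:.0%} consumption; need 5")
    coeffs = np.polyfit(t[:n_keep], p[:n_keep], deg=2)
    v0 = float(coeffs[1])
    if v0 < 0:
        warnings.warn("estimate_v0 returned a negative slope", stacklevel=2)
    return v0


def direct_linear_plot(points: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Median-based Km/Vmax estimate from (s, v) pairs.

    Each observation defines the line Vmax = v + (v/s) Km in (Km, Vmax)
    space; the estimate is the component-wise median over all pairwise line
    intersections.  Parallel pairs are skipped.
    """
    pts = [(float(s), float(v)) for s, v in points]
    if len(pts) < 2:
        raise InputError("direct_linear_plot needs at least 2 points")
    if any(s <= 0 for s, _ in pts):
        raise InputError("substrate concentrations must be positive")
    if len({s for s, _ in pts}) < 2:
        raise EstimationError("all substrate concentrations identical")
    kms, vmaxs = [], []
    for (s1, v1), (s2, v2) in itertools.combinations(pts, 2):
        m1, m2 = v1 / s1, v2 / s2
        if m1 == m2:
            continue
        km = (v2 - v1) / (m1 - m2)
        kms.append(km)
        vmaxs.append(v1 + m1 * km)
    if not kms:
        raise EstimationError("all point pairs are degenerate (parallel lines)")
    return float(np.median(kms)), float(np.median(vmaxs))


# ---------------------------------------------------------------------------
# Global fitting


def _relative_residuals(v_obs: np.ndarray, v_pred: np.ndarray) -> np.ndarray:
    scale = np.maximum(np.abs(v_obs), 1e-12 * max(np.max(np.abs(v_obs)), 1e-300))
    return (v_obs - v_pred) / scale


def _seed_starts(data: RateDataset, model: ModelSpec, n_starts: int,
                 rng: np.random.Generator) -> list[dict]:
    """Multistart locations: direct-linear-plot anchored start plus random
    log-uniform draws within bounds."""
    bounds = model.parameter_bounds()
    names = model.parameter_names()
    starts = []

    def clip(name, value):
        lo, hi = bounds[name]
        return float(min(max(value, lo * 1.001), hi * 0.999))

    e0 = data.observations[0].mix.e0
    # apparent Km/Vmax versus cofactor at the highest G6P level
    try:
        g6p_max = max(o.mix.g6p for o in data.observations)
        pts_b = [(data.cofactor_conc(o), o.v0) for o in data.observations
                 if o.mix.g6p == g6p_max and data.cofactor_conc(o) > 0]
        km_b, vmax_b = direct_linear_plot(pts_b)
        b_max = max(data.cofactor_conc(o) for o in data.observations)
        pts_a = [(o.mix.g6p, o.v0) for o in data.observations
                 if data.cofactor_conc(o) == b_max and o.mix.g6p > 0]
        km_a, _ = direct_linear_plot(pts_a)
        anchored = {
            "kcat": clip("kcat", vmax_b / e0 if e0 > 0 else vmax_b),
            "km_cofactor": clip("km_cofactor", km_b),
            "ki_cofactor": clip("ki_cofactor", km_b),
            "km_g6p": clip("km_g6p", km_a),
        }
        for extra in ("kic_product", "kis_cofactor", "decay_rate"):
            if extra in names:
                lo, hi = bounds[extra]
                anchored[extra] = math.sqrt(lo * hi)
        starts.append(anchored)
    except (EstimationError, InputError, InsufficientDataError):
        pass
    while len(starts) < n_starts:
        start = {}
        for name in names:
            lo, hi = bounds[name]
            start[name] = float(10 ** rng.uniform(math.log10(lo), math.log10(hi)))
        starts.append(start)
    return starts


def _fit_from_start(data: RateDataset, model: ModelSpec, v_obs: np.ndarray,
                    start: dict, bounds: dict):
    """Least-squares refinement in log10 parameter space."""
    names = list(bounds)
    x0 = np.array([math.log10(start[n]) for n in names])
    lo = np.array([math.log10(bounds[n][0]) for n in names])
    hi = np.array([math.log10(bounds[n][1]) for n in names])

    def resid(x):
        params = {n: 10.0 ** xi for n, xi in zip(names, x)}
        return _relative_residuals(v_obs, model.predict(data, params))

    sol = least_squares(resid, np.clip(x0, lo, hi), bounds=(lo, hi),
                        method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
                        max_nfev=400 * len(names))
    params = {n: float(10.0 ** xi) for n, xi in zip(names, sol.x)}
    ssr = float(2.0 * sol.cost)
    return params, ssr, bool(sol.success)


def _aicc(ssr: float, n: int, k: int) -> float:
    # fits below 1e-8 relative residual per point are numerically "perfect";
    # flooring the SSR there keeps AICc comparisons exact on noiseless data
    ssr = max(ssr, n * 1e-16)
    aic = n * math.log(ssr / n) + 2 * k
    denom = n - k - 1
    if denom <= 0:
        return math.inf
    return aic + 2 * k * (k + 1) / denom


def global_fit(data: RateDataset, model: ModelSpec, seed: int = 0,
               n_starts: int = 16) -> FitResult:
    """Fit all design points simultaneously with relative weighting.

    Starts from a direct-linear-plot anchored seed plus bound-scaled random
    starts; the best converged start wins.
    """
    data.require_fittable()
    names = model.parameter_names()
    if len(names) >= len(data.observations):
        raise InputError(
            f"model has {len(names)} parameters but only "
            f"{len(data.observations)} observations")
    bounds = model.parameter_bounds()
    v_obs = np.array([o.v0 for o in data.observations])
    rng = np.random.default_rng(seed)
    starts = _seed_starts(data, model, n_starts, rng)
    best = None
    diagnostics = []
    for start in starts:
        try:
            params, ssr, ok = _fit_from_start(data, model, v_obs, start, bounds)
        except Exception as exc:  # numeric failure of one start only
            diagnostics.append(repr(exc))
            continue
        diagnostics.append(f"ssr={ssr:.3e} ok={ok}")
        if ok and (best is None or ssr < best[1]):
            best = (params, ssr)
    if best is None:
        raise ConvergenceError("no multistart converged", diagnostics)
    params, ssr = best
    return FitResult(
        estimates=params, ssr=ssr,
        aicc=_aicc(ssr, len(data.observations), len(names)),
        n_obs=len(data.observations), converged=True, seed=seed,
        model=model.label())


def bootstrap_ci(data: RateDataset, model: ModelSpec, fit: FitResult,
                 n_boot: int = 1000, seed: int = 0) -> FitResult:
    """Parametric bootstrap 95% CIs by relative-residual resampling.

    Residuals r_i = (v_obs - v_fit)/v_fit are resampled with replacement onto
    the fitted curve; each replicate is refitted starting from the original
    estimates.  ci95 holds the 2.5/97.5 percentiles per parameter.
    """
    if n_boot <= 0:
        raise UsageError("n_boot must be a positive integer")
    if not fit.converged:
        raise UsageError("bootstrap_ci requires a converged fit")
    bounds = model.parameter_bounds()
    v_obs = np.array([o.v0 for o in data.observations])
    v_fit = model.predict(data, fit.estimates)
    if np.any(v_fit <= 0):
        raise EstimationError("fitted rates must be positive for relative resampling")
    rel = (v_obs - v_fit) / v_fit
    rng = np.random.default_rng(seed)
    draws = {n: [] for n in bounds}
    failures = 0
    for _ in range(n_boot):
        v_b = v_fit * (1.0 + rng.choice(rel, size=rel.size, replace=True))
        v_b = np.maximum(v_b, 0.0)
        try:
            params, _, ok = _fit_from_start(
                _dataset_with_rates(data, v_b), model, v_b, fit.estimates, bounds)
        except Exception:
            ok = False
        if not ok:
            failures += 1
            continue
        for n in bounds:
            draws[n].append(params[n])
    n_ok = n_boot - failures
    if n_ok == 0:
        raise ConvergenceError("every bootstrap refit failed")
    if failures > 0.2 * n_boot:
        warnings.warn(f"{failures}/{n_boot} bootstrap refits failed; "
                      "intervals use successes only", stacklevel=2)
    ci95 = {n: (float(np.percentile(draws[n], 2.5)),
                float(np.percentile(draws[n], 97.5))) for n in bounds}
    return FitResult(
        estimates=dict(fit.estimates), ssr=fit.ssr, aicc=fit.aicc,
        n_obs=fit.n_obs, converged=True, seed=seed, model=fit.model,
        ci95=ci95, bootstrap_failures=failures)


def _dataset_with_rates(data: RateDataset, v_new: np.ndarray) -> RateDataset:
    obs = tuple(RateObservation(mix=o.mix, v0=float(v), replicate_id=o.replicate_id,
                                time=o.time)
                for o, v in zip(data.observations, v_new))
    return RateDataset(observations=obs, enzyme_name=data.enzyme_name,
                       cofactor=data.cofactor)


def compare_models(data: RateDataset, candidates: Sequence[ModelSpec],
                   seed: int = 0, n_starts: int = 16) -> ModelComparison:
    """Fit every candidate mechanism and rank by AICc with Akaike weights.

    Ties in AICc are broken toward the candidate with fewer parameters.
    """
    if len(candidates) < 2:
        raise UsageError("compare_models needs at least 2 candidates")
    fits, aiccs, excluded, labels = {}, {}, {}, []
    for i, cand in enumerate(candidates):
        label = cand.label()
        if label in fits or label in excluded:
            label = f"{label}#{i}"
        labels.append(label)
        if len(cand.parameter_names()) >= len(data.observations):
            excluded[label] = "parameter count >= observations"
            warnings.warn(f"candidate {label} excluded: {excluded[label]}",
                          stacklevel=2)
            continue
        try:
            fits[label] = global_fit(data, cand, seed=seed, n_starts=n_starts)
            aiccs[label] = fits[label].aicc
        except ConvergenceError as exc:
            excluded[label] = f"did not converge: {exc}"
            warnings.warn(f"candidate {label} excluded: {excluded[label]}",
                          stacklevel=2)
    if not aiccs:
        raise ConvergenceError("no candidate could be fitted")
    amin = min(aiccs.values())
    rel = {lbl: math.exp(-0.5 * (a - amin)) for lbl, a in aiccs.items()}
    total = sum(rel.values())
    weights = {lbl: r / total for lbl, r in rel.items()}
    # minimal AICc; near-ties (<1e-6) resolved toward fewer parameters
    n_params = {lbl: len(fits[lbl].estimates) for lbl in aiccs}
    selected = min(aiccs, key=lambda lbl: (round((aiccs[lbl] - amin) / 1e-6),
                                           n_params[lbl], labels.index(lbl)))
    return ModelComparison(labels=labels, aicc=aiccs, weights=weights,
                           selected=selected, fits=fits, excluded=excluded)


# ---------------------------------------------------------------------------
# Selwyn inactivation test


def selwyn_test(curves: Sequence[ProgressCurve], threshold: float = 0.05,
                n_grid: int = 100) -> tuple[float, str]:
    """Enzyme-inactivation check on progress curves at different e0.

    In the absence of inactivation, product depends on time and enzyme only
    through the product e0*t, so curves at different enzyme concentrations
    superimpose on the e0*t axis.  The statistic is the RMS pairwise
    deviation between the rescaled curves on their common e0*t range,
    normalized by the maximum product reached there.
    """
    if len(curves) < 2:
        raise UsageError("selwyn_test needs at least 2 curves")
    e0s = [c.mix.e0 for c in curves]
    if len(set(e0s)) < 2:
        raise UsageError("curves must span at least 2 distinct e0 values")
    if any(e <= 0 for e in e0s):
        raise InputError("every curve needs e0 > 0")
    xs = [np.asarray(c.times) * c.mix.e0 for c in curves]
    lo = max(x[0] for x in xs)
    hi = min(x[-1] for x in xs)
    if hi <= lo:
        raise InsufficientOverlapError("curves share no common e0*t range")
    grid = np.linspace(lo, hi, n_grid)
    interp = [np.interp(grid, x, np.asarray(c.product))
              for x, c in zip(xs, curves)]
    pmax = max(float(p.max()) for p in interp)
    if pmax <= 0:
        raise InputError("no product formed on the common range")
    sq = [np.mean((pi - pj) ** 2)
          for pi, pj in itertools.combinations(interp, 2)]
    statistic = float(math.sqrt(float(np.mean(sq))) / pmax)
    verdict = "no_inactivation" if statistic <= threshold else "inactivation"
    return statistic, verdict
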