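"""Generalized age-period-cohort (GAPC) stochastic mortality models.

Four members of the family are implemented, distinguished by link function
and by which age/period/cohort terms enter the linear predictor eta_xt:

* LC   (Lee-Carter):        log m_xt   = b1_x + b2_x * k2_t
* APC  (age-period-cohort): log m_xt   = a_x + k_t + g_{t-x}
* CBD  (Cairns-Blake-Dowd): logit q_xt = k1_t + k2_t * (x - xbar)
* RH   (Renshaw-Haberman):  log m_xt   = b1_x + b2_x * k2_t + b3_x * g_{t-x}

Event counts D_xt are modelled as Poisson with mean E_xt * g^{-1}(eta_xt)
(central exposure used throughout; at an annual grain no better denominator
is available for CBD's initial exposure). Estimation maximizes the Poisson
log-likelihood by blockwise Newton updates cycling over parameter blocks,
each step guarded by step-halving so the likelihood never decreases, until
the relative log-likelihood change drops below ``tol``. Non-convergence
(``max_iter`` reached, or a degenerate likelihood) is a reported state on the
results object, never an exception — comparison tables show such fits as NA.

The usual identifiability constraints are imposed afterwards by invariance
transformations that leave eta (and hence the fitted rates) unchanged:
sum(b2)=1, sum(k2)=0 for LC/RH, additionally sum(b3)=1, sum(g)=0 for RH, and
sum(g)=0 with sum(c*g)=0 (plus a centred period index) for APC.

For LC only, ``fit(method="lc_svd")`` gives the classical singular-value
route: b1 = row means of log m, (b2, k2) from the leading singular triplet of
the centred log-rate matrix, same constraints.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit, logit, xlogy

from .surfaces import RateSurface

KINDS = ("LC", "APC", "CBD", "RH")
_EPS = 1e-12
_MAX_STEP = 4.0  # per-update clip on parameter moves (stability guard)


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one GAPC family member and its fit options."""

    kind: str = "LC"
    fit_method: str = "poisson_mle"  # or "lc_svd" (LC only)
    max_iter: int = 500
    tol: float = 1e-8
    seed: int | None = None  # reserved for perturbed restarts

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}; options {KINDS}")
        if self.fit_method not in ("poisson_mle", "lc_svd"):
            raise ValueError(f"unknown fit_method {self.fit_method!r}")
        if self.fit_method == "lc_svd" and self.kind != "LC":
            raise ValueError("lc_svd is only defined for the LC model")

    @property
    def link(self) -> str:
        return "logit" if self.kind == "CBD" else "log"


class GAPCModel:
    """A GAPC model bound to one events/exposure surface.

    Parameters
    ----------
    surface : RateSurface
        Combined surface carrying both events and exposure (zero-exposure
        cells get weight 0; every age and year must have at least one
        positive-exposure cell).
    kind : str
        "LC", "APC", "CBD" or "RH".

    Alternatively use :meth:`from_arrays`.
    """

    def __init__(self, surface: RateSurface, kind: str = "LC"):
        if surface.events is None or surface.exposure is None:
            raise ValueError("GAPCModel needs a surface with events and exposure")
        if kind not in KINDS:
            raise ValueError(f"unknown model kind {kind!r}; options {KINDS}")
        D = np.asarray(surface.events, dtype=float)
        E = np.asarray(surface.exposure, dtype=float)
        if (D < 0).any():
            raise ValueError("negative event counts")
        if D.shape[0] < 3 or D.shape[1] < 3:
            raise ValueError("need at least 3 ages and 3 years")
        W = ((E > 0) & np.isfinite(D)).astype(float)
        if (W.sum(axis=1) == 0).any() or (W.sum(axis=0) == 0).any():
            raise ValueError("some age or year has no usable (positive-exposure) cell")
        self.surface = surface
        self.kind = kind
        self.D = np.where(W > 0, D, 0.0)
        self.E = np.where(E > 0, E, 1.0)
        self.W = W
        self.x = np.asarray(surface.ages, dtype=float)
        self.t = np.asarray(surface.years, dtype=float)
        self.xbar = float(self.x.mean())
        # cohort bookkeeping (RH/APC): c = t - x, mapped cellwise to an index
        cgrid = np.rint(self.t[None, :] - self.x[:, None]).astype(int)
        self.cohorts = np.unique(cgrid)
        lookup = {c: i for i, c in enumerate(self.cohorts)}
        self.cidx = np.vectorize(lookup.get)(cgrid)

    @classmethod
    def from_arrays(cls, events, exposure, ages, years, kind="LC", rate_kind="mortality", sex="both"):
        surf = RateSurface(kind=rate_kind, sex=sex, ages=ages, years=years,
                           events=np.asarray(events, float), exposure=np.asarray(exposure, float))
        return cls(surf, kind=kind)

    # ------------------------------------------------------------ likelihood
    def _eta(self, p: dict) -> np.ndarray:
        k = self.kind
        if k == "LC":
            return p["alpha"][:, None] + p["beta2"][:, None] * p["kappa2"][None, :]
        if k == "APC":
            return p["alpha"][:, None] + p["kappa1"][None, :] + p["gamma"][self.cidx]
        if k == "RH":
            return (
                p["alpha"][:, None]
                + p["beta2"][:, None] * p["kappa2"][None, :]
                + p["beta3"][:, None] * p["gamma"][self.cidx]
            )
        # CBD
        return p["kappa1"][None, :] + p["kappa2"][None, :] * (self.x - self.xbar)[:, None]

    def _mu(self, p: dict) -> np.ndarray:
        eta = self._eta(p)
        if self.kind == "CBD":
            return self.E * expit(eta)
        return self.E * np.exp(np.clip(eta, -60.0, 30.0))

    def loglik(self, p: dict) -> float:
        mu = self._mu(p)
        return float(np.sum(self.W * (xlogy(self.D, mu) - mu)))

    # ---------------------------------------------------------------- fitting
    def _init_params(self) -> dict:
        A, Y = self.D.shape
        p = {}
        if self.kind == "CBD":
            with np.errstate(divide="ignore"):
                col = (self.D * self.W).sum(0) / np.maximum((self.E * self.W).sum(0), _EPS)
            p["kappa1"] = logit(np.clip(col, 1e-8, 1 - 1e-8))
            p["kappa2"] = np.zeros(Y)
            return p
        with np.errstate(divide="ignore"):
            row = np.maximum((self.D * self.W).sum(1), 0.5) / np.maximum((self.E * self.W).sum(1), _EPS)
        p["alpha"] = np.log(row)
        if self.kind in ("LC", "RH"):
            p["beta2"] = np.full(A, 1.0 / A)
            p["kappa2"] = np.zeros(Y)
        if self.kind == "APC":
            p["kappa1"] = np.zeros(Y)
            p["gamma"] = np.zeros(len(self.cohorts))
        if self.kind == "RH":
            p["beta3"] = np.full(A, 1.0 / A)
            p["gamma"] = np.zeros(len(self.cohorts))
        return p

    def _try_step(self, p: dict, updates: dict[str, np.ndarray], ll0: float) -> float:
        """Apply a (possibly multi-block) Newton step with step-halving so the
        log-likelihood never decreases; returns the accepted log-likelihood."""
        base = {k: p[k].copy() for k in updates}
        scale = 1.0
        for _ in range(30):
            for k, d in updates.items():
                p[k] = base[k] + scale * d
            ll1 = self.loglik(p)
            if np.isfinite(ll1) and ll1 >= ll0 - 1e-13 * (1.0 + abs(ll0)):
                return ll1
            scale *= 0.5
        for k in updates:
            p[k] = base[k]
        return ll0

    def _newton_age(self, p, key, factor_t, ll):
        """delta_x = sum_t W(D-mu)f_t / sum_t W mu f_t^2 for eta += key_x * f_t."""
        mu = self._mu(p)
        num = (self.W * (self.D - mu) * factor_t[None, :]).sum(1)
        den = (self.W * mu * (factor_t**2)[None, :]).sum(1)
        if den.max() <= _EPS:
            return ll
        delta = np.clip(num / np.maximum(den, _EPS), -_MAX_STEP, _MAX_STEP)
        return self._try_step(p, {key: delta}, ll)

    def _newton_year(self, p, key, factor_x, ll):
        mu = self._mu(p)
        num = (self.W * (self.D - mu) * factor_x[:, None]).sum(0)
        den = (self.W * mu * (factor_x**2)[:, None]).sum(0)
        if den.max() <= _EPS:
            return ll
        delta = np.clip(num / np.maximum(den, _EPS), -_MAX_STEP, _MAX_STEP)
        return self._try_step(p, {key: delta}, ll)

    def _newton_cohort(self, p, factor_x, ll):
        mu = self._mu(p)
        num = np.zeros(len(self.cohorts))
        den = np.zeros(len(self.cohorts))
        np.add.at(num, self.cidx, self.W * (self.D - mu) * factor_x[:, None])
        np.add.at(den, self.cidx, self.W * mu * (factor_x**2)[:, None])
        if den.max() <= _EPS:
            return ll
        delta = np.clip(num / np.maximum(den, _EPS), -_MAX_STEP, _MAX_STEP)
        return self._try_step(p, {"gamma": delta}, ll)

    def _cbd_step(self, p, ll):
        eta = self._eta(p)
        q = expit(eta)
        mu = self.E * q
        z = (self.x - self.xbar)[:, None]
        resid = self.W * (self.D - mu) * (1.0 - q)
        g1 = resid.sum(0)
        g2 = (resid * z).sum(0)
        w = self.W * self.E * q * (1.0 - q) ** 2  # Fisher weights
        i11 = w.sum(0)
        i12 = (w * z).sum(0)
        i22 = (w * z**2).sum(0)
        det = np.maximum(i11 * i22 - i12**2, _EPS)
        d1 = np.clip((i22 * g1 - i12 * g2) / det, -_MAX_STEP, _MAX_STEP)
        d2 = np.clip((i11 * g2 - i12 * g1) / det, -_MAX_STEP, _MAX_STEP)
        return self._try_step(p, {"kappa1": d1, "kappa2": d2}, ll)

    def _renormalize(self, p):
        """Invariance transformations keeping eta (hence loglik) unchanged;
        applied each sweep for numerical conditioning."""
        k = self.kind
        if k in ("LC", "RH"):
            m = p["kappa2"].mean()
            p["alpha"] = p["alpha"] + p["beta2"] * m
            p["kappa2"] = p["kappa2"] - m
            c = p["beta2"].sum()
            if abs(c) > _EPS:
                p["beta2"] = p["beta2"] / c
                p["kappa2"] = p["kappa2"] * c
        if k == "RH":
            m = p["gamma"].mean()
            p["alpha"] = p["alpha"] + p["beta3"] * m
            p["gamma"] = p["gamma"] - m
            c = p["beta3"].sum()
            if abs(c) > _EPS:
                p["beta3"] = p["beta3"] / c
                p["gamma"] = p["gamma"] * c
        if k == "APC":
            m = p["kappa1"].mean()
            p["alpha"] = p["alpha"] + m
            p["kappa1"] = p["kappa1"] - m

    def _sweep(self, p, ll):
        k = self.kind
        if k == "CBD":
            return self._cbd_step(p, ll)
        ones_t = np.ones(len(self.t))
        ll = self._newton_age(p, "alpha", ones_t, ll)
        if k == "LC" or k == "RH":
            ll = self._newton_year(p, "kappa2", p["beta2"], ll)
            ll = self._newton_age(p, "beta2", p["kappa2"], ll)
        if k == "APC":
            ll = self._newton_year(p, "kappa1", np.ones(len(self.x)), ll)
            ll = self._newton_cohort(p, np.ones(len(self.x)), ll)
        if k == "RH":
            ll = self._newton_cohort(p, p["beta3"], ll)
            gamma_cell = p["gamma"][self.cidx]
            mu = self._mu(p)
            num = (self.W * (self.D - mu) * gamma_cell).sum(1)
            den = (self.W * mu * gamma_cell**2).sum(1)
            if den.max() > _EPS:
                delta = np.clip(num / np.maximum(den, _EPS), -_MAX_STEP, _MAX_STEP)
                ll = self._try_step(p, {"beta3": delta}, ll)
        self._renormalize(p)
        return ll

    def fit(self, method: str = "poisson_mle", max_iter: int = 500, tol: float = 1e-8,
            start: dict | None = None) -> "GAPCResults":
        """Fit the model; see the module docstring for the algorithm."""
        spec = ModelSpec(kind=self.kind, fit_method=method, max_iter=max_iter, tol=tol)
        if method == "lc_svd":
            return self._fit_lc_svd(spec)
        p = self._init_params() if start is None else {k: np.asarray(v, float).copy() for k, v in start.items()}
        ll = self.loglik(p)
        trace = [ll]
        converged = False
        for _ in range(max_iter):
            ll_new = self._sweep(p, ll)
            trace.append(ll_new)
            if not np.isfinite(ll_new):
                converged = False
                break
            # runaway linear predictor (zero cells push an MLE to infinity:
            # the fit degenerates rather than converges)
            eta = self._eta(p)
            if np.abs(eta[self.W > 0]).max() > 40.0:
                converged = False
                break
            denom = abs(ll) if ll != 0 else 1.0
            if abs(ll_new - ll) < tol * denom:
                converged = True
                ll = ll_new
                break
            ll = ll_new
        res = GAPCResults(
            model=self, kind=self.kind, params=_full_params(p),
            converged=converged, loglik=ll, loglik_trace=np.array(trace),
            n_iter=len(trace) - 1, spec=spec,
        )
        return apply_constraints(res)

    def _fit_lc_svd(self, spec: ModelSpec) -> "GAPCResults":
        with np.errstate(divide="ignore", invalid="ignore"):
            m = self.D / self.E
        if not ((m > 0) | (self.W == 0)).all():
            m = np.where(m > 0, m, np.nanmin(np.where(m > 0, m, np.nan)) * 1e-2)
        logm = np.log(m)
        alpha = logm.mean(axis=1)
        Z = logm - alpha[:, None]
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        beta = U[:, 0]
        kappa = s[0] * Vt[0]
        if beta.sum() < 0:
            beta, kappa = -beta, -kappa
        p = {"alpha": alpha, "beta2": beta, "kappa2": kappa}
        self._renormalize(p)
        ll = self.loglik(p)
        res = GAPCResults(
            model=self, kind="LC", params=_full_params(p), converged=True,
            loglik=ll, loglik_trace=np.array([ll]), n_iter=0, spec=spec,
        )
        return apply_constraints(res)

    def results_from_params(self, params: dict, converged: bool = True) -> "GAPCResults":
        """Wrap externally supplied raw parameters in a results object
        (no constraints applied — useful for studying the transformations)."""
        p = {k: np.asarray(v, float).copy() for k, v in params.items()}
        ll = self.loglik(p)
        return GAPCResults(
            model=self, kind=self.kind, params=_full_params(p), converged=converged,
            loglik=ll, loglik_trace=np.array([ll]), n_iter=0,
            spec=ModelSpec(kind=self.kind),
        )


def _full_params(p: dict) -> dict:
    out = {k: None for k in ("alpha", "beta2", "beta3", "kappa1", "kappa2", "gamma")}
    for k, v in p.items():
        out[k] = np.asarray(v, dtype=float)
    return out


@dataclass
class GAPCResults:
    """Fitted GAPC model: parameters, convergence state and fitted surface."""

    model: GAPCModel
    kind: str
    params: dict
    converged: bool
    loglik: float
    loglik_trace: np.ndarray
    n_iter: int
    spec: ModelSpec = field(default_factory=ModelSpec)

    # parameter views (None where a component is absent from the model)
    @property
    def alpha(self):
        return self.params["alpha"]

    @property
    def beta2(self):
        return self.params["beta2"]

    @property
    def beta3(self):
        return self.params["beta3"]

    @property
    def kappa1(self):
        return self.params["kappa1"]

    @property
    def kappa2(self):
        return self.params["kappa2"]

    @property
    def gamma(self):
        return self.params["gamma"]

    @property
    def cohorts(self):
        return self.model.cohorts

    def _clean(self) -> dict:
        return {k: v for k, v in self.params.items() if v is not None}

    @property
    def fitted_surface(self) -> RateSurface:
        """g^{-1}(eta) on the model's age x year grid (rates m_xt, or q_xt
        for CBD); strictly positive by construction."""
        eta = self.model._eta(self._clean())
        rates = expit(eta) if self.kind == "CBD" else np.exp(eta)
        s = self.model.surface
        return RateSurface(kind=s.kind, sex=s.sex, ages=s.ages, years=s.years,
                          rates=rates, age_labels=s.age_labels)

    @property
    def residual_surface(self) -> RateSurface:
        """Empirical link-scale residuals (observed minus fitted eta);
        NaN where the observed rate is missing or zero."""
        s = self.model.surface
        obs = s.rate
        eta = self.model._eta(self._clean())
        with np.errstate(divide="ignore", invalid="ignore"):
            if self.kind == "CBD":
                obs_link = np.log(obs / (1.0 - obs))
            else:
                obs_link = np.log(obs)
        resid = np.where(np.isfinite(obs_link), obs_link - eta, np.nan)
        return RateSurface(kind="residual", sex=s.sex, ages=s.ages, years=s.years,
                          rates=resid, age_labels=s.age_labels)

    def summary(self) -> str:
        lines = [
            f"GAPC results — {self.kind} ({self.spec.fit_method})",
            f"  converged   {self.converged}",
            f"  iterations  {self.n_iter}",
            f"  loglik      {self.loglik:.4f}",
            f"  grid        {len(self.model.x)} ages x {len(self.model.t)} years",
        ]
        for name in ("alpha", "beta2", "beta3", "kappa1", "kappa2", "gamma"):
            v = self.params[name]
            if v is not None:
                lines.append(f"  {name:<7} len {len(v)}  sum {v.sum():+.4e}")
        return "\n".join(lines)

    # ---------------------------------------------------------------- export
    def to_json(self, path: str | Path) -> None:
        payload = {
            "kind": self.kind,
            "converged": bool(self.converged),
            "loglik": self.loglik,
            "n_iter": int(self.n_iter),
            "ages": self.model.x.tolist(),
            "years": self.model.t.tolist(),
            "cohorts": self.model.cohorts.tolist(),
            "params": {k: (v.tolist() if v is not None else None) for k, v in self.params.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    def plot_parameters(self, path: str | Path | None = None):
        """Quick-look parameter panels (alpha/beta over age, kappa over time,
        gamma over cohort)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        names = [n for n in ("alpha", "beta2", "beta3", "kappa1", "kappa2", "gamma") if self.params[n] is not None]
        fig, axes = plt.subplots(1, len(names), figsize=(3 * len(names), 2.6))
        if len(names) == 1:
            axes = [axes]
        for ax, n in zip(axes, names):
            xvals = {"alpha": self.model.x, "beta2": self.model.x, "beta3": self.model.x,
                     "kappa1": self.model.t, "kappa2": self.model.t, "gamma": self.model.cohorts}[n]
            ax.plot(xvals, self.params[n], marker=".", lw=1)
            ax.set_title(n, fontsize=9)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=110)
            plt.close(fig)
        return fig


def apply_constraints(res: GAPCResults) -> GAPCResults:
    """Impose the identifiability constraints via invariance transformations.

    The fitted surface is unchanged (up to floating round-off far below 1e-12
    relative); the operation is idempotent.
    """
    p = {k: v.copy() for k, v in res._clean().items()}
    k = res.kind
    if k in ("LC", "RH"):
        m = p["kappa2"].mean()
        p["alpha"] = p["alpha"] + p["beta2"] * m
        p["kappa2"] = p["kappa2"] - m
        c = p["beta2"].sum()
        if abs(c) > _EPS:
            p["beta2"] = p["beta2"] / c
            p["kappa2"] = p["kappa2"] * c
    if k == "RH":
        m = p["gamma"].mean()
        p["alpha"] = p["alpha"] + p["beta3"] * m
        p["gamma"] = p["gamma"] - m
        c = p["beta3"].sum()
        if abs(c) > _EPS:
            p["beta3"] = p["beta3"] / c
            p["gamma"] = p["gamma"] * c
    if k == "APC":
        c = res.model.cohorts.astype(float)
        cbar = c.mean()
        # two passes: the second removes cancellation residue from the large
        # cohort values so sum(gamma) and sum(c*gamma) hold to ~1e-13
        for _ in range(2):
            g = p["gamma"]
            g1 = ((c - cbar) * (g - g.mean())).sum() / ((c - cbar) ** 2).sum()
            g0 = g.mean() - g1 * cbar
            p["gamma"] = g - (g0 + g1 * c)
            p["kappa1"] = p["kappa1"] + g0 + g1 * res.model.t
            p["alpha"] = p["alpha"] - g1 * res.model.x
        m = p["kappa1"].mean()
        p["alpha"] = p["alpha"] + m
        p["kappa1"] = p["kappa1"] - m
    return GAPCResults(
        model=res.model, kind=res.kind, params=_full_params(p),
        converged=res.converged, loglik=res.loglik,
        loglik_trace=res.loglik_trace, n_iter=res.n_iter, spec=res.spec,
    )


def fit_gapc(events: RateSurface, exposure: RateSurface, spec: ModelSpec) -> GAPCResults:
    """Functional entry point matching the surface-pair interface."""
    from .surfaces import compute_rates

    surf = compute_rates(events, exposure)
    return GAPCModel(surf, kind=spec.kind).fit(
        method=spec.fit_method, max_iter=spec.max_iter, tol=spec.tol
    )


def fitted_rates(res: GAPCResults, override: bool = False) -> RateSurface:
    """Fitted rate surface; refuses a non-converged fit unless overridden."""
    if not res.converged and not override:
        raise ValueError("fit did not converge; pass override=True to evaluate anyway")
    return res.fitted_surface
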