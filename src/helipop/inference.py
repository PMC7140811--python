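"""Maximum-likelihood fitting of divergence models to a joint SFS.

The interface follows the Model/Results convention: a
:class:`DivergenceModel` is built from an observed unfolded joint SFS and a
model id; ``fit()`` runs a multi-round, multi-replicate Nelder-Mead search
(random starts, then perturbation of the incumbent) and returns a
:class:`DivergenceFit` carrying the ML parameters, the profiled theta, the
log-likelihood, AIC, Fisher-information standard deviations and a
``summary()`` table.  Unit conversion to individuals/years uses
N_ref = theta / (4 mu L).

The likelihood is the Poisson form with the analytically profiled scale:
theta-hat = sum(data)/sum(model) over unmasked cells, equivalent to the
multinomial likelihood up to a data-only constant.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

from .diffusion import DEFAULT_DT_FAC, DEFAULT_GRIDS, DemographicParams, expected_sfs
from .sfs import JointSFS

logger = logging.getLogger(__name__)

DEFAULT_BOUNDS = {"nu": (1e-3, 100.0), "T": (1e-3, 10.0), "m": (1e-3, 20.0)}

#: migrants/year = m_scaled / 2 / generation_time: the per-generation number
#: of migrant individuals measured in units of N_ref (direction-independent).
MIGRATION_CONVENTION = "migrants_per_year = m_scaled / 2 / gen_time (N_ref units)"


def aic(ll: float, k: int) -> float:
    """Akaike information criterion 2k - 2*ll (k = free demographic params)."""
    if k < 0:
        raise ValueError("k must be non-negative")
    return 2.0 * k - 2.0 * ll


def delta_aic(aics) -> np.ndarray:
    aics = np.asarray(aics, dtype=float)
    return aics - aics.min()


def multinomial_loglik(data: JointSFS, model: JointSFS, eps: float = 1e-12):
    """Poisson log-likelihood with analytically optimal scaling.

    Returns (ll, theta_hat) where theta_hat = sum(data)/sum(model) over
    unmasked cells and ll = sum[d*log(theta*m) - theta*m - log(d!)].  Model
    cells that are zero where the data are positive are floored at ``eps``
    (with a warning), keeping the likelihood finite.
    """
    if data.data.shape != model.data.shape:
        raise ValueError("data and model spectra have different shapes")
    mask = data.mask | model.mask
    d = data.data[~mask]
    m = model.data[~mask].copy()
    bad = (m <= 0) & (d > 0)
    if bad.any():
        logger.warning("flooring %d zero model cells with observed data",
                       int(bad.sum()))
    m = np.maximum(m, eps)
    theta_hat = d.sum() / m.sum()
    lam = theta_hat * m
    ll = float(np.sum(d * np.log(lam) - lam - gammaln(d + 1.0)))
    return ll, float(theta_hat)


@dataclass
class OptimizerSchedule:
    """Multi-round Nelder-Mead search schedule.

    Round 1 draws each replicate's start log-uniformly within the bounds;
    every later round perturbs the best parameters found so far by a
    multiplicative factor 2**(fold*u), u ~ Uniform(-1, 1) per parameter.
    ``maxiter`` caps the Nelder-Mead iterations of each replicate.
    """

    rounds: int = 4
    replicates: tuple = (50, 50, 50, 100)
    maxiter: tuple = (3, 5, 15, 50)
    fold: tuple = (3, 2, 2, 1)

    def __post_init__(self):
        if not (len(self.replicates) == len(self.maxiter) == len(self.fold)
                == self.rounds):
            raise ValueError("schedule lists must all have length `rounds`")
        if min(self.replicates) < 1:
            raise ValueError("each round needs at least one replicate")

    @classmethod
    def reduced(cls) -> "OptimizerSchedule":
        """Two-round schedule for simulation studies and tests."""
        return cls(rounds=2, replicates=(10, 10), maxiter=(15, 200),
                   fold=(2, 1))


@dataclass
class DivergenceFit:
    """Results of a divergence-model fit."""

    model: str
    params: DemographicParams            # ML params, theta = theta_hat
    log_likelihood: float
    aic: float
    k: int
    sd: dict = field(default_factory=dict)        # FIM standard deviations
    trace: list = field(default_factory=list)     # (round, replicate, ll)
    converted: dict = field(default_factory=dict)
    migration_convention: str = MIGRATION_CONVENTION

    @property
    def theta_hat(self) -> float:
        return self.params.theta

    def convert(self, mu: float, L: float, gen_time: float = 1.0) -> dict:
        self.converted = convert_units(self, mu, L, gen_time)
        return self.converted

    def summary(self) -> str:
        lines = [
            f"Divergence model {self.model} fit",
            "=" * 34,
            f"log-likelihood {self.log_likelihood:12.3f}",
            f"AIC (k={self.k})   {self.aic:12.3f}",
            f"theta-hat      {self.theta_hat:12.4f}",
            "-" * 34,
            f"{'parameter':<18}{'estimate':>10}{'sd':>9}",
        ]
        for name in DemographicParams.free_param_names(self.model):
            sd = self.sd.get(name, np.nan)
            lines.append(f"{name:<18}{getattr(self.params, name):>10.4f}"
                         f"{sd:>9.4f}")
        if self.converted:
            lines.append("-" * 34)
            for key, val in self.converted.items():
                if isinstance(val, float):
                    lines.append(f"{key:<22}{val:>12.4g}")
            lines.append(f"convention: {self.migration_convention}")
        return "\n".join(lines)


class DivergenceModel:
    """Two-population divergence model bound to an observed joint SFS.

    Parameters
    ----------
    data : JointSFS
        Observed unfolded spectrum (wild on axis 0, cultivated on axis 1),
        absorbing corners masked.
    model : {'A', 'B', 'C'}
        Divergence without gene flow, with symmetric gene flow, or with
        asymmetric gene flow.
    grids : sequence of int
        Diffusion grid sizes for Richardson extrapolation.
    dt_fac : float
        Time-step control of the diffusion integration.
    bounds : dict, optional
        Override of the default search bounds per parameter kind
        ('nu', 'T', 'm') or per parameter name.
    """

    def __init__(self, data: JointSFS, model: str = "C", grids=DEFAULT_GRIDS,
                 dt_fac: float = DEFAULT_DT_FAC, bounds=None):
        if model not in ("A", "B", "C"):
            raise ValueError("model must be 'A', 'B' or 'C'")
        if getattr(data, "folded", False):
            raise ValueError("only unfolded spectra are supported")
        self.data = data
        self.model = model
        self.grids = tuple(grids)
        self.dt_fac = dt_fac
        self.param_names = DemographicParams.free_param_names(model)
        self.k = len(self.param_names)
        self.bounds = self._resolve_bounds(bounds)
        self.n_evals = 0

    def _resolve_bounds(self, bounds):
        spec = dict(DEFAULT_BOUNDS)
        named = {}
        if bounds:
            for key, val in bounds.items():
                if key in spec:
                    spec[key] = val
                else:
                    named[key] = val
        out = []
        for name in self.param_names:
            if name in named:
                out.append(tuple(named[name]))
            elif name == "T":
                out.append(tuple(spec["T"]))
            elif name.startswith("m"):
                out.append(tuple(spec["m"]))
            else:
                out.append(tuple(spec["nu"]))
        return np.array(out)  # (k, 2)

    # -- likelihood ---------------------------------------------------------
    def expected(self, vec) -> JointSFS:
        params = DemographicParams.from_vector(self.model, vec)
        return expected_sfs(params, self.data.sample_sizes,
                            grids=self.grids, dt_fac=self.dt_fac)

    def loglik(self, vec):
        """(ll, theta_hat) at a free-parameter vector."""
        self.n_evals += 1
        return multinomial_loglik(self.data, self.expected(vec))

    def _objective_log(self, logp):
        lo = np.log(self.bounds[:, 0])
        hi = np.log(self.bounds[:, 1])
        excess = np.maximum(logp - hi, 0.0) + np.maximum(lo - logp, 0.0)
        penalty = 1e8 * float((excess ** 2).sum())
        vec = np.exp(np.clip(logp, lo, hi))
        try:
            ll, _ = self.loglik(vec)
        except FloatingPointError:
            return 1e12
        return -ll + penalty

    # -- fitting ------------------------------------------------------------
    def fit(self, schedule: OptimizerSchedule | None = None, seed: int = 0,
            compute_fim: bool = True, fim_step: float = 1e-3) -> DivergenceFit:
        """Multi-round Nelder-Mead maximum-likelihood search.

        Deterministic for a fixed ``seed``.  The search runs on log
        parameters (the natural scale for rates and sizes spanning decades),
        with a smooth penalty outside the bounds.
        """
        schedule = schedule or OptimizerSchedule()
        rng = np.random.default_rng(seed)
        lo = np.log(self.bounds[:, 0])
        hi = np.log(self.bounds[:, 1])

        best_logp, best_ll = None, -np.inf
        trace = []
        for rnd in range(schedule.rounds):
            for rep in range(schedule.replicates[rnd]):
                if rnd == 0 or best_logp is None:
                    start = rng.uniform(lo, hi)
                else:
                    # perturb the best-so-far (updated across replicates)
                    u = rng.uniform(-1.0, 1.0, size=len(lo))
                    start = np.clip(
                        best_logp + schedule.fold[rnd] * u * np.log(2.0),
                        lo, hi)
                res = minimize(self._objective_log, start,
                               method="Nelder-Mead",
                               options={"maxiter": schedule.maxiter[rnd],
                                        "adaptive": True,
                                        "xatol": 1e-4, "fatol": 1e-2})
                ll = -float(res.fun)
                trace.append((rnd + 1, rep + 1, ll))
                if ll > best_ll:
                    best_ll, best_logp = ll, res.x
            logger.info("round %d best ll %.3f", rnd + 1, best_ll)
        if best_logp is None or not np.isfinite(best_ll):
            raise RuntimeError(f"all replicates failed; trace: {trace}")

        vec = np.exp(np.clip(best_logp, lo, hi))
        ll, theta_hat = self.loglik(vec)
        params = DemographicParams.from_vector(self.model, vec,
                                               theta=theta_hat)
        sd = {}
        if compute_fim:
            sds = fim_uncertainty(self, vec, rel_step=fim_step)
            sd = dict(zip(self.param_names, sds))
        return DivergenceFit(model=self.model, params=params,
                             log_likelihood=ll, aic=aic(ll, self.k),
                             k=self.k, sd=sd, trace=trace)


def fim_uncertainty(model: DivergenceModel, ml_vec, rel_step: float = 1e-3):
    """Standard deviations from the observed Fisher information.

    Central-difference Hessian of the log-likelihood at the ML point;
    standard deviations are square roots of the diagonal of the inverse
    information.  A non-positive-definite information matrix yields NaN for
    the affected parameters rather than an exception.
    """
    vec = np.asarray(ml_vec, dtype=float)
    k = len(vec)
    h = rel_step * np.abs(vec)

    def ll(v):
        return model.loglik(v)[0]

    hess = np.empty((k, k))
    f0 = ll(vec)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        fpp = ll(vec + ei)
        fmm = ll(vec - ei)
        hess[i, i] = (fpp - 2 * f0 + fmm) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            fij = ll(vec + ei + ej)
            fi = ll(vec + ei - ej)
            fj = ll(vec - ei + ej)
            fb = ll(vec - ei - ej)
            hess[i, j] = hess[j, i] = (fij - fi - fj + fb) / (4 * h[i] * h[j])
    fim = -hess
    try:
        cov = np.linalg.inv(fim)
        diag = np.diag(cov).copy()
        diag[diag < 0] = np.nan
        return np.sqrt(diag)
    except np.linalg.LinAlgError:
        return np.full(k, np.nan)


def convert_units(fit: DivergenceFit, mu: float, L: float,
                  gen_time: float = 1.0) -> dict:
    """Convert dimensionless ML estimates to biological units.

    N_ref = theta_hat/(4 mu L); sizes N_x = nu_x * N_ref; T in years =
    T * 2 * N_ref * gen_time; migration in migrants/year via the documented
    direction-independent convention m_scaled/2/gen_time.
    """
    if min(mu, L, gen_time) <= 0:
        raise ValueError("mu, L and gen_time must be positive")
    p = fit.params
    n_ref = fit.theta_hat / (4.0 * mu * L)
    out = {
        "N_ref": n_ref,
        "N_wild_current": p.nu_wild_current * n_ref,
        "N_cult_founder": p.nu_cult_founder * n_ref,
        "N_cult_current": p.nu_cult_current * n_ref,
        "T_years": p.T * 2.0 * n_ref * gen_time,
        "mu": mu, "L": L, "gen_time": gen_time,
        "migration_convention": MIGRATION_CONVENTION,
    }
    if fit.model == "B":
        out["M_sym"] = p.m_sym / 2.0 / gen_time
    elif fit.model == "C":
        out["M_w_to_c"] = p.m_w_to_c / 2.0 / gen_time
        out["M_c_to_w"] = p.m_c_to_w / 2.0 / gen_time
    return out


def scaled_migration_from_natural(migrants_per_year: float,
                                  gen_time: float = 1.0) -> float:
    """Inverse of the migration unit convention (natural -> dimensionless)."""
    return 2.0 * migrants_per_year * gen_time


def effective_length(bases_sequenced: float, snps_used: int,
                     snps_total: int) -> float:
    """Effective sequence length L = bases * (SNPs used / SNPs called)."""
    if snps_total <= 0 or snps_used <= 0:
        raise ValueError("SNP counts must be positive")
    if snps_used > snps_total:
        raise ValueError("snps_used cannot exceed snps_total")
    return bases_sequenced * snps_used / snps_total
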