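"""Double-hierarchical Gaussian models via Metropolis-within-Gibbs MCMC.

The core model regresses both the mean and the (log) residual SD of a
Gaussian response on covariates, with correlated per-individual random
intercepts on both parts:

    y_ij ~ Normal(X_ij' b_mean + a_i,  exp(Z_ij' b_sigma + b_i)^2)
    (a_i, b_i) ~ BVN(0; sd_a, sd_b, rho)

Letting residual variance differ between individuals and with covariates is
what separates this from an ordinary mixed model: it quantifies not just how
much individuals differ on average (sd_a) but how much they differ in
*plasticity* (sd_b), and whether mean level and plasticity covary (rho).
An optional AR(1) on within-individual standardised residuals absorbs
day-to-day carryover.

Priors: Normal(0, sd 10) on fixed effects (variance 100), half-t with 3
degrees of freedom on random-effect SDs (scale = the response's empirical
SD), uniform on the correlation and on the AR(1) coefficient.

Sampling: bespoke adaptive Metropolis-within-Gibbs.  The Gaussian mean part
(b_mean and the a_i) is updated by exact conjugate Gibbs draws; the sigma
part (b_sigma, b_i) by adaptive random-walk Metropolis (per-coordinate for
b_sigma, vectorised per-individual for b_i); the hyperparameters
(log sd_a, log sd_b, Fisher-z rho) by a joint random-walk block.  Proposal
scales adapt by Robbins-Monro during burn-in only, so the post-burn-in chain
is a valid fixed-kernel MCMC.  With AR(1) enabled the conjugate shortcuts no
longer hold and every block falls back to random-walk Metropolis under the
full AR(1) likelihood.

Effects are summarised by the posterior median, the 95% credible interval
and P_x, the percentage of posterior draws on the opposite side of zero from
the median; P_x < 5 is treated as a meaningful effect.

:func:`random_slope_fit` reuses the same machinery for an ordinary Gaussian
mixed model with correlated per-individual intercepts and slopes (the
TST-versus-fragmentation analyses).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DhglmSpec",
    "DhglmPosterior",
    "log_posterior",
    "fit",
    "px",
    "random_slope_fit",
    "split_rhat",
    "effective_sample_size",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclasses.dataclass
class DhglmSpec:
    """Model definition and sampler settings.

    ``mean_covariates`` / ``sigma_covariates`` name columns of the data
    table; an intercept is always included in both parts.  ``iterations``
    counts total iterations per chain including ``burn_in``.
    """

    response: str
    mean_covariates: list[str] = dataclasses.field(default_factory=list)
    sigma_covariates: list[str] = dataclasses.field(default_factory=list)
    id_col: str = "individual"
    ar1: bool = False
    prior_beta_sd: float = 10.0
    re_scale_df: float = 3.0
    re_scale: float | None = None  # default: empirical SD of the response
    chains: int = 4
    iterations: int = 6000
    burn_in: int = 1000
    thin: int = 5
    seed: int = 0
    prior_only: bool = False

    def __post_init__(self) -> None:
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")
        if self.thin < 1 or self.chains < 1:
            raise ValueError("thin and chains must be >= 1")


@dataclasses.dataclass
class _ModelData:
    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    idx: np.ndarray
    m: int
    individuals: np.ndarray
    x_names: list[str]
    z_names: list[str]
    re_scale: float


def _prepare(data: pd.DataFrame, spec: DhglmSpec, check_identifiability: bool = True) -> _ModelData:
    for col in [spec.response, spec.id_col, *spec.mean_covariates, *spec.sigma_covariates]:
        if col not in data.columns:
            raise ValueError(f"column {col!r} missing from data")
    y = data[spec.response].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite response values")
    ids, idx = np.unique(data[spec.id_col].to_numpy(), return_inverse=True)
    m = len(ids)
    counts = np.bincount(idx, minlength=m)
    if check_identifiability and not spec.prior_only:
        if m < 2:
            raise ValueError("need at least 2 individuals for identifiability")
        if counts.min() < 2:
            raise ValueError("need at least 2 observations per individual")

    def build(names):
        cols = [np.ones(len(data))]
        for nm in names:
            c = data[nm].to_numpy(dtype=float)
            if not np.all(np.isfinite(c)):
                raise ValueError(f"non-finite values in covariate {nm!r}")
            cols.append(c)
        return np.column_stack(cols), ["intercept", *names]

    X, x_names = build(spec.mean_covariates)
    Z, z_names = build(spec.sigma_covariates)
    re_scale = spec.re_scale if spec.re_scale is not None else float(np.std(y)) or 1.0

    if spec.prior_only:
        keep = np.zeros(len(y), dtype=bool)
        y, X, Z, idx = y[keep], X[keep], Z[keep], idx[keep]
        m = max(m, 2)

    # AR(1) needs rows grouped by individual in chronological order
    order = np.argsort(idx, kind="stable")
    return _ModelData(
        y=y[order], X=X[order], Z=Z[order], idx=idx[order], m=m,
        individuals=ids, x_names=x_names, z_names=z_names, re_scale=re_scale,
    )


def _half_t_logpdf(x: float, df: float, scale: float) -> float:
    if x <= 0:
        return -np.inf
    return float(stats.t.logpdf(x / scale, df) + np.log(2.0 / scale))


def _bvn_logpdf(a: np.ndarray, b: np.ndarray, sa: float, sb: float, rho: float) -> float:
    if sa <= 0 or sb <= 0 or not (-1.0 < rho < 1.0):
        return -np.inf
    omr2 = 1.0 - rho * rho
    q = (a / sa) ** 2 - 2.0 * rho * (a / sa) * (b / sb) + (b / sb) ** 2
    return float(np.sum(-_LOG_2PI - np.log(sa * sb) - 0.5 * np.log(omr2) - q / (2.0 * omr2)))


def _gauss_loglik(y, mu, log_sd):
    r = (y - mu) * np.exp(-log_sd)
    return float(np.sum(-0.5 * _LOG_2PI - log_sd) - 0.5 * np.sum(r * r))


def _ar1_loglik(y, mu, log_sd, idx, phi):
    """Gaussian likelihood with AR(1) on within-individual standardised residuals."""
    if not (-1.0 < phi < 1.0):
        return -np.inf
    r = (y - mu) * np.exp(-log_sd)
    base = float(np.sum(-0.5 * _LOG_2PI - log_sd))
    if len(r) == 0:
        return base
    first = np.concatenate([[True], idx[1:] != idx[:-1]])
    innov = r[1:] - phi * r[:-1]
    later = ~first[1:]
    omp2 = 1.0 - phi * phi
    ll = -0.5 * float(np.sum(r[first] ** 2))
    ll += -0.5 * float(np.sum(innov[later] ** 2)) / omp2
    ll += -0.5 * np.log(omp2) * float(np.sum(later))
    return base + ll


def log_posterior(params: dict, data: pd.DataFrame | _ModelData, spec: DhglmSpec) -> float:
    """Joint log density of data and priors at one parameter point.

    ``params`` holds ``beta_mean``, ``beta_sigma`` (arrays, intercept first),
    ``a``, ``b`` (per-individual arrays), ``sd_a``, ``sd_b``, ``rho`` and,
    when ``spec.ar1``, ``phi``.  Returns -inf outside the support.
    """
    md = data if isinstance(data, _ModelData) else _prepare(data, spec, check_identifiability=False)
    bm = np.asarray(params["beta_mean"], dtype=float)
    bs = np.asarray(params["beta_sigma"], dtype=float)
    a = np.asarray(params["a"], dtype=float)
    b = np.asarray(params["b"], dtype=float)
    sa, sb, rho = float(params["sd_a"]), float(params["sd_b"]), float(params["rho"])
    if not all(np.all(np.isfinite(v)) for v in (bm, bs, a, b)):
        raise ValueError("non-finite parameter values")
    if sa <= 0 or sb <= 0 or not (-1.0 < rho < 1.0):
        return -np.inf

    lp = float(np.sum(stats.norm.logpdf(bm, 0.0, spec.prior_beta_sd)))
    lp += float(np.sum(stats.norm.logpdf(bs, 0.0, spec.prior_beta_sd)))
    lp += _half_t_logpdf(sa, spec.re_scale_df, md.re_scale)
    lp += _half_t_logpdf(sb, spec.re_scale_df, md.re_scale)
    lp += _bvn_logpdf(a, b, sa, sb, rho)
    # rho and phi carry uniform priors on (-1, 1)

    mu = md.X @ bm + (a[md.idx] if len(md.idx) else 0.0)
    log_sd = md.Z @ bs + (b[md.idx] if len(md.idx) else 0.0)
    if spec.ar1:
        phi = float(params.get("phi", 0.0))
        lp += _ar1_loglik(md.y, mu, log_sd, md.idx, phi)
    else:
        lp += _gauss_loglik(md.y, mu, log_sd)
    return lp


# ---------------------------------------------------------------------------
# sampler machinery
# ---------------------------------------------------------------------------


class _AdaptiveScale:
    """Robbins-Monro proposal-scale adaptation toward a target acceptance."""

    def __init__(self, init, target=0.35):
        self.log_s = np.log(np.asarray(init, dtype=float))
        self.target = target
        self.k = 0

    @property
    def scale(self):
        return np.exp(self.log_s)

    def update(self, accepted, adapting: bool):
        self.k += 1
        if adapting:
            gamma = 1.0 / self.k**0.6
            self.log_s += gamma * (np.asarray(accepted, dtype=float) - self.target)


def _run_dhglm_chain(md: _ModelData, spec: DhglmSpec, seed) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed)
    n, m, p, q = len(md.y), md.m, md.X.shape[1], md.Z.shape[1]
    tau2 = spec.prior_beta_sd**2

    # initial values from simple moment fits
    if n:
        bm = np.linalg.lstsq(md.X, md.y, rcond=None)[0]
        resid_sd = float(np.std(md.y - md.X @ bm)) or 1.0
    else:
        bm = np.zeros(p)
        resid_sd = 1.0
    bs = np.zeros(q)
    bs[0] = np.log(resid_sd)
    a = np.zeros(m)
    b = np.zeros(m)
    sa, sb, rho, phi = 0.5 * resid_sd, 0.2, 0.0, 0.0

    s_bs = _AdaptiveScale(np.full(q, 0.05), target=0.44)
    s_b = _AdaptiveScale(np.full(m, 0.1), target=0.44)
    s_hyper = _AdaptiveScale(0.2, target=0.3)
    s_bm = _AdaptiveScale(np.full(p, 0.05), target=0.44)  # AR(1) path only
    s_a = _AdaptiveScale(np.full(m, 0.1 * resid_sd), target=0.44)
    s_phi = _AdaptiveScale(0.2, target=0.44)

    counts = np.bincount(md.idx, minlength=m).astype(float) if n else np.zeros(m)

    def loglik(mu, log_sd, phi_val):
        if spec.ar1:
            return _ar1_loglik(md.y, mu, log_sd, md.idx, phi_val)
        return _gauss_loglik(md.y, mu, log_sd)

    n_keep = (spec.iterations - spec.burn_in + spec.thin - 1) // spec.thin
    out = {
        "beta_mean": np.empty((n_keep, p)),
        "beta_sigma": np.empty((n_keep, q)),
        "sd_a": np.empty(n_keep),
        "sd_b": np.empty(n_keep),
        "rho": np.empty(n_keep),
        "a": np.empty((n_keep, m)),
        "b": np.empty((n_keep, m)),
    }
    if spec.ar1:
        out["phi"] = np.empty(n_keep)
    kept = 0

    for it in range(spec.iterations):
        adapting = it < spec.burn_in
        log_sd = md.Z @ bs + (b[md.idx] if n else 0.0)
        w = np.exp(-2.0 * log_sd) if n else np.empty(0)

        omr2 = 1.0 - rho * rho
        v_a = sa * sa * omr2  # conditional var of a_i | b_i
        m_a = rho * (sa / sb) * b
        v_b = sb * sb * omr2
        m_b = rho * (sb / sa) * a

        if not spec.ar1:
            # --- conjugate Gibbs: beta_mean ---
            r = md.y - (a[md.idx] if n else 0.0)
            Xw = md.X * w[:, None] if n else md.X
            prec = (md.X.T @ Xw if n else np.zeros((p, p))) + np.eye(p) / tau2
            mean = np.linalg.solve(prec, md.X.T @ (w * r) if n else np.zeros(p))
            L = np.linalg.cholesky(np.linalg.inv(prec))
            bm = mean + L @ rng.standard_normal(p)

            # --- conjugate Gibbs: a_i ---
            resid = md.y - md.X @ bm
            sw = np.bincount(md.idx, weights=w, minlength=m) if n else np.zeros(m)
            swr = np.bincount(md.idx, weights=w * resid, minlength=m) if n else np.zeros(m)
            post_prec = sw + 1.0 / v_a
            post_mean = (swr + m_a / v_a) / post_prec
            a = post_mean + rng.standard_normal(m) / np.sqrt(post_prec)
        else:
            # --- RW Metropolis: beta_mean (per coordinate) ---
            mu = md.X @ bm + a[md.idx]
            cur = loglik(mu, log_sd, phi)
            acc = np.zeros(p)
            for j in range(p):
                prop = bm.copy()
                prop[j] += s_bm.scale[j] * rng.standard_normal()
                new = loglik(md.X @ prop + a[md.idx], log_sd, phi)
                dprior = (bm[j] ** 2 - prop[j] ** 2) / (2 * tau2)
                if np.log(rng.random()) < new - cur + dprior:
                    bm, cur, acc[j] = prop, new, 1.0
            s_bm.update(acc, adapting)

            # --- RW Metropolis: a_i (loop; AR(1) couples samples in time) ---
            acc_a = np.zeros(m)
            for i in range(m):
                prop_a = a.copy()
                prop_a[i] += s_a.scale[i] * rng.standard_normal()
                new = loglik(md.X @ bm + prop_a[md.idx], log_sd, phi)
                dprior = ((a[i] - m_a[i]) ** 2 - (prop_a[i] - m_a[i]) ** 2) / (2 * v_a)
                if np.log(rng.random()) < new - cur + dprior:
                    a, cur, acc_a[i] = prop_a, new, 1.0
            s_a.update(acc_a, adapting)

        mu = md.X @ bm + (a[md.idx] if n else 0.0)

        # --- RW Metropolis: beta_sigma, one coordinate at a time ---
        cur = loglik(mu, log_sd, phi)
        acc = np.zeros(q)
        for j in range(q):
            step = s_bs.scale[j] * rng.standard_normal()
            prop = bs.copy()
            prop[j] += step
            new_log_sd = log_sd + md.Z[:, j] * step if n else log_sd
            new = loglik(mu, new_log_sd, phi)
            dprior = (bs[j] ** 2 - prop[j] ** 2) / (2 * tau2)
            if np.log(rng.random()) < new - cur + dprior:
                bs, log_sd, cur = prop, new_log_sd, new
                acc[j] = 1.0
        s_bs.update(acc, adapting)

        # --- RW Metropolis: b_i ---
        if not spec.ar1:
            # vectorised: individuals are conditionally independent
            delta = s_b.scale * rng.standard_normal(m)
            r2w = (md.y - mu) ** 2 * w if n else np.empty(0)
            s_r2w = np.bincount(md.idx, weights=r2w, minlength=m) if n else np.zeros(m)
            # change in sum(-log_sd - 0.5 r^2/sd^2) per individual
            dll = -counts * delta - 0.5 * s_r2w * (np.exp(-2.0 * delta) - 1.0)
            dprior = ((b - m_b) ** 2 - (b + delta - m_b) ** 2) / (2 * v_b)
            accept = np.log(rng.random(m)) < dll + dprior
            b = np.where(accept, b + delta, b)
            s_b.update(accept, adapting)
            log_sd = md.Z @ bs + (b[md.idx] if n else 0.0)
        else:
            acc_b = np.zeros(m)
            cur = loglik(mu, log_sd, phi)
            for i in range(m):
                prop_b = b.copy()
                prop_b[i] += s_b.scale[i] * rng.standard_normal()
                new_log_sd = md.Z @ bs + prop_b[md.idx]
                new = loglik(mu, new_log_sd, phi)
                dprior = ((b[i] - m_b[i]) ** 2 - (prop_b[i] - m_b[i]) ** 2) / (2 * v_b)
                if np.log(rng.random()) < new - cur + dprior:
                    b, log_sd, cur, acc_b[i] = prop_b, new_log_sd, new, 1.0
            s_b.update(acc_b, adapting)

        # --- Gibbs translation moves against the intercepts ---
        # shifting (intercept, all a_i) or (sigma intercept, all b_i) in
        # opposite directions leaves the likelihood invariant; the conditional
        # over the shift is Gaussian under the Gaussian priors, so this is an
        # exact Gibbs step that decouples the intercepts from the random
        # effects (they mix very slowly otherwise)
        prec_d = 1.0 / tau2 + m / v_a
        mean_d = (-bm[0] / tau2 + np.sum(a - m_a) / v_a) / prec_d
        d = mean_d + rng.standard_normal() / np.sqrt(prec_d)
        bm = bm.copy()
        bm[0] += d
        a = a - d
        m_b = rho * (sb / sa) * a  # a changed; refresh the conditional mean
        prec_d = 1.0 / tau2 + m / v_b
        mean_d = (-bs[0] / tau2 + np.sum(b - m_b) / v_b) / prec_d
        d = mean_d + rng.standard_normal() / np.sqrt(prec_d)
        bs = bs.copy()
        bs[0] += d
        b = b - d
        mu = md.X @ bm + (a[md.idx] if n else 0.0)
        log_sd = md.Z @ bs + (b[md.idx] if n else 0.0)

        # --- joint RW: (log sd_a, log sd_b, fisher-z rho) ---
        def hyper_logpost(sa_, sb_, rho_):
            if sa_ <= 0 or sb_ <= 0 or not (-1 < rho_ < 1):
                return -np.inf
            lp = _bvn_logpdf(a, b, sa_, sb_, rho_)
            lp += _half_t_logpdf(sa_, spec.re_scale_df, md.re_scale)
            lp += _half_t_logpdf(sb_, spec.re_scale_df, md.re_scale)
            # Jacobians: log-scale for the SDs, Fisher-z for rho
            lp += np.log(sa_) + np.log(sb_) + np.log(1.0 - rho_ * rho_)
            return lp

        z = np.arctanh(np.clip(rho, -0.999999, 0.999999))
        cur_h = hyper_logpost(sa, sb, rho)
        step = s_hyper.scale * rng.standard_normal(3)
        sa_p = sa * np.exp(step[0])
        sb_p = sb * np.exp(step[1])
        rho_p = np.tanh(z + step[2])
        new_h = hyper_logpost(sa_p, sb_p, rho_p)
        accepted = np.log(rng.random()) < new_h - cur_h
        if accepted:
            sa, sb, rho = sa_p, sb_p, float(rho_p)
        s_hyper.update(accepted, adapting)

        # --- RW: AR(1) coefficient on the Fisher-z scale ---
        if spec.ar1:
            zp = np.arctanh(np.clip(phi, -0.999999, 0.999999))
            cur = loglik(mu, log_sd, phi) + np.log(1.0 - phi * phi)
            phi_p = float(np.tanh(zp + s_phi.scale * rng.standard_normal()))
            new = loglik(mu, log_sd, phi_p) + np.log(1.0 - phi_p * phi_p)
            accepted = np.log(rng.random()) < new - cur
            if accepted:
                phi = phi_p
            s_phi.update(accepted, adapting)

        if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == 0:
            out["beta_mean"][kept] = bm
            out["beta_sigma"][kept] = bs
            out["sd_a"][kept] = sa
            out["sd_b"][kept] = sb
            out["rho"][kept] = rho
            out["a"][kept] = a
            out["b"][kept] = b
            if spec.ar1:
                out["phi"][kept] = phi
            kept += 1

    for k, v in out.items():
        out[k] = v[:kept]
    return out


def split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor.

    ``chains`` has shape (n_chains, n_draws); each chain is split in half.
    """
    chains = np.asarray(chains, dtype=float)
    n = chains.shape[1] // 2
    if n < 2:
        return float("nan")
    halves = np.concatenate([chains[:, :n], chains[:, n : 2 * n]], axis=0)
    w = halves.var(axis=1, ddof=1).mean()
    bmeans = halves.mean(axis=1)
    bvar = n * bmeans.var(ddof=1)
    if w == 0:
        return 1.0
    return float(np.sqrt(((n - 1) / n * w + bvar / n) / w))


def effective_sample_size(chains: np.ndarray) -> float:
    """Effective draws via Geyer's initial positive sequence, per chain, summed."""
    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    total = 0.0
    for ch in chains:
        n = len(ch)
        x = ch - ch.mean()
        v = x.var()
        if v == 0 or n < 4:
            total += n
            continue
        f = np.fft.rfft(x, 2 * n)
        acf = np.fft.irfft(f * np.conj(f))[:n].real / (v * n)
        # sum consecutive pairs until a pair goes non-positive
        s = 1.0
        t = 1
        while t + 1 < n:
            pair = acf[t] + acf[t + 1]
            if pair <= 0:
                break
            s += 2.0 * pair
            t += 2
        total += n / s
    return float(total)


def px(draws: np.ndarray) -> float:
    """Percentage of posterior draws across zero, against the median's sign.

    Direction is the sign of the posterior median (of the mean when the
    median is exactly zero, with a warning); P_x is 100 times the fraction
    of draws with the opposite sign.  Values below 5 flag a meaningful
    effect.
    """
    draws = np.asarray(draws, dtype=float).ravel()
    if len(draws) < 100:
        raise ValueError("need at least 100 draws for P_x")
    med = np.median(draws)
    if med == 0:
        warnings.warn("zero posterior median; direction taken from the mean",
                      RuntimeWarning, stacklevel=2)
        med = float(np.mean(draws))
    direction = np.sign(med)
    return float(100.0 * np.mean(np.sign(draws) == -direction))


@dataclasses.dataclass
class DhglmPosterior:
    """Thinned post-burn-in draws plus summaries for one fitted model.

    ``draws`` maps parameter names to arrays of shape (chains, draws) for
    scalars and (chains, draws, n_individuals) for the per-individual
    intercepts ``a`` and ``b``.
    """

    draws: dict[str, np.ndarray]
    individuals: np.ndarray
    spec: object

    def flat(self, name: str) -> np.ndarray:
        """All chains pooled, shape (chains*draws,) or (chains*draws, m)."""
        d = self.draws[name]
        return d.reshape(-1, *d.shape[2:])

    def ci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        lo = (1 - level) / 2
        d = self.flat(name)
        return float(np.quantile(d, lo)), float(np.quantile(d, 1 - lo))

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, d in self.draws.items():
            if d.ndim != 2:
                continue
            pooled = d.ravel()
            lo, hi = np.quantile(pooled, [0.025, 0.975])
            rows.append(
                {
                    "param": name,
                    "median": float(np.median(pooled)),
                    "ci_2.5": float(lo),
                    "ci_97.5": float(hi),
                    "px": px(pooled) if len(pooled) >= 100 else float("nan"),
                    "rhat": split_rhat(d),
                    "ess": effective_sample_size(d),
                }
            )
        return pd.DataFrame(rows).set_index("param")


def _scalarise(raw_chains: list[dict], names: dict[str, list[str]]) -> dict[str, np.ndarray]:
    """Re-key vector draws as name[label] scalar series across chains."""
    out: dict[str, np.ndarray] = {}
    first = raw_chains[0]
    for key, labels in names.items():
        arr = np.stack([c[key] for c in raw_chains])  # (chains, draws, k)
        for j, lab in enumerate(labels):
            out[f"{key}[{lab}]"] = arr[:, :, j]
    for key in first:
        if key in names:
            continue
        arr = np.stack([c[key] for c in raw_chains])
        out[key] = arr
    return out


def fit(data: pd.DataFrame, spec: DhglmSpec) -> DhglmPosterior:
    """Fit the DHGLM by MCMC; deterministic given ``spec.seed``.

    Runs ``spec.chains`` chains sequentially from independent seeds, discards
    ``spec.burn_in`` iterations, keeps every ``spec.thin``-th draw.  Raises
    when the identifiability preconditions fail or the initial density is
    not finite.
    """
    md = _prepare(data, spec)
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.chains)
    raw = [_run_dhglm_chain(md, spec, s) for s in seeds]

    init_check = {
        "beta_mean": raw[0]["beta_mean"][0],
        "beta_sigma": raw[0]["beta_sigma"][0],
        "a": raw[0]["a"][0],
        "b": raw[0]["b"][0],
        "sd_a": raw[0]["sd_a"][0],
        "sd_b": raw[0]["sd_b"][0],
        "rho": raw[0]["rho"][0],
    }
    if spec.ar1:
        init_check["phi"] = raw[0]["phi"][0]
    lp = log_posterior(init_check, md, spec)
    if not np.isfinite(lp):
        raise RuntimeError(f"non-finite posterior density at a kept draw: {init_check}")

    draws = _scalarise(raw, {"beta_mean": md.x_names, "beta_sigma": md.z_names})
    return DhglmPosterior(draws=draws, individuals=md.individuals, spec=spec)


# ---------------------------------------------------------------------------
# random-intercept / random-slope Gaussian mixed model
# ---------------------------------------------------------------------------


def _run_slope_chain(y, x, idx, m, prior_beta_sd, re_scale, iterations, burn_in, thin, seed):
    rng = np.random.default_rng(seed)
    n = len(y)
    X = np.column_stack([np.ones(n), x])
    tau2 = prior_beta_sd**2

    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    sigma = float(np.std(y - X @ beta)) or 1.0
    u = np.zeros(m)
    v = np.zeros(m)
    su, sv, rho = 0.5 * sigma, 0.1 * sigma, 0.0

    s_sigma = _AdaptiveScale(0.1, target=0.44)
    s_hyper = _AdaptiveScale(0.2, target=0.3)

    # per-individual sufficient statistics for the 2x2 Gibbs solve
    ni = np.bincount(idx, minlength=m).astype(float)
    sx = np.bincount(idx, weights=x, minlength=m)
    sxx = np.bincount(idx, weights=x * x, minlength=m)

    n_keep = (iterations - burn_in + thin - 1) // thin
    out = {
        "beta0": np.empty(n_keep), "beta1": np.empty(n_keep),
        "sigma": np.empty(n_keep), "sd_intercept": np.empty(n_keep),
        "sd_slope": np.empty(n_keep), "corr": np.empty(n_keep),
        "u": np.empty((n_keep, m)), "v": np.empty((n_keep, m)),
    }
    kept = 0

    for it in range(iterations):
        adapting = it < burn_in
        w = 1.0 / (sigma * sigma)

        # Gibbs: fixed effects
        r = y - u[idx] - v[idx] * x
        prec = w * (X.T @ X) + np.eye(2) / tau2
        mean = np.linalg.solve(prec, w * (X.T @ r))
        beta = mean + np.linalg.cholesky(np.linalg.inv(prec)) @ rng.standard_normal(2)

        # Gibbs: per-individual (u_i, v_i); 2x2 solves vectorised by hand
        resid = y - X @ beta
        sr = np.bincount(idx, weights=resid, minlength=m)
        sxr = np.bincount(idx, weights=x * resid, minlength=m)
        omr2 = 1.0 - rho * rho
        ip00 = 1.0 / (su * su * omr2)
        ip11 = 1.0 / (sv * sv * omr2)
        ip01 = -rho / (su * sv * omr2)
        A00 = w * ni + ip00
        A11 = w * sxx + ip11
        A01 = w * sx + ip01
        det = A00 * A11 - A01 * A01
        mu_u = (A11 * (w * sr) - A01 * (w * sxr)) / det
        mu_v = (A00 * (w * sxr) - A01 * (w * sr)) / det
        # sample from N(mu, A^-1) via cholesky of A: L = [[l11,0],[l21,l22]]
        l11 = np.sqrt(A00)
        l21 = A01 / l11
        l22 = np.sqrt(A11 - l21 * l21)
        z1, z2 = rng.standard_normal(m), rng.standard_normal(m)
        # solve L' e = z  =>  e2 = z2/l22, e1 = (z1 - l21 e2)/l11
        e2 = z2 / l22
        e1 = (z1 - l21 * e2) / l11
        u = mu_u + e1
        v = mu_v + e2

        # RW: log sigma (half-t prior)
        res = y - X @ beta - u[idx] - v[idx] * x
        sse = float(res @ res)

        def sig_logpost(s):
            if s <= 0:
                return -np.inf
            return (-n * np.log(s) - 0.5 * sse / (s * s)
                    + _half_t_logpdf(s, 3.0, re_scale) + np.log(s))

        sp = sigma * np.exp(s_sigma.scale * rng.standard_normal())
        accepted = np.log(rng.random()) < sig_logpost(sp) - sig_logpost(sigma)
        if accepted:
            sigma = float(sp)
        s_sigma.update(accepted, adapting)

        # joint RW: (log su, log sv, fisher-z rho)
        def hyper_logpost(su_, sv_, rho_):
            if su_ <= 0 or sv_ <= 0 or not (-1 < rho_ < 1):
                return -np.inf
            return (_bvn_logpdf(u, v, su_, sv_, rho_)
                    + _half_t_logpdf(su_, 3.0, re_scale)
                    + _half_t_logpdf(sv_, 3.0, re_scale)
                    + np.log(su_) + np.log(sv_) + np.log(1 - rho_ * rho_))

        z = np.arctanh(np.clip(rho, -0.999999, 0.999999))
        step = s_hyper.scale * rng.standard_normal(3)
        su_p = su * np.exp(step[0])
        sv_p = sv * np.exp(step[1])
        rho_p = float(np.tanh(z + step[2]))
        accepted = np.log(rng.random()) < hyper_logpost(su_p, sv_p, rho_p) - hyper_logpost(su, sv, rho)
        if accepted:
            su, sv, rho = su_p, sv_p, rho_p
        s_hyper.update(accepted, adapting)

        if it >= burn_in and (it - burn_in) % thin == 0:
            out["beta0"][kept] = beta[0]
            out["beta1"][kept] = beta[1]
            out["sigma"][kept] = sigma
            out["sd_intercept"][kept] = su
            out["sd_slope"][kept] = sv
            out["corr"][kept] = rho
            out["u"][kept] = u
            out["v"][kept] = v
            kept += 1
    for k in out:
        out[k] = out[k][:kept]
    return out


def random_slope_fit(
    data: pd.DataFrame,
    response: str,
    predictor: str,
    id_col: str = "individual",
    prior_beta_sd: float = 100.0,
    chains: int = 2,
    iterations: int = 3000,
    burn_in: int = 1000,
    thin: int = 2,
    seed: int = 0,
) -> DhglmPosterior:
    """Gaussian mixed model with correlated random intercepts and slopes.

        y_ij ~ Normal(b0 + b1 x_ij + u_i + v_i x_ij, sigma)
        (u_i, v_i) ~ BVN(0; sd_intercept, sd_slope, corr)

    The intercept-slope correlation answers whether individuals with a higher
    mean response change more or less steeply with the predictor.  Fixed
    effects carry Normal(0, sd 100) priors (variance 10000).  Raises when the
    predictor is constant (the slope is unidentifiable).
    """
    y = data[response].to_numpy(dtype=float)
    x = data[predictor].to_numpy(dtype=float)
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(x))):
        raise ValueError("non-finite data")
    if np.std(x) == 0:
        raise ValueError(f"predictor {predictor!r} is constant: slope unidentifiable")
    ids, idx = np.unique(data[id_col].to_numpy(), return_inverse=True)
    m = len(ids)
    if m < 2 or np.bincount(idx).min() < 2:
        raise ValueError("need >= 2 individuals and >= 2 observations each")
    re_scale = float(np.std(y)) or 1.0
    seeds = np.random.SeedSequence(seed).spawn(chains)
    raw = [
        _run_slope_chain(y, x, idx, m, prior_beta_sd, re_scale,
                         iterations, burn_in, thin, s)
        for s in seeds
    ]
    draws = {k: np.stack([c[k] for c in raw]) for k in raw[0]}
    class _Spec:  # minimal provenance for the posterior object
        pass
    sp = _Spec()
    sp.response, sp.predictor, sp.seed = response, predictor, seed
    return DhglmPosterior(draws=draws, individuals=ids, spec=sp)
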