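"""Bayesian multilevel Poisson regression of connectivity degree.

The model for the degree count y of channel i in participant j::

    y ~ Poisson(alpha)
    log(alpha) = (b0 + u0_i + w0_j)
               + (b1 + u1_i) . Group
               + (b2 + u2_i + w1_j) . Session
               + (b3 + u3_i) . Group x Session

with treatment (dummy) coding, reference levels Sham and Pre, so Group
and Session each contribute two coefficients and the interaction four.
Channel random effects carry an intercept and slopes for every
predictor; participant random effects carry an intercept and Session
slopes.  Priors are Normal(0, 2.5) on all fixed effects and
Exponential(rate 2, mean 0.5) on every random-effect SD; random effects
within a block (e.g. both Group dummies) share one SD and are modelled
as uncorrelated.

The posterior is explored with the package's own No-U-Turn sampler
using analytic gradients.  By default channel effects are non-centred
(their SD posteriors can collapse toward zero, which funnels a centred
chain) while participant effects are centred (each participant has many
observations, and centring removes the slow fixed-effect/random-mean
ridge).  Convergence is summarized by split-R-hat and bulk effective
sample size (via ArviZ).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from functools import cached_property

import numba
import numpy as np
import pandas as pd
from scipy import special

from . import _nuts
from .errors import DataError, ParameterError

logger = logging.getLogger(__name__)

GROUP_LEVELS = ("Sham", "DLPFC", "VLPFC")
SESSION_LEVELS = ("Pre", "Post", "Post1month")

FIXED_NAMES = (
    "b_Intercept",
    "b_groupDLPFC",
    "b_groupVLPFC",
    "b_sessionPost",
    "b_sessionPost1month",
    "b_groupDLPFC:sessionPost",
    "b_groupDLPFC:sessionPost1month",
    "b_groupVLPFC:sessionPost",
    "b_groupVLPFC:sessionPost1month",
)
SIGMA_NAMES = (
    "sd_channel__Intercept",
    "sd_channel__group",
    "sd_channel__session",
    "sd_channel__group:session",
    "sd_participant__Intercept",
    "sd_participant__sessionPost",
    "sd_participant__sessionPost1month",
)
#: SD block of each of the 9 channel-effect columns (indexes SIGMA_NAMES)
_U_BLOCK = np.array([0, 1, 1, 2, 2, 3, 3, 3, 3])
#: SD block of each of the 3 participant-effect columns
_W_BLOCK = np.array([4, 5, 6])

PRIOR_BETA_SD = 2.5
PRIOR_SIGMA_RATE = 2.0


@dataclass
class ModelParameters:
    """Generative coefficients of the degree model (log scale).

    Scalars given for a block are broadcast across it; the interaction
    block is ordered (DLPFC x Post, DLPFC x Post1month, VLPFC x Post,
    VLPFC x Post1month).
    """

    beta0: float = 0.0
    beta_group: np.ndarray | float = 0.0
    beta_session: np.ndarray | float = 0.0
    beta_interaction: np.ndarray | float = 0.0
    sigma_u: np.ndarray | float = 0.0
    sigma_w: np.ndarray | float = 0.0

    def __post_init__(self) -> None:
        self.beta_group = np.broadcast_to(np.asarray(self.beta_group, float), (2,)).copy()
        self.beta_session = np.broadcast_to(np.asarray(self.beta_session, float), (2,)).copy()
        self.beta_interaction = np.broadcast_to(
            np.asarray(self.beta_interaction, float), (4,)
        ).copy()
        self.sigma_u = np.broadcast_to(np.asarray(self.sigma_u, float), (4,)).copy()
        self.sigma_w = np.broadcast_to(np.asarray(self.sigma_w, float), (3,)).copy()
        if np.any(self.sigma_u < 0) or np.any(self.sigma_w < 0):
            raise ParameterError("random-effect SDs must be non-negative")

    @property
    def beta(self) -> np.ndarray:
        """All 9 fixed effects in design-column order."""
        return np.concatenate(
            [[self.beta0], self.beta_group, self.beta_session, self.beta_interaction]
        )


def validate_degree_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format degree table and return it unchanged."""
    required = {"participant", "group", "session", "channel", "degree"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"degree table misses columns {sorted(missing)}")
    if not set(df["group"]).issubset(GROUP_LEVELS):
        raise DataError(f"group levels must be drawn from {GROUP_LEVELS}")
    if not set(df["session"]).issubset(SESSION_LEVELS):
        raise DataError(f"session levels must be drawn from {SESSION_LEVELS}")
    y = df["degree"].to_numpy()
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise DataError("degree must be a non-negative integer count")
    dup = df.duplicated(subset=["participant", "session", "channel"])
    if dup.any():
        raise DataError("more than one row per participant x session x channel")
    return df


def fixed_design(df: pd.DataFrame) -> np.ndarray:
    """(n_obs, 9) treatment-coded fixed-effect design matrix."""
    gd = (df["group"] == "DLPFC").to_numpy(float)
    gv = (df["group"] == "VLPFC").to_numpy(float)
    sp = (df["session"] == "Post").to_numpy(float)
    sf = (df["session"] == "Post1month").to_numpy(float)
    one = np.ones(len(df))
    return np.column_stack(
        [one, gd, gv, sp, sf, gd * sp, gd * sf, gv * sp, gv * sf]
    )


@dataclass
class _Design:
    X: np.ndarray                 # (n, 9) fixed design
    Xw: np.ndarray                # (n, 3) participant design
    y: np.ndarray                 # counts
    channels: list
    participants: list
    ch_idx: np.ndarray
    p_idx: np.ndarray

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_participants(self) -> int:
        return len(self.participants)


def _build_design(df: pd.DataFrame) -> _Design:
    channels = sorted(df["channel"].unique().tolist())
    participants = sorted(df["participant"].unique().tolist())
    ch_idx = df["channel"].map({c: i for i, c in enumerate(channels)}).to_numpy()
    p_idx = df["participant"].map({p: i for i, p in enumerate(participants)}).to_numpy()
    X = fixed_design(df)
    Xw = X[:, [0, 3, 4]]
    return _Design(
        X=X,
        Xw=Xw,
        y=df["degree"].to_numpy(float),
        channels=channels,
        participants=participants,
        ch_idx=ch_idx,
        p_idx=p_idx,
    )


def linear_predictor(
    df: pd.DataFrame,
    params: ModelParameters,
    u: np.ndarray | None = None,
    w: np.ndarray | None = None,
) -> np.ndarray:
    """log(alpha) per row given coefficients and optional raw effects.

    ``u`` is (n_channels, 9) in design-column order, ``w`` is
    (n_participants, 3); omitted effects are zero.  Channel/participant
    indexing follows the sorted order of the table's labels.
    """
    d = _build_design(validate_degree_table(df))
    eta = d.X @ params.beta
    if u is not None:
        u = np.asarray(u, float)
        if u.shape != (d.n_channels, 9):
            raise ParameterError(f"u must have shape {(d.n_channels, 9)}")
        eta = eta + np.einsum("nk,nk->n", d.X, u[d.ch_idx])
    if w is not None:
        w = np.asarray(w, float)
        if w.shape != (d.n_participants, 3):
            raise ParameterError(f"w must have shape {(d.n_participants, 3)}")
        eta = eta + np.einsum("nk,nk->n", d.Xw, w[d.p_idx])
    return eta


def poisson_log_likelihood(
    df: pd.DataFrame,
    params: ModelParameters,
    u: np.ndarray | None = None,
    w: np.ndarray | None = None,
) -> float:
    """Exact Poisson log-likelihood of the table under the model."""
    eta = linear_predictor(df, params, u, w)
    y = df["degree"].to_numpy(float)
    return float(np.sum(y * eta - np.exp(eta) - special.gammaln(y + 1.0)))


# --------------------------------------------------------------------------
# posterior geometry (non-centred parameterization)
# --------------------------------------------------------------------------

@numba.njit(cache=True, fastmath=True)
def _core(z, ls, X, Xw, ch_idx, p_idx, y, prior_beta_sd, rate, centered_u, centered_w):  # pragma: no cover
    """Poisson GLMM log-density (up to the y! constant) and gradient.

    Layout: z = [beta (9), zu (9C), zw (3J)], ls = log sigma (7) with SD
    blocks (u0, u_group, u_session, u_interaction, w0, w_post, w_post1m).
    Each random-effect family is either centred (coefficients carried
    directly, Gaussian prior with SD sigma) or non-centred (coefficients
    are sigma * z with standard-normal z), selected by flag.
    """
    n = y.shape[0]
    nb = z.shape[0]
    C = ch_idx.max() + 1
    J = p_idx.max() + 1
    sigma = np.exp(ls)

    u_scale = np.empty(9)
    u_scale[0] = sigma[0]
    u_scale[1] = sigma[1]
    u_scale[2] = sigma[1]
    u_scale[3] = sigma[2]
    u_scale[4] = sigma[2]
    for k in range(5, 9):
        u_scale[k] = sigma[3]
    w_scale = np.empty(3)
    w_scale[0] = sigma[4]
    w_scale[1] = sigma[5]
    w_scale[2] = sigma[6]

    # fixed effects are always carried directly, with a N(0, prior_beta_sd)
    # prior applied below
    beta = z[:9]

    u = np.empty((C, 9))
    for c in range(C):
        for k in range(9):
            zi = z[9 + 9 * c + k]
            u[c, k] = zi if centered_u else u_scale[k] * zi
    off = 9 + 9 * C
    w = np.empty((J, 3))
    for j in range(J):
        for k in range(3):
            zi = z[off + 3 * j + k]
            w[j, k] = zi if centered_w else w_scale[k] * zi

    loglik = 0.0
    r = np.empty(n)
    for i in range(n):
        c = ch_idx[i]
        j = p_idx[i]
        eta = 0.0
        for k in range(9):
            eta += X[i, k] * (beta[k] + u[c, k])
        for k in range(3):
            eta += Xw[i, k] * w[j, k]
        if eta > 500.0:
            return -np.inf, np.zeros(nb + 7)
        mu = np.exp(eta)
        loglik += y[i] * eta - mu
        r[i] = y[i] - mu

    gbeta = np.zeros(9)
    gu = np.zeros((C, 9))
    gw = np.zeros((J, 3))
    for i in range(n):
        c = ch_idx[i]
        j = p_idx[i]
        ri = r[i]
        for k in range(9):
            xv = X[i, k] * ri
            gbeta[k] += xv
            gu[c, k] += xv
        for k in range(3):
            gw[j, k] += Xw[i, k] * ri

    grad = np.empty(nb + 7)
    logp = loglik
    gl = np.zeros(7)
    ub = np.array([0, 1, 1, 2, 2, 3, 3, 3, 3])
    pv = prior_beta_sd * prior_beta_sd
    for k in range(9):
        grad[k] = gbeta[k] - z[k] / pv
        logp -= 0.5 * z[k] * z[k] / pv
    for c in range(C):
        for k in range(9):
            idx = 9 + 9 * c + k
            zi = z[idx]
            if centered_u:
                s2 = u_scale[k] * u_scale[k]
                grad[idx] = gu[c, k] - zi / s2
                gl[ub[k]] += zi * zi / s2 - 1.0
                logp -= 0.5 * zi * zi / s2 + np.log(u_scale[k])
            else:
                grad[idx] = u_scale[k] * gu[c, k] - zi
                gl[ub[k]] += zi * gu[c, k] * u_scale[k]
                logp -= 0.5 * zi * zi
    for j in range(J):
        for k in range(3):
            idx = off + 3 * j + k
            zi = z[idx]
            if centered_w:
                s2 = w_scale[k] * w_scale[k]
                grad[idx] = gw[j, k] - zi / s2
                gl[4 + k] += zi * zi / s2 - 1.0
                logp -= 0.5 * zi * zi / s2 + np.log(w_scale[k])
            else:
                grad[idx] = w_scale[k] * gw[j, k] - zi
                gl[4 + k] += zi * gw[j, k] * w_scale[k]
                logp -= 0.5 * zi * zi
    for k in range(7):
        logp += np.log(rate) - rate * sigma[k] + ls[k]
        grad[nb + k] = gl[k] + 1.0 - rate * sigma[k]
    return logp, grad


class _Posterior:
    """Log-density and gradient of the degree model.

    Parameter vector layout: [beta (9), u-part (9C), w-part (3J),
    log_sigma (7)].  Fixed effects are carried directly; each
    random-effect family is centred or non-centred according to
    ``parameterization``: "mixed" (default; channel effects non-centred,
    participant effects centred), "centered" or "noncentered".  Mixed is
    the robust default here: channel-SD posteriors can collapse toward
    zero (funnel, needs non-centring) while participant intercepts are
    strongly identified (centring removes the fixed-effect ridge).
    """

    def __init__(
        self,
        design: _Design,
        parameterization: str = "mixed",
        prior_only: bool = False,
    ):
        self.prior_only = prior_only
        if prior_only:
            parameterization = "noncentered"  # iid Gaussian prior, no funnel
        if parameterization not in ("mixed", "centered", "noncentered"):
            raise ParameterError(f"unknown parameterization {parameterization!r}")
        self.parameterization = parameterization
        self.centered_u = parameterization == "centered"
        self.centered_w = parameterization in ("mixed", "centered")
        d = design
        self.y = d.y
        self.X = np.ascontiguousarray(d.X)
        self.Xw = np.ascontiguousarray(d.Xw)
        self.ch_idx = d.ch_idx.astype(np.int64)
        self.p_idx = d.p_idx.astype(np.int64)
        C, J = d.n_channels, d.n_participants
        self.n_beta = 9
        self.n_u = 9 * C
        self.n_w = 3 * J
        self.nb = self.n_beta + self.n_u + self.n_w
        self.dim = self.nb + 7
        self.block = np.concatenate([np.tile(_U_BLOCK, C), np.tile(_W_BLOCK, J)])
        self._ll_const = -float(np.sum(special.gammaln(d.y + 1.0)))

    def scale(self, sigma: np.ndarray) -> np.ndarray:
        s = np.empty(self.nb)
        s[: self.n_beta] = PRIOR_BETA_SD
        s[self.n_beta :] = sigma[self.block]
        return s

    def logp_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        z = theta[: self.nb]
        ls = np.clip(theta[self.nb :], -15.0, 15.0)
        if self.prior_only:
            sigma = np.exp(ls)
            logp = (
                -0.5 * z @ z
                + np.sum(np.log(PRIOR_SIGMA_RATE) - PRIOR_SIGMA_RATE * sigma + ls)
            )
            grad = np.concatenate([-z, 1.0 - PRIOR_SIGMA_RATE * sigma])
            return float(logp), grad
        logp, grad = _core(
            z, ls, self.X, self.Xw, self.ch_idx, self.p_idx, self.y,
            PRIOR_BETA_SD, PRIOR_SIGMA_RATE, self.centered_u, self.centered_w,
        )
        if not np.isfinite(logp):
            return -np.inf, grad
        return logp + self._ll_const, grad

    def natural(self, theta: np.ndarray) -> np.ndarray:
        """Map a raw draw to natural-scale parameters [b (nb), sigma (7)]."""
        sigma = np.exp(theta[self.nb :])
        b = theta[: self.nb].copy()
        if self.prior_only:
            return np.concatenate([self.scale(sigma) * b, sigma])
        scale = self.scale(sigma)
        u_sl = slice(self.n_beta, self.n_beta + self.n_u)
        w_sl = slice(self.n_beta + self.n_u, self.nb)
        if not self.centered_u:
            b[u_sl] *= scale[u_sl]
        if not self.centered_w:
            b[w_sl] *= scale[w_sl]
        return np.concatenate([b, sigma])


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """MCMC draws of the degree model in natural parameter scale.

    ``params`` has shape (n_chains, n_draws, n_parameters); parameter
    order is fixed effects, channel effects (9 per channel), participant
    effects (3 per participant), then the 7 SDs.
    """

    params: np.ndarray
    names: list[str]
    channels: list
    participants: list
    n_chains: int
    n_iter: int
    n_warmup: int
    divergences: list[int] = field(default_factory=list)
    accept_prob: list[float] = field(default_factory=list)
    seed: int | None = None

    @property
    def n_draws(self) -> int:
        return self.params.shape[1]

    @property
    def flat(self) -> np.ndarray:
        """(n_chains * n_draws, P) draws with chains stacked."""
        return self.params.reshape(-1, self.params.shape[-1])

    def _slices(self) -> dict[str, slice]:
        C, J = len(self.channels), len(self.participants)
        return {
            "beta": slice(0, 9),
            "u": slice(9, 9 + 9 * C),
            "w": slice(9 + 9 * C, 9 + 9 * C + 3 * J),
            "sigma": slice(9 + 9 * C + 3 * J, 9 + 9 * C + 3 * J + 7),
        }

    def beta_draws(self) -> np.ndarray:
        """(S, 9) fixed-effect draws, chains stacked."""
        return self.flat[:, self._slices()["beta"]]

    def u_draws(self) -> np.ndarray:
        """(S, n_channels, 9) channel-effect draws."""
        s = self.flat[:, self._slices()["u"]]
        return s.reshape(s.shape[0], len(self.channels), 9)

    def w_draws(self) -> np.ndarray:
        """(S, n_participants, 3) participant-effect draws."""
        s = self.flat[:, self._slices()["w"]]
        return s.reshape(s.shape[0], len(self.participants), 3)

    def sigma_draws(self) -> np.ndarray:
        return self.flat[:, self._slices()["sigma"]]

    @cached_property
    def _diagnostics(self) -> tuple[np.ndarray, np.ndarray]:
        import arviz as az

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ds = az.convert_to_dataset(self.params)
            rhat = az.rhat(ds)["x"].to_numpy()
            ess = az.ess(ds)["x"].to_numpy()
        return rhat, ess

    @property
    def rhat(self) -> np.ndarray:
        """Split-R-hat per parameter."""
        return self._diagnostics[0]

    @property
    def ess(self) -> np.ndarray:
        """Bulk effective sample size per parameter."""
        return self._diagnostics[1]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.flat, columns=self.names)
        df.insert(0, "chain", np.repeat(np.arange(self.n_chains), self.n_draws))
        df.insert(1, "draw", np.tile(np.arange(self.n_draws), self.n_chains))
        return df


def _parameter_names(channels, participants) -> list[str]:
    names = list(FIXED_NAMES)
    u_suffix = [n.removeprefix("b_") for n in FIXED_NAMES]
    for c in channels:
        names += [f"u_channel[{c}]__{s}" for s in u_suffix]
    for p in participants:
        names += [f"w_participant[{p}]__{s}" for s in ("Intercept", "sessionPost", "sessionPost1month")]
    names += list(SIGMA_NAMES)
    return names


def fit_poisson_glmm(
    data: pd.DataFrame,
    n_chains: int = 8,
    n_iter: int = 2000,
    n_warmup: int = 1000,
    seed: int | None = None,
    target_accept: float = 0.95,
    max_depth: int = 10,
    max_divergence_frac: float = 0.05,
    parameterization: str = "mixed",
    prior_only: bool = False,
) -> PosteriorDraws:
    """Sample the posterior of the multilevel Poisson degree model.

    Defaults follow the reporting convention of 8 chains of 2,000
    iterations with the first 1,000 as warm-up, so 8,000 retained draws.
    Chains run sequentially with seeds spawned from ``seed``.
    """
    df = validate_degree_table(data)
    if df.groupby("group")["participant"].nunique().min() < 2:
        raise DataError("need >= 2 participants per group")
    if df["session"].nunique() < 2:
        raise DataError("need >= 2 sessions")
    if n_warmup >= n_iter:
        raise ParameterError("n_warmup must be below n_iter")

    design = _build_design(df)
    post = _Posterior(design, parameterization=parameterization, prior_only=prior_only)
    n_draws = n_iter - n_warmup

    ss = np.random.SeedSequence(seed)
    chains = []
    divergences, accepts = [], []
    mean_log = np.log(max(df["degree"].mean(), 0.5))
    for k, child in enumerate(ss.spawn(n_chains)):
        rng = np.random.default_rng(child)
        x0 = np.zeros(post.dim)
        x0[: post.nb] = rng.normal(0.0, 0.05, post.nb)
        x0[0] = (0.0 if prior_only else mean_log) + rng.normal(0.0, 0.05)
        x0[post.nb :] = np.log(0.3) + rng.normal(0.0, 0.1, 7)
        res = _nuts.sample(
            post.logp_grad, x0, n_warmup, n_draws, rng,
            target_accept=target_accept, max_depth=max_depth,
        )
        nat = np.empty_like(res.draws[:, : post.nb + 7])
        for i, th in enumerate(res.draws):
            nat[i] = post.natural(th)
        chains.append(nat)
        divergences.append(res.n_divergent)
        accepts.append(res.accept_prob)
        logger.info(
            "chain %d: accept %.2f, %d divergent, step %.3g",
            k, res.accept_prob, res.n_divergent, res.step_size,
        )

    total_div = sum(divergences)
    if total_div > max_divergence_frac * n_chains * n_draws:
        logger.warning(
            "diagnostic failure: %d divergent transitions (> %.0f%% of draws)",
            total_div, 100 * max_divergence_frac,
        )
    return PosteriorDraws(
        params=np.stack(chains),
        names=_parameter_names(design.channels, design.participants),
        channels=design.channels,
        participants=design.participants,
        n_chains=n_chains,
        n_iter=n_iter,
        n_warmup=n_warmup,
        divergences=divergences,
        accept_prob=accepts,
        seed=seed,
    )


def check_convergence(
    draws: PosteriorDraws,
    rhat_max: float = 1.01,
    ess_min: float = 400.0,
) -> dict:
    """Convergence report: pass iff max R-hat <= rhat_max and min ESS >= ess_min."""
    if draws.n_chains < 2:
        raise ParameterError("R-hat requires at least 2 chains")
    rhat, ess = draws.rhat, draws.ess
    bad_rhat = [draws.names[i] for i in np.flatnonzero(rhat > rhat_max)]
    bad_ess = [draws.names[i] for i in np.flatnonzero(ess < ess_min)]
    return {
        "passed": not bad_rhat and not bad_ess,
        "max_rhat": float(np.nanmax(rhat)),
        "min_ess": float(np.nanmin(ess)),
        "rhat_threshold": rhat_max,
        "ess_threshold": ess_min,
        "offending_rhat": bad_rhat,
        "offending_ess": bad_ess,
        "total_divergences": int(sum(draws.divergences)),
    }
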