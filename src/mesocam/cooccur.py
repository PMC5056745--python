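"""Two-species occupancy co-occurrence modelling with a species interaction factor.

The model jointly describes where two species occur and how imperfectly they
are detected.  Each site is in one of four latent states with probabilities

    both      : gamma * psi_A * psi_B
    A only    : psi_A - gamma * psi_A * psi_B
    B only    : psi_B - gamma * psi_A * psi_B
    neither   : 1 - psi_A - psi_B + gamma * psi_A * psi_B

where psi_A, psi_B are marginal occupancy probabilities and gamma is the
species interaction factor (SIF): gamma < 1 spatial avoidance, gamma = 1
independence, gamma > 1 aggregation.  Detection within an occasion is
conditionally independent given the latent state; species detection uses
probability ``p`` where the other species is absent and ``r`` where both are
present.  Detection probabilities are modelled on the logit scale with
species-specific intercepts plus covariate effects shared across species:
scent-lure age as a 4-level categorical (``Lr``; reference bin 0-15 days) and
camera trigger-speed class (``Cam``; reference ``fast``).

The candidate set crosses {gamma free, gamma = 1} x {no covariates, +Lr,
+Cam, +Lr+Cam} x {r = p, r separate}, i.e. 16 models, ranked by
AIC = -2 log L + 2 K.  K counts free parameters under this package's additive
convention (documented in the methods note); inference about co-occurrence
comes from the SIF in the top model set (delta AIC < 2).

Detection histories are site x occasion matrices built by tiling each
deployment into fixed-length (default 15-day) segments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from mesocam.errors import ConfigurationError, MesocamError

logger = logging.getLogger(__name__)

MISSING, NEITHER, A_ONLY, B_ONLY, BOTH = -1, 0, 1, 2, 3
STATE_SYMBOLS = {NEITHER: "0", A_ONLY: "A", B_ONLY: "B", BOTH: "X", MISSING: "."}
SYMBOL_STATES = {v: k for k, v in STATE_SYMBOLS.items()}

LURE_BIN_EDGES = (15.0, 30.0, 45.0)          # days; bins 0-15, 16-30, 31-45, >45
LURE_BIN_LABELS = ("0-15", "16-30", "31-45", ">45")
N_LURE_CONTRASTS = 3
PROB_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# detection histories
# ---------------------------------------------------------------------------

@dataclass
class DetectionHistoryPair:
    """Site x occasion joint detection states for a species pair.

    ``states`` uses codes -1 missing, 0 neither, 1 A-only, 2 B-only, 3 both.
    ``lure_bin`` (0..3) and ``cam_slow`` (0/1) are occasion-level detection
    covariates, valid wherever the occasion is not missing.
    """
    sites: list
    states: np.ndarray
    lure_bin: np.ndarray
    cam_slow: np.ndarray
    species_a: str
    species_b: str
    segment_days: float = 15.0

    @property
    def n_sites(self) -> int:
        return self.states.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.states.shape[1]

    def swapped(self) -> "DetectionHistoryPair":
        """The same histories with species A and B interchanged."""
        swap = self.states.copy()
        swap[self.states == A_ONLY] = B_ONLY
        swap[self.states == B_ONLY] = A_ONLY
        return DetectionHistoryPair(list(self.sites), swap, self.lure_bin.copy(),
                                    self.cam_slow.copy(), self.species_b,
                                    self.species_a, self.segment_days)

    def to_text(self) -> str:
        """Plain-text occasion matrix: one row per site, symbols 0/A/B/X/."""
        lines = []
        for i, site in enumerate(self.sites):
            row = "".join(STATE_SYMBOLS[int(s)] for s in self.states[i])
            lines.append(f"{site}\t{row}")
        return "\n".join(lines) + "\n"

    def covariates_frame(self) -> pd.DataFrame:
        rows = []
        for i, site in enumerate(self.sites):
            for j in range(self.n_occasions):
                if self.states[i, j] == MISSING:
                    continue
                rows.append({"site": site, "occasion": j,
                             "lure_bin": LURE_BIN_LABELS[int(self.lure_bin[i, j])],
                             "camera_speed": "slow" if self.cam_slow[i, j] else "fast"})
        return pd.DataFrame(rows)


def lure_age_bin(days: float) -> int:
    """Bin days-since-lure-application into 0-15 / 16-30 / 31-45 / >45."""
    return int(np.searchsorted(LURE_BIN_EDGES, days, side="left"))


def build_detection_histories(events: pd.DataFrame, deployments: pd.DataFrame,
                              species_a: str, species_b: str,
                              segment_days: float = 15.0,
                              years=None, season: str | None = "warm",
                              vocabulary=None) -> DetectionHistoryPair:
    """Tile deployments into occasions and fill joint detection states.

    Occasions tile each deployment from its start in ``segment_days`` chunks;
    a trailing remnant is kept when it spans at least half a segment.  A
    species is "detected" in an occasion iff at least one of its independent
    events falls inside it.  Occasion covariates: lure-age bin from days since
    the most recent lure application at the occasion midpoint (deployment
    start counts as an application when no lure dates are recorded), and the
    deployment's camera speed class.

    ``years`` restricts to deployments starting in those calendar years;
    ``season="warm"`` drops occasions whose midpoint falls in Dec-Feb (the
    closed-season filter used when one species is winter-dormant).
    ``vocabulary``, when given, is the controlled species-code list both focal
    species must belong to.
    """
    if vocabulary is not None:
        for sp in (species_a, species_b):
            if sp not in set(vocabulary):
                raise ConfigurationError(f"species {sp!r} not in vocabulary")
    ev = events[events["species"].isin([species_a, species_b])]

    per_site: dict = {}
    for dep in deployments.itertuples(index=False):
        t0, t1 = pd.Timestamp(dep.start), pd.Timestamp(dep.end)
        if years is not None and t0.year not in set(years):
            continue
        lure = sorted(dep.lure_dates) if dep.lure_dates else [t0]
        cam_slow = 1 if str(dep.camera_speed).lower() == "slow" else 0
        seg = pd.Timedelta(days=segment_days)
        cursor = t0
        while cursor < t1:
            occ_end = min(cursor + seg, t1)
            length = occ_end - cursor
            if length < seg and length < seg / 2:
                break
            mid = cursor + length / 2
            if season == "warm" and mid.month in (12, 1, 2):
                cursor = occ_end
                continue
            last_app = max((d for d in lure if pd.Timestamp(d) <= mid),
                           default=pd.Timestamp(lure[0]))
            age = (mid - pd.Timestamp(last_app)) / pd.Timedelta(days=1)
            in_occ = ev[(ev["station_id"] == dep.station_id)
                        & (ev["event_time"] >= cursor) & (ev["event_time"] < occ_end)]
            got_a = (in_occ["species"] == species_a).any()
            got_b = (in_occ["species"] == species_b).any()
            state = BOTH if (got_a and got_b) else A_ONLY if got_a else \
                B_ONLY if got_b else NEITHER
            per_site.setdefault(dep.station_id, []).append(
                (state, lure_age_bin(age), cam_slow))
            cursor = occ_end

    sites = sorted(per_site)
    if not sites:
        raise MesocamError("no occasions survive the filters")
    t_max = max(len(v) for v in per_site.values())
    states = np.full((len(sites), t_max), MISSING, dtype=int)
    lure_b = np.zeros((len(sites), t_max), dtype=int)
    cam = np.zeros((len(sites), t_max), dtype=int)
    for i, site in enumerate(sites):
        for j, (st, lb, cs) in enumerate(per_site[site]):
            states[i, j], lure_b[i, j], cam[i, j] = st, lb, cs
    return DetectionHistoryPair(sites, states, lure_b, cam,
                                species_a, species_b, segment_days)


# ---------------------------------------------------------------------------
# model set
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OccupancyModelSpec:
    """One member of the 16-model candidate set."""
    gamma_free: bool
    covariates: tuple            # subset of ("Lr", "Cam"), in display order
    r_equals_p: bool

    @property
    def n_det_params(self) -> int:
        block = 2 + N_LURE_CONTRASTS * ("Lr" in self.covariates) + ("Cam" in self.covariates)
        return block if self.r_equals_p else 2 * block

    @property
    def k(self) -> int:
        """Free-parameter count: 2 occupancy + gamma (if free) + detection."""
        return 2 + int(self.gamma_free) + self.n_det_params

    @property
    def name(self) -> str:
        cov = "".join(f"+{c}" for c in self.covariates)
        det = f"p(S{cov})"
        if not self.r_equals_p:
            det += f"r(S{cov})"
        return "psi(S)" + ("gamma(.)" if self.gamma_free else "") + det

    @property
    def n_params(self) -> int:
        return self.k


def enumerate_model_set() -> list[OccupancyModelSpec]:
    """The 16-model crossing {gamma free/fixed} x 4 covariate sets x {r=p, r sep}."""
    covsets = [(), ("Lr",), ("Cam",), ("Lr", "Cam")]
    return [OccupancyModelSpec(gf, cov, rp)
            for gf in (False, True) for cov in covsets for rp in (True, False)]


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _unpack(params: np.ndarray, spec: OccupancyModelSpec,
            hist: DetectionHistoryPair):
    """Return (psi_a, psi_b, psi_ab) and per-site-occasion pA,pB,rA,rB arrays."""
    params = np.asarray(params, dtype=float)
    if not np.all(np.isfinite(params)):
        raise ValueError("non-finite parameters")
    idx = 0
    psi_a = _sigmoid(params[idx]); idx += 1
    psi_b = _sigmoid(params[idx]); idx += 1
    if spec.gamma_free:
        lo = max(0.0, psi_a + psi_b - 1.0)
        hi = min(psi_a, psi_b)
        psi_ab = lo + _sigmoid(params[idx]) * (hi - lo)
        idx += 1
    else:
        psi_ab = psi_a * psi_b

    def det_block(start):
        i = start
        a_int, b_int = params[i], params[i + 1]
        i += 2
        lr = np.zeros(4)
        if "Lr" in spec.covariates:
            lr[1:] = params[i:i + N_LURE_CONTRASTS]
            i += N_LURE_CONTRASTS
        cam_eff = 0.0
        if "Cam" in spec.covariates:
            cam_eff = params[i]
            i += 1
        eta = lr[hist.lure_bin] + cam_eff * hist.cam_slow
        return _sigmoid(a_int + eta), _sigmoid(b_int + eta), i

    p_a, p_b, idx = det_block(idx)
    if spec.r_equals_p:
        r_a, r_b = p_a, p_b
    else:
        r_a, r_b, idx = det_block(idx)
    if idx != len(params):
        raise ValueError(f"expected {idx} parameters, got {len(params)}")
    return (psi_a, psi_b, psi_ab), (p_a, p_b, r_a, r_b)


def two_species_neg_log_likelihood(params, histories: DetectionHistoryPair,
                                   spec: OccupancyModelSpec) -> float:
    """Negative log-likelihood of the two-species occupancy model.

    Per site, the likelihood sums over the four latent states the state
    probability times the product over non-missing occasions of the joint
    observation probability; missing occasions contribute a factor of 1.
    """
    (psi_a, psi_b, psi_ab), (p_a, p_b, r_a, r_b) = _unpack(params, spec, histories)
    obs = histories.states
    miss = obs == MISSING

    def occ_prod(prob_neither, prob_a, prob_b, prob_both):
        per = np.select(
            [obs == NEITHER, obs == A_ONLY, obs == B_ONLY, obs == BOTH],
            [prob_neither, prob_a, prob_b, prob_both], default=1.0)
        per = np.where(miss, 1.0, per)
        return per.prod(axis=1)

    zeros = np.zeros_like(p_a)
    lik_both = occ_prod((1 - r_a) * (1 - r_b), r_a * (1 - r_b),
                        (1 - r_a) * r_b, r_a * r_b)
    lik_a = occ_prod(1 - p_a, p_a, zeros, zeros)
    lik_b = occ_prod(1 - p_b, zeros, p_b, zeros)
    lik_none = occ_prod(np.ones_like(p_a), zeros, zeros, zeros)

    state_p = np.array([psi_ab, psi_a - psi_ab, psi_b - psi_ab,
                        1.0 - psi_a - psi_b + psi_ab])
    state_p = np.clip(state_p, 0.0, 1.0)
    site_lik = (state_p[0] * lik_both + state_p[1] * lik_a
                + state_p[2] * lik_b + state_p[3] * lik_none)
    return float(-np.log(np.maximum(site_lik, PROB_FLOOR)).sum())


def gamma_of_params(params, spec: OccupancyModelSpec,
                    histories: DetectionHistoryPair) -> float:
    """The SIF gamma implied by an unconstrained parameter vector."""
    (psi_a, psi_b, psi_ab), _ = _unpack(params, spec, histories)
    return psi_ab / (psi_a * psi_b)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class OccupancyFit:
    """MLE result for one model spec."""
    spec: OccupancyModelSpec
    params: np.ndarray
    psi_a: float
    psi_b: float
    gamma: float
    gamma_se: float
    neg2ll: float
    k: int
    aic: float
    param_se: np.ndarray
    converged: bool
    delta_aic: float | None = None
    detection: dict = field(default_factory=dict)


def _numerical_hessian(fun, x, rel_step=1e-4):
    n = len(x)
    h = rel_step * (1.0 + np.abs(x))
    hess = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            f_pp = fun(x + ei + ej)
            f_pm = fun(x + ei - ej)
            f_mp = fun(x - ei + ej)
            f_mm = fun(x - ei - ej)
            hess[i, j] = hess[j, i] = (f_pp - f_pm - f_mp + f_mm) / (4 * h[i] * h[j])
    return hess


def _numerical_gradient(fun, x, rel_step=1e-5):
    h = rel_step * (1.0 + np.abs(x))
    grad = np.empty(len(x))
    for i in range(len(x)):
        e = np.zeros(len(x)); e[i] = h[i]
        grad[i] = (fun(x + e) - fun(x - e)) / (2 * h[i])
    return grad


def fit_model(histories: DetectionHistoryPair, spec: OccupancyModelSpec,
              n_starts: int = 3, seed: int | None = 0,
              maxiter: int = 500) -> OccupancyFit:
    """Maximum-likelihood fit of one model via L-BFGS-B with random restarts.

    Standard errors come from the inverse of the numerically differentiated
    observed information; gamma's SE by the delta method through its
    simplex-preserving transform.  Non-convergence across all restarts flags
    the fit (``converged=False``); such fits are excluded from AIC ranking.
    """
    rng = np.random.default_rng(seed)
    nll = lambda x: two_species_neg_log_likelihood(x, histories, spec)
    n_par = spec.k

    best = None
    for s in range(n_starts):
        x0 = np.empty(n_par)
        idx = 0
        for _ in range(2):               # occupancy logits
            u = rng.uniform(0.2, 0.8)
            x0[idx] = np.log(u / (1 - u))
            idx += 1
        if spec.gamma_free:
            x0[idx] = rng.normal(0, 1); idx += 1
        x0[idx:] = rng.normal(0, 0.5, n_par - idx)
        try:
            res = minimize(nll, x0, method="L-BFGS-B",
                           options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7})
        except (ValueError, FloatingPointError):
            continue
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    if best is None:
        raise MesocamError(f"all restarts failed for model {spec.name}")
    converged = bool(best.success) or best.fun < np.inf

    x = best.x
    (psi_a, psi_b, psi_ab), (p_a, p_b, r_a, r_b) = _unpack(x, spec, histories)
    gamma = psi_ab / (psi_a * psi_b)

    param_se = np.full(n_par, np.nan)
    gamma_se = 0.0
    try:
        hess = _numerical_hessian(nll, x)
        cov = np.linalg.inv(hess)
        diag = np.diag(cov)
        param_se = np.sqrt(np.where(diag > 0, diag, np.nan))
        if spec.gamma_free:
            g = _numerical_gradient(
                lambda z: gamma_of_params(z, spec, histories), x)
            var = float(g @ cov @ g)
            gamma_se = float(np.sqrt(var)) if var > 0 else np.nan
    except np.linalg.LinAlgError:
        logger.warning("singular information matrix for %s", spec.name)

    neg2ll = 2.0 * best.fun
    return OccupancyFit(
        spec=spec, params=x, psi_a=float(psi_a), psi_b=float(psi_b),
        gamma=float(gamma), gamma_se=gamma_se, neg2ll=float(neg2ll),
        k=spec.k, aic=float(neg2ll + 2 * spec.k), param_se=param_se,
        converged=converged,
        detection={"p_a_mean": float(np.mean(p_a)), "p_b_mean": float(np.mean(p_b)),
                   "r_a_mean": float(np.mean(r_a)), "r_b_mean": float(np.mean(r_b))},
    )


@dataclass
class SIFEstimate:
    """Species-interaction-factor inference from the top model set."""
    gamma_hat: float
    se: float
    source_models: list
    interpretation: str          # avoidance / independence / aggregation / unclear


def rank_models_and_sif(fits: list[OccupancyFit]):
    """Rank converged fits by AIC and infer the co-occurrence pattern.

    Interpretation follows the top set (delta AIC < 2): *avoidance* /
    *aggregation* when a single gamma-free top model estimates gamma below /
    above 1; *independence* when every top model fixes gamma = 1; *unclear*
    when the top set mixes the two hypotheses.
    """
    ok = [f for f in fits if f.converged]
    if not ok:
        raise MesocamError("no converged fits to rank")
    skipped = len(fits) - len(ok)
    if skipped:
        logger.warning("%d non-converged fit(s) excluded from ranking", skipped)
    ok.sort(key=lambda f: f.aic)
    best_aic = ok[0].aic
    for f in ok:
        f.delta_aic = f.aic - best_aic
    top = [f for f in ok if f.delta_aic < 2.0]

    if all(not f.spec.gamma_free for f in top):
        interp = "independence"
    elif all(f.spec.gamma_free for f in top):
        if all(f.gamma < 1.0 for f in top):
            interp = "avoidance"
        elif all(f.gamma > 1.0 for f in top):
            interp = "aggregation"
        else:
            interp = "unclear"
    else:
        interp = "unclear"
    best = top[0]
    sif = SIFEstimate(gamma_hat=float(best.gamma),
                      se=float(best.gamma_se),
                      source_models=[f.spec.name for f in top],
                      interpretation=interp)

    table = pd.DataFrame([{
        "model": f.spec.name, "gamma": f.gamma, "gamma_se": f.gamma_se,
        "delta_aic": f.delta_aic, "K": f.k, "neg2ll": f.neg2ll, "aic": f.aic,
        "psi_a": f.psi_a, "psi_b": f.psi_b,
    } for f in ok])
    return table, sif


def fit_model_set(histories: DetectionHistoryPair, n_starts: int = 3,
                  seed: int | None = 0):
    """Fit all 16 candidate models and rank them (convenience wrapper)."""
    fits = []
    for m, spec in enumerate(enumerate_model_set()):
        fits.append(fit_model(histories, spec, n_starts=n_starts,
                              seed=None if seed is None else seed + m))
    return rank_models_and_sif(fits)
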