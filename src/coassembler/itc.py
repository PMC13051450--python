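"""Independent-binding-sites ITC: forward model, least-squares fit, selection.

Implements the standard one- and two-site-class independent-sites model for
an ITC perfusion cell.  After each injection the running totals of
macromolecule M_t and titrant X_t are dilution-corrected with the
displacement convention (each existing species is scaled by (1 - dV/V0) per
injection).  The free-titrant concentration solves

    X_t = X + M_t * sum_s n_s * X / (Kd_s + X)

(bisection, relative tolerance 1e-12), the cumulative heat is

    Q(i) = V0 * M_t(i) * sum_s n_s * dH_s * X / (Kd_s + X)

and the measured injection heat includes the displaced-volume correction

    dQ(i) = Q(i) - Q(i-1) + (dV_i / V0) * (Q(i) + Q(i-1)) / 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import least_squares


@dataclass
class Site:
    n: float       # stoichiometry (titrant per macromolecule)
    Kd: float      # dissociation constant, M
    dH: float      # enthalpy, kcal/mol of titrant bound

    def __post_init__(self):
        if self.Kd <= 0:
            raise ValueError("Kd must be positive")


@dataclass
class ITCModel:
    sites: list[Site]
    cell_volume: float          # L
    cell_conc: float            # M, macromolecule in cell
    syringe_conc: float         # M, titrant in syringe
    temperature: float = 298.15

    def __post_init__(self):
        if not 1 <= len(self.sites) <= 2:
            raise ValueError("supported models have one or two site classes")
        if self.cell_volume <= 0 or self.cell_conc <= 0 or self.syringe_conc <= 0:
            raise ValueError("volumes and concentrations must be positive")


@dataclass
class ITCIsotherm:
    injection_volumes: np.ndarray  # L
    heats: np.ndarray              # kcal per injection
    molar_ratio: np.ndarray        # cumulative titrant/macromolecule

    def __post_init__(self):
        self.injection_volumes = np.asarray(self.injection_volumes, float)
        self.heats = np.asarray(self.heats, float)
        self.molar_ratio = np.asarray(self.molar_ratio, float)
        if not (len(self.injection_volumes) == len(self.heats)
                == len(self.molar_ratio)):
            raise ValueError("isotherm columns must have equal length")
        if np.any(np.diff(self.molar_ratio) <= 0):
            raise ValueError("molar ratio must be strictly increasing")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "injection_index": np.arange(len(self.heats)),
            "volume_L": self.injection_volumes,
            "heat_kcal": self.heats,
            "molar_ratio": self.molar_ratio,
        })

    @classmethod
    def from_csv(cls, path, cell_volume=None, cell_conc=None, syringe_conc=None):
        import pandas as pd

        df = pd.read_csv(path)
        vol = df["volume_L"].to_numpy()
        if "molar_ratio" in df.columns:
            ratio = df["molar_ratio"].to_numpy()
        else:
            if None in (cell_volume, cell_conc, syringe_conc):
                raise ValueError("need cell setup to derive molar ratio")
            m, x = _totals(vol, cell_volume, cell_conc, syringe_conc)
            ratio = x / m
        return cls(injection_volumes=vol, heats=df["heat_kcal"].to_numpy(),
                   molar_ratio=ratio)


@dataclass
class ITCFitResult:
    model: ITCModel
    rss: float
    n_params: int
    param_se: dict[str, float]
    model_label: str
    n_obs: int
    converged: bool = True
    identifiable: bool = True

    @property
    def sites(self) -> list[Site]:
        return self.model.sites

    def aicc(self) -> float:
        n, k = self.n_obs, self.n_params
        aic = n * np.log(self.rss / n) + 2 * k
        denom = n - k - 1
        return float(aic + (2 * k * (k + 1)) / denom) if denom > 0 else np.inf


def _totals(injections: np.ndarray, v0: float, m0: float, x0: float):
    """Dilution-corrected totals after each injection (displacement convention)."""
    m_t = np.empty(len(injections))
    x_t = np.empty(len(injections))
    m, x = m0, 0.0
    for i, dv in enumerate(injections):
        f = dv / v0
        m *= (1.0 - f)
        x = x * (1.0 - f) + x0 * f
        m_t[i], x_t[i] = m, x
    return m_t, x_t


def _free_titrant(x_t: float, m_t: float, sites: list[Site]) -> float:
    """Solve X_t = X + M_t * sum n_s X/(Kd_s + X) by bisection (rel. 1e-12)."""
    if x_t <= 0:
        return 0.0

    def g(x):
        return x + m_t * sum(s.n * x / (s.Kd + x) for s in sites) - x_t

    lo, hi = 0.0, x_t
    assert g(hi) >= 0.0, "free-titrant bracket failed (non-monotone form?)"
    # interval well below the 1e-12 residual contract: the slope of g can
    # amplify interval width into residual by a couple of orders of magnitude
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if g(mid) > 0:
            hi = mid
        else:
            lo = mid
        if hi - lo <= 1e-15 * x_t:
            break
    return 0.5 * (lo + hi)


def _free_titrant_vec(x_t: np.ndarray, m_t: np.ndarray,
                      sites: list[Site]) -> np.ndarray:
    """Vectorised bisection of the free-titrant equation over injections."""
    ns = np.array([s.n for s in sites])
    kds = np.array([s.Kd for s in sites])

    def g(x):
        bound = (ns[:, None] * x[None, :] / (kds[:, None] + x[None, :])).sum(axis=0)
        return x + m_t * bound - x_t

    lo = np.zeros_like(x_t)
    hi = x_t.copy()
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        up = g(mid) > 0
        hi = np.where(up, mid, hi)
        lo = np.where(up, lo, mid)
        if np.all(hi - lo <= 1e-15 * np.maximum(x_t, 1e-300)):
            break
    return 0.5 * (lo + hi)


def forward_heats(model: ITCModel, injections) -> ITCIsotherm:
    """Per-injection heats (kcal) for an independent-sites titration."""
    injections = np.asarray(injections, float)
    if np.any(injections <= 0):
        raise ValueError("injection volumes must be positive")
    v0 = model.cell_volume
    m_t, x_t = _totals(injections, v0, model.cell_conc, model.syringe_conc)
    x = _free_titrant_vec(x_t, m_t, model.sites)
    ns = np.array([s.n for s in model.sites])
    kds = np.array([s.Kd for s in model.sites])
    dhs = np.array([s.dH for s in model.sites])
    q = v0 * m_t * (ns[:, None] * dhs[:, None] * x[None, :]
                    / (kds[:, None] + x[None, :])).sum(axis=0)
    dq = np.empty_like(q)
    q_prev = 0.0
    for i in range(len(q)):
        f = injections[i] / v0
        dq[i] = q[i] - q_prev + f * (q[i] + q_prev) / 2.0
        q_prev = q[i]
    ratio = x_t / m_t
    return ITCIsotherm(injection_volumes=injections, heats=dq, molar_ratio=ratio)


def wiseman_heats(model: ITCModel, injections) -> ITCIsotherm:
    """Closed-form single-site isotherm (Wiseman): independent oracle for the
    numeric solver; only valid for one site class."""
    if len(model.sites) != 1:
        raise ValueError("closed form applies to a single site class")
    s = model.sites[0]
    injections = np.asarray(injections, float)
    v0 = model.cell_volume
    m_t, x_t = _totals(injections, v0, model.cell_conc, model.syringe_conc)
    r = x_t / (s.n * m_t)
    k = model.sites[0].Kd / (s.n * m_t)
    term = 1.0 + r + k
    q = (s.n * m_t * s.dH * v0 / 2.0) * (term - np.sqrt(term ** 2 - 4.0 * r))
    dq = np.empty_like(q)
    q_prev = 0.0
    for i in range(len(q)):
        f = injections[i] / v0
        dq[i] = q[i] - q_prev + f * (q[i] + q_prev) / 2.0
        q_prev = q[i]
    return ITCIsotherm(injection_volumes=injections, heats=dq,
                       molar_ratio=x_t / m_t)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

_N_BOUNDS = (1e-3, 100.0)
_LOGKD_BOUNDS = (-12.0, 0.0)
_DH_BOUND = 1e3


def _unpack(x: np.ndarray) -> list[Site]:
    sites = []
    for i in range(0, len(x), 3):
        sites.append(Site(n=x[i], Kd=10.0 ** x[i + 1], dH=x[i + 2]))
    return sites


def fit_isotherm(data: ITCIsotherm, model_label: str,
                 cell_volume: float, cell_conc: float, syringe_conc: float,
                 temperature: float = 298.15,
                 starts: list[np.ndarray] | None = None) -> ITCFitResult:
    """Nonlinear least squares for {n_s, Kd_s, dH_s} with multi-start.

    Starting points cover a grid over log10 Kd (and site splits for the
    two-site model); the best-RSS solution wins.  Site classes in the result
    are sorted by ascending Kd (site 1 = high affinity).
    """
    if model_label not in ("one_site", "two_site"):
        raise ValueError("model_label must be 'one_site' or 'two_site'")
    n_sites = 1 if model_label == "one_site" else 2
    n_params = 3 * n_sites
    heats = data.heats
    n_obs = len(heats)
    if n_obs < 3 * n_sites:
        raise ValueError("too few injections for the requested model")

    injections = data.injection_volumes

    # residuals are normalised by the heat scale so the optimiser works on
    # O(1) quantities (raw heats are ~1e-7 kcal)
    heat_scale = float(np.max(np.abs(heats))) or 1.0

    def residuals(x):
        model = ITCModel(sites=_unpack(x), cell_volume=cell_volume,
                         cell_conc=cell_conc, syringe_conc=syringe_conc,
                         temperature=temperature)
        return (forward_heats(model, injections).heats - heats) / heat_scale

    # flat-isotherm guard
    spread = float(np.max(heats) - np.min(heats))
    scale = float(np.max(np.abs(heats))) if np.any(heats) else 0.0
    identifiable = scale > 0 and spread > 1e-6 * max(scale, 1e-30)

    # crude magnitude guesses
    total_heat = float(np.sum(heats))
    m_t, x_t = _totals(injections, cell_volume, cell_conc, syringe_conc)
    ratio_end = x_t[-1] / m_t[-1]
    dh_guess = total_heat / (cell_volume * cell_conc * max(ratio_end / 4.0, 1.0))

    if starts is None:
        starts = []
        log_kds = [-8.5, -7.0, -5.5, -4.0]
        dh0 = dh_guess if dh_guess else -5.0
        if n_sites == 1:
            for lk in log_kds:
                for n_guess in (0.5, 1.0, 2.5, ratio_end / 4.0, ratio_end / 2.0):
                    starts.append(np.array([max(n_guess, 0.1), lk, dh0]))
        else:
            for lk1 in log_kds:
                for lk2 in log_kds:
                    if lk2 <= lk1:
                        continue
                    for n1_guess in (1.0, 2.5):
                        for dh2_sign in (1.0, -1.0):
                            starts.append(np.array([
                                n1_guess, lk1, dh0,
                                max(ratio_end / 2.0, 4.0), lk2,
                                dh2_sign * abs(dh0) / 4.0,
                            ]))

    lb = np.tile([_N_BOUNDS[0], _LOGKD_BOUNDS[0], -_DH_BOUND], n_sites)
    ub = np.tile([_N_BOUNDS[1], _LOGKD_BOUNDS[1], _DH_BOUND], n_sites)

    best = None
    for x0 in starts:
        x0 = np.clip(np.asarray(x0, float), lb, ub)
        try:
            sol = least_squares(residuals, x0=x0, bounds=(lb, ub),
                                method="trf", x_scale="jac",
                                xtol=1e-14, ftol=1e-14,
                                gtol=1e-14, max_nfev=4000)
        except Exception:
            continue
        rss = float(np.sum(sol.fun ** 2)) * heat_scale ** 2
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:
        raise RuntimeError("all fit starts failed")
    rss, sol = best

    # sort site classes by ascending Kd
    sites = _unpack(sol.x)
    order = np.argsort([s.Kd for s in sites])
    sites = [sites[i] for i in order]

    # asymptotic standard errors from J at the solution
    dof = max(n_obs - n_params, 1)
    s2 = rss / dof
    try:
        jtj = (sol.jac.T @ sol.jac) * heat_scale ** 2
        cov = s2 * np.linalg.pinv(jtj)
        raw_se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except Exception:
        raw_se = np.full(n_params, np.nan)
    se = {}
    for rank, orig in enumerate(order):
        se[f"n{rank + 1}"] = float(raw_se[3 * orig])
        # delta method: se(Kd) = ln(10) * Kd * se(log10 Kd)
        se[f"Kd{rank + 1}"] = float(
            np.log(10) * sites[rank].Kd * raw_se[3 * orig + 1])
        se[f"dH{rank + 1}"] = float(raw_se[3 * orig + 2])

    fitted = ITCModel(sites=sites, cell_volume=cell_volume,
                      cell_conc=cell_conc, syringe_conc=syringe_conc,
                      temperature=temperature)
    return ITCFitResult(model=fitted, rss=rss, n_params=n_params,
                        param_se=se, model_label=model_label, n_obs=n_obs,
                        converged=bool(sol.success), identifiable=identifiable)


def select_model(fit_one: ITCFitResult, fit_two: ITCFitResult,
                 criterion: str = "F_test", alpha: float = 0.01):
    """Choose between nested one- and two-site fits.

    F-test on the RSS reduction with (dp, N - p2) degrees of freedom at the
    given alpha, or corrected-AIC comparison.  Ties (equal RSS and parameter
    count) go to the simpler model.
    Returns (label, statistic).
    """
    if fit_one.n_obs != fit_two.n_obs:
        raise ValueError("fits must be on the same data")
    if criterion == "F_test":
        dp = fit_two.n_params - fit_one.n_params
        dof2 = fit_one.n_obs - fit_two.n_params
        if dp <= 0 or dof2 <= 0:
            raise ValueError("invalid dof for F test")
        if fit_two.rss <= 0 or fit_one.rss <= fit_two.rss * (1 + 1e-12):
            if np.isclose(fit_one.rss, fit_two.rss, rtol=1e-9):
                return "one_site", 0.0
        f_stat = ((fit_one.rss - fit_two.rss) / dp) / (fit_two.rss / dof2)
        if f_stat <= 0:
            return "one_site", float(f_stat)
        p = stats.f.sf(f_stat, dp, dof2)
        return ("two_site" if p < alpha else "one_site"), float(f_stat)
    if criterion == "AICc":
        a1, a2 = fit_one.aicc(), fit_two.aicc()
        if a2 < a1:
            return "two_site", float(a1 - a2)
        return "one_site", float(a1 - a2)
    raise ValueError("criterion must be 'F_test' or 'AICc'")
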