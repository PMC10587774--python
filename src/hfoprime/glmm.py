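"""Gaussian identity-link mixed models of event-locked unit firing.

The response (``hfodiff_fr`` or ``bl_fr``) is modelled with a fixed
intercept, up to three fixed effects drawn from {log10_power, prespike,
followed_fRonO, followed_RonO, unit_type} plus their interactions, and
crossed random intercepts for unit, contact and patient (identifiers are
globally unique, so crossed and nested parameterizations coincide).  Fitting
uses maximum likelihood via :class:`statsmodels` MixedLM with variance
components; with no random terms the model reduces to ordinary least
squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

ALLOWED_FIXED = ("log10_power", "prespike", "followed_fRonO", "followed_RonO",
                 "unit_type")
RANDOM_IDS = ("unit_id", "contact_id", "patient_id")


@dataclass
class GlmmSpec:
    response: str = "hfodiff_fr"
    fixed: list[str] = field(default_factory=lambda: ["log10_power"])
    interactions: list[tuple[str, str]] = field(default_factory=list)
    random: list[str] = field(default_factory=lambda: list(RANDOM_IDS))

    def __post_init__(self) -> None:
        if self.response not in ("hfodiff_fr", "bl_fr"):
            raise ValueError(f"unsupported response {self.response!r}")
        if len(self.fixed) > 3:
            raise ValueError("at most three fixed effects")
        if len(self.interactions) > 4:
            raise ValueError("at most four interaction terms")
        for f in self.fixed:
            if f not in ALLOWED_FIXED:
                raise ValueError(f"unknown fixed effect {f!r}")
        for r in self.random:
            if r not in RANDOM_IDS:
                raise ValueError(f"unknown random identifier {r!r}")


@dataclass
class GlmmFit:
    coefficients: pd.Series
    std_errors: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    variance_components: dict[str, float]
    converged: bool
    method: str


def build_design(trials: pd.DataFrame, spec: GlmmSpec) -> pd.DataFrame:
    """Model frame: response, encoded fixed effects, grouping identifiers.

    Fixed effects that are constant in the data are dropped with a warning
    (e.g. all-solitary cohorts have no ``prespike`` contrast).  Excluded
    units must already be absent from *trials*.
    """
    df = trials.copy()
    if "contact_id" not in df.columns and "contact" in df.columns:
        df = df.rename(columns={"contact": "contact_id"})
    cols = {spec.response}
    fixed = []
    for f in spec.fixed:
        if f not in df.columns:
            raise ValueError(f"missing column {f!r}")
        col = df[f]
        if f == "unit_type":
            col = (col == "multi").astype(float)
            df["unit_type_multi"] = col
            name = "unit_type_multi"
        else:
            name = f
        if col.nunique() < 2:
            import warnings
            warnings.warn(f"fixed effect {f!r} has a single level; dropped")
            continue
        fixed.append(name)
        cols.add(name)
    inter = []
    for a, b in spec.interactions:
        a = "unit_type_multi" if a == "unit_type" else a
        b = "unit_type_multi" if b == "unit_type" else b
        if a in fixed and b in fixed:
            name = f"{a}_x_{b}"
            df[name] = df[a] * df[b]
            inter.append(name)
            cols.add(name)
    cols.update(c for c in spec.random if c in df.columns)
    frame = df[sorted(cols)].copy()
    frame.attrs["fixed"] = fixed + inter
    frame.attrs["response"] = spec.response
    frame.attrs["random"] = [r for r in spec.random if r in frame.columns]
    return frame


def fit_glmm(frame: pd.DataFrame, spec: GlmmSpec | None = None) -> GlmmFit:
    """Fit the mixed model by ML; falls back to OLS when no random terms."""
    fixed = frame.attrs["fixed"]
    response = frame.attrs["response"]
    random = frame.attrs.get("random", [])
    rhs = " + ".join(fixed) if fixed else "1"
    formula = f"{response} ~ {rhs}"
    if not random:
        res = smf.ols(formula, data=frame).fit()
        ci = res.conf_int()
        ci.columns = ["lo", "hi"]
        return GlmmFit(res.params, res.bse, res.pvalues, ci, {}, True, "ols")
    # one dummy grouping column; all three identifiers enter as crossed
    # variance components, which is exact because ids are globally unique
    df = frame.copy().reset_index(drop=True)
    df["_all"] = 1
    vc = {r: f"0 + C({r})" for r in random}
    model = smf.mixedlm(formula, data=df, groups="_all", vc_formula=vc)
    import warnings

    from statsmodels.tools.sm_exceptions import ConvergenceWarning
    with warnings.catch_warnings():
        # boundary estimates are expected and reported via the flag
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        res = model.fit(reml=False, method="lbfgs", maxiter=400, disp=False)
    fe = [n for n in res.params.index if n in ([ "Intercept"] + fixed)]
    ci_all = res.conf_int()
    ci = ci_all.loc[fe]
    ci.columns = ["lo", "hi"]
    vcomp = {k: float(v) for k, v in res.vcomp_named.items()} \
        if hasattr(res, "vcomp_named") else \
        dict(zip(random, map(float, np.atleast_1d(res.vcomp))))
    return GlmmFit(res.params[fe], res.bse[fe], res.pvalues[fe], ci,
                   vcomp, bool(res.converged), "mixedlm-ml")


def simulate_trials(n_trials: int, n_units: int, n_contacts: int,
                    n_patients: int, beta: dict[str, float],
                    re_sd: dict[str, float] | None = None,
                    sigma: float = 1.0, p_prespike: float = 0.3,
                    seed: int = 0) -> pd.DataFrame:
    """Draw a synthetic trial table from the model the GLMM assumes.

    *beta* keys: intercept, log10_power, prespike, prespike_x_power.
    *re_sd* keys: unit, contact, patient (intercept standard deviations).
    """
    rng = np.random.default_rng(seed)
    re_sd = re_sd or {"unit": 0.5, "contact": 0.3, "patient": 0.2}
    unit = rng.integers(0, n_units, n_trials)
    unit_contact = rng.integers(0, n_contacts, n_units)
    contact_patient = rng.integers(0, n_patients, n_contacts)
    contact = unit_contact[unit]
    patient = contact_patient[contact]
    u_re = rng.normal(0, re_sd["unit"], n_units)
    c_re = rng.normal(0, re_sd["contact"], n_contacts)
    p_re = rng.normal(0, re_sd["patient"], n_patients)
    power = rng.normal(1.0, 0.4, n_trials)
    pre = (rng.uniform(size=n_trials) < p_prespike).astype(float)
    y = (beta.get("intercept", 0.0)
         + beta.get("log10_power", 0.0) * power
         + beta.get("prespike", 0.0) * pre
         + beta.get("prespike_x_power", 0.0) * pre * power
         + u_re[unit] + c_re[contact] + p_re[patient]
         + rng.normal(0, sigma, n_trials))
    return pd.DataFrame({
        "hfodiff_fr": y, "bl_fr": rng.normal(5, 1, n_trials),
        "log10_power": power, "prespike": pre,
        "unit_id": [f"u{i}" for i in unit],
        "contact_id": [f"c{i}" for i in contact],
        "patient_id": [f"p{i}" for i in patient]})


def recovery_report(configs: list[dict], n_seeds: int = 10,
                    seed0: int = 0) -> pd.DataFrame:
    """Parameter-recovery harness: bias, RMSE and 95% CI coverage per config.

    Each config dict holds ``simulate_trials`` keyword arguments (minus seed);
    true coefficients come from its ``beta`` entry.
    """
    rows = []
    for ci, cfg in enumerate(configs):
        beta = cfg["beta"]
        spec = GlmmSpec(fixed=["log10_power", "prespike"],
                        interactions=[("prespike", "log10_power")])
        name_map = {"log10_power": "log10_power", "prespike": "prespike",
                    "prespike_x_power": "prespike_x_log10_power"}
        est = {k: [] for k in name_map}
        cover = {k: 0 for k in name_map}
        for s in range(n_seeds):
            df = simulate_trials(seed=seed0 + 1000 * ci + s, **cfg)
            frame = build_design(df, spec)
            fit = fit_glmm(frame, spec)
            for k, col in name_map.items():
                if col not in fit.coefficients.index:
                    continue
                est[k].append(fit.coefficients[col])
                lo, hi = fit.conf_int.loc[col]
                if lo <= beta.get(k, 0.0) <= hi:
                    cover[k] += 1
        for k in name_map:
            e = np.array(est[k])
            rows.append({"config": ci, "term": k, "true": beta.get(k, 0.0),
                         "mean_est": e.mean(), "bias": e.mean() - beta.get(k, 0.0),
                         "rmse": float(np.sqrt(np.mean((e - beta.get(k, 0.0)) ** 2))),
                         "coverage": cover[k] / max(len(e), 1)})
    return pd.DataFrame(rows)
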