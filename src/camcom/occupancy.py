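"""Single-season occupancy models with imperfect detection.

Maximum-likelihood estimation of site occupancy (psi) and per-occasion
detection probability (p), both on the logit scale with linear covariate
effects.  For a detection history y_i over surveyed occasions at site i,
the likelihood contribution is

    L_i = psi_i * prod_j p_i^{y_ij} (1 - p_i)^{1 - y_ij}          if any y_ij = 1
    L_i = psi_i * prod_j (1 - p_i)  +  (1 - psi_i)                otherwise

with missing occasions contributing nothing (the classic zero-inflated
binomial of single-season occupancy models).  Detection covariates are
site-level (distance to border/edge, or species traits in the stacked
multi-species model), so p is constant across occasions within a unit.

The module also provides AIC ranking with Akaike weights, full-model
averaging with unconditional standard errors, relative parameter
importance, and the stacked species x site model used to relate relative
species richness to habitat covariates and detection to trophic guild
and body mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .prep import DetectionMatrix, Standardization, collapse_habitat, standardize_covariates

BOUNDARY_LOGIT = 10.0
_GUILD_LEVELS = ("carnivore", "herbivore", "insectivore", "omnivore")


# ---------------------------------------------------------------------------
# Model specification and design matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Covariate structure of one candidate model.

    ``psi_terms`` and ``p_terms`` name site covariates (``border``,
    ``edge``, ``river``), the categorical ``habitat`` (montane vs
    lowland dummy) or, for the stacked model, the species-trait terms
    ``guild`` (categorical, carnivore reference) and ``mass``.
    Intercepts are always included.
    """

    psi_terms: tuple[str, ...] = ()
    p_terms: tuple[str, ...] = ()

    @property
    def label(self) -> str:
        def side(terms):
            return "(" + (", ".join(terms) if terms else ".") + ")"
        return f"psi{side(self.psi_terms)} p{side(self.p_terms)}"

    def has_term(self, term: str) -> bool:
        return term in self.psi_terms or term in self.p_terms


def _term_columns(units: pd.DataFrame, term: str,
                  check: bool = True) -> tuple[list[str], np.ndarray]:
    """Expand one model term into named design columns."""
    if term == "habitat":
        hab = units["habitat"]
        if set(hab.unique()) - {"montane", "lowland"}:
            hab = collapse_habitat(hab)
        col = (hab.to_numpy() == "montane").astype(float)
        if check and col.min() == col.max():
            raise ValueError("habitat has a single level: non-identifiable")
        return ["habitat[montane]"], col[:, None]
    if term == "guild":
        g = units["guild"].to_numpy()
        levels = [lv for lv in _GUILD_LEVELS if (g == lv).any()]
        if len(levels) < 2:
            raise ValueError("guild has a single level: non-identifiable")
        cols = np.column_stack([(g == lv).astype(float) for lv in levels[1:]])
        return [f"guild[{lv}]" for lv in levels[1:]], cols
    col_name = term if term in units.columns else f"{term}_m"
    if col_name not in units.columns:
        raise KeyError(f"covariate {term!r} not found")
    x = units[col_name].to_numpy(dtype=float)
    return [term], x[:, None]


def build_design(units: pd.DataFrame, terms: tuple[str, ...], prefix: str,
                 check: bool = True) -> tuple[list[str], np.ndarray]:
    """Design matrix with intercept for one side of the model.

    ``check=False`` skips the single-level identifiability check, for
    prediction designs where a factor may legitimately be constant.
    """
    names, cols = [f"{prefix}:(Intercept)"], [np.ones((len(units), 1))]
    for term in terms:
        nm, c = _term_columns(units, term, check=check)
        names.extend(f"{prefix}:{n}" for n in nm)
        cols.append(c)
    return names, np.hstack(cols)


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _history_stats(matrix) -> tuple[np.ndarray, np.ndarray]:
    """Detections d_i and surveyed-occasion counts n_i per unit."""
    values = matrix.values if isinstance(matrix, DetectionMatrix) else np.asarray(matrix, float)
    surveyed = ~np.isnan(values)
    n = surveyed.sum(axis=1)
    d = np.where(surveyed, values, 0.0).sum(axis=1)
    return d, n


def occupancy_neg_loglik(beta: np.ndarray, alpha: np.ndarray, matrix,
                         psi_design: np.ndarray, p_design: np.ndarray) -> float:
    """Negative log-likelihood of the single-season occupancy model.

    Sites whose history is entirely missing are excluded with a warning;
    a non-finite linear predictor raises.
    """
    d, n = _history_stats(matrix)
    keep = n > 0
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} unit(s) with all-missing "
                      "histories excluded from the likelihood")
    return _neg_loglik(np.concatenate([beta, alpha]), d[keep], n[keep],
                       np.asarray(psi_design, float)[keep],
                       np.asarray(p_design, float)[keep],
                       len(np.atleast_1d(beta)))


def _neg_loglik(theta, d, n, x_psi, x_p, k_psi) -> float:
    eta_psi = x_psi @ theta[:k_psi]
    eta_p = x_p @ theta[k_psi:]
    if not (np.isfinite(eta_psi).all() and np.isfinite(eta_p).all()):
        raise ValueError("non-finite linear predictor")
    log_psi = -np.logaddexp(0.0, -eta_psi)
    log_1mpsi = -np.logaddexp(0.0, eta_psi)
    log_p = -np.logaddexp(0.0, -eta_p)
    log_1mp = -np.logaddexp(0.0, eta_p)
    ll_det = d * log_p + (n - d) * log_1mp
    ll = np.where(d > 0, log_psi + ll_det,
                  np.logaddexp(log_psi + n * log_1mp, log_1mpsi))
    return float(-ll.sum())


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class OccupancyFit:
    """MLE result: logit-scale coefficients, covariance, AIC."""

    spec: ModelSpec
    coef: pd.Series                  # named psi:* then p:* coefficients
    k_psi: int
    vcov: np.ndarray
    loglik: float
    converged: bool
    boundary: bool
    standardization: Standardization | None = None
    message: str = ""
    n_units: int = 0

    @property
    def label(self) -> str:
        return self.spec.label

    @property
    def k(self) -> int:
        return len(self.coef)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.clip(np.diag(self.vcov), 0, None)),
                         index=self.coef.index)

    @property
    def beta(self) -> pd.Series:
        return self.coef.iloc[:self.k_psi]

    @property
    def alpha(self) -> pd.Series:
        return self.coef.iloc[self.k_psi:]

    @property
    def psi_terms(self) -> tuple[str, ...]:
        return self.spec.psi_terms

    @property
    def p_terms(self) -> tuple[str, ...]:
        return self.spec.p_terms

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"estimate": self.coef, "se": self.se})


def _approx_hess(fun, x, eps=1e-5):
    """Central-difference Hessian of a scalar function."""
    k = len(x)
    h = np.empty((k, k))
    steps = eps * np.maximum(1.0, np.abs(x))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = steps[i]
            ej = np.zeros(k); ej[j] = steps[j]
            h[i, j] = h[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej)
                - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4.0 * steps[i] * steps[j])
    return h


def _fit_units(d, n, x_psi, x_p, psi_names, p_names, spec,
               n_starts=5, seed=0, standardization=None) -> OccupancyFit:
    keep = n > 0
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} unit(s) with all-missing "
                      "histories excluded from the fit")
        d, n, x_psi, x_p = d[keep], n[keep], x_psi[keep], x_p[keep]
    if d.sum() == 0:
        raise ValueError("no detections: occupancy model cannot be fitted")
    k_psi, k_p = x_psi.shape[1], x_p.shape[1]
    obj = lambda th: _neg_loglik(th, d, n, x_psi, x_p, k_psi)

    rng = np.random.default_rng(seed)
    starts = [np.zeros(k_psi + k_p)]
    starts += [rng.normal(0.0, 1.0, k_psi + k_p) for _ in range(n_starts - 1)]
    best = None
    for x0 in starts:
        res = minimize(obj, x0, method="L-BFGS-B",
                       options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 1000})
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun - 1e-10):
            best = res
    theta = best.x
    hess = _approx_hess(obj, theta)
    converged = bool(best.success)
    try:
        eig = np.linalg.eigvalsh(hess)
        if eig.min() <= 1e-10 * max(1.0, eig.max()):
            converged = False
            vcov = np.linalg.pinv(hess)
        else:
            vcov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        converged, vcov = False, np.full((len(theta),) * 2, np.nan)
    boundary = bool(np.max(np.abs(theta)) > BOUNDARY_LOGIT)
    return OccupancyFit(
        spec=spec, coef=pd.Series(theta, index=psi_names + p_names),
        k_psi=k_psi, vcov=vcov, loglik=-best.fun, converged=converged,
        boundary=boundary, standardization=standardization,
        message=str(best.message), n_units=int(keep.sum()))


def fit_occupancy(matrix: DetectionMatrix, spec: ModelSpec,
                  covariates: pd.DataFrame, traits: pd.DataFrame | None = None,
                  n_starts: int = 5, seed: int = 0) -> OccupancyFit:
    """Fit one species' single-season occupancy model.

    Numeric covariates are z-scored internally and the transform stored
    on the fit for prediction-grid reuse.  Multiple optimizer starts
    guard against flat likelihoods; ``converged`` is false when the
    optimizer fails or the Hessian is near-singular, and estimates past
    +/-10 on the logit scale are flagged as boundary.
    """
    covs = covariates.set_index("site_id").loc[matrix.sites].reset_index()
    covs_z, std = standardize_covariates(covs)
    d, n = _history_stats(matrix)
    psi_names, x_psi = build_design(covs_z, spec.psi_terms, "psi")
    p_names, x_p = build_design(covs_z, spec.p_terms, "p")
    return _fit_units(d, n, x_psi, x_p, psi_names, p_names, spec,
                      n_starts=n_starts, seed=seed, standardization=std)


# ---------------------------------------------------------------------------
# Model selection, averaging, importance
# ---------------------------------------------------------------------------

@dataclass
class ModelSelectionTable:
    """AIC ranking with Akaike weights (best model first)."""

    table: pd.DataFrame              # label, k, AIC, delta, weight, cum_weight
    fits: list[OccupancyFit] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.table)


def rank_models(fits: list[OccupancyFit] | list[float]) -> ModelSelectionTable:
    """Rank models by AIC and compute Akaike weights.

    Accepts fitted models (non-converged ones are excluded with a
    warning) or raw AIC values.
    """
    if len(fits) == 0:
        raise ValueError("no models to rank")
    if isinstance(fits[0], OccupancyFit):
        dropped = [f.label for f in fits if not f.converged]
        if dropped:
            warnings.warn(f"excluding non-converged models: {dropped}")
        fits = [f for f in fits if f.converged]
        if not fits:
            raise ValueError("no converged models to rank")
        labels = [f.label for f in fits]
        ks = [f.k for f in fits]
        aics = np.array([f.aic for f in fits])
    else:
        aics = np.asarray(fits, dtype=float)
        labels = [f"model_{i + 1}" for i in range(len(aics))]
        ks = [np.nan] * len(aics)
        fits = []
    order = np.argsort(aics, kind="stable")
    aics = aics[order]
    delta = aics - aics[0]
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    df = pd.DataFrame({
        "label": [labels[i] for i in order],
        "k": [ks[i] for i in order],
        "AIC": aics, "delta": delta, "weight": w, "cum_weight": np.cumsum(w),
    })
    return ModelSelectionTable(table=df, fits=[fits[i] for i in order] if fits else [])


@dataclass
class AveragedModel:
    """Model-averaged coefficients with unconditional SEs.

    ``vcov`` is the weight-averaged covariance (conditional covariances
    plus between-model dispersion) used for delta-method prediction SEs;
    ``se`` holds the classic unconditional standard errors
    sum_i w_i * sqrt(var_i + (theta_i - theta_bar)^2).
    """

    coef: pd.Series
    se: pd.Series
    vcov: np.ndarray
    psi_terms: tuple[str, ...]
    p_terms: tuple[str, ...]
    weights: pd.Series
    standardization: Standardization | None = None

    @property
    def label(self) -> str:
        return "average of: " + "; ".join(self.weights.index)


def model_average(fits: list[OccupancyFit],
                  table: ModelSelectionTable | None = None,
                  weight_floor: float = 0.01,
                  method: str = "full") -> AveragedModel:
    """Average coefficients across supported models by Akaike weight.

    Models at or below ``weight_floor`` are dropped and weights
    renormalized.  ``method='full'`` treats a coefficient absent from a
    model as 0 with zero variance (full-model averaging, the default);
    ``method='natural'`` averages each coefficient only over the models
    containing it, with per-term renormalized weights.
    """
    if method not in ("full", "natural"):
        raise ValueError(f"unknown averaging method {method!r}")
    if table is None:
        table = rank_models(fits)
    fits = table.fits if table.fits else [f for f in fits if f.converged]
    weights = table.table["weight"].to_numpy()
    keep = weights > weight_floor
    if not keep.any():
        raise ValueError("no model above the weight floor")
    fits = [f for f, kp in zip(fits, keep) if kp]
    weights = weights[keep] / weights[keep].sum()

    names: list[str] = []
    for f in fits:
        names.extend(n for n in f.coef.index if n not in names)
    m, k = len(fits), len(names)
    theta = np.zeros((m, k))
    variance = np.zeros((m, k))
    vcovs = np.zeros((m, k, k))
    present = np.zeros((m, k), dtype=bool)
    for i, f in enumerate(fits):
        pos = [names.index(n) for n in f.coef.index]
        theta[i, pos] = f.coef.to_numpy()
        variance[i, pos] = np.clip(np.diag(f.vcov), 0, None)
        vcovs[i][np.ix_(pos, pos)] = f.vcov
        present[i, pos] = True

    if method == "full":
        theta_bar = weights @ theta
        dev = theta - theta_bar
        se = weights @ np.sqrt(variance + dev**2)
    else:
        w_nat = weights[:, None] * present
        w_sum = w_nat.sum(axis=0)
        w_nat = np.divide(w_nat, w_sum, out=np.zeros_like(w_nat), where=w_sum > 0)
        theta_bar = (w_nat * theta).sum(axis=0)
        dev = theta - theta_bar
        se = (w_nat * np.sqrt(variance + dev**2)).sum(axis=0)
    vcov = np.einsum("m,mjk->jk", weights,
                     vcovs + dev[:, :, None] * dev[:, None, :])

    psi_terms, p_terms = [], []
    for f in fits:
        psi_terms.extend(t for t in f.spec.psi_terms if t not in psi_terms)
        p_terms.extend(t for t in f.spec.p_terms if t not in p_terms)
    return AveragedModel(
        coef=pd.Series(theta_bar, index=names), se=pd.Series(se, index=names),
        vcov=vcov, psi_terms=tuple(psi_terms), p_terms=tuple(p_terms),
        weights=pd.Series(weights, index=[f.label for f in fits]),
        standardization=fits[0].standardization)


def parameter_importance(table: ModelSelectionTable, term: str) -> float:
    """Relative importance of a term: summed weight of models using it.

    ``term`` may be a bare covariate name (matched on either side) or
    prefixed, e.g. ``"psi:border"`` / ``"p:guild"``.
    """
    if not table.fits:
        raise ValueError("table carries no fitted models")
    side, name = (term.split(":", 1) if ":" in term else (None, term))
    def uses(spec: ModelSpec) -> bool:
        if side == "psi":
            return name in spec.psi_terms
        if side == "p":
            return name in spec.p_terms
        return spec.has_term(name)
    if not any(uses(f.spec) for f in table.fits):
        known = sorted({t for f in table.fits
                        for t in (*f.spec.psi_terms, *f.spec.p_terms)})
        raise ValueError(f"term {name!r} appears in no model; terms: {known}")
    w = table.table["weight"].to_numpy()
    return float(sum(wi for wi, f in zip(w, table.fits) if uses(f.spec)))


# ---------------------------------------------------------------------------
# Stacked multi-species model (relative richness and guild detection)
# ---------------------------------------------------------------------------

DEFAULT_STACKED_EXCLUDE = ()
"""Species excluded from the stacked model for guild homogeneity
(outliers by body mass / behaviour); set per dataset."""

DEFAULT_STACKED_MODEL_SET = (
    ModelSpec((), ("mass", "guild")),
    ModelSpec((), ("guild",)),
    ModelSpec(("habitat",), ("mass", "guild")),
    ModelSpec(("border",), ("guild",)),
    ModelSpec(("habitat",), ("guild",)),
    ModelSpec((), ()),
)


@dataclass
class StackedRichnessResult:
    """Stacked species x site occupancy fits and their summaries."""

    fits: list[OccupancyFit]
    table: ModelSelectionTable
    guild_p: pd.DataFrame            # per-guild detection estimate and SE
    site_richness: pd.Series         # expected species per site, best model
    n_species: int


def guild_detection(fit: OccupancyFit) -> pd.DataFrame:
    """Back-transformed per-guild detection with delta-method SEs.

    Evaluated at the reference of the other p covariates (standardized
    mass = 0, i.e. an average-mass species).
    """
    names = list(fit.coef.index)
    if not any(n.startswith("p:guild[") for n in names):
        raise ValueError("fit has no guild term on detection")
    levels = ["carnivore"] + [n[len("p:guild["):-1] for n in names
                              if n.startswith("p:guild[")]
    rows = []
    for lv in levels:
        e = np.zeros(len(names))
        e[names.index("p:(Intercept)")] = 1.0
        key = f"p:guild[{lv}]"
        if key in names:
            e[names.index(key)] = 1.0
        eta = float(e @ fit.coef.to_numpy())
        se_eta = float(np.sqrt(max(e @ fit.vcov @ e, 0.0)))
        p = expit(eta)
        rows.append({"guild": lv, "p": p, "se": p * (1 - p) * se_eta,
                     "logit_p": eta, "se_logit": se_eta})
    return pd.DataFrame(rows)


def stacked_richness_fit(
    matrices: dict[str, DetectionMatrix],
    traits: pd.DataFrame,
    covariates: pd.DataFrame,
    model_set: tuple[ModelSpec, ...] = DEFAULT_STACKED_MODEL_SET,
    exclude: tuple[str, ...] = DEFAULT_STACKED_EXCLUDE,
    mass_scale: str = "raw",
    n_starts: int = 3,
    seed: int = 0,
) -> StackedRichnessResult:
    """Fit the community of detection histories as stacked units.

    Each (species, site) pair is one occupancy unit; site covariates act
    on psi and species traits (guild, standardized body mass) on p, with
    species x site units treated as independent given covariates.  The
    per-site expected species richness is the summed fitted psi of the
    best-supported model.
    """
    species = [s for s in matrices if s not in exclude]
    if not species:
        raise ValueError("no species left after exclusions")
    tr = traits.set_index("species").loc[species]
    if tr["guild"].nunique() < 2 and any("guild" in s.p_terms for s in model_set):
        raise ValueError("a single guild is present: guild models are "
                         "non-identifiable")
    mass = tr["mass_kg"].to_numpy(dtype=float)
    if mass_scale == "log":
        mass = np.log(mass)
    elif mass_scale != "raw":
        raise ValueError(f"unknown mass_scale {mass_scale!r}")
    mass_z = (mass - mass.mean()) / mass.std(ddof=1) if len(species) > 1 else mass * 0.0

    sites0 = matrices[species[0]].sites
    covs = covariates.set_index("site_id").loc[sites0].reset_index()
    covs_z, std = standardize_covariates(covs)

    d_list, n_list, unit_frames = [], [], []
    for k, sp in enumerate(species):
        m = matrices[sp]
        if m.sites != sites0:
            raise ValueError(f"matrix for {sp!r} has a different site order")
        d, n = _history_stats(m)
        d_list.append(d)
        n_list.append(n)
        uf = covs_z.copy()
        uf["guild"] = tr["guild"].iloc[k]
        uf["mass"] = mass_z[k]
        unit_frames.append(uf)
    d = np.concatenate(d_list)
    n = np.concatenate(n_list)
    units = pd.concat(unit_frames, ignore_index=True)

    fits = []
    for spec in model_set:
        psi_names, x_psi = build_design(units, spec.psi_terms, "psi")
        p_names, x_p = build_design(units, spec.p_terms, "p")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            fits.append(_fit_units(d, n, x_psi, x_p, psi_names, p_names, spec,
                                   n_starts=n_starts, seed=seed,
                                   standardization=std))
    table = rank_models(fits)
    best = table.fits[0]

    guild_fit = next((f for f in table.fits if "guild" in f.spec.p_terms), None)
    guild_p = guild_detection(guild_fit) if guild_fit is not None else pd.DataFrame()

    psi_names, x_psi = build_design(covs_z, best.spec.psi_terms, "psi")
    psi_site = expit(x_psi @ best.beta.to_numpy())
    site_richness = pd.Series(len(species) * psi_site, index=sites0,
                              name="expected_richness")
    return StackedRichnessResult(fits=fits, table=table, guild_p=guild_p,
                                 site_richness=site_richness,
                                 n_species=len(species))


# ---------------------------------------------------------------------------
# Fit serialization (JSON)
# ---------------------------------------------------------------------------

def model_to_dict(model: OccupancyFit | AveragedModel) -> dict:
    """JSON-serializable form of a fit or averaged model."""
    d = {
        "label": model.label,
        "psi_terms": list(model.psi_terms),
        "p_terms": list(model.spec.p_terms if isinstance(model, OccupancyFit)
                        else model.p_terms),
        "coef_names": list(model.coef.index),
        "coef": [float(c) for c in model.coef],
        "se": [float(s) for s in model.se],
        "vcov": np.asarray(model.vcov).tolist(),
    }
    if isinstance(model, OccupancyFit):
        d.update(logLik=float(model.loglik), k=int(model.k),
                 AIC=float(model.aic), converged=bool(model.converged),
                 boundary=bool(model.boundary))
    else:
        d["weights"] = {k: float(v) for k, v in model.weights.items()}
    std = model.standardization
    if std is not None:
        d["standardization"] = {"means": std.means, "sds": std.sds}
    return d


def model_from_dict(d: dict) -> AveragedModel:
    """Rebuild a prediction-ready model from its JSON form.

    Loaded models are represented uniformly as :class:`AveragedModel`
    (a single fit is an average of one model with weight 1).
    """
    std = None
    if "standardization" in d:
        std = Standardization(means=dict(d["standardization"]["means"]),
                              sds=dict(d["standardization"]["sds"]))
    weights = d.get("weights", {d.get("label", "model"): 1.0})
    return AveragedModel(
        coef=pd.Series(d["coef"], index=d["coef_names"]),
        se=pd.Series(d["se"], index=d["coef_names"]),
        vcov=np.asarray(d["vcov"], dtype=float),
        psi_terms=tuple(d["psi_terms"]), p_terms=tuple(d["p_terms"]),
        weights=pd.Series(weights), standardization=std)


def save_model(model, path) -> None:
    import json

    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=1)


def load_model(path) -> AveragedModel:
    import json

    with open(path) as fh:
        return model_from_dict(json.load(fh))


def select_species(summary: pd.DataFrame, min_events: int = 10,
                   min_naive_occ: float = 0.1) -> list[str]:
    """Species eligible for species-specific fits: enough detections
    (>= min_events events) or wide enough naive occupancy."""
    ok = (summary["n_events"] >= min_events) | \
         (summary["naive_occupancy"] >= min_naive_occ)
    return summary.loc[ok, "species"].tolist()


def default_species_model_set() -> tuple[ModelSpec, ...]:
    """Candidate set for species-specific fits: null, p(border), p(edge),
    each single psi covariate and pairwise psi combinations, crossed with
    the p options."""
    psi_opts: list[tuple[str, ...]] = [()]
    singles = ["border", "edge", "river", "habitat"]
    psi_opts += [(t,) for t in singles]
    psi_opts += [(a, b) for i, a in enumerate(singles) for b in singles[i + 1:]]
    p_opts: list[tuple[str, ...]] = [(), ("border",), ("edge",)]
    return tuple(ModelSpec(psi, p) for psi in psi_opts for p in p_opts)
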