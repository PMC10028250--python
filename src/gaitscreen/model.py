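"""Probabilistic inverse model of subject characteristics from kinematics.

The model infers a subject characteristic theta (mass, size or age) per
stride from sex, nine spatiotemporal gait variables, twelve dynamic-posture
values (mean angle and eROM of six joints) and twelve coordination
components::

    theta ~ v1*alpha + vs*beta_s + sum_G vg*beta_g + sum_P vp*beta_p
            + sum_C vc*beta_c + v1*eps

a robust Bayesian linear regression: Student-t observation model with
Gamma-distributed degrees of freedom nu, Normal priors on intercept and
slopes, Half-Cauchy prior on the residual scale eps.  Predictors are
centered and scaled by the training set; the outcome is optionally
log-transformed (mass) and standardized, so the Normal(0, 2) slope priors
express the intended two-standard-deviations width of the observed values.
The model counts 36 free parameters: alpha, beta_sex, 9 gait slopes,
12 posture slopes, 12 coordination slopes and eps (nu is an auxiliary
shape parameter of the likelihood).

Sampling uses a blocked Gibbs sampler over the Student-t scale-mixture
representation (t_nu noise = Normal noise with Gamma-distributed
per-observation precision weights): the intercept and slopes are drawn
exactly from their conjugate multivariate normal conditional, the mixing
weights from their Gamma conditional, and the Half-Cauchy residual scale
and the Gamma-prior nu by univariate slice sampling.  Independent chains
feed the Gelman-Rubin (R-hat) and effective-sample-size diagnostics.
Per-stride inference draws posterior-predictive samples of theta at the
stride's predictor values across the posterior, and reports
Delta = predicted - actual.

The public surface follows the Model/Results pattern:
``SubjectModel.from_dataframe(df, outcome="age").fit(seed=0)`` returns a
:class:`SubjectModelResults` with ``summary()`` and ``predict()``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .fourier import ANALYSIS_JOINTS

GAIT_COLUMNS: tuple[str, ...] = (
    "stride_distance",
    "stride_frequency",
    "speed",
    "duty_factor_fore",
    "duty_factor_hind",
    "clearance_fore",
    "clearance_hind",
    "head_angle",
    "hindlimb_phase",
)
POSTURE_COLUMNS: tuple[str, ...] = tuple(f"{j}_mean" for j in ANALYSIS_JOINTS) + tuple(
    f"{j}_erom" for j in ANALYSIS_JOINTS
)
COORDINATION_COLUMNS: tuple[str, ...] = tuple(f"cc{i}" for i in range(1, 13))
SEX_COLUMN = "sex_male"

#: Default outcome transforms: mass is strictly positive and right-skewed.
DEFAULT_TRANSFORMS = {"mass": "log", "size": "identity", "age": "identity"}


@dataclass
class ModelDesign:
    """Design of one outcome model: predictors, transform, prior widths."""

    outcome: str
    transform: str = "identity"  # "identity" | "log"
    predictors: tuple[str, ...] = (SEX_COLUMN,) + GAIT_COLUMNS + POSTURE_COLUMNS + COORDINATION_COLUMNS
    slope_prior_sd: float = 2.0
    epsilon_prior_scale: float = 1.0
    nu_prior_alpha: float = 2.0
    nu_prior_beta: float = 0.1

    @property
    def n_free_parameters(self) -> int:
        """alpha + one slope per predictor + eps (nu not counted)."""
        return 1 + len(self.predictors) + 1

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__ | {"predictors": list(self.predictors)}, indent=2))


def split_dataset(
    rows: pd.DataFrame,
    validation_fraction: float | None = None,
    seed: int = 0,
    category_column: str = "birth_weight_category",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Split stride rows into (NBW train, NBW validation, LBW test).

    All low-birth-weight strides form the test set; a seeded random subset
    of normal-birth-weight strides of about the same size (or an explicit
    ``validation_fraction`` of the NBW strides) forms the validation set;
    the remainder trains the model.  The split is by stride, so strides of
    one subject may appear on both sides of the train/validation divide
    (subject-level leakage is not prevented).
    """
    is_lbw = rows[category_column].astype(str).str.upper() == "LBW"
    test = rows[is_lbw]
    nbw = rows[~is_lbw]
    if validation_fraction is not None:
        n_val = int(round(validation_fraction * len(nbw)))
    elif len(test) > 0:
        n_val = min(len(test), len(nbw) - 1)
    else:
        raise ValueError("no LBW rows: pass validation_fraction explicitly")
    rng = np.random.default_rng(seed)
    val_idx = rng.choice(nbw.index.to_numpy(), size=n_val, replace=False)
    validation = nbw.loc[sorted(val_idx, key=list(nbw.index).index)]
    train = nbw.drop(index=val_idx)
    return train, validation, test


def _slice_sample(x0: float, logp, rng: np.random.Generator, w: float = 0.5, max_steps: int = 50) -> float:
    """One univariate slice-sampling update (stepping out + shrinkage)."""
    y = logp(x0) + np.log(rng.random())
    lo = x0 - w * rng.random()
    hi = lo + w
    for _ in range(max_steps):
        if logp(lo) <= y:
            break
        lo -= w
    for _ in range(max_steps):
        if logp(hi) <= y:
            break
        hi += w
    for _ in range(100):
        x = lo + (hi - lo) * rng.random()
        if logp(x) > y:
            return x
        if x < x0:
            lo = x
        else:
            hi = x
    return x0  # pathological flat slice; keep current state


def _student_t_logpdf(z: np.ndarray, nu: np.ndarray) -> np.ndarray:
    """log pdf of the standard Student-t at z, vectorized over nu."""
    return (
        gammaln((nu + 1.0) / 2.0)
        - gammaln(nu / 2.0)
        - 0.5 * np.log(nu * np.pi)
        - (nu + 1.0) / 2.0 * np.log1p(z**2 / nu)
    )


class SubjectModel:
    """Bayesian inverse model for one subject characteristic.

    Parameters
    ----------
    design : ModelDesign
        Outcome name, transform and predictor list.
    train_rows : DataFrame
        One row per stride with all predictor columns and the outcome.
    """

    def __init__(self, design: ModelDesign, train_rows: pd.DataFrame):
        self.design = design
        missing = [c for c in design.predictors if c not in train_rows.columns]
        if missing:
            raise ValueError(f"missing predictor columns: {missing}")
        if design.outcome not in train_rows.columns:
            raise ValueError(f"missing outcome column {design.outcome!r}")
        if len(train_rows) < design.n_free_parameters:
            warnings.warn(
                f"only {len(train_rows)} training rows for {design.n_free_parameters} free parameters",
                stacklevel=2,
            )
        X = train_rows.loc[:, list(design.predictors)].to_numpy(dtype=float)
        sd = X.std(axis=0, ddof=0)
        scale = np.maximum(1.0, np.abs(X.mean(axis=0)))
        dead = [name for name, s, ref in zip(design.predictors, sd, scale) if not s > 1e-12 * ref]
        if dead:
            raise ValueError(f"degenerate (zero-variance) predictors: {dead}")
        y = train_rows[design.outcome].to_numpy(dtype=float)
        if design.transform == "log":
            if np.any(y <= 0):
                raise ValueError(f"log transform requires positive {design.outcome}")
            y = np.log(y)
        elif design.transform != "identity":
            raise ValueError(f"unknown transform {design.transform!r}")
        self.x_mean = X.mean(axis=0)
        self.x_sd = sd
        self.y_mean = float(y.mean())
        self.y_sd = float(y.std(ddof=0)) or 1.0
        self.X = (X - self.x_mean) / self.x_sd
        self.y = (y - self.y_mean) / self.y_sd
        self.train_rows = train_rows

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        outcome: str,
        transform: str | None = None,
        predictors: tuple[str, ...] | None = None,
    ) -> "SubjectModel":
        design = ModelDesign(
            outcome=outcome,
            transform=DEFAULT_TRANSFORMS.get(outcome, "identity") if transform is None else transform,
        )
        if predictors is not None:
            design.predictors = tuple(predictors)
        return cls(design, df)

    @property
    def n_free_parameters(self) -> int:
        return self.design.n_free_parameters

    # --- posterior geometry ---------------------------------------------
    @property
    def _ndim(self) -> int:
        return 1 + self.X.shape[1] + 2  # alpha, betas, log sigma, log nu

    def log_posterior(self, theta: np.ndarray) -> np.ndarray:
        """Joint log posterior density (marginal Student-t form).

        ``theta`` rows are [alpha, beta..., log sigma, log nu].  Used by
        tests as an independent check of the sampler's target; the sampler
        itself works on the scale-mixture augmentation.
        """
        theta = np.atleast_2d(theta)
        p = self.X.shape[1]
        alpha = theta[:, 0]
        beta = theta[:, 1 : 1 + p]
        log_sigma = theta[:, 1 + p]
        log_nu = theta[:, 2 + p]
        sigma = np.exp(log_sigma)
        nu = np.exp(log_nu)
        d = self.design

        lp = -0.5 * (alpha / d.slope_prior_sd) ** 2
        lp += -0.5 * ((beta / d.slope_prior_sd) ** 2).sum(axis=1)
        s0 = d.epsilon_prior_scale
        lp += -np.log1p((sigma / s0) ** 2) + log_sigma  # Half-Cauchy + Jacobian
        lp += (d.nu_prior_alpha - 1.0) * log_nu - d.nu_prior_beta * nu + log_nu

        mu = alpha[None, :] + self.X @ beta.T  # (n, C)
        z = (self.y[:, None] - mu) / sigma[None, :]
        lp += (_student_t_logpdf(z, nu[None, :]) - log_sigma[None, :]).sum(axis=0)
        return np.where(np.isfinite(lp), lp, -np.inf)

    # --- sampling -------------------------------------------------------
    def _run_chain(self, sweeps: int, keep: int, rng: np.random.Generator) -> np.ndarray:
        """One Gibbs chain; returns the last ``keep`` states.

        Scale-mixture augmentation: y_i = x_i beta + e_i with
        e_i | lam_i ~ N(0, sigma^2 / lam_i) and lam_i ~ Gamma(nu/2, nu/2)
        marginalizes to Student-t(nu) noise.  The sweep draws beta from its
        exact Gaussian conditional; log sigma and log nu are slice-sampled
        against the lam-marginalized Student-t likelihood (collapsing the
        weights avoids the slow sigma/nu-lam coupling); lam is then redrawn
        from its Gamma conditional.
        """
        X = np.column_stack([np.ones(len(self.y)), self.X])
        y = self.y
        n, q = X.shape
        d = self.design
        prior_prec = 1.0 / d.slope_prior_sd**2

        # start: ridge fit, unit weights
        coef = np.linalg.solve(X.T @ X + 1e-3 * np.eye(q), X.T @ y)
        coef = coef + 0.1 * rng.standard_normal(q)
        sigma = max(float((y - X @ coef).std(ddof=0)), 1e-3) * np.exp(0.2 * rng.standard_normal())
        nu = float(np.exp(np.log(15.0) + 0.3 * rng.standard_normal()))
        lam = np.ones(n)

        out = np.empty((keep, q + 2))
        s0 = d.epsilon_prior_scale
        for sweep in range(sweeps):
            # beta | lam, sigma
            Xl = X * lam[:, None]
            A = (Xl.T @ X) / sigma**2 + prior_prec * np.eye(q)
            b = (Xl.T @ y) / sigma**2
            L = np.linalg.cholesky(A)
            mean = np.linalg.solve(A, b)
            coef = mean + np.linalg.solve(L.T, rng.standard_normal(q))
            resid = y - X @ coef
            r2 = resid**2

            # log sigma | beta, nu (lam marginalized out -> Student-t lik.)
            def logp_u(u: float) -> float:
                s = np.exp(u)
                ll = -n * u - (nu + 1.0) / 2.0 * np.log1p(r2 / (nu * s * s)).sum()
                return ll - np.log1p((s / s0) ** 2) + u

            sigma = float(np.exp(_slice_sample(np.log(sigma), logp_u, rng, w=0.3)))

            # log nu | beta, sigma (lam marginalized out)
            z2 = r2 / sigma**2

            def logp_v(v: float) -> float:
                nv = np.exp(v)
                ll = n * (gammaln((nv + 1.0) / 2.0) - gammaln(nv / 2.0) - 0.5 * np.log(nv))
                ll -= (nv + 1.0) / 2.0 * np.log1p(z2 / nv).sum()
                return ll + (d.nu_prior_alpha - 1.0) * v - d.nu_prior_beta * nv + v

            nu = float(np.exp(_slice_sample(np.log(nu), logp_v, rng, w=1.0)))

            # lam_i | rest ~ Gamma((nu+1)/2, rate (nu + (r_i/sigma)^2)/2)
            rate = 0.5 * (nu + z2)
            lam = rng.gamma((nu + 1.0) / 2.0, 1.0 / rate)

            if sweep >= sweeps - keep:
                out[sweep - (sweeps - keep)] = np.concatenate([coef, [np.log(sigma)], [np.log(nu)]])
        return out

    def fit(
        self,
        draws: int = 1000,
        tune: int = 1000,
        chains: int = 4,
        seed: int | None = None,
        profile: str | None = None,
    ) -> "SubjectModelResults":
        """Sample the posterior: ``chains`` independent Gibbs chains, each
        ``tune`` warm-up sweeps (discarded) plus ``draws`` retained sweeps.

        ``profile='reference'`` switches to the heavy reference settings
        (32 chains, 2**14 tuning and sampling sweeps).  Fully deterministic
        for a given seed.
        """
        if profile == "reference":
            chains, tune, draws = 32, 2**14, 2**14
        root = np.random.default_rng(seed)
        chain_seeds = root.integers(2**31, size=chains)
        chain = np.stack(
            [self._run_chain(tune + draws, draws, np.random.default_rng(s)) for s in chain_seeds]
        )
        return SubjectModelResults(
            model=self,
            chain=chain,  # (chains, draws, ndim)
            acceptance_fraction=1.0,  # Gibbs/slice steps always move
            sampler_settings={"chains": chains, "tune": tune, "draws": draws, "seed": seed},
        )


@dataclass
class PredictiveInference:
    """Posterior-predictive inference of one outcome for one stride."""

    stride_id: str
    subject_id: str
    outcome: str
    samples: np.ndarray  # predictive draws of theta, natural scale
    actual: float

    @property
    def delta(self) -> np.ndarray:
        """Predicted minus actual, per predictive sample."""
        return self.samples - self.actual

    @property
    def mean_delta(self) -> float:
        return float(self.delta.mean())

    @property
    def sd(self) -> float:
        return float(self.samples.std(ddof=0))

    @property
    def fraction_below(self) -> float:
        """Fraction of predictive samples below the actual value."""
        return float((self.samples < self.actual).mean())


class SubjectModelResults:
    """Posterior draws, diagnostics and predictive inference for one model."""

    def __init__(self, model: SubjectModel, chain: np.ndarray, acceptance_fraction: float, sampler_settings: dict):
        self.model = model
        self.chain = chain  # (n_chains_as_walkers, n_draws, ndim)
        self.acceptance_fraction = acceptance_fraction
        self.sampler_settings = sampler_settings
        self._diagnostics: pd.DataFrame | None = None

    # --- parameter views ------------------------------------------------
    @property
    def parameter_names(self) -> list[str]:
        return ["alpha"] + [f"b_{p}" for p in self.model.design.predictors] + ["epsilon", "nu"]

    def _draws(self, flat: bool = True) -> np.ndarray:
        """Chain with sigma/nu back-transformed from log space."""
        c = self.chain.copy()
        c[..., -2:] = np.exp(c[..., -2:])
        return c.reshape(-1, c.shape[-1]) if flat else c

    def posterior(self) -> pd.DataFrame:
        """Flattened posterior draws, one column per parameter."""
        return pd.DataFrame(self._draws(flat=True), columns=self.parameter_names)

    # --- diagnostics ----------------------------------------------------
    def diagnostics(self) -> pd.DataFrame:
        """R-hat and effective sample size per parameter (walkers as chains)."""
        if self._diagnostics is None:
            import arviz as az

            c = self._draws(flat=False)
            data = {name: c[:, :, i] for i, name in enumerate(self.parameter_names)}
            idata = az.from_dict(posterior=data)
            rhat = az.rhat(idata)
            ess = az.ess(idata)
            self._diagnostics = pd.DataFrame(
                {
                    "rhat": [float(rhat[name].values) for name in self.parameter_names],
                    "ess": [float(ess[name].values) for name in self.parameter_names],
                },
                index=self.parameter_names,
            )
        return self._diagnostics

    @property
    def converged(self) -> bool:
        """All R-hat at or below 1.01."""
        return bool((self.diagnostics()["rhat"] <= 1.01).all())

    @property
    def n_free_parameters(self) -> int:
        return self.model.n_free_parameters

    def summary(self) -> pd.DataFrame:
        """Posterior mean, sd, central 95% interval and diagnostics."""
        draws = self._draws(flat=True)
        lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
        out = pd.DataFrame(
            {
                "mean": draws.mean(axis=0),
                "sd": draws.std(axis=0, ddof=0),
                "hdi_2.5%": lo,
                "hdi_97.5%": hi,
            },
            index=self.parameter_names,
        )
        return out.join(self.diagnostics())

    def slope_interval(self, predictor: str, prob: float = 0.95) -> tuple[float, float]:
        """Central credible interval of one (standardized) slope."""
        draws = self.posterior()[f"b_{predictor}"].to_numpy()
        a = 100 * (1 - prob) / 2
        lo, hi = np.percentile(draws, [a, 100 - a])
        return float(lo), float(hi)

    # --- posterior predictive -------------------------------------------
    def predict(
        self,
        rows: pd.DataFrame,
        n_samples: int | None = None,
        seed: int | None = None,
    ) -> list[PredictiveInference]:
        """Per-stride posterior-predictive inference.

        For every row, theta is drawn from the Student-t observation model
        at the row's predictor values, across (a seeded subsample of) the
        posterior draws; the inverse outcome transform is applied, and
        Delta = predicted - actual is available on each inference.
        """
        m = self.model
        scaling = {"x_mean": m.x_mean, "x_sd": m.x_sd, "y_mean": m.y_mean, "y_sd": m.y_sd}
        return _posterior_predict(self._draws(flat=True), m.design, scaling, rows, n_samples, seed)

    def save_posterior(self, path) -> None:
        """Write flattened posterior draws to CSV."""
        self.posterior().to_csv(path, index=False)

    def save_bundle(self, out_dir) -> None:
        """Write everything needed for later prediction to a directory.

        Layout: posterior.csv (flattened draws), design.json,
        scaling.json, diagnostics.csv, settings.json.
        """
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.save_posterior(out / "posterior.csv")
        self.model.design.to_json(out / "design.json")
        (out / "scaling.json").write_text(
            json.dumps(
                {
                    "x_mean": self.model.x_mean.tolist(),
                    "x_sd": self.model.x_sd.tolist(),
                    "y_mean": self.model.y_mean,
                    "y_sd": self.model.y_sd,
                }
            )
        )
        self.diagnostics().to_csv(out / "diagnostics.csv")
        (out / "settings.json").write_text(
            json.dumps({**self.sampler_settings, "acceptance_fraction": self.acceptance_fraction})
        )


def _posterior_predict(
    draws: np.ndarray,
    design: ModelDesign,
    scaling: dict,
    rows: pd.DataFrame,
    n_samples: int | None = None,
    seed: int | None = None,
) -> list[PredictiveInference]:
    missing = [c for c in design.predictors if c not in rows.columns]
    if missing:
        raise ValueError(f"missing predictor columns: {missing}")
    total = draws.shape[0]
    if n_samples is None:
        n_samples = min(total, 4000)
    rng = np.random.default_rng(seed)
    idx = rng.choice(total, size=n_samples, replace=n_samples > total)
    sub = draws[idx]
    p = len(design.predictors)
    alpha, beta = sub[:, 0], sub[:, 1 : 1 + p]
    sigma, nu = sub[:, 1 + p], sub[:, 2 + p]

    Xs = (rows.loc[:, list(design.predictors)].to_numpy(dtype=float) - scaling["x_mean"]) / scaling["x_sd"]
    mu = alpha[None, :] + Xs @ beta.T  # (S, D)
    t_noise = rng.standard_t(np.broadcast_to(nu, mu.shape))
    theta_std = mu + sigma[None, :] * t_noise
    theta = theta_std * scaling["y_sd"] + scaling["y_mean"]
    if design.transform == "log":
        theta = np.exp(theta)

    actual = (
        rows[design.outcome].to_numpy(dtype=float)
        if design.outcome in rows.columns
        else np.full(len(rows), np.nan)
    )
    stride_ids = (
        rows["stride_id"].astype(str).to_numpy() if "stride_id" in rows.columns else rows.index.astype(str).to_numpy()
    )
    subject_ids = (
        rows["subject_id"].astype(str).to_numpy()
        if "subject_id" in rows.columns
        else np.full(len(rows), "", dtype=object)
    )
    return [
        PredictiveInference(
            stride_id=stride_ids[i],
            subject_id=subject_ids[i],
            outcome=design.outcome,
            samples=theta[i],
            actual=float(actual[i]),
        )
        for i in range(len(rows))
    ]


class PosteriorPredictor:
    """Posterior-predictive inference from a saved model bundle."""

    def __init__(self, draws: np.ndarray, design: ModelDesign, scaling: dict):
        self.draws = draws
        self.design = design
        self.scaling = scaling

    @classmethod
    def load(cls, bundle_dir) -> "PosteriorPredictor":
        bundle = Path(bundle_dir)
        payload = json.loads((bundle / "design.json").read_text())
        payload["predictors"] = tuple(payload["predictors"])
        design = ModelDesign(**payload)
        scaling = json.loads((bundle / "scaling.json").read_text())
        scaling["x_mean"] = np.asarray(scaling["x_mean"])
        scaling["x_sd"] = np.asarray(scaling["x_sd"])
        draws = pd.read_csv(bundle / "posterior.csv").to_numpy(dtype=float)
        return cls(draws, design, scaling)

    def predict(self, rows: pd.DataFrame, n_samples: int | None = None, seed: int | None = None):
        return _posterior_predict(self.draws, self.design, self.scaling, rows, n_samples, seed)
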