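"""The normative lung-density model and its estimation.

The model has two coupled parts, both ordinary least squares on a cohort of
subjects with radiologically normal lungs:

1. *Volume translation* — predicted physiologic TLC (from gender and height)
   is translated to a predicted anatomic CT-volume by a gender-specific
   line, ``V_CT,pred = γ + δ·TLC_pred``.  TLC counts air including the
   trachea; CT-volume counts lung voxels including tissue and excluding the
   trachea, so the two scales differ systematically.

2. *Density law* — across normal subjects, log percentile density falls
   linearly with log lung volume.  Each control is normalized exactly like a
   patient (recalibrated PD15, volume-corrected to its predicted CT-volume
   with the sponge-model slope S), and the law

       log(rho_cor) = α + β·log(V_CT,pred) + ε,   ε ~ (0, σ²)

   is fitted by OLS with σ the residual standard deviation (n − 2 divisor).
   A subject's Standard Mass Score is then the studentized residual-style
   Z-score of its corrected density against this line; by construction the
   training cohort has in-sample mean SMS of exactly zero.

Regional variants (apical/central/basal) refit γ, δ, α, β, σ on the
region's own volumes and densities.

`NormativeDensityModel` is the model class (construct from a cohort
DataFrame, then :meth:`fit`); :class:`NormativeModel` is the results object
carrying coefficients, standard errors, a :meth:`~NormativeModel.summary`
table and persistence hooks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import (
    DegenerateModelWarning,
    DomainError,
    FitError,
    ScopeError,
)
from .reference_equations import load_default_tlc_coefficients, predicted_tlc

SCOPES = ("global", "apical", "central", "basal")
REGIONS = ("apical", "central", "basal")

_LOG = {"e": np.log, "10": np.log10}


def _log_fn(base: str) -> Callable[[np.ndarray], np.ndarray]:
    if base not in _LOG:
        raise DomainError(f"log base must be 'e' or '10', got {base!r}")
    return _LOG[base]


def _scope_columns(scope: str) -> tuple[str, str]:
    if scope == "global":
        return "v_ct", "pd15"
    if scope in REGIONS:
        return f"v_ct_{scope}", f"pd15_{scope}"
    raise ScopeError(f"unknown scope {scope!r}")


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclass
class VolumeTranslation:
    """γ + δ·TLC_pred for one gender (and scope)."""
    gamma: float
    delta: float
    se_gamma: float
    se_delta: float
    n: int

    def predict(self, tlc_pred: float) -> float:
        return self.gamma + self.delta * float(tlc_pred)


@dataclass
class DensityLaw:
    """α, β, σ of the log density–log volume regression for one scope."""
    alpha: float
    beta: float
    sigma: float
    se_alpha: float
    se_beta: float
    se_sigma: float
    n: int

    def predict_log_density(self, log_v_pred: float) -> float:
        return self.alpha + self.beta * float(log_v_pred)


@dataclass
class NormativeModel:
    """Fitted normative model: coefficients, uncertainties and provenance."""

    global_law: DensityLaw
    translations: dict            # scope -> gender -> VolumeTranslation
    regional_laws: dict = field(default_factory=dict)  # region -> DensityLaw
    slope_s: float = -1.1
    log_base: str = "e"
    n_subjects: int = 0
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.slope_s >= 0:
            raise DomainError(f"sponge-model slope S must be negative, got {self.slope_s}")
        _log_fn(self.log_base)

    # -- access -------------------------------------------------------------
    @property
    def scopes(self) -> tuple[str, ...]:
        return ("global", *self.regional_laws.keys())

    def law(self, scope: str = "global") -> DensityLaw:
        if scope == "global":
            return self.global_law
        if scope in self.regional_laws:
            return self.regional_laws[scope]
        raise ScopeError(f"model carries no density law for scope {scope!r}")

    def translation(self, gender: str, scope: str = "global") -> VolumeTranslation:
        by_gender = self.translations.get(scope)
        if by_gender is None:
            raise ScopeError(f"model carries no volume translation for scope {scope!r}")
        tr = by_gender.get(gender)
        if tr is None:
            raise ScopeError(
                f"volume translation for gender {gender!r} unavailable in this model"
            )
        return tr

    def predicted_v_ct(self, gender: str, tlc_pred: float,
                       scope: str = "global") -> float:
        """Predicted CT-volume (L) at predicted TLC, per gender and scope."""
        v = self.translation(gender, scope).predict(tlc_pred)
        if v <= 0:
            raise DomainError(f"non-positive predicted CT-volume {v:.3f} L")
        return v

    def log(self, x) -> np.ndarray:
        return _log_fn(self.log_base)(np.asarray(x, dtype=float))

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "Normative lung-density model",
            "=" * 64,
            f"subjects: {self.n_subjects}    log base: {self.log_base}    "
            f"sponge slope S: {self.slope_s}",
            f"provenance: {self.provenance or '-'}",
            "",
            f"{'scope':<10}{'alpha (SE)':>18}{'beta (SE)':>18}{'sigma':>10}",
            "-" * 64,
        ]
        for scope in self.scopes:
            law = self.law(scope)
            lines.append(
                f"{scope:<10}"
                f"{law.alpha:>10.4f} ({law.se_alpha:.4f})"
                f"{law.beta:>10.4f} ({law.se_beta:.4f})"
                f"{law.sigma:>10.4f}"
            )
        lines += ["", f"{'scope':<10}{'gender':<8}{'gamma (SE)':>18}{'delta (SE)':>18}",
                  "-" * 64]
        for scope, by_gender in self.translations.items():
            for gender, tr in by_gender.items():
                lines.append(
                    f"{scope:<10}{gender:<8}"
                    f"{tr.gamma:>10.4f} ({tr.se_gamma:.4f})"
                    f"{tr.delta:>10.4f} ({tr.se_delta:.4f})"
                )
        return "\n".join(lines)

    def plot_density_law(self, cohort: Optional[pd.DataFrame] = None,
                         scope: str = "global", ax=None):
        """Plot the fitted log density–log volume line, optionally with the
        cohort's corrected densities overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        law = self.law(scope)
        if cohort is not None:
            translations = {
                g: self.translation(g, scope)
                for g in set(cohort["gender"])
            }
            v_pred, rho_cor = _corrected_density(
                cohort, scope, self.slope_s, translations, None)
            ax.scatter(self.log(v_pred), self.log(rho_cor), s=12, alpha=0.6,
                       label="controls")
            grid = np.linspace(self.log(v_pred).min(), self.log(v_pred).max(), 50)
        else:
            grid = np.linspace(self.log(3.0), self.log(9.0), 50)
        ax.plot(grid, law.alpha + law.beta * grid, color="C3",
                label=f"{scope} law")
        ax.fill_between(grid, law.alpha + law.beta * grid - 2 * law.sigma,
                        law.alpha + law.beta * grid + 2 * law.sigma,
                        color="C3", alpha=0.15, label="±2σ")
        ax.set_xlabel(f"log{'' if self.log_base == 'e' else '10'} predicted CT-volume [L]")
        ax.set_ylabel(f"log{'' if self.log_base == 'e' else '10'} corrected PD15 [g/L]")
        ax.legend()
        return ax

    # -- persistence ---------------------------------------------------------
    def to_dict(self) -> dict:
        def law_d(law: DensityLaw) -> dict:
            return {k: getattr(law, k) for k in
                    ("alpha", "beta", "sigma", "se_alpha", "se_beta", "se_sigma", "n")}

        def tr_d(tr: VolumeTranslation) -> dict:
            return {k: getattr(tr, k) for k in
                    ("gamma", "delta", "se_gamma", "se_delta", "n")}

        return {
            "global_law": law_d(self.global_law),
            "regional_laws": {r: law_d(l) for r, l in self.regional_laws.items()},
            "translations": {
                scope: {g: tr_d(tr) for g, tr in by_gender.items()}
                for scope, by_gender in self.translations.items()
            },
            "slope_s": self.slope_s,
            "log_base": self.log_base,
            "n_subjects": self.n_subjects,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "NormativeModel":
        from .errors import SchemaError

        def law_from(d: Mapping, where: str) -> DensityLaw:
            for key in ("alpha", "beta", "sigma"):
                if key not in d:
                    raise SchemaError(f"normative model {where} is missing {key!r}")
            return DensityLaw(
                alpha=float(d["alpha"]), beta=float(d["beta"]), sigma=float(d["sigma"]),
                se_alpha=float(d.get("se_alpha", float("nan"))),
                se_beta=float(d.get("se_beta", float("nan"))),
                se_sigma=float(d.get("se_sigma", float("nan"))),
                n=int(d.get("n", 0)),
            )

        def tr_from(d: Mapping, where: str) -> VolumeTranslation:
            for key in ("gamma", "delta"):
                if key not in d:
                    raise SchemaError(f"normative model {where} is missing {key!r}")
            return VolumeTranslation(
                gamma=float(d["gamma"]), delta=float(d["delta"]),
                se_gamma=float(d.get("se_gamma", float("nan"))),
                se_delta=float(d.get("se_delta", float("nan"))),
                n=int(d.get("n", 0)),
            )

        if "global_law" not in payload or "translations" not in payload:
            raise SchemaError("normative model payload is missing global_law/translations")
        return cls(
            global_law=law_from(payload["global_law"], "global law"),
            regional_laws={r: law_from(d, f"{r} law")
                           for r, d in payload.get("regional_laws", {}).items()},
            translations={
                scope: {g: tr_from(d, f"{scope}/{g} translation")
                        for g, d in by_gender.items()}
                for scope, by_gender in payload["translations"].items()
            },
            slope_s=float(payload.get("slope_s", -1.1)),
            log_base=str(payload.get("log_base", "e")),
            n_subjects=int(payload.get("n_subjects", 0)),
            provenance=str(payload.get("provenance", "")),
        )


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

def _tlc_pred_column(df: pd.DataFrame, coefficients: Optional[Mapping]) -> np.ndarray:
    return np.array([
        predicted_tlc(g, h, coefficients)
        for g, h in zip(df["gender"], df["height"])
    ])


def fit_volume_translation(cohort: pd.DataFrame, scope: str = "global",
                           tlc_coefficients: Optional[Mapping] = None,
                           ) -> dict[str, VolumeTranslation]:
    """OLS of observed CT-volume on predicted TLC, per gender.

    A single-gender cohort yields a translation for that gender only;
    scoring a subject of the absent gender later raises a ScopeError.
    """
    v_col, _ = _scope_columns(scope)
    if v_col not in cohort:
        raise ScopeError(f"cohort lacks column {v_col!r} for scope {scope!r}")
    tlc = _tlc_pred_column(cohort, tlc_coefficients)
    out: dict[str, VolumeTranslation] = {}
    for gender in ("male", "female"):
        sel = (cohort["gender"] == gender).to_numpy()
        n = int(sel.sum())
        if n == 0:
            continue
        if n < 3:
            raise FitError(
                f"volume translation for {gender!r} needs ≥ 3 subjects, got {n}"
            )
        if np.ptp(tlc[sel]) == 0:
            raise FitError(
                f"predicted TLC is constant for {gender!r} (duplicated "
                "subjects?); translation slope unidentifiable"
            )
        x = sm.add_constant(tlc[sel])
        res = sm.OLS(cohort.loc[sel, v_col].to_numpy(dtype=float), x).fit()
        out[gender] = VolumeTranslation(
            gamma=float(res.params[0]), delta=float(res.params[1]),
            se_gamma=float(res.bse[0]), se_delta=float(res.bse[1]), n=n,
        )
    if not out:
        raise FitError("cohort holds no recognized gender values")
    return out


def _corrected_density(cohort: pd.DataFrame, scope: str, slope_s: float,
                       translations: Mapping[str, VolumeTranslation],
                       tlc_coefficients: Optional[Mapping],
                       ) -> tuple[np.ndarray, np.ndarray]:
    """(V_CT,pred, rho_cor) for every cohort row in the given scope."""
    v_col, d_col = _scope_columns(scope)
    for col in (v_col, d_col):
        if col not in cohort:
            raise ScopeError(f"cohort lacks column {col!r} for scope {scope!r}")
    dens = cohort[d_col].to_numpy(dtype=float)
    if np.any(dens <= 0):
        bad = cohort.loc[dens <= 0, "subject_id"].iloc[0] \
            if "subject_id" in cohort else int(np.flatnonzero(dens <= 0)[0])
        raise DomainError(f"non-positive density for subject {bad!r}")
    tlc = _tlc_pred_column(cohort, tlc_coefficients)
    v_pred = np.empty(len(cohort))
    for i, (gender, t) in enumerate(zip(cohort["gender"], tlc)):
        tr = translations.get(gender)
        if tr is None:
            raise ScopeError(f"volume translation for gender {gender!r} unavailable")
        v_pred[i] = tr.predict(t)
    v_obs = cohort[v_col].to_numpy(dtype=float)
    if np.any(v_obs <= 0) or np.any(v_pred <= 0):
        raise DomainError("non-positive lung volume in cohort")
    rho_cor = dens * (v_pred / v_obs) ** slope_s
    return v_pred, rho_cor


def fit_density_regression(cohort: pd.DataFrame, scope: str = "global",
                           slope_s: float = -1.1, log_base: str = "e",
                           translations: Optional[Mapping[str, VolumeTranslation]] = None,
                           tlc_coefficients: Optional[Mapping] = None,
                           min_subjects: int = 10) -> DensityLaw:
    """Fit α, β, σ of the normative density law for one scope.

    Controls are volume-corrected to their predicted CT-volume first, then
    log corrected density is regressed on log predicted volume; σ is the
    residual standard deviation with the n − 2 divisor.
    """
    if len(cohort) < min_subjects:
        raise FitError(
            f"density regression needs ≥ {min_subjects} subjects, got {len(cohort)}"
        )
    if translations is None:
        translations = fit_volume_translation(cohort, scope, tlc_coefficients)
    log = _log_fn(log_base)
    v_pred, rho_cor = _corrected_density(
        cohort, scope, slope_s, translations, tlc_coefficients)
    x = sm.add_constant(log(v_pred))
    res = sm.OLS(log(rho_cor), x).fit()
    sigma = float(np.sqrt(res.mse_resid))
    if sigma <= 1e-12:
        warnings.warn("cohort lies exactly on a log-log line; σ = 0 makes "
                      "Z-scores undefined", DegenerateModelWarning, stacklevel=2)
    n = len(cohort)
    return DensityLaw(
        alpha=float(res.params[0]), beta=float(res.params[1]), sigma=sigma,
        se_alpha=float(res.bse[0]), se_beta=float(res.bse[1]),
        se_sigma=sigma / math.sqrt(2 * (n - 2)) if n > 2 else float("nan"),
        n=n,
    )


class NormativeDensityModel:
    """Model class: a normative cohort plus estimation settings.

    Parameters
    ----------
    data
        Cohort DataFrame with canonical columns (``gender``, ``height``,
        ``v_ct``, ``pd15``; optional regional columns ``v_ct_<region>`` /
        ``pd15_<region>`` and covariates ``age``, ``smoking_status``).
    slope_s
        Sponge-model volume-correction exponent (default −1.1; −1 is the
        strict mass-preserving sponge model).
    log_base
        'e' or '10'; the SMS is invariant to this choice.
    tlc_coefficients
        TLC reference-equation table; defaults to the shipped ECSC/ERS set.
    """

    def __init__(self, data: pd.DataFrame, slope_s: float = -1.1,
                 log_base: str = "e",
                 tlc_coefficients: Optional[Mapping] = None,
                 min_subjects: int = 10, provenance: str = ""):
        if slope_s >= 0:
            raise DomainError("sponge-model slope S must be negative")
        _log_fn(log_base)
        self.data = data.reset_index(drop=True)
        self.slope_s = float(slope_s)
        self.log_base = log_base
        self.tlc_coefficients = (tlc_coefficients
                                 or load_default_tlc_coefficients())
        self.min_subjects = int(min_subjects)
        self.provenance = provenance

    @classmethod
    def from_cohort(cls, path, **kwargs) -> "NormativeDensityModel":
        from .io import read_cohort_frame

        df = read_cohort_frame(path)
        kwargs.setdefault("provenance", f"cohort file {path}")
        return cls(df, **kwargs)

    def _has_regional(self) -> bool:
        return all(c in self.data
                   for r in REGIONS for c in (f"v_ct_{r}", f"pd15_{r}"))

    def fit(self, regional: str | bool = "auto") -> NormativeModel:
        """Estimate all coefficients; returns a :class:`NormativeModel`.

        ``regional='auto'`` fits apical/central/basal sub-models when the
        cohort carries regional columns; ``True`` requires them; ``False``
        fits the global model only.
        """
        fit_regional = (self._has_regional() if regional == "auto"
                        else bool(regional))
        if regional is True and not self._has_regional():
            raise ScopeError("regional fit requested but cohort lacks regional columns")

        translations = {"global": fit_volume_translation(
            self.data, "global", self.tlc_coefficients)}
        global_law = fit_density_regression(
            self.data, "global", self.slope_s, self.log_base,
            translations["global"], self.tlc_coefficients, self.min_subjects)
        regional_laws = {}
        if fit_regional:
            for region in REGIONS:
                translations[region] = fit_volume_translation(
                    self.data, region, self.tlc_coefficients)
                regional_laws[region] = fit_density_regression(
                    self.data, region, self.slope_s, self.log_base,
                    translations[region], self.tlc_coefficients,
                    self.min_subjects)
        return NormativeModel(
            global_law=global_law, translations=translations,
            regional_laws=regional_laws, slope_s=self.slope_s,
            log_base=self.log_base, n_subjects=len(self.data),
            provenance=self.provenance,
        )

    def explore_covariates(self, **kwargs) -> "CovariateReport":
        return explore_covariates(self.data,
                                  tlc_coefficients=self.tlc_coefficients, **kwargs)

    def loocv(self, **kwargs) -> "LoocvResult":
        kwargs.setdefault("slope_s", self.slope_s)
        kwargs.setdefault("log_base", self.log_base)
        kwargs.setdefault("tlc_coefficients", self.tlc_coefficients)
        return loocv_sms(self.data, **kwargs)


# ---------------------------------------------------------------------------
# covariate exploration
# ---------------------------------------------------------------------------

@dataclass
class CovariateStep:
    action: str          # 'add' | 'remove' | 'drop-constant'
    term: str
    p_value: float
    f_value: float


@dataclass
class CovariateReport:
    candidate_terms: tuple[str, ...]
    selected_terms: tuple[str, ...]
    r_squared_final: float
    steps: list[CovariateStep]

    def to_dict(self) -> dict:
        return {
            "candidate_terms": list(self.candidate_terms),
            "selected_terms": list(self.selected_terms),
            "r_squared_final": self.r_squared_final,
            "steps": [vars(s) for s in self.steps],
        }

    def __str__(self) -> str:
        lines = ["Stepwise covariate exploration (response: log PD15)",
                 f"candidates: {', '.join(self.candidate_terms)}"]
        for s in self.steps:
            lines.append(f"  {s.action:<14}{s.term:<20}p={s.p_value:.4g}")
        lines.append(f"selected: {', '.join(self.selected_terms) or '(none)'}")
        lines.append(f"final R^2 = {self.r_squared_final:.3f}")
        return "\n".join(lines)


def _candidate_matrix(cohort: pd.DataFrame,
                      tlc_coefficients: Optional[Mapping]) -> dict[str, np.ndarray]:
    """Candidate design columns keyed by term name (groups share a term)."""
    terms: dict[str, np.ndarray] = {}
    if cohort["gender"].nunique() > 1:
        terms["gender"] = (cohort["gender"] == "female").to_numpy(float)[:, None]
    elif "gender" in cohort:
        terms["gender"] = np.zeros((len(cohort), 1))  # constant; dropped later
    if "smoking_status" in cohort and cohort["smoking_status"].notna().all():
        s = cohort["smoking_status"]
        terms["smoking_status"] = np.column_stack([
            (s == "ex").to_numpy(float), (s == "current").to_numpy(float)])
    if "age" in cohort and cohort["age"].notna().all():
        terms["age"] = cohort["age"].to_numpy(float)[:, None]
    tlc = _tlc_pred_column(cohort, tlc_coefficients)
    v = cohort["v_ct"].to_numpy(float)
    terms["log_v_ct"] = np.log(v)[:, None]
    terms["inspiration_level"] = np.log(v / tlc)[:, None]
    return terms


def explore_covariates(cohort: pd.DataFrame, slentry: float = 0.05,
                       slstay: float = 0.10,
                       tlc_coefficients: Optional[Mapping] = None,
                       ) -> CovariateReport:
    """Stepwise (forward with backward elimination) selection on log PD15.

    Candidates: gender, smoking status, age, log CT-volume and inspiration
    level ``log(V_CT / TLC_pred)``.  Entry requires partial-F p < ``slentry``
    (0.05); after each entry, included terms with p > ``slstay`` (0.10) are
    removed.  Constant candidates are dropped with a warning.
    """
    y = np.log(cohort["pd15"].to_numpy(float))
    terms = _candidate_matrix(cohort, tlc_coefficients)
    steps: list[CovariateStep] = []
    for name in list(terms):
        if np.allclose(np.ptp(terms[name], axis=0), 0):
            warnings.warn(f"candidate covariate {name!r} is constant; dropped",
                          DegenerateModelWarning, stacklevel=2)
            steps.append(CovariateStep("drop-constant", name, float("nan"),
                                       float("nan")))
            del terms[name]

    def fit_terms(names: Sequence[str]):
        cols = [terms[n] for n in names]
        x = np.hstack([np.ones((len(y), 1))] + cols) if cols else \
            np.ones((len(y), 1))
        return sm.OLS(y, x).fit()

    selected: list[str] = []
    current = fit_terms(selected)
    changed = True
    while changed:
        changed = False
        # forward: best entry below slentry
        best = None
        for name in terms:
            if name in selected:
                continue
            trial = fit_terms(selected + [name])
            f, p, _ = trial.compare_f_test(current)
            if p < slentry and (best is None or p < best[1]):
                best = (name, float(p), float(f), trial)
        if best is not None:
            selected.append(best[0])
            steps.append(CovariateStep("add", best[0], best[1], best[2]))
            current = best[3]
            changed = True
        # backward: worst removal above slstay
        worst = None
        for name in selected:
            reduced = fit_terms([n for n in selected if n != name])
            f, p, _ = current.compare_f_test(reduced)
            if p > slstay and (worst is None or p > worst[1]):
                worst = (name, float(p), float(f), reduced)
        if worst is not None:
            selected.remove(worst[0])
            steps.append(CovariateStep("remove", worst[0], worst[1], worst[2]))
            current = worst[3]
            changed = True
    return CovariateReport(
        candidate_terms=tuple(terms), selected_terms=tuple(selected),
        r_squared_final=float(current.rsquared), steps=steps,
    )


# ---------------------------------------------------------------------------
# leave-one-out cross-validation
# ---------------------------------------------------------------------------

@dataclass
class LoocvResult:
    mean_sms: float
    sd_sms: float
    scores: np.ndarray
    subject_ids: tuple[str, ...]

    def to_dict(self) -> dict:
        return {"mean_sms": self.mean_sms, "sd_sms": self.sd_sms,
                "n": len(self.scores)}


def loocv_sms(cohort: pd.DataFrame, slope_s: float = -1.1, log_base: str = "e",
              tlc_coefficients: Optional[Mapping] = None,
              min_subjects: int = 10) -> LoocvResult:
    """Leave-one-out cross-validation of the normalization.

    For every subject the model is refitted on the remaining n − 1 controls
    and the held-out subject's global SMS computed; a well-calibrated
    normalization gives held-out scores with mean ≈ 0 and SD ≈ 1.
    """
    from .sms import score_record  # local import to avoid a cycle

    n = len(cohort)
    if n < 11:
        raise FitError(f"leave-one-out cross-validation needs ≥ 11 subjects, got {n}")
    scores = np.empty(n)
    ids = []
    for i in range(n):
        train = cohort.drop(index=cohort.index[i])
        row = cohort.iloc[i]
        try:
            model = NormativeDensityModel(
                train, slope_s=slope_s, log_base=log_base,
                tlc_coefficients=tlc_coefficients,
                min_subjects=min(min_subjects, n - 1),
            ).fit(regional=False)
            result = score_record(
                subject_id=str(row.get("subject_id", i)), gender=row["gender"],
                height=float(row["height"]), v_ct=float(row["v_ct"]),
                pd15=float(row["pd15"]), model=model,
                tlc_coefficients=tlc_coefficients,
            )
        except Exception as exc:
            raise FitError(f"leave-one-out fold {i} failed: {exc}") from exc
        scores[i] = result.sms_global
        ids.append(str(row.get("subject_id", i)))
    sd = float(np.std(scores, ddof=1))
    if sd == 0.0:
        warnings.warn("held-out SMS has zero variance (duplicated subjects?)",
                      DegenerateModelWarning, stacklevel=2)
    return LoocvResult(mean_sms=float(np.mean(scores)), sd_sms=sd,
                       scores=scores, subject_ids=tuple(ids))
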