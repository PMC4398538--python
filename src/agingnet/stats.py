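"""Age-effect regression and Sobel-Goodman mediation models.

The regression machinery mirrors the conventional two-model design for
cross-sectional aging effects on a connectivity strength ``y``:

* reduced model:  y ~ b0 + b1*Age + b_s*Sex
* full model:     y ~ b0 + b1*Age + b2*Age^2 + b_s*Sex
* adjusted model: either of the above plus mediator / thickness covariates,
  whose age coefficient is the direct (adjusted) age effect.

Coefficients are reported as standardized betas: the outcome and every
continuous predictor are z-scored before fitting, while sex enters as its 0/1
code (standardizing a binary dummy only rescales its own coefficient and
leaves the age terms unchanged).  The quadratic term is the z-score of raw
age squared, not of centered age squared; raw age and age^2 are strongly
collinear over an adult age range, which is why standardized quadratic betas
can exceed 1 in magnitude.  The two parameterisations span the same column
space, so p-values for the quadratic term are identical either way.

Mediation of an age effect through a mediator M uses the normal-theory test
of the indirect effect a*b, where ``a`` is the age coefficient from
M ~ age + sex and ``b`` the mediator coefficient from y ~ age + M + sex:

    z_sobel   = a*b / sqrt(b^2 se_a^2 + a^2 se_b^2)
    z_aroian  : adds   + se_a^2 se_b^2 under the root (conservative)
    z_goodman : adds   - se_a^2 se_b^2 under the root (anti-conservative;
                flagged missing when the radicand is not positive)

A pathway is classified ``full`` mediation when the total age effect and the
Sobel test are significant but the direct (mediator-adjusted) age effect is
not; ``partial`` when the direct effect also remains significant; ``none``
otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


class ModelKind(str, Enum):
    REDUCED = "reduced"
    FULL = "full"
    THICKNESS_ADJUSTED = "thickness_adjusted"


class MediationClass(str, Enum):
    NONE = "none"
    PARTIAL = "partial"
    FULL = "full"


def zscore(x: np.ndarray) -> np.ndarray:
    """Sample z-score (ddof=1)."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot z-score a constant vector")
    return (x - x.mean()) / sd


def _as_vec(x, name: str, n: int | None = None) -> np.ndarray:
    v = np.asarray(x, dtype=float).ravel()
    if np.isnan(v).any():
        raise ValueError(f"{name} contains missing values")
    if n is not None and v.size != n:
        raise ValueError(f"{name} has length {v.size}, expected {n}")
    return v


# ---------------------------------------------------------------------------
# age-effect model


@dataclass
class AgeModelResults:
    """Standardized coefficients and inference for one fitted age model."""

    model: ModelKind
    outcome: str
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    nobs: int
    rsquared: float
    _sm_results: object = field(repr=False, default=None)

    @property
    def beta_age(self) -> float:
        return float(self.params["age"])

    @property
    def beta_age2(self) -> float:
        if "age2" not in self.params:
            raise AttributeError("quadratic term only present in the full model")
        return float(self.params["age2"])

    @property
    def beta_sex(self) -> float:
        return float(self.params["sex"])

    @property
    def p_age(self) -> float:
        return float(self.pvalues["age"])

    def summary(self) -> str:
        head = (
            f"Age model ({self.model.value}) for outcome '{self.outcome}'\n"
            f"n = {self.nobs}, R^2 = {self.rsquared:.4f}\n"
            f"{'term':<16}{'beta':>10}{'se':>10}{'t':>9}{'p':>12}\n"
        )
        rows = "".join(
            f"{name:<16}{self.params[name]:>10.4f}{self.bse[name]:>10.4f}"
            f"{self.tvalues[name]:>9.3f}{self.pvalues[name]:>12.4g}\n"
            for name in self.params.index
        )
        return head + rows


class AgeModel:
    """OLS age-effect model with standardized coefficients.

    Parameters
    ----------
    outcome
        Connectivity strength (or any scalar outcome), one value per subject.
    age
        Age in years.
    sex
        Binary 0/1 code, entered unstandardized as a covariate.
    covariates
        Optional named continuous covariates (e.g. mediator strength or mean
        cortical thickness); each is z-scored.
    """

    MIN_N = {ModelKind.REDUCED: 10, ModelKind.FULL: 12, ModelKind.THICKNESS_ADJUSTED: 10}

    def __init__(
        self,
        outcome,
        age,
        sex,
        covariates: Mapping[str, Sequence[float]] | None = None,
        outcome_name: str = "y",
    ):
        y = _as_vec(outcome, "outcome")
        n = y.size
        self.age = _as_vec(age, "age", n)
        self.sex = _as_vec(sex, "sex", n)
        if not np.isin(self.sex, (0.0, 1.0)).all():
            raise ValueError("sex must be coded 0/1")
        self.outcome = y
        self.outcome_name = outcome_name
        self.covariates = {
            k: _as_vec(v, k, n) for k, v in (covariates or {}).items()
        }
        self.nobs = n

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        outcome: str,
        age_col: str = "age",
        sex_col: str = "sex",
        covariate_cols: Sequence[str] = (),
    ) -> "AgeModel":
        return cls(
            data[outcome],
            data[age_col],
            data[sex_col],
            covariates={c: data[c] for c in covariate_cols},
            outcome_name=outcome,
        )

    def _design(self, kind: ModelKind) -> pd.DataFrame:
        if self.age.std(ddof=1) == 0:
            raise ValueError("age has zero variance")
        cols: dict[str, np.ndarray] = {"age": zscore(self.age)}
        if kind is ModelKind.FULL:
            cols["age2"] = zscore(self.age**2)
        cols["sex"] = self.sex
        for name, v in self.covariates.items():
            cols[name] = zscore(v)
        x = pd.DataFrame(cols)
        rank = np.linalg.matrix_rank(np.column_stack([np.ones(self.nobs), x.to_numpy()]))
        if rank < x.shape[1] + 1:
            bad = [
                c
                for c in x.columns
                if np.linalg.matrix_rank(
                    np.column_stack([np.ones(self.nobs), x.drop(columns=c).to_numpy()])
                )
                == rank
            ]
            raise ValueError(f"design is rank deficient; collinear columns: {bad}")
        return x

    def fit(self, kind: ModelKind | str = ModelKind.REDUCED) -> AgeModelResults:
        kind = ModelKind(kind)
        min_n = self.MIN_N[kind]
        if self.nobs < min_n:
            raise ValueError(f"{kind.value} model needs n >= {min_n}, got {self.nobs}")
        if kind is ModelKind.THICKNESS_ADJUSTED and not self.covariates:
            raise ValueError("adjusted model requires at least one covariate")
        y = zscore(self.outcome)
        x = self._design(kind)
        res = sm.OLS(y, sm.add_constant(x)).fit()
        keep = [c for c in res.params.index if c != "const"]
        return AgeModelResults(
            model=kind,
            outcome=self.outcome_name,
            params=res.params[keep],
            bse=res.bse[keep],
            tvalues=res.tvalues[keep],
            pvalues=res.pvalues[keep],
            nobs=self.nobs,
            rsquared=float(res.rsquared),
            _sm_results=res,
        )


def fit_reduced(y, age, sex, outcome_name: str = "y") -> AgeModelResults:
    """Linear age model: z(y) ~ z(age) + sex."""
    return AgeModel(y, age, sex, outcome_name=outcome_name).fit(ModelKind.REDUCED)


def fit_full(y, age, sex, outcome_name: str = "y") -> AgeModelResults:
    """Quadratic age model: z(y) ~ z(age) + z(age^2) + sex."""
    return AgeModel(y, age, sex, outcome_name=outcome_name).fit(ModelKind.FULL)


def fit_adjusted(
    y, age, sex, covariates: Mapping[str, Sequence[float]], outcome_name: str = "y"
) -> AgeModelResults:
    """Linear age model with extra standardized covariates (direct effect)."""
    return AgeModel(y, age, sex, covariates=covariates, outcome_name=outcome_name).fit(
        ModelKind.THICKNESS_ADJUSTED
    )


# ---------------------------------------------------------------------------
# multiple comparisons


def bonferroni(pvals, alpha: float = 0.05) -> tuple[np.ndarray, float]:
    """Bonferroni correction over a family of m tests.

    Returns ``(adjusted_p, threshold)`` where ``adjusted_p = min(1, m*p)`` and
    ``threshold = alpha/m``; rejecting adjusted p < alpha is identical to
    rejecting raw p < threshold.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    return np.minimum(1.0, m * p), alpha / m


# ---------------------------------------------------------------------------
# mediation


@dataclass
class MediationResults:
    """Sobel-family mediation inference for one age -> mediator -> outcome path."""

    a: float
    se_a: float
    b: float
    se_b: float
    z_sobel: float
    z_aroian: float
    z_goodman: float  # NaN when the Goodman radicand is not positive
    p_sobel: float
    p_aroian: float
    p_goodman: float
    nobs: int
    total: AgeModelResults | None = None
    direct: AgeModelResults | None = None

    @property
    def indirect(self) -> float:
        return self.a * self.b

    def classify(self, alpha: float = 0.05) -> MediationClass:
        if self.total is None or self.direct is None:
            raise ValueError("classification needs the total and direct model fits")
        return classify_mediation(self.total, self.direct, self, alpha)

    def summary(self) -> str:
        lines = [
            f"Sobel-Goodman mediation test (n = {self.nobs})",
            f"  a (age -> mediator)            = {self.a:.4f} (se {self.se_a:.4f})",
            f"  b (mediator -> outcome | age)  = {self.b:.4f} (se {self.se_b:.4f})",
            f"  indirect effect a*b            = {self.indirect:.4f}",
            f"  z_sobel   = {self.z_sobel:.4f}  p = {self.p_sobel:.4g}",
            f"  z_aroian  = {self.z_aroian:.4f}  p = {self.p_aroian:.4g}",
        ]
        if math.isnan(self.z_goodman):
            lines.append("  z_goodman = undefined (non-positive radicand)")
        else:
            lines.append(f"  z_goodman = {self.z_goodman:.4f}  p = {self.p_goodman:.4g}")
        if self.total is not None and self.direct is not None:
            lines.append(
                f"  total age effect  beta = {self.total.beta_age:.4f} "
                f"(p = {self.total.p_age:.4g})"
            )
            lines.append(
                f"  direct age effect beta = {self.direct.beta_age:.4f} "
                f"(p = {self.direct.p_age:.4g})"
            )
            lines.append(f"  classification (alpha=0.05): {self.classify().value}")
        return "\n".join(lines)


def sobel_z_from_paths(a: float, se_a: float, b: float, se_b: float) -> tuple[float, float, float]:
    """(z_sobel, z_aroian, z_goodman) from path estimates and their SEs."""
    base = b * b * se_a * se_a + a * a * se_b * se_b
    cross = se_a * se_a * se_b * se_b
    z_sobel = a * b / math.sqrt(base) if base > 0 else 0.0
    z_aroian = a * b / math.sqrt(base + cross) if base + cross > 0 else 0.0
    rad = base - cross
    z_goodman = a * b / math.sqrt(rad) if rad > 0 else math.nan
    return z_sobel, z_aroian, z_goodman


def _two_tailed_normal_p(z: float) -> float:
    if math.isnan(z):
        return math.nan
    return 2.0 * sps.norm.sf(abs(z))


class MediationModel:
    """Age -> mediator -> outcome mediation model with a sex covariate.

    Fits, on standardized variables,

    * the mediator path    M ~ age + sex           (gives a, se_a)
    * the outcome path     y ~ age + M + sex       (gives b, se_b and the
      direct age effect)
    * the total model      y ~ age + sex

    ``fit()`` returns :class:`MediationResults` carrying the Sobel, Aroian
    and Goodman z statistics with two-tailed normal p-values, plus the total
    and direct age-model fits needed for full/partial classification.
    """

    def __init__(self, age, mediator, outcome, sex, outcome_name: str = "y",
                 mediator_name: str = "mediator"):
        self.age = _as_vec(age, "age")
        n = self.age.size
        self.mediator = _as_vec(mediator, "mediator", n)
        self.outcome = _as_vec(outcome, "outcome", n)
        self.sex = _as_vec(sex, "sex", n)
        if n < 10:
            raise ValueError(f"mediation needs n >= 10, got {n}")
        self.outcome_name = outcome_name
        self.mediator_name = mediator_name
        self.nobs = n

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, mediator: str, outcome: str,
        age_col: str = "age", sex_col: str = "sex",
    ) -> "MediationModel":
        return cls(
            data[age_col], data[mediator], data[outcome], data[sex_col],
            outcome_name=outcome, mediator_name=mediator,
        )

    def fit(self) -> MediationResults:
        med_path = AgeModel(
            self.mediator, self.age, self.sex, outcome_name=self.mediator_name
        ).fit(ModelKind.REDUCED)
        out_model = AgeModel(
            self.outcome,
            self.age,
            self.sex,
            covariates={"mediator": self.mediator},
            outcome_name=self.outcome_name,
        )
        direct = out_model.fit(ModelKind.THICKNESS_ADJUSTED)
        total = AgeModel(
            self.outcome, self.age, self.sex, outcome_name=self.outcome_name
        ).fit(ModelKind.REDUCED)
        a, se_a = med_path.beta_age, float(med_path.bse["age"])
        b, se_b = float(direct.params["mediator"]), float(direct.bse["mediator"])
        z_s, z_a, z_g = sobel_z_from_paths(a, se_a, b, se_b)
        return MediationResults(
            a=a, se_a=se_a, b=b, se_b=se_b,
            z_sobel=z_s, z_aroian=z_a, z_goodman=z_g,
            p_sobel=_two_tailed_normal_p(z_s),
            p_aroian=_two_tailed_normal_p(z_a),
            p_goodman=_two_tailed_normal_p(z_g),
            nobs=self.nobs, total=total, direct=direct,
        )


def sobel_goodman(age, mediator, y, sex) -> MediationResults:
    """Convenience wrapper: fit :class:`MediationModel` and return its results."""
    return MediationModel(age, mediator, y, sex).fit()


def classify_mediation(
    total: AgeModelResults,
    direct: AgeModelResults,
    med: MediationResults,
    alpha: float = 0.05,
) -> MediationClass:
    """Full/partial/none classification of a mediation pathway.

    ``full``: total age effect significant, Sobel significant, direct age
    effect non-significant.  ``partial``: all three significant.  ``none``
    otherwise.
    """
    if total.nobs != direct.nobs or total.nobs != med.nobs:
        raise ValueError(
            f"mismatched sample sizes: total n={total.nobs}, direct n={direct.nobs}, "
            f"mediation n={med.nobs}"
        )
    total_sig = total.p_age < alpha
    sobel_sig = med.p_sobel < alpha
    direct_sig = direct.p_age < alpha
    if total_sig and sobel_sig:
        return MediationClass.PARTIAL if direct_sig else MediationClass.FULL
    return MediationClass.NONE
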